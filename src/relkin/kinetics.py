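"""Catalog of kinetic release models: released fraction as a function of time.

All predictors map days -> dimensionless released fraction. The headline
model is the biphasic Gallagher-Corrigan form with the Gorrasi burst
constant:

    Y(t) = b + Y1 (1 - exp(-k1 t)) + Y2 * exp(-k2 (t2 - t)) / (1 + exp(-k2 (t2 - t)))

i.e. a first-order dissolution stage plus a logistic erosion stage centred
at t2, shifted up by a constant burst offset b. Setting b = 0 recovers the
original Gallagher-Corrigan model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "GCGParams",
    "ModelSpec",
    "MODELS",
    "get_model",
    "gcg_predict",
    "predict",
]


@dataclass(frozen=True)
class GCGParams:
    """Parameters of the Gallagher-Corrigan model with Gorrasi burst offset.

    b, Y1, Y2 are fractions of the loading; k1, k2 are rate constants in
    1/day; t2 is the characteristic time (days) of the erosion stage. The
    asymptotic total release is b + Y1 + Y2, which may slightly exceed 1
    when fractions are normalized to a loading measured with uncertainty.
    """

    b: float
    Y1: float
    k1: float
    Y2: float
    k2: float
    t2: float

    def __post_init__(self) -> None:
        for name in ("b", "Y1", "Y2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("k1", "k2", "t2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    @property
    def total_release(self) -> float:
        """Asymptotic released fraction b + Y1 + Y2."""
        return self.b + self.Y1 + self.Y2

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("b", "Y1", "k1", "Y2", "k2", "t2")}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "GCGParams":
        return cls(b=d["b"], Y1=d["Y1"], k1=d["k1"], Y2=d["Y2"], k2=d["k2"], t2=d["t2"])


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def gcg_predict(params: GCGParams | Mapping[str, float], t) -> np.ndarray | float:
    """Released fraction under the Gallagher-Corrigan/Gorrasi model.

    The logistic erosion term is evaluated with `scipy.special.expit`,
    which is overflow-safe for arbitrarily large |k2 (t2 - t)|.
    """
    if isinstance(params, Mapping):
        params = GCGParams.from_dict(params)
    scalar = np.isscalar(t)
    t = _check_time(t)
    # exp(-k2 (t2 - t)) / (1 + exp(-k2 (t2 - t))) == expit(k2 (t - t2))
    y = (
        params.b
        + params.Y1 * (-np.expm1(-params.k1 * t))
        + params.Y2 * expit(params.k2 * (t - params.t2))
    )
    return float(y) if scalar else y


# ---------------------------------------------------------------------------
# classical models


def _zero_order(p: Sequence[float], t: np.ndarray) -> np.ndarray:
    (k,) = p
    return k * t


def _first_order(p: Sequence[float], t: np.ndarray) -> np.ndarray:
    (k,) = p
    return -np.expm1(-k * t)


def _higuchi(p: Sequence[float], t: np.ndarray) -> np.ndarray:
    (k,) = p
    return k * np.sqrt(t)


def _korsmeyer_peppas(p: Sequence[float], t: np.ndarray) -> np.ndarray:
    k, n = p
    with np.errstate(divide="ignore"):
        return k * np.power(t, n)


def _baker_lonsdale_lhs(m: float) -> float:
    return 1.5 * (1.0 - (1.0 - m) ** (2.0 / 3.0)) - m


def _baker_lonsdale(p: Sequence[float], t: np.ndarray) -> np.ndarray:
    """Fraction m solving (3/2)[1 - (1-m)^(2/3)] - m = k t on [0, 1].

    The left-hand side increases monotonically from 0 at m=0 to 1/2 at m=1,
    so kt >= 1/2 saturates at complete release.
    """
    (k,) = p
    kt = np.atleast_1d(k * t)
    out = np.empty_like(kt)
    for i, target in enumerate(kt):
        if target <= 0:
            out[i] = 0.0
        elif target >= 0.5:
            out[i] = 1.0
        else:
            out[i] = brentq(lambda m: _baker_lonsdale_lhs(m) - target, 0.0, 1.0, xtol=1e-14)
    return out.reshape(np.shape(k * t))


def _weibull(p: Sequence[float], t: np.ndarray) -> np.ndarray:
    alpha, beta = p
    return -np.expm1(-np.power(t, beta) / alpha)


def _gallagher_corrigan(p: Sequence[float], t: np.ndarray) -> np.ndarray:
    y1, k1, y2, k2, t2 = p
    return gcg_predict(GCGParams(b=0.0, Y1=y1, k1=k1, Y2=y2, k2=k2, t2=t2), t)


def _gallagher_corrigan_gorrasi(p: Sequence[float], t: np.ndarray) -> np.ndarray:
    b, y1, k1, y2, k2, t2 = p
    return gcg_predict(GCGParams(b=b, Y1=y1, k1=k1, Y2=y2, k2=k2, t2=t2), t)


@dataclass(frozen=True)
class ModelSpec:
    """A named kinetic model: predictor, parameter names and fitting bounds.

    ``bounds`` gives finite default (lo, hi) per parameter; the fitter may
    tighten data-dependent bounds (e.g. t2's upper limit to the last
    sampling time). ``note`` records the applicability caveat of the form.
    """

    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    fn: Callable[[Sequence[float], np.ndarray], np.ndarray]
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.param_names) != len(self.bounds):
            raise ValueError(f"{self.name}: parameter count does not match bounds")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{self.name}: bounds must be finite with lo < hi")

    @property
    def p(self) -> int:
        return len(self.param_names)


MODELS: dict[str, ModelSpec] = {
    m.name: m
    for m in (
        ModelSpec(
            "zero_order",
            ("k",),
            ((1e-6, 1.2),),
            _zero_order,
            note="constant-rate release; fraction k*t",
        ),
        ModelSpec(
            "first_order",
            ("k",),
            ((1e-4, 10.0),),
            _first_order,
            note="fraction 1 - exp(-k t); bounded above by 1",
        ),
        ModelSpec(
            "higuchi",
            ("k",),
            ((1e-6, 1.2),),
            _higuchi,
            note="matrix diffusion; fraction k*sqrt(t)",
        ),
        ModelSpec(
            "korsmeyer_peppas",
            ("k", "n"),
            ((1e-6, 1.2), (0.01, 1.5)),
            _korsmeyer_peppas,
            note="power law k*t^n; conventionally valid for fraction <= 0.6",
        ),
        ModelSpec(
            "baker_lonsdale",
            ("k",),
            ((1e-6, 0.5),),
            _baker_lonsdale,
            note="spherical-matrix diffusion, implicit in the released fraction",
        ),
        ModelSpec(
            "weibull",
            ("alpha", "beta"),
            ((1e-2, 1e4), (0.05, 5.0)),
            _weibull,
            note="empirical 1 - exp(-t^beta/alpha), no lag time",
        ),
        ModelSpec(
            "gallagher_corrigan",
            ("Y1", "k1", "Y2", "k2", "t2"),
            ((0.0, 1.2), (1e-4, 10.0), (0.0, 1.2), (1e-4, 10.0), (1.0, 365.0)),
            _gallagher_corrigan,
            note="biphasic dissolution + erosion, no burst offset",
        ),
        ModelSpec(
            "gallagher_corrigan_gorrasi",
            ("b", "Y1", "k1", "Y2", "k2", "t2"),
            ((0.0, 1.2), (0.0, 1.2), (1e-4, 10.0), (0.0, 1.2), (1e-4, 10.0), (1.0, 365.0)),
            _gallagher_corrigan_gorrasi,
            note="biphasic model with constant burst offset b",
        ),
    )
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODELS)}") from None


def _coerce_params(model: ModelSpec, params) -> np.ndarray:
    if isinstance(params, Mapping):
        missing = set(model.param_names) - set(params)
        extra = set(params) - set(model.param_names)
        if missing or extra:
            raise ValueError(
                f"{model.name} expects parameters {model.param_names}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        vec = np.array([params[n] for n in model.param_names], dtype=float)
    else:
        vec = np.asarray(params, dtype=float)
        if vec.shape != (model.p,):
            raise ValueError(
                f"{model.name} takes {model.p} parameter(s) {model.param_names}, "
                f"got shape {vec.shape}"
            )
    return vec


def predict(model: str | ModelSpec, params, t) -> np.ndarray | float:
    """Evaluate any cataloged model at time(s) t (days).

    ``params`` may be a sequence in ``model.param_names`` order or a
    name -> value mapping. Raises on unknown model names or wrong arity.
    """
    spec = get_model(model) if isinstance(model, str) else model
    vec = _coerce_params(spec, params)
    scalar = np.isscalar(t)
    t = _check_time(t)
    y = spec.fn(vec, t)
    return float(y) if scalar else np.asarray(y, dtype=float)
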