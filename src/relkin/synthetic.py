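"""Synthetic sample-and-replace release assays.

Generates replicate-level concentration tables with the statistical
structure the analysis assumes: a true cumulative-fraction curve from any
cataloged model, cut into per-interval released amounts, perturbed with
multiplicative noise, and expressed as supernatant concentrations — so
`cumulative_from_samples` exactly inverts the construction at zero noise.

Also carries the published Gallagher-Corrigan/Gorrasi parameter sets and
loadings for the PLGA microsphere formulations the pipeline was designed
around (UDCA/DX mono- and co-loaded, plus the triple-loaded GDNF system),
which drive parameter-recovery tests and the acceptance run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from relkin.assay import AnalyteLoading, ReleaseAssay
from relkin.kinetics import GCGParams, get_model, predict


def default_schedule(end_day: float) -> np.ndarray:
    """Sampling schedule: 24 h, 7 days, then weekly up to end_day inclusive.

    No partial weeks: ``default_schedule(20) -> [1, 7, 14]``.
    """
    if end_day < 7:
        raise ValueError(f"end_day must be >= 7, got {end_day}")
    return np.array([1.0] + [float(d) for d in range(7, int(end_day) + 1, 7)])


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a simulated assay.

    ``params`` maps analyte -> parameter mapping (or `GCGParams`) for
    ``model``; ``noise_cv`` is the coefficient of variation applied
    multiplicatively to each per-interval released amount. The seed is
    mandatory: simulation is deterministic given the config.
    """

    model: str
    params: Mapping[str, Mapping[str, float] | GCGParams]
    loadings: Mapping[str, AnalyteLoading]
    schedule_days: np.ndarray
    seed: int
    sample_mass_mg: float = 5.0
    medium_volume_ml: float = 2.0
    n_replicates: int = 3
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule_days", np.asarray(self.schedule_days, dtype=float))
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if np.any(np.diff(self.schedule_days) <= 0) or np.any(self.schedule_days <= 0):
            raise ValueError("schedule_days must be strictly increasing and > 0")
        if set(self.params) != set(self.loadings):
            raise ValueError(
                f"params and loadings must cover the same analytes: "
                f"{sorted(self.params)} vs {sorted(self.loadings)}"
            )


def _param_vector(model: str, params: Mapping[str, float] | GCGParams) -> dict[str, float]:
    if isinstance(params, GCGParams):
        d = params.as_dict()
        if model == "gallagher_corrigan":
            d.pop("b")
        return d
    return dict(params)


def _check_within_bounds(model: str, params: Mapping[str, float]) -> None:
    spec = get_model(model)
    for name, (lo, hi) in zip(spec.param_names, spec.bounds):
        v = params[name] if name in params else None
        if v is None:
            raise ValueError(f"{model}: missing parameter {name!r}")
        hi_eff = hi if name != "t2" else np.inf  # t2 bound is data-dependent at fit time
        if not lo <= v <= hi_eff:
            raise ValueError(f"{model}: parameter {name}={v} outside bounds [{lo}, {hi}]")


def generate_assay(config: SyntheticConfig) -> ReleaseAssay:
    """Simulate a replicate-level assay from a true release curve.

    Per replicate and analyte the true cumulative fraction F(t_k) is turned
    into per-interval released amounts dA_k = (F(t_k) - F(t_{k-1})) *
    loading * mass (with F = 0 before the first sampling), each perturbed
    multiplicatively with CV = ``noise_cv`` and floored at 0, then reported
    as supernatant concentration dA_k / volume. At zero noise
    `cumulative_from_samples` recovers F(t) exactly.
    """
    rng = np.random.default_rng(config.seed)
    t = config.schedule_days
    rows: list[tuple[float, int, str, float]] = []
    for analyte in sorted(config.params):
        pvec = _param_vector(config.model, config.params[analyte])
        _check_within_bounds(config.model, pvec)
        loading = config.loadings[analyte]
        frac = np.asarray(predict(config.model, pvec, t), dtype=float)
        true_amounts = np.diff(
            np.concatenate([[0.0], frac * loading.loading_per_mg * config.sample_mass_mg])
        )
        for rep in range(1, config.n_replicates + 1):
            if config.noise_cv > 0:
                factors = 1.0 + config.noise_cv * rng.standard_normal(t.size)
                amounts = np.maximum(0.0, true_amounts * factors)
            else:
                amounts = true_amounts
            conc = amounts / config.medium_volume_ml
            rows.extend((t[k], rep, analyte, conc[k]) for k in range(t.size))

    measurements = pd.DataFrame(rows, columns=["time_days", "replicate", "analyte", "concentration"])
    return ReleaseAssay(
        sample_mass_mg=config.sample_mass_mg,
        medium_volume_ml=config.medium_volume_ml,
        analytes={a: config.loadings[a] for a in config.loadings},
        times_days=t,
        measurements=measurements,
        n_replicates=config.n_replicates,
    )


# ---------------------------------------------------------------------------
# published reference parameter sets (formulation, analyte) -> GCGParams

_REFERENCE_ROWS: tuple[tuple[str, str, float, GCGParams], ...] = (
    # formulation, analyte, experimental 24-h burst fraction, fitted params
    ("UDCA-MSs", "UDCA", 0.0458, GCGParams(b=0.0408, Y1=0.2000, k1=0.0087, Y2=0.8550, k2=0.3760, t2=32.80)),
    ("DX-UDCA-MSs", "UDCA", 0.2100, GCGParams(b=0.1442, Y1=0.1264, k1=0.3027, Y2=0.4866, k2=0.3498, t2=30.03)),
    ("DX-UDCA-GDNF-MSs", "UDCA", 0.1018, GCGParams(b=0.0882, Y1=0.1568, k1=0.0469, Y2=0.9481, k2=0.2997, t2=30.37)),
    ("DX-MSs", "DX", 0.0468, GCGParams(b=0.02982, Y1=0.0468, k1=0.4090, Y2=0.6986, k2=0.1337, t2=49.15)),
    ("DX-UDCA-MSs", "DX", 0.1891, GCGParams(b=0.1436, Y1=0.2225, k1=0.2284, Y2=0.3442, k2=0.1661, t2=42.25)),
    ("DX-UDCA-GDNF-MSs", "DX", 0.1543, GCGParams(b=0.1066, Y1=0.3954, k1=0.1157, Y2=0.3442, k2=0.1537, t2=46.71)),
    ("DX-UDCA-GDNF-MSs", "GDNF", 0.2993, GCGParams(b=0.2648, Y1=0.1524, k1=0.1185, Y2=0.2688, k2=0.0885, t2=81.07)),
)

#: measured loadings per formulation and analyte (GDNF in ng/mg, rest µg/mg)
_REFERENCE_LOADINGS: dict[tuple[str, str], AnalyteLoading] = {
    ("UDCA-MSs", "UDCA"): AnalyteLoading("UDCA", 55.55, "ug", 0.5979),
    ("DX-MSs", "DX"): AnalyteLoading("DX", 103.74, "ug", 0.7936),
    ("DX-UDCA-MSs", "UDCA"): AnalyteLoading("UDCA", 49.52, "ug", 0.6515),
    ("DX-UDCA-MSs", "DX"): AnalyteLoading("DX", 95.79, "ug", 0.8612),
    ("DX-UDCA-GDNF-MSs", "UDCA"): AnalyteLoading("UDCA", 52.65, "ug", 0.6427),
    ("DX-UDCA-GDNF-MSs", "DX"): AnalyteLoading("DX", 101.04, "ug", 0.8436),
    ("DX-UDCA-GDNF-MSs", "GDNF"): AnalyteLoading("GDNF", 19.83, "ng", 0.5160),
}


def reference_parameter_sets() -> dict[tuple[str, str], GCGParams]:
    """Published fitted parameter sets keyed by (formulation, analyte)."""
    return {(form, analyte): params for form, analyte, _, params in _REFERENCE_ROWS}


def reference_experimental_burst() -> dict[tuple[str, str], float]:
    """Published model-free 24-h burst fractions keyed by (formulation, analyte)."""
    return {(form, analyte): burst for form, analyte, burst, _ in _REFERENCE_ROWS}


def reference_loadings() -> dict[tuple[str, str], AnalyteLoading]:
    """Measured analyte loadings keyed by (formulation, analyte)."""
    return dict(_REFERENCE_LOADINGS)


def reference_assay_config(
    formulation: str,
    analyte: str,
    seed: int,
    end_day: float = 91,
    n_replicates: int = 3,
    noise_cv: float = 0.0,
) -> SyntheticConfig:
    """Config simulating one published formulation/analyte release study."""
    key = (formulation, analyte)
    sets = reference_parameter_sets()
    if key not in sets:
        raise KeyError(f"no reference parameters for {key}; available: {sorted(sets)}")
    return SyntheticConfig(
        model="gallagher_corrigan_gorrasi",
        params={analyte: sets[key]},
        loadings={analyte: _REFERENCE_LOADINGS[key]},
        schedule_days=default_schedule(end_day),
        seed=seed,
        n_replicates=n_replicates,
        noise_cv=noise_cv,
    )
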