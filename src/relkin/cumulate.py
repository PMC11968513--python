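"""Cumulative release profiles from sample-and-replace measurements.

With full medium replacement at every sampling, the amount released in
interval k is simply ``C_k * V`` (concentration of the removed supernatant
times medium volume), so the cumulative amount at sampling k is the running
sum of those interval amounts. Profiles are normalized per mg of
microspheres and, via the analyte loading, to released fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from relkin.assay import ReleaseAssay


@dataclass
class CumulativeProfile:
    """Per-replicate and mean cumulative release for one analyte.

    Amounts are in the analyte's own unit (``unit``) per mg of
    microspheres. A replicate with a missing measurement has ``NaN``
    cumulative values from that sampling onward (the running sum is
    undefined there); means and SDs use the replicates available at each
    time. ``fraction_released`` is the mean divided by the loading;
    fractions above 1 are carried but flagged via ``exceeds_loading``.
    """

    analyte: str
    times_days: np.ndarray
    per_replicate_cumulative: np.ndarray  # (n_replicates, n_times), unit/mg
    mean_cumulative: np.ndarray
    sd_cumulative: np.ndarray
    fraction_released: np.ndarray
    loading_per_mg: float
    unit: str = "ug"

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.per_replicate_cumulative = np.atleast_2d(
            np.asarray(self.per_replicate_cumulative, dtype=float)
        )
        self.mean_cumulative = np.asarray(self.mean_cumulative, dtype=float)
        self.sd_cumulative = np.asarray(self.sd_cumulative, dtype=float)
        self.fraction_released = np.asarray(self.fraction_released, dtype=float)
        diffs = np.diff(self.per_replicate_cumulative, axis=1)
        if np.any(diffs < -1e-12 * np.maximum(1.0, np.abs(self.per_replicate_cumulative[:, :-1]))):
            raise ValueError(f"replicate cumulative series must be non-decreasing ({self.analyte})")
        if np.any(self.sd_cumulative < 0):
            raise ValueError("sd_cumulative must be >= 0")

    @property
    def exceeds_loading(self) -> np.ndarray:
        """Boolean mask of times where the mean fraction exceeds 1."""
        return self.fraction_released > 1.0

    @property
    def n_replicates(self) -> int:
        return self.per_replicate_cumulative.shape[0]


@dataclass(frozen=True)
class BurstSummary:
    """Model-free 24-h burst: cumulative release at the sampling nearest 1 day."""

    analyte: str
    burst_amount_per_mg: float
    burst_fraction: float
    burst_time_days: float

    def __post_init__(self) -> None:
        if not (0 <= self.burst_fraction <= 1.2):
            raise ValueError(f"burst_fraction must lie in [0, 1.2], got {self.burst_fraction}")


def cumulative_from_samples(assay: ReleaseAssay, analyte: str) -> CumulativeProfile:
    """Build the cumulative release profile of one analyte.

    Per replicate, cumulative amount at sampling k is
    ``sum_{i<=k} C_i * medium_volume_ml / sample_mass_mg``. The mean and SD
    are taken across replicates with data at each time; the fraction is the
    mean divided by the analyte loading.
    """
    if assay.sample_mass_mg <= 0 or assay.medium_volume_ml <= 0:
        raise ValueError("sample mass and medium volume must be positive")
    loading = assay.analytes[analyte] if analyte in assay.analytes else None
    if loading is None:
        raise KeyError(f"analyte {analyte!r} not present in assay ({sorted(assay.analytes)})")

    conc = assay.concentrations(analyte)  # (n_reps, n_times), NaN = missing
    amounts = conc * assay.medium_volume_ml  # amount removed per interval
    cumulative = np.cumsum(amounts, axis=1) / assay.sample_mass_mg  # NaN propagates forward

    mean, sd = _nan_mean_sd(cumulative)
    return CumulativeProfile(
        analyte=analyte,
        times_days=assay.times_days.copy(),
        per_replicate_cumulative=cumulative,
        mean_cumulative=mean,
        sd_cumulative=sd,
        fraction_released=mean / loading.loading_per_mg,
        loading_per_mg=loading.loading_per_mg,
        unit=loading.unit,
    )


def _nan_mean_sd(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mean and sample SD over non-NaN entries; SD 0 for n=1."""
    counts = np.sum(~np.isnan(mat), axis=0)
    if np.any(counts == 0):
        bad = np.where(counts == 0)[0]
        raise ValueError(f"no replicate has data at time index(es) {bad.tolist()}")
    mean = np.nanmean(mat, axis=0)
    sd = np.zeros_like(mean)
    multi = counts > 1
    if np.any(multi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # lone-replicate columns
            sd_all = np.nanstd(mat, axis=0, ddof=1)
        sd[multi] = sd_all[multi]
    return mean, sd


def experimental_burst(profile: CumulativeProfile) -> BurstSummary:
    """24-h burst read directly off the profile (no extrapolation).

    Uses the sampling time nearest 1 day; the schedule must sample within
    [0.5, 1.5] days, otherwise the burst is undefined.
    """
    t = profile.times_days
    idx = int(np.argmin(np.abs(t - 1.0)))
    if not (0.5 <= t[idx] <= 1.5):
        raise ValueError(
            f"no sampling time within [0.5, 1.5] days (earliest is {t[0]} d); burst undefined"
        )
    return BurstSummary(
        analyte=profile.analyte,
        burst_amount_per_mg=float(profile.mean_cumulative[idx]),
        burst_fraction=float(profile.fraction_released[idx]),
        burst_time_days=float(t[idx]),
    )


def interval_release_rate(profile: CumulativeProfile, t_start: float, t_end: float) -> float:
    """Mean release rate (amount/mg/day) over [t_start, t_end].

    Cumulative amounts at the interval ends are linearly interpolated
    between sampling times; both ends must lie within the observed span.
    """
    if t_start >= t_end:
        raise ValueError(f"t_start must be < t_end, got [{t_start}, {t_end}]")
    t = profile.times_days
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError(
            f"interval [{t_start}, {t_end}] outside observed span [{t[0]}, {t[-1]}]"
        )
    lo, hi = np.interp([t_start, t_end], t, profile.mean_cumulative)
    return float((hi - lo) / (t_end - t_start))


# ---------------------------------------------------------------------------
# profile table I/O (CLI artifact format)

PROFILE_COLUMNS = ("time_days", "mean_ug_per_mg", "sd_ug_per_mg", "fraction")


def write_profile(profile: CumulativeProfile, path: str | Path) -> None:
    """Write the mean profile as ``time_days,mean_ug_per_mg,sd_ug_per_mg,fraction``.

    Amount columns are in the analyte's own unit even when that is ng; the
    header is fixed for interoperability.
    """
    df = pd.DataFrame(
        {
            "time_days": profile.times_days,
            "mean_ug_per_mg": profile.mean_cumulative,
            "sd_ug_per_mg": profile.sd_cumulative,
            "fraction": profile.fraction_released,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_profile(path: str | Path, analyte: str = "", unit: str = "ug") -> CumulativeProfile:
    """Read a profile table written by `write_profile`.

    The replicate-level matrix is not stored in the table; the mean series
    stands in as a single pseudo-replicate. The loading is recovered from
    mean/fraction where the fraction is nonzero.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    got = tuple(df.columns)
    if got != PROFILE_COLUMNS:
        raise ValueError(f"unexpected profile header {got}, expected {PROFILE_COLUMNS}")
    mean = df["mean_ug_per_mg"].to_numpy(dtype=float)
    frac = df["fraction"].to_numpy(dtype=float)
    nz = frac > 0
    loading = float(np.median(mean[nz] / frac[nz])) if np.any(nz) else 1.0
    return CumulativeProfile(
        analyte=analyte or Path(path).stem,
        times_days=df["time_days"].to_numpy(dtype=float),
        per_replicate_cumulative=mean[np.newaxis, :],
        mean_cumulative=mean,
        sd_cumulative=df["sd_ug_per_mg"].to_numpy(dtype=float),
        fraction_released=frac,
        loading_per_mg=loading,
        unit=unit,
    )
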