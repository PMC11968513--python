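"""Domain types and file I/O for in vitro release assays.

An assay is a sample-and-replace dissolution experiment: microspheres of
known mass sit in a fixed medium volume, the whole supernatant is removed
and replaced at each sampling time, and the removed supernatant is assayed
for one or more analytes. Concentrations are stored in amount per mL using
each analyte's own mass unit (``ug`` or ``ng``); times are always in days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Fixed column order of the delimited assay file.
MEASUREMENT_COLUMNS = ("time_days", "replicate", "analyte", "concentration")

#: Allowed analyte amount units (per mL for concentrations, per mg for loadings).
AMOUNT_UNITS = ("ug", "ng")


class AssayValidationError(ValueError):
    """Raised when an assay or its file representation violates the contract."""


@dataclass(frozen=True)
class AnalyteLoading:
    """Loading of one analyte in the microspheres.

    Parameters
    ----------
    analyte:
        Analyte label, e.g. ``"DX"``.
    loading_per_mg:
        Amount of analyte per mg of microspheres, in ``unit`` per mg
        (micrograms for small molecules, nanograms for proteins).
    unit:
        Mass unit of the analyte amounts, ``"ug"`` or ``"ng"``.
    entrapment_fraction:
        Encapsulation efficiency as a fraction. Values slightly above 1 are
        permitted (analytical uncertainty can push measured efficiency past
        100%); ``None`` when not measured.
    """

    analyte: str
    loading_per_mg: float
    unit: str = "ug"
    entrapment_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.analyte:
            raise AssayValidationError("analyte label must be non-empty")
        if not np.isfinite(self.loading_per_mg) or self.loading_per_mg <= 0:
            raise AssayValidationError(
                f"loading_per_mg must be > 0, got {self.loading_per_mg!r} for {self.analyte!r}"
            )
        if self.unit not in AMOUNT_UNITS:
            raise AssayValidationError(f"unit must be one of {AMOUNT_UNITS}, got {self.unit!r}")
        if self.entrapment_fraction is not None and not (0 < self.entrapment_fraction <= 1.2):
            raise AssayValidationError(
                f"entrapment_fraction must lie in (0, 1.2], got {self.entrapment_fraction!r}"
            )


@dataclass
class ReleaseAssay:
    """A validated release assay: geometry, loadings, and raw measurements.

    ``measurements`` holds one row per (time, replicate, analyte) cell with a
    ``concentration`` column; missing cells are present with ``NaN``
    concentration rather than silently absent. On construction the table is
    completed to the full (time x replicate x analyte) grid and canonically
    sorted.
    """

    sample_mass_mg: float
    medium_volume_ml: float
    analytes: dict[str, AnalyteLoading]
    times_days: np.ndarray
    measurements: pd.DataFrame
    n_replicates: int

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self._validate_geometry()
        self._validate_times()
        self.measurements = self._normalize_measurements(self.measurements)

    # -- validation ------------------------------------------------------

    def _validate_geometry(self) -> None:
        if not np.isfinite(self.sample_mass_mg) or self.sample_mass_mg <= 0:
            raise AssayValidationError(f"sample_mass_mg must be > 0, got {self.sample_mass_mg!r}")
        if not np.isfinite(self.medium_volume_ml) or self.medium_volume_ml <= 0:
            raise AssayValidationError(
                f"medium_volume_ml must be > 0, got {self.medium_volume_ml!r}"
            )
        if self.n_replicates < 1:
            raise AssayValidationError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if not self.analytes:
            raise AssayValidationError("assay must declare at least one analyte loading")
        for name, loading in self.analytes.items():
            if name != loading.analyte:
                raise AssayValidationError(
                    f"analyte key {name!r} does not match loading label {loading.analyte!r}"
                )

    def _validate_times(self) -> None:
        t = self.times_days
        if t.ndim != 1 or t.size == 0:
            raise AssayValidationError("times_days must be a non-empty 1-D vector")
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise AssayValidationError("times_days must be finite and > 0")
        if np.any(np.diff(t) <= 0):
            raise AssayValidationError(f"times_days must be strictly increasing, got {t.tolist()}")

    def _normalize_measurements(self, df: pd.DataFrame) -> pd.DataFrame:
        missing_cols = set(MEASUREMENT_COLUMNS) - set(df.columns)
        if missing_cols:
            raise AssayValidationError(f"measurements missing columns: {sorted(missing_cols)}")
        df = df.loc[:, list(MEASUREMENT_COLUMNS)].copy()
        df["time_days"] = df["time_days"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["analyte"] = df["analyte"].astype(str)
        df["concentration"] = df["concentration"].astype(float)

        unknown = set(df["analyte"]) - set(self.analytes)
        if unknown:
            raise AssayValidationError(f"measurements reference unknown analytes: {sorted(unknown)}")
        known_times = set(self.times_days.tolist())
        stray = set(df["time_days"]) - known_times
        if stray:
            raise AssayValidationError(
                f"measurements reference times not in times_days: {sorted(stray)}"
            )
        bad_rep = df[(df["replicate"] < 1) | (df["replicate"] > self.n_replicates)]
        if len(bad_rep):
            raise AssayValidationError(
                f"replicate ids must lie in [1, {self.n_replicates}]; "
                f"offending rows: {bad_rep.index.tolist()}"
            )

        if len(df) == 0:
            # genuinely empty assay: no cells to flag, keep the table empty
            return df.reset_index(drop=True)

        dup = df.duplicated(subset=["time_days", "replicate", "analyte"], keep=False)
        if dup.any():
            keys = df.loc[dup, ["time_days", "replicate", "analyte"]].drop_duplicates()
            raise AssayValidationError(
                "duplicate (time, replicate, analyte) rows: "
                + ", ".join(
                    f"(t={r.time_days}, rep={r.replicate}, {r.analyte})"
                    for r in keys.itertuples()
                )
            )
        neg = df[df["concentration"] < 0]
        if len(neg):
            first = neg.iloc[0]
            raise AssayValidationError(
                f"negative concentration {first['concentration']} at "
                f"(t={first['time_days']}, rep={int(first['replicate'])}, {first['analyte']})"
            )

        # Complete to the full grid: absent cells become explicit NaN flags.
        full = pd.MultiIndex.from_product(
            [self.times_days, range(1, self.n_replicates + 1), sorted(self.analytes)],
            names=["time_days", "replicate", "analyte"],
        )
        df = (
            df.set_index(["time_days", "replicate", "analyte"])
            .reindex(full)
            .reset_index()
            .sort_values(["analyte", "replicate", "time_days"], kind="stable")
            .reset_index(drop=True)
        )
        return df

    # -- convenience -----------------------------------------------------

    @property
    def missing_cells(self) -> pd.DataFrame:
        """Rows of the grid whose concentration was never measured."""
        return self.measurements[self.measurements["concentration"].isna()]

    def concentrations(self, analyte: str) -> np.ndarray:
        """Concentration matrix of shape (n_replicates, n_times) for one analyte."""
        if analyte not in self.analytes:
            raise KeyError(f"unknown analyte {analyte!r}; assay has {sorted(self.analytes)}")
        sub = self.measurements[self.measurements["analyte"] == analyte]
        mat = (
            sub.pivot(index="replicate", columns="time_days", values="concentration")
            .reindex(index=range(1, self.n_replicates + 1), columns=self.times_days)
            .to_numpy()
        )
        return mat

    def equals(self, other: "ReleaseAssay") -> bool:
        return (
            self.sample_mass_mg == other.sample_mass_mg
            and self.medium_volume_ml == other.medium_volume_ml
            and self.analytes == other.analytes
            and self.n_replicates == other.n_replicates
            and np.array_equal(self.times_days, other.times_days)
            and self.measurements.equals(other.measurements)
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - delegation
        if not isinstance(other, ReleaseAssay):
            return NotImplemented
        return self.equals(other)


# ---------------------------------------------------------------------------
# metadata config


@dataclass(frozen=True)
class AssayMeta:
    """Assay geometry and per-analyte loadings, as read from a config file."""

    sample_mass_mg: float
    medium_volume_ml: float
    loadings: dict[str, AnalyteLoading] = field(default_factory=dict)


def read_meta(source: str | Path | Mapping) -> AssayMeta:
    """Read assay metadata from a JSON key-value config file (or a mapping).

    Expected keys: ``sample_mass_mg``, ``medium_volume_ml`` and an
    ``analytes`` mapping of label -> ``{loading_per_mg, unit,
    entrapment_fraction?}``.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        raw = json.loads(Path(source).read_text())
    try:
        mass = float(raw["sample_mass_mg"])
        volume = float(raw["medium_volume_ml"])
        analytes = raw["analytes"]
    except KeyError as exc:
        raise AssayValidationError(f"metadata missing required key: {exc}") from exc
    loadings = {
        name: AnalyteLoading(
            analyte=name,
            loading_per_mg=float(spec["loading_per_mg"]),
            unit=str(spec.get("unit", "ug")),
            entrapment_fraction=(
                float(spec["entrapment_fraction"]) if "entrapment_fraction" in spec else None
            ),
        )
        for name, spec in analytes.items()
    }
    return AssayMeta(sample_mass_mg=mass, medium_volume_ml=volume, loadings=loadings)


def write_meta(meta: AssayMeta, path: str | Path) -> None:
    """Serialize metadata to the JSON config format accepted by `read_meta`."""
    payload = {
        "sample_mass_mg": meta.sample_mass_mg,
        "medium_volume_ml": meta.medium_volume_ml,
        "analytes": {
            name: {
                "loading_per_mg": l.loading_per_mg,
                "unit": l.unit,
                **(
                    {"entrapment_fraction": l.entrapment_fraction}
                    if l.entrapment_fraction is not None
                    else {}
                ),
            }
            for name, l in meta.loadings.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# assay file I/O


def read_assay(path: str | Path, meta: AssayMeta | str | Path | Mapping) -> ReleaseAssay:
    """Read a delimited assay file plus metadata into a validated ReleaseAssay.

    The file must be comma-delimited with header
    ``time_days,replicate,analyte,concentration``; an empty concentration
    field marks a missing cell. Duplicate cells, negative concentrations and
    analytes absent from the metadata are rejected.
    """
    if not isinstance(meta, AssayMeta):
        meta = read_meta(meta)
    df = pd.read_csv(path, dtype={"analyte": str}, float_precision="round_trip")
    got = tuple(df.columns)
    if got != MEASUREMENT_COLUMNS:
        raise AssayValidationError(
            f"unexpected header {got}, expected {MEASUREMENT_COLUMNS} in {path}"
        )
    times = np.unique(df["time_days"].to_numpy(dtype=float)) if len(df) else np.array([1.0])
    n_replicates = int(df["replicate"].max()) if len(df) else 1
    return ReleaseAssay(
        sample_mass_mg=meta.sample_mass_mg,
        medium_volume_ml=meta.medium_volume_ml,
        analytes=dict(meta.loadings),
        times_days=np.sort(times),
        measurements=df if len(df) else _empty_measurements(),
        n_replicates=n_replicates,
    )


def _empty_measurements() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_days": pd.Series(dtype=float),
            "replicate": pd.Series(dtype=int),
            "analyte": pd.Series(dtype=str),
            "concentration": pd.Series(dtype=float),
        }
    )


def write_assay(assay: ReleaseAssay, path: str | Path) -> None:
    """Write the assay's measurement table as comma-delimited text.

    Concentrations are rendered with 17 significant digits so a write/read
    round trip reproduces every float bit-for-bit. Missing cells are written
    with an empty concentration field. Rows are in canonical
    (analyte, replicate, time) order; header and column order are fixed.
    """
    path = Path(path)
    lines = [",".join(MEASUREMENT_COLUMNS)]
    for row in assay.measurements.itertuples(index=False):
        conc = "" if np.isnan(row.concentration) else format(row.concentration, ".17g")
        lines.append(f"{format(row.time_days, '.17g')},{int(row.replicate)},{row.analyte},{conc}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise AssayValidationError(f"cannot write assay file {path}: {exc}") from exc


def meta_of(assay: ReleaseAssay) -> AssayMeta:
    """Extract the metadata block of an assay (for round-tripping)."""
    return AssayMeta(
        sample_mass_mg=assay.sample_mass_mg,
        medium_volume_ml=assay.medium_volume_ml,
        loadings=dict(assay.analytes),
    )
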