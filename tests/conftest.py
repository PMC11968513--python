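import numpy as np
import pandas as pd
import pytest

from relkin.assay import AnalyteLoading, ReleaseAssay
from relkin.cumulate import CumulativeProfile


def make_assay(times, conc_by_rep, analyte="DX", mass=5.0, volume=2.0, loading=100.0, unit="ug"):
    """Single-analyte assay from a {replicate: [conc...]} mapping."""
    rows = []
    for rep, concs in conc_by_rep.items():
        for t, c in zip(times, concs):
            rows.append((t, rep, analyte, c))
    return ReleaseAssay(
        sample_mass_mg=mass,
        medium_volume_ml=volume,
        analytes={analyte: AnalyteLoading(analyte, loading, unit)},
        times_days=np.asarray(times, dtype=float),
        measurements=pd.DataFrame(
            rows, columns=["time_days", "replicate", "analyte", "concentration"]
        ),
        n_replicates=max(conc_by_rep),
    )


def make_profile(times, fractions, loading=100.0, analyte="X", unit="ug"):
    """Profile directly from a mean fraction series (one pseudo-replicate)."""
    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    mean = fractions * loading
    return CumulativeProfile(
        analyte=analyte,
        times_days=times,
        per_replicate_cumulative=mean[np.newaxis, :],
        mean_cumulative=mean,
        sd_cumulative=np.zeros_like(mean),
        fraction_released=fractions,
        loading_per_mg=loading,
        unit=unit,
    )


@pytest.fixture
def simple_assay():
    """V=2 mL, mass=5 mg, one replicate, concentrations 1,2,3 ug/mL at 1,7,14 d."""
    return make_assay([1.0, 7.0, 14.0], {1: [1.0, 2.0, 3.0]})
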