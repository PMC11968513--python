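import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relkin.assay import (
    AnalyteLoading,
    AssayValidationError,
    MEASUREMENT_COLUMNS,
    ReleaseAssay,
    meta_of,
    read_assay,
    read_meta,
    write_assay,
    write_meta,
)
from tests.conftest import make_assay


def _write_csv(path, rows):
    lines = [",".join(MEASUREMENT_COLUMNS)]
    lines += [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


META = {
    "sample_mass_mg": 5.0,
    "medium_volume_ml": 2.0,
    "analytes": {"DX": {"loading_per_mg": 100.0, "unit": "ug"}},
}


class TestAnalyteLoading:
    def test_valid(self):
        l = AnalyteLoading("GDNF", 19.83, "ng", 0.516)
        assert l.unit == "ng"

    @pytest.mark.parametrize("loading", [0.0, -1.0, float("nan")])
    def test_rejects_bad_loading(self, loading):
        with pytest.raises(AssayValidationError):
            AnalyteLoading("DX", loading)

    @pytest.mark.parametrize("ee", [0.0, -0.1, 1.3])
    def test_rejects_bad_entrapment(self, ee):
        with pytest.raises(AssayValidationError):
            AnalyteLoading("DX", 10.0, entrapment_fraction=ee)

    def test_entrapment_slightly_above_one_allowed(self):
        AnalyteLoading("DX", 10.0, entrapment_fraction=1.0038)


class TestReadAssay:
    def test_three_row_parse(self, tmp_path):
        path = tmp_path / "a.csv"
        _write_csv(path, [(1, 1, "DX", 0.5), (7, 1, "DX", 1.0), (14, 1, "DX", 1.5)])
        assay = read_assay(path, META)
        assert assay.times_days.tolist() == [1.0, 7.0, 14.0]
        assert assay.n_replicates == 1
        assert len(assay.measurements) == 3

    def test_negative_concentration_rejected(self, tmp_path):
        path = tmp_path / "a.csv"
        _write_csv(path, [(1, 1, "DX", 0.5), (7, 1, "DX", -1.0)])
        with pytest.raises(AssayValidationError, match=r"negative concentration.*t=7"):
            read_assay(path, META)

    def test_duplicate_cell_rejected(self, tmp_path):
        path = tmp_path / "a.csv"
        _write_csv(path, [(1, 1, "DX", 0.5), (1, 1, "DX", 0.6)])
        with pytest.raises(AssayValidationError, match="duplicate"):
            read_assay(path, META)

    def test_unknown_analyte_rejected(self, tmp_path):
        path = tmp_path / "a.csv"
        _write_csv(path, [(1, 1, "UDCA", 0.5)])
        with pytest.raises(AssayValidationError, match="unknown analyte"):
            read_assay(path, META)

    def test_missing_cell_flagged_not_dropped(self, tmp_path):
        path = tmp_path / "a.csv"
        _write_csv(path, [(1, 1, "DX", 0.5), (7, 2, "DX", 1.0), (1, 2, "DX", 0.4), (7, 1, "DX", 0.9)])
        # knock out one cell
        _write_csv(path, [(1, 1, "DX", 0.5), (7, 2, "DX", 1.0), (1, 2, "DX", 0.4)])
        assay = read_assay(path, META)
        assert len(assay.measurements) == 4  # grid completed
        assert len(assay.missing_cells) == 1


class TestValidation:
    def test_non_monotone_times_rejected(self):
        with pytest.raises(AssayValidationError, match="strictly increasing"):
            make_assay([1.0, 7.0, 7.0], {1: [1, 2, 3]})

    def test_nonpositive_time_rejected(self):
        with pytest.raises(AssayValidationError):
            make_assay([0.0, 7.0], {1: [1, 2]})

    def test_zero_mass_rejected(self):
        with pytest.raises(AssayValidationError, match="sample_mass_mg"):
            make_assay([1.0], {1: [1.0]}, mass=0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(AssayValidationError, match="negative"):
            make_assay([1.0, 7.0], {1: [1.0, -0.1]})


class TestWriteAssay:
    def test_empty_assay_header_only(self, tmp_path):
        assay = make_assay([1.0], {1: [0.0]})
        assay.measurements = assay.measurements.iloc[0:0]
        path = tmp_path / "empty.csv"
        write_assay(assay, path)
        assert path.read_text().strip() == ",".join(MEASUREMENT_COLUMNS)

    def test_row_count(self, tmp_path):
        assay = make_assay([1.0, 7.0, 14.0], {1: [1, 2, 3], 2: [1, 2, 3], 3: [1, 2, 3]})
        path = tmp_path / "a.csv"
        write_assay(assay, path)
        assert len(path.read_text().strip().splitlines()) == 1 + 3 * 3 * 1

    def test_unwritable_path(self, tmp_path):
        assay = make_assay([1.0], {1: [1.0]})
        with pytest.raises(AssayValidationError, match="cannot write"):
            write_assay(assay, tmp_path / "no" / "such" / "dir" / "a.csv")

    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(42)
        concs = rng.exponential(1.0, 6)
        assay = make_assay([1.0, 7.0, 14.0], {1: concs[:3], 2: concs[3:]})
        path = tmp_path / "a.csv"
        write_assay(assay, path)
        back = read_assay(path, meta_of(assay))
        assert back.equals(assay)
        np.testing.assert_array_equal(
            back.measurements["concentration"].to_numpy(),
            assay.measurements["concentration"].to_numpy(),
        )


class TestMetaIO:
    def test_round_trip(self, tmp_path):
        meta = meta_of(make_assay([1.0], {1: [1.0]}))
        path = tmp_path / "meta.json"
        write_meta(meta, path)
        assert read_meta(path) == meta

    def test_missing_key(self, tmp_path):
        path = tmp_path / "meta.json"
        path.write_text('{"sample_mass_mg": 5.0}')
        with pytest.raises(AssayValidationError, match="missing required key"):
            read_meta(path)


@settings(max_examples=30, deadline=None)
@given(
    n_times=st.integers(1, 6),
    n_reps=st.integers(1, 4),
    analytes=st.lists(st.sampled_from(["DX", "UDCA", "GDNF"]), min_size=1, unique=True),
    data=st.data(),
)
def test_round_trip_property(tmp_path_factory, n_times, n_reps, analytes, data):
    """read(write(a)) == a over random schedules, replicates and analytes."""
    times = np.cumsum(
        data.draw(st.lists(st.floats(0.5, 10.0), min_size=n_times, max_size=n_times))
    )
    rows = []
    for a in analytes:
        for rep in range(1, n_reps + 1):
            for t in times:
                c = data.draw(st.floats(0.0, 100.0))
                rows.append((t, rep, a, c))
    assay = ReleaseAssay(
        sample_mass_mg=5.0,
        medium_volume_ml=2.0,
        analytes={a: AnalyteLoading(a, 50.0) for a in analytes},
        times_days=times,
        measurements=pd.DataFrame(
            rows, columns=["time_days", "replicate", "analyte", "concentration"]
        ),
        n_replicates=n_reps,
    )
    path = tmp_path_factory.mktemp("rt") / "a.csv"
    write_assay(assay, path)
    assert read_assay(path, meta_of(assay)).equals(assay)
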