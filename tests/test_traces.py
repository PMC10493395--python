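"""Trace container, CSV round-trips, normalization and replicate aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from secflux.exceptions import (
    EmptyInputError,
    GridError,
    NoGrowthError,
    ParameterError,
    SchemaError,
    TraceValidationError,
)
from secflux.traces import (
    KineticTrace,
    aggregate_replicates,
    normalize_trace,
    read_traces,
    read_wide_plate,
    write_traces,
)
from tests.conftest import make_trace


class TestKineticTraceValidation:
    def test_short_trace_rejected(self):
        with pytest.raises(TraceValidationError, match="at least 5"):
            make_trace([0, 1, 2, 3], [0, 1, 2, 3])

    def test_non_monotone_time_rejected(self):
        with pytest.raises(TraceValidationError, match="strictly increasing"):
            make_trace([0, 1, 1, 2, 3], np.zeros(5))

    def test_nonfinite_rejected(self):
        with pytest.raises(TraceValidationError, match="non-finite"):
            make_trace([0, 1, 2, 3, 4], [0, 1, np.nan, 3, 4])

    def test_normalized_bounds_enforced(self):
        with pytest.raises(TraceValidationError, match=r"\[-0.1, 1.1\]"):
            make_trace([0, 1, 2, 3, 4], [0, 0.5, 2.0, 1.0, 1.0], is_normalized=True)

    def test_unknown_assay_rejected(self):
        with pytest.raises(TraceValidationError, match="assay_kind"):
            make_trace([0, 1, 2, 3, 4], np.zeros(5), assay_kind="colorimetry")


class TestCsvRoundTrip:
    def _collection(self):
        t = np.linspace(0, 10, 11)
        return [
            make_trace(t, np.linspace(0, 100, 11), condition_id="DMSO",
                       compound_dose=0.0, replicate=(e, r))
            for e in (1, 2)
            for r in (1, 2, 3)
        ] + [
            make_trace(t, np.linspace(5, 80, 11), condition_id="cmpd",
                       compound_dose=0.05, replicate=(1, 1), assay_kind="elongation")
        ]

    def test_write_then_read_identity(self, tmp_path):
        traces = self._collection()
        path = tmp_path / "traces.csv"
        write_traces(traces, path)
        back = read_traces(path)
        assert len(back) == len(traces)
        key = lambda tr: (tr.condition_id, tr.compound_dose, tr.replicate, tr.assay_kind)
        for a, b in zip(sorted(traces, key=key), sorted(back, key=key)):
            assert key(a) == key(b)
            np.testing.assert_array_equal(a.time, b.time)
            np.testing.assert_array_equal(a.signal, b.signal)

    def test_grouping_two_wells(self, tmp_path):
        rows = []
        for tech in (1, 2):
            for i in range(10):
                rows.append({"time_h": i, "signal": i * tech, "condition": "c",
                             "technical": tech})
        pd.DataFrame(rows).to_csv(tmp_path / "w.csv", index=False)
        traces = read_traces(tmp_path / "w.csv")
        assert len(traces) == 2
        assert all(tr.n_points == 10 for tr in traces)

    def test_duplicated_timepoint_names_group(self, tmp_path):
        rows = [{"time_h": t, "signal": 0.0, "condition": "bad", "technical": 2}
                for t in [0, 1, 2, 2, 3, 4]]
        pd.DataFrame(rows).to_csv(tmp_path / "dup.csv", index=False)
        with pytest.raises(TraceValidationError, match="'bad'.*technical=2"):
            read_traces(tmp_path / "dup.csv")

    def test_missing_column_named(self, tmp_path):
        pd.DataFrame({"time_h": [0, 1], "condition": "c"}).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(SchemaError, match="'signal'"):
            read_traces(tmp_path / "m.csv")

    def test_empty_file(self, tmp_path):
        (tmp_path / "e.csv").write_text("")
        with pytest.raises(EmptyInputError):
            read_traces(tmp_path / "e.csv")

    def test_schema_mapping(self, tmp_path):
        df = pd.DataFrame({"Time": np.arange(6), "FU": np.arange(6.0), "Well": "A1"})
        df.to_csv(tmp_path / "s.csv", index=False)
        traces = read_traces(
            tmp_path / "s.csv", schema={"time_h": "Time", "signal": "FU", "condition": "Well"}
        )
        assert traces[0].condition_id == "A1"

    def test_wide_plate(self, tmp_path):
        sig = pd.DataFrame({"time_h": np.arange(6), "A1": np.arange(6.0), "A2": 2 * np.arange(6.0)})
        sig.to_csv(tmp_path / "sig.csv", index=False)
        pd.DataFrame(
            {"well": ["A1", "A2"], "condition": ["DMSO", "cmpd"], "dose_moleq": [0.0, 0.1]}
        ).to_csv(tmp_path / "layout.csv", index=False)
        traces = read_wide_plate(tmp_path / "sig.csv", tmp_path / "layout.csv")
        assert {tr.condition_id for tr in traces} == {"DMSO", "cmpd"}


class TestNormalization:
    def test_linear_ramp_maps_to_unit_interval(self, linear_ramp_trace):
        out = normalize_trace(linear_ramp_trace, baseline_window=1, plateau_window=1)
        assert out.is_normalized
        assert out.signal[0] == pytest.approx(0.0, abs=1e-12)
        assert out.signal[-1] == pytest.approx(1.0, abs=1e-12)

    def test_quench_invariance(self, linear_ramp_trace):
        """A 23% fluorophore quench (x0.77) leaves the normalized trace unchanged."""
        quenched = make_trace(linear_ramp_trace.time, 0.77 * linear_ramp_trace.signal)
        a = normalize_trace(linear_ramp_trace, 1, 1).signal
        b = normalize_trace(quenched, 1, 1).signal
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        offset=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, scale, offset):
        t = np.linspace(0, 9, 10)
        base = make_trace(t, np.linspace(0, 50, 10))
        moved = make_trace(t, scale * base.signal + offset)
        np.testing.assert_allclose(
            normalize_trace(base, 2, 2).signal,
            normalize_trace(moved, 2, 2).signal,
            rtol=1e-9, atol=1e-9,
        )

    def test_idempotent(self, linear_ramp_trace):
        once = normalize_trace(linear_ramp_trace, 2, 2)
        twice = normalize_trace(once, 2, 2)
        np.testing.assert_allclose(once.signal, twice.signal, atol=1e-12)

    def test_constant_trace_is_no_growth(self):
        tr = make_trace(np.arange(10), np.full(10, 7.0))
        with pytest.raises(NoGrowthError):
            normalize_trace(tr)

    def test_noisy_flat_trace_is_no_growth(self, rng):
        tr = make_trace(np.arange(50), 10 + rng.normal(0, 2.0, 50))
        with pytest.raises(NoGrowthError):
            normalize_trace(tr)

    def test_decreasing_trace_is_no_growth(self):
        tr = make_trace(np.arange(10), np.linspace(10, 0, 10))
        with pytest.raises(NoGrowthError):
            normalize_trace(tr)

    def test_overlapping_windows_rejected(self, linear_ramp_trace):
        with pytest.raises(ParameterError, match="overlap"):
            normalize_trace(linear_ramp_trace, baseline_window=6, plateau_window=6)


class TestAggregation:
    def _triplet(self, signals):
        t = np.arange(6.0)
        return [make_trace(t, s, replicate=(1, i + 1)) for i, s in enumerate(signals)]

    def test_identical_traces_zero_sem(self):
        s = np.linspace(0, 5, 6)
        agg = aggregate_replicates(self._triplet([s, s, s]))
        np.testing.assert_array_equal(agg.mean, s)
        np.testing.assert_allclose(agg.sem, 0.0, atol=1e-15)

    def test_hand_arithmetic(self):
        """Values {0, 0, 3} at a timepoint: mean 1, SEM 1 (n-1 denominator)."""
        sigs = [np.zeros(6), np.zeros(6), np.full(6, 3.0)]
        agg = aggregate_replicates(self._triplet(sigs))
        np.testing.assert_allclose(agg.mean, 1.0)
        np.testing.assert_allclose(agg.sem, 1.0)

    def test_experimental_level_averages_technicals_first(self):
        t = np.arange(6.0)
        traces = [
            make_trace(t, np.full(6, v), replicate=(e, r))
            for e, vals in [(1, (0.0, 2.0)), (2, (4.0, 4.0))]
            for r, v in enumerate(vals, 1)
        ]
        agg = aggregate_replicates(traces, level="experimental")
        assert agg.n == 2
        np.testing.assert_allclose(agg.mean, 2.5)  # mean of exp means 1 and 4
        np.testing.assert_allclose(agg.sem, 1.5)  # sd([1,4])/sqrt(2)

    def test_single_experiment_sem_flagged_not_error(self):
        t = np.arange(6.0)
        agg = aggregate_replicates([make_trace(t, t)], level="experimental")
        assert not agg.sem_defined
        assert np.isnan(agg.sem).all()

    def test_mismatched_grids_error(self):
        a = make_trace(np.arange(6.0), np.arange(6.0))
        b = make_trace(np.arange(6.0) + 0.5, np.arange(6.0))
        with pytest.raises(GridError):
            aggregate_replicates([a, b])

    def test_interpolation_on_union_grid(self):
        a = make_trace(np.arange(6.0), np.arange(6.0))
        b = make_trace(np.arange(6.0) + 0.5, np.arange(6.0) + 0.5)
        agg = aggregate_replicates([a, b], interpolate=True)
        assert agg.time.size == 12
        # both series lie on y = t inside the overlap (edges are held flat)
        inner = (agg.time >= 0.5) & (agg.time <= 5.0)
        np.testing.assert_allclose(agg.mean[inner], agg.time[inner])
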