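"""Correlation matrices, Fisher z, run averaging, network summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemiconn as hc
from hemiconn.connectivity import ZMatrix
from hemiconn.timeseries import TimeSeriesTable

from conftest import brute_force_correlation, pooled_within


def zmatrix_from_values(values, names):
    v = np.asarray(values, dtype=float)
    return ZMatrix(v, names)


class TestCorrelationMatrix:
    def test_self_correlation_and_sign_flip(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        r = hc.correlation_matrix(np.column_stack([x, -x]), ["a", "b"])
        assert r[0, 0] == pytest.approx(1.0)
        assert r[0, 1] == pytest.approx(-1.0)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.standard_normal((40, 5))
        names = [f"r{i}" for i in range(5)]
        ours = hc.correlation_matrix(values, names)
        oracle = brute_force_correlation(values)
        assert np.max(np.abs(ours - oracle)) < 1e-12

    def test_zero_variance_column_named_in_error(self):
        values = np.column_stack([np.random.default_rng(1).standard_normal(10), np.ones(10)])
        with pytest.raises(ValueError, match="flat_roi"):
            hc.correlation_matrix(values, ["ok", "flat_roi"])

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError, match="3 volumes"):
            hc.correlation_matrix(np.ones((2, 2)), ["a", "b"])


class TestFisherZ:
    def test_closed_form_values(self):
        r = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -0.5], [0.5, -0.5, 1.0]])
        z = hc.fisher_z(r, ["a", "b", "c"])
        assert z.values[0, 1] == pytest.approx(0.0)
        assert z.values[0, 2] == pytest.approx(0.5493, abs=1e-4)
        assert z.values[1, 2] == pytest.approx(-0.5493, abs=1e-4)
        assert np.isnan(z.values[0, 0])

    @settings(deadline=None, derandomize=True)
    @given(r=st.floats(-0.999, 0.999))
    def test_odd_function(self, r):
        mat = np.array([[1.0, r], [r, 1.0]])
        neg = np.array([[1.0, -r], [-r, 1.0]])
        zp = hc.fisher_z(mat, ["a", "b"]).values[0, 1]
        zn = hc.fisher_z(neg, ["a", "b"]).values[0, 1]
        assert zp == pytest.approx(-zn)
        assert zp == pytest.approx(np.arctanh(r))

    def test_perfect_correlation_clipped_with_warning(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="clipped"):
            z = hc.fisher_z(r, ["a", "b"])
        assert np.isfinite(z.values[0, 1])

    def test_out_of_range_rejected(self):
        r = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(ValueError, match="outside"):
            hc.fisher_z(r, ["a", "b"])


class TestAverageRuns:
    def test_single_run_unchanged(self):
        z = zmatrix_from_values([[0, 0.3], [0.3, 0]], ["a", "b"])
        out = hc.average_runs([z])
        assert out.values[0, 1] == pytest.approx(0.3)

    def test_mean_in_z_space(self):
        z1 = zmatrix_from_values([[0, 0.2], [0.2, 0]], ["a", "b"])
        z2 = zmatrix_from_values([[0, 0.4], [0.4, 0]], ["a", "b"])
        out = hc.average_runs([z1, z2])
        assert out.values[0, 1] == pytest.approx(0.3)

    def test_label_mismatch_rejected(self):
        z1 = zmatrix_from_values([[0, 0.2], [0.2, 0]], ["a", "b"])
        z2 = zmatrix_from_values([[0, 0.2], [0.2, 0]], ["a", "c"])
        with pytest.raises(ValueError, match="labels"):
            hc.average_runs([z1, z2])


class TestNetworkSummary:
    names6 = ["t1", "t2", "t3", "p1", "p2", "p3"]
    membership6 = {"t1": "ToM", "t2": "ToM", "t3": "ToM", "p1": "PAIN", "p2": "PAIN", "p3": "PAIN"}

    def test_uniform_matrix_gives_equal_means_zero_diff(self):
        v = np.full((6, 6), 0.37)
        np.fill_diagonal(v, 0.0)
        s = hc.summarize_networks(zmatrix_from_values(v, self.names6), self.membership6)
        assert s.within_tom == pytest.approx(0.37)
        assert s.within_pain == pytest.approx(0.37)
        assert s.between == pytest.approx(0.37)
        assert s.diff == pytest.approx(0.0)

    def test_pair_counts_enter_means(self, bilateral_set):
        # 6 ToM + 7 PAIN regions -> 15, 21 and 42 unordered pairs
        n = 13
        rng = np.random.default_rng(7)
        v = rng.standard_normal((n, n)) * 0.1
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        names = bilateral_set.names
        membership = bilateral_set.membership
        s = hc.summarize_networks(zmatrix_from_values(v, names), membership)
        nets = [membership[x] for x in names]
        wt = [v[i, j] for i in range(n) for j in range(i + 1, n) if nets[i] == nets[j] == "ToM"]
        wp = [v[i, j] for i in range(n) for j in range(i + 1, n) if nets[i] == nets[j] == "PAIN"]
        bw = [v[i, j] for i in range(n) for j in range(i + 1, n) if nets[i] != nets[j]]
        assert (len(wt), len(wp), len(bw)) == (15, 21, 42)
        assert s.within_tom == pytest.approx(np.mean(wt))
        assert s.within_pain == pytest.approx(np.mean(wp))
        assert s.between == pytest.approx(np.mean(bw))
        assert s.diff == pytest.approx(np.mean(wt + wp) - np.mean(bw))

    def test_singleton_network_rejected(self):
        names = ["t1", "p1", "p2"]
        membership = {"t1": "ToM", "p1": "PAIN", "p2": "PAIN"}
        v = np.zeros((3, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            hc.summarize_networks(zmatrix_from_values(v, names), membership)

    def test_ordering_invariance(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal((6, 6)) * 0.2
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        base = hc.summarize_networks(zmatrix_from_values(v, self.names6), self.membership6)
        perm = [3, 0, 5, 1, 4, 2]
        vp = v[np.ix_(perm, perm)]
        names_p = [self.names6[i] for i in perm]
        permuted = hc.summarize_networks(zmatrix_from_values(vp, names_p), self.membership6)
        for attr in ("within_tom", "within_pain", "between", "diff"):
            assert getattr(base, attr) == pytest.approx(getattr(permuted, attr))


class TestPlantedStructure:
    def test_within_exceeds_between_every_seed(self, planted_recovery):
        for s in planted_recovery["summaries"]["bilateral"]:
            assert s.diff > 0

    def test_lateralized_variants_agree_on_symmetric_data(self, planted_recovery):
        # planted structure is hemispherically symmetric: left- and right-
        # variant summaries estimate the same quantity
        # each lateralized variant has 5 ToM (10 pairs) and 4 PAIN (6 pairs) regions
        left = np.mean([pooled_within(s, 10, 6) for s in planted_recovery["summaries"]["left"]])
        right = np.mean([pooled_within(s, 10, 6) for s in planted_recovery["summaries"]["right"]])
        assert abs(left - right) < 0.05
        lb = np.mean([s.between for s in planted_recovery["summaries"]["left"]])
        rb = np.mean([s.between for s in planted_recovery["summaries"]["right"]])
        assert abs(lb - rb) < 0.05


class TestSubjectReport:
    def _tables(self, seed=0, runs=2):
        rng = np.random.default_rng(seed)
        names = ["t1", "t2", "p1", "p2"]
        return [
            TimeSeriesTable(rng.standard_normal((30, 4)), 0.7, names, f"run{i+1}")
            for i in range(runs)
        ]

    membership = {"t1": "ToM", "t2": "ToM", "p1": "PAIN", "p2": "PAIN"}

    def test_shape_contract(self):
        rec = hc.subject_report(self._tables(runs=1), self.membership, "bilateral")
        assert rec.zmatrix.values.shape == (4, 4)
        assert rec.n_runs == 1
        for v in rec.summary.as_dict().values():
            assert np.isfinite(v)

    def test_two_runs_equal_average_of_per_run_matrices(self):
        tables = self._tables(runs=2)
        rec = hc.subject_report(tables, self.membership, "bilateral")
        per_run = [hc.zmatrix_from_timeseries(t) for t in tables]
        avg = hc.average_runs(per_run)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(rec.zmatrix.values[off], avg.values[off])

    def test_record_round_trips_through_json(self, tmp_path):
        rec = hc.subject_report(self._tables(), self.membership, "left", subject="S1", qc={"mean_fd_power": 0.12})
        path = tmp_path / "record.json"
        rec.to_json(path)
        back = type(rec).from_json(path)
        assert back.subject == "S1" and back.variant == "left"
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(back.zmatrix.values[off], rec.zmatrix.values[off])
        assert back.summary.as_dict() == pytest.approx(rec.summary.as_dict())
        assert back.qc == rec.qc
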