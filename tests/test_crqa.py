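"""Cross-recurrence matrices, radius calibration, line measures.

Every quantitative operation is checked against an independent brute-force
oracle: exhaustive run-length scanning for line histograms, direct summation
for the measures, and a sorted-distance scan for the calibrated radius.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import cdist

import swayrqa as sq
from swayrqa.crqa import (
    CrossRecurrence,
    EpochTooShortError,
    LineHistogram,
    RecurrenceMatrix,
    calibrate_radius,
    crqa_measures,
    cross_recurrence_matrix,
    line_histograms,
    recurrence_rate,
)
from swayrqa.embedding import EmbeddedTrajectory, EmbeddingParams, delay_embed

from conftest import sinusoid


# ---------------------------------------------------------------------------
# independent oracles


def brute_run_lengths(mat, direction):
    """Exhaustive scan of maximal 1-runs along every diagonal or column."""
    rows, cols = mat.shape
    if direction == "diagonal":
        lines = [np.diagonal(mat, k) for k in range(-(rows - 1), cols)]
    else:
        lines = [mat[:, j] for j in range(cols)]
    lengths = []
    for line in lines:
        run = 0
        for v in line:
            if v:
                run += 1
            elif run:
                lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    return lengths


def brute_measures(mat, d_min=2, v_min=2):
    """Direct-summation recomputation of DET/LAM/means/entropies."""
    total = int(mat.sum())
    out = {}
    for direction, mn in (("diagonal", d_min), ("vertical", v_min)):
        lens = [l for l in brute_run_lengths(mat, direction) if l >= mn]
        w = sum(lens)
        frac = w / total if total else 0.0
        mean = w / len(lens) if lens else 0.0
        if lens:
            _, counts = np.unique(lens, return_counts=True)
            p = counts / counts.sum()
            ent = float(-(p * np.log(p)).sum())
        else:
            ent = 0.0
        out[direction] = (frac, mean, ent)
    return out


def embed1(x):
    return EmbeddedTrajectory(np.asarray(x, float).reshape(-1, 1), m=1, tau=1)


def random_matrix(rng, n_max=20):
    n = rng.integers(2, n_max + 1)
    return rng.random((n, n)) < rng.uniform(0.1, 0.6)


# ---------------------------------------------------------------------------


class TestCrossRecurrenceMatrix:
    def test_identical_trajectories_main_diagonal(self):
        a = delay_embed(sinusoid(duration=3.0), EmbeddingParams(m=2, tau=10))
        rm = cross_recurrence_matrix(a, a, radius=1e-9)
        assert np.all(np.diagonal(rm.R))

    def test_huge_radius_all_ones(self):
        a = embed1([0.0, 1.0, 2.0])
        b = embed1([5.0, 6.0, 7.0])
        rm = cross_recurrence_matrix(a, b, radius=100.0)
        assert rm.R.all()
        assert recurrence_rate(rm) == 1.0

    def test_three_point_toy_hand_computed(self):
        # a = {0,1,2}, b = {0,2,2}, radius 0.5:
        # rows (1,0,0), (0,0,0), (0,1,1); RR = 3/9
        rm = cross_recurrence_matrix(embed1([0, 1, 2]), embed1([0, 2, 2]), 0.5)
        expected = np.array([[1, 0, 0], [0, 0, 0], [0, 1, 1]], dtype=bool)
        np.testing.assert_array_equal(rm.R, expected)
        assert recurrence_rate(rm) == pytest.approx(3 / 9)

    def test_mismatched_embedding_rejected(self):
        a = delay_embed(sinusoid(duration=3.0), EmbeddingParams(m=2, tau=10))
        b = delay_embed(sinusoid(duration=3.0), EmbeddingParams(m=3, tau=10))
        with pytest.raises(ValueError, match="embedding parameters differ"):
            cross_recurrence_matrix(a, b, 0.1)

    def test_inclusive_threshold(self):
        rm = cross_recurrence_matrix(embed1([0.0]), embed1([0.5]), 0.5)
        assert rm.R[0, 0]


class TestCalibrateRadius:
    def test_matches_sorted_distance_oracle(self):
        rng = np.random.default_rng(7)
        a = EmbeddedTrajectory(rng.normal(size=(200, 3)), m=3, tau=1)
        b = EmbeddedTrajectory(rng.normal(size=(200, 3)), m=3, tau=1)
        cal = calibrate_radius(a, b, target_rr=0.025)
        assert cal.converged
        assert abs(cal.achieved_rr - 0.025) <= 0.001
        # oracle: k-th smallest of all N^2 distances, k = ceil(0.025 N^2)
        d = np.sort(cdist(a.points, b.points).ravel())
        k = int(np.ceil(0.025 * d.size))
        oracle_radius = d[k - 1]
        oracle_rr = np.searchsorted(d, cal.radius, side="right") / d.size
        assert cal.achieved_rr == pytest.approx(oracle_rr, abs=1e-12)
        assert abs(np.searchsorted(d, oracle_radius, side="right") / d.size - 0.025) <= 1 / d.size + 1e-12

    def test_saturation_for_target_near_one(self):
        rng = np.random.default_rng(1)
        a = EmbeddedTrajectory(rng.normal(size=(50, 2)), m=2, tau=1)
        b = EmbeddedTrajectory(rng.normal(size=(50, 2)), m=2, tau=1)
        cal = calibrate_radius(a, b, target_rr=0.999)
        d = cdist(a.points, b.points)
        assert (d <= cal.radius).mean() >= 0.998

    def test_rr_monotone_in_radius(self):
        rng = np.random.default_rng(2)
        a = EmbeddedTrajectory(rng.normal(size=(60, 2)), m=2, tau=1)
        b = EmbeddedTrajectory(rng.normal(size=(60, 2)), m=2, tau=1)
        radii = np.linspace(0.01, 4.0, 20)
        rrs = [
            recurrence_rate(cross_recurrence_matrix(a, b, r)) for r in radii
        ]
        assert np.all(np.diff(rrs) >= 0)

    def test_unreachable_target_flagged(self):
        # two distinct distances only: RR jumps from 1/4 to 1/2 to 1; a target
        # between the achievable plateaus cannot converge
        a = embed1([0.0, 10.0])
        b = embed1([0.0, 10.0])
        cal = calibrate_radius(a, b, target_rr=0.3, tol=0.001)
        assert not cal.converged
        assert cal.achieved_rr in (0.25, 0.5)

    def test_invalid_target_rejected(self):
        a = embed1([0.0, 1.0])
        with pytest.raises(ValueError):
            calibrate_radius(a, a, target_rr=1.5)


class TestLineHistograms:
    def test_identity_matrix_single_full_diagonal(self):
        rm = RecurrenceMatrix(np.eye(8, dtype=bool), radius=0.1)
        h = line_histograms(rm, "diagonal")
        assert h.counts[8] == 1
        assert h.counts[:8].sum() == 0

    def test_all_ones_vertical(self):
        rm = RecurrenceMatrix(np.ones((5, 5), dtype=bool), radius=1.0)
        h = line_histograms(rm, "vertical")
        assert h.counts[5] == 5
        assert h.total_points() == 25

    def test_against_brute_force_scanner(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mat = random_matrix(rng)
            rm = RecurrenceMatrix(mat, radius=0.5)
            for direction in ("diagonal", "vertical"):
                h = line_histograms(rm, direction)
                oracle = np.bincount(
                    brute_run_lengths(mat, direction), minlength=h.counts.size
                )
                np.testing.assert_array_equal(h.counts, oracle[: h.counts.size])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        arrays(
            np.bool_,
            st.tuples(st.integers(1, 12), st.integers(1, 12)),
        )
    )
    def test_conservation_property(self, mat):
        # sum of l*H(l) over all lengths equals the recurrent point count,
        # in both directions, for any binary matrix
        rm = RecurrenceMatrix(mat, radius=1.0)
        for direction in ("diagonal", "vertical"):
            h = line_histograms(rm, direction)
            assert h.total_points() == int(mat.sum())


class TestCrqaMeasures:
    @staticmethod
    def _measures(mat, **kw):
        rm = RecurrenceMatrix(mat, radius=1.0)
        h_d = line_histograms(rm, "diagonal", kw.pop("d_min", 2))
        h_v = line_histograms(rm, "vertical", kw.pop("v_min", 2))
        return crqa_measures(rm, h_d, h_v, **kw)

    def test_single_full_diagonal_is_pure_determinism(self):
        mat = np.eye(10, dtype=bool)
        res = self._measures(mat)
        assert res.det == pytest.approx(1.0)
        assert res.mean_diag == pytest.approx(10.0)
        assert res.ent_diag == pytest.approx(0.0)

    def test_isolated_points_give_zero_det_and_lam(self):
        mat = np.zeros((9, 9), dtype=bool)
        mat[0, 4] = mat[4, 0] = mat[8, 8] = True
        res = self._measures(mat)
        assert res.det == 0.0 and res.lam == 0.0
        assert res.mean_diag == 0.0 and res.ent_vert == 0.0

    def test_against_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            mat = random_matrix(rng)
            res = self._measures(mat)
            oracle = brute_measures(mat)
            for got, want in [
                (res.det, oracle["diagonal"][0]),
                (res.mean_diag, oracle["diagonal"][1]),
                (res.ent_diag, oracle["diagonal"][2]),
                (res.lam, oracle["vertical"][0]),
                (res.mean_vert, oracle["vertical"][1]),
                (res.ent_vert, oracle["vertical"][2]),
            ]:
                assert got == pytest.approx(want, abs=1e-12)

    def test_det_lam_nondecreasing_when_min_len_lowered(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            mat = random_matrix(rng)
            loose = self._measures(mat, d_min=1, v_min=1)
            strict = self._measures(mat, d_min=3, v_min=3)
            assert loose.det >= strict.det
            assert loose.lam >= strict.lam

    def test_entropy_in_bits_option(self):
        rng = np.random.default_rng(12)
        mat = random_matrix(rng)
        nats = self._measures(mat)
        bits = self._measures(mat, bits=True)
        assert bits.ent_diag == pytest.approx(nats.ent_diag / np.log(2))

    def test_histogram_matrix_mismatch_rejected(self):
        rm = RecurrenceMatrix(np.eye(5, dtype=bool), radius=1.0)
        wrong = LineHistogram("diagonal", np.array([0, 0, 0, 1]), 2)
        h_v = line_histograms(rm, "vertical")
        with pytest.raises(ValueError, match="mismatch"):
            crqa_measures(rm, wrong, h_v)


class TestCrqaEpoch:
    def test_identical_sinusoids_fully_deterministic(self):
        ts = sinusoid(freq=0.5, duration=20.0)
        res = sq.crqa_epoch(ts, ts, EmbeddingParams(m=3, tau=25))
        assert res.det >= 1.0 - 1e-6
        assert res.mean_diag > 50

    def test_tightly_coupled_low_frequency_epoch(self):
        # 0.2 Hz, no decoupling, small noise: nearly 100% determinism
        proto = sq.Protocol((sq.ProtocolEpoch("0.2Hz", 0.2, 30.0),), fs=100.0)
        plat = sq.generate_platform(proto)
        params = sq.CouplingParams(p_decouple=0.0, noise_sd=0.05, seed=0)
        com = sq.generate_com(plat, proto, params)
        res = sq.crqa_epoch(com, plat, EmbeddingParams(m=6, tau=25))
        assert res.det >= 0.99

    def test_achieved_rate_near_target(self):
        proto = sq.Protocol((sq.ProtocolEpoch("0.6Hz", 0.6, 10.0),), fs=100.0)
        plat = sq.generate_platform(proto)
        com = sq.generate_com(plat, proto, sq.CouplingParams(seed=4))
        res = sq.crqa_epoch(com, plat, EmbeddingParams(m=6, tau=25))
        assert abs(res.rr - 0.025) <= 0.001

    def test_too_short_epoch_raises(self):
        ts = sinusoid(duration=1.0)  # 100 samples < (m-1)*tau
        with pytest.raises(EpochTooShortError):
            sq.crqa_epoch(ts, ts, EmbeddingParams(m=6, tau=25))

    def test_results_object_summary_and_export(self, tmp_path):
        ts = sinusoid(freq=0.5, duration=15.0)
        model = CrossRecurrence(ts, ts, EmbeddingParams(m=2, tau=25), label="demo")
        res = model.fit()
        text = res.summary()
        assert "%determinism" in text and "radius" in text
        pbm = tmp_path / "plot.pbm"
        res.save_pbm(pbm)
        head = pbm.read_text().splitlines()
        assert head[0] == "P1"
        n_cols, n_rows = map(int, head[1].split())
        assert (n_rows, n_cols) == res.matrix.shape
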