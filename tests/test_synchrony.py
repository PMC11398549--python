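import numpy as np
import pytest
from scipy import signal as sps

from fibsym.graphs_io import NodeColoring
from fibsym.synchrony import (
    ClusterSet,
    PhaseSeries,
    PLVMatrix,
    cluster_plv,
    cs_to_coloring,
    detect_cs,
    group_average,
    instantaneous_phase,
    plv,
    plv_matrix,
    surrogate_pvalues,
)


def make_plv(labels, default, blocks):
    """Helper: symmetric PLV matrix with given block values."""
    n = len(labels)
    v = np.full((n, n), default)
    np.fill_diagonal(v, 1.0)
    idx = {lab: i for i, lab in enumerate(labels)}
    for (a, b), val in blocks.items():
        v[idx[a], idx[b]] = v[idx[b], idx[a]] = val
    return PLVMatrix(tuple(labels), v)


# ---------------------------------------------------------------------------
# phases


class TestInstantaneousPhase:
    def test_sinusoid_phase_advances_at_signal_frequency(self):
        dt, f, T = 0.5, 0.2, 400
        t = np.arange(T) * dt
        x = np.cos(2 * np.pi * f * t)[:, None]
        ps = instantaneous_phase(x, ["a"], dt=dt)
        dphi = np.diff(np.unwrap(ps.phases[:, 0]))[50:-50]  # trim transients
        assert np.allclose(dphi, 2 * np.pi * f * dt, atol=1e-3)

    def test_quadrature_pair_locks_at_pi_over_2(self):
        dt, f, T = 0.5, 0.1, 600
        t = np.arange(T) * dt
        x = np.column_stack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)])
        ps = instantaneous_phase(x, ["c", "s"], dt=dt)
        lag = np.angle(np.exp(1j * (ps.phases[:, 0] - ps.phases[:, 1])))[50:-50]
        assert np.allclose(lag, np.pi / 2, atol=1e-2)

    def test_bandpass_attenuates_out_of_band_by_20db(self):
        # filter design check at the fMRI sampling regime (TR = 2.5 s)
        sos = sps.butter(4, [0.01, 0.1], btype="bandpass", fs=1 / 2.5, output="sos")
        w, h = sps.sosfreqz(sos, worN=4096, fs=1 / 2.5)
        gain_db = 20 * np.log10(np.maximum(np.abs(h), 1e-12))
        # forward-backward application doubles the attenuation
        gain_db = 2 * gain_db
        stop = (w < 0.003) | (w > 0.17)
        assert gain_db[stop].max() <= -20.0

    def test_constant_series_rejected(self):
        x = np.ones((100, 1))
        with pytest.raises(ValueError, match="constant"):
            instantaneous_phase(x, ["a"], dt=1.0)

    @pytest.mark.parametrize("band", [(0.0, 0.1), (0.1, 0.01), (0.01, 0.3)])
    def test_invalid_band_rejected(self, band):
        x = np.random.default_rng(0).standard_normal((64, 1))
        with pytest.raises(ValueError):
            instantaneous_phase(x, ["a"], dt=2.5, band=band)


# ---------------------------------------------------------------------------
# PLV


class TestPLV:
    def test_identical_phases_give_one(self):
        p = np.random.default_rng(1).uniform(0, 2 * np.pi, 160)
        assert plv(p, p) == pytest.approx(1.0)

    def test_constant_offset_gives_one(self):
        p = np.random.default_rng(2).uniform(0, 2 * np.pi, 160)
        assert plv(p, p + np.pi / 3) == pytest.approx(1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        pa, pb = rng.uniform(0, 2 * np.pi, (2, 160))
        assert plv(pa + 1.23, pb + 1.23) == pytest.approx(plv(pa, pb))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            plv(np.zeros(10), np.zeros(11))

    def test_independent_uniform_phases_mean_matches_rayleigh(self):
        # Monte-Carlo oracle: E[PLV] for T independent uniform phase
        # differences is ~ sqrt(pi / (4 T)); T = 160 gives ~0.0700
        rng = np.random.default_rng(42)
        T, reps = 160, 10_000
        z = np.exp(1j * rng.uniform(0, 2 * np.pi, (reps, T)))
        vals = np.abs(z.mean(axis=1))
        expected = np.sqrt(np.pi / (4 * T))
        assert expected == pytest.approx(0.0700, abs=5e-4)
        assert vals.mean() == pytest.approx(expected, abs=2e-3)


class TestPLVMatrix:
    def test_single_roi_gives_unit_matrix(self):
        ps = PhaseSeries(("a",), np.linspace(0, 5, 50)[:, None], 1.0)
        m = plv_matrix(ps)
        assert m.values.shape == (1, 1) and m.values[0, 0] == 1.0

    def test_entrywise_agreement_with_pairwise_plv(self):
        rng = np.random.default_rng(9)
        ph = rng.uniform(0, 2 * np.pi, (160, 4))
        ps = PhaseSeries(tuple("abcd"), ph, 1.0)
        m = plv_matrix(ps)
        for i in range(4):
            for j in range(4):
                assert m.values[i, j] == pytest.approx(
                    plv(ph[:, i], ph[:, j]), abs=1e-12
                )

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            PLVMatrix(("a", "b"), np.array([[1.0, 0.2], [0.3, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            PLVMatrix(("a", "b"), np.array([[0.9, 0.2], [0.2, 1.0]]))


class TestGroupAverage:
    def test_average_of_identical_matrices_is_identity_op(self):
        m = make_plv(["a", "b"], 0.6, {})
        avg = group_average([m, m, m])
        assert np.allclose(avg.values, m.values)

    def test_arithmetic_mean_of_entries(self):
        m1 = make_plv(["a", "b"], 0.6, {})
        m2 = make_plv(["a", "b"], 0.8, {})
        assert group_average([m1, m2]).values[0, 1] == pytest.approx(0.7)

    def test_label_mismatch_rejected(self):
        m1 = make_plv(["a", "b"], 0.6, {})
        m2 = make_plv(["a", "c"], 0.6, {})
        with pytest.raises(ValueError, match="label mismatch"):
            group_average([m1, m2])


# ---------------------------------------------------------------------------
# surrogate test


class TestSurrogatePValues:
    def test_identical_pair_is_maximally_significant(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(160)
        series = np.column_stack([x, x])
        res = surrogate_pvalues(series, ["a", "b"], dt=1.0, n_perm=200, seed=1,
                                tail_fit=False)
        assert res.pvalues[("a", "b")] <= 1 / 201 + 1e-12
        assert res.significant[("a", "b")]

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(5)
        series = rng.standard_normal((160, 3))
        r1 = surrogate_pvalues(series, ["a", "b", "c"], dt=1.0, n_perm=120, seed=7)
        r2 = surrogate_pvalues(series, ["a", "b", "c"], dt=1.0, n_perm=120, seed=7)
        assert r1.pvalues == r2.pvalues
        assert r1.significant == r2.significant

    def test_type_one_error_near_nominal_alpha(self):
        # 500 independent white-noise pairs; uncorrected rejection rate at
        # alpha = 0.05 should be 0.05 +/- 0.02
        rng = np.random.default_rng(11)
        alpha, rejections, reps = 0.05, 0, 500
        for _ in range(reps):
            series = rng.standard_normal((160, 2))
            res = surrogate_pvalues(series, ["a", "b"], dt=1.0, n_perm=199,
                                    seed=int(rng.integers(2**31)), tail_fit=False)
            rejections += res.pvalues[("a", "b")] <= alpha
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_n_perm_floor(self):
        with pytest.raises(ValueError, match="n_perm"):
            surrogate_pvalues(np.zeros((160, 2)) + np.arange(160)[:, None],
                              ["a", "b"], dt=1.0, n_perm=10)


# ---------------------------------------------------------------------------
# CS detection


class TestDetectCS:
    def test_strong_triangle_dominates_weak_background(self):
        m = make_plv(
            list("ABCDE"), 0.2,
            {("A", "B"): 0.9, ("A", "C"): 0.9, ("B", "C"): 0.9},
        )
        cs = detect_cs(m)
        assert cs.cliques[0] == frozenset({"A", "B", "C"})
        assert cs.cluster_plvs[0] == pytest.approx(0.9)

    def test_two_clique_freezes_against_weaker_boundary(self):
        m = make_plv(["n1", "n2", "n3"], 0.3, {("n1", "n2"): 0.9, ("n1", "n3"): 0.5})
        cs = detect_cs(m)
        assert frozenset({"n1", "n2"}) in cs.cliques

    def test_all_equal_entries_give_single_all_node_cs(self):
        m = make_plv(list("abcd"), 0.5, {})
        cs = detect_cs(m)
        assert cs.cliques == (frozenset({"a", "b", "c", "d"}),)
        assert cs.singletons == frozenset()

    def test_cliques_disjoint_cover_and_ordered_by_strength(self):
        rng = np.random.default_rng(21)
        labels = tuple(f"r{i}" for i in range(8))
        for _ in range(30):
            a = rng.uniform(0.1, 0.9, (8, 8))
            v = (a + a.T) / 2
            np.fill_diagonal(v, 1.0)
            cs = detect_cs(PLVMatrix(labels, v))
            seen = set()
            for c in cs.cliques:
                assert len(c) >= 2
                assert not (c & seen)
                seen |= c
            assert seen | cs.singletons == set(labels)
            assert list(cs.cluster_plvs) == sorted(cs.cluster_plvs, reverse=True)

    def test_frozen_cliques_satisfy_condition_post_hoc(self):
        # every reported clique re-satisfies the inclusive clique condition
        # against the full matrix quantized to the detection precision
        rng = np.random.default_rng(33)
        labels = tuple(f"r{i}" for i in range(7))
        for _ in range(20):
            a = rng.uniform(0.1, 0.9, (7, 7))
            v = (a + a.T) / 2
            np.fill_diagonal(v, 1.0)
            m = PLVMatrix(labels, v)
            q = np.round(v, 3)
            idx = {lab: i for i, lab in enumerate(labels)}
            cs = detect_cs(m)
            for c in cs.cliques:
                members = sorted(c)
                n = len(members)
                internal = sum(q[idx[x], idx[y]]
                               for i, x in enumerate(members)
                               for y in members[i + 1:])
                half = n * (n - 1) / 2
                for k in members:
                    for k2 in labels:
                        if k2 in c:
                            continue
                        assert internal >= half * q[idx[k], idx[k2]] - 1e-9


class TestClusterPLV:
    def test_pair_is_the_single_entry(self):
        m = make_plv(["a", "b", "c"], 0.2, {("a", "b"): 0.77})
        assert cluster_plv(m, ["a", "b"]) == pytest.approx(0.77)

    def test_triangle_mean(self):
        m = make_plv(list("abc"), 0.9, {})
        assert cluster_plv(m, ["a", "b", "c"]) == pytest.approx(0.9)

    def test_empty_clique_rejected(self):
        m = make_plv(["a", "b"], 0.5, {})
        with pytest.raises(ValueError):
            cluster_plv(m, [])


class TestCSToColoring:
    def test_rs_style_cluster_set_gives_four_classes(self):
        labels = ("SMA", "PreMA_L", "PreMA_R", "BA_L", "BA_R", "SMG_L",
                  "SMG_R", "AG_L", "AG_R", "WA_L", "WA_R")
        cs = ClusterSet(
            cliques=(
                frozenset({"SMG_L", "SMG_R"}),
                frozenset({"SMA", "PreMA_L", "PreMA_R", "WA_L", "WA_R"}),
                frozenset({"AG_L", "AG_R"}),
                frozenset({"BA_L", "BA_R"}),
            ),
            cluster_plvs=(0.762, 0.712, 0.689, 0.689),
            formation_steps=(1, 2, 3, 4),
            singletons=frozenset(),
        )
        col = cs_to_coloring(cs, labels)
        assert col.k == 4

    def test_singletons_become_own_classes(self):
        cs = ClusterSet(
            cliques=(frozenset({"a", "b"}),),
            cluster_plvs=(0.9,),
            formation_steps=(1,),
            singletons=frozenset({"c", "d"}),
        )
        col = cs_to_coloring(cs, ("a", "b", "c", "d"))
        assert col.k == 3
        assert isinstance(col, NodeColoring)
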