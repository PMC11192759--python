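"""Bliss scoring, grid QC, k-means discretization, combination enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netavatar.conditioning import build_avatar
from netavatar.errors import DegenerateInputError, InputError
from netavatar.fixtures import FixtureSpec, make_toy_network
from netavatar.synergy import (
    CombinationGrid,
    bliss_excess_grid,
    combination_screen,
    discretize_synergy,
    enumerate_combinations,
    max_synergy,
    qc_grid,
)


def grid_from_matrix(kab, doses=None):
    kab = np.asarray(kab, dtype=float)
    da = np.arange(kab.shape[0], dtype=float) if doses is None else doses[0]
    db = np.arange(kab.shape[1], dtype=float) if doses is None else doses[1]
    return CombinationGrid(
        drugA="A", drugB="B", cell_line="CL", doses_A=da, doses_B=db, killrate_AB=kab
    )


class TestBlissExcess:
    def test_addition_law_arithmetic(self):
        excess = bliss_excess_grid([0.4], [0.5], np.array([[0.9]]))
        assert excess[0, 0] == pytest.approx(0.2)  # expected 0.7

    def test_antagonism_clamped_in_scoring(self):
        kab = np.array([[0.0, 0.5], [0.4, 0.6]])  # observed < expected at (1,1)
        g = grid_from_matrix(kab)
        res = max_synergy(g)
        excess = bliss_excess_grid(g.killrate_A, g.killrate_B, kab)
        assert excess[1, 1] == pytest.approx(-0.1)
        assert res.bliss_score == 0.0  # negative Bliss treated as total lack of synergy

    def test_all_zero_marginals_zero_excess(self):
        excess = bliss_excess_grid([0.0], [0.0], np.array([[0.0]]))
        assert excess[0, 0] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            bliss_excess_grid([0.1, 0.2], [0.1], np.zeros((3, 1)))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_excess_bounded_and_additivity_gives_zero(self, seed):
        rng = np.random.default_rng(seed)
        ka = rng.uniform(0, 1, 4)
        kb = rng.uniform(0, 1, 5)
        expected = ka[:, None] + kb[None, :] - ka[:, None] * kb[None, :]
        assert np.allclose(bliss_excess_grid(ka, kb, expected), 0.0)
        kab = rng.uniform(0, 1, (4, 5))
        excess = bliss_excess_grid(ka, kb, kab)
        assert np.all(excess >= -1.0) and np.all(excess <= 1.0)
        assert np.all(np.maximum(excess, 0.0) <= 1.0)

    def test_symmetry_under_drug_swap(self):
        rng = np.random.default_rng(3)
        kab = rng.uniform(0, 1, (4, 4))
        kab[0, :] = np.sort(kab[0, :])
        kab[:, 0] = np.sort(kab[:, 0])
        kab[0, 0] = 0.0
        g = grid_from_matrix(kab)
        gT = grid_from_matrix(kab.T)
        res, resT = max_synergy(g, force=True), max_synergy(gT, force=True)
        assert np.allclose(res.bliss_excess, resT.bliss_excess.T)
        assert res.bliss_score == pytest.approx(resT.bliss_score)


class TestMaxSynergy:
    def test_all_zero_grid(self):
        res = max_synergy(grid_from_matrix(np.zeros((3, 3))))
        assert res.bliss_score == 0.0 and res.bliss_max_ic50 == 0.0

    def test_single_positive_cell_at_sub_ic50(self):
        kab = np.zeros((3, 3))
        kab[1, 1] = 0.3
        res = max_synergy(grid_from_matrix(kab), ic50_A=2.0, ic50_B=2.0)
        assert res.bliss_score == pytest.approx(0.3)
        assert res.bliss_max_ic50 == pytest.approx(0.3)
        assert res.argmax_doses == (1.0, 1.0)

    def test_supra_ic50_max_excluded_from_restricted_score(self):
        # brute-force oracle over a constructed grid
        kab = np.zeros((4, 4))
        kab[3, 3] = 0.5  # supra-IC50 corner
        kab[1, 1] = 0.2  # sub-IC50 cell
        g = grid_from_matrix(kab)
        res = max_synergy(g, ic50_A=2.0, ic50_B=2.0)
        excess = np.maximum(bliss_excess_grid(g.killrate_A, g.killrate_B, kab), 0)
        brute_all = max(
            excess[i, j] for i, j in itertools.product(range(4), range(4))
        )
        brute_sub = max(
            excess[i, j]
            for i, j in itertools.product(range(4), range(4))
            if g.doses_A[i] < 2.0 and g.doses_B[j] < 2.0
        )
        assert res.bliss_score == pytest.approx(brute_all) == pytest.approx(0.5)
        assert res.bliss_max_ic50 == pytest.approx(brute_sub) == pytest.approx(0.2)

    def test_row_major_tie_break_on_argmax(self):
        kab = np.zeros((3, 3))
        kab[1, 2] = kab[2, 1] = 0.4
        res = max_synergy(grid_from_matrix(kab))
        assert res.argmax_doses == (1.0, 2.0)


class TestQC:
    def test_monotone_grid_passes(self):
        kab = np.linspace(0, 0.9, 16).reshape(4, 4)
        kab = np.sort(np.sort(kab, axis=0), axis=1)
        ok, reasons = qc_grid(grid_from_matrix(kab))
        assert ok and reasons == []

    def test_rising_marginal_viability_fails_naming_drug(self):
        kab = np.zeros((4, 4))
        kab[:, 0] = [0.7, 0.7, 0.1, 0.1]  # drug A viability jumps 0.3 -> 0.9
        ok, reasons = qc_grid(grid_from_matrix(kab))
        assert not ok
        assert any("drug A" in r for r in reasons)

    def test_constant_inert_grid_passes(self):
        ok, _ = qc_grid(grid_from_matrix(np.zeros((4, 4))))
        assert ok

    def test_non_finite_entries_fail(self):
        kab = np.zeros((3, 3))
        kab[2, 2] = np.nan
        ok, reasons = qc_grid(grid_from_matrix(kab))
        assert not ok and any("non-finite" in r for r in reasons)

    def test_small_noise_wiggle_tolerated(self):
        kab = np.zeros((4, 4))
        kab[:, 0] = [0.0, 0.05, 0.0, 0.08]  # jumps below the 0.1 tolerance
        ok, _ = qc_grid(grid_from_matrix(kab))
        assert ok


def exhaustive_1d_kmeans(values, k=3):
    """Oracle: best contiguous 3-partition of sorted values by within-SS."""
    xs = np.sort(np.asarray(values, dtype=float))
    n = len(xs)
    best, best_ss = None, np.inf
    for i, j in itertools.combinations(range(1, n), 2):
        parts = [xs[:i], xs[i:j], xs[j:]]
        ss = sum(((p - p.mean()) ** 2).sum() for p in parts if len(p))
        if ss < best_ss - 1e-12:
            best_ss, best = ss, parts
    return best, best_ss


class TestDiscretization:
    def test_three_obvious_clusters_recovered(self):
        scores = [0.0, 0.01, 0.02, 0.5, 0.51, 0.95, 1.0]
        cats, labels = discretize_synergy(scores)
        assert labels == ["non"] * 3 + ["moderate"] * 2 + ["strong"] * 2
        parts, _ = exhaustive_1d_kmeans(scores)
        assert cats.thresholds[0] == pytest.approx((max(parts[0]) + min(parts[1])) / 2)
        assert cats.thresholds[1] == pytest.approx((max(parts[1]) + min(parts[2])) / 2)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_matches_exhaustive_partition_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(0, 1, 10), 3)
        if len(np.unique(scores)) < 3:
            return
        cats, labels = discretize_synergy(scores, seed=0)
        parts, oracle_ss = exhaustive_1d_kmeans(scores)
        clusters = {}
        for s, l in zip(scores, labels):
            clusters.setdefault(l, []).append(s)
        km_ss = sum(
            ((np.array(v) - np.mean(v)) ** 2).sum() for v in clusters.values()
        )
        assert km_ss == pytest.approx(oracle_ss, abs=1e-9)

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            discretize_synergy([0.5, 0.5, 0.5, 0.5])

    def test_same_seed_same_thresholds(self):
        scores = np.random.default_rng(1).uniform(0, 1, 30)
        c1, _ = discretize_synergy(scores, seed=7)
        c2, _ = discretize_synergy(scores, seed=7)
        assert c1.thresholds == c2.thresholds


class TestEnumeration:
    def test_paper_scale_panel(self):
        ddr = [f"ddr{i}" for i in range(12)]
        non = [f"non{i}" for i in range(46)]
        pairs = enumerate_combinations(ddr, non)
        assert len(pairs) == 684

    def test_single_ddr_alone_no_pairs(self):
        assert enumerate_combinations(["d"], []) == []

    def test_small_panel_brute_force(self):
        pairs = enumerate_combinations(["d1", "d2"], ["n1"])
        assert pairs == [("d1", "d2"), ("d1", "n1"), ("d2", "d1"), ("d2", "n1")]

    def test_overlapping_panels_rejected(self):
        with pytest.raises(InputError):
            enumerate_combinations(["a", "b"], ["b", "c"])

    def test_duplicates_rejected(self):
        with pytest.raises(InputError):
            enumerate_combinations(["a", "a"], ["c"])


class TestFixtureGroundTruth:
    def test_redundant_pathways_synergize_same_pathway_does_not(
        self, avatar, profiles, fast_config
    ):
        """OR-logic survival: only dual-pathway blockade kills, so the
        cross-pathway pair is strongly synergistic while two drugs on one
        pathway show essentially no Bliss excess."""
        cross = combination_screen(
            avatar, profiles["anti_R1"], profiles["anti_R2"], None, None, fast_config
        )
        res_cross = max_synergy(cross)
        assert res_cross.qc_pass
        assert res_cross.bliss_score > 0.2

        same = combination_screen(
            avatar, profiles["anti_R1"], profiles["anti_P1"], None, None, fast_config
        )
        res_same = max_synergy(same)
        assert res_same.bliss_score < 0.05

    def test_corner_killrate_zero_and_marginals_consistent(
        self, avatar, profiles, fast_config
    ):
        g = combination_screen(
            avatar, profiles["anti_R1"], profiles["anti_R2"], None, None, fast_config
        )
        assert g.killrate_AB[0, 0] == 0.0
        assert np.array_equal(g.killrate_A, g.killrate_AB[:, 0])
        assert np.array_equal(g.killrate_B, g.killrate_AB[0, :])
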