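import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from cseg.identify import (
    FIPER_VARIANTS,
    adam_identify,
    adam_threshold,
    binarize_depletion,
    cs0csx_bin,
    cs0csx_identify,
    cs0csx_label,
    density_trough,
    fiper_consensus,
    fiper_identify,
    fiper_scores,
)
from cseg.io import GeneEffectMatrix, GeneSet


def matrix_from(values, genes=None, lines=None) -> GeneEffectMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    lines = lines or [f"L{j}" for j in range(arr.shape[1])]
    return GeneEffectMatrix(scores=pd.DataFrame(arr, index=genes, columns=lines))


# ---------------------------------------------------------------------------
# CS0-CSX


class TestCs0CsxBinning:
    def test_equal_width_bins_on_uniform_span(self):
        # scores uniformly spanning [-3, 0.3] with no clipping -> width 0.3
        vals = np.linspace(-3.0, 0.3, 110).reshape(11, 10)
        m = matrix_from(vals)
        bm = cs0csx_bin(m, clip_quantiles=(0.0, 1.0))
        widths = np.diff(bm.edges)
        assert np.allclose(widths, 0.3)
        # -2.95 falls in the most negative bin
        cell = np.argwhere(np.isclose(vals, vals.flat[np.abs(vals.flatten() + 2.95).argmin()]))
        i, j = cell[0]
        assert vals[i, j] < -2.9
        assert bm.bins.iloc[i, j] == 0

    def test_constant_matrix_is_hard_error(self):
        with pytest.raises(ValueError):
            cs0csx_bin(matrix_from(np.zeros((3, 3))))

    def test_score_on_interior_edge_goes_to_higher_bin(self):
        vals = np.linspace(0.0, 11.0, 12).reshape(3, 4)  # edges at integers
        m = matrix_from(vals)
        bm = cs0csx_bin(m, clip_quantiles=(0.0, 1.0))
        assert np.allclose(bm.edges, np.arange(12))
        # score exactly 1.0 sits on the CS0/CS1 edge -> CS1
        loc = np.argwhere(vals == 1.0)[0]
        assert bm.bins.iloc[loc[0], loc[1]] == 1

    def test_out_of_range_scores_clipped_into_terminal_bins(self):
        vals = np.concatenate([[-100.0, 100.0], np.linspace(-1, 1, 98)]).reshape(10, 10)
        m = matrix_from(vals)
        bm = cs0csx_bin(m, clip_quantiles=(0.05, 0.95))
        assert bm.bins.to_numpy()[vals == -100.0] == [0]
        assert bm.bins.to_numpy()[vals == 100.0] == [10]


class TestCs0CsxLabels:
    def test_all_scores_in_cs0_gives_e(self):
        # g0 deeply negative in all lines; others spread upward
        vals = np.vstack([[-3.0, -3.0, -3.0], *[[x, x, x] for x in np.linspace(-1, 0.3, 9)]])
        m = matrix_from(vals)
        t = cs0csx_identify(m, clip_quantiles=(0.0, 1.0))
        assert t.labels["g0"] == "E"

    def test_modal_bin_above_cs0_gives_ne(self):
        # per-line bins {CS0, CS3, CS3} -> modal CS3 -> NE
        base = np.linspace(0.0, 10.99, 33).reshape(11, 3)
        base[0] = [0.5, 3.5, 3.5]  # one CS0 score, two CS3 scores
        m = matrix_from(base)
        bm = cs0csx_bin(m, clip_quantiles=(0.0, 1.0))
        assert list(bm.bins.iloc[0]) == [0, 3, 3]
        t = cs0csx_label(m, bm)
        assert t.labels["g0"] == "NE"

    def test_all_missing_gene_excluded_with_warning(self):
        vals = np.linspace(-2, 1, 30).reshape(10, 3)
        m = matrix_from(vals)
        m.scores.iloc[4] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            t = cs0csx_identify(m, clip_quantiles=(0.0, 1.0))
        assert "g4" not in t.labels.index
        assert len(t.labels) == 9

    def test_invariant_to_cell_line_ordering(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.normal(size=(20, 10)))
        t1 = cs0csx_identify(m)
        shuffled = GeneEffectMatrix(scores=m.scores.iloc[:, ::-1].copy())
        t2 = cs0csx_identify(shuffled)
        pd.testing.assert_series_equal(t1.labels, t2.labels)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_modal_bin_matches_bruteforce_histogram_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = matrix_from(rng.normal(size=(20, 10)))
        bm = cs0csx_bin(m)
        t = cs0csx_label(m, bm)
        for gi, gene in enumerate(m.genes):
            # oracle: explicit per-score edge comparison + Counter, ties -> lower
            counts = Counter()
            for x in m.scores.iloc[gi]:
                if not np.isfinite(x):
                    continue
                b = 0
                for e in bm.edges[1:-1]:
                    if x >= e:
                        b += 1
                counts[b] += 1
            best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            assert t.labels[gene] == ("E" if best == 0 else "NE")

    def test_partition_of_universe(self):
        rng = np.random.default_rng(9)
        m = matrix_from(rng.normal(size=(30, 6)))
        t = cs0csx_identify(m)
        assert t.e_set.members | t.ne_set.members == set(m.genes)
        assert not (t.e_set.members & t.ne_set.members)


# ---------------------------------------------------------------------------
# ADaM


def exact_expected_cardinality(dep: np.ndarray) -> np.ndarray:
    """Exact permutation-null E|{g: depleted in >= n lines}| via the
    Poisson-binomial law: each column hits a given gene with prob k_j/G."""
    n_genes, n_lines = dep.shape
    probs = dep.sum(axis=0) / n_genes
    dist = np.array([1.0])
    for p in probs:
        dist = np.convolve(dist, [1 - p, p])
    tail = dist[::-1].cumsum()[::-1]
    return n_genes * tail[1:]


def oracle_n_star(dep: np.ndarray, ref_mask: np.ndarray) -> int:
    """Brute-force threshold search: explicit set cardinalities, exact null."""
    n_genes, n_lines = dep.shape
    observed, recall = [], []
    for n in range(1, n_lines + 1):
        selected = {g for g in range(n_genes) if dep[g].sum() >= n}
        observed.append(len(selected))
        ref = {g for g in range(n_genes) if ref_mask[g]}
        recall.append(len(selected & ref) / len(ref))
    observed = np.array(observed, dtype=float)
    expected = exact_expected_cardinality(dep)

    def minmax(x):
        x = np.asarray(x, dtype=float)
        return np.ones_like(x) if x.max() == x.min() else (x - x.min()) / (x.max() - x.min())

    score = minmax(observed - expected) * minmax(recall)
    best, best_n = -np.inf, None
    for i, s in enumerate(score):
        if s > best:
            best, best_n = s, i + 1
    return best_n


def toy_daisy() -> tuple[GeneEffectMatrix, GeneSet]:
    """6 genes x 3 lines: g1,g2 depleted everywhere, g3/g4 in one line each."""
    scores = pd.DataFrame(
        {
            "L1": [-1.2, -1.0, -0.8, 0.1, 0.2, 0.3],
            "L2": [-1.1, -0.9, 0.2, -0.7, 0.1, 0.2],
            "L3": [-1.3, -1.2, 0.3, 0.2, 0.1, 0.4],
        },
        index=["g1", "g2", "g3", "g4", "g5", "g6"],
    )
    return GeneEffectMatrix(scores=scores), GeneSet("ref", frozenset({"g1"}))


class TestAdam:
    def test_binarize_strict_inequality_and_missing(self):
        m = matrix_from([[-1.2, -0.5], [np.nan, -0.6]])
        b = binarize_depletion(m, -0.5)
        assert b.values.iloc[0, 0]  # -1.2 < -0.5
        assert not b.values.iloc[0, 1]  # exactly on the threshold
        assert not b.values.iloc[1, 0]  # missing -> False
        assert b.values.iloc[1, 1]

    def test_all_positive_matrix_binarizes_all_false_then_errors(self):
        m = matrix_from(np.abs(np.random.default_rng(0).normal(size=(5, 3))))
        b = binarize_depletion(m, -0.5)
        assert not b.values.to_numpy().any()
        with pytest.raises(ValueError, match="no depleted"):
            adam_threshold(b, GeneSet("r", frozenset({"g0"})), n_null=100)

    def test_empty_reference_overlap_is_hard_error(self):
        m, _ = toy_daisy()
        b = binarize_depletion(m, -0.5)
        with pytest.raises(ValueError, match="overlap"):
            adam_threshold(b, GeneSet("r", frozenset({"zzz"})), n_null=100)

    def test_toy_threshold_matches_bruteforce_oracle(self):
        m, ref = toy_daisy()
        b = binarize_depletion(m, -0.5)
        dep = b.values.to_numpy()
        ref_mask = b.values.index.isin(ref.members)
        expect = oracle_n_star(dep, ref_mask)
        n_star, profile = adam_threshold(b, ref, n_null=2000, seed=0)
        assert n_star == expect == 3
        assert (np.diff(profile.observed) <= 0).all()
        # exact null within Monte-Carlo error
        assert np.allclose(profile.expected, exact_expected_cardinality(dep), atol=0.3)

    def test_toy_identify_recovers_fully_depleted_genes(self):
        m, ref = toy_daisy()
        t = adam_identify(m, ref, n_null=500, seed=1)
        assert t.e_set.members == frozenset({"g1", "g2"})
        assert t.e_set.members | t.ne_set.members == set(m.genes)

    @pytest.mark.parametrize("seed,n_lines", [(0, 3), (1, 5), (2, 6), (3, 8)])
    def test_n_star_matches_exhaustive_search_on_small_matrices(self, seed, n_lines):
        rng = np.random.default_rng(seed)
        n_genes = 24
        essential = rng.random(n_genes) < 0.25
        p_dep = np.where(essential, 0.9, 0.1)
        dep = rng.random((n_genes, n_lines)) < p_dep[:, None]
        assert dep.any()  # guaranteed by these seeds; guards oracle validity
        genes = [f"g{i}" for i in range(n_genes)]
        b = binarize_depletion(
            matrix_from(np.where(dep, -1.0, 0.0), genes=genes), -0.5
        )
        ref = GeneSet("ref", frozenset(np.array(genes)[essential][:3]))
        ref_mask = b.values.index.isin(ref.members)
        n_star, _ = adam_threshold(b, ref, n_null=3000, seed=seed + 100)
        assert n_star == oracle_n_star(dep, ref_mask)

    def test_universal_reference_makes_recall_neutral(self):
        m, _ = toy_daisy()
        ref = GeneSet("all", frozenset(m.genes))
        b = binarize_depletion(m, -0.5)
        _, profile = adam_threshold(b, ref, n_null=500, seed=2)
        # recall curve is not constant here (some genes are never depleted),
        # but with the whole universe as reference the recall equals the
        # observed/total fraction; the combined score is still dominated by
        # the cardinality deviation at the top end
        assert profile.recall[0] == pytest.approx(4 / 6)


# ---------------------------------------------------------------------------
# FiPer


class TestFiperScores:
    def hand_matrix(self):
        # L1: g1=-2, g2=-1, g3=0 ; L2: g1=0, g2=-2, g3=-1
        return matrix_from([[-2.0, 0.0], [-1.0, -2.0], [0.0, -1.0]],
                           genes=["g1", "g2", "g3"])

    def test_variants_match_hand_computed_oracle(self):
        m = self.hand_matrix()
        expected = {
            "fixed": {"g1": 1.0, "g2": 0.5, "g3": 1.0},
            "average": {"g1": 0.5, "g2": 0.25, "g3": 0.75},
            "slope": {"g1": 1.0, "g2": 0.0, "g3": 0.0},  # minmax-rescaled
            "auc": {"g1": 0.5, "g2": 0.25, "g3": 0.75},
        }
        for variant, want in expected.items():
            fs = fiper_scores(m, variant)
            for g, v in want.items():
                assert fs.scores[g] == pytest.approx(v), (variant, g)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            fiper_scores(self.hand_matrix(), "median")

    def test_best_gene_everywhere_scores_zero(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(10, 6))
        vals[0] = -10.0  # strictly strongest dependency in every line
        m = matrix_from(vals)
        for variant in ("fixed", "average", "auc"):
            assert fiper_scores(m, variant).scores["g0"] == pytest.approx(0.0)

    def test_constant_cell_line_gives_uniform_half_percentile(self):
        vals = np.column_stack([np.zeros(6), np.linspace(-1, 1, 6)])
        m = matrix_from(vals)
        fs = fiper_scores(m, "average")
        # stable order: constant line contributes 0.5 to every gene's sequence
        seqs = fs.scores
        assert seqs.between(0, 1).all()
        # gene ranked k in the informative line has mean of {0.5, pct_k}
        pct = np.linspace(0, 1, 6)
        for i in range(6):
            assert seqs[f"g{i}"] == pytest.approx((0.5 + pct[i]) / 2)

    def test_invariant_to_per_line_constant_shift(self):
        rng = np.random.default_rng(11)
        m = matrix_from(rng.normal(size=(15, 5)))
        shifted = m.scores.copy()
        shifted["L2"] += 7.5
        m2 = GeneEffectMatrix(scores=shifted)
        for variant in FIPER_VARIANTS:
            a = fiper_scores(m, variant).scores
            b = fiper_scores(m2, variant).scores
            # per-line ranks unchanged; per-gene line ordering may change,
            # but 'average' is order-free and must match exactly
            if variant == "average":
                pd.testing.assert_series_equal(a, b)
            assert b.between(0, 1).all()


class TestDensityTrough:
    def bimodal(self, rng):
        return np.clip(
            np.concatenate([rng.normal(0.1, 0.05, 50), rng.normal(0.9, 0.05, 50)]), 0, 1
        )

    def test_trough_matches_bruteforce_grid_scan(self):
        rng = np.random.default_rng(21)
        x = self.bimodal(rng)
        got = density_trough(x, grid_points=512)
        assert 0.3 < got < 0.7
        # oracle: direct Gaussian-kernel sum on the same grid
        n = x.size
        bw = n ** (-1.0 / 5) * x.std(ddof=1)  # silverman, 1-d
        grid = np.linspace(0, 1, 512)
        dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2).sum(1)
        lo, hi = np.searchsorted(grid, 0.2), np.searchsorted(grid, 0.8)
        oracle = grid[lo + np.argmin(dens[lo:hi])]
        assert got == pytest.approx(oracle, abs=2 / 511)

    def test_unimodal_returns_no_trough(self):
        rng = np.random.default_rng(22)
        x = np.clip(rng.normal(0.5, 0.08, 200), 0, 1)
        assert density_trough(x) is None

    def test_symmetric_mixture_trough_at_midpoint(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0.3, 0.04, 300)
        x = np.clip(np.concatenate([a, 1.0 - a]), 0, 1)
        got = density_trough(x)
        assert got == pytest.approx(0.5, abs=0.02)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            density_trough(np.full(20, 0.5))
        with pytest.raises(ValueError):
            density_trough([0.1, 0.9])


class TestFiperIdentify:
    def test_consensus_partitions_universe(self, context_matrix):
        t = fiper_consensus(context_matrix)
        assert t.e_set.members | t.ne_set.members == set(context_matrix.genes)
        assert not (t.e_set.members & t.ne_set.members)

    def test_consensus_is_intersection_of_variants(self, context_matrix):
        variant_sets = [
            fiper_identify(context_matrix, v).members for v in FIPER_VARIANTS
        ]
        t = fiper_consensus(context_matrix)
        assert t.e_set.members == frozenset.intersection(*variant_sets)

    def test_unimodal_variant_contributes_empty_set(self):
        rng = np.random.default_rng(31)
        m = matrix_from(rng.normal(0, 0.3, size=(200, 8)))  # no essential class
        with pytest.warns(UserWarning, match="unimodal"):
            s = fiper_identify(m, "average")
        assert len(s) == 0
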