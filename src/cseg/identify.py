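"""E/NE identification from context gene-effect matrices.

Three algorithm families turn a genes x cell-lines score matrix into an
essential / not-essential label per gene:

* **CS0-CSX** — score binning.  All finite scores are divided into eleven
  equal-width bins (CS0..CS10) spanning a clipped quantile range; a gene is
  labelled E when its modal bin across cell lines is CS0, the most-negative
  bin.
* **ADaM** (adaptive daisy model) — semi-supervised.  Scores are binarised
  into a depletion matrix; the method then picks the minimal number of cell
  lines ``n*`` in which a gene must be depleted to be called essential, by
  jointly maximising the deviation of the observed "depleted in >= n lines"
  cardinality from a permutation null and the recall of a gold-standard
  reference essential-gene set.
* **FiPer** (fitness percentile) — unsupervised.  Per cell line, genes are
  rank-percentiled by score; per gene, cell lines are ordered from strongest
  to weakest dependency and the ordered percentile sequence is reduced to a
  scalar by one of four variants (fixed percentile, average, slope, AUC).
  The scalar distribution is bimodal on real screens; the split point is the
  Gaussian-KDE density trough between the two main modes, and the consensus
  E set is the intersection of the four variants' E sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from cseg.io import GeneEffectMatrix, GeneSet, LabelTable

FIPER_VARIANTS = ("fixed", "average", "slope", "auc")

#: Fraction of context cell lines a gene may be missing in before it is
#: dropped from rank-based scoring.
MAX_MISSING_FRACTION = 0.5


# ---------------------------------------------------------------------------
# CS0-CSX


@dataclass
class BinMapping:
    """Equal-width score bins CS0..CS(n-1) and the per-cell bin indices."""

    edges: np.ndarray  # n_bins + 1 ascending cut points (gene-effect units)
    bins: pd.DataFrame  # genes x cell lines, float with NaN for missing

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def cs0csx_bin(
    m: GeneEffectMatrix,
    n_bins: int = 11,
    clip_quantiles: tuple[float, float] = (0.001, 0.999),
) -> BinMapping:
    """Bin every score into ``n_bins`` equal-width groups CS0..CS(n_bins-1).

    The bins span the ``clip_quantiles`` score quantile range; scores outside
    are clipped into the terminal bins, so CS0 always holds the most negative
    scores.  Bins are left-closed/right-open: a score exactly on an interior
    edge belongs to the higher-index bin.
    """
    values = m.scores.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise ValueError("scores are constant or empty; bins undefined")
    lo, hi = np.quantile(finite, clip_quantiles)
    if not lo < hi:
        raise ValueError("degenerate quantile range; bins undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    inner = edges[1:-1]
    idx = np.digitize(values, inner, right=False).astype(float)
    idx[~np.isfinite(values)] = np.nan
    bins = pd.DataFrame(idx, index=m.scores.index, columns=m.scores.columns)
    return BinMapping(edges=edges, bins=bins)


def cs0csx_label(m: GeneEffectMatrix, bins: BinMapping) -> LabelTable:
    """Label each gene by its modal bin across cell lines.

    Modal bin CS0 -> E; anything else -> NE.  Ties go to the lower (more
    negative) bin index, conservative toward essentiality.  Genes whose
    scores are all missing are excluded with a warning; a modal top bin is
    allowed but flagged, as in practice too few genes concentrate there for
    it to act as a label of its own.
    """
    arr = bins.bins.to_numpy()
    n_bins = bins.n_bins
    counts = np.zeros((arr.shape[0], n_bins), dtype=int)
    for b in range(n_bins):
        counts[:, b] = np.nansum(arr == b, axis=1)
    total = counts.sum(axis=1)
    keep = total > 0
    if not keep.all():
        dropped = list(bins.bins.index[~keep])
        warnings.warn(f"{len(dropped)} gene(s) with all scores missing excluded")
    modal = counts[keep].argmax(axis=1)  # argmax takes the lowest index on ties
    genes = bins.bins.index[keep]
    if (modal == n_bins - 1).any():
        warnings.warn(
            f"{int((modal == n_bins - 1).sum())} gene(s) have modal bin "
            f"CS{n_bins - 1}; labelled NE"
        )
    labels = pd.Series(np.where(modal == 0, "E", "NE"), index=genes)
    return LabelTable(labels=labels, provenance="cs0csx")


def cs0csx_identify(
    m: GeneEffectMatrix,
    n_bins: int = 11,
    clip_quantiles: tuple[float, float] = (0.001, 0.999),
) -> LabelTable:
    """Convenience composition of :func:`cs0csx_bin` and :func:`cs0csx_label`."""
    return cs0csx_label(m, cs0csx_bin(m, n_bins=n_bins, clip_quantiles=clip_quantiles))


# ---------------------------------------------------------------------------
# ADaM


@dataclass
class BinaryDepletionMatrix:
    values: pd.DataFrame  # genes x cell lines, bool
    depletion_threshold: float


@dataclass
class AdamProfile:
    """Per-candidate-n diagnostics of the adaptive daisy threshold search."""

    n: np.ndarray  # candidate minimal cell-line counts, 1..N
    observed: np.ndarray  # |{g depleted in >= n lines}|
    expected: np.ndarray  # null mean under column-wise permutations
    recall: np.ndarray  # fraction of reference EGs captured at each n
    score: np.ndarray  # combined (minmax deviation) * (minmax recall)
    n_star: int


def binarize_depletion(m: GeneEffectMatrix, threshold: float) -> BinaryDepletionMatrix:
    """True where score < threshold (strict); missing scores count as False."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = m.scores.to_numpy(dtype=float)
    dep = np.where(np.isfinite(vals), vals < threshold, False)
    return BinaryDepletionMatrix(
        values=pd.DataFrame(dep, index=m.scores.index, columns=m.scores.columns),
        depletion_threshold=threshold,
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        # constant curve carries no preference; neutral weight
        return np.ones_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def adam_threshold(
    b: BinaryDepletionMatrix,
    ref_eg: GeneSet,
    n_null: int = 1000,
    seed: int = 42,
) -> tuple[int, AdamProfile]:
    """Choose the minimal number of cell lines ``n*`` for essentiality.

    For each candidate n in 1..N the observed cardinality of the fuzzy
    intersection {genes depleted in >= n lines} is compared with its
    expectation under ``n_null`` column-wise permutations of the depletion
    matrix (each preserving that cell line's depletion count), and with the
    recall of the reference essential set among the selected genes.  The two
    curves are minmax-normalised and multiplied; ``n*`` is the argmax, ties
    broken toward smaller n (the more inclusive essential set).
    """
    dep = b.values.to_numpy(dtype=bool)
    n_genes, n_lines = dep.shape
    row_counts = dep.sum(axis=1)
    if row_counts.sum() == 0:
        raise ValueError("no depleted genes in the binary matrix")
    ref_mask = b.values.index.isin(ref_eg.members)
    if not ref_mask.any():
        raise ValueError("reference essential set does not overlap the gene universe")

    ns = np.arange(1, n_lines + 1)
    hist = np.bincount(row_counts, minlength=n_lines + 1)
    observed = hist[::-1].cumsum()[::-1][1:]  # observed[k-1] = #genes with count >= k
    assert (np.diff(observed) <= 0).all(), "observed cardinality must be non-increasing"

    rng = np.random.default_rng(seed)
    acc = np.zeros(n_lines, dtype=float)
    for _ in range(n_null):
        perm = rng.permuted(dep, axis=0)  # shuffles each column independently
        rc = perm.sum(axis=1)
        h = np.bincount(rc, minlength=n_lines + 1)
        acc += h[::-1].cumsum()[::-1][1:]
    expected = acc / n_null

    ref_counts = row_counts[ref_mask]
    recall = np.array([(ref_counts >= n).mean() for n in ns])
    score = _minmax(observed - expected) * _minmax(recall)
    n_star = int(ns[int(np.argmax(score))])  # argmax -> first max -> smallest n
    profile = AdamProfile(
        n=ns, observed=observed.astype(float), expected=expected,
        recall=recall, score=score, n_star=n_star,
    )
    return n_star, profile


def adam_identify(
    m: GeneEffectMatrix,
    ref_eg: GeneSet,
    threshold: float = -0.5,
    n_null: int = 1000,
    seed: int = 42,
) -> LabelTable:
    """Full ADaM run: binarise, find n*, label genes depleted in >= n* lines E.

    The default depletion cut of -0.5 gene-effect units is the conventional
    DepMap depletion threshold (common-essential median is scaled to -1).
    """
    b = binarize_depletion(m, threshold)
    n_star, _ = adam_threshold(b, ref_eg, n_null=n_null, seed=seed)
    row_counts = b.values.to_numpy(dtype=bool).sum(axis=1)
    labels = pd.Series(np.where(row_counts >= n_star, "E", "NE"), index=m.scores.index)
    return LabelTable(labels=labels, provenance="adam")


# ---------------------------------------------------------------------------
# FiPer


@dataclass
class FiperScores:
    """Per-gene scalar rank-percentile score in [0, 1] for one variant."""

    scores: pd.Series  # index = gene, values in [0, 1]
    variant: str
    trough: float | None = None


def _drop_too_missing(m: GeneEffectMatrix) -> pd.DataFrame:
    scores = m.scores
    frac_missing = scores.isna().mean(axis=1)
    bad = frac_missing > MAX_MISSING_FRACTION
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) missing in >{MAX_MISSING_FRACTION:.0%} "
            "of context lines dropped from FiPer scoring"
        )
        scores = scores.loc[~bad]
    return scores


def fiper_scores(
    m: GeneEffectMatrix,
    variant: str,
    percentile: float = 0.90,
) -> FiperScores:
    """Reduce each gene's ordered rank-percentile sequence to one scalar.

    Per cell line, genes are ranked ascending by gene-effect score (average
    ranks on ties) and the ranks rescaled to [0, 1].  Per gene, its cell
    lines are ordered by score ascending — strongest dependency first — and
    the ordered percentile sequence is reduced by the chosen variant:

    - ``fixed``: the value at the ceil(percentile * N)-th ordered line;
    - ``average``: the mean over all lines;
    - ``slope``: the least-squares slope of percentile against ordered line
      index, minmax-rescaled over genes to [0, 1];
    - ``auc``: the trapezoidal area under the sequence divided by N - 1.
    """
    if variant not in FIPER_VARIANTS:
        raise ValueError(f"unknown FiPer variant {variant!r}; use one of {FIPER_VARIANTS}")
    scores = _drop_too_missing(m)
    if scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("FiPer needs at least 2 genes and 2 cell lines")

    vals = scores.to_numpy(dtype=float)
    pct = np.full_like(vals, np.nan)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        ok = np.isfinite(col)
        n_ok = int(ok.sum())
        if n_ok < 2:
            continue
        ranks = stats.rankdata(col[ok], method="average")
        pct[ok, j] = (ranks - 1.0) / (n_ok - 1.0)

    out = np.empty(vals.shape[0])
    for i in range(vals.shape[0]):
        row = vals[i]
        ok = np.isfinite(row) & np.isfinite(pct[i])
        order = np.argsort(row[ok], kind="stable")
        seq = pct[i, ok][order]
        n = seq.size
        if n == 0:
            out[i] = np.nan
            continue
        if variant == "fixed":
            k = min(max(math.ceil(percentile * n), 1), n)
            out[i] = seq[k - 1]
        elif variant == "average":
            out[i] = seq.mean()
        elif variant == "slope":
            if n < 2:
                out[i] = 0.0
            else:
                x = np.arange(1, n + 1, dtype=float)
                out[i] = np.polyfit(x, seq, 1)[0]
        else:  # auc
            out[i] = seq.mean() if n < 2 else np.trapezoid(seq) / (n - 1)

    series = pd.Series(out, index=scores.index).dropna()
    if variant == "slope":
        lo, hi = series.min(), series.max()
        series = (series - lo) / (hi - lo) if hi > lo else series * 0.0
    return FiperScores(scores=series, variant=variant)


def density_trough(
    scores,
    bandwidth_rule: str = "silverman",
    grid_points: int = 512,
) -> float | None:
    """Locate the density minimum between the two main modes of a score set.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a uniform grid over
    [0, 1]; the return value is the grid location of the lowest density
    strictly between the two highest local maxima.  Returns ``None`` when the
    estimated density is unimodal (no trough).
    """
    if bandwidth_rule != "silverman":
        raise ValueError(f"unsupported bandwidth rule {bandwidth_rule!r}")
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10 or np.unique(x).size < 2:
        raise ValueError("need at least 10 non-identical scores for a density estimate")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, grid_points)
    dens = kde(grid)
    padded = np.concatenate([[-np.inf], dens, [-np.inf]])
    # a mode must rise visibly above its surroundings: peaks whose prominence
    # is under 1% of the density maximum are sampling wiggle, not modes
    peaks, _ = signal.find_peaks(padded, prominence=0.01 * float(dens.max()))
    peaks -= 1  # undo padding offset; boundary modes included
    if peaks.size < 2:
        return None
    top_two = peaks[np.argsort(dens[peaks])[-2:]]
    left, right = int(top_two.min()), int(top_two.max())
    if right - left < 2:
        return None
    inner = np.arange(left + 1, right)
    return float(grid[inner[np.argmin(dens[inner])]])


def fiper_identify(
    m: GeneEffectMatrix,
    variant: str,
    percentile: float = 0.90,
    grid_points: int = 512,
) -> GeneSet:
    """E set of one FiPer variant: genes whose scalar falls below the trough."""
    fs = fiper_scores(m, variant, percentile=percentile)
    trough = density_trough(fs.scores.to_numpy(), grid_points=grid_points)
    fs.trough = trough
    if trough is None:
        warnings.warn(f"FiPer variant {variant!r}: unimodal score density, empty E set")
        return GeneSet(name=f"fiper_{variant}", members=frozenset())
    members = frozenset(fs.scores.index[fs.scores < trough])
    return GeneSet(name=f"fiper_{variant}", members=members)


def fiper_consensus(m: GeneEffectMatrix, percentile: float = 0.90) -> LabelTable:
    """Intersect the four variants' E sets; everything else in the scored
    universe is NE."""
    universe = _drop_too_missing(m).index
    e_sets = [fiper_identify(m, v, percentile=percentile) for v in FIPER_VARIANTS]
    consensus = frozenset.intersection(*[s.members for s in e_sets])
    labels = pd.Series(
        np.where(universe.isin(consensus), "E", "NE"), index=universe
    )
    return LabelTable(labels=labels, provenance="fiper_consensus")
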