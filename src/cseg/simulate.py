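"""Synthetic screens, networks and features with planted ground truth.

The generator emulates the structure of the real inputs at DepMap scaling:

* a gene-effect matrix in which common-essential genes score around -1 in
  every cell line, context-essential genes score around -1 only in the
  context (tissue) panel and around 0 elsewhere, and non-essential genes
  score around 0 everywhere;
* a preferential-attachment PPI in which essential genes are degree-biased
  hubs (the centrality-lethality premise), with every edge tagged by the
  context tissue token;
* gene feature tables ("bio"/"exp" groups) whose informative columns carry a
  class signal plus Gaussian noise, alongside pure-noise distractors.

All draws flow from one integer seed; the same spec + seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cseg.io import EdgeList, FeatureTable, GeneEffectMatrix, GeneSet

CLASSES = ("common_essential", "context_essential", "non_essential")


@dataclass
class SyntheticSpec:
    """Study conditions for a planted-truth screen.

    Score distributions follow the DepMap convention: essential knockouts
    centred at -1 gene-effect units, non-essential at 0, both with spread
    0.3.  Ten percent of genes are common-essential and ten percent
    context-essential, matching the rough "EGs are ~10% of the genome"
    figure with an equally sized context-only class on top.
    """

    n_genes: int = 1000
    n_context_lines: int = 15
    n_other_lines: int = 15
    frac_common_essential: float = 0.10
    frac_context_essential: float = 0.10
    mu_essential: float = -1.0
    sd_essential: float = 0.3
    sd_nonessential: float = 0.3
    missing_rate: float = 0.0
    # network
    ppi_edges_per_node: int = 3
    attachment_multiplier: float = 3.0
    tissue: str = "kidney"
    mislabel_fraction: float = 0.0
    # features
    n_informative: int = 10
    n_distractor: int = 20
    feature_signal: float = 2.0
    seed: int = 42

    def __post_init__(self) -> None:
        frac_ne = 1.0 - self.frac_common_essential - self.frac_context_essential
        if not (0.0 <= self.frac_common_essential <= 1.0) or not (
            0.0 <= self.frac_context_essential <= 1.0
        ) or frac_ne < -1e-9:
            raise ValueError("class fractions must be in [0,1] and sum to <= 1")
        if self.sd_essential < 0 or self.sd_nonessential < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def frac_non_essential(self) -> float:
        return 1.0 - self.frac_common_essential - self.frac_context_essential


@dataclass
class GroundTruth:
    """Planted class per gene."""

    classes: pd.Series  # gene -> one of CLASSES

    def __post_init__(self) -> None:
        bad = set(self.classes.unique()) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes {sorted(bad)}")

    def genes_of(self, cls: str) -> frozenset[str]:
        return frozenset(self.classes.index[self.classes == cls])

    @property
    def common_essential(self) -> GeneSet:
        return GeneSet("common_essential", self.genes_of("common_essential"))

    @property
    def context_essential(self) -> GeneSet:
        return GeneSet("context_essential", self.genes_of("context_essential"))

    @property
    def essential_in_context(self) -> GeneSet:
        members = self.genes_of("common_essential") | self.genes_of("context_essential")
        return GeneSet("essential_in_context", members)


def _assign_classes(spec: SyntheticSpec, rng: np.random.Generator) -> GroundTruth:
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    n_common = round(spec.frac_common_essential * spec.n_genes)
    n_context = round(spec.frac_context_essential * spec.n_genes)
    classes = np.array(
        ["common_essential"] * n_common
        + ["context_essential"] * n_context
        + ["non_essential"] * (spec.n_genes - n_common - n_context)
    )
    rng.shuffle(classes)
    return GroundTruth(classes=pd.Series(classes, index=pd.Index(genes, name="gene")))


def simulate_screen(spec: SyntheticSpec) -> tuple[GeneEffectMatrix, GroundTruth]:
    """Draw a gene-effect matrix over context + other cell-line panels.

    Context cell lines are named ``CTX_##`` and the non-context panel
    ``OTH_##``.  Optional uniform missing-value injection is controlled by
    ``spec.missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    gt = _assign_classes(spec, rng)
    n_ctx, n_oth = spec.n_context_lines, spec.n_other_lines
    cols = [f"CTX_{i:02d}" for i in range(n_ctx)] + [f"OTH_{i:02d}" for i in range(n_oth)]

    cls = gt.classes.to_numpy()
    mu = np.zeros((spec.n_genes, n_ctx + n_oth))
    sd = np.full((spec.n_genes, n_ctx + n_oth), spec.sd_nonessential)
    is_common = cls == "common_essential"
    is_context = cls == "context_essential"
    mu[is_common, :] = spec.mu_essential
    sd[is_common, :] = spec.sd_essential
    mu[is_context, :n_ctx] = spec.mu_essential
    sd[is_context, :n_ctx] = spec.sd_essential

    scores = rng.normal(mu, sd) if (sd > 0).any() else mu.copy()
    if (sd == 0).any():
        scores = np.where(sd == 0, mu, scores)
    if spec.missing_rate > 0:
        mask = rng.random(scores.shape) < spec.missing_rate
        scores = np.where(mask, np.nan, scores)

    df = pd.DataFrame(scores, index=gt.classes.index, columns=cols)
    # synthetic Entrez-style IDs keep written files in the standard dialect
    # ("SYMBOL (ID)" headers), so CSV round-trips detect orientation correctly
    entrez = {g: 100000 + i for i, g in enumerate(gt.classes.index)}
    return GeneEffectMatrix(scores=df, entrez=entrez), gt


def simulate_ppi(gt: GroundTruth, spec: SyntheticSpec) -> EdgeList:
    """Degree-biased preferential-attachment PPI over the ground-truth genes.

    Nodes join in random order and attach ``ppi_edges_per_node`` edges to
    existing nodes with probability proportional to (degree + 1), multiplied
    by ``attachment_multiplier`` when the target gene is essential in the
    context.  With multiplier > 1 essential genes become hubs.  Every edge is
    tagged with the context tissue token except a ``mislabel_fraction``
    retagged to a foreign tissue.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = list(gt.classes.index)
    essential = gt.essential_in_context.members
    order = list(rng.permutation(genes))
    m = max(1, spec.ppi_edges_per_node)

    degree = {g: 0 for g in genes}
    present: list[str] = []
    edges: list[tuple[str, str]] = []
    for i, g in enumerate(order):
        if i == 0:
            present.append(g)
            continue
        k = min(m, len(present))
        weights = np.array(
            [
                (degree[t] + 1.0)
                * (spec.attachment_multiplier if t in essential else 1.0)
                for t in present
            ]
        )
        weights /= weights.sum()
        targets = rng.choice(len(present), size=k, replace=False, p=weights)
        for ti in targets:
            t = present[ti]
            edges.append((g, t))
            degree[g] += 1
            degree[t] += 1
        present.append(g)

    df = pd.DataFrame(edges, columns=["gene_a", "gene_b"])
    tissue = np.full(len(df), spec.tissue, dtype=object)
    if spec.mislabel_fraction > 0:
        flip = rng.random(len(df)) < spec.mislabel_fraction
        tissue[flip] = "other_tissue"
    df["tissue"] = tissue
    return df


def simulate_bio_features(gt: GroundTruth, spec: SyntheticSpec) -> FeatureTable:
    """Informative + distractor numeric gene attributes ("bio"/"exp" groups).

    Informative columns are ``signal * 1[essential-in-context] + N(0, 1)``;
    distractors are pure N(0, 1) noise.  Both kinds are split evenly between
    the "bio" and "exp" group tags so group-wise assembly is exercised.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = gt.classes.index
    indicator = genes.isin(gt.essential_in_context.members).astype(float)

    cols, groups = {}, {}
    for j in range(spec.n_informative):
        name = f"signal_{j:02d}"
        cols[name] = spec.feature_signal * indicator + rng.normal(size=len(genes))
        groups[name] = "bio" if j % 2 == 0 else "exp"
    for j in range(spec.n_distractor):
        name = f"noise_{j:02d}"
        cols[name] = rng.normal(size=len(genes))
        groups[name] = "bio" if j % 2 == 0 else "exp"
    values = pd.DataFrame(cols, index=genes)
    return FeatureTable(values=values, groups=pd.Series(groups))
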