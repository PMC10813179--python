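"""Cross-method label-set comparison and csEG/core-fitness evaluation.

Two concerns live here: (i) exact intersection accounting over any number of
named essential-gene sets (the UpSet-style breakdown into exclusive regions),
and (ii) scoring predictions separately on context-specific essential genes
(csEGs: labelled E but absent from the core-fitness reference) versus
core-fitness genes (CFGs, e.g. the OGEE core-essential list), reported as
TPR/FNR percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd

from cseg.io import GeneSet


def _members(s) -> frozenset:
    return s.members if isinstance(s, GeneSet) else frozenset(s)


@dataclass
class IntersectionReport:
    """Exclusive-region cardinalities over the power set of the input sets."""

    set_names: tuple[str, ...]
    totals: dict  # name -> |set|
    regions: dict  # frozenset of names -> exclusive region size
    union_size: int

    def __post_init__(self) -> None:
        if sum(self.regions.values()) != self.union_size:
            raise AssertionError("exclusive regions must partition the union")
        for name in self.set_names:
            recovered = sum(v for k, v in self.regions.items() if name in k)
            if recovered != self.totals[name]:
                raise AssertionError(f"region sums do not recover |{name}|")

    @property
    def all_sets_intersection(self) -> int:
        return self.regions.get(frozenset(self.set_names), 0)

    def exclusive(self, name: str) -> int:
        """Genes found only by ``name``."""
        return self.regions.get(frozenset({name}), 0)

    def shared_by(self, *names: str) -> int:
        """Total overlap of the given sets (inclusive, not exclusive)."""
        want = set(names)
        return sum(v for k, v in self.regions.items() if want <= k)


def intersect_label_sets(sets: Mapping[str, GeneSet]) -> IntersectionReport:
    """Exact region cardinalities via per-gene membership signatures."""
    if len(sets) < 2:
        raise ValueError("need at least two sets to intersect")
    members = {name: _members(s) for name, s in sets.items()}
    universe = set().union(*members.values())
    regions: dict[frozenset, int] = {}
    for gene in universe:
        sig = frozenset(name for name, m in members.items() if gene in m)
        regions[sig] = regions.get(sig, 0) + 1
    return IntersectionReport(
        set_names=tuple(sets),
        totals={name: len(m) for name, m in members.items()},
        regions=regions,
        union_size=len(universe),
    )


def plot_intersections(report: IntersectionReport, path) -> None:
    """UpSet-style bar chart of exclusive region sizes (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items = sorted(report.regions.items(), key=lambda kv: -kv[1])
    labels = [" & ".join(sorted(k)) for k, _ in items]
    sizes = [v for _, v in items]
    fig, ax = plt.subplots(figsize=(max(6, len(items)), 4))
    ax.bar(range(len(items)), sizes, color="0.3")
    ax.set_xticks(range(len(items)))
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("genes in exclusive region")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# csEG vs core-fitness split


def cseg_split(e_labels: GeneSet, cfg: GeneSet) -> tuple[GeneSet, GeneSet]:
    """Split an E set into context-specific (E \\ CFG) and common (E & CFG)."""
    e = _members(e_labels)
    c = _members(cfg)
    cseg = GeneSet(name="csEG", members=frozenset(e - c))
    common = GeneSet(name="common_E", members=frozenset(e & c))
    return cseg, common


@dataclass
class SplitRates:
    """TPR/FNR (percent) on the csEG and CFG partitions of the labelled E set.

    Rates are None when a partition is empty (undefined, not zero).
    TPR + FNR == 100 within each non-empty partition by construction.
    """

    cseg_tpr: float | None
    cseg_fnr: float | None
    cfg_tpr: float | None
    cfg_fnr: float | None
    n_cseg: int
    n_cfg: int

    def as_dict(self) -> dict:
        return {
            "csEG": {"TPR": self.cseg_tpr, "FNR": self.cseg_fnr, "n": self.n_cseg},
            "CFG": {"TPR": self.cfg_tpr, "FNR": self.cfg_fnr, "n": self.n_cfg},
        }


def split_rates(predicted_e: GeneSet, labelled_e: GeneSet, cfg: GeneSet) -> SplitRates:
    """Percentage of labelled-E genes predicted E, split by core-fitness status.

    The denominators are the labelled csEG and labelled common-E subset
    sizes — the number of E-labelled genes served as input, not the number
    of predictions made.
    """
    labelled = _members(labelled_e)
    if not labelled:
        raise ValueError("labelled E set is empty")
    pred = _members(predicted_e)
    cseg, common = cseg_split(labelled_e, cfg)

    def rates(subset: frozenset) -> tuple[float | None, float | None]:
        if not subset:
            return None, None
        tpr = 100.0 * len(subset & pred) / len(subset)
        return tpr, 100.0 - tpr

    cseg_tpr, cseg_fnr = rates(cseg.members)
    cfg_tpr, cfg_fnr = rates(common.members)
    return SplitRates(
        cseg_tpr=cseg_tpr, cseg_fnr=cseg_fnr,
        cfg_tpr=cfg_tpr, cfg_fnr=cfg_fnr,
        n_cseg=len(cseg.members), n_cfg=len(common.members),
    )
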