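"""Readers, writers and shared containers for screen artifacts.

All files are plain text: CSV for gene-effect matrices, label tables and
feature tables; TSV for PPI edge lists; one-symbol-per-line text for gene
sets.  Gene identity is keyed by symbol throughout; the Entrez numeric ID in
DepMap-style ``"SYMBOL (ID)"`` headers is carried as metadata only, because
every other artifact in the workflow (PPI edges, feature tables, reference
gene lists) is symbol-keyed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_DEPMAP_HEADER = re.compile(r"^\s*(?P<symbol>[^()\s]+)\s*(?:\((?P<id>\d+)\))?\s*$")

VALID_LABELS = ("E", "NE")


# ---------------------------------------------------------------------------
# containers


@dataclass
class GeneEffectMatrix:
    """Knockout fitness scores, genes x cell lines.

    More negative scores mean stronger dependency (DepMap scaling: the median
    common-essential gene sits near -1, non-essential genes near 0).  Missing
    scores are kept as NaN; each downstream operation states its own
    missing-value policy.
    """

    scores: pd.DataFrame  # index = gene symbols, columns = cell lines
    entrez: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            dups = self.scores.index[self.scores.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if self.scores.columns.duplicated().any():
            raise ValueError("duplicate cell-line identifiers")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass
class LabelTable:
    """Gene -> {"E", "NE"} assignment with the producing method recorded."""

    labels: pd.Series  # index = gene symbol, values in {"E", "NE"}
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"labels must be E/NE, got {sorted(bad)}")
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate genes in label table")

    @property
    def e_set(self) -> GeneSet:
        genes = frozenset(self.labels.index[self.labels == "E"])
        return GeneSet(name=self.provenance or "E", members=genes)

    @property
    def ne_set(self) -> GeneSet:
        genes = frozenset(self.labels.index[self.labels == "NE"])
        return GeneSet(name=(self.provenance or "") + "_NE", members=genes)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTable):
            return NotImplemented
        return self.provenance == other.provenance and self.labels.sort_index().equals(
            other.labels.sort_index()
        )


# An edge list is a DataFrame with columns gene_a, gene_b plus free-form
# annotation columns (e.g. "tissue"); undirected semantics, no self-loops.
EdgeList = pd.DataFrame

FEATURE_GROUPS = ("bio", "exp", "orth", "subloc", "emb", "other")


@dataclass
class FeatureTable:
    """Gene x numeric-attribute table, each column tagged with a group.

    Groups follow the feature-family vocabulary of essential-gene predictors:
    "bio" (genetic/functional attributes), "exp" (expression), "orth"
    (orthology), "subloc" (subcellular localisation), "emb" (network
    embeddings), "other".
    """

    values: pd.DataFrame  # index = gene symbol
    groups: pd.Series  # index = column name, value = group tag

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature column names")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate genes in feature table")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"columns without a group tag: {sorted(missing)[:5]}")
        bad = set(self.groups.unique()) - set(FEATURE_GROUPS)
        if bad:
            raise ValueError(f"unknown feature groups: {sorted(bad)}")

    def columns_for(self, groups: Iterable[str]) -> list[str]:
        wanted = set(groups)
        return [c for c in self.values.columns if self.groups[c] in wanted]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# gene-effect matrices


def _parse_depmap_header(cell: str):
    m = _DEPMAP_HEADER.match(cell)
    if m is None or not m.group("symbol"):
        return None
    gid = m.group("id")
    return m.group("symbol"), (int(gid) if gid is not None else None)


def _looks_like_gene_headers(cells: Sequence[str]) -> bool:
    """DepMap gene headers carry a parenthesised numeric ID: "A1BG (1)"."""
    parsed = [_parse_depmap_header(str(c)) for c in cells]
    with_id = sum(1 for p in parsed if p is not None and p[1] is not None)
    return with_id >= max(1, len(cells) // 2)


def read_gene_effect(path, orientation: str = "auto") -> GeneEffectMatrix:
    """Read a gene-effect CSV in the DepMap dialect.

    ``orientation`` is one of ``cell_lines_by_genes`` (DepMap portal layout:
    rows are cell lines, columns are "SYMBOL (ID)" genes),
    ``genes_by_cell_lines``, or ``auto`` which detects gene headers by the
    parenthesised numeric ID.  The returned matrix is always canonical
    genes x cell lines; empty cells become NaN.
    """
    df = pd.read_csv(path, index_col=0)
    if orientation not in ("auto", "cell_lines_by_genes", "genes_by_cell_lines"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "auto":
        orientation = (
            "cell_lines_by_genes"
            if _looks_like_gene_headers(list(df.columns))
            else "genes_by_cell_lines"
        )
    if orientation == "cell_lines_by_genes":
        df = df.T  # -> genes x cell lines, gene labels still "SYMBOL (ID)"

    symbols: list[str] = []
    entrez: dict[str, int] = {}
    for raw in df.index:
        parsed = _parse_depmap_header(str(raw))
        if parsed is None:
            raise ValueError(f"malformed gene header cell: {raw!r}")
        sym, gid = parsed
        symbols.append(sym)
        if gid is not None:
            entrez[sym] = gid
    if len(set(symbols)) != len(symbols):
        seen: set[str] = set()
        dups = [s for s in symbols if s in seen or seen.add(s)]
        raise ValueError(f"duplicate gene symbols in file: {sorted(set(dups))[:5]}")
    df.index = pd.Index(symbols, name="gene")
    df = df.astype(float)
    df.columns = [str(c) for c in df.columns]
    return GeneEffectMatrix(scores=df, entrez=entrez)


def write_gene_effect(m: GeneEffectMatrix, path, orientation: str = "cell_lines_by_genes") -> None:
    """Write back in the DepMap dialect ("SYMBOL (ID)" headers where known)."""
    labels = [
        f"{g} ({m.entrez[g]})" if g in m.entrez else g for g in m.scores.index
    ]
    out = m.scores.copy()
    out.index = pd.Index(labels, name="gene")
    if orientation == "cell_lines_by_genes":
        out = out.T
        out.index.name = "cell_line"
    elif orientation != "genes_by_cell_lines":
        raise ValueError(f"unknown orientation {orientation!r}")
    out.to_csv(path)


def filter_context(m: GeneEffectMatrix, keep: Sequence[str]) -> GeneEffectMatrix:
    """Restrict a screen to a context (tissue) panel of cell lines."""
    keep = list(keep)
    if not keep:
        raise ValueError("keep must be non-empty")
    missing = [c for c in keep if c not in m.scores.columns]
    if missing:
        raise KeyError(f"cell lines not in matrix: {missing}")
    return GeneEffectMatrix(scores=m.scores.loc[:, keep].copy(), entrez=dict(m.entrez))


# ---------------------------------------------------------------------------
# gene sets


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read one gene symbol per line; '#' comments and blank lines ignored."""
    path = Path(path)
    members: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        members.append(token)
    unique = frozenset(members)
    if len(unique) < len(members):
        warnings.warn(f"{path.name}: {len(members) - len(unique)} duplicate gene symbols collapsed")
    if not unique:
        warnings.warn(f"{path.name}: empty gene set")
    return GeneSet(name=name or path.stem, members=unique)


def write_gene_set(s: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(s.members)) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# label tables


def write_labels(t: LabelTable, path) -> None:
    df = pd.DataFrame({"gene": t.labels.index, "label": t.labels.values})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# provenance: {t.provenance}\n")
        df.to_csv(fh, index=False)


def read_labels(path) -> LabelTable:
    provenance = ""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first.split(":", 1)[1].strip()
            body_start = 1
        else:
            body_start = 0
    df = pd.read_csv(path, comment="#")
    if not {"gene", "label"} <= set(df.columns):
        raise ValueError("label file must have 'gene' and 'label' columns")
    labels = []
    for i, raw in enumerate(df["label"]):
        token = str(raw).strip().upper()
        if token not in VALID_LABELS:
            # +2: header line, 1-based numbering; +1 more if provenance comment
            raise ValueError(
                f"unknown label {raw!r} on line {i + 2 + body_start}"
            )
        labels.append(token)
    series = pd.Series(labels, index=pd.Index(df["gene"].astype(str), name="gene"))
    return LabelTable(labels=series, provenance=provenance)


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path) -> EdgeList:
    """Read a TSV edge list: gene_a, gene_b, plus annotation columns.

    Self-loops are dropped; duplicate undirected edges (a,b)==(b,a) are
    collapsed keeping the first record's annotations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError("edge list must have 'gene_a' and 'gene_b' columns")
    df = df[df["gene_a"] != df["gene_b"]].copy()
    key = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    df = df.loc[~key.duplicated()].reset_index(drop=True)
    return df


def write_edge_list(edges: EdgeList, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(t: FeatureTable, path) -> None:
    """CSV with group-prefixed headers: "bio:gene_length", "emb:emb_000", ..."""
    out = t.values.copy()
    out.columns = [f"{t.groups[c]}:{c}" for c in out.columns]
    out.index.name = "gene"
    out.to_csv(path)


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, index_col=0)
    names, groups = [], {}
    for col in df.columns:
        if ":" not in col:
            raise ValueError(f"feature column {col!r} lacks a 'group:' prefix")
        grp, name = col.split(":", 1)
        names.append(name)
        groups[name] = grp
    df.columns = names
    df.index = df.index.astype(str)
    return FeatureTable(values=df.astype(float), groups=pd.Series(groups))
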