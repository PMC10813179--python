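"""Tissue PPI networks and node2vec gene embeddings.

The embedding follows the node2vec recipe: biased second-order random walks
over the undirected PPI (return bias ``p``, in-out bias ``q``) generate a
corpus of node sequences, and a skip-gram model with negative sampling
(SGNS) learns one d-dimensional vector per gene.  The SGNS trainer is a
small numpy SGD implementation; with a fixed seed and single-process
training it is bit-for-bit reproducible, which is part of the module's
contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from cseg.io import EdgeList, FeatureTable


@dataclass
class EmbeddingMatrix:
    """Gene -> d-dimensional vector plus the training metadata that made it."""

    vectors: pd.DataFrame  # index = gene, columns = emb_000..emb_{d-1}
    params: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def group_name(self) -> str:
        return f"embn2v{self.dim}"


def filter_tissue_edges(edges: EdgeList, tissue: str, field_name: str = "tissue") -> nx.Graph:
    """Keep edges whose tissue annotation contains the token (case-insensitive).

    Isolated nodes cannot arise because nodes enter the graph only through
    surviving edges.  Raises when no edge carries the tissue token.
    """
    if field_name not in edges.columns:
        raise KeyError(f"edge list has no {field_name!r} annotation column")
    token = tissue.lower()
    mask = edges[field_name].astype(str).str.lower().str.contains(token, regex=False)
    kept = edges.loc[mask]
    if kept.empty:
        raise ValueError(f"no edges annotated with tissue {tissue!r}")
    g = nx.Graph(tissue=tissue)
    g.add_edges_from(zip(kept["gene_a"], kept["gene_b"]))
    g.remove_edges_from(nx.selfloop_edges(g))
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


# ---------------------------------------------------------------------------
# random walks


def _csr_adjacency(g: nx.Graph) -> tuple[list, np.ndarray, np.ndarray]:
    """Nodes in sorted order plus CSR-style (indptr, neighbors) arrays with
    each neighbor list sorted, so membership tests can use searchsorted."""
    nodes = sorted(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
    neigh_lists = []
    for i, n in enumerate(nodes):
        nb = np.array(sorted(index[v] for v in g.neighbors(n)), dtype=np.int64)
        neigh_lists.append(nb)
        indptr[i + 1] = indptr[i] + nb.size
    neighbors = np.concatenate(neigh_lists) if neigh_lists else np.empty(0, dtype=np.int64)
    return nodes, indptr, neighbors


def generate_walks(
    g: nx.Graph,
    walk_length: int = 80,
    walks_per_node: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 42,
) -> tuple[list[str], list[np.ndarray]]:
    """node2vec biased walks; returns (node order, walks of node indices)."""
    nodes, indptr, neighbors = _csr_adjacency(g)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    uniform = p == 1.0 and q == 1.0
    walks: list[np.ndarray] = []
    for _ in range(walks_per_node):
        for start in rng.permutation(n):
            walk = np.empty(walk_length, dtype=np.int64)
            walk[0] = start
            cur = start
            prev = -1
            for step in range(1, walk_length):
                nb = neighbors[indptr[cur]: indptr[cur + 1]]
                if nb.size == 0:
                    walk = walk[:step]
                    break
                if uniform or prev < 0:
                    nxt = nb[rng.integers(nb.size)]
                else:
                    w = np.ones(nb.size)
                    w[nb == prev] = 1.0 / p
                    prev_nb = neighbors[indptr[prev]: indptr[prev + 1]]
                    adj_prev = prev_nb[np.searchsorted(prev_nb, nb).clip(max=prev_nb.size - 1)] == nb
                    far = ~adj_prev & (nb != prev)
                    w[far] = 1.0 / q
                    nxt = nb[np.searchsorted(np.cumsum(w), rng.random() * w.sum())]
                prev, cur = cur, nxt
                walk[step] = cur
            walks.append(walk)
    return nodes, walks


# ---------------------------------------------------------------------------
# skip-gram with negative sampling


def _walks_to_pairs(walks: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for walk in walks:
        L = walk.size
        for off in range(1, window + 1):
            if L <= off:
                continue
            a, b = walk[:-off], walk[off:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)  # symmetric context
            contexts.append(a)
    return np.concatenate(centers), np.concatenate(contexts)


def _train_sgns(
    centers: np.ndarray,
    contexts: np.ndarray,
    n_nodes: int,
    dim: int,
    negative: int,
    epochs: int,
    lr: float,
    seed: int,
    batch_size: int = 8192,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n_nodes, dim))
    w_out = np.zeros((n_nodes, dim))

    freq = np.bincount(contexts, minlength=n_nodes).astype(float)
    noise = freq ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    n_pairs = centers.size
    total_batches = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    batch_no = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = order[lo: lo + batch_size]
            c_idx, o_idx = centers[sel], contexts[sel]
            neg_idx = np.searchsorted(noise_cdf, rng.random((sel.size, negative)))

            step = lr * (1.0 - 0.99 * batch_no / total_batches)
            batch_no += 1

            c = w_in[c_idx]                      # (B, d)
            pos = w_out[o_idx]                   # (B, d)
            neg = w_out[neg_idx]                 # (B, k, d)

            s_pos = np.clip((c * pos).sum(1), -30.0, 30.0)
            s_neg = np.clip(np.einsum("bd,bkd->bk", c, neg), -30.0, 30.0)
            g_pos = 1.0 / (1.0 + np.exp(-s_pos)) - 1.0   # (B,)
            g_neg = 1.0 / (1.0 + np.exp(-s_neg))         # (B, k)

            # accumulate per-row gradients, then apply the *mean* gradient per
            # row: a row repeated r times in a batch would otherwise receive an
            # r-times-larger step, which diverges on small vocabularies
            grad_c = g_pos[:, None] * pos + np.einsum("bk,bkd->bd", g_neg, neg)
            g_in = np.zeros_like(w_in)
            np.add.at(g_in, c_idx, grad_c)
            cnt_in = np.bincount(c_idx, minlength=n_nodes)
            w_in -= step * g_in / np.maximum(cnt_in, 1)[:, None]

            g_out = np.zeros_like(w_out)
            np.add.at(g_out, o_idx, g_pos[:, None] * c)
            np.add.at(
                g_out,
                neg_idx.ravel(),
                (g_neg[..., None] * c[:, None, :]).reshape(-1, dim),
            )
            cnt_out = np.bincount(o_idx, minlength=n_nodes) + np.bincount(
                neg_idx.ravel(), minlength=n_nodes
            )
            w_out -= step * g_out / np.maximum(cnt_out, 1)[:, None]
    return w_in


def embed_network(
    g: nx.Graph,
    dim: int = 64,
    walk_length: int = 80,
    walks_per_node: int = 10,
    window: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    negative: int = 5,
    epochs: int = 5,
    lr: float = 1.0,
    seed: int = 42,
) -> EmbeddingMatrix:
    """Learn node2vec vectors for every node of the network.

    Defaults follow the node2vec reference settings (walk length 80, 10
    walks per node, window 10, p = q = 1) with embedding dimension 64, the
    size conventionally used for gene-essentiality feature sets.  The SGD
    trainer applies the per-row *mean* gradient within each minibatch, so
    the learning rate is on a batch-averaged-gradient scale (default 1.0),
    not the per-pair scale of classic word2vec.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    if g.number_of_nodes() < dim:
        warnings.warn(
            f"network has {g.number_of_nodes()} nodes, fewer than dim={dim}"
        )
    nodes, walks = generate_walks(
        g, walk_length=walk_length, walks_per_node=walks_per_node, p=p, q=q, seed=seed
    )
    centers, contexts = _walks_to_pairs(walks, window)
    vectors = _train_sgns(
        centers, contexts, n_nodes=len(nodes), dim=dim, negative=negative,
        epochs=epochs, lr=lr, seed=seed + 1,
    )
    cols = [f"emb_{i:03d}" for i in range(dim)]
    df = pd.DataFrame(vectors, index=pd.Index(nodes, name="gene"), columns=cols)
    params = dict(
        dim=dim, walk_length=walk_length, walks_per_node=walks_per_node,
        window=window, p=p, q=q, negative=negative, epochs=epochs, lr=lr, seed=seed,
    )
    return EmbeddingMatrix(vectors=df, params=params)


def align_features(
    emb: EmbeddingMatrix,
    universe,
    missing_policy: str = "zeros",
) -> FeatureTable:
    """Expand an embedding to a feature table over an ordered gene universe.

    ``zeros``: genes absent from the network get a zero vector plus an
    ``emb_missing`` indicator column set to 1.  ``drop``: absent genes are
    removed.  The zeros policy keeps the feature matrix aligned with the
    full label universe, which downstream feature assembly expects.
    """
    universe = list(universe)
    if missing_policy == "drop":
        present = [g for g in universe if g in emb.vectors.index]
        values = emb.vectors.loc[present].copy()
        groups = pd.Series("emb", index=values.columns)
        return FeatureTable(values=values, groups=groups)
    if missing_policy != "zeros":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    values = emb.vectors.reindex(universe)
    indicator = values.isna().all(axis=1).astype(float)
    values = values.fillna(0.0)
    values["emb_missing"] = indicator
    groups = pd.Series("emb", index=values.columns)
    return FeatureTable(values=values, groups=groups)
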