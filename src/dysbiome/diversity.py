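"""Rarefaction, alpha diversity (Shannon, richness, Faith's PD), Canberra.

Shannon is base 2 by default, matching the QIIME2 convention under which the
alpha metrics of the original workflow were computed; the base is an option.
Canberra is returned as the raw per-feature-normalised L1 sum with double-zero
features excluded; an ecology-style variant scaled by the number of non
double-zero features is available behind ``normalized=True`` (only rank order
matters for the permutation tests downstream).
"""

from __future__ import annotations

import io
import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .tables import AsvTable

log = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 20_000


def rarefy(table: AsvTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed=None) -> AsvTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (their ids are
    logged).  Rarefaction is performed once per sample with the given seed;
    repeated rarefactions are not averaged.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    dropped = list(totals.index[totals < depth])
    if dropped:
        log.warning("rarefy: dropping %d samples below depth %d: %s", len(dropped), depth, dropped)
    kept = totals.index[totals >= depth]
    out = np.empty((len(kept), table.n_asvs), dtype=np.int64)
    counts = table.counts.loc[kept].to_numpy()
    for i, row in enumerate(counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return AsvTable(
        pd.DataFrame(out, index=kept, columns=table.counts.columns),
        table.taxonomy,
        table.sequences,
    )


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i over positive counts."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector has undefined diversity")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def richness(counts) -> int:
    """Number of taxa with strictly positive count."""
    return int((np.asarray(counts) > 0).sum())


def _as_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    if isinstance(tree, str) and tree.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(tree))
    return TreeNode.read(str(tree))


def faith_pd(counts, asv_ids, tree) -> float:
    """Faith's phylogenetic diversity of the observed taxa.

    Sum of branch lengths on the union of root-to-tip paths of every tip with
    a positive count, including stem branches up to the root (rooted-tree
    convention).  ``tree`` may be a skbio TreeNode, a newick string, or a path.
    """
    c = np.asarray(counts)
    observed = [a for a, x in zip(asv_ids, c) if x > 0]
    if not observed:
        raise ValueError("no observed taxa; Faith's PD is undefined")
    t = _as_tree(tree)
    tips = {tip.name: tip for tip in t.tips()}
    missing = [a for a in observed if a not in tips]
    if missing:
        raise ValueError(f"observed ASVs missing from tree: {missing[:5]}")
    seen: set[int] = set()
    pd_sum = 0.0
    for name in observed:
        node = tips[name]
        while node is not None:
            if id(node) in seen:
                break
            seen.add(id(node))
            if node.length is not None:
                pd_sum += node.length
            node = node.parent
    return pd_sum


def alpha_diversity_table(table: AsvTable, tree=None, base: float = 2.0) -> pd.DataFrame:
    """Per-sample alpha diversity: shannon, richness, and faith_pd if a tree is given."""
    t = None if tree is None else _as_tree(tree)
    rows = []
    for sid in table.sample_ids:
        c = table.counts.loc[sid].to_numpy()
        row = {"shannon": shannon(c, base=base), "richness": richness(c)}
        if t is not None:
            row["faith_pd"] = faith_pd(c, table.asv_ids, t)
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample_id"))


def canberra_matrix(table, normalized: bool = False) -> DistanceMatrix:
    """All-pairs Canberra distance d(x,y) = sum_i |x_i-y_i| / (x_i+y_i).

    The sum runs over features where x_i + y_i > 0; double-zero features
    contribute nothing.  With ``normalized=True`` each distance is divided by
    its number of contributing features.
    """
    if isinstance(table, AsvTable):
        X = table.counts.to_numpy(dtype=float)
        ids = table.sample_ids
    else:
        X = np.asarray(table, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    D = np.zeros((n, n))
    for i in range(n - 1):
        diff = np.abs(X[i] - X[i + 1:])
        s = X[i] + X[i + 1:]
        mask = s > 0
        terms = np.divide(diff, s, out=np.zeros_like(diff), where=mask)
        d = terms.sum(axis=1)
        if normalized:
            nnz = mask.sum(axis=1)
            d = np.divide(d, nnz, out=np.zeros_like(d), where=nnz > 0)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return DistanceMatrix(D, ids)
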