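"""Community-level analyses: PERMANOVA with strata, classical PCoA, and
mean distance of query samples to a reference group.

The PERMANOVA is Anderson's one-way pseudo-F computed directly from the
distance matrix.  When a strata factor is given, labels are permuted only
within each stratum, which is how matched designs (e.g. case/control pairs or
subgroups) are respected under the null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

log = logging.getLogger(__name__)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    n_perm: int
    strata: str | None = None
    method: str = "random"

    def __post_init__(self) -> None:
        assert 0.0 < self.p <= 1.0


def _align_factor(dm: DistanceMatrix, factor) -> np.ndarray:
    """Order a factor (Series indexed by sample id, mapping, or array) by dm.ids."""
    if isinstance(factor, pd.Series):
        return factor.loc[list(dm.ids)].to_numpy()
    if isinstance(factor, dict):
        return np.asarray([factor[i] for i in dm.ids])
    arr = np.asarray(factor)
    if len(arr) != len(dm.ids):
        raise ValueError("factor length does not match distance matrix")
    return arr


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permute_within_strata(rng: np.random.Generator, codes: np.ndarray,
                          strata_codes: np.ndarray | None) -> np.ndarray:
    """One permutation of group codes; restricted within strata when given."""
    out = codes.copy()
    if strata_codes is None:
        rng.shuffle(out)
        return out
    for s in np.unique(strata_codes):
        idx = np.flatnonzero(strata_codes == s)
        out[idx] = out[idx[rng.permutation(len(idx))]]
    return out


def _exhaustive_codes(codes: np.ndarray, strata_codes: np.ndarray | None):
    """All distinct label arrangements (within strata), for tiny problems."""
    if strata_codes is None:
        blocks = [np.arange(len(codes))]
    else:
        blocks = [np.flatnonzero(strata_codes == s) for s in np.unique(strata_codes)]
    per_block = [sorted(set(itertools.permutations(codes[idx]))) for idx in blocks]
    for combo in itertools.product(*per_block):
        out = codes.copy()
        for idx, perm in zip(blocks, combo):
            out[idx] = perm
        yield out


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 999, strata=None,
              seed=None, method: str = "random") -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Parameters
    ----------
    grouping, strata
        Factors as pandas Series indexed by sample id, dicts, or arrays in
        distance-matrix order.  ``strata`` restricts null permutations so no
        sample ever crosses a stratum.
    method
        "random" draws ``n_perm`` Monte-Carlo permutations and applies the
        (+1)/(+1) p-value convention; "exhaustive" enumerates every distinct
        within-strata arrangement (tiny problems only) and p is the exact
        fraction of arrangements (including identity) with F* >= F.
    """
    labels = _align_factor(dm, grouping)
    levels, codes = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("grouping must have at least two levels")
    if np.bincount(codes).min() < 2:
        raise ValueError("every group needs at least two samples")
    strata_codes = None
    strata_name = None
    if strata is not None:
        strata_arr = _align_factor(dm, strata)
        strata_name = getattr(strata, "name", None) or "strata"
        _, strata_codes = np.unique(strata_arr, return_inverse=True)
        if np.bincount(strata_codes).min() < 2:
            raise ValueError("every stratum needs at least two samples")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, len(levels))
    eps = 1e-12
    if method == "exhaustive":
        hits = 0
        total = 0
        for perm_codes in _exhaustive_codes(codes, strata_codes):
            total += 1
            if _pseudo_f(d2, perm_codes, len(levels)) >= f_obs - eps:
                hits += 1
        return PermanovaResult(f_obs, hits / total, total - 1, strata_name, "exhaustive")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_codes = permute_within_strata(rng, codes, strata_codes)
        if _pseudo_f(d2, perm_codes, len(levels)) >= f_obs - eps:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(f_obs, p, n_perm, strata_name, "random")


# ---------------------------------------------------------------------------
# PCoA (classical metric multidimensional scaling)
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: pd.DataFrame      # samples x retained positive axes
    eigenvalues: np.ndarray        # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Classical scaling of a distance matrix.

    Eigendecomposition of the Gower-centred matrix -1/2 J (D*D) J; axes are
    ordered by eigenvalue.  Negative eigenvalues are reported but their axes
    are excluded (no Cailliez/Lingoes correction); ``k`` beyond the number of
    positive eigenvalues is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D2 = np.asarray(dm.data, dtype=float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10 if len(eigvals) else 0.0
    n_pos = int((eigvals > tol).sum())
    if k > n_pos:
        log.warning("pcoa: requested %d axes but only %d positive eigenvalues; truncating", k, n_pos)
        k = max(n_pos, 0)
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    pos_sum = eigvals[eigvals > 0].sum()
    prop = eigvals / pos_sum if pos_sum > 0 else np.zeros_like(eigvals)
    frame = pd.DataFrame(
        coords,
        index=pd.Index(list(dm.ids), name="sample_id"),
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
    return PcoaResult(frame, eigvals, prop)


# ---------------------------------------------------------------------------
# mean distance to a reference group
# ---------------------------------------------------------------------------

def mean_distance_to_group(dm: DistanceMatrix, query_ids, reference_ids) -> pd.Series:
    """Per-query arithmetic mean distance to the reference samples.

    A query that is itself in the reference set is excluded from its own mean.
    """
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("empty reference group")
    idx = {s: i for i, s in enumerate(dm.ids)}
    ref_idx = np.asarray([idx[r] for r in reference_ids])
    data = np.asarray(dm.data)
    out = {}
    for q in query_ids:
        qi = idx[q]
        cols = ref_idx[ref_idx != qi]
        if len(cols) == 0:
            raise ValueError(f"query {q!r} has no reference samples besides itself")
        out[q] = float(data[qi, cols].mean())
    return pd.Series(out, name="mean_distance")


def compare_mean_distances(dm: DistanceMatrix, query_a, query_b, reference_ids):
    """Two-tailed unpaired t-test comparing two query groups' mean distances
    to a common reference group (the F/RAI+ vs F/RAI- style contrast)."""
    a = mean_distance_to_group(dm, query_a, reference_ids)
    b = mean_distance_to_group(dm, query_b, reference_ids)
    t, p = stats.ttest_ind(a.to_numpy(), b.to_numpy())
    return {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "t": float(t), "p": float(p), "per_query_a": a, "per_query_b": b}
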