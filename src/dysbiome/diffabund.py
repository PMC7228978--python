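"""Per-ASV differential abundance with the pipeline's filtering and effect-size
conventions.

Matched case/control comparisons use the two-tailed Wilcoxon signed-rank test;
independent groups use the Mann-Whitney U test.  Zero differences in the
signed-rank test are dropped before ranking (Wilcoxon's rule) and the
effective n recorded; an ASV whose pairwise differences are all zero gets
p = 1 and is flagged degenerate.  Exact null distributions are used for small
effective samples without ties, otherwise the normal approximation with
continuity and tie correction.

The log mean fold change (LMFC) is log10(mean_A) - log10(mean_B) after
replacing zero cells by 1 — the pseudocount touches zero cells only; the
conventional all-cells pseudocount is available via ``pseudocount="all"``.
Positive LMFC means enriched in the first group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AsvTable, paired_samples

log = logging.getLogger(__name__)

EXACT_N_MAX = 25  #: exact signed-rank null used up to this effective n (no ties)

RESULT_COLUMNS = [
    "asv_id", "test", "statistic", "p", "q", "lmfc",
    "prevalence_A", "prevalence_B", "n_effective", "degenerate",
]


def prevalence_filter(table: AsvTable, min_prevalence: float = 0.20,
                      sample_ids=None) -> AsvTable:
    """Keep ASVs present (nonzero) in at least ``min_prevalence`` of samples.

    The boundary is inclusive: an ASV at exactly the threshold is retained.
    ``sample_ids`` restricts both the prevalence computation and the returned
    table to the samples under comparison.
    """
    if not (0 < min_prevalence <= 1):
        raise ValueError("min_prevalence must be in (0, 1]")
    t = table if sample_ids is None else table.select_samples(sample_ids)
    prev = (t.counts > 0).mean(axis=0)
    keep = prev.index[prev >= min_prevalence]
    return t.select_asvs(keep)


def log_mean_fold_change(table: AsvTable, group_a_ids, group_b_ids,
                         pseudocount: str = "zeros") -> pd.Series:
    """Per-ASV log10 mean fold change of group A over group B."""
    if len(list(group_a_ids)) == 0 or len(list(group_b_ids)) == 0:
        raise ValueError("both groups must be non-empty")
    X = table.counts.to_numpy(dtype=float)
    if pseudocount == "zeros":
        X = np.where(X == 0, 1.0, X)
    elif pseudocount == "all":
        X = X + 1.0
    else:
        raise ValueError("pseudocount must be 'zeros' or 'all'")
    frame = pd.DataFrame(X, index=table.counts.index, columns=table.counts.columns)
    mean_a = frame.loc[list(group_a_ids)].mean(axis=0)
    mean_b = frame.loc[list(group_b_ids)].mean(axis=0)
    lmfc = np.log10(mean_a) - np.log10(mean_b)
    lmfc.name = "lmfc"
    return lmfc


def _prevalence(table: AsvTable, ids) -> pd.Series:
    return (table.counts.loc[list(ids)] > 0).mean(axis=0)


def _signed_rank(diffs: np.ndarray) -> tuple[float, float, int, bool]:
    """Two-tailed signed-rank (statistic, p, effective n, degenerate flag)."""
    nz = diffs[diffs != 0]
    m = len(nz)
    if m == 0:
        return 0.0, 1.0, 0, True
    no_ties = len(np.unique(np.abs(nz))) == m
    method = "exact" if (m <= EXACT_N_MAX and no_ties) else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue), m, False


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(a), len(b)) <= EXACT_N_MAX and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _assemble(asv_ids, test_name, stats_, pvals, lmfc, prev_a, prev_b,
              n_eff, degenerate) -> pd.DataFrame:
    df = pd.DataFrame({
        "asv_id": asv_ids,
        "test": test_name,
        "statistic": stats_,
        "p": pvals,
        "q": bh_fdr(pvals),
        "lmfc": np.asarray(lmfc, dtype=float),
        "prevalence_A": np.asarray(prev_a, dtype=float),
        "prevalence_B": np.asarray(prev_b, dtype=float),
        "n_effective": n_eff,
        "degenerate": degenerate,
    })
    return df[RESULT_COLUMNS]


def paired_wilcoxon_per_asv(table: AsvTable, metadata: pd.DataFrame,
                            pseudocount: str = "zeros") -> pd.DataFrame:
    """Signed-rank test per ASV across matched case/control pairs.

    Group A is the cases (PWH), group B the matched controls, so positive
    LMFC means enriched in cases.  Every sample in ``table`` must belong to a
    complete pair present in the table.
    """
    pairs = paired_samples(metadata.loc[metadata.index.intersection(table.sample_ids)])
    in_pairs = set(pairs["case_id"]) | set(pairs["control_id"])
    unpaired = [s for s in table.sample_ids if s not in in_pairs]
    if unpaired:
        raise ValueError(f"unpaired samples present in table: {unpaired[:5]}")
    case_ids = list(pairs["case_id"])
    control_ids = list(pairs["control_id"])
    cases = table.counts.loc[case_ids].to_numpy(dtype=float)
    controls = table.counts.loc[control_ids].to_numpy(dtype=float)
    stats_, pvals, n_eff, degen = [], [], [], []
    for j in range(table.n_asvs):
        s, p, m, d = _signed_rank(cases[:, j] - controls[:, j])
        stats_.append(s)
        pvals.append(p)
        n_eff.append(m)
        degen.append(d)
    lmfc = log_mean_fold_change(table, case_ids, control_ids, pseudocount=pseudocount)
    return _assemble(table.asv_ids, "paired_wilcoxon", stats_, pvals, lmfc,
                     _prevalence(table, case_ids), _prevalence(table, control_ids),
                     n_eff, degen)


def mannwhitney_per_asv(table: AsvTable, group_a_ids, group_b_ids,
                        pseudocount: str = "zeros") -> pd.DataFrame:
    """Mann-Whitney U test per ASV between two independent groups."""
    group_a_ids = list(group_a_ids)
    group_b_ids = list(group_b_ids)
    if not group_a_ids or not group_b_ids:
        raise ValueError("both groups must be non-empty")
    A = table.counts.loc[group_a_ids].to_numpy(dtype=float)
    B = table.counts.loc[group_b_ids].to_numpy(dtype=float)
    stats_, pvals = [], []
    for j in range(table.n_asvs):
        s, p = _mann_whitney(A[:, j], B[:, j])
        stats_.append(s)
        pvals.append(p)
    lmfc = log_mean_fold_change(table, group_a_ids, group_b_ids, pseudocount=pseudocount)
    n_eff = len(group_a_ids) + len(group_b_ids)
    return _assemble(table.asv_ids, "mann_whitney", stats_, pvals, lmfc,
                     _prevalence(table, group_a_ids), _prevalence(table, group_b_ids),
                     [n_eff] * table.n_asvs, [False] * table.n_asvs)
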