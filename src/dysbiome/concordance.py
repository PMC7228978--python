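"""Signature selection, list-overlap arithmetic, and sign-concordance tests.

A *signature* is the list of ASVs passing a p-value rule in one comparison,
each carrying the sign of its log mean fold change.  Concordance across
comparisons asks whether overlapping ASVs shift in the same direction more
(or less) often than chance: under independent fair signs the null concordant
fraction is 50% for two comparisons and 25% for three (all-identical signs).

Two formulations of the test are always co-reported: a literal Fisher's exact
test on the 2x2 of observed vs expected concordant/discordant counts
(expected = the null fraction of n, rounded half-up), and the statistically
cleaner exact binomial test of the concordant count against the null fraction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import log_mean_fold_change, prevalence_filter
from .tables import AsvTable, paired_samples

log = logging.getLogger(__name__)


@dataclass
class SignatureList:
    """ASVs selected from one comparison, with the sign of their LMFC."""

    label: str
    signs: pd.Series            # index asv_id, values +1 / -1
    selection: str = ""

    def __post_init__(self) -> None:
        if (self.signs == 0).any():
            raise ValueError("signature ASVs must carry a nonzero sign")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.signs.index)

    def __len__(self) -> int:
        return len(self.signs)


def select_signature(results: pd.DataFrame, label: str = "",
                     alpha: float | None = 0.05, top_k: int | None = None) -> SignatureList:
    """Select a signature by strict p < alpha, or the top-k smallest p.

    Exactly one of ``alpha`` / ``top_k`` applies; ties at the top-k boundary
    are broken by |lmfc| descending, then ASV id lexicographic.  ASVs with
    zero LMFC carry no direction and are dropped with a warning.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    if (alpha is not None) == (top_k is not None):
        raise ValueError("specify exactly one of alpha or top_k")
    df = results
    zero = df["lmfc"] == 0
    if zero.any():
        log.warning("select_signature: dropping %d ASVs with zero lmfc", int(zero.sum()))
        df = df[~zero]
    if alpha is not None:
        if not (0 < alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        chosen = df[df["p"] < alpha]
        rule = f"p<{alpha}"
    else:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        order = df.assign(_abs=df["lmfc"].abs()).sort_values(
            ["p", "_abs", "asv_id"], ascending=[True, False, True])
        chosen = order.head(top_k)
        rule = f"top_{top_k}"
    signs = pd.Series(np.sign(chosen["lmfc"].to_numpy()).astype(int),
                      index=pd.Index(chosen["asv_id"], name="asv_id"))
    return SignatureList(label=label, signs=signs, selection=rule)


@dataclass
class OverlapStats:
    n_a: int
    n_b: int
    n_overlap: int
    pct_of_union: float


def overlap_stats(list_a: SignatureList, list_b: SignatureList) -> OverlapStats:
    """Overlap of two signatures as a percentage of their union."""
    a = set(list_a.asv_ids)
    b = set(list_b.asv_ids)
    n_overlap = len(a & b)
    union = len(a) + len(b) - n_overlap
    pct = 100.0 * n_overlap / union if union else 0.0
    return OverlapStats(len(a), len(b), n_overlap, pct)


def null_concordant_fraction(n_comparisons: int) -> float:
    """Chance that independent fair signs agree across all comparisons,
    by exhaustive enumeration of the equally likely sign vectors."""
    if n_comparisons < 2:
        raise ValueError("need at least two comparisons")
    vectors = list(itertools.product((-1, 1), repeat=n_comparisons))
    concordant = sum(1 for v in vectors if len(set(v)) == 1)
    return concordant / len(vectors)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ConcordanceResult:
    n: int
    n_concordant: int
    n_discordant: int
    null_fraction: float
    expected_concordant: int
    fisher_p: float
    binom_p: float
    table: list = field(default_factory=list)


def sign_concordance_test(signs, null_fraction: float = 0.5) -> ConcordanceResult:
    """Test whether sign agreement across comparisons deviates from a null
    concordant fraction.

    ``signs`` is a DataFrame (rows = overlapping ASVs, one column per
    comparison, entries +1/-1) or an iterable of sign tuples.  An ASV is
    concordant when all its signs are identical.
    """
    if not (0 < null_fraction < 1):
        raise ValueError("null_fraction must be in (0, 1)")
    if isinstance(signs, pd.DataFrame):
        rows = [tuple(r) for r in signs.to_numpy()]
    else:
        rows = [tuple(r) for r in signs]
    n = len(rows)
    if n == 0:
        raise ValueError("empty overlap: no ASVs to test")
    if any(0 in r for r in rows):
        raise ValueError("signs must be nonzero")
    n_conc = sum(1 for r in rows if len(set(np.sign(r))) == 1)
    n_disc = n - n_conc
    exp_conc = _round_half_up(null_fraction * n)
    exp_disc = n - exp_conc
    contingency = [[n_conc, n_disc], [exp_conc, exp_disc]]
    _, fisher_p = stats.fisher_exact(contingency, alternative="two-sided")
    binom_p = stats.binomtest(n_conc, n, null_fraction, alternative="two-sided").pvalue
    return ConcordanceResult(n, n_conc, n_disc, null_fraction, exp_conc,
                             float(fisher_p), float(binom_p), contingency)


def concordance_tile(table: AsvTable, metadata: pd.DataFrame,
                     signature: SignatureList, min_prevalence: float = 0.20,
                     subgroups=("F", "MSM", "MSW")) -> pd.DataFrame:
    """Per-subgroup LMFC of each global-signature ASV, with a presence mask.

    For every subgroup the case-vs-control LMFC is computed over that
    subgroup's paired samples; entries where within-subgroup prevalence falls
    below ``min_prevalence`` are masked (LMFC set to NaN, present_* False) —
    the "white squares" of the subgroup tile plot.
    """
    out = pd.DataFrame(index=pd.Index(signature.asv_ids, name="asv_id"))
    out["global_sign"] = signature.signs
    for g in subgroups:
        ids = metadata.index[metadata["subgroup"] == g].intersection(table.sample_ids)
        sub = table.select_samples(ids)
        pairs = paired_samples(metadata.loc[ids])
        lmfc = log_mean_fold_change(sub, pairs["case_id"], pairs["control_id"])
        prev = (sub.counts > 0).mean(axis=0)
        present = prev.reindex(signature.asv_ids).fillna(0.0) >= min_prevalence
        vals = lmfc.reindex(signature.asv_ids)
        out[f"lmfc_{g}"] = vals.where(present)
        out[f"present_{g}"] = present
    return out
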