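"""The Dysbiosis Index: log10 ratio of geometric means of case-enriched over
case-depleted taxon counts, per sample.

DI = log10( gm(x_1+1 ... x_n+1) / gm(y_1+1 ... y_m+1) )

where the x are read counts of taxa enriched in cases (paired Wilcoxon
p < 0.05 and LMFC > 0 in the case-vs-control screen) and the y the taxa
depleted in cases (p < 0.05, LMFC < 0), on a table rarefied to a uniform
depth.  The +1 pseudocount is added to every signature-taxon count (the
standard geometric-mean convention, which also removes zeroes); geometric
means are computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AsvTable


@dataclass
class DysbiosisSignature:
    """The enriched-in-case (x) and depleted-in-case (y) ASV id sets."""

    enriched_ids: list
    depleted_ids: list

    def __post_init__(self) -> None:
        self.enriched_ids = list(self.enriched_ids)
        self.depleted_ids = list(self.depleted_ids)
        if not self.enriched_ids or not self.depleted_ids:
            raise ValueError("both enriched and depleted sets must be non-empty")
        if set(self.enriched_ids) & set(self.depleted_ids):
            raise ValueError("enriched and depleted sets must be disjoint")


def signature_from_results(results: pd.DataFrame, alpha: float = 0.05) -> DysbiosisSignature:
    """Build the DI signature from a differential-abundance result table,
    using strict p < alpha and the sign of the LMFC."""
    sig = results[results["p"] < alpha]
    return DysbiosisSignature(
        enriched_ids=sig.loc[sig["lmfc"] > 0, "asv_id"].tolist(),
        depleted_ids=sig.loc[sig["lmfc"] < 0, "asv_id"].tolist(),
    )


def compute_di(table: AsvTable, signature: DysbiosisSignature) -> pd.Series:
    """Per-sample Dysbiosis Index on a (rarefied) count table."""
    missing = (set(signature.enriched_ids) | set(signature.depleted_ids)) - set(table.asv_ids)
    if missing:
        raise ValueError(f"signature ASVs absent from table: {sorted(missing)[:5]}")
    X = table.counts[signature.enriched_ids].to_numpy(dtype=float) + 1.0
    Y = table.counts[signature.depleted_ids].to_numpy(dtype=float) + 1.0
    di = np.log10(X).mean(axis=1) - np.log10(Y).mean(axis=1)
    return pd.Series(di, index=pd.Index(table.sample_ids, name="sample_id"), name="di")
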