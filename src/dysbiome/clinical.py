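"""Associations of microbiome summaries (DI, alpha diversity) with clinical
and inflammatory outcomes.

Models are random-intercept linear mixed models with the sex/sexual-practice
subgroup as the grouping factor, fit by maximum likelihood with Wald
p-values; with two fixed effects both are included jointly so each slope is
adjusted for the other.  A singular fit (between-group variance estimated at
zero) collapses to ordinary regression and is flagged, not an error.
Analyte panels are z-scaled per analyte before testing, and BH q-values are
computed across the full declared panel.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diffabund import bh_fdr

log = logging.getLogger(__name__)


def zscale_analytes(analytes: pd.DataFrame) -> pd.DataFrame:
    """Scale each analyte column to mean 0 / sd 1 (sample sd, ddof=1).

    Zero-variance analytes are flagged with a warning and passed through
    unscaled (centred columns of zeros would destroy their units silently).
    """
    out = analytes.copy()
    for col in out.columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            log.warning("zscale_analytes: analyte %r has zero variance; left unscaled", col)
            continue
        out[col] = (x - x.mean()) / sd
    return out


def lme_association(data: pd.DataFrame, outcome: str, predictors,
                    group: str = "subgroup") -> pd.DataFrame:
    """Random-intercept LME of one outcome on 1-2 fixed-effect predictors.

    Rows with missing values in the outcome, predictors, or grouping factor
    are dropped (logged).  Returns one row per predictor with columns
    outcome, predictor, slope, se, p, n, singular.
    """
    predictors = [predictors] if isinstance(predictors, str) else list(predictors)
    if not 1 <= len(predictors) <= 2:
        raise ValueError("supply one or two fixed-effect predictors")
    cols = [outcome, *predictors, group]
    sub = data[cols].dropna()
    n_dropped = len(data) - len(sub)
    if n_dropped:
        log.info("lme_association(%s): dropped %d rows with missing values", outcome, n_dropped)
    if sub[group].nunique() < 2:
        raise ValueError("grouping factor needs at least two levels")
    exog = sm.add_constant(sub[predictors].astype(float))
    model = sm.MixedLM(sub[outcome].astype(float), exog, groups=sub[group])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    singular = bool(np.all(np.asarray(res.cov_re) < 1e-8))
    if singular:
        log.warning("lme_association(%s): singular fit; random-intercept variance ~0", outcome)
    rows = []
    for pred in predictors:
        rows.append({
            "outcome": outcome,
            "predictor": pred,
            "slope": float(res.fe_params[pred]),
            "se": float(res.bse_fe[pred]),
            "p": float(res.pvalues[pred]),
            "n": len(sub),
            "singular": singular,
        })
    return pd.DataFrame(rows)


def associate_panel(data: pd.DataFrame, outcomes, predictors,
                    group: str = "subgroup") -> pd.DataFrame:
    """Fit the LME for every outcome in a declared panel and BH-adjust the
    per-predictor p-values across the whole panel (never post-hoc subsets)."""
    frames = [lme_association(data, out, predictors, group=group) for out in outcomes]
    res = pd.concat(frames, ignore_index=True)
    res["q"] = np.nan
    for pred, idx in res.groupby("predictor").groups.items():
        res.loc[idx, "q"] = bh_fdr(res.loc[idx, "p"].to_numpy())
    return res
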