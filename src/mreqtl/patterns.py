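"""Factorial summaries of cis/trans patterns across regions and chromosomes.

Two model families:

* a binomial GLM (logit link) of the probability that an eQTL is
  trans-acting (trans = 1, cis = 0) on brain region and feature chromosome,
  optionally with their interaction, reported as fitted percentages with
  delta-method standard errors per cell;
* an ordinary least-squares model of the absolute allele-substitution
  effect |beta| on cis/trans status crossed with region (or chromosome),
  reported as least-squares cell means with standard errors.

Interaction significance is assessed by a Wald test on the interaction
block.  Cells with no trans (or no cis) eQTLs sit on the boundary of the
logistic parameter space: their fitted percentage is reported as the
observed 0 or 100 with an undefined standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class PatternFit:
    """A fitted factorial pattern model."""

    kind: str  # "logistic" or "linear"
    formula: str
    coefficients: pd.DataFrame
    cells: pd.DataFrame
    interaction_statistic: Optional[float]
    interaction_df: Optional[float]
    interaction_pvalue: Optional[float]
    separation_flag: bool = False


def _formula(response: str, factors: Sequence[str], interaction: bool) -> str:
    terms = [f"C({f})" for f in factors]
    rhs = " + ".join(terms)
    if interaction and len(factors) > 1:
        rhs += " + " + ":".join(terms)
    return f"{response} ~ {rhs}"


def _interaction_wald(result, factors: Sequence[str]):
    """Wald test on the joint interaction block, if present."""
    names = [n for n in result.model.exog_names if all(f"C({f})" in n for f in factors) and ":" in n]
    if not names:
        return None, None, None
    constraint = ", ".join(f"{n} = 0" for n in names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        test = result.wald_test(constraint, scalar=True)
    stat = float(np.squeeze(test.statistic))
    pval = float(np.squeeze(test.pvalue))
    dof = float(np.squeeze(getattr(test, "df_denom", len(names)) or len(names)))
    return stat, len(names), pval


def _coef_frame(result) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": result.model.exog_names,
            "estimate": np.asarray(result.params),
            "se": np.asarray(result.bse),
            "pvalue": np.asarray(result.pvalues),
        }
    )


def fit_trans_proportion(
    records: pd.DataFrame,
    factors: Sequence[str] = ("region", "chromosome"),
    include_interaction: bool = False,
) -> PatternFit:
    """Logistic regression of the trans proportion on categorical factors.

    ``records`` needs a ``cis_trans`` column (or precomputed 0/1
    ``is_trans``) plus the factor columns.  Returns the coefficient table
    (treatment coding, alphabetically first level as reference), a per-cell
    table of fitted trans percentages with delta-method SEs, and the Wald
    test of the interaction block (when requested).
    """
    df = records.copy()
    if "is_trans" not in df.columns:
        df["is_trans"] = (df["cis_trans"] == "trans").astype(int)
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 observed levels")
    formula = _formula("is_trans", factors, include_interaction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = smf.glm(formula, data=df, family=sm.families.Binomial()).fit()
    separation = bool(np.any(np.abs(result.params) > 15))

    cells = (
        df.groupby(list(factors))["is_trans"]
        .agg(n="count", n_trans="sum")
        .reset_index()
    )
    pred = result.get_prediction(cells)
    fitted = pred.predicted_mean
    se = pred.se  # delta-method SE on the probability scale
    boundary = (cells["n_trans"] == 0) | (cells["n_trans"] == cells["n"])
    cells["fitted_pct_trans"] = 100.0 * fitted
    cells["se_pct"] = np.where(boundary, np.nan, 100.0 * se)
    cells["observed_pct_trans"] = 100.0 * cells["n_trans"] / cells["n"]

    stat, dof, pval = _interaction_wald(result, factors)
    return PatternFit(
        kind="logistic",
        formula=formula,
        coefficients=_coef_frame(result),
        cells=cells,
        interaction_statistic=stat,
        interaction_df=dof,
        interaction_pvalue=pval,
        separation_flag=separation,
    )


def fit_effect_size_model(
    records: pd.DataFrame,
    factors: Sequence[str] = ("cis_trans", "region"),
    include_interaction: bool = True,
) -> PatternFit:
    """Linear model of |beta| on cis/trans crossed with region/chromosome.

    Returns least-squares cell means with model-based SEs and the Wald/F
    test of the interaction block.  Factor-level combinations with no
    observations are excluded from the cell table with a warning.
    """
    df = records.copy()
    if "abs_beta" not in df.columns:
        df["abs_beta"] = np.abs(df["beta"])
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 observed levels")
    formula = _formula("abs_beta", factors, include_interaction)
    result = smf.ols(formula, data=df).fit()

    observed = df.groupby(list(factors)).size().rename("n").reset_index()
    full_grid = 1
    for f in factors:
        full_grid *= df[f].nunique()
    if len(observed) < full_grid:
        warnings.warn(
            f"{full_grid - len(observed)} empty factor cells excluded from the "
            "cell-mean table",
            stacklevel=2,
        )
    pred = result.get_prediction(observed)
    observed["cell_mean"] = pred.predicted_mean
    observed["se"] = pred.se_mean
    stat, dof, pval = _interaction_wald(result, factors)
    return PatternFit(
        kind="linear",
        formula=formula,
        coefficients=_coef_frame(result),
        cells=observed,
        interaction_statistic=stat,
        interaction_df=dof,
        interaction_pvalue=pval,
    )
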