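"""Fixed-effects linear model of ad-libitum buffet intake.

Ordinary least squares of each kcal outcome on emulsion arm, sex, buffet
time (hours from the 12 pm reference) and the arm-by-sex interaction, with
treatment coding against the (PS-LE1, female) reference cell and t-based
95% confidence intervals.  Plain OLS is used deliberately — no subject
random effect — even though completers contribute up to three rows each;
standard errors therefore ignore the within-subject correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .exceptions import DataError

__all__ = ["fit_intake_model", "fit_intake_table", "OUTCOMES"]

OUTCOMES = ("kcal_total", "kcal_fat", "kcal_carb", "kcal_protein")

_REF_ARM = "PS-LE1"
_REF_SEX = "female"


def _check_cells(records: pd.DataFrame) -> None:
    counts = records.groupby(["arm", "sex"], observed=True).size()
    arms = records["arm"].unique()
    empty = [
        (a, s)
        for a in arms
        for s in ("female", "male")
        if (a, s) not in counts.index
    ]
    if empty:
        raise DataError(
            "empty arm x sex cells prevent estimating the interaction: "
            + ", ".join(f"({a}, {s})" for a, s in empty)
        )


def fit_intake_model(records: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """OLS fit of one intake outcome; coefficient table with 95% CIs.

    Returns a frame with columns ``term, estimate, ci_low, ci_high, se,
    pvalue``, with human-readable term labels (``intercept``,
    ``buffet_time_h``, arm names, ``male``, ``arm x male``).
    """
    required = {"arm", "sex", "buffet_time_h", outcome}
    missing = required - set(records.columns)
    if missing:
        raise DataError(f"intake table lacks columns: {sorted(missing)}")
    _check_cells(records)
    df = records.copy()
    formula = (
        f"Q('{outcome}') ~ C(arm, Treatment('{_REF_ARM}')) "
        f"* C(sex, Treatment('{_REF_SEX}')) + buffet_time_h"
    )
    fit = smf.ols(formula, data=df).fit()
    ci = fit.conf_int(alpha=0.05)
    rows = []
    for name in fit.params.index:
        rows.append(
            {
                "term": _clean_term(name),
                "estimate": float(fit.params[name]),
                "ci_low": float(ci.loc[name, 0]),
                "ci_high": float(ci.loc[name, 1]),
                "se": float(fit.bse[name]),
                "pvalue": float(fit.pvalues[name]),
            }
        )
    return pd.DataFrame(rows)


def _clean_term(name: str) -> str:
    out = name
    out = out.replace(f"C(arm, Treatment('{_REF_ARM}'))[T.", "")
    out = out.replace(f"C(sex, Treatment('{_REF_SEX}'))[T.", "")
    out = out.replace("]", "")
    out = out.replace("Intercept", "intercept")
    out = out.replace(":", " x ")
    return out


def fit_intake_table(records: pd.DataFrame) -> pd.DataFrame:
    """Coefficient table across all four kcal outcomes (Table-2 shape).

    Rows are model terms; columns are outcome x {estimate, ci_low, ci_high}.
    """
    pieces = {}
    for outcome in OUTCOMES:
        tab = fit_intake_model(records, outcome).set_index("term")
        pieces[outcome] = tab[["estimate", "ci_low", "ci_high"]]
    wide = pd.concat(pieces, axis=1)
    wide.columns = [f"{o}_{c}" for o, c in wide.columns]
    return wide.reset_index()
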