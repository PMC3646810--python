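"""Pelagic-dive frequency per seal x sediment x diel cell, and the
fixed-effect linear model for sediment and time-of-day effects.

The default denominator is every classified dive over mapped sediment
(shallow + pelagic + benthic); ``denominator="deep"`` restricts it to
pelagic + benthic dives, the cells for which the generator's pelagic
probabilities are defined. The model is an ordinary least squares fit
of frequency on categorical sediment, diel and individual with
sequential (type-I) ANOVA F tests and no transform of the proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["pelagic_frequency_table", "fit_frequency_model"]

MAPPED_SEDIMENTS = ("fine", "coarse", "rock")


def pelagic_frequency_table(
    dives: pd.DataFrame, denominator: str = "all"
) -> pd.DataFrame:
    """Per (seal, sediment, diel) cell counts and pelagic frequency.

    Dives over unclassified sediment are excluded. Cells with no dives
    are omitted rather than reported as zero-count rows.
    """
    if denominator not in ("all", "deep"):
        raise ValueError("denominator must be 'all' or 'deep'")
    d = dives[dives["dive_type"].notna() & dives["sediment"].isin(MAPPED_SEDIMENTS)]
    if denominator == "deep":
        d = d[d["dive_type"].isin(("pelagic", "benthic"))]
    if len(d) == 0:
        return pd.DataFrame(
            columns=["seal_id", "sediment", "diel", "n_dives", "n_pelagic", "freq"]
        )
    grouped = d.groupby(["seal_id", "sediment", "diel"], sort=True, observed=True)
    table = grouped.agg(
        n_dives=("dive_type", "size"),
        n_pelagic=("dive_type", lambda s: int((s == "pelagic").sum())),
    ).reset_index()
    table["freq"] = table["n_pelagic"] / table["n_dives"]
    return table


def _group_means(cells: pd.DataFrame) -> pd.DataFrame:
    g = cells.groupby(["sediment", "diel"], sort=True)["freq"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out = out.rename(columns={"mean": "mean_freq", "std": "sd_freq", "count": "n_seals"})
    out["se_freq"] = out["sd_freq"] / np.sqrt(out["n_seals"])
    return out


def fit_frequency_model(cells: pd.DataFrame) -> dict:
    """OLS of frequency on sediment + diel + individual (no interaction).

    Returns a JSON-serialisable report with the model R^2, sequential
    ANOVA F statistics and p-values per factor, and the cross-seal
    sediment x diel group means with standard errors. Factors with a
    single observed level are dropped (recorded in the report) rather
    than fitted on a rank-deficient design.
    """
    cells = cells.copy()
    factors = ["sediment", "diel", "seal_id"]
    dropped = [f for f in factors if cells[f].nunique() < 2]
    kept = [f for f in factors if f not in dropped]
    report: dict = {
        "n_cells": int(len(cells)),
        "dropped_factors": dropped,
        "group_means": _group_means(cells).to_dict(orient="records"),
    }

    y = cells["freq"].to_numpy(dtype=float)
    if not kept or np.allclose(y, y[0]):
        # constant response or no usable factors: the null model
        report["r_squared"] = 0.0
        report["anova"] = {
            f: {"F": 0.0, "p_value": 1.0, "df_num": float(cells[f].nunique() - 1),
                "df_den": float(len(cells) - 1)}
            for f in kept
        }
        return report

    formula = "freq ~ " + " + ".join(f"C({f})" for f in kept)
    model = smf.ols(formula, data=cells).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    report["r_squared"] = float(model.rsquared)
    report["anova"] = {}
    df_den = float(anova.loc["Residual", "df"])
    for f in kept:
        row = anova.loc[f"C({f})"]
        report["anova"][f] = {
            "F": float(row["F"]),
            "p_value": float(row["PR(>F)"]),
            "df_num": float(row["df"]),
            "df_den": df_den,
        }
    return report
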