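"""Variable construction and estimation battery for the adoption survey.

Turns the raw survey tables into analysis variables — household-level
adoption flags from plot labels, the misclassification code, reconstructed
consumption expenditure with median-price imputation, poverty and
food-shortage indicators — and runs the welfare regressions: bivariate probit
for the food-shortage outcome, OLS and 2SLS (instrumented by consumption
trait preference and EA-level pest incidence) for log expenditures, 2SLS with
bootstrap standard errors for poverty, each with and without the
misclassification code as a control, at the household or plot level, with
EA-clustered standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimators as est
from .survey_synth import SurveyDataset

__all__ = [
    "MisclassRates",
    "compute_misclass_rates",
    "aggregate_household_adoption",
    "build_expenditure",
    "poverty_flag",
    "food_shortage_indicator",
    "build_analysis_table",
    "run_welfare_battery",
]

ANNUALIZE_FOOD = 365.0 / 7.0  # 7-day recall -> annual
ANNUALIZE_NONFOOD = 12.0  # monthly recall -> annual
POVERTY_LINE = 1.9  # per capita per day, abstract currency units

CONTROL_COLS = [
    "hh_size",
    "education",
    "age",
    "sex_male",
    "tlu",
    "land_ha",
    "log_asset",
    "off_farm",
    "extension",
    "credit",
    "road_quality",
    "dist_village",
    "dist_district",
]
INSTRUMENT_COLS = ["trait_pref", "village_pest"]


@dataclass(frozen=True)
class MisclassRates:
    """Confusion-matrix rates of the self report against the benchmark."""

    fn: float
    fp: float
    self_rate: float
    dna_rate: float
    level: str

    def __post_init__(self) -> None:
        for v in (self.fn, self.fp, self.self_rate, self.dna_rate):
            if not 0.0 <= v <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def compute_misclass_rates(plots: pd.DataFrame, level: str = "household") -> MisclassRates:
    """False-negative/false-positive rates at the plot or household level.

    Household level first aggregates both labels by logical OR over plots.
    """
    if plots.empty:
        raise ValueError("empty plot table")
    if level == "plot":
        dna = plots["dna_improved"].to_numpy()
        self_ = plots["self_improved"].to_numpy()
    elif level == "household":
        agg = aggregate_household_adoption(plots)
        dna = agg["dna_improved"].to_numpy()
        self_ = agg["self_improved"].to_numpy()
    else:
        raise ValueError(f"unknown level {level!r}")
    n1 = (dna == 1).sum()
    n0 = (dna == 0).sum()
    fn = float((self_[dna == 1] == 0).mean()) if n1 else 0.0
    fp = float((self_[dna == 0] == 1).mean()) if n0 else 0.0
    return MisclassRates(
        fn=fn,
        fp=fp,
        self_rate=float((self_ == 1).mean()),
        dna_rate=float((dna == 1).mean()),
        level=level,
    )


def aggregate_household_adoption(
    plots: pd.DataFrame, households: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Household adoption flags: grows at least one improved variety (OR).

    Applied separately to the benchmark and self-reported labels.  When a
    household table is supplied, plots referencing unknown households raise.
    """
    if plots.empty:
        raise ValueError("empty plot table")
    if households is not None:
        orphans = set(plots["hh_id"]) - set(households["hh_id"])
        if orphans:
            raise ValueError(f"orphan plots for unknown households: {sorted(orphans)[:5]}")
    return (
        plots.groupby("hh_id")[["dna_improved", "self_improved"]]
        .max()
        .reset_index()
    )


def build_expenditure(
    food_items: pd.DataFrame,
    nonfood_items: pd.DataFrame,
    households: pd.DataFrame,
) -> pd.DataFrame:
    """Per-capita expenditure from the consumption modules.

    Own-production and gift quantities are valued at the household's own unit
    value for the item when it purchased that item, else at the EA-level
    median unit value, else at the survey-wide median; items with no price
    anywhere are excluded (counted in the ``n_unpriced`` attribute).  Weekly
    food values are annualized by 365/7 and monthly non-food values by 12
    before combining and dividing by household size.
    """
    hh = households[["hh_id", "ea_id", "hh_size"]]
    food = food_items.merge(hh, on="hh_id", how="left")

    purchases = food[food["source"] == "purchase"]
    hh_uv = purchases.groupby(["hh_id", "item_id"])["unit_value"].median()
    ea_uv = purchases.groupby(["ea_id", "item_id"])["unit_value"].median()
    gl_uv = purchases.groupby("item_id")["unit_value"].median()

    imputed = food[food["source"] != "purchase"].copy()
    uv = (
        imputed.set_index(["hh_id", "item_id"]).index.map(hh_uv).to_numpy(dtype=float)
    )
    ea_fill = imputed.set_index(["ea_id", "item_id"]).index.map(ea_uv).to_numpy(dtype=float)
    gl_fill = imputed["item_id"].map(gl_uv).to_numpy(dtype=float)
    uv = np.where(np.isnan(uv), ea_fill, uv)
    uv = np.where(np.isnan(uv), gl_fill, uv)
    n_unpriced = int(np.isnan(uv).sum())
    if n_unpriced:
        warnings.warn(f"{n_unpriced} own/gift rows had no price anywhere; excluded")
    imputed["value"] = imputed["quantity"] * uv

    valued = pd.concat([purchases, imputed.dropna(subset=["value"])], ignore_index=True)
    weekly_food = valued.groupby("hh_id")["value"].sum()

    monthly_nonfood = nonfood_items.groupby("hh_id")["value_month"].sum()

    out = hh.copy()
    out["food_annual"] = out["hh_id"].map(weekly_food).fillna(0.0) * ANNUALIZE_FOOD
    out["nonfood_annual"] = out["hh_id"].map(monthly_nonfood).fillna(0.0) * ANNUALIZE_NONFOOD
    out["total_annual"] = out["food_annual"] + out["nonfood_annual"]
    out["pc_food"] = out["food_annual"] / out["hh_size"]
    out["pc_total"] = out["total_annual"] / out["hh_size"]
    out["pc_total_day"] = out["pc_total"] / 365.0
    with np.errstate(divide="ignore"):
        out["ln_pc_food"] = np.log(out["pc_food"].where(out["pc_food"] > 0))
        out["ln_pc_total"] = np.log(out["pc_total"].where(out["pc_total"] > 0))
    out.attrs["n_unpriced"] = n_unpriced
    return out.drop(columns=["ea_id", "hh_size"])


def poverty_flag(pc_total_day: np.ndarray | pd.Series, line: float = POVERTY_LINE) -> np.ndarray:
    """Poor = 1 iff daily per-capita expenditure is strictly below the line."""
    return (np.asarray(pc_total_day, dtype=float) < line).astype(int)


def food_shortage_indicator(
    months_short: np.ndarray | pd.Series, coding: str = "faced"
) -> np.ndarray:
    """Binary food-shortage flag from months-without-enough-food (0-12).

    ``coding="faced"`` (default) returns 1 when the household experienced a
    shortage in at least one month; ``coding="secure"`` returns the reverse
    (1 = never short), matching the questionnaire's verbal definition.
    """
    m = np.asarray(months_short)
    if ((m < 0) | (m > 12)).any():
        raise ValueError("months_short outside 0-12")
    faced = (m >= 1).astype(int)
    if coding == "faced":
        return faced
    if coding == "secure":
        return 1 - faced
    raise ValueError(f"unknown coding {coding!r}")


def build_analysis_table(
    dataset: SurveyDataset, level: str = "household", shortage_coding: str = "faced"
) -> pd.DataFrame:
    """Merge adoption flags, outcomes and covariates into one analysis table.

    At the plot level, household outcomes and covariates are repeated across
    the household's plots and the treatment is the plot-level label; standard
    errors remain clustered at the EA.
    """
    hh = dataset.households.copy()
    hh["log_asset"] = np.log(hh["asset_value"].clip(lower=1.0))
    agg = aggregate_household_adoption(dataset.plots, dataset.households)
    hh = hh.merge(
        agg.rename(columns={"dna_improved": "t_dna", "self_improved": "t_self"}),
        on="hh_id",
    )
    hh["eta"] = hh["t_self"] - hh["t_dna"]
    exp = build_expenditure(dataset.food_items, dataset.nonfood_items, dataset.households)
    hh = hh.merge(exp, on="hh_id")
    hh["poor"] = poverty_flag(hh["pc_total_day"])
    hh["food_shortage"] = food_shortage_indicator(hh["months_short"], shortage_coding)
    if level == "household":
        return hh
    if level == "plot":
        plots = dataset.plots.rename(
            columns={"dna_improved": "t_dna_plot", "self_improved": "t_self_plot"}
        )
        tab = plots.merge(
            hh.drop(columns=["t_dna", "t_self", "eta"]), on="hh_id", how="left"
        )
        tab["t_dna"] = tab["t_dna_plot"]
        tab["t_self"] = tab["t_self_plot"]
        tab["eta"] = tab["t_self"] - tab["t_dna"]
        return tab
    raise ValueError(f"unknown level {level!r}")


def _make_input(tab: pd.DataFrame, outcome: str, source: str, with_eta: bool):
    return est.RegressionInput.from_dataframe(
        tab,
        outcome=outcome,
        treatment={"self": "t_self", "dna": "t_dna"}[source],
        controls=CONTROL_COLS,
        location="region",
        instruments=INSTRUMENT_COLS,
        eta="eta" if with_eta else None,
        clusters="ea_id",
    )


def run_welfare_battery(
    dataset: SurveyDataset,
    adoption_source: str = "self",
    level: str = "household",
    outcomes: tuple[str, ...] | None = None,
    include_eta: str = "both",
    bootstrap_reps: int = 200,
    rng: np.random.Generator | None = None,
    shortage_coding: str = "faced",
) -> pd.DataFrame:
    """The study's estimation battery on one adoption source.

    Per outcome: food shortage via bivariate-probit treatment effects, log
    expenditures via OLS and 2SLS, poverty via 2SLS with cluster-bootstrap
    standard errors.  ``include_eta`` in {"no", "yes", "both"} controls
    whether the misclassification code enters as a regressor.  Returns a tidy
    table of estimates.
    """
    if adoption_source not in ("self", "dna"):
        raise ValueError("adoption_source must be 'self' or 'dna'")
    if rng is None:
        rng = np.random.default_rng(0)
    tab = build_analysis_table(dataset, level=level, shortage_coding=shortage_coding)
    if outcomes is None:
        outcomes = ("ln_pc_total",) if level == "plot" else (
            "food_shortage",
            "ln_pc_food",
            "ln_pc_total",
            "poor",
        )
    eta_variants = {"no": [False], "yes": [True], "both": [False, True]}[include_eta]

    records = []

    def add(outcome, with_eta, result):
        rec = result.to_record()
        rec.update(outcome=outcome, source=adoption_source, level=level, with_eta=with_eta)
        records.append(rec)

    for outcome in outcomes:
        for with_eta in eta_variants:
            inp = _make_input(tab, outcome, adoption_source, with_eta)
            if outcome == "food_shortage":
                if with_eta:
                    continue  # eta-control variant reported via OLS/IV outcomes
                add(outcome, with_eta, est.biprobit_ate(inp))
                continue
            if outcome == "poor":
                if with_eta:
                    res = est.eta_control_effect(inp)
                else:
                    res = est.iv_effect(inp)
                res.se = est.bootstrap_se(
                    est.eta_control_effect if with_eta else est.iv_effect,
                    inp,
                    B=bootstrap_reps,
                    rng=rng,
                )
                res.diagnostics["se_method"] = "cluster bootstrap"
                add(outcome, with_eta, res)
                continue
            # log expenditures: OLS and 2SLS
            if with_eta:
                no_iv = est.RegressionInput.from_dataframe(
                    tab,
                    outcome=outcome,
                    treatment={"self": "t_self", "dna": "t_dna"}[adoption_source],
                    controls=CONTROL_COLS,
                    location="region",
                    eta="eta",
                    clusters="ea_id",
                )
                add(outcome, with_eta, est.eta_control_effect(no_iv))
                add(outcome, with_eta, est.iv_effect(inp, include_eta=True))
            else:
                add(outcome, with_eta, est.ols_effect(inp))
                add(outcome, with_eta, est.iv_effect(inp))
    return pd.DataFrame.from_records(records)


def coefficient_differences(
    battery_self: pd.DataFrame, battery_dna: pd.DataFrame
) -> pd.DataFrame:
    """Self-minus-benchmark adoption coefficient per (outcome, estimator, eta)."""
    keys = ["outcome", "estimator", "with_eta", "level"]
    merged = battery_self.merge(
        battery_dna, on=keys, suffixes=("_self", "_dna"), how="inner"
    )
    merged["coef_diff"] = merged["coef_adoption_self"] - merged["coef_adoption_dna"]
    return merged[keys + ["coef_adoption_self", "coef_adoption_dna", "coef_diff"]]
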