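"""Synthetic clustered adoption survey with benchmark and self-reported labels.

Emulates a multistage household survey of cassava growers: enumeration areas
(EAs) as primary sampling clusters, five households per EA, one to four
cassava plots per household.  Each plot carries two adoption labels — a
benchmark ("DNA-fingerprinted") improved-variety status and an error-ridden
self report — with configurable false-negative/false-positive rates.  The
generator also produces Table-1-style household covariates, a seven-day food
consumption module with unit values and deliberate missingness (to exercise
median-price imputation), a non-food module, a months-of-food-shortage count,
and ground-truth welfare effects of adoption, all retained in a sidecar so
the analysis pipeline's estimates can be compared against the truth.

Misreporting is endogenous by construction, mimicking the patterns the
validation literature documents:

* household misreporting propensity loads *negatively* on the adoption latent
  index, so marginal adopters (and marginal non-adopters) misreport most —
  this is what attenuates IV estimates based on the self report;
* false negatives load *positively* on the household welfare unobservable and
  false positives negatively, so false negatives are richer than correct
  non-adopters and false positives poorer than correct adopters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr

__all__ = ["SurveyConfig", "SurveyDataset", "generate_survey", "generate_food_items"]

FOOD_SOURCES = ("purchase", "own_production", "gift")


@dataclass(frozen=True)
class SurveyConfig:
    """Study-design and ground-truth parameters of the synthetic survey."""

    n_ea: int = 500
    hh_per_ea: int = 5
    plots_min: int = 1
    plots_max: int = 4
    n_regions: int = 6

    true_adoption_rate: float = 0.66  # household-level benchmark rate
    fn_rate: float = 0.19  # share of benchmark adopters self-reporting non-adoption
    fp_rate: float = 0.15  # share of benchmark non-adopters self-reporting adoption
    improved_plot_share: float = 0.75  # improved plots within adopter households

    # ground-truth effects of adoption
    effect_log_expenditure: float = 0.35  # on log per-capita expenditure
    effect_food_shortage: float = -0.8  # latent probit index shift
    food_shortage_rate: float = 0.63

    # instruments
    trait_pref_rate: float = 0.59  # garri/fufu trait preference prevalence
    village_pest_rate: float = 0.25  # EA-level cassava pest incidence

    # endogeneity and misreporting structure
    endogeneity: float = 0.35  # welfare unobservable loading in adoption index
    misreport_wealth_link: float = 0.7
    misreport_margin_link: float = 3.0

    # consumption module
    n_food_items: int = 20
    n_nonfood_items: int = 10
    missing_unit_value_share: float = 0.10
    food_share_mean: float = 0.68

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "true_adoption_rate",
            "fn_rate",
            "fp_rate",
            "improved_plot_share",
            "trait_pref_rate",
            "village_pest_rate",
            "missing_unit_value_share",
            "food_shortage_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_ea < 2 or self.hh_per_ea < 1:
            raise ValueError("need at least 2 EAs and 1 household per EA")
        if not 1 <= self.plots_min <= self.plots_max:
            raise ValueError("invalid plots_per_hh range")

    @property
    def n_households(self) -> int:
        return self.n_ea * self.hh_per_ea

    @classmethod
    def from_file(cls, path: str | Path) -> "SurveyConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)


@dataclass
class SurveyDataset:
    """Household, plot and consumption tables plus the ground-truth sidecar."""

    households: pd.DataFrame
    plots: pd.DataFrame
    food_items: pd.DataFrame
    nonfood_items: pd.DataFrame
    ground_truth: dict
    config: SurveyConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.households.to_csv(outdir / "households.csv", index=False)
        self.plots.to_csv(outdir / "plots.csv", index=False)
        self.food_items.to_csv(outdir / "food_items.csv", index=False)
        self.nonfood_items.to_csv(outdir / "nonfood_items.csv", index=False)
        sidecar = dict(self.ground_truth)
        sidecar["config"] = dataclasses.asdict(self.config)
        (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "SurveyDataset":
        outdir = Path(outdir)
        sidecar = json.loads((outdir / "ground_truth.json").read_text())
        config = SurveyConfig(**sidecar.pop("config"))
        return cls(
            households=pd.read_csv(outdir / "households.csv"),
            plots=pd.read_csv(outdir / "plots.csv"),
            food_items=pd.read_csv(outdir / "food_items.csv"),
            nonfood_items=pd.read_csv(outdir / "nonfood_items.csv"),
            ground_truth=sidecar,
            config=config,
        )


def _calibrated_intercept(xb: np.ndarray, target: float) -> float:
    """Intercept c with mean(Phi(c + xb)) = target, by root bracketing."""
    f = lambda c: ndtr(c + xb).mean() - target
    return brentq(f, -8.0, 8.0)


def _rank_flip(score: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask flipping the k highest-scoring entries."""
    flip = np.zeros(score.size, dtype=bool)
    if k > 0:
        flip[np.argpartition(-score, k - 1)[:k]] = True
    return flip


def generate_survey(config: SurveyConfig | None = None) -> SurveyDataset:
    """Generate the full synthetic survey. Deterministic given ``config.seed``."""
    cfg = config or SurveyConfig()
    rng = np.random.default_rng(cfg.seed)
    n_hh = cfg.n_households

    # --- enumeration areas -------------------------------------------------
    ea_id = np.arange(cfg.n_ea)
    region = ea_id % cfg.n_regions
    village_pest_ea = (rng.random(cfg.n_ea) < cfg.village_pest_rate).astype(int)
    ea_welfare = rng.normal(0.0, 0.25, cfg.n_ea)
    ea_adopt = rng.normal(0.0, 0.30, cfg.n_ea)

    # --- household covariates ---------------------------------------------
    hh_ea = np.repeat(ea_id, cfg.hh_per_ea)
    hh_id = np.arange(n_hh)
    hh_size = 1 + rng.poisson(3.5, n_hh)
    education = np.clip(rng.normal(8.9, 4.0, n_hh), 0, 18).round(1)
    age = np.clip(rng.normal(51.0, 12.0, n_hh), 18, 95).round(0)
    sex_male = (rng.random(n_hh) < 0.89).astype(int)
    tlu = rng.gamma(0.5, 1.2, n_hh).round(2)
    land_ha = rng.gamma(2.0, 2.7, n_hh).round(2)
    asset_value = np.exp(rng.normal(6.2, 0.9, n_hh)).round(0)
    off_farm = (rng.random(n_hh) < 0.26).astype(int)
    extension = (rng.random(n_hh) < 0.36).astype(int)
    credit = (rng.random(n_hh) < 0.44).astype(int)
    road_quality = rng.choice([1, 2, 3, 4, 5], n_hh, p=[0.06, 0.16, 0.36, 0.26, 0.16])
    dist_village = rng.gamma(2.0, 1.5, n_hh).round(1)
    dist_district = rng.gamma(3.0, 4.2, n_hh).round(1)
    dist_fertilizer = rng.gamma(3.0, 4.0, n_hh).round(1)
    trait_pref = (rng.random(n_hh) < cfg.trait_pref_rate).astype(int)
    village_pest = village_pest_ea[hh_ea]

    u = rng.standard_normal(n_hh)  # household welfare unobservable ("ability")
    educ_z = (education - 9.0) / 4.0

    # --- benchmark (DNA) adoption ------------------------------------------
    xb = (
        0.8 * trait_pref
        + 0.6 * village_pest
        + 0.12 * educ_z
        + cfg.endogeneity * u
        + ea_adopt[hh_ea]
    )
    c_adopt = _calibrated_intercept(xb, cfg.true_adoption_rate)
    omega = rng.standard_normal(n_hh)
    latent_adopt = c_adopt + xb + omega
    dna_hh = (latent_adopt > 0).astype(int)

    # --- household-level misreporting --------------------------------------
    noise_fn = rng.standard_normal(n_hh)
    noise_fp = rng.standard_normal(n_hh)
    adopters = np.flatnonzero(dna_hh == 1)
    non_adopters = np.flatnonzero(dna_hh == 0)
    # Margin component excludes the welfare unobservable: marginal farmers
    # (weak observable/instrument push towards their own status) misidentify
    # varieties most, while the wealth link separately makes false negatives
    # rich and false positives poor.
    margin = latent_adopt - cfg.endogeneity * u
    score_fn = (
        -cfg.misreport_margin_link * margin
        + cfg.misreport_wealth_link * u
        + noise_fn
    )
    score_fp = (
        cfg.misreport_margin_link * margin
        - cfg.misreport_wealth_link * u
        + noise_fp
    )
    fn_flip = np.zeros(n_hh, dtype=bool)
    fp_flip = np.zeros(n_hh, dtype=bool)
    fn_flip[adopters] = _rank_flip(
        score_fn[adopters], int(round(cfg.fn_rate * adopters.size))
    )
    fp_flip[non_adopters] = _rank_flip(
        score_fp[non_adopters], int(round(cfg.fp_rate * non_adopters.size))
    )
    self_hh = np.where(fn_flip, 0, np.where(fp_flip, 1, dna_hh))

    # --- welfare outcomes ---------------------------------------------------
    ln_pc_total_true = (
        5.45
        + cfg.effect_log_expenditure * dna_hh
        + 0.04 * education
        - 0.05 * hh_size
        + 0.12 * np.log(asset_value)
        + 0.30 * u
        + ea_welfare[hh_ea]
        + rng.normal(0.0, 0.40, n_hh)
    )
    food_share = rng.beta(13.0, 13.0 * (1 - cfg.food_share_mean) / cfg.food_share_mean, n_hh)
    ln_pc_food_true = ln_pc_total_true + np.log(food_share)

    fs_xb = (
        cfg.effect_food_shortage * dna_hh
        - 0.25 * u
        - 0.08 * educ_z
        + 0.5 * ea_welfare[hh_ea]
    )
    c_short = _calibrated_intercept(fs_xb, cfg.food_shortage_rate)
    shortage = (c_short + fs_xb + rng.standard_normal(n_hh) > 0).astype(int)
    months_short = np.where(shortage == 1, 1 + rng.binomial(11, 0.2, n_hh), 0)
    shortage_ate = float(
        np.mean(
            ndtr(c_short + fs_xb - cfg.effect_food_shortage * dna_hh + cfg.effect_food_shortage)
            - ndtr(c_short + fs_xb - cfg.effect_food_shortage * dna_hh)
        )
    )

    households = pd.DataFrame(
        {
            "hh_id": hh_id,
            "ea_id": hh_ea,
            "region": region[hh_ea],
            "hh_size": hh_size,
            "education": education,
            "age": age,
            "sex_male": sex_male,
            "tlu": tlu,
            "land_ha": land_ha,
            "asset_value": asset_value,
            "off_farm": off_farm,
            "extension": extension,
            "credit": credit,
            "road_quality": road_quality,
            "dist_village": dist_village,
            "dist_district": dist_district,
            "dist_fertilizer": dist_fertilizer,
            "trait_pref": trait_pref,
            "village_pest": village_pest,
            "months_short": months_short,
        }
    )

    # --- plots ---------------------------------------------------------------
    n_plots = rng.integers(cfg.plots_min, cfg.plots_max + 1, n_hh)
    plot_hh = np.repeat(hh_id, n_plots)
    plot_within = np.concatenate([np.arange(k) for k in n_plots])
    n_plot_rows = plot_hh.size
    udraw = rng.random(n_plot_rows)
    dna_plot = np.zeros(n_plot_rows, dtype=int)
    adopter_plot = dna_hh[plot_hh] == 1
    dna_plot[adopter_plot] = (udraw[adopter_plot] < cfg.improved_plot_share).astype(int)
    # guarantee every adopter household has >= 1 improved plot
    frame = pd.DataFrame({"hh": plot_hh, "dna": dna_plot, "u": udraw})
    has_any = frame.groupby("hh")["dna"].transform("max")
    need_fix = adopter_plot & (has_any.to_numpy() == 0)
    if need_fix.any():
        fix_rows = (
            frame[need_fix].groupby("hh")["u"].idxmax().to_numpy()
        )
        dna_plot[fix_rows] = 1

    # self-reported labels: start from household-level flips
    self_plot = dna_plot.copy()
    self_plot[fn_flip[plot_hh]] = 0
    self_plot[fp_flip[plot_hh]] = 1

    # plot-level top-up flips so plot rates also hit the targets, preserving
    # the household OR-aggregate (flip only in households that keep another
    # self-improved plot, or whose self status is already 1)
    imp = np.flatnonzero(dna_plot == 1)
    target_fn_plots = int(round(cfg.fn_rate * imp.size))
    cur_fn = int(((dna_plot == 1) & (self_plot == 0)).sum())
    deficit = target_fn_plots - cur_fn
    if deficit > 0:
        cand = np.flatnonzero((dna_plot == 1) & (self_plot == 1) & (self_hh[plot_hh] == 1))
        order = cand[np.argsort(-score_fn[plot_hh[cand]], kind="stable")]
        n_self_imp = pd.Series(self_plot).groupby(plot_hh).transform("sum").to_numpy()
        chosen = []
        count_by_hh: dict[int, int] = {}
        for row in order:
            hh = plot_hh[row]
            used = count_by_hh.get(hh, 0)
            if n_self_imp[row] - used >= 2:  # keep at least one self-improved plot
                chosen.append(row)
                count_by_hh[hh] = used + 1
                if len(chosen) == deficit:
                    break
        self_plot[np.asarray(chosen, dtype=int)] = 0

    loc = np.flatnonzero(dna_plot == 0)
    target_fp_plots = int(round(cfg.fp_rate * loc.size))
    cur_fp = int(((dna_plot == 0) & (self_plot == 1)).sum())
    deficit = target_fp_plots - cur_fp
    if deficit > 0:
        cand = np.flatnonzero((dna_plot == 0) & (self_plot == 0) & (self_hh[plot_hh] == 1))
        order = cand[np.argsort(-score_fp[plot_hh[cand]], kind="stable")]
        self_plot[order[:deficit]] = 1

    improved_names = np.array(
        ["TMS-30572", "TMS-0419", "TMS-98505", "TMS-30555", "TMS-9206", "NR-8082", "CR-41-10"],
        dtype=object,
    )
    local_names = np.array(
        [f"Local-{k}" for k in range(1, 10)], dtype=object
    )
    name_draw = rng.integers(0, 1_000_000, n_plot_rows)
    variety_name = np.where(
        dna_plot == 1,
        improved_names[name_draw % len(improved_names)],
        local_names[name_draw % len(local_names)],
    )

    plots = pd.DataFrame(
        {
            "hh_id": plot_hh,
            "plot_id": plot_hh * 10 + plot_within,
            "dna_improved": dna_plot,
            "self_improved": self_plot,
            "variety_name": variety_name,
        }
    )

    # --- consumption modules -------------------------------------------------
    food_items, nonfood_items, prices = _consumption_tables(
        cfg, rng, households, ln_pc_total_true, ln_pc_food_true
    )

    realized_fn_hh = float(1 - self_hh[adopters].mean()) if adopters.size else 0.0
    realized_fp_hh = float(self_hh[non_adopters].mean()) if non_adopters.size else 0.0
    ground_truth = {
        "effect_log_expenditure": cfg.effect_log_expenditure,
        "effect_food_shortage_latent": cfg.effect_food_shortage,
        "effect_food_shortage_ate": shortage_ate,
        "dna_adoption_rate_hh": float(dna_hh.mean()),
        "self_adoption_rate_hh": float(self_hh.mean()),
        "fn_rate_hh": realized_fn_hh,
        "fp_rate_hh": realized_fp_hh,
        "poverty_line_per_day": 1.9,
        "seed": cfg.seed,
    }
    return SurveyDataset(
        households=households,
        plots=plots,
        food_items=food_items,
        nonfood_items=nonfood_items,
        ground_truth=ground_truth,
        config=cfg,
    )


def _consumption_tables(cfg, rng, households, ln_pc_total, ln_pc_food):
    """Vectorized food/non-food item tables for all households at once.

    Weekly household food value is ``exp(ln_pc_food) * hh_size * 7/365``;
    it is split across consumed items (Dirichlet-like shares).  Purchases
    carry observed unit values; own-production and gift rows carry only
    quantities, and for a configurable share of them the household has no
    purchase of the same item, forcing the pipeline onto the EA-median price.
    """
    n_hh = len(households)
    n_items = cfg.n_food_items
    hh_size = households["hh_size"].to_numpy()
    ea = households["ea_id"].to_numpy()

    base_price = np.exp(rng.normal(np.log(3.0), 0.5, n_items))
    ea_price = base_price[None, :] * np.exp(rng.normal(0.0, 0.10, (cfg.n_ea, n_items)))

    weekly_food = np.exp(ln_pc_food) * hh_size * 7.0 / 365.0

    consumed = rng.random((n_hh, n_items)) < 0.6
    raw_share = rng.gamma(1.0, 1.0, (n_hh, n_items)) * consumed
    totals = raw_share.sum(axis=1)
    # a household consuming nothing contributes no rows
    nonzero = totals > 0
    share = np.zeros_like(raw_share)
    share[nonzero] = raw_share[nonzero] / totals[nonzero, None]
    value = share * weekly_food[:, None]

    src_draw = rng.random((n_hh, n_items))
    source = np.where(src_draw < 0.55, 0, np.where(src_draw < 0.85, 1, 2))
    has_purchase_too = rng.random((n_hh, n_items)) > cfg.missing_unit_value_share

    hh_idx, item_idx = np.nonzero(consumed & (value > 0))
    src = source[hh_idx, item_idx]
    val = value[hh_idx, item_idx]
    split = (src > 0) & has_purchase_too[hh_idx, item_idx]

    price_noise = np.exp(rng.normal(0.0, 0.08, hh_idx.size))
    hh_price = ea_price[ea[hh_idx], item_idx] * price_noise
    ea_p = ea_price[ea[hh_idx], item_idx]

    rows = []
    # pure purchase rows
    mask = src == 0
    rows.append(
        pd.DataFrame(
            {
                "hh_id": households["hh_id"].to_numpy()[hh_idx[mask]],
                "item_id": item_idx[mask],
                "source": "purchase",
                "quantity": val[mask] / hh_price[mask],
                "value": val[mask],
                "unit_value": hh_price[mask],
            }
        )
    )
    # own/gift consumption valued at EA price (value unobserved in the survey)
    mask = src > 0
    own_val = np.where(split[mask], 0.6 * val[mask], val[mask])
    rows.append(
        pd.DataFrame(
            {
                "hh_id": households["hh_id"].to_numpy()[hh_idx[mask]],
                "item_id": item_idx[mask],
                "source": np.where(src[mask] == 1, "own_production", "gift"),
                "quantity": own_val / ea_p[mask],
                "value": np.nan,
                "unit_value": np.nan,
            }
        )
    )
    # companion purchase rows that reveal the household's unit value
    mask2 = (src > 0) & split
    rows.append(
        pd.DataFrame(
            {
                "hh_id": households["hh_id"].to_numpy()[hh_idx[mask2]],
                "item_id": item_idx[mask2],
                "source": "purchase",
                "quantity": 0.4 * val[mask2] / hh_price[mask2],
                "value": 0.4 * val[mask2],
                "unit_value": hh_price[mask2],
            }
        )
    )
    food = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["hh_id", "item_id", "source"], kind="stable")
        .reset_index(drop=True)
    )

    # non-food: monthly values summing (annualized) to total minus food
    annual_nonfood = np.clip(
        hh_size * (np.exp(ln_pc_total) - np.exp(ln_pc_food)), 0.0, None
    )
    monthly = annual_nonfood / 12.0
    nf_consumed = rng.random((n_hh, cfg.n_nonfood_items)) < 0.6
    nf_raw = rng.gamma(1.0, 1.0, (n_hh, cfg.n_nonfood_items)) * nf_consumed
    nf_tot = nf_raw.sum(axis=1)
    ok = nf_tot > 0
    nf_share = np.zeros_like(nf_raw)
    nf_share[ok] = nf_raw[ok] / nf_tot[ok, None]
    nf_val = nf_share * monthly[:, None]
    i, j = np.nonzero(nf_val > 0)
    nonfood = pd.DataFrame(
        {
            "hh_id": households["hh_id"].to_numpy()[i],
            "item_id": j,
            "value_month": nf_val[i, j],
        }
    )
    return food, nonfood, ea_price


def generate_food_items(
    hh: pd.Series | dict,
    rng: np.random.Generator,
    config: SurveyConfig | None = None,
    ln_pc_total: float = 6.6,
    ln_pc_food: float | None = None,
) -> pd.DataFrame:
    """Item-level consumption rows for a single household record.

    Thin wrapper over the vectorized module used by :func:`generate_survey`,
    for building small fixtures.  A household with zero food consumption
    (``ln_pc_food = -inf``) yields no rows.
    """
    cfg = config or SurveyConfig()
    hh = pd.Series(hh)
    frame = pd.DataFrame(
        {
            "hh_id": [hh.get("hh_id", 0)],
            "ea_id": [min(int(hh.get("ea_id", 0)), cfg.n_ea - 1)],
            "hh_size": [int(hh.get("hh_size", 1))],
        }
    )
    if ln_pc_food is None:
        ln_pc_food = ln_pc_total + np.log(cfg.food_share_mean)
    food, _, _ = _consumption_tables(
        cfg,
        rng,
        frame,
        np.array([float(ln_pc_total)]),
        np.array([float(ln_pc_food)]),
    )
    return food
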