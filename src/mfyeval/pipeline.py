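"""End-to-end orchestration over tabular cow and diet records.

Reads the two delimited tables (cow-level and diet-level, joined on
``herd_id``), resolves the fat-yield predictors per cow for each
configured DMI source, predicts milk fat yield, and evaluates the
predictions against the observed yields, emitting a two-column
performance table (animal-factors DMI first) plus the per-cow
prediction table.

Three DMI sources are supported:

``observed``
    a ``dmi_obs`` column in the cow table (e.g. research herds);
``animal_factors``
    the parity/energy/BW/BCS/DIM intake model — requires milk protein
    and lactose concentrations to compute milk net-energy output;
``feed_animal_factors``
    the feed-composition intake model, with the milk production target
    set to observed milk yield.

No record is silently dropped: every run logs record counts and raises
structured errors for missing columns or herds without a diet row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from mfyeval.config import RunConfig
from mfyeval.equations import (
    milk_net_energy,
    predict_dmi_animal,
    predict_dmi_feed_animal,
    predict_milk_fat_yield,
)
from mfyeval.errors import (
    MissingColumnError,
    MissingDietError,
    ValidationError,
)
from mfyeval.records import read_cow_table, read_diet_table
from mfyeval.stats import EvaluationReport, evaluate, format_report
from mfyeval.supply import ProteinSupply, resolve_mfy_inputs

logger = logging.getLogger("mfyeval")

__all__ = ["predict_frame", "run_evaluation", "summarize_inputs", "EvaluationRun"]


def _join_diets(cows: pd.DataFrame, diets: pd.DataFrame) -> pd.DataFrame:
    missing = sorted(set(cows["herd_id"]) - set(diets["herd_id"]))
    if missing:
        raise MissingDietError(missing)
    dup = diets["herd_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate diet rows for herd(s): {sorted(diets.loc[dup, 'herd_id'])}"
        )
    return cows.merge(diets, on="herd_id", how="left", validate="many_to_one")


class _DietView:
    """Column view of the joined table exposing diet attribute names."""

    def __init__(self, df: pd.DataFrame):
        self._df = df

    def __getattr__(self, name):
        return self._df[name].to_numpy()


def _resolve_dmi(df: pd.DataFrame, config: RunConfig, dmi_source: str) -> np.ndarray:
    if dmi_source == "observed":
        if "dmi_obs" not in df.columns or df["dmi_obs"].isna().any():
            raise MissingColumnError("cow", ["dmi_obs"])
        return df["dmi_obs"].to_numpy(dtype=float)
    if dmi_source == "animal_factors":
        for col in ("protein_pct", "lactose_pct"):
            if col not in df.columns or df[col].isna().any():
                raise MissingColumnError("cow", [col])
        # Energy target for the desired (observed) milk yield.
        ne = milk_net_energy(
            df["milk_yield"].to_numpy(dtype=float),
            df["fat_pct"].to_numpy(dtype=float),
            df["protein_pct"].to_numpy(dtype=float),
            df["lactose_pct"].to_numpy(dtype=float),
            coefficients=config.milk_ne_coefficients,
        )
        return predict_dmi_animal(
            df["an_parity"].to_numpy(dtype=int),
            ne,
            df["an_bw"].to_numpy(dtype=float),
            df["an_bcs"].to_numpy(dtype=float),
            df["an_daylact"].to_numpy(dtype=float),
        )
    if dmi_source == "feed_animal_factors":
        return predict_dmi_feed_animal(
            _DietView(df), df["milk_yield"].to_numpy(dtype=float)
        )
    raise ValidationError(f"unknown dmi_source '{dmi_source}'")


def predict_frame(
    cows: pd.DataFrame,
    diets: pd.DataFrame,
    config: Optional[RunConfig] = None,
    dmi_source: str = "animal_factors",
) -> pd.DataFrame:
    """Per-cow DMI and milk fat yield predictions for one DMI source.

    Returns one row per cow with columns ``cow_id, herd_id, dmi_source,
    dmi_kg_d, mfy_pred_g_d, mfy_obs_g_d``.  The production target is the
    observed milk yield; metabolizable protein supply comes from the
    ``mp_g`` column when present, else from the configured
    milk-yield-scaled fallback.
    """
    config = config or RunConfig()
    df = _join_diets(cows, diets)
    dmi = _resolve_dmi(df, config, dmi_source)
    if "mp_g" in df.columns and df["mp_g"].notna().all():
        mp = df["mp_g"].to_numpy(dtype=float)
    else:
        mp = config.mp_intercept_g + config.mp_slope_g_per_kg_milk * df[
            "milk_yield"
        ].to_numpy(dtype=float)
    inputs = resolve_mfy_inputs(
        dim=df["an_daylact"].to_numpy(dtype=float),
        dmi=dmi,
        diet=_DietView(df),
        supply=ProteinSupply(mp_g=mp),
    )
    mfy = predict_milk_fat_yield(inputs)
    out = pd.DataFrame(
        {
            "cow_id": df["cow_id"],
            "herd_id": df["herd_id"],
            "dmi_source": dmi_source,
            "dmi_kg_d": dmi,
            "mfy_pred_g_d": mfy,
            "mfy_obs_g_d": df["observed_mfy_g"].to_numpy(dtype=float),
        }
    )
    assert len(out) == len(cows), "record-count conservation violated"
    return out


@dataclass
class EvaluationRun:
    """Results of one full evaluation: reports per DMI source plus the
    stacked per-cow prediction table."""

    reports: list[EvaluationReport]
    predictions: pd.DataFrame
    config_digest: str = ""

    def report_text(self) -> str:
        return format_report(self.reports)


def run_evaluation(
    cows: pd.DataFrame | str,
    diets: pd.DataFrame | str,
    config: Optional[RunConfig] = None,
) -> EvaluationRun:
    """Predict and evaluate milk fat yield for every configured DMI source.

    ``cows``/``diets`` may be DataFrames or paths to delimited files.
    Logs record counts, negative-prediction warnings and skipped herd
    fits; never drops records silently.
    """
    config = config or RunConfig()
    if not isinstance(cows, pd.DataFrame):
        cows = read_cow_table(cows)
    if not isinstance(diets, pd.DataFrame):
        diets = read_diet_table(diets)
    logger.info(
        "evaluating %d cows in %d herds (config %s)",
        len(cows), cows["herd_id"].nunique(), config.digest(),
    )
    reports = []
    frames = []
    for source in config.dmi_sources:
        pred = predict_frame(cows, diets, config, source)
        frames.append(pred)
        rep = evaluate(
            pred["mfy_obs_g_d"],
            pred["mfy_pred_g_d"],
            pred["herd_id"],
            pred["dmi_kg_d"],
            dmi_source=source,
            convention=config.moment_convention,
        )
        n_neg = int((pred["mfy_pred_g_d"] < 0).sum())
        if n_neg:
            logger.warning("%s: %d negative predicted MFY value(s)", source, n_neg)
        for fit in rep.per_herd_fits:
            if fit.flagged:
                logger.warning(
                    "%s: herd %s regression skipped (%s)", source, fit.herd_id, fit.reason
                )
        logger.info("%s: n=%d, CCC=%.3f, RMSE=%.1f g/d", source, rep.n, rep.ccc, rep.rmse)
        reports.append(rep)
    predictions = pd.concat(frames, ignore_index=True)
    assert len(predictions) == len(cows) * len(config.dmi_sources)
    return EvaluationRun(reports, predictions, config.digest())


_COW_SUMMARY_VARS = [
    ("parity_raw", "Parity"),
    ("an_bw", "BW, kg"),
    ("an_daylact", "DIM, d"),
    ("milk_yield", "Milk yield, kg/d"),
    ("fat_pct", "Milk fat concentration, %"),
    ("observed_mfy_g", "Milk fat yield, g/d"),
]

_DIET_SUMMARY_VARS = [
    ("dt_adf", "ADF, % of DM"),
    ("dt_ndf", "NDF, % of DM"),
    ("fa_pct_dm", "Crude fat, % of DM"),
    ("dig_c160_pct_dm", "Digestible 16:0, % of DM"),
    ("dig_c183_pct_dm", "Digestible 18:3, % of DM"),
    ("ile_pct_mp", "Ile, % of MP"),
    ("met_pct_mp", "Met, % of MP"),
    ("forndf48_ndf", "NDF digestibility, % of NDF"),
]


def _describe(df: pd.DataFrame, variables, block: str) -> pd.DataFrame:
    rows = []
    for col, label in variables:
        if col not in df.columns:
            continue
        s = df[col].astype(float)
        rows.append(
            {
                "block": block,
                "variable": label,
                "mean": s.mean(),
                "sd": s.std(ddof=1) if len(s) > 1 else 0.0,
                "min": s.min(),
                "max": s.max(),
                "n": int(s.notna().sum()),
            }
        )
    return pd.DataFrame(rows)


def summarize_inputs(
    cows: pd.DataFrame | str, diets: pd.DataFrame | str
) -> pd.DataFrame:
    """Descriptive statistics (mean, SD, min, max, n) for the input tables.

    Three blocks: diet composition (per herd), cow-level variables, and
    herd averages (per-herd means of the cow variables plus herd size).
    """
    if not isinstance(cows, pd.DataFrame):
        cows = read_cow_table(cows)
    if not isinstance(diets, pd.DataFrame):
        diets = read_diet_table(diets)
    herd_means = cows.groupby("herd_id").agg(
        {c: "mean" for c, _ in _COW_SUMMARY_VARS if c in cows.columns}
    )
    herd_means["herd_n"] = cows.groupby("herd_id").size()
    herd_vars = [("herd_n", "Lactating cows, n")] + _COW_SUMMARY_VARS
    return pd.concat(
        [
            _describe(diets, _DIET_SUMMARY_VARS, "diet"),
            _describe(cows, _COW_SUMMARY_VARS, "cow"),
            _describe(herd_means.reset_index(), herd_vars, "herd_average"),
        ],
        ignore_index=True,
    )
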