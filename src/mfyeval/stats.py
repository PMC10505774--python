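"""Agreement statistics for observed versus predicted yields.

Implements the external-validation toolkit of the animal-modelling
literature:

* **Lin's concordance correlation coefficient (CCC)** split into
  precision (Pearson r) and accuracy (bias correction factor Cb),
  with ``ccc = r * cb`` holding exactly by construction;
* **RMSE with the three-way MSE partition** into central tendency bias
  (mean shift), regression bias (slope deviation) and disturbance bias
  (random scatter), which sum to the MSE identically under population
  (1/n) moments;
* **per-group OLS regressions** of observed on predicted (one per herd
  plus overall), the numeric content of an observed-vs-predicted
  scatter with per-farm regression lines.

The population (1/n) moment convention is the default because it makes
the partition an exact algebraic identity; the sample (n-1) convention
is available for cross-checking against software that uses it.  At herd
sizes in the hundreds the two differ far below reporting precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from mfyeval.errors import DegenerateInputError

__all__ = [
    "concordance",
    "rmse_partition",
    "grouped_regression",
    "evaluate",
    "EvaluationReport",
    "HerdFit",
]


def _moments(x: np.ndarray, y: np.ndarray, ddof: int):
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=ddof)
    vy = y.var(ddof=ddof)
    cov = ((x - mx) * (y - my)).sum() / (x.size - ddof)
    return mx, my, vx, vy, cov


def _check_pair(observed, predicted, min_n: int = 3):
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("observed and predicted must be 1-D of equal length")
    if x.size < min_n:
        raise DegenerateInputError(f"need at least {min_n} records, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DegenerateInputError("observed and predicted must be finite")
    return x, y


def concordance(observed, predicted, convention: str = "population"):
    """Lin's CCC and its precision/accuracy split.

    Returns ``(ccc, r, cb)`` where

        ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)
        r   = s_xy / (s_x * s_y)        (precision)
        cb  = ccc / r                   (accuracy; 1 = no location/scale shift)

    ``convention`` selects population (1/n, default) or sample (n-1)
    moments; the CCC is invariant to the choice only in the limit, but
    the difference is O(1/n).  Raises
    :class:`~mfyeval.errors.DegenerateInputError` when either vector has
    zero variance (r undefined) or fewer than three records.
    """
    x, y = _check_pair(observed, predicted)
    ddof = 0 if convention == "population" else 1
    mx, my, vx, vy, cov = _moments(x, y, ddof)
    if vx == 0 or vy == 0:
        raise DegenerateInputError("zero variance: Pearson r (and CCC) undefined")
    ccc = 2.0 * cov / (vx + vy + (mx - my) ** 2)
    r = cov / np.sqrt(vx * vy)
    cb = ccc / r
    return float(ccc), float(r), float(cb)


def rmse_partition(observed, predicted, convention: str = "population"):
    """RMSE and the three-way MSE bias partition.

    Returns ``(rmse, rmse_pct_mean, ect_pct, er_pct, ed_pct)``:

        MSE = mean((pred - obs)^2)
        ECT = (mean_pred - mean_obs)^2        central tendency bias
        ER  = (s_pred - r*s_obs)^2            regression (slope) bias
        ED  = (1 - r^2) * s_obs^2             disturbance bias

    With population (1/n) standard deviations ``ECT + ER + ED = MSE``
    is an exact identity; percentages are each component over MSE x 100,
    and ``rmse_pct_mean`` scales RMSE by the observed mean.  When
    MSE = 0 (perfect predictions) rmse is 0 and the partition
    percentages are returned as NaN.
    """
    x, y = _check_pair(observed, predicted)  # x = observed, y = predicted
    ddof = 0 if convention == "population" else 1
    mse = float(np.mean((y - x) ** 2))
    rmse = float(np.sqrt(mse))
    mean_obs = float(x.mean())
    rmse_pct_mean = rmse / mean_obs * 100.0 if mean_obs != 0 else float("nan")
    if mse == 0.0:
        return rmse, rmse_pct_mean, float("nan"), float("nan"), float("nan")
    mx, my, vx, vy, cov = _moments(x, y, ddof)
    sx, sy = np.sqrt(vx), np.sqrt(vy)
    if vx == 0 or vy == 0:
        raise DegenerateInputError("zero variance: bias partition undefined")
    r = cov / (sx * sy)
    ect = (my - mx) ** 2
    er = (sy - r * sx) ** 2
    ed = (1.0 - r**2) * vx
    denom = mse if ddof == 0 else ect + er + ed  # exact identity only at 1/n
    return (
        rmse,
        rmse_pct_mean,
        float(ect / denom * 100.0),
        float(er / denom * 100.0),
        float(ed / denom * 100.0),
    )


@dataclass
class HerdFit:
    """OLS fit of observed on predicted within one herd."""

    herd_id: str
    n: int
    slope: Optional[float]
    intercept: Optional[float]
    flagged: bool = False
    reason: str = ""


def _ols(observed: np.ndarray, predicted: np.ndarray):
    fit = sps.linregress(predicted, observed)
    return float(fit.slope), float(fit.intercept)


def grouped_regression(observed, predicted, herd_ids, min_herd_n: int = 3):
    """Overall and per-herd OLS regressions of observed on predicted.

    Herds with fewer than ``min_herd_n`` cows, or with no variance in
    their predicted values, are flagged and carry ``None`` coefficients
    rather than aborting the run.  Returns
    ``((overall_slope, overall_intercept), [HerdFit, ...])`` with herd
    fits ordered by herd id.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    herd_ids = np.asarray(herd_ids)
    if np.unique(y).size < 2:
        raise DegenerateInputError("need at least 2 distinct predicted values overall")
    overall = _ols(x, y)
    fits: list[HerdFit] = []
    for herd in sorted(pd.unique(herd_ids), key=str):
        mask = herd_ids == herd
        n = int(mask.sum())
        if n < min_herd_n:
            fits.append(HerdFit(str(herd), n, None, None, True, f"n < {min_herd_n}"))
            continue
        if np.unique(y[mask]).size < 2:
            fits.append(HerdFit(str(herd), n, None, None, True, "constant predictions"))
            continue
        slope, intercept = _ols(x[mask], y[mask])
        fits.append(HerdFit(str(herd), n, slope, intercept))
    return overall, fits


@dataclass
class EvaluationReport:
    """Agreement summary for one DMI source — the machine form of a
    model-performance table column."""

    dmi_source: str
    n: int
    mean_dmi: float
    sd_dmi: float
    mean_obs: float
    mean_pred: float
    ccc: float
    r: float
    cb: float
    rmse: float
    rmse_pct_mean: float
    ect_pct: float
    er_pct: float
    ed_pct: float
    overall_slope: float
    overall_intercept: float
    per_herd_fits: list[HerdFit] = field(default_factory=list)

    ROW_LABELS = {
        "mean_dmi": "DMI, kg/d",
        "mean_obs": "Observed mean MFY, g/d",
        "mean_pred": "Predicted mean MFY, g/d",
        "ccc": "Concordance correlation coefficient",
        "r": "r",
        "cb": "Bias correction factor",
        "rmse": "Root mean square error, g/d",
        "rmse_pct_mean": "RMSE, % of observed mean",
        "ect_pct": "Central tendency bias, % of MSE",
        "er_pct": "Regression bias, % of MSE",
        "ed_pct": "Disturbance bias, % of MSE",
    }

    def display_rows(self) -> dict[str, str]:
        """Rounded report rows: 2 dp for CCC/r/Cb, 1 dp elsewhere."""
        out = {}
        for attr, label in self.ROW_LABELS.items():
            v = getattr(self, attr)
            if attr == "mean_dmi":
                out[label] = f"{v:.1f} (SD = {self.sd_dmi:.1f})"
            elif attr in ("ccc", "r", "cb"):
                out[label] = f"{v:.2f}"
            else:
                out[label] = f"{v:,.1f}"
        return out


def evaluate(
    observed,
    predicted,
    herd_ids,
    dmi,
    dmi_source: str = "",
    convention: str = "population",
) -> EvaluationReport:
    """Full agreement evaluation of one prediction stream.

    Combines :func:`concordance`, :func:`rmse_partition` and
    :func:`grouped_regression` into an :class:`EvaluationReport`.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    dmi_arr = np.asarray(dmi, dtype=float)
    ccc, r, cb = concordance(x, y, convention)
    rmse, rmse_pct, ect, er, ed = rmse_partition(x, y, convention)
    (slope, intercept), herd_fits = grouped_regression(x, y, herd_ids)
    ddof = 0 if convention == "population" else 1
    return EvaluationReport(
        dmi_source=dmi_source,
        n=int(x.size),
        mean_dmi=float(dmi_arr.mean()),
        sd_dmi=float(dmi_arr.std(ddof=ddof)),
        mean_obs=float(x.mean()),
        mean_pred=float(y.mean()),
        ccc=ccc,
        r=r,
        cb=cb,
        rmse=rmse,
        rmse_pct_mean=rmse_pct,
        ect_pct=ect,
        er_pct=er,
        ed_pct=ed,
        overall_slope=slope,
        overall_intercept=intercept,
        per_herd_fits=herd_fits,
    )


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Side-by-side report table, one column per DMI source."""
    cols = {}
    for rep in reports:
        cols[rep.dmi_source] = rep.display_rows()
    return pd.DataFrame(cols)


def format_report(reports: list[EvaluationReport]) -> str:
    """Human-readable performance table (animal-factors column first)."""
    df = reports_to_frame(reports)
    return df.to_string()
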