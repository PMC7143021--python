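"""Study orchestration: univariate screen, PLSR and the three reduced models.

For each adulterant series (HFCS F55, HFCS F90, rape honey mixed into
acacia honey) the pipeline simulates the calibration and prediction
campaigns, extracts the 43-variable peak table, screens every line with a
univariate fit, fits the all-variable PLSR, and refits after GA, VIP and
SR variable selection — twelve evaluation reports in total, each carrying
calibration, cross-validation and external-prediction r/RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import (
    autoscale_apply,
    kfold_cv,
    ols_univariate,
    pearson_r,
    pls_predict,
    rmse,
    simpls_fit,
)
from .config import StudyConfig
from .lines import make_line_library
from .peaks import build_peak_table
from .selection import SelectionResult, ga_select, sr_select, vip_select
from .spectra_io import PeakTable
from .synthetic import child_seed, generate_dataset

__all__ = [
    "EvaluationReport",
    "StudyResult",
    "run_univariate_screen",
    "evaluate_pls",
    "refit_selected",
    "run_study",
]

logger = logging.getLogger(__name__)

METHODS = ("PLSR", "GA-PLSR", "VIP-PLSR", "SR-PLSR")


@dataclass
class EvaluationReport:
    """One Table-2-style row: a method's performance on one adulterant."""

    adulterant: str
    method: str
    n_lv: int
    n_vars: int
    r_cal: float
    rmse_cal: float
    r_cv: float
    rmse_cv: float
    r_pred: float
    rmse_pred: float
    predictions: dict = field(default_factory=dict)  # set -> {"actual": [...], "predicted": [...]}


def run_univariate_screen(peaks: PeakTable) -> pd.DataFrame:
    """One least-squares fit of fraction on intensity per emission line.

    Returns rows ordered by wavelength with unsigned r and RMSE in
    fraction units plus a ``rmse_pct`` rendering. A constant intensity
    column is flagged rather than fatal.
    """
    rows = []
    for j, line in enumerate(peaks.lines):
        x = peaks.intensities[:, j]
        try:
            res = ols_univariate(x, peaks.fractions)
            rows.append(
                {
                    "wavelength_nm": line.wavelength_nm,
                    "species": line.species,
                    "r": abs(res.r),
                    "rmse": res.rmse,
                    "rmse_pct": 100.0 * res.rmse,
                    "flag": "",
                }
            )
        except ValueError:
            rows.append(
                {
                    "wavelength_nm": line.wavelength_nm,
                    "species": line.species,
                    "r": np.nan,
                    "rmse": np.nan,
                    "rmse_pct": np.nan,
                    "flag": "constant",
                }
            )
    return pd.DataFrame(rows).sort_values("wavelength_nm", ignore_index=True)


def evaluate_pls(
    peaks_cal: PeakTable,
    peaks_pred: PeakTable,
    adulterant: str = "",
    method: str = "PLSR",
    cv_seed: int = 0,
    cv_folds: int = 10,
    max_lv: int = 10,
) -> EvaluationReport:
    """Autoscaled SIMPLS PLSR with CV-chosen LV count, evaluated on all sets."""
    X_cal, y_cal = peaks_cal.intensities, peaks_cal.fractions
    X_pred, y_pred_true = peaks_pred.intensities, peaks_pred.fractions
    cv = kfold_cv(X_cal, y_cal, A_max=max_lv, k=cv_folds, seed=cv_seed)
    model = simpls_fit(X_cal, y_cal, cv.chosen_A)
    yhat_cal = model.fitted
    yhat_cv = cv.cv_predictions[:, cv.chosen_A - 1]
    yhat_pred = pls_predict(model, X_pred)
    return EvaluationReport(
        adulterant=adulterant,
        method=method,
        n_lv=cv.chosen_A,
        n_vars=X_cal.shape[1],
        r_cal=pearson_r(yhat_cal, y_cal),
        rmse_cal=rmse(yhat_cal, y_cal),
        r_cv=pearson_r(yhat_cv, y_cal),
        rmse_cv=float(cv.rmsecv_by_A[cv.chosen_A - 1]),
        r_pred=pearson_r(yhat_pred, y_pred_true),
        rmse_pred=rmse(yhat_pred, y_pred_true),
        predictions={
            "calibration": {"actual": y_cal.tolist(), "predicted": yhat_cal.tolist()},
            "prediction": {"actual": y_pred_true.tolist(), "predicted": yhat_pred.tolist()},
        },
    )


def refit_selected(
    peaks_cal: PeakTable,
    peaks_pred: PeakTable,
    selection: SelectionResult,
    cv_seed: int = 0,
    adulterant: str = "",
    cv_folds: int = 10,
    max_lv: int = 10,
) -> EvaluationReport:
    """Refit PLSR on the selected variable subset (LV count re-chosen by CV)."""
    if selection.n_selected < 1:
        raise ValueError("selection mask is empty; cannot refit")
    report = evaluate_pls(
        peaks_cal.subset(selection.mask),
        peaks_pred.subset(selection.mask),
        adulterant=adulterant,
        method=f"{selection.method}-PLSR",
        cv_seed=cv_seed,
        cv_folds=cv_folds,
        max_lv=max_lv,
    )
    return report


@dataclass
class StudyResult:
    """All artifacts of one full study run."""

    reports: list
    univariate: dict  # adulterant -> DataFrame
    selections: dict  # (adulterant, method) -> SelectionResult
    peak_tables: dict  # (adulterant, set_name) -> PeakTable


def run_study(config: StudyConfig | None = None, seed: int = 0) -> StudyResult:
    """Run the complete simulated study under a single master seed.

    Child seeds fan out by fixed counter tags per adulterant and stage, so
    each branch's randomness is independent of the others. A failure in one
    adulterant branch is logged and the remaining branches still run.
    """
    config = config or StudyConfig()
    lines = tuple(make_line_library())
    reports: list[EvaluationReport] = []
    univariate: dict[str, pd.DataFrame] = {}
    selections: dict[tuple[str, str], SelectionResult] = {}
    peak_tables: dict[tuple[str, str], PeakTable] = {}

    from dataclasses import replace

    for ai, adulterant in enumerate(config.adulterant_kinds):
        try:
            data = generate_dataset(
                config.pure_kind,
                adulterant,
                design=config.design,
                noise=config.noise,
                seed=child_seed(seed, 1, ai),
                amplitude_config=config.amplitudes,
                grid_step_nm=config.grid_step_nm,
                peak_fwhm_nm=config.peak_fwhm_nm,
            )
            cal = build_peak_table(data.calibration, lines, config.half_window_nm)
            pred = build_peak_table(data.prediction, lines, config.half_window_nm)
            peak_tables[(adulterant, "calibration")] = cal
            peak_tables[(adulterant, "prediction")] = pred
            univariate[adulterant] = run_univariate_screen(cal)

            full = evaluate_pls(
                cal, pred, adulterant, "PLSR",
                cv_seed=child_seed(seed, 2, ai, 0),
                cv_folds=config.cv_folds, max_lv=config.max_lv,
            )
            reports.append(full)

            # VIP/SR scores come from the full-variable model at its
            # CV-chosen LV count
            model = simpls_fit(cal.intensities, cal.fractions, full.n_lv)
            Xs = autoscale_apply(model.scaler_X, cal.intensities)
            yc = cal.fractions - model.y_center

            sel_ga = ga_select(
                cal.intensities, cal.fractions,
                replace(config.ga, seed=child_seed(seed, 3, ai)),
            )
            sel_vip = vip_select(model, Xs, yc)
            sel_sr = sr_select(model, Xs, yc)

            for mi, sel in enumerate((sel_ga, sel_vip, sel_sr), start=1):
                selections[(adulterant, sel.method)] = sel
                reports.append(
                    refit_selected(
                        cal, pred, sel,
                        cv_seed=child_seed(seed, 2, ai, mi),
                        adulterant=adulterant,
                        cv_folds=config.cv_folds, max_lv=config.max_lv,
                    )
                )
        except Exception:
            logger.exception("adulterant branch %r failed; continuing", adulterant)
    return StudyResult(
        reports=reports, univariate=univariate, selections=selections, peak_tables=peak_tables
    )
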