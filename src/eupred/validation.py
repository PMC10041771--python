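"""Discrimination, calibration and bootstrap validation of EU model fits.

Discrimination is Harrell's concordance (c-statistic): the fraction of
pregnant / not-pregnant cycle pairs in which the pregnant cycle received
the higher predicted probability, ties counted one half.  Calibration is
summarized by the slope and intercept of a logistic regression of the
observed outcome on the logit of the predicted probability (slope 1,
intercept 0 under perfect calibration; slope < 1 indicates overfitting).

Internal validation follows Harrell's optimism bootstrap: the model is
rebuilt on each bootstrap resample of cycles, its performance measured
both on the resample (apparent) and on the original data (test); the
averaged apparent-minus-test difference — the optimism — is subtracted
from the original apparent metrics.  Evaluation is restricted to SET
cycles with the binary outcome pregnant (>= 1 gestational sac).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import rankdata

from .cohort import Cohort
from .model import (
    EUModelFit,
    EUModelSpec,
    FitOptions,
    fit_eu_model,
    predict_cycle,
)

__all__ = [
    "ValidationReport",
    "ExternalValidationResult",
    "concordance_auc",
    "calibration_slope",
    "internal_validate",
    "external_validate",
    "observed_vs_fitted_table",
    "calibration_curve",
]


def concordance_auc(predictions, outcomes) -> float:
    """Concordance (c-statistic) with ties counted 0.5.

    Rank-based Mann-Whitney form of the all-pairs count: with midranks r_i
    of the predictions, AUC = (sum of positive ranks - n1(n1+1)/2)/(n1 n0).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predictions and outcomes must be equal-length vectors")
    y = y.astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one positive and one negative outcome")
    ranks = rankdata(p)  # midranks: ties share the average rank
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def calibration_slope(predictions, outcomes) -> tuple[float, float]:
    """(slope, intercept) of outcome ~ logit(prediction), by IRLS logistic fit."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("predictions must lie strictly inside (0, 1)")
    if len(np.unique(y)) < 2:
        raise ValueError("need both outcome classes")
    lp = logit(p)
    if np.ptp(lp) < 1e-12:
        raise ValueError("constant predictor: calibration slope undefined")
    X = sm.add_constant(lp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    if not np.all(np.isfinite(res.params)) or np.abs(res.params[1]) > 1e3:
        raise ValueError("calibration fit did not converge (separation?)")
    return float(res.params[1]), float(res.params[0])


def calibration_intercept_at_slope_one(predictions, outcomes) -> float:
    """Calibration-in-the-large: intercept with the slope fixed at 1."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    lp = logit(p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, np.ones((len(y), 1)), offset=lp, family=sm.families.Binomial()).fit()
    return float(res.params[0])


def calibration_curve(predictions, outcomes, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count binned observed event rates against mean predictions."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for b in bins:
        if b.size == 0:
            continue
        rows.append(
            {
                "mean_predicted": float(p[b].mean()),
                "observed_rate": float(y[b].mean()),
                "n": int(b.size),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Internal (optimism bootstrap) validation


@dataclass
class ValidationReport:
    """Apparent and optimism-corrected discrimination and calibration."""

    apparent_auc: float
    apparent_slope: float
    auc_optimisms: np.ndarray
    slope_optimisms: np.ndarray
    n_bootstrap: int
    n_failed: int
    seed: int

    @property
    def corrected_auc(self) -> float:
        return float(self.apparent_auc - np.mean(self.auc_optimisms))

    @property
    def corrected_slope(self) -> float:
        return float(self.apparent_slope - np.mean(self.slope_optimisms))

    def to_dict(self) -> dict:
        return {
            "apparent_auc": self.apparent_auc,
            "corrected_auc": self.corrected_auc,
            "apparent_slope": self.apparent_slope,
            "corrected_slope": self.corrected_slope,
            "n_bootstrap": self.n_bootstrap,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "auc_optimisms": self.auc_optimisms.tolist(),
            "slope_optimisms": self.slope_optimisms.tolist(),
        }


def _set_predictions(
    fit: EUModelFit, design: "DesignData"
) -> tuple[np.ndarray, np.ndarray]:
    """P(pregnant) and observed pregnancy for the SET cycles of a design."""
    theta = np.concatenate([fit.beta_e, fit.beta_u])
    from .model import _cycle_probs

    _, u, e = _cycle_probs(theta, design)
    p = u[design.set_cycles] * e[design.set_rows]
    y = (design.y[design.set_cycles] >= 1).astype(int)
    # guard against probabilities saturating to exactly 0/1 in floating
    # point under extreme linear predictors (overfitted replicates)
    return np.clip(p, 1e-12, 1 - 1e-12), y


def _resample_design(d, idx: np.ndarray):
    """DesignData for a bootstrap resample of cycles (by original index)."""
    from dataclasses import replace as _dc_replace

    row1 = np.full(d.n_cycles, -1)
    row2 = np.full(d.n_cycles, -1)
    row1[d.set_cycles] = d.set_rows
    row1[d.det_cycles] = d.det_rows1
    row2[d.det_cycles] = d.det_rows2
    sel_r1, sel_r2 = row1[idx], row2[idx]
    is_det = sel_r2 >= 0
    m = is_det.astype(int) + 1
    starts = np.concatenate([[0], np.cumsum(m)])[:-1]
    rows = np.empty(int(m.sum()), dtype=int)
    rows[starts] = sel_r1
    rows[starts[is_det] + 1] = sel_r2[is_det]
    return _dc_replace(
        d,
        Xe=d.Xe[rows],
        Xu=d.Xu[idx] if d.Xu.shape[1] else np.zeros((idx.size, 0)),
        y=d.y[idx],
        set_cycles=np.flatnonzero(~is_det),
        set_rows=starts[~is_det],
        det_cycles=np.flatnonzero(is_det),
        det_rows1=starts[is_det],
        det_rows2=starts[is_det] + 1,
        cycle_ids=[f"b{k:05d}" for k in range(idx.size)],
    )


def _resample(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    idx = rng.integers(0, len(cohort), size=len(cohort))
    cycles = []
    for k, i in enumerate(idx):
        c = cohort[int(i)]
        # re-key so cycle_id stays unique within the resample
        cycles.append(
            type(c)(
                cycle_id=f"b{k:05d}:{c.cycle_id}",
                clinic=c.clinic,
                couple_id=c.couple_id,
                female_age=c.female_age,
                cycle_number=c.cycle_number,
                fertilization_method=c.fertilization_method,
                time_zero_convention=c.time_zero_convention,
                embryos=c.embryos,
                n_sacs=c.n_sacs,
            )
        )
    return Cohort(cycles=cycles, source=cohort.source + ":bootstrap")


def internal_validate(
    spec: EUModelSpec,
    cohort: Cohort,
    n_bootstrap: int = 200,
    seed: int = 0,
    refit: Optional[Callable[[Cohort], EUModelFit]] = None,
    fit_options: Optional[FitOptions] = None,
) -> ValidationReport:
    """Optimism-corrected AUC and calibration slope via Harrell's bootstrap.

    By default each resample refits the coefficients of ``spec`` (knots
    frozen from the original cohort).  Pass ``refit`` to rebuild the model
    some other way on each resample, e.g. re-running variable selection.
    Failed replicates are dropped and counted; more than 20% failures is
    an error.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    from dataclasses import replace as _dc_replace

    from .model import build_design

    rng = np.random.default_rng(seed)
    spec = spec.with_frozen_knots(cohort)
    base_options = fit_options or FitOptions(n_restarts=2, compute_covariance=False)

    custom_refit = refit is not None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        original_fit = refit(cohort) if custom_refit else fit_eu_model(spec, cohort, base_options)
        design0 = build_design(original_fit.spec, cohort)
        p0, y0 = _set_predictions(original_fit, design0)
        apparent_auc = concordance_auc(p0, y0)
        apparent_slope, _ = calibration_slope(p0, y0)

        if not custom_refit:
            from .model import _fit_design

            theta0 = np.concatenate([original_fit.beta_e, original_fit.beta_u])
            # replicates keep the model structure and warm-start at the
            # original solution; only the coefficients are refitted
            boot_options = _dc_replace(
                base_options,
                n_restarts=0,
                start=theta0,
                compute_covariance=False,
                gtol=max(base_options.gtol, 1e-6),
            )

        auc_opt, slope_opt, failed = [], [], 0
        for _ in range(n_bootstrap):
            try:
                if custom_refit:
                    sample = _resample(cohort, rng)
                    bfit = refit(sample)
                    design_b = build_design(bfit.spec, sample)
                    design_t = (
                        design0
                        if bfit.spec == original_fit.spec
                        else build_design(bfit.spec, cohort)
                    )
                else:
                    idx = rng.integers(0, len(cohort), size=len(cohort))
                    design_b = _resample_design(design0, idx)
                    bfit = _fit_design(original_fit.spec, design_b, boot_options)
                    design_t = design0
                pb, yb = _set_predictions(bfit, design_b)
                pt, yt = _set_predictions(bfit, design_t)
                auc_b = concordance_auc(pb, yb)
                auc_t = concordance_auc(pt, yt)
                slope_b, _ = calibration_slope(pb, yb)
                slope_t, _ = calibration_slope(pt, yt)
            except (ValueError, RuntimeError):
                failed += 1
                continue
            auc_opt.append(auc_b - auc_t)
            slope_opt.append(slope_b - slope_t)
    if failed > 0.2 * n_bootstrap:
        raise RuntimeError(f"{failed}/{n_bootstrap} bootstrap replicates failed")
    return ValidationReport(
        apparent_auc=apparent_auc,
        apparent_slope=apparent_slope,
        auc_optimisms=np.asarray(auc_opt),
        slope_optimisms=np.asarray(slope_opt),
        n_bootstrap=n_bootstrap,
        n_failed=failed,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# External validation


@dataclass
class ExternalValidationResult:
    """Frozen-model performance on an independent cohort, with bootstrap CIs."""

    auc: float
    auc_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    curve: pd.DataFrame
    n_cycles: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "intercept": self.intercept,
            "n_cycles": self.n_cycles,
            "seed": self.seed,
            "calibration_curve": self.curve.to_dict(orient="records"),
        }


def external_validate(
    fit: EUModelFit,
    cohort: Cohort,
    n_ci_bootstrap: int = 2000,
    seed: int = 0,
    set_only: bool = False,
) -> ExternalValidationResult:
    """Validate a frozen fit (knots and coefficients untouched) on a new cohort.

    Per-cycle predictions are P(>= 1 sac); 95% CIs are percentile bootstrap
    over resampled validation cycles.  ``set_only`` restricts to SET cycles.
    """
    cycles = [c for c in cohort if (not set_only) or (not c.is_det)]
    if not cycles:
        raise ValueError("no cycles to validate on")
    p = np.array([predict_cycle(fit, c).p_pregnant for c in cycles])
    y = np.array([int(c.pregnant) for c in cycles])
    auc = concordance_auc(p, y)
    slope, intercept = calibration_slope(p, y)
    rng = np.random.default_rng(seed)
    aucs, slopes = [], []
    n = len(cycles)
    for _ in range(n_ci_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            aucs.append(concordance_auc(p[idx], y[idx]))
            slopes.append(calibration_slope(p[idx], y[idx])[0])
        except ValueError:
            continue
    auc_ci = tuple(np.percentile(aucs, [2.5, 97.5])) if aucs else (np.nan, np.nan)
    slope_ci = tuple(np.percentile(slopes, [2.5, 97.5])) if slopes else (np.nan, np.nan)
    return ExternalValidationResult(
        auc=auc,
        auc_ci=(float(auc_ci[0]), float(auc_ci[1])),
        slope=slope,
        slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
        intercept=intercept,
        curve=calibration_curve(p, y),
        n_cycles=n,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Observed vs fitted outcome tables


def observed_vs_fitted_table(
    fit: Optional[EUModelFit], cohort: Cohort, normalize: str = "within"
) -> pd.DataFrame:
    """Outcome percentages by transfer type and sac count.

    Observed % = category count over cycles of that transfer type (or over
    all cycles with ``normalize="overall"``); fitted % = mean predicted
    category probability over the same cycles (omitted when ``fit`` is
    None).  The SET two-sac column is structurally zero.
    """
    if normalize not in ("within", "overall"):
        raise ValueError("normalize must be 'within' or 'overall'")
    n_total = len(cohort)
    rows = []
    for kind, is_det in (("SET", False), ("DET", True)):
        cycles = [c for c in cohort if c.is_det == is_det]
        n = len(cycles)
        denom = n_total if normalize == "overall" else n
        counts = [sum(c.n_sacs == k for c in cycles) for k in (0, 1, 2)]
        row = {"transfer": kind, "n": n}
        for k in (0, 1, 2):
            row[f"observed_{k}_sacs_pct"] = 100.0 * counts[k] / denom if denom else np.nan
        if fit is not None and n:
            probs = np.zeros(3)
            for c in cycles:
                p = np.asarray(predict_cycle(fit, c).p_sacs)
                probs[: p.size] += p
            probs = 100.0 * probs / denom
            for k in (0, 1, 2):
                row[f"fitted_{k}_sacs_pct"] = probs[k]
        rows.append(row)
    return pd.DataFrame(rows)
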