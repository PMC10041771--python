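"""Model development: backward elimination, E-vs-U placement, spline df.

Variable selection follows the relaxed backward-elimination rule used in
clinical prediction modelling: the whole term block of the candidate with
the largest likelihood-ratio p-value is removed while that p-value
exceeds the threshold (default 0.3).  Spline blocks are atomic — all
basis columns of a variable leave together.  Placement of a covariate in
the embryo (E) or uterus (U) part is decided by AIC, ties broken toward
E.  Spline degrees of freedom start at 2 per variable and are adjusted
per variable by AIC over a small ladder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort import Cohort
from .model import ETerm, EUModelFit, EUModelSpec, FitOptions, fit_eu_model

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "lrt_for_term",
    "backward_select",
    "choose_part_for_covariate",
    "adjust_spline_df",
]


@dataclass(frozen=True)
class SelectionStep:
    candidate: str
    statistic: float
    df: int
    p_value: float
    decision: str  # "removed" | "kept" | "df-set"
    loglik: float
    aic: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def append(self, step: SelectionStep) -> None:
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])

    def to_json(self) -> str:
        return json.dumps([s.__dict__ for s in self.steps], indent=2)


def lrt_for_term(full: EUModelFit, reduced: EUModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested reduction.

    statistic = 2 (loglik_full - loglik_reduced); df = parameter-count
    difference; p from the chi-square upper tail.
    """
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    reduced_vars = {t.variable for t in reduced.spec.e_terms}
    full_vars = {t.variable for t in full.spec.e_terms}
    if not reduced_vars <= full_vars or not set(reduced.spec.u_terms) <= set(full.spec.u_terms):
        raise ValueError("models are not nested")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(chi2.sf(stat, df))


def backward_select(
    spec: EUModelSpec,
    cohort: Cohort,
    threshold: float = 0.3,
    fit_options: Optional[FitOptions] = None,
) -> tuple[EUModelFit, SelectionTrace]:
    """Largest-p-first backward elimination of whole E-part term blocks.

    Repeatedly drops the candidate whose block LRT p-value is largest and
    exceeds ``threshold``; stops when every remaining term has p <= threshold.
    Ties remove the variable listed later in the candidate order.
    """
    if not (0.0 < threshold < 1.0) and threshold not in (0.0, 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    options = fit_options or FitOptions(n_restarts=2, compute_covariance=False)
    spec = spec.with_frozen_knots(cohort)
    trace = SelectionTrace()
    current = fit_eu_model(spec, cohort, options)
    while current.spec.e_terms:
        tests = []
        for term in current.spec.e_terms:
            reduced_spec = current.spec.drop_e_term(term.variable)
            try:
                reduced = fit_eu_model(reduced_spec, cohort, options)
            except Exception as err:
                raise RuntimeError(
                    f"backward selection failed refitting without {term.variable!r}"
                ) from err
            stat, df, p = lrt_for_term(current, reduced)
            tests.append((term.variable, stat, df, p, reduced))
        # largest p; ties broken toward the later-listed candidate
        worst = max(enumerate(tests), key=lambda kv: (kv[1][3], kv[0]))[1]
        name, stat, df, p, reduced = worst
        if p > threshold:
            trace.append(
                SelectionStep(name, stat, df, p, "removed", reduced.loglik, reduced.aic)
            )
            current = reduced
        else:
            for name_, stat_, df_, p_, _ in tests:
                trace.append(
                    SelectionStep(
                        name_, stat_, df_, p_, "kept", current.loglik, current.aic
                    )
                )
            break
    return current, trace


def choose_part_for_covariate(
    covariate: str,
    cohort: Cohort,
    base_spec: EUModelSpec,
    df: int = 2,
    fit_options: Optional[FitOptions] = None,
) -> tuple[str, pd.DataFrame]:
    """Place a covariate in the E or U part by AIC (ties go to E).

    The E placement uses a spline with the given df; the U placement is a
    linear cycle-level term (U-part effects act once per cycle).
    """
    if any(t.variable == covariate for t in base_spec.e_terms) or covariate in base_spec.u_terms:
        raise ValueError(f"{covariate!r} already placed in the base model")
    options = fit_options or FitOptions(n_restarts=2, compute_covariance=False)
    spec_e = replace(
        base_spec, e_terms=tuple([*base_spec.e_terms, ETerm(covariate, df)])
    ).with_frozen_knots(cohort)
    spec_u = replace(base_spec, u_terms=tuple([*base_spec.u_terms, covariate]))
    fits = {}
    for part, spec in (("E", spec_e), ("U", spec_u)):
        try:
            fits[part] = fit_eu_model(spec, cohort, options)
        except Exception as err:
            raise RuntimeError(f"fit failed with {covariate!r} in the {part} part") from err
    table = pd.DataFrame(
        {
            "part": ["E", "U"],
            "loglik": [fits["E"].loglik, fits["U"].loglik],
            "n_params": [fits["E"].n_params, fits["U"].n_params],
            "aic": [fits["E"].aic, fits["U"].aic],
        }
    )
    choice = "E" if fits["E"].aic <= fits["U"].aic else "U"
    return choice, table


def adjust_spline_df(
    spec: EUModelSpec,
    cohort: Cohort,
    ladder: Sequence[int] = (1, 2, 3),
    fit_options: Optional[FitOptions] = None,
) -> tuple[EUModelSpec, pd.DataFrame]:
    """Per-variable spline df minimizing AIC over a ladder (greedy, in order).

    Each variable's knots are re-placed at its new df; other variables keep
    their current setting while one is being tuned.
    """
    if len(ladder) == 0:
        raise ValueError("ladder must be non-empty")
    options = fit_options or FitOptions(n_restarts=2, compute_covariance=False)
    ladder = list(ladder)
    current = spec
    rows = []
    if len(ladder) == 1:
        return current, pd.DataFrame(rows)
    for term in spec.e_terms:
        best_df, best_aic = None, np.inf
        for df in ladder:
            trial = current.with_e_df(term.variable, df).with_frozen_knots(cohort)
            fit = fit_eu_model(trial, cohort, options)
            rows.append(
                {
                    "variable": term.variable,
                    "df": df,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                }
            )
            if fit.aic < best_aic:
                best_df, best_aic = df, fit.aic
        current = current.with_e_df(term.variable, best_df).with_frozen_knots(cohort)
    return current, pd.DataFrame(rows)
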