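"""The Embryo-Uterus (EU) model: likelihood, fitting and prediction.

The EU model factorizes the probability of observing ``k`` gestational
sacs after transferring one or two embryos into two logistic parts:

* the **U part** — the probability ``u`` that the recipient (uterus) is
  suitable in this cycle; a logistic model on cycle-level covariates
  (by default an intercept only);
* the **E part** — the probability ``e_j`` that embryo ``j`` develops
  into a gestational sac *given* a suitable recipient; a logistic model
  on per-embryo morphokinetic features and female age, with restricted
  cubic splines for non-linear effects.

Given receptivity, embryo viabilities are independent, so for a double
transfer

    P(2) = u e1 e2
    P(1) = u [e1 (1 - e2) + e2 (1 - e1)]
    P(0) = (1 - u) + u (1 - e1)(1 - e2)

The shared latent receptivity induces the positive correlation between
embryos transferred together, which is what lets mixed-outcome double
transfers (one sac out of two embryos) contribute to the likelihood
instead of being discarded.  Fitting is by direct maximization of the
likelihood over both parts jointly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .cohort import Cohort, CycleRecord, MorphokineticFeatures, extract_features
from .splines import SplineBasis, evaluate_basis, place_knots

__all__ = [
    "ETerm",
    "EUModelSpec",
    "EUModelFit",
    "CyclePrediction",
    "FitOptions",
    "FitError",
    "cycle_outcome_distribution",
    "log_likelihood",
    "fit_eu_model",
    "predict_cycle",
    "prediction_curve",
]

EMBRYO_COVARIATES = ("female_age", "t2", "int_t3_t2", "int_t5_t4")
CYCLE_COVARIATES = ("female_age", "cycle_number")

MODEL_JSON_VERSION = 1


class FitError(RuntimeError):
    """Optimizer failed; carries the best parameters found so far."""

    def __init__(self, message: str, best_fit: Optional["EUModelFit"] = None):
        super().__init__(message)
        self.best_fit = best_fit


# ---------------------------------------------------------------------------
# Specification


@dataclass(frozen=True)
class ETerm:
    """One covariate in the E part: spline df and (once fitted) frozen knots."""

    variable: str
    df: int = 2
    knots: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.variable not in EMBRYO_COVARIATES:
            raise ValueError(f"unknown embryo-level covariate {self.variable!r}")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.knots and len(self.knots) != self.df + 1:
            raise ValueError(
                f"{self.variable}: {len(self.knots)} knots inconsistent with df={self.df}"
            )

    @property
    def frozen(self) -> bool:
        return self.df == 1 or bool(self.knots)

    def basis(self) -> SplineBasis:
        if not self.frozen:
            raise ValueError(f"{self.variable}: knots not frozen yet")
        return SplineBasis(self.variable, self.knots if self.df > 1 else ())

    def column_names(self) -> list[str]:
        return [self.variable] + [f"{self.variable}{'′' * (j + 1)}" for j in range(self.df - 1)]


@dataclass(frozen=True)
class EUModelSpec:
    """Declarative model structure: covariates per part, spline df per term.

    ``u_fixed`` pins the receptivity probability to a constant (no U
    parameters); used for degenerate/illustrative fits.
    """

    e_terms: tuple[ETerm, ...] = ()
    u_terms: tuple[str, ...] = ()
    u_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "e_terms", tuple(self.e_terms))
        object.__setattr__(self, "u_terms", tuple(self.u_terms))
        names = [t.variable for t in self.e_terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate in E part")
        for name in self.u_terms:
            if name not in CYCLE_COVARIATES:
                raise ValueError(f"unknown cycle-level covariate {name!r}")
        overlap = set(names) & set(self.u_terms)
        if overlap:
            raise ValueError(f"covariate(s) in both parts: {sorted(overlap)}")
        if self.u_fixed is not None:
            if self.u_terms:
                raise ValueError("u_fixed is incompatible with u_terms")
            if not (0.0 <= self.u_fixed <= 1.0):
                raise ValueError("u_fixed must be a probability")

    @classmethod
    def from_dfs(
        cls,
        e_dfs: dict[str, int],
        u_terms: Sequence[str] = (),
        u_fixed: Optional[float] = None,
    ) -> "EUModelSpec":
        return cls(
            e_terms=tuple(ETerm(v, df) for v, df in e_dfs.items()),
            u_terms=tuple(u_terms),
            u_fixed=u_fixed,
        )

    @property
    def frozen(self) -> bool:
        return all(t.frozen for t in self.e_terms)

    @property
    def n_e_params(self) -> int:
        return 1 + sum(t.df for t in self.e_terms)

    @property
    def n_u_params(self) -> int:
        return 0 if self.u_fixed is not None else 1 + len(self.u_terms)

    @property
    def n_params(self) -> int:
        return self.n_e_params + self.n_u_params

    def e_column_names(self) -> list[str]:
        names = ["(intercept)"]
        for t in self.e_terms:
            names.extend(t.column_names())
        return names

    def u_column_names(self) -> list[str]:
        return [] if self.u_fixed is not None else ["(intercept)", *self.u_terms]

    def with_frozen_knots(self, cohort: Cohort) -> "EUModelSpec":
        """Place spline knots from the cohort's embryo-level covariate sample."""
        if self.frozen:
            return self
        values = _embryo_covariate_table(cohort)
        new_terms = []
        for t in self.e_terms:
            if t.frozen:
                new_terms.append(t)
            else:
                basis = place_knots(t.variable, values[t.variable], t.df)
                new_terms.append(replace(t, knots=basis.knots))
        return replace(self, e_terms=tuple(new_terms))

    def drop_e_term(self, variable: str) -> "EUModelSpec":
        kept = tuple(t for t in self.e_terms if t.variable != variable)
        if len(kept) == len(self.e_terms):
            raise ValueError(f"{variable!r} not in E part")
        return replace(self, e_terms=kept)

    def with_e_df(self, variable: str, df: int) -> "EUModelSpec":
        new_terms = tuple(
            ETerm(t.variable, df) if t.variable == variable else t for t in self.e_terms
        )
        return replace(self, e_terms=new_terms)


def default_spec(df: int = 2) -> EUModelSpec:
    """Full candidate set: female age, t2, t3-t2 and t5-t4 in the E part."""
    return EUModelSpec.from_dfs({v: df for v in EMBRYO_COVARIATES})


# ---------------------------------------------------------------------------
# Design matrices


def _embryo_covariate_table(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for cycle in cohort:
        for feats in extract_features(cycle):
            rows.append(
                {name: getattr(feats, name) for name in EMBRYO_COVARIATES}
            )
    return pd.DataFrame(rows, columns=list(EMBRYO_COVARIATES))


def _cycle_value(cycle: CycleRecord, name: str) -> float:
    if name == "female_age":
        return cycle.female_age
    if name == "cycle_number":
        return float(cycle.cycle_number)
    raise ValueError(f"unknown cycle-level covariate {name!r}")


@dataclass
class DesignData:
    """Precomputed matrices and index maps for fast likelihood evaluation."""

    Xe: np.ndarray  # (n_embryos, pE) with leading intercept column
    Xu: np.ndarray  # (n_cycles, pU); pU = 0 when u is fixed
    u_fixed: Optional[float]
    y: np.ndarray  # (n_cycles,) observed sac counts
    set_cycles: np.ndarray  # cycle indices with one embryo
    set_rows: np.ndarray  # Xe row of that embryo
    det_cycles: np.ndarray
    det_rows1: np.ndarray
    det_rows2: np.ndarray
    cycle_ids: list[str]

    @property
    def n_cycles(self) -> int:
        return self.y.size

    @property
    def n_embryos(self) -> int:
        return self.Xe.shape[0]


def build_design(spec: EUModelSpec, cohort: Cohort) -> DesignData:
    if not spec.frozen:
        raise ValueError("spec has unfrozen knots; call with_frozen_knots first")
    feat_values: dict[str, list[float]] = {v: [] for v in EMBRYO_COVARIATES}
    xu_rows: list[list[float]] = []
    y, cycle_ids = [], []
    set_c, set_r, det_c, det_r1, det_r2 = [], [], [], [], []
    row = 0
    for ci, cycle in enumerate(cohort):
        feats = extract_features(cycle)
        for f in feats:
            for v in EMBRYO_COVARIATES:
                feat_values[v].append(getattr(f, v))
        if spec.u_fixed is None:
            xu_rows.append([1.0] + [_cycle_value(cycle, n) for n in spec.u_terms])
        y.append(cycle.n_sacs)
        cycle_ids.append(cycle.cycle_id)
        if len(feats) == 1:
            set_c.append(ci)
            set_r.append(row)
        else:
            det_c.append(ci)
            det_r1.append(row)
            det_r2.append(row + 1)
        row += len(feats)
    # basis columns evaluated per term over all embryos at once
    blocks = [np.ones((row, 1))]
    for t in spec.e_terms:
        blocks.append(evaluate_basis(t.basis(), np.asarray(feat_values[t.variable])))
    Xe = np.hstack(blocks) if row else np.zeros((0, spec.n_e_params))
    Xu = (
        np.asarray(xu_rows, dtype=float).reshape(len(y), spec.n_u_params)
        if spec.u_fixed is None
        else np.zeros((len(y), 0))
    )
    return DesignData(
        Xe=Xe,
        Xu=Xu,
        u_fixed=spec.u_fixed,
        y=np.asarray(y, dtype=int),
        set_cycles=np.asarray(set_c, dtype=int),
        set_rows=np.asarray(set_r, dtype=int),
        det_cycles=np.asarray(det_c, dtype=int),
        det_rows1=np.asarray(det_r1, dtype=int),
        det_rows2=np.asarray(det_r2, dtype=int),
        cycle_ids=cycle_ids,
    )


# ---------------------------------------------------------------------------
# Outcome distribution and likelihood


def cycle_outcome_distribution(u: float, e: Sequence[float]) -> np.ndarray:
    """Probability vector over sac counts {0..m} for m transferred embryos.

    Closed-form marginalization of the latent (receptive, viable_j) states
    under conditional independence of viabilities given receptivity.
    """
    e = np.asarray(e, dtype=float)
    if not (0.0 <= u <= 1.0) or np.any(e < 0) or np.any(e > 1):
        raise ValueError("u and e must be probabilities in [0, 1]")
    if e.size == 1:
        p1 = u * e[0]
        return np.array([1.0 - p1, p1])
    if e.size == 2:
        e1, e2 = e
        p2 = u * e1 * e2
        p1 = u * (e1 * (1 - e2) + e2 * (1 - e1))
        p0 = (1 - u) + u * (1 - e1) * (1 - e2)
        return np.array([p0, p1, p2])
    raise ValueError("1 or 2 embryos supported")


_P_FLOOR = 1e-300


def _cycle_probs(theta: np.ndarray, d: DesignData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P_obs per cycle, u per cycle, e per embryo) at parameter vector theta."""
    pE = d.Xe.shape[1]
    beta_e, beta_u = theta[:pE], theta[pE:]
    e = expit(d.Xe @ beta_e)
    if d.u_fixed is None:
        u = expit(d.Xu @ beta_u)
    else:
        u = np.full(d.n_cycles, float(d.u_fixed))
    P = np.empty(d.n_cycles)
    # SET cycles
    if d.set_cycles.size:
        us = u[d.set_cycles]
        e1 = e[d.set_rows]
        p1 = us * e1
        ys = d.y[d.set_cycles]
        P[d.set_cycles] = np.where(ys == 1, p1, 1.0 - p1)
    # DET cycles
    if d.det_cycles.size:
        ud = u[d.det_cycles]
        e1, e2 = e[d.det_rows1], e[d.det_rows2]
        p2 = ud * e1 * e2
        p1 = ud * (e1 * (1 - e2) + e2 * (1 - e1))
        p0 = 1.0 - ud * (e1 + e2 - e1 * e2)
        yd = d.y[d.det_cycles]
        P[d.det_cycles] = np.where(yd == 2, p2, np.where(yd == 1, p1, p0))
    return P, u, e


def _loglik(theta: np.ndarray, d: DesignData) -> float:
    P, _, _ = _cycle_probs(theta, d)
    if np.any(P <= 0):
        return -np.inf
    return float(np.sum(np.log(P)))


def _negloglik_and_grad(theta: np.ndarray, d: DesignData) -> tuple[float, np.ndarray]:
    """Objective and analytic gradient on (possibly standardized) design."""
    pE = d.Xe.shape[1]
    P, u, e = _cycle_probs(theta, d)
    Pc = np.clip(P, _P_FLOOR, None)
    nll = -float(np.sum(np.log(Pc)))
    # weights w_cycle = (1/P) dP/du and per-embryo v = (1/P) dP/de_j
    wu = np.zeros(d.n_cycles)
    ve = np.zeros(d.n_embryos)
    if d.set_cycles.size:
        us, e1 = u[d.set_cycles], e[d.set_rows]
        ys = d.y[d.set_cycles]
        Ps = Pc[d.set_cycles]
        wu[d.set_cycles] = np.where(ys == 1, e1, -e1) / Ps
        ve[d.set_rows] = np.where(ys == 1, us, -us) / Ps
    if d.det_cycles.size:
        ud = u[d.det_cycles]
        e1, e2 = e[d.det_rows1], e[d.det_rows2]
        yd = d.y[d.det_cycles]
        Pd = Pc[d.det_cycles]
        S = e1 + e2 - e1 * e2
        dPdu = np.where(yd == 2, e1 * e2, np.where(yd == 1, e1 + e2 - 2 * e1 * e2, -S))
        dPde1 = ud * np.where(yd == 2, e2, np.where(yd == 1, 1 - 2 * e2, -(1 - e2)))
        dPde2 = ud * np.where(yd == 2, e1, np.where(yd == 1, 1 - 2 * e1, -(1 - e1)))
        wu[d.det_cycles] = dPdu / Pd
        ve[d.det_rows1] = dPde1 / Pd
        ve[d.det_rows2] = dPde2 / Pd
    grad_e = d.Xe.T @ (ve * e * (1 - e))
    if d.u_fixed is None:
        grad_u = d.Xu.T @ (wu * u * (1 - u))
        grad = np.concatenate([grad_e, grad_u])
    else:
        grad = grad_e
    return nll, -grad


def log_likelihood(
    spec: EUModelSpec, beta_e: np.ndarray, beta_u: np.ndarray, cohort: Cohort
) -> float:
    """Cohort log-likelihood; -inf when an observed outcome has probability 0."""
    d = build_design(spec, cohort)
    theta = np.concatenate([np.asarray(beta_e, float), np.asarray(beta_u, float)])
    if theta.size != d.Xe.shape[1] + d.Xu.shape[1]:
        raise ValueError("parameter vector length does not match spec")
    lp_e = d.Xe @ np.asarray(beta_e, float)
    if not np.all(np.isfinite(lp_e)):
        bad = int(np.argmax(~np.isfinite(lp_e)))
        raise ValueError(f"non-finite linear predictor (embryo row {bad})")
    return _loglik(theta, d)


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for maximum-likelihood fitting.

    ``n_restarts`` seeded random restarts are run in addition to a warm
    start at the plain logistic-regression solution for the E part with
    the U intercept at logit(0.9).
    """

    n_restarts: int = 5
    seed: int = 0
    maxiter: int = 1000
    gtol: float = 1e-8
    compute_covariance: bool = True
    start: Optional[np.ndarray] = None  # extra start on the original scale


@dataclass
class EUModelFit:
    """A fitted EU model: frozen spec, coefficients and diagnostics."""

    spec: EUModelSpec
    beta_e: np.ndarray
    beta_u: np.ndarray
    loglik: float
    converged: bool
    n_cycles: int
    n_embryos: int
    covariance: Optional[np.ndarray] = None
    covariance_unreliable: bool = False

    @property
    def n_params(self) -> int:
        return self.beta_e.size + self.beta_u.size

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def standard_errors(self) -> np.ndarray:
        if self.covariance is None:
            raise ValueError("covariance not computed for this fit")
        return np.sqrt(np.diag(self.covariance))

    def coefficients(self) -> pd.DataFrame:
        names = [f"E:{n}" for n in self.spec.e_column_names()] + [
            f"U:{n}" for n in self.spec.u_column_names()
        ]
        est = np.concatenate([self.beta_e, self.beta_u])
        out = pd.DataFrame({"term": names, "estimate": est})
        if self.covariance is not None:
            out["se"] = self.standard_errors()
        return out

    def log_likelihood(self, cohort: Cohort) -> float:
        return log_likelihood(self.spec, self.beta_e, self.beta_u, cohort)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_JSON_VERSION,
            "spec": {
                "e_terms": [
                    {"variable": t.variable, "df": t.df, "knots": list(t.knots)}
                    for t in self.spec.e_terms
                ],
                "u_terms": list(self.spec.u_terms),
                "u_fixed": self.spec.u_fixed,
            },
            "beta_e": self.beta_e.tolist(),
            "beta_u": self.beta_u.tolist(),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_cycles": int(self.n_cycles),
            "n_embryos": int(self.n_embryos),
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "covariance_unreliable": bool(self.covariance_unreliable),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, doc: dict) -> "EUModelFit":
        if doc.get("format_version") != MODEL_JSON_VERSION:
            raise ValueError(f"unsupported model format {doc.get('format_version')!r}")
        spec = EUModelSpec(
            e_terms=tuple(
                ETerm(t["variable"], t["df"], tuple(t["knots"]))
                for t in doc["spec"]["e_terms"]
            ),
            u_terms=tuple(doc["spec"]["u_terms"]),
            u_fixed=doc["spec"]["u_fixed"],
        )
        cov = doc.get("covariance")
        return cls(
            spec=spec,
            beta_e=np.asarray(doc["beta_e"], dtype=float),
            beta_u=np.asarray(doc["beta_u"], dtype=float),
            loglik=float(doc["loglik"]),
            converged=bool(doc["converged"]),
            n_cycles=int(doc["n_cycles"]),
            n_embryos=int(doc["n_embryos"]),
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            covariance_unreliable=bool(doc.get("covariance_unreliable", False)),
        )

    @classmethod
    def from_json(cls, source) -> "EUModelFit":
        import os

        if isinstance(source, (str, os.PathLike)) and not str(source).lstrip().startswith("{"):
            with open(source, "r", encoding="utf-8") as fh:
                return cls.from_dict(json.load(fh))
        if isinstance(source, (str, bytes)):
            return cls.from_dict(json.loads(source))
        return cls.from_dict(json.load(source))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score non-intercept columns; returns (Xs, mu, sd) with sd=1 guards."""
    mu = X.mean(axis=0) if X.size else np.zeros(X.shape[1])
    sd = X.std(axis=0) if X.size else np.ones(X.shape[1])
    if X.shape[1]:
        mu[0], sd[0] = 0.0, 1.0  # intercept untouched
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xs = (X - mu) / sd
    if X.shape[1]:
        Xs[:, 0] = 1.0
    return Xs, mu, sd


def _destandardize(beta_s: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    if beta_s.size == 0:
        return beta_s
    beta = beta_s / sd
    beta[0] = beta_s[0] - np.sum(beta_s[1:] * mu[1:] / sd[1:])
    return beta


def _hessian_fd(theta: np.ndarray, d: DesignData) -> np.ndarray:
    """Central finite differences of the analytic gradient of -loglik."""
    p = theta.size
    H = np.empty((p, p))
    for i in range(p):
        h = 1e-5 * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = _negloglik_and_grad(tp, d)
        _, gm = _negloglik_and_grad(tm, d)
        H[:, i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _warm_start_e(d_std: DesignData, spec: EUModelSpec) -> np.ndarray:
    """Plain logistic regression of any-sac pregnancy on embryo features."""
    from sklearn.linear_model import LogisticRegression

    y_embryo = np.zeros(d_std.n_embryos)
    pregnant = d_std.y >= 1
    if d_std.set_cycles.size:
        y_embryo[d_std.set_rows] = pregnant[d_std.set_cycles]
    if d_std.det_cycles.size:
        y_embryo[d_std.det_rows1] = pregnant[d_std.det_cycles]
        y_embryo[d_std.det_rows2] = pregnant[d_std.det_cycles]
    X = d_std.Xe[:, 1:]
    if X.shape[1] == 0 or len(np.unique(y_embryo)) < 2:
        rate = np.clip(y_embryo.mean(), 1e-3, 1 - 1e-3)
        beta_e = np.zeros(d_std.Xe.shape[1])
        beta_e[0] = logit(rate)
    else:
        lr = LogisticRegression(C=np.inf, max_iter=2000)
        lr.fit(X, y_embryo)
        beta_e = np.concatenate([lr.intercept_, lr.coef_[0]])
    if spec.u_fixed is not None:
        return beta_e
    beta_u = np.zeros(d_std.Xu.shape[1])
    beta_u[0] = logit(0.9)
    return np.concatenate([beta_e, beta_u])


def fit_eu_model(
    spec: EUModelSpec, cohort: Cohort, options: Optional[FitOptions] = None
) -> EUModelFit:
    """Maximum-likelihood fit of an EU model by quasi-Newton optimization.

    Covariates are standardized internally for conditioning and the
    coefficients back-transformed to the original scale.  Multi-start:
    a warm start at the E-part logistic-regression solution plus seeded
    random restarts; the best optimum is kept.
    """
    options = options or FitOptions()
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    spec = spec.with_frozen_knots(cohort)
    d = build_design(spec, cohort)
    return _fit_design(spec, d, options)


def _fit_design(spec: EUModelSpec, d: DesignData, options: FitOptions) -> EUModelFit:
    """Likelihood maximization given precomputed design matrices."""
    if not np.any(d.y >= 1) or not np.any(d.y == 0):
        raise ValueError("cohort must contain at least one pregnancy and one non-pregnancy")
    if d.det_cycles.size == 0 and spec.u_fixed is None:
        warnings.warn(
            "cohort has no DET cycles: the U intercept is only weakly identified "
            "(the likelihood depends on u and e only through their product)",
            stacklevel=2,
        )

    Xe_s, mu_e, sd_e = _standardize(d.Xe)
    Xu_s, mu_u, sd_u = _standardize(d.Xu)
    d_std = replace(d, Xe=Xe_s, Xu=Xu_s)

    starts = [_warm_start_e(d_std, spec)]
    if options.start is not None:
        st = np.asarray(options.start, dtype=float)
        pE = d.Xe.shape[1]
        # map original-scale start into standardized space
        be, bu = st[:pE].copy(), st[pE:].copy()
        be_s = be * sd_e
        be_s[0] = be[0] + np.sum(be[1:] * mu_e[1:])
        bu_s = bu * sd_u
        if bu.size:
            bu_s[0] = bu[0] + np.sum(bu[1:] * mu_u[1:])
        starts.append(np.concatenate([be_s, bu_s]))
    rng = np.random.default_rng(options.seed)
    p = d.Xe.shape[1] + d.Xu.shape[1]
    for _ in range(options.n_restarts):
        theta0 = rng.normal(0.0, 0.5, size=p)
        if spec.u_fixed is None:
            theta0[d.Xe.shape[1]] = rng.uniform(0.5, 3.0)  # U intercept positive
        starts.append(theta0)

    best = None
    any_success = False
    for theta0 in starts:
        res = minimize(
            _negloglik_and_grad,
            theta0,
            args=(d_std,),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": options.maxiter, "gtol": options.gtol, "ftol": 1e-16},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    theta_s = best.x
    pE = d.Xe.shape[1]
    beta_e = _destandardize(theta_s[:pE], mu_e, sd_e)
    beta_u = _destandardize(theta_s[pE:], mu_u, sd_u)
    theta = np.concatenate([beta_e, beta_u])
    ll = _loglik(theta, d)
    _, grad = _negloglik_and_grad(theta_s, d_std)
    converged = bool(best.success) and float(np.max(np.abs(grad))) < 1e-5

    if not any_success:
        raise FitError(
            "optimizer failed to converge from every start",
            best_fit=EUModelFit(
                spec=spec,
                beta_e=beta_e,
                beta_u=beta_u,
                loglik=ll,
                converged=False,
                n_cycles=d.n_cycles,
                n_embryos=d.n_embryos,
            ),
        )
    if not np.isfinite(ll):
        raise FitError("likelihood is zero at the optimum (impossible observation)")

    cov = None
    unreliable = False
    if options.compute_covariance:
        H = _hessian_fd(theta, d)
        cond = np.linalg.cond(H)
        unreliable = not np.isfinite(cond) or cond > 1e10
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
            unreliable = True

    return EUModelFit(
        spec=spec,
        beta_e=beta_e,
        beta_u=beta_u,
        loglik=ll,
        converged=converged,
        n_cycles=d.n_cycles,
        n_embryos=d.n_embryos,
        covariance=cov,
        covariance_unreliable=unreliable,
    )


# ---------------------------------------------------------------------------
# Prediction


@dataclass(frozen=True)
class CyclePrediction:
    """Predicted receptivity, per-embryo viabilities and sac-count distribution."""

    u: float
    e: tuple[float, ...]
    p_sacs: tuple[float, ...]

    @property
    def p_pregnant(self) -> float:
        return float(1.0 - self.p_sacs[0])

    @property
    def p_twin(self) -> float:
        return float(self.p_sacs[2]) if len(self.p_sacs) == 3 else 0.0


def _e_row(fit: EUModelFit, feats: MorphokineticFeatures) -> np.ndarray:
    cols = [1.0]
    for t in fit.spec.e_terms:
        cols.extend(evaluate_basis(t.basis(), getattr(feats, t.variable))[0])
    return np.asarray(cols)


def embryo_viability(fit: EUModelFit, feats: MorphokineticFeatures) -> float:
    """E-part probability for one embryo's features."""
    return float(expit(_e_row(fit, feats) @ fit.beta_e))


def receptivity(fit: EUModelFit, cycle: Optional[CycleRecord] = None) -> float:
    """U-part probability for a cycle (intercept-only U needs no cycle)."""
    if fit.spec.u_fixed is not None:
        return float(fit.spec.u_fixed)
    if fit.spec.u_terms and cycle is None:
        raise ValueError("U part has covariates; a cycle is required")
    row = [1.0] + [(_cycle_value(cycle, n)) for n in fit.spec.u_terms]
    return float(expit(np.asarray(row) @ fit.beta_u))


def predict_cycle(fit: EUModelFit, cycle: CycleRecord) -> CyclePrediction:
    """Receptivity, per-embryo viabilities and the sac-count distribution."""
    feats = extract_features(cycle)
    u = receptivity(fit, cycle)
    e = tuple(embryo_viability(fit, f) for f in feats)
    p = cycle_outcome_distribution(u, e)
    return CyclePrediction(u=u, e=e, p_sacs=tuple(float(v) for v in p))


def predict_pregnancy(fit: EUModelFit, cohort: Cohort) -> np.ndarray:
    """P(>= 1 gestational sac) per cycle."""
    return np.array([predict_cycle(fit, c).p_pregnant for c in cohort])


DEFAULT_FIXED = {"female_age": 32.0, "t2": 25.0, "int_t3_t2": 11.0, "int_t5_t4": 13.0}


def prediction_curve(
    fit: EUModelFit,
    varying: str,
    grid,
    fixed: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """SET pregnancy probability along a grid of one covariate.

    All other covariates are held at ``fixed`` (defaults: age 32 y, t2 25 h,
    t3-t2 11 h, t5-t4 13 h — values near typical medians, matching how the
    model's effect curves are usually displayed).
    """
    if varying not in EMBRYO_COVARIATES:
        raise ValueError(f"unknown covariate {varying!r}")
    values = dict(DEFAULT_FIXED)
    values.update(fixed or {})
    rows = []
    u = float(fit.spec.u_fixed) if fit.spec.u_fixed is not None else None
    if u is None:
        if fit.spec.u_terms:
            raise ValueError("prediction_curve supports intercept-only or fixed U parts")
        u = float(expit(fit.beta_u[0]))
    for value in np.asarray(grid, dtype=float):
        values[varying] = float(value)
        feats = MorphokineticFeatures(
            t2=values["t2"],
            int_t3_t2=values["int_t3_t2"],
            int_t5_t4=values["int_t5_t4"],
            female_age=values["female_age"],
        )
        e = embryo_viability(fit, feats)
        rows.append({varying: float(value), "p_pregnant": u * e})
    return pd.DataFrame(rows)
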