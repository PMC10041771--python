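"""Restricted (natural) cubic spline bases for non-linear covariate effects.

Harrell's parameterization: for ordered knots k1 < ... < kK the basis has
K - 1 columns.  Column 1 is x itself; nonlinear column j (j = 1..K-2) is

    [ (x-kj)+^3 - (x-k_{K-1})+^3 (kK-kj)/(kK-k_{K-1})
                + (x-kK)+^3 (k_{K-1}-kj)/(kK-k_{K-1}) ] / (kK-k1)^2

so every column is linear beyond the outer knots and the division by the
squared outer-knot span keeps the columns on the scale of x, which keeps
the likelihood optimization well conditioned.  df = K - 1; df = 1 means a
plain linear term with no knots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineBasis", "place_knots", "evaluate_basis", "KNOT_QUANTILES"]

# default knot locations as quantiles of the observed covariate sample
KNOT_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass(frozen=True)
class SplineBasis:
    """A frozen spline basis for one covariate.

    ``df = 1`` encodes a linear term (no knots); otherwise ``df = len(knots) - 1``.
    """

    variable: str
    knots: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.size:
            if k.size < 3:
                raise ValueError(f"{self.variable}: need >= 3 knots, got {k.size}")
            if not np.all(np.diff(k) > 0):
                raise ValueError(f"{self.variable}: knots must be strictly increasing")
        object.__setattr__(self, "knots", tuple(float(v) for v in k))

    @property
    def df(self) -> int:
        return max(len(self.knots) - 1, 1)

    @property
    def is_linear(self) -> bool:
        return not self.knots


def place_knots(variable: str, values, df: int) -> SplineBasis:
    """Choose knots from a covariate sample.

    df = 1 gives a linear basis; df = d > 1 places d + 1 knots at the
    default quantiles (linear-interpolation quantile estimator).
    """
    if df not in (1, 2, 3, 4):
        raise ValueError(f"df must be in 1..4, got {df}")
    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    if distinct.size < 10:
        raise ValueError(
            f"{variable}: need >= 10 distinct values to place knots, got {distinct.size}"
        )
    if df == 1:
        return SplineBasis(variable, ())
    qs = KNOT_QUANTILES[df + 1]
    knots = np.quantile(values, qs, method="linear")
    if not np.all(np.diff(knots) > 0):
        raise ValueError(f"{variable}: sample too concentrated, tied knots {knots}")
    return SplineBasis(variable, tuple(knots))


def evaluate_basis(basis: SplineBasis, x) -> np.ndarray:
    """Design columns for ``x`` (scalar or array) -> shape (n, df)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if basis.is_linear:
        return x[:, None].copy()
    k = np.asarray(basis.knots)
    K = k.size
    span2 = (k[-1] - k[0]) ** 2
    cols = [x]
    for j in range(K - 2):
        term = (
            _pos_cube(x - k[j])
            - _pos_cube(x - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
            + _pos_cube(x - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2])
        )
        cols.append(term / span2)
    return np.column_stack(cols)


def _pos_cube(v: np.ndarray) -> np.ndarray:
    return np.where(v > 0, v, 0.0) ** 3
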