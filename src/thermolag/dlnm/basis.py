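"""Natural cubic spline exposure basis and polynomial lag basis.

The natural cubic spline basis is the classical truncated-power
construction: with knots xi_1 < ... < xi_K the df = K - 1 columns (no
intercept) are

    N_1(x) = x,   N_{k+1}(x) = d_k(x) - d_{K-1}(x),  k = 1..K-2,

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k),

which is twice continuously differentiable and exactly linear beyond the
boundary knots.  df columns therefore require df + 1 knots: the two
boundary knots plus df - 1 interior knots.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["natural_cubic_design", "ExposureBasisSpec", "LagBasisSpec",
           "make_exposure_basis", "make_lag_basis", "quantile_knots"]


def natural_cubic_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the natural cubic spline basis (no intercept) at *x*.

    ``knots`` is the full sorted knot vector (boundary + interior),
    K >= 2 entries; the result has K - 1 columns.  NaN inputs give NaN
    rows.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 2:
        raise ValueError("need at least two knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    K = len(knots)
    xi_K = knots[-1]

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - xi_K, 0, None) ** 3
        return num / (xi_K - knots[k])

    cols = [x]
    if K > 2:
        d_last = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - d_last)
    out = np.column_stack(cols)
    return out if x.ndim else out  # (n, K-1)


def quantile_knots(values: np.ndarray, df: int) -> np.ndarray:
    """Boundary knots at min/max, df - 1 interior knots at equally spaced
    quantiles of the observed values."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(values, probs)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"fewer than {df} distinct values: "
                         "cannot place strictly increasing knots")
    return knots


@dataclass(frozen=True)
class ExposureBasisSpec:
    """Natural cubic spline basis over the exposure range.

    ``df`` columns; knots default to equally spaced quantiles with
    boundary knots at the observed min/max (set by :func:`make_exposure_basis`
    and stored so predictions rebuild the identical basis).
    """

    df: int
    knots: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.df < 3 or self.df > 8:
            raise ValueError("exposure spline df must be in 3..8")
        if self.knots is not None:
            k = np.asarray(self.knots, dtype=float)
            if len(k) != self.df + 1:
                raise ValueError("need df + 1 knots (2 boundary + df - 1 interior)")
            if np.any(np.diff(k) <= 0):
                raise ValueError("knots must be strictly increasing")

    def with_knots_from(self, values: np.ndarray) -> "ExposureBasisSpec":
        return ExposureBasisSpec(self.df, tuple(quantile_knots(values, self.df)))

    def design(self, x: np.ndarray) -> np.ndarray:
        if self.knots is None:
            raise ValueError("knots not set; call with_knots_from first")
        return natural_cubic_design(np.asarray(x, dtype=float), np.asarray(self.knots))

    @property
    def boundary(self) -> tuple[float, float]:
        assert self.knots is not None
        return self.knots[0], self.knots[-1]


@dataclass(frozen=True)
class LagBasisSpec:
    """Polynomial lag basis over lags 0..max_lag: entry (l, k) = l**k.

    The intercept column (k = 0) is included, so df counts the constant.
    df must not exceed max_lag; the infeasible combinations are the "na"
    cells of the sensitivity grid.
    """

    max_lag: int
    df: int

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.df < 1:
            raise ValueError("lag df must be >= 1")
        if self.df > self.max_lag:
            raise ValueError(
                f"na: lag polynomial df {self.df} unavailable with a "
                f"{self.max_lag}-day lag")

    def matrix(self) -> np.ndarray:
        lags = np.arange(self.max_lag + 1, dtype=float)
        return np.vander(lags, self.df, increasing=True)


def make_exposure_basis(values: np.ndarray, spec: ExposureBasisSpec
                        ) -> tuple[np.ndarray, ExposureBasisSpec]:
    """Basis matrix for the observed exposures plus the knot-resolved spec."""
    fitted = spec if spec.knots is not None else spec.with_knots_from(values)
    return fitted.design(values), fitted


def make_lag_basis(spec: LagBasisSpec) -> np.ndarray:
    return spec.matrix()
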