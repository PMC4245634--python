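"""Cross-basis: tensor product of exposure basis and lag basis, summed over lags."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..series import DailySeries
from .basis import ExposureBasisSpec, LagBasisSpec

__all__ = ["CrossBasisMatrix", "build_cross_basis"]


@dataclass(frozen=True)
class CrossBasisMatrix:
    """Per-day design columns for the lag-distributed exposure term.

    Column ``j * lag_df + k`` at day t holds
    ``sum_{l=0..L} b_j(x_{t-l}) * p_k(l)``; the first L rows (and any row
    whose lag window touches a missing exposure) are NaN and excluded from
    fitting.  The specs are retained so predictions can rebuild the same
    exposure basis and lag sums.
    """

    matrix: np.ndarray
    exposure_spec: ExposureBasisSpec
    lag_spec: LagBasisSpec
    exposure: np.ndarray  # original exposure values, for medians/grids

    @property
    def n_cols(self) -> int:
        return self.exposure_spec.df * self.lag_spec.df

    @property
    def valid_rows(self) -> np.ndarray:
        return np.all(np.isfinite(self.matrix), axis=1)

    def lag_sums(self) -> np.ndarray:
        """sum_l p_k(l) for each lag-basis column (cumulative prediction weights)."""
        return self.lag_spec.matrix().sum(axis=0)

    def column_names(self) -> list[str]:
        return [f"cb_e{j}_l{k}"
                for j in range(self.exposure_spec.df)
                for k in range(self.lag_spec.df)]


def build_cross_basis(exposure: DailySeries | np.ndarray,
                      e_spec: ExposureBasisSpec,
                      l_spec: LagBasisSpec) -> CrossBasisMatrix:
    """Build the cross-basis matrix for a daily exposure series."""
    x = exposure.values if isinstance(exposure, DailySeries) else np.asarray(
        exposure, dtype=float)
    L = l_spec.max_lag
    if len(x) < L + 1:
        raise ValueError(f"exposure needs at least {L + 1} days")

    B, e_spec = (e_spec.design(x), e_spec) if e_spec.knots is not None else (
        None, e_spec.with_knots_from(x))
    if B is None:
        B = e_spec.design(x)
    P = l_spec.matrix()  # (L+1, lag_df)
    n, J = B.shape
    Kd = l_spec.df

    out = np.zeros((n, J * Kd))
    for l in range(L + 1):
        Bl = np.full_like(B, np.nan)
        Bl[l:] = B[: n - l]
        # accumulate b_j(x_{t-l}) * p_k(l) into column (j, k)
        out += (Bl[:, :, None] * P[l][None, None, :]).reshape(n, J * Kd)
    return CrossBasisMatrix(out, e_spec, l_spec, x.copy())
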