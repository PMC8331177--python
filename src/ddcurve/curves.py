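"""Per-participant discounting analytics.

Given the seven normalized indifference points of one participant ×
condition × magnitude cell, this module provides

* ``fit_hyperbolic`` — nonlinear least-squares fit of the hyperbolic
  discounting model SV = 1 / (1 + k·D), with D in days and k the
  per-day discount rate;
* ``auc`` — the model-free area under the empirical discounting curve
  (delays normalized by the 120-month maximum, trapezoid rule), which
  runs from 0 (maximally steep discounting) to 1 (no discounting);
* ``count_inconsistencies`` — the number of indifference points that
  exceed the preceding one by more than 10% of the delayed amount,
  a standard screen for nonsystematic discounting data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .staircase import DELAY_DAYS, DELAY_MONTHS, InvalidDesignError

__all__ = [
    "AuCResult",
    "DiscountingCurve",
    "HyperbolicFit",
    "IncompleteCurveError",
    "auc",
    "auc_from_points",
    "count_inconsistencies",
    "fit_hyperbolic",
    "hyperbolic_sv",
]

#: Maximum delay of the task, in months; the AuC x-axis normalizer.
MAX_DELAY_MONTHS = 120.0

K_BOUNDS = (0.0, 10.0)
_K_STARTS = (1e-4, 1e-2, 1.0)


class IncompleteCurveError(ValueError):
    """A discounting curve is missing delays of the task design."""


@dataclass(frozen=True)
class DiscountingCurve:
    """Seven normalized indifference points for one design cell."""

    participant_id: str
    condition: str
    magnitude: str
    delayed_amount: int
    delays_months: tuple[float, ...] = DELAY_MONTHS
    svs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.svs) != len(self.delays_months):
            raise IncompleteCurveError(
                f"{len(self.delays_months)} delays but {len(self.svs)} subjective values"
            )
        if list(self.delays_months) != sorted(self.delays_months):
            raise InvalidDesignError("delays must be increasing")
        if any(not (0.0 <= v <= 1.0) for v in self.svs):
            raise ValueError("normalized subjective values must lie in [0, 1]")


@dataclass(frozen=True)
class HyperbolicFit:
    k: float          # per-day discount rate
    r_squared: float  # 1 - SSres/SStot; may be < 0 for nonmonotone data
    degenerate: bool = False


@dataclass(frozen=True)
class AuCResult:
    auc: float


def hyperbolic_sv(k: float, delay_days: np.ndarray | float) -> np.ndarray | float:
    """Hyperbolic discounting model SV = 1 / (1 + k·D)."""
    return 1.0 / (1.0 + k * np.asarray(delay_days, dtype=float))


def _delays_to_days(delays_months: Sequence[float]) -> np.ndarray:
    return np.array(
        [DELAY_DAYS.get(m, m * 30.0) for m in delays_months], dtype=float
    )


def fit_hyperbolic(curve: DiscountingCurve) -> HyperbolicFit:
    """Least-squares estimate of the hyperbolic discount rate k.

    The single free parameter is minimized over k in [0, 10] per day by
    bounded local optimization from several fixed starting points, which
    makes the fit deterministic.  R-squared is 1 - SSres/SStot; when the
    curve is flat (SStot = 0) the fit is flagged degenerate, with
    R-squared 1 for an exact fit and NaN otherwise.
    """
    days = _delays_to_days(curve.delays_months)
    sv = np.asarray(curve.svs, dtype=float)

    def sse(k: float) -> float:
        return float(np.sum((sv - hyperbolic_sv(k, days)) ** 2))

    best_k, best_sse = 0.0, sse(0.0)
    for start in _K_STARTS:
        res = optimize.minimize(
            lambda x: sse(x[0]), x0=[start], bounds=[K_BOUNDS], method="L-BFGS-B"
        )
        if res.fun < best_sse - 1e-15 or (
            abs(res.fun - best_sse) <= 1e-15 and res.x[0] < best_k
        ):
            best_k, best_sse = float(res.x[0]), float(res.fun)

    ss_tot = float(np.sum((sv - sv.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if best_sse < 1e-12 else float("nan")
        return HyperbolicFit(k=best_k, r_squared=r2, degenerate=True)
    return HyperbolicFit(k=best_k, r_squared=1.0 - best_sse / ss_tot)


def auc_from_points(
    delays_months: Sequence[float],
    svs: Sequence[float],
    max_delay_months: float = MAX_DELAY_MONTHS,
    anchor: bool = True,
) -> float:
    """Trapezoid-rule area under normalized (delay, SV) points.

    Delays are expressed as proportions of ``max_delay_months``; each
    trapezoid contributes (x2 - x1)(y1 + y2)/2.  With ``anchor`` a point
    (0, 1) is prepended — the delayed amount is worth itself at zero
    delay — so a non-discounter scores exactly 1.
    """
    x = np.asarray(delays_months, dtype=float) / max_delay_months
    y = np.asarray(svs, dtype=float)
    if anchor:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[1.0], y])
    return float(np.trapezoid(y, x))


def auc(curve: DiscountingCurve) -> AuCResult:
    """Area under the empirical discounting curve of a 7-delay cell."""
    if tuple(curve.delays_months) != DELAY_MONTHS:
        raise IncompleteCurveError(
            f"curve delays {curve.delays_months} do not match the task design "
            f"{DELAY_MONTHS}"
        )
    return AuCResult(auc=auc_from_points(curve.delays_months, curve.svs))


def count_inconsistencies(curve: DiscountingCurve, threshold: float = 0.1) -> int:
    """Number of inconsistent preferences along the curve.

    An indifference point is inconsistent when it exceeds the point at
    the preceding delay by more than ``threshold`` (default 10%) of the
    delayed amount, on the normalized scale: sv_j > sv_{j-1} + 0.1,
    strictly, over the six consecutive-delay pairs.
    """
    sv = np.asarray(curve.svs, dtype=float)
    return int(np.sum(sv[1:] > sv[:-1] + threshold))
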