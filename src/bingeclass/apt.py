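"""Alcohol Purchase Task (APT) demand-curve analytics.

A purchase task asks how many standard drinks a respondent would buy at
each price of a ladder (here 0-20 euros).  The module screens raw series
for nonsystematic responding (trend, bounce, reversals from zero),
computes the observed demand indices (intensity, Omax, Pmax, breakpoints),
fits the exponentiated demand equation

    Q(C) = Q0 * 10^(k * (exp(-alpha * Q0 * C) - 1))

by nonlinear least squares with the zero price substituted by 0.01 and the
span parameter k fixed at 3.20, and derives Essential Value

    EV = 1 / (100 * alpha * k^1.5),

a standardised measure of the commodity's reinforcing value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

SPAN_K = 3.20
ZERO_PRICE_SUB = 0.01


@dataclass(frozen=True)
class DemandCurve:
    """One respondent's price ladder and reported consumption."""

    prices: tuple[float, ...]
    consumption: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.prices, float)
        q = np.asarray(self.consumption, float)
        if p.shape != q.shape or p.ndim != 1:
            raise ValueError("prices and consumption must be equal-length vectors")
        if np.any(p < 0) or np.any(np.diff(p) <= 0):
            raise ValueError("prices must be nonnegative and strictly increasing")
        if np.any(q < 0):
            raise ValueError("consumption must be nonnegative")

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.prices, float)

    @property
    def q(self) -> np.ndarray:
        return np.asarray(self.consumption, float)


@dataclass(frozen=True)
class ScreenReport:
    """Nonsystematic-data screen: trend, bounce, reversals from zero."""

    trend_ok: bool
    bounce_ok: bool
    reversal_ok: bool
    trend_stat: float
    bounce_ratio: float
    reversal_count: int
    usable: bool = True

    @property
    def passed(self) -> bool:
        return self.usable and self.trend_ok and self.bounce_ok and self.reversal_ok


@dataclass(frozen=True)
class DemandFit:
    """Observed indices plus exponentiated-demand parameters for one curve."""

    intensity: float
    omax: float
    pmax: float
    breakpoint1: float | None
    breakpoint0: float | None
    q0: float | None = None
    alpha: float | None = None
    k: float = SPAN_K
    ev: float | None = None
    converged: bool = False
    rmse: float | None = None
    intensity_flagged: bool = False


def demand_quantity(price, q0: float, alpha: float, k: float = SPAN_K):
    """Exponentiated demand Q(C); exactly Q0 at C=0 for any alpha, k."""
    price = np.asarray(price, float)
    return q0 * 10.0 ** (k * (np.exp(-alpha * q0 * price) - 1.0))


def essential_value(alpha: float, k: float = SPAN_K) -> float:
    """Essential Value EV = 1/(100 * alpha * k^1.5)."""
    if alpha <= 0 or k <= 0:
        raise ValueError("alpha and k must be positive")
    return 1.0 / (100.0 * alpha * k**1.5)


def screen_curve(
    curve: DemandCurve,
    trend_threshold: float = 0.025,
    bounce_jump: float = 0.25,
    bounce_threshold: float = 0.10,
    reversal_zeros: int = 2,
    zero_sub: float = ZERO_PRICE_SUB,
) -> ScreenReport:
    """Screen a curve for trend, bounce and reversal violations.

    trend: log10-unit drop in consumption per log10-unit of price span,
    (log10 Q_first - log10 Q_last) / (log10 P_last - log10 P_first), over
    the positive-price rows (the zero-price row cannot enter a log-price
    span); zeros in consumption are offset by ``zero_sub``.  Flagged when
    below ``trend_threshold``.

    bounce: share of price-to-price consumption *increases* exceeding
    ``bounce_jump`` x intensity; flagged when above ``bounce_threshold``.

    reversal: nonzero consumption after a run of at least ``reversal_zeros``
    consecutive zeros; any occurrence flags the curve.
    """
    p, q = curve.p, curve.q
    if np.all(q == 0):
        return ScreenReport(False, True, True, 0.0, 0.0, 0, usable=False)

    pos = p > 0
    if pos.sum() >= 2:
        pp, qq = p[pos], q[pos]
        span = np.log10(pp[-1]) - np.log10(pp[0])
        drop = np.log10(qq[0] + zero_sub) - np.log10(qq[-1] + zero_sub)
        trend_stat = drop / span if span > 0 else 0.0
    else:
        trend_stat = 0.0
    trend_ok = trend_stat >= trend_threshold

    intensity = q[0] if p[0] == 0 else q[0]
    diffs = np.diff(q)
    jumps = int((diffs > bounce_jump * intensity).sum()) if intensity > 0 else int(
        (diffs > 0).sum()
    )
    bounce_ratio = jumps / len(diffs) if len(diffs) else 0.0
    bounce_ok = bounce_ratio <= bounce_threshold

    reversals = 0
    zero_run = 0
    for v in q:
        if v == 0:
            zero_run += 1
        else:
            if zero_run >= reversal_zeros:
                reversals += 1
            zero_run = 0
    reversal_ok = reversals == 0

    return ScreenReport(
        trend_ok=trend_ok,
        bounce_ok=bounce_ok,
        reversal_ok=reversal_ok,
        trend_stat=float(trend_stat),
        bounce_ratio=float(bounce_ratio),
        reversal_count=reversals,
    )


def observed_indices(curve: DemandCurve) -> DemandFit:
    """Observed demand indices: intensity, Omax, Pmax, BP1, BP0.

    intensity is consumption at the zero-price row when present, else
    consumption at the lowest price (flagged).  Pmax ties resolve to the
    lowest qualifying price.  BP1 (highest price with nonzero consumption)
    is None when consumption is identically zero; BP0 (lowest price with
    zero consumption) is None when consumption never reaches zero.
    """
    p, q = curve.p, curve.q
    flagged = p[0] != 0
    intensity = float(q[0])
    expenditure = p * q
    omax = float(expenditure.max())
    pmax = float(p[int(np.argmax(expenditure))])
    nonzero = q > 0
    bp1 = float(p[nonzero][-1]) if nonzero.any() else None
    zero = q == 0
    bp0 = float(p[zero][0]) if zero.any() else None
    return DemandFit(
        intensity=intensity,
        omax=omax,
        pmax=pmax,
        breakpoint1=bp1,
        breakpoint0=bp0,
        intensity_flagged=bool(flagged),
    )


def fit_exponentiated_demand(
    curve: DemandCurve,
    k: float = SPAN_K,
    loss: str = "linear",
    zero_sub: float = ZERO_PRICE_SUB,
    log_eps: float = 0.01,
) -> DemandFit:
    """Nonlinear least-squares fit of the exponentiated demand equation.

    The zero price is mapped to ``zero_sub`` euros.  Starting values are
    Q0 = observed intensity and alpha = 0.01, both bounded positive.
    ``loss="log"`` switches to least squares on log10(Q + log_eps).
    Returns the observed indices augmented with Q0, alpha, EV, a
    convergence flag and the residual RMSE.
    """
    obs = observed_indices(curve)
    p, q = curve.p, curve.q
    if int((q > 0).sum()) < 3:
        raise ValueError("need at least 3 positive-consumption points to fit demand")

    c = np.where(p == 0, zero_sub, p)
    if loss == "linear":
        model = lambda cc, q0, a: demand_quantity(cc, q0, a, k)
        target = q
    elif loss == "log":
        model = lambda cc, q0, a: np.log10(demand_quantity(cc, q0, a, k) + log_eps)
        target = np.log10(q + log_eps)
    else:
        raise ValueError("loss must be 'linear' or 'log'")

    p0 = (max(obs.intensity, 1e-3), 0.01)
    try:
        popt, _ = curve_fit(
            model, c, target, p0=p0, bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            maxfev=20000,
        )
        q0_hat, alpha_hat = float(popt[0]), float(popt[1])
        resid = q - demand_quantity(c, q0_hat, alpha_hat, k)
        converged = True
        rmse = float(np.sqrt(np.mean(resid**2)))
        ev = essential_value(alpha_hat, k)
    except RuntimeError:
        q0_hat = alpha_hat = ev = rmse = None
        converged = False

    return DemandFit(
        intensity=obs.intensity,
        omax=obs.omax,
        pmax=obs.pmax,
        breakpoint1=obs.breakpoint1,
        breakpoint0=obs.breakpoint0,
        q0=q0_hat,
        alpha=alpha_hat,
        k=k,
        ev=ev,
        converged=converged,
        rmse=rmse,
        intensity_flagged=obs.intensity_flagged,
    )


def derive_span_k(curves, floor: float = 0.01, extra: float = 0.5) -> float:
    """Sample-specific span: widest participant log10 consumption range + 0.5.

    Offered as an optional recomputation utility; the published analyses fix
    k = 3.20.  Zero consumption values are floored at ``floor`` before
    taking logs.
    """
    widest = 0.0
    for curve in curves:
        q = np.clip(curve.q, floor, None)
        widest = max(widest, float(np.log10(q.max()) - np.log10(q.min())))
    return widest + extra


class ExponentiatedDemand:
    """Estimator-style wrapper: fit one demand curve, expose fitted indices.

    Attributes after ``fit``: ``q0_``, ``alpha_``, ``ev_``, ``intensity_``,
    ``omax_``, ``pmax_``, ``breakpoint1_``, ``breakpoint0_``, ``converged_``.
    """

    def __init__(self, k: float = SPAN_K, loss: str = "linear"):
        self.k = k
        self.loss = loss

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "loss": self.loss}

    def set_params(self, **params) -> "ExponentiatedDemand":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, prices, consumption=None) -> "ExponentiatedDemand":
        curve = prices if isinstance(prices, DemandCurve) else DemandCurve(
            tuple(prices), tuple(consumption)
        )
        result = fit_exponentiated_demand(curve, k=self.k, loss=self.loss)
        self.fit_ = result
        for name in ("intensity", "omax", "pmax", "breakpoint1", "breakpoint0",
                     "q0", "alpha", "ev", "converged", "rmse"):
            setattr(self, name + "_", getattr(result, name))
        return self

    def predict(self, prices) -> np.ndarray:
        """Model-implied consumption at the given prices."""
        return demand_quantity(np.asarray(prices, float), self.q0_, self.alpha_, self.k)
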