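"""Partial proportional odds model (PPOM) for ordinal drinker groups.

The model places cumulative logits on the ordinal group outcome y in
{1..K}:

    P(y >= j | x) = expit(alpha_j + sum_k beta_kj x_k),   j = 2..K,

where a *proportional* predictor shares one coefficient across all
thresholds (beta_kj = beta_k) and a *non-proportional* predictor gets one
coefficient per threshold.  Category probabilities are successive
differences of the cumulative curve:

    P(y=1) = 1 - P(y>=2),  P(y=j) = P(y>=j) - P(y>=j+1),  P(y=K) = P(y>=K).

Because per-threshold coefficients are unconstrained, interior differences
can go negative for extreme covariate values; at prediction time such
components are clamped to zero and the vector renormalised (with a
warning), while during fitting an invalid probability incurs a smooth
linear barrier penalty so the optimiser is steered back to the valid
region with a well-defined gradient.

Estimation maximises the multinomial log-likelihood by quasi-Newton
(L-BFGS-B) with the analytic gradient, intercepts initialised at the
empirical cumulative logits and slopes at zero.  Standard errors come from
the inverse observed information (numerically differentiated analytic
gradient); Wald z = coef/SE with standard-normal two-sided p values.

A frozen *published classifier* is provided: the rounded intercepts
(-5.87, -7.37, -8.46) and slopes of the printed cumulative-probability
equations, with the full-precision slope set of the fitted model available
as an alternative (no full-precision intercepts were ever printed, so that
set pairs exact slopes with rounded intercepts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from sklearn.base import BaseEstimator, ClassifierMixin

from .survey import DrinkerGroup, ItemVector, RETAINED_ITEMS

_BARRIER_EPS = 1e-10

#: Threshold structure of the published model: which predictors share one
#: coefficient across thresholds ("proportional").
DEFAULT_PROPORTIONAL: dict[str, bool] = {
    "consumption_frequency": True,
    "drinks_typical_day": True,
    "six_drink_frequency": True,
    "consumption_speed": False,
    "drunkenness_frequency": True,
    "drunk_per_10": False,
    "hangover_per_10": False,
}

_PUBLISHED_INTERCEPTS = (-5.87, -7.37, -8.46)
_PUBLISHED_ROUNDED = {
    "six_drink_frequency": 0.43,
    "consumption_speed": (0.20, 0.07, -0.13),
    "drunkenness_frequency": 0.34,
    "drunk_per_10": (0.68, 0.11, 0.02),
    "hangover_per_10": (0.36, 0.05, -0.34),
}
_TABLE_FULL_PRECISION = {
    "six_drink_frequency": 0.42646,
    "consumption_speed": (0.20057, 0.07370, -0.12883),
    "drunkenness_frequency": 0.33708,
    "drunk_per_10": (0.68408, 0.11046, 0.02215),
    "hangover_per_10": (0.36077, 0.05129, -0.34092),
}


@dataclass(frozen=True)
class PPOMSpec:
    """Model structure: predictor names, proportionality flags, K levels."""

    predictors: tuple[str, ...]
    proportional: tuple[bool, ...]
    n_levels: int = 4

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 ordinal levels")
        if not self.predictors:
            raise ValueError("need at least one predictor")
        if len(self.proportional) != len(self.predictors):
            raise ValueError("one proportionality flag per predictor required")

    @classmethod
    def from_names(cls, predictors, proportional=None, n_levels: int = 4) -> "PPOMSpec":
        predictors = tuple(predictors)
        if proportional is None:
            proportional = tuple(DEFAULT_PROPORTIONAL.get(p, True) for p in predictors)
        elif isinstance(proportional, dict):
            proportional = tuple(bool(proportional.get(p, True)) for p in predictors)
        else:
            proportional = tuple(bool(f) for f in proportional)
        return cls(predictors, proportional, n_levels)

    @property
    def n_thresholds(self) -> int:
        return self.n_levels - 1

    def n_params(self) -> int:
        t = self.n_thresholds
        return t + sum(1 if f else t for f in self.proportional)

    def param_names(self) -> list[str]:
        t = self.n_thresholds
        names = [f"alpha_ge{j}" for j in range(2, self.n_levels + 1)]
        for p, flag in zip(self.predictors, self.proportional):
            if flag:
                names.append(p)
            else:
                names.extend(f"{p}_ge{j}" for j in range(2, self.n_levels + 1))
        return names

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a flat parameter vector into (intercepts, slope matrix p x T)."""
        t = self.n_thresholds
        alpha = theta[:t]
        B = np.empty((len(self.predictors), t))
        pos = t
        for k, flag in enumerate(self.proportional):
            if flag:
                B[k] = theta[pos]
                pos += 1
            else:
                B[k] = theta[pos : pos + t]
                pos += t
        return alpha, B


def _nll_and_grad(theta, X, y, spec: PPOMSpec):
    """Penalised negative log-likelihood and its analytic gradient.

    Category probabilities below _BARRIER_EPS are continued linearly
    (C^1 extension of log), acting as a barrier against invalid regions.
    """
    n = X.shape[0]
    t = spec.n_thresholds
    alpha, B = spec.unpack(theta)
    eta = alpha + X @ B  # n x T
    s = expit(eta)
    sp = s * (1.0 - s)

    p = np.empty(n)
    G = np.zeros((n, t))  # d loglik / d eta, up to the 1/p factor
    for c in range(1, spec.n_levels + 1):
        mask = y == c
        if not mask.any():
            continue
        if c == 1:
            p[mask] = 1.0 - s[mask, 0]
            G[mask, 0] = -sp[mask, 0]
        elif c == spec.n_levels:
            p[mask] = s[mask, t - 1]
            G[mask, t - 1] = sp[mask, t - 1]
        else:
            p[mask] = s[mask, c - 2] - s[mask, c - 1]
            G[mask, c - 2] = sp[mask, c - 2]
            G[mask, c - 1] = -sp[mask, c - 1]

    safe = p >= _BARRIER_EPS
    ll = np.where(safe, np.log(np.clip(p, _BARRIER_EPS, None)),
                  np.log(_BARRIER_EPS) + (p - _BARRIER_EPS) / _BARRIER_EPS)
    w = np.where(safe, 1.0 / np.clip(p, _BARRIER_EPS, None), 1.0 / _BARRIER_EPS)
    G = G * w[:, None]

    grad = np.empty_like(theta)
    grad[:t] = G.sum(axis=0)
    pos = t
    for k, flag in enumerate(spec.proportional):
        if flag:
            grad[pos] = (G.sum(axis=1) * X[:, k]).sum()
            pos += 1
        else:
            grad[pos : pos + t] = G.T @ X[:, k]
            pos += t
    return -float(ll.sum()), -grad


class PartialProportionalOdds(ClassifierMixin, BaseEstimator):
    """Partial proportional odds classifier for ordinal drinker groups.

    Parameters
    ----------
    predictors : sequence of str, optional
        Predictor names (columns of a DataFrame X, or positional order for
        array X).  Defaults to the five retained items.
    proportional : dict, sequence of bool, or None
        Which predictors share one coefficient across thresholds.  None
        uses the published structure for known items (True otherwise).
    n_levels : int
        Number of ordinal outcome levels K (4 groups).
    max_iter, gtol : optimisation controls.

    Attributes (after fit)
    ----------------------
    spec_ : PPOMSpec
    params_, se_, z_, p_ : flat arrays over the parameter layout
    intercepts_ : ndarray, one per threshold j=2..K
    coefs_ : dict, predictor -> float (shared) or ndarray (per threshold)
    loglik_ : float; converged_ : bool
    """

    def __init__(
        self,
        predictors=None,
        proportional=None,
        n_levels: int = 4,
        max_iter: int = 500,
        gtol: float = 1e-6,
    ):
        self.predictors = predictors
        self.proportional = proportional
        self.n_levels = n_levels
        self.max_iter = max_iter
        self.gtol = gtol

    # -- construction from frozen coefficients ------------------------------

    @classmethod
    def from_coefficients(
        cls, intercepts, coefs: dict, n_levels: int = 4, provenance: str = "frozen"
    ) -> "PartialProportionalOdds":
        """Build a ready-to-predict model from fixed coefficients.

        ``coefs`` maps predictor name to a scalar (shared coefficient) or a
        length K-1 sequence (per-threshold coefficients).
        """
        predictors = tuple(coefs)
        proportional = tuple(np.isscalar(v) for v in coefs.values())
        model = cls(predictors=predictors, proportional=proportional, n_levels=n_levels)
        spec = PPOMSpec(predictors, proportional, n_levels)
        if len(intercepts) != spec.n_thresholds:
            raise ValueError("need exactly one intercept per threshold")
        theta = list(intercepts)
        for v in coefs.values():
            theta.extend([float(v)] if np.isscalar(v) else [float(u) for u in v])
        model.spec_ = spec
        model.params_ = np.array(theta, float)
        model.intercepts_ = np.array(intercepts, float)
        model.coefs_ = {
            p: (float(v) if np.isscalar(v) else np.asarray(v, float))
            for p, v in coefs.items()
        }
        model.converged_ = True
        model.provenance_ = provenance
        model.classes_ = np.arange(1, n_levels + 1)
        return model

    # -- data plumbing ------------------------------------------------------

    def _resolve_X(self, X) -> np.ndarray:
        if isinstance(X, ItemVector):
            X = X.as_array(self.spec_.predictors)[None, :]
        elif isinstance(X, pd.DataFrame):
            missing = [p for p in self.spec_.predictors if p not in X.columns]
            if missing:
                raise ValueError(f"X lacks predictor column(s) {missing}")
            X = X[list(self.spec_.predictors)].to_numpy(float)
        else:
            X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != len(self.spec_.predictors):
            raise ValueError(
                f"X has {X.shape[1]} columns; model expects "
                f"{len(self.spec_.predictors)} predictors"
            )
        return X

    def _make_spec(self, X) -> PPOMSpec:
        predictors = self.predictors
        if predictors is None:
            predictors = (
                tuple(X.columns) if isinstance(X, pd.DataFrame) else RETAINED_ITEMS
            )
        return PPOMSpec.from_names(predictors, self.proportional, self.n_levels)

    # -- estimation ---------------------------------------------------------

    def fit(self, X, y):
        self.spec_ = self._make_spec(X)
        Xa = self._resolve_X(X)
        y = np.asarray(y, int)
        if len(y) != Xa.shape[0]:
            raise ValueError("X and y lengths differ")
        counts = np.bincount(y, minlength=self.n_levels + 1)[1 : self.n_levels + 1]
        if (counts == 0).any():
            empty = 1 + int(np.argmin(counts))
            raise ValueError(f"group {empty} has no observations")

        t = self.spec_.n_thresholds
        theta0 = np.zeros(self.spec_.n_params())
        n = len(y)
        for j in range(2, self.n_levels + 1):
            share = np.clip((y >= j).mean(), 1.0 / n, 1 - 1.0 / n)
            theta0[j - 2] = np.log(share / (1 - share))

        res = minimize(
            _nll_and_grad,
            theta0,
            args=(Xa, y, self.spec_),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.gtol / 10, "ftol": 1e-14},
        )
        theta, nll = self._newton_polish(res.x, Xa, y)
        _, grad = _nll_and_grad(theta, Xa, y, self.spec_)
        self.params_ = theta
        self.loglik_ = -nll
        self.converged_ = bool(np.max(np.abs(grad)) < self.gtol)
        self.n_obs_ = n
        self.provenance_ = "fitted"
        self.classes_ = np.arange(1, self.n_levels + 1)

        self.intercepts_, B = self.spec_.unpack(self.params_)
        self.coefs_ = {}
        pos = t
        for k, (p, flag) in enumerate(
            zip(self.spec_.predictors, self.spec_.proportional)
        ):
            if flag:
                self.coefs_[p] = float(self.params_[pos])
                pos += 1
            else:
                self.coefs_[p] = self.params_[pos : pos + t].copy()
                pos += t

        self._estimate_se(Xa, y)
        return self

    def _newton_polish(self, theta, Xa, y, max_steps: int = 50):
        """Damped Newton refinement using the observed information.

        L-BFGS gets close but its curvature approximation can stall short of
        the gradient tolerance; a few Newton steps with step-halving drive
        the gradient to machine-level zero in the smooth interior.
        """
        nll, grad = _nll_and_grad(theta, Xa, y, self.spec_)
        for _ in range(max_steps):
            if np.max(np.abs(grad)) < self.gtol / 10:
                break
            H = self._numeric_hessian(theta, Xa, y)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            scale = 1.0
            improved = False
            for _ in range(30):
                cand = theta - scale * step
                cand_nll, cand_grad = _nll_and_grad(cand, Xa, y, self.spec_)
                if cand_nll < nll:
                    theta, nll, grad = cand, cand_nll, cand_grad
                    improved = True
                    break
                scale /= 2
            if not improved:
                break
        return theta, nll

    def _numeric_hessian(self, theta, Xa, y) -> np.ndarray:
        m = len(theta)
        H = np.empty((m, m))
        for i in range(m):
            h = 1e-5 * (1.0 + abs(theta[i]))
            tp = theta.copy()
            tp[i] += h
            _, gp = _nll_and_grad(tp, Xa, y, self.spec_)
            tm = theta.copy()
            tm[i] -= h
            _, gm = _nll_and_grad(tm, Xa, y, self.spec_)
            H[:, i] = (gp - gm) / (2 * h)
        return 0.5 * (H + H.T)

    def _estimate_se(self, Xa, y):
        """Observed-information SEs via central differences of the gradient."""
        H = self._numeric_hessian(self.params_, Xa, y)
        self.hessian_ = H
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            # a numerically singular information matrix (e.g. collinear
            # predictors) may still "invert"; treat it as degenerate
            ok = np.all(diag > 0) and np.linalg.cond(H) < 1e10
        except np.linalg.LinAlgError:
            ok = False
        if not ok:
            cov = np.linalg.pinv(H)
            diag = np.abs(np.diag(cov))
            self.se_flagged_ = True
        else:
            self.se_flagged_ = False
        self.cov_ = cov
        self.se_ = np.sqrt(diag)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.z_ = np.where(self.se_ > 0, self.params_ / self.se_, 0.0)
        self.p_ = 2 * norm.sf(np.abs(self.z_))

    # -- prediction ---------------------------------------------------------

    def linear_predictor(self, X) -> np.ndarray:
        """eta_j = alpha_j + x'beta_j for thresholds j=2..K (n x K-1)."""
        Xa = self._resolve_X(X)
        alpha, B = self.spec_.unpack(self.params_)
        return alpha + Xa @ B

    def cumulative_proba(self, X) -> np.ndarray:
        """P(y >= j | x) for j=2..K as an (n, K-1) array."""
        return expit(self.linear_predictor(X))

    def category_proba(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Category probabilities with clamp-and-renormalise repair.

        Returns (probs n x K, clamped flag per row).  Negative interior
        differences (possible with per-threshold coefficients) are clamped
        to zero and the row renormalised to sum to one.
        """
        cum = self.cumulative_proba(X)
        n, t = cum.shape
        probs = np.empty((n, t + 1))
        probs[:, 0] = 1.0 - cum[:, 0]
        probs[:, 1:t] = cum[:, :-1] - cum[:, 1:]
        probs[:, t] = cum[:, -1]
        clamped = (probs < 0).any(axis=1)
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        return probs, clamped

    def predict_proba(self, X) -> np.ndarray:
        probs, clamped = self.category_proba(X)
        if clamped.any():
            warnings.warn(
                f"{int(clamped.sum())} row(s) had negative interior category "
                "probabilities clamped to zero and renormalised"
            )
        return probs

    def predict(self, X) -> np.ndarray:
        """Most probable group per row; ties resolve to the lower group."""
        probs, _ = self.category_proba(X)
        return probs.argmax(axis=1) + 1  # argmax returns first (lowest) max

    # -- inference ----------------------------------------------------------

    def wald_table(self, include_intercepts: bool = False) -> pd.DataFrame:
        """Per-coefficient Wald table: scope, estimate, SE, z, p.

        Shared coefficients get one row with scope ">=2, >=3, =4"; threshold-
        specific coefficients one row per threshold.  SE=0 rows are flagged.
        """
        if not hasattr(self, "se_"):
            raise ValueError("Wald table requires a fitted model with standard errors")
        if not self.converged_:
            warnings.warn("Wald table from a non-converged fit")
        t = self.spec_.n_thresholds
        K = self.n_levels
        scopes = [f">={j}" for j in range(2, K)] + [f"={K}"]
        rows = []
        pos = 0
        if include_intercepts:
            for j in range(t):
                rows.append(("(intercept)", scopes[j], pos))
                pos += 1
        else:
            pos = t
        for p, flag in zip(self.spec_.predictors, self.spec_.proportional):
            if flag:
                rows.append((p, ", ".join(scopes), pos))
                pos += 1
            else:
                for j in range(t):
                    rows.append((p, scopes[j], pos + j))
                pos += t
        table = pd.DataFrame(
            {
                "predictor": [r[0] for r in rows],
                "scope": [r[1] for r in rows],
                "coefficient": [self.params_[r[2]] for r in rows],
                "se": [self.se_[r[2]] for r in rows],
                "z": [self.z_[r[2]] for r in rows],
                "p": [self.p_[r[2]] for r in rows],
            }
        )
        table["flagged"] = table["se"] <= 0
        return table

    def to_dict(self) -> dict:
        """JSON-serialisable coefficient export with provenance."""
        return {
            "provenance": getattr(self, "provenance_", "unknown"),
            "n_levels": self.n_levels,
            "intercepts": list(map(float, self.intercepts_)),
            "coefficients": {
                p: (v if np.isscalar(v) else list(map(float, v)))
                for p, v in self.coefs_.items()
            },
            "proportional": dict(zip(self.spec_.predictors, map(bool, self.spec_.proportional))),
        }


def published_classifier(coefficient_set: str = "published-rounded") -> PartialProportionalOdds:
    """The frozen classifier of the printed cumulative-probability equations.

    ``"published-rounded"`` (default) uses the equations exactly as printed;
    ``"table-full-precision"`` swaps in the full-precision slope estimates
    (the fitted-model table), paired with the rounded intercepts since no
    full-precision intercepts exist.
    """
    if coefficient_set == "published-rounded":
        coefs = _PUBLISHED_ROUNDED
    elif coefficient_set == "table-full-precision":
        coefs = _TABLE_FULL_PRECISION
    else:
        raise ValueError(
            "coefficient_set must be 'published-rounded' or 'table-full-precision'"
        )
    return PartialProportionalOdds.from_coefficients(
        _PUBLISHED_INTERCEPTS, coefs, n_levels=4, provenance=coefficient_set
    )


# -- module-level operation wrappers ----------------------------------------


def _as_row(model: PartialProportionalOdds, x) -> np.ndarray:
    if isinstance(x, ItemVector):
        return x.as_array(model.spec_.predictors)[None, :]
    return np.atleast_2d(np.asarray(x, float))


def cumulative_probability(model: PartialProportionalOdds, x, j: int) -> float:
    """P(Group >= j | x) for a single respondent, j in 2..K."""
    if not 2 <= j <= model.n_levels:
        raise ValueError(f"threshold j must lie in 2..{model.n_levels}, got {j}")
    return float(model.cumulative_proba(_as_row(model, x))[0, j - 2])


def category_probabilities(model: PartialProportionalOdds, x) -> np.ndarray:
    """Membership probabilities over the K groups for one respondent."""
    probs, _ = model.category_proba(_as_row(model, x))
    return probs[0]


def classify(model: PartialProportionalOdds, x) -> DrinkerGroup:
    """Assign the group with highest membership probability (ties: lower)."""
    return DrinkerGroup(int(model.predict(_as_row(model, x))[0]))


def fit_ppom(
    X, y, predictors=None, proportional=None, n_levels: int = 4, **options
) -> PartialProportionalOdds:
    """Fit a PPOM by maximum likelihood (thin wrapper over the estimator)."""
    return PartialProportionalOdds(
        predictors=predictors, proportional=proportional, n_levels=n_levels, **options
    ).fit(X, y)


def wald_table(model: PartialProportionalOdds, **kwargs) -> pd.DataFrame:
    return model.wald_table(**kwargs)


def select_items(
    X: pd.DataFrame,
    y,
    candidates=None,
    alpha_level: float = 0.05,
    corr_threshold: float = 0.7,
    proportional=None,
    criterion: str = "lrt",
    **fit_options,
):
    """Significance- and collinearity-based predictor selection.

    Fits the full-candidate PPOM and drops predictors not significant at
    ``alpha_level``, then within each block of remaining predictors whose
    pairwise |r| exceeds ``corr_threshold`` keeps only the strongest one.

    ``criterion="lrt"`` (default) judges each predictor by a likelihood-
    ratio test of the full model against the model with that predictor
    removed — robust when the outcome is nearly separable in the items (a
    regime where Wald z collapses toward zero even for decisive predictors,
    the Hauck-Donner effect; derived cluster labels are close to separable
    by construction).  ``criterion="wald"`` uses the per-coefficient Wald
    p values instead.  Block ties are broken by the same criterion's
    statistic (LRT chi-square or max |z|).

    Returns (retained predictor list, audit trail DataFrame).
    """
    if criterion not in ("lrt", "wald"):
        raise ValueError("criterion must be 'lrt' or 'wald'")
    if candidates is None:
        candidates = [c for c in X.columns]
    candidates = list(candidates)
    model = fit_ppom(
        X[candidates], y, predictors=candidates, proportional=proportional, **fit_options
    )
    trail = []
    surviving = []
    best_stat = {}

    if criterion == "lrt":
        from scipy.stats import chi2

        prop_map = (
            proportional
            if isinstance(proportional, dict)
            else dict(zip(candidates, model.spec_.proportional))
        )
        y_arr = np.asarray(y, int)
        counts = np.bincount(y_arr)[1:]
        null_loglik = float((counts * np.log(counts / counts.sum())).sum())
        for p in candidates:
            rest = [c for c in candidates if c != p]
            if rest:
                sub_loglik = fit_ppom(X[rest], y, predictors=rest,
                                      proportional=prop_map, **fit_options).loglik_
            else:
                sub_loglik = null_loglik  # intercept-only multinomial
            df = 1 if dict(zip(model.spec_.predictors,
                               model.spec_.proportional))[p] else model.spec_.n_thresholds
            stat = max(0.0, 2 * (model.loglik_ - sub_loglik))
            pval = float(chi2.sf(stat, df))
            best_stat[p] = stat
            if pval >= alpha_level:
                trail.append((p, "dropped", f"LRT p = {pval:.3g} >= {alpha_level}"))
            else:
                surviving.append(p)
                trail.append((p, "significant", f"LRT p = {pval:.3g}"))
    else:
        table = model.wald_table()
        for p in candidates:
            rows = table[table.predictor == p]
            min_p = float(rows.p.min())
            best_stat[p] = float(rows.z.abs().max())
            if min_p >= alpha_level:
                trail.append((p, "dropped",
                              f"all coefficients p >= {alpha_level} (min p={min_p:.3g})"))
            else:
                surviving.append(p)
                trail.append((p, "significant", f"min p = {min_p:.3g}"))

    # collinearity blocks among survivors (connected components of |r| graph)
    corr = X[candidates].corr().abs()
    retained = list(surviving)
    parent = {p: p for p in surviving}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(surviving):
        for b in surviving[i + 1 :]:
            if corr.loc[a, b] > corr_threshold:
                parent[find(a)] = find(b)
    blocks: dict[str, list[str]] = {}
    for p in surviving:
        blocks.setdefault(find(p), []).append(p)
    for members in blocks.values():
        if len(members) > 1:
            keep = max(members, key=lambda p: best_stat[p])
            for p in members:
                if p != keep:
                    retained.remove(p)
                    trail.append(
                        (p, "dropped", f"correlated block (|r|>{corr_threshold}); "
                         f"kept {keep} (stronger {criterion})")
                    )

    if not retained:
        raise ValueError(
            "all candidate items dropped; audit trail: "
            + "; ".join(f"{p}: {r}" for p, _, r in trail)
        )
    retained = [p for p in candidates if p in retained]
    trail_df = pd.DataFrame(trail, columns=["item", "action", "reason"])
    return retained, trail_df
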