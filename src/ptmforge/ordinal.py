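"""Ordinal regression over methylation states (me0 < me1 < me2 < me3).

Strain effects on a four-state methylation distribution are modeled by a
cumulative-logit proportional-odds regression,

    P(Y <= j | strain s) = logistic(theta_j - beta_s),   j = 0, 1, 2,

with the reference strain fixed at beta = 0, so exp(beta_s) is the common
odds ratio of strain s shifting mass toward higher methylation states.
The proportional-odds assumption (a single beta across all three category
boundaries) can be relaxed by the adjacent-category model

    log(P(Y = j+1) / P(Y = j) | s) = alpha_j + gamma_{j,s},

whose per-boundary slopes make it the saturated between-strain model; a
likelihood-ratio test between the two quantifies how much the data resist
the proportional-odds constraint.

Replicate-level state fractions are modeled as weighted multinomials with
a declared effective count per replicate (default 1000), making the
precision assumption explicit; a raw-counts mode is available when true
spectral counts exist.

Both fits are Newton maximizations with step-halving; convergence demands
an infinity-norm score below 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STATES",
    "ConvergenceError",
    "SeparationError",
    "OrdinalFit",
    "AdjacentCategoryFit",
    "aggregate_counts",
    "fit_proportional_odds",
    "fit_adjacent_category",
    "lr_test",
    "significance_label",
]

STATES = ("me0", "me1", "me2", "me3")
_J = len(STATES)


class ConvergenceError(RuntimeError):
    """Newton iterations failed to reach the score tolerance."""


class SeparationError(RuntimeError):
    """A strain's distribution is degenerate; the MLE diverges."""


def aggregate_counts(
    data: pd.DataFrame,
    mode: str = "proportions",
    effective_n: float = 1000.0,
) -> pd.DataFrame:
    """Collapse a (strain, replicate, me0..me3) table to per-strain weights.

    ``mode="proportions"``: each replicate's row is normalized and scaled
    to ``effective_n`` pseudo-observations. ``mode="counts"``: rows are
    used as-is.
    """
    for col in ("strain", *STATES):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    vals = data[list(STATES)].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("state counts must be non-negative")
    if mode == "proportions":
        totals = vals.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("replicate with all-zero states cannot be normalized")
        vals = vals / totals * effective_n
    elif mode != "counts":
        raise ValueError(f"unknown mode {mode!r}")
    agg = pd.DataFrame(vals, columns=list(STATES))
    agg["strain"] = data["strain"].to_numpy()
    return agg.groupby("strain", sort=True)[list(STATES)].sum()


def _signature(weights: pd.DataFrame) -> tuple:
    return tuple(
        (str(s), *(round(float(v), 6) for v in row))
        for s, row in zip(weights.index, weights.to_numpy())
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class OrdinalFit:
    """A fitted proportional-odds model."""

    cutpoints: np.ndarray  # (3,), strictly increasing
    coefficients: dict  # strain -> beta (reference == 0.0)
    reference: str
    log_likelihood: float
    cov: np.ndarray  # covariance of free params [theta0..2, beta_nonref...]
    std_errors: dict  # strain -> se(beta)
    p_values: dict  # strain -> two-sided Wald p
    n_params: int
    converged: bool
    data_signature: tuple
    model: str = "proportional_odds"

    def odds_ratio(self, strain: str) -> float:
        return float(np.exp(self.coefficients[strain]))

    def odds_ratio_ci(self, strain: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        b, se = self.coefficients[strain], self.std_errors[strain]
        return float(np.exp(b - z * se)), float(np.exp(b + z * se))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for s, b in self.coefficients.items():
            if s == self.reference:
                continue
            lo, hi = self.odds_ratio_ci(s)
            rows.append(
                {
                    "strain": s,
                    "beta": b,
                    "odds_ratio": self.odds_ratio(s),
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": self.p_values[s],
                    "label": significance_label(self.p_values[s]),
                }
            )
        return pd.DataFrame(rows)


def _po_cell_probs(theta: np.ndarray, beta: float) -> np.ndarray:
    cum = _sigmoid(theta - beta)
    p = np.empty(_J)
    p[0] = cum[0]
    p[1] = cum[1] - cum[0]
    p[2] = cum[2] - cum[1]
    p[3] = 1.0 - cum[2]
    return p


def _po_ll_grad(params: np.ndarray, W: np.ndarray, strain_beta_idx: np.ndarray):
    """Log-likelihood and analytic score of the proportional-odds model.

    ``W`` is (n_strains, 4) weights; ``strain_beta_idx[s]`` is the index
    of strain s's beta within params (or -1 for the reference).
    """
    theta = params[:3]
    ll = 0.0
    grad = np.zeros_like(params)
    tiny = 1e-12
    for s in range(W.shape[0]):
        bidx = strain_beta_idx[s]
        beta = params[3 + bidx] if bidx >= 0 else 0.0
        eta = theta - beta
        F = _sigmoid(eta)
        f = F * (1.0 - F)
        p = _po_cell_probs(theta, beta)
        w = W[s]
        ll += float(np.dot(w, np.log(np.maximum(p, tiny))))
        # d ll / d eta_j = f_j (w_j/p_j - w_{j+1}/p_{j+1})
        r = w / np.maximum(p, tiny)
        g_eta = f * (r[:3] - r[1:])
        grad[:3] += g_eta
        if bidx >= 0:
            grad[3 + bidx] -= g_eta.sum()
    return ll, grad


def _numeric_hessian(grad_fn, params: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = params.size
    H = np.zeros((k, k))
    for i in range(k):
        up, dn = params.copy(), params.copy()
        up[i] += h
        dn[i] -= h
        H[:, i] = (grad_fn(up) - grad_fn(dn)) / (2 * h)
    return (H + H.T) / 2


def _newton(ll_grad, params, valid, tol=1e-6, max_iter=100):
    """Maximize by Newton steps with step-halving; returns (params, ll, H, ok)."""
    ll, grad = ll_grad(params)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            H = _numeric_hessian(lambda p: ll_grad(p)[1], params)
            return params, ll, H, True
        H = _numeric_hessian(lambda p: ll_grad(p)[1], params)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = grad / max(np.max(np.abs(grad)), 1.0)
        scale = 1.0
        for _ in range(40):
            trial = params + scale * step
            if valid(trial):
                tll, tgrad = ll_grad(trial)
                if np.isfinite(tll) and tll >= ll - 1e-12:
                    params, ll, grad = trial, tll, tgrad
                    break
            scale /= 2
        else:
            break
    H = _numeric_hessian(lambda p: ll_grad(p)[1], params)
    return params, ll, H, bool(np.max(np.abs(grad)) < tol)


def fit_proportional_odds(
    data: pd.DataFrame,
    reference: str,
    mode: str = "proportions",
    effective_n: float = 1000.0,
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit of strain effects.

    Raises :class:`SeparationError` when a strain's estimate diverges
    (complete separation) and :class:`ConvergenceError` when Newton
    iterations stall short of the 1e-6 score tolerance.
    """
    W_df = aggregate_counts(data, mode=mode, effective_n=effective_n)
    if reference not in W_df.index:
        raise ValueError(f"reference strain {reference!r} not in data")
    if W_df.to_numpy().sum() <= 0:
        raise ValueError("no observations")
    strains = list(W_df.index)
    W = W_df.to_numpy(dtype=float)
    if np.any(W.sum(axis=1) == 0):
        empty = [s for s, t in zip(strains, W.sum(axis=1)) if t == 0]
        raise ValueError(f"empty strain(s): {empty}")

    nonref = [s for s in strains if s != reference]
    beta_idx = np.array(
        [nonref.index(s) if s != reference else -1 for s in strains]
    )

    # Start at pooled empirical cumulative logits, beta = 0.
    pooled = W.sum(axis=0)
    cum = np.clip(np.cumsum(pooled)[:3] / pooled.sum(), 1e-4, 1 - 1e-4)
    params0 = np.concatenate([np.log(cum / (1 - cum)), np.zeros(len(nonref))])
    if not np.all(np.diff(params0[:3]) > 0):
        params0[:3] = np.array([-1.0, 0.0, 1.0])

    def valid(p):
        return bool(np.all(np.diff(p[:3]) > 0) and np.all(np.isfinite(p)))

    ll_grad = lambda p: _po_ll_grad(p, W, beta_idx)
    params, ll, H, ok = _newton(ll_grad, params0, valid)

    betas = params[3:]
    if np.any(np.abs(betas) > 20):
        raise SeparationError(
            "strain effect diverged (|beta| > 20); a strain's distribution is "
            "degenerate relative to the reference"
        )
    if not ok:
        raise ConvergenceError("proportional-odds Newton iterations did not converge")

    cov = np.linalg.inv(-H)
    se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    coefficients = {reference: 0.0}
    std_errors = {reference: 0.0}
    p_values = {reference: 1.0}
    for k, s in enumerate(nonref):
        b, se = float(betas[k]), float(se_all[3 + k])
        coefficients[s] = b
        std_errors[s] = se
        z = b / se if se > 0 else np.inf * np.sign(b)
        p_values[s] = float(2 * stats.norm.sf(abs(z)))
    return OrdinalFit(
        cutpoints=params[:3].copy(),
        coefficients={s: coefficients[s] for s in strains},
        reference=reference,
        log_likelihood=float(ll),
        cov=cov,
        std_errors=std_errors,
        p_values=p_values,
        n_params=params.size,
        converged=ok,
        data_signature=_signature(W_df),
    )


# ---------------------------------------------------------------------------
# Adjacent-category model


@dataclass(frozen=True)
class AdjacentCategoryFit:
    """Adjacent-category logit fit with per-boundary strain slopes."""

    alphas: np.ndarray  # (3,) boundary intercepts
    slopes: dict  # strain -> (3,) per-boundary effects (reference == 0)
    reference: str
    log_likelihood: float
    n_params: int
    converged: bool
    data_signature: tuple
    model: str = "adjacent_category"


def _ac_ll_grad(params: np.ndarray, W: np.ndarray, strain_slope_idx: np.ndarray):
    """Log-likelihood/score of the adjacent-category multinomial logit."""
    alphas = params[:3]
    ll = 0.0
    grad = np.zeros_like(params)
    for s in range(W.shape[0]):
        gidx = strain_slope_idx[s]
        gam = params[3 + 3 * gidx : 6 + 3 * gidx] if gidx >= 0 else np.zeros(3)
        u = np.concatenate([[0.0], np.cumsum(alphas + gam)])
        u -= u.max()
        p = np.exp(u)
        p /= p.sum()
        w = W[s]
        Wtot = w.sum()
        ll += float(np.dot(w, np.log(np.maximum(p, 1e-300))))
        # d u_j / d (alpha_l) = 1[j >= l+1]
        tail_w = np.cumsum(w[::-1])[::-1]  # sum_{j>=l} w_j
        tail_p = np.cumsum(p[::-1])[::-1]
        g = tail_w[1:] - Wtot * tail_p[1:]
        grad[:3] += g
        if gidx >= 0:
            grad[3 + 3 * gidx : 6 + 3 * gidx] += g
    return ll, grad


def fit_adjacent_category(
    data: pd.DataFrame,
    reference: str,
    mode: str = "proportions",
    effective_n: float = 1000.0,
) -> AdjacentCategoryFit:
    """ML fit of the adjacent-category model (no proportional-odds constraint)."""
    W_df = aggregate_counts(data, mode=mode, effective_n=effective_n)
    if reference not in W_df.index:
        raise ValueError(f"reference strain {reference!r} not in data")
    strains = list(W_df.index)
    W = W_df.to_numpy(dtype=float)
    if np.any(W.sum(axis=1) == 0):
        raise ValueError("empty strain present")
    nonref = [s for s in strains if s != reference]
    slope_idx = np.array([nonref.index(s) if s != reference else -1 for s in strains])

    params0 = np.zeros(3 + 3 * len(nonref))
    ll_grad = lambda p: _ac_ll_grad(p, W, slope_idx)
    valid = lambda p: bool(np.all(np.isfinite(p)))
    params, ll, H, ok = _newton(ll_grad, params0, valid)
    if np.any(np.abs(params) > 25):
        raise SeparationError("adjacent-category estimate diverged (zero cell)")
    if not ok:
        raise ConvergenceError("adjacent-category Newton iterations did not converge")

    slopes = {reference: np.zeros(3)}
    for k, s in enumerate(nonref):
        slopes[s] = params[3 + 3 * k : 6 + 3 * k].copy()
    return AdjacentCategoryFit(
        alphas=params[:3].copy(),
        slopes={s: slopes[s] for s in strains},
        reference=reference,
        log_likelihood=float(ll),
        n_params=params.size,
        converged=ok,
        data_signature=_signature(W_df),
    )


def lr_test(fit_null, fit_alt) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested fits on the same data.

    Returns (statistic, df, p). The null must be the smaller model and
    both fits must come from identical aggregated data.
    """
    if fit_null.data_signature != fit_alt.data_signature:
        raise ValueError("fits were computed on different data")
    df = fit_alt.n_params - fit_null.n_params
    if df < 0:
        raise ValueError("alternative model has fewer parameters than the null")
    stat = 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood)
    if stat < -1e-6:
        raise ValueError(
            "alternative log-likelihood below null: models are not nested"
        )
    stat = max(stat, 0.0)
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def significance_label(p: float, threshold: float = 0.01) -> str:
    """Figure-style annotation: '**' for p below the 0.01 threshold."""
    return "**" if p < threshold else ""
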