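"""Cox proportional-hazards fitting and Martingale / deviance residuals.

The survival tests in this package never put microbiome terms into the
hazard: the Cox model ``lambda(t | X) = lambda_0(t) exp(beta' X)`` is fit
once on the covariates alone, and its residuals become the tested regressor.
The Martingale residual ``M_i = Delta_i - Lambda_0(U_i) exp(beta' X_i)``
measures excess events relative to the fitted model; at the partial
likelihood maximizer (with the Breslow baseline) it satisfies the score
identities ``sum_i M_i = 0`` and ``sum_i M_i X_i = 0``, which is what makes
it usable as an outcome-free carrier of survival signal.

The deviance residual symmetrizes the skewed Martingale residual:

    D_i = sign(M_i) * sqrt(-2 * (M_i + Delta_i * log(Delta_i - M_i)))

Ties are handled by Breslow's method by default (Efron available); simulated
continuous event times are tie-free, where the two coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Covariates, SurvivalOutcome

__all__ = ["CoxFit", "ResidualSet", "fit_cox", "martingale_residuals",
           "deviance_residuals", "residual_set"]


class SeparationWarning(UserWarning):
    """Monotone partial likelihood: a covariate perfectly orders the events."""


@dataclass
class CoxFit:
    coefficients: np.ndarray          # (p,)
    baseline_times: np.ndarray        # unique event times, ascending
    baseline_cumhaz: np.ndarray       # cumulative hazard at those times
    linear_predictors: np.ndarray     # (n,) beta' X_i
    converged: bool
    separation: bool
    n_iter: int
    ties: str

    def cumhaz_at(self, times: np.ndarray) -> np.ndarray:
        """Step-function evaluation of the baseline cumulative hazard."""
        idx = np.searchsorted(self.baseline_times, np.asarray(times), side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz])
        return padded[idx]


@dataclass
class ResidualSet:
    martingale: np.ndarray
    deviance: np.ndarray


def fit_cox(outcome: SurvivalOutcome, X: Covariates | None = None, *,
            ties: str = "breslow", tol: float = 1e-9,
            max_iter: int = 100) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton's method.

    With ``p = 0`` (no covariates) this reduces to the Nelson-Aalen style
    baseline cumulative hazard. Monotone likelihood (separation) is detected
    by runaway coefficients and reported as a :class:`SeparationWarning` with
    the fit flagged, not an exception.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    t = outcome.time
    d = outcome.event
    n = t.shape[0]
    Xm = X.X if X is not None else np.empty((n, 0))
    p = Xm.shape[1]

    order = np.argsort(t, kind="stable")
    t_s, d_s = t[order], d[order]
    X_s = Xm[order]
    # tied groups: slices of equal time containing at least one event
    uniq_times, first_idx = np.unique(t_s, return_index=True)
    bounds = np.append(first_idx, n)

    beta = np.zeros(p)
    separation = False
    converged = p == 0
    n_iter = 0

    tie_free = len(uniq_times) == n
    ev_idx = np.where(d_s == 1)[0]

    def loglik_score_hess(beta):
        eta = X_s @ beta
        eta = eta - eta.max() if p else eta  # guard overflow; shift cancels per event
        w = np.exp(eta)
        S0_all = np.cumsum(w[::-1])[::-1]
        if tie_free:  # Breslow == Efron; fully vectorized
            S1_all = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]
            S2_all = np.cumsum((w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]))[::-1],
                               axis=0)[::-1]
            S0e = S0_all[ev_idx]
            S1e = S1_all[ev_idx]
            ratio = S1e / S0e[:, None]
            ll = eta[ev_idx].sum() - np.log(S0e).sum()
            score = X_s[ev_idx].sum(axis=0) - ratio.sum(axis=0)
            hess = -(S2_all[ev_idx] / S0e[:, None, None]
                     - ratio[:, :, None] * ratio[:, None, :]).sum(axis=0)
            return ll, score, hess
        S1_all = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]
        S2_all = np.cumsum((w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]))[::-1],
                           axis=0)[::-1]
        ll = 0.0
        score = np.zeros(p)
        hess = np.zeros((p, p))
        for k in range(len(uniq_times)):
            a, b = bounds[k], bounds[k + 1]
            ev = a + np.where(d_s[a:b] == 1)[0]
            m = len(ev)
            if m == 0:
                continue
            S0, S1, S2 = S0_all[a], S1_all[a], S2_all[a]
            ll += eta[ev].sum()
            score += X_s[ev].sum(axis=0)
            if ties == "breslow" or m == 1:
                ll -= m * np.log(S0)
                score -= m * S1 / S0
                hess -= m * (S2 / S0 - np.outer(S1, S1) / S0 ** 2)
            else:  # efron
                wD = w[ev].sum()
                S1D = (w[ev, None] * X_s[ev]).sum(axis=0)
                S2D = (w[ev, None, None] * X_s[ev, :, None] * X_s[ev, None, :]).sum(axis=0)
                for l in range(m):
                    f = l / m
                    s0 = S0 - f * wD
                    s1 = S1 - f * S1D
                    s2 = S2 - f * S2D
                    ll -= np.log(s0)
                    score -= s1 / s0
                    hess -= s2 / s0 - np.outer(s1, s1) / s0 ** 2
        return ll, score, hess

    if p:
        ll, score, hess = loglik_score_hess(beta)
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(-hess, score)
            except np.linalg.LinAlgError:
                separation = True
                break
            # step-halving line search
            new_beta = beta + step
            new_ll, new_score, new_hess = loglik_score_hess(new_beta)
            halvings = 0
            while new_ll < ll - 1e-12 and halvings < 20:
                step /= 2.0
                new_beta = beta + step
                new_ll, new_score, new_hess = loglik_score_hess(new_beta)
                halvings += 1
            beta, ll, score, hess = new_beta, new_ll, new_score, new_hess
            if np.linalg.norm(score) < tol:
                converged = True
                break
            if np.abs(beta).max() > 30:
                separation = True
                break
        # monotone likelihood: the score also vanishes as |beta| -> inf, so
        # Newton can "converge" at a large coefficient; flag that too
        if converged and np.abs(beta).max() > 10:
            separation = True
        if separation or not converged:
            if separation:
                warnings.warn("monotone partial likelihood (separation); "
                              "coefficients diverge", SeparationWarning)
            else:
                warnings.warn("Cox Newton iterations did not converge",
                              SeparationWarning)

    eta_full = Xm @ beta
    w_full = np.exp(eta_full)
    w_sorted = w_full[order]
    S0_all = np.cumsum(w_sorted[::-1])[::-1]

    # Breslow / Efron baseline cumulative hazard increments at event times
    if tie_free:
        return CoxFit(
            coefficients=beta,
            baseline_times=t_s[ev_idx],
            baseline_cumhaz=np.cumsum(1.0 / S0_all[ev_idx]),
            linear_predictors=eta_full,
            converged=converged,
            separation=separation,
            n_iter=n_iter,
            ties=ties,
        )
    bt, bh = [], []
    cum = 0.0
    for k in range(len(uniq_times)):
        a, b = bounds[k], bounds[k + 1]
        ev = a + np.where(d_s[a:b] == 1)[0]
        m = len(ev)
        if m == 0:
            continue
        if ties == "breslow" or m == 1:
            cum += m / S0_all[a]
        else:
            wD = w_sorted[ev].sum()
            cum += sum(1.0 / (S0_all[a] - (l / m) * wD) for l in range(m))
        bt.append(uniq_times[k])
        bh.append(cum)

    return CoxFit(
        coefficients=beta,
        baseline_times=np.asarray(bt),
        baseline_cumhaz=np.asarray(bh),
        linear_predictors=eta_full,
        converged=converged,
        separation=separation,
        n_iter=n_iter,
        ties=ties,
    )


def martingale_residuals(fit: CoxFit, outcome: SurvivalOutcome) -> np.ndarray:
    """M_i = Delta_i - Lambda_0(U_i) * exp(beta' X_i)."""
    return outcome.event - fit.cumhaz_at(outcome.time) * np.exp(fit.linear_predictors)


def deviance_residuals(M: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Signed square-root symmetrization of the Martingale residuals."""
    M = np.asarray(M, dtype=float)
    event = np.asarray(event)
    bad = (event == 1) & (event - M <= 0)
    bad |= (event == 0) & (M > 0)
    if bad.any():
        raise ValueError(
            f"deviance residual undefined for samples {np.where(bad)[0].tolist()}: "
            "log argument non-positive")
    inner = M.copy()
    ev = event == 1
    inner[ev] += np.log(1.0 - M[ev])  # Delta=1: log(Delta - M) = log(1 - M)
    # Delta=0 contributes no log term; M=0 gives D=0 exactly
    return np.sign(M) * np.sqrt(np.maximum(-2.0 * inner, 0.0))


def residual_set(outcome: SurvivalOutcome, X: Covariates | None = None, *,
                 ties: str = "breslow") -> tuple[CoxFit, ResidualSet]:
    """Fit the Cox model once and return both residual types."""
    fit = fit_cox(outcome, X, ties=ties)
    M = martingale_residuals(fit, outcome)
    D = deviance_residuals(M, outcome.event)
    return fit, ResidualSet(martingale=M, deviance=D)
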