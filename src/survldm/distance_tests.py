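"""Distance- and kernel-based global tests of microbiome-survival association.

Three families, all permutation-calibrated on a shared plan:

* ``permanova_fl_test`` — PERMANOVA pseudo-F with the covariates X and a Cox
  residual as explanatory variables.  The residual regressor is permuted,
  re-orthogonalized against X and re-normalized each permutation (the same
  Freedman-Lane-style scheme as the LDM tests); this inclusion of X in the
  permutation model is what gives the test its power advantage over the
  score-type tests when X confounds.
* ``mirkat_s_test`` — the kernel variance-component score statistic
  ``Q = M' K M`` on the Martingale residuals, with nulls obtained by
  permuting M directly, *without* re-adjustment.  This mirrors the published
  survival kernel test and is deliberately conservative when X is associated
  with the microbiome.
* ``mirkat_adjusted_test`` — the same score statistic computed on the
  X-adjusted (and normalized) residual, re-adjusting within permutations;
  with no covariates it reduces exactly to ``mirkat_s_test``.

With the linear kernel ``K = Z Z'`` (Gower-centered Euclidean distances of
centered Z) and no covariates, Q equals the LDM's unnormalized global
statistic ``sum_j (sum_i M_i Z_ij)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import (CombinedResult, PermStat, PermutationPlan, adjust,
                        adjust_rows, minp_combine, orthonormal_basis,
                        rank_pvalue)
from .io import Covariates
from .transforms import DistanceMatrix, KernelMatrix, gower_center

__all__ = ["PseudoFResult", "ScoreTestResult", "permanova_fl_test",
           "mirkat_score", "mirkat_s_test", "mirkat_adjusted_test",
           "dist_combined_omnibus"]


@dataclass
class PseudoFResult:
    F: float
    p: float
    metric: str
    residual: str
    B: int
    seed: int
    global_stat: PermStat = field(repr=False)


@dataclass
class ScoreTestResult:
    Q: float
    p: float
    kernel: str
    adjusted: bool
    residual: str
    B: int
    seed: int
    global_stat: PermStat = field(repr=False)


def _quad_forms(R: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Rowwise r' G r for a (B, n) matrix of regressors."""
    return ((R @ G) * R).sum(axis=1)


def permanova_fl_test(D: DistanceMatrix, X: Covariates | None, r: np.ndarray,
                      plan: PermutationPlan, *,
                      residual: str = "martingale") -> PseudoFResult:
    """PERMANOVA pseudo-F for a Cox-residual regressor, covariate-adjusted.

    With G the Gower-centered squared-distance kernel, H the projection onto
    span(basis(X), r~), the statistic is

        F = (r~' G r~) / ((tr G - tr HGH) / (n - p - 2)).
    """
    G = gower_center(D).K
    n = G.shape[0]
    if plan.n != n:
        raise ValueError("permutation plan size does not match the distances")
    basis = orthonormal_basis(X.X) if X is not None and X.p else np.empty((n, 0))
    p = basis.shape[1]
    df = n - p - 2
    if df <= 0:
        raise ValueError(f"residual degrees of freedom {df} <= 0")
    r = np.asarray(r, dtype=float)
    r = r - r.mean()
    r_t = adjust(r, basis, normalize=True)
    # tr(HGH) = tr(GH) for idempotent H = BB' + r~ r~'
    T0 = np.trace(G) - (np.einsum("ij,ik,jk->", G, basis, basis)
                        if p else 0.0)
    q_obs = float(r_t @ G @ r_t)
    F_obs = q_obs / (max(T0 - q_obs, 1e-300) / df)

    R_t = adjust_rows(r[plan.permutations], basis, normalize=True)
    q_null = _quad_forms(R_t, G)
    F_null = q_null / (np.maximum(T0 - q_null, 1e-300) / df)
    pval = rank_pvalue(F_obs, F_null)
    return PseudoFResult(F=F_obs, p=pval, metric=D.metric, residual=residual,
                         B=plan.B, seed=plan.seed,
                         global_stat=PermStat(f"permanovafl:{residual}:{D.metric}",
                                              F_obs, F_null))


def mirkat_score(K: KernelMatrix | np.ndarray, r: np.ndarray) -> float:
    """Variance-component score statistic Q = r' K r."""
    Km = K.K if isinstance(K, KernelMatrix) else np.asarray(K)
    r = np.asarray(r, dtype=float)
    return float(r @ Km @ r)


def mirkat_s_test(K: KernelMatrix, M: np.ndarray, plan: PermutationPlan, *,
                  kernel: str = "kernel") -> ScoreTestResult:
    """Survival kernel score test on the raw Martingale residuals.

    Nulls permute M without re-orthogonalizing against the covariates (they
    were only removed inside the Cox fit); under microbiome-confounder
    association this makes the test conservative.
    """
    Km = K.K
    if plan.n != Km.shape[0]:
        raise ValueError("permutation plan size does not match the kernel")
    M = np.asarray(M, dtype=float)
    Q = mirkat_score(K, M)
    Q_null = _quad_forms(M[plan.permutations], Km)
    p = rank_pvalue(Q, Q_null)
    return ScoreTestResult(Q=Q, p=p, kernel=kernel, adjusted=False,
                           residual="martingale", B=plan.B, seed=plan.seed,
                           global_stat=PermStat(f"mirkats:{kernel}", Q, Q_null))


def mirkat_adjusted_test(K: KernelMatrix, X: Covariates | None, r: np.ndarray,
                         plan: PermutationPlan, *, residual: str = "martingale",
                         kernel: str = "kernel") -> ScoreTestResult:
    """Kernel score test on the X-adjusted, normalized residual.

    Permutations re-adjust against X exactly as in ``permanova_fl_test``;
    with no covariates this reduces to ``mirkat_s_test``.
    """
    Km = K.K
    n = Km.shape[0]
    if plan.n != n:
        raise ValueError("permutation plan size does not match the kernel")
    basis = orthonormal_basis(X.X) if X is not None and X.p else np.empty((n, 0))
    r = np.asarray(r, dtype=float)
    r = r - r.mean()
    r_t = adjust(r, basis, normalize=True)
    Q = mirkat_score(Km, r_t)
    R_t = adjust_rows(r[plan.permutations], basis, normalize=True)
    Q_null = _quad_forms(R_t, Km)
    p = rank_pvalue(Q, Q_null)
    return ScoreTestResult(Q=Q, p=p, kernel=kernel, adjusted=True,
                           residual=residual, B=plan.B, seed=plan.seed,
                           global_stat=PermStat(f"mirkat-adj:{residual}:{kernel}",
                                                Q, Q_null))


def dist_combined_omnibus(results: list, ) -> CombinedResult:
    """Min-p combination across residual types and/or distances."""
    if not results:
        raise ValueError("nothing to combine")
    key = {(res.B, res.seed) for res in results}
    if len(key) != 1:
        raise ValueError("component tests were not run on the same "
                         "permutation plan")
    return minp_combine([res.global_stat for res in results])
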