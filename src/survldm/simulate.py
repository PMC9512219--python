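"""Synthetic microbiome + censored-survival data generator.

The design emulates a confounded association study:

* A binary group variable ``X`` (half the subjects each) shifts the
  composition: baseline frequencies ``pi_1`` (sorted decreasing, so taxon 1
  is the most abundant) and a confounded copy ``pi_2`` in which the
  frequencies of a randomly chosen set of taxa are permuted among
  themselves; subject frequencies are the mixture
  ``pi~(X_i) = (1 - b_XZ X_i) pi_1 + b_XZ X_i pi_2``.
* Counts are Dirichlet-multinomial with overdispersion ``theta``
  (concentration ``(1-theta)/theta``) and library sizes drawn from
  N(10000, (10000/3)^2), redrawn while below 1000, then rounded.
* A causal score ``S_i`` drives the event time: under model M1,
  ``S_i = sum_{j in A} d_j Z_ij / Zbar_j`` on observed frequencies of the 10
  most abundant taxa; under M2, ``S_i = sum_{j in A} d_j 1{Z_ij > 0}`` for
  10 taxa drawn from abundance ranks 11-100.  Directions ``d_j = +/-1`` are
  fixed across replicates of an experiment.
* Event times follow either a Cox model with Weibull W(2, 0.01) baseline,
  ``T_i = 10 B_i^{-1/2} (-log V_i)^{1/2}`` with
  ``B_i = exp(b_XS scale(X_i) + b scale(S_i))``, or an accelerated-hazards
  model with lognormal baseline,
  ``T_i = B_i^{-1} exp(Phi^{-1}[1 - exp(B_i log V_i)])``, which violates
  proportional hazards (crossing survival curves).  Censoring is
  Exp(mu); mu = 0.03 / 0.08 / 0.2 gives roughly 25% / 50% / 75% censoring
  under the Weibull model, mu = 0.5 roughly 50% under the AH model.

Experiment-level randomness (confounded set, causal set, directions, the
permutation of ``pi_2``) derives from the experiment seed and is fixed
across replicates; counts and survival draws use the replicate seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io import CountTable, Covariates, SurvivalOutcome

__all__ = ["SimConfig", "SimTruth", "SimReplicate", "make_baseline",
           "make_confounded_pair", "subject_frequencies", "draw_counts",
           "causal_score", "draw_survival", "simulate_replicate", "SimDesign"]


@dataclass
class SimConfig:
    n: int = 100
    J: int = 856
    gamma: float = 1.0               # power-law exponent of synthetic baseline
    baseline_file: str | None = None
    n_confounded: int = 100
    beta_XZ: float = 0.8
    theta: float = 0.02              # DM overdispersion
    lib_mean: float = 10000.0
    lib_sd: float = 10000.0 / 3.0
    lib_min: float = 1000.0
    model: str = "M1"                # M1 | M2 | custom (explicit causal_taxa)
    n_causal: int = 10
    causal_taxa: list[int] | None = None   # explicit 0-based ranks, optional
    score_scale: str | None = None   # abundance | presence; default per model
    beta: float = 0.0                # causal effect on the hazard
    beta_XS: float = 0.5             # group effect on the hazard
    hazard: str = "cox-weibull"      # cox-weibull | ah-lognormal
    censor_rate: float = 0.08        # Exp(mu) rate; 0 = no censoring
    seed: int = 0                    # experiment-level seed

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta_XZ <= 1.0:
            raise ValueError("beta_XZ must be in [0, 1]")
        if self.theta < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.censor_rate < 0:
            raise ValueError("censoring rate must be >= 0")
        if self.n % 2:
            raise ValueError("n must be even (half the subjects per group)")
        if self.hazard not in ("cox-weibull", "ah-lognormal"):
            raise ValueError(f"unknown hazard model {self.hazard!r}")
        if self.model not in ("M1", "M2", "custom"):
            raise ValueError(f"unknown causal model {self.model!r}")
        if self.model == "custom" and not self.causal_taxa:
            raise ValueError("custom model requires explicit causal_taxa")


@dataclass
class SimTruth:
    confounded: np.ndarray     # taxon indices associated with X
    causal: np.ndarray         # causal set A (column indices)
    delta: np.ndarray          # directions, +/-1 per causal taxon
    S: np.ndarray              # per-subject causal score
    T: np.ndarray              # latent event times
    C: np.ndarray              # latent censoring times


@dataclass
class SimReplicate:
    table: CountTable
    X: np.ndarray              # binary group, n/2 each
    outcome: SurvivalOutcome
    truth: SimTruth
    censored_fraction: float

    def covariates(self) -> Covariates:
        return Covariates(self.X[:, None].astype(float), ["X"]).center()


def make_baseline(config: SimConfig) -> np.ndarray:
    """Baseline frequencies pi_1: file-supplied or power-law j^(-gamma)."""
    if config.baseline_file is not None:
        freqs = np.loadtxt(config.baseline_file, dtype=float).ravel()
        if (freqs <= 0).any():
            raise ValueError("baseline frequencies must be positive")
    else:
        if config.gamma <= 0:
            raise ValueError("power-law exponent must be positive")
        freqs = np.arange(1, config.J + 1, dtype=float) ** (-config.gamma)
    freqs = np.sort(freqs)[::-1]
    return freqs / freqs.sum()


def make_confounded_pair(pi1: np.ndarray, n_confounded: int,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """pi_2: permute pi_1's frequencies within a random taxon set.

    Returns the confounded copy and the selected indices; the multiset of
    frequencies is conserved and taxa outside the set are untouched.
    """
    J = pi1.shape[0]
    if n_confounded > J:
        raise ValueError("n_confounded exceeds the number of taxa")
    idx = rng.choice(J, size=n_confounded, replace=False)
    pi2 = pi1.copy()
    pi2[idx] = pi1[rng.permutation(idx)]
    return pi2, np.sort(idx)


def subject_frequencies(pi1: np.ndarray, pi2: np.ndarray, beta_XZ: float,
                        X: np.ndarray) -> np.ndarray:
    """pi~(X_i) = (1 - b_XZ X_i) pi_1 + b_XZ X_i pi_2, per subject."""
    X = np.asarray(X, dtype=float)[:, None]
    return (1.0 - beta_XZ * X) * pi1[None, :] + beta_XZ * X * pi2[None, :]


def _draw_library_sizes(n: int, config: SimConfig,
                        rng: np.random.Generator) -> np.ndarray:
    L = rng.normal(config.lib_mean, config.lib_sd, size=n)
    while (bad := L < config.lib_min).any():  # left-truncation by redraw
        L[bad] = rng.normal(config.lib_mean, config.lib_sd, size=bad.sum())
    return np.rint(L).astype(np.int64)


def draw_counts(P: np.ndarray, theta: float, config: SimConfig,
                rng: np.random.Generator) -> CountTable:
    """Dirichlet-multinomial counts with mean P and overdispersion theta."""
    n, J = P.shape
    L = _draw_library_sizes(n, config, rng)
    counts = np.empty((n, J), dtype=np.int64)
    if theta == 0:
        for i in range(n):
            counts[i] = rng.multinomial(L[i], P[i])
    else:
        conc = P * ((1.0 - theta) / theta)
        g = rng.gamma(np.maximum(conc, 1e-12))
        g_sum = g.sum(axis=1, keepdims=True)
        comp = g / np.where(g_sum > 0, g_sum, 1.0)
        for i in range(n):
            counts[i] = rng.multinomial(L[i], comp[i])
    return CountTable(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        taxon_ids=[f"taxon{j + 1}" for j in range(J)],
        counts=counts,
    )


def causal_score(table: CountTable, model: str, A: np.ndarray,
                 delta: np.ndarray) -> np.ndarray:
    """S_i = sum_{j in A} d_j Z_ij / Zbar_j (M1) or d_j 1{Z_ij > 0} (M2)."""
    Z = table.counts / table.library_sizes[:, None]
    ZA = Z[:, A]
    if model == "M2":
        return ((ZA > 0) * delta[None, :]).sum(axis=1).astype(float)
    Zbar = ZA.mean(axis=0)
    ok = Zbar > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} causal taxa absent from every subject; "
                      "skipped in the score")
    ratio = np.zeros_like(ZA)
    ratio[:, ok] = ZA[:, ok] / Zbar[ok]
    return (ratio * delta[None, :]).sum(axis=1)


def _scale(v: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1 (ddof=1); constant input maps to zeros."""
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("constant input to scale(); term set to zero")
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def draw_survival(S: np.ndarray, X: np.ndarray, beta: float, beta_XS: float,
                  hazard: str, mu: float, rng: np.random.Generator
                  ) -> tuple[SurvivalOutcome, np.ndarray, np.ndarray]:
    """Event/censoring times from the chosen hazard model.

    Returns the observed outcome plus the latent (T, C).
    """
    n = S.shape[0]
    B = np.exp(beta_XS * _scale(X) + beta * _scale(S))
    V = rng.uniform(size=n)
    if hazard == "cox-weibull":
        # Weibull W(2, 0.01) baseline: Lambda_0(t) = 0.01 t^2
        T = 10.0 * B ** (-0.5) * (-np.log(V)) ** 0.5
    elif hazard == "ah-lognormal":
        inner = np.clip(1.0 - np.exp(B * np.log(V)), 1e-300, 1 - 1e-16)
        T = (1.0 / B) * np.exp(norm.ppf(inner))
    else:
        raise ValueError(f"unknown hazard model {hazard!r}")
    if mu < 0:
        raise ValueError("censoring rate must be >= 0")
    C = rng.exponential(1.0 / mu, size=n) if mu > 0 else np.full(n, np.inf)
    U = np.minimum(T, C)
    event = (T <= C).astype(np.int64)
    return SurvivalOutcome(U, event), T, C


@dataclass
class SimDesign:
    """Experiment-level quantities, fixed across replicates."""

    config: SimConfig
    pi1: np.ndarray = field(init=False)
    pi2: np.ndarray = field(init=False)
    confounded: np.ndarray = field(init=False)
    causal: np.ndarray = field(init=False)
    delta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.pi1 = make_baseline(cfg)
        self.pi2, self.confounded = make_confounded_pair(
            self.pi1, cfg.n_confounded, rng)
        if cfg.model == "M1":
            self.causal = np.arange(cfg.n_causal)  # most abundant taxa
        elif cfg.model == "M2":
            if cfg.J < 100:
                raise ValueError("model M2 draws causal taxa from ranks 11-100")
            self.causal = np.sort(rng.choice(np.arange(10, 100),
                                             size=cfg.n_causal, replace=False))
        else:
            self.causal = np.asarray(cfg.causal_taxa, dtype=np.intp)
        self.delta = rng.choice([-1.0, 1.0], size=self.causal.shape[0])


def simulate_replicate(config: SimConfig | SimDesign,
                       replicate_seed: int) -> SimReplicate:
    """One synthetic dataset; same (config, seeds) reproduce it exactly."""
    design = config if isinstance(config, SimDesign) else SimDesign(config)
    cfg = design.config
    rng = np.random.default_rng([cfg.seed, int(replicate_seed)])
    X = np.repeat([0, 1], cfg.n // 2)
    P = subject_frequencies(design.pi1, design.pi2, cfg.beta_XZ, X)
    table = draw_counts(P, cfg.theta, cfg, rng)
    if cfg.score_scale is not None:
        score_model = "M2" if cfg.score_scale == "presence" else "M1"
    else:
        score_model = "M2" if cfg.model == "M2" else "M1"
    S = causal_score(table, score_model, design.causal, design.delta)
    outcome, T, C = draw_survival(S, X, cfg.beta, cfg.beta_XS, cfg.hazard,
                                  cfg.censor_rate, rng)
    truth = SimTruth(confounded=design.confounded, causal=design.causal,
                     delta=design.delta, S=S, T=T, C=C)
    return SimReplicate(table=table, X=X, outcome=outcome, truth=truth,
                        censored_fraction=float(1.0 - outcome.event.mean()))
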