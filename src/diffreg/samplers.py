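"""Metropolis-within-Gibbs updates for the hierarchical splice-usage model.

The model, per group of samples: reads of sample i distribute over features
following a multinomial with per-sample relative abundances rho_i (Dirichlet
prior, hence conjugate Dirichlet posterior given the latent totals Y); within
feature t the split of reads over splice statuses follows a hierarchical
beta-binomial (bulk: S/U) or Dirichlet-multinomial (single-cell: S/U/A) with
per-sample proportions pi_i(t) ~ Beta/Dirichlet(delta(t)).  The observed data
are equivalence-class counts; the latent per-feature, per-status counts X are
sampled by multinomial allocation of each EC's reads across its members.

One sweep updates, in order, delta | pi (adaptive random-walk Metropolis on
log delta), pi | X, delta (conjugate), rho | X (conjugate) and X | Z, pi, rho
(multinomial allocation, run only every ``thin_latent`` iterations — the
undersampling scheme).  All stochastic steps draw from one seeded generator
in a fixed order, so a fit is exactly reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .ec_data import (
    BULK,
    ECDataset,
    EquivalenceClass,
    LatentCounts,
)
from .hyperprior import HyperPrior

PI_EPS = 1e-12  # interior clamp for proportion draws before log-density evaluation
ADAPT_START = 200  # iterations of fixed-kernel warm-up before covariance adaptation
INITIAL_STEP_SD = 0.5  # sqrt(0.25): fixed diagonal proposal sd during warm-up
ADAPT_JITTER = 0.01  # diagonal added to the adapted proposal covariance


@dataclass
class ModelParams:
    """Current parameter state: rho (N, F), pi (N, F, K), delta (F, K).

    ``pi_bar = delta / delta_plus`` and ``delta_plus = sum_k delta_k`` are
    pure functions of delta.
    """

    rho: np.ndarray
    pi: np.ndarray
    delta: np.ndarray

    @property
    def delta_plus(self) -> np.ndarray:
        return self.delta.sum(axis=1)

    @property
    def pi_bar(self) -> np.ndarray:
        return self.delta / self.delta_plus[:, None]

    def validate(self) -> None:
        if np.any(self.delta <= 0):
            raise ValueError("delta components must be positive")
        for arr in (self.rho, self.pi):
            if np.any(arr <= 0) or np.any(arr >= 1):
                raise ValueError("proportions must be strictly inside the simplex")


@dataclass
class MHState:
    """Adaptive random-walk state for the per-feature delta updates.

    Tracks the running mean and covariance of the log-delta chain history
    (Haario-style adaptation), the shared adaptation count and per-feature
    acceptance counts.
    """

    z: np.ndarray  # (F, K) current log delta
    t: int = 0
    mean: np.ndarray | None = None
    m2: np.ndarray | None = None  # (F, K, K) scatter
    n_accept: np.ndarray | None = None
    last_log_target: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_feat, k = self.z.shape
        if self.mean is None:
            self.mean = np.zeros((n_feat, k))
        if self.m2 is None:
            self.m2 = np.zeros((n_feat, k, k))
        if self.n_accept is None:
            self.n_accept = np.zeros(n_feat, dtype=int)

    def acceptance_rate(self) -> np.ndarray:
        return self.n_accept / max(self.t, 1)

    def _record(self, z: np.ndarray) -> None:
        """Welford update of the chain-history mean/scatter with the new state."""
        self.t += 1
        d = z - self.mean
        self.mean += d / self.t
        self.m2 += d[:, :, None] * (z - self.mean)[:, None, :]

    def proposal_chol(self) -> np.ndarray | None:
        """Cholesky factors of the adapted proposal covariance, or None in warm-up."""
        if self.t < ADAPT_START:
            return None
        k = self.z.shape[1]
        cov = self.m2 / max(self.t - 1, 1)
        prop = (2.38**2 / k) * cov + ADAPT_JITTER * np.eye(k)
        return np.linalg.cholesky(prop)


def delta_log_target(z: np.ndarray, log_pi_sum: np.ndarray, n_samples: int, prior: HyperPrior) -> np.ndarray:
    """Per-feature log p(delta | pi) up to a constant, in z = log delta.

    The likelihood term is the Beta/Dirichlet log-density of the per-sample
    proportions summed over samples (``log_pi_sum[f, k] = sum_i log pi_ik(f)``).
    The prior puts a flat Dirichlet on pi_bar and Normal(mu, sd) on
    log delta_plus; expressed as a density in z this contributes
    ``logN(log D; mu, sd) - K log D + sum_k z_k`` with D = sum_k exp(z_k).
    """
    z = np.clip(z, -40.0, 40.0)
    a = np.exp(z)
    a_plus = a.sum(axis=1)
    lik = n_samples * (gammaln(a_plus) - gammaln(a).sum(axis=1)) + ((a - 1.0) * log_pi_sum).sum(axis=1)
    log_d = np.log(a_plus)
    k = z.shape[1]
    prior_term = (
        -0.5 * ((log_d - prior.mu_log_prec) / prior.sd_log_prec) ** 2
        - np.log(prior.sd_log_prec)
        - 0.5 * np.log(2.0 * np.pi)
        - k * log_d
        + z.sum(axis=1)
    )
    return lik + prior_term


def update_delta(
    pi: np.ndarray,
    prior: HyperPrior,
    state: MHState,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """One adaptive Metropolis step on log delta for every feature.

    Proposals are z' = z + eps with eps ~ Normal(0, Sigma_prop); Sigma_prop
    is 0.25 I during warm-up and (2.38^2/K) Cov(history) + 0.01 I afterwards.
    Returns the new delta array and the summed per-feature log p(delta | pi)
    after the step (the trace used for stationarity testing).
    """
    n_feat, k = state.z.shape
    log_pi = np.log(np.clip(pi, PI_EPS, 1.0))
    log_pi_sum = log_pi.sum(axis=0)  # (F, K)
    lt_cur = delta_log_target(state.z, log_pi_sum, pi.shape[0], prior)
    if not np.all(np.isfinite(lt_cur)):
        bad = np.flatnonzero(~np.isfinite(lt_cur))
        raise FloatingPointError(
            f"non-finite delta log-target at current state for features {bad[:5]}; "
            "an interior violation occurred upstream"
        )
    chol = state.proposal_chol()
    noise = rng.standard_normal((n_feat, k))
    if chol is None:
        eps = INITIAL_STEP_SD * noise
    else:
        eps = np.einsum("fij,fj->fi", chol, noise)
    z_new = state.z + eps
    lt_new = delta_log_target(z_new, log_pi_sum, pi.shape[0], prior)
    lt_new = np.where(np.isfinite(lt_new), lt_new, -np.inf)
    accept = np.log(rng.uniform(size=n_feat)) < (lt_new - lt_cur)
    state.z[accept] = z_new[accept]
    state.n_accept += accept
    state._record(state.z.copy())
    lt_post = np.where(accept, lt_new, lt_cur)
    state.last_log_target = lt_post
    return np.exp(state.z), float(lt_post.sum())


def update_pi(x: LatentCounts, delta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Conjugate draw of per-sample splice proportions.

    Bulk: pi_S ~ Beta(delta_S + X_S, delta_U + X_U); single-cell:
    pi ~ Dirichlet(delta + X).  Draws are clamped strictly inside the
    simplex (1e-12) before later log-density evaluations.
    """
    alpha = delta[None, :, :] + x.x  # (N, F, K)
    k = alpha.shape[2]
    if k == 2:
        p = rng.beta(alpha[:, :, 0], alpha[:, :, 1])
        pi = np.stack([p, 1.0 - p], axis=2)
    else:
        g = rng.standard_gamma(alpha)
        pi = g / g.sum(axis=2, keepdims=True)
    pi = np.clip(pi, PI_EPS, 1.0 - PI_EPS)
    return pi / pi.sum(axis=2, keepdims=True)


def update_rho(x: LatentCounts, alpha0: float, rng: np.random.Generator) -> np.ndarray:
    """Conjugate Dirichlet draw of the per-sample feature abundances.

    rho_i ~ Dirichlet(alpha0 + Y_i); alpha0 > 0 keeps the posterior proper
    even for zero-count features.
    """
    g = rng.standard_gamma(alpha0 + x.y)  # (N, F)
    rho = g / g.sum(axis=1, keepdims=True)
    return np.clip(rho, PI_EPS, 1.0)


# ---------------------------------------------------------------------------
# Latent allocation
# ---------------------------------------------------------------------------

@dataclass
class CompiledSample:
    """One sample's ECs in array form for vectorized multinomial allocation.

    Single-member classes allocate deterministically and are frozen into
    ``base_x``; multi-member classes are stored padded to the maximum
    member-set size.
    """

    base_x: np.ndarray  # (F, K) deterministic singleton contributions
    counts: np.ndarray  # (E,) multi-member class counts
    mem_feat: np.ndarray  # (E, Mmax)
    mem_stat: np.ndarray  # (E, Mmax)
    valid: np.ndarray  # (E, Mmax) member mask
    total: int
    n_features: int
    n_stat: int

    @classmethod
    def from_dataset(cls, dataset: ECDataset, sample: int) -> "CompiledSample":
        n_feat = len(dataset.feature_index)
        n_stat = dataset.feature_index.n_statuses
        base = np.zeros((n_feat, n_stat), dtype=np.int64)
        multi: list[EquivalenceClass] = []
        for ec in dataset.classes[sample]:
            if len(ec.members) == 1:
                f, s = ec.members[0]
                base[f, int(s)] += ec.count
            else:
                multi.append(ec)
        m_max = max((len(ec.members) for ec in multi), default=1)
        n_ec = len(multi)
        mem_feat = np.zeros((n_ec, m_max), dtype=np.int64)
        mem_stat = np.zeros((n_ec, m_max), dtype=np.int64)
        valid = np.zeros((n_ec, m_max), dtype=bool)
        counts = np.zeros(n_ec, dtype=np.int64)
        for e, ec in enumerate(multi):
            counts[e] = ec.count
            for m, (f, s) in enumerate(ec.members):
                mem_feat[e, m], mem_stat[e, m], valid[e, m] = f, int(s), True
        return cls(
            base_x=base,
            counts=counts,
            mem_feat=mem_feat,
            mem_stat=mem_stat,
            valid=valid,
            total=dataset.total_count(sample),
            n_features=n_feat,
            n_stat=n_stat,
        )

    def equal_split_x(self) -> np.ndarray:
        """Deterministic integer initialization: equal split with largest-remainder rounding."""
        x = self.base_x.copy()
        for e in range(len(self.counts)):
            members = [
                (self.mem_feat[e, m], self.mem_stat[e, m])
                for m in range(self.mem_feat.shape[1])
                if self.valid[e, m]
            ]
            n, m_count = int(self.counts[e]), len(members)
            share, rem = divmod(n, m_count)
            for j, (f, s) in enumerate(members):
                x[f, s] += share + (1 if j < rem else 0)
        return x


def allocation_weights(
    compiled: CompiledSample,
    rho_i: np.ndarray,
    pi_i: np.ndarray,
    eff_len: np.ndarray | None,
) -> np.ndarray:
    """Unnormalized member weights for each multi-member EC.

    A read compatible with member (t, k) is allocated with weight
    rho_i(t) * pi_ik(t), divided by the effective length l_k(t) in bulk
    mode (length normalization keeps allocation independent of transcript
    length); no length division in single-cell mode.
    """
    w = rho_i[compiled.mem_feat] * pi_i[compiled.mem_feat, compiled.mem_stat]
    if eff_len is not None:
        w = w / eff_len[compiled.mem_feat, compiled.mem_stat]
    w = np.where(compiled.valid, w, 0.0)
    return w


def update_latent(
    compiled: CompiledSample,
    rho_i: np.ndarray,
    pi_i: np.ndarray,
    eff_len: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial re-allocation of every multi-member EC for one sample.

    Vectorized across ECs via sequential conditional binomials over member
    slots.  Returns the sample's full (F, K) latent count matrix (singleton
    contributions included); the grand total always equals the sample's EC
    total.
    """
    x = compiled.base_x.copy()
    if len(compiled.counts) == 0:
        return x
    w = allocation_weights(compiled, rho_i, pi_i, eff_len)
    w_total = w.sum(axis=1)
    if np.any(w_total <= 0):
        raise FloatingPointError(
            "equivalence class with all-zero allocation weights "
            "(impossible for interior parameters)"
        )
    m_max = w.shape[1]
    remaining_w = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
    n_rem = compiled.counts.copy()
    alloc = np.zeros_like(compiled.mem_feat)
    for j in range(m_max - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(remaining_w[:, j] > 0, w[:, j] / remaining_w[:, j], 0.0)
        draw = rng.binomial(n_rem, np.clip(p, 0.0, 1.0))
        alloc[:, j] = draw
        n_rem = n_rem - draw
    alloc[:, m_max - 1] = n_rem
    flat = (compiled.mem_feat * compiled.n_stat + compiled.mem_stat).ravel()
    add = np.bincount(flat, weights=alloc.ravel(), minlength=compiled.n_features * compiled.n_stat)
    return x + add.astype(np.int64).reshape(compiled.n_features, compiled.n_stat)


# ---------------------------------------------------------------------------
# Full sweep
# ---------------------------------------------------------------------------

@dataclass
class ChainState:
    """Mutable state threaded through the Gibbs sweeps of one group fit."""

    compiled: list[CompiledSample]
    x: LatentCounts
    params: ModelParams
    mh: MHState
    prior: HyperPrior
    eff_len: np.ndarray | None  # (F, 2) bulk effective lengths, None in single-cell
    alpha0: float = 1.0
    delta_substeps: int = 5
    latent_update_iters: list[int] = field(default_factory=list)


def gibbs_sweep(
    state: ChainState,
    iteration: int,
    rng: np.random.Generator,
    thin_latent: int = 10,
) -> float:
    """One Metropolis-within-Gibbs sweep: delta | pi, pi | X, delta, rho | X, X | Z, pi, rho.

    ``iteration`` is 1-based; the latent allocation runs only when
    ``iteration % thin_latent == 0`` (undersampling), X is held fixed
    otherwise.  The Metropolis sub-kernel for delta — the only non-Gibbs
    update — is iterated ``delta_substeps`` times per sweep, which costs
    little and markedly improves mixing for weakly identified features.
    Returns the summed marginal log-posterior of delta given pi, recorded
    for convergence testing.
    """
    for _ in range(max(state.delta_substeps, 1)):
        delta, log_post = update_delta(state.params.pi, state.prior, state.mh, rng)
    state.params.delta = delta
    state.params.pi = update_pi(state.x, delta, rng)
    state.params.rho = update_rho(state.x, state.alpha0, rng)
    if thin_latent <= 1 or iteration % thin_latent == 0:
        new_x = np.empty_like(state.x.x)
        for i, compiled in enumerate(state.compiled):
            new_x[i] = update_latent(
                compiled, state.params.rho[i], state.params.pi[i], state.eff_len, rng
            )
        state.x = LatentCounts(new_x)
        state.latent_update_iters.append(iteration)
    return log_post
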