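"""Per-group model fitting for bulk and single-cell data.

Each group of samples is fitted independently: latent counts are
initialized by deterministic equal-split allocation, proportions by
empirical (interior-clamped) frequencies and the hyper-parameters by a
method-of-moments fit; the Metropolis-within-Gibbs sampler then runs under
the convergence protocol.  Seeds for every (cluster, group) fit are derived
from the master seed and the fitted sample set, so results are bit
reproducible and invariant to group relabeling.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .convergence import ChainDiagnostics, run_until_converged
from .ec_data import (
    BULK,
    GROUP_LABELS,
    SINGLE_CELL,
    ECDataset,
    InputError,
    LatentCounts,
    collapse_intragene_ambiguity,
)
from .hyperprior import HyperPrior, estimate_hyperprior, mom_precision
from .samplers import (
    ChainState,
    CompiledSample,
    MHState,
    ModelParams,
    PI_EPS,
    gibbs_sweep,
)

logger = logging.getLogger("diffreg")


@dataclass
class Settings:
    """MCMC and filtering settings for a full analysis.

    Defaults follow the method's standard protocol: 2000 iterations with a
    500-iteration burn-in, latent states refreshed every 10 iterations, a
    uniform Dirichlet prior (alpha0 = 1) on the per-sample feature
    abundances, and one convergence-triggered rerun with doubled length.
    """

    n_iter: int = 2000
    burn_in: int = 500
    thin_latent: int = 10
    alpha0: float = 1.0
    seed: int = 1
    max_reruns: int = 1
    hw_alpha: float = 0.05
    min_count: int = 10
    n_prior_features: int = 1000
    unspliced_suffix: str = "-U"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GroupPosterior:
    """Kept MCMC draws for one (cluster, group) fit.

    Arrays have the kept iteration as leading axis: delta (M, F, K),
    pi (M, N, F, K), rho (M, N, F); pi_bar and delta_plus are derived from
    delta.  ``log_trace`` is the full log p(delta | pi) trace of the final
    chain (pre-burn-in included) for traceplots.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    mode: str
    cluster_id: str | None
    delta: np.ndarray
    pi: np.ndarray
    rho: np.ndarray
    log_trace: np.ndarray
    diagnostics: ChainDiagnostics

    @property
    def delta_plus(self) -> np.ndarray:
        return self.delta.sum(axis=2)

    @property
    def pi_bar(self) -> np.ndarray:
        return self.delta / self.delta_plus[:, :, None]

    @property
    def n_kept(self) -> int:
        return self.delta.shape[0]


def _derived_seed(master_seed: int, cluster_id: str | None, sample_ids: list[str]) -> np.random.SeedSequence:
    """Stable per-fit seed from master seed, cluster and the fitted sample set.

    Hashing the sorted sample ids (rather than the group label) makes a fit
    depend only on which samples it contains, so swapping the A/B labels
    swaps the fitted roles exactly.
    """
    c_hash = zlib.crc32((cluster_id or "").encode()) & 0x7FFFFFFF
    s_hash = zlib.crc32("|".join(sorted(sample_ids)).encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([int(master_seed), c_hash, s_hash])


def _initial_state(data: ECDataset, prior: HyperPrior, alpha0: float) -> ChainState:
    compiled = [CompiledSample.from_dataset(data, i) for i in range(data.n_samples)]
    x = LatentCounts(np.stack([c.equal_split_x() for c in compiled]))
    n, f, k = x.x.shape
    # empirical proportions, interior-clamped
    totals = x.y
    with np.errstate(invalid="ignore", divide="ignore"):
        pi0 = np.where(totals[:, :, None] > 0, x.x / np.maximum(totals, 1)[:, :, None], 1.0 / k)
    pi0 = np.clip(pi0, 1e-6, 1.0 - 1e-6)
    pi0 /= pi0.sum(axis=2, keepdims=True)
    rho0 = (alpha0 + totals) / (alpha0 + totals).sum(axis=1, keepdims=True)
    # method-of-moments delta per feature, fallback to ones
    delta0 = np.ones((f, k))
    for t in range(f):
        d_plus = mom_precision(x.x[:, t, :].astype(float))
        if np.isfinite(d_plus) and d_plus > 0:
            pooled = x.x[:, t, :].sum(axis=0).astype(float)
            if pooled.sum() > 0:
                pbar = np.clip(pooled / pooled.sum(), 1e-3, 1.0 - 1e-3)
                pbar /= pbar.sum()
                delta0[t] = np.clip(d_plus, 0.5, 1e4) * pbar
    eff_len = data.feature_index.eff_len_matrix() if data.mode == BULK else None
    params = ModelParams(rho=rho0, pi=pi0, delta=delta0)
    mh = MHState(z=np.log(delta0))
    return ChainState(
        compiled=compiled, x=x, params=params, mh=mh, prior=prior,
        eff_len=eff_len, alpha0=alpha0,
    )


def _run_chain(
    data: ECDataset,
    prior: HyperPrior,
    settings: Settings,
    n_iter: int,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    state = _initial_state(data, prior, settings.alpha0)
    n, f, k = state.x.x.shape
    draws = {
        "delta": np.empty((n_iter, f, k)),
        "pi": np.empty((n_iter, n, f, k)),
        "rho": np.empty((n_iter, n, f)),
    }
    trace = np.empty(n_iter)
    for it in range(1, n_iter + 1):
        trace[it - 1] = gibbs_sweep(state, it, rng, thin_latent=settings.thin_latent)
        draws["delta"][it - 1] = state.params.delta
        draws["pi"][it - 1] = state.params.pi
        draws["rho"][it - 1] = state.params.rho
    return draws, trace


def fit_group(
    data: ECDataset,
    prior: HyperPrior,
    settings: Settings,
    seed_seq: np.random.SeedSequence | None = None,
) -> GroupPosterior:
    """Fit the hierarchical model to one group of samples (one cluster)."""
    if data.n_samples == 0:
        raise InputError("cannot fit an empty group")
    if data.mode == SINGLE_CELL:
        data = collapse_intragene_ambiguity(data)
    else:
        data.feature_index.eff_len_matrix()  # validate lengths early
    if seed_seq is None:
        seed_seq = _derived_seed(settings.seed, data.cluster_id, data.sample_ids)
    streams = seed_seq.spawn(settings.max_reruns + 1)

    def closure(n_iter: int, attempt: int):
        rng = np.random.default_rng(streams[attempt])
        return _run_chain(data, prior, settings, n_iter, rng)

    kept, trace, diag = run_until_converged(
        closure,
        n_iter=settings.n_iter,
        burn_in=settings.burn_in,
        max_reruns=settings.max_reruns,
        alpha=settings.hw_alpha,
    )
    return GroupPosterior(
        feature_ids=list(data.feature_index.ids),
        sample_ids=list(data.sample_ids),
        mode=data.mode,
        cluster_id=data.cluster_id,
        delta=kept["delta"],
        pi=kept["pi"],
        rho=kept["rho"],
        log_trace=trace,
        diagnostics=diag,
    )


def fit_group_bulk(data: ECDataset, prior: HyperPrior, settings: Settings) -> GroupPosterior:
    if data.mode != BULK:
        raise InputError("fit_group_bulk expects bulk data")
    return fit_group(data, prior, settings)


def fit_group_sc(data: ECDataset, prior: HyperPrior, settings: Settings) -> GroupPosterior:
    if data.mode != SINGLE_CELL:
        raise InputError("fit_group_sc expects single-cell data")
    return fit_group(data, prior, settings)


def fit_all(
    data: ECDataset | list[ECDataset],
    settings: Settings,
    prior: HyperPrior | None = None,
) -> dict[tuple[str | None, str], GroupPosterior]:
    """Independent fits for every (cluster, group), keyed by (cluster_id, group).

    ``data`` is a single (possibly bulk) dataset or a list of per-cluster
    single-cell datasets with group labels assigned.  A shared prior may be
    supplied; otherwise one is estimated per cluster from the pooled groups.
    Clusters missing a group are skipped with a warning.
    """
    datasets = [data] if isinstance(data, ECDataset) else list(data)
    posteriors: dict[tuple[str | None, str], GroupPosterior] = {}
    for ds in datasets:
        missing = [g for g in GROUP_LABELS if not ds.samples_in_group(g)]
        if missing:
            logger.warning(
                "cluster %r skipped: no samples in group %s", ds.cluster_id, missing
            )
            continue
        cluster_prior = prior or estimate_hyperprior(
            ds, n_features=settings.n_prior_features, seed=settings.seed
        )
        for group in GROUP_LABELS:
            sub = ds.subset_samples(ds.samples_in_group(group))
            logger.info(
                "fitting cluster=%r group=%s (%d samples, %d features)",
                ds.cluster_id, group, sub.n_samples, len(sub.feature_index),
            )
            posteriors[(ds.cluster_id, group)] = fit_group(sub, cluster_prior, settings)
    return posteriors
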