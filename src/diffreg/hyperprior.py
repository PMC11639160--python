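"""Empirical-Bayes prior for the hierarchical precision parameters.

Each feature's per-sample splice proportions follow a beta (bulk) or
Dirichlet (single-cell) law with hyper-parameters delta; the precision
delta_plus = sum_k delta_k governs sample-to-sample variability.  An
informative prior for delta_plus is estimated once, from a random subset of
features pooled across both groups, by a method-of-moments beta-binomial /
Dirichlet-multinomial fit on equal-split provisional counts.  The prior
family is log delta_plus ~ Normal(mu, sd) with a uniform Dirichlet prior on
the group-level mean proportions pi_bar, so the prior is informative about
variability but flat about the quantity being tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .ec_data import ECDataset, equal_split_status_counts

logger = logging.getLogger("diffreg")

SD_FLOOR = 0.3
FALLBACK_MU = float(np.log(10.0))
FALLBACK_SD = 1.0


@dataclass(frozen=True)
class HyperPrior:
    """log delta_plus ~ Normal(mu_log_prec, sd_log_prec); pi_bar ~ flat Dirichlet."""

    mu_log_prec: float
    sd_log_prec: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_log_prec):
            raise ValueError("mu_log_prec must be finite")
        if self.sd_log_prec < SD_FLOOR:
            object.__setattr__(self, "sd_log_prec", SD_FLOOR)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HyperPrior":
        return cls(float(d["mu_log_prec"]), float(d["sd_log_prec"]))


def mom_precision(counts: np.ndarray) -> float:
    """Method-of-moments precision (delta_plus) for one feature.

    ``counts`` is an (n_samples, K) array of (possibly fractional) status
    counts.  Moment matching of the beta-binomial / Dirichlet-multinomial
    proportion variance, Var(p_ik) = pbar_k (1-pbar_k) (1+(n-1) rho)/n with
    rho = 1/(delta_plus+1), gives a per-component intraclass correlation
    estimate; components are averaged.  Returns NaN when the fit is invalid
    (fewer than two informative samples, zero overdispersion, rho outside
    (0, 1)).
    """
    counts = np.asarray(counts, dtype=float)
    n_i = counts.sum(axis=1)
    use = n_i > 0
    if use.sum() < 2:
        return np.nan
    counts, n_i = counts[use], n_i[use]
    p = counts / n_i[:, None]
    pbar = counts.sum(axis=0) / n_i.sum()
    nbar = n_i.mean()
    rhos = []
    for k in range(counts.shape[1]):
        if not 0.0 < pbar[k] < 1.0:
            continue
        s2 = p[:, k].var(ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (nbar * s2 / (pbar[k] * (1.0 - pbar[k])) - 1.0) / (nbar - 1.0)
        if np.isfinite(rho):
            rhos.append(rho)
    if not rhos:
        return np.nan
    rho = float(np.mean(rhos))
    if not 0.0 < rho < 1.0:
        return np.nan
    return 1.0 / rho - 1.0


def estimate_hyperprior(
    data: ECDataset,
    n_features: int = 1000,
    seed: int = 0,
) -> HyperPrior:
    """Estimate the log-precision prior from a random feature subset.

    Selects ``min(n_features, F)`` features uniformly at random, fits a
    method-of-moments precision per feature on equal-split provisional
    counts from all samples (both groups pooled — the prior cannot leak
    differential signal), and returns the mean/sd of the finite log
    precisions, with the sd floored at 0.3.  Falls back to a documented
    weak default (mu = log 10, sd = 1) when fewer than two features yield a
    valid fit.
    """
    if data.n_samples < 2:
        raise ValueError("hyperprior estimation needs at least 2 samples")
    x = equal_split_status_counts(data)  # (N, F, K)
    n_total = x.shape[1]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_total, size=min(n_features, n_total), replace=False)
    log_prec = []
    for f in chosen:
        d_plus = mom_precision(x[:, f, :])
        if np.isfinite(d_plus) and d_plus > 0:
            log_prec.append(np.log(d_plus))
    if len(log_prec) < 2:
        logger.warning(
            "hyperprior: only %d features with a valid moment fit; using the fallback "
            "prior Normal(log 10, 1)", len(log_prec)
        )
        return HyperPrior(FALLBACK_MU, FALLBACK_SD)
    log_prec = np.asarray(log_prec)
    return HyperPrior(float(log_prec.mean()), float(log_prec.std(ddof=1)))
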