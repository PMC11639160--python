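"""Two-group comparison of the relative unspliced abundance.

The comparison statistic is pi_tilde_U: the group-level unspliced fraction
pi_bar_U in bulk data, and pi_bar_U + 0.5 * pi_bar_A in single-cell data
(half of the ambiguous mass assigned to each splice version).  Two rankings
are produced per feature: the posterior probability p = Pr(B pi_tilde_U >
A pi_tilde_U), ranked by max(p, 1-p), and a Wald test on the bivariate
normal approximation of the (pi_bar_S, pi_bar_U) posterior.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ec_data import BULK, GROUP_LABELS, SINGLE_CELL
from .model_fit import GroupPosterior

logger = logging.getLogger("diffreg")

RESULT_COLUMNS = [
    "cluster_id",
    "feature_id",
    "pi_tilde_U_A",
    "pi_tilde_U_B",
    "prob_B_up",
    "rank_score",
    "wald_stat",
    "wald_df",
    "wald_pvalue",
]


def pi_tilde_u(pi_bar_draws: np.ndarray, mode: str) -> np.ndarray:
    """Per-draw pi_tilde_U from pi_bar draws (..., K).

    Bulk: pi_tilde_U = pi_bar_U; single-cell: pi_bar_U + 0.5 * pi_bar_A.
    """
    if mode == BULK:
        return pi_bar_draws[..., 1]
    if mode == SINGLE_CELL:
        return pi_bar_draws[..., 1] + 0.5 * pi_bar_draws[..., 2]
    raise ValueError(f"unknown mode {mode!r}")


def prob_up(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Posterior probability that group B's pi_tilde_U exceeds group A's.

    Draws are paired by iteration index after truncation to the common
    length; ties count half, so prob_up(A, B) + prob_up(B, A) = 1 exactly.
    """
    series_a, series_b = np.asarray(series_a), np.asarray(series_b)
    m = min(len(series_a), len(series_b))
    if m == 0:
        raise ValueError("empty posterior series")
    a, b = series_a[:m], series_b[:m]
    return float(((b > a).sum() + 0.5 * (b == a).sum()) / m)


def wald_test(draws_a: np.ndarray, draws_b: np.ndarray, mode: str) -> tuple[float, int, float]:
    """Wald test on the normal approximation of the pi_bar posterior.

    Single-cell: the kept (pi_bar_S, pi_bar_U) draws of each group are
    summarized by their mean vector and sample covariance (pi_bar_A is
    omitted as it is uniquely defined by the other two); the statistic is
    W = d' (S_A + S_B)^{-1} d with d the mean difference, referred to a
    chi-square with df = 2 (df reduced to the numerical rank when the
    pooled covariance is singular, via pseudo-inverse).  Bulk: univariate
    on pi_bar_U, df = 1.
    """
    draws_a, draws_b = np.asarray(draws_a), np.asarray(draws_b)
    if min(len(draws_a), len(draws_b)) < 10:
        raise ValueError("Wald test needs at least 10 kept draws per group")
    if mode == BULK:
        a = draws_a[..., 1] if draws_a.ndim > 1 else draws_a
        b = draws_b[..., 1] if draws_b.ndim > 1 else draws_b
        d = a.mean() - b.mean()
        v = a.var(ddof=1) + b.var(ddof=1)
        if v <= 0:
            return (0.0, 1, 1.0) if d == 0 else (np.inf, 1, 0.0)
        stat = float(d * d / v)
        return stat, 1, float(stats.chi2.sf(stat, 1))
    su_a, su_b = draws_a[:, :2], draws_b[:, :2]
    d = su_a.mean(axis=0) - su_b.mean(axis=0)
    pooled = np.cov(su_a, rowvar=False) + np.cov(su_b, rowvar=False)
    # draws are proportions, so an absolute eigenvalue floor is meaningful
    evals, evecs = np.linalg.eigh(pooled)
    keep = evals > 1e-12
    rank = int(keep.sum())
    if rank == 0:
        return (0.0, 2, 1.0) if np.allclose(d, 0) else (np.inf, 2, 0.0)
    proj = evecs[:, keep].T @ d
    stat = float((proj**2 / evals[keep]).sum())
    return stat, rank, float(stats.chi2.sf(stat, rank))


def build_results(
    posteriors: Mapping[tuple[str | None, str], GroupPosterior],
) -> pd.DataFrame:
    """Ranked per-(feature, cluster) differential table.

    Rows are ordered by rank_score = max(p, 1-p) descending with a
    deterministic (cluster_id, feature_id) tie-break; both the posterior
    probability and the Wald p-value are reported so either ranking can be
    used.
    """
    clusters = sorted({c for c, _ in posteriors}, key=lambda c: (c is not None, c))
    rows = []
    for cluster in clusters:
        try:
            post_a = posteriors[(cluster, "A")]
            post_b = posteriors[(cluster, "B")]
        except KeyError:
            logger.warning("cluster %r lacks a fitted group; skipped", cluster)
            continue
        feats_a, feats_b = post_a.feature_ids, post_b.feature_ids
        if feats_a != feats_b:
            common = [f for f in feats_a if f in set(feats_b)]
            logger.warning(
                "cluster %r: feature sets differ between groups; restricted to %d common features",
                cluster, len(common),
            )
        else:
            common = feats_a
        idx_a = {f: i for i, f in enumerate(feats_a)}
        idx_b = {f: i for i, f in enumerate(feats_b)}
        pb_a, pb_b = post_a.pi_bar, post_b.pi_bar
        for feat in common:
            fa, fb = idx_a[feat], idx_b[feat]
            series_a = pi_tilde_u(pb_a[:, fa, :], post_a.mode)
            series_b = pi_tilde_u(pb_b[:, fb, :], post_b.mode)
            p = prob_up(series_a, series_b)
            stat, df, pval = wald_test(pb_a[:, fa, :], pb_b[:, fb, :], post_a.mode)
            rows.append(
                {
                    "cluster_id": cluster,
                    "feature_id": feat,
                    "pi_tilde_U_A": float(series_a.mean()),
                    "pi_tilde_U_B": float(series_b.mean()),
                    "prob_B_up": p,
                    "rank_score": max(p, 1.0 - p),
                    "wald_stat": stat,
                    "wald_df": df,
                    "wald_pvalue": pval,
                }
            )
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    table = table.sort_values(
        by=["rank_score", "cluster_id", "feature_id"],
        ascending=[False, True, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    return table
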