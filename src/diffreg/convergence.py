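"""Stationarity testing, burn-in escalation and chain-rerun policy.

Convergence of a group fit is monitored on the marginal log-posterior trace
of the hyper-parameters, log p(delta | pi).  The Heidelberger & Welch (1983)
stationarity stage is applied: a Cramer-von Mises statistic on the
standardized Brownian-bridge (cumulative-sum) process of the trace, with the
spectral density at frequency zero estimated from the mean of the lowest
periodogram ordinates of the second half of the trace.  If the test fails at
the initial burn-in, the burn-in is raised stepwise to at most half the
chain; if it still fails, one fresh chain is run with doubled length and
burn-in.  Non-convergence after that is reported, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, kve

logger = logging.getLogger("diffreg")

MIN_TRACE_LEN = 100
ESCALATION_FRACTIONS = (0.25, 0.30, 0.35, 0.40, 0.45, 0.50)


@dataclass
class ChainDiagnostics:
    """Outcome of the stationarity protocol for one group fit."""

    n_iter: int
    burn_in: int
    hw_pvalue: float
    passed: bool
    reruns: int
    final_kept: int

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must lie in [0, n_iter)")


def pcramer(q: float, terms: int | None = None) -> float:
    """CDF of the asymptotic Cramer-von Mises distribution at q.

    Series expansion with modified Bessel functions (the classical
    representation).  The k-th term decays once (4k+1)^2 > 16 q, so the
    truncation point grows like sqrt(q); accuracy is ~1e-5 over the range
    relevant for testing.
    """
    if q <= 0:
        return 0.0
    if terms is None:
        terms = max(4, int(2.0 * np.sqrt(q)) + 2)
    total = 0.0
    for k in range(terms):
        u = (4 * k + 1) ** 2 / (16.0 * q)
        if u > 700:  # exp(-2u) underflows; the term is numerically zero
            continue
        coeff = np.exp(gammaln(k + 0.5) - gammaln(k + 1)) * np.sqrt(4 * k + 1) / (
            np.pi**1.5 * np.sqrt(q)
        )
        # kv(1/4, u) * exp(-u) computed stably via the scaled Bessel function
        total += coeff * np.exp(-2.0 * u) * kve(0.25, u)
    return float(min(max(total, 0.0), 1.0))


def spectrum0(x: np.ndarray, low_frac: float = 0.1, min_ordinates: int = 3) -> float:
    """Spectral density of ``x`` at frequency zero.

    Mean of the periodogram over the lowest ``max(min_ordinates,
    low_frac * n_freq)`` non-zero frequencies, after demeaning.  For white
    noise this estimates the variance.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    fx = np.fft.rfft(x)
    periodogram = (np.abs(fx) ** 2) / n
    n_freq = len(periodogram) - 1  # exclude the zero frequency
    if n_freq < 1:
        return 0.0
    m = max(min_ordinates, int(low_frac * n_freq))
    m = min(m, n_freq)
    return float(periodogram[1 : 1 + m].mean())


def _cvm_statistic(x: np.ndarray, s0: float) -> float:
    """Cramer-von Mises statistic of the standardized cumulative-sum process."""
    n = len(x)
    bridge = np.cumsum(x) - x.mean() * np.arange(1, n + 1)
    return float((bridge**2).sum() / (n**2 * s0))


def heidelberger_welch(
    trace: Sequence[float],
    alpha: float = 0.05,
    trim_fractions: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> tuple[bool, float, int | None]:
    """Heidelberger-Welch stationarity test on a scalar trace.

    The spectral variance S0 is estimated once from the second half of the
    full trace; the Cramer-von Mises statistic is then evaluated on the full
    trace and on successively trimmed prefixes (10% steps up to 50%).
    Returns ``(passed, pvalue, first_passing_start_index)``; a zero-variance
    trace is trivially stationary.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < MIN_TRACE_LEN:
        raise ValueError(f"trace too short for a stationarity test ({n} < {MIN_TRACE_LEN})")
    if np.ptp(trace) == 0.0:
        return True, 1.0, 0
    s0 = spectrum0(trace[n // 2 :])
    if s0 <= 0.0:
        return True, 1.0, 0
    pvalue = 0.0
    for frac in trim_fractions:
        start = int(np.ceil(frac * n))
        stat = _cvm_statistic(trace[start:], s0)
        pvalue = 1.0 - pcramer(stat)
        if pvalue > alpha:
            return True, pvalue, start
    return False, pvalue, None


FitClosure = Callable[[int, int], tuple[dict[str, np.ndarray], np.ndarray]]


def run_until_converged(
    fit_closure: FitClosure,
    n_iter: int = 2000,
    burn_in: int = 500,
    max_reruns: int = 1,
    alpha: float = 0.05,
) -> tuple[dict[str, np.ndarray], np.ndarray, ChainDiagnostics]:
    """Run a chain and enforce the stationarity protocol.

    ``fit_closure(n_iter, attempt)`` must run a fresh chain of the requested
    length and return ``(draws, trace)`` where ``draws`` maps names to
    arrays with the iteration as leading axis.  The log-posterior trace is
    tested at the initial burn-in, then at burn-ins escalated over
    {25%, 30%, ..., 50%} of the chain length; on failure one rerun with
    doubled length and burn-in is attempted.  Returns the kept draws, the
    full trace of the final chain, and diagnostics (``passed`` may be False
    after exhausting reruns — flagged, never raised).
    """
    if not 0 < burn_in < n_iter:
        raise ValueError("need 0 < burn_in < n_iter")
    cur_iter, cur_burn = n_iter, burn_in
    draws: dict[str, np.ndarray] = {}
    trace = np.empty(0)
    for attempt in range(max_reruns + 1):
        draws, trace = fit_closure(cur_iter, attempt)
        if len(trace) != cur_iter:
            raise ValueError("fit closure returned a trace of the wrong length")
        candidates = [cur_burn]
        for frac in ESCALATION_FRACTIONS:
            b = int(np.ceil(frac * cur_iter))
            if b > cur_burn and b <= cur_iter // 2:
                candidates.append(b)
        for b in candidates:
            if cur_iter - b < MIN_TRACE_LEN:
                continue
            passed, pvalue, _ = heidelberger_welch(trace[b:], alpha, trim_fractions=(0.0,))
            if passed:
                kept = {k: v[b:] for k, v in draws.items()}
                diag = ChainDiagnostics(cur_iter, b, pvalue, True, attempt, cur_iter - b)
                return kept, trace, diag
        if attempt < max_reruns:
            logger.info(
                "stationarity failed at chain length %d; rerunning with doubled "
                "length and burn-in", cur_iter,
            )
            cur_iter *= 2
            cur_burn *= 2
    b = cur_iter // 2
    _, pvalue, _ = heidelberger_welch(trace[b:], alpha, trim_fractions=(0.0,))
    logger.warning("stationarity not reached after %d rerun(s); results are flagged", max_reruns)
    kept = {k: v[b:] for k, v in draws.items()}
    diag = ChainDiagnostics(cur_iter, b, pvalue, False, max_reruns, cur_iter - b)
    return kept, trace, diag


# ---------------------------------------------------------------------------
# Traceplot export
# ---------------------------------------------------------------------------

def export_traceplot_data(posteriors: Mapping[str, object], feature_id: str):
    """Per-group kept-draw series of pi_tilde_U for one feature.

    ``posteriors`` maps group label to a fitted GroupPosterior.  Returns a
    long DataFrame (group, draw, pi_tilde_U) suitable for visual convergence
    assessment of the key comparison parameter.
    """
    import pandas as pd

    from .differential import pi_tilde_u

    frames = []
    for group, post in posteriors.items():
        if feature_id not in post.feature_ids:
            raise KeyError(f"unknown feature id {feature_id!r}")
        f = post.feature_ids.index(feature_id)
        series = pi_tilde_u(post.pi_bar[:, f, :], post.mode)
        frames.append(
            pd.DataFrame(
                {"group": group, "draw": np.arange(len(series)), "pi_tilde_U": series}
            )
        )
    return pd.concat(frames, ignore_index=True)


def plot_traceplot(posteriors: Mapping[str, object], feature_id: str, out_path: str) -> None:
    """Render the per-group pi_tilde_U trace to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = export_traceplot_data(posteriors, feature_id)
    fig, ax = plt.subplots(figsize=(7, 3))
    for group, sub in data.groupby("group"):
        ax.plot(sub["draw"], sub["pi_tilde_U"], lw=0.6, label=f"group {group}")
    ax.set_xlabel("kept draw")
    ax.set_ylabel(r"$\tilde{\pi}_U$")
    ax.set_title(feature_id)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
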