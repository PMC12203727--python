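"""Common-language effect sizes for transition enrichment and depletion.

Comparing one representative set gene against one representative background
gene: ``inc`` is the probability that the set gene shows the transition while
the background gene does not, ``dec`` the reverse, and

    CLES = (inc + (1 - dec)) / 2

so 0.5 means no enrichment, above 0.5 enrichment, below depletion. Both
factors are n=1 beta-binomial probabilities, i.e. the posterior proportions
p = alpha/(alpha+beta). Evaluated per posterior draw and summarized by the
mean and a central 95% interval. A group-size-N variant compares the counts
among N set genes and N background genes instead of single genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import betabinom

from .model import CELL_KEYS, PosteriorDraws

__all__ = ["inc_dec", "cles", "cles_posterior", "cles_group"]


def inc_dec(alpha_g, beta_g, alpha_a, beta_a):
    """Enrichment and depletion probabilities from the four shapes.

    inc = P(background gene does not transition) * P(set gene transitions)
    dec = P(background gene transitions) * P(set gene does not transition)
    """
    arrays = [np.asarray(x, dtype=float) for x in (alpha_g, beta_g, alpha_a, beta_a)]
    if any(np.any(a <= 0) for a in arrays):
        raise ValueError("shape parameters must be positive")
    alpha_g, beta_g, alpha_a, beta_a = arrays
    p_g = alpha_g / (alpha_g + beta_g)
    p_a = alpha_a / (alpha_a + beta_a)
    inc = (1.0 - p_a) * p_g
    dec = p_a * (1.0 - p_g)
    return inc, dec


def cles(inc, dec):
    """Common-language effect size (inc + (1 - dec)) / 2."""
    inc = np.asarray(inc, dtype=float)
    dec = np.asarray(dec, dtype=float)
    if np.any((inc < 0) | (inc > 1) | (dec < 0) | (dec > 1)):
        raise ValueError("inc and dec must lie in [0, 1]")
    return (inc + (1.0 - dec)) / 2.0


def _summarize(draws: PosteriorDraws, inc_d, dec_d, cles_d) -> pd.DataFrame:
    """Summarize per-draw effect arrays of shape (n_total_draws, n_cells)."""
    out = draws.cells.copy()
    out.insert(0, "gene_set", draws.gene_set)
    out["inc_mean"] = inc_d.mean(axis=0)
    out["dec_mean"] = dec_d.mean(axis=0)
    out["cles_mean"] = cles_d.mean(axis=0)
    out["cles_ci_low"] = np.quantile(cles_d, 0.025, axis=0)
    out["cles_ci_high"] = np.quantile(cles_d, 0.975, axis=0)
    return out


def cles_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-(t, d) effect sizes evaluated per posterior draw, then summarized.

    Returns one row per cell with inc/dec/CLES posterior means and the
    central 95% interval of CLES. The ``jensen_gap`` column reports the
    difference between the posterior mean of the per-draw CLES (the value
    used) and the CLES evaluated at the posterior-mean shapes.
    """
    C = draws.n_cells
    ag = draws.alpha_set.reshape(-1, C)
    bg = draws.beta_set.reshape(-1, C)
    aa = draws.alpha_bg.reshape(-1, C)
    ba = draws.beta_bg.reshape(-1, C)
    inc_d, dec_d = inc_dec(ag, bg, aa, ba)
    cles_d = cles(inc_d, dec_d)
    out = _summarize(draws, inc_d, dec_d, cles_d)
    inc_pm, dec_pm = inc_dec(ag.mean(axis=0), bg.mean(axis=0), aa.mean(axis=0), ba.mean(axis=0))
    out["jensen_gap"] = out["cles_mean"] - cles(inc_pm, dec_pm)
    return out


def _prob_greater(pmf_g: np.ndarray, pmf_a: np.ndarray) -> np.ndarray:
    """P(X_g > X_a) + 0.5 P(X_g = X_a) from pmf arrays (..., N+1)."""
    cdf_g = np.cumsum(pmf_g, axis=-1)
    p_le = np.einsum("...k,...k->...", pmf_a, cdf_g)  # P(X_g <= X_a)
    p_eq = np.einsum("...k,...k->...", pmf_a, pmf_g)
    return 1.0 - p_le + 0.5 * p_eq


def cles_group(draws: PosteriorDraws, group_size: int, chunk: int = 200) -> pd.DataFrame:
    """Group-size-N effect size: P(X_g > X_a) + 0.5 P(X_g = X_a).

    Per posterior draw, X_g ~ BetaBin(N, alpha_set, beta_set) and
    X_a ~ BetaBin(N, alpha_bg, beta_bg); the comparison probability is
    computed exactly from the two pmfs (ties get weight 1/2), so the result
    is deterministic given the draws. With N=1 this reduces algebraically to
    the single-gene CLES, (1 + p_g - p_a)/2.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    N = group_size
    C = draws.n_cells
    ag = draws.alpha_set.reshape(-1, C)
    bg = draws.beta_set.reshape(-1, C)
    aa = draws.alpha_bg.reshape(-1, C)
    ba = draws.beta_bg.reshape(-1, C)
    n_total = ag.shape[0]
    k = np.arange(N + 1)
    cles_d = np.empty((n_total, C))
    for lo in range(0, n_total, chunk):
        hi = min(lo + chunk, n_total)
        pmf_g = betabinom.pmf(k, N, ag[lo:hi, :, None], bg[lo:hi, :, None])
        pmf_a = betabinom.pmf(k, N, aa[lo:hi, :, None], ba[lo:hi, :, None])
        cles_d[lo:hi] = _prob_greater(pmf_g, pmf_a)
    inc_d, dec_d = inc_dec(ag, bg, aa, ba)
    out = _summarize(draws, inc_d, dec_d, cles_d)
    out["group_size"] = N
    return out


def effect_matrix(effects: pd.DataFrame, cell_from: str, cell_to: str, value: str = "cles_mean") -> pd.DataFrame:
    """Wide origin-states x target-states matrix for one cell-type pair."""
    sub = effects[(effects["cell_from"] == cell_from) & (effects["cell_to"] == cell_to)]
    return sub.pivot(index="state_from", columns="state_to", values=value)
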