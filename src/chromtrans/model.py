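"""Hierarchical beta-binomial model of gene-level transition counts.

For one gene set, the observed number of set genes ``s`` (out of ``S``) and
background genes ``a`` (out of ``A``) carrying a transition type ``t`` at a
differentiation step ``d``, per replicate pair, are modeled as

    s_{t,d,i,j} ~ BetaBin(S, alpha_g[t,d], beta_g[t,d])
    a_{t,d,i,j} ~ BetaBin(A, alpha_a[t,d], beta_a[t,d])

with Exponential(alpha_h) priors on all alpha shapes, Exponential(beta_h)
priors on all beta shapes, and Exponential(hyper_rate) hyperpriors on the two
shared rates (hyper_rate defaults to 10, a broad weakly-informative choice).
All (t,d) cells of the set *and* the background are fit jointly so the two
hyperparameters pool information across the whole grid.

The posterior is sampled by Gibbs-within-Metropolis: the exponential-rate
hyperparameters have conjugate Gamma full conditionals, and each cell's
shape pair is updated on the (logit mean, log precision) scale by an
adaptive random-walk Metropolis step, vectorized across all cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit
from scipy.stats import betabinom
from sklearn.base import BaseEstimator

__all__ = [
    "betabin_pmf",
    "betabin_logpmf",
    "PosteriorDraws",
    "TransitionEnrichmentModel",
    "fit",
    "rhat",
    "max_rhat",
    "posterior_predictive_check",
]

CELL_KEYS = ["state_from", "state_to", "cell_from", "cell_to"]


def betabin_logpmf(k, n, alpha, beta):
    """Log pmf of the beta-binomial distribution, computed in log space."""
    return betabinom.logpmf(k, n, alpha, beta)


def betabin_pmf(k, n, alpha, beta):
    """Beta-binomial pmf C(n,k) B(k+alpha, n-k+beta) / B(alpha, beta)."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > np.asarray(n)):
        raise ValueError("k must lie in [0, n]")
    if np.any(np.asarray(alpha) <= 0) or np.any(np.asarray(beta) <= 0):
        raise ValueError("shape parameters must be positive")
    return np.exp(betabin_logpmf(k, n, alpha, beta))


@dataclass
class PosteriorDraws:
    """MCMC draws for every (t, d) cell of one gene-set fit.

    Shape arrays are (chains, draws, n_cells); hyperparameter arrays are
    (chains, draws). ``cells`` maps the cell axis to its
    (state_from, state_to, cell_from, cell_to) labels.
    """

    cells: pd.DataFrame
    alpha_set: np.ndarray
    beta_set: np.ndarray
    alpha_bg: np.ndarray
    beta_bg: np.ndarray
    alpha_h: np.ndarray
    beta_h: np.ndarray
    S: int
    A: int
    gene_set: str = "set"

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_draws(self) -> int:
        return self.alpha_set.shape[0] * self.alpha_set.shape[1]

    def p_set(self) -> np.ndarray:
        """Per-draw transition proportion alpha/(alpha+beta) for the set."""
        return self.alpha_set / (self.alpha_set + self.beta_set)

    def p_bg(self) -> np.ndarray:
        return self.alpha_bg / (self.alpha_bg + self.beta_bg)

    def to_inference_data(self):
        import arviz as az

        coords = {"cell": np.arange(self.n_cells)}
        return az.from_dict(
            posterior={
                "alpha_set": self.alpha_set,
                "beta_set": self.beta_set,
                "alpha_bg": self.alpha_bg,
                "beta_bg": self.beta_bg,
                "alpha_h": self.alpha_h,
                "beta_h": self.beta_h,
            },
            coords=coords,
            dims={k: ["cell"] for k in ["alpha_set", "beta_set", "alpha_bg", "beta_bg"]},
        )

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd/central-95% summaries per parameter and cell."""
        rows = []
        names = ["alpha_set", "beta_set", "alpha_bg", "beta_bg"]
        for name in names:
            arr = getattr(self, name).reshape(-1, self.n_cells)
            for c in range(self.n_cells):
                lab = self.cells.iloc[c]
                rows.append(
                    {
                        "parameter": name,
                        **{k: lab[k] for k in CELL_KEYS},
                        "mean": arr[:, c].mean(),
                        "sd": arr[:, c].std(),
                        "q2.5": np.quantile(arr[:, c], 0.025),
                        "q50": np.quantile(arr[:, c], 0.5),
                        "q97.5": np.quantile(arr[:, c], 0.975),
                    }
                )
        for name in ["alpha_h", "beta_h"]:
            arr = getattr(self, name).ravel()
            rows.append(
                {
                    "parameter": name,
                    **{k: "" for k in CELL_KEYS},
                    "mean": arr.mean(),
                    "sd": arr.std(),
                    "q2.5": np.quantile(arr, 0.025),
                    "q50": np.quantile(arr, 0.5),
                    "q97.5": np.quantile(arr, 0.975),
                }
            )
        return pd.DataFrame(rows)


def _prepare_table(table: pd.DataFrame):
    """Validate a one-gene-set count table and stack it into arrays."""
    required = {"state_from", "state_to", "cell_from", "cell_to", "s", "S", "a", "A"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("count table is empty")
    if "gene_set" in table.columns and table["gene_set"].nunique() > 1:
        raise ValueError(
            "fit one gene set at a time (use fit_gene_sets for multi-set tables)"
        )
    if table["S"].nunique() > 1 or table["A"].nunique() > 1:
        raise ValueError("S and A must be constant within a gene set")
    S = int(table["S"].iloc[0])
    A = int(table["A"].iloc[0])
    if S <= 0 or A <= 0:
        raise ValueError("S and A must be positive")
    if (table["s"] > S).any() or (table["a"] > A).any() or (table[["s", "a"]] < 0).any().any():
        raise ValueError("counts must lie in [0, S] / [0, A]")

    cells = (
        table[CELL_KEYS].drop_duplicates().sort_values(CELL_KEYS).reset_index(drop=True)
    )
    key = table[CELL_KEYS].apply(tuple, axis=1)
    cell_of = {tuple(r): i for i, r in enumerate(cells.itertuples(index=False))}
    groups = table.groupby(key.map(cell_of))
    n_cells = len(cells)
    max_j = groups.size().max()
    s_obs = np.zeros((n_cells, max_j))
    a_obs = np.zeros((n_cells, max_j))
    mask = np.zeros((n_cells, max_j), dtype=bool)
    for c, grp in groups:
        j = len(grp)
        s_obs[c, :j] = grp["s"].to_numpy()
        a_obs[c, :j] = grp["a"].to_numpy()
        mask[c, :j] = True
    gene_set = str(table["gene_set"].iloc[0]) if "gene_set" in table.columns else "set"
    return cells, s_obs, a_obs, mask, S, A, gene_set


def _unit_loglik(u1, u2, k, n, mask):
    """Beta-binomial log-likelihood per unit on the (logit p, log nu) scale.

    The binomial coefficient is constant in the parameters and omitted.
    """
    p = expit(u1)
    nu = np.exp(u2)
    alpha = p * nu
    beta = nu - alpha
    a_col = alpha[:, None]
    b_col = beta[:, None]
    terms = betaln(k + a_col, n[:, None] - k + b_col) - betaln(a_col, b_col)
    return np.where(mask, terms, 0.0).sum(axis=1)


def _unit_logpost(u1, u2, k, n, mask, ah, bh):
    """Unnormalized log posterior per unit given the hyper rates."""
    p = expit(u1)
    nu = np.exp(u2)
    alpha = p * nu
    beta = nu - alpha
    with np.errstate(divide="ignore"):
        log_jac = 2.0 * u2 + np.log(p) + np.log1p(-p)
    prior = -ah * alpha - bh * beta + log_jac
    return _unit_loglik(u1, u2, k, n, mask) + prior


class TransitionEnrichmentModel(BaseEstimator):
    """Sklearn-style estimator for the hierarchical beta-binomial model.

    Parameters
    ----------
    hyper_rate : float, default 10.0
        Rate of the Exponential hyperpriors on the two shared rates.
    chains : int, default 4
        Independent MCMC chains (>= 2 required for split-R-hat).
    draws : int, default 1000
        Retained draws per chain (after warmup, thinned).
    warmup : int, default 1000
        Adaptation iterations per chain, discarded.
    thin : int, default 5
        Post-warmup iterations per retained draw.
    seed : int, default 0
        Seed for all sampler randomness.
    fixed_hypers : tuple (alpha_h, beta_h) or None
        Freeze the hyper rates instead of sampling them (mainly for
        validation against low-dimensional quadrature).
    rhat_threshold : float, default 1.05
        Fits whose maximum split-R-hat exceeds this emit a warning and set
        ``converged_ = False``.

    Attributes (after ``fit``)
    --------------------------
    posterior_ : PosteriorDraws
    rhat_ : pd.Series of per-parameter rank-normalized split-R-hat
    max_rhat_ : float
    converged_ : bool
    cells_ : DataFrame mapping the cell axis to (t, d) labels
    """

    def __init__(
        self,
        hyper_rate: float = 10.0,
        chains: int = 4,
        draws: int = 1000,
        warmup: int = 1000,
        thin: int = 5,
        seed: int = 0,
        fixed_hypers: tuple[float, float] | None = None,
        rhat_threshold: float = 1.05,
    ):
        self.hyper_rate = hyper_rate
        self.chains = chains
        self.draws = draws
        self.warmup = warmup
        self.thin = thin
        self.seed = seed
        self.fixed_hypers = fixed_hypers
        self.rhat_threshold = rhat_threshold

    def fit(self, X: pd.DataFrame, y=None) -> "TransitionEnrichmentModel":
        """Sample the joint posterior for one gene set's count table."""
        if self.hyper_rate <= 0:
            raise ValueError("hyper_rate must be positive")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for split-R-hat")
        cells, s_obs, a_obs, mask, S, A, gene_set = _prepare_table(X)
        C = len(cells)
        # stack set cells then background cells into 2C sampling units
        k = np.vstack([s_obs, a_obs])
        n = np.concatenate([np.full(C, S), np.full(C, A)]).astype(float)
        m2 = np.vstack([mask, mask])

        seeds = np.random.SeedSequence(self.seed).spawn(self.chains)
        out_shapes = np.empty((self.chains, self.draws, 2, 2 * C))
        out_hyper = np.empty((self.chains, self.draws, 2))
        for ch in range(self.chains):
            self._run_chain(
                np.random.default_rng(seeds[ch]), k, n, m2,
                out_shapes[ch], out_hyper[ch],
            )
        alpha = out_shapes[:, :, 0, :]
        beta = out_shapes[:, :, 1, :]
        self.posterior_ = PosteriorDraws(
            cells=cells,
            alpha_set=alpha[:, :, :C],
            beta_set=beta[:, :, :C],
            alpha_bg=alpha[:, :, C:],
            beta_bg=beta[:, :, C:],
            alpha_h=out_hyper[:, :, 0],
            beta_h=out_hyper[:, :, 1],
            S=S,
            A=A,
            gene_set=gene_set,
        )
        self.cells_ = cells
        self.rhat_ = rhat(self.posterior_)
        self.max_rhat_ = float(self.rhat_.max())
        self.converged_ = self.max_rhat_ <= self.rhat_threshold
        if not self.converged_:
            warnings.warn(
                f"max split-R-hat {self.max_rhat_:.3f} exceeds "
                f"{self.rhat_threshold}; treat posteriors with caution",
                stacklevel=2,
            )
        return self

    def _run_chain(self, rng, k, n, mask, out_shapes, out_hyper) -> None:
        m = k.shape[0]
        k_sum = np.where(mask, k, 0.0).sum(axis=1)
        n_tot = n * mask.sum(axis=1)
        p_hat = np.clip((k_sum + 0.5) / (n_tot + 1.0), 1e-6, 1 - 1e-6)
        u1 = logit(p_hat) + 0.2 * rng.standard_normal(m)
        u2 = np.log(10.0) + 0.5 * rng.standard_normal(m)
        if self.fixed_hypers is not None:
            ah, bh = map(float, self.fixed_hypers)
        else:
            ah = bh = 0.1
        scale = np.full((m, 2), 0.5)
        acc = np.zeros((m, 2))
        # global scale moves along the shape/hyper-coupled direction
        gscale = np.full(2, 0.2)
        gacc = np.zeros(2)
        window = 25
        total = self.warmup + self.draws * self.thin
        saved = 0
        logpost = _unit_logpost(u1, u2, k, n, mask, ah, bh)
        for it in range(total):
            for coord, u in ((0, u1), (1, u2)):
                prop = u + scale[:, coord] * rng.standard_normal(m)
                if coord == 0:
                    lp_prop = _unit_logpost(prop, u2, k, n, mask, ah, bh)
                else:
                    lp_prop = _unit_logpost(u1, prop, k, n, mask, ah, bh)
                accept = np.log(rng.random(m)) < lp_prop - logpost
                u[accept] = prop[accept]
                logpost[accept] = lp_prop[accept]
                acc[:, coord] += accept
            # joint multiplicative update of all alpha (resp. beta) shapes:
            # the shared hyper rates couple them, and zero-count cells leave
            # the common scale only weakly identified, so coordinate-wise
            # random walks alone cross this direction slowly
            p = expit(u1)
            nu = np.exp(u2)
            alpha = p * nu
            beta = nu - alpha
            ll_cur = _unit_loglik(u1, u2, k, n, mask)
            for side in (0, 1):
                c = np.exp(gscale[side] * rng.standard_normal())
                if side == 0:
                    alpha_p, beta_p = c * alpha, beta
                    rate, total_shape = ah, alpha.sum()
                else:
                    alpha_p, beta_p = alpha, c * beta
                    rate, total_shape = bh, beta.sum()
                nu_p = alpha_p + beta_p
                u1_p = logit(np.clip(alpha_p / nu_p, 1e-12, 1 - 1e-12))
                u2_p = np.log(nu_p)
                ll_prop = _unit_loglik(u1_p, u2_p, k, n, mask)
                log_r = (
                    (ll_prop - ll_cur).sum()
                    - rate * (c - 1.0) * total_shape
                    + m * np.log(c)
                )
                if np.log(rng.random()) < log_r:
                    u1, u2 = u1_p, u2_p
                    alpha, beta = alpha_p, beta_p
                    ll_cur = ll_prop
                    gacc[side] += 1
            if self.fixed_hypers is None:
                ah = rng.gamma(m + 1.0, 1.0 / (self.hyper_rate + alpha.sum()))
                bh = rng.gamma(m + 1.0, 1.0 / (self.hyper_rate + beta.sum()))
            logpost = _unit_logpost(u1, u2, k, n, mask, ah, bh)
            if it < self.warmup and (it + 1) % window == 0:
                scale *= np.exp(1.2 * (acc / window - 0.35))
                np.clip(scale, 1e-3, 10.0, out=scale)
                acc[:] = 0.0
                gscale *= np.exp(1.2 * (gacc / window - 0.4))
                np.clip(gscale, 1e-3, 2.0, out=gscale)
                gacc[:] = 0.0
            if it >= self.warmup and (it - self.warmup + 1) % self.thin == 0:
                out_shapes[saved, 0] = alpha
                out_shapes[saved, 1] = beta
                out_hyper[saved] = (ah, bh)
                saved += 1


def fit(table: pd.DataFrame, **params) -> PosteriorDraws:
    """Functional wrapper: fit the model and return the posterior draws."""
    return TransitionEnrichmentModel(**params).fit(table).posterior_


def fit_gene_sets(table: pd.DataFrame, **params) -> dict[str, "TransitionEnrichmentModel"]:
    """Fit one joint model per gene set in a multi-set count table."""
    models = {}
    for set_id, sub in table.groupby("gene_set"):
        models[set_id] = TransitionEnrichmentModel(**params).fit(sub)
    return models


def rhat(draws: PosteriorDraws) -> pd.Series:
    """Rank-normalized split-R-hat per scalar parameter."""
    import arviz as az

    if draws.alpha_set.shape[0] < 2:
        raise ValueError("split-R-hat requires at least 2 chains")
    shape_names = ["alpha_set", "beta_set", "alpha_bg", "beta_bg"]
    # frozen hyperparameters have zero variance and no meaningful R-hat
    hyper_names = [h for h in ["alpha_h", "beta_h"] if np.ptp(getattr(draws, h)) > 0]
    ds = az.rhat(draws.to_inference_data(), method="rank", var_names=shape_names + hyper_names)
    out = {}
    for name in shape_names:
        vals = ds[name].to_numpy()
        for c, v in enumerate(np.atleast_1d(vals)):
            out[f"{name}[{c}]"] = float(v)
    for name in hyper_names:
        out[name] = float(ds[name].to_numpy())
    return pd.Series(out, name="rhat")


def max_rhat(draws: PosteriorDraws) -> float:
    return float(rhat(draws).max())


def posterior_predictive_check(draws: PosteriorDraws, table: pd.DataFrame) -> pd.DataFrame:
    """Observed counts against the model's average expected counts.

    For each table row the expected count is the posterior mean of
    ``n * alpha/(alpha+beta)`` for that row's (t, d) cell and group (set or
    background); ``diff`` is expected minus observed. The ``summary`` attr
    holds the mean difference per (t, d, group).
    """
    if len(table) == 0:
        out = pd.DataFrame(
            columns=CELL_KEYS + ["group", "observed", "expected", "diff"]
        )
        out.attrs["summary"] = out
        return out
    cell_of = {
        tuple(r): i for i, r in enumerate(draws.cells.itertuples(index=False))
    }
    ep_set = draws.p_set().reshape(-1, draws.n_cells).mean(axis=0)
    ep_bg = draws.p_bg().reshape(-1, draws.n_cells).mean(axis=0)
    rows = []
    for r in table.itertuples():
        c = cell_of[(r.state_from, r.state_to, r.cell_from, r.cell_to)]
        rows.append(
            {
                "state_from": r.state_from,
                "state_to": r.state_to,
                "cell_from": r.cell_from,
                "cell_to": r.cell_to,
                "group": "set",
                "observed": r.s,
                "expected": draws.S * ep_set[c],
                "diff": draws.S * ep_set[c] - r.s,
            }
        )
        rows.append(
            {
                "state_from": r.state_from,
                "state_to": r.state_to,
                "cell_from": r.cell_from,
                "cell_to": r.cell_to,
                "group": "background",
                "observed": r.a,
                "expected": draws.A * ep_bg[c],
                "diff": draws.A * ep_bg[c] - r.a,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["summary"] = (
        out.groupby(CELL_KEYS + ["group"], as_index=False)["diff"].mean()
    )
    return out
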