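"""Bayesian calibration machinery.

Priors (uniform, log-uniform, lognormal), a lognormal measurement-error
likelihood with per-measurement-type geometric SDs, an adaptive random-walk
Metropolis sampler working in log space for positively supported parameters,
the Gelman–Rubin potential scale reduction diagnostic, and a Monte Carlo
(sampled-correlation) sensitivity screen used to choose which structural
parameters are worth calibrating.

The sampler is exchangeable-in-distribution with any correct MCMC targeting
the same posterior: chains are seeded and reproducible, but no bitwise
equivalence with other tools is implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_FAMILIES = ("uniform", "loguniform", "lognormal")


@dataclass(frozen=True)
class PriorSpec:
    """One independent marginal prior.

    uniform / loguniform use ``lower``/``upper``; lognormal uses ``median``
    (geometric mean) and ``gsd`` (geometric SD, > 1).
    """

    name: str
    family: str
    lower: float = math.nan
    upper: float = math.nan
    median: float = math.nan
    gsd: float = math.nan

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family in ("uniform", "loguniform"):
            if not (math.isfinite(self.lower) and math.isfinite(self.upper)
                    and self.lower < self.upper):
                raise ValueError(f"{self.name}: bounds must be finite with lower < upper")
            if self.family == "loguniform" and self.lower <= 0:
                raise ValueError(f"{self.name}: log-uniform needs a positive lower bound")
        else:
            if not (self.median > 0 and self.gsd > 1):
                raise ValueError(f"{self.name}: lognormal needs median > 0 and GSD > 1")

    # -- densities ----------------------------------------------------------
    def logpdf(self, x: float) -> float:
        if self.family == "uniform":
            if self.lower <= x <= self.upper:
                return -math.log(self.upper - self.lower)
            return -math.inf
        if x <= 0:
            return -math.inf
        if self.family == "loguniform":
            if self.lower <= x <= self.upper:
                return -math.log(x) - math.log(math.log(self.upper / self.lower))
            return -math.inf
        sig = math.log(self.gsd)
        z = (math.log(x) - math.log(self.median)) / sig
        return -math.log(x * sig * math.sqrt(2 * math.pi)) - 0.5 * z * z

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "uniform":
            return rng.uniform(self.lower, self.upper, size)
        if self.family == "loguniform":
            return np.exp(rng.uniform(math.log(self.lower), math.log(self.upper), size))
        return self.median * np.exp(math.log(self.gsd) * rng.standard_normal(size))

    def ppf(self, q):
        if self.family == "uniform":
            return self.lower + (self.upper - self.lower) * np.asarray(q)
        if self.family == "loguniform":
            return self.lower * (self.upper / self.lower) ** np.asarray(q)
        return self.median * np.exp(math.log(self.gsd) * stats.norm.ppf(q))

    # -- sampling-space transform -------------------------------------------
    @property
    def log_space(self) -> bool:
        """Whether random-walk proposals act on log(x)."""
        return self.family in ("loguniform", "lognormal")

    def to_sampling(self, x: float) -> float:
        return math.log(x) if self.log_space else x

    def from_sampling(self, u: float) -> float:
        return math.exp(u) if self.log_space else u

    def sampling_bounds(self) -> tuple[float, float]:
        if self.family == "uniform":
            return self.lower, self.upper
        if self.family == "loguniform":
            return math.log(self.lower), math.log(self.upper)
        return -math.inf, math.inf


def log_prior(params: Mapping[str, float],
              priors: Mapping[str, PriorSpec]) -> float:
    """Sum of independent marginal log-densities; -inf outside support."""
    total = 0.0
    for name, spec in priors.items():
        lp = spec.logpdf(params[name])
        if not math.isfinite(lp):
            return -math.inf
        total += lp
    return total


# ---------------------------------------------------------------------------
# lognormal measurement-error likelihood
# ---------------------------------------------------------------------------

@dataclass
class LikelihoodSpec:
    """Per-measurement-type lognormal error model.

    ``sigmas`` maps measurement type to the log-scale SD (sigma = ln GSD).
    """

    sigmas: dict[str, float]

    def __post_init__(self) -> None:
        for k, s in self.sigmas.items():
            if s <= 0:
                raise ValueError(f"sigma for {k!r} must be positive")


def log_likelihood(observed: np.ndarray, predicted: np.ndarray,
                   types: Sequence[str], lik: LikelihoodSpec) -> float:
    """Lognormal log-density of observations around model predictions.

    The model prediction is the median: ln(obs) ~ N(ln(pred), sigma_type^2).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal shapes")
    if np.any(observed <= 0) or np.any(predicted <= 0) or \
            not np.all(np.isfinite(predicted)):
        raise ValueError("lognormal likelihood needs positive finite values")
    sig = np.array([lik.sigmas[t] for t in types], dtype=float)
    z = (np.log(observed) - np.log(predicted)) / sig
    return float(np.sum(-np.log(observed * sig * math.sqrt(2 * math.pi))
                        - 0.5 * z * z))


# ---------------------------------------------------------------------------
# posterior sample container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Retained MCMC draws with chain/iteration provenance."""

    draws: pd.DataFrame             # columns: chain, iteration, <params>, log_posterior
    param_names: tuple[str, ...]
    acceptance: dict = field(default_factory=dict)

    def mode(self) -> dict[str, float]:
        """Maximum-log-posterior draw (joint posterior mode over the sample)."""
        row = self.draws.loc[self.draws["log_posterior"].idxmax()]
        return {n: float(row[n]) for n in self.param_names}

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        q = self.draws[name].quantile([a, 1.0 - a])
        return float(q.iloc[0]), float(q.iloc[1])

    def gelman_rubin(self) -> dict[str, float]:
        out = {}
        for n in self.param_names:
            chains = [g[n].to_numpy() for _, g in self.draws.groupby("chain")]
            ln = min(len(c) for c in chains)
            out[n] = gelman_rubin(np.array([c[:ln] for c in chains]))
        return out

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorSamples":
        df = pd.read_csv(path)
        names = tuple(c for c in df.columns
                      if c not in ("chain", "iteration", "log_posterior"))
        return cls(df, names)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor from m chains of length n.

    ``chains`` has shape (m, n).  Uses the classic between/within variance
    form: PSRF = sqrt(((n-1)/n * W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("need >= 2 chains of equal length >= 10")
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# adaptive random-walk Metropolis
# ---------------------------------------------------------------------------

def _reflect(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect proposals into [lo, hi] (symmetric kernel is preserved)."""
    u = u.copy()
    for _ in range(64):
        below = u < lo
        above = u > hi
        if not (below.any() or above.any()):
            break
        u[below] = 2 * lo[below] - u[below]
        u[above] = 2 * hi[above] - u[above]
    return np.clip(u, lo, hi)


def metropolis_sample(log_post: Callable[[dict], float],
                      priors: Mapping[str, PriorSpec],
                      n_chains: int = 5,
                      n_iter: int = 20_000,
                      seed: int = 0,
                      thin: int = 10,
                      update: str = "vector",
                      discard_frac: float = 0.5,
                      init_draws: int = 100,
                      initial: Sequence[Mapping[str, float]] | None = None,
                      progress: bool = False) -> PosteriorSamples:
    """Sample a posterior with seeded adaptive random-walk Metropolis chains.

    Proposals act in log space for positively supported parameters and are
    reflected at uniform bounds.  ``update='vector'`` uses a joint proposal
    whose covariance is adapted to the chain history during the discarded
    half (frozen afterwards); ``update='component'`` cycles through
    single-parameter proposals with per-component adapted scales.  Chains
    start at the best of ``init_draws`` independent prior draws unless
    explicit ``initial`` points are given.

    The first ``discard_frac`` of each chain is treated as warm-up and
    dropped; the remainder is thinned by ``thin``.
    """
    if n_chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    if update not in ("vector", "component"):
        raise ValueError("update must be 'vector' or 'component'")
    names = list(priors)
    d = len(names)
    lo = np.array([priors[n].sampling_bounds()[0] for n in names])
    hi = np.array([priors[n].sampling_bounds()[1] for n in names])
    widths = np.where(np.isfinite(hi - lo),
                      hi - lo,
                      np.array([2 * math.log(priors[n].gsd)
                                if priors[n].family == "lognormal" else 1.0
                                for n in names]))

    log_space = np.array([priors[n].log_space for n in names])

    def to_nat(u: np.ndarray) -> dict[str, float]:
        return {n: priors[n].from_sampling(u[i]) for i, n in enumerate(names)}

    def posterior(u: np.ndarray) -> float:
        # include the Jacobian of the log transform so the random walk in
        # sampling space targets the correct natural-space distribution
        lp = log_post(to_nat(u))
        if not math.isfinite(lp):
            return -math.inf
        return lp + float(u[log_space].sum())

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    n_keep_start = int(n_iter * discard_frac)
    records = []
    acceptance = {}
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        # --- initial point ---------------------------------------------
        if initial is not None:
            u = np.array([priors[n].to_sampling(initial[c][n]) for n in names])
            lp = posterior(u)
        else:
            best_u, best_lp = None, -math.inf
            for _ in range(init_draws):
                cand = np.array([priors[n].to_sampling(priors[n].sample(rng))
                                 for n in names])
                lpc = posterior(cand)
                if lpc > best_lp:
                    best_u, best_lp = cand, lpc
            if best_u is None or not math.isfinite(best_lp):
                raise RuntimeError("could not find a finite-posterior start point")
            u, lp = best_u, best_lp
        # --- sampling ----------------------------------------------------
        scale = widths / 20.0
        comp_scale = scale.copy()
        global_scale = 1.0
        cov_chol = None
        history = np.empty((n_iter, d))
        n_acc = 0
        n_prop = 0
        batch_acc = 0
        batch_n = 0
        batch_idx = 0
        for it in range(n_iter):
            adapting = it < n_keep_start
            if update == "vector":
                if cov_chol is not None:
                    step = cov_chol @ rng.standard_normal(d)
                else:
                    step = scale * rng.standard_normal(d)
                u_new = _reflect(u + global_scale * step, lo, hi)
                lp_new = posterior(u_new)
                n_prop += 1
                batch_n += 1
                if math.log(rng.uniform()) < lp_new - lp:
                    u, lp = u_new, lp_new
                    n_acc += 1
                    batch_acc += 1
                if adapting and batch_n == 50:
                    batch_idx += 1
                    rate = batch_acc / batch_n
                    global_scale *= math.exp((rate - 0.234) / math.sqrt(batch_idx))
                    batch_acc = batch_n = 0
                if adapting and it >= 500 and it % 500 == 0:
                    emp = np.cov(history[max(0, it - 5000):it].T)
                    emp = np.atleast_2d(emp) + 1e-10 * np.diag(widths ** 2)
                    try:
                        cov_chol = np.linalg.cholesky(2.38 ** 2 / d * emp)
                        global_scale = 1.0
                    except np.linalg.LinAlgError:
                        cov_chol = None
            else:  # component-wise
                for j in range(d):
                    u_new = u.copy()
                    u_new[j] += comp_scale[j] * rng.standard_normal()
                    u_new = _reflect(u_new, lo, hi)
                    lp_new = posterior(u_new)
                    n_prop += 1
                    if math.log(rng.uniform()) < lp_new - lp:
                        u, lp = u_new, lp_new
                        n_acc += 1
                if adapting and (it + 1) % 50 == 0:
                    batch_idx += 1
                    # crude per-batch global adjustment toward 0.44
                    rate = n_acc / max(n_prop, 1)
                    comp_scale *= math.exp((rate - 0.44) / math.sqrt(batch_idx))
            history[it] = u
            if it >= n_keep_start and (it - n_keep_start) % thin == 0:
                nat = to_nat(u)
                # report the natural-space log posterior (Jacobian removed)
                records.append({"chain": c, "iteration": it, **nat,
                                "log_posterior": lp - float(u[log_space].sum())})
        acceptance[c] = n_acc / max(n_prop, 1)
        if acceptance[c] == 0.0:
            raise RuntimeError(f"chain {c} accepted no proposals; "
                               "posterior may be degenerate")
    df = pd.DataFrame.from_records(records)
    return PosteriorSamples(df, tuple(names), acceptance)


# ---------------------------------------------------------------------------
# Monte Carlo sensitivity screening
# ---------------------------------------------------------------------------

def mc_sensitivity(model_fn: Callable[[dict], Mapping[str, float]],
                   priors: Mapping[str, PriorSpec],
                   n_samples: int = 200,
                   seed: int = 0) -> pd.DataFrame:
    """Rank parameters by sampled-correlation importance.

    Draws ``n_samples`` parameter vectors from the priors, evaluates the
    model's scalar output summaries, and computes |Spearman rho| between
    each parameter and each output.  Returns a table indexed by parameter
    with one column per output summary, an ``importance`` column (max over
    outputs) and a 1-based ``rank``.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 samples for a stable ranking")
    names = list(priors)
    rng = np.random.default_rng(seed)
    X = np.column_stack([priors[n].sample(rng, n_samples) for n in names])
    outs: dict[str, list[float]] = {}
    for i in range(n_samples):
        res = model_fn({n: X[i, j] for j, n in enumerate(names)})
        if np.isscalar(res):
            res = {"output": float(res)}
        for k, v in res.items():
            outs.setdefault(k, []).append(float(v))
    cols = {}
    for k, vals in outs.items():
        v = np.asarray(vals)
        rho = np.array([stats.spearmanr(X[:, j], v).statistic
                        if np.std(v) > 0 else 0.0 for j in range(len(names))])
        cols[k] = np.abs(np.nan_to_num(rho))
    df = pd.DataFrame(cols, index=names)
    df["importance"] = df.max(axis=1)
    df["rank"] = df["importance"].rank(ascending=False, method="min").astype(int)
    return df.sort_values("rank")
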