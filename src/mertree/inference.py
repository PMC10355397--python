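"""Bayesian core: multinomial likelihood, spike-and-slab prior, adaptive
Metropolis-within-Gibbs updates, and the level-by-level sampler.

The six mutation-type trees are tied together in two ways: contexts sharing a
central base contribute to a joint multinomial cell (the three alternate
probabilities plus the "no polymorphism" remainder must stay on the simplex),
and the spike-and-slab hyperparameters are shared across all trees within a
mer level.

Sampling proceeds level by level.  While level ``k`` is being sampled, all
shallower edges are frozen at their posterior means and all deeper edges are
implicitly zero, so the likelihood of counts aggregated to level ``k`` is
exact.  Each edge's log-shift ``phi`` gets a Gaussian random-walk Metropolis
update whose proposal scale adapts toward a 0.44 acceptance rate during
burn-in; its inclusion indicator ``delta`` and the shared slab probability
``pi`` get conjugate Gibbs updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .contexts import TreeSet
from .tabulate import CountTable, ProbabilityTable

DEFAULT_SHIFT_THRESHOLD = 1.1  # slab favored beyond a 10% multinomial shift
DEFAULT_SIGMA_RATIO = 10.0


def spike_slab_sigmas(
    ratio: float = DEFAULT_SIGMA_RATIO,
    shift_threshold: float = DEFAULT_SHIFT_THRESHOLD,
) -> tuple[float, float]:
    """Spike/slab standard deviations from the effect-size crossing rule.

    The two zero-mean Gaussian components, weighted equally, have equal
    density at ``|phi| = ln(shift_threshold)``: shifts smaller than the
    threshold favor the spike (no effect), larger ones the slab.  With the
    default 10% threshold and a 10x scale ratio this gives
    sigma_spike ~= 0.0442 and sigma_slab ~= 0.4419.
    """
    if ratio <= 1:
        raise ValueError("slab must be wider than spike")
    c = math.log(shift_threshold)
    sigma_spike = c * math.sqrt((ratio**2 - 1) / (2 * ratio**2 * math.log(ratio)))
    return sigma_spike, ratio * sigma_spike


@dataclass(frozen=True)
class LevelHyper:
    """Spike-and-slab hyperparameters shared by all six trees at one level."""

    level: int
    sigma_spike: float
    sigma_slab: float
    beta_a: float = 1.0
    beta_b: float = 1.0
    pi_init: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.sigma_spike < self.sigma_slab:
            raise ValueError("need 0 < sigma_spike < sigma_slab")
        if not 0 < self.pi_init < 1:
            raise ValueError("pi must be in (0,1)")

    @classmethod
    def default(cls, level: int, **kw) -> "LevelHyper":
        s, S = spike_slab_sigmas()
        return cls(level, s, S, **kw)


@dataclass(frozen=True)
class SamplerConfig:
    """Adaptive Metropolis-within-Gibbs schedule and priors.

    ``iterations`` counts full sweeps per level; the first ``burnin_frac``
    of them are discarded and used for proposal-scale adaptation, the rest
    are kept every ``thin`` sweeps.
    """

    iterations: int = 20_000
    burnin_frac: float = 0.5
    thin: int = 5
    chains: int = 2
    adapt_batch: int = 50
    target_accept: float = 0.44
    sigma_ratio: float = DEFAULT_SIGMA_RATIO
    shift_threshold: float = DEFAULT_SHIFT_THRESHOLD
    beta_a: float = 1.0
    beta_b: float = 1.0
    pi_init: float = 0.5
    fixed_pi: float | None = None  # disable the conjugate pi update (testing)
    theta_prior_mean: float = math.log(0.01)
    theta_prior_sd: float = 2.0
    init_log_scale: float | None = None  # None: precondition as 2.4/sqrt(counts)
    rhat_threshold: float = 1.1

    @property
    def burnin(self) -> int:
        return int(self.iterations * self.burnin_frac)

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burnin) // self.thin

    def with_(self, **kw) -> "SamplerConfig":
        return replace(self, **kw)

    def hyper(self, level: int) -> LevelHyper:
        s, S = spike_slab_sigmas(self.sigma_ratio, self.shift_threshold)
        return LevelHyper(level, s, S, self.beta_a, self.beta_b,
                          self.fixed_pi if self.fixed_pi is not None else self.pi_init)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _cell_loglik(N: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Sum of per-context multinomial log-likelihoods (coefficient omitted).

    ``n`` and ``p`` are (contexts, 3); returns -inf if any context's total
    alternate probability reaches 1, the sampler's rejection signal.
    """
    s = p.sum(axis=1)
    if (s >= 1).any() or (p < 0).any():
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(np.where(p > 0, p, 1.0)), 0.0)
    if ((n > 0) & (p == 0)).any():
        return -np.inf
    rest = (N - n.sum(axis=1)) * np.log1p(-s)
    return float(terms.sum() + rest.sum())


def multinomial_loglik(level_counts: CountTable, trees: TreeSet, level: int) -> float:
    """Joint log-likelihood of level-aggregated counts under the six trees."""
    probs = ProbabilityTable.from_trees(trees, level)
    total = 0.0
    for central in "AC":
        total += _cell_loglik(level_counts.N[central], level_counts.n[central],
                              probs.p[central])
    return total


def spike_slab_logprior(phi: float, delta: int, hyper: LevelHyper) -> float:
    """Log prior density of an edge shift given its inclusion indicator."""
    pi = hyper.pi_init
    sigma = hyper.sigma_slab if delta else hyper.sigma_spike
    weight = math.log(pi) if delta else math.log1p(-pi)
    return weight - 0.5 * math.log(2 * math.pi) - math.log(sigma) - phi**2 / (2 * sigma**2)


def slab_probability(phi, pi, hyper: LevelHyper):
    """P(delta = 1 | phi, pi): the conditional slab membership probability."""
    phi = np.asarray(phi, dtype=float)
    log_odds = (
        np.log(pi) - np.log1p(-pi)
        + np.log(hyper.sigma_spike) - np.log(hyper.sigma_slab)
        + phi**2 * (1 / (2 * hyper.sigma_spike**2) - 1 / (2 * hyper.sigma_slab**2))
    )
    return 1.0 / (1.0 + np.exp(-log_odds))


def gibbs_update_delta(phi, pi, hyper: LevelHyper, rng: np.random.Generator):
    """Bernoulli draw of the inclusion indicator from its full conditional."""
    prob = slab_probability(phi, pi, hyper)
    return (rng.random(np.shape(phi)) < prob).astype(np.int8)


def gibbs_update_pi(deltas, a: float, b: float, rng: np.random.Generator) -> float:
    """Conjugate Beta draw of the shared slab probability from all deltas."""
    deltas = np.asarray(deltas)
    k = int(deltas.sum())
    return float(rng.beta(a + k, b + deltas.size - k))


def adapt_step(batch_index: int) -> float:
    """Diminishing adaptation step for the proposal log-scale (capped at 0.01)."""
    return min(0.01, batch_index ** -0.5)


def adapt_proposals(log_scales, accept_rates, batch_index: int,
                    target: float = 0.44) -> np.ndarray:
    """Nudge proposal log-scales toward the target acceptance rate."""
    step = adapt_step(batch_index)
    return np.asarray(log_scales) + step * np.sign(np.asarray(accept_rates) - target)


# ---------------------------------------------------------------------------
# Level sampler
# ---------------------------------------------------------------------------

@dataclass
class LevelChain:
    """Thinned post-burn-in draws of one chain at one level."""

    level: int
    phi: dict[str, np.ndarray]        # central -> (draws, contexts, 3)
    delta: dict[str, np.ndarray]      # central -> (draws, contexts, 3); zeros at root
    pi: np.ndarray                    # (draws,)
    accept_rate: dict[str, np.ndarray]
    seed: int
    n_burnin: int
    thin: int


@dataclass
class _GroupState:
    N: np.ndarray
    n: np.ndarray
    base: np.ndarray
    phi: np.ndarray
    delta: np.ndarray
    log_scale: np.ndarray
    p: np.ndarray = field(init=False)
    s: np.ndarray = field(init=False)
    log1ms: np.ndarray = field(init=False)
    n_tot: np.ndarray = field(init=False)
    accepted: np.ndarray = field(init=False)
    batch_accepted: np.ndarray = field(init=False)

    def __post_init__(self):
        self.p = np.exp(self.base + self.phi)
        self.s = self.p.sum(axis=1)
        if (self.s >= 1).any():
            raise FloatingPointError(
                "non-finite likelihood at initialization; start from smaller phi"
            )
        self.log1ms = np.log1p(-self.s)
        self.n_tot = self.n.sum(axis=1)
        self.accepted = np.zeros_like(self.phi)
        self.batch_accepted = np.zeros_like(self.phi)


def sample_level(
    level_counts: CountTable,
    base_logp: dict[str, np.ndarray],
    level: int,
    config: SamplerConfig,
    seed: int,
    is_root: bool = False,
    init_phi: dict[str, np.ndarray] | None = None,
) -> LevelChain:
    """Run one adaptive MwG chain over all edges of all six trees at a level.

    ``base_logp[central]`` is the (contexts, 3) frozen log-probability
    contributed by shallower levels (zero at the root level, where the
    sampled parameter is theta itself under its Normal prior).  Deeper
    levels are implicitly zero, so aggregated counts give the exact
    likelihood.  Fixed seed implies a bit-identical chain.
    """
    rng = np.random.default_rng(seed)
    hyper = config.hyper(level)
    pi = hyper.pi_init
    inv2_spike = 1.0 / (2 * hyper.sigma_spike**2)
    inv2_slab = 1.0 / (2 * hyper.sigma_slab**2)
    states: dict[str, _GroupState] = {}
    for central in "AC":
        g = level_counts.N[central].shape[0]
        phi0 = np.zeros((g, 3)) if init_phi is None else np.array(init_phi[central], float)
        if is_root:
            phi0 = phi0 + config.theta_prior_mean * (init_phi is None)
        n = level_counts.n[central].astype(float)
        if config.init_log_scale is None:
            # random-walk preconditioning: the posterior sd of a log rate with
            # n events is ~n^-1/2, and the optimal Gaussian proposal ~2.4 sd
            log_scale = np.clip(np.log(2.4 / np.sqrt(n + 5.0)), -9.0, 0.0)
        else:
            log_scale = np.full((g, 3), float(config.init_log_scale))
        states[central] = _GroupState(
            N=level_counts.N[central].astype(float),
            n=n,
            base=np.asarray(base_logp[central], dtype=float),
            phi=phi0,
            delta=np.zeros((g, 3), dtype=np.int8),
            log_scale=log_scale,
        )

    n_draws = config.draws_per_chain
    saved_phi = {c: np.empty((n_draws, *states[c].phi.shape)) for c in "AC"}
    saved_delta = {c: np.zeros((n_draws, *states[c].phi.shape), dtype=np.int8) for c in "AC"}
    saved_pi = np.empty(n_draws)
    d = 0
    mu0, sd0 = config.theta_prior_mean, config.theta_prior_sd
    inv2_theta = 1.0 / (2 * sd0**2)

    for it in range(config.iterations):
        for central in "AC":
            st = states[central]
            for m in range(3):
                scale = np.exp(st.log_scale[:, m])
                eps = rng.standard_normal(st.phi.shape[0]) * scale
                phi_new = st.phi[:, m] + eps
                with np.errstate(over="ignore"):  # wild proposals become invalid
                    p_new = np.exp(st.base[:, m] + phi_new)
                s_new = st.s - st.p[:, m] + p_new
                valid = s_new < 1.0
                # clamp keeps log1p finite on the invalid entries; `valid`
                # in the acceptance mask makes their rejection certain
                log1ms_new = np.log1p(-np.minimum(s_new, 1 - 1e-12))
                dll = st.n[:, m] * eps + (st.N - st.n_tot) * (log1ms_new - st.log1ms)
                if is_root:
                    dlp = ((st.phi[:, m] - mu0) ** 2 - (phi_new - mu0) ** 2) * inv2_theta
                else:
                    inv2 = np.where(st.delta[:, m] == 1, inv2_slab, inv2_spike)
                    dlp = (st.phi[:, m] ** 2 - phi_new**2) * inv2
                accept = valid & (np.log(rng.random(phi_new.shape[0])) < dll + dlp)
                st.phi[:, m] = np.where(accept, phi_new, st.phi[:, m])
                st.p[:, m] = np.where(accept, p_new, st.p[:, m])
                st.s = np.where(accept, s_new, st.s)
                st.log1ms = np.where(accept, log1ms_new, st.log1ms)
                st.accepted[:, m] += accept
                st.batch_accepted[:, m] += accept
            if not is_root:
                st.delta = gibbs_update_delta(st.phi, pi, hyper, rng)
        if not is_root and config.fixed_pi is None:
            all_delta = np.concatenate([states[c].delta.ravel() for c in "AC"])
            pi = gibbs_update_pi(all_delta, hyper.beta_a, hyper.beta_b, rng)

        in_burnin = it < config.burnin
        if in_burnin and (it + 1) % config.adapt_batch == 0:
            batch_index = (it + 1) // config.adapt_batch
            for st in states.values():
                rate = st.batch_accepted / config.adapt_batch
                st.log_scale = adapt_proposals(
                    st.log_scale, rate, batch_index, config.target_accept
                )
                st.batch_accepted[:] = 0.0
        if not in_burnin and (it - config.burnin + 1) % config.thin == 0 and d < n_draws:
            for c, st in states.items():
                saved_phi[c][d] = st.phi
                saved_delta[c][d] = st.delta
            saved_pi[d] = pi
            d += 1

    return LevelChain(
        level=level,
        phi=saved_phi,
        delta=saved_delta,
        pi=saved_pi,
        accept_rate={c: states[c].accepted / max(config.iterations, 1) for c in "AC"},
        seed=seed,
        n_burnin=config.burnin,
        thin=config.thin,
    )


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor R-hat over (chains, draws, ...) arrays."""
    c, d = chains.shape[0], chains.shape[1]
    if c < 2 or d < 2:
        return np.full(chains.shape[2:], np.nan)
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean(axis=0)
    b = d * means.var(axis=0, ddof=1)
    var_plus = (d - 1) / d * w + b / d
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    return np.where(w > 0, rhat, 1.0)
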