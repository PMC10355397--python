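"""Model/Results objects wrapping the level-by-level sampler.

:class:`ContextTreeModel` is built from a finest-level :class:`CountTable`;
``fit()`` runs the adaptive Metropolis-within-Gibbs sampler level by level
(two chains by default) and returns a :class:`ContextTreeResults` carrying
posterior means, quantiles, posterior inclusion probabilities, convergence
diagnostics and the pooled draws needed for downstream model comparison.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from . import contexts as ctx
from .contexts import MutationType, TreeSet, alts_for, make_tree_set
from .inference import LevelChain, SamplerConfig, gelman_rubin, sample_level
from .tabulate import CountTable, ProbabilityTable, aggregate_to_level

EDGE_QUANTILES = (0.025, 0.05, 0.25, 0.5, 0.75, 0.95, 0.975)


class ContextTreeModel:
    """Hierarchical sequence-context model of polymorphism probabilities.

    Parameters
    ----------
    counts
        Finest-level count table (occurrence totals and per-alternate
        polymorphism counts).  Its level bounds the tree depth.
    K
        Tree depth to fit; defaults to the table's level.  Must be reachable
        by the table's architecture (odd for symmetric trees).
    config
        Sampler schedule and priors; defaults to :class:`SamplerConfig`.
    """

    def __init__(self, counts: CountTable, K: int | None = None,
                 config: SamplerConfig | None = None):
        counts.validate()
        self.architecture = counts.architecture
        self.K = int(K) if K is not None else counts.level
        if self.K > counts.level:
            raise ValueError(f"K={self.K} exceeds count table level {counts.level}")
        self.levels = ctx.levels_for(self.K, self.architecture)
        self.counts = aggregate_to_level(counts, self.K)
        self.config = config or SamplerConfig()

    @classmethod
    def from_tsv(cls, path, **kw) -> "ContextTreeModel":
        return cls(CountTable.read_tsv(path), **kw)

    def fit(self, seed: int = 0, chains: int | None = None) -> "ContextTreeResults":
        """Sample the posterior level by level and summarize it."""
        cfg = self.config
        n_chains = chains if chains is not None else cfg.chains
        seed_rng = np.random.default_rng(seed)
        chain_seeds = seed_rng.integers(2**31, size=(len(self.levels), n_chains))
        trees = make_tree_set(self.K, self.architecture)
        draws: dict[int, dict] = {}
        bases: dict[int, dict[str, np.ndarray]] = {}
        rhat: dict[int, dict[str, np.ndarray]] = {}
        accept: dict[int, dict[str, float]] = {}
        warnings: list[str] = []

        for li, level in enumerate(self.levels):
            level_counts = aggregate_to_level(self.counts, level)
            is_root = level == self.levels[0]
            base = {}
            for central in "AC":
                if is_root:
                    base[central] = np.zeros((1, 3))
                else:
                    pmap = ctx.parent_index_map(level, self.architecture)
                    cols = []
                    for alt in alts_for(central):
                        cum = trees[f"{central}>{alt}"].cumulative_log_p(
                            ctx.parent_level(level, self.architecture)
                        )
                        cols.append(cum[pmap])
                    base[central] = np.column_stack(cols)
            level_chains: list[LevelChain] = [
                sample_level(level_counts, base, level, cfg,
                             seed=int(chain_seeds[li, c]), is_root=is_root)
                for c in range(n_chains)
            ]
            pooled_phi = {c: np.concatenate([lc.phi[c] for lc in level_chains])
                          for c in "AC"}
            pooled_delta = {c: np.concatenate([lc.delta[c] for lc in level_chains])
                            for c in "AC"}
            pooled_pi = np.concatenate([lc.pi for lc in level_chains])
            draws[level] = {"phi": pooled_phi, "delta": pooled_delta, "pi": pooled_pi}
            bases[level] = base
            rhat[level] = {
                c: gelman_rubin(np.stack([lc.phi[c] for lc in level_chains]))
                for c in "AC"
            }
            accept[level] = {
                c: float(np.mean([lc.accept_rate[c] for lc in level_chains]))
                for c in "AC"
            }
            worst = max(np.nanmax(rhat[level][c]) for c in "AC")
            if n_chains >= 2 and worst > cfg.rhat_threshold:
                warnings.append(
                    f"level {level}: max R-hat {worst:.3f} exceeds {cfg.rhat_threshold}"
                )
            for central in "AC":
                mean = pooled_phi[central].mean(axis=0)
                for j, alt in enumerate(alts_for(central)):
                    tree = trees[f"{central}>{alt}"]
                    if is_root:
                        tree.theta = float(mean[0, j])
                    else:
                        tree.phi[level] = mean[:, j]

        return ContextTreeResults(
            model=self, trees=trees, draws=draws, bases=bases, rhat=rhat,
            accept=accept, seed=seed, n_chains=n_chains, warnings=warnings,
        )


class ContextTreeResults:
    """Posterior summaries and draws of a fitted context-tree model.

    Node posteriors condition on the level-by-level scheme: the log
    probability draws of a level-``k`` node are the frozen posterior-mean
    path through level ``k-1`` plus that node's own level-``k`` edge draws.
    """

    def __init__(self, model: ContextTreeModel, trees: TreeSet, draws, bases,
                 rhat, accept, seed: int, n_chains: int, warnings: list[str]):
        self.model = model
        self.trees = trees
        self.draws = draws
        self.bases = bases
        self.rhat = rhat
        self.accept = accept
        self.seed = seed
        self.n_chains = n_chains
        self.warnings = warnings
        self.architecture = model.architecture
        self.K = model.K
        self.levels = model.levels
        self.config = model.config

    @property
    def converged(self) -> bool:
        return not self.warnings

    # -- draw accessors ----------------------------------------------------

    def phi_draws(self, level: int, mtype: MutationType | str) -> np.ndarray:
        """(draws, contexts) posterior draws of the level's edge shifts."""
        if isinstance(mtype, str):
            mtype = MutationType.from_string(mtype)
        return self.draws[level]["phi"][mtype.ref][:, :, mtype.alt_index]

    def node_log_draws(self, level: int, mtype: MutationType | str) -> np.ndarray:
        """(draws, contexts) posterior draws of node log probabilities."""
        if isinstance(mtype, str):
            mtype = MutationType.from_string(mtype)
        base = self.bases[level][mtype.ref][:, mtype.alt_index]
        return base[None, :] + self.phi_draws(level, mtype)

    def pip(self, level: int, mtype: MutationType | str | None = None):
        """Posterior inclusion probability (mean slab membership) of edges."""
        if level == self.levels[0]:
            raise ValueError("the root level has no inclusion indicators")
        if mtype is None:
            return {c: self.draws[level]["delta"][c].mean(axis=0) for c in "AC"}
        if isinstance(mtype, str):
            mtype = MutationType.from_string(mtype)
        return self.draws[level]["delta"][mtype.ref][:, :, mtype.alt_index].mean(axis=0)

    def credible_interval(self, context: str, mtype: MutationType | str,
                          mass: float = 0.95) -> tuple[float, float]:
        """Equal-tailed credible interval of a node's polymorphism probability."""
        if not 0 < mass < 1:
            raise ValueError("mass must be in (0,1)")
        if isinstance(mtype, str):
            mtype = MutationType.from_string(mtype)
        level = len(context)
        if level not in self.levels:
            raise ctx.UnknownContextError(f"no level-{level} contexts in this fit")
        idx = ctx.context_index(context, self.architecture)
        draws = np.exp(self.node_log_draws(level, mtype)[:, idx])
        lo, hi = np.quantile(draws, [(1 - mass) / 2, 1 - (1 - mass) / 2])
        return float(lo), float(hi)

    def node_probabilities(self, level: int) -> ProbabilityTable:
        """Posterior-mean polymorphism probabilities at a level."""
        p = {}
        for central in "AC":
            cols = [
                np.exp(self.node_log_draws(level, f"{central}>{alt}")).mean(axis=0)
                for alt in alts_for(central)
            ]
            p[central] = np.column_stack(cols)
        return ProbabilityTable(level, self.architecture, p)

    # -- tabular summaries -------------------------------------------------

    def edge_summary(self, levels=None) -> pd.DataFrame:
        """One row per edge: posterior mean/quantiles of phi and the PIP."""
        rows = []
        for level in levels or self.levels[1:]:
            for central in "AC":
                names = ctx.enumerate_level(central, level, self.architecture)
                for j, alt in enumerate(alts_for(central)):
                    phi = self.draws[level]["phi"][central][:, :, j]
                    q = np.quantile(phi, EDGE_QUANTILES, axis=0)
                    df = pd.DataFrame({
                        "mutation_type": f"{central}>{alt}",
                        "context": names,
                        "level": level,
                        "phi_mean": phi.mean(axis=0),
                        "pip": self.draws[level]["delta"][central][:, :, j].mean(axis=0),
                        "rhat": self.rhat[level][central][:, j],
                    })
                    for qi, qv in zip(EDGE_QUANTILES, q):
                        df[f"phi_q{qi:g}"] = qv
                    rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        """Human-readable fit report."""
        cfg = self.config
        lines = [
            "Sequence-context tree model (adaptive Metropolis-within-Gibbs)",
            f"architecture: {self.architecture}   K: {self.K}   chains: {self.n_chains}",
            f"iterations/level: {cfg.iterations} (burn-in {cfg.burnin}, thin {cfg.thin})",
            f"seed: {self.seed}   converged: {self.converged}",
            "",
            f"{'level':>5} {'edges':>7} {'PIP>0.95':>9} {'mean pi':>8} "
            f"{'accept':>7} {'max Rhat':>9}",
        ]
        for level in self.levels:
            n_edges = 6 * ctx.n_contexts(level)
            if level == self.levels[0]:
                frac = float("nan")
                pi = float("nan")
            else:
                pips = np.concatenate([self.pip(level)[c].ravel() for c in "AC"])
                frac = float((pips > 0.95).mean())
                pi = float(self.draws[level]["pi"].mean())
            acc = np.mean([self.accept[level][c] for c in "AC"])
            worst = max(np.nanmax(self.rhat[level][c]) for c in "AC")
            lines.append(
                f"{level:>5} {n_edges:>7} {frac:>9.3f} {pi:>8.3f} {acc:>7.3f} {worst:>9.3f}"
            )
        lines.append("")
        lines.append("base polymorphism probabilities exp(theta):")
        for name in sorted(self.trees):
            lines.append(f"  {name}: {np.exp(self.trees[name].theta):.3g}")
        if self.warnings:
            lines.append("")
            lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "chains": self.n_chains,
            "config": dataclasses.asdict(self.config),
            "architecture": self.architecture,
            "K": self.K,
            "warnings": self.warnings,
            "counts_provenance": self.model.counts.provenance,
        }

    def save(self, path) -> None:
        """Write the versioned JSON model document with per-edge statistics."""
        edge_stats: dict = {}
        for central in "AC":
            for alt in alts_for(central):
                name = f"{central}>{alt}"
                j = alts_for(central).index(alt)
                edge_stats[name] = {}
                for level in self.levels[1:]:
                    phi = self.draws[level]["phi"][central][:, :, j]
                    edge_stats[name][level] = {
                        "phi_quantiles": np.quantile(phi, EDGE_QUANTILES, axis=0).T,
                        "pip": self.pip(level, name),
                    }
        ctx.save_tree_set(self.trees, path, edge_stats=edge_stats,
                          provenance=self.provenance())

    def save_chains(self, path) -> None:
        """Persist pooled draws to HDF5, keyed by level/central base."""
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs["provenance"] = json.dumps(self.provenance())
            for level in self.levels:
                grp = h5.create_group(f"level{level}")
                grp.create_dataset("pi", data=self.draws[level]["pi"])
                for central in "AC":
                    g = grp.create_group(central)
                    g.create_dataset("phi", data=self.draws[level]["phi"][central])
                    g.create_dataset("delta", data=self.draws[level]["delta"][central])
                    g.create_dataset("base", data=self.bases[level][central])


def fit(counts: CountTable, K: int | None = None,
        config: SamplerConfig | None = None, seed: int = 0,
        chains: int | None = None) -> ContextTreeResults:
    """One-call convenience wrapper: build the model and fit it."""
    return ContextTreeModel(counts, K=K, config=config).fit(seed=seed, chains=chains)
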