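"""Synthetic truth generation and the simulation experiments.

The generator emulates the qualitative structure of genome-scale polymorphism
data: per-context occurrence totals spanning orders of magnitude (log-normal
allocation), base polymorphism probabilities around 1e-3 to 1e-1 with the
CpG transition an order of magnitude above the rest, and per-level edge
shifts that are mostly zero, with the nonzero fraction decaying as the
context window grows.  Counts are then one multinomial draw per context.

Two experiment harnesses mirror the method's own validation: a
credible-interval calibration study (simulate -> fit -> coverage), and a
spike-in power study where one of two otherwise identical populations gets a
known log-shift (NLPPR) planted at target contexts and detection uses the
dual posterior-overlap criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import contexts as ctx
from .contexts import TreeSet, alts_for, make_tree_set, n_contexts
from .evaluate import CalibrationReport, calibration
from .compare import detect_divergence
from .inference import SamplerConfig
from .model import ContextTreeModel, ContextTreeResults
from .tabulate import CountTable, ProbabilityTable

#: Per-level fraction of nonzero edges (levels 1-5; level 1 is the root).
DEFAULT_GAMMA = (1.0, 0.5, 0.3, 0.15, 0.08)
DEFAULT_TAU = 0.4
DEFAULT_BASE_RANGE = (0.002, 0.02)
DEFAULT_CPG_BOOST = 10.0
_SIMPLEX_CAP = 0.5  # reject truths whose total alternate probability exceeds this


def _gamma_for(level: int, gamma) -> float:
    if isinstance(gamma, dict):
        return float(gamma[level])
    seq = list(gamma)
    while len(seq) < level:
        seq.append(seq[-1] / 2.0)
    return float(seq[level - 1])


def _cpg_level(architecture: str) -> int:
    """First level whose window includes the 3' neighbor (the CpG base)."""
    for level in ctx.levels_for(9, architecture)[1:]:
        if ctx.flank_widths(level, architecture)[1] >= 1:
            return level
    raise AssertionError("unreachable")


@dataclass
class TruthTable:
    """Known probability trees plus occurrence totals: the simulation truth."""

    trees: TreeSet
    totals: dict[str, np.ndarray]  # central base -> finest-level occurrence totals
    config: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return next(iter(self.trees.values())).K

    @property
    def architecture(self) -> str:
        return next(iter(self.trees.values())).architecture

    @property
    def levels(self) -> list[int]:
        return ctx.levels_for(self.K, self.architecture)

    def finest_probabilities(self) -> ProbabilityTable:
        return ProbabilityTable.from_trees(self.trees, self.K)

    def totals_at_level(self, level: int) -> dict[str, np.ndarray]:
        out = {}
        for c in "AC":
            tot = self.totals[c].astype(np.int64)
            lvl = self.K
            while lvl > level:
                pmap = ctx.parent_index_map(lvl, self.architecture)
                lvl = ctx.parent_level(lvl, self.architecture)
                tot = np.bincount(pmap, weights=tot, minlength=n_contexts(lvl)).astype(np.int64)
            out[c] = tot
        return out

    def aggregate_probability(self, level: int) -> ProbabilityTable:
        """Occurrence-weighted true polymorphism probability at a coarser level.

        This is the generating value of a level-``level`` context: the
        chance that a random occurrence under that context is polymorphic,
        i.e. the quantity a level-``level`` fit estimates.
        """
        fine = self.finest_probabilities()
        p = {}
        for c in "AC":
            w = self.totals[c].astype(float)
            num = fine.p[c] * w[:, None]
            den = w.copy()
            lvl = self.K
            while lvl > level:
                pmap = ctx.parent_index_map(lvl, self.architecture)
                lvl = ctx.parent_level(lvl, self.architecture)
                g = n_contexts(lvl)
                num = np.column_stack(
                    [np.bincount(pmap, weights=num[:, j], minlength=g) for j in range(3)]
                )
                den = np.bincount(pmap, weights=den, minlength=g)
            safe = np.where(den > 0, den, 1.0)
            p[c] = num / safe[:, None]
        return ProbabilityTable(level, self.architecture, p)

    def simulate_counts(self, seed: int) -> CountTable:
        """One multinomial draw of polymorphism counts per finest context."""
        rng = np.random.default_rng(seed)
        fine = self.finest_probabilities()
        table = CountTable(self.K, self.architecture,
                           provenance={"simulated": True, "seed": int(seed)})
        for c in "AC":
            p = fine.p[c]
            pvals = np.column_stack([p, 1.0 - p.sum(axis=1)])
            draws = rng.multinomial(self.totals[c], pvals)
            table.N[c] = self.totals[c].astype(np.int64)
            table.n[c] = draws[:, :3].astype(np.int64)
        table.validate()
        return table

    def to_json(self, path) -> None:
        doc = ctx.tree_set_to_dict(self.trees, provenance={"truth": True, **self.config})
        doc["totals"] = {c: self.totals[c].tolist() for c in "AC"}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            doc = json.load(fh)
        trees = ctx.tree_set_from_dict(doc)
        totals = {c: np.asarray(doc["totals"][c], dtype=np.int64) for c in "AC"}
        return cls(trees, totals, doc.get("provenance", {}))


def make_truth(
    seed: int,
    K: int = 5,
    architecture: str = ctx.RIGHT_ASYMMETRIC,
    gamma=DEFAULT_GAMMA,
    tau: float | dict = DEFAULT_TAU,
    base_range: tuple[float, float] = DEFAULT_BASE_RANGE,
    cpg_boost: float = DEFAULT_CPG_BOOST,
    totals: dict[str, np.ndarray] | None = None,
) -> TruthTable:
    """Draw a ground-truth tree set with sparse, level-decaying edge shifts.

    Base probabilities are log-uniform over ``base_range`` per mutation type;
    the CpG>T effect is planted as a ``ln(cpg_boost)`` shift on the first
    edge whose window sees the 3' neighbor.  Each deeper edge is nonzero
    with probability ``gamma[level]`` and then Normal(0, tau^2).  Truths
    whose total alternate probability would leave a context with less than
    half its mass unpolymorphed are rejected and redrawn edge-wise.
    """
    rng = np.random.default_rng(seed)
    trees = make_tree_set(K, architecture)
    lo, hi = np.log(base_range[0]), np.log(base_range[1])
    for name in sorted(trees):
        trees[name].theta = float(rng.uniform(lo, hi))

    def tau_for(level):
        return float(tau[level]) if isinstance(tau, dict) else float(tau)

    boost_level = _cpg_level(architecture) if cpg_boost and cpg_boost != 1.0 else None
    levels = ctx.levels_for(K, architecture)
    for name in sorted(trees):
        tree = trees[name]
        for level in levels[1:]:
            g = n_contexts(level)
            mask = rng.random(g) < _gamma_for(level, gamma)
            tree.phi[level] = np.where(mask, rng.normal(0.0, tau_for(level), g), 0.0)
    if boost_level is not None and boost_level <= K:
        tree = trees["C>T"]
        n5, _ = ctx.flank_widths(boost_level, architecture)
        for i, name_ctx in enumerate(ctx.enumerate_level("C", boost_level, architecture)):
            if name_ctx[n5 + 1] == "G":
                tree.phi[boost_level][i] += np.log(cpg_boost)

    # edge-wise rejection: redraw the finest shifts of any context whose
    # alternate probabilities eat too much of the simplex
    for _ in range(1000):
        fine = ProbabilityTable.from_trees(trees, K)
        bad = {c: fine.p[c].sum(axis=1) > _SIMPLEX_CAP for c in "AC"}
        if not any(b.any() for b in bad.values()):
            break
        for central in "AC":
            idx = np.flatnonzero(bad[central])
            if idx.size == 0:
                continue
            for alt in alts_for(central):
                tree = trees[f"{central}>{alt}"]
                lvl = levels[-1]
                nz = tree.phi[lvl][idx] != 0
                redraw = rng.normal(0.0, tau_for(lvl), idx.size)
                tree.phi[lvl][idx] = np.where(nz, redraw, tree.phi[lvl][idx])
                # damp the whole path if the finest edges were already zero
                tree.phi[lvl][idx] = np.where(nz, tree.phi[lvl][idx],
                                              tree.phi[lvl][idx] - 0.1)
    else:
        raise RuntimeError("could not draw a simplex-valid truth table")

    if totals is None:
        totals = make_totals(seed + 1, K, total_positions=10**6, architecture=architecture)
    cfg = {
        "seed": int(seed), "K": K, "architecture": architecture,
        "gamma": list(gamma) if not isinstance(gamma, dict) else gamma,
        "tau": tau, "base_range": list(base_range), "cpg_boost": cpg_boost,
    }
    return TruthTable(trees, totals, cfg)


def make_totals(
    seed: int,
    K: int,
    total_positions: int,
    dispersion: float = 1.0,
    architecture: str = ctx.RIGHT_ASYMMETRIC,
) -> dict[str, np.ndarray]:
    """Allocate genome positions to finest contexts with log-normal skew.

    A deterministic largest-remainder rounding makes the totals sum exactly
    to ``total_positions``; dispersion 0 gives equal totals.
    """
    if total_positions <= 0:
        raise ValueError("total_positions must be positive")
    rng = np.random.default_rng(seed)
    g = n_contexts(K)
    weights = np.exp(rng.normal(0.0, dispersion, 2 * g)) if dispersion > 0 else np.ones(2 * g)
    shares = weights / weights.sum() * total_positions
    alloc = np.floor(shares).astype(np.int64)
    remainder = int(total_positions - alloc.sum())
    if remainder:
        order = np.argsort(-(shares - np.floor(shares)), kind="stable")
        alloc[order[:remainder]] += 1
    return {"A": alloc[:g].copy(), "C": alloc[g:].copy()}


def spike_in(truth: TruthTable, context: str, mutation_type: str,
             nlppr: float) -> TruthTable:
    """Plant a known log-shift on a context's incoming edge.

    The target node's polymorphism probability is multiplied by
    ``exp(nlppr)`` and, by tree composition, so is every finest-level
    descendant.  The rest of the model is untouched.
    """
    trees = {name: tree.copy() for name, tree in truth.trees.items()}
    tree = trees[mutation_type]
    level = len(context)
    if level == 1:
        tree.theta += nlppr
    else:
        tree.phi[level][ctx.context_index(context, truth.architecture)] += nlppr
    out = TruthTable(trees, {c: truth.totals[c].copy() for c in "AC"},
                     {**truth.config, "spike": (context, mutation_type, nlppr)})
    fine = out.finest_probabilities()
    for c in "AC":
        if (fine.p[c].sum(axis=1) >= 1.0).any():
            raise ValueError("spike-in pushes a context off the probability simplex")
    return out


def select_power_contexts(
    truth: TruthTable,
    level: int,
    min_occurrences: int = 10**6,
    prob_range: tuple[float, float] = (0.005, 0.15),
    n_contexts: int | None = None,
) -> list[tuple[str, str]]:
    """Pick spike-in target context-mutations spread across the trees.

    Eligible cells need at least ``min_occurrences`` genomic occurrences and
    a generating probability inside ``prob_range``.  Targets are spread
    round-robin over (mutation type, parent context) groups: spiking many
    siblings of the same parent would let the parent edge absorb the shift
    and defeat the incoming-edge detection criterion by construction.  With
    ``n_contexts`` unset, one target per group is taken.  Selection is
    deterministic (most-occurrences-first within each group).
    """
    agg = truth.aggregate_probability(level)
    totals = truth.totals_at_level(level)
    groups: list[list[tuple[str, str]]] = []
    for central in "AC":
        names = ctx.enumerate_level(central, level, truth.architecture)
        for j, alt in enumerate(alts_for(central)):
            by_parent: dict[str, list[tuple[int, str]]] = {}
            for i, name in enumerate(names):
                p = agg.p[central][i, j]
                if totals[central][i] >= min_occurrences and prob_range[0] <= p <= prob_range[1]:
                    parent = ctx.parent_context(name, truth.architecture) if level > 1 else ""
                    by_parent.setdefault(parent, []).append((int(totals[central][i]), name))
            for parent in sorted(by_parent):
                ranked = sorted(by_parent[parent], key=lambda t: (-t[0], t[1]))
                groups.append([(name, f"{central}>{alt}") for _, name in ranked])
    want = len(groups) if n_contexts is None else n_contexts
    chosen: list[tuple[str, str]] = []
    depth = 0
    while len(chosen) < want and any(depth < len(g) for g in groups):
        for g in groups:
            if depth < len(g) and len(chosen) < want:
                chosen.append(g[depth])
        depth += 1
    if len(chosen) < want:
        raise ValueError(
            f"only {len(chosen)} eligible context-mutations (requested {want})"
        )
    return chosen


@dataclass
class PowerGrid:
    """Per (context, NLPPR) detection power plus the per-level >80% summary."""

    grid: pd.DataFrame
    replicates: int
    threshold: float
    excluded: int = 0

    def fraction_powered(self, nlppr: float, level: int,
                         power_floor: float = 0.8) -> float:
        sel = self.grid[(self.grid.nlppr == nlppr) & (self.grid.level == level)]
        if sel.empty:
            raise ValueError(f"no tested contexts at nlppr={nlppr}, level={level}")
        return float((sel.power > power_floor).mean())


def power_experiment(
    truth: TruthTable,
    test_contexts: list[tuple[str, str]],
    nlppr_list,
    replicates: int,
    fit_config: SamplerConfig,
    threshold: float = 0.01,
    seed: int = 0,
    chains: int = 2,
) -> PowerGrid:
    """Paired spike-in power study with the dual overlap detection rule.

    For each NLPPR, all ``test_contexts`` (context string, mutation type)
    are spiked simultaneously into a copy of ``truth``; per replicate a null
    and a spiked count table are simulated and fitted, and each target
    counts as detected when both its node-probability and incoming-edge
    posterior overlaps fall below ``threshold``.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    totals_by_level = {lvl: truth.totals_at_level(lvl) for lvl in truth.levels}
    rows = []
    excluded = 0
    for nlppr in nlppr_list:
        spiked = truth
        for context, mtype in test_contexts:
            spiked = spike_in(spiked, context, mtype, nlppr)
        detected = {tc: 0 for tc in test_contexts}
        used = 0
        for _ in range(replicates):
            s_null, s_alt, s_fit_a, s_fit_b = rng.integers(2**31, size=4)
            counts_null = truth.simulate_counts(int(s_null))
            counts_alt = spiked.simulate_counts(int(s_alt))
            res_a = ContextTreeModel(counts_null, config=fit_config).fit(
                seed=int(s_fit_a), chains=chains)
            res_b = ContextTreeModel(counts_alt, config=fit_config).fit(
                seed=int(s_fit_b), chains=chains)
            if not (res_a.converged and res_b.converged):
                excluded += 1
                continue
            used += 1
            hits = detect_divergence(res_a, res_b, threshold=threshold)
            hit_keys = set(zip(hits.context, hits.mutation_type))
            for tc in test_contexts:
                if tc in hit_keys:
                    detected[tc] += 1
        for (context, mtype) in test_contexts:
            level = len(context)
            idx = ctx.context_index(context, truth.architecture)
            central = mtype.split(">")[0]
            rows.append({
                "level": level,
                "context": context,
                "mutation_type": mtype,
                "nlppr": float(nlppr),
                "occurrences": int(totals_by_level[level][central][idx]),
                "power": detected[(context, mtype)] / used if used else np.nan,
                "replicates_used": used,
            })
    return PowerGrid(pd.DataFrame(rows), replicates, threshold, excluded)


def calibration_study(
    replicates: int,
    fit_config: SamplerConfig,
    seed: int = 0,
    K: int = 5,
    total_positions: int = 50_000_000,
    dispersion: float = 1.0,
    masses=(0.90, 0.95, 0.99),
) -> CalibrationReport:
    """The credible-interval calibration study at its standard conditions.

    Each replicate draws a fresh default-generator truth (sparse decaying
    shifts, CpG-boosted transitions) with log-normal occurrence totals
    spanning orders of magnitude, simulates counts, fits the model with two
    chains, and pools coverage of the generating probabilities across all
    context sizes.
    """

    def factory(s: int) -> TruthTable:
        totals = make_totals(s + 1, K, total_positions, dispersion)
        return make_truth(s, K=K, totals=totals)

    return calibration_experiment(factory, replicates, fit_config, seed=seed,
                                  masses=masses)


def power_study(
    nlppr_list,
    replicates: int,
    fit_config: SamplerConfig,
    seed: int = 0,
    level: int = 3,
    n_contexts: int = 24,
    min_occurrences: int = 10**6,
    prob_range: tuple[float, float] = (0.005, 0.15),
    total_positions: int = 64_000_000,
    dispersion: float = 0.25,
    threshold: float = 0.01,
) -> PowerGrid:
    """The spike-in power study at the 3-mer level, standard conditions.

    A single truth with abundant occurrences (every 3-mer context at or
    above ``min_occurrences``) and base probabilities inside ``prob_range``
    supplies the null population; targets spread across trees and parents
    are spiked at each NLPPR and detected with the dual <1% overlap rule.
    """
    rng = np.random.default_rng(seed)
    s_truth = int(rng.integers(2**31))
    s_exp = int(rng.integers(2**31))
    totals = make_totals(s_truth + 1, level, total_positions, dispersion)
    truth = make_truth(s_truth, K=level, totals=totals,
                       base_range=(0.005, 0.03), cpg_boost=4.0, tau=0.35)
    targets = select_power_contexts(truth, level, min_occurrences=min_occurrences,
                                    prob_range=prob_range, n_contexts=n_contexts)
    return power_experiment(truth, targets, nlppr_list, replicates, fit_config,
                            threshold=threshold, seed=s_exp)


def calibration_experiment(
    truth_factory,
    replicates: int,
    fit_config: SamplerConfig,
    seed: int = 0,
    masses=(0.90, 0.95, 0.99),
    chains: int = 2,
) -> CalibrationReport:
    """Simulate -> fit -> coverage, pooled over replicate truth tables.

    ``truth_factory`` maps a seed to a :class:`TruthTable` (pass
    ``lambda s: truth`` to reuse a fixed table).  Each replicate draws its
    own counts, fits the model, and checks whether the generating
    (occurrence-weighted) probability of every context-mutation lies inside
    the fitted equal-tailed credible intervals.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(replicates):
        s_truth, s_counts, s_fit = rng.integers(2**31, size=3)
        truth = truth_factory(int(s_truth))
        counts = truth.simulate_counts(int(s_counts))
        res = ContextTreeModel(counts, config=fit_config).fit(
            seed=int(s_fit), chains=chains)
        reports.append(calibration(truth, [res], masses=masses))
    return CalibrationReport.pool(reports)
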