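"""Cross-model comparison: posterior-overlap divergence detection, NLPPR
effect sizes, largest-shift edge ranking, and tail motif enrichment.

Two fitted models (e.g. two populations) are compared context by context.
The fraction overlap of two posterior sample sets is a proxy for the
probability that the underlying parameter is the same; a context-mutation is
flagged as divergent only when both its node-probability posterior and the
posterior of its incoming edge overlap below a threshold (default 1%) — the
edge condition keeps a single upstream shift from flagging its whole
subtree.  Effect sizes are reported as NLPPR, the natural log of the ratio
of posterior-mean polymorphism probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import contexts as ctx
from .contexts import MutationType, TreeSet, alts_for

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def nlppr(p_a: float, p_b: float) -> float:
    """Natural log of the polymorphism probability ratio (antisymmetric)."""
    if p_a <= 0 or p_b <= 0:
        raise ValueError("probabilities must be positive")
    return math.log(p_a / p_b)


def overlap(samples_a, samples_b, n_bins: int = 100) -> float:
    """Fraction overlap of two posterior sample sets.

    Histograms both sets on shared equal-width bins spanning the pooled
    range and sums the bin-wise minimum of the two empirical fractions.
    Deterministic given the draws; 1.0 for identical sample vectors, 0.0
    for disjoint supports.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample set")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 1.0  # both constant at the same value
    edges = np.linspace(lo, hi, n_bins + 1)
    fa = np.histogram(a, bins=edges)[0] / a.size
    fb = np.histogram(b, bins=edges)[0] / b.size
    return float(np.minimum(fa, fb).sum())


def _overlap_upper_bound(a: np.ndarray, b: np.ndarray) -> float:
    """Cheap Gaussian-approximation bound used to skip exact overlap work.

    Two distributions whose means differ by ``d`` pooled standard
    deviations overlap at least ~2*Phi(-d/2) under normality; requiring
    d >= 8 before the exact histogram is computed keeps every overlap that
    could plausibly exceed ~1e-2 (2*Phi(-4) ~ 6e-5 leaves two orders of
    margin for non-normal tails).
    """
    sd = a.std() + b.std()
    if sd == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    d = abs(a.mean() - b.mean()) / sd
    return 1.0 if d < 8.0 else 0.0


@dataclass
class DivergenceHit:
    context: str
    mutation_type: str
    level: int
    nlppr: float
    node_overlap: float
    shift_difference: float
    edge_overlap: float


def detect_divergence(res_a, res_b, threshold: float = 0.01,
                      levels=None, n_bins: int = 100) -> pd.DataFrame:
    """Contexts whose node and incoming-edge posteriors both barely overlap.

    ``res_a``/``res_b`` are fitted results over the same context universe.
    Returns a table mirroring the divergence-report layout: context,
    mutation type, NLPPR (from posterior-mean probabilities), node overlap,
    posterior-mean shift difference, and incoming-edge overlap.
    """
    if res_a.architecture != res_b.architecture or res_a.K != res_b.K:
        raise ctx.IncompatibleModelsError("fits do not share architecture/K")
    hits: list[DivergenceHit] = []
    for level in levels or res_a.levels:
        for central in "AC":
            for alt in alts_for(central):
                mtype = f"{central}>{alt}"
                node_a = res_a.node_log_draws(level, mtype)
                node_b = res_b.node_log_draws(level, mtype)
                edge_a = res_a.phi_draws(level, mtype)
                edge_b = res_b.phi_draws(level, mtype)
                d = min(node_a.shape[0], node_b.shape[0])
                if node_a.shape[0] != node_b.shape[0]:
                    warnings.warn(
                        f"draw counts differ ({node_a.shape[0]} vs {node_b.shape[0]}); "
                        f"truncating to {d}"
                    )
                node_a, node_b = node_a[:d], node_b[:d]
                edge_a, edge_b = edge_a[:d], edge_b[:d]
                names = ctx.enumerate_level(central, level, res_a.architecture)
                prefilter = threshold <= 0.05  # the bound is only safe far in the tail
                for i, name in enumerate(names):
                    if prefilter and _overlap_upper_bound(node_a[:, i], node_b[:, i]) >= threshold:
                        continue
                    node_ov = overlap(node_a[:, i], node_b[:, i], n_bins)
                    if node_ov >= threshold:
                        continue
                    if not prefilter or _overlap_upper_bound(edge_a[:, i], edge_b[:, i]) < threshold:
                        edge_ov = overlap(edge_a[:, i], edge_b[:, i], n_bins)
                    else:
                        edge_ov = 1.0
                    if edge_ov >= threshold:
                        continue
                    mean_pa = float(np.exp(node_a[:, i]).mean())
                    mean_pb = float(np.exp(node_b[:, i]).mean())
                    hits.append(DivergenceHit(
                        context=name, mutation_type=mtype, level=level,
                        nlppr=nlppr(mean_pa, mean_pb), node_overlap=node_ov,
                        shift_difference=float(edge_a[:, i].mean() - edge_b[:, i].mean()),
                        edge_overlap=edge_ov,
                    ))
    return pd.DataFrame(
        [h.__dict__ for h in hits],
        columns=["context", "mutation_type", "level", "nlppr",
                 "node_overlap", "shift_difference", "edge_overlap"],
    )


def rank_edges(model, level: int, top_k: int | None = None) -> pd.DataFrame:
    """Edges of a level ranked by absolute posterior-mean shift.

    ``model`` is a fitted results object or a plain tree set.  Ties break
    lexicographically by (mutation type, context).
    """
    rows = []
    if isinstance(model, dict):  # TreeSet
        trees: TreeSet = model
        arch = next(iter(trees.values())).architecture
        for name in sorted(trees):
            tree = trees[name]
            if level not in tree.phi:
                raise ValueError(f"tree has no level {level} edges")
            for i, context in enumerate(ctx.enumerate_level(tree.mutation_type.ref,
                                                            level, arch)):
                rows.append({"mutation_type": name, "context": context,
                             "phi_mean": float(tree.phi[level][i])})
        df = pd.DataFrame(rows)
    else:
        df = model.edge_summary(levels=[level])[["mutation_type", "context", "phi_mean"]]
    df = df.sort_values(["mutation_type", "context"], kind="stable")
    df = df.sort_values("phi_mean", key=lambda s: -s.abs(), kind="stable")
    df = df.reset_index(drop=True)
    return df if top_k is None else df.head(top_k)


def _motif_matches(names: list[str], motif: str) -> np.ndarray:
    if len(motif) != len(names[0]):
        raise ValueError(
            f"motif {motif!r} length {len(motif)} does not match "
            f"context length {len(names[0])} (motifs are anchored)"
        )
    allowed = [IUPAC[ch] for ch in motif.upper()]
    return np.array(
        [all(b in allowed[i] for i, b in enumerate(name)) for name in names]
    )


def tail_motif_enrichment(probs, motifs: dict[str, str],
                          tail_fraction: float = 0.01,
                          tail: str = "top") -> pd.DataFrame:
    """Hypergeometric enrichment of anchored IUPAC motifs in probability tails.

    For each mutation type, contexts are ranked by probability; the test
    asks whether a motif's matches are over-represented among the extreme
    ``tail_fraction`` of contexts relative to its background frequency.
    One-sided p-values are Bonferroni-adjusted across motifs.
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    if tail not in ("top", "bottom"):
        raise ValueError("tail must be 'top' or 'bottom'")
    rows = []
    n_tests = 0
    for central in "AC":
        names = ctx.enumerate_level(central, probs.level, probs.architecture)
        for j, alt in enumerate(alts_for(central)):
            p = probs.p[central][:, j]
            g = len(names)
            k_tail = max(1, int(math.ceil(tail_fraction * g)))
            order = np.argsort(-p if tail == "top" else p, kind="stable")
            in_tail = np.zeros(g, dtype=bool)
            in_tail[order[:k_tail]] = True
            for motif_name, motif in motifs.items():
                match = _motif_matches(names, motif)
                m = int(match.sum())
                k = int((match & in_tail).sum())
                pval = float(stats.hypergeom.sf(k - 1, g, m, k_tail))
                rows.append({
                    "mutation_type": f"{central}>{alt}", "motif": motif_name,
                    "pattern": motif, "tail": tail, "tail_size": k_tail,
                    "matches_total": m, "matches_in_tail": k, "p_value": pval,
                })
                n_tests += 1
    df = pd.DataFrame(rows)
    df["p_adjusted"] = np.minimum(df["p_value"] * len(motifs), 1.0)
    return df
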