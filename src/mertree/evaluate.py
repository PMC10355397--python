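"""Model quality metrics: holdout likelihood, rank agreement, perpendicular
error, and credible-interval calibration.

Holdout evaluation follows the even/odd genome-split protocol: a model fitted
on one parity's counts is scored by the multinomial log-likelihood of the
other parity's counts, after a single global linear scaling that matches the
model's expected polymorphism total to the holdout's observed total (so the
comparison measures spectrum shape, not dataset size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tabulate import CountTable, ProbabilityTable


@dataclass
class EvalReport:
    """Holdout multinomial likelihood and the scaling used to compute it."""

    loglik: float
    scale: float
    level: int
    n_contexts: int
    n_clipped: int


def holdout_loglik(probs: ProbabilityTable, holdout: CountTable,
                   scaled: bool = True, per_type: bool = False) -> EvalReport:
    """Multinomial log-likelihood of holdout counts under model probabilities.

    With ``scaled=True`` every probability is multiplied by the single scalar
    ``s = (observed polymorphisms) / (expected polymorphisms)`` first;
    contexts whose scaled probabilities would leave the simplex are
    renormalized to total 1 - 1e-12 and counted as clipped.  ``per_type``
    replaces the global scalar with one scalar per mutation type (the
    report's ``scale`` is then the polymorphism-weighted mean of those).
    """
    if probs.level != holdout.level or probs.architecture != holdout.architecture:
        raise ValueError(
            f"probability table (level {probs.level}) does not match holdout "
            f"(level {holdout.level})"
        )
    for c in "AC":
        bad = np.flatnonzero(~np.isfinite(probs.p[c]).all(axis=1))
        if bad.size:
            from .contexts import context_at_index
            raise ValueError(
                "missing model probability for context "
                + context_at_index(int(bad[0]), c, probs.level, probs.architecture)
            )
    if per_type and scaled:
        s_by = {
            c: holdout.n[c].sum(axis=0)
            / (holdout.N[c][:, None] * probs.p[c]).sum(axis=0)
            for c in "AC"
        }
        weights = np.concatenate([holdout.n[c].sum(axis=0) for c in "AC"])
        s = float(np.average(np.concatenate([s_by[c] for c in "AC"]),
                             weights=weights))
    else:
        expected = sum(float((holdout.N[c] * probs.p[c].sum(axis=1)).sum())
                       for c in "AC")
        s = holdout.total_polymorphisms / expected if scaled else 1.0
        s_by = {c: np.full(3, s) for c in "AC"}
    total = 0.0
    clipped = 0
    for c in "AC":
        p = probs.p[c] * s_by[c][None, :]
        rowsum = p.sum(axis=1)
        over = rowsum >= 1.0
        clipped += int(over.sum())
        if over.any():
            p = np.where(over[:, None], p / rowsum[:, None] * (1 - 1e-12), p)
            rowsum = np.where(over, 1 - 1e-12, rowsum)
        n = holdout.n[c]
        with np.errstate(divide="ignore"):
            terms = np.where(n > 0, n * np.log(np.where(p > 0, p, 1.0)), 0.0)
        if ((n > 0) & (p == 0)).any():
            total = -np.inf
        total += float(terms.sum() + ((holdout.N[c] - n.sum(axis=1)) * np.log1p(-rowsum)).sum())
    n_ctx = sum(len(holdout.N[c]) for c in "AC")
    return EvalReport(total, s, holdout.level, n_ctx, clipped)


def paired_frame(table_a: ProbabilityTable, table_b: ProbabilityTable):
    """Flat per-context paired probabilities (for scatter plots / TSV export)."""
    import pandas as pd

    a = table_a.to_frame().rename(columns={"p": "p_a"})
    b = table_b.to_frame().rename(columns={"p": "p_b"})
    return pd.merge(a, b, on=["mutation_type", "context"], validate="1:1")


def _paired(table_a: ProbabilityTable, table_b: ProbabilityTable,
            counts_a: CountTable | None, counts_b: CountTable | None,
            omit_zero_cells: bool):
    if table_a.level != table_b.level or table_a.architecture != table_b.architecture:
        raise ValueError("probability tables do not share a context universe")
    xs, ys, omitted = [], [], 0
    for c in "AC":
        a, b = table_a.p[c].ravel(), table_b.p[c].ravel()
        keep = np.ones(a.size, dtype=bool)
        if omit_zero_cells:
            if counts_a is not None:
                keep &= counts_a.n[c].ravel() > 0
            if counts_b is not None:
                keep &= counts_b.n[c].ravel() > 0
            if counts_a is None and counts_b is None:
                keep &= (a > 0) & (b > 0)
        omitted += int((~keep).sum())
        xs.append(a[keep])
        ys.append(b[keep])
    return np.concatenate(xs), np.concatenate(ys), omitted


def spearman_compare(table_a: ProbabilityTable, table_b: ProbabilityTable,
                     counts_a: CountTable | None = None,
                     counts_b: CountTable | None = None,
                     omit_zero_cells: bool = False):
    """Rank correlation of paired per-context probabilities.

    With ``omit_zero_cells`` set, cells with zero observed mutations in
    either dataset are dropped first (the convention for comparing
    pseudocount-dominated empirical estimates) and reported as omitted.
    Returns ``(rho, n_compared, n_omitted)``.
    """
    x, y, omitted = _paired(table_a, table_b, counts_a, counts_b, omit_zero_cells)
    if x.size < 3:
        raise ValueError(f"need at least 3 shared cells, got {x.size}")
    rho = stats.spearmanr(x, y).statistic
    return float(rho), int(x.size), omitted


def rmspe(table_a: ProbabilityTable, table_b: ProbabilityTable,
          scale: str = "log10", counts_a: CountTable | None = None,
          counts_b: CountTable | None = None,
          omit_zero_cells: bool = False) -> float:
    """Root mean squared perpendicular distance to the x=y identity line.

    Computed as ``sqrt(mean(((x - y)/sqrt(2))**2))`` on the chosen scale
    (log10 by default, matching how probability scatter is usually drawn).
    """
    x, y, _ = _paired(table_a, table_b, counts_a, counts_b, omit_zero_cells)
    if scale in ("log10", "ln"):
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError(
                "zero probabilities on a log scale; set omit_zero_cells or use raw"
            )
        f = np.log10 if scale == "log10" else np.log
        x, y = f(x), f(y)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    return float(np.sqrt(np.mean(((x - y) / np.sqrt(2.0)) ** 2)))


@dataclass
class CalibrationReport:
    """Fraction of generating probabilities captured by credible intervals."""

    masses: tuple
    hits: dict = field(default_factory=dict)    # mass -> {level: covered count}
    totals: dict = field(default_factory=dict)  # level -> checks

    @property
    def n(self) -> int:
        return int(sum(self.totals.values()))

    def coverage(self, mass: float) -> float:
        return sum(self.hits[mass].values()) / self.n

    def coverage_by_level(self, mass: float) -> dict[int, float]:
        return {lvl: self.hits[mass][lvl] / tot for lvl, tot in self.totals.items()}

    def as_dict(self) -> dict:
        return {
            "n_checks": self.n,
            "coverage": {str(m): self.coverage(m) for m in self.masses},
            "per_level": {
                str(m): {str(k): v for k, v in self.coverage_by_level(m).items()}
                for m in self.masses
            },
        }

    @classmethod
    def pool(cls, reports: list["CalibrationReport"]) -> "CalibrationReport":
        masses = reports[0].masses
        out = cls(masses)
        for r in reports:
            if r.masses != masses:
                raise ValueError("cannot pool reports with different masses")
            for lvl, tot in r.totals.items():
                out.totals[lvl] = out.totals.get(lvl, 0) + tot
            for m in masses:
                d = out.hits.setdefault(m, {})
                for lvl, h in r.hits[m].items():
                    d[lvl] = d.get(lvl, 0) + h
        return out


def calibration(truth, fits, masses=(0.90, 0.95, 0.99)) -> CalibrationReport:
    """Check how often fitted credible intervals capture the generating value.

    ``truth`` provides ``aggregate_probability(level)`` (the occurrence-
    weighted generating probability of each context-mutation); each fit in
    ``fits`` must have been run on counts simulated from that truth.
    Coverage is pooled over contexts, mutation types, levels and fits.
    """
    report = CalibrationReport(tuple(masses))
    for m in masses:
        report.hits[m] = {}
    for res in fits:
        if res.K != truth.K or res.architecture != truth.architecture:
            raise ValueError("fit and truth context universes differ")
        for level in res.levels:
            true_p = truth.aggregate_probability(level)
            n_checked = 0
            covered = {m: 0 for m in masses}
            for central in "AC":
                from .contexts import alts_for

                for j, alt in enumerate(alts_for(central)):
                    draws = np.exp(res.node_log_draws(level, f"{central}>{alt}"))
                    t = true_p.p[central][:, j]
                    for m in masses:
                        lo, hi = np.quantile(
                            draws, [(1 - m) / 2, 1 - (1 - m) / 2], axis=0
                        )
                        covered[m] += int(((t >= lo) & (t <= hi)).sum())
                    n_checked += t.size
            report.totals[level] = report.totals.get(level, 0) + n_checked
            for m in masses:
                report.hits[m][level] = report.hits[m].get(level, 0) + covered[m]
    return report
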