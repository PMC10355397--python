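"""Sequence-context algebra for k-mer polymorphism-probability trees.

A context tree describes how the probability that a site is polymorphic for a
given mutation type changes as the window of flanking sequence ("mer" level)
is expanded one nucleotide at a time.  The root edge carries the log base
polymorphism probability of the mutation type (``theta``); every deeper edge
carries ``phi``, the natural-log multiplicative shift gained by adding one
more flanking base.  A node's log probability is the sum of the edges on the
unique path from the root, so probabilities compose multiplicatively.

Contexts are always stored in canonical (folded) orientation: each context is
merged with its reverse complement so that the central base is A or C.  After
folding, exactly six mutation types remain (A>C, A>G, A>T, C>A, C>G, C>T) and
each is modelled by its own tree.

Three tree architectures are supported.  Asymmetric architectures expand by a
single base per level, alternating sides (``right_asymmetric`` adds the 3'
base first, at even levels; ``left_asymmetric`` is its mirror); the
``symmetric`` architecture only visits odd levels, adding one base on each
side per step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

RIGHT_ASYMMETRIC = "right_asymmetric"
LEFT_ASYMMETRIC = "left_asymmetric"
SYMMETRIC = "symmetric"
ARCHITECTURES = (RIGHT_ASYMMETRIC, LEFT_ASYMMETRIC, SYMMETRIC)

MODEL_FORMAT_VERSION = "1.0"


class InvalidShapeError(ValueError):
    pass


class UnknownContextError(KeyError):
    pass


class IncompatibleModelsError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class MutationType:
    """A folded single-nucleotide substitution class (reference base A or C)."""

    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in "AC":
            raise ValueError(f"canonical reference base must be A or C, got {self.ref!r}")
        if self.alt not in BASES or self.alt == self.ref:
            raise ValueError(f"invalid alternate base {self.alt!r} for ref {self.ref!r}")

    def __str__(self) -> str:
        return f"{self.ref}>{self.alt}"

    @classmethod
    def from_string(cls, s: str) -> "MutationType":
        ref, _, alt = s.partition(">")
        return cls(ref, alt)

    @property
    def alt_index(self) -> int:
        """Index of the alternate among this ref's three alts (lexicographic)."""
        return alts_for(self.ref).index(self.alt)


def alts_for(ref: str) -> tuple[str, ...]:
    """The three alternate bases of a canonical reference base, sorted."""
    return tuple(b for b in BASES if b != ref)


MUTATION_TYPES: tuple[MutationType, ...] = tuple(
    MutationType(ref, alt) for ref in "AC" for alt in alts_for(ref)
)


def canonical_fold(bases: str, central_index: int, alt: str) -> tuple[str, str, int]:
    """Fold a context window onto the canonical strand (central base A or C).

    Returns the window unchanged if the central base is already A or C;
    otherwise returns its reverse complement with the alternate allele
    complemented and the central index mirrored.
    """
    if not 0 <= central_index < len(bases):
        raise ValueError("central_index out of range")
    if any(b not in _BASE_CODE for b in bases) or alt not in _BASE_CODE:
        raise ValueError(f"non-ACGT base in window {bases!r} / alt {alt!r}")
    if bases[central_index] in "AC":
        return bases, alt, central_index
    return (
        reverse_complement(bases),
        alt.translate(_COMPLEMENT),
        len(bases) - 1 - central_index,
    )


def flank_widths(level: int, architecture: str) -> tuple[int, int]:
    """(5' flank, 3' flank) widths of a level-``level`` context window."""
    if level < 1:
        raise InvalidShapeError(f"level must be >= 1, got {level}")
    if architecture == RIGHT_ASYMMETRIC:
        return (level - 1) // 2, level // 2
    if architecture == LEFT_ASYMMETRIC:
        return level // 2, (level - 1) // 2
    if architecture == SYMMETRIC:
        if level % 2 == 0:
            raise InvalidShapeError("symmetric architecture has no even levels")
        return (level - 1) // 2, (level - 1) // 2
    raise ValueError(f"unknown architecture {architecture!r}")


def levels_for(K: int, architecture: str) -> list[int]:
    """The mer levels a tree of depth ``K`` actually visits, in order."""
    if architecture == SYMMETRIC:
        if K % 2 == 0:
            raise InvalidShapeError("symmetric architecture requires odd K")
        return list(range(1, K + 1, 2))
    return list(range(1, K + 1))


def parent_level(level: int, architecture: str) -> int:
    return level - 2 if architecture == SYMMETRIC else level - 1


@dataclass(frozen=True)
class ContextKey:
    """A folded context: its bases, mer level, and the architecture's shape."""

    bases: str
    architecture: str

    def __post_init__(self) -> None:
        n5, _ = flank_widths(len(self.bases), self.architecture)
        if self.bases[n5] not in "AC":
            raise ValueError(f"context {self.bases!r} is not canonical (central base must be A/C)")

    @property
    def level(self) -> int:
        return len(self.bases)

    @property
    def n5(self) -> int:
        return flank_widths(self.level, self.architecture)[0]

    @property
    def n3(self) -> int:
        return flank_widths(self.level, self.architecture)[1]

    @property
    def central(self) -> str:
        return self.bases[self.n5]


def children(context: ContextKey, K: int | None = None) -> list[ContextKey]:
    """The immediate child contexts reached by one expansion step.

    Asymmetric architectures add one base (4 children); the symmetric
    architecture adds one base on each side (16 children).  Children are in
    lexicographic order of the added bases (5' base outermost first).
    """
    level = context.level
    arch = context.architecture
    if K is not None and level >= K:
        raise InvalidShapeError(f"context at maximum level {K} has no children")
    if arch == SYMMETRIC:
        return [
            ContextKey(b5 + context.bases + b3, arch) for b5 in BASES for b3 in BASES
        ]
    child_level = level + 1
    n5_child, _ = flank_widths(child_level, arch)
    if n5_child > context.n5:  # added on the 5' side
        return [ContextKey(b + context.bases, arch) for b in BASES]
    return [ContextKey(context.bases + b, arch) for b in BASES]


def parent_context(bases: str, architecture: str) -> str:
    """The parent context string (one expansion step up the tree)."""
    level = len(bases)
    if level == 1:
        raise InvalidShapeError("root context has no parent")
    if architecture == SYMMETRIC:
        return bases[1:-1]
    n5, _ = flank_widths(level, architecture)
    n5_parent, _ = flank_widths(level - 1, architecture)
    return bases[1:] if n5 > n5_parent else bases[:-1]


def n_contexts(level: int) -> int:
    """Contexts per tree at a level: the central base is fixed."""
    return 4 ** (level - 1)


def context_index(bases: str, architecture: str) -> int:
    """Index of a context within the deterministic level enumeration.

    Equals the base-4 integer formed by the flanking bases read 5'->3'
    (the fixed central base is skipped), which is exactly lexicographic
    order of the context string.
    """
    n5, _ = flank_widths(len(bases), architecture)
    idx = 0
    for i, b in enumerate(bases):
        if i == n5:
            continue
        idx = idx * 4 + _BASE_CODE[b]
    return idx


def context_at_index(idx: int, central: str, level: int, architecture: str) -> str:
    n5, n3 = flank_widths(level, architecture)
    digits = []
    for _ in range(level - 1):
        digits.append(BASES[idx % 4])
        idx //= 4
    digits.reverse()
    return "".join(digits[:n5]) + central + "".join(digits[n5:])


def enumerate_level(central: str | MutationType, level: int, architecture: str) -> list[str]:
    """All ``4**(level-1)`` folded contexts of a tree at a level, sorted."""
    if isinstance(central, MutationType):
        central = central.ref
    if central not in "AC":
        raise ValueError("central base must be canonical (A or C)")
    return [context_at_index(i, central, level, architecture) for i in range(n_contexts(level))]


def parent_index_map(level: int, architecture: str) -> np.ndarray:
    """Vector mapping a level-``level`` context index to its parent's index."""
    if level <= 1:
        raise InvalidShapeError("level 1 contexts have no parent")
    n = n_contexts(level)
    idx = np.arange(n)
    if architecture == SYMMETRIC:
        return (idx % 4 ** (level - 2)) // 4
    n5, _ = flank_widths(level, architecture)
    n5_parent, _ = flank_widths(level - 1, architecture)
    if n5 > n5_parent:  # this level added the 5' (most significant) base
        return idx % 4 ** (level - 2)
    return idx // 4  # added the 3' (least significant) base


class ContextTree:
    """One mutation type's tree: root ``theta`` plus per-level ``phi`` edges.

    ``phi[level]`` is an array of length ``4**(level-1)`` aligned with
    :func:`enumerate_level`; entry ``i`` is the log-shift on the edge from the
    parent of context ``i`` to context ``i``.  All parameters are natural-log
    scale, so grafting and path composition are additive.
    """

    def __init__(
        self,
        mutation_type: MutationType,
        K: int,
        architecture: str = RIGHT_ASYMMETRIC,
        theta: float = float("nan"),
        phi: dict[int, np.ndarray] | None = None,
    ):
        if architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {architecture!r}")
        self.mutation_type = mutation_type
        self.K = int(K)
        self.architecture = architecture
        self.theta = float(theta)
        self.levels = levels_for(self.K, architecture)
        self.phi: dict[int, np.ndarray] = {}
        for lvl in self.levels[1:]:
            if phi is not None and lvl in phi:
                arr = np.asarray(phi[lvl], dtype=float)
                if arr.shape != (n_contexts(lvl),):
                    raise ValueError(f"phi at level {lvl} has wrong shape {arr.shape}")
                self.phi[lvl] = arr.copy()
            else:
                self.phi[lvl] = np.zeros(n_contexts(lvl))

    def copy(self) -> "ContextTree":
        return ContextTree(self.mutation_type, self.K, self.architecture, self.theta, self.phi)

    def _check_context(self, bases: str) -> int:
        level = len(bases)
        if level not in self.levels:
            raise UnknownContextError(f"no level-{level} contexts in this tree")
        n5, _ = flank_widths(level, self.architecture)
        if bases[n5] != self.mutation_type.ref:
            raise UnknownContextError(
                f"context {bases!r} has central base {bases[n5]!r}, "
                f"tree is {self.mutation_type}"
            )
        return context_index(bases, self.architecture)

    def cumulative_log_p(self, level: int) -> np.ndarray:
        """Log node probability of every context at a level (path sums)."""
        if level not in self.levels:
            raise UnknownContextError(f"tree has no level {level}")
        cum = np.array([self.theta])
        for lvl in self.levels[1:]:
            if lvl > level:
                break
            cum = cum[parent_index_map(lvl, self.architecture)] + self.phi[lvl]
        return cum

    def node_log_probability(self, context: str | ContextKey) -> float:
        """theta plus the sum of phi along the root -> context path."""
        bases = context.bases if isinstance(context, ContextKey) else context
        idx = self._check_context(bases)
        total = self.theta
        while len(bases) > 1:
            total += float(self.phi[len(bases)][context_index(bases, self.architecture)])
            bases = parent_context(bases, self.architecture)
        assert idx >= 0
        return total

    def node_probability(self, context: str | ContextKey) -> float:
        return float(np.exp(self.node_log_probability(context)))


TreeSet = dict[str, ContextTree]
"""A full model: one :class:`ContextTree` per mutation type, keyed by 'C>T' etc."""


def make_tree_set(K: int, architecture: str = RIGHT_ASYMMETRIC) -> TreeSet:
    return {str(m): ContextTree(m, K, architecture) for m in MUTATION_TYPES}


def _check_compatible(a: TreeSet, b: TreeSet) -> tuple[str, int]:
    ta, tb = next(iter(a.values())), next(iter(b.values()))
    if ta.architecture != tb.architecture or ta.K != tb.K:
        raise IncompatibleModelsError(
            f"models differ: ({ta.architecture}, K={ta.K}) vs ({tb.architecture}, K={tb.K})"
        )
    return ta.architecture, ta.K


def graft(model_a: TreeSet, model_b: TreeSet, boundary: int) -> TreeSet:
    """Compose a model from A's shallow levels and B's deep levels.

    Levels <= ``boundary`` (including the root theta) come from ``model_a``;
    levels above it from ``model_b``.  Node probabilities recompose additively
    on the log scale.
    """
    architecture, K = _check_compatible(model_a, model_b)
    if not 1 <= boundary <= K:
        raise ValueError(f"boundary must be in [1, {K}]")
    out: TreeSet = {}
    for name, tree_a in model_a.items():
        tree_b = model_b[name]
        phi = {
            lvl: (tree_a.phi[lvl] if lvl <= boundary else tree_b.phi[lvl])
            for lvl in tree_a.levels[1:]
        }
        out[name] = ContextTree(tree_a.mutation_type, K, architecture, tree_a.theta, phi)
    return out


# ---------------------------------------------------------------------------
# Serialization: versioned JSON model document
# ---------------------------------------------------------------------------

def tree_set_to_dict(
    trees: TreeSet,
    edge_stats: dict[str, dict[int, dict[str, np.ndarray]]] | None = None,
    provenance: dict | None = None,
) -> dict:
    """Serialize a model to a JSON-ready dict.

    ``edge_stats[mtype][level]`` may carry arrays (aligned with the level
    enumeration) of posterior quantiles / PIP to embed alongside each edge.
    """
    arch, K = _check_compatible(trees, trees)
    doc: dict = {
        "format_version": MODEL_FORMAT_VERSION,
        "architecture": arch,
        "K": K,
        "trees": [],
    }
    if provenance:
        doc["provenance"] = provenance
    for name in sorted(trees):
        tree = trees[name]
        entry: dict = {"mutation_type": name, "theta": tree.theta, "edges": []}
        for lvl in tree.levels[1:]:
            contexts = enumerate_level(tree.mutation_type.ref, lvl, arch)
            stats = (edge_stats or {}).get(name, {}).get(lvl, {})
            for i, ctx in enumerate(contexts):
                edge = {
                    "parent": parent_context(ctx, arch),
                    "child": ctx,
                    "level": lvl,
                    "phi_mean": float(tree.phi[lvl][i]),
                }
                for key, arr in stats.items():
                    val = np.asarray(arr)[i]
                    edge[key] = val.tolist() if np.ndim(val) else float(val)
                entry["edges"].append(edge)
        doc["trees"].append(entry)
    return doc


def tree_set_from_dict(doc: dict) -> TreeSet:
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise IncompatibleModelsError(f"unsupported model format version {version!r}")
    arch, K = doc["architecture"], doc["K"]
    trees: TreeSet = {}
    for entry in doc["trees"]:
        mtype = MutationType.from_string(entry["mutation_type"])
        tree = ContextTree(mtype, K, arch, theta=entry["theta"])
        for edge in entry["edges"]:
            lvl = edge["level"]
            tree.phi[lvl][context_index(edge["child"], arch)] = edge["phi_mean"]
        trees[str(mtype)] = tree
    return trees


def save_tree_set(trees: TreeSet, path, **kwargs) -> None:
    with open(path, "w") as fh:
        json.dump(tree_set_to_dict(trees, **kwargs), fh)


def load_tree_set(path) -> TreeSet:
    with open(path) as fh:
        return tree_set_from_dict(json.load(fh))
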