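"""Turn a genome, accessibility mask and variant set into context count tables.

The finest-level :class:`CountTable` is the sufficient statistic of the whole
model: for every folded context at the deepest mer level it records how many
genomic positions carry that context (``N``) and how many of them are
polymorphic for each alternate allele (``n_alt``).  Counting is done once at
the finest level and aggregated downward, which guarantees consistency across
levels.

Conventions: VCF positions are 1-based, BED intervals 0-based half-open,
internal coordinates 0-based.  The even/odd genome split used for independent
training/testing halves is defined on the 1-based coordinate.  A context
window may extend outside the mask or across the parity split — only the
focal position must be masked-in and parity-matched; the flanks are
covariates, not observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np
import pandas as pd

from . import contexts as ctx
from .contexts import (
    BASES,
    MutationType,
    alts_for,
    canonical_fold,
    flank_widths,
    n_contexts,
    parent_index_map,
    parent_level,
)

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class RefMismatchError(ValueError):
    pass


@dataclass
class GenomeMask:
    """Sorted, merged accessible intervals per chromosome (0-based half-open)."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, triples) -> "GenomeMask":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in triples:
            if end > start:
                by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        return cls(merged)

    @classmethod
    def read_bed(cls, path) -> "GenomeMask":
        triples = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                triples.append((f[0], int(f[1]), int(f[2])))
        return cls.from_intervals(triples)

    @classmethod
    def whole_sequences(cls, lengths: dict[str, int]) -> "GenomeMask":
        return cls.from_intervals((c, 0, n) for c, n in lengths.items())

    def chromosomes(self):
        return sorted(self.intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return False
        i = np.searchsorted(ivs[:, 0], pos0, side="right") - 1
        return i >= 0 and pos0 < ivs[i, 1]

    def boolean(self, chrom: str, length: int) -> np.ndarray:
        out = np.zeros(length, dtype=bool)
        for s, e in self.intervals.get(chrom, ()):
            out[max(0, s):min(length, e)] = True
        return out


@dataclass
class VariantRecord:
    """A single-nucleotide variant with allele count/frequency and quality."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_count: int = 1
    allele_frequency: float = 0.0
    quality: float | None = None

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
            raise ValueError(f"not a SNV: {self.chrom}:{self.pos} {self.ref}>{self.alt}")


@dataclass
class VariantFilters:
    """Variant partition rules: allele-count bounds, quality floor, AF bin."""

    min_allele_count: int | None = None
    max_allele_count: int | None = None
    exact_allele_count: int | None = None
    min_quality: float | None = None
    af_bin: tuple[float, float] | None = None  # half-open (lo, hi]

    def passes(self, v: VariantRecord) -> bool:
        if self.exact_allele_count is not None and v.allele_count != self.exact_allele_count:
            return False
        if self.min_allele_count is not None and v.allele_count < self.min_allele_count:
            return False
        if self.max_allele_count is not None and v.allele_count > self.max_allele_count:
            return False
        if self.min_quality is not None and (v.quality is None or v.quality < self.min_quality):
            return False
        if self.af_bin is not None:
            lo, hi = self.af_bin
            if not (lo < v.allele_frequency <= hi):
                return False
        return True


class CountTable:
    """Per-context occurrence totals and per-alternate polymorphism counts.

    ``N[central]`` is a vector over the level's context enumeration for each
    canonical central base; ``n[central]`` is the matching ``(contexts, 3)``
    matrix of polymorphic-site counts, columns ordered by :func:`alts_for`.
    """

    def __init__(self, level: int, architecture: str, provenance: dict | None = None):
        self.level = int(level)
        self.architecture = architecture
        g = n_contexts(self.level)
        self.N = {c: np.zeros(g, dtype=np.int64) for c in "AC"}
        self.n = {c: np.zeros((g, 3), dtype=np.int64) for c in "AC"}
        self.provenance = dict(provenance or {})

    def copy(self) -> "CountTable":
        out = CountTable(self.level, self.architecture, self.provenance)
        for c in "AC":
            out.N[c] = self.N[c].copy()
            out.n[c] = self.n[c].copy()
        return out

    def validate(self) -> None:
        for c in "AC":
            if (self.N[c] < 0).any() or (self.n[c] < 0).any():
                raise ValueError("negative counts")
            if (self.n[c].sum(axis=1) > self.N[c]).any():
                raise ValueError("polymorphism counts exceed occurrence totals")

    @property
    def total_positions(self) -> int:
        return int(sum(self.N[c].sum() for c in "AC"))

    @property
    def total_polymorphisms(self) -> int:
        return int(sum(self.n[c].sum() for c in "AC"))

    def counts_for(self, mtype: MutationType) -> np.ndarray:
        return self.n[mtype.ref][:, mtype.alt_index]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.level == other.level
            and self.architecture == other.architecture
            and all((self.N[c] == other.N[c]).all() for c in "AC")
            and all((self.n[c] == other.n[c]).all() for c in "AC")
        )

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for central in "AC":
            names = ctx.enumerate_level(central, self.level, self.architecture)
            for j, alt in enumerate(alts_for(central)):
                rows.append(
                    pd.DataFrame(
                        {
                            "mutation_type": f"{central}>{alt}",
                            "context": names,
                            "level": self.level,
                            "N": self.N[central],
                            "n_alt": self.n[central][:, j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True).sort_values(
            ["mutation_type", "context"], ignore_index=True
        )

    def write_tsv(self, path) -> None:
        header = {
            "level": self.level,
            "architecture": self.architecture,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first[1:]) if first.startswith("#") else {}
            df = pd.read_csv(fh if first.startswith("#") else path, sep="\t")
        level = int(meta.get("level", df["level"].iloc[0]))
        arch = meta.get("architecture", ctx.RIGHT_ASYMMETRIC)
        table = cls(level, arch, meta.get("provenance"))
        for _, row in df.iterrows():
            mt = MutationType.from_string(row["mutation_type"])
            i = ctx.context_index(row["context"], arch)
            table.N[mt.ref][i] = row["N"]
            table.n[mt.ref][i, mt.alt_index] = row["n_alt"]
        return table


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def _fold_offsets(level: int, architecture: str):
    """Window offsets (relative to the focal site) spelling the folded context.

    Returns (forward_offsets, reverse_offsets): for a focal base that is
    already canonical the folded flank digits are ``code[p + off]`` over
    ``forward_offsets``; for a G/T focal base they are ``3 - code[p + off]``
    over ``reverse_offsets``.  Both lists are ordered most-significant first
    (5' to 3' in the folded orientation).
    """
    n5, n3 = flank_widths(level, architecture)
    forward = [j for j in range(-n5, n3 + 1) if j != 0]
    reverse = [n5 - i for i in range(level) if i != n5]
    return forward, reverse, n5, n3


def _sequence_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_contexts(
    fasta,
    mask: GenomeMask,
    K: int,
    architecture: str = ctx.RIGHT_ASYMMETRIC,
    parity: str = "all",
) -> CountTable:
    """Tally folded level-``K`` context occurrences over masked positions.

    ``fasta`` is a path to an indexed FASTA or a mapping ``{chrom: sequence}``.
    ``parity`` keeps all positions, or only even / odd 1-based coordinates.
    Positions whose context window runs off the contig or contains a non-ACGT
    base are skipped and counted in ``provenance['skipped_windows']``.
    """
    if parity not in ("all", "even", "odd"):
        raise ValueError(f"parity must be all/even/odd, got {parity!r}")
    sequences = _open_fasta(fasta)
    table = CountTable(
        K,
        architecture,
        provenance={"parity": parity, "K": K, "skipped_windows": 0},
    )
    fwd, rev, n5, n3 = _fold_offsets(K, architecture)
    pad = max(n5, n3)
    weights = 4 ** np.arange(K - 2, -1, -1, dtype=np.int64) if K > 1 else np.zeros(0, np.int64)
    skipped = 0
    for chrom in mask.chromosomes():
        seq = sequences(chrom)
        L = len(seq)
        code = np.full(L + 2 * pad, -1, dtype=np.int64)
        code[pad:pad + L] = _sequence_codes(seq)
        masked = mask.boolean(chrom, L)
        if parity != "all":
            pos1 = np.arange(1, L + 1)
            masked &= (pos1 % 2 == 0) if parity == "even" else (pos1 % 2 == 1)
        center = code[pad:pad + L]
        is_fwd = (center == 0) | (center == 1)
        is_rev = (center == 2) | (center == 3)

        def window_ok(offsets):
            ok = np.ones(L, dtype=bool)
            for off in offsets:
                ok &= code[pad + off:pad + off + L] >= 0
            return ok

        def window_index(offsets, complement: bool):
            idx = np.zeros(L, dtype=np.int64)
            for off, w in zip(offsets, weights):
                digit = code[pad + off:pad + off + L]
                idx += ((3 - digit) if complement else digit) * w
            return idx

        ok_f = window_ok(fwd)
        ok_r = window_ok(rev)
        sel_f = masked & is_fwd & ok_f
        sel_r = masked & is_rev & ok_r
        skipped += int((masked & is_fwd & ~ok_f).sum() + (masked & is_rev & ~ok_r).sum())
        idx_f = window_index(fwd, complement=False)
        idx_r = window_index(rev, complement=True)
        g = n_contexts(K)
        for c, code_c in (("A", 0), ("C", 1)):
            table.N[c] += np.bincount(idx_f[sel_f & (center == code_c)], minlength=g)
            # G folds to C, T folds to A
            table.N[c] += np.bincount(idx_r[sel_r & (center == 3 - code_c)], minlength=g)
    table.provenance["skipped_windows"] = skipped
    return table


def _open_fasta(fasta):
    if isinstance(fasta, dict):
        return lambda chrom: fasta[chrom]
    import pysam

    ff = pysam.FastaFile(str(fasta))

    def fetch(chrom):
        if chrom not in ff.references:
            raise KeyError(f"chromosome {chrom!r} not in FASTA")
        return ff.fetch(chrom)

    return fetch


def fold_window(seq: str, pos0: int, level: int, architecture: str) -> tuple[str, int] | None:
    """Folded context string and its enumeration index at a genomic position.

    Returns None when the window runs off the sequence or contains a
    non-ACGT base.
    """
    n5, n3 = flank_widths(level, architecture)
    base = seq[pos0].upper() if pos0 < len(seq) else "N"
    if base in "AC":
        start, end = pos0 - n5, pos0 + n3 + 1
        if start < 0 or end > len(seq):
            return None
        window = seq[start:end].upper()
    elif base in "GT":
        start, end = pos0 - n3, pos0 + n5 + 1
        if start < 0 or end > len(seq):
            return None
        window = ctx.reverse_complement(seq[start:end].upper())
    else:
        return None
    if any(b not in "ACGT" for b in window):
        return None
    return window, ctx.context_index(window, architecture)


def tally_variants(
    variants,
    fasta,
    mask: GenomeMask,
    table: CountTable,
    filters: VariantFilters | None = None,
) -> CountTable:
    """Add folded (context, alternate) polymorphism counts to a totals table.

    ``variants`` is an iterable of :class:`VariantRecord` (see
    :func:`read_variants`).  Variants failing the filters, falling outside the
    mask/parity, mismatching the reference base, or lacking a countable
    context window are skipped; per-reason tallies land in the provenance.
    """
    filters = filters or VariantFilters()
    parity = table.provenance.get("parity", "all")
    sequences = _open_fasta(fasta)
    out = table.copy()
    skip = {"filtered": 0, "unmasked": 0, "ref_mismatch": 0, "bad_window": 0}
    cache: dict[str, str] = {}
    for v in variants:
        if not filters.passes(v):
            skip["filtered"] += 1
            continue
        pos0 = v.pos - 1
        if not mask.contains(v.chrom, pos0):
            skip["unmasked"] += 1
            continue
        if parity == "even" and v.pos % 2 != 0 or parity == "odd" and v.pos % 2 != 1:
            skip["unmasked"] += 1
            continue
        if v.chrom not in cache:
            cache[v.chrom] = sequences(v.chrom)
        seq = cache[v.chrom]
        if pos0 >= len(seq) or seq[pos0].upper() != v.ref:
            skip["ref_mismatch"] += 1
            continue
        folded = fold_window(seq, pos0, table.level, table.architecture)
        if folded is None:
            skip["bad_window"] += 1
            continue
        window, idx = folded
        _, alt, ci = canonical_fold(v.ref, 0, v.alt) if v.ref in "GT" else (v.ref, v.alt, 0)
        central = window[flank_widths(table.level, table.architecture)[0]]
        out.n[central][idx, alts_for(central).index(alt)] += 1
    out.provenance["variant_skips"] = skip
    out.validate()
    return out


def read_variants(path):
    """Yield VariantRecords from a VCF or a tab-delimited site list.

    The TSV form needs columns chrom,pos,ref,alt,allele_count,
    allele_frequency and optionally quality.  Multi-allelic VCF records are
    split; non-SNV alleles are dropped.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        import pysam

        with pysam.VariantFile(path) as vf:
            for rec in vf:
                info = rec.info
                acs = info.get("AC", None)
                afs = info.get("AF", None)
                for i, alt in enumerate(rec.alts or ()):
                    if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                        continue
                    ac = int(acs[i]) if acs is not None else 1
                    af = float(afs[i]) if afs is not None else 0.0
                    yield VariantRecord(
                        rec.chrom, rec.pos, rec.ref, alt, ac, af,
                        None if rec.qual is None else float(rec.qual),
                    )
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        has_q = "quality" in df.columns
        for row in df.itertuples(index=False):
            yield VariantRecord(
                str(row.chrom), int(row.pos), row.ref, row.alt,
                int(getattr(row, "allele_count", 1)),
                float(getattr(row, "allele_frequency", 0.0)),
                float(row.quality) if has_q and pd.notna(row.quality) else None,
            )


# ---------------------------------------------------------------------------
# Aggregation, down-sampling, empirical baseline
# ---------------------------------------------------------------------------

def aggregate_to_level(table: CountTable, level: int) -> CountTable:
    """Sum totals and alt counts over descendants, down to a coarser level."""
    if level == table.level:
        return table.copy()
    if level > table.level or level not in ctx.levels_for(table.level, table.architecture):
        raise ValueError(f"cannot aggregate level-{table.level} table to level {level}")
    out = table
    while out.level > level:
        plevel = parent_level(out.level, out.architecture)
        nxt = CountTable(plevel, out.architecture, out.provenance)
        pmap = parent_index_map(out.level, out.architecture)
        g = n_contexts(plevel)
        for c in "AC":
            nxt.N[c] = np.bincount(pmap, weights=out.N[c], minlength=g).astype(np.int64)
            for j in range(3):
                nxt.n[c][:, j] = np.bincount(
                    pmap, weights=out.n[c][:, j], minlength=g
                ).astype(np.int64)
        out = nxt
    return out


def downsample_sfs(variants, target: dict, bins, seed: int):
    """Uniformly subsample variants so each allele-frequency bin hits a target.

    ``bins`` maps a bin label to its half-open frequency interval (lo, hi];
    ``target`` maps the same labels to required counts.  Sampling is without
    replacement and deterministic per seed.
    """
    variants = list(variants)
    rng = np.random.default_rng(seed)
    by_bin: dict[str, list[int]] = {label: [] for label in bins}
    for i, v in enumerate(variants):
        for label, (lo, hi) in bins.items():
            if lo < v.allele_frequency <= hi:
                by_bin[label].append(i)
                break
    keep: list[int] = []
    for label in sorted(bins):
        want = int(target.get(label, 0))
        have = by_bin[label]
        if want > len(have):
            raise ValueError(
                f"bin {label!r}: target {want} exceeds available {len(have)} variants"
            )
        chosen = rng.choice(len(have), size=want, replace=False)
        keep.extend(have[j] for j in chosen)
    return [variants[i] for i in sorted(keep)]


class ProbabilityTable:
    """Per-context multinomial probabilities at one level.

    ``p[central]`` is a ``(contexts, 3)`` matrix aligned with the level's
    enumeration; columns follow :func:`alts_for`.
    """

    def __init__(self, level: int, architecture: str, p: dict[str, np.ndarray]):
        self.level = int(level)
        self.architecture = architecture
        self.p = {c: np.asarray(p[c], dtype=float) for c in "AC"}

    def for_type(self, mtype: MutationType | str) -> np.ndarray:
        if isinstance(mtype, str):
            mtype = MutationType.from_string(mtype)
        return self.p[mtype.ref][:, mtype.alt_index]

    @classmethod
    def from_trees(cls, trees: ctx.TreeSet, level: int) -> "ProbabilityTable":
        p = {}
        for central in "AC":
            cols = [
                np.exp(trees[f"{central}>{alt}"].cumulative_log_p(level))
                for alt in alts_for(central)
            ]
            p[central] = np.column_stack(cols)
        arch = next(iter(trees.values())).architecture
        return cls(level, arch, p)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for central in "AC":
            names = ctx.enumerate_level(central, self.level, self.architecture)
            for j, alt in enumerate(alts_for(central)):
                rows.append(
                    pd.DataFrame(
                        {
                            "mutation_type": f"{central}>{alt}",
                            "context": names,
                            "p": self.p[central][:, j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def empirical_probabilities(table: CountTable, pseudocount: float = 0.5) -> ProbabilityTable:
    """Maximum-likelihood (plus pseudocount) polymorphism probabilities.

    ``p_alt = (n_alt + pseudocount) / (N + 4 * pseudocount)`` — the classical
    per-context multinomial estimate used as the unregularized baseline.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    p = {}
    for c in "AC":
        denom = table.N[c].astype(float) + 4.0 * pseudocount
        if pseudocount == 0 and (denom == 0).any():
            raise ZeroDivisionError(
                "zero-occurrence context with pseudocount 0 has undefined probability"
            )
        p[c] = (table.n[c] + pseudocount) / denom[:, None]
    return ProbabilityTable(table.level, table.architecture, p)
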