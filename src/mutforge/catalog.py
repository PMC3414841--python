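"""Domain types for genomes, annotations, and somatic mutation catalogs.

Internal coordinates are 1-based inclusive throughout (the VCF convention);
BED input is converted on load.  A :class:`MutationCatalog` holds the
substitutions, indels and rearrangements of a single sample, with
substitutions kept sorted by (chrom, pos) and duplicate positions rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Mapping

import numpy as np

NUCLEOTIDES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte code per base used for vectorised genome scans
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when records contradict the attached reference genome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SubstitutionRecord:
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class IndelRecord:
    """An insertion or deletion.

    ``pos`` is the 1-based coordinate of the reference base immediately 5'
    of the event; for a deletion the removed bases occupy
    ``pos+1 .. pos+length``.
    """

    sample_id: str
    chrom: str
    pos: int
    kind: str  # deletion | insertion | complex
    seq: str
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion", "complex"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if not 1 <= self.length <= 50:
            raise ValueError(f"indel length out of range: {self.length}")
        if self.kind in ("deletion", "insertion") and len(self.seq) != self.length:
            raise ValueError("seq length must equal length for deletion/insertion")


@dataclass(frozen=True)
class RearrangementRecord:
    sample_id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    orientation: str = "+-"

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("breakpoint positions must be >= 1")

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom_a == self.chrom_b


class ReferenceGenome:
    """Uppercase DNA sequences keyed by chromosome, with a cached table of
    genome-wide trinucleotide occurrence counts collapsed to the 32
    pyrimidine-central contexts.  Windows containing N are excluded."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise FormatError(f"non-nucleotide characters {bad} in {chrom}")
            self._seqs[chrom] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def base(self, chrom: str, pos: int) -> str:
        return self._seqs[chrom][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice, truncated at chromosome bounds."""
        seq = self._seqs[chrom]
        return seq[max(start - 1, 0) : min(end, len(seq))]

    def trinucleotide_context(self, chrom: str, pos: int) -> str:
        """Forward-strand trinucleotide centred on ``pos``.

        Raises :class:`ValueError` at chromosome edges and when the window
        contains N (an undefined context).
        """
        seq = self._seqs[chrom]
        if not 2 <= pos <= len(seq) - 1:
            raise ValueError(f"position {chrom}:{pos} has no full trinucleotide window")
        ctx = seq[pos - 2 : pos + 1]
        if "N" in ctx:
            raise ValueError(f"undefined context (N) at {chrom}:{pos}")
        return ctx

    @cached_property
    def trinucleotide_counts(self) -> dict[str, int]:
        """Counts of the 32 pyrimidine-central trinucleotides genome-wide.

        Each window is collapsed so its central base is C or T (windows with
        a purine centre are reverse-complemented before counting).
        """
        counts: dict[str, int] = {}
        for f in NUCLEOTIDES:
            for c in "CT":
                for t in NUCLEOTIDES:
                    counts[f + c + t] = 0
        for seq in self._seqs.values():
            if len(seq) < 3:
                continue
            codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            five, centre, three = codes[:-2], codes[1:-1], codes[2:]
            valid = (five >= 0) & (centre >= 0) & (three >= 0)
            # collapse purine centres: revcomp maps code b -> 3 - b
            pur = (centre == 0) | (centre == 2)  # A or G
            f = np.where(pur, 3 - three, five)
            c = np.where(pur, 3 - centre, centre)
            t = np.where(pur, 3 - five, three)
            idx = (f * 16 + c * 4 + t)[valid]
            binned = np.bincount(idx, minlength=64)
            for j in np.nonzero(binned)[0]:
                ctx = NUCLEOTIDES[j // 16] + NUCLEOTIDES[(j // 4) % 4] + NUCLEOTIDES[j % 4]
                counts[ctx] += int(binned[j])
        return counts

    @property
    def total_trinucleotide_windows(self) -> int:
        return sum(self.trinucleotide_counts.values())


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int  # 1-based inclusive
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.tx_start > self.tx_end:
            raise ValueError(f"tx_start > tx_end for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start + 1


class GeneAnnotation:
    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.chrom, g.tx_start))
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise FormatError("duplicate gene_id in annotation")
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def overlapping(self, chrom: str, pos: int) -> list[Gene]:
        """Genes whose transcript span covers ``pos`` (linear scan per chrom
        with a bisect lower bound; gene sets here are small)."""
        out = []
        for g in self._by_chrom.get(chrom, ()):
            if g.tx_start > pos:
                break
            if g.tx_start <= pos <= g.tx_end:
                out.append(g)
        return out


class ExpressionTable:
    """Mapping (gene_id, sample_id) -> log2 expression."""

    def __init__(self, values: Mapping[tuple[str, str], float],
                 annotation: GeneAnnotation | None = None):
        self._values: dict[tuple[str, str], float] = {}
        for (gene, sample), v in values.items():
            if not np.isfinite(v):
                raise FormatError(f"non-finite expression for {gene}/{sample}")
            if annotation is not None and gene not in annotation:
                raise FormatError(f"expression gene {gene!r} absent from annotation")
            self._values[(gene, sample)] = float(v)

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self._values[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._values

    def items(self):
        return self._values.items()

    def gene_mean(self, gene_id: str) -> float:
        vals = [v for (g, _), v in self._values.items() if g == gene_id]
        if not vals:
            raise KeyError(gene_id)
        return float(np.mean(vals))

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self._values})


class CpGIslandSet:
    """Non-overlapping 1-based inclusive intervals, merged at load."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start > end:
                raise FormatError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._by_chrom[chrom] = [(s, e) for s, e in merged]

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, ivs in sorted(self._by_chrom.items()) for s, e in ivs]

    def total_length(self) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        import bisect

        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        i = bisect.bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos <= ivs[i][1]


class MutationCatalog:
    """All somatic mutations of one sample.

    Substitutions are stored sorted by (chrom lexicographic, pos ascending);
    duplicate (chrom, pos) substitutions are rejected because intermutation
    distances and doublet detection assume unique positions.
    """

    def __init__(
        self,
        sample_id: str,
        substitutions: Iterable[SubstitutionRecord] = (),
        indels: Iterable[IndelRecord] = (),
        rearrangements: Iterable[RearrangementRecord] = (),
        genome: ReferenceGenome | None = None,
    ):
        self.sample_id = sample_id
        subs = sorted(substitutions, key=lambda r: (r.chrom, r.pos))
        seen: set[tuple[str, int]] = set()
        for r in subs:
            if r.sample_id != sample_id:
                raise ValueError(f"record sample {r.sample_id!r} != catalog {sample_id!r}")
            key = (r.chrom, r.pos)
            if key in seen:
                raise ValueError(f"duplicate substitution at {r.chrom}:{r.pos}")
            seen.add(key)
        self.substitutions: list[SubstitutionRecord] = subs
        self.indels: list[IndelRecord] = sorted(indels, key=lambda r: (r.chrom, r.pos))
        self.rearrangements: list[RearrangementRecord] = list(rearrangements)
        if genome is not None:
            self.validate_against(genome)

    def validate_against(self, genome: ReferenceGenome) -> None:
        bad = [
            r
            for r in self.substitutions
            if r.chrom not in genome or genome.base(r.chrom, r.pos) != r.ref
        ]
        if bad:
            lines = ", ".join(f"{r.chrom}:{r.pos} {r.ref}" for r in bad[:10])
            raise ValidationError(
                f"{len(bad)} substitution(s) mismatch the reference genome: {lines}"
            )

    def __len__(self) -> int:
        return len(self.substitutions)

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for r in self.substitutions:
            out.setdefault(r.chrom, []).append(r.pos)
        return {c: np.asarray(p, dtype=np.int64) for c, p in out.items()}
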