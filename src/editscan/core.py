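"""Domain types shared across the pipeline.

Coordinate conventions
----------------------
Point positions (VCF, site-count tables, editing-site tables) are 1-based.
Intervals (:class:`GenomicInterval`, BED) are 0-based half-open.  A VCF
position ``pos`` maps to the interval ``[pos - 1, pos)``.

Strand is one of ``+``, ``-`` or ``.``; ``.`` is reserved for features with
no gene context (intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: integer codes used throughout the numeric kernels; N/other = 4
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
CODE_TO_BASE = np.array(["A", "C", "G", "T", "N"])


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (case preserved, N passed through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A=0, C=1, G=2, T/U=3, other=4)."""
    out = np.full(len(seq), 4, dtype=np.int8)
    upper = seq.upper()
    arr = np.frombuffer(upper.encode("ascii"), dtype=np.uint8)
    out[arr == ord("A")] = 0
    out[arr == ord("C")] = 1
    out[arr == ord("G")] = 2
    out[(arr == ord("T")) | (arr == ord("U"))] = 3
    return out


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A transcript-level gene model.

    Exons are sorted, non-overlapping and stored in ascending genomic order
    regardless of strand; every CDS interval is contained in an exon.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: List[GenomicInterval]
    cds: List[GenomicInterval] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.biotype not in ("protein_coding", "ncRNA"):
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype}")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(f"gene {self.gene_id}: CDS outside exons")
        for iv in list(self.exons) + list(self.cds):
            if iv.strand != self.strand:
                raise ValueError(f"gene {self.gene_id}: interval strand mismatch")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass
class SiteCounts:
    """Quality-filtered read counts by base at one site in one sample (1-based pos)."""

    sample_id: str
    chrom: str
    pos: int
    ref_base: str
    counts: Dict[str, int]

    def __post_init__(self):
        if self.ref_base not in BASES:
            raise ValueError(f"ref base {self.ref_base!r} not in {BASES}")
        for base, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {base} at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class SnpRecord:
    """One biallelic SNP with optional genotypes and ancestral-allele call.

    ``genotypes`` is an (n_samples, 2) int array of allele indices (0=ref,
    1=alt, -1=missing), or ``None`` when the source carries no GT data.
    ``ancestral`` is ``"A"/"C"/"G"/"T"`` or ``None`` for unknown.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    ancestral: Optional[str] = None
    alt_freq: float = float("nan")
    genotypes: Optional[np.ndarray] = None
    phased: bool = False

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt")
        if self.ancestral is not None and self.ancestral not in (self.ref, self.alt):
            raise ValueError(
                f"{self.chrom}:{self.pos}: ancestral {self.ancestral} is neither "
                "ref nor alt; use None for unknown"
            )

    @property
    def key(self):
        return (self.chrom, self.pos)

    def derived_freq(self) -> float:
        """Derived allele frequency; NaN when the ancestral allele is unknown."""
        if self.ancestral is None:
            return float("nan")
        return self.alt_freq if self.ancestral == self.ref else 1.0 - self.alt_freq


@dataclass(frozen=True)
class GwasRecord:
    """One variant row of a GWAS summary-statistics table."""

    chrom: str
    pos: int
    id: str
    p_value: float
    dataset_id: str = ""
    disease: str = ""

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"GWAS p-value {self.p_value} outside (0, 1]")

    @property
    def key(self):
        return (self.chrom, self.pos)


@dataclass
class CallerThresholds:
    """Thresholds of the editing-site identification pipeline.

    Defaults follow the published filtering cascade: mismatches need >= 2
    supporting reads at base/mapping quality >= 20; final sites need >= 3
    reads of each allele; samples are kept when >= 80% of their RNA variants
    are A-to-G/T-to-C; non-Alu sites face stricter filters (minimum level,
    homopolymer and splice-proximity exclusion).
    """

    min_alt_reads: int = 2
    bq_min: int = 20
    mq_min: int = 20
    min_ref_reads: int = 3
    min_alt_reads_final: int = 3
    sample_purity: float = 0.80
    nonalu_min_alt: int = 3
    nonalu_min_level: float = 0.1
    nonalu_homopolymer_max: int = 4
    nonalu_splice_distance: int = 4

    def __post_init__(self):
        if not (0 < self.sample_purity <= 1):
            raise ValueError("sample_purity must be in (0, 1]")
        for name in (
            "min_alt_reads",
            "bq_min",
            "mq_min",
            "min_ref_reads",
            "min_alt_reads_final",
            "nonalu_min_alt",
            "nonalu_homopolymer_max",
            "nonalu_splice_distance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
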