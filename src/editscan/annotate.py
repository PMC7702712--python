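"""Site characterisation: genic location, ADAR motif, SNP-type bias, level tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, SnpRecord, complement_base

GENIC_LABELS = ["CDS", "5UTR", "3UTR", "ncRNA", "intronic", "antisense", "intergenic"]
#: precedence when a site overlaps several features (functional first)
_PRECEDENCE = {lab: i for i, lab in enumerate(
    ["CDS", "3UTR", "5UTR", "ncRNA", "intronic", "antisense", "intergenic"]
)}


def _label_in_gene(gene: GeneModel, pos0: int) -> str:
    """Label of a position inside a gene on its own strand."""
    in_exon = any(e.start <= pos0 < e.end for e in gene.exons)
    if not in_exon:
        return "intronic"
    if gene.biotype == "ncRNA" or not gene.cds:
        return "ncRNA"
    if any(c.start <= pos0 < c.end for c in gene.cds):
        return "CDS"
    cds_start, cds_end = gene.cds[0].start, gene.cds[-1].end
    if pos0 < cds_start:
        return "5UTR" if gene.strand == "+" else "3UTR"
    return "3UTR" if gene.strand == "+" else "5UTR"


def annotate_genic(sites: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Assign one genic-location label per site.

    Precedence over overlapping features: CDS > 3'UTR/5'UTR > ncRNA exon >
    intronic > antisense > intergenic.  ``antisense`` means the site only
    overlaps genes on the strand opposite to its own; sites with strand "."
    never count as antisense (they have no orientation of their own) and
    take the best same-location label of any overlapping gene.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    labels = []
    for site in sites.itertuples(index=False):
        pos0 = site.pos - 1
        overlapping = [
            g for g in by_chrom.get(site.chrom, []) if g.contains(site.chrom, pos0)
        ]
        sense = [
            g for g in overlapping
            if site.strand == "." or g.strand == site.strand
        ]
        candidates = [_label_in_gene(g, pos0) for g in sense]
        if not candidates and overlapping:
            candidates = ["antisense"]
        if not candidates:
            candidates = ["intergenic"]
        labels.append(min(candidates, key=_PRECEDENCE.__getitem__))
    out = sites.copy()
    out["genic_location"] = labels
    return out


# ---------------------------------------------------------------------------
# Triplet motif


@dataclass
class MotifProfile:
    """Base frequencies immediately 5' and 3' of a set of sites (sense strand)."""

    upstream: np.ndarray  # length-4 frequency vector over A,C,G,T
    downstream: np.ndarray
    n_sites: int
    n_skipped: int = 0

    def __post_init__(self):
        for v in (self.upstream, self.downstream):
            if abs(float(np.sum(v)) - 1.0) > 1e-9:
                raise ValueError("frequency vector does not sum to 1")
        if self.n_sites <= 0:
            raise ValueError("profile needs at least one site")


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def motif_profile(sites: pd.DataFrame, sequences: Dict[str, str]) -> MotifProfile:
    """-1/+1 neighbour base frequencies on the sense strand.

    For minus-strand sites the genomic 3' neighbour, reverse complemented,
    is the sense 5' neighbour.  Sites at contig edges are skipped and
    counted.
    """
    up = np.zeros(4)
    down = np.zeros(4)
    n = 0
    skipped = 0
    for site in sites.itertuples(index=False):
        seq = sequences[site.chrom]
        pos0 = site.pos - 1
        if pos0 - 1 < 0 or pos0 + 1 >= len(seq):
            skipped += 1
            continue
        if site.strand == "-":
            u = complement_base(seq[pos0 + 1])
            d = complement_base(seq[pos0 - 1])
        else:
            u = seq[pos0 - 1]
            d = seq[pos0 + 1]
        if u not in _BASE_INDEX or d not in _BASE_INDEX:
            skipped += 1
            continue
        up[_BASE_INDEX[u]] += 1
        down[_BASE_INDEX[d]] += 1
        n += 1
    if n == 0:
        raise ValueError("no usable sites for motif profile")
    return MotifProfile(upstream=up / n, downstream=down / n, n_sites=n,
                        n_skipped=skipped)


def motif_depletion_test(
    profile: MotifProfile, background: MotifProfile, base: str = "G",
    side: str = "upstream",
) -> Tuple[float, float]:
    """One-sided binomial test that ``base`` is depleted next to editing sites.

    Returns ``(observed_frequency, p_value)`` against the background
    frequency of the same neighbour position at control sites.
    """
    i = _BASE_INDEX[base]
    vec = profile.upstream if side == "upstream" else profile.downstream
    bg = background.upstream if side == "upstream" else background.downstream
    k = int(round(vec[i] * profile.n_sites))
    res = stats.binomtest(k, profile.n_sites, float(bg[i]), alternative="less")
    return float(vec[i]), float(res.pvalue)


# ---------------------------------------------------------------------------
# SNP-type bias


@dataclass
class SnpTypeBias:
    frac_editing_type: float
    frac_control_type: float
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float


def _is_editing_type(ref: str, alt: str, strand: str) -> bool:
    pair = {ref, alt}
    if strand == "-":
        return pair == {"T", "C"}
    return pair == {"A", "G"}


def snp_type_bias(
    editing_snps: pd.DataFrame,
    control_snps: Sequence[SnpRecord],
) -> SnpTypeBias:
    """Bias of editing SNPs toward the A/G (sense) genotype vs control SNPs.

    ``editing_snps`` needs columns ref/alt/strand; controls are panel SNPs
    with A or T as the reference allele (strand-unaware pairs A/G and T/C
    count as editing-type).  Tested with Fisher's exact test on the 2x2
    table of editing-type vs other-type counts.
    """
    controls = [r for r in control_snps if r.ref in ("A", "T")]
    if editing_snps.empty or not controls:
        raise ValueError("both SNP sets must be nonempty")
    ed_type = [
        _is_editing_type(r.ref, r.alt, r.strand)
        for r in editing_snps.itertuples(index=False)
    ]
    ctl_type = [
        {r.ref, r.alt} in ({"A", "G"}, {"T", "C"}) for r in controls
    ]
    a, b = int(np.sum(ed_type)), int(len(ed_type) - np.sum(ed_type))
    c, d = int(np.sum(ctl_type)), int(len(ctl_type) - np.sum(ctl_type))
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return SnpTypeBias(
        frac_editing_type=a / (a + b),
        frac_control_type=c / (c + d),
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# Editing-level group comparisons


def compare_level_groups(
    level_sets: Dict[str, Sequence[float]],
) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests between editing-level groups.

    Uses midranks for ties with the tie-corrected normal approximation,
    switching to exact enumeration when both groups have n <= 8 (and no
    ties across the pooled sample).  Returns one row per unordered pair.
    """
    names = sorted(level_sets)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name in names:
        if len(level_sets[name]) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            x = np.asarray(level_sets[na], dtype=float)
            y = np.asarray(level_sets[nb], dtype=float)
            pooled = np.concatenate([x, y])
            exact = (
                len(x) <= 8 and len(y) <= 8
                and len(np.unique(pooled)) == len(pooled)
            )
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided",
                method="exact" if exact else "asymptotic",
            )
            rows.append(
                {"group_a": na, "group_b": nb, "n_a": len(x), "n_b": len(y),
                 "U": float(res.statistic), "p_value": float(res.pvalue),
                 "method": "exact" if exact else "asymptotic"}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Density bookkeeping (editing-SNP density vs control-SNP density per class)


def density_ratio(
    editing_labels: Sequence[str], control_labels: Sequence[str]
) -> pd.DataFrame:
    """Per-class editing-SNP share divided by control-SNP share.

    Equals 1 in every class when the generator plants no class preference.
    """
    ed = pd.Series(editing_labels).value_counts(normalize=True)
    ctl = pd.Series(control_labels).value_counts(normalize=True)
    classes = sorted(set(ed.index) | set(ctl.index))
    rows = [
        {"genic_location": c,
         "editing_share": float(ed.get(c, 0.0)),
         "control_share": float(ctl.get(c, 0.0)),
         "ratio": float(ed.get(c, 0.0)) / float(ctl.get(c)) if ctl.get(c, 0.0)
         else np.nan}
        for c in classes
    ]
    return pd.DataFrame(rows)
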