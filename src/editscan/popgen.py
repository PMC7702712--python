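"""Population-genetic statistics for the balancing-selection scan.

Derived allele frequency (DAF) spectra with Kolmogorov-Smirnov class
comparisons, Tajima's D and nucleotide diversity (pi) on fixed or sliding
windows, binned linkage-disequilibrium (r^2) decay, and outgroup-based
ancestral-allele inference.  All statistics operate on 0/1 haplotype
matrices (rows = haplotypes, columns = segregating sites); helpers convert
phased genotype panels to that form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, SnpRecord


# ---------------------------------------------------------------------------
# DAF


def compute_daf(
    records: Sequence[SnpRecord],
    classes: Optional[Dict[Tuple[str, int], str]] = None,
    maf_min: float = 0.001,
    strands: Optional[Dict[Tuple[str, int], str]] = None,
) -> pd.DataFrame:
    """Derived-allele-frequency records for SNPs with a known ancestral allele.

    SNPs with unknown ancestral state are excluded (counted in the
    ``attrs`` of the returned frame), as are SNPs at or below the strict
    minor-allele-frequency floor.  ``classes`` attaches a functional-class
    label per (chrom, pos); ``strands`` (sense strand per site) enables the
    ``ancestral_is_editable`` flag (ancestral allele is A on the sense
    strand).
    """
    rows = []
    n_unknown = 0
    n_maf = 0
    for rec in records:
        if rec.ancestral is None:
            n_unknown += 1
            continue
        daf = rec.derived_freq()
        maf = min(daf, 1.0 - daf)
        if not (maf > maf_min):
            n_maf += 1
            continue
        editable = None
        if strands is not None and rec.key in strands:
            s = strands[rec.key]
            editable = (rec.ancestral == "A" and s == "+") or (
                rec.ancestral == "T" and s == "-"
            )
        rows.append(
            {"chrom": rec.chrom, "pos": rec.pos, "id": rec.id, "daf": daf,
             "maf": maf,
             "class": (classes or {}).get(rec.key, "unassigned"),
             "ancestral_is_editable": editable}
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "daf", "maf", "class",
                       "ancestral_is_editable"],
    )
    df.attrs["n_unknown_ancestral"] = n_unknown
    df.attrs["n_maf_filtered"] = n_maf
    return df


@dataclass
class KsResult:
    statistic: float
    p_value: float
    spectrum_a: np.ndarray  # counts in 10 equal DAF bins
    spectrum_b: np.ndarray
    small_sample_warning: bool = False


def daf_ks(class_a: Sequence[float], class_b: Sequence[float]) -> KsResult:
    """Two-sample KS comparison of two DAF distributions.

    Exact p-value when both samples have n <= 30, asymptotic otherwise;
    spectra are reported in ten equal-width bins for plotting.  Samples
    with n < 5 only attach a warning (classes with very few sites are
    reported but flagged, not refused).
    """
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if (a.size <= 30 and b.size <= 30) else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    bins = np.linspace(0.0, 1.0, 11)
    return KsResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        spectrum_a=np.histogram(a, bins=bins)[0],
        spectrum_b=np.histogram(b, bins=bins)[0],
        small_sample_warning=(a.size < 5 or b.size < 5),
    )


# ---------------------------------------------------------------------------
# Tajima's D and pi


@dataclass
class WindowStat:
    """Segregating sites, pi and Tajima's D over one genomic window."""

    interval: Optional[GenomicInterval]
    n_haplotypes: int
    S: int
    pi_sum: float
    theta_w: float
    tajimas_d: Optional[float]

    @property
    def pi_per_bp(self) -> Optional[float]:
        if self.interval is None:
            return None
        return self.pi_sum / len(self.interval)


def tajima_constants(n: int) -> Dict[str, float]:
    """The standard normalisation constants of Tajima's D for n haplotypes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def site_heterozygosity(j: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site pairwise heterozygosity 2 j (n - j) / (n (n - 1))."""
    j = np.asarray(j, dtype=float)
    n = np.asarray(n, dtype=float)
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def window_stats(
    haplotypes: np.ndarray,
    interval: Optional[GenomicInterval] = None,
) -> WindowStat:
    """Tajima's D, pi and S from a (haplotypes x sites) 0/1 matrix.

    Missing alleles are coded -1 and handled per site (complete-case n for
    pi); the variance constants use the full haplotype count.  D is
    undefined (None) when no site segregates.
    """
    h = np.asarray(haplotypes)
    if h.ndim != 2:
        raise ValueError("haplotype matrix must be 2-D")
    n = h.shape[0]
    if n < 4:
        raise ValueError("need at least 4 haplotypes")
    if h.shape[1] == 0:
        return WindowStat(interval, n, 0, 0.0, 0.0, None)
    missing = h < 0
    n_site = n - missing.sum(axis=0)
    j = np.where(missing, 0, h).sum(axis=0)
    seg = (j > 0) & (j < n_site)
    S = int(seg.sum())
    valid = n_site > 1
    pi_sum = float(site_heterozygosity(j[valid], n_site[valid]).sum())
    k = tajima_constants(n)
    theta_w = S / k["a1"]
    if S == 0:
        return WindowStat(interval, n, 0, pi_sum, theta_w, None)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    d = (pi_sum - theta_w) / np.sqrt(var)
    return WindowStat(interval, n, S, pi_sum, theta_w, float(d))


def tajimas_d(haplotypes: np.ndarray) -> WindowStat:
    """Alias of :func:`window_stats` named after its headline statistic."""
    return window_stats(haplotypes)


def haplotypes_from_records(
    records: Sequence[SnpRecord],
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack phased genotype records into (positions, haplotype matrix).

    Returns positions (1-based) and a (2 * n_samples) x n_sites 0/1 matrix.
    """
    if not records:
        raise ValueError("no records")
    positions = np.array([r.pos for r in records])
    haps = np.stack([r.genotypes.reshape(-1) for r in records], axis=1)
    return positions, haps.astype(np.int8)


def snp_windows(
    positions: np.ndarray,
    haplotypes: np.ndarray,
    focal_positions: Sequence[int],
    flank: int = 150,
    classes: Optional[Dict[int, str]] = None,
    require_same_class: bool = True,
    chrom: str = "chr1",
) -> List[WindowStat]:
    """Per-focal-SNP windows (focal position +- ``flank``; 300 bp by default).

    When ``classes`` maps positions to functional-class labels and
    ``require_same_class`` is set, windows whose flanking SNPs leave the
    focal SNP's class are discarded (the stricter of the two behaviours;
    pass False to keep such windows with all their sites).
    """
    positions = np.asarray(positions)
    out = []
    for fp in focal_positions:
        lo, hi = fp - flank, fp + flank
        m = (positions >= lo) & (positions <= hi)
        if not m.any():
            continue
        if classes is not None:
            focal_class = classes.get(fp)
            window_classes = {classes.get(int(p)) for p in positions[m]}
            if require_same_class and window_classes != {focal_class}:
                continue
        iv = GenomicInterval(chrom, max(0, lo - 1), hi)
        out.append(window_stats(haplotypes[:, m], iv))
    return out


def pi_windows(
    positions: np.ndarray,
    haplotypes: np.ndarray,
    windows: Optional[Sequence[GenomicInterval]] = None,
    size: int = 200,
    step: int = 100,
    span: Optional[Tuple[int, int]] = None,
    chrom: str = "chr1",
) -> List[WindowStat]:
    """Nucleotide diversity per window, fixed list or sliding (200/100 default).

    ``span`` (0-based half-open) bounds the sliding mode; by default it
    covers the observed positions.  ``pi_per_bp`` divides by window length.
    """
    if windows is None:
        if size <= 0 or step <= 0:
            raise ValueError("window size and step must be positive")
        positions0 = np.asarray(positions) - 1
        lo, hi = span if span is not None else (int(positions0.min()),
                                                int(positions0.max()) + 1)
        starts = np.arange(lo, max(hi - size, lo) + 1, step)
        windows = [GenomicInterval(chrom, int(s), int(s) + size) for s in starts]
    out = []
    positions0 = np.asarray(positions) - 1
    for iv in windows:
        if len(iv) <= 0:
            raise ValueError("window size must be positive")
        m = (positions0 >= iv.start) & (positions0 < iv.end)
        out.append(window_stats(haplotypes[:, m], iv))
    return out


# ---------------------------------------------------------------------------
# LD decay


@dataclass
class LdBin:
    lo: int
    hi: int
    mean_r2: Optional[float]
    n_pairs: int


def r_squared(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Haplotype r^2 between two 0/1 columns; None when either is monomorphic."""
    p_a = float(np.mean(x))
    p_b = float(np.mean(y))
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None
    p_ab = float(np.mean(x * y))
    num = (p_ab - p_a * p_b) ** 2
    den = p_a * (1 - p_a) * p_b * (1 - p_b)
    return num / den


def ld_decay(
    focal_positions: Sequence[int],
    positions: np.ndarray,
    haplotypes: np.ndarray,
    lo: int = 500,
    hi: int = 10000,
    n_bins: int = 20,
) -> List[LdBin]:
    """Mean r^2 of focal-vs-flanking SNP pairs in equal-width distance bins.

    Pairs at distance d in [lo, hi) enter bin floor((d - lo) / width);
    monomorphic partners are skipped.  Defaults follow the 20-bin
    500-10,000 bp layout.
    """
    positions = np.asarray(positions)
    pos_index = {int(p): i for i, p in enumerate(positions)}
    width = (hi - lo) / n_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for fp in focal_positions:
        fi = pos_index.get(int(fp))
        if fi is None:
            continue
        x = haplotypes[:, fi]
        d = np.abs(positions - fp)
        m = (d >= lo) & (d < hi)
        for pi_ in np.flatnonzero(m):
            if pi_ == fi:
                continue
            r2 = r_squared(x, haplotypes[:, pi_])
            if r2 is None:
                continue
            b = int((d[pi_] - lo) // width)
            sums[b] += r2
            counts[b] += 1
    return [
        LdBin(
            lo=int(lo + b * width), hi=int(lo + (b + 1) * width),
            mean_r2=(sums[b] / counts[b]) if counts[b] else None,
            n_pairs=int(counts[b]),
        )
        for b in range(n_bins)
    ]


def genotype_r_squared(g1: np.ndarray, g2: np.ndarray) -> Optional[float]:
    """Unphased fallback: squared Pearson correlation of 0/1/2 dosages."""
    if np.std(g1) == 0 or np.std(g2) == 0:
        return None
    return float(np.corrcoef(g1, g2)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# Ancestral inference from an outgroup (fly mode)


def infer_ancestral_outgroup(
    records: Sequence[SnpRecord],
    outgroup: Dict[Tuple[str, int], str],
) -> Tuple[List[SnpRecord], int]:
    """Set each SNP's ancestral allele from an aligned outgroup base.

    The ancestral allele is the outgroup base when it equals ref or alt;
    gaps, unaligned positions and third alleles leave it unknown.  Returns
    the updated records and the number left unknown.
    """
    out = []
    n_unknown = 0
    for rec in records:
        base = outgroup.get(rec.key)
        base = base.upper() if isinstance(base, str) else None
        if base in (rec.ref, rec.alt):
            anc = base
        else:
            anc = None
            n_unknown += 1
        out.append(
            SnpRecord(
                chrom=rec.chrom, pos=rec.pos, id=rec.id, ref=rec.ref, alt=rec.alt,
                ancestral=anc, alt_freq=rec.alt_freq, genotypes=rec.genotypes,
                phased=rec.phased,
            )
        )
    return out, n_unknown
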