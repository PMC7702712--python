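"""Synthetic data with known ground truth for the editing/selection pipeline.

The generator emulates the statistical structure the analyses assume, not
the read-level detail of an RNA-seq experiment:

* a random reference carrying genes (exon/intron/CDS/UTR structure) that
  tile ~60% of the sequence, with Alu-like repeat intervals covering ~30%
  of genic bases;
* a Hardy-Weinberg genotype panel whose neutral sites follow a 1/f derived
  allele frequency spectrum and whose "balanced" sites draw intermediate
  frequencies from Beta(20, 20);
* per-sample pileup tables at editing sites (beta-distributed editing
  levels, ADAR-like depletion of 5' G) and at genic SNPs, with a uniform
  per-read error rate;
* reverse-complement editing-complementary-sequence (ECS) arms planted
  inside the same gene for a configurable fraction of editing sites;
* GWAS p-value tables with a controllable enrichment of sub-0.001 hits at
  editing SNPs.

All randomness flows from ``SimConfig.seed`` through per-stage
``numpy.random.default_rng([seed, stage])`` streams, so a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as esio
from .core import GeneModel, GenomicInterval, GwasRecord, SnpRecord, complement_base

# stage ids for derived RNG streams
_STAGE_REFERENCE = 1
_STAGE_PANEL = 2
_STAGE_READS = 3
_STAGE_GWAS = 4

_BASE = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a small but realistic cohort: 20 diploid samples,
    30x mean site coverage, editing levels from Beta(2, 2), a two-fold
    depletion of 5' G at editing sites, and no GWAS enrichment.
    """

    seed: int = 0
    n_samples: int = 20
    n_sites_neutral: int = 2000
    n_sites_balanced: int = 0
    n_editing_sites: int = 300
    frac_snp_editing: float = 0.5
    coverage_mean: float = 30.0
    editing_level_beta: Tuple[float, float] = (2.0, 2.0)
    level_min: float = 0.0
    motif_bias: float = 0.5
    ecs_fraction: float = 0.5
    gwas_enrichment_factor: float = 1.0
    seq_error_rate: float = 0.001
    # layout / population structure knobs
    gene_length: int = 6000
    intergenic_length: int = 4000
    alu_fraction: float = 0.3
    frac_ncrna: float = 0.2
    frac_snp_genic: float = 0.1
    extra_genes: int = 5
    pop_size: int = 5000  # haploid grid 2N for the 1/f frequency lattice
    editing_snp_selection: str = "balanced"  # or "neutral"
    balanced_beta: Tuple[float, float] = (20.0, 20.0)
    gwas_p_thresh: float = 0.001

    def __post_init__(self):
        for name in ("frac_snp_editing", "ecs_fraction", "level_min",
                     "alu_fraction", "frac_ncrna", "frac_snp_genic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.motif_bias <= 1.0):
            raise ValueError("motif_bias must be in (0, 1]")
        if self.gwas_enrichment_factor < 1.0:
            raise ValueError("gwas_enrichment_factor must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.seq_error_rate < 0 or self.seq_error_rate >= 1:
            raise ValueError("seq_error_rate must be in [0, 1)")
        if self.editing_snp_selection not in ("balanced", "neutral"):
            raise ValueError("editing_snp_selection must be balanced or neutral")

    @property
    def samples(self) -> List[str]:
        return [f"s{i + 1}" for i in range(self.n_samples)]


@dataclass
class Reference:
    """Output of :func:`simulate_reference`: sequence, annotation, truth skeleton."""

    sequences: Dict[str, str]
    genes: List[GeneModel]
    alu: List[GenomicInterval]
    truth: pd.DataFrame  # editing-site skeleton
    levels: np.ndarray  # (n_editing_sites, n_samples) true editing levels


@dataclass
class Panel:
    """Output of :func:`simulate_panel`: SNP records plus the unified truth table."""

    records: List[SnpRecord]
    samples: List[str]
    truth: pd.DataFrame  # editing sites + pure SNPs


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Reference, annotation, planted editing sites


def simulate_reference(config: SimConfig) -> Reference:
    """Build the reference sequence, gene models, Alu intervals and truth skeleton.

    One gene hosts one planted editing site.  The site's sense base is A
    (genomic T on minus-strand genes); its 5' neighbour is drawn with
    relative weights 0.25 for A/C/T and ``0.25 * motif_bias`` for G.  For
    ``ecs_fraction`` of sites the reverse complement of the 31-nt editing
    region is written into the same gene within +-2500 nt.
    """
    rng = _rng(config, _STAGE_REFERENCE)
    n_genes = config.n_editing_sites + config.extra_genes
    unit = config.gene_length + config.intergenic_length
    if config.gene_length < 5200:
        raise ValueError("gene_length must be >= 5200 to host an ECS arm")
    length = n_genes * unit + config.intergenic_length
    chrom = "chr1"
    seq = rng.integers(0, 4, size=length, dtype=np.int8)

    genes: List[GeneModel] = []
    alu: List[GenomicInterval] = []
    gene_rows = []
    for g in range(n_genes):
        start = config.intergenic_length + g * unit
        strand = "+" if rng.random() < 0.5 else "-"
        is_nc = rng.random() < config.frac_ncrna
        L = config.gene_length
        exon_bounds = [(0, 1500), (2500, 4500), (5000, L)]
        exons = [
            GenomicInterval(chrom, start + a, start + b, strand)
            for a, b in exon_bounds
        ]
        cds = []
        if not is_nc:
            for a, b in exon_bounds:
                lo, hi = max(a, 800), min(b, 5500)
                if lo < hi:
                    cds.append(GenomicInterval(chrom, start + lo, start + hi, strand))
        genes.append(
            GeneModel(
                gene_id=f"gene{g + 1}",
                transcript_id=f"tx{g + 1}",
                strand=strand,
                exons=exons,
                cds=cds,
                biotype="ncRNA" if is_nc else "protein_coding",
            )
        )
        alu_len = int(round(config.alu_fraction * L))
        alu_off = 1000
        if alu_len > 0:
            alu.append(GenomicInterval(chrom, start + alu_off, start + alu_off + alu_len))
        gene_rows.append((start, strand, g))

    # plant editing sites, one per gene
    site_order = rng.permutation(n_genes)[: config.n_editing_sites]
    n_snp_ed = int(round(config.frac_snp_editing * config.n_editing_sites))
    kinds = np.array(
        ["snp_editing"] * n_snp_ed
        + ["nonsnp_editing"] * (config.n_editing_sites - n_snp_ed)
    )
    rng.shuffle(kinds)
    has_ecs = rng.random(config.n_editing_sites) < config.ecs_fraction

    truth_rows = []
    for i, gidx in enumerate(site_order):
        start, strand, _ = gene_rows[gidx]
        off = int(rng.integers(600, 2001))
        pos0 = start + off  # 0-based
        # sense base A and biased 5' neighbour
        weights = np.array([0.25, 0.25, 0.25 * config.motif_bias, 0.25])
        weights /= weights.sum()
        nb_sense = rng.choice(_BASE, p=weights)  # order A,C,G,T
        if strand == "+":
            seq[pos0] = 0  # A
            seq[pos0 - 1] = int(np.where(_BASE == nb_sense)[0][0])
        else:
            seq[pos0] = 3  # genomic T, sense A
            comp = complement_base(nb_sense)
            seq[pos0 + 1] = int(np.where(_BASE == comp)[0][0])
        ecs_start = ecs_end = -1
        if has_ecs[i]:
            lo, hi = pos0 - 15, pos0 + 16
            arm_max = min(2400, config.gene_length - off - 60)
            d = int(rng.integers(400, arm_max))
            arm_start = pos0 + d
            region = seq[lo:hi]
            # reverse complement in code space: complement = 3 - code
            seq[arm_start : arm_start + 31] = (3 - region)[::-1]
            ecs_start, ecs_end = arm_start, arm_start + 31
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos0 + 1,
                "strand": strand,
                "gene_id": f"gene{gidx + 1}",
                "kind": kinds[i],
                "selection": (
                    config.editing_snp_selection if kinds[i] == "snp_editing" else "none"
                ),
                "ecs_start": ecs_start,
                "ecs_end": ecs_end,
            }
        )

    a, b = config.editing_level_beta
    levels = rng.beta(a, b, size=(config.n_editing_sites, config.n_samples))
    levels = np.clip(levels, config.level_min, 1.0)
    truth = pd.DataFrame(truth_rows)
    truth["mean_level"] = levels.mean(axis=1)
    sequences = {chrom: "".join(_BASE[seq])}
    return Reference(sequences=sequences, genes=genes, alu=alu, truth=truth,
                     levels=levels)


# ---------------------------------------------------------------------------
# Genotype panel


_NEUTRAL_CDF_CACHE: Dict[int, np.ndarray] = {}


def _draw_neutral_freq(rng: np.random.Generator, n: int, pop_size: int) -> np.ndarray:
    """Derived frequencies on the lattice k/2N with P(k) proportional to 1/k."""
    cdf = _NEUTRAL_CDF_CACHE.get(pop_size)
    if cdf is None:
        w = 1.0 / np.arange(1, 2 * pop_size)
        cdf = np.cumsum(w / w.sum())
        _NEUTRAL_CDF_CACHE[pop_size] = cdf
    k = np.searchsorted(cdf, rng.random(n)) + 1
    return k / (2.0 * pop_size)


def _draw_genotypes(
    rng: np.random.Generator, freq: float, n_samples: int, max_tries: int = 200
) -> np.ndarray:
    """HWE genotypes (n_samples, 2) polymorphic in the sample, or None."""
    for _ in range(max_tries):
        g = (rng.random((n_samples, 2)) < freq).astype(np.int8)
        s = g.sum()
        if 0 < s < 2 * n_samples:
            return g
    return None


def simulate_panel(config: SimConfig, reference: Reference) -> Panel:
    """Draw the SNP panel: editing SNPs plus neutral/balanced pure SNPs.

    Editing SNPs are A/G on the sense strand (genomic T/C on minus-strand
    genes); their derived allele frequency comes from the balanced
    Beta(20, 20) class by default, with the ancestral allele equally often
    the editable (A) and the edited (G) state.  Pure SNPs draw from the
    neutral 1/f spectrum with the reference as the ancestral allele.
    Every emitted site is polymorphic in the sample.
    """
    rng = _rng(config, _STAGE_PANEL)
    if config.n_samples < 2:
        raise ValueError("need at least 2 samples")
    chrom = next(iter(reference.sequences))
    seq = reference.sequences[chrom]
    truth = reference.truth.copy()
    occupied = set()
    for row in truth.itertuples(index=False):
        occupied.update(range(row.pos - 17, row.pos + 16))
        if row.ecs_start >= 0:
            occupied.update(range(row.ecs_start, row.ecs_end))

    records: List[SnpRecord] = []
    rows = []

    # --- editing SNPs
    ed = truth[truth["kind"] == "snp_editing"]
    ba, bb = config.balanced_beta
    for row in ed.itertuples(index=False):
        pos0 = row.pos - 1
        ref_base = seq[pos0]
        alt_base = "G" if row.strand == "+" else "C"
        eps = 1.0 / (2 * config.pop_size)
        while True:
            if config.editing_snp_selection == "balanced":
                f = float(np.clip(rng.beta(ba, bb), eps, 1 - eps))
            else:
                f = float(_draw_neutral_freq(rng, 1, config.pop_size)[0])
            geno = _draw_genotypes(rng, f, config.n_samples, max_tries=1)
            if geno is not None:
                break
        # f is the frequency of the derived allele; pick ancestral state
        anc_is_editable = rng.random() < 0.5
        ancestral = ref_base if anc_is_editable else alt_base
        # genotype array codes 1 = alt allele; derived allele is the non-ancestral
        if anc_is_editable:
            alt_geno = geno  # derived = alt (edited state)
        else:
            alt_geno = 1 - geno  # derived = ref; alt freq = 1 - f
        alt_freq = float(alt_geno.mean())
        records.append(
            SnpRecord(
                chrom=chrom, pos=row.pos, id=f"ed_{row.pos}", ref=ref_base,
                alt=alt_base, ancestral=ancestral, alt_freq=alt_freq,
                genotypes=alt_geno, phased=True,
            )
        )
        rows.append({"chrom": chrom, "pos": row.pos, "kind": "snp_editing",
                     "selection": row.selection, "ref": ref_base, "alt": alt_base,
                     "ancestral": ancestral, "derived_freq": float(f)})

    # --- pure SNPs (neutral and optional extra balanced)
    genic_spans = [(g.start, g.end) for g in reference.genes]
    genic_mask = np.zeros(len(seq), dtype=bool)
    for a, b in genic_spans:
        genic_mask[a:b] = True
    free = np.ones(len(seq), dtype=bool)
    free[list(occupied)] = False
    free[:20] = False
    free[-20:] = False
    genic_pool = np.flatnonzero(free & genic_mask)
    inter_pool = np.flatnonzero(free & ~genic_mask)

    n_pure = config.n_sites_neutral + config.n_sites_balanced
    n_genic = int(round(config.frac_snp_genic * n_pure))
    n_inter = n_pure - n_genic
    if n_genic > genic_pool.size or n_inter > inter_pool.size:
        raise ValueError("requested SNP sites exceed sequence capacity")
    pos_genic = rng.choice(genic_pool, size=n_genic, replace=False)
    pos_inter = rng.choice(inter_pool, size=n_inter, replace=False)
    pure_pos = np.sort(np.concatenate([pos_genic, pos_inter]))
    genic_flags = genic_mask[pure_pos]

    sel = np.array(
        ["neutral"] * config.n_sites_neutral + ["balanced"] * config.n_sites_balanced
    )
    rng.shuffle(sel)
    eps = 1.0 / (2 * config.pop_size)

    for pos0, s, genic in zip(pure_pos, sel, genic_flags):
        # redraw frequency and genotypes until the site segregates in the
        # cohort: the panel is conditioned on observed polymorphism
        while True:
            if s == "neutral":
                f = float(_draw_neutral_freq(rng, 1, config.pop_size)[0])
            else:
                f = float(np.clip(rng.beta(ba, bb), eps, 1 - eps))
            geno = _draw_genotypes(rng, f, config.n_samples, max_tries=1)
            if geno is not None:
                break
        ref_base = seq[pos0]
        alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        alt_freq = float(geno.mean())
        records.append(
            SnpRecord(
                chrom=chrom, pos=int(pos0) + 1, id=f"snp_{pos0 + 1}", ref=ref_base,
                alt=alt_base, ancestral=ref_base, alt_freq=alt_freq,
                genotypes=geno, phased=True,
            )
        )
        rows.append({"chrom": chrom, "pos": int(pos0) + 1, "kind": "pure_snp",
                     "selection": s, "ref": ref_base, "alt": alt_base,
                     "ancestral": ref_base, "derived_freq": float(f),
                     "genic": bool(genic)})

    records.sort(key=lambda r: (r.chrom, r.pos))
    snp_truth = pd.DataFrame(rows)
    nonsnp = truth[truth["kind"] == "nonsnp_editing"][["chrom", "pos", "kind",
                                                      "selection"]].copy()
    full = pd.concat([snp_truth, nonsnp], ignore_index=True, sort=False)
    full = full.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return Panel(records=records, samples=config.samples, truth=full)


# ---------------------------------------------------------------------------
# Pileups


def _counts_with_errors(
    rng: np.random.Generator, depth: int, base_probs: np.ndarray, err: float
) -> np.ndarray:
    """Draw per-base read counts with a uniform per-read error channel."""
    if err > 0:
        # each read keeps its base with prob 1-err, else uniform over the others
        m = np.full((4, 4), err / 3.0)
        np.fill_diagonal(m, 1.0 - err)
        base_probs = base_probs @ m
    return rng.multinomial(depth, base_probs)


def _base_probs(ref_code: int, alt_code: int, alt_frac: float) -> np.ndarray:
    p = np.zeros(4)
    p[ref_code] = 1.0 - alt_frac
    p[alt_code] += alt_frac
    return p


def simulate_editing_reads(
    config: SimConfig,
    reference: Reference,
    panel: Panel,
    level_scale: float = 1.0,
    sample_prefix: str = "",
    stage: int = _STAGE_READS,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit per-sample RNA site counts, DNA genotype calls and DNA site counts.

    RNA pileups cover every planted editing site and every genic pure SNP
    (intergenic SNPs are untranscribed and yield no RNA reads).  Depth is
    Poisson(``coverage_mean``) truncated at >= 1.  ``level_scale``
    multiplies every true editing level (capped at 0.98), which emulates
    ADAR over-expression/knockdown condition groups; ``sample_prefix``
    renames samples so condition groups can coexist in one table.

    Returns ``(rna_counts, dna_genotypes, dna_counts)`` data frames.
    """
    if config.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    rng = _rng(config, stage)
    chrom = next(iter(reference.sequences))
    seq = reference.sequences[chrom]
    samples = [sample_prefix + s for s in config.samples]
    code = {"A": 0, "C": 1, "G": 2, "T": 3}

    snp_by_pos = {r.pos: r for r in panel.records}
    levels = np.clip(reference.levels * level_scale, 0.0, 0.98)

    rna_rows = []
    dna_geno_rows = []
    dna_count_rows = []

    def draw_depth(r):
        d = int(r.poisson(config.coverage_mean))
        return max(d, 1)

    # editing sites
    for i, row in enumerate(reference.truth.itertuples(index=False)):
        pos = row.pos
        ref_base = seq[pos - 1]
        edited_base = "G" if row.strand == "+" else "C"
        rc, ec = code[ref_base], code[edited_base]
        snp = snp_by_pos.get(pos)
        for j, sample in enumerate(samples):
            depth = draw_depth(rng)
            lev = float(levels[i, j])
            if snp is None:
                frac = lev
                gt_alt = 0
            else:
                gt_alt = int(snp.genotypes[j].sum())
                frac = {0: lev, 1: 0.5, 2: 1.0}[gt_alt]
            counts = _counts_with_errors(
                rng, depth, _base_probs(rc, ec, frac), config.seq_error_rate
            )
            rna_rows.append((sample, chrom, pos, ref_base, *counts))
            if snp is not None:
                gt = "".join(sorted([ref_base, edited_base][k] for k in
                                    ([0, 0], [0, 1], [1, 1])[gt_alt]))
                for resource in ("wgs", "array"):
                    dna_geno_rows.append((sample, chrom, pos, resource, gt))
                dna_depth = draw_depth(rng)
                dcounts = _counts_with_errors(
                    rng, dna_depth, _base_probs(rc, ec, gt_alt / 2.0), 0.0
                )
                dna_count_rows.append((sample, chrom, pos, ref_base, *dcounts))

    # genic pure SNPs are RNA-covered; DNA genotypes for every pure SNP
    for rec in panel.records:
        if rec.id.startswith("ed_"):
            continue
        ref_c, alt_c = code[rec.ref], code[rec.alt]
        tr = panel.truth[(panel.truth["pos"] == rec.pos)]
        genic = bool(tr.iloc[0].get("genic", False)) if len(tr) else False
        for j, sample in enumerate(samples):
            gt_alt = int(rec.genotypes[j].sum())
            gt = "".join(sorted([rec.ref, rec.alt][k] for k in
                                ([0, 0], [0, 1], [1, 1])[gt_alt]))
            for resource in ("wgs", "array"):
                dna_geno_rows.append((sample, chrom, rec.pos, resource, gt))
            if genic:
                depth = draw_depth(rng)
                counts = _counts_with_errors(
                    rng, depth, _base_probs(ref_c, alt_c, gt_alt / 2.0),
                    config.seq_error_rate,
                )
                rna_rows.append((sample, chrom, rec.pos, rec.ref, *counts))

    cols = ["sample", "chrom", "pos", "ref", "nA", "nC", "nG", "nT"]
    rna = pd.DataFrame(rna_rows, columns=cols)
    rna["depth"] = rna[["nA", "nC", "nG", "nT"]].sum(axis=1)
    dna_geno = pd.DataFrame(
        dna_geno_rows, columns=["sample", "chrom", "pos", "resource", "genotype"]
    )
    dna_counts = pd.DataFrame(dna_count_rows, columns=cols)
    if len(dna_counts):
        dna_counts["depth"] = dna_counts[["nA", "nC", "nG", "nT"]].sum(axis=1)
    return rna, dna_geno, dna_counts


def simulate_condition_reads(
    config: SimConfig,
    reference: Reference,
    panel: Panel,
    factors: Dict[str, float],
) -> Dict[str, pd.DataFrame]:
    """RNA counts for several condition groups sharing one set of true levels.

    ``factors`` maps condition name -> editing-level multiplier (1.0 for the
    control group, e.g. 1.5 for ADAR over-expression).
    """
    out = {}
    for k, (cond, factor) in enumerate(sorted(factors.items())):
        rna, _, _ = simulate_editing_reads(
            config, reference, panel, level_scale=factor,
            sample_prefix=f"{cond}_", stage=_STAGE_READS + 10 + k,
        )
        out[cond] = rna
    return out


# ---------------------------------------------------------------------------
# GWAS summaries


def simulate_gwas(
    config: SimConfig, panel: Panel, dataset_id: str = "ds1", disease: str = "sim"
) -> List[GwasRecord]:
    """GWAS p-values for every panel SNP.

    Non-editing SNPs draw p ~ Uniform(0, 1).  With an enrichment factor
    above 1, each editing SNP hits ``p < gwas_p_thresh`` independently with
    probability ``factor * gwas_p_thresh`` (capped at 1); hits draw
    p ~ Uniform(0, thresh), misses p ~ Uniform(thresh, 1).  Factor 1 leaves
    editing SNPs on the plain uniform, so hit rates match controls in
    expectation and downstream test p-values stay calibrated.
    """
    if config.gwas_enrichment_factor < 1.0:
        raise ValueError("gwas_enrichment_factor must be >= 1")
    rng = _rng(config, _STAGE_GWAS)
    thresh = config.gwas_p_thresh
    rate = min(config.gwas_enrichment_factor * thresh, 1.0)
    n = len(panel.records)
    is_editing = np.array([r.id.startswith("ed_") for r in panel.records])
    p = rng.uniform(0.0, 1.0, size=n)
    if config.gwas_enrichment_factor > 1.0 and is_editing.any():
        m = int(is_editing.sum())
        hit = rng.random(m) < rate
        p_ed = np.where(
            hit,
            rng.uniform(0.0, thresh, size=m),
            rng.uniform(thresh, 1.0, size=m),
        )
        p[is_editing] = p_ed
    p = np.maximum(p, 1e-300)
    return [
        GwasRecord(chrom=rec.chrom, pos=rec.pos, id=rec.id, p_value=float(pv),
                   dataset_id=dataset_id, disease=disease)
        for rec, pv in zip(panel.records, p)
    ]


# ---------------------------------------------------------------------------
# Haplotype-level simulators for the population-genetic statistics


def simulate_neutral_windows(
    n_windows: int,
    n_hap: int,
    n_sites: int,
    seed: int,
    pop_size: int = 5000,
) -> np.ndarray:
    """Neutral windows: (n_windows, n_hap, n_sites) 0/1 haplotype arrays.

    Each site independently draws a population derived frequency from the
    1/f lattice and then Bernoulli haplotype states, re-drawn until the
    site segregates in the sample (fixed-S windows, no linkage).
    """
    rng = np.random.default_rng([seed, 101])
    out = np.empty((n_windows, n_hap, n_sites), dtype=np.int8)
    for wi in range(n_windows):
        for si in range(n_sites):
            while True:
                f = float(_draw_neutral_freq(rng, 1, pop_size)[0])
                col = (rng.random(n_hap) < f).astype(np.int8)
                s = col.sum()
                if 0 < s < n_hap:
                    out[wi, :, si] = col
                    break
    return out


def simulate_balanced_windows(
    n_windows: int,
    n_hap: int,
    n_sites: int,
    seed: int,
    linked_frac: float = 0.5,
    flip_rate: float = 0.05,
    beta: Tuple[float, float] = (20.0, 20.0),
    pop_size: int = 5000,
) -> np.ndarray:
    """Windows centred on a balanced polymorphism.

    The focal (first) site draws an intermediate frequency from
    Beta(*beta*); a ``linked_frac`` share of the flanking sites ride on the
    two balanced haplotype backgrounds (the focal column or its complement,
    with a small per-haplotype flip rate emulating recombination/mutation),
    the rest are neutral.  This is the minimal structure behind the excess
    of intermediate-frequency alleles and positive Tajima's D around a
    balanced locus.
    """
    rng = np.random.default_rng([seed, 102])
    neutral = simulate_neutral_windows(n_windows, n_hap, n_sites, seed + 7,
                                       pop_size=pop_size)
    out = neutral.copy()
    ba, bb = beta
    for wi in range(n_windows):
        while True:
            f = rng.beta(ba, bb)
            focal = (rng.random(n_hap) < f).astype(np.int8)
            if 0 < focal.sum() < n_hap:
                break
        out[wi, :, 0] = focal
        for si in range(1, n_sites):
            if rng.random() < linked_frac:
                base = focal if rng.random() < 0.5 else 1 - focal
                flips = rng.random(n_hap) < flip_rate
                col = np.where(flips, 1 - base, base).astype(np.int8)
                if 0 < col.sum() < n_hap:
                    out[wi, :, si] = col
    return out


def simulate_haplotype_blocks(
    n_hap: int,
    n_snps: int,
    length: int,
    switch_rate: float,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Block-copying haplotypes for LD-decay tests.

    Two founder haplotypes differ at every SNP; each sample haplotype is a
    mosaic of the founders with per-bp switch probability ``switch_rate``.
    Returns ``(haplotypes, positions)`` with haplotypes of shape
    (n_hap, n_snps).  Pairwise r^2 decays monotonically (in expectation)
    with distance at rate governed by ``switch_rate``.
    """
    rng = np.random.default_rng([seed, 103])
    positions = np.sort(rng.choice(np.arange(1, length), size=n_snps, replace=False))
    gaps = np.diff(positions, prepend=positions[0])
    haps = np.empty((n_hap, n_snps), dtype=np.int8)
    for h in range(n_hap):
        state = int(rng.random() < 0.5)
        for i, gap in enumerate(gaps):
            if i > 0:
                p_switch = 0.5 * (1.0 - (1.0 - 2.0 * switch_rate) ** int(gap))
                if rng.random() < p_switch:
                    state = 1 - state
            haps[h, i] = state
    return haps, positions


# ---------------------------------------------------------------------------
# End-to-end convenience


def simulate_all(config: SimConfig, outdir: Optional[str] = None):
    """Run every generator stage; optionally write the full fixture set."""
    reference = simulate_reference(config)
    panel = simulate_panel(config, reference)
    rna, dna_geno, dna_counts = simulate_editing_reads(config, reference, panel)
    gwas = simulate_gwas(config, panel)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        chrom = next(iter(reference.sequences))
        esio.write_fasta(os.path.join(outdir, "ref.fa"), reference.sequences)
        esio.write_gtf(os.path.join(outdir, "genes.gtf"), reference.genes)
        esio.write_bed3(os.path.join(outdir, "alu.bed"), reference.alu)
        esio.write_vcf(
            os.path.join(outdir, "panel.vcf"), panel.records, panel.samples,
            contigs={chrom: len(reference.sequences[chrom])},
        )
        esio.write_site_counts(os.path.join(outdir, "counts.tsv"), rna)
        esio.write_dna_genotypes(os.path.join(outdir, "dna_genotypes.tsv"), dna_geno)
        esio.write_site_counts(os.path.join(outdir, "dna_counts.tsv"), dna_counts)
        esio.write_gwas(os.path.join(outdir, "gwas.tsv"), gwas)
        panel.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    return reference, panel, rna, dna_geno, dna_counts, gwas
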