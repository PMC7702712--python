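"""The editing-site identification cascade.

Per-sample RNA variants (>= 2 supporting reads at base/mapping quality
>= 20, applied upstream in the pileup) are filtered by a per-sample purity
rule (>= 80% A-to-G/T-to-C variants), split into SNP-overlapping and
non-SNP candidates with DNA-genotype gating (SNP candidates require every
DNA resource to agree on a homozygous-reference genotype), and finalised
with allele-support, non-Alu stringency and gene-strand consistency
filters.  The caller is parameterised by ``edit_type`` so the C-to-T/G-to-A
negative control is a one-flag rerun of the same pipeline.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import BASES, CallerThresholds, GeneModel, GenomicInterval, SiteCounts

CALL_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "ref_count", "alt_count",
    "level", "region_class",
]

#: genomic mismatch pairs consistent with each edit type, strand-unaware
EDIT_PAIRS = {
    "AG": (("A", "G"), ("T", "C")),
    "CT": (("C", "T"), ("G", "A")),
}


@dataclass(frozen=True)
class VariantCall:
    """A single per-sample RNA-DNA mismatch call."""

    sample_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    ref_count: int
    alt_count: int
    region_class: str

    @property
    def level(self) -> float:
        return self.alt_count / (self.ref_count + self.alt_count)


class _IntervalIndex:
    """Sorted, per-chromosome lookup for (possibly overlapping) intervals."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([a for a, _ in ivs])
            # running maximum of ends makes the membership test a single
            # searchsorted even with overlapping intervals
            ends = np.maximum.accumulate(np.array([b for _, b in ivs]))
            self._by_chrom[chrom] = (starts, ends)

    def contains(self, chrom: str, pos0: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = np.searchsorted(starts, pos0, side="right")
        return i > 0 and ends[i - 1] > pos0

    def contains_many(self, chroms: pd.Series, pos0: pd.Series) -> np.ndarray:
        out = np.zeros(len(chroms), dtype=bool)
        for chrom in chroms.unique():
            m = (chroms == chrom).to_numpy()
            if chrom not in self._by_chrom:
                continue
            starts, ends = self._by_chrom[chrom]
            idx = np.searchsorted(starts, pos0.to_numpy()[m], side="right")
            ok = idx > 0
            ok[ok] = ends[idx[ok] - 1] > pos0.to_numpy()[m][ok]
            out[m] = ok
        return out


# ---------------------------------------------------------------------------
# Stage 1: per-sample variant calls


def call_variants(
    counts: "pd.DataFrame | Iterable[SiteCounts]",
    thresholds: CallerThresholds = CallerThresholds(),
    alu: Sequence[GenomicInterval] = (),
) -> pd.DataFrame:
    """Per-sample variant calls from quality-filtered pileup counts.

    Emits one row per (sample, site, alt base) with at least
    ``thresholds.min_alt_reads`` supporting reads; sites with zero coverage
    of both alleles are skipped.  ``region_class`` is ``Alu`` or ``nonAlu``
    from the repeat intervals.
    """
    if not isinstance(counts, pd.DataFrame):
        rows = [
            (c.sample_id, c.chrom, c.pos, c.ref_base,
             c.counts.get("A", 0), c.counts.get("C", 0),
             c.counts.get("G", 0), c.counts.get("T", 0))
            for c in counts
        ]
        counts = pd.DataFrame(
            rows, columns=["sample", "chrom", "pos", "ref", "nA", "nC", "nG", "nT"]
        )
    if counts.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    long = counts.melt(
        id_vars=["sample", "chrom", "pos", "ref"],
        value_vars=["nA", "nC", "nG", "nT"],
        var_name="alt", value_name="alt_count",
    )
    long["alt"] = long["alt"].str[1]
    codes = pd.Categorical(counts["ref"], categories=list("ACGT")).codes
    ref_count = counts[["nA", "nC", "nG", "nT"]].to_numpy()[
        np.arange(len(counts)), codes
    ]
    key = ["sample", "chrom", "pos"]
    long = long.merge(
        counts[key].assign(ref_count=ref_count), on=key, how="left"
    )
    calls = long[
        (long["alt"] != long["ref"])
        & (long["alt_count"] >= thresholds.min_alt_reads)
        & (long["alt_count"] + long["ref_count"] > 0)
    ].copy()
    calls["level"] = calls["alt_count"] / (calls["ref_count"] + calls["alt_count"])
    index = _IntervalIndex(alu)
    calls["region_class"] = np.where(
        index.contains_many(calls["chrom"], calls["pos"] - 1), "Alu", "nonAlu"
    )
    return calls[CALL_COLUMNS].sort_values(["sample", "chrom", "pos", "alt"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Stage 2: per-sample purity


def sample_purity_filter(
    calls: pd.DataFrame,
    thresholds: CallerThresholds = CallerThresholds(),
    edit_type: str = "AG",
) -> Tuple[List[str], pd.Series]:
    """Retain samples whose editing-consistent variant fraction is >= 80%.

    The stage is strand-unaware: both A>G and T>C count as
    editing-consistent (mirror pairs for the control edit type).  Samples
    with zero variants are dropped (fraction undefined).  Returns
    ``(retained_sample_ids, per_sample_fraction)``.
    """
    pairs = EDIT_PAIRS[edit_type]
    if calls.empty:
        return [], pd.Series(dtype=float)
    consistent = (
        ((calls["ref"] == pairs[0][0]) & (calls["alt"] == pairs[0][1]))
        | ((calls["ref"] == pairs[1][0]) & (calls["alt"] == pairs[1][1]))
    )
    frac = consistent.groupby(calls["sample"]).mean()
    retained = frac[frac >= thresholds.sample_purity].index.tolist()
    return sorted(retained), frac


# ---------------------------------------------------------------------------
# Stage 3: SNP / non-SNP split with DNA gating


def split_by_snp(
    calls: pd.DataFrame,
    snp_positions: Iterable[Tuple[str, int]],
    dna_genotypes: Dict[Tuple[str, str, int], Dict[str, str]],
) -> Dict[str, pd.DataFrame]:
    """Split calls into SNP-overlapping and non-SNP candidates.

    A call at a known SNP position survives only when every available DNA
    resource for that sample reports the same homozygous-reference
    genotype; heterozygous, non-reference, conflicting or missing DNA
    excludes the call.  Returns ``{"snp": ..., "nonsnp": ..., "excluded":
    ...}`` where the exclusion table carries a ``reason`` column
    (``het_or_nonref``, ``conflict``, ``no_dna``).
    """
    snp_set = set(snp_positions)
    at_snp = calls.apply(lambda r: (r["chrom"], r["pos"]) in snp_set, axis=1) \
        if len(calls) else pd.Series(dtype=bool)
    nonsnp = calls[~at_snp].copy() if len(calls) else calls.copy()
    snp_rows = calls[at_snp] if len(calls) else calls

    kept, excluded = [], []
    for row in snp_rows.itertuples(index=False):
        resources = dna_genotypes.get((row.sample, row.chrom, row.pos))
        if not resources:
            excluded.append((*row, "no_dna"))
            continue
        gts = set(resources.values())
        if len(gts) > 1:
            excluded.append((*row, "conflict"))
            continue
        gt = next(iter(gts))
        if gt == row.ref * 2:
            kept.append(row)
        else:
            excluded.append((*row, "het_or_nonref"))
    snp_df = pd.DataFrame(kept, columns=list(snp_rows.columns))
    excl_df = pd.DataFrame(excluded, columns=list(snp_rows.columns) + ["reason"])
    return {"snp": snp_df, "nonsnp": nonsnp, "excluded": excl_df}


# ---------------------------------------------------------------------------
# Stage 4: final site filters, strand inference


def _max_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


class _GeneIndex:
    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: Dict[str, List[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda g: g.start)
        self._starts = {
            chrom: [g.start for g in gs] for chrom, gs in self._by_chrom.items()
        }

    def overlapping(self, chrom: str, pos0: int) -> List[GeneModel]:
        gs = self._by_chrom.get(chrom, [])
        if not gs:
            return []
        i = bisect_right(self._starts[chrom], pos0)
        out = []
        # genes are non-nested in practice; scan back a bounded distance
        for g in gs[max(0, i - 8) : i]:
            if g.start <= pos0 < g.end:
                out.append(g)
        return out


def finalize_sites(
    candidates: Dict[str, pd.DataFrame],
    thresholds: CallerThresholds,
    genes: Sequence[GeneModel],
    sequences: Optional[Dict[str, str]] = None,
    edit_type: str = "AG",
) -> pd.DataFrame:
    """Aggregate per-sample candidates into final editing sites.

    Keeps per-sample calls with >= 3 reads of each allele; non-Alu calls
    additionally need level >= 0.1, no homopolymer run longer than 4 around
    the site, and distance > 4 nt from any annotated splice boundary.  The
    strand comes from the overlapping gene: a forward-pair mismatch (A>G)
    needs a + gene, the mirror pair (T>C) a - gene; contradicting calls are
    dropped, sites overlapping genes on both strands are ambiguous, and
    sites in no gene keep their genomic mismatch with strand ".".

    Returns one row per site: chrom, pos, strand, class, alu_flag,
    edit ref/alt on the genome, and the number of supporting samples.
    """
    fwd, rev = EDIT_PAIRS[edit_type]
    gene_index = _GeneIndex(genes)
    splice_bounds: Dict[str, List[int]] = {}
    for g in genes:
        bounds = []
        for e in g.exons:
            bounds.extend([e.start, e.end])
        internal = [b for b in bounds if b not in (g.start, g.end)]
        splice_bounds.setdefault(g.chrom, []).extend(internal)
    for chrom in splice_bounds:
        splice_bounds[chrom] = sorted(splice_bounds[chrom])

    def near_splice(chrom: str, pos0: int) -> bool:
        bs = splice_bounds.get(chrom, [])
        if not bs:
            return False
        i = bisect_right(bs, pos0)
        for b in bs[max(0, i - 1) : i + 1]:
            if abs(pos0 - b) <= thresholds.nonalu_splice_distance:
                return True
        return False

    out_rows = []
    for klass, df in (("snp_editing", candidates["snp"]),
                      ("nonsnp_editing", candidates["nonsnp"])):
        if df is None or df.empty:
            continue
        good = df[
            (df["ref_count"] >= thresholds.min_ref_reads)
            & (df["alt_count"] >= thresholds.min_alt_reads_final)
        ].copy()
        if good.empty:
            continue
        nonalu = good["region_class"] == "nonAlu"
        keep = np.ones(len(good), dtype=bool)
        if nonalu.any():
            keep &= (~nonalu.to_numpy()) | (
                (good["level"] >= thresholds.nonalu_min_level)
                & (good["alt_count"] >= thresholds.nonalu_min_alt)
            ).to_numpy()
            if sequences is not None:
                for i, row in enumerate(good.itertuples(index=False)):
                    if not keep[i] or row.region_class != "nonAlu":
                        continue
                    seq = sequences[row.chrom]
                    pos0 = row.pos - 1
                    # wide enough to expose any run longer than the cap that
                    # contains or borders the site
                    w = thresholds.nonalu_homopolymer_max + 1
                    window = seq[max(0, pos0 - w) : pos0 + w + 1]
                    if _max_run(window) > thresholds.nonalu_homopolymer_max:
                        keep[i] = False
                    elif near_splice(row.chrom, pos0):
                        keep[i] = False
        good = good[keep]
        if good.empty:
            continue
        for (chrom, pos, ref, alt), grp in good.groupby(
            ["chrom", "pos", "ref", "alt"], sort=True
        ):
            mismatch = (ref, alt)
            if mismatch not in (fwd, rev):
                continue
            overlapping = gene_index.overlapping(chrom, pos - 1)
            strands = {g.strand for g in overlapping}
            if strands == {"+", "-"}:
                continue  # ambiguous strand context
            if strands:
                strand = next(iter(strands))
                required = fwd if strand == "+" else rev
                if mismatch != required:
                    continue  # mismatch type contradicts gene strand
            else:
                strand = "."
            out_rows.append(
                {
                    "chrom": chrom, "pos": pos, "strand": strand, "class": klass,
                    "ref": ref, "alt": alt,
                    "alu_flag": bool((grp["region_class"] == "Alu").any()),
                    "n_samples": grp["sample"].nunique(),
                }
            )
    sites = pd.DataFrame(
        out_rows,
        columns=["chrom", "pos", "strand", "class", "ref", "alt", "alu_flag",
                 "n_samples"],
    )
    return sites.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Editing levels


def _sense_counts(row, ref: str, alt: str) -> Tuple[int, int]:
    a = int(getattr(row, f"n{ref}"))
    g = int(getattr(row, f"n{alt}"))
    return a, g


def editing_levels(
    sites: pd.DataFrame,
    counts: pd.DataFrame,
    tissue_map: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-sample editing levels, per-tissue means and the representative level.

    The level is edited/(reference + edited) on the sense strand, computed
    from genome-strand counts via the site's stored ref/alt orientation.
    Samples without coverage of either allele at a site are excluded from
    the tissue mean; the representative level is the maximum over tissue
    means.  Returns the site table with added ``level_<sample>``,
    ``tissue_mean_<tissue>`` and ``representative_level`` columns.
    """
    if tissue_map is None:
        tissue_map = {s: "tissue1" for s in counts["sample"].unique()}
    indexed = counts.set_index(["chrom", "pos", "sample"]).sort_index()
    samples = sorted(counts["sample"].unique())
    tissues = sorted(set(tissue_map.values()))
    out = sites.copy()
    level_cols = {s: [] for s in samples}
    tissue_means = {t: [] for t in tissues}
    reps = []
    for site in sites.itertuples(index=False):
        per_sample = {}
        for s in samples:
            try:
                row = indexed.loc[(site.chrom, site.pos, s)]
            except KeyError:
                level_cols[s].append(np.nan)
                continue
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            a = int(row[f"n{site.ref}"])
            g = int(row[f"n{site.alt}"])
            lev = np.nan if a + g == 0 else g / (a + g)
            per_sample[s] = lev
            level_cols[s].append(lev)
        t_means = {}
        for t in tissues:
            vals = [
                per_sample[s] for s in per_sample
                if tissue_map.get(s) == t and not np.isnan(per_sample[s])
            ]
            t_means[t] = float(np.mean(vals)) if vals else np.nan
            tissue_means[t].append(t_means[t])
        finite = [v for v in t_means.values() if not np.isnan(v)]
        reps.append(max(finite) if finite else np.nan)
    for s in samples:
        out[f"level_{s}"] = level_cols[s]
    for t in tissues:
        out[f"tissue_mean_{t}"] = tissue_means[t]
    out["representative_level"] = reps
    return out


# ---------------------------------------------------------------------------
# Condition comparison (ADAR perturbation experiments)


def compare_conditions(
    sites: pd.DataFrame,
    counts_by_condition: Dict[str, pd.DataFrame],
    dna_counts: Optional[pd.DataFrame] = None,
    min_depth: int = 10,
    min_level: float = 0.02,
    dna_min_depth: int = 5,
) -> pd.DataFrame:
    """Per-site editing-level differences between condition groups.

    Sites are kept when covered by >= ``min_depth`` reads in every sample of
    every condition and edited above ``min_level`` in at least one sample;
    SNP-editing sites additionally need DNA coverage >= ``dna_min_depth``
    with zero edited-allele reads.  The output has one mean level column
    per condition plus ``delta_<cond>`` columns relative to the first
    (alphabetical) condition.
    """
    conds = sorted(counts_by_condition)
    if len(conds) < 2:
        raise ValueError("need at least two condition groups")
    indexed = {
        c: df.set_index(["chrom", "pos", "sample"]).sort_index()
        for c, df in counts_by_condition.items()
    }
    dna_idx = None
    if dna_counts is not None and len(dna_counts):
        dna_idx = dna_counts.set_index(["chrom", "pos"]).sort_index()

    rows = []
    for site in sites.to_dict("records"):
        chrom, pos = site["chrom"], site["pos"]
        ref, alt = site["ref"], site["alt"]
        site_class = site.get("class")
        levels = {}
        ok = True
        max_level = 0.0
        for c in conds:
            try:
                sub = indexed[c].loc[(chrom, pos)]
            except KeyError:
                ok = False
                break
            depth = sub[["nA", "nC", "nG", "nT"]].sum(axis=1)
            if (depth < min_depth).any():
                ok = False
                break
            lev = sub[f"n{alt}"] / (sub[f"n{ref}"] + sub[f"n{alt}"])
            levels[c] = float(lev.mean())
            max_level = max(max_level, float(lev.max()))
        if not ok or max_level <= min_level:
            continue
        if site_class == "snp_editing" and dna_idx is not None:
            try:
                dsub = dna_idx.loc[[(chrom, pos)]]
            except KeyError:
                continue
            ddepth = dsub[["nA", "nC", "nG", "nT"]].sum(axis=1)
            if (ddepth < dna_min_depth).any() or (dsub[f"n{alt}"] > 0).any():
                continue
        row = {"chrom": chrom, "pos": pos, "class": site_class}
        for c in conds:
            row[f"level_{c}"] = levels[c]
        for c in conds[1:]:
            row[f"delta_{c}"] = levels[c] - levels[conds[0]]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summary


def snp_editing_proportion(n_snp_sites: int, n_nonsnp_sites: int) -> float:
    """Proportion of called editing sites that overlap known SNPs."""
    total = n_snp_sites + n_nonsnp_sites
    if total == 0:
        raise ValueError("no sites")
    return n_snp_sites / total


# ---------------------------------------------------------------------------
# End-to-end convenience


def call_editing_sites(
    counts: pd.DataFrame,
    snp_positions: Iterable[Tuple[str, int]],
    dna_genotypes: Dict[Tuple[str, str, int], Dict[str, str]],
    genes: Sequence[GeneModel],
    sequences: Optional[Dict[str, str]] = None,
    alu: Sequence[GenomicInterval] = (),
    thresholds: CallerThresholds = CallerThresholds(),
    edit_type: str = "AG",
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Run the full identification cascade; returns (sites, diagnostics)."""
    calls = call_variants(counts, thresholds, alu)
    retained, purity = sample_purity_filter(calls, thresholds, edit_type)
    calls = calls[calls["sample"].isin(retained)]
    parts = split_by_snp(calls, snp_positions, dna_genotypes)
    sites = finalize_sites(parts, thresholds, genes, sequences, edit_type)
    diagnostics = {
        "n_calls": len(calls),
        "retained_samples": retained,
        "purity": purity,
        "n_excluded_snp_calls": len(parts["excluded"]),
    }
    return sites, diagnostics
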