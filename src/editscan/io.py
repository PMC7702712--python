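"""Readers and writers for the external formats the pipeline touches.

VCF is read through :mod:`cyvcf2`, GTF through :mod:`gffutils`, FASTA
through :mod:`pyfaidx`; tabular formats (site counts, GWAS summaries, BED,
editing-site tables) go through :mod:`pandas`.  All readers normalise to the
conventions of :mod:`editscan.core`: 1-based point positions, 0-based
half-open intervals.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import BASES, GeneModel, GenomicInterval, GwasRecord, SiteCounts, SnpRecord


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str, require_biallelic: bool = True
) -> Tuple[List[SnpRecord], List[str], Dict[str, int]]:
    """Read a VCF into :class:`SnpRecord` objects.

    Returns ``(records, sample_order, dropped)`` where ``dropped`` counts the
    rows removed per reason (``indel``, ``multiallelic``, ``monomorphic``).
    Indels, multiallelic and monomorphic sites are removed when
    ``require_biallelic`` is set; the alternate-allele frequency is computed
    from the genotypes; the ancestral allele is taken from INFO/AA
    (case-insensitive, lowercase low-confidence calls accepted) and left
    unknown when AA is absent or matches neither allele.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"{path}: malformed VCF header ({exc})") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF has no sample columns (GT required)")

    records: List[SnpRecord] = []
    dropped = {"indel": 0, "multiallelic": 0, "monomorphic": 0}
    for var in vcf:
        if len(var.ALT) != 1:
            if require_biallelic:
                dropped["multiallelic"] += 1
                continue
            raise ParseError(
                f"{path}: multiallelic record at {var.CHROM}:{var.POS} "
                "with require_biallelic disabled is not representable"
            )
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            if require_biallelic:
                dropped["indel"] += 1
                continue
            raise ParseError(f"{path}: non-SNP allele at {var.CHROM}:{var.POS}")
        gts = var.genotypes
        if gts is None or len(gts) != len(samples):
            raise ParseError(f"{path}: missing GT at {var.CHROM}:{var.POS}")
        geno = np.array([[g[0], g[1]] for g in gts], dtype=np.int8)
        phased = all(bool(g[2]) for g in gts)
        called = geno[geno >= 0]
        if called.size == 0:
            dropped["monomorphic"] += 1
            continue
        alt_freq = float(np.mean(called == 1))
        if require_biallelic and (alt_freq == 0.0 or alt_freq == 1.0):
            dropped["monomorphic"] += 1
            continue
        aa = var.INFO.get("AA")
        ancestral = None
        if aa:
            aa = str(aa).split("|")[0].strip().upper()
            if aa in (ref, alt):
                ancestral = aa
        records.append(
            SnpRecord(
                chrom=var.CHROM,
                pos=var.POS,
                id=var.ID or ".",
                ref=ref,
                alt=alt,
                ancestral=ancestral,
                alt_freq=alt_freq,
                genotypes=geno,
                phased=phased,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records, samples, dropped


def write_vcf(
    path: str,
    records: Iterable[SnpRecord],
    samples: List[str],
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write SNP records as a minimal VCF v4.2 with GT and INFO/AA."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        sep_for = lambda rec: "|" if rec.phased else "/"
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = f"AA={rec.ancestral}" if rec.ancestral else "."
            if rec.genotypes is None:
                raise ValueError(f"{rec.chrom}:{rec.pos}: cannot write VCF without GT")
            sep = sep_for(rec)
            gts = [
                "./." if a < 0 else f"{a}{sep}{b}" for a, b in rec.genotypes.tolist()
            ]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}\t.\t.\t"
                f"{info}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models


def _biotype_from_attrs(attrs, has_cds: bool) -> str:
    for key in ("gene_biotype", "transcript_biotype", "gene_type"):
        if key in attrs:
            val = attrs[key][0] if isinstance(attrs[key], list) else attrs[key]
            return "protein_coding" if val == "protein_coding" else "ncRNA"
    return "protein_coding" if has_cds else "ncRNA"


def read_gene_models(path: str, fasta: Optional[str] = None) -> List[GeneModel]:
    """Read gene models from GTF (exon/CDS features) or BED12.

    The format is chosen by extension (``.bed``/``.bed12`` vs anything
    else).  When ``fasta`` is given, intervals beyond the declared contig
    length raise :class:`ParseError`.
    """
    if path.endswith((".bed", ".bed12")):
        models = _read_bed12(path)
    else:
        models = _read_gtf(path)
    if fasta is not None:
        from pyfaidx import Fasta

        fa = Fasta(fasta)
        for m in models:
            if m.chrom not in fa:
                raise ParseError(f"{path}: unknown contig {m.chrom}")
            if m.end > len(fa[m.chrom]):
                raise ParseError(
                    f"{path}: transcript {m.transcript_id} extends past end of "
                    f"{m.chrom} ({m.end} > {len(fa[m.chrom])})"
                )
    return models


def _read_gtf(path: str) -> List[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: Dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        entry = transcripts.setdefault(
            tid, {"gene_id": gid, "strand": feat.strand, "exons": [], "cds": [],
                  "attrs": feat.attributes}
        )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        entry["exons" if feat.featuretype == "exon" else "cds"].append(iv)
    models = []
    for tid, entry in transcripts.items():
        models.append(
            GeneModel(
                gene_id=entry["gene_id"],
                transcript_id=tid,
                strand=entry["strand"],
                exons=entry["exons"],
                cds=entry["cds"],
                biotype=_biotype_from_attrs(entry["attrs"], bool(entry["cds"])),
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start))
    return models


def _read_bed12(path: str) -> List[GeneModel]:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes",
        "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    models = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [
            GenomicInterval(row.chrom, row.start + s, row.start + s + sz, row.strand)
            for s, sz in zip(starts, sizes)
        ]
        cds = []
        if row.thick_end > row.thick_start:
            for e in exons:
                lo, hi = max(e.start, row.thick_start), min(e.end, row.thick_end)
                if lo < hi:
                    cds.append(GenomicInterval(row.chrom, lo, hi, row.strand))
        models.append(
            GeneModel(
                gene_id=str(row.name),
                transcript_id=str(row.name),
                strand=row.strand,
                exons=exons,
                cds=cds,
                biotype="protein_coding" if cds else "ncRNA",
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start))
    return models


def write_gtf(path: str, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_biotype "{m.biotype}";'
            )
            for iv in m.exons:
                fh.write(
                    f"{iv.chrom}\teditscan\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
            for iv in m.cds:
                fh.write(
                    f"{iv.chrom}\teditscan\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{m.strand}\t0\t{attrs}\n"
                )


def write_bed12(path: str, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(len(e)) for e in m.exons) + ","
            starts = ",".join(str(e.start - m.start) for e in m.exons) + ","
            thick = (m.cds[0].start, m.cds[-1].end) if m.cds else (m.start, m.start)
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.transcript_id}\t0\t{m.strand}\t"
                f"{thick[0]}\t{thick[1]}\t0\t{len(m.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# BED3 (Alu / repeat intervals)


def read_bed3(path: str) -> List[GenomicInterval]:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
    )
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()
    ]


def write_bed3(path: str, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Site-count tables (post-alignment pileup summaries)

SITE_COUNT_COLUMNS = ["sample", "chrom", "pos", "ref", "nA", "nC", "nG", "nT"]


def read_site_counts(path: str) -> Iterator[SiteCounts]:
    """Stream per-sample per-site base counts from a TSV.

    Rows whose reference base is not A/C/G/T raise :class:`ParseError`
    naming the offending row; negative counts are an error.  An empty file
    yields an empty stream.
    """
    df = read_site_counts_frame(path)
    for row in df.itertuples(index=False):
        yield SiteCounts(
            sample_id=row.sample,
            chrom=row.chrom,
            pos=int(row.pos),
            ref_base=row.ref,
            counts={"A": int(row.nA), "C": int(row.nC), "G": int(row.nG),
                    "T": int(row.nT)},
        )


def read_site_counts_frame(path: str) -> pd.DataFrame:
    """Site counts as a DataFrame with a recomputed ``depth`` column."""
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=SITE_COUNT_COLUMNS + ["depth"])
    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["ref"].isin(BASES)
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0]) + 2  # 1-based incl. header
        raise ParseError(f"{path}: row {row}: ref base {df['ref'][bad].iloc[0]!r}")
    counts = df[["nA", "nC", "nG", "nT"]].to_numpy()
    if (counts < 0).any():
        row = int(np.argwhere(counts < 0)[0, 0]) + 2
        raise ParseError(f"{path}: row {row}: negative count")
    df = df.copy()
    df["depth"] = counts.sum(axis=1)
    return df


def write_site_counts(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SITE_COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# GWAS summary statistics

GWAS_COLUMNS = ["id", "chrom", "pos", "p_value", "dataset_id", "disease"]


def read_gwas(path: str) -> List[GwasRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        GwasRecord(
            chrom=str(r.chrom), pos=int(r.pos), id=str(r.id),
            p_value=float(r.p_value), dataset_id=str(r.dataset_id),
            disease=str(r.disease),
        )
        for r in df.itertuples(index=False)
    ]


def write_gwas(path: str, records: Iterable[GwasRecord]) -> None:
    rows = [
        (r.id, r.chrom, r.pos, r.p_value, r.dataset_id, r.disease) for r in records
    ]
    pd.DataFrame(rows, columns=GWAS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path: str, sequences: Dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_fasta(path: str):
    """Open a FASTA for random access (pyfaidx handle)."""
    from pyfaidx import Fasta

    return Fasta(path, sequence_always_upper=True)


# ---------------------------------------------------------------------------
# DNA genotype resources (sample x site x resource diploid calls)

GENOTYPE_COLUMNS = ["sample", "chrom", "pos", "resource", "genotype"]


def read_dna_genotypes(path: str) -> Dict[Tuple[str, str, int], Dict[str, str]]:
    """Read DNA genotype calls keyed by (sample, chrom, pos) -> {resource: GT}.

    Genotypes are unordered two-letter strings such as ``AA`` or ``AG``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out: Dict[Tuple[str, str, int], Dict[str, str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault((r.sample, r.chrom, int(r.pos)), {})[r.resource] = r.genotype
    return out


def write_dna_genotypes(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, columns=GENOTYPE_COLUMNS)


# ---------------------------------------------------------------------------
# Editing-site tables

SITE_TABLE_COLUMNS = ["chrom", "pos", "strand", "class", "genic_location", "alu_flag"]


def write_sites_table(path: str, sites: pd.DataFrame) -> None:
    """Write the editing-site table (fixed columns first, per-sample levels after)."""
    fixed = [c for c in SITE_TABLE_COLUMNS if c in sites.columns]
    extra = [c for c in sites.columns if c not in SITE_TABLE_COLUMNS]
    sites.to_csv(path, sep="\t", index=False, columns=fixed + extra)


def read_sites_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
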