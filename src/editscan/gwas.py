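"""Enrichment of editing SNPs in GWAS association signals.

For each GWAS dataset the score is the percentage of editing SNPs with an
association p-value below the threshold divided by the same percentage
among control SNPs, with a two-sided Fisher's exact test on the underlying
2x2 table.  Diseases covered by several datasets are represented by the
dataset with the median score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .core import GwasRecord

Key = Tuple[str, int]


@dataclass
class EnrichmentResult:
    dataset_id: str
    disease: str
    a: int  # editing SNPs hitting p < threshold
    b: int  # editing SNPs not hitting
    c: int  # control SNPs hitting
    d: int  # control SNPs not hitting
    pct_editing: float
    pct_control: Optional[float]
    score: Optional[float]
    p_value: float
    enriched: bool

    @property
    def counts(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def enrich(
    editing_snps: Iterable[Key],
    control_snps: Iterable[Key],
    gwas_records: Sequence[GwasRecord],
    p_thresh: float = 0.001,
) -> EnrichmentResult:
    """Enrichment score and Fisher's exact p for one GWAS dataset.

    A "hit" is a GWAS p-value strictly below ``p_thresh``.  Only SNPs
    present in the GWAS table are evaluated; editing SNPs are removed from
    the control universe.  When no control SNP hits, the score is undefined
    (None) and only the exact-test p is reported.
    """
    editing = set(editing_snps)
    control = set(control_snps) - editing
    p_by_key: Dict[Key, float] = {}
    dataset_id = disease = ""
    for rec in gwas_records:
        p_by_key[rec.key] = rec.p_value
        dataset_id, disease = rec.dataset_id, rec.disease
    ed_ps = [p_by_key[k] for k in editing if k in p_by_key]
    ctl_ps = [p_by_key[k] for k in control if k in p_by_key]
    if not ed_ps or not ctl_ps:
        raise ValueError("no GWAS-covered SNPs in one of the sets")
    a = sum(p < p_thresh for p in ed_ps)
    b = len(ed_ps) - a
    c = sum(p < p_thresh for p in ctl_ps)
    d = len(ctl_ps) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    pct_ed = a / (a + b)
    pct_ctl = c / (c + d)
    score = (pct_ed / pct_ctl) if c > 0 else None
    return EnrichmentResult(
        dataset_id=dataset_id, disease=disease, a=a, b=b, c=c, d=d,
        pct_editing=pct_ed, pct_control=pct_ctl if c > 0 else None,
        score=score, p_value=float(p), enriched=pct_ed > pct_ctl,
    )


def enrich_datasets(
    editing_snps: Iterable[Key],
    control_snps: Iterable[Key],
    gwas_records: Sequence[GwasRecord],
    p_thresh: float = 0.001,
) -> List[EnrichmentResult]:
    """Run :func:`enrich` separately for every dataset in a GWAS table."""
    editing = set(editing_snps)
    control = set(control_snps)
    by_dataset: Dict[str, List[GwasRecord]] = {}
    for rec in gwas_records:
        by_dataset.setdefault(rec.dataset_id, []).append(rec)
    return [
        enrich(editing, control, recs, p_thresh)
        for _, recs in sorted(by_dataset.items())
    ]


def per_disease(results: Sequence[EnrichmentResult]) -> List[EnrichmentResult]:
    """One representative dataset per disease: the median enrichment score.

    With an even number of datasets the lower median is taken; datasets
    with an undefined score sort last and are only chosen when a disease
    has no defined score at all.
    """
    by_disease: Dict[str, List[EnrichmentResult]] = {}
    for r in results:
        by_disease.setdefault(r.disease, []).append(r)
    out = []
    for disease in sorted(by_disease):
        rs = sorted(
            by_disease[disease],
            key=lambda r: (r.score is None, r.score if r.score is not None else 0.0),
        )
        defined = [r for r in rs if r.score is not None]
        pool = defined or rs
        out.append(pool[(len(pool) - 1) // 2])
    return out
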