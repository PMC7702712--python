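"""Permutation-null tests that editing regions form double-stranded RNA.

Two complementary detectors, both calibrated by shuffling the editing
region and re-scoring against the same surrounding sequence:

* :func:`best_hybridization` scans the editing region (site +- 15 nt)
  against every antiparallel placement in the surrounding +-2500 nt of the
  same gene and returns the lowest stacking free energy — an
  editing-complementary-sequence (ECS) search.
* :func:`local_duplex_score` runs a Smith-Waterman local alignment of the
  editing region (site +- 25 nt) against the reverse complement of the
  +-2000 nt genomic window (match +2, mismatch -3, gap open -5, extend -2,
  no low-complexity filtering).

Because significance is rank-based against shuffles scored with the same
function, the calibration of the empirical p-value does not depend on the
absolute energy scale; the scorer is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .core import GeneModel, GenomicInterval, encode, revcomp

# pair codes: 0 none, 1 A:U, 2 U:A, 3 G:C, 4 C:G, 5 G:U, 6 U:G
_PAIR = np.zeros((5, 5), dtype=np.int8)
_PAIR[0, 3] = 1  # A-T
_PAIR[3, 0] = 2  # T-A
_PAIR[2, 1] = 3  # G-C
_PAIR[1, 2] = 4  # C-G
_PAIR[2, 3] = 5  # G-T wobble
_PAIR[3, 2] = 6  # T-G wobble


def _build_stack_table() -> np.ndarray:
    """Nearest-neighbour stacking free energies (kcal/mol, 37 C).

    Watson-Crick values follow the standard RNA nearest-neighbour set;
    stacks involving G:U wobbles use approximate values of the right
    magnitude.  The table satisfies the strand-flip symmetry
    S[p, q] = S[flip(q), flip(p)].
    """
    s = np.zeros((7, 7))
    wc = {
        (1, 1): -0.93, (1, 2): -1.10, (1, 3): -2.08, (1, 4): -2.24,
        (2, 1): -1.33, (2, 2): -0.93, (2, 3): -2.11, (2, 4): -2.35,
        (3, 1): -2.35, (3, 2): -2.24, (3, 3): -3.26, (3, 4): -3.42,
        (4, 1): -2.11, (4, 2): -2.08, (4, 3): -2.36, (4, 4): -3.26,
    }
    gu = {
        (1, 5): -0.55, (1, 6): -1.36, (2, 5): -1.27, (2, 6): -1.00,
        (3, 5): -1.53, (3, 6): -2.51, (4, 5): -1.41, (4, 6): -2.11,
        (5, 5): -0.50, (6, 6): -0.50, (5, 6): 0.47, (6, 5): -0.74,
    }
    flip = {1: 2, 2: 1, 3: 4, 4: 3, 5: 6, 6: 5}
    for (p, q), v in {**wc, **gu}.items():
        s[p, q] = v
        s[flip[q], flip[p]] = v
    return s


_STACK = _build_stack_table()
#: strand flip of a pair code (A:U <-> U:A etc.)
_FLIP = np.array([0, 2, 1, 4, 3, 6, 5], dtype=np.int8)


def _dinuc_table(stack: np.ndarray) -> np.ndarray:
    """Flatten the stacking model into a 25x25 dinucleotide lookup.

    Entry [a1*5+a2, b1*5+b2] is the stacking energy (in 0.01 kcal/mol
    integer units) contributed when region bases (a1, a2) face surround
    bases (b1, b2) and both positions form a pair; 0 otherwise.  Works on
    the reversed region so the scan walks both sequences forward; the
    strand-flip symmetry of the stack table makes the two traversals equal.
    """
    pairf = _FLIP[_PAIR]
    t = np.zeros((25, 25), dtype=np.int32)
    for a1 in range(5):
        for a2 in range(5):
            for b1 in range(5):
                for b2 in range(5):
                    p, q = pairf[a1, b1], pairf[a2, b2]
                    if p > 0 and q > 0:
                        t[a1 * 5 + a2, b1 * 5 + b2] = int(round(stack[p, q] * 100))
    return t.reshape(-1)


@njit(cache=False)
def _scan_one(region_rev, sd, n_off, table):  # pragma: no cover - jit
    L = region_rev.shape[0]
    rdk = np.empty(L - 1, dtype=np.int32)
    for i in range(L - 1):
        rdk[i] = (region_rev[i] * 5 + region_rev[i + 1]) * 25
    best = 0
    best_j = -1
    for j in range(n_off):
        e = 0
        for i in range(L - 1):
            e += table[rdk[i] + sd[j + i]]
        if e < best:
            best = e
            best_j = j
    return best / 100.0, best_j


@njit(cache=False)
def _scan_many(regions_rev, sd, n_off, table):  # pragma: no cover - jit
    m, L = regions_rev.shape
    out = np.empty(m)
    rdk = np.empty(L - 1, dtype=np.int32)
    for r in range(m):
        for i in range(L - 1):
            rdk[i] = (regions_rev[r, i] * 5 + regions_rev[r, i + 1]) * 25
        best = 0
        for j in range(n_off):
            e = 0
            for i in range(L - 1):
                e += table[rdk[i] + sd[j + i]]
            if e < best:
                best = e
        out[r] = best / 100.0
    return out


def _surround_dinucs(s: np.ndarray) -> np.ndarray:
    return (s[:-1].astype(np.int32) * 5 + s[1:]).astype(np.int32)


class StackingScorer:
    """Gapless antiparallel duplex scan with nearest-neighbour stacking.

    The score of a placement is the sum of stacking energies over
    consecutive base pairs (Watson-Crick and G:U); unpaired positions break
    the helix and contribute nothing, so every score is <= 0 and 0 means
    "no duplex".  Lower is more stable.  Energies live on a 0.01 kcal/mol
    lattice, so the integer kernel is exact.
    """

    def __init__(self, stack_table: Optional[np.ndarray] = None):
        self.stack = _STACK if stack_table is None else np.asarray(stack_table,
                                                                   dtype=float)
        self._table = _dinuc_table(self.stack)

    def score(self, region: str, surround: str) -> Tuple[float, int]:
        """Best (minimum) energy and the 0-based offset of the partner window."""
        r = encode(region)
        s = encode(surround)
        return self.score_codes(r, s)

    def score_codes(self, r: np.ndarray, s: np.ndarray) -> Tuple[float, int]:
        if s.size < r.size:
            raise ValueError("surround shorter than editing region")
        e, j = _scan_one(
            np.ascontiguousarray(r[::-1]), _surround_dinucs(s),
            s.size - r.size + 1, self._table,
        )
        return float(e), int(j)

    def score_many(self, regions: np.ndarray, surround: np.ndarray) -> np.ndarray:
        """Energies of many pre-encoded regions against one encoded surround."""
        regions = np.ascontiguousarray(np.asarray(regions)[:, ::-1])
        s = np.asarray(surround)
        return _scan_many(
            regions, _surround_dinucs(s), s.size - regions.shape[1] + 1,
            self._table,
        )


DEFAULT_SCORER = StackingScorer()


@dataclass
class StructureTestResult:
    """Observed duplex statistic versus its shuffle null at one site."""

    site: Tuple[str, int]
    observed: float
    null_mean: float
    empirical_p: float
    n_shuffles: int
    significant: bool
    best_partner: Optional[GenomicInterval] = None
    evaluable: bool = True

    def __post_init__(self):
        if self.evaluable and self.n_shuffles >= 1:
            lo = 1.0 / (self.n_shuffles + 1)
            if not (lo - 1e-12 <= self.empirical_p <= 1.0 + 1e-12):
                raise ValueError("empirical p outside [1/(n+1), 1]")


def best_hybridization(
    editing_region: str,
    surround: str,
    region_offset: int,
    scorer: Optional[StackingScorer] = None,
) -> Tuple[float, Tuple[int, int]]:
    """Most favourable hybridisation of the editing region inside its surround.

    ``region_offset`` locates the region within ``surround``; that self
    locus is masked so the trivial self-alignment can never win.  Returns
    ``(min_energy, (partner_start, partner_end))`` with partner coordinates
    relative to the surround (0 energy and an empty interval mean no
    duplex).
    """
    scorer = scorer or DEFAULT_SCORER
    if len(surround) < len(editing_region):
        raise ValueError("surround shorter than editing region")
    s = encode(surround)
    lo = max(0, region_offset)
    hi = min(len(surround), region_offset + len(editing_region))
    s[lo:hi] = 4  # mask the region's own locus
    e, j = scorer.score_codes(encode(editing_region), s)
    if j < 0:
        return 0.0, (0, 0)
    return float(e), (int(j), int(j) + len(editing_region))


def shuffle_null(
    region: str,
    surround: str,
    region_offset: int,
    n_shuffles: int = 10000,
    seed: int = 0,
    scorer: Optional[StackingScorer] = None,
    site: Tuple[str, int] = ("", 0),
    alpha: float = 0.01,
    greater_is_extreme: bool = False,
    statistic: Optional[Callable[[str], float]] = None,
) -> StructureTestResult:
    """Empirical p-value of the observed duplex statistic vs shuffled regions.

    The region is shuffled preserving mononucleotide composition
    (Fisher-Yates); the empirical p is the add-one rank
    ``(#{shuffles at least as extreme} + 1) / (n + 1)``.  The
    ``significant`` flag reproduces the top-rank rule: the observed value
    must beat all but fewer than ``alpha * n`` shuffles (p < 0.01 by
    default).  ``statistic`` overrides the default hybridisation scan
    (e.g. with a local-alignment score; set ``greater_is_extreme``).
    """
    if len(region) < 4:
        raise ValueError("editing region shorter than 4 nt")
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    if statistic is not None:
        observed = statistic(region)
        chars = np.array(list(region))
        null = np.empty(n_shuffles)
        for k in range(n_shuffles):
            null[k] = statistic("".join(rng.permutation(chars)))
    else:
        scorer = scorer or DEFAULT_SCORER
        observed, _ = best_hybridization(region, surround, region_offset, scorer)
        s = encode(surround)
        lo = max(0, region_offset)
        hi = min(len(surround), region_offset + len(region))
        s[lo:hi] = 4
        r = encode(region)
        shuffled = rng.permuted(np.tile(r, (n_shuffles, 1)), axis=1)
        null = scorer.score_many(shuffled, s)
    if greater_is_extreme:
        count_le = int(np.sum(null >= observed))
        count_lt = int(np.sum(null > observed))
    else:
        count_le = int(np.sum(null <= observed))
        count_lt = int(np.sum(null < observed))
    p = (count_le + 1) / (n_shuffles + 1)
    significant = count_lt < max(1, int(round(alpha * n_shuffles)))
    return StructureTestResult(
        site=site, observed=float(observed), null_mean=float(np.mean(null)),
        empirical_p=float(p), n_shuffles=n_shuffles, significant=bool(significant),
    )


# ---------------------------------------------------------------------------
# Local duplex alignment (bl2seq-like)

_SW_MATRIX = None


def _sw_aligner():
    from Bio import Align

    global _SW_MATRIX
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if _SW_MATRIX is None:
        from Bio.Align import substitution_matrices

        alphabet = "ACGTN"
        m = np.full((5, 5), -3.0)
        for i in range(4):
            m[i, i] = 2.0
        m[4, :] = -3.0
        m[:, 4] = -3.0
        _SW_MATRIX = substitution_matrices.Array(alphabet, 2, m)
    aligner.substitution_matrix = _SW_MATRIX
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def local_duplex_score(
    editing_region: str,
    genomic_window: str,
    region_offset: Optional[int] = None,
) -> float:
    """Best Smith-Waterman score of the region against the window's reverse
    complement (match +2, mismatch -3, gap open -5, extend -2).

    ``region_offset`` masks the region's own locus in the window before
    aligning.  Returns 0.0 when nothing aligns.
    """
    if not genomic_window:
        raise ValueError("empty genomic window")
    window = genomic_window.upper()
    if region_offset is not None:
        lo = max(0, region_offset)
        hi = min(len(window), region_offset + len(editing_region))
        window = window[:lo] + "N" * (hi - lo) + window[hi:]
    target = revcomp(window).upper()
    aligner = _sw_aligner()
    score = aligner.score(editing_region.upper(), target)
    return float(max(score, 0.0))


# ---------------------------------------------------------------------------
# Per-site drivers and the cohort summary


def _sense_region(
    sequences: Dict[str, str], chrom: str, pos: int, strand: str, flank: int
) -> str:
    seq = sequences[chrom]
    lo = max(0, pos - 1 - flank)
    hi = min(len(seq), pos + flank)
    region = seq[lo:hi]
    return revcomp(region) if strand == "-" else region


def ecs_test_sites(
    sites: pd.DataFrame,
    sequences: Dict[str, str],
    genes: Sequence[GeneModel],
    n_shuffles: int = 10000,
    seed: int = 0,
    region_flank: int = 15,
    surround_flank: int = 2500,
    scorer: Optional[StackingScorer] = None,
) -> List[StructureTestResult]:
    """Run the ECS shuffle test for every site in a sites table.

    The editing region is the site +- ``region_flank`` nt and the surround
    the site +- ``surround_flank`` nt, both clipped to the enclosing gene
    and taken on the sense strand.  Sites outside any gene are returned
    flagged not-evaluable.
    """
    gene_spans = [(g.chrom, g.start, g.end, g) for g in genes]
    out = []
    for i, site in enumerate(sites.itertuples(index=False)):
        pos0 = site.pos - 1
        gene = next(
            (g for c, a, b, g in gene_spans if c == site.chrom and a <= pos0 < b),
            None,
        )
        if gene is None:
            out.append(
                StructureTestResult(
                    site=(site.chrom, site.pos), observed=0.0, null_mean=0.0,
                    empirical_p=1.0, n_shuffles=n_shuffles, significant=False,
                    evaluable=False,
                )
            )
            continue
        seq = sequences[site.chrom]
        r_lo = max(gene.start, pos0 - region_flank)
        r_hi = min(gene.end, pos0 + region_flank + 1)
        s_lo = max(gene.start, pos0 - surround_flank)
        s_hi = min(gene.end, pos0 + surround_flank + 1)
        region = seq[r_lo:r_hi]
        surround = seq[s_lo:s_hi]
        if site.strand == "-":
            region = revcomp(region)
            surround = revcomp(surround)
            offset = s_hi - r_hi
        else:
            offset = r_lo - s_lo
        res = shuffle_null(
            region, surround, offset, n_shuffles=n_shuffles,
            seed=np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31),
            scorer=scorer, site=(site.chrom, site.pos),
        )
        out.append(res)
    return out


@dataclass
class EcsSummary:
    fraction_significant: float
    mean_observed: float
    mean_null: float
    wilcoxon_p: Optional[float]
    n_sites: int
    n_not_evaluable: int


def ecs_summary(results: Sequence[StructureTestResult]) -> EcsSummary:
    """Cohort summary: significant fraction and observed-vs-null comparison.

    The paired comparison is a Wilcoxon signed-rank test of observed
    statistics against the per-site shuffle-null means.
    """
    usable = [r for r in results if r.evaluable]
    if not usable:
        raise ValueError("no evaluable results")
    obs = np.array([r.observed for r in usable])
    null = np.array([r.null_mean for r in usable])
    frac = float(np.mean([r.significant for r in usable]))
    if np.allclose(obs, null):
        wp = None
    else:
        from scipy import stats

        wp = float(stats.wilcoxon(obs, null, alternative="two-sided").pvalue)
    return EcsSummary(
        fraction_significant=frac,
        mean_observed=float(obs.mean()),
        mean_null=float(null.mean()),
        wilcoxon_p=wp,
        n_sites=len(usable),
        n_not_evaluable=len(results) - len(usable),
    )
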