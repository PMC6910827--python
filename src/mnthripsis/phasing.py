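"""Haplotype assignment: which homolog does a CNA or junction affect?

In a trisomic clone carrying one transferred homolog of a distinct
haplotype, SNPs that are homozygous in the parental line (BAF < 0.05 or
> 0.95) but shifted to the trisomic heterozygote signature (BAF near
1/3 or 2/3, i.e. genotype AAB or ABB) are phase-informative: the
transferred homolog carries the allele absent from the parental
genotype.  Inside a CNA these SNPs discriminate the affected homolog:

* loss of the transferred copy returns BAF to homozygosity (AA/BB),
  loss of an endogenous copy leaves a balanced heterozygote (AB, ~0.5);
* duplication of the transferred copy moves BAF to 0.5 (AABB),
  duplication of an endogenous copy to 1/4 or 3/4 (AAAB/ABBB).

Junctions are assigned from WGS read pairs: among discordant pairs
(those supporting the junction) spanning an informative SNP, a
significant majority carrying the transferred allele assigns the
junction to the transferred homolog (one-sided exact binomial).

Expected BAF targets are computed from allele-count pairs generally, so
tetrasomic baselines (AABB and shifts thereof) use the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from scipy.stats import binomtest

from .types import (
    GenomicInterval,
    HaplotypeCall,
    ReadPairCounts,
    SnpRecord,
    Verdict,
)
from .cna import CnaCall
from .types import CopyState

__all__ = [
    "PhaseInformativeSnp",
    "find_phase_informative_snps",
    "assign_cna_allele_baf",
    "assign_junction_allele_reads",
    "summarize_affected_fraction",
    "HOM_LO",
    "HOM_HI",
    "SHIFT_LO",
    "SHIFT_HI",
]

HOM_LO = 0.05
HOM_HI = 0.95
SHIFT_LO = 0.15
SHIFT_HI = 0.85
TRISOMIC_WINDOW = 0.12
GAIN_WINDOW = 0.08
AB_WINDOW = 0.08
MIN_SNPS = 3
MAJORITY_MARGIN = 2 / 3


@dataclass(frozen=True)
class PhaseInformativeSnp:
    """A SNP at which the transferred homolog is distinguishable.

    ``expected_baseline_baf`` is the clone BAF expected in an intact
    aneuploid region (1/3 or 2/3 for a trisomy).
    """

    chrom: str
    pos: int
    parental_allele: str  # "A" or "B"
    transferred_allele: str
    expected_baseline_baf: float

    def __post_init__(self) -> None:
        if self.parental_allele == self.transferred_allele:
            raise ValueError("an informative SNP requires differing alleles")


def expected_baf(n_a: int, n_b: int) -> float:
    """B-allele fraction of an allele-count configuration."""
    return n_b / (n_a + n_b)


def find_phase_informative_snps(
    parental: Sequence[SnpRecord],
    clone: Sequence[SnpRecord],
    aneuploid_chrom: str,
    hom_lo: float = HOM_LO,
    hom_hi: float = HOM_HI,
    aneuploid_copies: int = 3,
    window: float = TRISOMIC_WINDOW,
) -> List[PhaseInformativeSnp]:
    """Select SNPs homozygous in the parental line whose clone BAF sits at
    the aneuploid heterozygote baseline on the aneuploid chromosome.

    ``clone`` should be an *unrearranged* aneuploid sample (or the clone
    itself when its rearrangements are sparse): a SNP inside a CNA of the
    supplied table would fail the baseline-window check precisely because
    of the shift the downstream assignment step is looking for.

    For a trisomy the baselines are 1/3 (parental AA, transferred B) and
    2/3 (parental BB, transferred A); for a tetrasomy with two
    transferred copies, 1/2; the baseline is computed from allele counts
    rather than hard-coded.  The clone BAF must lie within ``window`` of
    the baseline.
    """
    clone_by_pos: Dict[Tuple[str, int], SnpRecord] = {
        (r.chrom, r.pos): r for r in clone
    }
    n_extra = aneuploid_copies - 2
    out: List[PhaseInformativeSnp] = []
    overlap = 0
    for p in parental:
        if p.chrom != aneuploid_chrom:
            continue
        c = clone_by_pos.get((p.chrom, p.pos))
        if c is None:
            continue
        overlap += 1
        if p.baf < hom_lo:
            parental_allele, transferred_allele = "A", "B"
            baseline = expected_baf(2, n_extra)
        elif p.baf > hom_hi:
            parental_allele, transferred_allele = "B", "A"
            baseline = expected_baf(n_extra, 2)
        else:
            continue  # parental heterozygote: not phase-informative
        if abs(c.baf - baseline) > window:
            continue  # no shift: transferred copy carries the same allele
        out.append(
            PhaseInformativeSnp(p.chrom, p.pos, parental_allele, transferred_allele, baseline)
        )
    if overlap == 0:
        raise ValueError(
            f"parental and clone tables share no positions on {aneuploid_chrom}"
        )
    return out


def _vote_loss(
    snp: PhaseInformativeSnp,
    baf: float,
    shift_lo: float,
    shift_hi: float,
    ab_window: float,
) -> Optional[Verdict]:
    # transferred copy lost -> back to parental homozygosity
    if snp.parental_allele == "A" and baf <= shift_lo:
        return Verdict.TRANSFERRED
    if snp.parental_allele == "B" and baf >= shift_hi:
        return Verdict.TRANSFERRED
    # endogenous copy lost -> balanced heterozygote
    if abs(baf - 0.5) <= ab_window:
        return Verdict.ENDOGENOUS
    return None


def _vote_gain(
    snp: PhaseInformativeSnp,
    baf: float,
    aneuploid_copies: int,
    gain_window: float,
) -> Optional[Verdict]:
    n_extra = aneuploid_copies - 2
    if snp.parental_allele == "A":
        transferred_target = expected_baf(2, n_extra + 1)  # AABB = 0.5 for trisomy
        endogenous_target = expected_baf(3, n_extra)  # AAAB = 0.25
    else:
        transferred_target = expected_baf(n_extra + 1, 2)
        endogenous_target = expected_baf(n_extra, 3)  # ABBB = 0.75
    d_tr = abs(baf - transferred_target)
    d_en = abs(baf - endogenous_target)
    if d_tr <= gain_window and d_tr < d_en:
        return Verdict.TRANSFERRED
    if d_en <= gain_window and d_en < d_tr:
        return Verdict.ENDOGENOUS
    return None


def assign_cna_allele_baf(
    cna: CnaCall,
    informative_snps: Sequence[PhaseInformativeSnp],
    clone: Sequence[SnpRecord],
    shift_lo: float = SHIFT_LO,
    shift_hi: float = SHIFT_HI,
    min_snps: int = MIN_SNPS,
    margin: float = MAJORITY_MARGIN,
    ab_window: float = AB_WINDOW,
    gain_window: float = GAIN_WINDOW,
    aneuploid_copies: int = 3,
) -> HaplotypeCall:
    """Assign a CNA to the transferred or an endogenous homolog by BAF.

    Each informative SNP inside the CNA casts a vote according to the
    genotype-shift rules; the verdict is the majority provided at least
    ``min_snps`` votes were cast and the majority reaches ``margin`` of
    them, otherwise ambiguous.
    """
    clone_by_pos = {(r.chrom, r.pos): r for r in clone}
    votes: List[Verdict] = []
    for snp in informative_snps:
        if not cna.interval.contains(snp.chrom, snp.pos):
            continue
        rec = clone_by_pos.get((snp.chrom, snp.pos))
        if rec is None:
            continue
        if cna.state == CopyState.LOSS:
            vote = _vote_loss(snp, rec.baf, shift_lo, shift_hi, ab_window)
        else:
            vote = _vote_gain(snp, rec.baf, aneuploid_copies, gain_window)
        if vote is not None:
            votes.append(vote)
    target = f"{cna.clone_id}:{cna.interval.chrom}:{cna.interval.start}-{cna.interval.end}"
    n_tr = sum(v == Verdict.TRANSFERRED for v in votes)
    n_en = len(votes) - n_tr
    n_total = len(votes)
    if n_total < min_snps:
        return HaplotypeCall(target, Verdict.AMBIGUOUS, max(n_tr, n_en), n_total,
                             detail="insufficient informative SNPs")
    if n_tr >= margin * n_total and n_tr > n_en:
        return HaplotypeCall(target, Verdict.TRANSFERRED, n_tr, n_total)
    if n_en >= margin * n_total and n_en > n_tr:
        return HaplotypeCall(target, Verdict.ENDOGENOUS, n_en, n_total)
    return HaplotypeCall(target, Verdict.AMBIGUOUS, max(n_tr, n_en), n_total,
                         detail="no qualified majority")


def assign_junction_allele_reads(
    junction_id: str,
    counts: Sequence[ReadPairCounts],
    min_pairs: int = 3,
    alpha: float = 0.05,
) -> HaplotypeCall:
    """Assign a junction from discordant read-pair allele counts.

    Pools discordant pairs over the junction's informative SNPs and
    requires a one-sided exact binomial majority (against p = 0.5) at
    level ``alpha`` with at least ``min_pairs`` pairs; otherwise
    ambiguous.
    """
    rows = [c for c in counts if c.junction_id == junction_id]
    n_tr = sum(c.disc_transferred for c in rows)
    n_en = sum(c.disc_endogenous for c in rows)
    n = n_tr + n_en
    if n < min_pairs or n == 0:
        return HaplotypeCall(junction_id, Verdict.AMBIGUOUS, max(n_tr, n_en), n,
                             detail="insufficient discordant pairs")
    k = max(n_tr, n_en)
    p = binomtest(k, n, 0.5, alternative="greater").pvalue
    if p >= alpha:
        return HaplotypeCall(junction_id, Verdict.AMBIGUOUS, k, n,
                             detail=f"binomial p={p:.3g}")
    verdict = Verdict.TRANSFERRED if n_tr > n_en else Verdict.ENDOGENOUS
    return HaplotypeCall(junction_id, verdict, k, n, detail=f"binomial p={p:.3g}")


def summarize_affected_fraction(calls: Iterable[HaplotypeCall]) -> Dict[str, object]:
    """Fraction of non-ambiguous calls assigned to the transferred homolog."""
    calls = list(calls)
    n_tr = sum(c.verdict == Verdict.TRANSFERRED for c in calls)
    n_en = sum(c.verdict == Verdict.ENDOGENOUS for c in calls)
    n_amb = sum(c.verdict == Verdict.AMBIGUOUS for c in calls)
    informative = n_tr + n_en
    return {
        "n_transferred": n_tr,
        "n_endogenous": n_en,
        "n_ambiguous": n_amb,
        "fraction_transferred": (n_tr / informative) if informative else None,
    }
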