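"""LTR molecular-clock dating, pairwise distances and family clustering.

The two LTRs of a retrotransposon are identical at insertion time, so
their divergence k dates the insertion through T = k / (2r) with r the
substitution rate per site per year (default 1.3e-8, as estimated for
grass intergenic regions).  Divergence is 1 - identity, with identity
taken from a global pairwise alignment with affine gap costs and free end
gaps.  Families follow the 80-80-80 rule: two elements belong to the same
family when they share >= 80% identity over >= 80% coverage spanning at
least 80 bp, applied by greedy length-descending centroid clustering.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import InputError

logger = logging.getLogger(__name__)

DEFAULT_RATE = 1.3e-8  # substitutions / site / year

# global alignment, affine gaps, end gaps free; parameters documented
# and configurable via make_aligner
_MATCH = 1.0
_MISMATCH = -1.0
_GAP_OPEN = -2.0
_GAP_EXTEND = -0.5


def make_aligner(
    match: float = _MATCH,
    mismatch: float = _MISMATCH,
    gap_open: float = _GAP_OPEN,
    gap_extend: float = _GAP_EXTEND,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    try:  # biopython >= 1.88 naming
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[float, int, float]:
    """Identity, aligned overlap (bp) and coverage of two nucleotide sequences.

    Identity = matches / aligned columns excluding end gaps; coverage =
    aligned overlap / length of the LONGER sequence (the stricter
    denominator).  Overlap counts all columns between the first and last
    aligned pair, including internal gaps.
    """
    if not seq_a or not seq_b:
        raise InputError("empty sequence")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    n_cols = len(a_row)

    # trim end gaps: columns before the first / after the last aligned pair
    start = 0
    while start < n_cols and (a_row[start] == "-" or b_row[start] == "-"):
        start += 1
    end = n_cols
    while end > start and (a_row[end - 1] == "-" or b_row[end - 1] == "-"):
        end -= 1
    core_a, core_b = a_row[start:end], b_row[start:end]
    overlap = len(core_a)
    if overlap == 0:
        return 0.0, 0, 0.0
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    identity = matches / overlap
    coverage = overlap / max(len(seq_a), len(seq_b))
    return identity, overlap, coverage


@dataclass
class InsertionAge:
    """Insertion age of one element from LTR-pair divergence.

    ``divergence = 1 - identity``; ``age_years = divergence / (2 * rate)``.
    Elements without an LTR pair carry ``dating_unavailable=True``.
    """

    element_id: str
    identity: float | None
    divergence: float | None
    rate: float
    age_years: float | None
    dating_unavailable: bool = False

    @property
    def age_my(self) -> float | None:
        if self.age_years is None:
            return None
        return self.age_years / 1e6


def time_of_insertion(
    identity: float, rate: float = DEFAULT_RATE, element_id: str = ""
) -> InsertionAge:
    """Date an insertion from LTR identity by T = k / (2r)."""
    if not (0.0 <= identity <= 1.0):
        raise ValueError("identity must lie in [0, 1]")
    if rate <= 0.0:
        raise ValueError("rate must be positive")
    k = 1.0 - identity
    return InsertionAge(
        element_id=element_id,
        identity=identity,
        divergence=k,
        rate=rate,
        age_years=k / (2.0 * rate),
    )


def undatable(element_id: str, rate: float = DEFAULT_RATE) -> InsertionAge:
    """Placeholder for an element lacking an LTR pair."""
    return InsertionAge(
        element_id=element_id,
        identity=None,
        divergence=None,
        rate=rate,
        age_years=None,
        dating_unavailable=True,
    )


def mean_pairwise_pdistance(rows: list[str]) -> tuple[float, float]:
    """Mean and SD (n-1) of pairwise p-distances in an alignment.

    p-distance = mismatches / compared columns, with pairwise deletion of
    positions where either sequence has a gap.  Pairs without comparable
    columns are excluded with a warning.
    """
    if len(rows) < 2:
        raise ValueError("need >= 2 sequences")
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in rows]
    gap = np.bytes_(b"-")
    dists: list[float] = []
    for a, b in itertools.combinations(arrs, 2):
        ok = (a != gap) & (b != gap)
        n_ok = int(ok.sum())
        if n_ok == 0:
            warnings.warn("pair with zero comparable columns excluded")
            continue
        dists.append(float((a[ok] != b[ok]).sum()) / n_ok)
    if not dists:
        raise ValueError("no comparable pairs")
    mean = float(np.mean(dists))
    sd = float(np.std(dists, ddof=1)) if len(dists) > 1 else 0.0
    return mean, sd


@dataclass
class FamilyRule:
    """The 80-80-80 family criterion thresholds."""

    min_identity: float = 0.80
    min_coverage: float = 0.80
    min_overlap_bp: int = 80

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must lie in (0, 1]")
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError("min_coverage must lie in (0, 1]")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")

    def matches(self, identity: float, overlap: int, coverage: float) -> bool:
        return (
            identity >= self.min_identity
            and coverage >= self.min_coverage
            and overlap >= self.min_overlap_bp
        )


@dataclass
class FamilyAssignment:
    """Element -> family index plus the representative of each family."""

    family_of: dict[str, int]
    representatives: list[str]

    @property
    def n_families(self) -> int:
        return len(self.representatives)


def greedy_families(
    seqs: dict[str, str],
    rule: FamilyRule | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> FamilyAssignment:
    """Greedy centroid clustering under the 80-80-80 rule.

    Sequences are processed longest first (ties by identifier); each joins
    the first existing family whose REPRESENTATIVE it matches under the
    rule, else founds a new family.  Deterministic and order-stable: the
    documented sort makes the outcome independent of input order.
    """
    if not seqs:
        raise InputError("no sequences to cluster")
    if rule is None:
        rule = FamilyRule()
    if aligner is None:
        aligner = make_aligner()
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    family_of: dict[str, int] = {}
    reps: list[str] = []
    for sid in order:
        placed = False
        for fam, rep in enumerate(reps):
            ident, overlap, cov = pairwise_identity(
                seqs[sid], seqs[rep], aligner
            )
            if rule.matches(ident, overlap, cov):
                family_of[sid] = fam
                placed = True
                break
        if not placed:
            family_of[sid] = len(reps)
            reps.append(sid)
    logger.info("80-80-80 clustering: %d sequences -> %d families",
                len(seqs), len(reps))
    return FamilyAssignment(family_of=family_of, representatives=reps)
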