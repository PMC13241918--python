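"""Distance-based orthology assignment.

A captured genomic region is accepted as a copy of a targeted conserved locus
(UCE or USCO) when (a) enough independent samples mapped to it and (b) its
uncorrected p-distance to the locus probe falls below a cutoff. True orthologs
of conserved loci sit well below the cutoff while paralogous copies, carrying
substantial extra divergence, sit above it, so a single distance threshold
separates the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .errors import UndefinedValueError

GAP_CHARS = frozenset("-.")

ASSIGNED = "assigned"
REJECTED_DISTANCE = "rejected_distance"
REJECTED_SUPPORT = "rejected_support"


def p_distance(row_a: str, row_b: str) -> float:
    """Uncorrected p-distance between two aligned rows, in percent.

    A column is comparable when both rows carry a non-gap residue; the
    distance is 100 x mismatching / comparable columns. Symmetric by
    construction.

    Raises
    ------
    UndefinedValueError
        If the rows share no comparable column.
    ValueError
        If the rows differ in column count.
    """
    if len(row_a) != len(row_b):
        raise ValueError(
            f"aligned rows differ in length: {len(row_a)} vs {len(row_b)}"
        )
    comparable = 0
    mismatch = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        comparable += 1
        if a != b:
            mismatch += 1
    if comparable == 0:
        raise UndefinedValueError("no comparable (gap-free) columns")
    return 100.0 * mismatch / comparable


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -0.5,
) -> PairwiseAligner:
    """Global aligner with affine gap costs for probe-vs-region alignment."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(
    probe: str, region: str, aligner: Optional[PairwiseAligner] = None
) -> tuple[str, str]:
    """Globally align two unaligned sequences; returns the two aligned rows."""
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(probe.upper(), region.upper())[0]
    return str(aln[0]), str(aln[1])


def best_strand_distance(
    probe: str, region: str, aligner: Optional[PairwiseAligner] = None
) -> tuple[float, str]:
    """Lowest p-distance over both region strands; capture is strand-agnostic.

    Returns (distance percent, strand) with strand '+' or '-'.
    """
    if aligner is None:
        aligner = make_aligner()
    best = None
    for strand, seq in (("+", region), ("-", reverse_complement(region))):
        rows = align_pair(probe, seq, aligner)
        try:
            d = p_distance(*rows)
        except UndefinedValueError:
            continue
        if best is None or d < best[0]:
            best = (d, strand)
    if best is None:
        raise UndefinedValueError("no comparable columns on either strand")
    return best


@dataclass
class AssignConfig:
    """Thresholds of the distance classifier.

    max_distance is in percent; a region is accepted only strictly below it.
    min_samples_mapped is the minimum number of samples whose reads mapped to
    the region before it is even considered.
    """

    max_distance: float = 30.0
    min_samples_mapped: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.max_distance <= 100:
            raise ValueError("max_distance must be in [0, 100]")
        if self.min_samples_mapped < 0:
            raise ValueError("min_samples_mapped must be >= 0")


@dataclass
class RegionHit:
    """A candidate genomic region paired with the probe it may correspond to.

    Either ``aligned`` (two equal-length rows) or the raw ``probe_seq`` /
    ``region_seq`` pair must be provided; raw pairs are aligned on demand.
    """

    region_id: str
    genome_id: str = ""
    start: int = 0
    end: int = 0
    n_samples_mapped: int = 0
    probe_seq: str = ""
    region_seq: str = ""
    aligned: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.n_samples_mapped < 0:
            raise ValueError("n_samples_mapped must be >= 0")


@dataclass
class Assignment:
    region_id: str
    status: str
    distance: Optional[float]
    n_samples_mapped: int
    reason: str = ""
    strand: str = "+"


def classify_region(hit: RegionHit, config: AssignConfig | None = None) -> Assignment:
    """Classify a region as an ortholog of its probe's locus, or reject it.

    Support is checked first: an under-supported region is rejected without
    computing a distance. Distance acceptance is strict (< max_distance), so a
    region at exactly the cutoff is rejected.
    """
    if config is None:
        config = AssignConfig()
    if hit.n_samples_mapped < config.min_samples_mapped:
        return Assignment(
            hit.region_id, REJECTED_SUPPORT, None, hit.n_samples_mapped,
            reason=f"n_samples_mapped {hit.n_samples_mapped} < "
                   f"{config.min_samples_mapped}",
        )
    strand = "+"
    try:
        if hit.aligned is not None:
            dist = p_distance(*hit.aligned)
        else:
            dist, strand = best_strand_distance(hit.probe_seq, hit.region_seq)
    except UndefinedValueError:
        return Assignment(
            hit.region_id, REJECTED_DISTANCE, None, hit.n_samples_mapped,
            reason="undefined distance (no comparable columns)",
        )
    if dist < config.max_distance:
        return Assignment(hit.region_id, ASSIGNED, dist, hit.n_samples_mapped,
                          strand=strand)
    return Assignment(
        hit.region_id, REJECTED_DISTANCE, dist, hit.n_samples_mapped,
        reason=f"distance {dist:.4g} >= {config.max_distance}", strand=strand,
    )
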