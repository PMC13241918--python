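"""Probe-panel design for conserved loci.

Candidate conserved loci (UCEs, single-copy ortholog genes, mitochondrial
genes, rDNA) come in as small multi-genome alignments. UCE candidates pass a
filter cascade — captured in enough genomes, long enough, not hypervariable,
and not too divergent within either suborder — and the survivors are tiled
into fixed-length non-overlapping probes. Single-copy orthologs (USCOs)
instead contribute their two ends as independent end-probes, each registered
as a locus of its own; mitochondrial and rDNA alignments are tiled on their
majority consensus.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import UndefinedValueError
from .ortholog import GAP_CHARS, p_distance

UCE = "UCE"
USCO = "USCO"
MITO = "MITO"
RDNA = "RDNA"

MISSING_RESIDUES = frozenset("-.NX?")


@dataclass
class PanelConfig:
    """Filter cascade and probe geometry.

    probe_len: tiling probe length in bp (170 by default).
    end_probe_len: USCO end-probe length in bp (120).
    min_genomes: minimum genomes a UCE must be captured in (6).
    usco_min_genomes: minimum genomes sharing a USCO (5 of 6).
    min_locus_len: minimum UCE length in bp (120).
    max_variable_frac: maximum fraction of variable alignment columns (0.50).
    max_within_clade_div: maximum within-clade p-distance, as fraction (0.10).
    """

    probe_len: int = 170
    end_probe_len: int = 120
    min_genomes: int = 6
    usco_min_genomes: int = 5
    min_locus_len: int = 120
    max_variable_frac: float = 0.50
    max_within_clade_div: float = 0.10

    def __post_init__(self) -> None:
        if self.probe_len < 1 or self.end_probe_len < 1:
            raise ValueError("probe lengths must be >= 1")
        for name in ("max_variable_frac", "max_within_clade_div"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class CandidateLocus:
    """A conserved region with one aligned sequence per genome.

    seqs maps genome id -> aligned row; clades maps genome id -> clade label
    (e.g. the two suborders). All rows must have equal column counts.
    """

    id: str
    type: str
    seqs: Mapping[str, str]
    clades: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError(f"locus {self.id}: needs at least one sequence")
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"locus {self.id}: unequal alignment row lengths")

    @property
    def n_genomes(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        """Alignment column count."""
        return len(next(iter(self.seqs.values())))


@dataclass(frozen=True)
class Probe:
    """A fixed-length probe cut from a locus.

    offset is 0-based in the ungapped source sequence; role is 'tile' for
    non-overlapping tiling probes or 'end5'/'end3' for USCO end-probes.
    """

    locus_id: str
    offset: int
    length: int
    role: str
    sequence: str


def tile_probes(sequence: str, probe_len: int, locus_id: str = "") -> list[Probe]:
    """Cut non-overlapping fixed-length probes at offsets 0, L, 2L, ...

    A terminal remainder shorter than probe_len is dropped (probes are
    synthesised at fixed length), so the count is floor(len/probe_len).
    """
    if probe_len < 1:
        raise ValueError("probe_len must be >= 1")
    seq = ungap(sequence)
    probes = []
    for off in range(0, len(seq) - probe_len + 1, probe_len):
        probes.append(
            Probe(locus_id, off, probe_len, "tile", seq[off:off + probe_len])
        )
    return probes


def usco_end_probes(
    sequence: str, end_probe_len: int = 120, locus_id: str = ""
) -> list[Probe]:
    """Two end-probes per single-copy ortholog: first and last end_probe_len bp.

    Each end is treated downstream as an independent locus (the two ends of a
    gene are usually separated by introns of several hundred bp). A sequence
    shorter than two probe lengths yields a single truncated 5' probe with a
    warning rather than failing the whole panel.
    """
    seq = ungap(sequence)
    n = len(seq)
    if n < 2 * end_probe_len:
        warnings.warn(
            f"locus {locus_id or '<unnamed>'}: length {n} < "
            f"{2 * end_probe_len}; emitting a single truncated end-probe",
            stacklevel=2,
        )
        take = min(n, end_probe_len)
        return [Probe(locus_id, 0, take, "end5", seq[:take])]
    return [
        Probe(locus_id, 0, end_probe_len, "end5", seq[:end_probe_len]),
        Probe(locus_id, n - end_probe_len, end_probe_len, "end3",
              seq[n - end_probe_len:]),
    ]


def ungap(sequence: str) -> str:
    return "".join(c for c in sequence if c not in GAP_CHARS)


def consensus(seqs: Iterable[str]) -> str:
    """Majority-rule consensus over non-missing residues, column-wise.

    Columns where every row is missing become 'N'. Ties break to the
    alphabetically first residue for determinism.
    """
    rows = [s.upper() for s in seqs]
    if not rows:
        raise ValueError("no sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("unequal row lengths")
    out = []
    for col in zip(*rows):
        counts = Counter(c for c in col if c not in MISSING_RESIDUES)
        if not counts:
            out.append("N")
            continue
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        out.append(best[0])
    return "".join(out)


def variable_site_fraction(locus: CandidateLocus) -> float:
    """Fraction of comparable alignment columns that are variable.

    A column is comparable when >= 2 rows carry a non-missing residue, and
    variable when those residues include >= 2 distinct states. Gap-only or
    single-residue columns are excluded from the denominator so that missing
    data is not counted as variation.
    """
    if locus.n_genomes < 2:
        raise ValueError("variable_site_fraction needs >= 2 sequences")
    rows = [s.upper() for s in locus.seqs.values()]
    comparable = 0
    variable = 0
    for col in zip(*rows):
        residues = [c for c in col if c not in MISSING_RESIDUES]
        if len(residues) < 2:
            continue
        comparable += 1
        if len(set(residues)) >= 2:
            variable += 1
    if comparable == 0:
        raise UndefinedValueError("no comparable columns")
    return variable / comparable


def within_clade_divergence(locus: CandidateLocus) -> dict[str, float]:
    """Maximum pairwise p-distance (fraction) within each clade.

    Clades with fewer than two members are omitted. Pairs with no comparable
    columns are skipped.
    """
    by_clade: dict[str, list[str]] = {}
    for genome, seq in locus.seqs.items():
        clade = locus.clades.get(genome)
        if clade is not None:
            by_clade.setdefault(clade, []).append(seq)
    out: dict[str, float] = {}
    for clade, members in by_clade.items():
        if len(members) < 2:
            continue
        worst = 0.0
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                try:
                    d = p_distance(members[i], members[j]) / 100.0
                except UndefinedValueError:
                    continue
                worst = max(worst, d)
        out[clade] = worst
    return out


# Rejection reason codes, in the order the cascade applies them.
REASON_MIN_GENOMES = "min_genomes"
REASON_MIN_LEN = "min_locus_len"
REASON_VARIABLE = "max_variable_frac"
REASON_DIVERGENCE = "max_within_clade_div"


def filter_candidates(
    loci: Sequence[CandidateLocus], config: PanelConfig | None = None
) -> tuple[list[CandidateLocus], list[tuple[str, str]]]:
    """Apply the panel filter cascade; every rejection carries its first
    failing rule.

    UCE candidates face all four rules. USCO candidates only face the
    shared-genome rule (usco_min_genomes): their probes target gene ends,
    where the variability/divergence screens do not apply. Mito/rDNA
    candidates are kept unconditionally (their alignments are curated
    upstream).
    """
    if config is None:
        config = PanelConfig()
    kept: list[CandidateLocus] = []
    rejected: list[tuple[str, str]] = []
    for locus in loci:
        reason = _first_failure(locus, config)
        if reason is None:
            kept.append(locus)
        else:
            rejected.append((locus.id, reason))
    return kept, rejected


def _first_failure(locus: CandidateLocus, config: PanelConfig) -> Optional[str]:
    if locus.type == USCO:
        if locus.n_genomes < config.usco_min_genomes:
            return REASON_MIN_GENOMES
        return None
    if locus.type in (MITO, RDNA):
        return None
    if locus.n_genomes < config.min_genomes:
        return REASON_MIN_GENOMES
    if ungapped_length(locus) < config.min_locus_len:
        return REASON_MIN_LEN
    if locus.n_genomes >= 2:
        try:
            if variable_site_fraction(locus) > config.max_variable_frac:
                return REASON_VARIABLE
        except UndefinedValueError:
            return REASON_VARIABLE
        for div in within_clade_divergence(locus).values():
            if div > config.max_within_clade_div:
                return REASON_DIVERGENCE
    return None


def ungapped_length(locus: CandidateLocus) -> int:
    """Length of the longest ungapped row — the locus' physical extent."""
    return max(len(ungap(s)) for s in locus.seqs.values())


def design_probes(
    kept: Sequence[CandidateLocus], config: PanelConfig | None = None
) -> list[Probe]:
    """Emit the probe set for the filtered candidates.

    UCE / mito / rDNA loci are tiled on their consensus at probe_len; a kept
    locus shorter than one probe still yields a single probe padded policy-free
    (truncated) so no kept locus is silently dropped. USCOs yield two
    end-probes each.
    """
    if config is None:
        config = PanelConfig()
    probes: list[Probe] = []
    for locus in kept:
        cons = ungap(consensus(locus.seqs.values()))
        if locus.type == USCO:
            probes.extend(
                usco_end_probes(cons, config.end_probe_len, locus.id)
            )
        else:
            tiles = tile_probes(cons, config.probe_len, locus.id)
            if not tiles and cons:
                tiles = [Probe(locus.id, 0, len(cons), "tile", cons)]
            probes.extend(tiles)
    return probes


def build_panel_manifest(
    kept: Sequence[CandidateLocus], probes: Sequence[Probe]
) -> pd.DataFrame:
    """One row per targeted locus.

    Every UCE/mito/rDNA candidate is one locus; every USCO *end-probe* is an
    independent locus (the two ends of a gene behave as separate capture
    targets). Columns: locus_id, type, source_id, n_probes.
    """
    by_locus: dict[str, list[Probe]] = {}
    for p in probes:
        by_locus.setdefault(p.locus_id, []).append(p)
    rows = []
    seen: set[str] = set()
    for locus in kept:
        locus_probes = by_locus.get(locus.id, [])
        if locus.type == USCO:
            for p in locus_probes:
                lid = f"{locus.id}_{p.role}"
                _check_dup(lid, seen)
                rows.append(
                    {"locus_id": lid, "type": USCO, "source_id": locus.id,
                     "n_probes": 1}
                )
        else:
            _check_dup(locus.id, seen)
            rows.append(
                {"locus_id": locus.id, "type": locus.type,
                 "source_id": locus.id, "n_probes": len(locus_probes)}
            )
    manifest = pd.DataFrame(
        rows, columns=["locus_id", "type", "source_id", "n_probes"]
    )
    manifest.attrs["counts_by_type"] = (
        manifest["type"].value_counts().to_dict() if len(manifest) else {}
    )
    return manifest


def _check_dup(locus_id: str, seen: set[str]) -> None:
    if locus_id in seen:
        raise ValueError(f"duplicate locus id in manifest: {locus_id}")
    seen.add(locus_id)
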