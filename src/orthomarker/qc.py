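"""Alignment-level quality control for locus matrices.

Three concerns, applied before any phylogenetic or diversity use:

* per-sequence missingness — rows that are mostly gaps or Ns carry little
  signal and are dropped;
* matrix occupancy — loci recovered in too few samples, and samples missing
  too many loci, are removed (loci first, then samples);
* residual paralogy — within taxonomic groups, rows that sit unusually far
  from the group consensus are flagged as paralogous captures and removed in
  consecutive rounds at increasingly fine taxonomic levels (order, family,
  genus). The outlier rule (median + z x MAD of consensus distance) is this
  package's stand-in for dedicated paralog filters whose internal criterion
  is not published; it is labelled as such in all outputs.

Finally, surviving matrices can be concatenated into a supermatrix with a
partition manifest in the 1-based inclusive convention of partition files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedValueError
from .ortholog import p_distance
from .panel import consensus

logger = logging.getLogger(__name__)

MISSING_CHARS = frozenset("-.NX?nx")


@dataclass
class QCConfig:
    """Thresholds of the QC cascade.

    max_seq_missing: rows with missing fraction strictly above this are
        dropped (0.40).
    min_locus_occupancy: loci present in at least this fraction of samples
        are kept (1/3; 'at least' is inclusive).
    max_sample_missing: samples are kept while their missing-locus fraction
        is strictly below this (0.20).
    paralog_levels: taxonomy levels for consecutive paralog rounds, coarse to
        fine.
    paralog_z_threshold: MAD multiplier of the outlier rule.
    """

    max_seq_missing: float = 0.40
    min_locus_occupancy: float = 1.0 / 3.0
    max_sample_missing: float = 0.20
    paralog_levels: tuple[str, ...] = ("order", "family", "genus")
    paralog_z_threshold: float = 5.0

    def __post_init__(self) -> None:
        for name in ("max_seq_missing", "min_locus_occupancy",
                     "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.paralog_levels:
            raise ValueError("paralog_levels must be non-empty")


def missing_fraction(seq: str) -> float:
    if not seq:
        return 1.0
    return sum(c in MISSING_CHARS for c in seq) / len(seq)


@dataclass
class LocusMatrix:
    """One locus alignment: sample id -> aligned row (equal column counts)."""

    locus_id: str
    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if self.seqs and len({len(s) for s in self.seqs.values()}) > 1:
            raise ValueError(f"locus {self.locus_id}: unequal row lengths")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    @property
    def samples(self) -> list[str]:
        return list(self.seqs)

    def missing_fractions(self) -> dict[str, float]:
        return {s: missing_fraction(seq) for s, seq in self.seqs.items()}


def drop_gappy_sequences(
    matrix: LocusMatrix, config: QCConfig | None = None
) -> tuple[LocusMatrix, list[str]]:
    """Remove rows whose missing fraction exceeds max_seq_missing (strict >)."""
    if config is None:
        config = QCConfig()
    removed = [
        s for s, f in matrix.missing_fractions().items()
        if f > config.max_seq_missing
    ]
    kept = {s: seq for s, seq in matrix.seqs.items() if s not in removed}
    return LocusMatrix(matrix.locus_id, kept), removed


def occupancy_filter(
    matrices: Sequence[LocusMatrix],
    samples: Sequence[str],
    config: QCConfig | None = None,
) -> tuple[list[LocusMatrix], list[str], pd.DataFrame]:
    """Keep well-occupied loci, then well-covered samples.

    A locus is kept when it is present in at least min_locus_occupancy of the
    sample universe (inclusive: exactly one third passes at the default).
    Over the kept loci, a sample is kept while its missing-locus fraction is
    strictly below max_sample_missing. The order (loci before samples) means
    sample coverage is judged only on loci worth keeping.

    Returns (kept matrices restricted to kept samples, kept samples, log).
    """
    if config is None:
        config = QCConfig()
    samples = list(samples)
    n = len(samples)
    log_rows = []
    kept_loci: list[LocusMatrix] = []
    for m in matrices:
        present = sum(1 for s in samples if s in m.seqs)
        frac = present / n if n else 0.0
        ok = frac >= config.min_locus_occupancy
        log_rows.append({"item": m.locus_id, "kind": "locus",
                         "value": frac, "kept": ok})
        if ok:
            kept_loci.append(m)
    kept_samples: list[str] = []
    for s in samples:
        if kept_loci:
            missing = sum(1 for m in kept_loci if s not in m.seqs)
            frac = missing / len(kept_loci)
        else:
            frac = 1.0
        ok = frac < config.max_sample_missing
        log_rows.append({"item": s, "kind": "sample",
                         "value": frac, "kept": ok})
        if ok:
            kept_samples.append(s)
    keep = set(kept_samples)
    restricted = [
        LocusMatrix(m.locus_id,
                    {s: seq for s, seq in m.seqs.items() if s in keep})
        for m in kept_loci
    ]
    restricted = [m for m in restricted if m.seqs]
    if not restricted or not kept_samples:
        logger.warning("occupancy_filter: empty survivor set")
    return restricted, kept_samples, pd.DataFrame(log_rows)


def paralog_filter_round(
    matrix: LocusMatrix,
    grouping: Mapping[str, str],
    threshold: float = 5.0,
    mad_floor: float = 0.5,
) -> tuple[LocusMatrix, list[str]]:
    """One round of consensus-distance paralog screening within groups.

    Within each group of >= 3 rows, each row's p-distance (percent) to the
    group majority consensus is computed; rows strictly above
    median + threshold x MAD are removed. The MAD is floored (default 0.5
    percentage points) so that near-identical groups do not flag harmless
    jitter. Groups of < 3 rows are skipped (no consensus worth trusting) and
    logged. This is a robust-outlier stand-in for published paralog filters.
    """
    groups: dict[str, list[str]] = {}
    for sample in matrix.seqs:
        g = grouping.get(sample)
        if g is not None:
            groups.setdefault(g, []).append(sample)
    removed: list[str] = []
    for g, members in groups.items():
        if len(members) < 3:
            logger.info("paralog round: group %s has %d rows, skipped",
                        g, len(members))
            continue
        cons = consensus(matrix.seqs[s] for s in members)
        dists = {}
        for s in members:
            try:
                dists[s] = p_distance(matrix.seqs[s], cons)
            except UndefinedValueError:
                dists[s] = float("nan")
        vals = np.array([d for d in dists.values() if np.isfinite(d)])
        if vals.size < 3:
            continue
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        cut = med + threshold * max(mad, mad_floor)
        removed.extend(s for s, d in dists.items()
                       if np.isfinite(d) and d > cut)
    kept = {s: seq for s, seq in matrix.seqs.items() if s not in removed}
    return LocusMatrix(matrix.locus_id, kept), removed


def paralog_filter(
    matrix: LocusMatrix,
    taxonomy: Mapping[str, Mapping[str, str]],
    config: QCConfig | None = None,
) -> tuple[LocusMatrix, pd.DataFrame]:
    """Consecutive paralog rounds at each taxonomy level, coarse to fine.

    taxonomy maps sample -> {level: group}; each round runs on the previous
    round's survivors.
    """
    if config is None:
        config = QCConfig()
    log_rows = []
    current = matrix
    for level in config.paralog_levels:
        grouping = {
            s: taxonomy[s][level]
            for s in current.seqs
            if s in taxonomy and level in taxonomy[s]
        }
        current, removed = paralog_filter_round(
            current, grouping, config.paralog_z_threshold
        )
        for s in removed:
            log_rows.append({"locus_id": matrix.locus_id, "level": level,
                             "sample": s})
    return current, pd.DataFrame(log_rows,
                                 columns=["locus_id", "level", "sample"])


def concat_supermatrix(
    matrices: Sequence[LocusMatrix],
    samples: Optional[Sequence[str]] = None,
    missing_symbol: str = "-",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate locus matrices; absent samples are padded with the missing
    symbol.

    Returns (sample -> supermatrix row, partition table with 1-based inclusive
    column ranges per locus — the convention of partition files).
    """
    if samples is None:
        universe: list[str] = []
        for m in matrices:
            for s in m.seqs:
                if s not in universe:
                    universe.append(s)
        samples = universe
    parts = []
    rows = {s: [] for s in samples}
    start = 1
    for m in matrices:
        ncol = m.n_columns
        for s in samples:
            rows[s].append(m.seqs.get(s, missing_symbol * ncol))
        parts.append({"locus_id": m.locus_id, "start": start,
                      "end": start + ncol - 1})
        start += ncol
    supermatrix = {s: "".join(chunks) for s, chunks in rows.items()}
    return supermatrix, pd.DataFrame(parts, columns=["locus_id", "start", "end"])


def write_partition_file(partitions: pd.DataFrame, path) -> None:
    """RAxML-style partition text: one 'DNA, id = start-end' line per locus."""
    with open(path, "w") as fh:
        for row in partitions.itertuples():
            fh.write(f"DNA, {row.locus_id} = {row.start}-{row.end}\n")
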