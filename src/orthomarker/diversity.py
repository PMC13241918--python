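"""Per-individual genetic diversity from genotype calls.

The diversity statistic is the percentage of polymorphic (heterozygous)
sites within an individual: heterozygous exonic genotype calls passing the
call filters, divided by the exonic length covered at the minimum read
depth, times 100. Species-level diversity is the arithmetic mean over the
species' individuals. Cross-marker comparisons use ordinary least-squares
regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedValueError

logger = logging.getLogger(__name__)

VCF_COLUMNS = ["pos", "ref", "alt", "depth", "qual", "genotype"]


@dataclass
class CallFilterConfig:
    """Call-level filters: biallelic SNPs at >= min_depth reads and
    >= min_qual site quality, inside the exon mask."""

    min_depth: int = 6
    min_qual: float = 100.0
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class SiteCallSet:
    """One individual's site calls over an exon mask.

    ``records`` holds variant calls (columns pos, ref, alt, depth, qual,
    genotype; alt is comma-joined for multi-allelic records; pos is 0-based).
    ``exons`` is the exon mask as 0-based half-open intervals on ``contig``.
    ``depth`` gives per-position read depth for every masked position, in
    mask order (the denominator track).
    """

    sample_id: str
    species: str
    contig: str
    exons: list[tuple[int, int]]
    depth: np.ndarray
    records: pd.DataFrame

    def __post_init__(self) -> None:
        n = sum(e - s for s, e in self.exons)
        if len(self.depth) != n:
            raise ValueError(
                f"depth track has {len(self.depth)} entries for {n} masked bp"
            )

    def masked_positions(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(s, e) for s, e in self.exons]
        ) if self.exons else np.array([], dtype=int)

    # -- plain-text I/O ----------------------------------------------------

    def write_vcf(self, path: str | Path) -> None:
        """Minimal single-sample VCF v4.2 (1-based positions on output)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.contig}>\n")
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     f"{self.sample_id}\n")
            for row in self.records.itertuples():
                fh.write(
                    f"{self.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t"
                    f"{row.qual:.0f}\tPASS\tDP={row.depth}\tGT:DP\t"
                    f"{row.genotype}:{row.depth}\n"
                )

    def write_exon_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, e in self.exons:
                fh.write(f"{self.contig}\t{s}\t{e}\n")

    def write_depth_tsv(self, path: str | Path) -> None:
        """BED-graph-style per-position depth over the mask."""
        positions = self.masked_positions()
        with open(path, "w") as fh:
            for pos, d in zip(positions, self.depth):
                fh.write(f"{self.contig}\t{pos}\t{pos + 1}\t{int(d)}\n")

    @classmethod
    def from_files(
        cls,
        vcf_path: str | Path,
        bed_path: str | Path,
        depth_path: str | Path,
        species: str = "",
    ) -> "SiteCallSet":
        """Load from VCF + BED exon mask + per-position depth TSV."""
        import pysam

        exons: list[tuple[int, int]] = []
        contig = ""
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, s, e = line.split()[:3]
                contig = chrom
                exons.append((int(s), int(e)))
        depth_map: dict[int, int] = {}
        with open(depth_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                _, s, e, d = line.split()[:4]
                for pos in range(int(s), int(e)):
                    depth_map[pos] = int(d)
        positions = np.concatenate(
            [np.arange(s, e) for s, e in exons]
        ) if exons else np.array([], dtype=int)
        depth = np.array([depth_map.get(int(p), 0) for p in positions])
        rows = []
        sample_id = "sample"
        with pysam.VariantFile(str(vcf_path)) as vf:
            names = list(vf.header.samples)
            if names:
                sample_id = names[0]
            for rec in vf:
                alts = rec.alts or ()
                gt = "./."
                dp = rec.info.get("DP", 0)
                if names:
                    sample = rec.samples[names[0]]
                    alleles = sample.get("GT", (None, None))
                    if alleles and alleles[0] is not None:
                        gt = "/".join(str(a) for a in alleles)
                    dp = sample.get("DP", dp)
                rows.append(
                    {"pos": rec.pos - 1, "ref": rec.ref,
                     "alt": ",".join(alts), "depth": int(dp or 0),
                     "qual": float(rec.qual or 0.0), "genotype": gt}
                )
        records = pd.DataFrame(rows, columns=VCF_COLUMNS)
        return cls(sample_id, species, contig, exons, depth, records)


@dataclass
class DiversityEstimate:
    sample_id: str
    species: str
    n_het_sites: int
    covered_exon_len: int
    pct_polymorphic: float


def is_heterozygous(genotype: str) -> bool:
    alleles = genotype.replace("|", "/").split("/")
    return len(alleles) == 2 and "." not in alleles and alleles[0] != alleles[1]


def _in_mask(pos: int, exons: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in exons)


def filter_calls(
    records: pd.DataFrame,
    exons: Sequence[tuple[int, int]],
    config: CallFilterConfig | None = None,
) -> pd.DataFrame:
    """Keep biallelic SNP records inside the mask at sufficient depth and
    quality; malformed records are skipped with a warning."""
    if config is None:
        config = CallFilterConfig()
    keep = []
    for idx, row in records.iterrows():
        try:
            pos = int(row["pos"])
            depth = int(row["depth"])
            qual = float(row["qual"])
            ref = str(row["ref"])
            alts = [a for a in str(row["alt"]).split(",") if a and a != "."]
        except (TypeError, ValueError, KeyError):
            logger.warning("skipping malformed record at index %s", idx)
            continue
        if config.biallelic_only and len(alts) != 1:
            continue
        is_snp = len(ref) == 1 and all(len(a) == 1 for a in alts)
        if not is_snp:
            continue
        if not _in_mask(pos, exons):
            continue
        if depth < config.min_depth or qual < config.min_qual:
            continue
        keep.append(idx)
    return records.loc[keep]


def pct_polymorphic(
    callset: SiteCallSet, config: CallFilterConfig | None = None
) -> DiversityEstimate:
    """The per-individual diversity statistic.

    Numerator: heterozygous calls surviving the filters. Denominator: masked
    positions covered by at least min_depth reads in this individual. The
    same depth cutoff governs both, so a low-coverage individual loses both
    calls and denominator length coherently.
    """
    if config is None:
        config = CallFilterConfig()
    covered = int(np.sum(np.asarray(callset.depth) >= config.min_depth))
    if covered == 0:
        raise UndefinedValueError(
            f"sample {callset.sample_id}: no masked position at depth >= "
            f"{config.min_depth}"
        )
    kept = filter_calls(callset.records, callset.exons, config)
    n_het = int(sum(is_heterozygous(g) for g in kept["genotype"]))
    return DiversityEstimate(
        sample_id=callset.sample_id,
        species=callset.species,
        n_het_sites=n_het,
        covered_exon_len=covered,
        pct_polymorphic=100.0 * n_het / covered,
    )


def species_mean(estimates: Sequence[DiversityEstimate]) -> pd.DataFrame:
    """Arithmetic mean percent polymorphic per species, with sample counts."""
    frame = pd.DataFrame(
        [{"species": e.species, "pct_polymorphic": e.pct_polymorphic}
         for e in estimates]
    )
    if frame.empty:
        return pd.DataFrame(columns=["species", "mean_pct_polymorphic", "n"])
    out = frame.groupby("species", sort=True)["pct_polymorphic"].agg(
        mean_pct_polymorphic="mean", n="size"
    ).reset_index()
    out["n"] = out["n"].astype(int)
    return out


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def simple_linear_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionResult:
    """OLS of y on x with the classical t-based p-value for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise UndefinedValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        n=len(x),
    )
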