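"""Synthetic cohort generator with planted ground truth.

Every input the pipeline consumes can be generated here with known truth, so
each downstream stage is testable by parameter recovery:

* a multi-genome panel carrying conserved loci evolved under a symmetric
  single-parameter substitution model at controlled within/between-clade
  divergence, with a fraction of loci duplicated as extra-divergent paralogs;
* species trees with tips per species and an exact number of planted
  monophyly violations;
* per-individual site calls with planted heterozygosity over an exon mask,
  negative-binomial read depth and depth-proportional quality;
* genotype matrices with planted clusters of diverged allele frequencies;
* species trait tables with a planted effect of riparian-habitat association
  on log diversity.

All randomness flows from one master seed; each stage derives its own child
stream, so outputs are reproducible stage by stage and byte-identical for an
identical configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .diversity import SiteCallSet, VCF_COLUMNS
from .panel import CandidateLocus, UCE, USCO
from .phylobench import LabeledTree
from .structure import GenotypeMatrix

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Stage codes for child-seed derivation.
_STAGE_PANEL = 1
_STAGE_TREES = 2
_STAGE_CALLS = 3
_STAGE_SNPS = 4
_STAGE_TRAITS = 5


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of the synthetic cohort.

    Divergences are per-branch substitution probabilities under a symmetric
    model (a substituted site picks uniformly among the three alternative
    bases); theta is the per-exonic-site heterozygosity probability; depth is
    negative-binomial with the given mean and dispersion (shape); quality is
    qual_per_read per supporting read.
    """

    seed: int = 0
    # genome panel
    n_genomes: int = 6
    clade_labels: tuple[str, ...] = (
        "Caelifera", "Caelifera", "Caelifera",
        "Ensifera", "Ensifera", "Ensifera",
    )
    n_loci_uce: int = 290
    n_loci_usco: int = 54
    locus_len_range: tuple[int, int] = (120, 300)
    usco_len_range: tuple[int, int] = (300, 800)
    within_clade_div: float = 0.05
    between_clade_div: float = 0.20
    paralog_frac: float = 0.10
    paralog_extra_div: float = 0.35
    # trees
    n_species: int = 20
    tips_per_species: int = 3
    n_monophyly_violations: int = 3
    # site calls
    theta_per_species: Union[float, Mapping[str, float]] = 0.005
    exon_bp: int = 100_000
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    qual_per_read: float = 30.0
    # SNP matrix
    n_clusters: int = 3
    cluster_size: int = 10
    n_snps: int = 500
    cluster_divergence: float = 0.4
    missing_rate: float = 0.05
    # trait table
    beta_riparian: float = -0.11
    trait_noise_sd: float = 0.10
    log_diversity_intercept: float = -5.41

    def __post_init__(self) -> None:
        counts = {
            "n_genomes": self.n_genomes, "n_loci_uce": self.n_loci_uce,
            "n_loci_usco": self.n_loci_usco, "n_species": self.n_species,
            "tips_per_species": self.tips_per_species,
            "n_clusters": self.n_clusters, "cluster_size": self.cluster_size,
            "n_snps": self.n_snps, "exon_bp": self.exon_bp,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_monophyly_violations < 0:
            raise ValueError("n_monophyly_violations must be >= 0")
        for name in ("within_clade_div", "between_clade_div", "paralog_frac",
                     "paralog_extra_div", "cluster_divergence",
                     "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for th in self._thetas().values():
            if not 0.0 <= th <= 0.5:
                raise ValueError("theta must be in [0, 0.5]")
        if len(self.clade_labels) != self.n_genomes:
            raise ValueError("clade_labels must have one entry per genome")
        if self.locus_len_range[0] < 2:
            raise ValueError("locus length must be >= 2 bp")

    def theta(self, species: str) -> float:
        thetas = self._thetas()
        if species in thetas:
            return thetas[species]
        if "*" in thetas:
            return thetas["*"]
        raise KeyError(f"theta undefined for species {species!r}")

    def _thetas(self) -> dict[str, float]:
        if isinstance(self.theta_per_species, Mapping):
            return dict(self.theta_per_species)
        return {"*": float(self.theta_per_species)}

    def rng(self, stage: int, substream: int = 0) -> np.random.Generator:
        """Deterministic child stream for one generator stage."""
        return np.random.default_rng(
            np.random.SeedSequence(
                entropy=self.seed, spawn_key=(stage, substream)
            )
        )


# ---------------------------------------------------------------------------
# sequence evolution

def random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability p; a substituted
    site picks uniformly among the three alternative bases."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < p)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        idx = np.searchsorted(BASES, out[hit])
        out[hit] = BASES[(idx + shift) % 4]
    return out


def expected_pairwise_mismatch(q1: float, q2: float) -> float:
    """Closed-form expected mismatch fraction between two copies at branch
    substitution probabilities q1 and q2 from their common ancestor.

    A site differs when exactly one branch substituted, or both did and the
    two (uniform among three alternatives) picks disagree (prob 2/3).
    """
    return q1 * (1 - q2) + q2 * (1 - q1) + (2.0 / 3.0) * q1 * q2


def _decode(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# genome panel

@dataclass
class SyntheticPanel:
    """Genomes with planted conserved loci and the truth table.

    truth columns: locus_id, type, genome, start, end (0-based half-open
    coordinates in the genome), is_paralog.
    """

    genomes: dict[str, str]
    clades: dict[str, str]
    loci: list[CandidateLocus]
    truth: pd.DataFrame


def simulate_genome_panel(config: SimConfig) -> SyntheticPanel:
    """Plant conserved loci into a panel of genomes.

    Each locus has a root sequence; each clade ancestor is evolved from the
    root at between_clade_div/2, each genome copy from its clade ancestor at
    within_clade_div/2 — so two same-clade copies are separated by two
    branches of within_clade_div/2 and two cross-clade copies by the full
    between-clade path. Paralog copies are evolved from the root at
    paralog_extra_div and inserted at a second location of one genome.
    """
    rng = config.rng(_STAGE_PANEL)
    genome_ids = [f"genome{i + 1:02d}" for i in range(config.n_genomes)]
    clades = dict(zip(genome_ids, config.clade_labels))
    clade_names = sorted(set(config.clade_labels))
    chunks: dict[str, list[np.ndarray]] = {g: [] for g in genome_ids}
    offsets: dict[str, int] = {g: 0 for g in genome_ids}
    loci: list[CandidateLocus] = []
    truth_rows: list[dict] = []

    def _append(genome: str, seq: np.ndarray) -> tuple[int, int]:
        spacer = random_sequence(rng, int(rng.integers(50, 201)))
        chunks[genome].append(spacer)
        offsets[genome] += len(spacer)
        start = offsets[genome]
        chunks[genome].append(seq)
        offsets[genome] += len(seq)
        return start, offsets[genome]

    plan = (
        [(UCE, config.locus_len_range, i) for i in range(config.n_loci_uce)]
        + [(USCO, config.usco_len_range, i) for i in range(config.n_loci_usco)]
    )
    n_total = len(plan)
    paralog_loci = set(
        rng.choice(n_total, size=int(round(config.paralog_frac * n_total)),
                   replace=False)
    ) if config.paralog_frac > 0 else set()

    for idx, (ltype, len_range, type_idx) in enumerate(plan):
        locus_id = f"{ltype.lower()}-{type_idx + 1:04d}"
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        root = random_sequence(rng, length)
        clade_anc = {
            c: mutate(root, config.between_clade_div / 2.0, rng)
            for c in clade_names
        }
        seqs: dict[str, str] = {}
        for g in genome_ids:
            copy = mutate(clade_anc[clades[g]],
                          config.within_clade_div / 2.0, rng)
            start, end = _append(g, copy)
            seqs[g] = _decode(copy)
            truth_rows.append(
                {"locus_id": locus_id, "type": ltype, "genome": g,
                 "start": start, "end": end, "is_paralog": False}
            )
        loci.append(CandidateLocus(locus_id, ltype, seqs,
                                   clades={g: clades[g] for g in genome_ids}))
        if idx in paralog_loci:
            host = genome_ids[int(rng.integers(0, len(genome_ids)))]
            para = mutate(root, config.paralog_extra_div, rng)
            para = mutate(para, config.within_clade_div / 2.0, rng)
            start, end = _append(host, para)
            truth_rows.append(
                {"locus_id": locus_id, "type": ltype, "genome": host,
                 "start": start, "end": end, "is_paralog": True}
            )

    genomes = {
        g: _decode(np.concatenate(parts)) if parts else ""
        for g, parts in chunks.items()
    }
    truth = pd.DataFrame(
        truth_rows,
        columns=["locus_id", "type", "genome", "start", "end", "is_paralog"],
    )
    return SyntheticPanel(genomes=genomes, clades=clades, loci=loci,
                          truth=truth)


# ---------------------------------------------------------------------------
# labeled trees with planted monophyly violations

class _Node:
    __slots__ = ("children", "label", "length")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list["_Node"]] = None,
                 length: float = 0.1):
        self.label = label
        self.children = children or []
        self.length = length

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def simulate_labeled_trees(
    config: SimConfig,
) -> tuple[LabeledTree, list[str]]:
    """A species tree with tips per species and exactly
    n_monophyly_violations non-monophyletic species.

    The backbone is a random-join (coalescent-style) topology over species
    clades, each holding tips_per_species tips. A violation regrafts one tip
    of the violated species as sister to a host species' clade: the donor
    species becomes non-monophyletic while the host's tips still form a
    clade, so the planted violation count is exact. Returns the tree and the
    sorted list of violated species.
    """
    if config.n_species < 2:
        raise ValueError("n_species must be >= 2")
    v = config.n_monophyly_violations
    if v > config.n_species - 1:
        raise ValueError(
            "n_monophyly_violations must be <= n_species - 1"
        )
    rng = config.rng(_STAGE_TREES)
    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    clade_of: dict[str, _Node] = {}
    subtrees: list[_Node] = []
    for sp in species:
        tips = [_Node(label=f"{sp}_{j + 1}",
                      length=float(rng.exponential(0.02) + 0.001))
                for j in range(config.tips_per_species)]
        clade = _Node(children=tips,
                      length=float(rng.exponential(0.1) + 0.01))
        clade_of[sp] = clade
        subtrees.append(clade)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(
            _Node(children=[a, b],
                  length=float(rng.exponential(0.1) + 0.01))
        )
    root = subtrees[0]

    violated = sorted(
        rng.choice(config.n_species, size=v, replace=False).tolist()
    )
    violated_names = [species[i] for i in violated]
    hosts_pool = [sp for sp in species if sp not in violated_names]
    for sp in violated_names:
        donor_clade = clade_of[sp]
        tip = donor_clade.children.pop(0)
        host = hosts_pool[int(rng.integers(0, len(hosts_pool)))]
        host_clade = clade_of[host]
        _regraft_sister(root, host_clade, tip, rng)

    tree = LabeledTree.from_newick(root.newick() + ";")
    return tree, violated_names


def _regraft_sister(root: _Node, target: _Node, tip: _Node,
                    rng: np.random.Generator) -> None:
    """Insert a new node (tip, target) where target currently hangs."""
    parent = _find_parent(root, target)
    if parent is None:
        raise RuntimeError("target clade not found under root")
    idx = parent.children.index(target)
    joint = _Node(children=[tip, target],
                  length=float(rng.exponential(0.05) + 0.01))
    parent.children[idx] = joint


def _find_parent(node: _Node, target: _Node) -> Optional[_Node]:
    for child in node.children:
        if child is target:
            return node
        found = _find_parent(child, target)
        if found is not None:
            return found
    return None


def swap_tips(tree: LabeledTree, tip_a: str, tip_b: str) -> LabeledTree:
    """Exchange the species assignment of two tips (a label swap).

    Swapping one tip between two species makes both non-monophyletic;
    used as a construction check, not for exact-count planting.
    """
    mapping = dict(tree.tip_to_species)
    mapping[tip_a], mapping[tip_b] = mapping[tip_b], mapping[tip_a]
    return LabeledTree(tree.tree, mapping)


# ---------------------------------------------------------------------------
# site calls

def simulate_site_calls(
    config: SimConfig, species: str, sample_id: Optional[str] = None,
    substream: int = 0,
) -> SiteCallSet:
    """Per-individual site calls over an exon mask.

    Exons of 500 bp (separated by 250 bp of intron) cover exon_bp of exonic
    sequence on one contig. Depth is negative-binomial (gamma-Poisson) with
    the configured mean and dispersion; site quality is qual_per_read x
    depth. Each exonic site is heterozygous with probability theta. To
    exercise downstream filters, hom-alt records are planted at rate theta/2
    and triallelic records at rate theta/5; neither is heterozygous, so the
    planted heterozygosity truth is exactly theta.
    """
    theta = config.theta(species)
    rng = config.rng(_STAGE_CALLS, substream)
    exon_len, intron_len = 500, 250
    exons: list[tuple[int, int]] = []
    pos = 0
    remaining = config.exon_bp
    while remaining > 0:
        take = min(exon_len, remaining)
        exons.append((pos, pos + take))
        pos += take + intron_len
        remaining -= take
    n_sites = config.exon_bp

    lam = rng.gamma(shape=config.depth_dispersion,
                    scale=config.depth_mean / config.depth_dispersion,
                    size=n_sites)
    depth = rng.poisson(lam)
    positions = np.concatenate([np.arange(s, e) for s, e in exons])

    u = rng.random(n_sites)
    het = u < theta
    hom_alt = (u >= theta) & (u < theta * 1.5)
    triallelic = (u >= theta * 1.5) & (u < theta * 1.7)

    records = []
    refs = random_sequence(rng, n_sites)
    for i in np.flatnonzero(het | hom_alt | triallelic):
        ref = chr(refs[i])
        others = [b for b in "ACGT" if b != ref]
        if triallelic[i]:
            alts = rng.choice(others, size=2, replace=False)
            alt, gt = ",".join(alts), "1/2"
        elif hom_alt[i]:
            alt, gt = str(rng.choice(others)), "1/1"
        else:
            alt, gt = str(rng.choice(others)), "0/1"
        d = int(depth[i])
        records.append(
            {"pos": int(positions[i]), "ref": ref, "alt": alt,
             "depth": d, "qual": config.qual_per_read * d, "genotype": gt}
        )
    frame = pd.DataFrame(records, columns=VCF_COLUMNS)
    return SiteCallSet(
        sample_id=sample_id or f"{species}_ind{substream + 1}",
        species=species,
        contig="panel_exons",
        exons=exons,
        depth=depth,
        records=frame,
    )


# ---------------------------------------------------------------------------
# SNP matrix with planted clusters

def simulate_snp_matrix(
    config: SimConfig,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotype matrix with n_clusters planted clusters.

    Per SNP, an ancestral allele frequency is drawn uniformly on
    [0.15, 0.85]; each cluster's frequency is the ancestral one shifted by a
    Normal(0, cluster_divergence) perturbation, clipped to [0.01, 0.99].
    Genotypes are Binomial(2, cluster frequency); entries go missing
    uniformly at missing_rate. Site qualities are drawn uniformly on
    [60, 400] so quality filtering is non-trivial. Returns the matrix and
    the true cluster label per individual.
    """
    rng = config.rng(_STAGE_SNPS)
    k, size, m = config.n_clusters, config.cluster_size, config.n_snps
    n = k * size
    p0 = rng.uniform(0.15, 0.85, size=m)
    freqs = np.clip(
        p0[None, :] + rng.normal(0.0, config.cluster_divergence, size=(k, m)),
        0.01, 0.99,
    )
    labels = np.repeat(np.arange(k), size)
    G = rng.binomial(2, freqs[labels]).astype(float)
    if config.missing_rate > 0:
        G[rng.random(G.shape) < config.missing_rate] = np.nan
    matrix = GenotypeMatrix(
        genotypes=G,
        individuals=[f"ind{i + 1:03d}" for i in range(n)],
        snp_ids=[f"snp{j + 1:04d}" for j in range(m)],
        snp_qual=rng.uniform(60.0, 400.0, size=m),
        n_alleles=np.full(m, 2),
    )
    return matrix, labels


# ---------------------------------------------------------------------------
# trait table

IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR")


def simulate_trait_table(
    config: SimConfig,
    species_diversities: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Species trait table with a planted riparian effect on log diversity.

    Ordinal traits are drawn independently on small supports in the style of
    ecological indicator databases. The diversity column follows
    ln(proportion polymorphic) = intercept + beta_riparian x riparian score
    + Normal(0, trait_noise_sd). When per-species diversities are supplied
    (e.g. from the diversity pipeline), ln(their proportion) replaces the
    intercept as the species' baseline and the planted effect and noise are
    added on top.
    """
    rng = config.rng(_STAGE_TRAITS)
    if species_diversities is not None:
        species = list(species_diversities)
    else:
        species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    n = len(species)
    table = pd.DataFrame({
        "species": species,
        "iucn_category": rng.choice(
            IUCN_CATEGORIES, size=n, p=[0.45, 0.16, 0.18, 0.14, 0.07]
        ),
        "habitat_specialisation": rng.integers(1, 4, size=n),
        "riparian_indicator": rng.integers(0, 4, size=n),
        "dry_meadow_indicator": rng.integers(0, 4, size=n),
        "dispersal_potential": rng.integers(1, 5, size=n),
        "thermophilic_preference": rng.integers(1, 4, size=n),
        "elevation_level": rng.integers(1, 6, size=n),
        "museum": False,
    })
    if species_diversities is not None:
        base = np.log(
            np.array([species_diversities[s] for s in species]) / 100.0
        )
    else:
        base = np.full(n, config.log_diversity_intercept)
    log_prop = (
        base
        + config.beta_riparian * table["riparian_indicator"].to_numpy()
        + rng.normal(0.0, config.trait_noise_sd, size=n)
    )
    table["mean_pct_polymorphic"] = 100.0 * np.exp(log_prop)
    return table


# ---------------------------------------------------------------------------
# file emission

def write_fasta(seqs: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_cohort(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every synthetic input under outdir.

    Emits genomes and per-locus alignments (FASTA), the locus truth table
    (TSV), the labeled tree (Newick) with its tip map and violation truth
    (TSV), one individual's site calls (VCF + BED + depth TSV), the SNP
    matrix with truth labels (TSV), and the trait table (TSV). Returns the
    written paths. Identical configs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    panel = simulate_genome_panel(config)
    paths["genomes"] = outdir / "genomes.fasta"
    write_fasta(panel.genomes, paths["genomes"])
    loci_dir = outdir / "loci"
    loci_dir.mkdir(exist_ok=True)
    for locus in panel.loci:
        write_fasta(locus.seqs, loci_dir / f"{locus.id}.fasta")
    paths["loci_dir"] = loci_dir
    paths["locus_truth"] = outdir / "locus_truth.tsv"
    panel.truth.to_csv(paths["locus_truth"], sep="\t", index=False)

    tree, violated = simulate_labeled_trees(config)
    paths["tree"] = outdir / "tree.nwk"
    with open(paths["tree"], "w") as fh:
        fh.write(tree.tree.as_string(schema="newick"))
    paths["tip_map"] = outdir / "tip_map.tsv"
    pd.DataFrame(
        sorted(tree.tip_to_species.items()), columns=["tip", "species"]
    ).to_csv(paths["tip_map"], sep="\t", index=False)
    paths["violations"] = outdir / "violation_truth.tsv"
    pd.DataFrame({"species": violated}).to_csv(
        paths["violations"], sep="\t", index=False
    )

    calls = simulate_site_calls(config, "sp01")
    paths["vcf"] = outdir / f"{calls.sample_id}.vcf"
    calls.write_vcf(paths["vcf"])
    paths["exon_bed"] = outdir / "exons.bed"
    calls.write_exon_bed(paths["exon_bed"])
    paths["depth"] = outdir / f"{calls.sample_id}.depth.tsv"
    calls.write_depth_tsv(paths["depth"])

    matrix, labels = simulate_snp_matrix(config)
    paths["snp_matrix"] = outdir / "snp_matrix.tsv"
    frame = pd.DataFrame(matrix.genotypes, index=matrix.individuals,
                         columns=matrix.snp_ids)
    frame.to_csv(paths["snp_matrix"], sep="\t")
    paths["snp_truth"] = outdir / "cluster_truth.tsv"
    pd.DataFrame({"individual": matrix.individuals,
                  "cluster": labels}).to_csv(
        paths["snp_truth"], sep="\t", index=False
    )

    traits = simulate_trait_table(config)
    paths["traits"] = outdir / "traits.tsv"
    traits.to_csv(paths["traits"], sep="\t", index=False)
    return paths
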