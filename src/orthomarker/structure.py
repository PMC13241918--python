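"""Within-species spatial genetic structure from SNP matrices.

Biallelic SNPs are filtered on site quality and call rate (at both the SNP
and the individual level), genotypes (0/1/2 alternate-allele counts) are
mean-imputed and decomposed by PCA, and k-means is run over a range of k on
the leading components; the k with the highest average silhouette width is
reported. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs, coded 0/1/2 with NaN for missing.

    ``snp_qual`` carries per-SNP site quality; ``n_alleles`` (optional)
    marks sites that are not biallelic so they can be filtered.
    """

    genotypes: np.ndarray
    individuals: list[str]
    snp_ids: list[str]
    snp_qual: Optional[np.ndarray] = None
    n_alleles: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        n, m = self.genotypes.shape
        if len(self.individuals) != n or len(self.snp_ids) != m:
            raise ValueError("label lengths do not match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.genotypes.shape


@dataclass
class StructureConfig:
    """Filters and clustering controls.

    The missing-data thresholds follow the call-rate convention: a SNP (or
    individual) is kept when its fraction of non-missing genotypes is at
    least min_call_rate_*. (A literal reading of a 0.85% *missing* ceiling is
    available via missing_convention='max_missing_pct', which keeps items
    with under 0.85% missing entries.)
    """

    min_qual: float = 100.0
    biallelic_only: bool = True
    min_call_rate_snp: float = 0.85
    min_call_rate_individual: float = 0.85
    missing_convention: str = "call_rate"  # or "max_missing_pct"
    k_range: tuple[int, int] = (2, 10)
    n_init: int = 50
    seed: int = 0
    min_var_explained: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_call_rate_snp", "min_call_rate_individual"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("k_range must satisfy 2 <= min <= max")
        if self.missing_convention not in ("call_rate", "max_missing_pct"):
            raise ValueError("unknown missing_convention")


def _passes_missing(call_rate: float, threshold: float, convention: str) -> bool:
    if convention == "call_rate":
        return call_rate >= threshold
    # 'threshold' is reinterpreted as a maximum percent of missing entries.
    return (1.0 - call_rate) * 100.0 < threshold


def filter_snps(
    matrix: GenotypeMatrix, config: StructureConfig | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Quality and call-rate filtering: SNPs first, then individuals over the
    surviving SNPs."""
    if config is None:
        config = StructureConfig()
    G = matrix.genotypes
    n, m = G.shape
    snp_keep = np.ones(m, dtype=bool)
    if config.biallelic_only and matrix.n_alleles is not None:
        snp_keep &= np.asarray(matrix.n_alleles) == 2
    if matrix.snp_qual is not None:
        snp_keep &= np.asarray(matrix.snp_qual) >= config.min_qual
    call_rate_snp = 1.0 - np.isnan(G).mean(axis=0)
    snp_keep &= np.array([
        _passes_missing(c, config.min_call_rate_snp, config.missing_convention)
        for c in call_rate_snp
    ])
    G2 = G[:, snp_keep]
    if G2.shape[1] == 0:
        raise ValueError(
            "no SNP passed the filters; consider relaxing min_qual or the "
            "call-rate thresholds"
        )
    call_rate_ind = 1.0 - np.isnan(G2).mean(axis=1)
    ind_keep = np.array([
        _passes_missing(c, config.min_call_rate_individual,
                        config.missing_convention)
        for c in call_rate_ind
    ])
    if not ind_keep.any():
        raise ValueError(
            "no individual passed the filters; consider relaxing the "
            "call-rate thresholds"
        )
    log = pd.DataFrame({
        "snp_id": matrix.snp_ids,
        "kept": snp_keep,
        "call_rate": call_rate_snp,
    })
    filtered = GenotypeMatrix(
        genotypes=G2[ind_keep],
        individuals=[s for s, k in zip(matrix.individuals, ind_keep) if k],
        snp_ids=[s for s, k in zip(matrix.snp_ids, snp_keep) if k],
        snp_qual=(np.asarray(matrix.snp_qual)[snp_keep]
                  if matrix.snp_qual is not None else None),
        n_alleles=(np.asarray(matrix.n_alleles)[snp_keep]
                   if matrix.n_alleles is not None else None),
    )
    return filtered, log


def genotype_pca(
    matrix: GenotypeMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Centred PCA of the genotype matrix.

    Missing genotypes are mean-imputed per SNP; zero-variance SNPs are
    excluded (they carry no structure). Returns (scores, explained variance
    fractions).
    """
    G = matrix.genotypes if isinstance(matrix, GenotypeMatrix) else np.asarray(
        matrix, dtype=float
    )
    if G.shape[0] < 3:
        raise ValueError("PCA needs >= 3 individuals")
    col_mean = np.nanmean(G, axis=0)
    filled = np.where(np.isnan(G), col_mean, G)
    var = filled.var(axis=0)
    filled = filled[:, var > 0]
    if filled.shape[1] == 0:
        raise ValueError("no variable SNPs after imputation")
    centred = filled - filled.mean(axis=0)
    U, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = U * s
    var_frac = s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
    return scores, var_frac


@dataclass
class ClusterResult:
    chosen_k: int
    assignments: np.ndarray
    silhouette_by_k: dict[int, float]
    scores: np.ndarray
    individuals: list[str] = field(default_factory=list)


def select_k_kmeans(
    scores: np.ndarray,
    config: StructureConfig | None = None,
    individuals: Optional[Sequence[str]] = None,
) -> ClusterResult:
    """Silhouette-guided k selection.

    For each k in k_range, the best of n_init k-means restarts is scored by
    the average silhouette width on Euclidean distances; the k with the
    highest average silhouette wins, with ties broken to the smallest k.
    Values of k with too few points (n <= k) are skipped.
    """
    if config is None:
        config = StructureConfig()
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    silhouettes: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(config.k_range[0], config.k_range[1] + 1):
        if n <= k:
            logger.info("k=%d skipped (only %d individuals)", k, n)
            continue
        km = KMeans(n_clusters=k, n_init=config.n_init,
                    random_state=config.seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        silhouettes[k] = float(silhouette_score(X, labels, metric="euclidean"))
        labels_by_k[k] = labels
    if not silhouettes:
        raise ValueError("no k in range could be evaluated")
    best = max(silhouettes.values())
    chosen_k = min(k for k, s in silhouettes.items() if s == best)
    if sum(1 for s in silhouettes.values() if s == best) > 1:
        logger.info("silhouette tie at %.4f; choosing smallest k=%d",
                    best, chosen_k)
    return ClusterResult(
        chosen_k=chosen_k,
        assignments=labels_by_k[chosen_k],
        silhouette_by_k=silhouettes,
        scores=X,
        individuals=list(individuals) if individuals is not None else [],
    )


def cluster_structure(
    matrix: GenotypeMatrix, config: StructureConfig | None = None
) -> ClusterResult:
    """Full pipeline: filter SNPs, PCA, then silhouette-selected k-means on
    the leading components explaining >= min_var_explained of variance
    (always at least two components)."""
    if config is None:
        config = StructureConfig()
    filtered, _ = filter_snps(matrix, config)
    scores, var_frac = genotype_pca(filtered)
    n_comp = max(2, int(np.searchsorted(np.cumsum(var_frac),
                                        config.min_var_explained) + 1))
    n_comp = min(n_comp, scores.shape[1])
    result = select_k_kmeans(scores[:, :n_comp], config,
                             individuals=filtered.individuals)
    return result


def label_agreement(truth: Sequence[int], predicted: Sequence[int]) -> float:
    """Permutation-invariant clustering accuracy.

    Best one-to-one matching of predicted to true labels (Hungarian
    assignment on the contingency table), returning the fraction of
    individuals correctly assigned under that matching.
    """
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    t_vals = np.unique(t)
    p_vals = np.unique(p)
    table = np.zeros((len(t_vals), len(p_vals)), dtype=int)
    for i, tv in enumerate(t_vals):
        for j, pv in enumerate(p_vals):
            table[i, j] = np.sum((t == tv) & (p == pv))
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum()) / len(t)
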