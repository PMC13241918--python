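# orthomarker

Toolkit for building and validating **multi-locus conserved-marker panels**
for target-capture studies of species-rich insect groups (developed around
an Orthoptera-style setting with two suborders, Caelifera and Ensifera).
It covers the full downstream analysis path of such a panel:

* **Panel design** — harvest candidate conserved loci (UCEs, single-copy
  ortholog genes, mitochondrial genes, rDNA) from multi-genome alignments,
  apply a filter cascade (captured in ≥ 6 genomes, length ≥ 120 bp, ≤ 50%
  variable sites, ≤ 10% within-suborder p-distance), and tile survivors into
  non-overlapping 170-bp probes; single-copy orthologs contribute their two
  120-bp ends as independent loci.
* **Orthology assignment** — classify captured genomic regions against their
  probes by uncorrected p-distance (assigned when the distance is below 30%
  and ≥ 3 samples mapped), separating true orthologs from paralogous copies.
* **Locus QC** — drop sequences > 40% missing, keep loci present in ≥ 1/3 of
  samples and samples < 20% incomplete, screen residual paralogs by a robust
  consensus-distance rule in consecutive rounds (order → family → genus),
  and concatenate survivors into a partitioned supermatrix.
* **Genetic diversity** — the per-individual *percent polymorphic sites*:
  heterozygous exonic genotype calls (biallelic SNPs, depth ≥ 6, site
  quality ≥ 100) divided by the exonic length covered at ≥ 6 reads, × 100;
  species means and cross-marker regressions.
* **Monophyly benchmarking** — score species monophyly on labeled trees by
  bipartitions (unrooted semantics, singletons excluded) and compare marker
  sets on their shared species.
* **Trait association** — Gaussian GLM of log diversity on ordinal
  ecological traits after greedy correlation pruning, a two-sided Wilcoxon
  rank-sum test of threatened vs non-threatened species, and trait PCA.
* **Spatial structure** — SNP call-rate/quality filtering, genotype PCA and
  k-means with the number of clusters selected by the highest average
  silhouette width.
* **Synthetic cohorts** — a generator that plants every ground truth the
  pipeline estimates (locus divergences and paralogs, monophyly violations,
  per-site heterozygosity, cluster memberships, a riparian effect on log
  diversity), so the whole stack validates by parameter recovery without
  external data.

## Worked example

```python
from orthomarker.synthetic import SimConfig, simulate_snp_matrix, simulate_site_calls
from orthomarker.structure import StructureConfig, cluster_structure, label_agreement
from orthomarker.diversity import pct_polymorphic

config = SimConfig(seed=5, n_clusters=3, cluster_size=10, n_snps=500,
                   cluster_divergence=0.4)
matrix, truth = simulate_snp_matrix(config)
result = cluster_structure(matrix, StructureConfig(seed=5))
print(result.chosen_k, label_agreement(truth, result.assignments))

est = pct_polymorphic(simulate_site_calls(
    SimConfig(seed=11, theta_per_species=0.005), "sp01"))
print(f"{est.pct_polymorphic:.3f}% over {est.covered_exon_len} bp")
```

prints

```
3 1.0
0.507% over 99230 bp
```

— the silhouette scan recovers the three planted clusters with perfect
label agreement, and the diversity estimator returns 0.507% polymorphic
sites against a planted per-site heterozygosity of 0.5% over the ~99 kb of
exon covered at ≥ 6 reads.

The same functionality is exposed on the command line:

```bash
orthomarker simulate --config sim.json --outdir cohort/
orthomarker design-panel --loci cohort/loci --out panel/
orthomarker bench-monophyly --tree cohort/tree.nwk --tip-map cohort/tip_map.tsv
orthomarker estimate-diversity --vcf s.vcf --bed exons.bed --depth s.depth.tsv
orthomarker cluster-structure --matrix cohort/snp_matrix.tsv --seed 5
```

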