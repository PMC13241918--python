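# Methods

This note documents the models and procedures implemented in `orthomarker`,
the defaults they ship with, and what the synthetic validation does and does
not demonstrate.

## Sequence evolution in the synthetic panel

Planted loci evolve under a single-parameter symmetric substitution model:
each site substitutes independently with the branch's substitution
probability *q*, and a substituted site picks uniformly among the three
alternative bases. This is the simplest model with a closed-form pairwise
expectation, which the calibration tests rely on: for two copies separated
from a common ancestor by branches *q₁* and *q₂*, the expected mismatch
fraction is

    P(differ) = q₁(1−q₂) + q₂(1−q₁) + (2/3)·q₁q₂

(the last term covers coincident substitutions that disagree). Divergence
parameters are therefore per-branch substitution probabilities, not
multiple-hit-corrected distances. `within_clade_div` (default 0.05) is split
evenly across the two branches joining same-clade genomes, so the planted
pairwise divergence equals the configured value up to the quadratic term;
`between_clade_div` (default 0.20) is split the same way across clade
ancestors. Paralogs are copies of the locus root carrying
`paralog_extra_div` (default 0.35) plus a genome-branch contribution, which
puts their observed p-distance to a locus consensus near 40% — comfortably
above the 30% assignment cutoff, mirroring the bimodal distance separation
the classifier is built to exploit. No indels are simulated, so planted
locus copies are column-aligned by construction.

Genome panels default to 6 genomes (3 per suborder), 290 conserved-element
loci of 120–300 bp and 54 single-copy-ortholog genes of 300–800 bp — the
scale of the marker set the panel-design arithmetic targets (398 loci:
290 + 2×54 end-probe loci). Loci are embedded in random spacer sequence
with recorded 0-based half-open coordinates.

## Probe design choices

Tiling drops a terminal remainder shorter than one probe (probes are
synthesised at fixed length); a kept locus shorter than one probe still
emits a single truncated probe so the panel remains total. The
variable-site fraction uses a gap-aware denominator (columns with ≥ 2
non-missing residues), so missing data is not scored as variation.
"Divergence" is operationalised throughout as the uncorrected p-distance
over gap-free column pairs. Ortholog genes shorter than two end-probes
yield one truncated probe plus a warning rather than failing the run.
Candidate gene loci are screened only by the shared-genome rule (≥ 5 of 6
by default): their probes target exon ends where the variability and
divergence screens for full-locus alignments are not meaningful.

## Orthology classification

Regions are accepted when at least 3 samples mapped and the p-distance to
the probe is strictly below 30 (percent); the boundary value 30.0 is
rejected. Unaligned probe/region pairs are globally aligned with affine gap
costs (match +1, mismatch −1, open −5, extend −0.5) on both strands, and
the lower distance is used — capture is strand-agnostic. The uncorrected
distance variant is the default and exposed as configuration.

## Paralog screening (stand-in rule)

Published paralog filters for capture data do not document a reproducible
criterion, so the QC module uses an explicit robust-outlier stand-in,
labelled as such in outputs: within each taxonomic group of ≥ 3 sequences,
each row's p-distance to the group majority consensus is computed and rows
above median + z·MAD (z = 5 by default) are removed, with the MAD floored
at 0.5 percentage points so near-identical groups do not flag harmless
jitter. Rounds run coarse to fine (order → family → genus), each on the
previous round's survivors. On default synthetic settings the rule removes
≥ 90% of planted paralogs at ≤ 5% false removals (verified in the test
suite); the floor and multiplier are the knobs to revisit for data with
much higher within-group divergence.

## Diversity statistic

The per-individual statistic is 100 × (heterozygous filtered calls) /
(masked positions covered at ≥ `min_depth` reads in that individual).
Filters follow the capture-data convention: biallelic SNPs only, depth ≥ 6,
site QUAL ≥ 100 (site quality, not genotype GQ), positions restricted to
the exon mask. The same depth cutoff governs numerator and denominator, so
coverage loss shrinks both coherently; the denominator is per-individual,
matching a within-individual heterozygosity reading. Read depth in the
generator is negative-binomial (gamma–Poisson; mean 30, dispersion 5) to
emulate capture-efficiency overdispersion, and site quality is
`qual_per_read` × depth. The generator also plants hom-alt and triallelic
records so the filters face non-trivial input; neither affects the planted
heterozygosity truth. Estimator calibration: the estimate is binomial, so
tests and the acceptance run check recovery within 3·√(θ(1−θ)/L) of the
planted θ at L ≈ 50 kb covered.

## Monophyly

A species is monophyletic when its tips (or their complement — trees are
treated as unrooted) equal the leafset of some edge; polytomies use
soft-polytomy semantics and the scoring is root-invariant. Singleton
species are excluded from counts (a single sample cannot test exclusivity)
but carried in reports. Marker comparison restricts to species scored in
every tree. Violation planting in the generator regrafts one tip of the
violated species as sister to a host species' clade: this breaks exactly
the donor species (a tip swap would break two, making odd violation counts
unreachable), so planted counts are exact; a `swap_tips` helper provides
the classic both-broken construction.

## Trait association

The response is ln(proportion polymorphic) by default: the intercept of a
log-scale model back-transforms to a plausible baseline heterozygosity
(e.g. −5.41 → ≈ 0.45%), and an identity-scale response is available as
configuration. Ordinal predictors (threat rank LC<NT<VU<EN<CR, habitat
specialisation, riparian and dry-meadow indicator scores, dispersal,
thermophily, elevation) enter as numeric scores. Correlated predictors are
pruned greedily at |r| > 0.7 (the cutoff is configuration; the pruning
action, not the value, is the method), dropping the member of the worst
pair with the higher mean absolute correlation, ties to the later column.
Museum-flagged rows are excluded from association fits. The threatened
(VU+EN+CR) vs non-threatened (LC+NT) comparison uses a two-sided rank-sum
test, exact by enumeration when the smaller group has ≤ 10 observations
and the data are tie-free, normal-approximate otherwise; an all-equal
input returns p = 1. The generator plants
ln(prop) = intercept + β·riparian + N(0, σ) with β = −0.11 and σ = 0.1 by
default — an effect of the size and sign a riparian-specialisation signal
plausibly produces on log diversity; 200-replicate recovery and a
null-calibration run (≈ 5% rejections at α = 0.05) are part of the
acceptance computation.

## Spatial structure

SNPs are filtered by site quality (≥ 100) and call rate, then individuals
by call rate over surviving SNPs. The missing-data threshold is read as a
call-rate floor of 0.85 (85%): the literal alternative — a 0.85% ceiling on
missingness — would discard nearly everything at cohort sizes of ~20
individuals, but it remains selectable
(`missing_convention="max_missing_pct"`). No neutrality screen is applied;
"neutral SNP" selection is not operationalised here. Genotypes are coded
0/1/2, mean-imputed per SNP, zero-variance SNPs excluded, and decomposed by
centred PCA; k-means (50 restarts, seeded) runs on the leading components
explaining ≥ 80% of variance (at least two), and k ∈ [2, 10] is selected by
the highest average silhouette width with ties to the smallest k. Planted
clusters (3 clusters × 10 individuals, 500 SNPs, allele-frequency
perturbation SD 0.4, 5% missingness) are recovered exactly under these
defaults; recovery is scored by Hungarian-matched label agreement.

## Determinism and problem sizes

One master seed feeds every stage through independently derived child
streams (`numpy` SeedSequence spawn keys), so identical configurations
produce byte-identical output files and consuming one stage never perturbs
another. The validation suite and the acceptance script run at desk scale:
50–100 kb exon masks, 60–344 loci, 500 random oracle trees of ≤ 12 tips,
200 GLM replicates of 100 species, and 30-individual SNP matrices — sizes
chosen so the full stack re-validates in seconds while leaving every
statistical check at ≥ 3σ resolution.

## Limitations

The generator does not simulate reads, mapping error, indels,
heteroplasmy, nuclear-mitochondrial inserts, or linkage between SNPs;
cluster divergence is a frequency perturbation rather than an explicit
demography; trait columns other than the riparian score are independent
draws, so the trait PCA has no planted correlation structure. Passing
parameter-recovery tests therefore demonstrates correctness of the
implemented estimators under their own model assumptions, not robustness
to the mapping/assembly artefacts real capture data carry upstream of this
toolkit.
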