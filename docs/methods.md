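# Methods

This document defines the simulation model, the estimators, and the
numerical conventions used throughout `oryzapop`. Symbols: n = number of
diploid samples, m = number of called haplotypes at a site (≤ 2n), S =
number of segregating sites.

## Synthetic data generator (`simdata`)

### Demography

Data are simulated with the msprime coalescent. The wild progenitor is a
1-D stepping-stone of `n_wild_subpops` demes (size `wild_deme_size`,
symmetric migration `wild_migration`). The domesticate consists of
`n_dom_subpops` demes that merge, backwards in time, into a single
founding lineage which joins a wild source deme `bottleneck.time`
generations ago at a founding size of `bottleneck.severity` ×
`wild_deme_size`; forwards in time the cultivated demes then grow
exponentially at `recovery_growth_rate`. Defaults (wild deme size 5,000,
μ = 6e-8, bottleneck severity 0.1 at 3,000 generations, selfing rate
0.9) yield wild per-site diversity near 1.3e-3 and the qualitative
domestication signature: reduced cultivated diversity, cultivated
Tajima's D < 0 and wild D > 0.

### Selfing

Partial self-fertilization at rate s is modelled in two steps, using the
equilibrium inbreeding coefficient F = s/(2−s):

1. coalescent-effective population sizes are scaled by 1/(1+F), the
   standard effective-size reduction under partial selfing;
2. each individual is made autozygous with probability F (its second
   haplotype is replaced by a copy of the first), producing the excess
   homozygosity that the coalescent scaling alone does not create.

### Planted signals and truth log

- **Sweeps**: at a chosen position, a random `carrier_fraction` of the
  target group becomes homozygous for a "beneficial" background; linked
  variation within `width_bp` of the position is homogenized flank by
  flank from donor carriers, creating the high within-flank/low
  cross-flank LD contrast characteristic of a hard sweep.
- **Introgressions**: all samples of one cultivated subpopulation
  receive, homozygously, the alleles of a single donor individual from a
  distant wild deme over a fixed interval — a geographically restricted
  gene haplotype with a divergent history.
- The **truth log** records per-variant ancestral alleles (the reference
  allele is ancestral with probability `ref_is_ancestral_prob`),
  functional classes, outgroup-branch substitutions (rate
  `outgroup_divergence`), sweep windows, introgressed intervals and each
  sample's subpopulation, enabling exact validation downstream.

### Dataset bundle

`write_bundle` emits a VCF 4.2 file with GATK-style INFO annotations
(DP, QD, MQ, MQRankSum, ReadPosRankSum, FS) drawn from plausible
distributions plus a functional class (noncoding / synonymous /
nonsynonymous), a sample table (species, subpopulation, coordinates,
coverage), an outgroup alignment map, GFF3 candidate genes, an ancestry
Q-matrix concentrated on the true subpopulations, and the truth log.

### Realism and limits

Genotypes come from a genuine coalescent with recombination, so LD
decay, allele-frequency spectra and genealogical correlation are
realistic. Sweeps and introgressions are imposed deterministically
rather than forward-simulated; missingness is uniform rather than
coverage-dependent; INFO annotations are independent of genotype
quality. These simplifications are deliberate: they keep the truth log
exact.

## Variant QC (`variantio`)

Only biallelic SNPs are retained at parse time (multiallelic and
non-SNP records are counted and skipped). `tstv_profile` bins SNPs along
the range of one INFO annotation and reports count and Ts:Tv per bin —
since functional constraint favours transitions, a falling Ts:Tv
identifies annotation ranges enriched for artefacts, guiding threshold
choice. Two editable presets ("full", "strict") apply hard interval
filters per annotation plus a missing-data cap (no-call rate / n);
removals are attributed to the first failing filter in declared order.
`sample_stats` reports per-sample call rate, heterozygosity over called
genotypes, and a low-coverage flag.

## Diversity statistics (`diversity`)

- Per-site nucleotide diversity uses the unbiased pairwise estimator
  π = 2x(1−x)·m/(m−1) with x the sample allele frequency among m called
  haplotypes.
- Watterson's estimator M = S/a1 with a1 = Σ_{i<n_hap} 1/i.
- Tajima's D uses the 1989 variance constants; D is undefined (NaN)
  when S = 0.
- `windowed_scan` tiles each chromosome from position 1 with
  (optionally overlapping) windows; π and θ_W are reported per site
  using the window width, SNP density per kb; partial terminal windows
  are kept and flagged.
- Wild/cultivated comparisons: per-window ratios plus a genome-wide
  ratio of summed window values (robust to near-zero windows), and a
  tie-corrected Kruskal–Wallis test between the two window
  distributions.
- The MAF spectrum uses (low, high] bins, the first closed at 0;
  monomorphic sites are removed first.

## Unfolded SFS (`sfs`)

`polarize` assigns each variant's ancestral allele from an outgroup
alignment map, discarding variants that are unaligned, have a gap within
5 bp, map to multiple regions, or whose outgroup allele matches neither
REF nor ALT; the discard tally partitions all variants. The derived
frequency is computed from the integer derived-allele count divided by
called haplotypes — never as 1 − (alternate frequency), which lands a
few ulp off exact bin edges and shifts counts between bins.

The observed spectrum is restricted to synonymous + noncoding variants.
The neutral expectation places θ_W/i sites at derived count i
(i = 1..n_hap−1), binned by frequency i/n_hap, and sums to S by the
harmonic normalization. Observed and expected spectra are compared by
ECDFs evaluated at bin upper edges with a two-sample KS test
(asymptotic p with effective size n1·n2/(n1+n2)). Because the KS test
assumes independent sites, calibration runs use many short independent
chromosomes to decorrelate genealogies. The high-frequency excess
statistic sums positive (observed − expected) differences over bins in
(0.7, 1.0] as a percent of all observed sites.

## LD sweep scan (`sweep`)

For phased haplotypes, r² = D²/(p1 p2 q1 q2); unphased genotypes use
the squared Pearson correlation of genotype dosages as the standard
surrogate. For a window of W sites split after site l, the ω statistic
is the mean r² within the left and right groups divided by the mean r²
across them; ω is maximized over l ∈ {2..W−2}. Degenerate
cross-group means below 1e-12 cap ω at 1e6 with a `capped` flag.

`omega_scan` evaluates a regular grid (default 10 kb spacing; a spacing
wider than the chromosome evaluates once at the midpoint). The
assessment window holds the ≤ `max_sites` segregating sites nearest the
grid point within ±100 kb (consonant with LD decaying to baseline by
~300 kb); grid points with < 3 sites are skipped; values are also
log10-transformed for reporting. Outliers are the top 0.5% of grid
points: k = ⌈q·N⌉ with all threshold ties flagged. Candidate genes are
features lying strictly < 25 kb from a flagged point (distance 0 when
overlapping) that contain at least one moderate/high-impact variant.
`neutrality_cross_check` attaches the mean of every overlapping 25 kb
window of π and Tajima's D to each grid point.

## Population structure (`structure`)

- **LD pruning**: greedy within sliding windows (500 SNPs, step 50,
  r² > 0.25, never spanning chromosomes), iterated to a fixpoint so the
  retained set is idempotent under re-application.
- **PCA**: SVD of the column-centred genotype matrix; score covariance
  is diagonal and explained-variance ratios match the eigenvalues of
  the sample-space Gram matrix.
- **PC–geography**: Pearson r of each of the top 20 PCs against
  latitude and longitude with the two-sided t-test
  t = r√((n−2)/(1−r²)).
- **Ancestry assignment**: a sample is labelled with its argmax
  ancestry component iff the fraction is strictly > 0.5.
- **F_ST**: primary estimator is the variance decomposition
  σ²_S/(p(1−p)) with the genome-wide value a ratio of sums over sites
  (e.g. frequencies 0.2 vs 0.8 in equal-sized groups give 0.36); the
  Weir–Cockerham 1984 two-level θ is available for comparison.
  Classification bands: < 0.05 little, < 0.15 moderate, < 0.25 great,
  else very great.
- **Clines**: latitude ≥ 11°N is "north", longitude ≥ −6° is "east"
  (boundary points north/east); balanced subsamples of n = 15 per group
  prefer high-coverage samples when coverage is available, else a
  seeded uniform draw.
- **Kinship**: KING-robust φ = (N_het,het − 2·N_opp-hom) /
  (N_het(i) + N_het(j)) over jointly called sites; φ(self) = 0.5,
  parent–offspring ≈ 0.25.
- **Isolation by distance**: Haversine distances with R = 6,378 km;
  OLS of φ on distance after excluding distance outliers by Tukey
  1.5×IQR fences (kinship never enters the fences).

## Trees and gene haplotypes (`phylo`)

- Genome distance between samples x, y: mean |g_x − g_y|/2 over
  jointly called sites (pairwise deletion).
- Neighbour joining is the Saitou–Nei algorithm with the
  Studier–Keppler distance update, exact on additive matrices; negative
  branch lengths are clamped to 0 and counted. Trees are written as
  Newick via dendropy (labels with spaces stay quoted).
- Gene haplotypes cover a feature ± 5 kb flanks; heterozygotes are
  phased by the declared naive rule (reference allele to haplotype 1),
  missing genotypes become '?'. Haplotype groups are exact-string
  classes ranked by descending count (ties broken by first member id),
  with per-subpopulation composition.
- Gene trees use p-distance with pairwise deletion of '?', 'N' and '-';
  a fully ambiguous pair is an error.
- **Segregating-haplotype detection**: among the five most common
  groups of a gene, a group is flagged iff (i) its cultivated members
  all come from one subpopulation, (ii) none of its leaves lie inside
  the gene tree's major cultivated clade (the clade maximizing the
  Youden index of cultivated membership), and (iii) its nearest wild
  neighbour on the gene tree belongs to a different wild subpopulation
  than the genome tree's wild sister group of the cultivated samples.
  This is the signature of a divergent, geographically restricted gene
  history such as a local wild-to-crop introgression.

## Numerical conventions

- Ratio-of-sums aggregation (F_ST, π ratios, per-site diversity over
  windows) avoids instability from near-zero denominators in individual
  sites or windows.
- Frequencies that feed bin edges are always computed as integer counts
  divided by integer totals.
- Estimators return NaN (never ±inf) when undefined; degenerate ω
  denominators are capped and flagged.
- All stochastic steps take explicit integer seeds; derived seeds stay
  below 2³¹.

## Limitations

- The naive phasing rule misassigns phase for multiply heterozygous
  samples; haplotype-group counts are exact only for homozygous or
  fully called regions (the analysis scripts restrict gene haplotype
  extraction to fully called sites for this reason).
- The Weir–Cockerham estimator is provided per site without the
  small-sample ratio-of-averages refinements of downstream variants.
- The KS p-value is asymptotic and assumes independent sites;
  within-chromosome genealogical correlation makes it conservative only
  under the many-short-chromosomes study condition used for
  calibration.
- The ancestry Q-matrix is simulated, not estimated; structure results
  validate the assignment and geography logic, not an admixture model.
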