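# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that a maintainer would otherwise have to reverse
engineer from the code.

## Data model and conventions

Genotypes are stored as counts of `alleleB` per sample and marker (0/1/2,
missing −1). `alleleB` is the lexicographically larger of the two alleles
observed at the marker, so orientation is a pure function of the data: two
populations genotyped on the same array obtain the same orientation, which
is what makes *signed* r comparable across populations in the phase
persistence analysis. Orientation affects only the sign of r, never r²,
D' or any other reported statistic.

Coordinates are 1-based; interval lengths include both endpoint SNP
positions. Chromosomes 1–26 are the ovine autosomes, 27 is X, 0 means
unknown placement. Half-missing PED genotypes are set fully missing (the
strict convention). A marker observed with fewer than two alleles reads
back from PED with placeholder allele labels; genotype codes still
round-trip exactly.

## Quality control

The cascade runs in this order: (1) samples with more than 10% missing
genotypes; then, with marker statistics recomputed on the surviving
samples, (2) MAF < 0.05, (3) marker call rate < 95%, (4) Hardy–Weinberg
exact test below the Bonferroni-corrected threshold α/n (α = 0.05, n
defaulting to the pre-QC SNP count, so ~50k markers give 10⁻⁶), (5) unknown
placement, (6) sex chromosomes. Counts are sequential — a marker is counted
at the first step that removes it — so the report rows reconcile exactly
with initial minus remaining, and running QC twice removes nothing.

The HWE test is the standard conditional exact test: given the allele
counts, the probability of each possible heterozygote count is computed
(in log space via `gammaln`), and the p-value sums all outcomes no more
likely than the one observed. A χ² variant is available but the exact test
is the default, matching array-QC practice. MAF of an all-missing marker is
undefined; such markers are left to the call-rate step rather than counted
as MAF failures.

PCA standardizes each polymorphic marker by its allele frequency
((x − 2p)/√(2p(1−p))), mean-imputes missing calls and takes the SVD.
Because the centring uses the sample allele frequency, columns are exactly
mean-zero and the axes are the eigenvectors of the sample covariance.
Identical samples map to identical coordinates; a matrix with no genotypic
variation raises an error rather than returning noise axes.

## LD estimation

Phased input is counted directly; unphased genotypes go through the
two-locus EM, initialized at linkage equilibrium (deterministic, interior)
and iterated to a 10⁻¹⁰ frequency tolerance. Only the double-heterozygote
class is phase-ambiguous, so with none present EM reduces to gamete
counting. Note the irreducible limit of genotype-based estimation: the
realized coupling/repulsion split of double heterozygotes is random, so for
an individual pair the EM and phased estimates of r² legitimately differ
(mean |Δr²| ≈ 0.01 at 200 haplotypes, occasionally up to ~0.08); agreement
is therefore assessed on averages. Batch paths call the EM with a raised
iteration cap (50 000) because boundary MLEs (one haplotype class absent)
converge sublinearly.

Every reported r² is also sample-size corrected, r²corr = (r² − 1/n)/(1 −
1/n), which removes the chance level of n sampled haplotypes; negative
corrected values are retained, not clipped, so binned means stay unbiased.
D' is computed from raw frequencies (the correction is defined only for
r²). Pairs with a marker missing in more than half the samples are skipped.

Decay summaries assign pairs to half-open [lo, hi) physical-distance bins
(default edges 0–0.01–0.02–0.04–0.06–0.08–0.1–0.2–0.5–1–2–5–10–20 Mb) and
report per-bin unweighted mean ± SD of corrected r² plus counts, per
chromosome and pooled. The adjacent-pair statistic uses consecutive
post-QC markers, both unrestricted and restricted to ≤ 10 kb (both readings
of "adjacent SNPs at distances up to 10 kb" are emitted). The distance at
which mean r² crosses a threshold is linearly interpolated between the
midpoints of the bracketing bins.

## Persistence of LD phase

Signed r is tabulated per population for all intra-chromosomal pairs within
100 kb; pairs are matched across populations by marker-id identity, which
restricts the comparison to markers segregating and QC-surviving in both.
Within each 10-kb bin (width configurable) the Pearson correlation of the
matched signed-r vectors is computed with the bin's own means and SDs; bins
with fewer than two shared pairs or zero variance report NaN rather than a
number. Formulas for this quantity are often typeset ambiguously in the
literature; what is implemented is the standard Pearson correlation of the
matched signed-r vectors.

## Haplotype blocks

Pair classification follows the confidence-interval block definition: the
likelihood of the (expected) haplotype counts is evaluated on a D' grid
(step 0.001, allele frequencies fixed at observed values, D oriented to the
observed sign), and the 5th/95th percentiles of the normalized likelihood
mass give the one-sided bounds. Strong LD requires upper ≥ 0.98 and lower
≥ 0.7; strong recombination is upper < 0.9; the remainder is uninformative.
A candidate block is a marker span (within a 500-kb search window) whose
outermost pair is in strong LD and in which ≥ 95% of informative pairs are
in strong LD; candidates are accepted greedily by decreasing physical
length, ties to the leftmost, without overlap. Two-marker blocks are
allowed (minimum one informative pair). The recombination bound, fraction,
and window come from the reference block definition's defaults and are all
exposed in `BlockConfig`. Summaries report per-chromosome block counts,
block length (kb), percent of the chromosome span (first to last post-QC
marker) covered, and percent of SNPs inside blocks.

## Runs of homozygosity

The scan mirrors the standard sliding-window tools with the published flag
values: 20-SNP windows tolerate ≤ 1 heterozygous and ≤ 5 missing calls; a
SNP is run-eligible when ≥ 5% of the windows covering it pass; runs split
at inter-SNP gaps > 1000 kb; accepted segments must satisfy the minimum SNP
count, minimum length 10 kb and density ≥ 1 SNP / 1000 kb.

One refinement proved necessary. Because a single passing window suffices
for eligibility, eligible runs extend a few SNPs into heterozygote-bearing
flanks, so filtering whole runs on "≤ 1 internal heterozygote" would
discard true segments wholesale. Instead, within each eligible run the
maximal sub-segments containing at most the window heterozygote allowance
are enumerated (two-pointer over heterozygote positions), trimmed to
homozygous endpoints, and accepted greedily longest-first without overlap.
This keeps a 60-SNP homozygous stretch containing one heterozygote as a
single segment, breaks it when three are spread through it, and is
invariant to sample and chromosome processing order.

The minimum SNP count comes from the false-positive calculation
l = ⌈ln(α/(nₛ·nᵢ))/ln(1 − h̄)⌉ with α = 0.05 and h̄ the post-QC mean
observed heterozygosity (the pipeline wires this in automatically when
`min_snp_count` is left at 0). Two length floors coexist deliberately: the
scanner applies the 10-kb flag as printed, while F_ROH and the length
classes apply the ≥ 1 Mb autozygosity floor (`min_segment_mb`),
reconciling the "10 kb flag" and "ROH are > 1 Mb" conventions explicitly.
F_ROH divides summed segment length by the total autosomal length (marker
span per chromosome); length classes default to [1,5), [5,10), [10,15),
[15,20), ≥ 20 Mb (both the 15 and 20 Mb boundaries are kept).

The GRM-family estimators use within-population allele frequencies, skip
fixed loci and ignore missing calls per individual:
Fhat1 = mean[(x−2p)²/(2p(1−p))] − 1, Fhat2 = 1 − Σx(2−x)/Σ2p(1−p),
Fhat3 = mean[(x² − (1+2p)x + 2p²)/(2p(1−p))]. Fhat2 is exactly 1 for an
all-homozygous individual; all three average ~0 under random mating.

## Effective population size

The drift–recombination equilibrium expectation E[r²] = 1/(4cNe + 1) is
inverted per distance bin: Ne = (1/r²adj − α)/(4c) at t = 1/(2c)
generations, with c the bin-representative recombination distance in
Morgans (arithmetic midpoint by default; harmonic mean available), physical
distance converted at 1 Mb = 1 cM (configurable). α defaults to 1, the
plain no-mutation inversion; 2.2 is available as the common mutation-aware
alternative. Bin edges follow the cM ladder <0.01 up to 10–20 cM. Bins
with no pairs, undefined r², or non-positive Ne are dropped with a log
notice. The inversion is algebraically exact: composing it with the
expectation recovers Ne to machine precision.

## Synthetic data generator

A discrete-generation Wright–Fisher forward simulator of 2·Ne haplotypes:
each offspring gamete is a recombinant mosaic of one random parent's two
haplotypes, with switch probability between adjacent markers equal to the
map-implied recombination fraction (capped at 0.5) and free recombination
across chromosome boundaries; mating is random with selfing allowed.
Initial haplotypes are drawn site-wise at linkage equilibrium with allele
frequencies uniform on [0.05, 0.95]. Default geometry emulates a
medium-density ovine array study: 26 autosomes of 95 Mb, 58 kb output
marker spacing, 1 cM/Mb, 45 diploids sampled, burn-in 6·Ne generations.
Everything is a pure function of (config, seed).

Without mutation, drift fixes a large share of loci during burn-in. The
generator therefore simulates an `ascertainment_factor` (default 8) times
denser candidate grid and, after sampling, keeps loci at or above the
output MAF floor (default 0.05) thinned evenly back to the requested
spacing — the same ascertainment-for-common-SNPs that array design applies
to real genomes. Population splits copy the ancestral population after
burn-in, evolve the copies independently, and apply the MAF floor jointly
so both outputs share one marker map and orientation; a divergence of zero
returns disjoint samples of the same generation.

Autozygosity injection places non-overlapping exponentially distributed
tracts (mean 5 Mb by default) uniformly over the autosomal marker span
until the target fraction φ is covered, truncating the final tract so the
realized coverage matches φ up to marker discreteness; within a tract each
heterozygous call becomes homozygous for a random one of its two alleles.
The QC-violation planter writes each defect so it is removed at exactly one
cascade step (a single heterozygote for MAF ≈ 1/2n; > 5% missing among
surviving samples for call rate; an all-homozygote half/half split for
HWE; chromosome relabels to 0/27; 15% missingness for flagged samples,
spread over untouched markers only) and returns the truth record.

What the generator does *not* emulate: mutation (polymorphism is standing
variation only), variable recombination maps, genotyping error, selection,
and family structure. Consequently, passing tests demonstrate that the
estimators recover the parameters of this idealized neutral model — not
that real data are free of the corresponding artefacts.

## Validation conditions and problem sizes

* **Ne recovery**: Ne = 100, 20 × 5 Mb chromosomes at 1 cM/Mb, 100 diploids
  sampled, burn-in 400 (= 4·Ne) generations — long enough for LD at
  0.5–5 cM to equilibrate while most loci still segregate — averaged over
  10 seeds; measured bin means 93–98 against a truth of 100. Bins below
  0.5 cM are expected to be biased (unequilibrated LD plus
  segregation-conditioning) and are not part of the check.
* **F_ROH recovery**: 50 samples × ~42.6k markers at 58 kb (array scale),
  injected φ ∈ {0.05, 0.10, 0.25} with 5 Mb mean tracts; recovered means
  within ±0.005; HWE null data yield mean F_ROH = 0 with the Eq-style
  minimum SNP count in force.
* **Phase persistence**: Ne = 100 splits at divergence 0 / Ne / 4·Ne
  generations on ten 1-Mb chromosomes at 5 kb spacing with the map
  compressed to 25 cM/Mb. The compression puts the 0–100 kb window in the
  informative LD range (the statistic depends only on Ne·c, so this stands
  in for a large-Ne population at 1 cM/Mb that would be infeasible to
  burn in at desk scale). Replicates are pooled per level; the
  well-populated short-range bins decline monotonically with both distance
  and divergence time.
* **Estimator calibration**: 200 diploids × 3000 loci at HWE; all three
  Fhat means within ±0.02 of zero.

## Known limitations

* Unphased LD at array scale is O(pairs × EM) and intended for the
  distances the analyses need (≤ 20 Mb decay, ≤ 500 kb blocks, ≤ 100 kb
  phase); genome-wide all-pairs EM on 50k markers is not the target use.
* The D' confidence grid holds allele frequencies at their observed values
  (profile rather than joint likelihood), like the reference
  implementation.
* The exact HWE p-value uses a tie tolerance of one part in 10¹² when
  summing outcomes "no more likely than observed"; this matters only for
  exactly tied probabilities.
* Binary PLINK (BED/BIM/FAM) and VCF input, ancestry/admixture estimation,
  statistical phasing, ROH islands and pedigree inbreeding are out of
  scope.
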