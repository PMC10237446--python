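# snppop

SNP-array population genomics in Python: the complete analysis chain used in
livestock diversity studies — quality control, heterozygosity, PCA, linkage
disequilibrium (LD) decay, persistence of LD phase between populations,
haplotype blocks, runs of homozygosity (ROH), four genomic inbreeding
estimators, and LD-based effective population size — together with a
Wright–Fisher synthetic-genotype generator that provides ground truth for
every stage.

It is written for geneticists working with medium-density array data
(e.g. ovine 50K chips: ~26 autosomes, ~40–50k SNPs, tens of samples per
population) who want a scriptable, tested, single-package replacement for a
chain of PLINK / Haploview / GCTA / SNeP invocations.

## The statistics at the core

For two biallelic loci with allele frequencies $p_A, p_a, p_B, p_b$ and
haplotype frequencies $f_{AB}, f_{Ab}, f_{aB}, f_{ab}$:

* **LD**: $D = f_{AB}f_{ab} - f_{Ab}f_{aB}$,
  $r = D / \sqrt{p_A p_a p_B p_b}$, and $D' = |D| / D_{\max}$.
  Unphased genotypes go through the standard two-locus EM over
  double-heterozygote ambiguity; phased input is counted directly.
  Every reported $r^2$ is adjusted for chance at sample size $n$ haplotypes:
  $r^2_{\text{corr}} = (r^2 - 1/n)/(1 - 1/n)$.
* **Persistence of phase** between populations $k, k'$: the Pearson
  correlation $R_{kk'}$ of signed $r$ over shared marker pairs within
  distance bins (0–100 kb), under one shared allele orientation.
* **Haplotype blocks**: confidence-interval classification of pairs on
  $D'$ (strong LD: one-sided 95% bounds $\ge 0.98$ / $\ge 0.7$), block =
  run of markers whose outermost pair is in strong LD and $\ge 95\%$ of
  informative pairs are in strong LD.
* **ROH**: PLINK-style sliding-window scan (20-SNP windows, $\le 1$
  heterozygote), with the false-positive-calibrated minimum SNP count
  $l = \lceil \ln(\alpha / (n_s n_i)) / \ln(1 - \overline{het}) \rceil$, and
  $F_{ROH} = L_{ROH}/L_{AUTO}$.
* **Inbreeding**: $\hat F_1$ (GRM diagonal), $\hat F_2$ (excess
  homozygosity), $\hat F_3$ (uniting-gamete correlation).
* **Effective population size**: $E[r^2] = 1/(4 c N_e + 1)$ inverted per
  distance bin, $N_e = (1/r^2_{\text{adj}} - \alpha)/(4c)$ at
  $t = 1/(2c)$ generations ago, with 1 Mb = 1 cM by default.

## Worked example

Simulate two populations that split 20 generations ago, run the whole
pipeline, and read the digest:

```bash
snppop simulate --out-prefix demo/two --ne 60 --chromosomes 3 \
    --chrom-length-mb 2 --spacing-kb 50 --sample-size 20 \
    --generations 120 --split-generations 20 --seed 77
snppop run-all --ped demo/two.ped --map demo/two.map --out-dir demo/out --seed 77
snppop summarize demo/out
```

which prints (numbers from this exact invocation):

```
# snppop summary — demo/out

## popA
- mean adjacent-SNP r² (≤10 kb): nan
- pairs ≤10 kb with r² > 0.3: nan%
- haplotype blocks: 15
- mean F_ROH: 0.4319
- Ne at t=33 generations: 33

## popB
- mean adjacent-SNP r² (≤10 kb): nan
- pairs ≤10 kb with r² > 0.3: nan%
- haplotype blocks: 15
- mean F_ROH: 0.2425
- Ne at t=33 generations: 54

- phase persistence popA-popB, 10-20 kb: R = 0.995
```

Reading it: at 50 kb marker spacing no pairs fall inside 10 kb, so the
short-range statistics are undefined (`nan`); a tiny population (Ne = 60)
builds strong LD, hence many haplotype blocks and substantial genuine
autozygosity (mean F_ROH 0.24–0.43 — over 120 generations at this size the
expected inbreeding relative to the founders is 1 − (1 − 1/2Ne)^120 ≈ 0.63);
the most recent usable LD bin gives Ne estimates of the right order for the
simulated size; and two populations split only 20 generations ago still
share gametic phase almost perfectly (R = 0.995 at short range). Each
number is a cell of a TSV in `demo/out/`.

The same stages are available as library calls (`snppop.run_qc`,
`snppop.ld_decay`, `snppop.find_blocks`, `snppop.detect_roh`,
`snppop.ne_trajectory`, ...) on a `GenotypeMatrix`/`HaplotypeMatrix` read
from PED/MAP and optional phased-haplotype tables.

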