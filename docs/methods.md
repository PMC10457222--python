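# Methods

This note documents the models, the estimators, the synthetic-data
generator, and the numerical and design choices behind `introscan`. All
empirical statements here are computed by the test suite or by
`scripts/acceptance.py`.

## Data model

Genotypes are diploid alt-allele dosages in {0, 1, 2} with an explicit
missing sentinel; nothing is imputed at I/O time, because each statistic
defines its own missing-data handling (complete-case per site throughout).
Coordinates are 1-based and closed, matching VCF. Genetic positions come
from a 3-column (chrom, bp, cM) map with linear interpolation between
anchors and constant-rate extrapolation beyond them; with no map, a uniform
1 cM/Mb is assumed so the pipeline stays self-contained. PLINK .ped/.map
text carries no REF designation, so on read the lexicographically smaller
observed allele is taken as REF; round-trip identity therefore holds for
sites where both alleles are observed.

QC semantics: "at least 10% missing" removes the boundary case (rate ≥
0.10); MAF removal is strict (< 0.05); LD pruning retains only pairs with
r² strictly below the threshold, using greedy windowed removal (50 SNPs,
step 5 — window sizes are our choice; array practice varies and the
original pruning windowing is not specified).

## f3-admixture screen

The per-site term is (c − a)(c − b) − c(1 − c)/(n_c − 1), where a, b, c are
sample alt-frequencies of the two sources and the target and n_c is the
target's non-missing allele-copy count; the subtraction removes the bias
from finite target sample size. For a single-individual target n_c = 2 and
the correction is c(1 − c). f3 is the unweighted mean over usable sites;
the standard error comes from a weighted delete-one-block jackknife over
contiguous 5 cM blocks (block weights = SNP counts; the Busing et al.
delete-m formulas standard in three-population tests), which absorbs
linkage disequilibrium. Admixture is called at
f3 < 0 and Z < −3.

The screen tests every pool animal against each domestic breed separately
(three triads per animal) and flags on any significant triad, mirroring the
practice of testing breeds individually; pooling the breeds into one source
dilutes the contrast, because the pooled frequency averages three
independent drift realizations. With ~3 × 100 tests per study at |Z| > 3,
roughly 0.1–0.4 spurious flags per run are expected by chance, and single
runs do show an occasional borderline false flag; the acceptance script
reports false flags against simulator truth for transparency.

Power at this threshold is governed by genome length more than by SNP
count: for a mosaic individual the block jackknife correctly charges the
tract-scale variance, so a 2-Morgan toy genome cannot separate m ≈ 0.1
hybrids from noise, while the panel-scale study (18 chromosomes, ~22
Morgans, ~54K SNPs) flags most hybrids with m ≥ 0.10.

## Local ancestry HMM

Each phased hybrid haplotype is a 2-state chain (wild/domestic) along
genetic distance. Initial distribution (1 − m, m); between adjacent SNPs
separated by d Morgans the chain redraws its state from the prior with
probability 1 − exp(−g·d); emissions are Bernoulli in the source panels'
allele frequencies, smoothed by one pseudo-count per allele
(f → (count + 1)/(n + 2)) so fixed panel sites never yield zero
likelihoods. Posteriors come from the scaled forward–backward recursion
(vectorized across haplotypes; numerically stable for arbitrarily long
chromosomes) and are exact for this model — verified against brute-force
path enumeration on ≤ 12-site instances to 1e−10.

The original analysis used a two-layer cluster-based EM tool for this step;
that tool's internals are not reproducible from its description, so the
transparent HMM above replaces it while preserving the salient parameters:
g = 20 generations, the pooled three-breed domestic source, the 0.9
assignment threshold with an explicit "unassigned" label, and two
known-pure control animals run alongside the hybrids (their domestic
proportion, expected ≈ 0, is a run-quality metric). The cluster tool
averages 10 stochastic runs; the HMM is deterministic, so no averaging is
needed — an intentional difference. Thresholded calls, not raw posteriors,
feed all downstream summaries; unassigned sites are excluded from
denominators. Tract extraction merges runs of identical calls, absorbing
interior unassigned sites flanked by the same call.

Dating: domestic tract lengths under this chain are approximately
exponential with rate g(1 − m) per Morgan, giving
ĝ = 1/(mean domestic tract length × (1 − m)). Call-based tracts merge
across short missed segments of the opposite ancestry, which biases ĝ
downward slightly; truth-tract recovery on the default scenario stays
within 30% of the simulated g = 20. The companion conversion uses a 5-year
generation time, so g = 20 dates the admixture to ~100 years.

## Enrichment windows

Per site, the domestic fraction is (# haplotypes called domestic)/(all
hybrid haplotypes) — unassigned haplotypes count in the denominator, a
conservative choice for enrichment claims. Windows are maximal runs of ≥ 2
consecutive SNPs with fraction ≥ p, with no gap tolerance; with 6 hybrid
haplotypes the reported thresholds p0.67 and p0.83 can only be realized as
≥ 4/6 and ≥ 5/6. Every p0.83 window is nested in a p0.67 window by
construction.

Under the tract model the no-sweep count of p0.67 windows per genome is
governed by excursions of the 6-chain process, approximately
L × C(6,3) m³(1−m)³ × 3 g m per genome of L Morgans (≈ 2 for the default
scenario at m = 0.2) — noise windows are expected and are much shorter than
a planted 10 Mb region, which is recovered as a single covering window.

## Selection scans

**PBS.** Per-site Weir–Cockerham (1984) two-population FST (variance
components from genotypes, including observed heterozygosity), transformed
as T = −log(1 − FST) after clamping FST to [0, 1 − 1e−8]: negative per-site
estimates would give negative branch lengths and FST = 1 an infinite
branch. PBS = (T_AB + T_AC − T_BC)/2 for target A (hybrids), pure wild B,
reference wild C. The cutoff is the linear-interpolation 95th-percentile
quantile of defined PBS values; candidacy is strict (>); windows need ≥ 5
consecutive candidate SNPs. On LD-free simulated data per-site PBS is
nearly independent across sites, so null windows are rare and a sweep
region shows elevated but fragmented per-site values; window-level sweep
recovery is carried by XP-EHH, which integrates along the haplotype.

**Randomization null.** The published protocol for the randomization sets
is in unavailable supplementary text; the implemented scheme serves its
stated purpose (is a window just an artifact of a 3-animal target?): each
replicate draws n_target animals from the pure pool as a pseudo-target and
re-runs the full window scan against (pool minus draw, reference). For each
real window the recurrence is the fraction of replicates producing an
overlapping window; recurrence > 0.2 (configurable, a convention not a
claim) flags the window unreliable. Hybrid-specific windows have ≈ 0
recurrence; windows driven by loci where the pool as a whole is strongly
diverged from the reference recur for any draw and are flagged.

**XP-EHH.** Population-level EHH from each core marker: the probability
that two random haplotypes are identical from the core out to a marker,
extended outward until EHH < 0.05 (that crossing point is included in the
integral) or the chromosome ends; iHH is the trapezoid integral over cM,
both sides summed. Per site, raw = ln(iHH_A/iHH_B) with A = domestic pool
(positive ⇒ selection in A); sites with either iHH = 0 are dropped; scores
are standardized genome-wide. The window rule — standardized score at or
above the 95th percentile, candidate markers merged within 500 kb — is this
package's own configurable convention; the original window rule is in
unavailable supplementary text.

## Synthetic-data generator

Per-site ancestral frequencies are Beta(2, 2) — a mildly ascertained
spectrum emulating array content, where rare variants are depleted relative
to a neutral site-frequency spectrum. Population frequencies follow
Balding–Nichols: Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral p.
Under this model the pairwise Weir–Cockerham FST between two populations
with per-branch drift F is ≈ F (Monte-Carlo-verified in the tests), so the
default F = 0.18 per branch realizes the intended wild-vs-domestic FST
≈ 0.2; the outgroup uses F = 0.35. Sampled genotypes are Hardy–Weinberg
draws from the population frequencies, phased by construction.

Hybrid haplotypes follow the same Markov switch process the HMM assumes
(two-state in genetic distance, redraw rate g, prior m), with m drawn per
individual from U[0.10, 0.27] — the observed range of global domestic
proportions — and g = 20. Tract alleles are drawn Bernoulli from the
active source's frequencies; each domestic tract picks one breed uniformly
and keeps it for the tract. Modelling sources at the frequency level keeps
hybrids exchangeable with panel animals of the same ancestry — copying
literal panel haplotypes would make targets partial clones of the f3
source panel and distort the finite-sample correction — and makes LA
parameter recovery a clean closed loop. What this deliberately does not
emulate: linkage disequilibrium within the source populations, array
ascertainment against the outgroup, genotyping error and missingness, and
haplotype sharing between hybrids and specific panel animals outside sweep
regions. Passing recovery tests therefore demonstrate correctness of the
estimators under their own model assumptions, not robustness to every
property of real array data.

Planted sweeps replace all domestic-breed haplotypes in a region with one
core haplotype, mutated at 5e−5 per site — low enough that EHH from a
central core stays > 0.9 across a 10 Mb region — and force every hybrid
haplotype to carry the swept haplotype there (truth updated accordingly).

Default study sizes: the unit/default scenario uses 2 chromosomes × 5,000
SNPs × 100 Mb (2 Morgans) with 30 + 3 target animals — small enough for
fast recovery tests of local ancestry, windows and sweeps; the panel-scale
scenario mirrors the real design (18 autosomes × 3,000 SNPs × 125 Mb,
93 + 3 target animals, 19 reference, 3 × 10 breeds, 11 outgroup) and is
used wherever per-individual f3 power matters. Replicate-based checks run
on single-chromosome scaled-down studies; all sizes are package choices
made to keep each stage's statistical behaviour in its operating regime.

## Determinism

Every stochastic component takes an explicit seed or Generator;
`emit_study` is byte-reproducible, and the pipeline derives per-stage seeds
from one root seed via `SeedSequence`, so identical config + seed gives a
byte-identical summary.

## Known limitations

- Two ancestries only; a third (e.g. Asian) source is neither modelled nor
  distinguishable, matching the scope of the screen.
- Phased input is assumed (the simulator emits phased VCF); no phasing or
  unphased-genotype HMM is provided.
- The f3 screen's per-individual power is limited at m ≈ 0.10 on short
  genomes; prevalence estimates at panel scale carry occasional borderline
  false flags at |Z| ≈ 3.
- PBS window calling on LD-free data is conservative (see above); real
  array data with LD will produce longer candidate runs and more null
  windows, which is exactly what the randomization check is for.
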