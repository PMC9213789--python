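# Methods

This note records the model, the numerical choices, the desk-scale design,
and the known limitations of `nucleusgs`. It states how quantities are
computed; every empirical number it mentions is produced by the test suite
or by `scripts/acceptance.py` at run time.

## Population model

**Historical phase.** A neutral diploid Wright–Fisher population with
discrete generations and random mating (distinct parents per offspring; no
mutation, selection or migration). All loci start at allele frequency 0.5.
The census follows a schedule of phases with linear size interpolation —
full scale: 1,000 generations at 3,000, decline to 400 over 20 generations,
then a single random-mating expansion to 2,050 founders (50 males). The
bottleneck is what generates the marker–QTL linkage disequilibrium genomic
prediction needs. Because drift fixes loci, the locus grid is oversampled
(default 1.5×) and, at the end, the configured number of still-segregating
loci closest to the ideal even grid is retained per chromosome; a shortfall
raises a diagnostic naming the segregating count. The decline length
("gradually reduced") and the oversampling multiplier are config-exposed;
no mutation model is simulated, so standing variation is the only source of
polymorphism.

**Meiosis.** Haldane model: per chromosome, crossover count ~
Poisson(genetic length in Morgans), positions uniform, no interference,
independent assortment across chromosomes. Implemented as a vectorised
batch over all gametes of a generation (the 12,000-offspring full-scale
generation takes a few seconds). Haplotypes are held as plain `uint8`
arrays rather than bit-packed words: at the scales this package targets the
memory cost is modest and it keeps dosage, TBV and genotype-export code a
direct array expression.

**Trait.** Purely additive. Raw QTL effects are gamma(0.4, 1.66) magnitudes
with equiprobable sign (zero-mean architecture); calibration rescales them
once so the founder TBV variance equals the target h² on unit phenotypic
variance, sets `residual_sd = sqrt(1 − h²)`, and centres TBV at the founder
mean. Calibration is idempotent and invariant to common rescaling of the
raw effects. Phenotypes `P = TBV + e` are generated for every animal at
birth but only become *visible* to an analysis when recorded — recording
schemes pick `(n_males, n_females)` per litter, and study designs may
reveal additional reference phenotypes. This latent-plus-visibility design
lets one simulated population serve many designs without re-simulation
while candidate phenotypes remain strictly hidden (asserted in tests).

**Herd.** Discrete generations. Sows are shuffled into mating groups of
`sows_per_boar` per boar; each sow produces one litter of fixed size and
sex count. A random `raising_rate` fraction of each litter enters the
selection pool. Replacements are truncation-selected on pedigree-BLUP EBVs
fitted to all phenotypes recorded so far (shrinkage ratio from the base
trait values); with no records the criterion falls back to the seeded
random draw used at herd founding. Ties break by seeded jitter. Boar
replacement 100%, sow replacement 40% per generation.

## Evaluation engine

* **A machinery.** Meuwissen–Luo inbreeding (full sibs share F, exploited
  via a parent-pair cache), Henderson's sparse A⁻¹ with inbreeding, the
  tabular A for small pedigrees (the oracle), and matrix-free `A @ X`
  products through `A = T D T'` (Colleau), from which A22 blocks are cut
  without forming A. The indirect routes are tested to agree with the
  tabular matrix to 1e-9.
* **G.** VanRaden method 1 with allele frequencies from the genotyped set;
  monomorphic markers contribute nothing. Before entering H, G is rescaled
  onto the pedigree base with the two-parameter adjustment (`a + b·G`
  matching A22's mean diagonal and overall mean). Without this, the many
  generations separating the pedigree base from the genotyped animals put
  G and A22 on incompatible scales and single-step predictions degrade
  badly; the adjustment is standard single-step practice and is what the
  study's evaluation software applies by default. `Gw = 0.95·G_tuned +
  0.05·A22` guarantees invertibility (both knobs config-exposed).
* **H⁻¹.** `A⁻¹ + [0 0; 0 Gw⁻¹ − A22⁻¹]`, held as sparse-plus-dense-block
  and applied matrix-free; verified against dense inversion of the
  assembled H on small cases.
* **MME.** `[X'X X'Z; Z'X Z'Z + λK⁻¹][b; g] = [X'y; Z'y]` with the overall
  mean as the only fixed effect (the simulator generates no systematic
  environment). Systems up to 3,000 equations are solved densely; larger
  ones by Jacobi-preconditioned conjugate gradients (relative tolerance
  1e-8), which handles the 48,000-animal desk-scale pedigree with a dense
  genotyped block in seconds.
* **REML.** Average-information updates on (σ²ₐ, σ²ₑ) after a one-off
  eigendecomposition of the relationship among the phenotyped animals
  (every iteration is then O(n)); EM fallback if the AI matrix is singular;
  when an update would leave the parameter space the offending variance is
  pinned at a floor (1e-8 of the phenotypic variance) and a reduced Newton
  step is taken in the free component — a pinned variance with an inward-
  pointing score is reported as a boundary solution. Convergence: relative
  change < 1e-8, at most 100 iterations. Following the study protocol, the
  random per-litter phenotyping draw is repeated three times independently
  and the three estimates are averaged. REML sets are capped at 3,000
  records (random subsample) — at desk scale only the largest reference
  designs reach the cap. Smaller caps were found to bias σ²ₐ upward under
  selection (trend leakage), which is why the cap sits above the usual set
  sizes.
* **Metrics.** Accuracy is the Pearson correlation of TBV with (G)EBV over
  the candidate set, overall and per sex. Intensity is `φ(z)/p` for
  truncation fraction p. Gain per generation averages the sire and dam
  pathways: `ΔG = σ_A(i_♂ r_♂ + i_♀ r_♀)/2 · 1/L` with L = 1, σ_A from the
  scenario's REML, and p_♂ = 38/4800, p_♀ = 200/4800 (the selected
  fractions of the full-scale design; fractions, not counts, are held fixed
  across scales).

## Study designs

**Reference study** (20 generations, phenotype recording 1M+1F per litter
per generation except the last): reference populations are built per
litter — case 1: k males + k females per generation-19 litter
(k = proportion/20); case 2: 1M+1F from a single generation g; case 3:
1M+1F from every generation of a window ending at 19; case 4 is the
equal-size comparison between cases 1 and 3. Candidates are always 1M+1F
per generation-20 litter, genotyped and never phenotyped. Each design's
fit trains on the reference population's own phenotype records (per-group
protocol): the reference-size and generation-gap contrasts are then what
the accuracy responds to. A cumulative-records variant (all recorded
generations in every fit) was evaluated and rejected: it blunts the design
contrasts and, when subsampled, inflates σ²ₐ through the genetic trend.
Per-litter reference draws favour already-recorded animals so the small
designs coincide with the records that drove selection.

**Candidate study** (5 generations, recording 1M+2F per litter, generations
1–4): the genomic reference is 1M+1F per litter of generations 1–4 (a
subset of the recorded animals); generation-5 litters are genotyped under
the ratio × sex-split schemes (20%: 2:0/1:1/0:2; 30%: 3:0/2:1/1:1/1:2/0:3;
50%: 5:0/4:1/3:2/1:1/2:3/1:4/0:5 — the 50% "1:1" alternates 3:2 and 2:3
litters so the population-level ratio is 1:1, and the duplicated "4:1" in
the 50% series is read as 1:4 by symmetry). Fits use all recorded
phenotypes. Pathway accuracies use the genotyped candidates of each sex;
if a scheme genotypes no animals of one sex, that pathway's accuracy is
computed over all raised generation-5 animals of the sex (they carry
pedigree-only GEBVs through H), reproducing the penalty of leaving a sex
ungenotyped. The pedigree-BLUP baseline (no genotypes, same records, same
variance components, same population) provides the paired gain comparison.

## Desk-scale preset

Accuracy in this setting is governed by the reference size N, h², the
effective number of independent genome segments Mₑ (≈ 2NₑLC/ln(4NₑL)), and
the half-sib family structure that ties reference and candidates together,
so the scaled presets preserve, in order of importance: the 1:40 boar:sow
mating ratio (40-litter sire families — shrinking these was observed to
cost far more accuracy than shrinking the census), the ratio N/Mₑ, and the
herd's drift trajectory. Concretely:

* **reference study** — 12 boars × 480 sows (sow herd at 2/5; 12 sires keep
  inbreeding tolerable over 20 generations), genome 14 chromosomes × 300
  SNPs with the bottleneck at Nₑ = 160 over 8 generations (Mₑ at 2/5 of
  full scale, same cumulative drift t/N through the neck), founders 820
  (30 male);
* **candidate study** — 6 boars × 240 sows (1/5; six-sire drift is
  immaterial over four selection rounds), bottleneck Nₑ = 80 over 4
  generations (Mₑ at 1/5), founders 410 (30 male).

Reference sizes run 960–4,800 (case 1) and 1,920 (candidate study) against
candidate sets of 960 and 480–1,200 respectively.

What the desk scale reproduces well: the *relative* design effects —
accuracy rising with reference size, falling with generation gap, the
cumulative-reference optimum, scheme and sex-ratio contrasts, and the
ssGBLUP-over-BLUP margin. What it reproduces only approximately: absolute
accuracy levels (sampling noise is larger at 1/5 size, and with a
leptokurtic QTL architecture 19 generations of truncation selection erode
realised additive variance noticeably, which depresses late-generation
reference accuracies relative to a variance-retaining population). Single
replicates are noisy; the suite and the acceptance script use replicate
means and, for the design sweeps, correlate the replicate-mean accuracy
profile (the study's own curves are means over its runs). The acceptance
script's replicate counts (3 reference-study seeds, 4 candidate-study
seeds per heritability) and the test suite's (2–3) are the package's
problem-size choices.

Passing tests at desk scale show the machinery and the design contrasts are
right; they do not certify absolute accuracy values for a real 50K-chip
pig program, which depend on real LD, real family structure and real
recording schemes.

## Known limitations

* No mutation, overlapping generations, litter-size variation, dominance or
  epistasis; sex chromosomes are not simulated.
* One trait, one overall mean; no systematic environmental effects, no
  multi-trait indices.
* The historical phase starts from frequency 0.5 at every locus rather than
  a mutation–drift equilibrium; the oversample-and-subset step reproduces a
  plausible post-bottleneck MAF spectrum but not a calibrated one.
* H⁻¹ is exact (no APY or other large-n approximations); practical up to a
  few thousand genotyped animals.
* Selection on pedigree EBVs only within the simulation (GEBV-based
  within-herd selection is not simulated; the candidate study scores
  schemes by expected, not realised, gain).
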