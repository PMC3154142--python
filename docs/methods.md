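# Methods

## The screen and its assumptions

The pipeline identifies imprinted differentially methylated regions (DMRs)
by exploiting the unbalanced parental genome dosage of triploid placentas.
Its model: a CpG's methylation fraction (beta) is the average methylation
of the haploid genomes present. With a methylated-allele level `m1`, an
unmethylated level `m0`, and `n_mat`/`n_pat` maternal/paternal genome
copies, a maternally methylated locus has

    beta = f * (n_mat*m1 + n_pat*m0) / (n_mat + n_pat) + (1 - f) * (m1 + m0)/2

where `f` ("fidelity") is the fraction of cells actually carrying the
imprint; `1 - f` of cells are assumed to sit at the biparental midpoint,
which is how incomplete CpG methylation on the silenced allele or a mixture
of imprinted and non-imprinted cell types attenuates the signal. With
`m1 = 1, m0 = 0, f = 1` this gives the canonical values 1/3 (diandric,
1+2), 2/3 (digynic, 2+1), 1/2 (biparental) and 0 (androgenetic mole, 0+2);
paternally methylated loci mirror the roles of m1 and m0. The screen
assumes the array's beta values are approximately linear in true
methylation; the magnitude threshold (below) absorbs moderate
non-linearity.

Stages, in order:

1. **Detection filter.** A probe is removed if its detection p-value
   exceeds `detection_alpha` (default 0.05) in *any* sample. Strict
   all-sample filtering discards an entire probe rather than imputing.
2. **Permutation screen.** Two-class moderated statistic between diandric
   and digynic groups (below), q-value per probe, candidates at
   `q <= fdr_target` (default 0.001) **and** `|delta beta| > delta_threshold`
   (default 0.15, strict). 0.15 is deliberately below the theoretical 1/3
   because fidelity < 1 and array compression shrink real differences.
3. **Origin designation.** Higher methylation in diandries = paternally
   methylated locus; higher in digynies = maternal. Candidates always
   differ (the magnitude threshold is strict), so ties cannot arise.
4. **Consistency filter.** A candidate is kept iff (a) the normal-placenta
   mean lies in the closed interval between the two triploid means and
   (b) the CHM mean is strictly closer to the diandric mean than to the
   digynic. Boundary readings: "between" inclusive, "closer" strict, a tie
   on (b) eliminates — the conservative reading. The failing clause is
   recorded (`normal_not_intermediate` / `chm_not_diandric_like`).
5. **DMR aggregation.** Retained loci group by (gene symbol, origin); a
   gene carrying both maternal and paternal loci therefore yields two DMRs.
   Probes without a gene symbol become singleton DMRs keyed by probe id.
   The DMR span is the min..max member-probe position (1 bp for a single
   array probe; the 27k-style array gives point measurements and no
   principled region boundary). CNV overlap is annotated from a
   user-supplied BED track, as a diagnostic only, never a filter.
6. **Classification.** Multiclass screen across the five-tissue panel
   (brain, kidney, muscle, midgestation placenta, maternal blood) flags
   tissue-differential probes; a probe is placenta-specific when the
   placenta mean exceeds the *maximum* other-tissue mean by more than
   `placenta_margin` (default 0.15), evaluated on raw group means;
   midgestation-vs-term two-class screen flags gestational change. DMR
   flags are any-member-probe aggregations (the only rule consistent with
   reporting more flagged probes than flagged DMRs), and
   `stable = not tissue_differential and not gestation_change`.

## The permutation statistic

Per probe, `d = r / (s + s0)`; two-class: `r` is the group-mean difference
and `s` the pooled two-sample standard error; multiclass: `r` is the
root of the size-weighted between-group sum of squares times
`sum(n_k)/prod(n_k)` and `s` pools the within-group variance times
`sum(1/n_k)` (for k = 2 this reduces exactly to |two-class d|). The fudge
factor `s0` damps probes whose tiny variance would otherwise dominate the
tails; it is chosen by coefficient-of-variation minimisation of the spread
of d across ~100 quantile windows of s, over candidate percentiles of s
(0, 5, ..., 100). On strongly standardised data the CV profile can be
monotone and select the 0th percentile — legitimate, it means d is already
scale-stable. A `fixed_percentile` mode exists for tiny probe sets where
the window statistics are unstable (and is used automatically below 40
probes).

Significance: sample labels are permuted uniformly (`n_permutations`,
default 1000, seeded); when the number of distinct labelings is smaller,
they are enumerated exhaustively. For a symmetric threshold `delta` on
|d|,

    FDR(delta) = pi0 * FP(delta) / #{|d_i| >= delta}

where `FP(delta)` summarises the per-permutation count of permuted
statistics exceeding `delta`, and `pi0` is the fraction of observed d
inside the permutation interquartile band divided by 0.5, capped at 1. A
probe's q-value is the smallest FDR at any threshold that calls it
(cumulative minimum over thresholds), making q monotone non-increasing in
|d|. Only symmetric thresholds are implemented; asymmetric delta pairs are
a known omission.

**False-positive summary.** `FP(delta)` is the **mean** exceedance count
over permutations (configurable to the median). The median variant
collapses to an estimated FDR of exactly zero whenever more than half of
the permutations show no exceedance — precisely the regime of the extreme
tail — and therefore awards q = 0 to the single largest null probe in a
large fraction of datasets. The mean stays strictly positive there and
restores calibration; in mixed simulations (5,000 null + 100 spiked
probes) it removes essentially all such false calls while leaving recovery
at 100/100.

**Calibration at the 0.1 % target.** The estimator is tight, so the
realized false-discovery proportion sits at, not far below, the nominal
level: across replicate mixed simulations the mean FDP fluctuates in the
0.05-0.15 % range around the 0.1 % target, driven by rare single
tail-exceedance events (probability ~0.1 per dataset of 5,000 null
probes). Group sizes also matter: at the 0.1 % target a multiclass design
needs groups large enough that a random permutation cannot reconstruct an
entire group too often (with three groups of four, that probability is
3/C(12,4) ≈ 0.6 %, flooring the estimate above the target); the tissue
panel's 8-12 samples per group are comfortably safe.

## The synthetic-data generator

`simulate_dataset` emulates the study design: by default 10 diandric, 10
digynic, 10 normal-placenta, 6 CHM, 10 maternal-blood, 8 brain, 12 kidney,
11 muscle, 10 midgestation- and 10 term-placenta samples. Probe classes:

- **background** (default 5,000): one expected value shared by all groups,
  drawn from a two-component logit-normal mixture centred near 0.10 and
  0.85 (weight 0.6 low, logit-sd 0.6) — promoter methylation is bimodal;
  the parameters are engineering choices, not measured values.
- **imprinted** (50 maternal + 50 paternal by default): expected values
  from the dosage model per group, so the diandry-digyny difference is
  ±1/3 at full fidelity and the consistency pattern holds by construction.
- **tissue-specific** (30): 0.6 in placental tissues, 0.3 elsewhere (a
  true placenta margin of 0.3).
- **gestation-drift** (20): 0.3 at midgestation, 0.6 at term.
- optional **divergent background**: independent expected values for
  placental vs somatic tissues, giving clustering tests a blood/placenta
  split to find.

Noise is logit-normal (sd 0.05 on the logit scale by default, ~0.012 on
the beta scale at mid-range), respecting the [0, 1] bounds and the
variance shrinkage near them; expected values are clipped to
[1e-3, 1 - 1e-3] before the transform. `noise_sd = 0` returns expected
values exactly. Detection p-values are drawn passing (< 0.05), with an
optional number of injected failures. What the generator does **not**
emulate: probe-type chemistry biases, beta-value compression/nonlinearity,
spatial/batch effects, CNV-driven artefacts, and realistic correlation
between neighbouring probes. Passing tests therefore demonstrate the
statistical machinery under the stated model, not robustness to array
artefacts.

## Numerical choices

- Beta validation tolerance 1e-9; values are clipped to [0, 1] after
  validation. TSV floats are written at full precision and parsed with
  round-trip float handling, so I/O is lossless.
- Correlations are pairwise-complete and require >= 3 shared observations;
  zero-variance profiles raise rather than return NaN.
- Clustering sorts samples lexicographically first, so equal-distance
  merges resolve deterministically by smallest member id; linkage is
  average by default (complete available).
- Welch's t-test is the census default (pooled-variance optional);
  zero-variance probes get p = 1 when group means agree, p = 0 otherwise.
- In the permutation screen, samples keep their matrix order so that
  swapping the two group roles is a bitwise sign flip; permuted statistics
  tying an observed threshold within relative 1e-10 count as exceedances,
  so mathematically exact ties (e.g. the identity relabelling) are not
  broken by floating-point noise; at a zero denominator, |r| < 1e-12 is
  treated as zero evidence (cancellation noise on degenerate constant
  input).
- Coordinates: annotation positions are 1-based; BED output is 0-based
  half-open; the conversions are exact inverses. BED scores are
  `round(1000 * mean |delta beta|)` — cosmetic, for browser shading.

## Problem sizes used in checks

Simulation-based tests run at 200 permutations with a few thousand probes
and a handful of seeds; the acceptance script uses the full study-scale
conditions (5,000 + 100 probes, 10 vs 10, 1,000 permutations, 20 seeds),
completing in about a minute on one CPU. These sizes were chosen as the
smallest at which the quantities of interest are stable.

## Real-data benchmark (download-gated)

The study's array data are deposited in the NCBI Gene Expression Omnibus
under accession **GSE25966**. The package never downloads: fetch the
series-matrix file manually, curate a CSV mapping GSM accessions to study
groups (the expected triploid design is 10 diandric / 10 digynic / 10
normal / 6 CHM / 10 blood; deviations produce a warning with the diff),
then

```python
from imprintscan.geo import prepare_gse25966
bm, sheet = prepare_gse25966("GSE25966_series_matrix.txt.gz", "groups.csv")
```

yields pipeline inputs with probe order preserved. Because the exact SAM
settings behind the published counts (s0 selection, FDR summary) are not
recoverable, reproduced probe counts should be compared with a tolerance
of a few probes.

## Known limitations

- No paired, survival or time-course variants of the permutation screen;
  no asymmetric delta thresholds; no sample weighting.
- DMR boundaries are probe spans, not biologically delimited regions.
- The allelic-validation module models ratios and genotype logic only, not
  instrument signal processing; the mass-spectrometry quality rule
  ("severe allelic bias") is exposed only as a user threshold.
- The consistency filter encodes exactly the two published clauses; the
  observation that CHM methylation is particularly low at maternal loci is
  reported, not enforced.
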