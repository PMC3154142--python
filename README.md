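# imprintscan

Genome-wide mapping of imprinted differentially methylated regions (DMRs)
from promoter-methylation arrays of **diandric and digynic triploid
placentas**.

## The idea

Imprinted genes carry parent-of-origin-specific DNA methylation: one
parental allele of the associated DMR is methylated, the other is not.
Triploid conceptuses provide a natural dosage experiment. A diandric
triploid carries 1 maternal + 2 paternal haploid genomes, a digynic
triploid 2 + 1. At a maternally methylated imprinted CpG (methylated allele
level m1 = 1, unmethylated m0 = 0) the expected methylation fraction is the
genome-dosage average

    beta = (n_mat * m1 + n_pat * m0) / (n_mat + n_pat)

so diandries sit at 1/3, digynies at 2/3 — a theoretical 33.3 % difference —
while biparental tissue sits at 1/2 and an androgenetic complete
hydatidiform mole (CHM, 0 + 2) at 0. Non-imprinted probes are identical
across groups, so screening for diandry-digyny differences enriches
specifically for imprinted loci, and the CHM / normal-placenta reference
patterns police artefacts.

`imprintscan` implements the complete analysis as a tested, reusable
pipeline:

- **beta-value I/O and QC** — TSV beta matrices with detection p-values;
  probes failing detection (p > 0.05) in *any* sample are dropped.
- **profile statistics** — group means, Pearson correlations, hierarchical
  clustering of samples under 1 − r distance, per-probe Welch t-test census.
- **permutation screen (SAM)** — a from-scratch implementation of the
  moderated difference statistic d = r / (s + s0) with fudge-factor
  selection, pi0 estimation and permutation-based FDR (two-class and
  multiclass), the engine behind every "< 0.1 % FDR" call.
- **imprinting screen** — q <= 0.001 and |Δβ| > 0.15 candidate calling,
  parental-origin designation (higher in diandries = paternal), the
  two-clause consistency filter (normal placenta between the triploid
  means; CHM closer to diandric), aggregation of loci into DMRs per
  (gene, origin), and CNV-overlap annotation.
- **tissue/gestation classification** — multiclass screen across brain,
  kidney, muscle, placenta and blood; the > 15 % placenta-specificity
  margin rule; midgestation-vs-term change; "stable" DMR designation.
- **allelic validation logic** — informative mother-child SNP pairs,
  parental-allele inference, monoallelic-expression ratios (< 0.3),
  methylation/expression concordance, bisulphite-clone conversion filter.
- **synthetic data** — a generator producing beta matrices with exactly the
  dosage, tissue, gestation and logit-normal noise structure above, plus
  ground truth, so every stage is testable without array downloads.

## Worked example

```sh
imprintscan simulate --out sim --seed 5 \
    --config <(echo '{n_background: 300, n_maternal_dmr: 6, n_paternal_dmr: 6,
                      n_tissue_specific: 4, n_gestation_drift: 4}')
imprintscan screen --beta sim/beta.tsv --samples sim/samples.tsv \
    --annotation sim/annotation.tsv --permutations 200 --seed 5 --out scr
```

prints

```
candidates=12 eliminated=0 final=12 dmrs=6
```

all 12 simulated imprinted probes (6 maternal + 6 paternal) pass the
q <= 0.001 / |Δβ| > 0.15 screen, none is eliminated by the consistency
filter, and they aggregate into 6 DMRs (2 probes per gene). The BED output
carries one line per (gene, origin):

```
chr1	0	101	MATG00000|maternal	329	.
```

with score = 1000 × mean |Δβ| ≈ 333, the dosage-model difference. Running
the full pipeline (`imprintscan run-all --config run.yaml`) additionally
writes the eliminated-probe table, the tissue/gestation classification
(those imprinted DMRs are constant across tissues, hence `stable Y`) and a
JSON manifest with the probe counts at every stage, e.g.
`"n_candidates": 12, "n_eliminated": 0, "n_final_dml": 12, "n_dmrs": 6`.

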