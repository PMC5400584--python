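# domainspot

Domain-centric analysis of somatic cancer mutations. Most driver analyses
are gene-centric; `domainspot` instead treats the protein **domain family**
as the unit of recurrence. Because a Pfam-style family is a set of
homologous instances sharing one multiple sequence alignment (MSA),
mutations in *different* proteins can be compared at the *same* alignment
column — the coordinate where, e.g., BRAF V600E, c-KIT D816V and FLT3
D835Y coincide in the protein-kinase domain. The package is written for
computational cancer-genomics groups who have a protein-level mutation
catalog, a proteome, and domain annotations, and want to know which
domain families are unusually mutated and which alignment positions are
recurrence hotspots — separately for tumour suppressors (TS), oncogenes
(OG) and the gene set as a whole.

## What it computes

**Classification.** Protein-change strings are parsed into three classes:
missense (`V600E`), truncation (stop gains `E813*` and frameshifts
`Q1247fs*26`), and in-frame indels (`E746_A750delELREA`); anything else
is kept as `unclassified` and excluded downstream. Classes are always
analysed independently.

**Mapping.** Each mutation is located on every domain instance covering
its residue and then on the instance's MSA row: with local offset
`q = pos − start + 1`, the MSA column is the index of the `q`-th non-gap
character of the row.

**Domain enrichment.** For family *F* with exposure
`E_F = (Σ instance lengths) × n_samples` and observed count `O_F`, a 2×2
Pearson chi-square (no continuity correction, 1 df) compares
`[O_F, E_F − O_F]` with the pooled background row — either a panel of
450 cancer-unrelated families or, genome-wide, all other families:

    χ² = N (ad − bc)² / ((a+b)(c+d)(a+c)(b+d))

Bonferroni correction over the families tested per class; a family is
*enriched* only if significant **and** its rate exceeds the background
rate.

**Hotspots.** Under the null each of a family's `n` same-class mutations
hits any of the `L` alignment columns with probability `p = 1/L`, so a
column's count is Binomial(n, p) and its tail probability is

    P(X ≥ k) = Σ_{i=k..n} C(n, i) p^i (1 − p)^(n−i)

Only columns with `k ≥ 2` are tested; Bonferroni is over all tested
(family, column) pairs of the dataset-class run. The TS, OG and
whole-genome strata are analysed separately.

**Comparison.** Significant hotspots of the three strata are intersected
at family and at (family, column) resolution, and genome-wide hotspots
co-located with a TS/OG hotspot — in proteins not labelled TS/OG — are
reported as putative loss- or gain-of-function candidates.

**Gene classification.** The 20:20 rule (≥20 % truncations ⇒ TS-like;
≥20 % of missense at one position ⇒ OG-like) and a cross-validated
linear-SVM on the gene × family domain-composition matrix, with pooled
ROC AUC by the Mann–Whitney rank statistic.

**Synthetic cohorts.** `domainspot.simulate` generates all five inputs
with known truth — true alignments, planted hotspot columns, planted
enriched families, class-specific TS/OG mutation spectra — so every
stage is verifiable at desk scale.

## Worked example

```bash
domainspot run-all --seed 1 --in-dir simulated --out-dir results
```

simulates the default cohort (12 signal families, 450 background
families, 941 proteins, ~4,800 mutations from 150 samples) and prints:

```
results written to results
TS/missense: 25 recorded, 1 significant hotspots
OG/missense: 123 recorded, 3 significant hotspots
genome/missense: 232 recorded, 4 significant hotspots
TS/truncation: 18 recorded, 2 significant hotspots
OG/truncation: 0 recorded, 0 significant hotspots
genome/truncation: 20 recorded, 4 significant hotspots
TS/indel: 0 recorded, 0 significant hotspots
OG/indel: 3 recorded, 1 significant hotspots
genome/indel: 3 recorded, 1 significant hotspots
```

"Recorded" counts columns carrying ≥2 same-class mutations; the
"significant" ones are those surviving the binomial test with global
Bonferroni. The run recovers the planted truth: the two TS truncation
hotspots (`FAM_01` column 14, `FAM_02` column 10), the OG missense
hotspots, the OG indel hotspot, and the column co-planted in TS and OG
genes of `FAM_12`, which appears in the three-way position-level
intersection of `results/overlap_missense_position.tsv`. The genome
stratum additionally flags a couple of background-family columns — the
expected behaviour of the ≥2-filter-then-Bonferroni procedure when
per-family counts are low (see `docs/methods.md`). Per-stratum tables
(`hotspots_<dataset>_<class>.tsv`, `enrichment_*_<class>.tsv`,
`twenty_twenty.tsv`, `classifier_report.tsv`, `colocated_candidates.tsv`)
land in `results/`, and `simulated/truth.json` holds the planted ground
truth for comparison.

Library use mirrors the CLI:

```python
import domainspot as ds

data = ds.simulate(ds.SimulationSpec(seed=1))
print(ds.binomial_tail(n=2, k=2, p=1 / 100))   # 0.0001
```

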