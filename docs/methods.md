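# Methods

## Model and procedure

The package analyses protein-level somatic mutations at the resolution
of domain families. A *family* is a set of domain instances (protein,
start, end — 1-based inclusive) sharing one multiple sequence alignment;
an *MSA column* is the shared coordinate at which instances of different
proteins are compared. Three mutation classes are kept strictly
separate throughout: missense, truncation (nonsense + frameshift,
pooled because both abolish the downstream product), and in-frame
indels. Unparseable change strings are retained as `unclassified`,
logged, and excluded from every statistic; mutations whose stated
reference residue contradicts the proteome are dropped and logged
(bulk catalogs contain stale records), never raised as errors.

### Hotspot test

For one family, class and dataset stratum, let `n` be the number of
mutations of that class mapped anywhere in the family's alignment and
`L` the number of alignment columns. Under the null every mutation hits
each column with equal probability `p = 1/L`, so the count at a column
is Binomial(n, p); a column with observed count `k` gets the upper-tail
probability `P(X ≥ k)`, evaluated through the regularised incomplete
beta function (survival function), which is stable for large `n` and
tails far below double-precision underflow of naive summation. Columns
with `k < 2` are never tested (they still contribute to `n`). The
surviving tests are Bonferroni-corrected; by default `m` is the total
number of tested (family, column) pairs in the dataset-class run, with
per-family correction available as an option.

Choices worth making explicit:

* **p = 1/L over columns, not residues.** Members of a family have
  different lengths; the alignment column is the only coordinate shared
  across members, so the uniform null is placed on columns.
* **`n` is per (family, class, stratum).** Classes are tested
  independently, and each stratum (TS, OG, whole genome) recomputes `n`
  from its own mutation subset. Genes annotated as both TS and OG enter
  both cancer-gene strata.
* **Multi-residue indels are start-anchored**: an indel contributes to
  the column of its first affected residue only.
* **A mutation under overlapping instances of different families maps
  to each family independently**; excluding it would silently drop
  data.

### Enrichment test

A family's *exposure* is `(Σ instance lengths) × n_samples` — the count
of residue-sample opportunities, which jointly normalises for domain
frequency (number of instances), domain length and cohort size.
Observed mutations and remaining opportunities form one row of a 2×2
table; the other row pools the background (a fixed panel of
cancer-unrelated families, or all other families in genome-wide mode).
The statistic is the Pearson chi-square without continuity correction
(1 df), Bonferroni-corrected over the families tested per class. A
family counts as enriched only when it is significant *and* its
observed rate exceeds the background rate, so depleted families are
never flagged. Degenerate tables (a zero marginal) return stat 0,
p 1 with a log entry.

### Comparison and candidates

Significant hotspots of the three strata are intersected by exact set
algebra at two resolutions: family identity, and (family, MSA column)
position; the seven disjoint intersection regions are reported with
their member lists. "Co-located" requires identical family, column
*and* mutation class — no positional tolerance window. Genome-wide
hotspot positions matching a TS (OG) hotspot yield putative
loss-of-function (gain-of-function) candidate proteins after excluding
proteins already labelled TS/OG; a position matching both is reported
as ambiguous rather than resolved.

### Gene classification

The 20:20 rule is applied per gene within the cohort: truncation
fraction ≥ 0.20 calls TS; a single protein position carrying ≥ 20 % of
the gene's missense mutations calls OG; both conditions can hold.
Recurrence is counted at protein positions (the rule is defined on the
gene's own sequence, not the family alignment).

The domain-composition classifier builds a gene × family matrix of
instance counts (a flag switches to presence/absence) and runs
stratified k-fold cross-validation (default 10) with a pluggable binary
scorer; the default is a linear maximum-margin classifier (SVC, C = 1),
which is deterministic for fixed inputs. ROC AUC is computed by the
Mann–Whitney rank statistic with ties counted ½, and cross-checked
against the trapezoidal ROC integral on identical scores. Raw decision
values from different folds are not on a common scale, so pooled AUC is
computed on within-fold mid-ranks. Dual-labelled genes are excluded
from training and scored separately: their raw scores are calibrated to
[0, 1] by rank against the training scores, and called TS above 0.78,
OG below 1 − 0.83, otherwise unresolved.

### Built-in aligner

Families distributed as raw sequences are aligned by a self-contained
progressive aligner: BLOSUM62 pairwise global alignments give identity
distances, an average-linkage guide tree orders profile-profile merges,
and profiles are merged by dynamic programming over column count
vectors (gap-vs-residue −4, new gap column −6, deterministic
diagonal-up-left tie-break). The output is guaranteed to satisfy the
MSA invariants (equal row lengths; rows ungap to their inputs); exact
column agreement with any external aligner is not promised, and
precomputed alignments — including the generator's true alignments —
bypass this step entirely. An external aligner can be swapped in via
`--aligner external` with precomputed MSA files.

## Synthetic cohorts

The generator emulates the five inputs with known truth. Each family is
built by mutating a random ancestor per instance (substitution 0.30,
deletion 0.02, insertion 0.01 per column, insertions ≤ 3 residues), so
the true alignment is known by construction; instances are embedded in
proteins between random linkers (10–30 residues), and one protein can
host instances of several families, which makes the domain-composition
matrix non-trivial. Mutation counts per instance and class are Poisson
with mean `rate × multiplier × length × samples`; each mutation is
diverted to a planted hotspot column with probability equal to the
hotspot's excess fraction (when its instance is eligible and the column
is not gapped in that row), otherwise placed uniformly; linker residues
mutate at the plain background rate and become the unmapped fraction.
All protein-change strings are emitted in the parser's grammar with
reference residues read from the simulated proteome; an optional stale
fraction corrupts references to exercise the drop-and-log path.

Default study conditions: 12 signal families (lengths 40–80, 3–6
instances), 450 background families (2–4 instances), 150 samples, total
per-residue rate 2 × 10⁻⁴ per sample split by gene class — TS genes 62 %
missense / 33 % truncation, OG genes 85 % missense / 10 % truncation,
reflecting reported cohort compositions; indels are rare (5 %)
everywhere. Planted signal: truncation hotspots in two TS families,
missense hotspots in two OG families, one OG indel hotspot, one column
co-planted in the TS- and OG-hosted instances of a shared family
(excess fractions 0.25–0.30), and rate multipliers 10–60× on nine
(family, class) pairs. Hotspot-carrying families also carry a
multiplier so that their per-family `n` reaches ~70–180 — the regime in
which heavily mutated driver domains are actually tested.

What the generator does **not** emulate: trinucleotide signatures,
cancer-type-specific spectra, copy-number and fusion events,
COSMIC↔UniProt sequence reconciliation, and realistic family-size or
length distributions. Passing recovery tests therefore demonstrates
the statistical machinery under its stated null and planted
alternatives, not performance on real catalogs.

## Numerical and statistical notes

* The binomial tail agrees with exact rational-arithmetic summation to
  better than 1 × 10⁻¹² relative error over n ≤ 60 and p down to 1/200
  (checked against a `fractions.Fraction` oracle).
* The chi-square uses the closed form `N(ad − bc)²/((a+b)(c+d)(a+c)(b+d))`
  and is cross-checked against an independent contingency-table
  implementation.
* Result tables are written with `%.12e` floats, fixed column order and
  sorted rows; a rerun from the same seed is byte-identical, and a
  write/read round trip preserves 12 significant digits.
* All randomness flows from a single seed; cross-validation fold
  assignment, the simulator and the CLI derive from it.

## Known limitations

* **The ≥2 filter precedes the Bonferroni m.** Only tested positions
  count toward the correction, while the implicit search spans all
  columns. When per-family counts are small (a family with n ≈ 5–10
  mutations), a chance pair or triple at one column can clear the
  corrected threshold, so the genome-wide stratum — which contains many
  sparsely mutated families — reports a small tail of such columns even
  without planted signal. At the per-family sizes the test is meant for
  (n in the hundreds over L ≈ 100), the empirical family-wise type-I
  rate is ~2 % at α = 0.05. Interpret hotspot calls from families with
  small n cautiously.
* **Chi-square in the Bonferroni tail needs large expected counts.**
  With expected counts around 10 the far-tail p-values are
  anti-conservative (empirical any-flag rates up to ~0.11 at a nominal
  0.05); at cohort-scale expected counts (~200, the regime matching
  tens of thousands of samples) the test is conservative (~0.03–0.04).
* **Null variance of cross-validated AUC.** Under label permutation the
  pooled cross-validated AUC on 200 genes has a standard deviation of
  ~0.06 — substantially larger than the ~0.041 of a single-split
  Mann–Whitney AUC — because a learner legitimately detects chance
  label–feature structure present in a given permutation, and that
  signal generalises across folds. Permutation-based calibration of
  the classifier should use the cross-validated null distribution, not
  the analytic single-split one.
* The column null ignores per-column occupancy: insertion columns
  present in few instances receive proportionally fewer mutations than
  1/L. With the default indel rates this biases tests mildly toward
  core columns.
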