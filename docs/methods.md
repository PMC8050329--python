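# Methods

## The GSCU resampling statistic

For each gene the coding sequence is read start to stop codon; by default the
terminal stop is excluded from both the codon counts and the frequency
denominator (the inclusive reading is available via `include_stop=True`,
since curated CDS sets differ in whether they carry the stop). The per-gene
frequency of each U34 codon (AAA, GAA, CAA) is compared against the rest of
the orfeome: the p-value is the probability that a uniformly drawn other
gene has a *strictly* higher frequency. Ties do not count as higher. Two
estimators are provided:

* **exact** — the rank proportion (#higher)/(#others). This is the
  large-draw limit and the oracle used in tests; it can be 0.
* **Monte-Carlo** — the default, with `n_draws` = 10,000 uniform draws with
  replacement and the add-one estimator (1 + #greater)/(n_draws + 1), so
  p > 0 always and downstream q-value computation is well-defined.

Each (gene, codon) pair uses an RNG substream keyed on (seed, CRC32 of the
gene id, codon), so results are reproducible and independent of input order;
the candidate frequencies are sorted before sampling for the same reason.
Draws are fresh per gene and per codon rather than one shared resample
panel; with draws i.i.d. and 10,000 per comparison the two designs are
statistically indistinguishable at the reported precision.

q-values are computed **per codon across genes** (three separate
corrections). The default is Storey's method: π0 is estimated on the λ-grid
0.05…0.90 via π0(λ) = #{p>λ}/(m(1−λ)), smoothed with a cubic polynomial fit
and evaluated at λ = 0.90, clipped to [1/m, 1]; with fewer than 30 p-values
the smoother is unstable and π0 is fixed at 1 (conservative). q-values are
the step-down cumulative minima of π0·m·p/rank. Benjamini–Hochberg (via
statsmodels) is provided as the robust alternative for small panels.

Two enrichment rules are exposed: the statistical rule (per-codon q < 0.05,
with `enriched_any`/`enriched_all` for at-least-one / all-three codons) and
the deterministic cumulative rule f_AAA + f_GAA + f_CAA > 0.088 (strict
inequality at the boundary).

### A caution on FDR over resampling rank p-values

The GSCU p-value is a relative rank statistic: the gene ranked r from the
top gets p ≈ (r−1)/(n−1). A consequence worth understanding before relying
on the q < 0.05 rule: if the truly enriched genes simply occupy the top
ranks, their p-values sit exactly at the uniform quantiles of their ranks,
so π0·m·p/rank ≈ π0 for every one of them and no FDR threshold can separate
them from the background — the procedure only gains traction when the
p-value distribution departs from uniformity (heavy ties, atoms from
discrete counts, or a large excess of small p-values), as real orfeomes
with their tied and discrete codon counts can produce. On smooth simulated
orfeomes the cumulative-frequency rule is the discriminating classifier
(it recovers a 3× planted enrichment at ~0.99+ sensitivity with ~0.01 FDR
in the shipped benchmark), while the q-rule rejects nothing; the package
reports both.

## Synonymous recoding

AAA→AAG, CAA→CAG, GAA→GAG at codon boundaries only. The replacement codons
encode the same amino acids but are decoded independently of the U34
modification. The operation is idempotent, leaves translation invariant and
zeroes the U34-codon count; these three laws are property-tested over random
CDS.

## Positional bin profiles

Each counted codon at index i of L is assigned to bin ⌊i·n_bins/L⌋
(default 100 bins); the bin value is the U34 fraction of its codons, 0 for
an empty bin (genes shorter than n_bins leave gaps). Group comparisons
average profiles within each group and apply the two-sample KS test to the
two mean vectors; a pooled per-gene alternative is behind the `pooled` flag.
The mean-profile reading treats the group as the unit of comparison, which
matches comparing "the frequency of the U34 codons for each bin" between
gene sets; the ambiguity is noted here deliberately.

## Residue classes, pentasequences and the aggregation score

The default scheme uses the Kyte–Doolittle hydropathy scale. Classes are
derived from it: hydrophilic = {R,K,N,D,E,Q,H} (hydropathy ≤ −3.2),
hydrophobic = {A,M,C,F,L,V,I} (≥ +1.8), the rest neutral. This choice is a
declared assumption, not an external standard: it guarantees that D/E/K/R —
the only residues in the consensus motif — are hydrophilic, so every motif
hit is also a hydrophilic pentasequence (a cross-module invariant under
test). The scheme is a value object and fully swappable.

Pentasequence counting is overlapping sliding-window: every position whose
5 residues all share one class contributes +1, so a maximal run of length
L ≥ 5 yields L−4 windows. A run-based mode (each maximal run counts once) is
available for sensitivity analysis.

The composite score is log k = α₀ + α_hydr + α_ss + α_ch + α_pat with
α₀ = 0 (pH/temperature reference), α_hydr the hydropathy sum, α_ss the
number of annotated helix + strand *segments* (the annotation is consumed,
never predicted; absent annotation contributes 0; "number of structures" is
read as segment count, not residues in segments), α_ch the net charge with
K/R = +1, D/E = −1 and histidine 0 (only unambiguously charged residues
carry charge), and α_pat the total pentasequence count. The identity
log k = Σα is exact by construction and asserted, not rounded.

## Motif scanning and the direct-target predictor

The consensus [EKR]-[EKR]-[EKR]-R-[DEKR] is stored as a list of per-position
allowed-residue sets, so variant motifs can be scanned; all overlapping hits
are reported and proteome prevalence is presence/absence per protein. A
consensus builder derives such a pattern from a list of ungapped pentamers
by adding residues per position in decreasing frequency until they cover a
configurable fraction (default 90%) of the sequences — no alignment step is
needed for equal-length ungapped 5-mers.

The predictor is the conjunction: predicted direct target ⇔ codon-enriched
AND motif-bearing. Enriched, motif-free genes are flagged `codon_only` —
candidate indirect targets whose downregulation would have to be explained
by something other than their own aggregation. The enrichment rule
(`all_q`, `any_q` or `cum`) is a parameter; `cum` is deterministic and is
the recommended rule on simulated data (see the FDR caution above).

## Conservation

Column entropy is Shannon H = −Σ p·log₂p in bits over the residues present;
gaps are excluded and the distribution renormalised, because counting gaps
as a 21st symbol inflates entropy at alignment edges. Columns with more than
50% gaps are dropped from a window's mean with a logged flag; a fully gapped
column is an error. Scores are reported as log₂20 − H (larger = more
conserved); raw entropies are also emitted. Motif windows are pooled across
families and compared against `n_random` random non-motif 5-windows per
family (sampled with replacement, seeded) by two-sided Mann–Whitney; a
t-test is behind a flag. Mann–Whitney is the default because window scores
are bounded and skewed near the conserved ceiling.

## Synthetic data: what it emulates, and what it does not

* **Orfeome** — ATG + i.i.d. sense codons + stop. Baseline usage is uniform
  over the 61 sense codons by default; a human-like usage table is shipped
  so enrichment behaviour can be checked against a non-uniform baseline.
  Planted genes multiply the three U34-codon probabilities by
  `enrichment_multiplier` (default 3) and renormalise; defaults are 1,000
  genes, lengths ~ Normal(500, 100) codons, 5% planted. i.i.d. codons mean
  no positional autocorrelation, no codon-pair bias, no GC gradient —
  positional-profile analyses on synthetic data only see flat profiles.
* **Proteome** — i.i.d. uniform residues, with one random consensus-motif
  instance written over a uniform position in a `motif_prevalence` fraction
  of proteins. Real proteomes are compositionally biased and have domain
  structure; the background motif rate here (~0.7% per 400-residue protein)
  is far below real prevalence. Truth tables record both the planted flag
  and the scan-verified motif presence, so classifier scoring is exact even
  when a background window matches by chance.
* **Expression** — P(down) = 0.9 for (planted-enriched AND motif) genes and
  0.05 otherwise by default; log2 fold-changes Normal(−1.5, 0.4) for down
  and Normal(0, 0.25) otherwise; aggregate membership = down AND motif.
  These effect sizes represent a strong, clean knockdown; real proteomics
  adds missing values and fold-change compression that the generator does
  not model.
* **Ortholog families** — an ancestral sequence, an unmutated reference row
  and 9 derived rows with per-site i.i.d. substitution (to one of the 19
  other residues) at the background rate (default 0.5), except one designated
  5-window at the conserved rate (default 0.05, i.e. 0.1× background). No
  indels, so alignments are exact and the entropy statistic is isolated from
  aligner behaviour; no phylogenetic correlation between species rows, which
  makes the conservation test anti-conservative relative to a star-free real
  phylogeny.

Every generator is a pure function of (config, seed); rerunning is
bitwise-identical. Passing tests on this data therefore show the pipeline's
statistics behave as designed under its own assumptions — not that those
assumptions hold for any real orfeome.

## Numerical choices

* All coordinates 0-based, half-open; codon positions count codons, not
  nucleotides.
* Ambiguity codes (N etc.) exclude a CDS from the orfeome with a warning
  rather than being guessed: codon frequencies must be exact counts. A CDS
  without a terminal stop is accepted with a warning and all codons counted.
* Threshold comparisons are strict (> 0.088, q < 0.05) including exactly-at-
  boundary inputs.
* Mann–Whitney uses exact enumeration for both n ≤ 20 without ties, the
  tie-corrected normal approximation otherwise; the chi-square test is
  Pearson without Yates correction by default (a flag enables it), and a
  zero margin raises rather than returning 0/0.
* Degenerate inputs: empty comparison sets, empty samples, all-gap columns
  and zero-variance t-tests raise; empty proteins score 0 everywhere;
  sequences shorter than 5 residues yield empty window sets.

## Benchmark problem sizes

The shipped acceptance script runs at desk scale: 50-gene oracle orfeomes,
five 1,000-gene planted-enrichment replicates at 2,000 draws, 2,000-sequence
scan oracles, 2,000-replicate null calibrations, 20 conservation-power and
100 conservation-null replicates (50 and 10 families), and a 400-gene
end-to-end run — sizes chosen so the full battery completes in well under a
minute per stage while keeping binomial error bars a few percent wide.

## Known limitations

* The headline genome-scale numbers (thousands of enriched human genes,
  ~10% motif prevalence) require the human CDS set and Swissprot proteome
  and are not recomputed here.
* Storey's π0 is clamped to 1 below 30 p-values; q-values on tiny panels are
  effectively BH.
* The pipeline consumes precomputed alignments and secondary-structure
  annotations; it neither aligns nor predicts structure.
* TANGO-style amyloid profiles, exit-tunnel electrostatics and CMA-motif
  scanning are out of scope.
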