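# Methods

This note documents the models, statistics and numerical choices behind
`phosmap`, what the synthetic data generator does and does not emulate, and
the known limitations.

## Site localization and sequence windows

Modified peptides are normalised from three marker dialects (plain `#`,
MaxQuant `(ph)`, Spectronaut `[...]`) into a canonical form in which the
marker immediately follows the modified residue. Localization is exact
substring search: every occurrence of the stripped peptide in every protein
yields one site per modification position. Shared peptides therefore produce
one record per harbouring protein, and repeats within one protein are all
reported, flagged `ambiguous_within_protein`. No fuzzy matching is done and
isoleucine/leucine are not collapsed — inputs are assumed to be exported
identifications against the same database.

The window of a site is the `2h + 1`-mer centred on it (`h = 7` by default,
giving the 15-mers standard in motif analysis), padded with `_` where it
overhangs a terminus so the modified residue always sits at the centre.
An optional localization-probability filter (`min_loc_prob`) drops
low-confidence sites; the default keeps everything.

## Cross-species mapping

Protein pairing uses a built-in Smith–Waterman search (BLOSUM62, affine
gaps open 11 / extend 1) whose raw scores become bit scores through the
Karlin–Altschul conversion with fixed constants λ = 0.267, K = 0.041, and
E-values through the simplified `E = m·n·2⁻ˢ` (no effective-length
correction — deliberately, so the identity holds exactly for every emitted
hit). Best-hit selection: smallest E; ties by largest matching percentage
(identical aligned residues / query length), then longest alignment, then
lexicographically smallest subject accession for determinism. Precomputed
hits in 12-column BLAST tabular format can be imported instead; their
E-values are recomputed from the file's bit scores with the same formula so
all hits share one E-value definition.

Position transfer runs through a global Needleman–Wunsch alignment
(BLOSUM62, gap open 10 / extend 0.5). Equal-scoring alignments are resolved
by the aligner's deterministic enumeration order (first alignment). A site
whose alignment column holds a gap on the target side is reported
`gap_at_site`.

Window similarity counts positionally identical characters. Two semantics
are deliberate: the unknown residue `X` never matches (not even `X` vs `X`),
and terminus pads match each other by default (`ignore_pads=True` excludes
pad columns from the count instead — both behaviours are exposed because
terminal windows are genuinely ambiguous). The BLOSUM50 window score strips
pads and globally aligns the remainders (gap open 10 / extend 4; gap costs
follow the common pairwise-alignment defaults and are configurable).

Filters — `ws_min` (default 8, the threshold at which cumulative cross-
species hits level off), `blosum_min` (off by default) and the central-match
mode (`exact` | `phospho` | `any`, where `phospho` admits the five classes
S<>S, T<>T, Y<>Y, S<>T, S/T<>Y) — are independent, so each unmapped site
carries a single reason code (`no_hit`, `gap_at_site`, `fails_ws`,
`fails_blosum`, `central_mismatch`) and every input site appears exactly
once in the output.

## Motif enrichment

Discovery is the greedy iterative (motif-x-style) scheme. For the current
foreground/background window sets, each candidate cell (offset ≠ 0,
residue) is scored by the exact binomial upper tail of the foreground count
at the background cell frequency; frequencies exclude pads and `X` from
numerator and denominator. The smallest-p cell (ties: smaller |offset|,
then alphabetical residue) is fixed if its Bonferroni-corrected E-value
(`p × (width−1) × 20`) is below threshold (default 0.01) and its support is
at least `min_occ` (default 10); both sets are filtered to matching windows
and the step repeats. On termination the constraint set is emitted as one
motif, its foreground matches are removed, and the search restarts.

Two guards correct small-sample pathologies of the plugin binomial:

* **Background-noise gate.** The binomial treats the background frequency
  as exact; when the background is comparable in size to the foreground, a
  foreground-up / background-down fluctuation at any of the ~280 cells
  mimics enrichment (in simulation, two-thirds of null runs produced a
  spurious motif). Each candidate must therefore also pass a one-sided
  hypergeometric (Fisher) comparison of the two counts — which models both
  sampling noises — at the same corrected threshold. The reported
  `p_value`/`e_value` remain the classic binomial quantities. After the
  gate, ~1% of null runs report any motif.
* **Refinement support floor.** Conditioning steps beyond the first require
  the filtered background to retain at least `min_bg_size` windows
  (default 100): with a handful of background windows the cell frequencies
  are too noisy to support further conditioning, and recursion would fix
  spurious secondary constraints. A background cell observed 0 times is
  floored at `1/(n_valid + 1)` rather than reported as p = 0.

A motif's `p_value` is the largest (weakest) step p, so every reported
motif satisfies the threshold at each of its constraints. Tail
probabilities below ~1e−308 underflow to 0.0 in double precision; they are
reported as such rather than rescaled.

PWMs are per-column relative frequencies over the 20-residue alphabet (pads
and `X` excluded from the denominators; an uninformative column becomes
uniform; pseudocount 0 by default, configurable). PWM similarity is the
Pearson correlation of the flattened matrices (a `column-euclidean`
alternative is available); kinase ranking builds one PWM from the query
site's windows and one per library kinase (requiring ≥ 5 substrate
windows), sorting by descending similarity with alphabetical ties.

The per-cell residue-frequency test scores the observed foreground
frequency against a sampling distribution formed by `n_reference_sets`
(default 100) background bootstrap resamples of foreground size:
`t = (obs − mean)/sd` against a t distribution with `n − 1` df, two-sided.
Resampling is with replacement — subsets without replacement degenerate to
zero variance whenever the foreground is as large as the background.

## Kinase–substrate annotation and enrichment

Annotation joins sites to the KS table on substrate accession when both
sides carry one, else the gene symbol (case-insensitive), always together
with the site string (residue + position). Mapped sites join through their
*target*-side coordinates, which is what extends annotation into the query
species. Outputs follow the network idiom: pair, node and edge tables, with
duplicates collapsed.

Enrichment per kinase is Fisher's exact test (two-sided by default; both
one-sided modes are exposed) on foreground substrate sites vs the
background universe, BH-corrected across kinases. The universe defaults to
all input sites; `annotated_only=True` restricts it to sites carrying any
KS annotation.

## Conservation segmentation and species trees

The presence matrix is 0/1 over reference sites × species (1 = mapped and
passed filters), with rows typed pS/pT/pY. Species counts (row sums) are
binned into k equal-frequency segments (k = 5: Q1 least to Q5 most
conserved). Because many sites tie on the same count, a tied count value is
never split across segments: distinct counts are walked in ascending order
and each boundary is placed where the cumulative site count is nearest to
j/k of the total, while leaving enough distinct values for the remaining
segments. The segmentation is a partition, order-invariant, and errors when
k exceeds the number of distinct counts.

Per-segment feature enrichment uses the feature × segment 2×2 Fisher test
with BH across all (feature, segment) pairs and threshold adj-p < 0.01;
the reported ratio (feature share in segment over feature share overall)
satisfies Σ_s ratio_s · (segment size / total) = 1.

Species trees come from agglomerative clustering of presence columns
(Jaccard distance and average linkage by default; simple-matching and
complete linkage are options). Columns are sorted by species name before
clustering so linkage ties resolve deterministically; the newick branch
lengths are merge-height differences. Jaccard is undefined for an all-zero
species column, which is an error rather than a silent 0.

## Quantitative pipeline

Preprocessing: per-sample median division then log2 (missing values stay
missing; nonpositive intensities and all-missing samples are errors), a
missingness filter removing sites with missing fraction strictly above the
threshold (default 0.5; the comparative-workflow preset uses 0.4), and kNN
imputation over sites. A neighbour must have a value in the target sample
and share ≥ 1 observed sample with the incomplete site; distance is the
root mean squared difference over shared samples (normalising by the
overlap size keeps sites with different missingness patterns comparable);
the cell becomes the mean of the k = 10 nearest neighbours' values in that
sample, falling back to the site mean when no valid neighbour exists.
Observed cells are never altered.

Differential testing is the two-class unpaired SAM statistic
`d = (x̄₂ − x̄₁)/(s + s₀)` with `s` the pooled standard error and `s₀`
selected by the original percentile search (candidates at the 0, 5, …,
100th percentiles of `s`, minimizing the coefficient of variation of the
median absolute deviation of `d` across quantile bins of `s`). The null
distribution comes from distinct group-label reassignments — exhaustive
when at most `n_perm` exist (e.g. all 70 for a 4 + 4 design), otherwise
`n_perm = 1000` sampled without repetition. The q-value at a site is the
smallest estimated FDR (median permutation exceedance count over observed
call count, clipped to [0, 1]) over all |d| cutoffs that call the site; no
π₀ estimate is applied, which is conservative. A site is significant when
`q < 0.01` and `|log2FC| ≥ 1`. Both the q-threshold and the fold-change
gate are primary (the q-value plays the role that a permutation p-threshold
plays in looser descriptions of the procedure). Degenerate inputs
(zero-variance, zero-difference sites) give d = 0, not NaN.

## Synthetic data generator

`generate_fixture` emulates the tool's inputs at desk scale, as a pure
function of the seed: a random query proteome (uniform residue usage;
default 30 proteins of 200–400 aa), sites placed on a non-overlapping
window grid with centres drawn S/T/Y at 75/20/5% (the approximate composition
of measured phosphoproteomes), planted motif constraints written literally
into disjoint site subsets, an ortholog proteome derived by per-residue
substitution (default 5%) and indels (default 1%, split evenly between
insertion and deletion) with the exact query→target coordinate map
recorded, peptides cut as literal substrings around each site, a toy KS
table (five random kinases plus one tied to the first planted motif), and
a site × sample intensity matrix (per-site log2 baseline ~ N(20, 2),
sample noise sd 0.3, planted ± log2-effects of 3 in the second group,
missing completely at random at 10%).

What it does **not** emulate — and hence what passing tests do not show
about real data: realistic residue composition and homology structure
(real proteomes have domains, repeats and paralogs that stress best-hit
selection much harder), tryptic digestion and peptide detectability,
missingness that correlates with intensity (real DIA data is left-censored,
not MCAR), shared-peptide ambiguity at scale, and correlated noise across
samples. The generator's role is to make every contract and statistic
testable with known ground truth, not to benchmark biological recall.

## Numerical choices and limitations

* Determinism everywhere: explicit tie-breaks (best hits, motif cells,
  kinase ranking, species-name ordering in trees), a single seed per
  randomised routine.
* Fisher's exact test and BH come from scipy/statsmodels; tests verify
  them against an exact rational-arithmetic hypergeometric enumeration.
* Bit-score constants are fixed rather than estimated; E-values are
  comparable within a run, not calibrated against NCBI BLAST.
* Pairwise-alignment gap parameters are conventional defaults, exposed in
  `CrossmapParams`; mapping across very diverged or repetitive proteins
  deserves imported BLAST hits rather than the built-in search.
* The package does not ship any licensed annotation data (e.g. curated KS
  tables); users supply their own TSVs, and the bundled generator produces
  synthetic stand-ins for tests and demos.
* Multi-species analysis is pairwise per target species; no simultaneous
  multiple alignment is attempted.
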