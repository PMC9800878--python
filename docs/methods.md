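# Methods

This note documents the models behind `adipomap`: what the synthetic
generators emulate, the parameters that matter and their defaults, the
numerical conventions of the scoring chain, and the design choices made
where the method description left the design open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and shape

The package is an analysis pipeline of deterministic transforms —
annotation filtering, differential calling, connectivity scoring, robust-Z
screen analysis — organized module-per-stage with a thin click CLI. No
stage estimates parameters with uncertainty, so a fitted-model/results
object design would be artificial; the library functions plus the
`RunConfig`-driven orchestrators are the interface.

## Synthetic study conditions

All inputs are generated, never downloaded. Identical configuration + seed
gives bit-identical outputs: each generator draws from a named sub-stream
of the global seed, and per-perturbagen signatures derive their stream from
a CRC of the perturbagen id, so enlarging a compendium never reshuffles
existing signatures.

### Annotation maps

`generate_annotation_map` builds a term table that *realizes a specified
set of cascade cardinalities exactly*: for each of two keyword buckets the
total number of phrase-matching terms, how many are absent in the target
taxon, how many are cellular components, plus the number of dual-keyword
terms surviving both exclusions. Term names embed the keywords (underscores
rendered as spaces, since phrase searches treat them that way); taxon-absent
and cellular-component subsets are disjoint within a bucket so each removal
step is unambiguous. Term→gene links are uniform draws of 5–30 genes from
the shared universe. Infeasible specifications (overlap larger than a
bucket, exclusions exceeding a bucket's exclusive terms, negative counts)
are rejected at construction.

The module ships the reported human lipid/fatty-acid cardinalities
(736/273 matches, 54 + 6 taxon-absent, 234 + 7 cellular-component, 26
overlapping, 682 retained) as the default cascade specification.

### Differentiation time course

Probe-level log2 intensities over time points d0/d4/d13: per-gene baseline
~ N(7, 1), a per-probe offset ~ N(0, 0.25) (two probes per gene,
bead-array-like), and replicate noise ~ N(0, `noise_sd`). A planted
program of `program_size` genes (half up, half down) shifts by signed
|N(`program_log2fc_mean`, `program_log2fc_sd`)| log2 units, scaled by
i/(T−1) at the i-th time point — monotone in time, full effect at the last
time point. When an annotation map is supplied, program genes are drawn
from genes annotated to retained terms, making every program gene eligible
for query construction.

Defaults: 978 genes (a landmark-panel-sized universe), program of 400,
log2FC ~ |N(2, 0.5)|, noise 0.2, **4 replicate arrays per time point**.
The replicate count deserves a note: the original design assumed a
moderated empirical-Bayes differential fit, whose shrunken variances add
effective degrees of freedom. The package substitutes a plain Welch t-test
(the moderated fit is out of scope), which at 3 replicates has ~4 df and
cannot hold a deep pool of genes at adjusted p < 0.001; one extra replicate
restores comparable power, so the stringent threshold retains well over 150
annotated genes per direction — the regime the query construction needs.

### Reference compendium

Per (perturbagen, cell line), a gene-length Z-score vector. Nulls are
standard normal. With standardized program vector v (mean 0, variance 1
across genes) and planted effect e ∈ [0, 1], antagonists follow
−e·v + √(1−e²)·ε and agonists +e·v + √(1−e²)·ε, so the Pearson correlation
with the (negated) program is e in expectation — checked by Monte Carlo in
the tests. All cell lines of a perturbagen share the planted direction;
noise is cell-line-specific.

Defaults: 102 perturbagens × 3 cell lines, **2 planted antagonists, 0
agonists, 100 nulls**, effect 0.8. The planted composition follows from
the percentile arithmetic of the dual −99 filter: with the compendium
itself as reference pool, the weakest of k planted compounds can at best
out-rank the N nulls, giving tau ≈ −100(N + 1)/(N + k − 1 + ... ); at
N = 100 only k ≤ 2 lets *every* planted antagonist clear −99. Larger
planted sets are supported (and used where only specificity is asserted)
but full recovery is then not achievable by construction — a pool-relative
property of percentile scores, not an implementation artifact.

### Screen plates

A plate carries 3 vehicle wells, 3 wells per test compound, and 20
background perturbagens × 3 wells whose per-gene effects are N(0, 1) log2
units. The background wells matter: real screening plates hold many
diverse perturbagens, and the plate-wide MAD that the robust Z divides by
is dominated by that biological spread rather than by replicate noise.
Without them, the difference of two 3-replicate medians has a standard
deviation near 0.95 robust-Z units and the |ΔRZS| ≥ 2 rule false-positives
freely; with them the null ΔRZS spread is ~0.2 and the rule is well
calibrated. Planted anti-adipogenic compounds shift 10 marker genes by
`effect × background_effect_sd` raw log2 units, i.e. the stated number of
nominal robust-Z units (realized ΔRZS varies ±~25 % with the per-gene MAD
estimate, ample against the threshold of 2 for the default effect of −5).

What the generators do **not** emulate: bead-array chemistry and probe
hybridization, Luminex deconvolution and the 978→12,328 gene inference,
batch/plate-position effects, correlated gene modules, and heavy-tailed
expression noise. Passing tests therefore demonstrate correctness of the
pipeline's mathematics under its stated generative assumptions, not
performance on real microarray or L1000 data.

## Numerical conventions

- **Enrichment score.** Weight p = 1 (configurable; p = 0 recovers the
  classical KS statistic). The running sum is evaluated just before and
  just after every hit — the only points where extrema occur — in sequence
  order, so exact-magnitude ties resolve to the earliest extremum, matching
  a position-by-position scan. All-zero hit weights fall back to equal
  increments. Empty query–signature intersection is an error carrying
  overlap 0; a record is rejected when the overlap fraction is below 0.5
  (configurable), since silent partial matches corrupt ES.
- **Ranking ties** (equal signature values, equal |log2FC| at the k-th
  query position, probe collapse) break lexicographically for determinism.
- **WTCS** is 0 unless ES_up and ES_down strictly disagree in sign (a zero
  ES counts as agreement).
- **NCS** divides by the mean same-sign WTCS of the cell line; a lone
  same-sign value therefore normalizes to ±1.
- **tau and summary score** use leave-one-out percentiles with a strict
  magnitude comparison: the scored record is excluded from its own pool,
  so the most extreme record attains exactly ±100 and ties count against
  the candidate. Both thresholds are strict (< −99 survives).
- **Summary statistic**: the 33rd or 67th percentile (linear interpolation)
  of the cell-line NCS vector, whichever has larger magnitude, ties
  favoring the 33rd; this maximum-quantile convention mirrors the
  perturbagen-centric summaries used by connectivity services and is a
  reimplementation convention, not a published formula.
- **Differential calling**: Welch t with Benjamini–Hochberg adjustment;
  within-group variances floored at 1e−8 (log2 scale) so noise-free
  fixtures yield extreme statistics instead of dividing by zero.
- **Robust Z**: MAD scaled by 1.4826; zero-MAD rows are set to 0 and
  flagged rather than falling back to the standard deviation, which would
  forfeit robustness exactly where it matters.
- **Preranked enrichment**: gene-label permutation null (replicate counts
  cannot support sample permutation); NES divides by the mean |null ES| of
  matching sign; the nominal p uses the (b + 1)/(n + 1) estimator so it is
  never exactly zero; FDR is the standard NES-ratio estimate over the
  pooled normalized null, clipped to [0, 1]. Defaults: 1000 permutations,
  minimum set size 15, seed required.

## Open design points, resolved

- **Top-k ranking pool**: significant probes only (adjusted p < 0.001),
  then ranked purely by log2FC — significance gates eligibility, fold
  change orders the query.
- **"Median connectivity score"**: median tau across cell lines (the sort
  key of the candidate tables).
- **Enrichment ranking for the screen**: the per-gene median-RZS difference
  (treatment vs vehicle), i.e. the compound-vs-control effect; ranking
  pooled replicate RZS instead is exposed through the same function by
  passing a different vector.
- **Verdict rule**: a compound is called anti-adipogenic when an
  adipogenesis gene set is negatively enriched at nominal p ≤ 0.05; the
  NES < −2 rule is a presentation filter on the output tables, not the
  decision rule.

## Problem sizes

The default suite and the acceptance script run at the reference scale
above (978 genes, 1,956 probes, ≤ 500 perturbagens × 3 cell lines, ~75-well
plates, 1000 permutations); the full suite completes in well under a minute
and the acceptance script in a few seconds on one CPU. These sizes were
chosen as the smallest at which every statistical regime of the method
(deep query pools, percentile floors, plate-level standardization) is
exercised.

## Known limitations

- tau and summary scores are pool-relative; absolute values are not
  comparable across compendia, and headline counts that depend on a
  proprietary reference library are out of reach by construction.
- The Welch/BH differential substitute is less powerful than a moderated
  fit at small n; see the replicate-count note above.
- The FDR estimate shares the usual bias of NES-ratio estimates for small
  set collections; interpret q-values comparatively.
- Percent-change and 2^−ΔCt helpers implement the quantification formulas
  only; no dose–response modelling or ANOVA layer is provided.
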