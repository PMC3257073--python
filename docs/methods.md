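# Methods

`ubisite` predicts which lysines of a protein are ubiquitylated from
sequence context alone. This note documents the model, its parameters,
the synthetic benchmark the tests run on, and the numerical and design
choices a maintainer should know about.

## Problem and model

Ubiquitylation attaches ubiquitin to the ε-amino group of substrate
lysines. Experimentally verified sites define a positive class; all other
lysines of the same proteins are treated as negatives, which makes the
task imbalanced (roughly 1:1.9 in typical curated corpora) and makes the
Matthews correlation coefficient the primary headline metric.

Each candidate lysine is represented by a 21-residue window (10 residues
up- and downstream; shorter terminal contexts are padded with the inert
symbol `X`). Window sites are indexed 1..21 with the lysine at site 11.
(Published site-count analyses in this literature sometimes refer to the
central residue under other indices; this package consistently uses
center = 11 and window sites 1..21.)

Four feature families encode a window (627 features total at w = 21):

| family | size | content |
|---|---|---|
| AAC | 86 | 20 single-residue compositions + 66 merged dipeptide frequencies |
| PSSM | 420 | 21 stacked rows of the min-max-normalized PSI-BLAST profile |
| FACTOR | 100 | 5 Atchley factors × 20 flanking sites |
| DISORDER | 21 | per-site intrinsic-disorder scores |

Details and conventions:

* **AAC.** Dipeptides are counted on an 11-group reduced alphabet
  (`{A} {G} {P} {C} {ST} {NQ} {DE} {KR} {H} {ILMV} {FWY}`), giving
  11² = 121 ordered pairs merged into 11·12/2 = 66 unordered categories;
  with the 20 compositions the unmerged intermediate has 141 entries.
  The grouping is a standard physicochemical clustering and is swappable
  via `GroupScheme`. Compositions are normalized by the number of
  non-`X` residues and pair counts skip pairs touching `X`, so padding
  never manufactures signal.
* **PSSM.** Profiles are parsed from PSI-BLAST ASCII matrices (first 20
  numeric columns; columns re-ordered to the alphabetical amino-acid
  order) and min-max normalized to [0, 1] over the whole per-protein
  matrix — the simplest reading of a global (value − min)/(max − min)
  rescaling; a constant matrix degenerates to all 0.5 with a warning.
  Window rows beyond the protein ends contribute zero blocks. Running
  PSI-BLAST itself is out of scope; any provider of per-protein matrices
  plugs in.
* **FACTOR.** The five Atchley factor scores (electrostatic charge,
  codon diversity, molecular volume, secondary structure, polarity) of
  each flanking residue. The central site is always `K`, hence invariant
  and excluded — this is the only reading consistent with a 100-feature
  (20 × 5) block over a 21-site window.
* **DISORDER.** One score per window site, from any per-residue disorder
  predictor (e.g. VSL2-style output); padded sites score 0. Running a
  disorder predictor is out of scope; a provider interface supplies the
  tracks.

## Feature selection (FSNCMI)

Features are discretized per feature by equal-frequency binning into
B = 5 bins (robust to the skewed distributions composition features
have; deterministic; constant features collapse to one bin). All
information measures are plug-in estimates in bits.

The greedy selector seeds with the t-th feature by marginal MI with the
class and repeatedly adds the candidate f maximizing

    J'(f) = min_{fs ∈ FS} I(f; C | fs) / H(f, C)

Conditioning on single already-selected features keeps contingency
tables dense enough to estimate; the H(f,C) normalization counters the
bias of CMI toward many-valued features. Candidates whose criterion
falls to numerical zero (ε = 1e−12; plug-in estimates are rarely exactly
zero) carry no information beyond FS and are pruned permanently. Ties in
ranking and selection break toward the smaller registry index, making
the whole procedure deterministic.

Running the search from P = 10 consecutive starting ranks t = 0..9
yields overlapping but distinct subsets; their union is what the
ensemble consumes. Subset size is fixed at k = 12. A threshold rule that
stops when successive accepted J' values differ by less than `delta` is
implemented and configurable, but disabled by default (`delta = 0`): the
plateau of the J' trajectory is how k itself is chosen (the customary
diagnostic threshold on the plateau is 0.015), and once k is fixed the
threshold rule is redundant — on data where the trajectory flattens
quickly it would otherwise truncate subsets to 3–4 features and defeat
the multi-subset design. The seed feature has no greedy criterion; its
trajectory entry records its normalized marginal MI so that trajectory
and subset lengths always agree.

A greedy mRMR selector (max relevance I(f;C) minus mean redundancy to
FS) is included as the baseline comparator.

## Ensemble

One random forest (scikit-learn, 500 trees by default, √d features per
split, per-member seeds derived from a master seed by hashing) is
trained per subset on the same samples; Qbc = 10 members vote, and a
site is called positive when at least half the votes are positive. The
tie at even Qbc goes to the positive class, favoring sensitivity on the
minority class; this is configurable. Out-of-bag error can be recorded
per member as a diagnostic only. A `sweep_qbc` operation evaluates
nested ensembles (first q members) to reproduce performance-vs-Qbc
curves.

## Evaluation

Leave-one-protein-out jackknife, protein-grouped label-stratified k-fold
CV (scikit-learn `StratifiedGroupKFold`), and single-pass independent
tests, all pooling predictions into one confusion table. Splits are
always protein-level; windows of one protein never straddle a split.
By default feature selection re-runs inside every training fold; a
`paper_mode` flag replicates the older select-once-then-cross-validate
protocol and logs an explicit leakage warning, because that protocol
lets test-fold labels influence the selected features.

Metrics: Sn = TP/(TP+FN), Sp = TN/(TN+FP), AC = (TP+TN)/N (all reported
as percentages) and MCC, with any zero factor in the MCC denominator
yielding 0 by the usual convention. A provenance analysis counts
selected features per family and per window site over the multiset of
subsets, mirroring the figure-style summaries used in this literature.

## Synthetic benchmark

Real corpora of verified sites plus NR-database PSSM profiles are not
redistributable, so the test bed is generated. The default
`SyntheticSpec` draws 60 proteins of 120–260 residues with lysine
density 0.075 and marks 35% of lysines positive (~290/~505 sites,
matching the ~1:1.9 imbalance of curated training sets). Signal is
planted in three channels:

* sequence motif: window sites 8, 12, 14 prefer residues D, P, W with
  probability 0.85 in positive windows (positive centers are protected
  from being overwritten);
* surrogate PSSMs: background integer log-odds ~ round(N(0, 2)), plus a
  shift of +4 (noise sd 1.5) at the motif rows of positive sites in the
  preferred-residue column and one secondary column per site;
* disorder: uniform noise smoothed with a 3-residue moving average,
  plus a bump of 0.35 within ±3 residues of positive centers, clamped
  to [0, 1].

Surrogate PSSMs are synthetic by construction — they have the right
type, range and a controllable class signal but are not PSI-BLAST
output, and motifs are not real ubiquitylation preferences. Passing
tests therefore demonstrate algorithmic correctness and recoverable-
signal behaviour, not biological performance on real proteomes.

`GroundTruth.informative_ids` lists one feature per independently
perturbed channel: the 6 shifted PSSM cells, the 7 bumped disorder
sites, and per motif site the single factor feature with the largest
absolute value for the preferred residue (16 features total). The five
factor features of a site are deterministic functions of the same
residue, and compositions are window-aggregated proxies of the same
channels; counting such copies would penalize the selector for doing
exactly what it is designed to do — eliminate redundancy.

A label-permutation operation (labels shuffled within each protein,
features untouched) provides the negative control for the whole
pipeline.

## Numerical choices and degenerate inputs

* Log base 2 throughout; estimator agreement with brute-force oracles is
  asserted to 1e−9.
* Equal-frequency bin edges are interior quantiles; duplicate edges
  collapse, so heavily tied features occupy fewer bins.
* `criterion_J` returns 0 when H(f,C) = 0; MCC returns 0 on a zero
  denominator; a constant PSSM normalizes to all 0.5; empty windows,
  even window sizes, non-lysine centers, misaligned vectors and
  unreadable files raise immediately.
* Duplicate annotations: last row wins, with a warning. Coordinates are
  1-based in every file format.

## Problem sizes used by the test suite and acceptance script

The heavy experiments run at sizes chosen to keep the default runs
comfortable on a single CPU while leaving the conclusions unchanged:
selector recovery averages 20 generator seeds in the test suite and 5 in
`scripts/acceptance.py`; cross-validated discrimination and the
permutation null use 10 and 3 seeds respectively, with 150-tree forests
(the library default stays at 500 trees). The package-level default seed
for all examples is 0.

## Known limitations

* Plug-in MI estimates are biased upward on small strata; the selector's
  pruning threshold is therefore almost never triggered on continuous
  noisy data — pruning mainly removes exact duplicates, redundancy is
  otherwise handled by the criterion itself.
* The min-over-singletons approximation of conditioning on the whole
  selected set can overestimate the novelty of a candidate that is
  jointly (but not pairwise) redundant with FS.
* Homology reduction of input corpora (cd-hit-style filtering) is
  assumed done upstream; the package does not check for it.
* With protein-level splits, metrics have high variance when few
  proteins carry most sites; reports over repeated seeds include the
  standard deviation for this reason.
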