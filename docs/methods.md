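# Methods

This note documents the models and procedures implemented in
`cladesignal`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Trees and clades

Trees are rooted, with polytomies as first-class structure; no
binarization is ever performed. A *clade* is the terminal set of a
non-root internal node, and clade identity is exact terminal-set
equality under rooted semantics (no bipartition complementation); the
root's full set and singleton terminals are never counted as clades.
Tree comparison (`compare_clade_sets`) therefore counts shared terminal
sets between the internal nodes of two rooted trees on identical
terminals — the natural notion when both inputs are rooted consensus or
best trees. Newick parsing is delegated to dendropy (quoted labels,
bracket comments); an internal node label that parses as a number is
interpreted as a support value. Unifurcations are suppressed on read.
Serialization round-trips topology, labels, lengths and supports.

## Parsimony optimization

Characters are unordered categorical with unit change cost. `"?"`
(missing) and `"NA"` (inapplicable, e.g. paratenic-host records) are
both optimized as wildcards over the character's full alphabet: they can
assume any state at zero cost and thus never create transformation
events on their own. The minimum change count uses Hartigan's
generalization of Fitch's downpass, which is exact on multifurcating
trees (hard-polytomy model: every polytomy is a true multifurcation):
each internal node keeps the states contained in the largest number of
child state-sets and pays one step per uncovered child.

ACCTRAN and DELTRAN reconstructions come from a unit-cost dynamic
program (per-node, per-state minimum subtree cost) followed by a
top-down resolution pass. The root takes the cheapest state; on each
branch the child takes a state minimizing subtree-cost plus the change
indicator. Where keeping the parental state and changing are equally
optimal, ACCTRAN changes (accelerating transformations toward the
root), DELTRAN keeps (delaying them toward the tips). All remaining
ties, including the root state, are broken by the character's declared
alphabet order, so both reconstructions are deterministic. Both always
realize the Hartigan/Fitch score; this is asserted in the tests against
an independent brute-force enumeration.

A transformation is **nonambiguous** when the two reconstructions agree
on a branch's (from, to) pair. This is one defensible operationalization
of "nonambiguous"; enumerating *all* most-parsimonious reconstructions
would be stricter, and we deliberately do not guess beyond the two
canonical flavours. Nonambiguous transformations on branches subtending
≥ 3 terminals (configurable) are classified by the derived state's
origin count and bearer distribution: *unique* (one origin, all bearers
inside the clade), *private* (several origins, all bearers inside),
*nonprivate* (bearers outside). The origin count of a state is the
number of change events into it plus one if it is the root state; where
the two flavours disagree on that count, the larger is used, resolving
reconstruction ambiguity toward homoplasy (the conservative direction:
a state is only called *unique* when every canonical reconstruction
says so). Transformations on smaller clades are reported but left
unclassified rather than dropped. Branches carrying no nonambiguous
transformation of any character can be collapsed
(`collapse_unsupported`), which on weakly structured host/biogeography
data produces the expected highly polytomic cladogram.

Note a structural consequence of MPR semantics worth knowing when
interpreting output: *private* records require an origin nested inside
the focal clade after a reversal, because two parallel origins in
disjoint clades always leave bearers outside each origin's own branch.
The test suite contains a fully forced 20-terminal example.

## Metadata curation and encoding

The metadata table has one row per terminal and ten categorical
features: host class, order, family, genus, species (CatHC, CatHO,
CatHF, CatHG, CatHS), habitat and aquatic-ecosystem type (CatE1,
CatE2), and zoogeographical realm, continent, country/river basin
(CatL1, CatL2, CatL5). Curation runs five fixed steps: (1) drop rows
whose host role is intermediate or paratenic; (2) restrict to the
requested features; (3) drop feature columns above a missingness
threshold (default only fully missing columns — the intended behaviour
is to lose rows, not features); (4) drop rows with any missing cell;
(5) drop rows without a clade label. The order matters (a row lost to
its host role should not count as a missing-data casualty) and the
operation is idempotent. An optional synonym map is applied before
curation; hierarchical consistency (each species in one genus, each
country in one continent) is checked with warnings only, never
auto-corrected.

One-hot encoding creates one binary column per observed
(feature, value) pair, named `feature=value`, ordered by feature and
first observation. Every row activates exactly one column per feature,
so the expansion is lossless (`inverse_transform` restores the curated
table exactly) and the category mapping can be persisted to JSON for
exact replay on new rows. At the cardinalities typical of a curated
tapeworm dataset of ~494 terminals — (5, 28, 63, 116, 170, 2, 3, 10, 7,
42) — the encoded width is 446 columns.

## The perturbation experiment

`perturb_labels` replaces each terminal's clade label, independently
with probability *p*, by a uniform draw over the observed clade names.
The default draw *includes* the original label (effective change
probability p·(k−1)/k); an `exclusive` variant draws over the other
k−1 names. The inclusive default makes p = 1 exactly the uniform null
with chance accuracy 1/k. Perturbation precedes the 75/25 split, so
training and validation rows both carry perturbed labels and accuracy
is scored against perturbed validation labels — the natural reading of
the protocol as a constructed null for the classifier as a whole.

Each replicate perturbs, splits (simple random, unstratified;
stratification available but off by default), fits a
`RandomForestClassifier` with 100 trees (all other hyperparameters at
scikit-learn defaults, recorded in the run log), scores plain accuracy
on the held-out 25%, and captures impurity-based importances. The full
sweep covers p = 0.00 … 1.00 in 0.01 steps with ten replicates per
level (1010 fits). The degradation regression is OLS of accuracy on
level over all replicate points (per-level means available as an
option); it reports slope, intercept, R² and the slope's two-sided
p-value; the degenerate all-equal-accuracy case returns slope 0,
R² 0 rather than an undefined ratio. Importance rankings at a level are
replicate means, ties broken lexicographically; columns are value-level
one-hot names, so the ranking speaks about attributes such as
`CatHF=…` or `CatL2=…`, not whole features.

Reproducibility: one base seed expands through
`numpy.random.SeedSequence([base, level_index, replicate])` into
per-run seeds (kept below 2³¹), and each run derives three independent
child streams for perturbation, splitting and forest fitting. Identical
inputs and seed give bit-identical results; there is no hidden global
state.

## Synthetic data

The generator plants k monophyletic clades on a random rooted binary
tree (random pairwise joins within clades, then among clade roots).
Metadata are drawn per feature *chain*: the host-taxonomy chain is
generated at the species level and propagated up a fixed
species→genus→family→order→class map (round-robin assignment keeps
every parent category populated), geography at the country level under
country→continent, with realm, habitat and aquatic type independent —
realms deliberately cut across continents. Each clade owns a designated
chain-leaf value per chain (distinct across clades where the
cardinality allows; an error if no feature can separate the clades when
disjoint profiles are requested); a terminal uses its clade's value
with probability *s* (the signal) and a uniform global draw otherwise.
Missing cells are injected i.i.d. at rate *m*; a configured fraction of
rows is flagged as intermediate/paratenic-host records for curation to
remove.

Defaults mirror the study scale this package targets: k = 8 clades,
494 terminals, ten features at cardinalities (5, 28, 63, 116, 170, 2,
3, 10, 7, 42), s = 0.9. Character matrices for the parsimony side are
generated by planting a known number of state changes on disjoint
internal branches with distinct derived states, so the planted count
equals the true minimum and the Fitch score by construction.

What the generator does *not* emulate: within-clade phylogenetic
autocorrelation (profiles are clade-level constants, not a
branch-process), host-switching dynamics, uneven clade sizes unless
configured, correlated missingness, and the label noise of real
taxonomy. Consequently the synthetic p = 0 accuracy at s = 0.9 runs
close to 1.0 — higher than reported accuracies on real curated data
(~0.89), where clade profiles overlap. Passing tests therefore
demonstrate that the machinery detects planted signal and degrades to
chance correctly, not that any particular real dataset carries signal.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 101 × 10 sweep at
the 494-terminal scale (about three minutes on one CPU) and verify the
parsimony engine against exhaustive enumeration on 200 random trees of
up to 8 terminals and 4 states — sizes chosen so the brute-force oracle
remains exact yet fast. Statistical checks use three standard errors
over ten replicates (chance-level accuracy) or twenty seeded
repetitions (signal monotonicity). Forest fits use `n_jobs=1` for
determinism across machines.

## Known limitations

* "Nonambiguous" is defined via ACCTRAN/DELTRAN agreement, not via the
  full MPR set; a transformation both flavours happen to share could in
  principle be absent from some third reconstruction.
* Tree comparison assumes both trees are rooted and defined on exactly
  the same terminals; no pruning to a common subset is attempted.
* Curation reproduces a rule set, not a curatorial history: applied to
  a real dataset it may keep or drop a handful of rows that manual
  curation treated differently, and the report is the place to check.
* The forest protocol is fixed by design (100 trees, 75/25, impurity
  importances); there is no tuning, no alternative classifiers, and no
  probability calibration.
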