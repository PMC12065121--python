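# cladesignal

Detecting host and biogeographical signal in parasite phylogenies.

Parasite groups such as proteocephalid tapeworms colonize many host
lineages across many zoogeographical realms, and their host/geography
attributes are often too homoplastic to diagnose clades by classical
character optimization: mapped onto the tree one character at a time,
almost no branch is supported by a clean synapomorphy. Yet the *joint*
distribution of those attributes may still track the phylogeny.
`cladesignal` implements both sides of that comparison as a reusable,
fully tested pipeline:

1. **Parsimony character optimization.** Categorical host and
   biogeography characters (host class/order, habitat, aquatic-ecosystem
   type, realm, continent, …) are optimized on a rooted tree with
   Fitch/Hartigan parsimony (polytomies supported, `?`/`NA` cells treated
   as wildcards). Transformations on which the ACCTRAN and DELTRAN
   reconstructions agree are classified, for clades of ≥ 3 terminals, as
   **unique** (single origin, exclusive to the clade), **private**
   (homoplastic but exclusive) or **nonprivate** (bearers outside the
   clade); branches with no nonambiguous transformation of any character
   can be collapsed into polytomies.
2. **Random-forest clade prediction under a label-perturbation null.**
   The metadata table is curated (intermediate/paratenic-host rows and
   rows with missing cells dropped), one-hot encoded, and used to predict
   clade membership with 100-tree random forests. Clade labels are
   randomized with probability *p* ∈ {0, 0.01, …, 1}; at each level ten
   replicates of a random 75/25 train/validation split are scored, and
   accuracy is regressed on *p* by OLS. A real phylogenetic signal shows
   up as a strong linear decay (negative slope, high R²) from the
   unperturbed accuracy down to the 1/k chance level, with per-column
   impurity importances ranking the attributes that drive the prediction.

Rooted trees come in as Newick (via dendropy), clade partitions as
CSV/JSON, metadata as CSV; the forests, splits and regression use
scikit-learn and statsmodels. A synthetic-data generator produces trees
with planted monophyletic clades and hierarchically nested,
clade-correlated metadata (host class ⊃ order ⊃ family ⊃ genus ⊃
species; country ⊂ continent) at a tunable signal level, so the whole
pipeline is testable end to end without any downloads.

## Worked example

Simulate a 200-terminal tree with 8 planted clades and signal 0.9, then
run the perturbation experiment at five levels:

```sh
cladesignal simulate --seed 7 --clades 8 --terminals 200 --signal 0.9 --out sim
cladesignal curate   --metadata sim/metadata.csv --clades sim/clades.csv --out cur
cladesignal encode   --curated cur/curated.csv   --clades sim/clades.csv --out enc
cladesignal predict  --encoded enc/encoded.csv \
                     --levels 0,0.25,0.5,0.75,1 --replicates 5 --seed 7 --out pred
```

which prints

```
mean accuracy at p=0.00: 1.0000
{"slope": -0.8431999999999994, "intercept": 0.9455999999999991,
 "r_squared": 0.9482041652441107, "p_value": 2.7628192349633288e-16}
```

With no perturbation the forest places every held-out terminal in its
clade (accuracy 1.0000 — the planted signal is strong and the clade
profiles are disjoint). As labels are progressively randomized, accuracy
falls linearly toward the 1/8 chance level: the OLS slope is −0.84 with
R² = 0.95 and the slope's p-value ≈ 3 × 10⁻¹⁶, i.e. the decay is highly
significant and nearly perfectly linear — the behaviour expected when
the metadata genuinely inform the clades. `cladesignal report
--prediction-dir pred` renders the accuracy-vs-perturbation scatter with
the fitted line and the top-importance bar charts, each with a JSON
sidecar.

The same operations are available as a library: `parse_newick`,
`extract_clades`, `compare_clade_sets`, `fitch_score`,
`classify_transformations`, `collapse_unsupported`, `curate`,
`CladeOneHotEncoder`, `PerturbationSweep` (a scikit-learn estimator:
`fit(X, y)` exposes `runs_`, `regression_`, `result_`), and the
`SyntheticConfig`/`make_*` generator family. See `docs/methods.md` for
the model details and design choices.

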