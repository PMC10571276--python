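# Methods

This note documents the models and procedures implemented in `gutperm`,
the assumptions behind them, the parameters that matter, and what the
synthetic benchmarks do and do not establish.

## The gut-permanence problem

A molecule administered or produced in the intestine either crosses the
gut wall (by passive diffusion or mediated transport) or remains in the
lumen. The package operationalizes this as a binary label derived from
biospecimen evidence: molecules detected in both gut and serum, and oral
systemically acting drugs, are **Traversers**; molecules detected only in
the gut, plus all members of the four fatty-lipid (FL) classes —
Glycerolipids, Glycerophospholipids, Fatty acyls, Sphingolipids — are
**Lingerers** (the positive class). The FL classes are treated as
lingering regardless of serum detection because they are hydrolyzed by
lumenal lipases before absorption and resynthesized on the serosal side;
their serum presence reflects de novo synthesis, not permeation. This
label inherits an acknowledged approximation: serum detection of any
metabolite can in principle be de novo synthesis rather than gut-wall
crossing, so a small fraction of Traverser labels may be misassigned. The
label semantics document this; nothing in the code attempts to resolve it.

## Curation

Structures are normalized to a canonical neutral parent with RDKit's
`rdMolStandardize`: cleanup, largest-organic-fragment selection (salt and
solvent stripping), charge neutralization where chemically valid, then
canonical SMILES. The operation is idempotent, and structure identity
everywhere downstream is canonical-SMILES string equality (one
canonicalizer, no second fingerprint of identity). Stereochemistry is
retained by default; `strip_stereo=True` compares stereo-flattened
structures at deduplication.

Quantification-status filtering keeps `quantified` and
`detected_not_quantified` rows (configurable). Missing pKa cells are kept
absent — never imputed from structure — because downstream ionization
semantics define what absence means. When the same normalized structure
occurs in the drug set and a metabolite set, the drug-set record survives;
metabolite-internal duplicates merge their gut/serum flags.

## Ionization classes

At environment pH `ph`, a molecule has an ionized acidic group iff its
strongest-acidic pKa < `ph`, and an ionized basic group iff its
strongest-basic pKa > `ph` (strict inequalities; equality creates no
group). The class is the truth table over those booleans: acid, basic,
neutral, zwitterion. A missing pKa means the group is absent. Shipped pH
presets cover intestinal regions: 6.0 (duodenum), 6.4 (caecum), 7.0
(descending colon, jejunum), 7.4 (sigmoid/rectum/ileum — the default).
Membership is binary; no fraction-ionized or microspecies computation is
attempted. Implausible database pKa values are passed through unfiltered;
callers can screen them upstream.

## Descriptors, scaffolds, fingerprints

The 10 descriptors use RDKit's standard definitions. `hbd`/`hba` are the
Lipinski-style N/O-based counts (`NHOHCount`, `NOCount`), matching the
conventions under which the rule thresholds below were originally stated.
Ring counting follows the toolkit's SSSR convention. Scaffolds are
non-generic Bemis–Murcko frameworks (atom and bond types retained);
ringless molecules have none. Per-set scaffold statistics average ring
counts and ring-type fractions over *unique* scaffolds, while the
percentage of molecules bearing a scaffold is over all molecules. A ring
is aromatic when all its bonds are aromatic and hetero when it contains a
non-carbon atom; heteroaromatic rings count toward both fractions.
Fingerprints are RDKit path fingerprints at their defaults (2048 bits,
maximum path 7 bonds); Tanimoto is |AND|/|OR| with 0/0 defined as 0.

## Statistics

* **CLES** — P(X > Y) + ½·P(X = Y) by exact pair counting; values > 0.5
  mean the first sample sits higher.
* **Kruskal–Wallis + Conover** — the omnibus test uses tie-corrected
  ranks; for > 2 groups the Conover–Iman all-pairs post-hoc uses pooled
  tie-corrected ranks, the pooled-rank variance S², the
  chi-square-adjusted scale (N−1−H)/(N−k) and Student's t with N−k df,
  two-sided. Pairwise p-values are BH-adjusted.
* **Mann–Whitney grid** — one two-sided test per (class × property) cell,
  corrected with Benjamini–Hochberg *jointly across all tested cells* (the
  conservative pooled reading; a per-property family would be less
  stringent). Cells missing either group are excluded from the family.
  Direction comes from CLES against 0.5.
* **Contingency post-hoc** — expected counts from the independence model;
  adjusted residual r = (O−E)/√(E(1−rowfrac)(1−colfrac)). The cell-wise
  exact test collapses each cell to a 2×2 table (cell vs rest-of-row /
  rest-of-column) and applies the two-sided Fisher exact test; this
  collapse-plus-exact-test construction is implemented behind a small
  function boundary so an alternative cell test can be swapped in.
  Significance uses Bonferroni (default) or BH across all R·C cells of
  the analyzed table; direction is the residual sign. Cells in a zero
  margin are flagged untestable. For 2×2 tables every squared adjusted
  residual equals the Pearson chi-square statistic — used as a test
  oracle. All tests are two-sided with α = 0.05 by default.

## Rule baselines

Reversed Lipinski: Lingerer iff at least two of {mw > 500 Da, logp > 5,
hba > 10, hbd > 5}. Reversed Veber: Lingerer iff tpsa > 140 Å² or
rb > 10. Inequalities are strict, thresholds immutable; the violation
count is returned for diagnostics (near-misses matter when analyzing the
rules' false negatives). These are fixed baselines, never calibrated.

## Super Learner

Features: the 10 descriptors, the 4 ionization-class dummies and 17
chemical-class dummies — 31 predictors. The chemical-class vocabulary is
closed to 17 named classes plus "Other"; "Other" and unseen labels map to
an all-zero class block (the ionization block always one-hot sums to 1).
Standardization (per-column mean/sd) is fitted on training rows only and
reused verbatim for test rows; constant columns get unit scale.

Nine scikit-learn base classifiers at library defaults (logistic
regression, decision tree, SVM with probability output, Gaussian naive
Bayes, k-NN, AdaBoost, bagging, random forest, extra trees) are each run
over the same label-stratified 7-fold split of the training data, and the
out-of-fold positive-class probabilities form the n × 9 meta matrix —
probabilities rather than hard labels so the stack yields a continuous
score for AUROC/AUPRC. The meta-model is near-unpenalized logistic
regression (C = 10⁶) on the raw probabilities (not re-standardized). The
base models are then refit on the full training data; prediction runs the
refit bases and feeds their probabilities to the meta-model. Class = 
probability ≥ 0.5 (ties positive). Because meta-features are out-of-fold,
no base learner's training signal leaks into the meta-fit, which is what
gives stacking its guarantee of asymptotically matching the best base
learner.

Outer evaluation uses 8 folds stratified by chemical class (per-class
round-robin deal after a seeded shuffle, so per-class fold sizes differ by
at most one); fold 0 is the external test. Alternatively, Butina
sphere-exclusion clustering of path fingerprints at Tanimoto similarity
0.8 yields structure-disjoint splits: whole clusters are shuffled and
assigned to the test side until ~1/8 of the molecules is reached, and a
run aborts if a single cluster is too dominant to leave a usable split.
Fold stratification uses chemical class only (not the permanence label);
with the benchmark's class-stratum coupling this also keeps label
proportions approximately balanced.

Evaluation reports accuracy, precision, recall, F1 at threshold 0.5, plus
AUROC and AUPRC (average precision, the step-wise integral) for the whole
test set and for its FL / noFL subsets. **Standardized** metrics are the
arithmetic mean of the FL and noFL values, correcting for the imbalance
between the large homogeneous FL stratum and the harder noFL remainder;
AUROC is reported as absent for one-class subsets.

## Synthetic benchmarks

The generator emits chemically valid, normalization-stable structures from
closed template grammars, with per-stratum pKa annotations drawn from
truncated normal distributions (pKa is emulated database metadata, not
predicted from structure):

* **FL stratum** — triacylglycerols (60%), 1,2-diacylglycerols (20%) and
  neutral dimethyl-phosphate diacyl phosphoglycerides (20%) with saturated
  acyl chains drawn uniformly from C14–C20 by default, the
  palmitic/stearic band that dominates dietary glycerides. This yields the
  fatty-lipid profile: ringless, fsp3 > 0.9, hbd ≤ 1, mw > 500,
  rb > 10, neutral-dominated with an acid minority. The grammar is
  deliberately ester-based: free fatty-acid monomers would satisfy the
  forward rule-of-five and belong chemically to the small-acid territory
  of the noFL grammar; the fatty-acyl chemotype enters as the ester-bound
  chains and through the "Fatty acyls" class labels.
* **noFL stratum** — short mono-/di-carboxylic acids, polyols,
  pyranose-like sugars, amino-acid-like fragments, phenols/benzoic acids
  and an arenesulfonic acid; median mw < 350, ≤ 2 rings; acid/zwitterion
  enriched, purely basic molecules nearly absent.
* **Traverser stratum** — aromatic/heteroaromatic cores (benzene,
  pyridine, pyrimidine, indole, quinoline, benzimidazole, thiophene,
  furan, biaryl, piperidine, anilide) crossed with small substituents;
  ≥ 90% rule-of-five compliant, neutral/basic enriched. Half are emitted
  as drug-set records and half as gut+serum metabolites so both Traverser
  assembly routes are exercised.

`label_noise` flips permanence labels only (never structures or
descriptors) and records every flip in the truth table; `separation < 1`
mixes the noFL and Traverser grammars structurally (a fraction of each
stratum is drawn from the other's grammar) to soften the class boundary.
Defaults are noiseless and fully separated.

**What the benchmark shows and does not show.** Passing tests on this
benchmark demonstrates the correctness of the machinery — curation,
feature construction, leak-free stacking, evaluation arithmetic — and the
qualitative behavior of the rules (perfect on FL, poor on noFL). It does
not estimate real-data performance: real gut metabolomes have overlapping
strata, annotation errors, far more chemotypes, and class frequencies the
grammars do not reproduce. External metrics near 1.0 here reflect the
designed separability, not expected accuracy on database extracts.

## Numerical choices and problem sizes

Default benchmark sizes are 400 molecules per stratum (n = 1200), chosen
so stacking statistics are stable while a full train/evaluate cycle runs
in seconds on one CPU; the acceptance script and heavy tests use this
size, smaller fixtures (40–150 per stratum) serve the smoke tests. All
randomness flows from explicit integer seeds; one master seed is split
into per-stage seeds in the pipeline, and reruns are numerically
identical. Degenerate inputs are defined rather than crashed on: empty
fingerprint pairs have similarity 0, constant feature columns standardize
with unit scale, one-class evaluation scopes drop AUROC, zero-margin
contingency cells are untestable.

## Known limitations

* Ionization is binary class membership from two reported pKa values; no
  microspecies distribution, and database pKa outliers pass through.
* The permanence label is phenomenological: it cannot distinguish
  transport mechanisms, and de novo serum synthesis can misassign
  Traversers.
* The chemical-class vocabulary is closed; molecules outside it inform the
  model only through descriptors and ionization.
* Base-learner hyperparameters are library defaults (no search, no
  probability calibration), so the stack's headroom on hard real data is
  unexplored here.
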