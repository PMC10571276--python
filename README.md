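# gutperm

Cheminformatic characterization of human gut metabolites and
structure-based prediction of **in vivo gut permanence** — whether a
molecule stays in the intestinal lumen (a *Gut Lingerer*) or crosses the
gut wall (a *Gut Traverser*). The package is aimed at people designing
gut-targeted drugs and nutraceutics, who need compounds that act locally in
the intestine with minimal systemic exposure, and at metabolome researchers
who want to predict the compartment where a molecule will be found.

## What it does

Starting from compound tables (CSV/TSV or SDF) carrying SMILES, gut/serum
biospecimen flags, strongest-acidic/basic pKa values and a
ClassyFire-style chemical-class annotation, the library:

* **curates** structures — normalization to the canonical neutral parent
  (largest organic fragment, charge neutralization), quantification-status
  filtering, cross-source deduplication (drug-set records win ties);
* **assembles the compound sets** — Gut / Gut-Serum / Serum / DrugBank
  partitions; reassignment of the four "fatty lipid" (FL) classes
  (Glycerolipids, Glycerophospholipids, Fatty acyls, Sphingolipids) from
  Gut-Serum to Gut, since these are hydrolyzed by lumenal lipases and
  cannot cross the gut wall intact; the Gut-FL / Gut-noFL split; and the
  binary permanence labels (Lingerer = Gut-FL ∪ Gut-noFL, the positive
  class; Traverser = DrugBank ∪ updated Gut-Serum);
* **describes molecules** — the 10 descriptors (tpsa, logp, rb, hbd, hba,
  mw, nring, naring, qed, fsp3), non-generic Bemis–Murcko scaffold
  statistics, 2048-bit path fingerprints and maximum-Tanimoto similarity
  profiles;
* **classifies ionization** — acid / basic / neutral / zwitterion from the
  pKa pair at a configurable intestinal pH (strict inequalities:
  acidic group iff pKa_acid < pH, basic group iff pKa_base > pH);
* **tests hypotheses** — Kruskal–Wallis with Conover post-hoc and CLES
  effect sizes, Mann–Whitney grids with joint Benjamini–Hochberg
  correction, and contingency-table adjusted residuals with cell-wise
  exact Fisher post-hoc under Bonferroni correction;
* **predicts permanence** — reversed Lipinski (Lingerer iff ≥ 2 of
  mw > 500, logp > 5, hba > 10, hbd > 5) and reversed Veber (tpsa > 140 or
  rb > 10) baselines, and a from-scratch **Super Learner**: nine
  scikit-learn base classifiers are cross-validated over the training data
  to build an n × 9 matrix of out-of-fold probabilities, a logistic
  meta-model is fitted on that matrix, and the base models are refit on the
  full training data. Features are the 10 descriptors plus one-hot
  ionization (4) and chemical class (17) — 31 standardized predictors.
  Stratified random folds (chemical-class proportions preserved) and
  structure-disjoint Butina-cluster splits (Tanimoto 0.8) are provided.

A synthetic-data module generates fully labeled benchmark libraries from
closed template grammars (acylglycerol-like FL stratum, small-polar noFL
stratum, drug-like Traverser stratum) so the entire pipeline is testable
without any database download.

## Worked example

`examples/04_rules_vs_superlearner.py` builds a 450-molecule benchmark,
holds out one stratified fold and compares the rule baseline with the
stack:

```
training on 393 molecules, external test on 57
reversed Lipinski  F1 all=0.691  F1 stand=0.500
Super Learner      F1 all=0.960  F1 stand=0.959  AUROC=1.000
```

The "stand" (standardized) values average the FL-subset and noFL-subset
metrics, adjusting for the dominance of the easy, homogeneous fatty-lipid
stratum. The reversed rule is nearly perfect on FL molecules but collapses
on the small polar noFL Lingerers (its standardized F1 drops to 0.5); the
Super Learner recovers both subsets. The other scripts in `examples/`
demonstrate curation and set assembly, descriptors/scaffolds/similarity,
and ionization/enrichment analysis.

A thin CLI mirrors the library (`gutperm simulate | curate | assemble |
describe | ionize | stats | rules | train | evaluate | run-all`); see
`gutperm --help`.

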