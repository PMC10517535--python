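# Methods

## The model

`ecbs` implements similarity learning over chemical pairs. Instead of
classifying single compounds as active/inactive against a target, a random
forest classifies *pairs* of compounds as evolutionarily related or not:

* **Positive pairs (ERCPs)** are pairs of compounds that bind a common
  target (target scope) or bind targets sharing a protein-family annotation
  (family scope, one model per family database such as PFAM/SMART/SUPFAM).
* **Negative pairs** pair known actives with randomly drawn compounds,
  which are overwhelmingly likely to be unrelated.

A pair (a, b) is represented symmetrically from binary fingerprints: per
fingerprint kind, the AND of the two bit vectors (shared substructure)
concatenated with the XOR (differing substructure), kinds concatenated in a
declared order. This makes score(a, b) = score(b, a) structural rather than
a property to be learned. The published work does not print its pair
feature map; the AND⊕XOR construction is this package's own declared
choice, recorded in each model's `feature_spec`.

The similarity score of a library compound is the **maximum** pair score
against a panel of reference actives; virtual screening thresholds that
maximum (default 0.8).

### Iterative retraining

After an experimental round, compounds are labeled from percent-of-control
at 10 μM: POC < 20 active, POC > 80 inactive, the band between is ambiguous
and dropped. Four pairing schemes fold the new data back in:

| scheme | pairs | label |
|--------|----------------|----------|
| PP | P_new × P_prv | positive |
| NP | N_new × P_prv | negative |
| NN | N_new × N_prv | negative |
| PN | P_new × N_new | negative |

Only PP pairs are positive. NP pairs are the important ones in practice:
they pair *near-miss inactives* (structurally similar to actives but
experimentally inactive — exactly the false positives of the previous
model) with known actives, carving true-negative structure out of the
region the initial model over-scores. Retraining is a full refit on the
union of old and new pairs; forests are cheap at this scale and refitting
avoids order-dependence. PP does not, by default, include pairs among the
new actives themselves — new actives are paired with *known* actives; a
flag enables internal pairs.

## Fingerprints

| kind | length | construction |
|------|--------|--------------|
| `MACCS166` | 166 | RDKit MACCS keys, placeholder bit 0 dropped |
| `SUBSTRUCT_FP4` | 160 | ordered catalog of functional-group SMARTS shipped with the package |
| `MORGAN_R2_1024` | 1024 | Morgan, radius 2 |
| `PATH5_2048` | 2048 | path/subgraph fingerprint, paths ≤ 5 bonds ("RDK5") |
| `FCFP6_LIKE` | 1024 | Morgan radius 3 with pharmacophoric feature invariants |

`SUBSTRUCT_FP4` and `FCFP6_LIKE` are stand-ins for pattern fingerprints
whose exact bit definitions are tied to other software (Open Babel FP4,
Discovery Studio FCFP_6) and cannot be reproduced bit-for-bit; both are
fully specified by this package (the SMARTS catalog ships in
`src/ecbs/data/`, frozen in order) and are recorded in model metadata so a
model is never scored with fingerprints other than the ones it was trained
on. Pair models default to `MACCS166 + SUBSTRUCT_FP4`; clustering of tested
molecules defaults to `PATH5_2048`; the novelty similarity filter defaults
to `FCFP6_LIKE`.

Multi-fragment SMILES are reduced to the largest organic fragment before
fingerprinting (screening libraries contain salt forms). Tanimoto
similarity of two all-zero fingerprints is defined as 0, not NaN, so
degenerate records cannot poison a screen.

## Forest and determinism

Forests use 500 trees, sqrt-of-features candidate splits and probability
output — the defaults of the ranger-style forests this protocol was
designed around. All randomness (forest seeding, negative-pair sampling,
fold assignment, synthetic generation) flows from explicit integer seeds;
training sorts pairs into canonical (lexicographic id) order first, so a
fixed seed and fixed pair *set* give bit-identical predictions regardless
of input order.

## Evaluation protocol

Pair models see every compound in many pairs, so pair-level CV leaks.
Evaluation therefore splits *compounds* (sevenfold by default) and takes
every pair touching a held-out compound as that fold's test set. The test
set is **common** across all scheme combinations being compared — AUCPR
baselines depend on test prevalence, and holding the test set fixed makes
the numbers comparable; only training data varies. Scheme pairs touching
held-out compounds are excluded from training (asserted, not assumed).

Two protocol details are under-determined in the published description and
decided here:

* The pair universe from which the common test set is drawn is the base
  pairs plus the pairs of every scheme appearing in any requested
  combination. This is the only reading under which the "None" baseline and
  the retrained models can differ on a *common* test set: the test set then
  contains the near-miss pairs the baseline misranks.
* Only the target's own chemicals (members of positive pairs plus newly
  assayed compounds) are split into folds; the random-negative pool always
  stays in training. Actives form their own stratum so every fold's test
  set contains positive pairs. Random negatives are sampled once globally
  and then split, not re-sampled per fold.

AUCPR is step-wise average precision: traverse distinct thresholds in
descending score order (ties grouped at one threshold — forest
probabilities tie often) and sum ΔRecall × Precision. No interpolation, so
random rankings score near the positive prevalence instead of being
optimistically inflated.

## Screening pipeline

1. Score the library; keep compounds with best-pair score ≥ 0.8
   (inclusive).
2. Exclude hits whose maximum Tanimoto similarity to known actives is
   strictly greater than 0.47 (equality keeps the hit — the cutoff is an
   empirical p ≈ 0.01 similarity threshold, and "higher than" is read
   strictly).
3. Optional external exclusion hooks (e.g. a pharmacophore-match predicate
   computed by other software; pharmacophore modelling itself is out of
   scope here). The PAINS hook flags pan-assay interference structures but
   does not exclude by default — flagged compounds are a triage concern,
   not automatically invalid.
4. Butina-style leader clustering of the survivors (neighbors = Tanimoto ≥
   0.6) and selection of cluster centers as the minimal conserved scaffolds
   to test. The center is the leader — the compound with the most
   unassigned neighbors at selection time, ties broken by id. Note RDKit's
   Butina implementation sorts by *initial* neighbor count; this package
   recomputes neighbor counts among unassigned compounds at each step, per
   its documented rule, and is tested against an independent brute-force
   simulation of that rule.

## Synthetic data

The generator produces the regime the method is designed for, in two modes:

* **SMILES mode** (default): actives for a target share a scaffold core
  (quinazoline, benzimidazole, quinoline, ... — one per target) decorated
  with random substituents; near-miss inactives carry the same scaffold
  plus an activity-breaking group (sulfonamide, carboxylate, quaternary
  amine, ...); decoys are random assemblies from unrelated cores. Built
  with RDKit fragment zipping, so the full chemistry stack is exercised.
* **Abstract mode**: fingerprints sampled directly — scaffold bits shared
  within a target (dropped with probability `noise_rate`, default 0.05),
  breaker bits for near-misses, Bernoulli background (rate 0.08). Fast and
  toolkit-version independent; used for model/evaluation unit tests.

Default conditions: 2 family-related targets, 12 actives and 12 near-misses
per target, 60 decoys. An experimental round samples 4 new actives and a
dozen-odd new inactives with synthetic POC values in [0, 15] / [85, 100] so
labels round-trip the 20/80 bounds with margin. Affinities are log-uniform
on 1 nM–1 μM; previous-negative pools are ~4× the previous actives,
matching the typical NN:PP size ratio.

What the generator does **not** emulate: realistic medicinal-chemistry
property distributions, activity cliffs subtler than one breaker group,
assay noise in POC values, tautomer/stereo complexity, or library-scale
diversity. Passing tests show the machinery is correct and that the
NP-retraining effect appears when near-miss false positives exist; they do
not show the effect size on any real target.

## Problem sizes in the shipped checks

The acceptance script (`scripts/acceptance.py`) uses 10 replicate universes
at the default configuration for the retraining comparison (sevenfold CV,
three scheme combinations) and 10 replicates of a 2,000-compound library
(25 planted actives) for enrichment — sizes chosen so a complete from-
scratch run finishes in minutes on one CPU while leaving the qualitative
comparisons (NP > None; planted > background) clearly resolved.

## Known limitations

* Family-scope ensembles are implemented and tested, but the headline
  simulations use the target scope; with the default two-target universe
  the family scope mainly adds cross-scaffold positives.
* The forest is scikit-learn's; ranger's exact tree-building differs in
  detail, so absolute probabilities are not comparable across
  implementations (rankings, the quantity used everywhere, are).
* Abstract-mode compounds have no structures; operations requiring a mol
  (PAINS, substructure search, SDF export) raise a clear error for them.
* `aucpr` requires both classes in the test set; the evaluator's stratified
  compound split guarantees this by construction rather than skipping
  folds.
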