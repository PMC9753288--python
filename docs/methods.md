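# Methods

This note documents the models, rules and numerical conventions behind
`herbscreen`, the defaults and why they were chosen, what the synthetic
generators emulate, and the package's known limitations.

## Bioactivity curation

Input records carry `(compound_id, target_id, measure, value, units)`.
Curation keeps only IC50 and Ki records (pooled without a Cheng–Prusoff
correction — both measure a half-inhibition potency and mixing them is
the common pragmatic choice when assay metadata is unavailable), requires
a resolvable structure and a positive value, and converts nM/µM/mM/M to
nM. Every drop carries a reason code (`wrong-measure`, `no-structure`,
`bad-value`, `bad-units`) and per-reason counts reconcile with the input
count.

Replicates are collapsed with the unweighted arithmetic mean on the
linear nM scale, not the log scale. Averaging potencies in log space is
arguably more principled for multiplicative assay error, but the linear
mean is the simpler, stated convention here and is what the tests freeze.

The activity cutoff defaults to **1000 nM (1 µM)** with a *strict-less*
boundary: mean < cutoff → active, mean == cutoff → inactive. Both the
value and the boundary convention are explicit parameters/documentation
because potency splits vary by project; 1 µM is the conventional
mid-range split that keeps both classes populated for typical inhibitor
datasets.

## Descriptor families

**CATS (topological pharmacophore pairs).** Atoms are typed by SMARTS
rules shipped in `herbscreen/data/ppp_rules.yaml` (overridable):

| type | meaning | default rule |
|------|---------|--------------|
| D | H-bond donor | N or O with ≥1 H |
| A | H-bond acceptor | any N or O |
| P | positively ionizable | formal + charge, or sp³ amine not amide/anilide-like |
| N | negatively ionizable | formal − charge, or carboxylic-acid carbon |
| L | lipophilic | carbon bonded only to C/H |

An atom may carry several types or none. The vector has 15 unordered
type pairs × 10 bond-path distance bins (0–9) = 150 entries; a pair of
*distinct* atoms contributes once to each unordered type pair it
realizes. Self-pairs are excluded, so distance-0 bins are identically
zero and retained only for layout stability. `occurrence` scaling
divides each (t1,t2) block by (#atoms typed t1 + #atoms typed t2), 0/0 →
0; the raw (integer-count) mode is the QSAR default, occurrence scaling
is used where vectors of differently sized molecules are compared
(CATS nearest-neighbor target prediction). The implementation is
verified bin-for-bin against an independent Floyd–Warshall brute-force
enumeration in the test suite.

**Structural keys.** The public 166-key fragment fingerprint, computed
by RDKit (its 167-bit layout has an unused bit 0, which is dropped).

**2D panel.** A fixed, named panel of 27 graph-derived descriptors (MW,
heavy atoms, Crippen logP and MR, TPSA, HBD/HBA, rotatable bonds, ring
counts, fraction Csp³, heteroatom/halogen counts, formal charge, Balaban
J, Bertz complexity, Chi0/Chi1, Kappa1–3, Hall–Kier alpha, Labute ASA,
Wiener index, valence electrons). A descriptor undefined for a graph
(e.g. a topological index on a disconnected graph) maps to the sentinel
0 so matrices never carry missing values. The panel is a documented,
open stand-in for the broader proprietary 2D descriptor blocks used in
commercial suites; the three-family consensus architecture is unchanged
by the exact membership.

All descriptors are purely topological: stereochemistry is retained in
canonical SMILES but never influences features. Salts/mixtures are
reduced to the largest covalent fragment before anything else.

## Consensus QSAR

One `RandomForestClassifier` per family with defaults: 500 trees, √p
features per split, unlimited depth, `balanced_subsample` class weights
— robust settings for wide descriptor matrices, all overridable. The
consensus is the **unweighted arithmetic mean** of the three member
probabilities (majority voting is expressible by thresholding members
individually, but the mean is the minimal, smooth choice and is what the
screening threshold applies to). Candidate calls are **strict**:
`p > 0.5`, so exactly 0.5 is a non-candidate.

Cross-validation is stratified 5-fold (scikit-learn's splitter behind a
surface that errors when a class has fewer members than folds),
deterministic per seed. ACC is computed at the same 0.5 threshold used
for screening; AUC is the rank-based Mann–Whitney statistic with midrank
tie handling. All member fitting happens inside the training fold; a
dedicated test confirms held-out labels cannot influence fold
predictions.

## Target prioritization

Four internal methods replace version-unstable online services while
keeping their strategies:

1. **nn** — max Tanimoto (structural keys) to a target's ligands;
   predicted at score ≥ 0.7.
2. **sea** — sum of query–ligand Tanimotos ≥ 0.57 (the published
   similarity-ensemble pairwise cutoff), standardized against `n_null`
   (default 500) random same-size ligand sets drawn from the pooled
   reference universe; predicted at z ≥ 3. Zero null variance maps to
   z = 0 (raw equal to null mean) or ±∞.
3. **bayes** — Bernoulli naive Bayes per target over key bits with
   Laplace α = 1, scored as log posterior odds against a pooled
   background model; default prior odds 1, so prediction means the
   likelihood favors the target over background.
4. **cats_nn** — nearest neighbor in occurrence-scaled CATS space,
   score 1/(1 + Euclidean distance); predicted at score ≥ 0.35.

The consensus keeps targets predicted by ≥ `min_methods` (default 3)
methods. For ranking, each method's scores are min–max normalized within
the method before averaging, since Tanimotos, z-scores and log-odds live
on incomparable scales. Enrichment is the upper-tail hypergeometric
P(X ≥ k) with Benjamini–Hochberg adjustment across pathways.

## ADMET filtering

Endpoint values are inputs, not predictions. The default closed-interval
rules: logP ∈ [0, 3]; HIA, F30, BBB favorable probability ≥ 0.7; hERG,
H-HT, Ames risk probability ≤ 0.3; T½ ≥ 0.5 h. Boundary values pass.
These encode the conventional "favorable absorption, low toxicity" bands
of public ADMET predictors and are fully overridable; candidate
selection by default demands all 8 endpoints pass. `overlap_counts`
exports the pass-subset intersection counts that back an upset-style
plot.

## Cascade

Stages run in fixed order (tags → docking top-k → QSAR threshold → ADMET
clean sweep), so survivor sets are nested by construction and the
per-compound trace accounts for every elimination. Docking scores are
external; more-negative-is-better by default, top-k boundary ties broken
by ascending compound id. Missing score or ADMET rows are an error in
strict mode (default) and a logged drop in lenient mode. Reports contain
a config digest and seed but deliberately no wall-clock timestamps, so a
rerun with identical inputs is byte-identical — reproducibility is
treated as more valuable than embedded provenance timestamps, which
belong in external run logs.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed). The library grammar
combines six ring cores with ~23 substituents and plants one of five
"active chemotype" motifs (sulfonamide, CF₃, 4-chloroanilide,
furan-2-carboxamide, phenylsulfone) at configurable rates — 35% among
tagged compounds, 8% elsewhere. Defaults mirror the screening study's
shapes: 1,616 compounds, exactly 114 tagged with both `tumor` and
`inflammation`, docking top-k 25.

Bioactivity: a compound is truth-active with probability
0.5 + signal/2 if it carries a motif (0.5 − signal/2 otherwise; default
signal 0.9), flipped at the label-noise rate (default 0.05); potencies
are drawn log-normally (log₁₀ nM ~ N(2.0, 0.4) for actives, N(4.0, 0.4)
for inactives) truncated 0.05 log units away from the cutoff, so the
noiseless full-signal limit reproduces ground truth exactly even with
replicate jitter (multipliers clipped to [0.9, 1.1]). Replicates (rate
0.3, 2–3 copies) and mixed units (30% µM, 5% mM, plus 5% EC50 records)
exercise the curation rules. Docking scores are −(5·latent + ε),
ε ~ N(0, 1), with latent ∈ [0.7, 1] for motif carriers and [0, 0.3]
otherwise. ADMET endpoints pass independently at rate 0.85, with values
drawn inside bands strictly within/outside the default rules.

What this does **not** emulate: real medicinal-chemistry property
distributions, activity cliffs, correlated assay noise across databases,
target promiscuity, or structurally related-but-distinct chemotypes.
Passing tests therefore demonstrate that the pipeline's *logic* is
correct and that it recovers planted signal under controlled conditions
— not that any particular real-world screen would reach the same
accuracy.

Problem sizes used by the test suite and the acceptance script — a
500-compound modeling set for cross-validation and null calibration, 40
seeded trials per target-prediction method, and the full 1,616-compound
cascade — were chosen as the smallest sets on which the measured rates
are stable across seeds.

## Known limitations

- Pharmacophore typing is rule-based and graph-only; protonation states
  and tautomers are not enumerated.
- The Bernoulli-Bayes method ignores bit correlations (naive assumption).
- The similarity-ensemble null uses empirical z-scores, not an
  extreme-value fit, so very small reference sets give noisy z.
- IC50/Ki pooling and linear-scale averaging blur assay heterogeneity.
- No applicability-domain estimate accompanies consensus probabilities.
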