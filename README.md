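# herbscreen

Ligand-based virtual screening for natural-product libraries: curate public
bioactivity records into a modeling set, train a **consensus QSAR** model
over three descriptor families, prioritize likely protein targets with a
four-method similarity consensus, filter on eight ADMET endpoints, and
orchestrate everything as an auditable screening cascade.

The package is aimed at computational chemists who want the *screening
logic* of a docking + QSAR + ADMET campaign as reproducible, testable
code. Docking itself is deliberately external: the cascade ingests a
docking-score table produced by whatever engine you use.

## The method

**Curation.** Raw potency records (compound, target, measure, value,
units) are reduced to one row per compound: only IC50/Ki records with a
resolvable structure and a positive value are kept, all values are
converted to nM, replicates are collapsed to their arithmetic mean, and a
compound is labeled *active* iff its mean potency is strictly below a
configurable cutoff (default 1000 nM = 1 µM).

**Consensus QSAR.** Three descriptor families view each molecule: the
CATS topological pharmacophore-pair histogram (5 atom types D/A/P/N/L ×
15 unordered type pairs × bond-path distances 0–9 → 150 bins), the public
166-key structural-fragment fingerprint, and a fixed 27-descriptor 2D
physicochemical panel. One random forest is trained per family; the
consensus probability is the unweighted mean

    p_consensus(x) = (p_cats(x) + p_keys(x) + p_panel2d(x)) / 3

and a compound is a screening candidate iff `p_consensus > 0.5` (strict).
Models are judged by stratified 5-fold cross-validation (accuracy at the
0.5 threshold; rank-based AUC with midrank ties), with members always
fitted inside the training fold.

**Target prioritization.** Four ligand-similarity methods score
user-supplied reference ligand sets per target — max-Tanimoto nearest
neighbor, a similarity-ensemble z-score against a random-set null, a
Bernoulli naive-Bayes over fingerprint bits, and a CATS-space nearest
neighbor — and targets predicted by at least 3 of the 4 form the
consensus, with hypergeometric pathway enrichment (Benjamini–Hochberg
adjusted) on top.

**Cascade.** `tags → docking top-k → p_consensus > 0.5 → ADMET clean
sweep`, with nested survivor sets, a per-compound audit trace and
byte-reproducible reports.

A synthetic-data module generates every input — compound libraries from a
scaffold/substituent grammar with planted active-chemotype motifs,
bioactivity records, docking scores, ADMET tables, reference sets — so
the whole pipeline runs and is tested without any external data.

## Worked example

```sh
python examples/06_full_cascade.py
```

prints (seed 42):

```
stage survivors:
  tags       114
  docking     25
  qsar        21
  admet        6
final candidates: c00511, c00701, c00910, c01387, c01549, c01602
```

1,616 synthetic compounds enter; 114 carry both the `tumor` and
`inflammation` tags; the docking stage keeps its top 25; 21 of those
exceed the 0.5 consensus probability; 6 pass all eight ADMET endpoints.
`examples/03_train_consensus_qsar.py` shows the model quality behind
stage 3 (n=300, seed 7):

```
  cats       mean ACC 0.827  mean AUC 0.864
  keys       mean ACC 0.880  mean AUC 0.895
  panel2d    mean ACC 0.873  mean AUC 0.892
  consensus  mean ACC 0.877  mean AUC 0.905
```

The other examples (`examples/01…05`) each demonstrate one capability:
curation, descriptors, QSAR, target prediction, ADMET filtering. The same
functionality is scriptable via the `herbscreen` CLI
(`simulate`, `curate`, `featurize`, `train`, `predict-targets`, `admet`,
`run`).

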