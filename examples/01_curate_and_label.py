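"""Curate raw potency records into a binary-labeled modeling dataset.

Builds a handful of IC50/Ki records with mixed units and replicates, runs
curation -> deduplication -> labeling, and prints the per-compound means
and labels.
"""

from collections import Counter

from herbscreen import CompoundLibrary, CompoundRecord, BioactivityRecord
from herbscreen.curation import curate, deduplicate, label

structures = CompoundLibrary([
    CompoundRecord("c1", "CCO"),
    CompoundRecord("c2", "c1ccccc1O"),
    CompoundRecord("c3", "CC(=O)Oc1ccccc1C(=O)O"),
])

records = [
    BioactivityRecord("c1", "TGT1", "IC50", 100, "nM"),
    BioactivityRecord("c1", "TGT1", "Ki", 0.3, "uM"),     # 300 nM replicate
    BioactivityRecord("c2", "TGT1", "IC50", 2.5, "uM"),   # 2500 nM
    BioactivityRecord("c2", "TGT1", "EC50", 5, "nM"),     # wrong measure, dropped
    BioactivityRecord("c3", "TGT1", "Ki", 0.001, "mM"),   # exactly 1000 nM
]

drops = Counter()
curated = curate(records, structures, drop_counts=drops)
dataset = label(deduplicate(curated), structures, cutoff_nm=1000)

print(f"input records: {len(records)}, retained: {len(curated)}, drops: {dict(drops)}")
for entry in dataset.entries:
    print(f"  {entry.compound_id}: mean {entry.mean_activity_nm:g} nM -> {entry.label}")
print("A compound is active only when its mean potency is strictly below the")
print("1000 nM cutoff; c3 sits exactly on the boundary and is inactive.")
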