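"""Filter compounds on the eight ADMET endpoints.

Generates a synthetic endpoint table, evaluates each compound against the
default acceptance rules, selects clean sweeps (all 8 endpoints passed)
and prints the overlap counts behind an upset-style plot.
"""

from herbscreen.admet import (
    default_ruleset,
    evaluate_profile,
    overlap_counts,
    overlap_counts_to_rows,
    select_candidates,
)
from herbscreen.synthetic import GeneratorConfig, generate_admet_table

ids = [f"hit{i}" for i in range(1, 7)]
table, _ = generate_admet_table(ids, GeneratorConfig(admet_pass_rate=0.8, seed=8))

ruleset = default_ruleset()
profiles = [evaluate_profile(values, ruleset, cid) for cid, values in table.items()]
for p in profiles:
    failed = sorted(e for e, v in p.verdicts.items() if v == "fail")
    print(f"  {p.compound_id}: n_pass={p.n_pass}/8"
          + (f" (fails: {', '.join(failed)})" if failed else ""))

candidates = select_candidates(profiles, require_all=True)
print("candidates passing all 8 endpoints:", [p.compound_id for p in candidates])

print("overlap counts (endpoint subset -> compounds passing exactly it):")
for row in overlap_counts_to_rows(overlap_counts(profiles)):
    print(f"  {row['count']} compound(s) pass {row['size']} endpoints: {row['endpoints']}")
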