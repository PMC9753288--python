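"""Rule-based ADMET classification over eight developability endpoints.

Endpoint values are *inputs* (typically exported from an external ADMET
predictor), not predictions made here.  Six endpoints are classifier-style
probabilities in [0,1] (HIA, F30, BBB favorable; hERG, H-HT, Ames risk),
logP is a real partition coefficient and T_half is in hours.  Each endpoint
is judged against a closed acceptance interval — boundary values pass — and
a compound's profile records the per-endpoint verdicts and the number of
endpoints passed (0-8).  Candidate selection either requires a clean sweep
(n_pass == 8) or ranks by n_pass with an optional consensus-QSAR
probability tiebreak.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field

ENDPOINTS = ("logP", "HIA", "F30", "BBB", "T_half", "hERG", "H_HT", "Ames")
#: endpoints whose values are probabilities in [0,1]
PROB_ENDPOINTS = frozenset({"HIA", "F30", "BBB", "hERG", "H_HT", "Ames"})


@dataclass(frozen=True)
class EndpointRule:
    """Closed acceptance interval [lo, hi]; None means unbounded."""

    lo: float | None = None
    hi: float | None = None

    def passes(self, value: float) -> bool:
        if self.lo is not None and value < self.lo:
            return False
        if self.hi is not None and value > self.hi:
            return False
        return True


@dataclass
class ADMETRuleset:
    rules: dict[str, EndpointRule]

    def __post_init__(self) -> None:
        missing = set(ENDPOINTS) - set(self.rules)
        if missing:
            raise ValueError(f"ruleset missing endpoints: {sorted(missing)}")

    def to_dict(self) -> dict:
        return {e: {"lo": r.lo, "hi": r.hi} for e, r in self.rules.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ADMETRuleset":
        return cls({e: EndpointRule(v.get("lo"), v.get("hi")) for e, v in d.items()})


def default_ruleset() -> ADMETRuleset:
    """Conventional acceptance bands: moderate lipophilicity, favorable
    absorption/bioavailability/permeability probabilities >= 0.7, toxicity
    risk probabilities <= 0.3, half-life >= 0.5 h."""
    return ADMETRuleset({
        "logP": EndpointRule(0.0, 3.0),
        "HIA": EndpointRule(lo=0.7),
        "F30": EndpointRule(lo=0.7),
        "BBB": EndpointRule(lo=0.7),
        "T_half": EndpointRule(lo=0.5),
        "hERG": EndpointRule(hi=0.3),
        "H_HT": EndpointRule(hi=0.3),
        "Ames": EndpointRule(hi=0.3),
    })


@dataclass
class ADMETProfile:
    compound_id: str
    values: dict[str, float]
    verdicts: dict[str, str] = field(default_factory=dict)  # endpoint -> "pass"/"fail"

    @property
    def n_pass(self) -> int:
        return sum(v == "pass" for v in self.verdicts.values())

    @property
    def passed_set(self) -> frozenset[str]:
        return frozenset(e for e, v in self.verdicts.items() if v == "pass")


def evaluate_profile(values: dict[str, float], ruleset: ADMETRuleset,
                     compound_id: str = "") -> ADMETProfile:
    """Judge one compound's endpoint table row against the ruleset.

    Every endpoint must be present; probability endpoints must lie in
    [0,1].  Returns per-endpoint verdicts and n_pass.
    """
    for e in ENDPOINTS:
        if e not in values or values[e] is None or math.isnan(values[e]):
            raise ValueError(f"missing endpoint {e!r} for compound {compound_id!r}")
        if e in PROB_ENDPOINTS and not (0.0 <= values[e] <= 1.0):
            raise ValueError(
                f"endpoint {e!r} of {compound_id!r} is {values[e]}, outside [0, 1]"
            )
    verdicts = {
        e: "pass" if ruleset.rules[e].passes(values[e]) else "fail" for e in ENDPOINTS
    }
    return ADMETProfile(compound_id=compound_id, values=dict(values), verdicts=verdicts)


def select_candidates(
    profiles: list[ADMETProfile],
    require_all: bool = True,
    qsar_probability: dict[str, float] | None = None,
) -> list[ADMETProfile]:
    """Pick candidate compounds from evaluated profiles.

    ``require_all`` keeps only clean sweeps (n_pass == 8).  Otherwise
    profiles are ranked by n_pass descending with the consensus-QSAR
    probability (when supplied) breaking ties; ordering is stable under
    equal keys.
    """
    if require_all:
        return [p for p in profiles if p.n_pass == len(ENDPOINTS)]
    qp = qsar_probability or {}
    return sorted(profiles, key=lambda p: (-p.n_pass, -qp.get(p.compound_id, 0.0)))


def overlap_counts(profiles: list[ADMETProfile]) -> dict[frozenset[str], int]:
    """Count compounds by the exact endpoint subset they pass.

    Only observed pass-sets appear; counts sum to the number of profiles.
    The result is the data behind an upset-style intersection plot.
    """
    return dict(Counter(p.passed_set for p in profiles))


def overlap_counts_to_rows(counts: dict[frozenset[str], int]) -> list[dict]:
    """Flatten overlap counts into sortable rows for CSV/JSON export."""
    rows = [
        {"endpoints": "|".join(sorted(s)), "size": len(s), "count": c}
        for s, c in counts.items()
    ]
    rows.sort(key=lambda r: (-r["count"], -r["size"], r["endpoints"]))
    return rows


def read_admet_csv(path: str) -> dict[str, dict[str, float]]:
    """Read the fixed-header endpoint table: compound_id + the 8 endpoints."""
    out: dict[str, dict[str, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(ENDPOINTS) - set(reader.fieldnames):
            raise ValueError(f"{path}: header must contain compound_id and {ENDPOINTS}")
        for row in reader:
            out[row["compound_id"]] = {e: float(row[e]) for e in ENDPOINTS}
    return out


def write_admet_csv(values: dict[str, dict[str, float]], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", *ENDPOINTS])
        for cid in values:
            w.writerow([cid] + [f"{values[cid][e]:.6g}" for e in ENDPOINTS])
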