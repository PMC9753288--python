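"""Orchestration of the four-stage virtual-screening cascade.

The cascade narrows a compound library through fixed, ordered stages:

1. **tags** — keep compounds annotated with every required tag
   (e.g. ``tumor`` and ``inflammation``);
2. **docking** — keep the top-k compounds by an externally computed
   docking score (more negative is better by default; this package never
   runs a docking engine, it ingests a score table);
3. **qsar** — keep compounds whose consensus QSAR probability strictly
   exceeds the threshold (default 0.5);
4. **admet** — keep compounds passing all eight ADMET endpoint rules.

Survivor sets are nested by construction, every compound carries a full
audit trace, and reports are deterministic: identical inputs, seeds and
config produce byte-identical report files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

from .admet import ADMETRuleset, default_ruleset, evaluate_profile
from .compound_io import CompoundLibrary, filter_by_tags
from .qsar import ConsensusModel

log = logging.getLogger(__name__)

STAGES = ("tags", "docking", "qsar", "admet")


@dataclass
class CascadeConfig:
    required_tags: tuple[str, ...] = ("tumor", "inflammation")
    top_k: int = 25
    qsar_threshold: float = 0.5
    admet_ruleset: ADMETRuleset = field(default_factory=default_ruleset)
    lower_is_better: bool = True  # docking score direction
    strict: bool = True  # missing score/ADMET rows: error vs drop-with-warning
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0.0 < self.qsar_threshold < 1.0:
            raise ValueError("qsar_threshold must lie in (0, 1)")

    def digest(self) -> str:
        blob = json.dumps(
            {
                "required_tags": sorted(self.required_tags),
                "top_k": self.top_k,
                "qsar_threshold": self.qsar_threshold,
                "admet_ruleset": self.admet_ruleset.to_dict(),
                "lower_is_better": self.lower_is_better,
                "strict": self.strict,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def select_top_k(
    scores: dict[str, float], k: int, lower_is_better: bool = True
) -> set[str]:
    """The k best-scoring compound ids (ties broken by ascending id)."""
    if not scores:
        raise ValueError("empty docking score table")
    if k < 1:
        raise ValueError("k must be >= 1")
    sign = 1.0 if lower_is_better else -1.0
    ranked = sorted(scores, key=lambda cid: (sign * scores[cid], cid))
    return set(ranked[: min(k, len(ranked))])


@dataclass
class CascadeResult:
    stage_ids: dict[str, list[str]]  # stage name -> sorted surviving ids
    trace: dict[str, dict]  # compound_id -> per-stage details
    config_digest: str
    seed: int

    @property
    def stage_counts(self) -> list[int]:
        return [len(self.stage_ids[s]) for s in STAGES]

    @property
    def candidates(self) -> list[str]:
        return self.stage_ids["admet"]

    def to_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "stage_ids": self.stage_ids,
            "trace": self.trace,
            "config_digest": self.config_digest,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeResult":
        return cls(
            stage_ids=d["stage_ids"],
            trace=d["trace"],
            config_digest=d["config_digest"],
            seed=d["seed"],
        )


def run_cascade(
    library: CompoundLibrary,
    docking_scores: dict[str, float],
    consensus_model: ConsensusModel,
    admet_table: dict[str, dict[str, float]],
    config: CascadeConfig,
) -> CascadeResult:
    """Apply the four stages in fixed order and return the audited result."""
    lib_ids = set(library.ids())
    stray = set(docking_scores) - lib_ids
    if stray:
        raise ValueError(f"docking scores for unknown compounds: {sorted(stray)[:5]}")

    trace: dict[str, dict] = {
        rec.compound_id: {"tags": sorted(rec.tags), "eliminated_at": None}
        for rec in library
    }

    # stage 1: tag filter
    tagged = filter_by_tags(library, set(config.required_tags))
    tagged_ids = set(tagged.ids())
    for cid in lib_ids - tagged_ids:
        trace[cid]["eliminated_at"] = "tags"

    # stage 2: docking top-k among tag survivors
    stage_scores = {cid: docking_scores[cid] for cid in tagged_ids if cid in docking_scores}
    unscored = tagged_ids - set(stage_scores)
    if unscored:
        msg = f"{len(unscored)} tag-passing compounds lack docking scores"
        if config.strict:
            raise ValueError(f"{msg}: {sorted(unscored)[:5]}")
        log.warning("%s; dropping them (lenient mode)", msg)
        for cid in unscored:
            trace[cid]["eliminated_at"] = "docking"
            trace[cid]["docking_missing"] = True
    top_ids = select_top_k(stage_scores, config.top_k, config.lower_is_better) if stage_scores else set()
    ranked = sorted(stage_scores, key=lambda c: ((1 if config.lower_is_better else -1) * stage_scores[c], c))
    rank_of = {cid: r + 1 for r, cid in enumerate(ranked)}
    for cid in stage_scores:
        trace[cid]["docking_score"] = stage_scores[cid]
        trace[cid]["docking_rank"] = rank_of[cid]
        if cid not in top_ids and trace[cid]["eliminated_at"] is None:
            trace[cid]["eliminated_at"] = "docking"

    # stage 3: consensus QSAR probability threshold (strict >)
    top_sorted = sorted(top_ids)
    smiles = library.smiles_map()
    probs = consensus_model.predict_smiles([smiles[c] for c in top_sorted]) if top_sorted else []
    qsar_ids = set()
    for cid, p in zip(top_sorted, probs):
        trace[cid]["consensus_probability"] = float(p)
        if p > config.qsar_threshold:
            qsar_ids.add(cid)
        else:
            trace[cid]["eliminated_at"] = "qsar"

    # stage 4: ADMET require-all
    missing = {cid for cid in qsar_ids if cid not in admet_table}
    if missing:
        msg = f"{len(missing)} QSAR survivors lack ADMET rows"
        if config.strict:
            raise ValueError(f"{msg}: {sorted(missing)}")
        log.warning("%s; dropping them (lenient mode)", msg)
    admet_ids = set()
    for cid in sorted(qsar_ids):
        if cid in missing:
            trace[cid]["eliminated_at"] = "admet"
            trace[cid]["admet_missing"] = True
            continue
        profile = evaluate_profile(admet_table[cid], config.admet_ruleset, cid)
        trace[cid]["admet_n_pass"] = profile.n_pass
        trace[cid]["admet_verdicts"] = profile.verdicts
        if profile.n_pass == 8:
            admet_ids.add(cid)
        else:
            trace[cid]["eliminated_at"] = "admet"

    for cid in admet_ids:
        trace[cid]["final_verdict"] = "candidate"

    return CascadeResult(
        stage_ids={
            "tags": sorted(tagged_ids),
            "docking": sorted(top_ids),
            "qsar": sorted(qsar_ids),
            "admet": sorted(admet_ids),
        },
        trace=trace,
        config_digest=config.digest(),
        seed=config.seed,
    )


def report(result: CascadeResult, out_dir: str) -> dict[str, str]:
    """Write the machine-readable JSON trace and a human-readable summary.

    Outputs are deterministic (sorted keys, no wall-clock metadata): the
    same result always renders to byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    json_path = os.path.join(out_dir, "cascade_report.json")
    txt_path = os.path.join(out_dir, "cascade_report.txt")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = ["stage        survivors", "-----------  ---------"]
    for stage, count in zip(STAGES, result.stage_counts):
        lines.append(f"{stage:<11}  {count:>9}")
    lines.append("")
    lines.append("final candidates: " + (", ".join(result.candidates) or "(none)"))
    lines.append(f"config digest: {result.config_digest}  seed: {result.seed}")
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return {"json": json_path, "txt": txt_path}


def load_report(path: str) -> CascadeResult:
    with open(path, encoding="utf-8") as fh:
        return CascadeResult.from_dict(json.load(fh))
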