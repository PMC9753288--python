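"""Ligand-based target prioritization and pathway enrichment.

Four in-repo prediction methods share the strategies of the popular online
ligand-based tools, applied to user-supplied reference ligand sets:

* ``predict_nn`` — nearest-neighbor: max structural-key Tanimoto between
  the query and each target's known ligands.
* ``predict_sea_like`` — similarity-ensemble: the sum of pairwise Tanimoto
  similarities above 0.57 between query and ligand set, standardized
  against a seeded null of random same-size ligand sets drawn from the
  pooled reference universe; targets with z >= 3 are predicted.
* ``predict_bayes`` — per-target Bernoulli naive Bayes over structural-key
  bits with Laplace smoothing, scored as posterior odds against a pooled
  background model.
* ``predict_cats_nn`` — nearest-neighbor in occurrence-scaled CATS space,
  score = 1 / (1 + Euclidean distance).

Targets predicted by at least ``min_methods`` of the methods (default 3 of
4) form the consensus set, and a generic hypergeometric enrichment with
Benjamini-Hochberg adjustment relates consensus targets to pathway
annotations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .compound_io import CompoundRecord, canonicalize
from .descriptors import cats_vector, structural_keys, tanimoto_matrix

log = logging.getLogger(__name__)

SEA_PAIR_THRESHOLD = 0.57  # published similarity-ensemble pairwise cutoff
SEA_Z_CUTOFF = 3.0
NN_CUTOFF = 0.7
CATS_NN_CUTOFF = 0.35


@dataclass
class ReferenceSet:
    """Known active ligands (canonical SMILES) for one target."""

    target_id: str
    ligands: list[str]

    def __post_init__(self) -> None:
        if not self.ligands:
            raise ValueError(f"reference set {self.target_id!r} has no ligands")
        self.ligands = [canonicalize(s) for s in self.ligands]


@dataclass
class TargetPrediction:
    method_id: str
    scores: dict[str, float]
    predicted: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.predicted <= set(self.scores):
            raise ValueError("predicted targets must be a subset of scored targets")

    def argmax(self) -> str:
        return max(sorted(self.scores), key=lambda t: self.scores[t])


def _query_keys(query: CompoundRecord | str) -> np.ndarray:
    smiles = query.smiles if isinstance(query, CompoundRecord) else query
    return structural_keys(smiles)


def _refset_keys(refsets: list[ReferenceSet]) -> dict[str, np.ndarray]:
    return {rs.target_id: np.vstack([structural_keys(s) for s in rs.ligands]) for rs in refsets}


def predict_nn(
    query: CompoundRecord | str,
    refsets: list[ReferenceSet],
    cutoff: float = NN_CUTOFF,
) -> TargetPrediction:
    """Nearest-neighbor target prediction on structural keys."""
    if not refsets:
        raise ValueError("refsets must be non-empty")
    qfp = _query_keys(query)
    scores = {
        rs.target_id: float(tanimoto_matrix(qfp, fps).max())
        for rs, fps in zip(refsets, _refset_keys(refsets).values())
    }
    return TargetPrediction("nn", scores, {t for t, s in scores.items() if s >= cutoff})


def predict_sea_like(
    query: CompoundRecord | str,
    refsets: list[ReferenceSet],
    n_null: int = 500,
    seed: int = 0,
    pair_threshold: float = SEA_PAIR_THRESHOLD,
    z_cutoff: float = SEA_Z_CUTOFF,
) -> TargetPrediction:
    """Similarity-ensemble prediction standardized against a random null.

    The raw score of a target is the sum of query-to-ligand Tanimoto
    similarities at or above ``pair_threshold``.  The null distribution is
    built from ``n_null`` random ligand sets of the same size drawn (without
    replacement) from the pooled reference universe.
    """
    if not refsets:
        raise ValueError("refsets must be non-empty")
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    qfp = _query_keys(query)
    pooled: list[str] = [s for rs in refsets for s in rs.ligands]
    largest = max(len(rs.ligands) for rs in refsets)
    if len(pooled) < largest:
        raise ValueError("pooled universe smaller than the largest reference set")
    pooled_fps = np.vstack([structural_keys(s) for s in pooled])
    sims = tanimoto_matrix(qfp, pooled_fps)
    contrib = np.where(sims >= pair_threshold, sims, 0.0)

    # ligand index ranges per target within the pooled array
    offsets, start = {}, 0
    for rs in refsets:
        offsets[rs.target_id] = (start, start + len(rs.ligands))
        start += len(rs.ligands)

    rng = np.random.default_rng(seed)
    scores: dict[str, float] = {}
    for rs in refsets:
        lo, hi = offsets[rs.target_id]
        raw = float(contrib[lo:hi].sum())
        m = hi - lo
        null = np.array([
            contrib[rng.choice(len(pooled), size=m, replace=False)].sum()
            for _ in range(n_null)
        ])
        mu, sd = null.mean(), null.std(ddof=1)
        if sd == 0:
            z = 0.0 if raw == mu else math.copysign(np.inf, raw - mu)
        else:
            z = (raw - mu) / sd
        scores[rs.target_id] = float(z)
    return TargetPrediction("sea", scores, {t for t, z in scores.items() if z >= z_cutoff})


def predict_bayes(
    query: CompoundRecord | str,
    refsets: list[ReferenceSet],
    prior_odds: float = 1.0,
    alpha: float = 1.0,
) -> TargetPrediction:
    """Bernoulli naive-Bayes target scoring over structural-key bits.

    Per-bit frequencies are Laplace-smoothed (``alpha``); each target's
    likelihood is compared with a pooled-background model and the score is
    the log posterior odds.  Targets with posterior odds > 1 are predicted.
    Reference sets with fewer than two ligands cannot support frequency
    estimation and are skipped with a warning.
    """
    if not refsets:
        raise ValueError("refsets must be non-empty")
    usable = []
    for rs in refsets:
        if len(rs.ligands) < 2:
            log.warning("skipping target %s: fewer than 2 ligands", rs.target_id)
        else:
            usable.append(rs)
    if not usable:
        raise ValueError("no reference set has >= 2 ligands")
    x = _query_keys(query).astype(float)
    key_mats = _refset_keys(usable)
    pooled = np.vstack(list(key_mats.values()))
    theta_bg = (pooled.sum(axis=0) + alpha) / (pooled.shape[0] + 2 * alpha)
    scores: dict[str, float] = {}
    for rs in usable:
        fps = key_mats[rs.target_id]
        theta = (fps.sum(axis=0) + alpha) / (fps.shape[0] + 2 * alpha)
        loglr = float(
            (x * (np.log(theta) - np.log(theta_bg))).sum()
            + ((1 - x) * (np.log1p(-theta) - np.log1p(-theta_bg))).sum()
        )
        scores[rs.target_id] = loglr + math.log(prior_odds)
    return TargetPrediction("bayes", scores, {t for t, s in scores.items() if s > 0})


def predict_cats_nn(
    query: CompoundRecord | str,
    refsets: list[ReferenceSet],
    cutoff: float = CATS_NN_CUTOFF,
) -> TargetPrediction:
    """Nearest-neighbor prediction in occurrence-scaled CATS space."""
    if not refsets:
        raise ValueError("refsets must be non-empty")
    smiles = query.smiles if isinstance(query, CompoundRecord) else query
    qv = cats_vector(smiles, scaling_mode="occurrence")
    scores: dict[str, float] = {}
    for rs in refsets:
        dists = [np.linalg.norm(qv - cats_vector(s, scaling_mode="occurrence"))
                 for s in rs.ligands]
        scores[rs.target_id] = float(1.0 / (1.0 + min(dists)))
    return TargetPrediction("cats_nn", scores, {t for t, s in scores.items() if s >= cutoff})


ALL_METHODS = ("nn", "sea", "bayes", "cats_nn")


def predict_all(
    query: CompoundRecord | str,
    refsets: list[ReferenceSet],
    seed: int = 0,
    n_null: int = 500,
) -> list[TargetPrediction]:
    """Run the full four-method battery on one query."""
    return [
        predict_nn(query, refsets),
        predict_sea_like(query, refsets, n_null=n_null, seed=seed),
        predict_bayes(query, refsets),
        predict_cats_nn(query, refsets),
    ]


@dataclass
class ConsensusTargets:
    votes: dict[str, int]
    min_methods: int
    consensus: set[str]
    mean_scores: dict[str, float]

    def ranked(self) -> list[tuple[str, float]]:
        """Consensus targets ranked by mean method score, best first."""
        return sorted(
            ((t, self.mean_scores[t]) for t in self.consensus),
            key=lambda kv: (-kv[1], kv[0]),
        )


def consensus_targets(
    predictions: list[TargetPrediction], min_methods: int = 3
) -> ConsensusTargets:
    """Vote-count consensus: targets predicted by >= min_methods methods.

    The consensus set shrinks (weakly) as ``min_methods`` grows.  Mean
    scores average each method's score after min-max normalization within
    the method, so methods on different scales (Tanimoto, z, log-odds)
    contribute comparably to the ranking.
    """
    if min_methods > len(predictions):
        raise ValueError(
            f"min_methods={min_methods} exceeds the {len(predictions)} supplied methods"
        )
    votes: dict[str, int] = {}
    norm_scores: dict[str, list[float]] = {}
    for pred in predictions:
        vals = np.array(list(pred.scores.values()), dtype=float)
        finite = vals[np.isfinite(vals)]
        lo = finite.min() if finite.size else 0.0
        hi = finite.max() if finite.size else 1.0
        span = hi - lo if hi > lo else 1.0
        for t, s in pred.scores.items():
            s = hi if np.isposinf(s) else (lo if np.isneginf(s) else s)
            norm_scores.setdefault(t, []).append((s - lo) / span)
            votes.setdefault(t, 0)
        for t in pred.predicted:
            votes[t] += 1
    consensus = {t for t, v in votes.items() if v >= min_methods}
    mean_scores = {t: float(np.mean(v)) for t, v in norm_scores.items()}
    return ConsensusTargets(votes, min_methods, consensus, mean_scores)


@dataclass
class EnrichmentRow:
    pathway_id: str
    k: int  # overlap between selection and pathway
    n: int  # selection size
    K: int  # pathway size in the universe
    N: int  # universe size
    p_value: float
    p_adjusted: float


def enrich(
    selected: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of pathways among selected targets.

    For each pathway with K annotated targets in a universe of N, observing
    k of the n selected targets has upper-tail p = P(X >= k) under the
    hypergeometric null.  P-values are Benjamini-Hochberg adjusted across
    pathways and rows are returned sorted ascending by p.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not selected <= universe:
        raise ValueError("selected targets must lie within the universe")
    N, n = len(universe), len(selected)
    rows = []
    for pathway_id in sorted(annotation):
        members = annotation[pathway_id] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((pathway_id, k, K, min(max(p, 0.0), 1.0)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        EnrichmentRow(pathway_id=pid, k=k, n=n, K=K, N=N, p_value=p, p_adjusted=float(q))
        for (pid, k, K, p), q in zip(rows, p_adj)
    ]
    out.sort(key=lambda r: (r.p_value, r.pathway_id))
    return out
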