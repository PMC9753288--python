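"""Consensus QSAR: per-family random forests combined by probability averaging.

One random-forest classifier is trained per descriptor family (CATS,
structural keys, 2D panel).  The consensus probability of a compound being
active is the unweighted arithmetic mean of the three member probabilities,
and a compound is called a candidate when that probability strictly exceeds
the screening threshold (default 0.5).  Model quality is reported by
stratified 5-fold cross-validation as accuracy (at the same 0.5 threshold)
and the rank-based AUC with midrank tie handling — members are always
fitted inside the training fold only, so the report is leakage-free.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .curation import LabeledDataset
from .descriptors import FAMILIES, DescriptorMatrix, featurize

DEFAULT_THRESHOLD = 0.5

#: robust forest defaults for descriptor matrices; all overridable
DEFAULT_HYPERPARAMS = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "max_depth": None,
    "class_weight": "balanced_subsample",
}


def stratified_folds(labels: list[int] | np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Partition indices into k class-stratified folds, deterministic per seed.

    Per-fold class counts differ from perfect stratification by at most one.
    A class with fewer than k members cannot be spread across k folds and
    raises a ``ValueError`` naming the class.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls, count in Counter(y.tolist()).items():
        if count < k:
            raise ValueError(f"class {cls!r} has only {count} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(y)), y)]


@dataclass
class MemberModel:
    """One fitted forest over a single descriptor family."""

    family: str
    forest: RandomForestClassifier
    n_train: int
    class_balance: tuple[int, int]  # (n_inactive, n_active)
    seed: int
    hyperparams: dict

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the active class for each row of X."""
        proba = self.forest.predict_proba(np.asarray(X))
        (active_col,) = np.where(self.forest.classes_ == 1)[0]
        return proba[:, active_col]


def train_member(
    features: DescriptorMatrix,
    dataset: LabeledDataset,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> MemberModel:
    """Fit one member forest on a descriptor block aligned to the dataset."""
    if features.compound_ids != dataset.ids():
        features = features.subset(dataset.ids())
    y = np.asarray(dataset.labels())
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    forest = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    forest.fit(features.matrix, y)
    return MemberModel(
        family=features.family,
        forest=forest,
        n_train=len(y),
        class_balance=(int((y == 0).sum()), int((y == 1).sum())),
        seed=seed,
        hyperparams=hp,
    )


@dataclass
class ConsensusModel:
    """Three member forests plus the probability-averaging consensus rule."""

    members: dict[str, MemberModel]
    threshold: float = DEFAULT_THRESHOLD
    typing_rules: dict | None = None
    cats_scaling: str = "raw"

    def __post_init__(self) -> None:
        if set(self.members) != set(FAMILIES):
            raise ValueError(f"consensus needs exactly the families {FAMILIES}")

    def member_probabilities(self, features: dict[str, DescriptorMatrix]) -> dict[str, np.ndarray]:
        out = {}
        for fam in FAMILIES:
            if fam not in features:
                raise ValueError(f"missing features for family {fam!r}")
            out[fam] = self.members[fam].predict_proba(features[fam].matrix)
        return out

    def predict_proba(self, features: dict[str, DescriptorMatrix]) -> np.ndarray:
        probs = self.member_probabilities(features)
        return consensus_probability(*(probs[f] for f in FAMILIES))

    def predict_smiles(self, smiles_list: list[str]) -> np.ndarray:
        feats = {}
        for fam in FAMILIES:
            try:
                feats[fam] = featurize(fam, smiles_list, typing_rules=self.typing_rules,
                                       cats_scaling=self.cats_scaling)
            except ValueError as err:
                raise ValueError(f"featurization failed for family {fam!r}: {err}") from err
        return self.predict_proba(feats)

    def save(self, path: str) -> None:
        joblib.dump({"members": self.members, "threshold": self.threshold,
                     "typing_rules": self.typing_rules, "cats_scaling": self.cats_scaling,
                     "format_version": 1}, path)

    @classmethod
    def load(cls, path: str) -> "ConsensusModel":
        blob = joblib.load(path)
        return cls(members=blob["members"], threshold=blob["threshold"],
                   typing_rules=blob.get("typing_rules"),
                   cats_scaling=blob.get("cats_scaling", "raw"))


def consensus_probability(*member_probs: float | np.ndarray) -> float | np.ndarray:
    """Unweighted arithmetic mean of member probabilities."""
    if not member_probs:
        raise ValueError("at least one member probability required")
    stacked = np.asarray(member_probs, dtype=float)
    return stacked.mean(axis=0)


def classify(probability: float | np.ndarray, threshold: float = DEFAULT_THRESHOLD):
    """Candidate iff probability strictly exceeds the threshold.

    The boundary is exclusive: a probability exactly at the threshold is a
    non-candidate.
    """
    p = np.asarray(probability, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    calls = np.where(p > threshold, "candidate", "non-candidate")
    return calls.item() if calls.ndim == 0 else calls


def train_consensus(
    features: dict[str, DescriptorMatrix],
    dataset: LabeledDataset,
    hyperparams: dict | None = None,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> ConsensusModel:
    """Train all three members on aligned descriptor blocks."""
    members = {
        fam: train_member(features[fam], dataset, hyperparams, seed=seed + i)
        for i, fam in enumerate(FAMILIES)
    }
    return ConsensusModel(members=members, threshold=threshold)


def export_predictions(model: ConsensusModel, smiles_map: dict[str, str],
                       path: str) -> None:
    """Write per-compound member and consensus probabilities with calls
    (CSV: compound_id,p_cats,p_keys,p_panel2d,p_consensus,call)."""
    import csv

    ids = list(smiles_map)
    feats = {fam: featurize(fam, [smiles_map[c] for c in ids], ids,
                            typing_rules=model.typing_rules,
                            cats_scaling=model.cats_scaling)
             for fam in FAMILIES}
    member = model.member_probabilities(feats)
    p_cons = consensus_probability(*(member[f] for f in FAMILIES))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "p_cats", "p_keys", "p_panel2d",
                    "p_consensus", "call"])
        for i, cid in enumerate(ids):
            w.writerow([cid] + [f"{member[f][i]:.6f}" for f in FAMILIES]
                       + [f"{p_cons[i]:.6f}", classify(p_cons[i], model.threshold)])


@dataclass
class CVReport:
    """Per-fold and mean accuracy/AUC for each member and the consensus."""

    fold_assignments: list[np.ndarray]
    acc: dict[str, list[float]]  # family or "consensus" -> per-fold values
    auc: dict[str, list[float]]
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def mean_acc(self, which: str = "consensus") -> float:
        return float(np.mean(self.acc[which]))

    def mean_auc(self, which: str = "consensus") -> float:
        return float(np.mean(self.auc[which]))

    def summary(self) -> dict:
        keys = list(self.acc)
        return {
            "mean_acc": {k: self.mean_acc(k) for k in keys},
            "mean_auc": {k: self.mean_auc(k) for k in keys},
            "per_fold_acc": {k: list(map(float, v)) for k, v in self.acc.items()},
            "per_fold_auc": {k: list(map(float, v)) for k, v in self.auc.items()},
        }


def evaluate(
    features: dict[str, DescriptorMatrix],
    dataset: LabeledDataset,
    k: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> CVReport:
    """Stratified k-fold cross-validation of members and consensus.

    For each fold, all members are trained on the training split only and
    scored on the held-out split: accuracy at the screening threshold and
    the rank-based (Mann-Whitney) AUC with ties counted as half.
    """
    y = np.asarray(dataset.labels())
    ids = dataset.ids()
    aligned = {fam: features[fam].subset(ids) for fam in FAMILIES}
    folds = stratified_folds(y, k, seed)
    all_idx = np.arange(len(y))
    acc: dict[str, list[float]] = {fam: [] for fam in FAMILIES}
    auc: dict[str, list[float]] = {fam: [] for fam in FAMILIES}
    acc["consensus"], auc["consensus"] = [], []

    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_ds = LabeledDataset(
            [dataset.entries[i] for i in train_idx], cutoff_nm=dataset.cutoff_nm
        )
        fold_probs = []
        for i, fam in enumerate(FAMILIES):
            block = aligned[fam]
            train_block = DescriptorMatrix(
                fam, [ids[j] for j in train_idx], block.matrix[train_idx], block.feature_names
            )
            member = train_member(train_block, train_ds, hyperparams, seed=seed + 97 * f + i)
            p = member.predict_proba(block.matrix[test_idx])
            fold_probs.append(p)
            acc[fam].append(accuracy_score(y[test_idx], p > threshold))
            auc[fam].append(roc_auc_score(y[test_idx], p))
        p_cons = consensus_probability(*fold_probs)
        acc["consensus"].append(accuracy_score(y[test_idx], p_cons > threshold))
        auc["consensus"].append(roc_auc_score(y[test_idx], p_cons))

    return CVReport(fold_assignments=folds, acc=acc, auc=auc, threshold=threshold, seed=seed)
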