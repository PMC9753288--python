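"""Descriptor families for the consensus QSAR model and similarity kernels.

Three complementary views of a molecule feed the consensus model:

* **CATS** — the topological pharmacophore-pair histogram: atoms are typed as
  donor (D), acceptor (A), positively ionizable (P), negatively ionizable
  (N) or lipophilic (L) by SMARTS rules, and every unordered pair of
  *distinct* typed atoms is binned by its shortest-path (bond-count)
  distance, 0–9 bonds.  With 15 unordered type pairs × 10 distance bins the
  vector has 150 entries.  ``occurrence`` scaling divides each (t1,t2) entry
  by the number of atoms typed t1 plus the number typed t2.
* **structural keys** — the public 166-key structural-fragment fingerprint.
* **panel2d** — a fixed, documented panel of 27 graph-derived
  physicochemical descriptors (size, lipophilicity, polarity, flexibility,
  ring content, topological indices).

All three are purely topological: invariant to atom ordering and to
stereochemical annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, MACCSkeys, rdMolDescriptors

from .compound_io import CompoundLibrary, mol_from_smiles

PPP_TYPES = ("D", "A", "P", "N", "L")
#: 15 unordered type pairs in fixed layout order
PPP_PAIRS = tuple(
    (PPP_TYPES[i], PPP_TYPES[j])
    for i in range(len(PPP_TYPES))
    for j in range(i, len(PPP_TYPES))
)
N_DISTANCE_BINS = 10  # topological distances 0..9
CATS_LENGTH = len(PPP_PAIRS) * N_DISTANCE_BINS  # 150
N_KEYS = 166

FAMILIES = ("cats", "keys", "panel2d")


def load_ppp_rules(path: str | None = None) -> dict[str, list[str]]:
    """Load PPP typing rules (type -> list of SMARTS) and validate them.

    Malformed SMARTS is a configuration error raised at load time, not at
    first use.
    """
    if path is None:
        text = resources.files("herbscreen.data").joinpath("ppp_rules.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    rules = yaml.safe_load(text)
    if not isinstance(rules, dict) or set(rules) - set(PPP_TYPES):
        raise ValueError(f"PPP rules must map a subset of {PPP_TYPES} to SMARTS lists")
    for ptype, patterns in rules.items():
        for smarts in patterns:
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"malformed SMARTS for type {ptype}: {smarts!r}")
    return rules


_DEFAULT_RULES: dict[str, list[str]] | None = None


def default_ppp_rules() -> dict[str, list[str]]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_ppp_rules()
    return _DEFAULT_RULES


def _as_mol(molecule: Chem.Mol | str) -> Chem.Mol:
    if isinstance(molecule, str):
        return mol_from_smiles(molecule)
    return molecule


def assign_ppp(
    molecule: Chem.Mol | str, typing_rules: dict[str, list[str]] | None = None
) -> list[frozenset[str]]:
    """Assign pharmacophore types to every atom.

    Returns one (possibly empty) set of types per atom, indexed by atom
    index.  An atom receives a type when it is the first atom of a match of
    any of that type's SMARTS patterns.
    """
    mol = _as_mol(molecule)
    rules = typing_rules if typing_rules is not None else default_ppp_rules()
    assignment = [set() for _ in range(mol.GetNumAtoms())]
    for ptype, patterns in rules.items():
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"malformed SMARTS for type {ptype}: {smarts!r}")
            for match in mol.GetSubstructMatches(patt):
                assignment[match[0]].add(ptype)
    return [frozenset(s) for s in assignment]


def cats_index(t1: str, t2: str, dist: int) -> int:
    """Flat index of the (unordered type pair, distance) bin."""
    pair = tuple(sorted((t1, t2), key=PPP_TYPES.index))
    return PPP_PAIRS.index(pair) * N_DISTANCE_BINS + dist


def cats_vector(
    molecule: Chem.Mol | str,
    typing_rules: dict[str, list[str]] | None = None,
    scaling_mode: str = "raw",
) -> np.ndarray:
    """Topological pharmacophore-pair histogram (length 150).

    Raw mode: bin (t1t2, d) counts unordered pairs of *distinct* atoms {i,j}
    at shortest-path distance d where one atom carries t1 and the other t2;
    a pair contributes once to every unordered type pair it realizes.
    Self-pairs are excluded, so the d=0 bins are always zero and are kept
    only for layout stability.  Occurrence mode divides every (t1,t2) entry
    by (#atoms typed t1 + #atoms typed t2), with 0/0 -> 0.
    """
    if scaling_mode not in ("raw", "occurrence"):
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}")
    mol = _as_mol(molecule)
    types = assign_ppp(mol, typing_rules)
    vec = np.zeros(CATS_LENGTH)
    if mol.GetNumAtoms() > 1:
        dmat = Chem.GetDistanceMatrix(mol)
        n = mol.GetNumAtoms()
        for i in range(n):
            if not types[i]:
                continue
            for j in range(i + 1, n):
                if not types[j]:
                    continue
                d = dmat[i, j]
                if not np.isfinite(d) or d >= N_DISTANCE_BINS:
                    continue
                d = int(d)
                pairs = {tuple(sorted((t1, t2), key=PPP_TYPES.index))
                         for t1 in types[i] for t2 in types[j]}
                for t1, t2 in pairs:
                    vec[cats_index(t1, t2, d)] += 1
    if scaling_mode == "occurrence":
        counts = {t: sum(t in s for s in types) for t in PPP_TYPES}
        for p, (t1, t2) in enumerate(PPP_PAIRS):
            div = counts[t1] + counts[t2]
            sl = slice(p * N_DISTANCE_BINS, (p + 1) * N_DISTANCE_BINS)
            vec[sl] = vec[sl] / div if div else 0.0
    return vec


def cats_bin_names() -> list[str]:
    return [f"cats_{t1}{t2}_{d}" for (t1, t2) in PPP_PAIRS for d in range(N_DISTANCE_BINS)]


def structural_keys(molecule: Chem.Mol | str) -> np.ndarray:
    """The 166 public structural keys as a 0/1 vector.

    Deterministic for any SMILES spelling of the same molecular graph.
    """
    mol = _as_mol(molecule)
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits; bit 0 is unused padding
    arr = np.zeros(N_KEYS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        if bit >= 1:
            arr[bit - 1] = 1
    return arr


def _wiener_index(mol: Chem.Mol) -> float:
    if mol.GetNumAtoms() < 2:
        return 0.0
    dmat = Chem.GetDistanceMatrix(mol)
    finite = dmat[np.isfinite(dmat)]
    return float(finite.sum() / 2.0)


#: the fixed 2D physicochemical panel: name -> callable(mol) -> float
PANEL2D_FUNCS = {
    "mw": Descriptors.MolWt,
    "heavy_atoms": lambda m: float(m.GetNumHeavyAtoms()),
    "logp": Crippen.MolLogP,
    "mr": Crippen.MolMR,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "hbd": lambda m: float(rdMolDescriptors.CalcNumHBD(m)),
    "hba": lambda m: float(rdMolDescriptors.CalcNumHBA(m)),
    "rot_bonds": lambda m: float(rdMolDescriptors.CalcNumRotatableBonds(m)),
    "rings": lambda m: float(rdMolDescriptors.CalcNumRings(m)),
    "aromatic_rings": lambda m: float(rdMolDescriptors.CalcNumAromaticRings(m)),
    "saturated_rings": lambda m: float(rdMolDescriptors.CalcNumSaturatedRings(m)),
    "aliphatic_rings": lambda m: float(rdMolDescriptors.CalcNumAliphaticRings(m)),
    "fraction_csp3": rdMolDescriptors.CalcFractionCSP3,
    "heteroatoms": lambda m: float(rdMolDescriptors.CalcNumHeteroatoms(m)),
    "formal_charge": lambda m: float(Chem.GetFormalCharge(m)),
    "halogens": lambda m: float(sum(a.GetAtomicNum() in (9, 17, 35, 53) for a in m.GetAtoms())),
    "balaban_j": GraphDescriptors.BalabanJ,
    "bertz_ct": GraphDescriptors.BertzCT,
    "chi0": GraphDescriptors.Chi0,
    "chi1": GraphDescriptors.Chi1,
    "kappa1": GraphDescriptors.Kappa1,
    "kappa2": GraphDescriptors.Kappa2,
    "kappa3": GraphDescriptors.Kappa3,
    "hall_kier_alpha": GraphDescriptors.HallKierAlpha,
    "labute_asa": rdMolDescriptors.CalcLabuteASA,
    "wiener": _wiener_index,
    "valence_electrons": lambda m: float(Descriptors.NumValenceElectrons(m)),
}

PANEL2D_NAMES = tuple(PANEL2D_FUNCS)


def panel2d(molecule: Chem.Mol | str) -> np.ndarray:
    """Fixed 27-descriptor physicochemical panel (order: PANEL2D_NAMES).

    A descriptor that cannot be computed for a given graph (e.g. Balaban J
    on a disconnected graph) is replaced by the documented sentinel 0 with a
    warning; the returned vector never contains NaN/inf.
    """
    mol = _as_mol(molecule)
    out = np.empty(len(PANEL2D_NAMES))
    for k, name in enumerate(PANEL2D_NAMES):
        try:
            v = float(PANEL2D_FUNCS[name](mol))
        except Exception:  # noqa: BLE001 - any descriptor failure maps to sentinel
            v = float("nan")
        if not np.isfinite(v):
            warnings.warn(f"descriptor {name} undefined for this graph; using 0", stacklevel=2)
            v = 0.0
        out[k] = v
    return out


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| between two bit vectors.

    Defined as 0 when both vectors are all-zero; raises on length mismatch.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(query: np.ndarray, fps: np.ndarray) -> np.ndarray:
    """Vectorized Tanimoto of one query bit vector against rows of ``fps``."""
    q = np.asarray(query, dtype=bool)
    m = np.asarray(fps, dtype=bool)
    inter = np.logical_and(m, q).sum(axis=1).astype(float)
    union = np.logical_or(m, q).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(union > 0, inter / union, 0.0)
    return sims


@dataclass
class DescriptorMatrix:
    """Per-family feature block with rows aligned to compound ids."""

    family: str
    compound_ids: list[str]
    matrix: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.compound_ids):
            raise ValueError("row count must equal id count")
        if np.isnan(self.matrix).any():
            raise ValueError("descriptor matrix contains missing values")

    def subset(self, ids: list[str]) -> "DescriptorMatrix":
        index = {cid: k for k, cid in enumerate(self.compound_ids)}
        rows = [index[c] for c in ids]
        return DescriptorMatrix(self.family, list(ids), self.matrix[rows], self.feature_names)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, columns=self.feature_names).assign(
            compound_id=self.compound_ids
        ).set_index("compound_id").to_csv(path)


def featurize(
    family: str,
    smiles_list: list[str],
    compound_ids: list[str] | None = None,
    typing_rules: dict[str, list[str]] | None = None,
    cats_scaling: str = "raw",
) -> DescriptorMatrix:
    """Compute one descriptor family for a list of SMILES."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    ids = compound_ids if compound_ids is not None else [f"m{i}" for i in range(len(smiles_list))]
    rows = []
    for smi in smiles_list:
        mol = mol_from_smiles(smi)
        if family == "cats":
            rows.append(cats_vector(mol, typing_rules, cats_scaling))
        elif family == "keys":
            rows.append(structural_keys(mol).astype(float))
        else:
            rows.append(panel2d(mol))
    names = {
        "cats": cats_bin_names(),
        "keys": [f"key_{k + 1}" for k in range(N_KEYS)],
        "panel2d": list(PANEL2D_NAMES),
    }[family]
    return DescriptorMatrix(family, list(ids), np.vstack(rows), names)


def featurize_library(
    library: CompoundLibrary,
    typing_rules: dict[str, list[str]] | None = None,
    cats_scaling: str = "raw",
) -> dict[str, DescriptorMatrix]:
    """Compute all three descriptor families for a library."""
    smiles = [r.smiles for r in library]
    ids = library.ids()
    return {
        fam: featurize(fam, smiles, ids, typing_rules, cats_scaling) for fam in FAMILIES
    }
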