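"""Synthetic inputs with planted structure-activity signal.

Every file the screening pipeline consumes can be generated here, so the
whole cascade is exercisable with no external downloads:

* a compound library assembled from a scaffold + substituent SMILES
  grammar (guaranteed-valid structures, no repair loop), of which a chosen
  number carry both the ``tumor`` and ``inflammation`` tags;
* bioactivity records whose potencies are drawn log-normally below or
  above the activity cutoff depending on a planted substructure motif,
  with replicate records and mixed units injected at configurable rates;
* docking scores affine in a per-compound activity latent plus Gaussian
  noise;
* ADMET endpoint tables with controllable per-endpoint pass rates;
* per-target reference ligand sets, each target built around a distinct
  motif.

All generators are pure functions of (config, seed): rerunning with the
same configuration reproduces identical outputs.  Ground truth (motif
presence, latent activity, intended labels) is returned separately — and
written to ``*_truth.csv`` files by the CLI — and is never read by the
pipeline itself, only by tests and evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from rdkit import Chem

from .compound_io import CompoundLibrary, CompoundRecord, canonicalize
from .curation import BioactivityRecord
from .targets import ReferenceSet

# -- structure grammar --------------------------------------------------------

#: aromatic / aliphatic cores; {r} slots are filled with branch fragments
CORES_1SLOT = (
    "c1ccc({r})cc1",        # benzene
    "c1ccnc({r})c1",        # pyridine
    "C1CCN({r})CC1",        # piperidine (N-substituted)
    "C1CCC({r})CC1",        # cyclohexane
    "c1coc({r})c1",         # furan
    "c1csc({r})c1",         # thiophene
)
CORES_2SLOT = (
    "c1cc({r1})cc({r2})c1",
    "c1c({r1})cnc({r2})c1",
    "C1CC({r1})CCC1{r2}",
    "c1cc({r1})c({r2})cc1",
)

#: plain substituents — deliberately free of the default motifs below
SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "NCC",
    "Cl", "F", "Br", "C#N", "C(=O)O", "C(=O)OC", "C(=O)N", "CO", "CN",
    "CCO", "CCN", "OC(C)C", "C=C",
)

#: active-chemotype motifs: attachable SMILES fragment == its own SMARTS.
#: ring-closure digit 9 avoids collisions with the cores' digit 1
DEFAULT_MOTIFS = (
    "S(=O)(=O)N",             # sulfonamide
    "C(F)(F)F",               # trifluoromethyl
    "C(=O)Nc9ccc(Cl)cc9",     # 4-chloroanilide
    "NC(=O)c9ccco9",          # furan-2-carboxamide
    "S(=O)(=O)c9ccccc9",      # phenylsulfone
)


@dataclass
class GeneratorConfig:
    """Study conditions for all synthetic generators.

    Defaults emulate the shapes of the screening study: a 1,616-compound
    library of which 114 carry both cascade tags, potency records split at
    1 µM, mixed nM/µM/mM units with replicate measurements, docking scores
    correlated with the planted activity signal, and ADMET endpoints with
    a moderate per-endpoint pass rate.
    """

    n_library: int = 1616
    n_tagged: int = 114
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    motif_rate_tagged: float = 0.35
    motif_rate_untagged: float = 0.08
    signal_strength: float = 0.9
    label_noise: float = 0.05
    duplicate_rate: float = 0.3
    max_replicates: int = 3
    frac_um: float = 0.3     # fraction of records reported in µM
    frac_mm: float = 0.05    # fraction reported in mM
    frac_other_measure: float = 0.05  # extra EC50 records (dropped by curation)
    cutoff_nm: float = 1000.0
    dock_scale: float = 5.0
    dock_sigma: float = 1.0
    admet_pass_rate: float = 0.85
    n_targets: int = 4
    n_ligands_per_target: int = 15
    seed: int = 42

    def __post_init__(self) -> None:
        rates = (self.motif_rate_tagged, self.motif_rate_untagged, self.signal_strength,
                 self.label_noise, self.duplicate_rate, self.frac_um, self.frac_mm,
                 self.frac_other_measure, self.admet_pass_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.n_tagged > self.n_library:
            raise ValueError("n_tagged cannot exceed n_library")
        if self.n_targets > len(self.motifs):
            raise ValueError(
                f"cannot place {self.n_targets} targets with only {len(self.motifs)} motifs"
            )


def _motif_patterns(motifs: tuple[str, ...]) -> list[Chem.Mol]:
    patterns = []
    for m in motifs:
        patt = Chem.MolFromSmarts(m)
        if patt is None:
            raise ValueError(f"motif is not a valid SMARTS: {m!r}")
        patterns.append(patt)
    return patterns


def has_motif(smiles: str, motifs: tuple[str, ...]) -> int:
    """Index of the first matching motif, or -1 when none match."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return -1
    for i, patt in enumerate(_motif_patterns(motifs)):
        if mol.HasSubstructMatch(patt):
            return i
    return -1


def _build_smiles(rng: np.random.Generator, motif: str | None) -> str:
    """Assemble one guaranteed-valid SMILES from the grammar."""
    if rng.random() < 0.5:
        core = CORES_1SLOT[rng.integers(len(CORES_1SLOT))]
        r = motif if motif is not None else SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        return core.format(r=r)
    core = CORES_2SLOT[rng.integers(len(CORES_2SLOT))]
    r1 = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
    r2 = motif if motif is not None else SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
    return core.format(r1=r1, r2=r2)


def generate_library(config: GeneratorConfig) -> tuple[CompoundLibrary, pd.DataFrame]:
    """Compound library plus its ground-truth table.

    Exactly ``n_tagged`` records carry both the ``tumor`` and
    ``inflammation`` tags; motif placement rates differ between tagged and
    untagged compounds so the cascade's later stages see planted signal.
    The truth table holds motif index, tag status and the activity latent
    used by the docking-score generator.
    """
    rng = np.random.default_rng([config.seed, 1])
    tagged_idx = set(rng.choice(config.n_library, size=config.n_tagged, replace=False).tolist())
    other_tags = ("metabolism", "cardiovascular", "tumor", "inflammation", "")
    records, truth_rows = [], []
    for i in range(config.n_library):
        cid = f"c{i + 1:05d}"
        tagged = i in tagged_idx
        rate = config.motif_rate_tagged if tagged else config.motif_rate_untagged
        motif_idx = int(rng.integers(len(config.motifs))) if rng.random() < rate else -1
        motif = config.motifs[motif_idx] if motif_idx >= 0 else None
        smiles = canonicalize(_build_smiles(rng, motif))
        if tagged:
            tags = frozenset({"tumor", "inflammation"})
        else:
            t = other_tags[rng.integers(len(other_tags))]
            tags = frozenset({t}) if t else frozenset()
        latent = 0.7 + 0.3 * rng.random() if motif_idx >= 0 else 0.3 * rng.random()
        records.append(CompoundRecord(cid, smiles, name=f"syn-{i + 1}", tags=tags,
                                      source="synthetic"))
        truth_rows.append({"compound_id": cid, "tagged": tagged, "motif_idx": motif_idx,
                           "latent": latent})
    library = CompoundLibrary(records, metadata={"generator_seed": config.seed,
                                                 "n_rejected": 0})
    return library, pd.DataFrame(truth_rows)


def _truncnorm_log10(rng: np.random.Generator, mean: float, sd: float,
                     lo: float, hi: float) -> float:
    """Rejection-sampled normal in log10-potency space, truncated to [lo, hi]."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_bioactivity(
    library: CompoundLibrary, config: GeneratorConfig
) -> tuple[list[BioactivityRecord], pd.DataFrame]:
    """Potency records with planted motif-driven signal.

    A compound's chance of being truth-active is ``0.5 + signal/2`` when it
    carries a motif and ``0.5 - signal/2`` otherwise, then flipped with the
    label-noise rate.  Truth-actives draw log10(nM) from N(2.0, 0.4)
    truncated below log10(cutoff) - 0.05; truth-inactives from N(4.0, 0.4)
    truncated above log10(cutoff) + 0.05, so in the noiseless,
    full-strength limit curation reproduces the ground truth exactly even
    with replicate jitter (multipliers clipped to [0.9, 1.1]).
    """
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    rng = np.random.default_rng([config.seed, 2])
    log_cut = np.log10(config.cutoff_nm)
    records: list[BioactivityRecord] = []
    truth_rows = []
    rec_no = 0
    for rec in library:
        motif_idx = has_motif(rec.smiles, config.motifs)
        p_active = 0.5 + (config.signal_strength / 2.0) * (1 if motif_idx >= 0 else -1)
        truth_active = rng.random() < p_active
        if rng.random() < config.label_noise:
            truth_active = not truth_active
        if truth_active:
            lg = _truncnorm_log10(rng, 2.0, 0.4, 0.0, log_cut - 0.05)
        else:
            lg = _truncnorm_log10(rng, 4.0, 0.4, log_cut + 0.05, 6.0)
        base_nm = 10.0 ** lg
        n_rep = 1
        if rng.random() < config.duplicate_rate:
            n_rep = int(rng.integers(2, config.max_replicates + 1))
        for _ in range(n_rep):
            mult = float(np.clip(1.0 + rng.normal(0.0, 0.05), 0.9, 1.1))
            value_nm = base_nm * mult
            u = rng.random()
            if u < config.frac_mm:
                value, units = value_nm / 1e6, "mM"
            elif u < config.frac_mm + config.frac_um:
                value, units = value_nm / 1e3, "uM"
            else:
                value, units = value_nm, "nM"
            measure = "IC50" if rng.random() < 0.7 else "Ki"
            source = "chembl" if rng.random() < 0.5 else "bindingdb"
            rec_no += 1
            records.append(BioactivityRecord(rec.compound_id, "TGT1", measure,
                                             float(value), units, source,
                                             record_id=f"syn{rec_no:06d}"))
        if rng.random() < config.frac_other_measure:
            rec_no += 1
            records.append(BioactivityRecord(rec.compound_id, "TGT1", "EC50",
                                             float(base_nm), "nM", "chembl",
                                             record_id=f"syn{rec_no:06d}"))
        truth_rows.append({"compound_id": rec.compound_id, "motif_idx": motif_idx,
                           "truth_active": bool(truth_active),
                           "true_mean_nM": base_nm})
    return records, pd.DataFrame(truth_rows)


def generate_docking_scores(
    library: CompoundLibrary, config: GeneratorConfig
) -> dict[str, float]:
    """Docking scores affine in the activity latent: −(a·latent + ε).

    Motif-bearing compounds get latent in [0.7, 1.0], others in [0, 0.3];
    ε ~ N(0, σ²).  With σ = 0 and a > 0 the ranking is exactly the latent
    ranking, so top-k selection recovers the highest-signal compounds.
    """
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    rng = np.random.default_rng([config.seed, 3])
    scores: dict[str, float] = {}
    for rec in library:
        motif = has_motif(rec.smiles, config.motifs) >= 0
        latent = 0.7 + 0.3 * rng.random() if motif else 0.3 * rng.random()
        eps = rng.normal(0.0, config.dock_sigma) if config.dock_sigma > 0 else 0.0
        scores[rec.compound_id] = float(-(config.dock_scale * latent + eps))
    return scores


#: (band if endpoint passes, band if it fails) on each endpoint's own scale
_ADMET_BANDS = {
    "logP": ((0.5, 2.8), (3.2, 6.0)),
    "HIA": ((0.75, 0.99), (0.05, 0.6)),
    "F30": ((0.75, 0.99), (0.05, 0.6)),
    "BBB": ((0.75, 0.99), (0.05, 0.6)),
    "T_half": ((1.0, 24.0), (0.05, 0.4)),
    "hERG": ((0.01, 0.25), (0.4, 0.95)),
    "H_HT": ((0.01, 0.25), (0.4, 0.95)),
    "Ames": ((0.01, 0.25), (0.4, 0.95)),
}


def generate_admet_table(
    ids: list[str], config: GeneratorConfig
) -> tuple[dict[str, dict[str, float]], pd.DataFrame]:
    """Endpoint table with per-endpoint pass probability ``admet_pass_rate``.

    Values are drawn inside bands that sit strictly within (pass) or
    outside (fail) the default acceptance rules, so the intended verdicts
    are unambiguous; the truth table records the intended n_pass.
    """
    if not ids:
        raise ValueError("ids must be non-empty")
    rng = np.random.default_rng([config.seed, 4])
    table: dict[str, dict[str, float]] = {}
    truth_rows = []
    for cid in ids:
        row = {}
        n_pass = 0
        for endpoint, (pass_band, fail_band) in _ADMET_BANDS.items():
            ok = rng.random() < config.admet_pass_rate
            lo, hi = pass_band if ok else fail_band
            row[endpoint] = float(lo + (hi - lo) * rng.random())
            n_pass += ok
        table[cid] = row
        truth_rows.append({"compound_id": cid, "intended_n_pass": n_pass})
    return table, pd.DataFrame(truth_rows)


def generate_refsets(
    config: GeneratorConfig,
) -> tuple[list[ReferenceSet], pd.DataFrame]:
    """Reference ligand sets: each target's ligands share a distinct motif."""
    if config.n_targets < 2:
        raise ValueError("n_targets must be >= 2")
    rng = np.random.default_rng([config.seed, 5])
    refsets, truth_rows = [], []
    for t in range(config.n_targets):
        motif = config.motifs[t]
        ligands = [canonicalize(_build_smiles(rng, motif))
                   for _ in range(config.n_ligands_per_target)]
        target_id = f"T{t + 1}"
        refsets.append(ReferenceSet(target_id, ligands))
        truth_rows.append({"target_id": target_id, "motif": motif})
    return refsets, pd.DataFrame(truth_rows)


def make_query(config: GeneratorConfig, motif_idx: int, seed: int) -> str:
    """One motif-bearing query compound (for target-recovery evaluations)."""
    rng = np.random.default_rng([seed, 6])
    return canonicalize(_build_smiles(rng, config.motifs[motif_idx]))


def modeling_config(config: GeneratorConfig | None = None, n: int = 500,
                    seed: int = 7) -> GeneratorConfig:
    """Conditions for the QSAR modeling dataset: a smaller untagged library
    with balanced motif placement (rate 0.5) so both classes are populated."""
    base = config or GeneratorConfig()
    return replace(base, n_library=n, n_tagged=0, motif_rate_untagged=0.5, seed=seed)
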