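"""End-to-end demonstration pipeline on fully synthetic inputs.

``run_demo`` wires every stage together under one seed: it generates the
screening library (1,616 compounds, 114 double-tagged), a separate
modeling library with bioactivity records, curates and labels those
records, trains the three-family consensus QSAR model, generates docking
scores and ADMET tables, and runs the cascade.  The result's stage counts
start [114, 25] by construction of the generator defaults and the top-k
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cascade import CascadeConfig, CascadeResult, run_cascade
from .curation import LabeledDataset, build_dataset
from .descriptors import featurize_library
from .qsar import ConsensusModel, CVReport, evaluate, train_consensus
from .synthetic import GeneratorConfig, generate_admet_table, generate_bioactivity, \
    generate_docking_scores, generate_library, modeling_config


def train_demo_model(
    config: GeneratorConfig | None = None,
    n: int = 400,
    seed: int = 7,
    hyperparams: dict | None = None,
    with_cv: bool = False,
) -> tuple[ConsensusModel, LabeledDataset, CVReport | None]:
    """Generate a modeling dataset and train the consensus QSAR model."""
    mconf = modeling_config(config, n=n, seed=seed)
    mlib, _ = generate_library(mconf)
    records, _ = generate_bioactivity(mlib, mconf)
    dataset = build_dataset(records, mlib, cutoff_nm=mconf.cutoff_nm)
    keep = set(dataset.ids())
    sub = type(mlib)([r for r in mlib if r.compound_id in keep])
    features = featurize_library(sub)
    report = evaluate(features, dataset, k=5, seed=seed, hyperparams=hyperparams) if with_cv else None
    model = train_consensus(features, dataset, hyperparams, seed=seed)
    return model, dataset, report


@dataclass
class DemoRun:
    result: CascadeResult
    cv_report: CVReport | None
    config: GeneratorConfig


def run_demo(
    seed: int = 42,
    config: GeneratorConfig | None = None,
    hyperparams: dict | None = None,
    with_cv: bool = False,
    model: ConsensusModel | None = None,
) -> DemoRun:
    """Full synthetic cascade run; deterministic per seed."""
    gconf = config or GeneratorConfig(seed=seed)
    library, _ = generate_library(gconf)
    scores = generate_docking_scores(library, gconf)
    admet, _ = generate_admet_table(library.ids(), gconf)
    cv = None
    if model is None:
        model, _, cv = train_demo_model(gconf, seed=seed + 1, hyperparams=hyperparams,
                                        with_cv=with_cv)
    cconf = CascadeConfig(seed=seed)
    result = run_cascade(library, scores, model, admet, cconf)
    return DemoRun(result=result, cv_report=cv, config=gconf)
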