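"""Shared fixtures: tiny hand-built objects plus session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from modpanel import genes as gs
from modpanel.dataset import ExpressionDataset
from modpanel.repertoire import build_repertoire
from modpanel.simulate import SimulationConfig, simulate_selection_scenario, simulate_study


def make_dataset(values: dict[str, dict[str, float]], timepoints: dict[str, str],
                 platform: str = "counts", cohort: str = "c") -> ExpressionDataset:
    """Build a small dataset from {gene: {sample: value}} and {sample: timepoint}."""
    matrix = pd.DataFrame(values).T
    samples = pd.DataFrame({
        "subject_id": {s: f"subj_{s}" for s in matrix.columns},
        "timepoint": timepoints,
        "cohort": {s: cohort for s in matrix.columns},
        "platform": {s: platform for s in matrix.columns},
    })
    samples.index.name = "sample_id"
    return ExpressionDataset(matrix=matrix, samples=samples)


@pytest.fixture
def tiny_rep():
    """3 modules in 2 aggregates, 2-3 genes each."""
    return build_repertoire(
        {"M1.1": ["g1", "g2", "g3"], "M1.2": ["g4", "g5"], "M2.1": ["g6", "g7"]},
        {"M1.1": "A1", "M1.2": "A1", "M2.1": "A2"},
    )


@pytest.fixture(scope="session")
def scenario():
    """Deterministic noise-free screening scenario at the published scale."""
    return simulate_selection_scenario(0)


@pytest.fixture(scope="session")
def scenario_run(scenario):
    """Scenario plus the full screening/assembly results computed once."""
    records = gs.score_genes(scenario.ds_counts, scenario.ds_intensity,
                             scenario.repertoire, scenario.set_modules,
                             scenario.annotations)
    selections = gs.select_genes_per_set(records)
    core = {k: v for k, v in selections.items() if v}
    empty = [k for k in scenario.set_modules if not selections.get(k)]
    short = {k: [g for g in scenario.repertoire.genes_of_modules(scenario.set_modules[k])
                 if g not in selections.get(k, [])]
             for k in scenario.set_modules if 0 < len(selections.get(k, [])) < 4}
    panel = gs.supplement_panel(core, scenario.excluded_aggregates, empty, short,
                                scenario.ds_counts, scenario.annotations,
                                scenario.repertoire, scenario.set_modules)
    panel.housekeeping = gs.select_housekeeping(
        scenario.ds_counts, scenario.ds_intensity, scenario.prior_hk,
        scenario.literature_hk, exclude=set(panel.test_genes))
    return {"scenario": scenario, "records": records, "selections": selections,
            "core": core, "empty": empty, "short": short, "panel": panel}


@pytest.fixture(scope="session")
def mini_study():
    """Small (6 aggregates x 5 modules x 10 genes) synthetic study."""
    return simulate_study(SimulationConfig.miniature(seed=11))


@pytest.fixture(scope="session")
def full_study():
    """Published-scale synthetic study (38 aggregates / 382 modules)."""
    return simulate_study(SimulationConfig(seed=1234))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
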