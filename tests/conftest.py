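import numpy as np
import pandas as pd
import pytest

from bearhr.gps_qc import qc_trajectories
from bearhr.homerange import estimate_home_ranges
from bearhr.morpho import assemble_table, fit_pca
from bearhr.simulate import (
    ErrorModel,
    MovementParams,
    PopulationSpec,
    simulate_population,
    simulate_trajectory,
)

import helpers


@pytest.fixture(scope="session")
def clean_track() -> pd.DataFrame:
    """Reference bear: clean 2000-fix 1-h OU track, sigma = 2000 m, seed 1."""
    return helpers.make_clean_track()


@pytest.fixture(scope="session")
def small_pipeline():
    """A 16-bear population run end-to-end (corruption, QC, MCP, morpho, PCA)."""
    spec = PopulationSpec(n_males=10, n_females=6, seed=11)
    mp = MovementParams(n_fixes=400)
    trajs, morpho, truth = simulate_population(spec, mp, ErrorModel())
    clean, reports = qc_trajectories(trajs)
    hr, artifacts = estimate_home_ranges(clean, include_kud=False)
    pca = fit_pca(morpho, "four")
    bears = assemble_table(hr, morpho, pca=pca)
    return {
        "trajectories": trajs,
        "clean": clean,
        "qc_reports": reports,
        "home_ranges": hr,
        "morpho": morpho,
        "truth": truth,
        "pca": pca,
        "bears": bears,
    }
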