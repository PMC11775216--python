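import numpy as np
import pandas as pd
import pytest

import sdgspace as s


@pytest.fixture(scope="session")
def clean_planted():
    """Small noise-free planted panel: exact block structure end to end."""
    spec = s.SyntheticSpec(n_countries=20, n_indicators=12, n_years=3,
                           noise_sd=0.0, seed=11)
    panel, truth = s.generate_panel(spec)
    return spec, panel, truth


@pytest.fixture(scope="session")
def clean_year(clean_planted):
    """One complete year matrix plus derived RCA and binary advantage."""
    _, panel, truth = clean_planted
    matrix = s.select_year(panel, 2000)
    spec_m = s.compute_rca(matrix)
    m = s.binarize_advantage(spec_m)
    return matrix, spec_m, m, truth


@pytest.fixture(scope="session")
def study_scale_panel():
    """Default-shape panel (166 x 96 x 23) at the generator's default noise."""
    spec = s.default_study_shape()
    panel, truth = s.generate_panel(spec)
    return spec, panel, truth


@pytest.fixture(scope="session")
def study_scale_year(study_scale_panel):
    _, panel, truth = study_scale_panel
    matrix = s.select_year(panel, 2022)
    spec_m = s.compute_rca(matrix)
    m = s.binarize_advantage(spec_m)
    indices = s.eigen_indices(m, scores=matrix)
    return matrix, spec_m, m, indices, truth


def random_score_matrix(rng: np.random.Generator, n_countries: int,
                        n_indicators: int, year: int = 2020) -> s.ScoreMatrix:
    values = rng.uniform(5.0, 95.0, size=(n_countries, n_indicators))
    frame = pd.DataFrame(values,
                         index=[f"C{i:02d}" for i in range(n_countries)],
                         columns=[f"I{j:02d}" for j in range(n_indicators)])
    return s.ScoreMatrix(year=year, values=frame)
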