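import numpy as np
import pytest
from hypothesis import settings

import brushmech as bm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Table 1 printed rows, used across test modules
TABLE_ROWS = [
    # chemistry, ratio, n_sc, n_x, E, beta, E0, lmax_exp, lmax_calc
    ("NCO:OH", "1:1", 14, 50, 18.6, 0.24, 27.8, 2.1, 2.0),
    ("NCO:OH", "1:2", 14, 100, 11.1, 0.12, 13.5, 2.7, 2.9),
    ("NCO:OH", "1:4", 14, 200, 4.2, 0.10, 5.1, 3.2, 3.2),
    ("NCO:OH", "1:8", 14, 400, 2.1, 0.08, 2.3, 3.6, 3.5),
    ("NCO:OH", "1:1", 70, 50, 3.0, 0.31, 5.3, 1.9, 1.8),
    ("NCO:OH", "1:2", 70, 100, 1.3, 0.26, 2.1, 2.2, 2.0),
    ("F:M", "1:1", 14, 50, 15.3, 0.23, 22.3, 2.1, 2.1),
    ("F:M", "2:1", 14, 100, 6.3, 0.14, 7.8, 2.7, 2.6),
    ("F:M", "4:1", 14, 200, 1.5, 0.12, 1.8, 2.9, 2.8),
    ("PCMA", "1.5", 14, 100, 4.8, 0.06, 5.2, 4.2, 4.1),
    ("PCMA", "3", 14, 200, 1.7, 0.05, 1.8, 4.9, 4.5),
]


@pytest.fixture(scope="session")
def reference_table() -> bm.ReferenceTable:
    return bm.gen_table1_fixture()


@pytest.fixture
def elastic_tpa_trace():
    trace, truth = bm.gen_tpa()
    return trace, truth


def make_curve(E, beta, n_points=60, lam_max=None, noise=None, seed=None):
    nm = noise if noise is not None else bm.NoiseModel()
    curve, _ = bm.gen_tensile(E=E, beta=beta, n_points=n_points, lam_max=lam_max, noise=nm, seed=seed)
    return curve
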