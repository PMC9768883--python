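import numpy as np
import pandas as pd
import pytest

import corticospec as cs


@pytest.fixture(scope="session")
def atlas():
    return cs.make_atlas(0)


@pytest.fixture(scope="session")
def points(atlas):
    return [
        cs.SphericalPoint(r.colatitude_rad, r.longitude_rad)
        for r in atlas.itertuples()
    ]


@pytest.fixture(scope="session")
def basis7(points):
    return cs.build_basis(points, 7)


@pytest.fixture(scope="session")
def table1():
    return cs.table1_fixture()


@pytest.fixture(scope="session")
def truth(atlas):
    return cs.default_truth(atlas, J=9, L=7, seed=11)


@pytest.fixture(scope="session")
def small_ds(atlas, table1, truth, basis7):
    return cs.simulate_thickness(atlas, table1, truth, basis7)


@pytest.fixture(scope="session")
def fast_config():
    return cs.ModelConfig(iterations=900, burn_in=300, thinning=3, seed=7)


@pytest.fixture(scope="session")
def fitted_samples(small_ds, fast_config):
    """One study-scale fit shared by the model/FDR tests."""
    return cs.fit_thickness_model(small_ds, fast_config)


def random_sphere_points(rng, n):
    u = rng.uniform(-1.0, 1.0, size=n)
    lon = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return [
        cs.SphericalPoint(float(np.arccos(c)), float(t)) for c, t in zip(u, lon)
    ]


@pytest.fixture()
def two_group_cohort():
    def make(rng, n_hc=15, n_pat=15):
        rows = []
        for i in range(n_hc):
            rows.append({"subject_id": f"H{i:03d}", "group": "HC",
                         "age": float(rng.normal(28, 6)),
                         "sex": "M" if i % 2 else "F"})
        for i in range(n_pat):
            rows.append({"subject_id": f"P{i:03d}", "group": "LTLE",
                         "age": float(rng.normal(32, 8)),
                         "sex": "M" if i % 3 else "F"})
        return pd.DataFrame(rows)

    return make
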