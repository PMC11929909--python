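import numpy as np
import pytest

import qpop


@pytest.fixture(scope="session")
def design():
    return qpop.build_oacd(12)


@pytest.fixture(scope="session")
def panel():
    return qpop.default_panel()


@pytest.fixture(scope="session")
def noiseless_fit(design):
    """Ground truth + the model fitted to its noiseless plate."""
    truth = qpop.gen_ground_truth(
        12, planted_pairs=[(0, 1)], effect_scale=0.2, noise_sd=0.0, seed=7
    )
    plate = qpop.simulate_plate(truth, design, seed=11)
    model = qpop.fit_quadratic(qpop.normalize(plate), design)
    return truth, model


def brute_force_pair_ranking(model):
    """Independent oracle: explicit loops over all pairs and level choices."""
    F = model.n_factors
    rows = []
    for i in range(F):
        for j in range(i + 1, F):
            preds = []
            for li in (1, 2):
                for lj in (1, 2):
                    vec = np.zeros(F)
                    vec[i], vec[j] = li, lj
                    preds.append(model.predict(vec))
            preds = np.array(preds)
            rows.append(((i, j), preds.mean(), preds.std(ddof=1)))
    rows.sort(key=lambda r: (r[1], r[0]))
    return rows
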