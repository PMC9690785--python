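"""Shared fixtures: a small simulated clustered dataset and a quick fit.

Everything is generated programmatically with fixed seeds; no stored fixtures.
"""

import numpy as np
import pytest

import riaft_bart as rb
from riaft_bart.data_model import McmcConfig, PosteriorDraws


@pytest.fixture(scope="session")
def ph_sim():
    """A modest PH-scenario dataset with its analytic truth."""
    cfg = rb.ScenarioConfig(n=400, n_clusters=15, seed=42)
    dataset, truth = rb.simulate(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def fitted(ph_sim):
    """A quick riAFT-BART fit on the session dataset (reduced settings)."""
    _, dataset, _ = ph_sim
    cfg = McmcConfig(n_trees=20, n_burn=150, n_keep=150, seed=7)
    draws = rb.fit_riaft(dataset, cfg)
    return dataset, draws


def make_constant_draws(
    f_by_arm: dict[int, float],
    sigma: float = 0.5,
    tau: float = 0.3,
    n_keep: int = 4,
    n_clusters: int = 2,
    n_covariates: int = 2,
    n_treatments: int = 3,
    intercepts: np.ndarray | None = None,
) -> PosteriorDraws:
    """Fabricate a PosteriorDraws object whose regression function is constant
    in x and depends on treatment only: each per-draw forest is one depth-1..2
    tree stump over the treatment indicator columns.

    Used as a frozen-draw oracle: f(a, x) = f_by_arm[a] exactly, every draw.
    """
    p = n_covariates
    z = n_treatments
    # one tree splitting on the arm-2 indicator (column p; indicator 1 goes
    # right), whose left child splits on the arm-3 indicator (column p+1);
    # arm 1 has both indicators zero
    var = np.array([p, p + 1, -1, -1, -1], dtype=np.int32)
    cut = np.array([0.5, 0.5, 0.0, 0.0, 0.0])
    left = np.array([1, 3, -1, -1, -1], dtype=np.int32)
    right = np.array([2, 4, -1, -1, -1], dtype=np.int32)
    # node 2: arm 2; node 3: arm 1; node 4: arm 3
    value = np.array([0.0, 0.0, f_by_arm[2], f_by_arm[1], f_by_arm[3]])
    if z == 2:
        var = np.array([p, -1, -1], dtype=np.int32)
        cut = np.array([0.5, 0.0, 0.0])
        left = np.array([1, -1, -1], dtype=np.int32)
        right = np.array([2, -1, -1], dtype=np.int32)
        value = np.array([0.0, f_by_arm[1], f_by_arm[2]])
    forest = {
        "var": var, "cut": cut, "left": left, "right": right, "value": value,
        "tree_offsets": np.array([0, len(var)], dtype=np.int64),
    }
    b = intercepts if intercepts is not None else np.zeros(n_clusters)
    return PosteriorDraws(
        train_fit=np.zeros((n_keep, 1)),
        intercepts=np.tile(b, (n_keep, 1)),
        sigma=np.full(n_keep, sigma),
        tau=np.full(n_keep, tau),
        latent=np.zeros((n_keep, 1)),
        y_center=0.0,
        y_scale=1.0,  # identity outcome scaling: leaf values are log-time units
        cluster_ids=[f"c{k}" for k in range(n_clusters)],
        design_names=[f"x{i + 1}" for i in range(p)]
        + [f"treatment_{a}" for a in range(2, z + 1)],
        n_treatments=z,
        seed=0,
        forests=[forest] * n_keep,
    )
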