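"""Shared fixtures: all test inputs are generated in memory or in tmp dirs."""

import numpy as np
import pytest
from hypothesis import settings

from structscope import make_complex, make_interaction_cluster, make_pose_ensemble

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def complex_fixture():
    """Default planted complex: 7 focal contacts, 3 surviving Leu->Pro."""
    return make_complex(seed=11)


@pytest.fixture(scope="session")
def cluster_fixture():
    return make_interaction_cluster(seed=0)


@pytest.fixture()
def pose_ensemble(tmp_path):
    """Planted 40-pose ensemble (30% above-leaflet, 20% far C-terminus)."""
    return make_pose_ensemble(seed=23, n_poses=40, out_dir=tmp_path / "poses")


def brute_force_pairs(model, group_a, group_b, cutoff):
    """All-pairs oracle: cross-group residue pairs with min heavy-atom
    distance <= cutoff.  Returns {(key_a, key_b): min_distance}."""
    out = {}
    res_a = [r for cid in group_a for r in model.chains[cid]
             if not r.is_water and not (r.is_hetero and not r.is_water)]
    res_b = [r for cid in group_b for r in model.chains[cid]
             if not r.is_water and not (r.is_hetero and not r.is_water)]
    for ra in res_a:
        ca = np.array([a.coords for a in ra.heavy_atoms()])
        for rb in res_b:
            cb = np.array([a.coords for a in rb.heavy_atoms()])
            d = float(np.min(np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)))
            if d <= cutoff:
                out[(ra.key, rb.key)] = d
    return out
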