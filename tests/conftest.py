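import numpy as np
import pytest

from confenum.geometry_core import build_backbone, default_params

# the five well-separated Ramachandran basins used for planted-cluster tests
CLUSTER_MODES = [(-63, -43), (-120, 130), (-70, -20), (55, 40), (-150, 155)]


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def cluster_maker(params):
    """Factory for k planted torsion clusters of backbone conformations."""

    def make(k, n_each, seed, n_res=6):
        rng = np.random.default_rng(seed)
        confs, labels = [], []
        for ci, (m_phi, m_psi) in enumerate(CLUSTER_MODES[:k]):
            for _ in range(n_each):
                torsions = [
                    (m_phi + rng.normal(0, 3), m_psi + rng.normal(0, 3))
                    for _ in range(n_res)
                ]
                confs.append(build_backbone("AVLKEQ"[:n_res], torsions, params))
                labels.append(ci)
        return confs, labels

    return make
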