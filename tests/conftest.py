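"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

import fcharm as f


@pytest.fixture(scope="session")
def study():
    """Full-design synthetic study at a small edge count (seeded)."""
    ms, tr, truth = f.generate_study(f.paper_scale_config(n_edges=250), seed=11)
    return {"multisite": ms, "traveling": tr, "truth": truth,
            "combined": f.concat_datasets(ms, tr)}


@pytest.fixture(scope="session")
def decomposition(study):
    return f.fit_all_edges(study["combined"], lam=1.0)


def make_dataset(values, site, diagnosis, kind, participant=None, session=None):
    """Hand-rolled dataset from parallel per-row metadata lists."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    participant = participant or [f"p{i}" for i in range(n)]
    session = session or ["1"] * n
    meta = pd.DataFrame({
        "row_id": [f"r{i}" for i in range(n)],
        "participant_id": participant,
        "site_id": site,
        "diagnosis": diagnosis,
        "dataset_kind": kind,
        "session_id": session,
    })
    n_edges = values.shape[1]
    k = 2
    while k * (k - 1) // 2 < n_edges:
        k += 1
    edge_index = f.EdgeIndex(n_nodes=k, pairs=f.build_edge_index(k).pairs[:n_edges])
    return f.ConnectivityDataset(values=values, meta=meta, edge_index=edge_index)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
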