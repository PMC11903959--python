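import numpy as np
import pytest

from dfconn import (
    EnsembleSpec,
    build_meta_trajectory,
    build_spring_graph,
    build_toy_dimer,
    compute_df,
    sample_gnm_trajectory,
)
from dfconn.topology import MetaTrajectory


@pytest.fixture(scope="session")
def toy_dimer():
    """20 residues per protomer, deterministic."""
    return build_toy_dimer(20, seed=7)


@pytest.fixture(scope="session")
def toy_springs(toy_dimer):
    structure, _ = toy_dimer
    return build_spring_graph(structure)


@pytest.fixture(scope="session")
def toy_ensemble(toy_dimer, toy_springs):
    structure, spec = toy_dimer
    espec = EnsembleSpec(n_replicas=2, frames_per_replica=120, spacing_ps=10.0,
                         temperature_factor=0.5, seed=11)
    trajs = sample_gnm_trajectory(structure, toy_springs, espec)
    meta = build_meta_trajectory(trajs, structure)
    return structure, spec, meta


@pytest.fixture(scope="session")
def toy_df(toy_ensemble):
    structure, _, meta = toy_ensemble
    return compute_df(meta, structure)


def meta_from_frames(frames):
    """Wrap raw frame coordinates as an already-superposed meta-trajectory."""
    frames = np.asarray(frames, dtype=float)
    return MetaTrajectory(
        coords=frames,
        provenance=[("1", k, float(k)) for k in range(len(frames))],
        reference="frame 0",
        selection=np.arange(frames.shape[1]),
    )
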