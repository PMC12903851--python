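import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

warnings.filterwarnings("ignore", category=DeprecationWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="MDAnalysis")


@pytest.fixture
def toy_complex(tmp_path):
    """Miniature receptor PDB + 3-pose ligand SDF."""
    from replaypose.synthetic import make_toy_complex

    receptor, poses = make_toy_complex(20, 6, seed=3, out_dir=tmp_path / "fix")
    return receptor, poses


@pytest.fixture
def small_toy_buffer():
    """A small replay buffer on a 1-D harmonic landscape (deterministic)."""
    from replaypose.propagation import HarmonicWell, SystemState, ToyLangevinPropagator
    from replaypose.replay import ProtocolConfig, run_protocol

    land = HarmonicWell(center=np.zeros(1), k=1.0, kT=0.5)
    prop = ToyLangevinPropagator(landscape=land, dt=0.01)
    rng = np.random.default_rng(5)
    poses = [SystemState(coords=rng.normal(size=1), tag=f"pose_{i+1}") for i in range(3)]
    config = ProtocolConfig(
        n_poses=3,
        n_init_replicates=2,
        free_ps=0.3,
        restrained_ps=0.1,
        n_mc_steps=14,
        seed=42,
        restraint_force_constant=5.0,
    )
    return run_protocol(poses, None, config, prop)
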