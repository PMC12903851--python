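"""Replay-buffer engine: size law, lineage, determinism, selection, retries."""

import numpy as np
import pytest
from scipy.stats import chisquare

from replaypose.errors import PropagationError, ValidationError
from replaypose.propagation import (
    HarmonicWell,
    PropagationResult,
    SystemState,
    ToyLangevinPropagator,
)
from replaypose.replay import (
    BufferEntry,
    ProtocolConfig,
    ReplayBuffer,
    initialize_buffer,
    mc_step,
    run_protocol,
)
from replaypose.synthetic import TwoBasinSpec, make_two_basin_system


def _prop(dim=1, kT=0.5, dt=0.01):
    return ToyLangevinPropagator(landscape=HarmonicWell(center=np.zeros(dim), kT=kT), dt=dt)


def _poses(n, dim=1, seed=0):
    rng = np.random.default_rng(seed)
    return [SystemState(coords=rng.normal(size=dim), tag=f"pose_{i+1}") for i in range(n)]


def _config(P, R, S, seed=1, **kw):
    kw.setdefault("restraint_force_constant", 5.0)
    kw.setdefault("free_ps", 0.2)
    kw.setdefault("restrained_ps", 0.1)
    return ProtocolConfig(n_poses=P, n_init_replicates=R, n_mc_steps=S, seed=seed, **kw)


class TestSizeLaw:
    @pytest.mark.parametrize("P,R,S", [(2, 3, 5), (1, 1, 0), (3, 2, 4), (4, 1, 7)])
    def test_buffer_size_is_poses_times_replicates_plus_steps(self, P, R, S):
        buf = run_protocol(_poses(P), None, _config(P, R, S), _prop())
        assert len(buf) == P * R + S
        assert buf.lineage_is_forest()

    def test_single_pose_single_replicate(self):
        buf = initialize_buffer(_poses(1), None, _config(1, 1, 0), _prop())
        assert len(buf) == 1
        assert buf[0].mc_step == 0 and buf[0].parent_index is None

    def test_zero_mc_steps_equals_initialization(self):
        cfg = _config(2, 2, 0)
        a = run_protocol(_poses(2), None, cfg, _prop())
        b = initialize_buffer(_poses(2), None, cfg, _prop())
        assert np.array_equal(a.energies(), b.energies())

    def test_each_step_grows_buffer_by_one(self):
        cfg = _config(1, 2, 0)
        buf = initialize_buffer(_poses(1), None, cfg, _prop())
        for step in (1, 2, 3):
            before = len(buf)
            mc_step(buf, cfg, _prop(), step)
            assert len(buf) == before + 1


class TestDeterminism:
    def test_identical_seed_gives_bitwise_identical_buffer(self):
        cfg = _config(2, 2, 6, seed=9)
        a = run_protocol(_poses(2), None, cfg, _prop())
        b = run_protocol(_poses(2), None, cfg, _prop())
        assert np.array_equal(a.energies(), b.energies())
        assert np.array_equal(a.coords_array(), b.coords_array())
        assert [e.parent_index for e in a] == [e.parent_index for e in b]


class TestParentSelection:
    def test_singleton_buffer_forces_parent_zero(self):
        cfg = _config(1, 1, 0)
        buf = initialize_buffer(_poses(1), None, cfg, _prop())
        entry = mc_step(buf, cfg, _prop(), 1)
        assert entry.parent_index == 0

    def test_selection_uniform_over_growing_buffer(self):
        # u = parent / current_size must be uniform on [0, 1)
        cfg = _config(5, 10, 400, seed=3, free_ps=0.05, restrained_ps=0.05)
        buf = run_protocol(_poses(5), None, cfg, _prop())
        parents = np.array([e.parent_index for e in buf if e.mc_step > 0])
        sizes = 50 + np.arange(parents.size)
        counts, _ = np.histogram(parents / sizes, bins=10, range=(0, 1))
        assert chisquare(counts).pvalue >= 0.01

    def test_boltzmann_extension_prefers_low_energy(self):
        buf = ReplayBuffer(seed=0)
        for i, e in enumerate([-10.0, 0.0, 0.0, 0.0]):
            buf.append(BufferEntry(
                state=SystemState(coords=np.zeros(1), tag=f"e{i}"),
                averaged_energy=e, origin_pose="p", mc_step=0,
            ))
        cfg = _config(1, 1, 0, parent_selection="boltzmann", selection_kt=1.0)
        picks = []
        for step in range(1, 60):
            entry = mc_step(buf, cfg, _prop(), step)
            picks.append(entry.parent_index)
        assert np.mean(np.asarray(picks[:20]) == 0) > 0.5


class _FlakyPropagator:
    """Fails the free segment on its first `n_fail` calls."""

    def __init__(self, inner, n_fail):
        self.inner, self.n_fail, self.calls = inner, n_fail, 0

    def propagate_free(self, state, duration, seed):
        self.calls += 1
        if self.calls <= self.n_fail:
            raise PropagationError("synthetic failure", tag=state.tag)
        return self.inner.propagate_free(state, duration, seed)

    def propagate_restrained_average(self, *args, **kw):
        return self.inner.propagate_restrained_average(*args, **kw)


class TestFailurePolicy:
    def test_step_retries_then_succeeds(self):
        cfg = _config(1, 1, 0)
        buf = initialize_buffer(_poses(1), None, cfg, _prop())
        flaky = _FlakyPropagator(_prop(), n_fail=2)
        entry = mc_step(buf, cfg, flaky, 1)
        assert entry.mc_step == 1 and len(buf) == 2

    def test_step_aborts_after_three_attempts(self):
        cfg = _config(1, 1, 0)
        buf = initialize_buffer(_poses(1), None, cfg, _prop())
        flaky = _FlakyPropagator(_prop(), n_fail=99)
        with pytest.raises(PropagationError):
            mc_step(buf, cfg, flaky, 1)
        assert len(buf) == 1  # nothing appended

    def test_initialization_failure_returns_no_partial_buffer(self):
        flaky = _FlakyPropagator(_prop(), n_fail=99)
        with pytest.raises(PropagationError):
            initialize_buffer(_poses(2), None, _config(2, 2, 0), flaky)


class TestLineageInvariants:
    def test_entry_invariants_enforced(self):
        state = SystemState(coords=np.zeros(1))
        with pytest.raises(Exception):
            BufferEntry(state=state, averaged_energy=0.0, origin_pose="p", mc_step=1)
        with pytest.raises(Exception):
            BufferEntry(state=state, averaged_energy=0.0, origin_pose="p",
                        mc_step=0, parent_index=3)

    def test_lineage_forest_on_protocol_output(self, small_toy_buffer):
        assert small_toy_buffer.lineage_is_forest()
        for e in small_toy_buffer:
            if e.mc_step > 0:
                assert 0 <= e.parent_index < len(small_toy_buffer)


class TestTwoBasinExploration:
    def test_entries_appear_in_both_basins(self):
        land, states, _ = make_two_basin_system(TwoBasinSpec())
        prop = ToyLangevinPropagator(landscape=land, dt=0.01)
        cfg = ProtocolConfig(
            n_poses=2, n_init_replicates=3, free_ps=1.0, restrained_ps=0.3,
            n_mc_steps=60, seed=2, restraint_force_constant=10.0,
        )
        buf = run_protocol(states, None, cfg, prop)
        x = buf.coords_array().ravel()
        assert (x < 0).sum() > 0 and (x >= 0).sum() > 0


class TestSerialization:
    def test_toy_buffer_round_trips_through_directory(self, small_toy_buffer, tmp_path):
        small_toy_buffer.to_dir(tmp_path / "buf")
        back = ReplayBuffer.from_dir(tmp_path / "buf")
        assert len(back) == len(small_toy_buffer)
        assert np.allclose(back.energies(), small_toy_buffer.energies())
        assert np.allclose(back.coords_array(), small_toy_buffer.coords_array())
        assert [e.parent_index for e in back] == [e.parent_index for e in small_toy_buffer]

    def test_molecular_buffer_round_trips_via_pdb(self, tmp_path):
        from replaypose.structures import Structure

        rng = np.random.default_rng(0)
        template = Structure(
            atom_names=["C1", "C2"], elements=["C", "C"],
            coords=rng.random((2, 3)), residue_ids=[("L", "1", "LIG")] * 2,
        )
        buf = ReplayBuffer(seed=0)
        for i in range(3):
            buf.append(BufferEntry(
                state=SystemState(coords=rng.random((2, 3)), tag=f"t{i}"),
                averaged_energy=float(i), origin_pose="p1", mc_step=0,
            ))
        buf.to_dir(tmp_path / "mol", pose_template=template)
        back = ReplayBuffer.from_dir(tmp_path / "mol")
        assert np.abs(back.coords_array() - buf.coords_array()).max() <= 1e-3
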