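"""First-passage times, species populations, transition network, helicity."""

import numpy as np
import pytest

from oligostate.kinetics import (
    ensemble_oligomerization_times,
    helicity_by_oligomer_size,
    oligomerization_times,
    species_populations,
    transition_network,
)
from oligostate.oligomers import OligomerPartition, detect_oligomers
from oligostate.secondary import assign_ss_frame
from oligostate.synthetic import AssemblyScript, Event, canonical_script, generate


def _partition(components, frame=0):
    return OligomerPartition(frame_index=frame, edges=[], components=components)


class TestOligomerizationTimes:
    def test_scripted_first_passages_exact(self, stepwise_trajectory):
        script, top, frames, labels = stepwise_trajectory
        ot = oligomerization_times(labels.largest_sizes(), script.save_interval_ps)
        assert ot.as_tuple() == (2000.0, 7000.0, 18000.0)
        detected = np.array(
            [detect_oligomers(top, fr).largest_size for fr in frames]
        )
        ot2 = oligomerization_times(detected, script.save_interval_ps)
        assert ot2.as_tuple() == (2000.0, 7000.0, 18000.0)

    def test_dimer_at_frame_zero_gives_zero(self):
        ot = oligomerization_times(np.array([2, 2, 3]), 10.0)
        assert ot.ot2_ps == 0.0
        assert ot.ot3_ps == 20.0

    def test_never_formed_is_none_not_zero(self):
        ot = oligomerization_times(np.ones(10, dtype=int), 10.0)
        assert ot.as_tuple() == (None, None, None)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sizes = np.minimum.accumulate(rng.integers(1, 5, size=30)[::-1])[::-1]
            # any monotone-nondecreasing size sequence
            sizes = np.maximum.accumulate(rng.integers(1, 5, size=30))
            ot = oligomerization_times(sizes, 10.0)
            vals = [v for v in ot.as_tuple() if v is not None]
            assert vals == sorted(vals)

    def test_ensemble_stats(self):
        ots = [oligomerization_times(np.array([1, 2, 2]), 10.0),
               oligomerization_times(np.array([2, 2, 2]), 10.0),
               oligomerization_times(np.array([1, 1, 1]), 10.0)]
        stats = ensemble_oligomerization_times(ots)
        assert stats["OT2"]["n_defined"] == 2
        assert stats["OT2"]["n_undefined"] == 1
        assert stats["OT2"]["mean_ps"] == pytest.approx(5.0)
        assert stats["OT3"]["mean_ps"] is None


class TestSpeciesPopulations:
    def test_all_monomer(self):
        traj = [[_partition([[0], [1], [2], [3]], f)] for f in range(3)]
        # one trajectory with 3 frames
        sp = species_populations([list(np.concatenate(traj))], 10.0)
        np.testing.assert_allclose(sp.fractions[:, 0], 1.0)
        np.testing.assert_allclose(sp.fractions[:, 1:], 0.0)

    def test_two_dimers_frame(self):
        sp = species_populations([[_partition([[0, 1], [2, 3]])]], 10.0)
        np.testing.assert_allclose(sp.fractions[0], [0.0, 1.0, 0.0, 0.0])

    def test_fractions_sum_to_one(self, stepwise_trajectory):
        script, top, frames, _ = stepwise_trajectory
        parts = [detect_oligomers(top, fr) for fr in frames[::10]]
        sp = species_populations([parts], script.save_interval_ps)
        np.testing.assert_allclose(sp.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_staggered_ensemble_matches_hand_computation(self):
        # two trajectories: dimer at frame 1 in one, at frame 2 in the other
        t1 = [_partition([[0], [1], [2], [3]]),
              _partition([[0, 1], [2], [3]]),
              _partition([[0, 1], [2], [3]])]
        t2 = [_partition([[0], [1], [2], [3]]),
              _partition([[0], [1], [2], [3]]),
              _partition([[0, 1], [2], [3]])]
        sp = species_populations([t1, t2], 10.0)
        np.testing.assert_allclose(sp.fractions[:, 1], [0.0, 0.25, 0.5])
        np.testing.assert_allclose(sp.fractions[:, 0], [1.0, 0.75, 0.5])

    def test_length_mismatch_rejected(self):
        t1 = [_partition([[0], [1], [2], [3]])]
        t2 = t1 * 2
        with pytest.raises(ValueError, match="frames"):
            species_populations([t1, t2], 10.0)


class TestTransitionNetwork:
    def test_constant_state(self):
        net = transition_network([["I"] * 10])
        assert net.counts.sum() == 0
        assert net.populations_pct[0] == 100.0

    def test_hand_counted_undirected(self):
        net = transition_network([["I", "II", "I", "II"]])
        assert net.count("I", "II") == 3

    def test_monotone_growth_classification(self):
        net = transition_network([["I", "II", "IV", "VII"]])
        assert net.n_growth() == 3
        assert net.n_rearranging() == 0

    def test_rearranging_detected(self):
        net = transition_network([["VII", "VIII", "VII"]])
        assert net.n_rearranging() == 2
        assert net.n_growth() == 0

    def test_pooling_is_additive(self):
        seq1 = ["I", "II", "II", "III"]
        seq2 = ["I", "I", "II", "I"]
        pooled = transition_network([seq1, seq2])
        n1 = transition_network([seq1])
        n2 = transition_network([seq2])
        np.testing.assert_array_equal(pooled.counts, n1.counts + n2.counts)

    def test_populations_sum_to_100(self, stepwise_trajectory):
        _, _, _, labels = stepwise_trajectory
        net = transition_network([labels.state_labels])
        assert net.populations_pct.sum() == pytest.approx(100.0, abs=0.01)


class TestHelicityByOligomerSize:
    def test_all_coil_gives_zero(self, stepwise_trajectory):
        _, top, frames, _ = stepwise_trajectory
        sub = frames[::50]
        assignments = [assign_ss_frame(top, fr) for fr in sub]
        parts = [detect_oligomers(top, fr) for fr in sub]
        hel = helicity_by_oligomer_size(assignments, parts)
        for s, v in hel.items():
            if v is not None:
                assert v == 0.0

    def test_monomer_only_leaves_larger_sizes_undefined(self, wt_system):
        top, frames, _ = wt_system
        assignments = [assign_ss_frame(top, fr) for fr in frames]
        parts = [detect_oligomers(top, fr) for fr in frames]
        hel = helicity_by_oligomer_size(assignments, parts)
        assert hel[2] is None and hel[3] is None and hel[4] is None
        assert hel[1] is not None

    def test_helix_only_in_tetramer_increases_with_size(self):
        events = [
            Event(100.0, "associate", 0, 1),
            Event(200.0, "associate", 1, 2),
            Event(300.0, "associate", 2, 3),
        ]
        for p in range(4):
            events.append(Event(300.0, "set_conformation", p, value="helix"))
        s = AssemblyScript(events=events, duration_ps=600.0, seed=0)
        top, frames, _ = generate(s)
        assignments = [assign_ss_frame(top, fr) for fr in frames]
        parts = [detect_oligomers(top, fr) for fr in frames]
        hel = helicity_by_oligomer_size(assignments, parts)
        assert hel[4] > 0
        for s_ in (1, 2, 3):
            assert hel[s_] == 0.0


class TestExponentialWaitingTimes:
    def test_mean_ot2_recovers_rate(self):
        """Scripted Exp(rate) dimerization waiting times: the empirical
        mean OT2 over 100 trajectories lies within 3 SE of 1/rate."""
        rng = np.random.default_rng(2024)
        mean_wait_ps = 2000.0
        dt = 10.0
        n = 100
        ots = []
        for _ in range(n):
            wait = rng.exponential(mean_wait_ps)
            duration = max(wait + 1000.0, 2000.0)
            script = AssemblyScript(
                events=[Event(min(wait, duration), "associate", 0, 1)],
                duration_ps=duration, save_interval_ps=dt, seed=int(rng.integers(2**31)),
            )
            top, frames, labels = generate(script)
            detected = np.array(
                [detect_oligomers(top, fr).largest_size for fr in frames]
            )
            ots.append(oligomerization_times(detected, dt))
        vals = np.array([ot.ot2_ps for ot in ots], dtype=float)
        assert not np.isnan(vals).any()
        se = vals.std(ddof=1) / np.sqrt(n)
        # discretization biases OT2 upward by at most one save interval
        assert abs(vals.mean() - mean_wait_ps) <= 3 * se + dt
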