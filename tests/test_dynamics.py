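"""Attractors, basins, phases, fates and fate transitions."""

import pytest

from vulvanet.dynamics import (
    StateSpaceTooLarge,
    basin_summary,
    find_attractors,
    g1_length,
    label_phase,
    simulate_fate_transition,
    simulate_trajectory,
    wildtype_attractor_for_inputs,
)
from vulvanet.model import NODES, build_cell_cycle_module
from vulvanet.synthetic import RandomNetworkSpec, TabularModel, generate_random_model

POS = {name: i for i, name in enumerate(NODES)}


class TestWildTypeCensus:
    def test_eight_cyclic_attractors(self, wildtype_attractors):
        assert len(wildtype_attractors) == 8
        assert all(a.period > 1 for a in wildtype_attractors)

    def test_one_attractor_per_microenvironment(self, wildtype_attractors):
        inputs = sorted(a.inputs for a in wildtype_attractors)
        assert inputs == [(l3, ls) for l3 in range(4) for ls in range(2)]

    def test_basins_partition_state_space_evenly(self, wildtype_basins):
        assert wildtype_basins.total == 73728
        assert set(wildtype_basins.sizes) == {9216}

    def test_attractor_states_cycle_under_update(self, wildtype, wildtype_attractors):
        from vulvanet.model import update_state

        for att in wildtype_attractors:
            for i, state in enumerate(att.states):
                assert update_state(wildtype, state) == att.states[(i + 1) % att.period]

    def test_canonical_rotation_starts_at_smallest_state(self, wildtype_attractors):
        for att in wildtype_attractors:
            assert att.states[0] == min(att.states)

    def test_periods_by_microenvironment(self, wildtype_attractors):
        periods = {a.inputs: a.period for a in wildtype_attractors}
        assert periods[(1, 0)] == 10  # moderate Ras: ten-step cycle
        assert periods[(3, 0)] == 9  # high Ras shortens the cycle
        assert periods[(0, 0)] == 11  # tertiary/VPC cycle


class TestCellCycleModule:
    def test_single_attractor_covering_entire_state_space(self):
        module = build_cell_cycle_module()
        atts = find_attractors(module)
        assert len(atts) == 1
        assert atts[0].period == 11
        basins = basin_summary(module, atts)
        assert basins.sizes == (256,)

    def test_phase_word_of_module_cycle(self):
        module = build_cell_cycle_module()
        (att,) = find_attractors(module)
        assert sorted(att.phase_labels) == sorted(["G1"] * 6 + ["S"] * 2 + ["G2"] + ["M"] * 2)


class TestPhasesAndFates:
    def test_phase_marker_precedence(self):
        module = build_cell_cycle_module()
        pos = {n: i for i, n in enumerate(module.node_names)}

        def state(**kw):
            s = [0] * 8
            for k, v in kw.items():
                s[pos[k]] = v
            return s

        assert label_phase(state(SCF=1, **{"CDK-2/CYE-1": 1}), pos) == "S"
        assert label_phase(state(SCF=1, **{"EFL-1": 1}), pos) == "G2"
        assert label_phase(state(**{"CKI-1": 1, "LIN-35": 1, "APC": 1}), pos) == "G1"
        assert label_phase(state(**{"CDK-1/CYB-3": 1, "CDK-2/CYE-1": 1}), pos) == "M"

    def test_phase_blocks_are_contiguous_in_every_attractor(self, wildtype_attractors):
        # starting after the M block, each wild-type cycle reads G1+ S+ G2+ M+
        for att in wildtype_attractors:
            labels = list(att.phase_labels)
            n = len(labels)
            starts = [
                i for i in range(n) if labels[i - 1] == "M" and labels[i] != "M"
            ]
            assert len(starts) == 1
            rotated = labels[starts[0] :] + labels[: starts[0]]
            collapsed = [rotated[0]]
            for lab in rotated[1:]:
                if lab != collapsed[-1]:
                    collapsed.append(lab)
            assert collapsed == ["G1", "S", "G2", "M"]

    def test_g1_durations(self, wildtype_attractors):
        assert wildtype_attractor_for_inputs(wildtype_attractors, 3, 0).g1_length == 4
        assert wildtype_attractor_for_inputs(wildtype_attractors, 1, 0).g1_length == 5
        assert wildtype_attractor_for_inputs(wildtype_attractors, 0, 0).g1_length == 6

    def test_g1_length_of_quiescent_cycle_is_undefined(self):
        from vulvanet.dynamics import Attractor

        quiescent = Attractor(
            states=((0,) * 14,), period=1, inputs=(0, 0), fate="tertiary",
            g1_length=None, phase_labels=("G1",),
        )
        assert g1_length(quiescent) is None

    def test_fate_markers(self, wildtype_attractors):
        by_inputs = {a.inputs: a for a in wildtype_attractors}
        for ls in (0, 1):
            assert by_inputs[(3, ls)].fate == "primary"
        assert by_inputs[(2, 0)].fate == "primary"
        assert by_inputs[(2, 1)].fate == "secondary"
        for ls in (0, 1):
            assert by_inputs[(1, ls)].fate == "secondary"
        assert by_inputs[(0, 1)].fate == "secondary"
        assert by_inputs[(0, 0)].fate == "tertiary"

    def test_fusion_fate_without_wnt_input(self, wildtype):
        from vulvanet.model import apply_variant

        no_wnt = apply_variant(wildtype, lin39_basal=0)
        atts = find_attractors(no_wnt)
        tert_slice = [a for a in atts if a.inputs == (0, 0)]
        assert any(a.fate == "fusion" for a in tert_slice)


class TestTrajectories:
    def test_tertiary_slice_always_reaches_the_tertiary_cycle(self, wildtype, wildtype_attractors):
        tertiary = wildtype_attractor_for_inputs(wildtype_attractors, 0, 0)
        import random

        rng = random.Random(7)
        cards = wildtype.cardinalities
        for _ in range(25):
            state = [rng.randrange(c) for c in cards]
            state[POS["LIN-3"]] = 0
            state[POS["LS"]] = 0
            traj = simulate_trajectory(wildtype, state)
            assert set(traj.states[traj.entry_index :]) == set(tertiary.states)

    def test_trajectory_from_attractor_state_has_no_transient(self, wildtype, wildtype_attractors):
        att = wildtype_attractors[0]
        traj = simulate_trajectory(wildtype, att.states[3])
        assert traj.entry_index == 0
        assert traj.period == att.period

    def test_random_starts_end_in_a_wildtype_attractor(self, wildtype, wildtype_attractors):
        import random

        rng = random.Random(11)
        cycles = {frozenset(a.states) for a in wildtype_attractors}
        for _ in range(100):
            state = [rng.randrange(c) for c in wildtype.cardinalities]
            traj = simulate_trajectory(wildtype, state)
            assert frozenset(traj.states[traj.entry_index :]) in cycles


class TestFateTransitions:
    @pytest.mark.parametrize(
        "source_inputs,new_inputs,expected_fate",
        [
            ((1, 0), (3, 1), "primary"),  # secondary cell trans-differentiates
            ((1, 0), (3, 0), "primary"),
            ((3, 0), (2, 1), "secondary"),  # primary cell trans-differentiates
            ((3, 0), (0, 0), "tertiary"),  # primary cell de-differentiates
            ((1, 1), (0, 0), "tertiary"),  # secondary cell de-differentiates
            ((0, 0), (0, 0), "tertiary"),  # tertiary fate is stable without signals
            ((0, 0), (2, 0), "primary"),
            ((0, 0), (0, 1), "secondary"),
        ],
    )
    def test_microenvironment_determines_destination_fate(
        self, wildtype, wildtype_attractors, source_inputs, new_inputs, expected_fate
    ):
        source = wildtype_attractor_for_inputs(wildtype_attractors, *source_inputs)
        result = simulate_fate_transition(wildtype, source, new_inputs)
        assert result.unique
        assert result.fate == expected_fate


class TestEngineSafety:
    def test_refuses_oversized_state_space(self):
        spec = RandomNetworkSpec(cardinalities=(2,) * 10, seed=1)
        model = generate_random_model(spec)
        with pytest.raises(StateSpaceTooLarge):
            find_attractors(model, max_states=512)

    def test_constant_network_has_single_full_basin(self):
        # every rule constant 0: one fixed point attracting the whole space
        model = TabularModel(
            cardinalities=(2, 3, 2),
            tables=((0,) * 12, (0,) * 12, (0,) * 12),
        )
        atts = find_attractors(model)
        assert len(atts) == 1
        assert atts[0].period == 1
        assert basin_summary(model, atts).sizes == (12,)
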