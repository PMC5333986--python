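"""TI/TD response rules, homeostatic regulation and event simulation."""

import math

import numpy as np
import pytest

from gqm import (
    AffinityMatrix,
    CellType,
    Clone,
    Epitope,
    Repertoire,
    ResponseEvent,
    apply_td,
    apply_ti,
    build_network,
    check_ti_sharing,
    cognate_epitope,
    extruded_nodes,
    fractional_saturation,
    node_radius,
    regulate,
    simulate,
    solve_equilibrium,
)
from gqm.dynamics import KD_FLOOR, EventKind
from gqm.errors import DomainError, FrozenCloneError, SimulationError


def edge_weights(net):
    return {tuple(sorted((a, b))): d["weight"] for a, b, d in net.edges(data=True)}


class TestTI:
    def test_fold_must_exceed_one(self, natural_fixture):
        rep, mat, _ = natural_fixture
        with pytest.raises(DomainError):
            apply_ti(rep, mat, rep.clone_ids[0], 1.0)

    def test_ti_leaves_every_kd_untouched(self, natural_fixture):
        rep, mat, _ = natural_fixture
        before = {(c, e): kd for c, e, kd in mat.items()}
        _, mat2, _ = apply_ti(rep, mat, rep.clone_ids[0], 10.0)
        assert {(c, e): kd for c, e, kd in mat2.items()} == before

    def test_ti_changes_no_internodal_distance(self, natural_fixture):
        # the node grows but does not move: edge weights are bitwise equal
        rep, mat, state = natural_fixture
        net0 = build_network(rep, mat, state)
        rep2, mat2, state2 = apply_ti(rep, mat, rep.clone_ids[3], 25.0)
        net1 = build_network(rep2, mat2, state2)
        assert edge_weights(net0) == edge_weights(net1)

    def test_ti_on_unsaturated_clone_grows_its_radius(self, natural_fixture):
        rep, mat, state = natural_fixture
        clone = rep.clone_ids[0]
        r0 = node_radius(clone, state, mat)
        _, _, state2 = apply_ti(rep, mat, clone, 10.0)
        assert node_radius(clone, state2, mat) > r0

    def test_small_fold_gives_vanishing_radius_change(self, natural_fixture):
        rep, mat, state = natural_fixture
        clone = rep.clone_ids[0]
        r0 = node_radius(clone, state, mat)
        changes = []
        for eps in (1e-2, 1e-4, 1e-6):
            _, _, st = apply_ti(rep, mat, clone, 1.0 + eps)
            changes.append(abs(node_radius(clone, st, mat) - r0) / r0)
        assert changes[0] > changes[1] > changes[2]
        assert changes[2] < 1e-5


class TestTD:
    def test_cognate_kd_falls_exactly_tenfold_per_unit_step(self, natural_fixture):
        rep, mat, _ = natural_fixture
        clone = rep.clone_ids[0]
        cog = cognate_epitope(clone, mat)
        kd0 = mat.kd(clone, cog)
        _, mat2, _ = apply_td(rep, mat, clone, delta_pkd=1.0)
        assert mat2.kd(clone, cog) == pytest.approx(kd0 / 10, rel=1e-15)

    def test_td_strictly_decreases_cognate_and_never_noncognate(
        self, natural_fixture
    ):
        rep, mat, _ = natural_fixture
        rng = np.random.default_rng(11)
        for _ in range(20):
            clone = str(rng.choice(rep.clone_ids))
            cog = cognate_epitope(clone, mat)
            row0 = mat.row(clone)
            delta = float(rng.uniform(0.2, 2.0))
            decay = float(rng.uniform(0.0, 1.0))
            _, mat2, _ = apply_td(rep, mat, clone, delta, decay)
            row1 = mat2.row(clone)
            assert row1[cog] < row0[cog]
            for e, kd in row0.items():
                if e != cog:
                    assert row1.get(e, math.inf) >= kd

    def test_zero_decay_keeps_noncognate_entries(self, natural_fixture):
        rep, mat, _ = natural_fixture
        clone = rep.clone_ids[5]
        cog = cognate_epitope(clone, mat)
        _, mat2, _ = apply_td(rep, mat, clone, 1.0, 0.0)
        for e, kd in mat.row(clone).items():
            if e != cog:
                assert mat2.kd(clone, e) == kd

    def test_maturation_respects_the_affinity_floor(self, natural_fixture):
        rep, mat, _ = natural_fixture
        clone = rep.clone_ids[0]
        cog = cognate_epitope(clone, mat)
        _, mat2, _ = apply_td(rep, mat, clone, delta_pkd=20.0)
        assert mat2.kd(clone, cog) == KD_FLOOR

    def test_long_lived_clone_is_frozen(self):
        rep = Repertoire(
            clones={
                "llpc": Clone(
                    id="llpc",
                    ab_total=1e-9,
                    cell_type=CellType.LONG_LIVED_PLASMA,
                    long_lived=True,
                )
            },
            epitopes={"e": Epitope(id="e", ag_total=1e-7)},
        )
        mat = AffinityMatrix({("llpc", "e"): 1e-8})
        with pytest.raises(FrozenCloneError):
            apply_td(rep, mat, "llpc", 1.0)
        with pytest.raises(FrozenCloneError):
            regulate(rep, mat, "llpc")
        # TI boosting is still allowed for long-lived plasma cells
        rep2, _, _ = apply_ti(rep, mat, "llpc", 2.0)
        assert rep2.clones["llpc"].ab_total == 2e-9

    def test_repeated_maturation_extrudes_the_clone(self, natural_fixture):
        rep, mat, state = natural_fixture
        clone = rep.clone_ids[0]
        for _ in range(6):
            rep, mat, state = apply_td(rep, mat, clone, 1.0, 0.5)
        net = build_network(rep, mat, state)
        assert clone in extruded_nodes(net)


class TestRegulation:
    def test_already_at_target_returns_unchanged_state(self):
        # a lone clone against a trace epitope: ab_free ~ ab_total = kd
        rep = Repertoire(
            clones={"c": Clone(id="c", ab_total=1e-7)},
            epitopes={"e": Epitope(id="e", ag_total=1e-14)},
        )
        mat = AffinityMatrix({("c", "e"): 1e-7})
        rep2, _, _, res = regulate(rep, mat, "c", tolerance=0.01)
        assert rep2.clones["c"].ab_total == 1e-7
        assert abs(res) < 0.01

    def test_controller_reaches_half_saturation_set_point(self, natural_fixture):
        rep, mat, _ = natural_fixture
        for clone in rep.clone_ids[:5]:
            rep2, _, state, res = regulate(rep, mat, clone, tolerance=0.01)
            assert abs(res) < 0.01
            cog = cognate_epitope(clone, mat)
            occ = fractional_saturation(state.ab_free_of(clone), mat.kd(clone, cog))
            assert occ == pytest.approx(0.5, abs=0.01)

    def test_reregulation_after_antigen_doubling(self, natural_fixture):
        rep, mat, _ = natural_fixture
        clone = rep.clone_ids[7]
        rep1, _, _, _ = regulate(rep, mat, clone, tolerance=0.005)
        cog = cognate_epitope(clone, mat)
        doubled = Epitope(
            id=cog, ag_total=rep1.epitopes[cog].ag_total * 2,
            is_self=rep1.epitopes[cog].is_self,
        )
        rep2 = rep1.with_epitope(doubled)
        rep3, _, state, res = regulate(rep2, mat, clone, tolerance=0.005)
        assert abs(res) < 0.005
        assert abs(math.log10(state.ab_free_of(clone) / mat.kd(clone, cog))) < 0.005


class TestTISharing:
    def test_natural_repertoire_has_no_violations(self, natural_fixture):
        rep, mat, state = natural_fixture
        net = build_network(rep, mat, state)
        assert check_ti_sharing(net) == []

    def test_monoclonal_b1_dominance_is_flagged(self):
        # a B1 clone pushed to radius > 1 violates shared TI production
        rep = Repertoire(
            clones={"b1": Clone(id="b1", ab_total=1e-5, cell_type=CellType.B1)},
            epitopes={"e": Epitope(id="e", ag_total=1e-9)},
        )
        mat = AffinityMatrix({("b1", "e"): 1e-6})
        state = solve_equilibrium(rep, mat)
        net = build_network(rep, mat, state)
        assert net.nodes["b1"]["radius"] > 1
        assert check_ti_sharing(net) == ["b1"]

    def test_td_clone_may_exceed_one_without_flag(self):
        # oligoclonal/monoclonal TD responses may have [Ab]/K_D > 1
        rep = Repertoire(
            clones={"asc": Clone(id="asc", ab_total=1e-5, cell_type=CellType.ASC)},
            epitopes={"e": Epitope(id="e", ag_total=1e-9)},
        )
        mat = AffinityMatrix({("asc", "e"): 1e-8})
        state = solve_equilibrium(rep, mat)
        net = build_network(rep, mat, state)
        assert net.nodes["asc"]["radius"] > 1
        assert check_ti_sharing(net) == []


class TestSimulate:
    def test_empty_event_list_gives_single_initial_snapshot(self, natural_fixture):
        rep, mat, state = natural_fixture
        traj = simulate(rep, mat, [])
        assert len(traj) == 1
        np.testing.assert_array_equal(traj[0].state.ab_free, state.ab_free)

    def test_ti_events_compose_multiplicatively(self, natural_fixture):
        rep, mat, _ = natural_fixture
        clone = rep.clone_ids[2]
        two = simulate(
            rep,
            mat,
            [
                ResponseEvent(kind="TI", clone_id=clone, fold=3.0),
                ResponseEvent(kind="TI", clone_id=clone, fold=5.0),
            ],
        )
        one = simulate(rep, mat, [ResponseEvent(kind="TI", clone_id=clone, fold=15.0)])
        np.testing.assert_allclose(
            two.final.state.ab_free, one.final.state.ab_free, rtol=1e-9
        )

    def test_td_sequence_reproduces_extrusion_motif(self, natural_fixture):
        rep, mat, _ = natural_fixture
        clone = rep.clone_ids[0]
        events = [
            ResponseEvent(kind="TD", clone_id=clone, delta_pkd=1.0,
                          polyreactivity_decay=0.5)
        ] * 6
        traj = simulate(rep, mat, events)
        assert clone not in extruded_nodes(traj[0].network)
        assert clone in extruded_nodes(traj.final.network)

    def test_antigen_challenge_adds_epitope_and_reshapes_cognate(
        self, natural_fixture
    ):
        rep, mat, _ = natural_fixture
        clone = rep.clone_ids[0]
        strong = mat.kd(clone, cognate_epitope(clone, mat)) / 100
        traj = simulate(
            rep,
            mat,
            [
                ResponseEvent(
                    kind="ANTIGEN_CHALLENGE",
                    epitope_id="e_invader",
                    ag_total=1e-7,
                    affinities={clone: strong},
                )
            ],
        )
        assert cognate_epitope(clone, traj.final.matrix) == "e_invader"
        assert not traj.final.repertoire.epitopes["e_invader"].is_self

    def test_event_failures_carry_the_event_index(self, natural_fixture):
        rep, mat, _ = natural_fixture
        events = [
            ResponseEvent(kind="TI", clone_id=rep.clone_ids[0], fold=2.0),
            ResponseEvent(kind="TI", clone_id="missing", fold=2.0),
        ]
        with pytest.raises(SimulationError) as err:
            simulate(rep, mat, events)
        assert err.value.event_index == 1

    def test_event_parameter_validation(self):
        with pytest.raises(DomainError):
            ResponseEvent(kind="TI", clone_id="c", fold=0.5)
        with pytest.raises(DomainError):
            ResponseEvent(kind="TD", clone_id="c", delta_pkd=-1.0)
        with pytest.raises(DomainError):
            ResponseEvent(kind="ANTIGEN_CHALLENGE", epitope_id="e")
        assert ResponseEvent(kind="TI", clone_id="c", fold=2.0).kind is EventKind.TI
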