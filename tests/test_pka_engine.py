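import math

import numpy as np
import pytest

from macropka import (
    MicroEdge,
    build_dg0_network,
    charge_populations,
    cycle_closure_report,
    macroscopic_pka_closed_form,
    macroscopic_pkas_closed_form,
    macroscopic_pkas_titration,
    ph_dependent_dg,
    state_populations,
)
from macropka.microstates import MicrostateNetwork
from macropka.pka import CycleInconsistencyError, UnreachableStateError

from conftest import make_state, random_network


class TestBuildDg0Network:
    def test_single_deprotonation_gives_plus_c_units_times_pka(self, ctx):
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, -1)]
        net = build_dg0_network(
            states, "SM01_micro000",
            [MicroEdge("deprotonation_pka", "SM01_micro000", "SM01_micro001", 5.0)],
            ctx=ctx,
        )
        assert net.dg0["SM01_micro001"] == pytest.approx(ctx.c_units * 5.0, abs=1e-12)
        assert net.dg0["SM01_micro001"] == pytest.approx(6.8217, abs=1e-3)

    def test_protonation_gives_minus_c_units_times_pka(self, ctx):
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, +1)]
        net = build_dg0_network(
            states, "SM01_micro000",
            [MicroEdge("protonation_pka", "SM01_micro000", "SM01_micro001", 9.0)],
            ctx=ctx,
        )
        assert net.dg0["SM01_micro001"] == pytest.approx(-ctx.c_units * 9.0, abs=1e-12)
        assert net.dg0["SM01_micro001"] == pytest.approx(-12.278, abs=1e-2)

    def test_tautomer_edge_is_scaled_by_slope(self, ctx):
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, 0)]
        net = build_dg0_network(
            states, "SM01_micro000",
            [MicroEdge("tautomer_dg", "SM01_micro000", "SM01_micro001", 1.00)],
            slope_m=0.9, ctx=ctx,
        )
        assert net.dg0["SM01_micro001"] == pytest.approx(0.90, abs=1e-12)

    def test_chained_deprotonations_sum_single_steps(self, ctx):
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, -1),
                  make_state("SM01", 2, -2)]
        net = build_dg0_network(
            states, "SM01_micro000",
            [MicroEdge("deprotonation_pka", "SM01_micro000", "SM01_micro001", 4.0),
             MicroEdge("deprotonation_pka", "SM01_micro001", "SM01_micro002", 10.0)],
            ctx=ctx,
        )
        assert net.dg0["SM01_micro002"] == pytest.approx(ctx.c_units * 14.0, abs=1e-10)

    def test_disconnected_state_raises(self, ctx):
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, -1)]
        with pytest.raises(UnreachableStateError, match="SM01_micro001"):
            build_dg0_network(states, "SM01_micro000", [], ctx=ctx)

    def test_inconsistent_paths_raise_with_gap(self, ctx):
        # two parallel deprotonation edges disagreeing by 0.5 pKa units
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, -1)]
        edges = [
            MicroEdge("deprotonation_pka", "SM01_micro000", "SM01_micro001", 5.0),
            MicroEdge("deprotonation_pka", "SM01_micro000", "SM01_micro001", 5.5),
        ]
        with pytest.raises(CycleInconsistencyError) as err:
            build_dg0_network(states, "SM01_micro000", edges, ctx=ctx)
        assert err.value.worst_gap == pytest.approx(0.5 * ctx.c_units, abs=1e-9)

    def test_edge_charge_mismatch_rejected(self, ctx):
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, 0)]
        with pytest.raises(ValueError, match="charge change"):
            build_dg0_network(
                states, "SM01_micro000",
                [MicroEdge("deprotonation_pka", "SM01_micro000", "SM01_micro001", 5.0)],
                ctx=ctx,
            )

    @pytest.mark.parametrize("kind,charge,pka", [
        ("deprotonation_pka", -1, 3.7), ("protonation_pka", +1, 8.1),
    ])
    def test_round_trip_recovers_input_pka(self, ctx, kind, charge, pka):
        """A single micro-pKa edge inverts through the closed form exactly."""
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, charge)]
        net = build_dg0_network(
            states, "SM01_micro000",
            [MicroEdge(kind, "SM01_micro000", "SM01_micro001", pka)], ctx=ctx,
        )
        q_high = max(charge, 0)
        assert macroscopic_pka_closed_form(net, q_high, ctx) == pytest.approx(
            pka, abs=1e-9
        )


class TestPhDependentDg:
    def test_tautomer_target_is_ph_independent(self, ctx):
        net = MicrostateNetwork.from_states(
            "SM01", "SM01_micro000",
            [make_state("SM01", 0, 0), make_state("SM01", 1, 0)],
            {"SM01_micro001": 1.7},
        )
        for ph in (-2.0, 0.0, 7.4, 14.0):
            assert ph_dependent_dg(net, "SM01_micro001", ph, ctx) == 1.7

    def test_vanishes_at_the_micro_pka(self, ctx, acid_network):
        assert ph_dependent_dg(acid_network, "SM01_micro001", 5.0, ctx) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_ph_units_past_pka(self, ctx, acid_network):
        dg = ph_dependent_dg(acid_network, "SM01_micro001", 7.0, ctx)
        assert dg == pytest.approx(-2.0 * ctx.c_units, abs=1e-12)
        assert dg == pytest.approx(-2.7287, abs=1e-3)

    def test_missing_dg0_raises(self, ctx, acid_network):
        with pytest.raises(KeyError):
            ph_dependent_dg(acid_network, "SM01_micro777", 7.0, ctx)


class TestPopulations:
    def test_reference_only_network(self, ctx):
        net = MicrostateNetwork.from_states(
            "SM01", "SM01_micro000", [make_state("SM01", 0, 0)], {}
        )
        assert state_populations(net, 7.0, ctx) == {"SM01_micro000": 1.0}
        assert charge_populations(net, 7.0, ctx) == {0: 1.0}

    def test_isoenergetic_tautomers_split_evenly(self, ctx):
        net = MicrostateNetwork.from_states(
            "SM01", "SM01_micro000",
            [make_state("SM01", 0, 0), make_state("SM01", 1, 0)],
            {"SM01_micro001": 0.0},
        )
        for ph in (0.0, 5.0, 12.0):
            fr = state_populations(net, ph, ctx)
            assert fr["SM01_micro000"] == pytest.approx(0.5, abs=1e-12)
            assert fr["SM01_micro001"] == pytest.approx(0.5, abs=1e-12)

    def test_acid_anion_half_half_at_micro_pka(self, ctx, acid_network):
        fr = state_populations(acid_network, 5.0, ctx)
        assert fr["SM01_micro000"] == pytest.approx(0.5, abs=1e-9)
        assert fr["SM01_micro001"] == pytest.approx(0.5, abs=1e-9)

    def test_charge_groups_sum_state_fractions(self, ctx):
        rng = np.random.default_rng(7)
        net = random_network(rng)
        states = state_populations(net, 6.3, ctx)
        charges = charge_populations(net, 6.3, ctx)
        for q, frac in charges.items():
            manual = sum(x for sid, x in states.items() if net.charge_of(sid) == q)
            assert frac == pytest.approx(manual, abs=1e-12)

    @pytest.mark.parametrize("scale", [1.0, 400.0])
    def test_normalization_is_overflow_safe(self, ctx, scale):
        net = MicrostateNetwork.from_states(
            "SM01", "SM01_micro000",
            [make_state("SM01", 0, 0), make_state("SM01", 1, -1),
             make_state("SM01", 2, -2)],
            {"SM01_micro001": scale, "SM01_micro002": -scale},
        )
        for ph in (-12.0, 0.0, 20.0):
            fr = state_populations(net, ph, ctx)
            assert abs(sum(fr.values()) - 1.0) < 1e-9
            assert all(np.isfinite(list(fr.values())))

    def test_amphoteric_isoelectric_symmetry(self, ctx, amphoteric_network):
        # cation and anion populations balance midway between the two pKas
        fr = charge_populations(amphoteric_network, (4.0 + 9.0) / 2.0, ctx)
        assert fr[+1] == pytest.approx(fr[-1], rel=1e-9)

    def test_gauge_invariance_of_reference_offset(self, ctx):
        # adding one constant to every state's energy (reference included,
        # carried as an explicitly stored value) changes nothing observable
        net = random_network(np.random.default_rng(11))
        shifted = MicrostateNetwork.from_states(
            net.molecule_id, net.reference_id, net.states.values(),
            {sid: net.dg0.get(sid, 0.0) + 7.3 for sid in net.states},
        )
        for ph in (0.0, 6.2, 11.0):
            a = state_populations(net, ph, ctx)
            b = state_populations(shifted, ph, ctx)
            for sid in a:
                assert b[sid] == pytest.approx(a[sid], abs=1e-12)
        pkas0 = [p for _, _, p in macroscopic_pkas_closed_form(net, ctx)]
        pkas1 = [p for _, _, p in macroscopic_pkas_closed_form(shifted, ctx)]
        assert pkas1 == pytest.approx(pkas0, abs=1e-9)
        crossings0 = macroscopic_pkas_titration(net, ctx).pkas
        crossings1 = macroscopic_pkas_titration(shifted, ctx).pkas
        assert crossings1 == pytest.approx(crossings0, abs=1e-7)


class TestTitration:
    def test_single_deprotonation_crosses_at_its_pka(self, ctx, acid_network):
        res = macroscopic_pkas_titration(acid_network, ctx)
        assert len(res.crossings) == 1
        qh, ql, pka = res.crossings[0]
        assert (qh, ql) == (0, -1)
        assert pka == pytest.approx(5.0, abs=1e-6)

    def test_two_acid_tautomers_shift_by_log10_two(self, ctx):
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, 0),
                  make_state("SM01", 2, -1)]
        net = build_dg0_network(
            states, "SM01_micro000",
            [MicroEdge("tautomer_dg", "SM01_micro000", "SM01_micro001", 0.0),
             MicroEdge("deprotonation_pka", "SM01_micro000", "SM01_micro002", 5.0)],
            ctx=ctx,
        )
        res = macroscopic_pkas_titration(net, ctx)
        assert res.pkas == pytest.approx([5.0 + math.log10(2.0)], abs=1e-6)

    def test_tautomer_only_network_has_no_crossings(self, ctx):
        net = MicrostateNetwork.from_states(
            "SM01", "SM01_micro000",
            [make_state("SM01", 0, 0), make_state("SM01", 1, 0)],
            {"SM01_micro001": 0.8},
        )
        assert macroscopic_pkas_titration(net, ctx).crossings == []

    def test_amphoteric_network_yields_both_pkas(self, ctx, amphoteric_network):
        res = macroscopic_pkas_titration(amphoteric_network, ctx)
        assert [(c[0], c[1]) for c in res.crossings] == [(1, 0), (0, -1)]
        assert res.pkas == pytest.approx([4.0, 9.0], abs=1e-6)

    def test_charge_fractions_sum_to_one_on_grid(self, ctx, amphoteric_network):
        res = macroscopic_pkas_titration(amphoteric_network, ctx)
        total = sum(res.charge_fractions.values())
        assert np.max(np.abs(total - 1.0)) < 1e-9

    def test_most_protonated_fraction_is_monotone_nonincreasing(self, ctx):
        for seed in range(5):
            net = random_network(np.random.default_rng(seed))
            res = macroscopic_pkas_titration(net, ctx)
            top = res.charge_fractions[max(res.charge_fractions)]
            assert np.all(np.diff(top) <= 1e-12)

    def test_non_finite_dg0_is_an_input_error(self, ctx):
        net = MicrostateNetwork.from_states(
            "SM01", "SM01_micro000",
            [make_state("SM01", 0, 0), make_state("SM01", 1, -1)],
            {"SM01_micro001": math.inf},
        )
        with pytest.raises(ValueError, match="non-finite"):
            macroscopic_pkas_titration(net, ctx)

    def test_window_edge_crossing_warns(self, ctx):
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, -1)]
        net = build_dg0_network(
            states, "SM01_micro000",
            [MicroEdge("deprotonation_pka", "SM01_micro000", "SM01_micro001", 19.999)],
            ctx=ctx,
        )
        with pytest.warns(UserWarning, match="edge of the search window"):
            macroscopic_pkas_titration(net, ctx)


class TestClosedForm:
    def test_single_acid_reduces_to_micro_pka_exactly(self, ctx, acid_network):
        assert macroscopic_pka_closed_form(acid_network, 0, ctx) == pytest.approx(
            5.0, abs=1e-9
        )

    def test_two_isoenergetic_tautomers_give_pka_plus_log10_two(self, ctx):
        # independent oracle: Ka_ST = (1/Ka1 + 1/Ka2)^-1 with Ka1 = Ka2 = 1e-5
        ka_st = 1.0 / (1e5 + 1e5)
        net = MicrostateNetwork.from_states(
            "SM01", "SM01_micro000",
            [make_state("SM01", 0, 0), make_state("SM01", 1, 0),
             make_state("SM01", 2, -1)],
            {"SM01_micro001": 0.0, "SM01_micro002": ctx.c_units * 5.0},
        )
        assert macroscopic_pka_closed_form(net, 0, ctx) == pytest.approx(
            -math.log10(ka_st), abs=1e-9
        )

    def test_duplicating_both_groups_leaves_ratio_unchanged(self, ctx):
        base = {"SM01_micro001": 2.0, "SM01_micro002": ctx.c_units * 6.0}
        states = [make_state("SM01", 0, 0), make_state("SM01", 1, 0),
                  make_state("SM01", 2, -1)]
        net = MicrostateNetwork.from_states("SM01", "SM01_micro000", states, base)
        doubled_states = states + [make_state("SM01", 3, 0), make_state("SM01", 4, 0),
                                   make_state("SM01", 5, -1)]
        doubled = MicrostateNetwork.from_states(
            "SM01", "SM01_micro000", doubled_states,
            {**base, "SM01_micro003": 0.0, "SM01_micro004": 2.0,
             "SM01_micro005": ctx.c_units * 6.0},
        )
        # every tautomer of both groups duplicated with identical energies
        assert macroscopic_pka_closed_form(doubled, 0, ctx) == pytest.approx(
            macroscopic_pka_closed_form(net, 0, ctx), abs=1e-12
        )

    def test_missing_charge_group_raises(self, ctx, acid_network):
        with pytest.raises(ValueError, match="missing charge group"):
            macroscopic_pka_closed_form(acid_network, 2, ctx)


def test_titration_agrees_with_closed_form_on_random_networks(ctx):
    """Numerical titration and the partition-function log-ratio are the same
    quantity; spot-check on 40 random networks (the full 200-network suite
    runs in the acceptance tests)."""
    window = (-12.0, 20.0)
    for seed in range(40):
        net = random_network(np.random.default_rng(1000 + seed))
        titrated = macroscopic_pkas_titration(net, ctx, window=window)
        closed = [
            c for c in macroscopic_pkas_closed_form(net, ctx)
            if window[0] < c[2] < window[1]
        ]
        assert len(titrated.crossings) == len(closed)
        for (qh, ql, pka), (qh2, ql2, pka2) in zip(titrated.crossings, closed):
            assert (qh, ql) == (qh2, ql2)
            assert abs(pka - pka2) < 1e-6


class TestCycleClosure:
    def triangle(self, ctx, perturb=0.0):
        # ref --dG 1.0--> tautomer B; both deprotonate to the same anion.
        # Closure requires pKa(B) = pKa(ref) - 1.0/C_units.
        pka_a = 5.0
        pka_b = 5.0 - 1.0 / ctx.c_units + perturb
        return [
            MicroEdge("tautomer_dg", "SM01_micro000", "SM01_micro001", 1.0),
            MicroEdge("deprotonation_pka", "SM01_micro000", "SM01_micro002", pka_a),
            MicroEdge("deprotonation_pka", "SM01_micro001", "SM01_micro002", pka_b),
        ]

    def test_tree_has_zero_gap(self, ctx):
        edges = [
            MicroEdge("deprotonation_pka", "SM01_micro000", "SM01_micro001", 4.0),
            MicroEdge("tautomer_dg", "SM01_micro000", "SM01_micro002", 0.7),
        ]
        assert cycle_closure_report(edges, ctx=ctx) == 0.0

    def test_consistent_triangle_closes(self, ctx):
        assert cycle_closure_report(self.triangle(ctx), ctx=ctx) <= 1e-9

    def test_perturbed_triangle_opens_half_pka_gap(self, ctx):
        gap = cycle_closure_report(self.triangle(ctx, perturb=0.5), ctx=ctx)
        assert gap == pytest.approx(0.5 * ctx.c_units, abs=1e-9)
        assert gap == pytest.approx(0.682, abs=1e-3)
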