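import pytest

from macropka import MicroEdge, Microstate, ThermoContext, build_dg0_network


@pytest.fixture(scope="session")
def ctx():
    return ThermoContext()


def make_state(mol, idx, charge):
    return Microstate(mol, f"{mol}_micro{idx:03d}", "C", charge)


@pytest.fixture
def acid_network(ctx):
    """Monoprotic acid with micro pKa 5: neutral reference plus one anion."""
    ha = make_state("SM01", 0, 0)
    a = make_state("SM01", 1, -1)
    return build_dg0_network(
        [ha, a],
        ha.microstate_id,
        [MicroEdge("deprotonation_pka", ha.microstate_id, a.microstate_id, 5.0)],
        ctx=ctx,
    )


def random_network(rng, molecule_id="SM99"):
    """Random multi-charge, multi-tautomer network with dG0 uniform in ±15."""
    from macropka import MicrostateNetwork

    q_lo = int(rng.integers(-2, 1))
    q_hi = int(rng.integers(0, 3))
    while q_hi - q_lo + 1 > 4:  # at most 4 charge groups
        q_hi -= 1
    states, dg0 = [], {}
    idx = 0
    reference_id = None
    for q in range(q_lo, q_hi + 1):
        for _ in range(int(rng.integers(1, 5))):
            sid = f"{molecule_id}_micro{idx:03d}"
            states.append(Microstate(molecule_id, sid, "C", q))
            if q == 0 and reference_id is None:
                reference_id = sid
            else:
                dg0[sid] = float(rng.uniform(-15.0, 15.0))
            idx += 1
    return MicrostateNetwork.from_states(molecule_id, reference_id, states, dg0)


@pytest.fixture
def amphoteric_network(ctx):
    """Cation (conjugate-acid pKa 4), neutral reference, anion (pKa 9)."""
    ref = make_state("SM02", 0, 0)
    cation = make_state("SM02", 1, +1)
    anion = make_state("SM02", 2, -1)
    return build_dg0_network(
        [ref, cation, anion],
        ref.microstate_id,
        [
            MicroEdge("protonation_pka", ref.microstate_id, cation.microstate_id, 4.0),
            MicroEdge("deprotonation_pka", ref.microstate_id, anion.microstate_id, 9.0),
        ],
        ctx=ctx,
    )
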