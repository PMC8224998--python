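"""Macroscopic pKa from microstate free energies.

The pH-dependent free energy of microstate ``j`` relative to the neutral
reference ``k`` is

    dG_jk(pH) = dG0_jk + delta_m_jk * C_units * pH,          C_units = RT ln10

so Boltzmann weighting over all microstates gives the fraction of each
microstate at any pH.  Summing fractions over each formal charge and locating
the pH where two adjacent charge groups are equally populated is a formal
titration: that crossing pH is the macroscopic pKa.  The same quantity has a
closed form, log10(Z_q / Z_{q-1}) with Z_q the pH-0 partition function of
charge group q, because the shared normalization cancels at the crossing;
both routes are implemented and agree to numerical precision.

dG0 networks can be assembled from microscopic inputs (micro-pKa edges and
tautomer free-energy edges) via :func:`build_dg0_network`:

* tautomer edge (same charge):      dG0 contribution = m * dG (slope factor m),
* deprotonation edge (q -> q-1):    +C_units * pKa,
* protonation edge  (q -> q+1):     -C_units * pKa,

chained over any path from the reference; multi-proton transitions are the
sum of their single-proton steps.  Redundant paths must agree (thermodynamic
cycle closure); a disagreement beyond tolerance raises
:class:`CycleInconsistencyError`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .microstates import Microstate, MicrostateNetwork, ThermoContext

__all__ = [
    "MicroEdge",
    "TitrationResult",
    "UnreachableStateError",
    "CycleInconsistencyError",
    "build_dg0_network",
    "network_from_predictions",
    "ph_dependent_dg",
    "state_populations",
    "charge_populations",
    "macroscopic_pkas_titration",
    "macroscopic_pka_closed_form",
    "macroscopic_pkas_closed_form",
    "cycle_closure_report",
]

EDGE_KINDS = ("deprotonation_pka", "protonation_pka", "tautomer_dg")


class UnreachableStateError(ValueError):
    """A microstate cannot be reached from the reference through any edge path."""


class CycleInconsistencyError(ValueError):
    """Redundant edge paths disagree beyond tolerance (open thermodynamic cycle)."""

    def __init__(self, message: str, worst_gap: float):
        super().__init__(message)
        self.worst_gap = worst_gap


@dataclass(frozen=True)
class MicroEdge:
    """One microscopic input: a micro-pKa or a tautomerization free energy.

    ``value`` is a pKa (dimensionless) for the two pKa kinds and a free energy
    in kcal/mol (from_id -> to_id direction) for ``tautomer_dg``.

    For ``deprotonation_pka`` the edge points from the acid to its conjugate
    base (charge drops by one); for ``protonation_pka`` it points from the
    base to the conjugate acid (charge rises by one) and ``value`` is the pKa
    of that conjugate acid.
    """

    kind: str
    from_id: str
    to_id: str
    value: float

    def __post_init__(self):
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}; expected one of {EDGE_KINDS}")
        if self.from_id == self.to_id:
            raise ValueError(f"self-edge on {self.from_id!r}")


@dataclass
class TitrationResult:
    """Charge-population curves over a pH grid and the crossings found.

    ``crossings`` holds ``(q_high, q_low, pka)`` triples with
    ``q_high = q_low + 1``, sorted by pKa.
    """

    molecule_id: str
    ph_grid: np.ndarray
    charge_fractions: dict[int, np.ndarray]
    crossings: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def pkas(self) -> list[float]:
        return [c[2] for c in self.crossings]


def _edge_dg(edge: MicroEdge, slope_m: float, ctx: ThermoContext) -> float:
    """Free-energy contribution of traversing ``edge`` in its from->to direction."""
    if edge.kind == "tautomer_dg":
        return slope_m * edge.value
    if edge.kind == "deprotonation_pka":
        return ctx.c_units * edge.value
    return -ctx.c_units * edge.value  # protonation_pka


def _check_edge_charges(edge: MicroEdge, states: Mapping[str, Microstate]) -> None:
    for sid in (edge.from_id, edge.to_id):
        if sid not in states:
            raise KeyError(f"edge endpoint {sid!r} is not a known microstate")
    dq = states[edge.to_id].formal_charge - states[edge.from_id].formal_charge
    expected = {"deprotonation_pka": -1, "protonation_pka": +1, "tautomer_dg": 0}[edge.kind]
    if dq != expected:
        raise ValueError(
            f"{edge.kind} edge {edge.from_id}->{edge.to_id} has charge change "
            f"{dq:+d}, expected {expected:+d}"
        )


def build_dg0_network(
    states: Iterable[Microstate],
    reference: str,
    edges: Sequence[MicroEdge],
    slope_m: float = 1.0,
    ctx: ThermoContext = ThermoContext(),
    cycle_tol: float = 1e-6,
) -> MicrostateNetwork:
    """Assemble a dG0 network from microscopic pKa / tautomer-free-energy edges.

    Every state must be connected to the neutral reference through at least
    one edge path.  Edge contributions are summed along a spanning tree from
    the reference; every remaining edge is then checked for consistency, and
    a disagreement larger than ``cycle_tol`` (kcal/mol) raises
    :class:`CycleInconsistencyError` carrying the worst gap.

    The slope factor ``slope_m`` scales tautomer free-energy edges only
    (micro-pKa inputs from regression-corrected methods already carry it).
    """
    state_map = {s.microstate_id: s for s in states}
    if reference not in state_map:
        raise KeyError(f"reference {reference!r} not among states")
    if state_map[reference].formal_charge != 0:
        raise ValueError(f"reference {reference!r} must be neutral")
    for e in edges:
        _check_edge_charges(e, state_map)

    adjacency: dict[str, list[tuple[str, float]]] = {sid: [] for sid in state_map}
    for e in edges:
        dg = _edge_dg(e, slope_m, ctx)
        adjacency[e.from_id].append((e.to_id, dg))
        adjacency[e.to_id].append((e.from_id, -dg))

    dg0: dict[str, float] = {reference: 0.0}
    stack = [reference]
    while stack:
        here = stack.pop()
        for other, dg in adjacency[here]:
            if other not in dg0:
                dg0[other] = dg0[here] + dg
                stack.append(other)

    unreachable = sorted(set(state_map) - set(dg0))
    if unreachable:
        raise UnreachableStateError(
            f"microstates not connected to reference {reference!r}: {unreachable}"
        )

    worst = 0.0
    for e in edges:
        gap = abs(dg0[e.to_id] - dg0[e.from_id] - _edge_dg(e, slope_m, ctx))
        worst = max(worst, gap)
    if worst > cycle_tol:
        raise CycleInconsistencyError(
            f"redundant paths disagree by up to {worst:.6g} kcal/mol "
            f"(tolerance {cycle_tol:g})",
            worst_gap=worst,
        )

    molecule_id = state_map[reference].molecule_id
    return MicrostateNetwork(
        molecule_id=molecule_id,
        reference_id=reference,
        states=state_map,
        dg0=dg0,
    )


def network_from_predictions(
    molecule_id: str,
    reference_id: str,
    predictions: Iterable,
    states: Mapping[str, Microstate] | None = None,
) -> MicrostateNetwork:
    """Build a network directly from submitted reference->target dG0 values.

    ``predictions`` is any iterable of objects with ``target_id``, ``dg0`` and
    ``target_charge`` attributes (``TransitionPrediction``).  When a microstate
    table is supplied via ``states`` it provides charges and SMILES; states in
    the table without a prediction are marked unpredicted.
    """
    preds = list(predictions)
    if states is not None:
        state_map = dict(states)
        if reference_id not in state_map:
            raise KeyError(f"reference {reference_id!r} not in microstate table")
    else:
        state_map = {
            reference_id: Microstate(molecule_id, reference_id, "", 0)
        }
    dg0: dict[str, float] = {}
    for p in preds:
        if p.target_id == reference_id:
            raise ValueError(f"self-transition to reference {reference_id!r}")
        if p.target_id in dg0:
            raise ValueError(f"duplicate prediction for {p.target_id!r}")
        if p.target_id not in state_map:
            state_map[p.target_id] = Microstate(
                molecule_id, p.target_id, "", p.target_charge
            )
        dg0[p.target_id] = p.dg0
    unpredicted = {
        sid for sid in state_map if sid != reference_id and sid not in dg0
    }
    return MicrostateNetwork(
        molecule_id=molecule_id,
        reference_id=reference_id,
        states=state_map,
        dg0=dg0,
        unpredicted=unpredicted,
    )


def ph_dependent_dg(
    network: MicrostateNetwork,
    target: str,
    ph: float,
    ctx: ThermoContext = ThermoContext(),
) -> float:
    """dG_jk(pH) = dG0_jk + delta_m * C_units * pH, in kcal/mol."""
    return network.dg0_of(target) + network.delta_m(target) * ctx.c_units * ph


def _population_arrays(
    network: MicrostateNetwork,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """ids, dG0 and charge arrays of the collapsed, predicted states."""
    net = network.collapse_equivalences()
    ids = net.predicted_ids()
    g0 = np.array([net.dg0_of(i) for i in ids], dtype=float)
    if not np.all(np.isfinite(g0)):
        raise ValueError(f"{network.molecule_id}: non-finite dG0 values")
    q = np.array([net.charge_of(i) for i in ids], dtype=float)
    return ids, g0, q


def state_populations(
    network: MicrostateNetwork,
    ph: float,
    ctx: ThermoContext = ThermoContext(),
) -> dict[str, float]:
    """Boltzmann fraction of every (collapsed) microstate at a given pH.

    Overflow-safe for arbitrarily large |dG0/RT| via max-shift normalization.
    """
    ids, g0, q = _population_arrays(network)
    logw = -(g0 + q * ctx.c_units * ph) / ctx.rt
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return dict(zip(ids, w))


def charge_populations(
    network: MicrostateNetwork,
    ph: float,
    ctx: ThermoContext = ThermoContext(),
) -> dict[int, float]:
    """Total population fraction of each formal-charge group at a given pH."""
    net = network.collapse_equivalences()
    fractions = state_populations(net, ph, ctx)
    out: dict[int, float] = {}
    for sid, x in fractions.items():
        out[net.charge_of(sid)] = out.get(net.charge_of(sid), 0.0) + x
    return out


def _charge_fraction_matrix(
    g0: np.ndarray, q: np.ndarray, ph: np.ndarray, ctx: ThermoContext
) -> dict[int, np.ndarray]:
    """Fraction of each charge group at every pH of a grid (vectorized)."""
    logw = -(g0[:, None] + q[:, None] * ctx.c_units * ph[None, :]) / ctx.rt
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=0, keepdims=True)
    out: dict[int, np.ndarray] = {}
    for charge in np.unique(q):
        out[int(charge)] = w[q == charge].sum(axis=0)
    return out


def macroscopic_pkas_titration(
    network: MicrostateNetwork,
    ctx: ThermoContext = ThermoContext(),
    window: tuple[float, float] = (-12.0, 20.0),
    scan_step: float = 0.01,
    tol: float = 1e-8,
) -> TitrationResult:
    """Macroscopic pKas by numerical titration of charge-group populations.

    For every adjacent charge pair (q, q-1) present, the difference of the two
    charge-group fractions is scanned over the pH window on a regular grid;
    each sign change is refined by bisection to ``tol`` pH units.  A pair with
    no sign change in the window simply yields no crossing.  Crossings within
    one grid step of a window edge trigger a warning.
    """
    _, g0, q = _population_arrays(network)
    lo, hi = window
    grid = np.arange(lo, hi + scan_step / 2, scan_step)
    curves = _charge_fraction_matrix(g0, q, grid, ctx)

    def diff_at(ph: float, qh: int) -> float:
        c = _charge_fraction_matrix(g0, q, np.array([ph]), ctx)
        return float(c[qh][0] - c[qh - 1][0])

    crossings: list[tuple[int, int, float]] = []
    present = sorted(curves)
    for qh in present:
        if qh - 1 not in curves:
            continue
        d = curves[qh] - curves[qh - 1]
        exact = np.flatnonzero(d == 0.0)
        for i in exact:
            crossings.append((qh, qh - 1, float(grid[i])))
        sign_change = np.flatnonzero(d[:-1] * d[1:] < 0.0)
        for i in sign_change:
            root = brentq(diff_at, grid[i], grid[i + 1], args=(qh,), xtol=tol)
            crossings.append((qh, qh - 1, float(root)))
    for _, _, pka in crossings:
        if pka - lo < scan_step or hi - pka < scan_step:
            warnings.warn(
                f"{network.molecule_id}: crossing at pH {pka:.3f} lies at the "
                f"edge of the search window {window}",
                stacklevel=2,
            )
    crossings.sort(key=lambda c: c[2])
    return TitrationResult(
        molecule_id=network.molecule_id,
        ph_grid=grid,
        charge_fractions=curves,
        crossings=crossings,
    )


def macroscopic_pka_closed_form(
    network: MicrostateNetwork,
    q_high: int,
    ctx: ThermoContext = ThermoContext(),
) -> float:
    """Analytic macroscopic pKa between charge groups ``q_high`` and ``q_high - 1``.

    Returns log10(Z_high / Z_low) with Z_q = sum_{j in q} exp(-dG0_j / RT);
    independent of any other charge groups because the shared denominator of
    the population expression cancels at the crossing.
    """
    _, g0, q = _population_arrays(network)
    mask_h = q == q_high
    mask_l = q == q_high - 1
    if not mask_h.any() or not mask_l.any():
        raise ValueError(
            f"{network.molecule_id}: missing charge group "
            f"{q_high if not mask_h.any() else q_high - 1}"
        )
    lse_h = logsumexp(-g0[mask_h] / ctx.rt)
    lse_l = logsumexp(-g0[mask_l] / ctx.rt)
    return float((lse_h - lse_l) / math.log(10.0))


def macroscopic_pkas_closed_form(
    network: MicrostateNetwork,
    ctx: ThermoContext = ThermoContext(),
) -> list[tuple[int, int, float]]:
    """Closed-form pKa for every adjacent charge pair, as (q_high, q_low, pKa)."""
    charges = network.collapse_equivalences().charges()
    out = []
    for qh in charges:
        if qh - 1 in charges:
            out.append((qh, qh - 1, macroscopic_pka_closed_form(network, qh, ctx)))
    out.sort(key=lambda c: c[2])
    return out


def cycle_closure_report(
    edges: Sequence[MicroEdge],
    slope_m: float = 1.0,
    ctx: ThermoContext = ThermoContext(),
) -> float:
    """Worst absolute thermodynamic-cycle closure gap over the edge graph.

    Enumerates an independent cycle basis (plus two-cycles formed by parallel
    edges) and returns max |sum of signed contributions| in kcal/mol; 0.0 for
    tree-shaped edge sets.  Consistent inputs close every cycle exactly.
    """
    g = nx.Graph()
    worst = 0.0
    for e in edges:
        dg = _edge_dg(e, slope_m, ctx)
        if g.has_edge(e.from_id, e.to_id):
            data = g.edges[e.from_id, e.to_id]
            along = dg if data["src"] == e.from_id else -dg
            worst = max(worst, abs(along - data["dg"]))
        else:
            g.add_edge(e.from_id, e.to_id, dg=dg, src=e.from_id)
    for cycle in nx.cycle_basis(g):
        total = 0.0
        for u, v in zip(cycle, cycle[1:] + cycle[:1]):
            data = g.edges[u, v]
            total += data["dg"] if data["src"] == u else -data["dg"]
        worst = max(worst, abs(total))
    return worst
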