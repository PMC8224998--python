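"""Domain model for protonation microstates and their free-energy networks.

A *microstate* is one specific tautomer of one specific ionization (charge)
state of a molecule.  A molecule's microstates, together with standard-state
free energies ``dG0`` (pH 0, kcal/mol) of every microstate relative to a
chosen neutral *reference* microstate, form a :class:`MicrostateNetwork` —
the complete input needed to titrate the molecule and extract macroscopic
pKa values.

Sign/charge conventions used throughout the package:

* the reference microstate ``k`` is neutral and has ``dG0 = 0`` by definition;
* ``delta_m(j) = q(j) - q(k) = q(j)`` is the number of protons *gained* going
  from the reference to target ``j`` (−1 for a single deprotonation);
* free energies are in kcal/mol; ``C_units = RT ln 10`` (≈1.364 kcal/mol at
  298.15 K) converts between pKa units and free energy.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ThermoContext",
    "Microstate",
    "MicrostateNetwork",
    "validate_network",
    "delta_m",
    "MOLECULE_ID_PATTERN",
    "MICROSTATE_ID_PATTERN",
]

#: challenge-style identifiers, e.g. ``SM25`` / ``SM25_micro001``.  Deviations
#: are reported as warnings, not errors, so the library generalizes beyond
#: that naming scheme.
MOLECULE_ID_PATTERN = re.compile(r"^SM\d+$")
MICROSTATE_ID_PATTERN = re.compile(r"^(SM\d+)_micro\d+$")


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic constants for pKa/free-energy conversion.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Default 298.15 K (25 °C).
    gas_constant : float
        Gas constant in kcal/(mol·K).
    """

    temperature: float = 298.15
    gas_constant: float = 1.98720425e-3

    @property
    def rt(self) -> float:
        """RT in kcal/mol."""
        return self.gas_constant * self.temperature

    @property
    def c_units(self) -> float:
        """RT·ln10 in kcal/mol — free energy of one pKa unit (≈1.36434 at 298.15 K)."""
        return self.rt * math.log(10.0)


@dataclass(frozen=True)
class Microstate:
    """One tautomer at one formal charge of a molecule."""

    molecule_id: str
    microstate_id: str
    smiles: str
    formal_charge: int


@dataclass
class MicrostateNetwork:
    """A molecule's microstates plus standard-state free energies.

    ``dg0[j]`` is the pH-0 free energy (kcal/mol) of microstate ``j`` relative
    to the neutral reference microstate; the reference itself is implicitly 0
    (if stored, it must be stored as exactly 0.0).  Non-reference states with
    no ``dg0`` entry must be listed in ``unpredicted``.

    ``equivalences`` declares pairs of microstates assumed isoenergetic (e.g.
    a reference drawn with unspecified stereochemistry and its counterpart
    with specified stereochemistry).  For population calculations such pairs
    are collapsed to a single state, keeping the first ID of the pair (or the
    reference ID if the reference is involved).
    """

    molecule_id: str
    reference_id: str
    states: dict[str, Microstate]
    dg0: dict[str, float]
    equivalences: list[tuple[str, str]] = field(default_factory=list)
    unpredicted: set[str] = field(default_factory=set)

    @classmethod
    def from_states(
        cls,
        molecule_id: str,
        reference_id: str,
        states: Iterable[Microstate],
        dg0: Mapping[str, float],
        equivalences: Sequence[tuple[str, str]] = (),
        unpredicted: Iterable[str] = (),
    ) -> "MicrostateNetwork":
        return cls(
            molecule_id=molecule_id,
            reference_id=reference_id,
            states={s.microstate_id: s for s in states},
            dg0=dict(dg0),
            equivalences=list(equivalences),
            unpredicted=set(unpredicted),
        )

    # -- basic accessors ---------------------------------------------------

    def charge_of(self, microstate_id: str) -> int:
        try:
            return self.states[microstate_id].formal_charge
        except KeyError:
            raise KeyError(
                f"unknown microstate {microstate_id!r} in molecule {self.molecule_id}"
            ) from None

    def charges(self) -> list[int]:
        """Sorted distinct formal charges among states with a defined dG0."""
        return sorted({self.charge_of(i) for i in self.predicted_ids()})

    def predicted_ids(self) -> list[str]:
        """Reference plus every state with a dG0 entry, reference first."""
        ids = [self.reference_id]
        ids.extend(i for i in self.dg0 if i != self.reference_id)
        return ids

    def dg0_of(self, microstate_id: str) -> float:
        """dG0 lookup with the implicit 0 for the reference state."""
        if microstate_id == self.reference_id and microstate_id not in self.dg0:
            return 0.0
        try:
            return self.dg0[microstate_id]
        except KeyError:
            raise KeyError(
                f"no dG0 entry for {microstate_id!r} in molecule {self.molecule_id}"
            ) from None

    def delta_m(self, target: str) -> int:
        """Charge difference q(target) − q(reference) (= protons gained)."""
        return self.charge_of(target) - self.charge_of(self.reference_id)

    # -- equivalence collapse ----------------------------------------------

    def collapse_equivalences(self) -> "MicrostateNetwork":
        """Merge declared-isoenergetic pairs into single states.

        Returns a new network in which the second member of each pair is
        dropped (the reference is always the survivor when involved).  A
        dG0 known only for the dropped member is transferred to the kept one.
        """
        if not self.equivalences:
            return self
        states = dict(self.states)
        dg0 = dict(self.dg0)
        unpredicted = set(self.unpredicted)
        for a, b in self.equivalences:
            keep, drop = (b, a) if b == self.reference_id else (a, b)
            if drop not in states or keep not in states:
                continue
            if keep not in dg0 and drop in dg0 and keep != self.reference_id:
                dg0[keep] = dg0[drop]
                unpredicted.discard(keep)
            states.pop(drop, None)
            dg0.pop(drop, None)
            unpredicted.discard(drop)
        return MicrostateNetwork(
            molecule_id=self.molecule_id,
            reference_id=self.reference_id,
            states=states,
            dg0=dg0,
            equivalences=[],
            unpredicted=unpredicted,
        )

    def validate(self, charge_window: tuple[int, int] = (-4, 4)) -> list[str]:
        return validate_network(self, charge_window=charge_window)


def validate_network(
    network: MicrostateNetwork, charge_window: tuple[int, int] = (-4, 4)
) -> list[str]:
    """Check every network invariant; return a list of violation messages.

    An empty list means the network is valid.  Identifier-pattern deviations
    are reported via :mod:`warnings`, not as violations.  The function is
    side-effect free and idempotent.
    """
    v: list[str] = []
    ref = network.reference_id
    if ref not in network.states:
        v.append(f"reference {ref!r} not among states")
    else:
        if network.states[ref].formal_charge != 0:
            v.append(
                f"reference not neutral: {ref!r} has formal charge "
                f"{network.states[ref].formal_charge}"
            )
        if ref in network.dg0 and network.dg0[ref] != 0.0:
            v.append(f"reference {ref!r} stores dG0 {network.dg0[ref]!r}, must be 0")

    lo, hi = charge_window
    seen_prefix_warn = False
    for sid, st in network.states.items():
        if not (lo <= st.formal_charge <= hi):
            v.append(
                f"{sid}: formal charge {st.formal_charge} outside window [{lo}, {hi}]"
            )
        m = MICROSTATE_ID_PATTERN.match(sid)
        if m is None:
            if not seen_prefix_warn:
                warnings.warn(
                    f"{network.molecule_id}: microstate id {sid!r} does not follow "
                    "the SM##_micro### convention",
                    stacklevel=2,
                )
                seen_prefix_warn = True
        elif m.group(1) != st.molecule_id:
            v.append(
                f"{sid}: molecule prefix {m.group(1)!r} does not match "
                f"molecule_id {st.molecule_id!r}"
            )

    for sid, g in network.dg0.items():
        if sid not in network.states:
            v.append(f"dG0 entry for unknown microstate {sid!r}")
        if not math.isfinite(g):
            v.append(f"{sid}: non-finite dG0 {g!r}")

    for sid in network.states:
        if sid == ref:
            continue
        if sid not in network.dg0 and sid not in network.unpredicted:
            v.append(f"{sid}: no dG0 entry and not marked unpredicted")

    for a, b in network.equivalences:
        for sid in (a, b):
            if sid not in network.states:
                v.append(f"equivalence pair ({a}, {b}): unknown microstate {sid!r}")
        ga = 0.0 if a == ref else network.dg0.get(a)
        gb = 0.0 if b == ref else network.dg0.get(b)
        if ga is not None and gb is not None and ga != gb:
            v.append(
                f"equivalence pair ({a}, {b}) declared isoenergetic but "
                f"dG0 differ: {ga} vs {gb} kcal/mol"
            )
    return v


def delta_m(network: MicrostateNetwork, target: str) -> int:
    """Charge difference between ``target`` and the network's reference state."""
    return network.delta_m(target)


def smiles_is_valid(smiles: str) -> bool | None:
    """Syntactic SMILES check via RDKit, when installed; None if unavailable.

    Purely optional plumbing — nothing in the package requires chemically
    meaningful SMILES strings.
    """
    try:
        from rdkit import Chem, RDLogger
    except ImportError:
        return None
    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles) is not None
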