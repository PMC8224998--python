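"""Synthetic cohorts: microstate networks, simulated methods, reference data.

The generator emulates a blind physical-property challenge end to end so
every pipeline stage is testable without external downloads:

* molecules with a neutral reference microstate, formal charges in a window
  (default −2…+2) and 1–4 tautomers per charge state;
* "true" dG0 values constructed by sampling target macroscopic pKas
  uniformly (default 2–12) and inverting them through the partition-function
  relation, which guarantees every network titrates inside the search window;
* simulated methods = truth + per-method bias + Gaussian noise, with a
  configurable omission rate and an optional fraction of exact-zero
  predictions (to exercise the neutral-sign path);
* experimental tables whose pKas are the networks' true macroscopic values,
  logP uniform in the printed challenge range (0.58–2.96) and logD derived
  from logP and the true speciation at pH 7.4.

All randomness flows from ``CohortSpec.seed`` through per-component
``numpy`` seed sequences, so each generator is reproducible independently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .logd import logd_from_network
from .microstates import Microstate, MicrostateNetwork, ThermoContext
from .pka import macroscopic_pkas_closed_form
from .records import (
    ExperimentalRecord,
    MethodSubmission,
    PartitionRecord,
    TransitionPrediction,
)

__all__ = [
    "CohortSpec",
    "generate_networks",
    "generate_method_cohort",
    "generate_logp_cohort",
    "generate_experimental",
    "true_macroscopic_pkas",
]

_PKA_METHOD_CATEGORIES = ("QM", "QSPR/ML", "QM+LEC")
_LOGP_METHOD_CATEGORIES = ("Physical (QM)", "Empirical", "Physical (MM)")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic challenge cohort.

    Defaults mirror a realistic blind-challenge setting: 22 molecules,
    charges −2…+2 with 1–4 tautomers per charge, a 10-method cohort with
    0.5 kcal/mol Gaussian error and a 10% chance of omitting any given
    transition.
    """

    n_molecules: int = 22
    charge_range: tuple[int, int] = (-2, 2)
    tautomers_per_charge: tuple[int, int] = (1, 4)
    n_methods: int = 10
    noise_sd: float | Sequence[float] = 0.5
    bias: float | Sequence[float] = 0.0
    omission_rate: float = 0.1
    zero_fraction: float = 0.0
    pka_range: tuple[float, float] = (2.0, 12.0)
    tautomer_spread: float = 2.0
    #: if True, every molecule spans the full charge_range (e.g. a uniformly
    #: monoprotic cohort); if False the span varies per molecule
    fixed_charge_span: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1 or self.n_methods < 1:
            raise ValueError("counts must be >= 1")
        if not (self.charge_range[0] <= 0 <= self.charge_range[1]):
            raise ValueError("charge_range must include 0 (the neutral reference)")
        t_lo, t_hi = self.tautomers_per_charge
        if t_lo < 1 or t_hi < t_lo:
            raise ValueError("tautomers_per_charge must be a valid interval >= 1")
        for p in (self.omission_rate, self.zero_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")

    def _per_method(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_methods,))
        return np.array(arr)


def _component_rng(seed: int, component: int) -> np.random.Generator:
    # counter-based splitting: one root seed, one fixed lane per component
    return np.random.default_rng(np.random.SeedSequence([int(seed), component]))


def generate_networks(
    spec: CohortSpec, ctx: ThermoContext = ThermoContext()
) -> list[MicrostateNetwork]:
    """Generate microstate networks with known true dG0 values.

    Group free-energy levels are solved so that the closed-form macroscopic
    pKa of every adjacent charge pair equals its sampled target exactly.
    """
    rng = _component_rng(spec.seed, 1)
    networks = []
    for i in range(spec.n_molecules):
        mol = f"SM{i + 1:02d}"
        if spec.fixed_charge_span:
            q_lo, q_hi = spec.charge_range
        else:
            q_lo = int(rng.integers(spec.charge_range[0], 1))
            q_hi = int(rng.integers(0, spec.charge_range[1] + 1))
        charges = list(range(q_lo, q_hi + 1))
        t_lo, t_hi = spec.tautomers_per_charge
        n_taut = {q: int(rng.integers(t_lo, t_hi + 1)) for q in charges}

        # per-group tautomer offsets (kcal/mol above the group's lead state)
        offsets = {
            q: np.concatenate(
                [[0.0], rng.uniform(0.0, spec.tautomer_spread, n_taut[q] - 1)]
            )
            for q in charges
        }
        # log10 of the within-group partition function at the group level
        s = {
            q: float(logsumexp(-offsets[q] / ctx.rt)) / np.log(10.0) for q in charges
        }

        n_pairs = len(charges) - 1
        targets = np.sort(rng.uniform(*spec.pka_range, size=n_pairs))
        # pair (q, q-1) listed from the most protonated downward gets the
        # smallest pKa first, so dominance regions are sequentially ordered
        target_for = {
            (qh, qh - 1): t
            for (qh, t) in zip(range(q_hi, q_lo, -1), targets)
        }

        level = {0: 0.0}
        for q in range(1, q_hi + 1):
            t = target_for[(q, q - 1)]
            level[q] = level[q - 1] - ctx.c_units * (t - s[q] + s[q - 1])
        for q in range(-1, q_lo - 1, -1):
            t = target_for[(q + 1, q)]
            level[q] = level[q + 1] + ctx.c_units * (t - s[q + 1] + s[q])

        states: list[Microstate] = []
        dg0: dict[str, float] = {}
        counter = itertools.count(0)
        reference_id = ""
        for q in charges:
            for j, off in enumerate(offsets[q]):
                sid = f"{mol}_micro{next(counter):03d}"
                # placeholder SMILES: networks are synthetic, not chemical
                states.append(Microstate(mol, sid, "C", q))
                if q == 0 and j == 0:
                    reference_id = sid
                else:
                    dg0[sid] = level[q] + float(off)
        networks.append(
            MicrostateNetwork.from_states(mol, reference_id, states, dg0)
        )
    return networks


def true_macroscopic_pkas(
    network: MicrostateNetwork, ctx: ThermoContext = ThermoContext()
) -> list[float]:
    """The network's exact macroscopic pKas (closed form), sorted ascending."""
    return [pka for _, _, pka in macroscopic_pkas_closed_form(network, ctx)]


def generate_method_cohort(
    networks: Sequence[MicrostateNetwork], spec: CohortSpec
) -> list[MethodSubmission]:
    """Simulate a cohort of prediction methods over the given networks.

    Method ``m`` predicts ``dG0_true + bias[m] + N(0, noise_sd[m])`` for each
    transition, omits any transition with probability ``omission_rate`` and
    reports exactly 0.0 with probability ``zero_fraction``.
    """
    noise = spec._per_method(spec.noise_sd)
    bias = spec._per_method(spec.bias)
    root = np.random.SeedSequence([int(spec.seed), 2])
    submissions = []
    for m, child in enumerate(root.spawn(spec.n_methods)):
        rng = np.random.default_rng(child)
        preds: list[TransitionPrediction] = []
        for net in networks:
            for sid in sorted(net.dg0):
                if rng.random() < spec.omission_rate:
                    continue
                if spec.zero_fraction and rng.random() < spec.zero_fraction:
                    value = 0.0
                else:
                    value = net.dg0[sid] + bias[m] + rng.normal(0.0, noise[m])
                preds.append(
                    TransitionPrediction(
                        molecule_id=net.molecule_id,
                        reference_id=net.reference_id,
                        target_id=sid,
                        target_charge=net.charge_of(sid),
                        dg0=float(value),
                        sem=float(noise[m]),
                        model_uncertainty=float(noise[m]),
                    )
                )
        submissions.append(
            MethodSubmission(
                method_name=f"SIM{m:02d}",
                category=_PKA_METHOD_CATEGORIES[m % len(_PKA_METHOD_CATEGORIES)],
                predictions=preds,
            )
        )
    return submissions


def generate_logp_cohort(
    experimental: dict[str, ExperimentalRecord],
    spec: CohortSpec,
    ctx: ThermoContext = ThermoContext(),
) -> list[MethodSubmission]:
    """Simulate partitioning methods: true transfer free energy + noise.

    Noise and bias are in kcal/mol on the water->octanol transfer free
    energy, so the induced logP error is noise / (RT ln10).
    """
    from .logd import logp_to_transfer_dg, transfer_dg_to_logp

    noise = spec._per_method(spec.noise_sd)
    bias = spec._per_method(spec.bias)
    root = np.random.SeedSequence([int(spec.seed), 3])
    submissions = []
    for m, child in enumerate(root.spawn(spec.n_methods)):
        rng = np.random.default_rng(child)
        preds = []
        for mol in sorted(experimental):
            rec = experimental[mol]
            if rec.logp is None:
                continue
            dg = (
                logp_to_transfer_dg(rec.logp, ctx)
                + bias[m]
                + rng.normal(0.0, noise[m])
            )
            preds.append(
                PartitionRecord(
                    molecule_id=mol,
                    logp=transfer_dg_to_logp(dg, ctx),
                    source="submitted_transfer_dg",
                    transfer_dg=float(dg),
                    sem=float(noise[m]),
                    model_uncertainty=float(noise[m]),
                )
            )
        submissions.append(
            MethodSubmission(
                method_name=f"SIMP{m:02d}",
                category=_LOGP_METHOD_CATEGORIES[m % len(_LOGP_METHOD_CATEGORIES)],
                predictions=preds,
            )
        )
    return submissions


def generate_experimental(
    networks: Sequence[MicrostateNetwork],
    logp_range: tuple[float, float] = (0.58, 2.96),
    seed: int = 0,
    ph: float = 7.4,
    ctx: ThermoContext = ThermoContext(),
) -> dict[str, ExperimentalRecord]:
    """Experimental tables consistent with the networks' true speciation.

    pKas are the exact macroscopic values of each network, logP is uniform in
    ``logp_range`` and logD follows from logP and the neutral fraction at the
    stated pH — so a perfect method scores zero error end to end.
    """
    rng = _component_rng(seed, 4)
    out: dict[str, ExperimentalRecord] = {}
    for net in networks:
        logp = float(rng.uniform(*logp_range))
        pkas = tuple(true_macroscopic_pkas(net, ctx))
        logd = logd_from_network(logp, net, ph, ctx)
        out[net.molecule_id] = ExperimentalRecord(
            molecule_id=net.molecule_id, logp=logp, pkas=pkas, logd=logd
        )
    return out
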