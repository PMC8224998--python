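"""Distribution coefficients (logD) from partition coefficients and pKa.

The distribution coefficient at a given pH is the partition coefficient of
the neutral species corrected by the fraction of the molecule that is neutral
in the aqueous phase, under the assumption that ionic species cannot
partition into the organic phase:

    logD(pH) = logP + log10( x_neutral(pH) )

For a monoprotic compound this reduces to the familiar closed forms

    acid:  logD = logP - log10(1 + 10**(pH - pKa))
    base:  logD = logP - log10(1 + 10**(pKa - pH))

The correction term is always >= 0, so logD <= logP everywhere.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import logsumexp

from .microstates import MicrostateNetwork, ThermoContext
from .pka import _population_arrays
from .records import PartitionRecord  # noqa: F401  (module surface re-export)

__all__ = [
    "PartitionRecord",
    "transfer_dg_to_logp",
    "logp_to_transfer_dg",
    "logd_monoprotic",
    "logd_from_network",
    "null_logd",
]


def transfer_dg_to_logp(dg_transfer: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Convert a water->octanol transfer free energy (kcal/mol) to logP.

    Favorable transfer into octanol (negative dG) gives a positive logP:
    logP = -dG / (RT ln10).
    """
    return -dg_transfer / ctx.c_units


def logp_to_transfer_dg(logp: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Inverse of :func:`transfer_dg_to_logp`."""
    return -logp * ctx.c_units


def logd_monoprotic(logp: float, pka: float, ph: float, site: str) -> float:
    """Closed-form logD for a compound with a single ionizable site.

    ``site`` is ``"acid"`` (neutral below its pKa) or ``"base"`` (neutral
    above the pKa of its conjugate acid).  Uses log1p in log-space, so the
    result is finite for arbitrarily large corrections.
    """
    if site not in ("acid", "base"):
        raise ValueError(f"site must be 'acid' or 'base', got {site!r}")
    expo = (ph - pka) if site == "acid" else (pka - ph)
    # log10(1 + 10**expo), overflow-safe
    correction = np.logaddexp(0.0, expo * math.log(10.0)) / math.log(10.0)
    return logp - float(correction)


def logd_from_network(
    logp: float,
    network: MicrostateNetwork,
    ph: float,
    ctx: ThermoContext = ThermoContext(),
) -> float:
    """logD at a given pH from the full microstate speciation of a network.

    logD = logP + log10(x_neutral(pH)) with x_neutral the summed population
    of all charge-0 microstates.  Computed in log space, so no underflow for
    strongly ionized molecules; a vanishing neutral population yields -inf
    with a warning.
    """
    ids, g0, q = _population_arrays(network)
    if not (q == 0).any():
        raise ValueError(f"{network.molecule_id}: network has no neutral microstate")
    logw = -(g0 + q * ctx.c_units * ph) / ctx.rt
    log_x0 = logsumexp(logw[q == 0]) - logsumexp(logw)
    out = logp + float(log_x0) / math.log(10.0)
    if out == -math.inf:
        warnings.warn(
            f"{network.molecule_id}: neutral population underflows at pH {ph}",
            stacklevel=2,
        )
    return out


def null_logd(molecule_ids) -> dict[str, float]:
    """Null model: every molecule partitions equally between the two phases (logD 0)."""
    return {m: 0.0 for m in molecule_ids}
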