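"""Cross-method sign agreement for microstate transitions.

For each reference->target transition, methods are tallied by the sign of
their predicted free-energy change (positive, negative, or exactly zero —
some methods do submit exact zeros).  Disagreement is summarized by the
Shannon entropy

    H = -sum_i P_i ln P_i,   i in {positive, negative, neutral},

with the convention 0·ln 0 = 0.  H = 0 means every reporting method agreed
on the sign; ln 3 (≈1.0986) is the maximum three-way disagreement.

By default the fractions P_i are taken over the *full* method cohort, so a
method that omitted the transition dilutes all three fractions (they then
sum to less than one).  A predictors-only denominator is available via
``denominator="predictors"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .microstates import MicrostateNetwork
from .records import MethodSubmission

__all__ = ["SignTally", "tally_signs", "shannon_entropy", "entropy_table"]


@dataclass(frozen=True)
class SignTally:
    """Sign counts for one transition across a method cohort."""

    microstate_id: str
    n_methods_total: int
    n_positive: int
    n_negative: int
    n_neutral: int

    def __post_init__(self):
        if self.n_positive + self.n_negative + self.n_neutral > self.n_methods_total:
            raise ValueError(
                f"{self.microstate_id}: sign counts exceed cohort size "
                f"{self.n_methods_total}"
            )

    @property
    def n_predicted(self) -> int:
        return self.n_positive + self.n_negative + self.n_neutral


def tally_signs(
    submissions: Sequence[MethodSubmission], microstate_id: str
) -> SignTally:
    """Classify each method's dG0 for a target microstate by sign.

    The classification threshold is exact zero (no epsilon).  Methods with no
    prediction for the transition count only toward ``n_methods_total``.
    """
    if not submissions:
        raise ValueError("empty method cohort")
    pos = neg = neu = 0
    for sub in submissions:
        for p in sub.predictions:
            if p.target_id != microstate_id:
                continue
            if p.dg0 > 0:
                pos += 1
            elif p.dg0 < 0:
                neg += 1
            else:
                neu += 1
            break
    return SignTally(
        microstate_id=microstate_id,
        n_methods_total=len(submissions),
        n_positive=pos,
        n_negative=neg,
        n_neutral=neu,
    )


def shannon_entropy(tally: SignTally, denominator: str = "cohort") -> float:
    """Shannon entropy (nats) of the sign distribution of one transition.

    ``denominator="cohort"`` divides counts by the full cohort size (omitted
    predictions dilute the fractions); ``"predictors"`` divides by the number
    of methods that actually reported the transition.
    """
    if denominator == "cohort":
        n = tally.n_methods_total
    elif denominator == "predictors":
        n = tally.n_predicted
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if n <= 0:
        raise ValueError(f"{tally.microstate_id}: no methods to tally")
    h = 0.0
    for count in (tally.n_positive, tally.n_negative, tally.n_neutral):
        p = count / n
        if p > 0.0:
            h -= p * math.log(p)
    return h


def entropy_table(
    submissions: Sequence[MethodSubmission],
    networks: Iterable[MicrostateNetwork] | Mapping[str, MicrostateNetwork] | None = None,
    denominator: str = "cohort",
) -> pd.DataFrame:
    """Sign tallies and entropy for every transition, one row per microstate.

    When ``networks`` is given the rows cover every non-reference microstate
    of every network (including ones nobody predicted); otherwise the union
    of all predicted targets is used.  Sorted by descending entropy, then id.
    """
    if networks is not None:
        nets = networks.values() if isinstance(networks, Mapping) else networks
        targets = [
            (net.molecule_id, sid)
            for net in nets
            for sid in sorted(net.states)
            if sid != net.reference_id
        ]
    else:
        seen: dict[str, str] = {}
        for sub in submissions:
            for p in sub.predictions:
                seen.setdefault(p.target_id, p.molecule_id)
        targets = sorted((mol, sid) for sid, mol in seen.items())
    rows = []
    for mol, sid in targets:
        tally = tally_signs(submissions, sid)
        rows.append(
            {
                "molecule_id": mol,
                "microstate_id": sid,
                "n_methods_total": tally.n_methods_total,
                "n_positive": tally.n_positive,
                "n_negative": tally.n_negative,
                "n_neutral": tally.n_neutral,
                "shannon_entropy": shannon_entropy(tally, denominator=denominator),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "molecule_id",
            "microstate_id",
            "n_methods_total",
            "n_positive",
            "n_negative",
            "n_neutral",
            "shannon_entropy",
        ],
    )
    return df.sort_values(
        ["shannon_entropy", "microstate_id"], ascending=[False, True]
    ).reset_index(drop=True)
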