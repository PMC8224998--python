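"""Shared record types for submissions and experimental reference data."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PKA_CATEGORIES",
    "LOGP_CATEGORIES",
    "TransitionPrediction",
    "PartitionRecord",
    "MethodSubmission",
    "ExperimentalRecord",
]

#: method-category vocabulary for the pKa challenge
PKA_CATEGORIES = ("DL", "LFER", "QSPR/ML", "QM", "QM+LEC", "QM+MM", "Other")
#: method-category vocabulary for the partitioning (logP) challenge
LOGP_CATEGORIES = ("Physical (MM)", "Physical (QM)", "Empirical", "Mixed")


@dataclass(frozen=True)
class TransitionPrediction:
    """One method's predicted dG0 for one reference->target microstate transition.

    ``sem`` is the statistical repeatability of the prediction and
    ``model_uncertainty`` the method's self-estimated expected deviation from
    experiment, both in kcal/mol.
    """

    molecule_id: str
    reference_id: str
    target_id: str
    target_charge: int
    dg0: float
    sem: float = 0.0
    model_uncertainty: float = 0.0

    def __post_init__(self):
        if self.sem < 0 or self.model_uncertainty < 0:
            raise ValueError(
                f"{self.molecule_id}/{self.target_id}: sem and model_uncertainty "
                "must be non-negative"
            )
        if self.target_id == self.reference_id:
            raise ValueError(
                f"{self.molecule_id}: self-transition {self.reference_id!r}"
            )


@dataclass(frozen=True)
class PartitionRecord:
    """One method's octanol-water partition prediction for one molecule.

    ``source`` records whether the method submitted a logP directly or a
    water->octanol transfer free energy (kcal/mol); for the latter,
    logP = -transfer_dg / (RT ln10).
    """

    molecule_id: str
    logp: float
    source: str = "submitted_logp"  # or "submitted_transfer_dg"
    transfer_dg: float | None = None
    microstate_ids: tuple[str, ...] = ()
    sem: float = 0.0
    model_uncertainty: float = 0.0


@dataclass
class MethodSubmission:
    """A named, categorized set of predictions for all molecules of a challenge.

    ``predictions`` holds :class:`TransitionPrediction` objects for a pKa
    submission or :class:`PartitionRecord` objects for a partitioning one.
    """

    method_name: str
    category: str
    ranked: bool = True
    predictions: list = field(default_factory=list)
    compute_time_note: str = ""
    hardware_note: str = ""
    software_list: str = ""
    method_text: str = ""

    def validate_category(self, vocabulary) -> None:
        if self.category not in vocabulary:
            raise ValueError(
                f"{self.method_name}: category {self.category!r} not in {vocabulary}"
            )

    def by_molecule(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for p in self.predictions:
            out.setdefault(p.molecule_id, []).append(p)
        return out


@dataclass(frozen=True)
class ExperimentalRecord:
    """Experimental reference values for one molecule."""

    molecule_id: str
    logp: float | None = None
    pkas: tuple[float, ...] = ()
    logd: float | None = None
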