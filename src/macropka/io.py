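"""Readers and writers for submission files and result tables.

All files are flat comma-separated UTF-8 text with a header row, optionally
preceded by a metadata block of ``# key: value`` comment lines (method name,
category, ranked flag, declared unit, free-text notes).  This dialect is
self-defined and documented here; see the format notes in each reader.

Free energies are canonically kcal/mol.  pKa submissions may declare
``kJ/mol`` or ``pKa`` units in their metadata (or via the reader argument);
values are converted at read time.
"""

from __future__ import annotations

import csv
import io as _io
import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .evaluate import METRIC_NAMES, BootstrapInterval, MetricReport
from .microstates import Microstate, ThermoContext
from .pka import TitrationResult
from .records import (  # noqa: F401  (module surface re-exports)
    LOGP_CATEGORIES,
    PKA_CATEGORIES,
    ExperimentalRecord,
    MethodSubmission,
    PartitionRecord,
    TransitionPrediction,
)

__all__ = [
    "SubmissionFormatError",
    "DirectionalConventionError",
    "read_microstates_csv",
    "write_microstates_csv",
    "read_pka_submission",
    "write_pka_submission",
    "read_logp_submission",
    "write_logp_submission",
    "read_experimental_table",
    "write_experimental_table",
    "write_metric_table",
    "read_metric_table",
    "write_titration_table",
    "read_titration_table",
    "write_entropy_table",
]

KJ_PER_KCAL = 4.184
#: soft plausibility windows used for range warnings on experimental tables
_PLAUSIBLE = {"logp": (-1.0, 6.0), "pka": (0.0, 14.0), "logd": (-3.0, 5.0)}


class SubmissionFormatError(ValueError):
    """A submission file violates the documented CSV dialect."""


class DirectionalConventionError(SubmissionFormatError):
    """A transition is not defined away from the declared neutral reference."""


# ---------------------------------------------------------------------------
# helpers


def _split_metadata(path) -> tuple[dict[str, str], str]:
    """Separate the leading '# key: value' block from the CSV body."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    in_header = True
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if in_header and line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip().lower()] = value.strip()
                continue
            in_header = False
            body_lines.append(line)
    return meta, "".join(body_lines)


def _read_body(path, required: Sequence[str]) -> tuple[dict[str, str], pd.DataFrame]:
    meta, body = _split_metadata(path)
    try:
        df = pd.read_csv(_io.StringIO(body), dtype=str, skip_blank_lines=True)
    except Exception as exc:  # malformed CSV
        raise SubmissionFormatError(f"{path}: cannot parse CSV body: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SubmissionFormatError(f"{path}: missing columns {missing}")
    return meta, df

def _as_float(value, path, what) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SubmissionFormatError(f"{path}: non-numeric {what}: {value!r}") from None


def _as_int(value, path, what) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise SubmissionFormatError(f"{path}: malformed {what}: {value!r}") from None


def _check_declared_count(meta: dict, n_rows: int, path) -> None:
    declared = meta.get("n_predictions")
    if declared is not None and int(declared) != n_rows:
        raise SubmissionFormatError(
            f"{path}: declares {declared} predictions but contains {n_rows} rows "
            "(truncated file?)"
        )


def _unit_factor(unit: str, ctx: ThermoContext) -> float:
    u = unit.strip().lower()
    if u in ("kcal/mol", "kcal"):
        return 1.0
    if u in ("kj/mol", "kj"):
        return 1.0 / KJ_PER_KCAL
    if u in ("pka", "pka-units", "pka units"):
        return ctx.c_units
    raise SubmissionFormatError(f"unknown free-energy unit {unit!r}")


def _submission_metadata(meta: dict[str, str], default_name: str) -> dict:
    return {
        "method_name": meta.get("method_name", default_name),
        "category": meta.get("category", "Other"),
        "ranked": meta.get("ranked", "true").strip().lower() in ("true", "yes", "1"),
        "compute_time_note": meta.get("compute_time", ""),
        "hardware_note": meta.get("hardware", ""),
        "software_list": meta.get("software", ""),
        "method_text": meta.get("method", ""),
    }


def _write_metadata(fh, submission: MethodSubmission, extra: dict | None = None) -> None:
    fh.write(f"# method_name: {submission.method_name}\n")
    fh.write(f"# category: {submission.category}\n")
    fh.write(f"# ranked: {'true' if submission.ranked else 'false'}\n")
    for key, attr in (
        ("compute_time", "compute_time_note"),
        ("hardware", "hardware_note"),
        ("software", "software_list"),
        ("method", "method_text"),
    ):
        value = getattr(submission, attr)
        if value:
            fh.write(f"# {key}: {value}\n")
    for key, value in (extra or {}).items():
        fh.write(f"# {key}: {value}\n")


# ---------------------------------------------------------------------------
# microstate tables


def read_microstates_csv(path) -> dict[str, list[Microstate]]:
    """Read a microstate definition table, grouped by molecule.

    Columns: ``molecule_id, microstate_id, smiles, formal_charge``.
    """
    _, df = _read_body(path, ["molecule_id", "microstate_id", "smiles", "formal_charge"])
    out: dict[str, list[Microstate]] = {}
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["microstate_id"]
        if sid in seen:
            raise SubmissionFormatError(f"{path}: duplicate microstate_id {sid!r}")
        seen.add(sid)
        out.setdefault(row["molecule_id"], []).append(
            Microstate(
                molecule_id=row["molecule_id"],
                microstate_id=sid,
                smiles=row["smiles"] if isinstance(row["smiles"], str) else "",
                formal_charge=_as_int(row["formal_charge"], path, "formal charge"),
            )
        )
    return out


def write_microstates_csv(states_by_molecule: Mapping[str, Sequence[Microstate]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "microstate_id", "smiles", "formal_charge"])
        for mol in sorted(states_by_molecule):
            for s in states_by_molecule[mol]:
                w.writerow([s.molecule_id, s.microstate_id, s.smiles, s.formal_charge])


# ---------------------------------------------------------------------------
# pKa submissions


def read_pka_submission(
    path,
    unit: str = "kcal/mol",
    references: Mapping[str, str] | None = None,
    microstates: Mapping[str, Sequence[Microstate]] | None = None,
    strict: bool = False,
    ctx: ThermoContext = ThermoContext(),
) -> MethodSubmission:
    """Read a per-transition dG0 submission.

    Columns: ``molecule_id, reference_id, target_id, target_charge, dg0, sem,
    model_uncertainty``.  A ``# unit:`` metadata line overrides ``unit``.
    Transitions must be defined away from the neutral reference: a row whose
    reference differs from the declared reference for that molecule (from
    ``references`` or the first row seen) raises
    :class:`DirectionalConventionError`.  When a microstate table is given,
    a submitted target charge that disagrees with the table is a warning, or
    an error under ``strict``.
    """
    meta, df = _read_body(
        path,
        ["molecule_id", "reference_id", "target_id", "target_charge", "dg0", "sem",
         "model_uncertainty"],
    )
    _check_declared_count(meta, len(df), path)
    factor = _unit_factor(meta.get("unit", unit), ctx)
    charge_of = {}
    if microstates is not None:
        for mol_states in microstates.values():
            for s in mol_states:
                charge_of[s.microstate_id] = s.formal_charge

    predictions: list[TransitionPrediction] = []
    seen: set[tuple[str, str]] = set()
    ref_for: dict[str, str] = dict(references or {})
    for _, row in df.iterrows():
        mol, ref, target = row["molecule_id"], row["reference_id"], row["target_id"]
        if target == ref:
            raise SubmissionFormatError(
                f"{path}: self-transition {ref!r} -> {target!r} for {mol}"
            )
        expected_ref = ref_for.setdefault(mol, ref)
        if ref != expected_ref:
            raise DirectionalConventionError(
                f"{path}: {mol} row references {ref!r}, but transitions must be "
                f"defined away from the neutral reference {expected_ref!r}"
            )
        if charge_of and charge_of.get(ref, 0) != 0:
            raise DirectionalConventionError(
                f"{path}: {mol} reference {ref!r} is not neutral in the microstate table"
            )
        key = (mol, target)
        if key in seen:
            raise SubmissionFormatError(f"{path}: duplicate transition {key}")
        seen.add(key)
        q = _as_int(row["target_charge"], path, "target charge")
        if target in charge_of and charge_of[target] != q:
            msg = (
                f"{path}: {target} submitted with charge {q:+d} but the microstate "
                f"table says {charge_of[target]:+d}"
            )
            if strict:
                raise SubmissionFormatError(msg)
            warnings.warn(msg, stacklevel=2)
        predictions.append(
            TransitionPrediction(
                molecule_id=mol,
                reference_id=ref,
                target_id=target,
                target_charge=q,
                dg0=_as_float(row["dg0"], path, "dg0") * factor,
                sem=abs(_as_float(row["sem"], path, "sem")) * factor,
                model_uncertainty=abs(
                    _as_float(row["model_uncertainty"], path, "model uncertainty")
                ) * factor,
            )
        )
    return MethodSubmission(
        predictions=predictions,
        **_submission_metadata(meta, Path(path).stem),
    )


def write_pka_submission(submission: MethodSubmission, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_metadata(fh, submission, extra={"unit": "kcal/mol"})
        w = csv.writer(fh)
        w.writerow(
            ["molecule_id", "reference_id", "target_id", "target_charge", "dg0",
             "sem", "model_uncertainty"]
        )
        for p in submission.predictions:
            w.writerow(
                [p.molecule_id, p.reference_id, p.target_id, p.target_charge,
                 repr(p.dg0), repr(p.sem), repr(p.model_uncertainty)]
            )


# ---------------------------------------------------------------------------
# logP submissions


def read_logp_submission(
    path, ctx: ThermoContext = ThermoContext()
) -> MethodSubmission:
    """Read a partitioning submission.

    Columns: ``molecule_id, microstate_ids`` plus exactly one of
    ``transfer_dg`` (water->octanol, kcal/mol; converted to logP at read
    time) or ``logp``, then ``sem, model_uncertainty``.  Files carrying both
    or neither value column are rejected.
    """
    from .logd import transfer_dg_to_logp

    meta, df = _read_body(path, ["molecule_id"])
    _check_declared_count(meta, len(df), path)
    has_dg = "transfer_dg" in df.columns
    has_logp = "logp" in df.columns
    if has_dg == has_logp:
        raise SubmissionFormatError(
            f"{path}: need exactly one of 'transfer_dg' or 'logp' columns"
        )
    predictions: list[PartitionRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        mol = row["molecule_id"]
        if mol in seen:
            raise SubmissionFormatError(f"{path}: duplicate molecule {mol!r}")
        seen.add(mol)
        raw_ids = row.get("microstate_ids")
        micro_ids = (
            tuple(s for s in str(raw_ids).split(";") if s)
            if isinstance(raw_ids, str)
            else ()
        )
        sem = abs(_as_float(row["sem"], path, "sem")) if "sem" in df.columns else 0.0
        mu = (
            abs(_as_float(row["model_uncertainty"], path, "model uncertainty"))
            if "model_uncertainty" in df.columns
            else 0.0
        )
        if has_dg:
            dg = _as_float(row["transfer_dg"], path, "transfer_dg")
            predictions.append(
                PartitionRecord(
                    molecule_id=mol,
                    logp=transfer_dg_to_logp(dg, ctx),
                    source="submitted_transfer_dg",
                    transfer_dg=dg,
                    microstate_ids=micro_ids,
                    sem=sem,
                    model_uncertainty=mu,
                )
            )
        else:
            predictions.append(
                PartitionRecord(
                    molecule_id=mol,
                    logp=_as_float(row["logp"], path, "logp"),
                    source="submitted_logp",
                    microstate_ids=micro_ids,
                    sem=sem,
                    model_uncertainty=mu,
                )
            )
    return MethodSubmission(
        predictions=predictions,
        **_submission_metadata(meta, Path(path).stem),
    )


def write_logp_submission(
    submission: MethodSubmission, path, as_transfer_dg: bool = False
) -> None:
    value_col = "transfer_dg" if as_transfer_dg else "logp"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_metadata(fh, submission)
        w = csv.writer(fh)
        w.writerow(["molecule_id", "microstate_ids", value_col, "sem",
                    "model_uncertainty"])
        from .logd import logp_to_transfer_dg

        for p in submission.predictions:
            value = (
                p.transfer_dg
                if as_transfer_dg and p.transfer_dg is not None
                else (logp_to_transfer_dg(p.logp) if as_transfer_dg else p.logp)
            )
            w.writerow(
                [p.molecule_id, ";".join(p.microstate_ids), repr(float(value)),
                 repr(p.sem), repr(p.model_uncertainty)]
            )


# ---------------------------------------------------------------------------
# experimental reference tables


def read_experimental_table(path) -> dict[str, ExperimentalRecord]:
    """Read an experimental reference table.

    Columns: ``molecule_id, logp, pkas, logd`` with multiple pKa values
    ';'-delimited inside one cell.  Empty cells mean the value was not
    measured.  Values outside loose plausibility windows produce warnings,
    never errors.
    """
    _, df = _read_body(path, ["molecule_id"])
    out: dict[str, ExperimentalRecord] = {}
    for _, row in df.iterrows():
        mol = row["molecule_id"]

        def _opt(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return _as_float(v, path, col)

        logp = _opt("logp")
        logd = _opt("logd")
        raw = row.get("pkas")
        pkas: tuple[float, ...] = ()
        if isinstance(raw, str) and raw:
            pkas = tuple(_as_float(tok, path, "pka") for tok in raw.split(";") if tok)
        for name, value in (("logp", logp), ("logd", logd)):
            window = _PLAUSIBLE[name]
            if value is not None and not (window[0] <= value <= window[1]):
                warnings.warn(
                    f"{path}: {mol} {name}={value} outside plausible range {window}",
                    stacklevel=2,
                )
        for v in pkas:
            if not (_PLAUSIBLE["pka"][0] <= v <= _PLAUSIBLE["pka"][1]):
                warnings.warn(
                    f"{path}: {mol} pKa={v} outside plausible range {_PLAUSIBLE['pka']}",
                    stacklevel=2,
                )
        out[mol] = ExperimentalRecord(molecule_id=mol, logp=logp, pkas=pkas, logd=logd)
    return out


def write_experimental_table(records: Mapping[str, ExperimentalRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "logp", "pkas", "logd"])
        for mol in sorted(records):
            r = records[mol]
            w.writerow(
                [mol,
                 "" if r.logp is None else repr(r.logp),
                 ";".join(repr(v) for v in r.pkas),
                 "" if r.logd is None else repr(r.logd)]
            )


# ---------------------------------------------------------------------------
# result tables


def write_metric_table(reports: Sequence[MetricReport], path) -> None:
    """One row per method: point estimate and CI bounds for all six metrics."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        header = ["method", "category", "type", "n_molecules"]
        for m in METRIC_NAMES:
            header += [m, f"{m}_ci_low", f"{m}_ci_high"]
        w.writerow(header)
        for r in reports:
            row = [r.method_name, r.category, r.property_name, r.n_molecules]
            for m in METRIC_NAMES:
                b = r.metrics[m]
                row += [repr(b.point), repr(b.ci_low), repr(b.ci_high)]
            w.writerow(row)


def read_metric_table(path) -> list[MetricReport]:
    _, df = _read_body(path, ["method", "category", "type", "n_molecules"])
    reports = []
    for _, row in df.iterrows():
        metrics = {
            m: BootstrapInterval(
                point=_as_float(row[m], path, m),
                ci_low=_as_float(row[f"{m}_ci_low"], path, m),
                ci_high=_as_float(row[f"{m}_ci_high"], path, m),
            )
            for m in METRIC_NAMES
        }
        reports.append(
            MetricReport(
                method_name=row["method"],
                category=row["category"],
                metrics=metrics,
                n_molecules=_as_int(row["n_molecules"], path, "n_molecules"),
                property_name=row["type"] if isinstance(row["type"], str) else "",
            )
        )
    return reports


def write_titration_table(results: Sequence[TitrationResult], path) -> None:
    """Macroscopic pKa crossings, one row per (molecule, charge pair)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "q_high", "q_low", "pka"])
        for res in results:
            for qh, ql, pka in res.crossings:
                w.writerow([res.molecule_id, qh, ql, repr(pka)])


def read_titration_table(path) -> pd.DataFrame:
    _, df = _read_body(path, ["molecule_id", "q_high", "q_low", "pka"])
    return df.astype({"q_high": int, "q_low": int, "pka": float})


def write_entropy_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
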