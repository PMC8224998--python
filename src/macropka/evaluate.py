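"""Blind-challenge evaluation statistics.

Error metrics (RMSE, MAE, signed ME), correlation metrics (squared Pearson
R2, OLS slope, Kendall tau-b), 95% confidence intervals by bootstrapping over
molecules (10,000 resamples by default), minimum-cost matching of predicted
to experimental macroscopic pKa values, null baselines, per-molecule error
breakdowns and consistent-ranking shortlists.

Sign convention: errors are predicted - experimental, so a positive mean
signed error means systematic overprediction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import kendalltau

from .logd import logd_from_network
from .microstates import ThermoContext
from .pka import macroscopic_pkas_titration, network_from_predictions
from .records import ExperimentalRecord, MethodSubmission, PartitionRecord

__all__ = [
    "METRIC_NAMES",
    "NULL_LOGP",
    "PairedObservations",
    "BootstrapInterval",
    "MetricReport",
    "MatchResult",
    "compute_metrics",
    "coefficient_of_determination",
    "bootstrap_ci",
    "evaluate_method",
    "match_pkas",
    "consistent_shortlist",
    "per_molecule_mae",
    "null_logp_predictions",
    "pka_pairs_for_submission",
    "logp_pairs_for_submission",
    "logd_pairs_for_submissions",
]

METRIC_NAMES = ("rmse", "mae", "me", "r2", "slope", "kendall_tau")
#: constant-logP null baseline (mean cLogP of FDA-approved drug-like sets)
NULL_LOGP = 2.66

_ASCENDING_METRICS = ("rmse", "mae")  # lower is better
_DESCENDING_METRICS = ("r2", "kendall_tau")  # higher is better


@dataclass
class PairedObservations:
    """Aligned predicted/experimental value pairs for a set of molecules."""

    molecule_ids: list[str]
    predicted: np.ndarray
    experimental: np.ndarray
    predicted_sem: np.ndarray | None = None
    experimental_sem: np.ndarray | None = None

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.experimental = np.asarray(self.experimental, dtype=float)
        if not (
            len(self.molecule_ids) == self.predicted.size == self.experimental.size
        ):
            raise ValueError("molecule_ids, predicted and experimental lengths differ")

    def __len__(self) -> int:
        return self.predicted.size

    def subset(self, idx: np.ndarray) -> "PairedObservations":
        return PairedObservations(
            molecule_ids=[self.molecule_ids[i] for i in idx],
            predicted=self.predicted[idx],
            experimental=self.experimental[idx],
        )


@dataclass(frozen=True)
class BootstrapInterval:
    """Point estimate with a percentile bootstrap confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    n_skipped: int = 0


@dataclass
class MetricReport:
    """Per-method statistics: point estimate + CI for each of the six metrics."""

    method_name: str
    category: str
    metrics: dict[str, BootstrapInterval]
    n_molecules: int
    property_name: str = ""


@dataclass
class MatchResult:
    """Minimum-cost pairing of predicted with experimental pKa values."""

    pairs: list[tuple[float, float]]
    unmatched_predicted: list[float] = field(default_factory=list)
    unmatched_experimental: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# metrics


def _r2_slope(pred: np.ndarray, expt: np.ndarray) -> tuple[float, float]:
    if pred.size < 2 or np.var(pred) == 0.0 or np.var(expt) == 0.0:
        return math.nan, math.nan
    cov = np.cov(pred, expt, ddof=0)
    r = cov[0, 1] / math.sqrt(cov[0, 0] * cov[1, 1])
    slope = cov[0, 1] / cov[1, 1]  # OLS slope of predicted on experimental
    return r * r, slope


def _tau(pred: np.ndarray, expt: np.ndarray) -> float:
    if pred.size < 2 or np.unique(pred).size < 2 or np.unique(expt).size < 2:
        return math.nan
    return float(kendalltau(pred, expt, variant="b").statistic)


def compute_metrics(pairs: PairedObservations) -> dict[str, float]:
    """All six metrics at once; degenerate correlation metrics come back NaN."""
    err = pairs.predicted - pairs.experimental
    r2, slope = _r2_slope(pairs.predicted, pairs.experimental)
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "me": float(np.mean(err)),
        "r2": r2,
        "slope": slope,
        "kendall_tau": _tau(pairs.predicted, pairs.experimental),
    }


def coefficient_of_determination(pairs: PairedObservations, kind: str = "pearson") -> float:
    """R2 either as squared Pearson correlation (default, blind-challenge
    practice) or as the identity-line coefficient of determination
    1 - SS_res/SS_tot with residuals taken against experiment directly; the
    two agree only when predictions sit on the identity line."""
    pred, expt = pairs.predicted, pairs.experimental
    if kind == "pearson":
        return _r2_slope(pred, expt)[0]
    if kind == "regression":
        if np.var(expt) == 0.0:
            return math.nan
        ss_res = float(np.sum((pred - expt) ** 2))
        ss_tot = float(np.sum((expt - expt.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown R2 kind {kind!r}")


# ---------------------------------------------------------------------------
# bootstrap


def _metric_fn(metric: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if metric == "r2":
        return lambda p, e: _r2_slope(p, e)[0]
    if metric == "slope":
        return lambda p, e: _r2_slope(p, e)[1]
    if metric == "kendall_tau":
        return _tau
    raise KeyError(metric)


def _bootstrap_samples(
    pairs: PairedObservations,
    metric: str,
    idx: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Metric value for every resample row of ``idx``; error metrics are
    vectorized, correlation metrics are looped with degenerate resamples
    skipped (counted)."""
    pred, expt = pairs.predicted, pairs.experimental
    if metric in ("rmse", "mae", "me"):
        err = (pred - expt)[idx]
        if metric == "rmse":
            return np.sqrt(np.mean(err**2, axis=1)), 0
        if metric == "mae":
            return np.mean(np.abs(err), axis=1), 0
        return np.mean(err, axis=1), 0
    fn = _metric_fn(metric)
    vals = np.array([fn(pred[row], expt[row]) for row in idx])
    skipped = int(np.isnan(vals).sum())
    return vals[~np.isnan(vals)], skipped


def bootstrap_ci(
    pairs: PairedObservations,
    metric: str,
    n_samples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapInterval:
    """Percentile bootstrap-over-molecules confidence interval for one metric.

    Molecules are resampled with replacement ``n_samples`` times; the interval
    is the (1-level)/2 .. 1-(1-level)/2 percentile range of the resampled
    metric, widened if necessary to contain the full-data point estimate.
    Identical seeds give bit-identical output.
    """
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    if len(pairs) < 2:
        raise ValueError("bootstrap requires at least 2 molecules")
    point = compute_metrics(pairs)[metric]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pairs), size=(n_samples, len(pairs)))
    vals, skipped = _bootstrap_samples(pairs, metric, idx)
    if vals.size == 0:
        return BootstrapInterval(point, math.nan, math.nan, skipped)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    if math.isfinite(point):
        lo, hi = min(lo, point), max(hi, point)
    return BootstrapInterval(float(point), float(lo), float(hi), skipped)


def evaluate_method(
    pairs: PairedObservations,
    method_name: str,
    category: str = "",
    n_samples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    property_name: str = "",
) -> MetricReport:
    """Full :class:`MetricReport` for one method (shared resamples across metrics)."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pairs), size=(n_samples, len(pairs)))
    points = compute_metrics(pairs)
    alpha = (1.0 - level) / 2.0
    metrics: dict[str, BootstrapInterval] = {}
    for metric in METRIC_NAMES:
        vals, skipped = _bootstrap_samples(pairs, metric, idx)
        point = points[metric]
        if vals.size == 0 or not math.isfinite(point):
            metrics[metric] = BootstrapInterval(point, math.nan, math.nan, skipped)
            continue
        lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
        metrics[metric] = BootstrapInterval(
            float(point), float(min(lo, point)), float(max(hi, point)), skipped
        )
    return MetricReport(
        method_name=method_name,
        category=category,
        metrics=metrics,
        n_molecules=len(pairs),
        property_name=property_name,
    )


# ---------------------------------------------------------------------------
# pKa matching


def match_pkas(
    predicted: Sequence[float], experimental: Sequence[float]
) -> MatchResult:
    """Pair predicted with experimental macroscopic pKa values.

    Minimum-total-absolute-difference assignment (Hungarian algorithm);
    surplus values on either side are returned unmatched.  Pairs are ordered
    by experimental value.
    """
    pred = list(predicted)
    expt = list(experimental)
    if not pred or not expt:
        return MatchResult(pairs=[], unmatched_predicted=pred, unmatched_experimental=expt)
    cost = np.abs(np.subtract.outer(pred, expt))
    rows, cols = linear_sum_assignment(cost)
    pairs = sorted(
        ((pred[r], expt[c]) for r, c in zip(rows, cols)), key=lambda t: t[1]
    )
    return MatchResult(
        pairs=pairs,
        unmatched_predicted=[pred[i] for i in range(len(pred)) if i not in set(rows)],
        unmatched_experimental=[expt[j] for j in range(len(expt)) if j not in set(cols)],
    )


def match_pkas_bruteforce(
    predicted: Sequence[float], experimental: Sequence[float]
) -> float:
    """Minimum total |pred - exp| over all assignments, by enumeration.

    Independent oracle for :func:`match_pkas`; only sensible for small lists.
    """
    pred, expt = list(predicted), list(experimental)
    if not pred or not expt:
        return 0.0
    k = min(len(pred), len(expt))
    best = math.inf
    for p_sub in itertools.permutations(range(len(pred)), k):
        for e_sub in itertools.combinations(range(len(expt)), k):
            total = sum(abs(pred[i] - expt[j]) for i, j in zip(p_sub, e_sub))
            best = min(best, total)
    return best


# ---------------------------------------------------------------------------
# rankings and baselines


def consistent_shortlist(reports: Sequence[MetricReport], top_n: int) -> list[str]:
    """Methods in the top ``top_n`` simultaneously by RMSE, MAE, R2 and tau.

    RMSE/MAE rank ascending, R2/tau descending; ties at the boundary include
    every tied method.  The result is ordered by ascending RMSE.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    for r in reports:
        for m in _ASCENDING_METRICS + _DESCENDING_METRICS:
            if not math.isfinite(r.metrics[m].point):
                raise ValueError(f"{r.method_name}: metric {m} undefined")
    survivors = {r.method_name for r in reports}
    for m in _ASCENDING_METRICS:
        vals = sorted(r.metrics[m].point for r in reports)
        cut = vals[min(top_n, len(vals)) - 1]
        survivors &= {r.method_name for r in reports if r.metrics[m].point <= cut}
    for m in _DESCENDING_METRICS:
        vals = sorted((r.metrics[m].point for r in reports), reverse=True)
        cut = vals[min(top_n, len(vals)) - 1]
        survivors &= {r.method_name for r in reports if r.metrics[m].point >= cut}
    ordered = sorted(
        (r for r in reports if r.method_name in survivors),
        key=lambda r: r.metrics["rmse"].point,
    )
    return [r.method_name for r in ordered]


def per_molecule_mae(
    predictions_by_method: Mapping[str, Mapping[str, float]],
    experimental: Mapping[str, float],
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-molecule MAE averaged over methods, optionally stratified by category.

    ``predictions_by_method[method][molecule]`` holds one predicted value;
    molecules a method did not predict are simply excluded from that
    molecule's average, with counts reported.  Molecules with no predictions
    at all get NaN.  Returns a DataFrame indexed by molecule with columns
    ``mae``, ``n_methods`` and, when ``categories`` is given, ``mae (<cat>)``
    / ``n (<cat>)`` per category.
    """
    molecules = sorted(experimental)
    rows = []
    cats = sorted(set(categories.values())) if categories else []
    for mol in molecules:
        errs: dict[str, list[float]] = {c: [] for c in cats}
        all_errs: list[float] = []
        for method, preds in predictions_by_method.items():
            if mol not in preds:
                continue
            e = abs(preds[mol] - experimental[mol])
            all_errs.append(e)
            if categories:
                errs[categories[method]].append(e)
        row = {
            "molecule_id": mol,
            "mae": float(np.mean(all_errs)) if all_errs else math.nan,
            "n_methods": len(all_errs),
        }
        for c in cats:
            row[f"mae ({c})"] = float(np.mean(errs[c])) if errs[c] else math.nan
            row[f"n ({c})"] = len(errs[c])
        rows.append(row)
    return pd.DataFrame(rows).set_index("molecule_id")


def null_logp_predictions(molecule_ids: Iterable[str]) -> MethodSubmission:
    """Null baseline predicting a constant logP of 2.66 for every compound."""
    return MethodSubmission(
        method_name="NULL0",
        category="Empirical",
        ranked=False,
        predictions=[
            PartitionRecord(molecule_id=m, logp=NULL_LOGP) for m in molecule_ids
        ],
    )


# ---------------------------------------------------------------------------
# prediction/experiment pairing pipelines


def pka_pairs_for_submission(
    submission: MethodSubmission,
    experimental: Mapping[str, ExperimentalRecord],
    states_by_molecule: Mapping[str, Mapping[str, object]] | None = None,
    ctx: ThermoContext = ThermoContext(),
    window: tuple[float, float] = (-12.0, 20.0),
) -> tuple[PairedObservations, pd.DataFrame]:
    """Titrate a pKa submission and pair its macroscopic pKas with experiment.

    Each molecule's predicted dG0 network is titrated; the resulting
    crossings are matched to the experimental pKa list by minimum-cost
    assignment and each matched pair contributes one observation.  Unmatched
    values are tallied in the returned completeness table (they are misses,
    not penalized errors).
    """
    ids: list[str] = []
    pred: list[float] = []
    expt: list[float] = []
    completeness = []
    for mol, preds in sorted(submission.by_molecule().items()):
        rec = experimental.get(mol)
        if rec is None or not rec.pkas:
            continue
        states = states_by_molecule.get(mol) if states_by_molecule else None
        network = network_from_predictions(
            mol, preds[0].reference_id, preds, states=states
        )
        result = macroscopic_pkas_titration(network, ctx, window=window)
        match = match_pkas(result.pkas, rec.pkas)
        for p, e in match.pairs:
            ids.append(mol)
            pred.append(p)
            expt.append(e)
        completeness.append(
            {
                "molecule_id": mol,
                "n_matched": len(match.pairs),
                "n_unmatched_predicted": len(match.unmatched_predicted),
                "n_unmatched_experimental": len(match.unmatched_experimental),
            }
        )
    return (
        PairedObservations(ids, np.array(pred), np.array(expt)),
        pd.DataFrame(completeness),
    )


def logp_pairs_for_submission(
    submission: MethodSubmission,
    experimental: Mapping[str, ExperimentalRecord],
) -> PairedObservations:
    """Pair a partitioning submission's logP values with experiment."""
    ids, pred, expt = [], [], []
    for p in sorted(submission.predictions, key=lambda r: r.molecule_id):
        rec = experimental.get(p.molecule_id)
        if rec is None or rec.logp is None:
            continue
        ids.append(p.molecule_id)
        pred.append(p.logp)
        expt.append(rec.logp)
    return PairedObservations(ids, np.array(pred), np.array(expt))


def logd_pairs_for_submissions(
    logp_submission: MethodSubmission,
    pka_submission: MethodSubmission,
    experimental: Mapping[str, ExperimentalRecord],
    ph: float = 7.4,
    states_by_molecule: Mapping[str, Mapping[str, object]] | None = None,
    ctx: ThermoContext = ThermoContext(),
) -> PairedObservations:
    """Compose one logP submission with one pKa submission into logD estimates.

    Predicted logD(pH) = predicted logP + log10 of the neutral fraction of
    the pKa submission's dG0 network at that pH, paired against experimental
    logD values.
    """
    logp_by_mol = {p.molecule_id: p.logp for p in logp_submission.predictions}
    pka_by_mol = pka_submission.by_molecule()
    ids, pred, expt = [], [], []
    for mol in sorted(logp_by_mol):
        rec = experimental.get(mol)
        if rec is None or rec.logd is None or mol not in pka_by_mol:
            continue
        preds = pka_by_mol[mol]
        states = states_by_molecule.get(mol) if states_by_molecule else None
        network = network_from_predictions(
            mol, preds[0].reference_id, preds, states=states
        )
        ids.append(mol)
        pred.append(logd_from_network(logp_by_mol[mol], network, ph, ctx))
        expt.append(rec.logd)
    return PairedObservations(ids, np.array(pred), np.array(expt))
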