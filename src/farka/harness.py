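"""Cross-subject experiment drivers: M2S/S2S task plans, runs, and sweeps.

M2S (multi-source to single target) builds one leave-one-subject-out task
per subject, pooling the remaining subjects' aligned tangent features into a
single source field. S2S enumerates every ordered (source, target) pair.
Both enumerations are exhaustive and deterministic; the mean accuracy over
tasks is the evaluation metric. The only stochastic element in an experiment
is the data itself — alignment, tangent mapping, kernel adaptation, and the
SVM are all deterministic.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .alignment import EpochSet, estimate_covariances, align_subject
from .kka import KernelSpec
from .pipeline import FarkaParams, accuracy, fit, predict
from .spd import MeanSpec
from .synth import bandpass
from .tangent import TangentFeatures, tangent_map

__all__ = ["TaskPlan", "EvalReport", "plan_tasks", "subject_features", "run_plan", "sweep"]


@dataclass(frozen=True)
class TaskPlan:
    """An exhaustive cross-subject task enumeration."""

    mode: str
    subject_ids: tuple[str, ...]
    tasks: tuple[tuple[tuple[str, ...], str], ...]  # (source_ids, target_id)


@dataclass
class EvalReport:
    """Per-task accuracies and their mean, plus run metadata."""

    mode: str
    task_accuracies: dict  # "src->tgt" key -> accuracy (NaN on failure)
    mean_accuracy: float
    params: dict
    runtime_s: float
    warnings_: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "tasks": self.task_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "params": self.params,
            "runtime_s": self.runtime_s,
            "warnings": self.warnings_,
        }


def plan_tasks(subject_ids, mode: str) -> TaskPlan:
    """Enumerate all M2S (C tasks) or S2S (C*(C-1) ordered pairs) tasks."""
    ids = tuple(str(s) for s in subject_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if mode == "m2s":
        tasks = tuple(
            (tuple(s for s in ids if s != tgt), tgt) for tgt in ids
        )
    elif mode == "s2s":
        tasks = tuple(
            ((src,), tgt) for src, tgt in product(ids, ids) if src != tgt
        )
    else:
        raise ValueError("mode must be 'm2s' or 's2s'")
    return TaskPlan(mode=mode, subject_ids=ids, tasks=tasks)


def subject_features(
    e: EpochSet,
    align_space: str | None = "riemannian",
    band: tuple[float, float] | None = None,
    band_order: int = 50,
    shrinkage: float = 0.0,
) -> TangentFeatures:
    """Preprocess one subject: band-pass, covariances, alignment, tangent map.

    ``align_space=None`` skips alignment (the ablation variant); the tangent
    reference is the identity either way so the two variants differ only in
    the whitening step.
    """
    if band is not None:
        e = bandpass(e, band[0], band[1], order=band_order)
    covs = estimate_covariances(e, shrinkage=shrinkage)
    if align_space is not None:
        covs = align_subject(covs, MeanSpec(space=align_space))
        return tangent_map(covs, reference="identity")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return tangent_map(covs, reference="identity")


def _pool(features: list[TangentFeatures]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([f.vectors for f in features])
    y = np.concatenate([f.labels for f in features])
    return X, y


def run_plan(
    data: list[EpochSet],
    plan: TaskPlan,
    params: FarkaParams | None = None,
    align_space: str | None = "riemannian",
    band: tuple[float, float] | None = None,
    band_order: int = 50,
    shrinkage: float = 0.0,
) -> EvalReport:
    """Run every task in the plan and aggregate the accuracies.

    Per-subject preprocessing is computed once and shared across tasks (a
    subject's alignment does not depend on which task it appears in). A task
    that raises is recorded as a warning with NaN accuracy and the run
    continues.
    """
    params = params or FarkaParams()
    t0 = time.perf_counter()
    by_id = {e.subject_id: e for e in data}
    missing = [s for s in plan.subject_ids if s not in by_id]
    if missing:
        raise ValueError(f"plan subjects missing from data: {missing}")
    feats = {
        sid: subject_features(by_id[sid], align_space, band, band_order, shrinkage)
        for sid in plan.subject_ids
    }
    task_acc: dict[str, float] = {}
    notes: list[str] = []
    for source_ids, target_id in plan.tasks:
        key = f"{'+'.join(source_ids)}->{target_id}"
        try:
            X_s, y_s = _pool([feats[s] for s in source_ids])
            tgt = feats[target_id]
            model = fit(X_s, tgt.vectors, params, source_labels=y_s)
            task_acc[key] = accuracy(predict(model), tgt.labels)
        except Exception as err:  # record and continue
            task_acc[key] = float("nan")
            notes.append(f"task {key} failed: {err}")
    vals = [v for v in task_acc.values() if not math.isnan(v)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return EvalReport(
        mode=plan.mode,
        task_accuracies=task_acc,
        mean_accuracy=mean,
        params={
            "kernel": params.kernel.family,
            "gamma": params.kernel.gamma,
            "mu": params.mu,
            "eta": params.eta,
            "train_on": params.train_on,
            "align_space": align_space,
            "band": list(band) if band else None,
            "shrinkage": shrinkage,
        },
        runtime_s=time.perf_counter() - t0,
        warnings_=notes,
    )


def sweep(
    data: list[EpochSet],
    plan: TaskPlan,
    grid: dict,
    base_params: FarkaParams | None = None,
    **run_kwargs,
) -> list[tuple[dict, EvalReport]]:
    """Cartesian-product hyperparameter sweep.

    ``grid`` maps any of ``mu``, ``eta``, ``kernel`` (family name) to a list
    of values; returns ``(point, report)`` pairs in deterministic order.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    allowed = {"mu", "eta", "kernel"}
    bad = set(grid) - allowed
    if bad:
        raise ValueError(f"unknown sweep parameters: {sorted(bad)}")
    base = base_params or FarkaParams()
    keys = sorted(grid)
    results = []
    for combo in product(*(grid[k] for k in keys)):
        point = dict(zip(keys, combo))
        kernel = (
            KernelSpec(point["kernel"], base.kernel.gamma)
            if "kernel" in point
            else base.kernel
        )
        params = FarkaParams(
            kernel=kernel,
            mu=point.get("mu", base.mu),
            eta=point.get("eta", base.eta),
            r_max=base.r_max,
            train_on=base.train_on,
        )
        results.append((point, run_plan(data, plan, params, **run_kwargs)))
    return results
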