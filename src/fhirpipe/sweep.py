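"""Local, seeded hyperparameter and resource-ablation sweeps.

A sweep searches over FHIR resource-inclusion flags and training
hyperparameters, minimizing validation loss with a run budget (seeded
random search; a hosted Bayesian service is deliberately replaced by a
dependency-free local driver with the same search-space semantics). Each
run re-serializes the prepared samples under its flag configuration,
trains the required backend, and records validation loss and metrics.

Afterwards, :func:`importance_correlation` quantifies each parameter's
contribution to the target metric: Pearson correlation (booleans as 0/1)
across runs, and permutation importance of a random-forest surrogate fit
on configs -> metric, normalized to sum 1.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .modeling import BackendSpec, MetricsReport
from .pipeline import PreparedData, fit_and_score, materialize
from .serialization import PipelineConfig

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SweepRun:
    run_id: int
    config: dict  # flat: resource flags (bool) + hyperparameters (float)
    val_loss: float
    val_metrics: MetricsReport
    seed: int
    error: Optional[str] = None


@dataclasses.dataclass
class SweepResult:
    runs: list[SweepRun]
    best: SweepRun


def _sample_config(space: dict, rng: np.random.Generator) -> dict:
    """Draw one flat configuration from the declared search space.

    Space entries are either lists of choices or {"min","max"[,"log"]}
    ranges for continuous hyperparameters.
    """
    config: dict = {}
    for name, spec in space.items():
        if isinstance(spec, (list, tuple)):
            config[name] = spec[int(rng.integers(0, len(spec)))]
        elif isinstance(spec, dict) and "min" in spec and "max" in spec:
            lo, hi = float(spec["min"]), float(spec["max"])
            if spec.get("log"):
                value = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                value = float(rng.uniform(lo, hi))
            config[name] = value
        else:
            raise ValueError(f"invalid search-space entry for {name!r}: {spec!r}")
    return config


def _split_flat_config(flat: dict) -> tuple[dict, dict]:
    """Separate resource flags ('include_<Type>') from hyperparameters."""
    flags, hyper = {}, {}
    for key, value in flat.items():
        if key.startswith("include_"):
            flags[key[len("include_"):]] = bool(value)
        else:
            hyper[key] = value
    return flags, hyper


def run_sweep(
    space: dict,
    budget: int,
    prepared: PreparedData,
    base_config: PipelineConfig,
    seed: int = 0,
    max_samples: int = 100_000,
    k: int = 10,
) -> SweepResult:
    """Execute ``budget`` seeded random-search runs and return the best.

    Best = argmin validation loss, ties broken by higher validation F1 and
    then lower run_id. ``max_samples`` caps the per-run training subsample.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("search space must be non-empty")
    rng = np.random.default_rng(seed)
    runs: list[SweepRun] = []
    for run_id in range(budget):
        flat = _sample_config(space, rng)
        flags, hyper = _split_flat_config(flat)
        include = dict(base_config.include_resources)
        include.update(flags)
        try:
            config = dataclasses.replace(base_config, include_resources=include)
            samples = materialize(prepared, config)
            train_samples = [s for s in samples if s.split == "train"]
            if len(train_samples) > max_samples:
                keep_ids = set(
                    rng.choice(len(train_samples), size=max_samples,
                               replace=False).tolist())
                capped = [s for i, s in enumerate(train_samples) if i in keep_ids]
                samples = capped + [s for s in samples if s.split != "train"]
            backend = BackendSpec(hyperparams={**hyper}, seed=seed)
            fit = fit_and_score(samples, prepared.kind, prepared.label_space,
                                backend, k=k, eval_splits=("val",))
            val = fit.reports["val"]
            loss = val.loss if val.loss is not None else float("inf")
            runs.append(SweepRun(run_id, flat, float(loss), val, seed))
        except Exception as exc:  # noqa: BLE001 - per-run failures are data
            logger.warning("sweep run %d failed: %s", run_id, exc)
            runs.append(SweepRun(run_id, flat, float("inf"),
                                 MetricsReport(accuracy=0.0), seed, str(exc)))
    return SweepResult(runs=runs, best=select_best(runs))


def select_best(runs: Sequence[SweepRun]) -> SweepRun:
    """argmin val_loss; ties broken by higher val F1, then lower run_id."""
    successful = [r for r in runs if r.error is None]
    if not successful:
        causes = {r.run_id: r.error for r in runs}
        raise RuntimeError(f"all sweep runs failed: {causes}")

    def sort_key(run: SweepRun):
        f1 = run.val_metrics.f1
        if f1 is None:
            f1 = run.val_metrics.macro_f1 or 0.0
        return (run.val_loss, -f1, run.run_id)

    return min(successful, key=sort_key)


@dataclasses.dataclass
class ImportanceReport:
    importance: dict[str, float]       # non-negative, sums to 1
    correlation: dict[str, float]      # Pearson, in [-1, 1]
    constant_parameters: list[str]     # correlation undefined, reported as 0

    def ranked(self) -> list[str]:
        """Parameter names by descending importance (ties alphabetical)."""
        return [name for name, _ in sorted(self.importance.items(),
                                           key=lambda kv: (-kv[1], kv[0]))]


def importance_correlation(
    runs: Sequence[SweepRun],
    target: str = "val_loss",
    seed: int = 0,
    n_repeats: int = 10,
) -> ImportanceReport:
    """Per-parameter Pearson correlation with the target metric and
    permutation importance of a tree-ensemble surrogate, across runs."""
    usable = [r for r in runs if r.error is None]
    if len(usable) < 2:
        raise ValueError("need at least 2 successful runs with varying configs")
    names = sorted({key for r in usable for key in r.config})

    def target_value(run: SweepRun) -> float:
        if target == "val_loss":
            return run.val_loss
        value = getattr(run.val_metrics, target)
        return float(value) if value is not None else float("nan")

    X = np.array([[float(r.config.get(name, 0.0)) for name in names]
                  for r in usable])
    y = np.array([target_value(r) for r in usable])

    correlations: dict[str, float] = {}
    constants: list[str] = []
    for j, name in enumerate(names):
        col = X[:, j]
        if np.std(col) == 0 or np.std(y) == 0:
            correlations[name] = 0.0
            if np.std(col) == 0:
                constants.append(name)
            continue
        r = float(np.corrcoef(col, y)[0, 1])
        correlations[name] = max(-1.0, min(1.0, r))

    forest = RandomForestRegressor(n_estimators=200, random_state=seed)
    forest.fit(X, y)
    perm = permutation_importance(forest, X, y, n_repeats=n_repeats,
                                  random_state=seed)
    raw = np.clip(perm.importances_mean, 0.0, None)
    total = raw.sum()
    if total > 0:
        normalized = raw / total
    else:  # no parameter moves the target: flat importance by convention
        normalized = np.full(len(names), 1.0 / len(names))
    importance = {name: float(v) for name, v in zip(names, normalized)}
    return ImportanceReport(importance=importance, correlation=correlations,
                            constant_parameters=constants)
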