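"""Study/trial machinery: hyperparameter search scored by k-fold cross validation.

A *trial* is one hyperparameter configuration scored by the mean
validation pixel deviation over k folds; a *study* is a collection of
trials from which a single final model is derived by retraining on the
full dataset with the best trial's hyperparameters.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Tuple, Union

import numpy as np

from finmark.annotations import LandmarkDataset
from finmark.shape_model import (
    Hyperparameters,
    PredictorModel,
    mean_deviation,
    train_predictor,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParamRange",
    "SearchRanges",
    "DEFAULT_RANGES",
    "TrialRecord",
    "StudyResult",
    "kfold_split",
    "fold_seed",
    "run_trial",
    "run_study",
    "finalize_model",
    "deviation_cdf",
    "EmpiricalCDF",
]


@dataclass(frozen=True)
class ParamRange:
    """Closed search interval for one hyperparameter."""

    low: float
    high: float
    scale: Literal["linear", "log"] = "linear"
    integer: bool = False

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"low {self.low} > high {self.high}")
        if self.scale == "log" and self.low <= 0:
            raise ValueError("log-scale range requires low > 0")

    def sample(self, rng: np.random.Generator) -> Union[int, float]:
        if self.integer:
            return int(rng.integers(int(self.low), int(self.high) + 1))
        if self.scale == "log":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass(frozen=True)
class SearchRanges:
    """Per-parameter bounds for the nine predictor hyperparameters."""

    cascade_depth: ParamRange = ParamRange(8, 18, integer=True)
    tree_depth: ParamRange = ParamRange(2, 5, integer=True)
    trees_per_cascade: ParamRange = ParamRange(250, 750, integer=True)
    learning_rate: ParamRange = ParamRange(0.01, 0.3, scale="log")
    oversampling: ParamRange = ParamRange(5, 40, integer=True)
    feature_pool_size: ParamRange = ParamRange(200, 1000, integer=True)
    test_splits: ParamRange = ParamRange(20, 150, integer=True)
    feature_pool_padding: ParamRange = ParamRange(0.0, 0.2)
    regularization: ParamRange = ParamRange(0.01, 0.2, scale="log")

    def field_names(self) -> Tuple[str, ...]:
        return tuple(self.__dataclass_fields__)

    def sample(self, rng: np.random.Generator) -> Hyperparameters:
        return Hyperparameters(
            **{name: getattr(self, name).sample(rng) for name in self.field_names()}
        )

    def contains(self, hp: Hyperparameters) -> bool:
        return all(
            getattr(self, name).contains(getattr(hp, name)) for name in self.field_names()
        )

    def to_dict(self) -> dict:
        return {
            name: {
                "low": r.low,
                "high": r.high,
                "scale": r.scale,
                "integer": r.integer,
            }
            for name in self.field_names()
            for r in [getattr(self, name)]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SearchRanges":
        return cls(**{name: ParamRange(**bounds) for name, bounds in d.items()})


DEFAULT_RANGES = SearchRanges()


@dataclass
class TrialRecord:
    """One hyperparameter evaluation: configuration + per-fold scores."""

    trial_index: int
    hyperparameters: Hyperparameters
    fold_deviations: List[float]
    mean_deviation: float
    error: Optional[str] = None

    @property
    def failed(self) -> bool:
        return not math.isfinite(self.mean_deviation)

    def to_dict(self) -> dict:
        return {
            "trial_index": self.trial_index,
            "hyperparameters": self.hyperparameters.to_dict(),
            "fold_deviations": list(self.fold_deviations),
            "mean_deviation": self.mean_deviation,
            "error": self.error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(
            trial_index=d["trial_index"],
            hyperparameters=Hyperparameters.from_dict(d["hyperparameters"]),
            fold_deviations=list(d["fold_deviations"]),
            mean_deviation=d["mean_deviation"],
            error=d.get("error"),
        )


@dataclass
class StudyResult:
    trials: List[TrialRecord]
    k: int
    seed: int
    ranges: SearchRanges
    sampler: str = "random"

    @property
    def best_index(self) -> int:
        """Index of the best trial (lowest mean deviation; ties break to the
        lowest trial index)."""
        best = min(
            range(len(self.trials)), key=lambda i: (self.trials[i].mean_deviation, i)
        )
        if not math.isfinite(self.trials[best].mean_deviation):
            raise ValueError("all trials failed")
        return best

    @property
    def best_trial(self) -> TrialRecord:
        return self.trials[self.best_index]

    def running_minimum(self) -> List[float]:
        out: List[float] = []
        cur = math.inf
        for t in self.trials:
            cur = min(cur, t.mean_deviation)
            out.append(cur)
        return out

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "sampler": self.sampler,
            "ranges": self.ranges.to_dict(),
            "trials": [t.to_dict() for t in self.trials],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "StudyResult":
        d = json.loads(Path(path).read_text())
        return cls(
            trials=[TrialRecord.from_dict(t) for t in d["trials"]],
            k=d["k"],
            seed=d["seed"],
            ranges=SearchRanges.from_dict(d["ranges"]),
            sampler=d.get("sampler", "random"),
        )


def kfold_split(
    dataset: LandmarkDataset, k: int, seed: int
) -> List[Tuple[LandmarkDataset, LandmarkDataset]]:
    """Shuffle and partition into k (train, validation) pairs.

    Validation folds are pairwise disjoint, cover the whole dataset, and
    differ in size by at most one image. Deterministic given ``seed``.
    """
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    pairs = []
    for i in range(k):
        val_idx = folds[i]
        train_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        pairs.append((dataset.subset(train_idx.tolist()), dataset.subset(val_idx.tolist())))
    return pairs


def fold_seed(seed: int, trial_index: int, fold: int) -> int:
    """Deterministic per-fold training seed derivation (documented so that
    external re-runs can reproduce a trial exactly)."""
    return int(np.random.SeedSequence([seed, trial_index, fold]).generate_state(1)[0])


def run_trial(
    dataset: LandmarkDataset,
    hp: Hyperparameters,
    k: int,
    seed: int,
    trial_index: int = 0,
    image_root: Optional[Union[str, Path]] = None,
) -> TrialRecord:
    """Score one configuration by k-fold cross validation.

    A training failure on any fold marks the whole trial failed with an
    infinite score; the study continues.
    """
    pairs = kfold_split(dataset, k, seed)
    fold_devs: List[float] = []
    try:
        for fold, (train, val) in enumerate(pairs):
            model = train_predictor(train, hp, fold_seed(seed, trial_index, fold),
                                    image_root=image_root)
            fold_devs.append(mean_deviation(model, val, image_root=image_root))
    except Exception as exc:  # noqa: BLE001 - any per-fold failure fails the trial
        logger.warning("trial %d failed: %s", trial_index, exc)
        return TrialRecord(trial_index, hp, fold_devs, math.inf, error=str(exc))
    return TrialRecord(trial_index, hp, fold_devs, float(np.mean(fold_devs)))


def _adaptive_candidate(
    ranges: SearchRanges,
    best_hp: Hyperparameters,
    rng: np.random.Generator,
    mutation_rate: float = 0.4,
) -> Hyperparameters:
    """Local search around the incumbent: each parameter is resampled from
    its full range with probability ``mutation_rate``, otherwise kept."""
    values = {}
    for name in ranges.field_names():
        if rng.random() < mutation_rate:
            values[name] = getattr(ranges, name).sample(rng)
        else:
            values[name] = getattr(best_hp, name)
    return Hyperparameters(**values)


def run_study(
    dataset: LandmarkDataset,
    n_trials: int,
    ranges: SearchRanges = DEFAULT_RANGES,
    k: int = 5,
    seed: int = 0,
    sampler: Literal["random", "adaptive"] = "random",
    image_root: Optional[Union[str, Path]] = None,
) -> StudyResult:
    """Run ``n_trials`` hyperparameter evaluations and collect the records.

    ``sampler="random"`` draws every configuration independently and the
    full trial sequence is reproducible from ``seed``. ``"adaptive"``
    warms up with random draws, then alternates exploration with local
    mutations of the best configuration so far.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    warmup = max(3, n_trials // 3)
    trials: List[TrialRecord] = []
    for t in range(n_trials):
        if sampler == "random" or t < warmup:
            hp = ranges.sample(rng)
        elif sampler == "adaptive":
            finite = [tr for tr in trials if not tr.failed]
            if finite and rng.random() >= 0.25:
                incumbent = min(finite, key=lambda tr: (tr.mean_deviation, tr.trial_index))
                hp = _adaptive_candidate(ranges, incumbent.hyperparameters, rng)
            else:
                hp = ranges.sample(rng)
        else:
            raise ValueError(f"unknown sampler '{sampler}'")
        record = run_trial(dataset, hp, k, seed, trial_index=t, image_root=image_root)
        logger.info("trial %d: mean fold deviation %.3f px", t, record.mean_deviation)
        trials.append(record)
    result = StudyResult(trials=trials, k=k, seed=seed, ranges=ranges, sampler=sampler)
    result.best_index  # raises if every trial failed
    return result


def finalize_model(
    dataset: LandmarkDataset,
    study: StudyResult,
    seed: int,
    image_root: Optional[Union[str, Path]] = None,
) -> PredictorModel:
    """Retrain one model on the full dataset with the best trial's
    hyperparameters; the model's provenance records the study."""
    best = study.best_trial
    model = train_predictor(dataset, best.hyperparameters, seed, image_root=image_root)
    model.provenance = {
        "study_seed": study.seed,
        "n_trials": len(study.trials),
        "k": study.k,
        "sampler": study.sampler,
        "best_trial_index": best.trial_index,
        "best_cv_deviation_px": best.mean_deviation,
    }
    return model


@dataclass
class EmpiricalCDF:
    """Right-continuous empirical CDF over percent-of-diagonal deviations."""

    values: np.ndarray  # sorted ascending

    def __call__(self, x: float) -> float:
        return float(np.searchsorted(self.values, x, side="right")) / len(self.values)


def deviation_cdf(trials: Sequence[TrialRecord], normalizer: float) -> EmpiricalCDF:
    """Empirical CDF of trial scores expressed as % of the image diagonal.

    Failed (infinite-score) trials are excluded; raises if none succeeded.
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    scores = [100.0 * t.mean_deviation / normalizer for t in trials if not t.failed]
    if not scores:
        raise ValueError("no successful trials")
    return EmpiricalCDF(values=np.sort(np.asarray(scores)))
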