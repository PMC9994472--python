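"""Validation battery: shuffle-split cross-validation, CV-based function
selection, Rand index, and per-group accuracy.

Prediction quality is scored per test sample as the coefficient of
determination R² between the genome's real gene-content profile and the
profile predicted from its amplicon, then summarized as the *median* R² over
the predicted samples of an epoch (and pooled across epochs).  Samples with
no neighbor inside the ε neighborhood receive no prediction; they are
excluded from the R² median and accounted for separately as the percentage
of predicted samples — quality and coverage are deliberately reported as two
numbers, because lowering ε trades coverage for quality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DatabaseError,
    InvalidParameterError,
    UndefinedCVError,
    UndefinedRSquaredError,
)
from .predict import (
    DEFAULT_EPS,
    DEFAULT_K_NEIGHBORS,
    predict_profile,
    select_neighbors,
)
from .refdb import ReferenceDatabase

DEFAULT_TEST_FRACTION = 0.2
DEFAULT_EPOCHS = 10
DEFAULT_SEED = 42
DEFAULT_CV_THRESHOLD = 10.0


def test_set_size(n_genomes: int, test_fraction: float = DEFAULT_TEST_FRACTION) -> int:
    """Number of test samples per shuffle epoch: ``floor(test_fraction * N)``."""
    if not (0.0 < test_fraction < 1.0):
        raise InvalidParameterError(f"test_fraction must be in (0, 1), got {test_fraction}")
    return math.floor(test_fraction * n_genomes)


def r_squared(actual, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    ``SS_tot`` is the total sum of squares of ``actual`` around its own mean.
    May be negative when the prediction is worse than the constant-mean model.
    Undefined (raises) when ``actual`` is constant.
    """
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape:
        raise InvalidParameterError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size < 2:
        raise InvalidParameterError("need at least 2 components for R^2")
    ss_tot = float(((a - a.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedRSquaredError("actual vector is constant; R^2 undefined")
    ss_res = float(((a - p) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class EpochResult:
    epoch: int
    n_test: int
    n_predicted: int
    percent_predicted: float
    median_r2: float | None  # None when nothing was predicted


@dataclass
class ValidationReport:
    """Per-epoch and pooled results of shuffle-split cross-validation."""

    epochs: int
    test_fraction: float
    K: int
    eps: float
    seed: int
    per_epoch: list[EpochResult]
    pooled_r2: list[float] = field(repr=False, default_factory=list)

    @property
    def overall_median_r2(self) -> float | None:
        """Median of per-sample R² pooled across all epochs."""
        if not self.pooled_r2:
            return None
        return float(np.median(self.pooled_r2))

    @property
    def overall_percent_predicted(self) -> float:
        n_test = sum(e.n_test for e in self.per_epoch)
        n_pred = sum(e.n_predicted for e in self.per_epoch)
        return 100.0 * n_pred / n_test if n_test else 0.0

    def epoch_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "epoch": e.epoch,
                    "n_test": e.n_test,
                    "n_predicted": e.n_predicted,
                    "percent_predicted": e.percent_predicted,
                    "median_r2": e.median_r2,
                }
                for e in self.per_epoch
            ]
        )

    def summary(self) -> dict:
        return {
            "epochs": self.epochs,
            "test_fraction": self.test_fraction,
            "K": self.K,
            "eps": self.eps,
            "seed": self.seed,
            "overall_median_r2": self.overall_median_r2,
            "overall_percent_predicted": self.overall_percent_predicted,
            "per_epoch_median_r2": [e.median_r2 for e in self.per_epoch],
            "per_epoch_percent_predicted": [e.percent_predicted for e in self.per_epoch],
        }

    def save(self, tsv_path, json_path) -> None:
        self.epoch_table().to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


def _score_test_samples(db, train_db, test_ids, K, eps, function_indices):
    """Predict each held-out genome against the training RAVs; return per-sample R²."""
    rav_by_id = {r.genome_id: r for r in db.ravs}
    r2s = {}
    for gid in test_ids:
        rav = rav_by_id[gid]
        neighbors = select_neighbors(rav.kvector, train_db, K=K, eps=eps, query_id=gid)
        pred = predict_profile(neighbors, train_db)
        if not pred.is_predicted:
            r2s[gid] = None
            continue
        actual = db.profiles[gid]
        predicted = pred.predicted
        if function_indices is not None:
            actual = actual[function_indices]
            predicted = predicted[function_indices]
        r2s[gid] = r_squared(actual, predicted)
    return r2s


def shuffle_split_validate(
    db: ReferenceDatabase,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    epochs: int = DEFAULT_EPOCHS,
    K: int = DEFAULT_K_NEIGHBORS,
    eps: float = DEFAULT_EPS,
    seed: int = DEFAULT_SEED,
    function_indices=None,
) -> ValidationReport:
    """Repeated random 80/20 train/test splits with per-epoch median R².

    Each epoch draws ``floor(test_fraction * N)`` test genomes uniformly
    without replacement (seeded); every test genome's profile is predicted
    from the remaining training RAVs only.  ``function_indices`` optionally
    restricts the R² computation to a subset of the catalog (e.g. the highly
    variable functions).
    """
    n = len(db)
    if n < 5:
        raise InvalidParameterError(f"database too small for shuffle-split: {n} < 5")
    n_test = test_set_size(n, test_fraction)
    if n_test < 1:
        raise InvalidParameterError(
            f"test set would be empty: floor({test_fraction} * {n}) = 0"
        )
    if epochs < 1:
        raise InvalidParameterError(f"epochs must be >= 1, got {epochs}")
    if function_indices is not None:
        function_indices = np.asarray(function_indices, dtype=np.intp)

    rng = np.random.default_rng(seed)
    ids = db.genome_ids
    per_epoch = []
    pooled = []
    for epoch in range(epochs):
        test_idx = rng.choice(n, size=n_test, replace=False)
        test_ids = [ids[i] for i in sorted(test_idx)]
        train_db = db.subset(set(ids) - set(test_ids))
        r2s = _score_test_samples(db, train_db, test_ids, K, eps, function_indices)
        predicted = [v for v in r2s.values() if v is not None]
        pooled.extend(predicted)
        per_epoch.append(
            EpochResult(
                epoch=epoch,
                n_test=n_test,
                n_predicted=len(predicted),
                percent_predicted=100.0 * len(predicted) / n_test,
                median_r2=float(np.median(predicted)) if predicted else None,
            )
        )
    return ValidationReport(epochs, test_fraction, K, eps, seed, per_epoch, pooled)


def epsilon_sweep(
    db: ReferenceDatabase,
    eps_grid,
    K: int = DEFAULT_K_NEIGHBORS,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = DEFAULT_SEED,
    function_indices=None,
) -> pd.DataFrame:
    """Run shuffle-split validation at each ε of an ascending grid.

    The same seed is reused for every ε, so all grid points see identical
    train/test splits and differ only in the neighborhood radius; as a
    consequence percent_predicted is non-decreasing in ε.
    """
    eps_grid = list(eps_grid)
    if not eps_grid:
        raise InvalidParameterError("eps_grid must be non-empty")
    if any(b <= a for a, b in zip(eps_grid, eps_grid[1:])):
        raise InvalidParameterError("eps_grid must be strictly ascending")
    rows = []
    for eps in eps_grid:
        report = shuffle_split_validate(
            db, test_fraction=test_fraction, epochs=epochs, K=K, eps=eps,
            seed=seed, function_indices=function_indices,
        )
        rows.append(
            {
                "eps": eps,
                "median_r2": report.overall_median_r2,
                "percent_predicted": report.overall_percent_predicted,
            }
        )
    return pd.DataFrame(rows)


def coefficient_of_variation(db: ReferenceDatabase, function_index: int) -> float:
    """Sample standard deviation of a function's fraction across genomes, over its mean."""
    values = db.profile_matrix()[:, function_index]
    if values.size < 2:
        raise UndefinedCVError("CV needs at least 2 genomes")
    mean = float(values.mean())
    if mean <= 0:
        raise UndefinedCVError(f"function index {function_index} has zero mean across genomes")
    sd = float(values.std(ddof=1))
    return sd / mean


def select_variable_functions(
    db: ReferenceDatabase, threshold: float = DEFAULT_CV_THRESHOLD
) -> list[int]:
    """Indices of functions whose CV is strictly greater than ``threshold``.

    Functions with undefined CV (zero mean) are carried as non-variable.  The
    default threshold of 10 on the sd/mean ratio scale is extreme and mostly
    selects rare, patchily distributed functions.
    """
    selected = []
    for j in range(len(db.catalog)):
        try:
            cv = coefficient_of_variation(db, j)
        except UndefinedCVError:
            continue
        if cv > threshold:
            selected.append(j)
    return selected


def rand_index(partition_a, partition_b) -> float:
    """Plain (unadjusted) Rand index between two labelings of the same items.

    The fraction of item pairs on which the partitions agree: co-clustered in
    both or separated in both.  Computed by the pairwise definition;
    invariant to relabeling of cluster IDs.
    """
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError(f"partitions must be equal-length 1-D, got {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise InvalidParameterError("need at least 2 items")
    iu = np.triu_indices(n, k=1)
    same_a = (a[:, None] == a[None, :])[iu]
    same_b = (b[:, None] == b[None, :])[iu]
    return float((same_a == same_b).sum() / same_a.size)


def leave_one_out_scores(
    db: ReferenceDatabase,
    K: int = DEFAULT_K_NEIGHBORS,
    eps: float = DEFAULT_EPS,
    function_indices=None,
) -> dict[str, float | None]:
    """Per-genome R² with the genome's own RAV removed from the search space.

    Returns a mapping genome_id -> R², or None when the genome had no
    neighbor within ε.
    """
    if function_indices is not None:
        function_indices = np.asarray(function_indices, dtype=np.intp)
    scores: dict[str, float | None] = {}
    for rav in db.ravs:
        train_db = db.without(rav.genome_id)
        neighbors = select_neighbors(rav.kvector, train_db, K=K, eps=eps, query_id=rav.genome_id)
        pred = predict_profile(neighbors, train_db)
        if not pred.is_predicted:
            scores[rav.genome_id] = None
            continue
        actual = db.profiles[rav.genome_id]
        predicted = pred.predicted
        if function_indices is not None:
            actual = actual[function_indices]
            predicted = predicted[function_indices]
        scores[rav.genome_id] = r_squared(actual, predicted)
    return scores


def groupwise_accuracy(
    db: ReferenceDatabase,
    group_labels: dict[str, str],
    K: int = DEFAULT_K_NEIGHBORS,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Leave-one-out accuracy broken down by a user-supplied grouping.

    ``group_labels`` maps every genome ID to a group (e.g. a fungal family).
    Returns one row per group: group, n, median_r2 (NaN when no member of
    the group was predicted).
    """
    unknown = set(group_labels) - set(db.profiles)
    if unknown:
        raise DatabaseError(f"group labels refer to unknown genome IDs: {sorted(unknown)}")
    missing = set(db.profiles) - set(group_labels)
    if missing:
        raise DatabaseError(f"group labels missing for genomes: {sorted(missing)}")

    scores = leave_one_out_scores(db, K=K, eps=eps)
    rows = []
    groups = sorted(set(group_labels.values()))
    for group in groups:
        members = [g for g in db.genome_ids if group_labels[g] == group]
        member_scores = [scores[g] for g in members if scores[g] is not None]
        rows.append(
            {
                "group": group,
                "n": len(members),
                "median_r2": float(np.median(member_scores)) if member_scores else np.nan,
            }
        )
    return pd.DataFrame(rows)


def read_group_labels(path) -> dict[str, str]:
    """Read a two-column TSV (genome_id, group) into a mapping."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["genome_id", "group"], dtype=str)
    return dict(zip(frame["genome_id"], frame["group"]))
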