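"""The core prediction algorithm: ε-bounded K-nearest-neighbor profile averaging.

A query ITS sequence is turned into a k-mer frequency vector and compared to
every reference amplicon variant (RAV) by cosine distance
``1 - u.v / (|u||v|)``, which lies in [0, 1] for non-negative vectors.
Neighbor selection then follows five mutually exclusive cases:

* ``ZERO_DISTANCE_OVERRIDE`` — at least one RAV has distance 0 (identical
  k-mer vector); *all* zero-distance RAVs are used and nothing else,
  regardless of K and ε.
* ``FEWER_THAN_K`` / ``EXACTLY_K`` — the ε neighborhood holds fewer than /
  exactly K RAVs; all of them are used.
* ``TRUNCATED_TO_K`` — more than K RAVs lie within ε; the K closest are kept
  (distance ties broken by ascending genome ID, so output is deterministic).
* ``EMPTY`` — no RAV within ε; no prediction is made.  Raising ε is the
  user-facing remedy.

The predicted profile is the unweighted arithmetic mean of the selected
neighbors' profiles; since each profile sums to 1, so does the prediction.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    DegenerateVectorError,
    EmptyDatabaseError,
    FastaParseError,
    IntegrityError,
    InvalidParameterError,
    ItsfuncError,
)
from .kmers import KmerVector, count_kmers
from .refdb import ReferenceDatabase

logger = logging.getLogger(__name__)

DEFAULT_K_NEIGHBORS = 10
DEFAULT_EPS = 0.5

#: Cosine distances at or below this are treated as mathematically zero.
ZERO_DISTANCE_TOL = 1e-12


class SelectionCase(str, Enum):
    FEWER_THAN_K = "FEWER_THAN_K"
    EXACTLY_K = "EXACTLY_K"
    TRUNCATED_TO_K = "TRUNCATED_TO_K"
    ZERO_DISTANCE_OVERRIDE = "ZERO_DISTANCE_OVERRIDE"
    EMPTY = "EMPTY"


@dataclass(frozen=True)
class NeighborSet:
    """Neighbors selected for one query, with the selection case that applied."""

    query_id: str
    entries: tuple  # of (genome_id, distance), sorted ascending by (distance, genome_id)
    selection_case: SelectionCase

    @property
    def k_chosen(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Prediction:
    """Predicted profile for one query; ``predicted is None`` iff no neighbors.

    ``error`` is set (and ``neighbor_set`` is None) when the query itself was
    invalid, e.g. shorter than k — distinct from the no-neighbor outcome.
    """

    query_id: str
    predicted: np.ndarray | None
    neighbor_set: NeighborSet | None
    error: str | None = None

    @property
    def is_predicted(self) -> bool:
        return self.predicted is not None


def cosine_distance(u: KmerVector, v: KmerVector) -> float:
    """Cosine distance between two k-mer vectors of the same k."""
    if u.k != v.k:
        raise InvalidParameterError(f"k mismatch: {u.k} vs {v.k}")
    if u.valid_window_count == 0 or v.valid_window_count == 0:
        raise DegenerateVectorError("cannot compute cosine distance for a zero vector")
    nu = np.linalg.norm(u.frequencies)
    nv = np.linalg.norm(v.frequencies)
    d = 1.0 - float(u.frequencies @ v.frequencies) / (nu * nv)
    # non-negative components keep the true value in [0, 1]; clip float noise
    return min(max(d, 0.0), 1.0)


def _distances_to_all(query: KmerVector, db: ReferenceDatabase) -> np.ndarray:
    if query.k != db.k:
        raise InvalidParameterError(f"query k={query.k} does not match database k={db.k}")
    if query.valid_window_count == 0:
        raise DegenerateVectorError("query has no valid k-mer windows")
    q = query.frequencies
    qn = np.linalg.norm(q)
    dots = db.freq_matrix() @ q
    d = 1.0 - dots / (db.freq_norms() * qn)
    return np.clip(d, 0.0, 1.0)


def select_neighbors(
    query: KmerVector,
    db: ReferenceDatabase,
    K: int = DEFAULT_K_NEIGHBORS,
    eps: float = DEFAULT_EPS,
    query_id: str = "query",
) -> NeighborSet:
    """Apply the five neighbor-selection cases to one query.

    ε is inclusive (distance ≤ ε).  Distances ≤ 1e-12 count as exact matches
    and trigger the zero-distance override.
    """
    if len(db) == 0:
        raise EmptyDatabaseError("cannot select neighbors from an empty database")
    if K < 1:
        raise InvalidParameterError(f"K must be >= 1, got {K}")
    if not (0.0 < eps <= 1.0):
        raise InvalidParameterError(f"eps must be in (0, 1], got {eps}")

    ids = db.genome_ids
    dist = _distances_to_all(query, db)

    zero_mask = dist <= ZERO_DISTANCE_TOL
    if zero_mask.any():
        entries = sorted(
            ((ids[i], float(dist[i])) for i in np.flatnonzero(zero_mask)),
            key=lambda e: (e[1], e[0]),
        )
        return NeighborSet(query_id, tuple(entries), SelectionCase.ZERO_DISTANCE_OVERRIDE)

    within = np.flatnonzero(dist <= eps)
    if within.size == 0:
        return NeighborSet(query_id, (), SelectionCase.EMPTY)

    entries = sorted(
        ((ids[i], float(dist[i])) for i in within), key=lambda e: (e[1], e[0])
    )
    if len(entries) < K:
        case = SelectionCase.FEWER_THAN_K
    elif len(entries) == K:
        case = SelectionCase.EXACTLY_K
    else:
        case = SelectionCase.TRUNCATED_TO_K
        entries = entries[:K]
    return NeighborSet(query_id, tuple(entries), case)


def predict_profile(neighbors: NeighborSet, db: ReferenceDatabase) -> Prediction:
    """Average the selected neighbors' profiles componentwise (unweighted mean)."""
    if neighbors.selection_case is SelectionCase.EMPTY:
        return Prediction(neighbors.query_id, None, neighbors)
    try:
        stack = np.vstack([db.profiles[gid] for gid, _ in neighbors.entries])
    except KeyError as exc:
        raise IntegrityError(f"neighbor {exc.args[0]!r} has no profile in the database") from exc
    return Prediction(neighbors.query_id, stack.mean(axis=0), neighbors)


def predict_sequence(
    sequence: str,
    db: ReferenceDatabase,
    K: int = DEFAULT_K_NEIGHBORS,
    eps: float = DEFAULT_EPS,
    query_id: str = "query",
) -> Prediction:
    """Convenience: k-mer vectorize, select neighbors, average, in one call."""
    kv = count_kmers(sequence, k=db.k, record_id=query_id)
    neighbors = select_neighbors(kv, db, K=K, eps=eps, query_id=query_id)
    return predict_profile(neighbors, db)


def predict_records(
    records,
    db: ReferenceDatabase,
    K: int = DEFAULT_K_NEIGHBORS,
    eps: float = DEFAULT_EPS,
) -> list[Prediction]:
    """Predict for an iterable of ``(query_id, sequence)`` pairs, in input order.

    Per-record failures (e.g. a sequence shorter than k) are captured in the
    returned :class:`Prediction` rather than aborting the batch.
    """
    predictions = []
    for query_id, sequence in records:
        try:
            pred = predict_sequence(sequence, db, K=K, eps=eps, query_id=query_id)
        except ItsfuncError as exc:
            logger.warning("query %r failed: %s", query_id, exc)
            predictions.append(Prediction(query_id, None, None, error=str(exc)))
            continue
        ns = pred.neighbor_set
        if ns.selection_case is SelectionCase.EMPTY:
            logger.warning(
                "query %r: no neighbors within eps=%.3g; no prediction "
                "(a larger eps may admit neighbors)", query_id, eps,
            )
        else:
            logger.debug(
                "query %r: case=%s K_chosen=%d min_dist=%.6g",
                query_id, ns.selection_case.value, ns.k_chosen, ns.entries[0][1],
            )
        predictions.append(pred)
    return predictions


def predictions_to_table(predictions, catalog) -> pd.DataFrame:
    """Function-by-sample table: L rows in catalog order, one column per query.

    Unpredicted queries appear as all-NA columns so the column count always
    equals the input record count.
    """
    columns = {}
    for pred in predictions:
        if pred.is_predicted:
            columns[pred.query_id] = pred.predicted
        else:
            columns[pred.query_id] = np.full(len(catalog), np.nan)
    table = pd.DataFrame(columns, index=list(catalog))
    table.index.name = "function"
    return table


def predict_batch(
    query_fasta,
    db: ReferenceDatabase,
    K: int = DEFAULT_K_NEIGHBORS,
    eps: float = DEFAULT_EPS,
):
    """Predict every record of a query FASTA file.

    Returns ``(predictions, table)`` where ``table`` is the function-by-sample
    DataFrame.  An empty query file yields an empty table (header only).
    """
    try:
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(query_fasta), "fasta")]
    except (ValueError, OSError) as exc:
        raise FastaParseError(f"cannot parse {query_fasta}: {exc}") from exc
    if not records and os.path.getsize(query_fasta) > 0:
        raise FastaParseError(f"{query_fasta} is non-empty but contains no FASTA records")
    predictions = predict_records(records, db, K=K, eps=eps)
    return predictions, predictions_to_table(predictions, db.catalog)


def write_prediction_table(table: pd.DataFrame, path) -> None:
    """Write the prediction table as TSV, NA for unpredicted, 8 significant digits."""
    table.to_csv(path, sep="\t", na_rep="NA", float_format="%.8g", lineterminator="\n")
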