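"""Reference database: amplicon variants paired with gene-content profiles.

A database couples, for one amplicon class (ITS1, ITS2 or the full
ITS1-5.8S-ITS2 "concatenate"), a set of reference amplicon variants (RAVs)
with one normalized gene-content profile per genome and a shared function
catalog.  On disk it is a FASTA of sequences (record ID = genome ID) plus a
TSV matrix: a header row of function identifiers, then one row per genome
with the genome ID in the first column.  Profiles may arrive as raw counts;
the loader renormalizes every row to sum to 1, the canonical form in which a
profile component is the fraction of the genome's annotated functions
belonging to that function.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DatabaseError,
    DatabaseMismatchError,
    DegenerateProfileError,
    EmptyDatabaseError,
    InvalidParameterError,
)
from .kmers import DEFAULT_K, KmerVector, count_kmers

AMPLICON_CLASSES = ("ITS1", "ITS2", "concatenate")

#: Row sums further than this from 1 trigger renormalization at load time.
PROFILE_SUM_TOL = 1e-6


@dataclass(frozen=True)
class RAVRecord:
    """One reference amplicon variant: a genome's ITS sequence plus its k-vector."""

    genome_id: str
    amplicon_class: str
    sequence: str
    kvector: KmerVector


@dataclass
class ReferenceDatabase:
    """The KNN search space: RAVs, profiles, and the function catalog.

    Invariants: genome IDs are unique, every RAV has exactly one profile and
    vice versa, and all profiles share the catalog length ``L``.
    """

    amplicon_class: str
    ravs: list[RAVRecord]
    profiles: dict[str, np.ndarray]
    catalog: list[str]
    k: int = DEFAULT_K
    _freq_matrix: np.ndarray | None = field(default=None, repr=False, compare=False)
    _norms: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.amplicon_class not in AMPLICON_CLASSES:
            raise InvalidParameterError(
                f"amplicon_class must be one of {AMPLICON_CLASSES}, got {self.amplicon_class!r}"
            )
        ids = [r.genome_id for r in self.ravs]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise DatabaseError(f"duplicate genome IDs: {dupes}")
        missing_profiles = set(ids) - set(self.profiles)
        missing_seqs = set(self.profiles) - set(ids)
        if missing_profiles or missing_seqs:
            raise DatabaseMismatchError(missing_profiles, missing_seqs)
        L = len(self.catalog)
        for gid, prof in self.profiles.items():
            if len(prof) != L:
                raise DatabaseError(
                    f"profile for {gid!r} has length {len(prof)}, catalog has {L}"
                )

    def __len__(self) -> int:
        return len(self.ravs)

    @property
    def genome_ids(self) -> list[str]:
        return [r.genome_id for r in self.ravs]

    def freq_matrix(self) -> np.ndarray:
        """(n_ravs, 4^k) matrix of k-mer frequency vectors, cached."""
        if self._freq_matrix is None:
            self._freq_matrix = np.vstack([r.kvector.frequencies for r in self.ravs])
            self._norms = np.linalg.norm(self._freq_matrix, axis=1)
        return self._freq_matrix

    def freq_norms(self) -> np.ndarray:
        self.freq_matrix()
        return self._norms

    def profile_matrix(self) -> np.ndarray:
        """(n_ravs, L) profile matrix in RAV order."""
        return np.vstack([self.profiles[r.genome_id] for r in self.ravs])

    def subset(self, genome_ids) -> "ReferenceDatabase":
        """A new database restricted to the given genome IDs (RAV order kept)."""
        keep = set(genome_ids)
        ravs = [r for r in self.ravs if r.genome_id in keep]
        if not ravs:
            raise EmptyDatabaseError("subset selects no genomes")
        profiles = {r.genome_id: self.profiles[r.genome_id] for r in ravs}
        return ReferenceDatabase(self.amplicon_class, ravs, profiles, self.catalog, self.k)

    def without(self, genome_id: str) -> "ReferenceDatabase":
        """Leave-one-out copy with one genome removed from the search space."""
        if genome_id not in self.profiles:
            raise DatabaseError(f"unknown genome ID {genome_id!r}")
        return self.subset(g for g in self.genome_ids if g != genome_id)


def normalize_profile(raw) -> np.ndarray:
    """Divide a non-negative vector by its sum so components become fractions.

    Raises :class:`DegenerateProfileError` for all-zero or negative input.
    """
    values = np.asarray(raw, dtype=np.float64)
    if (values < 0).any():
        raise DegenerateProfileError("profile contains negative entries")
    total = values.sum()
    if total <= 0:
        raise DegenerateProfileError("profile sums to zero; cannot normalize")
    return values / total


def load_database(
    sequence_file,
    profile_file,
    amplicon_class: str = "concatenate",
    k: int = DEFAULT_K,
) -> ReferenceDatabase:
    """Read FASTA + profile TSV into a validated :class:`ReferenceDatabase`.

    K-mer vectors are precomputed for every RAV; any RAV yielding zero valid
    windows is rejected.  Profile rows are renormalized when they do not
    already sum to 1 (so raw count tables are accepted).
    """
    records = list(SeqIO.parse(str(sequence_file), "fasta"))
    if not records:
        raise EmptyDatabaseError(f"no FASTA records in {sequence_file}")

    table = pd.read_csv(profile_file, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    if table.index.duplicated().any():
        dupes = sorted(table.index[table.index.duplicated()].unique())
        raise DatabaseError(f"duplicate genome IDs in profile table: {dupes}")
    catalog = [str(c) for c in table.columns]
    if len(set(catalog)) != len(catalog):
        raise DatabaseError("duplicate function identifiers in profile header")

    fasta_ids = [r.id for r in records]
    if len(set(fasta_ids)) != len(fasta_ids):
        dupes = sorted({g for g in fasta_ids if fasta_ids.count(g) > 1})
        raise DatabaseError(f"duplicate genome IDs in FASTA: {dupes}")
    missing_profiles = set(fasta_ids) - set(table.index)
    missing_seqs = set(table.index) - set(fasta_ids)
    if missing_profiles or missing_seqs:
        raise DatabaseMismatchError(missing_profiles, missing_seqs)

    profiles: dict[str, np.ndarray] = {}
    for gid in fasta_ids:
        row = table.loc[gid].to_numpy(dtype=np.float64)
        if abs(row.sum() - 1.0) > PROFILE_SUM_TOL:
            row = normalize_profile(row)
        else:
            if (row < 0).any():
                raise DegenerateProfileError(f"profile for {gid!r} contains negative entries")
        profiles[gid] = row

    ravs = []
    for rec in records:
        kv = count_kmers(str(rec.seq), k=k, record_id=rec.id)
        if kv.valid_window_count == 0:
            raise DatabaseError(
                f"RAV {rec.id!r} yields no valid k-mer windows (all windows ambiguous)"
            )
        ravs.append(RAVRecord(rec.id, amplicon_class, str(rec.seq), kv))

    return ReferenceDatabase(amplicon_class, ravs, profiles, catalog, k)


def save_database(db: ReferenceDatabase, sequence_file, profile_file, force: bool = False) -> None:
    """Write a database back to FASTA + TSV.

    Round-trip contract: ``load_database(save_database(db))`` reproduces IDs,
    sequences, catalog and profiles to within 1e-12 (values are printed with
    17 significant digits).  Refuses to overwrite existing files unless
    ``force=True``.
    """
    for path in (sequence_file, profile_file):
        if not force and os.path.exists(path):
            raise DatabaseError(f"refusing to overwrite existing file {path} (use force=True)")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.genome_id, description="") for r in db.ravs
    ]
    SeqIO.write(seq_records, str(sequence_file), "fasta")
    frame = pd.DataFrame(
        db.profile_matrix(), index=db.genome_ids, columns=db.catalog
    )
    frame.index.name = "genome_id"
    frame.to_csv(profile_file, sep="\t", float_format="%.17g", lineterminator="\n")
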