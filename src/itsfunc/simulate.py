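"""Synthetic reference databases with the structure the predictor assumes.

The KNN predictor works because close relatives carry similar functional
repertoires: sequence similarity is a proxy for profile similarity.  The
simulator builds exactly that world.  A random root sequence and a root
gene-content profile are evolved down a balanced binary tree; each branch
substitutes sites of the sequence at a fixed per-site probability and
perturbs the profile by multiplicative log-normal jitter followed by
renormalization.  Leaves become reference amplicon variants with profiles
whose similarity decays smoothly with tree distance — so a held-out leaf is
well predicted by its near relatives, and predictions degrade as the
substitution rate rises.

Everything is fully determined by the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidParameterError
from .kmers import DEFAULT_K, count_kmers
from .refdb import RAVRecord, ReferenceDatabase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic database.

    Defaults describe an ITS-like world: 64 genomes, 500 bp amplicons,
    2% expected substitutions per site per tree branch, 50 functions, and
    mild (0.1 log-scale) per-branch profile jitter — close relatives stay
    within a cosine eps of 0.5 of each other and share most of their profile.
    """

    seed: int
    n_genomes: int = 64
    sequence_length: int = 500
    substitution_rate: float = 0.02
    profile_length: int = 50
    profile_concentration: float = 1.0
    profile_jitter: float = 0.1
    amplicon_class: str = "concatenate"
    k: int = DEFAULT_K

    def __post_init__(self):
        if self.n_genomes < 2:
            raise InvalidParameterError(f"n_genomes must be >= 2, got {self.n_genomes}")
        if self.sequence_length < self.k:
            raise InvalidParameterError("sequence_length must be >= k")
        if not (0.0 <= self.substitution_rate < 1.0):
            raise InvalidParameterError(
                f"substitution_rate must be in [0, 1), got {self.substitution_rate}"
            )
        if self.profile_length < 2:
            raise InvalidParameterError("profile_length must be >= 2")
        if self.profile_concentration <= 0:
            raise InvalidParameterError("profile_concentration must be > 0")
        if self.profile_jitter < 0:
            raise InvalidParameterError("profile_jitter must be >= 0")


def _mutate_sequence(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a uniformly chosen other base."""
    child = codes.copy()
    if rate <= 0:
        return child
    hits = np.flatnonzero(rng.random(codes.size) < rate)
    if hits.size:
        # offset 1..3 mod 4 guarantees a *different* base
        child[hits] = (child[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return child


def _jitter_profile(profile: np.ndarray, jitter: float, rng: np.random.Generator) -> np.ndarray:
    child = profile * np.exp(jitter * rng.standard_normal(profile.size))
    return child / child.sum()


def simulate_reference(config: SimulationConfig) -> ReferenceDatabase:
    """Evolve sequences and profiles down a balanced binary tree; leaves become RAVs.

    The tree depth is ``ceil(log2(n_genomes))``; when ``n_genomes`` is not a
    power of two the leaf list is truncated to the first ``n_genomes`` leaves.
    """
    rng = np.random.default_rng(config.seed)
    depth = math.ceil(math.log2(config.n_genomes))

    root_seq = rng.integers(0, 4, size=config.sequence_length).astype(np.int64)
    root_profile = rng.dirichlet(
        np.full(config.profile_length, config.profile_concentration)
    )

    level = [(root_seq, root_profile)]
    for _ in range(depth):
        nxt = []
        for seq, prof in level:
            for _child in range(2):
                nxt.append(
                    (
                        _mutate_sequence(seq, config.substitution_rate, rng),
                        _jitter_profile(prof, config.profile_jitter, rng),
                    )
                )
        level = nxt
    leaves = level[: config.n_genomes]

    ravs = []
    profiles = {}
    for i, (seq_codes, profile) in enumerate(leaves):
        gid = f"g{i:04d}"
        sequence = _BASES[seq_codes].tobytes().decode("ascii")
        kv = count_kmers(sequence, k=config.k, record_id=gid)
        ravs.append(RAVRecord(gid, config.amplicon_class, sequence, kv))
        profiles[gid] = profile
    catalog = [f"F{j:03d}" for j in range(config.profile_length)]
    return ReferenceDatabase(config.amplicon_class, ravs, profiles, catalog, config.k)


@dataclass(frozen=True)
class QueryRecord:
    query_id: str
    sequence: str
    source_id: str  # the database leaf this query diverged from


def simulate_queries(
    db: ReferenceDatabase,
    divergence_rate: float = 0.0,
    n_queries: int = 8,
    seed: int = 0,
):
    """Draw queries as mutated copies of database leaves, with their true profiles.

    Samples ``n_queries`` leaves with replacement, substitutes each sequence
    at ``divergence_rate`` per site, and returns ``(queries, true_profiles)``
    where ``true_profiles`` is a function-by-query DataFrame holding the
    originating leaves' profiles — the ground truth for scoring.  This is the
    mock-community workflow: each query stands for one consensus ITS from a
    metagenome, scored against its source genome's real gene content.
    """
    if n_queries < 1:
        raise InvalidParameterError(f"n_queries must be >= 1, got {n_queries}")
    if not (0.0 <= divergence_rate < 1.0):
        raise InvalidParameterError(f"divergence_rate must be in [0, 1), got {divergence_rate}")
    rng = np.random.default_rng(seed)
    code_of = {65: 0, 67: 1, 71: 2, 84: 3}

    queries = []
    truth = {}
    ids = db.genome_ids
    picks = rng.integers(0, len(ids), size=n_queries)
    for i, pick in enumerate(picks):
        source = db.ravs[pick]
        codes = np.array([code_of[ord(c)] for c in source.sequence], dtype=np.int64)
        mutated = _mutate_sequence(codes, divergence_rate, rng)
        qid = f"q{i:03d}_{source.genome_id}"
        queries.append(QueryRecord(qid, _BASES[mutated].tobytes().decode("ascii"), source.genome_id))
        truth[qid] = db.profiles[source.genome_id]
    true_profiles = pd.DataFrame(truth, index=list(db.catalog))
    true_profiles.index.name = "function"
    return queries, true_profiles


def write_queries(queries, fasta_path) -> None:
    records = [SeqRecord(Seq(q.sequence), id=q.query_id, description="") for q in queries]
    SeqIO.write(records, str(fasta_path), "fasta")


def write_config(config: SimulationConfig, json_path) -> None:
    """JSON sidecar recording the exact simulation parameters."""
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(asdict(config), fh, indent=2)
        fh.write("\n")
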