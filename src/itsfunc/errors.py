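"""Exception hierarchy.

All package-specific failures derive from :class:`ItsfuncError` so callers
can catch one base class; most also derive from :class:`ValueError` because
they signal invalid inputs rather than internal faults.
"""


class ItsfuncError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(ItsfuncError, ValueError):
    """A configuration parameter is out of its valid range (e.g. k < 1, K < 1)."""


class SequenceTooShortError(ItsfuncError, ValueError):
    """A sequence is shorter than the k-mer window; names the offending record."""

    def __init__(self, record_id: str | None, length: int, k: int):
        self.record_id = record_id
        self.length = length
        self.k = k
        who = f"record {record_id!r}" if record_id else "sequence"
        super().__init__(f"{who} has length {length} < k={k}; cannot extract any k-mer window")


class DegenerateVectorError(ItsfuncError, ValueError):
    """A k-mer vector with no valid windows where a distance is required."""


class DegenerateProfileError(ItsfuncError, ValueError):
    """A gene-content profile that cannot be normalized (all-zero or negative)."""


class DatabaseError(ItsfuncError, ValueError):
    """Problems with the reference database as a whole."""


class DatabaseMismatchError(DatabaseError):
    """FASTA record IDs and profile-table row IDs do not agree; lists offenders."""

    def __init__(self, missing_profiles=(), missing_sequences=()):
        self.missing_profiles = sorted(missing_profiles)
        self.missing_sequences = sorted(missing_sequences)
        parts = []
        if self.missing_profiles:
            parts.append(f"in FASTA but not in profile table: {self.missing_profiles}")
        if self.missing_sequences:
            parts.append(f"in profile table but not in FASTA: {self.missing_sequences}")
        super().__init__("genome ID mismatch; " + "; ".join(parts))


class EmptyDatabaseError(DatabaseError):
    """The reference database contains no records."""


class IntegrityError(DatabaseError):
    """Internal cross-reference broken, e.g. a neighbor ID without a profile."""


class UndefinedStatisticError(ItsfuncError, ValueError):
    """A statistic is mathematically undefined for the given input."""


class UndefinedRSquaredError(UndefinedStatisticError):
    """R-squared is undefined when the actual vector is constant (zero total variance)."""


class UndefinedCVError(UndefinedStatisticError):
    """Coefficient of variation is undefined for zero-mean or single-observation data."""


class FastaParseError(ItsfuncError, ValueError):
    """An input file could not be parsed as FASTA."""
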