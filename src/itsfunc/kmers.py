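"""Dense k-mer relative-abundance vectors for nucleotide sequences.

Every sequence is represented as a vector of length :math:`4^k` holding the
relative abundance of each k-mer (default ``k=5``, so 1024 components).
Components are indexed by the lexicographic enumeration of k-mers over the
alphabet ``A < C < G < T``.  A sliding window of width ``k`` and step 1 is
moved over the uppercased sequence; windows containing any character other
than A/C/G/T (Ns, IUPAC ambiguity codes, gaps) are skipped and do not enter
the denominator.  ``U`` is transliterated to ``T`` so RNA-style deposits are
tolerated.  Reverse complements are *not* canonicalized: amplicons are
assumed to be in a consistent orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidParameterError, SequenceTooShortError

DEFAULT_K = 5

_ALPHABET = "ACGT"

# byte -> base code (A=0, C=1, G=2, T=3), -1 for anything else
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_ALPHABET):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class KmerVector:
    """A length-:math:`4^k` relative-abundance vector over DNA k-mers.

    Attributes
    ----------
    k : int
        Window length.
    frequencies : numpy.ndarray
        Vector of ``4**k`` non-negative fractions summing to 1 when
        ``valid_window_count > 0``, all zero otherwise.
    valid_window_count : int
        Number of windows that consisted solely of A/C/G/T.
    """

    k: int
    frequencies: np.ndarray
    valid_window_count: int

    def __post_init__(self):
        if self.k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {self.k}")
        if len(self.frequencies) != 4**self.k:
            raise InvalidParameterError(
                f"frequency vector has length {len(self.frequencies)}, expected 4^{self.k}"
            )


def enumerate_kmers(k: int) -> list[str]:
    """Return all ``4**k`` k-mers in lexicographic order over ``A<C<G<T``."""
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    return ["".join(p) for p in product(_ALPHABET, repeat=k)]


def kmer_index(kmer: str) -> int:
    """Map a k-mer string to its index in the lexicographic enumeration (O(k))."""
    idx = 0
    for ch in kmer.upper():
        code = _CODE[ord(ch)] if ord(ch) < 256 else -1
        if code < 0:
            raise InvalidParameterError(f"not an unambiguous DNA k-mer: {kmer!r}")
        idx = idx * 4 + int(code)
    return idx


def count_kmers(sequence: str, k: int = DEFAULT_K, record_id: str | None = None) -> KmerVector:
    """Count sliding k-mer windows and return their relative abundances.

    Parameters
    ----------
    sequence : str
        Nucleotide sequence; case-insensitive, ``U`` treated as ``T``.
    k : int
        Window length (default 5).
    record_id : str, optional
        Identifier used in error messages.

    Raises
    ------
    SequenceTooShortError
        If the sequence (after uppercasing) is shorter than ``k``.
    InvalidParameterError
        If ``k < 1``.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    seq = sequence.upper().replace("U", "T")
    if len(seq) < k:
        raise SequenceTooShortError(record_id, len(seq), k)

    raw = seq.encode("ascii", errors="replace")  # non-ASCII -> b'?' -> invalid window
    codes = _CODE[np.frombuffer(raw, dtype=np.uint8)]
    windows = sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    n_valid = int(valid.sum())

    frequencies = np.zeros(4**k, dtype=np.float64)
    if n_valid > 0:
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        indices = windows[valid].astype(np.int64) @ powers
        counts = np.bincount(indices, minlength=4**k)
        frequencies = counts / n_valid
    return KmerVector(k=k, frequencies=frequencies, valid_window_count=n_valid)
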