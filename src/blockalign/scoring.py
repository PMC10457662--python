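"""Alphabets, substitution matrices, and position-specific scoring matrices.

Every alignment target is normalised into a :class:`Pssm`: a ``|p| x |sigma|``
integer profile with per-position gap open/close penalties.  A plain sequence
plus a substitution matrix is the special case where row ``j`` of the profile
is the matrix row of the target residue at position ``j`` and the gap arrays
are constant.

Sign convention: all gap parameters are non-positive integers that are *added*
to scores (e.g. ``g_open=-10, g_ext=-1``).  Constructors reject positive gap
penalties rather than silently negating them.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "Alphabet",
    "DNA",
    "PROTEIN",
    "SubstitutionMatrix",
    "GapParams",
    "Pssm",
    "make_dna_scheme",
    "load_blosum62",
    "pssm_from_sequence",
    "lookup",
]


class Alphabet:
    """An ordered residue alphabet with a designated wildcard.

    Characters outside the alphabet map to the wildcard index (if one is
    defined); indices are a bijection onto ``0..len(symbols)-1``.
    """

    def __init__(self, symbols: str, wildcard: str | None = None):
        if len(set(symbols)) != len(symbols):
            raise ValueError("alphabet symbols must be unique")
        if wildcard is not None and wildcard not in symbols:
            raise ValueError("wildcard must be one of the symbols")
        self.symbols = symbols
        self.wildcard = wildcard
        self._index = {ch: i for i, ch in enumerate(symbols)}

    def __len__(self) -> int:
        return len(self.symbols)

    def __repr__(self) -> str:
        return f"Alphabet({self.symbols!r}, wildcard={self.wildcard!r})"

    def index(self, ch: str) -> int:
        try:
            return self._index[ch]
        except KeyError:
            if self.wildcard is None:
                raise ValueError(f"character {ch!r} not in alphabet") from None
            return self._index[self.wildcard]

    def encode(self, seq: str) -> np.ndarray:
        """Map a string to an int array of alphabet indices."""
        return np.fromiter((self.index(c) for c in seq.upper()), dtype=np.int64,
                           count=len(seq))


#: DNA alphabet; N is the wildcard and scores 0 against everything in the
#: shipped DNA schemes.
DNA = Alphabet("ACGTN", wildcard="N")

#: Protein alphabet in BLOSUM62 (NCBI) column order; X is the wildcard.
PROTEIN = Alphabet("ARNDCQEGHILKMFPSTWYVBZX*", wildcard="X")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A square integer substitution matrix over an :class:`Alphabet`."""

    alphabet: Alphabet
    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.int64)
        if s.ndim != 2 or s.shape[0] != s.shape[1] or s.shape[0] != len(self.alphabet):
            raise ValueError("scores must be square over the alphabet")
        object.__setattr__(self, "scores", s)

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.alphabet.index(a), self.alphabet.index(b)])


def make_dna_scheme(match: int, mismatch: int) -> SubstitutionMatrix:
    """Match/mismatch scoring over ACGT; the N wildcard scores 0.

    ``match`` must be >= 0 and ``mismatch`` <= 0 (penalty convention).
    """
    if match < 0:
        raise ValueError("match score must be >= 0")
    if mismatch > 0:
        raise ValueError("mismatch score must be <= 0 (penalty convention)")
    n = len(DNA)
    m = np.full((n, n), mismatch, dtype=np.int64)
    np.fill_diagonal(m, match)
    wi = DNA.index("N")
    m[wi, :] = 0
    m[:, wi] = 0
    return SubstitutionMatrix(DNA, m)


def load_blosum62() -> SubstitutionMatrix:
    """The canonical published BLOSUM62 matrix (half-bit integer scores).

    Parsed from the NCBI-layout text fixture shipped with the package; covers
    the 20 amino acids plus ambiguity codes B/Z/X and the stop symbol.
    """
    ref = importlib.resources.files("blockalign").joinpath("data/BLOSUM62.txt")
    with importlib.resources.as_file(ref) as path:
        arr = substitution_matrices.read(str(path))
    if "".join(arr.alphabet) != PROTEIN.symbols:
        raise RuntimeError("BLOSUM62 fixture alphabet mismatch")
    return SubstitutionMatrix(PROTEIN, np.asarray(arr, dtype=np.int64))


@dataclass
class GapParams:
    """Affine gap penalties, per target position.

    A gap of length ``g`` in the target (an I run, vertical in the DP matrix)
    at column ``j`` costs ``g_ext*g + g_open_r[j]``; a gap of length ``g`` in
    the query (a D run, horizontal) spanning columns ``j..j+g-1`` costs
    ``g_ext*g + g_open_c[j] + g_close_c[j+g-1]``.  Arrays have length
    ``|p|+1`` and are indexed by DP-matrix column (0 is the padding column).
    All values are <= 0.
    """

    g_ext: int
    g_open_r: np.ndarray
    g_open_c: np.ndarray
    g_close_c: np.ndarray

    def __post_init__(self):
        self.g_open_r = np.asarray(self.g_open_r, dtype=np.int64)
        self.g_open_c = np.asarray(self.g_open_c, dtype=np.int64)
        self.g_close_c = np.asarray(self.g_close_c, dtype=np.int64)
        if self.g_ext > 0 or any(a.max(initial=0) > 0 for a in
                                 (self.g_open_r, self.g_open_c, self.g_close_c)):
            raise ValueError("gap penalties must be <= 0 (penalty convention)")
        if not (len(self.g_open_r) == len(self.g_open_c) == len(self.g_close_c)):
            raise ValueError("gap arrays must share one length (|p|+1)")

    @classmethod
    def constant(cls, length: int, g_open: int, g_ext: int,
                 g_close: int = 0) -> "GapParams":
        """Position-independent penalties for a target of ``length`` positions."""
        n = length + 1
        return cls(g_ext,
                   np.full(n, g_open, dtype=np.int64),
                   np.full(n, g_open, dtype=np.int64),
                   np.full(n, g_close, dtype=np.int64))


@dataclass
class Pssm:
    """A position-specific scoring matrix with gap penalties.

    ``profile_scores[j, sigma]`` is the score for aligning residue ``sigma``
    of the query to target position ``j`` (0-based).
    """

    alphabet: Alphabet
    profile_scores: np.ndarray
    gaps: GapParams
    consensus: str | None = field(default=None)

    def __post_init__(self):
        p = np.asarray(self.profile_scores, dtype=np.int64)
        if p.ndim != 2 or p.shape[1] != len(self.alphabet):
            raise ValueError("profile must be |p| x |alphabet|")
        if p.shape[0] == 0:
            raise ValueError("empty PSSM")
        if len(self.gaps.g_open_r) != p.shape[0] + 1:
            raise ValueError("gap arrays must have length |p|+1")
        self.profile_scores = p
        if self.consensus is None:
            idx = p.argmax(axis=1)
            self.consensus = "".join(self.alphabet.symbols[i] for i in idx)

    def __len__(self) -> int:
        return self.profile_scores.shape[0]

    def lookup(self, j: int, residue: str) -> int:
        """Score of ``residue`` at target position ``j`` (1-based, 1..|p|)."""
        if not 1 <= j <= len(self):
            raise IndexError(f"position {j} out of range 1..{len(self)}")
        return int(self.profile_scores[j - 1, self.alphabet.index(residue)])


def pssm_from_sequence(seq: str, matrix: SubstitutionMatrix, g_open: int,
                       g_ext: int, g_close: int = 0) -> Pssm:
    """Lift a plain sequence into the generalized PSSM representation.

    Row ``j`` of the profile is the matrix row for ``seq[j]``; gap penalties
    are constant at every position.
    """
    if len(seq) == 0:
        raise ValueError("empty target sequence")
    if g_open > 0 or g_ext > 0 or g_close > 0:
        raise ValueError("gap penalties must be <= 0 (penalty convention)")
    idx = matrix.alphabet.encode(seq)
    profile = matrix.scores[idx, :]
    gaps = GapParams.constant(len(seq), g_open, g_ext, g_close)
    return Pssm(matrix.alphabet, profile, gaps, consensus=None)


def lookup(pssm: Pssm, j: int, residue: str) -> int:
    """Module-level alias for :meth:`Pssm.lookup` (1-based position)."""
    return pssm.lookup(j, residue)
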