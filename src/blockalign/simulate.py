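"""Seeded generators for sequence pairs and PSSMs, plus sequence identity.

The generators emulate the summary properties of typical evaluation data:
Illumina-like short reads (length ~101, >=99% identity, at most 2 bp
indels), Nanopore-like long-read pairs (~90% identity with occasional long
indels), protein pairs at a target identity, and synthetic PSSMs with one
favoured residue per position.  Every generator is a pure function of its
arguments and seed, and returns the edit script it applied so the realized
identity is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import GapParams, Pssm, PROTEIN, load_blosum62
from .traceback import Cigar

__all__ = ["MutationProfile", "ILLUMINA_PROFILE", "NANOPORE_PROFILE",
           "make_pair", "nanopore_like", "illumina_like", "protein_pair",
           "random_pssm", "seq_identity", "script_identity"]

_DNA = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class MutationProfile:
    """Per-base mutation rates used to derive one read from another.

    ``sub_rate``/``ins_rate``/``del_rate`` are per-base probabilities;
    ``indel_range`` bounds ordinary indel lengths (inclusive); with
    probability ``long_gap_rate`` a single long indel with length in
    ``long_gap_range`` is added.
    """

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    indel_range: tuple[int, int] = (1, 1)
    long_gap_rate: float = 0.0
    long_gap_range: tuple[int, int] = (50, 400)
    long_gap_op: str = "random"  # "I", "D", or "random"

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate,
                  self.long_gap_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("sub+ins+del must be < 1")


#: Illumina-like: ~0.5% substitutions, rare 1-2 bp indels.
ILLUMINA_PROFILE = MutationProfile(sub_rate=0.005, ins_rate=0.001,
                                   del_rate=0.001, indel_range=(1, 2))

#: Nanopore-like: ~90% identity with an occasional 50-400 bp indel.
NANOPORE_PROFILE = MutationProfile(sub_rate=0.04, ins_rate=0.03,
                                   del_rate=0.03, indel_range=(1, 1),
                                   long_gap_rate=0.1, long_gap_range=(50, 400))


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _apply_script(p: str, script: list[tuple[str, str | int]],
                  ) -> str:
    """Replay an edit script against ``p`` to reconstruct the query."""
    out = []
    i = 0
    for op, arg in script:
        if op == "M":
            out.append(p[i:i + arg])
            i += arg
        elif op == "X":
            out.append(arg)
            i += len(arg)
        elif op == "I":
            out.append(arg)
        else:  # D
            i += arg
    if i != len(p):
        raise ValueError("edit script does not consume the reference")
    return "".join(out)


def script_identity(script: list[tuple[str, str | int]]) -> float:
    """matches / (matches + mismatches + insertions + deletions)."""
    matches = mm = gaps = 0
    for op, arg in script:
        if op == "M":
            matches += arg
        elif op == "X":
            mm += len(arg)
        else:
            gaps += arg if isinstance(arg, int) else len(arg)
    return matches / (matches + mm + gaps)


def _mutate(p: str, profile: MutationProfile, rng: np.random.Generator,
            alphabet: str = _DNA) -> tuple[str, list]:
    """Derive a query from ``p`` by per-base edits plus at most one long gap."""
    letters = list(alphabet)
    script: list[tuple[str, str | int]] = []
    long_at = -1
    long_op = "D"
    long_len = 0
    if profile.long_gap_rate > 0 and rng.random() < profile.long_gap_rate:
        long_at = int(rng.integers(0, len(p) + 1))
        if profile.long_gap_op == "random":
            long_op = "D" if rng.random() < 0.5 else "I"
        else:
            long_op = profile.long_gap_op
        long_len = int(rng.integers(profile.long_gap_range[0],
                                    profile.long_gap_range[1] + 1))
    i = 0
    while i < len(p):
        if long_len and long_at <= i:
            if long_op == "D":
                take = min(long_len, len(p) - i)
                script.append(("D", take))
                i += take
            else:
                script.append(("I", _random_seq(rng, long_len, alphabet)))
            long_len = 0
            continue
        u = rng.random()
        if u < profile.del_rate:
            n = min(int(rng.integers(profile.indel_range[0],
                                     profile.indel_range[1] + 1)), len(p) - i)
            script.append(("D", n))
            i += n
        elif u < profile.del_rate + profile.ins_rate:
            n = int(rng.integers(profile.indel_range[0],
                                 profile.indel_range[1] + 1))
            script.append(("I", _random_seq(rng, n, alphabet)))
            # fall through to also emit the current base
            script.append(("M", 1))
            i += 1
        elif u < profile.del_rate + profile.ins_rate + profile.sub_rate:
            others = [c for c in letters if c != p[i]]
            script.append(("X", str(rng.choice(others))))
            i += 1
        else:
            script.append(("M", 1))
            i += 1
    if long_at == len(p) and long_len and long_op == "I":
        script.append(("I", _random_seq(rng, long_len, alphabet)))
    # merge adjacent same-op runs for a compact script
    merged: list[tuple[str, str | int]] = []
    for op, arg in script:
        if merged and merged[-1][0] == op and op in "MD":
            merged[-1] = (op, merged[-1][1] + arg)
        elif merged and merged[-1][0] == op and op in "XI":
            merged[-1] = (op, merged[-1][1] + arg)
        else:
            merged.append((op, arg))
    return _apply_script(p, merged), merged


def make_pair(length: int, profile: MutationProfile, seed: int
              ) -> tuple[str, str, float]:
    """One (q, p, realized_identity) pair: p is uniform random DNA, q is p
    passed through the mutation profile."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    p = _random_seq(rng, length, _DNA)
    q, script = _mutate(p, profile, rng)
    return q, p, script_identity(script)


def nanopore_like(n_pairs: int, length_range: tuple[int, int] = (500, 2000),
                  seed: int = 0) -> list[tuple[str, str, float]]:
    """Long-read-like pairs with realized mean identity around 0.90."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        sub = int(rng.integers(0, 2 ** 31 - 1))
        out.append(make_pair(length, NANOPORE_PROFILE, sub))
    return out


def illumina_like(n_pairs: int, length: int = 101, seed: int = 0
                  ) -> list[tuple[str, str, float]]:
    """Short-read-like pairs: ~101 bp, >=99% identity, <=2 bp indels."""
    rng = np.random.default_rng(seed)
    return [make_pair(length, ILLUMINA_PROFILE, int(rng.integers(0, 2 ** 31 - 1)))
            for _ in range(n_pairs)]


def protein_pair(length: int, target_identity: float, seed: int
                 ) -> tuple[str, str]:
    """A protein pair with realized identity near ``target_identity``.

    Substitutions favour positive-scoring BLOSUM62 partners; indel rates are
    a small fraction of the divergence.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p = _random_seq(rng, length, _AA)
    if target_identity == 1.0:
        return p, p
    blosum = load_blosum62()
    d = 1.0 - target_identity
    indel = d / 10.0
    # realized identity ~ (1 - 1.5*del)(1 - sub) / (1 + 1.5*ins); solve for sub
    sub = 1.0 - target_identity * (1 + 1.5 * indel) / max(1 - 1.5 * indel, 1e-9)
    sub = min(max(sub, 0.0), 0.95)
    out = []
    aa_idx = {a: blosum.alphabet.index(a) for a in _AA}
    i = 0
    while i < len(p):
        u = rng.random()
        if u < indel:
            i += min(int(rng.integers(1, 3)), len(p) - i)  # deletion
        elif u < 2 * indel:
            out.append(_random_seq(rng, int(rng.integers(1, 3)), _AA))
            out.append(p[i])
            i += 1
        elif u < 2 * indel + sub:
            row = blosum.scores[aa_idx[p[i]]]
            cand = [a for a in _AA if a != p[i]]
            w = np.array([2.0 ** row[aa_idx[a]] for a in cand])
            out.append(str(rng.choice(cand, p=w / w.sum())))
            i += 1
        else:
            out.append(p[i])
            i += 1
    q = "".join(out)
    return (q if q else p[:1]), p


def random_pssm(length: int, seed: int, g_open: int = -10, g_ext: int = -1,
                g_close: int = 0) -> Pssm:
    """A synthetic protein PSSM: one favoured residue (+4..+8) per position,
    all other residues negative (-6..-1); constant gap penalties."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    n = len(PROTEIN)
    profile = rng.integers(-6, 0, size=(length, n)).astype(np.int64)
    fav = rng.integers(0, len(_AA), size=length)
    profile[np.arange(length), fav] = rng.integers(4, 9, size=length)
    gaps = GapParams.constant(length, g_open, g_ext, g_close)
    return Pssm(PROTEIN, profile, gaps)


def seq_identity(cigar: Cigar, q: str, p: str) -> float:
    """Sequence identity of an alignment: matches over all columns.

    Every gapped column (I or D) counts once in the denominator; the CIGAR
    must consume both sequences fully.
    """
    if cigar.query_span() != len(q) or cigar.target_span() != len(p):
        raise ValueError("CIGAR does not consume the sequences fully")
    i = j = matches = 0
    total = 0
    for op, n in cigar.runs:
        total += n
        if op == "M":
            matches += sum(1 for k in range(n) if q[i + k] == p[j + k])
            i += n
            j += n
        elif op == "I":
            i += n
        else:
            j += n
    return matches / total
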