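"""The three per-residue parameters and feature-vector assembly.

For each residue type X in a sequence of length N, three standardized
parameters are computed as (measure - null mean) / sqrt(null variance):

Type I   the proportion n_X/N against the binomial proportion null;
Type II  the mean of X's positions against the uniform-position null;
Type III the unbiased variance of X's positions against the same null.

Concatenating the (I, II, III) triplet for every alphabet symbol, in
alphabet order, yields a 60-component vector for protein and a
12-component vector for DNA/RNA.  Parameters whose measure or null
variance is undefined (no occurrences for Types II/III, a single
occurrence for Type III, or a zero null variance) are set to 0 — "no
evidence of deviation from the null" — so every vector is finite and
Euclidean distances stay well-defined.  Positions are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .null_model import (
    DEFAULT_CONVENTION,
    NullConvention,
    PriorComposition,
    _positional_moments,
    codon_prior,
    uniform_prior,
)
from .seq_io import Alphabet, PROTEIN, SequenceRecord


@dataclass(frozen=True)
class ResidueCounts:
    """Counts n_X and proportions p_X for every alphabet symbol."""

    n: dict[str, int]
    p: dict[str, float]
    N: int


@dataclass(frozen=True)
class PositionIndexSet:
    """1-based positions of one residue type, with mean and unbiased variance."""

    residue: str
    indices: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.indices)

    @property
    def m(self) -> Optional[float]:
        """Positional mean; None when the residue does not occur."""
        if not self.indices:
            return None
        return float(np.mean(self.indices))

    @property
    def v(self) -> Optional[float]:
        """Unbiased positional variance; None for fewer than 2 occurrences."""
        if len(self.indices) < 2:
            return None
        return float(np.var(self.indices, ddof=1))


@dataclass(frozen=True)
class FeatureVector:
    """Ordered (Type I, II, III) parameter triplets, one per alphabet symbol."""

    sequence_id: str
    components: np.ndarray
    alphabet: Alphabet = PROTEIN

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=float)
        object.__setattr__(self, "components", comp)
        if len(comp) != 3 * len(self.alphabet):
            raise ValueError(
                f"expected {3 * len(self.alphabet)} components for the "
                f"{self.alphabet.kind} alphabet, got {len(comp)}"
            )
        if not np.all(np.isfinite(comp)):
            raise ValueError(f"feature vector for {self.sequence_id!r} has non-finite components")

    def __len__(self) -> int:
        return len(self.components)

    def triplet(self, residue: str) -> np.ndarray:
        """The (I, II, III) parameters for one residue type."""
        i = self.alphabet.index(residue)
        return self.components[3 * i:3 * i + 3]


def count_residues(record: SequenceRecord, alphabet: Alphabet = PROTEIN) -> ResidueCounts:
    """Count every alphabet symbol in the sequence; proportions sum to 1."""
    record.validate(alphabet)
    n = {sym: 0 for sym in alphabet.symbols}
    for ch in record.residues:
        n[ch] += 1
    N = record.N
    p = {sym: c / N for sym, c in n.items()}
    return ResidueCounts(n, p, N)


def residue_positions(record: SequenceRecord, residue: str) -> PositionIndexSet:
    """1-based positions of ``residue`` in the sequence (possibly empty)."""
    idx = tuple(i + 1 for i, ch in enumerate(record.residues) if ch == residue)
    return PositionIndexSet(residue, idx)


def type1_parameter(n_X: int, N: int, pi_X: float) -> float:
    """Standardized composition: (n_X/N - pi_X) / sqrt(pi_X (1 - pi_X) / N)."""
    if N < 1:
        raise ValueError("sequence length N must be >= 1")
    if not 0 <= n_X <= N:
        raise ValueError(f"need 0 <= n_X <= N, got n_X={n_X}, N={N}")
    if not 0.0 < pi_X < 1.0:
        raise ValueError(f"pi_X must be in (0,1), got {pi_X}")
    return (n_X / N - pi_X) / math.sqrt(pi_X * (1.0 - pi_X) / N)


def type2_parameter(
    pos: PositionIndexSet, N: int, convention: NullConvention = DEFAULT_CONVENTION
) -> float:
    """Standardized positional mean; 0 for an empty index set or zero null variance."""
    if N < 1:
        raise ValueError("sequence length N must be >= 1")
    n = pos.count
    if n == 0:
        return 0.0
    mean2, var2, _, _ = _positional_moments(N, n, convention)
    if var2 is None or var2 <= 0.0:
        return 0.0
    return (pos.m - mean2) / math.sqrt(var2)


def type3_parameter(
    pos: PositionIndexSet, N: int, convention: NullConvention = DEFAULT_CONVENTION
) -> float:
    """Standardized unbiased positional variance; 0 for fewer than 2 occurrences."""
    if N < 1:
        raise ValueError("sequence length N must be >= 1")
    n = pos.count
    if n < 2:
        return 0.0
    _, _, mean3, var3 = _positional_moments(N, n, convention)
    if var3 is None or var3 <= 0.0:
        return 0.0
    return (pos.v - mean3) / math.sqrt(var3)


def default_prior(alphabet: Alphabet) -> PriorComposition:
    """Codon-multiplicity prior (over 64) for protein, uniform for DNA/RNA."""
    if alphabet.kind == "protein":
        return codon_prior("codons_over_64")
    return uniform_prior(alphabet)


def build_feature_vector(
    record: SequenceRecord,
    prior: PriorComposition | None = None,
    convention: NullConvention = DEFAULT_CONVENTION,
    alphabet: Alphabet = PROTEIN,
) -> FeatureVector:
    """Assemble the full feature vector for one sequence.

    Components are per-residue (I, II, III) triplets in alphabet order:
    60 components for protein, 12 for DNA/RNA.
    """
    if record.N == 0:
        raise ValueError(f"record {record.id!r} has an empty sequence")
    if prior is None:
        prior = default_prior(alphabet)
    # integer-encode once; per-symbol positions via flatnonzero
    lut = np.full(128, -1, dtype=np.int8)
    for i, sym in enumerate(alphabet.symbols):
        lut[ord(sym)] = i
    codes = lut[np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0):
        record.validate(alphabet)  # raises with position detail
    N = record.N
    comps = np.zeros(3 * len(alphabet))
    for i, sym in enumerate(alphabet.symbols):
        positions = np.flatnonzero(codes == i) + 1
        n = positions.size
        comps[3 * i] = type1_parameter(n, N, prior.pi[sym])
        if n >= 1:
            mean2, var2, mean3, var3 = _positional_moments(N, n, convention)
            if var2 is not None and var2 > 0.0:
                comps[3 * i + 1] = (positions.mean() - mean2) / math.sqrt(var2)
            if n >= 2 and var3 is not None and var3 > 0.0:
                comps[3 * i + 2] = (positions.var(ddof=1) - mean3) / math.sqrt(var3)
    return FeatureVector(record.id, comps, alphabet)


def build_vectors(
    records: Iterable[SequenceRecord],
    prior: PriorComposition | None = None,
    convention: NullConvention = DEFAULT_CONVENTION,
    alphabet: Alphabet = PROTEIN,
) -> list[FeatureVector]:
    """Feature vectors for a record collection, order-preserving.

    Each record is processed independently, so the output is identical
    regardless of evaluation order.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to vectorize")
    out = []
    for rec in records:
        try:
            out.append(build_feature_vector(rec, prior, convention, alphabet))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    return out
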