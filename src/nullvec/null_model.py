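"""Prior compositions and null-model moments.

The neutral null treats a sequence of length N as follows: the count of a
residue type X is binomial(N, pi_X), and given n observed residues of that
type their positions are uniform on 1..N.  Two positional conventions are
supported:

``iid_uniform``
    positions are n independent uniform draws (closed-form moments for the
    positional mean and its unbiased sample variance);
``srswor``
    positions are a simple random sample without replacement from 1..N
    (closed-form mean/variance for the positional mean; the variance of the
    sample variance is calibrated by Monte Carlo and cached).

The Type III (positional-variance) null mean defaults to the value implied
by the positional model; the verbal rule (N^2 - 1)/2 is available as
``type3_mean_rule="paper_literal"`` for fidelity checks only — it is far
from the sampling distribution of the unbiased variance of uniform
positions and destroys the mean-0/variance-1 calibration of the parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .seq_io import Alphabet, PROTEIN, SequenceRecord

logger = logging.getLogger(__name__)

#: Codon multiplicities of the standard genetic code (61 coding codons).
CODON_COUNTS = {
    "A": 4, "R": 6, "N": 2, "D": 2, "C": 2, "E": 2, "Q": 2, "G": 4,
    "H": 2, "I": 3, "L": 6, "K": 2, "M": 1, "F": 2, "P": 4, "S": 6,
    "T": 4, "W": 1, "Y": 2, "V": 4,
}
TOTAL_CODING_CODONS = 61

PRIOR_CONVENTIONS = ("codons_over_64", "codons_over_61", "dataset_frequency", "uniform")
POSITIONAL_MODELS = ("iid_uniform", "srswor")
TYPE3_MEAN_RULES = ("derived_from_positional_model", "paper_literal")

# Internal seed / replicate count for the cached srswor variance-of-variance
# calibration, fixed so feature vectors are reproducible run-to-run.
_MC_SEED = 20100219
_MC_REPS = 200_000


@dataclass(frozen=True)
class PriorComposition:
    """Null residue probabilities pi_X under a stated convention."""

    pi: dict[str, float]
    denominator_convention: str = "codons_over_64"

    def __post_init__(self) -> None:
        for sym, p in self.pi.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prior probability for {sym!r} must be in (0,1), got {p}")

    def renormalized(self) -> dict[str, float]:
        """Probabilities rescaled to sum to 1 (for sampling)."""
        total = sum(self.pi.values())
        return {sym: p / total for sym, p in self.pi.items()}

    def as_array(self, alphabet: Alphabet) -> np.ndarray:
        return np.array([self.pi[s] for s in alphabet.symbols], dtype=float)


@dataclass(frozen=True)
class NullConvention:
    """Configuration of the positional null and the Type III mean rule."""

    positional_model: str = "iid_uniform"
    type3_mean_rule: str = "derived_from_positional_model"

    def __post_init__(self) -> None:
        if self.positional_model not in POSITIONAL_MODELS:
            raise ValueError(f"positional_model must be one of {POSITIONAL_MODELS}")
        if self.type3_mean_rule not in TYPE3_MEAN_RULES:
            raise ValueError(f"type3_mean_rule must be one of {TYPE3_MEAN_RULES}")


DEFAULT_CONVENTION = NullConvention()


@dataclass(frozen=True)
class NullMoments:
    """Theoretical mean/variance pairs for the three measure types.

    ``var2`` is undefined (None) for n = 0; ``mean3``/``var3`` are undefined
    for n < 2 — downstream the corresponding parameters are set to 0.
    """

    mean1: float
    var1: float
    mean2: float
    var2: Optional[float]
    mean3: Optional[float]
    var3: Optional[float]


def codon_prior(denominator_convention: str = "codons_over_64") -> PriorComposition:
    """Prior from standard-genetic-code codon multiplicities.

    ``codons_over_64`` divides each count by 64 (so probabilities sum to
    61/64); ``codons_over_61`` divides by the 61 coding codons (sum 1).
    """
    if denominator_convention == "codons_over_64":
        denom = 64
    elif denominator_convention == "codons_over_61":
        denom = TOTAL_CODING_CODONS
    else:
        raise ValueError(
            f"codon prior supports codons_over_64/codons_over_61, got {denominator_convention!r}"
        )
    pi = {sym: count / denom for sym, count in CODON_COUNTS.items()}
    return PriorComposition(pi, denominator_convention)


def uniform_prior(alphabet: Alphabet) -> PriorComposition:
    """Uniform prior 1/|alphabet| per symbol (the default for DNA/RNA)."""
    p = 1.0 / len(alphabet)
    return PriorComposition({sym: p for sym in alphabet.symbols}, "uniform")


def dataset_prior(
    records: Iterable[SequenceRecord],
    alphabet: Alphabet = PROTEIN,
    floor: float = 1e-6,
) -> PriorComposition:
    """Prior from pooled residue frequencies across ``records``.

    Residues never observed get probability ``floor`` and the distribution
    is renormalized (logged), so every pi_X stays strictly inside (0,1).
    """
    records = list(records)
    if not records:
        raise ValueError("dataset prior needs at least one record")
    counts = {sym: 0 for sym in alphabet.symbols}
    total = 0
    for rec in records:
        for ch in rec.residues:
            counts[ch] += 1
        total += rec.N
    if total == 0:
        raise ValueError("dataset prior needs a positive pooled residue count")
    pi = {sym: c / total for sym, c in counts.items()}
    floored = [sym for sym, p in pi.items() if p == 0.0]
    if floored:
        logger.warning("residues %s unobserved; assigning floor %g and renormalizing", floored, floor)
        for sym in floored:
            pi[sym] = floor
        s = sum(pi.values())
        pi = {sym: p / s for sym, p in pi.items()}
    return PriorComposition(pi, "dataset_frequency")


def _positional_moments(
    N: int, n: int, convention: NullConvention
) -> tuple[float, Optional[float], Optional[float], Optional[float]]:
    """(mean2, var2, mean3, var3) for n positions on 1..N under the convention."""
    mean2 = (N + 1) / 2.0
    sigma2 = (N * N - 1) / 12.0  # variance of a single uniform position
    if convention.positional_model == "iid_uniform":
        var2 = sigma2 / n if n >= 1 else None
        mean3 = sigma2
        if n >= 2:
            mu4 = (N * N - 1) * (3 * N * N - 7) / 240.0
            var3 = mu4 / n - sigma2 * sigma2 * (n - 3) / (n * (n - 1))
        else:
            var3 = None
    else:  # srswor
        if n > N:
            raise ValueError(f"srswor cannot place n={n} positions in N={N} sites")
        var2 = (N + 1) * (N - n) / (12.0 * n) if n >= 1 else None
        mean3 = N * (N + 1) / 12.0
        if n >= 2:
            if n == N:
                var3 = 0.0  # all positions sampled: the variance is fixed
            else:
                var3 = _srswor_var3_cached(N, n)
        else:
            var3 = None
    if convention.type3_mean_rule == "paper_literal":
        mean3 = (N * N - 1) / 2.0
    elif n < 2:
        mean3 = None
    return mean2, var2, mean3, var3


def theoretical_moments(
    N: int, n: int, pi_X: float, convention: NullConvention = DEFAULT_CONVENTION
) -> NullMoments:
    """Null means/variances of the three measures for one residue type.

    Type I is the binomial proportion: mean pi_X, variance pi_X(1-pi_X)/N.
    Types II/III follow the positional convention (see module docstring).
    """
    if N < 1:
        raise ValueError(f"sequence length N must be >= 1, got {N}")
    if not 0 <= n <= N:
        raise ValueError(f"residue count n={n} must satisfy 0 <= n <= N={N}")
    if not 0.0 < pi_X < 1.0:
        raise ValueError(f"pi_X must be in (0,1), got {pi_X}")
    mean1 = pi_X
    var1 = pi_X * (1.0 - pi_X) / N
    mean2, var2, mean3, var3 = _positional_moments(N, n, convention)
    return NullMoments(mean1, var1, mean2, var2, mean3, var3)


def simulate_null_sequences(
    N: int,
    prior: PriorComposition,
    count: int,
    seed: int,
    alphabet: Alphabet = PROTEIN,
    id_prefix: str = "null",
) -> list[SequenceRecord]:
    """Draw ``count`` i.i.d. sequences of length N from the renormalized prior."""
    if N < 1:
        raise ValueError("sequence length must be >= 1")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    probs = np.array([prior.renormalized()[s] for s in alphabet.symbols])
    symbols = np.array(list(alphabet.symbols))
    draws = rng.choice(len(symbols), size=(count, N), p=probs)
    width = len(str(count))
    return [
        SequenceRecord(f"{id_prefix}_{i + 1:0{width}d}", "".join(symbols[row]))
        for i, row in enumerate(draws)
    ]


def calibrate_moments_mc(
    N: int,
    n: int,
    reps: int,
    seed: int,
    positional_model: str = "iid_uniform",
) -> dict[str, float]:
    """Monte Carlo moments of the positional mean and unbiased variance.

    Draws ``reps`` replicates of n positions on 1..N (with or without
    replacement) and returns the empirical ``mean2``/``var2`` of the
    positional mean and ``mean3``/``var3`` of the unbiased variance.
    Serves as the independent oracle for the analytic formulas.
    """
    if reps < 1000:
        raise ValueError("at least 1000 replicates required")
    if not 1 <= n <= N:
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    if positional_model not in POSITIONAL_MODELS:
        raise ValueError(f"positional_model must be one of {POSITIONAL_MODELS}")
    rng = np.random.default_rng(seed)
    means = np.empty(reps)
    variances = np.empty(reps) if n >= 2 else None
    batch = max(1, min(reps, int(4e7 // max(N, n))))
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        if positional_model == "iid_uniform":
            pos = rng.integers(1, N + 1, size=(b, n))
        else:
            # without replacement: argpartition of uniform keys per row
            keys = rng.random((b, N))
            pos = np.argpartition(keys, n - 1, axis=1)[:, :n] + 1
        means[done:done + b] = pos.mean(axis=1)
        if variances is not None:
            variances[done:done + b] = pos.var(axis=1, ddof=1)
        done += b
    out = {
        "mean2": float(means.mean()),
        "var2": float(means.var(ddof=1)),
    }
    if variances is not None:
        out["mean3"] = float(variances.mean())
        out["var3"] = float(variances.var(ddof=1))
    return out


_srswor_cache: dict[tuple[int, int], float] = {}


def _srswor_var3_cached(N: int, n: int) -> float:
    key = (N, n)
    if key not in _srswor_cache:
        mc = calibrate_moments_mc(N, n, _MC_REPS, _MC_SEED, positional_model="srswor")
        _srswor_cache[key] = mc["var3"]
    return _srswor_cache[key]
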