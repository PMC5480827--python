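"""The ESABO statistic and the pair-count algebra behind it.

ESABO (Entropy Shifts of Abundance Vectors under Boolean Operations) scores
the association between two species from their binarized abundance vectors
``b_i`` and ``b_j`` (presence/absence across samples).  The two vectors are
combined elementwise by a Boolean operation (AND by default) and the binary
entropy of the result is compared with a null ensemble in which ``b_j`` is
replaced by random permutations of itself.  The z-score

    z = (H_observed - mean_null) / std_null

is positive when co-occurrence is higher than random pairing predicts
(synergistic partners) and negative when it is lower (competitive partners).

Everything a pair contributes is captured by four co-occurrence counts
(alpha, beta, gamma, delta) = #(0,0), #(0,1), #(1,0), #(1,1); closed forms
for the counts after a Boolean operation, for the entropies, and for a
binomial co-occurrence z-score are provided alongside the permutation
statistic.  For the AND operation the permutation null is available in
closed form: the post-AND ones-count follows a hypergeometric law, so the
exact null mean and standard deviation are finite sums
(:func:`esabo_score_exact`), which serves as the oracle for the Monte-Carlo
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "PairCounts",
    "EsaboResult",
    "SUPPORTED_OPERATIONS",
    "binarize_table",
    "pair_counts",
    "boolean_combine",
    "shifted_pair_counts",
    "binary_entropy",
    "entropy_from_ones_fraction",
    "entropy_from_counts",
    "esabo_score",
    "esabo_score_exact",
    "cooccurrence_zscore",
    "cooccurrence_zscore_std",
    "jaccard_scores",
]

# Truth tables as output bits for the input pairs (0,0), (0,1), (1,0), (1,1).
# The six remaining two-argument Boolean functions (constants, projections and
# their complements) carry no pairwise information and are excluded.
_TRUTH_TABLES: dict[str, tuple[int, int, int, int]] = {
    "AND": (0, 0, 0, 1),
    "OR": (0, 1, 1, 1),
    "XOR": (0, 1, 1, 0),
    "NAND": (1, 1, 1, 0),
    "NOR": (1, 0, 0, 0),
    "EQL": (1, 0, 0, 1),
    "GT": (0, 0, 1, 0),
    "GE": (1, 0, 1, 1),
    "LT": (0, 1, 0, 0),
    "LE": (1, 1, 0, 1),
}
SUPPORTED_OPERATIONS = tuple(_TRUTH_TABLES)


@dataclass(frozen=True)
class PairCounts:
    """Joint presence/absence counts for a species pair.

    alpha = #samples with (0,0), beta = #(0,1), gamma = #(1,0),
    delta = #(1,1); the first coordinate refers to species i, the second to
    species j.  Dividing by ``n_samples`` gives the relative pair
    frequencies p_00, p_01, p_10, p_11.
    """

    alpha: int
    beta: int
    gamma: int
    delta: int

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_samples(self) -> int:
        return self.alpha + self.beta + self.gamma + self.delta

    @property
    def ones_i(self) -> int:
        """Marginal ones-count of species i."""
        return self.gamma + self.delta

    @property
    def ones_j(self) -> int:
        """Marginal ones-count of species j."""
        return self.beta + self.delta

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.alpha, self.beta, self.gamma, self.delta)


@dataclass(frozen=True)
class EsaboResult:
    """Observed entropy, permutation-null moments and z-score for one ordered pair."""

    observed_entropy: float
    null_mean: float
    null_std: float
    z_score: float  # NaN when the null is degenerate
    operation: str
    n_shuffles: int

    @property
    def is_defined(self) -> bool:
        return np.isfinite(self.z_score)


def _as_binary(vec, name: str = "vector") -> np.ndarray:
    arr = np.asarray(vec)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return arr.astype(np.int8)


def _check_pair(b_i, b_j) -> tuple[np.ndarray, np.ndarray]:
    b_i = _as_binary(b_i, "b_i")
    b_j = _as_binary(b_j, "b_j")
    if b_i.shape != b_j.shape:
        raise ValueError(f"length mismatch: {b_i.size} vs {b_j.size}")
    return b_i, b_j


def binarize_table(abundances: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Map a samples x taxa abundance table to presence/absence.

    An entry becomes 1 iff its abundance is >= ``threshold``.  The default
    threshold of 1 on count data maps zeros to absent and every positive
    count to present.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = abundances.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("abundance table must be numeric")
    if np.any(values < 0):
        raise ValueError("abundance table contains negative values")
    return pd.DataFrame(
        (values >= threshold).astype(np.int8),
        index=abundances.index,
        columns=abundances.columns,
    )


def pair_counts(b_i, b_j) -> PairCounts:
    """Tabulate the four joint outcomes of two binary vectors."""
    b_i, b_j = _check_pair(b_i, b_j)
    delta = int(np.sum(b_i & b_j))
    gamma = int(np.sum(b_i)) - delta
    beta = int(np.sum(b_j)) - delta
    alpha = b_i.size - beta - gamma - delta
    return PairCounts(alpha, beta, gamma, delta)


def _truth_table(op: str) -> tuple[int, int, int, int]:
    try:
        return _TRUTH_TABLES[op.upper()]
    except KeyError:
        raise ValueError(
            f"unknown operation {op!r}; supported: {', '.join(SUPPORTED_OPERATIONS)}"
        ) from None


def boolean_combine(b_i, b_j, op: str = "AND") -> np.ndarray:
    """Elementwise Boolean combination of two binary vectors."""
    b_i, b_j = _check_pair(b_i, b_j)
    table = np.array(_truth_table(op), dtype=np.int8)
    return table[2 * b_i + b_j]


def shifted_pair_counts(counts: PairCounts, op: str = "AND") -> PairCounts:
    """Joint counts of (b_i OP b_j, b_j) from the pre-operation counts.

    The Boolean operation only relabels the four joint cells, so the shifted
    counts are an exact bookkeeping: e.g. AND sends the gamma cell (1,0) to
    (0,0), giving (alpha+gamma, beta, 0, delta).  The total is conserved.
    """
    t00, t01, t10, t11 = _truth_table(op)
    # key = (result bit, b_j bit); each original cell lands in exactly one
    out = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 0}
    out[(t00, 0)] += counts.alpha
    out[(t01, 1)] += counts.beta
    out[(t10, 0)] += counts.gamma
    out[(t11, 1)] += counts.delta
    return PairCounts(out[(0, 0)], out[(0, 1)], out[(1, 0)], out[(1, 1)])


def entropy_from_ones_fraction(p: float | np.ndarray) -> float | np.ndarray:
    """Binary entropy H(p) = -p ln p - (1-p) ln(1-p) in nats, with 0 ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("ones-fraction must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) - np.where(
            p < 1, (1 - p) * np.log(1 - p), 0.0
        )
    return float(h) if h.ndim == 0 else h


def binary_entropy(vector) -> float:
    """Entropy (nats) of the 0/1 frequency distribution of a binary vector."""
    vec = _as_binary(vector)
    return float(entropy_from_ones_fraction(vec.mean()))


def entropy_from_counts(counts: PairCounts) -> float:
    """Entropy of species i's abundance vector from pair counts.

    The ones-fraction of b_i is (gamma + delta) / n; applying this to
    post-operation counts gives the entropy of the combined vector.
    """
    if counts.n_samples == 0:
        raise ValueError("empty pair counts")
    return float(entropy_from_ones_fraction(counts.ones_i / counts.n_samples))


def esabo_score(
    b_i,
    b_j,
    op: str = "AND",
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> EsaboResult:
    """ESABO z-score of one ordered pair against a permutation null.

    The observed statistic is the binary entropy of ``b_i OP b_j``.  The
    null ensemble recomputes it with ``b_j`` replaced by ``n_shuffles``
    uniform random permutations of itself (``b_i`` fixed, so both marginal
    compositions are preserved).  A degenerate null (zero spread, e.g. a
    constant ``b_j``) yields a NaN z-score flagged via ``is_defined``.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    b_i, b_j = _check_pair(b_i, b_j)
    t00, t01, t10, t11 = _truth_table(op)
    n = b_i.size
    observed = binary_entropy(boolean_combine(b_i, b_j, op))
    rng = np.random.default_rng(seed)
    # Permute b_j by ranking i.i.d. uniform keys; all n! orders equally likely.
    order = np.argsort(rng.random((n_shuffles, n)), axis=1)
    shuffled = b_j[order]
    overlap = (shuffled & b_i).sum(axis=1, dtype=np.int64)  # per-shuffle delta
    k_i = int(b_i.sum())
    k_j = int(b_j.sum())
    # ones-count of the combined vector is linear in the joint cell counts
    ones = (
        t11 * overlap
        + t10 * (k_i - overlap)
        + t01 * (k_j - overlap)
        + t00 * (n - k_i - k_j + overlap)
    )
    null_h = entropy_from_ones_fraction(ones / n)
    null_mean = float(null_h.mean())
    null_std = float(null_h.std(ddof=0))
    z = (observed - null_mean) / null_std if null_std > 0 else float("nan")
    return EsaboResult(observed, null_mean, null_std, z, op.upper(), n_shuffles)


def esabo_score_exact(b_i, b_j) -> EsaboResult:
    """Exact permutation-null ESABO score for the AND operation.

    Under a uniform permutation of ``b_j`` the post-AND ones-count follows a
    hypergeometric distribution (draw the positions of b_j's ones among the
    n sample slots; count hits among b_i's ones).  Null mean and standard
    deviation of the entropy are therefore exact finite sums over the
    hypergeometric support — the oracle against which the Monte-Carlo score
    converges.
    """
    b_i, b_j = _check_pair(b_i, b_j)
    n = b_i.size
    k_i = int(b_i.sum())
    k_j = int(b_j.sum())
    observed = binary_entropy(b_i & b_j)
    lo = max(0, k_i + k_j - n)
    hi = min(k_i, k_j)
    support = np.arange(lo, hi + 1)
    if support.size < 2:
        return EsaboResult(observed, observed, 0.0, float("nan"), "AND", 0)
    pmf = hypergeom(n, k_i, k_j).pmf(support)
    h = entropy_from_ones_fraction(support / n)
    null_mean = float(np.sum(pmf * h))
    null_var = float(np.sum(pmf * h**2) - null_mean**2)
    null_std = float(np.sqrt(max(null_var, 0.0)))
    z = (observed - null_mean) / null_std if null_std > 0 else float("nan")
    return EsaboResult(observed, null_mean, null_std, z, "AND", 0)


def cooccurrence_zscore(counts: PairCounts) -> tuple[float, float, float]:
    """Binomial co-occurrence score in the as-printed convention.

    Placing species i's ones-count among species j's slots at random gives
    expectation (gamma+delta)(beta+delta)/n for the (1,1) count delta and
    variance (gamma+delta)(beta+delta)(alpha+gamma)/n^2.  The returned z
    divides the deviation by the *variance* — the convention used in the
    worked co-abundance analyses this mirrors; see
    :func:`cooccurrence_zscore_std` for the standard-deviation-normalized
    variant.

    Returns ``(expectation, variance, z)``.
    """
    n = counts.n_samples
    if n == 0:
        raise ValueError("empty pair counts")
    expectation = counts.ones_i * counts.ones_j / n
    variance = counts.ones_i * counts.ones_j * (counts.alpha + counts.gamma) / n**2
    if variance == 0:
        return expectation, variance, float("nan")
    z = (counts.delta - expectation) / variance
    return expectation, variance, z


def cooccurrence_zscore_std(counts: PairCounts) -> tuple[float, float, float]:
    """Co-occurrence z-score normalized by the standard deviation.

    Same expectation and variance as :func:`cooccurrence_zscore`, but
    ``z = (delta - expectation) / sqrt(variance)`` — the statistically
    conventional scaling.
    """
    expectation, variance, _ = cooccurrence_zscore(counts)
    if variance == 0:
        return expectation, variance, float("nan")
    return expectation, variance, (counts.delta - expectation) / np.sqrt(variance)


def jaccard_scores(b_i, b_j) -> tuple[float, float]:
    """Binary Jaccard-style indices for co-presence and co-absence.

    ``j11`` normalizes the (1,1) frequency by the smaller marginal
    ones-count; ``j00`` normalizes the (0,0) frequency by the smaller
    marginal zeros-count.  A score whose normalizer vanishes (a constant
    vector) is returned as NaN.
    """
    c = pair_counts(b_i, b_j)
    min_ones = min(c.ones_i, c.ones_j)
    min_zeros = min(c.alpha + c.beta, c.alpha + c.gamma)
    j11 = c.delta / min_ones if min_ones > 0 else float("nan")
    j00 = c.alpha / min_zeros if min_zeros > 0 else float("nan")
    return j11, j00
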