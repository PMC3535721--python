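"""n-gram (GramN) feature vectors for mature miRNA sequences.

A sequence of length L contains L − n + 1 overlapping n-grams over the
RNA alphabet. GramN concatenates, for n = 1..N, the 4^n per-word
frequency blocks (lexicographic order A < C < G < U within each block).
Each block is normalized to sum to 1 and scaled by a per-block weight;
with weights summing to 1 every feature row sums to 1, making sequences
of different lengths directly comparable.

Optionally the seed region (1-based positions 2–8 by default, the
primary target-recognition segment of a mature miRNA) is emphasized by
counting n-grams fully contained in it twice before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import SequenceRecord

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def feature_dimension(max_n: int) -> int:
    """Total GramN dimension: sum of 4^n for n = 1..max_n (340 for N=4)."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    return sum(4**n for n in range(1, max_n + 1))


@dataclass(frozen=True)
class FeatureSpec:
    """Configuration for GramN featurization.

    Parameters
    ----------
    max_n : int
        Largest n-gram order N (4 for Gram4, 5 for Gram5).
    block_weights : tuple of float, optional
        One positive weight per n-block, summing to 1. Default: uniform
        1/max_n per block.
    seed_boost : bool
        Double-count n-grams lying entirely inside ``seed_range``.
    seed_range : (int, int)
        1-based inclusive positions of the seed region.
    """

    max_n: int = 4
    block_weights: tuple[float, ...] | None = None
    seed_boost: bool = False
    seed_range: tuple[int, int] = (2, 8)

    def __post_init__(self) -> None:
        if self.max_n < 1:
            raise ValueError("max_n must be >= 1")
        weights = self.block_weights
        if weights is None:
            weights = tuple(1.0 / self.max_n for _ in range(self.max_n))
            object.__setattr__(self, "block_weights", weights)
        else:
            weights = tuple(float(w) for w in weights)
            object.__setattr__(self, "block_weights", weights)
        if len(weights) != self.max_n:
            raise ValueError("block_weights must have max_n entries")
        if any(w <= 0 for w in weights):
            raise ValueError("block_weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise ValueError("block_weights must sum to 1")
        lo, hi = self.seed_range
        if not (1 <= lo <= hi):
            raise ValueError("seed_range must be 1-based inclusive with lo <= hi")

    @property
    def dimension(self) -> int:
        return feature_dimension(self.max_n)


@dataclass
class FeatureMatrix:
    """Row-stochastic GramN matrix; rows follow record order."""

    values: np.ndarray
    row_ids: list[str]
    spec: FeatureSpec = field(default_factory=FeatureSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length must match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def count_ngrams(seq: str, n: int) -> np.ndarray:
    """Occurrence counts of all 4^n words in ``seq``, lexicographic order.

    Overlapping occurrences all count; the counts sum to len(seq) − n + 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(seq) < n:
        raise ValueError(f"sequence length {len(seq)} < n={n}")
    try:
        codes = np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}; expected A/C/G/U") from None
    # rolling base-4 word index
    idx = np.zeros(len(seq) - n + 1, dtype=np.int64)
    for j in range(n):
        idx = idx * 4 + codes[j : j + len(idx)]
    return np.bincount(idx, minlength=4**n)


def _seed_ngram_counts(seq: str, n: int, seed_range: tuple[int, int]) -> np.ndarray:
    """Counts restricted to n-grams fully inside the 1-based seed range."""
    lo, hi = seed_range
    start = max(lo, 1)
    stop = min(hi, len(seq))  # inclusive
    if stop - start + 1 < n:
        return np.zeros(4**n, dtype=np.int64)
    return count_ngrams(seq[start - 1 : stop], n)


def featurize(records: Sequence[SequenceRecord], spec: FeatureSpec) -> FeatureMatrix:
    """Convert records to a GramN :class:`FeatureMatrix`.

    Per sequence and per n, counts are normalized to frequencies and the
    block scaled by its weight; blocks are concatenated in increasing n.
    Every row sums to 1. With ``seed_boost``, seed-contained n-grams are
    counted twice before normalization, which shifts mass toward seed
    words while preserving the row sum.
    """
    short = [r.id for r in records if r.length < spec.max_n]
    if short:
        raise ValueError(
            f"records shorter than max_n={spec.max_n}: {short[:5]}"
        )
    rows = np.zeros((len(records), spec.dimension), dtype=float)
    offsets = np.cumsum([0] + [4**n for n in range(1, spec.max_n + 1)])
    for i, rec in enumerate(records):
        for n in range(1, spec.max_n + 1):
            counts = count_ngrams(rec.seq, n).astype(float)
            if spec.seed_boost:
                counts += _seed_ngram_counts(rec.seq, n, spec.seed_range)
            total = counts.sum()
            block = counts / total if total > 0 else counts
            rows[i, offsets[n - 1] : offsets[n]] = spec.block_weights[n - 1] * block
    return FeatureMatrix(rows, [r.id for r in records], spec)


def ngram_words(n: int) -> list[str]:
    """The 4^n words of length n in lexicographic order (column labels)."""
    bases = "ACGU"
    words = [""]
    for _ in range(n):
        words = [w + b for w in words for b in bases]
    return words


def feature_names(spec: FeatureSpec) -> list[str]:
    """Column labels for a GramN matrix, block order matching featurize."""
    names: list[str] = []
    for n in range(1, spec.max_n + 1):
        names.extend(ngram_words(n))
    return names
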