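"""Synthetic miRNA-family fixtures for testing the full pipeline.

Emulates the family-size structure of a curated miRNA database: many
families (the biggest holding up to ~200 members, most far smaller),
where members of a family differ from a common ancestor mostly by point
substitutions at this sequence length (18–25 nt). A second pool of
"unlabeled" families mimics unclassified mature sequences: their records
carry the UNCLASSIFIED sentinel, but the true family is retained
separately so novel-family recovery can be scored.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    UNCLASSIFIED,
    SequenceRecord,
    write_family_table,
    write_fasta,
)

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    family_size_range defaults to [4, 200] with sizes drawn from a
    truncated geometric distribution (p = 0.15), so most families are
    small — mirroring real family-size skew; set min == max for fixed
    sizes. substitution_rate is the per-site probability that a member
    differs from its family ancestor (default 0.05). Ancestors are
    resampled until no two equal-length ancestors are within Hamming
    distance 3, which keeps families separable at low rates.
    """

    n_families: int = 10
    family_size_range: tuple[int, int] = (4, 200)
    length_range: tuple[int, int] = (18, 25)
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    n_unlabeled_families: int = 0
    unlabeled_size_range: tuple[int, int] = (4, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 0 or self.n_unlabeled_families < 0:
            raise ValueError("family counts must be non-negative")
        for lo, hi, name in (
            (*self.family_size_range, "family_size_range"),
            (*self.length_range, "length_range"),
            (*self.unlabeled_size_range, "unlabeled_size_range"),
        ):
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid {name}: [{lo}, {hi}]")
        for rate, name in (
            (self.substitution_rate, "substitution_rate"),
            (self.indel_rate, "indel_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _draw_size(rng: np.random.Generator, lo: int, hi: int, p: float = 0.15) -> int:
    """Truncated-geometric family size in [lo, hi] (skewed small)."""
    if lo == hi:
        return lo
    while True:
        size = lo + rng.geometric(p) - 1
        if size <= hi:
            return int(size)


def _draw_ancestor(
    rng: np.random.Generator,
    length_range: tuple[int, int],
    existing: list[str],
    min_hamming: int = 3,
    max_tries: int = 1000,
) -> str:
    """A random ancestor far (Hamming > min_hamming) from same-length peers."""
    for _ in range(max_tries):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(_BASES[rng.integers(0, 4, size=L)])
        ok = all(
            len(other) != L
            or sum(a != b for a, b in zip(seq, other)) > min_hamming
            for other in existing
        )
        if ok:
            return seq
    raise RuntimeError(
        "could not draw a sufficiently distinct ancestor; "
        "sequence space too crowded for the requested family count"
    )


def _mutate(rng: np.random.Generator, ancestor: str, rate: float, indel_rate: float) -> str:
    codes = np.array(list(ancestor))
    if rate > 0:
        hit = rng.random(codes.size) < rate
        for pos in np.flatnonzero(hit):
            choices = [b for b in "ACGU" if b != codes[pos]]
            codes[pos] = choices[int(rng.integers(0, 3))]
    seq = "".join(codes)
    if indel_rate > 0:
        out = []
        for ch in seq:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(ch)
            if r > 1 - indel_rate / 2:
                out.append(_BASES[int(rng.integers(0, 4))])  # insertion
        seq = "".join(out) or seq[:1]
    return seq


def generate(spec: SyntheticSpec) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate labeled records and the ground-truth id→family mapping.

    Labeled families are named ``fam0001``…; unlabeled families are
    named ``novel0001``… in the truth mapping while their records carry
    the UNCLASSIFIED sentinel.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    ancestors: list[str] = []

    def add_family(name: str, size: int, labeled: bool) -> None:
        ancestor = _draw_ancestor(rng, spec.length_range, ancestors)
        ancestors.append(ancestor)
        for m in range(1, size + 1):
            seq = _mutate(rng, ancestor, spec.substitution_rate, spec.indel_rate)
            rec_id = f"{name}-{m:03d}"
            label = name if labeled else UNCLASSIFIED
            records.append(SequenceRecord(rec_id, seq, label))
            truth[rec_id] = name

    for i in range(1, spec.n_families + 1):
        add_family(
            f"fam{i:04d}",
            _draw_size(rng, *spec.family_size_range),
            labeled=True,
        )
    for i in range(1, spec.n_unlabeled_families + 1):
        add_family(
            f"novel{i:04d}",
            _draw_size(rng, *spec.unlabeled_size_range),
            labeled=False,
        )
    return records, truth


def write_fixture(
    records: list[SequenceRecord],
    truth: dict[str, str],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a fixture: sequences.fasta, labels.tsv (with sentinel rows),
    truth.tsv (true families for every record). Returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "sequences.fasta",
        "labels": out_dir / "labels.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(records, paths["fasta"])
    write_family_table({r.id: r.family for r in records}, paths["labels"])
    write_family_table(truth, paths["truth"])
    return paths
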