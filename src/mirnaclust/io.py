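"""Reading and writing sequences, family labels, and pipeline outputs.

Mature miRNA sequences arrive as FASTA (RNA or DNA alphabet); family
membership arrives either as a two-column TSV (id, family) or as a
miFam-style flat file of ``ID``/``MI`` stanzas terminated by ``//``.
All outputs are UTF-8 text with ``\\n`` line endings and a fixed column
order so identical inputs produce identical bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Sentinel family label for sequences with no known family.
UNCLASSIFIED = "UNCLASSIFIED"

RNA_ALPHABET = frozenset("ACGU")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One mature miRNA sequence.

    Attributes
    ----------
    id : str
        Unique identifier (e.g. ``hsa-let-7a``).
    seq : str
        RNA string over ``{A, C, G, U}``.
    family : str
        Family label, or :data:`UNCLASSIFIED` when unknown.
    """

    id: str
    seq: str
    family: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(normalize input first)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def is_classified(self) -> bool:
        return self.family != UNCLASSIFIED


@dataclass
class Dataset:
    """An ordered collection of records; row order of all matrices downstream."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def families(self) -> set[str]:
        """Distinct non-sentinel family labels."""
        return {r.family for r in self.records if r.is_classified}

    @property
    def n_families(self) -> int:
        """Count of distinct known families; seeds the cluster-number sweep."""
        return len(self.families)

    def with_labels(self, labels: Mapping[str, str]) -> "Dataset":
        """Return a copy with family labels applied; missing ids → sentinel."""
        return Dataset(
            [
                SequenceRecord(r.id, r.seq, labels.get(r.id, UNCLASSIFIED))
                for r in self.records
            ]
        )


def _normalize_seq(raw: str, rec_id: str, policy: str) -> str | None:
    """Uppercase, map T→U, and apply the ambiguity policy.

    Returns None when the record should be dropped (permissive policy).
    """
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if not bad:
        return seq
    if policy == "strict":
        raise FastaParseError(
            f"record {rec_id!r}: invalid characters {sorted(bad)}"
        )
    logger.warning(
        "dropping record %r: ambiguous/invalid characters %s", rec_id, sorted(bad)
    )
    return None


def read_fasta(
    path: str | Path, alphabet_policy: str = "map_t_to_u_skip_ambiguous"
) -> list[SequenceRecord]:
    """Read mature sequences from a FASTA file.

    Parameters
    ----------
    path
        FASTA file, wrapped or unwrapped lines, DNA or RNA alphabet.
    alphabet_policy
        ``"map_t_to_u_skip_ambiguous"`` (default): lowercase is uppercased,
        T becomes U, and records still containing characters outside
        A/C/G/U (ambiguity codes such as N) are dropped with a warning.
        ``"strict"``: such records raise :class:`FastaParseError`.
    """
    if alphabet_policy not in ("strict", "map_t_to_u_skip_ambiguous"):
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    path = Path(path)
    if path.stat().st_size == 0:
        raise FastaParseError(f"{path}: empty FASTA file")
    # Reject bodies before any header with a line number; Bio.SeqIO is
    # silent about them.
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first header"
                )
            break
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        seq = _normalize_seq(str(rec.seq), rec.id, alphabet_policy)
        if seq is None:
            continue
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_family_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sequence id to family name.

    A header line is tolerated (detected as first line whose second column
    is literally ``family``). Repeating an id with the same family is
    idempotent; with a conflicting family it is an error.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            seq_id, family = parts[0].strip(), parts[1].strip()
            if lineno == 1 and family.lower() == "family":
                continue
            if seq_id in mapping and mapping[seq_id] != family:
                raise ValueError(
                    f"{path}:{lineno}: id {seq_id!r} mapped to both "
                    f"{mapping[seq_id]!r} and {family!r}"
                )
            mapping[seq_id] = family
    return mapping


def write_family_table(labels: Mapping[str, str], path: str | Path) -> None:
    """Write an id→family mapping as a two-column TSV (input order preserved)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tfamily\n")
        for seq_id, family in labels.items():
            fh.write(f"{seq_id}\t{family}\n")


def read_mifam(path: str | Path) -> dict[str, str]:
    """Parse a miFam-style family flat file.

    Stanzas look like::

        ID   let-7
        MI   MI0000060   hsa-let-7a
        MI   MI0000063   hsa-let-7c
        //

    Every member id maps to its stanza's family name. A member appearing
    in two stanzas is an error; a missing final ``//`` is accepted with a
    warning.
    """
    mapping: dict[str, str] = {}
    current_family: str | None = None
    open_stanza = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("//"):
                current_family = None
                open_stanza = False
                continue
            fields = line.split()
            tag = fields[0]
            if tag == "ID":
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: ID line without a name")
                current_family = fields[1]
                open_stanza = True
            elif tag == "MI":
                if current_family is None:
                    raise ValueError(f"{path}:{lineno}: MI line before any ID line")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: MI line needs accession and member id"
                    )
                member = fields[2]
                if member in mapping and mapping[member] != current_family:
                    raise ValueError(
                        f"{path}:{lineno}: member {member!r} appears in both "
                        f"{mapping[member]!r} and {current_family!r}"
                    )
                mapping[member] = current_family
            # other tags (AC, DE, ...) are ignored
    if open_stanza:
        logger.warning("%s: final stanza not terminated by '//'", path)
    return mapping


def write_assignments(clustering, dataset: Dataset, report, path: str | Path) -> None:
    """Write per-sequence cluster assignments as TSV.

    Columns: id, cluster_index, assigned_family_or_NONE, correct_flag.
    The assigned family is the family the member's cluster was credited
    to (its own family when credited, else NONE); correct_flag is 1 when
    the member was counted correct by the vote strategy.
    """
    correct_ids = set(report.correct_ids) if report is not None else set()
    credited = report.credited_families_by_cluster if report is not None else {}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tcluster\tassigned_family\tcorrect\n")
        for row, rec in enumerate(dataset.records):
            c = int(clustering.labels[row])
            fams = credited.get(c, ())
            assigned = rec.family if rec.family in fams else "NONE"
            flag = 1 if rec.id in correct_ids else 0
            fh.write(f"{rec.id}\t{c}\t{assigned}\t{flag}\n")


def write_report(report, path: str | Path) -> None:
    """Write an :class:`~mirnaclust.evaluation.EvaluationReport` as JSON."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
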