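"""Dataset containers and readers for sequences and labeled interaction pairs.

Proteins arrive as FASTA records; interactions as three-column delimited
text (``id_a id_b label``).  A :class:`Dataset` bundles both and enforces
referential integrity: every identifier named by a pair must resolve to a
sequence record, and an unordered pair may carry only one label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

#: Standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes accepted on read with a warning.
NONSTANDARD_RESIDUES = frozenset("BJOUXZ")


class IntegrityError(ValueError):
    """Raised when a dataset violates a structural invariant."""


class PairParseError(ValueError):
    """Raised when a pair-list line cannot be parsed."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein identifier with its amino-acid sequence (stored upper-case)."""

    protein_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise IntegrityError("protein_id must be non-empty")
        if len(self.residues) < 1:
            raise IntegrityError(
                f"protein {self.protein_id!r} has an empty sequence"
            )


@dataclass(frozen=True)
class InteractionPair:
    """An unordered protein pair with a binary interaction label."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise PairParseError(
                f"label must be 0 or 1, got {self.label!r} for "
                f"({self.id_a}, {self.id_b})"
            )

    @property
    def key(self) -> frozenset:
        """Order-insensitive identity of the pair."""
        return frozenset((self.id_a, self.id_b))


@dataclass
class Dataset:
    """Sequence records plus labeled pairs, with referential integrity."""

    records: list[SequenceRecord]
    pairs: list[InteractionPair]
    name: str = "dataset"
    _by_id: dict[str, SequenceRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for rec in self.records:
            if rec.protein_id in self._by_id:
                raise IntegrityError(
                    f"duplicate protein identifier {rec.protein_id!r}"
                )
            self._by_id[rec.protein_id] = rec
        seen: dict[frozenset, int] = {}
        for pair in self.pairs:
            for pid in (pair.id_a, pair.id_b):
                if pid not in self._by_id:
                    raise IntegrityError(
                        f"pair references unknown protein {pid!r}"
                    )
            prior = seen.get(pair.key)
            if prior is not None and prior != pair.label:
                raise IntegrityError(
                    f"unordered pair ({pair.id_a}, {pair.id_b}) appears with "
                    f"conflicting labels"
                )
            seen[pair.key] = pair.label

    @property
    def node_ids(self) -> list[str]:
        """All protein identifiers, in record order."""
        return [rec.protein_id for rec in self.records]

    def record(self, protein_id: str) -> SequenceRecord:
        return self._by_id[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects.

    The header token up to the first whitespace becomes the identifier;
    multi-line sequences are joined and upper-cased.  Duplicate identifiers
    and empty files are integrity errors.  Non-standard residue letters
    (B, J, O, U, X, Z) are accepted with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise IntegrityError(f"duplicate protein identifier {pid!r}")
        seen.add(pid)
        residues = str(entry.seq).upper()
        odd = set(residues) & NONSTANDARD_RESIDUES
        if odd:
            log.warning(
                "protein %s contains non-standard residues %s",
                pid, "".join(sorted(odd)),
            )
        unknown = set(residues) - STANDARD_RESIDUES - NONSTANDARD_RESIDUES
        if unknown:
            raise IntegrityError(
                f"protein {pid!r} contains non-amino-acid symbols "
                f"{''.join(sorted(unknown))!r}"
            )
        records.append(SequenceRecord(pid, residues))
    if not records:
        raise IntegrityError(f"FASTA file {path} contains no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_pairs(path: str | Path,
               records: Sequence[SequenceRecord]) -> list[InteractionPair]:
    """Read a 3-column pair list, validating identifiers against *records*.

    Lines are whitespace- or tab-delimited; ``#`` starts a comment.  An
    unordered pair appearing with both labels is an integrity error; a
    duplicate with a consistent label is kept once.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    known = {rec.protein_id for rec in records}
    pairs: list[InteractionPair] = []
    seen: dict[frozenset, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise PairParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            id_a, id_b, label_str = fields
            try:
                label = int(label_str)
            except ValueError:
                raise PairParseError(
                    f"{path}:{lineno}: label {label_str!r} is not an integer"
                ) from None
            if label not in (0, 1):
                raise PairParseError(
                    f"{path}:{lineno}: label must be 0 or 1, got {label}"
                )
            for pid in (id_a, id_b):
                if pid not in known:
                    raise IntegrityError(
                        f"{path}:{lineno}: unknown protein identifier {pid!r}"
                    )
            pair = InteractionPair(id_a, id_b, label)
            prior = seen.get(pair.key)
            if prior is not None:
                if prior != label:
                    raise IntegrityError(
                        f"{path}:{lineno}: unordered pair ({id_a}, {id_b}) "
                        f"appears with conflicting labels"
                    )
                continue
            seen[pair.key] = label
            pairs.append(pair)
    return pairs


def write_pairs(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    """Write pairs as tab-delimited ``id_a  id_b  label`` lines."""
    with open(path, "w") as fh:
        for pair in pairs:
            fh.write(f"{pair.id_a}\t{pair.id_b}\t{pair.label}\n")


@dataclass(frozen=True)
class BenchmarkProfile:
    """Expected summary statistics of a benchmark deposit."""

    name: str
    total_pairs: int
    positive_pairs: int
    negative_pairs: int
    min_residue_length: int = 1


#: Published composition of the S. cerevisiae core benchmark: balanced
#: positives/negatives, proteins shorter than 50 residues removed upstream.
SCEREVISIAE_CORE = BenchmarkProfile(
    name="S. cerevisiae core",
    total_pairs=11188,
    positive_pairs=5594,
    negative_pairs=5594,
    min_residue_length=50,
)


def verify_benchmark(dataset: Dataset,
                     expected: BenchmarkProfile) -> dict[str, object]:
    """Compare a loaded dataset against a benchmark profile.

    Returns a report dict with observed counts and a boolean per check;
    failures are reported, never raised.
    """
    total = len(dataset.pairs)
    positives = sum(1 for p in dataset.pairs if p.label == 1)
    negatives = total - positives
    min_len = min(len(r.residues) for r in dataset.records)
    report = {
        "profile": expected.name,
        "total_pairs": total,
        "positive_pairs": positives,
        "negative_pairs": negatives,
        "min_residue_length": min_len,
        "check_total": total == expected.total_pairs,
        "check_positives": positives == expected.positive_pairs,
        "check_negatives": negatives == expected.negative_pairs,
        "check_min_length": min_len >= expected.min_residue_length,
    }
    report["all_passed"] = all(
        v for k, v in report.items() if k.startswith("check_")
    )
    return report


def format_report(report: Mapping[str, object]) -> str:
    """Render a verification report as ``key: value`` lines."""
    return "\n".join(f"{k}: {v}" for k, v in report.items())
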