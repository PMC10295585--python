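"""Sequence/label I/O and deterministic dataset splitting.

Datasets are plain FASTA files plus a sidecar two-column TSV mapping
sequence id to functional class (e.g. ``tRNA``, ``miRNA``).  Class labels
may alternatively be carried in the FASTA header itself and extracted with
:func:`labels_from_headers`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "LabeledDataset",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "labels_from_headers",
    "stratified_split_indices",
    "split_dataset",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One ncRNA sequence: identifier, residues, optional class label."""

    id: str
    seq: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")


@dataclass
class LabeledDataset:
    """An ordered collection of records plus the closed class vocabulary."""

    records: list[SequenceRecord]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes[:5]}")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class vocabulary contains duplicates")
        known = set(self.classes)
        for r in self.records:
            if r.label is not None and r.label not in known:
                raise ValueError(f"label {r.label!r} of {r.id!r} not in class vocabulary")

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices], list(self.classes))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records.

    The header token up to the first whitespace becomes the id; sequences are
    uppercased; both T and U are accepted and preserved as read.  An entry
    with a header but no sequence lines is a parse error naming the header.
    """
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"FASTA entry {entry.id!r} has no sequence lines")
        records.append(SequenceRecord(id=entry.id, seq=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


def labels_from_headers(records: Sequence[SequenceRecord], delimiter: str = "|") -> dict[str, str]:
    """Extract ``{id_part: class_part}`` from ids shaped ``<id><delim><class>``."""
    mapping: dict[str, str] = {}
    for r in records:
        if delimiter not in r.id:
            raise ValueError(f"id {r.id!r} lacks the label delimiter {delimiter!r}")
        head, _, label = r.id.rpartition(delimiter)
        mapping[head] = label
    return mapping


def read_labels(path: str | Path, records: Sequence[SequenceRecord]) -> LabeledDataset:
    """Attach labels from a two-column TSV (id<TAB>class) to records.

    The class vocabulary becomes the sorted distinct labels.  Ids present in
    the table but absent from the records, or records without a label row,
    are errors.
    """
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            table[parts[0]] = parts[1]
    record_ids = {r.id for r in records}
    orphans = sorted(set(table) - record_ids)
    if orphans:
        raise ValueError(f"label table ids absent from sequences: {orphans[:10]}")
    missing = sorted(record_ids - set(table))
    if missing:
        raise ValueError(f"records without a label row: {missing[:10]}")
    labeled = [replace(r, label=table[r.id]) for r in records]
    classes = sorted(set(table.values()))
    return LabeledDataset(records=labeled, classes=classes)


def write_labels(ds: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ds.records:
            fh.write(f"{r.id}\t{r.label}\n")


def stratified_split_indices(
    labels: Sequence[str | None], fraction: float, seed: int
) -> tuple[list[int], list[int]]:
    """Index partition with round(fraction*N) items first, stratified by label.

    Per-class sample sizes follow largest-remainder allocation so the overall
    first-part size is exactly ``round(fraction * N)``.  Fully-None label
    lists fall back to a plain random split.  Seed-deterministic.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(labels)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    n_first = int(round(fraction * n))
    if n_first == 0 or n_first == n:
        raise ValueError(
            f"fraction {fraction} yields an empty part ({n_first} + {n - n_first} of {n})"
        )
    rng = np.random.default_rng(seed)
    if any(lab is None for lab in labels):
        order = rng.permutation(n)
        return sorted(order[:n_first].tolist()), sorted(order[n_first:].tolist())
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)  # type: ignore[arg-type]
    class_names = sorted(by_class)
    quota = {c: fraction * len(by_class[c]) for c in class_names}
    take = {c: int(np.floor(quota[c])) for c in class_names}
    short = n_first - sum(take.values())
    # distribute the remainder by largest fractional part, ties by name
    remainders = sorted(class_names, key=lambda c: (-(quota[c] - take[c]), c))
    for c in remainders[: max(short, 0)]:
        take[c] += 1
    first_idx: list[int] = []
    second_idx: list[int] = []
    for c in class_names:
        idx = np.array(by_class[c])
        perm = rng.permutation(len(idx))
        first_idx.extend(idx[perm[: take[c]]].tolist())
        second_idx.extend(idx[perm[take[c] :]].tolist())
    return sorted(first_idx), sorted(second_idx)


def split_dataset(
    ds: LabeledDataset, fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic stratified partition into (round(fraction*N), rest).

    Stratifies by class (proportional per-class sampling) so small
    validation splits never lose a class entirely; both parts share the
    parent class vocabulary.
    """
    first, second = stratified_split_indices(ds.labels(), fraction, seed)
    return ds.subset(first), ds.subset(second)
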