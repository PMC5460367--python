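"""Reading, validation and partitioning of labelled protein sequence datasets.

Datasets are plain FASTA files; class labels (1 = bioluminescent protein,
0 = non-BLP) and lineage tags travel in a sidecar TSV with columns
``id``, ``label`` and optionally ``lineage``.  Records may be unlabelled
(prediction mode).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)
LINEAGES = ("bacteria", "eukaryota", "archaea", "unknown")

#: dipeptide composition needs at least one adjacent pair
MIN_LENGTH = 2


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; names the offending line."""


@dataclass
class ProteinRecord:
    """One protein sequence with optional class label and lineage tag."""

    id: str
    sequence: str
    label: int | None = None
    lineage: str = "unknown"
    n_dropped: int = 0  # non-standard residues removed during sanitization

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {sorted(bad)} "
                "(sanitize first)"
            )
        if len(self.sequence) < MIN_LENGTH:
            raise ValueError(
                f"record {self.id!r}: sequence shorter than {MIN_LENGTH} residues"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")
        if self.lineage not in LINEAGES:
            raise ValueError(f"record {self.id!r}: unknown lineage {self.lineage!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDataset:
    """An ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> ProteinRecord:
        return self.records[i]

    @property
    def positive_count(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def negative_count(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        """Label vector of the labelled records, in dataset order."""
        return np.array([r.label for r in self.records if r.label is not None])

    def positives(self) -> "SequenceDataset":
        return SequenceDataset([r for r in self.records if r.label == 1])

    def negatives(self) -> "SequenceDataset":
        return SequenceDataset([r for r in self.records if r.label == 0])

    def subset(self, ids) -> "SequenceDataset":
        """Records whose id is in ``ids``, preserving dataset order."""
        wanted = set(ids)
        return SequenceDataset([r for r in self.records if r.id in wanted])

    def filter_lineage(self, lineage: str) -> "SequenceDataset":
        return SequenceDataset([r for r in self.records if r.lineage == lineage])


def sanitize_sequence(raw: str, policy: str = "drop") -> str:
    """Uppercase ``raw`` and resolve non-standard residues.

    policy="drop" removes B, J, O, U, X, Z, gap and whitespace characters and
    warns with the removal count; policy="reject" raises on the first
    non-standard character.
    """
    if policy not in ("drop", "reject"):
        raise ValueError(f"unknown sanitization policy {policy!r}")
    up = raw.upper()
    kept = [c for c in up if c in _STANDARD_SET]
    if policy == "reject":
        bad = [c for c in up if c not in _STANDARD_SET]
        if bad:
            raise ValueError(f"non-standard residue {bad[0]!r} with policy='reject'")
    n_removed = len(up) - len(kept)
    if n_removed:
        warnings.warn(
            f"dropped {n_removed} non-standard residue(s) from sequence",
            stacklevel=2,
        )
    clean = "".join(kept)
    if not clean:
        raise ValueError("no usable residues left after sanitization")
    return clean


def read_label_table(path) -> pd.DataFrame:
    """Sidecar TSV with columns id, label in {1,0} and optional lineage."""
    table = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = {"id", "label"} - set(table.columns)
    if missing:
        raise ValueError(f"label table {path}: missing columns {sorted(missing)}")
    if not table["label"].isin([0, 1]).all():
        raise ValueError(f"label table {path}: labels must be 0 or 1")
    if "lineage" not in table.columns:
        table["lineage"] = "unknown"
    table["lineage"] = table["lineage"].fillna("unknown")
    bad = set(table["lineage"]) - set(LINEAGES)
    if bad:
        raise ValueError(f"label table {path}: unknown lineages {sorted(bad)}")
    return table.set_index("id")


def read_fasta(
    path,
    labels=None,
    policy: str = "drop",
    header_regex: str | None = None,
) -> SequenceDataset:
    """Read a FASTA file (optionally joining a sidecar label table by id).

    ``header_regex`` is an escape hatch for datasets that carry labels in the
    FASTA header: a regex with named groups ``label`` and/or ``lineage``
    applied to each record description.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty file")

    label_map = read_label_table(labels) if labels is not None else None
    rx = re.compile(header_regex) if header_regex else None

    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq)
        clean = sanitize_sequence(raw, policy=policy)
        n_dropped = len(raw) - len(clean)
        label: int | None = None
        lineage = "unknown"
        if rx is not None:
            m = rx.search(entry.description)
            if m:
                gd = m.groupdict()
                if gd.get("label") is not None:
                    label = int(gd["label"])
                if gd.get("lineage") is not None:
                    lineage = gd["lineage"]
        if label_map is not None and entry.id in label_map.index:
            row = label_map.loc[entry.id]
            label = int(row["label"])
            lineage = str(row["lineage"])
        records.append(
            ProteinRecord(entry.id, clean, label=label, lineage=lineage,
                          n_dropped=n_dropped)
        )
    return SequenceDataset(records)


def write_fasta(data: SequenceDataset, fasta_path, labels_path=None, width: int = 60):
    """Write FASTA (wrapped at ``width``) and, optionally, the label TSV."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in data.records
    ]
    with open(fasta_path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(entries)
    if labels_path is not None:
        rows = [
            {"id": r.id, "label": r.label, "lineage": r.lineage}
            for r in data.records
            if r.label is not None
        ]
        pd.DataFrame(rows, columns=["id", "label", "lineage"]).to_csv(
            labels_path, sep="\t", index=False
        )


def split_train_test(
    data: SequenceDataset, train_fraction: float, seed: int
) -> tuple[SequenceDataset, SequenceDataset]:
    """Balanced training draw: round(fraction x positives) positives plus an
    equal number of sampled negatives; everything else is the test set."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    pos_ids = [r.id for r in data.records if r.label == 1]
    neg_ids = [r.id for r in data.records if r.label == 0]
    if not pos_ids or not neg_ids:
        raise ValueError("split_train_test requires both classes")
    n_train = round(train_fraction * len(pos_ids))
    if n_train < 1:
        raise ValueError("train_fraction too small: no positives selected")
    if n_train > len(neg_ids):
        raise ValueError(
            f"cannot draw {n_train} negatives to balance the training set "
            f"(only {len(neg_ids)} available)"
        )
    rng = np.random.default_rng(seed)
    train_pos = set(rng.choice(pos_ids, size=n_train, replace=False))
    train_neg = set(rng.choice(neg_ids, size=n_train, replace=False))
    train_ids = train_pos | train_neg
    train = data.subset(train_ids)
    test = SequenceDataset([r for r in data.records if r.id not in train_ids])
    return train, test


def undersample_balanced(data: SequenceDataset, seed: int) -> SequenceDataset:
    """All of the minority class plus an equal-size uniform sample of the
    majority class; returns exactly 2 x min(pos, neg) records."""
    pos_ids = [r.id for r in data.records if r.label == 1]
    neg_ids = [r.id for r in data.records if r.label == 0]
    if not pos_ids or not neg_ids:
        raise ValueError("undersample_balanced requires both classes")
    rng = np.random.default_rng(seed)
    if len(pos_ids) <= len(neg_ids):
        minority, majority = pos_ids, neg_ids
    else:
        minority, majority = neg_ids, pos_ids
    sampled = set(rng.choice(majority, size=len(minority), replace=False))
    keep = set(minority) | sampled
    return data.subset(keep)
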