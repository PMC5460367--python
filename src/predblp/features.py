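"""Sequence-derived feature encoders.

Four blocks, concatenated in fixed order into one named feature vector:

* AAC - amino acid composition: 20 residue frequencies, count(i)/L.
* DC - dipeptide composition: 400 adjacent-pair frequencies,
  count(i,j)/(L-1), row-major with the first residue on the N-terminal side.
* MTF - binary presence of the catalog motifs (see :mod:`predblp.motifs`).
* PCP - nine physicochemical properties: the sequence-average of each
  residue scale, min-max normalised by the scale's own 20 values so every
  entry lies in [0, 1].

Feature names are stable string keys (``AAC:A``, ``DC:AR``, ``MTF:EHH``,
``PCP:polarity``) so selection masks survive serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import motifs as _motifs
from .seqio import STANDARD_AA, ProteinRecord, SequenceDataset

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
BLOCK_ORDER = ("AAC", "DC", "MTF", "PCP")

AAC_NAMES = [f"AAC:{a}" for a in STANDARD_AA]
DC_NAMES = [f"DC:{a}{b}" for a in STANDARD_AA for b in STANDARD_AA]


@dataclass
class PropertyTable:
    """Nine named residue scales, one value per standard amino acid."""

    table: pd.DataFrame  # index: property names, columns: the 20 residues

    def __post_init__(self) -> None:
        cols = list(self.table.columns)
        if cols != list(STANDARD_AA):
            raise ValueError(
                "property table columns must be the 20 standard residues "
                f"in order {STANDARD_AA}"
            )
        if len(self.table) != 9:
            raise ValueError(f"expected 9 properties, got {len(self.table)}")
        values = self.table.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("property table contains non-finite values")
        spans = values.max(axis=1) - values.min(axis=1)
        degenerate = self.table.index[spans <= 0].tolist()
        if degenerate:
            raise ValueError(f"degenerate (constant) scales: {degenerate}")

    @property
    def properties(self) -> list[str]:
        return list(self.table.index)

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        frame = pd.read_csv(path, sep="\t", comment="#", index_col="property")
        return cls(frame[list(STANDARD_AA)])


def load_property_table(path=None) -> PropertyTable:
    """The shipped default scales, or a user TSV with the same layout."""
    if path is not None:
        return PropertyTable.from_tsv(path)
    ref = resources.files("predblp.data").joinpath("pcp_scales.tsv")
    with resources.as_file(ref) as p:
        return PropertyTable.from_tsv(p)


@dataclass
class FeatureVector:
    """Named, ordered feature values for one protein."""

    names: list[str]
    values: np.ndarray
    blocks: dict[str, tuple[int, int]]  # block name -> [start, stop)

    def __len__(self) -> int:
        return len(self.names)

    def block_values(self, block: str) -> np.ndarray:
        start, stop = self.blocks[block]
        return self.values[start:stop]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def _aac_values(sequence: str) -> np.ndarray:
    counts = np.zeros(20)
    for c in sequence:
        counts[_AA_INDEX[c]] += 1
    return counts / len(sequence)


def _dc_values(sequence: str) -> np.ndarray:
    if len(sequence) < 2:
        raise ValueError("dipeptide composition undefined for L < 2")
    counts = np.zeros(400)
    idx = np.fromiter((_AA_INDEX[c] for c in sequence), dtype=np.intp,
                      count=len(sequence))
    np.add.at(counts, idx[:-1] * 20 + idx[1:], 1.0)
    return counts / (len(sequence) - 1)


def _pcp_values(sequence: str, table: PropertyTable) -> np.ndarray:
    scales = table.table.to_numpy(dtype=float)  # 9 x 20
    comp = _aac_values(sequence)  # sequence mean of scale = scale . composition
    means = scales @ comp
    lo = scales.min(axis=1)
    hi = scales.max(axis=1)
    return (means - lo) / (hi - lo)


def aac_features(record: ProteinRecord) -> FeatureVector:
    """Amino acid composition: 20 frequencies summing to one."""
    return FeatureVector(list(AAC_NAMES), _aac_values(record.sequence),
                         {"AAC": (0, 20)})


def dc_features(record: ProteinRecord) -> FeatureVector:
    """Dipeptide composition: 400 adjacent-pair frequencies over L-1 pairs."""
    return FeatureVector(list(DC_NAMES), _dc_values(record.sequence),
                         {"DC": (0, 400)})


def pcp_features(record: ProteinRecord, table: PropertyTable | None = None) -> FeatureVector:
    """Min-max-normalised sequence averages of the nine property scales."""
    table = table if table is not None else load_property_table()
    names = [f"PCP:{p}" for p in table.properties]
    return FeatureVector(names, _pcp_values(record.sequence, table),
                         {"PCP": (0, len(names))})


def assemble_features(
    record: ProteinRecord,
    motif_catalog: _motifs.MotifCatalog | None = None,
    table: PropertyTable | None = None,
    blocks=BLOCK_ORDER,
) -> FeatureVector:
    """Concatenate the requested blocks in fixed order AAC||DC||MTF||PCP."""
    unknown = set(blocks) - set(BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown feature blocks {sorted(unknown)}")
    wanted = [b for b in BLOCK_ORDER if b in blocks]
    names: list[str] = []
    chunks: list[np.ndarray] = []
    ranges: dict[str, tuple[int, int]] = {}
    for block in wanted:
        if block == "AAC":
            block_names, values = list(AAC_NAMES), _aac_values(record.sequence)
        elif block == "DC":
            block_names, values = list(DC_NAMES), _dc_values(record.sequence)
        elif block == "MTF":
            if motif_catalog is None or len(motif_catalog) == 0:
                raise ValueError("MTF block requested without a motif catalog")
            block_names, values = _motifs.mtf_features(record, motif_catalog)
        else:  # PCP
            table = table if table is not None else load_property_table()
            block_names = [f"PCP:{p}" for p in table.properties]
            values = _pcp_values(record.sequence, table)
        start = len(names)
        names.extend(block_names)
        chunks.append(values)
        ranges[block] = (start, len(names))
    return FeatureVector(names, np.concatenate(chunks), ranges)


def feature_matrix(
    data: SequenceDataset,
    motif_catalog: _motifs.MotifCatalog | None = None,
    table: PropertyTable | None = None,
    blocks=BLOCK_ORDER,
) -> pd.DataFrame:
    """Feature vectors for every record, as a DataFrame indexed by id."""
    if "PCP" in blocks and table is None:
        table = load_property_table()  # load once for the whole dataset
    rows = []
    names: list[str] = []
    for record in data:
        fv = assemble_features(record, motif_catalog, table, blocks)
        if not names:
            names = fv.names
        rows.append(fv.values)
    return pd.DataFrame(np.array(rows) if rows else np.empty((0, 0)),
                        index=data.ids(), columns=names)
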