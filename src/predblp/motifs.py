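"""Gapped-motif discovery by difference of information gains (DIG).

The search space is small gapped patterns: k in {2, 3, 4} literal residues
with at most one wildcard between consecutive literals (a ``-`` in the
printed form, e.g. ``L-S-GR``); pure dipeptides (k=2, no gap) are excluded
because adjacent pairs already live in the dipeptide-composition block.

A pattern is a candidate motif when the fraction of positive (BLP)
sequences containing it exceeds the occurrence threshold T (default 10%).
Candidates are scored by DIG: with H0 the binary class entropy of the
pooled set, IG_B is the information gained by splitting off the positives
containing the pattern, IG_N the gain from splitting off the negatives
containing it, and DIG = IG_B - IG_N.  DIG is zero for patterns that are
absent everywhere or equally frequent in both classes, and approaches one
bit for a pattern covering every positive and no negative of a balanced
set.  The top-k patterns by DIG (default 10) form the motif catalog that
backs the binary MTF feature block.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
import pandas as pd

from .seqio import STANDARD_AA, SequenceDataset

_STANDARD_SET = frozenset(STANDARD_AA)

MAX_LITERALS = 4
MAX_SPAN = 7
DEFAULT_THRESHOLD = 0.10
DEFAULT_TOP_K = 10


@dataclass(frozen=True)
class MotifPattern:
    """k literal residues separated by 0- or 1-residue wildcard gaps."""

    literals: tuple[str, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.literals)
        if not 2 <= k <= MAX_LITERALS:
            raise ValueError(f"pattern needs 2..{MAX_LITERALS} literals, got {k}")
        if len(self.gaps) != k - 1:
            raise ValueError("need exactly k-1 gaps")
        if any(g not in (0, 1) for g in self.gaps):
            raise ValueError("each gap must be 0 or 1")
        if k == 2 and self.gaps != (1,):
            raise ValueError(
                "two-literal patterns must be gapped (pure dipeptides belong "
                "to the DC block)"
            )
        bad = set(self.literals) - _STANDARD_SET
        if bad:
            raise ValueError(f"non-standard literals {sorted(bad)}")
        if self.span > MAX_SPAN:
            raise ValueError(f"pattern span {self.span} exceeds {MAX_SPAN}")

    @property
    def span(self) -> int:
        return len(self.literals) + sum(self.gaps)

    @property
    def offsets(self) -> tuple[int, ...]:
        out = [0]
        for g in self.gaps:
            out.append(out[-1] + 1 + g)
        return tuple(out)

    def format(self) -> str:
        parts = [self.literals[0]]
        for g, lit in zip(self.gaps, self.literals[1:]):
            parts.append("-" * g + lit)
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


def parse_pattern(text: str) -> MotifPattern:
    """Parse the printed grammar: letters are literals, '-' one wildcard."""
    if not re.fullmatch(r"[A-Z](-?[A-Z])*", text or ""):
        raise ValueError(f"invalid motif string {text!r}")
    literals: list[str] = []
    gaps: list[int] = []
    pending_gap = 0
    for ch in text:
        if ch == "-":
            pending_gap += 1
        else:
            if literals:
                gaps.append(pending_gap)
            literals.append(ch)
            pending_gap = 0
    return MotifPattern(tuple(literals), tuple(gaps))


def format_pattern(pattern: MotifPattern) -> str:
    return pattern.format()


@lru_cache(maxsize=None)
def _compiled(formatted: str):
    rx = "".join("." if c == "-" else c for c in formatted)
    return re.compile(rx)


def matches(pattern: MotifPattern, sequence: str) -> bool:
    """True iff some window aligns the literals exactly, wildcards free."""
    return _compiled(pattern.format()).search(sequence) is not None


# --- pattern-space enumeration -------------------------------------------

def _gap_choices(k: int) -> list[tuple[int, ...]]:
    if k == 2:
        return [(1,)]
    return [g for g in product((0, 1), repeat=k - 1)]


#: (gaps, offsets) for every admissible literal-count/gap combination
_COMBOS: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
for _k in range(2, MAX_LITERALS + 1):
    for _gaps in _gap_choices(_k):
        _offs = [0]
        for _g in _gaps:
            _offs.append(_offs[-1] + 1 + _g)
        _COMBOS.append((_gaps, tuple(_offs)))


def iter_pattern_space(k: int):
    """All patterns with exactly ``k`` literals (brute-force enumeration)."""
    for gaps in _gap_choices(k):
        for lits in product(STANDARD_AA, repeat=k):
            yield MotifPattern(lits, gaps)


def presence_counts(sequences) -> dict[MotifPattern, int]:
    """Per-sequence presence counts of every pattern occurring in ``sequences``.

    Counts sequences containing at least one match, not occurrences.
    """
    counts: dict[tuple, int] = {}
    for seq in sequences:
        found = set()
        for ci, (_, offsets) in enumerate(_COMBOS):
            for lits in zip(*(seq[o:] for o in offsets)):
                found.add((ci, lits))
        for key in found:
            counts[key] = counts.get(key, 0) + 1
    return {
        MotifPattern(lits, _COMBOS[ci][0]): n for (ci, lits), n in counts.items()
    }


def enumerate_patterns(positives: SequenceDataset, threshold_T: float = DEFAULT_THRESHOLD):
    """Yield every pattern whose positive-class presence frequency exceeds T,
    in deterministic (lexicographic) order."""
    if len(positives) == 0:
        raise ValueError("positives must be non-empty")
    seqs = [r.sequence for r in positives]
    n = len(seqs)
    counts = presence_counts(seqs)
    passing = [p for p, c in counts.items() if c / n > threshold_T]
    yield from sorted(passing, key=lambda p: p.format())


# --- DIG scoring ----------------------------------------------------------

def _h2(p: float) -> float:
    """Binary entropy in bits, with 0*log0 = 0."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def _dig_from_counts(n_pos: int, n_neg: int, a: int, b: int) -> float:
    """DIG from the 2x2 presence table.

    a = positives containing the pattern, b = negatives containing it.
    The split {positives with P} vs rest leaves a pure group of size a and a
    remainder of n_pos - a positives and n_neg negatives (and symmetrically
    for the negative split), so DIG reduces to the difference of the two
    conditional entropies.
    """
    n = n_pos + n_neg
    rest_b = n - a
    cond_b = (rest_b / n) * _h2((n_pos - a) / rest_b) if rest_b else 0.0
    rest_n = n - b
    cond_n = (rest_n / n) * _h2(n_pos / rest_n) if rest_n else 0.0
    return cond_n - cond_b


def dig_score(
    pattern: MotifPattern, positives: SequenceDataset, negatives: SequenceDataset
) -> float:
    """Difference of information gains of ``pattern`` between the classes."""
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("dig_score requires both classes non-empty")
    a = sum(matches(pattern, r.sequence) for r in positives)
    b = sum(matches(pattern, r.sequence) for r in negatives)
    return _dig_from_counts(len(positives), len(negatives), a, b)


@dataclass
class MotifEntry:
    pattern: MotifPattern
    dig: float
    freq_pos: float
    freq_neg: float


@dataclass
class MotifCatalog:
    """Top motifs sorted by DIG descending (ties: lexicographic pattern)."""

    entries: list[MotifEntry] = field(default_factory=list)
    threshold_T: float = DEFAULT_THRESHOLD
    top_k: int = DEFAULT_TOP_K

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def patterns(self) -> list[MotifPattern]:
        return [e.pattern for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pattern": e.pattern.format(),
                    "dig": e.dig,
                    "freq_pos": e.freq_pos,
                    "freq_neg": e.freq_neg,
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, threshold_T=DEFAULT_THRESHOLD, top_k=DEFAULT_TOP_K):
        frame = pd.read_csv(path, sep="\t")
        entries = [
            MotifEntry(parse_pattern(row["pattern"]), float(row["dig"]),
                       float(row["freq_pos"]), float(row["freq_neg"]))
            for _, row in frame.iterrows()
        ]
        return cls(entries, threshold_T=threshold_T, top_k=top_k)


def discover_motifs(
    positives: SequenceDataset,
    negatives: SequenceDataset,
    threshold_T: float = DEFAULT_THRESHOLD,
    top_k: int = DEFAULT_TOP_K,
) -> MotifCatalog:
    """Score every candidate pattern by DIG and keep the top ``top_k``."""
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("discover_motifs requires both classes non-empty")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    n_pos, n_neg = len(positives), len(negatives)
    pos_counts = presence_counts([r.sequence for r in positives])
    neg_counts = presence_counts([r.sequence for r in negatives])
    scored = []
    for pattern, a in pos_counts.items():
        if a / n_pos <= threshold_T:
            continue
        b = neg_counts.get(pattern, 0)
        dig = _dig_from_counts(n_pos, n_neg, a, b)
        scored.append(MotifEntry(pattern, dig, a / n_pos, b / n_neg))
    scored.sort(key=lambda e: (-e.dig, e.pattern.format()))
    if len(scored) < top_k:
        warnings.warn(
            f"only {len(scored)} candidate motifs exceed the {threshold_T:.0%} "
            f"occurrence threshold (requested top {top_k})",
            stacklevel=2,
        )
    return MotifCatalog(scored[:top_k], threshold_T=threshold_T, top_k=top_k)


def mtf_features(record, catalog: MotifCatalog):
    """Binary presence vector over the catalog, in catalog order."""
    if len(catalog) == 0:
        raise ValueError("mtf_features requires a non-empty catalog")
    values = np.array(
        [1.0 if matches(e.pattern, record.sequence) else 0.0 for e in catalog]
    )
    names = [f"MTF:{e.pattern.format()}" for e in catalog]
    return names, values
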