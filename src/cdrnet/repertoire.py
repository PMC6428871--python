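"""Clone tables: reading, validation, filtering and public-clone detection.

A *clone* is an equivalence class of antibody sequences sharing 100% CDR3
amino-acid identity; it is the node of every similarity network built
downstream.  Input rows with identical ``cdr3_aa`` are therefore collapsed
by summing their counts, regardless of V-gene annotation (the V gene is
carried along as a label only).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 20 standard amino acids.  Ambiguity codes (X, *, _) are rejected:
#: the Levenshtein metric used downstream is defined over this alphabet only.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Column names per supported input dialect: (sequence, count, v_gene).
_DIALECTS = {
    "airr": ("junction_aa", "duplicate_count", "v_call"),
    "mixcr": ("aaSeqCDR3", "cloneCount", "bestVGene"),
    "csv": ("cdr3_aa", "count", "v_gene"),
}


class CloneValidationError(ValueError):
    """A clone record violates the alphabet or count constraints."""


class CloneTableFormatError(ValueError):
    """An input table is missing required columns for its dialect."""


def validate_sequence(seq: str) -> str:
    """Return ``seq`` uppercased, raising if empty or outside the alphabet."""
    if not isinstance(seq, str) or not seq:
        raise CloneValidationError(f"empty or non-string CDR3 sequence: {seq!r}")
    s = seq.upper()
    bad = set(s) - AMINO_ACIDS
    if bad:
        raise CloneValidationError(
            f"non-amino-acid character(s) {sorted(bad)} in CDR3 {seq!r}"
        )
    return s


@dataclass(frozen=True)
class CloneRecord:
    """One clone: a unique CDR3 amino-acid string with its read count."""

    cdr3_aa: str
    count: int
    v_gene: str | None = None
    frequency: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cdr3_aa", validate_sequence(self.cdr3_aa))
        if int(self.count) < 1:
            raise CloneValidationError(
                f"count must be >= 1, got {self.count} for {self.cdr3_aa}"
            )
        object.__setattr__(self, "count", int(self.count))


@dataclass
class Repertoire:
    """One sample's set of unique CDR3 clones.

    ``clones`` is ordered (node indices downstream follow this order) and
    ``cdr3_aa`` values are unique within the repertoire.
    """

    sample_id: str
    clones: list[CloneRecord] = field(default_factory=list)
    cohort: str | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        seqs = [c.cdr3_aa for c in self.clones]
        if len(set(seqs)) != len(seqs):
            dup = [s for s, n in Counter(seqs).items() if n > 1]
            raise CloneValidationError(
                f"duplicate cdr3_aa in repertoire {self.sample_id}: {dup[:5]}"
            )

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def sequences(self) -> list[str]:
        return [c.cdr3_aa for c in self.clones]

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clones], dtype=np.int64)

    @property
    def frequencies(self) -> np.ndarray:
        """Clone frequencies; computed from counts when not supplied."""
        stored = [c.frequency for c in self.clones]
        if all(f is not None for f in stored) and stored:
            return np.array(stored, dtype=float)
        counts = self.counts
        total = counts.sum()
        return counts / total if total > 0 else counts.astype(float)

    def sequence_set(self) -> frozenset[str]:
        return frozenset(c.cdr3_aa for c in self.clones)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cdr3_aa": self.sequences,
                "count": self.counts,
                "v_gene": [c.v_gene for c in self.clones],
            }
        )


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_repertoire`."""

    n_input: int
    n_kept: int
    n_removed_short: int
    n_removed_rare: int


@dataclass
class PublicCloneSet:
    """CDR3 sequences present in at least two repertoires of a cohort."""

    cohort: str
    clones: frozenset[str]
    per_clone_sharing: dict[str, int]

    def __contains__(self, seq: str) -> bool:
        return seq in self.clones

    def __len__(self) -> int:
        return len(self.clones)


def _collapse(rows: Iterable[tuple[str, int, str | None]]) -> list[CloneRecord]:
    """Collapse rows with identical cdr3_aa by summing counts (100% identity
    clone definition).  First-seen order and first-seen V gene are kept, so
    the result is independent of how duplicated rows are interleaved."""
    counts: dict[str, int] = {}
    vgenes: dict[str, str | None] = {}
    for seq, count, vg in rows:
        seq = validate_sequence(seq)
        if int(count) < 1:
            raise CloneValidationError(f"count must be >= 1, got {count} for {seq}")
        counts[seq] = counts.get(seq, 0) + int(count)
        if seq not in vgenes or vgenes[seq] is None:
            vgenes[seq] = vg
    return [CloneRecord(s, c, vgenes[s]) for s, c in counts.items()]


def read_clone_table(
    path: str | Path,
    format: str = "csv",
    sample_id: str | None = None,
    cohort: str | None = None,
    stage: str | None = None,
) -> Repertoire:
    """Read a clone table (AIRR TSV, MiXCR export TSV, or plain CSV).

    Rows of identical CDR3 amino-acid sequence are collapsed by summing
    counts.  Row order does not affect the resulting repertoire apart from
    first-seen clone order.
    """
    if format not in _DIALECTS:
        raise CloneTableFormatError(
            f"unknown format {format!r}; expected one of {sorted(_DIALECTS)}"
        )
    path = Path(path)
    seq_col, count_col, v_col = _DIALECTS[format]
    sep = "," if format == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (seq_col, count_col):
        if col not in df.columns:
            raise CloneTableFormatError(
                f"{path.name}: missing required column {col!r} for format {format!r}"
            )
    has_v = v_col in df.columns
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        seq = getattr(row, seq_col)
        raw_count = getattr(row, count_col)
        try:
            count = int(float(raw_count))
            rows.append((seq, count, getattr(row, v_col) if has_v else None))
        except CloneValidationError as err:
            raise CloneValidationError(f"{path.name} row {i}: {err}") from err
        except (TypeError, ValueError) as err:
            raise CloneValidationError(
                f"{path.name} row {i}: bad count {raw_count!r}"
            ) from err
    try:
        clones = _collapse(rows)
    except CloneValidationError as err:
        raise CloneValidationError(f"{path.name}: {err}") from err
    return Repertoire(
        sample_id=sample_id or path.stem, clones=clones, cohort=cohort, stage=stage
    )


def write_clone_csv(rep: Repertoire, path: str | Path) -> Path:
    """Write the canonical clone CSV (cdr3_aa,count,v_gene)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cdr3_aa", "count", "v_gene"])
        for c in rep.clones:
            writer.writerow([c.cdr3_aa, c.count, c.v_gene or ""])
    return path


def filter_repertoire(
    rep: Repertoire, min_len: int = 4, min_count: int = 2
) -> tuple[Repertoire, FilterReport]:
    """Apply the standard clone filters: CDR3 length >= ``min_len`` amino
    acids and count >= ``min_count`` (defaults keep clones of length >= 4
    that occurred more than once).

    Returns the filtered repertoire plus a report of removals per criterion
    (a clone failing both is counted under both).
    """
    if min_len < 1 or min_count < 1:
        raise ValueError("min_len and min_count must be >= 1")
    kept, n_short, n_rare = [], 0, 0
    for c in rep.clones:
        short = len(c.cdr3_aa) < min_len
        rare = c.count < min_count
        n_short += short
        n_rare += rare
        if not (short or rare):
            kept.append(c)
    report = FilterReport(len(rep.clones), len(kept), n_short, n_rare)
    filtered = replace(rep, clones=kept)
    return filtered, report


def find_public_clones(
    reps: Sequence[Repertoire], cohort: str | None = None
) -> PublicCloneSet:
    """Identify public clones: CDR3 sequences present in >= 2 repertoires.

    Sharing is counted per repertoire (subject), not per read.  Clones found
    in a single repertoire are private by definition.
    """
    if len(reps) < 2:
        raise ValueError("public-clone detection requires at least 2 repertoires")
    sharing: Counter[str] = Counter()
    for rep in reps:
        sharing.update(rep.sequence_set())
    public = {s: n for s, n in sharing.items() if n >= 2}
    name = cohort or (reps[0].cohort or "cohort")
    return PublicCloneSet(
        cohort=name, clones=frozenset(public), per_clone_sharing=public
    )
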