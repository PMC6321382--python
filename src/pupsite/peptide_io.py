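"""Sequence and window I/O.

Proteins are read from FASTA; candidate sites are lysine-centered peptide
windows of odd length 2w+1 (default w=10, length 21) padded with 'X' where
the context runs past a protein terminus.  Positions are 1-based in every
user-facing table and 0-based internally.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import ALPHABET, AMINO_ACIDS, PAD

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"
LABELS = (POSITIVE, NEGATIVE, UNKNOWN)

DEFAULT_HALF_WIDTH = 10


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter alphabet (unknowns as 'X')."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: residues outside alphabet: {sorted(bad)}"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length peptide window centered on a candidate lysine.

    ``site_pos`` is the 1-based position of the center residue in the parent
    protein; ``window`` has odd length 2w+1 with 'K' at the center and 'X'
    padding where the window extends past either terminus.
    """

    protein_id: str
    site_pos: int
    window: str
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        L = len(self.window)
        if L < 3 or L % 2 == 0:
            raise ValueError(
                f"window for {self.protein_id}:{self.site_pos} must have odd "
                f"length >= 3, got {L}"
            )
        bad = set(self.window) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"window for {self.protein_id}:{self.site_pos} contains "
                f"invalid residues: {sorted(bad)}"
            )
        if self.window[L // 2] != "K":
            raise ValueError(
                f"window for {self.protein_id}:{self.site_pos} is not centered "
                f"on 'K': {self.window}"
            )
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.site_pos < 1:
            raise ValueError("site_pos is 1-based and must be >= 1")

    @property
    def half_width(self) -> int:
        return len(self.window) // 2

    @property
    def sample_id(self) -> str:
        return f"{self.protein_id}:{self.site_pos}"


@dataclass
class SiteDataset:
    """An ordered collection of peptide windows with label bookkeeping."""

    windows: list[PeptideWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        lengths = {len(w.window) for w in self.windows}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent window lengths: {sorted(lengths)}")
        for w in self.windows:
            key = (w.protein_id, w.site_pos)
            if key in seen:
                raise ValueError(f"duplicate window {key[0]}:{key[1]}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(w.label for w in self.windows)
        return {lab: c.get(lab, 0) for lab in LABELS}

    @property
    def window_length(self) -> int | None:
        return len(self.windows[0].window) if self.windows else None

    def subset(self, label: str) -> list[PeptideWindow]:
        return [w for w in self.windows if w.label == label]

    @property
    def positives(self) -> list[PeptideWindow]:
        return self.subset(POSITIVE)

    @property
    def negatives(self) -> list[PeptideWindow]:
        return self.subset(NEGATIVE)

    def labels_array(self) -> np.ndarray:
        """Binary labels (1 = positive, 0 = negative); errors on 'unknown'."""
        out = np.empty(len(self.windows), dtype=int)
        for i, w in enumerate(self.windows):
            if w.label == UNKNOWN:
                raise ValueError(f"window {w.sample_id} has unknown label")
            out[i] = 1 if w.label == POSITIVE else 0
        return out


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file.

    Sequences are upper-cased; characters outside the 20-letter amino-acid
    alphabet (including 'X' itself, which is kept) are replaced by 'X' with a
    logged warning.  Duplicate ids and empty files are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in ALPHABET else PAD for c in seq)
        n_replaced = sum(1 for a, b in zip(seq, cleaned) if a != b)
        if n_replaced:
            logger.warning(
                "protein %s: %d non-standard residues replaced by 'X'",
                rec.id,
                n_replaced,
            )
        records.append(ProteinRecord(rec.id, cleaned))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def extract_windows(
    protein: ProteinRecord,
    positive_sites: Iterable[int] = (),
    half_width: int = DEFAULT_HALF_WIDTH,
) -> list[PeptideWindow]:
    """Extract one window per lysine in the protein.

    ``positive_sites`` are 1-based positions of annotated sites; each must
    point at a 'K'.  All other lysines are labeled negative.  Windows at the
    termini are padded with 'X' to length ``2 * half_width + 1``.
    """
    seq = protein.sequence
    pos_set = set(positive_sites)
    for p in sorted(pos_set):
        if p < 1 or p > len(seq) or seq[p - 1] != "K":
            raise ValueError(
                f"protein {protein.id!r}: annotated site {p} is not a lysine"
            )
    out: list[PeptideWindow] = []
    for i, res in enumerate(seq):  # i is 0-based
        if res != "K":
            continue
        left = seq[max(0, i - half_width) : i]
        right = seq[i + 1 : i + 1 + half_width]
        window = (
            PAD * (half_width - len(left))
            + left
            + "K"
            + right
            + PAD * (half_width - len(right))
        )
        label = POSITIVE if (i + 1) in pos_set else NEGATIVE
        out.append(PeptideWindow(protein.id, i + 1, window, label))
    return out


_TABLE_COLUMNS = ["protein_id", "site_pos", "window", "label"]


def read_window_table(path: str | Path) -> SiteDataset:
    """Read a tab-separated window table (protein_id, site_pos, window, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _TABLE_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {_TABLE_COLUMNS}, got {list(df.columns)}"
        )
    windows = [
        PeptideWindow(r.protein_id, int(r.site_pos), r.window, r.label)
        for r in df.itertuples(index=False)
    ]
    return SiteDataset(windows)


def write_window_table(dataset: SiteDataset, path: str | Path) -> None:
    """Write a window table; ``read_window_table`` round-trips it exactly."""
    lines = ["\t".join(_TABLE_COLUMNS)]
    for w in dataset.windows:
        lines.append(f"{w.protein_id}\t{w.site_pos}\t{w.window}\t{w.label}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class FeatureMatrix:
    """A named-column numeric matrix with rows aligned to a sample list.

    Every encoder emits one; every learner consumes one.  Feature names are
    unique; sample order is significant and preserved by all operations.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} rows but {len(self.sample_ids)} sample ids"
            )
        if d != len(self.feature_names):
            raise ValueError(
                f"{d} columns but {len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != d:
            dupes = [f for f, c in Counter(self.feature_names).items() if c > 1]
            raise ValueError(f"duplicate feature names: {dupes[:5]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_names,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(
            sample_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset, in the given order."""
        idx = {f: i for i, f in enumerate(self.feature_names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        cols = [idx[n] for n in names]
        return FeatureMatrix(
            list(self.sample_ids), list(names), self.values[:, cols]
        )

    def take(self, rows: Sequence[int]) -> "FeatureMatrix":
        """Row subset by positional index, in the given order."""
        rows = list(rows)
        return FeatureMatrix(
            [self.sample_ids[i] for i in rows],
            list(self.feature_names),
            self.values[np.asarray(rows, dtype=int), :],
        )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Comma-separated text: first column sample id, header of feature names."""
    fm.to_frame().to_csv(path, lineterminator="\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    return FeatureMatrix.from_frame(df)
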