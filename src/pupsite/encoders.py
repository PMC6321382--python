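"""Sequence feature encoders.

Five representations of a lysine-centered peptide window:

* **AAC** — amino acid composition: 20 residue frequencies over the non-'X'
  part of the window.
* **AAPC** — amino acid pair composition: 400 ordered adjacent-dipeptide
  frequencies (pairs containing 'X' are excluded from both numerator and
  denominator).
* **ANBPB** — adapted normal-distribution bi-profile Bayes: per-position
  residue counts tallied separately on positive and negative training
  windows, turned into posterior-like scores through the de Moivre-Laplace
  normal approximation of the binomial and the standard normal CDF.  A
  window of length L encodes to 2L components (positive profile then
  negative profile).
* **Top-n-gram** — per position of a residue frequency profile, the word of
  the n most frequent residues (descending frequency, alphabetical
  tie-break); features are normalized word occurrence counts.
* **PC-PseAAC** — parallel-correlation pseudo amino acid composition: AAC
  augmented with lambda sequence-order correlation factors computed from
  standardized hydrophobicity, hydrophilicity and side-chain mass.

All composition-style encoders ('X' excluded) emit vectors summing to 1;
every encoder is a pure function of its inputs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alphabet import (
    AA_INDEX,
    AA_PAIRS,
    ALPHABET,
    ALPHABET_INDEX,
    AMINO_ACIDS,
    PAD,
    PAIR_INDEX,
)
from .peptide_io import FeatureMatrix, PeptideWindow

logger = logging.getLogger(__name__)


def _seq(window: "PeptideWindow | str") -> tuple[str, str]:
    """Residue string and an identifier, from a window or a raw peptide."""
    if isinstance(window, str):
        bad = set(window) - set(ALPHABET)
        if bad:
            raise ValueError(f"invalid residues: {sorted(bad)}")
        return window, window
    return window.window, window.sample_id


AAC_FEATURES: list[str] = list(AMINO_ACIDS)
AAPC_FEATURES: list[str] = list(AA_PAIRS)


# ---------------------------------------------------------------------------
# AAC / AAPC
# ---------------------------------------------------------------------------

def encode_aac(window: PeptideWindow | str) -> np.ndarray:
    """20-component residue frequency vector, 'X' excluded from counts."""
    seq, ident = _seq(window)
    counts = np.zeros(20)
    for res in seq:
        if res != PAD:
            counts[AA_INDEX[res]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"window {ident}: all-'X' window has no composition"
        )
    return counts / total


def encode_aapc(window: PeptideWindow | str) -> np.ndarray:
    """400-component adjacent-dipeptide frequency vector.

    Adjacent pairs containing 'X' are excluded from numerator and
    denominator alike.
    """
    seq, ident = _seq(window)
    counts = np.zeros(400)
    n_valid = 0
    for a, b in zip(seq[:-1], seq[1:]):
        if a == PAD or b == PAD:
            continue
        counts[PAIR_INDEX[a + b]] += 1
        n_valid += 1
    if n_valid == 0:
        raise ValueError(
            f"window {ident}: no 'X'-free adjacent residue pair"
        )
    return counts / n_valid


# ---------------------------------------------------------------------------
# ANBPB
# ---------------------------------------------------------------------------

@dataclass
class ANBPBModel:
    """Positional residue-count profiles of the two training classes.

    Rows follow the 21-letter alphabet (20 amino acids + 'X') so padded
    windows encode without error; ``p`` is the per-residue baseline
    probability 1/21.
    """

    pos_counts: np.ndarray  # 21 x L
    neg_counts: np.ndarray  # 21 x L
    m_pos: int
    m_neg: int
    p: float = 1.0 / 21.0

    def __post_init__(self) -> None:
        self.pos_counts = np.asarray(self.pos_counts, dtype=float)
        self.neg_counts = np.asarray(self.neg_counts, dtype=float)
        if self.pos_counts.shape != self.neg_counts.shape:
            raise ValueError("positive/negative count shapes differ")
        if self.pos_counts.shape[0] != len(ALPHABET):
            raise ValueError("count matrices must have 21 residue rows")
        if not np.allclose(self.pos_counts.sum(axis=0), self.m_pos):
            raise ValueError("positive columns do not sum to m_pos")
        if not np.allclose(self.neg_counts.sum(axis=0), self.m_neg):
            raise ValueError("negative columns do not sum to m_neg")

    @property
    def window_length(self) -> int:
        return self.pos_counts.shape[1]


def _tally(windows: Sequence[PeptideWindow | str], length: int) -> np.ndarray:
    counts = np.zeros((len(ALPHABET), length))
    for w in windows:
        seq, ident = _seq(w)
        if len(seq) != length:
            raise ValueError(
                f"window {ident} has length {len(seq)}, expected {length}"
            )
        for j, res in enumerate(seq):
            counts[ALPHABET_INDEX[res], j] += 1
    return counts


def fit_anbpb(
    pos: Sequence[PeptideWindow], neg: Sequence[PeptideWindow]
) -> ANBPBModel:
    """Tally per-(residue, position) counts on each training class."""
    if not pos or not neg:
        raise ValueError("both training classes must be non-empty")
    length = len(_seq(pos[0])[0])
    return ANBPBModel(
        pos_counts=_tally(pos, length),
        neg_counts=_tally(neg, length),
        m_pos=len(pos),
        m_neg=len(neg),
    )


def encode_anbpb(
    model: ANBPBModel, window: PeptideWindow | str, v_mode: str = "binomial"
) -> np.ndarray:
    """2L-component positional posterior-like score vector.

    Component j is Phi((X_aj - m*p) / V_j) where X_aj is the training count
    of the window's residue a at position j, m the class sample count and
    Phi the standard normal CDF.  Positions 0..L-1 use the positive profile,
    L..2L-1 the negative one.  ``v_mode='binomial'`` (default) takes
    V_j = sqrt(m p (1-p)); ``'empirical'`` the population SD of the counts
    across residues at position j.
    """
    seq, _ = _seq(window)
    L = model.window_length
    if len(seq) != L:
        raise ValueError(
            f"window length {len(seq)} != model length {L}"
        )
    if v_mode not in ("binomial", "empirical"):
        raise ValueError(f"unknown v_mode {v_mode!r}")
    out = np.empty(2 * L)
    for block, (counts, m) in enumerate(
        [(model.pos_counts, model.m_pos), (model.neg_counts, model.m_neg)]
    ):
        mean = m * model.p
        if v_mode == "binomial":
            v = np.full(L, np.sqrt(m * model.p * (1.0 - model.p)))
        else:
            v = counts.std(axis=0, ddof=0)
            v[v == 0] = 1.0
        for j, res in enumerate(seq):
            i = ALPHABET_INDEX.get(res)
            if i is None:
                raise ValueError(f"residue {res!r} absent from model alphabet")
            z = (counts[i, j] - mean) / v[j]
            out[block * L + j] = norm.cdf(z)
    # Phi is strictly inside (0, 1); keep the encoding there despite
    # floating-point saturation at |z| beyond ~8
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def anbpb_feature_names(length: int) -> list[str]:
    return [f"pos{j + 1:02d}" for j in range(length)] + [
        f"neg{j + 1:02d}" for j in range(length)
    ]


# ---------------------------------------------------------------------------
# Residue profiles and Top-n-gram
# ---------------------------------------------------------------------------

@dataclass
class ResidueProfile:
    """L x 20 row-stochastic matrix of per-position residue frequencies."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 20:
            raise ValueError("profile must be an L x 20 matrix")
        if (self.freqs < 0).any():
            raise ValueError("profile frequencies must be non-negative")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


def profile_from_window(window: PeptideWindow | str) -> ResidueProfile:
    """One-hot profile; 'X' positions get the uniform 1/20 row.

    Stands in for an alignment-derived frequency profile when none is
    supplied.
    """
    seq, _ = _seq(window)
    freqs = np.zeros((len(seq), 20))
    for j, res in enumerate(seq):
        if res == PAD:
            freqs[j, :] = 1.0 / 20.0
        else:
            freqs[j, AA_INDEX[res]] = 1.0
    return ResidueProfile(freqs)


def top_n_gram_feature_names(n: int) -> list[str]:
    if n not in (1, 2):
        raise ValueError(f"top-n-gram supports n in {{1, 2}}, got {n}")
    return ["".join(t) for t in itertools.product(AMINO_ACIDS, repeat=n)]


def encode_top_n_gram(profile: ResidueProfile, n: int) -> np.ndarray:
    """20^n-component normalized occurrence counts of per-position words.

    The word at a position is formed from the n most frequent residues in
    descending frequency; ties are broken alphabetically.
    """
    if n not in (1, 2):
        raise ValueError(f"top-n-gram supports n in {{1, 2}}, got {n}")
    names = top_n_gram_feature_names(n)
    index = {w: i for i, w in enumerate(names)}
    counts = np.zeros(len(names))
    for row in profile.freqs:
        # sort by descending frequency, alphabetical within ties
        order = sorted(range(20), key=lambda i: (-row[i], AMINO_ACIDS[i]))
        word = "".join(AMINO_ACIDS[i] for i in order[:n])
        counts[index[word]] += 1
    return counts / profile.length


def write_profile(profile: ResidueProfile, path: str | Path) -> None:
    """Tab-separated, one row per position, 20 columns headed by residue."""
    pd.DataFrame(profile.freqs, columns=list(AMINO_ACIDS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_profile(path: str | Path) -> ResidueProfile:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(AMINO_ACIDS):
        raise ValueError(f"{path}: expected 20 residue columns")
    return ResidueProfile(df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# PC-PseAAC
# ---------------------------------------------------------------------------

@dataclass
class PropertyTables:
    """Raw (pre-standardization) per-residue physicochemical values."""

    hydrophobicity: dict[str, float]
    hydrophilicity: dict[str, float]
    side_chain_mass: dict[str, float]

    def __post_init__(self) -> None:
        for name, table in [
            ("hydrophobicity", self.hydrophobicity),
            ("hydrophilicity", self.hydrophilicity),
            ("side_chain_mass", self.side_chain_mass),
        ]:
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise ValueError(f"{name}: missing residues {sorted(missing)}")

    def standardized(self) -> np.ndarray:
        """3 x 20 matrix, each property centered and scaled by its
        population standard deviation over the 20 residues."""
        rows = []
        for table in (
            self.hydrophobicity,
            self.hydrophilicity,
            self.side_chain_mass,
        ):
            v = np.array([table[a] for a in AMINO_ACIDS])
            rows.append((v - v.mean()) / v.std(ddof=0))
        return np.vstack(rows)


def read_property_tables(path: str | Path) -> PropertyTables:
    df = pd.read_csv(path, sep="\t").set_index("aa")
    return PropertyTables(
        hydrophobicity=df["hydrophobicity"].to_dict(),
        hydrophilicity=df["hydrophilicity"].to_dict(),
        side_chain_mass=df["mass"].to_dict(),
    )


def load_default_property_tables() -> PropertyTables:
    """The canonical PseAAC hydrophobicity / hydrophilicity / side-chain
    mass tables shipped with the package."""
    ref = resources.files("pupsite").joinpath("data/pseaac_properties.tsv")
    with resources.as_file(ref) as path:
        return read_property_tables(path)


def encode_pc_pseaac(
    window: PeptideWindow | str,
    lam: int = 5,
    weight: float = 0.05,
    tables: PropertyTables | None = None,
) -> np.ndarray:
    """(20 + lam)-component pseudo amino acid composition.

    The first 20 components are residue frequencies and the last ``lam`` are
    tier correlation factors; both are divided by the shared denominator
    1 + weight * sum(theta), so the vector sums to 1.  The correlation
    function is the mean squared difference of the three standardized
    properties; tiers run over the non-'X' residue string.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight must be in [0, 1], got {weight}")
    if tables is None:
        tables = load_default_property_tables()
    raw, ident = _seq(window)
    seq = [r for r in raw if r != PAD]
    L = len(seq)
    if L == 0:
        raise ValueError(f"window {ident}: all-'X' window")
    if not 0 <= lam < L:
        raise ValueError(
            f"lambda must satisfy 0 <= lambda < effective length {L}, got {lam}"
        )
    props = tables.standardized()  # 3 x 20
    idx = np.array([AA_INDEX[r] for r in seq])
    vals = props[:, idx]  # 3 x L

    freqs = np.zeros(20)
    for i in idx:
        freqs[i] += 1
    freqs /= L

    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        diffs = vals[:, k:] - vals[:, :-k]  # 3 x (L-k)
        thetas[k - 1] = np.mean((diffs ** 2).mean(axis=0))
    denom = 1.0 + weight * thetas.sum()
    return np.concatenate([freqs / denom, weight * thetas / denom])


def pc_pseaac_feature_names(lam: int) -> list[str]:
    return list(AMINO_ACIDS) + [f"theta{k}" for k in range(1, lam + 1)]


# ---------------------------------------------------------------------------
# Matrix-level helpers and block concatenation
# ---------------------------------------------------------------------------

def _matrix(
    windows: Sequence[PeptideWindow], names: list[str], encode
) -> FeatureMatrix:
    values = np.vstack([encode(w) for w in windows]) if windows else np.empty((0, len(names)))
    return FeatureMatrix(
        sample_ids=[w.sample_id for w in windows],
        feature_names=names,
        values=values,
    )


def aac_matrix(windows: Sequence[PeptideWindow]) -> FeatureMatrix:
    return _matrix(windows, AAC_FEATURES, encode_aac)


def aapc_matrix(windows: Sequence[PeptideWindow]) -> FeatureMatrix:
    return _matrix(windows, AAPC_FEATURES, encode_aapc)


def anbpb_matrix(
    model: ANBPBModel,
    windows: Sequence[PeptideWindow],
    v_mode: str = "binomial",
) -> FeatureMatrix:
    return _matrix(
        windows,
        anbpb_feature_names(model.window_length),
        lambda w: encode_anbpb(model, w, v_mode=v_mode),
    )


def top_n_gram_matrix(
    windows: Sequence[PeptideWindow],
    n: int,
    profiles: Sequence[ResidueProfile] | None = None,
) -> FeatureMatrix:
    """Encode windows from supplied profiles, or one-hot fallbacks."""
    if profiles is None:
        profiles = [profile_from_window(w) for w in windows]
    if len(profiles) != len(windows):
        raise ValueError("one profile per window required")
    values = (
        np.vstack([encode_top_n_gram(p, n) for p in profiles])
        if windows
        else np.empty((0, 20 ** n))
    )
    return FeatureMatrix(
        sample_ids=[w.sample_id for w in windows],
        feature_names=top_n_gram_feature_names(n),
        values=values,
    )


def pc_pseaac_matrix(
    windows: Sequence[PeptideWindow],
    lam: int = 5,
    weight: float = 0.05,
    tables: PropertyTables | None = None,
) -> FeatureMatrix:
    if tables is None:
        tables = load_default_property_tables()
    return _matrix(
        windows,
        pc_pseaac_feature_names(lam),
        lambda w: encode_pc_pseaac(w, lam=lam, weight=weight, tables=tables),
    )


def combine_features(
    blocks: Sequence[tuple[str, FeatureMatrix]]
) -> FeatureMatrix:
    """Column-concatenate named feature blocks sharing a sample order.

    Feature names are prefixed with the block name so identical names in
    different blocks never collide silently.
    """
    if not blocks:
        raise ValueError("no feature blocks to combine")
    ref_ids = blocks[0][1].sample_ids
    for name, fm in blocks[1:]:
        if fm.sample_ids != ref_ids:
            raise ValueError(
                f"block {name!r}: sample order differs from first block"
            )
    names = [
        f"{block}:{feat}"
        for block, fm in blocks
        for feat in fm.feature_names
    ]
    values = np.hstack([fm.values for _, fm in blocks])
    return FeatureMatrix(list(ref_ids), names, values)
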