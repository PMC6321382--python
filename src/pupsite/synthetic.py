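"""Synthetic site datasets and residue profiles.

Emulates the statistical shape of a lysine-site training set — K-centered
21-mers, a configurable negative:positive imbalance (default 1:12), and
positional residue enrichment in the positive class — so every pipeline
stage is testable without any external download.  Negatives are drawn
i.i.d. from the background composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS
from .peptide_io import (
    DEFAULT_HALF_WIDTH,
    NEGATIVE,
    POSITIVE,
    PeptideWindow,
    SiteDataset,
)
from .encoders import ResidueProfile, profile_from_window


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


@dataclass
class MotifSpec:
    """Generative description of a positive-class sequence motif.

    ``position_bias`` maps 0-based window positions (never the center,
    which is always 'K') to 20-component residue probability vectors used
    for the positive class; everything else is drawn from ``background``.
    """

    enriched_positions: tuple[int, ...] = ()
    position_bias: dict[int, np.ndarray] = field(default_factory=dict)
    background: np.ndarray = field(default_factory=uniform_background)
    imbalance: float = 12.0
    half_width: int = DEFAULT_HALF_WIDTH
    seed: int = 0

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        center = self.half_width
        if set(self.enriched_positions) != set(self.position_bias):
            raise ValueError("enriched_positions must match position_bias keys")
        if center in self.position_bias:
            raise ValueError("the center position is always 'K'")
        for pos, p in list(self.position_bias.items()):
            p = np.asarray(p, dtype=float)
            if p.shape != (20,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"position {pos}: invalid probability vector")
            self.position_bias[pos] = p
        bg = self.background
        if bg.shape != (20,) or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
            raise ValueError("invalid background probabilities")
        if self.imbalance < 0:
            raise ValueError("imbalance must be non-negative")

    @classmethod
    def null(
        cls, imbalance: float = 12.0, seed: int = 0, half_width: int = DEFAULT_HALF_WIDTH
    ) -> "MotifSpec":
        """Zero effect: positives and negatives share the background."""
        return cls(imbalance=imbalance, seed=seed, half_width=half_width)

    @classmethod
    def strong(
        cls,
        residue: str = "L",
        positions: tuple[int, ...] = (7, 8, 12),
        prob: float = 0.9,
        imbalance: float = 12.0,
        seed: int = 0,
        half_width: int = DEFAULT_HALF_WIDTH,
    ) -> "MotifSpec":
        """One residue at ``prob`` on a few flanking positions, uniform rest."""
        i = AMINO_ACIDS.index(residue)
        bias = np.full(20, (1.0 - prob) / 19.0)
        bias[i] = prob
        return cls(
            enriched_positions=tuple(positions),
            position_bias={p: bias.copy() for p in positions},
            imbalance=imbalance,
            seed=seed,
            half_width=half_width,
        )


def _sample_windows(
    n: int,
    spec: MotifSpec,
    rng: np.random.Generator,
    positive: bool,
) -> list[str]:
    L = 2 * spec.half_width + 1
    letters = np.array(list(AMINO_ACIDS))
    cols = []
    for j in range(L):
        if j == spec.half_width:
            cols.append(np.full(n, "K"))
            continue
        p = (
            spec.position_bias[j]
            if positive and j in spec.position_bias
            else spec.background
        )
        cols.append(letters[rng.choice(20, size=n, p=p)])
    grid = np.stack(cols, axis=1)
    return ["".join(row) for row in grid]


def generate_motif_dataset(n_pos: int, spec: MotifSpec) -> SiteDataset:
    """n_pos positive and round(n_pos * imbalance) negative K-centered
    windows, deterministic under ``spec.seed``."""
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n_neg = int(round(n_pos * spec.imbalance))
    site_pos = spec.half_width + 1
    windows = [
        PeptideWindow(f"synt_pos_{i:05d}", site_pos, w, POSITIVE)
        for i, w in enumerate(_sample_windows(n_pos, spec, rng, positive=True))
    ]
    windows += [
        PeptideWindow(f"synt_neg_{i:05d}", site_pos, w, NEGATIVE)
        for i, w in enumerate(_sample_windows(n_neg, spec, rng, positive=False))
    ]
    return SiteDataset(windows)


def generate_noisy_profile(
    window: PeptideWindow, concentration: float, seed: int = 0
) -> ResidueProfile:
    """Dirichlet-noised frequency profile centered on the window's residues.

    Each row is drawn from Dirichlet(1 + concentration * onehot); as
    ``concentration`` grows the profile converges to the one-hot profile of
    the sequence.  'X' positions get a symmetric Dirichlet(1) row.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    base = profile_from_window(window).freqs
    alphas = 1.0 + concentration * (base == 1.0)  # one-hot rows only
    freqs = np.vstack([rng.dirichlet(a) for a in alphas])
    return ResidueProfile(freqs)
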