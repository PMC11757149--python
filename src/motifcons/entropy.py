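"""Shannon-entropy conservation profiles and sequence-logo matrices.

Column entropy is the plug-in estimate H = -sum p_b log2 p_b over the
base frequencies of an alignment column, in bits: 0 for an invariant
column, 2 for a column uniform over the four bases.  Gaps and N are
excluded from the counts; a column with fewer than two informative rows
is flagged missing (NaN) rather than silently scored 0, since a single
observation carries no conservation signal.

Window profiles are the mean column entropy of every ``width``-bp window
slid along one flank of the motif-centred alignment.  Logo matrices hold
per-position base frequencies and information content IC = 2 - H bits,
optionally with the small-sample correction e(n) = 3 / (2 ln 2 n)
subtracted (floored at 0), matching sequence-logo convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import GAP, MOTIF_LEN, OrthologousWindowSet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
FLANKS = (FIVE_PRIME, THREE_PRIME)


def column_entropy(counts: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy (bits) of one alignment column's base counts.

    ``counts`` is either a mapping over A/C/G/T or a length-4 sequence in
    A, C, G, T order.  Gap/N counts must already be excluded.  An all-gap
    column (total 0) has no defined entropy and raises rather than
    returning a spurious 0.
    """
    if isinstance(counts, Mapping):
        arr = np.array([float(counts.get(b, 0.0)) for b in BASES])
    else:
        arr = np.asarray(list(counts), dtype=float)
        if arr.shape != (4,):
            raise ValueError("expected counts for exactly the four bases A, C, G, T")
    if np.any(arr < 0):
        raise ValueError("negative base count")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-gap column: entropy is undefined, not 0")
    p = arr[arr > 0] / total
    return float(-(p * np.log2(p)).sum()) + 0.0  # normalise -0.0


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column base counts and entropies for one aligned group.

    ``entropies`` is NaN for columns with fewer than ``min_informative``
    non-gap rows (missing, never 0).
    """

    counts: np.ndarray          # (n_columns, 4) in A,C,G,T order
    totals: np.ndarray          # (n_columns,) non-gap counts
    entropies: np.ndarray       # (n_columns,) bits, NaN where missing
    min_informative: int = 2

    @classmethod
    def from_rows(
        cls, rows: Iterable[str], min_informative: int = 2
    ) -> "ColumnProfile":
        rows = [r.upper() for r in rows]
        if not rows:
            raise ValueError("no rows supplied")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("rows differ in length; input is not an alignment")
        n_cols = lengths.pop()
        counts = np.zeros((n_cols, 4), dtype=float)
        for row in rows:
            for col, ch in enumerate(row):
                idx = _BASE_INDEX.get(ch)
                if idx is not None:
                    counts[col, idx] += 1
        totals = counts.sum(axis=1)
        entropies = np.full(n_cols, np.nan)
        for col in range(n_cols):
            if totals[col] >= min_informative:
                entropies[col] = column_entropy(counts[col])
        return cls(
            counts=counts, totals=totals, entropies=entropies,
            min_informative=min_informative,
        )

    def __len__(self) -> int:
        return len(self.totals)


@dataclass(frozen=True)
class EntropyProfile:
    """Mean column entropies of sliding windows along one flank."""

    group: str
    flank: str                      # five_prime | three_prime
    width: int
    step: int
    window_starts: np.ndarray       # 0-based offsets within the flank
    values: np.ndarray              # mean entropy per window (bits), NaN if empty
    n_columns_effective: np.ndarray  # informative columns per window

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 2 + 1e-12):
            raise ValueError("window mean entropies must lie in [0, 2] bits")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "flank": self.flank,
                "window_start": self.window_starts,
                "mean_entropy": self.values,
                "n_columns_effective": self.n_columns_effective,
            }
        )


def _scan_entropies(
    entropies: np.ndarray, width: int, step: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    starts = np.arange(0, len(entropies) - width + 1, step)
    values = np.empty(len(starts))
    n_eff = np.empty(len(starts), dtype=int)
    for i, s in enumerate(starts):
        window = entropies[s : s + width]
        ok = np.isfinite(window)
        n_eff[i] = int(ok.sum())
        values[i] = window[ok].mean() if n_eff[i] else np.nan
    return starts, values, n_eff


def window_scan(
    windows: OrthologousWindowSet,
    width: int = 6,
    step: int = 1,
    min_informative: int = 2,
) -> dict[str, EntropyProfile]:
    """Sliding-window mean-entropy profiles for both flanks of a window set.

    Missing (NaN) columns are excluded from a window's mean and the
    effective column count is recorded.  A flank shorter than ``width``
    cannot host a single window and is an error.
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be positive")
    if windows.flank < width:
        raise ValueError(
            f"flank of {windows.flank} columns is shorter than the "
            f"{width}-bp window; need a flank of at least {width} columns"
        )
    profiles: dict[str, EntropyProfile] = {}
    for side in FLANKS:
        col_profile = ColumnProfile.from_rows(
            windows.flank_rows(side), min_informative=min_informative
        )
        starts, values, n_eff = _scan_entropies(col_profile.entropies, width, step)
        profiles[side] = EntropyProfile(
            group=windows.group,
            flank=side,
            width=width,
            step=step,
            window_starts=starts,
            values=values,
            n_columns_effective=n_eff,
        )
    return profiles


def pooled_window_values(profiles: Iterable[EntropyProfile]) -> np.ndarray:
    """Concatenate window means across profiles, dropping missing windows."""
    values = np.concatenate([np.atleast_1d(p.values) for p in profiles])
    return values[np.isfinite(values)]


@dataclass(frozen=True)
class LogoMatrix:
    """Per-position base frequencies and information content of a group."""

    frequencies: np.ndarray      # (width, 4) in A,C,G,T order, rows sum to 1
    information: np.ndarray      # (width,) bits
    n_per_position: np.ndarray   # informative (non-gap) rows per position
    n_sequences: int
    small_sample_correction: bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=[f"freq_{b}" for b in BASES])
        df.insert(0, "position", np.arange(len(self.information)))
        df["information_bits"] = self.information
        df["n_effective"] = self.n_per_position
        return df


def logo_matrix(
    windows: OrthologousWindowSet, small_sample_correction: bool = False
) -> LogoMatrix:
    """Sequence-logo matrix (frequencies + IC in bits) for one window set.

    IC = 2 - H per position; with the correction on, the small-sample
    term e(n) = 3 / (2 ln 2 n) is subtracted and the result floored at 0.
    """
    if windows.n == 0:
        raise ValueError("cannot build a logo from an empty window set")
    profile = ColumnProfile.from_rows(windows.rows, min_informative=1)
    totals = profile.totals
    freqs = np.full_like(profile.counts, np.nan)
    nonzero = totals > 0
    freqs[nonzero] = profile.counts[nonzero] / totals[nonzero, None]
    info = 2.0 - profile.entropies
    if small_sample_correction:
        with np.errstate(divide="ignore"):
            e_n = 3.0 / (2.0 * np.log(2.0) * totals)
        info = np.maximum(info - e_n, 0.0)
    return LogoMatrix(
        frequencies=freqs,
        information=info,
        n_per_position=totals.astype(int),
        n_sequences=windows.n,
        small_sample_correction=small_sample_correction,
    )


def plot_logo(matrix: LogoMatrix, ax=None):
    """Render a logo matrix as stacked letter-height bars (convenience only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.4 * len(matrix.information), 2.2))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    positions = np.arange(len(matrix.information))
    bottom = np.zeros(len(positions))
    for i, base in enumerate(BASES):
        heights = matrix.frequencies[:, i] * matrix.information
        heights = np.nan_to_num(heights)
        ax.bar(positions, heights, bottom=bottom, color=colors[base],
               width=0.85, label=base)
        bottom += heights
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.legend(ncol=4, fontsize=8, frameon=False)
    return ax
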