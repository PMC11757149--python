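"""Resampling null for flank conservation from fourfold-degenerate sites.

Each replicate draws ``k`` distinct fourfold site columns (without
replacement within the replicate), averages their Shannon entropies, and
the procedure is repeated ``n_replicates`` times (defaults: k = 6 sites,
1,000 replicates).  The resulting ensemble of replicate means is the
neutral reference distribution against which observed flank window
entropies are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import ColumnProfile
from .fourfold import FourfoldSiteIndex, extract_fourfold_sites
from .motifs import SequenceRecord


@dataclass(frozen=True)
class NullEnsemble:
    """Replicate mean entropies (bits) from fourfold-site resampling."""

    values: np.ndarray
    n_replicates: int
    sites_per_replicate: int
    seed: int | None
    sampling: str = "without_replacement"
    draws: np.ndarray | None = None   # (n_replicates, k) sampled column indices

    def __post_init__(self) -> None:
        if len(self.values) != self.n_replicates:
            raise ValueError("ensemble length does not match n_replicates")
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 2 + 1e-12
        ):
            raise ValueError("replicate mean entropies must lie in [0, 2] bits")

    def __len__(self) -> int:
        return self.n_replicates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": np.arange(self.n_replicates), "mean_entropy": self.values}
        )


def build_null(
    alignment: Sequence[SequenceRecord] | Sequence[str],
    sites: FourfoldSiteIndex | None = None,
    n_replicates: int = 1000,
    k: int = 6,
    seed: int | None = None,
    record_draws: bool = True,
) -> NullEnsemble:
    """Build the fourfold-site resampling null from a CDS alignment.

    ``sites`` defaults to a fresh fourfold extraction from the
    alignment.  Fewer than ``k`` usable site columns is an error — the
    procedure never falls back to sampling with replacement.
    """
    if n_replicates < 1 or k < 1:
        raise ValueError("n_replicates and k must be positive")
    if sites is None:
        sites = extract_fourfold_sites(alignment)
    rows = [
        rec.residues if isinstance(rec, SequenceRecord) else str(rec).upper()
        for rec in alignment
    ]
    if len(sites) < k:
        raise ValueError(
            f"only {len(sites)} fourfold site columns available but k={k} "
            "distinct sites are required per replicate; refusing to sample "
            "with replacement"
        )
    profile = ColumnProfile.from_rows(rows, min_informative=1)
    site_cols = np.asarray(sites.columns, dtype=int)
    site_entropies = profile.entropies[site_cols]
    if not np.all(np.isfinite(site_entropies)):
        raise ValueError("a fourfold site column has no informative rows")

    rng = np.random.default_rng(seed)
    m = len(site_cols)
    draws = np.empty((n_replicates, k), dtype=int)
    for r in range(n_replicates):
        draws[r] = rng.choice(m, size=k, replace=False)
    values = site_entropies[draws].mean(axis=1)
    return NullEnsemble(
        values=values,
        n_replicates=n_replicates,
        sites_per_replicate=k,
        seed=seed,
        sampling="without_replacement",
        draws=site_cols[draws] if record_draws else None,
    )
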