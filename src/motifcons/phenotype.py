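"""Fruit-shape and expression phenotype quantification.

The shoulder index θ = arctan((L1 − L2) / W) scores how far the valve
shoulders of the heart-shaped Capsella fruit protrude: L1 and L2 are two
measured lengths whose difference captures the shoulder, W the fruit
width (all abstract measured lengths from the upstream morphometry).
θ is reported in degrees by default and is scale-invariant.

Relative expression from qPCR follows the 2^-ΔCT method against an
internal reference gene (CrUBQ10 in the study system), with technical
replicates averaged on the CT scale.  The motif-presence versus
shape-change association across species is summarised as a 2×2 table
with its concordance fraction and a two-sided Fisher exact p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def shoulder_index(l1, l2, w, degrees: bool = True):
    """Shoulder index θ = arctan((L1 − L2) / W), degrees by default.

    Accepts scalars or arrays; W must be strictly positive.  θ lies in
    (−90°, 90°); swapping L1 and L2 negates it, and rescaling all three
    measurements by a common factor leaves it unchanged.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("fruit width W must be strictly positive")
    theta = np.arctan((l1 - l2) / w)
    if degrees:
        theta = np.degrees(theta)
    return float(theta) if theta.ndim == 0 else theta


def shoulder_index_table(
    measurements: pd.DataFrame, degrees: bool = True
) -> pd.DataFrame:
    """Add a ``shoulder_index`` column to a measurement table (L1, L2, W)."""
    required = {"L1", "L2", "W"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    out = measurements.copy()
    out["shoulder_index"] = shoulder_index(
        out["L1"].to_numpy(), out["L2"].to_numpy(), out["W"].to_numpy(),
        degrees=degrees,
    )
    return out


def relative_expression(delta_ct):
    """Relative expression ratio = 2^-ΔCT (so log2 ratio = -ΔCT exactly)."""
    delta_ct = np.asarray(delta_ct, dtype=float)
    if not np.all(np.isfinite(delta_ct)):
        raise ValueError("ΔCT values must be finite")
    ratio = np.power(2.0, -delta_ct)
    return float(ratio) if ratio.ndim == 0 else ratio


def average_technical_replicates(
    ct: pd.DataFrame, sample_col: str = "sample_id"
) -> pd.DataFrame:
    """Average technical qPCR replicates on the CT scale before ΔCT."""
    value_cols = [c for c in ("ct_target", "ct_reference") if c in ct.columns]
    if not value_cols:
        raise ValueError("expected ct_target / ct_reference columns")
    grouped = ct.groupby(sample_col, sort=False, as_index=False)
    out = grouped[value_cols].mean()
    out["n_replicates"] = grouped.size()["size"].to_numpy()
    return out


def relative_expression_table(ct: pd.DataFrame) -> pd.DataFrame:
    """ΔCT and 2^-ΔCT columns for a wide CT table.

    Requires ``ct_target`` and ``ct_reference`` columns; a missing or
    non-finite reference CT is an error, not a silent NaN.
    """
    if "ct_target" not in ct.columns:
        raise ValueError("CT table lacks a ct_target column")
    if "ct_reference" not in ct.columns:
        raise ValueError("CT table lacks a ct_reference (internal control) column")
    target = ct["ct_target"].to_numpy(dtype=float)
    reference = ct["ct_reference"].to_numpy(dtype=float)
    if not np.all(np.isfinite(reference)):
        raise ValueError("missing or non-finite reference CT values")
    if not np.all(np.isfinite(target)):
        raise ValueError("missing or non-finite target CT values")
    out = ct.copy()
    out["delta_ct"] = target - reference
    out["relative_expression"] = relative_expression(out["delta_ct"].to_numpy())
    return out


@dataclass(frozen=True)
class AssociationTable:
    """2×2 motif-presence × shape-change table with concordance and Fisher p.

    ``counts`` rows are motif present/absent, columns shape-change
    yes/no; concordance is the diagonal fraction (present & change plus
    absent & no change).
    """

    counts: np.ndarray
    concordance: float
    p_value: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (2, 2) or np.any(counts < 0):
            raise ValueError("counts must be a non-negative 2x2 table")

    @property
    def n(self) -> int:
        return int(np.asarray(self.counts).sum())


def motif_phenotype_association(
    species_table: pd.DataFrame,
    motif_col: str = "motif_present",
    shape_col: str = "shape_change",
) -> AssociationTable:
    """Cross-species association between binding-site presence and shape change.

    Rows with a missing label are excluded with a warning.  The
    association is reported descriptively (concordance fraction) plus a
    two-sided Fisher exact test; no phylogenetic correction is applied.
    """
    for col in (motif_col, shape_col):
        if col not in species_table.columns:
            raise ValueError(f"species table lacks column {col!r}")
    usable = species_table[[motif_col, shape_col]].copy()
    n_excluded = int(usable.isna().any(axis=1).sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} species with missing labels", stacklevel=2
        )
        usable = usable.dropna()
    if usable.empty:
        raise ValueError("no species with complete labels")
    motif = usable[motif_col].astype(bool).to_numpy()
    shape = usable[shape_col].astype(bool).to_numpy()
    counts = np.array(
        [
            [int(np.sum(motif & shape)), int(np.sum(motif & ~shape))],
            [int(np.sum(~motif & shape)), int(np.sum(~motif & ~shape))],
        ]
    )
    concordance = float((counts[0, 0] + counts[1, 1]) / counts.sum())
    _, p = sps.fisher_exact(counts, alternative="two-sided")
    return AssociationTable(
        counts=counts, concordance=concordance, p_value=float(p),
        n_excluded=n_excluded,
    )
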