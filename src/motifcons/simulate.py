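"""Synthetic promoter panels, CDS alignments and phenotype measurements.

Real inputs for this analysis are a TAIL-PCR-derived panel of promoter
sequences from Brassicaceae species (21 carrying the CTGTCA binding
site, 28 without it), codon alignments of *STM* orthologue coding
sequences, and fruit morphometrics / qPCR cycle thresholds.  No such
panel ships with the package, so this module generates panels with the
same statistical structure and a machine-readable truth sidecar
(motif coordinates, fourfold columns, group labels) so every downstream
stage can be tested against known ground truth.

The substitution model is deliberately simple: each flank position
mutates independently from a shared ancestral scaffold with a
group-specific per-column probability, substituting to one of the other
three bases uniformly.  There is no tree structure and no indels; what
that leaves out is discussed in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fourfold import FOURFOLD_FAMILY_PREFIXES, NON_FOURFOLD_SENSE_CODONS
from .motifs import (
    CONSENSUS,
    MOTIF_LEN,
    MUTANT_CENTER,
    SequenceRecord,
    WITH_SITE,
    WITHOUT_SITE,
    find_motif,
)

_BASES = "ACGT"
_OTHER_BASES = {b: [c for c in _BASES if c != b] for b in _BASES}


class RejectionSamplingError(RuntimeError):
    """Raised when bounded rejection sampling cannot satisfy a constraint."""


@dataclass(frozen=True)
class PanelSpec:
    """Study conditions for the promoter panel.

    Group sizes default to the study panel (21 species with the binding
    site, 28 without); substitution probabilities default to strongly
    conserved with-site flanks (0.01 per column) versus weakly
    constrained without-site flanks (0.30).  ``center_mut_prob`` is the
    probability that a without-site species carries a diverged centre;
    at its default of 1 the group labels are exactly recoverable from
    sequence content.
    """

    n_with_site: int = 21
    n_without_site: int = 28
    motif: str = CONSENSUS
    flank_len: int = 12
    sub_prob_with: float = 0.01
    sub_prob_without: float = 0.30
    center_mut_prob: float = 1.0
    seed: int = 0
    scaffold_len: int = 200
    motif_start: int = 100
    mutant_center: str | None = None
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_with_site < 1 or self.n_without_site < 1:
            raise ValueError("group sizes must be at least 1")
        if len(self.motif) != MOTIF_LEN or set(self.motif.upper()) - set(_BASES):
            raise ValueError("motif must be a hexamer over A/C/G/T")
        for name in ("sub_prob_with", "sub_prob_without", "center_mut_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.flank_len < MOTIF_LEN:
            raise ValueError(f"flank_len must be >= {MOTIF_LEN}")
        if self.motif_start < self.flank_len:
            raise ValueError("motif_start leaves no room for the 5' flank")
        if self.motif_start + MOTIF_LEN + self.flank_len > self.scaffold_len:
            raise ValueError("scaffold too short for the 3' flank")
        if self.mutant_center is not None:
            mc = self.mutant_center.upper()
            if len(mc) != MOTIF_LEN or set(mc) - set(_BASES):
                raise ValueError("mutant_center must be a hexamer over A/C/G/T")
            if mc == self.motif.upper():
                raise ValueError("mutant_center must differ from the consensus")


@dataclass(frozen=True)
class PromoterPanel:
    """A simulated panel plus its truth sidecar (consumed only by tests/QC)."""

    records: tuple[SequenceRecord, ...]
    truth: pd.DataFrame
    spec: PanelSpec

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        descriptions = {
            row.species_id: f"group={row.group} seed={self.spec.seed}"
            for row in self.truth.itertuples()
        }
        write_fasta(self.records, path, descriptions=descriptions)

    def association_table(self) -> pd.DataFrame:
        """Species table pairing motif presence with a shape-change label.

        Emulates the study observation that binding-site presence and
        the gynoecium-to-fruit shape change co-occur perfectly, so the
        synthetic label simply mirrors the group.
        """
        return pd.DataFrame(
            {
                "species": self.truth["species_id"],
                "motif_present": self.truth["group"] == WITH_SITE,
                "shape_change": self.truth["group"] == WITH_SITE,
            }
        )


def _mutate_outside(
    rng: np.random.Generator, scaffold: list[str], lo: int, hi: int, p: float
) -> list[str]:
    """Mutate every position outside [lo, hi) independently with prob p."""
    out = scaffold.copy()
    if p <= 0:
        return out
    for i in range(len(out)):
        if lo <= i < hi:
            continue
        if rng.random() < p:
            out[i] = _OTHER_BASES[out[i]][rng.integers(3)]
    return out


def _diverged_center(rng: np.random.Generator, motif: str) -> str:
    """A centre differing from the consensus at >= 1 position."""
    while True:
        centre = [
            _OTHER_BASES[b][rng.integers(3)] if rng.random() < 0.5 else b
            for b in motif
        ]
        centre = "".join(centre)
        if centre != motif:
            return centre


def simulate_promoter_panel(spec: PanelSpec) -> PromoterPanel:
    """Generate the two-group promoter panel.

    Every with-site sequence contains exactly one exact consensus match,
    at the recorded coordinate; without-site sequences contain none
    (rejection-sampled, with a bounded retry count so that a
    ``center_mut_prob`` too low to satisfy the constraint fails loudly
    instead of looping).  Reproducible: the same spec and seed give
    byte-identical FASTA output.
    """
    rng = np.random.default_rng(spec.seed)
    motif = spec.motif.upper()
    lo, hi = spec.motif_start, spec.motif_start + MOTIF_LEN

    # ancestral scaffold whose only consensus occurrence is the planted centre
    for _ in range(spec.max_retries):
        scaffold = [_BASES[i] for i in rng.integers(4, size=spec.scaffold_len)]
        scaffold[lo:hi] = list(motif)
        if len(find_motif("".join(scaffold), motif)) == 1:
            break
    else:
        raise RejectionSamplingError(
            "could not draw an ancestral scaffold with a unique consensus match"
        )

    ids: list[str] = []
    seqs: list[str] = []
    groups: list[str] = []
    centres: list[str] = []

    for i in range(spec.n_with_site):
        for _ in range(spec.max_retries):
            seq = _mutate_outside(rng, scaffold, lo, hi, spec.sub_prob_with)
            text = "".join(seq)
            if len(find_motif(text, motif)) == 1:
                break
        else:
            raise RejectionSamplingError(
                f"with-site sequence {i} kept acquiring spurious consensus "
                f"matches after {spec.max_retries} retries"
            )
        ids.append(f"with_{i + 1:02d}")
        seqs.append(text)
        groups.append(WITH_SITE)
        centres.append(motif)

    for i in range(spec.n_without_site):
        for _ in range(spec.max_retries):
            seq = _mutate_outside(rng, scaffold, lo, hi, spec.sub_prob_without)
            if rng.random() < spec.center_mut_prob:
                centre = spec.mutant_center or _diverged_center(rng, motif)
            else:
                centre = motif
            seq[lo:hi] = list(centre)
            text = "".join(seq)
            if not find_motif(text, motif):
                break
        else:
            raise RejectionSamplingError(
                f"without-site sequence {i} still matched the consensus after "
                f"{spec.max_retries} retries; center_mut_prob="
                f"{spec.center_mut_prob} is likely too low"
            )
        ids.append(f"without_{i + 1:02d}")
        seqs.append(text)
        groups.append(WITHOUT_SITE)
        centres.append(centre)

    # upstream distance with the ATG imagined immediately 3' of the scaffold,
    # measured to the motif's 3'-most base (the package's default convention)
    atg_offset = spec.scaffold_len
    upstream = atg_offset - hi + 1
    truth = pd.DataFrame(
        {
            "species_id": ids,
            "group": groups,
            "center_start": spec.motif_start,
            "center_end": hi,
            "center_seq": centres,
            "has_motif": [g == WITH_SITE for g in groups],
            "upstream_distance": upstream,
            "seed": spec.seed,
        }
    )
    records = tuple(
        SequenceRecord(id=rid, residues=seq, role="promoter")
        for rid, seq in zip(ids, seqs)
    )
    return PromoterPanel(records=records, truth=truth, spec=spec)


@dataclass(frozen=True)
class CdsSpec:
    """Study conditions for the neutral-control CDS alignment.

    ``fourfold_fraction`` sets the exact share of codons drawn from
    fourfold-degenerate families (positions chosen at random);
    ``third_pos_sub_prob`` is the per-row substitution probability at
    fourfold third positions — always synonymous, so the recorded truth
    columns stay fourfold in every sequence.
    """

    n_genes: int = 8
    n_codons: int = 200
    fourfold_fraction: float = 0.5
    third_pos_sub_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be at least 1")
        if self.n_codons < 3:
            raise ValueError("n_codons must be at least 3")
        if not (0.0 <= self.fourfold_fraction <= 1.0):
            raise ValueError("fourfold_fraction outside [0, 1]")
        if not (0.0 <= self.third_pos_sub_prob <= 1.0):
            raise ValueError("third_pos_sub_prob outside [0, 1]")


@dataclass(frozen=True)
class CdsAlignment:
    """A simulated gap-free codon alignment plus its fourfold truth columns."""

    records: tuple[SequenceRecord, ...]
    true_fourfold_columns: tuple[int, ...]
    spec: CdsSpec

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        write_fasta(
            self.records, path,
            descriptions={r.id: f"seed={self.spec.seed}" for r in self.records},
        )


_FOURFOLD_PREFIX_LIST = tuple(sorted(FOURFOLD_FAMILY_PREFIXES))


def simulate_cds_alignment(spec: CdsSpec) -> CdsAlignment:
    """Generate a codon alignment with known fourfold-degenerate columns.

    An ancestral gene is built codon by codon — fourfold-family codons
    at ``round(fourfold_fraction * n_codons)`` random positions,
    non-fourfold sense codons elsewhere — then each row substitutes the
    third base of fourfold codons independently.  First and second codon
    positions never mutate, so the truth columns are exactly the third
    positions of the ancestral fourfold codons.
    """
    rng = np.random.default_rng(spec.seed)
    n_fourfold = round(spec.fourfold_fraction * spec.n_codons)
    if spec.fourfold_fraction * spec.n_codons < 1:
        warnings.warn(
            "fourfold_fraction * n_codons < 1: alignment will contain no "
            "fourfold-degenerate columns",
            stacklevel=2,
        )
    positions = sorted(
        rng.choice(spec.n_codons, size=n_fourfold, replace=False).tolist()
    )
    fourfold_set = set(positions)
    ancestor: list[str] = []
    for j in range(spec.n_codons):
        if j in fourfold_set:
            prefix = _FOURFOLD_PREFIX_LIST[rng.integers(len(_FOURFOLD_PREFIX_LIST))]
            ancestor.append(prefix + _BASES[rng.integers(4)])
        else:
            ancestor.append(
                NON_FOURFOLD_SENSE_CODONS[rng.integers(len(NON_FOURFOLD_SENSE_CODONS))]
            )

    records = []
    for g in range(spec.n_genes):
        codons = ancestor.copy()
        for j in positions:
            if rng.random() < spec.third_pos_sub_prob:
                third = codons[j][2]
                codons[j] = codons[j][:2] + _OTHER_BASES[third][rng.integers(3)]
        records.append(
            SequenceRecord(
                id=f"gene_{g + 1:02d}", residues="".join(codons), role="cds"
            )
        )
    return CdsAlignment(
        records=tuple(records),
        true_fourfold_columns=tuple(3 * j + 2 for j in positions),
        spec=spec,
    )


@dataclass(frozen=True)
class MorphoSpec:
    """Per-genotype fruit-measurement means (µm) and measurement noise.

    Defaults sketch a heart-shaped wild type (valve shoulders protrude:
    L1 > L2) against a binding-site-deletion allele with reduced
    shoulders, at a plausible Capsella fruit scale.
    """

    genotypes: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "CrWT": (260.0, 160.0, 420.0),
            "site_deletion": (190.0, 160.0, 420.0),
        }
    )
    noise_sd: float = 15.0
    n_fruits: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fruits < 1:
            raise ValueError("n_fruits must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.genotypes:
            raise ValueError("at least one genotype is required")
        for name, (l1, l2, w) in self.genotypes.items():
            if l1 <= 0 or l2 <= 0 or w <= 0:
                raise ValueError(f"genotype {name!r} means must be positive")


def simulate_measurements(spec: MorphoSpec) -> pd.DataFrame:
    """Fruit measurements: Gaussian noise around the genotype means.

    Draws are truncated (by resampling) so that W stays positive and
    L1, L2 stay non-negative, preserving the measurement invariants.
    """
    rng = np.random.default_rng(spec.seed)

    def _draw(mean: float, lower: float) -> float:
        while True:
            v = rng.normal(mean, spec.noise_sd) if spec.noise_sd > 0 else mean
            if v > lower or (lower == 0.0 and v == 0.0):
                return float(v)

    rows = []
    for genotype, (l1_mean, l2_mean, w_mean) in spec.genotypes.items():
        for i in range(spec.n_fruits):
            rows.append(
                {
                    "fruit_id": f"{genotype}_{i + 1:02d}",
                    "genotype": genotype,
                    "L1": _draw(l1_mean, 0.0),
                    "L2": _draw(l2_mean, 0.0),
                    "W": _draw(w_mean, 0.0) if spec.noise_sd > 0 else w_mean,
                }
            )
    return pd.DataFrame(rows)


def simulate_ct(
    n: int,
    delta_ct_mean: float = 1.0,
    sd: float = 0.2,
    seed: int = 0,
    target: str = "CrSTM",
    reference: str = "CrUBQ10",
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """qPCR cycle-threshold table with noise on the ΔCT scale.

    The reference gene's CT is held at ``reference_ct`` and the target's
    CT is reference + ΔCT with ΔCT ~ Normal(delta_ct_mean, sd), so with
    sd = 0 the relative expression is exactly 2^-delta_ct_mean.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    delta = (
        rng.normal(delta_ct_mean, sd, size=n)
        if sd > 0
        else np.full(n, float(delta_ct_mean))
    )
    return pd.DataFrame(
        {
            "sample_id": [f"sample_{i + 1:02d}" for i in range(n)],
            "target_gene": target,
            "reference_gene": reference,
            "ct_target": reference_ct + delta,
            "ct_reference": reference_ct,
            "delta_ct": delta,
        }
    )
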