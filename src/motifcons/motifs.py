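"""Consensus motif scanning and orthologous-window extraction.

The analysis centres on a hexameric transcription-factor binding site
(consensus ``CTGTCA``, recognised by the SHOOTMERISTEMLESS homeodomain
protein) found in the promoters of *STM* orthologues.  This module scans
promoter sequences for exact consensus matches, reports their distance
upstream of the ATG start codon, and extracts the motif-centred
orthologous window (6 central columns plus a configurable flank on each
side; 20 bp with the default 7-column flank) from an aligned panel,
partitioning the rows into a with-site and a without-site group by the
content of their window centre.

Coordinates are 0-based, half-open internally.  Scanning is
forward-strand only by default because the binding site is defined in a
fixed promoter orientation; reverse-strand scanning is an explicit flag
and reverse hits are reported in forward coordinates with strand ``-``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

CONSENSUS = "CTGTCA"
MUTANT_CENTER = "ATATAA"  # the non-functional variant used as a canned diverged centre
GAP = "-"
MOTIF_LEN = 6

_PROMOTER_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

WITH_SITE = "with_site"
WITHOUT_SITE = "without_site"


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (A/C/G/T/N and gaps)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (promoter or CDS), optionally gapped.

    Residues are stored upper-case; only A/C/G/T/N and the alignment gap
    character ``-`` are accepted.  Other IUPAC ambiguity codes are
    rejected at construction: the sequence panels this package targets
    are Sanger/TAIL-PCR-derived, so ambiguity beyond N indicates an
    upstream problem rather than genuine polymorphism.
    """

    id: str
    residues: str
    species: str = ""
    role: str = "promoter"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        seq = self.residues.upper()
        if not seq:
            raise ValueError(f"sequence record {self.id!r} is empty")
        bad = set(seq) - _PROMOTER_ALPHABET - {GAP}
        if bad:
            raise ValueError(
                f"unsupported residue codes {sorted(bad)} in record {self.id!r}; "
                "only A/C/G/T/N and '-' are accepted"
            )
        object.__setattr__(self, "residues", seq)
        if not self.species:
            object.__setattr__(self, "species", self.id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class MotifHit:
    """One exact consensus match, in forward coordinates of the scanned sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str
    matched: str
    upstream_distance: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")
        if self.end - self.start != len(self.matched):
            raise ValueError("hit interval length does not match the matched text")


def _validate_consensus(consensus: str) -> str:
    consensus = consensus.upper()
    if len(consensus) != MOTIF_LEN or set(consensus) - set("ACGT"):
        raise ValueError(
            f"consensus must be a hexamer over A/C/G/T, got {consensus!r}"
        )
    return consensus


def find_motif(
    seq: SequenceRecord | str,
    consensus: str = CONSENSUS,
    both_strands: bool = False,
) -> list[MotifHit]:
    """Find all exact matches of ``consensus`` in ``seq``.

    N and gap characters never match.  With ``both_strands``, matches of
    the reverse complement are also reported, in forward coordinates and
    with ``strand='-'``; ``matched`` is always the consensus as read on
    the hit strand.  An empty input yields an empty list.
    """
    consensus = _validate_consensus(consensus)
    if isinstance(seq, SequenceRecord):
        text, seq_id = seq.residues, seq.id
    else:
        text, seq_id = seq.upper(), "<anonymous>"
    hits: list[MotifHit] = []
    targets = [(consensus, "+")]
    if both_strands:
        rc = reverse_complement(consensus)
        # a palindromic consensus would double-report; keep one strand then
        if rc != consensus:
            targets.append((rc, "-"))
    for target, strand in targets:
        pos = text.find(target)
        while pos != -1:
            hits.append(
                MotifHit(
                    sequence_id=seq_id,
                    start=pos,
                    end=pos + MOTIF_LEN,
                    strand=strand,
                    matched=consensus,
                )
            )
            pos = text.find(target, pos + 1)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def report_upstream_distance(
    hit: MotifHit, atg_offset: int, convention: str = "end"
) -> int:
    """1-based distance of a motif hit upstream of the ATG start codon.

    ``atg_offset`` is the 0-based position of the A of ATG in the same
    coordinate system as the hit.  Under the default ``end`` convention
    the distance is measured to the motif's 3'-most base, so a hit whose
    end abuts the ATG is "1 bp upstream"; under ``start`` it is measured
    to the motif's 5'-most base (``atg_offset - start``).
    """
    if convention not in {"end", "start"}:
        raise ValueError(f"convention must be 'end' or 'start', got {convention!r}")
    if hit.end > atg_offset:
        raise ValueError(
            f"hit [{hit.start}, {hit.end}) overlaps or lies 3' of the ATG at {atg_offset}"
        )
    if convention == "end":
        return atg_offset - hit.end + 1
    return atg_offset - hit.start


@dataclass(frozen=True)
class OrthologousWindowSet:
    """A group's aligned motif-centred windows.

    ``flank`` columns on each side of the 6 central columns; the default
    flank of 7 gives the 20-column window used for sequence logos.  Rows
    in a ``with_site`` set carry the exact consensus at the centre; rows
    in a ``without_site`` set do not (gapped centres count as absent).
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    group: str
    flank: int = 7
    consensus: str = CONSENSUS

    def __post_init__(self) -> None:
        if self.group not in {WITH_SITE, WITHOUT_SITE}:
            raise ValueError(f"unknown group label {self.group!r}")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        width = self.width
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(
                    f"row {rid!r} has {len(row)} columns, expected {width}"
                )
            centre = row[self.flank : self.flank + MOTIF_LEN]
            if self.group == WITH_SITE and centre != self.consensus:
                raise ValueError(
                    f"with_site row {rid!r} centre {centre!r} != consensus"
                )
            if self.group == WITHOUT_SITE and centre == self.consensus:
                raise ValueError(
                    f"without_site row {rid!r} carries the consensus centre"
                )

    @property
    def width(self) -> int:
        return 2 * self.flank + MOTIF_LEN

    @property
    def center_cols(self) -> tuple[int, ...]:
        return tuple(range(self.flank, self.flank + MOTIF_LEN))

    @property
    def n(self) -> int:
        return len(self.rows)

    def flank_rows(self, side: str) -> tuple[str, ...]:
        """Row slices for one flank: ``five_prime`` or ``three_prime``."""
        if side == "five_prime":
            return tuple(row[: self.flank] for row in self.rows)
        if side == "three_prime":
            return tuple(row[self.flank + MOTIF_LEN :] for row in self.rows)
        raise ValueError(f"side must be 'five_prime' or 'three_prime', got {side!r}")

    def to_records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(id=rid, residues=row, role="promoter")
            for rid, row in zip(self.ids, self.rows)
        ]


def _ungapped_to_column(row: str) -> list[int]:
    return [col for col, ch in enumerate(row) if ch != GAP]


def extract_windows(
    msa: Sequence[SequenceRecord],
    anchor_id: str,
    anchor_start: int,
    consensus: str = CONSENSUS,
    flank: int = 7,
) -> tuple[OrthologousWindowSet, OrthologousWindowSet]:
    """Extract the motif-centred orthologous window from an alignment.

    ``anchor_start`` is the 0-based start of the consensus in the
    *ungapped* reference row ``anchor_id``.  The 6 alignment columns
    covering the reference motif plus ``flank`` columns on each side are
    selected, and every row is assigned to the with-site or without-site
    group by exact consensus match of its (ungapped) window centre.
    Rows whose centre contains gaps go to the without-site group with a
    warning.  Both groups are returned as separately usable aligned
    sets, mirroring the practice of logo-building each group on its own.
    """
    consensus = _validate_consensus(consensus)
    by_id = {rec.id: rec for rec in msa}
    if anchor_id not in by_id:
        raise ValueError(f"anchor row {anchor_id!r} not present in the alignment")
    lengths = {len(rec.residues) for rec in msa}
    if len(lengths) != 1:
        raise ValueError("rows differ in length; input is not an alignment")
    aln_len = lengths.pop()

    ref = by_id[anchor_id]
    colmap = _ungapped_to_column(ref.residues)
    if anchor_start < 0 or anchor_start + MOTIF_LEN > len(colmap):
        raise ValueError(
            f"anchor {anchor_start} out of range for ungapped reference of "
            f"length {len(colmap)}"
        )
    if ref.ungapped[anchor_start : anchor_start + MOTIF_LEN] != consensus:
        raise ValueError(
            f"reference row {anchor_id!r} does not carry the consensus at "
            f"ungapped position {anchor_start}"
        )
    motif_cols = colmap[anchor_start : anchor_start + MOTIF_LEN]
    if motif_cols[-1] - motif_cols[0] != MOTIF_LEN - 1:
        raise ValueError(
            "reference motif spans alignment gap columns; a contiguous "
            f"{2 * flank + MOTIF_LEN}-column window cannot be extracted"
        )
    lo = motif_cols[0] - flank
    hi = motif_cols[-1] + 1 + flank
    if lo < 0 or hi > aln_len:
        raise ValueError(
            f"fewer than {2 * flank + MOTIF_LEN} columns available around the "
            f"anchor (need columns [{lo}, {hi}) in an alignment of {aln_len})"
        )

    with_ids: list[str] = []
    with_rows: list[str] = []
    without_ids: list[str] = []
    without_rows: list[str] = []
    for rec in msa:
        window = rec.residues[lo:hi]
        centre = window[flank : flank + MOTIF_LEN]
        if GAP in centre:
            warnings.warn(
                f"row {rec.id!r} has gaps in the window centre; assigned to "
                "the without-site group",
                stacklevel=2,
            )
            without_ids.append(rec.id)
            without_rows.append(window)
        elif centre == consensus:
            with_ids.append(rec.id)
            with_rows.append(window)
        else:
            without_ids.append(rec.id)
            without_rows.append(window)

    with_set = OrthologousWindowSet(
        ids=tuple(with_ids), rows=tuple(with_rows), group=WITH_SITE,
        flank=flank, consensus=consensus,
    )
    without_set = OrthologousWindowSet(
        ids=tuple(without_ids), rows=tuple(without_rows), group=WITHOUT_SITE,
        flank=flank, consensus=consensus,
    )
    return with_set, without_set
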