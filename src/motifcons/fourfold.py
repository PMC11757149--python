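"""Fourfold-degenerate-site extraction from codon-aware CDS alignments.

A fourfold-degenerate site is a third codon position at which all four
nucleotides encode the same amino acid — the eight codon families GCN
(Ala), CGN (Arg), GGN (Gly), CTN (Leu), CCN (Pro), TCN (Ser), ACN (Thr)
and GTN (Val) under the standard genetic code.  Because the family is
fixed by the first two codon bases, substitutions at these sites are
always synonymous, making them the conventional proxy for neutrally
evolving sequence and hence the source of the resampling null used to
judge flank conservation.

Only the standard nuclear genetic code is supported (plant nuclear
genes); the family table is embedded rather than parameterised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .motifs import GAP, SequenceRecord

#: First-two-base prefixes of the fourfold-degenerate codon families.
FOURFOLD_FAMILY_PREFIXES = frozenset(
    {"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"}
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Sense codons outside the fourfold families (no stop codons).
NON_FOURFOLD_SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if (a + b) not in FOURFOLD_FAMILY_PREFIXES and (a + b + c) not in STOP_CODONS
    )
)


@dataclass(frozen=True)
class FourfoldSiteIndex:
    """0-based alignment columns that are fourfold degenerate in every row."""

    columns: tuple[int, ...]
    source_ids: tuple[str, ...]
    genetic_code: str = "standard"

    def __post_init__(self) -> None:
        for col in self.columns:
            if col % 3 != 2:
                raise ValueError(
                    f"column {col} is not a third codon position (col % 3 != 2)"
                )

    def __len__(self) -> int:
        return len(self.columns)

    def __iter__(self):
        return iter(self.columns)


def _rows(alignment: Sequence[SequenceRecord] | Sequence[str]):
    ids, rows = [], []
    for i, rec in enumerate(alignment):
        if isinstance(rec, SequenceRecord):
            ids.append(rec.id)
            rows.append(rec.residues)
        else:
            ids.append(f"row_{i}")
            rows.append(str(rec).upper())
    return ids, rows


def extract_fourfold_sites(
    alignment: Sequence[SequenceRecord] | Sequence[str],
) -> FourfoldSiteIndex:
    """Third codon positions fourfold degenerate in **every** sequence.

    The alignment must be codon-aware: length divisible by 3 and free of
    gaps (a gapped codon breaks the frame guarantee and is rejected).
    Internal stop codons are rejected with the offending row and codon
    named; a stop in the final codon is tolerated as a terminal stop.
    """
    ids, rows = _rows(alignment)
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("rows differ in length; input is not an alignment")
    aln_len = lengths.pop()
    if aln_len % 3 != 0:
        raise ValueError(
            f"alignment length {aln_len} is not divisible by 3; codon frame unknown"
        )
    n_codons = aln_len // 3
    for rid, row in zip(ids, rows):
        if GAP in row:
            raise ValueError(
                f"row {rid!r} contains gaps; codon-aware gap handling requires "
                "a gap-free alignment"
            )
        for j in range(n_codons - 1):
            codon = row[3 * j : 3 * j + 3]
            if codon in STOP_CODONS:
                raise ValueError(
                    f"internal stop codon {codon} in row {rid!r} at codon {j}"
                )
    columns = []
    for j in range(n_codons):
        if all(row[3 * j : 3 * j + 2] in FOURFOLD_FAMILY_PREFIXES for row in rows):
            columns.append(3 * j + 2)
    return FourfoldSiteIndex(
        columns=tuple(columns), source_ids=tuple(ids), genetic_code="standard"
    )
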