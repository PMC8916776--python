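"""Per-column Shannon-entropy sequence diversity from alignments.

Entropy is reported in bits: H = -sum_a p_a log2 p_a over residue
frequencies in an alignment column; 0 bits means full conservation and
log2(20) ~ 4.32 bits a uniform column. Columns are mapped to reference
residue numbering through a designated reference row (gap columns of the
reference are unmapped). Gaps are excluded from the frequency
denominator by default; counting the gap as a 21st symbol is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

GAP_CHARS = set("-.")


@dataclass
class Alignment:
    """A gapped multiple sequence alignment with a reference row."""

    sequences: list[str]
    ids: list[str]
    reference_id: str
    first_residue_number: int = 1
    column_map: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference row {self.reference_id!r} not present")
        self.sequences = [s.upper() for s in self.sequences]
        ref = self.sequences[self.ids.index(self.reference_id)]
        self.column_map = {}
        residue = self.first_residue_number
        for col, ch in enumerate(ref):
            if ch not in GAP_CHARS:
                self.column_map[residue] = col
                residue += 1

    def column(self, col: int) -> list[str]:
        return [s[col] for s in self.sequences]

    @classmethod
    def from_fasta(
        cls, path: str | Path, reference_id: str, first_residue_number: int = 1
    ) -> "Alignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls(
            sequences=[str(r.seq) for r in recs],
            ids=[r.id for r in recs],
            reference_id=reference_id,
            first_residue_number=first_residue_number,
        )


def column_entropy(column: Sequence[str], gap_policy: str = "exclude") -> float:
    """Shannon entropy (bits) of one alignment column.

    ``gap_policy='exclude'`` drops gaps from the frequency denominator
    (an all-gap column is undefined, returned as NaN);
    ``'as_symbol'`` counts the gap as a 21st residue type.
    """
    if not column:
        raise ValueError("empty column")
    if gap_policy == "exclude":
        letters = [c.upper() for c in column if c.upper() not in GAP_CHARS]
        if not letters:
            return math.nan
    elif gap_policy == "as_symbol":
        letters = ["-" if c in GAP_CHARS else c.upper() for c in column]
    else:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    n = len(letters)
    freqs: dict[str, int] = {}
    for c in letters:
        freqs[c] = freqs.get(c, 0) + 1
    return -sum((k / n) * math.log2(k / n) for k in freqs.values())


def site_entropies(
    aln: Alignment,
    positions: Iterable[int] | None = None,
    gap_policy: str = "exclude",
) -> dict[int, float]:
    """Entropy (bits) per reference residue; unmapped positions -> NaN."""
    if positions is None:
        positions = sorted(aln.column_map)
    out: dict[int, float] = {}
    for pos in positions:
        col = aln.column_map.get(int(pos))
        out[int(pos)] = (
            math.nan if col is None else column_entropy(aln.column(col), gap_policy)
        )
    return out


def n_ungapped(aln: Alignment, position: int) -> int:
    """Number of non-gap residues in the column mapped to ``position``."""
    col = aln.column_map.get(position)
    if col is None:
        return 0
    return sum(1 for c in aln.column(col) if c not in GAP_CHARS)
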