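"""Codon-level utilities for saturation-mutagenesis libraries.

The standard genetic code, single-nucleotide-variant (SNV) codon
enumeration, and a validated coding-sequence container keyed to Ras
residue numbering (constructs typically start at residue 2, the
initiator Met being residue 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

BASES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
STOP_CODONS = ("TAA", "TAG", "TGA")
#: Row order used by enrichment heatmaps: 20 amino acids then the stop row.
AA_ORDER = AMINO_ACIDS + STOP

#: Standard genetic code, codon -> one-letter amino acid ('*' for stop).
GENETIC_CODE: dict[str, str] = {
    "".join(c): str(Seq("".join(c)).translate()) for c in product(BASES, repeat=3)
}


class InvalidSequenceError(ValueError):
    """A DNA string violates the A/C/G/T alphabet or frame constraints."""


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise InvalidSequenceError(f"not a valid codon: {codon!r}")
    return codon


def translate_codon(codon: str) -> str:
    """Translate a codon under the standard genetic code ('*' for stop)."""
    return GENETIC_CODE[_check_codon(codon)]


def translate(dna: str) -> str:
    """Translate an in-frame DNA string codon by codon."""
    if len(dna) % 3:
        raise InvalidSequenceError("sequence length not divisible by 3")
    return "".join(translate_codon(dna[i : i + 3]) for i in range(0, len(dna), 3))


def enumerate_snv_codons(codon: str) -> list[str]:
    """All nine codons one nucleotide away from ``codon``.

    Order is deterministic: position-major, alternative bases alphabetical.
    The input codon itself is never included.
    """
    codon = _check_codon(codon)
    out = []
    for i in range(3):
        for b in BASES:
            if b != codon[i]:
                out.append(codon[:i] + b + codon[i + 1 :])
    return out


def snv_accessible_substitutions(wt_codon: str) -> dict[str, int]:
    """Minimum nucleotide changes from ``wt_codon`` to reach each amino acid.

    Returns a 21-entry mapping (20 amino acids plus ``'*'``) to the minimal
    Hamming distance (0-3) over all codons encoding that amino acid. The
    wild-type amino acid maps to 0. Cancer mutation spectra are dominated by
    the distance-1 (SNV-accessible) entries.
    """
    wt_codon = _check_codon(wt_codon)
    dist: dict[str, int] = {}
    for trial in GENETIC_CODE:
        d = sum(a != b for a, b in zip(wt_codon, trial))
        aa = GENETIC_CODE[trial]
        if aa not in dist or d < dist[aa]:
            dist[aa] = d
    return dist


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame wild-type coding sequence with residue numbering.

    ``first_residue_number`` is the Ras-style number of the first encoded
    residue (e.g. 2 for a 2-166 construct whose initiator Met was removed).
    """

    id: str
    dna: str
    first_residue_number: int = 1
    protein: str = field(init=False)

    def __post_init__(self) -> None:
        dna = self.dna.upper()
        object.__setattr__(self, "dna", dna)
        if len(dna) % 3:
            raise InvalidSequenceError("coding sequence length not divisible by 3")
        prot = translate(dna)
        if STOP in prot:
            raise InvalidSequenceError("internal stop codon in coding sequence")
        object.__setattr__(self, "protein", prot)

    @property
    def n_codons(self) -> int:
        return len(self.dna) // 3

    @property
    def residue_numbers(self) -> range:
        return range(
            self.first_residue_number, self.first_residue_number + self.n_codons
        )

    def codon_at(self, residue: int) -> str:
        """The wild-type codon encoding residue ``residue`` (Ras numbering)."""
        i = residue - self.first_residue_number
        if not 0 <= i < self.n_codons:
            raise KeyError(f"residue {residue} outside construct {self.residue_numbers}")
        return self.dna[3 * i : 3 * i + 3]

    def aa_at(self, residue: int) -> str:
        return translate_codon(self.codon_at(residue))

    def with_codon(self, residue: int, codon: str) -> str:
        """DNA of this construct with one codon substituted."""
        codon = _check_codon(codon)
        i = (residue - self.first_residue_number) * 3
        self.codon_at(residue)  # bounds check
        return self.dna[:i] + codon + self.dna[i + 3 :]

    @classmethod
    def from_fasta(cls, path: str | Path, first_residue_number: int = 1) -> "CodingSequence":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(id=rec.id, dna=str(rec.seq), first_residue_number=first_residue_number)
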