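"""Variant calling from merged amplicon reads and per-codon count tables.

Reads are assumed pre-merged and pre-trimmed to the amplicon frame
(quality filtering, merging and adapter removal happen upstream). A read
is classified into exactly one category:

``wt_synonymous``
    translates to the wild-type protein (including the template itself
    and synonymous wild-type alleles, the internal null distribution);
``single_codon``
    exactly one codon differs at the DNA level and the translation
    differs at one residue (stop codons included, kept as ``'*'``);
``multi_codon``
    any other combination of differing codons — excluded from counting,
    since a single-codon library cannot attribute such reads;
``unreadable``
    length mismatch or ambiguous bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .genetics import (
    BASES,
    STOP_CODONS,
    CodingSequence,
    translate_codon,
)

CATEGORIES = ("wt_synonymous", "single_codon", "multi_codon", "unreadable")


class EmptyInputError(ValueError):
    """No reads were supplied."""


@dataclass(frozen=True)
class VariantCall:
    """Classification of one read against the wild-type reference."""

    category: str
    position: int | None = None
    codon: str | None = None
    amino_acid: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        has_detail = self.position is not None
        if (self.category == "single_codon") != has_detail:
            raise ValueError("position/codon/amino_acid present iff single_codon")


@dataclass
class VariantCountTable:
    """Per-(position, codon) counts for one sample.

    ``counts`` maps (residue number, codon) to a non-negative count;
    fractional values are allowed after baseline correction. ``wt_alleles``
    maps a synonymous wild-type allele identity (its DNA sequence, or a
    label for simulated data) to its count. Stop-codon entries live inside
    ``counts`` and are exposed through :attr:`stop_counts`.
    """

    sample_id: str
    counts: dict[tuple[int, str], float] = field(default_factory=dict)
    wt_alleles: dict[str, float] = field(default_factory=dict)
    total_reads: int = 0
    category_tally: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative variant count")
        if any(v < 0 for v in self.wt_alleles.values()):
            raise ValueError("negative wild-type allele count")

    @property
    def wt_allele_counts(self) -> list[float]:
        return list(self.wt_alleles.values())

    @property
    def stop_counts(self) -> dict[tuple[int, str], float]:
        return {k: v for k, v in self.counts.items() if k[1] in STOP_CODONS}

    def scaled(self, factor: float) -> "VariantCountTable":
        """Every count (variants and WT alleles alike) multiplied by ``factor``."""
        return VariantCountTable(
            sample_id=self.sample_id,
            counts={k: v * factor for k, v in self.counts.items()},
            wt_alleles={k: v * factor for k, v in self.wt_alleles.items()},
            total_reads=self.total_reads,
        )

    # ------------------------------------------------------------------ IO
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "position": pos,
                "codon": codon,
                "amino_acid": translate_codon(codon),
                "count": c,
            }
            for (pos, codon), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "position", "codon", "amino_acid", "count"]
        )

    def write(self, path: str | Path, wt_path: str | Path | None = None) -> None:
        """Write the count table (and optionally the WT-allele table) as TSV."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        if wt_path is not None:
            pd.DataFrame(
                {
                    "sample_id": self.sample_id,
                    "allele": list(self.wt_alleles),
                    "count": list(self.wt_alleles.values()),
                }
            ).to_csv(wt_path, sep="\t", index=False)

    @classmethod
    def read(
        cls, path: str | Path, wt_path: str | Path | None = None
    ) -> "VariantCountTable":
        df = pd.read_csv(path, sep="\t")
        sample_id = str(df["sample_id"].iloc[0]) if len(df) else "sample"
        counts = {
            (int(r.position), str(r.codon)): float(r.count) for r in df.itertuples()
        }
        wt: dict[str, float] = {}
        if wt_path is not None:
            wdf = pd.read_csv(wt_path, sep="\t")
            wt = {str(r.allele): float(r.count) for r in wdf.itertuples()}
        return cls(sample_id=sample_id, counts=counts, wt_alleles=wt,
                   total_reads=int(df["count"].sum()) if len(df) else 0)


def call_variant(read: str, reference: CodingSequence) -> VariantCall:
    """Classify one merged read against the wild-type coding sequence."""
    read = read.strip().upper()
    if len(read) != len(reference.dna) or any(b not in BASES for b in read):
        return VariantCall("unreadable")
    if read == reference.dna:
        return VariantCall("wt_synonymous")
    diffs: list[int] = []  # codon indices differing at the DNA level
    nonsyn: list[int] = []
    for i in range(reference.n_codons):
        codon = read[3 * i : 3 * i + 3]
        if codon != reference.dna[3 * i : 3 * i + 3]:
            diffs.append(i)
            if translate_codon(codon) != reference.protein[i]:
                nonsyn.append(i)
    if not nonsyn:
        return VariantCall("wt_synonymous")
    if len(diffs) == 1 and len(nonsyn) == 1:
        i = nonsyn[0]
        codon = read[3 * i : 3 * i + 3]
        return VariantCall(
            "single_codon",
            position=reference.first_residue_number + i,
            codon=codon,
            amino_acid=translate_codon(codon),
        )
    # one non-synonymous change plus synonymous hitchhikers, or >=2
    # non-synonymous codons: cannot be attributed to a library variant.
    return VariantCall("multi_codon")


def count_variants(
    reads: Iterable[str], reference: CodingSequence, sample_id: str = "sample"
) -> VariantCountTable:
    """Tally classified reads into a :class:`VariantCountTable`.

    multi_codon and unreadable reads are excluded from the table but
    reported in ``category_tally``.
    """
    counts: dict[tuple[int, str], float] = {}
    wt: dict[str, float] = {}
    tally = dict.fromkeys(CATEGORIES, 0)
    n = 0
    for read in reads:
        n += 1
        call = call_variant(read, reference)
        tally[call.category] += 1
        if call.category == "wt_synonymous":
            key = read.strip().upper()
            wt[key] = wt.get(key, 0) + 1
        elif call.category == "single_codon":
            k = (call.position, call.codon)
            counts[k] = counts.get(k, 0) + 1
    if n == 0:
        raise EmptyInputError("no reads supplied")
    return VariantCountTable(
        sample_id=sample_id,
        counts=counts,
        wt_alleles=wt,
        total_reads=n,
        category_tally=tally,
    )


def read_sequences(path: str | Path) -> list[str]:
    """Load reads from FASTQ/FASTA (by extension) or one-sequence-per-line text."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in {".fastq", ".fq"}:
        return [str(r.seq) for r in SeqIO.parse(str(p), "fastq")]
    if suffix in {".fasta", ".fa", ".fna"}:
        return [str(r.seq) for r in SeqIO.parse(str(p), "fasta")]
    return [line.strip() for line in p.read_text().splitlines() if line.strip()]
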