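"""Amplicon panel model and its on-disk formats (FASTA + CpG BED).

An :class:`AmpliconTarget` is one bisulfite-PCR amplicon: the top-strand
reference sequence of the targeted region together with the 0-based offsets
of the C of every CpG dinucleotide it contains.  The default nine-gene panel
carries the gene symbols CALD1, RRP1, FN1, DIP2C, RMI2, TDRD5, USP1, HDAC1
and DNMT1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Gene symbols of the default diagnostic panel, in fixed panel order.
DEFAULT_GENES: tuple[str, ...] = (
    "CALD1", "RRP1", "FN1", "DIP2C", "RMI2", "TDRD5", "USP1", "HDAC1", "DNMT1",
)

#: Genes hypomethylated in cases under the default synthetic truth.
DEFAULT_HYPO_GENES: tuple[str, ...] = ("DIP2C", "DNMT1", "RRP1", "USP1")

MIN_AMPLICON_LEN = 80
MAX_AMPLICON_LEN = 400


def find_cpg_sites(sequence: str) -> tuple[int, ...]:
    """Return 0-based offsets of the C of every CpG dinucleotide."""
    return tuple(
        i for i in range(len(sequence) - 1) if sequence[i] == "C" and sequence[i + 1] == "G"
    )


@dataclass(frozen=True)
class AmpliconTarget:
    """One panel amplicon: gene symbol, top-strand sequence, CpG offsets."""

    gene_symbol: str
    sequence: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        seq = self.sequence
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.gene_symbol}: sequence must be upper-case A/C/G/T")
        if not (MIN_AMPLICON_LEN <= len(seq) <= MAX_AMPLICON_LEN):
            raise ValueError(
                f"{self.gene_symbol}: amplicon length {len(seq)} outside "
                f"[{MIN_AMPLICON_LEN}, {MAX_AMPLICON_LEN}]"
            )
        pos = tuple(self.cpg_positions)
        object.__setattr__(self, "cpg_positions", pos)
        if len(pos) < 1:
            raise ValueError(f"{self.gene_symbol}: at least one CpG required")
        if any(b >= a for a, b in zip(pos[1:], pos)):
            raise ValueError(f"{self.gene_symbol}: cpg_positions must be strictly increasing")
        for p in pos:
            if p < 0 or p + 1 >= len(seq) or seq[p] != "C" or seq[p + 1] != "G":
                raise ValueError(f"{self.gene_symbol}: position {p} is not the C of a CpG")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @classmethod
    def from_sequence(cls, gene_symbol: str, sequence: str) -> "AmpliconTarget":
        """Build a target, discovering every CpG in ``sequence``."""
        return cls(gene_symbol, sequence, find_cpg_sites(sequence))


def write_panel_fasta(panel: Sequence[AmpliconTarget], path: str | Path) -> Path:
    """Write amplicon reference sequences as FASTA (header = gene symbol)."""
    path = Path(path)
    records = [
        SeqRecord(Seq(t.sequence), id=t.gene_symbol, description="") for t in panel
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def write_cpg_bed(panel: Sequence[AmpliconTarget], path: str | Path) -> Path:
    """Write CpG annotation as BED (0-based half-open, one record per CpG C)."""
    path = Path(path)
    rows = [
        (t.gene_symbol, p, p + 1, f"{t.gene_symbol}_CpG{i + 1}")
        for t in panel
        for i, p in enumerate(t.cpg_positions)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    return path


def load_panel(fasta_path: str | Path, bed_path: str | Path | None = None) -> list[AmpliconTarget]:
    """Load a panel from FASTA, taking CpG offsets from BED or by rescanning.

    When a BED file is given its positions are validated against the sequence;
    without one, every CpG dinucleotide in the sequence is annotated.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if bed_path is None:
        return [AmpliconTarget.from_sequence(g, s) for g, s in seqs.items()]
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, usecols=[0, 1], names=["gene", "start"]
    )
    panel = []
    for gene, seq in seqs.items():
        starts = tuple(int(x) for x in sorted(bed.loc[bed["gene"] == gene, "start"]))
        panel.append(AmpliconTarget(gene, seq, starts))
    return panel


def panel_genes(panel: Iterable[AmpliconTarget]) -> list[str]:
    return [t.gene_symbol for t in panel]
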