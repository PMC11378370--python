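"""Input/output: genome FASTA files and the gene catalogue table.

The catalogue is a tab-separated table with header
``id  chrom  start  end  strand  class`` using 1-based inclusive
coordinates, mirroring how de novo gene catalogues are published.
Conversion to Python's 0-based half-open indexing happens only at the
point of slicing a chromosome string, never in user-facing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONSERVATION_CLASSES = ("S0+", "S1", "S2", "S3", "S4", "intergene")

CATALOGUE_COLUMNS = ["id", "chrom", "start", "end", "strand", "class"]


@dataclass(frozen=True)
class CatalogueEntry:
    """One catalogued locus: genomic interval plus conservation class."""

    id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    conservation_class: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.id}: coordinates are 1-based, got start={self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.conservation_class not in CONSERVATION_CLASSES:
            raise ValueError(
                f"{self.id}: unknown conservation class {self.conservation_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into a dict chromosome name -> sequence."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        genome[record.id] = str(record.seq).upper()
    return genome


def write_genome(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_catalogue(path: str | Path) -> list[CatalogueEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = set(CATALOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalogue is missing columns: {sorted(missing)}")
    return [
        CatalogueEntry(
            id=str(row["id"]),
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
            conservation_class=str(row["class"]),
        )
        for _, row in df.iterrows()
    ]


def write_catalogue(entries: list[CatalogueEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (e.id, e.chrom, e.start, e.end, e.strand, e.conservation_class)
            for e in entries
        ],
        columns=CATALOGUE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
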