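"""Readers/writers for the formats the pipeline touches, and packaged fixtures.

All internal coordinates are 0-based, half-open.  GFF3 files use the
standard's 1-based inclusive convention; conversion happens only at the
read/write boundary.  Exon chains are stored in transcription order, i.e.
for minus-strand genes the first exon has the largest genomic coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file (names the offending record)."""


class ModelConsistencyError(ValueError):
    """A gene model violates a structural invariant (e.g. CDS outside exon)."""


@dataclass
class ProteinRecord:
    """A named amino-acid sequence with optional annotations."""

    id: str
    sequence: str
    species: str | None = None
    declared_subclade: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Table1Row:
    """One row of the packaged 44-gene cotton PRX characteristics table."""

    gene_name: str
    gene_id: str
    subclade: str
    exon_count: int
    protein_aa: int
    pI: float
    mw_da: float
    chromosome: str
    start: int
    end: int
    notes: str = ""

    def __post_init__(self) -> None:
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_name}: exon_count must be >= 1")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_name}: start must be < end")

    @property
    def species_prefix(self) -> str:
        """Two-letter species code derived from the gene name (Gh/Gb/Gr/Ga)."""
        return self.gene_name[:2]


def _check_chain(name: str, exons: list[tuple[int, int]], strand: str) -> None:
    for s, e in exons:
        if not 0 <= s < e:
            raise ModelConsistencyError(f"{name}: bad interval ({s}, {e})")
    genomic = sorted(exons)
    for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
        if s2 < e1:
            raise ModelConsistencyError(f"{name}: overlapping exons")
    expected = genomic if strand == "+" else genomic[::-1]
    if exons != expected:
        raise ModelConsistencyError(
            f"{name}: exons not in transcription order for strand {strand}"
        )


@dataclass
class GeneModel:
    """Exon/CDS coordinate chain of one gene on one strand of a contig.

    ``exons`` and ``cds`` are lists of 0-based half-open genomic intervals,
    ordered in transcription direction (descending genomic start on '-').
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelConsistencyError(
                f"{self.gene_id}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise ModelConsistencyError(f"{self.gene_id}: no exons")
        _check_chain(self.gene_id, self.exons, self.strand)
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ModelConsistencyError(
                    f"{self.gene_id}: CDS interval ({cs}, {ce}) "
                    "not contained in any exon"
                )

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        """Exons sorted by ascending genomic coordinate."""
        return sorted(self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Introns as genomic intervals, in transcription order."""
        genomic = self.exons_genomic
        gaps = [(e1, s2) for (_, e1), (s2, _) in zip(genomic, genomic[1:])]
        return gaps if self.strand == "+" else gaps[::-1]

    @property
    def span(self) -> tuple[int, int]:
        genomic = self.exons_genomic
        return genomic[0][0], genomic[-1][1]

    def cds_start(self) -> int:
        """Genomic coordinate of the first transcribed CDS base (the A of ATG).

        On '+' this is the smallest CDS start; on '-' it is the largest CDS
        end, returned as the 0-based position of that base.
        """
        if not self.cds:
            raise ModelConsistencyError(f"{self.gene_id}: no CDS annotation")
        if self.strand == "+":
            return min(s for s, _ in self.cds)
        return max(e for _, e in self.cds) - 1


@dataclass
class NucleotideRecord:
    """A named nucleotide sequence (ACGTN alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - NT_ALPHABET
        if bad:
            raise ParseError(f"record {self.id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path, alphabet: str = "protein"):
    """Read a FASTA file into validated records, preserving file order.

    Sequences are uppercased; gap characters and out-of-alphabet residues
    raise :class:`ParseError` naming the record.  ``alphabet`` is
    ``"protein"`` (returns :class:`ProteinRecord`) or ``"nucleotide"``
    (returns :class:`NucleotideRecord`).
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    cls = ProteinRecord if alphabet == "protein" else NucleotideRecord
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise ParseError(f"record {rec.id!r}: duplicate id")
        seen.add(rec.id)
        records.append(cls(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records (anything with .id and .sequence) as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_genome_fasta(path) -> dict[str, str]:
    """Read a genome FASTA into a contig -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3(path, transcript_ids: dict[str, str] | None = None) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features of a GFF3 file into gene models.

    One transcript per gene: multi-mRNA genes take the first mRNA unless
    ``transcript_ids`` maps the gene id to a chosen transcript id.  Exon
    chains of minus-strand genes are returned in transcription order.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if mrnas:
            chosen = mrnas[0]
            if transcript_ids and gene.id in transcript_ids:
                wanted = transcript_ids[gene.id]
                match = [m for m in mrnas if m.id == wanted]
                if not match:
                    raise ParseError(
                        f"gene {gene.id}: transcript {wanted!r} not found"
                    )
                chosen = match[0]
            parent = chosen
        else:
            parent = gene
        exons = [
            (f.start - 1, f.end)
            for f in db.children(parent, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(parent, featuretype="CDS", order_by="start")
        ]
        if not exons:
            raise ParseError(f"gene {gene.id}: no exon features")
        if gene.strand == "-":
            exons = sorted(exons)[::-1]
            cds = sorted(cds)[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene models as a minimal gene/mRNA/exon/CDS GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            base = f"{m.contig}\tcottonprx\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(
                f"{base}gene\t{s + 1}\t{e}{tail}.\tID={m.gene_id}\n"
                f"{base}mRNA\t{s + 1}\t{e}{tail}.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(sorted(m.exons), 1):
                fh.write(
                    f"{base}exon\t{xs + 1}\t{xe}{tail}.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}.t1\n"
                )
            for i, (cs, ce) in enumerate(sorted(m.cds), 1):
                fh.write(
                    f"{base}CDS\t{cs + 1}\t{ce}{tail}0\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id}.t1\n"
                )


_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def spliced_sequence(contig_seq: str, exons, strand: str) -> str:
    """Mature transcript sequence of an exon chain on a contig."""
    parts = [contig_seq[s:e] for s, e in sorted(exons)]
    seq = "".join(parts)
    return seq if strand == "+" else revcomp(seq)


def load_table1_fixture() -> list[Table1Row]:
    """Load the packaged 44-row gene characteristics fixture."""
    with resources.files("cottonprx.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    rows = [
        Table1Row(
            gene_name=r.gene_name,
            gene_id=r.gene_id,
            subclade=r.subclade,
            exon_count=int(r.exon_count),
            protein_aa=int(r.protein_aa),
            pI=float(r.pI),
            mw_da=float(r.mw_da),
            chromosome=r.chromosome,
            start=int(r.start),
            end=int(r.end),
            notes=str(r.notes),
        )
        for r in df.itertuples()
    ]
    if len(rows) != 44:
        raise ParseError(f"table1 fixture has {len(rows)} rows, expected 44")
    return rows


def table1_fixture_bytes() -> bytes:
    """Raw bytes of the packaged fixture (for integrity checks)."""
    return resources.files("cottonprx.data").joinpath("table1.tsv").read_bytes()


#: Subclade labels of the characteristics table mapped to active-site
#: subfamilies (PRX1 = typical two-cysteine PRX, PRX2 = chloroplastic type II,
#: TPX = cytosolic type II, PRX5 = mitochondrial type II, PRX6 = 1-Cys).
SUBCLADE_TO_SUBFAMILY = {
    "PRX1": "2-CysPRX",
    "PRX2": "PRXIIE",
    "TPX": "PRXIIB",
    "PRXQ": "PRXQ",
    "PRX5": "PRXIIF",
    "PRX6": "1-CysPRX",
}
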