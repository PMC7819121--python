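"""Strand-aware promoter extraction and cis-element catalogue scanning.

Promoters are the bases immediately upstream of the translation initiation
codon (default 2,500 bp, the extraction window; figures typically display
the proximal 1,500 bp, a separate report window).  The packaged catalogue
holds 28 named elements with IUPAC consensus strings in three classes:
9 abiotic-stress, 10 hormone-responsive and 9 growth/development elements.
Matching is exact IUPAC-set membership on both strands; no mismatches, no
position weights.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io_formats import GeneModel, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

ELEMENT_CLASSES = ("abiotic", "hormone", "growth", "light")

DEFAULT_EXTRACTION_LENGTH = 2500
DEFAULT_REPORT_WINDOW = 1500


@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str
    klass: str

    def __post_init__(self) -> None:
        if self.klass not in ELEMENT_CLASSES:
            raise ValueError(f"{self.name}: unknown class {self.klass!r}")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC codes {sorted(bad)}")


@dataclass(frozen=True)
class CisElementHit:
    gene_id: str
    element: str
    klass: str
    offset: int  # 1-based position of the leftmost matched base
    strand: str
    matched: str


def load_catalogue(path=None) -> list[CisElement]:
    """Load a name/consensus/class catalogue TSV (packaged default)."""
    if path is None:
        src = resources.files("cottonprx.data").joinpath("cis_elements.tsv")
        with src.open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    entries = [
        CisElement(str(name), str(consensus).upper(), str(klass))
        for name, consensus, klass in df.itertuples(index=False, name=None)
    ]
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("catalogue element names must be unique")
    return entries


def extract_promoter(
    genome: dict[str, str],
    model: GeneModel,
    length: int = DEFAULT_EXTRACTION_LENGTH,
) -> str:
    """The ``length`` bases immediately 5' of the CDS start (the ATG).

    For minus-strand genes the genomic bases 3' of the CDS start are taken
    and reverse-complemented, so the returned string always reads 5'->3'
    toward the start codon.  Truncated with a warning at contig edges.
    """
    if model.contig not in genome:
        raise KeyError(f"contig {model.contig!r} not in genome")
    contig = genome[model.contig]
    tis = model.cds_start()
    if model.strand == "+":
        start = max(0, tis - length)
        promoter = contig[start:tis]
    else:
        end = min(len(contig), tis + 1 + length)
        promoter = revcomp(contig[tis + 1 : end])
    if len(promoter) < length:
        warnings.warn(
            f"{model.gene_id}: promoter truncated to {len(promoter)} bp "
            "at contig edge",
            stacklevel=2,
        )
    return promoter


def _consensus_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in consensus
    )
    return re.compile(f"(?=({body}))")


def scan_elements(
    promoter: str,
    catalogue: list[CisElement],
    gene_id: str = "",
    strands: str = "both",
) -> list[CisElementHit]:
    """Every occurrence of every consensus on the requested strands.

    Offsets are 1-based from the promoter's 5' end and always refer to the
    leftmost base of the matched plus-strand window; minus-strand hits are
    occurrences of the reverse-complemented consensus.  Overlaps allowed;
    deterministic (offset, element, strand) order.
    """
    if strands not in ("both", "plus"):
        raise ValueError("strands must be 'both' or 'plus'")
    hits: list[CisElementHit] = []
    for element in catalogue:
        patterns = [("+", element.consensus)]
        if strands == "both":
            rc = element.consensus.translate(IUPAC_COMPLEMENT)[::-1]
            patterns.append(("-", rc))
        for strand, consensus in patterns:
            for m in _consensus_regex(consensus).finditer(promoter):
                hits.append(
                    CisElementHit(
                        gene_id=gene_id,
                        element=element.name,
                        klass=element.klass,
                        offset=m.start() + 1,
                        strand=strand,
                        matched=m.group(1),
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.element, h.strand))
    return hits


def class_summary(
    hits: list[CisElementHit], catalogue: list[CisElement]
) -> pd.DataFrame:
    """Per-gene hit counts and distinct element-type counts by class."""
    known = {e.name: e.klass for e in catalogue}
    for h in hits:
        if h.element not in known:
            raise ValueError(f"unknown element {h.element!r}")
    classes = sorted({e.klass for e in catalogue})
    genes = sorted({h.gene_id for h in hits})
    rows = []
    for gene in genes or [""]:
        gene_hits = [h for h in hits if h.gene_id == gene]
        for klass in classes:
            k_hits = [h for h in gene_hits if h.klass == klass]
            rows.append(
                (gene, klass, len(k_hits), len({h.element for h in k_hits}))
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "class", "n_hits", "n_distinct_types"]
    )


def catalogue_class_counts(catalogue: list[CisElement]) -> dict[str, int]:
    """Distinct element types per class in a catalogue."""
    counts: dict[str, int] = {}
    for e in catalogue:
        counts[e.klass] = counts.get(e.klass, 0) + 1
    return counts
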