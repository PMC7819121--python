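"""Exon/intron architecture: counts, lengths, phases, and 5'UTR introns."""

from __future__ import annotations

import pandas as pd

from .io_formats import GeneModel, ModelConsistencyError, Table1Row


def intron_count(model: GeneModel | Table1Row) -> int:
    """Number of introns: exon count minus one."""
    if isinstance(model, Table1Row):
        return model.exon_count - 1
    return len(model.exons) - 1


def _oriented(iv: tuple[int, int], strand: str) -> tuple[int, int]:
    # map genomic [s, e) onto an axis increasing in transcription direction
    s, e = iv
    return (s, e) if strand == "+" else (-e, -s)


def utr_intron_before_tis(model: GeneModel) -> bool:
    """True iff at least one intron lies wholly 5' of the first CDS base.

    An intron interrupting the start codon does not count: the whole intron
    must be upstream of the translation initiation site in transcription
    orientation.
    """
    if not model.cds:
        raise ModelConsistencyError(f"{model.gene_id}: CDS annotation required")
    tis = model.cds_start()
    tis_axis = tis if model.strand == "+" else -tis - 1
    return any(
        _oriented(intron, model.strand)[1] <= tis_axis
        for intron in model.introns
    )


def exon_intron_table(models: list[GeneModel]) -> pd.DataFrame:
    """Per-gene table of exon/intron lengths and intron phases.

    One row per feature in transcription order.  The phase of an intron is
    the cumulative CDS length 5' of it modulo 3 (UTR excluded, standard
    GFF3 semantics); exons and UTR-only introns carry phase NA.  Feature
    lengths sum to the genomic span of each gene.
    """
    rows = []
    for m in models:
        cds_axis = sorted(_oriented(iv, m.strand) for iv in m.cds)
        exons_axis = [_oriented(iv, m.strand) for iv in m.exons]
        introns_axis = [_oriented(iv, m.strand) for iv in m.introns]
        for i, (s, e) in enumerate(exons_axis, start=1):
            rows.append((m.gene_id, "exon", i, e - s, pd.NA))
            if i <= len(introns_axis):
                js, je = introns_axis[i - 1]
                cds_before = sum(
                    max(0, min(ce, js) - cs) for cs, ce in cds_axis
                )
                phase = cds_before % 3 if cds_before > 0 else pd.NA
                rows.append((m.gene_id, "intron", i, je - js, phase))
    return pd.DataFrame(
        rows, columns=["gene_id", "feature", "index", "length", "phase"]
    )
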