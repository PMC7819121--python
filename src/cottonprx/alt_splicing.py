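"""Alternative-splicing event classification against a reference gene model.

An observed transcript's exon chain is compared with the reference chain on
the same contig and strand.  Event types:

* IR    — a reference intron retained whole inside one transcript exon
* ES    — reference exon(s) skipped: both flanking introns merged into one
* A5SS  — the donor (5') boundary of an intron moved
* A3SS  — the acceptor (3') boundary of an intron moved; a retention of the
          3'-terminal bases of an intron is structurally A3SS but is also
          aliased "partial-IR" to match the vocabulary used for such events
          in cloning studies
* AFE / ALE — a different first / last exon with the internal chain intact

Boundary dinucleotides are the first two and last two bases of the spliced
segment in transcription orientation; a junction is canonical iff GT..AG.
ORF consequences use the longest open reading frame from an ATG to the
first in-frame stop; the reported ORF length excludes the stop codon, so
the encoded protein length is orf_bp / 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .io_formats import GeneModel, ModelConsistencyError, spliced_sequence

EVENT_TYPES = ("IR", "ES", "A3SS", "A5SS", "AFE", "ALE")


@dataclass
class TranscriptModel:
    """An exon chain (transcription order, genomic intervals) of a transcript."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    provenance: str = "observed"  # or "reference"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelConsistencyError(
                f"{self.transcript_id}: unknown strand {self.strand!r}"
            )
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ModelConsistencyError(
                    f"{self.transcript_id}: overlapping exons"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if self.exons != expected:
            raise ModelConsistencyError(
                f"{self.transcript_id}: exons not in transcription order"
            )


@dataclass
class ASEvent:
    """One typed splicing difference relative to the reference model.

    Indices are 1-based in transcription order.  ``intron_interval`` is the
    genomic interval of the spliced segment whose boundaries the event
    disrupts (for IR, the retained reference intron itself).
    """

    type: str
    ref_introns: tuple[int, ...] = ()
    ref_exons: tuple[int, ...] = ()
    length_bp: int = 0
    intron_interval: tuple[int, int] | None = None
    donor: str | None = None
    acceptor: str | None = None
    canonical: bool | None = None
    paper_label: str | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.length_bp <= 0:
            raise ValueError("event length must be positive")
        if self.paper_label is None:
            self.paper_label = self.type


def _orient(iv: tuple[int, int], strand: str) -> tuple[int, int]:
    s, e = iv
    return (s, e) if strand == "+" else (-e, -s)


def _deorient(iv: tuple[int, int], strand: str) -> tuple[int, int]:
    s, e = iv
    return (s, e) if strand == "+" else (-e, -s)


def _introns(exons_axis: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [
        (e1, s2) for (_, e1), (s2, _) in zip(exons_axis, exons_axis[1:])
    ]


def classify_events(ref: GeneModel, alt: TranscriptModel) -> list[ASEvent]:
    """Compare intron chains and emit typed events, ordered 5'->3'.

    Identical chains give an empty list.  Differing contig or strand is an
    error, not an event.
    """
    if ref.contig != alt.contig or ref.strand != alt.strand:
        raise ModelConsistencyError(
            f"{alt.transcript_id}: contig/strand differs from {ref.gene_id}"
        )
    strand = ref.strand
    re_axis = sorted(_orient(iv, strand) for iv in ref.exons)
    ae_axis = sorted(_orient(iv, strand) for iv in alt.exons)
    if re_axis == ae_axis:
        return []

    events: list[tuple[int, ASEvent]] = []

    def emit(pos: int, event: ASEvent) -> None:
        if event.intron_interval is not None:
            event.intron_interval = _deorient(event.intron_interval, strand)
        events.append((pos, event))

    # alternative first / last exon: internal chain identical, terminal
    # exon replaced by a non-overlapping one
    def _overlap(a, b) -> bool:
        return max(a[0], b[0]) < min(a[1], b[1])

    ri = _introns(re_axis)
    ai = _introns(ae_axis)

    if (
        len(re_axis) > 1
        and len(ae_axis) > 1
        and re_axis[1:] == ae_axis[1:]
        and not _overlap(re_axis[0], ae_axis[0])
    ):
        first = ae_axis[0]
        emit(
            first[0],
            ASEvent(
                type="AFE",
                ref_exons=(1,),
                length_bp=first[1] - first[0],
                intron_interval=(first[1], ae_axis[1][0]),
            ),
        )
        return _finalize(events)
    if (
        len(re_axis) > 1
        and len(ae_axis) > 1
        and re_axis[:-1] == ae_axis[:-1]
        and not _overlap(re_axis[-1], ae_axis[-1])
    ):
        last = ae_axis[-1]
        emit(
            last[0],
            ASEvent(
                type="ALE",
                ref_exons=(len(re_axis),),
                length_bp=last[1] - last[0],
                intron_interval=(ae_axis[-2][1], last[0]),
            ),
        )
        return _finalize(events)

    ri_set = set(ri)
    handled_ref: set[int] = set()

    for a in ai:
        if a in ri_set:
            continue
        touching = [i for i, r in enumerate(ri) if _overlap(r, a)]
        if not touching:
            continue  # novel intron wholly inside a reference exon
        handled_ref.update(touching)
        first_r, last_r = ri[touching[0]], ri[touching[-1]]
        skipped = [
            i
            for i, x in enumerate(re_axis)
            if a[0] <= x[0] and x[1] <= a[1]
        ]
        if skipped:
            emit(
                re_axis[skipped[0]][0],
                ASEvent(
                    type="ES",
                    ref_exons=tuple(i + 1 for i in skipped),
                    ref_introns=tuple(i + 1 for i in touching),
                    length_bp=sum(
                        re_axis[i][1] - re_axis[i][0] for i in skipped
                    ),
                    intron_interval=a,
                ),
            )
        if a[0] != first_r[0]:
            emit(
                a[0],
                ASEvent(
                    type="A5SS",
                    ref_introns=(touching[0] + 1,),
                    length_bp=abs(a[0] - first_r[0]),
                    intron_interval=a,
                    paper_label=(
                        "partial-IR"
                        if not skipped and a[0] > first_r[0]
                        else "A5SS"
                    ),
                ),
            )
        if a[1] != last_r[1]:
            emit(
                a[1],
                ASEvent(
                    type="A3SS",
                    ref_introns=(touching[-1] + 1,),
                    length_bp=abs(last_r[1] - a[1]),
                    intron_interval=a,
                    paper_label=(
                        "partial-IR" if a[1] < last_r[1] else "A3SS"
                    ),
                ),
            )

    ai_set = set(ai)
    for i, r in enumerate(ri):
        if i in handled_ref or r in ai_set:
            continue
        if any(x[0] <= r[0] and r[1] <= x[1] for x in ae_axis):
            emit(
                r[0],
                ASEvent(
                    type="IR",
                    ref_introns=(i + 1,),
                    length_bp=r[1] - r[0],
                    intron_interval=r,
                ),
            )

    return _finalize(events)


def _finalize(events: list[tuple[int, ASEvent]]) -> list[ASEvent]:
    events.sort(key=lambda t: t[0])
    return [e for _, e in events]


def boundary_dinucleotides(
    contig_seq: str, intron: tuple[int, int], strand: str
) -> tuple[str, str, bool]:
    """(donor, acceptor, canonical) of a spliced segment.

    Donor and acceptor are the first two and last two bases of the segment
    in transcription orientation; canonical iff the pair is GT..AG.  The
    segment must be at least 4 bp.
    """
    s, e = intron
    if e - s < 4:
        raise ValueError(f"intron ({s}, {e}) shorter than 4 bp")
    seq = contig_seq[s:e]
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    donor, acceptor = seq[:2], seq[-2:]
    return donor, acceptor, (donor == "GT" and acceptor == "AG")


def annotate_boundaries(
    events: list[ASEvent], genome: dict[str, str], ref: GeneModel
) -> list[ASEvent]:
    """Fill donor/acceptor dinucleotides and canonical flags in place."""
    contig = genome[ref.contig]
    for ev in events:
        if ev.intron_interval is None:
            continue
        d, a, canonical = boundary_dinucleotides(
            contig, ev.intron_interval, ref.strand
        )
        ev.donor, ev.acceptor, ev.canonical = d, a, canonical
    return events


def orf_and_translate(transcript: str) -> tuple[int, int]:
    """(ORF length in bp excluding the stop codon, protein length in aa).

    The longest ORF from an ATG to the first in-frame stop; ties go to the
    most 5' start.  (0, 0) when no complete ORF exists.
    """
    transcript = transcript.upper()
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    search = 0
    while True:
        atg = transcript.find("ATG", search)
        if atg < 0:
            break
        search = atg + 1
        for i in range(atg, len(transcript) - 2, 3):
            codon = transcript[i : i + 3]
            if codon in stops:
                best = max(best, i - atg)
                break
    return best, best // 3


def transcript_sequence(
    genome: dict[str, str], transcript: TranscriptModel
) -> str:
    """Mature (spliced) sequence of a transcript's exon chain."""
    return spliced_sequence(
        genome[transcript.contig], transcript.exons, transcript.strand
    )
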