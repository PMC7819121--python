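"""Seeded generators for every input the pipeline consumes.

Each generator plants known ground truth (subfamily labels, event types and
lengths, substitution counts, element offsets, fold changes) and returns it
in machine-readable form so the analysis modules can be round-trip tested.
Backgrounds are uniform over the relevant alphabet — the simplest null that
still exercises every matcher.  Protein backgrounds exclude cysteine so the
planted cysteines are the only ones a classifier can find; planted motifs
never overlap and keep a margin of at least 10 residues.

All randomness flows from ``SimulationConfig.seed``; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .active_site import (
    ONE_CYS_CTX,
    PRXIIB_CTX,
    PRXIIE_CTX,
    PRXIIF_CTX,
    PRXII_SPACING,
    TWO_CYS_CYSP_CTX,
    TWO_CYS_CYSR_CTX,
)
from .alt_splicing import TranscriptModel
from .io_formats import GeneModel, ProteinRecord, revcomp
from .promoter_cis import IUPAC, CisElement

# background alphabet excludes C: planted cysteines are the only cysteines
AA_BACKGROUND = "ADEFGHIKLMNPQRSTVWY"
NT_BACKGROUND = "ACGT"

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Knobs of all generators; defaults are the study conditions.

    Protein lengths per subfamily follow the characteristics table
    (146-266 aa across the family); the two-cysteine fixture is 250 aa with
    the peroxidatic Cys near residue 118 and the resolving EVCP context
    near residue 240.  Duplicate pairs carry a handful of planted
    substitutions on a 200-codon CDS (low divergence).  Ct tables use the
    3-replicate, 0/1/3/6/12 h design with a realistic 0.15-cycle replicate
    noise.
    """

    seed: int = 0
    protein_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "2-CysPRX": 250,
            "PRXQ": 216,
            "PRXIIB": 162,
            "PRXIIE": 227,
            "PRXIIF": 198,
            "1-CysPRX": 219,
        }
    )
    diagnostic_noise: int = 0  # mismatches planted into diagnostic contexts
    exon_counts: dict[str, int] = field(
        default_factory=lambda: {
            "2-CysPRX": 7,
            "PRXIIE": 1,
            "PRXIIB": 3,
            "PRXQ": 4,
            "PRXIIF": 5,
            "1-CysPRX": 4,
        }
    )
    duplicate_n_codons: int = 200
    duplicate_n_syn: int = 12
    duplicate_n_nonsyn: int = 6
    promoter_length: int = 2500
    ct_replicates: int = 3
    ct_timepoints: tuple[int, ...] = (0, 1, 3, 6, 12)
    ct_noise_sd: float = 0.15

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# proteins with planted active sites


#: Cys_P context of the PRXQ fixture: satisfies the catalytic core and
#: carries the resolving Cys four residues after Cys_P.
PRXQ_CTX = ("LPGAFTPSCSSKHC", 8)

#: Resolving-position contexts planted downstream of type II Cys_P contexts.
TYPE_II_CYSR_CTX = TWO_CYS_CYSR_CTX  # EVCP, Cys at index 2
RECLASS_CYSR_CTX = ("EVVP", 2)  # resolving Cys mutated to Val

_PROTEIN_BLUEPRINTS: dict[str, dict] = {
    # cysP: target 0-based position of the peroxidatic Cys;
    # resolving: (motif, cys_index, 0-based position of its anchor residue)
    "2-CysPRX": {
        "cysP_ctx": TWO_CYS_CYSP_CTX,
        "cysP": 117,
        "resolving": (TWO_CYS_CYSR_CTX, 239),
        # the EVCP context must stay inside the 250-aa sequence and inside
        # its C-terminal third, which caps the position jitter
        "max_shift": 9,
    },
    "PRXQ": {"cysP_ctx": PRXQ_CTX, "cysP": 48, "resolving": None},
    "PRXIIB": {
        "cysP_ctx": PRXIIB_CTX,
        "cysP": 49,
        "resolving": (TYPE_II_CYSR_CTX, 49 + PRXII_SPACING + 1),
    },
    "PRXIIE": {
        "cysP_ctx": PRXIIE_CTX,
        "cysP": 50,
        "resolving": (TYPE_II_CYSR_CTX, 50 + PRXII_SPACING + 1),
    },
    "PRXIIF": {
        "cysP_ctx": PRXIIF_CTX,
        "cysP": 49,
        "resolving": (TYPE_II_CYSR_CTX, 49 + PRXII_SPACING + 1),
    },
    "1-CysPRX": {"cysP_ctx": ONE_CYS_CTX, "cysP": 49, "resolving": None},
    "reclassified": {
        "cysP_ctx": PRXIIB_CTX,
        "cysP": 49,
        "resolving": (RECLASS_CYSR_CTX, 49 + PRXII_SPACING + 1),
    },
}

#: core-critical offsets relative to Cys_P that noise must never touch
_CORE_OFFSETS = (-7, -3, 0)


def _plant(seq: list[str], start: int, motif: str) -> None:
    if start < 0 or start + len(motif) > len(seq):
        raise ValueError("motif placement outside sequence")
    seq[start : start + len(motif)] = list(motif)


def _build_protein(
    rng: np.random.Generator,
    subfamily: str,
    name: str,
    lengths: dict[str, int],
    jitter: int = 0,
    noise: int = 0,
) -> tuple[ProteinRecord, dict]:
    bp = _PROTEIN_BLUEPRINTS[subfamily]
    label = "1-CysPRX" if subfamily == "reclassified" else subfamily
    length = lengths[label]
    jitter = min(jitter, bp.get("max_shift", jitter))
    shift = int(rng.integers(-jitter, jitter + 1)) if jitter else 0

    seq = list(rng.choice(list(AA_BACKGROUND), size=length))
    motif, cys_idx = bp["cysP_ctx"]
    cys_p = bp["cysP"] + shift
    _plant(seq, cys_p - cys_idx, motif)
    cys_r = None
    # a resolving Cys inside the Cys_P context itself (the PRXQ case)
    for j, aa in enumerate(motif):
        if aa == "C" and j > cys_idx:
            cys_r = cys_p + (j - cys_idx)
    if bp["resolving"] is not None:
        (r_motif, r_idx), anchor = bp["resolving"]
        anchor += shift
        _plant(seq, anchor - r_idx, r_motif)
        if "C" in r_motif:
            cys_r = anchor

    if noise:
        # mutate diagnostic-context residues, never the core P/T/Cys or any
        # planted cysteine
        candidates = [
            cys_p - cys_idx + i
            for i in range(len(motif))
            if (i - cys_idx) not in _CORE_OFFSETS and motif[i] != "C"
        ]
        for pos in rng.choice(candidates, size=min(noise, len(candidates)),
                              replace=False):
            current = seq[pos]
            choices = [a for a in AA_BACKGROUND if a != current]
            seq[pos] = str(rng.choice(choices))

    record = ProteinRecord(id=name, sequence="".join(seq))
    truth = {
        "id": name,
        "subfamily": label,
        "reclassified_from": "PRXIIB" if subfamily == "reclassified" else "",
        "cysP_pos": cys_p,
        "cysR_pos": cys_r,
        "spacing": (cys_r - cys_p - 1) if cys_r is not None else None,
    }
    return record, truth


CANONICAL_SUBFAMILY_ORDER = (
    "2-CysPRX", "1-CysPRX", "PRXQ", "PRXIIB", "PRXIIE", "PRXIIF",
)


def gen_proteins(
    config: SimulationConfig, n_random_per_subfamily: int = 0
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Canonical fixture proteins (one per subfamily, plus the Cys->Val
    reclassified type-II variant) and optional randomized replicates.

    Randomized replicates jitter the planted positions by up to 15 residues
    and resample the background; ``config.diagnostic_noise`` mismatches are
    planted into the diagnostic context of every randomized replicate.
    """
    rng = config.rng(1)
    lengths = config.protein_lengths
    records, truths = [], []
    for subfamily in CANONICAL_SUBFAMILY_ORDER:
        rec, truth = _build_protein(
            rng, subfamily, f"canonical_{subfamily}", lengths
        )
        records.append(rec)
        truths.append(truth)
    rec, truth = _build_protein(
        rng, "reclassified", "canonical_reclassified", lengths
    )
    records.append(rec)
    truths.append(truth)

    for subfamily in (*CANONICAL_SUBFAMILY_ORDER, "reclassified"):
        for i in range(n_random_per_subfamily):
            rec, truth = _build_protein(
                rng,
                subfamily,
                f"random_{subfamily}_{i}",
                lengths,
                jitter=15,
                noise=config.diagnostic_noise,
            )
            records.append(rec)
            truths.append(truth)
    return records, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# the five-exon splice-variant locus


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NT_BACKGROUND), size=n))


def _atg_free(rng: np.random.Generator, n: int) -> str:
    while True:
        s = _random_nt(rng, n)
        if "ATG" not in s:
            return s


_SAFE_CODONS = [
    a + b + c
    for a in NT_BACKGROUND
    for b in NT_BACKGROUND
    for c in NT_BACKGROUND
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]


def _random_cds(
    rng: np.random.Generator, n_codons: int, unique_atg: bool = True
) -> str:
    """ATG + stop-free codons + TAA.

    With ``unique_atg`` the start codon is the only ATG substring anywhere
    (needed when ORF detection must be forced); offending codons are
    resampled in place.
    """
    body = list(rng.choice(_SAFE_CODONS, size=n_codons - 2))
    cds = "ATG" + "".join(body) + "TAA"
    while unique_atg:
        pos = cds.find("ATG", 1)
        if pos < 0:
            break
        idx = pos // 3  # resample a codon overlapping the stray ATG
        body[max(0, idx - 1)] = str(rng.choice(_SAFE_CODONS))
        cds = "ATG" + "".join(body) + "TAA"
    return cds


@dataclass
class SpliceLocus:
    """A genome contig plus a reference model and observed transcripts."""

    genome: dict[str, str]
    gene: GeneModel
    transcripts: dict[str, TranscriptModel]
    truth: pd.DataFrame


# intron-retention segments of the five-exon fixture; both end with the
# genuine AG acceptor of their intron and are stop-free in reading frame
_RETAINED_15 = "CTTGAGCTTGGGCAG"
_RETAINED_14 = "TTGGTCTTGGCTAG"


def gen_prx14_locus(strand: str = "+") -> SpliceLocus:
    """The packaged five-exon splice-variant fixture.

    A 1,630-bp contig carrying a five-exon gene with a 597-bp reference ORF
    (600 bp of CDS including the stop), internal exons 2-4 summing to
    284 bp, and two observed variants: retention of the 3'-terminal 15
    bases of intron 1 (in-frame, ORF 612 bp / 204 aa, used acceptor AA,
    non-canonical) and skipping of exons 2-4 with retention of the
    3'-terminal 14 bases of intron 4 (ORF 327 bp / 109 aa, used acceptor
    AT, non-canonical).  Deterministic; ``strand='-'`` returns the
    reverse-complemented locus with identical truth.
    """
    rng = np.random.default_rng(20210118)
    cds = _random_cds(rng, 200)  # 600 bp including the TAA stop
    utr5 = _atg_free(rng, 60)
    utr3 = _atg_free(rng, 60)

    def intron(total: int, tail: str, alt_acceptor: str) -> str:
        filler = _random_nt(rng, total - 4 - len(tail))
        return "GT" + filler + alt_acceptor + tail

    i1 = intron(80, _RETAINED_15, "AA")
    i2 = "GT" + _random_nt(rng, 66) + "AG"
    i3 = "GT" + _random_nt(rng, 66) + "AG"
    i4 = intron(90, _RETAINED_14, "AT")

    exon1 = utr5 + cds[:120]
    exon2, exon3, exon4 = cds[120:220], cds[220:320], cds[320:404]
    exon5 = cds[404:600] + utr3
    flank5 = _random_nt(rng, 300)
    flank3 = _random_nt(rng, 300)
    contig = (
        flank5 + exon1 + i1 + exon2 + i2 + exon3 + i3 + exon4 + i4
        + exon5 + flank3
    )

    exons = [(300, 480), (560, 660), (730, 830), (900, 984), (1074, 1330)]
    cds_iv = [(360, 480), (560, 660), (730, 830), (900, 984), (1074, 1270)]
    gene = GeneModel("GhPRX14like", "simChr1", "+", list(exons), list(cds_iv))

    chains = {
        "ref": list(exons),
        "leaf_AS2": [(300, 480), (545, 660), (730, 830), (900, 984),
                     (1074, 1330)],
        "root_AS3": [(300, 480), (1060, 1330)],
    }
    transcripts = {
        name: TranscriptModel(
            transcript_id=name,
            gene_id=gene.gene_id,
            contig="simChr1",
            strand="+",
            exons=chain,
            provenance="reference" if name == "ref" else "observed",
        )
        for name, chain in chains.items()
    }
    truth = pd.DataFrame(
        [
            ("ref", "", 0, 597, 199),
            ("leaf_AS2", "A3SS", 15, 612, 204),
            ("root_AS3", "ES+A3SS", 14, 327, 109),
        ],
        columns=["transcript", "events", "retained_bp", "orf_bp", "protein_aa"],
    )
    locus = SpliceLocus({"simChr1": contig}, gene, transcripts, truth)
    _assert_prx14_orfs(locus)
    if strand == "-":
        locus = flip_locus(locus)
        _assert_prx14_orfs(locus)
    return locus


def _assert_prx14_orfs(locus: SpliceLocus) -> None:
    # construction-time self check: the fixture forces the published ORFs
    from .alt_splicing import orf_and_translate, transcript_sequence

    for row in locus.truth.itertuples():
        seq = transcript_sequence(locus.genome, locus.transcripts[row.transcript])
        got = orf_and_translate(seq)
        if got != (row.orf_bp, row.protein_aa):
            raise AssertionError(
                f"{row.transcript}: ORF {got} != ({row.orf_bp}, {row.protein_aa})"
            )


def flip_locus(locus: SpliceLocus) -> SpliceLocus:
    """Reverse-complement the contig and mirror every model onto '-'."""
    (contig_name, seq), = locus.genome.items()
    n = len(seq)
    flipped = {contig_name: revcomp(seq)}

    def flip_iv(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        return n - e, n - s

    def flip_strand(s: str) -> str:
        return "-" if s == "+" else "+"

    gene = GeneModel(
        locus.gene.gene_id,
        contig_name,
        flip_strand(locus.gene.strand),
        [flip_iv(iv) for iv in locus.gene.exons],
        [flip_iv(iv) for iv in locus.gene.cds],
    )
    transcripts = {
        name: TranscriptModel(
            t.transcript_id,
            t.gene_id,
            contig_name,
            flip_strand(t.strand),
            [flip_iv(iv) for iv in t.exons],
            t.provenance,
        )
        for name, t in locus.transcripts.items()
    }
    return SpliceLocus(flipped, gene, transcripts, locus.truth.copy())


# ---------------------------------------------------------------------------
# generic loci: per-subfamily exon counts, UTR introns, planted AS events


def gen_subfamily_gene_models(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """One plus-strand gene per subfamily with its typical exon count."""
    rng = config.rng(2)
    models: list[GeneModel] = []
    parts: list[str] = []
    cursor = 0

    def push(n: int) -> tuple[int, int]:
        nonlocal cursor
        parts.append(_random_nt(rng, n))
        cursor += n
        return cursor - n, cursor

    for subfamily, n_exons in sorted(config.exon_counts.items()):
        push(200)  # intergenic spacer
        exons = []
        for i in range(n_exons):
            exons.append(push(90))
            if i < n_exons - 1:
                push(60)
        models.append(
            GeneModel(
                gene_id=f"sim_{subfamily}",
                contig="simChr2",
                strand="+",
                exons=exons,
                cds=list(exons),
            )
        )
    push(200)
    return {"simChr2": "".join(parts)}, models


def gen_utr_intron_gene(
    config: SimulationConfig, strand: str = "+"
) -> tuple[dict[str, str], GeneModel]:
    """A two-intron gene whose first exon lies wholly in the 5'UTR."""
    rng = config.rng(3)
    seq = _random_nt(rng, 1000)
    exons = [(100, 180), (260, 500), (560, 800)]
    cds = [(300, 500), (560, 740)]  # CDS starts inside exon 2
    if strand == "-":
        seq = revcomp(seq)
        exons = [(1000 - e, 1000 - s) for s, e in exons]
        cds = [(1000 - e, 1000 - s) for s, e in cds]
    model = GeneModel("sim_utr_intron", "simChr3", strand, exons, cds)
    return {"simChr3": seq}, model


def gen_as_locus(
    config: SimulationConfig,
) -> tuple[dict[str, str], GeneModel, dict[str, TranscriptModel], pd.DataFrame]:
    """A five-exon gene with one planted variant per event type.

    Truth columns: transcript, event type, affected 1-based index
    (intron for IR/A3SS/A5SS, exon for ES/AFE/ALE) and length in bp.
    """
    rng = config.rng(4)
    exon_len = [int(rng.integers(80, 140)) for _ in range(5)]
    intron_len = [int(rng.integers(50, 90)) for _ in range(4)]
    cursor = 400
    exons = []
    for i, el in enumerate(exon_len):
        exons.append((cursor, cursor + el))
        cursor += el
        if i < 4:
            cursor += intron_len[i]
    contig = {"simChr4": _random_nt(rng, cursor + 400)}
    gene = GeneModel("sim_as", "simChr4", "+", list(exons), list(exons))
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(4)]

    k3 = int(rng.integers(5, 16))
    k5 = int(rng.integers(5, 16))
    afe_exon = (introns[0][0] + 5, introns[0][0] + 30)
    ale_exon = (introns[3][0] + 5, introns[3][0] + 35)

    variants: dict[str, list[tuple[int, int]]] = {
        "IR": [exons[0], (exons[1][0], exons[2][1]), exons[3], exons[4]],
        "ES": [exons[0], exons[1], exons[3], exons[4]],
        "A3SS": [
            exons[0], exons[1],
            (exons[2][0] - k3, exons[2][1]), exons[3], exons[4],
        ],
        "A5SS": [
            exons[0], (exons[1][0], exons[1][1] + k5),
            exons[2], exons[3], exons[4],
        ],
        "AFE": [afe_exon, *exons[1:]],
        "ALE": [*exons[:4], ale_exon],
    }
    transcripts = {
        name: TranscriptModel(
            transcript_id=f"sim_as_{name}",
            gene_id="sim_as",
            contig="simChr4",
            strand="+",
            exons=chain,
        )
        for name, chain in variants.items()
    }
    truth = pd.DataFrame(
        [
            ("IR", "IR", 2, introns[1][1] - introns[1][0]),
            ("ES", "ES", 3, exon_len[2]),
            ("A3SS", "A3SS", 2, k3),
            ("A5SS", "A5SS", 2, k5),
            ("AFE", "AFE", 1, afe_exon[1] - afe_exon[0]),
            ("ALE", "ALE", 5, ale_exon[1] - ale_exon[0]),
        ],
        columns=["transcript", "event", "index", "length_bp"],
    )
    return contig, gene, transcripts, truth


# ---------------------------------------------------------------------------
# promoters with planted cis-elements


def _instantiate(rng: np.random.Generator, consensus: str) -> str:
    return "".join(str(rng.choice(list(IUPAC[c]))) for c in consensus)


def gen_promoters(
    config: SimulationConfig,
    catalogue: list[CisElement],
    n_promoters: int = 10,
    n_planted: int = 6,
) -> tuple[list[str], pd.DataFrame]:
    """Random promoters with catalogue elements planted on both strands.

    Planted sites never overlap (10-bp margin, rejection-sampled).  Truth
    columns: promoter index, element, 1-based offset of the leftmost base,
    strand, planted instance.
    """
    rng = config.rng(5)
    length = config.promoter_length
    promoters, rows = [], []
    for p in range(n_promoters):
        seq = list(_random_nt(rng, length))
        occupied: list[tuple[int, int]] = []
        planted = 0
        while planted < n_planted:
            element = catalogue[int(rng.integers(len(catalogue)))]
            site = _instantiate(rng, element.consensus)
            strand = "+" if rng.random() < 0.5 else "-"
            ins = site if strand == "+" else revcomp(site)
            start = int(rng.integers(0, length - len(ins)))
            if any(
                start < e + 10 and s - 10 < start + len(ins)
                for s, e in occupied
            ):
                continue
            seq[start : start + len(ins)] = list(ins)
            occupied.append((start, start + len(ins)))
            rows.append((p, element.name, start + 1, strand, ins))
            planted += 1
        promoters.append("".join(seq))
    truth = pd.DataFrame(
        rows, columns=["promoter", "element", "offset", "strand", "planted"]
    )
    return promoters, truth


# ---------------------------------------------------------------------------
# duplicate CDS pairs with planted substitution classes


def _translate(codon: str) -> str:
    from Bio.Data.CodonTable import standard_dna_table

    return standard_dna_table.forward_table[codon]


def gen_duplicate_pairs(
    config: SimulationConfig, n_pairs: int = 1
) -> tuple[list[tuple[str, str, str, str]], pd.DataFrame]:
    """CDS pairs evolved by exactly the requested substitution counts.

    Starting from a random stop-free CDS, ``duplicate_n_syn`` synonymous and
    ``duplicate_n_nonsyn`` nonsynonymous single-base substitutions are
    applied to the copy, each in a distinct codon (so pathway averaging is
    exact) and each class-verified by translation.  Raises when the request
    cannot be satisfied.
    """
    rng = config.rng(6)
    n_codons = config.duplicate_n_codons
    if config.duplicate_n_syn + config.duplicate_n_nonsyn > n_codons - 2:
        raise ValueError("more substitutions requested than available codons")
    pairs, rows = [], []
    for p in range(n_pairs):
        cds_a = _random_cds(rng, n_codons, unique_atg=False)
        codons = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
        editable = list(range(1, n_codons - 1))  # keep start/stop intact
        rng.shuffle(editable)
        todo = ["syn"] * config.duplicate_n_syn + (
            ["nonsyn"] * config.duplicate_n_nonsyn
        )
        rng.shuffle(todo)
        applied = 0
        for kind in todo:
            done = False
            while editable and not done:
                idx = editable.pop()
                options = []
                for pos in range(3):
                    for b in NT_BACKGROUND:
                        if b == codons[idx][pos]:
                            continue
                        alt = (
                            codons[idx][:pos] + b + codons[idx][pos + 1 :]
                        )
                        if alt in STOP_CODONS or alt == "ATG":
                            continue
                        same = _translate(alt) == _translate(codons[idx])
                        if (kind == "syn") == same:
                            options.append(alt)
                if options:
                    codons[idx] = str(rng.choice(options))
                    applied += 1
                    done = True
            if not done:
                raise ValueError(f"cannot place a {kind} substitution")
        cds_b = "".join(codons)
        pairs.append((f"dupA_{p}", f"dupB_{p}", cds_a, cds_b))
        rows.append(
            (f"dupA_{p}", f"dupB_{p}",
             config.duplicate_n_syn, config.duplicate_n_nonsyn)
        )
    truth = pd.DataFrame(rows, columns=["id_a", "id_b", "n_syn", "n_nonsyn"])
    return pairs, truth


# ---------------------------------------------------------------------------
# Ct tables with planted fold changes


def gen_ct_table(
    config: SimulationConfig,
    genes: tuple[str, ...] = ("simPRX1", "simPRX2", "simPRX3", "simPRX4"),
    conditions: tuple[str, ...] = ("NaCl", "PEG", "SA"),
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(stress, control, truth) Ct tables for the three-step fold change.

    Ct values are constructed so the three-step procedure recovers the
    planted fold change exactly at zero noise: the reference gene sits at
    20 cycles, each gene has a baseline dCt drawn in [1, 4], and the stress
    target Ct is shifted by -log2(FC).  Fold changes at 0 h are 1;
    later timepoints draw log2 fold changes uniformly in [-2, 2].
    Gaussian noise of ``noise_sd`` cycles (default from config) is added to
    target Ct values per replicate.
    """
    rng = config.rng(7)
    sd = config.ct_noise_sd if noise_sd is None else noise_sd
    ct_ref = 20.0
    stress_rows, control_rows, truth_rows = [], [], []
    for gene in genes:
        baseline = float(rng.uniform(1.0, 4.0))
        for rep in range(1, config.ct_replicates + 1):
            for t in config.ct_timepoints:
                control_rows.append(
                    (gene, "control", t, rep, ct_ref + baseline, ct_ref)
                )
        for condition in conditions:
            for t in config.ct_timepoints:
                log2_fc = 0.0 if t == 0 else float(rng.uniform(-2.0, 2.0))
                truth_rows.append((gene, condition, t, 2.0 ** log2_fc))
                for rep in range(1, config.ct_replicates + 1):
                    noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
                    stress_rows.append(
                        (gene, condition, t, rep,
                         ct_ref + baseline - log2_fc + noise, ct_ref)
                    )
    cols = ["gene", "condition", "timepoint_h", "replicate",
            "ct_target", "ct_reference"]
    stress = pd.DataFrame(stress_rows, columns=cols)
    control = pd.DataFrame(control_rows, columns=cols)
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "condition", "timepoint_h", "fc"]
    )
    return stress, control, truth
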