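"""Ka/Ks estimation for duplicate CDS pairs and Ks-based divergence dating.

The estimator is the Nei-Gojobori (1986) counting method: synonymous and
nonsynonymous site counts are averaged over both sequences, observed
differences are averaged over all single-base substitution pathways
(pathways through stop codons excluded), and the proportions are corrected
for multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).
Divergence time follows the molecular-clock conversion T = Ks / (2 lambda)
with lambda the synonymous substitution rate per site per year
(1.5e-8 for dicots).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

DICOT_SYN_RATE = 1.5e-8

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
BASES = "ACGT"


class SaturationError(ValueError):
    """Observed substitution proportion >= 3/4; Jukes-Cantor undefined."""

    def __init__(self, kind: str, p: float):
        self.kind = kind
        super().__init__(
            f"{kind} substitution proportion p={p:.4f} >= 3/4 (saturated)"
        )


@dataclass
class DuplicatePair:
    """A duplicate gene pair with its substitution-rate estimates."""

    id_a: str
    id_b: str
    ka: float
    ks: float
    ka_ks: float | None  # None when Ks == 0
    t_mya: float
    lam: float = DICOT_SYN_RATE


def _validate_cds(name: str, cds: str) -> str:
    cds = cds.upper()
    if cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if len(cds) % 3:
        raise ValueError(f"{name}: CDS length not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {c} at codon {i + 1}")
        if c not in CODON_TABLE:
            raise ValueError(f"{name}: ambiguous codon {c} at codon {i + 1}")
    return cds


def codon_align(
    cds_a: str,
    cds_b: str,
    gap_score: float = -8.0,
    matrix: str = "BLOSUM62",
) -> list[tuple[str, str]]:
    """Align two CDSs at the protein level and back-thread to codon pairs.

    Terminal stop codons are trimmed; internal stops are errors.  The
    protein alignment is global with substitution matrix ``matrix`` and a
    linear gap penalty of ``gap_score`` per residue; gapped codon columns
    are excluded from the returned pairs.
    """
    cds_a = _validate_cds("cds_a", cds_a)
    cds_b = _validate_cds("cds_b", cds_b)
    prot_a = str(Seq(cds_a).translate())
    prot_b = str(Seq(cds_b).translate())

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_score
    aligner.extend_gap_score = gap_score
    alignment = aligner.align(prot_a, prot_b)[0]

    pairs: list[tuple[str, str]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for i in range(a_end - a_start):
            ai, bi = a_start + i, b_start + i
            pairs.append((cds_a[3 * ai : 3 * ai + 3], cds_b[3 * bi : 3 * bi + 3]))
    return pairs


def synonymous_fraction(codon: str, position: int) -> float:
    """Fraction of the three possible changes at one position that are
    synonymous.  Changes to stop codons count as nonsynonymous."""
    aa = CODON_TABLE[codon]
    syn = 0
    for b in BASES:
        if b == codon[position]:
            continue
        alt = codon[:position] + b + codon[position + 1 :]
        if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
            syn += 1
    return syn / 3.0


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    s = sum(synonymous_fraction(codon, pos) for pos in range(3))
    return s, 3.0 - s


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all orderings of the single-base steps; orderings passing
    through a stop codon are excluded (all orderings are used if every one
    is blocked, which cannot happen for stop-free endpoints differing at
    fewer than three positions in practice).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[current] == CODON_TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        (results if ok else blocked).append((syn, nonsyn))
    if not results:
        results = blocked
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float, kind: str) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p)."""
    if p >= 0.75:
        raise SaturationError(kind, p)
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(pairs: list[tuple[str, str]]) -> tuple[float, float]:
    """Nei-Gojobori (Ka, Ks) from aligned, ungapped codon pairs."""
    if not pairs:
        raise ValueError("need at least one ungapped codon pair")
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    for ca, cb in pairs:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        d_s, d_n = pathway_differences(ca, cb)
        sd += d_s
        nd += d_n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps, "synonymous") if ps > 0 else 0.0
    ka = jukes_cantor(pn, "nonsynonymous") if pn > 0 else 0.0
    return ka, ks


def divergence_time(ks: float, lam: float = DICOT_SYN_RATE) -> float:
    """Divergence time in MYA under T = Ks / (2 lambda)."""
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return ks / (2.0 * lam) / 1e6


def analyze_pair(
    id_a: str,
    id_b: str,
    cds_a: str,
    cds_b: str,
    lam: float = DICOT_SYN_RATE,
) -> DuplicatePair:
    """Full pipeline for one duplicate pair: align, count, correct, date."""
    ka, ks = ng86(codon_align(cds_a, cds_b))
    return DuplicatePair(
        id_a=id_a,
        id_b=id_b,
        ka=ka,
        ks=ks,
        ka_ks=(ka / ks) if ks > 0 else None,
        t_mya=divergence_time(ks, lam),
        lam=lam,
    )
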