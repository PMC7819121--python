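"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
(full enumeration, dense grid, character-by-character scan) without
touching the implementation path it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def ng86_oracle(codon_pairs):
    """(Ka, Ks) by literal enumeration of sites and substitution pathways."""
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in codon_pairs:
        for codon in (ca, cb):
            syn = 0.0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    alt = codon[:pos] + base + codon[pos + 1 :]
                    if GENETIC_CODE[alt] != "*" and (
                        GENETIC_CODE[alt] == GENETIC_CODE[codon]
                    ):
                        syn += 1.0 / 3.0
            s_sites += syn / 2.0
            n_sites += (3.0 - syn) / 2.0
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if diff:
            outcomes, blocked = [], []
            for order in permutations(diff):
                cur, s_steps, n_steps, ok = ca, 0, 0, True
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                    if GENETIC_CODE[nxt] == "*":
                        ok = False
                        break
                    if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                        s_steps += 1
                    else:
                        n_steps += 1
                    cur = nxt
                (outcomes if ok else blocked).append((s_steps, n_steps))
            use = outcomes or blocked
            sd += sum(o[0] for o in use) / len(use)
            nd += sum(o[1] for o in use) / len(use)
    ps, pn = sd / s_sites, nd / n_sites

    def jc(p):
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    return (jc(pn) if pn > 0 else 0.0), (jc(ps) if ps > 0 else 0.0)


def nw_score_oracle(a: str, b: str, matrix, gap: float) -> float:
    """Full dynamic-programming global alignment score (linear gaps)."""
    n, m = len(a), len(b)
    dp = np.empty((n + 1, m + 1))
    dp[0, :] = np.arange(m + 1) * gap
    dp[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = max(
                dp[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]],
                dp[i - 1, j] + gap,
                dp[i, j - 1] + gap,
            )
    return float(dp[n, m])


def pi_grid_oracle(sequence: str, net_charge, step: float = 0.001) -> float:
    """pH grid minimizing |net charge| over [0, 14]."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.abs([net_charge(sequence, ph) for ph in grid])
    return float(grid[int(np.argmin(charges))])


IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _matches_at(seq: str, pos: int, consensus: str) -> bool:
    if pos + len(consensus) > len(seq):
        return False
    return all(
        seq[pos + i] in IUPAC_SETS[c] for i, c in enumerate(consensus)
    )


def scan_oracle(promoter: str, catalogue):
    """(offset_1based, element, strand) tuples by naive sliding window."""
    hits = []
    for element in catalogue:
        rc = "".join(
            {
                "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N",
            }[c]
            for c in element.consensus[::-1]
        )
        for pos in range(len(promoter)):
            if _matches_at(promoter, pos, element.consensus):
                hits.append((pos + 1, element.name, "+"))
            if _matches_at(promoter, pos, rc):
                hits.append((pos + 1, element.name, "-"))
    return sorted(hits)


def fold_change_oracle(stress_df, control_df):
    """Literal three-step spreadsheet recomputation of fold changes."""
    out = {}
    for _, row in stress_df.iterrows():
        base = control_df[
            (control_df.gene == row.gene)
            & (control_df.timepoint_h == 0)
            & (control_df.replicate == row.replicate)
        ].iloc[0]
        dct1_stress = row.ct_target - row.ct_reference
        dct1_control0 = base.ct_target - base.ct_reference
        fc = 2.0 ** (-(dct1_stress - dct1_control0))
        out.setdefault(
            (row.gene, row.condition, row.timepoint_h), []
        ).append(fc)
    return {
        key: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for key, v in out.items()
    }
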