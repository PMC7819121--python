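"""Conserved active-site profiling and PRX subfamily classification.

Peroxiredoxins share the catalytic core P-x-x-x-T-x-x-C whose terminal
cysteine is the peroxidatic Cys (Cys_P), followed downstream by a conserved
serine and an aromatic W/F.  Subfamilies are told apart by the presence and
spacing of the resolving cysteine (Cys_R) and by diagnostic sequence
contexts around Cys_P:

* PRXQ          — Cys_R four residues after Cys_P (4 residues strictly between)
* type II (B/E/F) — Cys_R 24 residues downstream; PRXIIE carries the
  chloroplastic FGLPGAYTGVCSQ context, PRXIIF carries the type-II context
  with the conserved Ser replaced by Ala, PRXIIB is the remaining type II
* 2-CysPRX      — Cys_P inside the FFYPLDFTFVCPTEI context plus a distal
  Cys_R inside an EVCP context in the C-terminal third
* 1-CysPRX      — no resolving cysteine; includes type-II-like sequences
  whose resolving Cys is mutated to Val (reclassified from PRXIIB)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .io_formats import ProteinRecord

CORE_PATTERN = re.compile(r"P...T..C")

#: Cys_P context of typical two-cysteine PRXs (peroxidatic Cys at index 10).
TWO_CYS_CYSP_CTX = ("FFYPLDFTFVCPTEI", 10)
#: Cys_R context of typical two-cysteine PRXs (resolving Cys at index 2).
TWO_CYS_CYSR_CTX = ("EVCP", 2)
#: Chloroplastic type II (PRXIIE) Cys_P context.
PRXIIE_CTX = ("FGLPGAYTGVCSQ", 10)
#: Cytosolic type II (PRXIIB) Cys_P context.
PRXIIB_CTX = ("GLPGAFTPTCSMS", 9)
#: Mitochondrial type II (PRXIIF) Cys_P context: the conserved S after
#: Cys_P is replaced by A.  Index of that Ala relative to the motif start.
PRXIIF_CTX = ("GLPGAFTPTCAMS", 9)
PRXIIF_ALA_OFFSET = 10
#: 1-Cys Cys_P context (no downstream cysteine anywhere).
ONE_CYS_CTX = ("LPGDFTPVCTTE", 8)

SUBFAMILIES = ("2-CysPRX", "1-CysPRX", "PRXQ", "PRXIIB", "PRXIIE", "PRXIIF")

#: Residues strictly between Cys_P and Cys_R for PRXQ and type II PRXs.
PRXQ_SPACING = 4
PRXII_SPACING = 24


@dataclass
class ActiveSiteProfile:
    """Located conserved-site positions (all 0-based) and their spacing."""

    cysP_pos: int
    core_motif_span: tuple[int, int]
    cysR_pos: int | None = None
    spacing: int | None = None
    resolving_S_pos: int | None = None
    aromatic_pos: int | None = None
    diagnostic_hits: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cysR_pos is not None:
            if self.cysR_pos <= self.cysP_pos:
                raise ValueError("cysR_pos must lie downstream of cysP_pos")
            if self.spacing != self.cysR_pos - self.cysP_pos - 1:
                raise ValueError("spacing must equal cysR_pos - cysP_pos - 1")


@dataclass
class SubfamilyCall:
    label: str
    evidence: list[str] = field(default_factory=list)
    reclassified_from: str | None = None

    def __post_init__(self) -> None:
        if self.label == "UNCLASSIFIED" and self.evidence:
            raise ValueError("UNCLASSIFIED calls carry no evidence")
        if self.label != "UNCLASSIFIED" and not self.evidence:
            raise ValueError("classified calls must name the rules fired")


def context_mismatches(
    sequence: str, cys_pos: int, motif: str, cys_index: int
) -> int | None:
    """Mismatch count of ``motif`` aligned so motif[cys_index] sits at
    ``cys_pos``.

    Returns None when the motif would overhang the sequence or when any
    catalytic Cys position of the motif is not a Cys in the sequence
    (mismatches are never tolerated at cysteines).
    """
    start = cys_pos - cys_index
    if start < 0 or start + len(motif) > len(sequence):
        return None
    window = sequence[start : start + len(motif)]
    mismatches = 0
    for m, s in zip(motif, window):
        if m == s:
            continue
        if m == "C":
            return None
        mismatches += 1
    return mismatches


def find_active_site(
    protein: ProteinRecord,
    s_window: tuple[int, int] = (1, 80),
) -> ActiveSiteProfile | None:
    """Locate the catalytic core and soft downstream S / W-F positions.

    The earliest match of P-x-x-x-T-x-x-C is taken as the catalytic core;
    its terminal Cys is Cys_P.  Returns None when the core is absent (this
    is the candidate screen — absence is not an error).  The downstream
    conserved S and aromatic W/F are located within ``s_window`` residues
    of Cys_P and recorded as soft evidence only.
    """
    seq = protein.sequence
    m = CORE_PATTERN.search(seq)
    if m is None:
        return None
    cys_p = m.start() + 7
    profile = ActiveSiteProfile(
        cysP_pos=cys_p, core_motif_span=(m.start(), m.end())
    )
    lo, hi = s_window
    region = seq[cys_p + lo : cys_p + hi]
    s_rel = region.find("S")
    if s_rel >= 0:
        profile.resolving_S_pos = cys_p + lo + s_rel
    search_from = (
        profile.resolving_S_pos + 1 if profile.resolving_S_pos else cys_p + 1
    )
    for i in range(search_from, len(seq)):
        if seq[i] in "WF":
            profile.aromatic_pos = i
            break
    return profile


def locate_resolving_cys(
    profile: ActiveSiteProfile,
    protein: ProteinRecord,
    spacing_slack: int = 0,
) -> ActiveSiteProfile:
    """Find the nearest downstream Cys at a subfamily-consistent spacing.

    Allowed spacings are 4 (PRXQ) and 24 (type II), each widened by
    ``spacing_slack`` residues on both sides (default 0, at most 2).  The
    spacing is the number of residues strictly between the two cysteines.
    Returns an updated copy; cysR_pos stays None when no such Cys exists
    (distal 2-Cys resolving cysteines are handled by the classifier).
    """
    if not 0 <= spacing_slack <= 2:
        raise ValueError("spacing_slack must be between 0 and 2")
    windows = [
        (PRXQ_SPACING - spacing_slack, PRXQ_SPACING + spacing_slack),
        (PRXII_SPACING - spacing_slack, PRXII_SPACING + spacing_slack),
    ]
    seq = protein.sequence
    for pos in range(profile.cysP_pos + 1, len(seq)):
        if seq[pos] != "C":
            continue
        spacing = pos - profile.cysP_pos - 1
        if any(lo <= spacing <= hi for lo, hi in windows):
            return replace(profile, cysR_pos=pos, spacing=spacing)
    return replace(profile, cysR_pos=None, spacing=None)


def _distal_two_cys_resolving(
    seq: str, cys_p: int, short_tol: int
) -> int | None:
    """Position of a Cys inside an EVCP context in the C-terminal third."""
    motif, idx = TWO_CYS_CYSR_CTX
    third = 2 * len(seq) // 3
    for pos in range(max(cys_p + 1, third), len(seq)):
        if seq[pos] != "C":
            continue
        mm = context_mismatches(seq, pos, motif, idx)
        if mm is not None and mm <= short_tol:
            return pos
    return None


def classify_subfamily(
    profile: ActiveSiteProfile,
    protein: ProteinRecord,
    mismatch_tol: int = 2,
    short_motif_tol: int = 1,
) -> SubfamilyCall:
    """Assign one of the six subfamilies from the active-site profile.

    Decision order: PRXQ spacing, type II spacing (E/F diagnostics, else B),
    two-cysteine diagnostic contexts, then the no-resolving-Cys branch where
    type-II-like sequences with the resolving Cys mutated to Val are
    reclassified from PRXIIB to 1-CysPRX.  Diagnostic submotifs tolerate at
    most ``mismatch_tol`` mismatches (``short_motif_tol`` for the 4-residue
    EVCP context), never at a catalytic cysteine.
    """
    seq = protein.sequence
    cys_p = profile.cysP_pos
    hits = profile.diagnostic_hits

    for name, (motif, idx) in (
        ("2cys_cysP", TWO_CYS_CYSP_CTX),
        ("prxIIE", PRXIIE_CTX),
        ("prxIIB", PRXIIB_CTX),
        ("prxIIF", PRXIIF_CTX),
        ("1cys", ONE_CYS_CTX),
    ):
        mm = context_mismatches(seq, cys_p, motif, idx)
        if mm is not None and mm <= mismatch_tol:
            hits[name] = mm

    if profile.spacing == PRXQ_SPACING:
        return SubfamilyCall("PRXQ", ["spacing==4"])

    if profile.spacing == PRXII_SPACING:
        evidence = ["spacing==24"]
        e_mm = hits.get("prxIIE")
        f_mm = (
            hits["prxIIF"]
            if "prxIIF" in hits
            and seq[cys_p - PRXIIF_CTX[1] + PRXIIF_ALA_OFFSET] == "A"
            else None
        )
        if e_mm is not None and (f_mm is None or e_mm <= f_mm):
            return SubfamilyCall("PRXIIE", evidence + ["prxIIE diagnostic"])
        if f_mm is not None:
            return SubfamilyCall("PRXIIF", evidence + ["prxIIF S->A diagnostic"])
        return SubfamilyCall("PRXIIB", evidence + ["type II default"])

    if "2cys_cysP" in hits:
        cys_r = _distal_two_cys_resolving(seq, cys_p, short_motif_tol)
        if cys_r is not None:
            return SubfamilyCall(
                "2-CysPRX",
                ["2cys Cys_P context", f"distal EVCP Cys_R at {cys_r}"],
            )

    if profile.cysR_pos is None:
        # type II context whose resolving position carries Val: the paper's
        # Cys->Val mutants are moved from PRXIIB to 1-CysPRX.
        v_pos = cys_p + PRXII_SPACING + 1
        if "prxIIB" in hits and v_pos < len(seq) and seq[v_pos] == "V":
            return SubfamilyCall(
                "1-CysPRX",
                ["prxIIB context", "resolving C->V"],
                reclassified_from="PRXIIB",
            )
        return SubfamilyCall("1-CysPRX", ["no resolving Cys"])

    return SubfamilyCall("UNCLASSIFIED")


def classify_protein(
    protein: ProteinRecord,
    spacing_slack: int = 0,
    mismatch_tol: int = 2,
) -> tuple[ActiveSiteProfile | None, SubfamilyCall | None]:
    """Candidate screen + classification in one step.

    Returns (None, None) when the protein lacks the catalytic core.
    """
    profile = find_active_site(protein)
    if profile is None:
        return None, None
    profile = locate_resolving_cys(profile, protein, spacing_slack)
    call = classify_subfamily(profile, protein, mismatch_tol)
    return profile, call
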