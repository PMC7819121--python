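# Methods

This note documents the models and procedures implemented in `cottonprx`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and known limitations.

## Active-site profiling and subfamily classification

A protein is a PRX candidate iff it contains the catalytic core
`P-x-x-x-T-x-x-C` (earliest match wins; its terminal Cys is the
peroxidatic cysteine Cys_P). The downstream conserved Ser and aromatic
W/F of the full `PxxxTxxC…S…W/F` profile are located and logged as soft
evidence but are not required for a positive screen: requiring them is
not clearly warranted and would only remove candidates, never add any.
This motif screen replaces profile-HMM / homology-search identification
stages; it is the candidate filter of this package, not a stand-in
quality judgement on those methods.

The resolving cysteine Cys_R is the nearest downstream Cys whose spacing
(residues strictly between the two cysteines) is 4 (PRXQ) or 24 (type II
PRXs). Spacings are exact by default with a `spacing_slack` option
(0–2), because conserved spacings in the family are described as
approximate. The decision order is:

1. spacing 4 → **PRXQ**
2. spacing 24 → type II: **PRXIIE** if the chloroplastic
   `FGLPGAYTGVCSQ` context matches, **PRXIIF** if the type-II context
   with the conserved Ser replaced by Ala matches (the Ala is required
   literally), otherwise **PRXIIB**. Ties between E and F go to the lower
   mismatch count, then to E (documented arbitrary choice).
3. Cys_P inside the `FFYPLDFTFVCPTEI` context *and* a distal Cys inside
   an `EVCP` context in the C-terminal third → **2-CysPRX**. The
   "approximately residue 118 / 240" positions are logged, never used as
   filters.
4. no resolving Cys → **1-CysPRX**; if the type-II context matches and
   the residue at the would-be resolving position (Cys_P + 25) is Val,
   the call is 1-CysPRX with `reclassified_from = PRXIIB` (the
   Cys→Val mutant class).

Diagnostic contexts tolerate ≤ 2 mismatches (≤ 1 for the 4-residue
`EVCP`), never at a catalytic cysteine. These tolerances are this
package's choice: the underlying comparisons in the literature are done
by eye on alignments and no thresholds are published. The PRXIIB and
1-Cys context strings used by the generator and classifier are
synthetic constructions that satisfy the catalytic core; only the
PRXIIE, 2-Cys and S→A-variant contexts follow published descriptions.

## Protein properties

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water, matching the convention of standard pI/MW web tools;
`X` contributes a configurable average mass (default 110 Da). The
isoelectric point solves Henderson–Hasselbalch net charge = 0 by Brent
root-finding on [0, 14] (tolerance 1e-4); net charge uses the
Bjellqvist pKa set including its residue-specific N- and C-terminal
values. The whole table is data (`PkaTable`) and swappable.

One subtlety: with residue-specific terminal pKa values, appending an
acidic residue can *raise* the pI slightly when it changes the terminal
group's own pKa (e.g. `DA` → `DAD` moves the C-terminal pKa from 3.55 to
4.55). Monotonicity under acid appends holds exactly only for a uniform
terminal pKa, and the property tests are phrased accordingly.

Reproducing any particular published pI/MW table is out of scope — the
underlying sequences of such tables are not distributed with them — so
property tests (additivity, grid-search agreement, cross-check against
an independent implementation) govern this module.

## Gene structure

Intron count is exon count − 1. Intron phase is the cumulative CDS
length 5′ of the intron modulo 3 (UTR excluded; standard GFF3
semantics); introns 5′ of all CDS carry no phase. "Intron before the
translation initiation site" requires the whole intron upstream (in
transcription orientation) of the first CDS base — an intron
interrupting the start codon does not count. All operations are
strand-symmetric: statistics are unchanged under reverse-complementing
the contig and flipping the strand, which the tests verify with a
strand-flip oracle.

Internally all coordinates are 0-based half-open; GFF3's 1-based
inclusive convention is converted only at read/write boundaries.

## Ka/Ks and divergence dating

CDS pairs are aligned at the protein level (BLOSUM62, linear gap −8 per
residue — a deliberately simple, fully documented scheme) and
back-threaded to codons; gapped codon columns are excluded. Terminal
stop codons are trimmed; internal stops are hard errors.

The estimator is Nei–Gojobori (1986): per codon position, the
synonymous site fraction is the share of the three possible base
changes that preserve the amino acid, with changes to stop codons
counted as nonsynonymous — this keeps synonymous + nonsynonymous sites
exactly 3 per codon. Site counts are averaged over both sequences.
Observed differences at multi-difference codons are averaged over all
orderings of single-base steps, excluding orderings that pass through a
stop codon. Proportions are Jukes–Cantor corrected,
`d = −(3/4)·ln(1 − (4/3)p)`; `p ≥ 3/4` raises a saturation error naming
the class. NG86 was chosen over likelihood methods because it is fully
specifiable and deterministic; the module API (`analyze_pair`) leaves
room for alternative estimators.

Divergence time is `T = Ks/(2λ)` in years, reported in MYA, with
`λ = 1.5 × 10⁻⁸` synonymous substitutions/site/year as the dicot
default. Duplicate pairs are pipeline *input* (an id-pair table plus a
CDS FASTA); collinearity detection is not reimplemented.

## Promoter cis-elements

The promoter is the 2,500 bp immediately 5′ of the start codon
(minus-strand genes: reverse complement of the downstream genomic
bases), truncated with a warning at contig edges. Scanning is exact
IUPAC-set membership on both strands — no mismatches, no position
weights — with overlapping hits reported and deterministic
(offset, element, strand) order. Extraction length (2,500) and display
window (1,500) are separate configuration keys because the two differ
in common practice.

The packaged catalogue carries the 28 element names of the three
functional classes (9 abiotic stress, 10 hormone, 9 growth/development)
with PlantCARE-style consensus strings. The consensus strings are
editable data: published figures name the elements but not their
consensi, so all matching tests rely on generator-planted sites rather
than on any particular catalogue content. Whether both strands should
be scanned is unknowable from typical reports; both are scanned by
default (`strands` option).

## Expression

Fold change follows the literal three-step `2^−ΔCt` procedure:
ΔCt₁ = Ct(target) − Ct(reference) per replicate;
ΔCt₂ = ΔCt₁(stress, t) − ΔCt₁(control, 0 h), replicates paired by
index; FC = 2^−ΔCt₂. Mean and SD are computed over replicate-level fold
changes (n = 3 in the default design), matching error bars drawn on FC.
The procedure is scale-free in any constant added to both Ct values of
a replicate. FPKM matrices are transformed as `log2(FPKM + 1)`; the
pseudocount keeps unexpressed genes finite and is configurable. An
optional per-gene z-score flag is provided; neither min-max nor z-score
is claimed as "the" normalization of any published heatmap, since that
choice is typically unstated.

## Alternative splicing

Transcripts are supplied as exon chains (spliced alignment with
mismatches is out of scope). Classification compares intron sets in
transcription-oriented coordinates:

- reference intron absent and wholly inside one transcript exon → IR;
- reference exon(s) wholly inside one transcript intron → ES;
- intron donor/acceptor boundary moved → A5SS/A3SS, where "3′" means
  the acceptor side in transcription orientation. A retention of one
  end of an intron is structurally A3SS/A5SS; such events also carry
  the alias `paper_label = "partial-IR"` because cloning studies often
  label them intron retention. Length/ORF outputs are identical under
  either vocabulary.
- a different first/last exon with the internal chain intact → AFE/ALE.

Boundary dinucleotides are the first two and last two bases of the
spliced segment; canonical iff GT..AG. The packaged five-exon fixture
(597-bp reference ORF, internal exons summing to 284 bp) plants an `AA`
alternative acceptor 15 bases inside intron 1 and an `AT` alternative
acceptor 14 bases inside intron 4, so both used junctions are
non-canonical and the fixture forces the ORF arithmetic
597 + 15 = 612 = 3 × 204 and 597 − 284 + 14 = 327 = 3 × 109. Published
junction strings for such events do not state which side of each string
is donor versus acceptor; this fixture reproduces the acceptor-side
tokens and treats that as an interpretation, not a fact.

ORF detection takes the longest reading frame from an ATG to the first
in-frame stop (ties to the most 5′ start) and reports its length
excluding the stop codon, which makes protein length = ORF/3 — the only
convention consistent with a 597-bp ORF encoding 199 aa.

## Synthetic data: what it emulates, what it does not

Generators are seeded (`SimulationConfig.seed` fixes every output
bit-for-bit) and each returns a machine-readable truth table.

- **Proteins**: uniform background over the 19 non-Cys residues with
  subfamily contexts planted at canonical positions (2-Cys: Cys_P at
  residue 118, EVCP at 240 on a 250-aa chain; type II: spacing 24;
  PRXQ: spacing 4); randomized replicates jitter positions by up to
  ±15 residues (±9 for 2-Cys, bounded by the C-terminal-third
  constraint). Excluding Cys from the background guarantees the planted
  cysteines are the only ones — real proteins contain incidental
  cysteines, so passing round trips show rule correctness, not
  robustness to cysteine-rich backgrounds.
- **Loci**: per-subfamily exon counts follow the family's
  characteristics table (1–7 exons); the splice-variant fixture is
  deterministic (independent of the user seed) because it is a packaged
  reference object.
- **Duplicate pairs**: exactly the requested numbers of synonymous and
  nonsynonymous single-base substitutions, each in a distinct codon and
  class-verified by translation. Distinct codons make pathway averaging
  exact, so synonymous-only pairs yield Ka = 0 identically. No indels,
  no rate heterogeneity, no codon-usage bias.
- **Promoters**: planted element instances (IUPAC codes resolved
  uniformly) on both strands, non-overlapping with 10-bp margins.
  Background matches occur at their natural rate and are verified
  against a naive scanning oracle, not suppressed.
- **Ct tables**: the three-step procedure inverted, so planted fold
  changes are recovered exactly at zero noise; Gaussian replicate noise
  (default SD 0.15 cycles) models pipetting/detection variation only.

Default problem sizes (200-codon duplicate CDSs, 200 replicate pairs in
the recovery experiment, 100 random promoters of 300 bp against the
naive oracle, 100 randomized proteins per subfamily) were chosen as the
smallest sizes at which the statistical checks are meaningful.

## Known limitations

- The classifier is a rule system for the six plant PRX subfamilies; it
  does not handle atypical PRXs outside them (label `UNCLASSIFIED`).
- Exact reproduction of any published Ka/Ks table is best-effort: which
  counting/averaging variant a given "KaKs calculator" run used is
  typically unstated.
- Family tables in the literature are not fully self-consistent (e.g. a
  10-exon member coexisting with a stated 0–6 intron range, and one
  member placed both on a chromosome and "on scaffolds"); the packaged
  table transcribes the printed values and flags these rows in a notes
  column rather than resolving them.
- PSI/quantitative splicing, PWM promoter scoring, amplification-
  efficiency-corrected qPCR and tree-based dating are all out of scope.
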