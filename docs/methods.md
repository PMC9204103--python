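# Methods

## Labeling model and mass arithmetic

All masses are monoisotopic, in daltons, from the IUPAC atomic-mass tables
shipped with pyteomics. The biotinamidocaproyl adduct that
sulfo-NHS-LC-biotin leaves on a lysine ε-amine is fixed at composition
C16H25N3O3S (339.1617 Da); this is the unique small-molecule composition
consistent with the reagent's chemistry and the reported per-lysine shift.
Cysteines are treated as carbamidomethylated (+57.0215 Da, iodoacetamide
alkylation) whenever the fixed-modification flag is on, which is the
default throughout the pipeline to match standard in-gel digestion workups.
Ambiguity codes (B, Z, X, U) are rejected at parse time rather than
approximated: a silently wrong mass would propagate through every
downstream match.

## Digestion with blocked cleavage

Trypsin specificity is cleavage C-terminal to K/R, suppressed before P. A
lysine carrying a cleavage-blocking modification (the biotin adduct) is
removed from the candidate cut list entirely: peptides spanning it carry
the modification, and the protected site does **not** count toward the
missed-cleavage tally — protection is a chemical fact, not a digestion
failure, and counting it would make missed-cleavage filters meaningless.
Up to `max_missed` genuinely uncut sites are allowed (default 2; published
dimer-interface peptides show at least one internal K/R).

Candidate enumeration (`enumerate_modforms`) produces the theoretical
search space for matching: every tryptic peptide under every placement of
the variable modifications, deduplicated by span and modification
multiset. Two rules close the hypothesis space: every internal cut-site
lysine of an emitted peptide is either labeled (blocked) or a missed
cleavage, and the C-terminal residue of a peptide is never labeled — a
peptide ending at a lysine exists only because trypsin cut there, which a
label would have prevented. This convention is applied uniformly,
including a protein-C-terminal lysine, where a label would be invisible to
cleavage anyway. Lysines followed by proline are not cut sites but remain
labelable ("free" placements). A combinatorial cap (default 200,000 forms)
aborts enumeration with a diagnostic rather than exhausting memory.

The pipeline enumerates with up to 6 variable labels per peptide: a run of
c adjacent accessible lysines fuses into a single peptide carrying c
labels, so the cap must cover the label counts the blocked-cleavage model
can actually emit; below ~4 the search space simply lacks real digest
products.

## MS1 matching and MS/MS localization

Peptide-mass-fingerprint matching assigns each MS1 peak its best candidate
by absolute ppm error (default tolerance 50 ppm, typical for
reflector-mode MALDI-TOF; charge state {1}, configurable for ESI data),
with deterministic tie-breaking: fewer modifications, then fewer missed
cleavages, then lexicographic sequence. The full many-to-many match list
is retained for diagnostics; footprinting calls use the one-to-one
assignment.

Site localization follows the canonical Ascore construction. The MS/MS
spectrum is filtered to its top-d peaks per 100 m/z window for d = 1..10;
at each depth, each candidate site's hypothesis ladder (b/y, charge 1 by
default, no neutral losses) is scored by the cumulative binomial
P(X ≥ k) for k of n predicted ions matched within ±0.5 Da, success
probability d·(2·tol)/100, reported as −10·log₁₀P. The working depth is
the one separating the two leading hypotheses most; final scores are then
recomputed on the site-determining ions alone (b ions with index between
the two sites and the complementary y ions), and their difference is the
ΔAscore. ΔAscore > 19 (P < 0.0126) is the confident-localization default.
Two numerical choices matter:

- The depth filter keeps *all* peaks tied with the depth-th intensity in a
  window (a threshold, not a strict count), so filtering is invariant to
  the ordering of equally intense peaks; a spectrum supporting two sites
  identically then yields ΔAscore = 0 exactly.
- The original algorithm weight-averages peptide scores across depths;
  this implementation picks the single most separating depth (ties go to
  the smaller depth). For lysine-adduct localization with one label per
  peptide the simplification is inconsequential and easier to reason
  about.

Peptides with a single candidate site are inherently unambiguous and are
reported with a sentinel (infinite ΔAscore); peptides in which every
candidate lysine is labeled are likewise unambiguous per site. Peptides
with more labels than can be localized individually (label count strictly
between one and the candidate count) are skipped rather than guessed.

An accessibility map calls a lysine modified when at least `min_witnesses`
spectra (default 1) localize a label there at or above the ΔAscore
threshold. Maps from equivalent states can be pooled by union (default,
mirroring joint reporting of two cis-like preparations) or intersection.
Differential reports are plain set differences with deterministic
ordering, annotated against a domain table; positions within
`flank_window` residues of a boundary (default 5) are labeled
`flank:<domain>`, which reconciles literature statements that place a
residue "within" a domain whose printed boundaries narrowly exclude it.
Only the two domain boundaries the source study prints are shipped as
defaults (BH3 461–474, kinase domain 2206–2615); the BH3 start is printed
as 461 in one place and 462 in another, and the default follows the
figure-level annotation (461). All other domains must be user-supplied.

## Synthetic experiments

The generator simulates the full two-state design: a random protein
(default 750 residues, 50 lysines — matching the ~6.6% lysine density of
the 2644-residue, 175-lysine protein the design emulates; lysines never
terminal and never before proline so each is a bona fide cut site), a
shared accessible core (each remaining lysine accessible in both states
with probability 0.4), and state-unique accessible sets of 2 (cis) and 7
(trans) to echo the published differential's shape. Labeling is saturating
by default (efficiency 1.0). Digestion honors blocked cleavage; MS1 peaks
appear at [M+H]⁺ with Gaussian relative mass error (σ = 10 ppm), thinned
by a per-peptide detection probability (0.9), plus 20 uniform noise peaks
across m/z 500–3,500 (the MALDI acquisition window). Signal peaks are not
clipped to that window: the emulated study identified peptides by both
MALDI-TOF and window-free nano LC-MS/MS, and fused multi-label peptides
routinely exceed 3,500 Da. Each labeled peptide yields a b/y MS2 ladder
with per-fragment dropout (detection 0.9), intensities rank-correlated
with ion index (low-index ions run hot, so the Ascore depth filter sees a
plausible ordering), and uniform noise below the matched median. All
randomness flows from one seed; reruns are bit-identical.

Recovery is scored as precision/recall/F1 of the called modified-lysine
sets per state (empty call sets count precision 1 by convention), plus an
exact-match flag for the differential. With no mass error, full detection
and no noise the pipeline reproduces the ground truth exactly; under the
noise defaults, mean F1 across ten replicate seeds is ≈ 0.94.

What the generator does not emulate — and what passing tests therefore do
not show: isotope envelopes, chemical/matrix noise structure, retention
time, charge states above 1, label-competition kinetics at sub-saturating
reagent ratios, and real instrument intensity response. Closed-loop
recovery demonstrates the inference machinery is correct, not that real
spectra of comparable quality exist.

## Geometry utility

The ω dihedral of a peptide bond is computed from the CA(i)–C(i)–N(i+1)–
CA(i+1) frame with the standard atan2 formulation, returned in (−180°,
180°]. Classification uses half-widths of 30° around 0° (cis) and 180°
(trans); anything else is "twisted". The signed dihedral is invariant
under rigid motion and under reversal of the atom order, and negated by
mirror reflection. PDB input is restricted to ATOM records with complete
backbone atoms (via gemmi); the utility exists to verify cis/trans
assignments of modeled structures, not to parse arbitrary crystallographic
content.

## Problem sizes

Analyses and tests run on a 750-residue synthetic protein, ten replicate
seeds for recovery statistics, and the transcribed fixture tables; the
whole suite and the acceptance script each complete in well under a
minute on one CPU.
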