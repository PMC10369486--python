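# Methods

## Discretized rotamer model

A residue's side-chain conformation is the vector of its χ torsions,
measured with the right-hand IUPAC sign convention (cis = 0°, trans
reported as +180°; the −180° boundary is normalized to +180° so trans has
one representative). χ quadruples are the standard per-residue-type atom
definitions shipped in `chi_definitions.tsv`; ARG stops at χ₄ — its χ₅
guanidino torsion is excluded, and the ARG class list is correspondingly
the penultimate-library set.

Classification uses a closed inventory of 137 canonical classes
(`rotamer_inventory.tsv`), one mode vector per class, with a single bin
rule: a class qualifies when every per-angle circular deviation from its
mode is ≤ 30°. Among qualifying classes the smallest worst-angle
deviation wins; ties fall back to the deviation sum, then inventory
order. A χ vector qualifying for no class is **off**. Consequences of the
closed-world inventory: χ combinations not listed (e.g. LEU "pt")
classify as off even when each angle individually sits in a generic bin.

Three conventions deserve explicit statement:

- **Generic modes.** p = +65°, t = 180°, m = −65° with ±30° halfwidth, so
  the m bin is [−95°, −35°] and the t bin wraps (|χ| ≥ 150°). The +65°
  centre is the mirror image of the m interval; it is configurable in
  `bin_model.json`.
- **Symmetric termini are 180°-periodic.** The terminal branch torsion of
  ASP (χ₂, OD1/OD2), GLU (χ₃, OE1/OE2), PHE and TYR (χ₂, ring) only has
  meaning modulo 180°, because the two branch atoms are chemically
  equivalent. Bin membership at that single index therefore uses a
  180°-folded distance: a corrected χ₂ of −75° is 15° away from the PHE
  "p90°" mode, not 165°. Without this fold, conformations lying inside a
  bin that straddles the ±90° correction boundary would be misclassified
  as off.
- **Proline.** Ring pucker is classified on χ₁ alone: Cγ endo within 30°
  of +30°, Cγ exo within 30° of −30°, the χ₁ = 0 boundary assigned to
  exo, otherwise off. The endo-positive sign convention is this package's
  choice (verified self-consistently against its own builder); the
  literature states none.

## Nomenclature correction

IUPAC-IUB rules fix the branch naming of ASP/GLU/PHE/TYR so the terminal
symmetric torsion lies in (−90°, +90°]: values in [−180°, −90°] or
(+90°, +180°] are rotated by 180° (closed at −90, open at +90). The
correction targets the *terminal* torsion (ASP χ₂, GLU χ₃, PHE/TYR χ₂); a
`verbatim_indices` switch instead applies it at ASP χ₁ / GLU χ₂ for
parity with descriptions that number the rule that way, but the terminal
reading is the one consistent with class labels like ASP "t70°" and GLU
"mt-10°". For PHE/TYR the same test drives a record-level fix: swapping
CD1↔CD2 and CE1↔CE2 names (coordinates untouched), after which the
recomputed χ₂ is valid. Both operations are idempotent.

## Quality filters

Structure level: single chain and crystallographic resolution strictly
below 2.0 Å; structures without resolution metadata fail unless the
check is disabled (synthetic files carry an explicit 1.5 Å so they pass).
Residue level: every atom participating in the residue's torsions — its χ
atoms plus backbone N, CA, C — must be present with B-factor ≤ 40 Å² and
occupancy 1. Missing atoms dominate the flag; alternate locations other
than blank/'A' are dropped at parse time (the occupancy filter makes
other altlocs irrelevant downstream). Author numbering is preserved
verbatim; only the first MODEL of a file is read.

## Solvent accessibility

ACC is Shrake–Rupley accessible surface area computed directly: each atom
is sampled on a Fibonacci lattice of 960 points at radius r + 1.4 Å
(Chothia-style element radii: C 1.87, N 1.65, O 1.40, S 1.85 Å), a point
is occluded when it lies *within* (≤) a neighbour's extended radius, and
per-residue ACC sums the residue's heavy atoms. Doubling the point count
moves residue ACC by < 1% on test chains. Translation invariance is
exact; rotation invariance holds only to sampling noise because the
lattice is fixed in space. ACC strata: zero (= 0), low (0, 50], medium
(50, 100], high (> 100) Å²; bins of 20 Å² labelled by lower limit
(left-closed), capped at 320 Å² with an overflow bin. ACC/9.65 converts
to contacting-water counts. Note that DSSP-derived ACC differs from
Shrake–Rupley by a few Å² per residue; the 50/100 Å² thresholds are kept
as printed without recalibration, and a classic DSSP reader is provided
for parity runs. Without DSSP input, secondary structure falls back to a
coarse φ/ψ rule (helix within 30° of (−57, −47), strand within 30° of
(−120, +120), else coil), flagged approximate.

## Error analysis and statistics

Original and repacked structures are paired by (structure, chain, seq id,
insertion code); a type mismatch is an error, unmatched retained residues
are reported and excluded from denominators. A rotamer error is any class
label change; per-χ errors dichotomize the circular deviation at 30°
(exactly 30.0° counts correct). Decompositions: error rate per residue
type (errors/records), contribution per type (share of all errors, sums
to 100%), rates per ACC category and bin (empty strata absent, bins
beyond 220 Å² flagged low-n), accuracy per secondary structure / protein
size (100-residue bins) / side-chain-length group (I: CYS SER THR VAL;
II: ASN ASP HIS ILE LEU PHE PRO TRP TYR; III: GLN GLU MET; IV: LYS ARG),
per-class confidence (fraction of originals of a class predicted as the
same class, per program tag plus macro-average), and ranked "original to
predicted" transitions (count-descending, lexicographic tie-break).

ACC-vs-class structure is tested with one-way ANOVA per residue type
(classes with ≥ 2 records; off included) and Tukey HSD post hoc: raw
pair p-values from the studentized-range distribution, 95% CIs, and a
family-wise adjustment p′ = min(1, 963·p) — equivalently significance at
raw p < 0.05/963 = 0.000052 — reflecting a family of 963 ad-hoc
comparisons. The Bonferroni-style scaling reproduces the reference
adjusted values to printed precision (e.g. 1.67×10⁻⁵ → 1.61×10⁻²).

## Synthetic data: what it does and does not emulate

The generator builds single-chain all-atom structures by sequential NeRF
placement with ideal geometry (N–CA 1.458, CA–C 1.525, C–N 1.329 Å,
ω = 180°; backbone presets helix (−57, −47), strand (−120, 120), coil
(−80, 150), mixed 45/35/20%), L-chirality CB (improper N-C-CA-CB =
+122.6°), and side chains attached from per-type internal-coordinate
templates at sampled χ angles. Canonical residues sample χ uniformly
within ±15° of the class mode; off residues get exactly one χ drawn
uniformly from the complement of all bins at that index (> 30° from every
mode, under the same 180°-folded metric at symmetric termini), which
makes off ground truth unambiguous. PRO is built open-chain with
χ₂ = −1.2·χ₁ as an approximate pucker coupling; the Cδ–N closure is not
enforced. Metadata defaults: resolution 1.5 Å, B ~ N(20, 5²) clipped
below 40 (so the default passes the filter), corruption switches that set
one side-chain atom to B = 60 or occupancy 0.5 at a configured rate.

The mock predictor keeps the backbone and, with probability
ε = logistic(logit(ε₀) + slope·ACC), rebuilds a residue at a uniformly
chosen canonical class different from the truth, recording every action.
Class confusion is discrete, so pipeline recall against the ledger is
exactly 100% — the tests exploit this.

What this emulates well: the *accounting* of the analysis (filters,
correction, classification, pairing, decompositions, statistics) under
known truth. What it does not emulate: real rotamer frequency
distributions (classes are sampled uniformly), steric packing (no clash
relaxation; burial patterns of a real core), program-specific error
structure, crystallographic artefacts, or any correlation between class
and ACC beyond the injected slope. Passing tests therefore certify the
machinery, not claims about real proteins or real packing programs.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen once: 2000-residue
chains for confusion-rate recovery (three binomial standard errors per
residue type), 1200 residues for the ACC-slope experiment, cohorts of
8×150 residues in the analysis scripts, 1000 random frames for the
torsion oracle, 1000 null simulations for ANOVA type-I calibration, and
classification-vs-brute-force grids that coarsen with χ dimensionality
(5° exhaustive for 1–2 χ, 15–20° for 3 χ, 30–36° for 4 χ, plus seeded
random samples of the 5° grid). Equality tolerances: χ round-trip
< 10⁻⁴°, torsion oracle < 10⁻⁶°, ANOVA vs sum-of-squares oracle 10⁻⁸
relative.

## Known limitations

- The closed inventory means unlisted χ combinations are off by fiat.
- The proline endo/exo sign convention is internal; comparisons against
  other tools should verify pucker signs on a reference case.
- Shrake–Rupley ACC and DSSP ACC differ systematically; absolute strata
  boundaries are not recalibrated.
- The φ/ψ secondary-structure fallback is deliberately coarse (three
  codes) and flagged approximate.
- The quality filter reading of "all atoms involved in torsion
  calculations" is implemented as χ atoms plus own-backbone N/CA/C;
  neighbouring residues' atoms are not charged against a residue.
- One acceptance check (the 64→57 residue-filter count on PDB 1AHO chain
  A) needs the RCSB file supplied locally at `data/1AHO.pdb`.
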