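# Methods

## The screening model

The screen treats a peptide as dual-functional when it clears two
independent hurdles in sequence:

1. a bioactivity probability p (bile-acid-binding / micelle disruption)
   with the strict cut p > 0.5, and
2. an intestinal-delivery score on heat-treated porous silica, evaluated
   at the peptide's (mean hydrophobicity, mean pI) coordinates, with the
   strict cut score > 50.

Both comparisons are strict inequalities by design; a peptide sitting
exactly on a threshold is rejected. The second screen only ever sees
first-screen survivors, so the stage counts |library| ≥ |survivors| ≥
|finalists| are non-increasing by construction and are emitted in the
stage summary of every run, together with before/after means and SDs of
both descriptors per k-mer class.

### Descriptor coordinates

Mean hydrophobicity and mean pI are plain arithmetic means of per-residue
scale values over the peptide. The mean-pI descriptor is deliberately
*not* a Henderson–Hasselbalch isoelectric point: it is a map coordinate
defined by the same averaging formula as hydrophobicity. Scales are data
files, not code. The shipped defaults are the Kyte–Doolittle hydropathy
index (dimensionless, range −4.5 … +4.5) and the isoelectric points of the
free amino acids (pH units, range 2.77 … 10.76); with these tables a
typical peptide pool averages ≈ 6 in mean pI and slightly below 0 in mean
hydropathy. Because a delivery-score surface is only meaningful in the
coordinate system it was measured in, every surface records the scale
names it was built with and the pipeline refuses to combine a surface
with descriptors computed on different scales.

Peptide masses use the standard unmodified monoisotopic/average residue
tables (free termini, no cysteine modification); m/z follows the
[M + zH]^z+ convention, (M + z·m_proton)/z.

### First-screen models

Two interchangeable implementations satisfy the probability-model
interface:

- **Random forest** (scikit-learn), trained on labelled peptides with a
  fixed-order composition feature vector: 20 per-letter counts, length,
  mean hydrophobicity, mean pI, average mass, and the three class counts
  (basic {R,K}, acidic {D,E}, aromatic {F,Y,W}). Defaults: 300 trees,
  √p features per split, out-of-bag accuracy recorded, seed mandatory.
  The feature list is configurable because the exact feature set of any
  particular published classifier is rarely recoverable.
- **Logistic surrogate**: p = σ(β₀ + β_b·[has basic] + β_a·[has acidic] +
  β_r·[has aromatic]). Closed-form, deterministic, and structured like
  the enrichment signal the screen exploits (basic residues raise
  positivity odds, acidic residues lower them, aromatic residues raise
  them modestly). It is the reference model for tests and fully
  reproducible pipeline runs.

### Delivery surface

The surface is a rectangular grid of scores over strictly increasing
hydrophobicity and pI axes, interpreted by bilinear interpolation.
Queries outside the grid are clamped to the nearest edge coordinate
before interpolating: the physical behaviour of the silica delivery score
beyond the measured peptide range is unknown, and nearest-edge clamping
is the least-surprising choice; it is recorded in the surface metadata as
`extrapolation: clamp-to-edge`. Interpolated values are always bounded by
the four enclosing node values.

## Enrichment statistics

Class presence (≥ 1 residue of the class anywhere in the peptide) is
cross-tabulated against predicted positivity into a 2×2 table
(a = present∧positive, b = present∧negative, c = absent∧positive,
d = absent∧negative). The odds ratio is the cross-product (a·d)/(b·c);
both orientations are explicit in the API because the acidic-class
enrichment is conventionally reported in the *absent* orientation (odds
of positivity for peptides lacking D/E relative to those containing
them), and silent reciprocal errors are easy to make. Zero cells get the
Haldane–Anscombe +0.5 correction and the result is flagged. Reporting
convention: percentages to the nearest integer, odds ratios to three
significant figures.

The probability-vs-delivery-score relation is summarised by an ordinary
least-squares line and Pearson r, plus subset means for named
composition filters. The two default filters are ≥ 2 acidic residues,
and ≥ 2 acidic together with ≥ 2 aromatic residues; the "more than two"
phrasing that sometimes accompanies such subsets is ambiguous between
≥ 2 and ≥ 3, and this package resolves it as ≥ 2 (the filter factory
takes any minimum, so ≥ 3 is one argument away).

## Protease rule engine

Cleavage specificity is declarative data: a set of P1′ target residues
(the enzyme cuts N-terminal to these) plus blocking rules — context
predicates over P2, P1, P1′, P2′ that veto a cut. Bond i joins residues
i and i+1 (1-based). The shipped thermolysin file (cut before
A/F/I/L/M/V; vetoed when P2′ is proline or P1 is acidic) is labelled an
approximation of the ExPASy PeptideCutter table and is user-replaceable;
the full PeptideCutter exception tables are not reproduced here, so
exact concordance with that tool requires transcribing its rules into a
rule file.

Digestion is complete (every predicted bond is cut); partial/missed
cleavage is out of scope because the release question the screen asks is
all-or-none. A span is *released intact* iff both flanking bonds are cut
or lie at protein termini and no cut falls strictly inside. The minimal
releasable super-peptide search enumerates spans containing the query,
shortest first (ties: smallest start), within a total extension budget —
the operation behind rescuing a candidate whose own C-terminal bond is
not cleavable but whose one-residue extension is. Note the acidic-P1
veto is what protects an internal F following E from cleavage, which is
exactly the situation the bundled fixture `GGVEEFYCSVGG` reproduces.

Yield arithmetic is residue-count proportionality: from g of source
material, protein_mg = 1000·g·fraction and peptide_mg =
protein_mg·(peptide length / protein length). This mirrors the standard
back-of-envelope (a 7-residue peptide in a 460-residue parent carries
7/460 of its mass), not molar-mass proportionality.

## Dose-response fitting

The dose-response model is the four-parameter log-logistic curve
response(c) = bottom + (top − bottom)/(1 + (DC50/c)^slope), which nests
the two-parameter case via optional fixed asymptotes. DC50 is the
midpoint: the fitted curve at c = DC50 equals (bottom + top)/2 exactly,
and the fit is scale-equivariant in concentration. Fixing top = 100 and
bottom = 0 is the documented default for assay use because full
disruption is observed at saturating concentrations. Fitting is
nonlinear least squares with a deterministic multi-start grid (DC50 at
the 25/50/75% concentration quantiles × slopes 0.5/1/2/4) plus a few
seeded log-normal jittered starts; the best residual sum of squares
wins. Non-convergence is carried on the fit object (`converged=False`
with the solver message) and the DC50 accessor refuses unconverged fits.
Data must contain ≥ 4 distinct concentrations and non-constant
responses. If the optimiser lands on the mirrored parameterisation
(bottom > top), the exact 4PL identity swap(bottom, top), slope → −slope
restores the canonical form without changing the curve.

## Synthetic study conditions

The generators are pure functions of their config; the same seed gives
byte-identical files.

- **Proteins**: 200 proteins by default, lengths uniform on 60–300
  residues, i.i.d. residues from an average UniProt-like composition.
  This matches the scale of an edible-protein database screen (a few
  hundred proteins, ~10⁵–10⁶ windows) while keeping a full pipeline run
  in seconds; real proteins' domain structure, repeats and homology are
  deliberately not modelled, so passing tests say nothing about
  redundancy patterns in real databases.
- **Labels**: Bernoulli from the logistic class-presence model. Default
  weights are the natural logs of the published enrichment magnitudes —
  β_basic = ln 6.5, β_acidic = −ln 22, β_aromatic = ln 2.5 — with
  intercept −1.2 placing the positive rate near the one-third observed
  in real libraries. Class indicators of fixed-length peptides are
  weakly correlated (a residue used by one class is unavailable to
  another), so empirical odds ratios land *near*, not exactly on, the
  configured magnitudes; calibration checks therefore use magnitude
  windows, and the single-weight calibration study (only β_basic
  active) concentrates tightly around 6.5 at n = 50,000.
- **Surface**: the logistic ridge 100·σ(g_h·(h−h₀) − g_p·(p−p₀)), high
  at high hydrophobicity and low pI — the direction HT silica release at
  pH 7 favours — bounded in [0, 100] and monotone along each axis.
- **Dose-response**: log-spaced concentrations (0.3–10 mg/mL, 8 points
  × 3 replicates by default) around a true DC50 of 3.0 mg/mL with slope
  2, Gaussian noise sd 5, clipped to [0, 100]. These sit in the range
  of DC50s measured for real micelle-disruption peptides (≈ 3–4 mg/mL).

## Problem sizes used in checks

Library/screening oracle checks run on 25–100 synthetic proteins
(~10⁴–10⁵ windows); the label-model calibration uses 50,000 6-mers; DC50
recovery uses 200 simulated assays of 24 points each. A full synthetic
pipeline run at 150 proteins (~10⁵ independent peptides) completes in a
few seconds on one CPU.

## Known limitations

- The original bioactivity classifier, its 460-peptide training set, and
  the empirical silica delivery-score surface are prior work that is not
  publicly available; this package provides trainable/configurable
  components in their place. Consequently the exact finalist list of the
  original screen (five 6-mers) is *not* reproducible here and is not a
  test target; what is tested is the machinery, its calibration
  behaviour, and every quantity recomputable from published counts.
- Mean-pI is a descriptor, not a titration isoelectric point; do not
  compare it with electrophoresis-derived pI values.
- The thermolysin rules are an approximation; PeptideCutter's full
  exception tables must be transcribed for site-level concordance.
- Printed m/z values in the source literature for the reference peptide
  VEEFYCS ([M+H]⁺ 876.3480) sit ≈ 3.6 mDa above standard monoisotopic
  tables (876.344 computed here); the package's masses follow the
  standard tables, and the printed values are not used as oracles.
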