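# Methods

`cotscan` re-implements, as a tested pipeline, a proteome-scale analysis of
which signal sequences make a protein sensitive to cotransin, a
cyclodepsipeptide that blocks Sec61-mediated cotranslational translocation
in a signal-sequence-discriminatory way. The pipeline has five analytical
stages — SILAC ratio classification, consensus-motif scanning, enrichment
testing, property profiling and dose-response modelling — plus a synthetic
data generator that makes every stage testable without external downloads.

## Sensitivity classification from label-swap SILAC ratios

Each protein carries two DMSO/cotransin expression ratios: the forward
experiment reports it as heavy/light and the label-swapped reverse
experiment as light/heavy. A protein is **sensitive** when both ratios
strictly exceed the threshold (default 1.65; "higher than" is read as a
strict inequality, so a ratio of exactly 1.65 is not sensitive). A protein
with both ratios strictly below the reciprocal threshold 1/1.65 ≈ 0.606 is
called **up-regulated** — a numeric rule this package defines; the source
analysis noted up-regulation qualitatively without one. Everything else is
**resistant**, and proteins quantified in only one experiment are
**incomplete** rather than silently dropped. Requiring both experiments
makes the sensitive set a subset of either single-experiment set — the
dual filter can only be more conservative, a property the tests assert.

A helper converts channel intensities to ratios with optional
median-centering (the standard SILAC normalization assuming most proteins
are unaffected). With it, rescaling one channel by a constant — unequal
loading, instrument drift — cancels out and no call changes, provided no
true effect sits near the threshold.

## The conformational consensus motif

Cotransin-sensitive signal anchor sequences (SASs, the uncleaved TM1 of
membrane proteins) share a conformational pattern rather than a literal
one: two patches of small residues (Gly, Ala, Ser, Thr, Cys) — the first
of exactly two residues, the second of one or two — separated by two or
three bulky residues and bordered on at least one side by a large charged,
large polar or aromatic flanking residue. On an ideal α-helix the two
patches form two adjacent surface cavities.

The engine compiles this as a family of 12 concrete variants (separator
length {2,3} × second patch {1,2} × flank placement {left, right, both})
and also accepts arbitrary PROSITE-dialect patterns (`[ABC]`, `{ABC}`,
`x`, repeats `(m)`/`(m,n)`). Residue-class choices that the motif's verbal
definition leaves open were fixed as follows:

- **small** = {G,A,S,T,C};
- **bulky** (separator) = the 15-residue complement of the small set, the
  most permissive reading, since the separator residues were never
  enumerated; a hydrophobic-only alternative {L,I,V,F,M,W,Y,P} is
  provided for users who consider Pro or charged separators implausible
  inside a helix;
- **flank** = charged {D,E,K,R,H} ∪ large polar {N,Q} ∪ aromatic {F,W,Y},
  with His counted as charged;
- flanks must be immediately adjacent to the patches (offset 0; a
  configurable offset exists but defaults to strict adjacency).

Non-standard letters (B, Z, U, X, O) are retained in sequences but belong
to no class, so they can never satisfy an element — conservative matching.

Scanning runs N→C. All parses sharing a first-patch start are collapsed to
one canonical match: shortest separator first, then longest second patch,
with both flanks reported when present (a verbose mode reports the
alternatives). Cohort screens restrict matching to the annotated signal
span ± 2 residues, so a flank sitting just outside the annotated TM
boundary still counts. The single known extracellular-N-terminus SAS
orientation question is resolved by scanning N→C only and keeping topology
as metadata. The scanner is verified against a brute-force matcher —
every geometry at every offset, straight from the definition — exhaustively
over a reduced alphabet up to length 7 and on thousands of sampled longer
sequences.

## Enrichment statistics

Motif × sensitivity association among SASs is tested with Fisher's exact
test on the 2×2 table (sensitive with/without motif, non-sensitive
with/without). The two-sided p-value is computed by direct hypergeometric
enumeration using the probability-mass rule — sum the probabilities of
all tables with the observed margins that are no more probable than the
observed table. This convention is implemented explicitly (rather than
delegated) because two-sided conventions differ between packages; the
test suite verifies exact agreement with SciPy's independent
implementation over every 2×2 table with N ≤ 40. The odds ratio reported
is the sample value ad/bc, infinite when only the denominator is zero.
Whether the original test was one- or two-sided is not recorded; the
two-sided version is used, and for the headline table (12, 0, 5, 138) the
enumerated p is 2.39 × 10⁻¹⁴, far below the quoted 10⁻⁴ either way.

## Property profiles

Hydrophobicity uses GRAVY — the arithmetic mean of per-residue
Kyte–Doolittle hydropathy, with X excluded from numerator and denominator.
Profiles bin values into half-open classes [edge, edge + 4) and report
percent of cohort; out-of-range values are clipped into the boundary bins
and flagged, never dropped, so every profile sums to exactly 100%. The
historical description of the hydrophobicity axis is internally
inconsistent (a 0–25 scale binned 0–100), so rescaling is exposed as an
explicit linear map with default [−4.5, 4.5] → [0, 100] (the full
Kyte–Doolittle range onto the display axis). No curve fitting is done on
profiles; the plotted "fitted curves" of the original figures were never
defined, and optional smoothing is display-only.

## Helix projection

Signal anchors are modelled as strict α-helices: 100°/residue
(3.6 residues/turn), azimuth(i) = ((i − 1) × 100) mod 360. Cavity
annotation copies the two small-patch position sets from a motif match,
reports their member azimuths, circular-mean centroids (angles near 0/360
wrap, hence circular mean) and the centroid separation in [0°, 180°]. This
is projection geometry for interpretation and display (a helical-wheel SVG
is included); no 3D modelling or solvent-accessible-surface computation is
attempted — renderings in the original work were illustration, not
measurement.

## Motif-introduction design

The designer generalizes the experimental strategy of converting a
resistant SAS into a sensitive one by point mutation (four substitutions
in the aquaporin-2 TM1). For every one of the 12 motif variants at every
placement inside the search window, the required mutation set is exactly
the positions whose residue fails its class; the proposal is the
minimum-cardinality set over all placements, with ties broken by fewest
mutations, then leftmost match, then lexicographic substitution list.
Because the per-placement cost is fully determined, this placement
enumeration is an exact search at any mutation budget — no cap is needed
and none is imposed. Replacement residues default to one representative
per class (G small, L bulky, K flank), keeping proposals biologically
minimal; a full-alphabet mode and a switch forbidding flank creation are
provided. A verification mode checks a user-supplied mutation set (e.g. a
lab-designed quadruple) instead of searching. Minimality is tested against
an independent exhaustive oracle that tries every position subset and
replacement assignment on short sequences.

## Dose-response model

Flow-cytometry readouts are normalized as
percent = 100 × (treated − bg − (chx − bg)) / (dmso − bg − (chx − bg)):
untransfected background subtracted from every channel, the
cycloheximide value (protein already present at t₀) subtracted, and the
result expressed relative to the DMSO control. The background cancels
algebraically, so the statistic is invariant to a constant added to all
channels.

Inhibition curves follow a four-parameter logistic,
y(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill), fitted by least
squares on log-concentration with IC50 parameterized on the log scale.
Top is fixed at 100 by default (the data are DMSO-normalized); bottom is
left free in [0, 100) because inhibition is typically incomplete. The
original fitting model (Hill slope, bottom constraint) was not recorded;
these are this package's choices. Residuals are taken on the log-response
scale whenever all responses are positive ("auto" error model):
fluorescence-derived noise is proportional to signal, and the matched
error model removes most of the small-sample bias that absolute residuals
show on such data (an absolute-residual mode remains available, and is
used automatically when responses can be ≤ 0). Fewer than four distinct
concentrations, or data showing no decrease, yield a flagged fit failure
rather than an exception.

## Synthetic data

The generator emulates the study's structure so that planted truth is
always known:

- **SAS records**: Met + polar N-tail (4–11 residues), hydrophobic core
  of 18–25 residues drawn from a fixed TM-like multinomial, polar C-tail;
  annotated boundaries are the core. With the configured prevalence, one
  of the 12 motif geometries is planted wholly inside the core at a
  recorded position. The core multinomial keeps small residues rare
  (≈13% combined) so that accidental, unplanted motifs arise in only
  ≈3% of cores — matching the low screen background (5 of 143
  non-sensitive sequences) that the analysis assumes.
- **SP records**: tripartite architecture — positively charged n-region
  (1–5 residues), hydrophobic h-region (7–15), polar c-region (3–7)
  ending in an A-X-A cleavage pattern. No motif is planted; the empirical
  accidental rate (~3.5% per sequence, frozen from a 2000-sequence
  pilot) is what the false-positive test checks against.
- **Ratio tables**: sensitive proteins draw a true DMSO/cotransin ratio
  uniformly from 2–10 (the true effect-size distribution is unknown;
  only threshold exceedance was reported); resistant proteins have true
  ratio 1. Observed forward and reverse ratios multiply the truth by
  independent lognormal noise with CV 10% (mean 1), the standard
  multiplicative model for MS ratio data. An intensity layer consistent
  with the ratios supports the channel-scaling invariance test.
- **Cohort shape**: 217 proteins, 53 secretory / 164 membrane, membrane
  SAS:SP:unspecified ≈ 105:56:3, sensitive fractions 50/53 (secretory)
  and 21/164 (membrane), motif prevalence 1.0 in sensitive SASs and
  5/94 in resistant SASs.
- **Study-shaped ratio fixture**: the original per-protein supplementary
  table exists only as a PDF, so `paperlike_silac_table` builds a
  synthetic stand-in with the exact published stratum counts, drawing
  each stratum's ratios conditionally on its side of the dual-threshold
  criterion — faithful in the sense that the published counts are
  themselves defined by that criterion.
- **Dose-response**: the logistic curve times lognormal replicate noise
  on a log-spaced 1–50 μM grid (the experimental concentration range),
  3 replicates.

All generators are pure functions of (config, seed); repeated calls are
byte-identical, and truth labels are emitted explicitly.

What the generator does *not* emulate: peptide-level quantification and
missing-value mechanisms, real TM residue correlations (cores are i.i.d.
multinomial), database-derived boundary uncertainty, or real signal
sequences. Passing tests therefore demonstrate correctness of the
algorithms under the assumed statistical structure, not recovery of the
original biological findings; screens of the real sensitive/non-sensitive
SAS sets (and the TNF-α T45/T46 first-patch check) require external
sequence retrieval and are out of scope for the offline suite.

## Numerical choices and problem sizes

- Fisher enumeration uses log-gamma binomials with a 10⁻⁷ relative slack
  when comparing probability masses (the same guard SciPy uses for ties).
- Frequency profiles assert sum-to-100 within 10⁻⁹.
- The helix azimuth recurrence is exact at 100°/residue (period 18).
- Curve fits run with tolerances 10⁻¹³ so noiseless recovery is exact to
  ≲10⁻⁶ in IC50.
- Test problem sizes: scanner/oracle equivalence is exhaustive to
  length 7 over {G,L,K,A} plus 5000 sampled longer/full-alphabet
  sequences; planted-motif recall uses 1000 sequences; the Fisher grid is
  exhaustive for N ≤ 40; designer minimality uses 40 random short
  sequences against the exhaustive oracle; IC50 bias uses 500 simulated
  datasets. These sizes give the properties real coverage while keeping
  the whole suite in the low minutes on one core.

## Known limitations

- Signal-sequence boundaries are treated as trusted input; the pipeline
  validates but never predicts them.
- The motif model is purely set-membership — no position weights, no
  probabilistic scoring, no discovery of new motifs.
- The up-regulation rule and all cavity geometry descriptors are
  conveniences defined by this package, not published definitions.
- The dose-response fit reports asymptotic (curvature-based) standard
  errors only; no profile likelihood or bootstrap.
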