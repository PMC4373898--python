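# cotscan

Analysis toolkit for signal-sequence-selective translocation inhibition:
which proteins does cotransin — a cyclodepsipeptide blocking the Sec61
channel in a signal-sequence-discriminatory way — actually inhibit, and
what in their signal sequences makes them sensitive?

`cotscan` is aimed at proteomics / membrane-protein groups running (or
re-analysing) SILAC label-swap screens of translocation inhibitors. It
provides, as one pipeline with a library API and a CLI:

- **SILAC classification** — a protein is cotransin-sensitive when its
  DMSO/cotransin expression ratio exceeds 1.65 in *both* the forward
  (H/L) and label-swapped reverse (L/H) experiment; summaries stratify by
  protein class (secretory/membrane) and signal type (SP/SAS).
- **Consensus-motif scanning** — a fuzzy residue-class engine for the
  conformational consensus motif of sensitive signal anchors: two patches
  of small residues {G,A,S,T,C} (2, then 1–2 residues), separated by 2–3
  bulky residues, flanked on one or both sides by a large charged, large
  polar or aromatic residue. Arbitrary PROSITE-dialect patterns are also
  supported.
- **Enrichment statistics** — two-sided Fisher exact test (hypergeometric
  enumeration) of motif × sensitivity among signal anchors, plus GRAVY
  hydropathy and length frequency profiles.
- **Helix cavity projection** — ideal α-helix azimuths (100°/residue) and
  annotation of the two small-residue surface cavities of a motif match.
- **Mutation design** — exact minimal sets of point substitutions that
  introduce the motif into a resistant signal anchor (generalizing the
  F25G/F26G/G27L/Q33K-style redesign), plus a verification mode.
- **Dose-response modelling** — flow-cytometry normalization (background
  and cycloheximide subtraction, percent of DMSO) and four-parameter
  logistic IC50 fitting.
- **Synthetic data** — seeded generators for SAS/SP cohorts with planted
  motifs, label-swap ratio tables with known truth, and noisy
  dose-response curves, so the whole pipeline is testable offline.

## Worked example

```python
from cotscan import ContingencyTable2x2, fisher_exact, run_pipeline
from cotscan.synthetic import GeneratorConfig, PAPERLIKE_CONFIG, generate_study

# Enrichment of the motif among sensitive signal anchors:
# 12/12 sensitive SASs carry it, 5/143 non-sensitive membrane proteins do.
print(fisher_exact(ContingencyTable2x2(12, 0, 5, 138)))
# FisherResult(p_two_sided=2.38551941953149e-14, odds_ratio=inf)

# A full synthetic study with the published cohort shape (217 proteins).
study = generate_study(GeneratorConfig(
    seed=1, fraction_sensitive_by_class=PAPERLIKE_CONFIG.fraction_sensitive_by_class))
report = run_pipeline(ratios=study.ratios, sequences=study.sequences)
print(report.to_text())
```

which prints

```
cotscan pipeline report
========================
classification (threshold 1.65): 217 proteins
  membrane/SAS: resistant=97, sensitive=8
  membrane/SP: resistant=46, sensitive=10
  membrane/unspecified: resistant=3
  secretory/SP: resistant=3, sensitive=50
motif screen: 22 with / 195 without (skipped 0)
enrichment (SAS): table (8,0,11,86), p=2.71e-07, OR=inf
```

Reading the output: the dual-ratio filter called 68 of 217 synthetic
proteins sensitive (50 of 53 secretory ones — cotransin barely
discriminates among secretory proteins); the motif screen found the
planted consensus motif in all 8 sensitive SASs and in 11 of 97 resistant
ones (planted background plus a few chance matches in hydrophobic cores),
and the Fisher test on that 2×2 table rejects independence at
p ≈ 2.7 × 10⁻⁷. The exact numbers are reproducible from the seed.

The same pipeline runs from the shell on TSV/FASTA inputs:

```
cotscan simulate --seed 1 --outdir sim/
cotscan run --ratios sim/ratios.tsv --fasta sim/sequences.fasta \
            --annotations sim/annotations.tsv --out report.json
cotscan design --sequence KLLLLLL --max-mutations 3
cotscan fit-ic50 --data dose_response.tsv
```

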