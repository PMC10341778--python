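# glysite

Site-specific N-glycopeptide profiling from deconvoluted mass lists, plus
1:1 binding kinetics for biolayer interferometry (BLI) and a small
perfusion-culture productivity calculator.

`glysite` is aimed at protein analytics groups characterising recombinant
glycoproteins — e.g. a difficult-to-express receptor ectodomain produced in
CHO cells — who have deconvoluted LC-ESI-MS peak lists per protease digest
and want, per N-glycosylation sequon, the relative abundance of glycoform
categories (sialylated, galactosylated, agalactosylated, high-mannose,
unoccupied), and who measure antigen–antibody affinity on an Octet-style
BLI instrument.

## What it computes

**Glycoprofiling.** For a protein sequence the package enumerates sequons
(N-X-S/T, X ≠ P), digests in silico (trypsin: after K/R not before P;
chymotrypsin: after F/W/Y/L not before P; or both), and builds the table of
theoretical neutral monoisotopic masses

    m(peptide + glycan) = Σ residue masses + m(H2O) + fixed mods
                          + a·HexNAc + b·Hex + c·Fuc + d·NeuAc + e·NeuGc

over a bounded, biosynthetically constrained composition space. Each
deconvoluted peak is assigned to the candidate minimising |Δm/m| within a
ppm tolerance (ties → fewest monosaccharide types → lower mass); ambiguous
assignments are re-ranked by corroboration across protease digests, and
peaks whose evidence ties across sites are flagged and excluded from
quantification. Matched intensities are aggregated per site into category
proportions: high mannose (HexNAc₂Hex₅₋₉), terminal sialic acid
(NeuAc+NeuGc ≥ 1), terminal galactose (Hex > 3), terminal GlcNAc, or
unglycosylated, with fucosylation, Neu5Gc and LacNAc-repeat
(HexNAc > 6 and Hex − 3 > 4) flags.

**BLI kinetics.** Sensorgrams at analyte concentrations C are fitted
globally (shared kon, koff, Rmax; optional per-curve offset) with the 1:1
Langmuir model

    R(t) = Rmax · C/(C + KD) · (1 − e^−(kon·C + koff)·t),   KD = koff/kon

and dissociation R(t) = R(t₁)·e^−koff·(t−t₁). A worked example: an
antibody with kon = 2.06×10⁵ /(M·s) and koff = 6.57×10⁻⁴ /s has
KD = 3.19 nM.

**Bioprocess metrics.** For daily-exchange perfusion cultures,
qP [pg/cell/day] = titer [µg/mL] / VCD [10⁶ cells/mL], plus max titer and
cumulative harvested product.

Every stage has a synthetic-data generator (`glysite.synth`) so the whole
pipeline is testable end to end without instrument data.

## Worked example

```bash
glysite demo --seed 1
```

generates a 5-sequon glycoprotein, sialylation-dominated ground-truth
glycoform distributions per site, noisy peak lists for tryptic and
chymotryptic digests (5 ppm mass error SD, 1% intensity CV, 10% contaminant
peaks), multi-concentration sensorgrams (10–600 nM, 1% noise), runs both
pipelines and prints:

```
seed: 1
site N6: max |proportion error| = 0.0009
site N89: max |proportion error| = 0.0005
site N99: max |proportion error| = 0.0006
site N116: max |proportion error| = 0.0001
site N183: max |proportion error| = 0.0004
overall max |proportion error| = 0.0009
site assignment accuracy = 1.0000
KD true 3.19 nM, fitted 3.19 nM (relative error 0.02%)
culture: max titer 14.29 ug/mL, mean qP 0.491 pg/cell/day
```

Per site, "max |proportion error|" is the largest absolute deviation of any
recovered category proportion from the generator's ground truth; the KD
line compares the globally fitted equilibrium constant with the simulating
parameters.

Real data enter through the same CLI:

```bash
glysite profile --fasta protein.fasta --peaklist-dir peaks/ \
    --tol-ppm 10 --missed 2 --out-dir results/
glysite blifit --input sensorgrams.csv --report kinetics.tsv
glysite bioprocess --input culture.csv --shift-day 3
```

`profile` writes a site-by-category proportion table, the full annotated
glycoform table (composition, mass, ppm error, intensity, category, flags,
ambiguity), an unmatched-peak table and a stage-count log.

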