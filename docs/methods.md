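# Methods

## Theoretical glycopeptide masses

Peptide masses are neutral monoisotopic: the sum of residue masses plus one
water (18.0105647 Da), with fixed modifications added per residue
occurrence. The default fixed modification is carbamidomethyl-Cys
(+57.021464 Da), reflecting iodoacetamide alkylation before digestion;
variable modifications (e.g. Met oxidation) are not applied by default.
Monosaccharides enter as glycosidic residue masses (HexNAc 203.0793725,
Hex 162.0528234, Fuc 146.0579088, NeuAc 291.0954165, NeuGc 307.0903311 Da),
so glycan attachment is purely additive — condensation water is already
encoded. All constants are carried at 10⁻⁸ Da so sums over large
glycopeptides stay within 10⁻⁵ Da of full atomic-composition arithmetic.

In-silico digestion is fully specific: trypsin cleaves after K/R,
chymotrypsin after a configurable residue set (default F/W/Y/L — the common
low-specificity set without M; whether a given lab's chymotrypsin rule
includes L or M varies, hence the knob), neither before proline; the
combined protease uses the union of cleavage sites. Peptides with
0..`max_missed` missed cleavages are generated (default 2). Coordinates are
1-based inclusive. The zero-missed-cleavage peptides partition the input —
a property the suite checks on random sequences.

## The glycan composition space

The default search space enumerates HexNAc 2–8, Hex 3–12, Fuc 0–2,
NeuAc 0–4, NeuGc 0–2 under biosynthetic constraints:

* HexNAc = 2 → the mannose series only (Hex 5–9, no Fuc/NeuAc/NeuGc);
* HexNAc ≥ 3 → sialic acids capped at one per antenna
  (NeuAc + NeuGc ≤ HexNAc − 2) and hexoses capped at
  Hex ≤ max(HexNAc + 1, 6): three core mannoses plus at most one galactose
  per antenna — each further LacNAc unit brings its own HexNAc — with the
  floor of 6 admitting hybrid glycans that keep an unprocessed mannose arm.

The galactose cap matters in practice, not just aesthetically: without it
the space contains compositions such as HexNAc₃Hex₁₁ (eight galactoses on
one antenna) whose only role is to collide with real glycoforms. The glycan
residue lattice has a near-degeneracy at 37.72 mDa
(2 HexNAc + 2 Fuc + NeuAc + NeuGc ≈ 8 Hex), so those impossible
compositions sit within a few ppm of heavily sialylated glycopeptides and
absorb their peaks under realistic mass error, flipping
sialylated/galactosylated category calls. Capping galactose at the antenna
count removes the entire 8-Hex-shift family from the space (968
compositions remain). Two exact degeneracies are unavoidable and harmless:
Fuc + NeuGc = Hex + NeuAc (both add C17H27NO13), and compound applications
of it — these swaps always preserve the total sialic-acid count and
therefore the primary category; they are surfaced as ambiguity flags.

## Peak matching and quantification

A peak at observed neutral mass m matches a table entry of mass m₀ when
|m − m₀|/m₀ ≤ tol (default 10 ppm; configurable). Among in-tolerance
candidates the assignment minimises, in order: |ppm error| quantized to
0.01 ppm, the number of distinct monosaccharide types, the theoretical
mass. The quantization makes exactly isobaric compositions true ties (their
stored masses differ by ~10⁻⁶ Da of representation noise), so the parsimony
rule — not floating-point dust — decides them, and it does so consistently
across digests. The windowed (binary-search) implementation is held equal
to a brute-force all-pairs scan in the tests.

When several protease digests are analysed together, ambiguous assignments
are re-ranked by cross-digest corroboration (`resolve_cross_digest`): a
real glycoform appears in every digest that covers its site, on a different
peptide backbone and hence at an independent absolute mass, whereas a
chance near-isobar collision is digest-specific. Candidates are preferred
by (i) how many *other* digests currently assign the same (site,
composition), (ii) how many digests contain it as an in-tolerance candidate
at all, then the standard ranking; the assignment is iterated three rounds
so corroboration can propagate. With one digest this reduces exactly to the
plain ranking. Peaks whose top candidates still tie across different sites
on both mass and corroboration evidence (which happens when two sites sit
on equal-mass peptides) are flagged `site_ambiguous`.

Quantification divides each site's matched intensity per category by the
site's total matched intensity; unglycosylated-peptide matches count in the
denominator. Matches carrying no usable site information — peptides
covering several sequons, and site-ambiguous peaks — are excluded from
normalisation but kept in the report. `pooled` mode sums intensities
across digests before normalising; `per_digest` emits one profile per
(site, digest).

Residual limitation: when a cross-site pair of glycopeptides happens to
land within the mass-error scale in *both* digests simultaneously, mass
evidence alone cannot separate them. Across 40 simulated five-site runs at
the default noise (5 ppm SD), site-assignment accuracy was 1.0 in 37 runs
(minimum 0.981) and the maximum category-proportion error stayed ≤ 0.01 in
39 (one run reached 0.057 through an 8.7 mDa two-digest coincidence). Real
workflows break such ties with MS/MS fragments or retention time, which
this package deliberately does not model.

## 1:1 binding kinetics

The pseudo-first-order Langmuir model: during association at analyte
concentration C, R(t) = Req·(1 − e^(−kobs·t)) with kobs = kon·C + koff and
Req = Rmax·C/(C + KD); during dissociation R decays exponentially with
rate koff from its association-end value; KD = koff/kon. The global fit
shares kon, koff, Rmax across all concentrations, optionally adds one
additive offset per curve (on by default — reference-subtracted traces
often retain baseline offsets), and minimises pooled squared residuals with
`scipy.optimize.least_squares` (trust-region reflective). Rate constants
are optimised as log₁₀ values, bounded to kon ∈ [10², 10⁸] /(M·s),
koff ∈ [10⁻⁷, 1] /s; a koff at the lower bound is how a flat dissociation
(koff → 0) presents. Start values come from phase-wise heuristics: koff
from a log-linear regression on the top-concentration dissociation tail,
per-curve kobs from the 63.2%-of-plateau crossing time, kon from the slope
of kobs against C. "No specific binding" is declared when the fitted Rmax
is below 3× the residual noise SD (configurable) or the fit fails — the
instrument-software analogue is a fit rejected against the non-specific
binding control.

The closed-form association model is verified against numerical
integration of dR/dt = kon·C·(Rmax − R) − koff·R over a random parameter
grid; simulate-then-fit recovery at the study's scale (kon ≈ 2×10⁵,
koff ≈ 7×10⁻⁴, C ∈ {10, 50, 100, 300, 600} nM, 600 s phases, 1 Hz) gives
noiseless errors at solver precision and a median KD error ≈ 0.2% over 20
noise replicates at 1% of Rmax.

## Bioprocess metrics

With a full daily medium exchange each harvest titer is one day's
production, so qP = titer/VCD (µg/mL per 10⁶ cells/mL = pg/cell) per day,
using the day's VCD — the natural estimator when counts and exchange are
daily; no integral-of-viable-cells denominator is attempted. The summary
reports max titer and its day, mean qP over post-shift production days, and
cumulative product as the exact sum of daily titers. Both the fold change
in mean qP and the max-titer ratio are derivable from the summary; the
package asserts neither as "the" process improvement metric since they
answer different questions.

## Synthetic data: what it emulates, what it does not

`make_glycoprotein` builds proteins from Lys/Arg-terminated blocks (8–18
residues) whose filler alphabet excludes Asn, Pro, Lys, Arg, planting exact
numbers of N-X-S/T sequons (X from a set that also avoids chymotryptic
residues so motifs survive both digests); every sequon therefore sits on a
tryptic peptide of length 5–25 and no accidental sequons exist. Defaults: 5
sites, length 300 — the sequon count and spacing of a mid-size receptor
ectodomain, not its full backbone mass.

`sample_profiles` draws per-site category weights
(`sialylated_heavy`: terminal-Sia mass uniform in [0.70, 0.95), remainder
Dirichlet over the minor categories — the dominant-sialylation regime of a
CHO-produced construct; also `mannose_heavy`, `uniform`), then samples 1–4
compositions per category from the default space. `simulate_peaklist`
places each site's glycoforms on the fully cleaved covering peptide per
digest, perturbs masses with Gaussian ppm error (default SD 5 ppm),
intensities with unit-mean lognormal noise (default CV 1%), and adds
uniform-mass contaminant peaks (default 10% of the signal-peak count) at
0.5–2% of the base intensity — deconvoluted chemical noise is
low-abundance; contaminants rivalling analyte peaks would indicate a failed
run, not background. Sensorgram and culture generators add iid Gaussian
signal noise and unit-mean lognormal titer noise respectively. Every
generator is fully determined by its seed and writes self-describing header
comments.

What passing round trips therefore show: the mass table, matcher,
classifier and aggregation invert the stated noise model at realistic
scales. What they do not show: robustness to deconvolution artefacts,
in-source fragmentation, co-eluting isobaric *structures* (vs
compositions), cross-digest ionisation differences (the generator's shared
intensity scale across digests is idealised), or non-1:1 binding
mechanisms.

## Numerical choices and degenerate inputs

* Matching tolerance: 10 ppm default for real data; the synthetic round
  trip matches at 20 ppm = 4σ of its own 5 ppm error model so the
  tolerance window loses essentially no true peaks, and against the
  fully-specific (0-missed) table since the simulated digests are complete.
* Proportions over an empty match set yield a profile with zero total
  intensity and no proportions (not an error); an empty constraint-
  satisfying composition set is an empty list, not an error.
* Peak lists must parse completely: any non-numeric row aborts with line
  numbers, rather than silently dropping rows.
* Config files are flat `key = value`; unknown keys are rejected.
  CLI exit codes: 0 success, 1 input error, 2 convergence/quality warning.
* All randomness flows through `numpy.random.default_rng` seeded per
  generator; identical seeds give byte-identical output files.
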