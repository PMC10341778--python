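"""Seed-deterministic synthetic data for every pipeline stage.

Generates glycoproteins with planted N-X-S/T sequons, per-site ground-truth
glycoform distributions, noisy deconvoluted peak lists, 1:1 binding
sensorgrams and perfusion culture time series. The generators emulate the
statistical shape of the real inputs (sialylated-dominant site profiles,
ppm-scale mass error, low-level contaminant peaks, additive sensorgram
noise) — not raw spectra, isotopic envelopes or chromatography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .bioprocess import CultureRecord, CultureTimeseries
from .classify import Category, classify
from .core import (
    GlycanComposition,
    InputError,
    ProteinSequence,
    default_compositions,
    digest,
    find_sequons,
    glycan_mass,
    peptide_mass,
)
from .kinetics import Sensorgram, predict_sensorgram, write_sensorgrams
from .matching import PeakList, write_peaklist


class SynthesisError(RuntimeError):
    """Generator constraints could not be satisfied."""


#: Filler alphabet: no Asn (no accidental sequons), no Pro (keeps cleavage
#: rules simple), no Lys/Arg (tryptic boundaries are placed explicitly).
_FILLER = "ADEFGHILMQSTVWY"
#: Sequon X-residue alphabet: additionally avoids chymotryptic residues so
#: the planted motif survives both digests intact.
_SEQUON_X = "ADEGHQV"

PROFILE_STYLES = ("sialylated_heavy", "mannose_heavy", "uniform")


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# glycoprotein
# ---------------------------------------------------------------------------

def make_glycoprotein(
    n_sites: int = 5, length: int = 300, seed: int = 0
) -> ProteinSequence:
    """Random protein with exactly ``n_sites`` sequons, each on a tryptic
    peptide of length 8–18, built from Lys/Arg-terminated blocks."""
    if length < 3:
        raise InputError("length must be >= 3")
    if n_sites < 0:
        raise InputError("n_sites must be >= 0")
    rng = np.random.default_rng([seed, 0x91])
    min_block, max_block = 8, 18
    if n_sites * min_block > length:
        raise SynthesisError(
            f"cannot place {n_sites} sequons on tryptic peptides within "
            f"length {length}"
        )
    # Lys/Arg-terminated blocks summing exactly to `length`
    blocks: list[int] = []
    remaining = length
    while remaining > 0:
        if remaining <= max_block:
            size = remaining
        else:
            size = int(rng.integers(min_block, max_block + 1))
            if remaining - size < min_block:
                size = remaining - min_block
        blocks.append(size)
        remaining -= size
    eligible = [i for i, L in enumerate(blocks) if L >= min_block]
    if len(eligible) < n_sites:
        raise SynthesisError("too few peptide-sized blocks for requested sites")
    site_blocks = set(
        rng.choice(eligible, size=n_sites, replace=False).tolist()
    ) if n_sites else set()
    chunks = []
    for bi, L in enumerate(blocks):
        body = rng.choice(list(_FILLER), size=L - 1).tolist()
        if bi in site_blocks:
            a = int(rng.integers(1, L - 4))  # motif occupies a..a+2 < L-1
            body[a] = "N"
            body[a + 1] = str(rng.choice(list(_SEQUON_X)))
            body[a + 2] = str(rng.choice(["S", "T"]))
        chunks.append("".join(body) + str(rng.choice(["K", "R"])))
    protein = ProteinSequence(
        id=f"synthetic|{n_sites}sites|len{length}|seed{seed}",
        residues="".join(chunks),
    )
    if len(find_sequons(protein)) != n_sites:
        raise SynthesisError("sequon count check failed")  # pragma: no cover
    return protein


# ---------------------------------------------------------------------------
# ground-truth glycoform distributions
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to generate — and later score — a synthetic run."""

    protein: ProteinSequence
    #: per sequon position: glycan composition -> fraction (sums to 1)
    site_distributions: dict[int, dict[GlycanComposition, float]]
    mass_error_sd_ppm: float = 5.0
    intensity_cv: float = 0.01
    contaminant_fraction: float = 0.10
    seed: int = 0

    def category_fractions(self, position: int) -> dict[Category, float]:
        out: dict[Category, float] = {}
        for comp, frac in self.site_distributions[position].items():
            cat = classify(comp).primary
            out[cat] = out.get(cat, 0.0) + frac
        return out


def sample_profiles(
    n_sites: int,
    style: str = "sialylated_heavy",
    seed: int = 0,
    compositions: Sequence[GlycanComposition] | None = None,
    max_forms_per_category: int = 4,
) -> list[dict[GlycanComposition, float]]:
    """Per-site glycoform distributions drawn by category then composition.

    ``sialylated_heavy`` gives every site a terminal-Sia mass in [0.7, 1.0)
    (the dominant-sialylation regime); ``mannose_heavy`` favours the mannose
    series; ``uniform`` draws symmetric Dirichlet category weights.
    """
    if style not in PROFILE_STYLES:
        raise InputError(f"unknown profile style {style!r}")
    rng = np.random.default_rng([seed, 0x92])
    space = list(default_compositions() if compositions is None else compositions)
    buckets: dict[Category, list[GlycanComposition]] = {c: [] for c in Category}
    buckets[Category.UNGLYCOSYLATED].append(GlycanComposition())
    for comp in space:
        buckets[classify(comp).primary].append(comp)
    minor = [
        Category.TERMINAL_GAL,
        Category.TERMINAL_GLCNAC,
        Category.HIGH_MANNOSE,
        Category.UNGLYCOSYLATED,
    ]
    profiles = []
    for _ in range(n_sites):
        weights: dict[Category, float] = {}
        if style == "sialylated_heavy":
            sia = float(rng.uniform(0.70, 0.95))
            weights[Category.TERMINAL_SIA] = sia
            rest = rng.dirichlet(np.ones(len(minor))) * (1.0 - sia)
            weights.update(dict(zip(minor, rest.tolist())))
        elif style == "mannose_heavy":
            man = float(rng.uniform(0.5, 0.8))
            weights[Category.HIGH_MANNOSE] = man
            others = [c for c in Category if c is not Category.HIGH_MANNOSE]
            rest = rng.dirichlet(np.ones(len(others))) * (1.0 - man)
            weights.update(dict(zip(others, rest.tolist())))
        else:  # uniform
            weights = dict(
                zip(list(Category), rng.dirichlet(np.ones(len(Category))).tolist())
            )
        dist: dict[GlycanComposition, float] = {}
        for cat, w in weights.items():
            if w <= 0 or not buckets[cat]:
                continue
            k = int(rng.integers(1, min(max_forms_per_category, len(buckets[cat])) + 1))
            picks = rng.choice(len(buckets[cat]), size=k, replace=False)
            inner = rng.dirichlet(np.ones(k))
            for idx, iw in zip(picks.tolist(), inner.tolist()):
                comp = buckets[cat][idx]
                dist[comp] = dist.get(comp, 0.0) + w * iw
        total = sum(dist.values())
        profiles.append({c: f / total for c, f in dist.items()})
    return profiles


def make_ground_truth(
    n_sites: int = 5,
    length: int = 300,
    style: str = "sialylated_heavy",
    mass_error_sd_ppm: float = 5.0,
    intensity_cv: float = 0.01,
    contaminant_fraction: float = 0.10,
    seed: int = 0,
) -> GroundTruth:
    """Synthetic glycoprotein plus per-site glycoform distributions."""
    protein = make_glycoprotein(n_sites, length, seed)
    sites = find_sequons(protein)
    dists = sample_profiles(n_sites, style, seed)
    return GroundTruth(
        protein=protein,
        site_distributions={
            s.position: d for s, d in zip(sites, dists)
        },
        mass_error_sd_ppm=mass_error_sd_ppm,
        intensity_cv=intensity_cv,
        contaminant_fraction=contaminant_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruePeak:
    """Provenance of one simulated signal peak (for scoring recovery)."""

    digest: str
    site: int
    composition: GlycanComposition
    theoretical_mass: float
    observed_mass: float
    intensity: float


def simulate_peaklist(
    truth: GroundTruth,
    proteases: Sequence[str] = ("trypsin", "chymotrypsin"),
    base_intensity: float = 100.0,
) -> tuple[dict[str, PeakList], list[TruePeak]]:
    """Noisy deconvoluted peak lists, one per digest.

    For each sequon the fully cleaved covering peptide is glycosylated with
    every ground-truth composition; masses get Gaussian ppm error, the
    intensities (base * fraction) get unit-mean lognormal noise, and
    low-intensity contaminant peaks (uniform random masses, 0.5–2% of the
    base intensity) are mixed in at the configured rate.
    """
    rng = np.random.default_rng([truth.seed, 0x93])
    mods = truth.protein.fixed_modifications
    peaklists: dict[str, PeakList] = {}
    records: list[TruePeak] = []
    for protease in proteases:
        peptides = [p for p in digest(truth.protein, protease, max_missed=0)]
        masses, intens = [], []
        theo_masses = []
        for position, dist in sorted(truth.site_distributions.items()):
            covering = [p for p in peptides if p.covers(position)]
            if not covering:
                import warnings

                warnings.warn(
                    f"site {position} not covered by any {protease} peptide; skipped"
                )
                continue
            pep = covering[0]
            pep_mass = peptide_mass(pep, mods)
            for comp, frac in dist.items():
                theo = pep_mass + glycan_mass(comp)
                obs = theo * (
                    1.0 + rng.normal(0.0, truth.mass_error_sd_ppm) * 1e-6
                )
                inten = (
                    base_intensity
                    * frac
                    * float(_unit_mean_lognormal(rng, truth.intensity_cv))
                )
                masses.append(obs)
                intens.append(inten)
                theo_masses.append(theo)
                records.append(
                    TruePeak(
                        digest=protease,
                        site=position,
                        composition=comp,
                        theoretical_mass=theo,
                        observed_mass=obs,
                        intensity=inten,
                    )
                )
        n_cont = int(round(truth.contaminant_fraction * len(masses)))
        if n_cont and theo_masses:
            lo, hi = 0.95 * min(theo_masses), 1.05 * max(theo_masses)
            cont_masses = rng.uniform(lo, hi, size=n_cont)
            cont_intens = rng.uniform(0.005, 0.02, size=n_cont) * base_intensity
            masses.extend(cont_masses.tolist())
            intens.extend(cont_intens.tolist())
        order = np.argsort(masses)
        peaklists[protease] = PeakList(
            np.asarray(masses)[order], np.asarray(intens)[order], source=protease
        )
    return peaklists, records


def write_peaklist_files(
    truth: GroundTruth,
    out_dir: str | Path,
    proteases: Sequence[str] = ("trypsin", "chymotrypsin"),
    base_intensity: float = 100.0,
) -> dict[str, Path]:
    """Simulate and write one TSV peak list per digest, plus the protein
    FASTA and a ground-truth table; self-describing header comments."""
    from .core import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    peaklists, records = simulate_peaklist(truth, proteases, base_intensity)
    header = [
        f"synthetic peak list | seed={truth.seed}",
        f"mass_error_sd_ppm={truth.mass_error_sd_ppm} "
        f"intensity_cv={truth.intensity_cv} "
        f"contaminant_fraction={truth.contaminant_fraction}",
    ]
    paths: dict[str, Path] = {}
    for protease, peaks in peaklists.items():
        p = out_dir / f"{protease}.tsv"
        write_peaklist(peaks, p, comments=header + [f"digest={protease}"])
        paths[protease] = p
    fasta = out_dir / "protein.fasta"
    write_fasta([truth.protein], fasta)
    paths["fasta"] = fasta
    gt = out_dir / "ground_truth.tsv"
    with open(gt, "w") as fh:
        fh.write("digest\tsite\thexnac\thex\tfuc\tneuac\tneugc\t"
                 "theoretical_mass\tobserved_mass\tintensity\n")
        for r in records:
            c = r.composition
            fh.write(
                f"{r.digest}\t{r.site}\t{c.hexnac}\t{c.hex}\t{c.fuc}\t"
                f"{c.neuac}\t{c.neugc}\t{r.theoretical_mass:.6f}\t"
                f"{r.observed_mass:.6f}\t{r.intensity:.6f}\n"
            )
    paths["ground_truth"] = gt
    return paths


# ---------------------------------------------------------------------------
# sensorgrams
# ---------------------------------------------------------------------------

DEFAULT_CONCENTRATIONS = (10e-9, 50e-9, 100e-9, 300e-9, 600e-9)


def simulate_sensorgrams(
    kon: float = 2.06e5,
    koff: float = 6.57e-4,
    rmax: float = 1.0,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    t_baseline: float = 60.0,
    t_assoc: float = 600.0,
    t_dissoc: float = 600.0,
    dt: float = 1.0,
    noise_sd: float = 0.01,
    ligand_id: str = "synthetic-ligand",
    seed: int = 0,
) -> list[Sensorgram]:
    """Noisy 1:1 sensorgrams over baseline, association and dissociation.

    Defaults mirror a high-affinity antibody–antigen interaction measured
    at analyte concentrations from 10 to 600 nM with 600 s phases; noise is
    iid Gaussian in signal units (default 1% of the unit Rmax).
    """
    if kon <= 0 or rmax <= 0 or dt <= 0:
        raise InputError("kon, rmax and dt must be > 0")
    rng = np.random.default_rng([seed, 0x94])
    total = t_baseline + t_assoc + t_dissoc
    times = np.arange(0.0, total + dt / 2, dt)
    curves = []
    for i, conc in enumerate(concentrations):
        template = Sensorgram(
            ligand_id=ligand_id,
            analyte_concentration=float(conc),
            times=times,
            signals=np.zeros_like(times),
            t_assoc_start=t_baseline,
            t_assoc_end=t_baseline + t_assoc,
            t_dissoc_end=total,
            curve_id=f"{ligand_id}:{conc * 1e9:g}nM",
        )
        clean = predict_sensorgram(template, kon, koff, rmax, offset=0.0)
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 \
            else clean
        curves.append(
            Sensorgram(
                ligand_id=ligand_id,
                analyte_concentration=float(conc),
                times=times,
                signals=noisy,
                t_assoc_start=t_baseline,
                t_assoc_end=t_baseline + t_assoc,
                t_dissoc_end=total,
                curve_id=template.curve_id,
            )
        )
    return curves


def write_sensorgram_file(
    curves: Sequence[Sensorgram], path: str | Path, seed: int | None = None
) -> Path:
    path = Path(path)
    comments = ["synthetic 1:1 binding sensorgrams"]
    if seed is not None:
        comments.append(f"seed={seed}")
    write_sensorgrams(curves, path, comments=comments)
    return path


# ---------------------------------------------------------------------------
# culture time series
# ---------------------------------------------------------------------------

def simulate_culture(
    n_days: int = 7,
    vcd0: float = 5.0,
    growth_rate: float = 0.8,
    capacity: float = 45.0,
    shift_day: int = 3,
    post_shift_rate_factor: float = 0.25,
    qp_before: float = 0.1,
    qp_after: float = 0.5,
    noise_cv: float = 0.03,
    seed: int = 0,
) -> CultureTimeseries:
    """Perfusion culture with a temperature shift: logistic growth (1e6
    cells/mL units) that slows after ``shift_day``, daily harvest titer
    qP * VCD with unit-mean multiplicative noise."""
    if growth_rate < 0 or qp_before < 0 or qp_after < 0:
        raise InputError("rates must be >= 0")
    rng = np.random.default_rng([seed, 0x95])
    records = []
    vcd = vcd0
    for day in range(n_days + 1):
        if day > 0:
            r = growth_rate * (post_shift_rate_factor if day > shift_day else 1.0)
            vcd = vcd + r * vcd * (1.0 - vcd / capacity)
        qp = qp_after if day > shift_day else qp_before
        titer = qp * vcd * float(_unit_mean_lognormal(rng, noise_cv))
        viability = 0.98 if day <= shift_day else max(0.90, 0.98 - 0.01 * (day - shift_day))
        records.append(
            CultureRecord(day=day, vcd=round(vcd, 4), viability=viability,
                          titer=round(titer, 4))
        )
    return CultureTimeseries(records, temperature_shift_day=shift_day)
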