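"""End-to-end runs: FASTA → digest → theoretical table → peak matching →
classification → per-site profiles → report, plus the all-synthetic demo
that scores how well the pipeline recovers known ground truth."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import Category
from .config import ConfigError, RunConfig
from .core import (
    InputError,
    build_glycopeptide_table,
    default_constraint,
    enumerate_compositions,
    read_fasta,
    write_glycopeptide_table,
)
from .kinetics import global_fit, kd, read_sensorgrams, write_fit_report
from .matching import match_digests, quantify, read_peaklist, render_report
from .synth import (
    make_ground_truth,
    simulate_culture,
    simulate_peaklist,
    simulate_sensorgrams,
)
from .bioprocess import process_summary

logger = logging.getLogger("glysite")

#: Demo matching tolerance: 4 sigma of the simulated 5 ppm mass-error SD,
#: so true peaks are essentially never lost to the tolerance window.
DEMO_TOL_PPM = 20.0


def _compositions_from_config(config: RunConfig):
    constraints = [default_constraint] if config.use_default_constraint else None
    return enumerate_compositions(config.composition_bounds(), constraints)


def run_profile(config: RunConfig) -> dict:
    """Run the glycoprofiling pipeline per a RunConfig; returns stage counts
    and report paths. Raises InputError/ConfigError on bad inputs."""
    if not config.fasta:
        raise ConfigError("config.fasta is required for a profile run")
    if not config.peaklist_dir:
        raise ConfigError("config.peaklist_dir is required for a profile run")
    proteins = read_fasta(config.fasta)
    protein = proteins[0]
    if len(proteins) > 1:
        logger.warning("multiple FASTA records; using the first (%s)", protein.id)
    proteases = config.protease_list()
    comps = _compositions_from_config(config)
    table = build_glycopeptide_table(
        protein,
        proteases=proteases,
        max_missed=config.max_missed,
        compositions=comps,
        chymotrypsin_residues=config.chymotrypsin_residues,
    )
    n_entries = sum(len(v) for v in table.values())
    logger.info("theoretical table: %d entries over %d digests", n_entries,
                len(table))

    peak_dir = Path(config.peaklist_dir)
    if not peak_dir.is_dir():
        raise InputError(f"peak list directory not found: {peak_dir}")
    peaklists = {}
    for p in sorted(peak_dir.glob("*.tsv")) + sorted(peak_dir.glob("*.csv")):
        if p.stem in proteases:
            peaklists[p.stem] = read_peaklist(p)
    if not peaklists:
        raise InputError(
            f"no peak lists named after configured digests {proteases} in {peak_dir}"
        )
    n_peaks = sum(len(v) for v in peaklists.values())
    matches, unmatched = match_digests(peaklists, table, tol_ppm=config.tol_ppm)
    assert len(matches) + len(unmatched) == n_peaks
    logger.info("peaks: %d in, %d matched, %d unmatched", n_peaks, len(matches),
                len(unmatched))
    profiles = quantify(matches, combine=config.combine)
    out_dir = Path(config.out_dir)
    paths = render_report(profiles, matches, unmatched, out_dir)
    write_glycopeptide_table(table, out_dir / "theoretical_table.tsv")
    log_path = out_dir / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"protein\t{protein.id}\n")
        fh.write(f"digests\t{','.join(proteases)}\n")
        fh.write(f"table_entries\t{n_entries}\n")
        fh.write(f"peaks_in\t{n_peaks}\n")
        fh.write(f"peaks_matched\t{len(matches)}\n")
        fh.write(f"peaks_unmatched\t{len(unmatched)}\n")
        fh.write(f"sites_profiled\t{len(profiles)}\n")
    return {
        "protein": protein.id,
        "table_entries": n_entries,
        "peaks_in": n_peaks,
        "peaks_matched": len(matches),
        "peaks_unmatched": len(unmatched),
        "profiles": profiles,
        "paths": {**paths, "log": log_path},
    }


def run_blifit(config: RunConfig) -> dict:
    """Fit the 1:1 model to the configured sensorgram CSV."""
    if not config.bli_input:
        raise ConfigError("config.bli_input is required for a blifit run")
    curves = read_sensorgrams(config.bli_input)
    fit = global_fit(curves, fit_offset=config.fit_offset)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = out_dir / "kinetic_fit.tsv"
    write_fit_report([fit], report)
    return {"fit": fit, "report": report}


# ---------------------------------------------------------------------------
# demo: full synthetic round trip
# ---------------------------------------------------------------------------

@dataclass
class DemoSummary:
    """Recovery metrics of one synthetic round trip."""

    seed: int
    per_site_max_abs_error: dict = field(default_factory=dict)
    max_abs_proportion_error: float = 0.0
    site_assignment_accuracy: float = 1.0
    kd_true_nM: float = 0.0
    kd_fit_nM: float = 0.0
    kd_relative_error: float = 0.0
    kon_fit: float = 0.0
    koff_fit: float = 0.0
    max_titer: float = 0.0
    mean_qp: float = 0.0


def score_recovery(truth, profiles) -> tuple[dict, float]:
    """Per-site max absolute category-proportion error of recovered profiles
    against a GroundTruth, plus the overall maximum."""
    per_site: dict[int, float] = {}
    for prof in profiles:
        pos = prof.site.position
        true_fracs = truth.category_fractions(pos)
        errs = [
            abs(prof.proportion(cat) - true_fracs.get(cat, 0.0))
            for cat in Category
        ]
        per_site[pos] = max(errs)
    overall = max(per_site.values()) if per_site else 0.0
    return per_site, overall


def site_accuracy(records, matches) -> float:
    """Fraction of matched signal peaks assigned to their true sequon.

    Matched contaminants (peaks without a ground-truth record) are not
    counted for or against."""
    lookup = {(r.digest, round(r.observed_mass, 6)): r.site for r in records}
    correct = total = 0
    for m in matches:
        if m.site_ambiguous:
            continue
        key = (m.source, round(m.peak_mass, 6))
        if key not in lookup:
            continue
        total += 1
        if m.glycopeptide.site.position == lookup[key]:
            correct += 1
    return correct / total if total else 1.0


def run_demo(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_sites: int = 5,
    noise_sd: float = 0.01,
    mass_error_sd_ppm: float = 5.0,
    intensity_cv: float = 0.01,
    contaminant_fraction: float = 0.10,
    kon_true: float = 2.06e5,
    koff_true: float = 6.57e-4,
    tol_ppm: float = DEMO_TOL_PPM,
) -> DemoSummary:
    """Generate synthetic data, run both pipelines, score the recovery."""
    truth = make_ground_truth(
        n_sites=n_sites,
        seed=seed,
        mass_error_sd_ppm=mass_error_sd_ppm,
        intensity_cv=intensity_cv,
        contaminant_fraction=contaminant_fraction,
    )
    proteases = ("trypsin", "chymotrypsin")
    peaklists, records = simulate_peaklist(truth, proteases=proteases)
    # the simulated digests are complete, so the matched table is built at
    # full specificity; production configs default to 2 missed cleavages
    table = build_glycopeptide_table(
        truth.protein, proteases=proteases, max_missed=0
    )
    matches, unmatched = match_digests(peaklists, table, tol_ppm=tol_ppm)
    profiles = quantify(matches, combine="pooled")
    per_site, overall = score_recovery(truth, profiles)
    accuracy = site_accuracy(records, matches)

    curves = simulate_sensorgrams(
        kon=kon_true, koff=koff_true, noise_sd=noise_sd, seed=seed
    )
    fit = global_fit(curves, fit_offset=True)
    kd_true = kd(kon_true, koff_true)
    kd_err = abs(fit.kd - kd_true) / kd_true

    culture = simulate_culture(seed=seed)
    summary = process_summary(culture)

    if out_dir is not None:
        out_dir = Path(out_dir)
        render_report(profiles, matches, unmatched, out_dir)
        write_fit_report([fit], out_dir / "kinetic_fit.tsv")
    return DemoSummary(
        seed=seed,
        per_site_max_abs_error=per_site,
        max_abs_proportion_error=overall,
        site_assignment_accuracy=accuracy,
        kd_true_nM=kd_true * 1e9,
        kd_fit_nM=fit.kd * 1e9,
        kd_relative_error=kd_err,
        kon_fit=fit.kon,
        koff_fit=fit.koff,
        max_titer=summary.max_titer,
        mean_qp=summary.mean_qp,
    )
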