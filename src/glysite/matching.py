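"""Match deconvoluted neutral-mass peak lists against a theoretical
glycopeptide table and quantify per-site glycoform profiles.

Matching is ppm-tolerance nearest-neighbour assignment: a peak is assigned
to the in-tolerance candidate with the smallest |ppm error|, ties broken by
fewest distinct monosaccharide types, then by lower theoretical mass.
Ambiguity (several in-tolerance candidates) is flagged, never silently
dropped. Peak intensities are taken as given — deconvolution, charge and
isotope merging are assumed done upstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import SiteGlycoprofile, classify, site_profile
from .core import Glycopeptide, InputError


@dataclass
class PeakList:
    """Deconvoluted neutral monoisotopic masses with intensities."""

    masses: np.ndarray
    intensities: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.masses.shape != self.intensities.shape:
            raise InputError("masses and intensities must have the same length")
        if self.masses.size and (
            not np.all(np.isfinite(self.masses)) or np.any(self.masses <= 0)
        ):
            raise InputError("peak masses must be finite and > 0")
        if self.masses.size and np.any(self.intensities < 0):
            raise InputError("peak intensities must be >= 0")

    def __len__(self) -> int:
        return int(self.masses.size)

    def entries(self) -> list[tuple[float, float]]:
        return list(zip(self.masses.tolist(), self.intensities.tolist()))


#: ppm differences below this quantum are treated as ties during candidate
#: ranking. Exactly isobaric compositions (Fuc + Neu5Gc vs Hex + Neu5Ac is
#: the canonical pair: both add C17H27NO13) otherwise end up ranked by
#: float noise in the sub-0.001-ppm range; quantizing lets the parsimony
#: tie-break (fewest monosaccharide types, then lower mass) decide instead.
PPM_QUANTUM = 0.01


def _rank_key(candidate: tuple[Glycopeptide, float]) -> tuple:
    gp, ppm = candidate
    return (
        round(abs(ppm) / PPM_QUANTUM),
        gp.composition.n_residue_types,
        gp.mass,
    )


@dataclass
class MatchResult:
    """One peak assigned to one theoretical glycopeptide.

    ``candidates`` holds every in-tolerance candidate with its signed ppm
    error, best first. ``site_ambiguous`` marks peaks whose top-ranked
    candidates tie across different sequon sites (e.g. two sites carried by
    equal-mass peptides); such matches are reported but excluded from
    per-site quantification because the mass carries no site information.
    """

    peak_mass: float
    intensity: float
    glycopeptide: Glycopeptide
    ppm_error: float
    n_candidates: int = 1
    source: str = ""
    candidates: tuple = ()
    site_ambiguous: bool = False

    @property
    def ambiguous(self) -> bool:
        return self.n_candidates > 1


# ---------------------------------------------------------------------------
# peak-list I/O
# ---------------------------------------------------------------------------

def read_peaklist(
    path: str | Path,
    source: str | None = None,
    mass_column: str = "mass",
    intensity_column: str = "intensity",
) -> PeakList:
    """Parse a delimited peak list (TSV/CSV, ``#`` comments allowed).

    Columns are located by header name when a header row is present,
    positionally (mass, intensity) otherwise. Rows with non-numeric fields
    abort the parse with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"peak list not found: {path}")
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if "\t" in sample else ","
        for lineno, raw in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not raw or not "".join(raw).strip():
                continue
            if raw[0].lstrip().startswith("#"):
                continue
            rows.append((lineno, [c.strip() for c in raw]))
    if not rows:
        raise InputError(f"no parsable rows in {path}")
    mi, ii = 0, 1
    first = rows[0][1]
    if not _is_number(first[0]):  # header row
        try:
            mi = first.index(mass_column)
            ii = first.index(intensity_column)
        except ValueError:
            raise InputError(
                f"{path}: header lacks columns {mass_column!r}/{intensity_column!r}"
            ) from None
        rows = rows[1:]
    bad = [lineno for lineno, r in rows
           if len(r) <= max(mi, ii) or not (_is_number(r[mi]) and _is_number(r[ii]))]
    if bad:
        raise InputError(f"{path}: non-numeric rows at lines {bad}")
    if not rows:
        raise InputError(f"no parsable rows in {path}")
    masses = np.array([float(r[mi]) for _, r in rows])
    intens = np.array([float(r[ii]) for _, r in rows])
    return PeakList(masses, intens, source=source if source is not None else path.stem)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_peaklist(
    peaks: PeakList, path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write a TSV peak list; masses at 1e-6 Da precision."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("mass\tintensity\n")
        for m, i in peaks.entries():
            fh.write(f"{m:.6f}\t{i:.6f}\n")


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass deviation in parts per million of the theoretical mass."""
    return (observed - theoretical) / theoretical * 1e6


def match_peaks(
    peaks: PeakList,
    table: Sequence[Glycopeptide],
    tol_ppm: float = 10.0,
) -> tuple[list[MatchResult], list[tuple[float, float]]]:
    """Assign each peak to its best in-tolerance theoretical glycopeptide.

    Returns (matches, unmatched peaks). Equivalent to the all-pairs scan:
    candidates are entries with |obs - theo| / theo * 1e6 <= tol_ppm; the
    winner minimises (|ppm| quantized to PPM_QUANTUM, number of distinct
    monosaccharide types, theoretical mass).
    """
    if tol_ppm <= 0:
        raise InputError("tol_ppm must be > 0")
    matches: list[MatchResult] = []
    if len(table) == 0 or len(peaks) == 0:
        return matches, peaks.entries()
    unmatched: list[tuple[float, float]] = []
    order = sorted(range(len(table)), key=lambda i: table[i].mass)
    theo = np.array([table[i].mass for i in order])
    for obs, intensity in peaks.entries():
        # |obs - theo| <= tol * 1e-6 * theo  <=>  theo in [obs/(1+tol), obs/(1-tol)]
        lo = np.searchsorted(theo, obs / (1 + tol_ppm * 1e-6), side="left")
        hi = np.searchsorted(theo, obs / (1 - tol_ppm * 1e-6), side="right")
        cand = sorted(
            (
                (table[order[j]], ppm_error(obs, theo[j]))
                for j in range(lo, hi)
                if abs(ppm_error(obs, theo[j])) <= tol_ppm
            ),
            key=_rank_key,
        )
        if not cand:
            unmatched.append((obs, intensity))
            continue
        matches.append(_build_match(obs, intensity, cand, peaks.source))
    return matches, unmatched


def _build_match(
    obs: float, intensity: float, cand: list, source: str
) -> MatchResult:
    """MatchResult from a rank-sorted candidate list (best first)."""
    gp, ppm = cand[0]
    best_bin = round(abs(ppm) / PPM_QUANTUM)
    site_amb = any(
        round(abs(p) / PPM_QUANTUM) == best_bin
        and g.site.position != gp.site.position
        for g, p in cand[1:]
    )
    return MatchResult(
        peak_mass=obs,
        intensity=intensity,
        glycopeptide=gp,
        ppm_error=ppm,
        n_candidates=len(cand),
        source=source,
        candidates=tuple(cand),
        site_ambiguous=site_amb,
    )


def resolve_cross_digest(
    matches: Sequence[MatchResult], n_iter: int = 3
) -> list[MatchResult]:
    """Re-rank ambiguous assignments using corroboration across digests.

    A glycoform that is real appears in every protease digest that covers
    its site (on a different peptide backbone, hence at an independent
    mass), whereas a chance near-isobar collision is digest-specific. Each
    peak is therefore reassigned to the candidate with, in order: the most
    support from other digests' current assignments, the most digests in
    which it appears as an in-tolerance candidate, and then the standard
    (quantized |ppm|, parsimony, mass) rank. The assignment is iterated a
    few rounds so corroboration can propagate; with a single digest this
    reduces exactly to the plain ranking.
    """
    matches = list(matches)
    if not matches:
        return []
    cand_support: dict[tuple, set] = {}
    for m in matches:
        for gp, _ in m.candidates:
            cand_support.setdefault(
                (gp.site.position, gp.composition), set()
            ).add(m.source)
    win_support: dict[tuple, set] | None = None

    def key(candidate, source):
        gp, ppm = candidate
        k = (gp.site.position, gp.composition)
        ws = len(win_support.get(k, set()) - {source}) if win_support else 0
        return (-ws, -len(cand_support[k])) + _rank_key(candidate)

    current = matches
    for _ in range(n_iter):
        new: list[MatchResult] = []
        support: dict[tuple, set] = {}
        for m in current:
            cand = sorted(m.candidates, key=lambda c: key(c, m.source))
            gp, ppm = cand[0]
            # still site-ambiguous only if neither the mass nor the
            # cross-digest corroboration separates the top candidates
            best_evidence = key(cand[0], m.source)[:3]
            site_amb = any(
                key(c, m.source)[:3] == best_evidence
                and c[0].site.position != gp.site.position
                for c in cand[1:]
            )
            new.append(
                replace(
                    m,
                    glycopeptide=gp,
                    ppm_error=ppm,
                    candidates=tuple(cand),
                    site_ambiguous=site_amb,
                )
            )
            support.setdefault(
                (gp.site.position, gp.composition), set()
            ).add(m.source)
        win_support = support
        current = new
    return current


def match_digests(
    peaklists: dict[str, PeakList],
    table: dict[str, Sequence[Glycopeptide]],
    tol_ppm: float = 10.0,
    corroborate: bool = True,
) -> tuple[list[MatchResult], list[tuple[str, float, float]]]:
    """Match each digest's peak list against that digest's table.

    With ``corroborate`` (default) ambiguous assignments are re-ranked by
    cross-digest support (see resolve_cross_digest); with a single digest
    this is a no-op.
    """
    all_matches: list[MatchResult] = []
    all_unmatched: list[tuple[str, float, float]] = []
    for digest_name, peaks in peaklists.items():
        if digest_name not in table:
            raise InputError(f"no theoretical table for digest {digest_name!r}")
        m, u = match_peaks(peaks, table[digest_name], tol_ppm)
        all_matches.extend(m)
        all_unmatched.extend((digest_name, mass, inten) for mass, inten in u)
    if corroborate:
        all_matches = resolve_cross_digest(all_matches)
    return all_matches, all_unmatched


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify(
    matches: Iterable[MatchResult], combine: str = "pooled"
) -> list[SiteGlycoprofile]:
    """Per-site glycoform profiles from matched intensities.

    ``pooled`` sums intensities across digests per site before normalising;
    ``per_digest`` emits one profile per (site, digest). Matches that carry
    no usable site information — peptides covering more than one sequon,
    and peaks whose best candidates tie across sites — are excluded from
    per-site normalisation to avoid double counting (they remain in the
    match table for reporting).
    """
    if combine not in ("pooled", "per_digest"):
        raise InputError(f"combine must be 'pooled' or 'per_digest', got {combine!r}")
    groups: dict[tuple, list[MatchResult]] = {}
    for m in matches:
        if m.glycopeptide.n_sites_covered > 1 or m.site_ambiguous:
            continue
        key: tuple
        if combine == "pooled":
            key = (m.glycopeptide.site.position,)
        else:
            key = (m.glycopeptide.site.position, m.source)
        groups.setdefault(key, []).append(m)
    profiles = []
    for key in sorted(groups):
        ms = groups[key]
        digest = key[1] if combine == "per_digest" else None
        profiles.append(
            site_profile([(m.glycopeptide, m.intensity) for m in ms], digest=digest)
        )
    return profiles


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def render_report(
    profiles: Sequence[SiteGlycoprofile],
    matches: Sequence[MatchResult],
    unmatched: Sequence[tuple[str, float, float]],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the report triplet: site profiles, full glycoform table,
    unmatched peaks. Deterministic given identical inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .classify import write_profile_report

    paths = {
        "profiles": out_dir / "site_profiles.tsv",
        "glycoforms": out_dir / "glycoforms.tsv",
        "unmatched": out_dir / "unmatched_peaks.tsv",
    }
    write_profile_report(profiles, paths["profiles"])

    rows = []
    for m in sorted(
        matches, key=lambda m: (m.source, m.glycopeptide.site.position, m.peak_mass)
    ):
        cat = classify(m.glycopeptide.composition)
        c = m.glycopeptide.composition
        rows.append(
            {
                "digest": m.source,
                "site": m.glycopeptide.site.position,
                "peptide": m.glycopeptide.peptide.sequence,
                "hexnac": c.hexnac,
                "hex": c.hex,
                "fuc": c.fuc,
                "neuac": c.neuac,
                "neugc": c.neugc,
                "glycan": str(c),
                "theoretical_mass": round(m.glycopeptide.mass, 6),
                "observed_mass": round(m.peak_mass, 6),
                "ppm_error": round(m.ppm_error, 3),
                "intensity": round(m.intensity, 6),
                "category": cat.primary.value,
                "flags": ";".join(sorted(f.value for f in cat.flags)),
                "n_candidates": m.n_candidates,
                "multi_site_peptide": m.glycopeptide.n_sites_covered > 1,
            }
        )
    cols = [
        "digest", "site", "peptide", "hexnac", "hex", "fuc", "neuac", "neugc",
        "glycan", "theoretical_mass", "observed_mass", "ppm_error", "intensity",
        "category", "flags", "n_candidates", "multi_site_peptide",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(paths["glycoforms"], sep="\t", index=False)

    urows = [
        {"digest": d, "mass": round(mass, 6), "intensity": round(inten, 6)}
        for d, mass, inten in sorted(unmatched)
    ]
    pd.DataFrame(urows, columns=["digest", "mass", "intensity"]).to_csv(
        paths["unmatched"], sep="\t", index=False
    )
    return paths
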