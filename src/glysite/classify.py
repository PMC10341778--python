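"""Glycan category assignment and per-site glycoprofile aggregation.

Compositions are mapped to mutually exclusive reporting categories by the
outermost residue they imply — sialylated forms first, then galactosylated
complex forms, then agalactosylated (terminal GlcNAc) forms — with the
mannose series and the bare peptide split out first. Orthogonal structural
features (core fucosylation, Neu5Gc content, poly-LacNAc extension) are
reported as flags, not categories.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import GlycanComposition, Glycopeptide, InputError, SequonSite


class Category(str, enum.Enum):
    """Primary (mutually exclusive) glycoform category."""

    UNGLYCOSYLATED = "Unglycosylated"
    HIGH_MANNOSE = "HighMannose"
    TERMINAL_SIA = "TerminalSia"
    TERMINAL_GAL = "TerminalGal"
    TERMINAL_GLCNAC = "TerminalGlcNAc"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Flag(str, enum.Enum):
    """Orthogonal structural flags, independent of the primary category."""

    FUCOSYLATED = "Fucosylated"
    CONTAINS_NEU5GC = "ContainsNeu5Gc"
    LACNAC_REPEAT = "LacNAcRepeat"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GlycanCategory:
    primary: Category
    flags: frozenset = frozenset()


#: LacNAc-repeat rule: more than this many HexNAc ...
LACNAC_MIN_HEXNAC = 6
#: ... and more than this many galactoses (hexoses beyond the 3 core mannoses).
LACNAC_MIN_GAL = 4

#: Complex-glycan galactose proxy: hexoses beyond the trimannosyl core.
CORE_MANNOSES = 3


def classify(comp: GlycanComposition) -> GlycanCategory:
    """Assign the primary category and flags of one glycan composition.

    Precedence: unglycosylated, then the mannose series (HexNAc 2, Hex >= 5),
    then any sialylated form, then galactosylated (Hex > 3), else terminal
    GlcNAc. Flags: fucosylated (fuc >= 1), contains Neu5Gc (neugc >= 1),
    LacNAc repeat (HexNAc > 6 and Hex - 3 > 4).
    """
    if comp.is_zero:
        primary = Category.UNGLYCOSYLATED
    elif comp.hexnac == 2 and comp.hex >= 5:
        primary = Category.HIGH_MANNOSE
    elif comp.neuac + comp.neugc >= 1:
        primary = Category.TERMINAL_SIA
    elif comp.hex > CORE_MANNOSES:
        primary = Category.TERMINAL_GAL
    else:
        primary = Category.TERMINAL_GLCNAC
    flags = set()
    if comp.fuc >= 1:
        flags.add(Flag.FUCOSYLATED)
    if comp.neugc >= 1:
        flags.add(Flag.CONTAINS_NEU5GC)
    if comp.hexnac > LACNAC_MIN_HEXNAC and (comp.hex - CORE_MANNOSES) > LACNAC_MIN_GAL:
        flags.add(Flag.LACNAC_REPEAT)
    return GlycanCategory(primary=primary, flags=frozenset(flags))


@dataclass
class SiteGlycoprofile:
    """Relative category proportions of the glycoforms found at one sequon."""

    site: SequonSite | None
    proportions: dict = field(default_factory=dict)
    flag_fractions: dict = field(default_factory=dict)
    total_intensity: float = 0.0
    digest: str | None = None

    def proportion(self, category: Category) -> float:
        return self.proportions.get(category, 0.0)


def site_profile(
    matches: Iterable[tuple[Glycopeptide, float]], digest: str | None = None
) -> SiteGlycoprofile:
    """Intensity-weighted category proportions for one sequon site.

    Every match (including the unglycosylated peptide) contributes its
    intensity to the denominator. All matches must share one sequon.
    """
    matches = list(matches)
    if not matches:
        return SiteGlycoprofile(
            site=None, proportions={}, total_intensity=0.0, digest=digest
        )
    sites = {g.site for g, _ in matches}
    if len(sites) > 1:
        positions = sorted(s.position for s in sites)
        raise InputError(f"matches span multiple sequon sites: {positions}")
    site = next(iter(sites))
    total = 0.0
    by_category: dict[Category, float] = {}
    by_flag: dict[Flag, float] = {}
    for gp, intensity in matches:
        if intensity < 0:
            raise InputError("intensities must be >= 0")
        cat = classify(gp.composition)
        total += intensity
        by_category[cat.primary] = by_category.get(cat.primary, 0.0) + intensity
        for fl in cat.flags:
            by_flag[fl] = by_flag.get(fl, 0.0) + intensity
    if total == 0:
        return SiteGlycoprofile(site=site, proportions={}, total_intensity=0.0,
                                digest=digest)
    return SiteGlycoprofile(
        site=site,
        proportions={c: v / total for c, v in by_category.items()},
        flag_fractions={f: v / total for f, v in by_flag.items()},
        total_intensity=total,
        digest=digest,
    )


def sialylation_summary(profile: SiteGlycoprofile) -> tuple[float, float]:
    """(terminal-Sia fraction, terminal-Sia + terminal-Gal fraction)."""
    sia = profile.proportion(Category.TERMINAL_SIA)
    gal = profile.proportion(Category.TERMINAL_GAL)
    return sia, sia + gal


def write_profile_report(
    profiles: Sequence[SiteGlycoprofile], path: str | Path
) -> None:
    """TSV: one row per (site, digest, category) plus one per flag."""
    rows = []
    for p in profiles:
        digest = p.digest or "pooled"
        for cat in Category:
            rows.append(
                {
                    "site": p.site.position,
                    "digest": digest,
                    "kind": "category",
                    "label": cat.value,
                    "fraction": round(p.proportion(cat), 6),
                    "percent": round(100 * p.proportion(cat), 1),
                    "intensity": round(p.proportion(cat) * p.total_intensity, 3),
                }
            )
        for fl in Flag:
            frac = p.flag_fractions.get(fl, 0.0)
            rows.append(
                {
                    "site": p.site.position,
                    "digest": digest,
                    "kind": "flag",
                    "label": fl.value,
                    "fraction": round(frac, 6),
                    "percent": round(100 * frac, 1),
                    "intensity": round(frac * p.total_intensity, 3),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
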