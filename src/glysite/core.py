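"""Protein sequence handling, sequon detection, in-silico digestion and
glycopeptide mass arithmetic.

The theoretical table this module produces — every (peptide, sequon, glycan
composition) combination with its neutral monoisotopic mass — is the search
space against which deconvoluted peak lists are matched downstream.
Coordinates are 1-based inclusive throughout the public surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .masses import (
    AA_RESIDUE_MASS,
    CANONICAL_RESIDUES,
    DEFAULT_FIXED_MODS,
    FUC,
    HEX,
    HEXNAC,
    NEUAC,
    NEUGC,
    WATER,
)


class InputError(ValueError):
    """Invalid user-supplied input (sequence, file, parameter)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

PROTEASES = ("trypsin", "chymotrypsin", "trypsin+chymotrypsin")

#: Residues after which each protease cleaves (never before proline).
TRYPSIN_RESIDUES = "KR"
CHYMOTRYPSIN_RESIDUES = "FWYL"


def _validate_residues(residues: str, label: str = "sequence") -> None:
    for i, aa in enumerate(residues, start=1):
        if aa not in CANONICAL_RESIDUES:
            raise InputError(
                f"non-canonical residue {aa!r} at position {i} in {label}"
            )


@dataclass(frozen=True)
class ProteinSequence:
    """A protein with optional fixed modifications (mass shifts per residue)."""

    id: str
    residues: str
    fixed_modifications: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_MODS))

    def __post_init__(self) -> None:
        _validate_residues(self.residues, label=f"protein {self.id!r}")
        for aa, shift in self.fixed_modifications.items():
            if aa not in CANONICAL_RESIDUES:
                raise InputError(f"fixed modification on unknown residue {aa!r}")
            if not math.isfinite(shift) or shift < 0:
                raise InputError(
                    f"fixed modification shift for {aa!r} must be finite and >= 0"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequonSite:
    """An N-glycosylation sequon N-X-(S|T), X != P; position is the Asn (1-based)."""

    position: int
    motif: str

    def __post_init__(self) -> None:
        if len(self.motif) != 3 or self.motif[0] != "N":
            raise InputError(f"sequon motif must be N-X-S/T, got {self.motif!r}")
        if self.motif[1] == "P" or self.motif[2] not in "ST":
            raise InputError(f"invalid sequon motif {self.motif!r}")


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int
    protease: str
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise InputError(
                f"peptide coordinates {self.start}..{self.end} do not span "
                f"{len(self.sequence)} residues"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide residue counts of one glycoform.

    The all-zero composition denotes the unglycosylated peptide.
    """

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0
    neugc: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "fuc", "neuac", "neugc"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise InputError(f"{name} count must be a non-negative integer")

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac,
            self.hex + other.hex,
            self.fuc + other.fuc,
            self.neuac + other.neuac,
            self.neugc + other.neugc,
        )

    @property
    def is_zero(self) -> bool:
        return not (self.hexnac or self.hex or self.fuc or self.neuac or self.neugc)

    @property
    def n_residue_types(self) -> int:
        """Number of distinct monosaccharide types present (ambiguity tie-break)."""
        return sum(
            1 for v in (self.hexnac, self.hex, self.fuc, self.neuac, self.neugc) if v
        )

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.hexnac, self.hex, self.fuc, self.neuac, self.neugc)

    def __str__(self) -> str:
        if self.is_zero:
            return "unglycosylated"
        parts = []
        for label, v in zip(
            ("HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc"), self.as_tuple()
        ):
            if v:
                parts.append(f"{label}{v}")
        return "".join(parts)


@dataclass(frozen=True)
class Glycopeptide:
    """A peptide carrying one glycan composition at one sequon."""

    peptide: Peptide
    site: SequonSite
    composition: GlycanComposition
    mass: float
    #: number of sequons of the parent protein this peptide covers; entries
    #: with n_sites_covered > 1 are ambiguous for per-site quantification
    n_sites_covered: int = 1

    def __post_init__(self) -> None:
        if not self.peptide.covers(self.site.position):
            raise InputError(
                f"sequon position {self.site.position} outside peptide "
                f"{self.peptide.start}..{self.peptide.end}"
            )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def find_sequons(seq: ProteinSequence | str) -> list[SequonSite]:
    """Scan for N-X-(S|T) sequons with X != P; 1-based Asn positions, ascending."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if isinstance(seq, str):
        _validate_residues(residues)
    sites = []
    for i in range(len(residues) - 2):
        if (
            residues[i] == "N"
            and residues[i + 1] != "P"
            and residues[i + 2] in "ST"
        ):
            sites.append(SequonSite(position=i + 1, motif=residues[i : i + 3]))
    return sites


def cleavage_sites(
    residues: str, protease: str, chymotrypsin_residues: str = CHYMOTRYPSIN_RESIDUES
) -> list[int]:
    """0-based indices i such that the bond after residues[i] is cleaved.

    Trypsin cuts after K/R, chymotrypsin after the configured residue set
    (default F/W/Y/L); neither cuts before proline. The combined protease
    applies the union of both site sets.
    """
    if protease not in PROTEASES:
        raise InputError(f"unknown protease {protease!r}; choose from {PROTEASES}")
    targets = ""
    if "trypsin" in protease.split("+") or protease == "trypsin":
        targets += TRYPSIN_RESIDUES
    if "chymotrypsin" in protease:
        targets += chymotrypsin_residues
    sites = [
        i
        for i in range(len(residues) - 1)
        if residues[i] in targets and residues[i + 1] != "P"
    ]
    return sites


def digest(
    seq: ProteinSequence | str,
    protease: str = "trypsin",
    max_missed: int = 2,
    chymotrypsin_residues: str = CHYMOTRYPSIN_RESIDUES,
) -> list[Peptide]:
    """Exhaustive specific digestion with 0..max_missed missed cleavages.

    The 0-missed-cleavage peptides partition the sequence; higher tiers are
    every concatenation of up to ``max_missed + 1`` adjacent fragments.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if not residues:
        raise InputError("cannot digest an empty sequence")
    if isinstance(seq, str):
        _validate_residues(residues)
    if max_missed < 0:
        raise InputError("max_missed must be >= 0")
    cuts = cleavage_sites(residues, protease, chymotrypsin_residues)
    bounds = [0] + [c + 1 for c in cuts] + [len(residues)]
    peptides = []
    for missed in range(max_missed + 1):
        for j in range(len(bounds) - 1 - missed):
            a, b = bounds[j], bounds[j + 1 + missed]
            peptides.append(
                Peptide(
                    sequence=residues[a:b],
                    start=a + 1,
                    end=b,
                    protease=protease,
                    missed_cleavages=missed,
                )
            )
    return peptides


def peptide_mass(
    pep: Peptide | str, fixed_modifications: dict | None = None
) -> float:
    """Neutral monoisotopic peptide mass: residue sum + water + fixed mods."""
    sequence = pep.sequence if isinstance(pep, Peptide) else pep
    mods = DEFAULT_FIXED_MODS if fixed_modifications is None else fixed_modifications
    total = WATER
    for i, aa in enumerate(sequence, start=1):
        try:
            total += AA_RESIDUE_MASS[aa]
        except KeyError:
            raise InputError(f"unknown residue {aa!r} at position {i}") from None
        total += mods.get(aa, 0.0)
    return total


def glycan_mass(comp: GlycanComposition) -> float:
    """Neutral residue-mass sum of a glycan composition (0 for the zero glycan)."""
    return (
        comp.hexnac * HEXNAC
        + comp.hex * HEX
        + comp.fuc * FUC
        + comp.neuac * NEUAC
        + comp.neugc * NEUGC
    )


def glycopeptide_mass(
    pep: Peptide | str,
    comp: GlycanComposition,
    fixed_modifications: dict | None = None,
) -> float:
    """Neutral glycopeptide mass = peptide mass + glycan residue-mass sum.

    A non-zero glycan requires an N-X-S/T sequon within the peptide sequence.
    """
    sequence = pep.sequence if isinstance(pep, Peptide) else pep
    if not comp.is_zero and not find_sequons(sequence):
        raise InputError(
            f"peptide {sequence!r} carries no N-X-S/T sequon; cannot attach a glycan"
        )
    return peptide_mass(pep, fixed_modifications) + glycan_mass(comp)


# ---------------------------------------------------------------------------
# composition enumeration
# ---------------------------------------------------------------------------

#: Default per-monosaccharide (min, max) count bounds.
DEFAULT_BOUNDS = {
    "hexnac": (2, 8),
    "hex": (3, 12),
    "fuc": (0, 2),
    "neuac": (0, 4),
    "neugc": (0, 2),
}


def default_constraint(c: GlycanComposition) -> bool:
    """Biosynthetic plausibility filter for the default enumeration space.

    HexNAc = 2 compositions are restricted to the mannose series
    (Hex 5..9, no fucose or sialic acid). For complex/hybrid glycans
    (HexNAc >= 3) the sialic-acid total is capped at one per antenna
    (HexNAc - 2), and the hexose count at HexNAc + 1: the 3 core mannoses
    plus at most one galactose per antenna — each additional LacNAc unit
    brings its own HexNAc — with a floor of 6 to admit hybrid glycans that
    keep an unprocessed mannose arm.
    """
    if c.hexnac == 2:
        return c.fuc == 0 and c.neuac == 0 and c.neugc == 0 and 5 <= c.hex <= 9
    return (c.neuac + c.neugc) <= c.hexnac - 2 and c.hex <= max(c.hexnac + 1, 6)


def enumerate_compositions(
    bounds: dict | None = None,
    constraints: Iterable[Callable[[GlycanComposition], bool]] | None = None,
) -> list[GlycanComposition]:
    """Cartesian enumeration over count bounds, filtered by constraints.

    Deterministic lexicographic order by (hexnac, hex, fuc, neuac, neugc).
    Passing no constraints enumerates the raw bounded box.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    constraints = tuple(constraints or ())
    for name, (lo, hi) in bounds.items():
        if lo > hi:
            raise InputError(f"inconsistent bounds for {name}: {lo} > {hi}")
    out = []
    for hn in range(*_rng(bounds["hexnac"])):
        for hx in range(*_rng(bounds["hex"])):
            for fc in range(*_rng(bounds["fuc"])):
                for na in range(*_rng(bounds["neuac"])):
                    for ng in range(*_rng(bounds["neugc"])):
                        c = GlycanComposition(hn, hx, fc, na, ng)
                        if all(f(c) for f in constraints):
                            out.append(c)
    return out


def _rng(pair: tuple[int, int]) -> tuple[int, int]:
    return pair[0], pair[1] + 1


def default_compositions() -> list[GlycanComposition]:
    """The default glycoform search space: default bounds + default constraint."""
    return enumerate_compositions(DEFAULT_BOUNDS, [default_constraint])


# ---------------------------------------------------------------------------
# theoretical table
# ---------------------------------------------------------------------------

def build_glycopeptide_table(
    protein: ProteinSequence,
    proteases: Sequence[str] = ("trypsin",),
    max_missed: int = 2,
    compositions: Sequence[GlycanComposition] | None = None,
    include_unglycosylated: bool = True,
    chymotrypsin_residues: str = CHYMOTRYPSIN_RESIDUES,
) -> dict[str, list[Glycopeptide]]:
    """Theoretical glycopeptide search table, one entry list per protease.

    Every sequon-covering peptide is combined with every composition (plus
    the zero composition for the bare peptide when requested). The sequon
    check uses parent-protein coordinates: a protease may cut inside the
    N-X-S/T motif and the glycan still rides on the Asn-bearing peptide.
    """
    sites = find_sequons(protein)
    comps = list(default_compositions() if compositions is None else compositions)
    if include_unglycosylated:
        zero = GlycanComposition()
        if zero not in comps:
            comps = [zero] + comps
    table: dict[str, list[Glycopeptide]] = {}
    for protease in proteases:
        entries = []
        for pep in digest(protein, protease, max_missed, chymotrypsin_residues):
            covered = [s for s in sites if pep.covers(s.position)]
            for site in covered:
                for comp in comps:
                    entries.append(
                        Glycopeptide(
                            peptide=pep,
                            site=site,
                            composition=comp,
                            mass=peptide_mass(pep, protein.fixed_modifications)
                            + glycan_mass(comp),
                            n_sites_covered=len(covered),
                        )
                    )
        table[protease] = entries
    return table


def write_glycopeptide_table(
    table: dict[str, list[Glycopeptide]] | list[Glycopeptide], path: str | Path
) -> None:
    """Write a theoretical table as TSV (one row per glycopeptide entry)."""
    if isinstance(table, dict):
        rows = [(d, g) for d, entries in table.items() for g in entries]
    else:
        rows = [(g.peptide.protease, g) for g in table]
    df = pd.DataFrame(
        {
            "digest": [d for d, _ in rows],
            "peptide": [g.peptide.sequence for _, g in rows],
            "start": [g.peptide.start for _, g in rows],
            "end": [g.peptide.end for _, g in rows],
            "site": [g.site.position for _, g in rows],
            "hexnac": [g.composition.hexnac for _, g in rows],
            "hex": [g.composition.hex for _, g in rows],
            "fuc": [g.composition.fuc for _, g in rows],
            "neuac": [g.composition.neuac for _, g in rows],
            "neugc": [g.composition.neugc for _, g in rows],
            "mass": [round(g.mass, 6) for _, g in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path, fixed_modifications: dict | None = None
) -> list[ProteinSequence]:
    """Read single- or multi-record FASTA; the description line becomes the id."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        proteins.append(
            ProteinSequence(
                id=rec.description or rec.id,
                residues=str(rec.seq).upper(),
                fixed_modifications=dict(
                    DEFAULT_FIXED_MODS
                    if fixed_modifications is None
                    else fixed_modifications
                ),
            )
        )
    if not proteins:
        raise InputError(f"no FASTA records in {path}")
    return proteins


def write_fasta(proteins: Sequence[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.residues), 60):
                fh.write(p.residues[i : i + 60] + "\n")
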