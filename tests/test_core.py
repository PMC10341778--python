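"""Sequon scanning, digestion, mass arithmetic and composition enumeration."""

import pytest
from hypothesis import given, strategies as st

from glysite.core import (
    GlycanComposition,
    InputError,
    ProteinSequence,
    default_compositions,
    default_constraint,
    digest,
    enumerate_compositions,
    find_sequons,
    glycan_mass,
    glycopeptide_mass,
    peptide_mass,
    read_fasta,
    write_fasta,
)
from glysite.masses import CARBAMIDOMETHYL, WATER

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=3, max_size=80)


# ---------------------------------------------------------------------------
# sequons
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected",
    [
        ("NGS", [1]),
        ("NPS", []),
        ("NGSNGT", [1, 4]),
        ("AANGTAA", [3]),
        ("NNST", [1, 2]),  # overlapping sequons both count
        ("NGA", []),
    ],
)
def test_find_sequons_examples(seq, expected):
    assert [s.position for s in find_sequons(seq)] == expected


def test_find_sequons_rejects_noncanonical():
    with pytest.raises(InputError, match="position 2"):
        find_sequons("AXNGS")


@given(sequences)
def test_find_sequons_matches_window_scan(seq):
    brute = [
        i + 1
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    ]
    assert [s.position for s in find_sequons(seq)] == brute


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def test_trypsin_protects_proline():
    assert [p.sequence for p in digest("AKRPGK", "trypsin", 0)] == ["AK", "RPGK"]


def test_trypsin_missed_cleavage_tiers():
    peps = digest("AKRPGK", "trypsin", 1)
    assert {(p.sequence, p.missed_cleavages) for p in peps} == {
        ("AK", 0),
        ("RPGK", 0),
        ("AKRPGK", 1),
    }


def test_digest_without_sites_returns_whole_sequence():
    peps = digest("GGG", "trypsin", 0)
    assert [p.sequence for p in peps] == ["GGG"]
    assert (peps[0].start, peps[0].end) == (1, 3)


def test_chymotrypsin_rule_and_configurable_residues():
    assert [p.sequence for p in digest("AFGWPL", "chymotrypsin", 0)] == [
        "AF",
        "GWPL",
    ]
    # residue set without L: no cut after L
    assert [
        p.sequence
        for p in digest("ALGAF", "chymotrypsin", 0, chymotrypsin_residues="FWY")
    ] == ["ALGAF"]


def test_combined_digest_uses_union_of_sites():
    seq = "AKGFGR"
    tryp = {p.sequence for p in digest(seq, "trypsin", 0)}
    chym = {p.sequence for p in digest(seq, "chymotrypsin", 0)}
    both = [p.sequence for p in digest(seq, "trypsin+chymotrypsin", 0)]
    assert both == ["AK", "GF", "GR"]
    assert set(both) != tryp and set(both) != chym


def test_digest_empty_sequence_errors():
    with pytest.raises(InputError):
        digest("", "trypsin", 0)


@given(sequences, st.sampled_from(["trypsin", "chymotrypsin", "trypsin+chymotrypsin"]))
def test_zero_missed_peptides_concatenate_to_input(seq, protease):
    frags = [p.sequence for p in digest(seq, protease, 0)]
    assert "".join(frags) == seq


def test_digest_agrees_with_pyteomics_trypsin(random_sequences):
    """Cross-check tryptic fragments against an independent implementation."""
    from pyteomics import parser as pparser

    rule = r"[KR](?=[^P])"  # cleave after K/R except before proline
    for seq in random_sequences(50, seed=7):
        ours = {p.sequence for p in digest(seq, "trypsin", 2)}
        ref = set(pparser.cleave(seq, rule=rule, missed_cleavages=2))
        assert ours == ref


# ---------------------------------------------------------------------------
# masses
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected",
    [("G", 75.03203), ("GG", 132.05349), ("C", 178.04121)],
)
def test_peptide_mass_examples(seq, expected):
    assert peptide_mass(seq) == pytest.approx(expected, abs=1e-5)


def test_peptide_mass_without_fixed_mods():
    assert peptide_mass("C", fixed_modifications={}) == pytest.approx(
        178.04121 - CARBAMIDOMETHYL, abs=1e-5
    )


def test_peptide_mass_unknown_residue():
    with pytest.raises(InputError, match="position 3"):
        peptide_mass("GGZ")


@given(st.text(alphabet=AA, min_size=1, max_size=30),
       st.text(alphabet=AA, min_size=1, max_size=30))
def test_peptide_mass_additive_over_condensation(a, b):
    assert peptide_mass(a + b) == pytest.approx(
        peptide_mass(a) + peptide_mass(b) - WATER, abs=1e-6
    )


@pytest.mark.parametrize(
    "comp,expected",
    [
        (GlycanComposition(2, 3), 892.31722),
        (GlycanComposition(2, 5), 1216.42287),
        (GlycanComposition(), 0.0),
    ],
)
def test_glycan_mass_examples(comp, expected):
    assert glycan_mass(comp) == pytest.approx(expected, abs=1e-5)


def test_glycan_mass_oracle(random_compositions):
    """Residue-sum masses agree with atomic-composition summation."""
    from pyteomics import mass as pmass

    formulas = {
        "hexnac": "C8H13NO5",
        "hex": "C6H10O5",
        "fuc": "C6H10O4",
        "neuac": "C11H17NO8",
        "neugc": "C11H17NO9",
    }
    unit = {k: pmass.calculate_mass(formula=f) for k, f in formulas.items()}
    for comp in random_compositions(200, seed=3):
        oracle = sum(getattr(comp, k) * unit[k] for k in formulas)
        assert glycan_mass(comp) == pytest.approx(oracle, abs=1e-5)


def test_glycopeptide_mass_additivity():
    pep = "NGSGG"
    man5 = GlycanComposition(2, 5)
    assert glycopeptide_mass(pep, man5) == pytest.approx(
        peptide_mass(pep) + 1216.42287, abs=1e-5
    )
    # zero composition is the identity
    assert glycopeptide_mass(pep, GlycanComposition()) == peptide_mass(pep)
    # linearity: attaching a+b equals attaching a then adding b's residues
    a, b = GlycanComposition(2, 3), GlycanComposition(1, 1, 1, 1, 0)
    assert glycopeptide_mass(pep, a) + glycan_mass(b) == pytest.approx(
        glycopeptide_mass(pep, a + b), abs=1e-6
    )


def test_glycopeptide_requires_sequon_for_nonzero_glycan():
    with pytest.raises(InputError, match="sequon"):
        glycopeptide_mass("GGGG", GlycanComposition(2, 5))
    # bare peptide mass is fine without a sequon
    assert glycopeptide_mass("GGGG", GlycanComposition()) > 0


# ---------------------------------------------------------------------------
# composition enumeration
# ---------------------------------------------------------------------------

def test_enumerate_explicit_bounds_counts():
    bounds = {
        "hexnac": (2, 2), "hex": (3, 5), "fuc": (0, 0),
        "neuac": (0, 0), "neugc": (0, 0),
    }
    comps = enumerate_compositions(bounds)
    assert len(comps) == 3
    assert [c.hex for c in comps] == [3, 4, 5]


def test_enumerate_all_zero_bounds():
    bounds = {k: (0, 0) for k in ("hexnac", "hex", "fuc", "neuac", "neugc")}
    assert enumerate_compositions(bounds) == [GlycanComposition()]


def test_enumerate_inconsistent_bounds():
    bounds = {
        "hexnac": (3, 2), "hex": (3, 5), "fuc": (0, 0),
        "neuac": (0, 0), "neugc": (0, 0),
    }
    with pytest.raises(InputError):
        enumerate_compositions(bounds)


def test_default_space_satisfies_constraints_and_order():
    comps = default_compositions()
    assert comps == sorted(comps, key=lambda c: c.as_tuple())
    assert len(set(comps)) == len(comps)
    for c in comps:
        assert default_constraint(c)
        if c.hexnac == 2:
            assert c.fuc == c.neuac == c.neugc == 0 and 5 <= c.hex <= 9
        else:
            assert c.neuac + c.neugc <= c.hexnac - 2
            assert c.hex <= max(c.hexnac + 1, 6)


# ---------------------------------------------------------------------------
# FASTA and types
# ---------------------------------------------------------------------------

def test_fasta_round_trip(tmp_path, small_protein):
    path = tmp_path / "prot.fasta"
    write_fasta([small_protein], path)
    back = read_fasta(path)
    assert len(back) == 1
    assert back[0].residues == small_protein.residues
    assert back[0].id == small_protein.id


def test_read_fasta_missing_file(tmp_path):
    with pytest.raises(InputError, match="nope.fasta"):
        read_fasta(tmp_path / "nope.fasta")


def test_protein_sequence_validation():
    with pytest.raises(InputError):
        ProteinSequence(id="bad", residues="AGXK")
    with pytest.raises(InputError):
        ProteinSequence(id="bad", residues="AGK", fixed_modifications={"C": -1.0})
    with pytest.raises(InputError):
        GlycanComposition(hexnac=-1)
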