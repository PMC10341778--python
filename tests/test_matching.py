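"""Peak-list I/O, tolerance matching vs a brute-force oracle, and
quantification."""

import random

import numpy as np
import pytest

from glysite.classify import Category
from glysite.core import (
    GlycanComposition,
    Glycopeptide,
    InputError,
    Peptide,
    SequonSite,
    default_compositions,
    glycan_mass,
    peptide_mass,
)
from glysite.matching import (
    PPM_QUANTUM,
    MatchResult,
    PeakList,
    match_digests,
    match_peaks,
    ppm_error,
    quantify,
    read_peaklist,
    render_report,
    resolve_cross_digest,
    write_peaklist,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _gp(comp, peptide="AGNGTKR", site_pos=3):
    pep = Peptide(peptide, 1, len(peptide), "trypsin", 0)
    site = SequonSite(site_pos, peptide[site_pos - 1 : site_pos + 2])
    return Glycopeptide(pep, site, comp, peptide_mass(pep) + glycan_mass(comp))


def _random_table(r, n_peptides=4, n_comps=25):
    """Random glycopeptide table over a few sequon-bearing peptides."""
    space = default_compositions()
    table = []
    for _ in range(n_peptides):
        flank1 = "".join(r.choices("ADEGHQV", k=r.randint(1, 6)))
        flank2 = "".join(r.choices("ADEGHQV", k=r.randint(1, 6)))
        seq = flank1 + "NGT" + flank2 + "K"
        site_pos = len(flank1) + 1
        for comp in r.sample(space, n_comps):
            table.append(_gp(comp, peptide=seq, site_pos=site_pos))
    return table


# ---------------------------------------------------------------------------
# peak-list I/O
# ---------------------------------------------------------------------------

def test_read_peaklist_two_rows(tmp_path):
    p = tmp_path / "peaks.tsv"
    p.write_text("mass\tintensity\n1000.5\t10\n2000.25\t5\n")
    peaks = read_peaklist(p)
    assert len(peaks) == 2
    assert peaks.masses.tolist() == [1000.5, 2000.25]
    assert peaks.source == "peaks"


def test_read_peaklist_headerless_and_csv(tmp_path):
    p = tmp_path / "plain.csv"
    p.write_text("1000.5,10\n2000.25,5\n")
    assert len(read_peaklist(p)) == 2


def test_read_peaklist_reports_malformed_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("mass\tintensity\n1000.5\t10\noops\tnan?\n1500.0\t2\n")
    with pytest.raises(InputError, match=r"\[3\]"):
        read_peaklist(p)


def test_read_peaklist_missing_or_empty(tmp_path):
    with pytest.raises(InputError):
        read_peaklist(tmp_path / "absent.tsv")
    empty = tmp_path / "empty.tsv"
    empty.write_text("# only a comment\n")
    with pytest.raises(InputError, match="no parsable rows"):
        read_peaklist(empty)


def test_peaklist_write_read_round_trip(tmp_path):
    peaks = PeakList(
        np.array([1234.567891, 4321.123456]), np.array([1.5, 2.5]), source="x"
    )
    path = tmp_path / "rt.tsv"
    write_peaklist(peaks, path, comments=["round trip"])
    back = read_peaklist(path, source="x")
    assert np.allclose(back.masses, peaks.masses, atol=1e-6)
    assert np.allclose(back.intensities, peaks.intensities, atol=1e-6)


def test_peaklist_validation():
    with pytest.raises(InputError):
        PeakList(np.array([-1.0]), np.array([1.0]))
    with pytest.raises(InputError):
        PeakList(np.array([100.0]), np.array([-1.0]))


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_match_single_peak_within_tolerance():
    gp = _gp(GlycanComposition(2, 5), peptide="NGTK", site_pos=1)
    peaks = PeakList(np.array([gp.mass * (1 + 0.03e-6)]), np.array([7.0]))
    matches, unmatched = match_peaks(peaks, [gp], tol_ppm=10)
    assert len(matches) == 1 and not unmatched
    assert matches[0].ppm_error == pytest.approx(0.03, abs=0.01)
    assert matches[0].intensity == 7.0


def test_match_far_peak_unmatched():
    gp = _gp(GlycanComposition(2, 5), peptide="NGTK", site_pos=1)
    peaks = PeakList(np.array([gp.mass + 0.12]), np.array([7.0]))  # ~90 ppm
    matches, unmatched = match_peaks(peaks, [gp], tol_ppm=10)
    assert not matches and len(unmatched) == 1


def test_match_empty_inputs():
    gp = _gp(GlycanComposition(2, 5))
    empty = PeakList(np.array([]), np.array([]))
    assert match_peaks(empty, [gp], 10) == ([], [])
    peaks = PeakList(np.array([1000.0]), np.array([1.0]))
    matches, unmatched = match_peaks(peaks, [], 10)
    assert not matches and unmatched == [(1000.0, 1.0)]


def test_match_rejects_bad_tolerance():
    with pytest.raises(InputError):
        match_peaks(PeakList(np.array([1.0]), np.array([1.0])), [], 0)


def _brute_force(peaks, table, tol):
    """All-pairs reference matcher: same assignment rule, linear scan."""
    matches, unmatched = [], []
    for obs, inten in peaks.entries():
        cand = [
            (gp, ppm_error(obs, gp.mass))
            for gp in table
            if abs(ppm_error(obs, gp.mass)) <= tol
        ]
        if not cand:
            unmatched.append((obs, inten))
            continue
        gp, ppm = min(
            cand,
            key=lambda c: (
                round(abs(c[1]) / PPM_QUANTUM),
                c[0].composition.n_residue_types,
                c[0].mass,
            ),
        )
        matches.append((obs, gp.site.position, gp.composition, len(cand)))
    return matches, unmatched


def test_matcher_equals_brute_force_oracle():
    r = random.Random(11)
    for trial in range(30):
        table = _random_table(r)
        masses = []
        for _ in range(r.randint(5, 30)):
            if r.random() < 0.7:
                gp = r.choice(table)
                masses.append(gp.mass * (1 + r.gauss(0, 8e-6)))
            else:
                masses.append(r.uniform(800, 6000))
        peaks = PeakList(np.array(masses), np.ones(len(masses)))
        got_m, got_u = match_peaks(peaks, table, tol_ppm=10)
        exp_m, exp_u = _brute_force(peaks, table, 10)
        assert [(m.peak_mass, m.glycopeptide.site.position,
                 m.glycopeptide.composition, m.n_candidates) for m in got_m] == exp_m
        assert got_u == exp_u


def test_match_counts_and_monotonicity():
    r = random.Random(5)
    table = _random_table(r)
    masses = [gp.mass * (1 + r.gauss(0, 10e-6)) for gp in r.sample(table, 40)]
    masses += [r.uniform(800, 6000) for _ in range(10)]
    peaks = PeakList(np.array(masses), np.ones(len(masses)))
    previous = None
    for tol in (40, 20, 10, 5, 2, 1):
        matches, unmatched = match_peaks(peaks, table, tol)
        assert len(matches) + len(unmatched) == len(peaks)
        if previous is not None:
            assert len(matches) <= previous
        previous = len(matches)


# ---------------------------------------------------------------------------
# cross-digest corroboration
# ---------------------------------------------------------------------------

def test_resolve_is_identity_for_single_digest():
    r = random.Random(23)
    table = _random_table(r)
    masses = [gp.mass * (1 + r.gauss(0, 5e-6)) for gp in r.sample(table, 30)]
    peaks = PeakList(np.array(masses), np.ones(len(masses)), source="trypsin")
    matches, _ = match_peaks(peaks, table, tol_ppm=10)
    resolved = resolve_cross_digest(matches)
    assert [m.glycopeptide for m in resolved] == [m.glycopeptide for m in matches]


def test_match_digests_requires_matching_table():
    peaks = {"trypsin": PeakList(np.array([1000.0]), np.array([1.0]), "trypsin")}
    with pytest.raises(InputError):
        match_digests(peaks, {"chymotrypsin": []})


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def _match(gp, intensity, source="trypsin"):
    return MatchResult(gp.mass, intensity, gp, 0.0, source=source)


def test_quantify_single_site():
    ms = [
        _match(_gp(GlycanComposition(4, 5, 0, 1, 0)), 70),
        _match(_gp(GlycanComposition(4, 5)), 20),
        _match(_gp(GlycanComposition(4, 3)), 10),
    ]
    (prof,) = quantify(ms, combine="pooled")
    assert prof.proportion(Category.TERMINAL_SIA) == pytest.approx(0.7)
    assert prof.proportion(Category.TERMINAL_GAL) == pytest.approx(0.2)
    assert prof.proportion(Category.TERMINAL_GLCNAC) == pytest.approx(0.1)


def test_quantify_pooling_is_scale_invariant_across_digests():
    comp = GlycanComposition(4, 5, 0, 1, 0)
    one = [_match(_gp(comp), 70), _match(_gp(GlycanComposition(4, 5)), 30)]
    two = one + [
        _match(_gp(comp), 70, source="chymotrypsin"),
        _match(_gp(GlycanComposition(4, 5)), 30, source="chymotrypsin"),
    ]
    (p1,) = quantify(one, combine="pooled")
    (p2,) = quantify(two, combine="pooled")
    assert p1.proportions == pytest.approx(p2.proportions)
    per = quantify(two, combine="per_digest")
    assert len(per) == 2
    for p in per:
        assert p.proportions == pytest.approx(p1.proportions)


def test_quantify_excludes_unusable_matches():
    usable = _match(_gp(GlycanComposition(4, 5)), 10)
    multi = MatchResult(
        usable.glycopeptide.mass, 99,
        Glycopeptide(
            usable.glycopeptide.peptide, usable.glycopeptide.site,
            usable.glycopeptide.composition, usable.glycopeptide.mass,
            n_sites_covered=2,
        ),
        0.0,
    )
    amb = MatchResult(
        usable.glycopeptide.mass, 99, usable.glycopeptide, 0.0,
        site_ambiguous=True,
    )
    (prof,) = quantify([usable, multi, amb])
    assert prof.total_intensity == pytest.approx(10)


def test_quantify_rejects_unknown_mode():
    with pytest.raises(InputError):
        quantify([], combine="mean")


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def test_render_report_deterministic_and_complete(tmp_path):
    ms = [
        _match(_gp(GlycanComposition(4, 5, 1, 2, 0)), 70),
        _match(_gp(GlycanComposition(2, 5)), 30),
    ]
    profiles = quantify(ms)
    out1, out2 = tmp_path / "a", tmp_path / "b"
    paths1 = render_report(profiles, ms, [("trypsin", 999.9, 1.0)], out1)
    paths2 = render_report(profiles, ms, [("trypsin", 999.9, 1.0)], out2)
    for key in paths1:
        assert paths1[key].read_bytes() == paths2[key].read_bytes()
    glyco = paths1["glycoforms"].read_text().splitlines()
    assert len(glyco) == 3  # header + 2 matches
    assert "TerminalSia" in glyco[1] or "TerminalSia" in glyco[2]


def test_render_report_empty_run(tmp_path):
    paths = render_report([], [], [], tmp_path)
    # header-only glycoform table
    assert len(paths["glycoforms"].read_text().splitlines()) == 1
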