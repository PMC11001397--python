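"""Rotamer library loading, candidate assembly, matching and ranking."""

import numpy as np
import pytest

from altconf import (Peak, PeakSet, enumerate_candidates, load_rotamer_library,
                     match_rotamer, rank_and_dedupe)
from altconf.chi import CHI_TOPOLOGY, chi_definitions
from altconf.rotamers import (SYMMETRIC_CHI, RotamerCandidate,
                              _expected_chi_count)


def _peakset(chi, angles, intensities=None):
    intensities = intensities or [1.0] * len(angles)
    peaks = [Peak(angle=a, height=i, relative_intensity=i)
             for a, i in zip(angles, intensities)]
    return PeakSet(chain="A", seqid="2", residue_type="?", chi=chi, peaks=peaks)


def _candidate(residue_type, angles, intensities=None):
    intensities = intensities or tuple(1.0 for _ in angles)
    return RotamerCandidate(chain="A", seqid="2", residue_type=residue_type,
                            angles=tuple(angles),
                            relative_intensities=tuple(intensities))


def oracle_match(residue_type, angles, library, tolerance=30.0):
    """Independent reference: exhaustive scan of the library computing the
    max per-chi circular deviation per entry, filter <= tolerance, pick the
    highest frequency (name as deterministic tie-break)."""
    matches = []
    for entry in library.entries(residue_type):
        worst = 0.0
        for i, (a, m) in enumerate(zip(angles, entry.chi_means)):
            period = 180.0 if (residue_type, i + 1) in SYMMETRIC_CHI else 360.0
            d = abs(a - m) % period
            worst = max(worst, min(d, period - d))
        if worst <= tolerance:
            matches.append(entry)
    if not matches:
        return None
    return max(matches, key=lambda e: (e.frequency, e.name)).name


class TestLibrary:
    def test_all_chi_bearing_types_present(self, library):
        # every amino acid except Gly and Ala bears at least one chi;
        # Pro carries library entries even though the scanner skips its ring
        assert set(library.residue_types()) == set(CHI_TOPOLOGY) | {"PRO"}
        assert len(library.residue_types()) == 18

    def test_threonine_rotamer_names(self, library):
        names = {e.name for e in library.entries("THR")}
        assert names == {"p", "t", "m"}

    def test_chi_counts_match_topology(self, library):
        for rt in library.residue_types():
            n = _expected_chi_count(rt)
            for e in library.entries(rt):
                assert len(e.chi_means) == n
                assert 0 < e.frequency <= 1

    def test_duplicate_entry_rejected(self, tmp_path):
        p = tmp_path / "lib.csv"
        p.write_text("residue,rotamer,chi1,chi2,chi3,chi4,frequency\n"
                     "SER,p,62,,,,0.5\nSER,p,63,,,,0.4\n")
        with pytest.raises(ValueError, match="row 3.*duplicate"):
            load_rotamer_library(p)

    def test_chi_count_mismatch_rejected(self, tmp_path):
        p = tmp_path / "lib.csv"
        p.write_text("residue,rotamer,chi1,chi2,chi3,chi4,frequency\n"
                     "SER,p,62,170,,,0.5\n")
        with pytest.raises(ValueError, match="row 2"):
            load_rotamer_library(p)

    def test_bad_frequency_rejected(self, tmp_path):
        p = tmp_path / "lib.csv"
        p.write_text("residue,rotamer,chi1,chi2,chi3,chi4,frequency\n"
                     "SER,p,62,,,,1.7\n")
        with pytest.raises(ValueError, match="row 2"):
            load_rotamer_library(p)


class TestEnumerate:
    def test_cartesian_product_count(self):
        sets = [_peakset(1, [60, 180]), _peakset(2, [60, 180, 300])]
        assert len(enumerate_candidates("A", "2", "ILE", sets)) == 6

    def test_empty_chi_blocks_residue(self):
        sets = [_peakset(1, [60]), _peakset(2, [])]
        assert enumerate_candidates("A", "2", "ILE", sets) == []

    def test_single_peak_per_chi(self):
        sets = [_peakset(1, [60]), _peakset(2, [180])]
        cands = enumerate_candidates("A", "2", "ILE", sets)
        assert len(cands) == 1 and cands[0].angles == (60, 180)

    def test_signal_is_sum_of_relative_intensities(self):
        sets = [_peakset(1, [60, 300], [1.0, 0.5]),
                _peakset(2, [180], [1.0])]
        cands = enumerate_candidates("A", "2", "ILE", sets)
        assert sorted(c.signal for c in cands) == [1.5, 2.0]


class TestMatch:
    def test_exact_library_mean_matches_with_zero_deviation(self, library):
        p_mean = library.entry("THR", "p").chi_means
        c = match_rotamer(_candidate("THR", p_mean), library)
        assert c.matched.name == "p" and c.max_deviation == 0.0

    def test_just_outside_tolerance_rejected(self, library):
        # 31 degrees past the 'p' mean and > 30 from every other entry
        angle = (library.entry("THR", "p").chi_means[0] + 31.0) % 360
        c = match_rotamer(_candidate("THR", (angle,)), library, tolerance=30)
        assert c.matched is None

    def test_boundary_inclusive(self, library):
        angle = (library.entry("THR", "p").chi_means[0] + 30.0) % 360
        c = match_rotamer(_candidate("THR", (angle,)), library, tolerance=30)
        assert c.matched is not None

    def test_multiple_matches_highest_frequency_wins(self, library):
        # ASN (-176, 5) is within 30 degrees of both t-20 and t30;
        # t30 has the larger survey frequency
        c = match_rotamer(_candidate("ASN", (184.0, 5.0)), library)
        assert c.matched.name == oracle_match("ASN", (184.0, 5.0), library)
        assert c.matched.name == "t30"

    def test_symmetric_terminal_chi_mod_180(self, library):
        # Phe chi2 ~ t80 mean + 180 is the same ring orientation
        t80 = library.entry("PHE", "t80").chi_means
        flipped = (t80[0], (t80[1] + 180.0) % 360)
        assert match_rotamer(_candidate("PHE", flipped), library).matched.name == "t80"
        assert match_rotamer(_candidate("PHE", flipped), library,
                             symmetry=False).matched is None

    def test_unknown_residue_type_errors(self, library):
        with pytest.raises(KeyError):
            match_rotamer(_candidate("XXX", (0.0,)), library)

    def test_oracle_equivalence_random_angles(self, library):
        rng = np.random.default_rng(5)
        for rt in library.residue_types():
            n = _expected_chi_count(rt)
            for _ in range(100):
                angles = tuple(rng.uniform(0, 360, size=n))
                got = match_rotamer(_candidate(rt, angles), library).matched
                assert (got.name if got else None) == oracle_match(rt, angles,
                                                                   library)

    def test_tolerance_monotonicity(self, library):
        rng = np.random.default_rng(6)
        for rt in ("SER", "LEU", "LYS"):
            n = len(chi_definitions(rt))
            for _ in range(50):
                angles = tuple(rng.uniform(0, 360, size=n))
                lo = match_rotamer(_candidate(rt, angles), library,
                                   tolerance=15).matched
                hi = match_rotamer(_candidate(rt, angles), library,
                                   tolerance=40).matched
                if lo is not None:
                    assert hi is not None


class TestRankAndDedupe:
    def _matched(self, library, rt, name, signal):
        entry = library.entry(rt, name)
        n = len(entry.chi_means)
        c = RotamerCandidate(chain="A", seqid="2", residue_type=rt,
                             angles=entry.chi_means,
                             relative_intensities=(signal / n,) * n,
                             matched=entry)
        return c

    def test_same_name_keeps_highest_signal(self, library):
        a = self._matched(library, "ILE", "mt", 1.8)
        b = self._matched(library, "ILE", "mt", 1.2)
        out = rank_and_dedupe([b, a])
        assert len(out) == 1 and out[0].signal == pytest.approx(1.8)

    def test_descending_signal_order(self, library):
        cands = [self._matched(library, "SER", n, s)
                 for n, s in (("p", 0.9), ("m", 1.9), ("t", 1.5))]
        out = rank_and_dedupe(cands)
        assert [c.matched.name for c in out] == ["m", "t", "p"]

    def test_equal_signal_frequency_tiebreak(self, library):
        # SER m (freq 0.29) beats SER t (freq 0.22) at equal signal
        out = rank_and_dedupe([self._matched(library, "SER", "t", 1.0),
                               self._matched(library, "SER", "m", 1.0)])
        assert [c.matched.name for c in out] == ["m", "t"]

    def test_never_two_same_names_and_length_bounded(self, library):
        rng = np.random.default_rng(8)
        names = [e.name for e in library.entries("LEU")]
        cands = [self._matched(library, "LEU", rng.choice(names),
                               float(rng.uniform(0.1, 2)))
                 for _ in range(30)]
        out = rank_and_dedupe(cands)
        out_names = [c.matched.name for c in out]
        assert len(out_names) == len(set(out_names))
        assert len(out) <= len(cands)
        assert all(a.signal >= b.signal for a, b in zip(out, out[1:]))
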