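"""Peak-list matching, binomial-tail scoring and the no-enzyme search."""

import math

import pytest

from sepiapep import synthetic as syn
from sepiapep.chem import enumerate_variants, fragment_ions, mh_plus
from sepiapep.prohormone import MaturePeptide
from sepiapep.spectra import (
    SearchConfig,
    Spectrum,
    detection_table,
    match_fragments,
    match_precursor,
    read_mgf,
    read_peak_list,
    score_psm,
    search,
    write_mgf,
)


class TestMatchPrecursor:
    def test_small_positive_error_matches(self):
        # observed vs theoretical [M+H]+ of the dipeptide GA
        ppm = match_precursor(147.0770, 147.07641, tol_ppm=200)
        assert ppm == pytest.approx(4.0, abs=0.05)

    def test_exact_match_is_zero_ppm(self):
        assert match_precursor(147.07641, 147.07641) == 0.0

    def test_outside_tolerance_is_absent(self):
        # 147.11 sits ~228 ppm above: no match at 200 ppm
        assert match_precursor(147.11, 147.07641, tol_ppm=200) is None

    def test_symmetric_tolerance(self):
        theo = 1000.0
        for eps in (-200e-6, -50e-6, 0.0, 50e-6, 200e-6):
            assert match_precursor(theo * (1 + eps), theo, tol_ppm=200) is not None
        for eps in (-201e-6, 201e-6):
            assert match_precursor(theo * (1 + eps), theo, tol_ppm=200) is None

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_precursor(100.0, 100.0, tol_ppm=0)


class TestMatchFragments:
    def _spectrum(self, mzs, tissue="t", level=2):
        return Spectrum("s", tissue, level, [(mz, 1.0) for mz in mzs])

    def test_complete_series_fully_matched(self):
        ions = fragment_ions("GAESGE", series_set=("b", "y"))
        spec = self._spectrum([i.mz for i in ions])
        assert len(match_fragments(spec, ions)) == len(ions)

    def test_empty_spectrum_no_matches(self):
        ions = fragment_ions("GAESGE")
        assert match_fragments(self._spectrum([]), ions) == []

    def test_each_peak_used_once(self):
        # one peak within tolerance of two ions: only one assignment
        ions = fragment_ions("GG", series_set=("b", "y"))  # b1 58.03, y1 76.04
        spec = self._spectrum([58.2])
        matches = match_fragments(spec, ions, tol_da=0.6)
        assert len(matches) == 1
        assert matches[0][0].label == "b1+"  # nearest ion wins

    def test_retained_half_matches_half(self):
        ions = fragment_ions("GAESGEAHV", series_set=("b", "y"))
        kept = [i.mz for k, i in enumerate(ions) if k % 2 == 0]
        matches = match_fragments(self._spectrum(kept), ions, tol_da=0.01)
        assert len(matches) == len(kept)


class TestScore:
    def test_zero_matches_scores_zero(self):
        assert score_psm(0, 10, 100, 3300.0, 0.6) == 0.0

    def test_monotone_in_matches(self):
        low = score_psm(5, 10, 50, 3300.0, 0.6)
        high = score_psm(10, 10, 50, 3300.0, 0.6)
        assert high > low > 0

    def test_equals_exact_binomial_enumeration(self):
        # p = 10 peaks * 2 * 0.6 / 1200 = 0.01
        n, k, p = 10, 5, 0.01
        tail = sum(
            math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
        )
        assert score_psm(k, n, 10, 1200.0, 0.6) == pytest.approx(-math.log10(tail), rel=1e-9)

    def test_intensity_scaling_irrelevant(self):
        ions = fragment_ions("GAESGEAHV")
        spec1 = Spectrum("s", "t", 2, [(i.mz, 1.0) for i in ions])
        spec2 = Spectrum("s", "t", 2, [(i.mz, 1e6) for i in ions])
        assert len(match_fragments(spec1, ions)) == len(match_fragments(spec2, ions))


def _library(sequences):
    peptides = [
        MaturePeptide(sequence=s, name=f"SYN {i+1}") for i, s in enumerate(sequences)
    ]
    return [v for p in peptides for v in enumerate_variants(p)]


def _ms2(seq, tissue, sid="s1", extra=()):
    ions = fragment_ions(seq)
    peaks = [(i.mz, 100.0) for i in ions] + [(mz, 5.0) for mz in extra]
    return Spectrum(sid, tissue, 2, peaks, precursor_mz=mh_plus(seq))


class TestSearch:
    def test_empty_library_warns_and_returns_empty(self, caplog):
        spec = _ms2("GAESGEAHVFDSLGGG", "MNG")
        with caplog.at_level("WARNING"):
            assert search([spec], []) == []
        assert any("empty" in r.message for r in caplog.records)

    def test_perfect_spectrum_identified(self):
        lib = _library(["GAESGEAHVFDSLGGG", "FDSLGGGSFLGW"])
        psms = search([_ms2("GAESGEAHVFDSLGGG", "MNG")], lib)
        assert len(psms) == 1
        psm = psms[0]
        assert psm.variant.variant_sequence == "GAESGEAHVFDSLGGG"
        assert psm.tissue == "MNG"
        assert psm.ppm_error_precursor == pytest.approx(0.0, abs=1e-9)
        assert psm.n_matched == psm.n_theoretical

    def test_duplicate_spectra_identical_psms(self):
        lib = _library(["GAESGEAHVFDSLGGG"])
        specs = [_ms2("GAESGEAHVFDSLGGG", "MNG", sid=f"s{i}") for i in range(2)]
        a, b = search(specs, lib)
        assert (a.variant, a.n_matched, a.score) == (b.variant, b.n_matched, b.score)

    def test_survey_spectrum_matched_by_precursor_only(self):
        lib = _library(["GAESGEAHVFDSLGGG"])
        mh = mh_plus("GAESGEAHVFDSLGGG")
        spec = Spectrum("ms1", "OL", 1, [(mh, 500.0)])
        cfg = SearchConfig(score_threshold=0.0)
        psms = search([spec], lib, cfg)
        assert len(psms) == 1 and psms[0].n_theoretical == 0

    def test_detection_table_round_trip(self):
        lib = _library(["GAESGEAHVFDSLGGG", "FDSLGGGSFLGW"])
        specs = [
            _ms2("GAESGEAHVFDSLGGG", "MNG", "s1"),
            _ms2("FDSLGGGSFLGW", "OL", "s2"),
        ]
        table = detection_table(search(specs, lib), peptide_names=["SYN 1", "SYN 2"])
        assert bool(table.loc["SYN 1", "MNG"]) and bool(table.loc["SYN 2", "OL"])
        assert not table.loc["SYN 1", "OL"] and not table.loc["SYN 2", "MNG"]

    def test_empty_psms_all_false_table(self):
        table = detection_table([], peptide_names=["SYN 1"], tissues=["MNG"])
        assert table.shape == (1, 1) and not table.values.any()


class TestIO:
    def test_mgf_roundtrip(self, tmp_path):
        spec = _ms2("GAESGEAHVFDSLGGG", "MNG", "spec_1")
        path = tmp_path / "test.mgf"
        write_mgf([spec], path)
        back = read_mgf(path)
        assert len(back) == 1
        b = back[0]
        assert b.tissue == "MNG" and b.level == 2 and b.id == "spec_1"
        assert b.precursor_mz == pytest.approx(spec.precursor_mz, abs=1e-6)
        assert [m for m, _ in b.peaks] == pytest.approx([m for m, _ in spec.peaks])

    def test_two_column_peak_list(self, tmp_path):
        path = tmp_path / "peaks.txt"
        path.write_text("# comment\n700.5 120\n800.25 3\n")
        spec = read_peak_list(path, id="p", tissue="OvG")
        assert spec.peaks == [(700.5, 120.0), (800.25, 3.0)]
        assert spec.tissue == "OvG" and spec.level == 1

    def test_spectrum_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            Spectrum("s", "t", 2, [(700.0, -1.0)])

    def test_spectrum_rejects_bad_level(self):
        with pytest.raises(ValueError):
            Spectrum("s", "t", 3, [])
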