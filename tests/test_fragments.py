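"""Peptide construction, theoretical ions, assignment and coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phosbridge as pb
from phosbridge import reference as ref
from phosbridge.constants import H, H3PO4, NH2, NH3, PROTON
from phosbridge.fragments import (
    PeptideError,
    neutral_fragment_mass,
)


class TestBuildPeptide:
    def test_glycine_mass(self):
        # independent sum of atomic masses: C2H3NO + H2O = 75.032028
        assert pb.build_peptide("G").mass == pytest.approx(75.032028, abs=1e-6)

    def test_study_phosphopeptide(self):
        pep = pb.build_peptide("APLpSFRGSLPKSYVK")
        assert pep.length == 15
        assert pep.phosphosites == (4,)
        assert pep.sequence == "APLSFRGSLPKSYVK"

    def test_phospho_delta(self):
        assert pb.build_peptide("pSA").mass - pb.build_peptide("SA").mass == (
            pytest.approx(79.966331, abs=1e-6)
        )

    def test_acetyl_prefix(self):
        pep = pb.build_peptide("Ac-APLK")
        assert pep.mods[0] == "acetyl"
        assert pep.mass - pb.build_peptide("APLK").mass == pytest.approx(
            42.010565, abs=1e-6
        )

    def test_mass_equals_residue_sum(self, r6ps4):
        from phosbridge.constants import H2O, PHOSPHO
        from phosbridge.fragments import RESIDUE_MASS

        expected = sum(RESIDUE_MASS[a] for a in r6ps4.sequence) + H2O + PHOSPHO
        assert r6ps4.mass == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("bad", ["AXZ", "pGA", "A1B", ""])
    def test_rejects_malformed(self, bad):
        with pytest.raises(PeptideError):
            pb.build_peptide(bad)


class TestTheoreticalIons:
    def test_c1_of_alanine(self):
        pep = pb.build_peptide("AG")
        ion = pb.ion_by_label(pep, "c1")
        # 71.037114 (Ala) + 17.026549 (NH3) + 1.007276 (proton)
        assert ion.mz == pytest.approx(89.070939, abs=1e-6)

    def test_complementary_pair_sum_constant(self, r6ps4):
        # c_i + z•_{N-i} neutrals = M + NH3 - NH2 = M + 1.007825 for all i
        sums = [
            neutral_fragment_mass(r6ps4, "c", i)
            + neutral_fragment_mass(r6ps4, "z_rad", i)
            for i in range(1, r6ps4.length)
        ]
        expected = r6ps4.mass + NH3 - NH2
        assert np.allclose(sums, expected, atol=1e-6)
        assert expected - r6ps4.mass == pytest.approx(H, abs=1e-6)

    def test_z_prime_offset(self, r6ps4):
        for z in (1, 2):
            ions = pb.theoretical_ions(r6ps4, ("z_rad", "z_prime"), (z,))
            by = {(i.ion_type, i.site): i.mz for i in ions}
            for s in range(1, r6ps4.length):
                diff = by[("z_prime", s)] - by[("z_rad", s)]
                assert diff == pytest.approx(H / z, abs=1e-9)

    def test_every_combination_emitted_once(self, r6ps4):
        from phosbridge.fragments import ION_TYPES

        ions = pb.theoretical_ions(r6ps4, ION_TYPES, (1, 2), (0.0,))
        keys = [(i.ion_type, i.site, i.charge, round(i.neutral_loss, 3)) for i in ions]
        assert len(keys) == len(set(keys))
        site_types = 7  # a b c c_rad y z_rad z_prime
        # precursor-derived species are emitted at charge 1 only
        assert len(ions) == site_types * (r6ps4.length - 1) * 2 + 2

    def test_negative_mz_loss_combinations_dropped(self, r6ps4, full_ion_set):
        # c1 - H3PO4 would have negative mass; it must not be emitted
        labels = {i.label for i in full_ion_set(r6ps4)}
        assert "c1-H3PO4" not in labels
        assert "c2-H3PO4" in labels

    def test_charge_reduced_species_mass(self, r6ps4):
        ion = pb.ion_by_label(r6ps4, "M+2H_red")
        assert ion.mz == pytest.approx(r6ps4.mass + 2 * PROTON, abs=1e-9)

    def test_unknown_type_and_bad_charge(self, r6ps4):
        with pytest.raises(ValueError):
            pb.theoretical_ions(r6ps4, ("w",))
        with pytest.raises(ValueError):
            pb.theoretical_ions(r6ps4, ("c",), (0,))


class TestAssignment:
    def test_empty_peaklist(self, r6ps4, full_ion_set):
        peaks = pb.PeakList(np.array([]), np.array([]))
        assert pb.assign_peaks(peaks, full_ion_set(r6ps4)) == []

    def test_exact_peak_zero_ppm(self, r6ps4, full_ion_set):
        ion = pb.ion_by_label(r6ps4, "c12")
        peaks = pb.PeakList(np.array([ion.mz]), np.array([10.0]))
        (a,) = pb.assign_peaks(peaks, full_ion_set(r6ps4))
        assert a.ppm_error == 0.0
        assert a.ion.ion_type == "c" and a.ion.site == 12

    def test_planted_ions_recovered_among_decoys(self, r6ps4, full_ion_set):
        labels = ["c11", "c12", "c13", "c14", "z10", "z11", "z12", "z13",
                  "c11_rad", "z11_rad", "M+H", "M+2H_red"]
        shares = {lab: 100.0 / 12 for lab in labels}
        peaks = pb.gen_peaklist(r6ps4, shares, n_decoys=50, seed=9)
        asn = pb.assign_peaks(peaks, full_ion_set(r6ps4), tol_ppm=3.0)
        assert len(asn) == 12

    def test_relative_abundance_sums_to_100(self, r6ps4, full_ion_set):
        peaks = pb.gen_peaklist(
            r6ps4, ref.TABLE2_ABUNDANCE["R6pS4"], n_decoys=20, seed=2
        )
        asn = pb.relative_abundance(
            pb.assign_peaks(peaks, full_ion_set(r6ps4), tol_ppm=3.0)
        )
        assert sum(a.relative_abundance for a in asn) == pytest.approx(100.0, abs=1e-9)

    @given(st.lists(st.floats(0.01, 1e6), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=50)
    def test_relative_abundance_proportions(self, intensities):
        pep = pb.build_peptide("APLpSFRGSLPKSYVK")
        ion = pb.ion_by_label(pep, "c12")
        asn = [
            pb.FragmentAssignment(ion, ion.mz, i, 0.0) for i in intensities
        ]
        out = pb.relative_abundance(asn)
        total = sum(intensities)
        for a, i in zip(out, intensities):
            assert a.relative_abundance == pytest.approx(100 * i / total, rel=1e-12)

    def test_two_assignments_25_75(self, r6ps4):
        ion = pb.ion_by_label(r6ps4, "c12")
        asn = [
            pb.FragmentAssignment(ion, ion.mz, 1.0, 0.0),
            pb.FragmentAssignment(ion, ion.mz, 3.0, 0.0),
        ]
        out = pb.relative_abundance(asn)
        assert [a.relative_abundance for a in out] == [25.0, 75.0]

    def test_all_zero_intensities_rejected(self, r6ps4):
        ion = pb.ion_by_label(r6ps4, "c12")
        with pytest.raises(ValueError):
            pb.relative_abundance([pb.FragmentAssignment(ion, ion.mz, 0.0, 0.0)])


class TestCoverage:
    def test_no_assignments_one_full_gap(self, r6ps4):
        cov = pb.coverage_map([], r6ps4)
        assert cov.site_cover.sum() == 0
        assert cov.gaps == [(1, 14)]

    def test_full_c_ladder_no_gaps(self):
        pep = pb.build_peptide("PEPTI")
        asn = []
        for i in range(1, 5):
            ion = pb.ion_by_label(pep, f"c{i}")
            asn.append(pb.FragmentAssignment(ion, ion.mz, 1.0, 0.0))
        cov = pb.coverage_map(asn, pep)
        assert list(cov.site_cover) == [1, 1, 1, 1]
        assert cov.gaps == []

    def test_counts_invariant_to_order(self, table2_coverage):
        pep, asn, cov = table2_coverage("R6unmod")
        cov2 = pb.coverage_map(list(reversed(asn)), pep)
        assert (cov.site_cover == cov2.site_cover).all()

    def test_coverage_total_counts_site_fragments(self, table2_coverage):
        pep, asn, cov = table2_coverage("L6pS12")
        n_site_bearing = sum(1 for a in asn if a.ion.site is not None)
        assert cov.site_cover.sum() == n_site_bearing

    def test_r6ps4_table_reproduces_stated_gap(self, table2_coverage):
        # no fragments between the phosphoserine and Lys11: sites 4..10 empty
        _, _, cov = table2_coverage("R6pS4")
        assert all(cov.count_at(s) == 0 for s in range(4, 11))

    def test_r6ps12_table_reproduces_stated_gap(self, table2_coverage):
        # no fragments between Arg6 and the phosphoserine: sites 6..11 empty
        _, _, cov = table2_coverage("R6pS12")
        assert all(cov.count_at(s) == 0 for s in range(6, 12))


class TestGapBetween:
    def test_candidate_sites(self, table2_coverage):
        _, _, cov = table2_coverage("R6pS4")
        rep = pb.gap_between(cov, 4, 11)
        assert rep.sites == tuple(range(4, 11))

    def test_full_coverage_counts(self):
        pep = pb.build_peptide("PEPTI")
        asn = []
        for i in range(1, 5):
            ion = pb.ion_by_label(pep, f"c{i}")
            asn.append(pb.FragmentAssignment(ion, ion.mz, 1.0, 0.0))
        cov = pb.coverage_map(asn, pep)
        rep = pb.gap_between(cov, 1, 5)
        assert rep.n_fragments == 4
        assert rep.uncovered_sites == ()

    def test_out_of_range_pairs(self, table2_coverage):
        _, _, cov = table2_coverage("R6pS4")
        for a, b in [(0, 3), (5, 5), (3, 16), (11, 4)]:
            with pytest.raises(IndexError):
                pb.gap_between(cov, a, b)
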