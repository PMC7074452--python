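"""Annotation engine: candidate matching, regiochemistry, class rules, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemoclock.chem import (
    ADDUCTS,
    AcylChain,
    LipidSpecies,
    PROTON_ADDUCT,
    SODIUM_ADDUCT,
    acyl_loss_fragment_mz,
    ion_mz,
    species_formula,
)
from chemoclock.annotate import (
    LineagePrior,
    Ms2Spectrum,
    annotate,
    annotations_to_tsv,
    assign_regiochemistry,
    classify_betaine,
    classify_xanthophyll,
    decompose_acyls,
    match_candidates,
    read_mgf,
    read_peaklist_csv,
    write_mgf,
)
from chemoclock.simulate import generate_ms2_fixture

PRIOR = LineagePrior({"green_strain": "green", "brown_strain": "brown"})


def spectrum_for(peaks, precursor, **kw):
    return Ms2Spectrum(precursor_mz=precursor, peaks=np.array(peaks), **kw)


class TestMatchCandidates:
    def test_exhaustive_over_chain_space(self, config):
        """Engine output equals a brute-force enumeration of every chain pair."""
        tpl = config.templates["MGDG"]
        target = LipidSpecies(tpl, AcylChain(18, 3), AcylChain(16, 4))
        precursor = ion_mz(species_formula(target), SODIUM_ADDUCT)
        got = {
            (s.template.name, str(s.sn1), str(s.sn2), a.name)
            for s, a in match_candidates(precursor, [SODIUM_ADDUCT], 3.0, config)
            if isinstance(s, LipidSpecies) and s.template.name == "MGDG"
        }
        # independent oracle: enumerate ordered chain pairs directly
        cmin, cmax = config.chain_carbons
        dmax = config.chain_double_bonds[1]
        expect = set()
        for c1 in range(cmin, cmax + 1):
            for d1 in range(0, min(dmax, c1 // 2) + 1):
                for c2 in range(c1, cmax + 1):
                    for d2 in range(0, min(dmax, c2 // 2) + 1):
                        if c1 == c2 and d2 < d1:
                            continue
                        sp = LipidSpecies(tpl, AcylChain(c1, d1), AcylChain(c2, d2))
                        mz = ion_mz(species_formula(sp), SODIUM_ADDUCT)
                        if abs(mz - precursor) <= 3e-6 * precursor:
                            expect.add((("MGDG"), str(sp.sn1), str(sp.sn2), "[M+Na]+"))
        assert got == expect
        # all isomeric splits of the 34:7 composition are present
        assert ("MGDG", "16:4", "18:3", "[M+Na]+") in got

    def test_below_template_mass_is_empty(self, config):
        assert match_candidates(100.0, [PROTON_ADDUCT], 3.0, config) == []

    def test_tolerance_monotonicity(self, config, rng):
        for _ in range(10):
            mz = float(rng.uniform(400, 900))
            small = match_candidates(mz, [PROTON_ADDUCT, SODIUM_ADDUCT], 1.0, config)
            large = match_candidates(mz, [PROTON_ADDUCT, SODIUM_ADDUCT], 8.0, config)
            key = lambda c: (str(c[0]), c[1].name)
            assert {key(c) for c in small} <= {key(c) for c in large}

    def test_empty_adduct_set_rejected(self, config):
        with pytest.raises(ValueError, match="adduct"):
            match_candidates(500.0, [], 3.0, config)


class TestDecomposeAcyls:
    def test_matches_enumeration_oracle(self, config):
        tpl = config.templates["MGDG"]
        got = {
            (str(a), str(b))
            for a, b in decompose_acyls(tpl, 32, 0, chain_carbons=(14, 24))
        }
        assert ("16:0", "16:0") in got and ("14:0", "18:0") in got
        # brute-force ordered enumeration, halved
        ordered = [
            (c1, c2)
            for c1 in range(14, 25)
            for c2 in range(14, 25)
            if c1 + c2 == 32
        ]
        diag = sum(1 for c1, c2 in ordered if c1 == c2)
        assert len(got) == (len(ordered) + diag) // 2

    def test_boundary_single_pair(self, config):
        tpl = config.templates["MGDG"]
        pairs = decompose_acyls(tpl, 28, 0, chain_carbons=(14, 24))
        assert [(str(a), str(b)) for a, b in pairs] == [("14:0", "14:0")]


class TestRegiochemistry:
    def _mgdg_spectrum(self, species, i1, i2, extra=()):
        f1 = acyl_loss_fragment_mz(species, SODIUM_ADDUCT, 1)
        f2 = acyl_loss_fragment_mz(species, SODIUM_ADDUCT, 2)
        precursor = ion_mz(species_formula(species), SODIUM_ADDUCT)
        return spectrum_for([(f1, i1), (f2, i2), *extra], precursor)

    def test_galactolipid_sn1_loss_dominates(self, config):
        sp = LipidSpecies(config.templates["MGDG"], AcylChain(18, 3), AcylChain(16, 4))
        res = assign_regiochemistry(
            self._mgdg_spectrum(sp, 100, 40), sp, SODIUM_ADDUCT, config
        )
        assert res.status == "assigned"
        assert (str(res.sn1), str(res.sn2)) == ("18:3", "16:4")

    def test_equal_intensities_ambiguous(self, config):
        sp = LipidSpecies(config.templates["MGDG"], AcylChain(18, 3), AcylChain(16, 4))
        res = assign_regiochemistry(
            self._mgdg_spectrum(sp, 70, 70), sp, SODIUM_ADDUCT, config
        )
        assert res.status == "ambiguous"

    def test_betaine_sn2_loss_dominates(self, config):
        sp = LipidSpecies(config.templates["DGTS"], AcylChain(16, 0), AcylChain(18, 1))
        f_a = acyl_loss_fragment_mz(sp, SODIUM_ADDUCT, 1)  # loss of 16:0
        f_b = acyl_loss_fragment_mz(sp, SODIUM_ADDUCT, 2)  # loss of 18:1
        precursor = ion_mz(species_formula(sp), SODIUM_ADDUCT)
        res = assign_regiochemistry(
            spectrum_for([(f_a, 30), (f_b, 90)], precursor), sp, SODIUM_ADDUCT, config
        )
        # the more intense loss (18:1) marks sn-2 under the betaine rule
        assert res.status == "assigned"
        assert (str(res.sn1), str(res.sn2)) == ("16:0", "18:1")

    def test_missing_rule_is_ambiguous_not_error(self, config):
        sp = LipidSpecies(config.templates["MGDG"], AcylChain(18, 3), AcylChain(16, 4))
        res = assign_regiochemistry(
            self._mgdg_spectrum(sp, 100, 40), sp, PROTON_ADDUCT, config
        )
        assert res.status == "ambiguous" and "rule" in res.reason

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e6))
    def test_invariant_under_intensity_scaling(self, config, scale):
        sp = LipidSpecies(config.templates["MGDG"], AcylChain(18, 3), AcylChain(16, 4))
        base = assign_regiochemistry(
            self._mgdg_spectrum(sp, 100, 40), sp, SODIUM_ADDUCT, config
        )
        scaled = assign_regiochemistry(
            self._mgdg_spectrum(sp, 100 * scale, 40 * scale), sp, SODIUM_ADDUCT, config
        )
        assert (base.status, str(base.sn1)) == (scaled.status, str(scaled.sn1))


class TestBetaineClassification:
    def _betaine_spectrum(self, config, with_loss=True):
        sp = LipidSpecies(config.templates["DGTS"], AcylChain(16, 0), AcylChain(18, 1))
        precursor = ion_mz(species_formula(sp), SODIUM_ADDUCT)
        peaks = [(precursor - 59.0735, 60)] if with_loss else [(precursor - 10, 60)]
        return sp, spectrum_for(peaks, precursor)

    def test_green_lineage_gives_dgts(self, config):
        sp, s = self._betaine_spectrum(config)
        cls, used, _ = classify_betaine(s, sp, SODIUM_ADDUCT, "green_strain", PRIOR, config)
        assert cls == "DGTS" and used

    def test_brown_lineage_gives_dgta(self, config):
        sp, s = self._betaine_spectrum(config)
        cls, used, _ = classify_betaine(s, sp, SODIUM_ADDUCT, "brown_strain", PRIOR, config)
        assert cls == "DGTA" and used

    def test_missing_59_loss_undetermined(self, config):
        sp, s = self._betaine_spectrum(config, with_loss=False)
        cls, used, _ = classify_betaine(s, sp, SODIUM_ADDUCT, "green_strain", PRIOR, config)
        assert cls == "undetermined" and not used

    def test_missing_lineage_label_undetermined(self, config):
        sp, s = self._betaine_spectrum(config)
        cls, _, _ = classify_betaine(s, sp, SODIUM_ADDUCT, "mystery", PRIOR, config)
        assert cls == "undetermined"

    def test_green_strain_never_yields_dgta(self, config, rng):
        """Lineage-restricted betaine assignment, over random betaine spectra."""
        for seed in range(20):
            c1 = int(rng.integers(14, 23))
            sp = LipidSpecies(
                config.templates["DGTS"],
                AcylChain(c1, int(rng.integers(0, 4))),
                AcylChain(int(rng.integers(14, 23)), int(rng.integers(0, 4))),
            )
            s = generate_ms2_fixture(sp, seed=seed, config=config)
            ann = annotate(s, "green_strain", PRIOR, config)
            assert "DGTA " not in ann.label


class TestXanthophyllRules:
    def _pigments(self, config, names):
        return [(config.pigments[n], PROTON_ADDUCT) for n in names]

    def test_dehydration_series_is_prasinoxanthin(self, config):
        pras = config.pigments["prasinoxanthin"]
        precursor = ion_mz(pras.formula, PROTON_ADDUCT)
        s = spectrum_for(
            [(precursor - 18.011, 100), (precursor - 36.021, 50)], precursor
        )
        winner, ev, isomers = classify_xanthophyll(
            s, self._pigments(config, ["prasinoxanthin", "violaxanthin"]), config
        )
        assert winner.name == "prasinoxanthin" and len(ev) >= 2
        assert set(isomers) == {"prasinoxanthin", "violaxanthin"}

    def test_80_loss_is_violaxanthin(self, config):
        viola = config.pigments["violaxanthin"]
        precursor = ion_mz(viola.formula, PROTON_ADDUCT)
        s = spectrum_for([(precursor - 80.03, 100)], precursor)
        winner, _, _ = classify_xanthophyll(
            s, self._pigments(config, ["prasinoxanthin", "violaxanthin"]), config
        )
        assert winner.name == "violaxanthin"

    def test_two_diagnostics_are_fucoxanthin(self, config):
        fuco = config.pigments["fucoxanthin"]
        precursor = ion_mz(fuco.formula, PROTON_ADDUCT)
        s = spectrum_for([(109.1014, 80), (581.3975, 60)], precursor)
        winner, ev, _ = classify_xanthophyll(s, self._pigments(config, ["fucoxanthin"]), config)
        assert winner.name == "fucoxanthin" and len(ev) == 2

    def test_no_rule_fires_returns_none(self, config):
        pras = config.pigments["prasinoxanthin"]
        precursor = ion_mz(pras.formula, PROTON_ADDUCT)
        s = spectrum_for([(200.0, 10)], precursor)
        winner, _, isomers = classify_xanthophyll(
            s, self._pigments(config, ["prasinoxanthin", "violaxanthin"]), config
        )
        assert winner is None and len(isomers) == 2


class TestAnnotatePipeline:
    def test_noiseless_round_trip(self, config):
        sp = LipidSpecies(config.templates["MGDG"], AcylChain(18, 3), AcylChain(16, 4))
        s = generate_ms2_fixture(sp, config=config)
        ann = annotate(s, "green_strain", PRIOR, config)
        assert ann.label == "MGDG 18:3/16:4"
        assert ann.regio_status == "assigned" and ann.tier == 3

    def test_pure_noise_is_unknown(self, config):
        s = spectrum_for([(140.0, 5), (141.0, 9)], 150.0)
        ann = annotate(s, None, None, config)
        assert ann.label == "unknown" and ann.tier == 0

    def test_reversed_intensities_swap_sn_order(self, config):
        gen = LipidSpecies(config.templates["SQDG"], AcylChain(16, 0), AcylChain(18, 3))
        s = generate_ms2_fixture(gen, regio_canonical=False, config=config)
        ann = annotate(s, "green_strain", PRIOR, config)
        assert ann.species is not None
        assert {str(c) for c in ann.species.chains} == {"16:0", "18:3"}
        assert (ann.species.sn1, ann.species.sn2) == (gen.sn2, gen.sn1)

    def test_deterministic(self, config):
        sp = LipidSpecies(config.templates["DGTA"], AcylChain(22, 6), AcylChain(20, 5))
        s = generate_ms2_fixture(sp, n_decoys=5, ppm_jitter=3.0, seed=11, config=config)
        a1 = annotate(s, "brown_strain", PRIOR, config)
        a2 = annotate(s, "brown_strain", PRIOR, config)
        assert (a1.label, a1.tier, a1.regio_status) == (a2.label, a2.tier, a2.regio_status)


class TestSpectrumIO:
    def test_mgf_round_trip(self, config, tmp_path):
        sp = LipidSpecies(config.templates["MGDG"], AcylChain(18, 3), AcylChain(16, 4))
        original = [
            generate_ms2_fixture(sp, config=config),
            generate_ms2_fixture("fucoxanthin", config=config),
        ]
        for i, s in enumerate(original):
            s.rt_min = 5.0 + i
        path = str(tmp_path / "spectra.mgf")
        write_mgf(original, path)
        loaded = read_mgf(path)
        assert len(loaded) == 2
        for a, b in zip(original, loaded):
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-4)
            assert b.rt_min == pytest.approx(a.rt_min, abs=1e-6)
            np.testing.assert_allclose(b.peaks, a.peaks, atol=1e-4)

    def test_peaklist_csv(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(
            "spectrum_id,precursor_mz,rt_min,mz,intensity\n"
            "s1,500.5,4.2,200.1,10\n"
            "s1,500.5,4.2,300.2,20\n"
            "s2,600.6,5.1,150.0,5\n"
        )
        spectra = read_peaklist_csv(str(path))
        assert [s.spectrum_id for s in spectra] == ["s1", "s2"]
        assert spectra[0].peaks.shape == (2, 2)

    def test_annotation_tsv(self, config, tmp_path):
        sp = LipidSpecies(config.templates["MGDG"], AcylChain(18, 3), AcylChain(16, 4))
        s = generate_ms2_fixture(sp, config=config)
        ann = annotate(s, "green_strain", PRIOR, config)
        out = tmp_path / "ann.tsv"
        annotations_to_tsv([(s, ann)], str(out))
        lines = out.read_text().splitlines()
        assert len(lines) == 2 and "MGDG 18:3/16:4" in lines[1]

    def test_precursor_outside_instrument_range_rejected(self):
        with pytest.raises(ValueError, match="instrument range"):
            Ms2Spectrum(precursor_mz=50.0, peaks=np.empty((0, 2)))
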