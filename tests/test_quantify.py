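"""Window integration, the internal-reference formula, overlap corrections and
full-spectrum quantification."""

import numpy as np
import pytest

from oxynmr import (
    LineshapeParams,
    Spectrum,
    average_replicates,
    eq1_concentration,
    integrate_window,
    quantify_spectrum,
    render_spectrum,
)
from oxynmr.quantify import WindowArea, apply_corrections


def _flat(value=0.0):
    ppm = np.linspace(10, 0, 2001)
    return Spectrum(ppm, np.full_like(ppm, value))


class TestIntegrateWindow:
    def test_zero_trace_integrates_to_zero(self):
        assert integrate_window(_flat(0.0), (2.0, 3.0)) == 0.0

    def test_rectangle_of_height_h_width_w(self):
        assert integrate_window(_flat(2.5), (4.0, 4.8)) == pytest.approx(2.0, rel=1e-9)

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            integrate_window(_flat(), (9.5, 10.5))

    def test_truncated_lorentzian_fraction(self):
        from oxynmr._lorentz import lorentzian

        fwhm = 0.002
        ppm = np.linspace(10, 0, 20001)
        sp = Spectrum(ppm, lorentzian(ppm, 5.0, 1.0, fwhm))
        half = 20 * fwhm / 2  # ±20 half-widths
        area = integrate_window(sp, (5.0 - half, 5.0 + half))
        assert area == pytest.approx(0.968, abs=0.01)


class TestEq1:
    def test_zero_area_gives_zero(self):
        assert eq1_concentration(0.0, 2, 4.0) == 0.0

    def test_reference_identity_is_1000(self):
        # a signal with the reference's own area and proton count is 1 mol/mol TG
        assert eq1_concentration(4.0, 4, 4.0) == pytest.approx(1000.0)

    def test_inverts_to_the_day0_linoleic_value(self):
        assert eq1_concentration(2.9232, 2, 4.0) == pytest.approx(1461.6)

    def test_nonpositive_reference_area_rejected(self):
        with pytest.raises(ValueError):
            eq1_concentration(1.0, 1, 0.0)
        with pytest.raises(ValueError):
            eq1_concentration(1.0, 1, -2.0)


class TestApplyCorrections:
    def test_no_corrections_leaves_areas_unchanged(self, cat):
        sig = cat.signals["ald_2e_cho"]
        assert sig.corrections == ()
        wa = {"ald_2e_cho": WindowArea("ald_2e_cho", sig.window, 0.008)}
        out, concs = apply_corrections(wa, cat, a_tg=4.0, fwhm=0.002)
        assert out["ald_2e_cho"].corrected_area == pytest.approx(0.008)
        from oxynmr._lorentz import window_fraction

        own = window_fraction(sig.center, *sig.window, 0.002)
        assert concs["ald_2E_alkenal"] == pytest.approx(
            eq1_concentration(0.008 / own, 1, 4.0)
        )

    def test_fully_explained_window_clamps_to_zero(self, cat):
        # a diol window whose content is entirely the co-resonant carbinol peak
        lp = LineshapeParams()
        sp = render_spectrum({"HO_EPO_g1": 4.0}, cat, lp, meta={"day": 14})
        res = quantify_spectrum(sp, cat, lod=0.0)
        assert res.concentrations["dHO_pHO"] == pytest.approx(0.0, abs=0.05)

    def test_missing_contributor_is_an_error(self, cat):
        wa = {"dho_carb": WindowArea("dho_carb", cat.signals["dho_carb"].window, 0.01)}
        with pytest.raises(KeyError):
            apply_corrections(wa, cat, a_tg=4.0, fwhm=0.002)

    def test_diol_recovered_under_carbinol_overlap(self, cat):
        # the 3.42 ppm window holds both the diol protons and a hydroxy-epoxide
        # carbinol proton; subtraction must recover the diol within 2%
        lp = LineshapeParams()
        sp = render_spectrum({"dHO_pHO": 6.0, "HO_EPO_g1": 4.8}, cat, lp, meta={"day": 16})
        res = quantify_spectrum(sp, cat, lod=0.0)
        assert res.concentrations["dHO_pHO"] == pytest.approx(6.0, rel=0.02)


class TestQuantifySpectrum:
    def test_day0_composition_and_absence_of_oxidation_products(self, cat, clean_quants):
        q = clean_quants[0]
        assert q.concentrations["linoleic"] == pytest.approx(1461.6, rel=0.02)
        oxidation = [
            cid
            for cid, c in cat.compounds.items()
            if c.category in ("primary_oxidation", "secondary_oxidation", "sterol_oxide")
            and not c.aggregate
            and cat.quantifier_of(cid) is not None
        ]
        for cid in oxidation:
            assert q.concentrations[cid] < 0.5, cid

    def test_day13_hydroperoxide_maxima(self, clean_quants):
        q = clean_quants[13]
        assert q.concentrations["mHPO_cEE_dE"] == pytest.approx(140.9, rel=0.02)
        assert q.concentrations["mHPO_cZE_dE"] == pytest.approx(48.5, rel=0.02)

    def test_early_total_ooh_equals_the_isomer_sum(self, timecourse, clean_quants):
        q = clean_quants[7]
        truth = timecourse.row(7)
        expected = truth["mHPO_cZE_dE"] + truth["mHPO_cEE_dE"]
        assert q.concentrations["total_OOH"] == pytest.approx(expected, rel=0.02)

    def test_late_total_ooh_exceeds_the_isomer_sum(self, timecourse, clean_quants):
        # from day 9 other hydroperoxy species resonate in the wide window
        q = clean_quants[13]
        truth = timecourse.row(13)
        isomers = truth["mHPO_cZE_dE"] + truth["mHPO_cEE_dE"]
        assert q.concentrations["total_OOH"] > 1.2 * isomers

    def test_diepoxides_stay_below_detection_all_days(self, clean_spectra, cat):
        for day, sp in clean_spectra.items():
            res = quantify_spectrum(sp, cat)  # default LOD
            assert res.concentrations["dEPO"] == 0.0
            assert "below_lod" in res.flags["dEPO"]

    def test_reference_lost_on_an_empty_spectrum(self, cat):
        ppm = np.linspace(10, 0, 20001)
        with pytest.raises(ValueError, match="reference lost"):
            quantify_spectrum(Spectrum(ppm, np.zeros_like(ppm)), cat)

    def test_below_lod_reported_as_zero_and_flagged(self, cat, clean_spectra):
        res = quantify_spectrum(clean_spectra[16], cat, lod=0.5)
        assert res.concentrations["sterol_epo_5a6a"] == 0.0
        assert "below_lod" in res.flags["sterol_epo_5a6a"]
        # with a lower detection limit the printed maxima are recovered
        res2 = quantify_spectrum(clean_spectra[16], cat, lod=0.05)
        assert res2.concentrations["sterol_epo_5a6a"] == pytest.approx(0.18, abs=0.05)
        assert res2.concentrations["sterol_epo_5b6b"] == pytest.approx(0.14, abs=0.05)


class TestRoundTripIdentity:
    def test_quantify_of_render_is_the_identity(self, cat, timecourse, clean_quants):
        """Central property: render -> quantify recovers the fixture within 2%
        relative for well-detected channels (>= 2 mmol/mol TG, four times the
        default detection limit) and within the detection limit absolutely for
        smaller ones, on every fixture day, noise-free."""
        for day, q in clean_quants.items():
            truth = timecourse.row(day)
            for cid, tv in truth.items():
                if cat.quantifier_of(cid) is None or cat.compounds[cid].aggregate:
                    continue
                est = q.concentrations.get(cid, 0.0)
                if tv >= 2.0:
                    assert est == pytest.approx(tv, rel=0.02), (day, cid)
                else:
                    assert est == pytest.approx(tv, abs=0.5), (day, cid)

    def test_homogeneity_in_concentration(self, cat, timecourse):
        lp = LineshapeParams()
        row = timecourse.row(13)
        k = 1.7
        q1 = quantify_spectrum(render_spectrum(row, cat, lp, meta={"day": 13}), cat, lod=0.0)
        q2 = quantify_spectrum(
            render_spectrum({c: k * v for c, v in row.items()}, cat, lp, meta={"day": 13}),
            cat,
            lod=0.0,
        )
        for cid, v in q1.concentrations.items():
            if v > 1.0 and not cat.compounds[cid].aggregate:
                assert q2.concentrations[cid] == pytest.approx(k * v, rel=0.005), cid

    def test_invariance_under_global_intensity_scaling(self, cat, timecourse):
        row = timecourse.row(13)
        q1 = quantify_spectrum(
            render_spectrum(row, cat, LineshapeParams(area_scale=1.0), meta={"day": 13}),
            cat, lod=0.0,
        )
        q2 = quantify_spectrum(
            render_spectrum(row, cat, LineshapeParams(area_scale=12.5), meta={"day": 13}),
            cat, lod=0.0,
        )
        for cid, v in q1.concentrations.items():
            assert q2.concentrations[cid] == pytest.approx(v, abs=1e-8), cid


class TestAverageReplicates:
    def test_single_result_is_returned_unchanged(self, cat, clean_spectra):
        r = quantify_spectrum(clean_spectra[13], cat)
        assert average_replicates([r]) is r

    def test_identical_replicates_average_to_themselves(self, cat, clean_spectra):
        r = quantify_spectrum(clean_spectra[13], cat)
        avg = average_replicates([r, r])
        assert avg.concentrations == pytest.approx(r.concentrations)

    def test_replicate_mean_beats_single_noisy_determinations(self, cat, timecourse):
        # over many seed pairs, the two-replicate mean is closer to truth than
        # the single determinations are on average
        truth = timecourse.row(13)["mHPO_cEE_dE"]
        single_err, mean_err = [], []
        for seed in range(12):
            reps = []
            for rep in range(2):
                lp = LineshapeParams(noise_sd=6.0, seed=100 * seed + rep)
                sp = render_spectrum(timecourse.row(13), cat, lp, meta={"day": 13})
                reps.append(quantify_spectrum(sp, cat))
            single_err += [abs(r.concentrations["mHPO_cEE_dE"] - truth) for r in reps]
            mean_err.append(abs(average_replicates(reps).concentrations["mHPO_cEE_dE"] - truth))
        assert np.mean(mean_err) < np.mean(single_err)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])
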