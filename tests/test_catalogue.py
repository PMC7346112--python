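"""Catalogue structure, validation and the collision audit."""

import io

import pytest

from oxynmr.catalogue import (
    Catalogue,
    CatalogueError,
    CompoundClass,
    SignalAssignment,
    _read_rows,
    audit_collisions,
    load_catalogue,
    save_catalogue,
    suggest_correction_edges,
)

# centers the packaged catalogue must carry, straight from the running text
REQUIRED_CENTERS = {
    "mHPO_cZE_dE": 6.55,
    "mHPO_cEE_dE": 6.24,
    "dHPO_nc_dE": 4.82,
    "HPO_EPO_mE": 5.85,
    "mHO_cZE_dE": 6.48,
    "HO_EPO_g2": 3.96,
    "HO_KO_mE": 3.24,
    "mKO_cZE_dE": 7.49,
    "mKO_cEE_dE": 7.13,
    "KO_EPO_EE": 6.38,
    "KO_EPO_ZE": 3.52,
    "KO_EPO_vic": 7.02,
    "dHO_pHO": 3.42,
    "formic_acid": 8.01,
    "alkyl_furan": 7.27,
    "gamma_tocopherol": 6.360,
    "sitostanol": 0.651,
    "d7_avenasterol": 0.540,
    "sterol_epo_5a6a": 0.61,
    "sterol_epo_5b6b": 0.64,
}


def _mini(signals, compounds=None):
    comps = {c.id: c for c in (compounds or [])}
    comps.setdefault("TG", CompoundClass("TG", "reference", "acyl", 0))
    comps.setdefault("X", CompoundClass("X", "x", "secondary_oxidation", 10))
    sigs = {s.signal_id: s for s in signals}
    sigs.setdefault(
        "tg", SignalAssignment("tg", "TG", 4.14, (4.10, 4.18), 4, role="reference")
    )
    return Catalogue(compounds=comps, signals=sigs)


class TestPackagedCatalogue:
    def test_size_and_validity(self, cat):
        assert len(cat.compounds) >= 30
        assert cat.validate() is cat
        assert cat.field_mhz == 400.0

    def test_reference_is_the_tg_backbone(self, cat):
        refs = cat.reference_signals
        assert cat.reference_compound.id == "TG"
        assert cat.reference_n_protons == 4
        windows = sorted(s.window for s in refs)
        assert windows == [(4.10, 4.18), (4.26, 4.34)]

    @pytest.mark.parametrize("compound,center", sorted(REQUIRED_CENTERS.items()))
    def test_required_quantifier_centers(self, cat, compound, center):
        q = cat.quantifier_of(compound)
        assert q is not None
        assert q.center == pytest.approx(center, abs=0.015)

    def test_ooh_channel_windows(self, cat):
        sigs = {s.signal_id: s for s in cat.signals_of("total_OOH")}
        assert cat.compounds["total_OOH"].aggregate
        assert sigs["ooh_total_wide"].window == (8.30, 9.30)
        assert sigs["ooh_total_narrow"].window == (8.38, 8.52)

    def test_bisallylic_and_epoxide_channels(self, cat):
        assert cat.quantifier_of("linoleic").center == pytest.approx(2.77, abs=0.01)
        assert cat.quantifier_of("Z_EPO_Z_mE").window == (2.88, 2.98)
        assert cat.quantifier_of("E_EPO_Z_mE").window == (2.66, 2.73)

    def test_audit_is_clean(self, cat):
        assert audit_collisions(cat) == []

    def test_corrections_resolve_and_are_acyclic(self, cat):
        order = cat.correction_order()
        assert sorted(order) == sorted(cat.signals)

    def test_roundtrip_identity(self, cat, tmp_path):
        p = tmp_path / "cat.csv"
        save_catalogue(cat, p)
        again = load_catalogue(p)
        assert again.compounds == cat.compounds
        assert again.signals == cat.signals


class TestValidation:
    def test_empty_file_is_missing_reference(self):
        with pytest.raises(CatalogueError):
            _read_rows(io.StringIO("signal_id,compound_id\n"), 400.0)

    def test_correction_cycle_rejected(self):
        a = SignalAssignment("a", "X", 1.0, (0.9, 1.1), 1, corrections=("b",))
        b = SignalAssignment("b", "X", 2.0, (1.9, 2.1), 1, corrections=("a",))
        with pytest.raises(CatalogueError, match="cycle"):
            _mini([a, b]).validate()

    def test_two_reference_compounds_rejected(self):
        extra = SignalAssignment("tg2", "X", 5.0, (4.9, 5.1), 2, role="reference")
        with pytest.raises(CatalogueError, match="reference"):
            _mini([extra]).validate()

    def test_unresolved_compound_rejected(self):
        s = SignalAssignment("s", "nope", 1.0, (0.9, 1.1), 1)
        with pytest.raises(CatalogueError, match="unknown compound"):
            _mini([s]).validate()

    def test_bad_window_and_proton_count(self):
        with pytest.raises(CatalogueError):
            SignalAssignment("s", "X", 1.0, (1.1, 0.9), 1)
        with pytest.raises(CatalogueError):
            SignalAssignment("s", "X", 1.0, (0.9, 1.1), 0)
        with pytest.raises(CatalogueError):
            SignalAssignment("s", "X", 2.0, (0.9, 1.1), 1)  # center outside

    def test_duplicate_signal_id_rejected(self):
        hdr = ",".join(
            [
                "signal_id,compound_id,compound_name,category,first_detected_day",
                "aggregate,compound_notes,center_ppm,window_lo,window_hi,n_protons",
                "multiplicity,role,corrections,assumed,aggregate_member_of,notes",
            ]
        )
        row = "s,X,x,acyl,,0,,1.0,0.9,1.1,1,s,reference,,0,,"
        with pytest.raises(CatalogueError, match="duplicate"):
            _read_rows(io.StringIO("\n".join([hdr, row, row])), 400.0)


class TestAudit:
    def test_uncovered_overlap_reported(self):
        a = SignalAssignment("a", "X", 7.50, (7.40, 7.55), 1)
        b = SignalAssignment("b", "Y", 7.47, (7.45, 7.50), 1)
        y = CompoundClass("Y", "y", "secondary_oxidation", 10)
        cat = _mini([a, b], [y])
        assert audit_collisions(cat) == [("a", "b")]

    def test_corrections_edge_covers_overlap(self):
        a = SignalAssignment("a", "X", 7.50, (7.40, 7.55), 1, corrections=("b",))
        b = SignalAssignment("b", "Y", 7.47, (7.45, 7.50), 1)
        y = CompoundClass("Y", "y", "secondary_oxidation", 10)
        assert audit_collisions(_mini([a, b], [y])) == []


class TestEdgeSuggestion:
    def test_contained_peak_gets_an_edge(self):
        a = SignalAssignment("a", "X", 3.42, (3.38, 3.46), 1)
        b = SignalAssignment("b", "Y", 3.41, (3.39, 3.43), 1, role="qualifier")
        bq = SignalAssignment("bq", "Y", 5.94, (5.90, 5.98), 1)
        y = CompoundClass("Y", "y", "secondary_oxidation", 13)
        cat = _mini([a, b, bq], [y])
        series = {"X": [(12, 1.0), (16, 6.0)], "Y": [(13, 1.0), (16, 4.0)]}
        edges = suggest_correction_edges(cat, series)
        assert ("b", "a") in edges

    def test_far_apart_peaks_get_no_edge(self):
        a = SignalAssignment("a", "X", 7.0, (6.96, 7.04), 1)
        b = SignalAssignment("b", "Y", 2.0, (1.96, 2.04), 1)
        y = CompoundClass("Y", "y", "secondary_oxidation", 10)
        series = {"X": [(0, 5.0)], "Y": [(0, 5.0)]}
        assert suggest_correction_edges(_mini([a, b], [y]), series) == []


class TestPackagedConsistency:
    def test_shipped_csv_matches_the_generated_edges(self, cat):
        """The packaged CSV must equal base entries + generated leak edges."""
        from dataclasses import replace

        from oxynmr._entries import base_catalogue
        from oxynmr.synth import packaged_fixture

        base = base_catalogue().validate()
        edges = suggest_correction_edges(base, packaged_fixture().as_points())
        sigs = dict(base.signals)
        for src, tgt in edges:
            s = sigs[tgt]
            if src not in s.corrections:
                sigs[tgt] = replace(s, corrections=s.corrections + (src,))
        rebuilt = Catalogue(base.compounds, sigs).validate()
        assert rebuilt.compounds == cat.compounds
        assert rebuilt.signals == cat.signals
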