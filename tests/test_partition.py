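"""Component terms, Kpu assembly and tissue-to-blood predictions."""

import pytest

import tkidist
from tkidist.ionization import ModelMismatchError
from tkidist.partition import (
    COMPONENTS,
    decompose,
    lysosome_partition,
    predict_tbr,
    term_acidic_phospholipids,
    term_albumin,
    term_egfr,
    term_extracellular_water,
    term_intracellular_water,
    term_lysosome,
    term_neutral_lipids,
    tumor_to_lung_contrast,
)


class TestComponentTerms:
    def test_intracellular_water(self, params, blood):
        er, af = params.compound("erlotinib"), params.compound("afatinib")
        lung = params.tissue("lung")
        assert term_intracellular_water(er, lung, blood) == pytest.approx(0.4381, abs=1e-4)
        assert term_intracellular_water(af, lung, blood) == pytest.approx(0.9912, abs=1e-4)
        # equal intra/plasma pH leaves exactly the water fraction
        neutral = lung.model_copy(update={"ph_iw": blood.ph_plasma})
        assert term_intracellular_water(er, neutral, blood) == lung.f_iw

    def test_extracellular_water(self, params, blood):
        osi = params.compound("osimertinib")
        lung, tumor = params.tissue("lung"), params.tissue("tumor")
        assert term_extracellular_water(osi, lung, blood) == lung.f_ew  # pH 7.4
        assert term_extracellular_water(osi, tumor, blood) == pytest.approx(1.6706, abs=1e-3)

    def test_neutral_lipids(self, params, blood):
        er, af = params.compound("erlotinib"), params.compound("afatinib")
        lung = params.tissue("lung")
        assert term_neutral_lipids(er, lung, blood) == pytest.approx(0.03369, abs=1e-4)
        assert term_neutral_lipids(af, lung, blood) == pytest.approx(0.00506, abs=1e-4)
        fatfree = lung.model_copy(update={"f_nl": 0.0, "f_np": 0.0})
        assert term_neutral_lipids(er, fatfree, blood) == 0.0

    def test_albumin(self, params):
        er = params.compound("erlotinib")
        assert term_albumin(er, params.tissue("lung")) == pytest.approx(2.1764, abs=1e-3)
        assert term_albumin(er, params.tissue("brain")) == pytest.approx(0.4975, abs=1e-3)
        bare = params.tissue("lung").model_copy(update={"alb_ratio": 0.0})
        assert term_albumin(er, bare) == 0.0
        with pytest.raises(ModelMismatchError):
            term_albumin(params.compound("afatinib"), params.tissue("lung"))

    def test_acidic_phospholipids(self, params, blood):
        af, osi = params.compound("afatinib"), params.compound("osimertinib")
        lung = params.tissue("lung")
        assert term_acidic_phospholipids(osi, lung, blood) == pytest.approx(57.650, rel=1e-3)
        assert term_acidic_phospholipids(af, lung, blood) == pytest.approx(30.223, rel=1e-3)
        none = lung.model_copy(update={"ap_conc_mg_g": 0.0})
        assert term_acidic_phospholipids(af, none, blood) == 0.0
        with pytest.raises(ModelMismatchError):
            term_acidic_phospholipids(params.compound("erlotinib"), lung, blood)

    def test_egfr(self, params, blood):
        af = params.compound("afatinib")
        assert term_egfr(af, params.tissue("lung"), blood) == pytest.approx(15.413, rel=1e-3)
        assert term_egfr(af, params.tissue("tumor"), blood) == pytest.approx(148.18, rel=1e-3)
        assert term_egfr(af, params.tissue("bone"), blood) == 0.0
        assert term_egfr(af, params.tissue("brain"), blood) == 0.0

    def test_lysosome_partition(self, params, blood):
        af, osi = params.compound("afatinib"), params.compound("osimertinib")
        residual = params.tissue("tumor").cell_types[0]
        assert lysosome_partition(
            osi, residual, blood, "membrane", membrane_ap_mg_g=0.57
        ) == pytest.approx(1929.0, rel=1e-3)
        assert lysosome_partition(af, residual, blood, "ph_only") == pytest.approx(
            74.778, rel=1e-3
        )
        # no pH gradient -> no trapping
        iso = residual.model_copy(update={"ph_lys": 6.99})
        assert lysosome_partition(
            af, iso.model_copy(update={"ph_lys": 7.0 - 1e-12}), blood, "ph_only"
        ) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="mode"):
            lysosome_partition(af, residual, blood, "nosuch")

    def test_term_lysosome(self, params, blood):
        af, osi = params.compound("afatinib"), params.compound("osimertinib")
        assert term_lysosome(osi, params.tissue("lung"), blood) == pytest.approx(
            87.886, rel=1e-3
        )
        assert term_lysosome(af, params.tissue("tumor"), blood) == pytest.approx(
            25.730, rel=1e-3
        )
        assert term_lysosome(af, params.tissue("bone"), blood) == 0.0
        with pytest.raises(ModelMismatchError):
            term_lysosome(params.compound("erlotinib"), params.tissue("lung"), blood)


class TestAssembly:
    @pytest.mark.parametrize(
        "compound, tissue, expected",
        [
            ("erlotinib", "lung", 0.27738),
            ("afatinib", "tumor", 15.4578),
            ("osimertinib", "lung", 3.16663),
        ],
    )
    def test_final_model_predictions(self, params, blood, compound, tissue, expected):
        record = predict_tbr(params.compound(compound), params.tissue(tissue), blood)
        assert record.tbr == pytest.approx(expected, rel=1e-4)

    def test_decomposition_sum_consistency(self, params, blood):
        for cname in params.compounds:
            for tname in params.tissues:
                record = predict_tbr(params.compound(cname), params.tissue(tname), blood)
                bd = record.breakdown
                assert record.tbr == pytest.approx(
                    bd.total_unbound * bd.fu_over_bp * bd.coefficient, rel=1e-12
                )
                assert sum(bd.percentages.values()) == pytest.approx(100.0, abs=1e-9)
                assert all(v >= 0.0 for v in bd.terms.values())

    def test_not_applicable_components_mirror_model(self, params, blood):
        weak = decompose(params.compound("erlotinib"), params.tissue("lung"), blood)
        assert set(weak.not_applicable) == {"ap_minus", "lysosome"}
        strong = decompose(params.compound("osimertinib"), params.tissue("lung"), blood)
        assert set(strong.not_applicable) == {"albumin"}
        assert set(weak.terms) | set(weak.not_applicable) == set(COMPONENTS)

    @pytest.mark.parametrize(
        "field", ["egfr_nM", "ap_conc_mg_g", "alb_ratio"]
    )
    def test_tbr_monotone_in_binding_sites(self, params, blood, field):
        cname = "erlotinib" if field == "alb_ratio" else "osimertinib"
        compound = params.compound(cname)
        lung = params.tissue("lung")
        base = predict_tbr(compound, lung, blood).tbr
        for factor in (1.5, 3.0, 10.0):
            bumped = lung.model_copy(update={field: getattr(lung, field) * factor})
            higher = predict_tbr(compound, bumped, blood).tbr
            assert higher > base
            base = higher

    def test_tbr_monotone_in_lysosomal_volume(self, params, blood):
        compound = params.compound("osimertinib")
        lung = params.tissue("lung")
        base = predict_tbr(compound, lung, blood).tbr
        for factor in (1.5, 3.0):
            cells = tuple(
                c.model_copy(update={"f_lys": c.f_lys * factor}) for c in lung.cell_types
            )
            bumped = lung.model_copy(update={"cell_types": cells})
            higher = predict_tbr(compound, bumped, blood).tbr
            assert higher > base
            base = higher

    def test_membrane_mode_dominates_ph_only(self, params, blood):
        for cname in ("afatinib", "osimertinib"):
            compound = params.compound(cname)
            for tname in params.tissues:
                tissue = params.tissue(tname)
                membrane = term_lysosome(compound, tissue, blood, "membrane")
                ph_only = term_lysosome(compound, tissue, blood, "ph_only")
                assert membrane >= ph_only

    def test_tumor_parameterized_as_lung_predicts_lung(self, params, blood):
        lung = params.tissue("lung")
        fake_tumor = lung.model_copy(update={"name": "tumor"})
        for cname in params.compounds:
            compound = params.compound(cname)
            assert predict_tbr(compound, fake_tumor, blood).tbr == predict_tbr(
                compound, lung, blood
            ).tbr

    def test_contrast(self, params, blood):
        lung, tumor = params.tissue("lung"), params.tissue("tumor")
        for cname, above_one in (("erlotinib", True), ("afatinib", True),
                                 ("osimertinib", False)):
            c = tumor_to_lung_contrast(params.compound(cname), lung, tumor, blood)
            assert (c > 1.0) is above_one
        same = tumor_to_lung_contrast(
            params.compound("afatinib"), lung, lung.model_copy(update={"name": "tumor"}),
            blood,
        )
        assert same == pytest.approx(1.0, rel=1e-12)
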