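import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidq import lipid_id
from lipidq.lipid_id import (
    ADDUCTS,
    BUILTIN_CANDIDATES,
    adduct_mz,
    assign_msi_level,
    diagnostic_fragments,
    match_features,
    monoisotopic_mass,
    neutral_from_mz,
    parse_formula,
    ppm_error,
)


class TestParseFormula:
    def test_glycerophospholipid_formula(self):
        f = parse_formula("C24H50NO7P")
        assert f.as_dict() == {"C": 24, "H": 50, "N": 1, "O": 7, "P": 1}
        assert f.hill() == "C24H50NO7P"

    def test_implicit_counts(self):
        assert parse_formula("H2O").as_dict() == {"H": 2, "O": 1}

    @pytest.mark.parametrize("bad", ["C0H4", "C2X4", "C24H50 junk", "", "24C"])
    def test_malformed_formulas_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)

    def test_merge_additivity(self):
        a, b = parse_formula("C2H6O"), parse_formula("CH4")
        assert (a + b).as_dict() == {"C": 3, "H": 10, "O": 1}


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C24H50NO7P", 495.332490),   # LysoPC(16:0)
            ("C44H86NO8P", 787.609105),   # PC(18:0/18:1)
            ("C41H79O13P", 810.525829),   # PI(16:0/16:0)
            ("C26H54NO7P", 523.363790),   # LysoPC(18:0)
            ("CH4", 16.031300),
        ],
    )
    def test_reference_masses(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=2e-6)

    def test_matches_pyteomics(self):
        from pyteomics.mass import calculate_mass

        for cand in BUILTIN_CANDIDATES:
            assert monoisotopic_mass(cand.formula) == pytest.approx(
                calculate_mass(formula=cand.formula), abs=1e-5
            )

    @given(
        st.dictionaries(
            st.sampled_from("CHNOPS"), st.integers(1, 40), min_size=1, max_size=6
        ),
        st.dictionaries(
            st.sampled_from("CHNOPS"), st.integers(1, 40), min_size=1, max_size=6
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_additivity(self, d1, d2):
        def to_str(d):
            return "".join(f"{el}{n}" for el, n in sorted(d.items()))

        f1, f2 = parse_formula(to_str(d1)), parse_formula(to_str(d2))
        assert monoisotopic_mass(f1) + monoisotopic_mass(f2) == pytest.approx(
            monoisotopic_mass(f1 + f2), abs=1e-9
        )


class TestAdducts:
    def test_protonation(self):
        assert adduct_mz(495.332490, "M+H") == pytest.approx(496.339766, abs=1e-6)

    def test_deprotonation(self):
        assert adduct_mz(810.525829, "M-H") == pytest.approx(809.518553, abs=1e-6)

    def test_mode_assignment(self):
        assert ADDUCTS["M+H"].mode == "positive"
        assert ADDUCTS["M-H"].mode == "negative"
        assert ADDUCTS["M-CH3"].mode == "negative"

    @pytest.mark.parametrize("name", ["M+H", "M-H", "M-CH3"])
    def test_round_trip(self, name):
        mz = adduct_mz(750.123456, name)
        assert neutral_from_mz(mz, name) == pytest.approx(750.123456, abs=1e-12)

    def test_unknown_adduct_errors(self):
        with pytest.raises(ValueError):
            adduct_mz(100.0, "M+Na")


class TestPpmError:
    def test_definition(self):
        assert ppm_error(100.0010, 100.0000) == pytest.approx(10.00, abs=1e-6)

    def test_exact_match_is_zero(self):
        assert ppm_error(500.0, 500.0) == 0.0

    @pytest.mark.parametrize(
        "observed, formula, expected",
        [
            (835.533540, "C43H81O13P", -0.79),  # PI(16:0/18:1)
            (887.565099, "C47H85O13P", -0.46),  # PI(18:0/20:3)
            (809.516853, "C41H79O13P", -2.10),  # PI(16:0/16:0)
        ],
    )
    def test_deprotonated_reference_errors(self, observed, formula, expected):
        theo = adduct_mz(monoisotopic_mass(formula), "M-H")
        assert ppm_error(observed, theo) == pytest.approx(expected, abs=0.02)

    def test_first_order_antisymmetry(self):
        a, b = 500.0005, 500.0000
        assert ppm_error(a, b) + ppm_error(b, a) == pytest.approx(0.0, abs=1e-5)


class TestMatchFeatures:
    def _feature(self, mz, rt, mode):
        return pd.DataFrame(
            {"mz": [mz], "rt": [rt], "ion_mode": [mode]},
            index=pd.Index(["Fx"], name="feature_id"),
        )

    def test_lysopc_accepted_at_ten_ppm(self):
        anns = match_features(self._feature(496.344269, 1.32, "positive"))
        names = {a.name for a in anns}
        assert "LysoPC(16:0)" in names
        hit = next(a for a in anns if a.name == "LysoPC(16:0)")
        assert hit.adduct == "M+H" and 9.0 < hit.ppm_error < 9.2
        assert hit.rt_ok

    def test_rt_outside_class_window_rejected(self):
        anns = match_features(self._feature(496.344269, 7.5, "positive"))
        assert not any(a.name == "LysoPC(16:0)" for a in anns)

    def test_mass_error_beyond_tolerance_rejected(self):
        theo = adduct_mz(monoisotopic_mass("C24H50NO7P"), "M+H")
        anns = match_features(
            self._feature(theo * (1 + 11e-6), 1.32, "positive"), ms1_tol=10.0
        )
        assert anns == []

    def test_zero_tolerance_accepts_only_exact(self):
        theo = adduct_mz(monoisotopic_mass("C41H79O13P"), "M-H")
        exact = match_features(self._feature(theo, 5.8, "negative"), ms1_tol=0.0)
        assert any(a.name == "PI(16:0/16:0)" for a in exact)
        off = match_features(
            self._feature(theo + 1e-4, 5.8, "negative"), ms1_tol=0.0
        )
        assert off == []

    def test_mode_mismatch_rejected(self):
        theo = adduct_mz(monoisotopic_mass("C24H50NO7P"), "M+H")
        anns = match_features(self._feature(theo, 1.32, "negative"))
        assert not any(a.adduct == "M+H" for a in anns)

    def test_matches_ranked_by_abs_ppm(self):
        theo = adduct_mz(monoisotopic_mass("C47H85O13P"), "M-H")
        anns = match_features(self._feature(theo, 6.8, "negative"), ms1_tol=30.0)
        errs = [abs(a.ppm_error) for a in anns]
        assert errs == sorted(errs)


class TestFragmentsAndLevels:
    def test_phosphocholine_head_positive(self):
        frags = diagnostic_fragments("LysoPC", "positive")
        assert any(abs(f - 184.07332) < 1e-4 for f in frags)

    def test_palmitate_anion_for_pi(self):
        frags = diagnostic_fragments("PI", "negative", chains=((16, 0), (18, 1)))
        assert any(abs(f - 255.23295) < 1e-4 for f in frags)
        assert any(abs(f - 241.0119) < 1e-3 for f in frags)  # inositol phosphate

    def test_pc_negative_demethylated_ion(self):
        neutral = monoisotopic_mass("C44H86NO8P")
        frags = diagnostic_fragments("PC", "negative", neutral_mass=neutral)
        assert any(abs(f - 772.587) < 5e-3 for f in frags)

    def test_unknown_class_errors(self):
        with pytest.raises(ValueError, match="unknown lipid class"):
            diagnostic_fragments("TAG", "positive")

    def _ann(self, rt_ok):
        return lipid_id.LipidAnnotation(
            feature_id="F", name="LysoPC(18:0)", lipid_class="LysoPC",
            formula="C26H54NO7P", adduct="M+H", neutral_mass=523.36379,
            theoretical_mz=524.371066, ppm_error=1.0, rt_ok=rt_ok,
        )

    @pytest.mark.parametrize(
        "evidence, rt_ok, level",
        [
            ("standard_match", True, 1),
            ("fragment_match", True, 2),
            ("none", True, 2),     # MS1 + class-consistent RT
            ("none", None, 3),     # MS1 only, no window defined
        ],
    )
    def test_msi_levels(self, evidence, rt_ok, level):
        assert assign_msi_level(self._ann(rt_ok), evidence) == level

    def test_unknown_evidence_errors(self):
        with pytest.raises(ValueError):
            assign_msi_level(self._ann(True), "vibes")
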