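"""Per-specimen trophic metrics: frozen oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trophlink import (
    AAProfile,
    CalibrationConstants,
    InsufficientAminoAcidsError,
    TrophicWarning,
    compute_fcl_table,
    fcl_glu_phe,
    fcl_trp_scr,
    protist_index,
    read_specimen_csv,
    transfer_efficiency,
    weighted_mean_d15n,
    write_specimen_csv,
)
from trophlink.isotope import ALL_AAS


class TestFCLGluPhe:
    def test_zero_and_one_trophic_step(self, calib):
        beta = calib.pair("Glu", "Phe").beta
        tdf = calib.pair("Glu", "Phe").tdf
        assert fcl_glu_phe(10.0 + beta, 10.0, calib) == pytest.approx(1.0)
        assert fcl_glu_phe(10.0 + beta + tdf, 10.0, calib) == pytest.approx(2.0)

    def test_hand_computed_value(self, calib):
        # (25.0 - 8.0 - 3.6)/5.7 + 1, direct arithmetic
        assert fcl_glu_phe(25.0, 8.0, calib) == pytest.approx(3.3509, abs=1e-4)

    def test_below_one_returned_with_warning(self, calib):
        with pytest.warns(TrophicWarning):
            fcl = fcl_glu_phe(8.0, 8.0, calib)
        assert fcl < 1.0

    def test_nonfinite_rejected(self, calib):
        with pytest.raises(ValueError):
            fcl_glu_phe(float("nan"), 8.0, calib)


class TestWeightedMean:
    def test_constant_values_any_sds(self):
        assert weighted_mean_d15n(
            {"Glu": 5.5, "Ala": 5.5, "Pro": 5.5}, {"Glu": 0.24, "Ala": 0.08, "Pro": 0.25}
        ) == pytest.approx(5.5)

    def test_equal_sds_give_arithmetic_mean(self):
        assert weighted_mean_d15n(
            {"Glu": 1.0, "Ala": 2.0, "Pro": 6.0}, dict.fromkeys(ALL_AAS, 0.2)
        ) == pytest.approx(3.0)

    def test_hand_weighted_value(self):
        # weights 1/sigma^2: 17.3611, 156.25, 16 -> 4120.7222 / 189.6111
        got = weighted_mean_d15n(
            {"Glu": 20.0, "Ala": 22.0, "Pro": 21.0},
            {"Glu": 0.24, "Ala": 0.08, "Pro": 0.25},
        )
        assert got == pytest.approx(21.7325, abs=1e-4)

    def test_validation(self):
        with pytest.raises(ValueError):
            weighted_mean_d15n({}, {})
        with pytest.raises(ValueError):
            weighted_mean_d15n({"Glu": 1.0}, {"Glu": 0.0})

    @given(
        st.lists(
            st.floats(min_value=-20, max_value=40, allow_nan=False), min_size=1, max_size=5
        ),
        st.lists(st.floats(min_value=0.01, max_value=2.0), min_size=5, max_size=5),
    )
    def test_within_input_range(self, values, sds):
        names = list(ALL_AAS)[: len(values)]
        vmap = dict(zip(names, values))
        smap = dict(zip(names, sds))
        out = weighted_mean_d15n(vmap, smap)
        assert min(values) - 1e-9 <= out <= max(values) + 1e-9


class TestFCLTrpScr:
    def test_one_trophic_level_when_difference_equals_beta(self, calib):
        beta, _ = calib.weighted_beta_tdf()
        prof = AAProfile(
            "s1", 1990, {"Glu": 8 + beta, "Ala": 8 + beta, "Pro": 8 + beta, "Phe": 8.0, "Gly": 8.0}
        )
        assert fcl_trp_scr(prof, calib) == pytest.approx(1.0)

    def test_degenerate_weighting_reduces_to_glu_phe(self, calib):
        prof = AAProfile("s1", 1990, {"Glu": 25.0, "Phe": 8.0})
        with pytest.warns(TrophicWarning, match="partial"):
            got = fcl_trp_scr(prof, calib)
        assert got == pytest.approx(fcl_glu_phe(25.0, 8.0, calib))

    def test_missing_side_raises(self, calib):
        with pytest.raises(InsufficientAminoAcidsError, match="s1"):
            fcl_trp_scr(AAProfile("s1", 1990, {"Glu": 25.0, "Ala": 24.0}), calib)

    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_translation_invariance(self, shift):
        calib = CalibrationConstants.default()
        d15n = {"Glu": 24.0, "Ala": 23.5, "Pro": 23.0, "Phe": 8.0, "Gly": 9.0}
        base = fcl_trp_scr(AAProfile("a", 2000, dict(d15n)), calib)
        shifted = fcl_trp_scr(
            AAProfile("a", 2000, {k: v + shift for k, v in d15n.items()}), calib
        )
        assert shifted == pytest.approx(base, abs=1e-10)


class TestTransferEfficiency:
    def test_base_of_chain_and_one_step(self):
        assert transfer_efficiency(1.0, 0.2) == pytest.approx(1.0)
        assert transfer_efficiency(2.0, 0.2) == pytest.approx(0.2)

    def test_log_space_value(self):
        # 0.2**2.5 computed in log space: exp(2.5 * ln 0.2)
        assert transfer_efficiency(3.5, 0.2) == pytest.approx(0.0178885, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            transfer_efficiency(0.8, 0.2)
        with pytest.raises(ValueError):
            transfer_efficiency(2.0, 1.5)

    @given(st.floats(min_value=1.0, max_value=6.0), st.floats(min_value=0.05, max_value=0.9))
    def test_one_step_multiplies_by_gge(self, fcl, gge):
        te = transfer_efficiency(fcl, gge)
        assert transfer_efficiency(fcl + 1.0, gge) == pytest.approx(gge * te, rel=1e-12)
        assert transfer_efficiency(fcl + 0.5, gge) < te  # strictly decreasing


class TestProtistIndex:
    def _cohort(self, glu, ala):
        return [
            AAProfile(f"s{i}", 2000, {"Glu": g, "Ala": a})
            for i, (g, a) in enumerate(zip(glu, ala))
        ]

    def test_affine_relationship_gives_zero_residuals(self):
        glu = np.linspace(18, 26, 8)
        res = protist_index(self._cohort(glu, 1.3 * glu - 2.0))
        assert np.allclose(list(res.values()), 0.0, atol=1e-10)

    def test_underdetermined_cohort_rejected(self):
        with pytest.raises(ValueError):
            protist_index(self._cohort([20, 21], [22, 23]))
        with pytest.raises(ValueError):
            protist_index(self._cohort([20.0] * 5, [22, 23, 21, 22, 23]))

    def test_normal_equations_oracle(self):
        # Ala = 1.2 Glu + 0.5 + e with a fixed noise vector; expected
        # residuals are e minus its own OLS projection, solved here from
        # the normal equations independently of the implementation.
        glu = np.array([18.0, 19.0, 20.0, 21.0, 22.0, 23.0, 24.0, 25.0, 26.0, 27.0])
        e = np.array([0.21, -0.34, 0.05, 0.40, -0.18, 0.02, -0.27, 0.33, -0.11, -0.11])
        ala = 1.2 * glu + 0.5 + e
        X = np.column_stack([np.ones_like(glu), glu])
        coef = np.linalg.solve(X.T @ X, X.T @ e)
        expected = e - X @ coef
        res = protist_index(self._cohort(glu, ala))
        assert np.allclose([res[f"s{i}"] for i in range(10)], expected, atol=1e-10)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(3)
        glu = rng.uniform(18, 27, 25)
        ala = 1.1 * glu + rng.normal(0, 0.3, 25)
        res = protist_index(self._cohort(glu, ala))
        assert sum(res.values()) == pytest.approx(0.0, abs=1e-9)


class TestTableAndIO:
    def test_round_trip_csv_and_flags(self, tmp_path, calib):
        profiles = [
            AAProfile("a", 1990, {"Glu": 24.0, "Ala": 23.0, "Pro": 23.5, "Phe": 8.0, "Gly": 8.5},
                      station="ST1", standard_length=20.5),
            AAProfile("b", 1991, {"Glu": 23.0, "Phe": 8.2}),
            AAProfile("c", 1992, {"Ala": 22.0, "Gly": 8.1, "Glu": 23.5, "Phe": 8.3, "Pro": 23.0}),
            AAProfile("d", 1992, {"Glu": 24.2, "Ala": 23.4, "Pro": 23.1, "Phe": 8.4, "Gly": 8.2}),
        ]
        path = tmp_path / "spec.csv"
        write_specimen_csv(profiles, path)
        back = read_specimen_csv(path)
        assert [p.specimen_id for p in back] == ["a", "b", "c", "d"]
        assert back[1].d15n == {"Glu": 23.0, "Phe": 8.2}
        table = compute_fcl_table(back, calib)
        assert list(table["specimen_id"]) == ["a", "b", "c", "d"]
        assert "partial" in table.set_index("specimen_id").loc["b", "flags"]
        assert table["fcl_trp_scr"].notna().all()
        # efficiency consistent with the multi-AA FCL
        row = table.iloc[0]
        assert row["transfer_efficiency"] == pytest.approx(
            calib.gge ** (row["fcl_trp_scr"] - 1.0)
        )
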