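"""Synthetic-data generators: determinism, truth records, calibration."""

import numpy as np
import pandas as pd
import pytest

from greensolv.errors import InvalidSpecError
from greensolv.hsp import HSPTriple, SoluteSphere
from greensolv.inverse import predict_red
from greensolv.quality import class_sums, classify_fatty_acid
from greensolv.synth import (
    DEFAULT_HSP_RANGES,
    SyntheticSpec,
    default_fatty_acid_codes,
    gen_bioactivity,
    gen_composition,
    gen_red_table,
    gen_solvent_set,
    write_fixture_dir,
)


class TestSolventSet:
    def test_zero_solvents_gives_empty_list(self):
        assert gen_solvent_set(SyntheticSpec(seed=0, n_solvents=0)) == []

    def test_fixed_seed_is_bit_reproducible(self):
        a = gen_solvent_set(SyntheticSpec(seed=5))
        b = gen_solvent_set(SyntheticSpec(seed=5))
        assert a == b
        c = gen_solvent_set(SyntheticSpec(seed=6))
        assert a != c

    def test_default_ranges_bracket_the_packaged_solvents(self, solvents):
        (d_lo, d_hi) = DEFAULT_HSP_RANGES["delta_d"]
        (p_lo, p_hi) = DEFAULT_HSP_RANGES["delta_p"]
        (h_lo, h_hi) = DEFAULT_HSP_RANGES["delta_h"]
        for s in solvents:
            assert d_lo <= s.hsp.delta_d <= d_hi
            assert p_lo <= s.hsp.delta_p <= p_hi
            assert h_lo <= s.hsp.delta_h <= h_hi

    def test_degenerate_range_rejected(self):
        with pytest.raises(InvalidSpecError):
            SyntheticSpec(seed=0, hsp_ranges={"delta_d": (16.0, 13.0)})


class TestRedTable:
    def test_zero_noise_reproduces_forward_model(self):
        spec = SyntheticSpec(seed=9, red_noise_sd=0.0)
        solvents = gen_solvent_set(spec)
        observed, truth = gen_red_table(spec, solvents)
        np.testing.assert_allclose(observed, truth["noise_free_red"], atol=1e-15)

    def test_sphere_at_solvent_coordinate_scores_zero(self):
        spec = SyntheticSpec(seed=9, red_noise_sd=0.0)
        solvents = gen_solvent_set(spec)
        spec_at = SyntheticSpec(
            seed=9,
            red_noise_sd=0.0,
            sphere_truth=SoluteSphere("at", solvents[2].hsp, 6.0),
        )
        observed, _ = gen_red_table(spec_at, solvents)
        assert observed[2] == 0.0

    def test_noise_has_the_requested_scale(self):
        sd = 0.05
        solvents = gen_solvent_set(SyntheticSpec(seed=11))
        draws = []
        for rep in range(100):
            spec = SyntheticSpec(seed=2000 + rep, red_noise_sd=sd)
            observed, truth = gen_red_table(spec, solvents)
            draws.append(observed - truth["noise_free_red"])
        empirical_sd = np.asarray(draws).std()
        assert empirical_sd == pytest.approx(sd, rel=0.15)

    def test_observed_red_never_negative(self):
        spec = SyntheticSpec(seed=1, red_noise_sd=5.0)  # absurd noise
        solvents = gen_solvent_set(spec)
        observed, _ = gen_red_table(spec, solvents)
        assert (observed >= 0).all()


class TestComposition:
    def test_columns_sum_to_one_hundred(self):
        profiles = gen_composition(SyntheticSpec(seed=3))
        for p in profiles:
            assert sum(p.entries.values()) == pytest.approx(100.0, abs=1e-9)

    def test_codes_are_valid_and_span_all_classes(self):
        codes = default_fatty_acid_codes(10)
        classes = {classify_fatty_acid(c) for c in codes}
        assert classes == {"SFA", "MUFA", "PUFA"}
        summary = class_sums(gen_composition(SyntheticSpec(seed=3))[0])
        assert summary.sfa + summary.mufa + summary.pufa == pytest.approx(100.0)

    def test_concentration_controls_evenness(self):
        spread = []
        for conc in (0.5, 200.0):
            profiles = gen_composition(
                SyntheticSpec(seed=8, composition_concentration=conc, n_samples=50)
            )
            values = np.array([list(p.entries.values()) for p in profiles])
            spread.append(values.std())
        assert spread[1] < spread[0]  # large concentration -> near-uniform

    def test_reproducible_under_fixed_seed(self):
        a = gen_composition(SyntheticSpec(seed=4))
        b = gen_composition(SyntheticSpec(seed=4))
        assert a == b

    def test_too_few_acids_rejected(self):
        with pytest.raises(InvalidSpecError):
            gen_composition(SyntheticSpec(seed=0, n_fatty_acids=1))


class TestBioactivity:
    def test_perfect_target_correlation_is_exactly_linear(self):
        spec = SyntheticSpec(seed=2, target_correlation=1.0)
        driver = np.array([400.0, 450.0, 500.0, 600.0, 700.0, 800.0])
        table = gen_bioactivity(spec, driver)
        z = (driver - driver.mean()) / driver.std()
        np.testing.assert_allclose(table.data["tac"], 2.5 + 0.4 * z, atol=1e-12)

    def test_zero_target_gives_coefficients_centered_at_zero(self):
        coeffs = []
        for rep in range(200):
            spec = SyntheticSpec(seed=3000 + rep, target_correlation=0.0, n_samples=30)
            driver = spec.rng("driver").uniform(400, 800, 30)
            table = gen_bioactivity(spec, driver)
            coeffs.append(np.corrcoef(driver, table.data["tac"])[0, 1])
        assert abs(np.mean(coeffs)) < 0.05

    def test_ic50_endpoints_use_negative_sign_convention(self):
        spec = SyntheticSpec(seed=2, target_correlation=1.0)
        driver = np.linspace(400, 800, 6)
        table = gen_bioactivity(spec, driver)
        assert np.corrcoef(driver, table.data["dpph_ic50"])[0, 1] == pytest.approx(-1.0)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(InvalidSpecError):
            SyntheticSpec(seed=0, target_correlation=1.5)

    def test_driver_length_mismatch_rejected(self):
        with pytest.raises(InvalidSpecError):
            gen_bioactivity(SyntheticSpec(seed=0, n_samples=6), np.ones(4))


class TestFixtureRoundTrip:
    def test_fixture_dir_round_trips_through_package_readers(self, tmp_path):
        from greensolv.cosmo import read_relative_solubility_csv
        from greensolv.hsp import read_red_matrix_csv, read_solvents_csv
        from greensolv.quality import profiles_from_wide, read_composition_csv

        spec = SyntheticSpec(seed=17)
        paths = write_fixture_dir(spec, tmp_path)
        solvents = read_solvents_csv(paths["solvents"])
        regenerated_solvents = gen_solvent_set(spec)
        assert [s.name for s in solvents] == [s.name for s in regenerated_solvents]
        # lossless at the documented 12-significant-digit serialization
        np.testing.assert_allclose(
            np.array([s.hsp.as_array() for s in solvents]),
            np.array([s.hsp.as_array() for s in regenerated_solvents]),
            rtol=1e-11,
        )

        red = read_red_matrix_csv(paths["red"])
        observed, truth = gen_red_table(spec, gen_solvent_set(spec))
        np.testing.assert_allclose(red.to_numpy().ravel(), observed, rtol=1e-10)

        rel = read_relative_solubility_csv(paths["relsol"])
        assert rel.values.max() == pytest.approx(0.0, abs=1e-12)

        comp = read_composition_csv(paths["composition"])
        regenerated = gen_composition(spec)
        np.testing.assert_allclose(
            comp.to_numpy(),
            np.array([list(p.entries.values()) for p in regenerated]).T,
            rtol=1e-10,
        )

        import json

        truth_json = json.loads(paths["truth"].read_text())
        assert truth_json["sphere"]["r_spher"] == spec.sphere_truth.r_spher
        np.testing.assert_allclose(
            truth_json["noise_free_red"],
            predict_red(spec.sphere_truth, solvents),
            rtol=1e-10,
        )
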