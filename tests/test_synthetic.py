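import numpy as np
import pytest

from ensemblesdm.synthetic import (
    ANTHROPIC,
    NATIVE,
    MonthlyClimateField,
    VirtualSpecies,
    derive_bioclim,
    generate_climate,
    generate_landuse_pair,
    generate_virtual_species,
)
from ensemblesdm.grid import BIOCLIM_VARS


class TestGenerateClimate:
    def test_zero_delta_future_identical_to_current(self):
        cur, futs = generate_climate((6, 6), 1, 1, warming_deltas=[0.0],
                                     precip_factors=[1.0], seed=3)
        assert np.array_equal(futs[0].temp, cur.temp)
        assert np.array_equal(futs[0].precip, cur.precip)

    def test_uniform_warming_shifts_spatial_mean_exactly(self):
        cur, futs = generate_climate((8, 8), 1, 1, warming_deltas=[2.0], seed=3)
        assert np.isclose(futs[0].temp.mean() - cur.temp.mean(), 2.0)

    def test_same_seed_bit_identical(self):
        a = generate_climate((8, 8), 2, 2, seed=11)
        b = generate_climate((8, 8), 2, 2, seed=11)
        assert np.array_equal(a[0].temp, b[0].temp)
        for fa, fb in zip(a[1], b[1]):
            assert np.array_equal(fa.precip, fb.precip)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_climate((1, 5), 1, 1)
        with pytest.raises(ValueError, match="deltas"):
            generate_climate((6, 6), 2, 2, warming_deltas=[1.0])

    def test_precipitation_non_negative(self):
        cur, futs = generate_climate((10, 10), 2, 2, seed=5)
        assert (cur.precip >= 0).all()
        assert all((f.precip >= 0).all() for f in futs)


def _constant_field(t=20.0, p=100.0, dims=(3, 3)):
    return MonthlyClimateField(
        temp=np.full(dims + (12,), t), precip=np.full(dims + (12,), p)
    )


class TestDeriveBioclim:
    def test_constant_months_give_zero_seasonality(self):
        cg = derive_bioclim(_constant_field())
        assert np.allclose(cg.values["bio1"], 20.0)
        assert np.allclose(cg.values["bio4"], 0.0)
        assert np.allclose(cg.values["bio12"], 1200.0)
        assert np.allclose(cg.values["bio15"], 0.0)

    def test_temperature_seasonality_matches_spreadsheet_sd(self):
        months = np.arange(10.0, 33.0, 2.0)  # 10, 12, ..., 32
        assert len(months) == 12
        f = MonthlyClimateField(
            temp=np.tile(months, (2, 2, 1)), precip=np.full((2, 2, 12), 50.0)
        )
        cg = derive_bioclim(f)
        # population SD computed by explicit deviation sums
        mean = months.sum() / 12
        sd = (sum((m - mean) ** 2 for m in months) / 12) ** 0.5
        assert np.allclose(cg.values["bio4"], 100 * sd)

    def test_precip_cv_reported_as_percent_and_switchable(self):
        p = np.tile(np.array([50.0] * 6 + [150.0] * 6), (2, 2, 1))
        f = MonthlyClimateField(temp=np.full((2, 2, 12), 20.0), precip=p)
        pct = derive_bioclim(f).values["bio15"][0]
        raw = derive_bioclim(f, cv_as_percent=False).values["bio15"][0]
        assert np.isclose(pct, 100 * raw)
        assert np.isclose(raw, 50.0 / 100.0)  # SD 50 around mean 100

    def test_sample_sd_switch(self):
        months = np.arange(10.0, 33.0, 2.0)
        f = MonthlyClimateField(
            temp=np.tile(months, (2, 2, 1)), precip=np.full((2, 2, 12), 50.0)
        )
        b4_pop = derive_bioclim(f).values["bio4"][0]
        b4_smp = derive_bioclim(f, ddof=1).values["bio4"][0]
        assert b4_smp > b4_pop

    def test_zero_precip_cell_masked_as_undefined(self):
        p = np.full((3, 3, 12), 100.0)
        p[1, 1] = 0.0
        f = MonthlyClimateField(temp=np.full((3, 3, 12), 20.0), precip=p)
        cg = derive_bioclim(f)
        assert cg.grid.n_cells == 8
        assert not cg.grid.mask[1, 1]


class TestVirtualSpecies:
    def test_suitability_one_at_optimum_with_unit_scaling(self, small_climate):
        current, _ = small_climate
        mu = {v: float(current.values[v][0]) for v in BIOCLIM_VARS}
        sp = VirtualSpecies("v", mu=mu, sigma={v: 1.0 for v in BIOCLIM_VARS},
                            scaling=1.0)
        assert np.isclose(sp.suitability(current)[0], 1.0)

    def test_far_tail_suitability_negligible(self, small_climate):
        current, _ = small_climate
        mu = {v: float(current.values[v].mean()) for v in BIOCLIM_VARS}
        sigma = {v: 1.0 for v in BIOCLIM_VARS}
        mu["bio1"] = float(current.values["bio1"][0]) + 10.0  # 10 sigma away
        sp = VirtualSpecies("v", mu=mu, sigma=sigma)
        others = sum(
            ((current.values[v][0] - mu[v]) / sigma[v]) ** 2
            for v in BIOCLIM_VARS if v != "bio1"
        )
        assert sp.suitability(current)[0] <= np.exp(-0.5 * 100) * np.exp(-0.5 * 0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            VirtualSpecies("v", mu={v: 0 for v in BIOCLIM_VARS},
                           sigma={v: 0.0 for v in BIOCLIM_VARS})

    def test_presence_count_matches_binomial_oracle(self, small_climate):
        # Bernoulli(S) sampling: total presences within 3 binomial SDs
        current, _ = small_climate
        species, occ = generate_virtual_species(6, current, seed=99)
        for i, sp in enumerate(species):
            s = occ.truth[i]
            n, mean_s = len(s), s.mean()
            expected = n * mean_s
            sd = np.sqrt(np.sum(s * (1 - s)))
            assert abs(occ.values[i].sum() - expected) <= max(3 * sd, 6)

    def test_truth_in_unit_interval_and_min_presences(self, small_species):
        _, occ = small_species
        assert occ.truth.min() >= 0 and occ.truth.max() <= 1
        assert (occ.values.sum(axis=1) >= 10).all()

    def test_deterministic_under_seed(self, small_climate):
        current, _ = small_climate
        _, a = generate_virtual_species(3, current, seed=5)
        _, b = generate_virtual_species(3, current, seed=5)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.truth, b.truth)

    def test_retry_cap_exhaustion_names_species(self, small_climate):
        current, _ = small_climate
        with pytest.raises(RuntimeError, match="species index 0"):
            generate_virtual_species(
                1, current, seed=5, min_presences=10_000, retry_cap=3
            )


class TestLanduse:
    def test_zero_rate_identity(self):
        pair = generate_landuse_pair((20, 20), conversion_rate=0.0, seed=1)
        assert np.array_equal(pair.t0, pair.t1)

    def test_rate_one_converts_everything(self):
        pair = generate_landuse_pair((20, 20), conversion_rate=1.0, seed=1)
        assert (pair.t1 == ANTHROPIC).all()

    def test_conversion_count_oracle(self):
        pair = generate_landuse_pair(
            (40, 25), native_fraction_t0=1.0, conversion_rate=0.2, seed=2
        )
        converted = (pair.t0 == NATIVE) & (pair.t1 == ANTHROPIC)
        assert converted.sum() == round(0.2 * 1000)
        # no reversions
        assert not ((pair.t0 == ANTHROPIC) & (pair.t1 == NATIVE)).any()

    def test_conversion_prefers_high_truth_scores(self):
        pair = generate_landuse_pair((30, 30), conversion_rate=0.3, seed=3)
        native = pair.t0 == NATIVE
        conv = native & (pair.t1 == ANTHROPIC)
        kept = native & (pair.t1 == NATIVE)
        assert pair.truth_score[conv].mean() > pair.truth_score[kept].mean()

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_landuse_pair((10, 10), conversion_rate=1.5)
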