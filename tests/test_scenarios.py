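import numpy as np
import pytest

from marinefutures import (
    GuildResponse,
    GuildSensitivity,
    build_climate_forcing,
    build_development_forcing,
    compound_increase,
    compute_ecopath_balance,
    couple_terrestrial,
    enumerate_scenarios,
    parse_scenario_id,
    whole_percent,
)
from marinefutures.dynamics import N_YEARS
from marinefutures.scenarios import climate_multiplier_series
from marinefutures.synthetic import generate_terrestrial_drivers

from conftest import make_web


class TestScenarioGrid:
    def test_full_grid_has_18_unique_cells(self):
        grid = enumerate_scenarios()
        assert len(grid) == 18
        ids = [sc.id for sc in grid]
        assert len(set(ids)) == 18

    def test_partition_by_climate_and_precipitation(self):
        grid = enumerate_scenarios()
        for level in ("low", "medium", "high"):
            assert sum(sc.climate.level == level for sc in grid) == 6
        assert sum(sc.climate.precipitation == "dry" for sc in grid) == 9

    def test_id_round_trip(self):
        for sc in enumerate_scenarios():
            assert parse_scenario_id(sc.id) == sc
        with pytest.raises(ValueError):
            parse_scenario_id("XX-YY-damp")

    def test_rcp_metadata_consistent_triples(self):
        sc = parse_scenario_id("HC-LD-dry")
        assert sc.climate.rcp_label == "RCP8.5"
        assert sc.climate.radiative_forcing == 8.5
        assert sc.climate.warming_midcentury == 2.0
        assert sc.climate.slr_midcentury == 0.30
        low = parse_scenario_id("LC-LD-dry").climate
        assert (low.rcp_label, low.radiative_forcing) == ("RCP2.6", 2.6)


class TestCompoundIncrease:
    @pytest.mark.parametrize(
        "rate,years,total_pct",
        [(0.015, 35, 68), (0.020, 35, 99), (0.025, 35, 137)],
    )
    def test_tourism_growth_mortality_totals(self, rate, years, total_pct):
        assert whole_percent(compound_increase(rate, years)) == total_pct

    def test_exact_value_before_truncation(self):
        assert compound_increase(0.015, 35) == pytest.approx(68.39, abs=0.01)

    def test_zero_growth(self):
        assert compound_increase(0.0, 20) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compound_increase(-1.5, 10)
        with pytest.raises(ValueError):
            compound_increase(0.02, -1)


@pytest.fixture
def small_guild_web():
    return make_web(
        [
            ("kelp", "producer", dict(B0=20, PB=10, site_attachment=1.0)),
            ("snail", "consumer",
             dict(B0=4, PB=2, QB=8, F0_commercial=0.1, F0_recreational=0.1,
                  site_attachment=0.5, wetland_associated=True, guild="grazers")),
            ("detritus", "detritus", dict(B0=30)),
        ],
        {"snail": {"kelp": 1.0}},
    )


class TestClimateForcing:
    def test_mean_rule_for_intermediate_rcp(self):
        resp = GuildResponse(end_rcp85=0.4, end_rcp26=0.9)
        s45 = climate_multiplier_series(resp, "medium")
        s26 = climate_multiplier_series(resp, "low")
        s85 = climate_multiplier_series(resp, "high")
        np.testing.assert_allclose(s45, 0.5 * (s26 + s85), atol=1e-12)
        assert s45[-1] == pytest.approx(0.65)

    def test_radiative_ratio_anomaly_scaling(self):
        resp = GuildResponse(end_rcp85=0.4, end_rcp26=0.9, physical=True)
        s26 = climate_multiplier_series(resp, "low")
        # anomaly -0.6 scaled by 2.6/8.5 -> multiplier 0.8165
        assert s26[-1] == pytest.approx(1.0 - 0.6 * 2.6 / 8.5, abs=1e-9)
        assert s26[-1] == pytest.approx(0.8165, abs=1e-4)

    def test_neutral_sensitivities_give_identity_forcing(self, small_guild_web):
        gs = GuildSensitivity({"grazers": GuildResponse(1.0, 1.0),
                               "producer": GuildResponse(1.0, 1.0)})
        for sid in ("LC-LD-dry", "MC-MD-wet", "HC-HD-dry"):
            f = build_climate_forcing(parse_scenario_id(sid), gs, small_guild_web)
            for arr in f.channels.values():
                np.testing.assert_array_equal(arr, 1.0)

    def test_missing_guild_is_configuration_error(self, small_guild_web):
        gs = GuildSensitivity({})
        with pytest.raises(KeyError, match="grazers"):
            build_climate_forcing(parse_scenario_id("HC-HD-dry"), gs,
                                  small_guild_web)

    def test_intermediate_level_bracketed_and_ordered(self):
        # mean rule: RCP4.5 forcing lies between RCP2.6 and RCP8.5 everywhere;
        # for a pressured guild the end multiplier is ordered low>=med>=high
        resp = GuildResponse(end_rcp85=0.3, end_rcp26=0.8)
        s26 = climate_multiplier_series(resp, "low")
        s45 = climate_multiplier_series(resp, "medium")
        s85 = climate_multiplier_series(resp, "high")
        assert ((np.minimum(s26, s85) <= s45)
                & (s45 <= np.maximum(s26, s85))).all()
        assert s26[-1] >= s45[-1] >= s85[-1]

    def test_inverse_channel_receives_reciprocal(self, small_guild_web):
        gs = GuildSensitivity({
            "grazers": GuildResponse(0.5, 0.8,
                                     channels=("consumption",
                                               "inv:natural_mortality")),
            "producer": GuildResponse(1.0, 1.0),
        })
        f = build_climate_forcing(parse_scenario_id("HC-HD-dry"), gs,
                                  small_guild_web)
        i = small_guild_web.index("snail")
        np.testing.assert_allclose(
            f.channels["natural_mortality"][i],
            1.0 / f.channels["consumption"][i],
        )

    def test_rcp26_must_be_milder_than_rcp85(self):
        with pytest.raises(ValueError, match="closer to 1"):
            GuildResponse(end_rcp85=0.9, end_rcp26=0.5)


class TestDevelopmentForcing:
    def _forcing(self, web, sid, **kw):
        sc = parse_scenario_id(sid)
        drivers = generate_terrestrial_drivers(sc)
        bw = compute_ecopath_balance(web)
        return build_development_forcing(sc, drivers, web, bw.M0, **kw)

    def test_recreational_f_doubles_under_medium_growth(self, small_guild_web):
        f = self._forcing(small_guild_web, "LC-MD-dry")
        i = small_guild_web.index("snail")
        # half the baseline F is recreational; it compounds at 2%/yr
        expected = 0.5 + 0.5 * 1.02**35
        assert f.channels["fishing_mortality"][i, -1] == pytest.approx(expected)
        assert 1.02**35 == pytest.approx(2.0, abs=0.01)  # the ~99% increase

    def test_baseline_node_is_exactly_one(self, small_guild_web):
        f = self._forcing(small_guild_web, "HC-HD-wet")
        for arr in f.channels.values():
            np.testing.assert_array_equal(arr[:, 0], 1.0)

    def test_high_vs_low_growth_ratio(self, small_guild_web):
        fh = self._forcing(small_guild_web, "LC-HD-dry")
        fl = self._forcing(small_guild_web, "LC-LD-dry")
        i = small_guild_web.index("snail")
        # pure recreational component would give (1.025/1.015)^35 ~ 1.41
        assert (1.025 / 1.015) ** 35 == pytest.approx(1.41, abs=0.01)
        assert fh.channels["fishing_mortality"][i, -1] > \
            fl.channels["fishing_mortality"][i, -1]

    def test_monotone_in_time_for_positive_growth(self, small_guild_web):
        f = self._forcing(small_guild_web, "MC-MD-dry")
        i = small_guild_web.index("snail")
        assert (np.diff(f.channels["fishing_mortality"][i]) > 0).all()

    def test_mortality_caps_clip_increment(self, small_guild_web):
        bw = compute_ecopath_balance(small_guild_web)
        i = small_guild_web.index("snail")
        f_uncapped = self._forcing(small_guild_web, "HC-HD-wet")
        f_capped = self._forcing(small_guild_web, "HC-HD-wet",
                                 tourism_mortality_cap=0.001,
                                 other_use_mortality_cap=0.001)
        m_unc = f_uncapped.channels["natural_mortality"][i, -1]
        m_cap = f_capped.channels["natural_mortality"][i, -1]
        sigma = 0.5
        assert m_cap <= m_unc
        assert m_cap <= 1.0 + sigma * 0.002 / bw.M0[i] + 1e-12


class TestTerrestrialCoupling:
    def test_wetland_gain_maps_to_channels(self, small_guild_web):
        sc = parse_scenario_id("HC-HD-wet")
        drivers = generate_terrestrial_drivers(sc)
        assert drivers.wetland_estuary_area[-1] == pytest.approx(1.179)
        f = couple_terrestrial(drivers, small_guild_web)
        i = small_guild_web.index("snail")
        assert f.channels["consumption"][i, -1] == pytest.approx(1.179)
        assert f.channels["natural_mortality"][i, -1] == pytest.approx(
            1 / 1.179, abs=1e-9
        )
        assert f.channels["natural_mortality"][i, -1] == pytest.approx(0.848,
                                                                       abs=1e-3)
        assert f.channels["vulnerability"][i, -1] == pytest.approx(1 / 1.179)
        # non-associated group untouched
        j = small_guild_web.index("kelp")
        for arr in f.channels.values():
            np.testing.assert_array_equal(arr[j], 1.0)

    def test_constant_wetland_is_identity(self, small_guild_web):
        sc = parse_scenario_id("HC-HD-wet")
        drivers = generate_terrestrial_drivers(sc)
        drivers.wetland_estuary_area = np.ones(N_YEARS)
        f = couple_terrestrial(drivers, small_guild_web)
        for arr in f.channels.values():
            np.testing.assert_array_equal(arr, 1.0)

    def test_nonpositive_wetland_rejected(self, small_guild_web):
        sc = parse_scenario_id("HC-HD-wet")
        drivers = generate_terrestrial_drivers(sc)
        with pytest.raises(ValueError):
            drivers.wetland_estuary_area[5] = -1.0
            couple_terrestrial(drivers, small_guild_web)
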