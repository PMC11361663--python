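"""Factorial requirement calculators and the three-system comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dairymin import requirements as rq


class TestNetComponents:
    @pytest.mark.parametrize("mineral,bw,expected", [
        ("P", 700, 18.40),
        ("Ca", 500, 38.11),
    ])
    def test_net_maintenance(self, mineral, bw, expected):
        assert rq.net_maintenance(mineral, bw) == pytest.approx(expected, abs=0.01)

    def test_net_maintenance_monotone_in_bw(self):
        vals = [rq.net_maintenance("P", bw) for bw in (400, 500, 600, 700)]
        assert (np.diff(vals) > 0).all()

    @pytest.mark.parametrize("mineral,breed,my,expected", [
        ("P", "Holstein", 50, 45.0),
        ("Ca", "Jersey", 10, 13.8),
        ("P", "Jersey", 0, 0.0),
    ])
    def test_net_lactation(self, mineral, breed, my, expected):
        assert rq.net_lactation(mineral, breed, my) == pytest.approx(expected)

    def test_unknown_breed_needs_override(self):
        with pytest.raises(ValueError, match="override"):
            rq.net_lactation("P", "Gir", 20)
        assert rq.net_lactation("P", "Gir", 20, milk_conc_override=0.95) == 19.0


class TestProposedSystem:
    def test_high_yield_worked_example(self):
        res = rq.proposed_requirement(
            rq.Scenario(mineral="P", bw=700, milk_yield=50, dmi=27.0))
        r = res.rounded()
        assert r["dir"] == 92
        assert r["dietary_conc"] == 3.4

    def test_mid_yield_worked_example(self):
        res = rq.proposed_requirement(
            rq.Scenario(mineral="P", bw=600, milk_yield=30, dmi=20.7))
        r = res.rounded()
        assert r["dir"] == 63
        assert r["dietary_conc"] == 3.0

    def test_unit_mc_returns_net_total(self):
        sc = rq.Scenario(mineral="Ca", bw=650, milk_yield=35)
        res = rq.proposed_requirement(sc, mc=1.0)
        assert res.dir == res.net_total

    def test_dir_consistency_invariant(self):
        res = rq.proposed_requirement(rq.Scenario(mineral="P", bw=620, milk_yield=28))
        assert res.dir == pytest.approx((res.nrm + res.nrl) / res.mc_or_ac, abs=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(bw=st.floats(320, 750), my=st.floats(0, 52))
    def test_dir_increasing_in_bw_and_yield(self, bw, my):
        base = rq.proposed_requirement(rq.Scenario(mineral="P", bw=bw, milk_yield=my))
        more_bw = rq.proposed_requirement(rq.Scenario(mineral="P", bw=bw + 25, milk_yield=my))
        more_my = rq.proposed_requirement(rq.Scenario(mineral="P", bw=bw, milk_yield=my + 2))
        assert more_bw.dir > base.dir
        assert more_my.dir > base.dir


class TestComparators:
    def test_nasem_p_example(self):
        res = rq.nasem2021_requirement(
            rq.Scenario(mineral="P", bw=600, milk_yield=30, dmi=20.0))
        assert res.net_total == pytest.approx(47.36)
        assert res.dir == pytest.approx(65.8, abs=0.05)

    def test_nasem_maintenance_only_limit(self):
        res = rq.nasem2021_requirement(
            rq.Scenario(mineral="P", bw=600, milk_yield=0, dmi=1e-9))
        assert res.net_total == pytest.approx(0.0006 * 600, abs=1e-6)

    def test_nasem_ca_blended_ac(self):
        res = rq.nasem2021_requirement(
            rq.Scenario(mineral="Ca", bw=700, milk_yield=50, dmi=27.0,
                        forage_frac=0.40))
        assert res.mc_or_ac == pytest.approx(0.52)
        assert res.net_total == pytest.approx(75.8, abs=0.05)
        assert res.dir == pytest.approx(145.8, abs=0.1)

    def test_nrc_ca_example(self):
        res = rq.nrc2001_requirement(
            rq.Scenario(mineral="Ca", bw=700, milk_yield=50, forage_frac=0.40))
        assert res.net_total == pytest.approx(82.7)

    def test_nrc_ca_maintenance_only(self):
        res = rq.nrc2001_requirement(
            rq.Scenario(mineral="Ca", bw=500, milk_yield=0, forage_frac=0.5))
        assert res.net_total == pytest.approx(0.031 * 500)

    def test_nrc_p_example(self):
        res = rq.nrc2001_requirement(
            rq.Scenario(mineral="P", bw=700, milk_yield=50, dmi=27.0,
                        forage_frac=0.40))
        assert res.net_total == pytest.approx(72.14)
        assert res.mc_or_ac == pytest.approx(0.676)
        assert res.dir == pytest.approx(106.7, abs=0.05)

    def test_missing_dmi_raises_named_error(self):
        with pytest.raises(ValueError, match="dmi"):
            rq.nasem2021_requirement(rq.Scenario(mineral="P", bw=600, milk_yield=30))

    @settings(max_examples=40, deadline=None)
    @given(f=st.floats(0, 1))
    def test_blended_ac_within_endpoints(self, f):
        ac = rq.blended_ac(f, 0.40, 0.60)
        assert 0.40 <= ac <= 0.60


class TestCompareSystems:
    def scenario(self):
        return rq.Scenario(mineral="P", bw=700, milk_yield=50, dmi=27.0,
                           forage_frac=0.40)

    def test_identical_systems_zero_difference(self):
        res = rq.proposed_requirement(self.scenario())
        pct = 100 * (res.net_total - res.net_total) / res.net_total
        assert pct == 0.0

    def test_ca_net_above_nrc2001(self):
        comp = rq.compare_systems(
            rq.Scenario(mineral="Ca", bw=700, milk_yield=50, dmi=27.0,
                        forage_frac=0.40))
        assert comp["pct_difference_vs"]["NRC2001"]["net_total"] == pytest.approx(30.6, abs=0.1)

    def test_p_dir_below_nrc2001(self):
        comp = rq.compare_systems(self.scenario())
        assert comp["pct_difference_vs"]["NRC2001"]["dir"] < 0


class TestPresets:
    def test_bw_interpolation_hits_anchors(self):
        assert rq.preset_bw(10) == 500
        assert rq.preset_bw(50) == 700
        assert rq.preset_bw(30) == 600

    def test_dmi_interpolation_hits_anchors(self):
        assert rq.preset_dmi(30) == pytest.approx(20.7)
        assert rq.preset_dmi(50) == pytest.approx(27.0)

    def test_reference_grid_forage_schedule(self):
        grid = rq.reference_scenarios("Ca")
        fracs = [s.forage_frac for s in grid]
        assert fracs == [0.80, 0.60, 0.50, 0.45, 0.40]
        acs = [rq.nrc2001_requirement(s).mc_or_ac for s in grid]
        assert (np.diff(acs) > 0).all()  # less forage -> higher blended AC

    def test_yaml_presets_load(self):
        presets = rq.load_preset_scenarios("P")
        assert len(presets["comparison_grid"]) == 5
        assert presets["worked_examples"][0].bw == 700


@pytest.mark.parametrize("kwargs", [
    dict(mineral="Mg", bw=600, milk_yield=20),
    dict(mineral="P", bw=-1, milk_yield=20),
    dict(mineral="P", bw=600, milk_yield=-5),
    dict(mineral="P", bw=600, milk_yield=20, forage_frac=1.5),
])
def test_invalid_scenarios_rejected(kwargs):
    with pytest.raises(ValueError):
        rq.Scenario(**kwargs).validate()
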