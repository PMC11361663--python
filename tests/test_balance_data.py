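"""Record schema, CSV round-trips, metabolic scaling and inverse-SEM weights."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dairymin import balance_data as bd

CSV_HEADER = ",".join(bd.COLUMNS)


def make_csv(rows):
    return io.StringIO(CSV_HEADER + "\n" + "\n".join(rows))


ROW_FULL = ("r1,s1,a1,P,Holstein,mixed,600,30,20,500,160,30,330,250,"
            "80,40,1,27,0.9,2.5,")
ROW_NO_BW = "r2,s1,a1,P,Jersey,fixed,,25,18,500,160,30,330,250,70,35,0.8,25,1.0,2.0,"


class TestReadDataset:
    def test_parses_valid_rows(self):
        df = bd.read_dataset(make_csv([ROW_FULL, ROW_NO_BW]))
        assert len(df) == 2
        assert df.loc[0, "intake"] == 80
        assert df.loc[0, "breed"] == "Holstein"

    def test_missing_cells_stay_missing(self):
        df = bd.read_dataset(make_csv([ROW_NO_BW]))
        assert pd.isna(df.loc[0, "bw"])  # never silently 0

    @pytest.mark.parametrize("row,match", [
        (ROW_FULL.replace(",P,", ",Mg,"), "mineral"),
        (ROW_FULL.replace(",40,1,", ",-40,1,"), "negative fecal"),
        (ROW_FULL.replace("r1,", ","), "record_id"),
    ])
    def test_rejects_bad_rows(self, row, match):
        with pytest.raises(ValueError, match=match):
            bd.read_dataset(make_csv([row]))

    def test_duplicate_record_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            bd.read_dataset(make_csv([ROW_FULL, ROW_FULL]))

    def test_round_trip_preserves_values(self, p_records, tmp_path):
        path = tmp_path / "ds.csv"
        bd.write_dataset(p_records, path)
        back = bd.read_dataset(path)
        for col in bd.COLUMNS:
            a, b = p_records[col], back[col]
            if col in bd.STRING_COLUMNS:
                assert (a == b).all()
            else:
                assert np.allclose(a.to_numpy(float), b.to_numpy(float),
                                   equal_nan=True, rtol=0, atol=1e-12)


class TestScalarHelpers:
    @pytest.mark.parametrize("sed,divisor,expected", [
        (2.0, "half", 1.0),
        (0.0, "half", 0.0),
        (3.1, "sqrt2", 2.192),
    ])
    def test_sem_from_sed(self, sed, divisor, expected):
        assert bd.sem_from_sed(sed, divisor) == pytest.approx(expected, abs=5e-4)

    def test_sem_from_sed_rejects_negative(self):
        with pytest.raises(ValueError):
            bd.sem_from_sed(-1.0)

    @pytest.mark.parametrize("bw,expected", [(1, 1.0), (700, 136.09), (500, 105.74)])
    def test_metabolic_weight(self, bw, expected):
        assert bd.metabolic_weight(bw) == pytest.approx(expected, abs=0.01)

    def test_metabolic_weight_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bd.metabolic_weight(0)


class TestScaleObservations:
    def test_hand_arithmetic(self):
        row = ("r1,s1,a1,P,Holstein,mixed,625,30,20,500,160,30,330,250,"
               "75,40,1,27,0.9,2.5,")
        obs = bd.scale_observations(bd.read_dataset(make_csv([row])))
        assert obs.loc[0, "intake_mbw"] == pytest.approx(0.600, abs=1e-9)
        assert obs.loc[0, "excretion_mbw"] == pytest.approx(0.328, abs=1e-9)

    def test_incomplete_rows_dropped(self):
        no_urinary = ROW_FULL.replace("r1,", "r9,").replace(",40,1,", ",40,,")
        obs = bd.scale_observations(bd.read_dataset(make_csv([ROW_FULL, no_urinary])))
        assert list(obs["record_id"]) == ["r1"]
        assert obs.attrs["n_dropped"] == 1

    def test_scaling_preserves_fecal_share(self, p_records):
        obs = bd.scale_observations(p_records)
        kept = p_records.set_index("record_id").loc[obs["record_id"]]
        share = kept["fecal"] / (kept["fecal"] + kept["urinary"])
        recon = (kept["fecal"] / bd.metabolic_weight(kept["bw"])) / obs.set_index("record_id")["excretion_mbw"]
        assert np.allclose(share.to_numpy(), recon.to_numpy(), atol=1e-9)


def records_with_sems(sems, model_type="mixed", sed=None):
    rows = []
    for i, s in enumerate(sems):
        sem_txt = "" if s is None else str(s)
        sed_txt = "" if sed is None else str(sed[i])
        rows.append(f"r{i},s{i % 3},a1,P,Holstein,{model_type},600,30,20,"
                    f"500,160,30,330,250,80,40,1,27,0.9,{sem_txt},{sed_txt}")
    return bd.read_dataset(make_csv(rows))


class TestComputeWeights:
    def test_uniform_sems_give_unit_weights(self):
        w = bd.compute_weights(records_with_sems([2.0, 2.0, 2.0]))
        assert np.allclose(w["weight"], 1.0)

    def test_hand_arithmetic_no_trimming(self):
        w = bd.compute_weights(records_with_sems([1.0, 2.0, 4.0]))
        assert np.allclose(w["weight"], [12 / 7, 6 / 7, 3 / 7])
        assert not w["trimmed"].any()

    def test_trimming_floor_applied(self):
        w = bd.compute_weights(records_with_sems([0.1, 2.0, 4.0]))
        floor = 0.35 * (0.1 + 2.0 + 4.0) / 3
        assert w.loc[0, "trimmed"]
        assert w.loc[0, "w1"] == pytest.approx(1.0 / floor)

    def test_missing_sem_imputed_with_group_mean(self):
        w = bd.compute_weights(records_with_sems([2.0, None, 4.0]))
        assert w.loc[1, "imputed_sem"]
        assert w.loc[1, "w1"] == pytest.approx(1.0 / 3.0)

    def test_sed_fallback_uses_half_rule(self):
        rec = records_with_sems([None, 3.0, 3.0], model_type="fixed",
                                sed=[4.0, None, None])
        w = bd.compute_weights(rec)
        assert not w.loc[0, "imputed_sem"]
        assert w.loc[0, "w1"] == pytest.approx(1.0 / 2.0)

    def test_all_missing_group_raises(self):
        with pytest.raises(ValueError, match="impute"):
            bd.compute_weights(records_with_sems([None, None, None]))

    def test_group_means_are_one(self, p_records):
        w = bd.compute_weights(p_records)
        for _, grp in w.groupby("model_group"):
            assert grp["weight"].mean() == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.5, 50.0), min_size=3, max_size=12))
    def test_weights_antitone_in_sem(self, sems):
        w = bd.compute_weights(records_with_sems(sorted(sems)))
        diffs = np.diff(w["weight"].to_numpy())
        assert (diffs <= 1e-12).all()
        assert w["weight"].mean() == pytest.approx(1.0, abs=1e-9)
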