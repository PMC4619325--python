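"""Deviation metrics, four-zone classification, references and summaries."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcqc import chem
from lcqc.io_formats import SequenceEntry, TargetFeature
from lcqc.qc_metrics import (
    FeatureResult,
    ToleranceScheme,
    area_bias,
    classify,
    evaluate_results,
    ppm_error,
    rt_deviation,
    summarize,
)


def _entry(name="QCstd_01.mzXML", seq="sequence1", idx=1):
    return SequenceEntry(file_path=Path(name), sequence_id=seq, order_index=idx, missing=True)


def _target(name="JA", rt=1284.0):
    return TargetFeature(
        name=name, ion=chem.get_ion("[M+H]+"), expected_rt_s=rt,
        formula=chem.parse_formula("C12H18O3"),
    )


class TestPpmError:
    def test_worked_example(self):
        assert round(ppm_error(211.1340, 211.1329), 2) == 5.21

    def test_identity_is_zero(self):
        assert ppm_error(211.1329, 211.1329) == 0.0

    def test_antisymmetric_to_first_order(self):
        a, b = 211.1340, 211.1329
        assert ppm_error(a, b) == pytest.approx(-ppm_error(b, a), rel=1e-4)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


class TestRtDeviation:
    def test_signed_subtraction(self):
        assert rt_deviation(1278.0, 1284.0) == -6.0  # −0.1 min


class TestAreaBias:
    def test_three_area_example(self):
        areas = [1.0e5, 1.2e5, 0.8e5]
        ref = float(np.mean(areas))
        assert [round(area_bias(a, ref), 10) for a in areas] == [0.0, 20.0, -20.0]

    def test_constant_areas_have_zero_bias(self):
        assert area_bias(5e4, 5e4) == 0.0


class TestClassify:
    @pytest.mark.parametrize(
        "value,zone",
        [(3.0, "green"), (-3.0, "green"), (5.0, "yellow"), (8.0, "orange"),
         (8.0001, "red"), (-8.0001, "red"), (0.0, "green"), (4.2, "yellow")],
    )
    def test_printed_ppm_scheme_boundaries_inclusive(self, value, zone):
        assert classify(value, (3.0, 5.0, 8.0)) == zone

    def test_missing_value_maps_to_missing(self):
        assert classify(None, (3, 5, 8)) == "missing"
        assert classify(float("nan"), (3, 5, 8)) == "missing"

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=-20, max_value=20), st.floats(min_value=0.01, max_value=19))
    def test_monotone_in_absolute_value(self, v, step):
        order = ["green", "yellow", "orange", "red"]
        z1 = classify(v, (3, 5, 8))
        z2 = classify(abs(v) + step, (3, 5, 8))
        assert order.index(z2) >= order.index(z1)

    def test_rejects_non_ascending_limits(self):
        with pytest.raises(ValueError):
            classify(1.0, (5, 3, 8))

    def test_scheme_validates_limits(self):
        with pytest.raises(ValueError):
            ToleranceScheme(ppm_limits=(5.0, 3.0, 8.0))


class TestEvaluateResults:
    def _results(self, areas, seq="sequence1"):
        t = _target()
        out = []
        for i, a in enumerate(areas, start=1):
            out.append(
                FeatureResult(
                    feature=t, entry=_entry(f"QCstd_{i:02d}.mzXML", seq, i),
                    category="QCstd", found=True,
                    rt_s=1284.0, mz=211.1329, area=a,
                )
            )
        return out

    def test_data_mean_area_bias_averages_to_zero(self):
        res = evaluate_results(self._results([1.0e5, 1.2e5, 0.8e5]), ToleranceScheme())
        biases = [r.area_bias_pct for r in res]
        assert np.mean(biases) == pytest.approx(0.0, abs=1e-9)
        assert sorted(round(b, 6) for b in biases) == [-20.0, 0.0, 20.0]

    def test_every_found_result_gets_exactly_one_zone_per_parameter(self):
        res = evaluate_results(self._results([1.0, 2.0, 3.0]), ToleranceScheme())
        for r in res:
            assert set(r.zones) == {"rt", "ppm", "area"}
            assert all(z in ("green", "yellow", "orange", "red", "missing") for z in r.zones.values())

    def test_not_found_is_all_missing(self):
        t = _target()
        res = evaluate_results(
            [FeatureResult(feature=t, entry=_entry(), category="QCstd", found=False)],
            ToleranceScheme(),
        )
        assert res[0].zones == {"rt": "missing", "ppm": "missing", "area": "missing"}
        assert res[0].area_bias_pct is None

    def test_single_file_scope_under_data_mean_deviates_zero(self):
        scheme = ToleranceScheme(reference_mode={"rt": "data_mean", "ppm": "data_mean", "area": "data_mean"})
        res = evaluate_results(self._results([7e4]), scheme)
        assert res[0].rt_dev_s == pytest.approx(0.0)
        assert res[0].ppm_error == pytest.approx(0.0)
        assert res[0].area_bias_pct == pytest.approx(0.0)

    def test_per_sequence_scope_keeps_sequences_apart(self):
        res = self._results([1.0e5, 1.0e5], "sequence1") + self._results([2.0e5, 2.0e5], "sequence2")
        out = evaluate_results(res, ToleranceScheme())
        assert all(r.area_bias_pct == pytest.approx(0.0) for r in out)

    def test_fixed_references_come_from_target_list(self):
        res = evaluate_results(self._results([1e5]), ToleranceScheme())
        r = res[0]
        assert r.rt_dev_s == pytest.approx(r.rt_s - r.feature.expected_rt_s)
        assert r.ppm_error == pytest.approx(ppm_error(r.mz, r.feature.theoretical_mz))


class TestSummarize:
    def test_mean_and_sample_sd(self):
        t = _target()
        res = [
            FeatureResult(feature=t, entry=_entry(f"QCstd_{i}.mzXML", idx=i),
                          category="QCstd", found=True, area=a)
            for i, a in enumerate([2.0, 4.0], start=1)
        ]
        stats = summarize(res)
        row = stats[(stats.scope == "sequence")].iloc[0]
        assert row["n"] == 2
        assert row["area_mean"] == pytest.approx(3.0)
        assert row["area_sd"] == pytest.approx(np.sqrt(2.0))

    def test_rsd_of_constant_vector_is_zero(self):
        t = _target()
        res = [
            FeatureResult(feature=t, entry=_entry(f"QCstd_{i}.mzXML", idx=i),
                          category="QCstd", found=True, area=5.0)
            for i in range(1, 4)
        ]
        stats = summarize(res)
        assert stats[stats.scope == "category"].iloc[0]["area_rsd_pct"] == pytest.approx(0.0)

    def test_all_not_found_group_has_n_zero_and_missing_stats(self):
        t = _target()
        res = [FeatureResult(feature=t, entry=_entry(), category="blank", found=False)]
        stats = summarize(res)
        row = stats[stats.scope == "category"].iloc[0]
        assert row["n"] == 0 and row["n_missing"] == 1
        assert np.isnan(row["area_mean"])
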