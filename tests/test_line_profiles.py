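import numpy as np
import pytest

from sisterres.io_formats import ProfileRecord
from sisterres import line_profiles as lp
from sisterres.phantom_sim import PhantomSpec, generate_phantom, \
    sample_ground_truth_profiles


def record(positions, **channels):
    return ProfileRecord("c", "l", np.asarray(positions, dtype=float),
                         {k: np.asarray(v, dtype=float)
                          for k, v in channels.items()})


def gaussian(pos, center, sigma=0.15):
    return np.exp(-((pos - center) ** 2) / (2 * sigma ** 2))


class TestMinMaxNormalize:
    def test_simple_scaling(self):
        rec = record([0, 1, 2], dna=[2, 4, 6])
        norm = lp.minmax_normalize(rec)
        np.testing.assert_allclose(norm.channels["dna"], [0, 0.5, 1])

    def test_idempotent_on_unit_range(self):
        rec = record([0, 1, 2], dna=[0.0, 0.5, 1.0])
        norm = lp.minmax_normalize(rec)
        np.testing.assert_allclose(norm.channels["dna"], [0, 0.5, 1])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 20)
        pos = np.arange(20) * 0.05
        a = lp.minmax_normalize(record(pos, dna=v))
        b = lp.minmax_normalize(record(pos, dna=3.7 * v + 11.0))
        np.testing.assert_allclose(a.channels["dna"], b.channels["dna"],
                                   atol=1e-12)

    def test_constant_channel_rejected(self):
        with pytest.raises(lp.ProfileRejected):
            lp.minmax_normalize(record([0, 1, 2], dna=[5, 5, 5]))


class TestDnaMinusLabel:
    def test_worked_example(self):
        norm = lp.NormalizedProfile("c", "l", np.array([0.0, 1.0, 2.0]),
                                    {"dna": np.array([0.2, 0.8, 1.0]),
                                     "label": np.array([0.5, 0.4, 1.0])})
        out = lp.dna_minus_label(norm)
        np.testing.assert_allclose(out, [0.0, 1.1 / 1.3, 1.0], atol=1e-9)

    def test_label_below_dna_is_renormalized_dna(self):
        dna = np.array([0.0, 0.4, 1.0, 0.2])
        norm = lp.NormalizedProfile("c", "l", np.arange(4.0),
                                    {"dna": dna, "label": dna * 0.5})
        np.testing.assert_allclose(lp.dna_minus_label(norm), dna)

    def test_label_equal_dna_keeps_dna(self):
        dna = np.array([0.0, 0.5, 1.0])
        norm = lp.NormalizedProfile("c", "l", np.arange(3.0),
                                    {"dna": dna, "label": dna.copy()})
        np.testing.assert_allclose(lp.dna_minus_label(norm), dna)

    def test_output_spans_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(8, 40)
            norm = lp.NormalizedProfile(
                "c", "l", np.arange(n, dtype=float),
                {"dna": rng.uniform(0, 1, n), "label": rng.uniform(0, 1, n)})
            out = lp.dna_minus_label(norm)
            assert out.min() == 0.0 and out.max() == 1.0


class TestFitAndFindPeaks:
    def test_single_bump_centered(self):
        pos = np.arange(41) * 0.05
        norm = lp.NormalizedProfile("c", "l", pos,
                                    {"smc": gaussian(pos, 1.0)})
        peaks = lp.fit_and_find_peaks(norm, "smc")
        assert len(peaks.positions["smc"]) == 1
        assert peaks.positions["smc"][0] == pytest.approx(1.0, abs=0.05)

    def test_two_bumps_sorted(self):
        pos = np.arange(41) * 0.05
        y = gaussian(pos, 0.5) + gaussian(pos, 1.5)
        norm = lp.NormalizedProfile("c", "l", pos, {"smc": y / y.max()})
        peaks = lp.fit_and_find_peaks(norm, "smc")
        got = peaks.positions["smc"]
        assert len(got) == 2 and got[0] < got[1]
        np.testing.assert_allclose(got, [0.5, 1.5], atol=0.08)

    def test_too_few_samples_rejected(self):
        pos = np.arange(3) * 0.05
        norm = lp.NormalizedProfile("c", "l", pos, {"smc": [0.0, 1.0, 0.5]})
        with pytest.raises(lp.ProfileRejected):
            lp.fit_and_find_peaks(norm, "smc", lp.PeakParams(fit_degree=5,
                                                             degree_cap_divisor=1))


class TestClassifyAndMeasure:
    def _peaks(self, smc, label, dml):
        return lp.PeakSet(
            positions={"smc": np.asarray(smc, dtype=float),
                       "label": np.asarray(label, dtype=float),
                       "dna_minus_label": np.asarray(dml, dtype=float)},
            heights={k: np.ones(len(v)) for k, v in
                     [("smc", smc), ("label", label),
                      ("dna_minus_label", dml)]})

    @pytest.mark.parametrize("smc, mode, ok", [
        ([0.6], "single", True),
        ([0.4, 1.2], "single", False),
        ([0.4, 1.2], "split", True),
        ([0.6], "split", False),
    ])
    def test_peak_count_rules(self, smc, mode, ok):
        peaks = self._peaks(smc, [0.3], [0.9])
        accepted, reason = lp.classify_profile(peaks, mode)
        assert accepted is ok
        if not ok:
            assert "expected" in reason

    def test_extra_label_peak_rejected(self):
        peaks = self._peaks([0.6], [0.3, 0.8], [0.9])
        accepted, _ = lp.classify_profile(peaks, "single")
        assert not accepted

    def test_peak_to_peak(self):
        assert lp.peak_to_peak(self._peaks([0.6], [0.4], [1.0])) == \
            pytest.approx(0.6)
        assert lp.peak_to_peak(self._peaks([0.6], [0.7], [0.7])) == 0.0

    def test_radial_displacement_single_axis_outward(self):
        d, tie = lp.radial_displacement(self._peaks([0.6], [0.3], [0.9]),
                                        "single")
        assert d == pytest.approx(0.3) and not tie

    def test_radial_displacement_coincident(self):
        d, _ = lp.radial_displacement(self._peaks([0.5], [0.5], [0.9]),
                                      "single")
        assert d == 0.0

    def test_radial_displacement_split_nearest_axis_inward(self):
        d, tie = lp.radial_displacement(
            self._peaks([0.4, 1.2], [0.5], [1.1]), "split")
        assert d == pytest.approx(-0.1) and not tie

    def test_radial_displacement_tie_flagged_lower_axis(self):
        d, tie = lp.radial_displacement(
            self._peaks([0.4, 1.2], [0.8], [1.1]), "split")
        assert tie and d == pytest.approx(-0.4)

    def test_measure_profile_rejections_are_reported(self):
        pos = np.arange(20) * 0.05
        rec = record(pos, smc=gaussian(pos, 0.3) + gaussian(pos, 0.7),
                     label=gaussian(pos, 0.3), dna=gaussian(pos, 0.5))
        m = lp.measure_profile(rec, "single")
        assert not m.accepted and m.reason


class TestPhantomRecovery:
    @pytest.mark.parametrize("sep_nm", [300.0, 500.0, 700.0])
    def test_peak_to_peak_recovers_true_separation(self, sep_nm):
        spec = PhantomSpec(label_mode="one_sister", separation_d=sep_nm,
                           axis_mode="single", poisson=False, gaussian_sd=0.0)
        _, truth = generate_phantom(spec)
        recs = sample_ground_truth_profiles(spec, truth, n_lines=3)
        step_um = 0.05
        for rec in recs:
            m = lp.measure_profile(rec, "single")
            assert m.accepted, m.reason
            assert abs(m.dna_peak_distance - sep_nm / 1000.0) <= step_um

    def test_invariance_to_channel_rescaling(self):
        spec = PhantomSpec(label_mode="one_sister", separation_d=500.0,
                           axis_mode="single", poisson=False, gaussian_sd=0.0)
        _, truth = generate_phantom(spec)
        rec = sample_ground_truth_profiles(spec, truth, n_lines=1)[0]
        m0 = lp.measure_profile(rec, "single")
        scaled = ProfileRecord(rec.cell_id, rec.line_id, rec.positions, {
            "smc": 3.0 * rec.intensities["smc"] + 50.0,
            "label": 0.2 * rec.intensities["label"] + 7.0,
            "dna": 11.0 * rec.intensities["dna"] + 2.0})
        m1 = lp.measure_profile(scaled, "single")
        assert m1.dna_peak_distance == pytest.approx(m0.dna_peak_distance,
                                                     abs=1e-9)
        assert m1.radial_displacement == pytest.approx(m0.radial_displacement,
                                                       abs=1e-9)


class TestAlignProfiles:
    def _norm(self, pos, smc, label):
        dna = np.maximum(smc, label)
        n = lp.NormalizedProfile("c", "l", np.asarray(pos, dtype=float),
                                 {"smc": smc, "label": label, "dna": dna})
        n.channels["dna_minus_label"] = dna
        return n

    def test_single_profile_recentered(self):
        pos = np.arange(41) * 0.05
        n = self._norm(pos, gaussian(pos, 1.2), gaussian(pos, 0.8))
        out = lp.align_profiles([n], "single",
                                channels=("label",))
        peak = out["position"][np.nanargmax(out["label"])]
        assert peak == pytest.approx(0.8 - 1.2, abs=0.06)

    def test_mirror_profiles_average_symmetric(self):
        pos = np.arange(41) * 0.05
        smc = gaussian(pos, 1.0)
        a = self._norm(pos, smc, gaussian(pos, 0.7))
        b = self._norm(pos, smc, gaussian(pos, 1.3))
        out = lp.align_profiles([a, b], "single", channels=("label",))
        g, v = out["position"], out["label"]
        keep = ~np.isnan(v)
        sym = np.interp(-g[keep], g[keep], v[keep])
        # symmetric up to linear-interpolation error of the fitted anchor
        np.testing.assert_allclose(v[keep], sym, atol=0.02)

    def test_split_axis_phantom_mean_smc_equidistant(self):
        spec = PhantomSpec(label_mode="one_sister", separation_d=600.0,
                           axis_mode="split", poisson=False, gaussian_sd=0.0)
        _, truth = generate_phantom(spec)
        recs = sample_ground_truth_profiles(spec, truth, n_lines=4)
        norms = [lp.minmax_normalize(r) for r in recs]
        out = lp.align_profiles(norms, "split", channels=("smc",))
        g, v = out["position"], np.nan_to_num(out["smc"])
        left = g[(g < 0)][np.argmax(v[g < 0])]
        right = g[(g > 0)][np.argmax(v[g > 0])]
        assert abs(left + right) <= 0.06


class TestPercentages:
    def test_percent_split_examples(self):
        meas = [lp.AxisSegmentMeasurement("a", 10.0, 8.0, 2.0),
                lp.AxisSegmentMeasurement("b", 5.0, 0.0, 5.0)]
        out = lp.percent_split_axes(meas)
        assert out == {"a": pytest.approx(80.0), "b": 0.0}

    def test_percent_fragments_example(self):
        meas = [lp.FragmentMeasurement("a", {0: 0.0, 1: 9.0, 2: 1.0})]
        out = lp.percent_labelled_fragments(meas)
        assert out["a"] == {0: 0.0, 1: pytest.approx(90.0),
                            2: pytest.approx(10.0)}

    def test_single_class_is_hundred_percent(self):
        meas = [lp.FragmentMeasurement("a", {2: 4.2})]
        assert lp.percent_labelled_fragments(meas)["a"][2] == \
            pytest.approx(100.0)

    def test_zero_total_cells_skipped(self):
        meas = [lp.AxisSegmentMeasurement("a", 0.0, 0.0, 0.0)]
        assert lp.percent_split_axes(meas) == {}

    def test_matches_pandas_group_oracle(self):
        import pandas as pd
        rng = np.random.default_rng(7)
        meas = []
        for _ in range(300):
            cell = f"c{rng.integers(0, 20)}"
            split, single = rng.uniform(0, 5, 2)
            meas.append(lp.AxisSegmentMeasurement(cell, split + single,
                                                  split, single))
        got = lp.percent_split_axes(meas)
        df = pd.DataFrame([(m.cell_id, m.split_length, m.single_length)
                           for m in meas],
                          columns=["cell", "split", "single"])
        grp = df.groupby("cell").sum()
        want = (100 * grp.split / (grp.split + grp.single)).to_dict()
        assert got.keys() == want.keys()
        for cell in got:
            assert got[cell] == pytest.approx(want[cell])

    def test_fragment_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(8)
        meas = [lp.FragmentMeasurement(
                    f"c{rng.integers(0, 10)}",
                    {0: rng.uniform(0, 2), 1: rng.uniform(0, 2),
                     2: rng.uniform(0, 2)})
                for _ in range(200)]
        for percs in lp.percent_labelled_fragments(meas).values():
            assert sum(percs.values()) == pytest.approx(100.0, abs=1e-9)
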