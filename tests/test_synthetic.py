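"""Determinism, closed forms, and validity of the synthetic generators."""

import numpy as np
import pytest

from g4condense import synthetic as syn
from g4condense.errors import InvalidParameterError
from g4condense.gquad import enumerate_qgrs


class TestPromoterCounts:
    def test_degenerate_all_enriched(self):
        table, truth = syn.gen_promoter_counts(0, 5, enriched_scale=100,
                                               seed=1)
        assert len(table.promoter_ids) == 5
        assert all(truth.labels["enriched"].values())

    def test_mixture_means_ordered(self):
        table, _ = syn.gen_promoter_counts(1000, 50, 3, 60, 0.5, seed=7)
        bg = table.counts[~table.truth_labels]
        en = table.counts[table.truth_labels]
        assert len(table.promoter_ids) == 1050
        assert en.mean() > bg.mean()
        # sample means agree with the generating means
        assert bg.mean() == pytest.approx(3.0, rel=0.15)
        assert en.mean() == pytest.approx(60.0, rel=0.15)

    def test_determinism(self):
        a, _ = syn.gen_promoter_counts(100, 10, 3, 60, 0.5, seed=7)
        b, _ = syn.gen_promoter_counts(100, 10, 3, 60, 0.5, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            syn.gen_promoter_counts(0, 0, 3, 60, 0.5)        # empty
        with pytest.raises(InvalidParameterError):
            syn.gen_promoter_counts(100, 10, 60, 3, 0.5)     # scales swapped
        with pytest.raises(InvalidParameterError):
            syn.gen_promoter_counts(100, 10, 3, 60, -1.0)


class TestSensorgram:
    def test_kobs_slope_check(self):
        # finite-difference log-slope of the noiseless association phase
        ka, kd, conc = 2.5e5, 5.9e-4, 457e-9
        traces, _ = syn.gen_sensorgram("one_to_one",
                                       {"k_a": ka, "k_d": kd}, [conc],
                                       t_assoc=60, t_dissoc=1, dt=0.5)
        t, y = traces[0].phase_slice("association")
        asym = conc / (conc + kd / ka)
        slope = np.diff(np.log(asym - y[:-20])) / np.diff(t[:-20])
        assert np.allclose(-slope, ka * conc + kd, rtol=1e-6)

    def test_two_step_reduction_limit(self):
        common = dict(analyte_concentrations=[457e-9], t_assoc=120,
                      t_dissoc=120, dt=1.0, noise_sd=0.0, seed=0)
        one, _ = syn.gen_sensorgram("one_to_one",
                                    {"k_a": 2e5, "k_d": 1e-3}, **common)
        two, _ = syn.gen_sensorgram(
            "two_step", {"k_on1": 2e5, "k_off1": 1e-3, "k_on2": 0.0,
                         "k_off2": 0.0, "R1": 1.0, "R2": 1.0}, **common)
        assert np.allclose(one[0].response, two[0].response, atol=1e-12)

    def test_determinism_with_noise(self):
        kw = dict(model="one_to_one", params={"k_a": 2e5, "k_d": 1e-3},
                  analyte_concentrations=[1e-7], t_assoc=50, t_dissoc=50,
                  dt=1.0, noise_sd=0.05, seed=12)
        a, _ = syn.gen_sensorgram(**kw)
        b, _ = syn.gen_sensorgram(**kw)
        assert np.array_equal(a[0].response, b[0].response)

    def test_unknown_model_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.gen_sensorgram("three_step", {}, [1e-9])


class TestHillCurve:
    def test_half_saturation_and_asymptotes(self):
        kd = 19.1e-9
        curve, _ = syn.gen_hill_curve(kd, 4.42, 1.0,
                                      [1e-12, kd, 1e-4])
        assert curve.fractions[0] == pytest.approx(0.0, abs=1e-6)
        assert curve.fractions[1] == pytest.approx(0.5)
        assert curve.fractions[2] == pytest.approx(1.0, abs=1e-3)

    def test_log_slope_at_kd_equals_h(self):
        kd, h = 19.1e-9, 4.42
        X = np.geomspace(kd / 1.05, kd * 1.05, 7)
        curve, _ = syn.gen_hill_curve(kd, h, 1.0, X)
        y = curve.fractions
        slope = np.gradient(np.log(y / (1 - y)), np.log(X))
        assert slope[3] == pytest.approx(h, rel=1e-3)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.gen_hill_curve(1e-9, 1.0, 1.0, [])

    def test_noise_truncated_to_units(self):
        curve, _ = syn.gen_hill_curve(1e-9, 1.0, 1.0,
                                      np.geomspace(1e-11, 1e-7, 20),
                                      n_replicates=5, noise_sd=0.3, seed=2)
        assert np.all(curve.fractions >= 0)
        assert np.all(curve.fractions <= 1.0)


class TestFrapTraceGen:
    def test_noiseless_correction_is_identity(self):
        trace, _ = syn.gen_frap_trace(tau1=40, A1=0.4, tau2=4, A2=0.1,
                                      bleach_depth=0.6, bg_level=0.0,
                                      ref_drift=0.0, noise_sd=0.0)
        from g4condense.frap import correct_trace
        corr = correct_trace(trace)
        t = trace.time[trace.bleach_index:]
        expected = 0.4 + 0.4 * (1 - np.exp(-t / 40)) \
            + 0.1 * (1 - np.exp(-t / 4))
        assert np.allclose(corr[trace.bleach_index:], expected)

    def test_single_component_when_A2_zero(self):
        trace, _ = syn.gen_frap_trace(tau1=40, A1=0.5, A2=0.0,
                                      bleach_depth=0.7, noise_sd=0.0)
        from g4condense.frap import correct_trace
        corr = correct_trace(trace)
        t = trace.time[trace.bleach_index:]
        assert np.allclose(corr[trace.bleach_index:],
                           0.3 + 0.5 * (1 - np.exp(-t / 40)))

    def test_amplitude_constraint_enforced(self):
        with pytest.raises(InvalidParameterError):
            syn.gen_frap_trace(A1=0.5, A2=0.3, bleach_depth=0.7)


class TestDropletImageGen:
    def test_zero_droplets_pure_background(self):
        img, _ = syn.gen_droplet_image(32, 32, [], background_level=7.0,
                                       noise_sd=0.0, seed=0)
        assert np.all(img == 7.0)

    def test_determinism(self):
        kw = dict(width=64, height=64,
                  droplets=[((20, 20), 5, 100)], noise_sd=3.0, seed=5)
        a, _ = syn.gen_droplet_image(**kw)
        b, _ = syn.gen_droplet_image(**kw)
        assert np.array_equal(a, b)

    def test_overlap_flagged(self):
        _, truth = syn.gen_droplet_image(
            64, 64, [((20, 20), 6, 100), ((22, 22), 6, 100)],
            noise_sd=0, seed=0)
        assert truth.labels["overlapping"]

    def test_out_of_canvas_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.gen_droplet_image(32, 32, [((2, 2), 5, 100)])


class TestG4SequenceGen:
    def test_construction(self):
        seq, _ = syn.gen_g4_sequence(4, 3, [1, 1, 1], flank_length=0)
        assert len(seq) == 15
        assert seq[0:3] == "GGG" and seq[4:7] == "GGG"
        assert seq[3] in "ACT"

    def test_length_arithmetic(self):
        seq, _ = syn.gen_g4_sequence(2, 2, [7], flank_length=5)
        assert len(seq) == 2 * 2 + 7 + 2 * 5

    def test_loop_count_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.gen_g4_sequence(4, 3, [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_always_detectable(self, seed):
        seq, truth = syn.gen_g4_sequence(4, 3, [2, 3, 2], flank_length=8,
                                         seed=seed)
        cands = enumerate_qgrs(seq)
        assert any(c.start == truth.labels["motif_start"]
                   and c.loop_lengths == (2, 3, 2) for c in cands)


def test_sim_truth_json_round_trip(tmp_path):
    _, truth = syn.gen_promoter_counts(20, 5, 3, 60, 0.5, seed=1)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    import json
    back = json.loads(path.read_text())
    assert back["generator_name"] == "gen_promoter_counts"
    assert back["seed"] == 1
    assert back["params"]["n_enriched"] == 5
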