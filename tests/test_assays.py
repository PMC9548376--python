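import numpy as np
import pandas as pd
import pytest

from fuccitrack.assays import (ddct_fold_change, gate_dna_content, nc_ratio,
                               percent_change, quantify_rois)
from fuccitrack.synthetic import (simulate_ct_table, simulate_nuclei_field,
                                  simulate_pi_events)


class TestGateDnaContent:
    def test_single_population_is_all_g0g1(self):
        ev = simulate_pi_events((1.0, 0.0, 0.0), 0.05, 5000, seed=1)
        fr = gate_dna_content(ev)
        assert fr.f_g0g1 == pytest.approx(1.0, abs=0.02)
        assert fr.f_g2m == 0.0
        assert fr.g2m_over_g0g1 == pytest.approx(0.0, abs=0.02)
        assert fr.warnings

    def test_round_trip_recovers_fractions(self):
        """(0.6, 0.15, 0.25) at cv=0.05, n=10000: fractions recovered
        within two percentage points."""
        ev = simulate_pi_events((0.6, 0.15, 0.25), 0.05, 10000, seed=3)
        fr = gate_dna_content(ev)
        assert fr.f_g0g1 == pytest.approx(0.60, abs=0.02)
        assert fr.f_s == pytest.approx(0.15, abs=0.02)
        assert fr.f_g2m == pytest.approx(0.25, abs=0.02)
        assert fr.mu_g2m == pytest.approx(2 * fr.mu_g0g1, rel=0.05)

    def test_ratio_is_fraction_quotient(self):
        ev = simulate_pi_events((0.5, 0.2, 0.3), 0.05, 8000, seed=9)
        fr = gate_dna_content(ev)
        assert fr.g2m_over_g0g1 == pytest.approx(fr.f_g2m / fr.f_g0g1)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            gate_dna_content(np.full(400, 200.0))

    def test_manual_gates_override(self):
        # manual gates take events as they fall (no plateau correction), so
        # S events under the peak gates stay there, as in manual analysis
        ev = simulate_pi_events((0.6, 0.15, 0.25), 0.04, 10000, seed=5)
        fr = gate_dna_content(ev, manual_gates={"g0g1": (170, 230),
                                                "g2m": (360, 440)})
        assert fr.f_g0g1 == pytest.approx(0.60, abs=0.04)
        assert fr.f_g2m == pytest.approx(0.25, abs=0.04)

    def test_debris_excluded_before_gating(self):
        ev = simulate_pi_events((0.7, 0.1, 0.2), 0.05, 9000, seed=2)
        debris = pd.DataFrame({"intensity": np.full(1000, 30.0),
                               "sample": "wt", "phase": "debris"})
        fr = gate_dna_content(pd.concat([ev, debris], ignore_index=True))
        assert fr.f_g0g1 == pytest.approx(0.70, abs=0.03)


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "experiment",
                                           "replicate", "ct"])

    def _noiseless(self, ddct):
        rows = []
        for exp in (1, 2):
            for rep in (1, 2):
                rows += [("wt", "POLR2a", exp, rep, 18.0),
                         ("mut", "POLR2a", exp, rep, 18.0),
                         ("wt", "T", exp, rep, 21.0),
                         ("mut", "T", exp, rep, 21.0 + ddct)]
        return self._table(rows)

    def test_zero_ddct_gives_fold_one(self):
        rep = ddct_fold_change(self._noiseless(0.0), "T")
        assert rep.mean_fold == pytest.approx(1.0)
        assert (rep.per_experiment.ddct == 0).all()

    def test_plus_one_ddct_halves_expression(self):
        rep = ddct_fold_change(self._noiseless(1.0), "T")
        assert rep.mean_fold == pytest.approx(0.5)

    def test_fold_changes_multiply_when_ddcts_add(self):
        f1 = ddct_fold_change(self._noiseless(0.7), "T").mean_fold
        f2 = ddct_fold_change(self._noiseless(1.3), "T").mean_fold
        f12 = ddct_fold_change(self._noiseless(2.0), "T").mean_fold
        assert f1 * f2 == pytest.approx(f12)

    def test_round_trip_recovers_generating_fold(self):
        """True fold 0.51 with replicate noise 0.05: the mean fold over 3
        experiments lands within 0.05 for each of 50 seeds."""
        for seed in range(50):
            ct = simulate_ct_table({"CHD8_proximal": 0.51}, 18.0,
                                   replicates=4, noise_sd=0.05, seed=seed)
            rep = ddct_fold_change(ct, "CHD8_proximal")
            assert rep.mean_fold == pytest.approx(0.51, abs=0.05)

    def test_invariant_to_per_experiment_offset(self):
        ct = simulate_ct_table({"T": 0.7}, 18.0, 3, 0.0, seed=1)
        base = ddct_fold_change(ct, "T").mean_fold
        shifted = ct.copy()
        shifted.loc[shifted.experiment == 2, "ct"] += 3.7
        assert ddct_fold_change(shifted, "T").mean_fold == pytest.approx(base)

    def test_missing_reference_rejected(self):
        ct = simulate_ct_table({"T": 0.7}, 18.0, 3, 0.0, seed=1)
        broken = ct[~((ct.gene == "POLR2a") & (ct["sample"] == "mut")
                      & (ct.experiment == 2))]
        with pytest.raises(ValueError, match="POLR2a"):
            ddct_fold_change(broken, "T")


class TestRoiQuantification:
    def test_uniform_roi_mean_exact(self):
        img = np.zeros((20, 20))
        lab = np.zeros((20, 20), np.int32)
        img[2:6, 2:6] = 42.0
        lab[2:6, 2:6] = 1
        img[10:14, 10:12] = 7.0
        lab[10:14, 10:12] = 3
        table = quantify_rois(img, lab, "g")
        t = table.set_index("roi_id")
        assert t.loc[1, "mean_intensity"] == 42.0
        assert t.loc[3, "mean_intensity"] == 7.0
        assert t.loc[1, "area"] == 16
        assert 2 not in t.index  # zero-area label simply absent

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quantify_rois(np.zeros((4, 4)), np.zeros((4, 5), np.int32))

    def test_round_trip_group_means(self):
        field = simulate_nuclei_field((100.0, 57.0), (40, 40), 5.0, seed=2)
        for group, true_mean in (("wt", 100.0), ("mut", 57.0)):
            t = quantify_rois(field.images[group], field.labels[group], group)
            measured = (t.mean_intensity - 5.0).mean()  # background = 5
            assert measured == pytest.approx(true_mean, rel=0.05)


class TestNcRatio:
    def _table(self):
        return pd.DataFrame({
            "roi_id": [1, 2, 3, 4], "compartment": ["nucleus", "cytoplasm"] * 2,
            "mean_intensity": [200.0, 100.0, 50.0, 0.0],
            "area": [10] * 4, "group": "g"})

    def test_ratio_computed_per_cell(self):
        pairing = pd.DataFrame({"cell_id": ["a"], "nucleus_id": [1],
                                "cytoplasm_id": [2]})
        out = nc_ratio(self._table(), pairing)
        assert out.ratio.iloc[0] == 2.0

    def test_zero_cytoplasm_flagged_excluded(self):
        pairing = pd.DataFrame({"cell_id": ["a", "b"],
                                "nucleus_id": [1, 3],
                                "cytoplasm_id": [2, 4]})
        out = nc_ratio(self._table(), pairing)
        assert out[out.cell_id == "b"].excluded.iloc[0]
        assert np.isnan(out[out.cell_id == "b"].ratio.iloc[0])

    def test_unknown_roi_rejected(self):
        pairing = pd.DataFrame({"cell_id": ["a"], "nucleus_id": [1],
                                "cytoplasm_id": [99]})
        with pytest.raises(ValueError):
            nc_ratio(self._table(), pairing)


class TestPercentChange:
    def test_identical_groups_zero(self):
        pct, _ = percent_change([10, 20, 30], [10, 20, 30])
        assert pct == pytest.approx(0.0)

    def test_arithmetic(self):
        pct, _ = percent_change([100.0], [57.0])
        assert pct == pytest.approx(43.0)

    def test_round_trip_on_synthetic_field(self):
        """Fig-calibrated two-group field (means 100 vs 57, n=114/101)
        recovers a ~43% decrease."""
        field = simulate_nuclei_field((100.0, 57.0), (114, 101), 19.0, seed=3)
        means = {}
        for group in ("wt", "mut"):
            t = quantify_rois(field.images[group], field.labels[group], group)
            means[group] = t.mean_intensity - 5.0
        pct, sd = percent_change(means["wt"], means["mut"])
        assert pct == pytest.approx(43.0, abs=5.0)
        assert sd > 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            percent_change([], [1.0])
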