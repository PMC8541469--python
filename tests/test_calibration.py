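"""Energy-window classification and coefficient calibration."""

import numpy as np
import pytest

from petew.calibration import (LEW, PHOTOPEAK, UEW, EnergyWindowConfig,
                               ScatterCoefficients, classify_event,
                               classify_events, count_windows, event_bins,
                               fit_coefficients, true_count_total, true_counts)
from petew.listmode import ListModeSet

from conftest import make_random_listmode


def _set_with(geom, energies, scattered):
    """Events on a fixed opposed block pair with given energies/labels."""
    n = len(energies)
    e = np.asarray(energies, dtype=np.float32)
    sc = np.asarray(scattered, dtype=bool)
    return ListModeSet(
        geom,
        block=np.tile([0, 10], (n, 1)),
        u=np.zeros((n, 2), np.float32), v=np.zeros((n, 2), np.float32),
        doi=np.zeros((n, 2), np.float32), energy=e,
        scattered=np.stack([sc, np.zeros(n, bool)], axis=1),
        n_scatters=np.stack([sc.astype(np.int16), np.zeros(n, np.int16)], axis=1),
        origin_in_fov=np.ones(n, bool), source_id=np.zeros(n, np.int16))


class TestClassification:
    # representative energies: L = in 350-430, P = in 430-550, U = in 550-650
    L, P, U = 400.0, 500.0, 600.0

    @pytest.mark.parametrize("e1,e2,expected", [
        # photopeak only when both photons sit in the photopeak window
        (P, P, "photopeak"),
        # a low-window photon marks the event LEW, whatever the partner
        (L, P, "lew"), (P, L, "lew"), (L, L, "lew"),
        (L, U, "lew"), (U, L, "lew"),
        # otherwise an upper-window photon marks it UEW
        (U, P, "uew"), (P, U, "uew"), (U, U, "uew"),
    ])
    def test_tew_truth_table(self, e1, e2, expected):
        cfg = EnergyWindowConfig(mode="TEW")
        labels = classify_events(np.array([[e1, e2]]), cfg)
        assert {0: "lew", 1: "photopeak", 2: "uew"}[labels[0]] == expected

    @pytest.mark.parametrize("e1,e2,expected", [
        (P, P, "photopeak"), (U, U, "photopeak"), (P, U, "photopeak"),
        (L, P, "lew"), (L, U, "lew"), (L, L, "lew"),
    ])
    def test_dew_truth_table(self, e1, e2, expected):
        # DEW photopeak spans 430-650, so 600 keV photons are photopeak
        cfg = EnergyWindowConfig(mode="DEW")
        labels = classify_events(np.array([[e1, e2]]), cfg)
        assert {0: "lew", 1: "photopeak"}[labels[0]] == expected

    def test_partition_is_total(self, geom):
        lm = make_random_listmode(geom, n=3000, seed=9)
        for mode in ("DEW", "TEW"):
            cfg = EnergyWindowConfig(mode=mode)
            labels = classify_events(lm.energy, cfg)
            assert len(labels) == len(lm)
            assert set(np.unique(labels)) <= set(cfg.windows)

    def test_single_event_classifier(self, geom):
        lm = _set_with(geom, [[400.0, 511.0]], [True])
        assert classify_event(lm.event(0), EnergyWindowConfig("TEW")) == "lew"

    def test_invalid_window_configs(self):
        with pytest.raises(ValueError):
            EnergyWindowConfig(mode="XEW")
        with pytest.raises(ValueError):
            EnergyWindowConfig(mode="TEW", lew_upper=560.0, uew_lower=550.0)


class TestCountWindows:
    def test_empty_set(self, geom, binner):
        lm = make_random_listmode(geom, n=0, with_truth=False)
        wc = count_windows(lm, EnergyWindowConfig("TEW"), binner)
        assert wc.n_events == 0 and wc.totals.sum() == 0

    def test_counts_match_per_event_tally(self, geom, binner):
        """Window counts equal an independent single-pass per-event tally."""
        lm = make_random_listmode(geom, n=2000, seed=13, with_truth=False)
        cfg = EnergyWindowConfig("TEW")
        wc = count_windows(lm, cfg, binner)
        # brute force: loop events, classify by window rule, key by bin
        tally = {}
        n_ok = 0
        pair, flat, ok = event_bins(lm, binner)
        for i in range(len(lm)):
            if not ok[i]:
                continue
            n_ok += 1
            e1, e2 = lm.energy[i]
            if (350 <= e1 < 430) or (350 <= e2 < 430):
                w = LEW
            elif e1 >= 550 or e2 >= 550:
                w = UEW
            else:
                w = PHOTOPEAK
            key = (int(pair[i]) * binner.bins_per_pair + int(flat[i]), w)
            tally[key] = tally.get(key, 0) + 1
        assert wc.n_events == n_ok
        assert wc.counts.sum() == n_ok
        for (bid, w), c in tally.items():
            row = np.searchsorted(wc.bin_ids, bid)
            assert wc.bin_ids[row] == bid and wc.counts[row, w] == c

    def test_single_bin_concentration(self, geom, binner):
        lm = _set_with(geom, [[500.0, 500.0]] * 10, [False] * 10)
        wc = count_windows(lm, EnergyWindowConfig("TEW"), binner)
        assert len(wc.bin_ids) == 1
        assert wc.counts[0, PHOTOPEAK] == 10
        assert wc.counts[0, LEW] == 0 and wc.counts[0, UEW] == 0


class TestFitCoefficients:
    def test_no_scatter_gives_zero_coefficients(self, geom):
        lm = _set_with(geom, [[500.0, 500.0]] * 50, [False] * 50)
        k = fit_coefficients(lm, EnergyWindowConfig("DEW"))
        assert k.k[LEW] == 0.0

    def test_dew_quotient_on_constructed_counts(self, geom):
        # 100 LEW events + 40 scattered photopeak + 60 true photopeak
        energies = [[400.0, 511.0]] * 100 + [[500.0, 500.0]] * 100
        scattered = [True] * 100 + [True] * 40 + [False] * 60
        lm = _set_with(geom, energies, scattered)
        k = fit_coefficients(lm, EnergyWindowConfig("DEW"))
        assert k.k[LEW] == pytest.approx(0.4)

    def test_tew_exact_recovery_on_consistent_ensemble(self, geom):
        """NNLS recovers the generating (k_LEW, k_HEW) without noise."""
        k_lew, k_hew = 0.6, 0.2
        members = []
        for n_l, n_u in ((100, 50), (30, 200)):
            n_scat_pp = int(round(k_lew * n_l + k_hew * n_u))
            energies = ([[400.0, 511.0]] * n_l + [[600.0, 500.0]] * n_u
                        + [[500.0, 500.0]] * (n_scat_pp + 20))
            scattered = ([True] * n_l + [False] * n_u
                         + [True] * n_scat_pp + [False] * 20)
            members.append(_set_with(geom, energies, scattered))
        k = fit_coefficients(members, EnergyWindowConfig("TEW"))
        assert k.k[LEW] == pytest.approx(k_lew, abs=1e-9)
        assert k.k[UEW] == pytest.approx(k_hew, abs=1e-9)

    def test_coefficients_are_non_negative(self, cylinder_sets):
        for mode in ("DEW", "TEW"):
            k = fit_coefficients(cylinder_sets, EnergyWindowConfig(mode))
            assert all(v >= 0 for v in k.k.values())

    def test_calibration_requires_truth(self, geom):
        lm = make_random_listmode(geom, n=50, with_truth=False)
        with pytest.raises(ValueError):
            fit_coefficients(lm, EnergyWindowConfig("DEW"))

    def test_per_bin_floor_falls_back_to_global(self, geom, binner):
        lm = _set_with(geom, [[400.0, 511.0]] * 40 + [[500.0, 500.0]] * 60,
                       [True] * 70 + [False] * 30)
        k = fit_coefficients(lm, EnergyWindowConfig("DEW"), mode="per_bin",
                             binner=binner, count_floor=1000)
        assert k.mode == "per_bin"
        np.testing.assert_allclose(k.bin_k[:, 0], k.k[LEW])

    def test_save_load_round_trip(self, tmp_path, cylinder_sets):
        k = fit_coefficients(cylinder_sets, EnergyWindowConfig("TEW"))
        path = tmp_path / "coeff.json"
        k.save(path)
        back = ScatterCoefficients.load(path)
        assert back.k == k.k and back.window_mode == k.window_mode


class TestTrueCounts:
    def test_zero_coefficients_leave_photopeak(self, geom, binner):
        lm = _set_with(geom, [[500.0, 500.0]] * 30, [False] * 30)
        cfg = EnergyWindowConfig("DEW")
        wc = count_windows(lm, cfg, binner)
        k = ScatterCoefficients("global", "DEW", {LEW: 0.0})
        _, ct = true_counts(wc, k)
        assert ct.sum() == 30

    def test_negative_estimates_clamped_at_zero(self, geom, binner):
        # C_ph = 10 in one bin, k*C_LEW = 15 > 10 -> clamped to 0
        lm = _set_with(geom, [[400.0, 511.0]] * 30 + [[500.0, 500.0]] * 10,
                       [True] * 30 + [False] * 10)
        cfg = EnergyWindowConfig("DEW")
        wc = count_windows(lm, cfg, binner)
        k = ScatterCoefficients("global", "DEW", {LEW: 0.5})
        _, ct = true_counts(wc, k)
        assert ct.min() >= 0.0
        assert ct.sum() == 0.0

    def test_dew_self_consistency_identity(self, binner, cylinder_sets):
        """Global DEW k applied to its own calibration data reproduces the
        labelled unscattered photopeak total exactly."""
        cfg = EnergyWindowConfig("DEW")
        k = fit_coefficients(cylinder_sets, cfg)
        est = sum(true_count_total(count_windows(lm, cfg, binner), k)
                  for lm in cylinder_sets)
        truth = 0
        for lm in cylinder_sets:
            labels = classify_events(lm.energy, cfg)
            truth += int(((labels == PHOTOPEAK) & ~lm.event_scattered).sum())
        assert est == pytest.approx(truth, rel=1e-12)
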