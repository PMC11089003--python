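import numpy as np
import pandas as pd
import pytest

from xenoglia.radial import (
    annulus_means,
    detect_plaques,
    fit_exponential_decay,
    loess_curve,
    near_far_test,
    zscore_profiles,
)
from xenoglia.synthetic import ChannelModel, SimImageConfig, simulate_plaque_image


def _disk_image(shape=(100, 100), center=(50, 50), radius=10.0, value=100.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return np.where(d <= radius, value, 0.0)


class TestDetectPlaques:
    def test_blank_image_empty(self):
        out = detect_plaques(np.zeros((50, 50)), pixel_size_um=1.0)
        assert len(out) == 0

    def test_single_disk_geometry(self):
        img = _disk_image(radius=10.0)
        out = detect_plaques(img, pixel_size_um=1.0, threshold=50.0)
        assert len(out) == 1
        assert abs(out.loc[0, "row_px"] - 50) <= 1 and abs(out.loc[0, "col_px"] - 50) <= 1
        assert out.loc[0, "area_um2"] == pytest.approx(np.pi * 100, rel=0.05)

    def test_two_disjoint_disks(self):
        img = _disk_image(center=(25, 25), radius=8) + _disk_image(center=(75, 75), radius=8)
        out = detect_plaques(img, pixel_size_um=1.0, threshold=50.0)
        assert len(out) == 2

    def test_min_area_drops_specks(self):
        img = _disk_image(radius=10) + _disk_image(center=(10, 90), radius=1.5)
        out = detect_plaques(img, pixel_size_um=1.0, threshold=50.0, min_area_um2=50.0)
        assert len(out) == 1

    def test_otsu_threshold_on_noisy_disk(self, rng):
        img = _disk_image(radius=10) + rng.normal(0, 3, size=(100, 100))
        out = detect_plaques(img, pixel_size_um=1.0, threshold="otsu", min_area_um2=20)
        assert len(out) == 1


class TestAnnulusMeans:
    def test_constant_image(self):
        table = annulus_means(
            {"m": np.full((200, 200), 7.0)},
            centers=[(100, 100)],
            pixel_size_um=1.0,
            n_annuli=10,
            annulus_width_um=5.0,
        )
        assert np.allclose(table["mean_intensity"], 7.0)

    def test_radial_step_function(self):
        # value 1 inside 10 um, 0 outside; width 10/3: annuli 0-2 at 1, >=3 at ~0
        img = _disk_image(shape=(200, 200), center=(100, 100), radius=10.0, value=1.0)
        table = annulus_means(
            {"m": img}, centers=[(100, 100)], pixel_size_um=1.0
        ).set_index("annulus_index")
        assert np.allclose(table.loc[[0, 1], "mean_intensity"], 1.0)
        assert table.loc[2, "mean_intensity"] > 0.95  # boundary-pixel tolerance
        assert (table.loc[4:, "mean_intensity"] < 0.01).all()

    def test_pixel_partition(self):
        n_annuli, width = 24, 10 / 3
        table = annulus_means(
            {"m": np.zeros((300, 300))},
            centers=[(150, 150)],
            pixel_size_um=1.0,
            n_annuli=n_annuli,
            annulus_width_um=width,
        )
        rr, cc = np.mgrid[0:300, 0:300]
        d = np.sqrt((rr - 150) ** 2 + (cc - 150) ** 2)
        assert table["n_pixels"].sum() == (d < n_annuli * width).sum()

    def test_matches_bruteforce_pixel_loop(self, rng):
        img = rng.random((60, 60))
        center = (30.3, 29.1)
        width, n_annuli = 4.0, 8
        table = annulus_means(
            {"m": img}, centers=[center], pixel_size_um=1.5,
            n_annuli=n_annuli, annulus_width_um=width,
        ).set_index("annulus_index")
        sums = np.zeros(n_annuli)
        npix = np.zeros(n_annuli)
        for r in range(60):
            for c in range(60):
                d = 1.5 * np.hypot(r - center[0], c - center[1])
                a = int(d // width)
                if a < n_annuli:
                    sums[a] += img[r, c]
                    npix[a] += 1
        np.testing.assert_allclose(table["n_pixels"], npix)
        np.testing.assert_allclose(table["mean_intensity"], sums / npix, atol=1e-12)

    def test_nearest_center_assignment_counts_pixels_once(self):
        table = annulus_means(
            {"m": np.zeros((100, 100))},
            centers=[(50, 40), (50, 60)],
            pixel_size_um=1.0,
            n_annuli=30,
            annulus_width_um=2.0,
        )
        assert table.groupby("channel")["n_pixels"].sum()["m"] <= 100 * 100

    def test_annuli_outside_image_have_zero_pixels(self):
        table = annulus_means(
            {"m": np.zeros((40, 40))},
            centers=[(20, 20)],
            pixel_size_um=1.0,
            n_annuli=24,
            annulus_width_um=10 / 3,
        ).set_index("annulus_index")
        assert table.loc[23, "n_pixels"] == 0
        assert np.isnan(table.loc[23, "mean_intensity"])

    def test_rotation_invariance(self):
        rr, cc = np.mgrid[0:201, 0:201]
        img = 100 * np.exp(-np.hypot(rr - 100, cc - 100) / 20.0)
        a = annulus_means({"m": img}, [(100, 100)], 1.0).set_index("annulus_index")
        b = annulus_means({"m": np.rot90(img)}, [(100, 100)], 1.0).set_index("annulus_index")
        rel = np.abs(a["mean_intensity"] - b["mean_intensity"]) / a["mean_intensity"]
        assert (rel.dropna() < 0.01).all()


class TestZScore:
    def _table(self, values, channel="m"):
        return pd.DataFrame(
            {
                "plaque_id": 0,
                "annulus_index": range(len(values)),
                "inner_radius_um": 0.0,
                "outer_radius_um": 1.0,
                "channel": channel,
                "mean_intensity": values,
                "n_pixels": 10,
            }
        )

    def test_standardizes_each_channel(self, rng):
        t = pd.concat(
            [self._table(rng.random(30), "a"), self._table(rng.random(30) * 50, "b")],
            ignore_index=True,
        )
        z = zscore_profiles(t)
        for ch in ("a", "b"):
            sub = z.loc[z["channel"] == ch, "z"]
            assert sub.mean() == pytest.approx(0.0, abs=1e-9)
            assert sub.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self, rng):
        vals = rng.random(20)
        z1 = zscore_profiles(self._table(vals))["z"]
        z2 = zscore_profiles(self._table(3.0 * vals + 11.0))["z"]
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_two_values_use_sample_sd(self):
        z = zscore_profiles(self._table([1.0, 3.0]))["z"]
        np.testing.assert_allclose(z, [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)

    def test_zero_sd_channel_warns_zeros(self):
        with pytest.warns(UserWarning, match="zero"):
            z = zscore_profiles(self._table([5.0, 5.0, 5.0]))["z"]
        assert (z == 0.0).all()


class TestLoess:
    def test_exact_on_linear_data(self, rng):
        x = np.sort(rng.random(40)) * 10
        y = 2.5 * x - 1.0
        fit = loess_curve(x, y, span=0.5, degree=1)
        np.testing.assert_allclose(fit["fitted"], y, atol=1e-8)

    def test_constant_data_zero_se(self):
        x = np.arange(20.0)
        fit = loess_curve(x, np.full(20, 3.0))
        np.testing.assert_allclose(fit["fitted"], 3.0, atol=1e-10)
        np.testing.assert_allclose(fit["se"], 0.0, atol=1e-8)

    def test_matches_per_point_wls_oracle(self, rng):
        x = np.sort(rng.random(30)) * 5
        y = np.sin(x) + rng.normal(0, 0.1, 30)
        span, degree = 0.6, 1
        fit = loess_curve(x, y, span=span, degree=degree)
        k = int(np.ceil(span * len(x)))
        for i, x0 in enumerate(x):
            d = np.abs(x - x0)
            idx = np.argsort(d, kind="stable")[:k]
            w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
            X = np.vander(x[idx] - x0, degree + 1, increasing=True)
            beta = np.linalg.lstsq(
                X * np.sqrt(w)[:, None], y[idx] * np.sqrt(w), rcond=None
            )[0]
            assert fit["fitted"].iloc[i] == pytest.approx(beta[0], abs=1e-8)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            loess_curve(np.ones(10), np.arange(10.0))


class TestNearFar:
    def _profile_table(self, near_vals, far_vals, n_annuli=24):
        rows = []
        for pid, (nv, fv) in enumerate(zip(near_vals, far_vals)):
            for a in range(n_annuli):
                if a < 3:
                    v = nv
                elif a >= n_annuli - 3:
                    v = fv
                else:
                    v = (nv + fv) / 2
                rows.append((pid, a, "m", v, 10))
        return pd.DataFrame(
            rows, columns=["plaque_id", "annulus_index", "channel", "z", "n_pixels"]
        )

    def test_identical_near_far_is_null(self):
        t = self._profile_table([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        res = near_far_test(t, "m")
        assert res.t == 0.0 and res.p == pytest.approx(0.5)

    def test_direction_of_alternative(self):
        t = self._profile_table([2.0, 2.1, 1.9, 2.0], [0.1, 0.0, 0.2, 0.1])
        up = near_far_test(t, "m", alternative="near_greater")
        down = near_far_test(t, "m", alternative="far_greater")
        assert up.p < 0.01 and down.p > 0.5

    def test_replicate_with_missing_annuli_dropped(self):
        t = self._profile_table([2.0, 2.0, 2.0], [0.0, 0.0, 0.0])
        t.loc[(t["plaque_id"] == 0) & (t["annulus_index"] == 23), "n_pixels"] = 0
        with pytest.warns(UserWarning, match="dropped"):
            res = near_far_test(t, "m")
        assert len(res.near_means) == 2


class TestGradientRecovery:
    def _noise_free_profile(self, lam, direction, n_px=221):
        cm = {"X34": ChannelModel("plaque", amplitude=255.0),
              "m": ChannelModel(direction, amplitude=100.0, decay_length_um=lam, baseline=10.0)}
        cfg = SimImageConfig(
            image_size_px=(n_px, n_px), n_plaques=1, noise_sd=0.0,
            channel_models=cm, margin_um=100.0, seed=0,
        )
        channels, truth = simulate_plaque_image(cfg)
        center = truth.plaques[["row_px", "col_px"]].iloc[0]
        return annulus_means(
            {"m": channels["m"]}, [tuple(center)], cfg.pixel_size_um
        )

    @pytest.mark.parametrize("lam", [10.0, 20.0, 40.0])
    def test_decay_length_recovered_within_20pct(self, lam):
        table = self._noise_free_profile(lam, "up_near_plaque")
        mid = (table["inner_radius_um"] + table["outer_radius_um"]) / 2
        fit = fit_exponential_decay(mid, table["mean_intensity"], "up_near_plaque")
        assert fit["decay_length_um"] == pytest.approx(lam, rel=0.2)

    def test_up_channel_monotone_decreasing(self):
        table = self._noise_free_profile(20.0, "up_near_plaque").dropna()
        means = table.sort_values("annulus_index")["mean_intensity"].to_numpy()
        assert (np.diff(means) < 1e-9).all()

    def test_down_channel_monotone_increasing(self):
        table = self._noise_free_profile(20.0, "down_near_plaque").dropna()
        means = table.sort_values("annulus_index")["mean_intensity"].to_numpy()
        assert (np.diff(means) > -1e-9).all()

    def test_detected_vs_true_centers_agree_at_high_snr(self):
        cfg = SimImageConfig(
            image_size_px=(300, 300), n_plaques=3, noise_sd=1.0,
            margin_um=90.0, seed=12,
        )
        channels, truth = simulate_plaque_image(cfg)
        detected = detect_plaques(channels["X34"], cfg.pixel_size_um, min_area_um2=20)
        assert len(detected) == 3
        # match detected to true by proximity, then compare annulus profiles
        t_true = annulus_means(
            {"CD9": channels["CD9"]},
            truth.plaques[["row_px", "col_px"]].to_numpy(),
            cfg.pixel_size_um, n_annuli=12,
        )
        t_det = annulus_means(
            {"CD9": channels["CD9"]},
            detected[["row_px", "col_px"]].to_numpy(),
            cfg.pixel_size_um, n_annuli=12,
        )
        a = t_true.groupby("annulus_index")["mean_intensity"].mean()
        b = t_det.groupby("annulus_index")["mean_intensity"].mean()
        rel = (a - b).abs() / a
        assert (rel.dropna() < 0.02).all()
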