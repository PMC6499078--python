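"""Spatial logistic GAM: fitting, surfaces, flags, covariate selection."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import sumaerr as s
from conftest import spatial_labels

HOTSPOT = (6e4, 5e4, 3.5e4, 3.0)  # cx, cy, radius, odds multiplier


class TestFit:
    def test_smooth_detected_under_strong_spatial_signal(self):
        labels, meta, _ = spatial_labels(2000, 0, hotspot=HOTSPOT)
        model = s.fit_gam(labels, meta)
        assert model.smooth_p < 1e-3
        assert 0 < model.fitted.min() and model.fitted.max() < 1

    def test_null_labels_rarely_significant(self):
        ps = [s.fit_gam(*spatial_labels(800, seed)[:2]).smooth_p for seed in range(8)]
        # approximate calibration: no extreme p-values under the null
        assert min(ps) > 1e-4
        assert np.median(ps) > 0.05

    def test_too_few_points_rejected(self):
        labels, meta, _ = spatial_labels(50, 0)
        with pytest.raises(ValueError, match="at least 100"):
            s.fit_gam(labels, meta)

    def test_missing_coordinates_rejected(self):
        labels, meta, _ = spatial_labels(200, 0)
        with pytest.raises(ValueError, match="'x'"):
            s.fit_gam(labels, meta.drop(columns=["x"]))

    def test_loess_backend_agrees_on_strong_signal(self):
        labels, meta, _ = spatial_labels(800, 1, hotspot=(6e4, 5e4, 3.5e4, 5.0))
        sp = s.fit_gam(labels, meta, backend="spline")
        lo = s.fit_gam(labels, meta, backend="loess", span=0.3)
        s_sp, _ = sp.backend.smooth_at(meta["x"].to_numpy(), meta["y"].to_numpy())
        s_lo, _ = lo.backend.smooth_at(meta["x"].to_numpy(), meta["y"].to_numpy())
        assert np.corrcoef(s_sp, s_lo)[0, 1] > 0.7

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_fitted_surface_matches_mgcv_oracle(self, tmp_path):
        """Independent cross-check against R mgcv on the same binary data."""
        labels, meta, _ = spatial_labels(600, 2, hotspot=HOTSPOT)
        model = s.fit_gam(labels, meta)
        df = meta.copy()
        df["yb"] = (labels.labels == "high").astype(int).to_numpy()
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(textwrap.dedent(f"""
            library(mgcv)
            d <- read.csv("{csv}")
            m <- gam(yb ~ s(x, y), data = d, family = binomial)
            write.csv(data.frame(mu = fitted(m)), "{tmp_path}/mu.csv", row.names = FALSE)
        """))
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        mu_r = pd.read_csv(tmp_path / "mu.csv")["mu"].to_numpy()
        assert np.corrcoef(model.fitted, mu_r)[0, 1] > 0.85
        assert abs(model.fitted.mean() - mu_r.mean()) < 0.02


class TestSurface:
    def test_null_surface_flags_nothing_at_strict_alpha(self):
        labels, meta, _ = spatial_labels(1500, 3)
        surf = s.predict_surface(s.fit_gam(labels, meta), n_grid=50)
        assert surf.flagged_fraction == 0.0

    def test_hotspot_flags_concentrate_inside_true_disc(self):
        labels, meta, _ = spatial_labels(2500, 4, hotspot=HOTSPOT)
        surf = s.predict_surface(s.fit_gam(labels, meta), n_grid=50)
        fl = surf.flagged_points()
        assert len(fl) > 0 and (fl["flag"] == "hot").all()
        cx, cy, r, _ = HOTSPOT
        assert (fl["x"].mean() - cx) ** 2 + (fl["y"].mean() - cy) ** 2 <= r**2

    def test_hotspot_jaccard_recovery(self):
        """Soft, directional property: flagged area overlaps the true disc."""
        cx, cy, r, _ = HOTSPOT
        jacs = []
        for seed in range(6):
            labels, meta, _ = spatial_labels(2500, seed, hotspot=HOTSPOT)
            surf = s.predict_surface(s.fit_gam(labels, meta), n_grid=50)
            g = surf.grid
            truth = ((g["x"] - cx) ** 2 + (g["y"] - cy) ** 2 <= r**2).to_numpy()
            flag = (g["flag"] == "hot").to_numpy()
            union = (truth | flag).sum()
            jacs.append((truth & flag).sum() / union if union else 1.0)
        assert np.mean(jacs) >= 0.3

    def test_or_surface_invariant_to_translation(self):
        labels, meta, _ = spatial_labels(500, 5, hotspot=HOTSPOT)
        s1 = s.predict_surface(s.fit_gam(labels, meta), n_grid=20)
        shifted = meta.assign(x=meta["x"] + 123_456.0, y=meta["y"] - 654_321.0)
        s2 = s.predict_surface(s.fit_gam(labels, shifted), n_grid=20)
        np.testing.assert_allclose(
            s1.grid["odds_ratio"].to_numpy(), s2.grid["odds_ratio"].to_numpy(), rtol=1e-9
        )

    def test_grid_restricted_to_convex_hull(self):
        rng = np.random.default_rng(0)
        n = 300
        # points confined to a triangle: half the bounding box is outside
        x = rng.uniform(0, 1e5, n)
        y = rng.uniform(0, 1e5, n)
        keep = y <= x
        labels, meta, _ = spatial_labels(n, 1)
        meta = pd.DataFrame({"x": x[keep], "y": y[keep]})
        lab = s.SmmeLabelSet(labels.frame.iloc[: keep.sum()].reset_index(drop=True), 0.0, 80.0)
        surf = s.predict_surface(s.fit_gam(lab, meta), n_grid=30)
        # allow a thin boundary sliver from gridding
        assert (surf.grid["y"] <= surf.grid["x"] + 5e3).all()
        assert len(surf.grid) < 30 * 30 * 0.65

    def test_bad_arguments(self):
        labels, meta, _ = spatial_labels(200, 6)
        model = s.fit_gam(labels, meta)
        with pytest.raises(ValueError, match="spacing"):
            s.predict_surface(model, spacing=-5.0)
        with pytest.raises(ValueError, match="alpha"):
            s.predict_surface(model, alpha=2.0)


class TestCovariates:
    @staticmethod
    def _stub_model(betas_ses, covariates, column_map):
        class _Backend:
            @staticmethod
            def parametric_table():
                return np.asarray(betas_ses, dtype=float)

        return s.GamModel(
            backend=_Backend(), covariates=covariates, column_names=["(intercept)"] + [c.name for c in covariates],
            column_map=column_map, coords=np.zeros((2, 2)), deviance=0.0, edf=0.0, smooth_p=1.0,
        )

    def test_zero_coefficient_gives_unit_or_symmetric_ci(self):
        model = self._stub_model(
            [[0.0, 0.1], [0.0, 0.2]], [s.CovariateSpec("v", iqr=2.0)], {"v": [1]}
        )
        row = s.covariate_odds_ratios(model).iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["ci_low"] * row["ci_high"] == pytest.approx(1.0)  # symmetric on log scale

    def test_iqr_scaling_closed_form(self):
        model = self._stub_model(
            [[0.0, 0.1], [0.1, 0.02]], [s.CovariateSpec("nox", iqr=5.89)], {"nox": [1]}
        )
        row = s.covariate_odds_ratios(model).iloc[0]
        assert row["odds_ratio"] == pytest.approx(np.exp(0.589), rel=1e-12)

    def test_fitted_covariate_or_recovers_generative_effect(self):
        """A covariate equal to the hotspot indicator carries the log-odds
        contrast between inside and outside."""
        labels, meta, inside = spatial_labels(2000, 7, hotspot=HOTSPOT)
        meta = meta.assign(ind=inside.astype(float))
        model = s.fit_gam(labels, meta, [s.CovariateSpec("ind", iqr=1.0)])
        row = s.covariate_odds_ratios(model).iloc[0]
        assert row["odds_ratio"] == pytest.approx(3.0, rel=0.4)


class TestSelection:
    def test_noise_candidate_not_retained(self):
        retained = 0
        for seed in range(5):
            labels, meta, _ = spatial_labels(800, 10 + seed, hotspot=HOTSPOT)
            rng = np.random.default_rng(100 + seed)
            meta = meta.assign(noise=rng.normal(size=len(meta)))
            out = s.iterative_covariate_selection(labels, meta, [s.CovariateSpec("noise")], n_grid=30)
            retained += int(out["steps"]["retained"].iloc[0])
        assert retained <= 1

    def test_generating_covariate_retained_and_flattens_surface(self):
        labels, meta, inside = spatial_labels(2500, 20, hotspot=HOTSPOT)
        meta = meta.assign(ind=inside.astype(float))
        out = s.iterative_covariate_selection(labels, meta, [s.CovariateSpec("ind", iqr=1.0)], n_grid=40)
        assert out["steps"]["retained"].iloc[0]
        assert out["surface"].flagged_fraction <= out["unadjusted_surface"].flagged_fraction
        lo_u, hi_u = out["unadjusted_surface"].or_range
        lo_a, hi_a = out["surface"].or_range
        assert (hi_a - lo_a) < (hi_u - lo_u)  # residual OR range shrinks

    def test_adjustment_benefit_grows_with_effect_size(self):
        """The flagged-area reduction from adjusting for the generating
        covariate is monotone in the hotspot effect size."""
        reductions = []
        for mult in (1.5, 3.0, 6.0):
            labels, meta, inside = spatial_labels(2500, 30, hotspot=(6e4, 5e4, 3.5e4, mult))
            meta = meta.assign(ind=inside.astype(float))
            un = s.predict_surface(s.fit_gam(labels, meta), n_grid=40)
            ad = s.predict_surface(s.fit_gam(labels, meta, [s.CovariateSpec("ind", iqr=1.0)]), n_grid=40)
            reductions.append(un.flagged_fraction - ad.flagged_fraction)
        assert reductions == sorted(reductions)

    def test_empty_candidate_list_rejected(self):
        labels, meta, _ = spatial_labels(200, 0)
        with pytest.raises(ValueError, match="non-empty"):
            s.iterative_covariate_selection(labels, meta, [])


def test_geojson_round_trip(tmp_path):
    labels, meta, _ = spatial_labels(300, 1)
    surf = s.predict_surface(s.fit_gam(labels, meta), n_grid=10)
    path = tmp_path / "s.geojson"
    fc = s.surface_to_geojson(surf, path)
    import json

    loaded = json.loads(path.read_text())
    assert loaded == fc
    assert loaded["type"] == "FeatureCollection"
    assert len(loaded["features"]) == len(surf.grid)
    assert {"or", "se", "flag"} <= set(loaded["features"][0]["properties"])
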