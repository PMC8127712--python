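import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genoscape import (
    SyntheticConfig,
    generate_bundle,
    generate_env_stack,
    place_sites,
    read_bundle,
    simulate_allele_frequencies,
    write_bundle,
)


def morans_i_rook(x: np.ndarray) -> float:
    """Direct double-loop Moran's I with rook neighbours (oracle)."""
    rows, cols = x.shape
    xbar = x.mean()
    dev = x - xbar
    num = 0.0
    W = 0
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    num += dev[r, c] * dev[rr, cc]
                    W += 1
    den = (dev**2).sum()
    n = rows * cols
    return (n / W) * (num / den)


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SyntheticConfig(grid_rows=0)
        with pytest.raises(ValueError):
            SyntheticConfig(maf_threshold=0.6)
        with pytest.raises(ValueError):
            SyntheticConfig(n_adaptive=10, n_snps=5)
        with pytest.raises(ValueError):
            SyntheticConfig(driver_layer="nope")

    def test_dict_round_trip(self):
        cfg = SyntheticConfig(seed=9, warming_delta_max=1.5)
        assert SyntheticConfig.from_dict(cfg.to_dict()) == cfg


class TestEnvStackGeneration:
    def test_zero_delta_future_identical_to_current(self):
        cfg = SyntheticConfig(grid_rows=12, grid_cols=12, warming_delta_max=0.0, seed=2)
        cur, fut = generate_env_stack(cfg)
        assert np.array_equal(cur.data, fut.data)

    def test_warming_peaks_at_two_degrees_on_the_coastal_edge(self):
        """Default delta reaches 2.0 env-units at the ramp edge, 0 opposite."""
        cfg = SyntheticConfig(grid_rows=20, grid_cols=20, seed=3)
        cur, fut = generate_env_stack(cfg)
        delta = fut.layer("tmin") - cur.layer("tmin")
        assert np.max(delta) == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(delta[:, -1], 0.0, atol=1e-9)
        for name in cur.layer_names[1:]:
            assert np.array_equal(cur.layer(name), fut.layer(name))

    def test_layers_are_spatially_autocorrelated(self):
        """Generated layers beat cell-wise permutations of themselves on
        Moran's I (double-loop rook oracle) in at least 95/100 seeds."""
        wins = 0
        for seed in range(100):
            cfg = SyntheticConfig(
                grid_rows=15, grid_cols=15, autocorr_length=5.0, seed=seed
            )
            cur, _ = generate_env_stack(cfg)
            layer = cur.layer("tmin")
            rng = np.random.default_rng(seed + 10_000)
            perm = rng.permutation(layer.ravel()).reshape(layer.shape)
            if morans_i_rook(layer) > morans_i_rook(perm):
                wins += 1
        assert wins >= 95

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            SyntheticConfig(grid_rows=-1, grid_cols=5)


class TestSitePlacement:
    def test_two_sites_on_two_cells_exhaust_the_grid(self):
        cfg = SyntheticConfig(grid_rows=1, grid_cols=2, autocorr_length=0.0, seed=0)
        cur, _ = generate_env_stack(cfg)
        sites = place_sites(cur, n_sites=2, seed=0)
        assert sorted(zip(sites["row"], sites["col"])) == [(0, 0), (0, 1)]

    def test_default_yields_15_sites_inside_bounds(self):
        cfg = SyntheticConfig(seed=4)
        cur, _ = generate_env_stack(cfg)
        sites = place_sites(cur, seed=4)
        assert len(sites) == 15
        assert sites[["row", "col"]].drop_duplicates().shape[0] == 15
        assert sites["lon"].between(9.0, 9.0 + 0.6).all()
        assert sites["lat"].between(7.0 - 0.6, 7.0).all()

    @pytest.mark.parametrize("n_sites", [8, 15])
    def test_every_driver_quartile_holds_a_site(self, n_sites):
        """Stratification oracle: bin sites by raster driver quartiles."""
        cfg = SyntheticConfig(seed=5)
        cur, _ = generate_env_stack(cfg)
        sites = place_sites(cur, n_sites=n_sites, seed=5)
        driver = cur.layer("tmin")
        qs = np.quantile(driver, [0.25, 0.5, 0.75])
        vals = driver[sites["row"], sites["col"]]
        counts = np.histogram(vals, bins=[-np.inf, *qs, np.inf])[0]
        assert (counts >= 1).all()

    def test_more_sites_than_cells_raises(self):
        cfg = SyntheticConfig(grid_rows=2, grid_cols=2, seed=0)
        cur, _ = generate_env_stack(cfg)
        with pytest.raises(ValueError, match="exceeds"):
            place_sites(cur, n_sites=5, seed=0)


class TestAlleleFrequencySimulation:
    def test_flat_cline_without_noise_is_constant(self):
        cfg = SyntheticConfig(
            grid_rows=10, grid_cols=10, n_snps=10, n_adaptive=10, slope_b=0.0, noise_sd=0.0, seed=6
        )
        cur, _ = generate_env_stack(cfg)
        sites = place_sites(cur, cfg.n_sites, cfg.seed)
        table, truth = simulate_allele_frequencies(sites, cur, cfg)
        assert np.allclose(np.ptp(table.frequencies, axis=0), 0.0)

    def test_steep_noiseless_cline_is_monotone_in_the_driver(self):
        """Noiseless clines are perfectly rank-correlated with the driver
        (ρ = ±1 up to ties where the logistic saturates in floats)."""
        cfg = SyntheticConfig(
            grid_rows=10, grid_cols=10, n_snps=8, n_adaptive=8, slope_b=10.0, noise_sd=0.0, seed=7
        )
        cur, _ = generate_env_stack(cfg)
        sites = place_sites(cur, cfg.n_sites, cfg.seed)
        table, truth = simulate_allele_frequencies(sites, cur, cfg)
        E = np.array(
            [cur.layer("tmin")[r, c] for r, c in zip(sites["row"], sites["col"])]
        )
        order = np.argsort(E)
        for j, slope in enumerate(truth["slope"]):
            sign = np.sign(slope)
            f_sorted = table.frequencies[order, j]
            assert (sign * np.diff(f_sorted) >= 0).all()
            # on sites with distinct (unsaturated) frequencies ρ is exactly ±1
            _, first = np.unique(f_sorted, return_index=True)
            if len(first) > 1:
                rho = stats.spearmanr(f_sorted[first], E[order][first]).statistic
                assert rho == pytest.approx(sign, abs=1e-12)

    def test_frequencies_clamped_to_unit_interval(self):
        cfg = SyntheticConfig(noise_sd=0.5, seed=8)  # heavy noise forces clamping
        bundle = generate_bundle(cfg)
        f = bundle.freqs.frequencies
        assert f.min() >= 0.0 and f.max() <= 1.0

    def test_site_outside_raster_is_named(self):
        cfg = SyntheticConfig(grid_rows=5, grid_cols=5, seed=9)
        cur, _ = generate_env_stack(cfg)
        sites = pd.DataFrame(
            {"site_id": ["ok", "lost"], "lon": [9.02, 50.0], "lat": [6.98, 6.98]}
        )
        with pytest.raises(ValueError, match="lost"):
            simulate_allele_frequencies(sites, cur, cfg)

    def test_adaptive_signal_beats_neutral_correlation_tail(self):
        """≥90% of adaptive SNPs exceed the neutral 97.5th-percentile |r|
        with the driver, across 20 seeds (slope 8, noise 0.02)."""
        fracs = []
        for seed in range(20):
            bundle = generate_bundle(SyntheticConfig(seed=seed))
            E = bundle.env_at_sites()["tmin"].to_numpy()
            F = bundle.freqs.frequencies
            adaptive = bundle.truth["is_adaptive"].to_numpy()
            sd = F.std(axis=0)
            r = np.zeros(F.shape[1])
            ok = sd > 0
            r[ok] = [np.corrcoef(F[:, j], E)[0, 1] for j in np.flatnonzero(ok)]
            thr = np.percentile(np.abs(r[~adaptive]), 97.5)
            fracs.append((np.abs(r[adaptive]) > thr).mean())
        assert all(f >= 0.9 for f in fracs)


class TestBundlePersistence:
    def test_write_read_round_trip_is_exact(self, tmp_path):
        cfg = SyntheticConfig(grid_rows=10, grid_cols=10, n_snps=20, n_adaptive=5, seed=12)
        bundle = generate_bundle(cfg)
        write_bundle(bundle, tmp_path)
        back = read_bundle(tmp_path)
        assert back.config == cfg
        assert np.array_equal(bundle.env_current.data, back.env_current.data)
        assert np.array_equal(bundle.env_future.data, back.env_future.data)
        assert np.array_equal(bundle.freqs.frequencies, back.freqs.frequencies)
        assert bundle.freqs.snp_ids == back.freqs.snp_ids
        pd.testing.assert_frame_equal(bundle.sites, back.sites)
        pd.testing.assert_frame_equal(bundle.truth, back.truth)

    def test_manifest_records_the_seed(self, tmp_path):
        import json

        cfg = SyntheticConfig(grid_rows=6, grid_cols=6, n_snps=5, n_adaptive=2, seed=77)
        write_bundle(generate_bundle(cfg), tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 77

    def test_same_seed_writes_byte_identical_csvs(self, tmp_path):
        cfg = SyntheticConfig(grid_rows=8, grid_cols=8, n_snps=10, n_adaptive=3, seed=13)
        write_bundle(generate_bundle(cfg), tmp_path / "a")
        write_bundle(generate_bundle(cfg), tmp_path / "b")
        for name in ("sites.csv", "frequencies.csv", "truth.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_generate_bundle_seed_override():
    a = generate_bundle(SyntheticConfig(grid_rows=6, grid_cols=6, n_snps=4, n_adaptive=1, seed=1))
    b = generate_bundle(
        dataclasses.replace(a.config, seed=2)
    )
    assert not np.array_equal(a.env_current.data, b.env_current.data)
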