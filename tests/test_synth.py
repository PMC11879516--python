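"""Synthetic-study generator: determinism, LD structure, GWAS calibration,
schedule legality and the generative identity of the ESM regime."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dailysens.synth import (
    CrossoverParams,
    SynthConfig,
    simulate_esm,
    simulate_genotypes,
    simulate_summary_stats,
)


def within_block_corrs(geno, cfg):
    out = []
    for b in range(cfg.n_blocks):
        block = geno.dosages[:, b * cfg.snps_per_block : (b + 1) * cfg.snps_per_block]
        r = np.corrcoef(block, rowvar=False)
        iu = np.triu_indices_from(r, k=1)
        out.append(r[iu])
    return np.concatenate(out)


class TestGenotypes:
    def test_deterministic_under_seed(self):
        cfg = SynthConfig(seed=5, n_subjects=40, n_blocks=3, snps_per_block=4)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snp_map.equals(b.snp_map)

    def test_dosages_are_biallelic_counts(self):
        cfg = SynthConfig(seed=1, n_subjects=30, n_blocks=2, snps_per_block=5)
        g = simulate_genotypes(cfg)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}

    def test_uncorrelated_blocks_when_corr_zero(self):
        cfg = SynthConfig(seed=2, n_subjects=500, n_blocks=4, snps_per_block=8,
                          block_corr=0.0)
        g = simulate_genotypes(cfg)
        assert np.abs(within_block_corrs(g, cfg)).mean() < 0.1

    def test_block_ld_matches_monte_carlo_oracle(self):
        # independent re-simulation of the same latent-Gaussian threshold
        # scheme, coded from the definition with its own RNG
        cfg = SynthConfig(seed=3, n_subjects=1000, n_blocks=5, snps_per_block=10,
                          block_corr=0.9, maf_range=(0.1, 0.4))
        g = simulate_genotypes(cfg)
        observed = np.mean(within_block_corrs(g, cfg) ** 2)

        rng = np.random.default_rng(991)
        n, m, rho = 4000, 10, 0.9
        r2s = []
        for _ in range(5):
            mafs = rng.uniform(0.1, 0.4, m)
            thr = sps.norm.ppf(mafs)
            dose = np.zeros((n, m))
            for _hap in range(2):
                z = np.sqrt(rho) * rng.standard_normal((n, 1)) + np.sqrt(
                    1 - rho
                ) * rng.standard_normal((n, m))
                dose += z < thr
            r = np.corrcoef(dose, rowvar=False)
            r2s.append(np.mean(r[np.triu_indices(m, k=1)] ** 2))
        assert abs(observed - np.mean(r2s)) < 0.15

    def test_blocks_far_apart(self):
        cfg = SynthConfig(seed=1, n_subjects=10, n_blocks=3, snps_per_block=5)
        g = simulate_genotypes(cfg)
        bp = g.snp_map["bp"].to_numpy()
        ends = bp.reshape(3, 5)
        assert (ends[1:, 0] - ends[:-1, -1]).min() >= 2_000_000

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError, match="maf"):
            SynthConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError, match="maf"):
            SynthConfig(maf_range=(0.4, 0.2))


class TestSummaryStats:
    def test_zero_effect_limit(self):
        cfg = SynthConfig(seed=4, n_blocks=3, snps_per_block=5, prop_causal=1.0,
                          beta_sd=0.0)
        g = simulate_genotypes(cfg)
        st = simulate_summary_stats(g.snp_map, cfg)
        assert np.all(st.table["beta"] == 0.0)
        assert np.all(st.table["p"] == 1.0)

    def test_p_monotone_in_standardized_beta(self):
        cfg = SynthConfig(seed=5, n_blocks=10, snps_per_block=20, prop_causal=0.5)
        g = simulate_genotypes(cfg)
        st = simulate_summary_stats(g.snp_map, cfg)
        maf = g.snp_map["maf"].to_numpy()
        standardized = np.abs(st.table["beta"]) * np.sqrt(2 * maf * (1 - maf))
        rho = sps.spearmanr(st.table["p"], standardized).statistic
        assert rho < -0.99

    def test_null_p_values_uniform(self):
        cfg = SynthConfig(seed=6, n_blocks=250, snps_per_block=20, prop_causal=0.0)
        g_map = simulate_genotypes(
            cfg.replace(n_subjects=2)
        ).snp_map  # only the map is needed
        st = simulate_summary_stats(g_map, cfg)
        frac = (st.table["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_p_in_unit_interval(self):
        cfg = SynthConfig(seed=7, n_blocks=5, snps_per_block=10, beta_sd=0.5)
        g = simulate_genotypes(cfg)
        st = simulate_summary_stats(g.snp_map, cfg)
        p = st.table["p"]
        assert np.all((p > 0) & (p <= 1))

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_summary_stats(pd.DataFrame(), SynthConfig())


def small_esm_cfg(**kw):
    base = dict(seed=11, n_subjects=25, n_blocks=2, snps_per_block=4)
    base.update(kw)
    return SynthConfig(**base)


class TestEsmGeneration:
    def test_full_compliance_beep_count(self):
        cfg = small_esm_cfg(compliance=1.0)
        g = np.zeros(cfg.n_subjects)
        df, _ = simulate_esm(g, cfg)
        counts = df[df.observed].groupby("subject_id").size()
        assert (counts == 56).all()

    def test_schedule_legality(self):
        for seed in (0, 1, 2):
            cfg = small_esm_cfg(seed=seed)
            df, _ = simulate_esm(np.zeros(cfg.n_subjects), cfg)
            assert df["time_min"].between(600, 1320).all()
            gaps = df.groupby(["subject_id", "day"])["time_min"].diff().dropna()
            assert gaps.between(10, 170).all()

    def test_compliance_calibrated_to_observed_mean(self):
        # a 217-subject week at the default compliance completes ~40.7
        # questionnaires per person on average
        cfg = SynthConfig(seed=12, n_subjects=217, n_blocks=2, snps_per_block=4)
        df, _ = simulate_esm(np.zeros(217), cfg)
        mean_completed = df[df.observed].groupby("subject_id").size().mean()
        assert abs(mean_completed - 40.7) < 2.0

    def test_impossible_schedule_rejected(self):
        cfg = small_esm_cfg(signals_per_day=80)
        with pytest.raises(ValueError, match="impossible schedule"):
            simulate_esm(np.zeros(cfg.n_subjects), cfg)

    def test_deterministic_after_serialization(self):
        cfg = small_esm_cfg()
        a, _ = simulate_esm(np.zeros(cfg.n_subjects), cfg)
        b, _ = simulate_esm(np.zeros(cfg.n_subjects), cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_generative_identity_in_continuous_mode(self):
        # no rounding, no item noise: every index column equals its latent
        cfg = small_esm_cfg(round_items=False, item_noise_sd=0.0)
        df, truth = simulate_esm(np.zeros(cfg.n_subjects), cfg)
        from dailysens.esm import build_indices

        d = build_indices(df)
        obs = d.observed.to_numpy()
        np.testing.assert_allclose(
            d.loc[obs, "paranoia"], truth.latent_outcome[obs], rtol=0, atol=1e-12
        )

    def test_items_on_grid_when_rounded(self):
        cfg = small_esm_cfg(round_items=True)
        df, _ = simulate_esm(np.zeros(cfg.n_subjects), cfg)
        items = df.filter(like="item_").to_numpy()
        vals = items[~np.isnan(items)]
        assert set(np.unique(vals)) <= set(np.arange(1.0, 8.0))

    def test_context_means_near_presets(self):
        cfg = SynthConfig(seed=13, n_subjects=300, n_blocks=2, snps_per_block=4)
        df, _ = simulate_esm(np.zeros(300), cfg)
        obs = df[df.observed]
        assert abs(obs["item_situation_stressful"].mean() - 2.15) < 0.2
        assert abs(obs["item_situation_positive"].mean() - 5.35) < 0.2

    def test_null_interaction_slope_recovered(self):
        # s1 = 0, sigma_u = 0: OLS of outcome on G(E-c) finds nothing
        zs = []
        for seed in range(20):
            cfg = small_esm_cfg(
                seed=100 + seed,
                n_subjects=40,
                round_items=False,
                item_noise_sd=0.0,
                compliance=1.0,
                true_params=CrossoverParams(
                    b0=3.0, s0=0.0, s1=0.0, c=4.0, sigma_u=0.0, sigma_e=0.4
                ),
            )
            rng = np.random.default_rng(seed)
            g = rng.standard_normal(cfg.n_subjects)
            df, truth = simulate_esm(g, cfg)
            from dailysens.esm import build_indices, make_lagged_pairs

            pairs = make_lagged_pairs(
                build_indices(df), "positive", "paranoia", g=truth.g
            )
            x = (pairs.G * (pairs.E - 4.0)).to_numpy()
            res = sps.linregress(x, pairs.y.to_numpy())
            zs.append(res.slope / res.stderr)
        assert np.max(np.abs(zs)) < 3.0
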