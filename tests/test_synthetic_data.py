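import numpy as np
import pytest
from scipy.stats import spearmanr

from assemblage.niche import observed_breadths
from assemblage.synthetic_data import (
    GuildPlan,
    Metacommunity,
    NeutralSimConfig,
    NicheSimConfig,
    inject_correlated_pair,
    niche_weights,
    simulate_dataset,
    simulate_metacommunity,
    simulate_neutral_sample,
    simulate_niche_sample,
)


class TestMetacommunity:
    def test_sigma_zero_is_uniform(self):
        meta = simulate_metacommunity(10, sigma_log=0.0, seed=1)
        np.testing.assert_allclose(meta.p, 0.1)

    def test_deterministic(self):
        a = simulate_metacommunity(50, sigma_log=1.2, seed=9)
        b = simulate_metacommunity(50, sigma_log=1.2, seed=9)
        np.testing.assert_array_equal(a.p, b.p)

    def test_rank_abundance_strictly_decreasing(self):
        meta = simulate_metacommunity(500, sigma_log=1.5, seed=3)
        assert (np.diff(meta.p) < 0).all()
        assert np.isclose(meta.p.sum(), 1.0)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="S must be >= 2"):
            simulate_metacommunity(1, seed=0)

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            Metacommunity(p=np.array([0.5, 0.4]))


class TestNeutralSample:
    def test_full_immigration_tracks_metacommunity(self):
        # m=1: every replacement is an immigrant, so the local community is a
        # fresh multinomial draw from p at all times.
        meta = simulate_metacommunity(20, sigma_log=1.0, seed=5)
        cfg = NeutralSimConfig(S=20, N=5000, m=1.0, depth=50_000, seed=5)
        counts = simulate_neutral_sample(meta, cfg)
        mad = np.abs(counts / counts.sum() - meta.p).mean()
        assert mad < 0.005

    def test_zero_immigration_fixes_one_taxon(self):
        meta = simulate_metacommunity(5, sigma_log=0.5, seed=2)
        cfg = NeutralSimConfig(
            S=5, N=20, m=0.0, burn_in_steps=40_000, depth=1000, seed=2
        )
        counts = simulate_neutral_sample(meta, cfg)
        assert (counts > 0).sum() == 1  # monodominance under pure drift

    def test_depth_is_exact(self):
        meta = simulate_metacommunity(30, seed=1)
        cfg = NeutralSimConfig(S=30, N=100, m=0.3, depth=777, seed=1)
        assert simulate_neutral_sample(meta, cfg).sum() == 777

    def test_mismatched_sizes(self):
        meta = simulate_metacommunity(30, seed=1)
        with pytest.raises(ValueError, match="does not match"):
            simulate_neutral_sample(meta, NeutralSimConfig(S=10, seed=1))

    def test_occurrence_tracks_abundance(self):
        # occurrence frequency across samples is monotone in p
        meta = simulate_metacommunity(200, sigma_log=1.5, seed=11)
        cols = [
            simulate_neutral_sample(
                meta,
                NeutralSimConfig(S=200, N=500, m=0.2, depth=10_000, seed=11_000 + j),
            )
            for j in range(30)
        ]
        occ = (np.stack(cols, axis=1) > 0).mean(axis=1)
        rho = spearmanr(occ, meta.p).statistic
        assert rho > 0.9

    def test_invalid_configs(self):
        with pytest.raises(ValueError, match="m must"):
            NeutralSimConfig(S=10, m=1.5)
        with pytest.raises(ValueError, match="N must"):
            NeutralSimConfig(S=10, N=5)
        with pytest.raises(ValueError, match="depth"):
            NeutralSimConfig(S=10, depth=10)


class TestNicheSample:
    def test_flat_tolerance_reduces_to_metacommunity(self):
        meta = simulate_metacommunity(15, sigma_log=1.0, seed=4)
        env = np.linspace(-2, 2, 6)
        w = niche_weights(meta.p, env, np.zeros(15), np.full(15, np.inf))
        np.testing.assert_allclose(w, meta.p[:, None] * np.ones((1, 6)))

    def test_narrow_taxon_concentrates(self):
        # tolerance 0.01 with optimum on one of 18 sample envs: >=95% of the
        # taxon's expected reads land in that sample
        meta = simulate_metacommunity(10, sigma_log=0.0, seed=0)
        env = np.linspace(-2, 2, 18)
        optima = np.zeros(10)
        tolerances = np.full(10, np.inf)
        optima[0] = env[7]
        tolerances[0] = 0.01
        w = niche_weights(meta.p, env, optima, tolerances)
        taxon_share = w[0] / w[0].sum()
        assert taxon_share[7] > 0.95

    def test_identical_niches_preserve_abundance_ratio(self):
        meta = simulate_metacommunity(4, sigma_log=1.0, seed=8)
        env = np.array([0.0, 1.0])
        w = niche_weights(meta.p, env, np.zeros(4), np.full(4, 0.7))
        np.testing.assert_allclose(w[0] / w[1], meta.p[0] / meta.p[1])

    def test_pathological_optima_error(self):
        meta = simulate_metacommunity(3, sigma_log=0.0, seed=0)
        with pytest.raises(ValueError, match="vanish"):
            niche_weights(
                meta.p, np.array([0.0]), np.full(3, 1e6), np.full(3, 1e-3)
            )

    def test_sampled_counts_sum_to_depth(self):
        meta = simulate_metacommunity(12, seed=3)
        cfg = NicheSimConfig(
            env=np.linspace(-1, 1, 5),
            optima=np.zeros(12),
            tolerances=np.full(12, 1.0),
            depth=1234,
            seed=3,
        )
        assert simulate_niche_sample(meta, cfg, 2).sum() == 1234

    def test_config_validation(self):
        with pytest.raises(ValueError, match="positive"):
            NicheSimConfig(
                env=np.zeros(3), optima=np.zeros(2), tolerances=np.array([1.0, 0.0])
            )


class TestSimulateDataset:
    def test_deterministic(self):
        a, _ = simulate_dataset(S=30, groups={"A": 4}, lam=0.4, depth=1000, seed=5, N=100)
        b, _ = simulate_dataset(S=30, groups={"A": 4}, lam=0.4, depth=1000, seed=5, N=100)
        assert a == b

    def test_columns_sum_to_depth(self, small_table):
        assert (small_table.library_sizes == 3000).all()

    def test_truth_labels(self, small_dataset):
        _, truth = small_dataset
        assert truth.guild[:4] == ("generalist",) * 4
        assert truth.guild[4:8] == ("specialist",) * 4
        assert set(truth.guild[8:]) == {"intermediate"}

    def test_guild_plan_too_large(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_dataset(
                S=5, groups={"A": 4}, lam=0.5, guild_plan=GuildPlan(3, 3),
                depth=500, seed=0, N=50,
            )

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError, match="lam"):
            simulate_dataset(S=10, groups={"A": 4}, lam=1.5, depth=500, seed=0)

    def test_planted_narrow_taxa_have_smaller_breadth(self):
        # planted narrow-niche taxa show strictly smaller mean Levins breadth
        # than planted wide-niche taxa, across seeds
        for seed in range(5):
            table, truth = simulate_dataset(
                S=80, groups={"A": 10}, lam=1.0,
                guild_plan=GuildPlan(n_wide=5, n_narrow=5),
                depth=5000, seed=seed,
            )
            b = observed_breadths(table)
            wide = [i for i, g in enumerate(truth.guild) if g == "generalist"]
            narrow = [i for i, g in enumerate(truth.guild) if g == "specialist"]
            assert np.nanmean(b[narrow]) < np.nanmean(b[wide])


class TestInjectCorrelatedPair:
    def test_comonotone_limit(self, small_table):
        out = inject_correlated_pair(small_table, "OTU_0001", "OTU_0002", "+", 1.0, seed=3)
        ia, ib = 0, 1
        ra = np.argsort(np.argsort(out.counts[ia]))
        rb = np.argsort(np.argsort(out.counts[ib]))
        # identical latent -> identical rank order (up to ties in counts)
        assert spearmanr(out.counts[ia], out.counts[ib]).statistic > 0.99

    def test_antithetic_limit(self, small_table):
        out = inject_correlated_pair(small_table, "OTU_0001", "OTU_0002", "-", 1.0, seed=3)
        assert spearmanr(out.counts[0], out.counts[1]).statistic < -0.99

    def test_marginals_preserved(self, small_table):
        out = inject_correlated_pair(small_table, "OTU_0001", "OTU_0002", "+", 0.8, seed=1)
        assert sorted(out.counts[0]) == sorted(small_table.counts[0])
        assert sorted(out.counts[1]) == sorted(small_table.counts[1])
        np.testing.assert_array_equal(out.counts[2:], small_table.counts[2:])

    def test_unknown_otu(self, small_table):
        with pytest.raises(KeyError, match="nope"):
            inject_correlated_pair(small_table, "nope", "OTU_0002", "+", 0.5, seed=1)

    def test_strength_validation(self, small_table):
        with pytest.raises(ValueError, match="strength"):
            inject_correlated_pair(small_table, "OTU_0001", "OTU_0002", "+", 0.0, seed=1)
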