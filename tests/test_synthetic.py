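import numpy as np
import pytest
from scipy import stats

from regulonrank.synthetic_data import (
    GENOTYPES,
    SyntheticConfig,
    generate_expression,
    generate_network,
    generate_study,
)
from regulonrank.deg_stats import call_degs, run_gene_tests
from regulonrank.tf_enrichment import build_contingency, fisher_exact


def small_config(**kw) -> SyntheticConfig:
    base = dict(n_genes=400, n_tfs=40, n_active_tfs=5,
                targets_per_tf=(5, 20), seed=0)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("deg_fraction", 0.0),
            ("deg_fraction", 1.0),
            ("noise_sd", 0.0),
            ("pair_correlation", 1.5),
            ("n_active_tfs", 99),
            ("active_odds_ratio", 0.5),
            ("targets_per_tf", (0, 5)),
            ("targets_per_tf", (5, 100_000)),
        ],
    )
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValueError):
            small_config(**{field: value})

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(effect_size=2.5, seed=7)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestGenerateExpression:
    def test_same_seed_identical(self):
        cfg = small_config()
        em1, t1 = generate_expression(cfg)
        em2, t2 = generate_expression(cfg)
        assert t1 == t2
        np.testing.assert_array_equal(em1.values.to_numpy(),
                                      em2.values.to_numpy())

    def test_marginal_moments(self):
        cfg = SyntheticConfig(n_genes=4000, noise_sd=0.4,
                              pair_correlation=0.6, effect_size=0.0, seed=3)
        em, _ = generate_expression(cfg)
        un = em.values[em.group_samples("WT", "saline")].to_numpy()
        ind = em.values[em.group_samples("WT", "caerulein")].to_numpy()
        # per-gene means carry the N(8, 1.5) baseline
        assert un.mean() == pytest.approx(8.0, abs=0.1)
        assert np.std(un.mean(axis=1)) == pytest.approx(
            np.sqrt(1.5**2 + 0.4**2 / 3), abs=0.05
        )
        # within-pair correlation of the noise ~ pair_correlation
        d_un = un - un.mean(axis=1, keepdims=True)
        d_in = ind - ind.mean(axis=1, keepdims=True)
        r = np.corrcoef(d_un.ravel(), d_in.ravel())[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)

    def test_vanishing_noise_calls_exactly_the_planted(self):
        # the t statistic is scale-invariant, so the noise must truly vanish
        # (here: underflow against the baseline) for null genes to be silent;
        # planted genes then have zero variance with shifted means and are
        # flagged degenerate with p = 0
        cfg = small_config(noise_sd=1e-18, effect_size=1.0)
        em, truth = generate_expression(cfg)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            tab = run_gene_tests(
                em,
                em.group_samples("WT", "caerulein"),
                em.group_samples("WT", "saline"),
            )
        assert call_degs(tab) == truth

    def test_null_rejection_rate_near_alpha(self):
        cfg = SyntheticConfig(n_genes=5000, effect_size=0.0, seed=11)
        em, _ = generate_expression(cfg)
        tab = run_gene_tests(
            em,
            em.group_samples("WT", "caerulein"),
            em.group_samples("WT", "saline"),
        )
        assert 0.035 <= tab["is_deg"].mean() <= 0.065


class TestGenerateNetwork:
    def test_same_seed_identical(self):
        cfg = small_config()
        _, truth = generate_expression(cfg)
        n1, a1 = generate_network(cfg, truth)
        n2, a2 = generate_network(cfg, truth)
        assert n1.pairs == n2.pairs and a1 == a2

    def test_active_a_cell_matches_analytic_expectation(self):
        # odds ratio w on a 10% planted background makes each target draw a
        # planted DEG with probability w*0.1 / (0.9 + w*0.1) ~ 0.526 at w=10
        cfg = SyntheticConfig(
            n_genes=20_000, deg_fraction=0.1, n_tfs=120, n_active_tfs=100,
            targets_per_tf=(50, 50), active_odds_ratio=10.0, seed=5,
        )
        rng = np.random.default_rng(5)
        genes = [f"g{i:05d}" for i in range(1, cfg.n_genes + 1)]
        planted = set(rng.choice(genes, size=2000, replace=False))
        net, active = generate_network(cfg, planted, universe=genes)
        from regulonrank.regnet import tf_target_sets

        sets = tf_target_sets(net)
        a_cells = [len(sets[tf] & planted) for tf in active]
        expected = 50 * (10 * 0.1) / (0.9 + 10 * 0.1)
        sem = np.sqrt(expected * (1 - expected / 50) / len(a_cells))
        assert np.mean(a_cells) == pytest.approx(expected, abs=4 * sem + 0.5)

    def test_null_odds_ratio_makes_active_indistinguishable(self):
        cfg = SyntheticConfig(
            n_genes=2000, deg_fraction=0.15, n_tfs=200, n_active_tfs=100,
            targets_per_tf=(20, 40), active_odds_ratio=1.0, seed=9,
        )
        rng = np.random.default_rng(9)
        genes = [f"g{i:04d}" for i in range(1, cfg.n_genes + 1)]
        planted = set(rng.choice(genes, size=300, replace=False))
        net, active = generate_network(cfg, planted, universe=genes)
        from regulonrank.regnet import tf_target_sets

        sets = tf_target_sets(net)
        p_active, p_inactive = [], []
        for tf, targets in sets.items():
            tab = build_contingency(targets, planted, set(genes))
            (p_active if tf in active else p_inactive).append(
                fisher_exact(tab)
            )
        ks = stats.ks_2samp(p_active, p_inactive)
        assert ks.pvalue > 0.01


class TestGenerateStudy:
    def test_four_groups_twelve_samples(self):
        bundle = generate_study(small_config())
        em = bundle.expression
        assert em.n_samples == 4 * 3
        groups = {
            (gt, tr)
            for gt, tr in em.design[["genotype", "treatment"]].itertuples(
                index=False
            )
        }
        assert groups == {
            (g, t) for g in GENOTYPES for t in ("saline", "caerulein")
        }

    def test_ko_multiplier_one_gives_equal_planted_counts(self):
        bundle = generate_study(small_config(ko_deg_multiplier=1.0))
        wt, ko = (bundle.truth_degs[g] for g in GENOTYPES)
        assert len(wt) == len(ko)
        assert wt == ko  # KO set is built as a superset of the WT core

    def test_ko_planted_is_superset_with_multiplier(self):
        bundle = generate_study(small_config(ko_deg_multiplier=2.0))
        wt, ko = (bundle.truth_degs[g] for g in GENOTYPES)
        assert wt <= ko
        assert len(ko) == pytest.approx(2 * len(wt), abs=1)

    def test_bundle_write_round_trips(self, tmp_path):
        from regulonrank.io_formats import (
            read_expression_table,
            read_network_pairs,
        )

        bundle = generate_study(small_config())
        paths = bundle.write(tmp_path)
        em = read_expression_table(paths["matrix"], paths["design"])
        assert em.n_genes == bundle.expression.n_genes
        net = read_network_pairs(paths["network"],
                                 universe=set(em.gene_ids))
        assert net.pairs == bundle.network.pairs
        truth_lines = paths["truth_tfs"].read_text().splitlines()[1:]
        assert set(truth_lines) == bundle.active_tfs
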