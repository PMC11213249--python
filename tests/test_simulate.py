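import numpy as np
import pandas as pd
import pytest

from leafmix.simulate import (
    ConfigError,
    Constant,
    Monotone,
    NetworkSimConfig,
    ReferenceSimConfig,
    Sinusoid,
    leaf_reference_config,
    simulate_bulk_series,
    simulate_network,
    simulate_reference,
)


# ---------------------------------------------------------------- reference

def test_reference_empirical_means_match_planted_profiles():
    """Monte-Carlo oracle: with 2 types x 200 cells the per-gene empirical
    mean stays within 3 standard errors of the planted negative-binomial
    mean."""
    cfg = ReferenceSimConfig(
        n_cell_types=2, cells_per_type=(200, 200), n_genes=100,
        markers_per_type=10, marker_fold_change=8.0, baseline_mean=2.0,
        dispersion=2.0, seed=3,
    )
    ref = simulate_reference(cfg)
    for t in ref.true_profiles.columns:
        cells = ref.labels[ref.labels == t].index
        block = ref.counts[cells].to_numpy(dtype=float)
        mean = block.mean(axis=1)
        mu = ref.true_profiles[t].to_numpy()
        se = np.sqrt((mu + mu**2 / cfg.dispersion) / len(cells))
        # a gene lands outside 3 SE with prob ~0.3%; nearly all must be inside
        assert (np.abs(mean - mu) <= 3 * se + 1e-12).mean() >= 0.95


def test_zero_mean_profile_rows_produce_zero_counts():
    from leafmix.simulate import _nb_sample

    draws = _nb_sample(np.random.default_rng(0), np.zeros((5, 20)), 0.5)
    assert (draws == 0).all()


def test_default_leaf_roster_has_three_mesophyll_groups_and_confusable_hydathode():
    cfg = leaf_reference_config()
    assert sum(n.startswith("mesophyll") for n in cfg.type_names) == 3
    (a, b, w), = cfg.confusable_pairs
    assert cfg.type_names[b] == "hydathode"
    assert cfg.type_names[a] == "mesophyll_1"
    assert w == 0.8


def test_confusable_mixing_applied_to_profiles():
    cfg = ReferenceSimConfig(
        n_cell_types=2, cells_per_type=(5, 5), n_genes=20, markers_per_type=5,
        marker_fold_change=10.0, baseline_mean=1.0,
        confusable_pairs=((0, 1, 0.8),), seed=0,
    )
    ref = simulate_reference(cfg)
    p = ref.true_profiles.to_numpy()
    # type 1's profile is 0.2 * own + 0.8 * type 0's
    assert p[0, 1] == pytest.approx(0.2 * 1.0 + 0.8 * 10.0)


def test_reference_config_errors_name_the_field():
    with pytest.raises(ConfigError, match="cells_per_type"):
        ReferenceSimConfig(n_cell_types=2, cells_per_type=(5,), n_genes=10,
                           markers_per_type=2)
    with pytest.raises(ConfigError, match="markers_per_type"):
        ReferenceSimConfig(n_cell_types=2, cells_per_type=(5, 5), n_genes=3,
                           markers_per_type=2)
    with pytest.raises(ConfigError, match="weight"):
        ReferenceSimConfig(n_cell_types=2, cells_per_type=(5, 5), n_genes=10,
                           markers_per_type=2, confusable_pairs=((0, 1, 1.5),))


def test_identical_seeds_reproduce_identical_references():
    cfg = dict(n_cell_types=2, cells_per_type=(10, 10), n_genes=30,
               markers_per_type=3, seed=9)
    a = simulate_reference(ReferenceSimConfig(**cfg))
    b = simulate_reference(ReferenceSimConfig(**cfg))
    pd.testing.assert_frame_equal(a.counts, b.counts)


# ------------------------------------------------------------- bulk series

@pytest.fixture
def two_type_profiles():
    return pd.DataFrame(
        {"A": [5.0, 1.0, 1.0], "B": [1.0, 5.0, 1.0]}, index=["g1", "g2", "g3"]
    )


def test_single_type_series_has_fraction_one(two_type_profiles):
    profiles = two_type_profiles[["A"]]
    series = simulate_bulk_series(
        profiles, {"A": Constant(1.0)}, timepoints=[0, 6], depth=10000,
        n_replicates=2, replicate_noise_sd=0.0, seed=0,
    )
    assert (series.true_fractions["A"] == 1.0).all()


def test_constant_weights_normalize_to_fixed_fractions(two_type_profiles):
    series = simulate_bulk_series(
        two_type_profiles, {"A": Constant(1.0), "B": Constant(3.0)},
        timepoints=[0, 12], depth=10000, n_replicates=3,
        replicate_noise_sd=0.0, seed=1,
    )
    np.testing.assert_allclose(series.true_fractions["A"], 0.25)
    np.testing.assert_allclose(series.true_fractions["B"], 0.75)


def test_sinusoid_fraction_argmax_at_planted_phase(two_type_profiles):
    series = simulate_bulk_series(
        two_type_profiles,
        {"A": Sinusoid(amplitude=0.5, phase_hours=6.0), "B": Constant(1.0)},
        timepoints=range(0, 24, 2), depth=10000, n_replicates=1,
        replicate_noise_sd=0.0, seed=2,
    )
    frac = series.true_fractions["A"]
    times = series.metadata.loc[frac.idxmax(), "time_hours"]
    assert times == 6.0


def test_true_fraction_rows_on_simplex(two_type_profiles):
    series = simulate_bulk_series(
        two_type_profiles,
        {"A": Monotone(0.5, 2.0), "B": Sinusoid(0.3, 10.0)},
        timepoints=range(0, 24, 4), depth=5000, n_replicates=4,
        replicate_noise_sd=0.05, seed=3,
    )
    f = series.true_fractions.to_numpy()
    assert (f >= 0).all()
    np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-9)


def test_negative_trajectory_weight_raises(two_type_profiles):
    with pytest.raises(ConfigError, match="negative"):
        simulate_bulk_series(
            two_type_profiles,
            {"A": Sinusoid(amplitude=2.0, phase_hours=0.0), "B": Constant(1.0)},
            timepoints=[0, 12], depth=1000, n_replicates=1, seed=0,
        )


def test_bulk_counts_approach_poisson_at_large_dispersion(two_type_profiles):
    """Variance/mean of replicate bulk counts is ~1 when the only count
    noise is Poisson (replicate noise off, fixed fractions)."""
    profiles = pd.DataFrame(
        {"A": np.full(1000, 3.0)}, index=[f"g{i}" for i in range(1000)]
    )
    series = simulate_bulk_series(
        profiles, {"A": Constant(1.0)}, timepoints=[0], depth=200_000,
        n_replicates=50, replicate_noise_sd=0.0, seed=4,
    )
    X = series.counts.to_numpy(dtype=float)
    ratio = X.var(axis=1, ddof=1) / X.mean(axis=1)
    assert abs(ratio.mean() - 1.0) < 0.05


def test_traits_increase_with_age(two_type_profiles):
    series = simulate_bulk_series(
        two_type_profiles, {"A": Constant(1.0), "B": Constant(1.0)},
        timepoints=range(4, 30, 2), depth=1000, n_replicates=1,
        replicate_noise_sd=0.0, seed=5, time_column="age_days", traits=True,
    )
    from scipy.stats import spearmanr
    for trait in ("pseudotime", "biomass", "leaf_area"):
        rho = spearmanr(series.metadata["age_days"], series.metadata[trait])[0]
        assert rho > 0.9


# ----------------------------------------------------------------- network

def test_null_network_pair_counts_match_binomial_expectation():
    cfg = NetworkSimConfig(n_tfs=50, n_targets=100, n_edges=1000, n_terms=2,
                           annotation_prob=0.4, seed=6)
    counts, expect = [], []
    for rep in range(30):
        net = simulate_network(
            NetworkSimConfig(**{**cfg.__dict__, "seed": 600 + rep})
        )
        a = set(net.annotations["TERM000"])
        b = set(net.annotations["TERM001"])
        obs = (net.edges["source"].isin(a) & net.edges["target"].isin(b)).sum()
        tf_frac = np.mean([f"TF{i:04d}" in a for i in range(50)])
        tg_frac = np.mean([f"TG{i:04d}" in b for i in range(100)])
        counts.append(obs)
        expect.append(1000 * tf_frac * tg_frac)
    counts, expect = np.array(counts), np.array(expect)
    assert abs(counts.mean() - expect.mean()) < 3 * counts.std() / np.sqrt(len(counts))


def test_planted_pair_oversampled_by_enrichment_factor():
    """Expectation of the stated sampler: planted A->B edge count ~
    factor * p0 * n_edges (to Monte-Carlo tolerance at low density)."""
    obs, exp = [], []
    for rep in range(30):
        cfg = NetworkSimConfig(n_tfs=50, n_targets=200, n_edges=300, n_terms=2,
                               annotation_prob=0.2,
                               planted_pairs=(("TERM000", "TERM001", 5.0),),
                               seed=700 + rep)
        net = simulate_network(cfg)
        a, b = set(net.annotations["TERM000"]), set(net.annotations["TERM001"])
        obs.append(
            (net.edges["source"].isin(a) & net.edges["target"].isin(b)).sum()
        )
        tf_frac = np.mean([f"TF{i:04d}" in a for i in range(50)])
        tg_frac = np.mean([f"TG{i:04d}" in b for i in range(200)])
        p0 = tf_frac * tg_frac
        exp.append(5.0 * p0 * 300 / (1 + 4.0 * p0))  # weight renormalization
    obs, exp = np.array(obs, float), np.array(exp)
    assert abs(obs.mean() - exp.mean()) < 3 * obs.std() / np.sqrt(len(obs))


def test_annotation_prob_near_zero_gives_no_term_edges():
    cfg = NetworkSimConfig(n_tfs=20, n_targets=40, n_edges=100, n_terms=3,
                           annotation_prob=1e-9, seed=8)
    net = simulate_network(cfg)
    assert all(len(g) == 0 for g in net.annotations.values())


def test_network_config_errors():
    with pytest.raises(ConfigError, match="n_edges"):
        NetworkSimConfig(n_tfs=2, n_targets=2, n_edges=5, n_terms=1,
                         annotation_prob=0.5)
    with pytest.raises(ConfigError, match="enrichment_factor"):
        NetworkSimConfig(n_tfs=5, n_targets=5, n_edges=5, n_terms=2,
                         annotation_prob=0.5,
                         planted_pairs=(("TERM000", "TERM001", 0.5),))


def test_identical_seeds_reproduce_identical_networks():
    cfg = dict(n_tfs=10, n_targets=20, n_edges=50, n_terms=2,
               annotation_prob=0.3, seed=12)
    a = simulate_network(NetworkSimConfig(**cfg))
    b = simulate_network(NetworkSimConfig(**cfg))
    pd.testing.assert_frame_equal(a.edges, b.edges)
    assert a.annotations == b.annotations
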