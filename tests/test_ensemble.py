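"""Parameter sampling, ensemble reproducibility, cluster classification
and the recruitment-parameter sweeps."""

import numpy as np
import pytest
from scipy.stats import kstest

from transposim import (
    ClusterRules,
    EnsembleConfig,
    RunOutcome,
    build_network,
    classify_kmeans,
    classify_outcome,
    default_parameters,
    histogram2d_log,
    integrate_ode,
    outcomes_to_frame,
    run_ensemble,
    sample_parameter_set,
    summarize_clusters,
    sweep_2d,
    sweep_axes,
    terminal_outcome,
)
from transposim.ensemble import DEFAULT_SAMPLED
from transposim.network import ModelVariant
from transposim.params import ParameterSet


def _outcome(T_act, T_sil, VLP, variant="rdrp", **kw):
    defaults = dict(
        run_id=0, variant=ModelVariant.coerce(variant),
        params=default_parameters(), control=VLP < 1.0, diverged=False,
    )
    defaults.update(kw)
    o = RunOutcome(T_act=T_act, T_sil=T_sil, VLP=VLP, **defaults)
    return o


class TestSampler:
    def test_sample_within_hundredfold_range(self, rng, params):
        for _ in range(200):
            s = sample_parameter_set(params, 100.0, rng)
            assert 1.6 <= s.v_ta <= 160.0
            assert 0.01 <= s.j <= 1.0
            assert 0.0 <= s.f <= 1.0

    def test_degenerate_fold_range_collapses_to_reference(self, rng, params):
        s = sample_parameter_set(params, 1.0 + 1e-9, rng)
        for name in ParameterSet.names():
            assert s[name] == pytest.approx(params[name], rel=1e-4)

    def test_burst_size_fixed_unless_requested(self, rng, params):
        assert "n" not in DEFAULT_SAMPLED
        s = sample_parameter_set(params, 100.0, rng)
        assert s.n == params.n
        t = sample_parameter_set(params, 100.0, rng, sampled=ParameterSet.names())
        assert t.n == int(t.n) and t.n >= 1

    def test_log_sampler_is_log_uniform(self, params):
        """Under the log-uniform option the log of each draw follows a
        uniform law on [log(ref/10), log(10 ref)] (Kolmogorov-Smirnov)."""
        rng = np.random.default_rng(99)
        draws = np.array([
            sample_parameter_set(params, 100.0, rng, sampled=("v_ta",),
                                 sampler="log").v_ta
            for _ in range(4000)
        ])
        logs = np.log10(draws)
        lo, hi = np.log10(16 / 10), np.log10(16 * 10)
        stat = kstest(logs, "uniform", args=(lo, hi - lo))
        assert stat.pvalue > 0.01

    def test_linear_sampler_is_uniform(self, params):
        rng = np.random.default_rng(98)
        draws = np.array([
            sample_parameter_set(params, 100.0, rng, sampled=("d_m",)).d_m
            for _ in range(4000)
        ])
        lo, hi = 0.14 / 10, 0.14 * 10
        stat = kstest(draws, "uniform", args=(lo, hi - lo))
        assert stat.pvalue > 0.01


class TestEnsemble:
    def test_single_run_narrow_range_matches_default_run(self, params):
        cfg = EnsembleConfig(variant="rdrp", n_runs=1, fold_range=1 + 1e-9, seed=0)
        (out,) = run_ensemble(cfg)
        net = build_network("rdrp")
        ref = terminal_outcome(integrate_ode(net, params, output_grid=None))
        assert out.T_act == pytest.approx(ref.T_act, rel=1e-4)
        assert out.T_sil == pytest.approx(ref.T_sil, rel=1e-4)
        assert out.VLP == pytest.approx(ref.VLP, rel=1e-4)
        assert out.control == ref.control

    def test_same_master_seed_reproduces_outcomes(self):
        cfg = EnsembleConfig(variant="hairpin", n_runs=20, seed=7)
        a = run_ensemble(cfg)
        b = run_ensemble(cfg)
        assert a == b
        c = run_ensemble(EnsembleConfig(variant="hairpin", n_runs=20, seed=8))
        assert a != c

    def test_per_run_seeding_is_order_independent(self):
        """Run 13's sampled parameters depend only on (master seed, id)."""
        big = run_ensemble(EnsembleConfig(variant="rdrp", n_runs=15, seed=5))
        from transposim.ensemble import _run_rng

        p13 = sample_parameter_set(default_parameters(), 100.0, _run_rng(5, 13))
        assert big[13].params == p13

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig(n_runs=0)
        with pytest.raises(ValueError):
            EnsembleConfig(fold_range=1.0)

    def test_outcomes_frame_holds_sampled_parameters(self):
        outs = run_ensemble(EnsembleConfig(variant="rdrp", n_runs=5, seed=2))
        df = outcomes_to_frame(outs)
        assert len(df) == 5
        assert {"param_v_ta", "T_act", "T_sil", "VLP", "cluster"} <= set(df.columns)
        assert df.param_v_ta.between(1.6, 160).all()


class TestClassifier:
    # terminal states quoted from the published per-cluster medians
    @pytest.mark.parametrize("variant", ["rdrp", "antisense", "hairpin"])
    def test_no_invasion_cluster(self, variant):
        assert classify_outcome(_outcome(0.70, 0.51, 1.1e-4), variant) == "red"

    def test_red_boundary_inclusive(self):
        assert classify_outcome(_outcome(1.5, 0.5, 10.0), "rdrp") == "red"
        assert classify_outcome(_outcome(1.5, 0.51, 10.0), "rdrp") != "red"

    def test_rdrp_out_of_control_cluster(self):
        """The canonical model's third cluster: silenced copies vastly
        outnumber active ones while VLPs persist."""
        assert classify_outcome(_outcome(58.52, 1.63e4, 4.62), "rdrp") == "blue"
        assert classify_outcome(_outcome(36.75, 19.43, 0.01), "rdrp") == "green"

    def test_antisense_low_vlp_cluster(self):
        assert classify_outcome(_outcome(25.28, 2866.41, 19.2e-4), "antisense") == "blue"
        assert classify_outcome(_outcome(7.30, 110.21, 0.01), "antisense") == "green"

    def test_hairpin_has_no_third_cluster(self):
        assert classify_outcome(_outcome(7.64, 372.57, 0.05), "hairpin") == "green"
        assert classify_outcome(_outcome(25.0, 2.9e3, 1e-3), "hairpin") == "green"

    def test_diverged_run_is_unclassified(self):
        assert classify_outcome(_outcome(1e12, 0, 0, diverged=True), "rdrp") == "unclassified"

    def test_kmeans_alternative_recovers_rule_red_and_partitions_rest(self):
        outs = (
            [_outcome(0.7, 0.5, 1e-4) for _ in range(5)]
            + [_outcome(30 + i, 20, 0.01) for i in range(5)]
            + [_outcome(50 + i, 2e4, 5.0) for i in range(5)]
        )
        labels = classify_kmeans(outs, k=3, rng_seed=0)
        assert labels[:5] == ["red"] * 5
        assert set(labels[5:]) == {"green", "blue"}
        # the high-VLP cloud is the blue one
        assert labels[10:] == ["blue"] * 5


class TestSummary:
    def test_identical_outcomes_single_cluster(self):
        outs = [_outcome(10.0, 5.0, 0.1, cluster="green") for _ in range(4)]
        s = summarize_clusters(outs)
        assert s.loc["median_T_act", "green"] == 10.0
        assert s.loc["frac_runs", "green"] == 1.0
        assert s.loc["frac_runs", "red"] == 0.0
        assert np.isnan(s.loc["median_VLP", "red"])

    def test_medians_match_brute_force(self):
        vals = [(1.0, 2.0, 0.5), (3.0, 8.0, 0.2), (5.0, 4.0, 2.0), (7.0, 6.0, 0.1)]
        outs = [_outcome(a, b, c, cluster="green") for a, b, c in vals]
        s = summarize_clusters(outs)
        assert s.loc["median_T_act", "green"] == np.median([v[0] for v in vals])
        assert s.loc["median_T_sil", "green"] == np.median([v[1] for v in vals])
        assert s.loc["frac_controlled", "green"] == 0.75

    def test_fractions_relative_to_full_ensemble(self):
        outs = run_ensemble(EnsembleConfig(variant="rdrp", n_runs=30, seed=3))
        s = summarize_clusters(outs)
        assert s.loc["frac_runs"].sum() == pytest.approx(1.0)


class TestHistogram:
    def test_single_outcome_single_bin(self):
        counts, _, _ = histogram2d_log([_outcome(10.0, 100.0, 0.5)], bins=10)
        assert counts.sum() == 1
        assert (counts > 0).sum() == 1

    def test_counts_conserve_outcomes(self):
        rng = np.random.default_rng(0)
        outs = [
            _outcome(10 ** rng.uniform(-1, 3), 10 ** rng.uniform(-1, 4), 0.1)
            for _ in range(150)
        ]
        counts, _, _ = histogram2d_log(outs, bins=20)
        assert counts.sum() == 150

    def test_two_cluster_fixture_yields_two_modes(self):
        rng = np.random.default_rng(1)
        a = [_outcome(10 ** rng.normal(0, 0.1), 10 ** rng.normal(0, 0.1), 0.1)
             for _ in range(80)]
        b = [_outcome(10 ** rng.normal(3, 0.1), 10 ** rng.normal(3, 0.1), 0.1)
             for _ in range(80)]
        counts, xe, ye = histogram2d_log(
            a + b, bins=8, range_decades=((-1, 4), (-1, 4))
        )
        # two separated modes: all mass in the low-low and high-high
        # blocks, nothing along the middle of the diagonal
        assert counts[:3, :3].sum() == 80
        assert counts[5:, 5:].sum() == 80
        assert counts[3:5, 3:5].sum() == 0


class TestSweep:
    def test_axes_per_variant(self):
        assert sweep_axes("rdrp") == ("p_n", "p_c")
        assert sweep_axes("antisense") == ("p_nx", "p_cx")
        assert sweep_axes("hairpin") == ("p_nx", "p_cxx")

    def test_invalid_parameter_for_variant(self):
        with pytest.raises(ValueError, match="p_nx, p_cxx"):
            sweep_2d("hairpin", "p_nx", "p_cx", [1e-4], [1e-4])

    def test_single_point_grid_reproduces_default_run(self, params):
        df = sweep_2d("rdrp", "p_n", "p_c", [params.p_n], [params.p_c])
        net = build_network("rdrp")
        ref = terminal_outcome(integrate_ode(net, params, output_grid=None))
        assert df.total_te.iloc[0] == pytest.approx(ref.total_te, rel=1e-4)
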