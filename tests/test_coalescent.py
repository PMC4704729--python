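"""Simulator oracles: analytic coalescent expectations, distributional checks
against closed forms and against msprime, and reproducibility contracts."""

import numpy as np
import pytest
from scipy import stats

from projana.coalescent import (
    Genealogy,
    drop_mutation,
    simulate_genealogy,
    simulate_projection,
    simulate_site_arrays,
    simulate_sites,
)
from projana.demography import (
    Deme,
    DemographicModel,
    ModelValidationError,
    PopulationSplit,
    PulseAdmixture,
    SampleGroup,
)

from conftest import one_pop_model, pair_model


class TestPairwiseCoalescence:
    def test_contemporaneous_mean_tmrca(self):
        # E[T2] = 2N for two present-day lineages
        N, reps = 5000.0, 5000
        rng = np.random.default_rng(1)
        t = np.array([simulate_genealogy(pair_model(N=N), rng).tmrca() for _ in range(reps)])
        se = t.std() / np.sqrt(reps)
        assert abs(t.mean() - 2 * N) < 4 * se

    def test_serial_pair_mean_tmrca(self):
        # one lineage at 0, one at t: E[TMRCA] = t + 2N
        N, t_anc, reps = 2000.0, 3000.0, 5000
        rng = np.random.default_rng(2)
        t = np.array(
            [simulate_genealogy(pair_model(t_second=t_anc, N=N), rng).tmrca() for _ in range(reps)]
        )
        se = t.std() / np.sqrt(reps)
        assert abs(t.mean() - (t_anc + 2 * N)) < 4 * se

    def test_piecewise_constant_cdf(self):
        # size 1000 until 500 ga then 5000: pairwise coalescence CDF is
        # piecewise exponential with rates 1/2000 then 1/10000
        epochs = ((0.0, 1000.0), (500.0, 5000.0))
        rng = np.random.default_rng(3)
        t = np.array(
            [simulate_genealogy(pair_model(epochs=epochs), rng).tmrca() for _ in range(5000)]
        )

        def cdf(x):
            x = np.asarray(x, dtype=float)
            early = 1 - np.exp(-x / 2000.0)
            late = 1 - np.exp(-500 / 2000.0) * np.exp(-(x - 500) / 10000.0)
            return np.where(x < 500, early, late)

        assert stats.kstest(t, cdf).pvalue > 0.01


class TestEvents:
    def test_pulse_f1_equals_split(self):
        # a pulse moving every lineage is a split: TMRCA distributions agree
        def model(event):
            return DemographicModel(
                (Deme("a", ((0, 2000),)), Deme("b", ((0, 2000),))),
                (PopulationSplit(5000.0, "b", "a"),) if event == "split"
                else (PulseAdmixture(5000.0, "a", "b", 1.0), PopulationSplit(9000.0, "b", "a")),
                (SampleGroup("a", 0, 1, "panel"), SampleGroup("b", 0, 1, "panel")),
            )

        rng = np.random.default_rng(4)
        t_split = [simulate_genealogy(model("split"), rng).tmrca() for _ in range(4000)]
        t_pulse = [simulate_genealogy(model("pulse"), rng).tmrca() for _ in range(4000)]
        assert stats.ks_2samp(t_split, t_pulse).pvalue > 0.01

    def test_sampling_time_consistency(self):
        # no node may be more recent than any lineage below it
        model = DemographicModel(
            (Deme("focal", ((0, 3000),)), Deme("sister", ((0, 3000),))),
            (PopulationSplit(2000.0, "sister", "focal"),),
            (
                SampleGroup("focal", 0, 8, "panel"),
                SampleGroup("focal", 600.0, 4, "panel"),
                SampleGroup("sister", 1500.0, 1, "test"),
            ),
        )
        rng = np.random.default_rng(5)
        for _ in range(200):
            tree = simulate_genealogy(model, rng)
            for v in range(tree.n_nodes - 1):
                assert tree.node_time[tree.parent[v]] >= tree.node_time[v]
            # the ancient test leaf enters at 1500
            test_leaf = int(np.where(tree.leaf_role == 1)[0][0])
            assert tree.node_time[tree.parent[test_leaf]] >= 1500.0

    def test_stranded_model_raises(self):
        bad = DemographicModel(
            (Deme("a", ((0, 100),)), Deme("b", ((0, 100),))),
            (),
            (SampleGroup("a", 0, 2, "panel"), SampleGroup("b", 0, 2, "panel")),
        )
        with pytest.raises(ModelValidationError):
            simulate_site_arrays(bad, 10, seed=0)


class TestMutations:
    def test_two_leaf_symmetry(self, rng):
        # equal branch lengths: each leaf derived with probability 1/2
        tree = Genealogy(
            node_time=np.array([0.0, 0.0, 100.0]),
            parent=np.array([2, 2, -1]),
            n_leaves=2,
            leaf_role=np.array([0, 0]),
            leaf_deme=np.array([0, 0]),
        )
        hits = sum(drop_mutation(tree, rng)[0] for _ in range(4000))
        assert hits / 4000 == pytest.approx(0.5, abs=0.03)
        # exactly one mutation: the partition is always a proper subset
        for _ in range(50):
            mask = drop_mutation(tree, rng)
            assert 0 < mask.sum() < 2 or mask.sum() == 1

    def test_star_tree_singletons(self, rng):
        k = 6
        tree = Genealogy(
            node_time=np.array([0.0] * k + [50.0]),
            parent=np.array([k] * k + [-1]),
            n_leaves=k,
            leaf_role=np.zeros(k, dtype=int),
            leaf_deme=np.zeros(k, dtype=int),
        )
        counts = np.zeros(k)
        for _ in range(3000):
            mask = drop_mutation(tree, rng)
            assert mask.sum() == 1  # singletons only
            counts += mask
        assert stats.chisquare(counts).pvalue > 0.01

    def test_neutral_sfs_one_over_i(self):
        # panmictic sample of 10: E[#sites with i derived] proportional to 1/i
        model = one_pop_model(n_panel=9, t_test=0.0, N=1000.0)  # 10 exchangeable lineages
        derived, test = simulate_site_arrays(model, 100_000, seed=11)
        total = derived + test  # count over all 10 lineages
        counts = np.bincount(total, minlength=11)[1:10]
        expect = (1 / np.arange(1, 10))
        expect = expect / expect.sum() * counts.sum()
        assert stats.chisquare(counts, expect).pvalue > 0.01


class TestBulkPath:
    def test_deterministic_replay(self):
        model = one_pop_model(n_panel=20, t_test=500.0)
        d1, t1 = simulate_site_arrays(model, 2000, seed=9)
        d2, t2 = simulate_site_arrays(model, 2000, seed=9)
        d3, _ = simulate_site_arrays(model, 2000, seed=10)
        assert np.array_equal(d1, d2) and np.array_equal(t1, t2)
        assert not np.array_equal(d1, d3)

    def test_site_table_flags_monomorphic(self):
        df = simulate_sites(one_pop_model(n_panel=10), 500, seed=1)
        mono = ~df["panel_polymorphic"]
        assert (df.loc[mono, "derived_count"].isin([0, 10])).all()
        assert len(df) == 500

    def test_kernel_matches_python_path(self):
        # site spectrum from the compiled path agrees with branch-length
        # expectations accumulated over reference-path genealogies
        model = one_pop_model(n_panel=20, t_test=1000.0)
        derived, _ = simulate_site_arrays(model, 30_000, seed=21)
        kern = np.bincount(derived, minlength=21).astype(float)

        rng = np.random.default_rng(22)
        py = np.zeros(21)
        for _ in range(3000):
            tree = simulate_genealogy(model, rng)
            lens = tree.branch_lengths()
            panel_leaves = tree.leaf_role == 0
            for v in range(tree.n_nodes - 1):
                i = int(tree.leaves_below(v)[panel_leaves].sum())
                py[i] += lens[v]
        bins = [0, 1, 2, 3, 5, 8, 12, 17, 21]
        k = np.add.reduceat(kern, bins[:-1])
        p = np.add.reduceat(py, bins[:-1])
        keep = p > 0
        expect = p[keep] / p[keep].sum() * k[keep].sum()
        assert stats.chisquare(k[keep], expect).pvalue > 0.005

    def test_expected_mode_matches_sampled_mode(self):
        model = one_pop_model(n_panel=30, t_test=1000.0)
        cs = simulate_projection(model, 150_000, seed=31)
        ce = simulate_projection(model, 40_000, seed=32, expected=True)
        both = cs.defined & ce.defined
        assert np.nanmean(np.abs(cs.w[both] - ce.w[both])) < 0.05
        assert np.nanmean(cs.w[both]) == pytest.approx(np.nanmean(ce.w[both]), abs=0.02)


class TestAgainstMsprime:
    """msprime as an independent implementation of the same process."""

    def test_joint_spectrum_with_ancient_sample(self):
        import msprime

        # sites arise proportionally to branch length: draw Poisson(L/mean L)
        # mutations per msprime tree so both sides carry sampling noise and a
        # two-sample test applies
        N, t_anc, n_panel, reps = 2000.0, 1500.0, 12, 12_000
        rng = np.random.default_rng(170)
        samples = [
            msprime.SampleSet(n_panel // 2, time=0, ploidy=2),
            msprime.SampleSet(1, time=t_anc, ploidy=1),
        ]
        demog = msprime.Demography.isolated_model([N])

        def trees():
            return msprime.sim_ancestry(
                samples=samples, demography=demog, num_replicates=reps, random_seed=17
            )

        mean_len = np.mean([ts.first().total_branch_length for ts in
                            msprime.sim_ancestry(samples=samples, demography=demog,
                                                 num_replicates=300, random_seed=19)])
        counts = np.zeros(n_panel + 1)
        for ts in trees():
            tree = ts.first()
            nodes = [v for v in tree.nodes() if v != tree.root]
            lens = np.array([tree.branch_length(v) for v in nodes])
            m = rng.poisson(lens.sum() / mean_len)
            if m == 0:
                continue
            picks = rng.choice(len(nodes), size=m, p=lens / lens.sum())
            for j in picks:
                p = sum(1 for l in tree.leaves(nodes[j]) if l < n_panel)
                counts[p] += 1

        model = one_pop_model(n_panel=n_panel, t_test=t_anc, N=N)
        derived, _ = simulate_site_arrays(model, 60_000, seed=18)
        ours = np.bincount(derived, minlength=n_panel + 1).astype(float)
        table = np.vstack([ours, counts])
        keep = table.sum(axis=0) > 10
        assert stats.chi2_contingency(table[:, keep]).pvalue > 0.001
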