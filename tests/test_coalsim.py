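import numpy as np
import pytest
from scipy import stats

from abcorigin import coalsim
from abcorigin.coalsim import (
    ConfigurationError,
    DemographyParams,
    Genealogy,
    MutationConfig,
    PriorSet,
    draw_params,
    drop_sequence_mutations,
    drop_str_mutations,
    simulate_genealogy,
    simulate_reference_table,
)


def _two_leaf_genealogy(t):
    """Fixed cherry: two present-day leaves joined at time t."""
    return Genealogy(parent=np.array([2, 2, -1]),
                     time=np.array([0.0, 0.0, t]),
                     leaf_populations=["KM", "KM"], n_leaves=2)


class TestDrawParams:
    def test_degenerate_priors_return_bounds(self, rng):
        priors = PriorSet({
            "N_MK": (500.0, 500.0), "N_KM": (600.0, 600.0),
            "N_TK": (700.0, 700.0), "N_anc": (800.0, 800.0),
            "T1": (50.0, 50.0), "T2": (900.0, 900.0),
            "Tadm": (20.0, 20.0), "alpha": (0.4, 0.4)})
        p = draw_params(priors, "tree_like", rng)
        assert (p.N_MK, p.T1, p.T2) == (500.0, 50.0, 900.0)
        q = draw_params(priors, "admixture", rng)
        assert (q.Tadm, q.alpha) == (20.0, 0.4)

    def test_alpha_uniform_moments(self, rng):
        priors = PriorSet.default()
        draws = [draw_params(priors, "admixture", rng).alpha
                 for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    def test_treelike_ordering_always_holds(self, rng):
        priors = PriorSet.default()
        # widen T1 so that the ordering constraint actually bites
        priors.bounds["T1"] = (40.0, 2_000.0)
        for _ in range(500):
            p = draw_params(priors, "tree_like", rng)
            assert p.T1 < p.T2

    def test_incompatible_bounds_raise(self, rng):
        priors = PriorSet.default()
        priors.bounds["T1"] = (5_000.0, 6_000.0)  # entirely above T2 range
        with pytest.raises(ConfigurationError):
            draw_params(priors, "tree_like", rng)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            DemographyParams("tree_like", 100, 100, 100, 100, T1=50, T2=40)
        with pytest.raises(ConfigurationError):
            DemographyParams("admixture", 100, 100, 100, 100, T1=50,
                             Tadm=60, alpha=0.5)
        with pytest.raises(ConfigurationError):
            DemographyParams("nope", 100, 100, 100, 100, T1=50, T2=60)


class TestGenealogy:
    def test_mean_tmrca_single_deme(self, rng):
        # haploid pair coalescence: E[TMRCA] = N for n = 2
        N = 500.0
        p = DemographyParams("tree_like", N, N, N, N, T1=10.0, T2=20.0)
        times = [simulate_genealogy(p, {"MK": 2}, rng).time[2]
                 for _ in range(10_000)]
        assert np.mean(times) == pytest.approx(N, rel=0.05)

    def test_admixture_alpha_one_matches_treelike_offshoot(self, rng):
        """With alpha ~ 1 the admixture model is a KM offshoot of TK at
        Tadm, i.e. the tree-like model with T1 = Tadm, T2 = split."""
        N = 800.0
        adm = DemographyParams("admixture", N, N, N, N, T1=500.0,
                               Tadm=60.0, alpha=1.0 - 1e-12)
        tre = DemographyParams("tree_like", N, N, N, N, T1=60.0, T2=500.0)
        sizes = {"KM": 1, "TK": 1}
        t_adm = [simulate_genealogy(adm, sizes, rng).time[2]
                 for _ in range(5_000)]
        t_tre = [simulate_genealogy(tre, sizes, rng).time[2]
                 for _ in range(5_000)]
        assert stats.ks_2samp(t_adm, t_tre).pvalue > 0.01

    def test_admixture_alpha_zero_routes_to_mk(self, rng):
        # with a tiny MK deme both KM lineages coalesce just after Tadm
        p = DemographyParams("admixture", N_MK=0.01, N_KM=1e6, N_TK=1e6,
                             N_anc=1e6, T1=10_000.0, Tadm=40.0, alpha=1e-12)
        for _ in range(50):
            g = simulate_genealogy(p, {"KM": 2}, rng)
            assert 40.0 < g.time[2] < 41.0

    def test_leaves_at_zero_and_positive_branches(self, rng):
        p = DemographyParams("tree_like", 300, 400, 500, 600,
                             T1=50.0, T2=700.0)
        g = simulate_genealogy(p, {"MK": 4, "KM": 3, "TK": 3}, rng)
        assert np.all(g.time[:10] == 0.0)
        bl = g.branch_lengths()
        assert np.all(bl[g.parent >= 0] > 0)
        assert g.parent[g.root] == -1

    def test_total_sample_of_one_rejected(self, rng):
        p = DemographyParams("tree_like", 300, 400, 500, 600,
                             T1=50.0, T2=700.0)
        with pytest.raises(ValueError):
            simulate_genealogy(p, {"KM": 1}, rng)


class TestSequenceMutation:
    def test_mu_zero_reproduces_ancestral(self, rng):
        g = _two_leaf_genealogy(100.0)
        anc = np.zeros(50, dtype=int)  # all A
        panel = drop_sequence_mutations(g, 50, 0.0, rng, ancestral=anc)
        assert panel.sequences == ["A" * 50, "A" * 50]

    def test_pairwise_diff_matches_poisson_expectation(self, rng):
        # two leaves separated by branch length 2t: E[diffs] ~ 2 t mu L
        t, mu, L = 50.0, 1e-4, 100
        g = _two_leaf_genealogy(t)
        expect = 2 * t * mu * L
        diffs = []
        for _ in range(10_000):
            panel = drop_sequence_mutations(g, L, mu, rng)
            a, b = panel.sequences
            diffs.append(sum(x != y for x, y in zip(a, b)))
        assert np.mean(diffs) == pytest.approx(expect, rel=0.05)

    def test_mutation_count_mean_matches_variance(self, rng):
        # in the small-mu regime observed differences are nearly the raw
        # Poisson mutation count: mean and variance agree
        t, mu, L = 25.0, 1e-4, 100
        g = _two_leaf_genealogy(t)
        diffs = []
        for _ in range(20_000):
            panel = drop_sequence_mutations(g, L, mu, rng)
            a, b = panel.sequences
            diffs.append(sum(x != y for x, y in zip(a, b)))
        diffs = np.array(diffs, dtype=float)
        assert diffs.var() / diffs.mean() == pytest.approx(1.0, abs=0.1)

    def test_transition_bias(self, rng):
        # kappa = 10: transitions outnumber transversions about 5:1
        g = _two_leaf_genealogy(200.0)
        anc = np.zeros(2000, dtype=int)  # all A; transition target G
        panel = drop_sequence_mutations(g, 2000, 5e-4, rng, kappa=10.0,
                                        ancestral=anc)
        joined = "".join(panel.sequences)
        ts = joined.count("G")
        tv = joined.count("C") + joined.count("T")
        assert ts / max(tv, 1) > 2.5


class TestSTRMutation:
    def test_rate_zero_keeps_ancestral_repeat(self, rng):
        g = _two_leaf_genealogy(100.0)
        panel = drop_str_mutations(g, [0.0] * 17, rng, ancestral_repeat=20)
        assert np.all(panel.repeats == 20)

    def test_stepwise_variance_identity(self, rng):
        # |difference| between two lineages after 2t generations has
        # variance 2 t mu under the strict SMM
        t, mu = 400.0, 6.9e-4
        g = _two_leaf_genealogy(t)
        deltas = []
        for _ in range(20_000):
            panel = drop_str_mutations(g, [mu], rng)
            deltas.append(panel.repeats[0, 0] - panel.repeats[1, 0])
        assert np.var(deltas) == pytest.approx(2 * t * mu, rel=0.10)

    def test_linked_loci_correlate_unlinked_do_not(self, rng):
        """All 17 loci ride one genealogy, so locus-wise differences
        covary across replicates; independent genealogies do not."""
        N = 1_000.0
        p = DemographyParams("tree_like", N, N, N, N, T1=10.0, T2=20.0)
        mu = 6.9e-4
        linked = np.empty((2_000, 2))
        unlinked = np.empty((2_000, 2))
        for r in range(2_000):
            g = simulate_genealogy(p, {"MK": 2}, rng)
            panel = drop_str_mutations(g, [mu, mu], rng)
            linked[r] = np.abs(panel.repeats[0] - panel.repeats[1])
            row = []
            for _ in range(2):
                g2 = simulate_genealogy(p, {"MK": 2}, rng)
                q = drop_str_mutations(g2, [mu], rng)
                row.append(abs(q.repeats[0, 0] - q.repeats[1, 0]))
            unlinked[r] = row
        corr_linked = np.corrcoef(linked.T)[0, 1]
        corr_unlinked = np.corrcoef(unlinked.T)[0, 1]
        assert corr_linked > 0.1
        assert corr_linked > corr_unlinked + 0.05


class TestReferenceTable:
    def test_fixed_seed_reproducible(self):
        priors = PriorSet.default()
        cfg = MutationConfig()
        sizes = {"MK": 5, "KM": 5, "TK": 5}
        t1 = simulate_reference_table(
            "admixture", priors, 50, "HVRI", sizes, cfg,
            np.random.default_rng(99))
        t2 = simulate_reference_table(
            "admixture", priors, 50, "HVRI", sizes, cfg,
            np.random.default_rng(99))
        assert np.array_equal(t1.stats, t2.stats, equal_nan=True)
        assert np.array_equal(t1.params, t2.params, equal_nan=True)
        assert t1.stat_names == t2.stat_names

    def test_divergence_time_orders_fst(self, rng):
        """Under the tree-like model with T1 << T2 the KM-TK pair is far
        less differentiated than either pair involving MK."""
        priors = PriorSet({
            "N_MK": (2_000.0, 2_000.0), "N_KM": (2_000.0, 2_000.0),
            "N_TK": (2_000.0, 2_000.0), "N_anc": (2_000.0, 2_000.0),
            "T1": (40.0, 40.0), "T2": (3_000.0, 3_000.0),
            "Tadm": (10.0, 10.0), "alpha": (0.5, 0.5)})
        table = simulate_reference_table(
            "tree_like", priors, 500, "HVRI",
            {"MK": 10, "KM": 10, "TK": 10}, MutationConfig(), rng)
        d = {n: np.nanmean(table.stats[:, i])
             for i, n in enumerate(table.stat_names)}
        assert d["fst_KM_TK"] < d["fst_MK_KM"]
        assert d["fst_KM_TK"] < d["fst_MK_TK"]

    def test_ystr_rows_and_flags(self, rng):
        table = simulate_reference_table(
            "admixture", PriorSet.default(), 30, "YSTR",
            {"MK": 4, "KM": 4, "TK": 4}, MutationConfig(), rng)
        assert table.n_rows == 30
        assert len(table.stat_names) == 24
        assert table.flags.dtype == bool


class TestMsprimeCrossCheck:
    def test_treelike_tmrca_distribution_matches_msprime(self, rng):
        """Independent-simulator check: root times under the tree-like
        demography agree in distribution with msprime."""
        msprime = pytest.importorskip("msprime")
        N_MK, N_KM, N_TK, N_anc = 1_000.0, 800.0, 1_200.0, 900.0
        T1, T2 = 80.0, 1_500.0
        p = DemographyParams("tree_like", N_MK, N_KM, N_TK, N_anc,
                             T1=T1, T2=T2)
        sizes = {"MK": 3, "KM": 3, "TK": 3}
        ours = [simulate_genealogy(p, sizes, rng).time.max()
                for _ in range(2_000)]

        dem = msprime.Demography()
        dem.add_population(name="MK", initial_size=N_MK)
        dem.add_population(name="KM", initial_size=N_KM)
        dem.add_population(name="TK", initial_size=N_TK)
        dem.add_population(name="KMTK", initial_size=N_TK)
        dem.add_population(name="ANC", initial_size=N_anc)
        dem.add_population_split(time=T1, derived=["KM", "TK"],
                                 ancestral="KMTK")
        dem.add_population_split(time=T2, derived=["MK", "KMTK"],
                                 ancestral="ANC")
        reps = msprime.sim_ancestry(
            samples={"MK": 3, "KM": 3, "TK": 3}, demography=dem,
            ploidy=1, num_replicates=2_000, random_seed=4242)
        theirs = [next(ts.trees()).time(ts.first().root) for ts in reps]
        assert stats.ks_2samp(ours, theirs).pvalue > 0.01
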