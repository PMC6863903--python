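"""Synthetic community generator: tree/sequence consistency and count sampling."""

import numpy as np
import pytest
from scipy import stats

from strainpop import popgen, simdata


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_strains": 4, "clade_sizes": (2, 1)},  # sizes don't sum
            {"seq_error": 0.3},
            {"coverage": 1},
            {"genome_length": 30001},
            # expected substitutions beyond 10% of the genome
            {"genome_length": 3000, "d_between": 400, "d_within": 200},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simdata.SimulationConfig(**kwargs)

    def test_default_clade_structure(self):
        cfg = simdata.SimulationConfig()
        assert cfg.clade_sizes == (4, 3, 3, 1)
        assert sum(cfg.clade_sizes) == cfg.n_strains


class TestSimulateStrains:
    def test_single_strain_has_no_variation(self):
        cfg = simdata.SimulationConfig(n_strains=1, clade_sizes=(1,), seed=2)
        truth = simdata.simulate_strains(cfg)
        assert len(truth.strain_seqs) == 1
        assert len(truth.assigned_pos) == 0

    def test_two_strain_distance_is_poisson_distributed(self):
        cfg = simdata.SimulationConfig(
            n_strains=2, clade_sizes=(1, 1), d_between=100, d_within=0,
            genome_length=30000, seed=1,
        )
        truth = simdata.simulate_strains(cfg)
        a, b = truth.strain_seqs.values()
        d = hamming(a, b)
        lo, hi = stats.poisson.ppf([0.0005, 0.9995], 100)
        assert lo <= d <= hi
        assert d == len(truth.assigned_pos)

    def test_tree_and_sequences_are_consistent(self, small_community):
        _, truth, _ = small_community
        # planted substitutions hit distinct sites, so Hamming distances are
        # exactly additive over the tree paths encoded in the state matrix
        names = truth.strains
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                expected = int(
                    (truth.assigned_states[:, i] != truth.assigned_states[:, j]).sum()
                )
                assert hamming(truth.strain_seqs[a], truth.strain_seqs[b]) == expected

    def test_clade_recovery_by_distance_clustering(self, small_community):
        # single-linkage on the Hamming matrix at a midpoint threshold
        # recovers the planted clades (independent oracle via scipy)
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        _, truth, _ = small_community
        names = truth.strains
        n = len(names)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = hamming(truth.strain_seqs[names[i]], truth.strain_seqs[names[j]])
        labels = fcluster(linkage(squareform(d), "single"), t=d.max() / 2, criterion="distance")
        groups = {}
        for name, lab in zip(names, labels):
            groups.setdefault(lab, set()).add(name)
        planted = {}
        for name, c in truth.clade_map.items():
            planted.setdefault(c, set()).add(name)
        assert set(map(frozenset, groups.values())) == set(map(frozenset, planted.values()))

    def test_deterministic_under_seed(self):
        cfg = simdata.SimulationConfig(genome_length=6000, n_genes=10, seed=9)
        t1 = simdata.simulate_strains(cfg)
        t2 = simdata.simulate_strains(simdata.SimulationConfig(genome_length=6000, n_genes=10, seed=9))
        assert t1.strain_seqs == t2.strain_seqs
        assert t1.tree_newick == t2.tree_newick
        assert t1.frequencies.equals(t2.frequencies)
        c1 = simdata.simulate_counts(t1, cfg)
        c2 = simdata.simulate_counts(t2, cfg)
        assert c1 == c2


class TestSimulateCounts:
    def _pure_sample_truth(self, small_community, weights):
        cfg, truth, _ = small_community
        freqs = truth.frequencies.copy()
        row = np.zeros(len(truth.strains))
        for k, w in weights.items():
            row[k] = w
        freqs.iloc[0] = row
        return cfg, simdata.SyntheticTruth(**{**truth.__dict__, "frequencies": freqs})

    def test_single_strain_sample_monomorphic_at_assigned_sites(self, small_community):
        cfg, truth2 = self._pure_sample_truth(small_community, {0: 1.0})
        counts = simdata.simulate_counts(truth2, cfg)
        sample = truth2.samples[0]
        x = counts.sample_counts(sample)
        assigned = set(map(tuple, (truth2.pos_to_site(int(p)) for p in truth2.assigned_pos)))
        for i, site in enumerate(counts.sites):
            if site in assigned and x[i].sum() > 0:
                assert (x[i] > 0).sum() == 1  # error-free, one strain: monomorphic

    def test_balanced_mixture_within_binomial_interval(self):
        cfg = simdata.SimulationConfig(
            n_strains=2, clade_sizes=(1, 1), d_between=100, d_within=0,
            genome_length=30000, n_samples=1, coverage=1000, seq_error=0.0,
            dirichlet_alpha=1.0, invariant_snv_rate=0.0, seed=4,
        )
        truth = simdata.simulate_strains(cfg)
        truth.frequencies.iloc[0] = [0.5, 0.5]
        counts = simdata.simulate_counts(truth, cfg)
        sample = truth.samples[0]
        x = counts.sample_counts(sample)
        ref = [truth.root_seq[p] for p in truth.all_variant_positions()]
        inside = 0
        for i, r in enumerate(ref):
            cov = x[i].sum()
            alt = cov - x[i]["ACGT".index(r)]
            z = (alt - 0.5 * cov) / np.sqrt(0.25 * cov)
            inside += abs(z) <= 2.58  # 99% normal interval of Binomial(cov, 0.5)
        assert inside >= 0.95 * len(ref)

    def test_sequencing_error_rate_recovered_at_monomorphic_sites(self):
        cfg = simdata.SimulationConfig(
            n_strains=1, clade_sizes=(1,), genome_length=3000, n_genes=5,
            n_samples=1, coverage=40, seq_error=0.01, invariant_snv_rate=0.0, seed=6,
        )
        truth = simdata.simulate_strains(cfg)
        counts = simdata.simulate_counts(truth, cfg, sites="all")
        x = counts.sample_counts(truth.samples[0])
        ref_idx = ["ACGT".index(b) for b in truth.root_seq]
        total = x.sum()
        nonref = total - sum(x[i, r] for i, r in enumerate(ref_idx))
        rate = nonref / total
        assert rate == pytest.approx(0.01, rel=0.15)

    def test_expected_count_fraction_matches_strain_mixture(self, small_community):
        # frequency consistency at error 0: pooled count fraction tracks the
        # frequency-weighted strain allele mix
        cfg, truth, counts = small_community
        sample = truth.samples[2]
        positions = truth.all_variant_positions()
        p_true = truth.true_site_freqs(sample, positions)
        x = counts.sample_counts(sample)
        cov = x.sum(axis=1)
        f_obs = x / cov[:, None]
        resid = np.abs(f_obs - p_true).max(axis=1)
        se = np.sqrt(p_true.max(axis=1) * (1 - p_true.max(axis=1)) / cov)
        assert (resid <= np.maximum(5 * se, 0.12)).mean() > 0.99

    def test_pi_round_trip_converges_to_truth(self):
        cfg = simdata.SimulationConfig(
            n_strains=4, clade_sizes=(2, 2), d_between=120, d_within=30,
            genome_length=9000, n_genes=15, n_samples=1, coverage=2000,
            seq_error=0.0, invariant_snv_rate=0.0, seed=8,
        )
        truth = simdata.simulate_strains(cfg)
        counts = simdata.simulate_counts(truth, cfg)
        sample = truth.samples[0]
        positions = truth.all_variant_positions()
        p = truth.true_site_freqs(sample, positions)
        expected = float((1 - (p**2).sum(axis=1)).sum() / cfg.genome_length)
        got = popgen.pi_intra(counts, sample).value
        assert got == pytest.approx(expected, rel=0.05)


class TestGeneAbundances:
    def test_noiseless_groups_perfectly_correlated(self):
        m, truth = simdata.simulate_gene_abundances(
            n_core_genes=700, n_cag_groups=1, n_samples=6, noise_sd=0.0,
            outlier_rate=0.0, seed=3,
        )
        core = [g for g, l in truth["labels"].items() if l == "mgs"]
        sub = m.df.loc[core[:20]]
        assert np.allclose(np.corrcoef(sub), 1.0)

    def test_outlier_fraction_planted(self):
        m, truth = simdata.simulate_gene_abundances(
            n_core_genes=1000, n_cag_groups=0, n_samples=6, noise_sd=0.05,
            outlier_rate=0.01, seed=3,
        )
        assert len(truth["outliers"]) == 10

    def test_requires_mgs_sized_core(self):
        with pytest.raises(ValueError):
            simdata.simulate_gene_abundances(n_core_genes=600)
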