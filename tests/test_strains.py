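"""Strain distances, clades, dominance calls, ancestral states and spectra."""

import numpy as np
import pandas as pd
import pytest

from strainpop import simdata, strains
from strainpop.snv import AlleleCountMatrix


class TestPairwiseDistance:
    def test_matches_planted_substitutions(self, small_community):
        _, truth, _ = small_community
        h = truth.to_haplotype_set()
        d = strains.pairwise_snv_distance(h)
        states = truth.assigned_states
        for i, a in enumerate(h.strains):
            assert d.loc[a, a] == 0
            for j, b in enumerate(h.strains):
                expected = int((states[:, i] != states[:, j]).sum())
                assert d.loc[a, b] == expected == d.loc[b, a]

    def test_triangle_inequality(self, small_community):
        _, truth, _ = small_community
        d = strains.pairwise_snv_distance(truth.to_haplotype_set()).to_numpy()
        n = len(d)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j]


class TestPercentIdentity:
    @pytest.mark.parametrize("n_diff,expected", [(0, 100.0), (635, 99.95), (12700, 99.0)])
    def test_values(self, n_diff, expected):
        assert strains.percent_identity(n_diff, 1_270_000) == expected

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            strains.percent_identity(1, 0)
        with pytest.raises(ValueError):
            strains.percent_identity(11, 10)


class TestAssignClades:
    def test_recovers_planted_clades(self, small_community):
        _, truth, _ = small_community
        d = strains.pairwise_snv_distance(truth.to_haplotype_set())
        got = strains.assign_clades(d)  # automatic largest-gap threshold
        # same partition as the planted clade map (labels may differ)
        by_got, by_truth = {}, {}
        for s in d.index:
            by_got.setdefault(got[s], set()).add(s)
            by_truth.setdefault(truth.clade_map[s], set()).add(s)
        assert set(map(frozenset, by_got.values())) == set(map(frozenset, by_truth.values()))

    def test_threshold_extremes(self, small_community):
        _, truth, _ = small_community
        d = strains.pairwise_snv_distance(truth.to_haplotype_set())
        singletons = strains.assign_clades(d, threshold=0.5)
        assert len(set(singletons.values())) == len(d)
        one = strains.assign_clades(d, threshold=d.values.max() + 1)
        assert len(set(one.values())) == 1

    def test_invariant_to_strain_order(self, small_community):
        _, truth, _ = small_community
        d = strains.pairwise_snv_distance(truth.to_haplotype_set())
        perm = list(d.index)[::-1]
        d2 = d.loc[perm, perm]
        a = strains.assign_clades(d)
        b = strains.assign_clades(d2)
        groups = lambda m: set(frozenset(s for s in m if m[s] == c) for c in set(m.values()))
        assert groups(a) == groups(b)


class TestPresenceDominance:
    @pytest.mark.parametrize(
        "freqs,present,dominant",
        [
            ((0.96, 0.04), ["s1"], "s1"),
            ((0.5, 0.5), ["s1", "s2"], None),
            ((0.90, 0.10), ["s1", "s2"], "s1"),  # inclusive bounds
            ((0.04, 0.96), ["s2"], "s2"),
        ],
    )
    def test_calls(self, freqs, present, dominant):
        df = pd.DataFrame([freqs], index=["m1"], columns=["s1", "s2"])
        out = strains.strain_presence_and_dominance(df)
        assert out.loc["m1", "present"] == present
        assert out.loc["m1", "dominant"] == dominant or (
            dominant is None and out.loc["m1", "dominant"] is None
        )

    def test_rejects_unnormalized_rows(self):
        df = pd.DataFrame([[0.5, 0.2]], index=["m1"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            strains.strain_presence_and_dominance(df)


class TestDominantHaplotype:
    def test_major_allele_thresholds(self):
        counts = np.array([[[95, 5, 0, 0]], [[89, 11, 0, 0]], [[0, 0, 0, 0]]])
        m = AlleleCountMatrix([("g", 1), ("g", 2), ("g", 3)], ["s"], counts, 10)
        hap = strains.dominant_haplotype(m, "s")
        assert hap[("g", 1)] == "A"
        assert hap[("g", 2)] is None
        assert hap[("g", 3)] is None

    def test_recovers_dominant_strain_sequence(self, small_community):
        cfg, truth, _ = small_community
        # craft one sample dominated by the first strain at 97%
        freqs = truth.frequencies.copy()
        row = np.zeros(len(truth.strains))
        row[0], row[1] = 0.97, 0.03
        freqs.iloc[0] = row
        truth2 = simdata.SyntheticTruth(**{**truth.__dict__, "frequencies": freqs})
        counts = simdata.simulate_counts(truth2, cfg)
        sample = truth2.samples[0]
        hap = strains.dominant_haplotype(counts, sample)
        h = truth2.to_haplotype_set()
        dominant = truth2.strains[0]
        seq = truth2.strain_seqs[dominant]
        checked = 0
        for pos in truth2.assigned_pos:
            site = truth2.pos_to_site(int(pos))
            if hap.get(site) is not None:
                assert hap[site] == seq[pos]
                checked += 1
        assert checked > 0.8 * len(truth2.assigned_pos)

    def test_differential_snvs_excludes_undefined_sites(self):
        h1 = {("g", 1): "A", ("g", 2): "C", ("g", 3): None, ("g", 4): "G"}
        h2 = {("g", 1): "T", ("g", 2): "C", ("g", 3): "A", ("g", 4): None}
        n_diff, n_excl = strains.differential_snvs(h1, h2)
        assert (n_diff, n_excl) == (1, 2)
        assert strains.differential_snvs(h1, h1) == (0, 1)


class TestAncestralStates:
    def make(self, states):
        sites = pd.DataFrame(
            {"gene_id": ["g"], "pos": [1], "ref": ["A"], "alt": ["G"]}
        )
        names = [f"s{i+1}" for i in range(len(states))]
        return strains.StrainHaplotypeSet(sites, names, np.array([states]), 100)

    def test_majority_rule(self):
        h = self.make((0, 0, 1))
        assert strains.ancestral_states(h, "s3") == {("g", 1): "A"}

    def test_tie_broken_by_designated_tip(self):
        h = self.make((0, 1))
        assert strains.ancestral_states(h, "s2") == {("g", 1): "G"}
        assert strains.ancestral_states(h, "s1") == {("g", 1): "A"}

    def test_invariant_site(self):
        h = self.make((0, 0))
        assert strains.ancestral_states(h, "s1") == {("g", 1): "A"}


class TestDerivedAfs:
    def test_complement_rule(self):
        counts = np.array([[[10, 90, 0, 0]]])  # alt C at 0.9
        m = AlleleCountMatrix([("g", 1)], ["s"], counts, 10)
        hist, edges = strains.derived_afs(m, "s", {("g", 1): "C"}, n_bins=20)
        # ancestral is the alt allele -> derived frequency 0.1, bin (0.05, 0.1]
        assert hist.sum() == 1
        assert hist[1] == 1

    def test_mixture_modes_near_true_strain_frequencies(self, small_community):
        cfg, truth, _ = small_community
        freqs = truth.frequencies.copy()
        row = np.zeros(len(truth.strains))
        row[0], row[3] = 0.7, 0.3  # strains from different clades
        freqs.iloc[0] = row
        truth2 = simdata.SyntheticTruth(**{**truth.__dict__, "frequencies": freqs})
        counts = simdata.simulate_counts(truth2, cfg)
        h = truth2.to_haplotype_set()
        anc = strains.ancestral_states(h, h.strains[0])
        hist, edges = strains.derived_afs(counts, truth2.samples[0], anc, n_bins=10)
        interior = hist[1:9].sum()
        # every assigned polymorphic site sits at derived frequency 0.3 or 0.7
        # (which of the two depends on the ancestral call); only invariant
        # SNVs may land elsewhere in the interior
        near_modes = hist[2] + hist[3] + hist[6] + hist[7]  # (0.2,0.4] + (0.6,0.8]
        n_invariant = len(truth2.invariant_pos)
        assert near_modes >= 50
        assert interior - near_modes <= n_invariant

    def test_spectrum_degenerate_for_pure_sample(self, small_community):
        cfg, truth, _ = small_community
        freqs = truth.frequencies.copy()
        row = np.zeros(len(truth.strains))
        row[0] = 1.0
        freqs.iloc[0] = row
        truth2 = simdata.SyntheticTruth(**{**truth.__dict__, "frequencies": freqs})
        counts = simdata.simulate_counts(truth2, cfg)
        h = truth2.to_haplotype_set()
        anc = strains.ancestral_states(h, h.strains[0])
        hist, _ = strains.derived_afs(counts, truth2.samples[0], anc, n_bins=20)
        assigned = [i for i, s in enumerate(counts.sites) if h.has_site(s)]
        # every assigned site is at derived frequency 0 or 1: only edge bins filled
        assert hist[1:19].sum() <= len(counts.sites) - len(assigned)
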