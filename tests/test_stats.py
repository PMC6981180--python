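"""Gene usage, clustering, regressions and junction statistics."""

import numpy as np
import pandas as pd
import pytest

from vdjcompare.records import Repertoire, SequenceRecord
from vdjcompare.simulate import (SimulatorConfig, point_mass,
                                 simulate_rearrangements, simulate_repertoire,
                                 species_preset)
from vdjcompare.stats import (UsageProfile, cdr3_tail_frequency,
                              family_pair_frequency, gene_usage,
                              isotype_frequencies, length_distribution,
                              mutation_summary, short_cdrl3_fraction,
                              usage_matrix, usage_regression,
                              zscore_and_cluster)


def _rec(seq_id="s", v="IGHV1-2*01", d="IGHD1-1*01", j="IGHJ4*01",
         junction_aa="CARDYW", dup=1, isotype="IgM", locus="IGH",
         mutations=0, productive=True, **kw):
    return SequenceRecord(seq_id, v, j, junction_aa, d_call=d,
                          duplicate_count=dup, isotype=isotype, locus=locus,
                          v_mutation_count=mutations, productive=productive,
                          **kw)


class TestGeneUsage:
    def test_single_gene_gets_all_mass(self):
        rep = Repertoire([_rec(f"s{i}") for i in range(10)])
        prof = gene_usage(rep, "V")
        assert prof.frequencies == {"IGHV1-2": 1.0}

    def test_duplicate_weighting(self):
        rep = Repertoire([_rec("a", v="IGHV1-2*01", dup=3),
                          _rec("b", v="IGHV3-7*01", dup=1)])
        prof = gene_usage(rep, "V")
        assert prof.frequencies["IGHV1-2"] == pytest.approx(0.75)
        assert prof.frequencies["IGHV3-7"] == pytest.approx(0.25)

    def test_simulated_usage_within_3se_of_model(self, igh_presets):
        m = igh_presets["human_like"]
        recs = simulate_rearrangements(m, 20_000, np.random.default_rng(1))
        rep = Repertoire(recs, germline_ref=m.germline)
        rep = Repertoire([r for r in recs], germline_ref=m.germline)
        prof = gene_usage(rep, "V", include_nonproductive=True)
        n = len(recs)
        for gene, p_true in zip(m.v_genes, m.p_v):
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(prof.frequencies[gene] - p_true) < 3 * se

    def test_frequencies_sum_to_one(self):
        rep = Repertoire([_rec(f"s{i}", v=f"IGHV{1 + i % 3}-1*01")
                          for i in range(30)])
        prof = gene_usage(rep, "V")
        assert sum(prof.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_repertoire_rejected(self):
        with pytest.raises(ValueError):
            gene_usage(Repertoire([]), "V")


class TestZscoreAndCluster:
    def test_identical_columns_zscore_zero(self):
        mat = pd.DataFrame({"r1": [0.5, 0.3, 0.2], "r2": [0.5, 0.3, 0.2]},
                           index=["g1", "g2", "g3"])
        res = zscore_and_cluster(mat)
        assert np.allclose(res.zscores.values, 0.0)
        assert res.col_linkage[0, 2] == pytest.approx(0.0)

    def test_rows_have_mean_zero_sd_one_or_all_zero(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((8, 5)),
                           index=[f"g{i}" for i in range(8)],
                           columns=[f"r{i}" for i in range(5)])
        mat.iloc[3] = 0.2          # constant row
        z = zscore_and_cluster(mat).zscores
        for i in range(8):
            row = z.iloc[i].values
            if i == 3:
                assert np.allclose(row, 0.0)
            else:
                assert np.mean(row) == pytest.approx(0.0, abs=1e-12)
                assert np.std(row) == pytest.approx(1.0, abs=1e-12)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            zscore_and_cluster(pd.DataFrame({"only": [1.0, 2.0]}))

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.random((6, 4)),
                           index=[f"g{i}" for i in range(6)],
                           columns=[f"r{i}" for i in range(4)])
        res = zscore_and_cluster(mat)
        for label in mat.columns:
            assert label in res.col_newick
        assert res.col_newick.endswith(";")

    def test_presets_cluster_into_two_species_groups(self):
        """Usage profiles from the two species presets form two top-level
        clusters (2 + 2 repertoires, V segment)."""
        profiles = []
        for k, preset in enumerate(["omnirat_like", "omnirat_like",
                                    "human_like", "human_like"]):
            model, cfg = species_preset(preset)
            cfg.n_clones, cfg.n_reads_per_compartment = 1500, 2000
            cfg.seed, cfg.subject_id = 100 + k, f"{preset[:3]}{k}"
            ln, sp, _ = simulate_repertoire(cfg)
            rep = Repertoire(list(ln) + list(sp), f"{preset[:3]}{k}",
                             "pooled", "IGH", ln.germline_ref)
            profiles.append(gene_usage(rep, "V", collapse="clonotype"))
        mat = usage_matrix(profiles)
        mat.columns = ["rat0", "rat1", "hum2", "hum3"]
        clusters = zscore_and_cluster(mat).n_top_clusters(2)
        assert clusters["rat0"] == clusters["rat1"]
        assert clusters["hum2"] == clusters["hum3"]
        assert clusters["rat0"] != clusters["hum2"]


class TestUsageRegression:
    def _profile(self, freqs, label="a"):
        return UsageProfile(label=(label, "pooled", "IGH"), segment="V",
                            frequencies=freqs)

    def test_self_regression_is_identity(self):
        p = self._profile({"g1": 0.2, "g2": 0.3, "g3": 0.5})
        res = usage_regression(p, p)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols_oracle(self):
        # x = (0.2, 0.3, 0.5), y = (0.3, 0.2, 0.5): closed-form OLS
        x = np.array([0.2, 0.3, 0.5])
        y = np.array([0.3, 0.2, 0.5])
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        res = usage_regression(
            self._profile(dict(zip("abc", x))),
            self._profile(dict(zip("abc", y)), "b"))
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)

    def test_uncorrelated_permutation_gives_low_r2(self):
        rng = np.random.default_rng(2)
        freqs = rng.dirichlet(np.ones(100))
        genes = [f"g{i}" for i in range(100)]
        a = self._profile(dict(zip(genes, freqs)))
        b = self._profile(dict(zip(genes, rng.permutation(freqs))), "b")
        assert usage_regression(a, b).r_squared < 0.2

    def test_insufficient_shared_genes_rejected(self):
        a = self._profile({"g1": 0.5, "g2": 0.5})
        b = self._profile({"g1": 0.5, "g3": 0.5}, "b")
        with pytest.raises(ValueError, match="shared"):
            usage_regression(a, b)


class TestLengthDistributions:
    def test_point_mass(self):
        rep = Repertoire([_rec(f"s{i}", junction_aa="C" + "A" * 12 + "W")
                          for i in range(5)])
        dist = length_distribution(rep, "cdr3_length")
        assert dist.histogram == {12: 1.0}
        assert dist.mean == pytest.approx(12.0)

    def test_two_point_mean(self):
        rep = Repertoire([_rec("a", junction_aa="C" + "A" * 10 + "W"),
                          _rec("b", junction_aa="C" + "A" * 14 + "W")])
        assert length_distribution(rep, "cdr3_length").mean == pytest.approx(12)

    def test_simulated_point_mass_insertion_recovered(self):
        m, _ = species_preset("omnirat_like")
        m.p_n1 = point_mass(5, m.p_n1.size - 1)
        recs = simulate_rearrangements(m, 400, np.random.default_rng(3))
        rep = Repertoire(recs)
        dist = length_distribution(rep, "n1_length")
        assert dist.histogram == {5: 1.0}

    def test_histogram_mean_consistency(self, igh_presets):
        recs = simulate_rearrangements(igh_presets["human_like"], 2000,
                                       np.random.default_rng(4))
        dist = length_distribution(Repertoire(recs), "cdr3_length")
        mean_from_hist = sum(L * f for L, f in dist.histogram.items())
        assert dist.mean == pytest.approx(mean_from_hist, abs=1e-9)
        assert sum(dist.histogram.values()) == pytest.approx(1.0, abs=1e-9)


class TestFamilyPairFrequency:
    def test_no_matches_is_zero(self):
        rep = Repertoire([_rec("a", d="IGHD1-1*01", j="IGHJ4*01")])
        assert family_pair_frequency(rep) == 0.0

    def test_fraction_of_matching_records(self):
        recs = [_rec(f"m{i}", d="IGHD3-10*01", j="IGHJ6*01") for i in range(3)]
        recs += [_rec(f"o{i}", d="IGHD1-1*01", j="IGHJ4*01") for i in range(9)]
        assert family_pair_frequency(Repertoire(recs)) == pytest.approx(0.25)

    def test_kappa_input_rejected(self):
        rep = Repertoire([], locus="IGK")
        with pytest.raises(ValueError):
            family_pair_frequency(rep)


class TestCdr3Tail:
    def test_hand_example(self):
        recs = [_rec("a", junction_aa="C" + "A" * 10 + "W"),
                _rec("b", junction_aa="C" + "A" * 12 + "W"),
                _rec("c", junction_aa="C" + "A" * 14 + "W")]
        tail = cdr3_tail_frequency(Repertoire(recs))
        assert tail[10] == pytest.approx(1.0)
        assert tail[12] == pytest.approx(2 / 3)

    def test_tail_equals_one_minus_cdf(self, igh_presets):
        recs = simulate_rearrangements(igh_presets["omnirat_like"], 3000,
                                       np.random.default_rng(5))
        rep = Repertoire(recs)
        dist = length_distribution(rep, "cdr3_length")
        tail = cdr3_tail_frequency(rep)
        support = sorted(dist.histogram)
        cdf = 0.0
        for L in support:
            assert tail[L] == pytest.approx(1.0 - cdf, abs=1e-9)
            cdf += dist.histogram[L]
        values = [tail[L] for L in support]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestShortCdrl3:
    def test_fraction_arithmetic(self):
        recs = [_rec("hit", d=None, locus="IGK",
                     junction_aa="C" + "A" * 5 + "F")]
        recs += [_rec(f"s{i}", d=None, locus="IGK",
                      junction_aa="C" + "A" * 9 + "F") for i in range(199)]
        rep = Repertoire(recs, locus="IGK")
        assert short_cdrl3_fraction(rep) == pytest.approx(0.005)

    def test_heavy_chain_rejected(self):
        with pytest.raises(ValueError):
            short_cdrl3_fraction(Repertoire([], locus="IGH"))


class TestIsotypesAndMutations:
    def test_all_igm(self):
        rep = Repertoire([_rec(f"s{i}") for i in range(5)])
        assert isotype_frequencies(rep)["IgM"] == pytest.approx(1.0)

    def test_fifteen_percent_igg(self):
        recs = [_rec(f"g{i}", isotype="IgG") for i in range(15)]
        recs += [_rec(f"m{i}", isotype="IgM") for i in range(85)]
        freqs = isotype_frequencies(Repertoire(recs))
        assert freqs["IgG"] == pytest.approx(0.15)
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_simulated_igg_fraction_within_3se(self):
        model, cfg = species_preset("omnirat_like")
        cfg.n_clones, cfg.n_reads_per_compartment = 2000, 25_000
        cfg.shm_rate_igm = cfg.shm_rate_igg = 0.0
        cfg.seed = 31
        ln, sp, _ = simulate_repertoire(cfg)
        freqs = isotype_frequencies(ln.productive())
        n = len(ln.productive())
        se = np.sqrt(0.15 * 0.85 / n)
        assert abs(freqs["IgG"] - 0.15) < 3 * se

    def test_igg_more_mutated_than_igm(self):
        model, cfg = species_preset("omnirat_like")
        cfg.n_clones, cfg.n_reads_per_compartment = 2000, 10_000
        cfg.shm_rate_igm, cfg.shm_rate_igg = 2.0, 10.0
        cfg.igg_fraction_by_tissue = {"lymph_node": 0.3, "spleen": 0.3}
        cfg.seed = 32
        ln, _, _ = simulate_repertoire(cfg)
        # compare against the generating means over ALL reads: productivity
        # selects weakly against junction-breaking mutations, so the
        # productive-only means sit slightly below the Poisson truth
        summary = mutation_summary(Repertoire(list(ln), locus="IGH"),
                                   include_nonproductive=True)
        igm, igg = summary["IgM"], summary["IgG"]
        assert igg.mean > igm.mean
        assert abs(igm.mean - 2.0) < 3 * np.sqrt(2.0 / igm.n)
        assert abs(igg.mean - 10.0) < 3 * np.sqrt(10.0 / igg.n)

    def test_single_record_group_flagged(self):
        rep = Repertoire([_rec("a", isotype="IgG", mutations=4)])
        out = mutation_summary(rep)
        assert out["IgG"].sem == 0.0 and out["IgG"].single_member
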