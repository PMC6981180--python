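"""Simulator behaviour: deterministic limits, statistical oracles, clonal
structure and reproducibility."""

import numpy as np
import pytest

from vdjcompare.diversity import assign_clonotypes, build_incidence
from vdjcompare.io import write_airr
from vdjcompare.model import RecombinationModel
from vdjcompare.simulate import (SimulatorConfig, apply_shm, point_mass,
                                 simulate_rearrangement,
                                 simulate_rearrangements, simulate_repertoire,
                                 species_preset)

from conftest import make_tiny_model


def _degenerate_model() -> RecombinationModel:
    """One V/D/J, all trims and insertions zero, no P nucleotides."""
    m = make_tiny_model(uniform=True)
    m.p_v = np.array([1.0, 0.0])
    m.p_dj = np.array([[1.0], [0.0]])
    m.p_v_trim = np.tile([1.0, 0.0], (2, 1))
    m.p_d_trim = np.stack([np.array([[1.0, 0], [0, 0]])] * 2)
    m.p_j_trim = np.array([[1.0, 0.0]])
    m.p_n1 = np.array([1.0, 0.0])
    m.p_n2 = np.array([1.0, 0.0])
    m.use_p_nucleotides = False
    m.validate()
    return m


class TestSimulateRearrangement:
    def test_degenerate_model_is_deterministic_concatenation(self):
        m = _degenerate_model()
        # V=AAATGTGC (anchor 3), D=ACGT, J=ATGGGGC (anchor 1)
        # V[anchor:] + D + J[:W codon end] = "TGTGC" + "ACGT" + "ATGG"
        expected_junction = "TGTGC" + "ACGT" + "ATGG"
        for seed in (0, 1, 99):
            rec, events = simulate_rearrangement(
                m, np.random.default_rng(seed))
            assert rec.junction == expected_junction
            assert rec.sequence == "AAATGTGC" + "ACGT" + "ATGGGGC"
            assert events["n1_length"] == 0

    def test_point_mass_insertions(self):
        m, _ = species_preset("omnirat_like")
        m.p_n1 = point_mass(5, m.p_n1.size - 1)
        m.p_n2 = point_mass(5, m.p_n2.size - 1)
        recs = simulate_rearrangements(m, 200, np.random.default_rng(0))
        assert all(r.n1_length == 5 and r.n2_length == 5 for r in recs)

    def test_j_usage_matches_model_within_3se(self):
        m, _ = species_preset("human_like")
        # point the DJ joint at P(J6-proxy) = 0.3
        p_j = np.array([0.20, 0.14, 0.16, 0.10, 0.10, 0.30])
        m.p_dj = np.outer(m.p_d, p_j)
        n = 10_000
        recs = simulate_rearrangements(m, n, np.random.default_rng(5))
        obs = np.mean([r.j_gene == "IGHJ6" for r in recs])
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(obs - 0.3) < 3 * se

    def test_junction_length_identity_per_record(self, igh_presets):
        m = igh_presets["omnirat_like"]
        recs = simulate_rearrangements(m, 500, np.random.default_rng(2))
        for r in recs:
            v_junction = 11 - r.v_trim3          # Cys codon + 8-nt tail
            d_kept = len(m.germline[r.d_gene]) - r.d_trim5 - r.d_trim3
            j_kept = m.j_anchor[r.j_gene] - r.j_trim5 + 3
            base = v_junction + r.n1_length + d_kept + r.n2_length + j_kept
            p_total = len(r.junction) - base
            assert 0 <= p_total <= 8
            if min(r.v_trim3, r.d_trim5, r.d_trim3, r.j_trim5) > 0:
                assert p_total == 0   # P nts occur only at untrimmed ends

    def test_unnormalized_model_rejected(self):
        m = _degenerate_model()
        m.p_v = np.array([0.7, 0.6])
        with pytest.raises(Exception, match="sums"):
            simulate_rearrangements(m, 1, np.random.default_rng(0))


class TestApplySHM:
    def _record(self):
        m = _degenerate_model()
        return simulate_rearrangements(m, 1, np.random.default_rng(0))[0]

    def test_zero_mean_leaves_record_unchanged(self):
        rec = self._record()
        out = apply_shm(rec, 0.0, np.random.default_rng(0))
        assert out.v_mutation_count == 0
        assert out.sequence == rec.sequence

    def test_poisson_mean_recovered_within_3se(self):
        m, _ = species_preset("omnirat_like")
        recs = simulate_rearrangements(m, 10_000, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        counts = [apply_shm(r, 5.0, rng).v_mutation_count for r in recs]
        se = np.sqrt(5.0 / len(counts))
        assert abs(np.mean(counts) - 5.0) < 3 * se

    def test_mutation_count_capped_at_v_length(self):
        rec = self._record()
        out = apply_shm(rec, 500.0, np.random.default_rng(1))
        assert out.v_mutation_count <= rec.v_sequence_end

    def test_junction_mutations_recompute_cdr3(self):
        m, _ = species_preset("omnirat_like")
        recs = simulate_rearrangements(m, 200, np.random.default_rng(6))
        rng = np.random.default_rng(7)
        changed = sum(apply_shm(r, 8.0, rng).junction != r.junction
                      for r in recs)
        assert changed > 0
        for r in recs[:50]:
            out = apply_shm(r, 8.0, rng)
            assert len(out.junction) == len(r.junction)
            assert out.junction == out.sequence[
                out.junction_start: out.junction_start + len(out.junction)]


class TestSimulateRepertoire:
    def test_no_tissue_overlap_bounds_shared_clonotypes(self):
        m, cfg = species_preset("omnirat_like")
        cfg.n_clones, cfg.n_reads_per_compartment = 800, 1500
        cfg.tissue_overlap_prob = 0.0
        cfg.shm_rate_igm = cfg.shm_rate_igg = 0.0
        cfg.seed = 21
        ln, sp, truth = simulate_repertoire(cfg)
        table = build_incidence(assign_clonotypes(ln), assign_clonotypes(sp))
        assert table.q2 <= truth.cross_tissue_collisions()

    def test_full_overlap_gives_high_recapture(self):
        m, cfg = species_preset("omnirat_like")
        cfg.n_clones, cfg.n_reads_per_compartment = 150, 4000
        cfg.tissue_overlap_prob = 1.0
        cfg.shm_rate_igm = cfg.shm_rate_igg = 0.0
        cfg.seed = 22
        ln, sp, truth = simulate_repertoire(cfg)
        table = build_incidence(assign_clonotypes(ln), assign_clonotypes(sp))
        assert table.q2 / table.s_obs > 0.8

    def test_read_conservation(self):
        m, cfg = species_preset("human_like")
        cfg.n_clones, cfg.n_reads_per_compartment = 300, 700
        cfg.seed = 23
        ln, sp, _ = simulate_repertoire(cfg)
        assert len(ln) == len(sp) == 700

    def test_same_seed_gives_byte_identical_airr(self, tmp_path):
        m, cfg = species_preset("omnirat_like")
        cfg.n_clones, cfg.n_reads_per_compartment = 200, 300
        cfg.seed = 9
        paths = []
        for run in (0, 1):
            ln, sp, _ = simulate_repertoire(cfg)
            p = tmp_path / f"run{run}.tsv"
            write_airr(ln, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_truth_links_every_read_to_one_clone(self):
        m, cfg = species_preset("omnirat_like")
        cfg.n_clones, cfg.n_reads_per_compartment = 200, 400
        cfg.shm_rate_igm = cfg.shm_rate_igg = 0.0
        cfg.seed = 10
        ln, sp, truth = simulate_repertoire(cfg)
        for rec in list(ln) + list(sp):
            key = truth.clone_keys[rec.clone_id]
            assert (rec.v_gene, rec.j_gene, rec.cdr3_aa) == key


class TestSpeciesPreset:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            species_preset("mouse_like")

    def test_insertion_distributions_normalized(self, igh_presets):
        for m in igh_presets.values():
            assert m.p_n1.sum() == pytest.approx(1.0, abs=1e-12)
            assert m.p_n2.sum() == pytest.approx(1.0, abs=1e-12)

    def test_kappa_presets_valid(self):
        for name in ("human_like", "omnirat_like"):
            model, cfg = species_preset(name, locus="IGK")
            model.validate()
            recs = simulate_rearrangements(model, 50,
                                           np.random.default_rng(1))
            assert all(r.locus == "IGK" and r.d_call is None for r in recs)
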