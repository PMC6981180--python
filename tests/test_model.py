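"""Recombination-model inference, generation and KL divergence."""

import numpy as np
import pytest

from vdjcompare.model import (EVENTS, ModelError, RecombinationModel,
                              generate, infer_model, kl_complete, kl_event,
                              select_unmutated)
from vdjcompare.records import Repertoire
from vdjcompare.simulate import simulate_rearrangements, species_preset

from conftest import brute_force_joint_kl, make_tiny_model


def _records(model, n, seed=0):
    return simulate_rearrangements(model, n, np.random.default_rng(seed))


class TestSelectUnmutated:
    def _rep(self):
        recs = _records(make_tiny_model(uniform=True), 10, seed=1)
        for i, r in enumerate(recs):
            r.v_mutation_count = 0 if i < 5 else 3
            r.productive = True
        return Repertoire(recs)

    def test_shortfall_returns_all_qualifying(self):
        sel = select_unmutated(self._rep(), 100)
        assert len(sel) == 5
        assert all(r.v_mutation_count == 0 for r in sel)

    def test_subsample_is_seed_deterministic(self):
        rep = self._rep()
        ids_a = [r.sequence_id for r in select_unmutated(rep, 3, seed=42)]
        ids_b = [r.sequence_id for r in select_unmutated(rep, 3, seed=42)]
        assert ids_a == ids_b and len(ids_a) == 3

    def test_no_qualifying_records_is_an_error(self):
        rep = self._rep()
        for r in rep.records:
            r.v_mutation_count = 1
        with pytest.raises(ValueError, match="unmutated"):
            select_unmutated(rep, 5)

    def test_shm_free_simulation_all_qualify(self):
        model, cfg = species_preset("omnirat_like")
        from vdjcompare.simulate import simulate_repertoire
        cfg.n_clones, cfg.n_reads_per_compartment = 200, 300
        cfg.shm_rate_igm = cfg.shm_rate_igg = 0.0
        cfg.seed = 5
        ln, sp, _ = simulate_repertoire(cfg)
        n_prod = len(ln.productive())
        assert len(select_unmutated(ln, 10 ** 6)) == n_prod


class TestInferModel:
    def test_single_v_gets_probability_one_without_pseudocount(self):
        tiny = make_tiny_model(uniform=True)
        recs = _records(tiny, 4, seed=2)
        for r in recs:
            r.v_call = "TV1"
        inferred = infer_model(Repertoire(recs), tiny, pseudocount=0.0)
        assert inferred.p_v[0] == pytest.approx(1.0)
        assert inferred.p_v[1] == pytest.approx(0.0)

    def test_pseudocount_formula_on_two_cell_support(self):
        # counts {TV1: 1, TV2: 3}, pseudocount 1, support 2 -> 2/6 and 4/6
        tiny = make_tiny_model(uniform=True)
        recs = _records(tiny, 4, seed=3)
        for i, r in enumerate(recs):
            r.v_call = "TV1" if i == 0 else "TV2"
        inferred = infer_model(Repertoire(recs), tiny, pseudocount=1.0)
        assert inferred.p_v[0] == pytest.approx(2 / 6)
        assert inferred.p_v[1] == pytest.approx(4 / 6)

    def test_missing_annotation_field_named_in_error(self):
        tiny = make_tiny_model(uniform=True)
        recs = _records(tiny, 3, seed=4)
        recs[1].n1_length = None
        with pytest.raises(ValueError, match="n1_length"):
            infer_model(Repertoire(recs), tiny)

    def test_more_training_data_gives_smaller_kl(self):
        truth = make_tiny_model(seed=13)
        big = infer_model(Repertoire(_records(truth, 20_000, seed=5)), truth)
        small = infer_model(Repertoire(_records(truth, 200, seed=6)), truth)
        assert kl_complete(truth, big) < kl_complete(truth, small)


class TestGenerate:
    def test_zero_records_forbidden(self, tiny_model):
        with pytest.raises(ValueError):
            generate(tiny_model, 0)

    def test_fixed_seed_reproducible(self, tiny_model):
        a = generate(tiny_model, 50, seed=3)
        b = generate(tiny_model, 50, seed=3)
        assert [r.junction for r in a] == [r.junction for r in b]

    def test_generated_cdr3_distribution_matches_training(self):
        """Sequences generated from an inferred model reproduce the CDRH3
        length histogram of the training repertoire (total variation)."""
        truth, _ = species_preset("omnirat_like")
        train = _records(truth, 40_000, seed=7)
        inferred = infer_model(Repertoire(train), truth)
        gen = generate(inferred, 40_000, seed=8)

        def hist(records):
            vals = np.array([r.cdr3_length for r in records if r.productive])
            return np.bincount(vals, minlength=40)[:40] / len(vals)

        tv = 0.5 * np.abs(hist(train) - hist(list(gen))).sum()
        assert tv < 0.05


class TestKL:
    def test_identical_models_have_zero_divergence(self, tiny_model):
        for event in EVENTS:
            assert kl_event(tiny_model, tiny_model, event) == pytest.approx(0.0)
        assert kl_complete(tiny_model, tiny_model) == pytest.approx(0.0)

    def test_hand_computed_binary_v_choice(self):
        p = make_tiny_model(uniform=True)
        q = make_tiny_model(uniform=True)
        p.p_v = np.array([0.5, 0.5])
        q.p_v = np.array([0.25, 0.75])
        expected = 0.5 * np.log2(2) + 0.5 * np.log2(0.5 / 0.75)
        assert kl_event(p, q, "v_choice") == pytest.approx(expected)
        assert expected == pytest.approx(0.2075, abs=1e-4)

    def test_chain_rule_equals_enumerated_joint(self):
        p = make_tiny_model(seed=1)
        q = make_tiny_model(seed=2)
        assert kl_complete(p, q) == pytest.approx(
            brute_force_joint_kl(p, q), abs=1e-9)

    def test_nonnegative_and_bounded_below_by_events(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = make_tiny_model(seed=int(rng.integers(2 ** 31)))
            q = make_tiny_model(seed=int(rng.integers(2 ** 31)))
            events = [kl_event(p, q, e) for e in EVENTS]
            total = kl_complete(p, q)
            assert all(e >= -1e-12 for e in events)
            assert total >= max(events) - 1e-9

    def test_mismatched_supports_rejected(self, tiny_model):
        other, _ = species_preset("human_like")
        with pytest.raises(ModelError, match="mismatched"):
            kl_event(tiny_model, other, "v_choice")

    def test_symmetrized_option_is_jeffreys(self):
        p = make_tiny_model(seed=3)
        q = make_tiny_model(seed=4)
        assert kl_complete(p, q, symmetrized=True) == pytest.approx(
            kl_complete(p, q) + kl_complete(q, p))


class TestSerialization:
    def test_json_round_trip(self, tmp_path, tiny_model):
        path = tmp_path / "model.json"
        tiny_model.to_json(path)
        back = RecombinationModel.from_json(path)
        assert back.v_genes == tiny_model.v_genes
        np.testing.assert_allclose(back.p_dj, tiny_model.p_dj)
        np.testing.assert_allclose(back.p_d_trim, tiny_model.p_d_trim)
        assert back.v_anchor == tiny_model.v_anchor
        assert kl_complete(tiny_model, back) == pytest.approx(0.0, abs=1e-12)


class TestPresetModelDivergence:
    def test_intra_preset_models_closer_than_inter(self):
        """Models inferred from repeated draws of the rat-like preset lie
        closer to each other (complete KL) than to a human-like-trained
        model — the inter-species divergence dominates."""
        template, _ = species_preset("human_like")
        models = {}
        for name, preset, seed in (("rat_a", "omnirat_like", 70),
                                   ("rat_b", "omnirat_like", 71),
                                   ("rat_c", "omnirat_like", 72),
                                   ("hum_a", "human_like", 73)):
            truth, _ = species_preset(preset)
            recs = _records(truth, 20_000, seed=seed)
            models[name] = infer_model(Repertoire(recs), template)
        rats = ["rat_a", "rat_b", "rat_c"]
        intra = np.mean([kl_complete(models[a], models[b])
                         for a in rats for b in rats if a != b])
        inter = np.mean([kl_complete(models[a], models["hum_a"])
                         for a in rats])
        assert intra < inter
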