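"""Shared fixtures: tiny enumerable recombination models and oracles."""

from __future__ import annotations

import numpy as np
import pytest

from vdjcompare.model import RecombinationModel
from vdjcompare.records import GermlineGene
from vdjcompare.simulate import species_preset

# Tiny germline used by the enumerable model: anchors chosen so the junction
# geometry is valid for every trim in the support.
_TINY_V = {"TV1": ("AAATGTGC", 3), "TV2": ("CCCTGTAA", 3)}   # Cys at index 3
_TINY_D = {"TD1": "ACGT", "TD2": "GGCC"}
_TINY_J = {"TJ1": ("ATGGGGC", 1)}                            # Trp at index 1


def make_tiny_model(seed: int | None = None,
                    uniform: bool = False) -> RecombinationModel:
    """2 V x 2 D x 1 J model with trims <= 1 and insertions <= 1.

    The full scenario joint has 2*2*1*2*(2*2)*2*2*2 = 256 cells and can be
    enumerated exhaustively.  ``seed`` randomizes every event distribution
    (Dirichlet); ``uniform`` gives flat distributions.
    """
    rng = np.random.default_rng(seed)

    def dist(k):
        if uniform or seed is None:
            return np.full(k, 1.0 / k)
        return rng.dirichlet(np.ones(k) * 2.0)

    germline = {}
    v_anchor, j_anchor = {}, {}
    for name, (seq, anchor) in _TINY_V.items():
        germline[name] = GermlineGene(name, seq, "V", "IGH")
        v_anchor[name] = anchor
    for name, seq in _TINY_D.items():
        germline[name] = GermlineGene(name, seq, "D", "IGH")
    for name, (seq, anchor) in _TINY_J.items():
        germline[name] = GermlineGene(name, seq, "J", "IGH")
        j_anchor[name] = anchor

    model = RecombinationModel(
        v_genes=list(_TINY_V), d_genes=list(_TINY_D), j_genes=list(_TINY_J),
        p_v=dist(2), p_dj=dist(2).reshape(2, 1),
        p_v_trim=np.stack([dist(2) for _ in range(2)]),
        p_d_trim=np.stack([dist(4).reshape(2, 2) for _ in range(2)]),
        p_j_trim=np.stack([dist(2)]),
        p_n1=dist(2), p_n2=dist(2),
        ins_init=np.full(4, 0.25), ins_trans=np.full((4, 4), 0.25),
        germline=germline, v_anchor=v_anchor, j_anchor=j_anchor,
        use_p_nucleotides=False, name="tiny")
    model.validate()
    return model


def enumerate_scenarios(model: RecombinationModel):
    """Yield (probability, scenario tuple) over the full factorized joint."""
    nV, nJ = len(model.v_genes), len(model.j_genes)
    nD = len(model.d_genes)
    n5, n3 = model.p_d_trim.shape[1], model.p_d_trim.shape[2]
    for vi in range(nV):
        for di in range(nD):
            for ji in range(nJ):
                for vt in range(model.p_v_trim.shape[1]):
                    for d5 in range(n5):
                        for d3 in range(n3):
                            for jt in range(model.p_j_trim.shape[1]):
                                for n1 in range(model.p_n1.size):
                                    for n2 in range(model.p_n2.size):
                                        prob = (model.p_v[vi]
                                                * model.p_dj[di, ji]
                                                * model.p_v_trim[vi, vt]
                                                * model.p_d_trim[di, d5, d3]
                                                * model.p_j_trim[ji, jt]
                                                * model.p_n1[n1]
                                                * model.p_n2[n2])
                                        yield prob, (vi, di, ji, vt, d5, d3,
                                                     jt, n1, n2)


def brute_force_joint_kl(p: RecombinationModel, q: RecombinationModel) -> float:
    """KL (bits) between fully enumerated scenario joints — the oracle the
    chain-rule computation must match."""
    q_probs = {sc: prob for prob, sc in enumerate_scenarios(q)}
    total = 0.0
    for prob, sc in enumerate_scenarios(p):
        if prob > 0:
            total += prob * np.log2(prob / q_probs[sc])
    return float(total)


@pytest.fixture(scope="session")
def tiny_model() -> RecombinationModel:
    return make_tiny_model(seed=7)


@pytest.fixture(scope="session")
def igh_presets():
    """Heavy-chain preset models for both species."""
    rat, _ = species_preset("omnirat_like")
    hum, _ = species_preset("human_like")
    return {"omnirat_like": rat, "human_like": hum}
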