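"""Factorized generative model of heavy-chain V(D)J recombination.

The model factorizes the recombination scenario into independent "events":

    P(scenario) = P(V) * P(D,J) * P(vTrim3 | V) * P(dTrim5, dTrim3 | D)
                  * P(jTrim5 | J) * P(n1) * P(n2)

with non-templated insertion nucleotides drawn from a first-order Markov
chain (the Markov parameters shape sequences but are not part of the event
factorization compared by KL).  Inference here is annotation-based: each
record contributes its single best annotation, and every event distribution
is the pseudocount-smoothed empirical frequency over a declared finite
support.  This is a deliberate simplification of EM over hidden
recombination scenarios; see docs/methods.md.

KL divergences are forward, D(p||q), in bits.  Conditional events use the
chain rule: the expectation over the parent's marginal under ``p`` of the
conditional divergence, so the sum over all events equals the KL between the
full joint scenario distributions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import GermlineGene, Repertoire, strip_allele

log = logging.getLogger(__name__)

#: Event names in the factorization, in chain-rule order.
EVENTS = ("v_choice", "dj_choice", "v_trim", "d_trim", "j_trim",
          "n1_length", "n2_length")

_NORM_TOL = 1e-9


class ModelError(ValueError):
    """Invalid or incompatible recombination model."""


@dataclass
class RecombinationModel:
    """Event marginals/conditionals of heavy-chain V(D)J recombination.

    Gene axes are allele-stripped gene names; trim/insertion supports are
    ``0..shape-1`` in nucleotides.  Cells of ``p_d_trim`` with
    ``d5 + d3 > len(D)`` are structurally zero.
    """

    v_genes: list[str]
    d_genes: list[str]
    j_genes: list[str]
    p_v: np.ndarray                    # (nV,)
    p_dj: np.ndarray                   # (nD, nJ) joint
    p_v_trim: np.ndarray               # (nV, v_trim_max+1), conditional on V
    p_d_trim: np.ndarray               # (nD, d5_max+1, d3_max+1), cond. on D
    p_j_trim: np.ndarray               # (nJ, j_trim_max+1), conditional on J
    p_n1: np.ndarray                   # (ins_max+1,) VD insertion length
    p_n2: np.ndarray                   # (ins_max+1,) DJ insertion length
    ins_init: np.ndarray               # (4,) insertion nt initial probs, ACGT
    ins_trans: np.ndarray              # (4,4) first-order transition matrix
    germline: dict[str, GermlineGene]  # keyed by allele-stripped name
    v_anchor: dict[str, int]           # Cys codon start within each V
    j_anchor: dict[str, int]           # Trp codon start within each J
    locus: str = "IGH"
    use_p_nucleotides: bool = True     # <=2 nt palindrome at untrimmed ends
    name: str = ""

    # -- marginals ---------------------------------------------------------
    @property
    def p_d(self) -> np.ndarray:
        return self.p_dj.sum(axis=1)

    @property
    def p_j(self) -> np.ndarray:
        return self.p_dj.sum(axis=0)

    def validate(self) -> None:
        """Check normalization of every event distribution (tol 1e-9)."""
        checks = [("p_v", self.p_v.sum()), ("p_dj", self.p_dj.sum()),
                  ("p_n1", self.p_n1.sum()), ("p_n2", self.p_n2.sum()),
                  ("ins_init", self.ins_init.sum())]
        checks += [(f"p_v_trim[{g}]", row.sum())
                   for g, row in zip(self.v_genes, self.p_v_trim)]
        checks += [(f"p_d_trim[{g}]", plane.sum())
                   for g, plane in zip(self.d_genes, self.p_d_trim)]
        checks += [(f"p_j_trim[{g}]", row.sum())
                   for g, row in zip(self.j_genes, self.p_j_trim)]
        checks += [(f"ins_trans[{nt}]", row.sum())
                   for nt, row in zip("ACGT", self.ins_trans)]
        for label, total in checks:
            if abs(total - 1.0) > _NORM_TOL:
                raise ModelError(f"{label} sums to {total!r}, not 1")
        for arr in (self.p_v, self.p_dj, self.p_v_trim, self.p_d_trim,
                    self.p_j_trim, self.p_n1, self.p_n2, self.ins_init,
                    self.ins_trans):
            arr = np.asarray(arr)
            if np.isnan(arr).any():
                raise ModelError("NaN probability in model")
            if (arr < 0).any():
                raise ModelError("negative probability in model")

    def supports_match(self, other: "RecombinationModel") -> bool:
        return (self.v_genes == other.v_genes
                and self.d_genes == other.d_genes
                and self.j_genes == other.j_genes
                and self.p_v_trim.shape == other.p_v_trim.shape
                and self.p_d_trim.shape == other.p_d_trim.shape
                and self.p_j_trim.shape == other.p_j_trim.shape
                and self.p_n1.shape == other.p_n1.shape
                and self.p_n2.shape == other.p_n2.shape)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "locus": self.locus, "name": self.name,
            "use_p_nucleotides": self.use_p_nucleotides,
            "v_genes": self.v_genes, "d_genes": self.d_genes,
            "j_genes": self.j_genes,
            "p_v": self.p_v.tolist(), "p_dj": self.p_dj.tolist(),
            "p_v_trim": self.p_v_trim.tolist(),
            "p_d_trim": self.p_d_trim.tolist(),
            "p_j_trim": self.p_j_trim.tolist(),
            "p_n1": self.p_n1.tolist(), "p_n2": self.p_n2.tolist(),
            "ins_init": self.ins_init.tolist(),
            "ins_trans": self.ins_trans.tolist(),
            "v_anchor": self.v_anchor, "j_anchor": self.j_anchor,
            "germline": {g.gene: {"name": g.name, "sequence": g.sequence,
                                  "segment": g.segment, "locus": g.locus}
                         for g in self.germline.values()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RecombinationModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        germline = {k: GermlineGene(name=v["name"], sequence=v["sequence"],
                                    segment=v["segment"], locus=v["locus"])
                    for k, v in d["germline"].items()}
        model = cls(
            v_genes=d["v_genes"], d_genes=d["d_genes"], j_genes=d["j_genes"],
            p_v=np.array(d["p_v"]), p_dj=np.array(d["p_dj"]),
            p_v_trim=np.array(d["p_v_trim"]), p_d_trim=np.array(d["p_d_trim"]),
            p_j_trim=np.array(d["p_j_trim"]),
            p_n1=np.array(d["p_n1"]), p_n2=np.array(d["p_n2"]),
            ins_init=np.array(d["ins_init"]), ins_trans=np.array(d["ins_trans"]),
            germline=germline, v_anchor=d["v_anchor"], j_anchor=d["j_anchor"],
            locus=d["locus"], use_p_nucleotides=d["use_p_nucleotides"],
            name=d.get("name", ""))
        model.validate()
        return model


# ---------------------------------------------------------------------------
# training-set selection and inference
# ---------------------------------------------------------------------------

def select_unmutated(rep: Repertoire, n: int, seed: int = 0) -> Repertoire:
    """Productive records with zero V-region mutations, subsampled to ``n``.

    If fewer than ``n`` qualify the shortfall is logged and all qualifying
    records are returned; zero qualifying records is an error.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pool = [r for r in rep.records if r.productive and r.v_mutation_count == 0]
    if not pool:
        raise ValueError("no productive unmutated records to select")
    if len(pool) > n:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(pool), size=n, replace=False))
        pool = [pool[i] for i in idx]
    else:
        log.info("select_unmutated: only %d of requested %d qualify",
                 len(pool), n)
    return Repertoire(pool, rep.subject_id, rep.tissue, rep.locus,
                      rep.germline_ref)


def _smooth(counts: np.ndarray, pseudocount: float,
            mask: Optional[np.ndarray] = None) -> np.ndarray:
    """(count + pc) / (total + pc * support size), over the valid support."""
    counts = counts.astype(float)
    if mask is not None:
        counts = counts * mask
        support = int(mask.sum())
    else:
        support = counts.size
    total = counts.sum() + pseudocount * support
    if total == 0:
        # no observations and no smoothing: fall back to uniform
        out = np.ones_like(counts) if mask is None else mask.astype(float)
        return out / out.sum()
    out = (counts + pseudocount) / total
    if mask is not None:
        out = out * mask
        out /= out.sum()
    return out


def infer_model(rep: Repertoire | Iterable, template: RecombinationModel,
                pseudocount: float = 0.5) -> RecombinationModel:
    """Empirical recombination model from annotated records.

    ``template`` fixes the germline reference and event supports (so that
    models inferred from different repertoires are KL-comparable); only the
    probability arrays are re-estimated.  Each event distribution is the
    pseudocount-smoothed frequency of the annotation fields.
    """
    records = rep.records if isinstance(rep, Repertoire) else list(rep)
    if not records:
        raise ValueError("no records to infer from")
    v_idx = {g: i for i, g in enumerate(template.v_genes)}
    d_idx = {g: i for i, g in enumerate(template.d_genes)}
    j_idx = {g: i for i, g in enumerate(template.j_genes)}

    c_v = np.zeros(len(template.v_genes))
    c_dj = np.zeros(template.p_dj.shape)
    c_vt = np.zeros(template.p_v_trim.shape)
    c_dt = np.zeros(template.p_d_trim.shape)
    c_jt = np.zeros(template.p_j_trim.shape)
    c_n1 = np.zeros(template.p_n1.shape)
    c_n2 = np.zeros(template.p_n2.shape)

    required = ("v_call", "d_call", "j_call")
    for r in records:
        for f in required:
            if not getattr(r, f):
                raise ValueError(f"record {r.sequence_id}: missing {f}")
        for f in ("n1_length", "n2_length", "d_trim5", "d_trim3"):
            if getattr(r, f) is None:
                raise ValueError(f"record {r.sequence_id}: missing {f}")
        try:
            vi, di, ji = v_idx[r.v_gene], d_idx[r.d_gene], j_idx[r.j_gene]
        except KeyError as exc:
            raise ValueError(f"record {r.sequence_id}: gene {exc} not in "
                             "template germline") from None
        w = r.duplicate_count
        c_v[vi] += w
        c_dj[di, ji] += w
        c_vt[vi, min(r.v_trim3, c_vt.shape[1] - 1)] += w
        c_dt[di, min(r.d_trim5, c_dt.shape[1] - 1),
             min(r.d_trim3, c_dt.shape[2] - 1)] += w
        c_jt[ji, min(r.j_trim5, c_jt.shape[1] - 1)] += w
        c_n1[min(r.n1_length, c_n1.size - 1)] += w
        c_n2[min(r.n2_length, c_n2.size - 1)] += w

    d_mask = _d_trim_valid_mask(template)

    model = RecombinationModel(
        v_genes=list(template.v_genes), d_genes=list(template.d_genes),
        j_genes=list(template.j_genes),
        p_v=_smooth(c_v, pseudocount),
        p_dj=_smooth(c_dj, pseudocount),
        p_v_trim=np.stack([_smooth(row, pseudocount) for row in c_vt]),
        p_d_trim=np.stack([_smooth(plane, pseudocount, mask=m)
                           for plane, m in zip(c_dt, d_mask)]),
        p_j_trim=np.stack([_smooth(row, pseudocount) for row in c_jt]),
        p_n1=_smooth(c_n1, pseudocount), p_n2=_smooth(c_n2, pseudocount),
        ins_init=template.ins_init.copy(), ins_trans=template.ins_trans.copy(),
        germline=dict(template.germline),
        v_anchor=dict(template.v_anchor), j_anchor=dict(template.j_anchor),
        locus=template.locus, use_p_nucleotides=template.use_p_nucleotides,
        name="inferred")
    model.validate()
    return model


def _d_trim_valid_mask(model: RecombinationModel) -> np.ndarray:
    """Boolean (nD, d5+1, d3+1) mask of trim pairs with d5+d3 <= len(D)."""
    nD, n5, n3 = model.p_d_trim.shape
    mask = np.zeros((nD, n5, n3), dtype=bool)
    for di, gene in enumerate(model.d_genes):
        L = len(model.germline[gene])
        for a in range(n5):
            for b in range(n3):
                mask[di, a, b] = a + b <= L
    return mask


def generate(model: RecombinationModel, n: int, seed: int = 0) -> Repertoire:
    """Draw ``n`` synthetic rearrangements from the model (SHM-free)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    from .simulate import simulate_rearrangements
    records = simulate_rearrangements(model, n, np.random.default_rng(seed))
    return Repertoire(records, subject_id="generated", tissue="pooled",
                      locus=model.locus)


# ---------------------------------------------------------------------------
# KL divergence
# ---------------------------------------------------------------------------

def _kl_vec(p: np.ndarray, q: np.ndarray) -> float:
    """D(p||q) in bits over a shared finite support."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    nz = p > 0
    if (q[nz] <= 0).any():
        return float("inf")
    return float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))


def kl_event(p: RecombinationModel, q: RecombinationModel, event: str) -> float:
    """Forward KL divergence D(p||q), in bits, for one recombination event.

    Conditional events (trims) are the expectation over the parent gene's
    marginal distribution under ``p`` of the conditional divergence.
    """
    if event not in EVENTS:
        raise ValueError(f"unknown event {event!r}; expected one of {EVENTS}")
    if not p.supports_match(q):
        raise ModelError("models have mismatched gene sets or supports")
    if event == "v_choice":
        return _kl_vec(p.p_v, q.p_v)
    if event == "dj_choice":
        return _kl_vec(p.p_dj, q.p_dj)
    if event == "v_trim":
        return float(sum(w * _kl_vec(pr, qr) for w, pr, qr
                         in zip(p.p_v, p.p_v_trim, q.p_v_trim)))
    if event == "d_trim":
        return float(sum(w * _kl_vec(pr, qr) for w, pr, qr
                         in zip(p.p_d, p.p_d_trim, q.p_d_trim)))
    if event == "j_trim":
        return float(sum(w * _kl_vec(pr, qr) for w, pr, qr
                         in zip(p.p_j, p.p_j_trim, q.p_j_trim)))
    if event == "n1_length":
        return _kl_vec(p.p_n1, q.p_n1)
    return _kl_vec(p.p_n2, q.p_n2)


def kl_complete(p: RecombinationModel, q: RecombinationModel,
                symmetrized: bool = False) -> float:
    """Chain-rule KL over all events = KL between joint scenario laws (bits).

    With ``symmetrized=True`` returns the Jeffreys divergence
    ``D(p||q) + D(q||p)``.
    """
    fwd = sum(kl_event(p, q, e) for e in EVENTS)
    if not symmetrized:
        return float(fwd)
    return float(fwd + sum(kl_event(q, p, e) for e in EVENTS))


def kl_event_table(models: dict[str, RecombinationModel]) -> "pd.DataFrame":
    """Pairwise per-event and complete KL for every ordered model pair."""
    import pandas as pd
    rows = []
    for a, pa in models.items():
        for b, pb in models.items():
            if a == b:
                continue
            row = {"model_p": a, "model_q": b}
            row.update({e: kl_event(pa, pb, e) for e in EVENTS})
            row["complete"] = sum(row[e] for e in EVENTS)
            rows.append(row)
    return pd.DataFrame(rows)
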