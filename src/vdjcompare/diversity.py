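"""Clonotype assignment, cross-compartment incidence and richness estimation.

A clonotype is the exact-identity class (V gene, J gene, CDR3 amino-acid
sequence), with gene names allele-stripped.  The lymph-node and spleen
compartments of one animal act as two independent sampling units: a
clonotype seen in both must derive from at least two B cells, which makes
the pair usable as a capture-recapture design.  Richness is estimated with
the incidence-based Chao2 estimator (m = 2 units, the (m-1)/m = 1/2 factor
kept explicitly) and the abundance-based Chao1 estimator:

    Chao2 = S_obs + (1/2) * Q1^2 / (2 * Q2)          (Q2 > 0)
    Chao2 = S_obs + (1/2) * Q1 * (Q1 - 1) / (2 * (Q2 + 1))   (bias-corrected)
    Chao1 = S_obs + F1^2 / (2 * F2)                  (F2 > 0, analogous)

Both are lower-bound-type estimators: they correct for unseen types only as
far as the rare-type counts allow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .records import Repertoire, SequenceRecord

ClonotypeKey = tuple  # (v_gene, j_gene, cdr3_aa)


@dataclass
class Clonotype:
    key: ClonotypeKey
    compartment_counts: dict[str, int] = field(default_factory=dict)

    @property
    def abundance(self) -> int:
        return sum(self.compartment_counts.values())


@dataclass
class ClonotypeSet:
    """Clonotypes of one repertoire plus the rejection tally."""

    clonotypes: list[Clonotype]
    rejected: int
    label: tuple

    def keys(self) -> set:
        return {c.key for c in self.clonotypes}

    def abundances(self) -> np.ndarray:
        return np.array(sorted(c.abundance for c in self.clonotypes),
                        dtype=int)

    def __len__(self) -> int:
        return len(self.clonotypes)


def record_key(r: SequenceRecord) -> Optional[ClonotypeKey]:
    cdr3 = r.cdr3_aa
    if not cdr3 or not r.v_gene or not r.j_gene:
        return None
    return (r.v_gene, r.j_gene, cdr3)


def assign_clonotypes(rep: Repertoire,
                      include_nonproductive: bool = False) -> ClonotypeSet:
    """Collapse productive records into clonotypes (deterministic key order).

    Productive records lacking a CDR3 or gene call are rejected and counted.
    """
    table: dict[ClonotypeKey, Clonotype] = {}
    rejected = 0
    for r in rep.records:
        if not r.productive and not include_nonproductive:
            continue
        key = record_key(r)
        if key is None:
            rejected += 1
            continue
        ct = table.get(key)
        if ct is None:
            ct = table[key] = Clonotype(key)
        ct.compartment_counts[r.tissue] = (
            ct.compartment_counts.get(r.tissue, 0) + r.duplicate_count)
    return ClonotypeSet([table[k] for k in sorted(table)], rejected, rep.label)


# ---------------------------------------------------------------------------
# incidence and Chao estimators
# ---------------------------------------------------------------------------

@dataclass
class IncidenceTable:
    """Binary incidence of clonotypes over m = 2 sampling units."""

    s_obs: int
    q1: int     # detected in exactly one unit
    q2: int     # detected in both units
    m: int = 2

    def __post_init__(self) -> None:
        if self.q1 + self.q2 != self.s_obs:
            raise ValueError("Q1 + Q2 must equal S_obs")


def build_incidence(ln: "ClonotypeSet | set", sp: "ClonotypeSet | set"
                    ) -> IncidenceTable:
    """Two-unit incidence table from lymph-node and spleen clonotype sets."""
    a = ln.keys() if isinstance(ln, ClonotypeSet) else set(ln)
    b = sp.keys() if isinstance(sp, ClonotypeSet) else set(sp)
    union = a | b
    if not union:
        raise ValueError("empty clonotype union")
    q2 = len(a & b)
    return IncidenceTable(s_obs=len(union), q1=len(union) - q2, q2=q2)


@dataclass(frozen=True)
class DiversityEstimate:
    estimator: str
    estimate: float
    s_obs: int
    inputs: dict

    def __post_init__(self) -> None:
        if self.estimate < self.s_obs - 1e-9:
            raise ValueError("richness estimate below observed richness")


def chao2(table: IncidenceTable, bias_corrected: bool = False
          ) -> DiversityEstimate:
    """Incidence-based Chao2 richness estimate for m = 2 sampling units.

    The bias-corrected form is used automatically when Q2 = 0 (the classic
    form is undefined there) and on request always.
    """
    if table.m != 2:
        raise ValueError("chao2 implemented for m = 2 sampling units")
    factor = (table.m - 1) / table.m
    if bias_corrected or table.q2 == 0:
        extra = factor * table.q1 * (table.q1 - 1) / (2.0 * (table.q2 + 1))
        name = "chao2_bias_corrected"
    else:
        extra = factor * table.q1 ** 2 / (2.0 * table.q2)
        name = "chao2"
    return DiversityEstimate(estimator=name,
                             estimate=float(table.s_obs + extra),
                             s_obs=table.s_obs,
                             inputs={"q1": table.q1, "q2": table.q2,
                                     "m": table.m})


def chao1(abundances: Sequence[int], bias_corrected: bool = False
          ) -> DiversityEstimate:
    """Abundance-based Chao1 richness estimate from clonotype abundances."""
    ab = np.asarray(list(abundances), dtype=int)
    if ab.size == 0:
        raise ValueError("empty abundance vector")
    if (ab <= 0).any():
        raise ValueError("abundances must be positive integers")
    s_obs = int(ab.size)
    f1 = int((ab == 1).sum())
    f2 = int((ab == 2).sum())
    if bias_corrected or f2 == 0:
        extra = f1 * (f1 - 1) / (2.0 * (f2 + 1))
        name = "chao1_bias_corrected"
    else:
        extra = f1 ** 2 / (2.0 * f2)
        name = "chao1"
    return DiversityEstimate(estimator=name, estimate=float(s_obs + extra),
                             s_obs=s_obs, inputs={"f1": f1, "f2": f2})


# ---------------------------------------------------------------------------
# rarefaction and fraction sweeps
# ---------------------------------------------------------------------------

def _expand_keys(records: Iterable[SequenceRecord],
                 unit: str = "clonotype") -> list:
    """Read-level key list (duplicate_count expanded)."""
    keys = []
    for r in records:
        if not r.productive:
            continue
        key = record_key(r) if unit == "clonotype" else (r.sequence or None)
        if key is None:
            continue
        keys.extend([key] * r.duplicate_count)
    return keys


def rarefaction(records: Iterable[SequenceRecord],
                fractions: Sequence[float] = tuple(np.round(
                    np.arange(0.1, 1.01, 0.1), 2)),
                n_reps: int = 10, seed: int = 0,
                unit: str = "clonotype") -> pd.DataFrame:
    """Mean unique-clonotype count at read subsample fractions.

    Each fraction f < 1 is the mean over ``n_reps`` independent
    without-replacement subsamples of ``floor(f*N)`` reads; f = 1 is computed
    once on the full data.  Returns a frame with columns fraction, n_reads,
    mean_unique.
    """
    keys = _expand_keys(records, unit)
    if not keys:
        raise ValueError("no usable reads")
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    codes = pd.factorize(pd.Series(keys))[0]
    n = len(codes)
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        k = int(np.floor(f * n))
        if k == 0:
            rows.append({"fraction": f, "n_reads": 0, "mean_unique": 0.0})
            continue
        if f == 1.0:
            uniq = [len(np.unique(codes))]
        else:
            uniq = [len(np.unique(rng.choice(codes, size=k, replace=False)))
                    for _ in range(n_reps)]
        rows.append({"fraction": float(f), "n_reads": k,
                     "mean_unique": float(np.mean(uniq))})
    return pd.DataFrame(rows)


def diversity_vs_fraction(ln: Repertoire, sp: Repertoire,
                          fractions: Sequence[float] = tuple(np.round(
                              np.arange(0.1, 1.01, 0.1), 2)),
                          estimator: str = "chao2", n_reps: int = 10,
                          seed: int = 0,
                          unit: str = "clonotype") -> pd.DataFrame:
    """Richness estimates over increasingly large read fractions.

    Applies the rarefaction subsampling scheme per compartment, then the
    chosen estimator (``chao2`` on the two-compartment incidence, ``chao1``
    on pooled abundances).  ``unit`` switches between clonotype identity and
    unique nucleotide sequence identity.
    """
    if estimator not in ("chao2", "chao1"):
        raise ValueError(f"unknown estimator {estimator!r}")
    keys_ln = _expand_keys(ln.records, unit)
    keys_sp = _expand_keys(sp.records, unit)
    if not keys_ln or not keys_sp:
        raise ValueError("both compartments need usable reads")
    rng = np.random.default_rng(seed)
    arr_ln = pd.Series(keys_ln)
    arr_sp = pd.Series(keys_sp)
    rows = []
    for f in fractions:
        if f <= 0 or f > 1:
            raise ValueError("fractions must lie in (0, 1]")
        reps = 1 if f == 1.0 else n_reps
        ests = []
        for _ in range(reps):
            if f == 1.0:
                sub_ln, sub_sp = arr_ln, arr_sp
            else:
                sub_ln = arr_ln.sample(n=int(np.floor(f * len(arr_ln))),
                                       replace=False,
                                       random_state=int(rng.integers(2**31)))
                sub_sp = arr_sp.sample(n=int(np.floor(f * len(arr_sp))),
                                       replace=False,
                                       random_state=int(rng.integers(2**31)))
            if estimator == "chao2":
                table = build_incidence(set(sub_ln), set(sub_sp))
                ests.append(chao2(table).estimate)
            else:
                counts = pd.concat([sub_ln, sub_sp]).value_counts()
                ests.append(chao1(counts.to_numpy()).estimate)
        rows.append({"fraction": float(f), "mean_estimate": float(np.mean(ests)),
                     "n_reps": reps})
    return pd.DataFrame(rows)
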