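"""Clonotype sharing between individuals and species pools.

"Public" clonotypes — identical (V gene, J gene, CDR3 aa) classes observed
in more than one individual — are quantified with exact set algebra.  The
normalization of a sharing fraction is ambiguous in common usage, so every
result carries three modes side by side:

* ``union``   |a n b| / |a u b|   (Jaccard; the default)
* ``mean``    |a n b| / ((|a| + |b|) / 2)
* ``per_set`` |a n b| / |a| and |a n b| / |b|

Shared-vs-unshared comparisons (CDR3 length, V-family usage, position
frequency matrices for sequence logos) weight each unique clonotype once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import gene_family
from .stats import DistributionSummary, _weighted_summary

AA_CATEGORIES = {
    "polar": set("GSTYCQN"),
    "basic": set("KRH"),
    "acidic": set("DE"),
    "hydrophobic": set("AVLIPWFM"),
}
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

MODES = ("union", "mean", "per_set")


@dataclass
class SharingResult:
    labels: tuple
    set_sizes: dict
    intersection: int
    venn_regions: dict          # frozenset(labels) -> exclusive region size
    fractions: dict             # mode -> value(s)
    mode: str = "union"

    @property
    def fraction(self) -> float:
        f = self.fractions[self.mode]
        return f if isinstance(f, float) else float(np.mean(list(f.values())))


def _as_set(s) -> set:
    if hasattr(s, "keys") and callable(s.keys) and not isinstance(s, dict):
        return set(s.keys())
    return set(s)


def pairwise_sharing(a, b, labels: tuple = ("a", "b"),
                     mode: str = "union") -> SharingResult:
    """Overlap of two clonotype sets under all normalization modes."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    sa, sb = _as_set(a), _as_set(b)
    if not sa or not sb:
        raise ValueError("empty clonotype set")
    inter = len(sa & sb)
    union = len(sa | sb)
    fractions = {
        "union": inter / union,
        "mean": inter / ((len(sa) + len(sb)) / 2.0),
        "per_set": {labels[0]: inter / len(sa), labels[1]: inter / len(sb)},
    }
    venn = {frozenset([labels[0]]): len(sa) - inter,
            frozenset([labels[1]]): len(sb) - inter,
            frozenset(labels): inter}
    return SharingResult(labels=tuple(labels),
                         set_sizes={labels[0]: len(sa), labels[1]: len(sb)},
                         intersection=inter, venn_regions=venn,
                         fractions=fractions, mode=mode)


def multiway_sharing(sets: Mapping[str, Iterable],
                     mode: str = "union") -> SharingResult:
    """Exact Venn region sizes for >= 2 sets via inclusion-exclusion.

    The exclusive size of region S is
    ``sum over T >= S of (-1)^(|T|-|S|) * |intersection of T|``.
    The headline fraction is |intersection of all| / |union of all|.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    named = {k: _as_set(v) for k, v in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least 2 sets")
    labels = tuple(named)
    inter_cache: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            acc = set.intersection(*(named[k] for k in combo))
            inter_cache[frozenset(combo)] = len(acc)
    venn: dict[frozenset, int] = {}
    for region in inter_cache:
        size = 0
        others = [l for l in labels if l not in region]
        for r in range(len(others) + 1):
            for extra in combinations(others, r):
                t = region | frozenset(extra)
                size += (-1) ** len(extra) * inter_cache[t]
        venn[region] = size
    union = len(set.union(*named.values()))
    full = inter_cache[frozenset(labels)]
    sizes = {k: len(v) for k, v in named.items()}
    mean_size = np.mean(list(sizes.values()))
    fractions = {
        "union": full / union if union else 0.0,
        "mean": full / mean_size if mean_size else 0.0,
        "per_set": {k: full / sizes[k] for k in labels if sizes[k]},
    }
    return SharingResult(labels=labels, set_sizes=sizes, intersection=full,
                         venn_regions=venn, fractions=fractions, mode=mode)


@dataclass
class PoolOverlap:
    per_subject: dict
    combined: float
    pool_size: int


def pool_overlap(query_sets: Mapping[str, Iterable], pool: Iterable
                 ) -> PoolOverlap:
    """Fraction of each subject's clonotypes found in a reference pool."""
    pool_set = _as_set(pool)
    if not pool_set:
        raise ValueError("empty pool")
    named = {k: _as_set(v) for k, v in query_sets.items()}
    for k, s in named.items():
        if not s:
            raise ValueError(f"empty query set {k!r}")
    per = {k: len(s & pool_set) / len(s) for k, s in named.items()}
    combined_set = set.union(*named.values())
    combined = len(combined_set & pool_set) / len(combined_set)
    return PoolOverlap(per_subject=per, combined=combined,
                       pool_size=len(pool_set))


# ---------------------------------------------------------------------------
# shared vs unshared characterization
# ---------------------------------------------------------------------------

@dataclass
class SharedUnsharedComparison:
    shared_lengths: Optional[DistributionSummary]
    unshared_lengths: Optional[DistributionSummary]
    shared_v_family: dict
    unshared_v_family: dict
    n_shared: int
    n_unshared: int


def _family_freqs(keys: Sequence[tuple]) -> dict:
    fams = pd.Series([gene_family(k[0]) for k in keys])
    if fams.empty:
        return {}
    freqs = fams.value_counts(normalize=True)
    return {str(k): float(v) for k, v in sorted(freqs.items())}


def compare_shared_unshared(query, pool) -> SharedUnsharedComparison:
    """Partition a clonotype set by membership in a comparison pool and
    contrast CDR3-length distributions and V-family usage.

    Each unique clonotype counts once.  An empty partition side yields a
    one-sided result (``None`` length summary, empty usage dict).
    """
    q, p = _as_set(query), _as_set(pool)
    if not q:
        raise ValueError("empty query set")
    shared = sorted(q & p)
    unshared = sorted(q - p)

    def lengths(keys):
        if not keys:
            return None
        vals = np.array([len(k[2]) for k in keys], dtype=float)
        return _weighted_summary(vals, np.ones(len(vals)), "cdr3_length")

    return SharedUnsharedComparison(
        shared_lengths=lengths(shared), unshared_lengths=lengths(unshared),
        shared_v_family=_family_freqs(shared),
        unshared_v_family=_family_freqs(unshared),
        n_shared=len(shared), n_unshared=len(unshared))


# ---------------------------------------------------------------------------
# sequence logos
# ---------------------------------------------------------------------------

@dataclass
class PositionFrequencyMatrix:
    """Column-normalized amino-acid frequencies for fixed-length CDR3s."""

    length: int
    matrix: pd.DataFrame          # rows = AA_ORDER, columns = positions
    categories: dict[str, str]    # aa -> category name
    torso_positions: list[int]    # first t_n and last t_c positions
    n_sequences: int

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def cdr3_logo(clonotypes, length: int, t_n: int = 2, t_c: int = 2
              ) -> PositionFrequencyMatrix:
    """Position frequency matrix over the CDR3s of the given length.

    ``t_n``/``t_c`` flag the torso positions (nearest the V and J anchors);
    the head positions in between carry most junctional variability.
    """
    keys = _as_set(clonotypes)
    seqs = sorted({k[2] for k in keys if len(k[2]) == length})
    if not seqs:
        raise ValueError(f"no clonotypes with CDR3 length {length}")
    counts = np.zeros((len(AA_ORDER), length))
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for s in seqs:
        for pos, aa in enumerate(s):
            if aa in aa_index:
                counts[aa_index[aa], pos] += 1
    col_sums = counts.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    matrix = pd.DataFrame(counts / col_sums, index=list(AA_ORDER),
                          columns=range(length))
    categories = {aa: name for name, members in AA_CATEGORIES.items()
                  for aa in members}
    torso = list(range(min(t_n, length))) + \
        [p for p in range(max(length - t_c, 0), length)]
    return PositionFrequencyMatrix(length=length, matrix=matrix,
                                   categories=categories,
                                   torso_positions=sorted(set(torso)),
                                   n_sequences=len(seqs))
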