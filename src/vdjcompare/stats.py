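"""Repertoire-level summary statistics.

Gene-segment usage profiles and their z-score/hierarchical-clustering view,
pairwise usage regressions, CDR3 and insertion length distributions, D3/J6
family co-usage, cumulative long-CDRH3 curves, isotype frequencies and SHM
summaries.

All statistics operate on productive records only (non-productive records
are retained by the I/O layer but excluded here unless
``include_nonproductive=True``) and weight reads by ``duplicate_count`` by
default; ``weighted=False`` switches to unique-sequence counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy

from .records import Repertoire, gene_family

LENGTH_VARIABLES = ("cdr3_length", "n1_length", "n2_length",
                    "vj_insertion_length")


def _analysis_frame(rep: Repertoire, include_nonproductive: bool = False
                    ) -> pd.DataFrame:
    df = rep.to_frame()
    if not include_nonproductive:
        df = df[df["productive"]]
    return df


# ---------------------------------------------------------------------------
# gene usage
# ---------------------------------------------------------------------------

@dataclass
class UsageProfile:
    """Duplicate-weighted gene frequencies for one repertoire and segment."""

    label: tuple
    segment: str
    frequencies: dict[str, float]

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies, name="_".join(map(str, self.label)))


def gene_usage(rep: Repertoire, segment: str, weighted: bool = True,
               include_nonproductive: bool = False,
               collapse: str = "read") -> UsageProfile:
    """Per-gene usage frequencies (allele-stripped) for one segment.

    Genes present in the repertoire's germline reference but unobserved get
    frequency 0, so profiles from the same reference share a support.

    ``collapse="clonotype"`` counts each unique (V, J, CDR3 aa) clonotype
    once instead of weighting by reads, which removes clonal-expansion noise
    from cross-repertoire comparisons.
    """
    if segment not in ("V", "D", "J"):
        raise ValueError("segment must be V, D or J")
    if collapse not in ("read", "clonotype"):
        raise ValueError("collapse must be 'read' or 'clonotype'")
    df = _analysis_frame(rep, include_nonproductive)
    if df.empty:
        raise ValueError("no productive records")
    if collapse == "clonotype":
        df = df.drop_duplicates(subset=["v_gene", "j_gene", "cdr3_aa"])
        weighted = False
    col = {"V": "v_gene", "D": "d_gene", "J": "j_gene"}[segment]
    w = df["duplicate_count"] if weighted else pd.Series(1, index=df.index)
    counts = w.groupby(df[col]).sum()
    counts = counts[counts.index != ""]
    if counts.empty:
        raise ValueError(f"no {segment} calls present")
    freqs = (counts / counts.sum()).to_dict()
    if rep.germline_ref:
        for gene, g in rep.germline_ref.items():
            if g.segment == segment and gene not in freqs:
                freqs[gene] = 0.0
    return UsageProfile(label=rep.label, segment=segment,
                        frequencies={g: float(freqs[g]) for g in sorted(freqs)})


def usage_matrix(profiles: list[UsageProfile]) -> pd.DataFrame:
    """Genes x repertoires frequency matrix (union support, zero-filled)."""
    if not profiles:
        raise ValueError("no profiles")
    segs = {p.segment for p in profiles}
    if len(segs) > 1:
        raise ValueError(f"mixed segments: {sorted(segs)}")
    df = pd.concat([p.as_series() for p in profiles], axis=1).fillna(0.0)
    return df.sort_index()


@dataclass
class ClusterResult:
    zscores: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    col_order: list[str]
    row_order: list[str]
    col_newick: str
    row_newick: str

    def n_top_clusters(self, k: int, axis: str = "col") -> dict[str, int]:
        """Cut the dendrogram into ``k`` flat clusters; label -> cluster id."""
        linkage = self.col_linkage if axis == "col" else self.row_linkage
        labels = (list(self.zscores.columns) if axis == "col"
                  else list(self.zscores.index))
        flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        return dict(zip(labels, (int(c) for c in flat)))


def _newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def fmt(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return (f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)})"
                f":{length:.6g}")

    return fmt(tree, tree.dist) + ";"


def zscore_and_cluster(matrix: pd.DataFrame,
                       linkage_method: str = "average") -> ClusterResult:
    """Row-wise z-scoring plus Euclidean hierarchical clustering.

    Rows (genes) are z-scored with the population (n-denominator) standard
    deviation; zero-variance rows map to all-zeros.  Rows and columns are
    clustered with the given linkage on Euclidean distance; labels are
    pre-sorted lexicographically so distance ties resolve reproducibly.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 repertoire columns to cluster")
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    z = matrix.sub(mean, axis=0).div(sd.replace(0.0, np.inf), axis=0)
    col_link = hierarchy.linkage(z.T.values, method=linkage_method,
                                 metric="euclidean")
    row_link = hierarchy.linkage(z.values, method=linkage_method,
                                 metric="euclidean")
    col_labels = list(z.columns)
    row_labels = list(z.index)
    col_order = [col_labels[i] for i in hierarchy.leaves_list(col_link)]
    row_order = [row_labels[i] for i in hierarchy.leaves_list(row_link)]
    return ClusterResult(zscores=z, row_linkage=row_link, col_linkage=col_link,
                         col_order=col_order, row_order=row_order,
                         col_newick=_newick(col_link, col_labels),
                         row_newick=_newick(row_link, row_labels))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_genes: int


def usage_regression(a: UsageProfile, b: UsageProfile) -> RegressionResult:
    """OLS of b's gene frequencies on a's over their shared gene support.

    Frequencies are renormalized over the intersection of supports, so
    profiles from different germline sets remain comparable.
    """
    if a.segment != b.segment:
        raise ValueError("profiles must be for the same segment")
    shared = sorted(set(a.frequencies) & set(b.frequencies))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    x = np.array([a.frequencies[g] for g in shared])
    y = np.array([b.frequencies[g] for g in shared])
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("zero total frequency over shared support")
    x, y = x / x.sum(), y / y.sum()
    fit = sstats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            n_genes=len(shared))


# ---------------------------------------------------------------------------
# length distributions
# ---------------------------------------------------------------------------

@dataclass
class DistributionSummary:
    """Normalized integer-support histogram with mean and SEM."""

    variable: str
    histogram: dict[int, float]
    mean: float
    sem: float
    n: float                     # total weight behind the histogram

    def tail(self) -> dict[int, float]:
        """P(X >= L) for every L in the support (monotone non-increasing,
        exactly 1 at the minimum observed value)."""
        support = sorted(self.histogram)
        out, acc = {}, 0.0
        for L in reversed(support):
            acc += self.histogram[L]
            out[L] = min(acc, 1.0)
        out[support[0]] = 1.0
        return {L: out[L] for L in support}


def _weighted_summary(values: np.ndarray, weights: np.ndarray,
                      variable: str) -> DistributionSummary:
    total = weights.sum()
    mean = float((values * weights).sum() / total)
    var = float((weights * (values - mean) ** 2).sum() / total)
    sem = float(np.sqrt(var / total))
    raw: dict[int, float] = {}
    for v, w in zip(values, weights):
        raw[int(v)] = raw.get(int(v), 0.0) + float(w)
    hist = {k: w / total for k, w in raw.items()}
    return DistributionSummary(variable=variable,
                               histogram=dict(sorted(hist.items())),
                               mean=mean, sem=sem, n=float(total))


def length_distribution(rep: Repertoire, variable: str,
                        weighted: bool = True,
                        collapse: str = "read") -> DistributionSummary:
    """Duplicate-weighted histogram of an integer length variable.

    ``collapse="clonotype"`` keeps one record per unique (V, J, CDR3 aa)
    clonotype, removing clonal-expansion weight from the distribution.
    """
    if variable not in LENGTH_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    df = _analysis_frame(rep)
    if collapse == "clonotype":
        df = df.drop_duplicates(subset=["v_gene", "j_gene", "cdr3_aa"])
        weighted = False
    vals = pd.to_numeric(df[variable], errors="coerce")
    mask = vals.notna()
    if not mask.any():
        raise ValueError(f"no non-missing values of {variable}")
    w = (df.loc[mask, "duplicate_count"].to_numpy(float) if weighted
         else np.ones(int(mask.sum())))
    return _weighted_summary(vals[mask].to_numpy(float), w, variable)


def family_pair_frequency(rep: Repertoire, d_family: str = "IGHD3",
                          j_family: str = "IGHJ6", weighted: bool = True,
                          collapse: str = "read") -> float:
    """Fraction of records whose D family and J family both match."""
    if rep.locus != "IGH":
        raise ValueError("family_pair_frequency requires an IGH repertoire")
    df = _analysis_frame(rep)
    if df.empty:
        raise ValueError("no productive records")
    if collapse == "clonotype":
        df = df.drop_duplicates(subset=["v_gene", "j_gene", "cdr3_aa"])
        weighted = False
    d_fam = df["d_gene"].map(gene_family)
    j_fam = df["j_gene"].map(gene_family)
    hit = (d_fam == d_family) & (j_fam == j_family)
    w = df["duplicate_count"].to_numpy(float) if weighted else np.ones(len(df))
    return float(w[hit.to_numpy()].sum() / w.sum())


def cdr3_tail_frequency(rep: Repertoire, weighted: bool = True
                        ) -> dict[int, float]:
    """P(CDR3 length >= L) per observed L; equals 1 at the minimum length."""
    return length_distribution(rep, "cdr3_length", weighted=weighted).tail()


def short_cdrl3_fraction(rep: Repertoire, k: int = 5,
                         weighted: bool = True) -> float:
    """Fraction of kappa records with CDRL3 of exactly ``k`` amino acids."""
    if rep.locus != "IGK":
        raise ValueError("short_cdrl3_fraction requires an IGK repertoire")
    dist = length_distribution(rep, "cdr3_length", weighted=weighted)
    return float(dist.histogram.get(k, 0.0))


# ---------------------------------------------------------------------------
# isotype and SHM
# ---------------------------------------------------------------------------

def isotype_frequencies(rep: Repertoire, weighted: bool = True,
                        include_nonproductive: bool = False
                        ) -> dict[str, float]:
    """Frequencies over {IgM, IgG, unknown}, summing to 1.

    ``include_nonproductive=True`` counts every read; isotype is a property
    of the transcript, not of junction productivity.
    """
    if rep.locus != "IGH":
        raise ValueError("isotypes apply to IGH repertoires")
    df = _analysis_frame(rep, include_nonproductive)
    if df.empty:
        raise ValueError("no productive records with isotype labels")
    w = df["duplicate_count"] if weighted else pd.Series(1, index=df.index)
    totals = w.groupby(df["isotype"]).sum()
    out = {iso: float(totals.get(iso, 0.0) / totals.sum())
           for iso in ("IgM", "IgG", "unknown")}
    return out


@dataclass(frozen=True)
class GroupMean:
    mean: float
    sem: float
    n: float
    single_member: bool = False


def mutation_summary(rep: Repertoire, by: str = "isotype",
                     weighted: bool = True,
                     include_nonproductive: bool = False
                     ) -> dict[str, GroupMean]:
    """Mean V-region mutation count per group (isotype) with SEM.

    Empty groups are omitted; single-record groups report SEM 0 with the
    ``single_member`` flag set.  ``include_nonproductive=True`` averages over
    all reads, which is the unbiased view of the mutation load itself
    (productivity selects weakly against junction-breaking mutations).
    """
    if by != "isotype":
        raise ValueError("only grouping by isotype is supported")
    df = _analysis_frame(rep, include_nonproductive)
    if df.empty:
        raise ValueError("no productive records")
    out: dict[str, GroupMean] = {}
    for iso, grp in df.groupby("isotype"):
        vals = grp["v_mutation_count"].to_numpy(float)
        w = (grp["duplicate_count"].to_numpy(float) if weighted
             else np.ones(len(grp)))
        total = w.sum()
        mean = float((vals * w).sum() / total)
        if len(vals) < 2:
            out[str(iso)] = GroupMean(mean, 0.0, float(total), True)
            continue
        var = float((w * (vals - mean) ** 2).sum() / total)
        out[str(iso)] = GroupMean(mean, float(np.sqrt(var / total)),
                                  float(total))
    return out
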