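"""Synthetic V(D)J repertoire generation with known ground truth.

The simulator draws recombination scenarios from a
:class:`~vdjcompare.model.RecombinationModel` (heavy chain) or
:class:`KappaModel` (kappa chain), assembles nucleotide sequences, and builds
two-tissue repertoires with clonal structure, isotype mixture and somatic
hypermutation, so that every downstream statistic can be checked against the
generating truth.

Species presets
---------------
``human_like`` and ``omnirat_like`` share one packaged toy germline set
(12 V, 9 D, 6 J heavy; 10 V, 5 J kappa) and differ only in their event
distributions, emulating the contrasts reported for humanized-rat versus
human repertoires: the rat-like preset draws shorter N insertions, favours
short D genes, uses the D3-family/J6 pair less often, produces shorter
CDRH3s, rarely makes 5-aa CDRL3s, and has tissue-dependent IgG fractions
(lymph node 0.15, spleen 0.003) with lower SHM than the human-like preset.

Randomness: one root seed; each subsystem (clone rearrangements, compartment
assignment, read sampling, isotype, SHM) gets an independent stream derived
from the root seed and a fixed subsystem index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Union

import numpy as np
from scipy import stats as sstats

from .io import packaged_germline_path, read_germline_fasta
from .model import RecombinationModel
from .records import (GermlineGene, Repertoire, SequenceRecord, translate_nt)

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_NT = np.array(list("ACGT"))
#: P-nucleotide length distribution at an untrimmed coding end (<=2 nt).
P_LEN_PROBS = (0.5, 0.3, 0.2)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# distribution builders
# ---------------------------------------------------------------------------

def truncated_geometric(mean: float, kmax: int) -> np.ndarray:
    """Geometric pmf on 0..kmax (ratio mean/(mean+1)), renormalized."""
    if mean < 0:
        raise ValueError("mean must be >= 0")
    if mean == 0:
        out = np.zeros(kmax + 1)
        out[0] = 1.0
        return out
    q = mean / (mean + 1.0)
    pmf = (1 - q) * q ** np.arange(kmax + 1)
    return pmf / pmf.sum()


def nbinom_lengths(mean: float, kmax: int, r: float = 4.0) -> np.ndarray:
    """Negative-binomial pmf on 0..kmax — a peaked, over-dispersed length
    law used for N-insertion lengths."""
    if mean <= 0:
        out = np.zeros(kmax + 1)
        out[0] = 1.0
        return out
    p = r / (r + mean)
    pmf = sstats.nbinom.pmf(np.arange(kmax + 1), r, p)
    return pmf / pmf.sum()


def insertion_lengths(mean: float, kmax: int, zero_weight: float = 0.0,
                      r: float = 4.0) -> np.ndarray:
    """N-insertion length law: a zero-inflated negative binomial.

    The point mass at zero models TdT-independent junctions; these
    insertion-free rearrangements carry most of the convergent
    ("public") clonotype probability.  ``mean`` is the overall mean, so the
    negative-binomial component has mean ``mean / (1 - zero_weight)``.
    """
    if not 0 <= zero_weight < 1:
        raise ValueError("zero_weight must lie in [0, 1)")
    body = nbinom_lengths(mean / (1 - zero_weight), kmax, r=r)
    out = (1 - zero_weight) * body
    out[0] += zero_weight
    return out / out.sum()


def point_mass(k: int, kmax: int) -> np.ndarray:
    out = np.zeros(kmax + 1)
    out[k] = 1.0
    return out


# ---------------------------------------------------------------------------
# kappa-chain model (no D segment; single VJ insertion)
# ---------------------------------------------------------------------------

@dataclass
class KappaModel:
    """Light-chain analogue of the heavy-chain recombination model."""

    v_genes: list[str]
    j_genes: list[str]
    p_v: np.ndarray
    p_j: np.ndarray
    p_v_trim: np.ndarray               # (nV, vt_max+1)
    p_j_trim: np.ndarray               # (nJ, jt_max+1)
    p_ins: np.ndarray                  # VJ insertion length
    ins_init: np.ndarray
    ins_trans: np.ndarray
    germline: dict[str, GermlineGene]
    v_anchor: dict[str, int]           # Cys codon start in V
    j_anchor: dict[str, int]           # Phe codon start in J
    locus: str = "IGK"
    use_p_nucleotides: bool = True
    name: str = ""

    def validate(self) -> None:
        for label, total in ([("p_v", self.p_v.sum()), ("p_j", self.p_j.sum()),
                              ("p_ins", self.p_ins.sum())]
                             + [(f"p_v_trim[{g}]", r.sum()) for g, r
                                in zip(self.v_genes, self.p_v_trim)]
                             + [(f"p_j_trim[{g}]", r.sum()) for g, r
                                in zip(self.j_genes, self.p_j_trim)]):
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} sums to {total!r}, not 1")


AnyModel = Union[RecombinationModel, KappaModel]


# ---------------------------------------------------------------------------
# simulator configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulatorConfig:
    """Knobs of a two-compartment repertoire simulation."""

    species_preset: Union[str, AnyModel] = "omnirat_like"
    n_clones: int = 5000
    n_reads_per_compartment: int = 5000
    clone_abundance_exponent: float = 2.0      # Zipf alpha > 1
    tissue_overlap_prob: float = 0.05
    shm_rate_igm: float = 2.0                  # Poisson mean nt mutations
    shm_rate_igg: float = 10.0
    igg_fraction_by_tissue: dict = dc_field(
        default_factory=lambda: {"lymph_node": 0.15, "spleen": 0.003})
    seed: int = 0
    locus: str = "IGH"
    subject_id: str = "sim"
    species: str = ""

    def validate(self) -> None:
        if self.n_clones < 1 or self.n_reads_per_compartment < 1:
            raise ValueError("n_clones and n_reads_per_compartment must be >= 1")
        if self.clone_abundance_exponent <= 1:
            raise ValueError("clone_abundance_exponent must be > 1")
        probs = [self.tissue_overlap_prob, *self.igg_fraction_by_tissue.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.shm_rate_igm < 0 or self.shm_rate_igg < 0:
            raise ValueError("SHM rates must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated study."""

    model: AnyModel
    config: SimulatorConfig
    clone_keys: dict[str, tuple]       # clone_id -> (v_gene, j_gene, cdr3_aa)
    clone_compartments: dict[str, tuple]
    clone_sizes: dict[str, int]
    clone_productive: dict[str, bool]

    def true_clonotype_keys(self, productive_only: bool = True) -> set:
        return {k for cid, k in self.clone_keys.items()
                if not productive_only or self.clone_productive[cid]}

    def key_collision_count(self) -> int:
        """Number of extra clones hidden by clonotype-key collisions."""
        keys = list(self.clone_keys.values())
        return len(keys) - len(set(keys))

    def cross_tissue_collisions(self) -> int:
        """Pairs of distinct single-compartment clones in different tissues
        that share a clonotype key (upper bound on spurious Q2)."""
        by_key: dict[tuple, set] = {}
        for cid, key in self.clone_keys.items():
            by_key.setdefault(key, set()).update(self.clone_compartments[cid])
        return sum(1 for tissues in by_key.values() if len(tissues) > 1)


# ---------------------------------------------------------------------------
# single-rearrangement sampling
# ---------------------------------------------------------------------------

def _cond_draw(rng, gene_idx: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Per-record draw from a row-conditional distribution table."""
    out = np.zeros(len(gene_idx), dtype=int)
    flat = np.arange(table.shape[1] if table.ndim == 2 else
                     table.shape[1] * table.shape[2])
    for g in np.unique(gene_idx):
        mask = gene_idx == g
        probs = table[g].ravel()
        out[mask] = rng.choice(flat, size=mask.sum(), p=probs)
    return out


def _markov_string(rng, length: int, init_cum: np.ndarray,
                   trans_cum: np.ndarray) -> str:
    if length == 0:
        return ""
    us = rng.random(length)
    idx = int(np.searchsorted(init_cum, us[0]))
    chars = [idx]
    for k in range(1, length):
        idx = int(np.searchsorted(trans_cum[idx], us[k]))
        chars.append(idx)
    return "".join("ACGT"[i] for i in chars)


def _p_nt(rng, enabled: bool, trim: int) -> int:
    """P-nucleotide length: only possible at an untrimmed coding end."""
    if not enabled or trim != 0:
        return 0
    return int(rng.choice(3, p=P_LEN_PROBS))


def simulate_rearrangements(model: AnyModel, n: int,
                            rng: np.random.Generator) -> list[SequenceRecord]:
    """Draw ``n`` independent rearrangements (no SHM, duplicate_count 1)."""
    if isinstance(model, RecombinationModel):
        model.validate()
        return _simulate_igh(model, n, rng)
    model.validate()
    return _simulate_igk(model, n, rng)


def simulate_rearrangement(model: AnyModel, rng: np.random.Generator
                           ) -> tuple[SequenceRecord, dict]:
    """One rearrangement plus its chosen-event dictionary."""
    rec = simulate_rearrangements(model, 1, rng)[0]
    events = {"v_gene": rec.v_gene, "d_gene": rec.d_gene or None,
              "j_gene": rec.j_gene, "v_trim3": rec.v_trim3,
              "d_trim5": rec.d_trim5, "d_trim3": rec.d_trim3,
              "j_trim5": rec.j_trim5, "n1_length": rec.n1_length,
              "n2_length": rec.n2_length,
              "vj_insertion_length": rec.vj_insertion_length}
    return rec, events


def _finish(seq_parts: list[str], junction: str) -> tuple[str, str, bool]:
    junction_aa = translate_nt(junction)
    in_frame = len(junction) % 3 == 0
    productive = (in_frame and len(junction_aa) >= 2
                  and junction_aa.startswith("C")
                  and junction_aa[-1] in "WF"
                  and "*" not in junction_aa)
    return junction_aa, "".join(seq_parts), productive


def _simulate_igh(model: RecombinationModel, n: int,
                  rng: np.random.Generator) -> list[SequenceRecord]:
    nV, nD, nJ = len(model.v_genes), len(model.d_genes), len(model.j_genes)
    v_idx = rng.choice(nV, size=n, p=model.p_v)
    dj = rng.choice(nD * nJ, size=n, p=model.p_dj.ravel())
    d_idx, j_idx = dj // nJ, dj % nJ
    vt = _cond_draw(rng, v_idx, model.p_v_trim)
    dt_flat = _cond_draw(rng, d_idx, model.p_d_trim)
    n3 = model.p_d_trim.shape[2]
    dt5, dt3 = dt_flat // n3, dt_flat % n3
    jt = _cond_draw(rng, j_idx, model.p_j_trim)
    n1 = rng.choice(model.p_n1.size, size=n, p=model.p_n1)
    n2 = rng.choice(model.p_n2.size, size=n, p=model.p_n2)

    init_cum = np.cumsum(model.ins_init)
    trans_cum = np.cumsum(model.ins_trans, axis=1)
    v_seqs = [model.germline[g].sequence for g in model.v_genes]
    d_seqs = [model.germline[g].sequence for g in model.d_genes]
    j_seqs = [model.germline[g].sequence for g in model.j_genes]
    v_anchor = [model.v_anchor[g] for g in model.v_genes]
    j_anchor = [model.j_anchor[g] for g in model.j_genes]

    records = []
    pn = model.use_p_nucleotides
    for i in range(n):
        V, D, J = v_seqs[v_idx[i]], d_seqs[d_idx[i]], j_seqs[j_idx[i]]
        v_end = len(V) - vt[i]
        d_kept = D[dt5[i]: len(D) - dt3[i]]
        j_start = jt[i]
        p_v = _revcomp(V[v_end - _p_nt(rng, pn, vt[i]):] or "") if vt[i] == 0 else ""
        p_d5 = _revcomp(d_kept[: _p_nt(rng, pn, dt5[i])]) if dt5[i] == 0 and d_kept else ""
        p_d3 = _revcomp(d_kept[len(d_kept) - _p_nt(rng, pn, dt3[i]):] or "") if dt3[i] == 0 and d_kept else ""
        p_j = _revcomp(J[j_start: j_start + _p_nt(rng, pn, jt[i])]) if jt[i] == 0 else ""
        ins1 = _markov_string(rng, int(n1[i]), init_cum, trans_cum)
        ins2 = _markov_string(rng, int(n2[i]), init_cum, trans_cum)

        mid = p_v + ins1 + p_d5 + d_kept + p_d3 + ins2 + p_j
        anchor = v_anchor[v_idx[i]]
        wpos = j_anchor[j_idx[i]]
        junction = V[anchor:v_end] + mid + J[j_start: wpos + 3]
        sequence = V[:v_end] + mid + J[j_start:]
        junction_aa, sequence, productive = _finish([sequence], junction)
        records.append(SequenceRecord(
            sequence_id=f"sim{i:08d}",
            v_call=model.germline[model.v_genes[v_idx[i]]].name,
            d_call=model.germline[model.d_genes[d_idx[i]]].name,
            j_call=model.germline[model.j_genes[j_idx[i]]].name,
            junction_aa=junction_aa, junction=junction, sequence=sequence,
            locus="IGH", v_trim3=int(vt[i]), d_trim5=int(dt5[i]),
            d_trim3=int(dt3[i]), j_trim5=int(jt[i]),
            n1_length=int(n1[i]), n2_length=int(n2[i]),
            productive=productive,
            v_sequence_end=v_end, junction_start=anchor))
    return records


def _simulate_igk(model: KappaModel, n: int,
                  rng: np.random.Generator) -> list[SequenceRecord]:
    nV, nJ = len(model.v_genes), len(model.j_genes)
    v_idx = rng.choice(nV, size=n, p=model.p_v)
    j_idx = rng.choice(nJ, size=n, p=model.p_j)
    vt = _cond_draw(rng, v_idx, model.p_v_trim)
    jt = _cond_draw(rng, j_idx, model.p_j_trim)
    ins = rng.choice(model.p_ins.size, size=n, p=model.p_ins)
    init_cum = np.cumsum(model.ins_init)
    trans_cum = np.cumsum(model.ins_trans, axis=1)

    records = []
    pn = model.use_p_nucleotides
    for i in range(n):
        V = model.germline[model.v_genes[v_idx[i]]].sequence
        J = model.germline[model.j_genes[j_idx[i]]].sequence
        v_end = len(V) - vt[i]
        p_v = _revcomp(V[v_end - _p_nt(rng, pn, vt[i]):] or "") if vt[i] == 0 else ""
        p_j = _revcomp(J[jt[i]: jt[i] + _p_nt(rng, pn, jt[i])]) if jt[i] == 0 else ""
        mid = p_v + _markov_string(rng, int(ins[i]), init_cum, trans_cum) + p_j
        anchor = model.v_anchor[model.v_genes[v_idx[i]]]
        fpos = model.j_anchor[model.j_genes[j_idx[i]]]
        junction = V[anchor:v_end] + mid + J[jt[i]: fpos + 3]
        sequence = V[:v_end] + mid + J[jt[i]:]
        junction_aa, sequence, productive = _finish([sequence], junction)
        records.append(SequenceRecord(
            sequence_id=f"sim{i:08d}",
            v_call=model.germline[model.v_genes[v_idx[i]]].name,
            d_call=None,
            j_call=model.germline[model.j_genes[j_idx[i]]].name,
            junction_aa=junction_aa, junction=junction, sequence=sequence,
            locus="IGK", v_trim3=int(vt[i]), j_trim5=int(jt[i]),
            vj_insertion_length=int(ins[i]), productive=productive,
            v_sequence_end=v_end, junction_start=anchor))
    return records


# ---------------------------------------------------------------------------
# somatic hypermutation
# ---------------------------------------------------------------------------

def apply_shm(record: SequenceRecord, mean_mutations: float,
              rng: np.random.Generator) -> SequenceRecord:
    """Poisson(mean) point substitutions, uniform over the V region.

    Positions inside the junction may mutate; the junction, CDR3 and
    productive flag are recomputed.  A draw exceeding the V-region length is
    capped (with a warning).  Returns a new record.
    """
    if mean_mutations < 0:
        raise ValueError("mean_mutations must be >= 0")
    if record.v_sequence_end is None:
        raise ValueError("record lacks v_sequence_end; cannot place mutations")
    m = int(rng.poisson(mean_mutations)) if mean_mutations > 0 else 0
    v_len = record.v_sequence_end
    if m > v_len:
        log.warning("SHM draw %d exceeds V length %d; capping", m, v_len)
        m = v_len
    if m == 0:
        return replace(record, v_mutation_count=0)
    seq = list(record.sequence)
    positions = rng.choice(v_len, size=m, replace=False)
    for pos in positions:
        current = seq[pos]
        options = [nt for nt in "ACGT" if nt != current]
        seq[pos] = options[int(rng.integers(3))]
    sequence = "".join(seq)
    jstart = record.junction_start or 0
    junction = sequence[jstart: jstart + len(record.junction)]
    junction_aa = translate_nt(junction)
    in_frame = len(junction) % 3 == 0
    productive = (in_frame and len(junction_aa) >= 2
                  and junction_aa.startswith("C") and junction_aa[-1] in "WF"
                  and "*" not in junction_aa)
    return replace(record, sequence=sequence, junction=junction,
                   junction_aa=junction_aa, productive=productive,
                   v_mutation_count=m)


# ---------------------------------------------------------------------------
# two-compartment repertoire simulation
# ---------------------------------------------------------------------------

def _resolve_model(config: SimulatorConfig) -> AnyModel:
    if isinstance(config.species_preset, (RecombinationModel, KappaModel)):
        return config.species_preset
    model, _ = species_preset(config.species_preset, locus=config.locus)
    return model


def simulate_repertoire(config: SimulatorConfig
                        ) -> tuple[Repertoire, Repertoire, SimulationTruth]:
    """Simulate a (lymph node, spleen) repertoire pair with clonal truth.

    Each of ``n_clones`` clones is one independent rearrangement; a clone is
    seeded in both compartments with probability ``tissue_overlap_prob``,
    otherwise in one chosen uniformly.  Clone sizes follow a Zipf law with
    exponent ``clone_abundance_exponent``; reads are sampled per compartment
    in proportion to clone size, then isotype and SHM are applied per read.
    """
    config.validate()
    model = _resolve_model(config)
    seed = int(config.seed)
    rng_clone = np.random.default_rng([seed, 1])
    rng_assign = np.random.default_rng([seed, 2])
    rng_sample = np.random.default_rng([seed, 3])
    rng_isotype = np.random.default_rng([seed, 4])
    rng_shm = np.random.default_rng([seed, 5])

    templates = simulate_rearrangements(model, config.n_clones, rng_clone)
    clone_ids = [f"{config.subject_id}_clone{i:07d}"
                 for i in range(config.n_clones)]

    both = rng_assign.random(config.n_clones) < config.tissue_overlap_prob
    side = rng_assign.random(config.n_clones) < 0.5
    compartments = []
    for i in range(config.n_clones):
        if both[i]:
            compartments.append(("lymph_node", "spleen"))
        else:
            compartments.append(("lymph_node",) if side[i] else ("spleen",))

    sizes = np.minimum(rng_assign.zipf(config.clone_abundance_exponent,
                                       size=config.n_clones), 100_000)

    truth = SimulationTruth(
        model=model, config=config,
        clone_keys={cid: (t.v_gene, t.j_gene, t.cdr3_aa)
                    for cid, t in zip(clone_ids, templates)},
        clone_compartments=dict(zip(clone_ids, compartments)),
        clone_sizes={cid: int(s) for cid, s in zip(clone_ids, sizes)},
        clone_productive={cid: t.productive
                          for cid, t in zip(clone_ids, templates)})

    reps = {}
    for tissue in ("lymph_node", "spleen"):
        present = np.array([tissue in c for c in compartments])
        weights = sizes * present
        if weights.sum() == 0:
            raise ValueError(f"no clones seeded in {tissue}")
        probs = weights / weights.sum()
        counts = rng_sample.multinomial(config.n_reads_per_compartment, probs)
        igg_p = config.igg_fraction_by_tissue.get(tissue, 0.0)
        records = []
        read_no = 0
        for ci in np.nonzero(counts)[0]:
            template = templates[ci]
            for _ in range(int(counts[ci])):
                isotype = ("IgG" if config.locus == "IGH"
                           and rng_isotype.random() < igg_p else
                           ("IgM" if config.locus == "IGH" else "unknown"))
                rate = (config.shm_rate_igg if isotype == "IgG"
                        else config.shm_rate_igm)
                rec = apply_shm(template, rate, rng_shm)
                rec = replace(
                    rec,
                    sequence_id=f"{config.subject_id}_{tissue}_{read_no:07d}",
                    subject_id=config.subject_id, species=config.species,
                    tissue=tissue, isotype=isotype,
                    clone_id=clone_ids[ci], duplicate_count=1)
                records.append(rec)
                read_no += 1
        reps[tissue] = Repertoire(records, config.subject_id, tissue,
                                  config.locus,
                                  germline_ref=getattr(model, "germline", None))
    return reps["lymph_node"], reps["spleen"], truth


# ---------------------------------------------------------------------------
# species presets
# ---------------------------------------------------------------------------

_IGH_V_ANCHOR_TAIL = 11    # toy V genes end with Cys codon + 8 trimmable nt
_IGH_J_SUFFIX = 34         # Trp codon + 31 nt constant-side suffix
_IGK_V_ANCHOR_TAIL = 24    # Cys codon + 21 nt (CQQYNSYP)
_IGK_J_SUFFIX = 31         # Phe codon + 28 nt suffix

#: Per-preset event parameters.  Choice vectors are over the packaged toy
#: gene sets (ordered as in the FASTA); trim/insertion means in nt.
_IGH_PRESETS = {
    "human_like": {
        "p_v": [0.080, 0.060, 0.050, 0.090, 0.120, 0.070,
                0.130, 0.060, 0.090, 0.110, 0.080, 0.060],
        # D choice favours the long D2/D3/D4 segments
        "p_d": [0.05, 0.15, 0.10, 0.10, 0.08, 0.15, 0.13, 0.12, 0.12],
        "p_j": [0.130, 0.140, 0.150, 0.270, 0.175, 0.135],
        "v_trim_mean": 1.5, "d5_trim_mean": 1.5, "d3_trim_mean": 1.5,
        "j_trim_mean": 2.0, "ins_mean": 6.0, "ins_zero_weight": 0.10,
    },
    "omnirat_like": {
        "p_v": [0.050, 0.110, 0.080, 0.060, 0.070, 0.130,
                0.060, 0.120, 0.050, 0.080, 0.110, 0.080],
        # D choice favours the short D1/D5/D6/D7 segments
        "p_d": [0.20, 0.08, 0.04, 0.04, 0.04, 0.14, 0.12, 0.18, 0.16],
        "p_j": [0.150, 0.150, 0.170, 0.230, 0.165, 0.135],
        "v_trim_mean": 2.0, "d5_trim_mean": 1.5, "d3_trim_mean": 2.5,
        "j_trim_mean": 2.0, "ins_mean": 4.0, "ins_zero_weight": 0.20,
    },
}

_IGK_PRESETS = {
    "human_like": {
        "p_v": [0.13, 0.09, 0.12, 0.08, 0.07, 0.10, 0.11, 0.14, 0.09, 0.07],
        "p_j": [0.26, 0.22, 0.14, 0.22, 0.16],
        "v_trim_mean": 2.0, "v_trim_tail": 0.04,   # deep-trim mixture weight
        "j_trim_mean": 1.5, "ins_mean": 2.5, "ins_zero_weight": 0.10,
    },
    "omnirat_like": {
        "p_v": [0.08, 0.12, 0.09, 0.11, 0.10, 0.12, 0.08, 0.10, 0.11, 0.09],
        "p_j": [0.24, 0.20, 0.16, 0.24, 0.16],
        "v_trim_mean": 1.0, "v_trim_tail": 0.0,
        "j_trim_mean": 1.5, "ins_mean": 0.8, "ins_zero_weight": 0.20,
    },
}

_INS_INIT = np.array([0.20, 0.30, 0.30, 0.20])
_INS_TRANS = np.array([[0.22, 0.28, 0.30, 0.20],
                       [0.18, 0.32, 0.30, 0.20],
                       [0.20, 0.28, 0.34, 0.18],
                       [0.20, 0.30, 0.28, 0.22]])

V_TRIM_MAX, D_TRIM_MAX, J_TRIM_MAX, INS_MAX = 8, 10, 12, 24
K_V_TRIM_MAX, K_J_TRIM_MAX, K_INS_MAX = 12, 6, 10


def _d_trim_joint(gene_len: int, mean5: float, mean3: float) -> np.ndarray:
    """Independent truncated-geometric 5'/3' trims restricted to
    d5 + d3 <= gene length, renormalized."""
    p5 = truncated_geometric(mean5, D_TRIM_MAX)
    p3 = truncated_geometric(mean3, D_TRIM_MAX)
    joint = np.outer(p5, p3)
    for a in range(D_TRIM_MAX + 1):
        for b in range(D_TRIM_MAX + 1):
            if a + b > gene_len:
                joint[a, b] = 0.0
    return joint / joint.sum()


def build_igh_model(p_v, p_d, p_j, v_trim_mean, d5_trim_mean, d3_trim_mean,
                    j_trim_mean, ins_mean, ins_zero_weight=0.0, name="",
                    p_dj=None, use_p_nucleotides=True) -> RecombinationModel:
    """Assemble a heavy-chain model over the packaged toy IGH germline."""
    genes = read_germline_fasta(packaged_germline_path("igh_toy"), segment="V")
    by_seg = {"V": [], "D": [], "J": []}
    for g in genes:
        seg = ("V" if "IGHV" in g.name else
               "D" if "IGHD" in g.name else "J")
        by_seg[seg].append(GermlineGene(g.name, g.sequence, seg, "IGH",
                                        g.species_tag))
    vs, ds, js = by_seg["V"], by_seg["D"], by_seg["J"]
    germline = {g.gene: g for g in vs + ds + js}
    p_v = np.asarray(p_v, dtype=float)
    if p_dj is None:
        p_dj = np.outer(np.asarray(p_d, float), np.asarray(p_j, float))
    p_dj = np.asarray(p_dj, dtype=float)
    p_dj = p_dj / p_dj.sum()
    model = RecombinationModel(
        v_genes=[g.gene for g in vs], d_genes=[g.gene for g in ds],
        j_genes=[g.gene for g in js],
        p_v=p_v / p_v.sum(), p_dj=p_dj,
        p_v_trim=np.tile(truncated_geometric(v_trim_mean, V_TRIM_MAX),
                         (len(vs), 1)),
        p_d_trim=np.stack([_d_trim_joint(len(g), d5_trim_mean, d3_trim_mean)
                           for g in ds]),
        p_j_trim=np.tile(truncated_geometric(j_trim_mean, J_TRIM_MAX),
                         (len(js), 1)),
        p_n1=insertion_lengths(ins_mean, INS_MAX, ins_zero_weight),
        p_n2=insertion_lengths(ins_mean, INS_MAX, ins_zero_weight),
        ins_init=_INS_INIT.copy(), ins_trans=_INS_TRANS.copy(),
        germline=germline,
        v_anchor={g.gene: len(g) - _IGH_V_ANCHOR_TAIL for g in vs},
        j_anchor={g.gene: len(g) - _IGH_J_SUFFIX for g in js},
        locus="IGH", use_p_nucleotides=use_p_nucleotides, name=name)
    model.validate()
    return model


def _build_igk_model(params: dict, name: str) -> KappaModel:
    genes = read_germline_fasta(packaged_germline_path("igk_toy"), segment="V",
                                locus="IGK")
    vs = [GermlineGene(g.name, g.sequence, "V", "IGK") for g in genes
          if "IGKV" in g.name]
    js = [GermlineGene(g.name, g.sequence, "J", "IGK") for g in genes
          if "IGKJ" in g.name]
    germline = {g.gene: g for g in vs + js}
    vt = truncated_geometric(params["v_trim_mean"], K_V_TRIM_MAX)
    tail_w = params.get("v_trim_tail", 0.0)
    if tail_w > 0:
        # heavy-trim tail: extra mass spread over deep 3' trims (7..12 nt),
        # the route to rare very short CDRL3s
        deep = np.zeros(K_V_TRIM_MAX + 1)
        deep[7:] = 1.0 / (K_V_TRIM_MAX - 6)
        vt = (1 - tail_w) * vt + tail_w * deep
    p_v = np.asarray(params["p_v"], float)
    p_j = np.asarray(params["p_j"], float)
    model = KappaModel(
        v_genes=[g.gene for g in vs], j_genes=[g.gene for g in js],
        p_v=p_v / p_v.sum(), p_j=p_j / p_j.sum(),
        p_v_trim=np.tile(vt, (len(vs), 1)),
        p_j_trim=np.tile(truncated_geometric(params["j_trim_mean"],
                                             K_J_TRIM_MAX), (len(js), 1)),
        p_ins=insertion_lengths(params["ins_mean"], K_INS_MAX,
                                params.get("ins_zero_weight", 0.0)),
        ins_init=_INS_INIT.copy(), ins_trans=_INS_TRANS.copy(),
        germline=germline,
        v_anchor={g.gene: len(g) - _IGK_V_ANCHOR_TAIL for g in vs},
        j_anchor={g.gene: len(g) - _IGK_J_SUFFIX for g in js},
        name=name)
    model.validate()
    return model


def species_preset(name: str, locus: str = "IGH"
                   ) -> tuple[AnyModel, SimulatorConfig]:
    """Packaged toy model + simulator defaults for a species-like preset."""
    if name not in ("human_like", "omnirat_like"):
        raise ValueError(f"unknown preset {name!r}")
    if locus == "IGH":
        model: AnyModel = build_igh_model(name=name, **_IGH_PRESETS[name])
    elif locus == "IGK":
        model = _build_igk_model(_IGK_PRESETS[name], name)
    else:
        raise ValueError(f"unknown locus {locus!r}")
    if name == "human_like":
        config = SimulatorConfig(
            species_preset=model, locus=locus, species="human_like",
            shm_rate_igm=4.0, shm_rate_igg=20.0,
            igg_fraction_by_tissue={"lymph_node": 0.16, "spleen": 0.16,
                                    "pooled": 0.16})
    else:
        config = SimulatorConfig(
            species_preset=model, locus=locus, species="omnirat_like",
            shm_rate_igm=2.0, shm_rate_igg=10.0,
            igg_fraction_by_tissue={"lymph_node": 0.15, "spleen": 0.003,
                                    "pooled": 0.08})
    return model, config
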