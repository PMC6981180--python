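"""Canonical record model for annotated immunoglobulin rearrangements.

Every other module consumes these containers: :class:`GermlineGene` for
reference gene segments, :class:`SequenceRecord` for one annotated
rearrangement (heavy or kappa chain) and :class:`Repertoire` for an ordered
collection of records from one (subject, tissue, locus).

Conventions
-----------
* ``junction_aa`` includes the two anchor residues (Cys ... Trp/Phe, IMGT);
  ``cdr3_aa`` excludes them, so ``cdr3_length = len(junction_aa) - 2``.
* Gene calls are kept verbatim (``v_call`` etc.); the allele-stripped form
  (``IGHV4-34*01`` -> ``IGHV4-34``) is derived once and used by all analyses.
* CDR3 lengths are in amino acids; insertion/trim lengths in nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Optional

import pandas as pd

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

VALID_NT = frozenset("ACGT")
TISSUES = ("lymph_node", "spleen", "pooled")
ISOTYPES = ("IgM", "IgG", "unknown")


def translate_nt(seq: str) -> str:
    """Translate a nucleotide string codon-by-codon (trailing partial codon
    dropped, unknown codons become ``X``)."""
    n = len(seq) - len(seq) % 3
    return "".join(CODON_TABLE.get(seq[i:i + 3], "X") for i in range(0, n, 3))


def strip_allele(call: str) -> str:
    """Drop the IMGT allele suffix: ``IGHV4-34*01`` -> ``IGHV4-34``."""
    return call.split("*", 1)[0] if call else ""


def gene_family(gene: str) -> str:
    """Family = gene name up to the first hyphen (``IGHD3-10`` -> ``IGHD3``).

    Genes without a position token (``IGHJ6``) are their own family.
    """
    return strip_allele(gene).split("-", 1)[0]


@dataclass(frozen=True)
class GermlineGene:
    """One germline gene segment from a reference set."""

    name: str                 # full identifier incl. allele, e.g. IGHV4-34*01
    sequence: str
    segment: str              # V, D or J
    locus: str                # IGH or IGK
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence or not set(self.sequence) <= VALID_NT:
            raise ValueError(f"{self.name}: sequence must be non-empty over ACGT")
        if self.segment not in ("V", "D", "J"):
            raise ValueError(f"{self.name}: segment must be V/D/J")
        if self.locus not in ("IGH", "IGK"):
            raise ValueError(f"{self.name}: locus must be IGH/IGK")
        if self.locus == "IGK" and self.segment == "D":
            raise ValueError(f"{self.name}: kappa locus has no D segments")

    @property
    def gene(self) -> str:
        return strip_allele(self.name)

    @property
    def family(self) -> str:
        return gene_family(self.name)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceRecord:
    """One annotated rearrangement (a read after upstream error correction)."""

    sequence_id: str
    v_call: str
    j_call: str
    junction_aa: str
    subject_id: str = ""
    species: str = ""
    tissue: str = "pooled"
    locus: str = "IGH"
    d_call: Optional[str] = None
    sequence: str = ""                 # full assembled V(D)J nt sequence
    junction: str = ""                 # junction nt (Cys codon .. W/F codon)
    isotype: str = "unknown"
    v_mutation_count: int = 0
    n1_length: Optional[int] = None    # VD insertion (IGH)
    n2_length: Optional[int] = None    # DJ insertion (IGH)
    vj_insertion_length: Optional[int] = None   # VJ insertion (IGK)
    v_trim3: int = 0
    d_trim5: Optional[int] = None
    d_trim3: Optional[int] = None
    j_trim5: int = 0
    duplicate_count: int = 1
    productive: bool = True
    clone_id: Optional[str] = None     # simulator provenance; None on real data
    v_sequence_end: Optional[int] = None   # 0-based exclusive end of V region
    junction_start: Optional[int] = None   # 0-based junction start in sequence

    @property
    def v_gene(self) -> str:
        return strip_allele(self.v_call)

    @property
    def d_gene(self) -> str:
        return strip_allele(self.d_call) if self.d_call else ""

    @property
    def j_gene(self) -> str:
        return strip_allele(self.j_call)

    @property
    def cdr3_aa(self) -> str:
        return self.junction_aa[1:-1] if len(self.junction_aa) >= 2 else ""

    @property
    def cdr3_length(self) -> Optional[int]:
        return len(self.junction_aa) - 2 if len(self.junction_aa) >= 2 else None

    def validate(self) -> None:
        """Raise ValueError on any violated record invariant."""
        if not self.sequence_id:
            raise ValueError("missing sequence_id")
        if not self.v_call or not self.j_call:
            raise ValueError("missing v_call/j_call")
        if not self.junction_aa:
            raise ValueError("missing junction_aa")
        for name in ("v_mutation_count", "v_trim3", "j_trim5"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name}")
        for name in ("n1_length", "n2_length", "vj_insertion_length",
                     "d_trim5", "d_trim3"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValueError(f"negative {name}")
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count < 1")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.isotype not in ISOTYPES:
            raise ValueError(f"unknown isotype {self.isotype!r}")
        if self.productive:
            j = self.junction_aa
            if not (j.startswith("C") and j[-1] in "WF"):
                raise ValueError("productive junction must be C...W/F")
            if "*" in self.cdr3_aa:
                raise ValueError("productive CDR3 contains a stop codon")


_RECORD_FIELDS = [f.name for f in fields(SequenceRecord)]


@dataclass
class Repertoire:
    """Ordered collection of records from one (subject, tissue, locus)."""

    records: list[SequenceRecord] = field(default_factory=list)
    subject_id: str = ""
    tissue: str = "pooled"
    locus: str = "IGH"
    germline_ref: Optional[dict[str, GermlineGene]] = None

    @property
    def label(self) -> tuple[str, str, str]:
        return (self.subject_id, self.tissue, self.locus)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def productive(self) -> "Repertoire":
        """Sub-repertoire of productive records (the default analysis input)."""
        return Repertoire([r for r in self.records if r.productive],
                          self.subject_id, self.tissue, self.locus,
                          self.germline_ref)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per record plus derived gene columns."""
        rows = {name: [getattr(r, name) for r in self.records]
                for name in _RECORD_FIELDS}
        df = pd.DataFrame(rows)
        df["v_gene"] = [r.v_gene for r in self.records]
        df["d_gene"] = [r.d_gene for r in self.records]
        df["j_gene"] = [r.j_gene for r in self.records]
        df["cdr3_aa"] = [r.cdr3_aa for r in self.records]
        df["cdr3_length"] = [r.cdr3_length for r in self.records]
        return df


def concat_repertoires(reps: Iterable[Repertoire], subject_id: str = "",
                       tissue: str = "pooled") -> Repertoire:
    reps = list(reps)
    if not reps:
        raise ValueError("no repertoires to concatenate")
    locus = reps[0].locus
    if any(r.locus != locus for r in reps):
        raise ValueError("cannot concatenate repertoires of different loci")
    records = [r for rep in reps for r in rep.records]
    return Repertoire(records, subject_id, tissue, locus, reps[0].germline_ref)
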