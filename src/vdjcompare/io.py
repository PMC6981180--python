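"""Reading and writing AIRR rearrangement tables and germline gene sets.

The rearrangement dialect is the AIRR-C v1 TSV: tab-separated, UTF-8, one
header row, one rearrangement per row.  Standard columns keep their AIRR
names (``sequence_id``, ``v_call``, ``junction_aa``, ``duplicate_count`` ...);
study-specific fields (``tissue``, ``isotype``, insertion/trim lengths) ride
along as extra columns.  Records that violate the record invariants are
dropped on read and counted, never silently kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import GermlineGene, Repertoire, SequenceRecord

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("sequence_id", "v_call", "j_call", "junction_aa")

#: Fixed column order written by :func:`write_airr`.
AIRR_COLUMNS = [
    "sequence_id", "subject_id", "species", "tissue", "locus",
    "sequence", "junction", "junction_aa", "cdr3_aa", "cdr3_length",
    "v_call", "d_call", "j_call", "v_gene", "d_gene", "j_gene",
    "isotype", "v_mutation_count",
    "n1_length", "n2_length", "vj_insertion_length",
    "v_trim3", "d_trim5", "d_trim3", "j_trim5",
    "duplicate_count", "productive", "clone_id",
    "v_sequence_end", "junction_start",
]

_INT_OPTIONAL = ("n1_length", "n2_length", "vj_insertion_length",
                 "d_trim5", "d_trim3")


class AirrFormatError(ValueError):
    """Malformed rearrangement table (e.g. a missing mandatory column)."""


def _opt_int(value) -> Optional[int]:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(float(value))


def _req_int(value, default: int = 0) -> int:
    v = _opt_int(value)
    return default if v is None else v


def read_airr(path: str | Path, locus: str = "IGH") -> Repertoire:
    """Read an AIRR rearrangement TSV into a :class:`Repertoire`.

    Rows failing the record invariants (missing junction, negative lengths,
    inconsistent productive flag ...) are dropped; the rejection tally is
    stored on the returned repertoire as ``rejected_count`` and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty and df.columns.size == 0:
        log.warning("%s: empty rearrangement file", path)
        rep = Repertoire([], locus=locus)
        rep.rejected_count = 0  # type: ignore[attr-defined]
        return rep
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise AirrFormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)}")

    records: list[SequenceRecord] = []
    rejected = 0
    subject = tissue = ""
    for row in df.to_dict("records"):
        try:
            rec = SequenceRecord(
                sequence_id=row.get("sequence_id", ""),
                subject_id=row.get("subject_id", ""),
                species=row.get("species", ""),
                tissue=row.get("tissue") or "pooled",
                locus=row.get("locus") or locus,
                v_call=row.get("v_call", ""),
                d_call=row.get("d_call") or None,
                j_call=row.get("j_call", ""),
                sequence=row.get("sequence", ""),
                junction=row.get("junction", ""),
                junction_aa=row.get("junction_aa", ""),
                isotype=row.get("isotype") or "unknown",
                v_mutation_count=_req_int(row.get("v_mutation_count")),
                n1_length=_opt_int(row.get("n1_length")),
                n2_length=_opt_int(row.get("n2_length")),
                vj_insertion_length=_opt_int(row.get("vj_insertion_length")),
                v_trim3=_req_int(row.get("v_trim3")),
                d_trim5=_opt_int(row.get("d_trim5")),
                d_trim3=_opt_int(row.get("d_trim3")),
                j_trim5=_req_int(row.get("j_trim5")),
                duplicate_count=_req_int(row.get("duplicate_count"), 1),
                productive=str(row.get("productive", "T")).upper() in ("T", "TRUE", "1"),
                clone_id=row.get("clone_id") or None,
                v_sequence_end=_opt_int(row.get("v_sequence_end")),
                junction_start=_opt_int(row.get("junction_start")),
            )
            rec.validate()
        except (ValueError, TypeError):
            rejected += 1
            continue
        records.append(rec)
        subject = subject or rec.subject_id
        tissue = tissue or rec.tissue

    if rejected:
        log.info("%s: accepted %d records, rejected %d", path, len(records), rejected)
    rep = Repertoire(records, subject_id=subject, tissue=tissue or "pooled",
                     locus=locus)
    rep.rejected_count = rejected  # type: ignore[attr-defined]
    return rep


def write_airr(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as an AIRR TSV (column order :data:`AIRR_COLUMNS`).

    Lossless for every record field: ``read_airr(write_airr(rep))`` returns
    field-identical records.
    """
    path = Path(path)
    rows = []
    for r in rep.records:
        row = {
            "sequence_id": r.sequence_id, "subject_id": r.subject_id,
            "species": r.species, "tissue": r.tissue, "locus": r.locus,
            "sequence": r.sequence, "junction": r.junction,
            "junction_aa": r.junction_aa, "cdr3_aa": r.cdr3_aa,
            "cdr3_length": "" if r.cdr3_length is None else r.cdr3_length,
            "v_call": r.v_call, "d_call": r.d_call or "",
            "j_call": r.j_call, "v_gene": r.v_gene, "d_gene": r.d_gene,
            "j_gene": r.j_gene, "isotype": r.isotype,
            "v_mutation_count": r.v_mutation_count,
            "n1_length": "" if r.n1_length is None else r.n1_length,
            "n2_length": "" if r.n2_length is None else r.n2_length,
            "vj_insertion_length": ("" if r.vj_insertion_length is None
                                    else r.vj_insertion_length),
            "v_trim3": r.v_trim3,
            "d_trim5": "" if r.d_trim5 is None else r.d_trim5,
            "d_trim3": "" if r.d_trim3 is None else r.d_trim3,
            "j_trim5": r.j_trim5,
            "duplicate_count": r.duplicate_count,
            "productive": "T" if r.productive else "F",
            "clone_id": r.clone_id or "",
            "v_sequence_end": "" if r.v_sequence_end is None else r.v_sequence_end,
            "junction_start": "" if r.junction_start is None else r.junction_start,
        }
        rows.append(row)
    df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_germline_fasta(path: str | Path, segment: str,
                        locus: str = "IGH", species_tag: str = "") -> list[GermlineGene]:
    """Read germline gene segments from an IMGT-style FASTA.

    The gene name is the second pipe-delimited token of the header when pipes
    are present (IMGT convention), otherwise the first whitespace-delimited
    word.  Duplicate gene names raise an error listing the duplicates.
    """
    path = Path(path)
    genes: list[GermlineGene] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        if "|" in header:
            name = header.split("|")[1].strip()
        else:
            name = header.split()[0].strip()
        seen[name] = seen.get(name, 0) + 1
        genes.append(GermlineGene(name=name, sequence=str(entry.seq).upper(),
                                  segment=segment, locus=locus,
                                  species_tag=species_tag))
    dups = sorted(n for n, c in seen.items() if c > 1)
    if dups:
        raise ValueError(f"{path}: duplicate gene names: {', '.join(dups)}")
    return genes


@dataclass(frozen=True)
class SegmentLengthSummary:
    mean: float
    sem: float
    n: int


def mean_segment_length(genes: list[GermlineGene]) -> SegmentLengthSummary:
    """Mean nucleotide length of a single-segment germline set, with SEM.

    SEM uses the sample standard deviation (ddof=1); a single gene gives
    SEM 0.
    """
    if not genes:
        raise ValueError("empty germline set")
    segments = {g.segment for g in genes}
    if len(segments) > 1:
        raise ValueError(f"mixed segment types: {sorted(segments)}")
    lengths = np.array([len(g) for g in genes], dtype=float)
    sem = 0.0 if len(lengths) < 2 else float(lengths.std(ddof=1) / np.sqrt(len(lengths)))
    return SegmentLengthSummary(mean=float(lengths.mean()), sem=sem, n=len(lengths))


def packaged_germline_path(name: str) -> Path:
    """Path to a packaged toy germline FASTA (``igh_toy``, ``igk_toy``,
    ``d_human_synthetic``, ``d_rat_synthetic``)."""
    p = Path(__file__).parent / "data" / f"{name}.fasta"
    if not p.exists():
        raise ValueError(f"unknown packaged germline set {name!r}")
    return p
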