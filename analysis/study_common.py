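"""Shared helpers for the numbered analysis scripts.

The study design mirrors the comparative setup: three rat-like animals with
lymph-node and spleen compartments, plus two human-like subjects, all heavy
chain; kappa repertoires are drawn separately where a script needs them.
Scripts cache the simulated study under results/study/ as AIRR TSVs so every
later step can be rerun independently.
"""

from __future__ import annotations

from pathlib import Path

from vdjcompare import read_airr, species_preset, simulate_repertoire, write_airr
from vdjcompare.records import Repertoire, concat_repertoires

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
STUDY_DIR = RESULTS / "study"

SUBJECTS = [("rat1", "omnirat_like"), ("rat2", "omnirat_like"),
            ("rat3", "omnirat_like"), ("hum1", "human_like"),
            ("hum2", "human_like")]
N_CLONES = 6000
N_READS = 8000
SEED = 20200124


def simulate_study(force: bool = False) -> dict:
    """Simulate (or load the cached) study; returns
    {subject: {"preset": ..., tissue: Repertoire}}."""
    STUDY_DIR.mkdir(parents=True, exist_ok=True)
    study = {}
    for k, (sid, preset) in enumerate(SUBJECTS):
        paths = {t: STUDY_DIR / f"{sid}_{t}.tsv"
                 for t in ("lymph_node", "spleen")}
        model, cfg = species_preset(preset)
        entry = {"preset": preset}
        if force or not all(p.exists() for p in paths.values()):
            cfg.subject_id, cfg.seed = sid, SEED + k
            cfg.n_clones = N_CLONES
            cfg.n_reads_per_compartment = N_READS
            ln, sp, _ = simulate_repertoire(cfg)
            write_airr(ln, paths["lymph_node"])
            write_airr(sp, paths["spleen"])
            entry.update({"lymph_node": ln, "spleen": sp})
        else:
            for t, p in paths.items():
                rep = read_airr(p)
                rep.subject_id, rep.tissue = sid, t
                entry[t] = rep
        for t in ("lymph_node", "spleen"):
            entry[t].germline_ref = model.germline
        study[sid] = entry
    return study


def pooled(study: dict) -> dict[str, Repertoire]:
    return {sid: concat_repertoires([e["lymph_node"], e["spleen"]],
                                    subject_id=sid)
            for sid, e in study.items()}
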