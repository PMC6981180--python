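"""End-to-end study orchestration.

``run_pipeline`` takes one structured config (YAML or dict), simulates or
ingests repertoires, runs the enabled analyses and writes per-analysis TSV
tables, serialized models, Newick dendrograms, an optional heatmap figure, a
run log with per-stage record tallies, and a single deterministic
``summary.json``.  Rerunning the same config yields byte-identical summary
output.
"""

from __future__ import annotations

import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import model as md
from . import sharing as sh
from . import stats as st
from .io import read_airr, write_airr
from .records import Repertoire, concat_repertoires
from .simulate import SimulatorConfig, simulate_repertoire, species_preset

log = logging.getLogger(__name__)

_TOP_KEYS = {"seed", "output_dir", "subjects", "inputs", "analyses",
             "model", "figures", "rarefaction_fractions"}
_SUBJECT_KEYS = {"id", "preset", "locus", "n_clones",
                 "n_reads_per_compartment", "tissue_overlap_prob",
                 "clone_abundance_exponent"}
_ANALYSES = ("stats", "model", "diversity", "sharing")


class ConfigError(ValueError):
    """Config fails schema validation; message lists offending keys."""


def default_config() -> dict:
    """Default synthetic study: 3 rat-like animals (two tissues each) and
    2 human-like subjects, 20k reads per compartment."""
    subjects = [{"id": f"rat{i}", "preset": "omnirat_like", "locus": "IGH",
                 "n_clones": 8000, "n_reads_per_compartment": 10000}
                for i in (1, 2, 3)]
    subjects += [{"id": f"hum{i}", "preset": "human_like", "locus": "IGH",
                  "n_clones": 8000, "n_reads_per_compartment": 10000}
                 for i in (1, 2)]
    return {"seed": 1, "output_dir": "pipeline_out", "subjects": subjects,
            "analyses": {k: True for k in _ANALYSES},
            "model": {"n_train": 10000, "pseudocount": 0.5},
            "figures": False}


def _validate_config(cfg: dict) -> dict:
    bad = sorted(set(cfg) - _TOP_KEYS)
    if bad:
        raise ConfigError(f"unknown config keys: {', '.join(bad)}")
    if not cfg.get("subjects") and not cfg.get("inputs"):
        raise ConfigError("config needs 'subjects' (simulate) or 'inputs'")
    for sub in cfg.get("subjects", []):
        bad = sorted(set(sub) - _SUBJECT_KEYS)
        if bad:
            raise ConfigError(
                f"subject {sub.get('id', '?')}: unknown keys {', '.join(bad)}")
        if "id" not in sub:
            raise ConfigError("every subject needs an 'id'")
    for inp in cfg.get("inputs", []):
        for key in ("id", "tissue", "path"):
            if key not in inp:
                raise ConfigError(f"input entries need '{key}'")
    analyses = cfg.get("analyses", {})
    bad = sorted(set(analyses) - set(_ANALYSES))
    if bad:
        raise ConfigError(f"unknown analyses: {', '.join(bad)}")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return _validate_config(yaml.safe_load(fh))


def _round(x, nd=8):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in sorted(x.items())}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def _simulate_subjects(cfg: dict, seed: int, outdir: Path, summary: dict
                       ) -> dict[str, dict[str, Repertoire]]:
    study: dict[str, dict[str, Repertoire]] = {}
    rep_dir = outdir / "repertoires"
    rep_dir.mkdir(parents=True, exist_ok=True)
    for k, sub in enumerate(cfg.get("subjects", [])):
        preset = sub.get("preset", "omnirat_like")
        locus = sub.get("locus", "IGH")
        model, sim_cfg = species_preset(preset, locus=locus)
        sim_cfg.subject_id = sub["id"]
        sim_cfg.seed = seed * 1000 + k
        for key in ("n_clones", "n_reads_per_compartment",
                    "tissue_overlap_prob", "clone_abundance_exponent"):
            if key in sub:
                setattr(sim_cfg, key, sub[key])
        ln, sp, truth = simulate_repertoire(sim_cfg)
        study[sub["id"]] = {"lymph_node": ln, "spleen": sp}
        for tissue, rep in study[sub["id"]].items():
            write_airr(rep, rep_dir / f"{sub['id']}_{tissue}.tsv")
        summary.setdefault("counts", {})[sub["id"]] = {
            "reads": len(ln) + len(sp),
            "productive": len(ln.productive()) + len(sp.productive()),
            "true_clones": sim_cfg.n_clones,
            "preset": preset}
        log.info("simulated %s (%s): %d reads", sub["id"], preset,
                 len(ln) + len(sp))
    for inp in cfg.get("inputs", []):
        rep = read_airr(inp["path"], locus=inp.get("locus", "IGH"))
        rep.subject_id = inp["id"]
        rep.tissue = inp["tissue"]
        study.setdefault(inp["id"], {})[inp["tissue"]] = rep
        summary.setdefault("counts", {})[inp["id"]] = {
            "reads": len(rep), "productive": len(rep.productive()),
            "rejected": getattr(rep, "rejected_count", 0)}
    return study


def _pooled(study: dict[str, dict[str, Repertoire]]) -> dict[str, Repertoire]:
    return {sid: concat_repertoires(reps.values(), subject_id=sid)
            for sid, reps in study.items()}


def _run_stats(study, pooled, outdir: Path, summary: dict,
               figures: bool) -> None:
    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    profiles = {}
    for sid, reps in study.items():
        for tissue, rep in reps.items():
            if len(rep.productive()) == 0:
                continue
            for seg in ("V", "D", "J") if rep.locus == "IGH" else ("V", "J"):
                try:
                    profiles.setdefault(seg, []).append(
                        st.gene_usage(rep, seg, collapse="clonotype"))
                except ValueError:
                    continue
    usage_summary = {}
    for seg, profs in profiles.items():
        mat = st.usage_matrix(profs)
        mat.columns = ["_".join(p.label[:2]) for p in profs]
        mat.to_csv(stats_dir / f"usage_{seg}.tsv", sep="\t")
        if mat.shape[1] >= 2:
            clust = st.zscore_and_cluster(mat)
            clust.zscores.to_csv(stats_dir / f"usage_{seg}_zscores.tsv",
                                 sep="\t")
            (stats_dir / f"usage_{seg}_columns.nwk").write_text(
                clust.col_newick + "\n")
            usage_summary[seg] = {"column_order": clust.col_order}
            if figures:
                _heatmap(clust, stats_dir / f"usage_{seg}_heatmap.png")
    summary["gene_usage"] = usage_summary

    length_rows, scalar = [], {}
    for sid, rep in pooled.items():
        prod = rep.productive()
        if len(prod) == 0:
            continue
        entry = {}
        for var in (("cdr3_length", "n1_length", "n2_length")
                    if rep.locus == "IGH" else
                    ("cdr3_length", "vj_insertion_length")):
            try:
                dist = st.length_distribution(prod, var)
            except ValueError:
                continue
            entry[var] = {"mean": dist.mean, "sem": dist.sem}
            length_rows += [{"subject": sid, "variable": var, "length": L,
                             "frequency": f}
                            for L, f in dist.histogram.items()]
        if rep.locus == "IGH":
            entry["d3_j6_frequency"] = st.family_pair_frequency(prod)
            entry["isotype_frequencies"] = st.isotype_frequencies(prod)
            entry["mutation_by_isotype"] = {
                iso: {"mean": g.mean, "sem": g.sem}
                for iso, g in st.mutation_summary(prod).items()}
        else:
            entry["cdrl3_5aa_fraction"] = st.short_cdrl3_fraction(prod)
        scalar[sid] = entry
    pd.DataFrame(length_rows).to_csv(stats_dir / "length_distributions.tsv",
                                     sep="\t", index=False)
    summary["repertoire_stats"] = scalar


def _heatmap(clust: "st.ClusterResult", path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    z = clust.zscores.loc[clust.row_order, clust.col_order]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(z))))
    im = ax.imshow(z.values, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(z.shape[0]), z.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _run_model(study, pooled, cfg, seed, outdir: Path, summary: dict) -> None:
    model_dir = outdir / "models"
    model_dir.mkdir(exist_ok=True)
    mcfg = cfg.get("model", {})
    n_train = int(mcfg.get("n_train", 10000))
    pseudocount = float(mcfg.get("pseudocount", 0.5))
    template, _ = species_preset("human_like")
    models, preset_of = {}, {}
    for sid, rep in pooled.items():
        if rep.locus != "IGH":
            continue
        try:
            train = md.select_unmutated(rep, n_train, seed=seed)
        except ValueError:
            log.warning("%s: no unmutated training records", sid)
            continue
        inferred = md.infer_model(train, template, pseudocount=pseudocount)
        inferred.name = sid
        inferred.to_json(model_dir / f"{sid}_model.json")
        models[sid] = inferred
        preset_of[sid] = summary.get("counts", {}).get(sid, {}).get("preset", "")
        log.info("%s: inferred model from %d unmutated records", sid,
                 len(train))
    if len(models) >= 2:
        table = md.kl_event_table(models)
        table.to_csv(model_dir / "kl_divergences.tsv", sep="\t", index=False)
        intra, inter = [], []
        for _, row in table.iterrows():
            same = preset_of.get(row["model_p"]) == preset_of.get(row["model_q"])
            (intra if same else inter).append(row["complete"])
        summary["model"] = {
            "n_models": len(models),
            "mean_intra_preset_kl_bits": float(np.mean(intra)) if intra else None,
            "mean_inter_preset_kl_bits": float(np.mean(inter)) if inter else None,
        }


def _run_diversity(study, cfg, seed, outdir: Path, summary: dict) -> None:
    div_dir = outdir / "diversity"
    div_dir.mkdir(exist_ok=True)
    fractions = cfg.get("rarefaction_fractions",
                        [round(f, 2) for f in np.arange(0.1, 1.01, 0.1)])
    out = {}
    curves = []
    for sid, reps in study.items():
        if "lymph_node" not in reps or "spleen" not in reps:
            continue
        ln_ct = dv.assign_clonotypes(reps["lymph_node"])
        sp_ct = dv.assign_clonotypes(reps["spleen"])
        if not ln_ct.keys() or not sp_ct.keys():
            continue
        table = dv.build_incidence(ln_ct, sp_ct)
        est2 = dv.chao2(table)
        pooled_counts = pd.Series(
            dv._expand_keys(list(reps["lymph_node"].records)
                            + list(reps["spleen"].records))).value_counts()
        est1 = dv.chao1(pooled_counts.to_numpy())
        curve = dv.rarefaction(list(reps["lymph_node"].records)
                               + list(reps["spleen"].records),
                               fractions=fractions, seed=seed)
        curve.insert(0, "subject", sid)
        curves.append(curve)
        out[sid] = {"s_obs": table.s_obs, "q1": table.q1, "q2": table.q2,
                    "chao2": est2.estimate, "chao1": est1.estimate}
    if curves:
        pd.concat(curves).to_csv(div_dir / "rarefaction.tsv", sep="\t",
                                 index=False)
    summary["diversity"] = out


def _run_sharing(study, pooled, outdir: Path, summary: dict) -> None:
    share_dir = outdir / "sharing"
    share_dir.mkdir(exist_ok=True)
    keysets, preset_of = {}, {}
    for sid, rep in pooled.items():
        if rep.locus != "IGH":
            continue
        ct = dv.assign_clonotypes(rep)
        if ct.keys():
            keysets[sid] = ct.keys()
            preset_of[sid] = summary.get("counts", {}).get(sid, {}).get(
                "preset", "")
    if len(keysets) < 2:
        return
    out: dict = {}
    rows = []
    for a, b in combinations(keysets, 2):
        res = sh.pairwise_sharing(keysets[a], keysets[b], labels=(a, b))
        rows.append({"a": a, "b": b, "union": res.fractions["union"],
                     "mean": res.fractions["mean"],
                     **{f"per_{k}": v
                        for k, v in res.fractions["per_set"].items()}})
    pd.DataFrame(rows).to_csv(share_dir / "pairwise_sharing.tsv", sep="\t",
                              index=False)
    out["n_pairs"] = len(rows)

    presets = sorted({p for p in preset_of.values() if p})
    groups = {p: {sid: keysets[sid] for sid in keysets if preset_of[sid] == p}
              for p in presets}
    for p, members in groups.items():
        if len(members) >= 2:
            multi = sh.multiway_sharing(members)
            out[f"multiway_{p}"] = {
                "all_shared_fraction": multi.fractions["union"],
                "venn": {"+".join(sorted(k)): v
                         for k, v in multi.venn_regions.items()}}
    if len(groups) == 2 and all(groups.values()):
        # query the animal-model preset against the human-like pool
        q_name = next((p for p in presets if "omnirat" in p), presets[0])
        p_name = next(p for p in presets if p != q_name)
        pool = set.union(*groups[p_name].values())
        overlap = sh.pool_overlap(groups[q_name], pool)
        out["pool_overlap"] = {"per_subject": overlap.per_subject,
                               "combined": overlap.combined,
                               "query_preset": q_name,
                               "pool_preset": p_name}
        query_pool = set.union(*groups[q_name].values())
        comp = sh.compare_shared_unshared(query_pool, pool)
        out["shared_vs_unshared"] = {
            "shared_mean_cdr3": comp.shared_lengths.mean
            if comp.shared_lengths else None,
            "unshared_mean_cdr3": comp.unshared_lengths.mean
            if comp.unshared_lengths else None,
            "n_shared": comp.n_shared, "n_unshared": comp.n_unshared}
        for L in (8, 13):
            try:
                pfm = sh.cdr3_logo(query_pool & pool, L)
                pfm.to_tsv(share_dir / f"logo_shared_len{L}.tsv")
            except ValueError:
                pass
    summary["sharing"] = out


def run_pipeline(config: dict | str | Path,
                 output_dir: Optional[str | Path] = None,
                 seed: Optional[int] = None) -> Path:
    """Run the configured study end to end; returns the report directory."""
    cfg = (load_config(config) if isinstance(config, (str, Path))
           else _validate_config(dict(config)))
    outdir = Path(output_dir or cfg.get("output_dir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("vdjcompare")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        summary: dict = {"seed": seed}
        analyses = {k: cfg.get("analyses", {}).get(k, True)
                    for k in _ANALYSES}
        study = _simulate_subjects(cfg, seed, outdir, summary)
        pooled = _pooled(study)
        if analyses["stats"]:
            _run_stats(study, pooled, outdir, summary,
                       bool(cfg.get("figures", False)))
        if analyses["model"]:
            _run_model(study, pooled, cfg, seed, outdir, summary)
        if analyses["diversity"]:
            _run_diversity(study, cfg, seed, outdir, summary)
        if analyses["sharing"]:
            _run_sharing(study, pooled, outdir, summary)
        (outdir / "summary.json").write_text(
            json.dumps(_round(summary), indent=1, sort_keys=True) + "\n")
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
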