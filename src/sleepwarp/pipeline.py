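"""End-to-end orchestration: synthesize -> features -> warp -> forecast.

``run_pipeline`` drives the whole analysis from a single validated config
(YAML/dict), writes every artifact with provenance (config hash, seed),
and is deterministic: the same config and seed produce byte-identical
outputs. Completed stages are skipped on re-runs unless ``force=True``.

Cycle segmentation and static sleep statistics are re-exported here from
:mod:`sleepwarp.cycles` as part of the reporting surface.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import QCError
from .cycles import SleepCycle, StaticStats, segment_cycles, static_stats  # noqa: F401 (re-export)
from .forecast import coefficients_by_horizon, cross_validate, significance_by_horizon
from .io import (
    write_bandpower_tsv,
    write_hypnogram_tsv,
    write_json,
    write_matrix_tsv,
    linkage_to_newick,
)
from .synthgen import generate_cohort
from .warping import (
    build_night_features,
    cluster_archetypes,
    compare_within_across,
    oe_dba,
    pairwise_dissimilarity,
    shared_archetype,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline",
           "segment_cycles", "static_stats", "SleepCycle", "StaticStats"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "sleepwarp_out",
    "stages": ["synth", "warp", "forecast"],
    "cohort": {"n_subjects": 8, "nights_per_subject": 10, "clusters": None},
    "features": {"resolution_s": 60.0},
    "warp": {"exclude_adjacent": True, "max_iter": 10, "tol": 1e-3, "cluster_k": 2},
    "forecast": {
        "directions": ["NREM->REM", "REM->NREM"],
        "horizons": None,
        "n_folds": 10,
        "surrogates": 10,
    },
}

_SCHEMA: dict[tuple[str, ...], type | tuple] = {
    ("seed",): int,
    ("out_dir",): str,
    ("stages",): list,
    ("cohort", "n_subjects"): int,
    ("cohort", "nights_per_subject"): int,
    ("features", "resolution_s"): (int, float),
    ("warp", "exclude_adjacent"): bool,
    ("warp", "max_iter"): int,
    ("warp", "tol"): (int, float),
    ("warp", "cluster_k"): int,
    ("forecast", "n_folds"): int,
    ("forecast", "surrogates"): int,
}


def load_config(source: str | Path | dict | None = None) -> dict:
    """Merge a YAML file or dict over the default config."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if source is None:
        return cfg
    user = source if isinstance(source, dict) else yaml.safe_load(Path(source).read_text())
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Return all schema violations (empty list = valid)."""
    errors = []
    known_stages = {"synth", "warp", "forecast"}
    for path_keys, typ in _SCHEMA.items():
        node = cfg
        for k in path_keys:
            if not isinstance(node, dict) or k not in node:
                errors.append(f"missing config key: {'.'.join(path_keys)}")
                node = None
                break
            node = node[k]
        if node is not None and not isinstance(node, typ):
            if not (isinstance(typ, tuple) and isinstance(node, typ)):
                errors.append(
                    f"config key {'.'.join(path_keys)} has type {type(node).__name__}, "
                    f"expected {typ}"
                )
    for st in cfg.get("stages", []):
        if st not in known_stages:
            errors.append(f"unknown stage {st!r}; allowed: {sorted(known_stages)}")
    ncl = cfg.get("cohort", {}).get("clusters")
    if ncl is not None and len(ncl) != cfg["cohort"]["n_subjects"]:
        errors.append("cohort.clusters must list one cluster id per subject")
    return errors


def _config_hash(cfg: dict) -> str:
    """Hash of the scientific configuration (output location excluded so
    the same analysis in two directories is recognised as identical)."""
    scientific = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(scientific, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: str | Path | dict | None = None, force: bool = False) -> dict:
    """Execute the configured stages in dependency order.

    Returns the report dict (also written to ``out_dir/report.json``).
    Raises ``ValueError`` listing *all* config violations before any
    computation; skips stages whose outputs already exist for the same
    config hash unless ``force``.
    """
    cfg = load_config(config)
    errors = validate_config(cfg)
    if isinstance(config, (str, Path)) and not Path(config).exists():
        errors.insert(0, f"config file not found: {config}")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    manifest_path = out / "manifest.json"
    manifest = {"config": cfg, "config_hash": chash, "version": __version__, "stages_done": []}
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash:
            manifest = old

    seed = cfg["seed"]
    report: dict = {"config_hash": chash, "seed": seed}

    # ---- synth ---------------------------------------------------------
    profiles, nights = generate_cohort(
        n_subjects=cfg["cohort"]["n_subjects"],
        nights_per_subject=cfg["cohort"]["nights_per_subject"],
        seed=seed,
        clusters=cfg["cohort"]["clusters"],
    )
    planted = {p.subject_id: p.cluster for p in profiles}
    if "synth" in cfg["stages"] and ("synth" not in manifest["stages_done"] or force):
        hdir, bdir = out / "hypnograms", out / "bandpower"
        hdir.mkdir(exist_ok=True)
        bdir.mkdir(exist_ok=True)
        stats_rows = []
        for n in nights:
            stem = f"{n.subject_id}-{n.night_index:02d}"
            write_hypnogram_tsv(n.hypnogram, hdir / f"{stem}.tsv")
            write_bandpower_tsv(n.bandpower, bdir / f"{stem}.tsv")
            st = static_stats(n.hypnogram)
            stats_rows.append(
                {
                    "night_id": stem,
                    "subject_id": n.subject_id,
                    "tst_min": st.total_sleep_min,
                    "waso_min": st.waso_min,
                    "n_cycles": st.n_cycles,
                    "rem_pct": st.rem_pct,
                    **{f"{s}_pct": st.stage_pct[s] for s in ("N1", "N2", "N3", "REM")},
                }
            )
        pd.DataFrame(stats_rows).to_csv(
            out / "static_stats.tsv", sep="\t", index=False, float_format="%.6g"
        )
        write_json(planted, out / "planted_clusters.json")
        manifest["stages_done"] = sorted(set(manifest["stages_done"]) | {"synth"})
    report["n_nights"] = len(nights)

    # ---- warp ----------------------------------------------------------
    if "warp" in cfg["stages"]:
        wdir = out / "warp"
        wdir.mkdir(exist_ok=True)
        feats = []
        rejected = []
        for n in nights:
            try:
                feats.append(
                    build_night_features(
                        n.bandpower,
                        n.hypnogram,
                        resolution_s=cfg["features"]["resolution_s"],
                        night_id=f"{n.subject_id}-{n.night_index:02d}",
                        subject_id=n.subject_id,
                        night_index=n.night_index,
                    )
                )
            except QCError as err:
                rejected.append({"night": f"{n.subject_id}-{n.night_index:02d}", "reason": err.reason})
        matrix, tidy = pairwise_dissimilarity(
            feats, exclude_adjacent=cfg["warp"]["exclude_adjacent"]
        )
        write_matrix_tsv(matrix, wdir / "dissimilarity.tsv")
        tidy.to_csv(wdir / "dissimilarity_tidy.tsv", sep="\t", index=False, float_format="%.10g")
        cmp_res = compare_within_across(tidy)
        write_json(
            {
                "t": cmp_res.t,
                "p": cmp_res.p,
                "mean_within": cmp_res.mean_within,
                "sd_within": cmp_res.sd_within,
                "mean_across": cmp_res.mean_across,
                "sd_across": cmp_res.sd_across,
            },
            wdir / "within_across.json",
        )
        subjects = sorted({f.subject_id for f in feats})
        archetypes = []
        for sid in subjects:
            arch = oe_dba(
                [f for f in feats if f.subject_id == sid],
                max_iter=cfg["warp"]["max_iter"],
                tol=cfg["warp"]["tol"],
                subject_id=sid,
            )
            archetypes.append(arch)
            np.savetxt(wdir / f"archetype_{sid}.tsv", arch.matrix.T, delimiter="\t", fmt="%.10g")
        clus = cluster_archetypes(archetypes, k=cfg["warp"]["cluster_k"])
        write_matrix_tsv(clus.distance, wdir / "archetype_dissimilarity.tsv")
        (wdir / "dendrogram.nwk").write_text(
            linkage_to_newick(clus.linkage, list(clus.distance.index)) + "\n"
        )
        write_json(clus.labels, wdir / "clusters.json")
        for cid in sorted(set(clus.labels.values())):
            members = [f for f in feats if clus.labels[f.subject_id] == cid]
            if members:
                sh = shared_archetype(members, max_iter=cfg["warp"]["max_iter"])
                np.savetxt(
                    wdir / f"shared_archetype_cluster{cid}.tsv",
                    sh.matrix.T,
                    delimiter="\t",
                    fmt="%.10g",
                )
        report["warp"] = {
            "n_features": len(feats),
            "n_rejected": len(rejected),
            "mean_within": cmp_res.mean_within,
            "mean_across": cmp_res.mean_across,
            "t": cmp_res.t,
            "p": cmp_res.p,
            "clusters": clus.labels,
            "planted_clusters": planted,
        }
        write_json(rejected, wdir / "rejected_nights.json")

    # ---- forecast ------------------------------------------------------
    if "forecast" in cfg["stages"]:
        fdir = out / "forecast"
        fdir.mkdir(exist_ok=True)
        report["forecast"] = {}
        for direction in cfg["forecast"]["directions"]:
            res = cross_validate(
                nights,
                direction=direction,
                horizons=cfg["forecast"]["horizons"],
                n_folds=cfg["forecast"]["n_folds"],
                seed=seed,
            )
            sig = significance_by_horizon(res, surrogates=cfg["forecast"]["surrogates"], seed=seed)
            mean_coef, sd_coef = coefficients_by_horizon(res.models_by_horizon)
            tag = direction.replace("->", "_to_")
            write_json(
                {
                    "direction": direction,
                    "auc": {str(h): res.auc_by_horizon[h] for h in res.horizons},
                    "trivial_auc": {str(h): res.trivial_auc_by_horizon[h] for h in res.horizons},
                    "significant_horizons": sig.significant_horizons,
                },
                fdir / f"auc_{tag}.json",
            )
            mean_coef.to_csv(fdir / f"coefficients_{tag}.tsv", sep="\t", float_format="%.10g")
            report["forecast"][direction] = {
                "mean_auc": {h: res.mean_auc(h) for h in res.horizons},
                "mean_trivial_auc": {h: res.mean_auc(h, "trivial") for h in res.horizons},
                "significant_horizons": sorted(sig.significant_horizons),
            }

    manifest["stages_done"] = sorted(set(manifest["stages_done"]) | set(cfg["stages"]))
    write_json(manifest, manifest_path)
    write_json(report, out / "report.json")
    _write_markdown_report(report, out / "report.md")
    return report


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = ["# sleepwarp run report", "", f"- config hash: `{report['config_hash']}`",
             f"- seed: {report['seed']}", f"- nights: {report.get('n_nights', 'n/a')}"]
    if "warp" in report:
        w = report["warp"]
        lines += [
            "",
            "## Night-to-night dissimilarity",
            f"- mean within-subject D = {w['mean_within']:.3f}",
            f"- mean across-subject D = {w['mean_across']:.3f}",
            f"- t = {w['t']:.2f}, p = {w['p']:.3g}",
            f"- archetype clusters: {w['clusters']}",
        ]
    for direction, f in report.get("forecast", {}).items():
        lines += [
            "",
            f"## Transition forecasting ({direction})",
            f"- significant horizons: {f['significant_horizons']}",
        ]
    path.write_text("\n".join(lines) + "\n")
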