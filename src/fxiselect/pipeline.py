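"""End-to-end orchestration: simulate -> preprocess -> fit -> sensitivity ->
overlap -> enrich -> network, with a reproducible run manifest.

A single YAML/JSON config drives the whole run; every output file is listed
in ``manifest.json`` with its SHA-256 digest, so reruns with the same config
and seed are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

import fxiselect
from fxiselect import enrichment, fp_lasso, network, preprocess, synthetic

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},
    "fit": {
        "covariates": list(fp_lasso.DEFAULT_COVARIATES),
        "powers": list(fp_lasso.DEFAULT_POWERS),
        "n_lambdas": 100,
        "eps": fp_lasso.DEFAULT_EPS,
        "k": 10,
        "include_fxi_ag": False,
    },
    "sensitivity": {"aptt_threshold": fp_lasso.DEFAULT_APTT_THRESHOLD},
    "enrichment": {"rho_threshold": 0.80, "alpha": 0.05},
    "network": {
        "inflation": 2.0,
        "restrict_physical": True,
        "min_weight": 0.0,
    },
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()


def _fit_kwargs(cfg: dict, seed: int) -> dict:
    fit = cfg["fit"]
    return {
        "covariate_cols": tuple(fit["covariates"]),
        "fp_config": fp_lasso.FPConfig(
            powers=tuple(float(p) for p in fit["powers"])
        ),
        "seed": seed,
        "k": int(fit["k"]),
        "n_lambdas": int(fit["n_lambdas"]),
        "eps": float(fit["eps"]),
        "include_fxi_ag": bool(fit["include_fxi_ag"]),
    }


def run_all(
    config: dict | str | Path | None,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute the full pipeline on a synthetic cohort; returns the manifest."""
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, rel: str, **kw) -> Path:
        path = outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t" if rel.endswith(".tsv") else ",", **kw)
        written.append(path)
        return path

    def save_json(obj, rel: str) -> Path:
        path = outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        written.append(path)
        return path

    # --- simulate ----------------------------------------------------------
    sim_cfg = synthetic.SimulationConfig(**cfg["simulate"], seed=seed)
    cohort, proteins = synthetic.generate_cohort(sim_cfg)
    gene_sets = synthetic.generate_gene_sets(sim_cfg)
    edges = synthetic.generate_interactions(sim_cfg)
    fixture_dir = outdir / "fixtures"
    paths = synthetic.write_fixtures(
        cohort, proteins, fixture_dir, truth=sim_cfg.truth()
    )
    written.extend(paths.values())
    gmt_path = fixture_dir / "gene_sets.gmt"
    enrichment.write_gmt(
        enrichment.GeneSetDB(sets={k: frozenset(v) for k, v in gene_sets.items()}),
        gmt_path,
    )
    written.append(gmt_path)
    edges_path = fixture_dir / "interactions.tsv"
    edges.to_csv(edges_path, sep="\t", index=False)
    written.append(edges_path)

    # --- preprocess --------------------------------------------------------
    filtered = preprocess.apply_exclusions(cohort)
    exclusions = filtered.attrs["exclusions"]
    save_df(filtered, "preprocess/cohort_filtered.csv")
    acute = filtered[filtered["timepoint"] == synthetic.ACUTE]
    followup = filtered[filtered["timepoint"] == synthetic.FOLLOWUP]

    _, tlog = preprocess.normality_transform(proteins.loc[acute.index])
    tlog.to_json(outdir / "preprocess/transform_log.json")
    written.append(outdir / "preprocess/transform_log.json")

    strata = preprocess.stratify_fxi(acute["fxi_c"])
    save_df(preprocess.baseline_table(acute, strata), "preprocess/baseline_acute.tsv")

    paired_a = filtered.set_index("subject_id")
    acute_by_subject = paired_a[paired_a["timepoint"] == synthetic.ACUTE]["fxi_c"]
    fu_by_subject = paired_a[paired_a["timepoint"] == synthetic.FOLLOWUP]["fxi_c"]
    try:
        paired = preprocess.paired_fxi_test(acute_by_subject, fu_by_subject)
    except ValueError as exc:
        paired = {"error": str(exc)}
    save_json(paired, "preprocess/paired_test.json")

    # --- fit both timepoints ----------------------------------------------
    fit_kw = _fit_kwargs(cfg, seed)
    selections: dict[str, fp_lasso.ProteinSelection] = {}
    for name, sample in (("acute", acute), ("followup", followup)):
        sel = fp_lasso.fit_timepoint_model(sample, proteins, **fit_kw)
        selections[name] = sel
        sel_path = outdir / f"selection/{name}.tsv"
        sel_path.parent.mkdir(parents=True, exist_ok=True)
        sel.to_tsv(sel_path)
        written.append(sel_path)
        save_json(sel.manifest(), f"selection/{name}_manifest.json")

    # --- sensitivity analyses ---------------------------------------------
    aptt_thr = float(cfg["sensitivity"]["aptt_threshold"])
    sens_counts = {}
    for name, sample in (("acute", acute), ("followup", followup)):
        for kind, fn, kw in (
            ("no_doac", fp_lasso.sensitivity_no_doac, {}),
            ("aptt", fp_lasso.sensitivity_aptt, {"aptt_threshold": aptt_thr}),
        ):
            try:
                sel = fn(sample, proteins, **kw, **fit_kw)
            except ValueError as exc:
                logger.warning("sensitivity %s/%s skipped: %s", name, kind, exc)
                save_json({"error": str(exc)}, f"sensitivity/{name}_{kind}.json")
                continue
            sens_path = outdir / f"sensitivity/{name}_{kind}.tsv"
            sens_path.parent.mkdir(parents=True, exist_ok=True)
            sel.to_tsv(sens_path)
            written.append(sens_path)
            overlap_full = fp_lasso.overlap_selections(selections[name], sel)
            sens_counts[f"{name}_{kind}"] = {
                "n_excluded": sel.n_excluded,
                "n_selected": len(sel.selected),
                "overlap_with_full": len(overlap_full.shared),
            }
    save_json(sens_counts, "sensitivity/summary.json")

    # --- overlap across timepoints ----------------------------------------
    overlap = fp_lasso.overlap_selections(selections["acute"], selections["followup"])
    save_json(
        {
            "shared": overlap.shared,
            "acute_specific": overlap.only_a,
            "followup_specific": overlap.only_b,
            **overlap.counts(),
        },
        "overlap/overlap.json",
    )

    # --- enrichment --------------------------------------------------------
    db = enrichment.read_gmt(gmt_path, source="synthetic")
    background = list(proteins.columns)
    rho_thr = float(cfg["enrichment"]["rho_threshold"])
    alpha = float(cfg["enrichment"]["alpha"])
    enr_results = {}
    for name, sample in (("acute", acute), ("followup", followup)):
        query = enrichment.augment_query(
            selections[name].selected, proteins.loc[sample.index], rho_threshold=rho_thr
        )
        res = enrichment.enrich(query, db, background, alpha=alpha)
        enr_results[name] = res
        save_df(res, f"enrichment/{name}.tsv", index=False)
    save_json(
        enrichment.compare_timepoints(enr_results["acute"], enr_results["followup"]),
        "enrichment/compare.json",
    )

    # --- network -----------------------------------------------------------
    net_cfg = cfg["network"]
    edge_df = edges
    if float(net_cfg["min_weight"]) > 0:
        edge_df = edge_df[edge_df["weight"] >= float(net_cfg["min_weight"])]
    graph = network.build_graph(
        edge_df, restrict_physical=bool(net_cfg["restrict_physical"])
    )
    if graph.number_of_nodes():
        labels = network.mcl_cluster(graph, inflation=float(net_cfg["inflation"]))
        clusters = pd.DataFrame(
            sorted(labels.items()), columns=["node", "cluster"]
        )
        save_df(clusters, "network/clusters.tsv", index=False)
        complexes = network.mcode(graph)
        labelled = network.label_complexes(complexes, db, background)
        save_df(labelled, "network/complexes.tsv", index=False)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "version": fxiselect.__version__,
        "seed": seed,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "exclusions": exclusions,
        "selection_counts": {
            name: len(sel.selected) for name, sel in selections.items()
        },
        "cv_r2": {name: sel.cv_r2 for name, sel in selections.items()},
        "shared_proteins": overlap.shared,
        "sensitivity": sens_counts,
        "files": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest
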