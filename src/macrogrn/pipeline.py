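"""End-to-end pipeline orchestration with a structured config.

Stages run in dependency order::

    simulate -> expression -> bicluster
                           -> coexpress -> topology
                           -> grn       -> validate

Each stage writes its artifacts under ``<outdir>/<stage>/`` together with
a ``manifest.json`` recording the parameters used and the SHA-256 of
every output file.  Manifests carry no timestamps, so two runs with an
identical config produce byte-identical stage outputs; wall-clock
information goes only to ``run.log``.

Every random operation derives its seed from the single config ``seed``
with a fixed per-stage offset; there is no hidden global randomness.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import warnings
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import biclustering, chip_validation, coexpression, expression, grn, io_formats
from . import synthetic_data, topology
from .containers import PromoterWindow
from .exceptions import DependencyError, UsageError

STAGES = ("simulate", "expression", "bicluster", "coexpress", "grn", "topology", "validate")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "inputs": None,  # optional: paths for real data instead of the simulate stage
    "simulate": {
        "n_tfs": 30,
        "n_genes": 600,
        "n_strains": 5,
        "n_replicates": 2,
        "on_tpm_mean": 100.0,
        "off_tpm_mean": 1.0,
        "replicate_sd": 0.25,
        "decoy_rate": 0.2,
        "peak_dropout": 0.0,
    },
    "expression": {
        "tpm_threshold": 10.0,
        "pseudocount": 1.0,
        "de_alpha": 0.05,
        "de_fc": 2.0,
        "kmeans_k": 9,
        "top_variable": 6000,
    },
    "bicluster": {
        "delta": None,
        "alpha": 1.2,
        "n_biclusters": 2,
    },
    "coexpress": {
        "powers": list(range(1, 21)),
        "soft_power": 18,  # fixed power; None = pick by scale-free fit
        "fit_target": 0.68,
        "min_module_size": 30,
        "target_mean_degree": 15.0,
    },
    "grn": {
        "tpm_threshold": 10.0,
        "promoter_upstream": 1000,
        "promoter_downstream": 100,
        "strict_unique_targets": True,
    },
    "topology": {
        "hub_threshold": 50,
        "n_bins": 10,
    },
    "validate": {
        "tf": None,  # default: the TF with most predicted targets
        "strain": None,  # default: first strain
        "dropout": 0.0,
        "false_rate": 0.0,
        "chip_targets_path": None,  # real-data alternative to simulated ChIP
    },
}


def _merge_config(user: Mapping | None) -> dict:
    """Overlay a user config onto the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if user is None:
        return cfg
    for key, val in user.items():
        if key not in cfg:
            raise UsageError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, Mapping):
            for sub, subval in val.items():
                if sub not in cfg[key]:
                    raise UsageError(f"unknown config key {key}.{sub}")
                cfg[key][sub] = subval
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: Mapping) -> None:
    outputs = {
        p.name: _sha256(p)
        for p in sorted(stage_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    payload = {"stage": stage, "parameters": params, "outputs": outputs}
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1, default=str)
        fh.write("\n")


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _load_bundle(outdir: Path, cfg: dict, stage: str):
    sim_dir = outdir / "simulate"
    if (sim_dir / "expression.tsv").is_file():
        return synthetic_data.read_bundle(sim_dir)
    inputs = cfg.get("inputs")
    if inputs:
        return io_formats.read_input_bundle(
            inputs["expression"],
            inputs["peaks"],
            inputs["annotation"],
            inputs["prior"],
            inputs["samples"],
        )
    raise DependencyError(
        f"stage '{stage}' needs an input bundle: run the 'simulate' stage "
        "first or provide an 'inputs' section in the config"
    )


def _require(outdir: Path, stage: str, needed_stage: str, filename: str) -> Path:
    path = outdir / needed_stage / filename
    if not path.is_file():
        raise DependencyError(
            f"stage '{stage}' requires {needed_stage}/{filename}; "
            f"run the '{needed_stage}' stage first"
        )
    return path


def _read_log_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: dict, outdir: Path, log: logging.Logger) -> None:
    stage_dir = outdir / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    params = synthetic_data.SimulationParams(seed=cfg["seed"], **cfg["simulate"])
    truth = synthetic_data.generate_ground_truth(params)
    bundle = synthetic_data.simulate_bundle(truth, params)
    synthetic_data.write_bundle(bundle, stage_dir)
    synthetic_data.write_ground_truth(truth, stage_dir)
    log.info(
        "simulated %d strains x %d replicates, %d TFs, %d genes, prior %d pairs",
        params.n_strains, params.n_replicates, params.n_tfs, params.n_genes,
        len(bundle[3]),
    )
    _write_manifest(stage_dir, "simulate", _json_safe({**cfg["simulate"], "seed": cfg["seed"]}))


def _stage_expression(cfg: dict, outdir: Path, log: logging.Logger) -> None:
    stage_dir = outdir / "expression"
    stage_dir.mkdir(parents=True, exist_ok=True)
    expr, _, _, _ = _load_bundle(outdir, cfg, "expression")
    p = cfg["expression"]
    filtered, log_matrix = expression.normalize_expression(
        expr, tpm_threshold=p["tpm_threshold"], pseudocount=p["pseudocount"]
    )
    log.info("expression filter kept %d / %d genes", log_matrix.shape[0], expr.values.shape[0])
    log_matrix.to_csv(stage_dir / "log_matrix.tsv", sep="\t",
                      index_label="gene_id", float_format="%.8g")
    io_formats.write_strain_map(expr.sample_to_strain, stage_dir / "samples.tsv")

    summary_rows = []
    for a, b in combinations(filtered.strains, 2):
        de = expression.differential_expression(
            log_matrix, expr.sample_to_strain, a, b,
            alpha=p["de_alpha"], fc_cut=p["de_fc"],
        )
        de.to_csv(stage_dir / f"de_{a}_vs_{b}.tsv", sep="\t",
                  index_label="gene_id", float_format="%.8g")
        summary_rows.append(
            {"strain_a": a, "strain_b": b,
             "n_up": int((de["call"] == "up").sum()),
             "n_down": int((de["call"] == "down").sum())}
        )
    pd.DataFrame(summary_rows).to_csv(stage_dir / "de_summary.tsv", sep="\t", index=False)

    n_top = min(p["top_variable"], log_matrix.shape[0])
    if n_top < p["top_variable"]:
        log.info("top_variable clipped to the %d available genes", n_top)
    clusters = expression.variable_gene_kmeans(
        log_matrix, n_top=n_top, k=p["kmeans_k"], seed=cfg["seed"]
    )
    clusters.to_csv(stage_dir / "kmeans_clusters.tsv", sep="\t", index_label="gene_id")

    scores, frac = expression.pca_scores(log_matrix)
    scores.to_csv(stage_dir / "pca_scores.tsv", sep="\t",
                  index_label="sample", float_format="%.8g")
    pd.DataFrame({"component": scores.columns, "variance_fraction": frac}) \
        .to_csv(stage_dir / "pca_variance.tsv", sep="\t", index=False, float_format="%.8g")
    _write_manifest(stage_dir, "expression", _json_safe({**p, "seed": cfg["seed"]}))


def _stage_bicluster(cfg: dict, outdir: Path, log: logging.Logger) -> None:
    stage_dir = outdir / "bicluster"
    stage_dir.mkdir(parents=True, exist_ok=True)
    log_matrix = _read_log_matrix(_require(outdir, "bicluster", "expression", "log_matrix.tsv"))
    p = cfg["bicluster"]
    sds = log_matrix.std(axis=1, ddof=1)
    z = log_matrix.loc[sds > 0]
    z = z.sub(z.mean(axis=1), axis=0).div(sds[sds > 0], axis=0)
    biclusters = biclustering.cheng_church(
        z, delta=p["delta"], alpha=p["alpha"],
        n_biclusters=p["n_biclusters"], seed=cfg["seed"],
    )
    log.info("found %d bicluster(s); first has %s rows",
             len(biclusters), len(biclusters[0].rows) if biclusters else 0)
    biclustering.write_bicluster_table(biclusters, stage_dir / "biclusters.tsv")
    _write_manifest(stage_dir, "bicluster", _json_safe({**p, "seed": cfg["seed"]}))


def _stage_coexpress(cfg: dict, outdir: Path, log: logging.Logger) -> None:
    stage_dir = outdir / "coexpress"
    stage_dir.mkdir(parents=True, exist_ok=True)
    log_matrix = _read_log_matrix(_require(outdir, "coexpress", "expression", "log_matrix.tsv"))
    p = cfg["coexpress"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        power, fit_table = coexpression.pick_soft_threshold(
            log_matrix, powers=p["powers"], target_fit=p["fit_target"]
        )
    if p["soft_power"] is not None:
        power = int(p["soft_power"])
    fit_table.to_csv(stage_dir / "fit_indices.tsv", sep="\t", index=False,
                     float_format="%.8g")
    log.info("soft-threshold power %d", power)
    adj, tom = coexpression.build_adjacency_tom(log_matrix, power)
    modules = coexpression.detect_modules(tom, min_module_size=p["min_module_size"])
    modules.to_csv(stage_dir / "modules.tsv", sep="\t", index_label="gene_id")
    net = coexpression.coexpression_edges(
        adj, target_mean_degree=p["target_mean_degree"]
    )
    net.module = modules
    net.edges.to_csv(stage_dir / "edges.tsv", sep="\t", index=False, float_format="%.8g")
    net.connectivity.to_csv(stage_dir / "connectivity.tsv", sep="\t",
                            index_label="gene_id", float_format="%.8g")
    n_modules = int((modules != coexpression.UNASSIGNED_MODULE).sum() and
                    modules[modules != coexpression.UNASSIGNED_MODULE].nunique())
    log.info("coexpression: %d edges, %d modules", len(net.edges), n_modules)
    _write_manifest(stage_dir, "coexpress",
                    _json_safe({**p, "chosen_power": power,
                                "edge_threshold": net.threshold, "seed": cfg["seed"]}))


def _stage_grn(cfg: dict, outdir: Path, log: logging.Logger) -> None:
    stage_dir = outdir / "grn"
    stage_dir.mkdir(parents=True, exist_ok=True)
    expr, peaks, annotation, prior = _load_bundle(outdir, cfg, "grn")
    p = cfg["grn"]
    window = PromoterWindow(p["promoter_upstream"], p["promoter_downstream"])
    strain_grns = []
    for strain in expr.strains:
        accessible = grn.accessible_promoter_genes(peaks[strain], annotation, window)
        g = grn.build_strain_grn(
            expr, strain, accessible, prior, tpm_threshold=p["tpm_threshold"]
        )
        strain_grns.append(g)
        io_formats.write_grn_edge_list(g, stage_dir / f"grn_{strain}.tsv", "tsv")
        log.info("%s GRN: %d TFs, %d targets, %d edges",
                 strain, len(g.tfs), len(g.targets), g.n_edges)
    pan = grn.combine_grns(strain_grns, "union")
    core = grn.combine_grns(strain_grns, "intersection")
    grn.write_combined_grn(pan, stage_dir / "pan_grn.tsv")
    grn.write_combined_grn(core, stage_dir / "core_grn.tsv")

    unique = grn.strain_unique_tfs(expr, prior.tfs, tpm_threshold=p["tpm_threshold"])
    with open(stage_dir / "unique_tfs.tsv", "w") as fh:
        fh.write("strain\ttf\n")
        for strain in expr.strains:
            for tf in sorted(unique[strain]):
                fh.write(f"{strain}\t{tf}\n")
    for g in strain_grns:
        others = [o for o in strain_grns if o.strain != g.strain]
        present = unique[g.strain] & g.tfs
        sub = grn.unique_tf_grn(g, others, present, strict=p["strict_unique_targets"])
        io_formats.write_grn_edge_list(sub, stage_dir / f"unique_grn_{g.strain}.tsv", "tsv")

    rows = []
    for g in strain_grns:
        table, _ = grn.grn_summary(g)
        for rec in table.itertuples(index=False):
            rows.append({"strain": g.strain, "tf": rec.tf, "out_degree": rec.out_degree})
    pd.DataFrame(rows).to_csv(stage_dir / "tf_out_degrees.tsv", sep="\t", index=False)

    stats = {
        "per_strain": {
            g.strain: {"n_tfs": len(g.tfs), "n_targets": len(g.targets),
                       "n_nodes": len(g.nodes), "n_edges": g.n_edges}
            for g in strain_grns
        },
        "pan": dict(zip(("n_tfs", "n_targets", "n_nodes"), pan.node_counts()))
        | {"n_edges": len(pan.edges)},
        "core": dict(zip(("n_tfs", "n_targets", "n_nodes"), core.node_counts()))
        | {"n_edges": len(core.edges)},
    }
    with open(stage_dir / "grn_stats.json", "w") as fh:
        json.dump(_json_safe(stats), fh, sort_keys=True, indent=1)
        fh.write("\n")
    _write_manifest(stage_dir, "grn", _json_safe({**p, "seed": cfg["seed"]}))


def _stage_topology(cfg: dict, outdir: Path, log: logging.Logger) -> None:
    stage_dir = outdir / "topology"
    stage_dir.mkdir(parents=True, exist_ok=True)
    edges_path = _require(outdir, "topology", "coexpress", "edges.tsv")
    edges = pd.read_csv(edges_path, sep="\t")
    p = cfg["topology"]
    import networkx as nx

    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b, weight=float(row.weight))
    records = topology.compute_centralities(graph, hub_threshold=p["hub_threshold"])
    io_formats.write_centrality_table(records, stage_dir / "centralities.tsv")
    hubs = topology.hub_genes(records, hub_threshold=p["hub_threshold"])
    with open(stage_dir / "hubs.tsv", "w") as fh:
        fh.write("node\n")
        for node in sorted(hubs):
            fh.write(f"{node}\n")

    degrees = records["degree"].to_numpy()
    try:
        r2, slope = topology.powerlaw_fit_r2(degrees, n_bins=p["n_bins"])
    except UsageError:
        r2, slope = float("nan"), float("nan")
    ref = topology.random_reference_graph(
        graph.number_of_nodes(), graph.number_of_edges(), seed=cfg["seed"] + 101
    )
    try:
        ref_degrees = np.array([d for _, d in ref.degree()])
        r2_ref, slope_ref = topology.powerlaw_fit_r2(ref_degrees, n_bins=p["n_bins"])
    except UsageError:
        r2_ref, slope_ref = float("nan"), float("nan")

    # TF-vs-gene centrality comparison on the co-expression graph
    comparison = {}
    try:
        _, _, _, prior = _load_bundle(outdir, cfg, "topology")
        tf_nodes = [n for n in records.index if n in prior.tfs]
        gene_nodes = [n for n in records.index if n not in prior.tfs]
        if tf_nodes and gene_nodes:
            for col in ("connectivity", "betweenness", "stress", "degree"):
                stat, pval = topology.compare_group_centrality(
                    records.loc[tf_nodes, col], records.loc[gene_nodes, col]
                )
                comparison[col] = {
                    "tf_mean": float(records.loc[tf_nodes, col].mean()),
                    "gene_mean": float(records.loc[gene_nodes, col].mean()),
                    "statistic": stat, "p_value": pval,
                }
    except DependencyError:
        pass

    stats = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "scale_free_r2": r2,
        "scale_free_slope": slope,
        "random_reference_r2": r2_ref,
        "random_reference_slope": slope_ref,
        "hub_count": len(hubs),
        "hub_fraction": len(hubs) / max(graph.number_of_nodes(), 1),
        "tf_vs_gene": comparison,
    }
    with open(stage_dir / "topology_stats.json", "w") as fh:
        json.dump(_json_safe(stats), fh, sort_keys=True, indent=1)
        fh.write("\n")
    log.info("topology: %d nodes, scale-free r2 %.3f, %d hubs",
             stats["n_nodes"], r2, len(hubs))
    _write_manifest(stage_dir, "topology", _json_safe({**p, "seed": cfg["seed"]}))


def _stage_validate(cfg: dict, outdir: Path, log: logging.Logger) -> None:
    stage_dir = outdir / "validate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    p = cfg["validate"]
    grn_dir = outdir / "grn"
    if not grn_dir.is_dir():
        raise DependencyError("stage 'validate' requires the 'grn' stage outputs")
    truth_path = outdir / "simulate" / "ground_truth.json"
    records = []
    if p["chip_targets_path"]:
        chip = frozenset(
            line.strip() for line in open(p["chip_targets_path"]) if line.strip()
        )
        strain = p["strain"]
        g = io_formats.read_grn_edge_list(grn_dir / f"grn_{strain}.tsv", "tsv")
        records.append(chip_validation.target_recovery(g, p["tf"], chip))
    elif truth_path.is_file():
        truth = synthetic_data.read_ground_truth(truth_path)
        strain = p["strain"] or truth.strains[0]
        g = io_formats.read_grn_edge_list(grn_dir / f"grn_{strain}.tsv", "tsv")
        tf = p["tf"]
        if tf is None:
            out = g.out_degrees()
            if not out:
                raise DependencyError(f"{strain} GRN is empty; nothing to validate")
            tf = max(sorted(out), key=lambda t: out[t])
        chip = synthetic_data.simulate_chip_peaks(
            truth, strain, tf, dropout=p["dropout"], false_rate=p["false_rate"],
            seed=cfg["seed"] + 211,
        )
        records.append(chip_validation.target_recovery(g, tf, chip))
    else:
        raise DependencyError(
            "stage 'validate' needs either simulated ground truth or a "
            "validate.chip_targets_path entry"
        )
    chip_validation.write_validation_table(records, stage_dir / "validation.tsv")
    r = records[0]
    log.info("ChIP validation of %s in %s: precision %.3f, recall %.3f",
             r.tf, r.strain, r.recovery_fraction, r.chip_fraction)
    _write_manifest(stage_dir, "validate", _json_safe({**p, "seed": cfg["seed"]}))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "expression": _stage_expression,
    "bicluster": _stage_bicluster,
    "coexpress": _stage_coexpress,
    "grn": _stage_grn,
    "topology": _stage_topology,
    "validate": _stage_validate,
}


def run_pipeline(
    config: Mapping | None,
    outdir: str | Path,
    stages: Sequence[str] = STAGES,
    log_level: int = logging.INFO,
) -> dict:
    """Run the requested stages in dependency order.

    Returns the fully merged config that was executed.  Unknown stages or
    config keys raise a usage error; a stage whose upstream artifacts are
    missing raises a dependency error naming the stage.
    """
    cfg = _merge_config(config)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise UsageError(f"unknown stage(s) {unknown}; valid stages: {list(STAGES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("macrogrn.pipeline")
    log.setLevel(log_level)
    log.handlers.clear()
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s [%(name)s] %(message)s")
    )
    log.addHandler(handler)
    try:
        log.info("config: %s", json.dumps(_json_safe(cfg), sort_keys=True, default=str))
        for stage in STAGES:
            if stage not in stages:
                continue
            log.info("=== stage %s ===", stage)
            _STAGE_FUNCS[stage](cfg, outdir, log)
    finally:
        handler.close()
        log.removeHandler(handler)
    return cfg
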