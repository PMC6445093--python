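"""End-to-end pipeline: simulate -> differential -> network -> integrate
-> survival -> report.

The run directory receives every stage's table plus a deterministic
machine-readable ``report.json`` and a human-readable ``report.txt``
(timestamps go to the log file only, so two runs at the same seed are
byte-identical where it matters).
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossspecies, differential, io as tio, network, simulate, survival
from .simulate import SimulationConfig as _SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds (defaults are the study's stated cutoffs) and paths."""

    seed: int = 0
    outdir: str = "run"
    simulate: bool = True
    # thresholds
    fc_cutoff: float = 1.25
    min_cohorts: int = 3
    p_single: float = 0.05
    p_combined: float = 0.1
    score_min: float = 6.0
    min_confidence: int = 500
    f20_cutoff: float = 1.3
    secretome_up: float = 1.5
    secretome_down: float = 0.67
    high_fraction: float = 0.25
    # inputs when simulate is off
    cohort_paths: tuple = ()
    mouse_path: str | None = None
    cellline_path: str | None = None
    secretome_path: str | None = None
    edge_paths: tuple = ()
    survival_path: str | None = None
    annotation_path: str | None = None
    regulators: tuple = network.DEFAULT_REGULATORS
    exclusion: tuple = tuple(sorted(network.DEFAULT_EXCLUSION))
    simulation: _SimulationConfig = field(default_factory=_SimulationConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """INI-style config: [run] for pipeline options, [simulation] for
        generator parameters, [inputs] for file paths."""
        parser = configparser.ConfigParser()
        if not parser.read(path):
            raise FileNotFoundError(f"config file not found: {path}")
        kwargs: dict = {}
        run_fields = {f.name: f.type for f in fields(cls)}
        for key, value in parser.items("run") if parser.has_section("run") else []:
            if key not in run_fields:
                raise ValueError(f"unknown run option {key!r}")
            current = getattr(cls(), key)
            if isinstance(current, bool):
                kwargs[key] = parser.getboolean("run", key)
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        if parser.has_section("inputs"):
            for key, value in parser.items("inputs"):
                if key == "cohorts":
                    kwargs["cohort_paths"] = tuple(value.split())
                elif key == "edges":
                    kwargs["edge_paths"] = tuple(value.split())
                else:
                    kwargs[f"{key}_path"] = value
        if parser.has_section("simulation"):
            sim_kwargs = {}
            defaults = simulate.SimulationConfig()
            for key, value in parser.items("simulation"):
                cur = getattr(defaults, key)
                sim_kwargs[key] = type(cur)(value)
            kwargs["simulation"] = simulate.SimulationConfig(**sim_kwargs)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    outdir: Path
    report: dict
    signature: list[str]

    def checksum(self) -> str:
        """SHA-256 over the deterministic outputs (everything but the log)."""
        h = hashlib.sha256()
        for path in sorted(self.outdir.rglob("*")):
            if path.is_file() and path.name != "run.log":
                h.update(path.name.encode())
                h.update(path.read_bytes())
        return h.hexdigest()


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"simulate disabled and no {what} input configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing {what} input file: {p}")
    return p


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage in order; stage failure raises with partial outputs
    preserved in the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("tgfbsig")
    root.addHandler(handler)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> PipelineResult:
    logger.info("thresholds: fc>%s in >=%s/4, p_single<%s, p_combined<%s, "
                "score>=%s, conf>%s, F20>%s, secretome %s/%s, high_frac=%s",
                config.fc_cutoff, config.min_cohorts, config.p_single,
                config.p_combined, config.score_min, config.min_confidence,
                config.f20_cutoff, config.secretome_up, config.secretome_down,
                config.high_fraction)
    report: dict = {"seed": config.seed, "thresholds": {
        "fc_cutoff": config.fc_cutoff, "min_cohorts": config.min_cohorts,
        "p_single": config.p_single, "p_combined": config.p_combined,
        "score_min": config.score_min, "min_confidence": config.min_confidence,
        "f20_cutoff": config.f20_cutoff, "secretome_up": config.secretome_up,
        "secretome_down": config.secretome_down,
        "high_fraction": config.high_fraction}}

    # ---- stage 1: inputs -------------------------------------------------
    truth = None
    if config.simulate:
        study = simulate.simulate_study(config.simulation, seed=config.seed)
        study.write(outdir / "inputs")
        cohorts = study.cohorts
        mouse = study.mouse
        graph_full = study.graph
        panel = study.cellline_panel
        secretome = study.secretome
        surv_df = study.survival
        annotation = study.annotation_sets()
        truth = study.truth
        signature_genes_cfg = list(truth.signature_genes)
    else:
        if len(config.cohort_paths) != 4:
            raise FileNotFoundError(
                "simulate disabled: need exactly 4 cohort input files, got "
                f"{len(config.cohort_paths)}")
        cohorts = {}
        for p in config.cohort_paths:
            df = tio.read_cohort_tsv(_require(p, "cohort"))
            cid = str(df["cohort_id"].iloc[0]) if "cohort_id" in df else Path(p).stem
            cohorts[cid] = df
        mouse = tio.read_mouse_tsv(_require(config.mouse_path, "mouse series"))
        panel = tio.read_cellline_tsv(_require(config.cellline_path, "cell-line"))
        secretome = (tio.read_secretome_tsv(config.secretome_path)
                     if config.secretome_path else None)
        if not config.edge_paths:
            raise FileNotFoundError("simulate disabled and no edges input configured")
        graph_full = network.load_and_merge_edges(
            [_require(p, "edges") for p in config.edge_paths],
            min_confidence=config.min_confidence)
        surv_df = tio.read_survival_csv(_require(config.survival_path, "survival"))
        annotation = (tio.read_gmt(config.annotation_path)
                      if config.annotation_path else None)
        signature_genes_cfg = None

    # ---- stage 2: differential ------------------------------------------
    diff = differential.differential_analysis(
        cohorts, fc_cutoff=config.fc_cutoff, p_single=config.p_single,
        p_combined=config.p_combined, min_cohorts=config.min_cohorts,
        score_cutoff=config.score_min)
    conc = diff.concordant
    conc.reset_index().to_csv(outdir / "concordant_proteins.tsv", sep="\t",
                              index=False)
    for cid, tbl in diff.per_cohort.items():
        tbl.reset_index().to_csv(outdir / f"candidates_{cid}.tsv", sep="\t",
                                 index=False)
    up, down = diff.up, diff.down
    report["differential"] = {
        "per_cohort_candidates": {cid: int(t["candidate"].sum())
                                  for cid, t in diff.per_cohort.items()},
        "n_up": len(up), "n_down": len(down),
        "up": sorted(up), "down": sorted(down)}
    logger.info("differential: %d up, %d down", len(up), len(down))

    # ---- stage 3: network ------------------------------------------------
    graph = network.filter_graph(graph_full, min_confidence=config.min_confidence)
    seeds = sorted(up | down)
    subnet, mapping = network.induced_subnetwork(graph, seeds) if seeds else (None, None)
    if subnet is not None:
        # pool 1: proteins quantified in all cohorts; pool 2: FC>cutoff in >=3/4
        prot = differential.protein_table(cohorts, score_cutoff=config.score_min)
        detected_all = set(prot.dropna().index)
        fc_cols = [c for c in conc.columns if c.startswith("fc_")]
        n_above = ((conc[fc_cols] > config.fc_cutoff).sum(axis=1)
                   + (conc[fc_cols] < 1 / config.fc_cutoff).sum(axis=1))
        pool2 = set(conc.index[n_above >= config.min_cohorts])
        hubs, skipped = network.select_hubs(
            graph, seeds, [detected_all, pool2], n_per_pool=2,
            exclusion=set(config.exclusion))
        hub_symbols = [h.symbol for h in hubs]
        regulators = [r for r in config.regulators if r in graph]
        augmented = network.augment_with_hubs(graph, subnet, hub_symbols,
                                              regulators)
        topo_seed = network.topology_metrics(subnet)
        topo_aug = network.topology_metrics(augmented)
        layers = (network.assign_layers(augmented, regulators)
                  if regulators else None)
        fcs = conc.loc[[s for s in augmented.nodes if s in conc.index],
                       fc_cols].mean(axis=1).to_dict()
        network.node_attribute_table(augmented, layers, fcs).reset_index().to_csv(
            outdir / "network_nodes.tsv", sep="\t", index=False)
        tio.write_edges_tsv(augmented, outdir / "network_edges.tsv")
        report["network"] = {
            "n_seeds": len(seeds),
            "unmapped_seeds": mapping.unmapped,
            "n_components_seed_network": mapping.n_components,
            "hubs": [{"symbol": h.symbol, "pool": h.pool_id,
                      "links": h.links_to_seed} for h in hubs],
            "hub_skips": [{"symbol": h.symbol, "pool": h.pool_id,
                           "links": h.links_to_seed} for h in skipped],
            "topology_seed_network": topo_seed.as_dict(),
            "topology_augmented": topo_aug.as_dict(),
        }
        (outdir / "topology.json").write_text(
            json.dumps(report["network"], indent=2, sort_keys=True,
                       default=_json_default) + "\n")
        if annotation:
            enr = network.geneset_enrichment(
                set(seeds), annotation, set(graph_full.nodes))
            enr.reset_index().to_csv(outdir / "enrichment.tsv", sep="\t",
                                     index=False)
            report["enrichment_top_terms"] = enr.head(3).reset_index()[
                ["term", "overlap", "p", "q"]].to_dict("records")
    else:
        report["network"] = {"n_seeds": 0}

    # ---- stage 4: cross-species integration ------------------------------
    integ = crossspecies.integrate(
        up, down, mouse, panel, secretome_ratios=secretome,
        f20_cutoff=config.f20_cutoff, up_cutoff=config.secretome_up,
        down_cutoff=config.secretome_down)
    integ.provenance_table().reset_index().to_csv(
        outdir / "refined_signature.tsv", sep="\t", index=False)
    signature = integ.signature
    report["integration"] = {
        "n_mouse_f20": len(integ.mouse_set),
        "n_common": len(integ.common),
        "removed_not_in_celllines": sorted(integ.removed_not_in_celllines),
        "n_secretome_up": len(integ.secretome_up),
        "n_secretome_down": len(integ.secretome_down),
        "secretome_overlap_with_signature": sorted(
            set(signature) & (integ.secretome_up | integ.secretome_down)),
        "signature": signature}
    logger.info("refined signature: %s", signature)

    # ---- stage 5: survival ------------------------------------------------
    genes = signature or signature_genes_cfg or []
    missing_expr = [g for g in genes if g not in surv_df.columns]
    genes = [g for g in genes if g in surv_df.columns]
    if missing_expr:
        logger.warning("no expression data for signature gene(s) %s; "
                       "evaluating the remaining %d", missing_expr, len(genes))
    if genes:
        model = survival.SignatureSurvivalModel.from_dataframe(surv_df, genes)
        res = model.fit(high_fraction=config.high_fraction)
        for group, curve in res.km_curves.items():
            curve.reset_index().to_csv(outdir / f"km_{group}.tsv", sep="\t",
                                       index=False)
        fit_report = {
            "genes": genes,
            "genes_without_expression": missing_expr,
            "n_high": res.stratification.n_high,
            "n_low": res.stratification.n_low,
            "logrank_chi2": res.logrank.statistic,
            "logrank_p": res.logrank.pvalue,
            "cox_univariate": res.cox_univariate.reset_index().to_dict("records"),
            "cox_multivariate": res.cox_multivariate.reset_index().to_dict("records"),
        }
        corr = survival.tgfb_correlation(surv_df, genes)
        fit_report["tgfb_correlation"] = corr.reset_index().to_dict("records")
        report["survival"] = fit_report
        (outdir / "survival_fit.json").write_text(
            json.dumps(fit_report, indent=2, sort_keys=True,
                       default=_json_default) + "\n")
    else:
        report["survival"] = {"skipped": "signature genes absent from cohort"}

    # ---- stage 6: report --------------------------------------------------
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n")
    (outdir / "report.txt").write_text(_render_report(report))
    if truth is not None:
        recovered_up = set(report["differential"]["up"])
        report["truth_check"] = {
            "signature_matches_planted":
                signature == sorted(truth.signature_genes),
            "n_up_recovered": len(recovered_up & truth.up_proteins),
        }
    return PipelineResult(outdir=outdir, report=report, signature=signature)


def _render_report(report: dict) -> str:
    lines = ["Plasma progression-signature pipeline report",
             f"seed: {report['seed']}", "",
             "Thresholds: " + ", ".join(f"{k}={v}" for k, v in
                                        sorted(report["thresholds"].items())), ""]
    d = report["differential"]
    lines.append(f"Differential: {d['n_up']} up, {d['n_down']} down "
                 f"(per-cohort candidates: "
                 + ", ".join(f"{k}={v}" for k, v in
                             sorted(d["per_cohort_candidates"].items())) + ")")
    net = report.get("network", {})
    if "topology_seed_network" in net:
        t = net["topology_seed_network"]
        lines.append(
            f"Seed network: {t['n_nodes']} nodes, {t['n_edges']} edges, "
            f"{net['n_components_seed_network']} components; clustering "
            f"{t['clustering_coefficient']:.3f}, mean degree "
            f"{t['avg_neighbors']:.3f}, path length "
            + (f"{t['characteristic_path_length']:.3f}"
                if t["characteristic_path_length"] else "undefined"))
        hubs = ", ".join(f"{h['symbol']}({h['links']})" for h in net["hubs"])
        lines.append(f"Hubs added: {hubs or 'none'}")
        if net["hub_skips"]:
            skips = ", ".join(f"{h['symbol']}({h['links']})"
                              for h in net["hub_skips"])
            lines.append(f"Excluded top-ranked hubs: {skips}")
    integ = report["integration"]
    lines.append(f"Cross-species: {integ['n_common']} common proteins, "
                 f"signature = {', '.join(integ['signature']) or '(empty)'}")
    surv = report["survival"]
    if "logrank_p" in surv:
        uni = {r["covariate"]: r for r in surv["cox_univariate"]}
        hr = uni["risk_high"]
        lines.append(
            f"Survival: high {surv['n_high']} / low {surv['n_low']}; log-rank "
            f"p = {surv['logrank_p']:.4g}; HR(high vs low) = {hr['HR']:.3f} "
            f"(95% CI {hr['ci_lower']:.3f}-{hr['ci_upper']:.3f})")
    return "\n".join(lines) + "\n"
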