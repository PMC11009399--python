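"""End-to-end orchestration: simulate -> filter -> segment -> ncm -> network -> enrich.

Stage interfaces are files (TSV/FASTA/JSON) under a single output directory,
so any stage can be re-run from checkpoints or fed with real upstream tool
outputs in place of the synthetic inputs.  Identical configuration and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichstats, filtering, ncm, network, segmentation, synthdata
from .containers import AbundanceMatrix

__all__ = ["PipelineConfig", "run_pipeline", "stratified_ncm"]


@dataclass
class PipelineConfig:
    outdir: str = "plasmidome_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    run_filter: bool = True
    run_segment: bool = True
    run_ncm: bool = True
    run_network: bool = True
    run_enrich: bool = True
    # thresholds
    min_cov: float = 0.70
    depth_cutoff_fraction: float = 0.01
    dedup_identity: float = 0.95
    dedup_coverage: float = 0.95
    segment_min_len: int = 1000
    segment_min_id: float = 0.80
    cluster_min_id: float = 0.80
    cluster_mutual_cov: float = 0.90
    selection_pct: float = 95.0
    selection_rule: str = "quantile"
    n_perm: int = 1000
    fdr_alpha: float = 0.05
    enrich_gene_ratio: float = 0.1
    enrich_q_max: float = 0.01
    sim: synthdata.SimulationConfig = field(default_factory=synthdata.SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = synthdata.SimulationConfig(**data.pop("sim", {}))
        return cls(sim=sim, **data)

    def fingerprint(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # paths are not part of the scientific configuration
        d["sim"]["planted_selection"] = [list(t) for t in d["sim"]["planted_selection"]]
        return d


def _read_inputs(indir: Path):
    abundance = pd.read_csv(indir / "abundance.tsv", sep="\t", index_col=0)
    coverage = pd.read_csv(indir / "coverage.tsv", sep="\t", index_col=0)
    depth = pd.read_csv(indir / "read_depth.tsv", sep="\t", index_col=0)["read_depth"]
    metadata = pd.read_csv(indir / "metadata.tsv", sep="\t", index_col=0)
    annotations = pd.read_csv(indir / "annotations.tsv", sep="\t", index_col=0)
    sequences = synthdata.read_fasta(indir / "plasmids.fasta")
    return AbundanceMatrix(abundance, coverage, depth), metadata, annotations, sequences


def _segment_annotations(clusters, plasmid_annotations: pd.DataFrame) -> dict:
    """Segment clusters inherit the pathway labels of their member plasmids."""
    out = {}
    for cl in clusters:
        labels: set = set()
        for pid in cl.member_plasmids:
            spec = plasmid_annotations.loc[pid, "pathways"]
            if isinstance(spec, str) and spec:
                labels.update(spec.split(";"))
        out[cl.cluster_id] = sorted(labels)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    indir = outdir / "input"
    report: dict = {"config": config.fingerprint(), "counts": {}, "ncm": {},
                    "network": {}, "enrichment": {}}

    if config.simulate:
        synthdata.simulate_study(config.sim, outdir=indir)
    abund, metadata, annotations, sequences = _read_inputs(indir)
    report["counts"]["plasmids_input"] = int(abund.abundance.shape[1])
    report["counts"]["samples"] = int(abund.abundance.shape[0])

    # ---- filtering -------------------------------------------------------
    if config.run_filter:
        presence = filtering.call_presence(abund, min_cov=config.min_cov)
        report["counts"]["plasmids_covered"] = int(presence.any(axis=0).sum())
        presence, cutoff = filtering.apply_depth_cutoff(
            abund, presence, fraction=config.depth_cutoff_fraction)
        report["counts"]["depth_cutoff"] = cutoff
        # keep columns for dropped plasmids so segment mapping stays total
        presence = presence.reindex(columns=abund.entity_ids, fill_value=False)
    else:
        presence = abund.abundance.gt(0)
        report["counts"]["plasmids_covered"] = int(presence.any(axis=0).sum())
    report["counts"]["plasmids_present"] = int(presence.any(axis=0).sum())
    presence.to_csv(outdir / "presence.tsv", sep="\t")

    # ---- segmentation ----------------------------------------------------
    incidence = None
    clusters = []
    if config.run_segment:
        hits = segmentation.find_shared_segments(
            sequences, min_len=config.segment_min_len, min_id=config.segment_min_id,
            presence=presence)
        clusters = segmentation.cluster_segments(
            hits, sequences, min_id=config.cluster_min_id,
            mutual_cov=config.cluster_mutual_cov)
        incidence = segmentation.segment_incidence(clusters, presence)
        report["counts"]["segment_hits"] = len(hits)
        report["counts"]["segment_clusters"] = len(clusters)
        report["counts"]["segment_clusters_shared"] = int(incidence.shape[1])
        pd.DataFrame(
            [(cl.cluster_id, pid, s, e, round(iden, 4))
             for cl in clusters for pid, s, e, iden in cl.members],
            columns=["cluster_id", "plasmid_id", "start", "end", "identity"],
        ).to_csv(outdir / "segment_members.tsv", sep="\t", index=False)
        incidence.astype(int).to_csv(outdir / "segment_incidence.tsv", sep="\t")

    # ---- neutral community model ----------------------------------------
    selected_plasmids: list = []
    if config.run_ncm:
        d = ncm.default_detection_limit(abund.abundance)
        report["ncm"] = stratified_ncm(abund.abundance, presence, metadata,
                                       annotations, d=d)
        stats_all = ncm.occurrence_stats(abund.abundance, presence)
        fit_all = ncm.fit_ncm(stats_all, d)
        selected_plasmids = sorted(
            ncm.select_deviant(fit_all, pct=config.selection_pct,
                               rule=config.selection_rule).tolist())
        frame = fit_all.to_frame()
        frame["selected"] = frame["entity_id"].isin(selected_plasmids)
        frame.to_csv(outdir / "ncm_fit.tsv", sep="\t", index=False)
        report["ncm"]["selected_entities"] = selected_plasmids
        ncm.plot_fit(fit_all, outdir / "ncm_fit.png", selected=selected_plasmids)
        (outdir / "ncm_summary.json").write_text(
            json.dumps({"Nm": fit_all.Nm, "d": d, "R2": fit_all.r2,
                        "n_samples": stats_all.n_samples}, indent=1, sort_keys=True))

    # ---- sharing network -------------------------------------------------
    sig_segments: dict = {}
    if config.run_network and incidence is not None and incidence.shape[1] >= 1:
        net = network.build_sharing_network(incidence, metadata)
        ens = network.NullEnsemble(incidence, n_perm=config.n_perm, seed=config.seed)
        groups = network.group_connectivity_test(incidence, metadata, ens)
        edges = network.edge_significance(net, ens, alpha=config.fdr_alpha)
        segs = network.segment_significance(incidence, metadata, ens,
                                            alpha=config.fdr_alpha)
        ratios, ratio_tests = network.strength_ratio(net)
        xcont = network.cross_continental_summary(edges)
        groups.to_csv(outdir / "group_tests.tsv", sep="\t", index=False)
        edges.to_csv(outdir / "edge_significance.tsv", sep="\t", index=False)
        segs.to_csv(outdir / "segment_significance.tsv", sep="\t", index=False)
        ratios.to_csv(outdir / "strength_ratios.tsv", sep="\t")
        import networkx as nx
        nx.write_graphml(net.to_networkx(), outdir / "network.graphml")
        report["network"]["density"] = net.density
        report["network"]["significant_groups"] = groups.loc[
            groups["q"] <= config.fdr_alpha, "group"].tolist()
        for d_ in sorted(segs["disease"].unique()):
            sub = segs[segs["disease"] == d_]
            sig_segments[d_] = sub.loc[sub["significant"], "segment"].tolist()
            report["network"].setdefault("selected_segment_fraction", {})[d_] = \
                float(sub["significant"].mean())
        report["network"]["cross_continental"] = xcont.to_dict(orient="records")

    # ---- enrichment ------------------------------------------------------
    if config.run_enrich and clusters:
        seg_annot = _segment_annotations(clusters, annotations)
        background = list(seg_annot)
        rows = []
        for d_, segs_sel in sig_segments.items():
            segs_sel = [s for s in segs_sel if s in seg_annot]
            if not segs_sel:
                continue
            table = enrichstats.hypergeom_enrich(
                segs_sel, background, seg_annot,
                min_gene_ratio=config.enrich_gene_ratio, q_max=config.enrich_q_max)
            table.insert(0, "disease", d_)
            rows.append(table)
        enrich = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["enrichment"]["n_terms"] = int(len(enrich))
        life_table, life_tests = enrichstats.lifestyle_proportion_tests(
            presence, annotations, metadata)
        life_table.to_csv(outdir / "lifestyle_stats.tsv", sep="\t", index=False)
        lengths, length_test = enrichstats.adjusted_length_compare(annotations)
        lengths.to_csv(outdir / "length_stats.tsv", sep="\t")
        report["enrichment"]["adjusted_length"] = length_test

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                   default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def stratified_ncm(abundance: pd.DataFrame, presence: pd.DataFrame,
                   metadata: pd.DataFrame, annotations: pd.DataFrame,
                   d: float, min_entities: int = 10) -> dict:
    """NCM fits per disease, per lifestyle, and per disease x lifestyle.

    Disease strata subset samples; lifestyle strata subset entities.  Strata
    with fewer than ``min_entities`` informative entities are skipped with a
    note.  R^2 ratios are reported relative to the healthy stratum when one
    exists.
    """
    out: dict = {"strata": {}, "skipped": []}

    def _fit(label, abund_s, pres_s, entities=None):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stats = ncm.occurrence_stats(abund_s, pres_s, entities=entities)
                if len(stats) < min_entities:
                    out["skipped"].append(label)
                    return
                fit = ncm.fit_ncm(stats, d)
            out["strata"][label] = {"Nm": fit.Nm, "R2": fit.r2,
                                    "n_entities": len(stats)}
        except ValueError:
            out["skipped"].append(label)

    _fit("all", abundance, presence)
    lifestyles = annotations["lifestyle"] if "lifestyle" in annotations else None
    for disease in sorted(metadata["disease"].unique()):
        rows = metadata.index[metadata["disease"] == disease].intersection(abundance.index)
        _fit(f"disease:{disease}", abundance.loc[rows], presence.loc[rows])
        if lifestyles is not None:
            for life in sorted(lifestyles.unique()):
                ents = [e for e in abundance.columns
                        if lifestyles.get(e) == life]
                _fit(f"disease:{disease}|lifestyle:{life}",
                     abundance.loc[rows], presence.loc[rows], entities=ents)
    if lifestyles is not None:
        for life in sorted(lifestyles.unique()):
            ents = [e for e in abundance.columns if lifestyles.get(e) == life]
            _fit(f"lifestyle:{life}", abundance, presence, entities=ents)
    healthy = out["strata"].get("disease:healthy")
    if healthy and healthy["R2"]:
        out["r2_ratio_vs_healthy"] = {
            k: v["R2"] / healthy["R2"] for k, v in out["strata"].items()
            if k.startswith("disease:") and "|" not in k}
    return out
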