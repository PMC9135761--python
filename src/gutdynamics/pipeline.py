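"""End-to-end orchestration of the analysis stages with a declarative
YAML config, fixed fan-out seeds, and structured per-stage logging.

Stage order: simulate -> qc -> genescore -> label -> organ_specific ->
temporal -> ko.  Every stage writes its artifacts under
``<outdir>/<stage>/`` and appends a structured record to the run report;
the resolved config (with its hash) is echoed into the output directory,
and a rerun with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genescore as gs
from . import ko as kom
from . import specificity as sp
from . import temporal as tp
from .genomics import (
    PeakSet, parse_bed, parse_pwm, read_fasta, read_labeled_matrix,
    read_fragments_frame, write_labeled_matrix,
)
from .simulate import PlantedTruth, SimConfig, simulate_to_dir

logger = logging.getLogger("gutdynamics")

STAGES = ["simulate", "qc", "genescore", "label", "organ_specific", "temporal", "ko"]

# fixed per-stage seed offsets fanned out from the global seed
SEED_OFFSETS = {
    "simulate": 0, "qc": 101, "genescore": 202, "label": 303,
    "organ_specific": 404, "temporal": 505, "ko": 606,
}


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration key/value."""


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; defaults are the study thresholds."""

    outdir: str = "gutdynamics_run"
    seed: int = 1
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    inputs: dict = field(default_factory=dict)       # explicit input paths
    min_fragments: int = 1000
    min_tss: float = 4.0
    fold_min: float = 2.5
    ko_fold: float = 2.0
    flank_bp: int = 50_000
    n_top_genes: int = 200
    n_top_peaks: int = 2000
    fdr_max: float = 0.05
    log2fc_genes: float = 1.5
    log2fc_peaks: float = 1.0
    repress_fc: float = 0.5
    pseudocount: float = 0.5
    kmeans_k: int = 8
    n_background: int = 50

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + SEED_OFFSETS[stage]) % (2**31)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load, type-check and default-fill a pipeline config.

    Unknown keys are rejected by name.  For enabled stages that consume
    explicit input paths (when the simulate stage is disabled), file
    existence is checked up front.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    if overrides:
        raw = {**raw, **overrides}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" in raw:
        bad = set(raw["stages"]) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stage toggle(s): {sorted(bad)}")
        stages = {s: True for s in STAGES}
        stages.update({k: bool(v) for k, v in raw["stages"].items()})
        raw = {**raw, "stages": stages}
    if "sim" in raw:
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(raw["sim"]) - sim_known
        if bad:
            raise ConfigError(f"unknown sim key(s): {sorted(bad)}")
    cfg = PipelineConfig(**raw)
    for f in dataclasses.fields(PipelineConfig):
        val = getattr(cfg, f.name)
        if f.name in ("min_fragments", "flank_bp", "n_top_genes", "n_top_peaks",
                      "kmeans_k", "n_background", "seed") and not isinstance(val, int):
            raise ConfigError(f"config key {f.name!r} must be an integer")
    if not cfg.stages.get("simulate", True):
        needed = {
            "qc": ["fragments", "genes"],
            "organ_specific": ["bulk_early_prefix"],
        }
        for stage, keys in needed.items():
            if cfg.stages.get(stage):
                for key in keys:
                    p = cfg.inputs.get(key)
                    if p is None or not Path(p).exists():
                        raise ConfigError(
                            f"stage {stage!r} enabled but input {key!r} missing or absent on disk"
                        )
    return cfg


def write_resolved_config(cfg: PipelineConfig, outdir: Path) -> None:
    payload = cfg.to_dict()
    payload["_config_hash"] = cfg.config_hash()
    (outdir / "config.resolved.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 gene annotation (score column = length class) with TSS."""
    genes = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "name", "length_class", "strand"],
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    return genes


def _log_stage(report: dict, stage: str, status: str, t0: float, **info) -> None:
    rec = {"stage": stage, "status": status, "seconds": round(time.time() - t0, 2), **info}
    report["stages"].append(rec)
    logger.info("stage=%s status=%s %s", stage, status, info)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every enabled stage in dependency order; returns the report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_resolved_config(cfg, outdir)
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": []}
    state: dict = {}

    for stage in STAGES:
        if not cfg.stages.get(stage, True):
            continue
        t0 = time.time()
        try:
            info = _STAGE_FUNCS[stage](cfg, outdir, state)
            _log_stage(report, stage, "ok", t0, **(info or {}))
        except Exception as exc:  # stage failure: retain partial outputs
            _log_stage(report, stage, "failed", t0, error=str(exc))
            break
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str) + "\n")
    return report


# ---------------------------------------------------------------------------
# Stage implementations

def _stage_simulate(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    sim_cfg = SimConfig(seed=cfg.stage_seed("simulate"), **cfg.sim)
    simdir = outdir / "sim"
    truth = simulate_to_dir(sim_cfg, simdir)
    state["simdir"] = simdir
    state["sim_cfg"] = sim_cfg
    state["truth"] = truth
    return {"n_peaks": sim_cfg.n_peaks_total, "n_cells": sim_cfg.n_cells_per_organ * len(sim_cfg.organs)}


def _resolve(cfg: PipelineConfig, state: dict, key: str, sim_name: str) -> Path:
    if key in cfg.inputs:
        return Path(cfg.inputs[key])
    if "simdir" in state:
        return state["simdir"] / sim_name
    raise ConfigError(f"no input path for {key!r} and simulate stage disabled")


def _stage_qc(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    frags = read_fragments_frame(_resolve(cfg, state, "fragments", "fragments.tsv"))
    genes = read_genes_bed(_resolve(cfg, state, "genes", "genes.bed"))
    totals = frags.groupby("barcode")["count"].sum()
    tss = gs.compute_tss_enrichment(frags, genes)
    profiles = pd.DataFrame(
        {"n_fragments": totals, "tss_enrichment": tss.reindex(totals.index, fill_value=0.0)}
    )
    retained, qc_report = gs.qc_filter_cells(profiles, cfg.min_fragments, cfg.min_tss)
    stagedir = outdir / "qc"
    stagedir.mkdir(exist_ok=True)
    profiles.assign(retained=profiles.index.isin(retained.index)).to_csv(
        stagedir / "qc_report.tsv", sep="\t"
    )
    state["fragments"] = frags
    state["genes"] = genes
    state["retained_barcodes"] = retained.index
    return qc_report


def _stage_genescore(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    frags = state["fragments"]
    keep = frags["barcode"].isin(state["retained_barcodes"])
    frags = frags.loc[keep]
    contig_lengths = {
        c: int(frags.loc[frags["contig"] == c, "end"].max()) + 1000
        for c in frags["contig"].unique()
    }
    mat, bins, barcodes = gs.bin_fragment_counts(frags, 500, contig_lengths)
    scores = gs.compute_gene_scores(mat, bins, barcodes, state["genes"])
    stagedir = outdir / "genescore"
    stagedir.mkdir(exist_ok=True)
    write_labeled_matrix(
        scores.to_numpy(), list(scores.index), list(scores.columns), stagedir / "gene_scores"
    )
    state["gene_scores"] = scores
    return {"n_genes": scores.shape[0], "n_cells": scores.shape[1]}


def _stage_label(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    cells = pd.read_csv(_resolve(cfg, state, "cells", "cells.tsv"), sep="\t")
    clusters = cells.set_index("barcode")["organ"]  # true clusters are inputs
    truth: PlantedTruth | None = state.get("truth")
    if truth is None and "markers" not in cfg.inputs:
        raise ConfigError("label stage needs a marker table (inputs.markers) or simulated truth")
    if truth is not None:
        markers = gs.MarkerTable(primary=truth.marker_genes)
    else:
        markers = gs.MarkerTable(primary=json.loads(Path(cfg.inputs["markers"]).read_text()))
    scores = state["gene_scores"]
    assignment, flagged = gs.assign_organ_labels(
        scores, clusters.reindex(scores.columns), markers
    )
    stagedir = outdir / "label"
    stagedir.mkdir(exist_ok=True)
    pd.Series(assignment, name="organ").rename_axis("cluster").to_csv(
        stagedir / "cluster_labels.tsv", sep="\t"
    )
    info = {"n_clusters": len(assignment), "ties_flagged": len(flagged)}
    if truth is not None:
        correct = sum(1 for cl, org in assignment.items() if cl == org)
        info["label_recovery"] = correct / max(len(assignment), 1)
    state["cluster_labels"] = assignment
    state["cells"] = cells
    return info


def _mean_by_organ(frame: pd.DataFrame) -> pd.DataFrame:
    organs = sorted({c.rsplit("_rep", 1)[0] for c in frame.columns})
    return pd.DataFrame(
        {o: frame[[c for c in frame.columns if c.rsplit("_rep", 1)[0] == o]].mean(axis=1)
         for o in organs}
    )


def _stage_organ_specific(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    sim_cfg: SimConfig = state["sim_cfg"]
    early, late = sim_cfg.stage_pairs[0]
    stagedir = outdir / "organ_specific"
    stagedir.mkdir(exist_ok=True)
    peaks = parse_bed(_resolve(cfg, state, "peaks", "peaks.bed"))
    called = {}
    for stage_label in (early, late):
        counts = read_labeled_matrix(
            state["simdir"] / f"bulk_atac_{stage_label.replace('.', '_')}"
        )
        signal = _mean_by_organ(sp.depth_normalize(counts))
        sets = sp.call_organ_specific_peaks(
            signal, k=cfg.kmeans_k, seed=cfg.stage_seed("organ_specific"),
            fold_min=cfg.fold_min,
        )
        called[stage_label] = sets
        for organ, s in sets.items():
            (stagedir / f"specific_peaks_{stage_label.replace('.', '_')}_{organ}.tsv").write_text(
                "\n".join(s.features) + ("\n" if s.features else "")
            )
    grid = sp.overlap_enrichment_grid(
        {o: peaks.subset(s.features) for o, s in called[early].items() if s.features},
        {o: peaks.subset(s.features) for o, s in called[late].items() if s.features},
        peaks,
    )
    grid.to_csv(stagedir / "overlap_enrichment.tsv", sep="\t", index=False)
    state["organ_specific"] = called
    state["peaks"] = peaks
    info: dict = {}
    truth: PlantedTruth | None = state.get("truth")
    if truth is not None:
        recov = {}
        for organ, planted in truth.organ_specific_peaks.items():
            got = set(called[early][organ].features)
            recov[organ] = len(got & set(planted)) / max(len(planted), 1)
        info["specific_peak_recovery"] = round(float(np.mean(list(recov.values()))), 4)
    return info


def _stage_temporal(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    sim_cfg: SimConfig = state["sim_cfg"]
    early, late = sim_cfg.stage_pairs[0]
    stagedir = outdir / "temporal"
    stagedir.mkdir(exist_ok=True)
    genes = state["genes"]
    peaks: PeakSet = state["peaks"]
    simdir = state["simdir"]
    expr_e = pd.read_csv(simdir / f"expression_{early.replace('.', '_')}.tsv", sep="\t", index_col=0)
    expr_l = pd.read_csv(simdir / f"expression_{late.replace('.', '_')}.tsv", sep="\t", index_col=0)
    bulk_e = _mean_by_organ(sp.depth_normalize(
        read_labeled_matrix(simdir / f"bulk_atac_{early.replace('.', '_')}")))
    bulk_l = _mean_by_organ(sp.depth_normalize(
        read_labeled_matrix(simdir / f"bulk_atac_{late.replace('.', '_')}")))

    organs = list(expr_e.columns)
    top_genes, top_peaks = {}, {}
    for organ in organs:
        top_genes[organ], _ = tp.rank_temporal_changes(
            expr_e[organ], expr_l[organ], cfg.n_top_genes, cfg.pseudocount)
        top_peaks[organ], _ = tp.rank_temporal_changes(
            bulk_e[organ], bulk_l[organ], cfg.n_top_peaks, cfg.pseudocount)

    # association-score matrix: gene-set organ x peak-set organ
    scores = pd.DataFrame(index=organs, columns=organs, dtype=float)
    tallies = {}
    G = len(genes)
    for po in organs:
        mapping = tp.associate_genes_peaks(genes, peaks.subset(top_peaks[po]), cfg.flank_bp)
        O = sum(1 for v in mapping.values() if v)
        for go in organs:
            target = top_genes[go]
            O_T = sum(1 for g in target if mapping.get(g))
            scores.loc[go, po] = tp.association_score(
                tp.AssociationInput(G=G, O=O, G_T=len(target), O_T=O_T, flank_bp=cfg.flank_bp))
            if go == po:
                tallies[go] = (O_T, len(target))
    scores.to_csv(stagedir / "association_scores.tsv", sep="\t")

    # relative motif enrichment on the first organ's early/late signal
    motifs = parse_pwm(simdir / "motifs.pwm")
    genome = read_fasta(simdir / "genome.fa")
    sites = {m.id: tp.scan_pwm(m, genome) for m in motifs}
    organ0 = organs[0]
    results = tp.relative_motif_enrichment(
        peaks, bulk_e[organ0], bulk_l[organ0], sites, cfg.pseudocount)
    pd.DataFrame(
        [(r.motif_id, r.n_sites_in_peaks, r.score, r.direction, r.p) for r in results],
        columns=["motif", "n_sites", "score", "direction", "p"],
    ).to_csv(stagedir / "motif_scores.tsv", sep="\t", index=False)

    # lineage restriction: organ open/closed peak sets from bulk signal
    def _open_sets(signal: pd.DataFrame) -> dict[str, PeakSet]:
        peak_max = signal.max(axis=1)
        return {
            o: peaks.subset(signal.index[signal[o] >= 0.5 * peak_max])
            for o in signal.columns
        }
    pair = tuple(organs[:2])
    lineage = tp.lineage_restriction(
        _open_sets(bulk_e), {o: s for o, s in _open_sets(bulk_l).items() if o in pair},
        expr_e, expr_l, genes, organ_pair=pair,
        flank_bp=cfg.flank_bp, repress_fc=cfg.repress_fc, pseudocount=cfg.pseudocount,
    )
    (stagedir / "lineage_restriction.json").write_text(json.dumps({
        "counts": {k: list(v) for k, v in lineage.counts.items()},
        "binomial_p": lineage.binomial_p,
    }, indent=1) + "\n")
    state["top_genes"] = top_genes
    state["top_peaks"] = top_peaks
    return {
        "association_diag_mean": round(float(np.diag(scores.to_numpy(dtype=float)).mean()), 3),
        "tallies": {k: f"{v[0]}/{v[1]}" for k, v in tallies.items()},
    }


def _stage_ko(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    stagedir = outdir / "ko"
    stagedir.mkdir(exist_ok=True)
    simdir = state["simdir"]
    peaks: PeakSet = state["peaks"]
    counts = read_labeled_matrix(simdir / "bulk_atac_ko")
    norm = sp.depth_normalize(counts)
    ko_cols = [c for c in norm.columns if c.startswith("KO")]
    wt_cols = [c for c in norm.columns if c.startswith("WT")]
    cats = kom.categorize_ko_peaks(norm[ko_cols], norm[wt_cols], peaks, fold=cfg.ko_fold,
                                   pseudocount=cfg.pseudocount)
    for cat, names in cats.as_dict().items():
        sub = peaks.subset(names)
        sub.df.to_csv(stagedir / f"peaks_{cat}.bed", sep="\t", header=False, index=False)

    # project peak fates onto single cells
    frags = state["fragments"]
    frags = frags[frags["barcode"].isin(state["retained_barcodes"])]
    mat, pnames, barcodes = gs.count_fragments_in_peaks(frags, peaks)
    dev_rows = {}
    for cat, names in cats.as_dict().items():
        if not names:
            continue
        dev = kom.deviation_zscore(
            mat, pnames, barcodes, names, n_background=cfg.n_background,
            seed=cfg.stage_seed("ko"))
        dev_rows[cat] = dev.z
    pd.DataFrame(dev_rows).to_csv(stagedir / "deviation_zscores.tsv", sep="\t")

    organ_sets = {
        o: peaks.subset(s.features)
        for o, s in state.get("organ_specific", {}).get(
            state["sim_cfg"].stage_pairs[0][1], {}).items() if s.features
    }
    if organ_sets:
        frac = kom.organ_overlap_fractions(cats, peaks, organ_sets)
        frac.to_csv(stagedir / "organ_overlap_fractions.tsv", sep="\t")

    de_lists = {}
    for organ in list(state["sim_cfg"].organs)[:2]:
        p = simdir / f"de_up_{organ}.tsv"
        if p.exists():
            de_lists[organ] = [g for g in p.read_text().splitlines() if g]
    info: dict = {"n_gained": len(cats.gained), "n_lost": len(cats.lost)}
    if de_lists:
        table = kom.categorize_genes_by_peakset(
            de_lists, cats, state["genes"], peaks, flank_bp=cfg.flank_bp)
        summary = kom.summarize_category_percentages(table)
        summary.to_csv(stagedir / "gene_category_summary.tsv", sep="\t", index=False)
    truth: PlantedTruth | None = state.get("truth")
    if truth is not None:
        info["ko_gained_recovery"] = round(
            len(set(cats.gained) & set(truth.ko_gained)) / max(len(truth.ko_gained), 1), 4)
        info["ko_lost_recovery"] = round(
            len(set(cats.lost) & set(truth.ko_lost)) / max(len(truth.ko_lost), 1), 4)
    return info


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "genescore": _stage_genescore,
    "label": _stage_label,
    "organ_specific": _stage_organ_specific,
    "temporal": _stage_temporal,
    "ko": _stage_ko,
}
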