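"""End-to-end orchestration: simulate -> quantify -> classify -> mark dynamics
-> stats, driven by a single YAML config, with a run manifest and logging.

Every output table is written with deterministic row order and float
formatting, so two runs with the same config and seed are byte-identical
(the manifest's timestamps are excluded from that contract).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .coverage_quant import metagene_profile, tss_profile
from .genome_io import (
    CoverageTrack,
    GenomicWindow,
    read_coverage,
    read_gene_models,
    read_table,
    write_table,
)
from .mark_dynamics import (
    DEFAULT_MARK_PSEUDOCOUNT,
    GENE_BODY,
    mark_change,
    mark_expression_association,
    select_by_mark_change,
    spreading_summary,
)
from .set_stats import fisher_overlap, mann_whitney_u
from .synthetic_data import SyntheticConfig, write_dataset
from .transcription_analysis import (
    DEFAULT_LENGTH_EDGES,
    S_GAINED,
    S_LOST,
    UNCHANGED,
    classify_regulation,
    combine_fold_changes,
    delta_pi,
    expressed_genes,
    length_stratify,
    log2_fold_change,
    pausing_index,
    pi_curve,
)

__all__ = ["RunConfig", "StageError", "validate_config", "run_pipeline", "load_config"]

log = logging.getLogger("senespread.pipeline")

ALL_STAGES = ("simulate", "quantify", "classify", "pause", "markshift", "stats")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    output_dir: str = "senespread_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    inputs: dict[str, Any] = field(default_factory=dict)  # genes/rna_counts/gro_counts/tracks
    promoter_window: GenomicWindow = field(
        default_factory=lambda: GenomicWindow("tss", -300, 200)
    )
    pausing_promoter_window: GenomicWindow = field(
        default_factory=lambda: GenomicWindow("tss", -50, 300)
    )
    body_from: int = 300
    up_thresh: float = 1.0
    down_thresh: float = -1.0
    expressed_min_density: float = 0.5
    mark_loss_threshold: float = -2.5
    association_bin_edges: list[float] = field(default_factory=lambda: [-2.5, -1.0])
    length_edges: list[int] = field(default_factory=lambda: list(DEFAULT_LENGTH_EDGES))
    mark_pseudocount: float = DEFAULT_MARK_PSEUDOCOUNT
    pausing_track: str = "gro"  # mark name carrying nascent-transcription signal

    def to_dict(self) -> dict:
        d = {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "inputs": {k: str(v) if not isinstance(v, dict) else {m: str(p) for m, p in v.items()}
                       for k, v in self.inputs.items()},
            "promoter_window": _window_dict(self.promoter_window),
            "pausing_promoter_window": _window_dict(self.pausing_promoter_window),
            "body_from": self.body_from,
            "up_thresh": self.up_thresh,
            "down_thresh": self.down_thresh,
            "expressed_min_density": self.expressed_min_density,
            "mark_loss_threshold": self.mark_loss_threshold,
            "association_bin_edges": list(self.association_bin_edges),
            "length_edges": list(self.length_edges),
            "mark_pseudocount": self.mark_pseudocount,
            "pausing_track": self.pausing_track,
        }
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def _window_dict(w: GenomicWindow) -> dict:
    return {"anchor": w.anchor, "rel_start": w.rel_start, "rel_end": w.rel_end}


def _window_from(d: dict) -> GenomicWindow:
    return GenomicWindow(d["anchor"], int(d["rel_start"]), int(d["rel_end"]))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    kwargs: dict[str, Any] = {}
    for key in (
        "output_dir", "seed", "inputs", "body_from", "up_thresh", "down_thresh",
        "expressed_min_density", "mark_loss_threshold", "association_bin_edges",
        "length_edges", "mark_pseudocount", "pausing_track",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        if "length_lognormal" in syn:
            syn["length_lognormal"] = tuple(syn["length_lognormal"])
        if "conditions" in syn:
            syn["conditions"] = tuple(syn["conditions"])
        kwargs["synthetic"] = SyntheticConfig(**syn)
    for key in ("promoter_window", "pausing_promoter_window"):
        if key in raw:
            kwargs[key] = _window_from(raw[key])
    cfg = RunConfig(**kwargs)
    if cfg.synthetic is not None and "seed" in raw:
        cfg.synthetic.seed = cfg.seed
    return cfg


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty means valid.  Never raises."""
    problems: list[str] = []
    if config.synthetic is None:
        for key in ("genes", "rna_counts"):
            path = config.inputs.get(key)
            if path is None:
                problems.append(f"missing input {key!r} and no synthetic config")
            elif not Path(path).exists():
                problems.append(f"input file not found: {path}")
        for mark, path in (config.inputs.get("tracks") or {}).items():
            if not Path(path).exists():
                problems.append(f"track file not found ({mark}): {path}")
        gro = config.inputs.get("gro_counts")
        if gro is not None and not Path(gro).exists():
            problems.append(f"input file not found: {gro}")
    if not config.down_thresh < 0 < config.up_thresh:
        problems.append(
            f"thresholds must satisfy down < 0 < up "
            f"(got down={config.down_thresh}, up={config.up_thresh})"
        )
    edges = list(config.length_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        problems.append(f"length_edges not strictly increasing: {edges}")
    aedges = list(config.association_bin_edges)
    if any(b <= a for a, b in zip(aedges, aedges[1:])):
        problems.append(f"association_bin_edges not strictly increasing: {aedges}")
    for name, val in (
        ("up_thresh", config.up_thresh),
        ("down_thresh", config.down_thresh),
        ("mark_loss_threshold", config.mark_loss_threshold),
        ("expressed_min_density", config.expressed_min_density),
    ):
        if not pd.notna(val) or val in (float("inf"), float("-inf")):
            problems.append(f"threshold {name} must be finite")
    return problems


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Any stage failure raises :class:`StageError` naming the stage.  The
    manifest (also written to ``manifest.json``) records the config echo,
    package version, per-output sha256 hashes, exclusion counts, skipped
    stages and timestamps.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    stages = list(stages) if stages else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(out / "run.log")

    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages_run": [],
        "stages_skipped": [s for s in ALL_STAGES if s not in stages],
        "outputs": {},
        "exclusions": {},
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    state: dict[str, Any] = {}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        log.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state, manifest)
        except Exception as exc:  # surfaced with stage context
            raise StageError(stage, exc) from exc
        manifest["stages_run"].append(stage)
        log.info("stage %s: done", stage)

    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    for p in sorted(out.glob("*")):
        if p.is_file() and p.name not in ("manifest.json", "run.log"):
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _setup_run_logging(path: Path) -> None:
    root = logging.getLogger("senespread")
    root.setLevel(logging.INFO)
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root.addHandler(fh)


# -- stage implementations ---------------------------------------------------


def _load_inputs(config: RunConfig, out: Path, state: dict) -> None:
    """Populate state from files (synthetic outputs or user-supplied paths)."""
    if "genes" in state:
        return
    inputs = state.get("paths") or config.inputs
    state["genes"] = read_gene_models(inputs["genes"])
    rna = read_table(inputs["rna_counts"]).set_index("gene_id")
    state["rna_counts"] = rna
    gro_path = inputs.get("gro_counts")
    state["gro_counts"] = (
        read_table(gro_path).set_index("gene_id") if gro_path else None
    )
    tracks: dict[str, CoverageTrack] = {}
    track_paths = inputs.get("tracks") or {
        k: v for k, v in inputs.items()
        if isinstance(v, (str, Path)) and str(v).endswith(".bedGraph")
    }
    for name, path in track_paths.items():
        tracks[name] = read_coverage(path, label=name)
    state["tracks"] = tracks
    truth_path = inputs.get("ground_truth")
    state["truth"] = read_table(truth_path) if truth_path else None


def _stage_simulate(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    if config.synthetic is None:
        raise ValueError("simulate stage requires an embedded synthetic config")
    paths = write_dataset(config.synthetic, out)
    state["paths"] = {k: p for k, p in paths.items()}
    state["paths"]["tracks"] = {
        k: p for k, p in paths.items() if str(p).endswith(".bedGraph")
    }


def _stage_quantify(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    _load_inputs(config, out, state)
    genes = state["genes"]
    for name, track in sorted(state["tracks"].items()):
        prof = metagene_profile(track, genes)
        write_table(prof.to_frame(), out / f"metagene_{name}.tsv")
        manifest["exclusions"][f"metagene_{name}_short_genes"] = prof.n_excluded_short
        write_table(tss_profile(track, genes), out / f"tss_profile_{name}.tsv")


def _stage_classify(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    _load_inputs(config, out, state)
    genes = state["genes"]
    rna = state["rna_counts"]
    cond_a, cond_b = rna.columns[:2]
    lib = {c: float(rna[c].sum()) for c in rna.columns}
    fc_rna = log2_fold_change(rna[cond_a], rna[cond_b], lib[cond_a], lib[cond_b])
    fc_gro = None
    gro = state["gro_counts"]
    if gro is not None:
        glib = {c: float(gro[c].sum()) for c in gro.columns}
        fc_gro = log2_fold_change(
            gro[cond_a], gro[cond_b], glib[cond_a], glib[cond_b]
        )
    fc = combine_fold_changes(fc_rna, fc_gro)
    exon_len = {g.gene_id: g.exonic_length for g in genes}
    expressed = expressed_genes(
        rna[[cond_a, cond_b]], lib, exon_len, config.expressed_min_density
    )
    calls = classify_regulation(
        fc, expressed, config.up_thresh, config.down_thresh
    )
    write_table(fc.reset_index(), out / "fold_changes.tsv")
    write_table(calls, out / "regulation_calls.tsv")
    state["fc"] = fc
    state["calls"] = calls
    state["expressed"] = expressed


def _tracks_for(state: dict, mark: str) -> tuple[CoverageTrack, CoverageTrack] | None:
    pair = sorted(k for k in state["tracks"] if k.startswith(f"{mark}_"))
    if len(pair) != 2:
        return None
    return state["tracks"][pair[0]], state["tracks"][pair[1]]


def _stage_pause(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    _load_inputs(config, out, state)
    pair = _tracks_for(state, config.pausing_track)
    if pair is None:
        log.info("pause: no %s_* track pair found; stage skipped", config.pausing_track)
        manifest.setdefault("notes", []).append("pause skipped: no nascent track pair")
        return
    track_a, track_b = pair
    genes = state["genes"]
    recs_a = [pausing_index(track_a, g, config.pausing_promoter_window, config.body_from)
              for g in genes]
    recs_b = [pausing_index(track_b, g, config.pausing_promoter_window, config.body_from)
              for g in genes]
    rows = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in recs_a],
            "pi_a": [r.pi for r in recs_a],
            "pi_b": [r.pi for r in recs_b],
            "valid_a": [r.valid for r in recs_a],
            "valid_b": [r.valid for r in recs_b],
        }
    )
    write_table(rows, out / "pausing.tsv")
    manifest["exclusions"]["pausing_invalid_a"] = int((~rows["valid_a"]).sum())
    manifest["exclusions"]["pausing_invalid_b"] = int((~rows["valid_b"]).sum())
    curve = pi_curve(recs_a)
    write_table(curve, out / "pi_curve_a.tsv")
    write_table(pi_curve(recs_b), out / "pi_curve_b.tsv")
    dpi = delta_pi(recs_a, recs_b)
    write_table(dpi.reset_index().rename(columns={"index": "gene_id"}),
                out / "delta_pi.tsv")
    state["pausing"] = (recs_a, recs_b)


def _dynamics_mark(config: RunConfig, state: dict) -> str | None:
    marks = sorted({k.rsplit("_", 1)[0] for k in state["tracks"]})
    marks = [m for m in marks if m != config.pausing_track and _tracks_for(state, m)]
    return marks[0] if marks else None


def _stage_markshift(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    _load_inputs(config, out, state)
    mark = _dynamics_mark(config, state)
    if mark is None:
        log.info("markshift: no two-condition mark track pair; stage skipped")
        manifest.setdefault("notes", []).append("markshift skipped: no mark track pair")
        return
    track_a, track_b = _tracks_for(state, mark)
    genes = state["genes"]
    prom = mark_change(track_a, track_b, genes, config.promoter_window,
                       config.mark_pseudocount)
    body = mark_change(track_a, track_b, genes, GENE_BODY, config.mark_pseudocount,
                       promoter_exclusion_bp=config.body_from)
    write_table(pd.concat([prom, body], ignore_index=True), out / "mark_changes.tsv")
    selected = select_by_mark_change(prom, config.mark_loss_threshold, "below")
    write_table(pd.DataFrame({"gene_id": sorted(selected)}), out / "mark_loss_genes.tsv")

    if "fc" in state:
        assoc = mark_expression_association(prom, state["fc"], config.association_bin_edges)
        write_table(assoc, out / "association_report.tsv")
    binning = length_stratify(genes, config.length_edges)
    records, by_bin = spreading_summary(
        track_a, track_b, genes, config.promoter_window, config.body_from, binning
    )
    write_table(records, out / "spreading.tsv")
    if by_bin is not None:
        write_table(by_bin, out / "spreading_by_length.tsv")
    manifest["exclusions"]["spreading_dropped"] = records.attrs.get("n_dropped", 0)
    merged = body.set_index("gene_id").join(binning.assignment, how="inner")
    body_by_len = (
        merged.groupby("length_bin")["log2fc_mark"]
        .agg(["median", "mean", "count"])
        .reindex(range(binning.n_bins))
        .reset_index()
    )
    body_by_len["length_bin_label"] = binning.labels
    write_table(body_by_len, out / "body_mark_fc_by_length.tsv")
    state["mark_prom"] = prom
    state["mark_body"] = body


def _stage_stats(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    _load_inputs(config, out, state)
    if "calls" not in state:
        log.info("stats: classify outputs unavailable; stage skipped")
        manifest.setdefault("notes", []).append("stats skipped: classify not run")
        return
    genes = {g.gene_id: g for g in state["genes"]}
    calls = state["calls"].set_index("gene_id")
    rows = []
    lengths = {
        lbl: [genes[g].length for g in calls.index[calls["label"] == lbl] if g in genes]
        for lbl in (S_GAINED, S_LOST, UNCHANGED)
    }
    for lbl in (S_GAINED, S_LOST):
        if lengths[lbl] and lengths[UNCHANGED]:
            res = mann_whitney_u(lengths[lbl], lengths[UNCHANGED])
            rows.append(
                {
                    "test": "mannwhitney_length", "group_x": lbl, "group_y": UNCHANGED,
                    "n_x": res.n_x, "n_y": res.n_y,
                    "statistic": res.statistic, "p_value": res.p_value,
                }
            )
    truth = state.get("truth")
    if truth is not None:
        universe = set(calls.index)
        tr = truth.set_index("gene_id")["label"]
        for call_lbl, true_lbl in ((S_GAINED, "GAINED"), (S_LOST, "LOST")):
            called = set(calls.index[calls["label"] == call_lbl])
            planted = set(tr.index[tr == true_lbl]) & universe
            if planted:
                er = fisher_overlap(called, planted, universe)
                rows.append(
                    {
                        "test": "fisher_overlap", "group_x": call_lbl,
                        "group_y": f"planted_{true_lbl}",
                        "n_x": len(called), "n_y": len(planted),
                        "statistic": er.odds_ratio, "p_value": er.p_value,
                        "jaccard": er.jaccard,
                    }
                )
    write_table(pd.DataFrame(rows), out / "stats.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "classify": _stage_classify,
    "pause": _stage_pause,
    "markshift": _stage_markshift,
    "stats": _stage_stats,
}
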