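"""End-to-end orchestration: simulate/ingest → analyze → map → report.

A run is driven by a single declarative :class:`RunConfig` (loadable
from YAML).  Stages execute in dependency order; every artifact is
written under the output directory and the report carries provenance
(config hash, package version, seed), so identical config + seed yields
identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

import sptmap
from sptmap import comovement, compartments, diffusion, simkit, spatial_maps, state_switch
from sptmap import io as spio
from sptmap.errors import ConfigurationError

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "make_report"]

ALL_STAGES = ("simulate", "diffuse", "map", "compartments", "comove", "hmm")


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    output_dir: str = "sptmap_out"
    seed: int = 0
    frame_interval: float = 0.035
    pixel_size: float = 0.107
    stages: tuple[str, ...] = ALL_STAGES
    # input tables (ignored when the simulate stage runs)
    mrna_tracks: Optional[str] = None
    ribo_tracks: Optional[str] = None
    marker_image: Optional[str] = None
    simulate: dict = dc_field(default_factory=dict)
    diffusion: dict = dc_field(default_factory=dict)
    map: dict = dc_field(default_factory=dict)
    compartments: dict = dc_field(default_factory=dict)
    comove: dict = dc_field(default_factory=dict)
    hmm: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_canonical_yaml(self) -> str:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["stages"] = list(self.stages)
        return yaml.safe_dump(data, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_yaml().encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Everything one run produced, with provenance."""

    config_hash: str
    seed: int
    version: str
    sections: dict

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "sptmap_version": self.version,
            },
            "sections": self.sections,
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        # NaN breaks both JSON portability and dict equality (NaN != NaN)
        return float(obj) if np.isfinite(obj) else None
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, diffusion.MsdCurve):
        return _jsonable(obj.to_dataframe().to_dict("list"))
    if isinstance(obj, diffusion.ExplorationArea):
        return {"area_um2": obj.area, "plateau": obj.plateau}
    return obj


def _simulate_stage(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.simulate
    sim = simkit.SimConfig(
        frame_interval=cfg.frame_interval,
        pixel_size=cfg.pixel_size,
        field_size=tuple(p.get("field_size", (20.0, 20.0))),
        n_frames=int(p.get("n_frames", 500)),
        localization_sd=float(p.get("localization_sd", 0.025)),
        mean_track_length=float(p.get("mean_track_length", 6.2)),
        rng_seed=cfg.seed,
    )
    motion_comoving = simkit.MotionSpec(**p.get(
        "motion_comoving", {"kind": "two_state", "D1": 0.4, "D2": 0.1,
                            "k12": 2.0, "k21": 1.0 / 1.3}
    ))
    motion_free = simkit.MotionSpec(**p.get("motion_free", {"kind": "brownian", "D": 0.4}))
    mrna, ribo, gt = simkit.simulate_comoving_channels(
        sim,
        n_mrna=int(p.get("n_mrna", 300)),
        n_ribo=int(p.get("n_ribo", 100)),
        comoving_fraction=float(p.get("comoving_fraction", 0.05)),
        pair_offset_sd=float(p.get("pair_offset_sd", 0.05)),
        motion_comoving=motion_comoving,
        motion_free=motion_free,
    )
    spio.write_tracks(mrna, outdir / "mrna_tracks.csv")
    spio.write_tracks(ribo, outdir / "ribo_tracks.csv")
    gt.write(outdir / "ground_truth")
    section = {"n_mrna_tracks": int(mrna.track_id.nunique()),
               "n_ribo_tracks": int(ribo.track_id.nunique()),
               "n_true_pairs": int(len(gt.pairs))}
    if p.get("adhesion_field", True):
        _, mask, _ = simkit.simulate_adhesion_field(
            sim, n_adhesions=int(p.get("n_adhesions", 8)),
            adhesion_size=float(p.get("adhesion_size", 1.5)),
            D_near=0.1, D_far=0.4, n_tracks=1,
        )
        spio.write_mask(outdir / "adhesion_mask.tif", mask)
        section["adhesion_mask"] = "adhesion_mask.tif"
    return section


def run_pipeline(cfg: RunConfig) -> AnalysisReport:
    """Execute the configured stages and write all artifacts.

    Returns an :class:`AnalysisReport`; the same config and seed produce
    identical artifacts.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sections: dict = {}

    mrna = ribo = None
    mask_img = None
    if "simulate" in cfg.stages:
        sections["simulate"] = _simulate_stage(cfg, outdir)
        mrna = spio.read_tracks(outdir / "mrna_tracks.csv")
        ribo = spio.read_tracks(outdir / "ribo_tracks.csv")
        if (outdir / "adhesion_mask.tif").exists():
            mask_img = spio.read_mask(outdir / "adhesion_mask.tif")
    else:
        if cfg.mrna_tracks:
            mrna = spio.read_tracks(cfg.mrna_tracks)
        if cfg.ribo_tracks:
            ribo = spio.read_tracks(cfg.ribo_tracks)
        if cfg.marker_image:
            mask_img = spio.read_stack(cfg.marker_image)[0] > 0
    if mrna is None and any(
        s in cfg.stages for s in ("diffuse", "map", "compartments", "comove", "hmm")
    ):
        raise ConfigurationError("analysis stages require trajectories (simulate stage or mrna_tracks)")

    dt = cfg.frame_interval
    if "diffuse" in cfg.stages:
        sec = {}
        for name, tr in (("mrna", mrna), ("ribo", ribo)):
            if tr is None or tr.empty:
                continue
            d = diffusion.collect_displacements(tr, 1, dt)
            entry = {"n_displacements": len(d)}
            if len(d) >= 100:
                entry["fit_one"] = diffusion.fit_cdf_one(d)
            if len(d) >= 1000:
                fix = cfg.diffusion.get("fix_D")
                entry["fit_two"] = diffusion.fit_cdf_two(
                    d, fix_D=tuple(fix) if fix else None
                )
            msd = diffusion.msd_ensemble(
                tr, int(cfg.diffusion.get("max_lag_frames", 10)), dt
            )
            msd.to_dataframe().to_csv(outdir / f"msd_{name}.csv", index=False)
            entry["msd_file"] = f"msd_{name}.csv"
            entry["mean_lifetime_s"] = float(diffusion.track_lifetimes(tr, dt).mean())
            sec[name] = entry
        sections["diffuse"] = sec

    if "map" in cfg.stages:
        dmap = spatial_maps.local_diffusion_map(
            mrna, dt,
            grid_spacing=float(cfg.map.get("grid_spacing", 0.020)),
            capture_radius=float(cfg.map.get("capture_radius", 0.080)),
            min_displacements=int(cfg.map.get("min_displacements", 5)),
        )
        dmap.to_dataframe().to_csv(outdir / "diffusion_map_mrna.csv", index=False)
        dens = spatial_maps.density_map(mrna, float(cfg.map.get("bin_size", 0.05)))
        sections["map"] = {
            "n_defined_nodes": int(len(dmap.values)),
            "n_localizations": dens.total,
            "map_file": "diffusion_map_mrna.csv",
        }

    if "compartments" in cfg.stages and mask_img is not None:
        cmask = compartments.CompartmentMask(mask=mask_img, pixel_size=cfg.pixel_size)
        part = compartments.partition_tracks(
            mrna, cmask,
            dilation_radius=float(cfg.compartments.get("dilation_radius", 0.160)),
            min_inside_fraction=float(cfg.compartments.get("min_inside_fraction", 0.0)),
            on_outside="clip",
        )
        part.to_csv(outdir / "partition_mrna.csv", index=False)
        sec = {"n_adhesion_tracks": int((part.label == "adhesion").sum()),
               "n_non_adhesion_tracks": int((part.label == "non_adhesion").sum())}
        if sec["n_adhesion_tracks"] and sec["n_non_adhesion_tracks"]:
            try:
                rep = compartments.compare_compartments(mrna, part, dt)
                sec["report"] = rep.to_dict()
            except ConfigurationError:
                sec["report"] = None
        sections["compartments"] = sec

    if "comove" in cfg.stages and ribo is not None and not ribo.empty:
        pairs = comovement.find_comoving(
            mrna, ribo,
            d_max=float(cfg.comove.get("d_max", 0.320)),
            min_frames=int(cfg.comove.get("min_frames", 3)),
        )
        comovement.pairs_to_dataframe(pairs).to_csv(
            outdir / "comoving_pairs.csv", index=False
        )
        dists = comovement.frame_distances(mrna, ribo)
        dd = comovement.normalized_distance_distribution(
            dists, bin_width=float(cfg.comove.get("bin_width", 0.107)),
            r_max=float(cfg.comove.get("r_max", 3.0)),
        )
        dd.to_dataframe().to_csv(outdir / "distance_distribution.csv", index=False)
        sections["comove"] = {
            "n_pairs": len(pairs),
            "pairs_file": "comoving_pairs.csv",
            "subsets": comovement.comoving_subset_analysis(pairs, mrna, ribo, dt),
        }

    if "hmm" in cfg.stages:
        model = state_switch.select_model(
            mrna, dt,
            K_candidates=tuple(cfg.hmm.get("K_candidates", (1, 2))),
            n_restarts=int(cfg.hmm.get("n_restarts", 2)),
            seed=cfg.seed,
        )
        with open(outdir / "hmm_model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
        anns = state_switch.annotate_tracks(mrna, model)
        pd.concat(
            [a.visits.assign(track_id=a.track_id) for a in anns], ignore_index=True
        ).to_csv(outdir / "hmm_visits.csv", index=False)
        sec = {"model": model.to_dict()}
        if model.K > 1:
            hists = state_switch.duration_histograms(anns, internal_only=True)
            sec["internal_visits"] = {
                s: {"n_visits": h.n_visits, "mean_duration_s": h.mean_duration}
                for s, h in hists.items()
            }
        sections["hmm"] = sec

    report = AnalysisReport(
        config_hash=cfg.config_hash, seed=cfg.seed,
        version=sptmap.__version__, sections=_jsonable(sections),
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return report


def make_report(report: AnalysisReport, path=None) -> str:
    """Render an analysis report as a Markdown document.

    Regenerating from the same report yields a byte-identical body.
    """
    lines = [
        "# sptmap analysis report",
        "",
        f"- config hash: `{report.config_hash}`",
        f"- seed: {report.seed}",
        f"- sptmap version: {report.version}",
        "",
    ]
    for name, section in sorted(report.sections.items()):
        lines.append(f"## {name}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(section, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    doc = "\n".join(lines)
    if path is not None:
        Path(path).write_text(doc)
    return doc
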