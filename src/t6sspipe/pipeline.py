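"""End-to-end orchestration: simulate -> segment -> detect -> stats -> coloc -> track.

All randomness flows from the single ``seed`` in the configuration; every
field and channel draws from an independent child of that seed, so a run is
bit-reproducible for a fixed (config, seed) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import io as pio
from .cellstats import PerCellCounts, assign_foci, summarize_counts, DistributionSummary
from .colocalization import ColocSummary, coloc_summary, colocalize, pearson_costes
from .containers import Focus, ImageStack, LabelMask, Track
from .detection import DetectionParams, detect_foci
from .dynamics import (TrackingParams, apply_registration, link_tracks,
                       register_frames, track_stats, TrackStats)
from .segmentation import SegmentationParams, segment_cells
from .simulate import (ChannelModel, FieldConfig, KineticsConfig, OpticsModel,
                       FieldGroundTruth, mask_channel, render_channel,
                       sample_field, simulate_timelapse, tssb_channel,
                       tssb_gfp_channel, tssh_channel, tssl_channel,
                       TSSB_ISOLATED_PMF)


class TimelapseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    frame_interval_s: float = Field(10.0, gt=0)
    duration_s: float = Field(240.0, gt=0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_fields: int = Field(1, ge=1)
    field: FieldConfig = Field(default_factory=FieldConfig)
    optics: OpticsModel = Field(default_factory=OpticsModel)
    channels: list[ChannelModel] = Field(
        default_factory=lambda: [mask_channel(), tssb_channel()])
    noise: bool = True
    timelapse: Optional[TimelapseConfig] = None


class ColocConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    threshold_um: float = Field(0.272, gt=0)
    costes: bool = False


class InputConfig(BaseModel):
    """File-based input: one field, one TIFF per channel."""

    model_config = ConfigDict(extra="forbid")

    stacks: dict[str, str]  # channel name -> TIFF path
    pixel_size_um: Optional[float] = None
    z_spacing_um: Optional[float] = None


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    simulate: Optional[SimulationConfig] = Field(default_factory=SimulationConfig)
    inputs: Optional[InputConfig] = None
    mask_channel: str = "gfp"
    focus_channels: list[str] = Field(default_factory=lambda: ["tssb"])
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    detection: DetectionParams = Field(default_factory=DetectionParams)
    coloc: ColocConfig = Field(default_factory=ColocConfig)
    tracking: TrackingParams = Field(default_factory=TrackingParams)
    seed: int = 0


@dataclass
class FieldResult:
    index: int
    truth: Optional[FieldGroundTruth]
    mask: LabelMask
    n_cells: int
    threshold: float
    foci: dict[str, list[Focus]]
    counts: dict[str, PerCellCounts]
    coloc: Optional[ColocSummary] = None
    costes_r: Optional[float] = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    fields: list[FieldResult]
    pooled_counts: dict[str, np.ndarray]  # channel -> non-border per-cell counts
    pooled_single_counts: dict[str, np.ndarray]
    summary: dict[str, DistributionSummary]
    summary_single: dict[str, DistributionSummary]
    coloc: Optional[ColocSummary] = None
    costes_r: Optional[float] = None
    tracks: Optional[list[Track]] = None
    track_stats: Optional[TrackStats] = None

    def to_summary_dict(self) -> dict:
        out: dict = {"n_fields": len(self.fields),
                     "n_cells": {ch: int(len(v)) for ch, v in
                                 self.pooled_counts.items()}}
        for ch, s in self.summary.items():
            out[ch] = {"mean_foci_per_cell": s.mean_foci_per_cell,
                       "histogram": s.histogram,
                       "frac_at_least_one": s.frac_at_least_one,
                       "n_cells": s.n_cells}
        for ch, s in self.summary_single.items():
            out[f"{ch}_single"] = {"mean_foci_per_cell": s.mean_foci_per_cell,
                                   "histogram": s.histogram,
                                   "n_cells": s.n_cells}
        if self.coloc is not None:
            c = self.coloc
            out["coloc"] = {
                "threshold_um": c.threshold_um,
                "frac_red_coloc": c.frac_red_coloc,
                "frac_green_coloc": c.frac_green_coloc,
                "n_red": c.n_red, "n_green": c.n_green,
                "ratio_red_to_green": c.ratio_red_to_green,
                "n_pairs": c.n_pairs,
            }
        if self.costes_r is not None:
            out["costes_pearson_r"] = self.costes_r
        if self.track_stats is not None:
            ts = self.track_stats
            out["tracking"] = {"n_tracks": ts.n_tracks,
                               "mean_lifetime_s": ts.mean_lifetime_s,
                               "turnover": ts.turnover,
                               "period_s": ts.period_s}
        return out


def _analyse_field(index: int, stacks: dict[str, ImageStack],
                   truth: Optional[FieldGroundTruth],
                   config: PipelineConfig) -> FieldResult:
    seg = segment_cells(stacks[config.mask_channel], config.segmentation)
    mask2d = seg.mask.max_projection()
    foci: dict[str, list[Focus]] = {}
    counts: dict[str, PerCellCounts] = {}
    for ch in config.focus_channels:
        foci[ch] = detect_foci(stacks[ch], config.detection, channel=ch)
        counts[ch] = assign_foci(mask2d, foci[ch])
    coloc = None
    costes_r = None
    if len(config.focus_channels) == 2:
        green, red = config.focus_channels[0], config.focus_channels[1]
        px = stacks[red].pixel_size_um
        coloc = colocalize(foci[red], foci[green], px,
                           config.coloc.threshold_um)
        if config.coloc.costes:
            costes_r = pearson_costes(stacks[green].max_projection(),
                                      stacks[red].max_projection()).pearson_r
    return FieldResult(index=index, truth=truth, mask=seg.mask,
                       n_cells=seg.n_cells, threshold=seg.threshold,
                       foci=foci, counts=counts, coloc=coloc,
                       costes_r=costes_r)


def _simulated_stacks(config: PipelineConfig, field_seed: np.random.SeedSequence
                      ) -> tuple[dict[str, ImageStack], FieldGroundTruth]:
    sim = config.simulate
    s_truth, s_render = field_seed.spawn(2)
    truth = sample_field(sim.field, sim.channels, s_truth)
    stacks = {}
    for ch, s_ch in zip(sim.channels, s_render.spawn(len(sim.channels))):
        stacks[ch.name] = render_channel(truth, ch, sim.optics, s_ch,
                                         noise=sim.noise)
    return stacks, truth


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the configured pipeline and optionally write the result bundle."""
    root = np.random.SeedSequence(config.seed)
    fields: list[FieldResult] = []

    if config.simulate is not None and config.simulate.timelapse is not None:
        return _run_timelapse(config, out_dir)

    if config.inputs is not None:
        stacks = {
            name: pio.read_stack(path, pixel_size_um=config.inputs.pixel_size_um,
                                 z_spacing_um=config.inputs.z_spacing_um,
                                 channel_label=name)
            for name, path in config.inputs.stacks.items()
        }
        fields.append(_analyse_field(0, stacks, None, config))
    elif config.simulate is not None:
        for i, fs in enumerate(root.spawn(config.simulate.n_fields)):
            stacks, truth = _simulated_stacks(config, fs)
            fields.append(_analyse_field(i, stacks, truth, config))
    else:
        raise ValueError("config needs either simulate or inputs")

    pooled: dict[str, list[int]] = {ch: [] for ch in config.focus_channels}
    pooled_single: dict[str, list[int]] = {ch: [] for ch in config.focus_channels}
    for fr in fields:
        for ch in config.focus_channels:
            pcc = fr.counts[ch]
            pooled[ch].extend(pcc.counts[lab] for lab in pcc.labels("all"))
            pooled_single[ch].extend(pcc.counts[lab]
                                     for lab in pcc.labels("single"))
    pooled_arr = {ch: np.asarray(v, dtype=int) for ch, v in pooled.items()}
    pooled_single_arr = {ch: np.asarray(v, dtype=int)
                         for ch, v in pooled_single.items()}
    summary = {ch: summarize_counts(v) for ch, v in pooled_arr.items() if v.size}
    summary_single = {ch: summarize_counts(v)
                      for ch, v in pooled_single_arr.items() if v.size}

    coloc = None
    if len(config.focus_channels) == 2:
        d_rg = np.concatenate([fr.coloc.dist_red_to_green for fr in fields])
        d_gr = np.concatenate([fr.coloc.dist_green_to_red for fr in fields])
        n_red = sum(fr.coloc.n_red for fr in fields)
        n_green = sum(fr.coloc.n_green for fr in fields)
        n_pairs = sum(fr.coloc.n_pairs for fr in fields)
        coloc = coloc_summary(d_rg, d_gr, config.coloc.threshold_um,
                              n_red=n_red, n_green=n_green)
        coloc.n_pairs = n_pairs
        coloc.n_red_only = n_red - n_pairs
        coloc.n_green_only = n_green - n_pairs

    costes_r = fields[0].costes_r if fields else None
    result = PipelineResult(config=config, fields=fields,
                            pooled_counts=pooled_arr,
                            pooled_single_counts=pooled_single_arr,
                            summary=summary, summary_single=summary_single,
                            coloc=coloc, costes_r=costes_r)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _run_timelapse(config: PipelineConfig,
                   out_dir: str | Path | None) -> PipelineResult:
    sim = config.simulate
    tl = sim.timelapse
    movie_channel = next((c for c in sim.channels
                          if c.name in config.focus_channels), sim.channels[-1])
    frames, truth = simulate_timelapse(sim.field, movie_channel, sim.optics,
                                       tl.kinetics, tl.frame_interval_s,
                                       tl.duration_s, config.seed,
                                       noise=sim.noise)
    planes = [f.max_projection() for f in frames]
    offsets, _ = register_frames(planes, config.tracking.ncc_min)
    foci_per_frame = [detect_foci(p, config.detection,
                                  channel=movie_channel.name, frame=k)
                      for k, p in enumerate(planes)]
    foci_per_frame = apply_registration(foci_per_frame, offsets)
    tracks = link_tracks(foci_per_frame, config.tracking)

    # cell mask from the true geometries' footprint is not available to real
    # data; use a rendered noiseless diffuse view of the movie channel
    mask_truth = FieldGroundTruth(field=sim.field, cells=truth.cells, foci={})
    mask_stack = render_channel(
        mask_truth,
        mask_channel(movie_channel.name).model_copy(
            update={"diffuse_intensity": max(movie_channel.diffuse_intensity,
                                             30.0)}),
        sim.optics, np.random.SeedSequence(config.seed).spawn(1)[0],
        noise=sim.noise)
    seg = segment_cells(mask_stack, config.segmentation)
    stats = track_stats(tracks, tl.frame_interval_s,
                        mask=seg.mask.max_projection(), n_frames=len(frames))
    fr = FieldResult(index=0, truth=truth, mask=seg.mask, n_cells=seg.n_cells,
                     threshold=seg.threshold,
                     foci={movie_channel.name:
                           [f for fs in foci_per_frame for f in fs]},
                     counts={})
    result = PipelineResult(config=config, fields=[fr], pooled_counts={},
                            pooled_single_counts={}, summary={},
                            summary_single={}, tracks=tracks,
                            track_stats=stats)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_tracks_csv(out / "tracks.csv", tracks)
        pio.write_track_summary_csv(out / "track_summary.csv", tracks,
                                    tl.frame_interval_s)
        pio.write_events_csv(out / "events.csv", truth)
        pio.write_json(out / "summary.json", result.to_summary_dict())
        pio.save_config(out / "config_resolved.yaml", config)
    return result


def _write_bundle(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    for fr in result.fields:
        pio.write_mask(out / f"mask_field{fr.index:03d}.tif", fr.mask)
    all_foci = [f for fr in result.fields for ch in fr.foci.values() for f in ch]
    px = (cfg.simulate.optics.pixel_size_um if cfg.simulate is not None
          else (cfg.inputs.pixel_size_um or 1.0))
    pio.write_foci_csv(out / "foci.csv", all_foci, px)
    first_channel = cfg.focus_channels[0]
    pio.write_per_cell_counts_csv(
        out / "per_cell_counts.csv",
        {fr.index: fr.counts[first_channel] for fr in result.fields
         if first_channel in fr.counts})
    pio.write_json(out / "summary.json", result.to_summary_dict())
    pio.save_config(out / "config_resolved.yaml", cfg)


# ---------------------------------------------------------------------------
# study-condition presets
# ---------------------------------------------------------------------------


def population_survey_config(n_fields: int = 50, seed: int = 0) -> PipelineConfig:
    """Snapshot survey of sheath foci over the whole population.

    50 default fields of ~80 cells reproduce the scale of the reference
    snapshot survey (~4,000 cells).
    """
    return PipelineConfig(
        simulate=SimulationConfig(
            n_fields=n_fields,
            channels=[mask_channel("gfp"), tssb_channel("tssb")]),
        mask_channel="gfp", focus_channels=["tssb"], seed=seed)


def isolated_survey_config(n_fields: int = 20, seed: int = 0) -> PipelineConfig:
    """Survey restricted to isolated single cells (single-cell count statistics)."""
    return PipelineConfig(
        simulate=SimulationConfig(
            n_fields=n_fields,
            channels=[mask_channel("gfp"),
                      tssb_channel("tssb", pmf=TSSB_ISOLATED_PMF)]),
        mask_channel="gfp", focus_channels=["tssb"], seed=seed)


def dual_reporter_config(mode: str, n_fields: int = 30,
                         seed: int = 0) -> PipelineConfig:
    """Dual-reporter co-localization runs: sheath-GFP plus a red partner.

    ``mode="tssh"``: rare red foci (~0.2/cell) that seek out green foci.
    ``mode="tssl"``: abundant red foci (~0.9/cell); each green focus is
    matched with probability 0.85.
    """
    green = tssb_gfp_channel("tssb_gfp")
    if mode == "tssh":
        red = tssh_channel("tssb_gfp", name="tssh")
    elif mode == "tssl":
        red = tssl_channel("tssb_gfp", name="tssl")
    else:
        raise ValueError("mode must be 'tssh' or 'tssl'")
    return PipelineConfig(
        simulate=SimulationConfig(n_fields=n_fields, channels=[green, red]),
        mask_channel="tssb_gfp", focus_channels=["tssb_gfp", red.name],
        seed=seed)
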