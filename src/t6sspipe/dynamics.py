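"""Time-lapse analysis: drift registration, focus linking and turnover stats.

Linking is greedy nearest-neighbour frame-to-frame association, adequate at
the sparse focus densities of sheath reporters (about one focus per cell at
most); a short gap tolerance bridges single-frame detection dropouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.ndimage import median_filter

from .containers import Focus, LabelMask, Track


class TrackingParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_disp_px: float = Field(5.0, gt=0)
    max_gap_frames: int = Field(1, ge=0)
    ncc_min: float = Field(0.1, ge=0, le=1)  # registration confidence floor


def register_frames(frames: list[np.ndarray], ncc_min: float = 0.1,
                    suppress_puncta_px: int = 5
                    ) -> tuple[list[tuple[int, int]], list[bool]]:
    """Integer (dx, dy) drift of every frame relative to frame 0.

    Offsets maximize the circular normalized cross-correlation with frame 0.
    Diffraction-limited puncta blink between frames and can dominate the
    correlation, so frames are median-filtered (``suppress_puncta_px``)
    first: drift is carried by the cell bodies, not the transient foci.
    Frames whose best correlation falls below ``ncc_min`` (featureless or
    pure noise) get a zero offset and a raised flag.
    """
    if len(frames) < 2:
        raise ValueError("registration needs at least two frames")

    def prep(img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=float)
        if suppress_puncta_px > 1:
            img = median_filter(img, size=suppress_puncta_px, mode="nearest")
        return img

    ref = prep(frames[0])
    ref0 = ref - ref.mean()
    ref_sd = ref0.std()
    offsets: list[tuple[int, int]] = []
    flagged: list[bool] = []
    npix = ref.size
    f_ref = np.fft.rfft2(ref0)
    for frame in frames:
        img = prep(frame)
        if img.shape != ref.shape:
            raise ValueError("all frames must share a shape")
        img0 = img - img.mean()
        sd = img0.std()
        if ref_sd == 0 or sd == 0:
            offsets.append((0, 0))
            flagged.append(True)
            continue
        corr = np.fft.irfft2(np.fft.rfft2(img0) * np.conj(f_ref), s=ref.shape)
        ncc = corr / (npix * ref_sd * sd)
        peak = np.unravel_index(np.argmax(ncc), ncc.shape)
        # a genuine alignment peak is both absolutely strong and an extreme
        # outlier of the correlation map; the maximum over a pure-noise map
        # only reaches ~sqrt(2 ln N) standard deviations
        z = (ncc[peak] - ncc.mean()) / max(ncc.std(), 1e-12)
        if ncc[peak] < ncc_min or z < 6.0:
            offsets.append((0, 0))
            flagged.append(True)
            continue
        dy, dx = peak
        if dy > ref.shape[0] // 2:
            dy -= ref.shape[0]
        if dx > ref.shape[1] // 2:
            dx -= ref.shape[1]
        offsets.append((int(dx), int(dy)))
        flagged.append(False)
    return offsets, flagged


def apply_registration(foci_per_frame: list[list[Focus]],
                       offsets: list[tuple[int, int]]) -> list[list[Focus]]:
    """Shift detected focus coordinates into the frame-0 reference."""
    out: list[list[Focus]] = []
    for foci, (dx, dy) in zip(foci_per_frame, offsets):
        out.append([Focus(x=f.x - dx, y=f.y - dy, channel=f.channel,
                          frame=f.frame, integrated_intensity=f.integrated_intensity,
                          peak_snr=f.peak_snr, z_plane=f.z_plane,
                          degenerate=f.degenerate) for f in foci])
    return out


def link_tracks(foci_per_frame: list[list[Focus]],
                params: TrackingParams | None = None) -> list[Track]:
    """Greedy nearest-neighbour linking with bounded displacement and gaps.

    Detections within ``max_disp_px`` of an open track's last position extend
    it (closest pairs first); tracks unmatched for more than ``max_gap_frames``
    close; leftover detections start new tracks. Deterministic for fixed
    input: ties break on (distance, track id, detection index).
    """
    params = params or TrackingParams()
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    for frame_idx, foci in enumerate(foci_per_frame):
        open_tracks = [t for t in open_tracks
                       if frame_idx - t.last_frame <= params.max_gap_frames + 1]
        candidates = []
        for ti, t in enumerate(open_tracks):
            _, lx, ly, _ = t.points[-1]
            for di, f in enumerate(foci):
                d = float(np.hypot(f.x - lx, f.y - ly))
                if d <= params.max_disp_px:
                    candidates.append((d, ti, di))
        candidates.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, ti, di in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            f = foci[di]
            open_tracks[ti].points.append(
                (frame_idx, f.x, f.y, f.integrated_intensity))
            used_tracks.add(ti)
            used_dets.add(di)
        for di, f in enumerate(foci):
            if di not in used_dets:
                t = Track(track_id=len(tracks),
                          points=[(frame_idx, f.x, f.y, f.integrated_intensity)])
                tracks.append(t)
                open_tracks.append(t)
    return tracks


@dataclass
class TrackStats:
    lifetimes_s: np.ndarray
    mean_lifetime_s: float | None
    turnover: float | None  # mean fraction of cells switching focus state
    turnover_series: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    period_s: float | None = None
    n_tracks: int = 0
    flags: list[str] = dc_field(default_factory=list)


def _cell_state_matrix(tracks: list[Track], mask: LabelMask,
                       n_frames: int) -> tuple[np.ndarray, np.ndarray]:
    labels = mask.plane_labels()
    label_values = np.array([int(v) for v in np.unique(labels) if v > 0])
    index = {lab: i for i, lab in enumerate(label_values)}
    state = np.zeros((len(label_values), n_frames), dtype=bool)
    h, w = labels.shape
    for t in tracks:
        for (frame, x, y, _) in t.points:
            r, c = int(round(y)), int(round(x))
            if 0 <= r < h and 0 <= c < w and labels[r, c] > 0:
                state[index[int(labels[r, c])], frame] = True
    return label_values, state


def track_stats(tracks: list[Track], frame_interval_s: float,
                mask: LabelMask | None = None,
                n_frames: int | None = None) -> TrackStats:
    """Lifetime distribution, per-cell focus-state turnover, and cycle period.

    Turnover and period require a cell mask: turnover is the fraction of
    cells whose has-a-focus state differs between consecutive frames
    (averaged over frame pairs); the period is the mean onset-to-onset
    interval over cells with at least two focus onsets.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    flags: list[str] = []
    if not tracks:
        # a movie with no focus events has zero turnover by definition
        turnover = 0.0 if (mask is not None and n_frames and n_frames >= 2) else None
        return TrackStats(lifetimes_s=np.zeros(0), mean_lifetime_s=None,
                          turnover=turnover, n_tracks=0,
                          flags=["no tracks: empty statistics"])
    lifetimes = np.array([t.lifetime_s(frame_interval_s) for t in tracks])
    if n_frames is None:
        n_frames = max(t.last_frame for t in tracks) + 1

    turnover = None
    turnover_series = np.zeros(0)
    period = None
    if mask is not None and n_frames >= 2:
        _, state = _cell_state_matrix(tracks, mask, n_frames)
        if state.shape[0] == 0:
            flags.append("no labelled cells for turnover")
        else:
            changed = state[:, 1:] != state[:, :-1]
            turnover_series = changed.mean(axis=0)
            turnover = float(turnover_series.mean())
            cycles: list[float] = []
            for row in state:
                onsets = np.flatnonzero(~row[:-1] & row[1:]) + 1
                if row[0]:
                    onsets = np.concatenate([[0], onsets])
                if len(onsets) >= 2:
                    cycles.extend(np.diff(onsets) * frame_interval_s)
            if cycles:
                period = float(np.mean(cycles))
            else:
                flags.append("no cell completed two cycles: period undefined")
    elif mask is None:
        flags.append("no cell mask: turnover and period not computed")

    return TrackStats(lifetimes_s=lifetimes,
                      mean_lifetime_s=float(lifetimes.mean()),
                      turnover=turnover, turnover_series=turnover_series,
                      period_s=period, n_tracks=len(tracks), flags=flags)
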