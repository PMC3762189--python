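"""End-to-end movie analysis: stack -> tracks -> dwell times -> affinity.

Chains the single-molecule operations exactly as the underlying assays do:
preprocess and detect in the molecule channel, link with nearest neighbors,
apply the four-rule filter, classify binding events against junction
annotations, fit per-class off rates from the binned survival curves, run
the binding-site census on the segmented filament channel, and convert the
average per-frame occupancy into per-class dissociation constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .singlemol import (
    BindingSiteCensus,
    MoleculeTrack,
    classify_tracks,
    count_side_sites,
    detect_molecules,
    filter_tracks,
    kd_from_fraction_bound,
    link_tracks,
    off_rate_from_lifetimes,
    preprocess_frame,
)

__all__ = ["MovieReport", "analyze_movie", "segment_filaments"]


def segment_filaments(filament_channel: np.ndarray,
                      min_object_px: int = 12) -> np.ndarray:
    """Binary filament mask by Otsu thresholding plus small-object removal."""
    from scipy import ndimage
    from skimage.filters import threshold_otsu

    img = np.asarray(filament_channel, float)
    mask = img > threshold_otsu(img)
    # morphological area opening: drop non-filamentous specks
    labels, n_obj = ndimage.label(mask)
    if n_obj:
        sizes = ndimage.sum_labels(mask, labels, range(1, n_obj + 1))
        small = np.flatnonzero(sizes < min_object_px) + 1
        mask[np.isin(labels, small)] = False
    return mask


@dataclass
class MovieReport:
    """Everything the movie pipeline measures."""

    tracks: list[MoleculeTrack]
    n_tracks_raw: int
    rejections: dict[str, int]
    k_off: dict[str, float] = field(default_factory=dict)
    tau: dict[str, float] = field(default_factory=dict)
    n_events: dict[str, int] = field(default_factory=dict)
    census: BindingSiteCensus | None = None
    fraction_bound: dict[str, float] = field(default_factory=dict)
    K_D: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_tracks_raw": self.n_tracks_raw,
            "n_tracks_kept": len(self.tracks),
            "rejections": self.rejections,
            "k_off_per_s": self.k_off,
            "tau_s": self.tau,
            "n_events": self.n_events,
            "fraction_bound": self.fraction_bound,
            "K_D": self.K_D,
            "side_sites": self.census.side_sites if self.census else None,
            "n_junctions": self.census.n_junctions if self.census else None,
        }


def analyze_movie(stack: np.ndarray,
                  frame_interval: float,
                  filament_channel: np.ndarray | None = None,
                  filament_mask: np.ndarray | None = None,
                  junctions=None,
                  ligand_conc_nM: float | None = None,
                  max_displacement: float = 2.0,
                  junction_radius: float = 3.0,
                  detect_kwargs: dict | None = None,
                  bin_width: float = 5.0,
                  min_events: int = 20) -> MovieReport:
    """Run the full single-molecule pipeline on an image stack.

    ``junctions`` are caller-supplied (x, y) branch-junction annotations
    (visually counted in the original assays; ground truth for synthetic
    movies).  When ``ligand_conc_nM`` is given, per-class dissociation
    constants are computed from the average per-frame occupancy, in nM.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, H, W)")
    if filament_mask is None:
        if filament_channel is None:
            raise ValueError("need filament_mask or filament_channel")
        filament_mask = segment_filaments(filament_channel)
    junctions = (np.zeros((0, 2)) if junctions is None
                 else np.asarray(junctions, float).reshape(-1, 2))
    kwargs = detect_kwargs or {}
    detections = [detect_molecules(preprocess_frame(frame),
                                   frame_index=i, **kwargs)
                  for i, frame in enumerate(stack)]
    raw = link_tracks(detections, max_displacement=max_displacement,
                      frame_interval=frame_interval)
    kept, rejections = filter_tracks(raw, n_frames=stack.shape[0],
                                     filament_mask=filament_mask)
    classify_tracks(kept, junctions, junction_radius=junction_radius)

    report = MovieReport(tracks=kept, n_tracks_raw=len(raw),
                         rejections=rejections)
    for klass in ("filament_side", "branch_junction", "nascent_branch"):
        lifetimes = [t.lifetime_s for t in kept if t.binding_class == klass]
        report.n_events[klass] = len(lifetimes)
        if len(lifetimes) >= min_events:
            k, tau = off_rate_from_lifetimes(lifetimes, bin_width=bin_width,
                                             min_events=min_events)
            report.k_off[klass] = k
            report.tau[klass] = tau

    report.census = count_side_sites(filament_mask, len(junctions))
    if ligand_conc_nM is not None and report.census.side_sites > 0:
        n_junc_frame = np.zeros(stack.shape[0])
        n_side_frame = np.zeros(stack.shape[0])
        for i, dets in enumerate(detections):
            for d in dets:
                if (len(junctions)
                        and np.hypot(junctions[:, 0] - d.x,
                                     junctions[:, 1] - d.y).min()
                        <= junction_radius):
                    n_junc_frame[i] += 1
                else:
                    n_side_frame[i] += 1
        fb_side = float(n_side_frame.mean() / report.census.side_sites)
        report.fraction_bound["filament_side"] = fb_side
        if 0 < fb_side < 1:
            report.K_D["filament_side"] = kd_from_fraction_bound(
                fb_side, ligand_conc_nM)
        if len(junctions):
            fb_j = float(n_junc_frame.mean() / len(junctions))
            report.fraction_bound["branch_junction"] = fb_j
            if 0 < fb_j < 1:
                report.K_D["branch_junction"] = kd_from_fraction_bound(
                    fb_j, ligand_conc_nM)
    return report
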