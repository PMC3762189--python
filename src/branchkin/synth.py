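"""Seeded synthetic-data generators for every input the analyses consume.

The pyrene-trace generator produces noisy polymerization ensembles from any
network variant at the bulk-assay reaction conditions (3 uM actin, 20-50 nM
Arp2/3 complex, 100 nM GST-VCA, cortactin ladders); the dwell-time generator
produces frame-quantized, boundary-censored exponential lifetimes; and the
movie generator renders two-channel TIRF-like image stacks of static
filaments with branch junctions and single molecules binding and unbinding
with per-class exponential kinetics, together with full ground truth.

All generators are pure functions of (spec, seed): identical inputs give
bitwise-identical outputs.  Defaults reproduce the experimental conditions
of the single-molecule assays (106.7 nm pixels, 1.5-2 nM labeled cortactin,
junction/side kinetics k_on 2.0e6 / 1.21e4 M^-1 s^-1 and k_off 0.034 /
0.063 s^-1); the 1% relative trace noise and the Poisson+Gaussian camera
noise are generic realistic choices, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .network import build_network
from .simulate import Conditions, simulate
from .singlemol import count_side_sites
from .traces import UNPOLYMERIZED_AT_EQ, PolymerizationTrace

__all__ = [
    "TraceGeneratorSpec",
    "MovieGeneratorSpec",
    "SyntheticMovie",
    "gen_pyrene_ensemble",
    "gen_dwell_times",
    "gen_tirf_movie",
    "set4_conditions",
]

#: Cortactin concentration ladder of the synergy assays (uM).
CORTACTIN_LADDER = (0.0, 0.005, 0.025, 0.075, 0.1, 0.25, 1.0)
#: GST-VCA (monomeric) ladder of the activation assays (uM).
VCA_LADDER = (0.0, 0.01, 0.025, 0.05, 0.1, 0.15, 0.25, 0.5, 1.0)


def set4_conditions(cortactin_ladder=CORTACTIN_LADDER,
                    t_end: float = 2000.0) -> list[Conditions]:
    """Synergy-assay conditions: 3 uM actin, 20 nM Arp2/3, 100 nM GST-VCA,
    a ladder of cortactin concentrations."""
    return [Conditions(actin_monomer=3.0, arp23=0.02, gst_vca_monomeric=0.1,
                       cortactin=c, t_end=t_end) for c in cortactin_ladder]


@dataclass(frozen=True)
class TraceGeneratorSpec:
    """Recipe for a noisy pyrene-trace ensemble.

    ``noise_sd`` is relative to each trace's amplitude; ``fluorescence_mode``
    applies the inverse of the plateau calibration (arbitrary gain and
    offset) so the consumer must convert back.
    """

    variant: str = "displacement"
    conditions: tuple[Conditions, ...] = field(
        default_factory=lambda: tuple(set4_conditions()))
    noise_sd: float = 0.01
    seed: int = 0
    fluorescence_mode: bool = False
    overrides: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")


def gen_pyrene_ensemble(spec: TraceGeneratorSpec
                        ) -> tuple[list[PolymerizationTrace], dict]:
    """Simulate the spec's conditions and add seeded Gaussian noise.

    Returns the trace list and a ground-truth record (generating variant,
    rate overrides, noise level, and the fluorescence gain/offset when
    applicable) for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    overrides = dict(spec.overrides) or None
    net = build_network(spec.variant, overrides=overrides)
    traces = []
    gains = []
    for cond in spec.conditions:
        res = simulate(net, cond)
        signal = res.polymerized_actin.copy()
        amplitude = float(signal.max()) or 1.0
        signal = signal + spec.noise_sd * amplitude * rng.standard_normal(
            signal.size)
        meta = {"actin_monomer": cond.actin_monomer, "arp23": cond.arp23,
                "gst_vca_monomeric": cond.gst_vca_monomeric,
                "cortactin": cond.cortactin, "t_end": cond.t_end,
                "variant": spec.variant}
        if spec.fluorescence_mode:
            # invert the plateau calibration with a random positive gain
            gain = float(rng.uniform(200.0, 800.0))
            offset = float(rng.uniform(20.0, 80.0))
            gains.append((gain, offset))
            signal = offset + gain * signal / max(
                cond.actin_monomer - UNPOLYMERIZED_AT_EQ, 1e-9)
            mode = "fluorescence"
        else:
            mode = "concentration"
        traces.append(PolymerizationTrace(res.time, signal,
                                          total_actin=cond.actin_monomer,
                                          mode=mode, conditions=meta))
    truth = {"variant": spec.variant, "overrides": dict(spec.overrides),
             "noise_sd": spec.noise_sd, "seed": spec.seed,
             "fluorescence_gains": gains}
    return traces, truth


def gen_dwell_times(k_off: float, n: int, frame_interval: float,
                    movie_span: float, seed: int = 0):
    """Exponential dwell times, frame-quantized and boundary-censored.

    Events start uniformly over the movie span, so some overlap the first
    or last frame and are flagged censored - exactly the events the track
    filter's boundary rule removes.  Returns a pandas DataFrame with the
    true and observed (quantized) lifetimes and censoring flags.
    """
    import pandas as pd

    if k_off <= 0 or n <= 0 or frame_interval <= 0 or movie_span <= 0:
        raise ValueError("all arguments must be positive")
    if movie_span < frame_interval:
        raise ValueError("movie span shorter than one frame interval")
    rng = np.random.default_rng(seed)
    true_lifetimes = rng.exponential(1.0 / k_off, size=n)
    starts = rng.uniform(0.0, movie_span, size=n)
    ends = starts + true_lifetimes
    first_frame = np.floor(starts / frame_interval).astype(int)
    last_frame = np.floor(np.minimum(ends, np.nextafter(movie_span, 0))
                          / frame_interval).astype(int)
    n_frames_total = int(np.ceil(movie_span / frame_interval))
    frames = last_frame - first_frame + 1
    censored_start = first_frame == 0
    censored_end = ends >= (n_frames_total - 1) * frame_interval
    return pd.DataFrame({
        "true_lifetime_s": true_lifetimes,
        "start_s": starts,
        "lifetime_frames": frames,
        "lifetime_s": frames * frame_interval,
        "censored_start": censored_start,
        "censored_end": censored_end,
    })


# ---------------------------------------------------------------------------
# Two-channel TIRF movie generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovieGeneratorSpec:
    """Recipe for a synthetic smTIRF acquisition.

    Kinetic defaults are the measured junction/side constants of labeled
    cortactin (k_on in M^-1 s^-1, k_off in s^-1); ``conc_nM`` is the labeled
    ligand concentration.  Filament geometry is synthetic (random polylines
    of ~3 px width) - adequate for census and tracking, not a polymerization
    model.
    """

    field_size: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 106.7
    n_filaments: int = 14
    filament_step_px: float = 18.0
    filament_segments: int = 8
    branch_density_per_um: float = 0.08
    conc_nM: float = 1.5
    k_on_side: float = 1.21e4      # M^-1 s^-1 per site
    k_on_junction: float = 2.0e6   # M^-1 s^-1 per junction
    k_off_side: float = 0.063      # s^-1
    k_off_junction: float = 0.034  # s^-1
    frame_interval: float = 0.2    # s (5 fps)
    n_frames: int = 1000
    psf_sigma: float = 1.2         # px
    spot_intensity: float = 1000.0  # photons per molecule per frame
    background: float = 100.0      # photons per pixel per frame
    read_noise: float = 2.0        # e- rms
    seed: int = 0

    def __post_init__(self):
        for name in ("k_on_side", "k_on_junction", "k_off_side",
                     "k_off_junction", "frame_interval", "conc_nM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SyntheticMovie:
    """A rendered movie plus complete ground truth."""

    stack: np.ndarray                 # (n_frames, H, W) uint16 camera counts
    filament_channel: np.ndarray      # static 488-channel image
    filament_mask: np.ndarray         # bool
    junctions: np.ndarray             # (n, 2) x, y
    tracks: "object"                  # DataFrame: ground-truth binding events
    side_sites: int
    spec: MovieGeneratorSpec

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]


def _draw_filaments(rng, shape, n_filaments, step_px=18, n_steps=8,
                    margin=12):
    """Random polylines rasterized at ~3 px width; returns mask and the
    per-filament skeleton pixel lists.

    Polylines are kept ``margin`` px inside the field (bouncing off the
    margin box) so PSFs of bound molecules stay fully in-frame.
    """
    from skimage.draw import line

    mask = np.zeros(shape, dtype=bool)
    skeletons = []
    h, w = shape
    for _ in range(n_filaments):
        y, x = rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)
        theta = rng.uniform(0, 2 * np.pi)
        pts_y, pts_x = [], []
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.25)
            y2 = y + step_px * np.sin(theta)
            x2 = x + step_px * np.cos(theta)
            if not (margin <= y2 <= h - margin
                    and margin <= x2 <= w - margin):
                theta += np.pi / 2  # bounce back into the field
                y2 = np.clip(y + step_px * np.sin(theta), margin, h - margin)
                x2 = np.clip(x + step_px * np.cos(theta), margin, w - margin)
            ry, rx = line(int(round(y)), int(round(x)),
                          int(round(y2)), int(round(x2)))
            pts_y.extend(ry.tolist())
            pts_x.extend(rx.tolist())
            y, x = y2, x2
        skel = np.zeros(shape, dtype=bool)
        skel[pts_y, pts_x] = True
        skeletons.append(np.column_stack(np.nonzero(skel))[:, ::-1])  # x, y
        mask |= skel
    mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
    return mask, skeletons


def _sample_events(rng, rate_per_s, k_off, span, warmup):
    """Poisson binding-event stream over [-warmup, span) with exponential
    dwell times; returns (start, duration) arrays for events overlapping
    [0, span)."""
    total = span + warmup
    n = rng.poisson(rate_per_s * total)
    starts = rng.uniform(-warmup, span, size=n)
    durations = rng.exponential(1.0 / k_off, size=n)
    visible = starts + durations > 0
    return starts[visible], durations[visible]


def gen_tirf_movie(spec: MovieGeneratorSpec) -> SyntheticMovie:
    """Render a two-channel TIRF-like acquisition with ground truth.

    Molecules bind side sites (uniformly over filament pixels) and branch
    junctions with independent per-class Poisson kinetics under excess
    ligand, dwell exponentially, and are rendered as Gaussian PSF spots
    over a Poisson shot-noise + Gaussian read-noise background.  The
    binding-site census of the rendered mask sets the side event rate, so
    the movie's occupancy statistics are consistent with the census
    arithmetic used downstream.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    mask, skeletons = _draw_filaments(rng, (h, w), spec.n_filaments,
                                      step_px=spec.filament_step_px,
                                      n_steps=spec.filament_segments)

    # junctions sampled along skeletons at the requested linear density
    all_skel = np.vstack([s for s in skeletons if len(s)])
    px_per_um = 1000.0 / spec.pixel_size_nm
    total_len_um = sum(len(s) for s in skeletons) / px_per_um
    n_junctions = max(1, int(round(spec.branch_density_per_um
                                   * total_len_um)))
    idx = rng.choice(len(all_skel), size=min(n_junctions, len(all_skel)),
                     replace=False)
    junctions = all_skel[idx].astype(float)  # (n, 2) x, y

    census = count_side_sites(mask, len(junctions),
                              pixel_size_nm=spec.pixel_size_nm)
    conc_M = spec.conc_nM * 1e-9
    span = spec.n_frames * spec.frame_interval
    warmup = 5.0 / min(spec.k_off_side, spec.k_off_junction)

    events = []
    # side events: uniform over filament pixels outside the 5-px junction
    # footprints (the census removes those pixels from the side-site pool)
    if len(junctions):
        dist2 = ((all_skel[:, None, 0] - junctions[None, :, 0])**2
                 + (all_skel[:, None, 1] - junctions[None, :, 1])**2)
        side_skel = all_skel[dist2.min(axis=1) > 3.0**2]
    else:
        side_skel = all_skel
    rate_side = spec.k_on_side * conc_M * census.side_sites
    starts, durs = _sample_events(rng, rate_side, spec.k_off_side, span,
                                  warmup)
    pix = side_skel[rng.integers(0, len(side_skel), size=len(starts))]
    for (x, y), s, d in zip(pix, starts, durs):
        events.append((float(x), float(y), s, d, "filament_side"))
    # junction events: each junction is a single site, so binding follows an
    # alternating renewal process (free -> bind -> dwell -> free); two
    # molecules never co-occupy one junction
    bind_rate = spec.k_on_junction * conc_M  # s^-1 per free junction
    for x, y in junctions:
        t = -warmup
        while t < span:
            t += rng.exponential(1.0 / bind_rate)
            if t >= span:
                break
            dwell = rng.exponential(1.0 / spec.k_off_junction)
            if t + dwell > 0:
                events.append((float(x), float(y), t, dwell,
                               "branch_junction"))
            t += dwell

    import pandas as pd

    tracks = pd.DataFrame(events, columns=["x", "y", "start_s",
                                           "duration_s", "binding_class"])
    tracks["first_frame"] = np.floor(
        np.maximum(tracks.start_s, 0.0) / spec.frame_interval).astype(int)
    tracks["last_frame"] = np.minimum(
        np.floor((tracks.start_s + tracks.duration_s)
                 / spec.frame_interval), spec.n_frames - 1).astype(int)
    tracks = tracks[tracks.last_frame >= tracks.first_frame].reset_index(
        drop=True)
    tracks["track_id"] = np.arange(len(tracks))

    mean_bound = float((tracks.last_frame - tracks.first_frame + 1).sum()
                       / spec.n_frames)
    area_limit = h * w / (16 * np.pi * spec.psf_sigma**2)
    if mean_bound > area_limit:
        raise ValueError(
            f"overcrowded field: ~{mean_bound:.0f} molecules/frame exceeds "
            f"the resolvable limit (~{area_limit:.0f})")

    # render (camera counts, uint16)
    stack = np.empty((spec.n_frames, h, w), dtype=np.uint16)
    half = max(int(np.ceil(4 * spec.psf_sigma)), 3)
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    norm = 1.0 / (2 * np.pi * spec.psf_sigma**2)
    by_frame: dict[int, list[tuple[float, float]]] = {}
    for row in tracks.itertuples():
        for f in range(row.first_frame, row.last_frame + 1):
            by_frame.setdefault(f, []).append((row.x, row.y))
    for f in range(spec.n_frames):
        photons = np.full((h, w), spec.background, dtype=float)
        for x, y in by_frame.get(f, ()):
            ix, iy = int(round(x)), int(round(y))
            dy, dx = y - iy, x - ix
            stamp = spec.spot_intensity * norm * np.exp(
                -((xx - dx)**2 + (yy - dy)**2) / (2 * spec.psf_sigma**2))
            y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
            x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
            photons[y0:y1, x0:x1] += stamp[y0 - iy + half:y1 - iy + half,
                                           x0 - ix + half:x1 - ix + half]
        frame = rng.poisson(photons) + rng.normal(0.0, spec.read_noise,
                                                  size=(h, w))
        stack[f] = np.clip(np.rint(frame), 0, 65535)

    filament_channel = rng.poisson(
        np.where(mask, 600.0, 50.0)).astype(np.uint16)

    return SyntheticMovie(stack=stack, filament_channel=filament_channel,
                          filament_mask=mask, junctions=junctions,
                          tracks=tracks, side_sites=census.side_sites,
                          spec=spec)
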