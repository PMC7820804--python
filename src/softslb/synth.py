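"""Synthetic-data generators with known ground truth.

Every analysis stage in this package can be exercised end to end on data
produced here: 2D Brownian tracks with static localization noise, rendered
TIRF-like image stacks, Axelrod-model FRAP recovery traces, calcium-trace
populations with controllable responder fractions, two-channel contact
images with a depleted probe channel, and Hertzian AFM approach curves with
an optional bilayer push-through discontinuity.

All generators are deterministic given (ground truth, seed). Defaults follow
the experimental conditions the analyses were designed for: 10 ms camera
frames for lipid tracking, 1 s calcium sampling over 10 min, 0.5 nm AFM
z-sampling, a 4.59 kPa soft-gel modulus, and a 3.9 nm POPC bilayer z-jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import afm, calcium, frap
from .exclusion import TwoChannelContactImage
from .spt import Track

__all__ = [
    "DiffusionGroundTruth",
    "FRAPGroundTruth",
    "CalciumPopulationGroundTruth",
    "ContactGroundTruth",
    "ForceCurveGroundTruth",
    "simulate_tracks",
    "render_image_stack",
    "photons_for_snr",
    "simulate_frap_curve",
    "simulate_calcium_population",
    "render_calcium_stack",
    "simulate_contact_image",
    "simulate_force_curve",
]


# ---------------------------------------------------------------------------
# ground-truth parameter sets


@dataclass
class DiffusionGroundTruth:
    """One or two freely diffusing populations plus static localization noise."""

    component_D: tuple[float, ...] = (1.0,)  # um^2/s
    component_fractions: tuple[float, ...] = (1.0,)
    sigma_loc: float = 0.03  # um, static localization precision
    frame_interval: float = 0.01  # s
    exposure_time: float = 0.01  # s (bookkeeping only; no sub-frame blur)
    n_tracks: int = 200
    track_length: int = 20  # frames

    def __post_init__(self) -> None:
        if len(self.component_D) != len(self.component_fractions):
            raise ValueError("component_D and component_fractions must match")
        if abs(sum(self.component_fractions) - 1.0) > 1e-9:
            raise ValueError("component_fractions must sum to 1")
        if any(d < 0 for d in self.component_D) or self.sigma_loc < 0:
            raise ValueError("diffusion coefficients and sigma_loc must be >= 0")
        if self.track_length < 2:
            raise ValueError("track_length must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass
class FRAPGroundTruth:
    """Axelrod-model recovery parameters.

    ``baseline_F0`` is the immobile-fraction plateau; when None it is set to
    the self-consistent bleach depth (1 - e^-K)/K, so that the model value
    at t = 0 equals F0 (as holds for real data, where F0 is read off the
    first post-bleach frame).
    """

    bleach_depth_K: float = 1.0
    tau_D: float = 2.0  # s
    mobile_fraction_Mf: float = 0.9
    beam_radius_w: float = 1.2  # um
    baseline_F0: float | None = None  # normalized intensity
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.bleach_depth_K <= 0:
            raise ValueError("bleach depth K must be positive")
        if self.tau_D <= 0 or self.beam_radius_w <= 0:
            raise ValueError("tau_D and beam radius must be positive")
        if not 0.0 <= self.mobile_fraction_Mf <= 1.0:
            raise ValueError("mobile fraction must lie in [0, 1]")
        if self.baseline_F0 is None:
            k = self.bleach_depth_K
            self.baseline_F0 = (1.0 - np.exp(-k)) / k


@dataclass
class CalciumPopulationGroundTruth:
    """Population of per-cell traces at 1 s sampling over 10 min by default."""

    n_cells: int = 200
    responder_fraction: float = 0.7
    multipeak_fraction_of_responders: float = 0.3
    baseline_level: float = 100.0  # a.u.
    peak_height_multiples: tuple[float, float] = (4.0, 1.0)  # mean, sd (> 1)
    peak_width: float = 8.0  # s, FWHM of the Gaussian transient
    latency_mean: float = 120.0  # s, exponential latency of the first peak
    noise_sd: float = 2.0  # a.u.
    duration: float = 600.0  # s
    frame_interval: float = 1.0  # s

    def __post_init__(self) -> None:
        for fr in (self.responder_fraction, self.multipeak_fraction_of_responders):
            if not 0.0 <= fr <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.peak_height_multiples[0] <= 1:
            raise ValueError("mean peak height must exceed 1 baseline multiple")
        if self.duration / self.frame_interval < 10:
            raise ValueError("need at least 10 frames")


@dataclass
class ContactGroundTruth:
    image_shape: tuple[int, int] = (128, 128)
    contact_geometry: tuple = (("disk", 64.0, 64.0, 18.0),)
    cell_geometry: tuple = (("disk", 64.0, 64.0, 45.0),)
    enrichment_factor_ch1: float = 6.0  # contact-channel boost inside contact
    depletion_factor_ch2: float = 0.5  # probe mean-in / mean-out
    base_level: float = 100.0  # a.u., probe level over the cell
    contact_background: float = 10.0  # a.u., contact channel outside contact
    probe_background: float = 2.0  # a.u., probe level outside the cell
    background_gradient: float = 0.0  # a.u./pixel, linear ramp along x
    noise_sd: float = 0.0  # a.u.

    def __post_init__(self) -> None:
        if self.enrichment_factor_ch1 < 1:
            raise ValueError("enrichment factor must be >= 1")
        if not 0.0 <= self.depletion_factor_ch2 <= 1.0:
            raise ValueError("depletion factor must lie in [0, 1]")


@dataclass
class ForceCurveGroundTruth:
    """Hertzian approach curve, optionally with a bilayer breakthrough.

    Exactly one of ``indenter_radius_um`` (sphere) or ``half_angle_deg``
    (four-sided pyramid) must be set. ``z_jump_nm = 0`` means no
    push-through. ``substrate_modulus_E`` defaults to the layer modulus
    (bilayer on matched support, the slope-ratio ~ 1 situation).
    """

    young_modulus_E: float = 4590.0  # Pa, soft-gel condition
    poisson_ratio: float = 0.5  # incompressible default
    indenter_radius_um: float | None = None
    half_angle_deg: float | None = 35.0
    substrate_modulus_E: float | None = None
    z_jump_nm: float = 0.0
    breakthrough_force_nN: float = 2.0
    contact_point_um: float = 0.3
    noise_sd_nN: float = 0.02
    sampling_step_nm: float = 0.5
    z_range_um: float | None = None  # auto when None

    def __post_init__(self) -> None:
        if self.young_modulus_E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5 + 1e-12:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if (self.indenter_radius_um is None) == (self.half_angle_deg is None):
            raise ValueError("set exactly one of sphere radius or pyramid angle")
        if self.z_jump_nm < 0:
            raise ValueError("z_jump must be >= 0")
        if self.contact_point_um < 0:
            raise ValueError("contact point must be >= 0")


# ---------------------------------------------------------------------------
# tracks and rendered stacks


def simulate_tracks(gt: DiffusionGroundTruth, seed: int,
                    box_size: float | None = None) -> list[Track]:
    """Simulate 2D Brownian tracks with static localization noise.

    Per-axis displacements are Gaussian with variance 2 D dt; independent
    Gaussian noise of sd ``sigma_loc`` is added to every coordinate (static
    error; no sub-frame motion blur). Tracks start at the origin, or uniform
    in a ``box_size`` x ``box_size`` field (um) when given.
    """
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(gt.component_D), size=gt.n_tracks,
                      p=np.asarray(gt.component_fractions, dtype=float))
    tracks = []
    frames = np.arange(gt.track_length)
    for i in range(gt.n_tracks):
        D = gt.component_D[comp[i]]
        steps = rng.normal(0.0, np.sqrt(2 * D * gt.frame_interval),
                           size=(gt.track_length - 1, 2))
        xy = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        if box_size is not None:
            xy = xy + rng.uniform(0, box_size, size=2)
        xy = xy + rng.normal(0.0, gt.sigma_loc, size=xy.shape)
        tracks.append(Track(particle_id=i, frames=frames.copy(), xy=xy,
                            frame_interval=gt.frame_interval))
    return tracks


def photons_for_snr(snr: float, background_level: float,
                    psf_sigma: float) -> float:
    """Spot photon count giving a target peak SNR on a Poisson background.

    SNR = amplitude / sqrt(background), amplitude = photons / (2 pi sigma^2).
    """
    return snr * np.sqrt(background_level) * 2 * np.pi * psf_sigma**2


def render_image_stack(
    tracks: list[Track],
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = 0.1,  # um/px
    psf_sigma: float = 1.3,  # px
    photons_per_spot: float = 500.0,
    background_level: float = 10.0,
    seed: int = 0,
    poisson_noise: bool = True,
):
    """Render tracks as Gaussian spots on a constant background.

    Each localization becomes a 2D Gaussian of integrated intensity
    ``photons_per_spot`` evaluated at pixel centers; Poisson noise is applied
    to the whole frame unless disabled. Spots whose centers fall outside the
    field are clipped with a warning. Returns (stack, truth) where truth is a
    list of (frame, particle_id, x_px, y_px) rows.
    """
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    n_frames = max(int(t.frames.max()) for t in tracks) + 1 if tracks else 0
    stack = np.full((n_frames, *shape), float(background_level))
    amp = photons_per_spot / (2 * np.pi * psf_sigma**2)
    r = int(np.ceil(4 * psf_sigma))
    truth = []
    clipped = 0
    for t in tracks:
        for f, (x_um, y_um) in zip(t.frames, t.xy):
            x, y = x_um / pixel_size, y_um / pixel_size
            if not (0 <= x < shape[1] and 0 <= y < shape[0]):
                clipped += 1
                continue
            truth.append((int(f), t.particle_id, x, y))
            x0, x1 = max(0, int(x) - r), min(shape[1], int(x) + r + 1)
            y0, y1 = max(0, int(y) - r), min(shape[0], int(y) + r + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            stack[f, y0:y1, x0:x1] += amp * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2 * psf_sigma**2))
    if clipped:
        _warnings.warn(f"{clipped} localizations outside the field were clipped",
                       stacklevel=2)
    if poisson_noise:
        stack = rng.poisson(stack).astype(float)
    return stack, truth


# ---------------------------------------------------------------------------
# FRAP


def simulate_frap_curve(gt: FRAPGroundTruth, timepoints, seed: int) -> frap.FRAPTrace:
    """Noisy Axelrod recovery trace sampled at ``timepoints`` (t = 0 at the
    first post-bleach frame)."""
    t = np.asarray(timepoints, dtype=float)
    if t[0] != 0:
        raise ValueError("timepoints must start at 0 (first post-bleach frame)")
    rng = np.random.default_rng(seed)
    clean = frap.axelrod_recovery(t, gt.bleach_depth_K, gt.tau_D,
                                  gt.mobile_fraction_Mf, gt.baseline_F0)
    noisy = clean + rng.normal(0.0, gt.noise_sd, size=t.shape)
    return frap.FRAPTrace(times=t, intensities=noisy, prebleach_intensity=1.0,
                          postbleach_intensity=float(clean[0]))


# ---------------------------------------------------------------------------
# calcium


@dataclass
class CalciumTruth:
    cell_id: int
    responder: bool
    n_peaks: int
    peak_times: tuple[float, ...] = field(default_factory=tuple)


def simulate_calcium_population(
    gt: CalciumPopulationGroundTruth, seed: int
) -> tuple[list[calcium.CalciumTrace], list[CalciumTruth]]:
    """Simulate per-cell calcium traces with ground-truth labels.

    Responders get one Gaussian transient (or 2-3 for multi-peak cells) at
    exponentially distributed latencies, scaled in baseline multiples;
    non-responders are baseline plus noise.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, gt.duration, gt.frame_interval)
    sigma = gt.peak_width / 2.3548  # FWHM -> sd
    traces, truths = [], []
    for i in range(gt.n_cells):
        y = np.full_like(t, gt.baseline_level)
        responder = rng.random() < gt.responder_fraction
        peak_times: list[float] = []
        if responder:
            multi = rng.random() < gt.multipeak_fraction_of_responders
            n_peaks = int(rng.integers(2, 4)) if multi else 1
            t0 = min(rng.exponential(gt.latency_mean), 0.7 * gt.duration)
            peak_times.append(t0)
            for _ in range(n_peaks - 1):
                gap = rng.uniform(6 * sigma, max(12 * sigma, 60.0))
                nxt = peak_times[-1] + gap
                if nxt < gt.duration - 3 * sigma:
                    peak_times.append(nxt)
            for tp in peak_times:
                mult = max(rng.normal(*gt.peak_height_multiples), 1.5)
                y = y + (mult - 1.0) * gt.baseline_level * np.exp(
                    -((t - tp) ** 2) / (2 * sigma**2))
        y = y + rng.normal(0.0, gt.noise_sd, size=t.shape)
        traces.append(calcium.CalciumTrace(cell_id=i, times=t.copy(),
                                           intensities=y, valid_from=0.0))
        truths.append(CalciumTruth(cell_id=i, responder=bool(peak_times),
                                   n_peaks=len(peak_times),
                                   peak_times=tuple(peak_times)))
    return traces, truths


def render_calcium_stack(
    traces: list[calcium.CalciumTrace],
    shape: tuple[int, int] = (256, 256),
    cell_radius: int = 6,
    background_level: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Render traces as static disks on a grid (one disk per cell).

    Returns (stack, centers) with centers as (cell_id, x, y) rows.
    """
    rng = np.random.default_rng(seed)
    n_frames = len(traces[0].times)
    pitch = 4 * cell_radius
    per_row = (shape[1] - pitch) // pitch
    if per_row < 1 or len(traces) > per_row * ((shape[0] - pitch) // pitch):
        raise ValueError("too many cells for the field of view")
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    stack = np.full((n_frames, *shape), float(background_level))
    centers = []
    for k, tr in enumerate(traces):
        cx = pitch + (k % per_row) * pitch
        cy = pitch + (k // per_row) * pitch
        centers.append((tr.cell_id, cx, cy))
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell_radius**2
        stack[:, disk] = tr.intensities[:, None]
    stack += rng.normal(0.0, noise_sd, size=stack.shape)
    return stack, centers


# ---------------------------------------------------------------------------
# contact images


def _geometry_mask(shape: tuple[int, int], geometry) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for item in geometry:
        kind = item[0]
        if kind == "disk":
            _, cx, cy, r = item
            if not (0 <= cx < shape[1] and 0 <= cy < shape[0]):
                raise ValueError("contact region outside image")
            mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        elif kind == "ellipse":
            _, cx, cy, a, b, theta = item
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
        else:
            raise ValueError(f"unknown geometry kind {kind!r}")
    return mask


def simulate_contact_image(gt: ContactGroundTruth, seed: int):
    """Two-channel contact image with a depleted probe channel.

    The probe channel inside the contact equals ``depletion_factor_ch2``
    times its level over the rest of the cell, so exclusion on the
    ground-truth masks is exactly 1 - depletion_factor when noise and
    gradient are zero. Returns (TwoChannelContactImage, truth dict with
    ``contact_mask`` and ``cell_mask``).
    """
    rng = np.random.default_rng(seed)
    shape = gt.image_shape
    contact = _geometry_mask(shape, gt.contact_geometry)
    cell = _geometry_mask(shape, gt.cell_geometry) | contact
    ch1 = np.full(shape, gt.contact_background)
    ch1[contact] *= gt.enrichment_factor_ch1
    ch2 = np.full(shape, gt.probe_background)
    ch2[cell] = gt.base_level
    ch2[contact] = gt.base_level * gt.depletion_factor_ch2
    if gt.background_gradient:
        ramp = gt.background_gradient * np.arange(shape[1])[None, :]
        ch1 = ch1 + ramp
        ch2 = ch2 + ramp
    if gt.noise_sd:
        ch1 = ch1 + rng.normal(0.0, gt.noise_sd, size=shape)
        ch2 = ch2 + rng.normal(0.0, gt.noise_sd, size=shape)
    img = TwoChannelContactImage(np.clip(ch1, 0, None), np.clip(ch2, 0, None))
    return img, {"contact_mask": contact, "cell_mask": cell}


# ---------------------------------------------------------------------------
# AFM force curves


def _hertz(gt: ForceCurveGroundTruth, delta_um, E: float):
    if gt.indenter_radius_um is not None:
        return afm.hertz_force_sphere(delta_um, E, gt.indenter_radius_um,
                                      gt.poisson_ratio)
    return afm.hertz_force_pyramid(delta_um, E, gt.half_angle_deg,
                                   gt.poisson_ratio)


def _delta_at_force(gt: ForceCurveGroundTruth, force_nN: float, E: float) -> float:
    if gt.indenter_radius_um is not None:
        coef = (4.0 / 3.0) * (E / (1 - gt.poisson_ratio**2)) * np.sqrt(
            gt.indenter_radius_um * 1e-6) * 1e9 * (1e-6) ** 1.5
        return float((force_nN / coef) ** (2.0 / 3.0))
    return afm._pyramid_delta_at_force(force_nN, E, gt.half_angle_deg,
                                       gt.poisson_ratio)


def simulate_force_curve(gt: ForceCurveGroundTruth, seed: int) -> afm.ForceCurve:
    """Synthetic approach curve: flat baseline, Hertzian contact, optional
    push-through.

    With ``z_jump_nm > 0`` the layer branch is followed until the force
    reaches ``breakthrough_force_nN``; the curve then bridges a z extent of
    z_jump (flat when layer and substrate stiffness match) and continues on
    the substrate's Hertz branch whose contact point is shifted by z_jump
    toward the substrate.
    """
    h = gt.sampling_step_nm * 1e-3  # um
    c = gt.contact_point_um
    E_sub = gt.substrate_modulus_E or gt.young_modulus_E
    zj = gt.z_jump_nm * 1e-3
    if gt.z_jump_nm > 0:
        delta_b = _delta_at_force(gt, gt.breakthrough_force_nN, gt.young_modulus_E)
        post_margin = 0.7
        auto_range = c + delta_b + zj + post_margin
    else:
        delta_b = None
        auto_range = c + 1.0
    z_range = gt.z_range_um if gt.z_range_um is not None else auto_range
    z = np.arange(0.0, z_range + 0.5 * h, h)
    if c >= z[-1]:
        raise ValueError("contact point outside the sampled z range")
    force = np.zeros_like(z)
    in_contact = z >= c
    if gt.z_jump_nm == 0:
        force[in_contact] = _hertz(gt, z[in_contact] - c, gt.young_modulus_E)
    else:
        z_b = c + delta_b
        z_e = z_b + zj
        f_end = float(_hertz(gt, z_e - c - zj, E_sub))
        layer = in_contact & (z < z_b)
        bridge = (z >= z_b) & (z < z_e)
        substrate = z >= z_e
        force[layer] = _hertz(gt, z[layer] - c, gt.young_modulus_E)
        if bridge.any():
            frac = (z[bridge] - z_b) / max(zj, 1e-12)
            force[bridge] = gt.breakthrough_force_nN + frac * (
                f_end - gt.breakthrough_force_nN)
        force[substrate] = _hertz(gt, z[substrate] - c - zj, E_sub)
    if gt.noise_sd_nN > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, gt.noise_sd_nN, size=z.shape)
    meta = {"ground_truth": gt, "seed": seed}
    return afm.ForceCurve(z=z, force=force, metadata=meta)
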