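"""Single-particle tracking and diffusion analysis.

Detection (Gaussian-fit localization), greedy nearest-neighbor linking,
ensemble mean-square-displacement (MSD) fitting with static and dynamic
error terms, and jump-distance (JD) mixture analysis of per-step squared
displacements.

Units: positions are in pixels at the detection layer and in micrometres
(um) at the analysis layer; the caller converts with a pixel size.
Time is in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max

__all__ = [
    "Localization",
    "Track",
    "MSDCurve",
    "MSDFit",
    "JDFit",
    "detect_particles",
    "link_tracks",
    "filter_tracks",
    "compute_ensemble_msd",
    "fit_msd",
    "jump_distance_fit",
]


@dataclass
class Localization:
    """A single sub-pixel localization in one frame."""

    frame: int
    x: float
    y: float
    intensity: float
    background: float
    snr: float


@dataclass
class Track:
    """Time-ordered 2D localizations of one particle.

    ``xy`` is an (n, 2) array; coordinates in um unless stated otherwise.
    """

    particle_id: int
    frames: np.ndarray
    xy: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy must have equal length")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    def displacements(self, lag: int = 1) -> np.ndarray:
        """Squared displacements at integer ``lag`` (contiguous frames only)."""
        idx = np.nonzero(self.frames[lag:] - self.frames[:-lag] == lag)[0]
        d = self.xy[idx + lag] - self.xy[idx]
        return np.einsum("ij,ij->i", d, d)


@dataclass
class MSDCurve:
    lag_times: np.ndarray  # s, starting at one frame interval
    msd: np.ndarray  # um^2
    sem: np.ndarray  # um^2
    n_tracks: int
    frame_interval: float


@dataclass
class MSDFit:
    """Linear MSD fit MSD(t) = 4 D t + 4 sigma^2 - (4/3) D t_E."""

    D: float  # um^2/s
    sigma_loc: float  # um
    exposure_time: float  # s
    n_points_fit: int
    residual: float  # rms, um^2
    clamped: bool = False  # D or sigma^2 hit the >= 0 bound

    @property
    def sigma_sq(self) -> float:
        """Static localization variance sigma^2 (um^2)."""
        return self.sigma_loc**2

    @property
    def offset(self) -> float:
        """Full fitted intercept 4 sigma^2 - (4/3) D t_E (um^2).

        Reported alongside sigma_loc and sigma_sq because published MSD
        intercepts are quoted in any of the three conventions.
        """
        return 4 * self.sigma_loc**2 - (4.0 / 3.0) * self.D * self.exposure_time


@dataclass
class JDFit:
    """Jump-distance mixture fit; components sorted fast-first (D descending)."""

    fractions: np.ndarray
    D: np.ndarray  # um^2/s
    delta_t: float  # s
    n_steps: int
    n_tracks: int
    log_likelihood: float
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    collapsed: bool = False

    @property
    def components(self) -> list[tuple[float, float]]:
        return [(float(f), float(d)) for f, d in zip(self.fractions, self.D)]


# ---------------------------------------------------------------------------
# detection


def _gauss2d(params, yy, xx):
    amp, x0, y0, sig, off = params
    return off + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sig**2))


def detect_particles(
    frame: np.ndarray,
    min_intensity: float,
    psf_sigma_guess: float = 1.3,
) -> list[Localization]:
    """Detect diffraction-limited spots in one 2D frame.

    Candidate maxima on a lightly smoothed frame are refined by 2D Gaussian
    least-squares fits on a local window. ``min_intensity`` is the minimum
    background-subtracted peak amplitude (raw-image units). SNR is
    (peak - local background) / background noise sd, the convention behind
    reported per-condition mean SNR values.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("detect_particles expects a single 2D frame")
    sm_sigma = 1.0
    smoothed = ndimage.gaussian_filter(frame, sm_sigma)
    # smoothing attenuates a Gaussian peak of sd s by s^2/(s^2+sm^2) (2D)
    atten = psf_sigma_guess**2 / (psf_sigma_guess**2 + sm_sigma**2)
    bg_global = np.median(smoothed)
    coords = peak_local_max(
        smoothed,
        min_distance=max(2, int(round(2 * psf_sigma_guess))),
        threshold_abs=bg_global + 0.5 * atten * min_intensity,
        exclude_border=False,
    )
    r = max(3, int(np.ceil(3 * psf_sigma_guess)))
    out: list[Localization] = []
    for py, px in coords:
        y0, y1 = max(0, py - r), min(frame.shape[0], py + r + 1)
        x0, x1 = max(0, px - r), min(frame.shape[1], px + r + 1)
        win = frame[y0:y1, x0:x1]
        if win.size < 9:
            continue
        border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
        bg = float(np.median(border))
        bg_sd = 1.4826 * float(np.median(np.abs(border - bg)))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        p0 = (max(frame[py, px] - bg, 1e-6), px, py, psf_sigma_guess, bg)
        try:
            res = optimize.least_squares(
                lambda p: (_gauss2d(p, yy, xx) - win).ravel(),
                p0,
                bounds=(
                    [0, x0 - 1, y0 - 1, 0.3 * psf_sigma_guess, -np.inf],
                    [np.inf, x1, y1, 3 * psf_sigma_guess, np.inf],
                ),
                max_nfev=200,
            )
        except ValueError:
            continue
        amp, xf, yf, _sig, off = res.x
        if amp < min_intensity:
            continue
        if not (0 <= xf < frame.shape[1] and 0 <= yf < frame.shape[0]):
            continue
        snr = amp / bg_sd if bg_sd > 0 else np.inf
        out.append(Localization(frame=-1, x=float(xf), y=float(yf),
                                intensity=float(amp), background=float(off),
                                snr=float(snr)))
    return out


# ---------------------------------------------------------------------------
# linking


def _mutual_nn_pairs(a: np.ndarray, b: np.ndarray, max_d: float) -> list[tuple[int, int]]:
    """Greedy smallest-distance-first assignment between point sets a and b."""
    if len(a) == 0 or len(b) == 0:
        return []
    dm = cdist(a, b)
    pairs: list[tuple[int, int]] = []
    while True:
        i, j = np.unravel_index(np.argmin(dm), dm.shape)
        if dm[i, j] > max_d:
            break
        pairs.append((int(i), int(j)))
        dm[i, :] = np.inf
        dm[:, j] = np.inf
        if not np.isfinite(dm).any():
            break
    return pairs


def link_tracks(
    per_frame: list[list[Localization]] | list[np.ndarray],
    max_displacement: float,
    frame_interval: float,
) -> list[Track]:
    """Link per-frame localizations into tracks by greedy nearest neighbor.

    No gap closing: a particle missing for one frame terminates its track.
    ``per_frame`` entries may be Localization lists or (n, 2) position arrays,
    in the same length units as ``max_displacement``.
    """
    pos_per_frame: list[np.ndarray] = []
    for locs in per_frame:
        if len(locs) and isinstance(locs[0], Localization):
            pos_per_frame.append(np.array([[l.x, l.y] for l in locs]))
        else:
            arr = np.asarray(locs, dtype=float).reshape(-1, 2)
            pos_per_frame.append(arr)

    next_id = 0
    active: dict[int, list[tuple[int, np.ndarray]]] = {}  # id -> [(frame, xy)]
    finished: list[list[tuple[int, np.ndarray]]] = []
    prev_ids: list[int] = []
    for f, pos in enumerate(pos_per_frame):
        if f == 0 or not prev_ids:
            new_ids = []
            for p in pos:
                active[next_id] = [(f, p)]
                new_ids.append(next_id)
                next_id += 1
            prev_ids = new_ids
            continue
        prev_pos = np.array([active[i][-1][1] for i in prev_ids]).reshape(-1, 2)
        pairs = _mutual_nn_pairs(prev_pos, pos, max_displacement)
        matched_prev = {i for i, _ in pairs}
        matched_cur = {j for _, j in pairs}
        cur_ids: list[int] = [None] * len(pos)  # type: ignore[list-item]
        for i, j in pairs:
            tid = prev_ids[i]
            active[tid].append((f, pos[j]))
            cur_ids[j] = tid
        for i, tid in enumerate(prev_ids):
            if i not in matched_prev:
                finished.append(active.pop(tid))
        for j, p in enumerate(pos):
            if j not in matched_cur:
                active[next_id] = [(f, p)]
                cur_ids[j] = next_id
                next_id += 1
        prev_ids = [tid for tid in cur_ids if tid is not None]
    finished.extend(active.values())

    tracks = []
    for k, pts in enumerate(finished):
        frames = np.array([f for f, _ in pts])
        xy = np.array([p for _, p in pts]).reshape(-1, 2)
        order = np.argsort(frames)
        tracks.append(Track(k, frames[order], xy[order], frame_interval))
    tracks.sort(key=lambda t: (t.frames[0], t.particle_id))
    return tracks


def filter_tracks(tracks: list[Track], min_length: int = 6) -> list[Track]:
    """Keep only tracks longer than five frames (>= ``min_length`` points)."""
    kept = [t for t in tracks if len(t) >= min_length]
    if tracks and not kept:
        warnings.warn("all tracks removed by length filter", stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# MSD


def compute_ensemble_msd(tracks: list[Track], max_lag: int) -> MSDCurve:
    """Ensemble MSD pooled over tracks and overlapping start frames.

    The standard error at each lag is computed from the pooled sample of
    squared displacements.
    """
    if not tracks:
        raise ValueError("no tracks")
    dts = {t.frame_interval for t in tracks}
    if len(dts) != 1:
        raise ValueError("tracks must share a common frame_interval")
    dt = dts.pop()
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag >= max(len(t) for t in tracks):
        raise ValueError("max_lag longer than every track")
    msd = np.empty(max_lag)
    sem = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        sq = np.concatenate([t.displacements(lag) for t in tracks if len(t) > lag])
        if sq.size == 0:
            raise ValueError(f"no displacements at lag {lag}")
        msd[lag - 1] = sq.mean()
        sem[lag - 1] = sq.std(ddof=1) / np.sqrt(sq.size) if sq.size > 1 else 0.0
    lags = dt * np.arange(1, max_lag + 1)
    return MSDCurve(lags, msd, sem, n_tracks=len(tracks), frame_interval=dt)


def fit_msd(
    curve: MSDCurve,
    n_points: int = 5,
    exposure_time: float = 0.0,
    model: str = "exposure",
) -> MSDFit:
    """Fit the first ``n_points`` lags of an ensemble MSD curve.

    model="exposure" (default): MSD = 4 D t + 4 sigma^2 - (4/3) D t_E with
    t_E = ``exposure_time`` (camera integration; motion-blur correction).
    model="lag": both time symbols read as the lag, collapsing the model to
    MSD = (8/3) D t + 4 sigma^2.

    Negative fitted D or sigma^2 are clamped to zero and flagged.
    """
    if n_points < 2:
        raise ValueError("need at least two points to fit")
    if len(curve.lag_times) < n_points:
        raise ValueError("curve has fewer lags than n_points")
    t = curve.lag_times[:n_points]
    y = curve.msd[:n_points]
    slope, intercept = np.polyfit(t, y, 1)
    clamped = False
    if model == "exposure":
        D = slope / 4.0
        if D < 0:
            D, clamped = 0.0, True
        sigma_sq = (intercept + (4.0 / 3.0) * D * exposure_time) / 4.0
    elif model == "lag":
        D = slope * 3.0 / 8.0
        if D < 0:
            D, clamped = 0.0, True
        sigma_sq = intercept / 4.0
    else:
        raise ValueError("model must be 'exposure' or 'lag'")
    if sigma_sq < 0:
        sigma_sq, clamped = 0.0, True
    resid = float(np.sqrt(np.mean((slope * t + intercept - y) ** 2)))
    return MSDFit(D=float(D), sigma_loc=float(np.sqrt(sigma_sq)),
                  exposure_time=exposure_time, n_points_fit=n_points,
                  residual=resid, clamped=clamped)


# ---------------------------------------------------------------------------
# jump-distance analysis


def _exp_mixture_em(s: np.ndarray, k: int, max_iter: int = 500, tol: float = 1e-10):
    """Maximum-likelihood exponential mixture on squared jumps s via EM.

    Returns (weights, means, loglik_path). The M-step is closed form, so the
    likelihood is non-decreasing at every iteration.
    """
    n = s.size
    order = np.sort(s)
    # quantile-block initialization: component j gets the j-th block mean
    means = np.array([
        order[int(j * n / k):int((j + 1) * n / k)].mean() for j in range(k)
    ])
    means = np.maximum(means, 1e-12 * max(order[-1], 1.0))
    w = np.full(k, 1.0 / k)
    path = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step
        log_pdf = -np.log(means)[None, :] - s[:, None] / means[None, :]
        log_w = np.log(w)[None, :] + log_pdf
        m = log_w.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_w - m).sum(axis=1))
        ll = float(lse.sum())
        path.append(ll)
        resp = np.exp(log_w - lse[:, None])
        # M-step
        nk = resp.sum(axis=0)
        w = nk / n
        means = (resp * s[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        means = np.maximum(means, 1e-300)
        if ll - prev < tol * max(1.0, abs(ll)):
            break
        prev = ll
    return w, means, np.array(path)


def jump_distance_fit(
    tracks: list[Track],
    n_components: int = 2,
    min_steps: int = 30,
    method: str = "mle",
    collapse_ratio: float = 2.0,
) -> JDFit:
    """Fit the one-step squared-displacement distribution to a mixture of
    freely diffusing populations.

    P(r^2, dt) = sum_j [f_j / (4 D_j dt)] exp(-r^2 / (4 D_j dt)), an
    exponential mixture in r^2 with component means 4 D_j dt. The default is
    maximum likelihood on the raw r^2 sample (EM); ``method="lsq"`` fits the
    same density to a histogram by least squares as a cross-check.

    If the fitted fast and slow coefficients are within ``collapse_ratio`` of
    each other the fit is collapsed to one component and flagged.
    """
    if not tracks:
        raise ValueError("no tracks")
    dts = {t.frame_interval for t in tracks}
    if len(dts) != 1:
        raise ValueError("tracks must share a common frame_interval")
    dt = dts.pop()
    s = np.concatenate([t.displacements(1) for t in tracks])
    s = s[s > 0]
    if s.size < min_steps:
        raise ValueError(
            f"only {s.size} one-step displacements; need at least {min_steps}"
        )

    if method == "mle":
        w, means, path = _exp_mixture_em(s, n_components)
    elif method == "lsq":
        w, means = _exp_mixture_lsq(s, n_components)
        path = np.empty(0)
    else:
        raise ValueError("method must be 'mle' or 'lsq'")

    collapsed = False
    if n_components > 1 and means.max() / max(means.min(), 1e-300) < collapse_ratio:
        w, means, path = _exp_mixture_em(s, 1)
        collapsed = True

    D = means / (4.0 * dt)
    order = np.argsort(D)[::-1]
    w, D, mu = w[order], D[order], means[order]
    if path.size:
        ll = float(path[-1])
    else:
        pdf = (w[None, :] / mu[None, :] * np.exp(-s[:, None] / mu[None, :])).sum(axis=1)
        ll = float(np.log(np.maximum(pdf, 1e-300)).sum())
    return JDFit(fractions=w, D=D, delta_t=dt, n_steps=int(s.size),
                 n_tracks=len(tracks), log_likelihood=ll, loglik_path=path,
                 collapsed=collapsed)


def _exp_mixture_lsq(s: np.ndarray, k: int):
    """Binned least-squares fit of the exponential mixture density."""
    counts, edges = np.histogram(s, bins="auto", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def density(params):
        logits = np.concatenate([params[:k - 1], [0.0]])
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        mu = np.exp(params[k - 1:])
        return (w[None, :] / mu[None, :] * np.exp(-centers[:, None] / mu[None, :])).sum(axis=1), w, mu

    order = np.sort(s)
    mu0 = [max(order[int(j * s.size / k):int((j + 1) * s.size / k)].mean(), 1e-12)
           for j in range(k)]
    p0 = np.concatenate([np.zeros(k - 1), np.log(mu0)])
    res = optimize.least_squares(lambda p: density(p)[0] - counts, p0, max_nfev=2000)
    _, w, mu = density(res.x)
    return w, mu
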