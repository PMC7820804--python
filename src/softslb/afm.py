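"""AFM approach force-curve analysis.

Young's modulus extraction with the Hertz contact model (spherical indenter;
Sneddon pyramidal variant also provided) and detection of supported-lipid-
bilayer push-through (breakthrough) events from changes in the gradient of
the force curve. The z extent of a breakthrough ("z-jump") measures bilayer
thickness.

Units at the interface: z in um, force in nN, moduli in Pa, z-jumps in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.signal import savgol_filter

__all__ = [
    "ForceCurve",
    "HertzFit",
    "PushThroughEvent",
    "hertz_force_sphere",
    "hertz_force_pyramid",
    "find_contact_point",
    "fit_hertz",
    "detect_push_through",
    "slope_ratio",
]


@dataclass
class ForceCurve:
    """Approach segment of an AFM force curve (z increases toward sample)."""

    z: np.ndarray  # um, piezo extension
    force: np.ndarray  # nN
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.shape != self.force.shape or self.z.ndim != 1:
            raise ValueError("z and force must be 1D arrays of equal length")
        if not np.all(np.isfinite(self.force)) or not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite values in force curve")
        d = np.diff(self.z)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("z must be strictly monotone within the segment")
        if len(d) and d[0] < 0:  # store approach in increasing-z order
            self.z = self.z[::-1].copy()
            self.force = self.force[::-1].copy()


@dataclass
class HertzFit:
    young_modulus_E: float  # Pa
    contact_point: float  # um
    poisson_ratio: float
    indenter_radius: float  # um
    max_indentation: float  # um used in the fit
    residual: float  # rms, nN
    force_offset: float = 0.0  # nN, jointly fitted baseline


@dataclass
class PushThroughEvent:
    z_start: float  # um
    z_end: float  # um
    z_jump: float  # nm
    breakthrough_force: float  # nN
    slope_before: float  # nN/um
    slope_after: float  # nN/um

    @property
    def slope_ratio(self) -> float:
        if self.slope_after == 0:
            raise ZeroDivisionError("slope_after is zero; ratio undefined")
        return self.slope_before / self.slope_after


# ---------------------------------------------------------------------------
# contact models

def hertz_force_sphere(delta_um, E_pa: float, radius_um: float,
                       poisson_ratio: float = 0.5):
    """Hertz force (nN) for a spherical indenter:
    F = (4/3) [E/(1-nu^2)] sqrt(R) delta^(3/2)."""
    d = np.maximum(np.asarray(delta_um, dtype=float), 0.0)
    f_newton = (4.0 / 3.0) * (E_pa / (1 - poisson_ratio**2)) * np.sqrt(
        radius_um * 1e-6) * (d * 1e-6) ** 1.5
    return f_newton * 1e9


def hertz_force_pyramid(delta_um, E_pa: float, half_angle_deg: float,
                        poisson_ratio: float = 0.5):
    """Sneddon force (nN) for a four-sided pyramidal indenter:
    F = [tan(alpha)/sqrt(2)] [E/(1-nu^2)] delta^2, alpha the face half-angle."""
    d = np.maximum(np.asarray(delta_um, dtype=float), 0.0)
    f_newton = (np.tan(np.radians(half_angle_deg)) / np.sqrt(2.0)) * (
        E_pa / (1 - poisson_ratio**2)) * (d * 1e-6) ** 2
    return f_newton * 1e9


def _pyramid_delta_at_force(force_nN: float, E_pa: float, half_angle_deg: float,
                            poisson_ratio: float = 0.5) -> float:
    """Indentation depth (um) at which the pyramidal Hertz law reaches a force."""
    coef = (np.tan(np.radians(half_angle_deg)) / np.sqrt(2.0)) * (
        E_pa / (1 - poisson_ratio**2)) * 1e-3  # nN per um^2
    return float(np.sqrt(force_nN / coef))


# ---------------------------------------------------------------------------
# contact point

def find_contact_point(curve: ForceCurve, baseline_fraction: float = 0.1,
                       refine: bool = True) -> float:
    """Locate the tip-sample contact point on an approach curve.

    The baseline (noise floor) is estimated on the leading
    ``baseline_fraction`` of the curve; the crossing of baseline + 3 sd is
    refined by a local power-law fit F = A (z - c)^p. Baseline-relative, so
    constant force offsets do not move the contact point.
    """
    n = len(curve.z)
    if n < 20:
        raise ValueError("curve too short")
    nb = max(10, int(baseline_fraction * n))
    base = curve.force[:nb]
    b0, bsd = float(base.mean()), float(base.std())
    thr = b0 + 3 * bsd
    above = curve.force > thr
    # require the crossing to persist (5 consecutive samples) to reject noise
    idx = None
    run = 0
    for i in range(nb, n):
        run = run + 1 if above[i] else 0
        if run >= min(5, n - nb):
            idx = i - run + 1
            break
    if idx is None:
        raise ValueError("no contact: force never exceeds the baseline band")
    c0 = curve.z[idx]
    if not refine:
        return float(c0)
    # refine on a window from the crossing up to a modest force level
    fmax = curve.force[-1] - b0
    hi = np.searchsorted(curve.force[idx:], b0 + max(0.3 * fmax, 6 * bsd)) + idx
    lo = max(nb, idx - (hi - idx))
    zz, ff = curve.z[lo:hi], curve.force[lo:hi] - b0

    def resid(p):
        log_a, c, pw = p
        d = np.maximum(zz - c, 0.0)
        return np.exp(log_a) * d**pw - ff

    try:
        res = optimize.least_squares(
            resid, [np.log(max(fmax, 1e-6)), c0, 1.7],
            bounds=([-50, curve.z[lo], 1.0], [50, curve.z[min(hi, n - 1)], 3.0]),
            max_nfev=500)
        c = float(res.x[1])
    except Exception:
        return float(c0)
    if not (curve.z[0] <= c <= curve.z[-1]):
        return float(c0)
    return c


# ---------------------------------------------------------------------------
# Hertz fit

def fit_hertz(
    curve: ForceCurve,
    indenter_radius: float,
    poisson_ratio: float = 0.5,
    max_indentation: float | None = None,
    fit_contact_point: bool = True,
) -> HertzFit:
    """Least-squares fit of the spherical Hertz model to an approach curve.

    By default the contact point and a constant force offset are fitted
    jointly with the modulus, which makes the result invariant to constant
    force offsets. ``max_indentation`` (um) limits the fit range beyond the
    initial contact-point estimate.
    """
    if indenter_radius <= 0:
        raise ValueError("indenter_radius must be positive")
    c0 = find_contact_point(curve)
    zmax = curve.z[-1] if max_indentation is None else c0 + max_indentation
    sel = curve.z <= zmax
    z, f = curve.z[sel], curve.force[sel]
    if not np.any(z > c0) or np.allclose(f[z > c0], f[z > c0][:1]):
        raise ValueError("no indentation beyond contact point")
    span = max(f.max() - f.min(), 1e-12)
    e0 = 1e3  # Pa, generic soft-matter starting point

    def model(params):
        log_e, c, off = params
        return hertz_force_sphere(z - c, np.exp(log_e), indenter_radius,
                                  poisson_ratio) + off

    p0 = [np.log(e0), c0, float(np.median(f[z < c0])) if np.any(z < c0) else 0.0]
    if fit_contact_point:
        res = optimize.least_squares(lambda p: model(p) - f, p0, max_nfev=2000)
        log_e, c, off = res.x
    else:
        res = optimize.least_squares(
            lambda p: model([p[0], c0, p[1]]) - f, [p0[0], p0[2]], max_nfev=2000)
        log_e, off = res.x
        c = c0
    if not res.success:
        raise RuntimeError(f"Hertz fit did not converge: {res.message}")
    E = float(np.exp(log_e))
    resid = float(np.sqrt(np.mean((model([log_e, c, off]) - f) ** 2)))
    return HertzFit(young_modulus_E=E, contact_point=float(c),
                    poisson_ratio=poisson_ratio, indenter_radius=indenter_radius,
                    max_indentation=float(curve.z[sel][-1] - c), residual=resid,
                    force_offset=float(off))


# ---------------------------------------------------------------------------
# push-through detection

def _quad_root_near(coefs: np.ndarray, level: float, z_near: float) -> float | None:
    """Real root of quadratic(z) = level closest to z_near, or None."""
    a, b, c = coefs
    roots = np.roots([a, b, c - level])
    roots = roots[np.abs(roots.imag) < 1e-9].real
    if roots.size == 0:
        return None
    return float(roots[np.argmin(np.abs(roots - z_near))])


def _edge_extrapolation_offset(f: np.ndarray, w: int) -> np.ndarray:
    """Backward-minus-forward linear-extrapolation offset at every split.

    At index i, a line fitted to the ``w`` samples before i and a line fitted
    to the ``w`` samples after i are both extrapolated to i; the offset
    between them is ~0 on a smooth branch (curvature bias cancels to second
    order) and equals the local force deficit slope * z_jump across a
    breakthrough. Entries outside [w, n-1-w] are 0.
    """
    n = len(f)
    u = np.arange(-w, 0, dtype=float)  # offsets of the left window
    ubar = u.mean()
    suu = ((u - ubar) ** 2).sum()
    k_left = 1.0 / w + (0.0 - ubar) * (u - ubar) / suu  # eval at u = 0
    k_right = k_left[::-1]  # mirrored forward window
    left = np.convolve(f, k_left[::-1], mode="full")
    right = np.convolve(f, k_right[::-1], mode="full")
    o = np.zeros(n)
    idx = np.arange(w, n - w)
    o[idx] = left[idx - 1] - right[idx + w]
    return o


def _scan_breaks(f: np.ndarray, lo: int, hi: int, w_base: int, thr: float,
                 noise_sd: float, i_c: int, depth: int = 0) -> list[int]:
    """Recursively locate change points (absolute indices) in f[lo:hi].

    The strongest above-threshold extrapolation offset marks an event; the
    flanking sub-segments are re-scanned with windows adapted to their
    length, which resolves stacked events closer together than the base
    window.
    """
    seg = f[lo:hi]
    w = min(w_base, max(15, len(seg) // 5))
    if len(seg) < 2 * w + 20 or depth > 8:
        return []
    o = _edge_extrapolation_offset(seg, w)
    sigma_o = noise_sd * np.sqrt(8.0 / w)
    # exclude the contact-point vicinity: the stiffness onset itself bends
    # the extrapolations within ~one window of the kink
    start = max(w, i_c + int(1.2 * w) - lo)
    stop = len(seg) - w
    if stop - start < 5:
        return []
    window = o[start:stop]
    peak = int(np.argmax(window)) + start
    if o[peak] <= thr * sigma_o:
        return []
    center = lo + peak
    guard = max(10, w // 10)
    found = [center]
    found += _scan_breaks(f, lo, center - guard, w_base, thr, noise_sd, i_c,
                          depth + 1)
    found += _scan_breaks(f, center + guard, hi, w_base, thr, noise_sd, i_c,
                          depth + 1)
    return found


def detect_push_through(
    curve: ForceCurve,
    gradient_window: int | None = None,
    drop_threshold: float = 5.0,
    refine_matched: bool = True,
) -> list[PushThroughEvent]:
    """Detect bilayer breakthrough events via changes in the force gradient.

    A breakthrough interrupts the positive-stiffness contact branch with a
    near-constant or falling stretch whose z extent is the bilayer z-jump.
    The detector scans a change-point statistic: at every split point, lines
    fitted to ``gradient_window`` samples on either side are extrapolated to
    the split, and their offset is compared against the baseline force noise
    (an offset appears exactly where the gradient structure changes; on
    smooth Hertzian branches the curvature bias of the two extrapolations
    cancels). Contiguous regions exceeding ``drop_threshold`` noise-sd are
    events. The z-jump is then measured as the horizontal offset between
    quadratic fits of the flanking branches at the breakthrough force; when
    the branch stiffnesses agree within ~20% (bilayer on a matched support)
    a joint shared-shape piecewise fit refines the jump.

    ``gradient_window=None`` auto-scales to ~1/6 of the curve (capped at
    1001 points): the offset noise shrinks as 1/sqrt(window) while the
    breakthrough signal does not decay, so wide windows are needed to
    resolve nanometre jumps at sub-nm sampling. Returns an empty list when
    no event is found (a smooth Hertzian curve is a valid outcome).
    """
    z, f = curve.z, curve.force
    n = len(z)
    if n < 60:
        raise ValueError("curve too short for push-through analysis")
    steps = np.diff(z)
    h = float(np.median(steps))
    if steps.std() > 1e-3 * h:  # resample to uniform spacing
        zu = np.arange(z[0], z[-1] + 0.5 * h, h)
        f = np.interp(zu, z, f)
        z = zu
        n = len(z)

    c = find_contact_point(ForceCurve(z, f), refine=False)
    i_c = int(np.searchsorted(z, c))
    w = gradient_window if gradient_window else min(1001, max(15, n // 6))
    w = min(w, (n - 2) // 2)
    # baseline noise from first differences: insensitive to the slow force
    # rise that leaks into the pre-contact stretch when the contact estimate
    # is biased late
    base = f[:max(10, i_c)]
    noise_sd = max(
        1.4826 * float(np.median(np.abs(np.diff(base)))) / np.sqrt(2.0), 1e-9)
    sigma_o = noise_sd * np.sqrt(8.0 / w)

    centers = sorted(_scan_breaks(f, 0, n, w, drop_threshold, noise_sd, i_c))
    if not centers:
        return []

    events: list[PushThroughEvent] = []
    guard = max(10, w // 10)
    for r_i, center in enumerate(centers):
        # branch fit windows flanking the event, clipped at neighbors/contact
        a_min = centers[r_i - 1] + guard if r_i > 0 else i_c + max(5, w // 20)
        b_max = centers[r_i + 1] - guard if r_i + 1 < len(centers) else n
        a0, a1 = max(a_min, center - guard - 3 * w), center - guard
        b0, b1 = center + guard, min(b_max, center + guard + 3 * w)
        if a1 - a0 < 30 or b1 - b0 < 30:
            continue
        qb = np.polyfit(z[a0:a1], f[a0:a1], 2)
        qa = np.polyfit(z[b0:b1], f[b0:b1], 2)
        ws = min(51, (a1 - a0) | 1)
        f_sm = savgol_filter(f, ws, 2)
        fb = float(f_sm[center])
        zb = _quad_root_near(qb, fb, z[a1])
        za = _quad_root_near(qa, fb, z[b0])
        if zb is None or za is None:
            continue
        slope_b = float(np.polyval(np.polyder(qb), zb))
        slope_a = float(np.polyval(np.polyder(qa), za))
        jump = za - zb
        if jump <= 0:
            continue
        if refine_matched and slope_a > 0 and 0.8 < slope_b / slope_a < 1.25:
            ref = _matched_shape_refine(z[a0:b1], f[a0:b1], qb, zb, jump)
            if ref is not None:
                zb, jump, fb = ref
                za = zb + jump
        events.append(PushThroughEvent(
            z_start=float(zb), z_end=float(za), z_jump=float(jump * 1e3),
            breakthrough_force=fb, slope_before=slope_b, slope_after=slope_a))
    return events


def _matched_shape_refine(z, f, qb, zb0, jump0):
    """Joint piecewise fit assuming equal bilayer/substrate stiffness.

    Model: F = A (z - c)^2 up to z_b, flat bridge of width ``jump``, then the
    same parabola shifted by ``jump``. Returns (z_b, jump, F_break) or None.
    """
    A0 = qb[0]
    if A0 <= 0:
        return None
    c0 = -qb[1] / (2 * A0)

    def model(p):
        a, cc, z_b, jmp = p
        fb = a * (z_b - cc) ** 2
        out = np.where(z <= z_b, a * np.maximum(z - cc, 0.0) ** 2,
                       np.where(z <= z_b + jmp, fb,
                                a * np.maximum(z - cc - jmp, 0.0) ** 2))
        return out

    p0 = [A0, c0, zb0, max(jump0, 1e-6)]
    try:
        res = optimize.least_squares(
            lambda p: model(p) - f, p0,
            bounds=([0, -np.inf, z[0], 0], [np.inf, z[-1], z[-1], z[-1] - z[0]]),
            max_nfev=400)
    except Exception:
        return None
    if not res.success:
        return None
    a, cc, z_b, jmp = res.x
    return float(z_b), float(jmp), float(a * (z_b - cc) ** 2)


def slope_ratio(event: PushThroughEvent) -> float:
    """Ratio of the contact slopes before and after push-through."""
    if event.slope_after == 0:
        raise ZeroDivisionError("slope_after is zero; ratio undefined")
    return event.slope_before / event.slope_after
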