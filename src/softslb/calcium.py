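"""Per-cell calcium-trace extraction and signaling metrics.

Cells are segmented per frame (Otsu on a smoothed frame), tracked by
centroid nearest-neighbor linking, and their mean-intensity traces analyzed
for transients. A cell "responds" when it shows >= 1 peak passing the height
and prominence criteria; "blinking" cells show > 1 peak. All thresholds are
expressed in multiples of the cell's own baseline, so the metrics are
invariant under rescaling the whole movie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .spt import _mutual_nn_pairs

__all__ = [
    "CalciumTrace",
    "PeakCall",
    "CellSummary",
    "PopulationSummary",
    "estimate_baseline",
    "extract_traces",
    "detect_peaks",
    "summarize_cell",
    "summarize_population",
]

DEFAULT_MIN_HEIGHT_MULTIPLE = 1.5
DEFAULT_MIN_PROMINENCE_MULTIPLE = 0.5


@dataclass
class CalciumTrace:
    cell_id: int
    times: np.ndarray  # s
    intensities: np.ndarray  # a.u.
    baseline: float | None = None  # a.u.; estimated lazily when None
    valid_from: float = 0.0  # s, first frame the cell was detected

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must match")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PeakCall:
    time: float  # s
    height_multiple: float  # peak / baseline
    prominence: float  # a.u.
    integrated_intensity: float  # a.u. * s, above baseline over the peak window


@dataclass
class CellSummary:
    cell_id: int
    n_peaks: int
    responding: bool
    multipeak: bool
    time_to_first_peak: float | None  # s from valid_from
    mean_height_multiple: float | None
    integrated_intensity: float  # summed over peaks


@dataclass
class PopulationSummary:
    n_cells: int
    fraction_responding: float
    fraction_multipeak_of_responders: float | None  # None when no responders
    mean_time_to_first_peak: float | None
    mean_integrated_intensity: float | None
    mean_height_multiple: float | None


def estimate_baseline(trace: CalciumTrace, n_frames: int = 10) -> float:
    """Median of the first ``n_frames`` valid frames of the trace."""
    sel = trace.times >= trace.valid_from
    head = trace.intensities[sel][:n_frames]
    if head.size == 0:
        raise ValueError("no valid frames to estimate a baseline")
    return float(np.median(head))


def extract_traces(
    stack: np.ndarray,
    min_cell_area: int = 20,
    smooth_sigma: float = 2.0,
    frame_interval: float = 1.0,
    max_move: float = 10.0,
) -> list[CalciumTrace]:
    """Segment and track cells in a single-channel time-lapse.

    Per frame: Otsu threshold on a Gaussian-smoothed copy, connected
    components of at least ``min_cell_area`` pixels, mean raw intensity per
    component. Components are tracked across frames by greedy centroid
    nearest-neighbor linking within ``max_move`` pixels.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, y, x) stack")
    per_frame_pos: list[np.ndarray] = []
    per_frame_mean: list[np.ndarray] = []
    for frame in stack:
        sm = ndimage.gaussian_filter(frame, smooth_sigma)
        if np.ptp(sm) == 0:
            per_frame_pos.append(np.empty((0, 2)))
            per_frame_mean.append(np.empty(0))
            continue
        # threshold on a log-compressed frame: keeps the background/cell
        # split stable when individual cells flare far above baseline
        compressed = np.log1p(np.clip(sm - sm.min(), 0, None))
        mask = compressed > threshold_otsu(compressed)
        bg = float(np.median(frame[~mask])) if (~mask).any() else 0.0
        lab = label(mask)
        cents, means = [], []
        for reg in regionprops(lab, intensity_image=frame):
            if reg.area < min_cell_area:
                continue
            vals = reg.image_intensity[reg.image]
            # half-max refinement: the Otsu mask includes the blurred rim,
            # which would dilute the mean with background pixels
            cut = bg + 0.5 * (np.percentile(vals, 90) - bg)
            sel = vals >= cut
            if sel.sum() < max(1, min_cell_area // 4):
                continue
            cents.append(reg.centroid[::-1])  # (x, y)
            means.append(float(vals[sel].mean()))
        per_frame_pos.append(np.asarray(cents).reshape(-1, 2))
        per_frame_mean.append(np.asarray(means))

    # link centroids; carry per-cell (frame, mean intensity) lists
    next_id = 0
    active: dict[int, list[tuple[int, float]]] = {}
    done: list[list[tuple[int, float]]] = []
    prev_ids: list[int] = []
    for f, pos in enumerate(per_frame_pos):
        means = per_frame_mean[f]
        if not prev_ids:
            prev_ids = []
            for j in range(len(pos)):
                active[next_id] = [(f, float(means[j]))]
                prev_ids.append(next_id)
                next_id += 1
            prev_pos = pos
            continue
        pairs = _mutual_nn_pairs(prev_pos, pos, max_move)
        matched_prev = {i for i, _ in pairs}
        matched_cur = {j for _, j in pairs}
        cur_ids: list[int | None] = [None] * len(pos)
        for i, j in pairs:
            tid = prev_ids[i]
            active[tid].append((f, float(means[j])))
            cur_ids[j] = tid
        for i, tid in enumerate(prev_ids):
            if i not in matched_prev:
                done.append(active.pop(tid))
        for j in range(len(pos)):
            if j not in matched_cur:
                active[next_id] = [(f, float(means[j]))]
                cur_ids[j] = next_id
                next_id += 1
        prev_ids = [tid for tid in cur_ids if tid is not None]
        prev_pos = pos[[j for j, tid in enumerate(cur_ids) if tid is not None]]
    done.extend(active.values())

    traces = []
    for k, pts in enumerate(sorted(done, key=lambda p: (p[0][0], -len(p)))):
        frames = np.array([f for f, _ in pts])
        vals = np.array([v for _, v in pts])
        traces.append(CalciumTrace(cell_id=k, times=frames * frame_interval,
                                   intensities=vals,
                                   valid_from=float(frames[0] * frame_interval)))
    if not traces:
        warnings.warn("no cells detected in stack", stacklevel=2)
    return traces


def detect_peaks(
    trace: CalciumTrace,
    min_height_multiple: float = DEFAULT_MIN_HEIGHT_MULTIPLE,
    min_prominence_multiple: float = DEFAULT_MIN_PROMINENCE_MULTIPLE,
    baseline_frames: int = 10,
) -> list[PeakCall]:
    """Detect calcium transients as local maxima with height and prominence
    thresholds expressed in baseline multiples."""
    b = trace.baseline if trace.baseline is not None else estimate_baseline(
        trace, baseline_frames)
    if b <= 0:
        raise ValueError("baseline must be positive")
    y = trace.intensities
    idx, props = find_peaks(
        y, height=min_height_multiple * b, prominence=min_prominence_multiple * b)
    calls = []
    for i, p in enumerate(idx):
        lb, rb = props["left_bases"][i], props["right_bases"][i]
        seg_t = trace.times[lb:rb + 1]
        seg_y = np.clip(y[lb:rb + 1] - b, 0.0, None)
        integ = float(np.trapezoid(seg_y, seg_t)) if len(seg_t) > 1 else 0.0
        calls.append(PeakCall(time=float(trace.times[p]),
                              height_multiple=float(y[p] / b),
                              prominence=float(props["prominences"][i]),
                              integrated_intensity=integ))
    return calls


def summarize_cell(trace: CalciumTrace, peaks: list[PeakCall]) -> CellSummary:
    n = len(peaks)
    return CellSummary(
        cell_id=trace.cell_id,
        n_peaks=n,
        responding=n >= 1,
        multipeak=n > 1,
        time_to_first_peak=(peaks[0].time - trace.valid_from) if n else None,
        mean_height_multiple=(float(np.mean([p.height_multiple for p in peaks]))
                              if n else None),
        integrated_intensity=float(sum(p.integrated_intensity for p in peaks)),
    )


def summarize_population(cells: list[CellSummary]) -> PopulationSummary:
    if not cells:
        raise ValueError("need at least one cell")
    n = len(cells)
    responders = [c for c in cells if c.responding]
    frac_resp = len(responders) / n
    frac_multi = (sum(c.multipeak for c in responders) / len(responders)
                  if responders else None)
    lat = [c.time_to_first_peak for c in responders]
    hts = [c.mean_height_multiple for c in responders]
    return PopulationSummary(
        n_cells=n,
        fraction_responding=frac_resp,
        fraction_multipeak_of_responders=frac_multi,
        mean_time_to_first_peak=float(np.mean(lat)) if lat else None,
        mean_integrated_intensity=(float(np.mean(
            [c.integrated_intensity for c in responders])) if responders else None),
        mean_height_multiple=float(np.mean(hts)) if hts else None,
    )
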