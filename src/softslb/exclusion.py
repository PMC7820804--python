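"""Receptor-exclusion quantification at adhesion contacts.

Two registered channels per cell: an adhesion marker (e.g. rCD2) defining
the close contact and a probe channel (e.g. the large phosphatase CD45)
whose depletion is quantified as

    Exclusion = 1 - mean(probe inside contact) / mean(probe outside contact)

where "outside" is the rest of the cell footprint (union of the contact mask
and the probe's own Otsu mask). Exclusion of 1 means complete depletion;
negative values (enrichment) are reported, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import remove_small_objects
from skimage.restoration import rolling_ball

__all__ = [
    "TwoChannelContactImage",
    "ExclusionResult",
    "average_stack",
    "rolling_ball_background",
    "otsu_threshold",
    "otsu_mask",
    "compute_exclusion",
]


@dataclass
class TwoChannelContactImage:
    channel_contact: np.ndarray  # adhesion marker
    channel_probe: np.ndarray  # excluded-protein marker
    pixel_size: float = 1.0  # um/px

    def __post_init__(self) -> None:
        self.channel_contact = np.asarray(self.channel_contact, dtype=float)
        self.channel_probe = np.asarray(self.channel_probe, dtype=float)
        if self.channel_contact.shape != self.channel_probe.shape:
            raise ValueError("channels must have equal shape")
        if (self.channel_contact < 0).any() or (self.channel_probe < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass
class ExclusionResult:
    contact_mask: np.ndarray
    cell_mask: np.ndarray
    mean_in: float
    mean_out: float
    exclusion: float  # 1 - mean_in / mean_out


def average_stack(stack: np.ndarray) -> np.ndarray:
    """Pixel-wise mean over the frames of a stack."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("expected a non-empty (frames, y, x) stack")
    return stack.mean(axis=0)


def rolling_ball_background(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction (negatives clipped to zero)."""
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(image.shape):
        raise ValueError("radius must be smaller than the image")
    bg = rolling_ball(image, radius=radius)
    return np.clip(image - bg, 0.0, None)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold over a 256-bin histogram between image min and max.

    Maximizes the inter-class variance; on ties the lowest threshold wins.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise ValueError("degenerate histogram: image is constant")
    counts, edges = np.histogram(image, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    sum0 = np.cumsum(counts * centers)
    mu0 = np.where(w0 > 0, sum0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (sum0[-1] - sum0) / np.maximum(w1, 1), 0.0)
    between = w0[:-1] * w1[:-1] * (mu0[:-1] - mu1[:-1]) ** 2
    k = int(np.argmax(between))
    return float(edges[k + 1])


def otsu_mask(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Binary mask of pixels above the Otsu threshold."""
    return np.asarray(image, dtype=float) > otsu_threshold(image, nbins)


def compute_exclusion(img: TwoChannelContactImage,
                      min_object_size: int = 0) -> ExclusionResult:
    """Quantify probe exclusion from the contact.

    contact mask = Otsu(contact channel); cell mask = contact mask united
    with Otsu(probe channel); mean probe intensity inside the contact vs over
    the rest of the cell footprint gives Exclusion = 1 - mean_in / mean_out.
    ``min_object_size`` optionally removes small mask islands (off by
    default).
    """
    contact = otsu_mask(img.channel_contact)
    probe_mask = otsu_mask(img.channel_probe)
    if min_object_size > 0:
        contact = remove_small_objects(contact, min_object_size)
        probe_mask = remove_small_objects(probe_mask, min_object_size)
    cell = contact | probe_mask
    outside = cell & ~contact
    if not contact.any():
        raise ValueError("empty contact mask")
    if not outside.any():
        raise ValueError("no cell region outside the contact")
    mean_in = float(img.channel_probe[contact].mean())
    mean_out = float(img.channel_probe[outside].mean())
    if mean_out == 0:
        raise ValueError("mean probe intensity outside the contact is zero")
    return ExclusionResult(contact_mask=contact, cell_mask=cell,
                           mean_in=mean_in, mean_out=mean_out,
                           exclusion=1.0 - mean_in / mean_out)
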