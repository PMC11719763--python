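"""Sinus-obstruction detection by per-element ray tracing.

The MRI data between every array element and the target is traced as a
pyramid of rays. Ray brightness is normalized globally: the mean over the
first 1 mm of all rays (air just outside the head) maps to 0 and the 90th
percentile over the last 2 mm of all rays (white matter around the target)
maps to 1. A ray is *blocked* when any sample on its intracranial portion
falls below 10% of white-matter brightness — on T1-like contrast only
air-filled spaces (sinuses) are that dark.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .array_model import ArrayGeometry, TransducerPose
from .exceptions import DegenerateNormalizationError
from .head_volume import HeadVolume, sample_ray

#: Fraction of white-matter brightness below which a voxel counts as air.
BLOCKED_THRESHOLD = 0.10

TABLE_BINS = ("None", "<10%", "10-20%", "20-30%", ">30%")


@dataclass(frozen=True)
class RayBundle:
    """Per-element ray samples on a common step, NaN-padded to equal length.

    ``samples[i, k]`` is the intensity at arc length ``k * step_mm`` from
    element i toward the target; rays end at the target so trailing entries
    are NaN. ``normalization`` holds the (air_ref, wm_ref) references once
    :func:`normalize_rays` has run.
    """

    samples: np.ndarray  # (n_elements, n_max_samples)
    step_mm: float
    lengths_mm: np.ndarray  # (n_elements,)
    normalization: tuple | None = None

    @property
    def n_rays(self) -> int:
        return self.samples.shape[0]

    def arc_lengths(self) -> np.ndarray:
        return np.arange(self.samples.shape[1]) * self.step_mm


def trace_bundle(volume: HeadVolume, geom: ArrayGeometry, pose: TransducerPose,
                 target_ras, step_mm: float = 0.5) -> RayBundle:
    """Trace equal-step rays from every element center to the target."""
    target_ras = np.asarray(target_ras, float)
    starts = pose.to_ras(geom.element_centers)
    rows = []
    lengths = np.empty(geom.n_active)
    for i, p0 in enumerate(starts):
        arc, vals = sample_ray(volume, p0, target_ras, step_mm)
        rows.append(vals)
        lengths[i] = float(np.linalg.norm(target_ras - p0))
    n_max = max(len(r) for r in rows)
    samples = np.full((geom.n_active, n_max), np.nan)
    for i, r in enumerate(rows):
        samples[i, :len(r)] = r
    return RayBundle(samples, step_mm, lengths)


def normalize_rays(bundle: RayBundle) -> RayBundle:
    """Affine brightness normalization: air -> 0, white matter -> 1.

    air_ref is the mean over the first 1 mm of all rays; wm_ref is the 90th
    percentile over the last 2 mm of all rays (nearest the target).
    """
    if bundle.lengths_mm.min() < 3.0:
        raise ValueError("rays must be at least 3 mm long to normalize")
    arc = bundle.arc_lengths()
    head = bundle.samples[:, arc <= 1.0]
    air_ref = float(np.nanmean(head))
    tail_mask = arc[None, :] >= (bundle.lengths_mm[:, None] - 2.0)
    tail = bundle.samples[tail_mask & ~np.isnan(bundle.samples)]
    wm_ref = float(np.percentile(tail, 90.0))
    if abs(wm_ref - air_ref) < 1e-12:
        raise DegenerateNormalizationError(
            "air and white-matter references coincide (flat volume)")
    normed = (bundle.samples - air_ref) / (wm_ref - air_ref)
    return replace(bundle, samples=normed, normalization=(air_ref, wm_ref))


def detect_blocked(bundle: RayBundle, threshold: float = BLOCKED_THRESHOLD,
                   skip_mm: float = 1.0, skip_leading_air: bool = True
                   ) -> np.ndarray:
    """Per-element blocked flags on a normalized bundle.

    The leading portion of each ray is excluded from the test: always the
    first ``skip_mm``, and (by default) the contiguous sub-threshold run at
    the ray start — the air between the array face and the skin, which is not
    a sinus. A ray is blocked if any remaining sample falls below
    ``threshold``.
    """
    if bundle.normalization is None:
        raise ValueError("bundle must be normalized first")
    arc = bundle.arc_lengths()
    s = bundle.samples
    exclude = np.isnan(s) | (arc[None, :] < skip_mm)
    if skip_leading_air:
        below = (s < threshold) | np.isnan(s)
        # first index where the ray rises to/above threshold
        entry = np.argmin(below, axis=1)  # 0 if first sample already >= thr
        all_below = below.all(axis=1)
        entry[all_below] = s.shape[1]
        exclude |= np.arange(s.shape[1])[None, :] < entry[:, None]
    tested = np.where(exclude, np.inf, s)
    return (tested < threshold).any(axis=1)


def blocked_fraction(blocked: np.ndarray) -> float:
    return float(np.count_nonzero(blocked)) / blocked.size


def blocked_fraction_bin(fraction: float) -> str:
    """Categorize a blocked-element fraction into the reporting bins.

    'None' is reserved for exactly zero; other bins are left-closed:
    [0.10, 0.20) -> '10-20%', etc.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return "None"
    if fraction < 0.10:
        return "<10%"
    if fraction < 0.20:
        return "10-20%"
    if fraction < 0.30:
        return "20-30%"
    return ">30%"


def analyze_sinus_blockage(volume: HeadVolume, geom: ArrayGeometry,
                           pose: TransducerPose, target_ras,
                           step_mm: float = 0.5,
                           threshold: float = BLOCKED_THRESHOLD) -> dict:
    """End-to-end sinus analysis: trace, normalize, detect, summarize."""
    bundle = normalize_rays(trace_bundle(volume, geom, pose, target_ras, step_mm))
    blocked = detect_blocked(bundle, threshold)
    frac = blocked_fraction(blocked)
    return {
        "blocked": blocked,
        "n_blocked": int(blocked.sum()),
        "blocked_fraction": frac,
        "bin": blocked_fraction_bin(frac),
        "bundle": bundle,
    }
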