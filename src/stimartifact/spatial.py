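"""Spatial characterization: median artifact maps, planar interpolation,
the saturation region at an amplifier limit, and the worst-case distance.

The saturation limit of interest derives from an implantable ultra-low-power
front-end: a 2.2 V supply behind a 66 dB (2000x) gain saturates at an
input-referred +/-1,100 uV.  The worst-case distance (WCD) is the maximum
distance from the stimulation-channel midpoint to the |V| = limit contour
of the interpolated artifact map — the radius a recording electrode must
stay outside of to avoid front-end saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from skimage import measure as _measure

from .core import (ArtifactAmplitudeMap, DipoleFitResult, ElectrodeSet,
                   EpochAnnotation, PipelineError, PulseResponses)

__all__ = ["InterpolatedField", "SaturationResult", "saturation_limit_uv",
           "epoch_artifact_map", "interpolate_map", "saturation_region",
           "summarize_fits"]

DEFAULT_SATURATION_LIMIT_UV = 1100.0


def saturation_limit_uv(supply_v: float = 2.2, gain: float = 2000.0) -> float:
    """Input-referred saturation limit (uV) of an amplifier front-end.

    An amplifier powered from ``supply_v`` volts with linear gain ``gain``
    clips once the input exceeds supply/gain; 2.2 V at 2000x gives 1100 uV.
    """
    if supply_v <= 0 or gain <= 0:
        raise ValueError("supply voltage and gain must be positive")
    return supply_v / gain * 1e6


def gain_from_db(gain_db: float) -> float:
    """Linear voltage gain from dB (66 dB ~ 2000x)."""
    return 10.0 ** (gain_db / 20.0)


def epoch_artifact_map(responses: PulseResponses,
                       annotation: EpochAnnotation) -> ArtifactAmplitudeMap:
    """Median signed per-pulse amplitude per included electrode."""
    values = {lab: float(np.median(a))
              for lab, a in responses.amplitudes.items()}
    if not values:
        raise PipelineError("epoch_artifact_map",
                            "no included channels remain for this epoch")
    return ArtifactAmplitudeMap(values=values,
                                stim_pair=annotation.stim_pair,
                                amplitude=annotation.amplitude,
                                excluded=dict(responses.excluded))


@dataclass(eq=False)
class InterpolatedField:
    """Piecewise-linear artifact field on the grid's least-squares plane."""

    xs: np.ndarray  # (nx,) plane coordinates, mm
    ys: np.ndarray  # (ny,)
    values: np.ndarray  # (ny, nx), NaN outside the electrode convex hull
    center: np.ndarray  # (3,) plane origin in 3-D mm
    axes: np.ndarray  # (2, 3) orthonormal in-plane axes
    points2d: Dict[str, np.ndarray]  # electrode label -> (2,) plane coords
    resolution: float
    interpolator: Optional[LinearNDInterpolator] = None

    def project(self, point: Sequence[float]) -> np.ndarray:
        """Project a 3-D point (mm) onto the field's plane coordinates."""
        p = np.asarray(point, dtype=float).reshape(3)
        return self.axes @ (p - self.center)

    def value_at(self, xy: Sequence[float]) -> float:
        """Exact piecewise-linear field value at 2-D plane coordinates."""
        if self.interpolator is not None:
            return float(self.interpolator(*np.asarray(xy, dtype=float)))
        x, y = xy
        i = int(np.clip(np.round((y - self.ys[0]) / self.resolution), 0,
                        len(self.ys) - 1))
        j = int(np.clip(np.round((x - self.xs[0]) / self.resolution), 0,
                        len(self.xs) - 1))
        return float(self.values[i, j])


def interpolate_map(amap: ArtifactAmplitudeMap, electrodes: ElectrodeSet,
                    resolution: float = 0.5) -> InterpolatedField:
    """Interpolate median amplitudes over the electrode plane.

    Included electrode positions are projected onto their least-squares
    plane; the map is piecewise-linear on a Delaunay triangulation of the
    projected positions and defined only inside their convex hull (no
    extrapolation).  Excluded electrodes contribute no nodes; positions
    inside the hull take values interpolated from their neighbours.
    """
    labels = [l for l in amap.values if l in electrodes.labels]
    if len(labels) < 3:
        raise PipelineError("interpolate_map",
                            "need >= 3 included electrodes to interpolate")
    pos = np.vstack([electrodes.position_of(l) for l in labels])
    center = pos.mean(axis=0)
    centered = pos - center
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise PipelineError("interpolate_map", "included electrodes are collinear")
    axes = vt[:2]
    pts2d = centered @ axes.T
    vals = np.array([amap.values[l] for l in labels])

    xmin, ymin = pts2d.min(axis=0)
    xmax, ymax = pts2d.max(axis=0)
    xs = np.arange(xmin, xmax + resolution / 2, resolution)
    ys = np.arange(ymin, ymax + resolution / 2, resolution)
    interp = LinearNDInterpolator(pts2d, vals, fill_value=np.nan)
    gx, gy = np.meshgrid(xs, ys)
    grid = interp(gx, gy)
    return InterpolatedField(xs=xs, ys=ys, values=grid, center=center,
                             axes=axes,
                             points2d={l: p for l, p in zip(labels, pts2d)},
                             resolution=resolution, interpolator=interp)


@dataclass(eq=False)
class SaturationResult:
    limit: float  # uV
    contours: List[np.ndarray]  # list of (m, 2) plane-coordinate polylines, mm
    wcd: float  # mm
    clipped_at_hull: bool
    midpoint2d: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def contour_points(self) -> np.ndarray:
        if not self.contours:
            return np.empty((0, 2))
        return np.vstack(self.contours)


def saturation_region(field: InterpolatedField,
                      midpoint: Sequence[float],
                      limit: float = DEFAULT_SATURATION_LIMIT_UV,
                      ) -> SaturationResult:
    """Saturation contour |V| = limit and the worst-case distance.

    ``midpoint`` is the stimulation-channel midpoint, either as 3-D mm
    coordinates (projected onto the field plane) or already-2-D plane
    coordinates.  If no raster point reaches the limit, WCD is 0 with an
    empty contour.  ``clipped_at_hull`` is set when the saturated region
    touches the electrode convex hull, in which case the WCD understates
    the true extent (the field is unobserved beyond the grid).
    """
    mid = np.asarray(midpoint, dtype=float).ravel()
    mid2d = field.project(mid) if mid.size == 3 else mid
    absfield = np.abs(field.values)
    nanmask = ~np.isfinite(absfield)
    work = np.where(nanmask, 0.0, absfield)
    sat = work >= limit
    if not sat.any():
        return SaturationResult(limit=limit, contours=[], wcd=0.0,
                                clipped_at_hull=False, midpoint2d=mid2d)

    # hull contact: saturated cell on the raster border or next to a NaN cell
    clipped = bool(sat[0, :].any() or sat[-1, :].any()
                   or sat[:, 0].any() or sat[:, -1].any())
    if not clipped and nanmask.any():
        neigh = np.zeros_like(sat)
        neigh[1:, :] |= nanmask[:-1, :]
        neigh[:-1, :] |= nanmask[1:, :]
        neigh[:, 1:] |= nanmask[:, :-1]
        neigh[:, :-1] |= nanmask[:, 1:]
        clipped = bool((sat & neigh).any())

    raw = _measure.find_contours(work, level=limit)
    contours = []
    for c in raw:  # (row, col) -> (x, y) mm
        xy = np.column_stack([field.xs[0] + c[:, 1] * field.resolution,
                              field.ys[0] + c[:, 0] * field.resolution])
        contours.append(xy)
    if contours:
        pts = np.vstack(contours)
        wcd = float(np.max(np.linalg.norm(pts - mid2d, axis=1)))
    else:
        # entire observed field saturated: fall back to farthest saturated cell
        ii, jj = np.nonzero(sat)
        pts = np.column_stack([field.xs[jj], field.ys[ii]])
        wcd = float(np.max(np.linalg.norm(pts - mid2d, axis=1)))
        clipped = True
    return SaturationResult(limit=limit, contours=contours, wcd=wcd,
                            clipped_at_hull=clipped, midpoint2d=mid2d)


def summarize_fits(fits: Sequence[DipoleFitResult]) -> Dict[str, Dict[str, float]]:
    """Median and MAD of k-hat, n-hat and R^2 across stimulation channels.

    MAD is the raw median absolute deviation, median(|x - median(x)|),
    robust against the outliers contributed by corner/edge stimulation
    channels.
    """
    if len(fits) == 0:
        raise ValueError("summarize_fits requires at least one fit")

    def med_mad(x: np.ndarray) -> Dict[str, float]:
        med = float(np.median(x))
        return {"median": med, "mad": float(np.median(np.abs(x - med)))}

    return {
        "k_hat_ohm_mm": med_mad(np.array([f.k_hat for f in fits])),
        "n_hat_uv": med_mad(np.array([f.n_hat for f in fits])),
        "r_squared": med_mad(np.array([f.r_squared for f in fits])),
    }
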