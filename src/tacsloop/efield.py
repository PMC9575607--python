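"""Analytic quasistatic electric-field model for the dual-site montage.

The scalp electrodes are treated as point current sources on the boundary of
a homogeneous conductive half-space.  A point source injecting current ``I``
into a half-space of conductivity ``sigma`` produces a radial field

    E(r) = I / (2 pi sigma r^2)

directed away from the source (the half-space doubles the usual full-space
solid angle factor 4 pi to 2 pi).  Montage fields follow by superposition.

Two derived quantities matter for montage design:

* the *midpoint shunt field* — the field component along the inter-site axis
  at a gray-matter point midway between the frontal and parietal sites.  For
  the in-phase condition mirror symmetry cancels it exactly; in the antiphase
  condition the two sites' contributions add, which is the shunt effect that
  this montage's geometry (returns close to their center, sites far apart)
  keeps below the 0.1 V/m physiological threshold;
* the *focality volume* — the gray-matter volume with field magnitude at or
  above 75% of the peak, the peak being the 99.9th percentile of voxel values
  (nearest-rank) to suppress outliers.  Smaller volume = more focal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .montage import Montage

__all__ = [
    "ShuntGeometry",
    "FieldGrid",
    "point_source_field",
    "montage_field",
    "midpoint_shunt_field",
    "focality_volume",
    "compare_conditions",
]

#: Field magnitude considered the threshold for measurable physiological
#: effects in neurons (V/m).
PHYSIOLOGICAL_THRESHOLD_V_PER_M = 0.1

_MM_TO_M = 1e-3
_MA_TO_A = 1e-3
_CM_TO_M = 1e-2


def point_source_field(
    current_ma: float,
    sigma: float,
    source_mm,
    eval_point_mm,
) -> np.ndarray:
    """Field vector (V/m) of one point electrode on a conductive half-space.

    Parameters
    ----------
    current_ma : signed injected current, mA peak.
    sigma : medium conductivity, S/m.
    source_mm, eval_point_mm : positions in mm.

    Raises
    ------
    ZeroDivisionError if the evaluation point coincides with the source.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    d = (np.asarray(eval_point_mm, dtype=float) - np.asarray(source_mm, dtype=float)) * _MM_TO_M
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ZeroDivisionError("evaluation point coincides with the source electrode")
    mag = (current_ma * _MA_TO_A) / (2.0 * np.pi * sigma * r * r)
    return mag * d / r


def montage_field(m: Montage, eval_points_mm, sigma: float = 0.275) -> np.ndarray:
    """Field magnitudes (V/m) of the full montage at each evaluation point.

    Vector superposition over all ten electrode contributions; linear in all
    currents.  ``eval_points_mm`` is (n, 3) or a single 3-vector.

    Raises
    ------
    ZeroDivisionError if any evaluation point coincides with an electrode.
    """
    pts = np.atleast_2d(np.asarray(eval_points_mm, dtype=float)) * _MM_TO_M
    pos = m.positions * _MM_TO_M
    cur = m.currents * _MA_TO_A
    diff = pts[:, None, :] - pos[None, :, :]  # (n, 10, 3)
    r = np.linalg.norm(diff, axis=2)  # (n, 10)
    if np.any(r == 0.0):
        raise ZeroDivisionError("evaluation point coincides with an electrode")
    vec = (cur[None, :, None] / (2.0 * np.pi * sigma * r[:, :, None] ** 3)) * diff
    mags = np.linalg.norm(vec.sum(axis=1), axis=1)
    if np.ndim(eval_points_mm) == 1:
        return mags[0]
    return mags


@dataclass(frozen=True)
class ShuntGeometry:
    """Sagittal-plane geometry for the midpoint shunt estimate.

    Distances (cm) are measured along the inter-site axis from the midpoint
    between the sites: ``d2`` to each site's center electrode (so the
    inter-site distance is ``2 * d2``), ``d1`` to the near return and ``d3``
    to the far return of each site (``d1 + d3 = 2 * d2`` when returns sit
    symmetrically at the center-return distance from their center).  ``depth``
    is the gray-matter evaluation depth below the scalp at the midpoint.
    """

    d1: float = 3.5  # cm, midpoint -> near return
    d2: float = 6.5  # cm, midpoint -> site center (inter-site distance 13 cm)
    d3: float = 9.5  # cm, midpoint -> far return
    sigma: float = 0.275  # S/m, gray matter
    depth: float = 1.5  # cm, scalp -> gray matter at midline

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "d3", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")


def midpoint_shunt_field(
    g: ShuntGeometry = ShuntGeometry(),
    center_current_ma: float = 1.0,
    condition: str = "anti_phase",
) -> float:
    """Axial field magnitude (V/m) at the gray-matter inter-site midpoint.

    Per-site contribution: the three electrodes on the inter-site axis (near
    return at ``d1``, center at ``d2``, far return at ``d3``; returns carry a
    quarter of the center current, opposite sign) each contribute an axial
    component ``I * d / (2 pi sigma R^3)`` with ``R = sqrt(d^2 + depth^2)``.
    In the in-phase condition the two sites' axial components cancel by
    mirror symmetry (returns exactly 0); in the antiphase condition they add,
    doubling the single-site value.

    The result is monotone increasing in ``center_current_ma`` and monotone
    decreasing in ``sigma``.
    """
    if condition not in ("in_phase", "anti_phase"):
        raise ValueError(f"bad condition {condition!r}")
    if condition == "in_phase":
        return 0.0

    i_center = center_current_ma * _MA_TO_A
    i_return = i_center / 4.0

    def axial(current_a: float, dist_cm: float) -> float:
        d = dist_cm * _CM_TO_M
        rr = np.hypot(d, g.depth * _CM_TO_M)
        return current_a * d / (2.0 * np.pi * g.sigma * rr**3)

    single_site = axial(i_center, g.d2) - axial(i_return, g.d1) - axial(i_return, g.d3)
    return abs(2.0 * single_site)


@dataclass
class FieldGrid:
    """Regular voxel grid of field magnitudes (V/m)."""

    voxel_size_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    values: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 0)))

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (not np.all(np.isfinite(self.values)) or np.any(self.values < 0)):
            raise ValueError("field magnitudes must be finite and >= 0")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img_or_path) -> "FieldGrid":
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) else nib.load(img_or_path)
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0]):
            raise ValueError(f"anisotropic voxels not supported: {zooms}")
        return cls(
            voxel_size_mm=float(zooms[0]),
            origin_mm=tuple(np.asarray(img.affine)[:3, 3]),
            values=np.asarray(img.dataobj, dtype=float),
        )


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the smallest value with at least ``q``% of
    the sample at or below it (rank = ceil(q/100 * n), 1-based)."""
    flat = np.sort(np.asarray(values, dtype=float).ravel())
    if flat.size == 0:
        raise ValueError("empty sample")
    # guard against float excess (e.g. 0.999 * 1000 = 999.0000000000001)
    rank = int(np.ceil(q / 100.0 * flat.size - 1e-9))
    rank = min(max(rank, 1), flat.size)
    return float(flat[rank - 1])


def focality_volume(grid: FieldGrid, threshold_frac: float = 0.75) -> tuple[float, float]:
    """Focality metric of a field grid.

    Returns ``(volume_mm3, peak_v_per_m)`` where peak is the 99.9th
    percentile (nearest rank) of voxel magnitudes and the volume counts
    voxels at or above ``threshold_frac * peak``.  Invariant under uniform
    scaling of all field values.  A degenerate all-zero grid returns the
    total grid volume with a warning (every voxel trivially meets a zero
    threshold).
    """
    if grid.values.size == 0:
        raise ValueError("empty field grid")
    peak = nearest_rank_percentile(grid.values, 99.9)
    if peak == 0.0:
        warnings.warn("all-zero field grid: focality volume equals total volume", stacklevel=2)
    n_above = int(np.count_nonzero(grid.values >= threshold_frac * peak))
    return n_above * grid.voxel_volume_mm3, peak


def compare_conditions(v_in_mm3: float, v_anti_mm3: float) -> float:
    """Percent change of the antiphase focality volume relative to in-phase,
    ``100 * (v_anti - v_in) / v_in`` (display-rounded by callers)."""
    if v_in_mm3 <= 0:
        raise ValueError(f"in-phase volume must be > 0, got {v_in_mm3}")
    return 100.0 * (v_anti_mm3 - v_in_mm3) / v_in_mm3
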