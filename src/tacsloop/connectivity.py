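"""Online evaluation engine: nuisance regression and windowed connectivity.

Mirrors a real-time fMRI pipeline at ROI level: as each volume arrives the
two ROI mean signals are residualized against an expanding nuisance design
(Legendre polynomial drift terms, six rigid-body motion parameters, mean
white-matter and ventricle signals, and RETROICOR Fourier terms of cardiac
and respiratory phase), then the block's evaluation window is scored with a
Pearson correlation and Fisher's r-to-z transform.  Scoring block ``b`` uses
only samples acquired before its window end — no lookahead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import scipy.linalg

from .schedule import HEMODYNAMIC_DELAY_S, RunSchedule, block_window_samples
from .simulate import RoiTimeSeries

__all__ = [
    "ConnectivityOutcome",
    "RoiMaskSpec",
    "sphere_mask",
    "build_nuisance_regressors",
    "residualize",
    "windowed_connectivity",
    "score_block",
    "fisher_z",
]

#: |r| is clipped here before atanh so degenerate windows give a finite z.
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityOutcome:
    """Per-block connectivity estimate; ``valid=False`` marks windows that
    failed preconditions (e.g. zero variance) and carries no r/z."""

    block_index: int
    r: float | None
    z: float | None
    n_samples: int
    valid: bool = True


def fisher_z(r: float) -> float:
    """Fisher r-to-z, with |r| clipped at 1 - 1e-7 for finiteness."""
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


@dataclass(frozen=True)
class RoiMaskSpec:
    """Sphere ROI on a regular voxel grid."""

    center_mm: tuple[float, float, float]
    radius_mm: float = 10.0
    voxel_size_mm: float = 2.0
    origin_mm: tuple[float, float, float] = (-90.0, -126.0, -72.0)
    shape: tuple[int, int, int] = (91, 109, 91)  # MNI-152 bounding box at 2 mm

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be > 0")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


def sphere_mask(spec: RoiMaskSpec) -> np.ndarray:
    """Binary voxel mask: voxels whose centers lie within the sphere.

    Warns if the sphere is clipped by the grid; raises on an empty mask
    (sphere entirely outside the grid).
    """
    origin = np.asarray(spec.origin_mm)
    center = np.asarray(spec.center_mm)
    lo = origin
    hi = origin + (np.asarray(spec.shape) - 1) * spec.voxel_size_mm
    if np.any(center - spec.radius_mm < lo) or np.any(center + spec.radius_mm > hi):
        warnings.warn("sphere extends beyond the grid; mask will be clipped", stacklevel=2)
    axes = [
        origin[i] + spec.voxel_size_mm * np.arange(spec.shape[i]) - center[i]
        for i in range(3)
    ]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    mask = d2 <= spec.radius_mm**2
    if not mask.any():
        raise ValueError("sphere mask is empty: center outside the grid")
    return mask


def mask_to_nifti(mask: np.ndarray, spec: RoiMaskSpec) -> nib.Nifti1Image:
    return nib.Nifti1Image(mask.astype(np.uint8), spec.affine)


def build_nuisance_regressors(
    ts: RoiTimeSeries,
    poly_order: int = 3,
    retroicor_order: int = 2,
    n_samples: int | None = None,
) -> np.ndarray:
    """Nuisance design matrix for the first ``n_samples`` samples.

    Column order: Legendre polynomials P0..P_poly_order on time rescaled to
    [-1, 1]; the six motion channels; WM; CSF; then for each physiological
    trace (cardiac first, then respiratory) the RETROICOR pairs
    cos(k phi), sin(k phi) for k = 1..retroicor_order.
    """
    if poly_order < 0 or retroicor_order < 0:
        raise ValueError("orders must be >= 0")
    n = ts.n_samples if n_samples is None else int(n_samples)
    if n > ts.n_samples:
        raise ValueError(f"requested {n} samples, series has {ts.n_samples}")
    t = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n)
    cols = [np.polynomial.legendre.legvander(t, poly_order)]
    cols.append(ts.motion[:n])
    cols.append(ts.wm[:n, None])
    cols.append(ts.csf[:n, None])
    for phase in (ts.cardiac_phase[:n], ts.resp_phase[:n]):
        for k in range(1, retroicor_order + 1):
            cols.append(np.column_stack([np.cos(k * phase), np.sin(k * phase)]))
    return np.column_stack(cols)


def residualize(series: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of ``series`` (n x m) against ``design``
    (n x k).

    Rank-deficient designs have their dependent columns dropped (with a
    warning) before the fit; residuals are orthogonal to every retained
    design column.  Requires more samples than design columns.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] == 1 and series.size > 1:
        series = series.T
    design = np.asarray(design, dtype=float)
    n, k = design.shape
    if series.shape[0] != n:
        raise ValueError("series and design sample counts differ")
    if n <= k:
        raise ValueError(f"need more samples ({n}) than design columns ({k})")
    rank = np.linalg.matrix_rank(design)
    if rank < k:
        warnings.warn(
            f"design rank {rank} < {k} columns; dropping dependent columns",
            stacklevel=2,
        )
        _, _, piv = scipy.linalg.qr(design, pivoting=True, mode="economic")
        design = design[:, np.sort(piv[:rank])]
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ beta


def windowed_connectivity(
    cleaned: np.ndarray, window: tuple[int, int], block_index: int
) -> ConnectivityOutcome:
    """Pearson correlation + Fisher z of the two channels over the window.

    Returns an invalid outcome (r, z unset) if either channel has zero
    variance in the window; the closed loop treats that as a failed block.
    """
    start, stop = window
    n = stop - start
    if n < 4:
        raise ValueError(f"window [{start}, {stop}) too short (need >= 4 samples)")
    seg = np.asarray(cleaned, dtype=float)[start:stop]
    if seg.shape[0] != n:
        raise ValueError(f"window [{start}, {stop}) exceeds the available samples")
    sd = seg.std(axis=0)
    if np.any(sd == 0.0):
        return ConnectivityOutcome(block_index, None, None, n, valid=False)
    r = float(np.corrcoef(seg[:, 0], seg[:, 1])[0, 1])
    return ConnectivityOutcome(block_index, r, fisher_z(r), n, valid=True)


def score_block(
    ts: RoiTimeSeries,
    run: RunSchedule,
    block_index: int,
    shift_s: float = HEMODYNAMIC_DELAY_S,
    window_s: float | None = None,
    poly_order: int = 3,
    retroicor_order: int = 2,
    residualize_first: bool = True,
) -> ConnectivityOutcome:
    """Score one block the way the online pipeline would.

    The nuisance design expands with acquisition: it is built from all
    samples up to the block's window end, the ROI signals are residualized
    over that causal span, and the window is then correlated.  Early in the
    run the full design can have as many columns as acquired samples; the
    trailing columns (highest-order RETROICOR terms last) are then dropped
    until at least two residual degrees of freedom remain.  With
    ``residualize_first=False`` the raw ROI means are correlated instead
    (order-of-operations variant).
    """
    b = run.blocks[block_index]
    start, stop = block_window_samples(b, run.tr, shift_s, window_s, run=run)
    if stop > ts.n_samples:
        raise ValueError(
            f"block {block_index} window ends at sample {stop}, "
            f"only {ts.n_samples} acquired"
        )
    if residualize_first:
        design = build_nuisance_regressors(ts, poly_order, retroicor_order, n_samples=stop)
        # Early in acquisition the projection rank can approach the causal
        # sample count; windowed residuals would then live in a low-dim
        # space and show spuriously perfect correlation.  Keep the residual
        # space at least window-length + 2 dimensions, dropping trailing
        # columns (highest-order RETROICOR terms go first).
        max_cols = max(1, stop - (stop - start) - 2)
        if design.shape[1] > max_cols:
            design = design[:, :max_cols]
        cleaned = residualize(ts.data[:stop], design)
    else:
        cleaned = ts.data[:stop]
    return windowed_connectivity(cleaned, (start, stop), block_index)
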