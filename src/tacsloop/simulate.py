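"""Synthetic two-ROI BOLD generator for desk-scale closed-loop testing.

The generator stands in for the scanner: it produces frontal/parietal ROI
mean signals at TR = 2 s whose within-block correlation depends on the
applied stimulation parameters through a hidden unimodal response surface
(:class:`SurfaceModel`).  The per-individual parameter-outcome relationship
is unknown in vivo, so the surface is an explicit model of the *assumption*
the closed loop relies on — that some setting couples the two regions more
strongly than others — not of any measured physiology.

Coupling is implemented by shared-latent mixing: for target correlation r,

    x = sqrt(|r|) s + sqrt(1 - |r|) e1
    y = sign(r) sqrt(|r|) s + sqrt(1 - |r|) e2

with s, e1, e2 independent unit normals per sample, giving population
correlation exactly r and unit marginal variance.  The coupling follows the
stimulation block with a pure 6-s hemodynamic onset lag, matching the 6-s
shift of the evaluation window; outside lagged windows the coupling is the
off-target baseline.  On top of the coupled signal the generator adds slow
polynomial drift, linear leakage of six rigid-body motion channels, white
matter / CSF signal leakage, sinusoids of cardiac and respiratory phase
(what RETROICOR regressors remove), and white measurement noise.

All randomness flows from a single seed; each block draws from its own
counter-keyed substream so that changing one block's parameters never
perturbs another block's data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .params import StimParams
from .schedule import HEMODYNAMIC_DELAY_S, RunSchedule

__all__ = [
    "SurfaceModel",
    "NuisanceModel",
    "RoiTimeSeries",
    "surface_coupling",
    "make_physio_traces",
    "simulate_run",
    "BlockwiseRunSimulator",
]


@dataclass(frozen=True)
class SurfaceModel:
    """Hidden stimulation-parameter -> inter-ROI coupling surface.

    A circular-Gaussian bump over (frequency, phase difference): coupling
    peaks at ``r_max`` at (``f_opt``, ``phi_opt``) and decays to ``r_base``
    with length scales ``width_f`` (Hz) and ``width_phi`` (degrees); phase
    distance is computed on the circle (wrap at 360).  The default optimum
    (6 Hz, 0 deg) mirrors the theta-band prior used to seed the optimizer.
    """

    f_opt: float = 6.0  # Hz
    phi_opt: float = 0.0  # degrees
    r_max: float = 0.8
    r_base: float = 0.0
    width_f: float = 20.0  # Hz
    width_phi: float = 60.0  # degrees
    noise_sd: float = 1.0  # white measurement noise, signal units
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.r_base <= self.r_max < 1.0):
            raise ValueError("need -1 < r_base <= r_max < 1")
        if self.width_f <= 0 or self.width_phi <= 0:
            raise ValueError("widths must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class NuisanceModel:
    """Amplitudes and rates of the structured nuisance components.

    Amplitudes are in units of the (unit-variance) coupled signal; set all
    to zero for a clean coupled-signal-only simulation.
    """

    drift_amp: float = 1.0  # slow Legendre drift (orders 1..3)
    motion_amp: float = 0.5  # leakage of the 6 motion channels
    wmcsf_amp: float = 0.5  # white-matter / CSF leakage
    physio_amp: float = 0.3  # cardiac + respiratory sinusoids
    # rates chosen so the TR-aliased frequencies of the first two cardiac
    # and respiratory harmonics are all distinct and away from 0: the
    # RETROICOR columns then stay linearly independent at TR = 2 s
    cardiac_hz: float = 1.17  # ~70 bpm (aliases: 0.17, 0.16 Hz)
    resp_hz: float = 0.31  # ~19 breaths/min (aliases: 0.19, 0.12 Hz)
    motion_step_sd: float = 0.05  # random-walk increment, mm or degrees

    @classmethod
    def none(cls) -> "NuisanceModel":
        return cls(drift_amp=0.0, motion_amp=0.0, wmcsf_amp=0.0, physio_amp=0.0)


@dataclass
class RoiTimeSeries:
    """TR-sampled two-ROI signal matrix plus the nuisance channels the
    real-time pipeline would receive from the scanner and peripherals."""

    tr: float
    data: np.ndarray  # (n, 2): frontal, parietal ROI means
    motion: np.ndarray  # (n, 6): three shifts, three rotations
    wm: np.ndarray  # (n,)
    csf: np.ndarray  # (n,)
    cardiac_phase: np.ndarray  # (n,), radians
    resp_phase: np.ndarray  # (n,), radians
    block_params: tuple[StimParams, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        for name in ("motion", "wm", "csf", "cardiac_phase", "resp_phase"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} samples, data has {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in data")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    def truncated(self, n: int) -> "RoiTimeSeries":
        """First ``n`` samples only — what a real-time consumer has seen."""
        return RoiTimeSeries(
            tr=self.tr,
            data=self.data[:n],
            motion=self.motion[:n],
            wm=self.wm[:n],
            csf=self.csf[:n],
            cardiac_phase=self.cardiac_phase[:n],
            resp_phase=self.resp_phase[:n],
            block_params=self.block_params,
            seed=self.seed,
        )

    def to_table(self) -> pd.DataFrame:
        cols = {
            "frontal": self.data[:, 0],
            "parietal": self.data[:, 1],
            **{f"motion_{i}": self.motion[:, i] for i in range(6)},
            "wm": self.wm,
            "csf": self.csf,
            "cardiac_phase": self.cardiac_phase,
            "resp_phase": self.resp_phase,
        }
        return pd.DataFrame(cols)

    def sidecar(self) -> dict:
        return {
            "tr": self.tr,
            "seed": self.seed,
            "block_params": [asdict(p) for p in self.block_params],
        }

    def save(self, table_path, sidecar_path) -> None:
        self.to_table().to_csv(table_path, sep="\t", index=False)
        with open(sidecar_path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=1)


def surface_coupling(m: SurfaceModel, p: StimParams) -> float:
    """Deterministic target correlation for one stimulation setting."""
    df = (p.frequency - m.f_opt) / m.width_f
    dphi = ((p.phase_diff - m.phi_opt + 180.0) % 360.0 - 180.0) / m.width_phi
    return m.r_base + (m.r_max - m.r_base) * float(np.exp(-(df**2) - dphi**2))


def make_physio_traces(
    n_samples: int, tr: float, cardiac_hz: float = 1.0, resp_hz: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Cardiac and respiratory phase vectors, ``2 pi rate t mod 2 pi``."""
    if cardiac_hz <= 0 or resp_hz <= 0:
        raise ValueError("physiological rates must be > 0")
    t = np.arange(n_samples) * tr
    return (2 * np.pi * cardiac_hz * t) % (2 * np.pi), (2 * np.pi * resp_hz * t) % (2 * np.pi)


def _block_rng(seed: int, block_index: int) -> np.random.Generator:
    # counter-keyed substream: block data never depends on other blocks
    return np.random.default_rng(np.random.SeedSequence([int(seed), 2 * block_index + 3]))


class BlockwiseRunSimulator:
    """Generates a run one stimulation block at a time.

    The closed loop only knows a block's parameters once the optimizer has
    proposed them, so samples are produced per block on demand; generating
    every block and concatenating reproduces :func:`simulate_run` exactly.
    """

    def __init__(
        self,
        run: RunSchedule,
        surface: SurfaceModel,
        seed: int | None = None,
        nuisance: NuisanceModel | None = None,
        delay_s: float = HEMODYNAMIC_DELAY_S,
    ):
        self.run = run
        self.surface = surface
        self.seed = int(surface.seed if seed is None else seed)
        self.nuisance = NuisanceModel() if nuisance is None else nuisance
        self.delay_s = delay_s
        n = run.n_samples
        self.data = np.full((n, 2), np.nan)
        self._generated = np.zeros(len(run.blocks), dtype=bool)
        self._params: list[StimParams | None] = [None] * len(run.blocks)
        self._make_nuisance_traces(n)

    def _make_nuisance_traces(self, n: int) -> None:
        nm = self.nuisance
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        t = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n)
        # slow drift: random Legendre coefficients, orders 1..3, per ROI
        coeffs = rng.normal(size=(4, 2))
        coeffs[0] = 0.0  # no constant offset; intercept handled by regression
        self._drift = nm.drift_amp * np.polynomial.legendre.legvander(t, 3) @ coeffs
        # rigid-body motion: slow random walk, 3 shifts + 3 rotations
        self.motion = np.cumsum(rng.normal(scale=nm.motion_step_sd, size=(n, 6)), axis=0)
        self._motion_coef = nm.motion_amp * rng.normal(size=(6, 2))
        # WM / CSF: AR(1)-smoothed traces leaking into both ROIs
        def ar1(x, a=0.8):
            y = np.empty_like(x)
            prev = 0.0
            for i, v in enumerate(x):
                prev = a * prev + np.sqrt(1 - a * a) * v
                y[i] = prev
            return y

        self.wm = ar1(rng.normal(size=n))
        self.csf = ar1(rng.normal(size=n))
        self._wmcsf_coef = nm.wmcsf_amp * rng.normal(size=(2, 2))
        self.cardiac_phase, self.resp_phase = make_physio_traces(
            n, self.run.tr, nm.cardiac_hz, nm.resp_hz
        )
        basis = np.column_stack(
            [
                np.cos(self.cardiac_phase),
                np.sin(self.cardiac_phase),
                np.cos(self.resp_phase),
                np.sin(self.resp_phase),
            ]
        )
        self._physio = nm.physio_amp * basis @ rng.normal(size=(4, 2))
        self._nuisance_sum = (
            self._drift
            + self.motion @ self._motion_coef
            + np.column_stack([self.wm, self.csf]) @ self._wmcsf_coef
            + self._physio
        )

    def _segment(self, block_index: int) -> tuple[int, int]:
        b = self.run.blocks[block_index]
        start = int(round(b.onset / self.run.tr))
        stop = int(round((b.onset + b.duration) / self.run.tr))
        return start, min(stop, self.run.n_samples)

    def generate_block(self, block_index: int, params: StimParams) -> tuple[int, int]:
        """Fill the block's samples given its stimulation parameters; returns
        the half-open sample range produced."""
        b = self.run.blocks[block_index]
        start, stop = self._segment(block_index)
        n_seg = stop - start
        # coupling active only in the hemodynamically lagged stimulation window
        t = (np.arange(start, stop) + 0.0) * self.run.tr
        w0 = b.onset + self.delay_s
        w1 = w0 + b.stim_duration
        r_target = surface_coupling(self.surface, params)
        r = np.where((t >= w0) & (t < w1), r_target, self.surface.r_base)

        rng = _block_rng(self.seed, block_index)
        s = rng.normal(size=n_seg)
        e = rng.normal(size=(n_seg, 2))
        a = np.sqrt(np.abs(r))
        c = np.sqrt(1.0 - np.abs(r))
        x = a * s + c * e[:, 0]
        y = np.sign(r) * a * s + c * e[:, 1]
        seg = np.column_stack([x, y])
        seg += self.surface.noise_sd * rng.normal(size=(n_seg, 2))
        seg += self._nuisance_sum[start:stop]
        self.data[start:stop] = seg
        self._generated[block_index] = True
        self._params[block_index] = params
        return start, stop

    def as_timeseries(self) -> RoiTimeSeries:
        if not self._generated.all():
            raise ValueError("not all blocks have been generated yet")
        return RoiTimeSeries(
            tr=self.run.tr,
            data=self.data.copy(),
            motion=self.motion.copy(),
            wm=self.wm.copy(),
            csf=self.csf.copy(),
            cardiac_phase=self.cardiac_phase.copy(),
            resp_phase=self.resp_phase.copy(),
            block_params=tuple(self._params),  # type: ignore[arg-type]
            seed=self.seed,
        )

    def partial_timeseries(self, n_samples: int) -> RoiTimeSeries:
        """Samples [0, n_samples) — only valid once those blocks exist."""
        if np.any(np.isnan(self.data[:n_samples])):
            raise ValueError("requested samples include ungenerated blocks")
        full = RoiTimeSeries(
            tr=self.run.tr,
            data=np.nan_to_num(self.data, copy=True),
            motion=self.motion,
            wm=self.wm,
            csf=self.csf,
            cardiac_phase=self.cardiac_phase,
            resp_phase=self.resp_phase,
            seed=self.seed,
        )
        return full.truncated(n_samples)


def simulate_run(
    run: RunSchedule,
    m: SurfaceModel,
    params_per_block,
    seed: int | None = None,
    nuisance: NuisanceModel | None = None,
) -> RoiTimeSeries:
    """Simulate a whole run with known per-block stimulation parameters.

    Fully reproducible from ``seed`` (defaults to ``m.seed``); equivalent to
    streaming the blocks through :class:`BlockwiseRunSimulator` in any order.
    """
    params = tuple(params_per_block)
    if len(params) != len(run.blocks):
        raise ValueError(
            f"got {len(params)} parameter sets for {len(run.blocks)} blocks"
        )
    sim = BlockwiseRunSimulator(run, m, seed=seed, nuisance=nuisance)
    for i, p in enumerate(params):
        sim.generate_block(i, p)
    return sim.as_timeseries()
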