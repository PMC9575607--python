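"""Closed-loop protocol orchestration and evaluation.

Full protocol for one simulated participant: two 15-block training runs in
which the simplex optimizer proposes a stimulation setting for every block
and receives the block's Fisher-z connectivity back (30 evaluations total,
optimizer state carried across the run boundary), a ~7-minute washout rest
(a session-log marker only — the simulator carries no aftereffect state),
then a 15-block test run at the selected parameters.

Two arms: the *experimental* arm maximizes frontoparietal connectivity and
is tested at its best (max) setting; the *control* arm minimizes and is
tested at its best (min) setting — i.e. the min-optimization control
condition, which controls for the experience of being optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityOutcome, score_block
from .optimizer import EvalRecord, SimplexOptimizer, round_to_device
from .params import StimParams
from .schedule import (
    RunSchedule,
    block_window_samples,
    build_run_schedule,
    tile_trials,
)
from .simulate import BlockwiseRunSimulator, NuisanceModel, SurfaceModel, simulate_run

__all__ = [
    "LoopResult",
    "ArmComparison",
    "run_training",
    "run_test",
    "run_protocol",
    "compare_arms",
    "pooled_t_from_summary",
    "trajectory_report",
    "arm_separation",
    "WASHOUT_REST_S",
]

WASHOUT_REST_S = 410.0  # rest scan between training and test (6 min 50 s)

_ARM_MODE = {"experimental": "maximize", "control": "minimize"}


@dataclass
class LoopResult:
    """Everything one simulated participant produced."""

    arm: str
    selected_params: StimParams | None
    training_history: list[EvalRecord]
    training_outcomes: list[ConnectivityOutcome]
    test_outcomes: list[ConnectivityOutcome] = field(default_factory=list)
    test_mean_z: float | None = None
    test_sd_z: float | None = None
    seed: int | None = None
    session_log: list[str] = field(default_factory=list)

    @property
    def best_training_z(self) -> float | None:
        """Extreme training outcome under the arm's mode (max for the
        experimental arm, min for the control arm)."""
        if not self.training_history:
            return None
        return self.training_history[-1].best_outcome


def _child_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] % (2**31))


def run_training(
    surface: SurfaceModel,
    opt: SimplexOptimizer,
    schedules,
    arm: str,
    seed: int,
    nuisance: NuisanceModel | None = None,
) -> LoopResult:
    """Run the online optimization over the given training schedules.

    Per block: the optimizer proposes a continuous point, it is
    device-rounded, the simulator generates that block's samples, the
    connectivity engine scores the (hemodynamically shifted) window using
    only samples acquired so far, and the outcome feeds back into the
    optimizer.  Invalid windows count as optimizer failures and the loop
    continues.
    """
    if arm not in _ARM_MODE:
        raise ValueError(f"arm must be experimental/control, got {arm!r}")
    history_offset = 0
    outcomes: list[ConnectivityOutcome] = []
    log: list[str] = []
    for run_idx, run in enumerate(schedules):
        log.append(f"training_run_{run_idx + 1}")
        sim = BlockwiseRunSimulator(
            run, surface, seed=_child_seed(seed, 100 + run_idx), nuisance=nuisance
        )
        for b in range(len(run.blocks)):
            point, _move = opt.propose_next()
            params = round_to_device(point)
            _, stop = sim.generate_block(b, params)
            _w0, w1 = block_window_samples(run.blocks[b], run.tr, run=run)
            # streaming contract: the engine only ever sees samples < w1
            out = score_block(sim.partial_timeseries(w1), run, b)
            outcomes.append(out)
            opt.update(params, out.z if out.valid else None)
        if run_idx < len(schedules) - 1:
            log.append("run_boundary")
    return LoopResult(
        arm=arm,
        selected_params=opt.best_params,
        training_history=list(opt.history),
        training_outcomes=outcomes,
        seed=seed,
        session_log=log,
    )


def run_test(
    params: StimParams,
    surface: SurfaceModel,
    schedule: RunSchedule,
    seed: int,
    nuisance: NuisanceModel | None = None,
) -> tuple[list[ConnectivityOutcome], float, float]:
    """Test run: all blocks at the fixed selected parameters.

    Returns the per-block outcomes and the mean/SD of the valid z values.
    """
    ts = simulate_run(
        schedule,
        surface,
        [params] * len(schedule.blocks),
        seed=seed,
        nuisance=nuisance,
    )
    outcomes = [score_block(ts, schedule, b) for b in range(len(schedule.blocks))]
    zs = np.array([o.z for o in outcomes if o.valid])
    return outcomes, float(zs.mean()), float(zs.std(ddof=1))


def run_protocol(
    arm: str,
    surface: SurfaceModel,
    seed: int,
    nuisance: NuisanceModel | None = None,
    n_blocks_per_run: int = 15,
    opt_kwargs: dict | None = None,
) -> LoopResult:
    """Full protocol for one arm: training 1+2, washout marker, test run."""
    schedule = tile_trials(build_run_schedule(n_blocks=n_blocks_per_run))
    opt = SimplexOptimizer(mode=_ARM_MODE[arm], **(opt_kwargs or {}))
    result = run_training(surface, opt, [schedule, schedule], arm, seed, nuisance)
    result.session_log.append(f"washout_rest_{WASHOUT_REST_S:.0f}s")
    if result.selected_params is None:
        # every training block invalid: no parameters to test
        return result
    result.session_log.append("test_run")
    result.test_outcomes, result.test_mean_z, result.test_sd_z = run_test(
        result.selected_params,
        surface,
        schedule,
        seed=_child_seed(seed, 200),
        nuisance=nuisance,
    )
    return result


@dataclass(frozen=True)
class ArmComparison:
    mean_diff: float
    t: float
    df: int
    p: float


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> ArmComparison:
    """Pooled-variance two-sample t from summary statistics."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        raise ZeroDivisionError("zero pooled variance")
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ArmComparison(mean_diff=float(m1 - m2), t=float(t), df=df, p=float(p))


def compare_arms(exp_z, ctrl_z) -> ArmComparison:
    """Pooled two-sample t between the arms' test-run z values
    (df = n1 + n2 - 2, two-sided p)."""
    exp_z = np.asarray(exp_z, dtype=float)
    ctrl_z = np.asarray(ctrl_z, dtype=float)
    if exp_z.size < 2 or ctrl_z.size < 2:
        raise ValueError("each arm needs at least two values")
    return pooled_t_from_summary(
        exp_z.mean(), exp_z.std(ddof=1), exp_z.size,
        ctrl_z.mean(), ctrl_z.std(ddof=1), ctrl_z.size,
    )


def trajectory_report(result: LoopResult) -> pd.DataFrame:
    """Per-block training table: parameters, outcome, verdict, triangle."""
    h = result.training_history
    return pd.DataFrame(
        {
            "block": [r.evaluation_index for r in h],
            "triangle_index": [r.triangle_index for r in h],
            "move": [r.move for r in h],
            "frequency": [r.params.frequency for r in h],
            "phase": [r.params.phase_diff for r in h],
            "z": [r.outcome for r in h],
            "successful": [r.verdict == "success" for r in h],
            "best_z": [r.best_outcome for r in h],
        }
    )


def arm_separation(exp_best_z: float, ctrl_best_z: float) -> float:
    """Separation of the arms' extreme training responses,
    best z(experimental) - best z(control); antisymmetric under arm swap."""
    return float(exp_best_z) - float(ctrl_best_z)
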