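"""Nelder-Mead simplex search over integer stimulation parameters.

The optimizer searches (frequency in Hz, inter-site phase difference in
degrees) treating the two axes as equal-unit coordinates.  One candidate is
evaluated per stimulation block, so the classic Nelder-Mead iteration is
unrolled into an ask/tell state machine: seed the three vertices of an
equilateral triangle (center at the theta-band prior (6 Hz, 0 deg),
circumradius 5 units), then reflect / expand / contract / shrink with the
standard coefficients (alpha=1, gamma=2, rho=0.5, sigma=0.5).

Two protocol-specific rules sit on top of the simplex moves:

* device rounding — the stimulator accepts only integers, so every proposed
  continuous point is rounded half-away-from-zero before evaluation (the
  simplex itself keeps continuous vertices), the frequency is clipped to the
  device range [1, 150] Hz, and the phase is wrapped into [0, 359] only at
  the device boundary while the optimizer works on the unwrapped axis;
* failure counting — each evaluated block gets a verdict: success iff its
  outcome strictly improves, under the optimization mode, on the previous
  block's outcome (invalid blocks always fail; the stricter
  improves-on-best-so-far rule is available as ``success_rule="best"``).
  After two consecutive failures the current triangle is abandoned and a
  new one is seeded, centered on the best parameters found so far, with the
  circumradius halved if the abandoned triangle improved the best outcome
  (refine locally) and doubled if it never did (escalate the step size to
  probe a larger neighbourhood, capped at 40 units).  Both the restart
  construction and the success rule are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import FREQ_MAX_HZ, FREQ_MIN_HZ, StimParams

__all__ = [
    "NelderMeadCoefficients",
    "RestartPolicy",
    "EvalRecord",
    "SimplexOptimizer",
    "init_simplex",
    "round_to_device",
    "round_half_away_from_zero",
    "DEFAULT_CENTER",
    "DEFAULT_CIRCUMRADIUS",
    "DEFAULT_ANGLES_DEG",
    "ALTERNATE_SEED_VERTICES",
]

DEFAULT_CENTER = (6.0, 0.0)
DEFAULT_CIRCUMRADIUS = 5.0
DEFAULT_ANGLES_DEG = (90.0, 210.0, 330.0)

#: Alternative seed-vertex preset that circulates in written descriptions
#: of this protocol.  It is *not* consistent with the equilateral
#: construction ((1, -3) is not 5 units from (6, 0)), which instead yields
#: {(6, 5), (10, -3), (2, -3)}; both presets ship and neither is silently
#: preferred.
ALTERNATE_SEED_VERTICES = ((6.0, 5.0), (1.0, -3.0), (2.0, -3.0))


def round_half_away_from_zero(x: float) -> int:
    """Round halves away from zero: 2.5 -> 3, -2.5 -> -3."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def round_to_device(point) -> StimParams:
    """Map a continuous (frequency, phase) point onto stimulator integers.

    Round-half-away-from-zero on both axes; frequency clipped to the device
    range; the phase keeps its unwrapped value (:attr:`StimParams.device_phase`
    wraps it for the stimulator).
    """
    f, phi = float(point[0]), float(point[1])
    if not (np.isfinite(f) and np.isfinite(phi)):
        raise ValueError(f"non-finite parameter point {point}")
    freq = min(max(round_half_away_from_zero(f), FREQ_MIN_HZ), FREQ_MAX_HZ)
    return StimParams(frequency=freq, phase_diff=round_half_away_from_zero(phi))


def init_simplex(
    center=DEFAULT_CENTER,
    circumradius: float = DEFAULT_CIRCUMRADIUS,
    angles_deg=DEFAULT_ANGLES_DEG,
) -> np.ndarray:
    """Exact equilateral-triangle vertices: center + R (cos a, sin a).

    With the defaults this yields {(6, 5), (1.67, -2.5), (10.33, -2.5)},
    which device rounding maps to {(6, 5), (2, -3), (10, -3)}.
    """
    if circumradius <= 0:
        raise ValueError(f"circumradius must be > 0, got {circumradius}")
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if a.shape != (3,):
        raise ValueError("need exactly three vertex angles")
    return np.asarray(center, dtype=float) + circumradius * np.column_stack(
        [np.cos(a), np.sin(a)]
    )


@dataclass(frozen=True)
class NelderMeadCoefficients:
    alpha: float = 1.0  # reflection
    gamma: float = 2.0  # expansion
    rho: float = 0.5  # contraction
    sigma: float = 0.5  # shrink


@dataclass(frozen=True)
class RestartPolicy:
    """Triangle-restart rule applied after ``max_failures`` consecutive
    unsuccessful blocks.

    The new triangle is centered on the best parameters found so far.  Its
    circumradius adapts to what the abandoned triangle achieved: if that
    triangle improved the best outcome at least once, the radius shrinks
    (refine around the new best); if it produced no improvement at all, the
    radius grows (the current scale is uninformative — escalate the step
    size to probe a larger neighbourhood).
    """

    max_failures: int = 2
    shrink_factor: float = 0.5  # after a triangle that improved the best
    grow_factor: float = 2.0  # after a triangle that never improved it
    min_radius: float = 1.0
    max_radius: float = 40.0


@dataclass(frozen=True)
class EvalRecord:
    """One evaluated block in the trajectory log."""

    evaluation_index: int
    triangle_index: int
    move: str
    params: StimParams
    outcome: float | None
    verdict: str  # "success" | "failure"
    best_outcome: float | None


@dataclass
class _Proposal:
    point: np.ndarray
    move: str
    role: str  # "seed" | "reflect" | "expand" | "contract_out" | "contract_in" | "shrink"
    vertex_index: int | None = None  # for seed/shrink roles


class SimplexOptimizer:
    """Ask/tell Nelder-Mead over the integer stimulation-parameter plane.

    ``propose_next`` returns the continuous candidate and a move label;
    the caller device-rounds it, evaluates the block, and feeds the outcome
    back through ``update``.  Invalid outcomes (None or NaN) rank below
    every valid outcome and always count as failures.
    """

    def __init__(
        self,
        mode: str = "maximize",
        center=DEFAULT_CENTER,
        circumradius: float = DEFAULT_CIRCUMRADIUS,
        angles_deg=DEFAULT_ANGLES_DEG,
        vertices=None,
        coefficients: NelderMeadCoefficients = NelderMeadCoefficients(),
        restart: RestartPolicy = RestartPolicy(),
        success_rule: str = "previous",
        degeneracy_tol: float = 1e-9,
    ):
        if mode not in ("maximize", "minimize"):
            raise ValueError(f"mode must be maximize/minimize, got {mode!r}")
        if success_rule not in ("previous", "best"):
            raise ValueError(f"success_rule must be previous/best, got {success_rule!r}")
        self.success_rule = success_rule
        self.mode = mode
        self.coeff = coefficients
        self.restart_policy = restart
        self.degeneracy_tol = degeneracy_tol
        self._center = np.asarray(center, dtype=float)
        self._radius = float(circumradius)
        self._angles = tuple(float(a) for a in angles_deg)
        if vertices is None:
            vertices = init_simplex(center, circumradius, self._angles)
        self.vertices = np.asarray(vertices, dtype=float).copy()
        if self.vertices.shape != (3, 2):
            raise ValueError("simplex needs exactly three 2-D vertices")
        self.outcomes: list[float | None] = [None, None, None]
        self._evaluated = [False, False, False]
        self._eval_seq = [0, 0, 0]  # tie-break: earlier-evaluated ranks better
        self.fail_count = 0
        self.triangle_index = 0
        self.history: list[EvalRecord] = []
        self.best_params: StimParams | None = None
        self.best_outcome: float | None = None
        self._prev_outcome: float | None = None
        self._any_evaluated = False
        self._improved_in_triangle = False
        self._stage = "seed"
        self._pending: _Proposal | None = None
        self._shrink_queue: list[int] = []
        self._reflect_ctx: dict | None = None

    # -- ordering helpers ------------------------------------------------
    def _key(self, outcome: float | None) -> float:
        if outcome is None or not np.isfinite(outcome):
            return -np.inf
        return outcome if self.mode == "maximize" else -outcome

    def _improves_best(self, outcome: float | None) -> bool:
        if outcome is None or not np.isfinite(outcome):
            return False
        if self.best_outcome is None:
            return True
        return self._key(outcome) > self._key(self.best_outcome)

    def _order(self) -> list[int]:
        """Vertex indices best -> worst (ties: earlier evaluation wins)."""
        return sorted(
            range(3), key=lambda i: (-self._key(self.outcomes[i]), self._eval_seq[i])
        )

    def _degenerate(self) -> bool:
        a, b, c = self.vertices
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
        return area2 < self.degeneracy_tol

    # -- proposal --------------------------------------------------------
    def propose_next(self) -> tuple[np.ndarray, str]:
        """Next continuous candidate and its move label (deterministic)."""
        if self._pending is not None:
            return self._pending.point.copy(), self._pending.move

        if self._stage == "seed":
            i = self._evaluated.index(False)
            self._pending = _Proposal(self.vertices[i].copy(), "init", "seed", i)
            return self._pending.point.copy(), self._pending.move

        if self._stage == "shrink":
            i = self._shrink_queue[0]
            self._pending = _Proposal(self.vertices[i].copy(), "shrink", "shrink", i)
            return self._pending.point.copy(), self._pending.move

        # stage "reflect"
        if self._degenerate():
            self._restart()
            return self.propose_next()
        order = self._order()
        b, s, w = order
        centroid = (self.vertices[b] + self.vertices[s]) / 2.0
        x_r = centroid + self.coeff.alpha * (centroid - self.vertices[w])
        self._reflect_ctx = {"order": order, "centroid": centroid, "x_r": x_r}
        self._pending = _Proposal(x_r.copy(), "reflect", "reflect")
        return x_r.copy(), "reflect"

    # -- update ----------------------------------------------------------
    def update(self, params: StimParams, outcome: float | None) -> str:
        """Record the outcome of the last proposed point; returns the verdict.

        ``params`` must be the device rounding of the last proposal.
        Applies the Nelder-Mead bookkeeping for the move, then the
        success/failure rule and (if due) the triangle restart.
        """
        if self._pending is None:
            raise RuntimeError("update() called with no outstanding proposal")
        expected = round_to_device(self._pending.point)
        if params != expected:
            raise ValueError(f"outcome for {params}, expected proposal {expected}")
        proposal = self._pending
        self._pending = None

        if self.success_rule == "best":
            success = self._improves_best(outcome)
        else:  # vs the immediately preceding block
            k = self._key(outcome)
            success = np.isfinite(k) and (
                not self._any_evaluated or k > self._key(self._prev_outcome)
            )
        verdict = "success" if success else "failure"
        if self._improves_best(outcome):
            self.best_params = params
            self.best_outcome = outcome
            self._improved_in_triangle = True
        self.fail_count = 0 if success else self.fail_count + 1
        self._prev_outcome = outcome
        self._any_evaluated = True

        self._apply_move(proposal, outcome)
        self.history.append(
            EvalRecord(
                evaluation_index=len(self.history),
                triangle_index=self.triangle_index,
                move=proposal.move,
                params=params,
                outcome=outcome,
                verdict=verdict,
                best_outcome=self.best_outcome,
            )
        )
        if self.fail_count >= self.restart_policy.max_failures:
            self._restart()
        return verdict

    def _set_vertex(self, i: int, point: np.ndarray, outcome: float | None) -> None:
        self.vertices[i] = point
        self.outcomes[i] = outcome
        self._evaluated[i] = True
        self._eval_seq[i] = len(self.history) + 1

    def _apply_move(self, proposal: _Proposal, outcome: float | None) -> None:
        c = self.coeff
        if proposal.role == "seed":
            self._set_vertex(proposal.vertex_index, proposal.point, outcome)
            if all(self._evaluated):
                self._stage = "reflect"
            return
        if proposal.role == "shrink":
            self._set_vertex(proposal.vertex_index, proposal.point, outcome)
            self._shrink_queue.pop(0)
            if not self._shrink_queue:
                self._stage = "reflect"
            return

        ctx = self._reflect_ctx
        order = ctx["order"]
        b, s, w = order
        centroid = ctx["centroid"]

        if proposal.role == "reflect":
            k_r = self._key(outcome)
            if k_r > self._key(self.outcomes[b]):
                # try to expand past the reflection
                x_e = centroid + c.gamma * (proposal.point - centroid)
                ctx["f_r"] = outcome
                self._pending = _Proposal(x_e, "expand", "expand")
            elif k_r > self._key(self.outcomes[s]):
                self._set_vertex(w, proposal.point, outcome)
            else:
                ctx["f_r"] = outcome
                if k_r > self._key(self.outcomes[w]):
                    x_c = centroid + c.rho * (proposal.point - centroid)
                    self._pending = _Proposal(x_c, "contract_out", "contract_out")
                else:
                    x_c = centroid + c.rho * (self.vertices[w] - centroid)
                    self._pending = _Proposal(x_c, "contract_in", "contract_in")
            return

        if proposal.role == "expand":
            if self._key(outcome) > self._key(ctx["f_r"]):
                self._set_vertex(w, proposal.point, outcome)
            else:
                self._set_vertex(w, ctx["x_r"], ctx["f_r"])
            return

        if proposal.role == "contract_out":
            if self._key(outcome) >= self._key(ctx["f_r"]):
                self._set_vertex(w, proposal.point, outcome)
            else:
                self._start_shrink(b)
            return

        if proposal.role == "contract_in":
            if self._key(outcome) > self._key(self.outcomes[w]):
                self._set_vertex(w, proposal.point, outcome)
            else:
                self._start_shrink(b)
            return

        raise AssertionError(f"unknown proposal role {proposal.role}")

    def _start_shrink(self, best_index: int) -> None:
        sigma = self.coeff.sigma
        for i in range(3):
            if i != best_index:
                self.vertices[i] = self.vertices[best_index] + sigma * (
                    self.vertices[i] - self.vertices[best_index]
                )
                self.outcomes[i] = None
                self._evaluated[i] = False
        self._shrink_queue = [i for i in range(3) if i != best_index]
        self._stage = "shrink"

    def _restart(self) -> None:
        """Abandon the triangle: new one at the best-so-far parameters, with
        the circumradius adapted per :class:`RestartPolicy`."""
        factor = (
            self.restart_policy.shrink_factor
            if self._improved_in_triangle
            else self.restart_policy.grow_factor
        )
        self._radius = min(
            max(self._radius * factor, self.restart_policy.min_radius),
            self.restart_policy.max_radius,
        )
        self._improved_in_triangle = False
        if self.best_params is not None:
            self._center = np.array(
                [self.best_params.frequency, self.best_params.phase_diff], dtype=float
            )
        self.vertices = init_simplex(self._center, self._radius, self._angles)
        self.outcomes = [None, None, None]
        self._evaluated = [False, False, False]
        self._eval_seq = [0, 0, 0]
        self.fail_count = 0
        self.triangle_index += 1
        self._stage = "seed"
        self._pending = None
        self._shrink_queue = []
        self._reflect_ctx = None

    # -- reporting -------------------------------------------------------
    def history_table(self) -> pd.DataFrame:
        """Trajectory log; write with ``df.to_csv(path, sep="\\t",
        index=False)``."""
        return pd.DataFrame(
            {
                "evaluation_index": [h.evaluation_index for h in self.history],
                "triangle_index": [h.triangle_index for h in self.history],
                "move": [h.move for h in self.history],
                "frequency": [h.params.frequency for h in self.history],
                "device_phase": [h.params.device_phase for h in self.history],
                "unwrapped_phase": [h.params.phase_diff for h in self.history],
                "outcome_z": [h.outcome for h in self.history],
                "verdict": [h.verdict for h in self.history],
                "best_z": [h.best_outcome for h in self.history],
            }
        )
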