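"""Dual-site 4x1 high-definition tACS montage.

Two stimulation sites (frontal F4, parietal P4), each a ring montage of one
center electrode surrounded by four return electrodes at a nominal 3 cm
center-return distance.  The center electrode carries the full site current
(1 mA peak by default) and the four returns split the opposite-sign current
equally (0.25 mA each), so each site is self-contained (zero net current,
Kirchhoff's law at the scalp).

Phase condition is encoded as a sign convention on the parietal site: in the
in-phase condition both sites drive identical waveforms; in the antiphase
condition the parietal currents are flipped, which is what creates the
possibility of a shunt field between the sites (see :mod:`tacsloop.efield`).

Coordinates are millimetre positions on a head model (MNI-aligned); they are
treated as opaque mm coordinates.  The 13 cm inter-site distance used in the
shunt formulas is a configured scalp-surface value, not the 3-D chord between
the printed coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Electrode",
    "Montage",
    "MontageConfig",
    "ValidationReport",
    "DEFAULT_ELECTRODE_POSITIONS",
    "ROI_CENTERS_MM",
    "build_dual_site_montage",
    "validate_montage",
    "load_montage_config",
    "montage_to_table",
]

#: Electrode positions (mm, MNI-aligned head model).  Keys are electrode
#: labels; each site has one center ("F4", "P4") and four returns.
DEFAULT_ELECTRODE_POSITIONS: dict[str, tuple[float, float, float]] = {
    "F4": (49.65, 53.71, 72.15),
    "R_F1": (51.35, 28.51, 86.09),
    "R_F2": (25.05, 58.87, 87.63),
    "R_F3": (42.95, 74.26, 51.96),
    "R_F4": (64.83, 41.57, 52.64),
    "P4": (48.73, -84.52, 66.10),
    "R_P1": (49.02, -95.93, 38.49),
    "R_P2": (25.63, -89.69, 84.28),
    "R_P3": (52.57, -62.68, 85.96),
    "R_P4": (65.54, -67.52, 51.97),
}

#: ROI sphere centers (mm, MNI) used for the frontal/parietal connectivity
#: masks.  Note these are left-hemisphere coordinates while the stimulation
#: sites are right-hemisphere F4/P4; both coordinate sets are shipped as
#: configured and the discrepancy is deliberately not resolved here.
ROI_CENTERS_MM: dict[str, tuple[float, float, float]] = {
    "frontal": (-45.0, 49.0, 27.0),
    "parietal": (-45.0, -75.0, 46.0),
}

_SITES = ("frontal", "parietal")
_SITE_OF_LABEL_PREFIX = {"F": "frontal", "P": "parietal"}


@dataclass(frozen=True)
class Electrode:
    """One scalp electrode of the montage.

    current is the signed peak amplitude in mA; sign encodes waveform
    polarity relative to the site's reference sinusoid.
    """

    label: str
    position: tuple[float, float, float]  # mm
    current: float  # mA, signed peak
    role: str  # "center" | "return"
    site: str  # "frontal" | "parietal"

    def __post_init__(self) -> None:
        if self.role not in ("center", "return"):
            raise ValueError(f"bad role {self.role!r}")
        if self.site not in _SITES:
            raise ValueError(f"bad site {self.site!r}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for {self.label!r}")


@dataclass(frozen=True)
class Montage:
    """Ten-electrode dual-site montage with a phase-condition sign convention."""

    electrodes: tuple[Electrode, ...]
    center_return_distance: float = 30.0  # mm, nominal
    phase_condition: str = "in_phase"  # "in_phase" | "anti_phase"

    def __post_init__(self) -> None:
        if self.phase_condition not in ("in_phase", "anti_phase"):
            raise ValueError(f"bad phase_condition {self.phase_condition!r}")
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate electrode labels")

    def site_electrodes(self, site: str) -> tuple[Electrode, ...]:
        return tuple(e for e in self.electrodes if e.site == site)

    def center(self, site: str) -> Electrode:
        (c,) = [e for e in self.site_electrodes(site) if e.role == "center"]
        return c

    def returns(self, site: str) -> tuple[Electrode, ...]:
        return tuple(e for e in self.site_electrodes(site) if e.role == "return")

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.electrodes], dtype=float)

    @property
    def currents(self) -> np.ndarray:
        return np.array([e.current for e in self.electrodes], dtype=float)

    def with_phase_condition(self, condition: str) -> "Montage":
        """Return the montage under the given phase condition.

        Switching condition flips exactly the five parietal-site current
        signs; applying the switch twice is the identity.
        """
        if condition == self.phase_condition:
            return self
        flipped = tuple(
            replace(e, current=-e.current) if e.site == "parietal" else e
            for e in self.electrodes
        )
        return replace(self, electrodes=flipped, phase_condition=condition)


@dataclass
class MontageConfig:
    """Configuration for :func:`build_dual_site_montage`."""

    positions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ELECTRODE_POSITIONS)
    )
    center_current_ma: float = 1.0
    center_return_distance_mm: float = 30.0
    phase_condition: str = "in_phase"
    distance_tolerance_rel: float = 0.20  # curved-scalp placement slack


def _site_of(label: str) -> str:
    key = label.replace("R_", "")[0]
    try:
        return _SITE_OF_LABEL_PREFIX[key]
    except KeyError:
        raise ValueError(f"cannot infer site from label {label!r}") from None


def build_dual_site_montage(config: MontageConfig | None = None) -> Montage:
    """Assemble the 10-electrode dual-site montage from a configuration.

    Return currents are ``-center_current / n_returns`` per site so each site
    carries zero net current; in the antiphase condition the parietal site's
    currents are sign-flipped.

    Raises
    ------
    ValueError
        on missing or duplicated labels, or if the assigned currents fail the
        per-site zero-net-current check (a configuration bug).
    """
    config = config or MontageConfig()
    labels = list(config.positions)
    if len(labels) != 10 or len(set(labels)) != 10:
        raise ValueError(f"montage needs 10 uniquely labelled electrodes, got {labels}")

    electrodes: list[Electrode] = []
    for site in _SITES:
        site_labels = [lab for lab in labels if _site_of(lab) == site]
        centers = [lab for lab in site_labels if not lab.startswith("R_")]
        returns = [lab for lab in site_labels if lab.startswith("R_")]
        if len(centers) != 1 or len(returns) != 4:
            raise ValueError(
                f"site {site!r} needs 1 center + 4 returns, got {site_labels}"
            )
        sign = -1.0 if (site == "parietal" and config.phase_condition == "anti_phase") else 1.0
        i_center = sign * config.center_current_ma
        i_return = -i_center / len(returns)
        electrodes.append(
            Electrode(centers[0], tuple(config.positions[centers[0]]), i_center, "center", site)
        )
        electrodes.extend(
            Electrode(lab, tuple(config.positions[lab]), i_return, "return", site)
            for lab in returns
        )
        net = i_center + len(returns) * i_return
        if abs(net) > 1e-12:
            raise ValueError(f"site {site!r} net current {net} mA != 0")

    return Montage(
        electrodes=tuple(electrodes),
        center_return_distance=config.center_return_distance_mm,
        phase_condition=config.phase_condition,
    )


@dataclass
class ValidationReport:
    """Geometry/current audit of a montage (report-only, never raises)."""

    net_current: dict[str, float]  # mA per site
    center_return_distances: dict[str, tuple[float, float]]  # mm (min, max) per site
    min_intersite_return_distance: float  # mm
    center_center_distance: float  # mm
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_montage(
    m: Montage,
    distance_tolerance_rel: float = 0.20,
    current_tolerance_ma: float = 1e-9,
) -> ValidationReport:
    """Audit per-site current balance and the two montage design rules:
    returns close to their own center, and the two sites' return groups
    well separated from each other.
    """
    violations: list[str] = []
    net = {}
    cr_dist = {}
    for site in _SITES:
        center = m.center(site)
        rets = m.returns(site)
        net[site] = center.current + sum(r.current for r in rets)
        if abs(net[site]) > current_tolerance_ma:
            violations.append(f"{site}: net current {net[site]:+.4g} mA != 0")
        d = [
            float(np.linalg.norm(np.subtract(r.position, center.position)))
            for r in rets
        ]
        cr_dist[site] = (min(d), max(d))
        lo = m.center_return_distance * (1 - distance_tolerance_rel)
        hi = m.center_return_distance * (1 + distance_tolerance_rel)
        for r, dist in zip(rets, d):
            if not (lo <= dist <= hi):
                violations.append(
                    f"{site}: return {r.label} at {dist:.1f} mm from center, "
                    f"outside [{lo:.1f}, {hi:.1f}] mm"
                )

    inter = min(
        float(np.linalg.norm(np.subtract(a.position, b.position)))
        for a, b in itertools.product(m.returns("frontal"), m.returns("parietal"))
    )
    # shunt design rule: inter-site return gap should exceed the center-return
    # distance, else a return sits effectively on the other site
    if inter < m.center_return_distance:
        violations.append(
            f"inter-site return-return distance {inter:.1f} mm < "
            f"center-return distance {m.center_return_distance:.1f} mm"
        )
    cc = float(
        np.linalg.norm(
            np.subtract(m.center("frontal").position, m.center("parietal").position)
        )
    )
    return ValidationReport(
        net_current=net,
        center_return_distances=cr_dist,
        min_intersite_return_distance=inter,
        center_center_distance=cc,
        violations=violations,
    )


def load_montage_config(path) -> MontageConfig:
    """Read a montage configuration from a YAML key-value file.

    Recognized keys: ``electrodes`` (mapping label -> [x, y, z] mm),
    ``center_current_ma``, ``center_return_distance_mm``, ``phase_condition``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = MontageConfig()
    if "electrodes" in raw:
        cfg.positions = {
            str(lab): tuple(float(v) for v in xyz) for lab, xyz in raw["electrodes"].items()
        }
    for key in ("center_current_ma", "center_return_distance_mm"):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
    if "phase_condition" in raw:
        cfg.phase_condition = str(raw["phase_condition"])
    return cfg


def montage_to_table(m: Montage) -> pd.DataFrame:
    """Electrode table (label, x, y, z, current, role, site); write with
    ``df.to_csv(path, sep="\\t", index=False)`` for the TSV export."""
    return pd.DataFrame(
        {
            "label": [e.label for e in m.electrodes],
            "x": [e.position[0] for e in m.electrodes],
            "y": [e.position[1] for e in m.electrodes],
            "z": [e.position[2] for e in m.electrodes],
            "current": [e.current for e in m.electrodes],
            "role": [e.role for e in m.electrodes],
            "site": [e.site for e in m.electrodes],
        }
    )
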