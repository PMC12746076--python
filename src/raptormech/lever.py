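"""Third-class lever model of avian ankle dorsiflexion.

The m. tibialis cranialis inserts on a tubercle a short distance distal to
the ankle joint (the fulcrum), while a grasped prey item resists at the
distal end of the tarsometatarsus. Dorsiflexing the foot to lift prey is
therefore a third-class lever: the force arm FA (fulcrum to tubercle) is
shorter than the resistance arm RA (fulcrum to prey), so the muscle must
produce a force larger than the prey's weight.

Quantities, for prey of mass m under gravity g:

* resistance of prey      RP = m * g                     [N]
* required muscle force   F  = RP * RA / FA              [N]
* mechanical advantage    MA = FA / RA                   [dimensionless]
* torque                  tau = F * RA                   [N m]  (default)

The default torque convention multiplies the required muscle force by the
outlever, which is how the published comparison tables are computed. The
standard single-joint moment balance (tau = RP * RA = F * FA) is available
as ``convention="joint"`` for cross-checks; the two differ by a factor of
1/MA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

STANDARD_GRAVITY = 9.81  # m s^-2

TORQUE_CONVENTIONS = ("outlever", "joint")


@dataclass(frozen=True)
class LeverGeometry:
    """Lever arms of one species' ankle, in metres.

    ``FA`` is the inlever (fulcrum to m. tibialis cranialis insertion),
    ``RA`` the outlever (fulcrum to the point of resistance, taken as the
    distal end of the tarsometatarsus).
    """

    species: str
    FA: float
    RA: float

    def __post_init__(self) -> None:
        if self.FA <= 0 or self.RA <= 0:
            raise ValueError(
                f"{self.species}: lever arms must be positive "
                f"(FA={self.FA}, RA={self.RA})"
            )
        if self.FA >= self.RA:
            # Third-class levers have FA < RA; unusual but not impossible.
            warnings.warn(
                f"{self.species}: FA >= RA (mechanical advantage >= 1); "
                "not a third-class lever",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PreyScenario:
    """A hypothetical prey item: name, mass in kg, gravity in m s^-2."""

    prey: str
    mass: float
    g: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"prey mass must be positive, got {self.mass}")
        if self.g <= 0:
            raise ValueError(f"g must be positive, got {self.g}")


@dataclass(frozen=True)
class LeverSolution:
    """Solved lever model for one species/prey pair."""

    species: str
    prey: str
    RP: float
    RA: float
    FA: float
    MA: float
    muscle_force: float
    torque: float
    torque_joint: float = field(repr=False, default=float("nan"))


def resistance_force(scenario: PreyScenario) -> float:
    """Weight force of the prey item, RP = mass * g, in newtons."""
    return scenario.mass * scenario.g


def mechanical_advantage(geometry: LeverGeometry) -> float:
    """MA = FA / RA: the inlever/outlever ratio, dimensionless."""
    return geometry.FA / geometry.RA


def muscle_force(RP: float, geometry: LeverGeometry) -> float:
    """Muscle force required to balance prey weight: F = RP * RA / FA."""
    if RP < 0:
        raise ValueError(f"resistance force must be >= 0, got {RP}")
    return RP * geometry.RA / geometry.FA


def required_torque(
    F: float, geometry: LeverGeometry, convention: str = "outlever"
) -> float:
    """Torque to lift the prey, in N m.

    ``convention="outlever"`` returns F * RA (muscle force times outlever),
    matching the published comparison tables. ``convention="joint"``
    returns F * FA, the joint moment of the standard static balance
    (identically RP * RA).
    """
    if F < 0:
        raise ValueError(f"muscle force must be >= 0, got {F}")
    if convention == "outlever":
        return F * geometry.RA
    if convention == "joint":
        return F * geometry.FA
    raise ValueError(
        f"unknown torque convention {convention!r}; "
        f"expected one of {TORQUE_CONVENTIONS}"
    )


def solve(
    geometry: LeverGeometry,
    scenario: PreyScenario,
    convention: str = "outlever",
) -> LeverSolution:
    """Solve the full lever model for one species/prey pair."""
    RP = resistance_force(scenario)
    MA = mechanical_advantage(geometry)
    F = muscle_force(RP, geometry)
    return LeverSolution(
        species=geometry.species,
        prey=scenario.prey,
        RP=RP,
        RA=geometry.RA,
        FA=geometry.FA,
        MA=MA,
        muscle_force=F,
        torque=required_torque(F, geometry, convention),
        torque_joint=required_torque(F, geometry, "joint"),
    )


def lever_table(
    geometries: list[LeverGeometry],
    scenarios: list[PreyScenario],
    convention: str = "outlever",
    paired: bool = False,
) -> pd.DataFrame:
    """Cross (or paired) table of lever solutions.

    With ``paired=True``, ``geometries`` and ``scenarios`` are zipped
    row-for-row (each species gets its own prey item); otherwise the full
    cross product is computed, scenarios outermost. All values are kept at
    full precision; use :func:`format_table` for display rounding.
    """
    if not geometries or not scenarios:
        raise ValueError("geometries and scenarios must be non-empty")
    if convention not in TORQUE_CONVENTIONS:
        raise ValueError(f"unknown torque convention {convention!r}")
    if paired:
        if len(geometries) != len(scenarios):
            raise ValueError("paired=True requires equal-length lists")
        pairs = list(zip(geometries, scenarios))
    else:
        pairs = [(g, s) for s in scenarios for g in geometries]
    rows = [solve(g, s, convention) for g, s in pairs]
    return pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "prey": [r.prey for r in rows],
            "RP_N": [r.RP for r in rows],
            "RA_m": [r.RA for r in rows],
            "FA_m": [r.FA for r in rows],
            "MA": [r.MA for r in rows],
            "muscle_force_N": [r.muscle_force for r in rows],
            "torque_Nm": [r.torque for r in rows],
        }
    )


def format_table(table: pd.DataFrame) -> pd.DataFrame:
    """Round a lever table to the display precision of the published one."""
    out = table.copy()
    out["RP_N"] = out["RP_N"].round(2)
    out["MA"] = out["MA"].round(2)
    out["muscle_force_N"] = out["muscle_force_N"].round(2)
    out["torque_Nm"] = out["torque_Nm"].round(2)
    return out


def arms_from_morphometrics_mm(
    species: str, tmt_length_mm: float, tubercle_distance_mm: float
) -> LeverGeometry:
    """Build lever arms from skeletal measurements in millimetres.

    The outlever RA is the full tarsometatarsus length and the inlever FA
    the proximal-margin-to-tubercle distance, both converted to metres.
    """
    return LeverGeometry(
        species=species,
        RA=tmt_length_mm / 1000.0,
        FA=tubercle_distance_mm / 1000.0,
    )


def focal_geometries() -> list[LeverGeometry]:
    """Lever geometries of the six focal species, from the bundled arms."""
    from raptormech.datasets import FOCAL_LEVER_ARMS

    return [
        LeverGeometry(species=sp, RA=ra, FA=fa)
        for sp, (ra, fa) in FOCAL_LEVER_ARMS.items()
    ]


def focal_scenarios() -> list[PreyScenario]:
    """The bundled chipmunk and opossum prey scenarios."""
    from raptormech.datasets import PREY_SCENARIOS

    return [PreyScenario(prey=p, mass=m) for p, m in PREY_SCENARIOS.items()]
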