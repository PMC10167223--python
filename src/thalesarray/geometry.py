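"""Exact 2-D geometry of the Thales construction.

The Geometric Framework for nutrition represents a diet as a *nutritional
rail* — a ray from the origin of nutrient space whose direction is the diet's
fixed nutrient ratio — and an animal's regulated optimum as the *intake
target*, the coordinate it defends when allowed free dietary choice.

Under the closest-distance-optimisation (CDO) rule of compromise, intake on
an imbalanced rail falls on the perpendicular foot of the target on that
rail.  By Thales' theorem those feet lie on the circle whose diameter is the
origin–target segment, so the inscribed angle ``beta`` at the observed intake
point B — between the directions B→origin and B→target — equals 90° exactly
when the animal follows CDO.  ``beta > 90°`` places the point inside the
circle (under-consumption relative to the CDO foot); ``beta < 90°`` places it
outside (a tolerated surplus).

All public angles are in degrees.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateVertexError",
    "InvalidTargetError",
    "RailParseError",
    "IntakePoint",
    "IntakeTarget",
    "Rail",
    "ThalesCircle",
    "AngleRecord",
    "thales_angle",
    "beta_deviation",
    "cdo_projection",
    "circle_position",
    "parse_rail",
]


class DegenerateVertexError(ValueError):
    """The intake point coincides with the origin or the intake target."""


class InvalidTargetError(ValueError):
    """The intake target is degenerate (zero norm or outside the positive quadrant)."""


class RailParseError(ValueError):
    """A rail label does not match the ``a:b`` ratio grammar."""


def _as_xy(obj, name: str) -> np.ndarray:
    xy = np.asarray(getattr(obj, "xy", obj), dtype=float)
    if xy.shape[-1] != 2:
        raise ValueError(f"{name} must be a 2-D coordinate, got shape {xy.shape}")
    if not np.all(np.isfinite(xy)):
        raise ValueError(f"{name} has non-finite coordinates: {xy}")
    return xy


@dataclass(frozen=True)
class IntakePoint:
    """Cumulative intake of two nutrients by one individual (triangle vertex B)."""

    nutrient_a: float
    nutrient_b: float

    def __post_init__(self) -> None:
        xy = np.array([self.nutrient_a, self.nutrient_b], dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError(f"intake coordinates must be finite, got {xy}")
        if np.any(xy < 0):
            raise ValueError(f"intake coordinates must be non-negative, got {xy}")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.nutrient_a, self.nutrient_b], dtype=float)


@dataclass(frozen=True)
class IntakeTarget:
    """Average defended intake coordinate (triangle vertex C); strictly positive."""

    nutrient_a: float
    nutrient_b: float

    def __post_init__(self) -> None:
        xy = np.array([self.nutrient_a, self.nutrient_b], dtype=float)
        if not np.all(np.isfinite(xy)):
            raise InvalidTargetError(f"target coordinates must be finite, got {xy}")
        if np.any(xy <= 0):
            raise InvalidTargetError(
                f"target must lie strictly inside the positive quadrant, got {xy}"
            )

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.nutrient_a, self.nutrient_b], dtype=float)

    @property
    def norm(self) -> float:
        return float(np.hypot(self.nutrient_a, self.nutrient_b))


_RAIL_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*:\s*(\d+(?:\.\d+)?)\s*$")


@dataclass(frozen=True)
class Rail:
    """A nutritional rail: the ray from the origin with fixed nutrient ratio a:b."""

    ratio_a: float
    ratio_b: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.ratio_a < 0 or self.ratio_b < 0:
            raise ValueError(f"rail ratio components must be non-negative: {self}")
        if self.ratio_a + self.ratio_b <= 0:
            raise ValueError("rail ratio must not be 0:0")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the rail."""
        v = np.array([self.ratio_a, self.ratio_b], dtype=float)
        return v / np.linalg.norm(v)


def parse_rail(label: str) -> Rail:
    """Parse a ratio label like ``"1:4"`` into a :class:`Rail`.

    Ratios are scale invariant: ``"7:35"`` and ``"1:5"`` give the same
    direction.  ``"0:0"`` and malformed labels raise :class:`RailParseError`.
    """
    m = _RAIL_RE.match(str(label))
    if m is None:
        raise RailParseError(f"rail label {label!r} does not match 'a:b'")
    a, b = float(m.group(1)), float(m.group(2))
    if a + b <= 0:
        raise RailParseError(f"rail label {label!r} is the degenerate ratio 0:0")
    return Rail(a, b, label=str(label).strip())


@dataclass(frozen=True)
class ThalesCircle:
    """Circle with the origin–target segment as diameter.

    Every point at which the inscribed angle beta equals 90° lies on this
    circle; the CDO feet of all rails do.
    """

    target: IntakeTarget
    center: np.ndarray = field(init=False, repr=False)
    radius: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", self.target.xy / 2.0)
        object.__setattr__(self, "radius", self.target.norm / 2.0)

    def signed_distance(self, point) -> float:
        """Distance of *point* from the circumference (negative = inside)."""
        p = _as_xy(point, "point")
        return float(np.linalg.norm(p - self.center) - self.radius)


@dataclass(frozen=True)
class AngleRecord:
    """Per-observation Thales angle with its rail/species labels."""

    beta_deg: float
    deviation_deg: float
    position: str
    rail_label: str
    species: str = ""
    group: str | None = None


def _beta_from_vectors(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosb = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosb, -1.0, 1.0)))


def thales_angle(point, target, *, _tol: float = 1e-12) -> float:
    """Angle beta (degrees) at the intake point between origin and target.

    Vectorised over the leading axes of *point*: an ``(n, 2)`` array of
    points returns an ``(n,)`` array of angles.

    Returns values in ``[0, 180]``: a point collinear strictly between origin
    and target returns 180 (limiting inscribed angle); a collinear point
    beyond the target returns 0.

    Raises
    ------
    DegenerateVertexError
        If any point coincides (within machine tolerance, relative to the
        construction scale) with the origin or the target.
    InvalidTargetError
        If the target has zero norm.
    """
    t = _as_xy(target, "target")
    tnorm = np.linalg.norm(t)
    if tnorm <= 0:
        raise InvalidTargetError("intake target must have positive norm")
    p = _as_xy(point, "point")
    scale = max(tnorm, float(np.max(np.linalg.norm(np.atleast_2d(p), axis=-1))))
    u = -p  # B -> A (origin)
    v = t - p  # B -> C (target)
    if np.any(np.linalg.norm(np.atleast_2d(u), axis=-1) <= _tol * scale):
        raise DegenerateVertexError("intake point coincides with the origin")
    if np.any(np.linalg.norm(np.atleast_2d(v), axis=-1) <= _tol * scale):
        raise DegenerateVertexError("intake point coincides with the intake target")
    beta = _beta_from_vectors(u, v)
    return float(beta) if beta.ndim == 0 else beta


def beta_deviation(point, target) -> float:
    """Deviation ``beta - 90`` in degrees.

    Positive: the point lies inside the Thales circle (under-consumption
    relative to the CDO foot).  Negative: outside (tolerated surplus).
    Vectorised like :func:`thales_angle`.
    """
    return thales_angle(point, target) - 90.0


def cdo_projection(rail: Rail | str, target) -> IntakePoint:
    """Perpendicular foot of the intake target on a rail: the CDO prediction.

    The foot minimises Euclidean distance from the target among points of the
    rail ray and satisfies ``thales_angle(foot, target) == 90`` whenever it is
    distinct from both origin and target.
    """
    if isinstance(rail, str):
        rail = parse_rail(rail)
    t = _as_xy(target, "target")
    d = rail.direction
    foot = d * float(t @ d)
    return IntakePoint(foot[0], foot[1])


def circle_position(point, target, tol_deg: float = 1e-8) -> str:
    """Classify a point as ``"inside"``, ``"on"`` or ``"outside"`` the Thales circle.

    The angle criterion is used: deviation beyond ``+tol_deg`` is inside,
    below ``-tol_deg`` outside.  It is equivalent to comparing the distance
    from the circle centre against the radius.
    """
    dev = beta_deviation(point, target)
    if dev > tol_deg:
        return "inside"
    if dev < -tol_deg:
        return "outside"
    return "on"


def make_angle_record(
    point,
    target,
    rail_label: str,
    *,
    species: str = "",
    group: str | None = None,
    tol_deg: float = 1e-8,
) -> AngleRecord:
    """Bundle beta, its deviation and circle position for one observation."""
    beta = thales_angle(point, target)
    return AngleRecord(
        beta_deg=beta,
        deviation_deg=beta - 90.0,
        position=circle_position(point, target, tol_deg=tol_deg),
        rail_label=rail_label,
        species=species,
        group=group,
    )
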