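"""Synthetic nutrient-array generators and the noise-stability simulation.

Two jobs live here.  First, generators for archetypal nutrient arrays — the
closest-distance-optimisation (CDO) semicircle and the classic alternative
rules of compromise (equal total intake, square, inverted square, linear,
concave) — used as fixtures with known geometry for testing and for power
studies.  Second, a Monte-Carlo study of how the Thales angle estimate
behaves as measurement error of different distributional families (Gaussian,
Poisson, gamma) is added to an array whose true angle is 90° everywhere.

Generated intake coordinates may go negative under large noise; the
generators deliberately do not censor them (rejecting negative intakes is an
I/O concern, and censoring would bias the angle distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import IntakeTarget, Rail, cdo_projection, parse_rail, _beta_from_vectors
from .io import IntakeDataset

__all__ = [
    "NoiseModel",
    "SimulationResult",
    "NoIntersectionError",
    "DEFAULT_RAILS",
    "DEFAULT_TARGET",
    "generate_cdo_array",
    "generate_archetype_array",
    "noise_stability_simulation",
    "fraction_family_narrowest",
]

#: Five-rail design used across classic locust/moth feeding studies.
DEFAULT_RAILS = ("1:5", "1:2", "1:1", "2:1", "5:1")

#: Default intake target (protein, carbohydrate), mg; P:C about 1:1.4 so the
#: target is not collinear with any default rail.
DEFAULT_TARGET = (25.0, 35.0)

ARCHETYPES = ("equal_distance", "target_distance", "square", "inverted_square", "linear", "concave")


class NoIntersectionError(ValueError):
    """The requested construction does not intersect one of the rails."""


@dataclass(frozen=True)
class NoiseModel:
    """Additive per-coordinate measurement error.

    ``scale`` is the family's natural dispersion parameter: the standard
    deviation for ``gaussian``, lambda for ``poisson``, the shape (with unit
    rate) for ``gamma``.  Centered noise (default) has the distribution's
    theoretical mean subtracted, so growing the scale grows dispersion
    without translating the array; ``centered=False`` keeps the raw draws.
    """

    family: str = "gaussian"
    scale: float = 1.0
    centered: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "poisson", "gamma"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"noise scale must be positive, got {self.scale}")

    @property
    def sd(self) -> float:
        """Theoretical standard deviation of one draw."""
        return self.scale if self.family == "gaussian" else float(np.sqrt(self.scale))

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.family == "gaussian":
            return rng.normal(0.0, self.scale, shape)
        if self.family == "poisson":
            x = rng.poisson(self.scale, shape).astype(float)
        else:
            x = rng.gamma(self.scale, 1.0, shape)
        return x - self.scale if self.centered else x


def _resolve(target, rails) -> tuple[np.ndarray, list[Rail]]:
    t = target.xy if isinstance(target, IntakeTarget) else np.asarray(target, float)
    IntakeTarget(t[0], t[1])  # validate
    parsed = [r if isinstance(r, Rail) else parse_rail(r) for r in rails]
    if not parsed:
        raise ValueError("at least one rail is required")
    return t, parsed


def _assemble(
    base_points: list[tuple[str, np.ndarray]],
    n_per_rail: int,
    noise: NoiseModel | None,
    rng: np.random.Generator,
    target: np.ndarray,
    species: str,
    n_choice: int,
) -> IntakeDataset:
    rows = []
    for label, point in base_points:
        pts = np.tile(point, (n_per_rail, 1))
        if noise is not None:
            pts = pts + noise.draw(rng, pts.shape)
        for p in pts:
            rows.append((species, "rail", label, p[0], p[1], None))
    if n_choice:
        pts = np.tile(target, (n_choice, 1))
        if noise is not None:
            pts = pts + noise.draw(rng, pts.shape)
        for p in pts:
            rows.append((species, "choice", None, p[0], p[1], None))
    frame = pd.DataFrame(
        rows, columns=["species", "treatment", "rail", "nutrient_a", "nutrient_b", "group"]
    )
    return IntakeDataset(frame)


def generate_cdo_array(
    target=DEFAULT_TARGET,
    rails=DEFAULT_RAILS,
    n_per_rail: int = 20,
    noise: NoiseModel | None = None,
    seed=None,
    *,
    species: str = "synthetic_cdo",
    n_choice: int = 0,
) -> IntakeDataset:
    """Array following closest-distance optimisation: every point sits at the
    perpendicular foot of the target on its rail (true beta = 90°), plus
    optional per-coordinate noise.  ``n_choice`` adds choice-treatment rows
    centred on the target itself, for target-estimation workflows.
    """
    if n_per_rail < 1:
        raise ValueError("n_per_rail must be >= 1")
    t, parsed = _resolve(target, rails)
    rng = np.random.default_rng(seed)
    base = [(r.label or f"{r.ratio_a:g}:{r.ratio_b:g}", cdo_projection(r, t).xy) for r in parsed]
    return _assemble(base, n_per_rail, noise, rng, t, species, n_choice)


def _rail_target_angle(rail: Rail, t: np.ndarray) -> float:
    """Unsigned angle (radians) between the rail and the target ray."""
    cosw = float(np.clip(rail.direction @ (t / np.linalg.norm(t)), -1.0, 1.0))
    return float(np.arccos(cosw))


def generate_archetype_array(
    kind: str,
    target=DEFAULT_TARGET,
    rails=DEFAULT_RAILS,
    n_per_rail: int = 20,
    noise: NoiseModel | None = None,
    seed=None,
    *,
    radius: float | None = None,
    branch: str = "outer",
    shrink: float = 0.5,
    species: str | None = None,
    n_choice: int = 0,
) -> IntakeDataset:
    """Array following one of the classic non-CDO rules of compromise.

    kinds
    -----
    ``equal_distance``
        Equal total intake on every rail: points on the arc of radius
        ``radius`` (default |target|) centred on the *origin*.  The rail
        sharing the target's ratio then recovers the target itself, and the
        angle profile is ``beta = 90° − α/2`` (α = rail-to-target angle):
        below 90° everywhere, most strongly at the most imbalanced rails —
        the generalist's surplus-tolerant parabola.
    ``target_distance``
        Points at a fixed Euclidean distance ``radius`` from the *target*
        (``branch="outer"`` beyond the perpendicular foot, ``"inner"``
        before it); raises :class:`NoIntersectionError` for rails whose foot
        lies farther from the target than ``radius``.
    ``square``
        Nutrient A held at the target's A-coordinate on every rail.
    ``inverted_square``
        Nutrient B held at the target's B-coordinate.
    ``linear``
        Total intake A+B held at the target's total.
    ``concave``
        CDO feet shrunk toward the origin by a factor
        ``1 − shrink·(α/α_max)²``: under-consumption growing with rail
        imbalance, the specialist's concave array.
    """
    if kind not in ARCHETYPES:
        raise ValueError(f"unknown archetype {kind!r}; choose from {ARCHETYPES}")
    if n_per_rail < 1:
        raise ValueError("n_per_rail must be >= 1")
    t, parsed = _resolve(target, rails)
    tnorm = float(np.linalg.norm(t))
    rng = np.random.default_rng(seed)

    base: list[tuple[str, np.ndarray]] = []
    alphas = [_rail_target_angle(r, t) for r in parsed]
    alpha_max = max(alphas) or 1.0
    for rail, alpha in zip(parsed, alphas):
        d = rail.direction
        label = rail.label or f"{rail.ratio_a:g}:{rail.ratio_b:g}"
        if kind == "equal_distance":
            r = tnorm if radius is None else float(radius)
            if r <= 0:
                raise ValueError("equal_distance radius must be positive")
            point = d * r
        elif kind == "target_distance":
            if radius is None:
                raise ValueError("target_distance requires an explicit radius")
            proj = float(t @ d)
            disc = proj**2 - (tnorm**2 - radius**2)
            if disc < 0:
                raise NoIntersectionError(
                    f"rail {label}: foot distance exceeds radius {radius}"
                )
            s = proj + np.sqrt(disc) if branch == "outer" else proj - np.sqrt(disc)
            if s < 0:
                raise NoIntersectionError(f"rail {label}: no intersection on the ray")
            point = d * s
        elif kind == "square":
            if d[0] <= 0:
                raise NoIntersectionError(f"rail {label} never reaches nutrient A = {t[0]}")
            point = d * (t[0] / d[0])
        elif kind == "inverted_square":
            if d[1] <= 0:
                raise NoIntersectionError(f"rail {label} never reaches nutrient B = {t[1]}")
            point = d * (t[1] / d[1])
        elif kind == "linear":
            point = d * ((t[0] + t[1]) / (d[0] + d[1]))
        else:  # concave
            if not 0 <= shrink < 1:
                raise ValueError("shrink must be in [0, 1)")
            factor = 1.0 - shrink * (alpha / alpha_max) ** 2
            point = cdo_projection(rail, t).xy * factor
        base.append((label, point))
    return _assemble(
        base, n_per_rail, noise, rng, t, species or f"synthetic_{kind}", n_choice
    )


# ---------------------------------------------------------------------------
# Noise-stability simulation


@dataclass
class SimulationResult:
    """Grid of Thales-angle estimates under increasing noise.

    One row per (family, scale): the mean estimated beta across replicates,
    the confidence band across replicates, its width, and the noise scale
    expressed as a proportion of the intake-target magnitude.
    """

    grid: pd.DataFrame
    seed: int | None
    config: dict = field(default_factory=dict)

    def family(self, name: str) -> pd.DataFrame:
        return self.grid[self.grid["family"] == name].reset_index(drop=True)


#: The stability study's default scale grid: 0.01 to 100 in steps of 0.5.
DEFAULT_SCALE_GRID = tuple(np.arange(0.01, 100.0, 0.5))

#: Unit-magnitude known-90° array for the stability study (see docs/methods.md:
#: the scale grid then spans error-free to error-dominated conditions).
STABILITY_TARGET = (1.0, 1.0)
STABILITY_RAILS = ("1:4", "1:3", "3:1", "4:1")


def noise_stability_simulation(
    families=("gaussian", "poisson", "gamma"),
    scale_grid=DEFAULT_SCALE_GRID,
    n: int = 100,
    reps: int = 100,
    target=STABILITY_TARGET,
    rails=STABILITY_RAILS,
    seed: int | None = None,
    *,
    centered: bool = True,
    ci_level: float = 0.95,
) -> SimulationResult:
    """Stability of the angle estimate under increasing measurement error.

    For each family and each scale in the grid, ``reps`` replicate arrays of
    ``n`` points are drawn on the CDO feet (true beta = 90°) with that
    family's noise added per coordinate; each replicate yields a mean-beta
    estimate, and the row records the mean and the ``ci_level`` t-band of
    those estimates.  Rows are sorted by family then scale, and every
    (family, scale) cell has its own child stream of ``seed``, so the grid
    is bit-reproducible and rows are independently reproducible.
    """
    scales = np.asarray(list(scale_grid), dtype=float)
    if len(scales) == 0 or np.any(scales <= 0) or np.any(np.diff(scales) <= 0):
        raise ValueError("scale_grid must be positive and strictly increasing")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    families = tuple(families)
    if not families:
        raise ValueError("at least one noise family is required")
    t, parsed = _resolve(target, rails)
    tnorm = float(np.linalg.norm(t))
    feet = np.array([cdo_projection(r, t).xy for r in parsed])
    # distribute n points across rails as evenly as possible
    counts = np.full(len(parsed), n // len(parsed))
    counts[: n % len(parsed)] += 1
    pts = np.repeat(feet, counts, axis=0)

    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(families) * len(scales)))
    tcrit = stats.t.ppf(0.5 + ci_level / 2, reps - 1) if reps > 1 else np.nan
    rows = []
    for family in families:
        for scale in scales:
            rng = np.random.default_rng(next(children))
            noise = NoiseModel(family, float(scale), centered=centered)
            B = pts + noise.draw(rng, (reps,) + pts.shape)
            beta = _beta_from_vectors(-B, t - B)
            means = beta.mean(axis=1)
            m = float(means.mean())
            half = float(tcrit * means.std(ddof=1)) if reps > 1 else 0.0
            rows.append(
                {
                    "family": family,
                    "scale": float(scale),
                    "noise_proportion": float(scale) / tnorm,
                    "mean_beta": m,
                    "lwr95": m - half,
                    "upr95": m + half,
                    "band_width": 2 * half,
                    "n": int(n),
                    "reps": int(reps),
                }
            )
    grid = pd.DataFrame(rows)
    return SimulationResult(
        grid=grid,
        seed=seed,
        config={
            "families": families,
            "n": n,
            "reps": reps,
            "target": tuple(map(float, t)),
            "rails": tuple(r.label or f"{r.ratio_a:g}:{r.ratio_b:g}" for r in parsed),
            "centered": centered,
            "ci_level": ci_level,
            "n_scales": len(scales),
        },
    )


def fraction_family_narrowest(result: SimulationResult, family: str = "gaussian") -> float:
    """Fraction of grid scales at which *family*'s confidence band is strictly
    the narrowest of all simulated families (bands compared at matched noise
    proportion, i.e. per scale row)."""
    wide = result.grid.pivot(index="scale", columns="family", values="band_width")
    if family not in wide.columns:
        raise ValueError(f"family {family!r} not present in the result")
    others = wide.drop(columns=[family])
    if others.shape[1] == 0:
        raise ValueError("need at least two families to compare")
    return float((wide[family].lt(others.min(axis=1))).mean())
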