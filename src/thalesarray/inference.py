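"""Per-rail deviation estimates and hypothesis tests.

The statistical machinery mirrors standard linear-model practice: the angle
deviation (beta − 90°) of every individual intake point is the response, the
rail ratio is a factor, and per-rail means with pooled-variance confidence
intervals come from a cell-means model (one coefficient per rail, no
intercept) so each coefficient *is* the rail mean.  A rail whose CI covers 0
is consistent with closest-distance optimisation.  An omnibus one-way F
tests whether deviations differ among rails; a sequential two-way ANOVA
tests whether two species differ in the *shape* of their arrays (the
species × rail interaction).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .geometry import DegenerateVertexError, thales_angle, circle_position
from .io import IntakeDataset, TargetSpec, estimate_intake_target

__all__ = [
    "InferenceError",
    "angle_records",
    "estimate_rail_deviations",
    "omnibus_rail_test",
    "interaction_test",
]

RECORD_COLUMNS = ["species", "rail", "group", "beta_deg", "deviation_deg", "position"]


class InferenceError(ValueError):
    """The design does not support the requested estimate or test."""


def angle_records(
    dataset: IntakeDataset,
    target_spec: TargetSpec | dict[str, TargetSpec] | None = None,
    *,
    include_choice: bool = False,
    tol_deg: float = 1e-8,
) -> pd.DataFrame:
    """Thales angle of every individual rail intake against the species target.

    One row per rail-treatment observation with columns
    ``species, rail, group, beta_deg, deviation_deg, position``.  Choice rows
    define the target and are excluded unless ``include_choice=True``, in
    which case their angles enter under the factor level ``"choice"`` (their
    geometry is near-degenerate at the target; the option exists so that
    alternative factor codings of published analyses can be reproduced).

    Observations coinciding with the origin or the target are dropped with a
    warning and counted in the frame's ``attrs["n_dropped"]``.
    """
    per_species_spec = target_spec if isinstance(target_spec, dict) else None
    rows: list[dict] = []
    dropped: list[str] = []
    targets: dict[str, tuple[float, float]] = {}
    for species in dataset.species:
        spec = (
            per_species_spec.get(species) if per_species_spec is not None else target_spec
        )
        target = estimate_intake_target(dataset, species, spec)
        targets[species] = (target.nutrient_a, target.nutrient_b)
        subset = dataset.rail_rows(species)
        if include_choice:
            choice = dataset.choice_rows(species).copy()
            choice["rail"] = "choice"
            subset = pd.concat([subset, choice], ignore_index=True)
        for _, row in subset.iterrows():
            point = np.array([row["nutrient_a"], row["nutrient_b"]])
            try:
                beta = thales_angle(point, target)
            except DegenerateVertexError as exc:
                dropped.append(f"{species}/{row['rail']}: {exc}")
                continue
            rows.append(
                {
                    "species": species,
                    "rail": row["rail"],
                    "group": row.get("group"),
                    "beta_deg": beta,
                    "deviation_deg": beta - 90.0,
                    "position": circle_position(point, target, tol_deg=tol_deg),
                }
            )
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} degenerate observation(s): "
            + " | ".join(dropped[:5]),
            stacklevel=2,
        )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records.attrs["n_dropped"] = len(dropped)
    records.attrs["dropped"] = dropped
    records.attrs["targets"] = targets
    return records


def _species_subset(records: pd.DataFrame, species: str | None) -> pd.DataFrame:
    if species is not None:
        records = records[records["species"] == species]
    if len(records) == 0:
        raise InferenceError(f"no angle records for species {species!r}")
    return records


def estimate_rail_deviations(
    records: pd.DataFrame,
    species: str | None = None,
    *,
    ci_level: float = 0.95,
    pooled: bool = True,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-rail mean deviation from 90° with confidence intervals.

    Default is the cell-means linear model ``deviation ~ C(rail) - 1`` with
    pooled residual variance; ``pooled=False`` gives independent per-rail
    t-intervals instead.  Output columns: ``species, ratio, n, mean_beta_dev,
    lwr95, upr95, p_value, consistent_with_cdo`` (bound names follow the CI
    level; ``p_holm`` added when ``holm=True``).
    """
    if not 0 < ci_level < 1:
        raise InferenceError(f"ci_level must be in (0,1), got {ci_level}")
    records = _species_subset(records, species)
    alpha = 1.0 - ci_level
    lo, hi = f"lwr{ci_level * 100:g}", f"upr{ci_level * 100:g}"
    out_rows = []
    for sp, sub in records.groupby("species", sort=True):
        rails = sorted(sub["rail"].unique())
        if pooled:
            if len(sub) <= len(rails):
                raise InferenceError(
                    "no residual degrees of freedom: every rail has a single observation"
                )
            model = smf.ols("deviation_deg ~ C(rail) - 1", data=sub).fit()
            ci = model.conf_int(alpha=alpha)
            for rail in rails:
                name = f'C(rail)[{rail}]'
                est = model.params[name]
                out_rows.append(
                    {
                        "species": sp,
                        "ratio": rail,
                        "n": int((sub["rail"] == rail).sum()),
                        "mean_beta_dev": float(est),
                        lo: float(ci.loc[name, 0]),
                        hi: float(ci.loc[name, 1]),
                        "p_value": float(model.pvalues[name]),
                    }
                )
        else:
            for rail in rails:
                x = sub.loc[sub["rail"] == rail, "deviation_deg"].to_numpy()
                n = len(x)
                if n < 2:
                    raise InferenceError(
                        f"rail {rail!r} has {n} observation(s); "
                        "independent intervals need at least 2"
                    )
                m, se = float(np.mean(x)), float(stats.sem(x))
                tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
                tstat = m / se if se > 0 else np.inf * np.sign(m)
                out_rows.append(
                    {
                        "species": sp,
                        "ratio": rail,
                        "n": n,
                        "mean_beta_dev": m,
                        lo: m - tcrit * se,
                        hi: m + tcrit * se,
                        "p_value": float(2 * stats.t.sf(abs(tstat), n - 1)),
                    }
                )
    out = pd.DataFrame(out_rows)
    if holm:
        out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    out["consistent_with_cdo"] = (out[lo] <= 0) & (out[hi] >= 0)
    return out


def omnibus_rail_test(records: pd.DataFrame, species: str | None = None) -> dict:
    """One-way ANOVA of the angle deviations on the rail factor.

    Returns ``{"F", "df1", "df2", "p"}``.  Needs at least two factor levels
    and one residual degree of freedom.
    """
    records = _species_subset(records, species)
    groups = [g["deviation_deg"].to_numpy() for _, g in records.groupby("rail")]
    k, n = len(groups), len(records)
    if k < 2:
        raise InferenceError("omnibus test needs at least two rail levels")
    if n - k < 1:
        raise InferenceError("omnibus test needs at least one residual df")
    F, p = stats.f_oneway(*groups)
    return {"F": float(F), "df1": k - 1, "df2": n - k, "p": float(p)}


def interaction_test(
    records: pd.DataFrame, species_pair: tuple[str, str] | None = None
) -> dict:
    """Species × rail interaction from a sequential two-way ANOVA.

    Fits ``deviation ~ species + rail + species:rail`` with sequential
    (fit-order) sums of squares, main effects first, on the rails shared by
    both species, and returns the interaction ``{"F", "df1", "df2", "p"}``.
    With balanced data this coincides with the other ANOVA types.
    """
    if species_pair is None:
        all_sp = sorted(records["species"].unique())
        if len(all_sp) != 2:
            raise InferenceError(
                f"species_pair required when records contain {len(all_sp)} species"
            )
        species_pair = (all_sp[0], all_sp[1])
    a, b = species_pair
    sub = records[records["species"].isin([a, b])]
    shared = sorted(
        set(sub.loc[sub["species"] == a, "rail"]) & set(sub.loc[sub["species"] == b, "rail"])
    )
    if len(shared) < 2:
        raise InferenceError(
            f"species {a!r} and {b!r} share {len(shared)} rail level(s); need >= 2"
        )
    sub = sub[sub["rail"].isin(shared)]
    model = smf.ols(
        "deviation_deg ~ C(species) + C(rail) + C(species):C(rail)", data=sub
    ).fit()
    table = sm.stats.anova_lm(model, typ=1)
    row = table.loc["C(species):C(rail)"]
    return {
        "F": float(row["F"]),
        "df1": int(row["df"]),
        "df2": int(table.loc["Residual", "df"]),
        "p": float(row["PR(>F)"]),
    }
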