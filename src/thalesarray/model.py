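"""Model/Results interface tying the pieces together.

Follows the fit-object convention of statistical modelling packages: build a
:class:`CompromiseModel` from an intake table, call :meth:`fit`, and work
with the returned :class:`CompromiseResults` — per-rail deviation estimates
with confidence intervals, omnibus and interaction tests, a ``summary()``
table, plots and CSV/JSON export.

Example
-------
>>> from thalesarray import CompromiseModel, simulate
>>> data = simulate.generate_cdo_array(seed=1, n_choice=10,
...                                    noise=simulate.NoiseModel("gaussian", 1.0))
>>> res = CompromiseModel(data).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .geometry import IntakeTarget, ThalesCircle
from .io import (
    IntakeDataset,
    TargetSpec,
    estimate_intake_target,
    read_intake_csv,
    validate_intake_frame,
    write_summary_csv,
)
from . import inference

__all__ = ["CompromiseModel", "CompromiseResults"]


class CompromiseModel:
    """Thales-angle analysis of a nutrient-intake array.

    Parameters
    ----------
    data
        An :class:`~thalesarray.io.IntakeDataset`, or a raw DataFrame that
        will be validated first.
    target
        ``None`` (estimate from each species' choice rows), an ``(a, b)``
        coordinate applied to all species, a :class:`TargetSpec`, or a
        ``{species: TargetSpec | (a, b)}`` mapping.
    species
        Optional subset of species to analyse.
    tol_deg
        Angular tolerance for the on-circle classification.
    """

    def __init__(
        self,
        data: IntakeDataset | pd.DataFrame,
        target=None,
        species: list[str] | None = None,
        tol_deg: float = 1e-8,
    ):
        if isinstance(data, pd.DataFrame):
            data = validate_intake_frame(data)
        if species:
            sub = data.frame[data.frame["species"].isin(species)]
            missing = set(species) - set(data.species)
            if missing:
                raise inference.InferenceError(f"species not in dataset: {sorted(missing)}")
            data = IntakeDataset(sub, data.report)
        self.data = data
        self.target_spec = _normalise_target(target)
        self.tol_deg = tol_deg

    @classmethod
    def from_csv(cls, path, column_map=None, **kwargs) -> "CompromiseModel":
        return cls(read_intake_csv(path, column_map), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, column_map=None, **kwargs) -> "CompromiseModel":
        return cls(validate_intake_frame(frame, column_map), **kwargs)

    @property
    def targets(self) -> dict[str, IntakeTarget]:
        """Resolved intake target per species."""
        out = {}
        for sp in self.data.species:
            spec = (
                self.target_spec.get(sp)
                if isinstance(self.target_spec, dict)
                else self.target_spec
            )
            out[sp] = estimate_intake_target(self.data, sp, spec)
        return out

    def fit(
        self,
        ci_level: float = 0.95,
        *,
        pooled: bool = True,
        holm: bool = False,
        include_choice: bool = False,
    ) -> "CompromiseResults":
        """Compute angle records and per-rail estimates for every species."""
        records = inference.angle_records(
            self.data, self.target_spec, include_choice=include_choice, tol_deg=self.tol_deg
        )
        if len(records) == 0:
            raise inference.InferenceError("no usable angle records in the dataset")
        estimates = inference.estimate_rail_deviations(
            records, ci_level=ci_level, pooled=pooled, holm=holm
        )
        omnibus = {}
        for sp in sorted(records["species"].unique()):
            sub = records[records["species"] == sp]
            if sub["rail"].nunique() >= 2 and len(sub) - sub["rail"].nunique() >= 1:
                omnibus[sp] = inference.omnibus_rail_test(records, sp)
        return CompromiseResults(self, records, estimates, omnibus, ci_level)


def _normalise_target(target):
    if target is None or isinstance(target, TargetSpec):
        return target
    if isinstance(target, dict):
        return {k: _normalise_target(v) for k, v in target.items()}
    if isinstance(target, IntakeTarget):
        return TargetSpec.explicit(target.nutrient_a, target.nutrient_b)
    a, b = target
    return TargetSpec.explicit(float(a), float(b))


class CompromiseResults:
    """Fitted per-rail deviations from the CDO rule of compromise.

    Attributes
    ----------
    records : pandas.DataFrame
        One row per intake point: ``species, rail, group, beta_deg,
        deviation_deg, position``.
    estimates : pandas.DataFrame
        Per-rail mean deviation, CI bounds, p-value and the
        ``consistent_with_cdo`` flag.
    omnibus : dict
        Per-species one-way rail-effect F test.
    """

    def __init__(self, model, records, estimates, omnibus, ci_level):
        self.model = model
        self.records = records
        self.estimates = estimates
        self.omnibus = omnibus
        self.ci_level = ci_level

    @property
    def targets(self) -> dict[str, IntakeTarget]:
        return self.model.targets

    def circle(self, species: str) -> ThalesCircle:
        return ThalesCircle(self.targets[species])

    def interaction(self, species_a: str, species_b: str) -> dict:
        """Species × rail interaction test between two fitted species."""
        return inference.interaction_test(self.records, (species_a, species_b))

    # -- output -----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable per-rail estimate table plus test statistics."""
        lo, hi = _bound_names(self.estimates)
        rows = [
            [
                r["species"],
                r["ratio"],
                str(int(r["n"])),
                f"{r['mean_beta_dev']:.3f}",
                f"{r[lo]:.3f}",
                f"{r[hi]:.3f}",
                "yes" if r["consistent_with_cdo"] else "no",
            ]
            for _, r in self.estimates.iterrows()
        ]
        table = SimpleTable(
            rows,
            headers=["species", "P:C ratio", "n", "mean beta-90", lo, hi, "CDO?"],
            title=f"Thales-angle deviations from CDO ({self.ci_level:.0%} CI)",
        )
        lines = [str(table)]
        for sp, om in self.omnibus.items():
            lines.append(
                f"{sp}: rail effect F({om['df1']}, {om['df2']}) = {om['F']:.3f}, "
                f"p = {om['p']:.3g}"
            )
        dropped = self.records.attrs.get("n_dropped", 0)
        if dropped:
            lines.append(f"note: {dropped} degenerate observation(s) dropped")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        write_summary_csv(self.estimates, path)

    def report_dict(self) -> dict:
        """JSON-serialisable report of estimates, tests and provenance."""
        return {
            "ci_level": self.ci_level,
            "targets": {
                sp: [t.nutrient_a, t.nutrient_b] for sp, t in self.targets.items()
            },
            "estimates": self.estimates.to_dict(orient="records"),
            "omnibus": self.omnibus,
            "n_records": int(len(self.records)),
            "n_dropped": int(self.records.attrs.get("n_dropped", 0)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report_dict(), fh, indent=2, default=_jsonable)

    # -- plotting ---------------------------------------------------------

    def plot_array(self, species: str | None = None, ax=None):
        """Nutrient-space panel: rails, intake points, per-rail means, the
        intake target and the Thales circle."""
        from .plotting import plot_array

        return plot_array(self, species=species, ax=ax)

    def plot_deviations(self, species: str | None = None, ax=None, raw_beta: bool = False):
        """Per-rail deviation summary with CI bars and the CDO reference line."""
        from .plotting import plot_deviations

        return plot_deviations(self, species=species, ax=ax, raw_beta=raw_beta)


def _bound_names(estimates: pd.DataFrame) -> tuple[str, str]:
    lo = next(c for c in estimates.columns if c.startswith("lwr"))
    hi = next(c for c in estimates.columns if c.startswith("upr"))
    return lo, hi


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
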