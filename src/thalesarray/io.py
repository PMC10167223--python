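"""Reading, validating and modelling nutrient-intake tables.

The expected table has one row per individual animal: a species label, a
treatment (``rail`` for a fixed-ratio no-choice diet, ``choice`` for free
choice between complementary foods), the rail's ratio label for rail rows,
and the cumulative intake of the two nutrients.  By convention nutrient A is
protein and nutrient B carbohydrate (rail labels read as P:C, units mg), but
the column mapping is configurable and units are carried opaquely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import IntakeTarget, RailParseError, parse_rail

__all__ = [
    "DEFAULT_COLUMNS",
    "DatasetError",
    "LoadReport",
    "IntakeDataset",
    "TargetSpec",
    "read_intake_csv",
    "validate_intake_frame",
    "estimate_intake_target",
    "write_summary_csv",
    "read_summary_csv",
]

#: Default mapping from canonical field -> CSV column name.
DEFAULT_COLUMNS = {
    "species": "species",
    "treatment": "treatment",
    "rail": "rail",
    "nutrient_a": "protein",
    "nutrient_b": "carbohydrate",
    "group": "group",
}

_CANONICAL = ["species", "treatment", "rail", "nutrient_a", "nutrient_b", "group"]


class DatasetError(ValueError):
    """Structural problem with an intake table (missing columns, empty file...)."""


@dataclass
class LoadReport:
    """What was kept and what was rejected when loading a table."""

    n_rows: int = 0
    n_kept: int = 0
    rejected: list[str] = field(default_factory=list)
    counts: pd.DataFrame | None = None

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class TargetSpec:
    """How to obtain the intake target: an explicit coordinate or the mean of
    the species' choice-treatment rows."""

    mode: str = "from_choice"  # or "explicit"
    nutrient_a: float | None = None
    nutrient_b: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("explicit", "from_choice"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        if self.mode == "explicit":
            if self.nutrient_a is None or self.nutrient_b is None:
                raise ValueError("explicit target requires both coordinates")
            IntakeTarget(self.nutrient_a, self.nutrient_b)  # validate

    @classmethod
    def explicit(cls, nutrient_a: float, nutrient_b: float) -> "TargetSpec":
        return cls("explicit", nutrient_a, nutrient_b)


class IntakeDataset:
    """A validated intake table.

    Wraps a :class:`pandas.DataFrame` with canonical columns ``species``,
    ``treatment`` (``rail``/``choice``), ``rail`` (label, rail rows only),
    ``nutrient_a``, ``nutrient_b`` and optional ``group``.
    """

    def __init__(self, frame: pd.DataFrame, report: LoadReport | None = None):
        if len(frame) == 0:
            raise DatasetError("intake dataset has no valid rows")
        self.frame = frame.reset_index(drop=True)
        self.report = report or LoadReport(
            n_rows=len(frame), n_kept=len(frame), counts=_counts(frame)
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def rails(self, species: str | None = None) -> list[str]:
        df = self.rail_rows(species)
        return sorted(df["rail"].unique(), key=_rail_sort_key)

    def rail_rows(self, species: str | None = None) -> pd.DataFrame:
        df = self.frame[self.frame["treatment"] == "rail"]
        if species is not None:
            df = df[df["species"] == species]
        return df

    def choice_rows(self, species: str | None = None) -> pd.DataFrame:
        df = self.frame[self.frame["treatment"] == "choice"]
        if species is not None:
            df = df[df["species"] == species]
        return df


def _rail_sort_key(label: str):
    # order rails by nutrient-A share of the ratio (0:1 first, a-biased last)
    r = parse_rail(label)
    return r.ratio_a / (r.ratio_a + r.ratio_b)


def _counts(frame: pd.DataFrame) -> pd.DataFrame:
    return (
        frame.groupby(["species", "treatment", "rail"], dropna=False)
        .size()
        .rename("n")
        .reset_index()
    )


def validate_intake_frame(
    frame: pd.DataFrame, column_map: dict[str, str] | None = None
) -> IntakeDataset:
    """Validate a raw table row by row.

    Rows failing validation (bad treatment, malformed rail label, negative or
    non-finite intake) are rejected with row-indexed messages collected in the
    :class:`LoadReport`; a missing mapped column or an entirely invalid table
    raises :class:`DatasetError`.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(_CANONICAL)
        if unknown:
            raise DatasetError(f"unknown column-map keys: {sorted(unknown)}")
        cmap.update(column_map)

    missing = [
        cmap[k]
        for k in ("species", "treatment", "rail", "nutrient_a", "nutrient_b")
        if cmap[k] not in frame.columns
    ]
    if missing:
        raise DatasetError(f"missing required column(s): {missing}")

    report = LoadReport(n_rows=len(frame))
    rows: list[dict] = []
    has_group = cmap["group"] in frame.columns
    for idx, row in frame.iterrows():
        problems: list[str] = []
        treatment = str(row[cmap["treatment"]]).strip().lower()
        if treatment not in ("rail", "choice"):
            problems.append(f"treatment {row[cmap['treatment']]!r} not rail/choice")
        rail_label = None
        if treatment == "rail":
            try:
                rail_label = parse_rail(row[cmap["rail"]]).label
            except RailParseError as exc:
                problems.append(str(exc))
        vals = {}
        for key in ("nutrient_a", "nutrient_b"):
            try:
                v = float(row[cmap[key]])
            except (TypeError, ValueError):
                problems.append(f"{cmap[key]} is not numeric")
                continue
            if not np.isfinite(v):
                problems.append(f"{cmap[key]} is not finite")
            elif v < 0:
                problems.append(f"{cmap[key]} is negative ({v})")
            else:
                vals[key] = v
        if problems:
            report.rejected.append(f"row {idx}: " + "; ".join(problems))
            continue
        rows.append(
            {
                "species": str(row[cmap["species"]]).strip(),
                "treatment": treatment,
                "rail": rail_label,
                "nutrient_a": vals["nutrient_a"],
                "nutrient_b": vals["nutrient_b"],
                "group": (str(row[cmap["group"]]) if has_group and pd.notna(row[cmap["group"]]) else None),
            }
        )

    if report.rejected:
        warnings.warn(
            f"rejected {len(report.rejected)} invalid row(s): "
            + " | ".join(report.rejected[:5])
            + (" ..." if len(report.rejected) > 5 else ""),
            stacklevel=2,
        )
    if not rows:
        raise DatasetError("no valid rows after validation: " + "; ".join(report.rejected[:3]))
    out = pd.DataFrame(rows, columns=_CANONICAL)
    report.n_kept = len(out)
    report.counts = _counts(out)
    return IntakeDataset(out, report)


def read_intake_csv(path, column_map: dict[str, str] | None = None) -> IntakeDataset:
    """Read and validate an intake CSV (RFC-4180, UTF-8, header row required)."""
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"{path}: empty file") from exc
    except FileNotFoundError as exc:
        raise DatasetError(f"{path}: file not found") from exc
    if len(raw) == 0:
        raise DatasetError(f"{path}: no data rows")
    return validate_intake_frame(raw, column_map)


def estimate_intake_target(
    dataset: IntakeDataset,
    species: str,
    target_spec: TargetSpec | None = None,
) -> IntakeTarget:
    """Intake target for a species: explicit coordinate, or the arithmetic
    mean of its choice-treatment rows ("average coordinates").
    """
    if target_spec is not None and target_spec.mode == "explicit":
        return IntakeTarget(target_spec.nutrient_a, target_spec.nutrient_b)
    choice = dataset.choice_rows(species)
    if len(choice) == 0:
        raise DatasetError(
            f"no choice-treatment rows for species {species!r}; "
            "supply an explicit target instead"
        )
    return IntakeTarget(
        float(choice["nutrient_a"].mean()), float(choice["nutrient_b"].mean())
    )


SUMMARY_COLUMNS = ["species", "ratio", "n", "mean_beta_dev", "lwr95", "upr95"]


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    """Serialise a per-rail estimate table (species, ratio, mean deviation,
    CI bounds) to CSV at full precision.  An empty summary is an error."""
    if summary is None or len(summary) == 0:
        raise DatasetError(f"refusing to write an empty summary to {path}")
    cols = [c for c in SUMMARY_COLUMNS if c in summary.columns] + [
        c for c in summary.columns if c not in SUMMARY_COLUMNS
    ]
    try:
        summary[cols].to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise DatasetError(f"cannot write summary to {path}: {exc}") from exc


def read_summary_csv(path) -> pd.DataFrame:
    """Read back a summary written by :func:`write_summary_csv`."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise DatasetError(f"{path}: empty summary")
    return df
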