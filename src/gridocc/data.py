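"""Domain types, validation, and CSV I/O for removal-design occupancy surveys.

The sampling design is hierarchical: 100 km^2 grid cells (primary units) each
contain a handful of ~3 ha subunits (patches or roadside transects), and each
subunit receives up to six 30-minute surveys grouped into three visits of two
surveys each (``visit = ceil(k / 2)``).  Under the removal protocol, all
surveys in a grid cell cease after the visit in which the species is first
detected anywhere in that cell, so detection histories are ragged.

This module owns the tabular containers (:class:`Dataset`), covariate
standardization (:class:`Standardizer`), the NLCD developed-land tabulation,
and the RFC-4180 CSV readers/writers shared by the simulator, the likelihood,
and the CLI.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "GridCell",
    "Subunit",
    "SurveyRecord",
    "Standardizer",
    "Dataset",
    "standardize",
    "tabulate_developed",
    "tabulate_developed_table",
    "read_dataset",
    "write_dataset",
    "design_summary",
    "DEVELOPED_NLCD_CLASSES",
    "DEFAULT_STATE_LEVELS",
]

#: NLCD land-cover codes counted as "developed": open space, low, medium and
#: high intensity development.
DEVELOPED_NLCD_CLASSES = frozenset({21, 22, 23, 24})

DEFAULT_STATE_LEVELS = ("IL", "MN", "WI")

SUBUNIT_KINDS = ("patch", "roadside")

GRID_COLUMNS = ("grid_id", "state", "n_occupied_neighbors", "developed_prop")
SUBUNIT_COLUMNS = ("subunit_id", "grid_id", "kind", "developed_prop_500m")
SURVEY_COLUMNS = (
    "grid_id",
    "subunit_id",
    "k",
    "visit",
    "day_of_year",
    "detection",
    "conducted",
)


class SchemaError(ValueError):
    """A CSV/table is missing required columns or has malformed values."""


class ValidationError(ValueError):
    """Structurally valid data violate a design invariant."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridCell:
    """A 100 km^2 primary sampling unit.

    Parameters
    ----------
    id : str
        Unique grid identifier.
    state : str
        Administrative state label; must be one of the configured levels.
    n_occupied_neighbors : int
        Number of the (at most eight) Moore-adjacent grid cells with a
        confirmed occurrence record, in [0, 8].
    developed_prop : float
        Proportion of the cell's area in developed land cover, in [0, 1].
    """

    id: str
    state: str
    n_occupied_neighbors: int
    developed_prop: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_occupied_neighbors <= 8):
            raise ValidationError(
                f"grid {self.id}: n_occupied_neighbors must be in 0..8, "
                f"got {self.n_occupied_neighbors}"
            )
        if not (0.0 <= self.developed_prop <= 1.0):
            raise ValidationError(
                f"grid {self.id}: developed_prop must be in [0, 1], "
                f"got {self.developed_prop}"
            )


@dataclass(frozen=True)
class Subunit:
    """A ~3.14 ha patch or roadside transect nested in a grid cell."""

    id: str
    grid_id: str
    kind: str
    developed_prop_500m: float

    def __post_init__(self) -> None:
        if self.kind not in SUBUNIT_KINDS:
            raise ValidationError(
                f"subunit {self.id}: kind must be one of {SUBUNIT_KINDS}, "
                f"got {self.kind!r}"
            )
        if not (0.0 <= self.developed_prop_500m <= 1.0):
            raise ValidationError(
                f"subunit {self.id}: developed_prop_500m must be in [0, 1]"
            )


@dataclass(frozen=True)
class SurveyRecord:
    """One 30-minute visual encounter survey.

    ``k`` indexes the survey 1..6 within the subunit; ``visit = ceil(k/2)``
    groups the two paired surveys of each visit.  ``detection`` is meaningful
    only when ``conducted`` is true.
    """

    grid_id: str
    subunit_id: str
    k: int
    visit: int
    day_of_year: int
    detection: int
    conducted: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 6):
            raise ValidationError(f"survey k must be in 1..6, got {self.k}")
        if self.visit != math.ceil(self.k / 2):
            raise ValidationError(
                f"survey (subunit {self.subunit_id}, k={self.k}): visit "
                f"{self.visit} inconsistent with ceil(k/2)={math.ceil(self.k/2)}"
            )
        if self.conducted and self.detection not in (0, 1):
            raise ValidationError(
                f"survey (subunit {self.subunit_id}, k={self.k}): detection "
                f"must be 0 or 1"
            )
        if not (1 <= self.day_of_year <= 366):
            raise ValidationError("day_of_year must be in 1..366")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardizer:
    """Mean/SD captured at fit time; maps covariates to z-scores and back."""

    mean: float
    sd: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(values) -> tuple[np.ndarray, Standardizer]:
    """Center and scale a covariate to mean 0, variance 1 (ddof=1).

    Returns the standardized vector and a :class:`Standardizer` holding the
    sample mean and SD for back-transformation.

    Raises
    ------
    ValidationError
        If fewer than two values are supplied or the covariate is constant.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValidationError("standardize requires at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValidationError("standardize requires finite values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValidationError("constant covariate: zero variance")
    st = Standardizer(mean, sd)
    return st.transform(x), st


# ---------------------------------------------------------------------------
# Developed-land tabulation
# ---------------------------------------------------------------------------


def tabulate_developed(pixel_counts) -> float:
    """Proportion of pixels in the four NLCD developed classes (21-24).

    Parameters
    ----------
    pixel_counts : mapping or pandas object
        Land-cover class code -> pixel count for one spatial unit.  A
        DataFrame with ``nlcd_class_code`` and ``pixel_count`` columns is
        also accepted.
    """
    if isinstance(pixel_counts, pd.DataFrame):
        missing = {"nlcd_class_code", "pixel_count"} - set(pixel_counts.columns)
        if missing:
            raise SchemaError(f"landcover table missing columns: {sorted(missing)}")
        counts = dict(
            zip(pixel_counts["nlcd_class_code"], pixel_counts["pixel_count"])
        )
    elif isinstance(pixel_counts, pd.Series):
        counts = pixel_counts.to_dict()
    elif isinstance(pixel_counts, Mapping):
        counts = dict(pixel_counts)
    else:
        raise SchemaError("pixel_counts must be a mapping or pandas object")

    if not counts:
        raise ValidationError("empty pixel-count table")
    if any(v < 0 for v in counts.values()):
        raise ValidationError("pixel counts must be nonnegative")
    total = float(sum(counts.values()))
    if total == 0:
        raise ValidationError("total pixel count is zero")
    dev = float(sum(v for c, v in counts.items() if int(c) in DEVELOPED_NLCD_CLASSES))
    return dev / total


def tabulate_developed_table(landcover: pd.DataFrame) -> pd.Series:
    """Per-unit developed proportion from a long landcover table.

    ``landcover`` has columns ``unit_id, nlcd_class_code, pixel_count``.
    """
    missing = {"unit_id", "nlcd_class_code", "pixel_count"} - set(landcover.columns)
    if missing:
        raise SchemaError(f"landcover table missing columns: {sorted(missing)}")
    return landcover.groupby("unit_id", sort=True).apply(
        lambda g: tabulate_developed(g[["nlcd_class_code", "pixel_count"]]),
        include_groups=False,
    )


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Validated grid -> subunit -> survey tables.

    ``surveys`` is normalized to conducted surveys only: rows flagged
    ``conducted = False`` on input are treated as structural missingness and
    dropped, so every retained row carries a 0/1 detection.
    """

    grids: pd.DataFrame
    subunits: pd.DataFrame
    surveys: pd.DataFrame
    state_levels: tuple[str, ...] = DEFAULT_STATE_LEVELS
    max_subunits_per_grid: int = 6

    @classmethod
    def from_frames(
        cls,
        grids: pd.DataFrame,
        subunits: pd.DataFrame,
        surveys: pd.DataFrame,
        state_levels: tuple[str, ...] | None = None,
        max_subunits_per_grid: int = 6,
    ) -> "Dataset":
        grids = grids.copy().reset_index(drop=True)
        subunits = subunits.copy().reset_index(drop=True)
        surveys = surveys.copy().reset_index(drop=True)

        _require_columns(grids, GRID_COLUMNS, "grids")
        _require_columns(subunits, SUBUNIT_COLUMNS, "subunits")
        _require_columns(surveys, SURVEY_COLUMNS[:-1], "surveys")

        if "conducted" not in surveys.columns:
            surveys["conducted"] = True
        conducted = _as_bool(surveys["conducted"])
        surveys = surveys.loc[conducted].reset_index(drop=True)
        surveys["k"] = surveys["k"].astype(int)
        surveys["visit"] = surveys["visit"].astype(int)
        surveys["day_of_year"] = surveys["day_of_year"].astype(int)
        surveys["detection"] = surveys["detection"].astype(int)
        surveys["conducted"] = True

        grids["n_occupied_neighbors"] = grids["n_occupied_neighbors"].astype(int)
        grids["developed_prop"] = grids["developed_prop"].astype(float)
        subunits["developed_prop_500m"] = subunits["developed_prop_500m"].astype(float)

        if state_levels is None:
            observed = tuple(sorted(grids["state"].astype(str).unique()))
            state_levels = (
                DEFAULT_STATE_LEVELS
                if set(observed) <= set(DEFAULT_STATE_LEVELS)
                else observed
            )

        ds = cls(
            grids=grids,
            subunits=subunits,
            surveys=surveys,
            state_levels=tuple(state_levels),
            max_subunits_per_grid=max_subunits_per_grid,
        )
        ds.validate()
        return ds

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        g, s, y = self.grids, self.subunits, self.surveys

        if g["grid_id"].duplicated().any():
            dup = g.loc[g["grid_id"].duplicated(), "grid_id"].tolist()
            raise ValidationError(f"duplicate grid ids: {dup}")
        bad_state = sorted(set(g["state"]) - set(self.state_levels))
        if bad_state:
            raise ValidationError(
                f"unknown state labels {bad_state}; levels are {self.state_levels}"
            )
        if ((g["n_occupied_neighbors"] < 0) | (g["n_occupied_neighbors"] > 8)).any():
            raise ValidationError("n_occupied_neighbors outside 0..8")
        if ((g["developed_prop"] < 0) | (g["developed_prop"] > 1)).any():
            raise ValidationError("developed_prop outside [0, 1]")

        if s["subunit_id"].duplicated().any():
            raise ValidationError("duplicate subunit ids")
        orphan = sorted(set(s["grid_id"]) - set(g["grid_id"]))
        if orphan:
            raise ValidationError(f"subunits reference unknown grids: {orphan}")
        bad_kind = sorted(set(s["kind"]) - set(SUBUNIT_KINDS))
        if bad_kind:
            raise ValidationError(f"unknown subunit kinds: {bad_kind}")
        if ((s["developed_prop_500m"] < 0) | (s["developed_prop_500m"] > 1)).any():
            raise ValidationError("developed_prop_500m outside [0, 1]")
        per_grid = s.groupby("grid_id").size()
        over = per_grid[per_grid > self.max_subunits_per_grid]
        if len(over):
            raise ValidationError(
                f"grids exceed {self.max_subunits_per_grid} subunits: "
                f"{over.index.tolist()}"
            )

        orphan = sorted(set(y["subunit_id"]) - set(s["subunit_id"]))
        if orphan:
            raise ValidationError(f"surveys reference unknown subunits: {orphan}")
        sub_grid = s.set_index("subunit_id")["grid_id"]
        mism = y.loc[y["grid_id"].values != sub_grid.loc[y["subunit_id"]].values]
        if len(mism):
            raise ValidationError(
                "survey grid_id disagrees with subunit nesting for subunits "
                f"{sorted(mism['subunit_id'].unique())}"
            )
        if ((y["k"] < 1) | (y["k"] > 6)).any():
            raise ValidationError("survey index k outside 1..6")
        expected_visit = np.ceil(y["k"] / 2).astype(int)
        bad = y.loc[y["visit"].values != expected_visit.values]
        if len(bad):
            raise ValidationError(
                "visit inconsistent with ceil(k/2) for rows with subunits "
                f"{sorted(bad['subunit_id'].unique())}"
            )
        if y.duplicated(subset=["subunit_id", "k"]).any():
            raise ValidationError("duplicate survey index k within a subunit")
        if not y["detection"].isin([0, 1]).all():
            raise ValidationError("detection must be 0 or 1")
        if ((y["day_of_year"] < 1) | (y["day_of_year"] > 366)).any():
            raise ValidationError("day_of_year outside 1..366")

        self._check_removal_consistency()

    def _check_removal_consistency(self) -> None:
        """No conducted survey may exist after a grid's first-detection visit."""
        fdv = self.first_detection_visit()
        if fdv.empty:
            return
        y = self.surveys
        offenders = []
        for grid_id, v in fdv.items():
            later = y[(y["grid_id"] == grid_id) & (y["visit"] > v)]
            if len(later):
                offenders.append(grid_id)
        if offenders:
            raise ValidationError(
                "removal-consistency violation: conducted surveys after the "
                f"first-detection visit in grids {sorted(offenders)}"
            )

    # -- derived views ------------------------------------------------------

    def first_detection_visit(self) -> pd.Series:
        """Visit index of the first detection per grid (grids with >=1 hit)."""
        hits = self.surveys[self.surveys["detection"] == 1]
        if hits.empty:
            return pd.Series(dtype=int)
        return hits.groupby("grid_id")["visit"].min()

    @property
    def n_grids(self) -> int:
        return len(self.grids)

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    @property
    def n_surveys(self) -> int:
        return len(self.surveys)

    def copy(self) -> "Dataset":
        return Dataset(
            self.grids.copy(),
            self.subunits.copy(),
            self.surveys.copy(),
            self.state_levels,
            self.max_subunits_per_grid,
        )


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing columns: {missing}")


def _as_bool(col: pd.Series) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy()
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "t": True, "f": False, "yes": True, "no": False,
    }
    out = []
    for v in col:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        elif isinstance(v, (int, np.integer, float, np.floating)):
            out.append(bool(v))
        else:
            key = str(v).strip().lower()
            if key not in mapping:
                raise SchemaError(f"unparseable boolean in 'conducted': {v!r}")
            out.append(mapping[key])
    return np.asarray(out, dtype=bool)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_dataset(
    survey_csv: str | Path,
    grid_csv: str | Path,
    subunit_csv: str | Path,
    **kwargs,
) -> Dataset:
    """Read and validate the three dataset CSVs.

    CSVs are RFC-4180 with a header row; columns per table:

    * surveys: grid_id, subunit_id, k, visit, day_of_year, detection, conducted
    * grids: grid_id, state, n_occupied_neighbors, developed_prop (+ optional
      row, col for the prioritization lattice)
    * subunits: subunit_id, grid_id, kind, developed_prop_500m
    """
    surveys = pd.read_csv(survey_csv)
    grids = pd.read_csv(grid_csv)
    subunits = pd.read_csv(subunit_csv)
    return Dataset.from_frames(grids, subunits, surveys, **kwargs)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write grids.csv, subunits.csv, surveys.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "grids": out / "grids.csv",
        "subunits": out / "subunits.csv",
        "surveys": out / "surveys.csv",
    }
    dataset.grids.to_csv(paths["grids"], index=False)
    dataset.subunits.to_csv(paths["subunits"], index=False)
    dataset.surveys.to_csv(paths["surveys"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Naive design tabulations
# ---------------------------------------------------------------------------


def design_summary(dataset: Dataset) -> dict[str, int]:
    """Deterministic design counts: units, surveys, and raw detection tallies.

    These are the model-free summaries of a removal-design campaign: how many
    grids/subunits/surveys were realized, how many grids had at least one
    detection, total detections, and how many detections fell in the first
    visit (surveys 1-2).
    """
    y = dataset.surveys
    hits = y[y["detection"] == 1]
    return {
        "n_grids": int(dataset.n_grids),
        "n_subunits": int(dataset.n_subunits),
        "n_surveys": int(dataset.n_surveys),
        "n_detected_grids": int(hits["grid_id"].nunique()),
        "n_detections": int(len(hits)),
        "n_first_visit_detections": int((hits["visit"] == 1).sum()),
    }
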