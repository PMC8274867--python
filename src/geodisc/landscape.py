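"""Gridded landscape data model, ingest/export, boundary distances, covariate contrasts.

The observation unit is a ~500 m grid cell carrying five spatial-location
covariates (elevation, slope, distance to roads / settlements / rivers), an
optional region label, a land-tenure label (IT, OA, PA or OTHER) and annual
aboveground carbon density (t C/ha) over a contiguous year range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

#: the five spatial-location covariates, in canonical order
COVARIATES = ("elevation", "slope", "dist_roads", "dist_settlements", "dist_rivers")

#: recognised land-tenure labels: Indigenous Territory, Overlapped Area,
#: Protected Area, and unprotected other lands (the control pool)
TENURES = ("IT", "OA", "PA", "OTHER")

DEFAULT_YEARS = tuple(range(2003, 2017))


class SchemaError(ValueError):
    """A required field is missing or malformed in the input source."""


class ValidationError(ValueError):
    """An ingested table violates a landscape invariant."""


def carbon_col(year: int) -> str:
    return f"carbon_{year}"


@dataclass
class LandscapeGrid:
    """A regular grid of observation units.

    ``table`` holds one row per cell with columns ``cell_id, row, col, x, y``,
    the five covariates, ``region`` (optional), ``tenure`` and one
    ``carbon_<year>`` column per year.  Coordinates ``x, y`` are planar km at
    the cell centre; ``cell_size`` is the cell edge in km.
    """

    table: pd.DataFrame
    years: tuple[int, ...] = DEFAULT_YEARS
    cell_size: float = 0.5
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.shape is None:
            self.shape = (int(self.table["row"].max()) + 1, int(self.table["col"].max()) + 1)

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def carbon(self, year: int) -> pd.Series:
        if year not in self.years:
            raise KeyError(f"year {year} outside range {self.years[0]}-{self.years[-1]}")
        return self.table[carbon_col(year)]

    def tenure_mask(self, tenure_class: str) -> np.ndarray:
        return (self.table["tenure"] == tenure_class).to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def equals(self, other: "LandscapeGrid") -> bool:
        return (
            self.years == other.years
            and self.cell_size == other.cell_size
            and self.table.reset_index(drop=True).equals(other.table.reset_index(drop=True))
        )


@dataclass
class BoundaryDistanceField:
    """Per-cell signed Euclidean distance (km) to the nearest cell of opposite
    membership in ``tenure_class``: positive inside, negative outside."""

    tenure_class: str
    distance: np.ndarray  # aligned with grid.table rows

    def inside(self) -> np.ndarray:
        return self.distance > 0


@dataclass
class CovariateContrast:
    """Mann-Whitney contrast of one covariate, tenure vs other lands."""

    covariate: str
    mean_treatment: float
    mean_control: float
    statistic: float
    p_value: float

    @property
    def mean_difference(self) -> float:
        return self.mean_treatment - self.mean_control


_REQUIRED = ["row", "col", "tenure", *COVARIATES]


def load_grid(
    source,
    schema: dict[str, str] | None = None,
    years: tuple[int, ...] | None = None,
    cell_size: float = 0.5,
) -> LandscapeGrid:
    """Build a validated :class:`LandscapeGrid` from a table or aligned array stack.

    Parameters
    ----------
    source
        A CSV path, a DataFrame (one row per cell), or a mapping of field name
        to 2D array sharing a common shape (the raster-stack analogue; carbon
        layers keyed ``carbon_<year>``).
    schema
        Optional mapping from source column names to canonical field names.
    years
        Contiguous year range; inferred from ``carbon_<year>`` columns if omitted.

    Cells with missing covariates are dropped (count logged).  Violations of
    the landscape invariants raise :class:`ValidationError`.
    """
    if isinstance(source, dict):
        shapes = {np.asarray(a).shape for a in source.values()}
        if len(shapes) != 1:
            raise SchemaError(f"array layers disagree in shape: {shapes}")
        (shape,) = shapes
        nrow, ncol = shape
        rr, cc = np.mgrid[0:nrow, 0:ncol]
        df = pd.DataFrame({"row": rr.ravel(), "col": cc.ravel()})
        for name, arr in source.items():
            df[name] = np.asarray(arr).ravel()
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)

    if schema:
        df = df.rename(columns=schema)

    missing = [f for f in _REQUIRED if f not in df.columns]
    if missing:
        raise SchemaError(f"missing required fields: {missing}")

    if years is None:
        found = sorted(int(c.split("_")[1]) for c in df.columns if c.startswith("carbon_"))
        if not found:
            raise SchemaError("no carbon_<year> columns found")
        years = tuple(found)
    if list(years) != list(range(years[0], years[-1] + 1)):
        raise ValidationError(f"year range not contiguous: {years}")
    ycols = [carbon_col(y) for y in years]
    missing_y = [c for c in ycols if c not in df.columns]
    if missing_y:
        raise SchemaError(f"missing carbon layers: {missing_y}")

    n0 = len(df)
    df = df.dropna(subset=list(COVARIATES))
    if len(df) < n0:
        logger.warning("dropped %d cells with missing covariates", n0 - len(df))

    bad_tenure = set(df["tenure"].unique()) - set(TENURES)
    if bad_tenure:
        raise ValidationError(f"unknown tenure labels: {sorted(bad_tenure)}")
    carbon = df[ycols].to_numpy(dtype=float)
    if np.isnan(carbon).any() or (carbon < 0).any():
        raise ValidationError("carbon density must be non-negative and complete")
    for c in ("dist_roads", "dist_settlements", "dist_rivers"):
        if (df[c] < 0).any():
            raise ValidationError(f"{c} must be non-negative")
    if ((df["slope"] < 0) | (df["slope"] > 90)).any():
        raise ValidationError("slope must lie in [0, 90] degrees")

    if "x" not in df.columns:
        df["x"] = (df["col"].to_numpy() + 0.5) * cell_size
        df["y"] = (df["row"].to_numpy() + 0.5) * cell_size
    if "cell_id" not in df.columns:
        df["cell_id"] = np.arange(len(df))
    if "region" not in df.columns:
        df["region"] = "all"

    order = ["cell_id", "row", "col", "x", "y", *COVARIATES, "region", "tenure", *ycols]
    df = df[order].reset_index(drop=True)
    return LandscapeGrid(table=df, years=tuple(years), cell_size=cell_size)


def boundary_distance(grid: LandscapeGrid, tenure_class: str) -> BoundaryDistanceField:
    """Signed Euclidean distance of every cell to the ``tenure_class`` boundary.

    Distance is centre-to-centre to the nearest cell of opposite membership,
    in km; positive for cells inside the class, negative outside.  Requires at
    least one cell on each side of the boundary.
    """
    if tenure_class not in TENURES:
        raise ValueError(f"unknown tenure class {tenure_class!r}")
    nrow, ncol = grid.shape
    inside = np.zeros((nrow, ncol), dtype=bool)
    inside[grid.table["row"].to_numpy(), grid.table["col"].to_numpy()] = grid.tenure_mask(
        tenure_class
    )
    if inside.all() or not inside.any():
        raise ValueError(
            f"no {tenure_class} boundary exists: tenure map is uniform"
        )
    # EDT gives distance to the nearest background (False) cell: for inside
    # cells sample against ~inside, for outside cells against inside.
    d_in = ndimage.distance_transform_edt(inside, sampling=grid.cell_size)
    d_out = ndimage.distance_transform_edt(~inside, sampling=grid.cell_size)
    signed = np.where(inside, d_in, -d_out)
    per_cell = signed[grid.table["row"].to_numpy(), grid.table["col"].to_numpy()]
    return BoundaryDistanceField(tenure_class=tenure_class, distance=per_cell)


def covariate_contrast(
    grid: LandscapeGrid, tenure_class: str, covariates: tuple[str, ...] = COVARIATES
) -> list[CovariateContrast]:
    """Two-sided Mann-Whitney rank-sum contrasts of each covariate between the
    tenure class and other lands, establishing non-random spatial placement."""
    treat = grid.table[grid.tenure_mask(tenure_class)]
    ctrl = grid.table[grid.tenure_mask("OTHER")]
    if len(treat) < 2 or len(ctrl) < 2:
        raise ValueError("both arms need at least 2 cells for a rank-sum contrast")
    out = []
    for cov in covariates:
        u, p = stats.mannwhitneyu(treat[cov], ctrl[cov], alternative="two-sided")
        out.append(
            CovariateContrast(
                covariate=cov,
                mean_treatment=float(treat[cov].mean()),
                mean_control=float(ctrl[cov].mean()),
                statistic=float(u),
                p_value=float(p),
            )
        )
    return out


def contrasts_frame(contrasts: list[CovariateContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "covariate": c.covariate,
                "mean_treatment": c.mean_treatment,
                "mean_control": c.mean_control,
                "mean_difference": c.mean_difference,
                "statistic": c.statistic,
                "p_value": c.p_value,
            }
            for c in contrasts
        ]
    )
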