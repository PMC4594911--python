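"""Stand panel data model, CSV I/O, and the self-thinning eligibility filter.

The core objects are :class:`StandPanel` — repeated (age, density, mean
volume) measurements for a set of permanent plots — and
:class:`ModelDataset`, the log–log triples ``(lnN, lnV, plot_index)`` that
the self-thinning models consume.  A plot enters the modelling dataset only
if its cumulative mortality since planting exceeds a threshold (10% by
default): below that, competition-driven mortality has not set in and the
plot does not trace the size–density boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "StandRecord",
    "StandPanel",
    "ModelDataset",
    "CANONICAL_COLUMNS",
    "read_stand_table",
    "write_stand_table",
    "filter_self_thinning",
    "to_log_pairs",
]


class FormatError(ValueError):
    """A delimited input file does not match the expected schema."""


class ValidationError(ValueError):
    """A record violates a stand-data invariant (e.g. nonpositive density)."""


#: canonical snake_case column names of the stand CSV schema
CANONICAL_COLUMNS = ("plot_id", "planting_density", "age", "density", "mean_volume")


class StandRecord(NamedTuple):
    """One measurement of one plot.

    Attributes
    ----------
    plot_id : str
        Plot identifier.
    planting_density : float
        Nominal initial stocking, trees/ha.
    age : float
        Stand age at measurement, years.
    density_N : float
        Surviving density, trees/ha.
    mean_volume_V : float
        Mean stem volume, dm^3 per tree.
    """

    plot_id: str
    planting_density: float
    age: float
    density_N: float
    mean_volume_V: float


@dataclass
class StandPanel:
    """Repeated stand measurements, grouped by plot and sorted by age.

    Wraps a :class:`pandas.DataFrame` with the canonical columns
    ``plot_id, planting_density, age, density, mean_volume``.  Construction
    validates the stand-data invariants: positive densities, volumes and
    ages, density never above the nominal planting density, strictly
    increasing ages within a plot, and no ingrowth (density non-increasing
    with age within a plot).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise ValidationError("panel has no records")
        df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
        df["plot_id"] = df["plot_id"].astype(str)
        for col in CANONICAL_COLUMNS[1:]:
            df[col] = pd.to_numeric(df[col], errors="raise")
        # first-appearance plot order is preserved through a stable sort
        order = {p: k for k, p in enumerate(df["plot_id"].drop_duplicates())}
        df["_ord"] = df["plot_id"].map(order)
        df = df.sort_values(["_ord", "age"], kind="stable").drop(columns="_ord")
        df = df.reset_index(drop=True)

        bad = df.index[
            (df["density"] <= 0) | (df["mean_volume"] <= 0) | (df["age"] <= 0)
        ]
        if len(bad):
            r = int(bad[0])
            raise ValidationError(
                f"row {r} (plot {df.at[r, 'plot_id']}): density, mean_volume and "
                f"age must all be positive"
            )
        over = df.index[df["density"] > df["planting_density"]]
        if len(over):
            r = int(over[0])
            raise ValidationError(
                f"row {r} (plot {df.at[r, 'plot_id']}): density "
                f"{df.at[r, 'density']} exceeds planting density "
                f"{df.at[r, 'planting_density']}"
            )
        for pid, grp in df.groupby("plot_id", sort=False):
            ages = grp["age"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                raise ValidationError(f"plot {pid}: ages must be strictly increasing")
            dens = grp["density"].to_numpy()
            if np.any(np.diff(dens) > 0):
                raise ValidationError(
                    f"plot {pid}: density must be non-increasing with age (no ingrowth)"
                )
        self.frame = df

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[StandRecord]) -> "StandPanel":
        rows = [
            (r.plot_id, r.planting_density, r.age, r.density_N, r.mean_volume_V)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)))

    # -- accessors ---------------------------------------------------------
    @property
    def records(self) -> list[StandRecord]:
        return [
            StandRecord(row.plot_id, row.planting_density, row.age, row.density, row.mean_volume)
            for row in self.frame.itertuples(index=False)
        ]

    @property
    def plot_ids(self) -> list[str]:
        return list(self.frame["plot_id"].drop_duplicates())

    @property
    def n_plots(self) -> int:
        return self.frame["plot_id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def mortality(self) -> pd.Series:
        """Cumulative mortality fraction per plot.

        Computed against the nominal planting density:
        ``(planting_density - min(density)) / planting_density``.
        """
        g = self.frame.groupby("plot_id", sort=False)
        mn = g["density"].min()
        planted = g["planting_density"].first()
        return (planted - mn) / planted


@dataclass(frozen=True)
class ModelDataset:
    """Log-transformed modelling dataset: ``lnV = a + b lnN`` on plot clusters.

    ``plot_index`` is 1-based and contiguous, assigned in first-appearance
    order of ``plot_id`` in the source panel.
    """

    lnN: np.ndarray
    lnV: np.ndarray
    plot_index: np.ndarray
    plot_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("lnN", "lnV"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        idx = np.asarray(self.plot_index, dtype=int)
        object.__setattr__(self, "plot_index", idx)
        if len(idx) and (idx.min() != 1 or idx.max() != len(np.unique(idx))):
            raise ValidationError("plot_index must cover 1..n_plots contiguously")
        if not (len(self.lnN) == len(self.lnV) == len(idx)):
            raise ValidationError("lnN, lnV, plot_index must have equal length")

    @property
    def n_obs(self) -> int:
        return len(self.lnN)

    @property
    def n_plots(self) -> int:
        return len(np.unique(self.plot_index))


def read_stand_table(path, dialect: Mapping[str, str] | None = None) -> StandPanel:
    """Read a stand panel from a delimited text file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    dialect : mapping, optional
        Map from canonical column name (``plot_id``, ``planting_density``,
        ``age``, ``density``, ``mean_volume``) to the header actually used
        in the file.  Defaults to the identity map.

    Raises
    ------
    FormatError
        If a required column is absent.
    ValidationError
        If a row violates a stand-data invariant.
    """
    df = pd.read_csv(path)
    dialect = dict(dialect or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        actual = dialect.get(canonical, canonical)
        if actual not in df.columns:
            raise FormatError(
                f"{path}: missing required column {actual!r} (for {canonical!r})"
            )
        rename[actual] = canonical
    return StandPanel(df.rename(columns=rename))


def write_stand_table(panel: StandPanel, path, retained: Mapping[str, bool] | None = None) -> None:
    """Write a panel back to the canonical CSV schema.

    If ``retained`` is given (plot_id -> bool), a boolean ``retained``
    column is appended — the output of the self-thinning filter audit.
    """
    df = panel.frame.copy()
    if retained is not None:
        df["retained"] = df["plot_id"].map(dict(retained)).astype(bool)
    df.to_csv(path, index=False)


def filter_self_thinning(
    panel: StandPanel, mortality_threshold: float = 0.10, *,
    reference: str = "planting",
) -> StandPanel:
    """Retain only plots whose cumulative mortality strictly exceeds the threshold.

    Self-thinning is taken to have started once a plot has lost more than
    ``mortality_threshold`` (default 10%) of its stems.  Mortality is
    cumulative: ``(reference density - min observed density) / reference
    density``, where the reference is the nominal planting density by
    default (``reference="planting"``) or the first measured density
    (``reference="first"``).  All records of a retained plot are kept;
    plots at exactly the threshold are excluded.

    Raises
    ------
    ValidationError
        If the panel is empty or no plot passes the filter.
    """
    if not 0 <= mortality_threshold < 1:
        raise ValueError("mortality_threshold must lie in [0, 1)")
    g = panel.frame.groupby("plot_id", sort=False)
    mn = g["density"].min()
    if reference == "planting":
        ref = g["planting_density"].first()
    elif reference == "first":
        ref = g["density"].first()
    else:
        raise ValueError(f"unknown mortality reference {reference!r}")
    mortality = (ref - mn) / ref
    keep = mortality.index[mortality > mortality_threshold]
    if len(keep) == 0:
        raise ValidationError(
            f"no self-thinning plots: no plot has cumulative mortality > "
            f"{mortality_threshold:.0%}"
        )
    kept = panel.frame[panel.frame["plot_id"].isin(set(keep))]
    return StandPanel(kept)


def to_log_pairs(panel: StandPanel) -> ModelDataset:
    """Transform a (filtered) panel to ``(lnN, lnV, plot_index)`` triples.

    Natural logarithms throughout; cluster indices are assigned 1..n_plots
    in first-appearance order of ``plot_id``.
    """
    df = panel.frame
    if (df["density"] <= 0).any() or (df["mean_volume"] <= 0).any():
        raise ValidationError("nonpositive density or volume; cannot take logs")
    ids = panel.plot_ids
    index_of = {p: k + 1 for k, p in enumerate(ids)}
    return ModelDataset(
        lnN=np.log(df["density"].to_numpy(dtype=float)),
        lnV=np.log(df["mean_volume"].to_numpy(dtype=float)),
        plot_index=df["plot_id"].map(index_of).to_numpy(dtype=int),
        plot_ids=tuple(ids),
    )
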