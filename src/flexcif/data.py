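"""Survival datasets, delimited-text readers and life tables.

A :class:`SurvDataset` holds one row per subject: follow-up time ``t_i``
(years), the failure indicator ``delta_i`` (0 censored, 1 dead), the cause
code ``j_i`` (0 iff censored, otherwise 1..J) and a numeric covariate frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("flexcif")

__all__ = ["SurvDataset", "read_surv_data", "load_mgus_like", "LifeTable",
           "read_lifetable"]


@dataclass
class SurvDataset:
    """Competing-risks sample ``(t_i, delta_i, j_i, x_i)``."""

    time: np.ndarray
    status: np.ndarray
    cause: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.cause = np.asarray(self.cause, dtype=int)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        self.covariates = self.covariates.reset_index(drop=True)
        n = self.time.shape[0]
        if not (self.status.shape[0] == self.cause.shape[0]
                == len(self.covariates) == n):
            raise ValueError("time, status, cause and covariates disagree in length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("follow-up times must be positive and finite")
        if not np.array_equal(self.status == 0, self.cause == 0):
            raise ValueError("cause must be 0 exactly for censored rows (status 0)")
        if self.covariates.size and self.covariates.isna().any().any():
            raise ValueError("covariates contain missing values; filter first")

    @property
    def n(self) -> int:
        return int(self.time.shape[0])

    @property
    def causes(self) -> list[int]:
        """Distinct observed cause codes, sorted, censoring excluded."""
        return sorted(int(j) for j in np.unique(self.cause) if j != 0)

    def covariate_matrix(self, names) -> np.ndarray:
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise KeyError(f"covariates not in dataset: {missing}")
        return self.covariates[list(names)].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.time, "status": self.status,
                            "cause": self.cause})
        return pd.concat([out, self.covariates], axis=1)

    def subset(self, mask) -> "SurvDataset":
        mask = np.asarray(mask, dtype=bool)
        return SurvDataset(self.time[mask], self.status[mask],
                           self.cause[mask], self.covariates.loc[mask])


def read_surv_data(path, *, sep=",", time_col="time", status_col="status",
                   cause_col="cause", covariate_cols=None) -> SurvDataset:
    """Read a delimited survival table.

    Any column other than the three mapped ones is treated as a covariate
    unless ``covariate_cols`` narrows the list.  Rows with missing values in
    the modelled covariates are dropped with a logged count.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (time_col, status_col, cause_col):
        if col not in df.columns:
            raise ValueError(f"required column '{col}' not found in {path}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns
                          if c not in (time_col, status_col, cause_col)]
    keep = df[covariate_cols].notna().all(axis=1) if covariate_cols else \
        pd.Series(True, index=df.index)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with missing modelled covariates", dropped)
    df = df.loc[keep]
    return SurvDataset(df[time_col].to_numpy(float),
                       df[status_col].to_numpy(int),
                       df[cause_col].to_numpy(int),
                       df[covariate_cols])


def load_mgus_like(source, *, sep=",", progression_time="ptime",
                   progression_status="pstat", death_time="futime",
                   death_status="death", covariate_cols=("age", "sex", "mspike"),
                   sex_col="sex", female_label="F", months_to_years=True):
    """Compose first-event competing-risks records from a two-outcome table.

    The layout mirrors registry follow-up data where progression to a
    malignancy and death are recorded separately: progression (cause 1) is
    absorbing, so a subject who progresses and later dies counts as cause 1
    at the progression time; a death without progression is cause 2; anyone
    else is censored at last follow-up.  Input times in months are converted
    to years by default.

    Returns ``(dataset, n_dropped)`` where ``n_dropped`` counts rows removed
    for missing modelled covariates.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else \
        pd.read_csv(source, sep=sep)
    for col in (progression_time, progression_status, death_time, death_status):
        if col not in df.columns:
            raise ValueError(f"required column '{col}' missing")
    bad = (df[progression_time] < 0) | (df[death_time] < 0) | \
        ((df[progression_status] == 1) & (df[progression_time] > df[death_time]))
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} rows have negative or inverted event times")
    covariate_cols = list(covariate_cols)
    keep = df[covariate_cols].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing modelled covariates", n_dropped)
    df = df.loc[keep].reset_index(drop=True)

    prog = df[progression_status].to_numpy(int) == 1
    died = df[death_status].to_numpy(int) == 1
    time = np.where(prog, df[progression_time], df[death_time]).astype(float)
    cause = np.where(prog, 1, np.where(died, 2, 0))
    status = (cause > 0).astype(int)
    # a recorded time of zero is interpreted as an event within the first
    # half time unit (month), as registry data round down
    time = np.maximum(time, 0.5)
    if months_to_years:
        time = time / 12.0
    cov = df[covariate_cols].copy()
    if sex_col in cov.columns and cov[sex_col].dtype == object:
        cov[sex_col] = (cov[sex_col] == female_label).astype(float)
    return SurvDataset(time, status, cause, cov), n_dropped


class LifeTable:
    """Annual mortality rates indexed by sex, integer age and calendar year.

    ``sex`` is coded 0 = man, 1 = woman, matching the simulation's Bernoulli
    covariate.  Rates are hazards per person-year, assumed constant within
    each (age, year) cell.
    """

    def __init__(self, frame: pd.DataFrame):
        req = {"sex", "age", "year", "rate"}
        if not req.issubset(frame.columns):
            raise ValueError(f"life table needs columns {sorted(req)}")
        if (frame["rate"] < 0).any():
            raise ValueError("life-table rates must be non-negative")
        self.frame = frame.reset_index(drop=True)
        self._ages = np.sort(frame["age"].unique())
        self._years = np.sort(frame["year"].unique())
        self.age_min, self.age_max = int(self._ages[0]), int(self._ages[-1])
        self.year_min, self.year_max = int(self._years[0]), int(self._years[-1])
        n_age = self.age_max - self.age_min + 1
        n_year = self.year_max - self.year_min + 1
        self._grid = np.full((2, n_age, n_year), np.nan)
        sx = frame["sex"].to_numpy(int)
        ag = frame["age"].to_numpy(int) - self.age_min
        yr = frame["year"].to_numpy(int) - self.year_min
        self._grid[sx, ag, yr] = frame["rate"].to_numpy(float)
        if np.isnan(self._grid).any():
            raise ValueError("life table has gaps over its (sex, age, year) span")

    def rate(self, sex, age, year) -> np.ndarray:
        """Annual rate at attained (continuous) age and calendar year."""
        sex = np.asarray(sex, dtype=int)
        ai = np.floor(np.asarray(age, dtype=float)).astype(int)
        yi = np.floor(np.asarray(year, dtype=float)).astype(int)
        out_age = (ai < self.age_min) | (ai > self.age_max)
        out_year = (yi < self.year_min) | (yi > self.year_max)
        if np.any(out_age) or np.any(out_year):
            a0 = np.atleast_1d(ai)[np.atleast_1d(out_age | out_year)][0]
            y0 = np.atleast_1d(yi)[np.atleast_1d(out_age | out_year)][0]
            raise ValueError(
                f"life table does not cover (age={a0}, year={y0}); "
                f"span is ages [{self.age_min},{self.age_max}] x "
                f"years [{self.year_min},{self.year_max}]")
        return self._grid[sex, ai - self.age_min, yi - self.year_min]


def read_lifetable(path, sep=",") -> LifeTable:
    """Read a life table from delimited text with columns sex, age, year, rate."""
    return LifeTable(pd.read_csv(path, sep=sep))
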