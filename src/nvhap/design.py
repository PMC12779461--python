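"""Shared design-matrix construction for the regression models.

All models in this package (length-of-stay hurdle, event logistic,
mortality logistic) share one covariate layout: an intercept, site
indicator columns (first site is the reference), calendar time as a
continuous "years since study start" term, an annual sine/cosine pair
for week-of-year seasonality, the binary patient flags, and — for the
event model only — length of stay as a final linear column.

Calendar year enters continuously (not as factor levels) so that
post-period predictions extrapolate linearly instead of failing on
year levels unseen in the pre-period fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi
DAYS_PER_YEAR = 365.25


@dataclass
class DesignInfo:
    """Recorded layout of a fitted design matrix, reused at prediction time."""

    site_levels: list[str]
    covariates: list[str]
    study_start: pd.Timestamp
    include_los: bool = False
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.columns:
            cols = ["intercept"]
            cols += [f"site_{s}" for s in self.site_levels[1:]]
            cols += ["year_c", "sin_woy", "cos_woy"]
            cols += list(self.covariates)
            if self.include_los:
                cols.append("los")
            self.columns = cols

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def los_index(self) -> int:
        if not self.include_los:
            raise ValueError("design does not carry a length-of-stay column")
        return len(self.columns) - 1


def years_since(dates: pd.Series, origin: pd.Timestamp) -> np.ndarray:
    if not pd.api.types.is_datetime64_any_dtype(dates):
        dates = pd.to_datetime(dates)
    return (dates - pd.Timestamp(origin)).dt.days.to_numpy() / DAYS_PER_YEAR


def season_angle(dates: pd.Series) -> np.ndarray:
    if not pd.api.types.is_datetime64_any_dtype(dates):
        dates = pd.to_datetime(dates)
    doy = dates.dt.dayofyear.to_numpy()
    return TWO_PI * doy / DAYS_PER_YEAR


def design_info(
    df: pd.DataFrame,
    covariates: list[str],
    study_start,
    include_los: bool = False,
    site_levels: list[str] | None = None,
) -> DesignInfo:
    if site_levels is None:
        site_levels = sorted(df["site"].unique())
    return DesignInfo(
        site_levels=list(site_levels),
        covariates=list(covariates),
        study_start=pd.Timestamp(study_start),
        include_los=include_los,
    )


def build_matrix(df: pd.DataFrame, info: DesignInfo, los=None) -> np.ndarray:
    """Build the design matrix for ``df`` following ``info``.

    ``los``: only for designs with ``include_los``; defaults to the ``los``
    column of ``df``; may be a scalar to standardize everyone to one level.
    """
    n = len(df)
    cols = [np.ones(n)]
    site = df["site"].to_numpy()
    for s in info.site_levels[1:]:
        cols.append((site == s).astype(float))
    unseen = set(site) - set(info.site_levels)
    if unseen:
        raise ValueError(f"sites absent from the fitted design: {sorted(unseen)}")
    cols.append(years_since(df["admit_date"], info.study_start))
    ang = season_angle(df["admit_date"])
    cols.append(np.sin(ang))
    cols.append(np.cos(ang))
    for c in info.covariates:
        cols.append(df[c].to_numpy(dtype=float))
    if info.include_los:
        if los is None:
            los = df["los"].to_numpy(dtype=float)
        cols.append(np.broadcast_to(np.asarray(los, dtype=float), (n,)).copy())
    return np.column_stack(cols)


def check_full_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(columns[j])
            r = rj
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
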