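"""Reduce monthly environmental series to standardized annual covariates.

Monthly indices (longlining effort, sea surface temperature, Southern
Oscillation Index) are averaged over biologically defined seasonal
windows — the breeding season (April-September of year t) and the
non-breeding season (December of t-1 through February of t, labelled
year t) — optionally lagged by one to four seasons, screened for
collinearity, and reduced either by averaging (same units) or by PCA on
the correlation matrix (mixed units).  The result is a year-indexed
table of z-standardized covariates ready to enter a survival design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CovariateSeries",
    "ReducedCovariate",
    "seasonal_average",
    "seasonal_table",
    "lag_covariate",
    "standardize",
    "screen_correlated",
    "reduce_correlated",
    "read_monthly_csv",
    "write_reduced_csv",
]

SEASON_MONTHS = {"breeding": tuple(range(4, 10)),      # Apr-Sep of year t
                 "nonbreeding": (12, 1, 2)}            # Dec(t-1)-Feb(t)


@dataclass
class CovariateSeries:
    """A monthly environmental index for one region.

    ``values`` is indexed by a pandas PeriodIndex with monthly frequency.
    """

    name: str
    region: str
    values: pd.Series
    units: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v.index, pd.PeriodIndex) or v.index.freqstr not in ("M",):
            raise ValueError(f"{self.name}: values need a monthly PeriodIndex")
        if not v.index.is_monotonic_increasing:
            raise ValueError(f"{self.name}: index must be sorted")
        full = pd.period_range(v.index[0], v.index[-1], freq="M")
        if len(full) != len(v.index):
            missing = full.difference(v.index)
            raise ValueError(f"{self.name}: non-contiguous monthly index "
                             f"(missing {list(missing[:3])}...)")

    @property
    def label(self) -> str:
        return f"{self.name}_{self.region}" if self.region else self.name


@dataclass
class ReducedCovariate:
    """A standardized annual covariate with its construction provenance."""

    name: str
    values: pd.Series  # indexed by year, mean ~0, sd ~1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError(f"{self.name}: provenance must be non-empty")


# ---------------------------------------------------------------------------
# seasonal windows and lags

def seasonal_average(series: CovariateSeries, season: str, year: int) -> float:
    """Mean of the monthly values in a seasonal window.

    ``breeding`` averages April-September of ``year``; ``nonbreeding``
    averages December of ``year - 1`` with January-February of ``year``
    (the winter preceding breeding season ``year``).
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"season must be one of {tuple(SEASON_MONTHS)}")
    vals = []
    for m in SEASON_MONTHS[season]:
        y = year - 1 if (season == "nonbreeding" and m == 12) else year
        per = pd.Period(f"{y}-{m:02d}", freq="M")
        if per not in series.values.index:
            raise KeyError(f"{series.label}: missing month {per}")
        vals.append(series.values.loc[per])
    return float(np.mean(vals))


def seasonal_table(series: CovariateSeries, years) -> pd.DataFrame:
    """Season-by-year table with columns 'nonbreeding' and 'breeding'."""
    rows = {}
    for season in ("nonbreeding", "breeding"):
        rows[season] = {y: seasonal_average(series, season, y) for y in years}
    return pd.DataFrame(rows)


def lag_covariate(seasonal: pd.DataFrame, lag_seasons: int) -> pd.DataFrame:
    """Shift a season-by-year table back by 1-4 seasons.

    Within a calendar year the non-breeding window (Dec-Feb) precedes
    the breeding window (Apr-Sep), so the season sequence is
    ... nb(t), br(t), nb(t+1), br(t+1) ...  A lag of 1 assigns each
    slot the value of the previous season; a lag of 2 equals a one-year
    shift.
    """
    if lag_seasons not in (1, 2, 3, 4):
        raise ValueError("lag_seasons must be in 1..4")
    years = list(seasonal.index)
    seq = []  # chronological (year, season) slots
    for y in years:
        seq.append((y, "nonbreeding"))
        seq.append((y, "breeding"))
    flat = [seasonal.loc[y, s] for (y, s) in seq]
    lagged_flat = [np.nan] * lag_seasons + flat[:-lag_seasons]
    out = seasonal.copy()
    for (y, s), v in zip(seq, lagged_flat):
        out.loc[y, s] = v
    return out


# ---------------------------------------------------------------------------
# standardization and reduction

def standardize(values: pd.Series) -> tuple[pd.Series, float, float]:
    """z-score a year-indexed series; returns (z, mean, sd)."""
    v = values.dropna()
    mu = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ValueError("cannot standardize a constant series")
    return (values - mu) / sd, mu, sd


def screen_correlated(candidates: pd.DataFrame, alpha: float = 0.05,
                      threshold: float | None = None) -> list[list[str]]:
    """Group candidate covariates by pairwise correlation.

    Two columns are linked when their Pearson correlation is significant
    at ``alpha`` (two-sided t-test) — or, if ``threshold`` is given,
    when |r| exceeds it.  Returns the connected components (singletons
    included), each a list of column names.
    """
    cols = list(candidates.columns)
    adj = {c: set() for c in cols}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = candidates[[a, b]].dropna()
            if len(pair) < 3:
                continue
            r, p = stats.pearsonr(pair[a], pair[b])
            linked = (abs(r) >= threshold) if threshold is not None else (p < alpha)
            if linked:
                adj[a].add(b)
                adj[b].add(a)
    seen, groups = set(), []
    for c in cols:
        if c in seen:
            continue
        stack, comp = [c], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x] - seen)
        groups.append(sorted(comp))
    return groups


def _pca_correlation(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA on standardized columns (i.e. on the correlation matrix).
    Returns (scores, explained-variance fractions); loadings are signed
    so the largest-magnitude loading of each component is positive."""
    from sklearn.decomposition import PCA

    pca = PCA()
    scores = pca.fit_transform(z)
    load = pca.components_
    for k in range(load.shape[0]):
        j = int(np.argmax(np.abs(load[k])))
        if load[k, j] < 0:
            load[k] = -load[k]
            scores[:, k] = -scores[:, k]
    return scores, pca.explained_variance_ratio_


def reduce_correlated(candidates: pd.DataFrame, units: dict[str, str],
                      groups: list[list[str]] | None = None,
                      alpha: float = 0.05, threshold: float | None = None,
                      n_components: int = 2) -> tuple[pd.DataFrame, dict]:
    """Collapse correlated covariates into standardized annual covariates.

    Same-unit groups are averaged then z-scored; mixed-unit groups go
    through a PCA on the correlation matrix, retaining the first
    ``n_components`` scores (named ``PC1<members>`` ...).  Singleton
    groups pass through standardized.  Returns the reduced year-by-
    covariate table and a provenance dict (members, method, explained
    variance for PCA components).
    """
    if groups is None:
        groups = screen_correlated(candidates, alpha=alpha, threshold=threshold)
    out = {}
    provenance = {}
    for group in groups:
        sub = candidates[group].dropna()
        if len(group) == 1:
            name = group[0]
            z, mu, sd = standardize(candidates[name])
            out[name] = z
            provenance[name] = {"members": group, "method": "passthrough",
                                "mean": mu, "sd": sd}
            continue
        member_units = {units[g] for g in group}
        if len(member_units) == 1:
            name = "avg_" + "_".join(group)
            avg = candidates[group].mean(axis=1)
            z, mu, sd = standardize(avg)
            out[name] = z
            provenance[name] = {"members": group, "method": "average",
                                "mean": mu, "sd": sd}
        else:
            zcols = np.column_stack([standardize(sub[g])[0].loc[sub.index]
                                     for g in group])
            scores, evr = _pca_correlation(zcols)
            stem = "".join(sorted({g.split("_")[0] for g in group}))
            for k in range(min(n_components, scores.shape[1])):
                name = f"PC{k + 1}{stem}"
                s = pd.Series(scores[:, k], index=sub.index)
                z, mu, sd = standardize(s)
                out[name] = z
                provenance[name] = {
                    "members": group, "method": "pca",
                    "component": k + 1,
                    "explained_variance": float(evr[k]),
                }
    return pd.DataFrame(out), provenance


# ---------------------------------------------------------------------------
# I/O

def read_monthly_csv(path) -> list[CovariateSeries]:
    """Read monthly series from CSV columns (year, month, region,
    variable, value, [units])."""
    df = pd.read_csv(path)
    needed = {"year", "month", "region", "variable", "value"}
    if not needed <= set(df.columns):
        raise ValueError(f"monthly CSV needs columns {sorted(needed)}")
    df["region"] = df["region"].fillna("")
    if "units" in df.columns:
        df["units"] = df["units"].fillna("")
    out = []
    for (var, region), sub in df.groupby(["variable", "region"], sort=True):
        sub = sub.sort_values(["year", "month"])
        idx = pd.PeriodIndex(
            [pd.Period(f"{y}-{m:02d}", freq="M")
             for y, m in zip(sub["year"], sub["month"])]
        )
        units = str(sub["units"].iloc[0]) if "units" in sub.columns else ""
        out.append(CovariateSeries(var, str(region),
                                   pd.Series(sub["value"].to_numpy(), index=idx),
                                   units=units))
    return out


def write_reduced_csv(path, reduced: pd.DataFrame) -> None:
    """Write a reduced-covariate table as long CSV (year, covariate, value)."""
    long = reduced.reset_index(names="year").melt(
        id_vars="year", var_name="covariate", value_name="value"
    ).dropna()
    long.sort_values(["covariate", "year"]).to_csv(path, index=False)
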