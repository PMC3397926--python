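"""Synthetic capture histories and environmental series.

Generates data with the statistical structure the analysis assumes: a
two-panel annual monitoring design with a gap, transient contamination
(a fraction of newly marked animals permanently emigrates immediately
after marking), Markovian trap-dependent recapture (a logit offset
after a capture), and annual survival driven by standardized
environmental covariates through a logit-linear model.

The defaults mirror the study conditions: 4,555 adult histories over
annual occasions 1978-2011 with a 2000-2003 gap, two disjoint panels of
3,227 and 1,328 individuals, mean adult survival 0.915, and covariate
slopes (-0.104, -0.212, -0.137) for longlining effort, annual SOI and
two-year SST.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .covariates import CovariateSeries, seasonal_table, standardize
from .design import StudyDesign, simple_design
from .encounter import EncounterHistory

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_covariates",
    "default_covariate_table",
    "simulate_histories",
    "simulate_cjs",
]

DEFAULT_SLOPES = {"LL_CC_br": -0.104, "SOIyr": -0.212, "SST_CC_2yr": -0.137}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of the synthetic study.

    Logit-scale survival is ``survival_intercept + Σ slope·z`` over the
    standardized covariates; ``capture_logit`` is the m2-state capture
    logit and ``trap_delta`` the m1 offset; ``transient_fraction`` is
    the per-cohort share of immediate permanent emigrants.
    ``phi_override`` (per-interval survival probabilities) bypasses the
    covariate model when set.
    """

    design: StudyDesign = field(default_factory=StudyDesign.default)
    n_individuals: int = 4555
    panel_split: tuple[float, ...] = (3227.0, 1328.0)
    survival_intercept: float = 2.3749  # logit(0.915)
    survival_slopes: tuple[tuple[str, float], ...] = tuple(DEFAULT_SLOPES.items())
    capture_logit: float = 0.4
    trap_delta: float = 1.5
    transient_fraction: float = 0.3
    sex_ratio: float = 0.5
    recruitment_decay: float = 0.15
    phi_override: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.transient_fraction < 1:
            raise ValueError("transient_fraction must be in [0, 1)")
        if len(self.panel_split) != len(self.design.panels):
            raise ValueError("panel_split length must match number of panels")


@dataclass
class SimulatedDataset:
    """Histories plus the generating truth, for recovery tests."""

    histories: list[EncounterHistory]
    phi_true: np.ndarray          # per-interval resident survival
    p_base: float                 # m2-state capture probability
    trap_delta: float
    covariates: pd.DataFrame | None
    config: SimulationConfig
    seed: int | None

    def truth_frame(self) -> pd.DataFrame:
        years = self.config.design.occasions[:-1]
        return pd.DataFrame({"year": years, "phi_true": self.phi_true})


# ---------------------------------------------------------------------------
# environmental series

def simulate_covariates(design: StudyDesign, seed: int | None = None,
                        shared_factor_loading: float = 0.0,
                        noise_scale: float = 1.0) -> list[CovariateSeries]:
    """Monthly LL/SST/SOI series spanning the study (plus two lead years
    for lagged windows).

    SST is a seasonal cycle plus AR(1) anomalies, SOI a standardized
    AR(1), and LL a positive effort series that rises and then declines
    across the span.  ``shared_factor_loading`` injects a common annual
    factor into LL and SST anomalies to exercise the correlation-
    reduction rules.
    """
    rng = np.random.default_rng(seed)
    y0, y1 = design.occasions[0] - 2, design.occasions[-1]
    idx = pd.period_range(f"{y0}-01", f"{y1}-12", freq="M")
    n = len(idx)
    years = np.array([p.year for p in idx])
    months = np.array([p.month for p in idx])
    factor_by_year = {y: rng.normal() for y in range(y0, y1 + 1)}
    factor = np.array([factor_by_year[y] for y in years])

    def ar1(rho, sd):
        sd = sd * noise_scale
        x = np.empty(n)
        x[0] = rng.normal(scale=sd / np.sqrt(1 - rho ** 2)) if sd else 0.0
        innov = rng.normal(scale=sd, size=n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + innov[i]
        return x

    out = []
    for region in ("CC", "BA"):
        cyc = 19.0 + 3.0 * np.cos(2 * np.pi * (months - 8) / 12)
        sst = cyc + ar1(0.8, 0.35) + shared_factor_loading * factor
        out.append(CovariateSeries("SST", region, pd.Series(sst, index=idx),
                                   units="degC"))
    soi = ar1(0.6, 0.8)
    out.append(CovariateSeries("SOI", "", pd.Series(soi, index=idx),
                               units="index"))
    for region in ("CC", "BA"):
        mid = (y0 + y1) / 2
        bump = np.exp(-((years - mid) / 12.0) ** 2)
        ll = 2.0e6 * bump * np.exp(0.25 * ar1(0.7, 0.4)
                                   + 0.3 * shared_factor_loading * factor)
        out.append(CovariateSeries("LL", region, pd.Series(ll, index=idx),
                                   units="hooks"))
    return out


def default_covariate_table(design: StudyDesign, seed: int | None = None,
                            ) -> pd.DataFrame:
    """The three standardized annual covariates of the default survival
    model, built from simulated monthly series:

    * ``LL_CC_br`` — breeding-season longlining effort;
    * ``SOIyr`` — mean of the current non-breeding and previous breeding
      season SOI (one full year);
    * ``SST_CC_2yr`` — mean of four consecutive seasonal windows of
      breeding-ground SST (two years).
    """
    series = {s.label: s for s in simulate_covariates(design, seed=seed)}
    years = list(design.occasions)
    wide = range(years[0] - 1, years[-1] + 1)
    ll = seasonal_table(series["LL_CC"], wide)
    soi = seasonal_table(series["SOI"], wide)
    sst = seasonal_table(series["SST_CC"], wide)
    tab = {}
    tab["LL_CC_br"] = pd.Series({y: ll.loc[y, "breeding"] for y in years})
    tab["SOIyr"] = pd.Series(
        {y: (soi.loc[y, "nonbreeding"] + soi.loc[y - 1, "breeding"]) / 2
         for y in years})
    tab["SST_CC_2yr"] = pd.Series(
        {y: np.mean([sst.loc[y, "breeding"], sst.loc[y, "nonbreeding"],
                     sst.loc[y - 1, "breeding"], sst.loc[y - 1, "nonbreeding"]])
         for y in years})
    out = {}
    for name, vals in tab.items():
        z, _, _ = standardize(vals)
        out[name] = z
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# capture histories

def _true_phi(config: SimulationConfig,
              covariates: pd.DataFrame | None) -> np.ndarray:
    k = config.design.n_occasions
    if config.phi_override is not None:
        phi = np.atleast_1d(np.asarray(config.phi_override, dtype=float))
        if phi.size == 1:
            phi = np.full(k - 1, phi[0])
        if phi.size != k - 1:
            raise ValueError(f"phi_override needs {k - 1} interval values")
        return phi
    eta = np.full(k - 1, config.survival_intercept)
    if covariates is not None:
        slopes = dict(config.survival_slopes)
        for name, slope in slopes.items():
            if name not in covariates.columns:
                raise KeyError(f"covariate table lacks {name!r}")
            vals = covariates[name]
            z = (vals - vals.mean()) / vals.std(ddof=1)
            for t, y in enumerate(config.design.occasions[:-1]):
                eta[t] += slope * float(z.loc[y])
    return special.expit(eta)


def simulate_histories(config: SimulationConfig,
                       covariates: pd.DataFrame | None = None,
                       seed: int | None = None) -> SimulatedDataset:
    """Simulate encounter histories under the generative CJS model.

    Each individual recruits (is marked) at an active occasion of its
    panel, drawn from a geometric-decay schedule favouring the panel's
    first years.  With probability ``transient_fraction`` it emigrates
    permanently right after marking; residents survive each interval
    with the true Φ_t and are detected at active occasions with
    probability ``expit(capture_logit + trap_delta·[captured at the
    previous active occasion])``.
    """
    rng = np.random.default_rng(seed)
    design = config.design
    k = design.n_occasions
    active = design.active_mask()
    phi = _true_phi(config, covariates)

    split = np.asarray(config.panel_split, dtype=float)
    n_panel = np.floor(split / split.sum() * config.n_individuals).astype(int)
    n_panel[0] += config.n_individuals - n_panel.sum()

    panels, entries = [], []
    for g, npan in enumerate(n_panel):
        occ = design.panel_occasions(design.panel_names[g])
        w = np.exp(-config.recruitment_decay * np.arange(occ.size))
        w /= w.sum()
        panels.append(np.full(npan, g))
        entries.append(rng.choice(occ, size=npan, p=w))
    panel = np.concatenate(panels)
    entry = np.concatenate(entries)
    n = config.n_individuals

    sex = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    transient = rng.random(n) < config.transient_fraction
    p1 = special.expit(config.capture_logit + config.trap_delta)
    p2 = special.expit(config.capture_logit)

    det = np.zeros((n, k), dtype=np.int8)
    alive = np.zeros(n, dtype=bool)
    prev_det = np.zeros(n, dtype=bool)  # detected at previous active occasion
    for t in range(k):
        newly = entry == t
        alive |= newly
        det[newly, t] = 1
        is_active = active[panel, t]
        cand = alive & is_active & ~newly & (entry < t)
        if cand.any():
            p = np.where(prev_det[cand], p1, p2)
            det[cand, t] = rng.random(cand.sum()) < p
        upd = is_active & (entry <= t)
        prev_det[upd] = det[upd, t] == 1
        if t < k - 1:
            surv_p = np.where(transient & (entry <= t), 0.0, phi[t])
            survive = rng.random(n) < surv_p
            alive &= np.where(entry <= t, survive, True)

    histories = [
        EncounterHistory(f"sim{i:06d}", sex[i],
                         design.panel_names[panel[i]], det[i])
        for i in range(n)
    ]
    return SimulatedDataset(
        histories=histories, phi_true=phi,
        p_base=float(p2), trap_delta=config.trap_delta,
        covariates=covariates, config=config, seed=seed,
    )


def simulate_cjs(n: int, n_occasions: int, phi: float, p: float,
                 tau: float = 0.0, delta: float = 0.0,
                 seed: int | None = None,
                 recruitment_decay: float = 0.0) -> SimulatedDataset:
    """Small-scale convenience wrapper: a gap-free single-panel design
    with constant survival ``phi`` and base capture probability ``p``."""
    design = simple_design(n_occasions)
    config = SimulationConfig(
        design=design, n_individuals=n, panel_split=(1.0,),
        capture_logit=float(special.logit(p)), trap_delta=delta,
        transient_fraction=tau, recruitment_decay=recruitment_decay,
        phi_override=(float(phi),),
    )
    return simulate_histories(config, covariates=None, seed=seed)
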