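"""Overdispersion-corrected model selection and covariate testing.

Ranks fitted CJS models by QAICc — deviance over the variance-inflation
factor c-hat plus a parameter penalty, optionally with the small-sample
correction — and tests covariate effects by analysis of deviance
(ANODEV), locating each covariate model between a constant and a fully
time-dependent reference model.  The companion deviance R² measures the
share of temporal deviance variation a covariate explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["qaicc", "delta_qaicc", "anodev", "r_squared",
           "AnodevResult", "SelectionTable", "build_selection_table"]


def qaicc(dev: float, n_params: int, c_hat: float,
          ess: float | None = None, small_sample: bool = False) -> float:
    """Quasi-likelihood AIC: DEV/ĉ + 2·np, plus 2·np(np+1)/(ess−np−1)
    when the small-sample term is requested (ess = effective sample
    size, the total number of releases)."""
    if c_hat <= 0:
        raise ValueError("c_hat must be positive")
    value = dev / c_hat + 2.0 * n_params
    if small_sample:
        if ess is None:
            raise ValueError("small-sample correction needs ess")
        if ess <= n_params + 1:
            raise ValueError(
                f"ess={ess} must exceed np+1={n_params + 1} for the "
                "small-sample correction")
        value += 2.0 * n_params * (n_params + 1) / (ess - n_params - 1)
    return float(value)


def delta_qaicc(table: pd.DataFrame, column: str = "qaicc") -> pd.DataFrame:
    """Add ΔQAICc (difference from the best model) and a ``preferred``
    flag marking models within 2 units of the best."""
    out = table.copy()
    out["delta_qaicc"] = out[column] - out[column].min()
    out["preferred"] = out["delta_qaicc"] <= 2.0
    return out


@dataclass
class AnodevResult:
    F: float
    p: float
    df1: int
    df2: int
    flagged: bool = False
    note: str = ""


def anodev(dev_cst: float, dev_cov: float, dev_t: float,
           n_cov: int, n: int) -> AnodevResult:
    """Analysis-of-deviance F-test of a covariate model.

    F = [(DEV(Mcst) − DEV(Mcov))/n_cov] / [(DEV(Mcov) − DEV(Mt))/(n − n_cov − 1)]
    on (n_cov, n − n_cov − 1) degrees of freedom, where n is the number
    of time-varying survival parameters of the reference time-dependent
    model.  Deviance inversions and a saturating covariate are flagged
    rather than raised.
    """
    if n_cov < 1:
        raise ValueError("n_cov must be >= 1")
    if n <= n_cov + 1:
        raise ValueError(f"n={n} must exceed n_cov+1={n_cov + 1}")
    df1, df2 = n_cov, n - n_cov - 1
    flagged = not (dev_t <= dev_cov <= dev_cst)
    num = (dev_cst - dev_cov) / df1
    den = (dev_cov - dev_t) / df2
    if den <= 0:
        return AnodevResult(np.inf, 0.0, df1, df2, flagged=True,
                            note="covariate saturates the time variation")
    F = num / den
    p = float(stats.f.sf(F, df1, df2))
    note = "deviance ordering violated" if flagged else ""
    return AnodevResult(float(F), p, df1, df2, flagged=flagged, note=note)


def r_squared(dev_cst: float, dev_cov: float, dev_t: float) -> float:
    """Deviance R²: (DEV(Mcst) − DEV(Mcov)) / (DEV(Mcst) − DEV(Mt)),
    the fraction of temporal deviance variation explained by the
    covariate(s)."""
    denom = dev_cst - dev_t
    if denom <= 0:
        raise ValueError("constant and time-dependent deviances coincide; "
                         "no time variation to explain")
    return float((dev_cst - dev_cov) / denom)


@dataclass
class SelectionTable:
    """A ranked model table with the c-hat and ess that built it."""

    table: pd.DataFrame
    c_hat: float
    ess: float | None = None
    small_sample: bool = False

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        cols = [c for c in ("model_id", "label", "np", "dev", "qaicc",
                            "delta_qaicc", "anodev_F", "anodev_p", "r2",
                            "mcst") if c in self.table.columns]
        return self.table[cols].to_string(index=False,
                                          float_format=lambda v: f"{v:.3f}")


def build_selection_table(models: list[dict], c_hat: float,
                          ess: float | None = None,
                          small_sample: bool = False,
                          mcst: dict | None = None,
                          dev_t: float | None = None,
                          n_t: int | None = None) -> SelectionTable:
    """Assemble a ranked selection table from fitted-model summaries.

    Each entry of ``models`` needs keys ``model_id``, ``label``, ``np``,
    ``dev``, and optionally ``n_cov``.  ``mcst`` maps a covariate
    model's id to the id of its constant reference; models listed there
    get ANODEV F/p (against the time-dependent deviance ``dev_t`` with
    ``n_t`` time parameters) and the deviance R².
    """
    rows = []
    by_id = {m["model_id"]: m for m in models}
    for m in models:
        row = {"model_id": m["model_id"], "label": m.get("label", ""),
               "np": m["np"], "dev": m["dev"],
               "qaicc": qaicc(m["dev"], m["np"], c_hat,
                              ess=ess, small_sample=small_sample)}
        if mcst and m["model_id"] in mcst:
            if dev_t is None or n_t is None:
                raise ValueError("ANODEV requires dev_t and n_t")
            ref = by_id[mcst[m["model_id"]]]
            n_cov = m.get("n_cov", 1)
            res = anodev(ref["dev"], m["dev"], dev_t, n_cov, n_t)
            row.update({"mcst": ref["model_id"], "anodev_F": res.F,
                        "anodev_p": res.p,
                        "r2": r_squared(ref["dev"], m["dev"], dev_t)})
        rows.append(row)
    df = delta_qaicc(pd.DataFrame(rows))
    return SelectionTable(df, c_hat=c_hat, ess=ess, small_sample=small_sample)
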