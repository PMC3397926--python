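"""Cormack-Jolly-Seber likelihood engine.

Builds design matrices for survival (Φ) and capture (p) on the logit
scale, and maximizes the CJS likelihood conditional on first capture.
Model structure covers time and sex factors, Markovian trap-dependence
states on capture (m1 = captured at the previous occasion, m2 = not),
environmental covariates with linear/quadratic forms and single or
period-split slopes, and fixed-zero capture masks for monitoring gaps
and panel structure.

The likelihood is computed from sufficient counts aggregated over
individuals.  Conditional on first release, each observed segment
contributes survival and (re)capture factors, and the tail after the
last capture contributes the never-seen-again recursion
``χ_t = (1 − Φ_t) + Φ_t (1 − p_{t+1}) χ_{t+1}`` with p forced to zero
wherever capture is impossible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import optimize, special

from .design import StudyDesign
from .encounter import EncounterHistory, MArray

__all__ = [
    "CovariateTerm",
    "ModelSpec",
    "parse_spec",
    "CJSData",
    "DesignData",
    "FitResult",
    "build_design",
    "neg_log_likelihood",
    "fit",
    "predict_survival",
    "marray_neg_log_likelihood",
]


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class CovariateTerm:
    """A covariate entering the survival linear predictor.

    ``form`` is "linear" or "quadratic" (quadratic always includes the
    linear term); ``split`` fits one slope per monitoring period instead
    of a single slope over the whole span.
    """

    name: str
    form: str = "linear"
    split: bool = False

    def __post_init__(self) -> None:
        if self.form not in ("linear", "quadratic"):
            raise ValueError(f"unknown covariate form {self.form!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative survival/capture structure of one CJS model."""

    phi_time: bool = False
    phi_sex: bool = False
    phi_sex_by_time: bool = False
    phi_covariates: tuple[CovariateTerm, ...] = ()
    p_time: bool = False
    p_sex: bool = False
    p_trap: bool = False
    p_interaction: bool = False  # full interaction among included p factors

    @property
    def label(self) -> str:
        phi_parts = []
        if self.phi_sex_by_time:
            phi_parts.append("sex*t")
        else:
            if self.phi_sex:
                phi_parts.append("sex")
            if self.phi_time:
                phi_parts.append("t")
        for ct in self.phi_covariates:
            s = ct.name
            if ct.form == "quadratic":
                s = f"[{s}]^2"
            if ct.split:
                s += "_split"
            phi_parts.append(s)
        p_factors = [f for f, on in (("m", self.p_trap), ("sex", self.p_sex),
                                     ("t", self.p_time)) if on]
        sep = "*" if self.p_interaction else "+"
        return (f"phi({'+'.join(phi_parts) or '.'}) "
                f"p({sep.join(p_factors) or '.'})")

    @classmethod
    def constant(cls) -> "ModelSpec":
        return cls()


def parse_spec(phi: str, p: str) -> ModelSpec:
    """Build a ModelSpec from shorthand strings.

    ``phi``: "." (constant), "t", "sex", "sex+t", "sex*t", or a
    '+'-joined list of covariate names; a covariate token may carry the
    suffix "^2" (quadratic) or ":split" (one slope per period).
    ``p``: factors among {m, sex, t} joined by "+" (additive) or "*"
    (full interaction), or ".".
    """
    phi = phi.strip()
    kw: dict = {"phi_covariates": []}
    if phi not in (".", ""):
        if phi.replace(" ", "") == "sex*t":
            kw["phi_sex_by_time"] = True
        else:
            for tok in (t.strip() for t in phi.split("+")):
                if tok == "t":
                    kw["phi_time"] = True
                elif tok == "sex":
                    kw["phi_sex"] = True
                else:
                    split = tok.endswith(":split")
                    if split:
                        tok = tok[: -len(":split")]
                    form = "quadratic" if tok.endswith("^2") else "linear"
                    if form == "quadratic":
                        tok = tok[:-2]
                    kw["phi_covariates"].append(
                        CovariateTerm(tok, form=form, split=split))
    kw["phi_covariates"] = tuple(kw["phi_covariates"])
    p = p.strip()
    if p not in (".", ""):
        sep = "*" if "*" in p else "+"
        kw["p_interaction"] = sep == "*"
        for tok in (t.strip() for t in p.split(sep)):
            if tok == "m":
                kw["p_trap"] = True
            elif tok == "sex":
                kw["p_sex"] = True
            elif tok == "t":
                kw["p_time"] = True
            else:
                raise ValueError(f"unknown capture factor {tok!r}")
    return ModelSpec(**kw)


# ---------------------------------------------------------------------------
# sufficient counts

@dataclass
class CJSData:
    """Aggregated sufficient counts for the conditional CJS likelihood.

    ``S[t, s]`` — survival-interval exposures (individuals known alive
    over interval t); ``C/N[t, s, m, g]`` — detections / in-span
    non-detections at occasion t by sex s, trap state m (0 = m1,
    1 = m2), panel g; ``last[t, s, g]`` — last captures at t (each
    contributes one χ factor).
    """

    design: StudyDesign
    sexes: tuple[str, ...]
    S: np.ndarray
    C: np.ndarray
    N: np.ndarray
    last: np.ndarray
    n_histories: int
    ess: int  # total number of releases (effective sample size)

    @classmethod
    def from_histories(cls, histories: list[EncounterHistory],
                       design: StudyDesign,
                       include_unknown_sex: bool = False) -> "CJSData":
        kept = [h for h in histories
                if include_unknown_sex or h.sex != "unknown"]
        if not kept:
            raise ValueError("no histories (after excluding unknown sex)")
        sexes = tuple(sorted({h.sex for h in kept}))
        sex_idx = {s: i for i, s in enumerate(sexes)}
        pan_idx = {p: i for i, p in enumerate(design.panel_names)}
        k = design.n_occasions
        ns, ng = len(sexes), len(design.panels)
        active = design.active_mask()
        # previous active occasion per (panel, occasion)
        prev_active = np.full((ng, k), -1, dtype=int)
        for g in range(ng):
            lastp = -1
            for j in range(k):
                prev_active[g, j] = lastp
                if active[g, j]:
                    lastp = j

        patterns: Counter = Counter()
        for h in kept:
            patterns[(h.sex, h.panel, h.detections.tobytes())] += 1

        S = np.zeros((k - 1, ns))
        C = np.zeros((k, ns, 2, ng))
        N = np.zeros((k, ns, 2, ng))
        last = np.zeros((k, ns, ng))
        ess = 0
        for (sex, panel, blob), w in patterns.items():
            d = np.frombuffer(blob, dtype=np.int8)
            s = sex_idx[sex]
            g = pan_idx[panel]
            nz = np.flatnonzero(d)
            f, L = int(nz[0]), int(nz[-1])
            S[f:L, s] += w
            for t in range(f + 1, L + 1):
                pa = prev_active[g, t]
                m = 0 if (pa >= 0 and d[pa]) else 1
                if d[t]:
                    C[t, s, m, g] += w
                else:
                    N[t, s, m, g] += w
            if L < k - 1:
                last[L, s, g] += w
            ess += w * int((nz < k - 1).sum())
        return cls(design, sexes, S, C, N, last, len(kept), ess)


# ---------------------------------------------------------------------------
# design matrices

def _informative_intervals(design: StudyDesign) -> np.ndarray:
    """Boolean per interval: some panel can observe both endpoints."""
    k = design.n_occasions
    info = np.zeros(k - 1, dtype=bool)
    for p in design.panel_names:
        occ = design.panel_occasions(p)
        if occ.size >= 2:
            info[occ.min():occ.max()] = True
    return info


@dataclass
class DesignData:
    """Design matrices plus the bookkeeping to map parameters to the
    per-occasion Φ and p tables."""

    spec: ModelSpec
    design: StudyDesign
    sexes: tuple[str, ...]
    X_phi: np.ndarray
    X_p: np.ndarray
    phi_names: tuple[str, ...]
    p_names: tuple[str, ...]
    active: np.ndarray                 # (n_panels, K) capture possible
    informative: np.ndarray            # (K-1,) interval carries data
    covariate_values: pd.DataFrame | None = None
    covariate_scaling: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.X_phi.shape[1] + self.X_p.shape[1]

    def tables(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Real-scale Φ (K-1, n_sex) and p (K, n_sex, 2) tables from the
        stacked parameter vector (p row 0 is never referenced)."""
        q1 = self.X_phi.shape[1]
        ns = len(self.sexes)
        k = self.design.n_occasions
        eta_phi = self.X_phi @ params[:q1]
        eta_p = self.X_p @ params[q1:]
        phi = special.expit(eta_phi).reshape(k - 1, ns)
        p = np.zeros((k, ns, 2))
        p[1:] = special.expit(eta_p).reshape(k - 1, ns, 2)
        return phi, p


def build_design(spec: ModelSpec, design: StudyDesign,
                 covariates: pd.DataFrame | None = None,
                 sexes: tuple[str, ...] = ("female", "male"),
                 coding: str = "Treatment") -> DesignData:
    """Build logit-scale design matrices for a model specification.

    Φ rows run over (interval × sex), p rows over (recapture occasion ×
    sex × trap state), both in row-major order.  Identifiability is
    handled by corner-point (treatment) coding; ``coding="Sum"`` gives
    the sum-to-zero reparameterization (same model space).  Covariates
    are looked up by interval start year and z-standardized over the
    informative intervals.  Intervals with no possible data (inside a
    monitoring gap between disjoint panels) share one pooled time level.
    """
    k = design.n_occasions
    years = design.occasions
    ns = len(sexes)
    informative = _informative_intervals(design)
    if len(design.panels) >= 2:
        p1_end = design.panels[0].end
    else:
        p1_end = None

    # ---- Φ rows
    rows = []
    for t in range(k - 1):
        tlab = str(years[t]) if informative[t] else "gap"
        period = "p1" if (p1_end is None or years[t] <= p1_end) else "p2"
        for s in sexes:
            rows.append({"tlab": tlab, "sex": s, "period": period,
                         "year": years[t]})
    phi_df = pd.DataFrame(rows)
    phi_df["tlab"] = pd.Categorical(phi_df["tlab"],
                                    categories=_unique(phi_df["tlab"]))
    phi_df["sex"] = pd.Categorical(phi_df["sex"], categories=list(sexes))
    phi_df["period"] = pd.Categorical(phi_df["period"],
                                      categories=_unique(phi_df["period"]))

    scaling = {}
    terms = []
    if spec.phi_sex_by_time and ns > 1:
        terms.append(f"C(sex, {coding}) * C(tlab, {coding})")
    else:
        if spec.phi_sex and ns > 1:
            terms.append(f"C(sex, {coding})")
        if spec.phi_time or spec.phi_sex_by_time:
            terms.append(f"C(tlab, {coding})")
    for ct in spec.phi_covariates:
        if covariates is None or ct.name not in covariates.columns:
            raise KeyError(f"unknown covariate {ct.name!r}")
        vals = covariates[ct.name]
        yy = [y for t, y in enumerate(years[:-1]) if informative[t]]
        missing = [y for y in yy if y not in vals.index or pd.isna(vals.get(y))]
        if missing:
            raise ValueError(f"covariate {ct.name!r} missing years {missing}")
        mu = float(vals.loc[yy].mean())
        sd = float(vals.loc[yy].std(ddof=1))
        if sd == 0:
            raise ValueError(f"covariate {ct.name!r} is constant")
        scaling[ct.name] = (mu, sd)
        z = [(float(vals.get(y, mu)) - mu) / sd for y in phi_df["year"]]
        col = f"z_{_safe(ct.name)}"
        phi_df[col] = z
        if ct.split:
            if p1_end is None:
                raise ValueError(
                    f"split-slope for {ct.name!r} requested but the design "
                    "has no period structure (single panel)")
            terms.append(f"C(period):{col}")
        else:
            terms.append(col)
        if ct.form == "quadratic":
            if ct.split:
                terms.append(f"C(period):I({col} ** 2)")
            else:
                terms.append(f"I({col} ** 2)")
    X_phi = dmatrix(" + ".join(["1"] + terms), phi_df, return_type="dataframe")

    # ---- p rows
    active = design.active_mask()
    any_active = active.any(axis=0)
    base_lab = next(str(years[o]) for o in range(1, k) if any_active[o])
    rows = []
    for o in range(1, k):
        tlab = str(years[o]) if any_active[o] else base_lab
        for s in sexes:
            for m in ("m1", "m2"):
                rows.append({"tlab": tlab, "sex": s, "m": m})
    p_df = pd.DataFrame(rows)
    p_df["tlab"] = pd.Categorical(p_df["tlab"], categories=_unique(p_df["tlab"]))
    p_df["sex"] = pd.Categorical(p_df["sex"], categories=list(sexes))
    p_df["m"] = pd.Categorical(p_df["m"], categories=["m1", "m2"])

    factors = []
    if spec.p_trap:
        factors.append(f"C(m, {coding})")
    if spec.p_sex and ns > 1:
        factors.append(f"C(sex, {coding})")
    if spec.p_time:
        factors.append(f"C(tlab, {coding})")
    sep = " * " if spec.p_interaction else " + "
    X_p = dmatrix(" + ".join(["1"] + ([sep.join(factors)] if factors else [])),
                  p_df, return_type="dataframe")

    return DesignData(
        spec=spec, design=design, sexes=tuple(sexes),
        X_phi=np.asarray(X_phi, dtype=float), X_p=np.asarray(X_p, dtype=float),
        phi_names=tuple(X_phi.columns), p_names=tuple(X_p.columns),
        active=active, informative=informative,
        covariate_values=covariates, covariate_scaling=scaling,
    )


def _unique(seq):
    seen, out = set(), []
    for x in seq:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)


# ---------------------------------------------------------------------------
# likelihood

def _chi_table(phi: np.ndarray, p: np.ndarray, active: np.ndarray) -> np.ndarray:
    """χ[t, s, g] = P(never detected after t | alive and captured at t).

    The capture at t puts the animal in trap state m1 at the next
    *active* occasion it could be seen; every later occasion is m2.
    Occasions where capture is impossible contribute a factor of one.
    """
    k1, ns = phi.shape
    k = k1 + 1
    ng = active.shape[0]
    chi = np.ones((k, ns, ng))
    # base recursion: all-m2 states, per panel
    B = np.ones((k, ns, ng))
    for t in range(k - 2, -1, -1):
        pe = p[t + 1, :, 1][:, None] * active[:, t + 1][None, :]
        B[t] = (1.0 - phi[t])[:, None] + phi[t][:, None] * (1.0 - pe) * B[t + 1]
    next_active = np.full((ng, k), -1, dtype=int)
    for g in range(ng):
        na = -1
        for j in range(k - 1, -1, -1):
            next_active[g, j] = na
            if active[g, j]:
                na = j
    for g in range(ng):
        for L in range(k - 1):
            u = next_active[g, L]
            if u < 0:
                chi[L, :, g] = 1.0
                continue
            pe1 = p[u, :, 0]  # m1 state at the first active occasion after L
            v = (1.0 - phi[u - 1]) + phi[u - 1] * (1.0 - pe1) * B[u, :, g]
            for t in range(u - 2, L - 1, -1):
                v = (1.0 - phi[t]) + phi[t] * v
            chi[L, :, g] = v
    return chi


def neg_log_likelihood(params: np.ndarray, dd: DesignData, data: CJSData,
                       scaled: bool = False) -> float:
    """Negative conditional log-likelihood at a parameter point.

    ``scaled=True`` divides by the number of histories (useful for
    optimizer tolerances); the deviance convention is
    DEV = 2 × (unscaled) value.
    """
    params = np.asarray(params, dtype=float)
    if not np.isfinite(params).all():
        raise ValueError("non-finite parameters")
    if params.size != dd.n_params:
        raise ValueError(f"expected {dd.n_params} parameters, got {params.size}")
    phi, p = dd.tables(params)
    active = dd.active.astype(float)
    # p_eff[t, s, m, g]
    p_eff = p[:, :, :, None] * active.T[:, None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(data.S * np.log(phi)))
        lp = np.where(data.C > 0, np.log(np.maximum(p_eff, 1e-300)), 0.0)
        ll += float(np.sum(data.C * lp))
        lq = np.where(data.N > 0, np.log(np.maximum(1.0 - p_eff, 1e-300)), 0.0)
        ll += float(np.sum(data.N * lq))
        chi = _chi_table(phi, p, dd.active)
        lc = np.where(data.last > 0, np.log(np.maximum(chi, 1e-300)), 0.0)
        ll += float(np.sum(data.last * lc))
    if not np.isfinite(ll):
        return np.inf
    nll = -ll
    return nll / data.n_histories if scaled else nll


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    """A maximized CJS model: coefficients, deviance, parameter count."""

    spec: ModelSpec
    dd: DesignData
    estimates: np.ndarray
    se: np.ndarray
    param_names: tuple[str, ...]
    deviance: float
    np_estimated: int
    converged: bool
    gradient_norm: float
    vcov: np.ndarray
    n_histories: int
    ess: int
    inestimable_intervals: np.ndarray  # bool per interval (no data support)

    @property
    def phi_se_tables(self):
        return _real_scale(self.dd.X_phi, self.estimates[: self.dd.X_phi.shape[1]],
                           self.vcov[: self.dd.X_phi.shape[1],
                                     : self.dd.X_phi.shape[1]])

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.estimates, "se": self.se},
                            index=list(self.param_names))


def _real_scale(X, beta, vcov):
    eta = X @ beta
    var = np.einsum("ij,jk,ik->i", X, vcov, X)
    se_eta = np.sqrt(np.maximum(var, 0.0))
    prob = special.expit(eta)
    se = prob * (1 - prob) * se_eta  # delta method
    lo = special.expit(eta - 1.96 * se_eta)
    hi = special.expit(eta + 1.96 * se_eta)
    return prob, se, lo, hi


def _fd_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    q = x.size
    H = np.empty((q, q))
    hs = h * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(q):
        ei = np.zeros(q)
        ei[i] = hs[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / hs[i] ** 2
        for j in range(i + 1, q):
            ej = np.zeros(q)
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


def fit(spec: ModelSpec, data: CJSData, design: StudyDesign | None = None,
        covariates: pd.DataFrame | None = None, n_starts: int = 5,
        seed: int | None = None, dd: DesignData | None = None,
        compute_np: bool = True, maxiter: int = 1000) -> FitResult:
    """Maximize the CJS likelihood by quasi-Newton from multiple starts.

    The number of estimable parameters is the numerical rank of the
    Hessian at the optimum (tolerance 1e-6 × largest eigenvalue), which
    discounts confounded terms such as the terminal Φ·p product of
    fully time-dependent models.  Non-convergence is flagged, never
    raised.
    """
    if dd is None:
        if design is None:
            design = data.design
        dd = build_design(spec, design, covariates=covariates, sexes=data.sexes)
    rng = np.random.default_rng(seed)
    obj = lambda x: neg_log_likelihood(x, dd, data, scaled=True)
    best = None
    for start in range(max(1, n_starts)):
        x0 = np.zeros(dd.n_params)
        if start > 0:
            x0 += rng.normal(scale=0.5, size=dd.n_params)
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 10 ** 6,
                     "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    gnorm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    converged = bool(best.success or gnorm < 1e-4)
    n = data.n_histories
    deviance = 2.0 * best.fun * n

    H = _fd_hessian(obj, best.x)
    H = (H + H.T) / 2
    eig = np.linalg.eigvalsh(H)
    tol = max(1e-6 * eig.max(), 1e-9) if eig.max() > 0 else 1e-9
    np_est = int((eig > tol).sum()) if compute_np else dd.n_params
    vcov = np.linalg.pinv(H * n, rcond=1e-10)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))

    exposure = data.S.sum(axis=1)
    inestimable = exposure == 0

    return FitResult(
        spec=spec, dd=dd, estimates=best.x, se=se,
        param_names=dd.phi_names + dd.p_names,
        deviance=float(deviance), np_estimated=np_est,
        converged=converged, gradient_norm=gnorm, vcov=vcov,
        n_histories=n, ess=data.ess, inestimable_intervals=inestimable,
    )


def predict_survival(result: FitResult) -> pd.DataFrame:
    """Year-indexed annual survival with delta-method CIs.

    Rows for intervals without data support (the monitoring gap between
    disjoint panels) are flagged ``estimable=False``; in covariate
    models their point prediction still follows the linear predictor.
    """
    dd = result.dd
    k = dd.design.n_occasions
    ns = len(dd.sexes)
    prob, se, lo, hi = result.phi_se_tables
    rows = []
    has_cov = bool(dd.spec.phi_covariates)
    for t in range(k - 1):
        for si, s in enumerate(dd.sexes):
            i = t * ns + si
            estimable = not result.inestimable_intervals[t] or has_cov
            rows.append({
                "year": dd.design.occasions[t], "sex": s,
                "phi": prob[i], "se": se[i], "lo": lo[i], "hi": hi[i],
                "estimable": estimable,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# m-array likelihood (independent route, no trap/sex/covariate structure)

def marray_neg_log_likelihood(phi: np.ndarray, p: np.ndarray,
                              marr: MArray) -> float:
    """Negative multinomial log-likelihood of a reduced m-array.

    ``phi[t]`` is survival over interval t (t = 0..K-2); ``p[j]`` is
    capture probability at occasion j (entry 0 unused).  Serves as an
    independent implementation route for cross-checking the
    history-based likelihood on models without trap dependence.
    """
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    k = len(marr.occasions)
    ll = 0.0
    for i in range(k - 1):
        if marr.releases[i] == 0:
            continue
        cell = np.zeros(k)
        for j in range(i + 1, k):
            pr = 1.0
            for t in range(i, j):
                pr *= phi[t]
                pr *= (1.0 - p[t + 1]) if t + 1 < j else p[j]
            cell[j] = pr
        pr_never = 1.0 - cell.sum()
        for j in range(i + 1, k):
            if marr.m[i, j] > 0:
                ll += marr.m[i, j] * np.log(cell[j])
        ns = marr.never_seen[i]
        if ns > 0:
            ll += ns * np.log(pr_never)
    return -float(ll)
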