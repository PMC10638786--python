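"""Univariate twin variance decomposition by full-information ML.

Methylation at a CpG measured on MZ and DZ cotwins is modelled as bivariate
normal per pair with a common mean structure (intercept plus optional age
and sex regressors) and covariance

    var = a^2 + c^2 + d^2 + e^2
    cov_MZ = a^2 + c^2 + d^2          cov_DZ = a^2/2 + c^2 + d^2/4

where a, c, d, e are nonnegative path coefficients for additive genetic,
shared-environment, dominance and unique-environment influences. C and D are
never fitted together (a classical twin design cannot separate them). The
model menu is ACE, ADE, AE, CE, DE, E; model selection accepts nested
reductions whose likelihood-ratio test against the relevant full model is
non-significant and prefers parsimony, arbitrating the ACE vs ADE families
by AIC. Incomplete pairs contribute univariate likelihood terms.

Standardized components (a2 = a^2 / var, ...) are reported, with optional
profile-likelihood 95% confidence intervals; profile bounds that cannot be
bracketed (parameter at its boundary) are reported as undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MODELS", "VarianceComponents", "simulate_twin_pairs",
    "twin_correlations", "fit_twin_model", "select_best_model",
    "check_candidate",
]

MODELS = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "DE": ("d", "e"),
    "E": ("e",),
}

_COV_WEIGHT_MZ = {"a": 1.0, "c": 1.0, "d": 1.0, "e": 0.0}
_COV_WEIGHT_DZ = {"a": 0.5, "c": 1.0, "d": 0.25, "e": 0.0}

_CHI2_95 = stats.chi2.ppf(0.95, 1)


@dataclass
class VarianceComponents:
    model: str
    a2: float
    c2: float
    d2: float
    e2: float
    total_variance: float
    mean_coefficients: dict
    loglik: float
    n_params: int
    r_mz: float
    r_dz: float
    ci: dict = field(default_factory=dict)   # component -> (lo, hi) | (None, None)
    converged: bool = True
    paths: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def h2(self) -> float:
        """Narrow-sense heritability (a2); report d2 separately for ADE."""
        return self.a2


def simulate_twin_pairs(n_mz: int, n_dz: int, r_mz: float, r_dz: float,
                        mean: float = 0.0, sd: float = 1.0,
                        seed: int = 0) -> pd.DataFrame:
    """Bivariate-normal twin pairs at the given intra-pair correlations."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7717]))
    out = []
    for n, r, zyg in ((n_mz, r_mz, "MZ"), (n_dz, r_dz, "DZ")):
        z1 = rng.standard_normal(n)
        z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
        out.append(pd.DataFrame({"y1": mean + sd * z1, "y2": mean + sd * z2,
                                 "zygosity": zyg}))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# data preparation and likelihood

def _mean_columns(pairs: pd.DataFrame) -> list[str]:
    cols = []
    if {"age1", "age2"} <= set(pairs.columns):
        cols.append("age")
    if {"sex1", "sex2"} <= set(pairs.columns):
        cols.append("sex")
    return cols


def _prepare(pairs: pd.DataFrame):
    """Split into complete MZ / complete DZ / singletons with mean regressors."""
    covs = _mean_columns(pairs)
    q = len(covs)

    def regressors(sub, member):
        z = np.empty((len(sub), q))
        for k, c in enumerate(covs):
            col = sub[f"{c}{member}"]
            if c == "sex":
                z[:, k] = (col.values == "F").astype(float)
            else:
                z[:, k] = col.values.astype(float)
        return z

    groups = {}
    complete = pairs[pairs.y1.notna() & pairs.y2.notna()]
    for zyg in ("MZ", "DZ"):
        sub = complete[complete.zygosity == zyg]
        groups[zyg] = (
            np.column_stack([sub.y1.values, sub.y2.values]),
            np.stack([regressors(sub, 1), regressors(sub, 2)], axis=1)
            if q else np.zeros((len(sub), 2, 0)),
        )
    singles = []
    for member, other in ((1, 2), (2, 1)):
        sub = pairs[pairs[f"y{member}"].notna() & pairs[f"y{other}"].isna()]
        if len(sub):
            singles.append((sub[f"y{member}"].values.astype(float),
                            regressors(sub, member)))
    return groups, singles, covs


def _negloglik(theta, groups, singles, paths, q):
    mu, beta = theta[0], theta[1:1 + q]
    path_vals = dict(zip(paths, theta[1 + q:]))
    comps = {k: path_vals.get(k, 0.0) ** 2 for k in ("a", "c", "d", "e")}
    var = sum(comps.values())
    if var <= 1e-300:
        return 1e12
    nll = 0.0
    for zyg, wts in (("MZ", _COV_WEIGHT_MZ), ("DZ", _COV_WEIGHT_DZ)):
        y, z = groups[zyg]
        if len(y) == 0:
            continue
        cov = sum(wts[k] * comps[k] for k in comps)
        det = var * var - cov * cov
        if det <= 1e-300:
            return 1e12
        m = mu + (z @ beta if q else 0.0)
        r = y - m
        quad = (var * (r[:, 0] ** 2 + r[:, 1] ** 2)
                - 2.0 * cov * r[:, 0] * r[:, 1]) / det
        nll += 0.5 * (len(y) * (2 * np.log(2 * np.pi) + np.log(det))
                      + quad.sum())
    for y, z in singles:
        m = mu + (z @ beta if q else 0.0)
        r = y - m
        nll += 0.5 * (len(y) * np.log(2 * np.pi * var) + (r ** 2).sum() / var)
    return nll


def twin_correlations(pairs: pd.DataFrame) -> tuple[float, float]:
    """Double-entry intraclass correlations per zygosity.

    Values are residualized on the available mean regressors (age, sex) by
    OLS before each pair contributes both orderings to a Pearson correlation.
    Returns NaN for a zygosity group with fewer than 2 complete pairs.
    """
    covs = _mean_columns(pairs)
    complete = pairs[pairs.y1.notna() & pairs.y2.notna()].copy()
    if covs:
        rows = []
        for member in (1, 2):
            d = {"y": complete[f"y{member}"].values}
            for c in covs:
                col = complete[f"{c}{member}"]
                d[c] = ((col.values == "F").astype(float) if c == "sex"
                        else col.values.astype(float))
            rows.append(pd.DataFrame(d))
        stacked = pd.concat(rows, ignore_index=True)
        X = np.column_stack([np.ones(len(stacked))]
                            + [stacked[c].values for c in covs])
        coef, *_ = np.linalg.lstsq(X, stacked.y.values, rcond=None)
        resid = stacked.y.values - X @ coef
        half = len(complete)
        complete = complete.assign(e1=resid[:half], e2=resid[half:])
    else:
        complete = complete.assign(e1=complete.y1, e2=complete.y2)
    out = []
    for zyg in ("MZ", "DZ"):
        sub = complete[complete.zygosity == zyg]
        if len(sub) < 2:
            out.append(np.nan)
            continue
        x = np.concatenate([sub.e1.values, sub.e2.values])
        y = np.concatenate([sub.e2.values, sub.e1.values])
        out.append(float(np.corrcoef(x, y)[0, 1]))
    return out[0], out[1]


def _starts(pairs: pd.DataFrame, paths, q, n_starts):
    y_all = np.concatenate([pairs.y1.dropna().values, pairs.y2.dropna().values])
    mu0, sd0 = float(np.mean(y_all)), float(np.std(y_all) + 1e-12)
    r_mz, r_dz = twin_correlations(pairs)
    r_mz = 0.5 if not np.isfinite(r_mz) else np.clip(r_mz, -0.9, 0.99)
    r_dz = 0.25 if not np.isfinite(r_dz) else np.clip(r_dz, -0.9, 0.99)
    a2 = float(np.clip(2 * (r_mz - r_dz), 0.02, 0.95))
    c2 = float(np.clip(2 * r_dz - r_mz, 0.02, 0.95))
    base = {"a": a2, "c": c2, "d": a2 / 2, "e": max(0.02, 1 - a2 - c2)}
    tot = sum(base[k] for k in paths)
    start0 = [mu0] + [0.0] * q + [sd0 * np.sqrt(base[k] / tot) for k in paths]
    starts = [np.array(start0)]
    rng = np.random.default_rng(12345)
    while len(starts) < n_starts:
        frac = rng.dirichlet(np.ones(len(paths)))
        starts.append(np.array([mu0] + [0.0] * q
                               + list(sd0 * np.sqrt(frac))))
    return starts, sd0


def fit_twin_model(pairs: pd.DataFrame, model: str = "ACE",
                   n_starts: int = 4, compute_ci: bool = False
                   ) -> VarianceComponents:
    """Fit one variance-component model by FIML with multi-start optimization."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {sorted(MODELS)}, got {model!r}")
    paths = MODELS[model]
    groups, singles, covs = _prepare(pairs)
    q = len(covs)
    n_complete = sum(len(groups[z][0]) for z in groups)
    if n_complete < 2:
        raise ValueError("need at least 2 complete pairs")
    starts, sd0 = _starts(pairs, paths, q, n_starts)
    bounds = ([(None, None)] * (1 + q)
              + [(0.0, 20.0 * sd0) for _ in paths])
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _negloglik, x0, args=(groups, singles, paths, q),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success or best.fun < 1e11)
    theta = best.x
    path_vals = dict(zip(paths, np.abs(theta[1 + q:])))
    comps = {k: path_vals.get(k, 0.0) ** 2 for k in ("a", "c", "d", "e")}
    var = sum(comps.values())
    std = {k: v / var for k, v in comps.items()}
    r_mz, r_dz = twin_correlations(pairs)
    mean_coefs = {"intercept": float(theta[0])}
    for k, c in enumerate(covs):
        mean_coefs[c] = float(theta[1 + k])
    vc = VarianceComponents(
        model=model, a2=std["a"], c2=std["c"], d2=std["d"], e2=std["e"],
        total_variance=float(var), mean_coefficients=mean_coefs,
        loglik=float(-best.fun), n_params=1 + q + len(paths),
        r_mz=r_mz, r_dz=r_dz, converged=converged,
        paths={k: float(v) for k, v in path_vals.items()})
    if compute_ci:
        vc.ci = _profile_cis(vc, theta, groups, singles, paths, q, bounds)
    return vc


def _profile_cis(vc, theta_hat, groups, singles, paths, q, bounds):
    """Profile-likelihood 95% CIs for the standardized components."""
    ll_max = vc.loglik
    cis = {}
    for j, comp in enumerate(paths):
        idx = 1 + q + j
        mle = abs(theta_hat[idx])

        def profile_dev(val):
            x0 = theta_hat.copy()
            x0[idx] = val
            bnds = list(bounds)
            bnds[idx] = (val, val)
            res = optimize.minimize(
                _negloglik, x0, args=(groups, singles, paths, q),
                method="L-BFGS-B", bounds=bnds,
                options={"maxiter": 1000, "ftol": 1e-12})
            return 2.0 * (ll_max - (-res.fun)) - _CHI2_95, res.x

        def standardized(x):
            vals = dict(zip(paths, np.abs(x[1 + q:])))
            total = sum(v ** 2 for v in vals.values())
            return vals[comp] ** 2 / total

        lo = hi = None
        scale = max(mle, np.sqrt(vc.total_variance))
        try:
            f0, _ = profile_dev(max(mle * 1e-6, 0.0))
            if f0 > 0:
                r = optimize.brentq(lambda v: profile_dev(v)[0],
                                    max(mle * 1e-6, 1e-12), mle, xtol=1e-6)
                lo = standardized(profile_dev(r)[1])
            else:
                lo = 0.0
        except ValueError:
            lo = None
        try:
            upper = mle + 4.0 * scale + 1e-6
            f1, _ = profile_dev(upper)
            if f1 > 0:
                r = optimize.brentq(lambda v: profile_dev(v)[0],
                                    mle + 1e-12, upper, xtol=1e-6)
                hi = standardized(profile_dev(r)[1])
            else:
                hi = None
        except ValueError:
            hi = None
        cis[comp + "2"] = (lo, hi)
    return cis


def select_best_model(pairs: pd.DataFrame, n_starts: int = 4,
                      alpha: float = 0.05) -> VarianceComponents:
    """Fit all six models and pick the best-supported parsimonious one.

    Within each full-model family (ACE: {ACE, AE, CE, E}; ADE: {ADE, AE, DE,
    E}), a nested reduction is accepted when the likelihood-ratio test
    against the family's full model is non-significant at ``alpha``; the
    most parsimonious accepted model wins (loglik breaks ties at equal
    parameter count). The two family winners are arbitrated by AIC; ties go
    to fewer parameters, then to the ACE family.
    """
    fits = {}
    for m in MODELS:
        try:
            fits[m] = fit_twin_model(pairs, m, n_starts=n_starts)
        except Exception:          # noqa: BLE001 - flagged, not silent
            continue
    fits = {m: f for m, f in fits.items() if f.converged}
    if len(fits) < 2:
        raise RuntimeError("fewer than two twin models converged")
    families = {"ACE": ["ACE", "AE", "CE", "E"], "ADE": ["ADE", "AE", "DE", "E"]}
    winners = {}
    for fam, members in families.items():
        if fam not in fits:
            continue
        full = fits[fam]
        accepted = [full]
        for m in members[1:]:
            if m not in fits:
                continue
            sub = fits[m]
            lrt = 2.0 * (full.loglik - sub.loglik)
            df = full.n_params - sub.n_params
            p = stats.chi2.sf(max(lrt, 0.0), df)
            if p >= alpha:
                accepted.append(sub)
        winners[fam] = min(accepted,
                           key=lambda f: (f.n_params, -f.loglik))
    if not winners:
        raise RuntimeError("no full model (ACE/ADE) converged")
    order = ["ACE", "ADE"]
    return min(winners.values(),
               key=lambda f: (round(f.aic, 9), f.n_params,
                              order.index("ACE" if f.model in families["ACE"]
                                          else "ADE")))


# ---------------------------------------------------------------------------
# candidate eligibility: SD filter plus saturated-model assumption checks

def _saturated_negloglik(theta, data):
    """Saturated bivariate normal: free mean/SD per (zygosity, twin order),
    free correlation per zygosity. theta = 4 means, 4 log-SDs, 2 atanh-r."""
    mus, lsds, zr = theta[:4], theta[4:8], theta[8:]
    nll = 0.0
    for g, (y,) in enumerate(data):      # g: 0 = MZ, 1 = DZ
        if len(y) == 0:
            continue
        m1, m2 = mus[2 * g], mus[2 * g + 1]
        s1, s2 = np.exp(lsds[2 * g]), np.exp(lsds[2 * g + 1])
        r = np.tanh(zr[g])
        det = (s1 * s2) ** 2 * (1 - r ** 2)
        r1 = (y[:, 0] - m1) / s1
        r2 = (y[:, 1] - m2) / s2
        quad = (r1 ** 2 + r2 ** 2 - 2 * r * r1 * r2) / (1 - r ** 2)
        nll += 0.5 * (len(y) * (2 * np.log(2 * np.pi) + np.log(det))
                      + quad.sum())
    return nll


def _fit_saturated(pairs: pd.DataFrame, tie_means=None, tie_sds=None):
    """ML fit of the saturated pair model with optional parameter tying.

    ``tie_means`` / ``tie_sds`` are lists of index groups over the four
    (MZ twin1, MZ twin2, DZ twin1, DZ twin2) slots to constrain equal.
    Returns (loglik, n_free_params).
    """
    complete = pairs[pairs.y1.notna() & pairs.y2.notna()]
    data = []
    start = np.zeros(10)
    for g, zyg in enumerate(("MZ", "DZ")):
        sub = complete[complete.zygosity == zyg]
        y = np.column_stack([sub.y1.values, sub.y2.values]) \
            if len(sub) else np.zeros((0, 2))
        data.append((y,))
        if len(sub) >= 2:
            start[2 * g] = y[:, 0].mean()
            start[2 * g + 1] = y[:, 1].mean()
            start[4 + 2 * g] = np.log(y[:, 0].std() + 1e-12)
            start[4 + 2 * g + 1] = np.log(y[:, 1].std() + 1e-12)
            start[8 + g] = np.arctanh(np.clip(np.corrcoef(y.T)[0, 1],
                                              -0.99, 0.99))
    tie_means = tie_means or []
    tie_sds = tie_sds or []
    # reduced parameterization: map free slots through tying groups
    mean_map = list(range(4))
    sd_map = list(range(4))
    for grp in tie_means:
        for i in grp[1:]:
            mean_map[i] = grp[0]
    for grp in tie_sds:
        for i in grp[1:]:
            sd_map[i] = grp[0]
    free_mean = sorted(set(mean_map))
    free_sd = sorted(set(sd_map))
    n_free = len(free_mean) + len(free_sd) + 2

    def expand(xfree):
        mu_free = dict(zip(free_mean, xfree[:len(free_mean)]))
        sd_free = dict(zip(free_sd,
                           xfree[len(free_mean):len(free_mean) + len(free_sd)]))
        full = np.empty(10)
        full[:4] = [mu_free[mean_map[i]] for i in range(4)]
        full[4:8] = [sd_free[sd_map[i]] for i in range(4)]
        full[8:] = xfree[-2:]
        return full

    x0 = np.concatenate([
        [np.mean([start[i] for i in range(4) if mean_map[i] == j])
         for j in free_mean],
        [np.mean([start[4 + i] for i in range(4) if sd_map[i] == j])
         for j in free_sd],
        start[8:],
    ])
    res = optimize.minimize(lambda x: _saturated_negloglik(expand(x), data),
                            x0, method="BFGS",
                            options={"maxiter": 2000, "gtol": 1e-8})
    return float(-res.fun), n_free


def check_candidate(pairs: pd.DataFrame, sd_threshold: float = 0.05,
                    alpha: float = 0.01) -> tuple[bool, list[str]]:
    """Twin-modelling eligibility: SD filter plus assumption checks.

    A CpG is eligible when the sample SD of its methylation values exceeds
    ``sd_threshold`` and likelihood-ratio tests against the saturated pair
    model detect no difference (at ``alpha``) in means or variances across
    twin order or across zygosity. Always returns the reasons examined.
    """
    reasons = []
    values = np.concatenate([pairs.y1.dropna().values,
                             pairs.y2.dropna().values])
    if values.std(ddof=1) <= sd_threshold:
        reasons.append(f"methylation SD {values.std(ddof=1):.4f} "
                       f"<= {sd_threshold}")
    ll_sat, k_sat = _fit_saturated(pairs)
    checks = {
        "means differ across twin order":
            dict(tie_means=[[0, 1], [2, 3]]),
        "means differ across zygosity":
            dict(tie_means=[[0, 2], [1, 3]]),
        "variances differ across twin order":
            dict(tie_sds=[[0, 1], [2, 3]]),
        "variances differ across zygosity":
            dict(tie_sds=[[0, 2], [1, 3]]),
    }
    for label, kw in checks.items():
        ll0, k0 = _fit_saturated(pairs, **kw)
        lrt = max(0.0, 2.0 * (ll_sat - ll0))
        p = stats.chi2.sf(lrt, k_sat - k0)
        if p < alpha:
            reasons.append(f"{label} (LRT p = {p:.2e})")
    return len(reasons) == 0, reasons
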