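"""Sex differences in methylation levels and in twin-model parameters.

Two complementary views: a rank test on methylation values between males and
females (Bonferroni-corrected across the tested CpGs, significance at
adjusted p < 0.01), and five-group sex-limitation twin models fitted by FIML
over MZ male, MZ female, DZ male, DZ female and opposite-sex DZ pairs.

In the sex-limitation model every parameter (mean, path coefficients, hence
total variance) carries a sex index; the opposite-sex DZ covariance is
rg * a_m * a_f + c_m * c_f with the genetic cross-correlation rg bounded in
[0, 0.5] (0.5 = the same genes act in both sexes, as in same-sex DZ pairs;
the shared-environment cross-sex correlation is fixed at 1 by convention).
Quantitative sex differences are tested by equating parameters across sexes
(omnibus: all at once; then one at a time); the qualitative difference is
tested by freeing rg against rg = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WilcoxonSexResult", "SexLimitationFit", "LrtResult",
    "wilcoxon_sex_test", "simulate_sex_pairs", "fit_sex_limitation",
    "omnibus_sex_test", "parameter_sex_tests",
]

SEX_PARAMETERS = ("mean", "a", "c", "e", "total_variance", "rg")


@dataclass
class WilcoxonSexResult:
    statistic: float
    p_raw: float
    p_bonferroni: float
    significant: bool


def wilcoxon_sex_test(values, sex, m_tests: int = 1) -> WilcoxonSexResult:
    """Two-sample rank test of methylation between sexes.

    Normal approximation with tie and continuity correction; Bonferroni
    adjustment over ``m_tests``; significance at adjusted p < 0.01.
    """
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    xm = values[sex == "M"]
    xf = values[sex == "F"]
    if len(xm) == 0 or len(xf) == 0:
        raise ValueError("both sexes must be represented")
    if np.ptp(values) == 0:
        res_stat, p = float(len(xm) * len(xf) / 2.0), 1.0
    else:
        res = stats.mannwhitneyu(xm, xf, alternative="two-sided",
                                 use_continuity=True, method="asymptotic")
        res_stat, p = float(res.statistic), float(res.pvalue)
    p_bonf = min(1.0, p * m_tests)
    return WilcoxonSexResult(statistic=res_stat, p_raw=p,
                             p_bonferroni=p_bonf,
                             significant=p_bonf < 0.01)


# ---------------------------------------------------------------------------
# five-group sex-limitation FIML

_GROUPS = ("MZm", "MZf", "DZm", "DZf", "DZos")


def _group_of(row) -> str:
    if row.zygosity == "MZ":
        return "MZm" if row.sex1 == "M" else "MZf"
    if row.sex1 == row.sex2:
        return "DZm" if row.sex1 == "M" else "DZf"
    return "DZos"


def _split_groups(pairs: pd.DataFrame) -> dict[str, np.ndarray]:
    complete = pairs[pairs.y1.notna() & pairs.y2.notna()].copy()
    out = {g: [] for g in _GROUPS}
    for row in complete.itertuples():
        g = _group_of(row)
        y1, y2 = row.y1, row.y2
        if g == "DZos" and row.sex1 == "F":   # normalize: male listed first
            y1, y2 = y2, y1
        out[g].append((y1, y2))
    return {g: np.array(v, dtype=float).reshape(-1, 2) for g, v in out.items()}


def simulate_sex_pairs(n_per_group: int, a2_m: float, a2_f: float,
                       mu_m: float = 0.0, mu_f: float = 0.0,
                       var_m: float = 1.0, var_f: float = 1.0,
                       rg: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """AE-structured pairs for the five sex-by-zygosity groups."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E8]))
    rows = []

    def draw(n, mu, cov_mat, zyg, s1, s2):
        y = rng.multivariate_normal(mu, cov_mat, size=n)
        return pd.DataFrame({"y1": y[:, 0], "y2": y[:, 1], "zygosity": zyg,
                             "sex1": s1, "sex2": s2})

    am, af = np.sqrt(a2_m * var_m), np.sqrt(a2_f * var_f)
    rows.append(draw(n_per_group, [mu_m, mu_m],
                     [[var_m, a2_m * var_m], [a2_m * var_m, var_m]],
                     "MZ", "M", "M"))
    rows.append(draw(n_per_group, [mu_f, mu_f],
                     [[var_f, a2_f * var_f], [a2_f * var_f, var_f]],
                     "MZ", "F", "F"))
    rows.append(draw(n_per_group, [mu_m, mu_m],
                     [[var_m, 0.5 * a2_m * var_m],
                      [0.5 * a2_m * var_m, var_m]], "DZ", "M", "M"))
    rows.append(draw(n_per_group, [mu_f, mu_f],
                     [[var_f, 0.5 * a2_f * var_f],
                      [0.5 * a2_f * var_f, var_f]], "DZ", "F", "F"))
    cov_os = rg * am * af
    rows.append(draw(n_per_group, [mu_m, mu_f],
                     [[var_m, cov_os], [cov_os, var_f]], "DZ", "M", "F"))
    return pd.concat(rows, ignore_index=True)


@dataclass
class SexLimitationFit:
    params: dict                 # mu_m, mu_f, a_m, a_f, (c_m, c_f), e_m, e_f
    rg: float
    rg_free: bool
    include_c: bool
    equated: tuple
    loglik: float
    n_params: int
    converged: bool
    pairs: pd.DataFrame = field(repr=False, default=None)

    def variance(self, sex: str) -> float:
        p = self.params
        return (p[f"a_{sex}"] ** 2 + p.get(f"c_{sex}", 0.0) ** 2
                + p[f"e_{sex}"] ** 2)

    def standardized(self, sex: str) -> dict:
        v = self.variance(sex)
        p = self.params
        return {"a2": p[f"a_{sex}"] ** 2 / v,
                "c2": p.get(f"c_{sex}", 0.0) ** 2 / v,
                "e2": p[f"e_{sex}"] ** 2 / v}


def _sexlim_negloglik(theta, data, include_c):
    if include_c:
        mu_m, mu_f, a_m, a_f, c_m, c_f, e_m, e_f, rg = theta
    else:
        mu_m, mu_f, a_m, a_f, e_m, e_f, rg = theta
        c_m = c_f = 0.0
    v_m = a_m ** 2 + c_m ** 2 + e_m ** 2
    v_f = a_f ** 2 + c_f ** 2 + e_f ** 2
    if min(v_m, v_f) <= 1e-300:
        return 1e12
    spec = {
        "MZm": (mu_m, mu_m, v_m, v_m, a_m ** 2 + c_m ** 2),
        "MZf": (mu_f, mu_f, v_f, v_f, a_f ** 2 + c_f ** 2),
        "DZm": (mu_m, mu_m, v_m, v_m, 0.5 * a_m ** 2 + c_m ** 2),
        "DZf": (mu_f, mu_f, v_f, v_f, 0.5 * a_f ** 2 + c_f ** 2),
        "DZos": (mu_m, mu_f, v_m, v_f, rg * a_m * a_f + c_m * c_f),
    }
    nll = 0.0
    for g, (m1, m2, v1, v2, cv) in spec.items():
        y = data[g]
        if len(y) == 0:
            continue
        det = v1 * v2 - cv * cv
        if det <= 1e-300:
            return 1e12
        r1 = y[:, 0] - m1
        r2 = y[:, 1] - m2
        quad = (v2 * r1 ** 2 + v1 * r2 ** 2 - 2 * cv * r1 * r2) / det
        nll += 0.5 * (len(y) * (2 * np.log(2 * np.pi) + np.log(det))
                      + quad.sum())
    return nll


def fit_sex_limitation(pairs: pd.DataFrame, equate=(),
                       rg: str | float = "free", include_c: bool = False,
                       n_starts: int = 3) -> SexLimitationFit:
    """FIML fit of the five-group sex-limitation model.

    ``equate`` lists parameters tied across sexes ('mean', 'a', 'c', 'e',
    'total_variance'); ``rg`` is 'free' (bounded in [0, 0.5]) or a fixed
    value. With an empty opposite-sex group a free rg is unidentifiable and
    rejected.
    """
    equate = tuple(equate)
    unknown = set(equate) - {"mean", "a", "c", "e", "total_variance"}
    if unknown:
        raise ValueError(f"unknown parameters to equate: {sorted(unknown)}")
    if "c" in equate and not include_c:
        raise ValueError("cannot equate 'c' in a model without C")
    data = _split_groups(pairs)
    rg_free = rg == "free"
    if rg_free and len(data["DZos"]) == 0:
        raise ValueError("free rg is unidentifiable without opposite-sex "
                         "DZ pairs")
    names = (["mu_m", "mu_f", "a_m", "a_f"]
             + (["c_m", "c_f"] if include_c else []) + ["e_m", "e_f", "rg"])
    k = len(names)
    y_all = np.concatenate([v.ravel() for v in data.values() if len(v)])
    mu0, sd0 = float(y_all.mean()), float(y_all.std() + 1e-12)
    bounds = []
    for nm in names:
        if nm.startswith("mu"):
            bounds.append((None, None))
        elif nm == "rg":
            bounds.append((rg, rg) if not rg_free else (0.0, 0.5))
        else:
            bounds.append((0.0, 20.0 * sd0))

    cons = []
    ix = {nm: i for i, nm in enumerate(names)}

    def eqc(f):
        cons.append({"type": "eq", "fun": f})

    for par in equate:
        if par == "mean":
            eqc(lambda x: x[ix["mu_m"]] - x[ix["mu_f"]])
        elif par == "total_variance":
            def tv(x, inc=include_c):
                vm = x[ix["a_m"]] ** 2 + x[ix["e_m"]] ** 2 \
                    + (x[ix["c_m"]] ** 2 if inc else 0.0)
                vf = x[ix["a_f"]] ** 2 + x[ix["e_f"]] ** 2 \
                    + (x[ix["c_f"]] ** 2 if inc else 0.0)
                return vm - vf
            eqc(tv)
        else:
            eqc(lambda x, p=par: x[ix[f"{p}_m"]] - x[ix[f"{p}_f"]])

    rng = np.random.default_rng(98765)
    starts = []
    for s in range(n_starts):
        frac = (np.array([0.5, 0.5]) if s == 0
                else rng.dirichlet(np.ones(2)))
        x0 = np.zeros(k)
        x0[ix["mu_m"]] = x0[ix["mu_f"]] = mu0
        for sex in ("m", "f"):
            x0[ix[f"a_{sex}"]] = sd0 * np.sqrt(frac[0])
            if include_c:
                x0[ix[f"c_{sex}"]] = sd0 * 0.2
            x0[ix[f"e_{sex}"]] = sd0 * np.sqrt(frac[1])
        x0[ix["rg"]] = 0.4 if rg_free else float(rg)
        starts.append(x0)
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _sexlim_negloglik, x0, args=(data, include_c),
            method="SLSQP", bounds=bounds, constraints=cons,
            options={"maxiter": 800, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    params = {nm: float(abs(v)) if not nm.startswith("mu") and nm != "rg"
              else float(v) for nm, v in zip(names, theta)}
    rg_val = params.pop("rg")
    n_params = (k - 1) + int(rg_free) - len(cons)
    return SexLimitationFit(
        params=params, rg=rg_val, rg_free=rg_free, include_c=include_c,
        equated=equate, loglik=float(-best.fun), n_params=n_params,
        converged=bool(best.success or best.fun < 1e11), pairs=pairs)


@dataclass
class LrtResult:
    statistic: float
    df: int
    p: float
    p_adjusted: float
    significant: bool


def _lrt(fit_free: SexLimitationFit, fit_constrained: SexLimitationFit,
         m_tests: int) -> LrtResult:
    df = fit_free.n_params - fit_constrained.n_params
    if df <= 0:
        raise ValueError("the constrained model is not nested in the free one")
    stat = max(0.0, 2.0 * (fit_free.loglik - fit_constrained.loglik))
    p = float(stats.chi2.sf(stat, df))
    p_adj = min(1.0, p * m_tests)
    return LrtResult(statistic=float(stat), df=df, p=p, p_adjusted=p_adj,
                     significant=p_adj < 0.01)


def omnibus_sex_test(fit_free: SexLimitationFit,
                     fit_equated: SexLimitationFit,
                     m_tests: int = 1) -> LrtResult:
    """All-parameters-equal LRT: any sex difference in the model at all."""
    if fit_equated.include_c != fit_free.include_c:
        raise ValueError("fits use different component sets")
    return _lrt(fit_free, fit_equated, m_tests)


def parameter_sex_tests(fit_free: SexLimitationFit, parameter_list=None,
                        m_tests: int = 1) -> dict[str, LrtResult]:
    """One LRT per parameter: which parameter differs between the sexes.

    'mean', 'a', 'c', 'e' and 'total_variance' are tested by equating the
    parameter across sexes; 'rg' (the qualitative sex difference) by fixing
    the genetic cross-correlation to 0.5.
    """
    if fit_free.pairs is None:
        raise ValueError("the free fit must retain its pairs for refitting")
    if parameter_list is None:
        parameter_list = ["mean", "a", "e", "total_variance"] + \
            (["c"] if fit_free.include_c else []) + \
            (["rg"] if fit_free.rg_free else [])
    out = {}
    for par in parameter_list:
        if par not in SEX_PARAMETERS:
            raise ValueError(f"unknown parameter {par!r}; choose from "
                             f"{SEX_PARAMETERS}")
        if par == "rg":
            constrained = fit_sex_limitation(
                fit_free.pairs, equate=fit_free.equated, rg=0.5,
                include_c=fit_free.include_c)
        else:
            constrained = fit_sex_limitation(
                fit_free.pairs, equate=(*fit_free.equated, par),
                rg="free" if fit_free.rg_free else fit_free.rg,
                include_c=fit_free.include_c)
        out[par] = _lrt(fit_free, constrained, m_tests)
    return out
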