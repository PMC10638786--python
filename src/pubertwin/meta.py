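"""Dual-platform EWAS meta-analysis on partial-correlation effect sizes.

Per-platform t statistics are converted to standardized partial correlations
r = t / sqrt(t^2 + df) with sampling variance (1 - r^2)^2 / df, combined by
inverse-variance fixed-effect meta-analysis over the CpGs present on both
platforms, and triaged for heterogeneity with Cochran's Q. CpGs whose
Benjamini-Hochberg-adjusted Q p-value falls below 0.01 are re-estimated with
a DerSimonian-Laird random-effects model. Significance tiers: strict
(p <= 2.4e-7, the 450K array-wide threshold) and suggestive (p <= 1e-5);
an additional flag marks |r| > 0.13 (the effect-size annotation filter).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "t_to_partial_r", "fixed_effect_meta", "cochran_q", "random_effect_meta",
    "benjamini_hochberg", "run_meta_pipeline",
    "STRICT_P", "SUGGESTIVE_P", "HET_Q_BH", "EFFECT_FILTER",
]

STRICT_P = 2.4e-7
SUGGESTIVE_P = 1e-5
HET_Q_BH = 0.01
EFFECT_FILTER = 0.13


def t_to_partial_r(t: float, n: int, p_count: int) -> tuple[float, float]:
    """Partial correlation and its sampling variance from a regression t.

    df = n - p_count (the residual df of the regression whose t is supplied,
    with p_count counting the intercept and exposure among the coefficients).
    """
    df = n - p_count
    if df < 1:
        raise ValueError(f"residual df must be >= 1, got {df}")
    t = float(t)
    if np.isinf(t):
        return float(np.sign(t)), 0.0
    r = t / np.sqrt(t * t + df)
    var = (1.0 - r * r) ** 2 / df
    return float(r), float(var)


def _check_effects(effects, variances):
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.shape != v.shape or y.ndim != 1 or y.size < 1:
        raise ValueError("effects and variances must be equal-length vectors")
    if (v <= 0).any():
        raise ValueError("variances must be positive")
    return y, v


def fixed_effect_meta(effects, variances) -> tuple[float, float, float]:
    """Inverse-variance weighted fixed-effect estimate, SE and normal p."""
    y, v = _check_effects(effects, variances)
    w = 1.0 / v
    est = float((w * y).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2 * stats.norm.sf(abs(est / se)))
    return est, se, p


def cochran_q(effects, variances) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic and its chi-square p (k-1 df)."""
    y, v = _check_effects(effects, variances)
    if y.size < 2:
        raise ValueError("Q requires at least 2 studies")
    w = 1.0 / v
    est = (w * y).sum() / w.sum()
    q = float((w * (y - est) ** 2).sum())
    p = float(stats.chi2.sf(q, y.size - 1))
    return q, p


def random_effect_meta(effects, variances) -> tuple[float, float, float]:
    """DerSimonian-Laird random-effects estimate, SE and normal p.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); with Q <= k-1
    the result equals the fixed-effect estimate.
    """
    y, v = _check_effects(effects, variances)
    k = y.size
    if k < 2:
        return fixed_effect_meta(y, v)
    w = 1.0 / v
    q, _ = cochran_q(y, v)
    denom = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    wr = 1.0 / (v + tau2)
    est = float((wr * y).sum() / wr.sum())
    se = float(1.0 / np.sqrt(wr.sum()))
    p = float(2 * stats.norm.sf(abs(est / se)))
    return est, se, p


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _tier(p: float) -> str:
    if p <= STRICT_P:
        return "strict"
    if p <= SUGGESTIVE_P:
        return "suggestive"
    return "none"


def run_meta_pipeline(results_450k: pd.DataFrame,
                      results_epic: pd.DataFrame,
                      t_column: str = "t") -> pd.DataFrame:
    """Meta-analyse two per-platform EWAS result tables.

    Inputs are indexed by cpg_id with columns ``t`` (or ``t_moderated`` via
    ``t_column``), ``n`` and ``p_count``. Only the intersection of CpG panels
    is analysed. Heterogeneity Q p-values are BH-adjusted over all analysed
    CpGs; CpGs with adjusted Q p < 0.01 are flagged heterogeneous and
    re-estimated with random effects.
    """
    common = results_450k.index.intersection(results_epic.index)
    if len(common) == 0:
        raise ValueError("the two platforms share no CpG sites")
    rows = []
    for cpg in common:
        eff, var = [], []
        for res in (results_450k, results_epic):
            row = res.loc[cpg]
            r, v = t_to_partial_r(row[t_column], int(row["n"]),
                                  int(row["p_count"]))
            eff.append(r)
            var.append(v)
        est, se, p = fixed_effect_meta(eff, var)
        q, q_p = cochran_q(eff, var)
        rows.append({"cpg_id": cpg, "r_meta": est, "se_meta": se,
                     "p_value": p, "Q": q, "q_p": q_p,
                     "r_450k": eff[0], "r_epic": eff[1],
                     "var_450k": var[0], "var_epic": var[1]})
    out = pd.DataFrame(rows).set_index("cpg_id")
    out["q_p_bh"] = benjamini_hochberg(out.q_p.values)
    out["heterogeneous"] = out.q_p_bh < HET_Q_BH
    out["method"] = np.where(out.heterogeneous, "random", "fixed")
    for cpg in out.index[out.heterogeneous]:
        row = out.loc[cpg]
        est, se, p = random_effect_meta(
            [row.r_450k, row.r_epic], [row.var_450k, row.var_epic])
        out.loc[cpg, ["r_meta", "se_meta", "p_value"]] = est, se, p
    out["tier"] = [_tier(p) for p in out.p_value]
    out["passes_effect_filter"] = out.r_meta.abs() > EFFECT_FILTER
    return out.drop(columns=["r_450k", "r_epic", "var_450k", "var_epic"])
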