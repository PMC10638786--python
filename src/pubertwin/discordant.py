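"""Discordant twin-pair decomposition of exposure-methylation associations.

The individual-level association is split into a between-pair effect (of the
pair-mean exposure) and a within-pair effect (of each twin's deviation from
the cotwin), fitted as a linear mixed model with a family random intercept
(REML) and fixed covariates. A nonzero within-pair effect is inconsistent
with purely familial (genetic or shared-environment) confounding and is
consistent with an environmentally driven, potentially causal relationship.

A CpG is classified as differentially methylated within pairs when the
pooled (MZ + DZ) within-pair effect is significant and the MZ-only
within-pair effect is suggestive (p < 0.10) in the same direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DiscordanceResult", "decompose_exposure", "fit_within_between",
    "classify_discordance", "run_discordance",
]

POOLED_WITHIN_P = 0.05    # "significant" pooled within-pair effect
MZ_WITHIN_P = 0.10        # suggestive MZ-only threshold


@dataclass
class DiscordanceResult:
    cpg_id: str = ""
    beta_between: float = np.nan
    se_between: float = np.nan
    p_between: float = np.nan
    beta_within: float = np.nan
    se_within: float = np.nan
    p_within: float = np.nan
    n_pairs: int = 0


def decompose_exposure(pairs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Long-format between/within predictors from pairwise exposures.

    ``pairs`` needs columns family_id, x1, x2, y1, y2 (plus optional per-twin
    covariate columns suffixed 1/2 and pair-level columns passed through).
    between = (x1 + x2) / 2 per pair; within = x_self - x_cotwin per twin
    (antisymmetric). Incomplete pairs are excluded; their count is returned.
    Concordant pairs have within = 0 but still inform the between effect.
    """
    complete = pairs[pairs.x1.notna() & pairs.x2.notna()
                     & pairs.y1.notna() & pairs.y2.notna()]
    n_excluded = len(pairs) - len(complete)
    per_twin_cov = sorted({c[:-1] for c in pairs.columns
                           if c[-1] in "12" and c[:-1] not in ("x", "y")})
    pair_cols = [c for c in pairs.columns
                 if not (c[-1] in "12" and c[:-1] in
                         {"x", "y", *per_twin_cov})]
    rows = []
    for member, other in ((1, 2), (2, 1)):
        d = complete[pair_cols].copy()
        d["y"] = complete[f"y{member}"].values
        d["between"] = (complete.x1.values + complete.x2.values) / 2.0
        d["within"] = (complete[f"x{member}"].values
                       - complete[f"x{other}"].values)
        for c in per_twin_cov:
            d[c] = complete[f"{c}{member}"].values
        rows.append(d)
    long = pd.concat(rows, ignore_index=True)
    return long, n_excluded


def fit_within_between(long: pd.DataFrame, covariates=()) -> DiscordanceResult:
    """REML mixed model y ~ between + within + covariates + (1 | family).

    The within regressor is half the cotwin difference, i.e. each twin's
    deviation from the pair mean. On that scale a purely individual-level
    (causal-consistent) exposure effect produces equal between and within
    coefficients, while purely familial confounding leaves the within
    coefficient at zero — the discriminating contrast of the design.

    Wald normal p-values for both coefficients. When all within values are
    zero the within effect is inestimable: the result carries NaN for it and
    a warning is raised.
    """
    if long.family_id.nunique() < 10:
        raise ValueError("need at least 10 pairs")
    all_zero_within = bool((long.within == 0).all())
    X = pd.DataFrame({"const": 1.0}, index=long.index)
    X["between"] = long.between.values
    if not all_zero_within:
        X["within"] = long.within.values / 2.0   # deviation from pair mean
    for c in covariates:
        v = long[c]
        X[c] = (pd.factorize(v)[0].astype(float)
                if v.dtype == object else v.values.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(long.y.values, X.values, groups=long.family_id.values)
        fit = model.fit(reml=True)
    res = DiscordanceResult(n_pairs=int(long.family_id.nunique()))
    names = list(X.columns)
    bi = names.index("between")
    res.beta_between = float(fit.fe_params[bi])
    res.se_between = float(fit.bse_fe[bi])
    res.p_between = float(fit.pvalues[bi])
    if all_zero_within:
        warnings.warn("all within-pair exposure differences are zero; the "
                      "within effect is not estimable", UserWarning)
    else:
        wi = names.index("within")
        res.beta_within = float(fit.fe_params[wi])
        res.se_within = float(fit.bse_fe[wi])
        res.p_within = float(fit.pvalues[wi])
    return res


def classify_discordance(pooled: DiscordanceResult,
                         mz_only: DiscordanceResult | None,
                         pooled_threshold: float = POOLED_WITHIN_P
                         ) -> tuple[bool, str]:
    """Environmentally driven (causal-consistent) classification rule.

    Requires a significant pooled within-pair effect, a suggestive
    (p < 0.10) MZ-only within-pair effect, and agreement in direction.
    """
    if mz_only is None or not np.isfinite(mz_only.p_within):
        return False, "MZ-only within-pair fit unavailable"
    if not np.isfinite(pooled.p_within):
        return False, "pooled within-pair effect not estimable"
    if pooled.p_within >= pooled_threshold:
        return False, f"pooled within-pair p {pooled.p_within:.3g} >= " \
                      f"{pooled_threshold}"
    if mz_only.p_within >= MZ_WITHIN_P:
        return False, f"MZ-only within-pair p {mz_only.p_within:.3g} >= " \
                      f"{MZ_WITHIN_P}"
    if np.sign(pooled.beta_within) != np.sign(mz_only.beta_within):
        return False, "within-pair effects disagree in direction"
    return True, "classified"


def run_discordance(pairs: pd.DataFrame, covariates=(), cpg_id: str = ""
                    ) -> dict:
    """Pooled and MZ-only within/between fits plus the classification."""
    long, n_excl = decompose_exposure(pairs)
    pooled = fit_within_between(long, covariates)
    pooled.cpg_id = cpg_id
    mz_long = long[long.zygosity == "MZ"]
    mz_only = None
    if mz_long.family_id.nunique() >= 10:
        mz_only = fit_within_between(mz_long, covariates)
        mz_only.cpg_id = cpg_id
    classified, reason = classify_discordance(pooled, mz_only)
    return {"cpg_id": cpg_id, "pooled": pooled, "mz_only": mz_only,
            "classified": classified, "reason": reason,
            "n_pairs_excluded": n_excl}
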