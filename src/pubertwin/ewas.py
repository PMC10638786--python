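"""Per-CpG EWAS engine: family-clustered GLS, variance moderation and QC.

Each CpG's beta values are regressed on an exposure plus covariates.
Relatedness of cotwins is handled by a consensus within-family residual
correlation (estimated across CpGs, pooled on the Fisher-z scale) plugged
into generalized least squares with a block-diagonal residual correlation
matrix: ``rho`` within complete twin pairs, zero elsewhere. Residual
variances across CpGs are then shrunk toward a pooled inverse-chi-square
prior (empirical-Bayes moderated t statistics). Test-statistic bias and
inflation are summarised by robust location/scale estimates of the z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "EwasDesign", "EwasResult", "estimate_consensus_correlation",
    "fit_cpg_gls", "run_ewas", "moderate_statistics",
    "select_covariate_model", "estimate_inflation_bias",
]


@dataclass
class EwasDesign:
    """Design matrix with family labels and a named exposure column.

    ``X`` must include an intercept column and be of full column rank.
    """

    X: pd.DataFrame
    family: np.ndarray
    exposure: str

    def __post_init__(self) -> None:
        if self.exposure not in self.X.columns:
            raise ValueError(f"exposure column {self.exposure!r} not in design")
        if len(self.family) != len(self.X):
            raise ValueError("family labels must match design rows")
        self.family = np.asarray(self.family)
        rank = np.linalg.matrix_rank(self.X.values)
        if rank < self.X.shape[1]:
            raise ValueError("design matrix is rank-deficient")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p_count(self) -> int:
        return self.X.shape[1]


@dataclass
class EwasResult:
    cpg_id: str
    beta_hat: float
    se: float
    t: float
    df_residual: int
    n: int
    p_count: int
    p_value: float
    sigma2: float = np.nan   # residual variance, for moderation


def _pair_blocks(family: np.ndarray) -> np.ndarray:
    """Row indices (k, 2) of complete pairs; singleton rows are left alone."""
    fam = pd.Series(family)
    idx = fam.groupby(fam).indices
    return np.array([v for v in idx.values() if len(v) == 2], dtype=int)


def estimate_consensus_correlation(Y: pd.DataFrame, design: EwasDesign) -> float:
    """Pooled within-family residual correlation of methylation.

    Per CpG, OLS residuals are computed for the design, the cotwin-residual
    correlation is taken over complete families, Fisher z-transformed, pooled
    by a 10% trimmed mean across CpGs, and transformed back. Singleton
    families do not contribute.
    """
    blocks = _pair_blocks(design.family)
    if len(blocks) == 0:
        raise ValueError("no complete families: cannot estimate the "
                         "within-family correlation")
    X = design.X.values
    Yv = np.asarray(Y, dtype=float)
    coef, *_ = np.linalg.lstsq(X, Yv.T, rcond=None)
    resid = Yv.T - X @ coef                       # samples x cpgs
    r1, r2 = resid[blocks[:, 0]], resid[blocks[:, 1]]
    r1 = r1 - r1.mean(axis=0)
    r2 = r2 - r2.mean(axis=0)
    denom = np.sqrt((r1 ** 2).sum(axis=0) * (r2 ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (r1 * r2).sum(axis=0) / denom
    r = np.clip(r[np.isfinite(r)], -0.999, 0.999)
    if r.size == 0:
        raise ValueError("no CpG yielded a finite within-family correlation")
    z = np.arctanh(r)
    pooled = stats.trim_mean(z, 0.1) if r.size > 1 else z[0]
    return float(np.tanh(pooled))


def fit_cpg_gls(y: np.ndarray, design: EwasDesign, rho: float,
                cpg_id: str = "") -> EwasResult:
    """GLS fit of one CpG with residual correlation ``rho`` within pairs.

    With ``rho = 0`` (or no complete pairs) this reduces exactly to OLS. The
    t statistic for the exposure is on ``n - p_count`` residual df.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    y = np.asarray(y, dtype=float)
    X = design.X.values.astype(float)
    n, p = X.shape
    yw, Xw = y.copy(), X.copy()
    blocks = _pair_blocks(design.family)
    if rho != 0.0 and len(blocks):
        # whiten each 2-block by the inverse Cholesky of [[1, rho], [rho, 1]]
        s = np.sqrt(1.0 - rho ** 2)
        i1, i2 = blocks[:, 0], blocks[:, 1]
        yw[i2] = (y[i2] - rho * y[i1]) / s
        Xw[i2] = (X[i2] - rho * X[i1]) / s
    coef, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    df = n - p
    if df <= 0:
        raise ValueError("nonpositive residual degrees of freedom")
    sigma2 = float(resid @ resid / df)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    j = list(design.X.columns).index(design.exposure)
    se = float(np.sqrt(sigma2 * xtx_inv[j, j]))
    beta = float(coef[j])
    tval = beta / se
    p_value = float(2 * stats.t.sf(abs(tval), df))
    return EwasResult(cpg_id=cpg_id, beta_hat=beta, se=se, t=tval,
                      df_residual=df, n=n, p_count=p, p_value=p_value,
                      sigma2=sigma2)


def run_ewas(Y: pd.DataFrame, design: EwasDesign,
             rho: float | None = None) -> pd.DataFrame:
    """Fit every CpG in ``Y`` (CpG x sample); estimates ``rho`` if None."""
    if list(Y.columns) != list(design.X.index):
        Y = Y.loc[:, design.X.index]
    if rho is None:
        rho = estimate_consensus_correlation(Y, design)
    rows = [fit_cpg_gls(Y.loc[c].values, design, rho, cpg_id=c)
            for c in Y.index]
    out = pd.DataFrame([vars(r) for r in rows]).set_index("cpg_id")
    out.attrs["rho"] = rho
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderation

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to sample
    variances with common residual df, via the log-variance digamma/trigamma
    identities. Returns d0 = inf when the observed log-variance spread is no
    larger than the sampling spread."""
    s2 = np.asarray(s2, dtype=float)
    if np.unique(s2).size < 2:
        raise ValueError("need >= 2 distinct residual variances to "
                         "identify the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0)
                        - np.log(d0 / 2.0)))
    return float(d0), s0sq


def moderate_statistics(results: pd.DataFrame,
                        d0_override: float | None = None) -> pd.DataFrame:
    """Shrink residual variances toward the pooled prior and recompute t.

    Posterior variance s~^2 = (d0*s0^2 + d*s^2) / (d0 + d); moderated
    t = beta_hat / (s~ * sqrt(v)) on d0 + d df. With ``d0_override = 0`` the
    moderated statistics equal the ordinary ones; with d0 = inf every CpG is
    tested against the common variance s0^2.
    """
    if len(results) < 10:
        raise ValueError("need >= 10 CpGs to moderate variances")
    df = results.df_residual.to_numpy(dtype=float)
    if np.unique(df).size != 1:
        raise ValueError("moderation expects a common residual df per CpG")
    d = df[0]
    s2 = results.sigma2.to_numpy(dtype=float)
    if d0_override is not None:
        d0 = float(d0_override)
        e = (np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0))
        if d0 == 0:
            s0sq = np.nan
        elif np.isinf(d0):
            s0sq = float(np.exp(np.mean(e)))
        else:
            s0sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0)
                                - np.log(d0 / 2.0)))
    else:
        d0, s0sq = fit_variance_prior(s2, d)
    out = results.copy()
    if d0 == 0:
        s2_post = s2
        df_total = d
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d
    scale = np.sqrt(s2 / s2_post)
    out["s2_post"] = s2_post
    out["t_moderated"] = out.t * scale
    if np.isinf(df_total):
        out["p_moderated"] = 2 * stats.norm.sf(np.abs(out.t_moderated))
    else:
        out["p_moderated"] = 2 * stats.t.sf(np.abs(out.t_moderated), df_total)
    out.attrs.update({"d0": d0, "s0_sq": s0sq, "df_total": df_total})
    return out


def select_covariate_model(Y: pd.DataFrame, candidate_designs) -> int:
    """Pick the covariate set preferred by the most CpGs under per-CpG AIC.

    Ties go to the candidate with fewer columns, then to the earlier one.
    """
    designs = list(candidate_designs)
    if len(designs) < 2:
        if len(designs) == 1:
            return 0
        raise ValueError("need at least one candidate design")
    n = designs[0].n
    index = list(designs[0].X.index)
    for d in designs[1:]:
        if d.n != n or list(d.X.index) != index:
            raise ValueError("candidate designs must share the same samples")
    Yv = np.asarray(Y.loc[:, index], dtype=float)
    aic = np.empty((len(designs), len(Y)))
    for k, d in enumerate(designs):
        X = d.X.values
        coef, *_ = np.linalg.lstsq(X, Yv.T, rcond=None)
        rss = ((Yv.T - X @ coef) ** 2).sum(axis=0)
        aic[k] = n * np.log(rss / n) + 2 * (d.p_count + 1)
    # per-CpG winner; exact AIC ties go to fewer columns, then earlier index
    votes = np.zeros(len(designs), dtype=int)
    mins = aic.min(axis=0)
    for j in range(aic.shape[1]):
        tied = np.flatnonzero(aic[:, j] == mins[j])
        winner = min(tied, key=lambda k: (designs[k].p_count, k))
        votes[winner] += 1
    best = np.flatnonzero(votes == votes.max())
    if len(best) > 1:
        best = sorted(best, key=lambda k: (designs[k].p_count, k))
    return int(best[0])


def estimate_inflation_bias(z: np.ndarray) -> tuple[float, float]:
    """Robust bias/inflation of EWAS z-scores.

    bias = median(z); inflation = 1.4826 * MAD(z). A robust location/scale
    summary of the test-statistic distribution used for QC: unbiased,
    uninflated statistics give (0, 1).
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 10:
        raise ValueError("need >= 10 finite z-scores")
    bias = float(np.median(z))
    inflation = float(stats.median_abs_deviation(z, scale="normal"))
    return bias, inflation
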