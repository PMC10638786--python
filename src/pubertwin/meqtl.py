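"""meQTL counting and correlation with heritability.

Consumes a user-supplied (or synthetic) SNP-CpG association table with
columns snp_id, chrom, pos, cpg_id, cis_trans, p, beta; counts per-CpG
genome-wide significant associations (strictly p < 5e-8) and correlates the
counts with twin-model heritability estimates by Spearman rank correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MEQTL_P_THRESHOLD", "count_meqtls", "spearman_correlation",
           "load_meqtl_table"]

MEQTL_P_THRESHOLD = 5e-8

_REQUIRED = ("snp_id", "cpg_id", "p")


def load_meqtl_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(_REQUIRED) - set(table.columns)
    if missing:
        raise ValueError(f"meQTL table lacks columns: {sorted(missing)}")
    return table


def count_meqtls(table: pd.DataFrame, cpg_ids,
                 threshold: float = MEQTL_P_THRESHOLD) -> pd.DataFrame:
    """Per-CpG counts of associations with p strictly below ``threshold``.

    CpGs absent from the table get count 0. Duplicate (snp, cpg) rows are an
    input error, reported by name. A cis/trans breakdown is included when the
    table carries a ``cis_trans`` column.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if len(table):
        dup = table.duplicated(subset=["snp_id", "cpg_id"], keep=False)
        if dup.any():
            first = table[dup].iloc[0]
            raise ValueError(
                f"duplicate meQTL row for ({first.snp_id}, {first.cpg_id})")
    cpg_ids = list(cpg_ids)
    out = pd.DataFrame(index=pd.Index(cpg_ids, name="cpg_id"),
                       data={"n_meqtl": 0, "n_cis": 0, "n_trans": 0})
    if len(table):
        sig = table[table.p < threshold]
        counts = sig.groupby("cpg_id").size()
        out.loc[out.index.intersection(counts.index), "n_meqtl"] = \
            counts[counts.index.isin(out.index)]
        if "cis_trans" in table.columns and len(sig):
            for label, col in (("cis", "n_cis"), ("trans", "n_trans")):
                c = sig[sig.cis_trans == label].groupby("cpg_id").size()
                out.loc[out.index.intersection(c.index), col] = \
                    c[c.index.isin(out.index)]
    return out


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; p via the t
    approximation on n - 2 df. A constant input leaves rho undefined (NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
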