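"""Alpha-diversity estimators and exact rarefaction.

Shannon H' (natural log) and the Gini-Simpson complement 1 - sum(p_i^2) are
defined on any non-negative abundance vector; the richness estimators Chao1
and ACE and the hypergeometric rarefaction curve require integer read
counts, matching practice for sequence libraries (richness extrapolation is
meaningless on relative fingerprint heights).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .tables import OtuTable

__all__ = ["shannon", "simpson", "chao1", "ace", "rarefaction_curve", "diversity_table"]


def _positive(abundances) -> np.ndarray:
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if np.any(a < 0):
        raise ValueError("negative abundances")
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("all-zero abundance vector")
    return a


def _counts(counts) -> np.ndarray:
    a = _positive(counts)
    if not np.allclose(a, np.round(a), atol=0):
        raise ValueError("richness estimators require integer counts")
    return a.astype(np.int64)


def shannon(abundances) -> float:
    """Shannon diversity H' = -sum p_i ln p_i, in nats."""
    a = _positive(abundances)
    p = a / a.sum()
    return float(-(p * np.log(p)).sum())


def simpson(abundances) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (probability two reads differ)."""
    a = _positive(abundances)
    p = a / a.sum()
    return float(1.0 - (p**2).sum())


def chao1(counts) -> float:
    """Chao1 richness: classic form when doubletons exist, else bias-corrected.

    S_obs + F1^2/(2 F2) if F2 > 0, else S_obs + F1(F1-1)/(2(F2+1)), with
    F1/F2 the singleton/doubleton counts.
    """
    c = _counts(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1**2 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace(counts, rare_cutoff: int = 10) -> float:
    """ACE richness estimator (abundance-based coverage).

    Rare OTUs are those with <= ``rare_cutoff`` reads.  With sample coverage
    C_ace = 1 - F1/N_rare and gamma^2 the rare-class CV estimate,
    ACE = S_abund + S_rare/C_ace + (F1/C_ace) gamma^2.  Falls back to
    :func:`chao1` when coverage is zero (all rare OTUs are singletons).
    """
    c = _counts(counts)
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(c.size)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(counts)
    fi = np.bincount(rare, minlength=rare_cutoff + 1)
    i = np.arange(len(fi))
    ssum = float((i * (i - 1) * fi).sum())
    gamma2 = max(s_rare * ssum / (c_ace * n_rare * (n_rare - 1)) - 1.0, 0.0) \
        if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def rarefaction_curve(counts, depths) -> list:
    """Exact expected richness E[S(n)] at each subsampling depth n.

    E[S(n)] = sum_i (1 - C(N - N_i, n) / C(N, n)) computed via log-factorials
    (no resampling).  Depths must satisfy 0 <= n <= N.
    """
    c = _counts(counts)
    n_total = int(c.sum())

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = []
    for n in depths:
        n = int(n)
        if n < 0 or n > n_total:
            raise ValueError(f"rarefaction depth {n} outside [0, {n_total}]")
        if n == 0:
            out.append((0, 0.0))
            continue
        # P(OTU i missing) = C(N-N_i, n)/C(N, n); zero when n > N - N_i
        miss = np.where(
            n_total - c >= n,
            np.exp(log_comb(n_total - c, n) - log_comb(n_total, n)),
            0.0,
        )
        out.append((n, float((1.0 - miss).sum())))
    return out


def diversity_table(table: OtuTable, rare_cutoff: int = 10) -> pd.DataFrame:
    """Per-sample diversity records for an OtuTable.

    Shannon and Simpson are computed in either mode; Chao1, ACE and read
    totals only in counts mode (NaN otherwise), since richness estimators
    require integer library counts.
    """
    rows = []
    is_counts = table.mode == "counts"
    for sid, row in zip(table.sample_ids, table.values):
        rec = {
            "sample_id": sid,
            "s_obs": int((row > 0).sum()),
            "shannon_h": shannon(row),
            "simpson": simpson(row),
        }
        if is_counts:
            rec["chao1"] = chao1(row)
            rec["ace"] = ace(row, rare_cutoff)
            rec["n_reads"] = int(row.sum())
        else:
            rec["chao1"] = np.nan
            rec["ace"] = np.nan
            rec["n_reads"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
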