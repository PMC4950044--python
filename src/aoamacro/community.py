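"""Permutation tests and constrained ordination.

One-way and two-way crossed ANOSIM (Clarke's rank-based R with label
permutation nulls, or exhaustive enumeration on small designs), canonical
correspondence analysis (chi-square community response constrained on
environmental variables), redundancy analysis with optional covariate
partialling, and environment/space/time variation partitioning into the
seven Venn fractions of adjusted R-squared.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sympy.utilities.iterables import multiset_permutations

from .beta import DistanceMatrix, OrdinationResult
from .tables import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "AnosimResult",
    "VariationPartition",
    "anosim_oneway",
    "anosim_twoway",
    "cca",
    "rda",
    "variation_partitioning",
]

_EXHAUSTIVE_LIMIT = 500_000


@dataclass
class AnosimResult:
    factor_name: str
    R: float
    p_value: float
    n_permutations: int
    design: str = "one_way"
    per_stratum_R: list = field(default_factory=list)


def _anosim_r(ranks: np.ndarray, iu, ju, labels: np.ndarray) -> float:
    """Clarke's R from pre-ranked condensed distances.

    R = (mean between-group rank - mean within-group rank) / (M/2),
    M = n(n-1)/2 the number of pairs.
    """
    within = labels[iu] == labels[ju]
    m = ranks.size
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (m / 2.0))


def _check_groups(labels: np.ndarray, min_size: int = 2) -> None:
    vals, counts = np.unique(labels, return_counts=True)
    if vals.size < 2:
        raise ValueError("ANOSIM needs >= 2 groups")
    if counts.min() < min_size:
        small = vals[np.argmin(counts)]
        raise ValueError(f"group {small!r} has {counts.min()} sample(s); need >= {min_size}")


def anosim_oneway(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = None,
    factor_name: str = "group",
) -> AnosimResult:
    """One-way ANOSIM with a label-permutation null.

    Dissimilarities are ranked once (mean ranks for ties).  With ``n_perm``
    an integer, p = (1 + #{perm R >= observed}) / (n_perm + 1); with
    ``n_perm=None`` all distinct label assignments are enumerated and p is
    the exact fraction (the observed assignment included).
    """
    if d.kind != "dissimilarity":
        raise ValueError("ANOSIM requires a dissimilarity matrix")
    labels = np.asarray(list(groups))
    n = len(d.labels)
    if labels.size != n:
        raise ValueError(f"{labels.size} labels for {n} samples")
    _check_groups(labels)
    iu, ju = np.triu_indices(n, k=1)
    cond = d.values[iu, ju]
    if np.allclose(cond, cond[0]):
        warnings.warn("constant distance matrix: ANOSIM R defined as 0")
        return AnosimResult(factor_name, 0.0, 1.0, 0, "one_way")
    ranks = rankdata(cond)
    r_obs = _anosim_r(ranks, iu, ju, labels)

    if n_perm is None:
        perms = list(multiset_permutations(list(labels)))
        if len(perms) > _EXHAUSTIVE_LIMIT:
            raise ValueError(f"{len(perms)} assignments exceed the enumeration limit")
        r_all = np.array([_anosim_r(ranks, iu, ju, np.asarray(p)) for p in perms])
        p_val = float((r_all >= r_obs - 1e-12).sum() / len(perms))
        return AnosimResult(factor_name, r_obs, p_val, len(perms), "one_way")

    rng = np.random.default_rng(seed)
    codes = np.unique(labels, return_inverse=True)[1]
    perm = np.vstack([rng.permutation(codes) for _ in range(n_perm)])
    within = perm[:, iu] == perm[:, ju]
    m = ranks.size
    r_w = np.where(within, ranks, 0.0).sum(axis=1) / within.sum(axis=1)
    r_b = np.where(~within, ranks, 0.0).sum(axis=1) / (~within).sum(axis=1)
    r_perm = (r_b - r_w) / (m / 2.0)
    p_val = float((1 + (r_perm >= r_obs - 1e-12).sum()) / (n_perm + 1))
    return AnosimResult(factor_name, r_obs, p_val, n_perm, "one_way")


def _stratum_r(d: DistanceMatrix, idx: np.ndarray, labels: np.ndarray):
    """Within-stratum ranked R; None when inestimable (no within or between pairs)."""
    sub = d.values[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    if iu.size == 0:
        return None
    within = labels[iu] == labels[ju]
    if within.all() or not within.any():
        return None
    ranks = rankdata(sub[iu, ju])
    return _anosim_r(ranks, iu, ju, labels), (ranks, iu, ju)


def anosim_twoway(
    d: DistanceMatrix,
    factor_a,
    factor_b,
    n_perm: int = 999,
    seed: int = None,
    names=("A", "B"),
):
    """Two-way crossed ANOSIM: each factor tested within strata of the other.

    For factor A, a one-way R is computed inside every level of B (ranks
    taken within the stratum) and the estimable per-stratum values averaged
    unweighted; the null permutes A labels independently within each B
    stratum.  Strata where A is inestimable (single level, or no
    within/between pairs) are skipped with a log record.  Returns a pair of
    :class:`AnosimResult` (factor A, factor B).
    """
    a = np.asarray(list(factor_a))
    b = np.asarray(list(factor_b))
    out = []
    for tested, strata, name in ((a, b, names[0]), (b, a, names[1])):
        res = _twoway_single(d, tested, strata, n_perm, seed, name)
        out.append(res)
    return tuple(out)


def _twoway_single(d, tested, strata, n_perm, seed, name) -> AnosimResult:
    stratum_data = []
    for level in pd.unique(strata):
        idx = np.flatnonzero(strata == level)
        got = _stratum_r(d, idx, tested[idx])
        if got is None:
            logger.info("anosim_twoway: factor %s inestimable in stratum %r, skipped", name, level)
            continue
        r_s, (ranks, iu, ju) = got
        stratum_data.append((idx, tested[idx], ranks, iu, ju, r_s))
    if not stratum_data:
        raise ValueError(f"factor {name}: inestimable in every stratum")
    per_r = [s[-1] for s in stratum_data]
    r_obs = float(np.mean(per_r))

    if n_perm is None:
        # exact product-space enumeration of within-stratum assignments
        per_lists = []
        total = 1
        for _, lab, ranks, iu, ju, _ in stratum_data:
            perms = list(multiset_permutations(list(lab)))
            total *= len(perms)
            if total > _EXHAUSTIVE_LIMIT:
                raise ValueError("exhaustive two-way enumeration too large")
            per_lists.append([_anosim_r(ranks, iu, ju, np.asarray(p)) for p in perms])
        count = 0
        target = sum(per_r)
        for combo in itertools.product(*per_lists):
            if sum(combo) >= target - 1e-12:
                count += 1
        return AnosimResult(name, r_obs, count / total, total, "two_way_crossed", per_r)

    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        vals = []
        for _, lab, ranks, iu, ju, _ in stratum_data:
            pl = rng.permutation(lab)
            vals.append(_anosim_r(ranks, iu, ju, pl))
        r_perm[k] = np.mean(vals)
    p_val = float((1 + (r_perm >= r_obs - 1e-12).sum()) / (n_perm + 1))
    return AnosimResult(name, r_obs, p_val, n_perm, "two_way_crossed", per_r)


# ---------------------------------------------------------------------------
# constrained ordination


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        x = pd.get_dummies(x, drop_first=True, dtype=float)
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def _drop_collinear(x: np.ndarray) -> tuple:
    """Greedily keep columns that increase matrix rank; warn about the rest."""
    keep, dropped = [], []
    rank = 0
    for j in range(x.shape[1]):
        trial = x[:, keep + [j]]
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(j)
    if dropped:
        warnings.warn(f"collinear constraint columns dropped: {dropped}")
    return x[:, keep], dropped


def cca(y: OtuTable, x) -> OrdinationResult:
    """Canonical correspondence analysis.

    The community table is chi-square transformed (contingency residuals
    Q = (p_ij - r_i c_j) / sqrt(r_i c_j)) and projected onto the constraints
    by row-weighted least squares; the fitted matrix is decomposed by SVD,
    eigenvalues being squared singular values.  ``prop_explained`` is
    relative to the total inertia of Q; the proportion relative to the
    constrained inertia is in ``extras['prop_explained_constrained']``
    (reported both ways because the "% of variation" convention differs
    between software).
    """
    yv = np.asarray(y.values if isinstance(y, OtuTable) else y, dtype=float)
    if np.any(yv.sum(axis=1) == 0):
        raise ValueError("community table has an all-zero sample row")
    if np.any(yv.sum(axis=0) == 0):
        raise ValueError("community table has an all-zero OTU column")
    xm = _as_matrix(x)
    if xm.shape[0] != yv.shape[0]:
        raise ValueError("constraint rows do not match community samples")

    total = yv.sum()
    p = yv / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    qbar = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    total_inertia = float((qbar**2).sum())

    # weighted centering of constraints (row weights r), then sqrt(r) scaling
    xc = xm - (r[:, None] * xm).sum(axis=0)
    xc, dropped = _drop_collinear(xc)
    xw = np.sqrt(r)[:, None] * xc
    if xw.shape[1] == 0 or np.allclose(xw, 0):
        fitted = np.zeros_like(qbar)
    else:
        beta, *_ = np.linalg.lstsq(xw, qbar, rcond=None)
        fitted = xw @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    tol = (s.max() if s.size else 0.0) * 1e-10
    k = int((s > tol).sum())
    eig = s[:k] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        site = (u[:, :k] * s[:k]) / np.sqrt(r)[:, None]  # LC site scores
        species = vt[:k].T / np.sqrt(c)[:, None]
    # biplot arrows: weighted correlation of constraints with site scores
    if k and xw.shape[1]:
        constraint = np.corrcoef(
            np.hstack([xw, u[:, :k] * s[:k]]), rowvar=False
        )[: xw.shape[1], xw.shape[1]:]
    else:
        constraint = np.zeros((xw.shape[1], k))
    return OrdinationResult(
        eigenvalues=eig,
        prop_explained=eig / total_inertia if total_inertia > 0 else eig,
        site_scores=site,
        species_scores=species,
        constraint_scores=constraint,
        extras={
            "total_inertia": total_inertia,
            "constrained_inertia": float(eig.sum()),
            "prop_explained_constrained": eig / eig.sum() if eig.size and eig.sum() > 0 else eig,
            "dropped_constraints": dropped,
        },
    )


def _residualize(m: np.ndarray, z: np.ndarray) -> np.ndarray:
    zc = np.column_stack([np.ones(len(m)), z])
    beta, *_ = np.linalg.lstsq(zc, m, rcond=None)
    return m - zc @ beta


def rda(y, x, covariates=None) -> OrdinationResult:
    """Redundancy analysis, optionally partial.

    ``y`` (samples x responses) is centered column-wise; with covariates,
    both ``y`` and ``x`` are first residualized on them (partial RDA).  The
    fitted values of the multivariate least-squares regression of y on x
    are eigen-decomposed; R^2 = SS_fitted / SS_total and adjusted R^2
    follows Ezekiel, 1 - (1 - R^2)(n - 1)/(n - m - 1) with m the predictor
    rank.  Raises when n <= m.
    """
    yv = np.asarray(y.values if isinstance(y, OtuTable) else y, dtype=float)
    xm = _as_matrix(x)
    n = yv.shape[0]
    if xm.shape[0] != n:
        raise ValueError("predictor rows do not match response rows")
    yc = yv - yv.mean(axis=0)
    xc = xm - xm.mean(axis=0)
    x_scale = float(np.linalg.norm(xc)) if xc.size else 0.0
    if covariates is not None:
        zm = _as_matrix(covariates)
        if zm.size:
            yc = _residualize(yc, zm)
            xc = _residualize(xc, zm)
    # predictor rank judged against the pre-partialling scale, so directions
    # annihilated by the covariates do not resurface as numerical noise
    if xc.size:
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        keep = s > max(x_scale, 1.0) * 1e-9
        m = int(keep.sum())
    else:
        m = 0
    if n <= m + 1:
        raise ValueError(f"{m} predictors with {n} samples: design underdetermined")
    if m == 0:
        fitted = np.zeros_like(yc)
    else:
        basis = u[:, keep]
        fitted = basis @ (basis.T @ yc)
    ss_total = float((yc**2).sum())
    ss_fitted = float((fitted**2).sum())
    r2 = ss_fitted / ss_total if ss_total > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    tol = (s.max() if s.size else 0.0) * 1e-10
    k = int((s > tol).sum())
    eig = s[:k] ** 2 / max(n - 1, 1)
    return OrdinationResult(
        eigenvalues=eig,
        prop_explained=eig * max(n - 1, 1) / ss_total if ss_total > 0 else eig,
        site_scores=u[:, :k] * s[:k],
        species_scores=vt[:k].T,
        extras={"r_squared": r2, "adj_r_squared": adj, "rank": m, "n": n},
    )


@dataclass
class VariationPartition:
    """Venn decomposition of adjusted R-squared over three predictor blocks."""

    fractions: dict          # unique/pairwise/triple adjusted-R^2 fractions
    residual: float
    total_explained: float
    negative_flagged: list = field(default_factory=list)


def variation_partitioning(y, env, space, time) -> VariationPartition:
    """Partition community variance over environment, space and time blocks.

    Fits the seven nested RDAs (each block, each pair, all three), converts
    each to Ezekiel-adjusted R^2, and solves the inclusion-exclusion system
    for the unique, pairwise-overlap and triple-overlap fractions plus the
    residual.  Negative fractions (a known feature of adjusted-R^2
    partitioning) are reported as computed and flagged.
    """
    blocks = {"env": _as_matrix(env), "space": _as_matrix(space), "time": _as_matrix(time)}
    adj = {}
    for name, bx in blocks.items():
        try:
            adj[frozenset([name])] = rda(y, bx).extras["adj_r_squared"]
        except ValueError as exc:
            raise ValueError(f"block {name!r}: {exc}") from None
    for pair in itertools.combinations(blocks, 2):
        xm = np.hstack([blocks[pair[0]], blocks[pair[1]]])
        adj[frozenset(pair)] = rda(y, xm).extras["adj_r_squared"]
    adj[frozenset(blocks)] = rda(y, np.hstack(list(blocks.values()))).extras["adj_r_squared"]

    # unknowns: a=env only, b=space only, c=time only, d=env&space, e=space&time,
    # f=env&time, g=all three
    names = ["a", "b", "c", "d", "e", "f", "g"]
    contains = {
        "env": {"a", "d", "f", "g"},
        "space": {"b", "d", "e", "g"},
        "time": {"c", "e", "f", "g"},
    }
    keys = list(adj)
    mat = np.zeros((len(keys), 7))
    rhs = np.zeros(len(keys))
    for i, key in enumerate(keys):
        covered = set().union(*(contains[b] for b in key))
        for j, nm in enumerate(names):
            mat[i, j] = 1.0 if nm in covered else 0.0
        rhs[i] = adj[key]
    sol, *_ = np.linalg.lstsq(mat, rhs, rcond=None)

    label = {
        "a": "env",
        "b": "space",
        "c": "time",
        "d": "env&space",
        "e": "space&time",
        "f": "env&time",
        "g": "env&space&time",
    }
    fractions = {label[nm]: float(v) for nm, v in zip(names, sol)}
    total = float(adj[frozenset(blocks)])
    residual = 1.0 - total
    flagged = [k for k, v in fractions.items() if v < 0]
    return VariationPartition(
        fractions=fractions,
        residual=residual,
        total_explained=total,
        negative_flagged=flagged,
    )
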