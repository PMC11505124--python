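"""Permutation statistics for community matrices, written from first
principles: Bray-Curtis dissimilarity, crossed two-factor PERMANOVA via
the Gower-centered partitioning of a distance matrix, Mantel matrix
correlation, and the Mann-Whitney U test with tie-corrected normal
approximation and exact small-sample enumeration.

All permutation p-values use the add-one convention
p = (1 + #{T_perm >= T_obs}) / (n_perm + 1), so the smallest attainable
p is 1/(n_perm + 1) and results are bit-reproducible for a fixed seed.
A single integer seed fans out to independent substreams via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .core import CommunityMatrix, ENV_FACTORS, FFG_CODES, TaxonAttributes, ValidationError


# --------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValidationError("labels do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal must be zero")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]


def bray_curtis(
    data: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = sum|x - y| / sum(x + y) between rows.

    A pair of all-zero rows has an indeterminate quotient; by convention
    their distance is 0 (identical empty communities).
    """
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = [str(i) if not isinstance(i, tuple) else "/".join(map(str, i))
                      for i in data.index]
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(len(x))]
    if (x < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative abundances")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d)


def euclidean(
    data: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Plain Euclidean distance between rows."""
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = [str(i) if not isinstance(i, tuple) else "/".join(map(str, i))
                      for i in data.index]
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if labels is None:
            labels = [str(i) for i in range(len(x))]
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d)


DISTANCES = {"braycurtis": bray_curtis, "euclidean": euclidean}


# --------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Sequential (Type I) partitioning of a distance matrix.

    ``table`` rows are the model terms in fitting order, then Residual
    and Total, with columns df, sum_sq, r_squared, pseudo_F, p_value.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int | None = None

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _gower_center(d: np.ndarray) -> np.ndarray:
    """G = -1/2 J A J with A = d**2 and J the centering matrix; the
    McArdle-Anderson inner-product matrix whose trace is the total sum
    of squares."""
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy(levels: pd.Series) -> np.ndarray:
    cats = pd.Categorical(levels)
    return np.eye(len(cats.categories))[cats.codes]


def _hat(x: np.ndarray) -> np.ndarray:
    # orthogonal projector onto col(x); SVD handles the rank deficiency
    # of full dummy blocks alongside the intercept
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum())
    u = u[:, :rank]
    return u @ u.T


def permanova(
    dm: DistanceMatrix,
    factors: pd.DataFrame | Mapping[str, Sequence],
    terms: Sequence[str] = ("section", "month"),
    interaction: bool = True,
    n_perm: int = 999,
    seed: int | None = None,
    permutations: Literal["random", "exact"] = "random",
) -> PermanovaResult:
    """Crossed-factor PERMANOVA on a distance matrix.

    Sums of squares are sequential in the order of ``terms``; each term's
    pseudo-F is tested against the residual mean square under free
    permutation of the sample labels.  ``permutations="exact"``
    enumerates all n! relabelings (tiny designs only) instead of Monte
    Carlo sampling.
    """
    d = dm.values
    n = len(dm)
    if n < 4:
        raise ValidationError("PERMANOVA needs at least 4 samples")
    fac = pd.DataFrame(factors)
    if len(fac) != n:
        raise ValidationError("factor table does not match distance matrix")
    for t in terms:
        if fac[t].nunique() < 2:
            raise ValidationError(f"factor {t!r} is constant; degenerate design")

    # sequential model matrices: intercept, +term1, +term2, ..., +interaction
    blocks = [np.ones((n, 1))]
    names: list[str] = []
    dfs: list[int] = []
    for t in terms:
        blocks.append(_dummy(fac[t]))
        names.append(t)
        dfs.append(fac[t].nunique() - 1)
    if interaction:
        if len(terms) != 2:
            raise ValidationError("interaction requires exactly two terms")
        combo = fac[terms[0]].astype(str) + "\x00" + fac[terms[1]].astype(str)
        blocks.append(_dummy(combo))
        names.append(" x ".join(terms))
        dfs.append((fac[terms[0]].nunique() - 1) * (fac[terms[1]].nunique() - 1))

    hats = []
    x = blocks[0]
    for b in blocks[1:]:
        x = np.hstack([x, b])
        hats.append(_hat(x))
    h_full = hats[-1]
    ident = np.eye(n)

    g = _gower_center(d)
    # per-term projectors: H_k - H_{k-1}
    projectors = [hats[0] - np.ones((n, n)) / n]
    for k in range(1, len(hats)):
        projectors.append(hats[k] - hats[k - 1])
    resid_proj = ident - h_full

    def _ss(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        term_ss = np.array([float((p * gmat).sum()) for p in projectors])
        return term_ss, float((resid_proj * gmat).sum())

    ss_terms, ss_res = _ss(g)
    ss_total = float(np.trace(g))
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    if permutations == "exact":
        perms = np.array(list(itertools.permutations(range(n))))
        n_used = len(perms) - 1  # identity included in numerator/denominator
        exceed = np.zeros(len(names))
        tol = 1e-9 * np.maximum(1.0, np.abs(f_obs))
        for p in perms:
            gp = g[np.ix_(p, p)]
            ssp, resp = _ss(gp)
            fp = (ssp / np.array(dfs)) / (resp / df_res)
            exceed += fp >= f_obs - tol
        pvals = exceed / len(perms)
        n_report = n_used
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        exceed = np.ones(len(names))  # add-one: observed counts itself
        chunk = 128
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            idx = np.array([rng.permutation(n) for _ in range(b)])
            gp = g[idx[:, :, None], idx[:, None, :]]  # (b, n, n)
            ssp = np.stack([(p * gp).sum(axis=(1, 2)) for p in projectors], axis=1)
            resp = (resid_proj * gp).sum(axis=(1, 2))
            fp = (ssp / np.array(dfs)) / (resp / df_res)[:, None]
            exceed += (fp >= f_obs - 1e-9 * np.maximum(1.0, np.abs(f_obs))).sum(axis=0)
            done += b
        pvals = exceed / (n_perm + 1)
        n_report = n_perm

    rows = []
    for name, df_t, ss_t, f_t, p_t in zip(names, dfs, ss_terms, f_obs, pvals):
        rows.append([name, df_t, ss_t, ss_t / ss_total, f_t, p_t])
    rows.append(["Residual", df_res, ss_res, ss_res / ss_total, np.nan, np.nan])
    rows.append(["Total", n - 1, ss_total, 1.0, np.nan, np.nan])
    table = pd.DataFrame(
        rows, columns=["term", "df", "sum_sq", "r_squared", "pseudo_F", "p_value"]
    ).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_report, seed=seed)


# --------------------------------------------------------------------------
# Mantel


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str = "pearson"


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    method: Literal["pearson", "spearman"] = "pearson",
    alternative: Literal["greater", "two-sided"] = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson (or Spearman) correlation over the upper-triangle
    entries; the null distribution permutes rows and columns of ``d2``
    simultaneously.  Zero variance in either triangle leaves r undefined
    (NaN) with p = NaN.
    """
    if d1.labels != d2.labels:
        raise ValidationError("distance matrices must share label order")
    n = len(d1)
    if n < 4:
        raise ValidationError("Mantel needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    m2 = d2.values
    if method == "spearman":
        x = sps.rankdata(x)

        def tri(mat: np.ndarray) -> np.ndarray:
            return sps.rankdata(mat[iu])
    else:
        def tri(mat: np.ndarray) -> np.ndarray:
            return mat[iu]

    y = tri(m2)
    if np.std(x) == 0 or np.std(y) == 0:
        return MantelResult(float("nan"), float("nan"), n_perm, method)
    xc = (x - x.mean()) / x.std()

    def corr(yv: np.ndarray) -> float:
        return float((xc * (yv - yv.mean()) / yv.std()).mean())

    r_obs = corr(y)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exceed = 1
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_p = corr(tri(m2[np.ix_(p, p)]))
        if alternative == "greater":
            exceed += r_p >= r_obs - 1e-12
        else:
            exceed += abs(r_p) >= abs(r_obs) - 1e-12
    return MantelResult(r_obs, exceed / (n_perm + 1), n_perm, method)


# --------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class MannWhitneyResult:
    """U statistic of the first sample, tie-corrected normal deviate Z
    (continuity-corrected, negative when x tends below y), and two-sided
    p-values: ``p_normal`` always, ``p_exact`` for small samples, and
    ``p`` the preferred one of the two."""

    u: float
    z: float
    p: float
    p_normal: float
    p_exact: float | None
    n_x: int
    n_y: int
    method: str


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U_x = #{(i,j): x_i > y_j} + 0.5 #ties, via midranks."""
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[:nx].sum()
    return float(rx - nx * (nx + 1) / 2)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["auto", "normal", "exact"] = "auto",
    exact_limit: int = 10,
) -> MannWhitneyResult:
    """Two-sample Mann-Whitney (Wilcoxon rank-sum) test.

    The normal approximation uses the tie-corrected variance and a 0.5
    continuity correction; for small pooled sizes (``auto`` with
    n_x + n_y <= exact_limit) the exact two-sided p is obtained by
    enumerating every split of the pooled values and counting U values
    at least as far from the null mean as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValidationError("both samples must be non-empty")
    u = _u_statistic(x, y)
    mu = nx * ny / 2

    pooled = np.concatenate([x, y])
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = nx * ny / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        z = 0.0
        p_normal = 1.0
    else:
        diff = u - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
        p_normal = float(2 * special.ndtr(-abs(z)))
        p_normal = min(1.0, p_normal)

    p_exact = None
    use_exact = method == "exact" or (method == "auto" and n <= exact_limit)
    if use_exact:
        dev = abs(u - mu)
        hits = 0
        total = 0
        for comb in itertools.combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            u_p = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_p - mu) >= dev - 1e-12:
                hits += 1
            total += 1
        p_exact = hits / total

    if p_exact is not None:
        return MannWhitneyResult(u, z, p_exact, p_normal, p_exact, nx, ny, "exact")
    return MannWhitneyResult(u, z, p_normal, p_normal, None, nx, ny, "normal")


# --------------------------------------------------------------------------
# Mantel screen: FFG x environmental factor x month


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Deterministically fan one seed out to n child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def mantel_screen(
    matrix: CommunityMatrix,
    attrs: Mapping[str, TaxonAttributes],
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    method: Literal["pearson", "spearman"] = "pearson",
) -> pd.DataFrame:
    """Per-month Mantel grid: FFG community distance vs. single-factor
    environmental distance.

    For each month, the community distance of one FFG is Bray-Curtis on
    the sub-matrix of that FFG's taxa; the environmental distance is
    Euclidean on the z-standardized factor column.  Cells where the FFG
    is absent in that month, or the factor is constant, are NaN.
    """
    from .ffg import _ffg_of

    ffg = _ffg_of(matrix, attrs)
    months = list(dict.fromkeys(matrix.meta["month"]))
    seeds = iter(spawn_seeds(seed, len(months) * len(FFG_CODES) * len(ENV_FACTORS)))
    rows = []
    for month in months:
        mask = (matrix.meta["month"] == month).to_numpy()
        dens = matrix.density.loc[mask]
        env_m = env.loc[dens.index]
        for g in FFG_CODES:
            taxa_g = ffg[ffg == g].index
            sub = dens[taxa_g]
            absent = sub.to_numpy().sum() == 0
            d_comm = None if absent else bray_curtis(sub)
            for factor in ENV_FACTORS:
                s = next(seeds)
                col = env_m[factor].to_numpy(dtype=float)
                if absent or np.std(col) == 0:
                    rows.append({"month": month, "ffg": g, "factor": factor,
                                 "r": np.nan, "p_value": np.nan})
                    continue
                zcol = (col - col.mean()) / col.std()
                d_env = euclidean(zcol[:, None], labels=d_comm.labels)
                res = mantel(d_comm, d_env, n_perm=n_perm, seed=s, method=method)
                rows.append({"month": month, "ffg": g, "factor": factor,
                             "r": res.r, "p_value": res.p_value})
    return pd.DataFrame(rows)
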