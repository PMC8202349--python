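"""Community statistics: abundance thresholding, log normalization,
site-conditioned redundancy analysis with permutation tests, indicator
species (IndVal) analysis and Kruskal-Wallis comparisons.

The workflow mirrors the classical grazing-experiment analysis: OTU
counts are converted to relative abundances, OTUs below a relative
abundance of 0.001 in a sample are treated as absent there, the matrix is
log transformed, and treatment/date/interaction/CH4-rate effects are
tested by partial RDA with the study sites as the conditioning factor.
Bioindicator OTUs per treatment are found with the IndVal statistic
(specificity x fidelity) and a permutation test at alpha = 0.001 on
10 000 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatsParams:
    """Defaults follow the study protocol: absence below 0.001 relative
    abundance, log base 2, 10 000 permutations, bioindicator alpha 0.001."""

    absence_threshold: float = 0.001
    log_base: float = 2.0
    n_permutations: int = 10_000
    bioindicator_alpha: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.absence_threshold < 1.0:
            raise ValueError("absence_threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.bioindicator_alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.log_base <= 1.0:
            raise ValueError("log_base must be > 1")


# --------------------------------------------------------------------------
# Matrix preparation
# --------------------------------------------------------------------------

def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each row (sample) by its total count."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("sample with zero total count")
    return counts.div(totals, axis=0)


def threshold_relative_abundance(
    M: pd.DataFrame, p: StatsParams = StatsParams()
) -> pd.DataFrame:
    """Set entries strictly below the absence threshold to zero.

    No renormalization is applied; columns that become all-zero are kept.
    """
    if (M.values < 0).any():
        raise ValueError("negative entries")
    out = M.copy()
    out[out < p.absence_threshold] = 0.0
    return out


def log_normalize(M: pd.DataFrame, p: StatsParams = StatsParams()) -> pd.DataFrame:
    """Log transform x -> log_b(x) + 1 for x > 0, 0 stays 0.

    If the matrix contains non-integer values (e.g. relative abundances)
    the whole matrix is first divided by its smallest positive entry, so
    the smallest observed value maps to exactly 1 and all transformed
    values remain non-negative.
    """
    X = M.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative entries")
    pos = X[X > 0]
    if pos.size and not np.allclose(X, np.round(X)):
        X = X / pos.min()
    out = np.zeros_like(X)
    nz = X > 0
    out[nz] = np.log(X[nz]) / np.log(p.log_base) + 1.0
    return pd.DataFrame(out, index=M.index, columns=M.columns)


# --------------------------------------------------------------------------
# Design matrices
# --------------------------------------------------------------------------

def _dummy(values: pd.Series) -> np.ndarray:
    """Treatment-contrast dummy coding (first level dropped)."""
    d = pd.get_dummies(values.astype("category"), drop_first=True)
    return d.to_numpy(dtype=float)


def design_matrices(
    metadata: pd.DataFrame,
    terms: Sequence[str] = ("treatment", "date", "treatment:date", "ch4_rate"),
    condition: Optional[str] = "site",
) -> tuple[dict[str, np.ndarray], Optional[np.ndarray]]:
    """Build ordered explanatory term blocks and the conditioning block.

    Factor columns are dummy-coded; ``a:b`` denotes the interaction of two
    factors (products of their dummy columns); numeric columns are used
    as-is (one centered column).
    """
    blocks: dict[str, np.ndarray] = {}
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            da, db = _dummy(metadata[a]), _dummy(metadata[b])
            cols = [da[:, i] * db[:, j] for i in range(da.shape[1]) for j in range(db.shape[1])]
            blocks[term] = np.column_stack(cols) if cols else np.empty((len(metadata), 0))
        elif pd.api.types.is_numeric_dtype(metadata[term]):
            x = metadata[term].to_numpy(dtype=float)
            blocks[term] = (x - x.mean())[:, None]
        else:
            blocks[term] = _dummy(metadata[term])
    Z = None
    if condition is not None:
        Z = _dummy(metadata[condition])
    return blocks, Z


# --------------------------------------------------------------------------
# Partial RDA
# --------------------------------------------------------------------------

def _orthonormal_basis(A: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of A (rank-revealing SVD)."""
    if A.size == 0:
        return np.empty((A.shape[0], 0))
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    r = int((s > tol * max(A.shape) * (s[0] if s.size else 1.0)).sum())
    return U[:, :r]


@dataclass
class RDAResult:
    """Fitted partial redundancy analysis.

    Inertias are on the variance scale (sums of squares divided by n-1) so
    that conditioned + constrained + unconstrained = total variance of the
    centered response.
    """

    terms: list[str]
    total_inertia: float
    conditioned_inertia: float
    constrained_inertia: float
    unconstrained_inertia: float
    eigenvalues: np.ndarray
    sample_scores: pd.DataFrame
    otu_scores: pd.DataFrame
    term_df: dict[str, int]
    residual_df: int
    # internals reused by the permutation test
    _Yc: np.ndarray = field(repr=False, default=None)
    _Qz: np.ndarray = field(repr=False, default=None)
    _term_blocks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def partial_rda(
    Y: pd.DataFrame,
    X_terms: Mapping[str, np.ndarray],
    Z: Optional[np.ndarray] = None,
) -> RDAResult:
    """Redundancy analysis of Y on the X terms, conditioned on Z.

    Y columns are centered; Y and every X block are residualized on the
    conditioning block (plus intercept); the constrained space is the
    column space of the residualized X, and the constrained axes are the
    singular directions of the fitted values.
    """
    Yv = Y.to_numpy(dtype=float)
    n, p = Yv.shape
    Yc = Yv - Yv.mean(axis=0)

    ones = np.ones((n, 1))
    Zfull = ones if Z is None or Z.size == 0 else np.column_stack([ones, Z])
    Qz = _orthonormal_basis(Zfull)

    blocks = {t: np.asarray(b, dtype=float) for t, b in X_terms.items()}
    X_all = np.column_stack([b for b in blocks.values()]) if blocks else np.empty((n, 0))
    Qzx = _orthonormal_basis(np.column_stack([Zfull, X_all]))

    # sequential rank increments per term
    term_df: dict[str, int] = {}
    running = Zfull
    prev_rank = Qz.shape[1]
    for t, b in blocks.items():
        running = np.column_stack([running, b])
        r = _orthonormal_basis(running).shape[1]
        term_df[t] = r - prev_rank
        if term_df[t] == 0:
            # a constant block spans nothing beyond the intercept and simply
            # contributes no constrained inertia; anything else with zero
            # marginal rank is aliased with earlier terms or the condition
            centered = b - b.mean(axis=0) if b.size else b
            if b.size and np.abs(centered).max() > 1e-12:
                raise np.linalg.LinAlgError(
                    f"term '{t}' is aliased with the condition or earlier terms")
        prev_rank = r

    fit_z = Qz @ (Qz.T @ Yc)
    Yr = Yc - fit_z
    fit_full = Qzx @ (Qzx.T @ Yc)
    fitted = fit_full - fit_z          # constrained component
    resid = Yc - fit_full

    denom = n - 1
    total = float((Yc ** 2).sum()) / denom
    conditioned = float((fit_z ** 2).sum()) / denom
    constrained = float((fitted ** 2).sum()) / denom
    unconstrained = float((resid ** 2).sum()) / denom

    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s ** 2 / denom
    keep = eig > max(1e-12, 1e-9 * (eig[0] if eig.size else 1.0))
    n_axes = int(keep.sum())
    axes = [f"RDA{i + 1}" for i in range(n_axes)]
    sample_scores = pd.DataFrame(U[:, :n_axes] * s[:n_axes], index=Y.index, columns=axes)
    otu_scores = pd.DataFrame(Vt[:n_axes].T, index=Y.columns, columns=axes)

    residual_df = n - Qzx.shape[1]
    if residual_df < 1:
        raise ValueError("no residual degrees of freedom")

    return RDAResult(
        terms=list(blocks),
        total_inertia=total,
        conditioned_inertia=conditioned,
        constrained_inertia=constrained,
        unconstrained_inertia=unconstrained,
        eigenvalues=eig[:n_axes],
        sample_scores=sample_scores,
        otu_scores=otu_scores,
        term_df=term_df,
        residual_df=residual_df,
        _Yc=Yc,
        _Qz=Qz,
        _term_blocks=blocks,
    )


def permutation_test(
    result: RDAResult,
    p: StatsParams = StatsParams(),
    scope: str = "terms",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Permutation tests of the fitted partial RDA.

    ``scope='model'`` tests the joint effect of all terms; ``'terms'``
    tests each term sequentially in formula order (each against the model
    with the preceding terms); ``'axes'`` tests each constrained axis.
    The null is generated by permuting the rows of the reduced-model
    residuals while the fitted reduced-model part (condition included)
    stays in place.  p = (1 + #{F* >= F}) / (1 + m).
    """
    if scope not in ("terms", "model", "axes"):
        raise ValueError("scope must be 'terms', 'model' or 'axes'")
    m = p.n_permutations
    rng = np.random.default_rng(seed)
    Yc, Qz = result._Yc, result._Qz
    n = Yc.shape[0]
    blocks = result._term_blocks
    Zcols = Qz  # orthonormal, includes intercept

    X_all = np.column_stack(list(blocks.values())) if blocks else np.empty((n, 0))
    Qfull = _orthonormal_basis(np.column_stack([Zcols, X_all]))
    df_res = result.residual_df

    def fstats(Y: np.ndarray, Qred: np.ndarray, Qbig: np.ndarray, df_num: int) -> float:
        ss_big = float(((Qbig.T @ Y) ** 2).sum())
        ss_red = float(((Qred.T @ Y) ** 2).sum())
        rss = float((Y ** 2).sum()) - float(((Qfull.T @ Y) ** 2).sum())
        return ((ss_big - ss_red) / df_num) / (rss / df_res)

    rows = []
    if scope == "model":
        df_num = Qfull.shape[1] - Qz.shape[1]
        F_obs = fstats(Yc, Qz, Qfull, df_num)
        fit_red = Qz @ (Qz.T @ Yc)
        E = Yc - fit_red
        count = 0
        for _ in range(m):
            Yp = fit_red + E[rng.permutation(n)]
            if fstats(Yp, Qz, Qfull, df_num) >= F_obs:
                count += 1
        rows.append(("model", df_num, F_obs, (1 + count) / (1 + m)))
    elif scope == "terms":
        running = [Zcols]
        Qred = Zcols
        for t, b in blocks.items():
            Qbig = _orthonormal_basis(np.column_stack(running + [b]))
            df_num = result.term_df[t]
            if df_num == 0:
                rows.append((t, 0, float("nan"), 1.0))
                running.append(b)
                Qred = Qbig
                continue
            F_obs = fstats(Yc, Qred, Qbig, df_num)
            fit_red = Qred @ (Qred.T @ Yc)
            E = Yc - fit_red
            count = 0
            for _ in range(m):
                Yp = fit_red + E[rng.permutation(n)]
                if fstats(Yp, Qred, Qbig, df_num) >= F_obs:
                    count += 1
            rows.append((t, df_num, F_obs, (1 + count) / (1 + m)))
            running.append(b)
            Qred = Qbig
    else:  # axes
        fit_red = Qz @ (Qz.T @ Yc)
        E = Yc - fit_red
        unconstr = result.unconstrained_inertia
        for k, lam in enumerate(result.eigenvalues):
            F_obs = lam / (unconstr / df_res) if unconstr > 0 else np.inf
            count = 0
            for _ in range(m):
                Yp = fit_red + E[rng.permutation(n)]
                fit_full = Qfull @ (Qfull.T @ Yp)
                fitted = fit_full - Qz @ (Qz.T @ Yp)
                s = np.linalg.svd(fitted, compute_uv=False)
                eig = s ** 2 / (n - 1)
                rss = float(((Yp - fit_full) ** 2).sum()) / (n - 1)
                lam_p = eig[k] if k < eig.size else 0.0
                Fp = lam_p / (rss / df_res) if rss > 0 else np.inf
                if Fp >= F_obs:
                    count += 1
            rows.append((f"RDA{k + 1}", 1, F_obs, (1 + count) / (1 + m)))
    return pd.DataFrame(rows, columns=["term", "df", "F", "p"]).set_index("term")


# --------------------------------------------------------------------------
# IndVal indicator species analysis
# --------------------------------------------------------------------------

def indval(
    M: pd.DataFrame,
    groups: Sequence[str],
    p: StatsParams = StatsParams(),
    seed: Optional[int] = None,
    method: str = "sampled",
) -> pd.DataFrame:
    """Indicator value analysis of each OTU against a sample grouping.

    For OTU j in group k, specificity A = mean abundance in k divided by
    the sum of the group means, fidelity B = occurrence frequency within
    k, and IndVal = A * B.  Each OTU's statistic is its maximum over
    groups; significance is the probability of a strictly higher statistic
    under random relabeling of the samples ((1 + exceedances) / (1 + m)).

    With ``method='exact'`` all n! relabelings are enumerated instead of
    sampling (small n only); p = (1 + exceedances) / (1 + n!).

    Returns a DataFrame indexed by OTU id with columns group, A, B,
    indval, p and bioindicator (p < alpha).
    """
    X = M.to_numpy(dtype=float)
    n = X.shape[0]
    labels = np.asarray(groups)
    if len(labels) != n:
        raise ValueError("groups length must match samples")
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least two groups")
    G = np.zeros((k, n))
    G[inv, np.arange(n)] = 1.0
    sizes = G.sum(axis=1)
    if (sizes == 0).any():
        raise ValueError("group with zero samples")

    def stat(Gm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        means = (Gm @ X) / sizes[:, None]
        tot = means.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(tot > 0, means / np.where(tot > 0, tot, 1.0), 0.0)
        B = (Gm @ (X > 0)) / sizes[:, None]
        IV = A * B
        best = IV.max(axis=0)
        which = IV.argmax(axis=0)
        return IV, best, which, A

    IV, best, which, A_mat = stat(G)
    B_mat = (G @ (X > 0)) / sizes[:, None]

    exceed = np.zeros(X.shape[1], dtype=np.int64)
    if method == "exact":
        from itertools import permutations as _perms
        from math import factorial
        if factorial(n) > 50_000:
            raise ValueError("exact enumeration infeasible for this n")
        m_eff = 0
        for perm in _perms(range(n)):
            _, best_p, _, _ = stat(G[:, list(perm)])
            exceed += best_p > best
            m_eff += 1
    elif method == "sampled":
        rng = np.random.default_rng(seed)
        m_eff = p.n_permutations
        for _ in range(m_eff):
            perm = rng.permutation(n)
            _, best_p, _, _ = stat(G[:, perm])
            exceed += best_p > best
    else:
        raise ValueError("method must be 'sampled' or 'exact'")
    pvals = (1 + exceed) / (1 + m_eff)

    idx = np.arange(X.shape[1])
    return pd.DataFrame(
        {
            "group": uniq[which],
            "A": A_mat[which, idx],
            "B": B_mat[which, idx],
            "indval": best,
            "p": pvals,
            "bioindicator": pvals < p.bioindicator_alpha,
        },
        index=M.columns,
    )


# --------------------------------------------------------------------------
# Kruskal-Wallis
# --------------------------------------------------------------------------

def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis rank sum test (tie-corrected H, chi-squared p).

    Degenerate input where every observation is identical returns H = 0,
    p = 1 instead of failing.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    H, pval = sps.kruskal(*groups)
    return float(H), float(pval)
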