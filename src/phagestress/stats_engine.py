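"""Shared statistical machinery.

Ordinary least squares on explicit design matrices, sequential (Type I)
ANOVA, one/two-tailed t-tests, Bonferroni adjustment, Tukey-Kramer HSD with
studentized-range p-values, Welch's t-test, and a compact letter display.

Everything here is deterministic: no random number generation occurs in this
module. Factor encoding convention: treatment contrasts (dummy coding) with
the first level in sorted order as baseline unless a reference level is
pinned by the caller; coefficient values (not fitted values) depend on this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearModelFit",
    "TukeyComparison",
    "fit_ols",
    "sequential_anova",
    "tukey_hsd",
    "compact_letters",
    "welch_t",
    "bonferroni",
    "one_tailed_p",
]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (aliased columns)."""


@dataclass
class LinearModelFit:
    """A least-squares fit with the pieces t/F machinery needs.

    coefficients and cov_matrix are indexed by coefficient name;
    term_assignments maps each coefficient to the model term it belongs to.
    """

    coefficients: pd.Series
    cov_matrix: pd.DataFrame
    residual_df: int
    residual_ss: float
    n_obs: int
    term_assignments: dict[str, str] = field(default_factory=dict)

    @property
    def residual_ms(self) -> float:
        if self.residual_df == 0:
            return np.nan
        return self.residual_ss / self.residual_df

    def std_err(self, name: str) -> float:
        return float(np.sqrt(self.cov_matrix.loc[name, name]))


def fit_ols(design: pd.DataFrame, response: np.ndarray | pd.Series,
            term_assignments: dict[str, str] | None = None) -> LinearModelFit:
    """Least-squares fit of `response` on the columns of `design`.

    Raises RankDeficientError naming aliased columns, and ValueError on
    non-finite responses or more columns than rows.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise ValueError("response length does not match design rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if not np.all(np.isfinite(X)):
        raise ValueError("design contains non-finite values")
    n, p = X.shape
    if n < p:
        raise ValueError(f"fewer rows ({n}) than coefficients ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        aliased = _aliased_columns(X, list(design.columns))
        raise RankDeficientError(
            "rank-deficient design; aliased columns: " + ", ".join(aliased))

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss / df_resid if df_resid > 0 else 0.0
    cov = xtx_inv * sigma2
    cov = (cov + cov.T) / 2.0  # enforce exact symmetry
    names = list(design.columns)
    return LinearModelFit(
        coefficients=pd.Series(beta, index=names),
        cov_matrix=pd.DataFrame(cov, index=names, columns=names),
        residual_df=df_resid,
        residual_ss=rss,
        n_obs=n,
        term_assignments=dict(term_assignments or {c: c for c in names}),
    )


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    aliased = []
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.hstack([kept, X[:, j:j + 1]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            aliased.append(name)
    return aliased


def sequential_anova(design: pd.DataFrame, response: np.ndarray | pd.Series,
                     terms: list[tuple[str, list[str]]],
                     include_intercept: bool = True) -> pd.DataFrame:
    """Sequential (Type I) ANOVA over an ordered list of model terms.

    `terms` is an ordered list of (term_name, design_column_names). Each term
    adds its columns to the columns of all preceding terms; SS(term) is the
    drop in residual sum of squares, computed by projection on successively
    orthogonalized column blocks (equivalent to nested re-fits but one pass).
    F uses the full model's residual mean square. When `include_intercept`
    a grand-mean column is fitted first and not reported, matching the usual
    ANOVA table convention.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")

    blocks: list[tuple[str, np.ndarray]] = []
    if include_intercept:
        blocks.append(("(Intercept)", np.ones((n, 1))))
    for name, cols in terms:
        missing = [c for c in cols if c not in design.columns]
        if missing:
            raise ValueError(f"term {name!r} references unknown columns {missing}")
        blocks.append((name, np.asarray(design[cols], dtype=float)))

    # Successively orthogonalize each block against everything before it;
    # the projection of y onto the orthogonalized block is that term's
    # sequential SS (identical to RSS(reduced) - RSS(fuller)).
    Q_prev = np.empty((n, 0))
    rows = []
    resid = y.copy()
    for name, B in blocks:
        if Q_prev.shape[1]:
            # two-pass orthogonalization guards against the precision loss
            # of classical Gram-Schmidt on near-collinear blocks
            B = B - Q_prev @ (Q_prev.T @ B)
            B = B - Q_prev @ (Q_prev.T @ B)
        # SVD-based orthonormal basis: rank decisions by singular value,
        # robust where unpivoted QR diagonals are not
        U, sv, _ = np.linalg.svd(B, full_matrices=False)
        scale = sv.max() if sv.size else 0.0
        Qb = U[:, sv > 1e-9 * max(scale, 1e-300)]
        df_term = Qb.shape[1]
        proj = Qb @ (Qb.T @ resid)
        ss = float(proj @ proj)
        resid = resid - proj
        Q_prev = np.hstack([Q_prev, Qb])
        if name != "(Intercept)":
            rows.append({"term": name, "df": df_term, "sum_sq": ss})

    rss = float(resid @ resid)
    df_resid = n - Q_prev.shape[1]
    if df_resid <= 0:
        raise ValueError("saturated model: zero residual degrees of freedom")
    ms_resid = rss / df_resid
    for row in rows:
        row["mean_sq"] = row["sum_sq"] / row["df"] if row["df"] else np.nan
        if ms_resid > 0 and row["df"]:
            row["F"] = row["mean_sq"] / ms_resid
            row["p"] = float(stats.f.sf(row["F"], row["df"], df_resid))
        else:
            row["F"] = np.nan
            row["p"] = np.nan
    rows.append({"term": "Residual", "df": df_resid, "sum_sq": rss,
                 "mean_sq": ms_resid, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


@dataclass
class TukeyComparison:
    level_a: str
    level_b: str
    diff: float
    q_stat: float
    p_adj: float
    significant: bool


def tukey_hsd(group_means: dict[str, float], group_ns: dict[str, int],
              mse: float, df_resid: int, alpha: float = 0.05) -> list[TukeyComparison]:
    """All-pairs Tukey(-Kramer) HSD from group summaries.

    q = |mean_a - mean_b| / sqrt(mse/2 * (1/n_a + 1/n_b)); the adjusted p is
    the studentized-range tail probability with k groups and `df_resid`
    error degrees of freedom. Unequal group sizes use the Kramer form.
    """
    levels = sorted(group_means)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if not mse > 0:
        raise ValueError("mse must be positive (zero residual variance)")
    k = len(levels)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = group_means[b] - group_means[a]
            se = np.sqrt(mse / 2.0 * (1.0 / group_ns[a] + 1.0 / group_ns[b]))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_resid))
            p = min(1.0, max(p, np.finfo(float).tiny))
            out.append(TukeyComparison(a, b, float(diff), float(q), p, p < alpha))
    return out


def compact_letters(comparisons: list[TukeyComparison],
                    levels: list[str] | None = None,
                    alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from pairwise adjusted p-values.

    Levels that are *not* significantly different (p_adj >= alpha) share at
    least one letter. Built by insert-and-absorb: starting from one group of
    all levels, each significant pair splits every group containing both
    into two groups (each missing one member), then groups contained in
    others are absorbed. The display is not unique, but the sharing relation
    it encodes is exactly p_adj >= alpha.
    """
    if levels is None:
        levels = sorted({c.level_a for c in comparisons} |
                        {c.level_b for c in comparisons})
    groups: list[set[str]] = [set(levels)]
    for c in comparisons:
        if c.p_adj >= alpha:
            continue
        nxt = []
        for g in groups:
            if c.level_a in g and c.level_b in g:
                nxt.append(g - {c.level_a})
                nxt.append(g - {c.level_b})
            else:
                nxt.append(g)
        # absorb duplicates / subsets
        groups = [g for i, g in enumerate(nxt)
                  if g and not any(i != j and g <= h and (g < h or i > j)
                                   for j, h in enumerate(nxt))]
    groups.sort(key=lambda g: min(levels.index(l) for l in g))
    letters = {lev: "" for lev in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lev in sorted(g, key=levels.index):
            letters[lev] += letter
    return letters


def welch_t(sample_a, sample_b) -> dict[str, float]:
    """Welch two-sample t-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p_two_sided": 1.0}
        raise ValueError("both samples degenerate with unequal means")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return {"t": float(t), "df": float(df), "p_two_sided": min(1.0, p)}


def one_tailed_p(t_value: float, df: int, direction: str = "less") -> float:
    """P(T_df <= t) for direction='less', P(T_df >= t) for 'greater'."""
    if direction == "less":
        return float(stats.t.cdf(t_value, df))
    if direction == "greater":
        return float(stats.t.sf(t_value, df))
    raise ValueError(f"unknown direction {direction!r}")


def bonferroni(p: float, m: int) -> float:
    """min(1, m*p); m is the number of tests in the family."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)
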