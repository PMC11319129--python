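"""Inferential layer: two-way ANOVA, LSD multiple comparisons with
compact letter displays, Pearson correlation matrices, and polynomial
trend fits with confidence bands.

The core ANOVA path targets the balanced age x N factorial (fixed
effects, interaction included, no block term by default) and uses the
closed-form cell-means decomposition; unbalanced data fall back to
Type-II sums of squares via statsmodels with a warning.  LSD pairwise
comparisons are deliberately unadjusted for multiplicity.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError, DesignError, DomainError

ALPHA_DEFAULT = 0.05


# --------------------------------------------------------------------------
# two-way ANOVA

@dataclass
class AnovaTable:
    """Fixed-effects two-way ANOVA table with interaction.

    ``terms`` maps term name (factor A, factor B, "A:B", "Residual") to a
    dict with df, ss, ms, F, p.  In balanced designs the term sums of
    squares add to the total sum of squares and the dfs add to n - 1.
    """

    terms: dict
    n: int
    balanced: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.terms, orient="index")

    def __getitem__(self, term):
        return self.terms[term]


def two_way_anova(y, a, b, names=("A", "B"), include_block=None) -> AnovaTable:
    """Two-way fixed-effects ANOVA with interaction.

    Parameters
    ----------
    y : array-like of responses
    a, b : array-like of factor labels (same length as y)
    names : names for the two factors in the output table
    include_block : optional array of block labels added as an additive
        term (removed from the residual), off by default.

    Balanced designs use the exact cell-means decomposition; unbalanced
    ones fall back to Type-II sums of squares (statsmodels) with a warning.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    if not (len(y) == len(a) == len(b)):
        raise ContractError("y, a, b must have equal length")
    lev_a, ia = np.unique(a, return_inverse=True)
    lev_b, ib = np.unique(b, return_inverse=True)
    n = y.size
    cells = len(lev_a) * len(lev_b)
    counts = np.zeros((len(lev_a), len(lev_b)), dtype=int)
    np.add.at(counts, (ia, ib), 1)
    if (counts == 0).any():
        empty = [(lev_a[i], lev_b[j]) for i, j in zip(*np.nonzero(counts == 0))]
        raise DesignError(f"empty design cell(s): {empty}")
    if n - cells < 1:
        raise DesignError("zero residual degrees of freedom")
    balanced = counts.min() == counts.max()

    if include_block is not None or not balanced:
        if not balanced:
            warnings.warn(
                "unbalanced design: using Type-II sums of squares", stacklevel=2
            )
        return _anova_unbalanced(y, a, b, names, include_block, balanced, n)

    r = counts[0, 0]
    gm = y.mean()
    sums = np.zeros((len(lev_a), len(lev_b)))
    np.add.at(sums, (ia, ib), y)
    cell_means = sums / r
    mean_a = cell_means.mean(axis=1)
    mean_b = cell_means.mean(axis=0)
    ss_a = len(lev_b) * r * ((mean_a - gm) ** 2).sum()
    ss_b = len(lev_a) * r * ((mean_b - gm) ** 2).sum()
    inter = cell_means - mean_a[:, None] - mean_b[None, :] + gm
    ss_ab = r * (inter ** 2).sum()
    ss_e = ((y - cell_means[ia, ib]) ** 2).sum()

    df_a = len(lev_a) - 1
    df_b = len(lev_b) - 1
    df_ab = df_a * df_b
    df_e = n - cells
    ms_e = ss_e / df_e
    terms = {}
    for name, ss, df in (
        (names[0], ss_a, df_a),
        (names[1], ss_b, df_b),
        (f"{names[0]}:{names[1]}", ss_ab, df_ab),
    ):
        ms = ss / df
        if ms_e == 0:
            warnings.warn("zero residual variance: F undefined", stacklevel=2)
            F = p = float("nan")
        else:
            F = ms / ms_e
            p = float(sps.f.sf(F, df, df_e))
        terms[name] = {"df": df, "ss": ss, "ms": ms, "F": F, "p": p}
    terms["Residual"] = {
        "df": df_e, "ss": ss_e, "ms": ms_e, "F": float("nan"), "p": float("nan")
    }
    return AnovaTable(terms=terms, n=n, balanced=True)


def _anova_unbalanced(y, a, b, names, block, balanced, n):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "A": a.astype(str), "B": b.astype(str)})
    formula = "y ~ C(A) * C(B)"
    if block is not None:
        df["blk"] = np.asarray(block).astype(str)
        formula += " + C(blk)"
    fit = smf.ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    rename = {
        "C(A)": names[0],
        "C(B)": names[1],
        "C(A):C(B)": f"{names[0]}:{names[1]}",
        "C(blk)": "Block",
    }
    terms = {}
    for row_name, row in tab.iterrows():
        name = rename.get(row_name, row_name)
        terms[name] = {
            "df": int(row["df"]),
            "ss": float(row["sum_sq"]),
            "ms": float(row["sum_sq"] / row["df"]),
            "F": float(row["F"]) if np.isfinite(row["F"]) else float("nan"),
            "p": float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else float("nan"),
        }
    return AnovaTable(terms=terms, n=n, balanced=balanced)


# --------------------------------------------------------------------------
# LSD pairwise comparisons + compact letter display

@dataclass
class LetterDisplay:
    """Compact letter display: groups sharing a letter are not
    significantly different by the unadjusted LSD t-test."""

    letters: dict            # group -> letter string, e.g. "ab"
    means: dict              # group -> mean
    alpha: float
    pairwise: pd.DataFrame = field(repr=False, default=None)


def lsd_pairwise(
    means: dict,
    n_per_group: dict | int,
    mse: float,
    df_e: int,
    alpha: float = ALPHA_DEFAULT,
) -> LetterDisplay:
    """All-pairs LSD t-tests on the ANOVA residual mean square.

    t_ij = (m_i - m_j) / sqrt(MSE (1/n_i + 1/n_j)), two-sided p on df_e.
    Letters are assigned from the maximal cliques of the non-significance
    graph, ordered by descending clique-best mean, so two groups share a
    letter exactly when their pairwise p >= alpha.
    """
    if mse <= 0 or not np.isfinite(mse):
        raise DomainError(f"mse must be > 0, got {mse}")
    if df_e < 1:
        raise DomainError(f"df_e must be >= 1, got {df_e}")
    groups = list(means)
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in groups}
    rows = []
    nonsig = {g: {g} for g in groups}
    for g1, g2 in itertools.combinations(groups, 2):
        se = np.sqrt(mse * (1.0 / n_per_group[g1] + 1.0 / n_per_group[g2]))
        t = (means[g1] - means[g2]) / se
        p = float(2.0 * sps.t.sf(abs(t), df_e))
        rows.append({"group1": g1, "group2": g2, "t": float(t), "p": p,
                     "significant": p < alpha})
        if p >= alpha:
            nonsig[g1].add(g2)
            nonsig[g2].add(g1)
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "t", "p", "significant"])
    letters = _compact_letters(groups, means, nonsig)
    return LetterDisplay(letters=letters, means=dict(means), alpha=alpha,
                         pairwise=pairwise)


def _compact_letters(groups, means, nonsig):
    """Maximal cliques of the non-significance graph -> letters a, b, c...

    Group counts here are small (N levels, age classes), so subset
    enumeration is exact and cheap.
    """
    if len(groups) > 20:
        raise DomainError("compact letter display supports at most 20 groups")
    idx = {g: i for i, g in enumerate(groups)}
    adj = [set() for _ in groups]
    for g in groups:
        for h in nonsig[g]:
            adj[idx[g]].add(idx[h])
    cliques = []
    order = list(range(len(groups)))
    for size in range(len(groups), 0, -1):
        for combo in itertools.combinations(order, size):
            s = set(combo)
            if all(s <= adj[i] | {i} for i in combo):
                if not any(s < c for c in cliques):
                    if not any(s <= c for c in cliques):
                        cliques.append(s)
    # order cliques by the best (largest) mean they contain, descending
    cliques.sort(key=lambda c: -max(means[groups[i]] for i in c))
    alphabet = "abcdefghijklmnopqrst"
    letters = {g: "" for g in groups}
    for letter, c in zip(alphabet, cliques):
        for i in sorted(c, key=lambda i: -means[groups[i]]):
            letters[groups[i]] += letter
    return letters


# --------------------------------------------------------------------------
# Pearson correlation matrix

def pearson_matrix(data) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p for named value vectors.

    ``data`` is a DataFrame or a dict of equal-length vectors.  Each pair
    uses its complete cases and needs n >= 3; zero-variance variables get
    NaN with a warning.  Returns (r_matrix, p_matrix), symmetric with a
    unit diagonal.
    """
    df = pd.DataFrame(data)
    cols = list(df.columns)
    k = len(cols)
    r_mat = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p_mat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for c1, c2 in itertools.combinations(cols, 2):
        sub = df[[c1, c2]].dropna()
        if len(sub) < 3:
            raise DomainError(f"pair ({c1}, {c2}) has n < 3 complete cases")
        x, y = sub[c1].to_numpy(float), sub[c2].to_numpy(float)
        if (x == x[0]).all() or (y == y[0]).all():
            warnings.warn(f"zero variance in pair ({c1}, {c2}); r undefined")
            r, p = float("nan"), float("nan")
        else:
            res = sps.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        r_mat.loc[c1, c2] = r_mat.loc[c2, c1] = r
        p_mat.loc[c1, c2] = p_mat.loc[c2, c1] = p
    return r_mat, p_mat


def significance_stars(p: float) -> str:
    """Display convention: *** p<0.001, ** p<0.01, * p<0.05, else ''. """
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# --------------------------------------------------------------------------
# trend fits

@dataclass
class TrendFit:
    """Polynomial least-squares trend of a response against a predictor."""

    coefficients: tuple       # (intercept, linear[, quadratic])
    r_squared: float
    p_value: float            # overall F-test against the intercept-only model
    order: int
    n: int
    _model: object = field(repr=False, default=None)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return sum(c * x ** i for i, c in enumerate(self.coefficients))

    def confidence_band(self, x, level: float = 0.95):
        """(lower, upper) confidence band for the mean response at x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        X = np.column_stack([x ** i for i in range(self.order + 1)])
        pred = self._model.get_prediction(X)
        ci = pred.conf_int(alpha=1 - level)
        return ci[:, 0], ci[:, 1]


def trend_fit(x, y, order: int = 1) -> TrendFit:
    """Fit a linear (order 1) or quadratic (order 2) trend by OLS.

    Returns coefficients in ascending power order, R-squared, and the
    overall F-test p-value.  Requires more distinct x values than the
    polynomial order.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if order not in (1, 2):
        raise ContractError(f"order must be 1 or 2, got {order}")
    if x.size != y.size:
        raise ContractError("x and y must have equal length")
    if x.size < order + 2:
        raise DomainError(f"need n >= {order + 2} points for order {order}")
    if len(np.unique(x)) <= order:
        raise DomainError(
            f"need more than {order} distinct x values for order {order}"
        )
    X = np.column_stack([x ** i for i in range(order + 1)])
    model = sm.OLS(y, X).fit()
    return TrendFit(
        coefficients=tuple(float(c) for c in model.params),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        order=order,
        n=int(x.size),
        _model=model,
    )
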