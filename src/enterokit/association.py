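"""Association of community types and composition with host, gut, diet
and metabolome variables.

Multivariate tests: PERMANOVA (pseudo-F on a distance matrix, sequential
Type I sums of squares for multi-term designs, adonis2-style) and envfit
(least-squares vector fitting of variables onto ordination axes with
permutation p-values). Univariate screening uses Mann-Whitney for
continuous and Fisher exact for categorical variables with BH adjustment
within each declared variable family. Permutation p-values use the
add-one rule, so p >= 1/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .beta import DistanceMatrix, Ordination
from .discriminant import bh_adjust, fisher_exact_2x2, mann_whitney_u


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, ss, pseudo_f, p
    n_perm: int
    seed: int

    @property
    def pseudo_f(self) -> float:
        return float(self.table["pseudo_f"].iloc[0])

    @property
    def p_value(self) -> float:
        return float(self.table["p"].iloc[0])


def _design_columns(design: pd.Series) -> np.ndarray:
    """Numeric columns for one model term (dummy-coded if categorical)."""
    if design.dtype.kind in "OUSb" or isinstance(design.dtype, pd.CategoricalDtype):
        d = pd.get_dummies(design, drop_first=True, dtype=float)
        if d.shape[1] == 0:
            raise ValueError(f"term {design.name!r} is constant")
        return d.to_numpy()
    v = design.to_numpy(dtype=float)[:, None]
    if np.ptp(v) == 0:
        raise ValueError(f"term {design.name!r} is constant")
    return v


def permanova(dm: DistanceMatrix, design: pd.Series | pd.DataFrame,
              n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix.

    A Series is a single grouping/covariate; a DataFrame is fitted as
    sequential (Type I) terms in column order. The pseudo-F for each term
    uses the trace of hat-projected Gower-centered -D^2/2, and p-values
    come from permuting samples (add-one rule).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(design, pd.Series):
        design = design.to_frame()
    design = design.loc[list(dm.ids)]
    for col in design.columns:
        vc = design[col]
        if vc.dtype.kind in "OUSb" and (vc.value_counts() == 1).any():
            warnings.warn(f"term {col!r} has a group with a single sample")
    n = dm.shape[0]
    d2 = dm.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    ss_total = float(np.trace(g))

    terms = [_design_columns(design[c]) for c in design.columns]
    hats, dfs = [], []
    prev_rank = 1  # intercept
    x = np.ones((n, 1))
    h_prev = np.full((n, n), 1.0 / n)
    for t in terms:
        x = np.column_stack([x, t])
        q, _ = np.linalg.qr(x)
        rank = int(np.linalg.matrix_rank(x))
        h = q[:, :rank] @ q[:, :rank].T
        hats.append((h_prev, h))
        dfs.append(rank - prev_rank)
        prev_rank, h_prev = rank, h
    df_res = n - prev_rank

    def term_stats(gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.array([float((h * gm).sum() - (hp * gm).sum())
                       for hp, h in hats])
        ss_res = float(np.trace(gm)) - float((hats[-1][1] * gm).sum())
        f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = term_stats(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        _, f_perm = term_stats(g[np.ix_(p, p)])
        exceed += f_perm >= f_obs - 1e-12
    pvals = (1 + exceed) / (1 + n_perm)
    table = pd.DataFrame({"term": list(design.columns), "df": dfs,
                          "ss": ss_obs, "pseudo_f": f_obs, "p": pvals})
    table.attrs["ss_total"] = ss_total
    table.attrs["df_residual"] = df_res
    return PermanovaResult(table=table, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# envfit

def envfit(ordination: Ordination, variables: pd.DataFrame,
           n_perm: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Fit each continuous variable onto the ordination axes by least
    squares; report r^2, the normalized direction vector, a permutation p
    (variable permuted, axes fixed) and BH-adjusted q across variables."""
    scores = ordination.coords
    if scores.shape[1] < 2:
        raise ValueError("ordination must have at least 2 axes")
    rng = np.random.default_rng(seed)
    rows = []
    for var in variables.columns:
        v = variables[var].reindex(scores.index).astype(float)
        ok = v.notna().to_numpy()
        s = scores.to_numpy()[ok]
        vv = v.to_numpy()[ok]
        n = ok.sum()
        if np.ptp(vv) == 0:
            rows.append({"variable": var, "r2": 0.0,
                         "direction": tuple(np.zeros(s.shape[1])),
                         "p": 1.0, "n": int(n)})
            continue
        sc = s - s.mean(axis=0)
        vc = vv - vv.mean()
        q, _ = np.linalg.qr(sc)
        beta, *_ = np.linalg.lstsq(sc, vc, rcond=None)
        r2 = float((q.T @ vc @ (q.T @ vc)) / (vc @ vc))
        direction = tuple(beta / np.linalg.norm(beta))
        # vectorized permutations of the variable
        perm = np.array([rng.permutation(vc) for _ in range(n_perm)]).T
        proj = q.T @ perm
        r2_perm = (proj ** 2).sum(axis=0) / (vc @ vc)
        p = float((1 + (r2_perm >= r2 - 1e-12).sum()) / (1 + n_perm))
        rows.append({"variable": var, "r2": r2, "direction": direction,
                     "p": p, "n": int(n)})
    out = pd.DataFrame(rows).set_index("variable")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# two-way ANOVA (Type II)

def two_way_anova(y: pd.Series, factor_a: pd.Series, factor_b: pd.Series,
                  interaction: bool = False) -> pd.Series:
    """Type II F-test p-values for two main effects on the additive model
    (suited to unbalanced designs); the interaction is dropped with a
    warning when any cell is empty."""
    df = pd.DataFrame({"y": y.astype(float), "a": factor_a.astype(str),
                       "b": factor_b.astype(str)}).dropna()
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels")
    if interaction:
        cells = df.groupby(["a", "b"], sort=False).size()
        full = df["a"].nunique() * df["b"].nunique()
        if len(cells) < full:
            warnings.warn("empty cell: interaction dropped")
            interaction = False
    formula = "y ~ C(a) + C(b)" + (" + C(a):C(b)" if interaction else "")
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    return pd.Series({"factor_a": float(anova.loc["C(a)", "PR(>F)"]),
                      "factor_b": float(anova.loc["C(b)", "PR(>F)"])})


# ---------------------------------------------------------------------------
# probabilistic quotient normalization

def pq_normalize(spectra: pd.DataFrame) -> pd.DataFrame:
    """Divide each spectrum by the median of its bin-wise quotients to the
    median reference spectrum (zero-reference bins excluded)."""
    x = spectra.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 spectra")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero spectrum")
    ref = np.median(x, axis=0)
    usable = ref > 0
    if not usable.any():
        raise ValueError("reference spectrum is all zero")
    factors = np.median(x[:, usable] / ref[usable], axis=1)
    return pd.DataFrame(x / factors[:, None], index=spectra.index,
                        columns=spectra.columns)


# ---------------------------------------------------------------------------
# Fisher exact for 2 x c tables

def fisher_exact_2xc(table: np.ndarray, n_mc: int = 100_000,
                     seed: int = 0) -> float:
    """Two-sided Fisher exact p for a 2 x c contingency table: full
    enumeration (Freeman-Halton) when the table is small (c <= 5,
    n <= 60), otherwise Monte-Carlo over tables with fixed margins."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape[0] != 2:
        raise ValueError("first dimension must be 2")
    if t.shape[1] == 2:
        return fisher_exact_2x2(t)
    row1 = int(t[0].sum())
    cols = t.sum(axis=0)
    n = int(t.sum())

    def log_prob(k: np.ndarray) -> float:
        # multivariate hypergeometric log-pmf for first-row counts k
        from scipy.special import gammaln
        num = sum(gammaln(c + 1) - gammaln(ki + 1) - gammaln(c - ki + 1)
                  for c, ki in zip(cols, k))
        den = gammaln(n + 1) - gammaln(row1 + 1) - gammaln(n - row1 + 1)
        return float(num - den)

    obs = log_prob(t[0])
    if t.shape[1] <= 5 and n <= 60:
        total = 0.0
        ranges = [range(min(int(c), row1) + 1) for c in cols[:-1]]
        for partial in itertools.product(*ranges):
            last = row1 - sum(partial)
            if not 0 <= last <= cols[-1]:
                continue
            lp = log_prob(np.array(list(partial) + [last]))
            if lp <= obs + 1e-12:
                total += np.exp(lp)
        return float(min(total, 1.0))
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols, row1, size=n_mc)
    lps = np.array([log_prob(k) for k in draws])
    return float((1 + (lps <= obs + 1e-12).sum()) / (1 + n_mc))


# ---------------------------------------------------------------------------
# univariate screening

@dataclass
class AssociationReport:
    table: pd.DataFrame
    alpha: float


def screen_variables(community_types: pd.Series, metadata: pd.DataFrame,
                     families: dict[str, str] | None = None,
                     delta_pairs: dict[str, tuple[str, str]] | None = None,
                     alpha: float = 0.05, seed: int = 0) -> AssociationReport:
    """Screen every metadata variable against the two community types:
    Mann-Whitney for continuous, Fisher exact for categorical variables,
    BH adjustment within each declared variable family. Paired race
    variables supplied in ``delta_pairs`` are tested as deltas T1 - T0.
    Missing values are pairwise-deleted, never imputed; variables with
    fewer than 3 usable values in a group are skipped."""
    labels = community_types
    groups = sorted(pd.unique(labels.dropna()))
    if len(groups) != 2:
        raise ValueError("two community types required")
    meta = metadata.copy()
    for new, (t1, t0) in (delta_pairs or {}).items():
        meta[new] = meta[t1].astype(float) - meta[t0].astype(float)
        meta = meta.drop(columns=[t1, t0])
    rows = []
    for var in meta.columns:
        v = meta[var].reindex(labels.index)
        ok = v.notna()
        lab = labels[ok]
        vv = v[ok]
        n1 = int((lab == groups[0]).sum())
        n2 = int((lab == groups[1]).sum())
        if n1 < 3 or n2 < 3:
            warnings.warn(f"variable {var!r} skipped: too few observations")
            continue
        categorical = (vv.dtype.kind in "OUSb"
                       or isinstance(vv.dtype, pd.CategoricalDtype))
        if categorical:
            tab = pd.crosstab(lab, vv).to_numpy()
            p = fisher_exact_2xc(tab, seed=seed)
            stat = float("nan")
            test = "fisher"
            direction = ""
        else:
            x = vv[lab == groups[0]].to_numpy(dtype=float)
            y = vv[lab == groups[1]].to_numpy(dtype=float)
            if np.ptp(vv.to_numpy(dtype=float)) == 0:
                stat, p = float("nan"), 1.0
            else:
                stat, p = mann_whitney_u(x, y)
            test = "mann-whitney"
            direction = (f"higher in {groups[0]}" if np.mean(x) > np.mean(y)
                         else f"higher in {groups[1]}")
        rows.append({"variable": var,
                     "family": (families or {}).get(var, "all"),
                     "test": test, "statistic": stat, "p": p,
                     "direction": direction, "n": n1 + n2})
    table = pd.DataFrame(rows).set_index("variable")
    table["q"] = np.nan
    for fam in table["family"].unique():
        m = table["family"] == fam
        table.loc[m, "q"] = bh_adjust(table.loc[m, "p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return AssociationReport(table=table, alpha=alpha)
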