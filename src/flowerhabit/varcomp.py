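"""ANOVA, variance components and broad-sense heritability for RCBD trials.

Two linear models are fitted to plot scores T:

* single-year:  T_ik  = u + g_i + b_k + e_ik
* multi-year:   T_ijk = u + g_i + y_j + (gy)_ij + b_k(j) + e_ijk

with g = genotype (accession), y = year, gy = genotype-by-year interaction and
b_k(j) = block nested within year.  Fixed-effects F-tests use Type III sums of
squares computed by model comparison under sum-to-zero contrasts: the SS of a
term is the increase in residual SS when that term's columns are dropped from
the full model.  On balanced data this equals the sequential decomposition.

Variance components treat the same terms as random.  Two estimators are
provided: ``ems_mom`` equates observed mean squares to their expectations
(balanced designs only) and ``reml`` maximises the restricted likelihood
numerically.  For balanced designs the restricted likelihood factorises into
independent mean-square strata, and its interior optimum coincides with the
method-of-moments solution; negative solutions are truncated to zero and
flagged.

Broad-sense heritability on an entry-mean basis:

* single-year:  H2 = Vg / (Vg + Ve / r)
* multi-year:   H2 = Vg / (Vg + Vgy / y + Ve / (y r))

with r replicates (blocks) and y years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

__all__ = [
    "anova_single_year",
    "anova_multi_year",
    "estimate_varcomp",
    "h2_single",
    "h2_multi",
    "stars",
    "VarianceComponents",
    "HeritabilityEstimate",
    "VarianceComponentEstimator",
    "HeritabilityEstimator",
]


def stars(p: float) -> str:
    """Significance annotation: * <=0.05, ** <=0.01, *** <=0.001, NS otherwise."""
    if p is None or np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


# ---------------------------------------------------------------- design codes


def _sum_code(values: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: L levels -> L-1 columns; last level = -1."""
    idx = {lv: i for i, lv in enumerate(levels)}
    n, L = len(values), len(levels)
    M = np.zeros((n, L - 1))
    for row, v in enumerate(values):
        i = idx[v]
        if i < L - 1:
            M[row, i] = 1.0
        else:
            M[row, :] = -1.0
    return M


def _interaction(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Khatri-Rao product of two coded factors."""
    n = A.shape[0]
    return (A[:, :, None] * B[:, None, :]).reshape(n, -1)


def _nested_block_code(df: pd.DataFrame, years: list) -> np.ndarray:
    """Sum-coded block factor applied separately within each year (b_k(j))."""
    cols = []
    for y in years:
        in_year = (df["year"] == y).to_numpy()
        blocks = sorted(df.loc[in_year, "block"].unique())
        if len(blocks) < 2:
            continue
        M = np.zeros((len(df), len(blocks) - 1))
        M[in_year, :] = _sum_code(df.loc[in_year, "block"], blocks)
        cols.append(M)
    if not cols:
        return np.zeros((len(df), 0))
    return np.hstack(cols)


def _rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _type3_table(y: np.ndarray, terms: dict[str, np.ndarray]) -> pd.DataFrame:
    n = y.size
    X_full = np.hstack([np.ones((n, 1))] + [terms[t] for t in terms])
    rss_full, rank_full = _rss_rank(X_full, y)
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("saturated model: residual has zero degrees of freedom")
    ms_res = rss_full / df_res

    rows = []
    for t in terms:
        X_red = np.hstack(
            [np.ones((n, 1))] + [terms[u] for u in terms if u != t]
        )
        rss_red, rank_red = _rss_rank(X_red, y)
        ss = max(rss_red - rss_full, 0.0)
        df_t = rank_full - rank_red
        if df_t == 0:
            raise ValueError(f"term {t!r} has zero degrees of freedom")
        ms = ss / df_t
        F = ms / ms_res if ms_res > 0 else np.nan
        p = float(stats.f.sf(F, df_t, df_res)) if np.isfinite(F) else np.nan
        rows.append((t, df_t, ss, ms, F, p))
    rows.append(("residual", df_res, rss_full, ms_res, np.nan, np.nan))
    tab = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"]).set_index("source")
    tab["stars"] = [stars(p) if np.isfinite(p) else "" for p in tab["p"]]
    return tab


def _check_obs(observations: pd.DataFrame, response: str) -> pd.DataFrame:
    for c in ("accession_id", "year", "block", response):
        if c not in observations.columns:
            raise ValueError(f"observations missing column {c!r}")
    if observations.empty:
        raise ValueError("empty observation set")
    return observations


def anova_single_year(
    observations: pd.DataFrame, response: str = "pct100", year=None
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (accession + block) for one year's plots.

    Type III sums of squares via drop-term model comparison under sum-to-zero
    contrasts; F against the residual mean square.  Pass ``year`` to select a
    year from a multi-year table.
    """
    obs = _check_obs(observations, response)
    if year is not None:
        obs = obs[obs["year"] == year]
        if obs.empty:
            raise ValueError(f"no observations for year {year!r}")
    if obs["year"].nunique() != 1:
        raise ValueError("single-year ANOVA needs exactly one year; pass year=...")
    if obs["accession_id"].nunique() < 2:
        raise ValueError("need at least 2 accessions")
    if obs["block"].nunique() < 2:
        raise ValueError("need at least 2 blocks")
    y = obs[response].to_numpy(dtype=float)
    terms = {
        "accession": _sum_code(obs["accession_id"], sorted(obs["accession_id"].unique())),
        "block": _sum_code(obs["block"], sorted(obs["block"].unique())),
    }
    return _type3_table(y, terms)


def anova_multi_year(
    observations: pd.DataFrame, response: str = "pct100", years=None
) -> pd.DataFrame:
    """Multi-year fixed-effects ANOVA: accession + year + accession x year +
    block within year, Type III by drop-term comparison.

    ``years`` selects a subset (e.g. excluding an anomalous season); at least
    two years are required.
    """
    obs = _check_obs(observations, response)
    if years is not None:
        obs = obs[obs["year"].isin(list(years))]
    year_levels = sorted(obs["year"].unique())
    if len(year_levels) < 2:
        raise ValueError("multi-year ANOVA needs at least 2 years")
    acc_levels = sorted(obs["accession_id"].unique())
    if len(acc_levels) < 2:
        raise ValueError("need at least 2 accessions")
    y = obs[response].to_numpy(dtype=float)
    A = _sum_code(obs["accession_id"], acc_levels)
    Y = _sum_code(obs["year"], year_levels)
    terms = {
        "accession": A,
        "year": Y,
        "accession:year": _interaction(A, Y),
        "block_in_year": _nested_block_code(obs, year_levels),
    }
    if terms["block_in_year"].shape[1] == 0:
        raise ValueError("block-within-year term has zero degrees of freedom")
    return _type3_table(y, terms)


# ------------------------------------------------------- balanced mean squares


def _balance_shape(obs: pd.DataFrame) -> tuple[int, int, int] | None:
    """(a, y, r) if the design is a complete crossing with one plot per cell."""
    a = obs["accession_id"].nunique()
    ny = obs["year"].nunique()
    r = obs["block"].nunique()
    if len(obs) != a * ny * r:
        return None
    if obs.groupby(["accession_id", "year", "block"]).size().max() != 1:
        return None
    return a, ny, r


def _balanced_ss(obs: pd.DataFrame, response: str) -> dict:
    """Classical balanced ANOVA strata for the multi-year (or single-year) model."""
    shape = _balance_shape(obs)
    if shape is None:
        raise ValueError("design is not balanced")
    a, ny, r = shape
    y = obs[response].to_numpy(dtype=float)
    gm = y.mean()
    acc_m = obs.groupby("accession_id")[response].mean()
    ss = {"accession": float(ny * r * ((acc_m - gm) ** 2).sum())}
    df = {"accession": a - 1}
    if ny > 1:
        yr_m = obs.groupby("year")[response].mean()
        cell_m = obs.groupby(["accession_id", "year"])[response].mean()
        inter = (
            cell_m
            - acc_m.reindex(cell_m.index.get_level_values(0)).to_numpy()
            - yr_m.reindex(cell_m.index.get_level_values(1)).to_numpy()
            + gm
        )
        blk_m = obs.groupby(["year", "block"])[response].mean()
        blk_dev = blk_m - yr_m.reindex(blk_m.index.get_level_values(0)).to_numpy()
        ss["year"] = float(a * r * ((yr_m - gm) ** 2).sum())
        ss["accession:year"] = float(r * (inter**2).sum())
        ss["block_in_year"] = float(a * (blk_dev**2).sum())
        df["year"] = ny - 1
        df["accession:year"] = (a - 1) * (ny - 1)
        df["block_in_year"] = ny * (r - 1)
    else:
        blk_m = obs.groupby("block")[response].mean()
        ss["block"] = float(a * ((blk_m - gm) ** 2).sum())
        df["block"] = r - 1
    ss_total = float(((y - gm) ** 2).sum())
    ss["residual"] = max(ss_total - sum(v for k, v in ss.items()), 0.0)
    df["residual"] = (len(y) - 1) - sum(df.values())
    if df["residual"] <= 0:
        raise ValueError("residual has zero degrees of freedom")
    return {"ss": ss, "df": df, "shape": (a, ny, r)}


# ----------------------------------------------------------- variance components


@dataclass
class VarianceComponents:
    """Random-effects variance components for the trial models."""

    scope: str  # "single_year" | "multi_year"
    vg: float
    verror: float
    vgy: float = 0.0
    vblock: float = 0.0
    vyear: float = 0.0
    n_reps: int = 1
    n_years: int = 1
    method: str = "ems_mom"
    truncated: tuple = ()
    converged: bool = True

    def __post_init__(self):
        for name in ("vg", "verror", "vgy", "vblock", "vyear"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _ems_solve(ms: dict, a: int, ny: int, r: int, scope: str) -> dict:
    if scope == "multi_year":
        ve = ms["residual"]
        vgy = (ms["accession:year"] - ve) / r
        vg = (ms["accession"] - ms["accession:year"]) / (r * ny)
        vb = (ms["block_in_year"] - ve) / a
        vy = (ms["year"] - ms["accession:year"] - ms["block_in_year"] + ve) / (a * r)
        return {"vg": vg, "vgy": vgy, "vblock": vb, "vyear": vy, "verror": ve}
    ve = ms["residual"]
    return {
        "vg": (ms["accession"] - ve) / r,
        "vblock": (ms["block"] - ve) / a,
        "verror": ve,
    }


def _stratum_coeffs(a: int, ny: int, r: int, scope: str, env_terms: str = "random"):
    """Linear map from variance components to expected stratum mean squares.

    With ``env_terms="fixed"`` the year and block strata are absorbed by fixed
    effects and only the genetic strata enter the restricted likelihood.
    """
    if scope == "multi_year":
        if env_terms == "random":
            names = ["vg", "vgy", "vblock", "vyear", "verror"]
            M = {
                "accession": [r * ny, r, 0, 0, 1],
                "year": [0, r, a, a * r, 1],
                "accession:year": [0, r, 0, 0, 1],
                "block_in_year": [0, 0, a, 0, 1],
                "residual": [0, 0, 0, 0, 1],
            }
        else:
            names = ["vg", "vgy", "verror"]
            M = {
                "accession": [r * ny, r, 1],
                "accession:year": [0, r, 1],
                "residual": [0, 0, 1],
            }
    else:
        if env_terms == "random":
            names = ["vg", "vblock", "verror"]
            M = {
                "accession": [r, 0, 1],
                "block": [0, a, 1],
                "residual": [0, 0, 1],
            }
        else:
            names = ["vg", "verror"]
            M = {
                "accession": [r, 1],
                "residual": [0, 1],
            }
    strata = list(M)
    return names, strata, np.array([M[s] for s in strata], dtype=float)


def _reml_balanced(
    ss: dict, dfs: dict, a: int, ny: int, r: int, scope: str, env_terms: str = "random"
) -> tuple[dict, bool]:
    """REML for the balanced model via its exact stratum factorisation.

    -2 log RL = sum_s [df_s log(theta_s) + SS_s / theta_s] up to a constant,
    with theta = C v linear in the components v >= 0.  Optimised over u with
    v = u^2 (nonnegativity built in), warm-started at the method-of-moments
    solution, whose interior stationary point it reproduces.
    """
    names, strata, C = _stratum_coeffs(a, ny, r, scope, env_terms)
    SS = np.array([ss[s] for s in strata])
    DF = np.array([dfs[s] for s in strata], dtype=float)
    scale = max(SS.sum() / DF.sum(), 1e-12)

    def fgrad(u):
        v = u * u
        theta = C @ v
        theta = np.maximum(theta, 1e-300)
        f = float(np.sum(DF * np.log(theta) + SS / theta))
        w = DF / theta - SS / theta**2
        return f, 2.0 * u * (C.T @ w)

    mom = _ems_solve({s: ss[s] / dfs[s] for s in ss}, a, ny, r, scope)
    starts = [
        np.sqrt([max(mom[n], 1e-8 * scale) for n in names]),
        np.sqrt(np.full(len(names), scale)),
        np.sqrt([1e-6 * scale] * (len(names) - 1) + [scale]),
    ]
    best = None
    ok = False
    for u0 in starts:
        res = optimize.minimize(
            fgrad, u0, jac=True, method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        ok = ok or res.success
    v = dict(zip(names, (best.x * best.x).tolist()))
    return v, ok


def _generic_reml(
    y: np.ndarray, Zs: dict[str, np.ndarray], X: np.ndarray | None = None
) -> tuple[dict, bool]:
    """Gaussian REML with explicit n x n covariance (small unbalanced designs).

    y = X beta + sum_r Z_r u_r + e; minimises log|V| + log|X' V^-1 X| + y' P y
    over log-variances (fixed effects profiled out).  O(n^3) per evaluation.
    """
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    ZZt = {k: Z @ Z.T for k, Z in Zs.items()}
    names = list(Zs) + ["verror"]
    s2 = float(np.var(y))

    def neg2rll(tau):
        v = np.exp(tau)
        V = v[-1] * np.eye(n)
        for i, k in enumerate(Zs):
            V += v[i] * ZZt[k]
        try:
            c = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return 1e30
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        Vi_y = cho_solve(c, y)
        Vi_X = cho_solve(c, X)
        XtViX = X.T @ Vi_X
        sign, ld_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e30
        b = X.T @ Vi_y
        quad = float(y @ Vi_y) - float(b @ np.linalg.solve(XtViX, b))
        return logdet + ld_x + quad

    lo = np.log(1e-8 * max(s2, 1e-12))
    tau0 = np.log(np.full(len(names), max(s2 / len(names), 1e-10)))
    best = None
    for start in (tau0, tau0 + 1.0, tau0 - 2.0):
        res = optimize.minimize(
            neg2rll, start, method="L-BFGS-B",
            bounds=[(lo, None)] * len(names),
            options={"ftol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    v = np.exp(best.x)
    v[v <= np.exp(lo) * 1.01] = 0.0
    return dict(zip(names, v.tolist())), bool(best.success)


def _design_Z(
    obs: pd.DataFrame, scope: str, env_terms: str = "random"
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Random-effect indicator matrices and fixed-effect design for REML."""

    def indicator(series):
        return pd.get_dummies(series).to_numpy(dtype=float)

    n = len(obs)
    Zs = {"vg": indicator(obs["accession_id"])}
    X = [np.ones((n, 1))]
    if scope == "multi_year":
        Zs["vgy"] = indicator(
            obs["accession_id"].astype(str) + "\x1f" + obs["year"].astype(str)
        )
        if env_terms == "random":
            Zs["vyear"] = indicator(obs["year"])
            Zs["vblock"] = indicator(
                obs["year"].astype(str) + "\x1f" + obs["block"].astype(str)
            )
        else:
            years = sorted(obs["year"].unique())
            X.append(_sum_code(obs["year"], years))
            X.append(_nested_block_code(obs, years))
    else:
        if env_terms == "random":
            Zs["vblock"] = indicator(obs["block"])
        else:
            X.append(_sum_code(obs["block"], sorted(obs["block"].unique())))
    return Zs, np.hstack(X)


def estimate_varcomp(
    observations: pd.DataFrame,
    scope: str = "multi_year",
    method: str = "reml",
    response: str = "pct100",
    env_terms: str = "random",
) -> VarianceComponents:
    """Estimate random-effects variance components of the trial model.

    ``ems_mom`` (balanced designs only) equates observed to expected mean
    squares; ``reml`` maximises the restricted likelihood (exact stratum
    factorisation when balanced, explicit-covariance REML otherwise).
    Negative method-of-moments solutions are truncated to zero and flagged.

    ``env_terms`` controls the year and block(year) terms: ``"random"`` fits
    the all-random model; ``"fixed"`` absorbs them as fixed design effects and
    estimates only the genetic components (Vg, Vgy, Ve) — the entry-mean
    heritability components — in which case balanced REML coincides with the
    mean-square equations whenever the solution is interior.
    """
    obs = _check_obs(observations, response)
    if scope not in ("single_year", "multi_year"):
        raise ValueError(f"unknown scope {scope!r}")
    if env_terms not in ("random", "fixed"):
        raise ValueError(f"unknown env_terms {env_terms!r}")
    if scope == "single_year" and obs["year"].nunique() != 1:
        raise ValueError("single_year scope needs exactly one year of data")
    if scope == "multi_year" and obs["year"].nunique() < 2:
        raise ValueError("multi_year scope needs at least two years")

    shape = _balance_shape(obs)
    converged = True
    if method == "ems_mom":
        if shape is None:
            raise ValueError("ems_mom requires a balanced design; use method='reml'")
        strata = _balanced_ss(obs, response)
        ms = {s: strata["ss"][s] / strata["df"][s] for s in strata["ss"]}
        a, ny, r = strata["shape"]
        v = _ems_solve(ms, a, ny, r, scope)
        if env_terms == "fixed":
            v.pop("vblock", None)
            v.pop("vyear", None)
    elif method == "reml":
        if shape is not None:
            strata = _balanced_ss(obs, response)
            a, ny, r = strata["shape"]
            v, converged = _reml_balanced(
                strata["ss"], strata["df"], a, ny, r, scope, env_terms
            )
        else:
            a = obs["accession_id"].nunique()
            ny = obs["year"].nunique()
            y = obs[response].to_numpy(dtype=float)
            Zs, X = _design_Z(obs, scope, env_terms)
            v, converged = _generic_reml(y, Zs, X)
            r = max(int(round(len(obs) / (a * ny))), 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    truncated = tuple(sorted(k for k, val in v.items() if val < 0))
    scale = max(abs(val) for val in v.values()) if v else 0.0
    clean = {k: (0.0 if val < max(1e-10 * scale, 0.0) else float(val)) for k, val in v.items()}
    clean.update({k: 0.0 for k in truncated})
    return VarianceComponents(
        scope=scope,
        vg=clean.get("vg", 0.0),
        vgy=clean.get("vgy", 0.0),
        vblock=clean.get("vblock", 0.0),
        vyear=clean.get("vyear", 0.0),
        verror=clean.get("verror", 0.0),
        n_reps=r,
        n_years=ny if scope == "multi_year" else 1,
        method=method,
        truncated=truncated,
        converged=converged,
    )


# ---------------------------------------------------------------- heritability


@dataclass
class HeritabilityEstimate:
    h2: float
    scope: str
    components: VarianceComponents | None = None

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"H2 must be in [0,1], got {self.h2}")


def h2_single(vg: float, verror: float, n_reps: int) -> HeritabilityEstimate:
    """Entry-mean broad-sense heritability, one year: Vg / (Vg + Ve/r)."""
    if vg < 0 or verror < 0:
        raise ValueError("variance components must be nonnegative")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    denom = vg + verror / n_reps
    if denom == 0:
        raise ValueError("all variance components are zero: H2 undefined")
    return HeritabilityEstimate(h2=vg / denom, scope="single_year")


def h2_multi(
    vg: float, vgy: float, verror: float, n_years: int, n_reps: int
) -> HeritabilityEstimate:
    """Entry-mean broad-sense heritability across years:
    Vg / (Vg + Vgy/y + Ve/(y r))."""
    if min(vg, vgy, verror) < 0:
        raise ValueError("variance components must be nonnegative")
    if n_years < 2:
        raise ValueError("n_years must be >= 2 for the multi-year formula")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    denom = vg + vgy / n_years + verror / (n_years * n_reps)
    if denom == 0:
        raise ValueError("all variance components are zero: H2 undefined")
    return HeritabilityEstimate(h2=vg / denom, scope="multi_year")


# ------------------------------------------------------------------ estimators


class VarianceComponentEstimator(BaseEstimator):
    """Random-effects variance-component fit as a sklearn-style estimator.

    Parameters
    ----------
    scope : {"multi_year", "single_year"}
    method : {"reml", "ems_mom"}
    response : str
        Score column to model ("pct100" or "pct60").

    Attributes (after ``fit``)
    --------------------------
    components_ : VarianceComponents
    vg_, vgy_, vblock_, vyear_, verror_ : float
    """

    def __init__(
        self,
        scope: str = "multi_year",
        method: str = "reml",
        response: str = "pct100",
        env_terms: str = "random",
    ):
        self.scope = scope
        self.method = method
        self.response = response
        self.env_terms = env_terms

    def fit(self, X: pd.DataFrame, y=None):
        c = estimate_varcomp(
            X, scope=self.scope, method=self.method,
            response=self.response, env_terms=self.env_terms,
        )
        self.components_ = c
        self.vg_, self.vgy_, self.vblock_ = c.vg, c.vgy, c.vblock
        self.vyear_, self.verror_ = c.vyear, c.verror
        return self


class HeritabilityEstimator(BaseEstimator):
    """Broad-sense heritability from a plot-observation table.

    Fits the random-effects model in the requested scope and evaluates the
    entry-mean H2 formula with the replicate and year counts taken from the
    data (overridable).

    Attributes (after ``fit``)
    --------------------------
    components_ : VarianceComponents
    H2_ : float
    n_reps_, n_years_ : int
    """

    def __init__(
        self,
        scope: str = "multi_year",
        method: str = "reml",
        response: str = "pct100",
        n_reps: int | None = None,
        env_terms: str = "random",
    ):
        self.scope = scope
        self.method = method
        self.response = response
        self.n_reps = n_reps
        self.env_terms = env_terms

    def fit(self, X: pd.DataFrame, y=None):
        c = estimate_varcomp(
            X, scope=self.scope, method=self.method,
            response=self.response, env_terms=self.env_terms,
        )
        self.components_ = c
        self.n_reps_ = int(self.n_reps if self.n_reps is not None else c.n_reps)
        self.n_years_ = c.n_years
        if self.scope == "single_year":
            est = h2_single(c.vg, c.verror, self.n_reps_)
        else:
            est = h2_multi(c.vg, c.vgy, c.verror, self.n_years_, self.n_reps_)
        self.H2_ = est.h2
        return self
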