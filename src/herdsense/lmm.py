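"""Linear mixed models with a single (rank-1 per group) random effect.

Covers the three model families used for the behavioral analysis:

* M1 — daily characteristic ~ lameness + DIM (+ interaction) with a
  random intercept per cow;
* M2 — daily rumination time ~ lameness + milk + one feeding
  characteristic (+ interactions) with a random intercept per cow;
* M3 — visit intake ~ visit duration and its interactions with mean
  locomotion score and mean milk yield, no intercept, with a random
  per-cow slope on duration.

Because each cow contributes a single random coefficient, the marginal
covariance is block diagonal with rank-1 blocks ``sigma2 * (I + lambda *
z z')``; the likelihood is profiled over the variance ratio ``lambda``
with Woodbury identities, and fixed effects follow by generalized least
squares at the optimum.  Inference on fixed effects uses ML likelihood
ratio tests; reported coefficients may use REML.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ConvergenceError",
    "fit_lmm",
    "lrt",
    "reduce_interactions",
    "rss_r2",
    "lsm",
    "compare_models",
    "m1_spec",
    "m2_spec",
    "m3_spec",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of one mixed model.

    ``fixed`` terms are column names of the data frame; an interaction is
    written ``"a:b"`` and enters as the elementwise product.  ``random``
    is ``"intercept"`` for a per-group random intercept or ``"slope:col"``
    for a per-group random slope on ``col``.
    """

    response: str
    fixed: tuple[str, ...]
    intercept: bool = True
    random: str = "intercept"
    group: str = "cow_id"
    name: str = ""

    def with_terms(self, fixed: tuple[str, ...]) -> "ModelSpec":
        return replace(self, fixed=tuple(fixed))

    @property
    def interactions(self) -> tuple[str, ...]:
        return tuple(t for t in self.fixed if ":" in t)


@dataclass
class ModelFit:
    """Result of one (RE)ML fit."""

    spec: ModelSpec
    method: str
    params: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    sigma2: float          # residual variance
    group_var: float       # variance of the random coefficient
    lam: float             # group_var / sigma2
    loglik: float
    rss: float             # sum of squared conditional residuals
    n: int
    p: int                 # number of fixed-effect columns
    aic: float
    bic: float
    var_means: dict[str, float] = field(default_factory=dict)
    dropped: tuple[str, ...] = ()
    converged: bool = True
    index: pd.Index | None = None

    @property
    def k(self) -> int:
        """Parameter count for information criteria (fixed + 2 variances)."""
        return self.p + 2


def _term_column(data: pd.DataFrame, term: str) -> np.ndarray:
    col = np.ones(len(data))
    for factor in term.split(":"):
        if factor not in data.columns:
            raise KeyError(f"unknown model term component {factor!r}")
        col = col * data[factor].to_numpy(dtype=float)
    return col


def _design(spec: ModelSpec, data: pd.DataFrame):
    cols, names = [], []
    if spec.intercept:
        cols.append(np.ones(len(data)))
        names.append("(Intercept)")
    for term in spec.fixed:
        cols.append(_term_column(data, term))
        names.append(term)
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    y = data[spec.response].to_numpy(dtype=float)
    if spec.random == "intercept":
        z = np.ones(len(data))
    elif spec.random.startswith("slope:"):
        z = data[spec.random.split(":", 1)[1]].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown random structure {spec.random!r}")
    groups = data[spec.group].to_numpy()
    return y, X, names, z, groups


def _drop_aliased(X: np.ndarray, names: list[str]):
    """Greedy removal of columns that do not increase the design rank."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropping aliased terms: {dropped}")
    return X[:, keep], [names[i] for i in keep], tuple(dropped)


class _Profile:
    """Profiled deviance over the variance ratio for rank-1 group blocks.

    All per-group sufficient statistics are precomputed, so each
    evaluation at a new variance ratio is a handful of vectorized
    operations (Woodbury identity per rank-1 block).
    """

    def __init__(self, y, X, z, groups, reml: bool):
        order = np.argsort(groups, kind="stable")
        y, X, z = y[order], X[order], z[order]
        g = np.asarray(groups)[order]
        _, starts = np.unique(g, return_index=True)
        self.n, self.p = X.shape
        self.reml = reml

        zX = z[:, None] * X
        zy = z * y
        self.ztz = np.add.reduceat(z * z, starts)          # (G,)
        self.ztX = np.add.reduceat(zX, starts, axis=0)     # (G, p)
        self.zty = np.add.reduceat(zy, starts)             # (G,)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.n_groups = len(starts)

    def beta_and_q(self, lam: float):
        w = lam / (1.0 + lam * self.ztz)                   # (G,)
        XtVX = self.XtX - np.einsum("g,gi,gj->ij", w, self.ztX, self.ztX)
        XtVy = self.Xty - (w * self.zty) @ self.ztX
        beta = np.linalg.solve(XtVX, XtVy)
        ztr = self.zty - self.ztX @ beta                   # (G,)
        rtr = (self.yty - 2.0 * beta @ self.Xty
               + beta @ self.XtX @ beta)
        q = rtr - float(w @ (ztr * ztr))
        logdet = float(np.sum(np.log1p(lam * self.ztz)))
        return beta, max(q, 1e-300), logdet, XtVX

    def cond_rss(self, lam: float, beta: np.ndarray) -> float:
        """Sum of squared conditional residuals (BLUP group effects)."""
        ztr = self.zty - self.ztX @ beta
        rtr = (self.yty - 2.0 * beta @ self.Xty
               + beta @ self.XtX @ beta)
        b = lam * ztr / (1.0 + lam * self.ztz)
        return float(rtr - 2.0 * b @ ztr + (b * b) @ self.ztz)

    def loglik(self, lam: float) -> float:
        _, q, logdet, XtVX = self.beta_and_q(lam)
        n, p = self.n, self.p
        if self.reml:
            s2 = q / (n - p)
            _, ld_x = np.linalg.slogdet(XtVX)
            return -0.5 * ((n - p) * np.log(2 * np.pi * s2) + logdet
                           + ld_x + (n - p))
        s2 = q / n
        return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, method: str = "REML",
            ) -> ModelFit:
    """Fit the mixed model by profiling the variance ratio.

    Rows with missing values in any used column are dropped.  Aliased
    fixed-effect columns are removed with a warning.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")

    used = {spec.response, spec.group}
    for term in spec.fixed:
        used.update(term.split(":"))
    if spec.random.startswith("slope:"):
        used.add(spec.random.split(":", 1)[1])
    df = data.copy()
    for c in used:
        if c not in df.columns:
            raise KeyError(f"column {c!r} missing from data")
        if df[c].dtype == bool:
            df[c] = df[c].astype(float)
    df = df.dropna(subset=list(used))

    y, X, names, z, groups = _design(spec, df)
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 groups")
    X, names, dropped = _drop_aliased(X, names)
    p = X.shape[1]
    n = len(y)
    if n <= p:
        raise ValueError("more fixed effects than observations")

    prof = _Profile(y, X, z, groups, reml=(method == "REML"))

    def nll(loglam: float) -> float:
        return -prof.loglik(np.exp(loglam))

    res = optimize.minimize_scalar(nll, bounds=(-16.0, 16.0),
                                   method="bounded",
                                   options={"xatol": 1e-9})
    if not res.success:  # pragma: no cover - bounded rarely fails
        raise ConvergenceError(f"profile optimization failed: {res.message}")
    lam = float(np.exp(res.x))
    # allow the boundary solution lambda -> 0 (plain OLS)
    if -nll(-50.0) >= -res.fun:
        lam = 0.0

    beta, q, logdet, XtVX = prof.beta_and_q(lam)
    s2 = q / (n - p) if method == "REML" else q / n
    ll = prof.loglik(lam)
    cov = s2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))

    rss = prof.cond_rss(lam, beta)

    k = p + 2
    aic = -2.0 * ll + 2.0 * k
    bic = -2.0 * ll + k * np.log(n)

    var_means = {c: float(df[c].mean())
                 for c in used if c != spec.group
                 and np.issubdtype(df[c].dtype, np.number)}

    return ModelFit(
        spec=spec, method=method,
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma2=float(s2), group_var=float(lam * s2), lam=lam,
        loglik=float(ll), rss=float(rss), n=n, p=p,
        aic=float(aic), bic=float(bic),
        var_means=var_means, dropped=dropped, index=df.index,
    )


def lrt(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """Likelihood ratio test of nested ML fits.

    Returns ``(statistic, df, p_value)``.
    """
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("LRT requires ML fits")
    if full.n != reduced.n:
        raise ValueError("fits must use identical rows")
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError("reduced model is not nested in the full model")
    df = full.p - reduced.p
    if df < 0:
        raise ValueError("reduced model has more terms than the full model")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        warnings.warn("negative LR statistic; refit advisable")
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 and stat <= 0 else float(chi2.sf(stat, max(df, 1)))
    if df == 0:
        p = 1.0 if stat <= 1e-8 else p
    return float(stat), int(df), p


def _order(term: str) -> int:
    return term.count(":")


def reduce_interactions(spec: ModelSpec, data: pd.DataFrame,
                        alpha: float = 0.05,
                        ) -> tuple[ModelSpec, list[dict]]:
    """Drop non-significant interactions one by one, highest order first.

    Only *maximal* interactions (not contained in a retained higher-order
    interaction) are eligible.  Main effects are never dropped.  Returns
    the final spec and the drop path.
    """
    current = spec
    path: list[dict] = []
    while True:
        inter = [t for t in current.fixed if ":" in t]
        if not inter:
            break
        maximal = [t for t in inter
                   if not any(set(t.split(":")) < set(u.split(":"))
                              for u in inter if u != t)]
        full_fit = fit_lmm(current, data, method="ML")
        tested = []
        for t in maximal:
            red = current.with_terms(tuple(x for x in current.fixed if x != t))
            red_fit = fit_lmm(red, data, method="ML")
            stat, df, p = lrt(full_fit, red_fit)
            tested.append((t, p))
        nonsig = [(t, p) for t, p in tested if p >= alpha]
        if not nonsig:
            break
        top_order = max(_order(t) for t, _ in nonsig)
        cands = [(t, p) for t, p in nonsig if _order(t) == top_order]
        drop_term, drop_p = max(cands, key=lambda tp: tp[1])
        current = current.with_terms(
            tuple(t for t in current.fixed if t != drop_term))
        path.append({"dropped": drop_term, "p": drop_p})
    return current, path


def rss_r2(fit: ModelFit, null_fit: ModelFit) -> float:
    """R-squared from conditional residual sums of squares against the
    intercept-plus-random-cow null model."""
    if null_fit.rss <= 0:
        return np.nan
    return (null_fit.rss - fit.rss) / null_fit.rss


def lsm(fit: ModelFit, factor: str = "lame",
        levels=(0.0, 1.0)) -> pd.DataFrame:
    """Least-square means of *factor* with covariates at their grand means.

    SEs come from the fixed-effect covariance via the linear predictor.
    """
    names = list(fit.params.index)
    touches = any(factor in t.split(":") for t in names if t != "(Intercept)")
    if not touches:
        raise ValueError(f"factor {factor!r} not in the fixed effects")
    rows = []
    for level in levels:
        x = np.zeros(len(names))
        for j, term in enumerate(names):
            if term == "(Intercept)":
                x[j] = 1.0
                continue
            val = 1.0
            for f in term.split(":"):
                val *= level if f == factor else fit.var_means[f]
            x[j] = val
        est = float(x @ fit.params.to_numpy())
        se = float(np.sqrt(x @ fit.cov.to_numpy() @ x))
        rows.append({factor: level, "lsm": est, "se": se})
    return pd.DataFrame(rows)


def compare_models(specs: list[ModelSpec], data: pd.DataFrame,
                   null_spec: ModelSpec | None = None,
                   method: str = "ML") -> pd.DataFrame:
    """Fit several specs on identical rows; tabulate RSS, R2, AIC, BIC.

    Rows incomplete for *any* spec are removed first so every model sees
    the same data.  The table is ordered by decreasing RSS.
    """
    used = set()
    for s in specs + ([null_spec] if null_spec else []):
        used.add(s.response)
        for t in s.fixed:
            used.update(t.split(":"))
    cols = [c for c in used if c in data.columns]
    df = data.dropna(subset=cols)

    null_fit = fit_lmm(null_spec, df, method=method) if null_spec else None
    rows = []
    if null_fit is not None:
        rows.append({"name": null_spec.name or "null", "rss": null_fit.rss,
                     "r2": np.nan, "aic": null_fit.aic, "bic": null_fit.bic,
                     "n": null_fit.n})
    for s in specs:
        f = fit_lmm(s, df, method=method)
        if null_fit is not None and f.n != null_fit.n:
            raise ValueError("row-set mismatch between models")
        rows.append({
            "name": s.name or "+".join(s.fixed),
            "rss": f.rss,
            "r2": rss_r2(f, null_fit) if null_fit else np.nan,
            "aic": f.aic, "bic": f.bic, "n": f.n,
        })
    out = pd.DataFrame(rows).sort_values("rss", ascending=False,
                                         kind="stable")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# canonical model specs


def m1_spec(response: str, interaction: bool = True) -> ModelSpec:
    """Daily characteristic ~ lameness + DIM (+ interaction), random cow."""
    fixed = ("lame", "dim") + (("lame:dim",) if interaction else ())
    return ModelSpec(response=response, fixed=fixed, name=f"M1[{response}]")


def m1_null(response: str) -> ModelSpec:
    return ModelSpec(response=response, fixed=(), name=f"M1null[{response}]")


def m2_spec(dfchar: str, interactions: bool = True) -> ModelSpec:
    """Daily rumination time ~ lame + milk + feeding characteristic."""
    fixed = ["lame", "dMY", dfchar]
    if interactions:
        fixed += [f"lame:{dfchar}", f"dMY:{dfchar}", "lame:dMY",
                  f"lame:dMY:{dfchar}"]
    return ModelSpec(response="dRUMtime", fixed=tuple(fixed),
                     name=f"M2[{dfchar}]")


def m3_spec() -> ModelSpec:
    """Visit intake (g) ~ duration (min) x {locomotion, milk}, no
    intercept, random per-cow slope on duration."""
    return ModelSpec(
        response="vFMI_g",
        fixed=("vFdur_min", "vFdur_min:mean_locomotion",
               "vFdur_min:milk_mean"),
        intercept=False,
        random="slope:vFdur_min",
        name="M3",
    )


def m3_data(visits: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Assemble the visit-level M3 data frame (grams and minutes)."""
    df = visits.loc[visits["duration_s"] > 0,
                    ["cow_id", "duration_s", "fmi_kg"]].copy()
    df["vFdur_min"] = df["duration_s"] / 60.0
    df["vFMI_g"] = df["fmi_kg"] * 1000.0
    cols = cohort[["cow_id", "mean_locomotion", "milk_level"]].rename(
        columns={"milk_level": "milk_mean"})
    return df.merge(cols, on="cow_id", how="left")
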