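"""REML animal model for repeated race records.

The association between genotype and ace points is estimated with the mixed
model

    y = mu + genotype + sex + breeder + race_category
           + weather_start + weather_end + pe + a + e,

where ``pe`` is a permanent-individual effect (iid across birds, shared by a
bird's repeated records), ``a`` is a polygenic effect with covariance
sigma2_a * A for the pedigree-derived additive relationship matrix A, and ``e``
is the residual.  Both random effects attach to pigeon identity, so the
marginal covariance of the records is

    V = Z (sigma2_i I + sigma2_a A) Z' + sigma2_e I,

with Z the n x q incidence of records on birds.  Variance components are
estimated by restricted maximum likelihood; because the random structure is a
q-dimensional bird effect, all likelihood algebra is reduced to q x q and
p x p crossproducts (Woodbury identity), which keeps each evaluation cheap even
for thousands of records.  Fixed effects come from generalized least squares at
the optimum; tests use the large-sample normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .errors import InputError
from .pedigree_kinship import RelationshipMatrix
from .race_scoring import (
    BREEDER_LEVELS,
    CATEGORY_LEVELS,
    SEX_LEVELS,
    WEATHER_END_LEVELS,
    WEATHER_START_LEVELS,
)

GENOTYPE_LEVELS = ("AG/AG", "AG/TT", "TT/TT")

DEFAULT_FACTORS: dict[str, tuple[str, ...]] = {
    "genotype": GENOTYPE_LEVELS,
    "sex": SEX_LEVELS,
    "breeder": BREEDER_LEVELS,
    "category": CATEGORY_LEVELS,
    "weather_start": WEATHER_START_LEVELS,
    "weather_end": WEATHER_END_LEVELS,
}

_COMPONENTS = ("individual", "polygenic", "residual")


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed factors enter the model and with which level order.

    The first level of each factor is the reference and is absorbed into the
    intercept.  Random structure: a permanent-individual effect and, when a
    relationship matrix is supplied, a polygenic effect.
    """

    response: str = "ap"
    factors: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FACTORS)
    )
    include_individual: bool = True
    include_polygenic: bool = True


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components on the response scale (AP^2 units)."""

    sigma2_i: float
    sigma2_a: float
    sigma2_e: float

    def as_dict(self) -> dict[str, float]:
        return {
            "individual": self.sigma2_i,
            "polygenic": self.sigma2_a,
            "residual": self.sigma2_e,
        }


@dataclass
class Design:
    """Numeric design built from a scored record table."""

    y: np.ndarray
    X: np.ndarray
    xnames: list[str]
    Z: np.ndarray
    ids: list[str]
    A: Optional[np.ndarray]
    include_individual: bool
    factor_levels: dict[str, list[str]]
    factor_columns: dict[str, dict[str, Optional[int]]]
    dropped_factors: list[str]
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    A: Optional[RelationshipMatrix] = None,
) -> Design:
    """Build response, fixed-effect and random-effect structures.

    Factors observed at a single level are dropped with a warning; levels
    absent from the declaration raise.  When ``A`` is given its sub-matrix over
    the phenotyped birds becomes the polygenic covariance structure.
    """
    if spec.response not in records.columns:
        raise InputError(f"response column {spec.response!r} missing from records")
    if "pigeon_id" not in records.columns:
        raise InputError("records need a pigeon_id column")
    y = records[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise InputError("response contains non-finite values")

    n = len(records)
    ids = list(dict.fromkeys(records["pigeon_id"].astype(str)))
    id_index = {a: i for i, a in enumerate(ids)}
    Z = np.zeros((n, len(ids)))
    for row, pid in enumerate(records["pigeon_id"].astype(str)):
        Z[row, id_index[pid]] = 1.0

    A_sub = None
    if spec.include_polygenic and A is not None:
        A_sub = A.submatrix(ids).values

    cols = [np.ones(n)]
    xnames = ["intercept"]
    factor_levels: dict[str, list[str]] = {}
    factor_columns: dict[str, dict[str, Optional[int]]] = {}
    dropped: list[str] = []
    for factor, declared in spec.factors.items():
        if factor not in records.columns:
            raise InputError(f"factor column {factor!r} missing from records")
        values = records[factor].astype(str)
        unknown = sorted(set(values) - set(declared))
        if unknown:
            raise InputError(
                f"factor {factor!r} has undeclared level(s) {unknown}"
            )
        present = [lv for lv in declared if (values == lv).any()]
        if len(present) < 2:
            warnings.warn(
                f"factor {factor!r} has a single observed level and was dropped",
                stacklevel=2,
            )
            dropped.append(factor)
            continue
        factor_levels[factor] = present
        colmap: dict[str, Optional[int]] = {present[0]: None}
        for lv in present[1:]:
            colmap[lv] = len(cols)
            cols.append((values == lv).to_numpy(dtype=float))
            xnames.append(f"{factor}[{lv}]")
        factor_columns[factor] = colmap

    X = np.column_stack(cols)
    return Design(
        y=y,
        X=X,
        xnames=xnames,
        Z=Z,
        ids=ids,
        A=A_sub,
        include_individual=spec.include_individual,
        factor_levels=factor_levels,
        factor_columns=factor_columns,
        dropped_factors=dropped,
        spec=spec,
    )


@dataclass
class MixedModelResult:
    varcomp: VarianceComponents
    fixed: pd.DataFrame  # estimate, se per fixed-effect column
    cov_beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    design: Design
    fixed_variances: dict[str, float]


class _RemlProblem:
    """Precomputed crossproducts and the restricted log-likelihood."""

    def __init__(self, design: Design):
        y, X, Z = design.y, design.X, design.Z
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise InputError("fixed-effect design matrix is singular")
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.ZtZ = Z.T @ Z
        self.q = Z.shape[1]
        self.A = design.A
        self.include_individual = design.include_individual

    def bird_covariance(self, s2i: float, s2a: float) -> Optional[np.ndarray]:
        """G = s2i I + s2a A over birds; None when both terms vanish."""
        G = None
        if self.include_individual and s2i > 0:
            G = s2i * np.eye(self.q)
        if self.A is not None and s2a > 0:
            G = (G if G is not None else 0.0) + s2a * self.A
        return G

    def _pieces(self, s2i: float, s2a: float, s2e: float):
        G = self.bird_covariance(s2i, s2a)
        if G is None:
            XtVX = self.XtX / s2e
            XtVy = self.Xty / s2e
            yVy = self.yty / s2e
            logdetV = self.n * np.log(s2e)
        else:
            cG = cho_factor(G, lower=True)
            Ginv = cho_solve(cG, np.eye(self.q))
            M = Ginv + self.ZtZ / s2e
            cM = cho_factor(M, lower=True)
            logdetG = 2.0 * np.sum(np.log(np.diag(cG[0])))
            logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
            MZtX = cho_solve(cM, self.ZtX)
            MZty = cho_solve(cM, self.Zty)
            XtVX = self.XtX / s2e - (self.ZtX.T @ MZtX) / s2e**2
            XtVy = self.Xty / s2e - (self.ZtX.T @ MZty) / s2e**2
            yVy = self.yty / s2e - float(self.Zty @ MZty) / s2e**2
            logdetV = self.n * np.log(s2e) + logdetG + logdetM
        return XtVX, XtVy, yVy, logdetV

    def restricted_loglik(self, s2i: float, s2a: float, s2e: float):
        XtVX, XtVy, yVy, logdetV = self._pieces(s2i, s2a, s2e)
        cXtVX = cho_factor(XtVX, lower=True)
        beta = cho_solve(cXtVX, XtVy)
        logdetXVX = 2.0 * np.sum(np.log(np.diag(cXtVX[0])))
        yPy = yVy - float(XtVy @ beta)
        ll = -0.5 * (
            (self.n - self.p) * np.log(2.0 * np.pi) + logdetV + logdetXVX + yPy
        )
        cov_beta = cho_solve(cXtVX, np.eye(self.p))
        return float(ll), beta, cov_beta


def fit_reml(
    design: Design,
    start: Optional[VarianceComponents] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    fix: Optional[dict[str, float]] = None,
) -> MixedModelResult:
    """Estimate variance components by REML and fixed effects by GLS.

    Free variance components are optimized on the log scale with L-BFGS-B from
    two default starts (equal split; residual-dominant) to guard against local
    optima; ``start`` adds a third user start.  Components named in ``fix`` are
    held at the given value (0 removes the term).  Non-convergence returns the
    best iterate flagged ``converged=False`` rather than raising.
    """
    fix = dict(fix or {})
    for name, value in fix.items():
        if name not in _COMPONENTS:
            raise InputError(f"unknown variance component {name!r}")
        if value < 0:
            raise InputError(f"fixed variance for {name!r} must be >= 0")
    if fix.get("residual", 1.0) <= 0:
        raise InputError("residual variance cannot be fixed at zero")

    prob = _RemlProblem(design)
    active = []
    if design.include_individual:
        active.append("individual")
    if design.A is not None:
        active.append("polygenic")
    active.append("residual")
    free = [c for c in active if c not in fix]

    vary = float(np.var(design.y, ddof=1))
    if vary <= 0:
        raise InputError("response has zero variance")

    def unpack(theta: np.ndarray) -> dict[str, float]:
        vals = dict.fromkeys(_COMPONENTS, 0.0)
        for name in active:
            if name in fix:
                vals[name] = fix[name]
        for name, t in zip(free, theta):
            vals[name] = float(np.exp(t))
        return vals

    if not free:
        vals = unpack(np.empty(0))
        ll, beta, cov_beta = prob.restricted_loglik(
            vals["individual"], vals["polygenic"], vals["residual"]
        )
        return _finalize(design, vals, ll, beta, cov_beta, True, 0, 0.0, fix)

    # special case: only the residual is free and no bird terms remain ->
    # closed-form REML (residual mean square), no iteration needed
    if free == ["residual"] and prob.bird_covariance(
        fix.get("individual", 0.0), fix.get("polygenic", 0.0)
    ) is None:
        XtVX = prob.XtX
        beta = np.linalg.solve(XtVX, prob.Xty)
        rss = prob.yty - 2 * float(prob.Xty @ beta) + float(beta @ XtVX @ beta)
        s2e = rss / (prob.n - prob.p)
        ll, beta, cov_beta = prob.restricted_loglik(
            fix.get("individual", 0.0), fix.get("polygenic", 0.0), s2e
        )
        vals = {"individual": fix.get("individual", 0.0),
                "polygenic": fix.get("polygenic", 0.0),
                "residual": s2e}
        return _finalize(design, vals, ll, beta, cov_beta, True, 0, 0.0, fix)

    def negloglik(theta: np.ndarray) -> float:
        vals = unpack(theta)
        try:
            ll, _, _ = prob.restricted_loglik(
                vals["individual"], vals["polygenic"], vals["residual"]
            )
        except np.linalg.LinAlgError:
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    lo, hi = np.log(vary) - 20.0, np.log(vary) + 6.0
    bounds = [(lo, hi)] * len(free)
    starts = []
    k = len(free)
    starts.append(np.log(np.full(k, vary / k)))
    resid_dom = np.full(k, 0.05 * vary)
    if "residual" in free:
        resid_dom[free.index("residual")] = 0.9 * vary
    starts.append(np.log(resid_dom))
    if start is not None:
        user = np.array(
            [max(start.as_dict()[name], vary * 1e-8) for name in free]
        )
        starts.append(np.log(user))

    best = None
    for theta0 in starts:
        res = optimize.minimize(
            negloglik,
            np.clip(theta0, lo, hi),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    if tol < 1e-7:
        # tight-tolerance requests: polish the quasi-Newton optimum with a
        # derivative-free simplex pass (finite-difference gradients limit
        # L-BFGS-B to ~1e-4 accuracy on the variance scale)
        polish = optimize.minimize(
            negloglik,
            best.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if polish.fun <= best.fun:
            polish.jac = best.jac
            polish.nit += best.nit
            polish.success = best.success
            best = polish

    vals = unpack(best.x)
    # bird components driven to the lower bound are numerically zero
    for name, t in zip(free, best.x):
        if name != "residual" and t <= lo + 1e-9:
            vals[name] = 0.0
    ll, beta, cov_beta = prob.restricted_loglik(
        max(vals["individual"], 0.0), max(vals["polygenic"], 0.0), vals["residual"]
    )
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    return _finalize(
        design, vals, ll, beta, cov_beta, bool(best.success), int(best.nit), grad_norm, fix
    )


def _finalize(design, vals, ll, beta, cov_beta, converged, n_iter, grad_norm, fix):
    se = np.sqrt(np.diag(cov_beta))
    fixed = pd.DataFrame({"estimate": beta, "se": se}, index=design.xnames)
    vc = VarianceComponents(
        sigma2_i=vals["individual"] if design.include_individual else 0.0,
        sigma2_a=vals["polygenic"] if design.A is not None else 0.0,
        sigma2_e=vals["residual"],
    )
    return MixedModelResult(
        varcomp=vc,
        fixed=fixed,
        cov_beta=cov_beta,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        grad_norm=grad_norm,
        design=design,
        fixed_variances=dict(fix),
    )


def _lsmean_vector(design: Design, factor: str, level: str) -> np.ndarray:
    """Contrast vector for a least-squares mean: the named factor at ``level``,
    every other factor averaged equally over its observed levels."""
    if factor not in design.factor_levels:
        raise InputError(f"factor {factor!r} is not in the fitted model")
    if level not in design.factor_levels[factor]:
        raise InputError(f"level {level!r} not observed for factor {factor!r}")
    c = np.zeros(design.p)
    c[0] = 1.0
    for f, colmap in design.factor_columns.items():
        if f == factor:
            col = colmap[level]
            if col is not None:
                c[col] = 1.0
        else:
            w = 1.0 / len(design.factor_levels[f])
            for lv, col in colmap.items():
                if col is not None:
                    c[col] = w
    return c


def genotype_lsmeans(result: MixedModelResult, factor: str = "genotype") -> pd.DataFrame:
    """Model-based (least-squares) means per genotype, with standard errors."""
    design = result.design
    if factor not in design.factor_levels:
        raise InputError(f"factor {factor!r} is not in the fitted model")
    beta = result.fixed["estimate"].to_numpy()
    rows = []
    for level in design.factor_levels[factor]:
        c = _lsmean_vector(design, factor, level)
        est = float(c @ beta)
        se = float(np.sqrt(c @ result.cov_beta @ c))
        rows.append({"level": level, "lsmean": est, "se": se})
    return pd.DataFrame(rows).set_index("level")


def contrast(
    result: MixedModelResult, level_a: str, level_b: str, factor: str = "genotype"
) -> dict[str, float]:
    """Wald test of lsmean(level_b) - lsmean(level_a)."""
    design = result.design
    if level_a == level_b:
        return {"estimate": 0.0, "se": 0.0, "z": 0.0, "p": 1.0}
    ca = _lsmean_vector(design, factor, level_a)
    cb = _lsmean_vector(design, factor, level_b)
    d = cb - ca
    beta = result.fixed["estimate"].to_numpy()
    est = float(d @ beta)
    se = float(np.sqrt(d @ result.cov_beta @ d))
    z = est / se if se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"estimate": est, "se": se, "z": z, "p": p}


def genotype_contrasts(
    result: MixedModelResult, alpha: float = 0.05, factor: str = "genotype"
) -> pd.DataFrame:
    """All pairwise genotype contrasts (later level minus earlier level)."""
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    design = result.design
    if factor not in design.factor_levels:
        raise InputError(f"factor {factor!r} is not in the fitted model")
    levels = design.factor_levels[factor]
    rows = []
    for ga, gb in combinations(levels, 2):
        c = contrast(result, ga, gb, factor=factor)
        rows.append(
            {
                "contrast": f"{gb} - {ga}",
                "estimate": c["estimate"],
                "se": c["se"],
                "z": c["z"],
                "p": c["p"],
                "significant": c["p"] <= alpha,
            }
        )
    return pd.DataFrame(rows).set_index("contrast")


def summarize_by_genotype(
    records: pd.DataFrame, genotypes: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Raw mean AP and SE per genotype for all / short / long races.

    ``records`` must be scored (ap, category columns); genotype comes either
    from a ``genotype`` column or by merging a (pigeon_id, genotype) table.
    Records for ungenotyped pigeons are excluded with a counted warning.
    Empty genotype-by-scope groups simply do not appear.
    """
    df = records.copy()
    if "genotype" not in df.columns:
        if genotypes is None:
            raise InputError("no genotype column and no genotype table supplied")
        df = df.merge(
            genotypes[["pigeon_id", "genotype"]], on="pigeon_id", how="left"
        )
    n_missing = int(df["genotype"].isna().sum())
    if n_missing:
        warnings.warn(
            f"excluded {n_missing} record(s) for pigeons without a genotype",
            stacklevel=2,
        )
        df = df.dropna(subset=["genotype"])
    for col in ("ap", "category"):
        if col not in df.columns:
            raise InputError(f"records must be scored first (missing {col!r})")

    rows = []
    for scope in ("all", "short", "long"):
        sub = df if scope == "all" else df[df["category"] == scope]
        for g, grp in sub.groupby("genotype", sort=True):
            ap = grp["ap"].to_numpy(dtype=float)
            se = float(np.std(ap, ddof=1) / np.sqrt(len(ap))) if len(ap) > 1 else np.nan
            rows.append(
                {
                    "genotype": g,
                    "scope": scope,
                    "rr": len(ap),
                    "mean_ap": float(np.mean(ap)),
                    "se": se,
                }
            )
    return pd.DataFrame(rows).set_index(["genotype", "scope"])
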