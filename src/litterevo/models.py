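"""Continuous-trait macroevolution models on a phylogeny: BM, EB, OU.

Under each model the tip trait values are multivariate normal with mean
``z0 * 1`` (the root/ancestral state) and a covariance matrix determined by
the model parameters and the tree's shared-ancestry structure:

* **BM** (Brownian motion):  ``V_ij = beta * t_ij`` where ``t_ij`` is the
  root-to-MRCA path length of tips i and j and ``beta = sigma^2`` the rate
  (trait variance per Myr).
* **EB** (early burst): BM whose instantaneous rate decays exponentially in
  time at rate ``r <= 0``:  ``V_ij = beta * (exp(r * t_ij) - 1) / r``, with
  the BM limit at r = 0.
* **OU** (Ornstein-Uhlenbeck): mean reversion with strength ``alpha`` toward
  an optimum held equal to the root state:
  ``V_ij = beta/(2 alpha) * exp(-alpha (T_i + T_j - 2 t_ij))
  * (1 - exp(-2 alpha t_ij))``, BM limit at alpha = 0.  Valid for
  non-ultrametric trees (T_i is the root-to-tip depth of tip i).

Per-species measurement error enters as ``se_i^2`` added to the covariance
diagonal and held fixed during fitting.  Models are fit by maximum
likelihood: the root state and rate have closed-form generalized-least-
squares solutions given the shape parameter (r or alpha), which is optimized
numerically within bounds; with measurement error the rate no longer
profiles out and (beta, shape) are optimized jointly.  The OU "phylogenetic
half-life" ln(2)/alpha measures how fast ancestral influence decays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .selection import aicc as _aicc
from .tree import Phylogeny, SharedAncestryMatrix, shared_ancestry

__all__ = [
    "TraitVector",
    "EvoModelFit",
    "FitOptions",
    "SingularCovarianceError",
    "bm_covariance",
    "eb_covariance",
    "ou_covariance",
    "log_likelihood",
    "fit_ml",
    "fit_all_models",
    "phylogenetic_half_life",
    "read_trait_table",
]

MODELS = ("BM", "EB", "OU")

#: free parameters per model under the optimum-equals-root OU convention
PARAM_COUNT = {"BM": 2, "EB": 3, "OU": 3}
#: alternative convention counting a free OU optimum as a fourth parameter
PARAM_COUNT_FREE_OPTIMUM = {"BM": 2, "EB": 3, "OU": 4}

_COND_LIMIT = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    def __init__(self, cond: float):
        self.cond = cond
        super().__init__(
            f"covariance matrix is numerically singular (condition number "
            f"~{cond:.3g} > {_COND_LIMIT:.0e})"
        )


@dataclass
class TraitVector:
    """Species-aligned ln-scale trait values with optional standard errors."""

    species_order: list[str]
    values: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species_order),):
            raise ValueError("values must align with species_order")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite (no missing data)")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.values.shape:
                raise ValueError("se must align with values")
            if np.any(~np.isfinite(self.se)) or np.any(self.se < 0):
                raise ValueError("se must be finite and >= 0")

    @property
    def n(self) -> int:
        return len(self.species_order)


def read_trait_table(path, trait: str | None = None) -> TraitVector:
    """Read a CSV/TSV with columns species, value (or a named trait), se.

    If ``trait`` is given, that column is used as the value column; a column
    ``se`` or ``<trait>_se`` supplies standard errors when present.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    value_col = trait or "value"
    if value_col not in df.columns:
        raise ValueError(f"trait table has no column {value_col!r}")
    se_col = None
    for cand in (f"{value_col}_se", "se"):
        if cand in df.columns:
            se_col = cand
            break
    return TraitVector(
        species_order=df["species"].astype(str).tolist(),
        values=df[value_col].to_numpy(dtype=float),
        se=df[se_col].to_numpy(dtype=float) if se_col else None,
    )


# ---------------------------------------------------------------------------
# Covariance builders
# ---------------------------------------------------------------------------


def bm_covariance(sam: SharedAncestryMatrix, beta: float) -> np.ndarray:
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    return beta * sam.t_shared


def eb_covariance(sam: SharedAncestryMatrix, beta: float, r: float) -> np.ndarray:
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if r > 0:
        raise ValueError(f"early-burst rate change must be <= 0, got {r}")
    t = sam.t_shared
    if r == 0:
        return beta * t
    return beta * np.expm1(r * t) / r


def ou_covariance(sam: SharedAncestryMatrix, beta: float, alpha: float) -> np.ndarray:
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    t = sam.t_shared
    if alpha == 0:
        return beta * t
    T = sam.tip_depth
    decay = np.exp(-alpha * (T[:, None] + T[None, :] - 2.0 * t))
    return (beta / (2.0 * alpha)) * decay * (-np.expm1(-2.0 * alpha * t))


def _shape_matrix(model_id: str, sam: SharedAncestryMatrix, theta: float) -> np.ndarray:
    """Covariance at beta = 1; theta is r (EB) or alpha (OU), ignored for BM."""
    if model_id == "BM":
        return sam.t_shared
    if model_id == "EB":
        return eb_covariance(sam, 1.0, theta)
    if model_id == "OU":
        return ou_covariance(sam, 1.0, theta)
    raise ValueError(f"unknown model {model_id!r}")


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _chol(V: np.ndarray):
    """Cholesky factor with a condition-number guard on the diagonal."""
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        raise SingularCovarianceError(np.linalg.cond(V)) from None
    d = np.diag(L)
    cond_est = (d.max() / d.min()) ** 2
    if cond_est > _COND_LIMIT:
        raise SingularCovarianceError(cond_est)
    return L


def log_likelihood(
    V: np.ndarray,
    z0: float,
    trait: TraitVector,
    use_se: bool = False,
) -> float:
    """Multivariate-normal log-density of the tip values.

    With ``use_se``, per-species squared standard errors are added to the
    covariance diagonal before factorization.
    """
    V = np.asarray(V, dtype=float)
    x = trait.values
    n = len(x)
    if V.shape != (n, n):
        raise ValueError("covariance shape does not match trait length")
    if use_se and trait.se is not None:
        V = V + np.diag(trait.se**2)
    L = _chol(V)
    resid = x - z0
    u = linalg.solve_triangular(L, resid, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (n * math.log(2.0 * math.pi) + logdet + u @ u))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Optimizer configuration for :func:`fit_ml`.

    Bounds default to wide, biologically inert ranges; the EB rate-change
    lower bound scales with tree depth so that the rate can decay by up to
    five orders of magnitude from root to tips.
    """

    use_se: bool = False
    restarts: int = 10
    seed: int = 0
    beta_bounds: tuple[float, float] = (1e-8, 1e4)
    # alpha = 0 is the exact BM limit, so the OU search space nests BM
    alpha_bounds: tuple[float, float] = (0.0, 50.0)
    r_bounds: tuple[float, float] | None = None  # default set from depth
    z0_bounds: tuple[float, float] | None = None  # default from trait range
    free_optimum_params: bool = False  # count the OU optimum as a 4th param

    def resolved_r_bounds(self, depth: float) -> tuple[float, float]:
        if self.r_bounds is not None:
            return self.r_bounds
        return (-math.log(1e5) / depth, 0.0)


@dataclass
class EvoModelFit:
    """A fitted trait-evolution model: MLE parameters and information scores."""

    model_id: str
    beta: float
    z0: float
    lnL: float
    p: int
    n: int
    aic: float
    aicc: float
    alpha: float | None = None
    r: float | None = None
    half_life: float | None = None
    bound_hits: list[str] = field(default_factory=list)
    restarts: int = 0

    def as_row(self) -> dict:
        return {
            "model": self.model_id,
            "lnL": self.lnL,
            "beta": self.beta,
            "r": self.r,
            "alpha": self.alpha,
            "z0": self.z0,
            "p": self.p,
            "n": self.n,
            "AIC": self.aic,
            "AICc": self.aicc,
            "half_life": self.half_life,
            "bound_hits": ";".join(self.bound_hits),
        }


def phylogenetic_half_life(alpha: float) -> float:
    """t_1/2 = ln(2)/alpha, the time to traverse half the distance from the
    ancestral state to the optimum; +inf for alpha <= 0 (the BM limit)."""
    if alpha <= 0:
        return math.inf
    return math.log(2.0) / alpha


def _gls_profile(C: np.ndarray, x: np.ndarray):
    """Closed-form (z0, Q, logdet) for covariance beta*C given shape C.

    z0 = (1' C^-1 x) / (1' C^-1 1); Q = (x - z0)' C^-1 (x - z0).
    """
    L = _chol(C)
    one = np.ones_like(x)
    u1 = linalg.solve_triangular(L, one, lower=True)
    ux = linalg.solve_triangular(L, x, lower=True)
    z0 = float((u1 @ ux) / (u1 @ u1))
    resid = ux - z0 * u1
    Q = float(resid @ resid)
    logdet = float(2.0 * np.sum(np.log(np.diag(L))))
    return z0, Q, logdet


def _profiled_lnl(C: np.ndarray, x: np.ndarray, beta_bounds):
    """Maximized lnL over (z0, beta) for V = beta*C; beta clamped to bounds."""
    n = len(x)
    z0, Q, logdet = _gls_profile(C, x)
    beta = Q / n
    beta_c = min(max(beta, beta_bounds[0]), beta_bounds[1])
    lnl = -0.5 * (
        n * math.log(2.0 * math.pi) + n * math.log(beta_c) + logdet + Q / beta_c
    )
    return lnl, beta_c, z0


def fit_ml(
    model_id: str,
    trait: TraitVector,
    tree: Phylogeny,
    options: FitOptions | None = None,
) -> EvoModelFit:
    """Fit a trait-evolution model by bounded maximum likelihood.

    The tree may contain extra tips; the shared-ancestry matrix is restricted
    to the trait's species.  Without measurement error the root state and
    rate are profiled out analytically and only the shape parameter (alpha or
    r) is optimized, from a seeded multi-start; with measurement error the
    (rate, shape) pair is optimized by bounded quasi-Newton from seeded
    restarts.  Deterministic given ``options.seed``.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; expected one of {MODELS}")
    options = options or FitOptions()
    tip_set = set(tree.tip_labels)
    missing = [s for s in trait.species_order if s not in tip_set]
    if missing:
        raise ValueError(f"trait species missing from tree: {missing}")
    sam = shared_ancestry(tree).reorder(trait.species_order)
    return _fit_ml_sam(model_id, trait, sam, options)


def _fit_ml_sam(
    model_id: str,
    trait: TraitVector,
    sam: SharedAncestryMatrix,
    options: FitOptions,
) -> EvoModelFit:
    x = trait.values
    n = len(x)
    depth = sam.depth
    use_se = options.use_se and trait.se is not None and np.any(trait.se > 0)
    rng = np.random.default_rng(options.seed)

    if model_id == "BM":
        theta_bounds = None
    elif model_id == "EB":
        theta_bounds = options.resolved_r_bounds(depth)
    else:
        theta_bounds = options.alpha_bounds

    if not use_se:
        lnl_fn = lambda theta: _profiled_lnl(
            _shape_matrix(model_id, sam, theta), x, options.beta_bounds
        )
        if theta_bounds is None:
            lnl, beta, z0 = lnl_fn(0.0)
            theta = None
        else:
            theta = _optimize_shape(lnl_fn, theta_bounds, model_id, options, rng)
            lnl, beta, z0 = lnl_fn(theta)
    else:
        lnl, beta, z0, theta = _fit_with_se(
            model_id, trait, sam, theta_bounds, options, rng
        )

    alpha = theta if model_id == "OU" else None
    r = theta if model_id == "EB" else None
    p = (
        PARAM_COUNT_FREE_OPTIMUM[model_id]
        if options.free_optimum_params
        else PARAM_COUNT[model_id]
    )
    bound_hits = _bound_flags(model_id, beta, theta, options, theta_bounds)
    return EvoModelFit(
        model_id=model_id,
        beta=beta,
        z0=z0,
        lnL=lnl,
        p=p,
        n=n,
        aic=-2.0 * lnl + 2.0 * p,
        aicc=_aicc(lnl, p, n),
        alpha=alpha,
        r=r,
        half_life=phylogenetic_half_life(alpha) if model_id == "OU" else None,
        bound_hits=bound_hits,
        restarts=options.restarts,
    )


def _optimize_shape(lnl_fn, bounds, model_id, options, rng) -> float:
    """1-D bounded maximization over the shape parameter (alpha or r).

    Seeded multi-start: endpoint values, a deterministic spread across the
    bounds, and jittered starts; the best start is polished with Brent."""
    lo, hi = bounds
    if model_id == "OU":  # log-spaced spread for the scale-like alpha
        base = np.geomspace(max(lo, 1e-7), hi, num=max(options.restarts, 4))
    else:
        base = np.linspace(lo, hi, num=max(options.restarts, 4))
    jitter = rng.uniform(lo, hi, size=max(options.restarts // 2, 2))
    cands = np.unique(np.clip(np.concatenate([[lo, hi], base, jitter]), lo, hi))

    def neg(theta: float) -> float:
        try:
            return -lnl_fn(float(theta))[0]
        except SingularCovarianceError:
            return np.inf

    vals = np.array([neg(t) for t in cands])
    best_i = int(np.argmin(vals))
    best_theta, best_val = float(cands[best_i]), float(vals[best_i])

    # polish within the bracket around the best grid point
    left = cands[best_i - 1] if best_i > 0 else lo
    right = cands[best_i + 1] if best_i < len(cands) - 1 else hi
    res = optimize.minimize_scalar(
        neg, bounds=(left, right), method="bounded",
        options={"xatol": 1e-12},
    )
    if res.fun < best_val:
        best_theta, best_val = float(res.x), float(res.fun)
    # global polish in case the bracket missed
    res2 = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
    )
    if res2.fun < best_val:
        best_theta = float(res2.x)
    return best_theta


def _fit_with_se(model_id, trait, sam, theta_bounds, options, rng):
    """Joint (log beta, theta) optimization with fixed diag(se^2)."""
    x = trait.values
    n = len(x)
    D = np.diag(trait.se**2)
    lb_beta, ub_beta = np.log(options.beta_bounds[0]), np.log(options.beta_bounds[1])

    def lnl_at(log_beta: float, theta: float):
        beta = math.exp(log_beta)
        V = beta * _shape_matrix(model_id, sam, theta) + D
        L = _chol(V)
        one = np.ones(n)
        u1 = linalg.solve_triangular(L, one, lower=True)
        ux = linalg.solve_triangular(L, x, lower=True)
        z0 = float((u1 @ ux) / (u1 @ u1))
        resid = ux - z0 * u1
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        lnl = -0.5 * (n * math.log(2 * math.pi) + logdet + resid @ resid)
        return float(lnl), z0

    def neg(params):
        try:
            return -lnl_at(*params)[0] if len(params) == 2 else -lnl_at(params[0], 0.0)[0]
        except SingularCovarianceError:
            return np.inf

    # start from the no-measurement-error solution
    no_se = TraitVector(trait.species_order, trait.values)
    opts0 = FitOptions(
        use_se=False, restarts=options.restarts, seed=options.seed,
        beta_bounds=options.beta_bounds, alpha_bounds=options.alpha_bounds,
        r_bounds=options.r_bounds,
    )
    warm = _fit_ml_sam(model_id, no_se, sam, opts0)
    theta_warm = warm.alpha if model_id == "OU" else warm.r

    if theta_bounds is None:
        bounds = [(lb_beta, ub_beta)]
        starts = [[math.log(max(warm.beta, options.beta_bounds[0]))]]
        for _ in range(options.restarts - 1):
            starts.append([rng.uniform(lb_beta, ub_beta)])
    else:
        bounds = [(lb_beta, ub_beta), theta_bounds]
        starts = [
            [math.log(max(warm.beta, options.beta_bounds[0])), float(theta_warm)]
        ]
        for _ in range(options.restarts - 1):
            starts.append(
                [rng.uniform(lb_beta, ub_beta),
                 rng.uniform(theta_bounds[0], theta_bounds[1])]
            )

    best = None
    for s in starts:
        res = optimize.minimize(
            neg, np.array(s), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"{model_id} fit with measurement error failed to converge from "
            f"{len(starts)} starts"
        )
    log_beta = float(best.x[0])
    theta = float(best.x[1]) if theta_bounds is not None else None
    lnl, z0 = lnl_at(log_beta, theta if theta is not None else 0.0)
    return lnl, math.exp(log_beta), z0, theta


def _bound_flags(model_id, beta, theta, options, theta_bounds) -> list[str]:
    flags = []
    for name, val, (lo, hi) in [("beta", beta, options.beta_bounds)]:
        if math.isclose(val, lo, rel_tol=1e-6) or math.isclose(val, hi, rel_tol=1e-6):
            flags.append(name)
    if theta is not None and theta_bounds is not None:
        lo, hi = theta_bounds
        name = "alpha" if model_id == "OU" else "r"
        at_lo = math.isclose(theta, lo, rel_tol=1e-6, abs_tol=1e-12)
        at_hi = math.isclose(theta, hi, rel_tol=1e-6, abs_tol=1e-12)
        if at_lo or at_hi:
            flags.append(name)
    return flags


def fit_all_models(
    trait: TraitVector,
    tree: Phylogeny,
    options: FitOptions | None = None,
    models: tuple[str, ...] = MODELS,
) -> dict[str, EvoModelFit]:
    """Fit BM, EB and OU to one trait; keys are model ids."""
    return {m: fit_ml(m, trait, tree, options) for m in models}
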