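"""Multi-regime Ornstein-Uhlenbeck and Brownian-motion trait models on trees.

Implements the seven-model suite used for regime comparisons on painted
ultrametric phylogenies:

========  =================================================================
BM1       single-rate Brownian motion (root mean mu, one sigma^2)
BMS       Brownian motion with regime-specific rates
OU1       single-optimum OU (one theta, alpha, sigma^2)
OUM       regime-specific optima theta, shared alpha and sigma^2
OUMV      regime-specific theta and sigma^2, shared alpha
OUMA      regime-specific theta and alpha, shared sigma^2
OUMVA     all three parameters regime-specific
========  =================================================================

The trait follows ``dX = alpha(t) (theta(t) - X) dt + sigma(t) dW`` with
piecewise-constant parameters along each root-to-tip path (the regime of a
branch is the regime painted on it).  Tips are then jointly Gaussian with
mean ``W theta`` -- ``W`` the row-stochastic matrix of exponentially
discounted regime occupancies -- and a covariance assembled from per-branch
OU variance increments attenuated toward the present.  By default the root
is fixed (zero variance) at the root regime's optimum; a stationary-root
mode adds the stationary variance ``sigma^2/(2 alpha)`` of the root regime.

Optima (and the BM root mean) are profiled out by GLS at every likelihood
evaluation, and the overall sigma^2 scale has a closed-form ML solution, so
numerical optimization only runs over the log of alpha (and of regime rate
ratios), from a deterministic multi-start grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .exceptions import FitError, ValidationError
from .phylo import Phylogeny, RegimeMap, check_ultrametric

__all__ = [
    "MODELS",
    "ModelSpec",
    "OUModel",
    "OUResults",
    "build_design",
    "build_covariance",
    "loglik",
    "simulate_tips",
]

LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which of (theta, alpha, sigma^2) vary by regime, and whether the
    process is OU (alpha > 0) or BM (alpha = 0)."""

    name: str
    is_ou: bool
    multi_theta: bool
    multi_alpha: bool
    multi_sigma: bool

    def k(self, n_regimes: int) -> int:
        """Free-parameter count (includes profiled optima / root mean)."""
        if not self.is_ou:  # BM: root mean + sigma^2 (per regime or shared)
            return 1 + (n_regimes if self.multi_sigma else 1)
        k = n_regimes if self.multi_theta else 1
        k += n_regimes if self.multi_alpha else 1
        k += n_regimes if self.multi_sigma else 1
        return k


MODELS: dict[str, ModelSpec] = {
    "BM1": ModelSpec("BM1", False, False, False, False),
    "BMS": ModelSpec("BMS", False, False, False, True),
    "OU1": ModelSpec("OU1", True, False, False, False),
    "OUM": ModelSpec("OUM", True, True, False, False),
    "OUMV": ModelSpec("OUMV", True, True, False, True),
    "OUMA": ModelSpec("OUMA", True, True, True, False),
    "OUMVA": ModelSpec("OUMVA", True, True, True, True),
}
MODEL_ORDER = ["BM1", "BMS", "OU1", "OUM", "OUMV", "OUMA", "OUMVA"]


# ---------------------------------------------------------------- tree cache
class _TreeCache:
    """Per-(tree, painting) precomputation for fast likelihood evaluation.

    ``P[i, j] = 1`` iff the branch subtending node j lies on the root-to-i
    path; with it, path attenuations and per-regime variance increments are
    matrix-vector products.
    """

    def __init__(self, tree: Phylogeny, regimes: RegimeMap):
        self.tree = tree
        self.alphabet = regimes.alphabet
        self.R = len(self.alphabet)
        ridx = regimes.regime_index()
        n = tree.n_nodes
        self.n_nodes = n
        self.blen = tree.blen.copy()
        self.blen[tree.root] = 0.0  # root edges are bookkeeping, not process time
        self.breg = np.zeros(n, dtype=np.int64)
        for node, r in regimes.branch_regime.items():
            self.breg[node] = ridx[r]
        self.breg[tree.root] = ridx[regimes.root_regime]
        self.root_ridx = ridx[regimes.root_regime]
        self.reg_mask = np.stack([(self.breg == r) for r in range(self.R)]).astype(float)
        self.reg_mask[:, tree.root] = 0.0

        P = np.zeros((n, n))
        for node in tree.preorder():
            p = tree.parent[node]
            if p >= 0:
                P[node] = P[p]
                P[node, node] = 1.0
        self.P = P
        self.tips = np.array(tree.tip_ids)
        self.Ptips = P[self.tips]
        d = tree.depths()
        self.depth = d
        self.T = float(max(d[self.tips]))
        self.mrca = tree.mrca_matrix()

    def attenuation(self, alphas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative attenuation A(0->node) and E = exp(-A)."""
        a_branch = alphas[self.breg] * self.blen
        A = self.P @ a_branch
        return A, np.exp(-A)

    def design(self, alphas: np.ndarray) -> np.ndarray:
        """Row-stochastic tip x regime weight matrix (fixed-root mode adds the
        residual root weight to the root regime's column)."""
        A, E = self.attenuation(alphas)
        ab = alphas[self.breg]
        u = np.exp(A) * -np.expm1(-ab * self.blen)  # e^{A_j} (1 - e^{-alpha l})
        W = (self.Ptips @ (u[None, :] * self.reg_mask).T) * E[self.tips][:, None]
        W[:, self.root_ridx] += E[self.tips]
        return W

    def cov_basis(self, alphas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-regime variance-increment accumulations Gtil (nodes x R) and E.

        For unit sigma^2 in regime r, ``V_ij = E_i E_j Gtil[mrca(i,j), r]``.
        """
        A, E = self.attenuation(alphas)
        ab = alphas[self.breg]
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(
                ab > 0, -np.expm1(-2.0 * ab * self.blen) / (2.0 * ab), self.blen
            )
        c = np.exp(2.0 * A) * phi
        Gtil = self.P @ (c[None, :] * self.reg_mask).T
        return Gtil, E

    def covariance(
        self, alphas: np.ndarray, sigmas: np.ndarray, root_mode: str = "fixed"
    ) -> np.ndarray:
        Gtil, E = self.cov_basis(alphas)
        H = Gtil @ sigmas
        if root_mode == "stationary":
            a0 = alphas[self.root_ridx]
            if a0 <= 0:
                raise ValidationError("stationary root undefined for alpha = 0 (BM)")
            H = H + sigmas[self.root_ridx] / (2.0 * a0)
        Et = E[self.tips]
        return np.outer(Et, Et) * H[self.mrca]


def _as_cache(tree: Phylogeny, regimes: RegimeMap) -> _TreeCache:
    return _TreeCache(tree, regimes)


def _single_regime_map(tree: Phylogeny, label: str = "all") -> RegimeMap:
    return RegimeMap(
        {n: label for n in range(tree.n_nodes) if n != tree.root}, (label,), label
    )


# --------------------------------------------------------------- public ops
def build_design(tree: Phylogeny, regimes: RegimeMap, alphas) -> np.ndarray:
    """Tip x regime weight matrix W for per-regime pull strengths ``alphas``."""
    alphas = _per_regime(alphas, regimes)
    if np.any(alphas < 0):
        raise ValidationError("alpha must be >= 0")
    return _as_cache(tree, regimes).design(alphas)


def build_covariance(
    tree: Phylogeny, regimes: RegimeMap, alphas, sigmas, root_mode: str = "fixed"
) -> np.ndarray:
    """Tip covariance matrix under the piecewise OU (or BM, alpha=0) process."""
    alphas = _per_regime(alphas, regimes)
    sigmas = _per_regime(sigmas, regimes)
    if np.any(alphas < 0):
        raise ValidationError("alpha must be >= 0")
    if np.any(sigmas <= 0):
        raise ValidationError("sigma^2 must be > 0")
    V = _as_cache(tree, regimes).covariance(alphas, sigmas, root_mode)
    w = linalg.eigvalsh(V)
    if w[0] <= 0:
        raise ValidationError(f"covariance not positive definite (min eigenvalue {w[0]:.3g})")
    return V


def _per_regime(x, regimes: RegimeMap) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    R = len(regimes.alphabet)
    if x.size == 1:
        return np.full(R, x[0])
    if x.size != R:
        raise ValidationError(f"expected 1 or {R} per-regime values, got {x.size}")
    return x


def loglik(
    tree: Phylogeny,
    regimes: RegimeMap,
    params: dict,
    tip_values,
    root_mode: str = "fixed",
) -> float:
    """Gaussian log-likelihood of tip values under explicit parameters.

    ``params`` carries ``theta`` (scalar or per regime; for BM the root mean),
    ``alpha`` (scalar/per regime; 0 for BM) and ``sigma2`` (scalar/per regime).
    """
    cache = _as_cache(tree, regimes)
    alphas = _per_regime(params["alpha"], regimes)
    sigmas = _per_regime(params["sigma2"], regimes)
    theta = np.atleast_1d(np.asarray(params["theta"], dtype=float))
    y = _tip_vector(tree, tip_values)
    V = cache.covariance(alphas, sigmas, root_mode)
    if theta.size == 1:
        mean = np.full(len(y), theta[0])
    elif np.all(alphas == 0):
        mean = np.full(len(y), theta[cache.root_ridx])
    else:
        mean = cache.design(alphas) @ theta
    return _mvn_logpdf(y - mean, V)


def _mvn_logpdf(resid: np.ndarray, V: np.ndarray) -> float:
    n = len(resid)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValidationError(f"singular covariance: {exc}") from None
    z = linalg.solve_triangular(L, resid, lower=True)
    return float(-0.5 * n * LOG2PI - np.log(np.diag(L)).sum() - 0.5 * z @ z)


def _tip_vector(tree: Phylogeny, tip_values) -> np.ndarray:
    if isinstance(tip_values, dict):
        missing = [l for l in tree.tip_labels if l not in tip_values]
        if missing:
            raise ValidationError(f"tips without trait values: {missing}")
        return np.array([float(tip_values[l]) for l in tree.tip_labels])
    y = np.asarray(tip_values, dtype=float)
    if y.shape != (tree.n_tips,):
        raise ValidationError("tip value vector length does not match tip count")
    return y


def simulate_tips(
    tree: Phylogeny,
    regimes: RegimeMap,
    params: dict,
    seed,
    root_mode: str = "fixed",
) -> dict[str, float]:
    """Draw one tip-value realization ``y ~ MVN(W theta, V)`` (BM: mean mu 1)."""
    cache = _as_cache(tree, regimes)
    alphas = _per_regime(params["alpha"], regimes)
    sigmas = _per_regime(params["sigma2"], regimes)
    theta = np.atleast_1d(np.asarray(params["theta"], dtype=float))
    y = _simulate_cached(cache, alphas, sigmas, theta, seed, root_mode)
    return dict(zip(tree.tip_labels, y))


def _simulate_cached(cache, alphas, sigmas, theta, seed, root_mode) -> np.ndarray:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = cache.covariance(alphas, sigmas, root_mode)
    if theta.size == 1 or np.all(alphas == 0):
        mean = np.full(len(cache.tips), theta[0] if theta.size == 1 else theta[cache.root_ridx])
    else:
        mean = cache.design(alphas) @ theta
    L = linalg.cholesky(V + 1e-12 * np.mean(np.diag(V)) * np.eye(len(V)), lower=True)
    return mean + L @ rng.standard_normal(len(V))


# -------------------------------------------------------------------- model
@dataclass
class FitConfig:
    """Deterministic multi-start optimization settings."""

    alpha_bounds: tuple[float, float] = (1e-4, 50.0)  # in units of 1/T
    rho_bounds: tuple[float, float] = (1e-4, 1e4)  # regime variance/pull ratios
    n_alpha_grid: int = 5
    n_rho_grid: int = 5
    n_polish: int = 4
    maxiter: int = 300
    tol: float = 1e-8
    extra_starts: tuple = ()  # optional warm-start vectors in packed log space


class OUModel:
    """Trait-evolution model on a regime-painted ultrametric tree.

    Parameters
    ----------
    tree : Phylogeny
        Rooted ultrametric tree.
    tip_values : dict or array
        Trait value per tip (arrays follow ``tree.tip_labels`` order).
    regimes : RegimeMap, optional
        Branch painting; required for regime-dependent models.
    model : str
        One of BM1, BMS, OU1, OUM, OUMV, OUMA, OUMVA.
    root_mode : str
        "fixed" (root at the root regime's optimum, zero variance; default)
        or "stationary" (adds the root regime's stationary variance).
    common_theta : bool
        Constrain the optima to a single shared theta while keeping the
        model's alpha/sigma^2 regime structure (used by null bootstraps).
    """

    def __init__(
        self,
        tree: Phylogeny,
        tip_values,
        regimes: RegimeMap | None = None,
        model: str = "OUM",
        root_mode: str = "fixed",
        common_theta: bool = False,
        check_tree: bool = True,
        cache: "_TreeCache | None" = None,
    ):
        if model not in MODELS:
            raise ValidationError(f"unknown model {model!r} (choose from {MODEL_ORDER})")
        self.spec = MODELS[model]
        self.model_name = model
        if regimes is None:
            regimes = _single_regime_map(tree)
        self.tree = tree
        self.regimes = regimes
        self.root_mode = root_mode
        self.common_theta = common_theta
        if check_tree:
            ok, dev = check_ultrametric(tree, rel_tol=1e-6)
            if not ok:
                raise ValidationError(
                    f"tree is not ultrametric (relative depth deviation {dev:.3g})"
                )
        self.cache = cache if cache is not None else _as_cache(tree, regimes)
        self.y = _tip_vector(tree, tip_values)
        self.n = len(self.y)
        R = self.cache.R
        self.n_free_alpha = (R if self.spec.multi_alpha else 1) if self.spec.is_ou else 0
        self.n_free_rho = (R - 1) if self.spec.multi_sigma else 0
        self.n_theta = R if (self.spec.multi_theta and not common_theta) else 1

    @classmethod
    def from_dataframe(
        cls, tree: Phylogeny, data: pd.DataFrame, value_col: str, label_col: str = "clade", **kw
    ) -> "OUModel":
        vals = dict(zip(data[label_col].astype(str), data[value_col].astype(float)))
        return cls(tree, vals, **kw)

    @property
    def k(self) -> int:
        k = MODELS[self.model_name].k(self.cache.R)
        if self.common_theta and self.spec.multi_theta:
            k -= self.cache.R - 1
        return k

    # ------------------------------------------------------------- internals
    def _unpack(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Packed log-parameters -> (alphas per regime, relative sigma2 per regime)."""
        R = self.cache.R
        if self.spec.is_ou:
            a = np.exp(u[: self.n_free_alpha])
            alphas = a if self.spec.multi_alpha else np.full(R, a[0])
        else:
            alphas = np.zeros(R)
        rel = np.ones(R)
        if self.spec.multi_sigma:
            rel[1:] = np.exp(u[self.n_free_alpha :])
        return alphas, rel

    def _design_for(self, alphas: np.ndarray) -> np.ndarray:
        if self.n_theta == 1:
            return np.ones((self.n, 1))
        return self.cache.design(alphas)

    def _profile(self, u: np.ndarray):
        """Profile logL over theta (GLS) and the overall sigma^2 scale.

        Returns (logL, theta_hat, scale_hat, alphas, rel_sigma)."""
        alphas, rel = self._unpack(u)
        Gtil, E = self.cache.cov_basis(alphas)
        H = Gtil @ rel
        if self.root_mode == "stationary" and self.spec.is_ou:
            H = H + rel[self.cache.root_ridx] / (2.0 * alphas[self.cache.root_ridx])
        Et = E[self.cache.tips]
        V0 = np.outer(Et, Et) * H[self.cache.mrca]
        try:
            L = linalg.cholesky(V0, lower=True)
        except linalg.LinAlgError:
            return -np.inf, None, None, alphas, rel
        W = self._design_for(alphas)
        Wt = linalg.solve_triangular(L, W, lower=True)
        yt = linalg.solve_triangular(L, self.y, lower=True)
        theta, *_ = np.linalg.lstsq(Wt, yt, rcond=None)
        r = yt - Wt @ theta
        rss = float(r @ r)
        if rss <= 0:
            return -np.inf, None, None, alphas, rel
        scale = rss / self.n
        logdet = 2.0 * np.log(np.diag(L)).sum()
        ll = -0.5 * self.n * (LOG2PI + 1.0 + np.log(scale)) - 0.5 * logdet
        return float(ll), theta, scale, alphas, rel

    def _starts(self, config: FitConfig) -> list[np.ndarray]:
        T = self.cache.T
        lo, hi = np.log(config.alpha_bounds[0] / T), np.log(config.alpha_bounds[1] / T)
        a_grid = np.linspace(lo, hi, config.n_alpha_grid)
        rho_grid = np.linspace(
            np.log(0.25), np.log(4.0), min(config.n_rho_grid, 3)
        )
        grids = []
        for _ in range(self.n_free_alpha):
            grids.append(a_grid)
        for _ in range(self.n_free_rho):
            grids.append(rho_grid)
        if not grids:
            return [np.array([])]
        mesh = np.meshgrid(*grids, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        starts = [p for p in pts]
        starts.extend(np.asarray(s, dtype=float) for s in config.extra_starts)
        return starts

    def _bounds(self, config: FitConfig):
        T = self.cache.T
        b = [(np.log(config.alpha_bounds[0] / T), np.log(config.alpha_bounds[1] / T))] * self.n_free_alpha
        b += [(np.log(config.rho_bounds[0]), np.log(config.rho_bounds[1]))] * self.n_free_rho
        return b

    # ------------------------------------------------------------------ fit
    def fit(self, config: FitConfig | None = None) -> "OUResults":
        config = config or FitConfig()
        if self.n < self.k + 2:
            raise ValidationError(
                f"{self.model_name}: need at least k+2 = {self.k + 2} tips, have {self.n}"
            )
        ndim = self.n_free_alpha + self.n_free_rho
        starts = self._starts(config)
        if ndim == 0:
            ll, theta, scale, alphas, rel = self._profile(np.array([]))
            if not np.isfinite(ll):
                raise FitError(f"{self.model_name}: likelihood evaluation failed")
            return self._package(np.array([]), ll, theta, scale, alphas, rel, [ll], 0)

        objs = []
        for s in starts:
            ll = self._profile(s)[0]
            objs.append(-ll if np.isfinite(ll) else np.inf)
        order = np.argsort(objs, kind="stable")[: max(1, config.n_polish)]
        bounds = self._bounds(config)

        def nll(u):
            ll = self._profile(u)[0]
            return -ll if np.isfinite(ll) else 1e12

        best = None
        restart_objs = []
        for idx in order:
            res = optimize.minimize(
                nll,
                starts[idx],
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": config.maxiter, "ftol": config.tol, "gtol": 1e-10},
            )
            restart_objs.append(float(res.fun))
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise FitError(
                f"{self.model_name}: no start converged (objectives {restart_objs})"
            )
        ll, theta, scale, alphas, rel = self._profile(best.x)
        return self._package(best.x, ll, theta, scale, alphas, rel, restart_objs, len(order))

    def _package(self, u, ll, theta, scale, alphas, rel, restart_objs, n_restarts):
        sigmas = scale * rel
        T = self.cache.T
        at_upper = bool(self.spec.is_ou and np.any(alphas >= 0.999 * 50.0 / T))
        return OUResults(
            model=self,
            packed=np.asarray(u, dtype=float),
            llf=float(ll),
            theta=np.asarray(theta, dtype=float),
            alphas=alphas.copy(),
            sigmas=np.asarray(sigmas, dtype=float),
            restart_objectives=list(restart_objs),
            n_restarts=n_restarts,
            alpha_at_upper_bound=at_upper,
        )


@dataclass
class OUResults:
    """Fitted trait-evolution model: estimates, information criteria, diagnostics."""

    model: OUModel
    packed: np.ndarray
    llf: float
    theta: np.ndarray  # GLS optima (length R, or 1 for single-theta models)
    alphas: np.ndarray  # per regime (0 for BM)
    sigmas: np.ndarray  # per regime
    restart_objectives: list[float]
    n_restarts: int
    alpha_at_upper_bound: bool = False
    _bse_cache: np.ndarray | None = field(default=None, repr=False)

    # --------------------------------------------------------------- scalars
    @property
    def k(self) -> int:
        return self.model.k

    @property
    def nobs(self) -> int:
        return self.model.n

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def alphabet(self) -> tuple[str, ...]:
        return self.model.cache.alphabet

    @property
    def theta_by_regime(self) -> dict[str, float]:
        if len(self.theta) == 1:
            return {r: float(self.theta[0]) for r in self.alphabet}
        return {r: float(t) for r, t in zip(self.alphabet, self.theta)}

    @property
    def alpha_by_regime(self) -> dict[str, float]:
        return {r: float(a) for r, a in zip(self.alphabet, self.alphas)}

    @property
    def sigma2_by_regime(self) -> dict[str, float]:
        return {r: float(s) for r, s in zip(self.alphabet, self.sigmas)}

    def params_dict(self) -> dict:
        return {
            "theta": self.theta if len(self.theta) > 1 else float(self.theta[0]),
            "alpha": self.alphas,
            "sigma2": self.sigmas,
        }

    # ---------------------------------------------------------- uncertainty
    def theta_bse(self) -> np.ndarray:
        """Standard errors of the optima from the GLS covariance
        ``(W' V^-1 W)^-1`` at the fitted shape parameters."""
        m = self.model
        V = m.cache.covariance(self.alphas, self.sigmas, m.root_mode)
        W = m._design_for(self.alphas)
        L = linalg.cholesky(V, lower=True)
        Wt = linalg.solve_triangular(L, W, lower=True)
        cov = np.linalg.pinv(Wt.T @ Wt)
        return np.sqrt(np.diag(cov))

    def bse(self) -> dict[str, float]:
        """Standard errors of all parameters from the numerically observed
        information matrix (central differences of the full log-likelihood)."""
        names, x0 = self._natural_params()
        h = np.maximum(np.abs(x0), 1e-3) * 1e-4
        p = len(x0)
        Hm = np.zeros((p, p))

        def f(x):
            return self._loglik_at(x)

        f0 = f(x0)
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = h[i]
                ej = np.zeros(p); ej[j] = h[j]
                if i == j:
                    val = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
                else:
                    val = (
                        f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                    ) / (4 * h[i] * h[j])
                Hm[i, j] = Hm[j, i] = val
        cov = np.linalg.pinv(-Hm)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        return dict(zip(names, se))

    def _natural_params(self):
        names, vals = [], []
        for r, t in self.theta_by_regime.items():
            names.append(f"theta[{r}]")
            vals.append(t)
            if len(self.theta) == 1:
                names[-1] = "theta"
                break
        spec = self.model.spec
        if spec.is_ou:
            if spec.multi_alpha:
                for r, a in self.alpha_by_regime.items():
                    names.append(f"alpha[{r}]"); vals.append(a)
            else:
                names.append("alpha"); vals.append(float(self.alphas[0]))
        if spec.multi_sigma:
            for r, s in self.sigma2_by_regime.items():
                names.append(f"sigma2[{r}]"); vals.append(s)
        else:
            names.append("sigma2"); vals.append(float(self.sigmas[0]))
        return names, np.array(vals, dtype=float)

    def _loglik_at(self, x: np.ndarray) -> float:
        m = self.model
        spec = m.spec
        R = m.cache.R
        i = 0
        ntheta = 1 if len(self.theta) == 1 else R
        theta = x[i : i + ntheta]; i += ntheta
        if spec.is_ou:
            na = R if spec.multi_alpha else 1
            alphas = x[i : i + na]; i += na
            alphas = alphas if spec.multi_alpha else np.full(R, alphas[0])
        else:
            alphas = np.zeros(R)
        ns = R if spec.multi_sigma else 1
        sig = x[i : i + ns]
        sigmas = sig if spec.multi_sigma else np.full(R, sig[0])
        if np.any(sigmas <= 0) or (spec.is_ou and np.any(alphas <= 0)):
            return -np.inf
        V = m.cache.covariance(alphas, sigmas, m.root_mode)
        if ntheta == 1:
            mean = np.full(m.n, theta[0])
        else:
            mean = m.cache.design(alphas) @ theta
        try:
            return _mvn_logpdf(m.y - mean, V)
        except ValidationError:
            return -np.inf

    # -------------------------------------------------------------- sampling
    def simulate(self, seed, size: int = 1) -> np.ndarray:
        """Parametric draws of tip vectors under the fitted parameters
        (shape ``(size, n_tips)``, tips in ``tree.tip_labels`` order)."""
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        m = self.model
        theta = self.theta if len(self.theta) > 1 else np.atleast_1d(self.theta[0])
        out = np.empty((size, m.n))
        for i in range(size):
            out[i] = _simulate_cached(
                m.cache, self.alphas, self.sigmas, theta, rng, m.root_mode
            )
        return out

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        lines = [
            f"{self.model.model_name} fit  (n = {self.nobs} tips, k = {self.k}, "
            f"root mode = {self.model.root_mode})",
            f"  logL = {self.llf:.4f}   AIC = {self.aic:.4f}   AICc = {self.aicc:.4f}",
        ]
        tse = self.theta_bse()
        if len(self.theta) == 1:
            lines.append(f"  theta            = {self.theta[0]:.6g}  (SE {tse[0]:.3g})")
        else:
            for i, r in enumerate(self.alphabet):
                lines.append(f"  theta[{r}] = {self.theta[i]:.6g}  (SE {tse[i]:.3g})")
        for r, a in self.alpha_by_regime.items():
            lines.append(f"  alpha[{r}] = {a:.6g}")
        for r, s in self.sigma2_by_regime.items():
            lines.append(f"  sigma2[{r}] = {s:.6g}")
        lines.append(
            f"  restarts polished = {self.n_restarts}; best objective = "
            f"{-self.llf:.6f}"
            + ("; WARNING: alpha at upper bound" if self.alpha_at_upper_bound else "")
        )
        return "\n".join(lines)
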