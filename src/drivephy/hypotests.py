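"""Regime-difference inference: parametric bootstrap of OU optima,
Mann-Whitney comparisons, and PGLS regression on the meiosis regime.

Two ways of judging a difference between regime optima are provided.

* :func:`parametric_bootstrap` + :func:`mann_whitney` reproduces the
  descriptive workflow of comparing the two bootstrap theta distributions
  with a rank test.  This quantifies the separation of the two estimate
  distributions, but it is not a calibrated hypothesis test: under a true
  common optimum the two bootstrap distributions still separate by the
  sampling error of the original fit, so the rank-test P is anti-conservative.
* :func:`theta_difference_test` (default method ``"null-boot"``) is the
  calibrated counterpart: it refits the model with a single shared optimum,
  simulates under that null fit, refits both models to each replicate, and
  compares the observed likelihood-ratio statistic against its simulated
  null distribution.

PGLS regresses a clade-level response (square-root transformed by default)
on the regime indicator (symmetric = 0, asymmetric = 1) with Brownian
residual correlation from the clade tree (Pagel's lambda fixed at 1 by
default, optionally ML-estimated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm

from .exceptions import FitError, ValidationError
from .ou import FitConfig, OUModel, OUResults, _simulate_cached

logger = logging.getLogger(__name__)

__all__ = [
    "mann_whitney",
    "MannWhitneyResult",
    "parametric_bootstrap",
    "BootstrapDistribution",
    "theta_difference_test",
    "ThetaTestResult",
    "PGLS",
    "PGLSResults",
]


# ------------------------------------------------------------- Mann-Whitney
@dataclass
class MannWhitneyResult:
    U: float
    p_value: float
    n1: int
    n2: int
    tie_correction: bool
    method: str

    def __iter__(self):  # allow tuple-unpacking (U, p)
        yield self.U
        yield self.p_value


def mann_whitney(sample_a, sample_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when ``n1*n2 <= 100`` and there are no cross-sample
    ties; otherwise the normal approximation with continuity and tie
    corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney requires non-empty samples")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    exact = (a.size * b.size <= 100) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return MannWhitneyResult(
        U=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        tie_correction=bool(has_ties and not exact),
        method="exact" if exact else "asymptotic",
    )


# ---------------------------------------------------------------- bootstrap
@dataclass
class BootstrapDistribution:
    """Per-replicate optimum estimates from a parametric bootstrap."""

    model_name: str
    thetas: pd.DataFrame  # one column per regime, n_reps rows
    alphas: pd.DataFrame
    sigmas: pd.DataFrame
    seed: int
    n_reps: int
    n_redraws: int = 0

    def theta_samples(self, regime: str) -> np.ndarray:
        return self.thetas[regime].to_numpy()

    def compare_regimes(self, regime_a: str, regime_b: str) -> MannWhitneyResult:
        """Rank-test comparison of the two bootstrap theta distributions
        (the descriptive separation measure; see module docstring)."""
        return mann_whitney(self.theta_samples(regime_a), self.theta_samples(regime_b))

    def plot_density(self, ax=None, regime_colors=None):
        """Kernel-density plot of the bootstrap optima per regime."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for r in self.thetas.columns:
            x = self.theta_samples(r)
            kde = stats.gaussian_kde(x) if np.ptp(x) > 0 else None
            grid = np.linspace(x.min() - 3 * x.std() - 1e-9, x.max() + 3 * x.std() + 1e-9, 200)
            color = (regime_colors or {}).get(r)
            if kde is not None:
                ax.fill_between(grid, kde(grid), alpha=0.4, label=r, color=color)
            ax.axvline(x.mean(), linestyle="--", color=color)
        ax.set_xlabel("bootstrap optimum (theta)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def _refit_config(fitted: OUResults) -> FitConfig:
    # warm start at the generating MLEs plus a light grid
    return FitConfig(n_alpha_grid=3, n_rho_grid=3, n_polish=2,
                     extra_starts=(tuple(fitted.packed),))


def parametric_bootstrap(
    fitted: OUResults,
    n_reps: int = 100,
    seed: int = 0,
    config: FitConfig | None = None,
) -> BootstrapDistribution:
    """Simulate-and-refit bootstrap under a fitted model's MLEs.

    Each replicate simulates tip values on the same tree and painting and
    refits the same model; failed refits are logged and re-drawn (an error is
    raised if more than 20 % of replicates fail).
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    model = fitted.model
    config = config or _refit_config(fitted)
    rng = np.random.default_rng(seed)
    theta_rows, alpha_rows, sigma_rows = [], [], []
    n_redraws = 0
    max_redraws = max(1, int(0.2 * n_reps) + 1)
    theta = fitted.theta if len(fitted.theta) > 1 else np.atleast_1d(fitted.theta[0])
    while len(theta_rows) < n_reps:
        y = _simulate_cached(
            model.cache, fitted.alphas, fitted.sigmas, theta, rng, model.root_mode
        )
        try:
            refit = OUModel(
                model.tree,
                y,
                regimes=model.regimes,
                model=model.model_name,
                root_mode=model.root_mode,
                common_theta=model.common_theta,
                check_tree=False,
                cache=model.cache,
            ).fit(config)
        except (FitError, ValidationError) as exc:
            n_redraws += 1
            logger.warning("bootstrap refit failed (redraw %d): %s", n_redraws, exc)
            if n_redraws > max_redraws:
                raise FitError(
                    f"parametric bootstrap: {n_redraws} refits failed "
                    f"(> 20% of {n_reps} replicates)"
                ) from None
            continue
        theta_rows.append(refit.theta_by_regime)
        alpha_rows.append(refit.alpha_by_regime)
        sigma_rows.append(refit.sigma2_by_regime)
    return BootstrapDistribution(
        model_name=model.model_name,
        thetas=pd.DataFrame(theta_rows),
        alphas=pd.DataFrame(alpha_rows),
        sigmas=pd.DataFrame(sigma_rows),
        seed=seed,
        n_reps=n_reps,
        n_redraws=n_redraws,
    )


# ------------------------------------------------------- theta difference
@dataclass
class ThetaTestResult:
    statistic: float  # observed theta difference (regime_a - regime_b)
    p_value: float
    method: str
    n_reps: int
    regime_a: str
    regime_b: str
    n_redraws: int = 0
    detail: dict = field(default_factory=dict)


def theta_difference_test(
    fitted: OUResults,
    n_reps: int = 100,
    seed: int = 0,
    method: str = "null-boot",
    regimes: tuple[str, str] | None = None,
) -> ThetaTestResult:
    """Test H0: the two regimes share one optimum.

    ``method="null-boot"`` (default, calibrated): refit with a common theta,
    simulate under that null fit, refit both the constrained and the
    regime-specific model to every replicate, and compare the observed
    likelihood-ratio statistic ``LR = 2 (logL_alt - logL_null)`` against its
    simulated null distribution; the Monte-Carlo P is
    ``(1 + #{LR* >= LR}) / (n_reps + 1)``.  (The likelihood ratio, unlike the
    raw optimum difference, is insensitive to the variance inflation the
    null fit suffers when the regimes truly differ.)

    ``method="mw"``: bootstrap under the *fitted* (alternative) model and
    compare the two theta distributions with the Mann-Whitney test -- the
    descriptive workflow; its P measures distribution separation and is not
    a calibrated test level.
    """
    model = fitted.model
    alphabet = model.cache.alphabet
    if regimes is None:
        if len(alphabet) != 2:
            raise ValidationError("specify the two regimes to compare")
        regimes = (alphabet[0], alphabet[1])
    ra, rb = regimes
    observed = fitted.theta_by_regime[ra] - fitted.theta_by_regime[rb]

    if method == "mw":
        boot = parametric_bootstrap(fitted, n_reps=n_reps, seed=seed)
        mw = boot.compare_regimes(ra, rb)
        return ThetaTestResult(
            statistic=float(observed),
            p_value=mw.p_value,
            method="mw",
            n_reps=n_reps,
            regime_a=ra,
            regime_b=rb,
            n_redraws=boot.n_redraws,
            detail={"U": mw.U},
        )
    if method != "null-boot":
        raise ValidationError("method must be 'null-boot' or 'mw'")

    null_fit = OUModel(
        model.tree,
        model.y,
        regimes=model.regimes,
        model=model.model_name,
        root_mode=model.root_mode,
        common_theta=True,
        check_tree=False,
        cache=model.cache,
    ).fit()
    lr_obs = 2.0 * (fitted.llf - null_fit.llf)
    rng = np.random.default_rng(seed)
    config = _refit_config(fitted)
    null_config = _refit_config(null_fit)
    null_stats = []
    n_redraws = 0
    max_redraws = max(1, int(0.2 * n_reps) + 1)
    theta0 = np.atleast_1d(null_fit.theta[0])
    while len(null_stats) < n_reps:
        y = _simulate_cached(
            model.cache, null_fit.alphas, null_fit.sigmas, theta0, rng, model.root_mode
        )
        try:
            refit_alt = OUModel(
                model.tree, y, regimes=model.regimes, model=model.model_name,
                root_mode=model.root_mode, check_tree=False, cache=model.cache,
            ).fit(config)
            refit_null = OUModel(
                model.tree, y, regimes=model.regimes, model=model.model_name,
                root_mode=model.root_mode, common_theta=True, check_tree=False,
                cache=model.cache,
            ).fit(null_config)
        except (FitError, ValidationError):
            n_redraws += 1
            if n_redraws > max_redraws:
                raise FitError("null bootstrap: too many failed refits") from None
            continue
        null_stats.append(2.0 * (refit_alt.llf - refit_null.llf))
    null_stats = np.asarray(null_stats)
    p = (1.0 + np.sum(null_stats >= lr_obs)) / (n_reps + 1.0)
    return ThetaTestResult(
        statistic=float(observed),
        p_value=float(p),
        method="null-boot",
        n_reps=n_reps,
        regime_a=ra,
        regime_b=rb,
        n_redraws=n_redraws,
        detail={"null_theta": float(null_fit.theta[0]), "lr": float(lr_obs)},
    )


# --------------------------------------------------------------------- PGLS
class PGLS:
    """Phylogenetic generalized least squares of a clade-level response on
    the meiosis-regime indicator.

    Parameters
    ----------
    tree : Phylogeny
        Clade-level tree whose tips are the analysis units.
    response : dict or array
        Response value per tip (non-negative if ``sqrt_transform``).
    predictor : dict or array
        Regime per tip: strings ("asymmetric"/"symmetric") or 0/1 codes
        (symmetric = 0, asymmetric = 1).
    sqrt_transform : bool
        Square-root the response (variance stabilization); default True.
    lam : float or "ml"
        Pagel's lambda scaling of off-diagonal covariances; 1 = Brownian,
        0 = ordinary least squares, "ml" = profile-ML estimate in [0, 1].
    """

    def __init__(
        self,
        tree: Phylogeny,
        response,
        predictor,
        sqrt_transform: bool = True,
        lam: float | str = 1.0,
    ):
        self.tree = tree
        y = self._tip_map(response)
        x = self._tip_map(predictor, coerce=False)
        x = np.array([self._code(v) for v in x], dtype=float)
        if sqrt_transform:
            if np.any(y < 0):
                raise ValidationError("negative response with sqrt transform enabled")
            y = np.sqrt(y)
        self.y = y
        self.x = x
        self.sqrt_transform = sqrt_transform
        self.lam = lam
        d = tree.depths()
        M = tree.mrca_matrix()
        self.C = d[M]  # Brownian covariance: shared root-to-MRCA path length
        np.fill_diagonal(self.C, [d[i] for i in tree.tip_ids])
        self.X = np.column_stack([np.ones_like(x), x])
        if np.linalg.matrix_rank(self.X) < 2:
            raise ValidationError("singular design: predictor has a single level")

    def _tip_map(self, values, coerce: bool = True):
        if isinstance(values, dict):
            missing = [l for l in self.tree.tip_labels if l not in values]
            if missing:
                raise ValidationError(f"tips without values: {missing}")
            out = [values[l] for l in self.tree.tip_labels]
        else:
            out = list(values)
            if len(out) != self.tree.n_tips:
                raise ValidationError("value vector length does not match tip count")
        return np.asarray(out, dtype=float) if coerce else out

    @staticmethod
    def _code(v) -> float:
        if isinstance(v, str):
            if v not in ("asymmetric", "symmetric"):
                raise ValidationError(f"unknown regime {v!r}")
            return 1.0 if v == "asymmetric" else 0.0
        return float(v)

    def _sigma(self, lam: float) -> np.ndarray:
        C = lam * self.C
        np.fill_diagonal(C, np.diag(self.C))
        return C

    def fit(self) -> "PGLSResults":
        if self.lam == "ml":
            lam_hat = self._fit_lambda()
        else:
            lam_hat = float(self.lam)
            if not 0 <= lam_hat <= 1:
                raise ValidationError("lambda must lie in [0, 1]")
        C = self._sigma(lam_hat)
        if lam_hat == 0:
            res = sm.OLS(self.y, self.X).fit()
        else:
            res = sm.GLS(self.y, self.X, sigma=C).fit()
        return PGLSResults(self, res, lam_hat)

    def _fit_lambda(self) -> float:
        def nll(lam: float) -> float:
            C = self._sigma(lam)
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                return 1e12
            Xt = np.linalg.solve(L, self.X)
            yt = np.linalg.solve(L, self.y)
            beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
            r = yt - Xt @ beta
            n = len(yt)
            rss = float(r @ r)
            if rss <= 0:
                return 1e12
            return 0.5 * n * (np.log(2 * np.pi) + 1 + np.log(rss / n)) + np.log(
                np.diag(L)
            ).sum()

        res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded")
        return float(res.x)


@dataclass
class PGLSResults:
    """Slope/intercept estimates with phylogenetic GLS uncertainty."""

    model: PGLS
    _sm: object
    lam: float

    @property
    def params(self) -> np.ndarray:  # [intercept, slope]
        return np.asarray(self._sm.params)

    @property
    def slope(self) -> float:
        return float(self.params[1])

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._sm.bse)

    @property
    def tvalues(self) -> np.ndarray:
        return np.asarray(self._sm.tvalues)

    @property
    def pvalues(self) -> np.ndarray:
        return np.asarray(self._sm.pvalues)

    @property
    def df_resid(self) -> int:
        return int(self._sm.df_resid)

    def summary(self) -> str:
        rows = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "P>|t|": self.pvalues,
            },
            index=["intercept", "regime[asymmetric]"],
        )
        head = (
            f"PGLS (lambda = {self.lam:.3f}, response "
            f"{'sqrt-transformed' if self.model.sqrt_transform else 'raw'}, "
            f"df = {self.df_resid})"
        )
        return head + "\n" + rows.to_string(float_format=lambda v: f"{v:.4g}")
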