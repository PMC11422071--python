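"""Multiple imputation of missing quantitative phenotypes by chained equations.

Each incomplete trait is regressed on all other quantitative traits and the
missing cells are replaced by posterior-predictive draws: the residual
variance is drawn from its scaled inverse-chi-square posterior, the
coefficients from their conditional normal posterior, and the imputed values
from the resulting predictive normal.  Several independent chains are run and
convergence is assessed with the potential-scale-reduction statistic (R-hat)
of the per-trait mean and SD trajectories of the imputed values; the chains
are declared converged when every R-hat lies within 1.0 +/- 0.1.

The final completed matrix used downstream is the per-cell mean of the last
``n_draws`` retained completed matrices (taken from the chain ends,
round-robin).  Observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .collection import GermplasmCollection

__all__ = [
    "ImputationResult",
    "ChainedEquationsImputer",
    "impute",
    "rhat",
    "compare_distributions",
]

RHAT_LOW, RHAT_HIGH = 0.9, 1.1


def rhat(chains) -> float:
    """Potential scale reduction over >= 2 equal-length scalar trajectories.

    ``sqrt((W (n-1)/n + B/n) / W)`` with W the mean within-chain variance and
    B = n * variance of the chain means (sample variances throughout).
    Returns ``inf`` when W = 0 with B > 0, and 1.0 when both are 0.
    """
    arr = np.asarray(list(chains), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = arr.shape
    W = float(arr.var(axis=1, ddof=1).mean())
    B = float(n * arr.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    return float(np.sqrt((W * (n - 1) / n + B / n) / W))


@dataclass
class ImputationResult:
    """Completed draws, their pooled mean, and convergence diagnostics."""

    completed_draws: list[np.ndarray]
    pooled: np.ndarray
    rhat_mean: dict[str, float]
    rhat_sd: dict[str, float]
    n_iterations: int
    converged: bool
    seed: int | None = None

    def diagnostics(self) -> dict:
        return {
            "rhat": {
                t: {"mean": self.rhat_mean[t], "sd": self.rhat_sd[t]} for t in self.rhat_mean
            },
            "n_iterations": self.n_iterations,
            "converged": bool(self.converged),
            "seed": self.seed,
        }


class ChainedEquationsImputer(BaseEstimator, TransformerMixin):
    """Chained-equations multiple imputation with R-hat convergence checking.

    Parameters
    ----------
    n_chains : independent chains (>= 2; R-hat is undefined otherwise).
    n_iter : sweeps per chain.
    n_draws : completed matrices retained (from the chain ends) and pooled.
    random_state : seed for all draws; same seed gives bit-identical results.

    Attributes (after ``fit``)
    --------------------------
    pooled_ : completed matrix, per-cell mean of the retained draws.
    draws_ : the retained completed matrices.
    rhat_mean_, rhat_sd_ : per-column R-hat of the imputed-value mean / SD
        trajectories across chains (1.0 by convention for complete columns).
    converged_ : True iff every R-hat lies in [0.9, 1.1].
    """

    def __init__(self, n_chains: int = 4, n_iter: int = 40, n_draws: int = 5, random_state: int | None = None):
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_draws = n_draws
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (R-hat undefined for one chain)")
        n, p = X.shape
        miss = np.isnan(X)
        for j in range(p):
            if miss[:, j].all():
                raise ValueError(f"column {j} has no observed values: nothing to condition on")
        rng = np.random.default_rng(self.random_state)
        col_means = np.nanmean(X, axis=0)
        incomplete = [j for j in range(p) if miss[:, j].any()]

        # trajectories[c][j] = (means over iters, sds over iters) of imputed cells
        traj_mean = np.zeros((self.n_chains, self.n_iter, p))
        traj_sd = np.zeros((self.n_chains, self.n_iter, p))
        chain_states: list[list[np.ndarray]] = []
        for _c in range(self.n_chains):
            Xc = X.copy()
            for j in incomplete:
                obs = Xc[~miss[:, j], j]
                # start from seeded draws of observed values
                Xc[miss[:, j], j] = rng.choice(obs, size=int(miss[:, j].sum()), replace=True)
            states = []
            for t in range(self.n_iter):
                for j in incomplete:
                    self._sweep(Xc, miss, j, rng, col_means)
                for j in range(p):
                    cells = Xc[miss[:, j], j]
                    traj_mean[_c, t, j] = cells.mean() if cells.size else col_means[j]
                    traj_sd[_c, t, j] = cells.std(ddof=1) if cells.size > 1 else 0.0
                states.append(Xc.copy())
            chain_states.append(states)

        draws: list[np.ndarray] = []
        t = self.n_iter - 1
        while len(draws) < self.n_draws and t >= 0:
            for c in range(self.n_chains):
                if len(draws) < self.n_draws:
                    draws.append(chain_states[c][t])
            t -= 1
        pooled = np.mean(draws, axis=0)
        pooled[~miss] = X[~miss]

        self.rhat_mean_ = np.ones(p)
        self.rhat_sd_ = np.ones(p)
        for j in incomplete:
            self.rhat_mean_[j] = rhat(traj_mean[:, :, j])
            self.rhat_sd_[j] = rhat(traj_sd[:, :, j])
        rhats = np.concatenate([self.rhat_mean_, self.rhat_sd_])
        self.converged_ = bool(np.all((rhats >= RHAT_LOW) & (rhats <= RHAT_HIGH)))
        self.draws_ = draws
        self.pooled_ = pooled
        self.missing_mask_ = miss
        self.n_features_in_ = p
        return self

    @staticmethod
    def _sweep(Xc, miss, j, rng, col_means):
        """One posterior-predictive draw for column j given the others."""
        n, p = Xc.shape
        others = [k for k in range(p) if k != j]
        obs = ~miss[:, j]
        y = Xc[obs, j]
        if others:
            D = np.column_stack([np.ones(n), Xc[:, others]])
        else:
            D = np.ones((n, 1))
        Do, Dm = D[obs], D[~obs]
        q = D.shape[1]
        if y.size <= q:
            # too few observations for the regression: draw around the mean
            mu, sd = y.mean(), (y.std(ddof=1) if y.size > 1 else 0.0)
            Xc[~obs, j] = mu + sd * rng.standard_normal(Dm.shape[0])
            return
        beta_hat, *_ = np.linalg.lstsq(Do, y, rcond=None)
        resid = y - Do @ beta_hat
        dof = y.size - q
        rss = float(resid @ resid)
        sigma2 = rss / rng.chisquare(dof) if rss > 0 else 0.0
        XtX = Do.T @ Do
        cov = sigma2 * np.linalg.pinv(XtX)
        beta = rng.multivariate_normal(beta_hat, cov, method="svd")
        Xc[~obs, j] = Dm @ beta + np.sqrt(sigma2) * rng.standard_normal(Dm.shape[0])

    def transform(self, X):
        """Return a completed copy of ``X``.

        For the matrix seen in ``fit`` (same observed cells) this is the
        pooled matrix; any other matrix is completed by a fresh fit with the
        same settings.
        """
        X = np.asarray(X, dtype=float)
        if (
            hasattr(self, "pooled_")
            and X.shape == self.pooled_.shape
            and np.array_equal(np.isnan(X), self.missing_mask_)
            and np.allclose(X[~self.missing_mask_], self.pooled_[~self.missing_mask_])
        ):
            return self.pooled_.copy()
        est = ChainedEquationsImputer(self.n_chains, self.n_iter, self.n_draws, self.random_state)
        return est.fit(X).pooled_


def impute(
    c: GermplasmCollection,
    n_chains: int = 4,
    n_iter: int = 40,
    n_draws: int = 5,
    seed: int | None = None,
) -> ImputationResult:
    """Impute a collection's missing quantitative phenotypes.

    Returns an :class:`ImputationResult`; use ``c.with_phenotypes(res.pooled)``
    for the completed collection.  A collection with no missing cells returns
    itself with all R-hat = 1 and ``converged=True``.
    """
    X = c.phenotypes
    if not np.isnan(X).any():
        names = c.trait_names
        return ImputationResult(
            completed_draws=[X.copy()],
            pooled=X.copy(),
            rhat_mean={t: 1.0 for t in names},
            rhat_sd={t: 1.0 for t in names},
            n_iterations=0,
            converged=True,
            seed=seed,
        )
    est = ChainedEquationsImputer(n_chains=n_chains, n_iter=n_iter, n_draws=n_draws, random_state=seed)
    est.fit(X)
    names = c.trait_names
    return ImputationResult(
        completed_draws=est.draws_,
        pooled=est.pooled_,
        rhat_mean={t: float(est.rhat_mean_[j]) for j, t in enumerate(names)},
        rhat_sd={t: float(est.rhat_sd_[j]) for j, t in enumerate(names)},
        n_iterations=n_iter,
        converged=est.converged_,
        seed=seed,
    )


def compare_distributions(observed, completed) -> dict:
    """Welch two-sample test of observed-only vs completed values.

    Used to check that imputation did not shift a trait's distribution.
    Returns the t statistic, two-sided p-value and Cohen's d.  Two samples
    with zero variance and equal means give p = 1 by convention.
    """
    a = np.asarray(observed, dtype=float)
    b = np.asarray(completed, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    if va == 0.0 and vb == 0.0:
        equal = np.isclose(a.mean(), b.mean())
        return {"t": 0.0 if equal else float("inf"), "p": 1.0 if equal else 0.0, "cohen_d": 0.0 if equal else float("inf")}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    pooled_sd = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    d = float((a.mean() - b.mean()) / pooled_sd) if pooled_sd > 0 else 0.0
    return {"t": float(t), "p": float(p), "cohen_d": d}
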