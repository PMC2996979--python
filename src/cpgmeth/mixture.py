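"""Univariate normal mixture modelling of CpGo/e values.

A transcriptome whose genes split into hyper- and hypo-methylated
fractions shows a bimodal CpGo/e distribution. We model the values
C_i as

    C_i ~ p1·N(mu1, sigma1²) + p2·N(mu2, sigma2²),   p1 + p2 = 1,

fit by expectation–maximisation, and compare the two-component model
against the single-normal null by log-likelihood. Because the usual
chi-square approximation for a likelihood-ratio test is invalid when
testing the number of mixture components (the null lies on the
parameter-space boundary and mixing weights are unidentified under it),
:func:`compare_models` reports the raw statistic together with a
parametric-bootstrap p-value and AIC/BIC.

The API follows the statsmodels convention: build a
:class:`NormalMixture` model from data, call :meth:`~NormalMixture.fit`,
and read estimates off the returned :class:`NormalMixtureResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numba
import numpy as np
from scipy import stats

from .dinucleotide import DinucleotideProfile, InsufficientDataError

logger = logging.getLogger(__name__)

_LABEL_HYPER = "predicted_hyper"
_LABEL_HYPO = "predicted_hypo"
_LABEL_MISSING = "missing"


class DegenerateDataError(ValueError):
    """All observations identical; a mixture fit is meaningless."""


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x, mu, sd):
    # inlined normal log-density; scipy's argument checking is too slow
    # inside the EM loop and the parametric bootstrap
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI


@numba.njit(cache=False, fastmath=True)
def _em2_kernel(x, w1, mu1, mu2, sd1, sd2, var_floor, tol,
                max_iter):  # pragma: no cover - exercised via _em
    """Two-component EM inner loop (compiled).

    Returns (w, mu, sd, ll_path, resp, converged, n_iter). Densities are
    evaluated directly (data scale ~1, sds floored, no underflow risk);
    a 1e-300 guard keeps the log finite for extreme outliers.
    """
    n = x.size
    w2 = 1.0 - w1
    resp = np.empty((n, 2))
    ll_path = np.empty(max_iter)
    converged = False
    n_iter = 0
    c = 1.0 / np.sqrt(2.0 * np.pi)
    for it in range(max_iter):
        ll = 0.0
        s1 = 0.0
        sx1 = 0.0
        sx2 = 0.0
        for i in range(n):
            z1 = (x[i] - mu1) / sd1
            z2 = (x[i] - mu2) / sd2
            p1 = w1 * c / sd1 * np.exp(-0.5 * z1 * z1)
            p2 = w2 * c / sd2 * np.exp(-0.5 * z2 * z2)
            tot = p1 + p2
            if tot < 1e-300:
                tot = 1e-300
                p1 = 0.5e-300
            ll += np.log(tot)
            r1 = p1 / tot
            resp[i, 0] = r1
            resp[i, 1] = 1.0 - r1
            s1 += r1
            sx1 += r1 * x[i]
            sx2 += (1.0 - r1) * x[i]
        ll_path[it] = ll
        n_iter = it + 1
        if it > 0:
            prev = ll_path[it - 1]
            if abs(ll - prev) <= tol * (abs(prev) + tol):
                converged = True
                break
        # M step
        s2 = n - s1
        if s1 < 1e-300:
            s1 = 1e-300
        if s2 < 1e-300:
            s2 = 1e-300
        w1 = s1 / n
        w2 = 1.0 - w1
        mu1 = sx1 / s1
        mu2 = sx2 / s2
        v1 = 0.0
        v2 = 0.0
        for i in range(n):
            d1 = x[i] - mu1
            d2 = x[i] - mu2
            v1 += resp[i, 0] * d1 * d1
            v2 += resp[i, 1] * d2 * d2
        sd1 = np.sqrt(max(v1 / s1, var_floor * var_floor))
        sd2 = np.sqrt(max(v2 / s2, var_floor * var_floor))
    w = np.array([w1, w2])
    mu = np.array([mu1, mu2])
    sd = np.array([sd1, sd2])
    return w, mu, sd, ll_path[:n_iter], resp, converged, n_iter


class NormalMixture:
    """k-component univariate normal mixture model (k = 1 or 2).

    Parameters
    ----------
    endog : array-like
        Observed values (finite; typically defined CpGo/e ratios).
    k : int
        Number of components, 1 or 2.

    Notes
    -----
    ``fit`` runs EM to convergence (relative log-likelihood change below
    ``tol`` or ``max_iter`` sweeps) from the best of ``restarts`` seeded
    initialisations: component means from a quantile split of the data,
    a pooled standard deviation, and uniform weights, with quantiles
    jittered across restarts. Standard deviations are floored at
    ``1e-6 ×`` the data range to exclude degenerate spike components.
    """

    def __init__(self, endog, k: int = 2):
        endog = np.asarray(endog, dtype=float)
        if endog.ndim != 1:
            raise ValueError("endog must be one-dimensional")
        if not np.all(np.isfinite(endog)):
            raise ValueError("endog must be finite; drop undefined ratios first")
        if k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        if endog.size < 10 * k:
            raise InsufficientDataError(
                f"need at least {10 * k} observations for k={k}, got {endog.size}"
            )
        if np.ptp(endog) == 0.0:
            raise DegenerateDataError("all observations are identical")
        self.endog = endog
        self.k = k
        self.nobs = endog.size

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0, restarts: int = 20, tol: float = 1e-8,
            max_iter: int = 1000) -> "NormalMixtureResults":
        x = self.endog
        var_floor = 1e-6 * float(np.ptp(x))
        if self.k == 1:
            mu = float(np.mean(x))
            sigma = max(float(np.std(x)), var_floor)  # MLE (population) sd
            llf = float(np.sum(_norm_logpdf(x, mu, sigma)))
            resp = np.ones((x.size, 1))
            return NormalMixtureResults(
                self, weights=np.array([1.0]), means=np.array([mu]),
                sds=np.array([sigma]), llf=llf, converged=True, n_iter=0,
                responsibilities=resp, llf_path=np.array([llf]),
            )

        rng = np.random.default_rng(seed)
        best: tuple | None = None
        for r in range(restarts):
            if r == 0:
                q = (0.25, 0.75)
            else:
                lo = rng.uniform(0.02, 0.48)
                hi = rng.uniform(0.52, 0.98)
                q = (lo, hi)
            mu0 = np.quantile(x, q)
            sd0 = np.full(2, max(float(np.std(x)), var_floor))
            w0 = np.full(2, 0.5)
            out = _em(x, w0, mu0, sd0, var_floor, tol, max_iter)
            if best is None or out[3][-1] > best[3][-1]:
                best = out
        assert best is not None
        w, mu, sd, ll_path, resp, converged, n_iter = best
        # canonical increasing-mean order
        order = np.argsort(mu)
        w, mu, sd = w[order], mu[order], sd[order]
        resp = resp[:, order]
        return NormalMixtureResults(
            self, weights=w, means=mu, sds=sd, llf=float(ll_path[-1]),
            converged=converged, n_iter=n_iter, responsibilities=resp,
            llf_path=ll_path,
        )


def _em(x, w, mu, sd, var_floor, tol, max_iter):
    """One EM run; returns (w, mu, sd, llf_path, resp, converged, n_iter)."""
    return _em2_kernel(
        np.ascontiguousarray(x, dtype=np.float64),
        float(w[0]), float(mu[0]), float(mu[1]), float(sd[0]), float(sd[1]),
        float(var_floor), float(tol), int(max_iter),
    )


class NormalMixtureResults:
    """Fitted normal mixture: estimates, likelihood and responsibilities.

    Components are stored in increasing-mean order; ``responsibilities``
    holds per-observation posterior component probabilities (rows sum
    to 1).
    """

    def __init__(self, model: NormalMixture, weights, means, sds, llf,
                 converged, n_iter, responsibilities, llf_path):
        self.model = model
        self.k = model.k
        self.weights = np.asarray(weights)
        self.means = np.asarray(means)
        self.sds = np.asarray(sds)
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.responsibilities = np.asarray(responsibilities)
        self.llf_path = np.asarray(llf_path)

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1  # k means + k sds + (k-1) free weights

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.llf

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.model.nobs) - 2 * self.llf

    def pdf(self, grid) -> np.ndarray:
        """Mixture density on a grid (for density plots alongside data)."""
        grid = np.asarray(grid, dtype=float)
        return sum(
            self.weights[j] * stats.norm.pdf(grid, self.means[j], self.sds[j])
            for j in range(self.k)
        )

    def component_pdfs(self, grid) -> np.ndarray:
        """Scaled component densities w_j·N(mu_j, sd_j), one row per component."""
        grid = np.asarray(grid, dtype=float)
        return np.vstack([
            self.weights[j] * stats.norm.pdf(grid, self.means[j], self.sds[j])
            for j in range(self.k)
        ])

    def posterior(self, values) -> np.ndarray:
        """Posterior component probabilities for new values (n × k)."""
        values = np.asarray(values, dtype=float)
        logpdf = np.column_stack([
            np.log(self.weights[j]) + _norm_logpdf(values, self.means[j], self.sds[j])
            for j in range(self.k)
        ])
        m = logpdf.max(axis=1, keepdims=True)
        log_total = m + np.log(np.exp(logpdf - m).sum(axis=1, keepdims=True))
        return np.exp(logpdf - log_total)

    def summary(self) -> str:
        lines = [
            f"Normal mixture (k={self.k}), n={self.model.nobs}",
            f"  log-likelihood {self.llf:.4f}  AIC {self.aic:.2f}  "
            f"BIC {self.bic:.2f}",
            f"  converged={self.converged} after {self.n_iter} iterations",
            "  comp   weight      mean        sd",
        ]
        for j in range(self.k):
            lines.append(
                f"  {j + 1:>4}  {self.weights[j]:>7.4f}  {self.means[j]:>8.4f}"
                f"  {self.sds[j]:>8.4f}"
            )
        return "\n".join(lines)


def fit_mixture(values, k: int, seed: int = 0, restarts: int = 20,
                tol: float = 1e-8, max_iter: int = 1000) -> NormalMixtureResults:
    """Convenience wrapper: ``NormalMixture(values, k).fit(...)``."""
    return NormalMixture(values, k).fit(seed=seed, restarts=restarts, tol=tol,
                                        max_iter=max_iter)


@dataclass
class ModelComparison:
    """k=2 vs k=1 comparison: raw LRT statistic, bootstrap p, AIC/BIC."""

    log_lik_1: float
    log_lik_2: float
    lrt_stat: float
    bootstrap_p: float | None
    n_boot: int
    aic_1: float
    aic_2: float
    bic_1: float
    bic_2: float
    fit1: NormalMixtureResults
    fit2: NormalMixtureResults

    def summary(self) -> str:
        lines = [
            "Model comparison: two-component mixture vs single normal",
            f"  logL(k=1) = {self.log_lik_1:.4f}   logL(k=2) = {self.log_lik_2:.4f}",
            f"  LRT statistic 2*(logL2 - logL1) = {self.lrt_stat:.4f}",
            f"  AIC: {self.aic_1:.2f} -> {self.aic_2:.2f}   "
            f"BIC: {self.bic_1:.2f} -> {self.bic_2:.2f}",
        ]
        if self.bootstrap_p is not None:
            lines.append(
                f"  parametric bootstrap p = {self.bootstrap_p:.4f} "
                f"({self.n_boot} replicates)"
            )
        return "\n".join(lines)


def compare_models(values, n_boot: int = 99, seed: int = 0,
                   restarts: int = 20) -> ModelComparison:
    """Fit k=1 and k=2 and test the improvement in fit.

    If ``n_boot > 0``, ``n_boot`` datasets of the same size are simulated
    from the fitted single normal, each refit with both models, and the
    p-value is the plus-one-corrected fraction whose LRT statistic
    reaches the observed one: ``(b + 1) / (n_boot + 1)``.
    """
    values = np.asarray(values, dtype=float)
    fit1 = fit_mixture(values, k=1)
    fit2 = fit_mixture(values, k=2, seed=seed, restarts=restarts)
    lrt = 2.0 * (fit2.llf - fit1.llf)
    if lrt < -1e-6:
        raise AssertionError(f"nesting violated: LRT statistic {lrt} < 0")

    boot_p = None
    if n_boot > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x626F6F74]))
        b = 0
        for i in range(n_boot):
            sim = rng.normal(fit1.means[0], fit1.sds[0], size=values.size)
            s1 = fit_mixture(sim, k=1)
            s2 = fit_mixture(sim, k=2, seed=int(rng.integers(2**31)),
                             restarts=max(5, restarts // 4))
            if 2.0 * (s2.llf - s1.llf) >= lrt:
                b += 1
        boot_p = (b + 1) / (n_boot + 1)
    return ModelComparison(
        log_lik_1=fit1.llf, log_lik_2=fit2.llf, lrt_stat=lrt,
        bootstrap_p=boot_p, n_boot=n_boot,
        aic_1=fit1.aic, aic_2=fit2.aic, bic_1=fit1.bic, bic_2=fit2.bic,
        fit1=fit1, fit2=fit2,
    )


def classify(fit: NormalMixtureResults,
             profiles: list[DinucleotideProfile]) -> dict[str, str]:
    """Label each sequence hyper- or hypo-methylated from the k=2 fit.

    A sequence is ``predicted_hyper`` when the posterior responsibility
    of the lower-mean component exceeds 0.5 (ties go to hyper);
    sequences with undefined CpGo/e are labelled ``missing``.
    """
    if fit.k != 2:
        raise ValueError("classification requires a k=2 fit")
    if not fit.converged:
        raise ValueError("refusing to classify from a non-converged fit")
    labels: dict[str, str] = {}
    defined = [p for p in profiles if p.cpg_oe is not None]
    if defined:
        post = fit.posterior([p.cpg_oe for p in defined])
        for p, row in zip(defined, post):
            labels[p.sequence_id] = _LABEL_HYPER if row[0] >= 0.5 else _LABEL_HYPO
    for p in profiles:
        if p.cpg_oe is None:
            labels[p.sequence_id] = _LABEL_MISSING
    return labels
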