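"""Gaussian random-intercept mixed models via the closed-form profiled
likelihood.

For a single random intercept per group, V = sigma_e^2 (I + psi Z Z') with
psi = sigma_u^2 / sigma_e^2 is block diagonal, so GLS estimates, the
profiled error variance and log|V| are all closed-form in psi; ML and REML
reduce to a one-dimensional optimisation over psi that handles the
sigma_u = 0 boundary exactly (a boundary solution is reported as a flagged
singular fit).  ML is used for model selection, REML for the final averaged
report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .design import design_matrix

__all__ = ["LinearMixedModel", "LMMResults", "fit_lmm"]


@dataclass
class LMMResults:
    params: pd.Series
    bse: pd.Series
    llf: float
    k: int
    nobs: int
    sigma_u: float
    sigma_e: float
    method: str
    converged: bool
    singular: bool

    @property
    def aicc(self) -> float:
        k, n = self.k, self.nobs
        if n - k - 1 <= 0:
            return float("inf")
        return -2 * self.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    def wald_pvalues(self, use_t: bool = True) -> pd.Series:
        """Wald p-values; t reference with residual df = n - k_fixed by
        default, normal otherwise (both conventions are selectable)."""
        from scipy import stats

        z = self.params / self.bse
        if use_t:
            df = max(self.nobs - len(self.params), 1)
            return pd.Series(2 * stats.t.sf(np.abs(z), df), index=self.params.index)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def summary(self) -> str:
        lines = [
            f"Linear mixed model ({self.method}, n={self.nobs})",
            f"logLik={self.llf:.3f}  AICc={self.aicc:.3f}  k={self.k}",
            f"sigma_u={self.sigma_u:.4f}  sigma_e={self.sigma_e:.4f}"
            + ("  [boundary]" if self.singular else ""),
            "",
        ]
        p = self.wald_pvalues()
        for name in self.params.index:
            lines.append(
                f"{name:<22} {self.params[name]:>10.4f} {self.bse[name]:>9.4f} "
                f"{p[name]:>8.4f}"
            )
        return "\n".join(lines)


class LinearMixedModel:
    """Random-intercept LMM over a term list; ``fit`` selects ML or REML."""

    def __init__(self, data: pd.DataFrame, response: str, terms, group: str):
        self.data = data
        self.response = response
        self.terms = list(terms)
        self.group = group
        self.names = ["Intercept"] + self.terms

    def _profile(self, psi, X, y, group_slices):
        """GLS quantities for V = I + psi * ZZ' (block diagonal per group)."""
        p = X.shape[1]
        XtVX = X.T @ X
        XtVy = X.T @ y
        ytVy = float(y @ y)
        logdet = 0.0
        for sl in group_slices:
            ni = sl.stop - sl.start
            shrink = psi / (1.0 + psi * ni)
            sx = X[sl].sum(axis=0)
            sy = float(y[sl].sum())
            XtVX -= shrink * np.outer(sx, sx)
            XtVy -= shrink * sx * sy
            ytVy -= shrink * sy * sy
            logdet += math.log1p(psi * ni)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - float(XtVy @ beta)  # r' V^-1 r at the GLS solution
        return beta, XtVX, max(rss, 1e-300), logdet

    def fit(self, method: str = "ML") -> LMMResults:
        if method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        X = design_matrix(self.data, self.terms)
        y = np.asarray(self.data[self.response], dtype=float)
        groups = np.asarray(self.data[self.group])
        order = np.argsort(groups, kind="stable")
        X, y, groups = X[order], y[order], groups[order]
        n, p = X.shape
        bounds_n = n if method == "ML" else n - p
        starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
        slices = [
            slice(a, b) for a, b in zip(starts, np.r_[starts[1:], n])
        ]

        def negllf(log_psi):
            psi = math.exp(log_psi)
            _, XtVX, rss, logdet = self._profile(psi, X, y, slices)
            s2 = rss / bounds_n
            val = -0.5 * (bounds_n * (math.log(2 * math.pi * s2) + 1.0) + logdet)
            if method == "REML":
                sign, ld = np.linalg.slogdet(XtVX)
                val -= 0.5 * ld
            return -val

        # coarse grid then local refinement over log psi; include the
        # sigma_u = 0 boundary explicitly
        grid = np.linspace(-12.0, 6.0, 37)
        vals = [negllf(g) for g in grid]
        best = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            negllf, bracket=None, bounds=(best - 1.0, best + 1.0), method="bounded",
            options={"xatol": 1e-10},
        )
        log_psi = float(res.x)
        llf = -float(res.fun)
        boundary_llf = -negllf(-300.0)  # psi ~ 0
        singular = False
        if boundary_llf >= llf - 1e-10:
            log_psi, llf, singular = -300.0, boundary_llf, True
        psi = math.exp(log_psi)
        beta, XtVX, rss, _ = self._profile(psi, X, y, slices)
        s2 = rss / bounds_n
        cov = s2 * np.linalg.inv(XtVX)
        return LMMResults(
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=self.names),
            llf=llf,
            k=p + 2,  # fixed effects + sigma_u + sigma_e
            nobs=n,
            sigma_u=float(np.sqrt(psi * s2)) if not singular else 0.0,
            sigma_e=float(np.sqrt(s2)),
            method=method,
            converged=True,
            singular=singular,
        )


def fit_lmm(data, response, terms, group, method: str = "ML") -> LMMResults:
    return LinearMixedModel(data, response, terms, group).fit(method=method)
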