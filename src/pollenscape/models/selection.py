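"""Predictor screening, collinearity filtering, all-subsets AICc selection
and conditional model averaging.

The procedure mirrors common multi-model inference practice: (1) fit
single-metric models and keep metrics whose Wald p-value is <= 0.15,
separately for the conditional and zero-inflation components; probe area
metrics for a quadratic term (kept when it lowers AICc) and linear-element
metrics for an interaction with the O:P ratio of their own type; (2) mark
metric pairs with Pearson |r| > 0.7 as mutually exclusive; (3) enumerate all
admissible predictor subsets (marginality and exclusivity enforced), fit
with ML, keep models with delta-AICc <= 2, and conditionally average the
kept models' coefficients with Akaike weights and Burnham-Anderson
unconditional standard errors.  Gaussian mixed models are refitted with REML
before the averaged report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import required_mains, term_metrics
from .lmm import LinearMixedModel
from .zimixed import ZeroInflatedMixedModel

__all__ = [
    "FitRecord",
    "ZIFitter",
    "LMMFitter",
    "ScreenResult",
    "AveragedModel",
    "screen_metrics",
    "collinearity_filter",
    "all_subsets_average",
]

MAX_CANDIDATES = 12


@dataclass
class FitRecord:
    """Family-agnostic view of one fitted candidate model."""

    terms: dict[str, tuple[str, ...]]  # component -> terms
    coef: dict[tuple[str, str], tuple[float, float]]  # (component, term) -> (est, se)
    pvalues: dict[tuple[str, str], float]
    llf: float
    k: int
    nobs: int
    converged: bool

    @property
    def aicc(self) -> float:
        k, n = self.k, self.nobs
        if n - k - 1 <= 0:
            return float("inf")
        return -2 * self.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)


class ZIFitter:
    """Fits zero-inflated mixed models for given cond/zi term sets."""

    components = ("cond", "zi")
    supports_reml = False

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        group: str,
        family: str = "poisson",
        trials: str | None = None,
        nodes: int = 9,
        seed: int = 0,
        restarts: int = 1,
    ):
        self.data, self.response, self.group = data, response, group
        self.family, self.trials, self.nodes = family, trials, nodes
        self.seed, self.restarts = seed, restarts

    def fit(self, terms: dict[str, tuple[str, ...]], method: str = "ML") -> FitRecord:
        cond = tuple(terms.get("cond", ()))
        zi = tuple(terms.get("zi", ()))
        model = ZeroInflatedMixedModel.from_dataframe(
            self.data,
            self.response,
            cond,
            zi,
            self.group,
            family=self.family,
            trials=self.trials,
            nodes=self.nodes,
        )
        res = model.fit(seed=self.seed, restarts=self.restarts)
        coef: dict[tuple[str, str], tuple[float, float]] = {}
        pvals: dict[tuple[str, str], float] = {}
        se = res.bse
        p = res.wald_pvalues()
        for i, t in enumerate(cond, start=1):
            coef[("cond", t)] = (float(res.params[i]), float(se[f"cond_{t}"]))
            pvals[("cond", t)] = float(p[f"cond_{t}"])
        for j, t in enumerate(zi, start=1):
            i = model.p + j
            coef[("zi", t)] = (float(res.params[i]), float(se[f"zi_{t}"]))
            pvals[("zi", t)] = float(p[f"zi_{t}"])
        return FitRecord(
            {"cond": cond, "zi": zi}, coef, pvals, res.llf, res.k, res.nobs, res.converged
        )


class LMMFitter:
    """Fits Gaussian random-intercept models for given term sets."""

    components = ("cond",)
    supports_reml = True

    def __init__(self, data: pd.DataFrame, response: str, group: str, use_t: bool = True):
        self.data, self.response, self.group = data, response, group
        self.use_t = use_t

    def fit(self, terms: dict[str, tuple[str, ...]], method: str = "ML") -> FitRecord:
        cond = tuple(terms.get("cond", ()))
        res = LinearMixedModel(self.data, self.response, cond, self.group).fit(method)
        p = res.wald_pvalues(use_t=self.use_t)
        coef = {
            ("cond", t): (float(res.params[t]), float(res.bse[t])) for t in cond
        }
        pvals = {("cond", t): float(p[t]) for t in cond}
        return FitRecord({"cond": cond}, coef, pvals, res.llf, res.k, res.nobs, res.converged)


# ---------------------------------------------------------------------------
# Step 1: single-metric screening

@dataclass
class ScreenResult:
    candidates: dict[str, list[str]]  # component -> candidate terms
    skipped: list[str] = field(default_factory=list)

    def all_terms(self) -> list[tuple[str, str]]:
        return [(c, t) for c, ts in self.candidates.items() for t in ts]


def screen_metrics(
    fitter,
    metrics,
    alpha: float = 0.15,
    area_metrics=(),
    op_partner: dict[str, str] | None = None,
) -> ScreenResult:
    """Single-metric screening at p <= alpha, per component.

    ``area_metrics`` are additionally probed with a quadratic term, kept when
    it yields a lower AICc; metrics in ``op_partner`` (linear-element length
    -> its own-type O:P ratio column) are probed for an interaction, kept
    when the interaction's p <= alpha.
    """
    op_partner = op_partner or {}
    out = ScreenResult({c: [] for c in fitter.components})
    for metric in metrics:
        for comp in fitter.components:
            try:
                base = fitter.fit({comp: (metric,)})
            except Exception:
                out.skipped.append(f"{comp}:{metric}")
                continue
            if not base.converged:
                out.skipped.append(f"{comp}:{metric}")
                continue
            selected = base.pvalues[(comp, metric)] <= alpha
            if metric in area_metrics:
                # curvilinear/unimodal probe: a quadratic model with lower
                # AICc and a significant quadratic term qualifies the metric
                # even when the linear trend alone does not
                quad = f"I({metric}^2)"
                try:
                    qfit = fitter.fit({comp: (metric, quad)})
                    if (
                        qfit.converged
                        and qfit.aicc < base.aicc
                        and qfit.pvalues[(comp, quad)] <= alpha
                    ):
                        if not selected:
                            selected = True
                        out.candidates[comp].append(metric)
                        out.candidates[comp].append(quad)
                except Exception:
                    out.skipped.append(f"{comp}:{quad}")
            if selected and metric not in out.candidates[comp]:
                out.candidates[comp].append(metric)
            if not selected:
                continue
            if metric in op_partner:
                op = op_partner[metric]
                inter = f"{metric}:{op}"
                try:
                    ifit = fitter.fit({comp: (metric, op, inter)})
                    if ifit.converged and ifit.pvalues[(comp, inter)] <= alpha:
                        if op not in out.candidates[comp]:
                            out.candidates[comp].append(op)
                        out.candidates[comp].append(inter)
                except Exception:
                    out.skipped.append(f"{comp}:{inter}")
    return out


# ---------------------------------------------------------------------------
# Step 2: collinearity

def collinearity_filter(
    data: pd.DataFrame, metrics, r_max: float = 0.7
) -> set[frozenset[str]]:
    """Pairs of metrics with Pearson |r| > r_max (mutually exclusive in any
    one model)."""
    metrics = list(metrics)
    out: set[frozenset[str]] = set()
    for a, b in itertools.combinations(metrics, 2):
        r = np.corrcoef(
            np.asarray(data[a], dtype=float), np.asarray(data[b], dtype=float)
        )[0, 1]
        if np.abs(r) > r_max:
            out.add(frozenset((a, b)))
    return out


# ---------------------------------------------------------------------------
# Step 3: all-subsets selection + conditional averaging

@dataclass
class AveragedModel:
    table: pd.DataFrame  # component, term, estimate, se, ci_lower, ci_upper, n_models
    selection: pd.DataFrame  # model_id, terms, llf, k, aicc, delta, weight
    n_fitted: int


def _admissible(subset, exclusive_pairs) -> bool:
    by_comp: dict[str, set[str]] = {}
    for comp, term in subset:
        by_comp.setdefault(comp, set()).add(term)
    for comp, terms in by_comp.items():
        for t in terms:
            for main in required_mains(t):
                if main not in terms:
                    return False
        metrics = {m for t in terms for m in term_metrics(t)}
        for pair in exclusive_pairs:
            if pair <= metrics:
                return False
    return True


def all_subsets_average(
    fitter,
    candidates: dict[str, list[str]],
    exclusive_pairs: set[frozenset[str]] | None = None,
    delta_aicc: float = 2.0,
    ci_level: float = 0.95,
) -> AveragedModel:
    """Enumerate admissible subsets, keep delta-AICc <= 2, average.

    Conditional averaging: a term's averaged coefficient uses only the kept
    models containing it; its unconditional SE is the Akaike-weighted mean of
    sqrt(se_m^2 + (beta_m - beta_bar)^2) over those models.  Gaussian mixed
    models are refitted with REML for the reported estimates (weights stay
    ML-AICc based).
    """
    from scipy.stats import norm

    exclusive_pairs = exclusive_pairs or set()
    items = [(c, t) for c, ts in candidates.items() for t in ts]
    if len(items) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(items)} candidate terms exceed the all-subsets guard "
            f"({MAX_CANDIDATES}); tighten the screen"
        )
    fits: list[tuple[tuple, FitRecord]] = []
    for r in range(len(items) + 1):
        for subset in itertools.combinations(items, r):
            if not _admissible(subset, exclusive_pairs):
                continue
            terms = {c: tuple(t for cc, t in subset if cc == c) for c in fitter.components}
            try:
                rec = fitter.fit(terms, method="ML")
            except Exception:
                continue
            if rec.converged:
                fits.append((subset, rec))
    if not fits:
        raise RuntimeError("no candidate model converged")
    aiccs = np.array([rec.aicc for _, rec in fits])
    best = aiccs.min()
    keep_idx = np.flatnonzero(aiccs - best <= delta_aicc)
    kept = [fits[i] for i in keep_idx]
    deltas = aiccs[keep_idx] - best
    w = np.exp(-deltas / 2.0)
    w /= w.sum()
    # REML refit of kept models for reporting, where the family supports it
    report: list[FitRecord] = []
    for subset, rec in kept:
        if fitter.supports_reml:
            terms = {c: tuple(t for cc, t in subset if cc == c) for c in fitter.components}
            report.append(fitter.fit(terms, method="REML"))
        else:
            report.append(rec)
    zq = norm.ppf(0.5 + ci_level / 2.0)
    rows = []
    all_keys = sorted({key for rec in report for key in rec.coef})
    for key in all_keys:
        comp, term = key
        idx = [i for i, rec in enumerate(report) if key in rec.coef]
        wj = w[idx] / w[idx].sum()
        est = np.array([report[i].coef[key][0] for i in idx])
        se = np.array([report[i].coef[key][1] for i in idx])
        avg = float(np.sum(wj * est))
        use = float(np.sum(wj * np.sqrt(se**2 + (est - avg) ** 2)))
        rows.append(
            {
                "component": comp,
                "term": term,
                "estimate": avg,
                "se": use,
                "ci_lower": avg - zq * use,
                "ci_upper": avg + zq * use,
                "n_models": len(idx),
            }
        )
    sel_rows = []
    for (subset, rec), d, wi in zip(kept, deltas, w):
        sel_rows.append(
            {
                "model": " + ".join(f"{c}:{t}" for c, t in subset) or "(intercept only)",
                "logLik": rec.llf,
                "k": rec.k,
                "AICc": rec.aicc,
                "delta": float(d),
                "weight": float(wi),
            }
        )
    return AveragedModel(
        table=pd.DataFrame(rows),
        selection=pd.DataFrame(sel_rows).sort_values("delta").reset_index(drop=True),
        n_fitted=len(fits),
    )
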