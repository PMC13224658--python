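"""Consensus paternity assignment from microsatellite genotypes.

Each offspring of a known mother (pollen receptor) is assigned either to one
candidate pollen donor from its own forest patch, or to UNASSIGNED — pollen
from an unsampled or immigrant father.  The model is an error-tolerant
Mendelian likelihood: at each locus the trio likelihood is a mixture

    L_locus = (1 - e) * T(g_off | g_mother, g_father) + e * P_HWE(g_off)

where ``T`` is the Mendelian transmission probability, ``e`` the per-locus
genotyping error rate, and ``P_HWE`` the Hardy-Weinberg genotype probability
of the offspring under the patch allele frequencies.  For an unsampled
father the paternal allele is integrated over the allele frequencies.

Assignment maximises, per offspring,

    log[ p_sampled * L(candidate) ]   vs   log[ (1 - p_sampled) * L(unsampled) ]

by a simulated-annealing search over per-offspring father labels.  Because
unsampled fathers are integrated per offspring (no sibship clustering), the
posterior factorises over offspring; an annealing sweep therefore re-draws
every label from its conditional posterior at the current temperature, which
is exactly the one-offspring-at-a-time Gibbs proposal run to completion.
Five independent seeded runs are combined by a >=2-of-5 consensus rule.
Self-incompatibility: a candidate whose MLG equals the mother's (including
the mother herself) has zero likelihood unless ``selfing_allowed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import (
    GenotypeSet,
    MismatchStatus,
    Role,
    SampleRecord,
    allele_frequencies,
    mlg_key,
    resolve_mother_mismatches,
)

__all__ = [
    "UNASSIGNED",
    "locus_error_rate",
    "PaternityConfig",
    "RunResult",
    "ConsensusAssignment",
    "transmission_prob",
    "offspring_lik_unsampled",
    "hwe_prob",
    "pair_loglik",
    "score_matrix",
    "anneal_run",
    "consensus",
    "assign_patch",
    "assign_all",
]

UNASSIGNED = "UNASSIGNED"
NEG_INF = float("-inf")


def locus_error_rate(e_slot: float, n_slots: int = 6) -> float:
    """Convert a per-allele-slot error probability to the locus-level rate
    the likelihood mixture expects.

    A trio exposes six allele slots per locus (two per participant); if each
    errs independently with probability ``e_slot``, the observed trio locus
    deviates from the error-free trio with probability 1 - (1 - e_slot)^6.
    Published microsatellite error rates (from repeat genotyping) are
    locus-level and need no conversion.
    """
    return 1.0 - (1.0 - e_slot) ** n_slots


@dataclass
class PaternityConfig:
    error_rate: float = 0.012
    p_sampled: float = 0.5
    n_runs: int = 5
    min_support: int = 2
    n_sweeps: int = 200
    t0: float = 2.0
    cooling: float = 0.95
    selfing_allowed: bool = False
    max_mother_mismatch: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 < self.p_sampled < 1:
            raise ValueError("p_sampled must be in (0, 1)")
        if self.min_support > self.n_runs:
            raise ValueError("min_support cannot exceed n_runs")


@dataclass
class RunResult:
    seed: int
    assignment: dict[str, str]  # offspring_id -> donor_id or UNASSIGNED
    loglik: float


@dataclass
class ConsensusAssignment:
    assignment: dict[str, str] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)
    mother: dict[str, str] = field(default_factory=dict)
    patch: dict[str, str] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)  # offspring_id -> reason

    def merge(self, other: "ConsensusAssignment") -> None:
        self.assignment.update(other.assignment)
        self.support.update(other.support)
        self.mother.update(other.mother)
        self.patch.update(other.patch)
        self.excluded.update(other.excluded)

    def assigned(self) -> dict[str, str]:
        return {o: d for o, d in self.assignment.items() if d != UNASSIGNED}


# ---------------------------------------------------------------------------
# Single-locus likelihood pieces

def transmission_prob(
    g_off: tuple[int, int], g_mother: tuple[int, int], g_father: tuple[int, int]
) -> float:
    """P(offspring unordered pair | one allele drawn uniformly from each parent)."""
    target = tuple(sorted(g_off))
    p = 0.0
    for m in g_mother:
        for f in g_father:
            if tuple(sorted((m, f))) == target:
                p += 0.25
    return p


def hwe_prob(g_off: tuple[int, int], freqs: dict[int, float]) -> float:
    """Hardy-Weinberg probability of an unordered genotype."""
    a, b = g_off
    pa = freqs.get(a, 0.0)
    pb = freqs.get(b, 0.0)
    return pa * pa if a == b else 2.0 * pa * pb


def offspring_lik_unsampled(
    g_off: tuple[int, int], g_mother: tuple[int, int], freqs: dict[int, float]
) -> float:
    """P(offspring | mother, father drawn from HWE allele frequencies)."""
    target = tuple(sorted(g_off))
    p = 0.0
    for m in g_mother:
        for a, fa in freqs.items():
            if tuple(sorted((m, a))) == target:
                p += 0.5 * fa
    return p


def pair_loglik(
    offspring: SampleRecord,
    mother: SampleRecord,
    father: SampleRecord | None,
    freqs: dict[str, dict[int, float]],
    e: float,
    selfing_allowed: bool = False,
    panel: Sequence[str] | None = None,
) -> float:
    """Log-likelihood of a mother-father(-or-unsampled)-offspring trio.

    Loci missing in any participant are skipped.  ``father=None`` integrates
    the paternal contribution over the allele frequencies.
    """
    loci = list(panel) if panel is not None else list(offspring.alleles)
    if father is not None and not selfing_allowed:
        if father.sample_id == mother.sample_id or _same_mlg(father, mother, loci):
            return NEG_INF
    total = 0.0
    for l in loci:
        if not (offspring.typed(l) and mother.typed(l)):
            continue
        if father is not None and not father.typed(l):
            continue
        g_off = offspring.alleles[l]
        fl = freqs[l]
        if father is None:
            t = offspring_lik_unsampled(g_off, mother.alleles[l], fl)
        else:
            t = transmission_prob(g_off, mother.alleles[l], father.alleles[l])
        lik = (1.0 - e) * t + e * hwe_prob(g_off, fl)
        if lik <= 0.0:
            return NEG_INF
        total += math.log(lik)
    return total


def _same_mlg(a: SampleRecord, b: SampleRecord, loci: Sequence[str]) -> bool:
    try:
        return mlg_key(a, loci) == mlg_key(b, loci)
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Configuration search

def score_matrix(
    offspring: Sequence[SampleRecord],
    mothers: dict[str, SampleRecord],
    candidates: Sequence[SampleRecord],
    freqs: dict[str, dict[int, float]],
    cfg: PaternityConfig,
    panel: Sequence[str] | None = None,
) -> np.ndarray:
    """(n_offspring, n_candidates + 1) log-score matrix; last column = UNASSIGNED.

    ``p_sampled`` is the prior probability that the true father is in the
    candidate set, spread uniformly over its members: entry [i, c] =
    log(p_sampled / |C|) + pair log-likelihood with candidate c; entry
    [i, -1] = log(1 - p_sampled) + unsampled-father log-likelihood.
    """
    n, c = len(offspring), len(candidates)
    S = np.full((n, c + 1), NEG_INF)
    lp = math.log(cfg.p_sampled / c) if c else NEG_INF
    lq = math.log(1.0 - cfg.p_sampled)
    for i, off in enumerate(offspring):
        mother = mothers[off.mother_id]
        for j, cand in enumerate(candidates):
            ll = pair_loglik(
                off, mother, cand, freqs, cfg.error_rate, cfg.selfing_allowed, panel
            )
            S[i, j] = lp + ll if ll > NEG_INF else NEG_INF
        ll0 = pair_loglik(off, mother, None, freqs, cfg.error_rate, True, panel)
        S[i, c] = lq + ll0 if ll0 > NEG_INF else NEG_INF
    return S


def anneal_labels(S: np.ndarray, cfg: PaternityConfig, seed: int) -> tuple[np.ndarray, float]:
    """Simulated-annealing maximisation of sum_i S[i, label_i].

    Each sweep re-draws every offspring's label from its conditional
    posterior softmax(S_i / T) via the Gumbel-max trick (the labels are
    conditionally independent, so the simultaneous re-draw is valid Gibbs);
    the best configuration visited is returned.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    n, k = S.shape
    # rows that are entirely -inf (structurally impossible) are pinned to
    # UNASSIGNED and contribute 0 to the reported log-likelihood
    dead = ~np.isfinite(S).any(axis=1)
    S_ = S.copy()
    S_[dead, -1] = 0.0
    labels = np.array(
        [rng.choice(np.flatnonzero(np.isfinite(S_[i]))) for i in range(n)]
    )
    best = labels.copy()

    def total(lab):
        return float(S_[np.arange(n), lab].sum())

    best_val = total(labels)
    t = cfg.t0
    for _ in range(cfg.n_sweeps):
        gumbel = rng.gumbel(size=(n, k))
        scored = np.where(np.isfinite(S_), S_ / t + gumbel, NEG_INF)
        labels = scored.argmax(axis=1)
        val = total(labels)
        if val > best_val:
            best_val = val
            best = labels.copy()
        t *= cfg.cooling
    return best, best_val


def anneal_run(
    offspring: Sequence[SampleRecord],
    mothers: dict[str, SampleRecord],
    candidates: Sequence[SampleRecord],
    freqs: dict[str, dict[int, float]],
    cfg: PaternityConfig,
    seed: int,
    panel: Sequence[str] | None = None,
    S: np.ndarray | None = None,
) -> RunResult:
    """One stochastic search run: MAP father label per offspring."""
    if S is None:
        S = score_matrix(offspring, mothers, candidates, freqs, cfg, panel)
    labels, val = anneal_labels(S, cfg, seed)
    ids = [c.sample_id for c in candidates] + [UNASSIGNED]
    return RunResult(
        seed=seed,
        assignment={o.sample_id: ids[l] for o, l in zip(offspring, labels)},
        loglik=val,
    )


def consensus(runs: Sequence[RunResult], cfg: PaternityConfig) -> ConsensusAssignment:
    """Accept a donor appearing in >= min_support runs with maximal support.

    Ties between donors at maximal support fall back to UNASSIGNED.  For
    unassigned offspring the recorded support is the number of runs agreeing
    on UNASSIGNED.
    """
    if len(runs) != cfg.n_runs:
        raise ValueError(f"expected {cfg.n_runs} runs, got {len(runs)}")
    out = ConsensusAssignment()
    offspring_ids = runs[0].assignment.keys()
    for oid in offspring_ids:
        votes: dict[str, int] = {}
        for r in runs:
            votes[r.assignment[oid]] = votes.get(r.assignment[oid], 0) + 1
        donor_votes = {d: c for d, c in votes.items() if d != UNASSIGNED}
        if donor_votes:
            top = max(donor_votes.values())
            winners = [d for d, c in donor_votes.items() if c == top]
            if top >= cfg.min_support and len(winners) == 1:
                out.assignment[oid] = winners[0]
                out.support[oid] = top
                continue
        out.assignment[oid] = UNASSIGNED
        out.support[oid] = votes.get(UNASSIGNED, 0)
    return out


# ---------------------------------------------------------------------------
# Patch-level driver

def assign_patch(
    gs: GenotypeSet,
    patch_id: str,
    cfg: PaternityConfig,
    seed: int | None = None,
) -> ConsensusAssignment:
    """Full 5-run consensus paternity for one forest patch.

    Candidates are all adult genotypes of the patch (receptors included);
    allele frequencies are computed from the patch adults.  Offspring whose
    genotype mismatches the mother at more than ``max_mother_mismatch`` loci
    are excluded as INCOMPATIBLE.
    """
    if seed is None:
        seed = cfg.seed
    panel = gs.locus_names
    patch = gs.subset(lambda s: s.patch_id == patch_id)
    candidates = [s for s in patch.samples if s.role != Role.OFFSPRING]
    mothers = {s.sample_id: s for s in patch.by_role(Role.RECEPTOR)}
    result = ConsensusAssignment()
    offspring: list[SampleRecord] = []
    for off in patch.by_role(Role.OFFSPRING):
        mother = mothers.get(off.mother_id)
        if mother is None:
            result.excluded[off.sample_id] = "mother_not_in_patch"
            continue
        fixed, _, status = resolve_mother_mismatches(off, mother, cfg.max_mother_mismatch)
        if status == MismatchStatus.INCOMPATIBLE:
            result.excluded[off.sample_id] = "incompatible_with_mother"
            continue
        offspring.append(fixed)
    if not offspring:
        return result
    freqs = allele_frequencies(gs, subset=lambda s: s.patch_id == patch_id and s.role != Role.OFFSPRING)
    if not candidates:
        for off in offspring:
            result.assignment[off.sample_id] = UNASSIGNED
            result.support[off.sample_id] = cfg.n_runs
            result.mother[off.sample_id] = off.mother_id
            result.patch[off.sample_id] = patch_id
        return result
    S = score_matrix(offspring, mothers, candidates, freqs, cfg, panel)
    runs = [
        anneal_run(offspring, mothers, candidates, freqs, cfg, seed + r, panel, S=S)
        for r in range(cfg.n_runs)
    ]
    cons = consensus(runs, cfg)
    result.assignment.update(cons.assignment)
    result.support.update(cons.support)
    for off in offspring:
        result.mother[off.sample_id] = off.mother_id
        result.patch[off.sample_id] = patch_id
    return result


def assign_all(gs: GenotypeSet, cfg: PaternityConfig) -> ConsensusAssignment:
    """Per-patch consensus paternity over every patch with offspring.

    Per-patch seeds are pre-assigned from the master seed so patches could be
    processed in any order (or concurrently) with identical results.
    """
    result = ConsensusAssignment()
    patches = sorted({s.patch_id for s in gs.by_role(Role.OFFSPRING)})
    for i, patch_id in enumerate(patches):
        result.merge(assign_patch(gs, patch_id, cfg, seed=cfg.seed + 1000 * i))
    return result
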