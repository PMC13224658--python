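"""Pollen-flow summaries per pollen receptor and per donor.

``PF_within`` is the proportion of a receptor's genotyped offspring that were
assigned to a pollen donor from the receptor's own forest patch; its
complement ``1 - PF_within`` is the pollen immigration rate (unassigned
offspring count as immigrant pollen, which makes the estimate conservative
with respect to within-patch flow).  Offspring genetic diversity is measured
as rarefied allelic richness ``A_r``: the expected number of distinct
alleles per locus in a random subsample of gene copies, rarefied to five
offspring individuals (10 gene copies); receptors with fewer than five
genotyped offspring are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

from .genotypes import GenotypeSet, Role, SampleRecord
from .paternity import UNASSIGNED, ConsensusAssignment

__all__ = [
    "ReceptorSummary",
    "DonorSummary",
    "DonorAggregate",
    "pf_within",
    "rarefied_allelic_richness",
    "receptor_summaries",
    "donor_statistics",
]


@dataclass
class ReceptorSummary:
    receptor_id: str
    patch_id: str
    n_offspring: int
    n_within: int
    pf_within: float
    immigration_rate: float
    a_r: float | None = None
    a_r_sum: float | None = None


@dataclass
class DonorSummary:
    donor_id: str
    cluster_id: str | None
    n_assigned_offspring: int
    distance_to_edge: float | None = None
    receptor_distances: list[float] = field(default_factory=list)


@dataclass
class DonorAggregate:
    n_effective_donors: int
    n_clusters: int
    fraction_clusters_donating: float
    median_offspring_per_donor: float | None
    median_donor_receptor_distance: float | None
    median_distance_to_edge: float | None


def pf_within(cons: ConsensusAssignment, receptor_id: str) -> tuple[int, int]:
    """(n_offspring, n_within) for one receptor from the consensus map."""
    n = n_within = 0
    for oid, mother in cons.mother.items():
        if mother != receptor_id:
            continue
        n += 1
        if cons.assignment.get(oid, UNASSIGNED) != UNASSIGNED:
            n_within += 1
    if n == 0:
        raise ValueError(f"receptor {receptor_id}: no offspring in consensus")
    return n, n_within


def rarefied_allelic_richness(
    offspring: Sequence[SampleRecord],
    loci: Sequence[str],
    g_individuals: int = 5,
    aggregate: str = "mean",
) -> float:
    """Exact (hypergeometric) rarefied allele count, averaged over loci.

    Per locus with ``N`` typed gene copies carrying ``N_i`` copies of allele
    i, the expected number of distinct alleles in a random subsample of
    ``g = 2 * g_individuals`` copies is

        A_r(locus) = sum_i [ 1 - C(N - N_i, g) / C(N, g) ]

    (``g`` is truncated to ``N`` when fewer copies are available).  Loci with
    no typed copies are skipped.  ``aggregate`` is "mean" (default) or "sum"
    over loci.
    """
    if len(offspring) < g_individuals:
        raise ValueError(
            f"need >= {g_individuals} offspring for rarefaction, got {len(offspring)}"
        )
    g_copies = 2 * g_individuals
    per_locus = []
    for locus in loci:
        counts: dict[int, int] = {}
        for s in offspring:
            if s.typed(locus):
                for a in s.alleles[locus]:
                    counts[a] = counts.get(a, 0) + 1
        n_total = sum(counts.values())
        if n_total == 0:
            continue
        g = min(g_copies, n_total)
        denom = math.comb(n_total, g)
        a_r = sum(1.0 - math.comb(n_total - ni, g) / denom for ni in counts.values())
        per_locus.append(a_r)
    if not per_locus:
        raise ValueError("no typed locus across offspring")
    total = sum(per_locus)
    return total / len(per_locus) if aggregate == "mean" else total


def receptor_summaries(
    cons: ConsensusAssignment,
    gs: GenotypeSet,
    g_individuals: int = 5,
) -> list[ReceptorSummary]:
    """Per-receptor PF_within, immigration rate and A_r.

    ``A_r`` is absent for receptors with fewer than ``g_individuals``
    genotyped offspring ("fewer than five berries" exclusion).
    """
    by_mother: dict[str, list[SampleRecord]] = {}
    for s in gs.by_role(Role.OFFSPRING):
        if s.sample_id in cons.mother:  # excluded offspring don't count
            by_mother.setdefault(s.mother_id, []).append(s)
    out = []
    for rec in gs.by_role(Role.RECEPTOR):
        kids = by_mother.get(rec.sample_id)
        if not kids:
            continue
        n, n_within = pf_within(cons, rec.sample_id)
        summ = ReceptorSummary(
            receptor_id=rec.sample_id,
            patch_id=rec.patch_id,
            n_offspring=n,
            n_within=n_within,
            pf_within=n_within / n,
            immigration_rate=1.0 - n_within / n,
        )
        if len(kids) >= g_individuals:
            summ.a_r = rarefied_allelic_richness(kids, gs.locus_names, g_individuals, "mean")
            summ.a_r_sum = rarefied_allelic_richness(kids, gs.locus_names, g_individuals, "sum")
        out.append(summ)
    return sorted(out, key=lambda r: r.receptor_id)


def donor_statistics(
    cons: ConsensusAssignment,
    gs: GenotypeSet,
    cluster_of: dict[str, str] | None = None,
    cluster_coords: dict[str, tuple[float, float]] | None = None,
    patch_boundaries: dict[str, object] | None = None,
    n_clusters_total: int | None = None,
) -> tuple[list[DonorSummary], DonorAggregate]:
    """Effective pollen donors and their spatial statistics.

    ``patch_boundaries`` maps patch_id to a shapely polygon; edge distance is
    the distance from the donor's cluster point to the nearest point of its
    patch boundary.  Donors without coordinates are kept but excluded from
    the distance medians.
    """
    cluster_of = cluster_of or {}
    counts: dict[str, int] = {}
    rec_of: dict[str, list[str]] = {}
    for oid, donor in cons.assigned().items():
        counts[donor] = counts.get(donor, 0) + 1
        rec_of.setdefault(donor, []).append(cons.mother[oid])
    summaries: list[DonorSummary] = []
    donor_clusters = set()
    for donor_id in sorted(counts):
        rec = gs[donor_id] if donor_id in gs else None
        cid = cluster_of.get(donor_id) or (rec.cluster_id if rec else None)
        if cid is not None:
            donor_clusters.add(cid)
        summ = DonorSummary(donor_id, cid, counts[donor_id])
        pt = None
        if cluster_coords and cid in cluster_coords:
            pt = cluster_coords[cid]
        elif rec is not None and rec.coords is not None:
            pt = rec.coords
        if pt is not None:
            if patch_boundaries and rec is not None and rec.patch_id in patch_boundaries:
                from shapely.geometry import Point

                summ.distance_to_edge = Point(pt).distance(
                    patch_boundaries[rec.patch_id].boundary
                )
            for rid in rec_of[donor_id]:
                r = gs[rid] if rid in gs else None
                if r is not None and r.coords is not None:
                    summ.receptor_distances.append(math.dist(pt, r.coords))
        summaries.append(summ)
    if n_clusters_total is None:
        n_clusters_total = len(
            {s.cluster_id for s in gs.adults() if s.cluster_id is not None}
        )
    all_distances = [d for s in summaries for d in s.receptor_distances]
    edge = [s.distance_to_edge for s in summaries if s.distance_to_edge is not None]
    agg = DonorAggregate(
        n_effective_donors=len(summaries),
        n_clusters=n_clusters_total,
        fraction_clusters_donating=(
            len(donor_clusters) / n_clusters_total if n_clusters_total else float("nan")
        ),
        median_offspring_per_donor=median(counts.values()) if counts else None,
        median_donor_receptor_distance=median(all_distances) if all_distances else None,
        median_distance_to_edge=median(edge) if edge else None,
    )
    return summaries, agg
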