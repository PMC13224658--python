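"""Synthetic two-generation landscape-genetic studies with full ground truth.

Generates, from one master seed: a square agricultural landscape window with
forest patches, tiled land-use classes and oriented linear elements; clonal
plant populations (shoot clusters with size-dependent clonality, genotypes
drawn from Hardy-Weinberg at configured microsatellite frequencies);
trapline-driven, strictly outcrossing mating (bumblebee foraging routes of
10-30 visits spanning patches, a geometric pollen-carryover queue, and a
self-incompatibility check rejecting donors with the receptor's own MLG);
and per-slot genotyping error.  Every offspring's true father, father patch
and immigrant status are recorded so each pipeline stage can be verified
against truth.

All randomness flows from one master seed through named substreams
(landscape, genets, routes, errors), so stages can be regenerated
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
import numpy as np
from shapely.geometry import LineString, Point, Polygon, box

from .genotypes import GenotypeSet, Locus, Role, SampleRecord
from .landscape import LandUseMap, LinearElementSet, PopulationSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "Population",
    "SCENARIOS",
    "gen_landscape",
    "gen_populations",
    "simulate_mating",
    "apply_genotyping_error",
    "simulate_study",
]

_SUBSTREAMS = {"landscape": 1, "genets": 2, "routes": 3, "errors": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _SUBSTREAMS[stream]])


@dataclass
class SimConfig:
    """Study-design parameters; defaults emulate the field design:
    a 5 km window with 9 forest patches, heavy-tailed shoot-cluster sizes
    (~85% below 10 shoots), monoclonality falling with cluster size
    (0.62 / 0.46 / 0.28), 7 loci with 97 alleles, 0-1.22% genotyping error,
    6-14 receptors per patch with 1-41 offspring each, and trapline routes
    of 10-30 visits."""

    window: float = 5000.0
    n_patches: int = 9
    patch_radius: tuple[float, float] = (120.0, 300.0)
    clusters_per_patch: tuple[int, int] = (24, 300)
    # zero-truncated negative binomial over shoots per cluster:
    # P(<10 shoots) ~ 0.85 with a heavy tail
    nb_r: float = 0.2
    nb_p: float = 0.0943
    monoclonal_probs: dict = field(
        default_factory=lambda: {"<5": 0.62, "5-20": 0.46, ">20": 0.28}
    )
    extra_genets_mean: float = 0.7  # polyclonal clusters hold 2 + Poisson genets
    allele_counts: tuple[int, ...] = (14, 14, 14, 14, 14, 14, 13)
    error_rate: float = 0.012
    receptors_per_patch: tuple[int, int] = (6, 14)
    offspring_per_receptor: tuple[int, int] = (1, 41)
    clonality_subsample_frac: float = 0.03  # clusters sampled with >1 shoot
    clonality_max_shoots: int = 6
    route_visits: tuple[int, int] = (10, 30)
    p_switch: float = 0.2
    kappa: float = 0.5  # pollen carryover geometric decay
    n_neighbors: int = 5  # within-patch move: uniform over k nearest clusters
    repeat_routes: bool = False
    s_locus: bool = False
    n_s_alleles: int = 20
    max_routes: int = 200000
    # landscape composition (fractions of grid cells outside forest patches)
    frac_maize: float = 0.45
    frac_grass: float = 0.08
    frac_rapeseed: float = 0.12
    cell_size: float = 250.0
    land_margin: float = 1000.0  # land-use tiled beyond the window so
    # buffers of edge receptors stay covered
    elements_per_type: int = 25
    element_length: tuple[float, float] = (150.0, 600.0)
    orientation: str = "random"  # random | parallel | orthogonal
    seed: int = 0

    def panel(self) -> list[Locus]:
        return [
            Locus(f"L{i+1}", frozenset(range(100 + i * 100, 100 + i * 100 + k)))
            for i, k in enumerate(self.allele_counts)
        ]


SCENARIOS: dict[str, dict] = {
    "within_only": {"p_switch": 0.0},
    "trapline_mixed": {"p_switch": 0.2},
    "high_carryover": {"p_switch": 0.2, "kappa": 0.9},
    "orientation_parallel": {"orientation": "parallel"},
    "orientation_orthogonal": {"orientation": "orthogonal"},
}


# ---------------------------------------------------------------------------
# Landscape

def gen_landscape(
    cfg: SimConfig, seed: int | None = None
) -> tuple[LandUseMap, LinearElementSet, dict[str, Polygon]]:
    """Non-overlapping forest-patch polygons, a land-use tiling of the
    window, and oriented linear elements."""
    total = cfg.frac_maize + cfg.frac_grass + cfg.frac_rapeseed
    if total > 1.0 + 1e-9:
        raise ValueError("land-use fractions exceed 1")
    rng = _rng(cfg.seed if seed is None else seed, "landscape")
    W = cfg.window
    patches: dict[str, Polygon] = {}
    centers = []
    tries = 0
    while len(patches) < cfg.n_patches and tries < 20000:
        tries += 1
        r = rng.uniform(*cfg.patch_radius)
        c = rng.uniform(r, W - r, size=2)
        if any(math.dist(c, c2) < r + r2 + 100.0 for c2, r2 in centers):
            continue
        pid = f"F{len(patches)+1:02d}"
        patches[pid] = Point(c).buffer(r, quad_segs=32)
        centers.append((tuple(c), r))
    if len(patches) < cfg.n_patches:
        raise ValueError("could not place patches; lower n_patches or radius")
    # land-use tiling (grid cells classified by the configured fractions)
    m = cfg.land_margin
    n_cells = int(np.ceil((W + 2 * m) / cfg.cell_size))
    probs = [cfg.frac_maize, cfg.frac_grass, cfg.frac_rapeseed, 1.0 - total]
    classes = ("MAIZE", "SEMNATGRASS", "RAPESEED", "OTHER")
    polys = []
    for i in range(n_cells):
        for j in range(n_cells):
            cls = classes[rng.choice(4, p=probs)]
            polys.append(
                (
                    cls,
                    box(
                        -m + i * cfg.cell_size,
                        -m + j * cfg.cell_size,
                        min(-m + (i + 1) * cfg.cell_size, W + m),
                        min(-m + (j + 1) * cfg.cell_size, W + m),
                    ),
                )
            )
    lum = LandUseMap(polys)
    # linear elements with controlled orientation relative to patch centers
    elems = []
    cxy = np.array([c for c, _ in centers])
    for typ in ("L_ROAD", "L_WATER", "L_WOOD"):
        for _ in range(cfg.elements_per_type):
            mid = rng.uniform(0, W, size=2)
            nearest = cxy[np.argmin(np.linalg.norm(cxy - mid, axis=1))]
            to_patch = mid - nearest
            nrm = np.linalg.norm(to_patch)
            if nrm < 1e-9:
                to_patch, nrm = np.array([1.0, 0.0]), 1.0
            u = to_patch / nrm
            if cfg.orientation == "parallel":
                d = u
            elif cfg.orientation == "orthogonal":
                d = np.array([-u[1], u[0]])
            else:
                ang = rng.uniform(0, 2 * np.pi)
                d = np.array([np.cos(ang), np.sin(ang)])
            half = rng.uniform(*cfg.element_length) / 2.0
            a, b = mid - half * d, mid + half * d
            elems.append((typ, LineString([tuple(a), tuple(b)])))
    return lum, LinearElementSet(elems), patches


# ---------------------------------------------------------------------------
# Populations

@dataclass
class Genet:
    genet_id: str
    genotype: dict[str, tuple[int, int]]
    shoot_share: float
    s_alleles: tuple[int, int] = (0, 0)


@dataclass
class Cluster:
    cluster_id: str
    patch_id: str
    center: tuple[float, float]
    shoots: int
    genets: list[Genet]


@dataclass
class Population:
    cfg: SimConfig
    panel: list[Locus]
    freqs: dict[str, np.ndarray]  # locus -> allele frequencies (Dirichlet draw)
    alleles: dict[str, np.ndarray]  # locus -> allele codes
    clusters: list[Cluster]
    receptors: dict[str, tuple[str, str]]  # receptor sample id -> (cluster, genet)
    sampled: dict[str, str]  # sample_id -> genet_id
    samples: list[SampleRecord]

    def to_genotype_set(self) -> GenotypeSet:
        return GenotypeSet(self.panel, list(self.samples))

    def shoots_per_cluster(self) -> dict[str, int]:
        return {c.cluster_id: c.shoots for c in self.clusters}

    def cluster_coords(self) -> dict[str, tuple[float, float]]:
        return {c.cluster_id: c.center for c in self.clusters}

    def genet_of_sample(self, sample_id: str) -> str | None:
        return self.sampled.get(sample_id)


def _draw_genotype(rng, alleles, freqs) -> dict[str, tuple[int, int]]:
    return {
        locus: tuple(sorted(rng.choice(alleles[locus], size=2, p=freqs[locus])))
        for locus in alleles
    }


def _size_class(shoots: int) -> str:
    return "<5" if shoots < 5 else ("5-20" if shoots <= 20 else ">20")


def gen_populations(
    cfg: SimConfig,
    patches: dict[str, Polygon],
    seed: int | None = None,
) -> Population:
    """Clonal shoot clusters inside patches, with adult samples.

    Each cluster is monoclonal with the probability of its size class,
    otherwise holds 2 + Poisson extra genets; shoots are split among genets
    by a stick-breaking share.  One shoot per cluster is sampled (the field
    default); a small fraction of clusters gets a multi-shoot clonality
    subsample.  Receptors are chosen per patch among sampled clusters.
    """
    rng = _rng(cfg.seed if seed is None else seed, "genets")
    panel = cfg.panel()
    alleles = {l.name: np.array(sorted(l.allele_set)) for l in panel}
    freqs = {
        l.name: rng.dirichlet(np.ones(len(alleles[l.name]))) for l in panel
    }
    clusters: list[Cluster] = []
    samples: list[SampleRecord] = []
    sampled: dict[str, str] = {}
    receptors: dict[str, tuple[str, str]] = {}
    lo, hi = cfg.clusters_per_patch
    for pid, poly in sorted(patches.items()):
        n_clusters = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        minx, miny, maxx, maxy = poly.bounds
        pts = []
        while len(pts) < n_clusters:
            p = rng.uniform((minx, miny), (maxx, maxy))
            if poly.contains(Point(p)):
                pts.append(tuple(p))
        patch_clusters = []
        for ci, center in enumerate(pts):
            cid = f"{pid}_C{ci:04d}"
            shoots = 0
            while shoots == 0:
                shoots = int(rng.negative_binomial(cfg.nb_r, cfg.nb_p))
            mono = shoots == 1 or rng.random() < cfg.monoclonal_probs[_size_class(shoots)]
            k = 1 if mono else min(2 + int(rng.poisson(cfg.extra_genets_mean)), shoots)
            # integer shoot counts per genet (each genet owns >= 1 shoot)
            shares = rng.dirichlet(np.ones(k) * 2.0)
            shoot_counts = 1 + rng.multinomial(shoots - k, shares)
            genets = [
                Genet(
                    genet_id=f"{cid}_g{g}",
                    genotype=_draw_genotype(rng, alleles, freqs),
                    shoot_share=float(shoot_counts[g] / shoots),
                    s_alleles=tuple(sorted(rng.integers(1, cfg.n_s_alleles + 1, size=2)))
                    if cfg.s_locus
                    else (0, 0),
                )
                for g in range(k)
            ]
            cluster = Cluster(cid, pid, center, shoots, genets)
            clusters.append(cluster)
            patch_clusters.append(cluster)
        # sampling: 1 shoot/cluster; clonality subsample on a small fraction
        n_receptors = int(rng.integers(cfg.receptors_per_patch[0], cfg.receptors_per_patch[1] + 1))
        receptor_idx = set(
            rng.choice(len(patch_clusters), size=min(n_receptors, len(patch_clusters)), replace=False)
        )
        for ci, cluster in enumerate(patch_clusters):
            n_shoots_sampled = 1
            if rng.random() < cfg.clonality_subsample_frac:
                n_shoots_sampled = int(
                    min(cluster.shoots, rng.integers(2, cfg.clonality_max_shoots + 1))
                )
            # draw shoots without replacement; each shoot belongs to a genet
            shoot_labels = np.repeat(
                np.arange(len(cluster.genets)),
                np.round(
                    np.array([g.shoot_share for g in cluster.genets]) * cluster.shoots
                ).astype(int),
            )
            genet_draws = rng.choice(shoot_labels, size=n_shoots_sampled, replace=False)
            is_receptor = ci in receptor_idx
            for s_i, gi in enumerate(genet_draws):
                genet = cluster.genets[gi]
                jitter = rng.uniform(-0.3, 0.3, size=2)
                sid = f"{genet.genet_id}_s{s_i}"
                role = Role.RECEPTOR if (is_receptor and s_i == 0) else Role.DONOR
                samples.append(
                    SampleRecord(
                        sample_id=sid,
                        role=role,
                        patch_id=cluster.patch_id,
                        cluster_id=cluster.cluster_id,
                        coords=(cluster.center[0] + jitter[0], cluster.center[1] + jitter[1]),
                        alleles=dict(genet.genotype),
                    )
                )
                sampled[sid] = genet.genet_id
                if role == Role.RECEPTOR:
                    receptors[sid] = (cluster.cluster_id, genet.genet_id)
    return Population(cfg, panel, freqs, alleles, clusters, receptors, sampled, samples)


# ---------------------------------------------------------------------------
# Mating

@dataclass
class SimTruth:
    father_genet: dict[str, str]  # offspring_id -> genet id
    father_patch: dict[str, str]
    father_sampled_as: dict[str, str | None]  # adult sample id if sampled
    immigrant: dict[str, bool]
    receptor_within: dict[str, float]  # receptor sample id -> true within fraction
    cluster_mlgs: dict[str, list[str]]
    events: list[dict] = field(default_factory=list)
    starved_receptors: list[str] = field(default_factory=list)

    def within_fraction(self) -> float:
        if not self.immigrant:
            return float("nan")
        vals = list(self.immigrant.values())
        return 1.0 - sum(vals) / len(vals)


def _mendelian_child(rng, mother: dict, father: dict) -> dict:
    return {
        locus: tuple(
            sorted((mother[locus][rng.integers(2)], father[locus][rng.integers(2)]))
        )
        for locus in mother
    }


def simulate_mating(
    pop: Population, seed: int | None = None, log_events: bool = False
) -> tuple[GenotypeSet, SimTruth]:
    """Trapline foraging routes siring offspring on receptor clusters.

    Routes of 10-30 cluster visits move to one of the k nearest same-patch
    clusters, or switch to a random other patch with probability p_switch.
    A visit to a receptor cluster draws a pollen donor from the carryover
    queue (weight kappa^age over previously visited genets; age 0 = the
    immediately preceding visit) and sires one ovule iff the
    self-incompatibility check passes; the visited cluster's own genet then
    joins the queue.  Receptors that never reach their target offspring
    count are logged as starved.
    """
    cfg = pop.cfg
    rng = _rng(cfg.seed if seed is None else seed, "routes")
    clusters = pop.clusters
    by_patch: dict[str, list[int]] = {}
    for i, c in enumerate(clusters):
        by_patch.setdefault(c.patch_id, []).append(i)
    coords = np.array([c.center for c in clusters])
    # k nearest same-patch neighbours, precomputed
    neighbors: list[np.ndarray] = []
    for i, c in enumerate(clusters):
        idx = np.array([j for j in by_patch[c.patch_id] if j != i])
        if idx.size == 0:
            neighbors.append(np.array([i]))
            continue
        d = np.linalg.norm(coords[idx] - coords[i], axis=1)
        neighbors.append(idx[np.argsort(d)[: cfg.n_neighbors]])
    receptor_cluster_idx: dict[int, list[str]] = {}
    cluster_index = {c.cluster_id: i for i, c in enumerate(clusters)}
    targets: dict[str, int] = {}
    for rid, (cid, _) in pop.receptors.items():
        receptor_cluster_idx.setdefault(cluster_index[cid], []).append(rid)
        targets[rid] = int(
            rng.integers(cfg.offspring_per_receptor[0], cfg.offspring_per_receptor[1] + 1)
        )
    genet_by_id = {g.genet_id: (c, g) for c in clusters for g in c.genets}
    receptor_genet = {rid: pop.receptors[rid][1] for rid in pop.receptors}
    sample_of_genet: dict[str, str] = {}
    for sid, gid in pop.sampled.items():
        sample_of_genet.setdefault(gid, sid)
    patch_ids = sorted(by_patch)
    offspring: list[SampleRecord] = []
    truth = SimTruth({}, {}, {}, {}, {}, {c.cluster_id: [g.genet_id for g in c.genets] for c in clusters})
    produced = {rid: 0 for rid in targets}
    remaining = {rid for rid, t in targets.items() if t > 0}
    fixed_route: list[int] | None = None
    n_routes = 0
    while remaining and n_routes < cfg.max_routes:
        n_routes += 1
        visits: list[str] = []  # genet ids along the route, most recent last
        if cfg.repeat_routes and fixed_route is not None:
            route = fixed_route
        else:
            route = []
            pos = int(rng.integers(len(clusters)))
            length = int(rng.integers(cfg.route_visits[0], cfg.route_visits[1] + 1))
            for _ in range(length):
                route.append(pos)
                if len(patch_ids) > 1 and rng.random() < cfg.p_switch:
                    other = [p for p in patch_ids if p != clusters[pos].patch_id]
                    pos = int(rng.choice(by_patch[other[int(rng.integers(len(other)))]]))
                else:
                    pos = int(rng.choice(neighbors[pos]))
            if cfg.repeat_routes:
                fixed_route = route
        for pos in route:
            cluster = clusters[pos]
            shares = np.array([g.shoot_share for g in cluster.genets])
            genet = cluster.genets[int(rng.choice(len(cluster.genets), p=shares))]
            for rid in receptor_cluster_idx.get(pos, []):
                if rid not in remaining or not visits:
                    continue
                ages = np.arange(len(visits))[::-1]  # last visit has age 0
                with np.errstate(divide="ignore"):
                    w = np.where(ages == 0, 1.0, cfg.kappa ** ages)
                if w.sum() <= 0:
                    continue
                donor_gid = visits[int(rng.choice(len(visits), p=w / w.sum()))]
                donor_cluster, donor = genet_by_id[donor_gid]
                mother_gid = receptor_genet[rid]
                _, mother = genet_by_id[mother_gid]
                # self-incompatibility: identical MLG never sires
                if donor.genotype == mother.genotype:
                    continue
                if cfg.s_locus:
                    pollen_s = donor.s_alleles[int(rng.integers(2))]
                    if pollen_s in mother.s_alleles:
                        continue
                oid = f"{rid}_o{produced[rid]:03d}"
                child = _mendelian_child(rng, mother.genotype, donor.genotype)
                offspring.append(
                    SampleRecord(
                        sample_id=oid,
                        role=Role.OFFSPRING,
                        patch_id=cluster.patch_id,
                        cluster_id=None,
                        mother_id=rid,
                        alleles=child,
                    )
                )
                truth.father_genet[oid] = donor_gid
                truth.father_patch[oid] = donor_cluster.patch_id
                truth.father_sampled_as[oid] = sample_of_genet.get(donor_gid)
                truth.immigrant[oid] = donor_cluster.patch_id != cluster.patch_id
                if log_events:
                    truth.events.append(
                        {"route": n_routes, "offspring": oid, "donor": donor_gid,
                         "queue": list(visits)}
                    )
                produced[rid] += 1
                if produced[rid] >= targets[rid]:
                    remaining.discard(rid)
            visits.append(genet.genet_id)
    truth.starved_receptors = sorted(remaining)
    for rid in targets:
        kids = [oid for oid in truth.immigrant if oid.startswith(f"{rid}_o")]
        if kids:
            truth.receptor_within[rid] = 1.0 - sum(truth.immigrant[k] for k in kids) / len(kids)
    return GenotypeSet(pop.panel, offspring), truth


# ---------------------------------------------------------------------------
# Genotyping error

def apply_genotyping_error(
    gs: GenotypeSet, e: float, seed: int, freqs: dict[str, dict[int, float]] | None = None
) -> GenotypeSet:
    """Independently replace each typed allele slot with a frequency-weighted
    random allele with probability e."""
    if not 0 <= e <= 1:
        raise ValueError("error rate must be in [0, 1]")
    rng = _rng(seed, "errors")
    if freqs is None:
        from .genotypes import allele_frequencies

        freqs = allele_frequencies(gs)
    codes = {l: np.array(sorted(freqs[l])) for l in freqs}
    probs = {l: np.array([freqs[l][a] for a in codes[l]]) for l in freqs}
    out = []
    for s in gs.samples:
        new_alleles = {}
        for locus, pair in s.alleles.items():
            new_pair = list(pair)
            for slot in range(2):
                if new_pair[slot] > 0 and rng.random() < e:
                    new_pair[slot] = int(rng.choice(codes[locus], p=probs[locus]))
            new_alleles[locus] = tuple(sorted(new_pair))
        out.append(dc_replace(s, alleles=new_alleles))
    return GenotypeSet(gs.panel, out)


# ---------------------------------------------------------------------------
# Full study

def simulate_study(cfg: SimConfig, log_events: bool = False):
    """Generate a complete study: landscape, adults, offspring, truth.

    Returns (landscape triple, Population, combined GenotypeSet with
    genotyping error applied, SimTruth).
    """
    lum, elems, patches = gen_landscape(cfg)
    pop = gen_populations(cfg, patches)
    offspring_gs, truth = simulate_mating(pop, log_events=log_events)
    combined = GenotypeSet(pop.panel, pop.samples + offspring_gs.samples)
    freqs = {l: dict(zip(map(int, pop.alleles[l]), map(float, pop.freqs[l]))) for l in pop.alleles}
    noisy = apply_genotyping_error(combined, cfg.error_rate, cfg.seed, freqs=freqs)
    return (lum, elems, patches), pop, noisy, truth


def populations_geojson(patches: dict[str, Polygon], occupied: set[str] | None = None) -> PopulationSet:
    return PopulationSet(
        (pid, poly, occupied is None or pid in occupied) for pid, poly in patches.items()
    )
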