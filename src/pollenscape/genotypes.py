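"""Multilocus genotype handling for clonal plant parentage studies.

Reads and validates microsatellite allele tables, identifies repeated
multilocus genotypes (MLGs, i.e. putative clones), applies the
receptor-priority deduplication rules, summarises clonality by shoot-cluster
size, and enforces the mother-offspring Mendelian compatibility rule used
before paternity assignment.

Alleles are integer fragment lengths (assumed pre-binned); 0 codes a missing
allele.  A locus is "typed" in a sample iff both allele slots are > 0.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Role",
    "Locus",
    "SampleRecord",
    "GenotypeSet",
    "ClonalityReport",
    "MismatchStatus",
    "read_allele_table",
    "read_allele_xlsx",
    "write_allele_table",
    "mlg_key",
    "find_repeated_mlgs",
    "repeated_mlg_counts",
    "deduplicate",
    "clonality_report",
    "allele_frequencies",
    "resolve_mother_mismatches",
]

MISSING = 0


class Role(str, Enum):
    DONOR = "donor"
    RECEPTOR = "receptor"
    OFFSPRING = "offspring"


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker: a name plus the set of known allele codes."""

    name: str
    allele_set: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.allele_set):
            raise ValueError(f"locus {self.name}: allele codes must be positive")


@dataclass
class SampleRecord:
    sample_id: str
    role: Role
    patch_id: str
    alleles: dict[str, tuple[int, int]]
    cluster_id: str | None = None
    mother_id: str | None = None
    coords: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        # canonicalise: unordered pair stored sorted
        self.alleles = {k: tuple(sorted(v)) for k, v in self.alleles.items()}

    def typed(self, locus: str) -> bool:
        a, b = self.alleles.get(locus, (MISSING, MISSING))
        return a > 0 and b > 0

    def typed_loci(self) -> list[str]:
        return [l for l in self.alleles if self.typed(l)]


@dataclass
class GenotypeSet:
    """A validated panel of loci plus a collection of samples."""

    panel: list[Locus]
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = [k for k, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate sample_id(s): {sorted(dupes)[:5]}")
        self._by_id = {s.sample_id: s for s in self.samples}

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def subset(self, pred) -> "GenotypeSet":
        return GenotypeSet(self.panel, [s for s in self.samples if pred(s)])

    def by_role(self, role: Role) -> list[SampleRecord]:
        return [s for s in self.samples if s.role == role]

    def adults(self) -> list[SampleRecord]:
        return [s for s in self.samples if s.role != Role.OFFSPRING]

    def patches(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patch_id)
        return list(seen)


# ---------------------------------------------------------------------------
# I/O

_META_COLS = ["sample_id", "role", "patch_id", "cluster_id", "mother_id", "x", "y"]


def _parse_rows(
    rows: Iterable[dict],
    panel: Sequence[Locus],
    source: str,
) -> GenotypeSet:
    samples: list[SampleRecord] = []
    errors: list[str] = []
    known = {l.name: set(l.allele_set) for l in panel}
    observed: dict[str, set[int]] = {l.name: set() for l in panel}
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        sid = (row.get("sample_id") or "").strip()
        if not sid:
            errors.append(f"row {i}: empty sample_id")
            continue
        try:
            role = Role((row.get("role") or "").strip().lower())
        except ValueError:
            errors.append(f"row {i} ({sid}): unknown role {row.get('role')!r}")
            continue
        mother = (row.get("mother_id") or "").strip() or None
        if role == Role.OFFSPRING and mother is None:
            errors.append(f"row {i} ({sid}): offspring without mother_id")
            continue
        alleles: dict[str, tuple[int, int]] = {}
        bad = False
        for locus in panel:
            pair = []
            for slot in (1, 2):
                raw = row.get(f"{locus.name}_{slot}", "")
                try:
                    val = int(float(raw)) if str(raw).strip() != "" else MISSING
                except (TypeError, ValueError):
                    errors.append(f"row {i} ({sid}): malformed allele {raw!r} at {locus.name}")
                    bad = True
                    break
                if val < 0 or (known[locus.name] and val > 0 and val not in known[locus.name]):
                    errors.append(f"row {i} ({sid}): invalid allele {val} at {locus.name}")
                    bad = True
                    break
                pair.append(val)
            if bad:
                break
            alleles[locus.name] = (pair[0], pair[1])
        if bad:
            continue
        coords = None
        if str(row.get("x", "")).strip() != "" and str(row.get("y", "")).strip() != "":
            coords = (float(row["x"]), float(row["y"]))
        for name, pair in alleles.items():
            observed[name].update(a for a in pair if a > 0)
        samples.append(
            SampleRecord(
                sample_id=sid,
                role=role,
                patch_id=(row.get("patch_id") or "").strip(),
                cluster_id=(row.get("cluster_id") or "").strip() or None,
                mother_id=mother,
                coords=coords,
                alleles=alleles,
            )
        )
    if errors:
        raise ValueError(f"{source}: invalid rows:\n" + "\n".join(errors))
    # widen each locus allele_set with what was observed
    full_panel = [
        Locus(l.name, frozenset(l.allele_set) | frozenset(observed[l.name])) for l in panel
    ]
    gs = GenotypeSet(full_panel, samples)
    mothers = {s.sample_id for s in samples if s.role == Role.RECEPTOR}
    orphans = [
        s.sample_id
        for s in samples
        if s.role == Role.OFFSPRING and s.mother_id not in mothers
    ]
    if orphans:
        raise ValueError(f"{source}: offspring with unknown mother: {orphans[:5]}")
    return gs


def read_allele_table(path, panel: Sequence[Locus]) -> GenotypeSet:
    """Read a CSV allele table (two columns per locus, missing coded 0)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = [c for c in ("sample_id", "role", "patch_id") if c not in reader.fieldnames]
        for locus in panel:
            for slot in (1, 2):
                if f"{locus.name}_{slot}" not in reader.fieldnames:
                    missing_cols.append(f"{locus.name}_{slot}")
        if missing_cols:
            raise ValueError(f"{path}: missing columns {missing_cols}")
        return _parse_rows(reader, panel, str(path))


def read_allele_xlsx(path, panel: Sequence[Locus], sheet: int | str = 0) -> GenotypeSet:
    """Convert a two-column-per-locus XLSX sheet into a :class:`GenotypeSet`.

    Accepts sheets shaped like the CSV interface (same column names).
    """
    import pandas as pd

    df = pd.read_excel(path, sheet_name=sheet, dtype=object)
    rows = df.where(df.notna(), "").to_dict(orient="records")
    return _parse_rows(rows, panel, str(path))


def write_allele_table(gs: GenotypeSet, path) -> None:
    cols = _META_COLS + [f"{l.name}_{s}" for l in gs.panel for s in (1, 2)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for s in gs.samples:
            row = [
                s.sample_id,
                s.role.value,
                s.patch_id,
                s.cluster_id or "",
                s.mother_id or "",
                "" if s.coords is None else repr(float(s.coords[0])),
                "" if s.coords is None else repr(float(s.coords[1])),
            ]
            for l in gs.panel:
                a, b = s.alleles.get(l.name, (MISSING, MISSING))
                row += [a, b]
            w.writerow(row)


# ---------------------------------------------------------------------------
# MLG identification

def mlg_key(sample: SampleRecord, panel: Sequence[str] | None = None) -> tuple:
    """Canonical multilocus-genotype key: sorted allele pair per locus, panel order.

    Under the strict missing-data policy a missing locus is part of the key,
    so a partially typed sample never equals a fully typed one.
    """
    loci = list(panel) if panel is not None else sorted(sample.alleles)
    if not any(sample.typed(l) for l in loci):
        raise ValueError(f"{sample.sample_id}: all loci missing")
    return tuple(tuple(sorted(sample.alleles.get(l, (MISSING, MISSING)))) for l in loci)


def _tolerant_match(a: SampleRecord, b: SampleRecord, loci: Sequence[str]) -> bool:
    """True iff genotypes agree at every locus typed in BOTH samples."""
    shared = 0
    for l in loci:
        if a.typed(l) and b.typed(l):
            shared += 1
            if tuple(sorted(a.alleles[l])) != tuple(sorted(b.alleles[l])):
                return False
    return shared > 0


def find_repeated_mlgs(gs: GenotypeSet, policy: str = "strict") -> list[tuple[tuple, list[str]]]:
    """Group samples sharing an MLG; only groups of >=2 members are returned.

    policy="strict": exact key equality (missing loci included in the key).
    policy="tolerant": missing loci act as wildcards (transitive closure via
    union-find, so a partially typed sample can bridge two groups).
    """
    loci = gs.locus_names
    if policy == "strict":
        groups: dict[tuple, list[str]] = defaultdict(list)
        for s in gs.samples:
            groups[mlg_key(s, loci)].append(s.sample_id)
        return sorted(
            ((k, sorted(v)) for k, v in groups.items() if len(v) >= 2),
            key=lambda kv: kv[1][0],
        )
    if policy != "tolerant":
        raise ValueError(f"unknown MLG policy {policy!r}")
    n = len(gs.samples)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _tolerant_match(gs.samples[i], gs.samples[j], loci):
                parent[find(i)] = find(j)
    comp: dict[int, list[str]] = defaultdict(list)
    for i, s in enumerate(gs.samples):
        comp[find(i)].append(s.sample_id)
    out = []
    for members in comp.values():
        if len(members) >= 2:
            rep = gs[sorted(members)[0]]
            out.append((mlg_key(rep, loci), sorted(members)))
    return sorted(out, key=lambda kv: kv[1][0])


def repeated_mlg_counts(gs: GenotypeSet, policy: str = "strict") -> dict[str, int]:
    """The three counting conventions for 'repeated MLGs'.

    ``groups``: number of MLGs observed more than once; ``samples_involved``:
    samples carrying a repeated MLG; ``redundant_copies``: samples beyond the
    first per group.
    """
    groups = find_repeated_mlgs(gs, policy=policy)
    involved = sum(len(m) for _, m in groups)
    return {
        "groups": len(groups),
        "samples_involved": involved,
        "redundant_copies": involved - len(groups),
    }


# ---------------------------------------------------------------------------
# Deduplication

@dataclass
class RemovalRecord:
    sample_id: str
    reason: str
    kept_twin_of: str | None = None


def deduplicate(
    gs: GenotypeSet, policy: str = "strict"
) -> tuple[GenotypeSet, list[RemovalRecord]]:
    """Remove repeated-MLG duplicates with receptor priority.

    Within each repeated-MLG group: pollen receptors are always kept; all
    other adults in the group are removed (one smallest-id adult is kept as
    representative when the group holds no receptor).  Offspring are removed
    only as "apparent twins" — several identical-MLG offspring of the SAME
    mother — keeping the lexicographically smallest; offspring sharing an MLG
    with an adult (e.g. their own mother) are retained.
    """
    removals: list[RemovalRecord] = []
    drop: set[str] = set()
    for _, members in find_repeated_mlgs(gs, policy=policy):
        recs = [gs[m] for m in members]
        adults = sorted(
            (r for r in recs if r.role != Role.OFFSPRING), key=lambda r: r.sample_id
        )
        receptors = [r for r in adults if r.role == Role.RECEPTOR]
        if receptors:
            keep_adults = {r.sample_id for r in receptors}
        else:
            keep_adults = {adults[0].sample_id} if adults else set()
        for r in adults:
            if r.sample_id not in keep_adults:
                removals.append(
                    RemovalRecord(r.sample_id, "duplicate_adult_mlg", sorted(keep_adults)[0])
                )
                drop.add(r.sample_id)
        by_mother: dict[str, list[SampleRecord]] = defaultdict(list)
        for r in recs:
            if r.role == Role.OFFSPRING:
                by_mother[r.mother_id].append(r)
        for sibs in by_mother.values():
            sibs = sorted(sibs, key=lambda r: r.sample_id)
            for twin in sibs[1:]:
                removals.append(
                    RemovalRecord(twin.sample_id, "apparent_twin", sibs[0].sample_id)
                )
                drop.add(twin.sample_id)
    kept = GenotypeSet(gs.panel, [s for s in gs.samples if s.sample_id not in drop])
    return kept, removals


def write_removal_log(removals: list[RemovalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "reason", "kept_twin_of"])
        for r in removals:
            w.writerow([r.sample_id, r.reason, r.kept_twin_of or ""])


# ---------------------------------------------------------------------------
# Clonality

SIZE_CLASSES = ("<5", "5-20", ">20")


def size_class(shoots: int) -> str:
    if shoots < 5:
        return "<5"
    if shoots <= 20:
        return "5-20"
    return ">20"


@dataclass
class ClonalityReport:
    overall_monoclonal_fraction: float
    by_size_class: dict[str, float]
    n_clusters: int
    n_singleton_excluded: int
    by_size_class_n: dict[str, int] = field(default_factory=dict)


def clonality_report(
    gs: GenotypeSet, shoots_per_cluster: dict[str, int], policy: str = "strict"
) -> ClonalityReport:
    """Fraction of monoclonal shoot clusters, overall and per size class.

    A cluster is monoclonal iff all its sampled shoots share one MLG.
    Clusters with a single sampled shoot carry no information and are
    excluded from every denominator (counted in ``n_singleton_excluded``).
    """
    by_cluster: dict[str, list[SampleRecord]] = defaultdict(list)
    for s in gs.adults():
        if s.cluster_id is not None:
            by_cluster[s.cluster_id].append(s)
    mono: dict[str, bool] = {}
    singletons = 0
    for cid, members in by_cluster.items():
        if len(members) < 2:
            singletons += 1
            continue
        keys = {mlg_key(m, gs.locus_names) if policy == "strict" else None for m in members}
        if policy == "strict":
            mono[cid] = len(keys) == 1
        else:
            loci = gs.locus_names
            mono[cid] = all(
                _tolerant_match(members[0], m, loci) for m in members[1:]
            )
    if not mono:
        raise ValueError("no cluster with >=2 genotyped shoots")
    cls_tot: Counter = Counter()
    cls_mono: Counter = Counter()
    for cid, is_mono in mono.items():
        cls = size_class(shoots_per_cluster.get(cid, len(by_cluster[cid])))
        cls_tot[cls] += 1
        cls_mono[cls] += is_mono
    return ClonalityReport(
        overall_monoclonal_fraction=sum(cls_mono.values()) / sum(cls_tot.values()),
        by_size_class={
            c: (cls_mono[c] / cls_tot[c]) if cls_tot[c] else float("nan")
            for c in SIZE_CLASSES
        },
        n_clusters=sum(cls_tot.values()),
        n_singleton_excluded=singletons,
        by_size_class_n={c: cls_tot[c] for c in SIZE_CLASSES},
    )


# ---------------------------------------------------------------------------
# Allele frequencies

def allele_frequencies(
    gs: GenotypeSet, subset=None
) -> dict[str, dict[int, float]]:
    """Per-locus relative allele frequencies from typed loci only."""
    samples = [s for s in gs.samples if subset is None or subset(s)]
    freqs: dict[str, dict[int, float]] = {}
    for locus in gs.locus_names:
        counts: Counter = Counter()
        for s in samples:
            if s.typed(locus):
                a, b = s.alleles[locus]
                counts[a] += 1
                counts[b] += 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"locus {locus}: no typed samples in subset")
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
    return freqs


# ---------------------------------------------------------------------------
# Mother-offspring mismatch rule

class MismatchStatus(str, Enum):
    OK = "ok"
    RESOLVED = "resolved"
    INCOMPATIBLE = "incompatible"


def resolve_mother_mismatches(
    offspring: SampleRecord, mother: SampleRecord, max_mismatch: int = 1
) -> tuple[SampleRecord, int, MismatchStatus]:
    """Blank loci where the offspring shares no allele with its mother.

    Up to ``max_mismatch`` mismatching loci are set to missing (0, 0) in a
    modified copy; more mismatches flag the pair INCOMPATIBLE (the offspring
    is then excluded from paternity and logged by the caller).
    """
    if offspring.mother_id != mother.sample_id:
        raise ValueError(
            f"{offspring.sample_id}: mother_id {offspring.mother_id!r} != {mother.sample_id!r}"
        )
    mismatches = [
        l
        for l in offspring.alleles
        if offspring.typed(l)
        and mother.typed(l)
        and not set(offspring.alleles[l]) & set(mother.alleles[l])
    ]
    if not mismatches:
        return offspring, 0, MismatchStatus.OK
    if len(mismatches) > max_mismatch:
        return offspring, len(mismatches), MismatchStatus.INCOMPATIBLE
    new_alleles = dict(offspring.alleles)
    for l in mismatches:
        new_alleles[l] = (MISSING, MISSING)
    fixed = replace(offspring, alleles=new_alleles)
    return fixed, len(mismatches), MismatchStatus.RESOLVED
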