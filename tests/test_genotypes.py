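"""Genotype table I/O, MLG identification, deduplication, clonality and the
mother-offspring mismatch rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pollenscape.genotypes import (
    GenotypeSet,
    Locus,
    MismatchStatus,
    Role,
    allele_frequencies,
    clonality_report,
    deduplicate,
    find_repeated_mlgs,
    mlg_key,
    read_allele_table,
    read_allele_xlsx,
    resolve_mother_mismatches,
    write_allele_table,
)

from conftest import make_sample, random_genotype_set


def _csv(tmp_path, text):
    p = tmp_path / "table.csv"
    p.write_text(text)
    return p


PANEL = [Locus("L1", frozenset({101, 103, 105})), Locus("L2", frozenset({200, 202}))]

HEADER = "sample_id,role,patch_id,cluster_id,mother_id,x,y,L1_1,L1_2,L2_1,L2_2\n"


class TestReadAlleleTable:
    def test_toy_csv_parses(self, tmp_path):
        path = _csv(
            tmp_path,
            HEADER
            + "A,donor,P1,C1,,0,0,101,103,200,200\n"
            + "R,receptor,P1,C2,,1,1,101,101,200,202\n"
            + "O,offspring,P1,,R,,,101,105,200,202\n",
        )
        gs = read_allele_table(path, PANEL)
        assert len(gs) == 3 and len(gs.panel) == 2
        assert gs["O"].mother_id == "R"
        assert gs["A"].alleles["L1"] == (101, 103)

    def test_negative_allele_names_row(self, tmp_path):
        path = _csv(tmp_path, HEADER + "A,donor,P1,C1,,,,-1,103,200,200\n")
        with pytest.raises(ValueError, match="row 2"):
            read_allele_table(path, PANEL)

    def test_unknown_role_and_orphan_offspring(self, tmp_path):
        with pytest.raises(ValueError, match="unknown role"):
            read_allele_table(
                _csv(tmp_path, HEADER + "A,seedling,P1,C1,,,,101,103,200,200\n"), PANEL
            )
        with pytest.raises(ValueError, match="without mother_id"):
            read_allele_table(
                _csv(tmp_path, HEADER + "O,offspring,P1,,,,,101,103,200,200\n"), PANEL
            )

    def test_duplicate_sample_id(self, tmp_path):
        path = _csv(
            tmp_path,
            HEADER
            + "A,donor,P1,C1,,,,101,103,200,200\nA,donor,P1,C2,,,,101,103,200,200\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_allele_table(path, PANEL)

    def test_no_offspring_is_valid(self, tmp_path):
        path = _csv(tmp_path, HEADER + "A,donor,P1,C1,,,,101,103,200,200\n")
        gs = read_allele_table(path, PANEL)
        assert gs.by_role(Role.OFFSPRING) == []

    def test_roundtrip(self, tmp_path):
        gs = random_genotype_set(np.random.default_rng(0), 20)
        out = tmp_path / "out.csv"
        write_allele_table(gs, out)
        back = read_allele_table(out, gs.panel)
        assert [s.alleles for s in back.samples] == [s.alleles for s in gs.samples]

    def test_xlsx_converter_matches_csv(self, tmp_path):
        import pandas as pd

        rows = [
            {"sample_id": "A", "role": "donor", "patch_id": "P1", "cluster_id": "C1",
             "mother_id": "", "x": 0, "y": 0, "L1_1": 101, "L1_2": 103,
             "L2_1": 200, "L2_2": 200},
            {"sample_id": "R", "role": "receptor", "patch_id": "P1", "cluster_id": "C2",
             "mother_id": "", "x": 1, "y": 1, "L1_1": 101, "L1_2": 101,
             "L2_1": 200, "L2_2": 202},
        ]
        xlsx = tmp_path / "table.xlsx"
        pd.DataFrame(rows).to_excel(xlsx, index=False)
        gs = read_allele_xlsx(xlsx, PANEL)
        assert len(gs) == 2 and gs["R"].alleles["L2"] == (200, 202)


class TestMLGKey:
    def test_pair_order_irrelevant(self):
        a = make_sample("a", Role.DONOR, {"L1": (101, 103), "L2": (200, 200)})
        b = make_sample("b", Role.DONOR, {"L1": (103, 101), "L2": (200, 200)})
        assert mlg_key(a, ["L1", "L2"]) == mlg_key(b, ["L1", "L2"])

    def test_single_allele_difference(self):
        a = make_sample("a", Role.DONOR, {"L1": (101, 103), "L2": (200, 200)})
        b = make_sample("b", Role.DONOR, {"L1": (101, 105), "L2": (200, 200)})
        assert mlg_key(a, ["L1", "L2"]) != mlg_key(b, ["L1", "L2"])

    def test_missing_locus_policy_truth_table(self):
        """Strict: partial never equals full; tolerant grouping treats the
        missing locus as a wildcard."""
        full = make_sample("full", Role.DONOR, {"L1": (101, 103), "L2": (200, 200)})
        part = make_sample("part", Role.DONOR, {"L1": (101, 103), "L2": (0, 0)})
        other = make_sample("othr", Role.DONOR, {"L1": (101, 105), "L2": (0, 0)})
        loci = ["L1", "L2"]
        assert mlg_key(full, loci) != mlg_key(part, loci)
        gs = GenotypeSet(PANEL, [full, part, other])
        assert find_repeated_mlgs(gs, policy="strict") == []
        tolerant = find_repeated_mlgs(gs, policy="tolerant")
        assert len(tolerant) == 1 and tolerant[0][1] == ["full", "part"]

    def test_all_missing_raises(self):
        s = make_sample("s", Role.DONOR, {"L1": (0, 0), "L2": (0, 0)})
        with pytest.raises(ValueError, match="all loci missing"):
            mlg_key(s, ["L1", "L2"])


class TestFindRepeatedMLGs:
    def test_one_shared_group(self):
        geno = {"L1": (101, 103), "L2": (200, 202)}
        samples = [make_sample(f"s{i}", Role.DONOR, dict(geno)) for i in range(2)]
        samples += [
            make_sample(f"u{i}", Role.DONOR, {"L1": (101, 101 + 2 * i), "L2": (200, 200)})
            for i in range(3)
        ]
        groups = find_repeated_mlgs(GenotypeSet(PANEL, samples))
        assert len(groups) == 1 and groups[0][1] == ["s0", "s1"]

    def test_all_distinct(self):
        samples = [
            make_sample(f"s{i}", Role.DONOR, {"L1": (101, 103), "L2": (200 + 2 * i, 200)})
            for i in range(3)
        ]
        panel = [PANEL[0], Locus("L2", frozenset({200, 202, 204}))]
        assert find_repeated_mlgs(GenotypeSet(panel, samples)) == []

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_agrees_with_pairwise_oracle(self, seed):
        """Grouping must match an O(n^2) all-pairs comparison."""
        gs = random_genotype_set(np.random.default_rng(seed), 100, n_alleles=3)
        loci = gs.locus_names
        keyed = {s.sample_id: mlg_key(s, loci) for s in gs.samples}
        oracle_pairs = {
            frozenset((a.sample_id, b.sample_id))
            for i, a in enumerate(gs.samples)
            for b in gs.samples[i + 1 :]
            if keyed[a.sample_id] == keyed[b.sample_id]
        }
        got_pairs = set()
        for _, members in find_repeated_mlgs(gs):
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    got_pairs.add(frozenset((a, b)))
        assert got_pairs == oracle_pairs


class TestDeduplicate:
    GENO = {"L1": (101, 103), "L2": (200, 202)}

    def test_receptor_priority(self):
        gs = GenotypeSet(
            PANEL,
            [
                make_sample("adult", Role.DONOR, dict(self.GENO)),
                make_sample("rec", Role.RECEPTOR, dict(self.GENO)),
            ],
        )
        kept, removals = deduplicate(gs)
        assert [s.sample_id for s in kept.samples] == ["rec"]
        assert removals[0].sample_id == "adult"

    def test_apparent_twins_one_removed(self):
        gs = GenotypeSet(
            PANEL,
            [
                make_sample("mom", Role.RECEPTOR, {"L1": (101, 105), "L2": (200, 202)}),
                make_sample("o1", Role.OFFSPRING, dict(self.GENO), mother="mom"),
                make_sample("o2", Role.OFFSPRING, dict(self.GENO), mother="mom"),
            ],
        )
        kept, removals = deduplicate(gs)
        assert {s.sample_id for s in kept.samples} == {"mom", "o1"}
        assert removals[0].reason == "apparent_twin"
        assert removals[0].kept_twin_of == "o1"

    def test_parent_offspring_mlg_sharing_retained(self):
        """Identical-MLG offspring of DIFFERENT mothers both stay, as does an
        offspring sharing its mother's MLG."""
        gs = GenotypeSet(
            PANEL,
            [
                make_sample("m1", Role.RECEPTOR, dict(self.GENO)),
                make_sample("m2", Role.RECEPTOR, {"L1": (101, 105), "L2": (200, 202)}),
                make_sample("oa", Role.OFFSPRING, dict(self.GENO), mother="m1"),
                make_sample("ob", Role.OFFSPRING, dict(self.GENO), mother="m2"),
            ],
        )
        kept, removals = deduplicate(gs)
        assert len(kept) == 4 and removals == []

    def test_never_removes_receptor_and_idempotent(self):
        rng = np.random.default_rng(5)
        gs = random_genotype_set(rng, 60, n_alleles=2)
        # promote a few to receptors
        for s in gs.samples[:10]:
            s.role = Role.RECEPTOR
        kept, removals = deduplicate(gs)
        removed_ids = {r.sample_id for r in removals}
        assert all(gs[r].role != Role.RECEPTOR for r in removed_ids)
        assert len(kept) + len(removals) == len(gs)
        kept2, removals2 = deduplicate(kept)
        assert removals2 == [] and len(kept2) == len(kept)


class TestClonality:
    def test_fractions_and_size_classes(self):
        g1 = {"L1": (101, 103), "L2": (200, 202)}
        g2 = {"L1": (101, 105), "L2": (200, 202)}
        samples = [
            make_sample("a1", Role.DONOR, dict(g1), cluster="c_mono"),
            make_sample("a2", Role.DONOR, dict(g1), cluster="c_mono"),
            make_sample("b1", Role.DONOR, dict(g1), cluster="c_mixed"),
            make_sample("b2", Role.DONOR, dict(g2), cluster="c_mixed"),
            make_sample("c1", Role.DONOR, dict(g2), cluster="c_mono2"),
            make_sample("c2", Role.DONOR, dict(g2), cluster="c_mono2"),
            make_sample("d1", Role.DONOR, dict(g2), cluster="c_single"),
        ]
        rep = clonality_report(
            GenotypeSet(PANEL, samples),
            {"c_mono": 3, "c_mixed": 10, "c_mono2": 30, "c_single": 2},
        )
        assert rep.overall_monoclonal_fraction == pytest.approx(2 / 3)
        assert rep.by_size_class["<5"] == 1.0
        assert rep.by_size_class["5-20"] == 0.0
        assert rep.by_size_class[">20"] == 1.0
        assert rep.n_singleton_excluded == 1

    def test_simulated_rates_within_binomial_band(self):
        """Clusters generated with known per-class monoclonal rates must be
        recovered within the 95% binomial band."""
        from pollenscape.simulate import SimConfig, gen_landscape, gen_populations

        cfg = SimConfig(
            n_patches=3, clusters_per_patch=(70, 80), clonality_subsample_frac=1.0,
            clonality_max_shoots=10_000, window=3000.0, seed=11,
        )
        _, _, patches = gen_landscape(cfg)
        pop = gen_populations(cfg, patches)
        rep = clonality_report(pop.to_genotype_set(), pop.shoots_per_cluster())
        truth = cfg.monoclonal_probs
        for cls, n in rep.by_size_class_n.items():
            if n < 20:
                continue
            p = truth[{"<5": "<5", "5-20": "5-20", ">20": ">20"}[cls]]
            half = 1.96 * np.sqrt(p * (1 - p) / n)
            assert abs(rep.by_size_class[cls] - p) <= half + 0.02


class TestAlleleFrequencies:
    def test_simple_counts(self):
        s1 = make_sample("s1", Role.DONOR, {"L1": (101, 101), "L2": (200, 200)})
        s2 = make_sample("s2", Role.DONOR, {"L1": (101, 103), "L2": (200, 202)})
        freqs = allele_frequencies(GenotypeSet(PANEL, [s1, s2]))
        assert freqs["L1"] == {101: 0.75, 103: 0.25}
        assert freqs["L2"] == {200: 0.75, 202: 0.25}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_counting_oracle_and_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        gs = random_genotype_set(rng, 25, missing_rate=0.2)
        try:
            freqs = allele_frequencies(gs)
        except ValueError:
            return  # a locus with no typed samples is a documented error
        for locus in gs.locus_names:
            counts = {}
            for s in gs.samples:
                if s.typed(locus):
                    for a in s.alleles[locus]:
                        counts[a] = counts.get(a, 0) + 1
            total = sum(counts.values())
            assert freqs[locus] == {a: c / total for a, c in counts.items()}
            assert sum(freqs[locus].values()) == pytest.approx(1.0, abs=1e-12)
        shuffled = GenotypeSet(gs.panel, list(reversed(gs.samples)))
        assert allele_frequencies(shuffled) == freqs


class TestMotherMismatch:
    def test_mismatch_blanked(self):
        mom = make_sample("m", Role.RECEPTOR, {"L1": (101, 103), "L2": (200, 202)})
        off = make_sample(
            "o", Role.OFFSPRING, {"L1": (105, 105), "L2": (200, 200)}, mother="m"
        )
        fixed, n, status = resolve_mother_mismatches(off, mom)
        assert status == MismatchStatus.RESOLVED and n == 1
        assert fixed.alleles["L1"] == (0, 0)
        assert fixed.alleles["L2"] == (200, 200)
        # output is Mendelian-compatible with the mother at every typed locus
        assert all(
            set(fixed.alleles[l]) & set(mom.alleles[l])
            for l in fixed.alleles
            if fixed.typed(l) and mom.typed(l)
        )

    def test_compatible_unchanged(self):
        mom = make_sample("m", Role.RECEPTOR, {"L1": (101, 103), "L2": (200, 202)})
        off = make_sample(
            "o", Role.OFFSPRING, {"L1": (101, 105), "L2": (202, 202)}, mother="m"
        )
        fixed, n, status = resolve_mother_mismatches(off, mom)
        assert status == MismatchStatus.OK and n == 0 and fixed is off

    def test_too_many_mismatches_flagged(self):
        panel3 = ["L1", "L2", "L3"]
        mom = make_sample(
            "m", Role.RECEPTOR,
            {"L1": (101, 103), "L2": (200, 202), "L3": (300, 302)},
        )
        off = make_sample(
            "o", Role.OFFSPRING,
            {"L1": (105, 107), "L2": (204, 206), "L3": (304, 306)}, mother="m",
        )
        _, n, status = resolve_mother_mismatches(off, mom, max_mismatch=1)
        assert status == MismatchStatus.INCOMPATIBLE and n == 3
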