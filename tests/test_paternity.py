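"""Mendelian likelihood pieces, the annealing search, and the consensus rule."""

import itertools
import math

import numpy as np
import pytest

from pollenscape.genotypes import GenotypeSet, Locus, Role, SampleRecord
from pollenscape.paternity import (
    UNASSIGNED,
    PaternityConfig,
    RunResult,
    anneal_run,
    consensus,
    hwe_prob,
    offspring_lik_unsampled,
    pair_loglik,
    score_matrix,
    transmission_prob,
)

from conftest import make_sample


def unordered_pairs(alleles):
    return [tuple(sorted(p)) for p in itertools.combinations_with_replacement(alleles, 2)]


class TestTransmissionProb:
    def test_forced_homozygous(self):
        assert transmission_prob((1, 1), (1, 1), (1, 1)) == 1.0

    def test_quarter(self):
        assert transmission_prob((1, 3), (1, 2), (3, 4)) == 0.25

    def test_impossible(self):
        assert transmission_prob((1, 1), (1, 2), (2, 3)) == 0.0

    def test_sums_to_one_over_offspring_exhaustive(self):
        """For every parental pair on a 6-allele locus the transmission
        probabilities over all unordered offspring genotypes sum to 1."""
        alleles = list(range(1, 7))
        pairs = unordered_pairs(alleles)
        for gm in pairs:
            for gf in pairs:
                total = sum(transmission_prob(go, gm, gf) for go in pairs)
                assert total == pytest.approx(1.0, abs=1e-12)


class TestUnsampledLikelihood:
    def test_enumerated_example(self):
        # mother (A,B), offspring (A,C): paternal C via maternal A: 0.5 * 0.2
        freqs = {1: 0.5, 2: 0.3, 3: 0.2}
        assert offspring_lik_unsampled((1, 3), (1, 2), freqs) == pytest.approx(0.1)

    def test_homozygous_example(self):
        freqs = {1: 0.7, 2: 0.3}
        assert offspring_lik_unsampled((1, 1), (1, 1), freqs) == pytest.approx(0.7)

    def test_normalises_over_offspring(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(5))
        freqs = {a + 1: float(p[a]) for a in range(5)}
        for gm in unordered_pairs(range(1, 6)):
            total = sum(
                offspring_lik_unsampled(go, gm, freqs)
                for go in unordered_pairs(range(1, 6))
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestPairLoglik:
    FREQS = {"L1": {101: 0.5, 103: 0.3, 105: 0.2}, "L2": {200: 0.6, 202: 0.4}}

    def make_trio(self):
        mom = make_sample("m", Role.RECEPTOR, {"L1": (101, 103), "L2": (200, 202)})
        dad = make_sample("d", Role.DONOR, {"L1": (101, 101), "L2": (200, 200)})
        off = make_sample(
            "o", Role.OFFSPRING, {"L1": (105, 105), "L2": (200, 200)}, mother="m"
        )
        return off, mom, dad

    def test_incompatible_zero_error(self):
        off, mom, dad = self.make_trio()
        assert pair_loglik(off, mom, dad, self.FREQS, e=0.0) == -math.inf

    def test_incompatible_with_error_matches_formula(self):
        off, mom, dad = self.make_trio()
        got = pair_loglik(off, mom, dad, self.FREQS, e=0.01)
        # L1: incompatible -> e * HWE(105,105); L2: T = 0.5 (maternal 200 from
        # a heterozygous mother, paternal 200 certain)
        expected = math.log(0.01 * hwe_prob((105, 105), self.FREQS["L1"])) + math.log(
            0.99 * 0.5 + 0.01 * hwe_prob((200, 200), self.FREQS["L2"])
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_selfing_blocked_by_mlg_identity(self):
        mom = make_sample("m", Role.RECEPTOR, {"L1": (101, 103), "L2": (200, 202)})
        clone = make_sample("c", Role.DONOR, {"L1": (101, 103), "L2": (200, 202)})
        off = make_sample(
            "o", Role.OFFSPRING, {"L1": (101, 101), "L2": (200, 200)}, mother="m"
        )
        assert pair_loglik(off, mom, clone, self.FREQS, e=0.01) == -math.inf
        assert pair_loglik(off, mom, clone, self.FREQS, e=0.01, selfing_allowed=True) > -math.inf

    def test_locus_order_invariance(self):
        off, mom, dad = self.make_trio()
        a = pair_loglik(off, mom, dad, self.FREQS, e=0.01, panel=["L1", "L2"])
        b = pair_loglik(off, mom, dad, self.FREQS, e=0.01, panel=["L2", "L1"])
        assert a == pytest.approx(b, rel=1e-12)

    def test_monotone_in_error_for_incompatible_trio(self):
        off, mom, dad = self.make_trio()
        vals = [pair_loglik(off, mom, dad, self.FREQS, e=e) for e in (0.001, 0.01, 0.1)]
        assert vals == sorted(vals)


def random_instance(rng, n_off, n_cand, n_alleles=6):
    panel = [Locus("L1", frozenset(range(1, n_alleles + 1))),
             Locus("L2", frozenset(range(11, 11 + n_alleles)))]
    codes = {l.name: np.array(sorted(l.allele_set)) for l in panel}
    freqs = {l.name: {int(a): 1.0 / n_alleles for a in codes[l.name]} for l in panel}

    def draw(sid, role, mother=None):
        alleles = {
            l.name: tuple(sorted(rng.choice(codes[l.name], 2))) for l in panel
        }
        return make_sample(sid, role, alleles, mother=mother)

    mom = draw("mom", Role.RECEPTOR)
    cands = [draw(f"c{i}", Role.DONOR) for i in range(n_cand)]
    offs = []
    for k in range(n_off):
        dad = cands[rng.integers(n_cand)] if (n_cand and rng.random() < 0.7) else draw("x", Role.DONOR)
        child = {
            l.name: tuple(
                sorted(
                    (mom.alleles[l.name][rng.integers(2)], dad.alleles[l.name][rng.integers(2)])
                )
            )
            for l in panel
        }
        offs.append(make_sample(f"o{k}", Role.OFFSPRING, child, mother="mom"))
    return offs, {"mom": mom}, cands, freqs


def exhaustive_map(S):
    """Brute-force MAP over all (n_candidates+1)^n_offspring configurations,
    via an iterative outer sum (vectorised enumeration)."""
    totals = S[0]
    for row in S[1:]:
        totals = (totals[:, None] + row[None, :]).ravel()
    best = int(np.nanargmax(np.where(np.isfinite(totals), totals, -np.inf)))
    k = S.shape[1]
    labels = []
    for _ in range(S.shape[0]):
        labels.append(best % k)
        best //= k
    return np.array(labels[::-1]), float(np.max(totals))


class TestAnnealRun:
    def test_unique_optimum_found(self):
        rng = np.random.default_rng(1)
        offs, moms, cands, freqs = random_instance(rng, 1, 1)
        # force the candidate to be the true father: offspring drawn from him
        cfg = PaternityConfig(error_rate=0.0, seed=0)
        mom, dad = moms["mom"], cands[0]
        child = {
            l: tuple(sorted((mom.alleles[l][0], dad.alleles[l][0])))
            for l in mom.alleles
        }
        off = make_sample("o0", Role.OFFSPRING, child, mother="mom")
        res = anneal_run([off], moms, cands, freqs, cfg, seed=0)
        S = score_matrix([off], moms, cands, freqs, cfg)
        if S[0, 0] > S[0, 1]:
            assert res.assignment["o0"] == "c0"

    def test_no_candidates_all_unassigned(self):
        rng = np.random.default_rng(2)
        offs, moms, _, freqs = random_instance(rng, 4, 1)
        res = anneal_run(offs, moms, [], freqs, PaternityConfig(), seed=0)
        assert set(res.assignment.values()) == {UNASSIGNED}

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        offs, moms, cands, freqs = random_instance(rng, 8, 3)
        cfg = PaternityConfig(error_rate=0.02)
        a = anneal_run(offs, moms, cands, freqs, cfg, seed=42)
        b = anneal_run(offs, moms, cands, freqs, cfg, seed=42)
        assert a.assignment == b.assignment and a.loglik == b.loglik

    def test_matches_exhaustive_oracle_on_small_instances(self):
        """MAP configuration equals vectorised brute-force enumeration."""
        cfg = PaternityConfig(error_rate=0.02, n_sweeps=80)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            offs, moms, cands, freqs = random_instance(
                rng, int(rng.integers(3, 8)), int(rng.integers(1, 5))
            )
            S = score_matrix(offs, moms, cands, freqs, cfg)
            res = anneal_run(offs, moms, cands, freqs, cfg, seed=seed, S=S)
            _, best_val = exhaustive_map(S)
            hits += math.isclose(res.loglik, best_val, rel_tol=0, abs_tol=1e-9)
        assert hits >= 19


class TestConsensus:
    def _runs(self, votes):
        """Build 5 RunResults for a single offspring with the given donors."""
        return [RunResult(i, {"o": v}, 0.0) for i, v in enumerate(votes)]

    def test_two_of_five_accepted(self):
        cfg = PaternityConfig()
        out = consensus(self._runs(["d1", UNASSIGNED, "d1", UNASSIGNED, UNASSIGNED]), cfg)
        assert out.assignment["o"] == "d1" and out.support["o"] == 2

    def test_single_run_not_accepted(self):
        cfg = PaternityConfig()
        out = consensus(self._runs(["d1", UNASSIGNED, UNASSIGNED, UNASSIGNED, UNASSIGNED]), cfg)
        assert out.assignment["o"] == UNASSIGNED

    def test_tie_falls_back_to_unassigned(self):
        cfg = PaternityConfig()
        out = consensus(self._runs(["d1", "d1", "d2", "d2", UNASSIGNED]), cfg)
        assert out.assignment["o"] == UNASSIGNED

    def test_higher_support_wins(self):
        cfg = PaternityConfig()
        out = consensus(self._runs(["d1", "d1", "d1", "d2", "d2"]), cfg)
        assert out.assignment["o"] == "d1" and out.support["o"] == 3

    def test_run_count_checked(self):
        with pytest.raises(ValueError):
            consensus(self._runs(["d1"] * 4), PaternityConfig())


class TestSelfIncompatibility:
    def test_no_accepted_pair_has_mother_mlg(self):
        """With selfing disallowed, the mother's clone (and herself) never
        appears as an accepted donor."""
        from pollenscape.paternity import assign_patch

        rng = np.random.default_rng(9)
        panel = [Locus(f"L{i}", frozenset(range(1, 7))) for i in range(1, 4)]
        codes = np.arange(1, 7)

        def draw(sid, role, alleles=None, mother=None, cluster=None):
            if alleles is None:
                alleles = {
                    l.name: tuple(sorted(rng.choice(codes, 2))) for l in panel
                }
            return make_sample(sid, role, alleles, mother=mother, cluster=cluster)

        mom = draw("mom", Role.RECEPTOR, cluster="c0")
        clone = draw("clone", Role.DONOR, alleles=dict(mom.alleles), cluster="c0")
        others = [draw(f"d{i}", Role.DONOR, cluster=f"c{i+1}") for i in range(3)]
        offs = []
        for k in range(6):
            child = {
                l.name: tuple(
                    sorted((mom.alleles[l.name][rng.integers(2)],
                            mom.alleles[l.name][rng.integers(2)]))
                )
                for l in panel
            }
            offs.append(draw(f"o{k}", Role.OFFSPRING, alleles=child, mother="mom"))
        gs = GenotypeSet(panel, [mom, clone] + others + offs)
        cons = assign_patch(gs, "P1", PaternityConfig(error_rate=0.01, seed=1))
        assert all(d not in ("mom", "clone") for d in cons.assigned().values())
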