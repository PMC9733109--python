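"""Admixture assignment, parentage LOD, and sire-proportion tests."""

import math

import numpy as np
import pytest

from competab import popgen, simulate
from competab.popgen import AlleleFreqPanel, Genotype


def _geno(ind, loci, **kw):
    return Genotype(individual_id=ind, loci=tuple(loci), **kw)


def _panel(pop, per_locus):
    return AlleleFreqPanel(population=pop, freqs=tuple(per_locus))


class TestEstimateFreqs:
    def test_hand_counts_on_toy_founders(self):
        a = [_geno(f"a{i}", [(1, 1)], population="A") for i in range(5)]
        b = [_geno(f"b{i}", [(2, 2)], population="B") for i in range(4)]
        b.append(_geno("b5", [(1, 2)], population="B"))
        panels = popgen.estimate_freqs({"A": a, "B": b}, pseudocount=0.0)
        assert panels["A"].freqs[0] == {1: 1.0, 2: 0.0}
        assert panels["B"].freqs[0][1] == pytest.approx(0.1)
        assert panels["B"].freqs[0][2] == pytest.approx(0.9)

    def test_pseudocount_shrinks_toward_uniform(self):
        a = [_geno(f"a{i}", [(1, 1)], population="A") for i in range(5)]
        b = [_geno(f"b{i}", [(2, 2)], population="B") for i in range(5)]
        raw = popgen.estimate_freqs({"A": a, "B": b}, pseudocount=0.0)
        smooth = popgen.estimate_freqs({"A": a, "B": b}, pseudocount=2.0)
        assert raw["A"].freqs[0][1] == 1.0
        assert 0.5 < smooth["A"].freqs[0][1] < 1.0
        assert sum(smooth["A"].freqs[0].values()) == pytest.approx(1.0)

    def test_missing_locus_warns_and_uses_uniform(self):
        a = [_geno(f"a{i}", [None], population="A") for i in range(5)]
        b = [_geno(f"b{i}", [(1, 2)], population="B") for i in range(5)]
        with pytest.warns(UserWarning, match="entirely missing"):
            panels = popgen.estimate_freqs({"A": a, "B": b})
        assert panels["A"].freqs[0] == {1: 0.5, 2: 0.5}


class TestAssignOrigin:
    def _divergent_panels(self):
        pa = _panel("A", [{1: 0.9, 2: 0.1}] * 13)
        pb = _panel("B", [{1: 0.1, 2: 0.9}] * 13)
        return pa, pb

    def test_label_symmetry(self):
        pa, pb = self._divergent_panels()
        g = _geno("x", [(1, 2)] * 13)
        q_ab = popgen.assign_origin(g, pa, pb).q_hat
        q_ba = popgen.assign_origin(g, pb, pa).q_hat
        assert q_ab + q_ba == pytest.approx(1.0, abs=1e-3)

    def test_pure_and_f1_archetypes(self):
        pa, pb = self._divergent_panels()
        pure = popgen.assign_origin(_geno("p", [(1, 1)] * 13), pa, pb)
        assert pure.origin_class == "pure_A" and pure.q_hat >= 0.9
        f1 = popgen.assign_origin(_geno("h", [(1, 2)] * 13), pa, pb)
        assert f1.origin_class == "mixed"
        assert abs(f1.q_hat - 0.5) < 0.05

    def test_identical_panels_flagged_uninformative(self):
        pa = _panel("A", [{1: 0.5, 2: 0.5}] * 13)
        pb = _panel("B", [{1: 0.5, 2: 0.5}] * 13)
        res = popgen.assign_origin(_geno("x", [(1, 2)] * 13), pa, pb)
        assert res.uninformative and res.q_hat == 0.5 and res.origin_class == "mixed"

    def test_too_few_typed_loci_unassigned(self):
        pa, pb = self._divergent_panels()
        g = _geno("x", [(1, 1)] * 3 + [None] * 10)
        assert popgen.assign_origin(g, pa, pb).origin_class == "unassigned"

    def test_accuracy_improves_with_divergence(self):
        hits = []
        for fst in (0.02, 0.3):
            cfg = simulate.PedigreeSimConfig(
                fst=fst, founders_per_population=20, n_pure_matings=10,
                n_mixed_matings=0, offspring_per_mating=2, genotyping_error=0.0,
                missing_rate=0.0, seed=17,
            )
            records, manifest, truth = simulate.gen_pedigree(cfg)
            genos = popgen.genotypes_from_records(records, manifest)
            founders = {
                p: [g for g in genos if g.population == p] for p in ("CB", "MC")
            }
            panels = popgen.estimate_freqs(founders)
            ok = n = 0
            for g in genos:
                if g.cohort != "final":
                    continue
                want = truth["offspring"][g.individual_id]["class"]
                got = popgen.assign_origin(g, panels["CB"], panels["MC"]).origin_class
                n += 1
                ok += got == {"pure_A": "pure_A", "pure_B": "pure_B"}[want]
            hits.append(ok / n)
        assert hits[1] >= hits[0]


class TestParentLOD:
    BG = {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}

    def test_clone_has_maximal_lod(self):
        bg = _panel("pooled", [self.BG] * 13)
        off = _geno("o", [(1, 2)] * 13)
        clone = _geno("c", [(1, 2)] * 13)
        other = _geno("u", [(3, 4)] * 13)
        assert popgen.parent_lod(off, clone, bg) > popgen.parent_lod(off, other, bg)

    def test_zero_error_mendelian_exclusion_is_minus_infinity(self):
        bg = _panel("pooled", [self.BG] * 2)
        off = _geno("o", [(1, 1), (1, 1)])
        cand = _geno("c", [(2, 2), (1, 1)])  # first locus impossible
        assert popgen.parent_lod(off, cand, bg, error_rate=0.0) == -math.inf

    def test_excluded_never_outranks_unexcluded_at_zero_error(self):
        bg = _panel("pooled", [self.BG] * 13)
        off = _geno("o", [(1, 2)] * 13)
        compatible = _geno("c", [(2, 3)] * 13)
        excluded = _geno("e", [(3, 4)] + [(1, 2)] * 12)
        assert popgen.parent_lod(off, compatible, bg, 0.0) > popgen.parent_lod(
            off, excluded, bg, 0.0
        )

    def test_missing_loci_skipped(self):
        bg = _panel("pooled", [self.BG] * 2)
        off = _geno("o", [(1, 2), None])
        cand = _geno("c", [(1, 3), (4, 4)])
        two = popgen.parent_lod(off, cand, bg)
        one = popgen.parent_lod(_geno("o", [(1, 2)]), _geno("c", [(1, 3)]),
                                _panel("pooled", [self.BG]))
        assert two == pytest.approx(one)

    def test_true_parent_beats_unrelated_on_simulated_trios(self):
        cfg = simulate.PedigreeSimConfig(
            founders_per_population=25, n_pure_matings=0, n_mixed_matings=12,
            offspring_per_mating=2, genotyping_error=0.0, missing_rate=0.0, seed=23,
        )
        records, manifest, truth = simulate.gen_pedigree(cfg)
        genos = {g.individual_id: g for g in
                 popgen.genotypes_from_records(records, manifest)}
        bg = popgen.pooled_freqs([g for g in genos.values() if g.cohort == "founder"])
        rng = np.random.default_rng(1)
        wins = n = 0
        for ind, t in truth["offspring"].items():
            off = genos[ind]
            father = genos[t["father"]]
            unrelated_pool = [
                g for g in genos.values()
                if g.cohort == "founder" and g.sex == "M"
                and g.individual_id != t["father"]
            ]
            unrelated = unrelated_pool[int(rng.integers(len(unrelated_pool)))]
            n += 1
            wins += popgen.parent_lod(off, father, bg) > popgen.parent_lod(
                off, unrelated, bg
            )
        assert wins / n >= 0.95


class TestConsensusRule:
    def _setup(self):
        bg = _panel("pooled", [{1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}] * 13)
        off = _geno("o", [(1, 2)] * 13)
        return bg, off

    def test_top2_same_population_accepted(self):
        bg, off = self._setup()
        cands = [
            _geno("m1", [(1, 3)] * 13, sex="M", population="CB"),
            _geno("m2", [(2, 3)] * 13, sex="M", population="CB"),
            _geno("m3", [(3, 4)] * 13, sex="M", population="MC"),
        ]
        res = popgen.assign_parent_population(off, cands, bg)
        assert res.consensus["M"] == "CB"

    def test_top2_split_is_undetermined(self):
        bg, off = self._setup()
        cands = [
            _geno("m1", [(1, 3)] * 13, sex="M", population="CB"),
            _geno("m2", [(2, 3)] * 13, sex="M", population="MC"),
            _geno("m3", [(3, 4)] * 13, sex="M", population="CB"),
        ]
        res = popgen.assign_parent_population(off, cands, bg)
        assert res.consensus["M"] == "undetermined"

    def test_fewer_than_two_candidates_undetermined(self):
        bg, off = self._setup()
        cands = [_geno("m1", [(1, 3)] * 13, sex="M", population="CB")]
        res = popgen.assign_parent_population(off, cands, bg)
        assert res.consensus["M"] == "undetermined"
        assert res.consensus["F"] == "undetermined"

    def test_deterministic_tie_break_by_id(self):
        bg, off = self._setup()
        twin_a = _geno("a_twin", [(1, 3)] * 13, sex="M", population="CB")
        twin_b = _geno("b_twin", [(1, 3)] * 13, sex="M", population="CB")
        res = popgen.assign_parent_population(off, [twin_b, twin_a], bg)
        assert [c[0] for c in res.candidates["M"]] == ["a_twin", "b_twin"]


class TestSireProportions:
    def test_published_room_counts(self):
        tests = popgen.sire_population_test({"113": (11, 5), "114": (33, 3)})
        assert tests["pooled"]["binom_exact"].extra["n"] == 52
        assert tests["pooled"]["prop_cc"].p_value < 0.001
        assert tests["114"]["prop_cc"].p_value < 0.001
        assert tests["113"]["prop_mirrored"].p_value == pytest.approx(0.077, abs=5e-4)

    def test_even_split_is_null(self):
        tests = popgen.sire_population_test({"r": (10, 10)})
        assert tests["r"]["prop_cc"].p_value == 1.0

    def test_zero_offspring_skipped(self):
        assert popgen.sire_population_test({"r": (0, 0)})["r"] is None
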