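import itertools
import math

import numpy as np
import pytest

from mlof.bayes import PosteriorRecord, PriorRecord, posterior
from mlof.phenotypes import (
    Ontology,
    PairReport,
    PhenotypeRecord,
    classify_inheritance,
    classify_mechanism,
    hybrid_gene_fraction,
    lin_similarity,
    mechanism_composition,
    phenotype_similarity,
    prioritise_dn_pairs,
    rank_divergent_pairs,
)
from mlof.synthetic import make_hybrid_cohort, make_toy_ontology, write_obo
from mlof.variants import Variant, VariantSet

import networkx as nx


def _vs(gene, positions):
    return VariantSet(gene, [Variant(p, "G", "R") for p in positions])


def _rec(pid, gene, hpo, omim, positions=(1, 2, 3), **kw):
    return PhenotypeRecord(
        phenotype_id=pid,
        gene=gene,
        hpo_inheritance=frozenset(hpo),
        gene_omim_inheritance=frozenset(omim),
        variant_set=_vs(gene, positions),
        **kw,
    )


class TestClassifyInheritance:
    def test_exclusively_ad_gene(self):
        r = _rec("P1", "G1", {"AD"}, {"AD"})
        assert classify_inheritance(r, [r]) == "AD"

    def test_exclusively_ar_gene(self):
        r = _rec("P1", "G1", {"AR"}, {"AR"})
        assert classify_inheritance(r, [r]) == "AR"

    def test_both_modes_on_same_phenotype(self):
        r = _rec("P1", "G1", {"AD", "AR"}, {"AD", "AR"})
        assert classify_inheritance(r, [r]) == "AD_AR_same"

    def test_mixed_gene_splits_ar_and_ad_phenotypes(self):
        ar = _rec("P1", "G1", {"AR"}, {"AD", "AR"}, positions=(1, 2, 3))
        ad = _rec("P2", "G1", {"AD"}, {"AD", "AR"}, positions=(4, 5, 6))
        ctx = [ar, ad]
        assert classify_inheritance(ar, ctx) == "AR_of_mixed"
        assert classify_inheritance(ad, ctx) == "AD_of_mixed"

    def test_mixed_requires_sufficient_variants(self):
        ar = _rec("P1", "G1", {"AR"}, {"AR"}, positions=(1, 2, 3))
        ad = _rec("P2", "G1", {"AD"}, {"AR"}, positions=(4,))  # < 3 positions
        assert classify_inheritance(ar, [ar, ad]) == "AR"

    def test_x_linked_takes_precedence(self):
        r = _rec("P1", "G1", {"AD", "AR"}, {"XL"})
        assert classify_inheritance(r, [r]) == "XLR"

    def test_unclassifiable_returns_none(self):
        r = _rec("P1", "G1", set(), {"AD"})
        assert classify_inheritance(r, [r]) is None

    def test_order_invariance(self):
        recs = [
            _rec("P1", "G1", {"AR"}, {"AD", "AR"}),
            _rec("P2", "G1", {"AD"}, {"AD", "AR"}, positions=(7, 8, 9)),
            _rec("P3", "G1", {"AD"}, {"AD", "AR"}, positions=(2,)),
        ]
        for perm in itertools.permutations(recs):
            assert classify_inheritance(recs[0], list(perm)) == "AR_of_mixed"


class TestClassifyMechanism:
    def test_dosage_sufficiency_gives_lof(self):
        r = _rec("P1", "G1", {"AD"}, {"AD"}, dosage_sufficient=True)
        assert classify_mechanism(r, [r]) == "LOF"

    def test_reported_lof_label(self):
        r = _rec("P1", "G1", {"AD"}, {"AD"}, mechanism_label="LOF")
        assert classify_mechanism(r, [r]) == "LOF"

    def test_unlabelled_ad_gene_is_unknown(self):
        r = _rec("P1", "G1", {"AD"}, {"AD"})
        assert classify_mechanism(r, [r]) == "Unknown"

    def test_gof_excluded_in_mixed_gene(self):
        gof = _rec("P1", "G1", {"AD"}, {"AD", "AR"}, mechanism_label="GOF")
        ar = _rec("P2", "G1", {"AR"}, {"AD", "AR"}, positions=(5, 6, 7))
        assert classify_mechanism(gof, [gof, ar]) is None

    def test_gof_and_dn_in_pure_ad_gene(self):
        gof = _rec("P1", "G1", {"AD"}, {"AD"}, mechanism_label="GOF")
        dn = _rec("P2", "G2", {"AD"}, {"AD"}, mechanism_label="DN")
        assert classify_mechanism(gof, [gof]) == "GOF"
        assert classify_mechanism(dn, [dn]) == "DN"

    def test_non_ad_phenotype_not_classified(self):
        r = _rec("P1", "G1", {"AR"}, {"AR"}, mechanism_label="LOF")
        assert classify_mechanism(r, [r]) is None


def _post(dn, gof, lof):
    return PosteriorRecord(post_dn=dn, post_gof=gof, post_lof=lof)


class TestMechanismComposition:
    def test_argmax_counting(self):
        recs = [
            _rec("P1", "G1", {"AD"}, {"AD"}, mlof=0.7, posteriors=_post(0.2, 0.1, 0.9)),
            _rec("P2", "G2", {"AD"}, {"AD"}, mlof=0.6, posteriors=_post(0.1, 0.2, 0.8)),
            _rec("P3", "G3", {"AD"}, {"AD"}, mlof=0.3, posteriors=_post(0.3, 0.8, 0.2)),
        ]
        out = mechanism_composition(recs)
        assert out["LOF"]["fraction"] == pytest.approx(2 / 3)
        assert out["GOF"]["fraction"] == pytest.approx(1 / 3)
        assert out["DN"]["fraction"] == 0.0
        assert sum(v["fraction"] for v in out.values()) == pytest.approx(1.0)

    def test_identical_bootstrap_thresholds_zero_width(self):
        recs = [
            _rec("P1", "G1", {"AD"}, {"AD"}, mlof=0.7, posteriors=_post(0.2, 0.1, 0.9)),
            _rec("P2", "G2", {"AD"}, {"AD"}, mlof=0.3, posteriors=_post(0.8, 0.2, 0.2)),
        ]
        out = mechanism_composition(recs, threshold_boot=[0.5] * 100)
        for mech in out.values():
            assert mech["ci_low"] == mech["ci_high"]

    def test_recovers_planted_fractions(self):
        rng = np.random.default_rng(33)
        recs = []
        planted = {"LOF": 0.6, "DN": 0.25, "GOF": 0.15}
        n = 400
        labels = rng.choice(list(planted), p=list(planted.values()), size=n)
        for i, lab in enumerate(labels):
            if lab == "LOF":
                post = _post(0.2, 0.1, float(rng.uniform(0.6, 0.95)))
            elif lab == "DN":
                post = _post(float(rng.uniform(0.6, 0.95)), 0.2, 0.1)
            else:
                post = _post(0.2, float(rng.uniform(0.6, 0.95)), 0.1)
            recs.append(_rec(f"P{i}", f"G{i}", {"AD"}, {"AD"}, mlof=0.5, posteriors=post))
        out = mechanism_composition(recs)
        for mech, frac in planted.items():
            se = math.sqrt(frac * (1 - frac) / n)
            assert out[mech]["fraction"] == pytest.approx(frac, abs=4 * se)


class TestHybridGeneFraction:
    def test_straddling_gene_is_hybrid(self):
        recs = [
            _rec("P1", "G1", {"AD"}, {"AD"}, mlof=0.6),
            _rec("P2", "G1", {"AD"}, {"AD"}, mlof=0.4),
            _rec("P3", "G2", {"AD"}, {"AD"}, mlof=0.6),
            _rec("P4", "G2", {"AD"}, {"AD"}, mlof=0.7),
        ]
        out = hybrid_gene_fraction(recs, threshold=0.508)
        assert out["fraction"] == pytest.approx(0.5)
        assert out["n_genes"] == 2

    def test_planted_hybrid_status_recovered_exactly(self):
        records, truth = make_hybrid_cohort(80, 0.45, threshold=0.508, seed=9)
        out = hybrid_gene_fraction(records, threshold=0.508)
        expected = sum(truth.values()) / len(truth)
        assert out["fraction"] == pytest.approx(expected)

    def test_bootstrap_interval_contains_point(self):
        records, _ = make_hybrid_cohort(60, 0.4, threshold=0.508, seed=2)
        boot = list(np.random.default_rng(0).normal(0.508, 0.02, 200))
        out = hybrid_gene_fraction(records, 0.508, threshold_boot=boot)
        assert out["ci_low"] <= out["fraction"] <= out["ci_high"]


class TestRankDivergentPairs:
    def _scored(self, gene, pid, mlof, positions, hpo={"AD"}):
        return _rec(pid, gene, hpo, {"AD"}, positions=positions, mlof=mlof)

    def test_straddling_pair_flagged(self):
        recs = [
            self._scored("SMC1", "A", 0.656, (1, 2, 3)),
            self._scored("SMC1", "B", 0.274, (10, 11, 12)),
        ]
        pairs = rank_divergent_pairs(recs, threshold=0.508)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.delta == pytest.approx(0.382)
        assert "straddles_threshold" in p.flags

    def test_identical_and_subset_sets_excluded(self):
        recs = [
            self._scored("G1", "A", 0.7, (1, 2, 3)),
            self._scored("G1", "B", 0.3, (1, 2, 3)),
            self._scored("G2", "C", 0.7, (1, 2, 3)),
            self._scored("G2", "D", 0.3, (1, 2, 3, 4)),
        ]
        assert rank_divergent_pairs(recs, 0.508) == []

    def test_recessive_only_genes_excluded(self):
        recs = [
            self._scored("G1", "A", 0.7, (1, 2, 3), hpo={"AR"}),
            self._scored("G1", "B", 0.3, (4, 5, 6), hpo={"AR"}),
        ]
        assert rank_divergent_pairs(recs, 0.508) == []

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(55)
        recs = []
        for g in range(12):
            for p in range(int(rng.integers(2, 5))):
                start = int(rng.integers(1, 50))
                recs.append(
                    self._scored(
                        f"G{g}", f"G{g}.P{p}", float(rng.uniform(0, 1)),
                        tuple(range(start, start + 4)),
                    )
                )
        pairs = rank_divergent_pairs(recs, threshold=0.508)
        # oracle: every within-gene combination, distinct/intersect only
        from mlof.evaluation import set_relationship

        by_gene = {}
        for r in recs:
            by_gene.setdefault(r.gene, []).append(r)
        expected = set()
        deltas = []
        for g, rs in by_gene.items():
            for a, b in itertools.combinations(sorted(rs, key=lambda r: r.phenotype_id), 2):
                if set_relationship(a.variant_set, b.variant_set) in ("distinct", "intersect"):
                    expected.add((g, a.phenotype_id, b.phenotype_id))
                    deltas.append(abs(a.mlof - b.mlof))
        assert {(p.gene, p.phenotype_a, p.phenotype_b) for p in pairs} == expected
        cut = np.percentile(deltas, 95)
        for p in pairs:
            straddle = min(p.mlof_a, p.mlof_b) < 0.508 <= max(p.mlof_a, p.mlof_b)
            assert ("divergent" in p.flags) == (p.delta > cut and straddle)
        assert [p.delta for p in pairs] == sorted((p.delta for p in pairs), reverse=True)


def _toy_dag():
    """Seven-term DAG and six-phenotype corpus with hand-enumerated ICs.

    root R; A, B below R; C, D below A; E, F below B.
    Corpus: P1 {C}, P2 {C,D}, P3 {D}, P4 {E}, P5 {F}, P6 {C,F}.
    Term or descendant frequencies: R 6/6, A 4/6, B 3/6,
    C 3/6, D 2/6, E 1/6, F 2/6.
    """
    g = nx.DiGraph()
    for child, parent in [("A", "R"), ("B", "R"), ("C", "A"), ("D", "A"), ("E", "B"), ("F", "B")]:
        g.add_edge(child, parent)
    ann = {
        "P1": {"C"}, "P2": {"C", "D"}, "P3": {"D"},
        "P4": {"E"}, "P5": {"F"}, "P6": {"C", "F"},
    }
    return Ontology(g, ann)


class TestLinSimilarity:
    def test_hand_enumerated_ic_values(self):
        ont = _toy_dag()
        assert ont.ic["R"] == pytest.approx(0.0)
        assert ont.ic["A"] == pytest.approx(-math.log(4 / 6))
        assert ont.ic["B"] == pytest.approx(-math.log(3 / 6))
        assert ont.ic["C"] == pytest.approx(-math.log(3 / 6))
        assert ont.ic["D"] == pytest.approx(-math.log(2 / 6))
        assert ont.ic["E"] == pytest.approx(-math.log(1 / 6))
        assert ont.ic["F"] == pytest.approx(-math.log(2 / 6))

    def test_self_similarity_is_one(self):
        ont = _toy_dag()
        for t in "ABCDEF":
            assert lin_similarity(t, t, ont) == pytest.approx(1.0)

    def test_root_only_common_ancestor_gives_zero(self):
        ont = _toy_dag()
        assert lin_similarity("C", "E", ont) == 0.0

    def test_hand_computed_pairwise_scores(self):
        ont = _toy_dag()
        ic = lambda t: ont.ic[t]
        assert lin_similarity("C", "D", ont) == pytest.approx(
            2 * ic("A") / (ic("C") + ic("D"))
        )
        assert lin_similarity("E", "F", ont) == pytest.approx(
            2 * ic("B") / (ic("E") + ic("F"))
        )

    def test_symmetry_and_range(self):
        ont = _toy_dag()
        for a in "CDEF":
            for b in "CDEF":
                s = lin_similarity(a, b, ont)
                assert 0.0 <= s <= 1.0
                assert s == pytest.approx(lin_similarity(b, a, ont))

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            lin_similarity("C", "ZZ", _toy_dag())


class TestPhenotypeSimilarity:
    def test_identical_sets(self):
        assert phenotype_similarity({"C", "D"}, {"C", "D"}, _toy_dag()) == pytest.approx(1.0)

    def test_disjoint_branches_zero(self):
        assert phenotype_similarity({"C"}, {"E"}, _toy_dag()) == 0.0

    def test_hand_computed_best_match_average(self):
        ont = _toy_dag()
        s_cd = lin_similarity("C", "D", ont)
        # {C,D} vs {D,F}: forward best matches (C->D: s_cd, D->D: 1),
        # reverse (D->max(s_cd,1)=1, F->0)
        expected = ((s_cd + 1) / 2 + (1 + 0) / 2) / 2
        assert phenotype_similarity({"C", "D"}, {"D", "F"}, ont) == pytest.approx(expected)


class TestOntologyConstruction:
    def test_toy_ontology_ic_monotone_from_parent_to_child(self):
        ont, g, _ = make_toy_ontology(depth=4, branching=2, n_phenotypes=12, seed=3)
        assert ont.ic.get("T:0001", 0.0) == pytest.approx(0.0)
        for child, parent in g.edges:
            if child in ont.ic and parent in ont.ic:
                assert ont.ic[child] >= ont.ic[parent] - 1e-12

    def test_obo_roundtrip(self, tmp_path):
        ont, g, ann = make_toy_ontology(depth=3, branching=3, n_phenotypes=8, seed=5)
        path = tmp_path / "toy.obo"
        write_obo(g, path)
        back = Ontology.from_obo(path, ann)
        assert set(back.graph.nodes) == set(g.nodes)
        assert set(back.graph.edges) == set(g.edges)
        assert back.ic == pytest.approx(ont.ic)

    def test_same_seed_identical(self):
        a = make_toy_ontology(3, 2, 6, seed=7)
        b = make_toy_ontology(3, 2, 6, seed=7)
        assert set(a[1].edges) == set(b[1].edges)
        assert a[2] == b[2]


class TestPrioritiseDnPairs:
    def _pair(self, gene, mlof_ad, mlof_ar, sim):
        return PairReport(gene, f"{gene}-AD", f"{gene}-AR", mlof_ad, mlof_ar, "distinct", sim)

    def test_high_confidence_nonlof_rule(self):
        # dominant scores below threshold and below the recessive phenotype
        pairs = [self._pair("CLCN7L", 0.455, 0.549, 0.57)]
        priors = {"CLCN7L": PriorRecord("CLCN7L", 0.6, 0.2, 0.5)}
        out = prioritise_dn_pairs(pairs, 0.508, priors)
        assert len(out) == 1
        assert "high_confidence_nonlof" in out[0].flags

    def test_dn_prior_must_exceed_gof_prior(self):
        pairs = [self._pair("G1", 0.3, 0.6, 0.8)]
        priors = {"G1": PriorRecord("G1", 0.3, 0.4, 0.5)}
        assert prioritise_dn_pairs(pairs, 0.508, priors) == []

    def test_brute_force_filter_oracle(self):
        rng = np.random.default_rng(91)
        pairs, priors = [], {}
        for g in range(30):
            gene = f"G{g}"
            priors[gene] = PriorRecord(
                gene, float(rng.uniform(0, 1)), float(rng.uniform(0, 1)), 0.5
            )
            for j in range(int(rng.integers(1, 4))):
                p = self._pair(gene, float(rng.uniform(0, 1)), float(rng.uniform(0, 1)),
                               float(rng.uniform(0, 1)))
                p.phenotype_a += f".{j}"
                pairs.append(p)
        out = prioritise_dn_pairs(pairs, 0.508, priors, similarity_min=0.5)
        # oracle: apply the three rules directly
        best = {}
        for p in pairs:
            if not (p.mlof_a < 0.508 and p.mlof_a < p.mlof_b):
                continue
            pr = priors[p.gene]
            if not pr.p_dn > pr.p_gof:
                continue
            if p.gene not in best or p.similarity > best[p.gene].similarity:
                best[p.gene] = p
        expected = sorted(
            (p for p in best.values() if p.similarity > 0.5),
            key=lambda p: (-p.similarity, p.gene),
        )
        assert [(p.gene, p.similarity) for p in out] == [(p.gene, p.similarity) for p in expected]
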