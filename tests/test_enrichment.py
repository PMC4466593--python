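"""Fisher overrepresentation, fold enrichment and the three analyses."""

import math

import numpy as np
import pytest

from mirlink.diffexpr import FilterSpec
from mirlink.enrichment import (
    GeneSet,
    GeneSetCollection,
    fisher_overrep,
    hypergeom_tail_p,
    mirna_bindingsite_enrichment,
    mirna_pathway_enrichment,
    pathway_enrichment,
)
from mirlink.pipeline import run_de
from mirlink.targets import consensus_filter, targets_of

import oracles


def ids(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestFisherOverrep:
    def test_fold_enrichment_arithmetic(self):
        universe = set(ids("g", 20))
        geneset = set(ids("g", 5))           # K = 5
        query = set(ids("g", 4)) | {"g10", "g11", "g12", "g13"}  # n=8, k=4
        res = fisher_overrep(query, geneset, universe)
        assert (res.k, res.n, res.K, res.N) == (4, 8, 5, 20)
        assert res.fold_enrichment == pytest.approx(2.0)

    def test_p_equals_hypergeometric_tail_sum(self):
        universe = set(ids("g", 20))
        geneset = set(ids("g", 5))
        query = set(ids("g", 4)) | {"g10", "g11", "g12", "g13"}
        res = fisher_overrep(query, geneset, universe)
        expected = sum(
            math.comb(5, j) * math.comb(15, 8 - j) for j in (4, 5)
        ) / math.comb(20, 8)
        assert res.p_raw == pytest.approx(expected, rel=1e-12)

    def test_query_equal_to_universe_saturates(self):
        universe = set(ids("g", 12))
        geneset = set(ids("g", 4))
        res = fisher_overrep(universe, geneset, universe)
        assert res.k == res.K == 4
        assert res.p_raw == pytest.approx(1.0)
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_empty_query_yields_null_result_not_error(self):
        universe = set(ids("g", 10))
        res = fisher_overrep({"not_in_universe"}, set(ids("g", 3)), universe)
        assert (res.k, res.n) == (0, 0)
        assert res.p_raw == 1.0
        assert math.isnan(res.fold_enrichment)

    def test_monotone_nonincreasing_in_k(self):
        ps = [hypergeom_tail_p(k, 100, 30, 20) for k in range(0, 21)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_fold_direction_agrees_with_overrepresentation(self):
        rng = np.random.default_rng(0)
        universe = set(ids("g", 50))
        for _ in range(20):
            q = set(rng.choice(sorted(universe), 12, replace=False))
            s = set(rng.choice(sorted(universe), 10, replace=False))
            res = fisher_overrep(q, s, universe)
            if not math.isnan(res.fold_enrichment) and res.fold_enrichment != 1:
                assert (res.fold_enrichment > 1) == (
                    res.k / res.n > res.K / res.N
                )

    @pytest.mark.parametrize("seed", range(3))
    def test_tail_p_matches_exact_oracle_randomized(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            exact = oracles.hypergeom_tail_exact(k, N, K, n)
            assert hypergeom_tail_p(k, N, K, n) == pytest.approx(
                exact, rel=1e-9, abs=1e-300
            )


def collection_of(sets_dict, universe):
    return GeneSetCollection(
        sets={
            name: GeneSet(name=name, description="", members=frozenset(m))
            for name, m in sets_dict.items()
        },
        universe=frozenset(universe),
    )


class TestPathwayEnrichment:
    def test_single_set_family_keeps_raw_p(self):
        universe = ids("g", 30)
        coll = collection_of({"only": universe[:6]}, universe)
        res = pathway_enrichment(set(universe[:5]), coll)
        assert len(res) == 1
        assert res[0].p_adj == pytest.approx(res[0].p_raw)
        assert res[0].family_size == 1

    def test_disjoint_query_finds_nothing(self):
        universe = ids("g", 30)
        coll = collection_of(
            {"a": universe[:5], "b": universe[5:10]}, universe
        )
        res = pathway_enrichment(set(universe[20:25]), coll)
        assert all(r.k == 0 and not r.significant for r in res)

    def test_planted_set_ranks_first(self, small_bundle):
        det = FilterSpec(kind="gene", p_threshold=0.05, use_adjusted=False)
        de = run_de(small_bundle.genes, det)
        query = de.up_features | de.down_features
        res = pathway_enrichment(query, small_bundle.pathways)
        # the generator oversamples expected-DE genes into every pathway,
        # so the most DE-loaded set must lead the ranking with a tiny p
        assert res[0].p_raw < 0.05
        overlap_rate = res[0].k / res[0].K
        assert overlap_rate > res[-1].k / max(res[-1].K, 1)

    def test_empty_collection_yields_empty_list(self):
        coll = collection_of({}, ids("g", 10))
        assert pathway_enrichment({"g1"}, coll) == []


class TestBindingSiteEnrichment:
    def test_perfectly_concentrated_mirna_has_minimal_p(self, noiseless_bundle):
        t = consensus_filter(noiseless_bundle.interactions, 2)
        universe = set(noiseless_bundle.pathways.universe)
        mirna, regulon = next(iter(noiseless_bundle.truth.regulons.items()))
        res = mirna_bindingsite_enrichment(set(regulon), t, universe)
        assert res[0].name == mirna
        assert res[0].k == len(regulon)

    def test_single_mirna_equals_direct_fisher_call(self, noiseless_bundle):
        t = consensus_filter(noiseless_bundle.interactions, 2)
        universe = set(noiseless_bundle.pathways.universe)
        mirna, regulon = next(iter(noiseless_bundle.truth.regulons.items()))
        de_genes = set(list(regulon)[:5]) | set(list(universe)[:10])
        family = mirna_bindingsite_enrichment(de_genes, t, universe)
        single = {r.name: r for r in family}[mirna]
        direct = fisher_overrep(de_genes, targets_of(t, {mirna}), universe)
        assert single.p_raw == pytest.approx(direct.p_raw, rel=1e-12)
        assert (single.k, single.n, single.K) == (direct.k, direct.n, direct.K)

    def test_mirnas_without_in_universe_targets_are_skipped(self, caplog):
        import pandas as pd

        from mirlink.targets import InteractionTable

        frame = pd.DataFrame(
            [{"mirna": "m1", "gene": "g1", "s1": 1, "s2": 1, "support": 2},
             {"mirna": "m2", "gene": "outside", "s1": 1, "s2": 1, "support": 2}]
        )
        t = consensus_filter(
            InteractionTable(frame=frame, source_names=("s1", "s2")), 2
        )
        with caplog.at_level("INFO", logger="mirlink.enrichment"):
            res = mirna_bindingsite_enrichment({"g1"}, t, {"g1", "g2"})
        assert [r.name for r in res] == ["m1"]
        assert "skipped" in caplog.text


class TestMirnaPathwayEnrichment:
    def test_empty_mirna_list_finds_nothing(self, noiseless_bundle):
        t = consensus_filter(noiseless_bundle.interactions, 2)
        res, n_query = mirna_pathway_enrichment(
            set(), t, noiseless_bundle.pathways
        )
        assert n_query == 0
        assert all(not r.significant for r in res)

    def test_regulon_matching_pathway_saturates(self, noiseless_bundle):
        t = consensus_filter(noiseless_bundle.interactions, 2)
        mirna, regulon = next(iter(noiseless_bundle.truth.regulons.items()))
        coll = collection_of(
            {"regulon_pw": set(regulon)}, noiseless_bundle.pathways.universe
        )
        res, n_query = mirna_pathway_enrichment({mirna}, t, coll)
        assert n_query == len(regulon)
        assert res[0].k == res[0].K == len(regulon)
        assert res[0].significant

    def test_duplicate_mirna_ids_do_not_change_output(self, noiseless_bundle):
        t = consensus_filter(noiseless_bundle.interactions, 2)
        mirnas = list(noiseless_bundle.truth.regulons)[:2]
        a, _ = mirna_pathway_enrichment(set(mirnas), t,
                                        noiseless_bundle.pathways)
        b, _ = mirna_pathway_enrichment(list(mirnas) + list(mirnas), t,
                                        noiseless_bundle.pathways)
        assert [(r.name, r.p_raw) for r in a] == [(r.name, r.p_raw) for r in b]
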