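from __future__ import annotations

import math

import pytest

from oracles import hypergeom_tail_comb, hypergeom_tail_draws

from netpharm.enrichment import (
    enrich,
    filter_significant,
    hypergeom_tail,
    partition_modules,
)
from netpharm.model import (
    AnnotationCollection,
    AnnotationTerm,
    EnrichmentResult,
    ValidationError,
)


def _ann(*specs):
    return AnnotationCollection(
        AnnotationTerm(term_id=tid, name=name, members=frozenset(members))
        for tid, name, members in specs
    )


class TestHypergeomTail:
    def test_matches_draw_enumeration_at_small_scale(self):
        N, K, n = 20, 5, 5
        for k in range(0, min(n, K) + 1):
            assert hypergeom_tail(N, K, n, k) == pytest.approx(
                hypergeom_tail_draws(N, K, n, k), abs=1e-12
            )

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeom_tail(100, 20, 15, k) for k in range(0, 16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_ease_variant_shifts_the_tail(self):
        assert hypergeom_tail(50, 10, 10, 4, ease=True) == pytest.approx(
            hypergeom_tail(50, 10, 10, 3), abs=1e-12
        )
        assert hypergeom_tail(50, 10, 10, 1, ease=True) == pytest.approx(1.0)


class TestEnrich:
    def test_list_equal_to_universe_gives_unit_fold(self):
        universe = [f"G{i}" for i in range(30)]
        ann = _ann(("T1", "a", universe[:7]), ("T2", "b", universe[5:20]))
        results = enrich(universe, ann, universe)
        assert all(r.fold_enrichment == pytest.approx(1.0) for r in results)
        assert all(r.p_raw == pytest.approx(1.0) for r in results)

    def test_fold_enrichment_closed_form(self):
        universe = [f"G{i:03d}" for i in range(100)]
        gene_list = universe[:10]
        # term: 4 members in the list, 1 outside -> k=4, n=10, K=5, N=100
        ann = _ann(("T1", "term", gene_list[:4] + [universe[50]]))
        (res,) = enrich(gene_list, ann, universe)
        assert res.fold_enrichment == pytest.approx(8.0)
        assert (res.k, res.n, res.K, res.N) == (4, 10, 5, 100)

    def test_members_outside_universe_are_dropped(self):
        universe = [f"G{i}" for i in range(20)]
        ann = _ann(("T1", "a", universe[:5] + ["ALIEN"]))
        (res,) = enrich(universe[:10], ann, universe)
        assert res.K == 5

    def test_results_sorted_by_p_then_fold(self):
        universe = [f"G{i}" for i in range(50)]
        gene_list = universe[:10]
        ann = _ann(
            ("T1", "weak", gene_list[:2] + universe[20:28]),
            ("T2", "strong", gene_list[:6] + universe[30:34]),
        )
        results = enrich(gene_list, ann, universe)
        assert [r.term_id for r in results] == ["T2", "T1"]

    def test_bh_q_monotone_and_at_least_p(self):
        universe = [f"G{i}" for i in range(60)]
        gene_list = universe[:12]
        ann = _ann(
            *[
                (f"T{j}", f"t{j}", universe[j : j + 10])
                for j in range(0, 40, 4)
            ]
        )
        results = enrich(gene_list, ann, universe)
        qs = [r.q_bh for r in results]  # results already sorted by p
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q_bh >= r.p_raw - 1e-12 for r in results)

    def test_fold_invariant_under_universe_replication(self):
        universe = [f"G{i}" for i in range(25)]
        gene_list = universe[:5]
        members = universe[:3] + universe[10:14]
        ann = _ann(("T1", "a", members))
        (base,) = enrich(gene_list, ann, universe)
        doubled_universe = universe + [g + "_B" for g in universe]
        doubled_members = members + [g + "_B" for g in members]
        doubled_list = gene_list + [g + "_B" for g in gene_list]
        (doubled,) = enrich(
            doubled_list, _ann(("T1", "a", doubled_members)), doubled_universe
        )
        assert doubled.fold_enrichment == pytest.approx(base.fold_enrichment)

    def test_empty_inputs_rejected(self):
        ann = _ann(("T1", "a", ["G1"]))
        with pytest.raises(ValidationError):
            enrich([], ann, ["G1"])
        with pytest.raises(ValidationError):
            enrich(["ZZ"], ann, ["G1"])  # outside the universe


class TestFilterSignificant:
    def _res(self, p, fe=2.0):
        return EnrichmentResult(
            term_id=f"T{p}", term_name="t", k=2, n=10, K=5, N=100,
            fold_enrichment=fe, p_raw=p, q_bh=min(1.0, p * 2),
        )

    def test_boundary_rules(self):
        kept = filter_significant([self._res(0.046), self._res(0.05)], p_cut=0.05)
        assert [r.p_raw for r in kept] == [0.046]

    def test_fold_cut_is_inclusive(self):
        kept = filter_significant(
            [self._res(0.01, fe=1.0), self._res(0.01, fe=0.5)], fe_cut=1.0
        )
        assert len(kept) == 1


class TestPartitionModules:
    def test_single_module_covers_everything(self):
        universe = [f"G{i}" for i in range(30)]
        gene_list = universe[:10]
        ann = _ann(("T1", "only", gene_list))
        results = enrich(gene_list, ann, universe)
        part = partition_modules(gene_list, results, 1, ann)
        assert part.modules["only"] == frozenset(g.upper() for g in gene_list)

    def test_disjoint_planted_terms_recover_bipartition(self):
        universe = [f"G{i:02d}" for i in range(40)]
        left, right = universe[:5], universe[5:10]
        gene_list = left + right
        ann = _ann(("T1", "left", left), ("T2", "right", right))
        results = enrich(gene_list, ann, universe)
        part = partition_modules(gene_list, results, 2, ann)
        assert part.modules["left"] == frozenset(left)
        assert part.modules["right"] == frozenset(right)

    def test_redundant_term_is_absorbed(self):
        universe = [f"G{i:02d}" for i in range(40)]
        gene_list = universe[:8]
        ann = _ann(
            ("T1", "core", gene_list),
            ("T2", "near-duplicate", gene_list[:7]),  # Jaccard 7/8 with core
            ("T3", "other", universe[20:28] + gene_list[:1]),
        )
        results = enrich(gene_list, ann, universe)
        part = partition_modules(gene_list, results, 2, ann)
        assert "near-duplicate" not in part.modules

    def test_uncovered_genes_fall_into_unassigned(self):
        universe = [f"G{i}" for i in range(30)]
        gene_list = universe[:6]
        ann = _ann(("T1", "half", gene_list[:3]))
        results = enrich(gene_list, ann, universe)
        part = partition_modules(gene_list, results, 1, ann)
        assert part.modules["unassigned"] == frozenset(g.upper() for g in gene_list[3:])

    def test_study_scale_bundle_recovers_four_planted_modules(
        self, study_bundle, study_tables
    ):
        import json

        from netpharm import networks as nets

        truth = json.loads(study_bundle.ground_truth.read_text())
        net4 = nets.build_ppi_network(
            study_tables["ct"], study_tables["disease"], study_tables["ppi"]
        )
        universe = set(net4.nodes())
        hub_genes = truth["planted_hub_genes"]
        ann = study_tables["annotations"]
        results = enrich(hub_genes, ann, universe)
        significant = filter_significant(results, p_cut=0.05, fe_cut=1.0)
        part = partition_modules(hub_genes, significant, 4, ann)
        planted_names = set(truth["planted_terms"].values())
        recovered = [label for label in part.labels if label != "unassigned"]
        assert len(recovered) == 4
        assert set(recovered) == planted_names
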