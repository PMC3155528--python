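import numpy as np
import pandas as pd
import pytest

from brainstates.connections import (
    ConnectionMatrix,
    Pathway,
    PathwayCatalog,
    infer_edges,
    intrinsic_pairs,
    pair_counts,
)
from brainstates.enrichment import binomial_tail
from brainstates.multistate import MultiStateTable, StateModel, up_regions


def _table_from_up_sets(up_sets: dict[str, set[str]], regions: tuple[str, ...]):
    """One probe per gene; genes with empty up sets are one-state."""
    models, recs = {}, []
    for gene, ups in up_sets.items():
        pid = f"probe_{gene}"
        assignment = np.array([1 if r in ups else 0 for r in regions])
        if ups:
            model = StateModel(regions, (3.0, 9.0), assignment)
            n_states = 2
        else:
            model = StateModel(regions, (6.0,), np.zeros(len(regions), int))
            n_states = 1
        models[pid] = model
        recs.append((pid, gene, n_states, up_regions(model)))
    probes = pd.DataFrame(
        recs, columns=["probe_id", "gene", "n_states", "up_regions"]
    ).set_index("probe_id")
    return MultiStateTable(probes=probes, models=models, region_ids=regions)


def _catalog(pairs):
    return PathwayCatalog(
        [
            Pathway(f"PW{i}", "peptide", frozenset(l), frozenset(r))
            for i, (l, r) in enumerate(pairs)
        ]
    )


REGIONS = ("A", "B", "C", "D")


class TestPairCounts:
    def test_single_extrinsic_pathway(self):
        table = _table_from_up_sets({"L": {"A"}, "R": {"B"}}, REGIONS)
        cm = pair_counts(table, _catalog([({"L"}, {"R"})]))
        expected = np.zeros((4, 4), int)
        expected[0, 1] = 1
        np.testing.assert_array_equal(cm.counts.to_numpy(), expected)
        assert cm.n_pathways_used == 1

    def test_intrinsic_pathway_counts_on_diagonal(self):
        table = _table_from_up_sets({"L": {"A"}, "R": {"A"}}, REGIONS)
        cm = pair_counts(table, _catalog([({"L"}, {"R"})]))
        assert cm.counts.at["A", "A"] == 1
        assert cm.counts.to_numpy().sum() == 1

    def test_pathway_with_one_state_side_excluded(self):
        table = _table_from_up_sets({"L": {"A"}, "R": set()}, REGIONS)
        cm = pair_counts(table, _catalog([({"L"}, {"R"})]))
        assert cm.n_pathways_used == 0
        assert cm.counts.to_numpy().sum() == 0

    def test_unknown_catalog_gene_warns_and_skips(self):
        table = _table_from_up_sets({"L": {"A"}, "R": {"B"}}, REGIONS)
        catalog = _catalog([({"L", "GHOST"}, {"R"})])
        with pytest.warns(UserWarning, match="GHOST"):
            cm = pair_counts(table, catalog)
        assert cm.counts.at["A", "B"] == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        regions = tuple(f"r{i}" for i in range(6))
        genes = {}
        for i in range(24):
            ups = {r for r in regions if rng.random() < 0.3}
            if len(ups) == len(regions):
                ups.discard(regions[0])
            genes[f"g{i}"] = ups
        table = _table_from_up_sets(genes, regions)
        pairs = []
        names = list(genes)
        for _ in range(10):
            lig = set(rng.choice(names, rng.integers(1, 3), replace=False))
            rec = set(rng.choice(names, rng.integers(1, 3), replace=False))
            pairs.append((lig, rec))
        catalog = _catalog(pairs)
        cm = pair_counts(table, catalog)
        multi = {g for g, ups in genes.items() if ups}
        for ai, a in enumerate(regions):
            for bi, b in enumerate(regions):
                expected = 0
                for lig, rec in pairs:
                    if not (lig & multi and rec & multi):
                        continue
                    lig_up = any(a in genes[g] for g in lig)
                    rec_up = any(b in genes[g] for g in rec)
                    expected += lig_up and rec_up
                assert cm.counts.iat[ai, bi] == expected

    def test_swapped_roles_transpose_counts(self):
        rng = np.random.default_rng(5)
        regions = tuple(f"r{i}" for i in range(5))
        genes = {}
        for i in range(12):
            ups = {r for r in regions if rng.random() < 0.4} or {regions[0]}
            if len(ups) == len(regions):
                ups.discard(regions[0])
            genes[f"g{i}"] = ups
        table = _table_from_up_sets(genes, regions)
        pairs = [({f"g{2*i}"}, {f"g{2*i+1}"}) for i in range(6)]
        swapped = [(r, l) for l, r in pairs]
        a = pair_counts(table, _catalog(pairs)).counts.to_numpy()
        b = pair_counts(table, _catalog(swapped)).counts.to_numpy()
        np.testing.assert_array_equal(a, b.T)


class TestInferEdges:
    def _matrix(self, counts, n_used):
        regions = [f"r{i}" for i in range(counts.shape[0])]
        return ConnectionMatrix(
            pd.DataFrame(counts, index=regions, columns=regions), n_used, {}
        )

    def test_all_zero_counts_yield_no_edges(self):
        edges = infer_edges(self._matrix(np.zeros((4, 4), int), 10), p0=0.3)
        assert edges.edges.empty

    def test_exact_tail_at_printed_parameters(self):
        # 68 pathways, p0 = 0.29899 -> pair success probability 0.089395
        p = binomial_tail(18, 68, 0.29899**2)
        import math

        q = 0.29899**2
        oracle = sum(
            math.comb(68, i) * q**i * (1 - q) ** (68 - i) for i in range(18, 69)
        )
        assert p == pytest.approx(oracle, abs=1e-12)
        counts = np.zeros((48, 48), int)
        counts[0, 1] = 18
        edges = infer_edges(self._matrix(counts, 68), p0=0.29899)
        row = edges.all_pairs[(edges.all_pairs["source"] == "r00")]
        # region labels are r0..; find the tested pair by count
        tested = edges.all_pairs[edges.all_pairs["count"] == 18].iloc[0]
        assert tested["p_value"] == pytest.approx(oracle, abs=1e-12)
        assert edges.multiplicity == 48 * 48

    def test_cutoff_is_upper_quantile_with_strict_exceedance(self):
        counts = np.zeros((10, 10), int)
        counts[0, 1] = 30
        counts[2, 3] = 6
        m = self._matrix(counts, 68)
        edges = infer_edges(m, p0=0.3, q=0.05)
        assert edges.cutoff == int(np.floor(np.quantile(counts.ravel(), 0.95)))
        assert set(zip(edges.edges["source"], edges.edges["target"])) <= {
            ("r0", "r1"), ("r2", "r3")
        }
        # the dominant pair passes both count cutoff and Bonferroni binomial
        assert ("r0", "r1") in set(zip(edges.edges["source"], edges.edges["target"]))

    def test_zero_pathways_errors(self):
        with pytest.raises(ValueError):
            infer_edges(self._matrix(np.zeros((3, 3), int), 0), p0=0.3)

    def test_null_calibration_monte_carlo(self):
        # up states placed uniformly at rate p0: mean pair count ~ n*p0^2 and
        # essentially no Bonferroni-significant pairs
        rng = np.random.default_rng(7)
        n, R, p0 = 68, 20, 0.3
        n_rep = 500
        sig = 0
        total_counts = 0.0
        for _ in range(n_rep):
            lig = rng.random((n, R)) < p0
            rec = rng.random((n, R)) < p0
            counts = np.einsum("pi,pj->ij", lig.astype(int), rec.astype(int))
            m = self._matrix(counts, n)
            edges = infer_edges(m, p0=p0, alpha=0.01)
            sig += int((edges.all_pairs["adjusted_p"] < 0.01).sum())
            total_counts += counts.mean()
        assert sig / (n_rep * R * R) <= 0.01
        mean_count = total_counts / n_rep
        se = np.sqrt(n * p0**2 * (1 - p0**2) / (n_rep * R * R))
        assert mean_count == pytest.approx(n * p0**2, abs=5 * se + 0.05)


class TestIntrinsicPairs:
    def test_shared_region_scores_one(self):
        table = _table_from_up_sets({"Vip": {"SCN"}, "Vipr2": {"SCN"}},
                                    ("SCN", "ME", "Hb"))
        res = intrinsic_pairs(table, _catalog([({"Vip"}, {"Vipr2"})]))
        assert len(res) == 1
        assert res.loc[0, "matched_regions"] == "SCN"
        assert res.loc[0, "n_matched"] == 1

    def test_disjoint_up_sets_excluded(self):
        table = _table_from_up_sets({"L": {"A"}, "R": {"B"}}, REGIONS)
        res = intrinsic_pairs(table, _catalog([({"L"}, {"R"})]))
        assert res.empty

    def test_ranked_by_intersection_size(self):
        table = _table_from_up_sets(
            {"L1": {"A", "B", "C"}, "R1": {"B", "C", "D"},
             "L2": {"A"}, "R2": {"A"}},
            REGIONS,
        )
        res = intrinsic_pairs(
            table, _catalog([({"L1"}, {"R1"}), ({"L2"}, {"R2"})])
        )
        assert list(res["n_matched"]) == [2, 1]
        assert res.loc[0, "matched_regions"] == "B,C"


class TestPathwayCatalogIO:
    def test_tsv_round_trip(self, tmp_path):
        catalog = _catalog([({"L1", "L2"}, {"R1"}), ({"L3"}, {"R2", "R3"})])
        catalog.write_tsv(tmp_path / "c.tsv")
        back = PathwayCatalog.read_tsv(tmp_path / "c.tsv")
        assert {
            (p.pathway_id, p.ligand_genes, p.receptor_genes) for p in back
        } == {(p.pathway_id, p.ligand_genes, p.receptor_genes) for p in catalog}

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            Pathway("PW1", "gas", frozenset(), frozenset({"R"}))
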