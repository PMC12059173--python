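import itertools

import numpy as np
import pandas as pd
import pytest

from tlsarch.repertoire import (
    ClonotypeAssignment,
    classify_cells,
    clonal_diversity,
    define_bcr_clonotypes,
    define_tcr_clonotypes,
    estimate_bcr_threshold,
    shared_feature_fraction,
    sharing_matrix,
)
from tlsarch.synthetic import CompositionSpec, RepertoireSpec, simulate_composition, simulate_repertoire

from .conftest import chain


def chains_df(*records):
    return pd.DataFrame(records)


class TestClassifyCells:
    def test_tcr_and_bcr_chains_make_ambiguous(self):
        df = chains_df(chain("c1", "TRA", "AAA"), chain("c1", "TRB", "CCC"),
                       chain("c1", "IGH", "GGG"))
        assert classify_cells(df)["c1"] == "ambiguous"

    def test_three_chains_of_one_arm_make_multichain(self):
        df = chains_df(chain("c1", "TRA", "AAA"), chain("c1", "TRA", "AAC"),
                       chain("c1", "TRB", "CCC"), chain("c1", "TRB", "CCG"),
                       chain("c1", "TRB", "CCT"))
        assert classify_cells(df)["c1"] == "multichain"

    def test_canonical_pair_is_tcr(self):
        df = chains_df(chain("c1", "TRA", "AAA"), chain("c1", "TRB", "CCC"))
        assert classify_cells(df)["c1"] == "TCR"

    def test_secondary_light_chain_allowed_for_bcr(self):
        df = chains_df(chain("c1", "IGH", "AAA"), chain("c1", "IGK", "CCC"),
                       chain("c1", "IGL", "GGG"))
        assert classify_cells(df)["c1"] == "BCR"

    def test_duplicate_records_deduplicated(self):
        df = chains_df(chain("c1", "TRA", "AAA"), chain("c1", "TRA", "AAA"),
                       chain("c1", "TRB", "CCC"))
        assert classify_cells(df)["c1"] == "TCR"


class TestTcrClonotypes:
    def test_identical_pairs_share_clonotype_and_are_clonal(self):
        df = chains_df(chain("c1", "TRA", "AAA"), chain("c1", "TRB", "CCC"),
                       chain("c2", "TRA", "AAA"), chain("c2", "TRB", "CCC"))
        a = define_tcr_clonotypes(df)
        assert a.cell_to_clonotype["c1"] == a.cell_to_clonotype["c2"]
        assert a.clone_size[a.cell_to_clonotype["c1"]] == 2
        assert a.is_clonal().all()

    def test_both_arms_required_for_identity(self):
        df = chains_df(chain("c1", "TRA", "AAA"), chain("c1", "TRB", "CCC"),
                       chain("c2", "TRA", "AAT"), chain("c2", "TRB", "CCC"))
        a = define_tcr_clonotypes(df)
        assert a.cell_to_clonotype["c1"] != a.cell_to_clonotype["c2"]

    def test_single_arm_key_distinct_from_paired(self):
        df = chains_df(chain("c1", "TRB", "CCC"),
                       chain("c2", "TRA", "AAA"), chain("c2", "TRB", "CCC"))
        a = define_tcr_clonotypes(df)
        assert a.cell_to_clonotype["c1"] != a.cell_to_clonotype["c2"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_equals_brute_force_grouping(self, seed):
        rng = np.random.default_rng(seed)
        juncs = ["AAA", "AAC", "AAG", "CCA"]
        records, truth_keys = [], {}
        for i in range(40):
            tra = rng.choice(juncs)
            trb = rng.choice(juncs)
            records += [chain(f"c{i}", "TRA", tra), chain(f"c{i}", "TRB", trb)]
            truth_keys[f"c{i}"] = (tra, trb)
        a = define_tcr_clonotypes(chains_df(*records))
        # brute force: same key <-> same clonotype id
        for x, y in itertools.combinations(truth_keys, 2):
            same_key = truth_keys[x] == truth_keys[y]
            same_id = a.cell_to_clonotype[x] == a.cell_to_clonotype[y]
            assert same_key == same_id

    def test_record_order_invariance(self):
        records = [chain("c1", "TRA", "AAA"), chain("c1", "TRB", "CCC"),
                   chain("c2", "TRA", "AAA"), chain("c2", "TRB", "CCC"),
                   chain("c3", "TRA", "GGG"), chain("c3", "TRB", "TTT")]
        fwd = define_tcr_clonotypes(chains_df(*records)).cell_to_clonotype
        rev = define_tcr_clonotypes(chains_df(*records[::-1])).cell_to_clonotype
        assert fwd.sort_index().equals(rev.sort_index())


def bcr_chain(cell_id, junction, v="IGHV1", j="IGHJ4"):
    return chain(cell_id, "IGH", junction, v, j)


class TestBcrThreshold:
    def _bimodal_chains(self, n_families=15, family_size=4, seed=0):
        """Well-separated synthetic clone families: within-clone distance
        ~a couple of percent, between-clone ~40%+."""
        rng = np.random.default_rng(seed)
        nt = np.array(list("ACGT"))
        records = []
        k = 0
        for f in range(n_families):
            ancestor = rng.choice(nt, size=45)
            for _ in range(family_size):
                seq = ancestor.copy()
                hit = rng.choice(45, size=1, replace=False)
                for i in hit:
                    seq[i] = rng.choice(nt[nt != seq[i]])
                records.append(bcr_chain(f"b{k}", "".join(seq)))
                k += 1
        return chains_df(*records)

    def test_planted_bimodality_gives_intermediate_threshold(self):
        thr = estimate_bcr_threshold(self._bimodal_chains())
        assert 0.05 < thr < 0.3

    def test_identical_sequences_fall_back(self):
        records = [bcr_chain(f"b{i}", "ACG" * 15) for i in range(25)]
        assert estimate_bcr_threshold(chains_df(*records)) == 0.15

    def test_too_few_chains_fall_back(self):
        records = [bcr_chain(f"b{i}", "ACG" * 15) for i in range(5)]
        assert estimate_bcr_threshold(chains_df(*records)) == 0.15

    def test_invariant_to_duplicating_every_sequence(self):
        df = self._bimodal_chains()
        doubled = pd.concat(
            [df, df.assign(cell_id=df["cell_id"] + "_dup")], ignore_index=True
        )
        assert estimate_bcr_threshold(df) == pytest.approx(
            estimate_bcr_threshold(doubled), abs=1e-12
        )


class TestBcrClonotypes:
    def test_identical_junctions_cluster_together(self):
        df = chains_df(bcr_chain("b1", "AAACCC"), bcr_chain("b2", "AAACCC"))
        a = define_bcr_clonotypes(df, threshold=0.1)
        assert a.cell_to_clonotype["b1"] == a.cell_to_clonotype["b2"]

    def test_distant_pair_splits(self):
        # distance 2/6 = 0.33 > 0.15, no intermediates
        df = chains_df(bcr_chain("b1", "AAACCC"), bcr_chain("b2", "AAAGGG"))
        a = define_bcr_clonotypes(df, threshold=0.15)
        assert a.cell_to_clonotype["b1"] != a.cell_to_clonotype["b2"]

    def test_single_linkage_chains_through_intermediates(self):
        # A-B 0.1, B-C 0.1, A-C 0.2 with threshold 0.15: all merge
        A = "A" * 10
        B = "A" * 9 + "C"
        C = "A" * 8 + "CC"
        df = chains_df(bcr_chain("b1", A), bcr_chain("b2", B), bcr_chain("b3", C))
        a = define_bcr_clonotypes(df, threshold=0.15)
        assert len(set(a.cell_to_clonotype)) == 1

    def test_different_vjl_partitions_never_merge(self):
        df = chains_df(bcr_chain("b1", "AAACCC", v="IGHV1"),
                       bcr_chain("b2", "AAACCC", v="IGHV2"))
        a = define_bcr_clonotypes(df, threshold=1.0)
        assert a.cell_to_clonotype["b1"] != a.cell_to_clonotype["b2"]

    def test_threshold_zero_equals_exact_identity(self):
        df = chains_df(bcr_chain("b1", "AAACCC"), bcr_chain("b2", "AAACCC"),
                       bcr_chain("b3", "AAACCG"))
        a = define_bcr_clonotypes(df, threshold=0.0)
        assert a.cell_to_clonotype["b1"] == a.cell_to_clonotype["b2"]
        assert a.cell_to_clonotype["b1"] != a.cell_to_clonotype["b3"]

    def test_threshold_one_merges_whole_partition(self):
        df = chains_df(bcr_chain("b1", "AAACCC"), bcr_chain("b2", "GGGTTT"),
                       bcr_chain("b3", "CCCAAA"))
        a = define_bcr_clonotypes(df, threshold=1.0)
        assert len(set(a.cell_to_clonotype)) == 1

    def test_ambiguous_v_call_resolved_to_first(self):
        df = chains_df(bcr_chain("b1", "AAACCC", v="IGHV1,IGHV9"),
                       bcr_chain("b2", "AAACCC", v="IGHV1"))
        a = define_bcr_clonotypes(df, threshold=0.1)
        assert a.cell_to_clonotype["b1"] == a.cell_to_clonotype["b2"]


def enumerate_diversity(sizes):
    """Independent oracle: direct formula on a clone-size multiset."""
    p = np.array(sizes) / sum(sizes)
    shannon = float(-(p * np.log(p)).sum())
    order = sorted(sizes, reverse=True)
    cum, k = 0, 0
    for s in order:
        cum += s
        k += 1
        if cum >= sum(sizes) / 2:
            break
    return shannon, 100.0 * k / len(sizes)


def assignment_from_sizes(sizes):
    mapping = {}
    c = 0
    for i, s in enumerate(sizes):
        for _ in range(s):
            mapping[f"cell{c}"] = f"clone{i}"
            c += 1
    classes = pd.Series("TCR", index=list(mapping))
    return ClonotypeAssignment(pd.Series(mapping, dtype=object), classes)


class TestDiversity:
    def test_monoclonal(self):
        r = clonal_diversity(assignment_from_sizes([5]))
        assert r.shannon == 0.0
        assert r.d50 == 100.0

    def test_four_equal_clonotypes(self):
        r = clonal_diversity(assignment_from_sizes([2, 2, 2, 2]))
        assert r.shannon == pytest.approx(np.log(4), abs=1e-12)
        assert r.d50 == 50.0

    def test_hand_computed_5311(self):
        r = clonal_diversity(assignment_from_sizes([5, 3, 1, 1]))
        p = np.array([0.5, 0.3, 0.1, 0.1])
        assert r.shannon == pytest.approx(float(-(p * np.log(p)).sum()), abs=1e-12)
        assert r.d50 == 25.0  # top clone alone covers half the cells

    def test_exhaustive_small_repertoires(self):
        """All clone-size multisets of <= 6 cells over <= 3 clonotypes."""
        for n_clones in (1, 2, 3):
            for sizes in itertools.combinations_with_replacement(range(1, 7), n_clones):
                if sum(sizes) > 6:
                    continue
                r = clonal_diversity(assignment_from_sizes(list(sizes)))
                shannon, d50 = enumerate_diversity(list(sizes))
                assert r.shannon == pytest.approx(shannon, abs=1e-12)
                assert r.d50 == pytest.approx(d50, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            clonal_diversity(assignment_from_sizes([3]), cells=pd.Index(["nope"]))


def make_assignment(cell_clusters, cell_clones):
    cells = pd.DataFrame({
        "cell_id": list(cell_clusters),
        "subcluster": list(cell_clusters.values()),
        "tls_status": "mTLS",
        "sample_id": "s1",
    })
    classes = pd.Series("TCR", index=list(cell_clones))
    assignment = ClonotypeAssignment(pd.Series(cell_clones, dtype=object), classes)
    return assignment, cells


class TestSharing:
    def test_disjoint_repertoires_have_zero_off_diagonal(self):
        a, cells = make_assignment(
            {"c1": "A", "c2": "A", "c3": "B"},
            {"c1": "x", "c2": "x", "c3": "y"},
        )
        M = sharing_matrix(a, cells)
        assert M.loc["A", "B"] == 0
        assert M.loc["A", "A"] == 1 and M.loc["B", "B"] == 1

    def test_spanning_clonotype_counts_in_every_pair(self):
        a, cells = make_assignment(
            {"c1": "A", "c2": "B", "c3": "C"},
            {"c1": "x", "c2": "x", "c3": "x"},
        )
        M = sharing_matrix(a, cells)
        for pair in (("A", "B"), ("A", "C"), ("B", "C")):
            assert M.loc[pair] == 1

    def test_matches_brute_force_set_intersection(self):
        rng = np.random.default_rng(9)
        clusters = ["A", "B", "C"]
        cell_clusters = {f"c{i}": rng.choice(clusters) for i in range(60)}
        cell_clones = {f"c{i}": f"cl{rng.integers(0, 15)}" for i in range(60)}
        a, cells = make_assignment(cell_clusters, cell_clones)
        M = sharing_matrix(a, cells)
        members = {}
        for cid in cell_clusters:
            members.setdefault(cell_clones[cid], set()).add(cell_clusters[cid])
        for x in clusters:
            for y in clusters:
                expected = sum(1 for occ in members.values() if x in occ and y in occ)
                assert M.loc[x, y] == expected

    def test_symmetry_and_cluster_removal_monotonicity(self):
        rng = np.random.default_rng(10)
        cell_clusters = {f"c{i}": rng.choice(["A", "B", "C"]) for i in range(50)}
        cell_clones = {f"c{i}": f"cl{rng.integers(0, 10)}" for i in range(50)}
        a, cells = make_assignment(cell_clusters, cell_clones)
        M = sharing_matrix(a, cells)
        assert M.equals(M.T)
        reduced_cells = cells[cells["subcluster"] != "C"]
        M2 = sharing_matrix(a, reduced_cells)
        for x in ("A", "B"):
            for y in ("A", "B"):
                assert M2.loc[x, y] <= M.loc[x, y]


class TestSharedFeatureFraction:
    def test_all_spanning_gives_one(self):
        a, cells = make_assignment(
            {"c1": "A", "c2": "B", "c3": "A", "c4": "B"},
            {"c1": "x", "c2": "x", "c3": "y", "c4": "y"},
        )
        f = shared_feature_fraction(a, cells, {"A"}, {"B"})
        assert f["fraction"].iloc[0] == 1.0

    def test_no_spanning_gives_zero(self):
        a, cells = make_assignment(
            {"c1": "A", "c2": "A", "c3": "B", "c4": "B"},
            {"c1": "x", "c2": "x", "c3": "y", "c4": "y"},
        )
        f = shared_feature_fraction(a, cells, {"A"}, {"B"})
        assert f["fraction"].iloc[0] == 0.0

    def test_hand_counted_fixture(self):
        # 8 expanded clonotypes, 3 spanning both groups -> 0.375
        cell_clusters, cell_clones = {}, {}
        k = 0
        for i in range(8):
            spanning = i < 3
            for j in range(2):
                cid = f"c{k}"; k += 1
                cell_clusters[cid] = "B" if (spanning and j == 1) else "A"
                cell_clones[cid] = f"cl{i}"
        a, cells = make_assignment(cell_clusters, cell_clones)
        f = shared_feature_fraction(a, cells, {"A"}, {"B"})
        assert f["fraction"].iloc[0] == 0.375

    def test_overlapping_groups_rejected(self):
        a, cells = make_assignment({"c1": "A"}, {"c1": "x"})
        with pytest.raises(ValueError):
            shared_feature_fraction(a, cells, {"A"}, {"A"})


class TestSimulatedRecovery:
    def test_zero_sharing_prob_gives_empty_off_diagonal(self):
        spec = CompositionSpec(statuses=("nTLS",), samples_per_status=1,
                               cells_per_sample=400, clusters=("T1", "T2"),
                               base_proportions=(0.5, 0.5), seed=31)
        cells = simulate_composition(spec)
        chains, truth = simulate_repertoire(cells, RepertoireSpec(seed=32))
        a = define_tcr_clonotypes(chains)
        M = sharing_matrix(a, cells, "subcluster")
        assert M.loc["T1", "T2"] == 0

    def test_ambiguous_fraction_recovered(self):
        spec = CompositionSpec(statuses=("nTLS",), samples_per_status=1,
                               cells_per_sample=1000, clusters=("T1",),
                               base_proportions=(1.0,), seed=33)
        cells = simulate_composition(spec)
        chains, _ = simulate_repertoire(
            cells, RepertoireSpec(ambiguous_frac=0.1, seed=34)
        )
        classes = classify_cells(chains)
        n_amb = int((classes == "ambiguous").sum())
        # binomial(1000, 0.1): 3 sigma ~ 28
        assert abs(n_amb - 100) < 30

    def test_planted_sharing_probability_recovered(self):
        spec = CompositionSpec(statuses=("nTLS",), samples_per_status=1,
                               cells_per_sample=5000, clusters=("T1", "T2"),
                               base_proportions=(0.5, 0.5), seed=35)
        cells = simulate_composition(spec)
        s = 0.3
        chains, _ = simulate_repertoire(
            cells, RepertoireSpec(sharing_prob={("T1", "T2"): s}, seed=36)
        )
        a = define_tcr_clonotypes(chains)
        M = sharing_matrix(a, cells, "subcluster")
        n1 = M.loc["T1", "T1"]
        s_hat = M.loc["T1", "T2"] / n1
        se = np.sqrt(s * (1 - s) / n1)
        assert abs(s_hat - s) <= 3 * se

    def test_large_exponent_gives_near_uniform_clones(self):
        spec = CompositionSpec(statuses=("nTLS",), samples_per_status=1,
                               cells_per_sample=300, clusters=("T1",),
                               base_proportions=(1.0,), seed=37)
        cells = simulate_composition(spec)
        chains, _ = simulate_repertoire(
            cells, RepertoireSpec(clone_size_exponent=30.0, seed=38)
        )
        a = define_tcr_clonotypes(chains)
        r = clonal_diversity(a)
        assert r.shannon == pytest.approx(np.log(r.n_clonotypes), rel=0.02)
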