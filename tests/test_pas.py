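import numpy as np
import pandas as pd
import pytest

import pasdrift as pdr
from pasdrift.pathways import PathwayCollection, PathwayDefinition

from _oracles import bh_adjust, brute_force_pas


def _em(values: dict, genes: list[str], dataset_id="d") -> pdr.ExpressionMatrix:
    return pdr.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes), dataset_id=dataset_id
    )


class TestCNR:
    def test_ratio_to_reference_mean(self):
        case = pd.Series({"g1": 10.0, "g2": 5.0})
        ref = pd.DataFrame({"r1": [4.0, 5.0], "r2": [6.0, 5.0]}, index=["g1", "g2"])
        cnr = pdr.compute_cnr(case, ref)
        assert cnr["g1"] == pytest.approx(2.0)
        assert cnr["g2"] == pytest.approx(1.0)

    def test_hand_computed_three_gene_oracle(self):
        case = pd.Series({"g1": 3.0, "g2": 8.0, "g3": 0.5})
        ref = pd.DataFrame(
            {"r1": [1.0, 2.0, 1.0], "r2": [2.0, 6.0, 3.0]}, index=["g1", "g2", "g3"]
        )
        cnr = pdr.compute_cnr(case, ref)
        # hand ratios: 3/1.5, 8/4, 0.5/2
        assert cnr.to_list() == pytest.approx([2.0, 2.0, 0.25])

    def test_gene_missing_from_reference_dropped_with_warning(self):
        case = pd.Series({"g1": 1.0, "gX": 2.0})
        ref = pd.DataFrame({"r1": [1.0], "r2": [3.0]}, index=["g1"])
        with pytest.warns(UserWarning, match="dropped"):
            cnr = pdr.compute_cnr(case, ref)
        assert list(cnr.index) == ["g1"]

    def test_geometric_reference_mean(self):
        case = pd.Series({"g1": 4.0})
        ref = pd.DataFrame({"r1": [1.0], "r2": [16.0]}, index=["g1"])
        assert pdr.compute_cnr(case, ref, ref_average="geometric")["g1"] == pytest.approx(1.0)


class TestDifferential:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(3, 0.5, size=(5, 3))
        case = pd.DataFrame(vals, index=[f"g{i}" for i in range(5)])
        res = pdr.test_differential(case, case.copy())
        assert np.allclose(res["p"], 1.0)
        assert np.allclose(res["fc"], 1.0)

    def test_bh_adjustment_matches_hand_recursion(self):
        rng = np.random.default_rng(1)
        case = pd.DataFrame(
            rng.lognormal(3, 0.4, size=(40, 4)), index=[f"g{i}" for i in range(40)]
        )
        ref = pd.DataFrame(
            rng.lognormal(3, 0.4, size=(40, 4)), index=case.index
        )
        res = pdr.test_differential(case, ref)
        assert res["q"].to_numpy() == pytest.approx(
            bh_adjust(res["p"].to_list()), abs=1e-12
        )

    def test_bh_toy_example(self):
        # step-up on (0.01, 0.02, 0.03) gives q = 0.03 for all three
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_q_monotone_with_p_rank_and_bounded(self):
        rng = np.random.default_rng(2)
        case = pd.DataFrame(rng.lognormal(3, 0.4, (30, 3)), index=range(30))
        ref = pd.DataFrame(rng.lognormal(3.2, 0.4, (30, 3)), index=range(30))
        res = pdr.test_differential(case, ref).sort_values("p")
        q = res["q"].to_numpy()
        assert (np.diff(q) >= -1e-15).all()
        assert (q <= 1.0).all() and (q >= res["p"].to_numpy() - 1e-15).all()

    def test_strong_shift_is_detected(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(50)]
        base = rng.normal(6, 1, 50)
        case_log = base[:, None] + rng.normal(0, 0.1, (50, 10))
        ref_log = base[:, None] + rng.normal(0, 0.1, (50, 10))
        case_log[0] += 2.0  # one gene shifted 4-fold
        res = pdr.test_differential(
            pd.DataFrame(2.0**case_log, index=genes),
            pd.DataFrame(2.0**ref_log, index=genes),
        )
        assert res.loc["g0", "q"] < 0.05
        assert res.loc["g0", "fc"] > 3.0

    def test_single_sample_group_warns_p_one(self):
        case = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"])
        ref = pd.DataFrame({"r1": [1.0, 2.0], "r2": [2.0, 3.0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = pdr.test_differential(case, ref)
        assert (res["p"] == 1.0).all()

    def test_disjoint_gene_sets_error(self):
        case = pd.DataFrame({"s1": [1.0]}, index=["gA"])
        ref = pd.DataFrame({"r1": [1.0]}, index=["gB"])
        with pytest.raises(ValueError, match="no genes"):
            pdr.test_differential(case, ref)


class TestBTIF:
    @pytest.mark.parametrize(
        "fc,q,mode,expected",
        [
            (1.6, 0.01, "filtered", 1),
            (1.4, 0.001, "filtered", 0),   # fails the fold-change gate
            (0.5, 0.01, "filtered", 1),    # 2-fold down passes via 1/FC
            (1.6, 0.2, "filtered", 0),     # fails the FDR gate
            (1.0, 1.0, "unfiltered", 1),
        ],
    )
    def test_gates(self, fc, q, mode, expected):
        out = pdr.compute_btif(
            pd.Series({"g": fc}), pd.Series({"g": q}), mode
        )
        assert out["g"] == expected

    def test_filtered_flags_are_subset_of_unfiltered(self):
        rng = np.random.default_rng(4)
        fc = pd.Series(rng.lognormal(0, 0.5, 100))
        q = pd.Series(rng.uniform(0, 1, 100))
        filt = pdr.compute_btif(fc, q, "filtered")
        unfilt = pdr.compute_btif(fc, q, "unfiltered")
        assert (filt <= unfilt).all()


class TestComputePAS:
    def test_all_btif_zero_gives_zero(self, toy_collection):
        cnr = pd.Series({"gA": 2.0, "gB": 0.5, "gC": 3.0})
        btif = pd.Series(0, index=cnr.index)
        assert pdr.compute_pas(toy_collection["p1"], cnr, btif) == 0.0

    def test_single_activator_log10(self):
        p = PathwayDefinition("p", "p", {"gA": 1.0})
        assert pdr.compute_pas(
            p, pd.Series({"gA": 10.0}), pd.Series({"gA": 1})
        ) == pytest.approx(1.0)

    def test_activator_repressor_cancellation(self):
        p = PathwayDefinition("p", "p", {"gA": 1.0, "gB": -1.0})
        cnr = pd.Series({"gA": 4.0, "gB": 4.0})
        btif = pd.Series({"gA": 1, "gB": 1})
        assert pdr.compute_pas(p, cnr, btif) == pytest.approx(0.0)

    def test_no_member_gene_present_is_nan(self):
        p = PathwayDefinition("p", "p", {"gZ": 1.0})
        with pytest.warns(UserWarning, match="undefined"):
            out = pdr.compute_pas(p, pd.Series({"gA": 2.0}), pd.Series({"gA": 1}))
        assert np.isnan(out)

    def test_missing_members_contribute_zero(self):
        p = PathwayDefinition("p", "p", {"gA": 1.0, "gZ": -1.0})
        with pytest.warns(UserWarning, match="missing"):
            out = pdr.compute_pas(p, pd.Series({"gA": 10.0}), pd.Series({"gA": 1}))
        assert out == pytest.approx(1.0)


def _toy_study(rng):
    """Random single-dataset study: <=10 genes, <=6 samples, 1-3 pathways."""
    n_genes = rng.integers(3, 11)
    genes = [f"g{i}" for i in range(n_genes)]
    n_ref = rng.integers(2, 4)
    n_case = rng.integers(2, 4)
    samples = [f"s{i}" for i in range(n_ref + n_case)]
    values = pd.DataFrame(
        np.exp(rng.normal(3, 1, (n_genes, len(samples)))), index=genes, columns=samples
    )
    ref = samples[:n_ref]
    groups = {"ref": [("d", s) for s in ref], "case": [("d", s) for s in samples[n_ref:]]}
    n_pw = rng.integers(1, 4)
    pathways = []
    for k in range(n_pw):
        size = rng.integers(1, n_genes + 1)
        members = rng.choice(genes, size=size, replace=False)
        roles = {
            g: float(rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0])) for g in members
        }
        pathways.append(PathwayDefinition(f"pw{k}", f"pw{k}", roles))
    coll = PathwayCollection(pathways=pathways)
    mode = str(rng.choice(["filtered", "unfiltered"]))
    return values, groups, ref, coll, mode


class TestPASMatrix:
    def test_matches_brute_force_oracle(self):
        """Pipeline PAS equals an independent loop-based recomputation to 1e-12."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            values, groups, ref, coll, mode = _toy_study(rng)
            em = pdr.ExpressionMatrix(values=values, dataset_id="d")
            pas = pdr.compute_pas_matrix(
                {"d": em}, groups, coll, {"d": ref}, mode=mode
            )
            expected = brute_force_pas(
                expression={g: values.loc[g].to_dict() for g in values.index},
                genes=list(values.index),
                samples=list(values.columns),
                groups={g: [s for _, s in m] for g, m in groups.items()},
                reference_samples=ref,
                pathways={p.pathway_id: dict(p.gene_roles) for p in coll},
                mode=mode,
            )
            for s, scores in expected.items():
                for pid, want in scores.items():
                    got = pas.values.loc[pid, s]
                    assert got == pytest.approx(want, abs=1e-12)

    def test_reference_group_self_scored_filtered_is_exactly_zero(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(6)]
        values = pd.DataFrame(
            np.exp(rng.normal(3, 0.5, (6, 4))), index=genes,
            columns=["a", "b", "c", "d"],
        )
        em = pdr.ExpressionMatrix(values=values, dataset_id="d")
        coll = PathwayCollection(
            [PathwayDefinition("p", "p", {g: 1.0 for g in genes})]
        )
        groups = {"ref": [("d", s) for s in values.columns]}
        pas = pdr.compute_pas_matrix(
            {"d": em}, groups, coll, {"d": list(values.columns)},
            self_reference_mode="filtered",
        )
        assert (pas.values.to_numpy() == 0.0).all()

    def test_unfiltered_sample_at_reference_mean_scores_zero(self):
        values = pd.DataFrame(
            {"r1": [2.0, 8.0], "r2": [4.0, 2.0], "c": [3.0, 5.0]},
            index=["g1", "g2"],
        )
        # case sample equals the reference mean gene-wise -> every CNR is 1
        em = pdr.ExpressionMatrix(values=values, dataset_id="d")
        coll = PathwayCollection([PathwayDefinition("p", "p", {"g1": 1.0, "g2": -0.5})])
        groups = {"case": [("d", "c")]}
        pas = pdr.compute_pas_matrix(
            {"d": em}, groups, coll, {"d": ["r1", "r2"]}, mode="unfiltered"
        )
        assert pas.values.loc["p", "c"] == pytest.approx(0.0, abs=1e-15)

    def test_scaling_case_adds_arr_weighted_log_constant(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(5)]
        base = pd.DataFrame(
            np.exp(rng.normal(3, 0.5, (5, 5))), index=genes,
            columns=["r1", "r2", "r3", "c1", "c2"],
        )
        roles = {"g0": 1.0, "g1": -1.0, "g2": 0.5, "g3": -0.5, "g4": 1.0}
        coll = PathwayCollection([PathwayDefinition("p", "p", roles)])
        groups = {"case": [("d", "c1"), ("d", "c2")]}
        ref = ["r1", "r2", "r3"]

        def pas_of(values):
            em = pdr.ExpressionMatrix(values=values, dataset_id="d")
            return pdr.compute_pas_matrix(
                {"d": em}, groups, coll, {"d": ref}, mode="unfiltered"
            ).values.loc["p"]

        c = 3.7
        scaled = base.copy()
        scaled[["c1", "c2"]] *= c
        shift = sum(roles.values()) * np.log10(c)
        delta = pas_of(scaled) - pas_of(base)
        assert delta.to_numpy() == pytest.approx(shift, abs=1e-10)

    def test_pas_additive_over_disjoint_pathway_partition(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(8)]
        values = pd.DataFrame(
            np.exp(rng.normal(3, 0.6, (8, 5))), index=genes,
            columns=["r1", "r2", "c1", "c2", "c3"],
        )
        roles = {g: float(rng.choice([-1.0, -0.5, 0.5, 1.0])) for g in genes}
        whole = PathwayCollection([PathwayDefinition("all", "all", roles)])
        parts = PathwayCollection(
            [
                PathwayDefinition("a", "a", {g: roles[g] for g in genes[:3]}),
                PathwayDefinition("b", "b", {g: roles[g] for g in genes[3:]}),
            ]
        )
        em = pdr.ExpressionMatrix(values=values, dataset_id="d")
        groups = {"case": [("d", s) for s in ["c1", "c2", "c3"]]}
        ref = ["r1", "r2"]
        pas_whole = pdr.compute_pas_matrix({"d": em}, groups, whole, {"d": ref})
        pas_parts = pdr.compute_pas_matrix({"d": em}, groups, parts, {"d": ref})
        total = pas_parts.values.loc["a"] + pas_parts.values.loc["b"]
        assert pas_whole.values.loc["all"].to_numpy() == pytest.approx(
            total.to_numpy(), abs=1e-12
        )

    def test_dataset_without_reference_is_error(self, toy_collection):
        values = pd.DataFrame({"s1": [1.0] * 5, "s2": [2.0] * 5},
                              index=["gA", "gB", "gC", "gD", "gE"])
        em = pdr.ExpressionMatrix(values=values, dataset_id="d")
        with pytest.raises(ValueError, match="reference"):
            pdr.compute_pas_matrix(
                {"d": em}, {"case": [("d", "s1")]}, toy_collection, {}
            )
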