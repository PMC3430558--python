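"""Similarity scoring, indexing, ranked retrieval and PR evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import innershape as ins
from innershape.descriptors import Descriptor
from innershape.retrieval import (
    DEFAULT_RECALL_GRID,
    MoleculeRecord,
    PRCurve,
    _interpolated_precision,
)


def pdf_descriptor(weights, method="IDSS", source_id=""):
    bins = np.asarray(weights, dtype=float)
    return Descriptor(method=method, bins=bins / bins.sum(),
                      source_id=source_id)


class TestSimilarity:
    def test_identity(self):
        d = pdf_descriptor([1, 2, 3])
        s = ins.similarity(d, d)
        assert s.value == 1.0 and s.l1 == 0.0

    def test_disjoint_supports(self):
        a = pdf_descriptor([1, 0, 0, 0])
        b = pdf_descriptor([0, 0, 1, 1])
        s = ins.similarity(a, b)
        assert s.value == pytest.approx(0.0)
        assert s.l1 == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "other",
        [
            Descriptor(method="D2", bins=np.full(4, 0.25)),
            Descriptor(method="IDSS", bins=np.full(8, 0.125)),
            Descriptor(method="IDSS", bins=np.full(4, 0.25), mode="fixed_range"),
        ],
    )
    def test_mismatch_rejected(self, other):
        a = pdf_descriptor([1, 1, 1, 1])
        with pytest.raises(ValueError, match="mismatch"):
            ins.similarity(a, other)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 10.0), min_size=5, max_size=5),
        st.lists(st.floats(0.0, 10.0), min_size=5, max_size=5),
    )
    def test_bounds_and_symmetry(self, wa, wb):
        if sum(wa) == 0 or sum(wb) == 0:
            return
        a, b = pdf_descriptor(wa), pdf_descriptor(wb)
        s_ab, s_ba = ins.similarity(a, b), ins.similarity(b, a)
        assert 0.0 - 1e-12 <= s_ab.value <= 1.0 + 1e-12
        assert s_ab.value == pytest.approx(s_ba.value)
        assert s_ab.value == pytest.approx(1 - s_ab.l1 / 2)


def toy_index():
    recs = [
        MoleculeRecord(id=f"m{i}", group="g" + str(i // 2),
                       descriptors={"IDSS": pdf_descriptor(w, source_id=f"m{i}")})
        for i, w in enumerate([[4, 1, 0], [3, 2, 0], [0, 1, 4], [0, 2, 3]])
    ]
    return ins.build_index(recs)


class TestIndex:
    def test_build_and_len(self):
        assert len(toy_index()) == 4

    def test_duplicate_id_rejected(self):
        rec = MoleculeRecord(id="x", descriptors={"IDSS": pdf_descriptor([1, 1])})
        with pytest.raises(ValueError, match="duplicate"):
            ins.build_index([rec, rec])

    def test_too_few_records_rejected(self):
        rec = MoleculeRecord(id="x", descriptors={"IDSS": pdf_descriptor([1, 1])})
        with pytest.raises(ValueError):
            ins.build_index([rec])

    def test_save_load_bit_exact(self, tmp_path):
        index = toy_index()
        path = str(tmp_path / "db.jsonl")
        index.save(path)
        loaded = ins.Index.load(path)
        assert loaded.ids == index.ids
        for mol_id in index.ids:
            for m, d in index[mol_id].descriptors.items():
                assert np.array_equal(loaded[mol_id].descriptors[m].bins, d.bins)
            assert loaded[mol_id].group == index[mol_id].group


class TestQuery:
    def test_identical_probe_ranks_first_with_one(self):
        index = toy_index()
        probe = pdf_descriptor([4, 1, 0])  # == m0, but anonymous probe
        ranked = ins.query(index, probe, k=4)
        assert ranked[0] == ("m0", pytest.approx(1.0))

    def test_k_larger_than_database(self):
        index = toy_index()
        ranked = ins.query(index, pdf_descriptor([1, 1, 1]), k=100)
        assert len(ranked) == 4

    def test_self_match_excluded_for_members(self):
        index = toy_index()
        ranked = ins.query(index, index["m0"].descriptors["IDSS"], k=10)
        assert all(mol_id != "m0" for mol_id, _ in ranked)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            ins.query(toy_index(), pdf_descriptor([1, 1, 1]), k=0)

    def test_ranking_invariant_to_unrelated_additions(self):
        index = toy_index()
        probe = pdf_descriptor([2, 2, 1])
        before = [mol_id for mol_id, _ in ins.query(index, probe, k=10)]
        extra = MoleculeRecord(
            id="zz", group="zz",
            descriptors={"IDSS": pdf_descriptor([1, 5, 1], source_id="zz")})
        bigger = ins.build_index(list(index.records) + [extra])
        after = [mol_id for mol_id, _ in ins.query(bigger, probe, k=10)
                 if mol_id != "zz"]
        assert after == before

    def test_rods_rank_above_spheres_for_bent_probe(self):
        rng = np.random.default_rng(0)
        recs = []
        for i, angle in enumerate([0, 25, 50, 75]):
            g = ins.make_synthetic_shape(
                "bent_rod", length=36, radius=3, bend_angle=angle,
                seed=int(rng.integers(1, 2**31)), source_id=f"rod{i}")
            recs.append(MoleculeRecord(
                id=f"rod{i}", group="rod",
                descriptors={"IDSS": ins.describe(g, "IDSS", n_samples=96,
                                                  seed=1)}))
        for i, radius in enumerate([5, 7, 9, 11]):
            g = ins.make_synthetic_shape(
                "sphere", radius=radius,
                seed=int(rng.integers(1, 2**31)), source_id=f"sph{i}")
            recs.append(MoleculeRecord(
                id=f"sph{i}", group="sphere",
                descriptors={"IDSS": ins.describe(g, "IDSS", n_samples=96,
                                                  seed=1)}))
        index = ins.build_index(recs)
        probe_grid = ins.make_synthetic_shape(
            "bent_rod", length=36, radius=3, bend_angle=60, seed=99,
            source_id="probe")
        probe = ins.describe(probe_grid, "IDSS", n_samples=96, seed=1)
        ranked = [mol_id for mol_id, _ in ins.query(index, probe, k=8)]
        assert all(r.startswith("rod") for r in ranked[:4])


class TestPrecisionRecall:
    def test_perfect_retrieval_horizontal_line(self):
        # Identical descriptors within groups: precision 1 at every recall.
        recs = []
        for g, w in [("a", [5, 1]), ("b", [1, 5])]:
            for i in range(3):
                recs.append(MoleculeRecord(
                    id=f"{g}{i}", group=g,
                    descriptors={"IDSS": pdf_descriptor(w)}))
        overall, per_group = ins.precision_recall(ins.build_index(recs), "IDSS")
        np.testing.assert_allclose(overall.precision, 1.0)
        assert ins.auc(overall) == pytest.approx(1.0)

    def test_output_ranges(self):
        overall, _ = ins.precision_recall(toy_index(), "IDSS")
        assert np.all((overall.precision >= 0) & (overall.precision <= 1))
        assert np.all(np.diff(overall.recall) > 0)

    def test_singleton_group_excluded_with_warning(self):
        recs = list(toy_index().records)
        recs.append(MoleculeRecord(
            id="solo", group="solo",
            descriptors={"IDSS": pdf_descriptor([1, 1, 1])}))
        with pytest.warns(UserWarning, match="singleton"):
            overall, per_group = ins.precision_recall(
                ins.build_index(recs), "IDSS")
        assert "solo" not in per_group

    def test_random_descriptors_match_null_model(self):
        # Random rankings: average precision approaches the relevant
        # fraction (g-1)/(N-1); checked against an independent
        # permutation-based oracle.
        g, grid = 6, DEFAULT_RECALL_GRID
        rng = np.random.default_rng(0)
        aucs, curves = [], []
        for _ in range(20):
            recs = []
            for grp in ("a", "b"):
                for i in range(g):
                    recs.append(MoleculeRecord(
                        id=f"{grp}{i}", group=grp,
                        descriptors={"IDSS": pdf_descriptor(
                            rng.dirichlet(np.ones(16)))}))
            overall, _ = ins.precision_recall(ins.build_index(recs), "IDSS")
            aucs.append(ins.auc(overall))
            curves.append(overall.precision)
        # independent oracle: random permutations of the same group layout
        oracle = []
        for _ in range(200):
            relevant = np.zeros(2 * g - 1, dtype=bool)
            relevant[rng.choice(2 * g - 1, g - 1, replace=False)] = True
            p = _interpolated_precision(relevant, g - 1, grid)
            curve = PRCurve(recall=grid, precision=p)
            oracle.append(ins.auc(curve))
        assert abs(np.mean(aucs) - np.mean(oracle)) < 0.08
        # At high recall the interpolation bias fades and precision
        # approaches the relevant fraction (g-1)/(N-1).
        tail = [np.mean(c[grid >= 0.5]) for c in curves]
        assert abs(np.mean(tail) - (g - 1) / (2 * g - 1)) < 0.10


class TestAUC:
    def test_constant_curves(self):
        grid = DEFAULT_RECALL_GRID
        assert ins.auc(PRCurve(grid, np.ones_like(grid))) == pytest.approx(1.0)
        assert ins.auc(PRCurve(grid, np.full_like(grid, 0.5))) == pytest.approx(0.5)

    def test_piecewise_linear_toy_curve(self):
        # Hand trapezoid over {(0,1), (0.5,1), (1,0)} = 0.5 + 0.25.
        curve = PRCurve(recall=np.array([0.0, 0.5, 1.0]),
                        precision=np.array([1.0, 1.0, 0.0]))
        assert ins.auc(curve) == pytest.approx(0.75)
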