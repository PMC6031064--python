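import numpy as np
import pytest

from protdyn.dataset import (MutationRecord, SchemaError, augment_reverse,
                             classify_stability, compare_methods, evaluate,
                             make_splits, read_mutation_table,
                             synthetic_feature_table,
                             synthetic_mutation_table)
from protdyn.structure import MutationSpec


def make_record(i=0, ddg=1.0, direction="forward", pdb="1ABC"):
    spec = MutationSpec(chain_id="A", wild_aa="A", residue_number=i + 1,
                        mutant_aa="G")
    return MutationRecord(pdb_id=pdb, chain_id="A", mutation=spec,
                          ddg_exp=ddg, direction=direction,
                          group_key=f"{pdb}:A:{i + 1}")


class TestReadMutationTable:
    def test_stabilizing_positive(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("pdb_id,chain,mutation,ddg\n1ABC,A,A17G,1.5\n")
        records, rejected = read_mutation_table(p)
        assert not rejected
        assert records[0].ddg_exp == 1.5
        assert str(records[0].mutation) == "A17G"

    def test_destabilizing_positive_flips_sign(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("pdb_id,chain,mutation,ddg\n1ABC,A,A17G,1.5\n")
        records, _ = read_mutation_table(
            p, sign_convention="destabilizing_positive")
        assert records[0].ddg_exp == -1.5

    def test_malformed_mutation_rejected_with_line(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("pdb_id,chain,mutation,ddg\n"
                     "1ABC,A,A17X,1.5\n1ABC,A,A18G,0.3\n")
        records, rejected = read_mutation_table(p)
        assert len(records) == 1
        assert rejected[0][0] == 2

    def test_schema_error_lists_headers(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("foo,bar\n1,2\n")
        with pytest.raises(SchemaError, match="foo"):
            read_mutation_table(p)

    def test_tsv_accepted(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("pdb_id\tchain\tmutation\tddg\n1ABC\tA\tA17G\t1.5\n")
        records, _ = read_mutation_table(p)
        assert len(records) == 1


class TestAugmentReverse:
    def test_doubles_and_negates(self):
        fwd = [make_record(i, ddg=1.5) for i in range(3)]
        out, warnings = augment_reverse(fwd)
        assert len(out) == 6 and not warnings
        rev = out[1]
        assert rev.direction == "reverse"
        assert rev.ddg_exp == -1.5
        assert rev.mutation.wild_aa == "G" and rev.mutation.mutant_aa == "A"
        assert rev.group_key == out[0].group_key

    def test_zero_ddg_stays_zero(self):
        out, _ = augment_reverse([make_record(ddg=0.0)])
        assert out[1].ddg_exp == 0.0
        assert not np.signbit(out[1].ddg_exp)

    def test_duplicates_dropped_with_warning(self):
        fwd = [make_record(0), make_record(0)]
        out, warnings = augment_reverse(fwd)
        assert len(out) == 2 and len(warnings) == 1

    def test_involution_reproduces_forward_half(self):
        fwd = [make_record(i, ddg=float(i) - 1.0) for i in range(5)]
        out, _ = augment_reverse(fwd)
        reverses = [r for r in out if r.direction == "reverse"]
        recovered = [r.reversed_record() for r in reverses]
        forwards = [r for r in out if r.direction == "forward"]
        assert [(str(r.mutation), r.ddg_exp) for r in recovered] == \
               [(str(r.mutation), r.ddg_exp) for r in forwards]

    def test_non_forward_input_rejected(self):
        with pytest.raises(ValueError):
            augment_reverse([make_record(direction="reverse")])


class TestMakeSplits:
    def test_kfold_partition(self):
        records, _ = augment_reverse([make_record(i) for i in range(53)])
        folds = make_splits(records, mode="kfold", k=10, seed=4)
        assert sum(len(f) for f in folds) == len(records)
        seen = set()
        for f in folds:
            ids = {id(r) for r in f}
            assert not ids & seen
            seen |= ids

    def test_groups_never_straddle_folds(self):
        records, _ = augment_reverse([make_record(i) for i in range(40)])
        folds = make_splits(records, mode="kfold", k=7, seed=1)
        fold_of_group = {}
        for fi, fold in enumerate(folds):
            for r in fold:
                fold_of_group.setdefault(r.group_key, set()).add(fi)
        assert all(len(v) == 1 for v in fold_of_group.values())

    def test_deterministic_per_seed(self):
        records = [make_record(i) for i in range(30)]
        f1 = make_splits(records, k=5, seed=9)
        f2 = make_splits(records, k=5, seed=9)
        assert [[str(r.mutation) for r in f] for f in f1] == \
               [[str(r.mutation) for r in f] for f in f2]

    def test_fold_sizes_balanced(self):
        records = [make_record(i) for i in range(101)]
        folds = make_splits(records, k=10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_k_exceeding_groups_rejected(self):
        with pytest.raises(ValueError):
            make_splits([make_record(0)], k=10)

    def test_train_blind_split(self):
        records = [make_record(i) for i in range(100)]
        train, blind = make_splits(records, mode="train_blind", seed=3)
        assert len(train) + len(blind) == 100
        assert not {r.group_key for r in train} & {r.group_key for r in blind}


class TestClassifyStability:
    @pytest.mark.parametrize("ddg,expected", [
        (0.0, "stabilizing"),
        (3.2, "stabilizing"),
        (-0.01, "destabilizing"),
    ])
    def test_boundary_rule(self, ddg, expected):
        assert classify_stability(ddg) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_stability(float("nan"))


class TestEvaluate:
    def test_perfect_predictions(self):
        records = [make_record(i, ddg=float(i)) for i in range(10)]
        rep = evaluate([float(i) for i in range(10)], records)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.rmse == 0.0

    def test_constant_shift(self):
        records = [make_record(i, ddg=float(i)) for i in range(10)]
        rep = evaluate([float(i) + 1.0 for i in range(10)], records)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        pred = np.array([1.0, 2, 3, 4, 5])
        exp = np.array([2.0, 2, 4, 4, 6])
        records = [make_record(i, ddg=e) for i, e in enumerate(exp)]
        rep = evaluate(pred, records, outlier_fraction=0.2)
        # hand formulas
        r_hand = (np.mean(pred * exp) - pred.mean() * exp.mean()) / (
            pred.std() * exp.std())
        assert rep.pearson_r == pytest.approx(r_hand, rel=1e-12)
        assert rep.rmse == pytest.approx(np.sqrt(np.mean((pred - exp) ** 2)),
                                         rel=1e-12)
        assert rep.n_trimmed == 4

    def test_trimming_never_increases_rmse(self):
        rng = np.random.default_rng(0)
        exp = rng.normal(size=200)
        pred = exp + rng.normal(scale=0.7, size=200)
        records = [make_record(i, ddg=e) for i, e in enumerate(exp)]
        rep = evaluate(pred, records)
        assert rep.rmse_trimmed <= rep.rmse
        assert rep.n_trimmed == 180

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        exp = rng.normal(size=50)
        pred = exp + rng.normal(scale=0.5, size=50)
        records = [make_record(i, ddg=e) for i, e in enumerate(exp)]
        rep1 = evaluate(pred, records)
        order = rng.permutation(50)
        rep2 = evaluate(pred[order], [records[i] for i in order])
        assert rep1.pearson_r == pytest.approx(rep2.pearson_r, rel=1e-12)
        assert rep1.rmse == pytest.approx(rep2.rmse, rel=1e-12)

    def test_direction_and_class_subreports(self):
        fwd = [make_record(i, ddg=float(i) - 2.0) for i in range(6)]
        records, _ = augment_reverse(fwd)
        pred = [r.ddg_exp + 0.1 for r in records]
        rep = evaluate(pred, records)
        assert set(rep.subreports) == {"forward", "reverse", "stabilizing",
                                       "destabilizing"}
        assert rep.subreports["forward"].n == 6
        assert rep.subreports["reverse"].n == 6

    def test_zero_variance_marked_undefined(self):
        records = [make_record(i, ddg=1.0) for i in range(5)]
        rep = evaluate([1.0] * 5, records)
        assert np.isnan(rep.pearson_r)


class TestCompareMethods:
    def test_equal_correlations_give_p_one(self):
        p = compare_methods({"a": (0.5, 400), "b": (0.5, 400)})
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_large_gap_significant(self):
        p = compare_methods({"a": (0.9, 500), "b": (0.0, 500)})
        assert p.loc["a", "b"] < 0.001
        # closed-form cross-check
        z = (np.arctanh(0.9) - np.arctanh(0.0)) / np.sqrt(2.0 / 497.0)
        from scipy.stats import norm
        assert p.loc["a", "b"] == pytest.approx(2 * norm.sf(abs(z)), rel=1e-9)

    def test_symmetry(self):
        p = compare_methods({"a": (0.7, 300), "b": (0.6, 300)})
        assert p.loc["a", "b"] == p.loc["b", "a"]

    def test_perfect_correlation_clamped(self):
        p = compare_methods({"a": (1.0, 100), "b": (0.5, 100)})
        assert np.isfinite(p.loc["a", "b"])


class TestSyntheticGenerators:
    def test_mutation_table_composition(self):
        records = synthetic_mutation_table(seed=0)
        assert len(records) == 2648
        stab = sum(1 for r in records if r.ddg_exp >= 0)
        assert stab == 602
        assert len(records) - stab == 2046

    def test_mutation_table_deterministic(self):
        a = synthetic_mutation_table(n_mutations=100, n_stabilizing=20, seed=3)
        b = synthetic_mutation_table(n_mutations=100, n_stabilizing=20, seed=3)
        assert [(r.pdb_id, str(r.mutation), r.ddg_exp) for r in a] == \
               [(r.pdb_id, str(r.mutation), r.ddg_exp) for r in b]

    def test_feature_table_signal(self):
        x, y = synthetic_feature_table(n_rows=500, seed=1)
        resid = y - (0.8 * x["f0"] - 0.5 * x["f1"])
        assert resid.std() == pytest.approx(0.2, abs=0.05)
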