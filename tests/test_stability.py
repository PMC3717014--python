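import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import refstab as rs
from _oracles import cv_bruteforce, m_values_bruteforce
from conftest import random_rq

rq_matrices = st.integers(min_value=0, max_value=10_000).map(
    lambda s: random_rq(np.random.default_rng(s),
                        n_genes=3 + s % 4, n_samples=4 + s % 5)
)


class TestPairwiseVariation:
    def test_constant_ratio_gives_zero(self):
        frame = pd.DataFrame([[1.0, 2.0], [2.0, 4.0]], index=["A", "B"])
        v = rs.pairwise_variation_matrix(frame)
        assert v.loc["A", "B"] == pytest.approx(0.0)

    def test_hand_derived_value(self, micro_rq):
        # log2 ratios of A vs C over the two samples are (0, -2): SD sqrt(2)
        v = rs.pairwise_variation_matrix(micro_rq)
        assert v.loc["A", "C"] == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert np.allclose(v.values, v.values.T)
        assert np.allclose(np.diag(v.values), 0.0)

    def test_rejects_nonpositive_rq(self):
        frame = pd.DataFrame([[1.0, -2.0], [2.0, 4.0]])
        with pytest.raises(ValueError):
            rs.pairwise_variation_matrix(frame)

    @pytest.mark.parametrize("shape", [(1, 5), (3, 1)])
    def test_minimum_size(self, shape):
        frame = pd.DataFrame(np.ones(shape))
        with pytest.raises(ValueError):
            rs.pairwise_variation_matrix(frame)


class TestMValues:
    def test_micro_example(self, micro_rq):
        m = rs.m_values(micro_rq)
        assert m["A"] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        assert m["B"] == pytest.approx(0.7071, abs=1e-4)
        assert m["C"] == pytest.approx(1.4142, abs=1e-4)

    def test_two_genes_share_their_single_v(self):
        frame = pd.DataFrame([[1.0, 2.0, 1.5], [1.0, 3.0, 1.0]], index=["A", "B"])
        m = rs.m_values(frame)
        assert m["A"] == pytest.approx(m["B"])

    def test_identical_columns_all_zero(self):
        frame = pd.DataFrame(np.tile([[1.0, 5.0, 2.0]], (4, 1)))
        assert (rs.m_values(frame) == 0).all()

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            rs.m_values(pd.DataFrame([[1.0, 2.0]]))

    @given(rq_matrices)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_oracle_equivalence(self, frame):
        m = rs.m_values(frame)
        oracle = m_values_bruteforce(frame)
        for g in frame.index:
            assert m[g] == pytest.approx(oracle[g], abs=1e-12)

    @given(rq_matrices, st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_per_sample_and_per_gene_scaling(self, frame, seed):
        rng = np.random.default_rng(seed)
        c_s = np.exp(rng.normal(size=frame.shape[1]))
        d_g = np.exp(rng.normal(size=frame.shape[0]))
        scaled = frame * c_s[None, :] * d_g[:, None]
        np.testing.assert_allclose(rs.m_values(scaled), rs.m_values(frame), atol=1e-9)

    def test_dropping_worst_gene_never_raises_remaining_pair_variation_mean(self):
        # definition-level sanity on random instances
        for seed in range(10):
            frame = random_rq(np.random.default_rng(seed), 5, 8)
            v = rs.pairwise_variation_matrix(frame)
            worst = rs.m_values(frame).idxmax()
            rest = [g for g in frame.index if g != worst]
            before = v.loc[rest, rest].values[np.triu_indices(len(rest), 1)].mean()
            after_v = rs.pairwise_variation_matrix(frame.loc[rest])
            after = after_v.values[np.triu_indices(len(rest), 1)].mean()
            assert after == pytest.approx(before, abs=1e-12)


class TestCV:
    def test_hand_value(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        assert rs.coefficient_of_variation(frame)["g"] == pytest.approx(0.5)

    def test_constant_row_zero(self):
        frame = pd.DataFrame([[3.3] * 5], index=["g"])
        assert rs.coefficient_of_variation(frame)["g"] == 0.0

    @given(rq_matrices, st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_per_gene_scaling_invariant_per_sample_not(self, frame, seed):
        rng = np.random.default_rng(seed)
        d_g = np.exp(rng.normal(size=frame.shape[0]))
        np.testing.assert_allclose(
            rs.coefficient_of_variation(frame * d_g[:, None]),
            rs.coefficient_of_variation(frame),
            atol=1e-12,
        )
        # a non-uniform per-sample scaling must change at least one CV
        c_s = np.exp(np.linspace(0.0, 2.0, frame.shape[1]))
        changed = rs.coefficient_of_variation(frame * c_s[None, :])
        assert not np.allclose(changed, rs.coefficient_of_variation(frame), atol=1e-6)

    @given(rq_matrices)
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_oracle_equivalence(self, frame):
        cv = rs.coefficient_of_variation(frame)
        oracle = cv_bruteforce(frame)
        for g in frame.index:
            assert cv[g] == pytest.approx(oracle[g], abs=1e-12)


class TestClassify:
    def _report(self, m, cv, policy=None):
        genes = [f"g{i}" for i in range(len(m))]
        return rs.classify(pd.Series(m, index=genes), pd.Series(cv, index=genes), policy)

    def test_cv_gate_rejects_despite_good_m(self):
        # an acceptable M (0.8 < 1) does not rescue a 61% CV
        rep = self._report([0.8], [0.61])
        row = rep.iloc[0]
        assert row["passes_m"] and not row["passes_cv"] and not row["validated"]

    def test_both_gates_pass(self):
        row = self._report([0.52], [0.30]).iloc[0]
        assert row["validated"]

    def test_strict_inequality_at_cutoffs(self):
        row = self._report([1.0], [0.50]).iloc[0]
        assert not row["passes_m"] and not row["passes_cv"]

    def test_homogeneous_policy_tightens_gates(self):
        policy = rs.CutoffPolicy.homogeneous()
        assert (policy.m_cutoff, policy.cv_cutoff) == (0.5, 0.25)
        row = self._report([0.6], [0.30], policy).iloc[0]
        assert not row["validated"]

    def test_report_serialization_includes_thresholds(self, tmp_path):
        from refstab.stability import write_stability_report

        rep = self._report([0.4, 1.2], [0.2, 0.6])
        p = tmp_path / "stab.csv"
        write_stability_report(rep, p)
        text = p.read_text()
        assert text.startswith("# m_cutoff=1 cv_cutoff=0.5")
        back = pd.read_csv(p, comment="#", index_col="gene")
        assert back["validated"].tolist() == [True, False]


class TestNormalizedCV:
    def test_normalized_cv_differs_and_content_shift_cancels(self, study_rq):
        raw = rs.coefficient_of_variation(study_rq)
        norm = rs.coefficient_of_variation(study_rq, normalize_to=study_rq.genes)
        assert not np.allclose(raw, norm)
        # normalizing to all genes removes the sample-wide content shift,
        # so the normalized CV is typically smaller
        assert norm.mean() < raw.mean()

    def test_unknown_reference_gene_rejected(self, micro_rq):
        with pytest.raises(KeyError, match="nope"):
            rs.coefficient_of_variation(micro_rq, normalize_to=["nope"])
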