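import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tensorfe.decomposition import HosvdResult, hosvd
from tensorfe.pattern_select import (
    PatternLabel,
    choose_auxiliary_components,
    choose_gene_component,
    classify_condition_vector,
    constancy_score,
    select_interesting_condition_components,
)
from tensorfe.synthetic import SyntheticSpec, generate
from tensorfe.tensorize import ExpressionTensor, build_tensor, standardize


def _result_with(condition=None, replicate=None, hour=None, core=None):
    """HosvdResult stub with given factors (identity defaults)."""
    condition = np.eye(3) if condition is None else condition
    replicate = np.eye(5) if replicate is None else replicate
    hour = np.eye(5) if hour is None else hour
    r1 = 4
    core = np.zeros((r1, 3, 5, 5)) if core is None else core
    gene = np.eye(10)[:, :r1]
    return HosvdResult(
        factors=[gene, condition, replicate, hour],
        core=core,
        gene_ids=[f"g{i}" for i in range(10)],
    )


class TestClassify:
    @pytest.mark.parametrize(
        "vec,label",
        [
            ((0.577, 0.577, 0.577), PatternLabel.CONSTANT),
            ((0.9, -0.3, -0.32), PatternLabel.ALTERED_NOT_RECOVERED),
            ((0.0, 1.0, -1.0), PatternLabel.OVERSHOOT),
            ((0.2, -0.9, 0.65), PatternLabel.ALTERED_RECOVERED),
            ((0.0, 1.0, 0.05), PatternLabel.ALTERED_RECOVERED),
            ((0.0, 0.05, -1.0), PatternLabel.OTHER),  # RS moves, SD does not
        ],
    )
    def test_pattern_rules(self, vec, label):
        assert classify_condition_vector(np.array(vec)) is label

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            classify_condition_vector(np.zeros(3))

    @given(
        st.tuples(*[st.floats(-2, 2) for _ in range(3)]).filter(
            lambda v: sum(x * x for x in v) > 1e-4
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_label_invariant_under_global_sign_flip(self, vec):
        u = np.array(vec)
        assert classify_condition_vector(u) is classify_condition_vector(-u)

    @given(
        st.tuples(*[st.floats(-2, 2) for _ in range(3)]).filter(
            lambda v: sum(x * x for x in v) > 1e-4
        ),
        st.floats(0.1, 50),
    )
    @settings(max_examples=200, derandomize=True)
    def test_label_scale_invariant(self, vec, c):
        u = np.array(vec)
        assert classify_condition_vector(u) is classify_condition_vector(c * u)


class TestConstancy:
    def test_constant_vector_scores_one(self):
        assert constancy_score(np.full(5, -2.3)) == pytest.approx(1.0)

    def test_zero_sum_scores_zero(self):
        assert constancy_score(np.array([1.0, -1.0, 0.0])) == pytest.approx(0.0)

    def test_unit_axis_vector(self):
        assert constancy_score(np.array([1.0, 0, 0])) == pytest.approx(1 / np.sqrt(3))

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=8).filter(
            lambda v: sum(x * x for x in v) > 1e-4
        ),
        st.floats(0.01, 100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance(self, vec, c):
        u = np.array(vec)
        assert constancy_score(c * u) == pytest.approx(constancy_score(u), abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            constancy_score(np.zeros(4))


class TestChooseAuxiliary:
    def test_constant_columns_chosen(self):
        rep = np.column_stack([np.full(5, 1 / np.sqrt(5)), *np.eye(5)[:, :4].T.reshape(4, 5)])
        # build an orthonormal-ish factor: first column constant
        rep, _ = np.linalg.qr(rep)
        hour = np.eye(5)
        res = _result_with(replicate=rep, hour=hour)
        l3, l4 = choose_auxiliary_components(res)
        assert l3 == 1
        assert l4 == 1  # identity columns tie at 1/sqrt(5); first wins

    def test_tie_broken_to_smaller_index(self):
        factor = np.eye(5)  # all columns have equal constancy 1/sqrt(5)
        res = _result_with(replicate=factor)
        l3, _ = choose_auxiliary_components(res)
        assert l3 == 1


class TestChooseGeneComponent:
    def test_argmax_of_fiber(self):
        core = np.zeros((4, 3, 5, 5))
        core[0, 1, 0, 0] = 1.0
        core[1, 1, 0, 0] = -5.0
        core[2, 1, 0, 0] = 4.0
        choice = choose_gene_component(_result_with(core=core), l2=2, l3=1, l4=1)
        assert choice.l1 == 2
        assert choice.g_value == -5.0

    def test_search_limit_restricts_scan(self):
        core = np.zeros((4, 3, 5, 5))
        core[0, 0, 0, 0] = 1.0
        core[3, 0, 0, 0] = 9.0
        choice = choose_gene_component(
            _result_with(core=core), l2=1, l3=1, l4=1, search_limit=2
        )
        assert choice.l1 == 1

    def test_all_zero_fiber_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            choose_gene_component(_result_with(), l2=1, l3=1, l4=1)

    def test_bad_search_limit_rejected(self):
        with pytest.raises(ValueError, match="search_limit"):
            choose_gene_component(_result_with(), l2=1, l3=1, l4=1, search_limit=0)

    def test_rank1_planted_condition_pattern(self):
        # tensor a (x) p (x) 1 (x) 1 with p the not-recovered contrast:
        # the whole structure sits in gene component 1 at the l2 matching p
        rng = np.random.default_rng(7)
        a = rng.normal(size=30)
        a /= np.linalg.norm(a)
        p = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
        ones_k = np.ones(4) / 2.0
        ones_m = np.ones(2) / np.sqrt(2)
        x = 5.0 * np.einsum("i,j,k,m->ijkm", a, p, ones_k, ones_m)
        t = ExpressionTensor(
            values=x,
            observed=np.ones((3, 4, 2), dtype=bool),
            gene_ids=[f"g{i}" for i in range(30)],
            standardized=True,
        )
        res = hosvd(t)
        # condition component 1 carries p (up to sign)
        assert abs(abs(np.dot(res.condition_factor[:, 0], p)) - 1) < 1e-10
        choice = choose_gene_component(res, l2=1, l3=1, l4=1, search_limit=4)
        assert choice.l1 == 1
        assert abs(abs(np.dot(res.gene_factor[:, 0], a)) - 1) < 1e-10


class TestSelectInteresting:
    def test_study_shapes_flagged_in_order(self):
        factor = np.column_stack(
            [
                np.array([0.77, 0.50, 0.39]),  # baseline-like: excluded
                np.array([0.63, -0.53, -0.57]),  # altered, stays altered
                np.array([0.08, -0.69, 0.72]),  # overshoot
            ]
        )
        got = select_interesting_condition_components(_result_with(condition=factor))
        assert got == [
            (2, PatternLabel.ALTERED_NOT_RECOVERED),
            (3, PatternLabel.OVERSHOOT),
        ]

    def test_identity_factor_labels_by_rule(self):
        got = select_interesting_condition_components(_result_with(condition=np.eye(3)))
        # (1,0,0): SD and RS both drop, RS tracks SD -> not recovered;
        # (0,1,0): SD altered, RS back at baseline -> recovered;
        # (0,0,1): SD unmoved -> not flagged (other)
        assert got == [
            (1, PatternLabel.ALTERED_NOT_RECOVERED),
            (2, PatternLabel.ALTERED_RECOVERED),
        ]

    def test_one_signed_columns_never_flagged(self):
        factor = np.column_stack(
            [
                np.array([0.9, 0.3, 0.32]),
                np.array([0.3, 0.9, 0.31]),
                np.array([0.1, 0.2, 0.9]),
            ]
        )
        assert select_interesting_condition_components(_result_with(condition=factor)) == []


class TestPipelinePatternRecovery:
    @pytest.mark.parametrize(
        "pattern",
        [PatternLabel.ALTERED_NOT_RECOVERED, PatternLabel.OVERSHOOT],
    )
    def test_single_planted_pattern_recovered_once(self, pattern):
        """A 3-sigma planted pattern is flagged at exactly one component."""
        for seed in range(20):
            spec = SyntheticSpec(
                n_genes=4000, planted=[(pattern, 0.05, 3.0)], seed=seed
            )
            matrix, design, _ = generate(spec)
            res = hosvd(standardize(build_tensor(matrix, design)))
            flagged = select_interesting_condition_components(res)
            assert [l2 for l2, lab in flagged if lab is pattern] != []
            assert sum(lab is pattern for _, lab in flagged) == 1
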