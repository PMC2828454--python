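import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pncca import (
    classify_effect,
    restrict_quantification,
    scale_matrix,
    scale_snp,
    transform_variable,
    unrestricted_quantification,
)
from pncca.containers import MISSING, DegenerateDataError


def monotone_oracle(raw, counts):
    """Exhaustive minimizer of the count-weighted SSE over monotone triples.

    Any optimum pools adjacent categories to their weighted mean, so
    enumerating the block partitions of 3 ordered elements (both
    directions) and keeping feasible candidates is exact.
    """
    raw = np.asarray(raw, float)
    w = np.asarray(counts, float)

    def pooled(blocks):
        out = np.empty(3)
        for blk in blocks:
            idx = list(blk)
            out[idx] = (w[idx] * raw[idx]).sum() / max(w[idx].sum(), 1e-300)
        return out

    partitions = [
        [(0,), (1,), (2,)],
        [(0, 1), (2,)],
        [(0,), (1, 2)],
        [(0, 1, 2)],
    ]
    best, best_sse = None, np.inf
    for direction in (1, -1):
        for part in partitions:
            cand = pooled(part)
            d = np.diff(direction * cand)
            if (d < -1e-12).any():
                continue
            sse = float((w * (raw - cand) ** 2).sum())
            if sse < best_sse - 1e-15:
                best, best_sse = cand, sse
    return best, best_sse


class TestUnrestricted:
    def test_category_means(self):
        q = unrestricted_quantification(np.array([0, 0, 1, 1]), np.array([1.0, 1, -1, -1]))
        assert q == {0: 1.0, 1: -1.0}

    def test_orthogonal_target_gives_zero(self):
        codes = np.array([0, 0, 1, 1, 2, 2])
        target = np.array([1.0, -1, 1, -1, 1, -1])
        q = unrestricted_quantification(codes, target)
        assert all(abs(v) < 1e-12 for v in q.values())

    def test_matches_normal_equations(self, rng):
        codes = rng.integers(0, 3, 200)
        target = rng.standard_normal(200)
        target -= target.mean()
        q = unrestricted_quantification(codes, target)
        G = np.eye(3)[codes]
        ref = np.linalg.solve(G.T @ G, G.T @ target)
        np.testing.assert_allclose([q[k] for k in range(3)], ref, atol=1e-10)

    def test_empty_category_rejected(self):
        with pytest.raises(DegenerateDataError):
            unrestricted_quantification(np.full(5, MISSING), np.zeros(5))


class TestRestrict:
    @pytest.mark.parametrize(
        "raw,counts,expected,effect,direction",
        [
            ((-1, 0, 1), (5, 5, 5), (-1, 0, 1), "additive", "ascending"),
            ((0, 0, 1), (5, 5, 5), (0, 0, 1), "recessive", "ascending"),
            ((1, 0, -1), (5, 5, 5), (1, 0, -1), "additive", "descending"),
        ],
    )
    def test_printed_patterns(self, raw, counts, expected, effect, direction):
        restricted, eff, direc = restrict_quantification(raw, counts)
        np.testing.assert_allclose(restricted, expected)
        assert (eff, direc) == (effect, direction)

    def test_violation_pooled_to_weighted_mean(self):
        restricted, effect, _ = restrict_quantification((0.0, 1.0, 0.2), (10, 5, 5))
        ref, _ = monotone_oracle((0.0, 1.0, 0.2), (10, 5, 5))
        np.testing.assert_allclose(restricted, ref, atol=1e-10)

    def test_idempotent(self, rng):
        for _ in range(50):
            raw = rng.standard_normal(3)
            counts = rng.integers(1, 30, 3)
            once, *_ = restrict_quantification(raw, counts)
            twice, *_ = restrict_quantification(once, counts)
            np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(300):
            raw = rng.standard_normal(3)
            counts = rng.integers(1, 50, 3)
            restricted, *_ = restrict_quantification(raw, counts)
            ref, ref_sse = monotone_oracle(raw, counts)
            w = counts.astype(float)
            sse = float((w * (raw - restricted) ** 2).sum())
            assert sse <= ref_sse + 1e-10

    def test_projection_never_beats_unrestricted(self, rng):
        # restricted scores fit the target no better than the raw means
        for _ in range(50):
            codes = rng.integers(0, 3, 100)
            target = rng.standard_normal(100)
            target -= target.mean()
            qmap = unrestricted_quantification(codes, target)
            raw = np.array([qmap[k] for k in range(3)])
            counts = np.bincount(codes, minlength=3)
            restricted, *_ = restrict_quantification(raw, counts)
            sse_raw = ((target - raw[codes]) ** 2).sum()
            sse_res = ((target - restricted[codes]) ** 2).sum()
            assert sse_res >= sse_raw - 1e-10
            if (np.diff(raw) >= 0).all() or (np.diff(raw) <= 0).all():
                assert sse_res == pytest.approx(sse_raw)


class TestClassify:
    @pytest.mark.parametrize(
        "quants,expected",
        [
            ((0, 0, 1), "recessive"),
            ((0, 1, 1), "dominant"),
            ((0, 0.4, 1), "additive"),
            ((0.3, 0.3, 0.3), "constant"),
            ((1, 1, 0), "recessive"),  # wildtype/het tied, hom apart
            ((1, 0, 0), "dominant"),   # het/hom tied, wildtype apart
        ],
    )
    def test_patterns(self, quants, expected):
        assert classify_effect(quants) == expected

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            classify_effect((0, 1, 0.5))


class TestTransform:
    def test_standardized_output(self, rng):
        codes = rng.integers(0, 3, 500)
        x = transform_variable(codes, np.array([-1.0, 0.0, 1.0]))
        assert x.mean() == pytest.approx(0, abs=1e-12)
        assert x.std() == pytest.approx(1, abs=1e-12)

    def test_constant_quantification_gives_zero_column(self):
        codes = np.array([0, 1, 2, 1])
        np.testing.assert_array_equal(transform_variable(codes, np.full(3, 0.7)), 0)

    def test_two_category_column_is_affine_in_indicator(self, rng):
        codes = rng.integers(0, 2, 200)
        target = rng.standard_normal(200)
        sol = scale_snp(codes, target - target.mean())
        if sol.effect_type != "constant":
            r = np.corrcoef(sol.transformed_column, codes)[0, 1]
            assert abs(abs(r) - 1) < 1e-10


class TestScaleSnp:
    def test_heterozygote_betweenness(self, rng):
        for _ in range(100):
            codes = rng.integers(0, 3, 60)
            target = rng.standard_normal(60)
            sol = scale_snp(codes, target - target.mean())
            c0, c1, c2 = sol.quantifications
            assert min(c0, c2) - 1e-12 <= c1 <= max(c0, c2) + 1e-12

    def test_collapsed_snp_reported_dominant_coded(self, rng):
        codes = rng.integers(0, 2, 300)  # hom-rare collapsed into het
        target = codes + 0.1 * rng.standard_normal(300)
        sol = scale_snp(codes, target - target.mean())
        assert sol.effect_type == "dominant"

    def test_matrix_path_matches_per_snp_path(self, rng):
        codes = rng.integers(0, 3, (150, 40)).astype(np.int8)
        codes[:, 5] = rng.integers(0, 2, 150)          # no hom-rare observed
        codes[:, 6] = np.where(codes[:, 6] == 1, 0, codes[:, 6])  # no het observed
        target = rng.standard_normal(150)
        target = (target - target.mean()) / target.std()
        X, quants = scale_matrix(codes, target)
        for j in range(40):
            sol = scale_snp(codes[:, j], target)
            np.testing.assert_allclose(X[:, j], sol.transformed_column, atol=1e-9)
            np.testing.assert_allclose(quants[j], sol.std_quantifications, atol=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    raw=st.tuples(*[st.floats(-3, 3) for _ in range(3)]),
    counts=st.tuples(*[st.integers(1, 40) for _ in range(3)]),
)
def test_pava_is_exhaustive_minimizer(raw, counts):
    restricted, _, _ = restrict_quantification(raw, counts)
    ref, ref_sse = monotone_oracle(raw, counts)
    w = np.asarray(counts, float)
    sse = float((w * (np.asarray(raw) - restricted) ** 2).sum())
    assert sse <= ref_sse + 1e-9
    d = np.diff(restricted)
    assert (d >= -1e-12).all() or (d <= 1e-12).all()


def test_scaling_table_roundtrip(tmp_path, rng):
    codes = rng.integers(0, 3, (100, 3)).astype(np.int8)
    target = rng.standard_normal(100)
    target = (target - target.mean()) / target.std()
    sols = [scale_snp(codes[:, j], target, snp_id=f"rs{j}") for j in range(3)]
    from pncca.scaling import solutions_to_table, table_to_solutions

    path = tmp_path / "scaling.csv"
    solutions_to_table(sols, path)
    back = table_to_solutions(path)
    for a, b in zip(sols, back):
        assert a.snp_id == b.snp_id
        assert a.effect_type == b.effect_type
        np.testing.assert_allclose(a.std_quantifications, b.std_quantifications, atol=1e-10)
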