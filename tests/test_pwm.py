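"""Weight-map training, weighted matching, and template files."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from veinmap.exceptions import (
    DegenerateTemplateError,
    DegenerateTemplateWarning,
    DegenerateWeightsError,
    IncompatibleCodesError,
    InsufficientTrainingError,
)
from veinmap.features import BinaryCode
from veinmap.pwm import (
    WeightMap,
    achievable_weights,
    decide,
    hamming_distance,
    load_template,
    make_matcher,
    pbbm_similarity,
    save_template,
    train_pbbm,
    train_pwm,
    train_template,
    weighted_similarity,
)


def codes_from_rows(rows, tag="lbp"):
    return [BinaryCode.from_bits(np.asarray(r), tag) for r in rows]


class TestHammingDistance:
    def test_identity_and_complement(self, random_codes):
        (a,) = random_codes(1, 100)
        assert hamming_distance(a, a) == 0.0
        assert hamming_distance(a, a.complement()) == 1.0

    def test_hand_example(self):
        a, b = codes_from_rows([[1, 0, 1, 1, 0], [1, 1, 1, 0, 0]])
        assert hamming_distance(a, b) == pytest.approx(2 / 5)

    def test_mismatch_rejected(self, random_codes):
        a = random_codes(1, 32)[0]
        b = random_codes(1, 40)[0]
        with pytest.raises(IncompatibleCodesError):
            hamming_distance(a, b)


class TestTrainPwm:
    @pytest.mark.parametrize(
        "k,m1,expected",
        [
            (8, 0, 1.0),
            (8, 1, 0.5625),
            (8, 2, 0.25),
            (8, 3, 0.0625),
            (8, 4, 0.0),
            (2, 1, 0.0),
            (2, 0, 1.0),
            (2, 2, 1.0),
            (6, 3, 0.0),
        ],
    )
    def test_weight_from_agreement_count(self, k, m1, expected):
        rows = [[1] if i < m1 else [0] for i in range(k)]
        wm = train_pwm(codes_from_rows(rows), "c")
        assert wm.weights[0] == pytest.approx(expected)
        assert wm.k_train == k

    def test_identical_codes_all_weight_one(self, random_codes):
        code = random_codes(1, 50)[0]
        wm = train_pwm([code] * 5, "c")
        assert (wm.weights == 1.0).all()

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(10):
            k = int(rng.integers(2, 8))
            rows = rng.integers(0, 2, (k, 20))
            wm = train_pwm(codes_from_rows(rows), "c")
            assert np.allclose(wm.weights, oracles.naive_pwm_double_sum(rows))

    def test_single_code_rejected(self, random_codes):
        with pytest.raises(InsufficientTrainingError):
            train_pwm(random_codes(1, 16), "c")

    def test_mixed_tags_rejected(self, random_codes):
        codes = random_codes(2, 16, "lbp") + random_codes(1, 16, "llbp-N21")
        with pytest.raises(IncompatibleCodesError):
            train_pwm(codes, "c")

    def test_achievable_weight_sets(self):
        assert np.allclose(
            achievable_weights(8), [0.0, 0.0625, 0.25, 0.5625, 1.0]
        )
        assert np.allclose(achievable_weights(2), [0.0, 1.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    k=st.integers(2, 10),
    length=st.integers(1, 40),
    seed=st.integers(0, 2**31 - 1),
)
def test_weight_bounds_and_quantization(k, length, seed):
    """Pre-normalization stability is in [0.5, 1], weights in [0, 1], and
    every weight falls in the finite set forced by the agreement counts."""
    rows = np.random.default_rng(seed).integers(0, 2, (k, length))
    wm = train_pwm(codes_from_rows(rows), "c")
    p = (wm.weights + 1.0) / 2.0
    assert (p >= 0.5).all() and (p <= 1.0).all()
    assert (wm.weights >= 0.0).all() and (wm.weights <= 1.0).all()
    allowed = achievable_weights(k)
    assert np.all(np.isclose(wm.weights[:, None], allowed[None, :]).any(axis=1))


class TestTrainPbbm:
    def test_identical_codes_full_mask(self, random_codes):
        code = random_codes(1, 30)[0]
        mask, template = train_pbbm([code] * 4, "c")
        assert mask.mask.all()
        assert template == code

    def test_k2_mask_is_xnor(self, rng):
        rows = rng.integers(0, 2, (2, 25))
        mask, _ = train_pbbm(codes_from_rows(rows), "c")
        assert np.array_equal(mask.mask, (rows[0] == rows[1]).astype(np.uint8))

    def test_matches_constancy_oracle_and_pwm_ones(self, rng):
        rows = rng.integers(0, 2, (6, 40))
        codes = codes_from_rows(rows)
        mask, _ = train_pbbm(codes, "c")
        assert np.array_equal(mask.mask, oracles.naive_best_bits(rows))
        wm = train_pwm(codes, "c")
        assert np.array_equal(mask.mask, (wm.weights == 1.0).astype(np.uint8))

    def test_empty_mask_warns(self):
        rows = [[0, 1], [1, 0]]
        with pytest.warns(DegenerateTemplateWarning):
            mask, _ = train_pbbm(codes_from_rows(rows), "c")
        assert mask.n_best == 0


class TestWeightedSimilarity:
    def test_self_match_is_one(self, random_codes, rng):
        (a,) = random_codes(1, 64)
        w = WeightMap(rng.random(64), "lbp", 4, "c")
        assert weighted_similarity(a, a, w) == pytest.approx(1.0)

    def test_all_ones_reduces_to_hamming(self, random_codes):
        a, b = random_codes(2, 128)
        w = WeightMap(np.ones(128), "lbp", 4, "c")
        assert weighted_similarity(a, b, w) == pytest.approx(
            1.0 - hamming_distance(a, b)
        )

    def test_hand_example(self):
        a, b = codes_from_rows([[1, 1, 0, 0], [1, 0, 1, 0]])
        w = WeightMap(np.array([1.0, 0.5, 0.5, 0.0]), "lbp", 2, "c")
        assert weighted_similarity(a, b, w) == pytest.approx(0.5)

    def test_matches_naive_oracle(self, rng, random_codes):
        a, b = random_codes(2, 50)
        weights = rng.random(50)
        w = WeightMap(weights, "lbp", 3, "c")
        assert weighted_similarity(a, b, w) == pytest.approx(
            oracles.naive_weighted_similarity(a.bits, b.bits, weights)
        )

    def test_zero_map_rejected(self, random_codes):
        a, b = random_codes(2, 16)
        w = WeightMap(np.zeros(16), "lbp", 2, "c")
        with pytest.raises(DegenerateWeightsError):
            weighted_similarity(a, b, w)

    def test_monotone_in_disagreements(self, rng):
        """Flipping a probe bit at a positive-weight position never
        increases the similarity."""
        bits = rng.integers(0, 2, 40)
        a = BinaryCode.from_bits(bits, "lbp")
        weights = rng.random(40)
        w = WeightMap(weights, "lbp", 3, "c")
        probe_bits = bits.copy()
        prev = weighted_similarity(a, BinaryCode.from_bits(probe_bits, "lbp"), w)
        for i in np.argsort(-weights)[:10]:
            probe_bits[i] ^= 1
            cur = weighted_similarity(a, BinaryCode.from_bits(probe_bits, "lbp"), w)
            assert cur <= prev + 1e-12
            prev = cur


class TestPbbmSimilarity:
    def test_reductions(self, random_codes, rng):
        a, b = random_codes(2, 80)
        rows = rng.integers(0, 2, (3, 80))
        codes = codes_from_rows(rows)
        mask, template = train_pbbm(codes, "c")
        if mask.n_best:
            got = pbbm_similarity(template, b, mask)
            w = WeightMap(mask.mask.astype(float), "lbp", 3, "c")
            assert got == pytest.approx(weighted_similarity(template, b, w))
        full = train_pbbm([a] * 2, "c")[0]
        assert pbbm_similarity(a, b, full) == pytest.approx(
            1.0 - hamming_distance(a, b)
        )
        assert pbbm_similarity(a, a, full) == 1.0

    def test_empty_mask_rejected(self, random_codes):
        a, b = random_codes(2, 8)
        with pytest.warns(DegenerateTemplateWarning):
            mask, _ = train_pbbm(
                codes_from_rows([[0] * 8, [1] * 8]), "c"
            )
        with pytest.raises(DegenerateTemplateError):
            pbbm_similarity(a, b, mask)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(k=st.integers(2, 7), length=st.integers(4, 30), seed=st.integers(0, 2**31 - 1))
def test_pbbm_is_special_case_of_pwm(k, length, seed):
    """Matching with the 0/1 best-bit mask as a weight map gives exactly
    the best-bit similarity, for any training set with at least one
    constant bit."""
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, 2, (k, length))
    rows[:, 0] = 1  # guarantee a nonempty mask
    codes = codes_from_rows(rows)
    mask, template = train_pbbm(codes, "c")
    probe = BinaryCode.from_bits(rng.integers(0, 2, length), "lbp")
    w = WeightMap(mask.mask.astype(float), "lbp", k, "c")
    assert pbbm_similarity(template, probe, mask) == pytest.approx(
        weighted_similarity(template, probe, w)
    )


def test_decide_is_strict():
    assert decide(0.8, 0.7)
    assert not decide(0.7, 0.7)
    assert not decide(0.0, 0.0)


def test_asymptotic_weight_recovery():
    """A bit that is 1 i.i.d. with probability pi across training codes
    gets weight -> (2 pi - 1)^2 as k grows."""
    rng = np.random.default_rng(7)
    k = 2000
    pis = np.array([0.5, 0.7, 0.9, 0.97])
    rows = (rng.random((k, pis.size)) < pis).astype(np.uint8)
    wm = train_pwm(codes_from_rows(rows), "c")
    assert np.allclose(wm.weights, (2 * pis - 1) ** 2, atol=0.05)


class TestTemplateFiles:
    def test_roundtrip_bit_exact(self, tmp_path, random_codes):
        codes = random_codes(5, 73)
        tpl = train_template(codes, "subject01")
        path = save_template(tpl, tmp_path)
        loaded = load_template(path)
        assert loaded.class_id == "subject01"
        assert loaded.operator_tag == tpl.operator_tag
        assert loaded.weight_map.k_train == 5
        assert loaded.codes == tpl.codes
        assert loaded.pbbm_template == tpl.pbbm_template
        assert np.array_equal(loaded.mask.mask, tpl.mask.mask)
        # weights survive at the stored float32 precision
        assert np.array_equal(
            loaded.weight_map.weights,
            tpl.weight_map.weights.astype("<f4").astype(np.float64),
        )
        # write -> read -> write reproduces the file byte for byte
        second = save_template(loaded, tmp_path / "again")
        assert path.read_bytes() == second.read_bytes()
        # sidecar metadata is consistent
        meta = (tmp_path / "subject01.json").read_text()
        assert '"k_train": 5' in meta

    def test_matcher_kinds(self, desk_population):
        split = desk_population.gallery.with_split_first(4)
        training = split.training()
        for kind in ("plain", "pbbm", "pwm"):
            matcher = make_matcher(kind, training)
            cid = split.class_ids[0]
            a, b = split.test_codes(cid)[:2]
            assert 0.0 <= matcher.score(cid, a, b) <= 1.0
        with pytest.raises(ValueError):
            make_matcher("nope", training)
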