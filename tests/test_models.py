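import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcrmap import (
    DNA,
    CompressorConfig,
    FiniteContextModel,
    Mixture,
    ModelSpec,
    SubstitutionTolerantModel,
    estimate_probability,
    generate_random,
    mixture_step,
    parse_model_string,
)
from lcrmap.models import build_model


class TestEstimator:
    @pytest.mark.parametrize(
        "count,total,b,size,expected",
        [
            (0, 0, 1, 4, 0.25),           # uniform under Laplace with no evidence
            (7, 7, 1, 4, 8 / 11),
            (1, 1, 1, 4, 2 / 5),
            (0, 0, 1, 20, 1 / 20),
        ],
    )
    def test_values(self, count, total, b, size, expected):
        assert estimate_probability(count, total, b, size) == pytest.approx(expected)

    def test_likelihood_limit(self):
        # large b approaches the relative-frequency estimate
        assert estimate_probability(3, 10, 1e12, 4) == pytest.approx(0.3, abs=1e-9)

    def test_monotonic_in_bet(self):
        # a dominating symbol's probability is non-decreasing in b
        probs = [estimate_probability(9, 10, b, 4) for b in (1, 2, 5, 10, 100)]
        assert probs == sorted(probs)

    @pytest.mark.parametrize("args", [(0, 0, 0.5, 4), (5, 3, 1, 4), (0, 0, 1, 1)])
    def test_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            estimate_probability(*args)


class TestFiniteContextModel:
    def _feed(self, model, seq):
        for s in seq:
            model.observe(s)

    def test_uniform_before_full_context(self):
        model = FiniteContextModel(ModelSpec(order=3), DNA)
        model.observe("A")
        assert model.predict() == [0.25] * 4

    def test_counted_distribution(self):
        # context "AA" seen with A seven times
        model = FiniteContextModel(ModelSpec(order=2), DNA)
        self._feed(model, "A" * 9)
        probs = model.predict()
        assert probs[DNA.index("A")] == pytest.approx(8 / 11)
        for s in "CGT":
            assert probs[DNA.index(s)] == pytest.approx(1 / 11)

    @pytest.mark.parametrize("spec", [
        ModelSpec(order=2),
        ModelSpec(order=3, bet=50, ir=True),
        ModelSpec(order=2, kind="stcm", tolerance=1),
    ])
    def test_distribution_sums_to_one(self, spec):
        model = build_model(spec, DNA)
        self._feed(model, generate_random(300, 5))
        assert sum(model.predict()) == pytest.approx(1.0, abs=1e-12)

    def test_ambiguous_symbol_resets_context(self):
        model = FiniteContextModel(ModelSpec(order=2), DNA)
        self._feed(model, "AAAAA")
        model.observe("N")
        assert model.predict() == [0.25] * 4  # context broken -> uniform

    def test_ir_update_uses_reverse_complement(self):
        # observing context "AT" + symbol "G" registers rc("ATG") = "CAT":
        # IR context "CA" gains symbol "T"
        model = FiniteContextModel(ModelSpec(order=2, ir=True), DNA)
        self._feed(model, "ATG")
        counts, total = model.ir_table.counts("CA")
        assert total == 1
        assert counts[DNA.index("T")] == 1

    def test_ir_lowers_bits_on_inverted_repeat(self):
        block = generate_random(400, 3)
        seq = block + DNA.reverse_complement(block)
        means = {}
        for ir in (False, True):
            mix = Mixture(CompressorConfig((ModelSpec(order=8, bet=50, ir=ir),)), DNA)
            bits = [mix.step(s) for s in seq]
            means[ir] = sum(bits[len(block):]) / len(block)
        assert means[True] < means[False]

    def test_cache_evicts_oldest_update(self):
        model = FiniteContextModel(ModelSpec(order=1, cache=3), DNA)
        self._feed(model, "AC")  # one update: (A -> C)
        assert model.table.counts("A")[1] == 1
        self._feed(model, "GT")  # two more stream steps
        self._feed(model, "A")   # 5th step: first step's update evicted
        assert model.table.counts("A")[1] == 0
        assert model.table.total_updates() <= 3

    def test_cache_equal_to_length_matches_unbounded(self):
        seq = generate_random(300, 7)
        bounded = FiniteContextModel(ModelSpec(order=4, cache=len(seq)), DNA)
        unbounded = FiniteContextModel(ModelSpec(order=4), DNA)
        for s in seq:
            assert bounded.predict() == unbounded.predict()
            bounded.observe(s)
            unbounded.observe(s)

    def test_brute_force_count_equivalence(self):
        """Per-position probabilities equal a brute-force k-mer recount."""
        for trial in range(20):
            seq = generate_random(150, 1000 + trial)
            k = 1 + trial % 3
            model = FiniteContextModel(ModelSpec(order=k), DNA)
            for i, s in enumerate(seq):
                probs = model.predict()
                if i >= k:
                    ctx = seq[i - k:i]
                    total = sum(
                        1 for j in range(k, i) if seq[j - k:j] == ctx
                    )
                    count = sum(
                        1 for j in range(k, i)
                        if seq[j - k:j] == ctx and seq[j] == s
                    )
                    expected = (count + 1.0) / (total + 4.0)
                    assert probs[DNA.index(s)] == expected
                model.observe(s)


class TestSubstitutionTolerantModel:
    def test_zero_tolerance_equals_plain_fcm(self):
        seq = generate_random(600, 9)
        fcm = FiniteContextModel(ModelSpec(order=3), DNA)
        stcm = SubstitutionTolerantModel(
            ModelSpec(order=3, kind="stcm", tolerance=0), DNA
        )
        for s in seq:
            assert fcm.predict() == stcm.predict()
            fcm.observe(s)
            stcm.observe(s)

    def test_tolerates_isolated_substitution(self):
        """After training on an A-run, the symbol following a lone C is
        predicted far better by the tolerant model than by the plain FCM."""
        stream = "A" * 10 + "AAAAACAAAA"

        def prob_trace(spec):
            model = build_model(spec, DNA)
            out = []
            for s in stream:
                out.append(model.predict()[DNA.index(s)])
                model.observe(s)
            return out

        plain = prob_trace(ModelSpec(order=2))
        tolerant = prob_trace(ModelSpec(order=2, kind="stcm", tolerance=1))
        after_c = stream.rindex("C") + 1
        assert tolerant[after_c] > plain[after_c]

    def test_window_counter_bounded_by_tolerance(self):
        spec = ModelSpec(order=4, kind="stcm", tolerance=2)
        model = SubstitutionTolerantModel(spec, DNA)
        for s in generate_random(500, 11):
            model.observe(s)
            assert model.substitutions_in_window <= spec.tolerance


class TestMixture:
    def test_single_model_quarter_probability(self):
        bits, weights = mixture_step([1.0], [0.25], [0.9])
        assert bits == pytest.approx(2.0)
        assert weights == [1.0]

    def test_two_model_blend(self):
        bits, weights = mixture_step([0.5, 0.5], [0.5, 0.25], [0.9, 0.9])
        assert bits == pytest.approx(math.log2(8 / 3))
        assert sum(weights) == pytest.approx(1.0)
        assert weights[0] > weights[1]  # better model gains weight

    @settings(derandomize=True, max_examples=30)
    @given(
        probs=st.lists(st.floats(1e-6, 1 - 1e-6), min_size=2, max_size=4),
        gamma=st.floats(0.1, 1.0),
    )
    def test_weights_remain_probability_vector(self, probs, gamma):
        weights = [1.0 / len(probs)] * len(probs)
        for _ in range(50):
            _, weights = mixture_step(weights, probs, [gamma] * len(probs))
        assert sum(weights) == pytest.approx(1.0, abs=1e-9)
        assert all(w > 0 for w in weights)


class TestModelString:
    def test_fcm_with_stcm_companion(self):
        specs = parse_model_string("13:50:1:0:0.9/5:0.8")
        assert len(specs) == 2
        fcm, stcm = specs
        assert (fcm.order, fcm.bet, fcm.ir, fcm.cache, fcm.gamma) == (13, 50, True, None, 0.9)
        assert fcm.kind == "fcm"
        assert (stcm.tolerance, stcm.gamma, stcm.kind) == (5, 0.8, "stcm")
        assert (stcm.order, stcm.bet, stcm.ir, stcm.cache) == (13, 50, True, None)

    def test_bounded_cache(self):
        (spec,) = parse_model_string("4:1:0:500:0.9")
        assert spec.cache == 500

    @pytest.mark.parametrize("text", ["13:50", "a:b:c:d:e", "2:1:0:0:0.9/5", "2:0.5:0:0:0.9"])
    def test_malformed_strings(self, text):
        with pytest.raises(ValueError):
            parse_model_string(text)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(order=0),
            dict(order=2, bet=0.5),
            dict(order=2, gamma=0.0),
            dict(order=2, cache=0),
            dict(order=2, kind="stcm", tolerance=3),
        ],
    )
    def test_spec_validation(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)
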