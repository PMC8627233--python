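"""Quantization, ROM handling, the streaming selection network, and voting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oilknn import approx_arith as aa
from oilknn import knn_core as kc


def exact_mult(a, b):
    return a * b


@pytest.fixture(scope="module")
def small_params():
    return kc.QuantizationParams(("f0", "f1", "f2", "f3"), (0.0,) * 4, (1.0,) * 4)


def random_rom(rng, n_entries=60, n_features=4, params=None):
    if params is None:
        params = kc.QuantizationParams(
            tuple(f"f{i}" for i in range(n_features)), (0.0,) * n_features, (255.0,) * n_features
        )
    entries = [
        kc.RomEntry(tuple(int(v) for v in rng.integers(0, 256, n_features)), int(rng.integers(0, 6)), i)
        for i in range(n_entries)
    ]
    return kc.Rom(entries=entries, params=params)


class TestQuantizer:
    def test_range_endpoints(self):
        p = kc.fit_quantizer(np.array([[0.0], [1.0]]), ("f",))
        q = kc.quantize(p, np.array([[0.0], [1.0]]))
        assert q[0, 0] == 0 and q[1, 0] == 255

    def test_clamping_outside_training_range(self):
        p = kc.fit_quantizer(np.array([[0.0], [1.0]]), ("f",))
        q = kc.quantize(p, np.array([[-3.0], [2.5]]))
        assert q[0, 0] == 0 and q[1, 0] == 255

    def test_midpoint_rounds_half_up_to_128(self):
        # 255 * 0.5 = 127.5 -> round-half-up -> 128
        p = kc.fit_quantizer(np.array([[0.0], [1.0]]), ("f",))
        assert kc.quantize(p, np.array([[0.5]]))[0, 0] == 128

    def test_constant_feature_raises_with_name(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        with pytest.raises(kc.DegenerateFeatureError, match="bad_feature"):
            kc.fit_quantizer(X, ("ok", "bad_feature"))

    def test_params_json_round_trip(self):
        p = kc.QuantizationParams(("a", "b"), (0.0, -1.5), (2.0, 3.5))
        assert kc.QuantizationParams.from_json(p.to_json()) == p


class TestRom:
    def test_hex_round_trip(self, small_params):
        rng = np.random.default_rng(3)
        rom = random_rom(rng, n_entries=20, params=small_params)
        restored = kc.Rom.from_hex_lines(rom.to_hex_lines(), small_params)
        assert restored.entries == rom.entries

    def test_capacity_enforced(self, small_params):
        entries = [kc.RomEntry((0, 0, 0, 0), 0, i) for i in range(601)]
        with pytest.raises(ValueError, match="capacity"):
            kc.Rom(entries=entries, params=small_params)

    def test_index_gaps_rejected(self, small_params):
        entries = [kc.RomEntry((0, 0, 0, 0), 0, 0), kc.RomEntry((0, 0, 0, 0), 0, 2)]
        with pytest.raises(ValueError, match="gaps"):
            kc.Rom(entries=entries, params=small_params)

    def test_bad_hex_line_length_rejected(self, small_params):
        with pytest.raises(ValueError, match="hex chars"):
            kc.Rom.from_hex_lines(["0011"], small_params)

    def test_build_rom_stratifies_100_per_class(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(1200, 4))
        y = np.repeat(np.arange(6), 200)
        params = kc.fit_quantizer(X, ("a", "b", "c", "d"))
        rom = kc.build_rom(X, y, params, rom_size=600, seed=5)
        assert len(rom) == 600
        counts = np.bincount(rom.labels(), minlength=6)
        assert (counts == 100).all()

    def test_build_rom_redistributes_shortfall(self):
        rng = np.random.default_rng(0)
        # class 0 has only 10 samples; the other five absorb its shortfall
        y = np.concatenate([np.zeros(10, dtype=int), np.repeat(np.arange(1, 6), 300)])
        X = rng.uniform(0, 1, size=(len(y), 4))
        params = kc.fit_quantizer(X, ("a", "b", "c", "d"))
        rom = kc.build_rom(X, y, params, rom_size=600, seed=5)
        counts = np.bincount(rom.labels(), minlength=6)
        assert len(rom) == 600
        assert counts[0] == 10
        assert counts[1:].sum() == 590
        assert (counts[1:] >= 100).all()


class TestSquaredDistance:
    def test_identical_vectors_have_zero_distance(self):
        x = (10, 200, 3, 255)
        assert kc.squared_distance(x, x, exact_mult) == 0

    def test_single_max_term(self):
        assert kc.squared_distance((255, 0, 0, 0), (0, 0, 0, 0), exact_mult) == 65025

    def test_max_term_under_carry_dropping_multiplier(self):
        """The approximate square of 255 is the audited value 60929."""
        mult = lambda a, b: aa.mult8_approx(a, b, aa.mult4_exact_decomposed)  # noqa: E731
        assert kc.squared_distance((255, 0, 0, 0), (0, 0, 0, 0), mult) == 60929

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 255), min_size=4, max_size=4),
           st.lists(st.integers(0, 255), min_size=4, max_size=4))
    def test_symmetry_for_any_multiplier(self, x, y):
        # squaring only ever sees equal operands, so symmetry holds even for
        # a non-commutative multiplier
        mult = lambda a, b: aa.mult8_approx(a, b, aa.mult4_exact_decomposed)  # noqa: E731
        assert kc.squared_distance(x, y, mult) == kc.squared_distance(y, x, mult)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kc.squared_distance((1, 2), (1, 2, 3), exact_mult)


def brute_force_top7(rom, xq, indices=None):
    """Full-sort oracle under the (distance, ROM index) tie rule."""
    feats = rom.feature_matrix()
    labels = rom.labels()
    pool = range(len(rom)) if indices is None else indices
    recs = []
    for i in pool:
        d = int(((feats[i] - np.asarray(xq, dtype=np.int64)) ** 2).sum())
        recs.append(kc.NeighborRecord(d, int(labels[i]), i))
    recs.sort(key=lambda r: (r.distance, r.index))
    return recs[: kc.K_NEIGHBORS]


class TestSnlf:
    def test_fourteen_cache_registers(self):
        state = kc.SnlfState()
        assert len(state.odd_bank) + len(state.even_bank) == 14
        assert all(r.distance == kc.MAX_DISTANCE for r in state.odd_bank + state.even_bank)

    def test_rom_of_seven_returns_everything(self):
        rng = np.random.default_rng(11)
        rom = random_rom(rng, n_entries=7)
        xq = rng.integers(0, 256, 4)
        got = kc.snlf_stream(rom, xq, exact_mult)
        assert sorted(r.index for r in got) == list(range(7))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_full_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rom = random_rom(rng, n_entries=120)
        for _ in range(10):
            xq = rng.integers(0, 256, 4)
            assert kc.snlf_stream(rom, xq, exact_mult) == brute_force_top7(rom, xq)

    def test_duplicate_distances_resolve_by_rom_index(self):
        params = kc.QuantizationParams(("f",), (0.0,), (255.0,))
        entries = [kc.RomEntry((10,), i % 6, i) for i in range(30)]  # all equidistant
        rom = kc.Rom(entries=entries, params=params)
        got = kc.snlf_stream(rom, (0,), exact_mult)
        assert [r.index for r in got] == list(range(7))

    @pytest.mark.parametrize("seed", [5, 6])
    def test_each_parity_bank_keeps_its_substream_top7(self, seed):
        rng = np.random.default_rng(seed)
        rom = random_rom(rng, n_entries=101)
        xq = rng.integers(0, 256, 4)
        state = kc.snlf_run(rom, xq, exact_mult)
        odd_idx = [i for i in range(len(rom)) if i % 2 == 0]   # first arrival = odd cycle
        even_idx = [i for i in range(len(rom)) if i % 2 == 1]
        assert sorted(state.odd_bank, key=lambda r: (r.distance, r.index)) == \
            brute_force_top7(rom, xq, odd_idx)
        assert sorted(state.even_bank, key=lambda r: (r.distance, r.index)) == \
            brute_force_top7(rom, xq, even_idx)

    def test_empty_rom_rejected(self, small_params):
        rom = kc.Rom(entries=[], params=small_params)
        with pytest.raises(ValueError, match="empty"):
            kc.snlf_stream(rom, (0, 0, 0, 0), exact_mult)


class TestVote:
    def _recs(self, labels, distances):
        return [kc.NeighborRecord(d, lab, i) for i, (lab, d) in enumerate(zip(labels, distances))]

    def test_unanimity(self):
        assert kc.vote(self._recs([3] * 7, [1] * 7)) == 3

    def test_strict_plurality(self):
        assert kc.vote(self._recs([0, 0, 0, 1, 1, 2, 2], [9] * 7)) == 0

    def test_tie_breaks_on_summed_distance(self):
        # classes 0,1,2 tie at two votes; summed distances 10, 4, 10 -> class 1
        labels = [0, 0, 1, 1, 2, 2, 3]
        distances = [5, 5, 2, 2, 5, 5, 100]
        assert kc.vote(self._recs(labels, distances)) == 1

    def test_tie_breaks_on_label_after_distance(self):
        labels = [0, 0, 1, 1, 2, 2, 3]
        distances = [2, 2, 2, 2, 2, 2, 9]  # full three-way tie -> smallest label
        assert kc.vote(self._recs(labels, distances)) == 0

    def test_requires_exactly_seven(self):
        with pytest.raises(ValueError):
            kc.vote(self._recs([0] * 6, [1] * 6))


class TestClassify:
    def test_self_query_with_plurality_premise(self):
        params = kc.QuantizationParams(("f0", "f1"), (0.0, 0.0), (255.0, 255.0))
        # 5 coincident class-2 entries plus far-away others
        entries = [kc.RomEntry((100, 100), 2, i) for i in range(5)]
        entries += [kc.RomEntry((200, 200), j % 6, 5 + j) for j in range(10)]
        rom = kc.Rom(entries=entries, params=params)
        assert kc.classify((100.0, 100.0), rom, exact_mult) == 2

    def test_agrees_with_oracle_on_random_queries(self, fitted_rom):
        rng = np.random.default_rng(42)
        lo = np.array(fitted_rom.params.mins)
        hi = np.array(fitted_rom.params.maxs)
        X = rng.uniform(lo, hi, size=(50, len(lo)))
        for x in X:
            assert kc.classify(x, fitted_rom, exact_mult) == kc.knn_oracle(x, fitted_rom)

    def test_batch_path_equals_streaming_path(self, fitted_rom, test_queries):
        X, _ = test_queries
        sq = kc.square_table(None)
        batch = kc.classify_batch(X[:40], fitted_rom, sq)
        stream = [kc.classify(x, fitted_rom, exact_mult) for x in X[:40]]
        assert batch.tolist() == stream

    def test_approximate_agreement_pinned(self, fitted_rom, test_queries):
        """Regression pin: on the fixed seed-1 query set the carry-dropping
        multiplier changes a few neighbor sets but no votes."""
        from oilknn import pipeline

        X, _ = test_queries
        exact = kc.classify_batch(X, fitted_rom, None)
        approx = kc.classify_batch(X, fitted_rom, pipeline.multiplier_square_table("table10"))
        assert float(np.mean(exact == approx)) == 1.0
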