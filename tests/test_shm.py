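"""Somatic hypermutation: load sampling, targeting weights, substitution events."""

import numpy as np
import pytest

from bcrsim.reference_model import SHMModel, fivemer_to_index
from bcrsim.shm import apply_shm, position_weights, sample_mutation_count


def _uniform_model(**overrides):
    kwargs = dict(
        freq_bin_edges=np.array([0.1, 0.1 + 1e-12]),
        freq_probs=np.array([1.0]),
        fivemer_mutability=np.ones(1024),
        region_factor={lab: 1.0 for lab in
                       ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3", "fwr4", "np")},
        substitution=None,
    )
    kwargs.update(overrides)
    return SHMModel(**kwargs)


def test_mutation_count_arithmetic():
    rng = np.random.default_rng(0)
    zero = _uniform_model(freq_bin_edges=np.array([0.0, 1e-12]))
    assert sample_mutation_count(zero, 400, rng) == 0
    fixed = _uniform_model()  # all mass at f = 0.1
    assert sample_mutation_count(fixed, 350, rng) == 35


def test_mutation_count_mean_tracks_expectation(bundle):
    rng = np.random.default_rng(1)
    n, seq_len = 10_000, 300
    draws = [sample_mutation_count(bundle.shm, seq_len, rng) for _ in range(n)]
    expected = seq_len * bundle.shm.expected_frequency()
    # 3 sigma on the mean of a bounded draw
    sigma = np.std(draws) / np.sqrt(n)
    assert abs(np.mean(draws) - expected) < 3 * sigma + 0.5


def test_uniform_model_gives_equal_interior_weights():
    model = _uniform_model()
    seq = "ACGTACGTACGTACGTACGT"
    w = position_weights(seq, ["cdr3"] * len(seq), model)
    assert np.allclose(w, w[0])


def test_hotspot_weight_ratio_in_weights():
    table = np.ones(1024)
    table[fivemer_to_index("AGCTA")] = 8.0
    model = _uniform_model(fivemer_mutability=table)
    seq = "TTAGCTATT"  # AGCTA centered at position 4
    w = position_weights(seq, ["cdr3"] * len(seq), model)
    assert w[4] == pytest.approx(8.0)
    assert w[3] == pytest.approx(1.0)


def test_position_weights_match_sliding_window_oracle(bundle):
    """Brute-force 5-mer lookup per position reproduces the weight vector."""
    seq = "ACGTACGGTTCACGATGCAT"
    labels = ["fwr1"] * 8 + ["cdr1"] * 6 + ["fwr2"] * 6
    w = position_weights(seq, labels, bundle.shm)
    table = bundle.shm.fivemer_mutability
    for i in range(len(seq)):
        window = seq[max(0, i - 2) : i + 3]
        if i < 2 or i > len(seq) - 3:
            mut = table.mean()
        else:
            mut = table[fivemer_to_index(seq[i - 2 : i + 3])]
        assert w[i] == pytest.approx(mut * bundle.shm.region_factor[labels[i]])


def test_zero_weights_rejected():
    model = _uniform_model(fivemer_mutability=np.zeros(1024))
    with pytest.raises(ValueError, match="degenerate"):
        position_weights("ACGTACGTAC", ["cdr3"] * 10, model)


def test_apply_shm_zero_mutations_is_identity(locus, bundle):
    from bcrsim.recombination import simulate_rearrangement

    r = simulate_rearrangement(locus, bundle, rng=np.random.default_rng(0))
    model = _uniform_model(freq_bin_edges=np.array([0.0, 1e-12]))
    apply_shm(r, model, np.random.default_rng(1))
    assert r.mutated_sequence == r.sequence
    assert r.mutations == []
    assert r.mutation_freq == 0.0


def test_double_mutation_rejected(mutated_repertoire, bundle):
    r = next(x for x in mutated_repertoire if x.mutations)
    with pytest.raises(ValueError, match="already mutated"):
        apply_shm(r, bundle.shm, np.random.default_rng(0))


def test_mutation_records_consistent(mutated_repertoire):
    """from-base matches the unmutated sequence; to-base differs; positions unique."""
    for r in mutated_repertoire:
        positions = [p for p, _, _ in r.mutations]
        assert positions == sorted(positions)
        assert len(set(positions)) == len(positions)
        for pos, frm, to in r.mutations:
            assert r.sequence[pos] == frm
            assert r.mutated_sequence[pos] == to
            assert frm != to
        assert r.mutation_freq == pytest.approx(len(r.mutations) / len(r.sequence))


def test_hamming_distance_equals_mutation_count(mutated_repertoire):
    for r in mutated_repertoire:
        hamming = sum(a != b for a, b in zip(r.sequence, r.mutated_sequence))
        assert hamming == len(r.mutations)


def test_sequential_policy_also_consistent(locus, bundle):
    from bcrsim.recombination import simulate_rearrangement

    r = simulate_rearrangement(locus, bundle, shm_on=True, rng=np.random.default_rng(5))
    apply_shm(r, bundle.shm, np.random.default_rng(6), policy="sequential")
    for pos, frm, to in r.mutations:
        assert r.sequence[pos] == frm and r.mutated_sequence[pos] == to and frm != to
    assert len(r.mutations) == sum(
        a != b for a, b in zip(r.sequence, r.mutated_sequence)
    )


def test_count_clamped_to_mutable_positions():
    model = _uniform_model(
        freq_bin_edges=np.array([1.0 - 1e-12, 1.0]),  # ask for ~everything
        fivemer_mutability=np.ones(1024),
        region_factor={"cdr3": 1.0, "np": 0.0},
    )
    from bcrsim.recombination import Rearrangement

    seq = "ACGTACGTACGTACGTACGT"
    r = Rearrangement(
        sequence_id="x", v_call="", d_call="", j_call="",
        v_trim_3p=0, d_trim_5p=0, d_trim_3p=0, j_trim_5p=0,
        np1_seq="", np2_seq="", v_part="", d_part="", j_part="",
        sequence=seq, mutated_sequence=seq, junction="", junction_aa="",
        productive=False, region_map=["cdr3"] * 10 + ["np"] * 10,
    )
    apply_shm(r, model, np.random.default_rng(0))
    assert len(r.mutations) == 10  # clamped to positions with positive weight
    assert all(pos < 10 for pos, _, _ in r.mutations)
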