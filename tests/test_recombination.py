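"""Segment sampling, trimming, NP insertion, and assembly ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcrsim.germline import Locus, make_allele
from bcrsim.recombination import (
    generate_np,
    sample_segments,
    sample_trim_length,
    simulate_one,
    simulate_repertoire,
    trim_segment,
    truncated_trim_vector,
)
from bcrsim.reference_model import (
    MarkovInsertionModel,
    POOLED,
    TrimmingModel,
    UsageModel,
)
from bcrsim import gof


def test_trim_segment_examples():
    assert trim_segment("ACGTAC", 1, 2) == "CGT"
    assert trim_segment("ACGTAC", 0, 0) == "ACGTAC"
    with pytest.raises(ValueError):
        trim_segment("AC", 1, 1)


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet="ACGT", min_size=1, max_size=40), st.data())
def test_trim_segment_slicing_property(seq, data):
    n5 = data.draw(st.integers(0, len(seq) - 1))
    n3 = data.draw(st.integers(0, len(seq) - 1 - n5))
    out = trim_segment(seq, n5, n3)
    assert out == seq[n5 : len(seq) - n3]
    assert len(out) == len(seq) - n5 - n3


def test_truncation_renormalization_exact():
    """Uniform mass on {0..9} truncated at 2 renormalizes to 1/3 each."""
    model = TrimmingModel({"D_5p": {POOLED: np.full(10, 0.1)}})
    vec = truncated_trim_vector(model, "D_5p", "IGHD1", max_trim=2)
    assert np.allclose(vec, [1 / 3, 1 / 3, 1 / 3])


def test_point_mass_trim_always_zero():
    model = TrimmingModel({"V_3p": {POOLED: np.array([1.0])}})
    rng = np.random.default_rng(0)
    assert all(
        sample_trim_length(model, "V_3p", "IGHV1", 50, rng) == 0 for _ in range(20)
    )


def test_absent_family_uses_pooled_support():
    vec = np.zeros(6)
    vec[3] = 1.0
    model = TrimmingModel({"J_5p": {POOLED: vec, "IGHJ1": np.array([1.0])}})
    rng = np.random.default_rng(0)
    # family not modelled -> pooled (all mass on 3)
    assert sample_trim_length(model, "J_5p", "IGHJ9", 10, rng) == 3


def _mini_locus(v_genes):
    v = [make_allele(f"{g}*01", "V", "GCT" * 104 + "ACGT") for g in v_genes]
    d = [make_allele("IGHD1-1*01", "D", "ACGTACGTACGT")]
    j = [make_allele("IGHJ1*01", "J", "ACGTACGTACGT" + "TGGGGTGCTGGGGCTGCT")]
    return Locus({"V": v, "D": d, "J": j}, seed=0)


def test_sample_segments_flat_gene_uniform():
    locus = _mini_locus(["IGHV1-1", "IGHV2-2"])
    usage = UsageModel({}, {}, mode="flat-gene")
    rng = np.random.default_rng(1)
    counts = {"IGHV1-1": 0, "IGHV2-2": 0}
    for _ in range(10_000):
        v, _, _ = sample_segments(locus, usage, rng)
        counts[v.gene] += 1
    assert abs(counts["IGHV1-1"] - 5000) <= 150  # binomial 3 sigma


def test_sample_segments_two_stage_weights():
    locus = _mini_locus(["IGHV1-1", "IGHV1-2"])
    usage = UsageModel(
        {"V": {"IGHV1": 1.0}, "D": {"IGHD1": 1.0}, "J": {"IGHJ1": 1.0}},
        {
            "IGHV1": {"IGHV1-1": 0.25, "IGHV1-2": 0.75},
            "IGHD1": {"IGHD1-1": 1.0},
            "IGHJ1": {"IGHJ1": 1.0},
        },
    )
    rng = np.random.default_rng(2)
    n2 = sum(
        sample_segments(locus, usage, rng)[0].gene == "IGHV1-2" for _ in range(10_000)
    )
    assert abs(n2 - 7500) <= 130  # binomial 3 sigma


def test_sample_segments_single_gene_forced():
    locus = _mini_locus(["IGHV5-5"])
    usage = UsageModel({}, {}, mode="flat-gene")
    rng = np.random.default_rng(3)
    assert all(
        sample_segments(locus, usage, rng)[0].gene == "IGHV5-5" for _ in range(10)
    )


def test_generate_np_degenerate_cases():
    first = np.array([0.0, 0.0, 1.0, 0.0])  # always G
    trans = np.zeros((3, 4, 4))
    trans[:, :, 0] = 1.0  # always A next
    model = MarkovInsertionModel("nonmutated", first, trans)
    rng = np.random.default_rng(0)
    assert generate_np(0, model, rng) == ""
    assert generate_np(3, model, rng) == "GAA"
    # overflow: positions beyond the table reuse the last matrix
    assert generate_np(8, model, rng) == "GAAAAAAA"


def test_generate_np_pair_distribution(bundle):
    """Empirical length-2 pair frequencies match first_base x transition."""
    model = bundle.markov_nonmut
    rng = np.random.default_rng(7)
    counts = np.zeros((4, 4))
    index = {b: i for i, b in enumerate("ACGT")}
    for _ in range(40_000):
        s = generate_np(2, model, rng)
        counts[index[s[0]], index[s[1]]] += 1
    expected = model.first_base[:, None] * model.transition[0]
    _, p, _ = gof.chi2_gof(counts.ravel(), expected.ravel())
    assert p > 0.001


def test_decomposition_invariant(mutated_repertoire):
    """sequence == v_part + np1 + d_part + np2 + j_part, independently rebuilt."""
    for r in mutated_repertoire:
        assert r.sequence == r.v_part + r.np1_seq + r.d_part + r.np2_seq + r.j_part
        assert len(r.np1_seq) >= 0 and len(r.np2_seq) >= 0
        assert len(r.mutations) == sum(
            a != b for a, b in zip(r.sequence, r.mutated_sequence)
        )


def test_parts_verbatim_in_germline(mutated_repertoire, by_name):
    for r in mutated_repertoire[:200]:
        v = by_name[r.v_call].ungapped_seq
        d = by_name[r.d_call].ungapped_seq
        j = by_name[r.j_call].ungapped_seq
        assert v[: len(v) - r.v_trim_3p] == r.v_part
        assert d[r.d_trim_5p : len(d) - r.d_trim_3p] == r.d_part
        assert j[r.j_trim_5p :] == r.j_part


def test_region_map_covers_sequence(mutated_repertoire):
    for r in mutated_repertoire[:200]:
        assert len(r.region_map) == len(r.sequence)
        np1_zone = r.region_map[len(r.v_part) : len(r.v_part) + len(r.np1_seq)]
        assert all(lab == "np" for lab in np1_zone)


def test_same_seed_identical_rearrangement(locus, bundle):
    a = simulate_one(locus, bundle, index=4, seed=123, shm_on=True)
    b = simulate_one(locus, bundle, index=4, seed=123, shm_on=True)
    assert a == b


def test_order_invariance_of_substreams(locus, bundle):
    """Per-index substreams: reversed generation gives identical records."""
    serial = list(simulate_repertoire(locus, bundle, 20, shm_on=True, rng_seed=9))
    reversed_order = [
        simulate_one(locus, bundle, i, 9, shm_on=True) for i in range(19, -1, -1)
    ][::-1]
    assert serial == reversed_order


def test_sequence_ids_zero_padded(locus, bundle):
    recs = list(simulate_repertoire(locus, bundle, 5, rng_seed=0, id_prefix="run"))
    assert [r.sequence_id for r in recs] == [f"run_{i:06d}" for i in range(1, 6)]


def test_productive_only_yields_productive(locus, bundle):
    recs = list(
        simulate_repertoire(
            locus, bundle, 30, shm_on=False, productive_only=True, rng_seed=2
        )
    )
    assert all(r.productive for r in recs)
    for r in recs:
        assert len(r.junction) % 3 == 0
        assert r.junction_aa[0] == "C" and r.junction_aa[-1] in "WF"


def test_junction_spans_cys_to_anchor(mutated_repertoire, by_name):
    for r in mutated_repertoire[:200]:
        if r.junction_start is None:
            assert r.junction == "" and not r.productive
            continue
        v = by_name[r.v_call]
        assert r.junction_start == v.anchor
        assert r.junction == r.mutated_sequence[r.junction_start : r.junction_end]
        assert r.sequence[v.anchor : v.anchor + 3] in {"TGT", "TGC"}
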