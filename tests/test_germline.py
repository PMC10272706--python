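"""Germline FASTA parsing, IMGT region projection, and locus construction."""

import numpy as np
import pytest

from bcrsim.germline import (
    GermlineError,
    build_locus,
    find_j_anchor,
    load_germline_fasta,
    make_allele,
)

NONGAP_CODON = "GCT"  # Ala, non-stop


def _gapped_v(gap_codons=(30, 31, 32, 60), anchor="TGC", tail=""):
    """312-column gapped V with gaps at the given IMGT codons."""
    codons = []
    for c in range(1, 105):
        if c in gap_codons:
            codons.append("...")
        elif c == 104:
            codons.append(anchor)
        else:
            codons.append(NONGAP_CODON)
    return "".join(codons) + tail


def test_gapped_v_parsing_and_projection(tmp_path):
    # 312 gapped columns with 12 gaps -> 300 nt ungapped
    gapped = _gapped_v()
    assert len(gapped) == 312
    path = tmp_path / "v.fasta"
    path.write_text(f">IGHV9-9*01\n{gapped}\n")
    (allele,) = load_germline_fasta(path, "V")
    assert len(allele.ungapped_seq) == 300
    assert allele.family == "IGHV9"
    assert allele.gene == "IGHV9-9"
    # anchor: ungapped projection of gapped position 310 (1-based) = 3*103
    expected_anchor = sum(c != "." for c in gapped[: 3 * 103])
    assert allele.anchor == expected_anchor
    assert allele.anchored
    assert allele.ungapped_seq[allele.anchor : allele.anchor + 3] == "TGC"


def test_pipe_header_decomposition(tmp_path):
    path = tmp_path / "d.fasta"
    path.write_text(">x|IGHD3-10*01|Homo sapiens|F\nACGTACGTAC\n")
    (allele,) = load_germline_fasta(path, "D")
    assert allele.name == "IGHD3-10*01"
    assert allele.gene == "IGHD3-10"
    assert allele.family == "IGHD3"


def test_lowercase_input_uppercased(tmp_path):
    path = tmp_path / "d.fasta"
    path.write_text(">IGHD1-1*01\nacgtacgtacgt\n")
    (allele,) = load_germline_fasta(path, "D")
    assert allele.ungapped_seq == "ACGTACGTACGT"


def test_duplicate_name_rejected(tmp_path):
    path = tmp_path / "d.fasta"
    path.write_text(">IGHD1-1*01\nACGTACGTAC\n>IGHD1-1*01\nACGTACGTAC\n")
    with pytest.raises(GermlineError, match="duplicate"):
        load_germline_fasta(path, "D")


def test_invalid_characters_name_the_record(tmp_path):
    path = tmp_path / "d.fasta"
    path.write_text(">IGHD1-1*01\nACGTXCGTAC\n")
    with pytest.raises(GermlineError, match="IGHD1-1"):
        load_germline_fasta(path, "D")


def test_short_v_flagged_non_anchored():
    allele = make_allele("IGHV1-1*01", "V", NONGAP_CODON * 50)
    assert not allele.anchored
    assert allele.anchor is None


def test_v_region_projection_covers_prefix(ref):
    """Concatenating region substrings in order equals the covered prefix."""
    for allele in ref.v:
        parts = [
            allele.ungapped_seq[s:e] for s, e in allele.regions.values()
        ]
        end = max(e for _, e in allele.regions.values())
        assert "".join(parts) == allele.ungapped_seq[:end]


def test_gap_strip_round_trip(ref):
    """Re-inserting gaps at their recorded columns reproduces gapped_seq."""
    for allele in ref.v:
        rebuilt = []
        it = iter(allele.ungapped_seq)
        for c in allele.gapped_seq:
            rebuilt.append("." if c == "." else next(it))
        assert "".join(rebuilt) == allele.gapped_seq
        assert allele.gapped_seq.replace(".", "") == allele.ungapped_seq


def test_j_anchor_motif(ref):
    for allele in ref.j:
        assert allele.anchored
        a = allele.anchor
        assert allele.ungapped_seq[a : a + 3] in {"TGG", "TTT", "TTC"}
        assert find_j_anchor(allele.ungapped_seq) == a


def test_build_locus_all_alleles_identity(ref):
    locus = build_locus(ref.v, ref.d, ref.j, "all", rng_seed=3)
    assert locus.alleles("V") == list(ref.v)
    assert locus.alleles("D") == list(ref.d)
    assert locus.alleles("J") == list(ref.j)


def test_build_locus_deterministic(ref):
    a = build_locus(ref.v, ref.d, ref.j, "diploid", rng_seed=11)
    b = build_locus(ref.v, ref.d, ref.j, "diploid", rng_seed=11)
    for seg in "VDJ":
        assert [x.name for x in a.alleles(seg)] == [x.name for x in b.alleles(seg)]


def test_build_locus_diploid_at_most_two_per_gene(ref):
    locus = build_locus(ref.v, ref.d, ref.j, "diploid", rng_seed=2)
    for seg in "VDJ":
        for gene in locus.genes(seg):
            names = [a.name for a in locus.alleles_for_gene(seg, gene)]
            assert 1 <= len(names) <= 2
            assert len(set(names)) == len(names)


def test_build_locus_haploid_uniform_choice():
    """A gene with 3 alleles: each allele chosen ~1000 times in 3000 builds."""
    alleles = [
        make_allele(f"IGHD1-1*0{i}", "D", "ACGTACGTAC") for i in (1, 2, 3)
    ]
    other = [make_allele("IGHV1-1*01", "V", "GCT" * 104)]
    j = [make_allele("IGHJ1*01", "J", "ACGTACGTACGT" + "TGGGGTGCTGGG" * 3)]
    counts = {}
    for seed in range(3000):
        locus = build_locus(other, alleles, j, "haploid", rng_seed=seed)
        name = locus.alleles("D")[0].name
        counts[name] = counts.get(name, 0) + 1
    assert set(counts) == {a.name for a in alleles}
    for c in counts.values():
        assert abs(c - 1000) <= 100  # binomial 3 sigma


def test_build_locus_haploid_single_allele_forced(ref):
    locus = build_locus(ref.v, ref.d, ref.j, "haploid", rng_seed=0)
    for seg in "VDJ":
        for gene in locus.genes(seg):
            assert len(locus.alleles_for_gene(seg, gene)) == 1


def test_empty_input_rejected(ref):
    with pytest.raises(GermlineError):
        build_locus([], ref.d, ref.j, "haploid", rng_seed=0)
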