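"""VDJ recombination: segment selection, trimming, NP insertion, assembly.

Every simulated sequence carries its complete ground truth: the chosen
alleles, exact trim lengths, the inserted NP strings, and (after SHM) every
mutation event, so that the assembled sequence can always be reconstructed
from the record alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .germline import GermlineAllele, Locus
from .reference_model import (
    BASES,
    MarkovInsertionModel,
    POOLED,
    ReferenceBundle,
    TrimmingModel,
    USAGE_EMPIRICAL,
    USAGE_FLAT_FAMILY,
    USAGE_FLAT_GENE,
    UsageModel,
)

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


class SimulationError(RuntimeError):
    pass


@dataclass
class Rearrangement:
    """One simulated sequence plus the full record of how it was made."""

    sequence_id: str
    v_call: str
    d_call: str
    j_call: str
    v_trim_3p: int
    d_trim_5p: int
    d_trim_3p: int
    j_trim_5p: int
    np1_seq: str
    np2_seq: str
    v_part: str
    d_part: str
    j_part: str
    sequence: str  # assembled, pre-SHM
    mutated_sequence: str  # == sequence when SHM off
    junction: str
    junction_aa: str
    productive: bool
    mutations: list = field(default_factory=list)  # (pos, from, to), 0-based
    mutation_freq: float = 0.0
    region_map: list = field(default_factory=list)  # per-position labels
    # junction coordinates on the assembled sequence (0-based half-open),
    # None when an anchor was trimmed away
    junction_start: Optional[int] = None
    junction_end: Optional[int] = None

    def ground_truth_key(self) -> tuple:
        return (
            self.v_call,
            self.d_call,
            self.j_call,
            self.v_trim_3p,
            self.d_trim_5p,
            self.d_trim_3p,
            self.j_trim_5p,
            self.np1_seq,
            self.np2_seq,
        )


def trim_segment(seq: str, n5: int, n3: int) -> str:
    """Remove n5 bases from the 5' end and n3 from the 3' end."""
    if n5 < 0 or n3 < 0:
        raise ValueError("trim lengths must be non-negative")
    if n5 + n3 >= len(seq):
        raise ValueError(f"cannot trim {n5}+{n3} bases from a {len(seq)} nt segment")
    return seq[n5 : len(seq) - n3]


def _weighted_key(probs: dict, keys: list, rng) -> str:
    """Draw one of ``keys`` with mass from ``probs`` renormalized over them."""
    w = np.array([probs.get(k, 0.0) for k in keys], dtype=float)
    total = w.sum()
    if total <= 0:
        raise SimulationError("zero total usage mass after restriction")
    return keys[rng.choice(len(keys), p=w / total)]


def sample_segments(locus: Locus, usage: UsageModel, rng) -> tuple:
    """Two-stage usage draw (family, then gene, then allele) per segment."""
    chosen = []
    for seg in ("V", "D", "J"):
        genes = locus.genes(seg)
        if usage.mode == USAGE_FLAT_GENE:
            gene = genes[rng.integers(len(genes))]
        else:
            families = locus.families(seg)
            if usage.mode == USAGE_FLAT_FAMILY:
                family = families[rng.integers(len(families))]
                fam_genes = sorted({a.gene for a in locus.alleles(seg) if a.family == family})
                gene = fam_genes[rng.integers(len(fam_genes))]
            else:
                try:
                    family = _weighted_key(usage.family_probs.get(seg, {}), families, rng)
                except SimulationError as exc:
                    raise SimulationError(f"segment {seg}: {exc}") from exc
                fam_genes = sorted({a.gene for a in locus.alleles(seg) if a.family == family})
                try:
                    gene = _weighted_key(
                        usage.gene_probs_within_family.get(family, {}), fam_genes, rng
                    )
                except SimulationError as exc:
                    raise SimulationError(f"segment {seg} family {family}: {exc}") from exc
        alleles = locus.alleles_for_gene(seg, gene)
        chosen.append(alleles[rng.integers(len(alleles))])
    return tuple(chosen)


def truncated_trim_vector(
    model: TrimmingModel, site: str, family: str, max_trim: int
) -> np.ndarray:
    """Family trim vector truncated at ``max_trim`` and renormalized."""
    vec = model.vector(site, family)
    cut = vec[: max_trim + 1].astype(float)
    total = cut.sum()
    if total <= 0:
        # all admissible mass was beyond the cut; fall back to no trimming
        out = np.zeros(max_trim + 1)
        out[0] = 1.0
        return out
    return cut / total


def sample_trim_length(
    model: TrimmingModel, site: str, family: str, max_trim: int, rng
) -> int:
    """Draw a trim length, clamped by truncation-renormalization at ``max_trim``."""
    vec = truncated_trim_vector(model, site, family, max_trim)
    return int(rng.choice(len(vec), p=vec))


def generate_np(length: int, model: MarkovInsertionModel, rng) -> str:
    """Insertion string from the position-dependent nucleotide chain."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if length == 0:
        return ""
    bases = np.empty(length, dtype=np.int64)
    bases[0] = rng.choice(4, p=model.first_base)
    for p in range(1, length):
        row = model.matrix_for(p)[bases[p - 1]]
        bases[p] = rng.choice(4, p=row)
    return "".join(BASES[b] for b in bases)


def translate(seq: str) -> str:
    table = _codon_table()
    return "".join(table.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3))


_CODON_TABLE = None


def _codon_table():
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def _junction_coords(
    v: GermlineAllele, j: GermlineAllele, v_trim: int, j_trim: int, j_offset: int
):
    """Junction span on the assembled sequence, or None if an anchor is gone."""
    if not (v.anchored and j.anchored):
        return None
    if v_trim > len(v) - (v.anchor + 3):  # 2nd-CYS codon trimmed into
        return None
    if j_trim > j.anchor:  # J anchor trimmed into
        return None
    start = v.anchor
    end = j_offset + (j.anchor - j_trim) + 3
    return start, end


def assess_productivity(mutated_sequence: str, junction_start, junction_end) -> tuple:
    """(junction, junction_aa, productive) for the given assembled sequence."""
    if junction_start is None:
        return "", "", False
    junction = mutated_sequence[junction_start:junction_end]
    if len(junction) % 3 != 0:
        return junction, "", False
    aa = translate(junction)
    productive = bool(aa) and aa[0] == "C" and aa[-1] in "WF" and "*" not in aa
    if productive:
        # no stop codon anywhere in the V-anchored reading frame
        offset = junction_start % 3
        frame = mutated_sequence[offset:]
        frame = frame[: 3 * (len(frame) // 3)]
        if "*" in translate(frame):
            productive = False
    return junction, aa, productive


def simulate_rearrangement(
    locus: Locus,
    bundle: ReferenceBundle,
    shm_on: bool = False,
    rng=None,
    sequence_id: str = "sim_000001",
    protect_anchors: bool = False,
) -> Rearrangement:
    """Run one full recombination: select, trim, insert, assemble, annotate.

    ``protect_anchors`` clamps V/J trims so the conserved anchor codons
    survive (used in productive-only simulation).  SHM itself is applied
    separately by :mod:`bcrsim.shm`; this function only picks the matching
    insertion-chain variant.
    """
    if rng is None:
        rng = np.random.default_rng()
    v, d, j = sample_segments(locus, bundle.usage, rng)

    if protect_anchors and v.anchored:
        v_max = len(v) - (v.anchor + 3)
    else:
        v_max = len(v) - 1
    v3 = sample_trim_length(bundle.trimming, "V_3p", v.family, v_max, rng)
    d5 = sample_trim_length(bundle.trimming, "D_5p", d.family, len(d) - 1, rng)
    d3 = sample_trim_length(bundle.trimming, "D_3p", d.family, len(d) - 1 - d5, rng)
    if protect_anchors and j.anchored:
        j_max = j.anchor
    else:
        j_max = len(j) - 1
    j5 = sample_trim_length(bundle.trimming, "J_5p", j.family, j_max, rng)

    v_part = trim_segment(v.ungapped_seq, 0, v3)
    d_part = trim_segment(d.ungapped_seq, d5, d3)
    j_part = trim_segment(j.ungapped_seq, j5, 0)

    np1_len = int(rng.choice(len(bundle.np_lengths.dists["np1"]), p=bundle.np_lengths.dists["np1"]))
    np2_len = int(rng.choice(len(bundle.np_lengths.dists["np2"]), p=bundle.np_lengths.dists["np2"]))
    markov = bundle.markov_mut if shm_on else bundle.markov_nonmut
    np1 = generate_np(np1_len, markov, rng)
    np2 = generate_np(np2_len, markov, rng)

    sequence = v_part + np1 + d_part + np2 + j_part

    v_labels = v.region_labels()[: len(v_part)]
    d_labels = ["cdr3"] * len(d_part)
    j_labels = j.region_labels()[j5:]
    region_map = v_labels + ["np"] * len(np1) + d_labels + ["np"] * len(np2) + j_labels

    j_offset = len(v_part) + len(np1) + len(d_part) + len(np2)
    coords = _junction_coords(v, j, v3, j5, j_offset)
    jstart, jend = coords if coords else (None, None)
    junction, junction_aa, productive = assess_productivity(sequence, jstart, jend)

    return Rearrangement(
        sequence_id=sequence_id,
        v_call=v.name,
        d_call=d.name,
        j_call=j.name,
        v_trim_3p=v3,
        d_trim_5p=d5,
        d_trim_3p=d3,
        j_trim_5p=j5,
        np1_seq=np1,
        np2_seq=np2,
        v_part=v_part,
        d_part=d_part,
        j_part=j_part,
        sequence=sequence,
        mutated_sequence=sequence,
        junction=junction,
        junction_aa=junction_aa,
        productive=productive,
        region_map=region_map,
        junction_start=jstart,
        junction_end=jend,
    )


def simulate_one(
    locus: Locus,
    bundle: ReferenceBundle,
    index: int,
    seed: int,
    shm_on: bool = False,
    productive_only: bool = False,
    id_prefix: str = "sim",
    shm_policy: str = "static",
    max_attempts: int = 200,
) -> Rearrangement:
    """Simulate the record at ``index`` from its own random substream.

    The substream depends only on (seed, index, attempt), so any generation
    order — serial, reversed, or parallel — produces identical records.
    """
    from .shm import apply_shm

    sequence_id = f"{id_prefix}_{index + 1:06d}"
    for attempt in range(max_attempts):
        rng = np.random.default_rng([abs(int(seed)), int(index), attempt])
        r = simulate_rearrangement(
            locus,
            bundle,
            shm_on=shm_on,
            rng=rng,
            sequence_id=sequence_id,
            protect_anchors=productive_only,
        )
        if shm_on:
            apply_shm(r, bundle.shm, rng, policy=shm_policy)
        if not productive_only or r.productive:
            r.attempts = attempt + 1  # type: ignore[attr-defined]
            return r
    raise SimulationError(
        f"index {index}: no productive rearrangement in {max_attempts} attempts"
    )


def simulate_repertoire(
    locus: Locus,
    bundle: ReferenceBundle,
    n: int,
    shm_on: bool = False,
    productive_only: bool = False,
    rng_seed: int = 42,
    id_prefix: str = "sim",
    shm_policy: str = "static",
    stats: Optional[dict] = None,
) -> Iterator[Rearrangement]:
    """Yield exactly ``n`` rearrangements, one independent substream each.

    Under ``productive_only`` non-productive draws are rejected and redrawn;
    an overall rejection rate above 99% over a 10,000-attempt window aborts
    with a diagnostic.  ``stats`` (if given) is filled with rejection and
    uniqueness counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    attempts = 0
    accepted = 0
    unique = set()
    for index in range(n):
        r = simulate_one(
            locus,
            bundle,
            index,
            rng_seed,
            shm_on=shm_on,
            productive_only=productive_only,
            id_prefix=id_prefix,
            shm_policy=shm_policy,
        )
        attempts += getattr(r, "attempts", 1)
        accepted += 1
        unique.add(r.ground_truth_key())
        if attempts >= 10_000 and accepted / attempts < 0.01:
            raise SimulationError(
                f"rejection rate {1 - accepted / attempts:.3f} over {attempts} attempts; "
                "check that the locus and reference support productive rearrangements"
            )
        yield r
    rejections = attempts - accepted
    if stats is not None:
        stats.update(
            rejections=rejections, attempts=attempts, unique_recombinations=len(unique)
        )
    logger.info(
        "simulated n=%d rejections=%d unique_recombinations=%d", n, rejections, len(unique)
    )
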