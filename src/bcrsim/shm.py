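"""Somatic hypermutation: per-sequence load, 5-mer x region targeting, substitution.

The per-sequence mutation count is drawn from a binned frequency
distribution (mutations per nucleotide, uniform within the chosen bin).
Positions are then selected without replacement with probability
proportional to ``mutability(5-mer) * region_factor(region)``.  By default
the weights are computed once on the unmutated sequence ("static" policy),
which keeps ground truth independent of mutation order; a "sequential"
policy that re-evaluates contexts after each mutation is also available.
"""

from __future__ import annotations

import logging

import numpy as np

from .reference_model import BASES, SHMModel

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i


def encode(sequence: str) -> np.ndarray:
    """Sequence -> int codes (A=0, C=1, G=2, T=3; -1 for anything else)."""
    return _BASE_CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def fivemer_codes(sequence: str) -> np.ndarray:
    """Per-position 5-mer code centered at each position; -1 where the
    window runs off the sequence or contains a non-ACGT base (N fallback)."""
    e = encode(sequence)
    n = len(e)
    codes = np.full(n, -1, dtype=np.int64)
    if n >= 5:
        valid = (
            (e[:-4] >= 0) & (e[1:-3] >= 0) & (e[2:-2] >= 0) & (e[3:-1] >= 0) & (e[4:] >= 0)
        )
        win = (
            e[:-4] * 256 + e[1:-3] * 64 + e[2:-2] * 16 + e[3:-1] * 4 + e[4:]
        )
        codes[2 : n - 2] = np.where(valid, win, -1)
    return codes


def sample_mutation_count(model: SHMModel, seq_len: int, rng) -> int:
    """Draw a mutation frequency and convert it to a count for this length."""
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    b = int(rng.choice(len(model.freq_probs), p=model.freq_probs))
    f = float(rng.uniform(model.freq_bin_edges[b], model.freq_bin_edges[b + 1]))
    return min(int(round(f * seq_len)), seq_len)


def position_weights(sequence: str, region_map, model: SHMModel) -> np.ndarray:
    """Mutation weight per position: 5-mer mutability x region factor.

    Flank positions (and any N-containing context) take the table mean.
    """
    if len(region_map) != len(sequence):
        raise ValueError("region_map must cover every position")
    codes = fivemer_codes(sequence)
    mut = np.where(codes >= 0, model.fivemer_mutability[codes], model.mutability_fallback)
    factors = np.array([model.region_factor.get(lab, 1.0) for lab in region_map])
    weights = mut * factors
    if not np.any(weights > 0):
        raise ValueError("degenerate SHM model: all position weights are zero")
    return weights


def _substitute(code: int, from_base: int, model: SHMModel, rng) -> int:
    if model.substitution is not None and code >= 0:
        row = model.substitution[code]
        if row.sum() > 0:
            return int(rng.choice(4, p=row))
    others = [b for b in range(4) if b != from_base]
    return others[rng.integers(3)]


def apply_shm(r, model: SHMModel, rng, policy: str = "static"):
    """Mutate a rearrangement in place and record every event.

    Chooses ``m`` distinct positions by weighted sampling without
    replacement, substitutes each center base via the 5-mer substitution
    table (uniform over the three other bases when absent), and updates the
    junction, translation and productivity of the mutated sequence.
    """
    from .recombination import assess_productivity

    if r.mutated_sequence != r.sequence:
        raise ValueError(f"{r.sequence_id}: already mutated")
    if policy not in {"static", "sequential"}:
        raise ValueError(f"unknown SHM policy {policy!r}")

    seq = r.sequence
    n = len(seq)
    m = sample_mutation_count(model, n, rng)
    weights = position_weights(seq, r.region_map, model)
    n_positive = int(np.count_nonzero(weights))
    if m > n_positive:
        logger.warning(
            "%s: mutation count %d exceeds %d mutable positions; clamped",
            r.sequence_id,
            m,
            n_positive,
        )
        m = n_positive

    mutations = []
    if m > 0:
        current = np.array(list(seq))
        if policy == "static":
            codes = fivemer_codes(seq)
            probs = weights / weights.sum()
            positions = rng.choice(n, size=m, replace=False, p=probs)
            for pos in sorted(int(p) for p in positions):
                from_b = seq[pos]
                to_idx = _substitute(int(codes[pos]), "ACGT".index(from_b), model, rng)
                current[pos] = BASES[to_idx]
                mutations.append((pos, from_b, BASES[to_idx]))
        else:
            chosen = set()
            for _ in range(m):
                w = position_weights("".join(current), r.region_map, model).copy()
                for p in chosen:
                    w[p] = 0.0
                if w.sum() <= 0:
                    break
                pos = int(rng.choice(n, p=w / w.sum()))
                chosen.add(pos)
                code = int(fivemer_codes("".join(current))[pos])
                from_b = str(current[pos])
                to_idx = _substitute(code, "ACGT".index(from_b), model, rng)
                current[pos] = BASES[to_idx]
            for pos in sorted(chosen):
                mutations.append((pos, seq[pos], str(current[pos])))
        r.mutated_sequence = "".join(current)
    r.mutations = mutations
    r.mutation_freq = len(mutations) / n
    r.junction, r.junction_aa, r.productive = assess_productivity(
        r.mutated_sequence, r.junction_start, r.junction_end
    )
    return r
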