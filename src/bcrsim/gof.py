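"""Goodness-of-fit diagnostics for simulated repertoires.

Utilities to compare the empirical output of the simulator against the
generating reference bundle: chi-square tests with small-bin merging,
total-variation distance, truncation-adjusted expected trim counts (the
clamped D trims follow a renormalized-truncated vector whose support depends
on each record's segment lengths), pooled Markov transition counts, and
hotspot/coldspot realized mutation rates.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .recombination import truncated_trim_vector
from .shm import fivemer_codes
from .synthetic import hotspot_class


def chi2_gof(observed, expected, min_expected: float = 5.0):
    """Chi-square GoF with adjacent-bin merging so every expected count
    reaches ``min_expected``.  Returns (statistic, p_value, dof)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed/expected shape mismatch")
    # scale expected to the observed total (counts may come from different
    # normalizations)
    expected = expected * observed.sum() / expected.sum()
    obs_m, exp_m = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_m.append(o_acc)
            exp_m.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 or o_acc > 0:
        if exp_m:
            obs_m[-1] += o_acc
            exp_m[-1] += e_acc
        else:
            obs_m, exp_m = [o_acc], [e_acc]
    obs_m = np.array(obs_m)
    exp_m = np.array(exp_m)
    dof = len(obs_m) - 1
    if dof < 1:
        return 0.0, 1.0, 0
    stat = float(np.sum((obs_m - exp_m) ** 2 / exp_m))
    return stat, float(sps.chi2.sf(stat, dof)), dof


def tv_distance(p, q) -> float:
    """Total-variation distance between two distributions on a shared support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    n = max(len(p), len(q))
    p = np.pad(p, (0, n - len(p)))
    q = np.pad(q, (0, n - len(q)))
    return 0.5 * float(np.abs(p / p.sum() - q / q.sum()).sum())


def tv_distance_maps(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


_SITE_FIELDS = {
    "V_3p": ("v_call", "v_trim_3p"),
    "D_5p": ("d_call", "d_trim_5p"),
    "D_3p": ("d_call", "d_trim_3p"),
    "J_5p": ("j_call", "j_trim_5p"),
}


def trim_counts(records, bundle, germline_by_name, site: str, protect_anchors: bool = False):
    """(observed, expected) trim-length counts for one site.

    The expected counts are truncation-adjusted: each record contributes the
    renormalized-truncated vector its draw actually came from, given its
    segment length (and, for D_3p, the realized D_5p; for V/J under anchor
    protection, the anchor position).
    """
    call_field, trim_field = _SITE_FIELDS[site]
    l_max = bundle.trimming.l_max(site)
    observed = np.zeros(l_max + 1)
    expected = np.zeros(l_max + 1)
    for r in records:
        allele = germline_by_name[getattr(r, call_field)]
        seg_len = len(allele.ungapped_seq)
        if site == "V_3p":
            if protect_anchors and allele.anchored:
                max_trim = seg_len - (allele.anchor + 3)
            else:
                max_trim = seg_len - 1
        elif site == "D_5p":
            max_trim = seg_len - 1
        elif site == "D_3p":
            max_trim = seg_len - 1 - r.d_trim_5p
        else:  # J_5p
            if protect_anchors and allele.anchored:
                max_trim = allele.anchor
            else:
                max_trim = seg_len - 1
        vec = truncated_trim_vector(bundle.trimming, site, allele.family, min(max_trim, l_max))
        expected[: len(vec)] += vec
        observed[getattr(r, trim_field)] += 1
    return observed, expected


def family_usage_counts(records, bundle, germline_by_name, segment: str):
    """(observed, expected) family counts for one segment as aligned arrays."""
    call_field = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment]
    probs = bundle.usage.family_probs[segment]
    families = sorted(probs)
    counts = {f: 0 for f in families}
    for r in records:
        counts[germline_by_name[getattr(r, call_field)].family] += 1
    n = len(records)
    observed = np.array([counts[f] for f in families], dtype=float)
    expected = np.array([probs[f] * n for f in families])
    return observed, expected, families


def np_length_counts(records, bundle, junction: str):
    vec = bundle.np_lengths.dists[junction]
    observed = np.zeros(len(vec))
    field = "np1_seq" if junction == "np1" else "np2_seq"
    for r in records:
        observed[len(getattr(r, field))] += 1
    return observed, vec * len(records)


def markov_transition_counts(np_strings, p_max: int):
    """Pooled (position, from-base, to-base) counts over insertion strings.

    Positions at or beyond ``p_max`` pool into the last matrix, mirroring the
    model's overflow rule.  Returns array (p_max-1, 4, 4).
    """
    counts = np.zeros((p_max - 1, 4, 4))
    code = {b: i for i, b in enumerate("ACGT")}
    for s in np_strings:
        for p in range(1, len(s)):
            counts[min(p, p_max - 1) - 1, code[s[p - 1]], code[s[p]]] += 1
    return counts


def markov_row_pvalues(np_strings, model, min_row_obs: int = 200):
    """Chi-square p-value per (position, from-base) row with enough data."""
    counts = markov_transition_counts(np_strings, model.p_max)
    pvals = []
    for p in range(counts.shape[0]):
        for r in range(4):
            row = counts[p, r]
            if row.sum() >= min_row_obs:
                _, pval, _ = chi2_gof(row, model.transition[p, r], min_expected=5.0)
                pvals.append(pval)
    return pvals


def hotspot_coldspot_rates(records):
    """Aggregate realized mutation rate at hotspot- vs coldspot-centered
    positions, classified on each unmutated sequence."""
    pos_counts = np.zeros(3)  # cold, neutral, hot
    mut_counts = np.zeros(3)
    for r in records:
        codes = fivemer_codes(r.sequence)
        classes = np.array([hotspot_class(int(c)) if c >= 0 else 0 for c in codes])
        mutated = np.zeros(len(codes), dtype=bool)
        for pos, _, _ in r.mutations:
            mutated[pos] = True
        for cls_idx, cls in ((0, -1), (1, 0), (2, 1)):
            mask = classes == cls
            pos_counts[cls_idx] += mask.sum()
            mut_counts[cls_idx] += mutated[mask].sum()
    rates = np.divide(mut_counts, pos_counts, out=np.zeros(3), where=pos_counts > 0)
    return {"cold": rates[0], "neutral": rates[1], "hot": rates[2]}
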