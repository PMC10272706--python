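"""Learn a complete ReferenceBundle from an annotated AIRR rearrangement TSV.

This is the "simulate from your own reference data" path: given a repertoire
annotated with calls, trims, NP strings and SHM events (this package's own
output qualifies), every sampling distribution the simulator needs is
estimated: usage frequencies, per-family trim histograms (families below
``min_count`` records pool), NP length histograms, Laplace-smoothed
position-indexed insertion transition matrices split by mutated status,
the per-sequence mutation-frequency histogram, per-5-mer mutability
(mutated-position counts over occurrence counts, normalized to mean 1) and
per-region mutation-rate factors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .airr_io import parse_shm_events
from .reference_model import (
    BASE_INDEX,
    MarkovInsertionModel,
    N_FIVEMERS,
    NPLengthModel,
    POOLED,
    ReferenceBundle,
    SHMModel,
    TrimmingModel,
    UsageModel,
)
from .shm import fivemer_codes

logger = logging.getLogger(__name__)

# positions at or beyond this insertion index share one transition matrix
BUILDER_P_MAX = 10

_REQUIRED = ["v_call", "d_call", "j_call", "np1", "np2", "sequence"]
_TRIM_COLS = ["v_trim_3p", "d_trim_5p", "d_trim_3p", "j_trim_5p"]


class BuilderError(ValueError):
    pass


def _gene(call: str) -> str:
    return call.split("*")[0]


def _family(call: str) -> str:
    return _gene(call).split("-")[0]


def _derive_trims(df: pd.DataFrame, germline_by_name: dict) -> pd.DataFrame:
    """Derive trim columns from alignment coordinates against the germline."""
    need = ["v_sequence_end", "j_sequence_start", "d_sequence_start", "d_sequence_end"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise BuilderError(
            "missing required columns: " + ", ".join(_TRIM_COLS) + " (or " + ", ".join(need) + ")"
        )
    v3, d5, d3, j5 = [], [], [], []
    for row in df.itertuples(index=False):
        v = germline_by_name[row.v_call]
        d = germline_by_name[row.d_call]
        j = germline_by_name[row.j_call]
        v3.append(len(v.ungapped_seq) - int(row.v_sequence_end))
        j5.append(len(j.ungapped_seq) - (len(row.sequence) - (int(row.j_sequence_start) - 1)))
        germ = list(row.sequence)
        for pos, frm, _ in parse_shm_events(getattr(row, "shm_events", "") or ""):
            germ[pos] = frm
        d_part = "".join(germ[int(row.d_sequence_start) - 1 : int(row.d_sequence_end)])
        idx = d.ungapped_seq.find(d_part)
        if idx < 0:
            idx = 0
        d5.append(idx)
        d3.append(len(d.ungapped_seq) - idx - len(d_part))
    out = df.copy()
    out["v_trim_3p"], out["d_trim_5p"], out["d_trim_3p"], out["j_trim_5p"] = v3, d5, d3, j5
    return out


def _histogram(values, l_max: int) -> np.ndarray:
    counts = np.bincount(np.asarray(values, dtype=int), minlength=l_max + 1).astype(float)
    return counts / counts.sum()


def _markov_from_strings(strings) -> MarkovInsertionModel:
    first = np.ones(4)  # Laplace prior
    trans = np.ones((BUILDER_P_MAX - 1, 4, 4))
    for s in strings:
        if not s:
            continue
        if s[0] in BASE_INDEX:
            first[BASE_INDEX[s[0]]] += 1
        for p in range(1, len(s)):
            a, b = s[p - 1], s[p]
            if a in BASE_INDEX and b in BASE_INDEX:
                trans[min(p, BUILDER_P_MAX - 1) - 1, BASE_INDEX[a], BASE_INDEX[b]] += 1
    first /= first.sum()
    trans /= trans.sum(axis=2, keepdims=True)
    return MarkovInsertionModel(variant="", first_base=first, transition=trans)


def build_bundle(airr_tsv, germline_by_name: dict, min_count: int = 50) -> ReferenceBundle:
    """Estimate every simulator distribution from an annotated repertoire."""
    df = pd.read_csv(airr_tsv, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise BuilderError("missing required columns: " + ", ".join(missing))
    if len(df) == 0:
        raise BuilderError("zero usable rows in input")

    no_d = df["d_call"] == ""
    if no_d.any():
        logger.info("%d rows lack d_call; excluded from D statistics", int(no_d.sum()))

    if not all(c in df.columns for c in _TRIM_COLS):
        df = _derive_trims(df, germline_by_name)
    for c in _TRIM_COLS + ["shm_count"] if "shm_count" in df.columns else _TRIM_COLS:
        df[c] = df[c].astype(int)
    if "shm_count" not in df.columns:
        df["shm_count"] = 0
    df["np1_length"] = df["np1"].str.len()
    df["np2_length"] = df["np2"].str.len()

    # --- usage ------------------------------------------------------------
    family_probs: dict = {}
    gene_probs: dict = {}
    for seg, col in (("V", "v_call"), ("D", "d_call"), ("J", "j_call")):
        calls = df.loc[df[col] != "", col]
        genes = calls.map(_gene)
        gene_counts = genes.value_counts()
        fam_counts: dict = {}
        for g, c in gene_counts.items():
            fam_counts[g.split("-")[0]] = fam_counts.get(g.split("-")[0], 0) + c
        total = sum(fam_counts.values())
        family_probs[seg] = {f: c / total for f, c in fam_counts.items()}
        for g, c in gene_counts.items():
            fam = g.split("-")[0]
            gene_probs.setdefault(fam, {})[g] = c / fam_counts[fam]
    usage = UsageModel(family_probs, gene_probs)

    # --- trimming -----------------------------------------------------------
    site_cols = {"V_3p": ("v_call", "v_trim_3p"), "D_5p": ("d_call", "d_trim_5p"),
                 "D_3p": ("d_call", "d_trim_3p"), "J_5p": ("j_call", "j_trim_5p")}
    trim_dists: dict = {}
    for site, (call_col, trim_col) in site_cols.items():
        sub = df[df[call_col] != ""]
        fams = sub[call_col].map(_family)
        l_max = int(sub[trim_col].max())
        dists = {POOLED: _histogram(sub[trim_col], l_max)}
        for fam, group in sub.groupby(fams)[trim_col]:
            if len(group) >= min_count:
                dists[fam] = _histogram(group, l_max)
            else:
                logger.info("trimming[%s]: family %s has %d < %d records; pooled",
                            site, fam, len(group), min_count)
        trim_dists[site] = dists
    trimming = TrimmingModel(trim_dists)

    # --- NP lengths ---------------------------------------------------------
    np_lengths = NPLengthModel(
        {
            "np1": _histogram(df["np1_length"], int(df["np1_length"].max())),
            "np2": _histogram(df["np2_length"], int(df["np2_length"].max())),
        }
    )

    # --- insertion chains, split by mutated status ---------------------------
    nonmut_rows = df[df["shm_count"] == 0]
    mut_rows = df[df["shm_count"] > 0]
    strings = {
        "nonmutated": list(nonmut_rows["np1"]) + list(nonmut_rows["np2"]),
        "mutated": list(mut_rows["np1"]) + list(mut_rows["np2"]),
    }
    models = {}
    for variant in ("nonmutated", "mutated"):
        other = "mutated" if variant == "nonmutated" else "nonmutated"
        use = strings[variant]
        if not any(use):
            logger.warning("no %s rows with insertions; reusing %s matrices", variant, other)
            use = strings[other]
        m = _markov_from_strings(use)
        m.variant = variant
        models[variant] = m

    # --- SHM ------------------------------------------------------------------
    if "shm_freq" in df.columns:
        freqs = df["shm_freq"].replace("", "0").astype(float).to_numpy()
    else:
        freqs = df["shm_count"].to_numpy() / df["sequence"].str.len().to_numpy()
    fmax = float(freqs.max())
    if fmax <= 0:
        edges = np.array([0.0, 1e-6])
        probs = np.array([1.0])
    else:
        edges = np.linspace(0.0, fmax * (1 + 1e-9), 101)
        counts, _ = np.histogram(freqs, bins=edges)
        probs = counts / counts.sum()

    occ = np.zeros(N_FIVEMERS)
    mut = np.zeros(N_FIVEMERS)
    region_pos: dict = {}
    region_mut: dict = {}
    for row in df.itertuples(index=False):
        events = parse_shm_events(getattr(row, "shm_events", "") or "")
        germ = list(row.sequence)
        for pos, frm, _ in events:
            germ[pos] = frm
        germ_seq = "".join(germ)
        codes = fivemer_codes(germ_seq)
        valid = codes >= 0
        occ += np.bincount(codes[valid], minlength=N_FIVEMERS)
        mut_positions = [pos for pos, _, _ in events]
        for pos in mut_positions:
            if codes[pos] >= 0:
                mut[codes[pos]] += 1
        labels = _region_labels_for_row(row, germline_by_name)
        if labels is not None:
            mutated_mask = np.zeros(len(labels), dtype=bool)
            for pos in mut_positions:
                if pos < len(labels):
                    mutated_mask[pos] = True
            for lab in set(labels):
                idx = [i for i, l in enumerate(labels) if l == lab]
                region_pos[lab] = region_pos.get(lab, 0) + len(idx)
                region_mut[lab] = region_mut.get(lab, 0) + int(mutated_mask[idx].sum())

    observed = occ > 0
    mutability = np.ones(N_FIVEMERS)
    rates = np.divide(mut, occ, out=np.zeros(N_FIVEMERS), where=observed)
    if rates[observed].mean() > 0:
        mutability[observed] = rates[observed] / rates[observed].mean()

    total_pos = sum(region_pos.values())
    total_mut = sum(region_mut.values())
    region_factor = {lab: 1.0 for lab in ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3", "fwr4", "np")}
    if total_mut > 0:
        overall = total_mut / total_pos
        for lab, npos in region_pos.items():
            if npos > 0:
                region_factor[lab] = (region_mut.get(lab, 0) / npos) / overall

    shm = SHMModel(
        freq_bin_edges=edges,
        freq_probs=probs,
        fivemer_mutability=mutability,
        region_factor=region_factor,
        substitution=None,
    )

    bundle = ReferenceBundle(
        usage=usage,
        trimming=trimming,
        np_lengths=np_lengths,
        markov_nonmut=models["nonmutated"],
        markov_mut=models["mutated"],
        shm=shm,
        provenance=f"learned from {airr_tsv} ({len(df)} rows, min_count={min_count})",
    )
    bundle.validate()
    return bundle


def _region_labels_for_row(row, germline_by_name: dict):
    """Rebuild per-position region labels from the row's ground truth."""
    try:
        v = germline_by_name[row.v_call]
        d = germline_by_name[row.d_call]
        j = germline_by_name[row.j_call]
    except (KeyError, AttributeError):
        return None
    v3, d5, d3, j5 = (
        int(row.v_trim_3p),
        int(row.d_trim_5p),
        int(row.d_trim_3p),
        int(row.j_trim_5p),
    )
    v_len = len(v.ungapped_seq) - v3
    d_len = len(d.ungapped_seq) - d5 - d3
    return (
        v.region_labels()[:v_len]
        + ["np"] * len(row.np1)
        + ["cdr3"] * d_len
        + ["np"] * len(row.np2)
        + j.region_labels()[j5:]
    )


def summarize(airr_tsv) -> dict:
    """Repertoire summary tables: usage, trim and NP histograms, junction
    lengths, and per-position mutation rate along the assembled sequence."""
    df = pd.read_csv(airr_tsv, sep="\t", dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise BuilderError("zero usable rows in input")
    out: dict = {}

    usage_frames = []
    for seg, col in (("V", "v_call"), ("D", "d_call"), ("J", "j_call")):
        calls = df.loc[df[col] != "", col].map(_gene)
        freqs = calls.value_counts(normalize=True)
        usage_frames.append(
            pd.DataFrame({"segment": seg, "gene": freqs.index, "frequency": freqs.values})
        )
    out["usage"] = pd.concat(usage_frames, ignore_index=True)

    for col, name in (("np1", "np1_length"), ("np2", "np2_length")):
        lengths = df[col].str.len()
        hist = lengths.value_counts(normalize=True).sort_index()
        out[name] = pd.DataFrame({"length": hist.index, "frequency": hist.values})

    if all(c in df.columns for c in _TRIM_COLS):
        frames = []
        for site, col in (("V_3p", "v_trim_3p"), ("D_5p", "d_trim_5p"),
                          ("D_3p", "d_trim_3p"), ("J_5p", "j_trim_5p")):
            hist = df[col].astype(int).value_counts(normalize=True).sort_index()
            frames.append(pd.DataFrame({"site": site, "length": hist.index, "frequency": hist.values}))
        out["trims"] = pd.concat(frames, ignore_index=True)

    jl = df["junction"].str.len() if "junction" in df.columns else pd.Series([], dtype=int)
    hist = jl.value_counts(normalize=True).sort_index()
    out["junction_length"] = pd.DataFrame({"length": hist.index, "frequency": hist.values})

    max_len = int(df["sequence"].str.len().max())
    denom = np.zeros(max_len)
    numer = np.zeros(max_len)
    for row in df.itertuples(index=False):
        L = len(row.sequence)
        denom[:L] += 1
        for pos, _, _ in parse_shm_events(getattr(row, "shm_events", "") or ""):
            if pos < max_len:
                numer[pos] += 1
    rate = np.divide(numer, denom, out=np.zeros(max_len), where=denom > 0)
    out["per_position_mutation_rate"] = pd.DataFrame(
        {"position": np.arange(1, max_len + 1), "rate": rate}
    )
    return out
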