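"""FASTA and AIRR rearrangement-schema TSV output, plus reconstruction checks.

The TSV carries the standard AIRR columns with 1-based inclusive
coordinates plus custom ground-truth columns (trim lengths and SHM events),
so that every output sequence is exactly reconstructable from its row: the
``verify`` path re-derives each sequence from calls + trims + NP strings +
mutation events and compares it byte-for-byte with the sequence column.
"""

from __future__ import annotations

import csv
import logging

logger = logging.getLogger(__name__)

AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "rev_comp",
    "productive",
    "v_call",
    "d_call",
    "j_call",
    "sequence_alignment",
    "germline_alignment",
    "junction",
    "junction_aa",
    "np1",
    "np1_length",
    "np2",
    "np2_length",
    "v_sequence_start",
    "v_sequence_end",
    "d_sequence_start",
    "d_sequence_end",
    "j_sequence_start",
    "j_sequence_end",
    # custom ground-truth columns
    "v_trim_3p",
    "d_trim_5p",
    "d_trim_3p",
    "j_trim_5p",
    "shm_count",
    "shm_events",
    "shm_freq",
]


class ReconstructionError(ValueError):
    pass


def write_fasta(records, path) -> int:
    """Write mutated sequences as FASTA, 80-column wrapped. Returns count."""
    n = 0
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.sequence_id}\n")
            seq = r.mutated_sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
            n += 1
    if n == 0:
        logger.warning("wrote empty FASTA to %s", path)
    return n


def format_shm_events(mutations) -> str:
    """Semicolon-joined ``pos:from>to`` with 1-based positions."""
    return ";".join(f"{pos + 1}:{frm}>{to}" for pos, frm, to in mutations)


def parse_shm_events(text: str) -> list:
    """Inverse of :func:`format_shm_events`, back to 0-based tuples."""
    if not text:
        return []
    out = []
    for token in text.split(";"):
        pos_s, change = token.split(":")
        frm, to = change.split(">")
        out.append((int(pos_s) - 1, frm, to))
    return out


def _row(r) -> dict:
    v_end = len(r.v_part)
    d_start = v_end + len(r.np1_seq) + 1
    d_end = d_start + len(r.d_part) - 1
    j_start = d_end + len(r.np2_seq) + 1
    j_end = j_start + len(r.j_part) - 1
    return {
        "sequence_id": r.sequence_id,
        "sequence": r.mutated_sequence,
        "rev_comp": "F",
        "productive": "T" if r.productive else "F",
        "v_call": r.v_call,
        "d_call": r.d_call,
        "j_call": r.j_call,
        "sequence_alignment": r.mutated_sequence,
        "germline_alignment": r.sequence,
        "junction": r.junction,
        "junction_aa": r.junction_aa,
        "np1": r.np1_seq,
        "np1_length": len(r.np1_seq),
        "np2": r.np2_seq,
        "np2_length": len(r.np2_seq),
        "v_sequence_start": 1,
        "v_sequence_end": v_end,
        "d_sequence_start": d_start,
        "d_sequence_end": d_end,
        "j_sequence_start": j_start,
        "j_sequence_end": j_end,
        "v_trim_3p": r.v_trim_3p,
        "d_trim_5p": r.d_trim_5p,
        "d_trim_3p": r.d_trim_3p,
        "j_trim_5p": r.j_trim_5p,
        "shm_count": len(r.mutations),
        "shm_events": format_shm_events(r.mutations),
        "shm_freq": format(r.mutation_freq, ".8g"),
    }


def write_airr_tsv(records, path) -> int:
    """Write one AIRR-schema row per rearrangement. Returns row count."""
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=AIRR_COLUMNS, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for r in records:
            writer.writerow(_row(r))
            n += 1
    if n == 0:
        logger.warning("wrote empty AIRR TSV to %s", path)
    return n


def read_airr_tsv(path) -> list:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def reconstruct(row: dict, germline_by_name: dict) -> str:
    """Rebuild the mutated sequence from ground-truth fields alone.

    Raises :class:`ReconstructionError` (naming the row) if the rebuilt
    sequence does not equal the sequence column exactly.
    """
    sid = row.get("sequence_id", "<unknown>")
    try:
        v = germline_by_name[row["v_call"]]
        d = germline_by_name[row["d_call"]]
        j = germline_by_name[row["j_call"]]
    except KeyError as exc:
        raise ReconstructionError(f"row {sid}: unknown allele {exc}") from exc
    v3 = int(row["v_trim_3p"])
    d5 = int(row["d_trim_5p"])
    d3 = int(row["d_trim_3p"])
    j5 = int(row["j_trim_5p"])
    v_part = v.ungapped_seq[: len(v.ungapped_seq) - v3]
    d_part = d.ungapped_seq[d5 : len(d.ungapped_seq) - d3]
    j_part = j.ungapped_seq[j5:]
    seq = list(v_part + row["np1"] + d_part + row["np2"] + j_part)
    for pos, frm, to in parse_shm_events(row.get("shm_events", "")):
        if pos >= len(seq) or seq[pos] != frm:
            raise ReconstructionError(
                f"row {sid}: mutation {pos + 1}:{frm}>{to} inconsistent with germline assembly"
            )
        seq[pos] = to
    rebuilt = "".join(seq)
    if rebuilt != row["sequence"]:
        raise ReconstructionError(
            f"row {sid}: reconstructed sequence differs from sequence column"
        )
    return rebuilt


def verify_tsv(path, germline_by_name: dict) -> tuple[int, list]:
    """Reconstruct every row of a TSV; returns (n_rows, list of error strings)."""
    errors = []
    rows = read_airr_tsv(path)
    for row in rows:
        try:
            reconstruct(row, germline_by_name)
        except ReconstructionError as exc:
            errors.append(str(exc))
    return len(rows), errors
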