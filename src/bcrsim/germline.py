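"""Germline allele parsing and simulated-locus construction.

V alleles are expected in IMGT-gapped form (gaps ``.`` pad every sequence to
the IMGT unique numbering), which lets framework/CDR boundaries and the
conserved 2nd-CYS (codon 104) be read off fixed codon coordinates.  D and J
alleles are ungapped; the J anchor (J-TRP/J-PHE of the W/F-G-x-G motif) is
located by scanning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_CHARS = set("ACGTN.")

# IMGT unique numbering codon ranges (1-based codons, inclusive) on the
# gapped V alignment.  Codon 104 is the 2nd-CYS.
IMGT_V_REGIONS = {
    "fwr1": (1, 26),
    "cdr1": (27, 38),
    "fwr2": (39, 55),
    "cdr2": (56, 65),
    "fwr3": (66, 104),
}
SECOND_CYS_CODON = 104
V_ANCHOR_CODONS = {"TGT", "TGC"}
J_ANCHOR_CODONS = {"TGG", "TTT", "TTC"}


class GermlineError(ValueError):
    pass


@dataclass
class GermlineAllele:
    """One named V, D or J allele with region annotations.

    Coordinates are 0-based half-open on ``ungapped_seq``.  ``anchor`` is the
    start of the conserved anchor codon (2nd-CYS for V, J-TRP/J-PHE for J);
    ``anchored`` is False when no valid anchor codon could be located, in
    which case the allele is excluded from productive simulation but remains
    usable otherwise.
    """

    name: str
    segment: str  # V, D or J
    gapped_seq: str
    ungapped_seq: str = ""
    gene: str = ""
    family: str = ""
    regions: dict = field(default_factory=dict)
    anchor: Optional[int] = None
    anchored: bool = False

    def __post_init__(self):
        if not self.ungapped_seq:
            self.ungapped_seq = self.gapped_seq.replace(".", "")
        if not self.gene:
            self.gene = self.name.split("*")[0]
        if not self.family:
            self.family = self.gene.split("-")[0]

    def __len__(self) -> int:
        return len(self.ungapped_seq)

    def region_labels(self) -> list[str]:
        """Per-position region label on the ungapped sequence."""
        if self.segment == "D":
            return ["cdr3"] * len(self.ungapped_seq)
        if self.segment == "J":
            a = self.anchor if self.anchored else 0
            return ["cdr3"] * a + ["fwr4"] * (len(self.ungapped_seq) - a)
        labels = []
        for name, (start, end) in self.regions.items():
            labels.extend([name] * (end - start))
        # Anything past the annotated regions (short alleles) keeps the last
        # label so the map always covers the sequence.
        while len(labels) < len(self.ungapped_seq):
            labels.append(labels[-1] if labels else "fwr1")
        return labels[: len(self.ungapped_seq)]


@dataclass
class Locus:
    """A simulated individual's heavy-chain locus: chosen alleles per segment."""

    alleles_by_segment: dict
    seed: int

    def alleles(self, segment: str) -> list[GermlineAllele]:
        return self.alleles_by_segment[segment]

    def genes(self, segment: str) -> list[str]:
        return sorted({a.gene for a in self.alleles(segment)})

    def families(self, segment: str) -> list[str]:
        return sorted({a.family for a in self.alleles(segment)})

    def alleles_for_gene(self, segment: str, gene: str) -> list[GermlineAllele]:
        return [a for a in self.alleles(segment) if a.gene == gene]

    def by_name(self) -> dict:
        out = {}
        for seg in self.alleles_by_segment.values():
            for a in seg:
                out[a.name] = a
        return out


def _parse_header(header: str) -> str:
    token = header.split()[0]
    if "|" in token:
        fields = token.split("|")
        if len(fields) < 2 or not fields[1]:
            raise GermlineError(f"cannot extract allele name from header {header!r}")
        return fields[1]
    return token


def _project(gapped: str):
    """Map gapped column index -> ungapped index (count of non-gaps before)."""
    positions = np.cumsum([c != "." for c in gapped])
    return lambda col: int(positions[col - 1]) if col > 0 else 0


def _annotate_v(allele: GermlineAllele) -> None:
    gapped = allele.gapped_seq
    proj = _project(gapped)
    n_cols = len(gapped)
    regions = {}
    for name, (c_start, c_end) in IMGT_V_REGIONS.items():
        g_start = 3 * (c_start - 1)
        g_end = 3 * c_end
        if g_start >= n_cols:
            break
        regions[name] = (proj(g_start), proj(min(g_end, n_cols)))
    anchor_col = 3 * (SECOND_CYS_CODON - 1)  # 0-based gapped start of codon 104
    anchored = False
    anchor = None
    if n_cols >= 3 * SECOND_CYS_CODON:
        codon_cols = gapped[anchor_col : anchor_col + 3]
        if "." not in codon_cols:
            anchor = proj(anchor_col)
            if allele.ungapped_seq[anchor : anchor + 3] in V_ANCHOR_CODONS:
                anchored = True
    if not anchored:
        logger.warning("V allele %s has no valid 2nd-CYS; flagged non-anchored", allele.name)
        anchor = None
    else:
        # germline-encoded start of CDR3 begins after the 2nd-CYS codon
        cdr3_start = anchor + 3
        if cdr3_start < len(allele.ungapped_seq):
            regions["cdr3"] = (cdr3_start, len(allele.ungapped_seq))
        # fwr3 ends at the end of codon 104
        if "fwr3" in regions:
            regions["fwr3"] = (regions["fwr3"][0], min(regions["fwr3"][1], cdr3_start))
    allele.regions = regions
    allele.anchor = anchor
    allele.anchored = anchored


def find_j_anchor(seq: str) -> Optional[int]:
    """Locate the J anchor codon (W/F of the W/F-G-x-G motif), first match."""
    for p in range(0, len(seq) - 11):
        if (
            seq[p : p + 3] in J_ANCHOR_CODONS
            and seq[p + 3 : p + 5] == "GG"
            and seq[p + 9 : p + 11] == "GG"
        ):
            return p
    return None


def _annotate_j(allele: GermlineAllele) -> None:
    anchor = find_j_anchor(allele.ungapped_seq)
    if anchor is None:
        logger.warning("J allele %s has no W/F-G-x-G anchor; flagged non-anchored", allele.name)
        allele.anchored = False
        allele.regions = {"fwr4": (0, len(allele.ungapped_seq))}
        return
    allele.anchor = anchor
    allele.anchored = True
    allele.regions = {"fwr4": (anchor, len(allele.ungapped_seq))}


def make_allele(name: str, segment: str, seq: str) -> GermlineAllele:
    """Build and annotate an allele from its (possibly gapped) sequence."""
    seq = seq.upper()
    bad = set(seq) - VALID_CHARS
    if bad:
        raise GermlineError(f"record {name}: invalid characters {sorted(bad)}")
    if segment != "V" and "." in seq:
        raise GermlineError(f"record {name}: gaps only allowed in V sequences")
    allele = GermlineAllele(name=name, segment=segment, gapped_seq=seq)
    if segment == "V":
        _annotate_v(allele)
    elif segment == "J":
        _annotate_j(allele)
    return allele


def load_germline_fasta(path, segment: str) -> list[GermlineAllele]:
    """Parse a germline FASTA into annotated alleles.

    Headers may be bare allele names ("IGHV1-2*02") or IMGT pipe-delimited
    (allele name in the second field).  V records may carry IMGT gaps.
    """
    if segment not in {"V", "D", "J"}:
        raise ValueError(f"segment must be V, D or J, got {segment!r}")
    alleles = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        name = _parse_header(record.description)
        if name in seen:
            raise GermlineError(f"duplicate allele name {name!r} in {path}")
        seen.add(name)
        alleles.append(make_allele(name, segment, str(record.seq)))
    if not alleles:
        raise GermlineError(f"no FASTA records found in {path}")
    return alleles


def load_germline_dir(directory) -> dict:
    """Load v.fasta / d.fasta / j.fasta from a directory."""
    directory = Path(directory)
    out = {}
    for seg, fname in (("V", "v.fasta"), ("D", "d.fasta"), ("J", "j.fasta")):
        p = directory / fname
        if not p.exists():
            raise GermlineError(f"missing germline file {p}")
        out[seg] = load_germline_fasta(p, seg)
    return out


HAPLOID = "haploid"
DIPLOID = "diploid"
ALL_ALLELES = "all"


def build_locus(v, d, j, heterozygosity: str = DIPLOID, rng_seed: int = 0) -> Locus:
    """Draw a simulated individual locus from the available alleles.

    haploid: one allele per gene, uniformly; diploid: two distinct alleles
    per gene when available, else one; all: every allele retained.
    """
    if heterozygosity not in {HAPLOID, DIPLOID, ALL_ALLELES}:
        raise ValueError(f"unknown heterozygosity mode {heterozygosity!r}")
    rng = np.random.default_rng([abs(int(rng_seed)), 0x10C05])
    out = {}
    for seg, alleles in (("V", v), ("D", d), ("J", j)):
        if not alleles:
            raise GermlineError(f"empty allele list for segment {seg}")
        if heterozygosity == ALL_ALLELES:
            out[seg] = list(alleles)
            continue
        chosen = []
        genes = sorted({a.gene for a in alleles})
        for gene in genes:
            candidates = sorted(
                (a for a in alleles if a.gene == gene), key=lambda a: a.name
            )
            k = 1 if heterozygosity == HAPLOID else min(2, len(candidates))
            idx = rng.choice(len(candidates), size=k, replace=False)
            chosen.extend(candidates[i] for i in sorted(idx))
        out[seg] = chosen
    return Locus(alleles_by_segment=out, seed=int(rng_seed))
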