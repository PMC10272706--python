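"""Synthetic germline alleles and reference distributions.

Generates a plausible, fully self-contained human-IGH-like reference: gapped
V alleles with a valid 2nd-CYS, short D segments, anchored J segments, and a
complete :class:`~bcrsim.reference_model.ReferenceBundle` (geometric-tailed
family trim distributions, Poisson-shaped NP lengths with mode ~5, GC-biased
position-dependent insertion chains, a gamma-shaped per-sequence mutation
frequency with mean ~0.05, and a 5-mer mutability table with classical
WRC/GYW hotspots at 8x and SYC/GRS coldspots at 0.25x background).

Background 5-mer weights carry a mild lognormal jitter (sigma 0.25, mean
preserved) so the table is near-continuous, as empirically derived
mutability tables are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .germline import GermlineAllele, find_j_anchor, make_allele
from .reference_model import (
    BASES,
    MarkovInsertionModel,
    N_FIVEMERS,
    NPLengthModel,
    POOLED,
    ReferenceBundle,
    SHMModel,
    TrimmingModel,
    UsageModel,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
NONSTOP_CODONS = sorted(
    {a + b + c for a in BASES for b in BASES for c in BASES} - STOP_CODONS
)

TRIM_L_MAX = {"V_3p": 9, "D_5p": 8, "D_3p": 8, "J_5p": 10}
NP_N_MAX = 20
MARKOV_P_MAX = 10
HOTSPOT_WEIGHT = 8.0
COLDSPOT_WEIGHT = 0.25


@dataclass
class SyntheticReference:
    """Return value of :func:`make_synthetic_reference`."""

    v: list
    d: list
    j: list
    bundle: ReferenceBundle
    fasta_text: dict = field(default_factory=dict)  # segment -> FASTA string
    germline_dir: Path | None = None
    bundle_dir: Path | None = None

    @property
    def germline(self) -> dict:
        return {"V": self.v, "D": self.d, "J": self.j}


def _codon(rng) -> str:
    return NONSTOP_CODONS[rng.integers(len(NONSTOP_CODONS))]


def _bases(rng, n) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _point_variant(seq: str, rng, frame_codons: bool, protected: set) -> str:
    """One substitution; in coding frame avoid creating stops."""
    seq = list(seq)
    while True:
        pos = int(rng.integers(len(seq)))
        if pos in protected or seq[pos] == ".":
            continue
        old = seq[pos]
        new = BASES[rng.integers(4)]
        if new == old:
            continue
        if frame_codons:
            c0 = 3 * (pos // 3)
            trial = seq[:]
            trial[pos] = new
            if "".join(trial[c0 : c0 + 3]) in STOP_CODONS:
                continue
        seq[pos] = new
        return "".join(seq)


def _make_v_gapped(rng) -> str:
    n_gap_cdr1 = int(rng.integers(2, 5))  # gap codons at the end of CDR1
    n_gap_cdr2 = int(rng.integers(1, 3))  # gap codons at the end of CDR2
    gap_codons = set(range(39 - n_gap_cdr1, 39)) | set(range(66 - n_gap_cdr2, 66))
    codons = []
    for c in range(1, 105):  # IMGT codons 1..104
        if c in gap_codons:
            codons.append("...")
        elif c == 104:
            codons.append("TGT" if rng.random() < 0.5 else "TGC")
        else:
            codons.append(_codon(rng))
    tail = _bases(rng, int(rng.integers(2, 7)))  # germline-encoded CDR3 start
    return "".join(codons) + tail


def _make_j_seq(rng) -> str:
    while True:
        k = int(rng.integers(9, 14))  # codons from the anchor to the 3' end
        a = int(rng.integers(12, 19))  # nt before the anchor
        if not 40 <= a + 3 * k <= 60:
            continue
        codons = ["TGG", "GG" + BASES[rng.integers(4)], _codon(rng), "GG" + BASES[rng.integers(4)]]
        codons += [_codon(rng) for _ in range(k - 4)]
        for _ in range(50):
            prefix = _bases(rng, a)
            seq = prefix + "".join(codons)
            if find_j_anchor(seq) == a:
                return seq


def _geometric_trim_vector(mean: float, l_max: int) -> np.ndarray:
    p = 1.0 / (1.0 + mean)
    k = np.arange(l_max + 1)
    v = p * (1.0 - p) ** k
    return v / v.sum()


def _markov_variant(variant: str, gc: float, rng) -> MarkovInsertionModel:
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    first = rng.dirichlet(40 * base)
    transition = np.stack(
        [
            np.stack([rng.dirichlet(25 * base) for _ in range(4)])
            for _ in range(MARKOV_P_MAX - 1)
        ]
    )
    return MarkovInsertionModel(variant=variant, first_base=first, transition=transition)


def hotspot_class(idx: int) -> int:
    """+1 for WRC/GYW hotspot contexts, -1 for SYC/GRS coldspots, else 0.

    The class is decided by the base at the central (mutated) position and
    its immediate neighbours: WRC (W=A/T, R=A/G, mutated C), GYW (mutated G,
    Y=C/T, W=A/T); SYC (S=C/G, Y=C/T, mutated C), GRS (mutated G, R=A/G,
    S=C/G).
    """
    n5 = idx % 4
    n4 = (idx // 4) % 4
    n3 = (idx // 16) % 4
    n2 = (idx // 64) % 4
    n1 = (idx // 256) % 4
    A, C, G, T = 0, 1, 2, 3
    if n3 == C and n2 in (A, G) and n1 in (A, T):
        return 1
    if n3 == G and n4 in (C, T) and n5 in (A, T):
        return 1
    if n3 == C and n2 in (C, T) and n1 in (G, C):
        return -1
    if n3 == G and n4 in (A, G) and n5 in (G, C):
        return -1
    return 0


def _fivemer_mutability(rng) -> np.ndarray:
    base = np.ones(N_FIVEMERS)
    for i in range(N_FIVEMERS):
        cls = hotspot_class(i)
        if cls == 1:
            base[i] = HOTSPOT_WEIGHT
        elif cls == -1:
            base[i] = COLDSPOT_WEIGHT
    sigma = 0.25
    jitter = rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=N_FIVEMERS)
    return base * jitter


def _substitution_table() -> np.ndarray:
    # transition (A<->G, C<->T) favoured 2:1 over each transversion
    partner = {0: 2, 1: 3, 2: 0, 3: 1}
    table = np.zeros((N_FIVEMERS, 4))
    for center in range(4):
        row = np.full(4, 0.25)
        row[center] = 0.0
        row[partner[center]] = 0.5
        for i in range(N_FIVEMERS):
            if (i // 16) % 4 == center:
                table[i] = row
    return table


def make_synthetic_reference(
    n_v_genes: int = 12,
    n_d_genes: int = 8,
    n_j_genes: int = 4,
    seed: int = 0,
    out_dir=None,
) -> SyntheticReference:
    """Generate synthetic germline FASTA content plus a full ReferenceBundle.

    Deterministic in ``seed``.  When ``out_dir`` is given, germline FASTA
    files are written under ``out_dir/germline`` and the bundle under
    ``out_dir/bundle``.
    """
    for name, n in (("n_v_genes", n_v_genes), ("n_d_genes", n_d_genes), ("n_j_genes", n_j_genes)):
        if n < 2:
            raise ValueError(f"{name} must be >= 2, got {n}")
    rng = np.random.default_rng([abs(int(seed)), 0x5EED])

    v_alleles, d_alleles, j_alleles = [], [], []

    n_v_fam = min(4, n_v_genes)
    for i in range(n_v_genes):
        fam = (i % n_v_fam) + 1
        gene = f"IGHV{fam}-{i + 1}"
        base = _make_v_gapped(rng)
        v_alleles.append(make_allele(f"{gene}*01", "V", base))
        if i % 2 == 0:
            anchor_cols = set(range(309, 312))
            var = _point_variant(base, rng, frame_codons=True, protected=anchor_cols)
            v_alleles.append(make_allele(f"{gene}*02", "V", var))

    n_d_fam = min(3, n_d_genes)
    for i in range(n_d_genes):
        fam = (i % n_d_fam) + 1
        gene = f"IGHD{fam}-{i + 1}"
        base = _bases(rng, int(rng.integers(10, 38)))
        d_alleles.append(make_allele(f"{gene}*01", "D", base))
        if i % 3 == 0:
            var = _point_variant(base, rng, frame_codons=False, protected=set())
            d_alleles.append(make_allele(f"{gene}*02", "D", var))

    for i in range(n_j_genes):
        gene = f"IGHJ{i + 1}"
        base = _make_j_seq(rng)
        j_alleles.append(make_allele(f"{gene}*01", "J", base))
        if i % 2 == 1:
            anchor = find_j_anchor(base)
            for _ in range(100):
                var = _point_variant(base, rng, frame_codons=False, protected=set(range(anchor, len(base))))
                if find_j_anchor(var) == anchor:
                    j_alleles.append(make_allele(f"{gene}*02", "J", var))
                    break

    # --- usage ----------------------------------------------------------
    family_probs: dict = {}
    gene_probs: dict = {}
    for seg, alleles in (("V", v_alleles), ("D", d_alleles), ("J", j_alleles)):
        genes = sorted({a.gene for a in alleles})
        weights = rng.gamma(2.0, 1.0, size=len(genes))
        weights /= weights.sum()
        fam_of = {a.gene: a.family for a in alleles}
        fams: dict = {}
        for g, w in zip(genes, weights):
            fams[fam_of[g]] = fams.get(fam_of[g], 0.0) + w
        family_probs[seg] = fams
        for g, w in zip(genes, weights):
            gene_probs.setdefault(fam_of[g], {})[g] = w / fams[fam_of[g]]
    usage = UsageModel(family_probs, gene_probs)

    # --- trimming -------------------------------------------------------
    seg_families = {
        "V_3p": sorted({a.family for a in v_alleles}),
        "D_5p": sorted({a.family for a in d_alleles}),
        "D_3p": sorted({a.family for a in d_alleles}),
        "J_5p": sorted({a.family for a in j_alleles}),
    }
    trim_dists: dict = {}
    for site, fams in seg_families.items():
        l_max = TRIM_L_MAX[site]
        d = {
            fam: _geometric_trim_vector(float(rng.uniform(1.5, 4.5)), l_max) for fam in fams
        }
        pooled = np.mean(np.stack(list(d.values())), axis=0)
        d[POOLED] = pooled / pooled.sum()
        trim_dists[site] = d
    trimming = TrimmingModel(trim_dists)

    # --- NP lengths -----------------------------------------------------
    k = np.arange(NP_N_MAX + 1)
    np_dists = {}
    for junc, lam in (("np1", 4.8), ("np2", 5.2)):
        v = stats.poisson.pmf(k, lam)
        np_dists[junc] = v / v.sum()
    np_lengths = NPLengthModel(np_dists)

    # --- insertion chains ----------------------------------------------
    markov_nonmut = _markov_variant("nonmutated", 0.56, rng)
    markov_mut = _markov_variant("mutated", 0.64, rng)

    # --- SHM -------------------------------------------------------------
    edges = np.linspace(0.0, 0.25, 26)
    centers = (edges[:-1] + edges[1:]) / 2
    probs = stats.gamma.pdf(centers, a=2.5, scale=0.02)
    probs /= probs.sum()
    shm = SHMModel(
        freq_bin_edges=edges,
        freq_probs=probs,
        fivemer_mutability=_fivemer_mutability(rng),
        region_factor={
            "fwr1": 0.7,
            "cdr1": 1.6,
            "fwr2": 0.7,
            "cdr2": 1.6,
            "fwr3": 0.8,
            "cdr3": 1.8,
            "fwr4": 0.7,
            "np": 1.0,
        },
        substitution=_substitution_table(),
    )

    bundle = ReferenceBundle(
        usage=usage,
        trimming=trimming,
        np_lengths=np_lengths,
        markov_nonmut=markov_nonmut,
        markov_mut=markov_mut,
        shm=shm,
        provenance=(
            f"synthetic reference (seed={seed}, v_genes={n_v_genes}, "
            f"d_genes={n_d_genes}, j_genes={n_j_genes})"
        ),
    )
    bundle.validate()

    fasta_text = {
        seg: "".join(f">{a.name}\n{a.gapped_seq}\n" for a in alleles)
        for seg, alleles in (("V", v_alleles), ("D", d_alleles), ("J", j_alleles))
    }

    ref = SyntheticReference(
        v=v_alleles, d=d_alleles, j=j_alleles, bundle=bundle, fasta_text=fasta_text
    )
    if out_dir is not None:
        from .reference_model import save_bundle

        out_dir = Path(out_dir)
        gdir = out_dir / "germline"
        gdir.mkdir(parents=True, exist_ok=True)
        for seg, fname in (("V", "v.fasta"), ("D", "d.fasta"), ("J", "j.fasta")):
            (gdir / fname).write_text(fasta_text[seg])
        save_bundle(bundle, out_dir / "bundle", overwrite=True)
        ref.germline_dir = gdir
        ref.bundle_dir = out_dir / "bundle"
    return ref
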