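"""Sampling-distribution bundle: containers, validation, and TSV/JSON (de)serialization.

A :class:`ReferenceBundle` holds every distribution the simulator draws from:
segment usage, per-family trim-length vectors, NP insertion lengths,
position-dependent nucleotide transition matrices (separate mutated and
non-mutated variants), and the somatic-hypermutation model (per-sequence
mutation-frequency bins plus 5-mer x region mutability).  Bundles serialize
to a directory of long-format TSV files plus a manifest, so users can edit
or supply their own reference data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
TRIM_SITES = ("V_3p", "D_5p", "D_3p", "J_5p")
NP_JUNCTIONS = ("np1", "np2")
REGION_LABELS = ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3", "fwr4", "np")
POOLED = "__pooled__"
N_FIVEMERS = 4 ** 5

USAGE_EMPIRICAL = "empirical"
USAGE_FLAT_GENE = "flat-gene"
USAGE_FLAT_FAMILY = "flat-family"

_TOL = 1e-9


class BundleValidationError(ValueError):
    """Raised with every violated invariant listed, not just the first."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid reference bundle:\n  " + "\n  ".join(self.problems))


def fivemer_to_index(fivemer: str) -> Optional[int]:
    """Base-4 code of a 5-mer, or None if it contains non-ACGT characters."""
    idx = 0
    for c in fivemer:
        b = BASE_INDEX.get(c)
        if b is None:
            return None
        idx = idx * 4 + b
    return idx


def index_to_fivemer(idx: int) -> str:
    out = []
    for _ in range(5):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


@dataclass
class UsageModel:
    family_probs: dict  # segment -> {family: prob}
    gene_probs_within_family: dict  # family -> {gene: prob}
    mode: str = USAGE_EMPIRICAL

    def validate(self, problems):
        for seg, probs in self.family_probs.items():
            _check_probmap(probs, f"usage family_probs[{seg}]", problems)
        for fam, probs in self.gene_probs_within_family.items():
            _check_probmap(probs, f"usage gene_probs[{fam}]", problems)
        if self.mode not in {USAGE_EMPIRICAL, USAGE_FLAT_GENE, USAGE_FLAT_FAMILY}:
            problems.append(f"unknown usage mode {self.mode!r}")


@dataclass
class TrimmingModel:
    """Per trim-site, per gene-family probability vector over trim lengths 0..L_max."""

    dists: dict  # site -> {family: np.ndarray}

    def vector(self, site: str, family: str) -> np.ndarray:
        site_dists = self.dists[site]
        if family in site_dists:
            return site_dists[family]
        logger.debug("trim site %s: family %s absent, pooled fallback", site, family)
        return site_dists[POOLED]

    def l_max(self, site: str) -> int:
        return max(len(v) for v in self.dists[site].values()) - 1

    def validate(self, problems):
        for site in TRIM_SITES:
            if site not in self.dists:
                problems.append(f"trimming: missing site {site}")
                continue
            if POOLED not in self.dists[site]:
                problems.append(f"trimming[{site}]: missing pooled fallback")
            for fam, vec in self.dists[site].items():
                _check_probvec(vec, f"trimming[{site}][{fam}]", problems)


@dataclass
class NPLengthModel:
    dists: dict  # "np1"/"np2" -> np.ndarray over lengths 0..N_max

    def validate(self, problems):
        for junc in NP_JUNCTIONS:
            if junc not in self.dists:
                problems.append(f"np_lengths: missing junction {junc}")
                continue
            _check_probvec(self.dists[junc], f"np_lengths[{junc}]", problems)


@dataclass
class MarkovInsertionModel:
    """Position-dependent nucleotide chain for NP insertions.

    ``transition[p-1]`` is the 4x4 row-stochastic matrix used for insertion
    position p (row = base at p-1, column = base at p); positions beyond the
    table reuse the last matrix.
    """

    variant: str  # "nonmutated" or "mutated"
    first_base: np.ndarray  # (4,)
    transition: np.ndarray  # (P_max-1, 4, 4)

    @property
    def p_max(self) -> int:
        return self.transition.shape[0] + 1

    def matrix_for(self, position: int) -> np.ndarray:
        return self.transition[min(position, self.p_max - 1) - 1]

    def validate(self, problems):
        _check_probvec(self.first_base, f"markov_{self.variant}.first_base", problems)
        for p in range(self.transition.shape[0]):
            for r in range(4):
                row = self.transition[p, r]
                if np.any(row < 0) or abs(row.sum() - 1.0) > _TOL:
                    problems.append(
                        f"markov_{self.variant}: non-stochastic row "
                        f"position={p + 1} from={BASES[r]} (sum={row.sum():.12g})"
                    )


@dataclass
class SHMModel:
    """Somatic hypermutation: per-sequence load plus per-position targeting.

    ``freq_bin_edges``/``freq_probs`` define the binned per-sequence mutation
    frequency (mutations per nucleotide); ``fivemer_mutability`` is a
    1024-long weight array indexed by 5-mer code (N-containing contexts take
    the table mean); ``region_factor`` multiplies by immunoglobulin region.
    """

    freq_bin_edges: np.ndarray  # (B+1,)
    freq_probs: np.ndarray  # (B,)
    fivemer_mutability: np.ndarray  # (1024,)
    region_factor: dict  # label -> factor
    substitution: Optional[np.ndarray] = None  # (1024, 4), zero at center base

    @property
    def mutability_fallback(self) -> float:
        return float(self.fivemer_mutability.mean())

    def expected_frequency(self) -> float:
        """Mean mutation frequency implied by the binned distribution."""
        centers = (self.freq_bin_edges[:-1] + self.freq_bin_edges[1:]) / 2.0
        return float(np.dot(self.freq_probs, centers))

    def validate(self, problems):
        _check_probvec(self.freq_probs, "shm.freq_probs", problems)
        if len(self.freq_bin_edges) != len(self.freq_probs) + 1:
            problems.append("shm: bin edge / prob length mismatch")
        if np.any(np.diff(self.freq_bin_edges) <= 0):
            problems.append("shm: bin edges not strictly increasing")
        if self.fivemer_mutability.shape != (N_FIVEMERS,):
            problems.append("shm: fivemer_mutability must have 1024 entries")
        elif np.any(self.fivemer_mutability < 0):
            problems.append("shm: negative 5-mer mutability weight")
        for label, f in self.region_factor.items():
            if f < 0:
                problems.append(f"shm: negative region factor for {label}")
        if self.substitution is not None:
            if self.substitution.shape != (N_FIVEMERS, 4):
                problems.append("shm: substitution table must be (1024, 4)")
            else:
                sums = self.substitution.sum(axis=1)
                bad = np.where(np.abs(sums - 1.0) > _TOL)[0]
                for idx in bad[:5]:
                    problems.append(
                        f"shm: substitution row {index_to_fivemer(int(idx))} sums to "
                        f"{sums[idx]:.12g}"
                    )


@dataclass
class ReferenceBundle:
    usage: UsageModel
    trimming: TrimmingModel
    np_lengths: NPLengthModel
    markov_nonmut: MarkovInsertionModel
    markov_mut: MarkovInsertionModel
    shm: SHMModel
    provenance: str = ""

    def validate(self) -> None:
        problems: list[str] = []
        self.usage.validate(problems)
        self.trimming.validate(problems)
        self.np_lengths.validate(problems)
        self.markov_nonmut.validate(problems)
        self.markov_mut.validate(problems)
        self.shm.validate(problems)
        if problems:
            raise BundleValidationError(problems)
        # Fallback closure: warn (once) for families used but not modelled.
        seg_for_site = {"V_3p": "V", "D_5p": "D", "D_3p": "D", "J_5p": "J"}
        for site, seg in seg_for_site.items():
            for fam in self.usage.family_probs.get(seg, {}):
                if fam not in self.trimming.dists[site]:
                    logger.warning(
                        "trimming[%s]: family %s not modelled; pooled fallback", site, fam
                    )

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(_bundle_to_jsonable(self), sort_keys=True).encode()
        ).hexdigest()


def _check_probvec(vec, name, problems):
    vec = np.asarray(vec, dtype=float)
    if np.any(vec < 0):
        problems.append(f"{name}: negative probability")
    if abs(vec.sum() - 1.0) > _TOL:
        problems.append(f"{name}: sums to {vec.sum():.12g}, not 1")


def _check_probmap(probs, name, problems):
    vals = np.array(list(probs.values()), dtype=float)
    if vals.size == 0:
        problems.append(f"{name}: empty")
        return
    if np.any(vals < 0):
        problems.append(f"{name}: negative probability")
    if abs(vals.sum() - 1.0) > _TOL:
        problems.append(f"{name}: sums to {vals.sum():.12g}, not 1")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FILES = {
    "usage": "usage.tsv",
    "trimming": "trimming.tsv",
    "np_lengths": "np_lengths.tsv",
    "markov_nonmut": "markov_nonmut.tsv",
    "markov_mut": "markov_mut.tsv",
    "shm_freq": "shm_freq.tsv",
    "fivemer_mutability": "fivemer_mutability.tsv",
    "fivemer_substitution": "fivemer_substitution.tsv",  # optional
    "region_factor": "region_factor.tsv",
    "manifest": "manifest.json",
}


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def _read_tsv(path: Path) -> list[dict]:
    import csv

    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def save_bundle(bundle: ReferenceBundle, directory, overwrite: bool = False) -> None:
    """Write the bundle to its TSV/JSON file set (12 significant digits)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / _FILES["manifest"]
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")

    rows = []
    for seg in sorted(bundle.usage.family_probs):
        for fam in sorted(bundle.usage.family_probs[seg]):
            rows.append(("family", seg, fam, "", _fmt(bundle.usage.family_probs[seg][fam])))
    seg_of_family = {
        fam: seg for seg, fams in bundle.usage.family_probs.items() for fam in fams
    }
    for fam in sorted(bundle.usage.gene_probs_within_family):
        for gene in sorted(bundle.usage.gene_probs_within_family[fam]):
            rows.append(
                (
                    "gene",
                    seg_of_family.get(fam, ""),
                    fam,
                    gene,
                    _fmt(bundle.usage.gene_probs_within_family[fam][gene]),
                )
            )
    _write_tsv(directory / _FILES["usage"], ["kind", "segment", "family", "gene", "prob"], rows)

    rows = []
    for site in TRIM_SITES:
        for fam in sorted(bundle.trimming.dists[site]):
            for length, p in enumerate(bundle.trimming.dists[site][fam]):
                rows.append((site, fam, length, _fmt(p)))
    _write_tsv(directory / _FILES["trimming"], ["site", "family", "length", "prob"], rows)

    rows = []
    for junc in NP_JUNCTIONS:
        for length, p in enumerate(bundle.np_lengths.dists[junc]):
            rows.append((junc, length, _fmt(p)))
    _write_tsv(directory / _FILES["np_lengths"], ["junction", "length", "prob"], rows)

    for key, model in (("markov_nonmut", bundle.markov_nonmut), ("markov_mut", bundle.markov_mut)):
        rows = []
        for b, p in zip(BASES, model.first_base):
            rows.append(("first", 0, "", b, _fmt(p)))
        for pos in range(model.transition.shape[0]):
            for r, from_b in enumerate(BASES):
                for c, to_b in enumerate(BASES):
                    rows.append(("trans", pos + 1, from_b, to_b, _fmt(model.transition[pos, r, c])))
        _write_tsv(
            directory / _FILES[key], ["kind", "position", "from_base", "to_base", "prob"], rows
        )

    rows = [
        (_fmt(lo), _fmt(hi), _fmt(p))
        for lo, hi, p in zip(
            bundle.shm.freq_bin_edges[:-1], bundle.shm.freq_bin_edges[1:], bundle.shm.freq_probs
        )
    ]
    _write_tsv(directory / _FILES["shm_freq"], ["bin_low", "bin_high", "prob"], rows)

    rows = [
        (index_to_fivemer(i), _fmt(w)) for i, w in enumerate(bundle.shm.fivemer_mutability)
    ]
    _write_tsv(directory / _FILES["fivemer_mutability"], ["fivemer", "weight"], rows)

    if bundle.shm.substitution is not None:
        rows = []
        for i in range(N_FIVEMERS):
            for c, b in enumerate(BASES):
                p = bundle.shm.substitution[i, c]
                if p > 0:
                    rows.append((index_to_fivemer(i), b, _fmt(p)))
        _write_tsv(directory / _FILES["fivemer_substitution"], ["fivemer", "to_base", "prob"], rows)

    rows = [(lab, _fmt(f)) for lab, f in sorted(bundle.shm.region_factor.items())]
    _write_tsv(directory / _FILES["region_factor"], ["region", "factor"], rows)

    manifest = {
        "provenance": bundle.provenance,
        "usage_mode": bundle.usage.mode,
        "checksum": bundle.checksum(),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_bundle(directory) -> ReferenceBundle:
    """Load and fully validate a bundle directory.

    Validation failures enumerate every violated invariant in a single
    :class:`BundleValidationError`.
    """
    directory = Path(directory)
    required = [k for k in _FILES if k not in ("fivemer_substitution",)]
    missing = [
        _FILES[k] for k in required if not (directory / _FILES[k]).exists()
    ]
    if missing:
        raise FileNotFoundError(f"bundle at {directory} missing files: {', '.join(missing)}")

    with open(directory / _FILES["manifest"]) as fh:
        manifest = json.load(fh)

    family_probs: dict = {}
    gene_probs: dict = {}
    for row in _read_tsv(directory / _FILES["usage"]):
        if row["kind"] == "family":
            family_probs.setdefault(row["segment"], {})[row["family"]] = float(row["prob"])
        else:
            gene_probs.setdefault(row["family"], {})[row["gene"]] = float(row["prob"])
    usage = UsageModel(family_probs, gene_probs, mode=manifest.get("usage_mode", USAGE_EMPIRICAL))

    trim_rows: dict = {}
    for row in _read_tsv(directory / _FILES["trimming"]):
        trim_rows.setdefault(row["site"], {}).setdefault(row["family"], {})[
            int(row["length"])
        ] = float(row["prob"])
    trimming = TrimmingModel(
        {
            site: {
                fam: np.array([d[k] for k in range(max(d) + 1)]) for fam, d in fams.items()
            }
            for site, fams in trim_rows.items()
        }
    )

    np_rows: dict = {}
    for row in _read_tsv(directory / _FILES["np_lengths"]):
        np_rows.setdefault(row["junction"], {})[int(row["length"])] = float(row["prob"])
    np_lengths = NPLengthModel(
        {junc: np.array([d[k] for k in range(max(d) + 1)]) for junc, d in np_rows.items()}
    )

    markov = {}
    for key, variant in (("markov_nonmut", "nonmutated"), ("markov_mut", "mutated")):
        first = np.zeros(4)
        trans: dict = {}
        for row in _read_tsv(directory / _FILES[key]):
            if row["kind"] == "first":
                first[BASE_INDEX[row["to_base"]]] = float(row["prob"])
            else:
                pos = int(row["position"])
                trans.setdefault(pos, np.zeros((4, 4)))[
                    BASE_INDEX[row["from_base"]], BASE_INDEX[row["to_base"]]
                ] = float(row["prob"])
        p_max = max(trans) + 1 if trans else 1
        transition = np.stack([trans[p] for p in range(1, p_max)]) if trans else np.zeros((0, 4, 4))
        markov[key] = MarkovInsertionModel(variant=variant, first_base=first, transition=transition)

    freq_rows = _read_tsv(directory / _FILES["shm_freq"])
    edges = [float(r["bin_low"]) for r in freq_rows] + [float(freq_rows[-1]["bin_high"])]
    probs = np.array([float(r["prob"]) for r in freq_rows])

    mutability = np.zeros(N_FIVEMERS)
    for row in _read_tsv(directory / _FILES["fivemer_mutability"]):
        idx = fivemer_to_index(row["fivemer"])
        if idx is None:
            raise BundleValidationError([f"bad 5-mer {row['fivemer']!r} in mutability table"])
        mutability[idx] = float(row["weight"])

    substitution = None
    sub_path = directory / _FILES["fivemer_substitution"]
    if sub_path.exists():
        substitution = np.zeros((N_FIVEMERS, 4))
        for row in _read_tsv(sub_path):
            idx = fivemer_to_index(row["fivemer"])
            substitution[idx, BASE_INDEX[row["to_base"]]] = float(row["prob"])

    region_factor = {
        row["region"]: float(row["factor"])
        for row in _read_tsv(directory / _FILES["region_factor"])
    }

    shm = SHMModel(
        freq_bin_edges=np.array(edges),
        freq_probs=probs,
        fivemer_mutability=mutability,
        region_factor=region_factor,
        substitution=substitution,
    )
    bundle = ReferenceBundle(
        usage=usage,
        trimming=trimming,
        np_lengths=np_lengths,
        markov_nonmut=markov["markov_nonmut"],
        markov_mut=markov["markov_mut"],
        shm=shm,
        provenance=manifest.get("provenance", ""),
    )
    bundle.validate()
    return bundle


def _bundle_to_jsonable(bundle: ReferenceBundle) -> dict:
    def vec(v):
        return [_fmt(x) for x in np.asarray(v).ravel()]

    return {
        "usage_mode": bundle.usage.mode,
        "family_probs": {
            seg: {f: _fmt(p) for f, p in sorted(d.items())}
            for seg, d in sorted(bundle.usage.family_probs.items())
        },
        "gene_probs": {
            fam: {g: _fmt(p) for g, p in sorted(d.items())}
            for fam, d in sorted(bundle.usage.gene_probs_within_family.items())
        },
        "trimming": {
            site: {f: vec(v) for f, v in sorted(d.items())}
            for site, d in sorted(bundle.trimming.dists.items())
        },
        "np_lengths": {j: vec(v) for j, v in sorted(bundle.np_lengths.dists.items())},
        "markov_nonmut": [vec(bundle.markov_nonmut.first_base), vec(bundle.markov_nonmut.transition)],
        "markov_mut": [vec(bundle.markov_mut.first_base), vec(bundle.markov_mut.transition)],
        "shm_freq": [vec(bundle.shm.freq_bin_edges), vec(bundle.shm.freq_probs)],
        "fivemer_mutability": vec(bundle.shm.fivemer_mutability),
        "substitution": None if bundle.shm.substitution is None else vec(bundle.shm.substitution),
        "region_factor": {k: _fmt(v) for k, v in sorted(bundle.shm.region_factor.items())},
    }


def __getattr__(name):
    # re-exported so the reference-model surface includes the generator,
    # lazily to avoid a circular import with bcrsim.synthetic
    if name == "make_synthetic_reference":
        from .synthetic import make_synthetic_reference

        return make_synthetic_reference
    raise AttributeError(name)
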