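"""Synthetic ALP proteomes with planted ground truth.

Generates protein sequences that emulate the salient features of the real
methanogen ALP repertoires — Asn/Thr-enriched repeat domains, N-/C-terminal
membrane anchors with cytoplasmic KK-type pairs, 1–7 right-handed
beta-helical (RBH) repeats with a chain of conserved loop asparagines,
1–27 archaeal big domain (ABD) repeats with invariant loop glycines, and a
minority of transglutaminase/pseudomurein/other architectures — together
with the exact domain intervals, anchor positions, motif positions and
group labels used to produce them. Every pipeline stage can therefore be
scored against a known truth without any external data.

Class-conditional architecture grammars are the inverse of the
classification rules, so the planted group label is consistent with the
emitted architecture by construction. Linkers are drawn from a polar
background so planted anchors are the only hydrophobic stretches. All
randomness flows through numpy Generators keyed (seed, protein index), so
a spec with a fixed seed reproduces its output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architecture import ALPGroup, SYMBOLS
from .seqio import (
    AMINO_ACIDS,
    AnnotationSource,
    DomainAnnotation,
    DomainType,
    ProteinRecord,
    Alignment,
    write_domain_table,
    write_fasta,
)

#: group frequencies proportional to the reported subgroup sizes of the two
#: real repertoires (IA 40, IB 12, IIA 13, IIB 5, III 4, Others 13) plus the
#: 14 domain-free sequences discarded as NOT_ALP
DEFAULT_GROUP_WEIGHTS: dict[ALPGroup, float] = {
    ALPGroup.IA: 40 / 101,
    ALPGroup.IB: 12 / 101,
    ALPGroup.IIA: 13 / 101,
    ALPGroup.IIB: 5 / 101,
    ALPGroup.III: 4 / 101,
    ALPGroup.OTHERS: 13 / 101,
    ALPGroup.NOT_ALP: 14 / 101,
}

#: uniform background residue model the Asn/Thr boost is measured against
BACKGROUND_FREQS: dict[str, float] = {aa: 0.05 for aa in AMINO_ACIDS}

_LINKER_RESIDUES = list("STNQDEGP")
_TM_RESIDUES, _TM_WEIGHTS = list("LIVF"), [0.40, 0.25, 0.20, 0.15]
_SHORT_RESIDUES, _SHORT_WEIGHTS = list("LF"), [0.70, 0.30]
_GUARD_RESIDUES = list("NQDE")          # strongly hydrophilic, no K/R
_RBH_CONSERVED_N_PERIOD = 22            # one conserved loop Asn per coil
_ABD_GLY_OFFSETS = (9, 24, 39, 54, 69)  # invariant loop glycines (0-based)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic proteome; defaults mirror the real repertoires."""

    n_proteins: int = 91
    group_weights: dict[ALPGroup, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS)
    )
    rbh_repeat_range: tuple[int, int] = (1, 7)
    abd_repeat_range: tuple[int, int] = (1, 27)
    abd_len_range: tuple[int, int] = (80, 120)
    rbh_len_range: tuple[int, int] = (250, 1236)
    tm_len_range: tuple[int, int] = (20, 28)
    asn_thr_boost: float = 2.0
    dual_mad_prob: float = 11 / 91
    no_mad_prob: float = 5 / 91
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.group_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group weights must sum to 1 (got {total})")
        for name in ("rbh_repeat_range", "abd_repeat_range", "abd_len_range",
                     "rbh_len_range", "tm_len_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"empty or invalid range {name}: {(lo, hi)}")
        if self.asn_thr_boost < 1.0:
            raise ValueError("asn_thr_boost must be ≥ 1")
        if self.asn_thr_boost * 0.10 >= 1.0:
            raise ValueError("asn_thr_boost too large for a proper distribution")


@dataclass(frozen=True)
class ProteinTruth:
    """Planted ground truth for one synthetic protein."""

    protein_id: str
    group: ALPGroup
    architecture: str
    anchors: tuple[tuple[int, int, str], ...]   # (start, end, kind)
    motifs: tuple[tuple[int, str], ...]         # (position, pair)


# ---------------------------------------------------------------------------
# residue samplers
# ---------------------------------------------------------------------------

def _boosted_distribution(boost: float) -> tuple[list[str], np.ndarray]:
    """Background with Asn and Thr multiplied by ``boost`` exactly.

    N and T get boost×0.05 each; the other 18 residues share the remainder
    equally, so log2(freq/background) is exactly log2(boost) for N and T.
    """
    p = np.full(20, (1.0 - 0.10 * boost) / 18.0)
    letters = list(AMINO_ACIDS)
    for aa in "NT":
        p[letters.index(aa)] = 0.05 * boost
    return letters, p


def _interior_distribution(
    boost: float, conserved: str, conserved_fraction: float
) -> tuple[list[str], np.ndarray]:
    """Interior distribution compensating for a planted conserved residue.

    Chosen so the whole domain (conserved positions plus interior draws)
    matches the boosted target composition in expectation.
    """
    letters, target = _boosted_distribution(boost)
    s = conserved_fraction
    q = target / (1.0 - s)
    ci = letters.index(conserved)
    q[ci] = max(0.0, (target[ci] - s) / (1.0 - s))
    q /= q.sum()
    return letters, q


def _draw(rng: np.random.Generator, n: int, letters: list[str], p=None) -> str:
    return "".join(rng.choice(letters, size=n, p=p))


def _linker(rng: np.random.Generator, lo: int, hi: int) -> str:
    return _draw(rng, int(rng.integers(lo, hi + 1)), _LINKER_RESIDUES)


# ---------------------------------------------------------------------------
# domain emitters
# ---------------------------------------------------------------------------

def _abd_seq(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    lo, hi = spec.abd_len_range
    n = int(rng.integers(lo, hi + 1))
    s = len(_ABD_GLY_OFFSETS) / n
    letters, q = _interior_distribution(spec.asn_thr_boost, "G", s)
    seq = list(_draw(rng, n, letters, q))
    for off in _ABD_GLY_OFFSETS:
        if off < n:
            seq[off] = "G"
    return "".join(seq)


def _rbh_seq(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    lo, hi = spec.rbh_len_range
    n = int(rng.integers(lo, hi + 1))
    s = 1.0 / _RBH_CONSERVED_N_PERIOD
    letters, q = _interior_distribution(spec.asn_thr_boost, "N", s)
    seq = list(_draw(rng, n, letters, q))
    for i in range(0, n, _RBH_CONSERVED_N_PERIOD):
        seq[i] = "N"
    return "".join(seq)


def _generic_domain_seq(rng: np.random.Generator, lo: int, hi: int) -> str:
    # mild hydrophobic depletion keeps random domains from mimicking anchors
    letters = list(AMINO_ACIDS)
    w = np.array([0.5 if aa in "LIVFMCW" else 1.0 for aa in letters])
    return _draw(rng, int(rng.integers(lo, hi + 1)), letters, w / w.sum())


def _tm_seq(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    lo, hi = spec.tm_len_range
    return _draw(rng, int(rng.integers(lo, hi + 1)), _TM_RESIDUES, _TM_WEIGHTS)


def _short_seq(rng: np.random.Generator) -> str:
    # 10-12 residues of L/F: Fauchère-Pliška mean > 1 but, with hydrophilic
    # guards, below the 19-window Kyte-Doolittle TM criterion
    return _draw(rng, int(rng.integers(10, 13)), _SHORT_RESIDUES, _SHORT_WEIGHTS)


def _amph_seq(rng: np.random.Generator) -> str:
    # 18-mer with hydrophobic residues on one helical face (100° per residue)
    out = []
    for i in range(18):
        angle = (i * 100) % 360
        if angle < 180:
            out.append(rng.choice(list("LIF")))
        else:
            out.append(rng.choice(list("SQN")))
    return "".join(out)


def _motif_pair(rng: np.random.Generator) -> str:
    u = rng.random()
    if u < 0.40:
        return "KK"
    if u < 0.80:
        return "KN"
    return str(rng.choice(["KR", "RK", "RN", "KD", "RD", "RR"]))


# ---------------------------------------------------------------------------
# architecture grammars (inverse of the classification rules)
# ---------------------------------------------------------------------------

def _sample_sigma(rng: np.random.Generator, group: ALPGroup, spec: SyntheticSpec) -> str:
    r_lo, r_hi = spec.rbh_repeat_range
    a_lo, a_hi = spec.abd_repeat_range
    if group is ALPGroup.IA:
        # a single RBH dominates the real subgroup; repeats occur
        j = 1 if rng.random() < 0.65 else int(rng.integers(max(2, r_lo), r_hi + 1))
        k = int(rng.integers(a_lo, a_hi + 1))
        return "r" * j + "a" * k
    if group is ALPGroup.IB:
        j = int(rng.integers(r_lo, r_hi + 1))
        k = int(rng.integers(max(1, a_lo), a_hi + 1))
        k1 = int(rng.integers(1, k + 1))  # ≥1 ABD N-terminal to the RBH block
        return "a" * k1 + "r" * j + "a" * (k - k1)
    if group is ALPGroup.IIA:
        k = int(rng.integers(a_lo, min(a_hi, 17) + 1))  # 1-17 repeats observed
        return "a" * k
    if group is ALPGroup.IIB:
        return "r" * int(rng.integers(r_lo, r_hi + 1))
    if group is ALPGroup.III:
        k = int(rng.integers(1, 6))
        b = "b" if rng.random() < 0.5 else ""
        return "a" * k + b + "g"
    if group is ALPGroup.OTHERS:
        k = int(rng.integers(1, 6))
        j = int(rng.integers(1, 4))
        template = int(rng.integers(0, 4))
        return ["a" * k + "o", "o" + "r" * j + "a" * k, "a" * k + "b", "g" + "a" * k][template]
    # NOT_ALP decoys: no ABD, no RBH
    return "o" * int(rng.integers(0, 4))


_DOMAIN_TYPES = {
    "a": DomainType.ABD,
    "r": DomainType.RBH,
    "g": DomainType.TG,
    "b": DomainType.PMB,
    "o": DomainType.OTHER,
}


def _domain_seq(rng: np.random.Generator, symbol: str, spec: SyntheticSpec) -> str:
    if symbol == "a":
        return _abd_seq(rng, spec)
    if symbol == "r":
        return _rbh_seq(rng, spec)
    if symbol == "g":
        return _generic_domain_seq(rng, 150, 250)
    if symbol == "b":
        return _generic_domain_seq(rng, 60, 100)
    return _generic_domain_seq(rng, 80, 300)


# ---------------------------------------------------------------------------
# protein assembly
# ---------------------------------------------------------------------------

def _assemble_protein(
    rng: np.random.Generator, pid: str, group: ALPGroup, spec: SyntheticSpec
) -> tuple[ProteinRecord, list[DomainAnnotation], ProteinTruth]:
    sigma = _sample_sigma(rng, group, spec)
    no_mad = rng.random() < spec.no_mad_prob
    n_kind = None
    c_anchor = False
    if not no_mad:
        u = rng.random()
        n_kind = "TM" if u < 0.8 else ("SHORT_HYDROPHOBIC" if u < 0.9 else "AMPHIPATHIC")
        c_anchor = rng.random() < spec.dual_mad_prob

    parts: list[str] = []
    annotations: list[tuple[DomainType, int, int]] = []  # resolved to ids later
    anchors: list[tuple[int, int, str]] = []
    motifs: list[tuple[int, str]] = []
    pos = 0  # length emitted so far

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        start = pos + 1
        pos += len(seq)
        return start, pos

    if n_kind is not None:
        emit(_linker(rng, 1, 6))
        if n_kind in ("TM", "SHORT_HYDROPHOBIC"):
            mstart, _ = emit(_motif_pair(rng))
            motifs.append((mstart, parts[-1]))
        astart, aend = emit(
            _tm_seq(rng, spec) if n_kind == "TM"
            else _short_seq(rng) if n_kind == "SHORT_HYDROPHOBIC"
            else _amph_seq(rng)
        )
        anchors.append((astart, aend, n_kind))
        annotations.append((DomainType.MAD, astart, aend))
        if n_kind == "SHORT_HYDROPHOBIC":
            emit(_draw(rng, 4, _GUARD_RESIDUES))

    for symbol in sigma:
        emit(_linker(rng, 5, 20))
        dstart, dend = emit(_domain_seq(rng, symbol, spec))
        annotations.append((_DOMAIN_TYPES[symbol], dstart, dend))

    if c_anchor:
        emit(_linker(rng, 5, 20))
        astart, aend = emit(_tm_seq(rng, spec))
        anchors.append((astart, aend, "TM"))
        annotations.append((DomainType.MAD, astart, aend))
        mstart, _ = emit(_motif_pair(rng))
        motifs.append((mstart, parts[-1]))
        emit(_linker(rng, 1, 4))
    else:
        emit(_linker(rng, 3, 15))

    if pos < 128:  # keep proteins within the realistic length range
        emit(_draw(rng, 128 - pos, _LINKER_RESIDUES))

    sequence = "".join(parts)
    raw_arch = "".join(
        SYMBOLS[t] for t, _, _ in sorted(annotations, key=lambda x: x[1])
    )
    record = ProteinRecord(
        id=pid, sequence=sequence,
        description=f"group={group.value} arch={raw_arch or '-'}",
    )
    anns = [
        DomainAnnotation(protein_id=pid, domain_type=t, start=s, end=e,
                         source=AnnotationSource.SYNTHETIC)
        for t, s, e in sorted(annotations, key=lambda x: x[1])
    ]
    truth = ProteinTruth(
        protein_id=pid, group=group, architecture=raw_arch,
        anchors=tuple(anchors), motifs=tuple(motifs),
    )
    return record, anns, truth


def generate_proteome(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[DomainAnnotation], list[ProteinTruth]]:
    """Sample a full synthetic proteome: records, annotations, ground truth."""
    groups = list(spec.group_weights)
    weights = np.array([spec.group_weights[g] for g in groups])
    records: list[ProteinRecord] = []
    annotations: list[DomainAnnotation] = []
    truths: list[ProteinTruth] = []
    for i in range(spec.n_proteins):
        rng = np.random.default_rng([spec.seed, i])
        group = groups[int(rng.choice(len(groups), p=weights))]
        rec, anns, truth = _assemble_protein(rng, f"SYN{i:04d}", group, spec)
        records.append(rec)
        annotations.extend(anns)
        truths.append(truth)
    return records, annotations, truths


def write_truth_table(truths: list[ProteinTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgroup\tarchitecture\tanchors\tmotifs\n")
        for t in truths:
            anchor_s = ";".join(f"{s}-{e}-{k}" for s, e, k in t.anchors)
            motif_s = ";".join(f"{p}-{pair}" for p, pair in t.motifs)
            fh.write(f"{t.protein_id}\t{t.group.value}\t{t.architecture}\t"
                     f"{anchor_s}\t{motif_s}\n")


def simulate_to_dir(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a proteome and write proteins.fasta, domains.tsv, truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, annotations, truths = generate_proteome(spec)
    paths = {
        "proteins": out / "proteins.fasta",
        "domains": out / "domains.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(records, paths["proteins"])
    write_domain_table(annotations, paths["domains"])
    write_truth_table(truths, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# random additive trees (validation inputs for distance phylogenetics)
# ---------------------------------------------------------------------------

def random_additive_distance_matrix(n_taxa: int, rng: np.random.Generator):
    """Patristic distances of a random binary unrooted tree.

    Edge lengths are uniform on [0.05, 1.0], so the matrix is strictly
    additive with a unique binary realization — the ground truth for
    checking that neighbor joining reconstructs tree distances exactly.
    Returns an :class:`alpscan.phylo.DistanceMatrix`.
    """
    from .phylo import DistanceMatrix

    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    labels = [f"T{i}" for i in range(n_taxa)]
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_taxa)}
    active = list(range(n_taxa))
    next_id = n_taxa
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b, a = active.pop(int(j)), active.pop(int(i))
        u = next_id
        next_id += 1
        adj[u] = []
        for x in (a, b):
            w = float(rng.uniform(0.05, 1.0))
            adj[u].append((x, w))
            adj[x].append((u, w))
        active.append(u)
    a, b = active
    w = float(rng.uniform(0.05, 1.0))
    adj[a].append((b, w))
    adj[b].append((a, w))
    d = np.zeros((n_taxa, n_taxa))
    for leaf in range(n_taxa):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, wt in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + wt
                    stack.append(v)
        for other in range(n_taxa):
            d[leaf, other] = dist[other]
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=tuple(labels), values=d)


# ---------------------------------------------------------------------------
# ABD alignment generator
# ---------------------------------------------------------------------------

def generate_abd_alignment(
    n_seqs: int,
    n_invariant_gly: int = 5,
    clade_labels: list[str] | None = None,
    n_columns: int = 100,
    clade_divergence: float = 0.5,
    substitution_rate: float = 0.05,
    seed: int = 0,
) -> tuple[Alignment, dict]:
    """Gap-free ABD-like alignment with planted invariant glycine columns.

    Clade structure is induced by clade-specific consensus substitutions at
    ``clade_divergence`` of the non-invariant columns; individual sequences
    then substitute each non-invariant column with probability
    ``substitution_rate``. Returns the alignment and a truth dict with the
    invariant column indices (0-based) and per-sequence clade labels.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    if n_invariant_gly > n_columns:
        raise ValueError("more invariant glycines than columns")
    if clade_labels is None:
        clade_labels = ["clade0"] * n_seqs
    if len(clade_labels) != n_seqs:
        raise ValueError("clade_labels length must equal n_seqs")
    rng = np.random.default_rng([seed])
    non_gly_letters = [aa for aa in AMINO_ACIDS if aa != "G"]
    gly_cols = sorted(rng.choice(n_columns, size=n_invariant_gly, replace=False).tolist())
    gly_set = set(gly_cols)
    consensus = [
        "G" if j in gly_set else str(rng.choice(non_gly_letters))
        for j in range(n_columns)
    ]
    mutable = [j for j in range(n_columns) if j not in gly_set]
    clade_consensus: dict[str, list[str]] = {}
    for clade in dict.fromkeys(clade_labels):
        cols = rng.choice(
            mutable, size=int(round(clade_divergence * len(mutable))), replace=False
        )
        cc = list(consensus)
        for j in cols:
            choices = [aa for aa in non_gly_letters if aa != cc[j]]
            cc[j] = str(rng.choice(choices))
        clade_consensus[clade] = cc
    rows = []
    for i in range(n_seqs):
        cc = clade_consensus[clade_labels[i]]
        seq = list(cc)
        for j in mutable:
            if rng.random() < substitution_rate:
                choices = [aa for aa in non_gly_letters if aa != cc[j]]
                seq[j] = str(rng.choice(choices))
        rows.append((f"ABD{i:04d}", "".join(seq)))
    truth = {"invariant_columns": tuple(gly_cols), "clade_labels": list(clade_labels)}
    return Alignment(records=tuple(rows)), truth
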