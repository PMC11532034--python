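"""Domain-architecture strings: encoding, clustering, ALP classification.

A protein's domain annotations, sorted by start, are transcribed into a
single-letter string (MAD→t, RBH→r, ABD→a, PMB→b, TG→g, OTHER→o); e.g. the
domain sequence TMD-RBH-ABD-ABD-ABD-ABD-ABD becomes ``traaaaa``. These
strings are clustered with DBSCAN (eps 0.5, minPts 1) on a normalized
Levenshtein distance and classified into ALP groups by a deterministic rule
cascade on the non-anchor symbols:

* NOT_ALP  — neither ABD nor RBH present (discarded from the repertoire)
* IA       — RBH repeats followed by ABD repeats (``r+a+``)
* IB       — both ABD and RBH, in any other arrangement
* IIA/IIB  — only ABD / only RBH
* III      — transglutaminase-type: ABDs before the TG domain, no RBH
* OTHERS   — any additional domain types
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from sklearn.cluster import DBSCAN

from .seqio import DomainAnnotation, DomainType

#: domain letter codes
SYMBOLS: dict[DomainType, str] = {
    DomainType.MAD: "t",
    DomainType.RBH: "r",
    DomainType.ABD: "a",
    DomainType.PMB: "b",
    DomainType.TG: "g",
    DomainType.OTHER: "o",
}
ALPHABET = frozenset(SYMBOLS.values())


@dataclass(frozen=True)
class ArchitectureString:
    """Ordered single-letter encoding of a protein's domain architecture."""

    protein_id: str
    raw: str

    def __post_init__(self) -> None:
        bad = set(self.raw) - ALPHABET
        if bad:
            raise ValueError(f"invalid architecture symbols: {sorted(bad)}")

    @property
    def compressed(self) -> tuple[tuple[str, int], ...]:
        """Run-length compressed form, e.g. ``traaa`` → ((t,1),(r,1),(a,3))."""
        return tuple((sym, len(list(g))) for sym, g in itertools.groupby(self.raw))

    def compressed_str(self) -> str:
        return "".join(f"{s}{n}" for s, n in self.compressed)


class ALPGroup(Enum):
    IA = "IA"
    IB = "IB"
    IIA = "IIA"
    IIB = "IIB"
    III = "III"
    OTHERS = "Others"
    NOT_ALP = "NOT_ALP"


@dataclass(frozen=True)
class ALPClass:
    value: ALPGroup
    rationale: str


@dataclass(frozen=True)
class ClusterResult:
    labels: dict[str, int]
    eps: float
    min_pts: int
    metric_name: str


def encode_architecture(annotations: Sequence[DomainAnnotation]) -> ArchitectureString:
    """Transcribe one protein's annotations (sorted by start) into letters.

    Non-MAD annotations must not overlap each other; MAD may overlap others
    (an anchor can sit inside or against a structural domain).
    """
    if not annotations:
        raise ValueError("cannot encode an empty annotation list without a protein id; "
                         "use encode_architecture_for(protein_id, [])")
    return encode_architecture_for(annotations[0].protein_id, annotations)


def encode_architecture_for(
    protein_id: str, annotations: Sequence[DomainAnnotation]
) -> ArchitectureString:
    ids = {a.protein_id for a in annotations}
    if ids and ids != {protein_id}:
        raise ValueError(f"annotations for multiple proteins: {sorted(ids)}")
    ordered = sorted(annotations, key=lambda a: (a.start, a.end))
    non_mad = [a for a in ordered if a.domain_type is not DomainType.MAD]
    for a, b in zip(non_mad, non_mad[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"overlapping non-MAD annotations on {protein_id!r}: "
                f"{a.domain_type.value} {a.start}..{a.end} / {b.domain_type.value} {b.start}..{b.end}"
            )
    raw = "".join(SYMBOLS[a.domain_type] for a in ordered)
    return ArchitectureString(protein_id=protein_id, raw=raw)


def string_distance(s1: ArchitectureString | str, s2: ArchitectureString | str) -> float:
    """Normalized Levenshtein distance on raw strings, in [0, 1].

    Edit distance divided by max(len1, len2); two empty strings are at
    distance 0. Raw (uncompressed) strings are used so repeat-count
    differences contribute to the distance.
    """
    a = s1.raw if isinstance(s1, ArchitectureString) else s1
    b = s2.raw if isinstance(s2, ArchitectureString) else s2
    if not a and not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return dist / max(len(a), len(b))


def distance_matrix(strings: Sequence[ArchitectureString]) -> np.ndarray:
    n = len(strings)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = string_distance(strings[i], strings[j])
    return d


def dbscan_cluster(
    strings: Sequence[ArchitectureString],
    eps: float = 0.5,
    min_pts: int = 1,
) -> ClusterResult:
    """DBSCAN over the pairwise normalized-Levenshtein matrix.

    With minPts = 1 every point is a core point, so the clustering equals
    the connected components of the graph joining pairs at distance ≤ eps.
    Labels are integers ≥ 1, renumbered by first occurrence in input order.
    """
    if not strings:
        raise ValueError("no architecture strings to cluster")
    d = distance_matrix(strings)
    raw_labels = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(d).labels_
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for arch, lab in zip(strings, raw_labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[arch.protein_id] = remap[lab]
    return ClusterResult(labels=labels, eps=eps, min_pts=min_pts,
                         metric_name="levenshtein_raw")


_IA_PATTERN = re.compile(r"r+a+")


def classify(arch: ArchitectureString) -> ALPClass:
    """Deterministic group assignment from the non-anchor symbol sequence.

    Rule cascade on σ = raw with all 't' removed:

    1. no 'a' and no 'r'                     → NOT_ALP
    2. 'g' present → III when no 'r', no 'o' and every 'a' precedes the
       first 'g' ('b' permitted anywhere);     else → OTHERS
    3. 'o' or 'b' present                    → OTHERS
    4. both 'a' and 'r': σ matches r+a+      → IA, else IB
    5. only 'a' → IIA; only 'r'              → IIB
    """
    sigma = arch.raw.replace("t", "")
    if "a" not in sigma and "r" not in sigma:
        return ALPClass(ALPGroup.NOT_ALP, "rule 1: no ABD and no RBH")
    if "g" in sigma:
        stripped = sigma.replace("b", "")
        first_g = stripped.index("g")
        abds_before_g = "a" not in stripped[first_g:]
        if "r" not in sigma and "o" not in sigma and abds_before_g:
            return ALPClass(ALPGroup.III, "rule 2: TG-type, ABDs N-terminal to TG")
        return ALPClass(ALPGroup.OTHERS, "rule 2: TG with extra/ill-placed domains")
    if "o" in sigma or "b" in sigma:
        return ALPClass(ALPGroup.OTHERS, "rule 3: non-core domain present")
    if "a" in sigma and "r" in sigma:
        if _IA_PATTERN.fullmatch(sigma):
            return ALPClass(ALPGroup.IA, "rule 4: RBH repeats followed by ABD repeats")
        return ALPClass(ALPGroup.IB, "rule 4: ABD/RBH order not fixed")
    if "a" in sigma:
        return ALPClass(ALPGroup.IIA, "rule 5: ABD only")
    return ALPClass(ALPGroup.IIB, "rule 5: RBH only")


def filter_alps(classes: Mapping[str, ALPClass]) -> tuple[set[str], set[str]]:
    """Partition protein ids into accepted ALPs and NOT_ALP rejects."""
    alps = {pid for pid, c in classes.items() if c.value is not ALPGroup.NOT_ALP}
    rejected = set(classes) - alps
    return alps, rejected


def classify_proteome(
    annotations_by_protein: Mapping[str, Sequence[DomainAnnotation]],
) -> dict[str, ALPClass]:
    """Encode and classify every protein of a proteome."""
    return {
        pid: classify(encode_architecture_for(pid, anns))
        for pid, anns in annotations_by_protein.items()
    }
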