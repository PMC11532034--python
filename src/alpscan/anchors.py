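"""Membrane-anchor detection from raw protein sequence.

ALPs are tethered to the archaeal membrane by membrane-anchoring domains
(MADs) of three kinds: full transmembrane (TM) helices, short (<20 aa)
hydrophobic helices that do not span the bilayer, and terminal amphipathic
helices that can lie parallel to the membrane surface. All three are called
from sequence alone:

* TM helices — sliding Kyte–Doolittle hydropathy window (window 19,
  threshold 1.6, the classic hydropathy-plot settings).
* short hydrophobic helices — terminal segments of 10–19 residues whose
  mean Fauchère–Pliška hydrophobicity (the HeliQuest "hydrophobicity
  index") exceeds 1.
* amphipathic helices — 18-residue terminal windows whose Eisenberg
  hydrophobic moment (100° per residue) reaches 0.5.

Di-basic (KK-type) pairs flanking TM helices on the cytoplasmic side are
scanned separately; they hint at helix orientation in the membrane.
"""

from __future__ import annotations

import cmath
import enum
import math
from dataclasses import dataclass

import numpy as np

from .seqio import AnnotationSource, DomainAnnotation, DomainType, ProteinRecord


@dataclass(frozen=True)
class HydrophobicityScale:
    """Per-residue transfer free-energy scores; 'X' and '-' score 0."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(f"scale {self.name!r} must key exactly the 20 residues")

    def __getitem__(self, residue: str) -> float:
        return self.values.get(residue, 0.0)


#: Fauchère–Pliška octanol/water transfer scale (relative to Gly = 0);
#: the scale behind HeliQuest's hydrophobicity index and moment.
FAUCHERE_PLISKA = HydrophobicityScale(
    "fauchere_pliska",
    {
        "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
        "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
        "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
        "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
    },
)

#: Kyte–Doolittle hydropathy, used for TM window scanning.
KYTE_DOOLITTLE = HydrophobicityScale(
    "kyte_doolittle",
    {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
)


class HelixKind(enum.Enum):
    TM = "TM"
    SHORT_HYDROPHOBIC = "SHORT_HYDROPHOBIC"
    AMPHIPATHIC = "AMPHIPATHIC"


class Terminal(enum.Enum):
    N = "N"
    C = "C"
    INTERNAL = "internal"


@dataclass(frozen=True)
class HelixCandidate:
    """A detected membrane-anchor segment (1-based inclusive interval)."""

    protein_id: str
    start: int
    end: int
    kind: HelixKind
    mean_hydrophobicity: float
    hydrophobic_moment: float
    terminal: Terminal

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class MotifClass(enum.Enum):
    DI_LYSINE = "DI_LYSINE"
    LYS_ASN = "LYS_ASN"
    OTHER_VARIANT = "OTHER_VARIANT"


class MotifSide(enum.Enum):
    UPSTREAM_OF_N_HELIX = "upstream_of_N_helix"
    DOWNSTREAM_OF_C_HELIX = "downstream_of_C_helix"


@dataclass(frozen=True)
class DiBasicMotif:
    """A KK-type pair flanking a TM helix on its presumed cytoplasmic side."""

    protein_id: str
    position: int          # 1-based index of the first residue of the pair
    pair: str
    motif_class: MotifClass
    flank_of: HelixCandidate
    side: MotifSide


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def mean_hydrophobicity(segment: str, scale: HydrophobicityScale = FAUCHERE_PLISKA) -> float:
    """Arithmetic mean of per-residue scale values ('X'/'-' contribute 0)."""
    if not segment:
        raise ValueError("empty segment")
    return sum(scale[r] for r in segment) / len(segment)


def hydrophobic_moment(
    segment: str,
    scale: HydrophobicityScale = FAUCHERE_PLISKA,
    delta_deg: float = 100.0,
) -> float:
    """Eisenberg hydrophobic moment μH at ``delta_deg`` per residue.

    μH = |Σ_k H_k · exp(i·k·δ)| / N with δ = 100° for an ideal α-helix.
    High values mean hydrophobicity is segregated onto one helix face.
    """
    if not segment:
        raise ValueError("empty segment")
    delta = math.radians(delta_deg)
    total = sum(scale[r] * cmath.exp(1j * k * delta) for k, r in enumerate(segment))
    return abs(total) / len(segment)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _terminal(start: int, end: int, length: int) -> Terminal:
    if start <= 40:
        return Terminal.N
    if end >= length - 39:
        return Terminal.C
    return Terminal.INTERNAL


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def _make_candidate(record: ProteinRecord, start: int, end: int, kind: HelixKind) -> HelixCandidate:
    seg = record.sequence[start - 1:end]
    scale = KYTE_DOOLITTLE if kind is HelixKind.TM else FAUCHERE_PLISKA
    return HelixCandidate(
        protein_id=record.id,
        start=start,
        end=end,
        kind=kind,
        mean_hydrophobicity=mean_hydrophobicity(seg, scale),
        hydrophobic_moment=hydrophobic_moment(seg),
        terminal=_terminal(start, end, len(record)),
    )


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_tm_segments(
    record: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
) -> list[HelixCandidate]:
    """Hydropathy-plot TM scan: maximal runs of above-threshold windows.

    Each residue position that can center a full window gets the
    Kyte–Doolittle mean of that window; consecutive above-threshold centers
    form a run, and a run of centers c1..c2 yields the segment
    [c1 - w//2, c2 + w//2]. Overlapping segments are merged.
    Sequences shorter than the window yield an empty list.
    """
    L = len(record)
    if L < window:
        return []
    half = window // 2
    scores = np.array([KYTE_DOOLITTLE[r] for r in record.sequence])
    means = np.convolve(scores, np.ones(window) / window, mode="valid")
    # means[i] is the window starting at 0-based i, centered at i + half
    above = means > threshold
    segments: list[list[int]] = []
    for i, flag in enumerate(above):
        if not flag:
            continue
        center = i + half + 1  # 1-based center
        start, end = center - half, center + half
        if segments and start <= segments[-1][1]:
            segments[-1][1] = end
        else:
            segments.append([start, end])
    return [_make_candidate(record, s, e, HelixKind.TM) for s, e in segments]


def _terminal_regions(length: int, span: int) -> list[tuple[int, int]]:
    regions = [(1, min(span, length))]
    tail = (max(1, length - span + 1), length)
    if tail[0] > regions[0][1]:
        regions.append(tail)
    else:
        regions = [(1, length)]
    return regions


def detect_short_hydrophobic(
    record: ProteinRecord,
    tm: list[HelixCandidate] | None = None,
    terminal_span: int = 60,
    min_len: int = 10,
    max_len: int = 19,
    index_min: float = 1.0,
) -> list[HelixCandidate]:
    """Short (<20 aa) hydrophobic helices near the termini.

    Candidate segments of ``min_len``–``max_len`` residues within the first
    or last ``terminal_span`` residues whose mean Fauchère–Pliška
    hydrophobicity exceeds ``index_min``. Only maximal segments are kept
    (no qualifying candidate contained in a longer one), candidates inside
    a TM helix are dropped, and overlapping survivors are resolved in
    favour of the higher mean.
    """
    if tm is None:
        tm = detect_tm_segments(record)
    L = len(record)
    tm_ivs = [(c.start, c.end) for c in tm]
    raw: list[tuple[int, int, float]] = []
    for lo, hi in _terminal_regions(L, terminal_span):
        for s in range(lo, hi + 1):
            for e in range(min(hi, s + max_len - 1), s + min_len - 2, -1):
                seg = record.sequence[s - 1:e]
                if len(seg) < min_len:
                    break
                m = mean_hydrophobicity(seg, FAUCHERE_PLISKA)
                if m > index_min:
                    raw.append((s, e, m))
                    break  # longer qualifying segment found; shorter ones not maximal
    # maximality across starts: drop candidates contained in another candidate
    keep = [
        (s, e, m) for s, e, m in raw
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2, _ in raw)
    ]
    # drop candidates contained in a TM helix
    keep = [
        (s, e, m) for s, e, m in keep
        if not any(ts <= s and e <= te for ts, te in tm_ivs)
    ]
    keep.sort(key=lambda t: (-t[2], t[0]))
    chosen: list[tuple[int, int]] = []
    for s, e, _ in keep:
        if not any(_overlap((s, e), iv) > 0 for iv in chosen):
            chosen.append((s, e))
    chosen.sort()
    return [_make_candidate(record, s, e, HelixKind.SHORT_HYDROPHOBIC) for s, e in chosen]


def detect_amphipathic(
    record: ProteinRecord,
    window: int = 18,
    mu_min: float = 0.5,
    terminal_span: int = 60,
) -> list[HelixCandidate]:
    """Amphipathic 18-mers near the termini (μH ≥ ``mu_min``).

    Chains of overlapping qualifying windows are collapsed to the single
    window of maximal moment.
    """
    L = len(record)
    if L < window:
        return []
    hits: list[tuple[int, int, float]] = []
    for lo, hi in _terminal_regions(L, terminal_span):
        for s in range(lo, hi - window + 2):
            e = s + window - 1
            mu = hydrophobic_moment(record.sequence[s - 1:e])
            if mu >= mu_min:
                hits.append((s, e, mu))
    hits.sort()
    groups: list[list[tuple[int, int, float]]] = []
    for h in hits:
        if groups and h[0] <= groups[-1][-1][1]:
            groups[-1].append(h)
        else:
            groups.append([h])
    best = [max(g, key=lambda t: t[2]) for g in groups]
    return [_make_candidate(record, s, e, HelixKind.AMPHIPATHIC) for s, e, _ in best]


# ---------------------------------------------------------------------------
# di-basic motifs
# ---------------------------------------------------------------------------

_VARIANT_FIRST = set("KR")
_VARIANT_SECOND = set("KRND")


def _classify_pair(pair: str) -> MotifClass | None:
    if pair == "KK":
        return MotifClass.DI_LYSINE
    if pair in ("KN", "NK"):
        return MotifClass.LYS_ASN
    if pair[0] in _VARIANT_FIRST and pair[1] in _VARIANT_SECOND:
        return MotifClass.OTHER_VARIANT
    return None


def scan_dibasic_motifs(
    record: ProteinRecord,
    tm: list[HelixCandidate],
    flank: int = 10,
) -> list[DiBasicMotif]:
    """First KK/KN/variant pair in the cytoplasmic flank of each TM helix.

    For an N-terminal TM helix the ``flank`` residues immediately upstream
    of its start are scanned; for a C-terminal one, the residues downstream
    of its end. The first matching pair (left to right) wins.
    """
    seq = record.sequence
    motifs: list[DiBasicMotif] = []
    for cand in tm:
        if cand.kind is not HelixKind.TM:
            continue
        if cand.terminal is Terminal.N:
            lo, hi = max(1, cand.start - flank), cand.start - 1
            side = MotifSide.UPSTREAM_OF_N_HELIX
        elif cand.terminal is Terminal.C:
            lo, hi = cand.end + 1, min(len(seq), cand.end + flank)
            side = MotifSide.DOWNSTREAM_OF_C_HELIX
        else:
            continue
        for p in range(lo, hi):  # pair occupies p, p+1 (both within flank)
            cls = _classify_pair(seq[p - 1:p + 1])
            if cls is not None:
                motifs.append(
                    DiBasicMotif(
                        protein_id=record.id,
                        position=p,
                        pair=seq[p - 1:p + 1],
                        motif_class=cls,
                        flank_of=cand,
                        side=side,
                    )
                )
                break
    return motifs


# ---------------------------------------------------------------------------
# MAD calling
# ---------------------------------------------------------------------------

_PRIORITY = {HelixKind.TM: 0, HelixKind.SHORT_HYDROPHOBIC: 1, HelixKind.AMPHIPATHIC: 2}


def resolve_overlaps(candidates: list[HelixCandidate]) -> list[HelixCandidate]:
    """TM > short-hydrophobic > amphipathic when intervals overlap ≥ 50%.

    The overlap fraction is measured on the lower-priority candidate.
    """
    ordered = sorted(candidates, key=lambda c: (_PRIORITY[c.kind], c.start))
    kept: list[HelixCandidate] = []
    for cand in ordered:
        suppressed = False
        for higher in kept:
            if _PRIORITY[higher.kind] < _PRIORITY[cand.kind]:
                ov = _overlap((cand.start, cand.end), (higher.start, higher.end))
                if ov / cand.length >= 0.5:
                    suppressed = True
                    break
        if not suppressed:
            kept.append(cand)
    kept.sort(key=lambda c: (c.start, c.end))
    return kept


def call_mads(
    record: ProteinRecord,
    tm: list[HelixCandidate],
    short: list[HelixCandidate],
    amphipathic: list[HelixCandidate],
) -> list[DomainAnnotation]:
    """Union of anchor candidates emitted as MAD annotations.

    A protein may legitimately yield zero MADs; it remains processable by
    every downstream stage.
    """
    resolved = resolve_overlaps(list(tm) + list(short) + list(amphipathic))
    return [
        DomainAnnotation(
            protein_id=record.id,
            domain_type=DomainType.MAD,
            start=c.start,
            end=c.end,
            source=AnnotationSource.DETECTED,
        )
        for c in resolved
    ]


def annotate_record(record: ProteinRecord) -> tuple[list[DomainAnnotation], list[DiBasicMotif]]:
    """Full anchor scan of one protein: MAD annotations + di-basic motifs."""
    tm = detect_tm_segments(record)
    short = detect_short_hydrophobic(record, tm=tm)
    amph = detect_amphipathic(record)
    mads = call_mads(record, tm, short, amph)
    motifs = scan_dibasic_motifs(record, tm)
    return mads, motifs
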