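import numpy as np
import pytest

from alpscan import SyntheticSpec, generate_proteome
from alpscan.seqio import group_by_protein


@pytest.fixture(scope="session")
def proteome():
    """A medium synthetic proteome shared by recovery tests (fixed seed)."""
    spec = SyntheticSpec(n_proteins=200, seed=11)
    records, annotations, truths = generate_proteome(spec)
    return {
        "spec": spec,
        "records": records,
        "records_by_id": {r.id: r for r in records},
        "annotations": annotations,
        "annotations_by_protein": group_by_protein(annotations),
        "truths": truths,
    }


def levenshtein_dp(a: str, b: str) -> int:
    """Brute-force dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def interval_coverage(planted: tuple[int, int], detected: list[tuple[int, int]]) -> float:
    """Fraction of the planted interval covered by the best detected interval."""
    s, e = planted
    best = max(
        (max(0, min(e, de) - max(s, ds) + 1) for ds, de in detected), default=0
    )
    return best / (e - s + 1)
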