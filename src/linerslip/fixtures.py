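"""Packaged published 2x2 contingency tables and known print discrepancies.

The two field trials behind this package report all raw data as 2x2
contingency tables crossing the milk-meter slip flag (SLP_MM), the three
audible observers (SLP_OB1..3, SLP_ANY) and the vacuum-recording flags
(SLP_V1, SLP_V2).  Those counts are shipped here verbatim so the full
statistics layer can be re-run offline; a checksum guards against
accidental edits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .agreement import ContingencyTable2x2

__all__ = [
    "PaperFixture",
    "TRIAL1_N",
    "TRIAL2_N",
    "get_fixture",
    "all_fixtures",
    "verify_fixtures",
    "KNOWN_DISCREPANCIES",
    "reconstruct_pair_vectors",
    "reconstruct_trial1_observer_vectors",
]

TRIAL1_N = 2039  # milking observations, trial 1 (audible vs. milk meter)
TRIAL2_N = 904   # milking observations, trial 2 (vacuum recorder vs. milk meter)


@dataclass(frozen=True)
class PaperFixture:
    """A published 2x2 table: (test, gold) counts a/b/c/d."""

    name: str
    table: ContingencyTable2x2
    trial: int
    source: str


_RAW = {
    # trial 1: rows = SLP_MM (test), columns = gold standard
    "mm_vs_ob1": (37, 89, 81, 1832, 1, "trial 1, milk meter vs observer 1"),
    "mm_vs_ob2": (69, 57, 28, 1885, 1, "trial 1, milk meter vs observer 2"),
    "mm_vs_ob3": (39, 87, 17, 1896, 1, "trial 1, milk meter vs observer 3"),
    "mm_vs_any": (92, 34, 107, 1806, 1, "trial 1, milk meter vs any observer"),
    # trial 1: observer cross-tables
    "ob1_vs_ob2": (29, 89, 68, 1853, 1, "trial 1, observer 1 vs observer 2"),
    "ob1_vs_ob3": (22, 96, 34, 1887, 1, "trial 1, observer 1 vs observer 3"),
    "ob1_vs_any": (118, 0, 81, 1840, 1, "trial 1, observer 1 vs any observer"),
    "ob2_vs_ob3": (39, 58, 17, 1925, 1, "trial 1, observer 2 vs observer 3"),
    "ob2_vs_any": (97, 0, 102, 1840, 1, "trial 1, observer 2 vs any observer"),
    "ob3_vs_any": (56, 0, 143, 1840, 1, "trial 1, observer 3 vs any observer"),
    # trial 2: rows = SLP_MM (test), columns = vacuum-recording gold standard
    "mm_vs_v1": (44, 3, 217, 640, 2, "trial 2, milk meter vs vacuum type 1"),
    "mm_vs_v2": (47, 0, 449, 408, 2, "trial 2, milk meter vs vacuum type 2"),
}

# sha256 over the canonical "name:a,b,c,d" listing; recomputed by
# verify_fixtures() to catch accidental edits of the counts above.
_CHECKSUM = "9cf38c2edff24caed5d14a7141557c4e79fbb0dcb155c76c6e64fc6648932b78"

# Published values that are inconsistent with (or not derivable from) the
# published tables themselves.  They are documentation, not targets: the
# package reports the value recomputed from the table counts.
KNOWN_DISCREPANCIES = {
    "kappa_mm_vs_v1": {
        "printed": 0.13,
        "from_table": 0.22,
        "note": "printed trial-2 kappa cannot be reconstructed from the "
                "published table counts (possibly stratified or a different "
                "estimator)",
    },
    "kappa_mm_vs_v2": {
        "printed": -0.18,
        "from_table": 0.09,
        "note": "printed trial-2 kappa cannot be reconstructed from the "
                "published table counts",
    },
    "kappa_mm_vs_ob1": {
        "printed": 0.25,
        "from_table": 0.26,
        "note": "borderline rounding discrepancy against the table counts",
    },
    "se_mm_vs_v2": {
        "printed": 0.10,
        "from_table": 0.09,
        "note": "47/496 = 0.095 rounds to 0.09; the printed CI (0.07-0.12) "
                "matches the table counts, the printed point value does not",
    },
    "combination_rows": {
        "printed": None,
        "from_table": None,
        "note": "observer-combination gold standards (OB1+2, OB1+3, OB2+3) "
                "need three-way joint counts that were never published",
    },
}


def _canonical() -> str:
    return ";".join(
        f"{name}:{v[0]},{v[1]},{v[2]},{v[3]}" for name, v in sorted(_RAW.items())
    )


def verify_fixtures() -> None:
    """Raise if the packaged counts no longer match their checksum."""
    digest = hashlib.sha256(_canonical().encode()).hexdigest()
    if digest != _CHECKSUM:
        raise RuntimeError(
            f"packaged contingency tables corrupted: checksum {digest} != {_CHECKSUM}"
        )


def get_fixture(name: str) -> PaperFixture:
    verify_fixtures()
    a, b, c, d, trial, source = _RAW[name]
    return PaperFixture(name=name, table=ContingencyTable2x2(a, b, c, d),
                        trial=trial, source=source)


def all_fixtures() -> list[PaperFixture]:
    return [get_fixture(name) for name in _RAW]


def reconstruct_pair_vectors(table: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Binary vectors (test, gold) whose cross-tabulation equals ``table``."""
    x = np.concatenate([
        np.ones(table.a), np.ones(table.b), np.zeros(table.c), np.zeros(table.d),
    ]).astype(int)
    y = np.concatenate([
        np.ones(table.a), np.zeros(table.b), np.ones(table.c), np.zeros(table.d),
    ]).astype(int)
    return x, y


def reconstruct_trial1_observer_vectors() -> dict[str, np.ndarray]:
    """Observation-level 0/1 vectors for the three trial-1 observers that are
    jointly consistent with every published pairwise observer table.

    The published pairwise intersections (OB1&OB2 = 29, OB1&OB3 = 22,
    OB2&OB3 = 39) and the union count (199) pin down the triple
    intersection: |union| = 118 + 97 + 56 - 29 - 22 - 39 + t = 199 gives
    t = 18, and all seven Venn regions come out non-negative.
    """
    t123 = 18
    only1 = 118 - 29 - 22 + t123          # 85
    only2 = 97 - 29 - 39 + t123           # 47
    only3 = 56 - 22 - 39 + t123           # 13
    just12 = 29 - t123                    # 11
    just13 = 22 - t123                    # 4
    just23 = 39 - t123                    # 21
    none = TRIAL1_N - (only1 + only2 + only3 + just12 + just13 + just23 + t123)
    blocks = [
        (only1, 1, 0, 0), (only2, 0, 1, 0), (only3, 0, 0, 1),
        (just12, 1, 1, 0), (just13, 1, 0, 1), (just23, 0, 1, 1),
        (t123, 1, 1, 1), (none, 0, 0, 0),
    ]
    ob1, ob2, ob3 = [], [], []
    for count, f1, f2, f3 in blocks:
        ob1.extend([f1] * count)
        ob2.extend([f2] * count)
        ob3.extend([f3] * count)
    return {
        "slp_ob1": np.array(ob1, dtype=int),
        "slp_ob2": np.array(ob2, dtype=int),
        "slp_ob3": np.array(ob3, dtype=int),
    }
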