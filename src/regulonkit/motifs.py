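"""Bundled illustrative PWMs for the four-motif promoter panel.

The panel names follow the motifs recurrently found over-represented in
retinoblastoma-corepressor-bound promoters: E2F (the canonical recruiting
factor's site), DREF (the DNA-replication-related element factor; the
canonical DRE is an 8-mer whose eighth base is poorly conserved, so that
column is kept close to uninformative), FOXJ2 (a forkhead-family site), and
RAM (a "retinoblastoma-associated" motif with no database match).

These matrices are SYNTHETIC stand-ins constructed from plausible consensus
sequences: no genuine position weight matrices for this panel are published,
so the bundled ones are illustrative only and must not be read as estimates
of real binding specificities. Column probabilities are deliberately
heterogeneous so score distributions have dense support.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .motifscan import PWM, encode

# uneven split of the non-consensus probability mass, rotated per position,
# so no two columns share an identical score multiset
_SPLITS = (0.5, 0.3, 0.2)


def pwm_from_consensus(motif_id: str, consensus: str, cons_probs: Sequence[float]) -> PWM:
    codes = encode(consensus)
    rows: List[List[float]] = []
    for i, (c, p) in enumerate(zip(codes, cons_probs)):
        rest = 1.0 - p
        others = [b for b in range(4) if b != int(c)]
        row = [0.0] * 4
        row[int(c)] = p
        for k, b in enumerate(others):
            row[b] = rest * _SPLITS[(k + i) % 3]
        rows.append(row)
    return PWM(motif_id=motif_id, probs=np.array(rows))


def bundled_pwms() -> Dict[str, PWM]:
    """The illustrative four-motif panel, keyed by motif id."""
    return {
        "E2F": pwm_from_consensus(
            "E2F",
            "TTTCGCGCCAA",
            [0.86, 0.79, 0.83, 0.88, 0.81, 0.90, 0.84, 0.87, 0.78, 0.74, 0.70],
        ),
        "DREF": pwm_from_consensus(
            "DREF",
            "TATCGATA",
            [0.88, 0.85, 0.90, 0.86, 0.87, 0.84, 0.82, 0.40],  # 8th base weakly held
        ),
        "FOXJ2": pwm_from_consensus(
            "FOXJ2",
            "TGTTTGTTTA",
            [0.80, 0.85, 0.77, 0.82, 0.88, 0.76, 0.84, 0.80, 0.72, 0.68],
        ),
        "RAM": pwm_from_consensus(
            "RAM",
            "GTAGCGGTAACG",
            [0.85, 0.80, 0.88, 0.82, 0.90, 0.86, 0.79, 0.83, 0.87, 0.81, 0.77, 0.84],
        ),
    }
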