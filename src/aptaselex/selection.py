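"""Frequency-threshold and fold-change rules for picking toggle-SELEX
candidates, plus the cross-strategy merge.

A species-toggled selection is summarized by comparing each sequence's
frequency before the toggle (last mouse cycle, e.g. M8) and after it (last
human cycle, e.g. M8H2).  Three rules pick candidates:

R1  undetected before AND frequency >= theta_H (1e-4) after;
R2  frequency > theta_M (5e-6) before, detected (> theta_D) after, and
    fold change > 10;
R3  frequency > theta_H before and fold change >= 2 (already abundant,
    still at least doubling).

"Undetected" means an observed count of zero; the background floor epsilon
(1e-6) only enters as the fold-change pseudo-frequency and as the
detection threshold of the descriptive enrichment report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import FrequencyMatrix

__all__ = [
    "SelectionThresholds",
    "RULE_PRESETS",
    "CandidateRecord",
    "MergedCandidate",
    "fold_change",
    "toggle_candidates",
    "enrichment_report",
    "merge_strategies",
    "candidates_to_frame",
]


@dataclass(frozen=True)
class SelectionThresholds:
    """Thresholds for the toggle-selection rules (all frequencies)."""

    background: float = 1e-6      # epsilon: detection floor for reports
    high_freq: float = 1e-4       # theta_H
    mid_freq: float = 5e-6        # theta_M
    min_detect: float = 1e-6      # theta_D
    fold_rule2: float = 10.0
    fold_rule3: float = 2.0
    fold_floor: float = 1e-6      # pseudo-frequency for undetected-before

    def __post_init__(self) -> None:
        for name in ("background", "high_freq", "mid_freq", "min_detect",
                     "fold_rule2", "fold_rule3", "fold_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.min_detect <= self.mid_freq <= self.high_freq:
            raise ValueError("need min_detect <= mid_freq <= high_freq")


#: Rule-set variants.  "methods" (default) conditions R2 on the pre-toggle
#: frequency (> theta_M) with a strict > 10x expansion; "results" is the
#: alternative published phrasing that conditions R2 on the post-toggle
#: frequency (>= theta_H) with a >= 10x expansion for any sequence detected
#: before the toggle.
RULE_PRESETS = ("methods", "results")


@dataclass
class CandidateRecord:
    """A sequence surviving one selection rule."""

    sequence: str
    strategy: str          # "cluster" or "toggle"
    rule_id: str           # "family", "R1", "R2" or "R3"
    f_before: float
    f_after: float
    fold_change: float
    family_id: str | None = None
    detected_before: bool = True


@dataclass
class MergedCandidate:
    """Deduplicated candidate with provenance from both strategies."""

    sequence: str
    strategies: tuple[str, ...]
    rule_ids: tuple[str, ...]
    f_after: float
    convergent: bool = False
    family_id: str | None = None


def fold_change(f_before: float, f_after: float, floor: float = 1e-6) -> float:
    """Enrichment fold change ``f_after / max(f_before, floor)``.

    The floor acts as a pseudo-frequency so that sequences undetected
    before the toggle get a finite (conservative) fold change.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if f_after < 0 or f_before < 0:
        raise ValueError("frequencies must be non-negative")
    return f_after / max(f_before, floor)


def toggle_candidates(matrix: FrequencyMatrix, before: str, after: str,
                      t: SelectionThresholds = SelectionThresholds(),
                      preset: str = "methods") -> list[CandidateRecord]:
    """Apply rules R1-R3 between two cycles of a frequency matrix.

    Each sequence is reported once, under the lowest-numbered rule it
    satisfies; output is sorted by post-toggle frequency descending, ties
    lexicographic.  Strictness of each comparison follows the rule
    wording: "higher than" is strict, "at least" is non-strict.  See
    :data:`RULE_PRESETS` for the two published phrasings of R2.
    """
    if preset not in RULE_PRESETS:
        raise ValueError(f"preset must be one of {RULE_PRESETS}")
    matrix.require_cycle(before)
    matrix.require_cycle(after)
    fb = matrix.freq[before].to_numpy()
    fa = matrix.freq[after].to_numpy()
    det_b = matrix.detected(before).to_numpy()
    fc = fa / np.maximum(fb, t.fold_floor)

    r1 = (~det_b) & (fa >= t.high_freq)
    if preset == "methods":
        r2 = (fb > t.mid_freq) & (fa > t.min_detect) & (fc > t.fold_rule2)
    else:
        r2 = det_b & (fa >= t.high_freq) & (fc >= t.fold_rule2)
    r3 = (fb > t.high_freq) & (fc >= t.fold_rule3)

    rule = np.full(len(fb), "", dtype=object)
    rule[r3] = "R3"
    rule[r2] = "R2"
    rule[r1] = "R1"

    seqs = matrix.sequences
    hits = [i for i in range(len(seqs)) if rule[i]]
    hits.sort(key=lambda i: (-fa[i], seqs[i]))
    return [
        CandidateRecord(
            sequence=seqs[i],
            strategy="toggle",
            rule_id=rule[i],
            f_before=float(fb[i]),
            f_after=float(fa[i]),
            fold_change=float(fc[i]),
            detected_before=bool(det_b[i]),
        )
        for i in hits
    ]


def enrichment_report(matrix: FrequencyMatrix, before: str, after: str,
                      t: SelectionThresholds = SelectionThresholds(),
                      fold: float = 16.0) -> dict[str, int]:
    """Descriptive counts of the toggle's effect.

    ``new_detected``: sequences detected after but not before with
    post-toggle frequency above the background floor epsilon;
    ``expanded``: sequences above epsilon after the toggle whose fold
    change exceeds ``fold`` (default 16).
    """
    matrix.require_cycle(before)
    matrix.require_cycle(after)
    fb = matrix.freq[before].to_numpy()
    fa = matrix.freq[after].to_numpy()
    det_b = matrix.detected(before).to_numpy()
    det_a = matrix.detected(after).to_numpy()
    fc = fa / np.maximum(fb, t.fold_floor)
    new_detected = int(((~det_b) & det_a & (fa > t.background)).sum())
    expanded = int(((fa > t.background) & (fc > fold)).sum())
    return {"new_detected": new_detected, "expanded": expanded,
            "fold_threshold": fold}


def merge_strategies(cluster_cands: list[CandidateRecord],
                     toggle_cands: list[CandidateRecord],
                     identity_threshold: float = 0.90) -> list[MergedCandidate]:
    """Merge the two strategies' candidates and flag convergent picks.

    A candidate is convergent when a candidate of the *other* strategy is
    identical or >= ``identity_threshold`` global-alignment identity to it
    (independent recovery of the same binder by both routes).  Exact
    duplicates across strategies collapse into one record keeping both
    provenances.  Output sorted by f_after descending, ties lexicographic.
    """
    from .families import pairwise_identity  # deferred: families imports us

    by_seq: dict[str, dict] = {}
    for rec in list(cluster_cands) + list(toggle_cands):
        d = by_seq.setdefault(rec.sequence, {
            "strategies": [], "rules": [], "f_after": rec.f_after,
            "family_id": rec.family_id,
        })
        if rec.strategy not in d["strategies"]:
            d["strategies"].append(rec.strategy)
        if rec.rule_id not in d["rules"]:
            d["rules"].append(rec.rule_id)
        if rec.family_id and not d["family_id"]:
            d["family_id"] = rec.family_id

    cluster_seqs = sorted({r.sequence for r in cluster_cands})
    toggle_seqs = sorted({r.sequence for r in toggle_cands})
    convergent: set[str] = set()
    for a in cluster_seqs:
        for b in toggle_seqs:
            if a == b or pairwise_identity(a, b) >= identity_threshold:
                convergent.add(a)
                convergent.add(b)

    out = [
        MergedCandidate(
            sequence=seq,
            strategies=tuple(d["strategies"]),
            rule_ids=tuple(d["rules"]),
            f_after=d["f_after"],
            convergent=seq in convergent,
            family_id=d["family_id"],
        )
        for seq, d in by_seq.items()
    ]
    out.sort(key=lambda m: (-m.f_after, m.sequence))
    return out


def candidates_to_frame(merged: list[MergedCandidate]) -> pd.DataFrame:
    rows = [(m.sequence, "+".join(m.strategies), "+".join(m.rule_ids),
             m.f_after, m.convergent, m.family_id or "") for m in merged]
    return pd.DataFrame(rows, columns=["sequence", "strategy", "rule_id",
                                       "f_after", "convergent", "family_id"])
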