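"""Sequence-family clustering and one-hot PCA of enriched variable regions.

Enriched sequences are grouped into "families" (clusters of near-identical
variable regions presumed to descend from one ancestral binder) by
average-linkage agglomeration on global-alignment distance ``1 - identity``.
A family's cumulative frequency Phi is the sum of its members' frequencies
at the analysed cycle; families whose Phi exceeds a threshold contribute
their most frequent member as a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import fcluster, linkage

from .reads import FrequencyMatrix
from .selection import CandidateRecord

__all__ = [
    "AlignmentScoring",
    "Family",
    "pairwise_identity",
    "identity_matrix",
    "cluster_families",
    "select_family_candidates",
    "pca_onehot",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring with linear gap cost."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner(mode="global",
                                  match_score=self.match,
                                  mismatch_score=self.mismatch,
                                  open_gap_score=self.gap,
                                  extend_gap_score=self.gap)
        return a


DEFAULT_SCORING = AlignmentScoring()


@dataclass
class Family:
    """A cluster of similar variable regions with member frequencies."""

    family_id: str
    members: pd.Series  # sequence -> frequency, sorted by (-freq, sequence)
    cumulative_frequency: float
    top_member: str

    def __post_init__(self) -> None:
        if self.top_member not in self.members.index:
            raise ValueError("top_member must be a member")


def pairwise_identity(a: str, b: str,
                      scoring: AlignmentScoring = DEFAULT_SCORING) -> float:
    """Fraction of identical columns in an optimal global alignment.

    identity = matches / alignment_length, a symmetric similarity in
    [0, 1].  Note ``1 - identity`` is not a metric (the triangle
    inequality can fail), which is why clustering uses average linkage
    rather than a metric-dependent method.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = scoring.aligner().align(a, b)[0]
    c = aln.counts()
    length = c.identities + c.mismatches + c.gaps
    return c.identities / length


def identity_matrix(sequences: list[str],
                    scoring: AlignmentScoring = DEFAULT_SCORING) -> np.ndarray:
    """Dense symmetric identity matrix over a sequence list."""
    n = len(sequences)
    out = np.eye(n)
    aligner = scoring.aligner()
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(sequences[i], sequences[j])[0]
            c = aln.counts()
            out[i, j] = out[j, i] = c.identities / (c.identities + c.mismatches + c.gaps)
    return out


def cluster_families(matrix: FrequencyMatrix, cycle: str, min_freq: float = 1e-6,
                     identity_threshold: float = 0.80,
                     scoring: AlignmentScoring = DEFAULT_SCORING,
                     max_sequences: int | None = 5000) -> list[Family]:
    """Cluster sequences with frequency >= ``min_freq`` at ``cycle`` into
    families.

    Average-linkage agglomeration on ``1 - identity``, cut at distance
    ``1 - identity_threshold``.  Input order is irrelevant: sequences are
    canonically sorted (frequency descending, then lexicographic) before
    clustering, and at most ``max_sequences`` of the most frequent are
    clustered (quadratic alignment cost).  Families are returned sorted by
    cumulative frequency descending, ties by top member.
    """
    if min_freq < 0:
        raise ValueError("min_freq must be >= 0")
    matrix.require_cycle(cycle)
    f = matrix.freq[cycle]
    f = f[f >= min_freq]
    if f.empty:
        return []
    order = sorted(f.index, key=lambda s: (-f[s], s))
    if max_sequences is not None:
        order = order[:max_sequences]
    f = f[order]
    n = len(order)
    if n == 1:
        labels = np.array([1])
    else:
        ident = identity_matrix(order, scoring)
        dist = 1.0 - ident[np.triu_indices(n, k=1)]
        z = linkage(dist, method="average")
        labels = fcluster(z, t=1.0 - identity_threshold, criterion="distance")

    fams: list[Family] = []
    for lab in np.unique(labels):
        members = f[labels == lab].sort_values(kind="stable", ascending=False)
        members = members[sorted(members.index, key=lambda s: (-members[s], s))]
        fams.append(Family(
            family_id="",
            members=members,
            cumulative_frequency=float(members.sum()),
            top_member=members.index[0],
        ))
    fams.sort(key=lambda fam: (-fam.cumulative_frequency, fam.top_member))
    for i, fam in enumerate(fams, start=1):
        fam.family_id = f"F{i:03d}"
    return fams


def select_family_candidates(families: list[Family],
                             phi_threshold: float = 1e-4) -> list[CandidateRecord]:
    """Top member of every family with cumulative frequency Phi strictly
    above ``phi_threshold``, tagged strategy="cluster"."""
    out = []
    for fam in families:
        if fam.cumulative_frequency > phi_threshold:
            out.append(CandidateRecord(
                sequence=fam.top_member,
                strategy="cluster",
                rule_id="family",
                f_before=float("nan"),
                f_after=float(fam.members.iloc[0]),
                fold_change=float("nan"),
                family_id=fam.family_id,
            ))
    return out


def families_to_frame(families: list[Family]) -> pd.DataFrame:
    """Flat table (family_id, sequence, frequency, cumulative_frequency,
    is_top) for TSV export."""
    rows = []
    for fam in families:
        for seq, fr in fam.members.items():
            rows.append((fam.family_id, seq, fr, fam.cumulative_frequency,
                         seq == fam.top_member))
    return pd.DataFrame(rows, columns=["family_id", "sequence", "frequency",
                                       "cumulative_frequency", "is_top"])


def pca_onehot(sequences: list[str]) -> np.ndarray:
    """First two principal-component coordinates of one-hot encoded
    sequences.

    Sequences are right-padded with a gap state to the maximum length,
    one-hot encoded over {A, C, G, T} (gap = all-zero), mean-centered and
    projected on the top-2 right singular directions.  Component signs are
    fixed so that each component's largest-magnitude loading is positive;
    components are ordered by decreasing explained variance.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    width = max(len(s) for s in sequences)
    alphabet = "ACGT"
    x = np.zeros((len(sequences), width * 4))
    for i, s in enumerate(sequences):
        for j, ch in enumerate(s):
            k = alphabet.find(ch)
            if k >= 0:
                x[i, 4 * j + k] = 1.0
    x -= x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = np.zeros((len(sequences), 2))
    k = min(2, s.size)
    for c in range(k):
        load = vt[c]
        sign = 1.0 if load[np.abs(load).argmax()] >= 0 else -1.0
        coords[:, c] = sign * u[:, c] * s[c]
    return coords
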