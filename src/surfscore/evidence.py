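"""Multi-channel evidence assembly, scoring, ranking, and Venn analytics.

The default study design has nine channels: three genomic
(tumor-vs-normal upregulated surface genes per dataset) and six
proteomic (three cell lines x two methods). A candidate must be present
in at least one genomic and at least one proteomic channel
(prerequisite); its score is the number of channels in which it appears,
so the maximum equals the channel count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from surfscore.errors import ValidationError

GENOMIC = "genomic"
PROTEOMIC = "proteomic"


@dataclass(frozen=True)
class ProteomicRun:
    """One (cell line, method) protein identification list."""

    cell_line: str
    method: str
    proteins: frozenset[str]

    @property
    def channel(self) -> str:
        return f"{self.cell_line}|{self.method}"


@dataclass
class EvidenceMatrix:
    """Proteins x channels boolean presence table, genomic columns first."""

    proteins: list[str]
    channels: list[str]
    channel_kind: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.proteins), len(self.channels)):
            raise ValidationError("presence: shape must be proteins x channels")
        if len(self.channel_kind) != len(self.channels):
            raise ValidationError("channel_kind: one kind per channel required")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channels: labels must be unique")
        bad = set(self.channel_kind) - {GENOMIC, PROTEOMIC}
        if bad:
            raise ValidationError(f"channel_kind: unknown kinds {sorted(bad)}")
        if self.presence.size and not self.presence.any(axis=1).all():
            raise ValidationError("presence: every protein must be present somewhere")

    @property
    def genomic_mask(self) -> np.ndarray:
        return np.array([k == GENOMIC for k in self.channel_kind])

    @property
    def proteomic_mask(self) -> np.ndarray:
        return ~self.genomic_mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.proteins, columns=self.channels)


@dataclass
class CandidateScore:
    """Evidence tally for one protein."""

    protein: str
    genomic_count: int
    proteomic_count: int
    passes_prerequisite: bool
    rank: int | None = None

    @property
    def score(self) -> int:
        return self.genomic_count + self.proteomic_count


def build_evidence_matrix(
    genomic_sets: list[tuple[str, set[str]]],
    proteomic_runs: list[ProteomicRun],
) -> EvidenceMatrix:
    """Assemble the presence matrix over the union of all input sets.

    Column order: genomic datasets in the given order, then proteomic
    runs in the given order. Duplicate dataset ids or (cell line,
    method) pairs are rejected.
    """
    dataset_ids = [d for d, _ in genomic_sets]
    if len(set(dataset_ids)) != len(dataset_ids):
        raise ValidationError("genomic_sets: duplicate dataset id")
    pairs = [(r.cell_line, r.method) for r in proteomic_runs]
    if len(set(pairs)) != len(pairs):
        raise ValidationError("proteomic_runs: duplicate (cell_line, method) pair")

    channel_sets: list[tuple[str, str, frozenset[str]]] = [
        (d, GENOMIC, frozenset(s)) for d, s in genomic_sets
    ] + [(r.channel, PROTEOMIC, r.proteins) for r in proteomic_runs]

    universe: set[str] = set()
    for _, _, members in channel_sets:
        universe |= members
    proteins = sorted(universe)
    index = {p: i for i, p in enumerate(proteins)}
    presence = np.zeros((len(proteins), len(channel_sets)), dtype=bool)
    for j, (_, _, members) in enumerate(channel_sets):
        for p in members:
            presence[index[p], j] = True
    return EvidenceMatrix(
        proteins=proteins,
        channels=[c for c, _, _ in channel_sets],
        channel_kind=[k for _, k, _ in channel_sets],
        presence=presence,
    )


def score_all(matrix: EvidenceMatrix) -> list[CandidateScore]:
    """Score every protein in the universe (no filtering, no ranks)."""
    g = matrix.presence[:, matrix.genomic_mask].sum(axis=1)
    p = matrix.presence[:, matrix.proteomic_mask].sum(axis=1)
    return [
        CandidateScore(
            protein=prot,
            genomic_count=int(gi),
            proteomic_count=int(pi),
            passes_prerequisite=bool(gi >= 1 and pi >= 1),
        )
        for prot, gi, pi in zip(matrix.proteins, g, p)
    ]


def score_candidates(
    matrix: EvidenceMatrix,
    min_score: int = 5,
    require_prerequisite: bool = True,
) -> list[CandidateScore]:
    """Ranked candidate list: prerequisite-passing proteins with
    score >= min_score, sorted by score desc, then genomic count desc,
    then protein id; ranks run densely from 1."""
    if min_score > len(matrix.channels):
        warnings.warn(
            f"min_score={min_score} exceeds the channel count "
            f"({len(matrix.channels)}); no candidate can qualify",
            stacklevel=2,
        )
        return []
    candidates = [
        c
        for c in score_all(matrix)
        if c.score >= min_score and (c.passes_prerequisite or not require_prerequisite)
    ]
    candidates.sort(key=lambda c: (-c.score, -c.genomic_count, c.protein))
    for rank, c in enumerate(candidates, start=1):
        c.rank = rank
    return candidates


def candidates_to_frame(candidates: list[CandidateScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": c.protein,
                "genomic_count": c.genomic_count,
                "proteomic_count": c.proteomic_count,
                "score": c.score,
                "passes_prerequisite": c.passes_prerequisite,
                "rank": c.rank,
            }
            for c in candidates
        ],
        columns=[
            "protein",
            "genomic_count",
            "proteomic_count",
            "score",
            "passes_prerequisite",
            "rank",
        ],
    )


def write_candidates_tsv(candidates: list[CandidateScore], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def venn_counts(sets: list[set[str]]) -> dict[str, int]:
    """Counts of every non-empty membership region across k sets.

    Keys are 1-based set positions joined by '+' (e.g. ``"1+3"``); all
    2^k - 1 regions are reported, including zero counts, and each element
    of the union is counted exactly once (in its exact pattern).
    """
    k = len(sets)
    if k < 2:
        raise ValidationError("sets: Venn analysis needs k >= 2 sets")
    regions = {
        "+".join(str(i + 1) for i in combo): 0
        for r in range(1, k + 1)
        for combo in combinations(range(k), r)
    }
    union: set[str] = set()
    for s in sets:
        union |= set(s)
    for element in union:
        pattern = [i for i, s in enumerate(sets) if element in s]
        regions["+".join(str(i + 1) for i in pattern)] += 1
    return regions


def write_venn_json(regions: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(regions, indent=1, sort_keys=True))


def channel_presence_report(matrix: EvidenceMatrix) -> dict:
    """Per-channel totals, pairwise overlaps, and the common count across
    cell lines within each proteomic method."""
    totals = {
        channel: int(count)
        for channel, count in zip(matrix.channels, matrix.presence.sum(axis=0))
    }
    overlaps: dict[str, int] = {}
    for (i, a), (j, b) in combinations(enumerate(matrix.channels), 2):
        overlaps[f"{a} & {b}"] = int(
            (matrix.presence[:, i] & matrix.presence[:, j]).sum()
        )
    method_common: dict[str, int] = {}
    proteomic_channels = [
        (c, i)
        for i, (c, k) in enumerate(zip(matrix.channels, matrix.channel_kind))
        if k == PROTEOMIC
    ]
    by_method: dict[str, list[int]] = {}
    for channel, i in proteomic_channels:
        method = channel.split("|", 1)[1] if "|" in channel else channel
        by_method.setdefault(method, []).append(i)
    for method, cols in by_method.items():
        method_common[method] = int(matrix.presence[:, cols].all(axis=1).sum())
    return {
        "per_channel": totals,
        "pairwise_overlap": overlaps,
        "per_method_common": method_common,
    }
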