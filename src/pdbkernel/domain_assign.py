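"""Recursive SCOP-style domain assignment over pluggable search backends.

The protocol: search the query sequence against a classified dataset and
keep hits passing both an E-value gate (< 0.01) and a structure-alignment
Z-score gate (> 4.5); if the sequence stage yields nothing, fall back to a
structure-only search against family representatives gated on Z-score
alone.  The best surviving hit (highest Z, ties to the longer target, then
the smaller id) donates its classification address over its query span.
Unassigned stretches longer than 30 residues are re-searched recursively;
shorter ones are merged into a neighboring domain at the end.

Backends are opaque: anything with ``search(query, start, end)`` returning
hits whose spans are global 1-based coordinates clipped to [start, end].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Protocol

UNASSIGNED = "UNASSIGNED"

#: class.fold.superfamily.family, e.g. "B.34.9.1"
ADDRESS_RE = re.compile(r"^[A-Za-z]\.\d+\.\d+\.\d+$")


@dataclass(frozen=True)
class SearchHit:
    target_id: str
    target_address: str
    e_value: float
    z_score: float
    query_span: tuple[int, int]
    target_len: int

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")
        s, e = self.query_span
        if s > e or s < 1:
            raise ValueError(f"bad query span {self.query_span}")


@dataclass
class Query:
    """Sequence plus an opaque structure handle for the backends."""

    seq: str
    structure: object | None = None

    def __len__(self) -> int:
        return len(self.seq)


class SearchBackend(Protocol):
    def search(self, query: Query, start: int, end: int) -> list[SearchHit]:
        """Hits for the query subinterval [start, end] (1-based, closed),
        spans in global query coordinates."""
        ...


@dataclass
class AssignParams:
    e_max: float = 0.01
    z_min: float = 4.5
    min_recurse_len: int = 30

    def __post_init__(self):
        if min(self.e_max, self.z_min, self.min_recurse_len) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class DomainAssignment:
    """Ordered, non-overlapping segments covering 1..query_len."""

    segments: list[tuple[int, int, str]]
    query_len: int

    def assigned_residues(self) -> int:
        return sum(e - s + 1 for s, e, a in self.segments if a != UNASSIGNED)

    def validate(self) -> None:
        pos = 1
        for s, e, _ in self.segments:
            if s != pos or e < s:
                raise ValueError(f"segments do not partition 1..{self.query_len}")
            pos = e + 1
        if pos != self.query_len + 1:
            raise ValueError(f"segments do not partition 1..{self.query_len}")


class BackendError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"{stage} backend failed: {cause}")
        self.stage = stage


def filter_hits(hits: list[SearchHit], params: AssignParams, stage: str
                ) -> list[SearchHit]:
    """Threshold gates, both strict.  The sequence stage requires the
    E-value AND the Z-score to pass; the structure stage checks Z alone."""
    if stage == "SEQ":
        return [h for h in hits
                if h.e_value < params.e_max and h.z_score > params.z_min]
    if stage == "STRUCT":
        return [h for h in hits if h.z_score > params.z_min]
    raise ValueError(f"unknown stage {stage!r}")


def pick_best_hit(hits: list[SearchHit]) -> SearchHit:
    """Highest Z-score; ties to the longer target, then the smaller id."""
    if not hits:
        raise ValueError("pick_best_hit needs at least one hit")
    return max(hits, key=lambda h: (h.z_score, h.target_len,
                                    _NegStr(h.target_id)))


class _NegStr(str):
    """Orders max() toward the lexicographically smaller string."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def _clip(span: tuple[int, int], start: int, end: int
          ) -> tuple[int, int] | None:
    s, e = max(span[0], start), min(span[1], end)
    return (s, e) if s <= e else None


def assign_domains(
    query: Query | str,
    seq_backend: SearchBackend,
    struct_backend: SearchBackend | None = None,
    params: AssignParams | None = None,
) -> DomainAssignment:
    """Run the full recursive protocol and return a finalized partition of
    the query into addressed and UNASSIGNED segments."""
    if isinstance(query, str):
        query = Query(seq=query)
    params = params or AssignParams()
    n = len(query)
    segments: list[tuple[int, int, str]] = []

    def search(backend: SearchBackend | None, stage: str,
               start: int, end: int) -> list[SearchHit]:
        if backend is None:
            return []
        try:
            hits = backend.search(query, start, end)
        except Exception as exc:  # surface which stage broke
            raise BackendError(stage, exc) from exc
        clipped = []
        for h in hits:
            span = _clip(h.query_span, start, end)
            if span is not None:
                clipped.append(replace(h, query_span=span))
        return filter_hits(clipped, params, stage)

    def solve(start: int, end: int) -> None:
        hits = search(seq_backend, "SEQ", start, end)
        if not hits:
            hits = search(struct_backend, "STRUCT", start, end)
        if not hits:
            segments.append((start, end, UNASSIGNED))
            return
        best = pick_best_hit(hits)
        s, e = best.query_span
        segments.append((s, e, best.target_address))
        for sub in ((start, s - 1), (e + 1, end)):
            if sub[0] > sub[1]:
                continue
            if sub[1] - sub[0] + 1 > params.min_recurse_len:
                solve(*sub)
            else:
                segments.append((sub[0], sub[1], UNASSIGNED))

    solve(1, n)
    segments.sort()
    draft = DomainAssignment(segments=_coalesce(segments), query_len=n)
    draft.validate()
    return merge_short_regions(draft, params)


def merge_short_regions(assignment: DomainAssignment,
                        params: AssignParams | None = None
                        ) -> DomainAssignment:
    """Absorb short unassigned segments into neighboring domains.

    A segment of length <= min_recurse_len with an assigned neighbor is
    absorbed: interior segments go to the neighbor whose adjacent assigned
    segment is longer (tie -> the preceding one); terminal segments go to
    their only neighbor.  Unassigned segments with no assigned neighbor
    stay unassigned.
    """
    params = params or AssignParams()
    segs = list(assignment.segments)
    out: list[tuple[int, int, str]] = []
    for idx, (s, e, addr) in enumerate(segs):
        if addr != UNASSIGNED or (e - s + 1) > params.min_recurse_len:
            out.append((s, e, addr))
            continue
        prev = segs[idx - 1] if idx > 0 else None
        nxt = segs[idx + 1] if idx + 1 < len(segs) else None
        prev_ok = prev is not None and prev[2] != UNASSIGNED
        next_ok = nxt is not None and nxt[2] != UNASSIGNED
        if prev_ok and next_ok:
            prev_len = prev[1] - prev[0] + 1
            next_len = nxt[1] - nxt[0] + 1
            addr = prev[2] if prev_len >= next_len else nxt[2]
        elif prev_ok:
            addr = prev[2]
        elif next_ok:
            addr = nxt[2]
        out.append((s, e, addr))
    result = DomainAssignment(segments=_coalesce(out),
                              query_len=assignment.query_len)
    result.validate()
    return result


def _coalesce(segments: list[tuple[int, int, str]]
              ) -> list[tuple[int, int, str]]:
    merged: list[tuple[int, int, str]] = []
    for seg in segments:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] + 1 == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


def overlap_fraction(predicted: tuple[int, int], reference: tuple[int, int]
                     ) -> float:
    """Fraction of the reference domain covered by the prediction —
    evaluation utility for users with their own reference classifications
    (a prediction covering > 0.8 is conventionally counted correct)."""
    ov = _clip(predicted, *reference)
    if ov is None:
        return 0.0
    return (ov[1] - ov[0] + 1) / (reference[1] - reference[0] + 1)
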