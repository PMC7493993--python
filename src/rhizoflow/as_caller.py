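"""Reference-free alternative-splicing detection from HSP-pair geometry.

Without a genome, alternative splicing between full-length isoforms of the
same gene leaves a characteristic signature in a pairwise local alignment:
two long high-scoring segment pairs (HSPs) that are contiguous (or overlap by
a few bases) on one transcript but are separated by a gap — the "AS gap" —
on the other.  An event is called when:

* both HSPs exceed a minimum length (default 1000 nt, applied per HSP),
* both HSPs have the same orientation,
* on one transcript the HSP intervals are contiguous or overlap by fewer
  than ``max_overlap`` (default 5) nt,
* on the other transcript the interval between the HSPs (the AS gap) exceeds
  ``min_gap`` (default 100) nt and lies at least ``min_end_distance``
  (default 100) nt from both transcript ends,
* the contiguous transcript is covered essentially end to end by the two
  HSPs (within ``end_slack`` nt at each end).

The default alignment engine is a gapless seed-and-merge aligner: exact
k-mer seeds are grouped by diagonal, merged across small gaps (isolated
substitutions), extended base by base, and verified by direct identity
counting.  It produces coordinates, handles both orientations, and is
pluggable — any engine emitting :class:`HSP` records can feed
:func:`call_as_events`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .sequence_features import revcomp
from .synthetic_data import Transcript


@dataclass
class HSP:
    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int  # forward-strand subject coordinates, also for reverse HSPs
    s_end: int
    orientation: str  # "forward" | "reverse"
    length: int
    identity: float


@dataclass
class ASEvent:
    continuous_id: str
    gapped_id: str
    hsp_pair: tuple[HSP, HSP]
    gap_start: int
    gap_end: int
    gap_length: int
    overlap_on_continuous: int  # positive = overlap, negative = gap between HSPs
    orientation: str


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(seq) - k + 1):
        index.setdefault(seq[j : j + k], []).append(j)
    return index


def _seed_hsps(
    qseq: str,
    sseq: str,
    min_hsp_len: int,
    min_identity: float,
    k: int = 15,
    merge_gap: int = 30,
    q_index: dict[str, list[int]] | None = None,
    s_index: dict[str, list[int]] | None = None,
) -> list[tuple[int, int, int, float]]:
    """Gapless HSPs as (q_start, q_end, diagonal, identity) on given strands."""
    if q_index is None:
        q_index = _kmer_index(qseq, k)
    if s_index is None:
        s_index = _kmer_index(sseq, k)
    by_diag: dict[int, list[int]] = {}
    for kmer in q_index.keys() & s_index.keys():
        for i in q_index[kmer]:
            for j in s_index[kmer]:
                by_diag.setdefault(i - j, []).append(i)
    out = []
    for diag, starts in by_diag.items():
        starts.sort()
        # merge covered intervals [i, i+k) with gaps <= merge_gap
        intervals: list[list[int]] = []
        for i in starts:
            if intervals and i - intervals[-1][1] <= merge_gap:
                intervals[-1][1] = max(intervals[-1][1], i + k)
            else:
                intervals.append([i, i + k])
        for qa, qb in intervals:
            # extend base-by-base while within bounds and characters match
            while qa > 0 and qa - diag > 0 and qseq[qa - 1] == sseq[qa - 1 - diag]:
                qa -= 1
            while (
                qb < len(qseq)
                and qb - diag < len(sseq)
                and qseq[qb] == sseq[qb - diag]
            ):
                qb += 1
            length = qb - qa
            if length < min_hsp_len:
                continue
            matches = sum(
                1 for x in range(qa, qb) if qseq[x] == sseq[x - diag]
            )
            ident = matches / length
            if ident >= min_identity:
                out.append((qa, qb, diag, ident))
    # de-duplicate identical spans found through different seed clusters
    uniq = sorted(set(out))
    return uniq


def pair_hsps(
    query: Transcript,
    subject: Transcript,
    min_hsp_len: int = 1000,
    min_identity: float = 0.95,
    k: int = 15,
    _indexes: tuple[dict, dict, dict] | None = None,
) -> list[HSP]:
    """All HSPs between one transcript pair, both orientations."""
    hsps: list[HSP] = []
    srev = revcomp(subject.seq)
    if _indexes is None:
        _indexes = (
            _kmer_index(query.seq, k),
            _kmer_index(subject.seq, k),
            _kmer_index(srev, k),
        )
    qi, si_fwd, si_rev = _indexes
    for orientation, sseq, si in (
        ("forward", subject.seq, si_fwd),
        ("reverse", srev, si_rev),
    ):
        for qa, qb, diag, ident in _seed_hsps(
            query.seq, sseq, min_hsp_len, min_identity, k=k, q_index=qi, s_index=si
        ):
            sa, sb = qa - diag, qb - diag
            if orientation == "reverse":
                sa, sb = len(subject.seq) - sb, len(subject.seq) - sa
            hsps.append(
                HSP(
                    query.id,
                    subject.id,
                    qa,
                    qb,
                    sa,
                    sb,
                    orientation,
                    qb - qa,
                    ident,
                )
            )
    return hsps


def all_vs_all_hsps(
    transcripts: Sequence[Transcript],
    min_hsp_len: int = 1000,
    min_identity: float = 0.95,
    k: int = 15,
) -> list[HSP]:
    """HSPs for every unordered transcript pair (self-pairs skipped).

    Per-transcript k-mer indexes (forward and reverse-complement) are built
    once; unrelated pairs fall through on an empty key intersection without
    any alignment work.
    """
    hsps: list[HSP] = []
    ts = list(transcripts)
    fwd = [_kmer_index(t.seq, k) for t in ts]
    rev = [_kmer_index(revcomp(t.seq), k) for t in ts]
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            hsps.extend(
                pair_hsps(
                    ts[i],
                    ts[j],
                    min_hsp_len,
                    min_identity,
                    k=k,
                    _indexes=(fwd[i], fwd[j], rev[j]),
                )
            )
    return hsps


def _try_event(
    h1: HSP,
    h2: HSP,
    qlen: int,
    slen: int,
    max_overlap: int,
    min_gap: int,
    min_end_distance: int,
    end_slack: int,
) -> ASEvent | None:
    """Attempt an event from two same-orientation HSPs sorted by q_start."""
    dq = h2.q_start - h1.q_end  # gap (positive) or overlap (negative) on query
    if h1.orientation == "forward":
        ds = h2.s_start - h1.s_end
        s_gap = (h1.s_end, h2.s_start)
        q_gap = (h1.q_end, h2.q_start)
    else:
        # on the forward subject strand, h1 (5' on query) occupies 3' coords
        ds = h1.s_start - h2.s_end
        s_gap = (h2.s_end, h1.s_start)
        q_gap = (h1.q_end, h2.q_start)

    def contiguous(d: int) -> bool:
        return -max_overlap < d <= 0

    # query contiguous, subject gapped
    if contiguous(dq) and ds > min_gap:
        if s_gap[0] >= min_end_distance and slen - s_gap[1] >= min_end_distance:
            if h1.q_start <= end_slack and qlen - h2.q_end <= end_slack:
                return ASEvent(
                    h1.query_id,
                    h1.subject_id,
                    (h1, h2),
                    s_gap[0],
                    s_gap[1],
                    ds,
                    -dq,
                    h1.orientation,
                )
    # subject contiguous, query gapped
    if contiguous(ds) and dq > min_gap:
        if q_gap[0] >= min_end_distance and qlen - q_gap[1] >= min_end_distance:
            s_lo = min(h1.s_start, h2.s_start)
            s_hi = max(h1.s_end, h2.s_end)
            if s_lo <= end_slack and slen - s_hi <= end_slack:
                return ASEvent(
                    h1.subject_id,
                    h1.query_id,
                    (h1, h2),
                    q_gap[0],
                    q_gap[1],
                    dq,
                    -ds,
                    h1.orientation,
                )
    return None


def call_as_events(
    hsps: Sequence[HSP],
    transcripts: Sequence[Transcript],
    min_hsp_len: int = 1000,
    max_overlap: int = 5,
    min_gap: int = 100,
    min_end_distance: int = 100,
    end_slack: int = 10,
) -> list[ASEvent]:
    """Apply the HSP-pair geometry rules and return deduplicated events."""
    lengths = {t.id: len(t.seq) for t in transcripts}
    for h in hsps:
        if h.query_id not in lengths or h.subject_id not in lengths:
            raise ValueError(f"HSP references unknown transcript: {h.query_id}/{h.subject_id}")
    groups: dict[tuple[str, str, str], list[HSP]] = {}
    for h in hsps:
        if h.length > min_hsp_len:
            groups.setdefault((h.query_id, h.subject_id, h.orientation), []).append(h)
    events: list[ASEvent] = []
    seen: set[tuple] = set()
    for (qid, sid, _), hs in groups.items():
        hs.sort(key=lambda h: h.q_start)
        for a in range(len(hs)):
            for b in range(a + 1, len(hs)):
                ev = _try_event(
                    hs[a],
                    hs[b],
                    lengths[qid],
                    lengths[sid],
                    max_overlap,
                    min_gap,
                    min_end_distance,
                    end_slack,
                )
                if ev is None:
                    continue
                key = (ev.continuous_id, ev.gapped_id, ev.gap_start, ev.gap_end)
                if key not in seen:
                    seen.add(key)
                    events.append(ev)
    events.sort(key=lambda e: (e.gapped_id, e.continuous_id, e.gap_start))
    return events


def events_to_rows(events: Sequence[ASEvent]) -> list[dict]:
    rows = []
    for e in events:
        h1, h2 = e.hsp_pair
        rows.append(
            {
                "continuous_id": e.continuous_id,
                "gapped_id": e.gapped_id,
                "gap_start": e.gap_start,
                "gap_end": e.gap_end,
                "gap_length": e.gap_length,
                "overlap_on_continuous": e.overlap_on_continuous,
                "orientation": e.orientation,
                "hsp1": f"{h1.q_start}-{h1.q_end}/{h1.s_start}-{h1.s_end}",
                "hsp2": f"{h2.q_start}-{h2.q_end}/{h2.s_start}-{h2.s_end}",
            }
        )
    return rows
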