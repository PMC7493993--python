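"""Per-transcript feature scanners for a genome-free transcriptome.

Three scanners operate directly on transcript sequences:

* **ORF/CDS prediction** — six-frame enumeration of open reading frames
  (standard genetic code, ATG start, TAA/TAG/TGA stop) with completeness
  classification and a hexamer log-likelihood coding score in the style of
  TransDecoder's Markov model.
* **SSR mining** — maximal perfect microsatellites of unit size 1-6 under
  MISA's default minimum-repeat thresholds, with compound-SSR grouping for
  repeats separated by at most an interruption limit.
* **lncRNA filtering** — a hard >200 nt length gate followed by a consensus
  vote of independent coding-potential criteria (ORF length, hexamer score,
  Fickett TESTCODE), emulating the CPC/CNCI/CPAT/Pfam multi-tool intersection
  used for transcriptome lncRNA catalogues without any external database.

Coordinates are 0-based half-open on the forward strand throughout, including
reverse-strand ORFs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .synthetic_data import Transcript

STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# ORFs


@dataclass
class ORFRecord:
    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0-2, frame on the scanned strand
    start: int  # forward-strand coordinates, 0-based half-open
    end: int
    has_start: bool
    has_stop: bool
    completeness: str  # complete | 5prime_partial | 3prime_partial | internal
    aa_length: int
    coding_score: float = 0.0
    is_primary: bool = False


def _classify(has_start: bool, has_stop: bool) -> str:
    if has_start and has_stop:
        return "complete"
    if has_stop:
        return "5prime_partial"
    if has_start:
        return "3prime_partial"
    return "internal"


def _scan_strand(seq: str, strand: str, seq_len: int, min_aa: int) -> list[ORFRecord]:
    out: list[ORFRecord] = []
    n = len(seq)

    def emit(s: int, e: int, frame: int, has_start: bool, has_stop: bool) -> None:
        comp = _classify(has_start, has_stop)
        aa = (e - s) // 3 - (1 if has_stop else 0)
        if aa < min_aa:
            return
        if strand == "+":
            fs, fe = s, e
        else:
            fs, fe = seq_len - e, seq_len - s
        out.append(
            ORFRecord("", strand, frame, fs, fe, has_start, has_stop, comp, aa)
        )

    for frame in range(3):
        seg_start = frame  # start of the current stop-free segment
        leading = True  # segment begins at the frame start (no stop before it)
        atgs: list[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon == "ATG":
                atgs.append(i)
            if codon in STOPS:
                stop_end = i + 3
                for a in atgs:
                    emit(a, stop_end, frame, True, True)
                if leading and (not atgs or atgs[0] != seg_start):
                    emit(seg_start, stop_end, frame, False, True)
                seg_start = stop_end
                leading = False
                atgs = []
            i += 3
        # trailing segment without a stop
        seg_end = i
        for a in atgs:
            emit(a, seg_end, frame, True, False)
        if leading and (not atgs or atgs[0] != seg_start) and seg_end > seg_start:
            emit(seg_start, seg_end, frame, False, False)
    return out


def find_orfs(transcript: Transcript, min_aa: int = 100) -> list[ORFRecord]:
    """Enumerate ORFs of at least ``min_aa`` amino acids in all six frames.

    Every ATG is paired with its first in-frame stop (complete) or the frame
    end (3' partial); additionally the leading stop-free stretch of each
    frame is reported as a 5' partial / internal ORF when it does not itself
    begin with ATG.  Codons containing N are treated as ordinary sense
    codons (never start, never stop).
    """
    seq = transcript.seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    orfs = _scan_strand(seq, "+", n, min_aa)
    orfs += _scan_strand(revcomp(seq), "-", n, min_aa)
    for o in orfs:
        o.transcript_id = transcript.id
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


def orf_nt_sequence(transcript: Transcript, orf: ORFRecord) -> str:
    """The ORF's nucleotide sequence in reading orientation."""
    sub = transcript.seq[orf.start : orf.end]
    return sub if orf.strand == "+" else revcomp(sub)


# ---------------------------------------------------------------------------
# Hexamer coding score


@dataclass
class HexamerTable:
    """In-frame hexamer frequencies for coding sequence vs position-free
    background, pseudocount-smoothed; the log-ratio is the coding score."""

    coding: dict[str, float]
    background: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"coding": self.coding, "background": self.background}, fh)

    @classmethod
    def from_json(cls, path) -> "HexamerTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(coding=d["coding"], background=d["background"])


_BASES = "ACGT"
ALL_HEXAMERS = [
    a + b + c + d + e + f
    for a in _BASES
    for b in _BASES
    for c in _BASES
    for d in _BASES
    for e in _BASES
    for f in _BASES
]


def _count_hexamers(seqs: Iterable[str], step: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        for i in range(0, len(s) - 5, step):
            h = s[i : i + 6]
            if set(h) <= set(_BASES):
                counts[h] = counts.get(h, 0) + 1
    return counts


def _freqs(counts: dict[str, int], pseudocount: float = 1.0) -> dict[str, float]:
    total = sum(counts.values()) + pseudocount * 4096
    return {h: (counts.get(h, 0) + pseudocount) / total for h in ALL_HEXAMERS}


def train_hexamer_table(
    coding_seqs: Sequence[str], noncoding_seqs: Sequence[str]
) -> HexamerTable:
    """Train frequencies: in-frame (step 3) for coding sequences, which must
    be supplied in frame 0; position-free (step 1) for the background set.
    Every one of the 4096 hexamers carries a pseudocount of 1."""
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both training sets must be non-empty")
    return HexamerTable(
        coding=_freqs(_count_hexamers(coding_seqs, step=3)),
        background=_freqs(_count_hexamers(noncoding_seqs, step=1)),
    )


def coding_score(orf_nt_seq: str, table: HexamerTable) -> float:
    """Sum of log(freq_coding/freq_background) over in-frame hexamers.

    Larger means more coding-like; sequences shorter than 6 nt score 0.
    Hexamers containing non-ACGT characters contribute 0.
    """
    s = orf_nt_seq.upper()
    score = 0.0
    for i in range(0, len(s) - 5, 3):
        h = s[i : i + 6]
        fc = table.coding.get(h)
        fb = table.background.get(h)
        if fc is not None and fb is not None:
            score += math.log(fc / fb)
    return score


def score_orfs(
    transcript: Transcript, orfs: Sequence[ORFRecord], table: HexamerTable
) -> list[ORFRecord]:
    """Attach coding scores and flag the maximal-scoring ORF as primary."""
    best = None
    for o in orfs:
        o.coding_score = coding_score(orf_nt_sequence(transcript, o), table)
        o.is_primary = False
        if best is None or o.coding_score > best.coding_score:
            best = o
    if best is not None:
        best.is_primary = True
    return list(orfs)


# ---------------------------------------------------------------------------
# Fickett TESTCODE

# Standard published TESTCODE lookup tables: probability that a sequence with
# the given position-asymmetry / composition parameter is coding, and the
# weight (discriminative power) of each parameter.
_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.60, 0.46, 0.31],
    "T": [0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24],
}
_POSITION_WEIGHT = {"A": 0.062, "C": 0.093, "G": 0.205, "T": 0.154}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.31, 0.24, 0.30, 0.33, 0.23],
    "G": [0.21, 0.40, 0.47, 0.46, 0.52, 0.58, 0.54, 0.28, 0.63, 0.40],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.23, 0.25],
}
_CONTENT_WEIGHT = {"A": 0.084, "C": 0.076, "G": 0.081, "T": 0.055}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic from position-dependent base composition.

    For each base the position parameter is max/(min+1) of its counts at the
    three codon positions and the content parameter is its overall fraction;
    both are converted to coding probabilities through the standard lookup
    tables and combined with the published weights.  Values above ~0.95
    indicate coding sequence.
    """
    s = seq.upper()
    if len(s) < 2:
        return 0.0
    score = 0.0
    for base in "ACGT":
        counts = [s[i::3].count(base) for i in range(3)]
        param = max(counts) / (min(counts) + 1.0)
        for idx, cut in enumerate(_POSITION_PARA):
            if param >= cut:
                score += _POSITION_PROB[base][idx] * _POSITION_WEIGHT[base]
                break
        content = s.count(base) / len(s)
        for idx, cut in enumerate(_CONTENT_PARA):
            if content >= cut:
                score += _CONTENT_PROB[base][idx] * _CONTENT_WEIGHT[base]
                break
    return score


# ---------------------------------------------------------------------------
# SSRs

#: MISA default minimum repeat numbers per motif length.
DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class SSRRecord:
    transcript_id: str
    motif: str  # canonical (lexicographically least rotation)
    unit_size: int
    repeats: int
    start: int
    end: int
    compound: bool = False
    compound_group: Optional[int] = None


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_ssrs(
    transcript: Transcript,
    thresholds: dict[int, int] = DEFAULT_SSR_THRESHOLDS,
    max_interruption: int = 100,
    min_transcript_len: int = 500,
) -> list[SSRRecord]:
    """Maximal perfect microsatellites under MISA-style rules.

    Transcripts shorter than ``min_transcript_len`` yield nothing.  A repeat
    is reported at the leftmost start of its periodic stretch, with the
    number of complete units; the motif must be primitive (not itself a
    repetition of a shorter unit).  Records separated by at most
    ``max_interruption`` nt are chained into a shared compound group.
    """
    seq = transcript.seq.upper()
    n = len(seq)
    if n < min_transcript_len:
        return []
    records: list[SSRRecord] = []
    for u in sorted(thresholds):
        thr = thresholds[u]
        limit = n - u * thr
        for i in range(limit + 1):
            unit = seq[i : i + u]
            if not set(unit) <= {"A", "C", "G", "T"}:
                continue
            if not _is_primitive(unit):
                continue
            # skip if the periodic stretch extends left of i
            if i >= 1 and seq[i - 1] == seq[i + u - 1]:
                continue
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            repeats = (j - i) // u
            if repeats >= thr:
                records.append(
                    SSRRecord(
                        transcript.id,
                        canonical_rotation(unit),
                        u,
                        repeats,
                        i,
                        i + u * repeats,
                    )
                )
    records.sort(key=lambda r: (r.start, r.end))
    # compound grouping
    group = 0
    open_group: list[SSRRecord] = []
    for rec in records:
        if open_group and rec.start - open_group[-1].end <= max_interruption:
            open_group.append(rec)
        else:
            if len(open_group) > 1:
                for r in open_group:
                    r.compound = True
                    r.compound_group = group
                group += 1
            open_group = [rec]
    if len(open_group) > 1:
        for r in open_group:
            r.compound = True
            r.compound_group = group
    return records


# ---------------------------------------------------------------------------
# lncRNA filtering


@dataclass
class LncRNACandidate:
    transcript_id: str
    length: int
    votes: dict[str, bool] = field(default_factory=dict)  # True = "noncoding"
    is_candidate: bool = False


def classify_lncrna(
    transcript: Transcript,
    orfs: Sequence[ORFRecord],
    table: Optional[HexamerTable] = None,
    coding_score_threshold: float = 0.0,
    min_votes: int = 2,
    min_orf_aa: int = 100,
    fickett_threshold: float = 0.95,
) -> LncRNACandidate:
    """Consensus lncRNA call: length gate then independent noncoding votes.

    Transcripts of 200 nt or less are rejected outright.  Three criteria then
    vote "noncoding": (a) no ORF of at least ``min_orf_aa`` amino acids,
    (b) the best ORF's hexamer coding score is below
    ``coding_score_threshold`` (vacuously noncoding when no ORF exists or no
    table is supplied), (c) the Fickett statistic falls below
    ``fickett_threshold``.  The transcript is a candidate iff at least
    ``min_votes`` criteria agree, mirroring a multi-tool intersection.
    """
    length = len(transcript.seq)
    cand = LncRNACandidate(transcript.id, length)
    if length <= 200:
        cand.votes = {}
        cand.is_candidate = False
        return cand
    vote_orf = not any(o.aa_length >= min_orf_aa for o in orfs)
    if table is not None and orfs:
        best = max(coding_score(orf_nt_sequence(transcript, o), table) for o in orfs)
        vote_score = best < coding_score_threshold
    else:
        vote_score = True
    vote_fickett = fickett_score(transcript.seq) < fickett_threshold
    cand.votes = {"orf_length": vote_orf, "coding_score": vote_score, "fickett": vote_fickett}
    cand.is_candidate = sum(cand.votes.values()) >= min_votes
    return cand


# ---------------------------------------------------------------------------
# Tabular output helpers


def orfs_to_rows(orfs: Sequence[ORFRecord]) -> list[dict]:
    return [
        {
            "transcript_id": o.transcript_id,
            "strand": o.strand,
            "frame": o.frame,
            "start": o.start,
            "end": o.end,
            "completeness": o.completeness,
            "aa_length": o.aa_length,
            "coding_score": o.coding_score,
            "is_primary": o.is_primary,
        }
        for o in orfs
    ]


def ssrs_to_rows(ssrs: Sequence[SSRRecord]) -> list[dict]:
    return [
        {
            "ID": s.transcript_id,
            "SSR_nr": i + 1,
            "type": f"p{s.unit_size}" + ("*" if s.compound else ""),
            "SSR": f"({s.motif}){s.repeats}",
            "size": s.end - s.start,
            "start": s.start,
            "end": s.end,
            "compound_group": s.compound_group if s.compound_group is not None else "",
        }
        for i, s in enumerate(ssrs)
    ]
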