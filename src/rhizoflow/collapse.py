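"""Redundancy collapse of transcript sets by greedy identity clustering.

Full-length isoform pipelines end with a CD-HIT-style step that removes
near-identical transcripts (identity >= 0.99 by default) so downstream feature
scans operate on a non-redundant set.  This module reproduces that step with
the classic greedy longest-first strategy: sequences are visited longest
first, each joins the first existing cluster whose *representative* it matches
at or above the identity threshold, otherwise it founds a new cluster.

Identity here is matches / global-alignment length (slightly stricter than
CD-HIT's matches / shorter-sequence length; the two coincide for
substitution-only variants).  Alignments are computed with edlib.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .synthetic_data import Transcript

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def global_identity(a: str, b: str) -> float:
    """Matches divided by global (Needleman-Wunsch) alignment length.

    Alignment length = matches + mismatches + insertions + deletions; the
    edit distance counts everything but matches, so identity falls out of the
    cigar length and the distance without inspecting the alignment itself.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    aln_len = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return (aln_len - res["editDistance"]) / aln_len


@dataclass
class Cluster:
    """One redundancy cluster; the representative is the longest member."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def collapse_transcripts(
    transcripts: Sequence[Transcript],
    identity_threshold: float = 0.99,
    prefilter_k: Optional[int] = None,
) -> tuple[list[Cluster], list[Transcript]]:
    """Greedy longest-first clustering at ``identity_threshold``.

    Parameters
    ----------
    transcripts
        Input set; ids must be unique.
    identity_threshold
        Minimum global identity to join a cluster (inclusive).
    prefilter_k
        If set (e.g. 11), candidate pairs sharing no k-mer of this length are
        skipped without alignment.  Pure optimisation; cannot change results
        because a pair above any practical identity threshold on transcript-
        scale sequences necessarily shares k-mers.

    Returns
    -------
    (clusters, non_redundant)
        Clusters in founding order and the representative transcripts
        (the non-redundant set).
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity threshold must lie in (0, 1]")
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")

    ordered = sorted(transcripts, key=lambda t: (-len(t.seq), t.id))
    clusters: list[Cluster] = []
    reps: list[Transcript] = []
    rep_kmers: list[set[str]] = []

    for t in ordered:
        placed = False
        tk = _kmer_set(t.seq, prefilter_k) if prefilter_k else None
        for ci, rep in enumerate(reps):
            if tk is not None and not (tk & rep_kmers[ci]):
                continue
            ident = global_identity(t.seq, rep.seq)
            if ident >= identity_threshold:
                clusters[ci].member_ids.append(t.id)
                clusters[ci].identities[t.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative_id=t.id, member_ids=[t.id], identities={t.id: 1.0})
            )
            reps.append(t)
            if prefilter_k:
                rep_kmers.append(tk if tk is not None else _kmer_set(t.seq, prefilter_k))
    return clusters, reps


def write_clusters_tsv(clusters: Sequence[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative\tmember\tidentity\n")
        for i, c in enumerate(clusters):
            for m in c.member_ids:
                fh.write(f"C{i:05d}\t{c.representative_id}\t{m}\t{c.identities[m]:.4f}\n")
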