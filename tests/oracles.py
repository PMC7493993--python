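"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result through a different algorithm and
shares no code with the implementation it checks.
"""

from __future__ import annotations

import re

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# ORFs: exhaustive six-frame enumeration


def orf_oracle(seq: str, min_aa: int) -> set[tuple]:
    """Every reported ORF as (strand, frame, start, end, completeness) on
    forward-strand coordinates.

    Enumerates, per strand and frame: every ATG paired with its first
    in-frame stop (complete) or the frame end (3' partial), plus the leading
    stop-free stretch when it does not itself begin with ATG (5' partial if
    stopped, internal otherwise).
    """
    stops = {"TAA", "TAG", "TGA"}
    out: set[tuple] = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            stop_idx = [ci for ci, c in enumerate(codons) if c in stops]

            def to_fwd(a: int, b: int) -> tuple[int, int]:
                return (a, b) if strand == "+" else (n - b, n - a)

            def record(a_codon: int, b_codon: int, has_start: bool, has_stop: bool):
                a = frame + 3 * a_codon
                b = frame + 3 * b_codon
                aa = (b - a) // 3 - (1 if has_stop else 0)
                if aa < min_aa:
                    return
                comp = {
                    (True, True): "complete",
                    (False, True): "5prime_partial",
                    (True, False): "3prime_partial",
                    (False, False): "internal",
                }[(has_start, has_stop)]
                fa, fb = to_fwd(a, b)
                out.add((strand, frame, fa, fb, comp))

            n_codons = len(codons)
            for ci, c in enumerate(codons):
                if c == "ATG":
                    nxt = next((si for si in stop_idx if si >= ci), None)
                    if nxt is None:
                        record(ci, n_codons, True, False)
                    else:
                        record(ci, nxt + 1, True, True)
            # leading stretch of the frame
            first_stop = stop_idx[0] if stop_idx else None
            seg_end = first_stop if first_stop is not None else n_codons
            if codons and codons[0] != "ATG" and seg_end > 0:
                if first_stop is not None:
                    record(0, first_stop + 1, False, True)
                else:
                    record(0, n_codons, False, False)
    return out


# ---------------------------------------------------------------------------
# SSRs: regex brute force


def _primitive(unit: str) -> bool:
    return all(
        not (len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d))
        for d in range(1, len(unit))
    )


def ssr_oracle(
    seq: str,
    thresholds: dict[int, int],
    min_transcript_len: int = 500,
) -> set[tuple]:
    """Maximal perfect repeats as (motif_canonical, unit, repeats, start, end).

    For each unit size a backreference regex finds runs; a run is kept at its
    leftmost start (not extendable one base to the left), trimmed to whole
    units, with a primitive motif.
    """
    out: set[tuple] = set()
    if len(seq) < min_transcript_len:
        return out
    for u, thr in thresholds.items():
        pat = re.compile(r"(?=([ACGT]{%d})(?:\1){%d,})" % (u, thr - 1))
        for m in pat.finditer(seq):
            i = m.start()
            unit = m.group(1)
            if not _primitive(unit):
                continue
            # leftmost start of the periodic stretch only
            if i >= 1 and seq[i - 1] == seq[i + u - 1]:
                continue
            j = i + u
            while j < len(seq) and seq[j] == seq[j - u]:
                j += 1
            reps = (j - i) // u
            if reps >= thr:
                canon = min(unit[r:] + unit[:r] for r in range(u))
                out.add((canon, u, reps, i, i + u * reps))
    return out


# ---------------------------------------------------------------------------
# AS rules applied to planted geometry (hand-coded, independent)


def as_rules(flank5: int, flank3: int, gap: int) -> bool:
    """The five splice-event criteria evaluated on planted coordinates:
    two HSPs (the flanks) each >1000 nt, same orientation (true by
    construction), contiguity on the short isoform (overlap 0 < 5 by
    construction), AS gap >100 nt, and gap at least 100 nt from both ends of
    the gapped isoform."""
    if not (flank5 > 1000 and flank3 > 1000):
        return False
    if not gap > 100:
        return False
    if flank5 < 100 or flank3 < 100:
        return False
    return True


# ---------------------------------------------------------------------------
# FPKM one-liner


def fpkm_oracle(counts, lengths):
    import numpy as np

    c = np.asarray(counts, dtype=float)
    L = np.asarray(lengths, dtype=float)[:, None]
    tot = c.sum(axis=0)[None, :]
    return c * 1e9 / (L * tot)


# ---------------------------------------------------------------------------
# TOM triple loop


def tom_oracle(adjacency):
    import numpy as np

    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom
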