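"""Pairwise alignment primitives shared across the pipeline.

Everything is built on edlib's bit-parallel edit-distance engine. Three
alignment modes are used throughout:

* global (``NW``) — both sequences consumed end to end; used for contig
  fusion identity and consensus polishing.
* infix (``HW``) — the query is consumed entirely, both of its ends are
  free on the target; this is the "semi-global" mode used for primer
  matching, containment checks and read-to-allele mapping.

edlib cigar conventions (verified): ``I`` consumes the query only,
``D`` consumes the target only, ``=``/``X`` consume both. Location ends
returned by edlib are inclusive; every function here converts them to
0-based half-open intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

_CIGAR_RE = re.compile(r"(\d+)([=XID])")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN alphabet, case preserved)."""
    return seq.translate(_COMP)[::-1]


def cigar_ops(cigar: str):
    """Iterate (length, op) pairs of an edlib extended cigar."""
    for m in _CIGAR_RE.finditer(cigar):
        yield int(m.group(1)), m.group(2)


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Global edit distance; -1 if it exceeds ``k`` (when k >= 0)."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


@dataclass(frozen=True)
class InfixHit:
    """Best placement of a whole query inside a target."""

    distance: int
    start: int  # target coordinate, 0-based
    end: int    # half-open

    @property
    def span(self) -> int:
        return self.end - self.start


def infix_align(query: str, target: str, k: int = -1, task: str = "locations"):
    """Semi-global alignment: query fully consumed, free ends on target.

    Returns an :class:`InfixHit` (first optimal location) or ``None`` when
    the distance exceeds ``k``.  With ``task='path'`` the hit carries the
    cigar in the extra attribute dict.
    """
    if not query:
        raise ValueError("empty query sequence")
    res = edlib.align(query, target, mode="HW", task=task, k=k)
    d = res["editDistance"]
    if d < 0:
        return None
    s, e = res["locations"][0]
    hit = InfixHit(distance=d, start=s, end=e + 1)
    if task == "path":
        return hit, res["cigar"]
    return hit


def global_cigar(query: str, target: str) -> tuple[int, str]:
    """Global alignment distance and cigar."""
    res = edlib.align(query, target, mode="NW", task="path")
    return res["editDistance"], res["cigar"]


def identity_over_shorter(a: str, b: str, k: int = -1) -> float:
    """Alignment identity of the shorter sequence over its best placement
    inside the longer one (1 - dist/len(shorter)); 0.0 when the bounded
    search finds no placement."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    hit = infix_align(short, long_, k=k)
    if hit is None:
        return 0.0
    return 1.0 - hit.distance / max(len(short), 1)


def semiglobal_distance_brute(query: str, target: str) -> tuple[int, int]:
    """Reference DP for infix alignment (query fully aligned, free ends on
    target).  Returns (min distance, end position on target, exclusive).

    Quadratic; exists as an independent oracle for the edlib-backed
    :func:`infix_align` and is only suitable for small inputs.
    """
    m, n = len(query), len(target)
    prev = np.arange(m + 1)
    best = prev[m]
    best_end = 0
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    for j in range(1, n + 1):
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = 0  # free start on target
        sub = prev[:m] + (q != t[j - 1])
        # vectorised column update needs the running min for gaps in target
        np.minimum(sub, prev[1:] + 1, out=cur[1:])
        for i in range(1, m + 1):  # gap in query (depends on cur[i-1])
            if cur[i - 1] + 1 < cur[i]:
                cur[i] = cur[i - 1] + 1
        if cur[m] < best:
            best, best_end = cur[m], j
        prev = cur
    return int(best), best_end


_OP_CODE = np.full(128, -1, dtype=np.int8)
for _c, _v in ((ord("="), 0), (ord("X"), 0), (ord("D"), 1), (ord("I"), 2)):
    _OP_CODE[_c] = _v


def _expand_cigar(cigar: str):
    """(lengths, op codes) arrays; codes: 0 = consumes both, 1 = target
    only (D), 2 = query only (I)."""
    pairs = _CIGAR_RE.findall(cigar)
    lens = np.array([int(p[0]) for p in pairs], dtype=np.int64)
    codes = _OP_CODE[np.frombuffer("".join(p[1] for p in pairs).encode(), np.uint8)]
    return lens, codes


def _ranges_to_index(starts: np.ndarray, lens: np.ndarray) -> np.ndarray:
    """Concatenate aranges [s, s+l) for each (s, l) pair, vectorized."""
    if lens.size == 0:
        return np.empty(0, dtype=np.int64)
    total = int(lens.sum())
    idx = np.ones(total, dtype=np.int64)
    ends = np.cumsum(lens)
    idx[0] = starts[0]
    idx[ends[:-1]] = starts[1:] - (starts[:-1] + lens[:-1]) + 1
    return np.cumsum(idx)


def project_reads_onto_template(
    reads: list[str], template: str, k: int = -1, collect_insertions: bool = False
):
    """Globally align each read to the template and project its bases onto
    template columns.

    Returns a (n_reads, len(template)) byte matrix: aligned base, ``-`` for
    a deletion in the read, or ``.`` where a bounded alignment failed.
    With ``collect_insertions`` additionally returns one dict per read
    mapping the template junction ``j`` (between columns j-1 and j) to the
    string the read inserts there, left-normalized through repeats.
    """
    n = len(template)
    mat = np.full((len(reads), n), ord("."), dtype=np.uint8)
    insertions: list[dict[int, str]] = [dict() for _ in reads]
    for idx, read in enumerate(reads):
        res = edlib.align(read, template, mode="NW", task="path", k=k)
        if res["editDistance"] < 0:
            continue
        lens, codes = _expand_cigar(res["cigar"])
        tcons = np.where(codes != 2, lens, 0)
        qcons = np.where(codes != 1, lens, 0)
        tstarts = np.concatenate([[0], np.cumsum(tcons)[:-1]])
        qstarts = np.concatenate([[0], np.cumsum(qcons)[:-1]])
        row = mat[idx]
        rbytes = np.frombuffer(read.encode(), dtype=np.uint8)
        m = codes == 0
        tidx = _ranges_to_index(tstarts[m], lens[m])
        qidx = _ranges_to_index(qstarts[m], lens[m])
        row[tidx] = rbytes[qidx]
        d = codes == 1
        if d.any():
            row[_ranges_to_index(tstarts[d], lens[d])] = ord("-")
        if collect_insertions:
            for o in np.flatnonzero(codes == 2):
                # left-normalize: equivalent placements in repeats must
                # land on one canonical junction or majority votes split
                q0 = int(qstarts[o])
                s = read[q0 : q0 + int(lens[o])]
                j = int(tstarts[o])
                while j > 0 and s[-1] == template[j - 1]:
                    s = s[-1] + s[:-1]
                    j -= 1
                prev = insertions[idx].get(j, "")
                insertions[idx][j] = prev + s
    if collect_insertions:
        return mat, insertions
    return mat
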