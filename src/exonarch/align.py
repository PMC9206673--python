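"""Desk-scale spliced alignment of long reads to a single locus.

Seed-chain-extend: exact k-mer anchors on both strands, colinear chaining
with free gaps for intron-sized locus jumps, anchor merging into exonic
blocks, x-drop end extension, match-maximizing placement of each intron
boundary, and GT-AG-aware boundary refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib

from .io import GeneLocus, ReadRecord, revcomp

__all__ = [
    "AlignParams",
    "AnchorChain",
    "ReadAlignment",
    "Rejection",
    "LocusIndex",
    "align_read",
    "refine_splice_boundaries",
    "import_alignments",
]


@dataclass(frozen=True)
class AlignParams:
    k: int = 13
    min_intron: int = 20
    max_intron: int = 1_000_000
    band: int = 16
    reject_identity: float = 0.66  # min fraction of read bases matched
    xdrop: int = 6


@dataclass
class AnchorChain:
    read_id: str
    orientation: str
    anchors: list[tuple[int, int, int]]  # (read_pos, locus_pos, length)
    chain_score: float


@dataclass
class ReadAlignment:
    """Chained exonic blocks of one read on the locus.

    ``blocks`` are (locus_start, locus_end, read_start, read_end), strictly
    increasing on both coordinates; consecutive blocks are separated on the
    locus by at least ``min_intron``.
    """

    read_id: str
    blocks: list[tuple[int, int, int, int]]
    block_identities: list[float]
    introns: list[tuple[str, str]]  # (donor dinuc, acceptor dinuc)
    total_identity: float
    orientation: str = "forward"
    sequence: str = ""  # read sequence in the aligned orientation

    def locus_intervals(self) -> list[tuple[int, int]]:
        return [(ls, le) for ls, le, _, _ in self.blocks]


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


class LocusIndex:
    """Exact k-mer index over a locus sequence."""

    def __init__(self, locus: GeneLocus, k: int = 13):
        self.locus = locus
        self.k = k
        self.kmers: dict[str, list[int]] = {}
        seq = locus.sequence
        for j in range(len(seq) - k + 1):
            self.kmers.setdefault(seq[j:j + k], []).append(j)


def _anchors(seq: str, index: LocusIndex) -> list[tuple[int, int, int]]:
    """Maximal exact anchors (read_pos, locus_pos, length >= k), built by
    merging k-mer hits lying on the same diagonal run."""
    k = index.k
    open_runs: dict[int, tuple[int, int, int]] = {}  # diag -> (r, l, len)
    done: list[tuple[int, int, int]] = []
    for i in range(len(seq) - k + 1):
        hits = index.kmers.get(seq[i:i + k])
        if not hits:
            continue
        for j in hits:
            diag = j - i
            run = open_runs.get(diag)
            if run is not None and i <= run[0] + run[2]:
                # extends the existing run on this diagonal
                new_len = i + k - run[0]
                if new_len > run[2]:
                    open_runs[diag] = (run[0], run[1], new_len)
            else:
                if run is not None:
                    done.append(run)
                open_runs[diag] = (i, j, k)
    done.extend(open_runs.values())
    done.sort()
    return done


def _chain(anchors: list[tuple[int, int, int]], p: AlignParams
           ) -> tuple[list[tuple[int, int, int]], float]:
    """Best colinear chain by quadratic DP.

    Gap cost is ~zero for intron-like gaps (locus gap in
    [min_intron, max_intron] with read gap <= band) and proportional to the
    diagonal offset otherwise.
    """
    n = len(anchors)
    if n == 0:
        return [], float("-inf")
    score = [float(a[2]) for a in anchors]
    prev = [-1] * n
    for i in range(n):
        ri, li, ni = anchors[i]
        for jj in range(i):
            rj, lj, nj = anchors[jj]
            dr = ri - (rj + nj)
            dg = li - (lj + nj)
            # small overlaps on either coordinate are allowed (indels near a
            # junction shift anchor diagonals) and penalized
            if dr < -p.band or dg < -p.band:
                continue
            ov = max(0, -dr, -dg)
            dr2 = max(dr, 0)
            dg2 = max(dg, 0)
            if dg2 - dr2 >= p.min_intron and dg2 <= p.max_intron:
                # intron-like: locus gap exceeds read gap by an intron length
                cost = 0.01 * dr2 + 0.5 * ov
            else:
                cost = 0.5 * abs(dr2 - dg2) + 0.1 * min(dr2, dg2) + 0.5 * ov
            s = score[jj] + ni - cost
            if s > score[i]:
                score[i] = s
                prev[i] = jj
    best = max(range(n), key=lambda i: score[i])
    chain = []
    i = best
    while i != -1:
        chain.append(anchors[i])
        i = prev[i]
    chain.reverse()
    return chain, score[best]


def _matches_from_cigar(cigar: str) -> tuple[int, int]:
    """(matched columns, total columns) from an edlib extended CIGAR."""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches, cols


def _block_identity(read_seg: str, locus_seg: str) -> tuple[int, float]:
    """Matched bases and identity of a gapped block alignment."""
    if not read_seg or not locus_seg:
        return 0, 0.0
    res = edlib.align(read_seg, locus_seg, task="path", mode="NW")
    m, cols = _matches_from_cigar(res["cigar"])
    return m, m / cols if cols else 0.0


def _extend_left(seq: str, locus: str, r0: int, l0: int, p: AlignParams
                 ) -> tuple[int, int]:
    """Gapped extension leftward from (r0, l0); returns the (read, locus)
    start of the best-scoring extension."""
    from ._dp import extend_from_origin

    cap = min(r0, 200)
    q = seq[r0 - cap:r0][::-1]
    t = locus[max(0, l0 - cap - p.band):l0][::-1]
    di, dj = extend_from_origin(q, t)
    return r0 - di, l0 - dj


def _extend_right(seq: str, locus: str, r1: int, l1: int, p: AlignParams
                  ) -> tuple[int, int]:
    from ._dp import extend_from_origin

    cap = min(len(seq) - r1, 200)
    q = seq[r1:r1 + cap]
    t = locus[l1:l1 + cap + p.band]
    di, dj = extend_from_origin(q, t)
    return r1 + di, l1 + dj


def _place_boundary(seq: str, locus: str, left_re: int, left_le: int,
                    right_rs: int, right_ls: int, min_intron: int
                    ) -> tuple[int, int, int]:
    """Distribute the unanchored read bases between two blocks around an
    intron.

    Returns (read_split, donor, acceptor): read bases < read_split extend
    the left block ending at locus ``donor``; bases >= read_split extend the
    right block starting at locus ``acceptor``.  The split maximizes exact
    matches, ties broken toward a GT..AG intron, then leftmost.
    """
    x = right_rs - left_re  # unplaced read bases
    best = None
    for j in range(x + 1):
        donor = left_le + j
        acceptor = right_ls - (x - j)
        if acceptor - donor < min_intron or acceptor > len(locus):
            continue
        m = 0
        for t in range(j):
            if seq[left_re + t] == locus[left_le + t]:
                m += 1
        for t in range(x - j):
            if seq[right_rs - 1 - t] == locus[right_ls - 1 - t]:
                m += 1
        gtag = (locus[donor:donor + 2] == "GT"
                and locus[acceptor - 2:acceptor] == "AG")
        key = (m, gtag, -j)
        if best is None or key > best[0]:
            best = (key, left_re + j, donor, acceptor)
    if best is None:
        return left_re, left_le, right_ls
    return best[1], best[2], best[3]


def _build_alignment(read_id: str, seq: str, locus: str,
                     chain: list[tuple[int, int, int]], orientation: str,
                     p: AlignParams) -> ReadAlignment:
    # group anchors into proto-blocks at intron-like gaps
    groups: list[list[tuple[int, int, int]]] = [[chain[0]]]
    for a in chain[1:]:
        pr, pl, pn = groups[-1][-1]
        dg = a[1] - (pl + pn)
        dr = a[0] - (pr + pn)
        if dg - max(dr, 0) >= p.min_intron:
            groups.append([a])
        else:
            groups[-1].append(a)
    # proto-block bounds (anchors within a group may sit on shifted
    # diagonals, so take the extreme anchors explicitly)
    bounds = []
    for g in groups:
        first = min(g, key=lambda a: a[0])
        last = max(g, key=lambda a: a[0] + a[2])
        bounds.append([first[1], last[1] + last[2], first[0], last[0] + last[2]])
    # end extension
    rs, ls = _extend_left(seq, locus, bounds[0][2], bounds[0][0], p)
    bounds[0][2], bounds[0][0] = rs, ls
    re_, le = _extend_right(seq, locus, bounds[-1][3], bounds[-1][1], p)
    bounds[-1][3], bounds[-1][1] = re_, le
    # boundary placement between consecutive blocks
    for bi in range(len(bounds) - 1):
        L, R = bounds[bi], bounds[bi + 1]
        if L[3] > R[2]:  # anchors overlap on the read (junction repeat)
            t = L[3] - R[2]
            L[3] -= t
            L[1] -= t
        split, donor, acceptor = _place_boundary(
            seq, locus, L[3], L[1], R[2], R[0], p.min_intron)
        L[3], L[1] = split, donor
        R[2], R[0] = split, acceptor

    blocks = [tuple(b) for b in bounds]
    idents = []
    matched = 0
    for ls_, le_, rs_, re__ in blocks:
        m, ident = _block_identity(seq[rs_:re__], locus[ls_:le_])
        matched += m
        idents.append(ident)
    introns = []
    for (ls1, le1, _, _), (ls2, le2, _, _) in zip(blocks, blocks[1:]):
        introns.append((locus[le1:le1 + 2], locus[ls2 - 2:ls2]))
    total_identity = matched / len(seq) if seq else 0.0
    return ReadAlignment(read_id, blocks, idents, introns, total_identity,
                         orientation, seq)


def align_read(read: ReadRecord, locus: GeneLocus | LocusIndex,
               params: AlignParams | None = None
               ) -> ReadAlignment | Rejection:
    """Align one read to the locus as an ordered chain of exonic blocks.

    Both orientations are seeded; the orientation with the higher optimal
    chain score is kept (tie -> forward).  The result is rejected when
    fewer than ``reject_identity`` of the read bases align (the amplicon
    mapper's retention rule), or when no 2-anchor chain exists.
    """
    p = params or AlignParams()
    index = locus if isinstance(locus, LocusIndex) else LocusIndex(locus, p.k)
    if index.k != p.k:
        raise ValueError("index k differs from params.k")
    if len(read.sequence) < 2 * p.k:
        return Rejection(read.read_id, "too_short")

    fwd = read.sequence
    rev = revcomp(fwd)
    chain_f, score_f = _chain(_anchors(fwd, index), p)
    chain_r, score_r = _chain(_anchors(rev, index), p)
    if score_f >= score_r:
        chain, seq, orientation = chain_f, fwd, "forward"
    else:
        chain, seq, orientation = chain_r, rev, "reverse"
    if len(chain) == 0 or (len(chain) < 2 and chain[0][2] < 2 * p.k):
        return Rejection(read.read_id, "unmappable")
    aln = _build_alignment(read.read_id, seq, index.locus.sequence, chain,
                           orientation, p)
    if aln.total_identity < p.reject_identity:
        return Rejection(read.read_id, "low_identity")
    return aln


def refine_splice_boundaries(aln: ReadAlignment, locus: GeneLocus,
                             window: int = 10) -> ReadAlignment:
    """Jointly shift each intron's donor/acceptor within +-window to the
    placement maximizing local matches, preferring GT..AG on ties, then the
    leftmost position.  A boundary with no GT-AG anywhere in the window is
    left where the score puts it and its dinucleotides recorded verbatim."""
    if not aln.introns:
        return aln
    seq = aln.sequence
    g = locus.sequence
    blocks = [list(b) for b in aln.blocks]
    for bi in range(len(blocks) - 1):
        L, R = blocks[bi], blocks[bi + 1]
        d, a = L[1], R[0]
        re_ = L[3]
        lo = max(-window, L[2] - re_ + 1, L[0] - d + 1, -a + 2)
        hi = min(window, R[3] - re_ - 1, R[1] - a - 1, len(g) - d - 2)
        best = None
        for s in range(lo, hi + 1):
            m = 0
            for t in range(-min(window, re_ - L[2]), s):
                pp = re_ + t
                if seq[pp] == g[d + t]:
                    m += 1
            for t in range(s, min(window, R[3] - re_)):
                pp = re_ + t
                if seq[pp] == g[a + t]:
                    m += 1
            gtag = g[d + s:d + s + 2] == "GT" and g[a + s - 2:a + s] == "AG"
            key = (m, gtag, -s)
            if best is None or key > best[0]:
                best = (key, s)
        if best is None:
            continue
        s = best[1]
        L[1], L[3] = d + s, re_ + s
        R[0], R[2] = a + s, re_ + s

    new_blocks = [tuple(b) for b in blocks]
    idents = []
    matched = 0
    for ls_, le_, rs_, re__ in new_blocks:
        m, ident = _block_identity(seq[rs_:re__], g[ls_:le_])
        matched += m
        idents.append(ident)
    introns = []
    for (l1, e1, _, _), (l2, e2, _, _) in zip(new_blocks, new_blocks[1:]):
        introns.append((g[e1:e1 + 2], g[l2 - 2:l2]))
    return replace(aln, blocks=new_blocks, block_identities=idents,
                   introns=introns,
                   total_identity=matched / len(seq) if seq else 0.0)


def import_alignments(path, reads: list[ReadRecord], locus: GeneLocus
                      ) -> list[ReadAlignment]:
    """Import externally produced alignments from BED12.

    Block intervals are taken verbatim; read coordinates are reconstructed
    cumulatively from the block sizes (the BED12 is assumed to cover the
    read end to end — BED carries no clipping), and identities are
    recomputed against the locus.
    """
    from .io import read_bed12

    by_id = {r.read_id: r for r in reads}
    entries = read_bed12(path)
    unknown = [name for name, _ in entries if name not in by_id]
    if unknown:
        raise ValueError(f"BED12 names not found among reads: {unknown}")
    out = []
    for name, intervals in entries:
        seq = by_id[name].sequence
        blocks = []
        cum = 0
        for ls, le in intervals:
            blocks.append((ls, le, cum, cum + (le - ls)))
            cum += le - ls
        idents = []
        matched = 0
        for ls, le, rs, re_ in blocks:
            m, ident = _block_identity(seq[rs:re_], locus.sequence[ls:le])
            matched += m
            idents.append(ident)
        introns = [(locus.sequence[e1:e1 + 2], locus.sequence[l2 - 2:l2])
                   for (_, e1, _, _), (l2, _, _, _) in zip(blocks, blocks[1:])]
        out.append(ReadAlignment(name, blocks, idents, introns,
                                 matched / len(seq) if seq else 0.0,
                                 "forward", seq))
    return out
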