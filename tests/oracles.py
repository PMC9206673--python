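"""Independent brute-force oracles used to check the package's fast paths.

Everything here is written the slow, obvious way (plain-Python dynamic
programming, exhaustive scans) and is deliberately kept free of imports
from the package's alignment and proteome internals.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_score(q: str, t: str, match=1, mismatch=-2, gap_open=-2,
             gap_extend=-1) -> int:
    """Best local-alignment score, affine gaps: cost(g) = open+(g-1)*ext."""
    m, n = len(q), len(t)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = match if q[i - 1] == t[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_free_identity(q: str, t: str, match=1, mismatch=-2, gap_open=-2,
                     gap_extend=-1) -> tuple[int, float]:
    """(score, identity) of an end-gap-free global alignment; identity is
    matches over path columns excluding terminal gaps, along a traceback
    preferring substitutions."""
    m, n = len(q), len(t)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = 0
    for i in range(m + 1):
        H[i][0] = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            sub = match if q[i - 1] == t[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + sub, E[i][j], F[i][j])
    cands = [(H[m][j], m, j) for j in range(n + 1)] + \
            [(H[i][n], i, n) for i in range(m + 1)]
    best, bi, bj = max(cands, key=lambda x: (x[0], -x[1], -x[2]))
    i, j, state = bi, bj, 0
    matches = cols = 0
    while i > 0 and j > 0:
        if state == 0:
            sub = match if q[i - 1] == t[j - 1] else mismatch
            if H[i - 1][j - 1] + sub == H[i][j]:
                cols += 1
                matches += q[i - 1] == t[j - 1]
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            state = 0 if E[i][j] == H[i][j - 1] + gap_open else 1
            j -= 1
        else:
            cols += 1
            state = 0 if F[i][j] == H[i - 1][j] + gap_open else 2
            i -= 1
    return int(best), matches / cols if cols else 0.0


def spliced_align_blocks(read: str, locus: str, min_intron=20, match=1,
                         mismatch=-2, gap=-2) -> list[tuple[int, int, int, int]]:
    """Brute-force spliced alignment: semi-global DP over (read, locus)
    with free locus gaps >= min_intron (introns) and linear small gaps.
    Returns blocks (locus_start, locus_end, read_start, read_end) of the
    best path.  The read must align end to end (use adapter-free reads).
    """
    m, n = len(read), len(locus)
    S = [[NEG] * (n + 1) for _ in range(m + 1)]
    B = [[None] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        S[0][j] = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = match if read[i - 1] == locus[j - 1] else mismatch
            cands = [(S[i - 1][j - 1] + sub, ("d", i - 1, j - 1)),
                     (S[i - 1][j] + gap, ("u", i - 1, j)),
                     (S[i][j - 1] + gap, ("l", i, j - 1))]
            S[i][j], B[i][j] = max(cands, key=lambda x: x[0])
        # intron relaxation (free jump along the locus)
        run = NEG
        best_arg = None
        for j in range(1, n + 1):
            jj = j - min_intron
            if jj >= 0 and S[i][jj] > run:
                run = S[i][jj]
                best_arg = jj
            if run > S[i][j]:
                S[i][j] = run
                B[i][j] = ("i", i, best_arg)
    bj = max(range(n + 1), key=lambda j: (S[m][j], -j))
    # traceback into blocks
    i, j = m, bj
    pairs = []  # aligned (read_pos, locus_pos) diag steps
    while i > 0 and j > 0 and B[i][j] is not None:
        kind, pi, pj = B[i][j]
        if kind == "d":
            pairs.append((i - 1, j - 1))
        i, j = pi, pj
    pairs.reverse()
    blocks = []
    for ri, lj in pairs:
        if blocks and lj - blocks[-1][1] < min_intron:
            blocks[-1][1] = lj + 1
            blocks[-1][3] = ri + 1
        else:
            blocks.append([lj, lj + 1, ri, ri + 1])
    return [(a, b, c, d) for a, b, c, d in blocks]


def enumerate_orfs(seq: str, starts=("ATG", "CTG", "GTG", "TTG"),
                   min_nt=300, longest_per_stop=True) -> list[tuple[int, int]]:
    """All (start, end-exclusive incl. stop) ORFs by exhaustive scanning."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for frame in range(3):
        for s in range(frame, len(seq) - 2, 3):
            if seq[s:s + 3] not in starts:
                continue
            for e in range(s + 3, len(seq) - 2, 3):
                if seq[e:e + 3] in stops:
                    if e + 3 - s >= min_nt:
                        out.append((s, e + 3))
                    break
    if longest_per_stop:
        by_stop = {}
        for s, e in out:
            if e not in by_stop or s < by_stop[e]:
                by_stop[e] = s
        out = [(s, e) for e, s in by_stop.items()]
    return sorted(out)


def min_overhangs_exhaustive(junctions: list[tuple[str, str]],
                             seqs: dict[str, str]) -> dict[tuple[str, str],
                                                           tuple[int, int]]:
    """Minimal-by-sum (then by a) unique overhangs per junction, by
    exhaustive enumeration and substring scanning."""
    out = {}
    for d, a in junctions:
        sd, sa = seqs[d], seqs[a]
        found = None
        for total in range(2, len(sd) + len(sa) + 1):
            for x in range(max(1, total - len(sa)),
                           min(len(sd), total - 1) + 1):
                y = total - x
                s = sd[-x:] + sa[:y]
                clash = False
                for d2, a2 in junctions:
                    if (d2, a2) == (d, a):
                        continue
                    s2 = seqs[d2][-min(x, len(seqs[d2])):] \
                        + seqs[a2][:min(y, len(seqs[a2]))]
                    if s == s2:
                        clash = True
                        break
                if not clash and not any(s in e for e in seqs.values()):
                    found = (x, y)
                    break
            if found:
                break
        out[(d, a)] = found
    return out


def tryptic_peptides(protein: str) -> list[str]:
    """Fully cleaved tryptic fragments by character scanning (no regex)."""
    frags = []
    cur = []
    for i, aa in enumerate(protein):
        cur.append(aa)
        nxt = protein[i + 1] if i + 1 < len(protein) else None
        if aa in "KR" and nxt != "P" and nxt is not None:
            frags.append("".join(cur))
            cur = []
    if cur:
        frags.append("".join(cur))
    return frags


# average and monoisotopic residue masses (Da), standard 20 amino acids
RESIDUE_AVG = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
RESIDUE_MONO = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "E": 129.04259, "Q": 128.05858, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}
WATER_AVG = 18.0153
WATER_MONO = 18.0105646863


def protein_mass(seq: str, monoisotopic: bool = False) -> float:
    table = RESIDUE_MONO if monoisotopic else RESIDUE_AVG
    water = WATER_MONO if monoisotopic else WATER_AVG
    return sum(table[a] for a in seq) + water


def hamming_demux(read: str, barcodes: dict[str, str], window: int,
                  max_mm: int) -> str | None:
    """Brute-force demultiplex oracle: best sliding-window Hamming match of
    each forward barcode against the read prefix and the reverse-complement
    prefix; None if unassigned or ambiguous."""
    comp = str.maketrans("ACGTN", "TGCAN")

    def scan(bc: str, s: str) -> int:
        best = len(bc)
        for off in range(max(1, len(s) - len(bc) + 1)):
            w = s[off:off + len(bc)]
            if len(w) < len(bc):
                break
            d = sum(1 for x, y in zip(bc, w) if x != y or y == "N")
            best = min(best, d)
        return best

    rc = read.translate(comp)[::-1]
    hits = []
    for sample, bc in barcodes.items():
        d = min(scan(bc, read[:window]), scan(bc, rc[:window]))
        if d <= max_mm:
            hits.append(sample)
    return hits[0] if len(hits) == 1 else None
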