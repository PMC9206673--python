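"""Exon-exon junction enumeration, uniqueness overhangs, the artificial
junction reference, and short-read support counting.

A junction's minimal overhangs (a, b) are the smallest suffix/prefix
lengths making its flanking string unambiguous evidence: unique among the
junction strings of the whole set and absent from every single exon
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cluster import TranscriptCluster

__all__ = [
    "Junction",
    "enumerate_junctions",
    "min_unique_overhangs",
    "build_junction_reference",
    "count_short_read_support",
    "query_junction_report",
]


@dataclass
class Junction:
    donor_exon: str
    acceptor_exon: str
    supporting_transcripts: list[str] = field(default_factory=list)
    long_read_count: int = 0
    short_read_count: int = 0
    min_overhang_5p: int | None = None
    min_overhang_3p: int | None = None
    discriminable: bool = True

    @property
    def junction_id(self) -> str:
        return f"{self.donor_exon}-{self.acceptor_exon}"


def enumerate_junctions(clusters: list[TranscriptCluster],
                        genomic_order: dict[str, int] | None = None
                        ) -> list[Junction]:
    """One Junction per ordered adjacent exon pair occurring in at least one
    transcript barcode; long_read_count sums the supporting transcripts'
    read counts."""
    if not clusters:
        raise ValueError("need at least one cluster")
    seen: dict[tuple[str, str], Junction] = {}
    for cl in clusters:
        names = cl.barcode.exon_names
        for d, a in zip(names, names[1:]):
            j = seen.get((d, a))
            if j is None:
                j = seen[(d, a)] = Junction(d, a)
            j.supporting_transcripts.append(cl.name)
            j.long_read_count += cl.total_count
    out = list(seen.values())
    if genomic_order:
        out.sort(key=lambda j: (genomic_order[j.donor_exon],
                                genomic_order[j.acceptor_exon]))
    return out


def _junction_string(j: Junction, exon_seqs: dict[str, str],
                     a: int, b: int) -> str:
    return exon_seqs[j.donor_exon][-a:] + exon_seqs[j.acceptor_exon][:b]


def min_unique_overhangs(junctions: list[Junction],
                         exon_seqs: dict[str, str]
                         ) -> tuple[dict[str, tuple[int, int]], tuple[int, int]]:
    """Per-junction minimal (a, b) overhangs and the global elementwise
    maxima (A, B).

    (a, b) is minimal by sum (ties -> lexicographically smallest) such that
    suffix_a(donor) + prefix_b(acceptor) equals no other junction's string
    built with the same overhangs and occurs inside no single exon
    sequence.  Junctions for which no such pair exists within the available
    exon lengths are flagged non-discriminable (typically acceptor-variant
    pairs sharing their donor boundary, whose junction sequences are
    genomically identical) and excluded from the global maxima.
    """
    def _twin(j: Junction, o: Junction) -> bool:
        """Sequence-identical junctions as far as both extend: the donors
        are suffix-related and the acceptors prefix-related (acceptor
        variants sharing their donor boundary produce these)."""
        d1, d2 = exon_seqs[j.donor_exon], exon_seqs[o.donor_exon]
        a1, a2 = exon_seqs[j.acceptor_exon], exon_seqs[o.acceptor_exon]
        return (d1.endswith(d2) or d2.endswith(d1)) \
            and (a1.startswith(a2) or a2.startswith(a1))

    per: dict[str, tuple[int, int]] = {}
    exon_list = list(exon_seqs.values())
    for j in junctions:
        others = [o for o in junctions if o is not j and not _twin(j, o)]
        if len(others) < len(junctions) - 1:
            j.discriminable = False
        max_a = len(exon_seqs[j.donor_exon])
        max_b = len(exon_seqs[j.acceptor_exon])
        found = None
        for total in range(2, max_a + max_b + 1):
            for a in range(max(1, total - max_b), min(max_a, total - 1) + 1):
                b = total - a
                s = _junction_string(j, exon_seqs, a, b)
                other_strings = [
                    _junction_string(o, exon_seqs,
                                     min(a, len(exon_seqs[o.donor_exon])),
                                     min(b, len(exon_seqs[o.acceptor_exon])))
                    for o in others]
                if s in other_strings:
                    continue
                if any(s in e for e in exon_list):
                    continue
                found = (a, b)
                break
            if found:
                break
        if found is None:
            j.discriminable = False
            found = (max_a, max_b)
        per[j.junction_id] = found
        j.min_overhang_5p, j.min_overhang_3p = found
    discr = [per[j.junction_id] for j in junctions if j.discriminable]
    if discr:
        global_a = max(a for a, _ in discr)
        global_b = max(b for _, b in discr)
    else:
        global_a = global_b = 0
    return per, (global_a, global_b)


def build_junction_reference(junctions: list[Junction],
                             exon_seqs: dict[str, str],
                             overhang_5p: int = 9, overhang_3p: int = 6
                             ) -> list[tuple[str, str, bool]]:
    """One record per junction: id, suffix+prefix sequence, truncated flag
    (set when an exon is shorter than the requested overhang)."""
    records = []
    for j in junctions:
        d = exon_seqs[j.donor_exon]
        a = exon_seqs[j.acceptor_exon]
        truncated = len(d) < overhang_5p or len(a) < overhang_3p
        seq = d[-min(overhang_5p, len(d)):] + a[:min(overhang_3p, len(a))]
        records.append((j.junction_id, seq, truncated))
    return records


def count_short_read_support(short_reads, junction_records,
                             junction_point: dict[str, int] | int = 9,
                             min_overlap: int = 15,
                             per_side_min: dict[str, tuple[int, int]] | None = None,
                             max_mismatch: int = 0) -> dict[str, int]:
    """Count reads supporting each junction record.

    A read supports a junction iff it carries a match to the junction
    record that covers the junction point with total matched length
    >= min_overlap and per-side matched lengths >= the per-side minima
    (defaulting to (1, 1)).  Matching is exact by default; max_mismatch=1
    tolerates one substitution in full-record matches.  Each read counts at
    most once per junction; unsupported junctions report zero.
    """
    counts: dict[str, int] = {}
    seqs = [(r[0], r[1]) for r in junction_records]
    for jid, _ in seqs:
        counts[jid] = 0
    for jid, ref in seqs:
        jp = junction_point[jid] if isinstance(junction_point, dict) \
            else min(junction_point, len(ref) - 1)
        a_min, b_min = (per_side_min or {}).get(jid, (1, 1))
        left_len = jp
        right_len = len(ref) - jp
        for read in short_reads:
            seq = read.sequence if hasattr(read, "sequence") else str(read)
            if _read_supports(seq, ref, jp, left_len, right_len,
                              a_min, b_min, min_overlap, max_mismatch):
                counts[jid] += 1
    return counts


def _read_supports(seq: str, ref: str, jp: int, left_len: int, right_len: int,
                   a_min: int, b_min: int, min_overlap: int,
                   max_mismatch: int) -> bool:
    # full-record occurrences (junction fully embedded in the read)
    if left_len >= a_min and right_len >= b_min and len(ref) >= min_overlap:
        if max_mismatch == 0:
            if ref in seq:
                return True
        else:
            for off in range(len(seq) - len(ref) + 1):
                mm = sum(x != y for x, y in zip(ref, seq[off:off + len(ref)]))
                if mm <= max_mismatch:
                    return True
    # partial occurrences at the read ends (exact only): the read begins
    # inside the donor overhang or ends inside the acceptor overhang
    for x in range(a_min, left_len):  # read starts mid-donor-suffix
        y = min(right_len, len(seq) - x)
        if y < b_min or x + y < min_overlap:
            continue
        if seq[:x + y] == ref[jp - x:jp + y]:
            return True
    for y in range(b_min, right_len):  # read ends mid-acceptor-prefix
        x = min(left_len, len(seq) - y)
        if x < a_min or x + y < min_overlap:
            continue
        if seq[-(x + y):] == ref[jp - x:jp + y]:
            return True
    return False


def junction_table(junctions: list[Junction]) -> pd.DataFrame:
    return pd.DataFrame([{
        "junction_id": j.junction_id,
        "donor_exon": j.donor_exon,
        "acceptor_exon": j.acceptor_exon,
        "n_transcripts": len(j.supporting_transcripts),
        "transcripts": ",".join(j.supporting_transcripts),
        "long_read_count": j.long_read_count,
        "short_read_count": j.short_read_count,
        "min_overhang_5p": j.min_overhang_5p,
        "min_overhang_3p": j.min_overhang_3p,
        "discriminable": j.discriminable,
    } for j in junctions])


def query_junction_report(junctions: list[Junction],
                          pairs: list[tuple[str, str]],
                          matrix=None) -> pd.DataFrame:
    """Screen a list of exon pairs (e.g. candidate pathological junctions):
    presence, supporting transcripts, and share of total expression."""
    by_id = {j.junction_id: j for j in junctions}
    total = int(matrix.counts.to_numpy().sum()) if matrix is not None else None
    rows = []
    for d, a in pairs:
        jid = f"{d}-{a}"
        j = by_id.get(jid)
        row = {"junction_id": jid, "present": j is not None,
               "n_transcripts": len(j.supporting_transcripts) if j else 0,
               "transcripts": ",".join(j.supporting_transcripts) if j else "",
               "long_read_count": j.long_read_count if j else 0}
        if total:
            row["pct_of_total_expression"] = \
                100.0 * (j.long_read_count if j else 0) / total
        rows.append(row)
    return pd.DataFrame(rows)
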