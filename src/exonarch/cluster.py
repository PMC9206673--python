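"""Exon-architecture barcoding, QC and transcript clustering.

Each read is annotated for the presence/absence of every catalog exon by
thresholded local alignment; the ordered exon list is the read's
architecture barcode, identical barcodes form one transcript cluster.
Reads are quality-controlled by global alignment against the theoretical
transcript (the concatenation of the barcode's exon sequences).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from ._dp import global_free_ends, smith_waterman
from .exons import ExonCatalog

__all__ = [
    "AnnotationParams",
    "ArchitectureBarcode",
    "AnnotatedRead",
    "TranscriptCluster",
    "annotate_exons",
    "qc_against_theoretical",
    "cluster_and_name",
]


@dataclass(frozen=True)
class AnnotationParams:
    """Scoring and filtering parameters for exon annotation and QC.

    Local-alignment scores follow the short-query nucleotide-search scheme
    (match +1, mismatch -2); a gap of length g costs
    gap_open + (g - 1) * gap_extend.  An exon is called present when its
    best local hit covers >= min_cov of the exon at >= min_ident identity.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -2
    gap_extend: int = -1
    min_cov: float = 0.8
    min_ident: float = 0.85
    qc_min_identity: float = 0.85
    min_cluster_reads: int = 1
    require_terminal_exons: bool = False
    qc_band_pad: int | None = 150

    def __post_init__(self) -> None:
        if not (self.mismatch < 0 <= self.match):
            raise ValueError("need mismatch < 0 <= match")
        for f in (self.min_cov, self.min_ident, self.qc_min_identity):
            if not 0 < f <= 1:
                raise ValueError("fractions must lie in (0, 1]")


@dataclass(frozen=True)
class ArchitectureBarcode:
    exon_names: tuple[str, ...]

    @property
    def canonical_string(self) -> str:
        return "|".join(self.exon_names)

    def __len__(self) -> int:
        return len(self.exon_names)


@dataclass
class AnnotatedRead:
    read_id: str
    sample_id: str | None
    barcode: ArchitectureBarcode
    hit_table: pd.DataFrame
    qc_identity: float | None = None
    qc_pass: bool | None = None


def annotate_exons(read, exon_seqs: dict[str, str], catalog: ExonCatalog,
                   params: AnnotationParams | None = None
                   ) -> tuple[ArchitectureBarcode | None, pd.DataFrame, str | None]:
    """Call exon presence/absence on a forward-oriented read.

    Returns (barcode, hit table, exclusion reason).  The barcode is None
    when the read is excluded ("no architecture" if no exon is present,
    "non_colinear" if read-position order disagrees with genomic order).
    Among variant-group members only the best-scoring present member is
    kept (tie -> longer variant).
    """
    p = params or AnnotationParams()
    seq = read.sequence if hasattr(read, "sequence") else str(read)
    rows = []
    present: dict[str, tuple[float, int]] = {}  # name -> (score, read_start)
    for name in catalog.names:
        es = exon_seqs[name]
        sw = smith_waterman(seq, es, p.match, p.mismatch, p.gap_open,
                            p.gap_extend)
        coverage = (sw["t_end"] - sw["t_start"]) / len(es)
        identity = sw["matches"] / sw["columns"] if sw["columns"] else 0.0
        ok = coverage >= p.min_cov and identity >= p.min_ident
        rows.append({"exon": name, "score": float(sw["score"]),
                     "coverage": coverage, "identity": identity,
                     "read_start": sw["q_start"], "present": ok})
        if ok:
            present[name] = (float(sw["score"]), sw["q_start"], coverage)
    hits = pd.DataFrame(rows, columns=["exon", "score", "coverage",
                                       "identity", "read_start", "present"])
    if not present:
        return None, hits, "no_architecture"

    # One member per variant group.  Coverage decides (with a 5% band for
    # error-induced edge trimming), then score, then the longer variant.
    # Coverage must outrank raw score: on a short-variant read the long
    # variant scores the same local hit (sometimes +1-2 from a chance
    # extension), and only its partial coverage reveals that the acceptor
    # extension is absent from the read; the 5% band is far below the
    # smallest alternative-acceptor offset.
    def _better(new: str, cur: str) -> bool:
        cov_n, cov_c = present[new][2], present[cur][2]
        if abs(cov_n - cov_c) > 0.05:
            return cov_n > cov_c
        key_n = (present[new][0], len(exon_seqs[new]))
        key_c = (present[cur][0], len(exon_seqs[cur]))
        return key_n > key_c

    chosen: dict[str, str] = {}
    for name in list(present):
        g = catalog.group_of(name)
        if g is None:
            continue
        cur = chosen.get(g)
        if cur is None or _better(name, cur):
            chosen[g] = name
    for name in list(present):
        g = catalog.group_of(name)
        if g is not None and chosen[g] != name:
            del present[name]

    order = catalog.genomic_order
    names = sorted(present, key=lambda n: order[n])
    by_read_pos = sorted(present, key=lambda n: present[n][1])
    if names != by_read_pos:
        return None, hits, "non_colinear"
    return ArchitectureBarcode(tuple(names)), hits, None


def qc_select_variants(seq, barcode: ArchitectureBarcode,
                       catalog: ExonCatalog, exon_seqs: dict[str, str],
                       params: AnnotationParams | None = None
                       ) -> tuple[ArchitectureBarcode, bool, float]:
    """Re-decide acceptor-variant membership by whole-read QC.

    Exon-local alignment cannot reliably separate variants that differ
    only by a short acceptor extension once errors fall near the junction
    (the extension is a few percent of the exon, inside the noise).  The
    global QC alignment is decisive: substituting the wrong variant costs
    the full extension as a gap, while read errors penalize every
    candidate equally.  Each variant group in the barcode is swapped in
    turn and the best global identity wins (ties keep the incumbent).
    Returns (barcode, keep, identity).
    """
    p = params or AnnotationParams()
    current = barcode
    keep, ident = qc_against_theoretical(seq, current, exon_seqs, p)
    improved = True
    while improved:
        improved = False
        for i, name in enumerate(current.exon_names):
            g = catalog.group_of(name)
            if g is None:
                continue
            for m in catalog.variant_groups[g]:
                if m == name:
                    continue
                alt_names = list(current.exon_names)
                alt_names[i] = m
                alt = ArchitectureBarcode(tuple(alt_names))
                k2, id2 = qc_against_theoretical(seq, alt, exon_seqs, p)
                if id2 > ident + 1e-12:
                    current, keep, ident = alt, k2, id2
                    improved = True
    return current, keep, ident


def theoretical_sequence(barcode: ArchitectureBarcode,
                         exon_seqs: dict[str, str]) -> str:
    return "".join(exon_seqs[n] for n in barcode.exon_names)


def qc_against_theoretical(read, barcode: ArchitectureBarcode,
                           exon_seqs: dict[str, str],
                           params: AnnotationParams | None = None
                           ) -> tuple[bool, float]:
    """Global (free-end-gap) alignment of the read against the theoretical
    transcript; identity is matches over alignment columns excluding end
    gaps.  Keep iff identity >= qc_min_identity."""
    if len(barcode) == 0:
        raise ValueError("barcode must be non-empty")
    p = params or AnnotationParams()
    theo = theoretical_sequence(barcode, exon_seqs)
    seq = read.sequence if hasattr(read, "sequence") else str(read)
    res = global_free_ends(theo, seq, p.match, p.mismatch, p.gap_open,
                           p.gap_extend, band_pad=p.qc_band_pad)
    return res["identity"] >= p.qc_min_identity, res["identity"]


@dataclass
class TranscriptCluster:
    name: str
    barcode: ArchitectureBarcode
    theoretical_sequence: str
    member_read_ids: list[str]
    per_sample_counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return len(self.member_read_ids)


def cluster_and_name(annotated: list[AnnotatedRead], exon_seqs: dict[str, str],
                     catalog: ExonCatalog,
                     params: AnnotationParams | None = None,
                     mode: str = "pacbio"
                     ) -> tuple[list[TranscriptCluster], pd.DataFrame]:
    """Cluster QC-passing reads by exact barcode equality.

    ONT mode first drops reads whose barcode lacks the catalog's first or
    last exon, then drops clusters seen fewer than ``min_cluster_reads``
    (default 10 in that mode); pacbio mode keeps everything (minimum 1).
    Clusters are sorted by descending total count (tie -> lexicographic
    barcode) and named T-1..T-N.  Returns (clusters, exclusion log).
    """
    p = params or AnnotationParams()
    if mode not in ("pacbio", "ont"):
        raise ValueError("mode must be 'pacbio' or 'ont'")
    min_reads = max(p.min_cluster_reads, 10) if mode == "ont" else \
        max(p.min_cluster_reads, 1)
    require_terminal = p.require_terminal_exons or mode == "ont"

    excluded = []
    groups: dict[str, list[AnnotatedRead]] = defaultdict(list)
    first_names = catalog.first_exon_names
    last_names = catalog.last_exon_names
    for ar in annotated:
        if require_terminal:
            names = set(ar.barcode.exon_names)
            if not (names & first_names) or not (names & last_names):
                excluded.append({"read_id": ar.read_id,
                                 "reason": "missing_terminal_exon"})
                continue
        groups[ar.barcode.canonical_string].append(ar)

    items = []
    for canon, members in groups.items():
        if len(members) < min_reads:
            for ar in members:
                excluded.append({"read_id": ar.read_id,
                                 "reason": "cluster_below_min_reads"})
            continue
        items.append((canon, members))
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))

    clusters = []
    for i, (canon, members) in enumerate(items):
        barcode = members[0].barcode
        per_sample: dict[str, int] = defaultdict(int)
        for ar in members:
            per_sample[ar.sample_id or "pooled"] += 1
        clusters.append(TranscriptCluster(
            f"T-{i + 1}", barcode, theoretical_sequence(barcode, exon_seqs),
            [ar.read_id for ar in members], dict(per_sample)))
    log = pd.DataFrame(excluded, columns=["read_id", "reason"])
    return clusters, log
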