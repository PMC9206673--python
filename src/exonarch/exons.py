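"""Exon catalog construction from pooled read alignments.

Block edges are clustered to a modal consensus, candidates sharing a donor
boundary but differing at their acceptor are kept as alternative-3'ss
variants (never merged), and only candidates framed by canonical AG..GT
splice dinucleotides on their intronic sides are retained.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io import GeneLocus

__all__ = [
    "Exon",
    "ExonCatalog",
    "BoundaryCandidate",
    "collect_boundaries",
    "validate_splice_sites",
    "exon_sequences",
]


@dataclass(frozen=True)
class Exon:
    """One catalog exon; ``donor_ok``/``acceptor_ok`` are None (not
    applicable) on the terminal side of the first/last exon."""

    name: str
    start: int
    end: int
    donor_ok: bool | None = None
    acceptor_ok: bool | None = None
    support: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"exon {self.name}: empty interval")


@dataclass
class ExonCatalog:
    exons: list[Exon]
    variant_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [e.name for e in self.exons]
        if len(set(names)) != len(names):
            raise ValueError("exon names must be unique")
        starts = [(e.start, e.end) for e in self.exons]
        if starts != sorted(starts):
            raise ValueError("exons must be sorted by (start, end)")

    def __len__(self) -> int:
        return len(self.exons)

    def by_name(self, name: str) -> Exon:
        return next(e for e in self.exons if e.name == name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.exons]

    @property
    def genomic_order(self) -> dict[str, int]:
        return {e.name: i for i, e in enumerate(self.exons)}

    @property
    def first_exon_names(self) -> set[str]:
        """Members of the group holding the catalog's 5'-most exon."""
        first = self.exons[0]
        for base, members in self.variant_groups.items():
            if first.name in members:
                return set(members)
        return {first.name}

    @property
    def last_exon_names(self) -> set[str]:
        last = max(self.exons, key=lambda e: e.end)
        for base, members in self.variant_groups.items():
            if last.name in members:
                return set(members)
        return {last.name}

    def group_of(self, name: str) -> str | None:
        for base, members in self.variant_groups.items():
            if name in members:
                return base
        return None


@dataclass(frozen=True)
class BoundaryCandidate:
    start: int
    end: int
    support: int


def _cluster_edges(coords: list[int], tol: int, jitter_window: int = 30,
                   jitter_frac: float = 0.05) -> dict[int, int]:
    """Map each observed edge coordinate to its cluster consensus.

    Mode-centric: the most supported coordinate (tie -> smaller) becomes a
    cluster center absorbing everything within ``tol`` of it; repeat on the
    remainder.  Unlike single-linkage this cannot chain two well-supported
    boundaries (e.g. alternative acceptors 18 nt apart) through sparse
    in-between jitter.  Sparse jitter itself — edges within
    ``jitter_window`` of a center but supported by under ``jitter_frac``
    of its reads — is attributed to the center rather than left to seed
    spurious boundaries (error bursts near a splice site can displace a
    per-read boundary well beyond ``tol``).  Consequence: an alternative
    boundary closer than ``jitter_window`` to a dominant one is only
    called when it carries at least that support fraction.
    """
    counts = Counter(coords)
    mapping: dict[int, int] = {}
    remaining = set(counts)
    while remaining:
        center = max(remaining, key=lambda x: (counts[x], -x))
        limit = jitter_frac * counts[center]
        for x in list(remaining):
            if abs(x - center) <= tol or (
                    abs(x - center) <= jitter_window
                    and counts[x] <= limit and x != center):
                mapping[x] = center
                remaining.discard(x)
    return mapping


def collect_boundaries(alignments, tol: int = 3, min_support: int = 1,
                       min_block_identity: float = 0.8
                       ) -> list[BoundaryCandidate]:
    """Cluster block edges across alignments into candidate exon intervals.

    Candidates sharing their donor (end) but differing in acceptor (start)
    by more than ``tol`` stay separate, so alternative 3' splice sites
    survive as distinct candidates.  Blocks aligned below
    ``min_block_identity`` contribute no edges (they are chimeric-path
    artifacts of heavily errored reads, not exon evidence).
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    blocks: list[tuple[int, int]] = []
    for aln in alignments:
        idents = getattr(aln, "block_identities", None)
        for bi, (ls, le, _, _) in enumerate(aln.blocks):
            if idents is not None and idents[bi] < min_block_identity:
                continue
            blocks.append((ls, le))
    start_map = _cluster_edges([b[0] for b in blocks], tol)
    end_map = _cluster_edges([b[1] for b in blocks], tol)
    joint = Counter((start_map[s], end_map[e]) for s, e in blocks)
    out = [BoundaryCandidate(s, e, n) for (s, e), n in joint.items()
           if n >= min_support and e > s]
    return sorted(out, key=lambda c: (c.start, c.end))


def validate_splice_sites(candidates: list[BoundaryCandidate], locus: GeneLocus,
                          accepted: tuple[tuple[str, str], ...] = (("GT", "AG"),),
                          ) -> tuple[ExonCatalog, pd.DataFrame]:
    """Keep candidates whose intronic flanks carry canonical splice
    dinucleotides (acceptor preceded by AG, donor followed by GT on the
    transcribed strand); terminal exons are checked only on their intronic
    side.  Returns the named catalog and an exclusion log.

    Retained exons are named E1..En in genomic order; acceptor variants
    sharing a donor boundary get suffixes a, b, ... by increasing start.
    """
    seq = locus.sequence
    donors = {d for d, a in accepted}
    acceptors = {a for d, a in accepted}
    cands = sorted(candidates, key=lambda c: (c.start, c.end))
    log_rows = []
    if not cands:
        return ExonCatalog([], {}), pd.DataFrame(
            columns=["start", "end", "support", "reason"])

    kept: list[tuple[BoundaryCandidate, bool | None, bool | None]] = []
    for c in cands:
        if c.start < 0 or c.end > len(seq):
            log_rows.append({"start": c.start, "end": c.end,
                             "support": c.support, "reason": "out_of_bounds"})
            continue
        # a candidate is terminal when nothing lies strictly up/downstream
        is_first = not any(o.end <= c.start for o in cands)
        is_last = not any(o.start >= c.end for o in cands)
        acc_ok: bool | None = None
        don_ok: bool | None = None
        if not is_first:
            acc_ok = c.start >= 2 and seq[c.start - 2:c.start] in acceptors
        if not is_last:
            don_ok = c.end + 2 <= len(seq) and seq[c.end:c.end + 2] in donors
        if acc_ok is False:
            log_rows.append({"start": c.start, "end": c.end,
                             "support": c.support, "reason": "acceptor_fail"})
            continue
        if don_ok is False:
            log_rows.append({"start": c.start, "end": c.end,
                             "support": c.support, "reason": "donor_fail"})
            continue
        kept.append((c, don_ok, acc_ok))

    # Group acceptor variants: same end coordinate and overlapping.
    by_end: dict[int, list] = defaultdict(list)
    for item in kept:
        by_end[item[0].end].append(item)
    groups = sorted(by_end.values(), key=lambda g: min(i[0].start for i in g))

    exons: list[Exon] = []
    variant_groups: dict[str, list[str]] = {}
    for gi, group in enumerate(groups):
        base = f"E{gi + 1}"
        group = sorted(group, key=lambda i: i[0].start)
        if len(group) == 1:
            c, don, acc = group[0]
            exons.append(Exon(base, c.start, c.end, don, acc, c.support))
        else:
            names = []
            for vi, (c, don, acc) in enumerate(group):
                nm = f"{base}{chr(ord('a') + vi)}"
                names.append(nm)
                exons.append(Exon(nm, c.start, c.end, don, acc, c.support))
            variant_groups[base] = names
    catalog = ExonCatalog(sorted(exons, key=lambda e: (e.start, e.end)),
                          variant_groups)
    log = pd.DataFrame(log_rows, columns=["start", "end", "support", "reason"])
    return catalog, log


def exon_sequences(catalog: ExonCatalog, locus: GeneLocus) -> dict[str, str]:
    """Substring extraction per catalog coordinates."""
    return {e.name: locus.sequence[e.start:e.end] for e in catalog.exons}
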