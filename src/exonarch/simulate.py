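"""Synthetic single-locus data with ground truth.

Builds toy multi-exon genes (GT-AG introns, optional alternative 3'
splice-site exon variants), draws per-sample isoform abundances, and emits
error-bearing barcoded long reads and junction-spanning short reads,
together with a manifest recording the truth for every read.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exons import Exon, ExonCatalog
from .io import GeneLocus, ReadRecord, SampleEntry, SampleSheet, revcomp, write_fastq

__all__ = [
    "SimulatedGene",
    "SimScenario",
    "SimResult",
    "ShortReadResult",
    "build_toy_gene",
    "make_sample_sheet",
    "simulate_long_reads",
    "simulate_short_reads",
]

# Fixed amplification primers flanking every insert (arbitrary but constant,
# mirroring a two-round barcoded amplicon design).
PRIMER_FWD = "TCAGGTCACCCACGACCATCAAATC"
PRIMER_REV = "ACATCGTAGCAGGATACAGTCAATG"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulatedGene:
    """A toy locus plus its true exon catalog and isoform repertoire."""

    locus: GeneLocus
    true_exons: ExonCatalog
    true_isoforms: list[tuple[str, tuple[str, ...]]]
    intron_lengths: tuple[int, ...]

    @property
    def isoform_names(self) -> list[str]:
        return [n for n, _ in self.true_isoforms]

    def isoform_sequence(self, name: str) -> str:
        seqs = {e.name: self.locus.sequence[e.start:e.end]
                for e in self.true_exons.exons}
        chain = dict(self.true_isoforms)[name]
        return "".join(seqs[x] for x in chain)


@dataclass
class SimScenario:
    """Study conditions for one simulated run.

    ``abundance_model`` is one of
      {"dirichlet": alpha}            symmetric concentration (or vector),
      {"proportions": [[...], ...]}   explicit per-sample proportions,
      {"counts": [[...], ...]}        exact per-sample isoform counts.
    Error rates are i.i.d. per base; probabilities capped at 0.2.
    """

    n_samples: int = 4
    abundance_model: dict = field(default_factory=lambda: {"dirichlet": 5.0})
    reads_per_sample: int = 500
    error_rates: tuple[float, float, float] = (0.01, 0.0025, 0.0025)
    seed: int = 0
    short_read_length: int = 100
    short_reads_per_sample: int = 1000
    truncation_prob: float = 0.0

    def __post_init__(self) -> None:
        for p in self.error_rates:
            if not 0.0 <= p <= 0.2:
                raise ValueError("error probabilities must lie in [0, 0.2]")
        if "proportions" in self.abundance_model:
            for row in self.abundance_model["proportions"]:
                if abs(sum(row) - 1.0) > 1e-9:
                    raise ValueError("proportions per sample must sum to 1")


_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


def _coding_cdna(rng: np.random.Generator, total: int) -> str:
    """ATG + random sense codons + TAA, ``total`` nt (must be 3-divisible):
    a clean open reading frame over the full-length transcript."""
    n_codons = total // 3 - 2
    body = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
    return "ATG" + body + "TAA"


def build_toy_gene(n_exons: int, alt3ss_exons: set[int] | frozenset[int] = frozenset(),
                   seed: int = 0, n_isoforms: int | None = None,
                   exon_codons: tuple[int, int] = (27, 54),
                   intron_length: tuple[int, int] = (60, 140),
                   n_frameshift_exons: int | None = None,
                   noncanonical_donor_exons: set[int] | frozenset[int] = frozenset(),
                   flank: int = 40) -> SimulatedGene:
    """Build a coding toy gene with ``n_exons`` exons.

    The full-length cDNA is one clean reading frame (ATG .. TAA, no internal
    in-frame stop) cut into exons.  Most internal exons are
    frame-preserving cassettes (length a multiple of 3) so that skipping
    them keeps the frame; ``n_frameshift_exons`` internal exons (default
    ~1 in 5) get a +1/+2 nt length so that isoform-dependent frameshifts
    and hence premature stop codons arise downstream, exercising the
    PTC/NMD filter.  Indices in ``alt3ss_exons`` (0-based, internal)
    additionally get an alternative-acceptor variant starting a
    codon-multiple 6-30 nt downstream, with AG embedded immediately
    upstream so both acceptors are canonical.

    The isoform repertoire always contains the full-length architecture and
    every isoform includes the first and last exon (amplicon primer
    design); internal exons are independently skippable.  Exon-flanking
    bases are arranged so true splice boundaries are uniquely recoverable
    (no equal-score boundary shift can also restore GT-AG).
    """
    if n_exons < 3:
        raise ValueError("n_exons must be >= 3")
    for i in alt3ss_exons:
        if not 0 < i < n_exons - 1:
            raise ValueError("alt 3'ss variants only on internal exons")
    rng = np.random.default_rng(seed)

    # exon lengths: codon multiples, plus +1/+2 on frame-shifting cassettes
    lengths = 3 * rng.integers(exon_codons[0], exon_codons[1], size=n_exons)
    internal = [i for i in range(1, n_exons - 1) if i not in alt3ss_exons]
    if n_frameshift_exons is None:
        n_frameshift_exons = max(1, len(internal) // 5) if len(internal) > 1 else 0
    fs = rng.choice(internal, size=min(n_frameshift_exons, len(internal)),
                    replace=False) if n_frameshift_exons else []
    for i in fs:
        lengths[i] += int(rng.integers(1, 3))
    lengths[-1] += (-int(lengths.sum())) % 3  # keep the terminal TAA in frame
    total = int(lengths.sum())
    cdna = _coding_cdna(rng, total)

    # Cut points between exons, nudged by codon steps so boundaries stay
    # uniquely recoverable from error-bearing reads: the bases flanking a
    # boundary differ from G (no equal-score shift can restore GT-AG) and
    # no decoy GT within the 12 nt upstream of a donor / no decoy AG within
    # the 12 nt downstream of an acceptor (an indel-shifted boundary
    # placement then always fails splice-site validation).
    def _cut_ok(s: str, c: int) -> bool:
        return (s[c - 1] != "G" and s[c] != "G"
                and "GT" not in s[max(0, c - 12):c]
                and "AG" not in s[c:c + 12])

    offsets = (0, 3, -3, 6, -6, 9, -9, 12, -12, 15, -15, 18, -18, 21, -21, 24)

    def _edge_ok(s: str, c: int) -> bool:
        return s[c - 1] != "G" and s[c] != "G"

    cuts = [0]
    for i in range(n_exons - 1):
        cut = cuts[-1] + int(lengths[i])
        lo = cuts[-1] + 30
        hi = min(cut + 24, total - 30 * (n_exons - 1 - i))
        # prefer decoy-free cuts; fall back to the edge-base rule alone,
        # which the boundary-identifiability guarantee cannot do without
        for pred in (_cut_ok, _edge_ok):
            hit = next((cut + off for off in offsets
                        if lo <= cut + off <= hi and pred(cdna, cut + off)),
                       None)
            if hit is not None:
                cut = hit
                break
        cuts.append(cut)
    cuts.append(total)

    # Alternative acceptors: embed AG a codon-multiple delta (>= 15 nt) into
    # the exon; the variant acceptor must be the only AG near either
    # acceptor and must not create an in-frame stop.  On failure the codons
    # under the constraint window are resampled.
    alt_delta: dict[int, int] = {}
    for i in sorted(alt3ss_exons):
        g = cuts[i]
        exon_len = cuts[i + 1] - g
        deltas = [d for d in range(15, 31, 3) if d <= exon_len - 15]
        for attempt in range(400):
            delta = deltas[attempt % len(deltas)]
            if attempt >= len(deltas):
                c0 = ((g + 2) // 3) * 3
                c1 = ((g + delta + 12) // 3) * 3
                body = "".join(rng.choice(_SENSE_CODONS, size=(c1 - c0) // 3))
                cdna = cdna[:c0] + body + cdna[c1:]
            cand = cdna[:g + delta - 2] + "AG" + cdna[g + delta:]
            lo_c = (g // 3) * 3
            ok = all(cand[cs:cs + 3] not in _STOPS
                     for cs in range(lo_c, min(g + delta + 15, total - 2), 3))
            # the region the embedding can affect: the canonical acceptor's
            # decoy window and the edge bases of both acceptors
            ok = ok and "AG" not in cand[g:g + 12] and cand[g] != "G"
            ok = ok and cand[g + delta] != "G"
            for p in range(g + delta - 12, g + delta + 11):
                if cand[p:p + 2] == "AG" and p != g + delta - 2:
                    ok = False
            if ok:
                cdna = cand
                alt_delta[i] = delta
                break
        if i not in alt_delta:
            raise RuntimeError("could not place alternative acceptor")

    exon_seqs = [cdna[a:b] for a, b in zip(cuts, cuts[1:])]
    if len(set(exon_seqs)) != n_exons:
        raise RuntimeError("degenerate draw: identical exon sequences")

    # Introns: GT..AG with no decoy GT in the first 14 nt and no decoy AG
    # in the last 14 nt, so indel-shifted boundary placements never land on
    # a spurious canonical site.
    intron_seqs: list[str] = []
    while len(intron_seqs) < n_exons - 1:
        ln = int(rng.integers(*intron_length))
        s = "GT" + "".join(rng.choice(_BASES, size=ln - 4)) + "AG"
        if "GT" not in s[1:14] and "AG" not in s[-14:-1]:
            intron_seqs.append(s)
    # optionally inject non-canonical (GC) donors to exercise the
    # splice-site validation filter
    for i in noncanonical_donor_exons:
        if not 0 <= i < n_exons - 1:
            raise ValueError("noncanonical donor index out of range")
        intron_seqs[i] = "GC" + intron_seqs[i][2:]

    # Locus flanks: a poly-G spacer abuts each terminal exon.  Neither
    # primer carries a GG run near the insert, so no gapped or ungapped
    # extension of a read can score positively into the flank and amplicon
    # ends are recovered exactly.
    left = "".join(rng.choice(_BASES, size=flank - 12)) + "G" * 12
    right = "G" * 12 + "".join(rng.choice(_BASES, size=flank - 12))

    pieces = [left]
    pos = len(left)
    exons: list[Exon] = []
    variant_groups: dict[str, list[str]] = {}
    for i, es in enumerate(exon_seqs):
        start = pos
        pieces.append(es)
        pos += len(es)
        base = f"E{i + 1}"
        don = i not in noncanonical_donor_exons
        if i in alt_delta:
            delta = alt_delta[i]
            exons.append(Exon(f"{base}a", start, pos, donor_ok=don, acceptor_ok=True))
            exons.append(Exon(f"{base}b", start + delta, pos, donor_ok=don,
                              acceptor_ok=True))
            variant_groups[base] = [f"{base}a", f"{base}b"]
        else:
            exons.append(Exon(base, start, pos,
                              donor_ok=don if i < n_exons - 1 else None,
                              acceptor_ok=True if i > 0 else None))
        if i < n_exons - 1:
            pieces.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    pieces.append(right)
    locus = GeneLocus("toy_locus", "".join(pieces))
    catalog = ExonCatalog(sorted(exons, key=lambda e: (e.start, e.end)),
                          variant_groups)

    # Isoform repertoire: full-length first, then random distinct subsets.
    if n_isoforms is None:
        n_isoforms = min(2 ** (n_exons - 2), 8)
    by_index: list[list[str]] = []
    for i in range(n_exons):
        base = f"E{i + 1}"
        by_index.append(variant_groups.get(base, [base]))
    architectures: list[tuple[str, ...]] = []
    full = tuple(v[0] for v in by_index)
    architectures.append(full)
    attempts = 0
    while len(architectures) < n_isoforms and attempts < 1000 * n_isoforms:
        attempts += 1
        chain = [by_index[0][0]]
        for i in range(1, n_exons - 1):
            if rng.random() < 0.7:  # inclusion probability per internal exon
                chain.append(str(rng.choice(by_index[i])))
        chain.append(by_index[-1][0])
        arch = tuple(chain)
        if len(arch) >= 2 and arch not in architectures:
            architectures.append(arch)
    isoforms = [(f"iso{i + 1:02d}", arch) for i, arch in enumerate(architectures)]

    return SimulatedGene(locus, catalog, isoforms,
                         tuple(len(s) for s in intron_seqs))


def make_sample_sheet(n_samples: int, seed: int = 0,
                      barcode_length: int = 16,
                      metadata: list[dict] | None = None) -> SampleSheet:
    """Generate a sample sheet with mutually distant random barcodes
    (pairwise Hamming distance >= 8 on each side)."""
    rng = np.random.default_rng(seed)
    entries = []
    codes: list[str] = []

    def draw() -> str:
        while True:
            c = "".join(rng.choice(_BASES, size=barcode_length))
            if all(sum(a != b for a, b in zip(c, o)) >= 8 for o in codes):
                codes.append(c)
                return c

    for i in range(n_samples):
        meta = metadata[i] if metadata else {}
        entries.append(SampleEntry(f"S{i + 1}", draw(), draw(), meta))
    return SampleSheet(entries)


def _mutate(seq: str, rates: tuple[float, float, float],
            rng: np.random.Generator) -> tuple[str, int, int, int]:
    """Apply i.i.d. per-base substitutions and single-base indels."""
    p_sub, p_ins, p_del = rates
    if p_sub == p_ins == p_del == 0.0:
        return seq, 0, 0, 0
    out = []
    n_sub = n_ins = n_del = 0
    u = rng.random((len(seq), 3))
    for i, base in enumerate(seq):
        if u[i, 2] < p_del:
            n_del += 1
            continue
        if u[i, 0] < p_sub:
            base = str(rng.choice([b for b in "ACGT" if b != base]))
            n_sub += 1
        out.append(base)
        if u[i, 1] < p_ins:
            out.append(str(rng.choice(_BASES)))
            n_ins += 1
    if not out:
        out = [seq[0]]
    return "".join(out), n_sub, n_ins, n_del


def _sample_proportions(scenario: SimScenario, n_isoforms: int,
                        rng: np.random.Generator) -> np.ndarray:
    model = scenario.abundance_model
    if "dirichlet" in model:
        alpha = model["dirichlet"]
        alpha = np.full(n_isoforms, alpha) if np.isscalar(alpha) else np.asarray(alpha)
        return rng.dirichlet(alpha, size=scenario.n_samples)
    if "proportions" in model:
        p = np.asarray(model["proportions"], dtype=float)
    elif "counts" in model:
        c = np.asarray(model["counts"], dtype=float)
        p = c / c.sum(axis=1, keepdims=True)
    else:
        raise ValueError("abundance_model needs dirichlet/proportions/counts")
    if p.shape != (scenario.n_samples, n_isoforms):
        raise ValueError("abundance model dimension mismatch")
    return p


@dataclass
class SimResult:
    reads: list[ReadRecord]
    manifest: pd.DataFrame
    true_proportions: np.ndarray  # samples x isoforms
    scenario: SimScenario

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fastq(self.reads, out_dir / "reads.fastq")
        self.manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        with open(out_dir / "scenario.json", "w") as fh:
            json.dump(dataclasses.asdict(self.scenario), fh, indent=1, default=list)


def simulate_long_reads(gene: SimulatedGene, scenario: SimScenario,
                        sheet: SampleSheet) -> SimResult:
    """Emit barcoded full-length cDNA reads.

    Read layout: barcode_fwd + PRIMER_FWD + isoform cDNA + revcomp(PRIMER_REV)
    + revcomp(barcode_rev), mutated by the error model and emitted in random
    orientation.  Per-sample isoform counts are multinomial draws from the
    per-sample proportions (or exact under the "counts" abundance model).
    With ``truncation_prob`` > 0, a uniform prefix or suffix of the cDNA
    insert is removed before the adapters are attached (a deliberately
    simple stand-in for incomplete molecules, aimed at the terminal-exon
    filter).
    """
    if len(sheet) != scenario.n_samples:
        raise ValueError("sample sheet size differs from scenario.n_samples")
    rng = np.random.default_rng(scenario.seed)
    iso_names = gene.isoform_names
    iso_seqs = [gene.isoform_sequence(n) for n in iso_names]
    props = _sample_proportions(scenario, len(iso_names), rng)

    exact_counts = "counts" in scenario.abundance_model
    reads: list[ReadRecord] = []
    rows = []
    for si, entry in enumerate(sheet):
        if exact_counts:
            counts = np.asarray(scenario.abundance_model["counts"][si], dtype=int)
        else:
            counts = rng.multinomial(scenario.reads_per_sample, props[si])
        order = rng.permutation(np.repeat(np.arange(len(iso_names)), counts))
        for ri, iso_idx in enumerate(order):
            insert = iso_seqs[iso_idx]
            if scenario.truncation_prob and rng.random() < scenario.truncation_prob:
                cut = int(rng.integers(1, len(insert)))
                insert = insert[cut:] if rng.random() < 0.5 else insert[:cut]
            raw = (entry.barcode_fwd + PRIMER_FWD + insert
                   + revcomp(PRIMER_REV) + revcomp(entry.barcode_rev))
            seq, n_sub, n_ins, n_del = _mutate(raw, scenario.error_rates, rng)
            flipped = bool(rng.random() < 0.5)
            if flipped:
                seq = revcomp(seq)
            rid = f"{entry.sample_id}_r{ri:05d}"
            reads.append(ReadRecord(rid, seq))
            rows.append({"read_id": rid, "sample": entry.sample_id,
                         "isoform": iso_names[iso_idx], "n_sub": n_sub,
                         "n_ins": n_ins, "n_del": n_del,
                         "orientation": "reverse" if flipped else "forward"})
    manifest = pd.DataFrame(rows, columns=["read_id", "sample", "isoform",
                                           "n_sub", "n_ins", "n_del",
                                           "orientation"])
    return SimResult(reads, manifest, props, scenario)


@dataclass
class ShortReadResult:
    reads: list[ReadRecord]
    manifest: pd.DataFrame  # read_id, isoform, start, junctions, overhangs
    scenario: SimScenario

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fastq(self.reads, out_dir / "short_reads.fastq")
        self.manifest.to_csv(out_dir / "short_manifest.tsv", sep="\t", index=False)


def simulate_short_reads(gene: SimulatedGene,
                         scenario: SimScenario) -> ShortReadResult:
    """Draw short reads uniformly along abundance-weighted random isoforms.

    The manifest lists, per read, every exon-exon junction it truly spans
    together with its 5'/3' overhang lengths (semicolon-separated, aligned
    with the junction list).
    """
    rng = np.random.default_rng(scenario.seed + 1)
    iso_names = gene.isoform_names
    iso_seqs = [gene.isoform_sequence(n) for n in iso_names]
    L = scenario.short_read_length
    if L > min(len(s) for s in iso_seqs):
        raise ValueError("short_read_length exceeds the shortest isoform")
    props = _sample_proportions(scenario, len(iso_names), rng).mean(axis=0)

    # Junction offsets within each isoform (cumulative exon lengths).
    exon_len = {e.name: e.end - e.start for e in gene.true_exons.exons}
    junctions_of: list[list[tuple[str, int]]] = []
    for _, chain in gene.true_isoforms:
        offs, cum = [], 0
        for a, b in zip(chain, chain[1:]):
            cum += exon_len[a]
            offs.append((f"{a}-{b}", cum))
        junctions_of.append(offs)

    n_reads = scenario.short_reads_per_sample * scenario.n_samples
    iso_draw = rng.choice(len(iso_names), size=n_reads, p=props)
    reads, rows = [], []
    for i, iso_idx in enumerate(iso_draw):
        seq = iso_seqs[iso_idx]
        start = int(rng.integers(0, len(seq) - L + 1))
        frag = seq[start:start + L]
        frag, n_sub, n_ins, n_del = _mutate(frag, scenario.error_rates, rng)
        spans = [(j, p - start, start + L - p)
                 for j, p in junctions_of[iso_idx] if start < p < start + L]
        rid = f"sr{i:06d}"
        reads.append(ReadRecord(rid, frag))
        rows.append({"read_id": rid, "isoform": iso_names[iso_idx],
                     "start": start,
                     "junctions": ";".join(j for j, _, _ in spans),
                     "overhangs_5p": ";".join(str(a) for _, a, _ in spans),
                     "overhangs_3p": ";".join(str(b) for _, _, b in spans),
                     "n_sub": n_sub, "n_ins": n_ins, "n_del": n_del})
    manifest = pd.DataFrame(rows)
    return ShortReadResult(reads, manifest, scenario)
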