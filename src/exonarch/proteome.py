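"""Theoretical proteome prediction from transcript clusters.

The filter chain mirrors the standard ORF triage for a deep isoform
catalog: (i) enumerate candidate translation initiation sites, (ii) keep
ORFs of at least 300 nt, (iii) keep ORFs whose genomic TIS carries
ribosome-profiling evidence, (iv) collapse duplicated proteins, (v) remove
ORFs whose stop codon lies upstream of the last exon (premature
termination codons, assumed NMD substrates).  Retained isoforms are
digested in silico and peptides classified by how many isoforms they map
to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from .cluster import TranscriptCluster
from .exons import ExonCatalog

__all__ = [
    "OrfRecord",
    "ProteinIsoform",
    "find_orfs",
    "orfs_for_transcripts",
    "filter_by_tis",
    "drop_duplicates_and_ptc",
    "molecular_weights",
    "digest_and_map",
    "PROTEASES",
]

STOPS = {"TAA", "TAG", "TGA"}
DEFAULT_STARTS = ("ATG", "CTG", "GTG", "TTG")


@dataclass
class OrfRecord:
    transcript: str
    frame: int
    start_codon: str
    tx_start: int
    tx_end: int  # exclusive, includes the stop codon
    protein: str
    genomic_tis: int | None = None
    stop_exon: str | None = None

    @property
    def length_nt(self) -> int:
        return self.tx_end - self.tx_start


def find_orfs(sequence: str, start_codons: tuple[str, ...] = DEFAULT_STARTS,
              min_orf_nt: int = 300, policy: str = "longest_per_stop",
              transcript: str = "") -> list[OrfRecord]:
    """Enumerate ORFs in the three forward frames.

    An ORF runs from a start codon to the first in-frame stop, stop
    included in its length; the 300-nt minimum therefore counts the stop
    codon.  ``longest_per_stop`` keeps, per (frame, stop), only the most
    upstream qualifying start; ``all_starts`` keeps every qualifying start.
    Near-cognate starts are translated as methionine.
    """
    if policy not in ("longest_per_stop", "all_starts"):
        raise ValueError("policy must be longest_per_stop or all_starts")
    out: list[OrfRecord] = []
    n = len(sequence)
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = sequence[pos:pos + 3]
            if codon in STOPS:
                qualifying = [s for s in starts if pos + 3 - s >= min_orf_nt]
                chosen = qualifying[:1] if policy == "longest_per_stop" \
                    else qualifying
                for s in chosen:
                    prot = "M" + str(Seq(sequence[s + 3:pos]).translate())
                    out.append(OrfRecord(transcript, frame,
                                         sequence[s:s + 3], s, pos + 3, prot))
                starts = []
            elif codon in start_codons:
                starts.append(pos)
        # ORFs without an in-frame stop are not reported: the PTC rule
        # needs a stop position.
    out.sort(key=lambda o: (o.tx_start, o.frame))
    return out


def _tx_to_genomic(tx_pos: int, chain: list[tuple[str, int, int]]
                   ) -> tuple[int, str]:
    """Map a transcript coordinate through the exon chain; returns the
    locus coordinate and the exon name containing it."""
    cum = 0
    for name, start, end in chain:
        ln = end - start
        if tx_pos < cum + ln:
            return start + (tx_pos - cum), name
        cum += ln
    raise ValueError(f"transcript position {tx_pos} beyond exon chain")


def orfs_for_transcripts(clusters: list[TranscriptCluster],
                         catalog: ExonCatalog,
                         start_codons: tuple[str, ...] = DEFAULT_STARTS,
                         min_orf_nt: int = 300,
                         policy: str = "longest_per_stop") -> list[OrfRecord]:
    """Run find_orfs on every theoretical transcript and map each ORF's TIS
    and stop codon back to locus coordinates through the exon chain.

    A stop codon spanning an exon-exon junction is assigned to the exon
    containing its first base.
    """
    coords = {e.name: (e.start, e.end) for e in catalog.exons}
    out = []
    for cl in clusters:
        chain = [(n, *coords[n]) for n in cl.barcode.exon_names]
        for orf in find_orfs(cl.theoretical_sequence, start_codons,
                             min_orf_nt, policy, transcript=cl.name):
            orf.genomic_tis, _ = _tx_to_genomic(orf.tx_start, chain)
            _, orf.stop_exon = _tx_to_genomic(orf.tx_end - 3, chain)
            out.append(orf)
    return out


def filter_by_tis(orfs: list[OrfRecord], validated_tis: set[int]
                  ) -> tuple[list[OrfRecord], pd.DataFrame]:
    """Keep ORFs whose genomic TIS is in the validated set.

    An empty validated set drops everything and warns loudly — supplying
    no evidence is different from evidence validating nothing.
    """
    observed = sorted({o.genomic_tis for o in orfs})
    if not validated_tis:
        warnings.warn("validated TIS set is empty: all ORFs dropped; "
                      "omit the filter instead if no evidence is available",
                      stacklevel=2)
    kept = [o for o in orfs if o.genomic_tis in validated_tis]
    report = pd.DataFrame({
        "genomic_tis": observed,
        "validated": [t in validated_tis for t in observed],
        "n_orfs": [sum(o.genomic_tis == t for o in orfs) for t in observed],
    })
    return kept, report


@dataclass
class ProteinIsoform:
    isoform_id: str
    protein: str
    source_transcripts: list[str]
    source_orfs: list[OrfRecord] = field(default_factory=list)
    tis_validated: bool = True
    ptc_flag: bool = False
    mw_average_da: float | None = None
    mw_mono_da: float | None = None


def drop_duplicates_and_ptc(orfs: list[OrfRecord], catalog: ExonCatalog
                            ) -> tuple[list[ProteinIsoform], pd.DataFrame,
                                       int]:
    """Collapse identical proteins, then remove isoforms whose stop codon
    maps to any exon other than the catalog's last exon (PTC -> NMD).

    Returns (isoforms, removal log, count after deduplication).
    """
    groups: dict[str, list[OrfRecord]] = {}
    order: list[str] = []
    for o in orfs:
        if o.protein not in groups:
            groups[o.protein] = []
            order.append(o.protein)
        groups[o.protein].append(o)
    n_dedup = len(order)

    last_names = catalog.last_exon_names
    isoforms: list[ProteinIsoform] = []
    log_rows = []
    idx = 0
    for prot in order:
        members = groups[prot]
        sources = sorted({m.transcript for m in members})
        # conservative: the protein is PTC-flagged if any source ORF's stop
        # falls upstream of the catalog's last exon
        ptc = any(m.stop_exon not in last_names for m in members)
        if ptc:
            log_rows.append({"protein_prefix": prot[:20],
                             "source_transcripts": ",".join(sources),
                             "stop_exon": members[0].stop_exon,
                             "reason": "PTC"})
            continue
        idx += 1
        isoforms.append(ProteinIsoform(f"P-{idx}", prot, sources, members))
    log = pd.DataFrame(log_rows, columns=["protein_prefix",
                                          "source_transcripts", "stop_exon",
                                          "reason"])
    return isoforms, log, n_dedup


def molecular_weights(isoforms: list[ProteinIsoform]) -> list[ProteinIsoform]:
    """Average and monoisotopic protein masses in daltons (residue masses
    plus one water)."""
    for iso in isoforms:
        bad = [i for i, aa in enumerate(iso.protein)
               if aa not in "ACDEFGHIKLMNPQRSTVWY"]
        if bad:
            raise ValueError(f"{iso.isoform_id}: non-standard residue at "
                             f"position {bad[0]}")
        iso.mw_average_da = molecular_weight(iso.protein, seq_type="protein")
        iso.mw_mono_da = molecular_weight(iso.protein, seq_type="protein",
                                          monoisotopic=True)
    return isoforms


# P1 / P1' cleavage-site predicates.  cleave_after(P1, P1') -> bool.
def _trypsin(p1: str, p1p: str) -> bool:
    return p1 in "KR" and p1p != "P"


def _elastase(p1: str, p1p: str) -> bool:
    return p1 in "AVSGLI" and p1p != "P"


def _thermolysin(p1: str, p1p: str) -> bool:
    return p1p in "AFILMV" and p1 not in "DE"


def _papain(p1: str, p1p: str) -> bool:
    return p1 in "RK" and p1p != "P"


PROTEASES = {
    "trypsin": (_trypsin, "after K/R, not before P"),
    "elastase": (_elastase, "after A/V/S/G/L/I, not before P"),
    "thermolysin": (_thermolysin, "before A/F/I/L/M/V, not after D/E"),
    "papain": (_papain, "after K/R, not before P"),
}


def _cleave(protein: str, rule) -> list[tuple[int, str]]:
    """Fully cleaved fragments as (start, sequence)."""
    cuts = [0]
    for i in range(len(protein) - 1):
        if rule(protein[i], protein[i + 1]):
            cuts.append(i + 1)
    cuts.append(len(protein))
    return [(a, protein[a:b]) for a, b in zip(cuts, cuts[1:])]


def digest_and_map(isoforms: list[ProteinIsoform], protease: str = "trypsin",
                   missed_cleavages: int = 2,
                   len_range: tuple[int, int] = (7, 30),
                   observed_peptides: set[str] | None = None) -> pd.DataFrame:
    """In-silico digestion and isoform-discriminating peptide mapping.

    Peptides within ``len_range`` with up to ``missed_cleavages`` missed
    cleavage sites are emitted and classified by substring mapping across
    the isoform set: isoform-unique (one isoform), group-discriminating
    (a proper subset), shared (all isoforms).  With an observed-peptide
    list, rows gain an ``observed`` column; isoforms with observed
    isoform-unique peptides gain unique support (see
    :func:`isoforms_with_unique_support`).  Junction-spanning flags are
    added separately by :func:`map_junction_spanning`.
    """
    if protease not in PROTEASES:
        rules = {k: v[1] for k, v in PROTEASES.items()}
        raise ValueError(f"unsupported protease {protease!r}; "
                         f"supported: {rules}")
    rule = PROTEASES[protease][0]
    n_iso = len(isoforms)
    rows = []
    for iso in isoforms:
        frags = _cleave(iso.protein, rule)
        for i in range(len(frags)):
            for m in range(missed_cleavages + 1):
                if i + m >= len(frags):
                    break
                start = frags[i][0]
                pep = "".join(f[1] for f in frags[i:i + m + 1])
                if not (len_range[0] <= len(pep) <= len_range[1]):
                    continue
                rows.append({"isoform_id": iso.isoform_id, "peptide": pep,
                             "start_aa": start, "missed": m})
    table = pd.DataFrame(rows,
                         columns=["isoform_id", "peptide", "start_aa",
                                  "missed"]).drop_duplicates(
        ["isoform_id", "peptide", "start_aa"])

    # substring mapping across the whole isoform set
    proteins = {iso.isoform_id: iso.protein for iso in isoforms}
    pep_map: dict[str, frozenset[str]] = {}
    for pep in table["peptide"].unique():
        pep_map[pep] = frozenset(i for i, p in proteins.items() if pep in p)

    def classify(pep: str) -> str:
        k = len(pep_map[pep])
        if k == 1:
            return "isoform_unique"
        if k == n_iso:
            return "shared"
        return "group_discriminating"

    table["n_isoforms"] = table["peptide"].map(lambda p: len(pep_map[p]))
    table["uniqueness"] = table["peptide"].map(classify)

    if observed_peptides is not None:
        obs = {p.upper() for p in observed_peptides}
        table["observed"] = table["peptide"].isin(obs)
    return table


def map_junction_spanning(table: pd.DataFrame,
                          isoforms: list[ProteinIsoform],
                          clusters: list[TranscriptCluster],
                          catalog: ExonCatalog) -> pd.DataFrame:
    """Add a junction_spanning flag: true when the peptide's coding span
    crosses an exon-exon junction in any source transcript of its
    isoform."""
    coords = {e.name: (e.start, e.end) for e in catalog.exons}
    chains = {cl.name: cl.barcode.exon_names for cl in clusters}
    by_id = {iso.isoform_id: iso for iso in isoforms}

    junction_offsets: dict[str, list[int]] = {}
    for t, chain in chains.items():
        offs, cum = [], 0
        for name in chain[:-1]:
            cum += coords[name][1] - coords[name][0]
            offs.append(cum)
        junction_offsets[t] = offs

    def flag(row) -> bool:
        iso = by_id[row["isoform_id"]]
        for orf in iso.source_orfs:
            nt0 = orf.tx_start + 3 * row["start_aa"]
            nt1 = nt0 + 3 * len(row["peptide"])
            for off in junction_offsets.get(orf.transcript, ()):
                if nt0 < off < nt1:
                    return True
        return False

    table = table.copy()
    table["junction_spanning"] = [flag(row) for _, row in table.iterrows()]
    return table


def isoforms_with_unique_support(table: pd.DataFrame) -> list[str]:
    """Isoform ids gaining unique support from observed isoform-unique
    peptides (requires an ``observed`` column)."""
    if "observed" not in table.columns:
        raise ValueError("table has no observed-peptide column")
    mask = (table["uniqueness"] == "isoform_unique") & table["observed"]
    return sorted(table.loc[mask, "isoform_id"].unique())
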