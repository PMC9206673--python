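"""Reference study conditions: canned simulation scenarios with the
metrics used to judge end-to-end recovery.

The default long-read scenario mirrors a targeted multiplexed amplicon
run: a 14-exon gene with one alternative-acceptor group, 12 isoforms,
4 barcoded samples of 500 reads, 1% substitutions and 0.5% indels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .junctions import build_junction_reference, count_short_read_support, \
    min_unique_overhangs
from .pipeline import PipelineResult, run_pipeline
from .simulate import SimScenario, SimulatedGene, build_toy_gene, \
    make_sample_sheet, simulate_long_reads, simulate_short_reads


@dataclass
class RecoveryReport:
    gene: SimulatedGene
    result: PipelineResult
    catalog_exact: bool
    n_exons_true: int
    n_exons_recovered: int
    n_isoforms_true: int
    n_isoforms_recovered: int
    n_false_barcodes_over2: int
    spearman_per_sample: list[float]

    @property
    def spearman_min(self) -> float:
        return min(self.spearman_per_sample)


def _recovery(gene: SimulatedGene, sim, sheet, res: PipelineResult
              ) -> RecoveryReport:
    tcoord = {e.name: (e.start, e.end) for e in gene.true_exons.exons}
    coord = {e.name: (e.start, e.end) for e in res.catalog.exons}
    got_cat = [(e.start, e.end) for e in res.catalog.exons]
    want_cat = [(e.start, e.end) for e in gene.true_exons.exons]
    rec = {tuple(coord[n] for n in c.barcode.exon_names): c
           for c in res.clusters}
    true = {tuple(tcoord[n] for n in chain): name
            for name, chain in gene.true_isoforms}
    false_over2 = sum(1 for k, c in rec.items()
                      if k not in true and c.total_count > 2)
    iso_names = gene.isoform_names
    realized = sim.manifest.groupby(["sample", "isoform"]).size()
    rhos = []
    for s in [e.sample_id for e in sheet]:
        want = np.array([realized.get((s, n), 0) for n in iso_names],
                        dtype=float)
        got = np.zeros(len(iso_names))
        for k, c in rec.items():
            if k in true:
                got[iso_names.index(true[k])] = c.per_sample_counts.get(s, 0)
        rhos.append(float(spearmanr(want, got).statistic))
    return RecoveryReport(gene, res, got_cat == want_cat, len(want_cat),
                          len(got_cat), len(true), len(set(rec) & set(true)),
                          false_over2, rhos)


def run_reference_scenario(seed: int = 1) -> tuple[RecoveryReport, object]:
    """The default PacBio-like study: 14 exons (one alternative-acceptor
    group), 12 isoforms, 4 samples x 500 reads, 1% / 0.5% errors."""
    gene = build_toy_gene(14, {7}, seed=seed, n_isoforms=12)
    sheet = make_sample_sheet(4, seed=seed + 100)
    scenario = SimScenario(n_samples=4, reads_per_sample=500,
                           error_rates=(0.01, 0.0025, 0.0025), seed=seed + 7)
    sim = simulate_long_reads(gene, scenario, sheet)
    res = run_pipeline(gene.locus, sim.reads, sheet,
                       validated_tis={gene.true_exons.exons[0].start})
    return _recovery(gene, sim, sheet, res), sim


def run_ont_scenario(seed: int = 1, truncation_prob: float = 0.0):
    """ONT-like study: 3 isoforms at exact true counts {120, 15, 6} in one
    sample, same error rates, ONT filters (terminal exons, >= 10 reads)."""
    gene = build_toy_gene(6, set(), seed=seed + 1, n_isoforms=3)
    sheet = make_sample_sheet(1, seed=seed + 200)
    scenario = SimScenario(n_samples=1,
                           abundance_model={"counts": [[120, 15, 6]]},
                           error_rates=(0.01, 0.0025, 0.0025),
                           seed=seed + 17, truncation_prob=truncation_prob)
    sim = simulate_long_reads(gene, scenario, sheet)
    res = run_pipeline(gene.locus, sim.reads, sheet, mode="ont")
    return gene, sim, res


def run_junction_scenario(seed: int = 1):
    """Zero-error long+short reads on a 6-exon gene without acceptor
    variants; returns measured and manifest-expected per-junction
    short-read support."""
    gene = build_toy_gene(6, set(), seed=seed + 2, n_isoforms=4)
    sheet = make_sample_sheet(2, seed=seed + 300)
    scenario = SimScenario(n_samples=2, reads_per_sample=60,
                           error_rates=(0.0, 0.0, 0.0), seed=seed + 23,
                           short_reads_per_sample=1500, short_read_length=100)
    sim = simulate_long_reads(gene, scenario, sheet)
    short = simulate_short_reads(gene, scenario)
    res = run_pipeline(gene.locus, sim.reads, sheet, short_reads=short.reads)

    seqs = {e.name: gene.locus.sequence[e.start:e.end]
            for e in res.catalog.exons}
    per, (ga, gb) = min_unique_overhangs(res.junctions, seqs)
    o5, o3 = max(9, ga), max(6, gb)
    records = build_junction_reference(res.junctions, seqs, o5, o3)
    counts = count_short_read_support(short.reads, records, junction_point=o5,
                                      min_overlap=15, per_side_min=per)
    expected = {j.junction_id: 0 for j in res.junctions}
    below_threshold_counted = 0
    for row in short.manifest.itertuples():
        if not row.junctions:
            continue
        for jid, a, b in zip(row.junctions.split(";"),
                             str(row.overhangs_5p).split(";"),
                             str(row.overhangs_3p).split(";")):
            if jid not in expected:
                continue
            a_min, b_min = per[jid]
            x, y = min(int(a), o5), min(int(b), o3)
            if x >= a_min and y >= b_min and x + y >= 15:
                expected[jid] += 1
    return gene, res, counts, expected


def run_gc_donor_scenario(seed: int = 1):
    """Zero-noise run on a gene carrying one injected GC (non-canonical)
    donor; the affected exon must be excluded with a logged reason."""
    gene = build_toy_gene(6, set(), seed=seed + 3, n_isoforms=4,
                          noncanonical_donor_exons={2})
    sheet = make_sample_sheet(1, seed=seed + 400)
    scenario = SimScenario(n_samples=1, reads_per_sample=40,
                           error_rates=(0.0, 0.0, 0.0), seed=seed + 31)
    sim = simulate_long_reads(gene, scenario, sheet)
    res = run_pipeline(gene.locus, sim.reads, sheet)
    return gene, res
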