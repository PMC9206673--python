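import numpy as np
import pytest

from exonarch.cluster import ArchitectureBarcode, TranscriptCluster
from exonarch.junctions import (build_junction_reference,
                                count_short_read_support, enumerate_junctions,
                                min_unique_overhangs, query_junction_report)
from oracles import min_overhangs_exhaustive


def _cluster(name, exons, n):
    return TranscriptCluster(name, ArchitectureBarcode(tuple(exons)), "",
                             [f"{name}.{i}" for i in range(n)], {"S1": n})


def test_enumeration_and_long_read_counts():
    clusters = [_cluster("T-1", ["A", "B", "C"], 12),
                _cluster("T-2", ["A", "C"], 25)]
    js = enumerate_junctions(clusters)
    by_id = {j.junction_id: j for j in js}
    assert set(by_id) == {"A-B", "B-C", "A-C"}
    assert by_id["A-C"].supporting_transcripts == ["T-2"]
    assert by_id["A-C"].long_read_count == 25
    assert by_id["A-B"].long_read_count == 12


def test_supporting_transcript_multiplicity():
    clusters = [_cluster(f"T-{i}", ["A", "B"] + (["C"] if i % 2 else []), 1)
                for i in range(1, 7)]
    js = enumerate_junctions(clusters)
    ab = next(j for j in js if j.junction_id == "A-B")
    assert len(ab.supporting_transcripts) == 6


def test_min_overhangs_match_exhaustive_oracle():
    rng = np.random.default_rng(5)
    for trial in range(100):
        n = int(rng.integers(3, 6))
        seqs = {f"E{i}": "".join(rng.choice(list("ACGT"),
                                            int(rng.integers(20, 60))))
                for i in range(n)}
        pairs = sorted({(f"E{a}", f"E{b}")
                        for a, b in rng.integers(0, n, (4, 2)) if a < b})
        if not pairs:
            continue
        clusters = [_cluster(f"T-{i}", list(p), 1)
                    for i, p in enumerate(pairs)]
        js = enumerate_junctions(clusters)
        per, (ga, gb) = min_unique_overhangs(js, seqs)
        oracle = min_overhangs_exhaustive(
            [(j.donor_exon, j.acceptor_exon) for j in js], seqs)
        for j in js:
            want = oracle[(j.donor_exon, j.acceptor_exon)]
            if want is not None:
                assert per[j.junction_id] == want, (trial, j.junction_id)
                assert j.discriminable
        discr = [per[j.junction_id] for j in js if j.discriminable]
        assert ga == max(a for a, _ in discr)
        assert gb == max(b for _, b in discr)


def test_single_junction_minimal_and_shared_acceptor_forced_donor():
    seqs = {"A": "ACCTACCTTG", "B": "TTGACCAGCA", "C": "CATTACGGAT"}
    js = enumerate_junctions([_cluster("T-1", ["A", "B"], 1)])
    per, _ = min_unique_overhangs(js, seqs)
    a, b = per["A-B"]
    s = seqs["A"][-a:] + seqs["B"][:b]
    assert not any(s in e for e in seqs.values())
    # shared acceptor: donor side must discriminate, so a >= 1 always holds
    js2 = enumerate_junctions([_cluster("T-1", ["A", "C"], 1),
                               _cluster("T-2", ["B", "C"], 1)])
    per2, _ = min_unique_overhangs(js2, seqs)
    assert all(a >= 1 for a, _ in per2.values())


def test_identical_boundary_junctions_non_discriminable(clean_run):
    """Acceptor variants share their donor boundary, so the two junctions
    from that shared donor into the next exon are sequence-identical and
    must be flagged non-discriminable; junctions into the two variant
    acceptors differ and stay discriminable."""
    res = clean_run["res"]
    catalog = res.catalog
    seqs = {e.name: clean_run["gene"].locus.sequence[e.start:e.end]
            for e in catalog.exons}
    base, (long_v, short_v) = next(iter(catalog.variant_groups.items()))
    end = catalog.by_name(long_v).end
    nxt = next(e.name for e in catalog.exons if e.start > end)
    clusters = [_cluster("T-1", ["E1", long_v, nxt], 1),
                _cluster("T-2", ["E1", short_v, nxt], 1)]
    js = enumerate_junctions(clusters)
    min_unique_overhangs(js, seqs)
    flags = {j.junction_id: j.discriminable for j in js}
    assert flags[f"{long_v}-{nxt}"] is False
    assert flags[f"{short_v}-{nxt}"] is False
    assert flags[f"E1-{long_v}"] is True
    assert flags[f"E1-{short_v}"] is True


def test_reference_records_and_truncation_flag():
    seqs = {"A": "ACGTACGTACGT", "B": "TGCA", "C": "GGCCGGCCGGCC"}
    clusters = [_cluster("T-1", ["A", "B"], 1), _cluster("T-2", ["A", "C"], 1)]
    js = enumerate_junctions(clusters)
    recs = build_junction_reference(js, seqs, overhang_5p=9, overhang_3p=6)
    assert len(recs) == len(js)
    by_id = {r[0]: r for r in recs}
    assert by_id["A-C"][1] == seqs["A"][-9:] + seqs["C"][:6]
    assert len(by_id["A-C"][1]) == 15
    assert by_id["A-C"][2] is False
    assert by_id["A-B"][2] is True  # B shorter than the 3' overhang


def test_junction_sequence_occurs_iff_adjacent_in_barcode(clean_run):
    res = clean_run["res"]
    seqs = {e.name: clean_run["gene"].locus.sequence[e.start:e.end]
            for e in res.catalog.exons}
    per, (ga, gb) = min_unique_overhangs(res.junctions, seqs)
    o5 = max(9, ga)
    o3 = max(6, gb)
    recs = {r[0]: r[1] for r in
            build_junction_reference(res.junctions, seqs, o5, o3)}
    for j in res.junctions:
        if not j.discriminable:
            continue
        s = recs[j.junction_id]
        for cl in res.clusters:
            names = cl.barcode.exon_names
            adjacent = (j.donor_exon, j.acceptor_exon) in zip(names, names[1:])
            assert (s in cl.theoretical_sequence) == adjacent, j.junction_id


def test_short_read_support_thresholds():
    seqs = {"A": "ACCTACCTTGACCTACCTTG", "B": "TTGACCAGCATTGACCAGCA"}
    clusters = [_cluster("T-1", ["A", "B"], 1)]
    js = enumerate_junctions(clusters)
    recs = build_junction_reference(js, seqs, 9, 6)

    spanning = seqs["A"][-10:] + seqs["B"][:10]  # overhangs (10, 10)
    low_3p = seqs["A"][-12:] + seqs["B"][:3]     # 3' overhang 3 < min 6
    counts = count_short_read_support(
        [spanning, low_3p], recs, junction_point=9, min_overlap=15,
        per_side_min={"A-B": (9, 6)})
    assert counts["A-B"] == 1

    short_total = seqs["A"][-8:] + seqs["B"][:6]  # total 14 < 15
    counts = count_short_read_support(
        [short_total], recs, junction_point=9, min_overlap=15,
        per_side_min={"A-B": (1, 1)})
    assert counts["A-B"] == 0


def test_zero_error_support_equals_manifest(clean_run):
    """Dual route: string-matching support counts equal the arithmetic
    expectation from the simulator's junction manifest."""
    res = clean_run["res"]
    gene = clean_run["gene"]
    short = clean_run["short"]
    seqs = {e.name: gene.locus.sequence[e.start:e.end]
            for e in res.catalog.exons}
    per, (ga, gb) = min_unique_overhangs(res.junctions, seqs)
    o5, o3 = max(9, ga), max(6, gb)
    recs = build_junction_reference(res.junctions, seqs, o5, o3)
    counts = count_short_read_support(short.reads, recs, junction_point=o5,
                                      min_overlap=15, per_side_min=per)
    # expectation from the manifest (true spanning reads and overhangs)
    expected = {j.junction_id: 0 for j in res.junctions}
    twins = {j.junction_id for j in res.junctions if not j.discriminable}
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
    for jid in expected:
        if jid in twins:
            continue  # sequence-identical junction pair: counts pool
        assert counts[jid] == expected[jid], jid


def test_query_report(clean_run):
    res = clean_run["res"]
    js = res.junctions
    present = (js[0].donor_exon, js[0].acceptor_exon)
    rep = query_junction_report(js, [present, ("E1", "ZZ")], res.matrix)
    assert rep.loc[0, "present"]
    assert not rep.loc[1, "present"]
    assert rep.loc[0, "pct_of_total_expression"] > 0
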