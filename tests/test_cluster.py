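import numpy as np
import pytest

from exonarch.cluster import (AnnotatedRead, AnnotationParams,
                              ArchitectureBarcode, annotate_exons,
                              cluster_and_name, qc_against_theoretical,
                              theoretical_sequence)
from exonarch._dp import global_free_ends, smith_waterman
from exonarch.exons import exon_sequences
from oracles import nw_free_identity, sw_score


@pytest.fixture(scope="module")
def annotation_setup(small_gene):
    catalog = small_gene.true_exons
    seqs = exon_sequences(catalog, small_gene.locus)
    return catalog, seqs


def test_exact_concatenation_barcode(annotation_setup, small_gene):
    catalog, seqs = annotation_setup
    name, chain = small_gene.true_isoforms[0]
    bc, hits, reason = annotate_exons(small_gene.isoform_sequence(name),
                                      seqs, catalog)
    assert reason is None
    assert bc.exon_names == chain
    assert bc.canonical_string == "|".join(chain)


def test_skipping_detected(annotation_setup):
    catalog, seqs = annotation_setup
    first = catalog.exons[0].name
    last = catalog.exons[-1].name
    read = seqs[first] + seqs[last]
    bc, _, reason = annotate_exons(read, seqs, catalog)
    assert reason is None
    assert bc.exon_names == (first, last)


def test_variant_suffix_discrimination(annotation_setup):
    """A read carrying the long acceptor variant reports only it (higher
    score); a read carrying the short variant reports only the short one
    (better coverage at equal score)."""
    catalog, seqs = annotation_setup
    base, (long_name, short_name) = next(iter(catalog.variant_groups.items()))
    assert seqs[long_name].endswith(seqs[short_name])
    first = catalog.exons[0].name
    for variant in (long_name, short_name):
        read = seqs[first] + seqs[variant]
        bc, hits, reason = annotate_exons(read, seqs, catalog)
        assert reason is None
        assert bc.exon_names == (first, variant)
    # oracle check of the +1/-2 scores driving the long-variant call
    read = seqs[first] + seqs[long_name]
    h = {r["exon"]: r["score"] for _, r in
         annotate_exons(read, seqs, catalog)[1].iterrows()}
    assert h[long_name] == sw_score(seqs[long_name], read)
    assert h[short_name] == sw_score(seqs[short_name], read)
    assert h[long_name] > h[short_name]


def test_qc_select_variants_corrects_wrong_member(annotation_setup, small_gene):
    """A read built on one acceptor variant keeps / regains that variant
    even when annotation proposed the other: the wrong variant's
    theoretical transcript costs the acceptor extension as a gap."""
    from exonarch.cluster import qc_select_variants

    catalog, seqs = annotation_setup
    base, (long_v, short_v) = next(iter(catalog.variant_groups.items()))
    first = catalog.exons[0].name
    for true_v, wrong_v in ((long_v, short_v), (short_v, long_v)):
        read = seqs[first] + seqs[true_v]
        wrong = ArchitectureBarcode((first, wrong_v))
        bc, keep, ident = qc_select_variants(read, wrong, catalog, seqs)
        assert bc.exon_names == (first, true_v)
        assert keep and ident == 1.0


def test_no_architecture_and_non_colinear(annotation_setup):
    catalog, seqs = annotation_setup
    rng = np.random.default_rng(3)
    junk = "".join(rng.choice(list("ACGT"), 300))
    bc, _, reason = annotate_exons(junk, seqs, catalog)
    assert bc is None and reason == "no_architecture"
    names = [catalog.exons[0].name, catalog.exons[-1].name]
    scrambled = seqs[names[1]] + seqs[names[0]]  # genomic order violated
    bc, _, reason = annotate_exons(scrambled, seqs, catalog)
    assert bc is None and reason == "non_colinear"


def test_local_scores_match_brute_force_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(100):
        q = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 40))))
        t = "".join(rng.choice(list("ACGT"), int(rng.integers(20, 80))))
        if rng.random() < 0.5:  # plant a mutated copy
            pos = int(rng.integers(0, len(t) - 5))
            ins = list(q)
            for k in rng.choice(len(ins), size=min(2, len(ins)), replace=False):
                ins[k] = str(rng.choice(list("ACGT")))
            t = t[:pos] + "".join(ins) + t[pos:]
        assert smith_waterman(t, q)["score"] == sw_score(q, t)


def test_qc_identity_matches_nw_oracle_random_instances():
    rng = np.random.default_rng(7)
    p = AnnotationParams(qc_band_pad=None)
    for _ in range(100):
        theo = "".join(rng.choice(list("ACGT"), int(rng.integers(40, 90))))
        read = list(theo)
        for k in rng.choice(len(read), size=int(rng.integers(0, 6)),
                            replace=False):
            read[k] = str(rng.choice(list("ACGT")))
        read = "".join(read)
        got = global_free_ends(theo, read)
        want_score, want_ident = nw_free_identity(theo, read)
        assert got["score"] == want_score
        assert got["identity"] == pytest.approx(want_ident)


def test_qc_identical_and_adapter_tails(annotation_setup, small_gene):
    catalog, seqs = annotation_setup
    name, chain = small_gene.true_isoforms[0]
    bc = ArchitectureBarcode(chain)
    theo = theoretical_sequence(bc, seqs)
    keep, ident = qc_against_theoretical(theo, bc, seqs)
    assert keep and ident == 1.0
    tailed = "ACGTACGTACGTACGTACGT" + theo + "TTTTGGGGCCCCAAAATTTT"
    keep, ident = qc_against_theoretical(tailed, bc, seqs)
    assert keep and ident == 1.0  # free end gaps absorb the adapters


def test_qc_scrambled_interior_dropped(annotation_setup, small_gene):
    catalog, seqs = annotation_setup
    name, chain = small_gene.true_isoforms[0]
    bc = ArchitectureBarcode(chain)
    theo = theoretical_sequence(bc, seqs)
    rng = np.random.default_rng(0)
    mid = list(theo)
    lo, hi = len(mid) // 3, 2 * len(mid) // 3
    scram = rng.permutation(list(mid[lo:hi]))
    read = "".join(mid[:lo]) + "".join(scram) + "".join(mid[hi:])
    keep, ident = qc_against_theoretical(read, bc, seqs)
    assert ident < 0.85 and not keep


def _annotated(reads_spec):
    out = []
    i = 0
    for barcode, sample, n in reads_spec:
        for _ in range(n):
            out.append(AnnotatedRead(f"r{i}", sample,
                                     ArchitectureBarcode(tuple(barcode)),
                                     None, 1.0, True))
            i += 1
    return out


def test_ont_min10_and_terminal_filters(annotation_setup):
    catalog, seqs = annotation_setup
    first = catalog.exons[0].name
    last = catalog.exons[-1].name
    mid = catalog.exons[2].name
    reads = _annotated([((first, mid, last), "S1", 12),
                        ((first, last), "S1", 9),
                        ((mid, last), "S1", 50)])  # lacks the first exon
    clusters, log = cluster_and_name(reads, seqs, catalog, mode="ont")
    assert [c.barcode.exon_names for c in clusters] == [(first, mid, last)]
    reasons = log.reason.value_counts().to_dict()
    assert reasons["missing_terminal_exon"] == 50
    assert reasons["cluster_below_min_reads"] == 9


def test_pacbio_keeps_all_and_ranks(annotation_setup):
    catalog, seqs = annotation_setup
    first = catalog.exons[0].name
    last = catalog.exons[-1].name
    mid = catalog.exons[2].name
    reads = _annotated([((first, mid, last), "S1", 12),
                        ((first, last), "S2", 9)])
    clusters, log = cluster_and_name(reads, seqs, catalog, mode="pacbio")
    assert [c.name for c in clusters] == ["T-1", "T-2"]
    assert clusters[0].total_count == 12
    assert clusters[0].per_sample_counts == {"S1": 12}
    assert clusters[1].per_sample_counts == {"S2": 9}
    assert clusters[0].theoretical_sequence == \
        seqs[first] + seqs[mid] + seqs[last]
    assert log.empty


def test_cluster_counts_partition_and_determinism(annotation_setup):
    catalog, seqs = annotation_setup
    first = catalog.exons[0].name
    last = catalog.exons[-1].name
    reads = _annotated([((first, last), "S1", 5),
                        ((first, catalog.exons[1].name, last), "S2", 5)])
    c1, l1 = cluster_and_name(reads, seqs, catalog)
    c2, l2 = cluster_and_name(reads, seqs, catalog)
    assert [c.name for c in c1] == [c.name for c in c2]
    assert [c.barcode.canonical_string for c in c1] == \
        [c.barcode.canonical_string for c in c2]
    assert sum(c.total_count for c in c1) + len(l1) == len(reads)
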