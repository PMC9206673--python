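import numpy as np
import pytest

from exonarch.proteome import (DEFAULT_STARTS, digest_and_map,
                               drop_duplicates_and_ptc, filter_by_tis,
                               find_orfs, isoforms_with_unique_support,
                               map_junction_spanning, molecular_weights,
                               orfs_for_transcripts, ProteinIsoform)
from oracles import enumerate_orfs, protein_mass, tryptic_peptides


def test_minimal_orf_at_300nt_boundary():
    seq = "ATG" + "AAA" * 99 + "TAA"  # 303 nt
    orfs = find_orfs(seq, start_codons=("ATG",))
    assert len(orfs) == 1
    assert orfs[0].protein == "M" + "K" * 99
    assert orfs[0].length_nt == 303

    exact = "ATG" + "AAA" * 98 + "TAA"  # 300 nt: retained
    assert len(find_orfs(exact, start_codons=("ATG",))) == 1
    short = "ATG" + "AAA" * 97 + "TAA"  # 297 nt: rejected
    assert find_orfs(short, start_codons=("ATG",)) == []


def test_longest_per_stop_keeps_most_upstream_start():
    seq = "ATG" + "CCC" * 3 + "ATG" + "AAA" * 99 + "TAA"
    orfs = find_orfs(seq, start_codons=("ATG",), min_orf_nt=300)
    assert len(orfs) == 1
    assert orfs[0].tx_start == 0
    both = find_orfs(seq, start_codons=("ATG",), min_orf_nt=300,
                     policy="all_starts")
    assert [o.tx_start for o in both] == [0, 12]


def test_find_orfs_matches_brute_force_random():
    rng = np.random.default_rng(0)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), 700))
        for policy, lps in (("longest_per_stop", True), ("all_starts", False)):
            got = [(o.tx_start, o.tx_end)
                   for o in find_orfs(seq, min_orf_nt=120, policy=policy)]
            want = enumerate_orfs(seq, DEFAULT_STARTS, min_nt=120,
                                  longest_per_stop=lps)
            assert sorted(got) == sorted(want)


def test_tis_filter_and_empty_set_warns(clean_run):
    res = clean_run["res"]
    orfs = orfs_for_transcripts(res.clusters, res.catalog)
    assert orfs, "expected ORFs in the coding toy gene"
    observed = {o.genomic_tis for o in orfs}
    kept, report = filter_by_tis(orfs, observed)
    assert len(kept) == len(orfs)  # validating everything is the identity
    one = next(iter(observed))
    kept1, report1 = filter_by_tis(orfs, {one})
    assert all(o.genomic_tis == one for o in kept1)
    assert report1.loc[report1.genomic_tis == one, "validated"].all()
    with pytest.warns(UserWarning, match="empty"):
        kept0, _ = filter_by_tis(orfs, set())
    assert kept0 == []


def test_genomic_tis_maps_through_exon_chain(clean_run):
    res = clean_run["res"]
    gene = clean_run["gene"]
    coords = {e.name: (e.start, e.end) for e in res.catalog.exons}
    for orf in orfs_for_transcripts(res.clusters, res.catalog):
        cl = next(c for c in res.clusters if c.name == orf.transcript)
        cum = 0
        for n in cl.barcode.exon_names:
            s, e = coords[n]
            if orf.tx_start < cum + (e - s):
                assert orf.genomic_tis == s + orf.tx_start - cum
                break
            cum += e - s
        # the locus codon at the TIS equals the transcript's start codon
        # only when the codon does not span a junction; check via sequence
        assert cl.theoretical_sequence[orf.tx_start:orf.tx_start + 3] == \
            orf.start_codon


def test_dedup_collapses_and_ptc_removes(clean_run):
    res = clean_run["res"]
    catalog = res.catalog
    orfs = orfs_for_transcripts(res.clusters, catalog)
    isoforms, log, n_dedup = drop_duplicates_and_ptc(orfs, catalog)
    assert len({i.protein for i in isoforms}) == len(isoforms)
    assert n_dedup <= len(orfs)
    assert len(isoforms) <= n_dedup
    last = catalog.last_exon_names
    for iso in isoforms:
        assert not iso.ptc_flag
        assert all(o.stop_exon in last for o in iso.source_orfs)
    if not log.empty:
        assert (log.reason == "PTC").all()


def test_duplicate_protein_merges_sources():
    from exonarch.proteome import OrfRecord
    from exonarch.exons import Exon, ExonCatalog

    cat = ExonCatalog([Exon("E1", 0, 10, None, True),
                       Exon("E2", 30, 40, True, None)])
    a = OrfRecord("T-1", 0, "ATG", 0, 12, "MKL", stop_exon="E2")
    b = OrfRecord("T-2", 0, "ATG", 0, 12, "MKL", stop_exon="E2")
    c = OrfRecord("T-3", 0, "ATG", 0, 12, "MQQ", stop_exon="E1")  # PTC
    isoforms, log, n_dedup = drop_duplicates_and_ptc([a, b, c], cat)
    assert n_dedup == 2
    assert len(isoforms) == 1
    assert isoforms[0].source_transcripts == ["T-1", "T-2"]
    assert list(log.reason) == ["PTC"]


def test_molecular_weights_match_residue_table():
    rng = np.random.default_rng(1)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    isoforms = [ProteinIsoform(f"P-{i}",
                               "".join(rng.choice(aas,
                                                  int(rng.integers(5, 80)))),
                               ["T"])
                for i in range(100)]
    molecular_weights(isoforms)
    for iso in isoforms:
        assert iso.mw_average_da == pytest.approx(
            protein_mass(iso.protein), rel=2e-4)
        assert iso.mw_mono_da == pytest.approx(
            protein_mass(iso.protein, monoisotopic=True), rel=2e-5)
    # additivity: mass(AB) = mass(A) + mass(B) - water
    a, b = isoforms[0].protein, isoforms[1].protein
    ab = ProteinIsoform("P-x", a + b, ["T"])
    molecular_weights([ab])
    assert ab.mw_average_da == pytest.approx(
        isoforms[0].mw_average_da + isoforms[1].mw_average_da - 18.0153,
        abs=0.01)


def test_molecular_weight_rejects_nonstandard():
    with pytest.raises(ValueError, match="position"):
        molecular_weights([ProteinIsoform("P-1", "MKX", ["T"])])


def test_trypsin_rule_and_pyteomics_oracle():
    frags = tryptic_peptides("MKRAAAK")
    assert frags == ["MK", "R", "AAAK"]
    table = digest_and_map([ProteinIsoform("P-1", "MKRAAAK", ["T"])],
                           missed_cleavages=0, len_range=(1, 50))
    assert set(table.peptide) == {"MK", "R", "AAAK"}
    # independent oracle: pyteomics cleavage on random proteins
    from pyteomics import parser as pparser
    rng = np.random.default_rng(2)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(30):
        prot = "".join(rng.choice(aas, 60))
        mine = set()
        t = digest_and_map([ProteinIsoform("P-1", prot, ["T"])],
                           missed_cleavages=2, len_range=(1, 60))
        mine = set(t.peptide)
        # the K/R-not-before-P rule, evaluated by pyteomics' cleaver
        ref = pparser.cleave(prot, r"[KR](?=[^P])",
                             missed_cleavages=2, min_length=1)
        assert mine == set(ref)


def test_unsupported_protease_lists_rules():
    with pytest.raises(ValueError, match="thermolysin"):
        digest_and_map([ProteinIsoform("P-1", "MKR", ["T"])],
                       protease="pepsinX")


def test_peptide_classes_partition_and_pigeonhole():
    iso = [ProteinIsoform("P-1", "MKRAAAKLLLKWWWK", ["T1"]),
           ProteinIsoform("P-2", "MKRAAAKLLLKYYYK", ["T2"]),
           ProteinIsoform("P-3", "MKRAAAKLLLKWWWK" + "QQQK", ["T3"])]
    t = digest_and_map(iso, missed_cleavages=1, len_range=(2, 30))
    assert set(t.uniqueness) <= {"isoform_unique", "group_discriminating",
                                 "shared"}
    n = t.peptide.map(lambda p: t.loc[t.peptide == p, "n_isoforms"].iloc[0])
    assert ((t.uniqueness == "shared") == (t.n_isoforms == 3)).all()
    assert ((t.uniqueness == "isoform_unique") == (t.n_isoforms == 1)).all()
    # identical isoform set duplicated: nothing is isoform-unique
    dup = [ProteinIsoform("P-1", "MKRAAAKLLLK", ["T1"]),
           ProteinIsoform("P-2", "MKRAAAKLLLK", ["T2"])]
    t2 = digest_and_map(dup, missed_cleavages=1, len_range=(2, 30))
    assert not (t2.uniqueness == "isoform_unique").any()


def test_isoform_unique_peptides_exist_for_exon_differences(clean_run):
    """Isoforms differing by an internal exon expose at least one
    isoform-unique peptide over that exon (exhaustive mapping)."""
    res = clean_run["res"]
    isoforms, _, _ = drop_duplicates_and_ptc(
        orfs_for_transcripts(res.clusters, res.catalog), res.catalog)
    if len(isoforms) < 2:
        pytest.skip("toy run yielded fewer than 2 isoforms")
    t = digest_and_map(isoforms, len_range=(7, 45))
    uniq = t[t.uniqueness == "isoform_unique"]
    assert not uniq.empty
    # brute-force check of the mapping classes
    prots = {i.isoform_id: i.protein for i in isoforms}
    for row in uniq.head(20).itertuples():
        hits = [k for k, p in prots.items() if row.peptide in p]
        assert hits == [row.isoform_id]


def test_junction_spanning_flags(clean_run):
    res = clean_run["res"]
    isoforms, _, _ = drop_duplicates_and_ptc(
        orfs_for_transcripts(res.clusters, res.catalog), res.catalog)
    if not isoforms:
        pytest.skip("no isoforms")
    t = digest_and_map(isoforms, len_range=(7, 45))
    t = map_junction_spanning(t, isoforms, res.clusters, res.catalog)
    coords = {e.name: (e.start, e.end) for e in res.catalog.exons}
    chains = {c.name: c.barcode.exon_names for c in res.clusters}
    by_id = {i.isoform_id: i for i in isoforms}
    for row in t.head(40).itertuples():
        iso = by_id[row.isoform_id]
        spans = False
        for orf in iso.source_orfs:
            nt0 = orf.tx_start + 3 * row.start_aa
            nt1 = nt0 + 3 * len(row.peptide)
            cum = 0
            for n in chains[orf.transcript][:-1]:
                s, e = coords[n]
                cum += e - s
                if nt0 < cum < nt1:
                    spans = True
        assert row.junction_spanning == spans


def test_observed_peptides_report(clean_run):
    res = clean_run["res"]
    isoforms, _, _ = drop_duplicates_and_ptc(
        orfs_for_transcripts(res.clusters, res.catalog), res.catalog)
    t = digest_and_map(isoforms, len_range=(7, 45))
    uniq = t[t.uniqueness == "isoform_unique"]
    if uniq.empty:
        pytest.skip("no unique peptides in toy set")
    pick = uniq.iloc[0]
    t2 = digest_and_map(isoforms, len_range=(7, 45),
                        observed_peptides={pick.peptide})
    assert isoforms_with_unique_support(t2) == [pick.isoform_id]


def test_filter_chain_monotonicity(clean_run):
    res = clean_run["res"]
    orfs = orfs_for_transcripts(res.clusters, res.catalog)
    observed = {o.genomic_tis for o in orfs}
    sub = set(list(observed)[:max(1, len(observed) // 2)])
    kept, _ = filter_by_tis(orfs, sub)
    isoforms, _, n_dedup = drop_duplicates_and_ptc(kept, res.catalog)
    assert len(orfs) >= len(kept) >= n_dedup >= len(isoforms)
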