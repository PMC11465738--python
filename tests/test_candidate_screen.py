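"""Unit and property tests for the candidate-selection cascade."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from caminer.candidate_screen import (
    AMINO_ACIDS,
    DomainHit,
    ProteinRecord,
    ReferentialIntegrityError,
    SampleMetadata,
    ScreenConfig,
    SimilarityHit,
    check_gene_boundaries,
    compile_report,
    dedup_candidates,
    filter_reference_by_keywords,
    filter_samples_by_environment,
    pairwise_identity,
    scan_motifs,
    select_scap_hits,
    select_similarity_hits,
    selected_ids,
)
from caminer.synthetic_data import make_screen_fixture

# ---------------------------------------------------------------------------
# keyword filtering (fnr reference construction)


@pytest.mark.parametrize(
    "title, kept",
    [
        ("putative carbonic anhydrase [organism]", True),
        ("Carbonic Anhydrase II", True),
        ("carbonic dehydratase, partial", True),
        ("calcium-binding protein", False),  # token "calcium" != "ca"
        ("Ca channel subunit", True),  # whole token matches case-insensitively
        ("carbonic acid transporter", False),  # phrase must appear contiguously
        ("anhydrase, carbonic", False),
        ("CA", True),
    ],
)
def test_keyword_filter(title, kept):
    idx = filter_reference_by_keywords(
        [title], ["carbonic anhydrase", "carbonic dehydratase", "ca"]
    )
    assert (idx == [0]) == kept


def test_keyword_filter_requires_keywords():
    with pytest.raises(ValueError):
        filter_reference_by_keywords(["anything"], [])


# ---------------------------------------------------------------------------
# branch selection


def _dhit(pid, acc, ev=1e-10):
    return DomainHit(protein_id=pid, profile_accession=acc, profile_name="x",
                     i_evalue=ev, bit_score=100.0, env_from=1, env_to=50)


def test_scap_branch_membership(default_config):
    hits = [_dhit("a", "PF00484.21"), _dhit("b", "PF99999.1")]
    assert select_scap_hits(hits, default_config) == {"a"}
    assert select_scap_hits([], default_config) == set()


def test_scap_branch_ignores_evalue(default_config):
    # membership alone counts: even a weak hit against a SCAP profile passes
    assert select_scap_hits([_dhit("a", "PF00194.23", ev=10.0)], default_config) == {"a"}


@pytest.mark.parametrize(
    "evalue, kept",
    [(1e-50, True), (1e-49, False), (0.0, True), (9.99e-51, True)],
)
def test_similarity_evalue_boundary_is_inclusive(default_config, evalue, kept):
    hit = SimilarityHit(query_id="q", subject_id="s", evalue=evalue, pct_identity=50.0)
    got = select_similarity_hits([hit], default_config)
    assert (got == {"q"}) == kept


def test_similarity_rejects_negative_evalue():
    with pytest.raises(ValueError):
        SimilarityHit(query_id="q", subject_id="s", evalue=-1.0, pct_identity=50.0)


# ---------------------------------------------------------------------------
# motif scanning


def brute_force_motif_scan(sequence, pattern):
    """Independent sliding-window oracle for motif positions (1-based)."""
    w = len(pattern)
    hits = []
    for s in range(len(sequence) - w + 1):
        ok = True
        for pc, rc in zip(pattern, sequence[s:s + w]):
            if pc == "x":
                if rc not in AMINO_ACIDS:
                    ok = False
                    break
            elif rc != pc:
                ok = False
                break
        if ok:
            hits.append(s + 1)
    return hits


@pytest.mark.parametrize(
    "seq, pattern, expected",
    [
        ("CADARHAAC", "CxDxR", [1]),
        ("CADARHAAC", "HxxC", [6]),
        ("AAAAA", "CxDxR", []),
        ("CCDCRCDER", "CxDxR", [1]),
        ("CCDDRR", "CxDxR", [1, 2]),  # overlapping matches both reported
        ("HAACHAAC", "HxxC", [1, 5]),
    ],
)
def test_scan_motifs_examples(seq, pattern, expected):
    assert scan_motifs(seq, [pattern])[pattern] == expected
    assert brute_force_motif_scan(seq, pattern) == expected


def test_scan_motifs_empty_sequence_errors():
    with pytest.raises(ValueError):
        scan_motifs("", ["CxDxR"])


def test_scan_motifs_wildcard_excludes_nonstandard():
    # X (unknown residue) is not matched by the wildcard
    assert scan_motifs("CXDXR", ["CxDxR"])["CxDxR"] == []


@settings(derandomize=True, max_examples=300)
@given(
    seq=st_.text(alphabet=AMINO_ACIDS, min_size=1, max_size=50),
    pattern=st_.sampled_from(["CxDxR", "HxxC", "CC", "HxH"]),
)
def test_scan_motifs_matches_brute_force(seq, pattern):
    assert scan_motifs(seq, [pattern])[pattern] == brute_force_motif_scan(seq, pattern)


def test_scan_motifs_brute_force_bulk(rng):
    """Agreement with the oracle on 1,000 random sequences of length <= 50."""
    for _ in range(1000):
        n = int(rng.integers(5, 51))
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))
        for pattern in ("CxDxR", "HxxC"):
            assert scan_motifs(seq, [pattern])[pattern] == brute_force_motif_scan(seq, pattern)


# ---------------------------------------------------------------------------
# gene boundaries


@pytest.mark.parametrize(
    "gene, expected",
    [
        ("ATGAAATAA", (True, True)),
        ("GTGAAATAG", (True, True)),
        ("TTGAAATGA", (True, True)),
        ("CCCAAACCC", (False, False)),
        ("ATGAAACCC", (True, False)),
        ("CCCAAATAA", (False, True)),
    ],
)
def test_gene_boundaries(gene, expected):
    assert check_gene_boundaries(gene) == expected


def test_gene_boundaries_rejects_short_and_bad_chars():
    with pytest.raises(ValueError):
        check_gene_boundaries("ATGTT")
    with pytest.raises(ValueError):
        check_gene_boundaries("ATGAAUTAA")
    with pytest.raises(ValueError):
        check_gene_boundaries("ATGANATAA")  # N rejected unless tolerated


def test_gene_boundaries_tolerates_n_as_failure():
    assert check_gene_boundaries("NTGAAATAN", allow_n=True) == (False, False)
    assert check_gene_boundaries("ATGANATAA", allow_n=True) == (True, True)


# ---------------------------------------------------------------------------
# pairwise identity


def exhaustive_alignment_identities(a, b):
    """All (score, identity%) over every global alignment of a and b.

    Scoring: match +1, mismatch 0, linear gap -1; identity over alignment
    length including gaps. Exponential enumeration — tiny strings only.
    """
    results = []

    def rec(i, j, score, ident, length):
        if i == len(a) and j == len(b):
            results.append((score, 100.0 * ident / length if length else 100.0))
            return
        if i < len(a) and j < len(b):
            m = a[i] == b[j]
            rec(i + 1, j + 1, score + (1 if m else 0), ident + (1 if m else 0), length + 1)
        if i < len(a):
            rec(i + 1, j, score - 1, ident, length + 1)
        if j < len(b):
            rec(i, j + 1, score - 1, ident, length + 1)

    rec(0, 0, 0, 0, 0)
    return results


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("ACDE", "ACDE", 100.0),
        ("ACDE", "ACDF", 75.0),
        ("AAAA", "CCCC", 0.0),
    ],
)
def test_pairwise_identity_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)


@settings(derandomize=True, max_examples=200)
@given(
    a=st_.text(alphabet="ACDE", min_size=1, max_size=5),
    b=st_.text(alphabet="ACDE", min_size=1, max_size=5),
)
def test_pairwise_identity_optimal_and_symmetric(a, b):
    got = pairwise_identity(a, b)
    assert got == pairwise_identity(b, a)
    alignments = exhaustive_alignment_identities(a, b)
    best = max(s for s, _ in alignments)
    identities_at_best = {round(i, 9) for s, i in alignments if s == best}
    assert round(got, 9) in identities_at_best


def test_pairwise_identity_rejects_empty():
    with pytest.raises(ValueError):
        pairwise_identity("", "ACD")


# ---------------------------------------------------------------------------
# de-duplication


def _prot(pid, seq, sample="s1", gene=None):
    return ProteinRecord(id=pid, sequence=seq, gene_nt=gene, sample_id=sample)


def test_dedup_identical_plus_unrelated():
    prots = [_prot("a", "ACDEFGHIKL"), _prot("b", "ACDEFGHIKL"), _prot("c", "WWWWWWWWWW")]
    reps = dedup_candidates(prots, 90.0)
    assert len(reps) == 2
    assert "c" in reps and "a" in reps  # tie broken by id: a before b


def test_dedup_exact_cutoff_is_inclusive():
    # 9/10 identical columns = exactly 90%
    a = "ACDEFGHIKL"
    b = "ACDEFGHIKW"
    assert pairwise_identity(a, b) == pytest.approx(90.0)
    reps = dedup_candidates([_prot("a", a), _prot("b", b)], 90.0)
    assert reps == ["a"]


def test_dedup_output_pairs_below_cutoff(rng):
    # all-pairs identity oracle over the returned representatives
    prots = []
    base = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 40))
    for k in range(8):
        seq = list(base)
        for p in rng.integers(0, 40, k):  # k mutations
            seq[p] = AMINO_ACIDS[(AMINO_ACIDS.index(seq[p]) + 1) % 20]
        prots.append(_prot(f"p{k}", "".join(seq)))
    cutoff = 90.0
    kept = dedup_candidates(prots, cutoff)
    seqs = {p.id: p.sequence for p in prots}
    for x, y in itertools.combinations(kept, 2):
        assert pairwise_identity(seqs[x], seqs[y]) < cutoff


# ---------------------------------------------------------------------------
# environment filter


@pytest.mark.parametrize(
    "temp, ph, kept",
    [(90.0, 9.0, True), (89.9, 9.0, False), (95.0, 6.5, False), (90.0, 7.0, False)],
)
def test_environment_filter_boundaries(temp, ph, kept):
    cfg = ScreenConfig(min_temperature=90.0, require_alkaline=True)
    meta = [SampleMetadata("s", temp, ph)]
    assert (filter_samples_by_environment(meta, cfg) == {"s"}) == kept


def test_environment_filter_no_alkaline_requirement():
    cfg = ScreenConfig(min_temperature=80.0, require_alkaline=False)
    meta = [SampleMetadata("s", 85.0, 6.0)]
    assert filter_samples_by_environment(meta, cfg) == {"s"}


# ---------------------------------------------------------------------------
# full cascade


def test_cascade_recovers_planted_truth(default_config):
    fixture = make_screen_fixture(12, 4, seed=7, config=default_config)
    reports = compile_report(*fixture.cascade_inputs(), config=default_config)
    assert selected_ids(reports) == fixture.truth
    assert len(fixture.truth) == 4


def test_cascade_rejects_cold_sample(default_config):
    fixture = make_screen_fixture(6, 2, seed=3, config=default_config)
    pid = sorted(fixture.truth)[0]
    # move the positive's sample to 25 degrees C
    meta = [
        SampleMetadata(m.sample_id, 25.0, m.pH, m.description)
        for m in fixture.metadata
    ]
    reports = compile_report(fixture.proteins, fixture.domain_table,
                             fixture.similarity_table, fixture.sp_tm_flags, meta,
                             default_config)
    rep = next(r for r in reports if r.protein_id == pid)
    assert not rep.selected
    assert any("environment" in reason for reason in rep.reasons)


def test_cascade_dedups_near_identical_positives(default_config):
    fixture = make_screen_fixture(8, 2, seed=11, config=default_config)
    a, b = sorted(fixture.truth)
    prot_a = next(p for p in fixture.proteins if p.id == a)
    # clone a's sequence onto b (with 2 mutations): identity ~99%
    seq = list(prot_a.sequence)
    seq[0] = "A" if seq[0] != "A" else "C"
    clone = ProteinRecord(id=b, sequence="".join(seq), gene_nt=prot_a.gene_nt,
                          sample_id=prot_a.sample_id)
    proteins = [clone if p.id == b else p for p in fixture.proteins]
    # b needs its own evidence; reuse fixture tables (b already has evidence)
    reports = compile_report(proteins, fixture.domain_table, fixture.similarity_table,
                             fixture.sp_tm_flags, fixture.metadata, default_config)
    sel = selected_ids(reports)
    assert len(sel & {a, b}) == 1
    loser = ({a, b} - sel).pop()
    rep = next(r for r in reports if r.protein_id == loser)
    assert not rep.cluster_representative


def test_cascade_branch_disjointness(default_config):
    fixture = make_screen_fixture(16, 6, seed=2, config=default_config)
    reports = compile_report(*fixture.cascade_inputs(), config=default_config)
    scap_hits = select_scap_hits(fixture.domain_table, default_config)
    for r in reports:
        if r.branch == "fnr":
            assert r.protein_id not in scap_hits


def test_cascade_row_order_invariance(default_config):
    fixture = make_screen_fixture(10, 3, seed=5, config=default_config)
    reports_fwd = compile_report(*fixture.cascade_inputs(), config=default_config)
    reports_rev = compile_report(
        list(reversed(fixture.proteins)),
        list(reversed(fixture.domain_table)),
        list(reversed(fixture.similarity_table)),
        fixture.sp_tm_flags,
        list(reversed(fixture.metadata)),
        default_config,
    )
    assert reports_fwd == reports_rev


def test_cascade_referential_integrity(default_config):
    fixture = make_screen_fixture(6, 2, seed=1, config=default_config)
    bad = fixture.domain_table + [_dhit("ghost", "PF00484.21")]
    with pytest.raises(ReferentialIntegrityError):
        compile_report(fixture.proteins, bad, fixture.similarity_table,
                       fixture.sp_tm_flags, fixture.metadata, default_config)


def test_cascade_sp_tm_reject_policy(default_config):
    cfg = ScreenConfig(sp_tm_policy="reject")
    fixture = make_screen_fixture(8, 3, seed=9, config=cfg)
    pid = sorted(fixture.truth)[0]
    flags = dict(fixture.sp_tm_flags)
    flags[pid] = True
    reports = compile_report(fixture.proteins, fixture.domain_table,
                             fixture.similarity_table, flags, fixture.metadata, cfg)
    rep = next(r for r in reports if r.protein_id == pid)
    assert rep.sp_or_tm and not rep.selected
    # under the default flag-only policy the same protein stays selected
    reports2 = compile_report(fixture.proteins, fixture.domain_table,
                              fixture.similarity_table, flags, fixture.metadata,
                              default_config)
    rep2 = next(r for r in reports2 if r.protein_id == pid)
    assert rep2.sp_or_tm and rep2.selected


def test_selected_implies_representative_and_env(default_config):
    fixture = make_screen_fixture(14, 5, seed=13, config=default_config)
    for r in compile_report(*fixture.cascade_inputs(), config=default_config):
        if r.selected:
            assert r.cluster_representative and r.env_ok
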