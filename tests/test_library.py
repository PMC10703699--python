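"""Guide library design: PAM scanning, off-target filter, NT generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sortscreen import (
    NON_TARGETING,
    GuideLibrary,
    GuideRecord,
    design_tiling_library,
    filter_off_target,
    generate_nt_guides,
    scan_candidate_guides,
    validate_library,
)
from sortscreen.library import IUPAC, pam_adjacent_windows, revcomp

from .conftest import random_dna


# ---------------------------------------------------------------- oracles
def brute_force_scan(seq, window, pam, L, anchor=0):
    """Position-by-position scan of both strands against the IUPAC pattern."""
    seq = seq.upper()
    hits = []
    w0, w1 = anchor + window[0], anchor + window[1]

    def ok(s, pat):
        return len(s) == len(pat) and all(
            c in IUPAC[p] for c, p in zip(s, pat)
        )

    for i in range(len(seq)):
        # forward
        if w0 <= i and i + L <= w1 and ok(seq[i + L : i + L + 6], pam):
            sp = seq[i : i + L]
            if set(sp) <= set("ACGT"):
                hits.append((i, "+", sp, seq[i + L : i + L + 6]))
        # reverse: PAM complement 5' of the spacer on the forward strand
        if w0 <= i and i + L <= w1 and i >= 6:
            pam_fwd = seq[i - 6 : i]
            sp_fwd = seq[i : i + L]
            if ok(revcomp(pam_fwd), pam) and set(sp_fwd) <= set("ACGT"):
                hits.append((i, "-", revcomp(sp_fwd), revcomp(pam_fwd)))
    return sorted(hits)


def brute_force_offtarget_keep(candidates, background, max_mm, pam):
    """Hamming distance at every PAM-adjacent window, both strands."""
    kept = []
    for rec in candidates:
        L = len(rec.spacer)
        n_close = n_exact = 0
        for site in pam_adjacent_windows(background, pam, L):
            if set(site) - set("ACGT"):
                continue
            d = sum(a != b for a, b in zip(rec.spacer, site))
            n_close += d < max_mm
            n_exact += d == 0
        if n_close - min(n_exact, 1) == 0:
            kept.append(rec.guide_id)
    return kept


# ------------------------------------------------------------------ scan
def test_scan_no_pam_no_guides():
    seq = "AC" * 25  # no NNGRRT on either strand
    assert scan_candidate_guides(seq, (0, 50), "NNGRRT", 21) == []


def test_scan_single_hand_placed_pam():
    seq = "A" * 21 + "AAGAGT" + "A" * 10
    out = scan_candidate_guides(seq, (0, len(seq)), "NNGRRT", 21)
    fwd = [r for r in out if r.strand == "+"]
    assert len(fwd) == 1
    assert fwd[0].spacer == "A" * 21
    assert fwd[0].pam == "AAGAGT"
    assert (fwd[0].start, fwd[0].end) == (0, 21)
    # brute force confirms the reverse strand contributes nothing extra
    oracle = brute_force_scan(seq, (0, len(seq)), "NNGRRT", 21)
    assert len(out) == len(oracle)


@pytest.mark.parametrize("pam", ["NNGRRT", "NNGRRN"])
def test_scan_matches_exhaustive_oracle_random_sequence(pam):
    rng = np.random.default_rng(11)
    seq = random_dna(rng, 500)
    out = scan_candidate_guides(seq, (0, 500), pam, 21)
    got = sorted((r.start, r.strand, r.spacer, r.pam) for r in out)
    assert got == brute_force_scan(seq, (0, 500), pam, 21)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(60, 240))
def test_scan_oracle_property(seed, n):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, n)
    out = scan_candidate_guides(seq, (0, n), "NNGRRN", 21)
    got = sorted((r.start, r.strand, r.spacer, r.pam) for r in out)
    assert got == brute_force_scan(seq, (0, n), "NNGRRN", 21)


def test_scan_window_outside_sequence_errors():
    with pytest.raises(ValueError, match="length"):
        scan_candidate_guides("ACGT" * 10, (-5, 30), "NNGRRT", 21)


def test_scan_ambiguous_bases_yield_no_candidates():
    seq = "N" * 21 + "AAGAGT" + "A" * 10
    out = scan_candidate_guides(seq, (0, len(seq)), "NNGRRT", 21)
    assert all("N" not in r.spacer for r in out)


# ------------------------------------------------------------ off-target
def _cands_from(seq, pam="NNGRRT"):
    return scan_candidate_guides(seq, (0, len(seq)), pam, 21)


def test_filter_design_locus_only_keeps_all():
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 200)
    cands = _cands_from(seq)
    assert cands, "fixture needs at least one candidate"
    kept = filter_off_target(cands, [seq])
    assert [r.guide_id for r in kept] == [r.guide_id for r in cands]


def test_filter_exact_second_copy_removed():
    rng = np.random.default_rng(6)
    seq = random_dna(rng, 200)
    cands = _cands_from(seq)
    victim = cands[0]
    decoy = random_dna(rng, 40) + victim.spacer + victim.pam + random_dna(rng, 40)
    kept = filter_off_target(cands, [seq, decoy])
    ids = {r.guide_id for r in kept}
    assert victim.guide_id not in ids
    # others with no copy in the decoy survive
    survivors = brute_force_offtarget_keep(cands, [seq, decoy], 4, "NNGRRT")
    assert sorted(ids) == sorted(survivors)

def test_filter_matches_hamming_oracle_2kb_background():
    rng = np.random.default_rng(7)
    seq = random_dna(rng, 300)
    bg = [seq, random_dna(rng, 2000)]
    cands = _cands_from(seq)
    kept = filter_off_target(cands, bg)
    assert sorted(r.guide_id for r in kept) == sorted(
        brute_force_offtarget_keep(cands, bg, 4, "NNGRRT")
    )


def test_filter_monotone_in_background():
    rng = np.random.default_rng(8)
    seq = random_dna(rng, 300)
    cands = _cands_from(seq)
    small = {r.guide_id for r in filter_off_target(cands, [seq])}
    big = {
        r.guide_id
        for r in filter_off_target(cands, [seq, random_dna(rng, 3000)])
    }
    assert big <= small


def test_filter_empty_background_errors():
    with pytest.raises(ValueError, match="background"):
        filter_off_target(_cands_from("A" * 21 + "AAGAGT" + "A" * 6), [])


# ------------------------------------------------------------------- NT
def test_nt_degenerate_two_letter_composition():
    # pooled frequencies put all mass on A and C; the G-only background
    # has no PAM sites so nothing collides
    out = generate_nt_guides(
        ["A" * 10 + "C" * 11] * 5, 10, ["G" * 100], seed=0
    )
    assert len(out) == 10
    assert all(set(r.spacer) <= {"A", "C"} for r in out)
    assert all(r.target_gene == NON_TARGETING for r in out)
    assert len({r.spacer for r in out}) == 10  # no duplicates emitted


def test_nt_composition_matches_pool():
    rng = np.random.default_rng(3)
    targeting = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(100)]
    out = generate_nt_guides(targeting, 120, ["ACGT"], seed=7)
    pooled = "".join(r.spacer for r in out)
    for base in "ACGT":
        assert pooled.count(base) / len(pooled) == pytest.approx(0.25, abs=0.03)


def test_nt_survives_its_own_background_filter():
    rng = np.random.default_rng(4)
    bg = [random_dna(rng, 1500)]
    targeting = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(50)]
    nts = generate_nt_guides(targeting, 20, bg, seed=9)
    sites = pam_adjacent_windows(bg, "NNGRRT", 21)
    for rec in nts:
        assert all(
            sum(a != b for a, b in zip(rec.spacer, s)) >= 4 for s in sites
        )


def test_nt_invalid_n_errors():
    with pytest.raises(ValueError):
        generate_nt_guides(["A" * 21], 0, ["ACGT"], seed=0)


def test_nt_unreachable_errors_with_draw_count():
    # background saturated with every near-A window -> all-A pool can't win
    with pytest.raises(RuntimeError, match="draws"):
        generate_nt_guides(
            ["A" * 21] * 3, 2, ["A" * 21 + "AAGAGT"], seed=0, max_draws=50
        )


# ---------------------------------------------------------------- design
def test_design_one_gene_one_pam():
    rng = np.random.default_rng(44)
    seq = random_dna(rng, 20) + "ACGTTGCAATGGCAATCGGAT" + "AAGAGT" + random_dna(rng, 20)
    anchor = len(seq) // 2
    lib = design_tiling_library(
        {"G1": (seq, anchor)},
        window=(-anchor, len(seq) - anchor),
        n_nt=5,
        seed=0,
    )
    audit = validate_library(lib)
    assert audit.n_nt == 5
    assert audit.n_targeting >= 1
    assert audit.n_total == audit.n_nt + audit.n_targeting


def test_design_gene_without_pam_reported_untargeted():
    rng = np.random.default_rng(45)
    ok_seq = "ACGTTGCAATGGCAATCGGAT" + "AAGAGT" + random_dna(rng, 53)
    lib = design_tiling_library(
        {"NOPAM": ("AC" * 40, 40), "OK": (ok_seq, 40)},
        window=(-40, 40),
        n_nt=3,
        seed=0,
    )
    assert "NOPAM" in lib.untargeted_genes
    assert "OK" not in lib.untargeted_genes
    assert "NOPAM" in validate_library(lib).untargeted_genes


def test_design_totals_match_composed_oracles():
    rng = np.random.default_rng(12)
    genes = {f"G{i}": (random_dna(rng, 240), 120) for i in range(5)}
    bg = [s for s, _ in genes.values()] + [random_dna(rng, 1000)]
    lib = design_tiling_library(genes, window=(-120, 120), background=bg,
                                n_nt=10, seed=1)
    expected = 0
    for g, (seq, anchor) in genes.items():
        cands = scan_candidate_guides(seq, (-120, 120), "NNGRRT", 21,
                                      anchor=anchor, gene=g)
        expected += len(brute_force_offtarget_keep(cands, bg, 4, "NNGRRT"))
    # duplicate spacers across genes may be dropped (keep-first)
    audit = validate_library(lib)
    assert audit.n_targeting <= expected
    assert expected - audit.n_targeting <= 2
    assert audit.n_total == audit.n_targeting + 10


def test_design_duplicate_gene_names_error():
    with pytest.raises(ValueError, match="duplicate"):
        design_tiling_library(
            [("G1", "ACGT" * 30, 60), ("G1", "TGCA" * 30, 60)],
            window=(-10, 10), n_nt=2, seed=0,
        )


# ----------------------------------------------------------------- audit
def test_audit_small_library(tiny_library):
    audit = validate_library(tiny_library)
    assert audit.n_total == 5
    assert audit.n_nt == 2
    assert audit.n_targeting == 3
    assert audit.n_genes_targeted == 2
    assert audit.mean_guides_per_gene == 1.5
    assert audit.min_guides_per_gene == 1


def test_audit_empty_library():
    audit = validate_library(GuideLibrary([]))
    assert audit.n_total == audit.n_nt == audit.n_targeting == 0


def test_audit_invariant_after_tsv_round_trip(tiny_library, tmp_path):
    path = tmp_path / "lib.tsv"
    tiny_library.to_tsv(path)
    back = GuideLibrary.from_tsv(path)
    audit = validate_library(back)
    assert audit.n_total == audit.n_nt + audit.n_targeting == 5
    # coordinates survive the 1-based export round trip
    orig = {r.guide_id: (r.start, r.end, r.strand) for r in tiny_library}
    for rec in back:
        assert (rec.start, rec.end, rec.strand) == orig[rec.guide_id]


def test_duplicate_spacer_dropped_with_warning():
    a = GuideRecord("a", "ACGT" * 5 + "A", target_gene="G1")
    b = GuideRecord("b", "ACGT" * 5 + "A", target_gene="G2")
    with pytest.warns(UserWarning, match="duplicate spacer"):
        lib = GuideLibrary([a, b])
    assert [r.guide_id for r in lib] == ["a"]
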