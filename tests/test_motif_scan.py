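import numpy as np
import pytest

from gisland._seq import expand_pattern, reverse_complement
from gisland.motif_scan import (
    Amplicon, ReferenceProtein, heme_motif_census, insilico_pcr, scan_pattern,
    screen_cytochrome_candidates,
)
from conftest import random_dna, random_protein
from oracles import brute_pattern_positions

DNAA = "TT(C|A)TCCAC(A|G)"


def test_dnaa_box_pattern_matching():
    assert len(scan_pattern("TTATCCACG", DNAA, both_strands=False)) == 1
    assert scan_pattern("TTGTCCACG", DNAA, both_strands=False) == []


def test_invalid_pattern_characters_rejected():
    with pytest.raises(ValueError):
        scan_pattern("ACGT", "AC?T")
    with pytest.raises(ValueError):
        scan_pattern("ACGT", "A(CG|T)A")


def test_strand_symmetry_of_hits(rng):
    s = random_dna(rng, 2000)
    fwd = {h.position for h in scan_pattern(s, DNAA) if h.strand == "+"}
    rc = reverse_complement(s)
    minus_on_rc = {len(s) - h.position - 9
                   for h in scan_pattern(rc, DNAA) if h.strand == "-"}
    assert fwd == minus_on_rc


def test_circular_scan_finds_origin_spanning_match():
    box = "TTATCCACG"
    s = box[4:] + random_dna(np.random.default_rng(0), 50) + box[:4]
    hits = scan_pattern(s, DNAA, both_strands=False, circular=True)
    assert any(h.position == len(s) - 4 for h in hits)
    assert scan_pattern(s, DNAA, both_strands=False, circular=False) == []


@pytest.mark.parametrize("pattern", [DNAA, "GATC", "CCWGG", "GGNNCC"])
def test_scan_agrees_with_positional_oracle(rng, pattern):
    s = random_dna(rng, 10_000)
    bases = expand_pattern(pattern)
    expect_fwd = brute_pattern_positions(s, bases)
    expect_rev = [len(s) - p - len(bases)
                  for p in brute_pattern_positions(reverse_complement(s), bases)]
    hits = scan_pattern(s, pattern)
    assert sorted(h.position for h in hits if h.strand == "+") == sorted(expect_fwd)
    assert sorted(h.position for h in hits if h.strand == "-") == sorted(expect_rev)
    for h in hits:
        sl = s[h.position : h.position + len(bases)]
        assert h.matched_text == (sl if h.strand == "+" else reverse_complement(sl))


@pytest.mark.parametrize("aa,count", [
    ("MACAACHG", 1),
    ("CAACHXXCAACH", 2),
    ("CCACHH", 1),
    ("MKLVNN", 0),
])
def test_heme_census_counts(aa, count):
    census = heme_motif_census([("p", aa)])
    got = census[0].motif_count if census else 0
    assert got == count


def test_heme_census_overlapping_motifs_counted_each():
    # CxxCH overlapping with a second start two residues later
    aa = "CAACHACH"  # motifs at 0 (CAACH) and 3 (CHACH)
    assert heme_motif_census([("p", aa)])[0].motif_count == 2


def test_heme_count_stable_under_motif_free_extension(rng):
    aa = "CAACH" * 3
    pad = "".join(np.array(list("ADEFGIKLMNPQRSTVWY"))[rng.choice(18, 40)])
    before = heme_motif_census([("p", aa)])[0].motif_count
    after = heme_motif_census([("p", aa + pad)])[0].motif_count
    assert before == after == 3


def test_multiheme_classification_above_ten_motifs():
    from gisland.motif_scan import census_report

    aa = "GG".join(["CAACH"] * 11)
    df = census_report(heme_motif_census([("p", aa)]))
    assert df.loc[0, "motif_count"] == 11
    assert bool(df.loc[0, "multiheme_gt10"])


def test_cytochrome_screen_fraction_rule(rng):
    cand = random_protein(rng, 300)
    refs = [ReferenceProtein(f"R{i}", cand, i < 3) for i in range(4)]
    census = heme_motif_census([("q", "CAACH" + cand)])
    out = screen_cytochrome_candidates(census, {"q": "CAACH" + cand}, refs)
    assert out[0].status == "retained"        # 3 of 4 hits labelled: 0.75
    assert out[0].annotated_fraction == pytest.approx(0.75)

    refs_none = [ReferenceProtein(f"R{i}", cand, False) for i in range(5)]
    out = screen_cytochrome_candidates(census, {"q": "CAACH" + cand}, refs_none)
    assert out[0].status == "rejected"        # 0 of 5 labelled

    unrelated = [ReferenceProtein("U", random_protein(rng, 300), True)]
    out = screen_cytochrome_candidates(census, {"q": "CAACH" + cand}, unrelated)
    assert out[0].status == "rejected"        # no hits at all

    out = screen_cytochrome_candidates(census, {"q": "CAACH" + cand}, None)
    assert out[0].status == "unscreened"


def test_planted_cytochromes_retained_and_decoys_rejected(small_bundle):
    proteome = dict(small_bundle.proteome)
    census = heme_motif_census(list(proteome.items()))
    screened = {
        e.locus_tag: e
        for e in screen_cytochrome_candidates(
            census, proteome, small_bundle.cytochrome_refs)
    }
    for t in small_bundle.truth.of_kind("cytochrome"):
        assert screened[t.params["locus"]].status == "retained"
    for t in small_bundle.truth.of_kind("decoy"):
        assert screened[t.params["locus"]].status == "rejected"


# ---------------------------------------------------------------------------
# in-silico PCR

FWD = "AGCATCGGTCAGCTGAATCT"
REV = "GGTTAGAGCGTGGTGCATTT"


def _toy_template(rng, product_len=50, pad=(0, 0)):
    inner = product_len - len(FWD) - len(REV)
    core = FWD + random_dna(rng, inner) + reverse_complement(REV)
    return random_dna(rng, pad[0]) + core + random_dna(rng, pad[1])


def test_constructed_template_yields_single_product(rng):
    t = _toy_template(rng, product_len=50)
    (amp,) = insilico_pcr(t, FWD, REV, circular=False)
    assert amp.length == 50
    assert amp.fwd_start == 0
    assert amp.product_seq.startswith(FWD)
    assert amp.product_seq.endswith(reverse_complement(REV))


def test_circular_template_product_spans_origin(rng):
    t = _toy_template(rng, product_len=200, pad=(0, 300))
    # rotate so the product spans the origin
    rot = t[100:] + t[:100]
    amps = insilico_pcr(rot, FWD, REV, circular=True)
    assert len(amps) == 1 and amps[0].length == 200
    assert insilico_pcr(rot, FWD, REV, circular=False) == []


def test_no_primer_sites_returns_empty(rng):
    assert insilico_pcr(random_dna(rng, 500), FWD, REV, circular=False) == []


def test_primer_length_validation(rng):
    with pytest.raises(ValueError):
        insilico_pcr("ACGT" * 30, "ACGTACGT", REV, circular=False)


def test_mismatch_tolerance_spares_three_prime_end(rng):
    t = _toy_template(rng, product_len=80)
    mid = 5
    mm = t[:mid] + ("A" if t[mid] != "A" else "C") + t[mid + 1:]
    assert insilico_pcr(mm, FWD, REV, circular=False, max_mismatch=0) == []
    assert len(insilico_pcr(mm, FWD, REV, circular=False, max_mismatch=1)) == 1
    # same mismatch inside the 3 terminal 3' bases is never tolerated
    p3 = len(FWD) - 1
    mm3 = t[:p3] + ("A" if t[p3] != "A" else "C") + t[p3 + 1:]
    assert insilico_pcr(mm3, FWD, REV, circular=False, max_mismatch=2) == []


def test_planted_primer_site_recovered_on_synthetic_genome(small_bundle):
    t = small_bundle.truth.of_kind("primer_site")[0]
    amps = insilico_pcr(small_bundle.replicon, t.params["fwd"], t.params["rev"])
    assert len(amps) == 1
    assert amps[0].length == t.params["product_len"]
    assert amps[0].fwd_start == t.start
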