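import numpy as np
import pytest
from Bio.Align import substitution_matrices

from gisland import homology as hom
from conftest import random_dna, random_protein
from oracles import sw_affine_score


class _Sub:
    def __init__(self, name):
        self.m = substitution_matrices.load(name)

    def __getitem__(self, key):
        return float(self.m[key])


@pytest.mark.parametrize("matrix,go,ge", [("BLOSUM62", 11, 1), ("BLOSUM45", 14, 2)])
def test_align_local_matches_quadratic_dp_oracle(rng, matrix, go, ge):
    sub = _Sub(matrix)
    for _ in range(60):
        a = random_protein(rng, int(rng.integers(5, 61)))
        b = random_protein(rng, int(rng.integers(5, 61)))
        rec = hom.align_local(a, b, matrix, go, ge)
        assert rec.raw_score == pytest.approx(
            sw_affine_score(a, b, sub, go, ge))


def test_self_alignment_full_identity(rng):
    a = random_protein(rng, 120)
    rec = hom.align_local(a, a)
    assert rec.identity == pytest.approx(100.0)
    assert rec.aln_len == 120
    assert rec.evalue < 1e-20


def test_single_substitution_identity(rng):
    a = random_protein(rng, 100)
    b = a[:50] + ("A" if a[50] != "A" else "G") + a[51:]
    rec = hom.align_local(a, b)
    assert rec.identity == pytest.approx(99.0, abs=1.0)


def test_unknown_matrix_rejected():
    with pytest.raises(ValueError):
        hom.align_local("MKV", "MKV", matrix="PAM1000")


def test_bit_score_monotone_in_raw_score(rng):
    a = random_protein(rng, 200)
    recs = [hom.align_local(a, a[: n]) for n in (50, 100, 200)]
    raw = [r.raw_score for r in recs]
    bit = [r.bit_score for r in recs]
    assert sorted(raw) == raw and sorted(bit) == bit


def test_best_hit_identity_and_deterministic_ties(rng):
    prots = [(f"P{i}", random_protein(rng, 150)) for i in range(5)]
    q = prots[2][1]
    hit = hom.best_hit(q, prots)
    assert hit.subject_id == "P2"
    # exact tie between two identical subjects: lower id wins
    dup = [("B", q), ("A", q)]
    assert hom.best_hit(q, dup).subject_id == "A"
    assert hom.best_hit(random_protein(rng, 20), prots, cutoff_evalue=1e-30) is None


def test_planted_orthologs_recovered_as_best_hits(small_bundle):
    ref = small_bundle.reference_proteomes[0]
    proteome = dict(small_bundle.proteome)
    island_loci = {t.params["locus"] for t in small_bundle.truth.of_kind("island_orf")}
    special = island_loci | {
        t.params["locus"]
        for k in ("cytochrome", "decoy")
        for t in small_bundle.truth.of_kind(k)
    }
    host_loci = [l for l in proteome if l not in special]
    hits = ok = 0
    for locus in host_loci[:40]:
        h = hom.best_hit(proteome[locus], ref, query_id=locus)
        hits += 1
        ok += h is not None and h.subject_id == f"G0_{locus}"
    assert ok / hits >= 0.95


def test_aai_identical_proteomes_and_subset(rng):
    prots = [(f"P{i}", random_protein(rng, 120)) for i in range(12)]
    s = hom.aai(prots, prots)
    assert s.mean_identity == pytest.approx(100.0, abs=1e-6)
    assert s.n_hits == 12
    s2 = hom.aai(prots, prots[:10])
    assert s2.mean_identity == pytest.approx(100.0, abs=1e-6)
    with pytest.raises(ValueError):
        hom.aai([], prots)


def test_aai_tracks_generator_divergence(small_bundle):
    # reference proteomes are host orthologs at ~30% per-site divergence
    proteome = dict(small_bundle.proteome)
    island = {t.params["locus"] for t in small_bundle.truth.of_kind("island_orf")}
    host = [(l, p) for l, p in proteome.items() if l not in island][:30]
    s = hom.aai(host, small_bundle.reference_proteomes[0][:60])
    assert s.mean_identity == pytest.approx(70.0, abs=3.0)


def test_top_hit_affiliation_fractions(rng):
    ref_x = [(f"X{i}", random_protein(rng, 150)) for i in range(5)]
    queries = [(f"q{i}", s) for i, (_, s) in enumerate(ref_x)]
    frac = hom.top_hit_affiliation(queries, {"X": ref_x, "Y": []})
    assert frac["X"] == 1.0 and frac["none"] == 0.0
    frac = hom.top_hit_affiliation(queries, {"X": [], "Y": []})
    assert frac["none"] == 1.0
    with pytest.raises(ValueError):
        hom.top_hit_affiliation(queries, {"X": ref_x, "Y": ref_x})


def test_presence_profile_flags_absentees(rng):
    core = random_protein(rng, 200)
    refs = [[("r", core)] for _ in range(4)]
    prof = hom.presence_profile([("q", core), ("alien", random_protein(rng, 200))],
                                refs)
    assert prof["q"] == (1.0, False)
    assert prof["alien"][0] == 0.0 and prof["alien"][1]


# ---------------------------------------------------------------------------
# near-identical diffing

def test_diff_identical_sequences_empty(rng):
    s = random_dna(rng, 10_000)
    assert hom.diff_near_identical(s, s) == []


def test_diff_recovers_planted_snp_and_long_deletion(rng):
    ref = random_dna(rng, 20_000)
    q = list(ref)
    q[5000] = "A" if ref[5000] != "A" else "C"
    query = "".join(q[:12_000] + q[12_119:])  # 119 bp deletion
    variants = hom.diff_near_identical(ref, query)
    kinds = sorted(v.kind for v in variants)
    assert kinds == ["deletion", "snp"]
    dele = next(v for v in variants if v.kind == "deletion")
    assert dele.length == 119
    snp = next(v for v in variants if v.kind == "snp")
    assert snp.position == 5000


def test_diff_random_edit_sets_always_reconstruct(rng):
    for _ in range(15):
        ref = random_dna(rng, 8_000)
        q = list(ref)
        for _ in range(int(rng.integers(1, 8))):
            p = int(rng.integers(100, 7_900))
            op = rng.choice(3)
            if op == 0:
                q[p] = "A" if q[p] != "A" else "G"
            elif op == 1:
                q[p:p] = list(random_dna(rng, int(rng.integers(1, 30))))
            else:
                del q[p : p + int(rng.integers(1, 30))]
        query = "".join(q)
        variants = hom.diff_near_identical(ref, query)
        assert hom.apply_variants(ref, variants) == query


def test_diff_refuses_divergent_sequences(rng):
    a = random_dna(rng, 5_000)
    b = random_dna(rng, 5_000)
    with pytest.raises(ValueError, match="divergent"):
        hom.diff_near_identical(a, b)
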