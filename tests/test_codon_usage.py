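import math

import numpy as np
import pytest

from gisland import codon_usage as cu
from gisland import synthetic as syn


def test_pseudo_count_rule_for_unused_codons():
    # a gene using only AAA for Lys: w(AAA)=1, w(AAG)=0.5/count(AAA)
    table = cu.build_codon_table(["AAAAAAAAAAAA"])  # 4 x AAA
    assert table.w["AAA"] == 1.0
    assert table.w["AAG"] == pytest.approx(0.5 / 4)


def test_family_weight_ratio():
    # Lys family counts {AAA: 4, AAG: 1} -> w {1.0, 0.25}
    table = cu.build_codon_table(["AAA" * 4 + "AAG"])
    assert table.w["AAA"] == 1.0
    assert table.w["AAG"] == 0.25


def test_build_codon_table_rejects_empty():
    with pytest.raises(ValueError):
        cu.build_codon_table([])


def test_cai_geometric_mean_and_exclusions():
    table = cu.build_codon_table(["AAA" * 4 + "AAG"])
    # two Lys codons with w 1.0 and 0.25 -> sqrt(0.25) = 0.5
    assert cu.cai("AAAAAG", table) == pytest.approx(0.5)
    # Met and Trp contribute nothing
    assert cu.cai("ATGAAAAAGTGG", table) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        cu.cai("ATGTGG", table)  # no scorable codons


def test_cai_invariant_under_codon_permutation(rng):
    regime = syn.alien_regime(0.5)
    prot = "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.choice(20, 60)])
    dna = syn._encode_protein(rng, prot, regime.probs, regime.families)[:-3]
    table = cu.build_codon_table([dna])
    codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
    rng.shuffle(codons)
    assert cu.cai("".join(codons), table) == pytest.approx(cu.cai(dna, table))


def test_gene_of_family_maximal_codons_scores_one():
    table = cu.build_codon_table(["AAACTGGGTCTGAAA"])
    best = {}
    for aa, fam in cu.SYNONYMOUS_FAMILIES.items():
        best[aa] = max(fam, key=lambda c: table.w[c])
    gene = "".join(best[aa] for aa in "KLGK")
    assert cu.cai(gene, table) == pytest.approx(1.0)


def test_empirical_weights_track_generating_distribution(rng):
    # >50 kb of coding sequence sampled from a known codon distribution
    regime = syn.host_regime(rng, 0.55, alpha=0.5)
    genes = []
    for _ in range(250):
        prot = syn._random_protein(rng, 280)
        genes.append(syn._encode_protein(rng, prot, regime.probs,
                                         regime.families)[:-3])
    table = cu.build_codon_table(genes)
    for aa, fam in cu.SYNONYMOUS_FAMILIES.items():
        if aa in ("M", "W"):
            continue
        p = regime.probs[aa]
        expected_w = p / p.max()
        for codon, ew in zip(regime.families[aa], expected_w):
            assert table.w[codon] == pytest.approx(ew, abs=0.05)


def test_expected_cai_quantile_monotone_and_seed_reproducible():
    table = cu.build_codon_table(["AAA" * 9 + "AAG" + "GGT" * 5 + "GGG"])
    aa = "KKKGGGKKKGGG" * 5
    e90 = cu.expected_cai(aa, table, n_boot=300, quantile=0.90, seed=4)
    e95 = cu.expected_cai(aa, table, n_boot=300, quantile=0.95, seed=4)
    e99 = cu.expected_cai(aa, table, n_boot=300, quantile=0.99, seed=4)
    assert e90 <= e95 <= e99 <= 1.0 + 1e-12
    again = cu.expected_cai(aa, table, n_boot=300, quantile=0.95, seed=4)
    assert again == e95  # bit-reproducible given the seed


def test_expected_cai_input_validation():
    table = cu.build_codon_table(["AAAAAG"])
    with pytest.raises(ValueError):
        cu.expected_cai("KKK", table, n_boot=50)
    with pytest.raises(ValueError):
        cu.expected_cai("MWM", table)


def test_all_optimal_gene_never_flagged_foreign():
    table = cu.build_codon_table(["AAA" * 9 + "AAG"])
    res = cu.normalized_cai("g1", "AAA" * 30, table, n_boot=200, seed=1,
                            aa_seq="K" * 30)
    assert res.cai == pytest.approx(1.0)
    assert res.ecai <= 1.0
    assert res.normalized >= 1.0
    assert not res.foreign_flag


def test_host_regime_genes_pass_and_alien_genes_fail_flagging(rng):
    host = syn.host_regime(rng, 0.55, alpha=0.25)
    genes = []
    for _ in range(80):
        prot = syn._random_protein(rng, 250)
        genes.append(syn._encode_protein(rng, prot, host.probs, host.families))
    table = cu.build_codon_table([g[:-3] for g in genes])
    alien = syn.alien_regime(0.55)
    uniform = {aa: np.ones(len(f)) / len(f) for aa, f in alien.families.items()}
    host_flags = alien_flags = 0
    n = 50
    for k in range(n):
        prot = syn._random_protein(rng, 250)
        hg = syn._encode_protein(rng, prot, host.probs, host.families)[:-3]
        ag = syn._encode_protein(rng, prot, uniform, alien.families)[:-3]
        host_flags += cu.normalized_cai("h", hg, table, n_boot=200,
                                        seed=rng, aa_seq=prot).foreign_flag
        alien_flags += cu.normalized_cai("a", ag, table, n_boot=200,
                                         seed=rng, aa_seq=prot).foreign_flag
    assert host_flags / n <= 0.10   # host-regime genes rarely flagged
    assert alien_flags / n >= 0.80  # alien-usage genes usually flagged
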