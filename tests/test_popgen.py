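"""Diversity/neutrality/differentiation statistics vs independent oracles.

Frozen constants marked "pegas" were computed with the R package pegas
(nuc.div / theta.s / tajima.test) on the identical seeded alignments.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from tm7pop.popgen import (
    PopulationAlignment,
    segregating_sites,
    nucleotide_diversity,
    mean_pairwise_differences,
    watterson_theta,
    tajimas_d,
    tajimas_d_from_counts,
    fu_li_dstar,
    fu_li_dstar_from_counts,
    coalescent_pvalue,
    simulate_sfs,
    statistic_from_sfs,
    hudson_fst,
    snn_statistic,
    snn_test,
    fdr_adjust,
    harmonic_number,
    _distance_matrix,
)
from tm7pop.simulate import simulate_two_pop


def _aln(seqs, pops=None, locus="toy"):
    pops = pops or ["pop1"] * len(seqs)
    ids = [f"a{i}|{p}" for i, (s, p) in enumerate(zip(seqs, pops))]
    return PopulationAlignment(locus=locus, ids=ids, seqs=list(seqs), pops=pops)


# ---------------------------------------------------------------------------
# Segregating sites / complete deletion


def test_identical_alleles_no_segregation():
    aln = _aln(["ACGTACGT"] * 4)
    assert segregating_sites(aln) == (0, [])


def test_single_segregating_column():
    aln = _aln(["AAAA", "AAAA", "GAAA", "GAAA"])
    s, sites = segregating_sites(aln)
    assert (s, sites) == (1, [0])


def test_columns_with_n_excluded():
    seqs = ["ACGA", "ANGA", "GCGA", "GCGT"]
    aln = _aln(seqs)
    # brute-force scan: usable columns are those without N in any row
    usable = [j for j in range(4) if all(s[j] != "N" for s in seqs)]
    seg = [j for j in usable if len({s[j] for s in seqs}) > 1]
    s, sites = segregating_sites(aln)
    assert sites == seg and s == len(seg)
    assert len(aln.included_columns()) == len(usable)


# ---------------------------------------------------------------------------
# pi / theta


def test_pi_two_alleles_one_difference():
    aln = _aln(["A" * 100, "G" + "A" * 99])
    assert nucleotide_diversity(aln) == pytest.approx(0.01)


def test_pi_identical_zero():
    assert nucleotide_diversity(_aln(["ACGT" * 5] * 3)) == 0


def test_pi_matches_bruteforce_all_pairs():
    rng = np.random.default_rng(17)
    seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
    aln = _aln(seqs)
    diffs = [
        sum(a != b for a, b in zip(seqs[i], seqs[j]))
        for i, j in combinations(range(4), 2)
    ]
    expected = np.mean(diffs) / 60
    assert nucleotide_diversity(aln) == pytest.approx(expected)


def test_watterson_n2():
    aln = _aln(["A" * 100, "G" + "A" * 99])
    assert watterson_theta(aln) == pytest.approx(0.01)


def test_watterson_hand_arithmetic():
    # n=4, S=11, L=1000 -> a1 = 11/6, theta = 11/(11/6)/1000 = 0.006
    assert harmonic_number(3) == pytest.approx(11 / 6)
    rng = np.random.default_rng(2)
    base = "".join(rng.choice(list("ACGT"), size=1000))
    seqs = [base] * 3
    mutant = list(base)
    cols = rng.choice(1000, size=11, replace=False)
    for c in cols:
        mutant[c] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[c]]
    aln = _aln(["".join(mutant)] + seqs)
    assert segregating_sites(aln)[0] == 11
    assert watterson_theta(aln) == pytest.approx(0.006)


def test_zero_s_zero_theta():
    assert watterson_theta(_aln(["ACGT"] * 4)) == 0


def test_single_allele_errors():
    with pytest.raises(ValueError):
        nucleotide_diversity(_aln(["ACGT"]))


# ---------------------------------------------------------------------------
# Tajima's D


def test_tajima_zero_numerator():
    # pi*L == S/a1 -> D == 0 exactly
    assert tajimas_d_from_counts(4, 11, 11 / harmonic_number(3)) == pytest.approx(0.0)


def test_tajima_sign_matches_numerator():
    rng = np.random.default_rng(0)
    for seed in range(20):
        aln, _ = simulate_two_pop(4, 4, 300, 4.0, 0.0, seed=seed)
        s, _ = segregating_sites(aln)
        if s == 0:
            continue
        num = mean_pairwise_differences(aln) - s / harmonic_number(aln.n - 1)
        d = tajimas_d(aln)
        assert np.sign(d) == np.sign(num) or num == 0


def test_all_singletons_negative_d():
    base = "A" * 50
    seqs = [base] * 6
    for i in range(3):  # three singleton mutations on different alleles
        s = list(seqs[i])
        s[10 + i] = "G"
        seqs[i] = "".join(s)
    assert tajimas_d(_aln(seqs)) < 0


FROZEN_ORACLE = {
    # seed: (n1, n2, L, theta, split, S, pi, theta_w, tajima_d, fu_li_dstar)
    # pi/theta_w/tajima_d from R pegas (nuc.div, theta.s, tajima.test);
    # tajima_d/fu_li_dstar confirmed with R PopGenome (neutrality.stats)
    # on the identical seeded FASTA exports.
    7: (6, 6, 500, 4.0, 0.3, 18, 0.014030303030, 0.011921013965,
        0.771232478427, 0.591263033),
    11: (5, 4, 300, 3.0, 0.3, 7, 0.009629629630, 0.008585194919,
         0.542683482728, 0.920832897),
    23: (16, 13, 800, 6.0, 0.3, 17, 0.004710591133, 0.005411019736,
         -0.445901240843, -0.886091807),
}


@pytest.mark.parametrize("seed", sorted(FROZEN_ORACLE))
def test_frozen_r_oracles(seed):
    n1, n2, L, theta, split, S, pi, tw, d, dstar = FROZEN_ORACLE[seed]
    aln, _ = simulate_two_pop(n1, n2, L, theta, split, seed=seed)
    assert segregating_sites(aln)[0] == S
    assert nucleotide_diversity(aln) == pytest.approx(pi, abs=1e-10)
    assert watterson_theta(aln) == pytest.approx(tw, abs=1e-10)
    assert tajimas_d(aln) == pytest.approx(d, abs=1e-9)
    assert fu_li_dstar(aln) == pytest.approx(dstar, abs=1e-6)


# ---------------------------------------------------------------------------
# Fu & Li's D*


def fu_li_dstar_oracle(n, eta, eta_s):
    """Independent exact-fraction transcription of the corrected D*
    variance constants (Fu & Li 1993)."""
    an = sum(Fraction(1, i) for i in range(1, n))
    bn = sum(Fraction(1, i * i) for i in range(1, n))
    an1 = an + Fraction(1, n)
    cn = Fraction(2 * (n * an - 2 * (n - 1)), (n - 1) * (n - 2))
    dn = (
        cn
        + Fraction(n - 2, (n - 1) ** 2)
        + Fraction(2, n - 1) * (Fraction(3, 2) - (2 * an1 - 3) / Fraction(n - 2) - Fraction(1, n))
    )
    nn = Fraction(n, n - 1)
    v = (nn**2 * bn + an**2 * dn - 2 * n * an * (an + 1) / Fraction((n - 1) ** 2)) / (
        an**2 + bn
    )
    u = nn * (an - nn) - v
    import math

    return float(nn * eta - an * eta_s) / math.sqrt(float(u * eta + v * eta * eta))


@pytest.mark.parametrize("n,eta,eta_s", [(5, 6, 2), (10, 12, 3), (29, 20, 8), (4, 3, 3)])
def test_dstar_matches_exact_fraction_oracle(n, eta, eta_s):
    assert fu_li_dstar_from_counts(n, eta, eta_s) == pytest.approx(
        fu_li_dstar_oracle(n, eta, eta_s), abs=1e-6
    )


def test_dstar_sign_structure():
    # no singletons, S > 0 -> positive
    seqs = ["A" * 40] * 6
    for i in (0, 1, 2):  # shared mutation in three alleles
        s = list(seqs[i])
        s[5] = "T"
        seqs[i] = "".join(s)
    assert fu_li_dstar(_aln(seqs)) > 0
    # all mutations singletons -> negative
    seqs = ["A" * 40] * 6
    for i in range(4):
        s = list(seqs[i])
        s[10 + i] = "G"
        seqs[i] = "".join(s)
    assert fu_li_dstar(_aln(seqs)) < 0


def test_dstar_null_calibration():
    rng = np.random.default_rng(5)
    vals = [statistic_from_sfs("fu_li_dstar", 15, simulate_sfs(15, 10, rng))
            for _ in range(2000)]
    assert abs(np.mean(vals)) < 0.15
    assert 0.6 < np.std(vals) < 1.3


# ---------------------------------------------------------------------------
# Coalescent p-values


def test_coalescent_p_at_median_near_one():
    rng = np.random.default_rng(9)
    sims = [statistic_from_sfs("tajima_d", 10, simulate_sfs(10, 6, rng))
            for _ in range(2000)]
    med = float(np.median(sims))
    p = coalescent_pvalue(10, 6, med, "tajima_d", reps=2000, seed=1)
    assert p > 0.8


def test_coalescent_p_extreme_observation():
    p = coalescent_pvalue(10, 6, 50.0, "tajima_d", reps=2000, seed=2)
    assert p <= 2 / 2000


def test_simulated_null_mean_near_zero():
    rng = np.random.default_rng(3)
    vals = np.array([statistic_from_sfs("tajima_d", 10, simulate_sfs(10, 5, rng))
                     for _ in range(3000)])
    se = vals.std() / np.sqrt(len(vals))
    assert abs(vals.mean()) < 3 * se + 0.05


# ---------------------------------------------------------------------------
# FST


def test_fst_fixed_difference_is_one():
    seqs = ["A" * 30] * 3 + ["G" * 30] * 3
    pops = ["pop1"] * 3 + ["pop2"] * 3
    res = hudson_fst(_aln(seqs, pops))
    assert res.defined and res.fst == pytest.approx(1.0)


def test_fst_monomorphic_undefined():
    res = hudson_fst(_aln(["ACGT" * 4] * 6, ["pop1"] * 3 + ["pop2"] * 3))
    assert not res.defined


def test_fst_panmictic_near_zero():
    vals = []
    for seed in range(200):
        aln, _ = simulate_two_pop(6, 6, 500, 5.0, 0.0, seed=3000 + seed)
        res = hudson_fst(aln)
        if res.defined:
            vals.append(res.fst)
    assert abs(np.mean(vals)) < 0.05


def test_fst_matches_bruteforce_pairwise():
    aln, _ = simulate_two_pop(5, 5, 400, 5.0, 1.0, seed=77)
    res = hudson_fst(aln)
    cols = aln.included_columns()
    idx1 = [i for i, p in enumerate(aln.pops) if p == "pop1"]
    idx2 = [i for i, p in enumerate(aln.pops) if p == "pop2"]

    def diff(i, j):
        return sum(aln.seqs[i][c] != aln.seqs[j][c] for c in cols)

    hw1 = np.mean([diff(i, j) for i, j in combinations(idx1, 2)])
    hw2 = np.mean([diff(i, j) for i, j in combinations(idx2, 2)])
    hb = np.mean([diff(i, j) for i in idx1 for j in idx2])
    assert res.fst == pytest.approx(1 - 0.5 * (hw1 + hw2) / hb)


# ---------------------------------------------------------------------------
# Snn


def snn_oracle(d, labels):
    """Naive loop version with fractional ties (independent of the
    vectorized quadratic-form path)."""
    n = len(labels)
    total = 0.0
    for i in range(n):
        row = [d[i][j] if j != i else np.inf for j in range(n)]
        m = min(row)
        nn = [j for j in range(n) if row[j] == m]
        total += sum(labels[j] == labels[i] for j in nn) / len(nn)
    return total / n


def test_snn_perfectly_separated():
    seqs = ["AAAA" + "C" * 20] * 4 + ["GGGG" + "C" * 20] * 4
    aln = _aln(seqs, ["pop1"] * 4 + ["pop2"] * 4)
    snn, p = snn_test(aln, reps=999, seed=0)
    assert snn == pytest.approx(1.0)
    assert p < 0.05


def test_snn_hand_computable_six_sequences():
    seqs = [
        "AAAAA",  # p1
        "AAAAT",  # p1
        "AAATT",  # p1
        "TTTTT",  # p2
        "TTTTA",  # p2
        "TTTAA",  # p2
    ]
    labels = np.array(["p1"] * 3 + ["p2"] * 3)
    aln = _aln(seqs, list(labels))
    d = _distance_matrix(aln)
    # hand check: each sequence's nearest neighbor is its within-group chain
    expected = snn_oracle(d.tolist(), list(labels))
    assert snn_statistic(d, labels) == pytest.approx(expected)
    assert expected == 1.0


def test_snn_vectorized_matches_loop_oracle():
    for seed in range(10):
        aln, _ = simulate_two_pop(5, 6, 300, 6.0, 0.5, seed=400 + seed)
        d = _distance_matrix(aln)
        labels = np.asarray(aln.pops)
        assert snn_statistic(d, labels) == pytest.approx(
            snn_oracle(d.tolist(), list(labels))
        )


def test_snn_invariant_to_relabelling_within_pops():
    aln, _ = simulate_two_pop(5, 5, 300, 5.0, 1.0, seed=21)
    snn1, _ = snn_test(aln, reps=1000, seed=1)
    # shuffle sequence order within populations
    order = [3, 1, 4, 2, 0, 8, 9, 5, 7, 6]
    aln2 = PopulationAlignment(
        locus=aln.locus,
        ids=[aln.ids[i] for i in order],
        seqs=[aln.seqs[i] for i in order],
        pops=[aln.pops[i] for i in order],
    )
    snn2, _ = snn_test(aln2, reps=1000, seed=1)
    assert snn1 == pytest.approx(snn2)


def test_snn_in_unit_interval():
    for seed in range(5):
        aln, _ = simulate_two_pop(4, 4, 200, 3.0, 0.2, seed=seed)
        snn, p = snn_test(aln, reps=500, seed=seed)
        assert 0.0 <= snn <= 1.0 and 0.0 < p <= 1.0


# ---------------------------------------------------------------------------
# FDR


def test_bh_hand_case():
    assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    assert fdr_adjust([0.3]) == [0.3]


def test_bh_all_ones():
    assert fdr_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]


def test_bh_never_decreases_and_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    p = rng.uniform(size=25).tolist()
    adj = fdr_adjust(p)
    assert all(a >= b for a, b in zip(adj, p))
    sm = multipletests(p, method="fdr_bh")[1]
    assert adj == pytest.approx(sm.tolist())


def test_bh_preserves_stepup_significance_count():
    rng = np.random.default_rng(4)
    p = sorted(rng.uniform(size=15))
    m = len(p)
    alpha = 0.05
    k = max([i + 1 for i in range(m) if p[i] <= (i + 1) / m * alpha], default=0)
    adj = fdr_adjust(p)
    assert sum(1 for q in adj if q <= alpha) == k
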