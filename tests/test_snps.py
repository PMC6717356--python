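"""SNP calling, coding effects, Fisher enumeration, topology mapping."""

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from tm7pop.popgen import PopulationAlignment
from tm7pop.snps import (
    SnpRecord,
    call_snps,
    any_fixed_difference,
    annotate_effect,
    fisher_exact_2x2,
    per_snp_differentiation,
    map_snp_to_topology,
    domain_side,
)


def _aln(seqs, pops, locus="locus1"):
    ids = [f"a{i}|{p}" for i, p in enumerate(pops)]
    return PopulationAlignment(locus=locus, ids=ids, seqs=seqs, pops=pops)


def _coding_aln(n1=4, n2=4, n_codons=4, edits=()):
    """Monomorphic coding alignment with optional (row, col, base) edits."""
    base = "ATGGCTGCTGCT"[: 3 * n_codons]
    seqs = [base] * (n1 + n2)
    for row, col, b in edits:
        s = list(seqs[row])
        s[col] = b
        seqs[row] = "".join(s)
    return _aln(seqs, ["basalt"] * n1 + ["chalk"] * n2)


# ---------------------------------------------------------------------------
# Calling


def test_call_counts_table():
    # column 3: two basalt alleles carry G, all chalk carry A
    aln = _coding_aln(n1=4, n2=4, edits=[(0, 3, "A"), (1, 3, "A")])
    # base at col 3 is G; rows 0,1 switched to A -> basalt A:2 G:2, chalk G:4
    (snp,) = [s for s in call_snps(aln) if s.column == 3]
    assert snp.codon_index == 1 and snp.codon_pos == 0
    assert snp.ref == "G" and snp.alt == "A"
    assert snp.table == ((2, 4), (2, 0))


def test_monomorphic_no_snps():
    assert call_snps(_coding_aln()) == []


def test_frame_error():
    aln = _aln(["ATGGC", "ATGGC"], ["p1", "p2"] )
    with pytest.raises(ValueError):
        call_snps(aln)


def test_no_fixed_difference_detector():
    aln = _coding_aln(edits=[(0, 3, "A")])
    assert not any_fixed_difference(call_snps(aln))
    fixed = _coding_aln(edits=[(i, 3, "A") for i in range(4)])
    assert any_fixed_difference(call_snps(fixed))


def test_n_columns_skipped():
    aln = _coding_aln(edits=[(0, 3, "N"), (1, 3, "A")])
    assert all(s.column != 3 for s in call_snps(aln))


def test_multiallelic_flagged():
    aln = _coding_aln(n1=4, n2=4, edits=[(0, 3, "A"), (1, 3, "C")])
    (snp,) = [s for s in call_snps(aln) if s.column == 3]
    assert snp.multiallelic


# ---------------------------------------------------------------------------
# Effects


def _snp(codon_index=0, codon_pos=0, ref="A", alt="G"):
    return SnpRecord(locus="l", column=3 * codon_index + codon_pos,
                     codon_index=codon_index, codon_pos=codon_pos,
                     ref=ref, alt=alt, counts={}, table=((1, 1), (1, 1)))


def test_synonymous_gaa_gag():
    snp = _snp(codon_index=0, codon_pos=2, ref="A", alt="G")
    assert annotate_effect(snp, "GAA") == "synonymous"


def test_nonsynonymous_aaa_gaa():
    snp = _snp(codon_index=0, codon_pos=0, ref="A", alt="G")
    assert annotate_effect(snp, "AAA") == "nonsynonymous"


def test_stop_gain_flagged():
    snp = _snp(codon_index=0, codon_pos=2, ref="T", alt="A")
    annotate_effect(snp, "TAT")
    assert snp.stop_gain


def test_outside_cds_errors():
    with pytest.raises(ValueError):
        annotate_effect(_snp(codon_index=5), "ATGGCT")


# ---------------------------------------------------------------------------
# Fisher's exact test


def test_fisher_paper_strong_table():
    assert fisher_exact_2x2(((14, 8), (1, 17))) < 0.001


def test_fisher_paper_weak_table():
    p = fisher_exact_2x2(((3, 15), (1, 17)))
    assert p > 0.6
    assert p == pytest.approx(0.602597, abs=1e-5)


def test_fisher_identical_rows_p1():
    assert fisher_exact_2x2(((5, 5), (5, 5))) == pytest.approx(1.0)


def test_fisher_zero_margin():
    assert fisher_exact_2x2(((0, 0), (3, 4))) == 1.0


def test_fisher_exhaustive_vs_scipy_n_le_40():
    """Full enumeration agreement with scipy for every table with n <= 40
    (coarse grid plus an exhaustive band at small n)."""
    for n in range(2, 41, 2):
        rng = np.random.default_rng(n)
        tables = []
        if n <= 12:
            tables = [
                (a, b, c, n - a - b - c)
                for a in range(n + 1)
                for b in range(n + 1 - a)
                for c in range(n + 1 - a - b)
            ]
        else:
            for _ in range(60):
                a = int(rng.integers(0, n + 1))
                b = int(rng.integers(0, n + 1 - a))
                c = int(rng.integers(0, n + 1 - a - b))
                tables.append((a, b, c, n - a - b - c))
        for a, b, c, d in tables:
            ours = fisher_exact_2x2(((a, b), (c, d)))
            ref = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12), (a, b, c, d)


def test_population_swap_leaves_p_unchanged():
    rng = np.random.default_rng(2)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 20, size=4)
        p1 = fisher_exact_2x2(((int(a), int(b)), (int(c), int(d))))
        p2 = fisher_exact_2x2(((int(b), int(a)), (int(d), int(c))))
        assert p1 == pytest.approx(p2)


# ---------------------------------------------------------------------------
# Per-SNP differentiation


def _two_pop_snp_aln(delta=0.9, n1=30, n2=26, seed=0):
    """One strongly differentiated nonsynonymous site plus background."""
    rng = np.random.default_rng(seed)
    n_codons = 10
    base = "ATG" + "GCT" * (n_codons - 1)
    seqs = []
    pops = ["basalt"] * n1 + ["chalk"] * n2
    for i in range(n1 + n2):
        s = list(base)
        freq = delta if i < n1 else 0.0
        if rng.random() < freq:
            s[4] = "A"  # codon GCT -> GAT: Ala -> Asp, nonsynonymous
        seqs.append("".join(s))
    return _aln(seqs, pops)


def test_locus_without_nonsyn_snps_counts_zero():
    # single synonymous SNP (GCT -> GCC at codon 3 position)
    aln = _coding_aln(edits=[(0, 5, "C"), (1, 5, "C")])
    snps = call_snps(aln)
    cds = "ATGGCTGCTGCT"
    snps, counts = per_snp_differentiation(snps, {"locus1": cds})
    assert counts["locus1"] == 0
    assert all(s.effect == "synonymous" for s in snps)


def test_power_strongly_divergent_site():
    hits = 0
    reps = 100
    for seed in range(reps):
        aln = _two_pop_snp_aln(delta=0.9, seed=seed)
        snps = call_snps(aln)
        cds = "ATG" + "GCT" * 9
        snps, counts = per_snp_differentiation(snps, {"locus1": cds})
        if counts["locus1"] >= 1:
            hits += 1
    assert hits / reps >= 0.95


def test_null_fdr_control():
    """With no true differentiation, the familywise discovery rate honors
    the BH guarantee."""
    false_hits = 0
    reps = 150
    rng = np.random.default_rng(10)
    for rep in range(reps):
        # shared polymorphism at identical frequency in both populations
        n1 = n2 = 20
        base = "ATG" + "GCT" * 9
        seqs = []
        for i in range(n1 + n2):
            s = list(base)
            if rng.random() < 0.4:
                s[4] = "A"
            if rng.random() < 0.25:
                s[7] = "T"
            seqs.append("".join(s))
        aln = _aln(seqs, ["basalt"] * n1 + ["chalk"] * n2)
        snps = call_snps(aln)
        snps, counts = per_snp_differentiation(snps, {"locus1": base})
        false_hits += 1 if counts.get("locus1", 0) > 0 else 0
    assert false_hits / reps <= 0.07


def test_per_locus_counts_invariant_to_order():
    aln = _two_pop_snp_aln(seed=3)
    snps = call_snps(aln)
    cds = "ATG" + "GCT" * 9
    _, c1 = per_snp_differentiation(list(snps), {"locus1": cds})
    _, c2 = per_snp_differentiation(list(reversed(snps)), {"locus1": cds})
    assert c1 == c2


def test_fdr_families_pooled_vs_per_locus():
    aln1 = _two_pop_snp_aln(seed=4)
    snps = call_snps(aln1)
    cds = {"locus1": "ATG" + "GCT" * 9}
    _, pooled = per_snp_differentiation(list(snps), cds, family="pooled")
    _, per_locus = per_snp_differentiation(list(snps), cds, family="per_locus")
    assert set(pooled) == set(per_locus)


# ---------------------------------------------------------------------------
# Topology mapping


SPANS = [(20, 43), (58, 81), (95, 118), (132, 155), (170, 193), (208, 231), (245, 268)]


def test_inside_third_helix():
    snp = _snp(codon_index=100)
    assert map_snp_to_topology(snp, SPANS) == "TM3"


def test_n_terminus():
    snp = _snp(codon_index=1)
    assert map_snp_to_topology(snp, SPANS) == "N-term"
    assert domain_side("N-term") == "outside"


def test_c_terminus():
    snp = _snp(codon_index=280)
    assert map_snp_to_topology(snp, SPANS, protein_len=300) == "C-term"
    assert domain_side("C-term") == "inside"


def test_loops_alternate_sides():
    # residues between helix k and k+1
    gaps = [(43, 58), (81, 95), (118, 132), (155, 170), (193, 208), (231, 245)]
    labels = []
    for lo, hi in gaps:
        snp = _snp(codon_index=(lo + hi) // 2)
        labels.append(map_snp_to_topology(snp, SPANS))
    assert labels == ["ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3"]
    sides = [domain_side(l) for l in labels]
    assert sides == ["inside", "outside"] * 3


def test_beyond_protein_errors():
    with pytest.raises(ValueError):
        map_snp_to_topology(_snp(codon_index=500), SPANS, protein_len=300)
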