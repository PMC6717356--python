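"""Per-SNP allele-frequency differentiation between two populations.

Calls biallelic SNPs from coding allele alignments, annotates synonymous /
nonsynonymous effects by codon translation, tests per-population allele
counts with a two-tailed Fisher exact test (point-probability rule),
BH-adjusts across nonsynonymous SNPs, and maps significant sites onto
predicted transmembrane topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mining.translate import translate_codon
from .popgen import PopulationAlignment, fdr_adjust

_VALID = frozenset("ACGT")


@dataclass
class SnpRecord:
    locus: str
    column: int  # 0-based alignment column
    codon_index: int  # 0-based
    codon_pos: int  # 0, 1, 2
    ref: str
    alt: str
    counts: dict  # pop -> {base: count} for ref and alt
    table: tuple  # ((ref_pop1, ref_pop2), (alt_pop1, alt_pop2))
    effect: str | None = None  # synonymous | nonsynonymous
    stop_gain: bool = False
    multiallelic: bool = False
    p_fisher: float | None = None
    p_fdr: float | None = None
    topology_domain: str | None = None
    fixed_between: bool = False


def call_snps(aln: PopulationAlignment) -> list[SnpRecord]:
    """Biallelic variable columns with per-population allele counts.

    Columns containing N/gap in any allele are excluded (complete deletion,
    consistent with the diversity statistics); multi-allelic columns are
    returned flagged but receive no test. The locus must be a complete ORF
    (length divisible by 3).
    """
    if aln.length % 3 != 0:
        raise ValueError(
            f"locus {aln.locus}: alignment length {aln.length} not divisible by 3"
        )
    labels = aln.population_labels()
    if len(labels) != 2:
        raise ValueError(f"expected 2 populations, got {labels}")
    pop_idx = {lab: [i for i, p in enumerate(aln.pops) if p == lab] for lab in labels}

    records: list[SnpRecord] = []
    for j in range(aln.length):
        column = [s[j] for s in aln.seqs]
        if any(b not in _VALID for b in column):
            continue
        bases = sorted(set(column))
        if len(bases) < 2:
            continue
        # ref = overall major allele, alt = minor (ties broken alphabetically)
        tallies = {b: column.count(b) for b in bases}
        ordered = sorted(bases, key=lambda b: (-tallies[b], b))
        ref, alt = ordered[0], ordered[1]
        counts = {
            lab: {b: sum(1 for i in pop_idx[lab] if column[i] == b) for b in bases}
            for lab in labels
        }
        table = (
            (counts[labels[0]].get(ref, 0), counts[labels[1]].get(ref, 0)),
            (counts[labels[0]].get(alt, 0), counts[labels[1]].get(alt, 0)),
        )
        set1 = {column[i] for i in pop_idx[labels[0]]}
        set2 = {column[i] for i in pop_idx[labels[1]]}
        fixed = len(set1) == 1 and len(set2) == 1 and set1 != set2
        records.append(
            SnpRecord(
                locus=aln.locus,
                column=j,
                codon_index=j // 3,
                codon_pos=j % 3,
                ref=ref,
                alt=alt,
                counts=counts,
                table=table,
                multiallelic=len(bases) > 2,
                fixed_between=fixed,
            )
        )
    return records


def any_fixed_difference(snps: list[SnpRecord]) -> bool:
    """Whether any SNP is fixed for different alleles between populations."""
    return any(r.fixed_between for r in snps)


def annotate_effect(snp: SnpRecord, cds: str) -> str:
    """Translate the ref and alt codons; sets and returns ``snp.effect``."""
    start = 3 * snp.codon_index
    if start + 3 > len(cds):
        raise ValueError("SNP maps outside the CDS")
    codon = list(cds[start : start + 3].upper())
    ref_codon = codon.copy()
    alt_codon = codon.copy()
    ref_codon[snp.codon_pos] = snp.ref
    alt_codon[snp.codon_pos] = snp.alt
    aa_ref = translate_codon("".join(ref_codon))
    aa_alt = translate_codon("".join(alt_codon))
    snp.stop_gain = "*" in (aa_ref, aa_alt)
    snp.effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return snp.effect


# ---------------------------------------------------------------------------
# Fisher's exact test (own enumeration; independent of scipy)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_2x2(table: tuple[tuple[int, int], tuple[int, int]]) -> float:
    """Two-tailed Fisher exact p by full hypergeometric enumeration.

    The two-tailed p sums the probabilities of all tables (with the observed
    margins) whose point probability does not exceed the observed one, within
    a 1e-7 relative tolerance.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0

    def log_p(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, r1, c1): x in cell (0,0)
        return (
            _log_comb(r1, x)
            + _log_comb(r2, c1 - x)
            - _log_comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = log_p(a)
    cutoff = obs + math.log(1 + 1e-7)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= cutoff:
            total += math.exp(lp)
    return min(1.0, total)


# ---------------------------------------------------------------------------
# Per-SNP differentiation


def per_snp_differentiation(
    snps: list[SnpRecord],
    cds_by_locus: dict[str, str] | None = None,
    alpha: float = 0.05,
    family: str = "pooled",
) -> tuple[list[SnpRecord], dict[str, int]]:
    """Fisher-test every nonsynonymous biallelic SNP and BH-adjust.

    ``family='pooled'`` adjusts across all loci together (default);
    ``family='per_locus'`` adjusts within each locus. Effects are annotated
    first when ``cds_by_locus`` is given. Returns the annotated records and
    per-locus counts of significant nonsynonymous SNPs.
    """
    if family not in ("pooled", "per_locus"):
        raise ValueError("family must be 'pooled' or 'per_locus'")
    if cds_by_locus is not None:
        for snp in snps:
            if snp.effect is None and not snp.multiallelic:
                annotate_effect(snp, cds_by_locus[snp.locus])

    testable = [s for s in snps if s.effect == "nonsynonymous" and not s.multiallelic]
    for snp in testable:
        snp.p_fisher = fisher_exact_2x2(snp.table)

    if family == "pooled":
        groups = {"__all__": testable}
    else:
        groups = {}
        for snp in testable:
            groups.setdefault(snp.locus, []).append(snp)
    for members in groups.values():
        adjusted = fdr_adjust([s.p_fisher for s in members])
        for snp, q in zip(members, adjusted):
            snp.p_fdr = q

    counts: dict[str, int] = {}
    for snp in snps:
        counts.setdefault(snp.locus, 0)
    for snp in testable:
        if snp.p_fdr is not None and snp.p_fdr < alpha:
            counts[snp.locus] += 1
    return snps, counts


# ---------------------------------------------------------------------------
# Topology mapping


_LOOP_LABELS = ["ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3"]


def map_snp_to_topology(
    snp: SnpRecord, tm_spans: list[tuple[int, int]], protein_len: int | None = None
) -> str:
    """Label the SNP's residue by transmembrane topology.

    ``tm_spans`` are half-open residue spans (from the built-in predictor or
    an imported topology). The N-terminus is extracellular (outside) by GPCR
    convention, so loops alternate inside/outside from TM1.
    """
    pos = snp.codon_index
    if protein_len is not None and pos >= protein_len:
        raise ValueError(f"residue {pos} beyond protein of length {protein_len}")
    spans = sorted(tm_spans)
    if protein_len is None and spans and pos >= max(e for _, e in spans) + 10_000:
        raise ValueError("residue position implausibly large")
    for k, (s, e) in enumerate(spans):
        if s <= pos < e:
            label = f"TM{k + 1}"
            break
    else:
        if not spans or pos < spans[0][0]:
            label = "N-term"
        elif pos >= spans[-1][1]:
            label = "C-term"
        else:
            for k in range(len(spans) - 1):
                if spans[k][1] <= pos < spans[k + 1][0]:
                    label = _LOOP_LABELS[k] if k < len(_LOOP_LABELS) else f"loop{k + 1}"
                    break
    snp.topology_domain = label
    return label


def domain_side(label: str) -> str:
    """'inside' / 'outside' / 'membrane' for a topology label (N-term out)."""
    if label.startswith("TM"):
        return "membrane"
    if label in ("N-term", "ECL1", "ECL2", "ECL3") or label == "outside":
        return "outside"
    return "inside"
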