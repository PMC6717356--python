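"""Per-locus diversity, neutrality tests and two-population differentiation.

Conventions (matching the workflow of classical sequence-polymorphism
software):

* missing data: any column containing a character outside {A,C,G,T} (N, gap,
  ambiguity) is excluded entirely from both S and the effective length
  (complete deletion);
* neutrality-test significance comes from the standard neutral coalescent
  conditioned on the observed number of segregating sites (mutations dropped
  uniformly on total branch length), two-tailed with add-one smoothing;
* FST is Hudson/Slatkin/Maddison 1 - Hw/Hb with the two populations
  weighted equally in Hw;
* the nearest-neighbor statistic Snn uses fractional tie splitting and a
  one-tailed label-permutation p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_VALID = frozenset("ACGT")
_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class PopulationAlignment:
    """Equal-length allele sequences with population labels.

    Labels are free strings (e.g. ``basalt``/``chalk`` or ``pop1``/``pop2``).
    """

    locus: str
    ids: list[str]
    seqs: list[str]
    pops: list[str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("alignment has no sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in locus {self.locus}: {lengths}")
        if not (len(self.ids) == len(self.seqs) == len(self.pops)):
            raise ValueError("ids, seqs and pops must be parallel lists")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def population_labels(self) -> list[str]:
        seen: list[str] = []
        for p in self.pops:
            if p not in seen:
                seen.append(p)
        return seen

    def subset(self, pop: str) -> "PopulationAlignment":
        keep = [i for i, p in enumerate(self.pops) if p == pop]
        if not keep:
            raise ValueError(f"no sequences labelled {pop!r}")
        return PopulationAlignment(
            locus=self.locus,
            ids=[self.ids[i] for i in keep],
            seqs=[self.seqs[i] for i in keep],
            pops=[pop] * len(keep),
        )

    def included_columns(self) -> list[int]:
        """Columns free of N/gap/ambiguity in every sequence."""
        cols = []
        for j in range(self.length):
            if all(s[j] in _VALID for s in self.seqs):
                cols.append(j)
        return cols

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        locus: str | None = None,
        population_map: dict[str, str] | None = None,
    ) -> "PopulationAlignment":
        """Read a per-locus multi-FASTA. The population is the ``|pop``
        suffix of each id unless a ``population_map`` (id -> pop) is given."""
        from Bio import SeqIO

        path = Path(path)
        ids, seqs, pops = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
            if population_map is not None:
                if rec.id not in population_map:
                    raise ValueError(f"no population for allele {rec.id!r}")
                pops.append(population_map[rec.id])
            elif "|" in rec.id:
                pops.append(rec.id.rsplit("|", 1)[1])
            else:
                raise ValueError(
                    f"allele {rec.id!r} lacks a '|pop' suffix and no map was given"
                )
        return cls(locus=locus or path.stem, ids=ids, seqs=seqs, pops=pops)


def alignment_from_vcf(
    path: str | Path,
    population_map: dict[str, str],
    locus: str | None = None,
) -> PopulationAlignment:
    """Build a SNP-only alignment from a VCF of phased/unphased genotypes.

    Each diploid sample contributes two allele sequences (suffix ``/1`` and
    ``/2``); columns are the biallelic SNP records in file order, so
    positional statistics (pi, S, FST, Snn) are per-SNP rather than
    per-locus-site. ``population_map`` maps sample name -> population.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in population_map]
    if missing:
        raise ValueError(f"samples without population assignment: {missing}")
    haplotypes: list[list[str]] = [[] for _ in range(2 * len(samples))]
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            continue  # biallelic SNPs only
        alleles = (variant.REF, variant.ALT[0])
        for si, gt in enumerate(variant.genotypes):
            a1, a2 = gt[0], gt[1]
            haplotypes[2 * si].append(alleles[a1] if a1 >= 0 else "N")
            haplotypes[2 * si + 1].append(alleles[a2] if a2 >= 0 else "N")
    ids, seqs, pops = [], [], []
    for si, sample in enumerate(samples):
        pop = population_map[sample]
        for h in (1, 2):
            ids.append(f"{sample}/{h}|{pop}")
            seqs.append("".join(haplotypes[2 * si + (h - 1)]))
            pops.append(pop)
    return PopulationAlignment(
        locus=locus or Path(path).stem, ids=ids, seqs=seqs, pops=pops
    )


def read_population_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: allele id, population label."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        allele, pop = line.split("\t")[:2]
        out[allele] = pop
    return out


# ---------------------------------------------------------------------------
# Column summaries


def _column_counts(aln: PopulationAlignment) -> tuple[list[int], np.ndarray]:
    """(included column indices, per-column base counts [n_cols x 4])."""
    cols = aln.included_columns()
    counts = np.zeros((len(cols), 4), dtype=np.int64)
    for k, j in enumerate(cols):
        for s in aln.seqs:
            counts[k, _BASE_CODE[s[j]]] += 1
    return cols, counts


def segregating_sites(aln: PopulationAlignment) -> tuple[int, list[int]]:
    """Number and positions (original column indices) of segregating sites
    among included columns."""
    cols, counts = _column_counts(aln)
    seg = [(counts[k] > 0).sum() >= 2 for k in range(len(cols))]
    sites = [j for j, s in zip(cols, seg) if s]
    return len(sites), sites


def mean_pairwise_differences(aln: PopulationAlignment) -> float:
    """Average number of differences over all C(n,2) allele pairs, counted
    on included columns."""
    if aln.n < 2:
        raise ValueError("need at least 2 alleles")
    _, counts = _column_counts(aln)
    n = aln.n
    pairs = n * (n - 1) / 2
    same = (counts * (counts - 1) / 2).sum()
    return float((pairs * len(counts) - same) / pairs) if len(counts) else 0.0


def nucleotide_diversity(aln: PopulationAlignment) -> float:
    """Per-site pi: mean pairwise differences / effective length."""
    l_eff = len(aln.included_columns())
    if l_eff == 0:
        return 0.0
    return mean_pairwise_differences(aln) / l_eff


def harmonic_number(n: int) -> float:
    return sum(1.0 / i for i in range(1, n + 1))


def watterson_theta(aln: PopulationAlignment) -> float:
    """Per-site Watterson estimator S / a1 / L_eff."""
    if aln.n < 2:
        raise ValueError("need at least 2 alleles")
    s, _ = segregating_sites(aln)
    l_eff = len(aln.included_columns())
    if l_eff == 0:
        return 0.0
    return s / harmonic_number(aln.n - 1) / l_eff


def _mutation_counts(aln: PopulationAlignment) -> tuple[int, int]:
    """(eta, eta_s): total mutations (bases-1 per column, minimum-change
    parsimony) and singleton mutations (a base observed exactly once)."""
    _, counts = _column_counts(aln)
    eta = eta_s = 0
    for row in counts:
        k = int((row > 0).sum())
        if k < 2:
            continue
        eta += k - 1
        eta_s += min(int((row == 1).sum()), k - 1)
    return eta, eta_s


# ---------------------------------------------------------------------------
# Neutrality statistics (count-level forms shared with the coalescent null)


def tajimas_d_from_counts(n: int, s: int, mean_pairwise: float) -> float:
    """Tajima's D from allele count, segregating sites and the mean number of
    pairwise differences (total, not per site); standard 1989 constants."""
    if s < 1:
        raise ValueError("Tajima's D undefined when S = 0")
    if n < 2:
        raise ValueError("need at least 2 alleles")
    a1 = harmonic_number(n - 1)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return (mean_pairwise - s / a1) / math.sqrt(var)


def fu_li_dstar_from_counts(n: int, eta: int, eta_s: int) -> float:
    """Fu & Li's D* (no outgroup) from total and singleton mutation counts,
    using the corrected 1993 variance constants."""
    if eta < 1:
        raise ValueError("Fu & Li's D* undefined when eta = 0")
    if n < 3:
        raise ValueError("need at least 3 alleles for D*")
    an = harmonic_number(n - 1)
    an1 = an + 1.0 / n
    bn = sum(1.0 / i**2 for i in range(1, n))
    cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / ((n - 1) ** 2)
        + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    nn = n / (n - 1.0)
    v = (nn**2 * bn + an**2 * dn - 2 * n * an * (an + 1) / ((n - 1) ** 2)) / (
        an**2 + bn
    )
    u = nn * (an - nn) - v
    return (nn * eta - an * eta_s) / math.sqrt(u * eta + v * eta * eta)


def tajimas_d(aln: PopulationAlignment) -> float:
    s, _ = segregating_sites(aln)
    return tajimas_d_from_counts(aln.n, s, mean_pairwise_differences(aln))


def fu_li_dstar(aln: PopulationAlignment) -> float:
    eta, eta_s = _mutation_counts(aln)
    return fu_li_dstar_from_counts(aln.n, eta, eta_s)


# ---------------------------------------------------------------------------
# Coalescent null


def simulate_sfs(n: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """One neutral-coalescent replicate conditioned on ``s`` mutations:
    returns the derived-allele count of each mutation (infinite sites)."""
    leaf_counts = [1] * n
    exposure = [0.0] * n
    branches_sz: list[int] = []
    branches_len: list[float] = []
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        for idx in range(k):
            exposure[idx] += t
        i, j = rng.choice(k, size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        branches_sz.extend((leaf_counts[i], leaf_counts[j]))
        branches_len.extend((exposure[i], exposure[j]))
        leaf_counts[i] += leaf_counts[j]
        exposure[i] = 0.0
        del leaf_counts[j], exposure[j]
        k -= 1
    lengths = np.asarray(branches_len)
    probs = lengths / lengths.sum()
    picks = rng.choice(len(branches_sz), size=s, p=probs)
    return np.asarray(branches_sz, dtype=np.int64)[picks]


def statistic_from_sfs(name: str, n: int, derived: np.ndarray) -> float:
    """Evaluate a neutrality statistic on a simulated set of derived counts."""
    s = len(derived)
    if name == "tajima_d":
        mean_pw = float((2.0 * derived * (n - derived)).sum() / (n * (n - 1)))
        return tajimas_d_from_counts(n, s, mean_pw)
    if name == "fu_li_dstar":
        eta_s = int(((derived == 1) | (derived == n - 1)).sum())
        return fu_li_dstar_from_counts(n, s, eta_s)
    raise ValueError(f"unknown statistic {name!r}")


def coalescent_pvalue(
    n: int,
    s: int,
    observed: float,
    statistic: str = "tajima_d",
    reps: int = 10000,
    seed: int = 0,
) -> float:
    """Two-tailed empirical p for an observed neutrality statistic under the
    standard coalescent conditioned on S; add-one smoothed:
    p = min(1, 2 * min(P(sim <= obs), P(sim >= obs)))."""
    if s < 1:
        raise ValueError("p-value undefined when S = 0")
    if reps < 1000:
        raise ValueError("use at least 1000 replicates")
    rng = np.random.default_rng(seed)
    sims = np.empty(reps)
    for r in range(reps):
        sims[r] = statistic_from_sfs(statistic, n, simulate_sfs(n, s, rng))
    p_le = (int((sims <= observed + 1e-12).sum()) + 1) / (reps + 1)
    p_ge = (int((sims >= observed - 1e-12).sum()) + 1) / (reps + 1)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Differentiation


@dataclass
class FstResult:
    fst: float
    defined: bool
    hw: float = float("nan")
    hb: float = float("nan")


def _distance_matrix(aln: PopulationAlignment) -> np.ndarray:
    cols = aln.included_columns()
    mat = np.zeros((aln.n, len(cols)), dtype=np.int8)
    for i, s in enumerate(aln.seqs):
        for k, j in enumerate(cols):
            mat[i, k] = _BASE_CODE[s[j]]
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)


def _two_pop_indices(aln: PopulationAlignment) -> tuple[str, str, np.ndarray, np.ndarray]:
    labels = aln.population_labels()
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 populations, got {labels}")
    pops = np.asarray(aln.pops)
    idx1 = np.flatnonzero(pops == labels[0])
    idx2 = np.flatnonzero(pops == labels[1])
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each population needs at least 2 alleles")
    return labels[0], labels[1], idx1, idx2


def hudson_fst(aln: PopulationAlignment) -> FstResult:
    """FST = 1 - Hw/Hb with populations weighted equally within; undefined
    (``defined=False``) when the locus is monomorphic."""
    _, _, idx1, idx2 = _two_pop_indices(aln)
    s, _ = segregating_sites(aln)
    if s == 0:
        return FstResult(fst=float("nan"), defined=False)
    d = _distance_matrix(aln)

    def _mean_within(idx: np.ndarray) -> float:
        sub = d[np.ix_(idx, idx)]
        m = len(idx)
        return float(sub[np.triu_indices(m, 1)].mean()) if m > 1 else 0.0

    hw = 0.5 * (_mean_within(idx1) + _mean_within(idx2))
    hb = float(d[np.ix_(idx1, idx2)].mean())
    if hb == 0:
        return FstResult(fst=float("nan"), defined=False)
    return FstResult(fst=1.0 - hw / hb, defined=True, hw=hw, hb=hb)


def snn_statistic(d: np.ndarray, labels: np.ndarray) -> float:
    """Hudson's nearest-neighbor statistic from a distance matrix; nearest
    neighbors at tied minimal distance are counted fractionally."""
    n = len(labels)
    total = 0.0
    for i in range(n):
        row = d[i].astype(float).copy()
        row[i] = np.inf
        m = row.min()
        nn = np.flatnonzero(row == m)
        total += (labels[nn] == labels[i]).mean()
    return total / n


def _nn_weight_matrix(d: np.ndarray) -> np.ndarray:
    """W[i, j] = fractional weight of j among i's nearest neighbors."""
    n = d.shape[0]
    w = np.zeros((n, n))
    for i in range(n):
        row = d[i].astype(float).copy()
        row[i] = np.inf
        nn = np.flatnonzero(row == row.min())
        w[i, nn] = 1.0 / len(nn)
    return w


def snn_test(
    aln: PopulationAlignment, reps: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """(Snn, one-tailed permutation p). Permutations preserve population
    sizes; p = (1 + #{perm >= observed}) / (1 + reps).

    Since label permutations leave the distance matrix (hence every
    nearest-neighbor set) unchanged, Snn under a labelling z reduces to the
    quadratic form (z'Wz + (1-z)'W(1-z)) / n, which is evaluated for all
    permutations in one vectorized pass.
    """
    _two_pop_indices(aln)
    d = _distance_matrix(aln)
    labels = np.asarray(aln.pops)
    observed = snn_statistic(d, labels)
    w = _nn_weight_matrix(d)
    n = len(labels)
    z = (labels == aln.population_labels()[0]).astype(float)
    rng = np.random.default_rng(seed)
    zs = rng.permuted(np.tile(z, (reps, 1)), axis=1)
    vals = ((zs @ w) * zs).sum(axis=1)
    vals += (((1 - zs) @ w) * (1 - zs)).sum(axis=1)
    vals /= n
    count = int((vals >= observed - 1e-12).sum())
    return observed, (count + 1) / (reps + 1)


# ---------------------------------------------------------------------------
# Multiple testing


def fdr_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


# ---------------------------------------------------------------------------
# Per-locus convenience


@dataclass
class NeutralityResult:
    n: int
    s: int
    pi: float
    theta_w: float
    tajima_d: float | None
    fu_li_dstar: float | None
    p_tajima: float | None
    p_fuli: float | None
    reps: int
    seed: int


def neutrality_tests(
    aln: PopulationAlignment, reps: int = 10000, seed: int = 0
) -> NeutralityResult:
    """Diversity plus Tajima's D and Fu & Li's D* with coalescent p-values
    for a single-population alignment (undefined stats flagged as None)."""
    s, _ = segregating_sites(aln)
    pi = nucleotide_diversity(aln)
    theta = watterson_theta(aln)
    if s == 0:
        return NeutralityResult(aln.n, 0, pi, theta, None, None, None, None, reps, seed)
    d = tajimas_d(aln)
    eta, eta_s = _mutation_counts(aln)
    dstar = fu_li_dstar_from_counts(aln.n, eta, eta_s) if aln.n >= 3 else None
    p_d = coalescent_pvalue(aln.n, s, d, "tajima_d", reps, seed)
    p_dstar = (
        coalescent_pvalue(aln.n, eta, dstar, "fu_li_dstar", reps, seed + 1)
        if dstar is not None
        else None
    )
    return NeutralityResult(aln.n, s, pi, theta, d, dstar, p_d, p_dstar, reps, seed)
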