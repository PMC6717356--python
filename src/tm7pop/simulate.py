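"""Seeded generators for every input the pipeline consumes.

* genomes with implanted intact / partial / pseudogene / short-complete
  receptor ORFs among decoy ORFs and random background, plus a truth table;
* Brownian-motion traits on a dated tree, optionally with a lifestyle shift;
* two-population coalescent allele alignments with a clean split and
  infinite-sites mutation.

All generators are pure functions of (seed, parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .mining.genome import GenomeAssembly, revcomp
from .mining.pipeline import load_reference_panel, query_panel_from_reference
from .popgen import PopulationAlignment

# ---------------------------------------------------------------------------
# Back-translation

_CODONS_FOR = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "Y": ["TAT", "TAC"],
    "C": ["TGT", "TGC"], "W": ["TGG"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "N": ["AAT", "AAC"], "K": ["AAA", "AAG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "A": ["GCT", "GCC", "GCA", "GCG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
}

STOPS = ["TAA", "TAG", "TGA"]


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice per residue (no stop appended)."""
    codons = []
    for aa in protein.upper().rstrip("*"):
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _random_dna(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Genome simulation


@dataclass
class ImplantedGene:
    name: str
    scaffold: str
    start: int
    end: int
    strand: str
    category: str  # intact | partial | pseudogene | short_complete | decoy
    source_protein: str
    disruptions: list[str] = field(default_factory=list)
    truncation_cause: str = "none"


@dataclass
class GenomeTruth:
    seed: int
    genes: list[ImplantedGene] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["name\tscaffold\tstart\tend\tstrand\tcategory\tdisruptions\ttruncation_cause"]
        for g in self.genes:
            lines.append(
                f"{g.name}\t{g.scaffold}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{g.category}\t{','.join(g.disruptions) or 'none'}\t{g.truncation_cause}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def by_category(self, category: str) -> list[ImplantedGene]:
        return [g for g in self.genes if g.category == category]


def _gene_dna(protein: str, rng: np.random.Generator) -> str:
    """ATG + body + stop codon for a panel protein (which begins with M)."""
    body = back_translate(protein, rng)
    return body + STOPS[rng.integers(3)]


def simulate_genome(
    seed: int,
    n_intact: int = 3,
    n_partial: int = 2,
    n_pseudo: int = 4,
    n_short: int = 1,
    n_decoys: int = 2,
    scaffold_len: int = 200_000,
    spacing: int = 400,
) -> tuple[GenomeAssembly, GenomeTruth]:
    """Implant receptor ORFs of every category plus decoy ORFs into random
    background on one scaffold; deterministic given the seed.

    Partial genes cycle through truncation causes: one at the scaffold start
    (5' lost to the edge), one at the scaffold end, others truncated by an
    implanted >=10-N assembly gap.
    """
    if min(n_intact, n_partial, n_pseudo, n_short, n_decoys) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    panel = load_reference_panel()
    receptors = [(pid, seq) for pid, seq in query_panel_from_reference(panel, "v1r")]
    decoys = [(pid, seq) for pid, seq in query_panel_from_reference(panel, "decoy")]

    pieces: list[tuple[str, str, ImplantedGene | None]] = []  # (kind, dna, truth)
    gene_no = 0

    def _next_receptor() -> tuple[str, str]:
        nonlocal gene_no
        pid, seq = receptors[gene_no % len(receptors)]
        gene_no += 1
        return pid, seq

    for i in range(n_intact):
        pid, prot = _next_receptor()
        dna = _gene_dna(prot, rng)
        pieces.append(("mid", dna, ImplantedGene(
            name=f"intact{i}", scaffold="scf1", start=-1, end=-1, strand="?",
            category="intact", source_protein=pid)))

    for i in range(n_short):
        pid, prot = _next_receptor()
        frag = prot[: 150 + int(rng.integers(0, 60))]  # < 270 codons
        dna = _gene_dna(frag, rng)
        pieces.append(("mid", dna, ImplantedGene(
            name=f"short{i}", scaffold="scf1", start=-1, end=-1, strand="?",
            category="short_complete", source_protein=pid)))

    for i in range(n_pseudo):
        pid, prot = _next_receptor()
        dna = _gene_dna(prot, rng)
        n_edits = 1 + int(rng.integers(0, 3))
        disruptions = []
        # edits confined to the middle third so both flanks stay alignable
        n_cod = len(dna) // 3
        codon_picks = sorted(
            rng.choice(np.arange(n_cod // 3, 2 * n_cod // 3), size=n_edits, replace=False)
        )
        shift = 0
        for ci in codon_picks:
            pos = 3 * ci + shift
            if rng.random() < 0.5:
                dna = dna[:pos] + STOPS[rng.integers(3)] + dna[pos + 3 :]
                disruptions.append(f"nonsense@{pos}")
            else:
                if rng.random() < 0.5:
                    dna = dna[:pos] + dna[pos + 1 :]
                    shift -= 1
                else:
                    dna = dna[:pos] + "ACGT"[rng.integers(4)] + dna[pos:]
                    shift += 1
                disruptions.append(f"frameshift@{pos}")
        pieces.append(("mid", dna, ImplantedGene(
            name=f"pseudo{i}", scaffold="scf1", start=-1, end=-1, strand="?",
            category="pseudogene", source_protein=pid, disruptions=disruptions)))

    for i in range(n_decoys):
        pid, prot = decoys[i % len(decoys)]
        dna = _gene_dna(prot, rng)
        pieces.append(("mid", dna, ImplantedGene(
            name=f"decoy{i}", scaffold="scf1", start=-1, end=-1, strand="?",
            category="decoy", source_protein=pid)))

    # Partial genes: cut at a codon boundary, losing the start or the stop.
    partials: list[tuple[str, str, ImplantedGene]] = []
    for i in range(n_partial):
        pid, prot = _next_receptor()
        dna = _gene_dna(prot, rng)
        cut = 3 * (len(dna) // 6)  # lose roughly half, codon-aligned
        # a 5'-truncated fragment must not open on an in-frame ATG, or the
        # miner would correctly see a complete (short) ORF instead
        while dna[cut : cut + 3] == "ATG":
            cut += 3
        if i == 0:
            partials.append(("edge_start", dna[cut:], ImplantedGene(
                name=f"partial{i}", scaffold="scf1", start=-1, end=-1, strand="+",
                category="partial", source_protein=pid,
                truncation_cause="scaffold_edge")))
        elif i == 1 and n_partial > 2:
            partials.append(("edge_end", dna[:-cut], ImplantedGene(
                name=f"partial{i}", scaffold="scf1", start=-1, end=-1, strand="+",
                category="partial", source_protein=pid,
                truncation_cause="scaffold_edge")))
        else:
            lost_start = bool(rng.random() < 0.5)
            trimmed = dna[cut:] if lost_start else dna[:-cut]
            kind = "gap_start" if lost_start else "gap_end"
            partials.append((kind, trimmed, ImplantedGene(
                name=f"partial{i}", scaffold="scf1", start=-1, end=-1, strand="+",
                category="partial", source_protein=pid,
                truncation_cause="assembly_gap")))

    # Assemble the scaffold.
    mid_pieces = pieces + [p for p in partials if p[0].startswith("gap")]
    rng.shuffle(mid_pieces := list(mid_pieces))
    edge_start = [p for p in partials if p[0] == "edge_start"]
    edge_end = [p for p in partials if p[0] == "edge_end"]

    gap_run = "N" * 50
    need = sum(len(p[1]) + spacing + len(gap_run) for p in mid_pieces)
    need += sum(len(p[1]) + spacing for p in edge_start + edge_end)
    if need + 2 * spacing > scaffold_len:
        raise ValueError("genes exceed scaffold capacity; increase scaffold_len")

    chunks: list[str] = []
    truth = GenomeTruth(seed=seed)
    cursor = 0

    def _emit(dna: str, info: ImplantedGene | None, strand: str) -> None:
        nonlocal cursor
        out = dna if strand == "+" else revcomp(dna)
        chunks.append(out)
        if info is not None:
            info.start, info.end, info.strand = cursor, cursor + len(out), strand
            truth.genes.append(info)
        cursor += len(out)

    def _emit_background(length: int) -> None:
        nonlocal cursor
        chunks.append("".join(_BASES[_random_dna(length, rng)]))
        cursor += length

    for kind, dna, info in edge_start:
        _emit(dna, info, "+")  # starts exactly at the scaffold edge
        _emit_background(spacing)

    n_mid = len(mid_pieces)
    slack = scaffold_len - need - (spacing if not edge_start else 0)
    pad = max(spacing, slack // max(n_mid + 1, 1))
    for kind, dna, info in mid_pieces:
        _emit_background(pad)
        if kind == "gap_start":
            chunks.append(gap_run)
            cursor += len(gap_run)
            _emit(dna, info, "+")
        elif kind == "gap_end":
            _emit(dna, info, "+")
            chunks.append(gap_run)
            cursor += len(gap_run)
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            _emit(dna, info, strand)

    if edge_end:
        _emit_background(max(spacing, scaffold_len - cursor - len(edge_end[0][1])))
        for kind, dna, info in edge_end:
            _emit(dna, info, "+")  # ends exactly at the scaffold edge
    else:
        _emit_background(max(0, scaffold_len - cursor))

    genome = GenomeAssembly(records=[("scf1", "".join(chunks))])
    return genome, truth


# ---------------------------------------------------------------------------
# Brownian traits


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float,
    seed: int,
    lifestyle_effect: float = 0.0,
    lifestyle: dict[str, int] | None = None,
    root_value: float = 0.0,
) -> dict[str, float]:
    """Brownian motion along branches: increments ~ Normal(0, sigma2 * bl).

    A positive ``lifestyle_effect`` subtracts that amount from tips coded 0
    (subterranean), creating a true positive count-vs-code correlation.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            bl = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(sigma2 * bl)) if sigma2 > 0 and bl > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            v = values[id(node)]
            label = node.taxon.label
            if lifestyle_effect and lifestyle is not None and lifestyle.get(label, 1) == 0:
                v -= lifestyle_effect
            out[label] = v
    return out


# ---------------------------------------------------------------------------
# Two-population coalescent


@dataclass
class TwoPopTruth:
    seed: int
    n1: int
    n2: int
    length: int
    theta: float
    split_time: float
    n_mutations: int = 0


def simulate_two_pop(
    n1: int,
    n2: int,
    L: int,
    theta: float,
    split_time: float,
    seed: int,
    labels: tuple[str, str] = ("pop1", "pop2"),
    locus: str = "sim",
) -> tuple[PopulationAlignment, TwoPopTruth]:
    """Clean-split two-population coalescent with infinite-sites mutation.

    Time is in units of 2N generations; within-deme pairs coalesce at rate 1.
    ``theta`` is the per-locus population mutation rate (mutations arise as
    Poisson(theta/2 * total branch length)); ``split_time=0`` is panmixia.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 alleles per population")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if split_time < 0:
        raise ValueError("split_time must be non-negative")
    rng = np.random.default_rng(seed)

    n = n1 + n2
    # lineage state: (leaf index set, birth time); two demes until split_time
    demes: list[list[tuple[frozenset, float]]] = [
        [(frozenset([i]), 0.0) for i in range(n1)],
        [(frozenset([n1 + i]), 0.0) for i in range(n2)],
    ]
    branches: list[tuple[frozenset, float]] = []  # (leaf set, length)
    t = 0.0

    def _coalesce(pool: list, time: float, rng: np.random.Generator) -> None:
        i, j = rng.choice(len(pool), size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        (set_i, born_i), (set_j, born_j) = pool[i], pool[j]
        branches.append((set_i, time - born_i))
        branches.append((set_j, time - born_j))
        pool[i] = (set_i | set_j, time)
        del pool[j]

    while True:
        k1, k2 = len(demes[0]), len(demes[1])
        rate = k1 * (k1 - 1) / 2 + k2 * (k2 - 1) / 2
        if rate == 0:
            t = split_time
            break
        dt = rng.exponential(1.0 / rate)
        if t + dt >= split_time:
            t = split_time
            break
        t += dt
        which = 0 if rng.random() < (k1 * (k1 - 1) / 2) / rate else 1
        _coalesce(demes[which], t, rng)

    pool = demes[0] + demes[1]
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential(2.0 / (k * (k - 1)))
        _coalesce(pool, t, rng)

    lengths = np.asarray([ln for _, ln in branches])
    total = lengths.sum()
    n_mut = int(rng.poisson(theta / 2.0 * total))
    if n_mut > L:
        raise ValueError(
            f"{n_mut} mutations exceed {L} sites; increase L or decrease theta"
        )

    ancestral = _random_dna(L, rng)
    matrix = np.tile(ancestral, (n, 1))
    if n_mut > 0:
        probs = lengths / total
        branch_picks = rng.choice(len(branches), size=n_mut, p=probs)
        columns = rng.choice(L, size=n_mut, replace=False)
        for b, col in zip(branch_picks, columns):
            carriers = list(branches[b][0])
            derived = (ancestral[col] + 1 + rng.integers(3)) % 4
            matrix[carriers, col] = derived

    seqs = ["".join(_BASES[row]) for row in matrix]
    ids = [f"{labels[0]}_{i}|{labels[0]}" for i in range(n1)] + [
        f"{labels[1]}_{i}|{labels[1]}" for i in range(n2)
    ]
    pops = [labels[0]] * n1 + [labels[1]] * n2
    aln = PopulationAlignment(locus=locus, ids=ids, seqs=seqs, pops=pops)
    truth = TwoPopTruth(seed, n1, n2, L, theta, split_time, n_mut)
    return aln, truth
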