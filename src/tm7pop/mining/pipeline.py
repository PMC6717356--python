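"""End-to-end mining of one genome: search, filter, merge, extend, classify.

Also hosts the bundled reference panel (receptor family + decoy GPCR-like
proteins) and the GFF3/FASTA/TSV writers.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

from .genome import GenomeAssembly, QueryPanel
from .orf import GeneCandidate, extend_to_orf, DEFAULT_WINDOW_NT, DEFAULT_GAP_MIN_N
from .search import (
    HomologyHit,
    translated_search,
    filter_hits,
    merge_hits,
)
from .tm import predict_tm_helices, MIN_PROTEIN_LEN
from .classify import (
    classify_candidate,
    confirm_identity,
    DEFAULT_MIN_CODONS,
    DEFAULT_MIN_NT,
)


def load_reference_panel() -> QueryPanel:
    """The bundled panel: receptor-family proteins (label ``v1r``) plus decoy
    GPCR-like proteins (label ``decoy``)."""
    ref = importlib.resources.files("tm7pop") / "data" / "reference_panel.fa"
    with importlib.resources.as_file(ref) as path:
        return QueryPanel.from_fasta(path)


def query_panel_from_reference(reference: QueryPanel, label: str = "v1r") -> QueryPanel:
    """Subset of the reference panel carrying the positive label, for use as
    search queries."""
    keep = [(pid, seq) for pid, seq in reference if QueryPanel.label_of(pid) == label]
    return QueryPanel(proteins=keep)


def mine_genome(
    genome: GenomeAssembly,
    queries: QueryPanel,
    *,
    reference: QueryPanel | None = None,
    hits: list[HomologyHit] | None = None,
    evalue_cutoff: float = 1e-5,
    min_hit_nt: int = DEFAULT_MIN_NT,
    merge_dist: int = 50,
    window_nt: int = DEFAULT_WINDOW_NT,
    gap_min_n: int = DEFAULT_GAP_MIN_N,
    min_codons: int = DEFAULT_MIN_CODONS,
    require_tm: bool = True,
) -> tuple[list[GeneCandidate], dict]:
    """Run the full mining pipeline on one genome.

    ``hits`` may carry externally imported search results; otherwise the
    built-in engine is used. When ``reference`` is given, candidates whose
    best reference alignment is not receptor-labelled are dropped.

    Returns (candidates, stage log).
    """
    log: dict = {}
    if hits is None:
        hits = translated_search(genome, queries, evalue_cutoff)
    log["hits_raw"] = len(hits)
    hits = filter_hits(hits, min_hit_nt)
    log["hits_after_length_filter"] = len(hits)
    loci = merge_hits(hits, merge_dist)
    log["loci_merged"] = len(loci)

    candidates: list[GeneCandidate] = []
    dropped = {"identity": 0, "unclassifiable": 0}
    for locus in loci:
        cand = extend_to_orf(genome, locus, window_nt, gap_min_n)
        if cand.protein and len(cand.protein) >= MIN_PROTEIN_LEN:
            cand.tm_count, cand.tm_spans = predict_tm_helices(cand.protein)
        classify_candidate(cand, min_codons=min_codons, require_tm=require_tm)
        if cand.category is None:
            dropped["unclassifiable"] += 1
            continue
        if reference is not None and not confirm_identity(cand, reference):
            dropped["identity"] += 1
            continue
        candidates.append(cand)
    log["dropped"] = dropped
    log["candidates"] = len(candidates)

    # Nomenclature: best-query stem + ordinal, in genomic order.
    counters: dict[str, int] = {}
    for cand in sorted(candidates, key=lambda c: (c.scaffold, c.start)):
        stem = cand.best_query.split("|")[0]
        counters[stem] = counters.get(stem, 0) + 1
        cand.name = f"{stem}-{counters[stem]}"
    return candidates, log


def write_gff3(candidates: list[GeneCandidate], path: str | Path) -> None:
    """GFF3 with 1-based inclusive coordinates; attributes carry category,
    disruptions and tm_count."""
    lines = ["##gff-version 3"]
    for c in sorted(candidates, key=lambda c: (c.scaffold, c.start)):
        attrs = [
            f"ID={c.name}",
            f"category={c.category}",
            f"disruptions={','.join(str(d) for d in c.disruptions) or 'none'}",
            f"tm_count={c.tm_count}",
            f"truncation_cause={c.truncation_cause}",
        ]
        lines.append(
            "\t".join(
                [
                    c.scaffold,
                    "tm7pop",
                    "gene",
                    str(c.start + 1),
                    str(c.end),
                    f"{c.evalue:.3g}",
                    c.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_candidate_fastas(
    candidates: list[GeneCandidate], cds_path: str | Path, protein_path: str | Path
) -> None:
    cds_lines, prot_lines = [], []
    for c in sorted(candidates, key=lambda c: (c.scaffold, c.start)):
        cds_lines.append(f">{c.name} category={c.category}\n{c.cds}")
        if c.protein:
            prot_lines.append(f">{c.name} category={c.category}\n{c.protein}")
    Path(cds_path).write_text("\n".join(cds_lines) + "\n" if cds_lines else "")
    Path(protein_path).write_text("\n".join(prot_lines) + "\n" if prot_lines else "")


def write_summary_tsv(summary, path: str | Path) -> None:
    df = summary.table.copy()
    df.loc["__mean__"] = summary.mean
    df.loc["__median__"] = summary.median
    df.to_csv(path, sep="\t", index_label="species")
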