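"""Translated homology search of protein queries against genome assemblies.

The built-in engine runs local Smith-Waterman (BLOSUM62, affine gaps: a gap
of length k costs 11 + k) of every query against all six translation frames
of every scaffold, using Biopython's C PairwiseAligner. Long frames are
scanned in overlapping windows so that multiple gene copies on one scaffold
are all reported. Significance uses Karlin-Altschul statistics with the
standard gapped parameters for BLOSUM62(11,1); the effective database size
is the total genome length times two strands.

An importer for external translated-search results in 12-column tabular
format is provided as the production-scale route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .genome import GenomeAssembly, QueryPanel
from .translate import six_frame_translate

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
# (NCBI BLAST defaults).
KA_LAMBDA = 0.267
KA_K = 0.041

GAP_OPEN = 11  # cost of opening a gap (first residue costs open + extend)
GAP_EXTEND = 1

DEFAULT_WINDOW_AA = 600
DEFAULT_STEP_AA = 300
DEFAULT_SEED_LEN = 5


@dataclass(frozen=True)
class HomologyHit:
    """One local alignment of a query protein to a genomic region.

    Coordinates are 0-based half-open on the forward strand; ``frame`` is
    strand-local (offset of codon starts within the strand-oriented
    sequence, 0-2).
    """

    scaffold: str
    start: int
    end: int
    strand: str
    frame: int
    query: str
    score: float
    bits: float
    evalue: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit start must precede end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class Locus:
    """A merged candidate locus: union of overlapping/nearby same-strand hits."""

    scaffold: str
    start: int
    end: int
    strand: str
    best_evalue: float
    best_query: str
    anchor_frame: int
    fragments: list[HomologyHit] = field(default_factory=list)

    @property
    def frames(self) -> set[int]:
        return {h.frame for h in self.fragments}


def make_aligner() -> Align.PairwiseAligner:
    """Local aligner with the engine's scoring scheme."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # PairwiseAligner charges open_gap_score for the first gapped residue, so
    # a length-k gap costs 11 + k with these values (BLAST convention).
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def evalue_from_score(score: float, query_len: int, db_len_nt: int) -> tuple[float, float]:
    """Karlin-Altschul (bits, E-value) for a raw alignment score.

    ``db_len_nt`` is the total nucleotide length searched; two strands are
    counted, i.e. the effective search space is ``query_len * 2 * db_len_nt``.
    """
    bits = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)
    evalue = query_len * 2 * db_len_nt * 2.0 ** (-bits)
    return bits, evalue


def _window_has_seed(window: str, seeds: set[str], k: int) -> bool:
    return any(window[i : i + k] in seeds for i in range(len(window) - k + 1))


def _frame_geometry(frame_index: int, scaffold_len: int) -> tuple[str, int]:
    strand = "+" if frame_index < 3 else "-"
    return strand, frame_index % 3


def _to_genomic(
    aa_start: int, aa_end: int, frame_index: int, scaffold_len: int
) -> tuple[int, int]:
    strand, f = _frame_geometry(frame_index, scaffold_len)
    s, e = f + 3 * aa_start, f + 3 * aa_end
    if strand == "+":
        return s, e
    return scaffold_len - e, scaffold_len - s


def translated_search(
    genome: GenomeAssembly,
    panel: QueryPanel,
    evalue_cutoff: float = 1e-5,
    *,
    window_aa: int = DEFAULT_WINDOW_AA,
    step_aa: int = DEFAULT_STEP_AA,
    seed_len: int | None = DEFAULT_SEED_LEN,
) -> list[HomologyHit]:
    """Search every panel protein against all six frames of every scaffold.

    Windows without an exact ``seed_len``-mer match to the query are skipped
    (BLAST-like seeding); pass ``seed_len=None`` to disable and force full
    Smith-Waterman everywhere (used by the oracle-equality tests).
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    if len(panel) == 0:
        raise ValueError("empty query panel")

    aligner = make_aligner()
    db_len = genome.total_length
    seeds = {}
    if seed_len is not None:
        for qid, qseq in panel:
            seeds[qid] = {
                qseq[i : i + seed_len] for i in range(len(qseq) - seed_len + 1)
            }

    hits: dict[tuple, HomologyHit] = {}
    for scaffold_id, seq in genome:
        frames = six_frame_translate(seq)
        for fi, prot in enumerate(frames):
            if not prot:
                continue
            starts = list(range(0, max(len(prot) - (window_aa - step_aa), 1), step_aa))
            for w_start in starts:
                window = prot[w_start : w_start + window_aa]
                for qid, qseq in panel:
                    if seed_len is not None and not _window_has_seed(
                        window, seeds[qid], seed_len
                    ):
                        continue
                    hit = _align_window(
                        aligner, window, qseq, qid, w_start, fi,
                        scaffold_id, len(seq), db_len, evalue_cutoff,
                    )
                    if hit is None:
                        continue
                    key = (hit.scaffold, hit.strand, hit.frame, hit.start, hit.end, hit.query)
                    prev = hits.get(key)
                    if prev is None or hit.evalue < prev.evalue:
                        hits[key] = hit
    out = sorted(
        hits.values(), key=lambda h: (h.scaffold, h.strand, h.start, h.end, h.query)
    )
    return out


def _align_window(
    aligner, window, qseq, qid, w_start, frame_index,
    scaffold_id, scaffold_len, db_len, evalue_cutoff,
):
    if len(window) == 0 or len(qseq) == 0:
        return None
    alignments = aligner.align(window, qseq)
    try:
        best = alignments[0]
    except IndexError:
        return None
    score = best.score
    bits, evalue = evalue_from_score(score, len(qseq), db_len)
    if evalue > evalue_cutoff:
        return None
    t_blocks = best.aligned[0]
    aa_start = int(t_blocks[0][0]) + w_start
    aa_end = int(t_blocks[-1][1]) + w_start
    g_start, g_end = _to_genomic(aa_start, aa_end, frame_index, scaffold_len)
    strand, frame = _frame_geometry(frame_index, scaffold_len)
    return HomologyHit(
        scaffold=scaffold_id, start=g_start, end=g_end, strand=strand,
        frame=frame, query=qid, score=score, bits=bits, evalue=evalue,
    )


def filter_hits(hits: list[HomologyHit], min_nt: int = 300) -> list[HomologyHit]:
    """Drop hits whose genomic span is shorter than ``min_nt``; order kept."""
    if min_nt <= 0:
        raise ValueError("min_nt must be positive")
    return [h for h in hits if h.span >= min_nt]


def merge_hits(hits: list[HomologyHit], merge_dist: int = 50) -> list[Locus]:
    """Union-merge same-scaffold, same-strand hits that overlap or lie within
    ``merge_dist`` nt of each other into one locus per gene copy.

    The anchor frame and best query of each locus come from its
    lowest-e-value fragment.
    """
    ordered = sorted(hits, key=lambda h: (h.scaffold, h.strand, h.start, h.end))
    loci: list[Locus] = []
    current: list[HomologyHit] = []

    def _flush() -> None:
        if not current:
            return
        best = min(current, key=lambda h: (h.evalue, -h.score))
        loci.append(
            Locus(
                scaffold=current[0].scaffold,
                start=min(h.start for h in current),
                end=max(h.end for h in current),
                strand=current[0].strand,
                best_evalue=best.evalue,
                best_query=best.query,
                anchor_frame=best.frame,
                fragments=list(current),
            )
        )

    for hit in ordered:
        if current and (
            hit.scaffold != current[0].scaffold
            or hit.strand != current[0].strand
            or hit.start > max(h.end for h in current) + merge_dist
        ):
            _flush()
            current = []
        current.append(hit)
    _flush()
    return loci


BLAST_TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | Path, genome: GenomeAssembly) -> list[HomologyHit]:
    """Import external translated-search hits (12-column tabular output).

    Subject coordinates are 1-based nucleotide positions; reverse-strand hits
    have sstart > send. The genome is needed to recover strand-local frames.
    """
    hits = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"expected 12 tab-separated columns, got {len(fields)}")
        rec = dict(zip(BLAST_TABULAR_COLUMNS, fields))
        sstart, send = int(rec["sstart"]), int(rec["send"])
        scaffold = rec["sseqid"]
        scaffold_len = len(genome[scaffold])
        if send >= sstart:
            strand, start, end = "+", sstart - 1, send
            frame = start % 3
        else:
            strand, start, end = "-", send - 1, sstart
            frame = (scaffold_len - end) % 3
        bits = float(rec["bitscore"])
        hits.append(
            HomologyHit(
                scaffold=scaffold, start=start, end=end, strand=strand,
                frame=frame, query=rec["qseqid"], score=bits, bits=bits,
                evalue=float(rec["evalue"]),
            )
        )
    return sorted(hits, key=lambda h: (h.scaffold, h.strand, h.start, h.end, h.query))
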