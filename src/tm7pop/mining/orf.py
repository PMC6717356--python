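"""In-frame extension of merged loci to complete ORFs.

Walks outward from a merged hit locus on its anchor reading frame: upstream
to the nearest in-frame ATG (stopping at an in-frame stop codon, an assembly
gap, or the scaffold edge) and downstream to the nearest in-frame stop.
Internal in-frame stops become nonsense disruptions; merged fragments whose
frames disagree with the anchor frame become frameshift disruptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GenomeAssembly, revcomp
from .translate import translate_cds
from .search import Locus

STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_WINDOW_NT = 3000
DEFAULT_GAP_MIN_N = 10


@dataclass
class Disruption:
    kind: str  # "nonsense" | "frameshift"
    offset: int  # 0-based nt offset of the affected codon within the cds

    def __str__(self) -> str:
        return f"{self.kind}@{self.offset}"


@dataclass
class GeneCandidate:
    """A mined locus after ORF extension (and later, classification)."""

    scaffold: str
    start: int  # forward-strand genomic, 0-based half-open
    end: int
    strand: str
    cds: str  # strand-oriented; includes the stop codon when has_stop
    protein: str
    has_start: bool
    has_stop: bool
    disruptions: list[Disruption] = field(default_factory=list)
    truncation_cause: str = "none"  # none | scaffold_edge | assembly_gap
    tm_count: int = -1  # -1 = not yet predicted
    tm_spans: list[tuple[int, int]] = field(default_factory=list)
    category: str | None = None
    name: str = ""
    best_query: str = ""
    evalue: float = float("nan")

    @property
    def n_codons(self) -> int:
        """Coding codons, excluding the terminal stop codon if present."""
        n = len(self.cds) // 3
        return n - 1 if self.has_stop else n

    @property
    def cds_len(self) -> int:
        return len(self.cds)


def _gap_run_length(seq: str, pos: int) -> int:
    """Length of the N run covering any N within seq[pos:pos+3]."""
    best = 0
    for i in range(pos, min(pos + 3, len(seq))):
        if seq[i] != "N":
            continue
        lo = i
        while lo > 0 and seq[lo - 1] == "N":
            lo -= 1
        hi = i
        while hi + 1 < len(seq) and seq[hi + 1] == "N":
            hi += 1
        best = max(best, hi - lo + 1)
    return best


def extend_to_orf(
    genome: GenomeAssembly,
    locus: Locus,
    window_nt: int = DEFAULT_WINDOW_NT,
    gap_min_n: int = DEFAULT_GAP_MIN_N,
) -> GeneCandidate:
    """Extend a merged locus to a candidate ORF (category left unset)."""
    scaffold_seq = genome[locus.scaffold]
    L = len(scaffold_seq)
    if not (0 <= locus.start < locus.end <= L):
        raise ValueError(
            f"locus {locus.start}-{locus.end} outside scaffold bounds (len {L})"
        )

    # Work in strand space: coordinates along the coding strand.
    if locus.strand == "+":
        s = scaffold_seq
        s_start, s_end = locus.start, locus.end
    else:
        s = revcomp(scaffold_seq)
        s_start, s_end = L - locus.end, L - locus.start
    frame = locus.anchor_frame

    # Snap locus boundaries onto the anchor codon grid.
    a0 = s_start - ((s_start - frame) % 3)
    if a0 < 0:
        a0 += 3
    e0 = s_end + ((frame - s_end) % 3)
    e0 = min(e0, frame + 3 * ((L - frame) // 3))

    truncation_cause = "none"

    # Upstream: nearest in-frame ATG before any in-frame stop.
    has_start = False
    cds_start = a0
    pos = a0
    while pos >= 0 and pos >= a0 - window_nt:
        codon = s[pos : pos + 3]
        if "N" in codon and _gap_run_length(s, pos) >= gap_min_n:
            truncation_cause = "assembly_gap"
            break
        if codon == "ATG":
            has_start = True
            cds_start = pos
            break
        if codon in STOP_CODONS and pos < a0:
            break
        cds_start = pos
        pos -= 3
    else:
        if pos < 0:
            truncation_cause = "scaffold_edge"

    # Downstream: nearest in-frame stop at or beyond the locus end.
    has_stop = False
    cds_end = e0
    pos = e0
    while pos + 3 <= L and pos + 3 <= e0 + window_nt:
        codon = s[pos : pos + 3]
        if "N" in codon and _gap_run_length(s, pos) >= gap_min_n:
            truncation_cause = "assembly_gap"
            break
        cds_end = pos + 3
        if codon in STOP_CODONS:
            has_stop = True
            break
        pos += 3
    else:
        if pos + 3 > L and truncation_cause == "none":
            truncation_cause = "scaffold_edge"

    cds = s[cds_start:cds_end]

    disruptions: list[Disruption] = []
    # Nonsense: in-frame stops strictly inside the cds (terminal stop excluded).
    n_codons_total = len(cds) // 3
    last = n_codons_total - 1 if has_stop else n_codons_total
    for ci in range(last):
        if cds[3 * ci : 3 * ci + 3] in STOP_CODONS:
            disruptions.append(Disruption("nonsense", 3 * ci))
    # Also look for a stop codon inside the hit region that precedes cds_start
    # being impossible by construction; nothing to do.

    # Frameshift: merged fragments whose frame disagrees with the anchor.
    seen_frames = {frame}
    for frag in sorted(locus.fragments, key=lambda h: h.start):
        if frag.frame not in seen_frames:
            seen_frames.add(frag.frame)
            if locus.strand == "+":
                frag_s = frag.start
            else:
                frag_s = L - frag.end
            offset = max(0, frag_s - cds_start)
            offset -= offset % 3
            disruptions.append(Disruption("frameshift", offset))
    disruptions.sort(key=lambda d: d.offset)

    clean = not disruptions
    protein = ""
    if clean:
        coding = cds[: 3 * last] if has_stop else cds
        protein = translate_cds(coding)

    if locus.strand == "+":
        g_start, g_end = cds_start, cds_end
    else:
        g_start, g_end = L - cds_end, L - cds_start

    return GeneCandidate(
        scaffold=locus.scaffold,
        start=g_start,
        end=g_end,
        strand=locus.strand,
        cds=cds,
        protein=protein,
        has_start=has_start,
        has_stop=has_stop,
        disruptions=disruptions,
        truncation_cause=truncation_cause,
        best_query=locus.best_query,
        evalue=locus.best_evalue,
    )
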