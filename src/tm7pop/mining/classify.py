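"""Category assignment, identity confirmation and repertoire summaries.

Classification rules:

* intact       -- >=270 coding codons (stop excluded), start AND stop codon,
                  no disruptions, seven predicted transmembrane helices;
* partial      -- no disruptions, exactly one of start/stop, cds > 300 nt,
                  and the missing end attributable to a scaffold edge or an
                  assembly gap;
* pseudogene   -- cds > 300 nt with >=1 nonsense/frameshift disruption;
* short_complete -- complete undisrupted ORF shorter than 270 codons
                  (reported separately, excluded from functional counts).

Candidates covered by none of these (e.g. cds <= 300 nt and not intact) are
dropped (category ``None``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import QueryPanel
from .orf import GeneCandidate
from .search import make_aligner

DEFAULT_MIN_CODONS = 270  # coding codons, stop codon excluded
DEFAULT_MIN_NT = 300
DEFAULT_IDENTITY_SCORE_FLOOR = 50.0

CATEGORIES = ("intact", "partial", "pseudogene", "short_complete")
FUNCTIONAL = ("intact", "partial")


def classify_candidate(
    cand: GeneCandidate,
    min_codons: int = DEFAULT_MIN_CODONS,
    min_nt: int = DEFAULT_MIN_NT,
    require_tm: bool = True,
) -> str | None:
    """Assign a category (see module docstring); mutates ``cand.category``."""
    complete = cand.has_start and cand.has_stop
    clean = not cand.disruptions
    tm_ok = (cand.tm_count == 7) or not require_tm

    category: str | None = None
    if clean and complete and cand.n_codons >= min_codons and tm_ok:
        category = "intact"
    elif clean and complete and cand.n_codons < min_codons:
        category = "short_complete"
    elif (
        clean
        and (cand.has_start != cand.has_stop)
        and cand.cds_len > min_nt
        and cand.truncation_cause != "none"
    ):
        category = "partial"
    elif not clean and cand.cds_len > min_nt:
        category = "pseudogene"
    cand.category = category
    return category


def confirm_identity(
    cand: GeneCandidate,
    reference_set: QueryPanel,
    positive_label: str = "v1r",
    score_floor: float = DEFAULT_IDENTITY_SCORE_FLOOR,
) -> bool:
    """True iff the candidate's translation aligns best to a sequence whose
    panel label equals ``positive_label`` with score above the floor.

    The reference set should bundle both true receptor proteins and decoy
    (other-GPCR) proteins so the best-hit rule has discriminating power.
    """
    if len(reference_set) == 0:
        raise ValueError("empty reference set")
    from .translate import translate_cds

    query = cand.protein or translate_cds(cand.cds)
    if not query:
        return False
    aligner = make_aligner()
    best_score, best_label = float("-inf"), None
    for rid, rseq in reference_set:
        score = aligner.score(query, rseq)
        if score > best_score:
            best_score, best_label = score, QueryPanel.label_of(rid)
    if best_score < score_floor:
        return False
    return best_label == positive_label


@dataclass
class RepertoireSummary:
    """Per-species category counts plus across-species mean/median."""

    table: pd.DataFrame  # index: species; columns: categories + functional
    mean: pd.Series
    median: pd.Series


def summarize_repertoire(
    candidates_by_species: dict[str, list[GeneCandidate]],
) -> RepertoireSummary:
    rows = {}
    for species, cands in candidates_by_species.items():
        counts = {cat: 0 for cat in CATEGORIES}
        for c in cands:
            if c.category in counts:
                counts[c.category] += 1
        counts["functional"] = counts["intact"] + counts["partial"]
        rows[species] = counts
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if table.empty:
        table = pd.DataFrame(columns=list(CATEGORIES) + ["functional"], dtype=int)
    return RepertoireSummary(table=table, mean=table.mean(), median=table.median())
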