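"""Stand-in transmembrane-helix prediction via Kyte-Doolittle hydropathy.

Sliding windows of 19 residues with mean hydropathy above 1.6 are collected,
overlapping windows merged, and each merged region reported as one helix of
19-25 residues (regions longer than 25 are trimmed around their best
window). An adapter accepts externally produced topology strings instead.
"""

from __future__ import annotations

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_TM_WINDOW = 19
DEFAULT_TM_THRESHOLD = 1.6
MAX_HELIX_LEN = 25
MIN_PROTEIN_LEN = 100


def predict_tm_helices(
    protein: str,
    window: int = DEFAULT_TM_WINDOW,
    threshold: float = DEFAULT_TM_THRESHOLD,
    max_helix_len: int = MAX_HELIX_LEN,
) -> tuple[int, list[tuple[int, int]]]:
    """Predict transmembrane helices; returns (count, [(start, end), ...]).

    Spans are 0-based half-open residue coordinates.
    """
    protein = protein.upper().rstrip("*")
    if len(protein) < MIN_PROTEIN_LEN:
        raise ValueError(
            f"protein too short for topology prediction ({len(protein)} < {MIN_PROTEIN_LEN})"
        )
    scores = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein]
    n = len(protein)
    if n < window:
        return 0, []
    # Rolling window means.
    win_means = []
    total = sum(scores[:window])
    win_means.append(total / window)
    for i in range(1, n - window + 1):
        total += scores[i + window - 1] - scores[i - 1]
        win_means.append(total / window)

    qualifying = [i for i, m in enumerate(win_means) if m >= threshold]
    if not qualifying:
        return 0, []

    # Merge overlapping qualifying windows into regions.
    regions: list[list[int]] = []  # [start_window, end_window] inclusive
    for i in qualifying:
        if regions and i <= regions[-1][1] + window - 1:
            # windows [prev, prev+window) and [i, i+window) overlap
            if i - regions[-1][1] < window:
                regions[-1][1] = i
                continue
        regions.append([i, i])

    spans: list[tuple[int, int]] = []
    for w_lo, w_hi in regions:
        lo, hi = w_lo, w_hi + window  # residue span covered by the windows
        if hi - lo > max_helix_len:
            # trim around the best-scoring window in the region
            best = max(range(w_lo, w_hi + 1), key=lambda i: win_means[i])
            center = best + window // 2
            lo = max(lo, center - max_helix_len // 2)
            hi = min(hi, lo + max_helix_len)
            lo = max(w_lo, hi - max_helix_len)
        spans.append((lo, hi))
    return len(spans), spans


def parse_topology_string(topology: str, helix_char: str = "M") -> tuple[int, list[tuple[int, int]]]:
    """Adapter for externally produced per-residue topology strings.

    ``topology`` is one character per residue; runs of ``helix_char`` (or 'H')
    are helices. Returns the same (count, spans) shape as
    :func:`predict_tm_helices`.
    """
    marks = {helix_char, "H"}
    spans = []
    start = None
    for i, ch in enumerate(topology):
        if ch in marks and start is None:
            start = i
        elif ch not in marks and start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, len(topology)))
    return len(spans), spans
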