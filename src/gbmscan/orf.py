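"""Six-frame longest open reading frame search.

Transcript assemblies without genome annotation need a proxy for the coding
region before gene-body methylation can be summarised. The filter used here
keeps, per transcript, the longest ORF over all six reading frames that
begins with ATG and ends with an in-frame stop codon (TAA/TAG/TGA, included
in the ORF span) with no internal stop. Transcripts yielding no such ORF are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfCall:
    """An ORF located on the forward coordinates of the input sequence.

    ``start``/``end`` are 1-based inclusive on the input (forward) sequence
    regardless of strand; ``frame`` is the 0-based frame offset on the
    scanned strand; ``length_nt`` includes the stop codon.
    """

    transcript_id: str | None
    strand: str
    frame: int
    start: int
    end: int
    length_nt: int


def _scan_frame(seq: str, frame: int) -> list[tuple[int, int]]:
    """Longest ATG→stop ORFs in one frame of ``seq``.

    Returns (start, end) 0-based half-open codon-aligned spans, one per
    stop-terminated segment, each anchored at the earliest ATG since the
    previous stop. Codons containing N are neither start nor stop.
    """
    spans = []
    atg = -1
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if atg >= 0:
                spans.append((atg, i + 3))
            atg = -1
        elif atg < 0 and codon == START_CODON:
            atg = i
    return spans


def longest_orf(seq: str, transcript_id: str | None = None) -> OrfCall | None:
    """Longest start-to-stop ORF over all six frames, or None.

    Ties are broken deterministically: forward strand before reverse, lower
    frame first, then leftmost start on the scanned strand.
    """
    s = seq.upper()
    if len(s) < 6:
        return None
    best: tuple[int, int, int, int, str] | None = None  # (-len, strand_rank, frame, start, strand)
    for strand, scanned in (("+", s), ("-", reverse_complement(s))):
        for frame in range(3):
            for a, b in _scan_frame(scanned, frame):
                key = (-(b - a), 0 if strand == "+" else 1, frame, a)
                if best is None or key < best[:4]:
                    best = (*key, strand)
    if best is None:
        return None
    neg_len, _, frame, a, strand = best
    length = -neg_len
    if strand == "+":
        start, end = a + 1, a + length
    else:
        # map the span on the reverse complement back to forward coordinates
        start, end = len(s) - (a + length) + 1, len(s) - a
    return OrfCall(transcript_id, strand, frame, start, end, length)


def filter_transcripts(sequences: dict[str, str], min_length_nt: int = 6) -> dict[str, OrfCall]:
    """Apply the longest-ORF filter to a transcript set.

    Returns the ORF call for every transcript that has a qualifying ORF of at
    least ``min_length_nt`` nucleotides; other transcripts are omitted.
    """
    kept = {}
    for tid, seq in sequences.items():
        call = longest_orf(seq, tid)
        if call is not None and call.length_nt >= min_length_nt:
            kept[tid] = call
    return kept
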