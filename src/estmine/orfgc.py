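"""CDS/UTR structure prediction on consensus sequences and GC/GC3 profiling.

The frame of an EST consensus is normally inferred from protein similarity;
here a longest-ORF heuristic stands in, with an optional guide channel so a
similarity-derived (frame, strand) can be injected when available.  GC3 — the
fraction of G/C at third codon positions — is the composition statistic of
interest: its distribution across a transcript set is summarised as a
100-class histogram smoothed with a three-class moving average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

from .errors import ParameterError

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class CdsAnnotation:
    """Predicted coding structure on a contig consensus.

    Coordinates are 0-based half-open on the strand the CDS is read from
    (i.e. on the reverse-complemented consensus when ``strand == '-'``); the
    CDS span includes its terminal stop codon when one is present.
    """

    contig_id: str
    frame: int  # 0 | 1 | 2
    strand: str  # "+" | "-"
    cds_start: int
    cds_end: int
    utr5_len: int
    utr3_len: int
    full_length: bool
    reason: str = "ok"  # "ok" | "no_start_codon"

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start


@dataclass
class GcMetrics:
    gc: float
    gc3: float


def _orfs_in_frame(seq: str, frame: int):
    """ATG-to-stop spans in one frame; an ORF with no downstream stop runs to
    the last complete codon.  Yields (start, end) half-open, stop included."""
    n = len(seq)
    last = frame + ((n - frame) // 3) * 3
    start = None
    for i in range(frame, last, 3):
        codon = seq[i:i + 3]
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in STOP_CODONS:
            yield start, i + 3, True
            start = None
    if start is not None:
        yield start, last, False


def _longest_stop_free_stretch(seq: str, frame: int):
    """Longest run of codons without a stop in one frame: (start, end)."""
    n = len(seq)
    last = frame + ((n - frame) // 3) * 3
    best = (frame, frame)
    run_start = frame
    for i in range(frame, last, 3):
        if seq[i:i + 3] in STOP_CODONS:
            if i - run_start > best[1] - best[0]:
                best = (run_start, i)
            run_start = i + 3
    if last - run_start > best[1] - best[0]:
        best = (run_start, last)
    return best


def predict_cds(consensus: str, contig_id: str = "", guide: tuple | None = None) -> CdsAnnotation:
    """Predict the CDS of a consensus sequence.

    Without a guide the longest ATG-initiated ORF across all six frames wins
    (ties: '+' strand first, then lower frame).  With a ``guide = (frame,
    strand)`` the search is restricted to that frame — emulating a
    similarity-derived frame whose bounds are then expanded 5' to the nearest
    upstream ATG and 3' to the next in-frame stop.

    When no frame contains an ATG the annotation falls back to the longest
    stop-free stretch (``full_length=False``, reason ``"no_start_codon"``).
    """
    if len(consensus) < 3:
        raise ParameterError("consensus shorter than one codon")
    consensus = consensus.upper()

    frames = (
        [(guide[0], guide[1])]
        if guide is not None
        else [(f, s) for s in "+-" for f in (0, 1, 2)]
    )
    best = None
    for frame, strand in frames:
        seq = consensus if strand == "+" else reverse_complement(consensus)
        for start, end, has_stop in _orfs_in_frame(seq, frame):
            cand = (end - start, strand == "+", -frame, start, end, frame, strand, has_stop)
            if best is None or cand[:3] > best[:3]:
                best = cand

    if best is None:
        # no ATG anywhere: report the best stop-free frame
        alt = None
        for frame, strand in frames:
            seq = consensus if strand == "+" else reverse_complement(consensus)
            s, e = _longest_stop_free_stretch(seq, frame)
            cand = (e - s, strand == "+", -frame, s, e, frame, strand)
            if alt is None or cand[:3] > alt[:3]:
                alt = cand
        _, _, _, s, e, frame, strand = alt
        n = len(consensus)
        return CdsAnnotation(
            contig_id=contig_id, frame=frame, strand=strand,
            cds_start=s, cds_end=e, utr5_len=s, utr3_len=n - e,
            full_length=False, reason="no_start_codon",
        )

    _, _, _, start, end, frame, strand, has_stop = best
    n = len(consensus)
    return CdsAnnotation(
        contig_id=contig_id, frame=frame, strand=strand,
        cds_start=start, cds_end=end,
        utr5_len=start, utr3_len=n - end,
        full_length=has_stop,  # ATG guaranteed by construction
    )


def gc_metrics(cds: str, include_stop: bool = False) -> GcMetrics:
    """GC and GC3 fractions of a CDS.

    The terminal stop codon (if any) is excluded by default: its third
    position is constrained by the code, not by mutation pressure.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ParameterError("CDS length must be divisible by 3")
    if not include_stop and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if not cds:
        raise ParameterError("empty CDS after stop removal")
    gc = sum(b in "GC" for b in cds) / len(cds)
    thirds = cds[2::3]
    gc3 = sum(b in "GC" for b in thirds) / len(thirds)
    return GcMetrics(gc=gc, gc3=gc3)


def smoothed_histogram(values, n_classes: int = 100):
    """Histogram of fractions over [0, 1] in ``n_classes`` equal classes,
    smoothed with a 3-class moving average (edge classes average their two
    available neighbours).

    Returns ``(smoothed, raw)`` count arrays of length ``n_classes``.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ParameterError("values must be nonempty")
    if ((values < 0) | (values > 1)).any():
        raise ParameterError("values must lie in [0, 1]")
    raw, _ = np.histogram(values, bins=n_classes, range=(0.0, 1.0))
    raw = raw.astype(float)
    smoothed = np.empty_like(raw)
    for i in range(n_classes):
        lo, hi = max(i - 1, 0), min(i + 2, n_classes)
        smoothed[i] = raw[lo:hi].mean()
    return smoothed, raw


def annotate_contigs(contigs) -> list:
    """Convenience: longest-ORF annotation for every contig consensus."""
    return [predict_cds(c.consensus, contig_id=c.contig_id) for c in contigs]


def extract_cds(consensus: str, ann: CdsAnnotation) -> str:
    """The CDS substring of a consensus in the annotated frame/strand."""
    seq = consensus if ann.strand == "+" else reverse_complement(consensus)
    return seq[ann.cds_start:ann.cds_end]
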