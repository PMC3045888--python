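"""Raw EST cleanup: adapter/polyA/quality trimming and contaminant screening.

Trimming mirrors the classic Sanger-EST cleanup: strip a leading vector
adapter remnant (allowing a small number of mismatches), strip terminal
mononucleotide polyA (3') and polyT (5') runs, clip the 3' end where a
sliding window of base qualities drops below a floor, and reject whatever
ends up shorter than the minimum usable length.

Contaminant screening consumes a precomputed similarity-hit table (12-column
tabular search output) against a bacterial nucleotide database: a cluster is
flagged when any hit is simultaneously significant (E-value at or below the
cutoff) and close (identity above the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import FormatError, ParameterError

_VALID = set("ACGTN")


@dataclass
class EstRead:
    """One 5'-sequenced cDNA read with its library assignment."""

    read_id: str
    library_id: str
    sequence: str
    qualities: list | None = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise FormatError(f"{self.read_id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(f"{self.read_id}: quality length mismatch")


@dataclass
class SimilarityHit:
    """One row of a 12-column tabular similarity search."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError("pct_identity outside [0, 100]")
        if self.evalue < 0:
            raise FormatError("negative evalue")


@dataclass
class TrimRejection:
    """A read removed during trimming, with the rule that removed it."""

    read_id: str
    reason: str  # "short" | "empty"


def _find_adapter(seq: str, adapter: str, max_mismatch: int = 2, scan: int = 0) -> int:
    """Return the end position of the leading adapter occurrence, or -1.

    The adapter is searched at start offsets ``0..scan`` (no indels); the
    earliest occurrence with <= ``max_mismatch`` substitutions wins.  The
    default anchors the search at the read start: 5' vector remnants sit at
    the very beginning, and a mismatch-tolerant scan of a wider window would
    hit random sequence too often for short adapters.
    """
    if not adapter:
        return -1
    alen = len(adapter)
    limit = min(scan, len(seq) - alen)
    for start in range(limit + 1):
        window = seq[start:start + alen]
        mism = sum(a != b for a, b in zip(window, adapter))
        if mism <= max_mismatch:
            return start + alen
    return -1


def _strip_run(seq: str, base: str, min_run: int, end: str):
    """Strip a terminal mononucleotide run of >= min_run from one end.

    Returns (start, stop) of the retained slice within ``seq``.
    """
    n = len(seq)
    if end == "5":
        i = 0
        while i < n and seq[i] == base:
            i += 1
        return (i, n) if i >= min_run else (0, n)
    i = n
    while i > 0 and seq[i - 1] == base:
        i -= 1
    return (0, i) if n - i >= min_run else (0, n)


def _quality_clip(quals, floor: float, window: int) -> int:
    """First index at which a sliding mean-quality window drops below floor;
    the read is clipped there.  Returns len(quals) when no window fails."""
    n = len(quals)
    if n < window:
        return n
    s = sum(quals[:window])
    if s / window < floor:
        return 0
    for start in range(1, n - window + 1):
        s += quals[start + window - 1] - quals[start - 1]
        if s / window < floor:
            return start
    return n


def trim_read(
    read: EstRead,
    min_length: int = 100,
    adapter: str = "",
    polya_min_run: int = 8,
    quality_floor: float = 16.0,
    window: int = 20,
    adapter_max_mismatch: int = 2,
    adapter_scan: int = 0,
):
    """Trim one EST read; returns a trimmed :class:`EstRead` or a
    :class:`TrimRejection` when the survivor is shorter than ``min_length``.

    The phases — leading adapter, 5' polyT, 3' polyA, 3' quality clip — are
    iterated to a fixed point (one phase can expose material for another,
    e.g. a quality clip uncovering a polyA run), which makes trimming
    idempotent.  The output is always a contiguous substring of the input.
    """
    if min_length < 1:
        raise ParameterError("min_length must be >= 1")
    bad = set(read.sequence) - _VALID
    if bad:
        raise FormatError(f"{read.read_id}: invalid characters {sorted(bad)}")

    lo, hi = 0, len(read.sequence)
    while True:
        start = (lo, hi)
        end = _find_adapter(read.sequence[lo:hi], adapter,
                            adapter_max_mismatch, adapter_scan)
        if end >= 0:
            lo += end
        a, b = _strip_run(read.sequence[lo:hi], "T", polya_min_run, "5")
        lo, hi = lo + a, lo + b
        a, b = _strip_run(read.sequence[lo:hi], "A", polya_min_run, "3")
        lo, hi = lo + a, lo + b
        if read.qualities is not None and hi > lo:
            clip = _quality_clip(read.qualities[lo:hi], quality_floor, window)
            hi = lo + clip
        if (lo, hi) == start:
            break

    if hi - lo < min_length:
        return TrimRejection(read_id=read.read_id, reason="short" if hi > lo else "empty")
    return replace(
        read,
        sequence=read.sequence[lo:hi],
        qualities=None if read.qualities is None else read.qualities[lo:hi],
    )


def trim_reads(reads, **kwargs):
    """Trim a batch; returns (kept reads, rejection records)."""
    kept, rejected = [], []
    for r in reads:
        out = trim_read(r, **kwargs)
        (rejected if isinstance(out, TrimRejection) else kept).append(out)
    return kept, rejected


def screen_contaminants(
    cluster_ids,
    hits,
    evalue_cut: float = 1e-40,
    identity_cut: float = 80.0,
    require_significant: bool = True,
):
    """Partition clusters into (clean, contaminant) sets from a hit table.

    A cluster is a contaminant iff it has at least one hit with
    ``evalue <= evalue_cut`` and ``pct_identity > identity_cut``.  With
    ``require_significant=False`` the E-value inequality is inverted
    (``evalue > evalue_cut``), reproducing the alternative literal reading of
    the threshold; the default treats weaker-than-cutoff hits as noise.
    """
    cluster_ids = set(cluster_ids)
    contaminant = set()
    for h in hits:
        if h.query_id not in cluster_ids:
            continue
        ev_ok = h.evalue <= evalue_cut if require_significant else h.evalue > evalue_cut
        if ev_ok and h.pct_identity > identity_cut:
            contaminant.add(h.query_id)
    return cluster_ids - contaminant, contaminant
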