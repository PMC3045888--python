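"""Overlap clustering of trimmed ESTs into contigs and singlets.

The clusterer is a greedy seed-and-extend agglomerator driven by the two
parameters that matter for reproducing the assembly behaviour: minimum
overlap length (default 40 bases) and minimum overlap identity (default
90%).  Reads are taken longest-first; each read joins the first existing
cluster whose reference it overlaps acceptably (shared-k-mer seeding picks
the candidate diagonal, a direct diagonal comparison scores it, and a banded
affine alignment is used as a fallback when the diagonal score is
borderline, to tolerate indels).  A read that matches no cluster founds a
new one.  Consensus sequences are column-wise majority calls over the member
alignment.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .errors import DataError, ParameterError

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE_ORDER = "ACGT"  # majority ties break alphabetically


@dataclass
class ContigMember:
    """One read placed in a contig: offset of its first base on the contig
    coordinate system, strand, and its consensus-oriented sequence."""

    read_id: str
    library_id: str
    offset: int
    strand: str  # "+" | "-"
    sequence: str
    qualities: list | None = None


@dataclass
class Contig:
    contig_id: str
    members: list = field(default_factory=list)
    consensus: str = ""

    @property
    def library_counts(self) -> dict:
        return dict(Counter(m.library_id for m in self.members))

    def depth(self) -> np.ndarray:
        """Read coverage per consensus column."""
        d = np.zeros(len(self.consensus), dtype=int)
        for m in self.members:
            d[m.offset:m.offset + len(m.sequence)] += 1
        return d


def _kmer_positions(seq: str, k: int) -> dict:
    pos = defaultdict(list)
    for i in range(len(seq) - k + 1):
        pos[seq[i:i + k]].append(i)
    return pos


def _diagonal_overlap(a: str, b: str, d: int):
    """Ungapped overlap of ``a`` placed at offset ``d`` on ``b``.

    Returns (overlap_length, identity).
    """
    a_start = max(0, -d)
    a_end = min(len(a), len(b) - d)
    n = a_end - a_start
    if n <= 0:
        return 0, 0.0
    xa = np.frombuffer(a[a_start:a_end].encode(), dtype="S1")
    xb = np.frombuffer(b[a_start + d:a_end + d].encode(), dtype="S1")
    matches = int((xa == xb).sum())
    return n, matches / n


_aligner = PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 1
_aligner.mismatch_score = -2
_aligner.open_gap_score = -5
_aligner.extend_gap_score = -1


def _banded_overlap(a: str, b: str, d: int, band: int = 10):
    """Affine-gap local alignment of the overlap region around diagonal ``d``.

    Returns (alignment_length, identity).  Used only when the plain diagonal
    comparison is borderline, so indel-containing overlaps are not lost.
    """
    a_start = max(0, -d - band)
    a_end = min(len(a), len(b) - d + band)
    b_start = max(0, d - band)
    b_end = min(len(b), len(a) + d + band)
    sa, sb = a[a_start:a_end], b[b_start:b_end]
    if not sa or not sb:
        return 0, 0.0
    try:
        aln = _aligner.align(sa, sb)[0]
    except (IndexError, ValueError):
        return 0, 0.0
    matches = 0
    length = 0
    for (qs, qe), (ts, te) in zip(aln.aligned[0], aln.aligned[1]):
        seg_a, seg_b = sa[qs:qe], sb[ts:te]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        length += qe - qs
    # count gap columns between aligned blocks toward alignment length
    blocks_a, blocks_b = aln.aligned[0], aln.aligned[1]
    for i in range(1, len(blocks_a)):
        length += max(
            blocks_a[i][0] - blocks_a[i - 1][1], blocks_b[i][0] - blocks_b[i - 1][1]
        )
    if length == 0:
        return 0, 0.0
    return length, matches / length


class _Cluster:
    __slots__ = ("cid", "reference", "ref_kmers", "members")

    def __init__(self, cid, read, k):
        self.cid = cid
        self.reference = read.sequence
        self.ref_kmers = _kmer_positions(read.sequence, k)
        self.members = [(read, 0, "+")]


def _best_placement(seq: str, cluster: _Cluster, k: int, min_overlap: int,
                    min_identity: float):
    """Best (offset, overlap, identity) of ``seq`` against the cluster
    reference, or None when no diagonal attracts enough seeds."""
    votes = Counter()
    for i in range(len(seq) - k + 1):
        for j in cluster.ref_kmers.get(seq[i:i + k], ()):
            votes[j - i] += 1
    if not votes:
        return None
    d, _ = votes.most_common(1)[0]
    n, ident = _diagonal_overlap(seq, cluster.reference, d)
    if n >= min_overlap and ident >= min_identity:
        return d, n, ident
    # borderline: retry with a banded affine alignment (tolerates indels)
    if n >= min_overlap and ident >= min_identity - 0.10:
        n2, ident2 = _banded_overlap(seq, cluster.reference, d)
        if n2 >= min_overlap and ident2 >= min_identity:
            return d, n2, ident2
    return None


def cluster_ests(
    reads,
    min_identity: float = 0.90,
    min_overlap: int = 40,
    check_revcomp: bool = True,
    k: int = 12,
):
    """Greedy agglomeration of reads into clusters.

    Returns ``(contigs, singlet_read_ids)``; every input read lands in exactly
    one contig or the singlet list.  Candidate clusters are examined in
    creation order, so ties resolve deterministically.
    """
    reads = list(reads)
    if not reads:
        raise ParameterError("reads must be nonempty")
    if not 0.0 < min_identity <= 1.0:
        raise ParameterError("min_identity must be in (0, 1]")
    order = sorted(reads, key=lambda r: (-len(r.sequence), r.read_id))

    clusters: list[_Cluster] = []
    kmer_to_clusters = defaultdict(set)  # seed kmers -> candidate cluster ids

    for read in order:
        placed = False
        seq_f = read.sequence
        seq_r = reverse_complement(seq_f) if check_revcomp else None
        candidates = set()
        for s in (seq_f, seq_r) if seq_r else (seq_f,):
            for i in range(0, max(len(s) - k + 1, 1), k):
                candidates |= kmer_to_clusters.get(s[i:i + k], set())
        for cid in sorted(candidates):
            cl = clusters[cid]
            hit = _best_placement(seq_f, cl, k, min_overlap, min_identity)
            strand = "+"
            if hit is None and seq_r is not None:
                hit = _best_placement(seq_r, cl, k, min_overlap, min_identity)
                strand = "-"
            if hit is not None:
                d, _, _ = hit
                cl.members.append((read, d, strand))
                placed = True
                break
        if not placed:
            cid = len(clusters)
            clusters.append(_Cluster(cid, read, k))
            for i in range(len(seq_f) - k + 1):
                kmer_to_clusters[seq_f[i:i + k]].add(cid)

    contigs, singlets = [], []
    n_contig = 0
    for cl in clusters:
        if len(cl.members) == 1:
            singlets.append(cl.members[0][0].read_id)
            continue
        n_contig += 1
        contigs.append(_finalize(cl, f"contig{n_contig:05d}"))
    return contigs, singlets


def _finalize(cl: _Cluster, contig_id: str) -> Contig:
    """Shift offsets to a common origin and call the majority consensus."""
    oriented = []
    for read, off, strand in cl.members:
        seq = read.sequence if strand == "+" else reverse_complement(read.sequence)
        quals = read.qualities
        if strand == "-" and quals is not None:
            quals = quals[::-1]
        oriented.append((read, off, strand, seq, quals))
    min_off = min(off for _, off, _, _, _ in oriented)
    width = max(off - min_off + len(seq) for _, off, _, seq, _ in oriented)
    counts = np.zeros((4, width), dtype=np.int32)
    members = []
    for read, off, strand, seq, quals in oriented:
        start = off - min_off
        idx = np.frombuffer(seq.encode(), dtype=np.uint8)
        for b, row in _BASE_INDEX.items():
            counts[row, start:start + len(seq)] += idx == ord(b)
        members.append(
            ContigMember(
                read_id=read.read_id,
                library_id=read.library_id,
                offset=start,
                strand=strand,
                sequence=seq,
                qualities=quals,
            )
        )
    best = counts.argmax(axis=0)  # argmax takes the first max: A<C<G<T tie-break
    consensus = "".join(_BASE_ORDER[i] if counts[:, j].sum() else "N"
                        for j, i in enumerate(best))
    return Contig(contig_id=contig_id, members=members, consensus=consensus)


def build_count_matrix(contigs, singlets, library_table):
    """Contig x library EST count matrix as a pandas DataFrame.

    ``library_table`` maps read_id -> library_id (dict, or a DataFrame with
    ``read_id``/``library_id`` columns).  Singlets appear as 1-count rows under
    their read id.  Libraries present in the table but devoid of assembled
    reads are retained as all-zero columns.
    """
    import pandas as pd

    if hasattr(library_table, "columns"):
        library_table = dict(zip(library_table["read_id"], library_table["library_id"]))
    libraries = sorted(set(library_table.values()))
    rows = {}
    for c in contigs:
        counts = {}
        for m in c.members:
            if m.read_id not in library_table:
                raise DataError(f"read {m.read_id} has no library assignment")
            lib = library_table[m.read_id]
            counts[lib] = counts.get(lib, 0) + 1
        rows[c.contig_id] = counts
    for rid in singlets:
        if rid not in library_table:
            raise DataError(f"read {rid} has no library assignment")
        rows[rid] = {library_table[rid]: 1}
    mat = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    return mat.reindex(columns=libraries).fillna(0.0).astype(int)


def assembly_summary(contigs, singlets) -> dict:
    """Descriptive statistics of an assembly (cluster = contig or singlet)."""
    sizes = [len(c.members) for c in contigs]
    lengths = [len(c.consensus) for c in contigs]
    n_contigs = len(contigs)
    per_library = Counter()
    for c in contigs:
        for lib in c.library_counts:
            per_library[lib] += 1
    return {
        "n_contigs": n_contigs,
        "n_singlets": len(singlets),
        "n_clusters": n_contigs + len(singlets),
        "mean_consensus_length": float(np.mean(lengths)) if lengths else 0.0,
        "min_consensus_length": min(lengths) if lengths else 0,
        "max_consensus_length": max(lengths) if lengths else 0,
        "contig_size_histogram": dict(Counter(sizes)),
        "fraction_le_20_ests": (sum(s <= 20 for s in sizes) / n_contigs) if n_contigs else 0.0,
        "fraction_lt_50_ests": (sum(s < 50 for s in sizes) / n_contigs) if n_contigs else 0.0,
        "contigs_per_library": dict(per_library),
    }
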