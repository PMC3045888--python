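"""Haplotype-filtered SNP detection in EST contigs, synonymy labels and KA/KS.

SNP calling in EST assemblies must separate true allelic variation from
sequencing error and from collapsed paralogs.  The detector applies three
filters in sequence:

1. *Candidate screen* — alignment columns with two or more observed alleles;
   when base qualities are available, alleles supported only by bases below
   the quality floor are discarded.
2. *Haplotype filter* (the core) — reads are partitioned into haplotypes by
   their allele vectors over the candidate columns; haplotypes consisting of
   a single read are removed, and a singleton allele (support 1) survives
   only if its carrier read belongs to a surviving haplotype defined by at
   least one other polymorphism.  Contigs whose two major haplotypes are
   separated by too many fixed differences are flagged as collapsed paralogs.
3. *Confidence screen* — a redundancy/balance score
   ``(1 - 1/d) * (2 * minor_support / d)`` with column depth ``d``; calls
   below the floor are dropped.

Synonymy labelling substitutes each alternate allele into its codon on the
annotated CDS; KA/KS uses per-codon fractional site counting with
uncorrected substitution proportions (within-contig divergence is small).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .errors import DataError, ParameterError
from .orfgc import extract_cds

PURINES = {"A", "G"}
TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"
BASES = "ACGT"


@dataclass
class SnpCall:
    contig_id: str
    position: int  # 0-based on the consensus
    ref_allele: str
    alleles: dict  # base -> read support
    allelic_class: str  # "bi" | "tri" | "tetra"
    mutation_class: str  # "transition" | "transversion" | "multi"
    confidence: float
    synonymy: str = "unlabeled"  # later: synonymous | nonsynonymous | noncoding | ambiguous

    @property
    def minor_support(self) -> int:
        return sorted(self.alleles.values())[-2] if len(self.alleles) > 1 else 0


@dataclass
class Haplotype:
    member_read_ids: list
    allele_vector: tuple  # one base or None per candidate position


@dataclass
class SnpResult:
    contig_id: str
    calls: list = field(default_factory=list)
    haplotypes: list = field(default_factory=list)
    paralog_flag: bool = False
    screened: bool = True  # False when the contig failed min_reads
    reason: str = "ok"


def _column_alleles(contig, min_quality=None):
    """Per-column base observations: {pos: {base: [read indices]}}.

    ``N`` never supports an allele; with qualities present, bases below
    ``min_quality`` are ignored.
    """
    columns = defaultdict(lambda: defaultdict(list))
    for ri, m in enumerate(contig.members):
        for j, base in enumerate(m.sequence):
            if base == "N":
                continue
            if min_quality is not None and m.qualities is not None:
                if m.qualities[j] < min_quality:
                    continue
            columns[m.offset + j][base].append(ri)
    return columns


def _mutation_class(alleles) -> str:
    if len(alleles) > 2:
        return "multi"
    pair = set(alleles)
    return "transition" if pair in TRANSITION_PAIRS else "transversion"


def detect_snps(
    contig,
    min_reads: int = 4,
    min_allele_support: int = 2,
    confidence_floor: float = 0.2,
    paralog_divergence_cut: float = 3.0,
    quality_floor: int | None = 20,
) -> SnpResult:
    """Run the three-filter SNP screen on one contig.

    ``paralog_divergence_cut`` is in fixed differences per 100 bp between the
    two largest haplotype groups.
    """
    n = len(contig.members)
    if n < min_reads:
        return SnpResult(contig_id=contig.contig_id, screened=False,
                         reason=f"fewer than {min_reads} reads")

    # Filter 1: candidate polymorphic columns
    columns = _column_alleles(contig, min_quality=quality_floor)
    candidates = sorted(pos for pos, obs in columns.items() if len(obs) >= 2)
    if not candidates:
        return SnpResult(contig_id=contig.contig_id)

    # Filter 2: haplotype partition over candidate columns.  Reads are
    # grouped greedily by allele-vector compatibility: a read joins the first
    # group whose vector it matches at every shared covered column (coverage
    # is ragged in 5'-anchored contigs, so exact-vector equality would
    # fragment haplotypes).
    vectors = []
    for ri, m in enumerate(contig.members):
        vec = []
        for pos in candidates:
            j = pos - m.offset
            base = m.sequence[j] if 0 <= j < len(m.sequence) else None
            vec.append(base if base in set(BASES) else None)
        vectors.append(tuple(vec))

    def covered(vec):
        return sum(b is not None for b in vec)

    order = sorted(range(n), key=lambda ri: (-covered(vectors[ri]), ri))
    group_vecs: list[list] = []   # consensus vector per group (None = unseen)
    group_members: list[list] = []
    for ri in order:
        vec = vectors[ri]
        placed = False
        for gi, gvec in enumerate(group_vecs):
            shared = [q for q in range(len(vec))
                      if vec[q] is not None and gvec[q] is not None]
            if shared and all(vec[q] == gvec[q] for q in shared):
                group_members[gi].append(ri)
                for q, b in enumerate(vec):
                    if b is not None and gvec[q] is None:
                        gvec[q] = b
                placed = True
                break
        if not placed:
            group_vecs.append(list(vec))
            group_members.append([ri])

    keep = [gi for gi, ris in enumerate(group_members) if len(ris) >= 2]
    keep.sort(key=lambda gi: -len(group_members[gi]))
    surviving_reads = set(ri for gi in keep for ri in group_members[gi])
    read_group = {ri: gi for gi in keep for ri in group_members[gi]}

    haplotypes = [
        Haplotype(member_read_ids=[contig.members[ri].read_id
                                   for ri in group_members[gi]],
                  allele_vector=tuple(group_vecs[gi]))
        for gi in keep
    ]

    calls = []
    for pi, pos in enumerate(candidates):
        obs = columns[pos]
        support = {b: len([ri for ri in ris if ri in surviving_reads])
                   for b, ris in obs.items()}
        support = {b: s for b, s in support.items() if s > 0}
        if len(support) < 2:
            continue
        ordered = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
        ok = True
        for b, s in ordered[1:]:
            if s >= min_allele_support:
                continue
            # singleton allele: kept only when its carrier shares a surviving
            # haplotype that is defined by at least one other polymorphism
            carriers = [ri for ri in obs[b] if ri in surviving_reads]
            linked = False
            for ri in carriers:
                gi = read_group.get(ri)
                if gi is None:
                    continue
                gvec = group_vecs[gi]
                if any(gvec[q] is not None for q in range(len(candidates))
                       if q != pi):
                    linked = True
                    break
            if not linked:
                ok = False
                break
        if not ok:
            continue

        # Filter 3: confidence from depth and allele balance
        depth = sum(support.values())
        minor = ordered[1][1]
        confidence = (1.0 - 1.0 / depth) * (2.0 * minor / depth)
        if confidence < confidence_floor:
            continue

        n_alleles = len(support)
        calls.append(
            SnpCall(
                contig_id=contig.contig_id,
                position=pos,
                ref_allele=contig.consensus[pos] if pos < len(contig.consensus) else "N",
                alleles=dict(support),
                allelic_class={2: "bi", 3: "tri"}.get(n_alleles, "tetra"),
                mutation_class=_mutation_class(support),
                confidence=confidence,
            )
        )

    # paralog screen: fixed differences between the two largest haplotypes
    paralog_flag = False
    if len(haplotypes) >= 2:
        h1, h2 = haplotypes[0].allele_vector, haplotypes[1].allele_vector
        fixed = sum(
            1 for a, b in zip(h1, h2) if a is not None and b is not None and a != b
        )
        span = _shared_span(contig, haplotypes[0], haplotypes[1])
        if span > 0 and fixed * 100.0 / span > paralog_divergence_cut:
            paralog_flag = True

    return SnpResult(
        contig_id=contig.contig_id,
        calls=calls,
        haplotypes=haplotypes,
        paralog_flag=paralog_flag,
    )


def _shared_span(contig, h1: Haplotype, h2: Haplotype) -> int:
    """Aligned bases shared by both haplotype groups (overlap of extents)."""
    def extent(h):
        ids = set(h.member_read_ids)
        spans = [(m.offset, m.offset + len(m.sequence))
                 for m in contig.members if m.read_id in ids]
        return min(s for s, _ in spans), max(e for _, e in spans)

    (s1, e1), (s2, e2) = extent(h1), extent(h2)
    return max(0, min(e1, e2) - max(s1, s2))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def classify_and_summarize(results, contigs) -> dict:
    """Dataset-level SNP statistics.

    SNP density is per 100 bp of screened (>= min_reads, non-paralog-flagged)
    consensus sequence; transition/transversion counts cover bi-allelic calls.
    """
    by_id = {c.contig_id: c for c in contigs}
    screened = [r for r in results if r.screened and not r.paralog_flag]
    calls = [call for r in screened for call in r.calls]
    n_ts = sum(1 for c in calls if c.mutation_class == "transition")
    n_tv = sum(1 for c in calls if c.mutation_class == "transversion")
    class_counts = Counter(c.allelic_class for c in calls)
    total_bases = sum(len(by_id[r.contig_id].consensus) for r in screened)
    n_with_snp = sum(1 for r in screened if r.calls)
    total = len(calls)
    return {
        "n_screened_contigs": len(screened),
        "n_paralog_flagged": sum(1 for r in results if r.screened and r.paralog_flag),
        "n_snps": total,
        "transitions": n_ts,
        "transversions": n_tv,
        "ts_tv_ratio": (n_ts / n_tv) if n_tv else float("nan"),
        "pct_bi": 100.0 * class_counts["bi"] / total if total else 0.0,
        "pct_tri": 100.0 * class_counts["tri"] / total if total else 0.0,
        "pct_tetra": 100.0 * class_counts["tetra"] / total if total else 0.0,
        "snp_density_per_100bp": (total * 100.0 / total_bases) if total_bases else 0.0,
        "fraction_contigs_with_snp": (n_with_snp / len(screened)) if screened else 0.0,
    }


# ---------------------------------------------------------------------------
# synonymy and KA/KS
# ---------------------------------------------------------------------------

def _consensus_position_to_cds(call_pos: int, ann, consensus_len: int):
    """Map a consensus position to a position on the CDS-strand sequence."""
    if ann.strand == "+":
        return call_pos
    return consensus_len - 1 - call_pos


def label_synonymy(call: SnpCall, annotation, consensus: str) -> SnpCall:
    """Label one call as synonymous / nonsynonymous / noncoding / ambiguous.

    Each alternate allele is substituted into its codon of the annotated CDS
    and the translations compared; tri-allelic sites with mixed effects are
    ``ambiguous``.
    """
    if call.position >= len(consensus):
        raise DataError(f"{call.contig_id}: SNP position beyond consensus")
    seq = consensus if annotation.strand == "+" else reverse_complement(consensus)
    pos = _consensus_position_to_cds(call.position, annotation, len(consensus))
    if not annotation.cds_start <= pos < annotation.cds_end:
        call.synonymy = "noncoding"
        return call
    off = pos - annotation.cds_start
    codon_start = annotation.cds_start + (off // 3) * 3
    within = pos - codon_start
    codon = seq[codon_start:codon_start + 3]
    if len(codon) < 3 or any(b not in BASES for b in codon):
        call.synonymy = "ambiguous"
        return call
    ref_aa = _CODON_TABLE[codon]
    # alleles are on the consensus strand: complement when the CDS is on '-'
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    changed = []
    for allele in call.alleles:
        base = allele if annotation.strand == "+" else comp[allele]
        if base == codon[within]:
            continue
        alt = codon[:within] + base + codon[within + 1:]
        changed.append(_CODON_TABLE[alt] != ref_aa)
    if not changed or not any(changed):
        call.synonymy = "synonymous"
    elif all(changed):
        call.synonymy = "nonsynonymous"
    else:  # tri/tetra-allelic with mixed effects
        call.synonymy = "ambiguous"
    return call


def synonymous_site_counts(cds: str):
    """Fractional synonymous (S) and nonsynonymous (N) site counts of a CDS.

    Each codon position contributes the fraction of its three possible
    substitutions that preserve the amino acid; S + N = 3 x #codons.  A
    terminal stop codon is excluded.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ParameterError("CDS length must be divisible by 3")
    if _CODON_TABLE.get(cds[-3:]) == "*":
        cds = cds[:-3]
    s = 0.0
    n_codons = 0
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if any(b not in BASES for b in codon):
            continue
        n_codons += 1
        aa = _CODON_TABLE[codon]
        for j in range(3):
            syn = sum(
                1 for b in BASES if b != codon[j]
                and _CODON_TABLE[codon[:j] + b + codon[j + 1:]] == aa
            )
            s += syn / 3.0
    return s, 3.0 * n_codons - s


@dataclass
class KaKsResult:
    contig_id: str
    ka: float
    ks: float
    ratio: float | None  # None when ks == 0

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def compute_kaks(calls, annotation, consensus: str) -> KaKsResult:
    """KA/KS for one contig from its labelled SNP calls.

    ``ka`` = nonsynonymous SNPs per nonsynonymous site, ``ks`` = synonymous
    SNPs per synonymous site (uncorrected proportions); the ratio is flagged
    undefined (``None``) when ``ks == 0``.
    """
    cds = extract_cds(consensus, annotation)
    if len(cds) < 3:
        raise DataError("no CDS to compute KA/KS on")
    s_sites, n_sites = synonymous_site_counts(cds)
    if s_sites == 0 or n_sites == 0:
        raise DataError("degenerate CDS: zero synonymous or nonsynonymous sites")
    labelled = [c for c in calls if c.synonymy in ("synonymous", "nonsynonymous")]
    n_syn = sum(1 for c in labelled if c.synonymy == "synonymous")
    n_non = sum(1 for c in labelled if c.synonymy == "nonsynonymous")
    ka = n_non / n_sites
    ks = n_syn / s_sites
    return KaKsResult(
        contig_id=annotation.contig_id,
        ka=ka,
        ks=ks,
        ratio=(ka / ks) if ks > 0 else None,
    )
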