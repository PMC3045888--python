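"""Synthetic transcriptomes and 5'-anchored EST libraries with known ground truth.

The generator emulates the data a Sanger-era cDNA sequencing project produces:
5'-sequenced reads from a transcript set with 5'UTR/CDS/3'UTR structure,
library-specific expression profiles split into "development" and "stress"
condition blocks, polyA tails, vector adapter remnants, 3' quality decay,
bacterial contaminant reads, bi-allelic variants at a controllable
transition:transversion ratio, and near-identical paralog pairs.

Every downstream stage (trimming, overlap clustering, ORF/GC profiling,
haplotype SNP filtering, digital differential expression) can therefore be
tested against planted truth rather than against itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

# Codon sets per amino acid, restricted to the 18 amino acids whose codon
# family offers both an A/T and a G/C third position.  Met (ATG) and Trp (TGG)
# have a fixed third base and would bias GC3 away from its target, so they are
# excluded from the sampled alphabet (the start codon still contributes its G).
_CODONS_BY_AA = {
    "F": ["TTT", "TTC"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"],
    "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
}
_SAMPLED_AAS = sorted(_CODONS_BY_AA)
_GC_THIRD = {
    aa: [c for c in codons if c[2] in "GC"] for aa, codons in _CODONS_BY_AA.items()
}
_AT_THIRD = {
    aa: [c for c in codons if c[2] in "AT"] for aa, codons in _CODONS_BY_AA.items()
}

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


# ---------------------------------------------------------------------------
# length-distribution specs
# ---------------------------------------------------------------------------

def sample_lengths(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` integer lengths from a distribution spec.

    Specs are small dicts::

        {"kind": "constant", "value": 650}
        {"kind": "uniform", "low": 400, "high": 900}
        {"kind": "truncnorm", "mean": 650, "sd": 150, "min": 100}

    The truncated normal is realised by resampling below the floor.
    """
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ParameterError(f"invalid distribution spec: {spec!r}")
    kind = spec["kind"]
    if kind == "constant":
        return np.full(n, int(spec["value"]))
    if kind == "uniform":
        low, high = int(spec["low"]), int(spec["high"])
        if high < low:
            raise ParameterError("uniform spec needs low <= high")
        return rng.integers(low, high + 1, size=n)
    if kind == "truncnorm":
        mean, sd, floor = float(spec["mean"]), float(spec["sd"]), int(spec.get("min", 0))
        if sd < 0:
            raise ParameterError("truncnorm sd must be >= 0")
        out = np.rint(rng.normal(mean, sd, size=n)).astype(int)
        bad = out < floor
        while bad.any():
            out[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum()))).astype(int)
            bad = out < floor
        return out
    raise ParameterError(f"unknown distribution kind: {kind!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One transcript: 5'UTR + CDS + 3'UTR, with its GC3 design target."""

    gene_id: str
    utr5: str
    cds: str
    utr3: str
    gc3_target: float

    def __post_init__(self):
        if not self.cds.startswith("ATG"):
            raise ParameterError(f"{self.gene_id}: CDS must start with ATG")
        if self.cds[-3:] not in STOP_CODONS:
            raise ParameterError(f"{self.gene_id}: CDS must end in a stop codon")
        if len(self.cds) % 3 != 0:
            raise ParameterError(f"{self.gene_id}: CDS length must be divisible by 3")
        for i in range(3, len(self.cds) - 3, 3):
            if self.cds[i:i + 3] in STOP_CODONS:
                raise ParameterError(f"{self.gene_id}: internal in-frame stop at {i}")

    @property
    def transcript(self) -> str:
        return self.utr5 + self.cds + self.utr3

    def gc3(self, include_stop: bool = False) -> float:
        """Realised fraction of G/C at third codon positions of the CDS."""
        cds = self.cds if include_stop else self.cds[:-3]
        thirds = cds[2::3]
        return sum(b in "GC" for b in thirds) / len(thirds)


@dataclass
class LibraryDesign:
    """Sampling recipe for one EST library."""

    library_id: str
    condition: str  # "development" | "stress"
    n_reads: int
    expression: dict  # gene_id -> sampling probability
    contaminant_fraction: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.condition not in ("development", "stress"):
            raise ParameterError(f"unknown condition {self.condition!r}")
        total = sum(self.expression.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"{self.library_id}: expression probabilities sum to {total}, not 1"
            )
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ParameterError("contaminant_fraction must be in [0, 1)")


@dataclass
class SimTruth:
    """Planted ground truth accumulated across generator stages."""

    de_genes: set = field(default_factory=set)
    snp_sites: list = field(default_factory=list)  # (gene_id, pos, (ref, alt), (f_ref, f_alt))
    paralog_pairs: list = field(default_factory=list)  # (gene_id, gene_id, divergence)
    contaminant_ids: set = field(default_factory=set)
    read_origins: dict = field(default_factory=dict)  # read_id -> gene_id | None
    read_haplotypes: dict = field(default_factory=dict)  # read_id -> 0 (ref) | 1 (alt)

    def merge(self, other: "SimTruth") -> "SimTruth":
        return SimTruth(
            de_genes=self.de_genes | other.de_genes,
            snp_sites=self.snp_sites + other.snp_sites,
            paralog_pairs=self.paralog_pairs + other.paralog_pairs,
            contaminant_ids=self.contaminant_ids | other.contaminant_ids,
            read_origins={**self.read_origins, **other.read_origins},
            read_haplotypes={**self.read_haplotypes, **other.read_haplotypes},
        )


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def _random_utr(length: int, rng: np.random.Generator) -> str:
    """Random UTR with every ATG occurrence broken (G -> C).

    Start-codon-free UTRs keep the longest-ORF predictor's errors attributable
    to frame selection rather than to spurious upstream starts planted by the
    generator itself.
    """
    seq = "".join(rng.choice(list(BASES), size=length))
    while "ATG" in seq:
        seq = seq.replace("ATG", "ATC")
    return seq


def _random_cds(n_codons: int, gc3_target: float, rng: np.random.Generator) -> str:
    """ATG + (n_codons-2) sampled codons + stop; third base G/C w.p. gc3_target."""
    body = []
    aas = rng.choice(_SAMPLED_AAS, size=n_codons - 2)
    gc_draw = rng.random(n_codons - 2) < gc3_target
    for aa, use_gc in zip(aas, gc_draw):
        pool = _GC_THIRD[aa] if use_gc else _AT_THIRD[aa]
        body.append(pool[rng.integers(len(pool))])
    stop = STOP_CODONS[rng.integers(3)]
    return "ATG" + "".join(body) + stop


def _mutate_base(base: str, ts_tv_ratio: float, rng: np.random.Generator) -> str:
    """Substitute a base; transition chosen with probability ts/(ts+1)."""
    if rng.random() < ts_tv_ratio / (ts_tv_ratio + 1.0):
        return TRANSITIONS[base]
    pool = [b for b in BASES if b != base and b != TRANSITIONS[base]]
    return pool[rng.integers(2)]


def generate_transcriptome(
    n_genes: int,
    length_params: dict | None = None,
    gc3_modes: list | None = None,
    ts_tv_ratio: float = 2.0,
    n_paralog_pairs: int = 0,
    n_allelic_variants: int = 0,
    seed: int = 0,
    utr5_length: dict | None = None,
    utr3_length: dict | None = None,
    paralog_divergence: float = 0.04,
    snps_per_variant_gene: int = 3,
):
    """Generate a synthetic transcript set with planted variants and paralogs.

    Parameters
    ----------
    n_genes
        Number of base genes (paralog copies are added on top).
    length_params
        Distribution spec for CDS length in codons (default truncated normal,
        mean 240 codons, sd 80, floor 60 — a ~720 bp median CDS).
    gc3_modes
        List of ``(center, weight)`` pairs; each gene draws its GC3 target
        from one mode.  Default single mode at 0.45.
    ts_tv_ratio
        Transition:transversion odds for planted variant alleles.
    n_allelic_variants
        Number of genes that receive a second haplotype carrying
        ``snps_per_variant_gene`` linked substitutions in the 5' 500 bp.
    n_paralog_pairs
        Number of genes duplicated at ``paralog_divergence`` per-site
        divergence.

    Returns
    -------
    (list of GeneModel, SimTruth)
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if ts_tv_ratio <= 0:
        raise ParameterError("ts_tv_ratio must be > 0")
    gc3_modes = gc3_modes or [(0.45, 1.0)]
    weights = np.array([w for _, w in gc3_modes], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ParameterError("gc3 mode weights must sum to 1")
    centers = np.array([c for c, _ in gc3_modes], dtype=float)
    if ((centers < 0) | (centers > 1)).any():
        raise ParameterError("gc3 mode centers must lie in [0, 1]")
    length_params = length_params or {"kind": "truncnorm", "mean": 240, "sd": 80, "min": 60}
    utr5_length = utr5_length or {"kind": "truncnorm", "mean": 160, "sd": 60, "min": 20}
    utr3_length = utr3_length or {"kind": "truncnorm", "mean": 240, "sd": 80, "min": 20}

    rng = np.random.default_rng(seed)
    n_codons = sample_lengths(length_params, n_genes, rng)
    u5 = sample_lengths(utr5_length, n_genes, rng)
    u3 = sample_lengths(utr3_length, n_genes, rng)
    mode_idx = rng.choice(len(centers), size=n_genes, p=weights)

    genes = []
    for i in range(n_genes):
        gid = f"g{i:04d}"
        target = float(centers[mode_idx[i]])
        genes.append(
            GeneModel(
                gene_id=gid,
                utr5=_random_utr(int(u5[i]), rng),
                cds=_random_cds(max(int(n_codons[i]), 3), target, rng),
                utr3=_random_utr(int(u3[i]), rng),
                gc3_target=target,
            )
        )

    truth = SimTruth()

    # allelic variants: one alternate haplotype of linked SNPs per chosen gene,
    # planted in the 5' 500 bp so 5'-anchored reads observe them
    if n_allelic_variants > 0:
        if n_allelic_variants > n_genes:
            raise ParameterError("n_allelic_variants exceeds n_genes")
        chosen = rng.choice(n_genes, size=n_allelic_variants, replace=False)
        for gi in chosen:
            g = genes[gi]
            tx = g.transcript
            span = min(len(tx), 500)
            k = min(snps_per_variant_gene, span)
            positions = sorted(rng.choice(span, size=k, replace=False))
            for pos in positions:
                ref = tx[pos]
                alt = _mutate_base(ref, ts_tv_ratio, rng)
                truth.snp_sites.append((g.gene_id, int(pos), (ref, alt), (0.5, 0.5)))

    # paralog pairs: duplicate genes with divergence * transcript-length
    # substitutions spread over UTRs and CDS (so the per-aligned-base fixed
    # difference density of a collapsed pair equals the divergence), avoiding
    # the start/stop codons, new in-frame stops, and new UTR start codons
    if n_paralog_pairs > 0:
        if n_paralog_pairs > n_genes:
            raise ParameterError("n_paralog_pairs exceeds n_genes")
        chosen = rng.choice(n_genes, size=n_paralog_pairs, replace=False)
        for gi in chosen:
            g = genes[gi]
            tx = list(g.transcript)
            cds_lo, cds_hi = len(g.utr5), len(g.utr5) + len(g.cds)
            n_mut = max(1, round(paralog_divergence * len(tx)))
            mutable = [
                p for p in range(len(tx))
                if not (cds_lo <= p < cds_lo + 3 or cds_hi - 3 <= p < cds_hi)
            ]
            rng.shuffle(mutable)
            done = 0
            for pos in mutable:
                if done >= n_mut:
                    break
                old = tx[pos]
                tx[pos] = _mutate_base(old, ts_tv_ratio, rng)
                if cds_lo <= pos < cds_hi:
                    codon_start = cds_lo + ((pos - cds_lo) // 3) * 3
                    if "".join(tx[codon_start:codon_start + 3]) in STOP_CODONS:
                        tx[pos] = old
                        continue
                else:
                    window = "".join(tx[max(pos - 2, 0):pos + 3])
                    if "ATG" in window:
                        tx[pos] = old
                        continue
                done += 1
            pid = g.gene_id + "p"
            seq = "".join(tx)
            genes.append(
                GeneModel(
                    gene_id=pid,
                    utr5=seq[:cds_lo],
                    cds=seq[cds_lo:cds_hi],
                    utr3=seq[cds_hi:],
                    gc3_target=g.gc3_target,
                )
            )
            truth.paralog_pairs.append((g.gene_id, pid, paralog_divergence))

    return genes, truth


# ---------------------------------------------------------------------------
# EST library simulation
# ---------------------------------------------------------------------------

@dataclass
class _VariantTable:
    """Per-gene alternate haplotype lookup built from SimTruth.snp_sites."""

    alt_sites: dict  # gene_id -> list of (pos, alt)
    alt_freq: dict   # gene_id -> frequency of the alternate haplotype

    @classmethod
    def from_truth(cls, truth: SimTruth):
        alt_sites, alt_freq = {}, {}
        for gene_id, pos, (ref, alt), (f_ref, f_alt) in truth.snp_sites:
            alt_sites.setdefault(gene_id, []).append((pos, alt))
            alt_freq[gene_id] = f_alt
        return cls(alt_sites, alt_freq)

    def haplotype(self, gene_id: str, transcript: str, use_alt: bool) -> str:
        if not use_alt or gene_id not in self.alt_sites:
            return transcript
        seq = list(transcript)
        for pos, alt in self.alt_sites[gene_id]:
            seq[pos] = alt
        return "".join(seq)


def _apply_substitutions(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        base = arr[i].decode()
        if base in BASES:
            pool = [b for b in BASES if b != base]
            arr[i] = pool[rng.integers(3)].encode()
    return arr.tobytes().decode()


def _quality_string(length: int, rng: np.random.Generator) -> list:
    """Phred-like scores: high 5' plateau decaying toward the 3' end."""
    pos = np.arange(length)
    decay_start = max(length - 120, 0)
    q = np.full(length, 40.0)
    tail = pos >= decay_start
    q[tail] = 40.0 - 32.0 * (pos[tail] - decay_start) / max(length - decay_start, 1)
    q = q + rng.normal(0, 2.0, size=length)
    return np.clip(np.rint(q), 2, 60).astype(int).tolist()


def simulate_est_libraries(
    genes,
    designs,
    read_length: dict | None = None,
    adapter: str = "",
    polyA_length: dict | None = None,
    truth: SimTruth | None = None,
    with_qualities: bool = False,
):
    """Sample 5'-anchored EST reads for every library design.

    Each read is ``adapter + 5' transcript fragment (+ substitution errors) +
    polyA`` where the polyA run is appended only when the fragment reaches the
    transcript's 3' end.  Contaminant reads are drawn from a uniform-composition
    pool and recorded in the returned truth.

    Returns ``(list of EstRead, SimTruth)``; the returned truth extends the
    passed-in transcriptome truth with contaminant ids, per-read gene origins
    and haplotype assignments, and the condition-dependent gene set implied by
    the designs.
    """
    from .preprocess import EstRead  # local import to avoid a cycle

    if not designs:
        raise ParameterError("designs must be nonempty")
    read_length = read_length or {"kind": "truncnorm", "mean": 650, "sd": 150, "min": 100}
    polyA_length = polyA_length or {"kind": "constant", "value": 0}
    gene_by_id = {g.gene_id: g for g in genes}
    for d in designs:
        missing = set(d.expression) - set(gene_by_id)
        if missing:
            raise ParameterError(f"{d.library_id}: unknown genes {sorted(missing)[:5]}")

    truth = truth or SimTruth()
    out_truth = truth.merge(SimTruth(de_genes=_infer_de_genes(designs)))
    variants = _VariantTable.from_truth(truth)

    reads = []
    for d in designs:
        rng = np.random.default_rng(d.seed)
        gene_ids = sorted(d.expression)
        probs = np.array([d.expression[g] for g in gene_ids])
        probs = probs / probs.sum()
        choices = rng.choice(len(gene_ids), size=d.n_reads, p=probs)
        contam = rng.random(d.n_reads) < d.contaminant_fraction
        lengths = sample_lengths(read_length, d.n_reads, rng)
        polya = sample_lengths(polyA_length, d.n_reads, rng)
        for i in range(d.n_reads):
            rid = f"{d.library_id}_r{i:05d}"
            if contam[i]:
                seq = "".join(rng.choice(list(BASES), size=int(lengths[i])))
                out_truth.contaminant_ids.add(rid)
                out_truth.read_origins[rid] = None
            else:
                gid = gene_ids[choices[i]]
                use_alt = gid in variants.alt_sites and rng.random() < variants.alt_freq[gid]
                tx = variants.haplotype(gid, gene_by_id[gid].transcript, use_alt)
                frag = tx[: int(lengths[i])]
                frag = _apply_substitutions(frag, d.error_rate, rng)
                if len(frag) >= len(tx) and polya[i] > 0:
                    frag = frag + "A" * int(polya[i])
                seq = adapter + frag
                out_truth.read_origins[rid] = gid
                out_truth.read_haplotypes[rid] = int(use_alt)
            quals = _quality_string(len(seq), rng) if with_qualities else None
            reads.append(
                EstRead(read_id=rid, library_id=d.library_id, sequence=seq, qualities=quals)
            )
    return reads, out_truth


def _infer_de_genes(designs, fold: float = 2.0) -> set:
    """Genes whose mean sampling probability differs > ``fold``-fold between
    the development and stress condition blocks."""
    by_cond = {"development": [], "stress": []}
    for d in designs:
        by_cond[d.condition].append(d.expression)
    if not by_cond["development"] or not by_cond["stress"]:
        return set()
    all_genes = set()
    for maps in by_cond.values():
        for m in maps:
            all_genes |= set(m)
    de = set()
    for g in all_genes:
        dev = np.mean([m.get(g, 0.0) for m in by_cond["development"]])
        stress = np.mean([m.get(g, 0.0) for m in by_cond["stress"]])
        lo, hi = min(dev, stress), max(dev, stress)
        if lo == 0.0 and hi > 0.0:
            de.add(g)
        elif lo > 0.0 and hi / lo > fold:
            de.add(g)
    return de


def build_condition_designs(
    genes,
    n_dev: int = 4,
    n_stress: int = 4,
    n_de: int = 20,
    fold: float = 5.0,
    n_reads: int = 2000,
    contaminant_fraction: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
):
    """Standard two-condition experiment: uniform baseline expression with
    ``n_de`` genes shifted ``fold``-fold between blocks (half up in stress,
    half up in development).

    Returns ``(designs, de_gene_set)``.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    if n_de > len(gene_ids):
        raise ParameterError("n_de exceeds number of genes")
    de_idx = rng.choice(len(gene_ids), size=n_de, replace=False)
    up_in_stress = set(gene_ids[i] for i in de_idx[: n_de // 2])
    up_in_dev = set(gene_ids[i] for i in de_idx[n_de // 2:])

    def expression(condition):
        w = {}
        for g in gene_ids:
            base = 1.0
            if condition == "stress" and g in up_in_stress:
                base = fold
            elif condition == "development" and g in up_in_dev:
                base = fold
            w[g] = base
        total = sum(w.values())
        return {g: v / total for g, v in w.items()}

    designs = []
    for j in range(n_dev):
        designs.append(
            LibraryDesign(
                library_id=f"DEV{j + 1}",
                condition="development",
                n_reads=n_reads,
                expression=expression("development"),
                contaminant_fraction=contaminant_fraction,
                error_rate=error_rate,
                seed=int(rng.integers(2 ** 31 - 1)),
            )
        )
    for j in range(n_stress):
        designs.append(
            LibraryDesign(
                library_id=f"STR{j + 1}",
                condition="stress",
                n_reads=n_reads,
                expression=expression("stress"),
                contaminant_fraction=contaminant_fraction,
                error_rate=error_rate,
                seed=int(rng.integers(2 ** 31 - 1)),
            )
        )
    return designs, up_in_stress | up_in_dev
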