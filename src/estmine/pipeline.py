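"""End-to-end pipeline orchestration with a reproducible run manifest.

Stage order follows the EST-mining workflow: simulate (or ingest) reads,
trim, screen contaminants, cluster into contigs, annotate ORFs and GC
content, call SNPs, test differential expression, and test term enrichment.
A single global seed is expanded into per-stage substreams so any stage can
be re-run in isolation; every stage records its parameters and the SHA-256
checksums of its outputs in the manifest.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemble, dde, enrich, io, orfgc, preprocess, simulate, snp
from .errors import ConfigError

STAGES = ["simulate", "trim", "screen", "cluster", "orfgc", "snp", "dde", "enrich"]


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    simulate: dict = field(default_factory=dict)
    trim: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    orfgc: dict = field(default_factory=dict)
    snp: dict = field(default_factory=dict)
    dde: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    from_counts: str | None = None  # skip straight to the DE stage

    @classmethod
    def from_yaml(cls, path):
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict):
        if "seed" not in raw or not isinstance(raw["seed"], int):
            raise ConfigError("config requires an integer 'seed'")
        if "outdir" not in raw:
            raise ConfigError("config requires 'outdir'")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest, stage, outputs, params, status="ok"):
    manifest["stages"].append(
        {
            "stage": stage,
            "status": status,
            "params": params,
            "outputs": {str(p): _checksum(Path(p)) for p in outputs},
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "outdir": str(out), "stages": []}

    try:
        if config.from_counts:
            matrix = pd.read_csv(config.from_counts, sep="\t", index_col=0)
            for skipped in ("simulate", "trim", "screen", "cluster", "orfgc", "snp"):
                manifest["stages"].append(
                    {"stage": skipped, "status": "skipped", "params": {}, "outputs": {}}
                )
            _run_dde(matrix, config, out, manifest)
        else:
            state = _run_simulate(config, out, manifest)
            state = _run_trim(state, config, out, manifest)
            state = _run_screen(state, config, out, manifest)
            state = _run_cluster(state, config, out, manifest)
            _run_orfgc(state, config, out, manifest)
            _run_snp(state, config, out, manifest)
            de_results = _run_dde(state["matrix"], config, out, manifest)
            _run_enrich(state, de_results, config, out, manifest)
    except Exception as exc:  # record the failed stage, then re-raise
        manifest["stages"].append(
            {"stage": "FAILED", "status": "error", "error": repr(exc), "outputs": {}}
        )
        io.write_json(manifest, out / "manifest.json")
        raise

    io.write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

_TERM_POOL = [
    "kinase", "transporter", "oxidoreductase", "ribosomal", "transferase",
    "protease", "chaperone", "photosynthesis",
]


def _run_simulate(config, out, manifest):
    p = dict(config.simulate)
    seed = p.pop("seed", _stage_seed(config.seed, "simulate"))
    n_genes = p.pop("n_genes", 150)
    gc3_modes = p.pop("gc3_modes", [[0.40, 0.5], [0.80, 0.5]])
    gc3_modes = [tuple(m) for m in gc3_modes]
    design_p = p.pop("designs", {})
    adapter = p.pop("adapter", "GTTTCCCAGTCACGATA")
    polya = p.pop("polyA_length", {"kind": "uniform", "low": 10, "high": 25})
    read_length = p.pop("read_length", None)
    with_qualities = p.pop("with_qualities", False)

    genes, truth = simulate.generate_transcriptome(
        n_genes=n_genes, gc3_modes=gc3_modes, seed=seed, **p
    )
    designs, de_genes = simulate.build_condition_designs(
        genes, seed=_stage_seed(config.seed, "designs"), **design_p
    )
    reads, truth = simulate.simulate_est_libraries(
        genes, designs, read_length=read_length, adapter=adapter,
        polyA_length=polya, truth=truth, with_qualities=with_qualities,
    )

    # planted term annotation: condition-shifted genes share a response term
    rng = np.random.default_rng(_stage_seed(config.seed, "terms"))
    terms = {
        g.gene_id: ("stress_response" if g.gene_id in de_genes
                    else _TERM_POOL[rng.integers(len(_TERM_POOL))])
        for g in genes
    }

    io.write_reads(reads, out / ("reads.fastq" if with_qualities else "reads.fasta"))
    io.write_library_table(reads, designs, out / "library_table.tsv")
    pd.DataFrame(sorted(terms.items()), columns=["gene_id", "term"]).to_csv(
        out / "annotations.tsv", sep="\t", index=False
    )
    io.write_json(
        {
            "de_genes": truth.de_genes,
            "contaminant_ids": truth.contaminant_ids,
            "snp_sites": truth.snp_sites,
            "paralog_pairs": truth.paralog_pairs,
        },
        out / "truth.json",
    )
    _record(
        manifest, "simulate",
        [out / ("reads.fastq" if with_qualities else "reads.fasta"),
         out / "library_table.tsv", out / "annotations.tsv", out / "truth.json"],
        {"n_genes": n_genes, "seed": seed, "n_libraries": len(designs)},
    )
    return {
        "genes": genes, "designs": designs, "reads": reads, "truth": truth,
        "terms": terms, "adapter": adapter,
    }


def _run_trim(state, config, out, manifest):
    p = dict(config.trim)
    p.setdefault("adapter", state.get("adapter", ""))
    kept, rejected = preprocess.trim_reads(state["reads"], **p)
    io.write_reads(kept, out / "trimmed.fasta", fmt="fasta")
    pd.DataFrame(
        [(r.read_id, r.reason) for r in rejected], columns=["read_id", "reason"]
    ).to_csv(out / "rejections.tsv", sep="\t", index=False)
    _record(manifest, "trim", [out / "trimmed.fasta", out / "rejections.tsv"],
            {**p, "n_kept": len(kept), "n_rejected": len(rejected)})
    return {**state, "reads": kept}


def _run_screen(state, config, out, manifest):
    p = dict(config.screen)
    hits_path = p.pop("hits", None)
    if hits_path:
        hits = io.read_hit_table(hits_path)
    else:
        # emulate a bacterial-database search using the planted contaminants
        hits = [
            preprocess.SimilarityHit(
                query_id=rid, subject_id="bacterium_sp", pct_identity=95.0,
                align_length=400, evalue=1e-60, bitscore=700.0,
            )
            for rid in sorted(state["truth"].contaminant_ids)
        ]
        io.write_hit_table(hits, out / "bacterial_hits.tsv")
    ids = {r.read_id for r in state["reads"]}
    clean, contaminant = preprocess.screen_contaminants(ids, hits, **p)
    kept = [r for r in state["reads"] if r.read_id in clean]
    io.write_reads(kept, out / "screened.fasta", fmt="fasta")
    _record(manifest, "screen", [out / "screened.fasta"],
            {**p, "n_clean": len(clean), "n_contaminant": len(contaminant)})
    return {**state, "reads": kept}


def _run_cluster(state, config, out, manifest):
    contigs, singlets = assemble.cluster_ests(state["reads"], **config.cluster)
    table = {r.read_id: r.library_id for r in state["reads"]}
    matrix = assemble.build_count_matrix(contigs, singlets, table)
    summary = assemble.assembly_summary(contigs, singlets)
    io.write_contig_fasta(contigs, out / "contigs.fasta")
    io.write_membership(contigs, out / "membership.tsv")
    matrix.to_csv(out / "count_matrix.tsv", sep="\t")
    io.write_json(summary, out / "assembly_summary.json")
    _record(
        manifest, "cluster",
        [out / "contigs.fasta", out / "membership.tsv", out / "count_matrix.tsv",
         out / "assembly_summary.json"],
        {**config.cluster, "n_contigs": len(contigs), "n_singlets": len(singlets)},
    )
    return {**state, "contigs": contigs, "singlets": singlets, "matrix": matrix,
            "summary": summary}


def _run_orfgc(state, config, out, manifest):
    annotations = orfgc.annotate_contigs(state["contigs"])
    rows, gc3_values = [], []
    for ann, contig in zip(annotations, state["contigs"]):
        rows.append(
            (ann.contig_id, ann.frame, ann.strand, ann.cds_start, ann.cds_end,
             ann.utr5_len, ann.utr3_len, ann.full_length)
        )
        if ann.full_length:
            cds = orfgc.extract_cds(contig.consensus, ann)
            gc3_values.append(orfgc.gc_metrics(cds).gc3)
    pd.DataFrame(
        rows,
        columns=["contig_id", "frame", "strand", "cds_start", "cds_end",
                 "utr5_len", "utr3_len", "full_length"],
    ).to_csv(out / "cds_annotations.tsv", sep="\t", index=False)
    outputs = [out / "cds_annotations.tsv"]
    if gc3_values:
        smoothed, raw = orfgc.smoothed_histogram(gc3_values, **config.orfgc)
        pd.DataFrame({"class": range(len(raw)), "raw": raw, "smoothed": smoothed}).to_csv(
            out / "gc3_histogram.tsv", sep="\t", index=False
        )
        outputs.append(out / "gc3_histogram.tsv")
    _record(manifest, "orfgc", outputs,
            {**config.orfgc, "n_full_length": len(gc3_values)})
    state["annotations"] = {a.contig_id: a for a in annotations}
    return state


def _run_snp(state, config, out, manifest):
    results = [snp.detect_snps(c, **config.snp) for c in state["contigs"]]
    anns = state.get("annotations", {})
    by_id = {c.contig_id: c for c in state["contigs"]}
    kaks_rows = []
    for res in results:
        ann = anns.get(res.contig_id)
        if ann is None or not res.calls:
            continue
        consensus = by_id[res.contig_id].consensus
        for call in res.calls:
            snp.label_synonymy(call, ann, consensus)
        try:
            kk = snp.compute_kaks(res.calls, ann, consensus)
            kaks_rows.append((kk.contig_id, kk.ka, kk.ks,
                              kk.ratio if kk.defined else ""))
        except Exception:
            pass
    summary = snp.classify_and_summarize(results, state["contigs"])
    io.write_snp_table(results, state["contigs"], out / "snp_calls.tsv")
    pd.DataFrame(kaks_rows, columns=["contig_id", "ka", "ks", "ratio"]).to_csv(
        out / "kaks.tsv", sep="\t", index=False
    )
    io.write_json(summary, out / "snp_summary.json")
    _record(manifest, "snp",
            [out / "snp_calls.tsv", out / "kaks.tsv", out / "snp_summary.json"],
            {**config.snp, **{k: summary[k] for k in ("n_snps", "n_screened_contigs")}})
    state["snp_results"] = results
    state["snp_summary"] = summary
    return state


def _run_dde(matrix, config, out, manifest):
    p = dict(config.dde)
    cfg = dde.DeConfig(**p)
    results = dde.select_de_contigs(matrix, cfg)
    df = pd.DataFrame(
        [
            (r.contig_id, r.r_value, r.r_pvalue,
             float(r.ac_matrix.to_numpy()[~np.eye(len(r.ac_matrix), dtype=bool)].min()),
             "+".join(sorted(r.significant_by)))
            for r in results
        ],
        columns=["contig_id", "R", "p_R", "min_AC_p", "significant_by"],
    )
    df.to_csv(out / "de_table.tsv", sep="\t", index=False)
    outputs = [out / "de_table.tsv"]
    if len(results) >= 2:
        z, order, profiles = dde.profile_cluster(results)
        profiles.to_csv(out / "de_profiles.tsv", sep="\t")
        (out / "de_dendrogram.nwk").write_text(dde.linkage_to_newick(z, list(profiles.index)) + "\n")
        dde.plot_heatmap(profiles, out / "de_heatmap.png", z=z)
        outputs += [out / "de_profiles.tsv", out / "de_dendrogram.nwk",
                    out / "de_heatmap.png"]
    _record(manifest, "dde", outputs, {**p, "n_significant": len(results)})
    return results


def _run_enrich(state, de_results, config, out, manifest):
    """Term enrichment of the DE-selected contigs against all tested contigs,
    using the planted per-gene annotation carried through read origins."""
    truth, terms = state["truth"], state["terms"]
    contig_gene = {}
    for c in state["contigs"]:
        origins = [truth.read_origins.get(m.read_id) for m in c.members]
        origins = [g for g in origins if g]
        if origins:
            contig_gene[c.contig_id] = Counter(origins).most_common(1)[0][0]
    de_ids = {r.contig_id for r in de_results}

    def term_counts(dataset_id, contig_ids):
        annotated = [contig_gene[c] for c in contig_ids if c in contig_gene]
        counts = Counter(terms[g] for g in annotated if g in terms)
        return enrich.TermCounts(dataset_id=dataset_id, counts=dict(counts),
                                 total_annotated=len(annotated))

    focal = term_counts("de", de_ids)
    union = term_counts("all", set(contig_gene))
    table = enrich.term_enrichment_table(focal, union)
    table.to_csv(out / "enrichment.tsv", sep="\t")
    outputs = [out / "enrichment.tsv"]

    fam_path = config.enrich.get("family_matrix")
    if fam_path:
        fam = pd.read_csv(fam_path, sep="\t", index_col=0)
        labels = enrich.family_prevalence_screen(
            fam, config.enrich.get("focal", []),
            **{k: v for k, v in config.enrich.items()
               if k in ("min_focal", "max_other", "prominent_ratio")},
        )
        labels.to_csv(out / "family_labels.tsv", sep="\t")
        outputs.append(out / "family_labels.tsv")
    _record(manifest, "enrich", outputs, {"n_focal": focal.total_annotated})
    return table
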