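"""The three SNP quality filters, synonymy labels and KA/KS site counting."""

import pytest

from estmine import (
    classify_and_summarize,
    compute_kaks,
    detect_snps,
    label_synonymy,
    predict_cds,
    synonymous_site_counts,
)
from estmine.assemble import Contig, ContigMember
from estmine.snp import SnpCall


def _contig(rows, cid="c1", offsets=None):
    """Build a contig from equal-length aligned member strings."""
    offsets = offsets or [0] * len(rows)
    members = [
        ContigMember(read_id=f"r{i}", library_id="L1", offset=off,
                     strand="+", sequence=seq)
        for i, (seq, off) in enumerate(zip(rows, offsets))
    ]
    width = max(off + len(seq) for seq, off in zip(rows, offsets))
    consensus = []
    for j in range(width):
        votes = {}
        for seq, off in zip(rows, offsets):
            if 0 <= j - off < len(seq):
                b = seq[j - off]
                votes[b] = votes.get(b, 0) + 1
        consensus.append(max(sorted(votes), key=lambda b: votes[b]) if votes else "N")
    return Contig(contig_id=cid, members=members, consensus="".join(consensus))


BASE = "ACGGTCAGTCAGGATCCAGTCAAGGTACCGGATTCAGGCA"  # 40 nt backbone


def _with(base, subs):
    s = list(base)
    for pos, b in subs.items():
        s[int(pos)] = b
    return "".join(s)


class TestDetectSnps:
    def test_linked_balanced_snps_called_biallelic(self):
        # two haplotypes, two linked columns: 2xC/2xT at 10, 2xA/2xG at 25
        hap_a = _with(BASE, {10: "C", 25: "A"})
        hap_b = _with(BASE, {10: "T", 25: "G"})
        res = detect_snps(_contig([hap_a, hap_a, hap_b, hap_b]))
        assert {c.position for c in res.calls} == {10, 25}
        assert all(c.allelic_class == "bi" for c in res.calls)
        assert len(res.haplotypes) == 2

    def test_isolated_singleton_allele_not_called(self):
        # 1xG/3xA at one column, no other polymorphism
        err = _with(BASE, {15: "G"})
        ref = _with(BASE, {15: "A"})
        res = detect_snps(_contig([err, ref, ref, ref]))
        assert res.calls == []

    def test_singleton_haplotypes_removed(self):
        err1 = _with(BASE, {5: "T"})
        err2 = _with(BASE, {20: "C"})
        ref = BASE
        res = detect_snps(_contig([err1, err2, ref, ref]))
        assert res.calls == []
        assert all(len(h.member_read_ids) >= 2 for h in res.haplotypes)

    def test_below_min_reads_returns_reason(self):
        res = detect_snps(_contig([BASE, BASE, BASE]))
        assert not res.screened and res.calls == []
        assert "4" in res.reason

    def test_paralog_flag_from_fixed_differences(self):
        # two groups of 2 reads differing at 12 of 300 aligned bases: 4/100bp
        backbone = (BASE * 8)[:300]
        positions = list(range(10, 300, 25))[:12]
        grp_a = backbone
        grp_b = _with(backbone, {
            p: ("A" if backbone[p] != "A" else "G") for p in positions
        })
        res = detect_snps(_contig([grp_a, grp_a, grp_b, grp_b]),
                          paralog_divergence_cut=3.0)
        assert res.paralog_flag

    def test_low_divergence_not_flagged(self):
        backbone = (BASE * 8)[:300]
        grp_b = _with(backbone, {50: "A" if backbone[50] != "A" else "G",
                                   150: "A" if backbone[150] != "A" else "G"})
        res = detect_snps(_contig([backbone, backbone, grp_b, grp_b]),
                          paralog_divergence_cut=3.0)
        assert not res.paralog_flag  # 2 diffs / 300 bp < 3/100bp

    def test_low_quality_bases_never_support_an_allele(self):
        hap_a = _with(BASE, {10: "C"})
        hap_b = _with(BASE, {10: "T"})
        quals_good = [40] * len(BASE)
        quals_bad = [40] * len(BASE)
        quals_bad[10] = 5
        members = [
            ContigMember(f"r{i}", "L1", 0, "+", seq, quals)
            for i, (seq, quals) in enumerate([
                (hap_a, quals_good), (hap_a, quals_good),
                (hap_b, quals_bad), (hap_b, quals_bad),
            ])
        ]
        contig = Contig(contig_id="c1", members=members, consensus=hap_a)
        res = detect_snps(contig, quality_floor=20)
        assert res.calls == []  # the T allele is only seen in low-quality bases

    def test_n_bases_never_support_an_allele(self):
        hap_n = _with(BASE, {10: "N"})
        res = detect_snps(_contig([hap_n, hap_n, BASE, BASE]))
        assert res.calls == []

    def test_confidence_formula(self):
        hap_a = _with(BASE, {10: "C", 25: "A"})
        hap_b = _with(BASE, {10: "T", 25: "G"})
        res = detect_snps(_contig([hap_a, hap_a, hap_b, hap_b]))
        for call in res.calls:
            # d=4, minor=2: (1 - 1/4) * (2*2/4) = 0.75
            assert call.confidence == pytest.approx(0.75)

    def test_zero_error_planted_snps_full_recall_no_false_calls(self):
        from estmine import LibraryDesign, generate_transcriptome, simulate_est_libraries
        from estmine import cluster_ests

        genes, truth = generate_transcriptome(
            n_genes=12, n_allelic_variants=6, seed=23,
            length_params={"kind": "constant", "value": 120},
            utr5_length={"kind": "constant", "value": 40},
            utr3_length={"kind": "constant", "value": 40},
        )
        d = LibraryDesign(
            library_id="L1", condition="development", n_reads=240,
            expression={g.gene_id: 1 / len(genes) for g in genes}, seed=31,
        )
        reads, truth = simulate_est_libraries(
            genes, [d], truth=truth,
            read_length={"kind": "constant", "value": 440},
            polyA_length={"kind": "constant", "value": 0},
        )
        contigs, _ = cluster_ests(reads)
        planted = {}
        for gid, pos, alleles, freqs in truth.snp_sites:
            planted.setdefault(gid, set()).add(pos)
        from collections import Counter

        for c in contigs:
            origins = Counter(truth.read_origins[m.read_id] for m in c.members)
            gid = origins.most_common(1)[0][0]
            haps = Counter(truth.read_haplotypes[m.read_id] for m in c.members)
            res = detect_snps(c)
            expected = planted.get(gid, set())
            # both alleles need >= 2 carriers for a guaranteed call
            if expected and min(haps.get(0, 0), haps.get(1, 0)) >= 2:
                assert {call.position for call in res.calls} == expected
            if not expected:
                assert res.calls == []


class TestClassifyAndSummarize:
    def _call(self, alleles, cid="c1", pos=0):
        support = {b: 2 for b in alleles}
        return SnpCall(
            contig_id=cid, position=pos, ref_allele=alleles[0],
            alleles=support,
            allelic_class={2: "bi", 3: "tri"}.get(len(alleles), "tetra"),
            mutation_class="multi", confidence=0.75,
        )

    def test_transition_transversion_classification(self):
        from estmine.snp import _mutation_class

        assert _mutation_class({"C", "T"}) == "transition"
        assert _mutation_class({"A", "G"}) == "transition"
        assert _mutation_class({"A", "C"}) == "transversion"
        assert _mutation_class({"A", "C", "G"}) == "multi"

    def test_density_arithmetic(self):
        hap_a = (BASE * 5)[:200]
        hap_b = _with(hap_a, {10: "C" if hap_a[10] != "C" else "T",
                                50: "C" if hap_a[50] != "C" else "T"})
        contig = _contig([hap_a, hap_a, hap_b, hap_b])
        res = detect_snps(contig)
        assert len(res.calls) == 2
        summary = classify_and_summarize([res], [contig])
        # 2 SNPs over 200 screened bases -> 1.0 per 100 bp
        assert summary["snp_density_per_100bp"] == pytest.approx(1.0)
        assert summary["fraction_contigs_with_snp"] == 1.0

    def test_paralog_flagged_contigs_excluded(self):
        backbone = (BASE * 8)[:300]
        positions = list(range(10, 300, 20))[:14]
        grp_b = _with(backbone, {
            p: ("A" if backbone[p] != "A" else "G") for p in positions
        })
        flagged = _contig([backbone, backbone, grp_b, grp_b], cid="par")
        res = detect_snps(flagged)
        assert res.paralog_flag
        summary = classify_and_summarize([res], [flagged])
        assert summary["n_screened_contigs"] == 0
        assert summary["n_paralog_flagged"] == 1
        assert summary["n_snps"] == 0


class TestSynonymy:
    def _ann(self, consensus):
        return predict_cds(consensus, contig_id="c1")

    def _call(self, pos, alleles):
        return SnpCall(
            contig_id="c1", position=pos, ref_allele=list(alleles)[0],
            alleles={b: 2 for b in alleles}, allelic_class="bi",
            mutation_class="transition", confidence=0.75,
        )

    def test_third_position_gga_ggg_synonymous(self):
        consensus = "ATGGGATAA"  # M G *
        ann = self._ann(consensus)
        call = label_synonymy(self._call(5, {"A", "G"}), ann, consensus)
        assert call.synonymy == "synonymous"

    def test_first_position_gga_aga_nonsynonymous(self):
        consensus = "ATGGGATAA"
        ann = self._ann(consensus)
        call = label_synonymy(self._call(3, {"G", "A"}), ann, consensus)
        assert call.synonymy == "nonsynonymous"

    def test_utr_snp_is_noncoding(self):
        consensus = "CCATGGGATAACC"
        ann = self._ann(consensus)
        call = label_synonymy(self._call(12, {"C", "T"}), ann, consensus)
        assert call.synonymy == "noncoding"

    def test_position_beyond_consensus_raises(self):
        from estmine import DataError

        consensus = "ATGGGATAA"
        with pytest.raises(DataError):
            label_synonymy(self._call(99, {"A", "G"}), self._ann(consensus), consensus)


class TestKaKs:
    def test_site_count_conservation(self, rng):
        from estmine.simulate import _random_cds

        for _ in range(10):
            cds = _random_cds(50, float(rng.random()), rng)
            s, n = synonymous_site_counts(cds)
            # stop codon excluded -> 49 counted codons
            assert s + n == pytest.approx(3 * 49)
            assert s > 0 and n > 0

    def test_hand_computed_quotients(self):
        # 100 codons of GGA (glycine, 4-fold) + stop: per codon S = 1 (third
        # position fully synonymous: GGN all Gly; first/second all change)
        consensus = "ATG" + "GGA" * 99 + "TAA"
        ann = predict_cds(consensus)
        s, n = synonymous_site_counts(consensus)
        # ATG: S=0; GGA third position: GGG/GGT/GGC all Gly -> 1 syn site;
        # first position (AGA/CGA/TGA): AGA,CGA = Arg, TGA = stop -> 0;
        # second position 0
        assert s == pytest.approx(99 * 1.0)
        assert n == pytest.approx(3 * 100 - 99)
        calls = [
            self._labelled(5, "synonymous"), self._labelled(8, "synonymous"),
            self._labelled(6, "nonsynonymous"),
        ]
        kk = compute_kaks(calls, ann, consensus)
        assert kk.ks == pytest.approx(2 / 99)
        assert kk.ka == pytest.approx(1 / (300 - 99))
        assert kk.ratio == pytest.approx(kk.ka / kk.ks)

    def _labelled(self, pos, syn):
        call = SnpCall(
            contig_id="", position=pos, ref_allele="G",
            alleles={"G": 2, "A": 2}, allelic_class="bi",
            mutation_class="transition", confidence=0.75,
        )
        call.synonymy = syn
        return call

    def test_zero_snps_gives_undefined_ratio(self):
        consensus = "ATG" + "GGA" * 30 + "TAA"
        kk = compute_kaks([], predict_cds(consensus), consensus)
        assert kk.ka == 0 and kk.ks == 0 and kk.ratio is None

    def test_only_synonymous_snps_give_zero_ratio(self):
        consensus = "ATG" + "GGA" * 30 + "TAA"
        kk = compute_kaks([self._labelled(5, "synonymous")],
                          predict_cds(consensus), consensus)
        assert kk.ka == 0 and kk.ratio == 0.0
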