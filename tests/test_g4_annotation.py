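"""Motif scanning, projection, classification and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from _oracles import (
    alt_const_ratio_oracle,
    enumerate_label_assignments,
    exact_permutation_p,
    oracle_scan_pg4,
)

from g4utr.g4_annotation import (
    G4Motif,
    TranscriptModel,
    classify_expression,
    classify_isoforms,
    partition_tracts,
    permute_isoform_labels,
    project_to_genome,
    sample_pg4_label_counts,
    scan_pg4,
    scan_transcripts,
    transcript_offsets_to_genome,
)
from g4utr.intervals import GenomeIntervals
from g4utr.oe_substitution import revcomp
from g4utr.synthetic_data import SimulationConfig, make_transcriptome, random_motif


class TestScanPG4:
    @pytest.mark.parametrize(
        "seq,spans",
        [
            ("GGGAGGGAGGGAGGG", [(0, 15)]),  # minimal canonical motif
            ("GGAGGAGGAGG", []),  # no run of >=3 G
            ("GGGAAAAAAAAGGGAGGGAGGG", []),  # only arrangement has an 8-nt loop
            ("", []),
            ("TTGGGGTGGGAGGGCATGGGTT", [(2, 20)]),  # first tract maximal (4 G)
        ],
    )
    def test_known_sequences(self, seq, spans):
        assert [(m.start, m.end) for m in scan_pg4(seq)] == spans

    def test_minimal_motif_structure(self):
        (m,) = scan_pg4("GGGAGGGAGGGAGGG")
        assert [t.length for t in m.tracts] == [3, 3, 3, 3]
        assert [e - s for s, e in m.gaps] == [1, 1, 1]
        m.validate()

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            scan_pg4("GGGAXGGG")

    def test_n_breaks_runs(self):
        # N never counts as G: GGN GG is not a tract
        assert scan_pg4("GGNGAGGGAGGGAGGGAGG") == []

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(2024)
        bases = np.array(list("ACGTN"))
        for _ in range(300):
            p = rng.dirichlet([2, 2, 6, 2, 0.3])
            seq = "".join(bases[rng.choice(5, size=250, p=p)])
            got = [(m.start, m.end) for m in scan_pg4(seq)]
            assert got == oracle_scan_pg4(seq), seq


class TestPartitionTracts:
    def test_central_offsets_minimal_motif(self):
        (m,) = scan_pg4("GGGAGGGAGGGAGGG")
        centrals = [t.positional_labels["central"] for t in m.tracts]
        assert centrals == [1, 5, 9, 13]

    def test_long_tract_unlabelled(self):
        (m,) = scan_pg4("GGGGAGGGAGGGAGGG")
        assert m.tracts[0].length == 4 and m.tracts[0].positional_labels is None
        assert all(t.positional_labels is not None for t in m.tracts[1:])

    def test_roundtrip_tiling_random_motifs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            seq = random_motif(rng)
            (m,) = scan_pg4(seq)
            tracts, gaps = partition_tracts(m)
            pieces = sorted([(t.start, t.end) for t in tracts] + gaps)
            rebuilt = "".join(seq[s:e] for s, e in pieces)
            assert rebuilt == seq
            assert pieces[0][0] == 0 and pieces[-1][1] == len(seq)


def _single_exon_tx(strand, utr5_seq="A" * 20):
    return TranscriptModel(
        transcript_id="T1",
        gene_id="G1",
        chrom="chr1",
        strand=strand,
        utr5_blocks=[(1000, 1100)],
        utr5_seq="A" * 100,
        cds_blocks=[(1200, 1500)] if strand == "+" else [(800, 900)],
    )


class TestProjection:
    def test_plus_strand_single_exon(self):
        t = _single_exon_tx("+")
        m = G4Motif(10, 25, "A" * 15, [], [], "T1", "5p")
        project_to_genome(m, t)
        assert m.genomic_blocks == [(1010, 1025)]

    def test_minus_strand_reflection(self):
        t = _single_exon_tx("-")
        m = G4Motif(10, 25, "A" * 15, [], [], "T1", "5p")
        project_to_genome(m, t)
        assert m.genomic_blocks == [(1075, 1090)]

    def test_splice_junction_two_blocks(self):
        # UTR = [1000,1040) + [2000,2060); motif spans the junction
        t = TranscriptModel(
            "T1", "G1", "chr1", "+",
            utr5_blocks=[(1000, 1040), (2000, 2060)], utr5_seq="A" * 100,
        )
        m = G4Motif(30, 55, "A" * 25, [], [], "T1", "5p")
        project_to_genome(m, t)
        assert m.genomic_blocks == [(1030, 1040), (2000, 2015)]
        assert sum(e - s for s, e in m.genomic_blocks) == 25

    def test_offset_beyond_utr_raises(self):
        t = _single_exon_tx("+")
        m = G4Motif(90, 105, "A" * 15, [], [], "T1", "5p")
        with pytest.raises(ValueError):
            project_to_genome(m, t)

    def test_cds_overlap_flagged(self):
        t = _single_exon_tx("+")
        cds = GenomeIntervals([("chr1", 1020, 1030)])
        m = G4Motif(10, 25, "A" * 15, [], [], "T1", "5p")
        project_to_genome(m, t, cds)
        assert m.cds_overlap
        m2 = G4Motif(40, 55, "A" * 15, [], [], "T1", "5p")
        project_to_genome(m2, t, cds)
        assert not m2.cds_overlap

    def test_minus_strand_matches_c_motif_on_plus_strand(self):
        """Projected blocks of a sense-scanned motif on a - strand transcript
        coincide with the C-run pattern on the + strand reference."""
        rng = np.random.default_rng(8)
        motif = random_motif(rng)
        sense = "ACT" * 10 + motif + "TCA" * 10
        plus = revcomp(sense)
        t = TranscriptModel(
            "T1", "G1", "chr1", "-",
            utr3_blocks=[(500, 500 + len(sense))], utr3_seq=sense,
        )
        (m,) = scan_pg4(sense, "T1", "3p")
        project_to_genome(m, t)
        ((gs, ge),) = m.genomic_blocks
        # the + strand slice over the projected block is the C-motif
        frag = plus[gs - 500 : ge - 500]
        assert frag == revcomp(motif)
        # its maximal C-runs mirror the motif's G-tracts in reverse order
        import re

        c_runs = [len(r) for r in re.findall("C+", frag) if len(r) >= 3]
        assert c_runs == [t.length for t in reversed(m.tracts)]


class TestIsoformClassification:
    def _tx(self, tx_id, gene="G1"):
        return TranscriptModel(tx_id, gene, "chr1", "+", utr5_blocks=[(0, 50)], utr5_seq="A" * 50)

    def _motif(self, tx_id, blocks):
        m = G4Motif(0, 15, "G" * 15, [], [], tx_id, "5p")
        m.genomic_blocks = blocks
        return m

    def test_constitutive_identical(self):
        txs = [self._tx(f"T{i}") for i in range(3)]
        motifs = [self._motif(f"T{i}", [(5, 20)]) for i in range(3)]
        c = classify_isoforms(txs, motifs, "5p")
        assert c.status == "constitutive" and c.identical_pg4
        assert (c.n_pg4_isoforms, c.n_total_isoforms) == (3, 3)

    def test_alternative(self):
        txs = [self._tx("T0"), self._tx("T1")]
        c = classify_isoforms(txs, [self._motif("T0", [(5, 20)])], "5p")
        assert c.status == "alternative"

    def test_cds_overlapping_motifs_ignored(self):
        txs = [self._tx("T0")]
        m = self._motif("T0", [(5, 20)])
        m.cds_overlap = True
        assert classify_isoforms(txs, [m], "5p").status == "non_pg4"

    def test_matches_generator_truth(self, small_transcriptome):
        tr = small_transcriptome
        motifs = scan_transcripts(tr.transcripts)
        by_gene = {}
        for t in tr.transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for r in tr.truth_genes.itertuples():
            c = classify_isoforms(by_gene[r.gene_id], motifs, r.utr_side)
            assert c.status == r.status
            assert c.n_pg4_isoforms == r.n_pg4_isoforms

    def test_invariant_to_transcript_order(self, small_transcriptome):
        tr = small_transcriptome
        motifs = scan_transcripts(tr.transcripts)
        gene = tr.truth_genes.iloc[0]["gene_id"]
        txs = [t for t in tr.transcripts if t.gene_id == gene]
        a = classify_isoforms(txs, motifs, "5p")
        b = classify_isoforms(list(reversed(txs)), motifs, "5p")
        assert vars(a) == vars(b)


class TestClassifyExpression:
    def _gene(self):
        txs = [
            TranscriptModel("P", "G1", "chr1", "+", utr5_blocks=[(0, 10)], utr5_seq="A" * 10),
            TranscriptModel("N", "G1", "chr1", "+", utr5_blocks=[(0, 10)], utr5_seq="A" * 10),
        ]
        return txs, {"P"}

    @pytest.mark.parametrize(
        "p_tpm,n_tpm,label",
        [
            (5.0, 3.0, "both_expressed"),
            (0.9, 1.2, "non_pg4_only"),
            (1.0, 1.0, "neither"),  # threshold is strict > 1
            (2.0, 0.5, "pg4_only"),
        ],
    )
    def test_threshold_rule(self, p_tpm, n_tpm, label):
        txs, pg4 = self._gene()
        tpm = pd.DataFrame({"muscle": [p_tpm, n_tpm]}, index=["P", "N"])
        assert classify_expression(txs, pg4, tpm) == {"muscle": label}

    def test_missing_transcript_raises(self):
        txs, pg4 = self._gene()
        tpm = pd.DataFrame({"muscle": [5.0]}, index=["P"])
        with pytest.raises(KeyError):
            classify_expression(txs, pg4, tpm)


class TestIsoformPermutation:
    def test_two_gene_fixture_matches_exhaustive_enumeration(self):
        # 2 genes x 2 isoforms, 1 pG4 each: 4 equally likely assignments,
        # all alternative, so p = 1 exactly
        res = permute_isoform_labels([(2, 1), (2, 1)], n_iter=999, seed=3)
        assert res.p_value == pytest.approx(exact_permutation_p([2, 2], [1, 1]))
        assert res.p_value == 1.0

    def test_richer_fixture_matches_enumeration(self):
        n, k = [3, 2, 4], [1, 2, 2]
        exact = exact_permutation_p(n, k)
        res = permute_isoform_labels(list(zip(n, k)), n_iter=20000, seed=11)
        assert res.observed_ratio == alt_const_ratio_oracle(k, n)
        assert res.p_value == pytest.approx(exact, abs=0.015)

    def test_single_isoform_genes_give_p_one(self):
        res = permute_isoform_labels([(1, 1)] * 10, n_iter=99, seed=1)
        assert res.p_value == 1.0

    def test_zero_pg4_genes_excluded(self, caplog):
        res = permute_isoform_labels([(2, 1), (3, 0)], n_iter=99, seed=1)
        assert res.n_iter == 99  # ran on the single remaining gene

    def test_sampler_distribution_matches_enumeration(self):
        """The sequential sampler is uniform over valid label assignments."""
        n = [3, 2, 4]
        k_total = 5
        tally = enumerate_label_assignments(n, k_total)
        total = sum(tally.values())
        rng = np.random.default_rng(42)
        draws = sample_pg4_label_counts(np.array(n), k_total, 20000, rng)
        for counts, mult in tally.items():
            freq = np.mean(np.all(draws == np.array(counts), axis=1))
            assert freq == pytest.approx(mult / total, abs=0.015)

    def test_null_p_values_valid(self):
        """KS-style diagnostic: under random pG4 assignment the permutation
        p-value is valid, i.e. P(p <= x) <= x (the alternative:constitutive
        ratio is discrete, so the p-value is conservative rather than exactly
        uniform)."""
        n = np.array([int(x) for x in np.random.default_rng(0).integers(1, 6, 40)])
        k_total = int(n.sum() * 0.5)
        k_total = max(len(n), k_total)
        gen = np.random.default_rng(99)
        pvals = []
        for _ in range(500):
            truth = sample_pg4_label_counts(n, k_total, 1, gen)[0]
            res = permute_isoform_labels(
                list(zip(n.tolist(), truth.tolist())), n_iter=199,
                seed=int(gen.integers(2**31)),
            )
            pvals.append(res.p_value)
        pvals = np.sort(pvals)
        grid = np.linspace(0.05, 1.0, 20)
        ecdf = np.searchsorted(pvals, grid, side="right") / len(pvals)
        assert np.max(ecdf - grid) < 0.05  # validity up to sampling noise
        assert np.mean(pvals) > 0.45  # and centred, not degenerate
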