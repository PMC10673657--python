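"""tasiARF scanning, TAS3 dual-site classification, cis/trans labels,
shared-phasiRNA reporting and network export."""

import numpy as np
import pandas as pd
import pytest

from phasikit.annotate import (
    annotate_loci,
    classify_cis_trans,
    classify_tas3,
    export_network,
    find_tasiarf_matches,
    shared_phasirna_report,
    tas3_report,
)
from phasikit.io_formats import revcomp
from phasikit.loci import PhasiRNA, PhasLocus

TASIARF = "TTCTTGACCTTGTAAGACCCC"  # 21 nt
RNG = np.random.default_rng(7)


def rand_seq(n):
    return "".join(RNG.choice(list("ACGT"), size=n))


def mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def brute_force_matches(query, genome, max_mm):
    hits = []
    for contig, seq in genome.items():
        for strand, q in (("+", query), ("-", revcomp(query))):
            for i in range(len(seq) - len(q) + 1):
                mm = sum(a != b for a, b in zip(seq[i : i + len(q)], q))
                if mm <= max_mm:
                    hits.append((contig, i + 1, strand, mm))
    return sorted(hits)


def make_locus(name="PHAS_c1_1", contig="c1", start=1000, end=1400):
    return PhasLocus(
        name=name, contig=contig, start=start, end=end, cycle=21,
        p_value=1e-9, p_adjusted=1e-6, max_phase_score=20, anchor=start,
    )


class TestTasiarfScan:
    def test_mismatch_ladder(self):
        genome = {
            "c1": rand_seq(300) + TASIARF + rand_seq(100)
            + mutate(TASIARF, [3]) + rand_seq(100)
            + mutate(TASIARF, [3, 9]) + rand_seq(100)
            + mutate(TASIARF, [3, 9, 15]) + rand_seq(200)
        }
        matches = find_tasiarf_matches({"arf": TASIARF}, genome, max_mismatches=2)
        assert sorted(m.mismatches for m in matches) == [0, 1, 2]

    def test_minus_strand_found(self):
        genome = {"c1": rand_seq(100) + revcomp(TASIARF) + rand_seq(100)}
        matches = find_tasiarf_matches({"arf": TASIARF}, genome)
        assert [(m.match_start, m.strand, m.mismatches) for m in matches] == [(101, "-", 0)]

    def test_flank_bounds_clamped(self):
        genome = {"c1": rand_seq(30) + TASIARF + rand_seq(60)}
        m = find_tasiarf_matches({"arf": TASIARF}, genome)[0]
        assert (m.flank_start, m.flank_end) == (1, len(genome["c1"]))
        genome = {"c1": rand_seq(400) + TASIARF + rand_seq(400)}
        m = find_tasiarf_matches({"arf": TASIARF}, genome)[0]
        assert (m.flank_start, m.flank_end) == (401 - 250, 421 + 250)

    def test_brute_force_oracle_equality(self):
        genome = {"c1": rand_seq(4000) + mutate(TASIARF, [5]) + rand_seq(4000)}
        got = sorted(
            (m.contig, m.match_start, m.strand, m.mismatches)
            for m in find_tasiarf_matches({"arf": TASIARF}, genome, max_mismatches=2)
        )
        assert got == brute_force_matches(TASIARF, genome, 2)

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            find_tasiarf_matches({"bad": "ACGT"}, {"c1": rand_seq(100)})


class TestClassifyTas3:
    MIR390 = rand_seq(21)

    def build_genome(self, with_5p=True, with_3p=True):
        site = revcomp(self.MIR390)
        left = site if with_5p else rand_seq(21)
        right = site if with_3p else rand_seq(21)
        seq = rand_seq(300) + left + rand_seq(60) + TASIARF + rand_seq(60) + right + rand_seq(300)
        return {"c1": seq}

    def classify(self, genome):
        match = find_tasiarf_matches({"arf": TASIARF}, genome)[0]
        return classify_tas3(match, genome, {"miR390": self.MIR390}, max_mismatches=0)

    def test_dual_site_architecture(self):
        m = self.classify(self.build_genome())
        assert m.classification == "TAS3-like"
        assert len(m.mir390_sites_5p) == 1 and len(m.mir390_sites_3p) == 1

    def test_single_site(self):
        assert self.classify(self.build_genome(with_3p=False)).classification == "single-site"

    def test_zero_sites(self):
        assert self.classify(self.build_genome(False, False)).classification == "unclassified"

    def test_report_columns(self):
        df = tas3_report([self.classify(self.build_genome())])
        assert df.iloc[0]["classification"] == "TAS3-like"


class TestCisTrans:
    def targets(self):
        return pd.DataFrame(
            [
                {"phasirna": "PHAS_c1_1_siR1", "transcript": "tx_self"},
                {"phasirna": "PHAS_c1_1_siR1", "transcript": "tx_family"},
                {"phasirna": "PHAS_c1_1_siR2", "transcript": "tx_other"},
            ]
        )

    COORDS = {
        "tx_self": ("c1", 950, 1450, "+"),
        "tx_family": ("c2", 5000, 6000, "+"),
        "tx_other": ("c2", 9000, 9500, "+"),
    }

    def test_classification_and_precedence(self):
        out = classify_cis_trans(
            self.targets(), [make_locus()], self.COORDS,
            locus_families={"PHAS_c1_1": "NB-LRR"},
            transcript_families={"tx_family": "NB-LRR", "tx_self": "NB-LRR"},
        )
        by_tx = dict(zip(out["transcript"], out["target_class"]))
        # overlapping the generating locus wins even when families also match
        assert by_tx == {"tx_self": "cis", "tx_family": "same_family", "tx_other": "other"}

    def test_row_order_invariance(self):
        a = classify_cis_trans(self.targets(), [make_locus()], self.COORDS)
        b = classify_cis_trans(
            self.targets().iloc[::-1].reset_index(drop=True), [make_locus()], self.COORDS
        )
        assert dict(zip(a["transcript"], a["target_class"])) == dict(
            zip(b["transcript"], b["target_class"])
        )

    def test_missing_annotation_degrades_to_other(self):
        out = classify_cis_trans(self.targets(), [make_locus()], self.COORDS)
        assert set(out["target_class"]) == {"cis", "other"}


class TestSharedAndNetwork:
    def loci_with_shared(self):
        a, b = make_locus("PHAS_c1_1"), make_locus("PHAS_c1_2", start=5000, end=5400)
        shared_seq = "ACGGTTACGGATCCGTAGCTA"
        a.phasirnas = [PhasiRNA("PHAS_c1_1_siR1", shared_seq, 1000, "+", {"l": 1})]
        b.phasirnas = [
            PhasiRNA("PHAS_c1_2_siR1", shared_seq, 5000, "+", {"l": 1}),
            PhasiRNA("PHAS_c1_2_siR2", "T" * 21, 5021, "+", {"l": 1}),
        ]
        return [a, b]

    def test_shared_report(self):
        df = shared_phasirna_report(self.loci_with_shared())
        assert len(df) == 1
        assert df.iloc[0]["n_loci"] == 2

    def test_no_sharing_empty(self):
        loci = self.loci_with_shared()
        loci[1].phasirnas = loci[1].phasirnas[1:]
        assert shared_phasirna_report(loci).empty
        assert shared_phasirna_report(loci[:1]).empty

    def test_network_edges_and_determinism(self):
        loci = self.loci_with_shared()
        targets = pd.DataFrame(
            [{"phasirna": "PHAS_c1_1_siR1", "transcript": "g1", "target_class": "cis"}]
        )
        net = export_network(loci, targets)
        gen = net[net["interaction"] == "generates"]
        tgt = net[net["interaction"] == "targets"]
        assert len(gen) == 3 and len(tgt) == 1
        assert tgt.iloc[0]["source"] == "PHAS_c1_1_siR1" and tgt.iloc[0]["sink"] == "g1"
        assert net.equals(export_network(loci, targets))


class TestAnnotateLoci:
    ANNOT = pd.DataFrame(
        [
            {"contig": "c1", "start": 900, "end": 1200, "label": "geneA", "family": "NB-LRR"},
            {"contig": "c1", "start": 1300, "end": 1500, "label": "geneB", "family": "PPR"},
        ]
    )

    def test_overlap_join_with_multi_hit_flag(self):
        df = annotate_loci([make_locus()], self.ANNOT)
        assert sorted(df["label"]) == ["geneA", "geneB"]
        assert df["multi_hit"].all()

    def test_unmatched_labeled_unannotated(self):
        df = annotate_loci([make_locus(contig="c9")], self.ANNOT)
        assert df.iloc[0]["label"] == "unannotated"

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            annotate_loci([make_locus()], pd.DataFrame({"contig": []}))
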