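"""Anchor location, translation, linker/domain calling, aggregation."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from bitescreen.amplicon_classify import (
    STATUS_AMBIGUOUS,
    STATUS_FRAME_ERROR,
    STATUS_INTERNAL_STOP,
    STATUS_NO_ANCHOR,
    STATUS_OK,
    STATUS_UNASSIGNED,
    CCSRead,
    ClassifierConfig,
    cdrh3_composition,
    classify_read,
    classify_reads,
    deduplicate,
    locate_anchors,
    status_counts,
    summarize_design_distribution,
)
from bitescreen.library_design import (
    HISTAG_2A_DNA,
    SIGNAL_AA,
    SIGNAL_DNA,
    AnchorSet,
    enumerate_library,
    reverse_translate,
)
from bitescreen.screen_sim import ReadErrorModel, simulate_ccs_reads


@pytest.fixture(scope="module")
def config(panel):
    return ClassifierConfig.from_definition(panel)


@pytest.fixture(scope="module")
def sample_variants(panel):
    """One variant per (linker, orientation) pair plus assorted CDRH3 hits."""
    variants = list(itertools.islice(enumerate_library(panel, with_dna=True), 200))
    picked = {}
    for v in variants:
        picked.setdefault((v.linker.name, v.orientation.label), v)
    return list(picked.values()) + variants[::37]


def _truth_tuple(v):
    return (v.cd19_variant.variant_id, v.cd3.name, v.linker.name, v.orientation.label)


def _call_tuple(call):
    if call.cdrh3_mutations:
        pos, _, aa = call.cdrh3_mutations[0]
        cd19 = f"{call.cd19_id}|{pos}{aa}"
    else:
        cd19 = f"{call.cd19_id}|parent"
    return (cd19, call.cd3_id, call.linker_id, call.orientation_label)


class TestRoundTrip:
    def test_clean_reads_reproduce_variant_labels_both_strands(
        self, sample_variants, config
    ):
        for v in sample_variants:
            fwd = CCSRead("f", v.dna_seq)
            rev = CCSRead("r", str(Seq(v.dna_seq).reverse_complement()))
            for read, strand in ((fwd, "forward"), (rev, "reverse")):
                call = classify_read(read, config)
                assert call.status == STATUS_OK
                assert call.strand == strand
                assert _call_tuple(call) == _truth_tuple(v)
                assert call.protein_seq == v.protein_seq

    def test_longest_linker_wins_over_its_prefix(self, sample_variants, config):
        rigid_long = next(v for v in sample_variants if v.linker.name == "rigid_long")
        call = classify_read(CCSRead("x", rigid_long.dna_seq), config)
        assert call.linker_id == "rigid_long"  # not the AEAAAKA prefix


class TestAnchors:
    @staticmethod
    def _substitute(dna, pos):
        """Substitution at pos that does not create an in-frame stop codon."""
        stops = {"TAA", "TAG", "TGA"}
        codon_start = pos - pos % 3
        for base in "ACGT":
            if base == dna[pos]:
                continue
            codon = dna[codon_start:pos] + [base] + dna[pos + 1 : codon_start + 3]
            if "".join(codon) not in stops:
                dna[pos] = base
                return

    def test_anchor_mismatch_boundary(self, sample_variants, config):
        v = sample_variants[0]
        mm = config.anchors.max_mismatches
        dna = list(v.dna_seq)
        # substitute inside the signal anchor: at the bound -> still ok
        for i in range(mm):
            self._substitute(dna, 3 * i + 1)
        at_bound = classify_read(CCSRead("b", "".join(dna)), config)
        assert at_bound.status == STATUS_OK
        # one more substitution -> anchor lost
        self._substitute(dna, 3 * mm + 1)
        over = classify_read(CCSRead("o", "".join(dna)), config)
        assert over.status == STATUS_NO_ANCHOR

    def test_missing_histag_anchor(self, sample_variants, config):
        v = sample_variants[0]
        truncated = v.dna_seq[: -len(HISTAG_2A_DNA)]
        assert classify_read(CCSRead("t", truncated), config).status == STATUS_NO_ANCHOR

    def test_reverse_strand_coordinates_remapped(self, sample_variants, config):
        v = sample_variants[0]
        rc = str(Seq(v.dna_seq).reverse_complement())
        oriented = locate_anchors(CCSRead("r", rc), config.anchors)
        assert oriented.strand == "reverse"
        assert oriented.seq[oriented.signal_start:oriented.signal_end] == SIGNAL_DNA

    def test_padding_outside_anchors_is_ignored(self, sample_variants, config):
        v = sample_variants[0]
        padded = "TTTTGCA" + v.dna_seq + "CCGGTTA"
        call = classify_read(CCSRead("p", padded), config)
        assert call.status == STATUS_OK
        assert call.protein_seq == v.protein_seq


class TestTranslationFailures:
    def test_insertion_between_anchors_is_frame_error(self, sample_variants, config):
        v = sample_variants[0]
        mid = len(SIGNAL_DNA) + 30
        dna = v.dna_seq[:mid] + "A" + v.dna_seq[mid:]
        assert classify_read(CCSRead("i", dna), config).status == STATUS_FRAME_ERROR

    def test_substitution_creating_stop_is_internal_stop(self, sample_variants, config):
        v = sample_variants[0]
        # find a lysine codon AAG in the body and mutate it to the TAG stop
        body_start = len(SIGNAL_DNA)
        idx = v.protein_seq.index("K", len(SIGNAL_AA))
        pos = body_start + 3 * (idx - len(SIGNAL_AA))
        assert v.dna_seq[pos : pos + 3] == "AAG"
        dna = v.dna_seq[:pos] + "T" + v.dna_seq[pos + 1 :]
        assert classify_read(CCSRead("s", dna), config).status == STATUS_INTERNAL_STOP

    def test_n_in_coding_span_is_ambiguous(self, sample_variants, config):
        v = sample_variants[0]
        mid = len(SIGNAL_DNA) + 31
        dna = v.dna_seq[:mid] + "N" + v.dna_seq[mid + 1 :]
        assert classify_read(CCSRead("n", dna), config).status == STATUS_AMBIGUOUS


class TestDomainCalls:
    def test_cdrh3_substitution_does_not_change_domain_call(
        self, sample_variants, config
    ):
        mutant = next(
            v for v in sample_variants if not v.cd19_variant.is_parent
        )
        call = classify_read(CCSRead("m", mutant.dna_seq), config)
        assert call.status == STATUS_OK
        assert call.cd19_id == mutant.cd19_variant.parent.name
        assert call.identity_scores["cd19"] == 1.0  # CDRH3 masked

    def test_scrambled_half_is_unassigned(self, sample_variants, config):
        v = sample_variants[0]
        s, e = v.linker_span
        left = v.protein_seq[len(SIGNAL_AA) : s]
        rng = np.random.default_rng(3)
        scrambled = "".join(rng.permutation(list(left)))
        protein = v.protein_seq[: len(SIGNAL_AA)] + scrambled + v.protein_seq[s:]
        dna = SIGNAL_DNA + reverse_translate(protein[19:-25]) + HISTAG_2A_DNA
        assert classify_read(CCSRead("sc", dna), config).status == STATUS_UNASSIGNED

    def test_no_panel_linker_is_ambiguous(self, panel, config):
        v = next(enumerate_library(panel))
        s, e = v.linker_span
        protein = v.protein_seq[:s] + "PQPQPQP" + v.protein_seq[e:]
        dna = SIGNAL_DNA + reverse_translate(protein[19:-25]) + HISTAG_2A_DNA
        assert classify_read(CCSRead("nl", dna), config).status == STATUS_AMBIGUOUS

    def test_two_cdrh3_substitutions_modes(self, panel, config):
        v = next(
            v for v in enumerate_library(panel, with_dna=True)
            if v.cd19_variant.is_parent
        )
        parent = v.cd19_variant.parent
        # mutate two CDRH3 residues at protein level, then rebuild the DNA
        vh_start = v.protein_seq.index(parent.vh_seq)
        p1 = vh_start + parent.cdrh3_start
        p2 = vh_start + parent.cdrh3_start + 2
        protein = list(v.protein_seq)
        protein[p1] = "A" if protein[p1] != "A" else "C"
        protein[p2] = "A" if protein[p2] != "A" else "C"
        protein = "".join(protein)
        dna = SIGNAL_DNA + reverse_translate(protein[19:-25]) + HISTAG_2A_DNA
        relaxed = classify_read(CCSRead("d", dna), config)
        assert relaxed.status == STATUS_OK and len(relaxed.cdrh3_mutations) == 2
        strict = ClassifierConfig.from_definition(
            panel, require_single_cdrh3_substitution=True
        )
        assert classify_read(CCSRead("d", dna), strict).status == STATUS_AMBIGUOUS


class TestAggregation:
    def _calls(self, variants, config, depth):
        reads = []
        for i, v in enumerate(variants):
            for d in range(depth[i]):
                reads.append(CCSRead(f"v{i}d{d}", v.dna_seq))
        return classify_reads(reads, config)

    def test_deduplicate_counts_and_order_invariance(self, sample_variants, config):
        calls = self._calls(sample_variants[:2], config, [10, 5])
        table = deduplicate(calls)
        assert len(table) == 2
        assert sorted(table["count"]) == [5, 10]
        permuted = deduplicate(list(reversed(calls)))
        pd.testing.assert_frame_equal(table, permuted)

    def test_deduplicate_empty(self):
        assert deduplicate([]).empty

    def test_status_counts_conserve_reads(self, sample_variants, config, panel):
        rng = np.random.default_rng(9)
        reads, _ = simulate_ccs_reads(
            sample_variants, ReadErrorModel(0.01, 5), rng
        )
        # corrupt a few reads so every failure mode is reachable
        reads[0] = CCSRead(reads[0].read_id, reads[0].dna_seq[60:])
        calls = classify_reads(reads, config)
        counts = status_counts(calls)
        assert int(counts.sum()) == len(reads)
        table = deduplicate(calls)
        assert int(table["count"].sum()) == int(counts[STATUS_OK])

    def test_distribution_fractions(self):
        # the published sorted-library split across CD19 binders: 34/25/29/8
        table = pd.DataFrame(
            {
                "cd19_id": ["4G7"] * 34 + ["B43"] * 25 + ["JUNO241"] * 29 + ["FMC63"] * 8,
                "cd3_id": ["L2K"] * 96,
                "linker_id": ["flex_short"] * 96,
                "orientation": ["CD19_VL-VH–CD3_VH-VL"] * 96,
                "count": [1] * 96,
            }
        )
        dist = summarize_design_distribution(table)
        assert dist["cd19_id"]["4G7"] == pytest.approx(34 / 96)
        assert dist["cd19_id"]["FMC63"] == pytest.approx(8 / 96)
        for facet, series in dist.items():
            assert series.sum() == pytest.approx(1.0)

    def test_distribution_weighting_modes(self):
        table = pd.DataFrame(
            {
                "cd19_id": ["a", "b"],
                "cd3_id": ["c", "c"],
                "linker_id": ["l1", "l2"],
                "orientation": ["o", "o"],
                "count": [9, 1],
            }
        )
        assert summarize_design_distribution(table, "unique")["cd19_id"]["a"] == 0.5
        assert summarize_design_distribution(table, "read_count")["cd19_id"]["a"] == 0.9
        assert summarize_design_distribution(pd.DataFrame(), "unique") == {}

    def test_uniform_sample_fractions_within_multinomial_error(
        self, panel, config
    ):
        rng = np.random.default_rng(17)
        variants = list(itertools.islice(enumerate_library(panel, with_dna=True), 400))
        reads, _ = simulate_ccs_reads(
            variants, ReadErrorModel(0.0, 1), rng, n_reads=800
        )
        table = deduplicate(classify_reads(reads, config))
        dist = summarize_design_distribution(table, weight="read_count")
        n = int(table["count"].sum())
        # linker facet should be near its true sampling share
        for name, frac in dist["linker_id"].items():
            true = (
                sum(1 for v in variants if v.linker.name == name) / len(variants)
            )
            sigma = (true * (1 - true) / n) ** 0.5
            assert abs(frac - true) <= 3 * sigma + 1e-9


class TestComposition:
    def test_identical_parents_are_pure(self, panel):
        table = pd.DataFrame(
            {"cd19_id": ["4G7"] * 5, "cdrh3_mutations": [""] * 5}
        )
        comp = cdrh3_composition(table, panel.cd19_refs)["4G7"]
        parent = next(r for r in panel.cd19_refs if r.name == "4G7")
        for pos, aa in enumerate(parent.cdrh3_seq, start=1):
            assert comp.matrix.loc[pos, aa] == 1.0
        assert np.allclose(comp.matrix.sum(axis=1), 1.0)

    def test_three_way_split_at_one_position(self, panel):
        parent = next(r for r in panel.cd19_refs if r.name == "B43")
        ref_aa = parent.cdrh3_seq[1]
        others = [a for a in "ACDEF" if a != ref_aa][:2]
        table = pd.DataFrame(
            {
                "cd19_id": ["B43"] * 3,
                "cdrh3_mutations": ["", f"2:{ref_aa}>{others[0]}", f"2:{ref_aa}>{others[1]}"],
            }
        )
        comp = cdrh3_composition(table, panel.cd19_refs)["B43"]
        assert comp.matrix.loc[2, ref_aa] == pytest.approx(1 / 3)
        assert comp.matrix.loc[2, others[0]] == pytest.approx(1 / 3)
        assert comp.matrix.loc[1, parent.cdrh3_seq[0]] == 1.0

    def test_length_inconsistent_member_excluded(self, panel):
        table = pd.DataFrame(
            {"cd19_id": ["4G7"] * 3, "cdrh3_mutations": ["", "", "99:A>V"]}
        )
        comp = cdrh3_composition(table, panel.cd19_refs)["4G7"]
        assert comp.n_sequences == 2 and comp.n_excluded == 1
        assert np.allclose(comp.matrix.sum(axis=1), 1.0)
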