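"""Identity, translation, grouping, gene conversion and diversity."""

import numpy as np
import pytest

from dinomfrs.annotate import (
    GROUP_MARKERS,
    cds_to_aa,
    classify_alleles,
    closest_allele,
    detect_gene_conversion,
    diversity_stats,
    load_contact_positions,
    percent_identity,
    translate,
    translate_allele,
)
from dinomfrs.refdb import AlleleSequence, ReferenceDB

from conftest import mutate, random_seq


class TestPercentIdentity:
    def test_identical(self, rng):
        s = random_seq(rng, 549)
        assert percent_identity(s, s) == 100.0

    def test_single_substitution(self, rng):
        s = random_seq(rng, 549)
        assert percent_identity(s, mutate(s, [100], rng)) == 99.8  # 548/549

    def test_39_substitutions(self, rng):
        s = random_seq(rng, 549)
        t = mutate(s, list(range(10, 400, 10)), rng)  # 39 positions
        assert percent_identity(s, t) == 92.9  # 510/549

    def test_symmetric(self, rng):
        a, b = random_seq(rng, 300), random_seq(rng, 310)
        assert percent_identity(a, b) == percent_identity(b, a)


class TestClosestAllele:
    def test_self_is_closest(self, small_db):
        cid, pct = closest_allele(small_db.alleles[1], small_db)
        assert cid == "A2" and pct == 100.0

    def test_tie_prefers_earlier(self, rng):
        base = random_seq(rng, 300)
        db = ReferenceDB(alleles=[AlleleSequence("B1", base),
                                  AlleleSequence("B2", base)])
        cid, pct = closest_allele(mutate(base, [5], rng), db)
        assert cid == "B1"

    def test_nearest_reported(self, small_db, rng):
        q = mutate(small_db.alleles[2].seq, [1, 50, 99], rng)
        cid, _ = closest_allele(q, small_db)
        assert cid == "A3"


@pytest.mark.parametrize("nt,aa", [(256, 86), (264, 88), (1, 1), (3, 1), (4, 2)])
def test_cds_to_aa(nt, aa):
    assert cds_to_aa(nt) == aa


class TestTranslate:
    def test_basic(self):
        assert translate("ATGGCT") == "MA"

    def test_motif_is_qiq(self):
        assert translate("CAGATACAA") == "QIQ"

    def test_frame_offset_and_partial_codon(self):
        assert translate("TATGGCTA", 1) == "MA"

    def test_ambiguity(self):
        assert translate("ATGNNN") == "MX"

    def test_stop(self):
        assert translate("TGATAA") == "**"

    def test_numbering_anchor(self):
        """The default frame puts CDS 256-264 at residues 86-88."""
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 549)
        # plant the motif at local positions 183-191 (CDS 256-264)
        seq = seq[:182] + "CAGATACAA" + seq[191:]
        aa, aa_start = translate_allele(seq)
        assert aa_start == 26
        idx = 86 - aa_start
        assert aa[idx : idx + 3] == "QIQ"
        assert cds_to_aa(256) == 86 and cds_to_aa(264) == 88


class TestClassify:
    def _aa_with_contacts(self, contacts, residues, rng, aa_start=26, n=182):
        aa = list("".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), n)))
        for pos, res in zip(contacts.positions, residues):
            aa[pos - aa_start] = res
        return "".join(aa)

    def test_low_contact_diversity_cluster(self, rng):
        contacts = load_contact_positions()
        shared = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 31))
        records = {
            f"g{i}": self._aa_with_contacts(contacts, shared,
                                            np.random.default_rng(i))
            for i in range(5)
        }
        records["far"] = self._aa_with_contacts(
            contacts, "".join(rng.choice(list("ARNDC"), 31)),
            np.random.default_rng(99))
        calls = classify_alleles(records, contacts)
        for i in range(5):
            assert calls[f"g{i}"][0] == "putative non-classical"
        assert calls["far"][0] == "classical"

    def test_identical_contacts_same_cluster_despite_backbone(self, rng):
        contacts = load_contact_positions()
        shared = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 31))
        records = {
            f"p{i}": self._aa_with_contacts(contacts, shared,
                                            np.random.default_rng(100 + i))
            for i in range(3)
        }
        calls = classify_alleles(records, contacts)
        assert len({calls[k][0] for k in records}) == 1

    def test_short_sequence_unclassified(self):
        calls = classify_alleles({"short": "MA"}, load_contact_positions())
        assert calls["short"][0] == "unclassified"

    def test_marker_residues_reported(self, rng):
        contacts = load_contact_positions()
        shared = list("".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 31)))
        # force the group-1 diagnostic residues
        for k, pos in enumerate(contacts.positions):
            if pos in GROUP_MARKERS["group1"]:
                shared[k] = GROUP_MARKERS["group1"][pos]
        records = {
            f"m{i}": self._aa_with_contacts(contacts, "".join(shared),
                                            np.random.default_rng(200 + i))
            for i in range(3)
        }
        calls = classify_alleles(records, contacts)
        hits = calls["m0"][1]
        assert "62H" in hits and "186N" in hits

    def test_order_invariant(self, rng):
        contacts = load_contact_positions()
        shared = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 31))
        records = {
            f"o{i}": self._aa_with_contacts(contacts, shared,
                                            np.random.default_rng(300 + i))
            for i in range(4)
        }
        a = classify_alleles(dict(records), contacts)
        b = classify_alleles(dict(reversed(list(records.items()))), contacts)
        assert a == b


class TestGeneConversion:
    def test_identical_pair_none(self, rng):
        s = random_seq(rng, 549)
        assert detect_gene_conversion(s, s) is None

    def test_structured_pair_detected(self, rng):
        """247 bp identical prefix, 106 bp divergent core, 256 bp
        identical suffix."""
        a = random_seq(rng, 609)
        inner = rng.choice(np.arange(248, 352), size=19, replace=False)
        core_positions = sorted({247, 352} | {int(p) for p in inner})
        b = mutate(a, core_positions, rng)
        rep = detect_gene_conversion(a, b)
        assert rep is not None
        assert rep.flank5_len == 247
        assert rep.flank3_len == 256
        assert rep.core_start == 248 and rep.core_end == 353
        assert rep.core_divergence == pytest.approx(21 / 106, abs=1e-9)

    def test_uniform_divergence_none(self, rng):
        a = random_seq(rng, 549)
        b = mutate(a, list(range(5, 545, 20)), rng)  # ~5% spread throughout
        assert detect_gene_conversion(a, b) is None

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_gene_conversion("ACGT" * 100, "ACGT" * 99)


class TestDiversity:
    def test_identical_pair(self, rng):
        s = random_seq(rng, 549)
        mean, mx, width = diversity_stats([s, s], 474, 593)
        assert (mean, mx, width) == (0.0, 0, 120)

    def test_window_width(self):
        assert diversity_stats(["A" * 549, "C" * 549], 474, 593)[2] == 120

    def test_hand_enumerated_mean(self, rng):
        s = random_seq(rng, 549)
        # local window is CDS 474-593 -> 0-based 400..519
        a = mutate(s, list(range(400, 420, 2)), rng)  # 10 diffs vs s
        seqs = [s, a]
        mean, mx, width = diversity_stats(seqs, 474, 593)
        assert mean == 10.0 and mx == 10

    def test_three_allele_mean(self, rng):
        """Pairwise differences {10, 20, 30} give mean 20.0, max 30."""
        base = random_seq(rng, 549)
        a = mutate(base, list(range(400, 420, 2)), rng)  # 10 diffs to base
        b = mutate(a, list(range(440, 480, 2)), rng)  # +20 -> 30 to base
        mean, mx, _ = diversity_stats([base, a, b], 474, 593)
        assert mean == 20.0 and mx == 30

    def test_short_allele_excluded(self, rng):
        s = random_seq(rng, 549)
        with pytest.raises(ValueError):
            diversity_stats([s[:300], s[:300]], 474, 593)


def test_annotate_alleles_report(small_db):
    from dinomfrs.annotate import annotate_alleles, annotations_to_table

    records = annotate_alleles(list(small_db.alleles), small_db)
    df = annotations_to_table(records)
    assert list(df["identity_pct"]) == [100.0] * len(small_db)
    assert set(df["class"]) <= {"classical", "putative non-classical",
                                "unclassified"}
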