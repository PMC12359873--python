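"""Chemistry presets, barcodes, tagmentation and conversion behaviour."""

import json

import numpy as np
import pytest

from scmod import chemistry, reference
from scmod.chemistry import ChemistryPreset, load_preset, make_barcode_plate
from scmod.reference import MethylomeTruth


class TestPresets:
    @pytest.mark.parametrize(
        "name,field,value",
        [
            ("sctaps-paper", "p_read_T_given_mC", 0.966),
            ("sctaps-paper", "p_read_T_given_hmC", 0.850),
            ("sctaps-paper", "p_read_T_given_uC", 0.0019),
            ("sccaps-paper", "p_read_T_given_mC", 0.0025),
            ("sccaps-paper", "p_read_T_given_hmC", 0.930),
            ("sccaps-paper", "p_read_T_given_uC", 0.0038),
        ],
    )
    def test_shipped_preset_values(self, name, field, value):
        assert getattr(load_preset(name), field) == value

    def test_unknown_name_lists_available(self):
        with pytest.raises(ValueError, match="sctaps-paper"):
            load_preset("no-such-preset")

    def test_custom_file_roundtrip_and_validation(self, tmp_path):
        path = tmp_path / "p.json"
        cfg = {"p_read_T_given_mC": 0.5, "p_read_T_given_hmC": 0.4, "p_read_T_given_uC": 0.01}
        path.write_text(json.dumps(cfg))
        assert load_preset(str(path)).p_read_T_given_mC == 0.5
        cfg["p_read_T_given_mC"] = 1.2
        path.write_text(json.dumps(cfg))
        with pytest.raises(ValueError, match="outside"):
            load_preset(str(path))


class TestBarcodes:
    def test_plate_is_96_unique_combinations(self):
        plate = make_barcode_plate()
        assert len(plate) == 96
        assert len({(b.i5, b.i7) for b in plate}) == 96
        assert len({b.well for b in plate}) == 96

    def test_tag_sets_have_min_hamming_3(self):
        plate = make_barcode_plate()
        i5s = sorted({b.i5 for b in plate})
        i7s = sorted({b.i7 for b in plate})
        assert len(i5s) == 8 and len(i7s) == 12
        for tags in (i5s, i7s):
            for i, a in enumerate(tags):
                for b in tags[i + 1 :]:
                    assert chemistry.hamming(a, b) >= 3


class TestTagment:
    def test_fragment_count_and_wells(self, spiked_ref):
        ref, _ = spiked_ref
        plate = make_barcode_plate()
        frags = chemistry.tagment(ref, plate, 100, spikein_fraction=0.0, seed=1)
        assert len(frags) == 9600
        wells = {b.well for b in plate}
        assert all(f.cell in wells for f in frags)
        assert all(0 <= f.start0 < f.end0 <= len(ref.contigs[f.contig]) for f in frags)

    def test_zero_spikein_fraction_stays_genomic(self, spiked_ref):
        ref, _ = spiked_ref
        frags = chemistry.tagment(ref, make_barcode_plate()[:2], 500, spikein_fraction=0.0, seed=2)
        spikes = set(ref.spikein_contigs().values())
        assert not any(f.contig in spikes for f in frags)

    def test_spikein_share_matches_binomial(self, spiked_ref):
        ref, _ = spiked_ref
        n = 10_000
        frags = chemistry.tagment(ref, make_barcode_plate()[:1], n, spikein_fraction=0.2, seed=3)
        spikes = set(ref.spikein_contigs().values())
        share = sum(f.contig in spikes for f in frags) / n
        sigma = np.sqrt(0.2 * 0.8 / n)
        assert abs(share - 0.2) < 3 * sigma

    def test_empty_cell_list_rejected(self, spiked_ref):
        ref, _ = spiked_ref
        with pytest.raises(ValueError, match="non-empty"):
            chemistry.tagment(ref, [], 10)


def _pairs(ref, truth, preset, frags, seed=0, read_len=120):
    return list(chemistry.generate_read_pairs(frags, ref, truth, preset, read_len, seed))


class TestConversion:
    def test_identity_chemistry_reproduces_reference(self, spiked_ref):
        ref, _ = spiked_ref
        preset = ChemistryPreset("identity", 0, 0, 0, seq_error=0)
        frags = chemistry.tagment(
            ref, make_barcode_plate()[:1], 50, spikein_fraction=0.0, seed=4
        )
        for rp in _pairs(ref, MethylomeTruth(), preset, frags):
            sub = ref.contigs[rp.contig]
            if rp.template_strand == "top":
                assert rp.r1 == sub[rp.r1_pos : rp.r1_pos + len(rp.r1)]
            else:
                assert rp.r2 == sub[rp.r2_pos : rp.r2_pos + len(rp.r2)]

    def test_forced_conversion_reads_all_t(self, spiked_ref):
        ref, truth = spiked_ref
        preset = ChemistryPreset("force", 1.0, 0, 0, seq_error=0)
        plate = make_barcode_plate()[:1]
        frags = [
            f
            for f in chemistry.tagment(ref, plate, 400, spikein_fraction=0.99, seed=5)
            if f.contig == "spike_mC" and f.template_strand == "top"
        ]
        cg = ref.cg_context_mask("spike_mC", "+")
        seen = 0
        for rp in _pairs(ref, truth, preset, frags):
            for q, base in enumerate(rp.r1):
                p = rp.r1_pos + q
                if cg[p]:
                    assert base == "T"
                    seen += 1
        assert seen > 100

    def test_taps_mc_conversion_matches_preset_within_3_sigma(self, spiked_ref):
        ref, truth = spiked_ref
        preset = load_preset("sctaps-paper", seq_error=0.0)
        plate = make_barcode_plate()[:1]
        frags = [
            f
            for f in chemistry.tagment(ref, plate, 9000, spikein_fraction=0.99, seed=6)
            if f.contig == "spike_mC"
        ]
        n_t = n_calls = 0
        for rp in _pairs(ref, truth, preset, frags):
            sub = ref.contigs[rp.contig]
            strand = "+" if rp.template_strand == "top" else "-"
            cg = ref.cg_context_mask(rp.contig, strand)
            read, pos = (rp.r1, rp.r1_pos) if rp.template_strand == "top" else (rp.r2, rp.r2_pos)
            # this read is reference-forward oriented for its segment
            for q, base in enumerate(read):
                p = pos + q
                if cg[p]:
                    n_calls += 1
                    n_t += base == ("T" if strand == "+" else "A")
        assert n_calls >= 20_000
        p = preset.p_read_T_given_mC
        sigma = np.sqrt(p * (1 - p) / n_calls)
        assert abs(n_t / n_calls - p) < 3 * sigma

    def test_non_cytosine_template_bases_verbatim(self, spiked_ref):
        ref, truth = spiked_ref
        preset = ChemistryPreset("all", 1.0, 1.0, 1.0, seq_error=0)
        frags = chemistry.tagment(
            ref, make_barcode_plate()[:1], 100, spikein_fraction=0.2, seed=7
        )
        for rp in _pairs(ref, truth, preset, frags):
            sub = ref.contigs[rp.contig]
            if rp.template_strand != "top":
                continue
            segment = sub[rp.r1_pos : rp.r1_pos + len(rp.r1)]
            for got, want in zip(rp.r1, segment):
                if want != "C":
                    assert got == want

    def test_adjacent_conversion_events_independent(self, spiked_ref):
        # empirical correlation of adjacent-site conversion indicators ~ 0
        ref, truth = spiked_ref
        preset = ChemistryPreset("half", 0.5, 0, 0, seq_error=0)
        frags = [
            f
            for f in chemistry.tagment(
                ref, make_barcode_plate()[:1], 10_000, spikein_fraction=0.99, seed=8
            )
            if f.contig == "spike_mC" and f.template_strand == "top"
        ]
        cg = np.flatnonzero(ref.cg_context_mask("spike_mC", "+"))
        xs, ys = [], []
        for rp in _pairs(ref, truth, preset, frags):
            lo, hi = rp.r1_pos, rp.r1_pos + len(rp.r1)
            inside = cg[(cg >= lo) & (cg < hi)]
            calls = [rp.r1[p - lo] == "T" for p in inside]
            xs.extend(calls[:-1])
            ys.extend(calls[1:])
        assert len(xs) > 10_000
        r = np.corrcoef(np.array(xs, float), np.array(ys, float))[0, 1]
        assert abs(r) < 0.05

    def test_short_fragment_truncates_reads(self, spiked_ref):
        ref, truth = spiked_ref
        frags = [chemistry.FragmentRecord(0, "chr1", 100, 180, "top", "A01")]
        preset = ChemistryPreset("identity", 0, 0, 0, seq_error=0)
        (rp,) = _pairs(ref, truth, preset, frags, read_len=120)
        assert rp.truncated
        assert len(rp.r1) == len(rp.r2) == 80

    def test_seq_error_rate_recovered(self, spiked_ref):
        ref, _ = spiked_ref
        preset = ChemistryPreset("err", 0, 0, 0, seq_error=0.01)
        frags = chemistry.tagment(
            ref, make_barcode_plate()[:1], 300, spikein_fraction=0.0, seed=9
        )
        mismatches = total = 0
        for rp in _pairs(ref, MethylomeTruth(), preset, frags, seed=9):
            if rp.template_strand != "top":
                continue
            segment = ref.contigs[rp.contig][rp.r1_pos : rp.r1_pos + len(rp.r1)]
            total += len(segment)
            mismatches += sum(a != b for a, b in zip(rp.r1, segment))
        rate = mismatches / total
        sigma = np.sqrt(0.01 * 0.99 / total)
        assert abs(rate - 0.01) < 4 * sigma


class TestFastqSamOutput:
    def test_files_written_and_consistent(self, spiked_ref, tmp_path):
        import pysam

        ref, truth = spiked_ref
        preset = load_preset("sctaps-paper")
        plate = make_barcode_plate()[:2]
        frags = chemistry.tagment(ref, plate, 50, spikein_fraction=0.1, seed=10)
        summary = chemistry.convert_and_sequence(
            frags,
            ref,
            truth,
            preset,
            r1_path=str(tmp_path / "r1.fastq"),
            r2_path=str(tmp_path / "r2.fastq"),
            sam_path=str(tmp_path / "truth.sam"),
            barcodes=plate,
            seed=10,
        )
        assert summary["n_pairs"] == 100
        with pysam.AlignmentFile(str(tmp_path / "truth.sam"), "r") as fh:
            records = list(fh)
        assert len(records) == 200
        for a in records:
            assert a.is_proper_pair and a.mapping_quality == 60
            assert a.get_tag("CB") in {b.well for b in plate}
            # SAM stores reference-forward sequence: all-match records must
            # agree with the reference at non-cytosine template positions
            seg = ref.contigs[a.reference_name][a.reference_start : a.reference_start + a.query_length]
            diffs = sum(x != y for x, y in zip(a.query_sequence, seg))
            assert diffs <= sum(c in "CG" for c in seg) + 5

    def test_dup_fraction_reemission(self, spiked_ref):
        ref, truth = spiked_ref
        preset = ChemistryPreset("identity", 0, 0, 0, seq_error=0)
        frags = chemistry.tagment(
            ref, make_barcode_plate()[:1], 10_000, spikein_fraction=0.0, seed=11
        )
        pairs = _pairs_with_dup(ref, truth, preset, frags, dup_frac=0.2, seed=11)
        extra = sum(1 for rp in pairs if rp.name.endswith("dup1"))
        sigma = np.sqrt(10_000 * 0.2 * 0.8)
        assert abs(extra - 2000) < 3 * sigma
        assert len(pairs) == 10_000 + extra


def _pairs_with_dup(ref, truth, preset, frags, dup_frac, seed):
    return list(
        chemistry.generate_read_pairs(frags, ref, truth, preset, 120, seed, dup_frac=dup_frac)
    )
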