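"""Secondary chemical shifts, residue classification, runs, CD heuristic."""

import math

import numpy as np
import pytest

from idpsitemap.disorder import (
    CdSpectrum,
    ClassificationRanges,
    RandomCoilTable,
    ResidueCall,
    cd_disorder_heuristic,
    classify_residues,
    detect_structured_runs,
    secondary_shifts,
)
from idpsitemap.shift_io import ProteinSequence, ShiftRecord, ShiftTable, attach_sequence
from idpsitemap.synth import GeneratorConfig, StructuredSegment, gen_shift_table


def make_profile(deltas, prolines=()):
    """Build a SecondaryShiftProfile-like object from {idx: (ca, cb, co)}."""
    from idpsitemap.disorder import SecondaryShiftProfile

    idxs = sorted(deltas)
    return SecondaryShiftProfile(
        residue_indices=idxs,
        dca={i: deltas[i][0] for i in idxs},
        dcb={i: deltas[i][1] for i in idxs},
        dco={i: deltas[i][2] for i in idxs},
        is_proline={i: i in prolines for i in idxs},
    )


class TestSecondaryShifts:
    def test_deviation_arithmetic_and_gly_cb_not_applicable(self, rc_table):
        seq = ProteinSequence("AG")
        rc_ca = rc_table.get("A", "CA")
        table = attach_sequence(
            ShiftTable(
                [
                    ShiftRecord(1, "A", "CA", rc_ca),          # exactly random coil
                    ShiftRecord(2, "G", "CA", rc_table.get("G", "CA") + 2.5),
                ]
            ),
            seq,
        )
        prof = secondary_shifts(table, rc_table)
        assert prof.dca[1] == 0.0
        assert prof.dca[2] == pytest.approx(2.5)
        assert math.isnan(prof.dcb[2])  # glycine has no CB

    def test_profile_plus_reference_reconstructs_observed_shifts(self, rc_table, config):
        table, _ = gen_shift_table(config, rc=rc_table)
        prof = secondary_shifts(table, rc_table)
        for rec in table.records:
            delta = prof.deltas(rec.residue_index)[rec.atom]
            ref = rc_table.get(rec.residue_type, rec.atom)
            assert delta + ref == pytest.approx(rec.shift, abs=1e-12)

    def test_full_table_at_reference_values_gives_zero_everywhere(self, rc_table):
        cfg = GeneratorConfig(seed=3, shift_sigma_ppm=0.0)
        table, _ = gen_shift_table(cfg, rc=rc_table)
        prof = secondary_shifts(table, rc_table)
        for i in prof.residue_indices:
            for v in prof.deltas(i).values():
                assert math.isnan(v) or v == 0.0


class TestClassification:
    @pytest.mark.parametrize(
        "deltas, prolines, expected",
        [
            ({1: (0.5, -0.3, 0.2)}, (), "coil"),               # inside the coil window
            ({1: (3.0, 0.0, 0.0)}, (1,), "coil"),               # proline window is +-4
            ({1: (2.5, -1.0, 1.0)}, (), "helix_indicating"),
            ({1: (-2.5, 1.0, -1.0)}, (), "strand_indicating"),
            ({1: (0.0, 0.0, 0.6)}, (), "helix_indicating"),     # CO window is +-0.5
            ({1: (math.nan, math.nan, math.nan)}, (), "insufficient_data"),
        ],
    )
    def test_call_assignment(self, deltas, prolines, expected):
        calls = classify_residues(make_profile(deltas, prolines))
        assert calls[0].call == expected

    def test_conflicting_signs_resolve_to_flagged_coil(self):
        # CA says helix, CB also far positive says strand
        calls = classify_residues(make_profile({1: (2.5, 2.5, 0.0)}))
        assert calls[0].call == "coil" and calls[0].conflict

    def test_widening_ranges_never_increases_runs(self, rc_table):
        cfg = GeneratorConfig(
            seed=5,
            structured_segments=(StructuredSegment(27, 33, "helix_like"),),
        )
        table, _ = gen_shift_table(cfg, rc=rc_table)
        prof = secondary_shifts(table, rc_table)
        counts = []
        for width in (0.5, 0.7, 1.0, 1.5, 3.0):
            ranges = ClassificationRanges(ca=width, cb=width, co=width * 5 / 7)
            counts.append(len(detect_structured_runs(classify_residues(prof, ranges))))
        assert counts == sorted(counts, reverse=True)


class TestRunDetection:
    def _calls(self, kinds):
        return [ResidueCall(i + 1, k) for i, k in enumerate(kinds)]

    def test_three_consecutive_helix_residues_form_one_run(self):
        kinds = ["coil"] * 26 + ["helix_indicating"] * 3 + ["coil"] * 5
        runs = detect_structured_runs(self._calls(kinds))
        assert [(r.start, r.end, r.kind) for r in runs] == [(27, 29, "helix_like")]

    def test_four_strand_residues_form_length_four_run(self):
        kinds = ["coil"] * 160 + ["strand_indicating"] * 4 + ["coil"] * 3
        runs = detect_structured_runs(self._calls(kinds))
        assert runs[0].start == 161 and runs[0].end == 164 and runs[0].length == 4

    def test_isolated_pairs_below_min_run_are_dropped(self):
        kinds = ["coil", "helix_indicating", "helix_indicating", "coil"]
        assert detect_structured_runs(self._calls(kinds)) == []

    def test_insufficient_data_breaks_runs(self):
        kinds = ["helix_indicating"] * 2 + ["insufficient_data"] + ["helix_indicating"] * 2
        assert detect_structured_runs(self._calls(kinds), min_run=3) == []


class TestPlantedSegmentRecovery:
    def test_reference_valued_tables_yield_zero_runs(self, rc_table):
        for seed in range(10):
            cfg = GeneratorConfig(seed=seed, shift_sigma_ppm=0.0)
            table, _ = gen_shift_table(cfg, rc=rc_table)
            calls = classify_residues(secondary_shifts(table, rc_table))
            assert detect_structured_runs(calls) == []

    def test_planted_helix_recovered_in_75pct_coverage_over_seeds(self, rc_table):
        seg = StructuredSegment(27, 33, "helix_like", offsets=(2.8, -0.9, 1.2))
        planted = set(range(27, 34))
        covered = total = 0
        for seed in range(100):
            cfg = GeneratorConfig(seed=seed, shift_sigma_ppm=0.2, structured_segments=(seg,))
            table, _ = gen_shift_table(cfg, rc=rc_table)
            runs = detect_structured_runs(classify_residues(secondary_shifts(table, rc_table)))
            members = set()
            for r in runs:
                if r.kind == "helix_like":
                    members |= set(range(r.start, r.end + 1))
            covered += len(members & planted)
            total += len(planted)
        assert covered / total >= 0.75


class TestCdHeuristic:
    @staticmethod
    def spectrum(dips):
        wl = np.arange(190.0, 261.0, 1.0)
        sig = np.zeros_like(wl)
        for center, depth, width in dips:
            sig -= depth * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return CdSpectrum(wl, sig)

    def test_coil_like_single_200nm_trough_flags_disorder(self):
        flag, features = cd_disorder_heuristic(self.spectrum([(200, 10, 6)]))
        assert flag
        assert features["global_min_wavelength"] == pytest.approx(200, abs=1)
        assert features["local_minima_above_210"] == []

    def test_helix_like_208_and_222nm_dips_do_not_flag(self):
        flag, features = cd_disorder_heuristic(
            self.spectrum([(208, 10, 5), (222, 10, 5)])
        )
        assert not flag
        assert any(w > 210 for w, _ in features["local_minima_above_210"])

    def test_flat_spectrum_not_flagged(self):
        wl = np.arange(190.0, 261.0, 1.0)
        flag, features = cd_disorder_heuristic(CdSpectrum(wl, np.ones_like(wl)))
        assert not flag and features["local_minima_above_210"] == []

    def test_insufficient_span_raises(self):
        wl = np.arange(200.0, 240.0, 1.0)
        with pytest.raises(ValueError):
            cd_disorder_heuristic(CdSpectrum(wl, np.zeros_like(wl)))
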