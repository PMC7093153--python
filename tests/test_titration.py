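"""Attenuation binning, site delineation (with brute-force oracle), CSP."""

import math

import numpy as np
import pytest

from idpsitemap.shift_io import IntensityTable, ProteinSequence, ShiftRecord, ShiftTable
from idpsitemap.synth import GeneratorConfig, gen_titration
from idpsitemap.titration import (
    ATTENUATED_BINS,
    AttenuationProfile,
    bin_for_reduction,
    csp,
    delineate_sites,
    intensity_ratios,
)

BIN_NAMES = ("minimal", "green", "yellow", "red", "not_evaluable")


def series(values, status=None):
    labels = ["1:0", "1:0.25"]
    return IntensityTable(
        labels, {i: list(v) for i, v in values.items()}, dict(status or {})
    )


def profile_from_bins(bins):
    """AttenuationProfile with only the bins populated (enough for sites)."""
    return AttenuationProfile(
        condition_labels=["1:0", "1:0.25"],
        reference_label="1:0.25",
        ratios={i: [1.0, math.nan] for i in bins},
        reduction_pct={i: math.nan for i in bins},
        bins=dict(bins),
    )


class TestBinning:
    @pytest.mark.parametrize(
        "i_ref, expected_bin, expected_reduction",
        [
            (0.15, "red", 85.0),      # reduction > 80
            (0.25, "yellow", 75.0),   # 60 < reduction <= 80
            (0.50, "green", 50.0),
            (1.00, "minimal", 0.0),
            (1.10, "minimal", 0.0),   # negative reduction clips to 0
            (0.20, "yellow", 80.0),   # boundary: exactly 80 is yellow
            (0.40, "green", 60.0),    # boundary: exactly 60 is green
            (0.60, "green", 40.0),    # boundary: exactly 40 is green
        ],
    )
    def test_reduction_and_bin_boundaries(self, i_ref, expected_bin, expected_reduction):
        prof = intensity_ratios(series({7: (1.0, i_ref)}))
        assert prof.reduction_pct[7] == pytest.approx(expected_reduction)
        assert prof.bins[7] == expected_bin

    def test_non_assigned_statuses_and_zero_reference_are_not_evaluable(self):
        prof = intensity_ratios(
            series(
                {1: (1.0, 0.1), 2: (1.0, 0.1), 3: (0.0, 0.1)},
                {2: "proline"},
            )
        )
        assert prof.bins[1] == "red"
        assert prof.bins[2] == "not_evaluable"
        assert prof.bins[3] == "not_evaluable"

    def test_bins_partition_every_evaluable_residue(self, config):
        table, _ = gen_titration(config)
        prof = intensity_ratios(table)
        for i in table.residue_indices():
            assert prof.bins[i] in BIN_NAMES
            if table.status[i] == "assigned":
                assert prof.bins[i] != "not_evaluable"

    def test_reference_defaults_to_first_non_zero_point(self, config):
        table, _ = gen_titration(config)
        assert intensity_ratios(table).reference_label == "1:0.25"


def oracle_sites(bins, max_gap):
    """Brute-force enumeration of maximal qualifying windows.

    A window [a, b] qualifies when a and b are attenuated, no internal
    stretch of more than max_gap consecutive non-attenuated residues
    occurs, and at least one residue in it is red; report windows that
    cannot be extended.
    """
    att = [i for i in sorted(bins) if bins[i] in ATTENUATED_BINS]
    out = []
    for ai, a in enumerate(att):
        for bi in range(ai, len(att)):
            b = att[bi]
            inner = att[ai : bi + 1]
            gaps_ok = all(
                inner[j + 1] - inner[j] - 1 <= max_gap for j in range(len(inner) - 1)
            )
            has_red = any(bins[i] == "red" for i in range(a, b + 1))
            if not (gaps_ok and has_red):
                continue
            extend_left = ai > 0 and a - att[ai - 1] - 1 <= max_gap
            extend_right = bi < len(att) - 1 and att[bi + 1] - b - 1 <= max_gap
            if not extend_left and not extend_right:
                out.append((a, b))
    return sorted(set(out))


class TestDelineation:
    def test_single_sandwiched_site(self):
        bins = {i: "minimal" for i in range(70, 131)}
        bins.update({i: "yellow" for i in range(84, 90)})
        bins.update({i: "red" for i in range(90, 101)})
        bins.update({i: "yellow" for i in range(101, 115)})
        sites = delineate_sites(profile_from_bins(bins))
        assert [(s.start, s.end) for s in sites] == [(84, 114)]
        assert sites[0].n_red == 11
        assert oracle_sites(bins, 3) == [(84, 114)]

    def test_cluster_without_red_is_discarded(self):
        bins = {i: "minimal" for i in range(1, 31)}
        bins.update({i: "yellow" for i in range(10, 16)})
        assert delineate_sites(profile_from_bins(bins)) == []

    def test_two_red_clusters_beyond_max_gap_stay_separate(self):
        bins = {i: "minimal" for i in range(1, 41)}
        bins.update({i: "red" for i in range(5, 10)})
        bins.update({i: "red" for i in range(20, 25)})
        sites = delineate_sites(profile_from_bins(bins), max_gap=3)
        assert [(s.start, s.end) for s in sites] == [(5, 9), (20, 24)]
        merged = delineate_sites(profile_from_bins(bins), max_gap=12)
        assert [(s.start, s.end) for s in merged] == [(5, 24)]

    def test_agrees_with_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(10, 201))
            bins = {
                i: rng.choice(
                    BIN_NAMES, p=[0.45, 0.15, 0.1, 0.15, 0.15]
                )
                for i in range(1, n + 1)
            }
            max_gap = int(rng.integers(0, 5))
            got = [(s.start, s.end) for s in delineate_sites(profile_from_bins(bins), max_gap)]
            assert got == oracle_sites(bins, max_gap)

    def test_increasing_max_gap_never_increases_site_count(self, config):
        table, _ = gen_titration(config)
        prof = intensity_ratios(table)
        counts = [len(delineate_sites(prof, g)) for g in range(0, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_generator_truth_sites_recovered_within_max_gap(self):
        for seed in range(10):
            table, truth = gen_titration(GeneratorConfig(seed=seed))
            sites = delineate_sites(intensity_ratios(table), max_gap=3)
            assert len(sites) == len(truth)
            for site, (t_start, t_end) in zip(sites, truth):
                assert abs(site.start - t_start) <= 3
                assert abs(site.end - t_end) <= 3

    def test_generated_ratios_non_increasing_across_titration_points(self, config):
        table, _ = gen_titration(config)
        prof = intensity_ratios(table)
        for i, ratios in prof.ratios.items():
            clean = [r for r in ratios if not math.isnan(r)]
            assert clean == sorted(clean, reverse=True)


class TestCsp:
    @staticmethod
    def hn_table(shifts):
        records = []
        for i, (h, n) in shifts.items():
            records.append(ShiftRecord(i, "A", "H", h))
            records.append(ShiftRecord(i, "A", "N", n))
        return ShiftTable(records)

    def test_combined_shift_arithmetic(self):
        zero = self.hn_table({1: (8.0, 120.0), 2: (8.1, 118.0), 3: (8.2, 121.0)})
        point = self.hn_table({1: (8.0, 120.0), 2: (8.13, 118.0), 3: (8.23, 121.2)})
        prof = csp([zero, point])
        assert prof.csp[1][0] == 0.0
        assert prof.csp[2][0] == pytest.approx(0.03)
        assert prof.csp[3][0] == pytest.approx(
            math.sqrt(0.03**2 + (0.14 * 0.2) ** 2), abs=1e-12
        )
        assert prof.csp[3][0] == pytest.approx(0.0410, abs=5e-5)

    def test_residue_missing_at_a_point_gets_nan(self):
        zero = self.hn_table({1: (8.0, 120.0), 2: (8.1, 118.0)})
        point = self.hn_table({1: (8.05, 120.5)})
        prof = csp([zero, point])
        assert math.isnan(prof.csp[2][0])
        assert prof.csp[1][0] > 0
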