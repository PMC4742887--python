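"""The two-criterion, replicate-aware hit-calling procedure.

The per-well t-test p-value is checked against an independent evaluation
of the pooled-variance Student formula; set algebra and replicate rules
are checked exactly.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from myoscreen.hit_calling import (
    HitCallConfig,
    KinaseCall,
    WellScore,
    call_kinase,
    call_screen,
    calls_to_frame,
    cell_number_only_report,
    compare_arms,
    hit_genes,
    score_well,
)
from myoscreen.screen_data import (
    KinaseLibrary,
    ScreenDataset,
    ScreenValidationError,
    SiteMeasurement,
    Well,
    WellRole,
)


def make_well(sites, role=WellRole.EXPERIMENTAL, gene="Src", plate="P1",
              coord="A1", arm="vehicle", rep=1):
    return Well(
        plate_id=plate,
        well_coordinate=coord,
        role=role,
        arm=arm,
        replicate_index=rep,
        sites=tuple(SiteMeasurement(t, m) for t, m in sites),
        target_gene=gene if role in (WellRole.EXPERIMENTAL, WellRole.KIF11_CONTROL) else None,
    )


def gm_reference_wells():
    """Five GM wells: well means 800..1200 (median 1000, raw MAD 100),
    site fractions tightly around 0.02."""
    wells = []
    for i, mean in enumerate([800, 900, 1000, 1100, 1200]):
        sites = [(mean, round(mean * f)) for f in (0.018, 0.02, 0.02, 0.022)]
        wells.append(
            make_well(sites, role=WellRole.GM_NEG_CONTROL, gene=None,
                      coord=f"B{i + 1}")
        )
    return wells


def pooled_t_p_oracle(sample, reference):
    """Pooled-variance one-sided Student's t by direct formula."""
    n1, n2 = len(sample), len(reference)
    m1, m2 = np.mean(sample), np.mean(reference)
    sp2 = ((n1 - 1) * np.var(sample, ddof=1) + (n2 - 1) * np.var(reference, ddof=1)) / (
        n1 + n2 - 2
    )
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    from scipy.stats import t as t_dist

    return t_dist.sf(t, n1 + n2 - 2)


class TestScoreWell:
    def test_strong_differentiation_and_depletion_scores_positive(self):
        gm = gm_reference_wells()
        well = make_well([(300, 90), (300, 96), (300, 84), (300, 93)])
        score = score_well(well, gm)
        assert score.myog_positive
        assert score.cell_positive  # 300 <= 1000 - 100
        assert score.well_positive
        # p-value matches the independent pooled-t evaluation
        gm_fracs = [f for w in gm for f in
                    (s.myogenin_pos_nuclei / s.total_nuclei for s in w.sites)]
        expected_p = pooled_t_p_oracle([0.30, 0.32, 0.28, 0.31], gm_fracs)
        assert score.p_value == pytest.approx(expected_p, rel=1e-9)

    def test_exchangeable_well_is_not_positive(self):
        gm = gm_reference_wells()
        sites = [(1000, round(1000 * f)) for f in (0.018, 0.02, 0.02, 0.022)]
        score = score_well(make_well(sites), gm)
        assert score.p_value >= 0.5
        assert not score.well_positive

    def test_conjunction_requires_both_criteria(self):
        gm = gm_reference_wells()
        # Myogenin up but cell number above median - MAD: not a positive well.
        rich = make_well([(950, 285), (950, 304), (950, 266), (950, 295)])
        score = score_well(rich, gm)
        assert score.myog_positive and not score.cell_positive
        assert not score.well_positive
        # Cell number down without Myogenin gain: also not positive.
        sparse = make_well([(300, round(300 * f)) for f in (0.018, 0.02, 0.02, 0.022)])
        score = score_well(sparse, gm)
        assert score.cell_positive and not score.myog_positive
        assert not score.well_positive

    def test_sensitizer_arm_ignores_cell_criterion(self):
        gm = [make_well([(s.total_nuclei, s.myogenin_pos_nuclei) for s in w.sites],
                        role=WellRole.GM_NEG_CONTROL, gene=None,
                        coord=f"C{i+1}", arm="sensitizer")
              for i, w in enumerate(gm_reference_wells())]
        rich = make_well([(950, 285), (950, 304), (950, 266), (950, 295)],
                         arm="sensitizer")
        score = score_well(rich, gm)
        assert score.myog_positive and not score.cell_positive
        assert score.well_positive  # cell criterion disabled in this arm

    def test_results_dialect_compares_to_dmi_band(self):
        gm = gm_reference_wells()
        dmi = [make_well([(500, 200)] * 4, role=WellRole.DM_I_POS_CONTROL,
                         gene=None, coord=f"D{i}") for i in range(1, 6)]
        config = HitCallConfig(cell_criterion_dialect="results")
        # 650 is above median(DM+I)=500 + MAD=0 -> not cell positive
        well = make_well([(650, 195), (650, 208), (650, 182), (650, 202)])
        assert not score_well(well, gm, config, dmi).cell_positive
        # 450 is below the DM+I median -> cell positive
        low = make_well([(450, 135), (450, 144), (450, 126), (450, 140)])
        assert score_well(low, gm, config, dmi).cell_positive

    def test_degenerate_variance_conventions(self):
        gm = [make_well([(100, 2)] * 4, role=WellRole.GM_NEG_CONTROL, gene=None,
                        coord=f"B{i}") for i in range(1, 4)]
        equal = score_well(make_well([(100, 2)] * 4), gm)
        assert equal.p_value == 1.0
        higher = score_well(make_well([(100, 50)] * 4), gm)
        assert higher.p_value == 0.0
        lower = score_well(make_well([(100, 0)] * 4), gm)
        assert lower.p_value == 1.0

    def test_all_empty_well_scores_not_positive(self):
        score = score_well(make_well([(0, 0)] * 4), gm_reference_wells())
        assert score.insufficient_data
        assert not score.well_positive


class TestCallKinase:
    def _scores(self, positives, arm="vehicle"):
        return [
            WellScore(gene="SRC", arm=arm, replicate_index=i + 1, p_value=0.01,
                      myog_positive=p, cell_positive=p, well_positive=p)
            for i, p in enumerate(positives)
        ]

    def test_two_of_three_suffices_in_vehicle_arm(self):
        call = call_kinase(self._scores([True, True, False]))
        assert call.is_hit and call.n_positive_replicates == 2

    def test_sensitizer_arm_requires_all_three(self):
        call = call_kinase(self._scores([True, True, False], arm="sensitizer"))
        assert not call.is_hit
        assert call_kinase(self._scores([True] * 3, arm="sensitizer")).is_hit

    def test_no_positive_replicates(self):
        call = call_kinase(self._scores([False] * 3))
        assert not call.is_hit and call.n_positive_replicates == 0

    def test_mixed_genes_rejected(self):
        scores = self._scores([True] * 3)
        bad = scores[:2] + [
            WellScore(gene="FYN", arm="vehicle", replicate_index=3, p_value=0.01,
                      myog_positive=True, cell_positive=True, well_positive=True)
        ]
        with pytest.raises(ScreenValidationError):
            call_kinase(bad)


def _flat_dataset(n_genes=2, site_builder=None):
    """Three replicate plates where every well carries identical counts."""
    if site_builder is None:
        site_builder = lambda gene, rep: [(100, 2)] * 4
    wells = []
    genes = [f"G{i}" for i in range(n_genes)]
    for rep in (1, 2, 3):
        plate = f"P-vehicle-r{rep}"
        for i in range(4):
            wells.append(make_well([(100, 2)] * 4, role=WellRole.GM_NEG_CONTROL,
                                   gene=None, plate=plate, coord=f"A{i + 1}", rep=rep))
        for j, gene in enumerate(genes):
            wells.append(make_well(site_builder(gene, rep), gene=gene, plate=plate,
                                   coord=f"B{j + 1}", rep=rep))
    return ScreenDataset(wells=wells, library=KinaseLibrary(tuple(genes)))


class TestCallScreen:
    def test_experimental_wells_equal_to_controls_give_zero_hits(self):
        calls = call_screen(_flat_dataset())
        assert len(calls) == 2
        assert not any(c.is_hit for c in calls)

    def test_planted_effects_are_called(self, planted_screen_small, small_library):
        ds, truth = planted_screen_small
        calls = call_screen(ds)
        planted = truth.planted_genes
        assert planted <= hit_genes(calls, "vehicle")

    def test_permutation_invariance(self, planted_screen_small):
        ds, _ = planted_screen_small
        calls = calls_to_frame(call_screen(ds))
        shuffled = ScreenDataset(
            wells=random.Random(5).sample(ds.wells, len(ds.wells)),
            library=ds.library,
        )
        assert calls_to_frame(call_screen(shuffled)).equals(calls)

    def test_sensitizer_hits_invariant_to_cell_number_perturbation(
        self, planted_screen_small
    ):
        ds, _ = planted_screen_small
        before = hit_genes(call_screen(ds), "sensitizer")
        perturbed_wells = []
        for w in ds.wells:
            if w.arm == "sensitizer" and w.role is WellRole.EXPERIMENTAL:
                # triple the nuclei counts at fixed Myogenin fractions
                sites = tuple(
                    SiteMeasurement(s.total_nuclei * 3, s.myogenin_pos_nuclei * 3)
                    for s in w.sites
                )
                perturbed_wells.append(
                    Well(w.plate_id, w.well_coordinate, w.role, w.arm,
                         w.replicate_index, sites, w.target_gene)
                )
            else:
                perturbed_wells.append(w)
        perturbed = ScreenDataset(wells=perturbed_wells, library=ds.library)
        assert hit_genes(call_screen(perturbed), "sensitizer") == before

    def test_conjunction_never_increases_hits(self, planted_screen_small):
        """Adding the cell-number criterion cannot add vehicle-arm hits."""
        ds, _ = planted_screen_small
        from myoscreen.hit_calling import _score_dataset_wells

        config = HitCallConfig()
        scores = _score_dataset_wells(ds, config)
        myog_only = conjoined = 0
        for (gene, arm), ss in scores.items():
            if arm != "vehicle" or len(ss) != 3:
                continue
            myog_only += sum(1 for s in ss if s.myog_positive) >= 2
            conjoined += sum(1 for s in ss if s.myog_positive and s.cell_positive) >= 2
        assert conjoined <= myog_only


class TestCompareArms:
    @staticmethod
    def _calls(universe, hits, arm):
        return [
            KinaseCall(gene=g, arm=arm, n_positive_replicates=3 if g in hits else 0,
                       is_hit=g in hits)
            for g in universe
        ]

    def test_inclusion_exclusion_identity(self):
        universe = [f"G{i}" for i in range(50)]
        a = set(universe[:12])
        b = set(universe[8:25])
        cmp = compare_arms(
            self._calls(universe, a, "vehicle"),
            self._calls(universe, b, "sensitizer"),
            library_size=50,
        )
        assert len(cmp.union_hits) == len(a) + len(b) - len(a & b)
        assert cmp.double_hits == frozenset(a & b)

    def test_identical_arms(self):
        universe = ["A", "B", "C"]
        cmp = compare_arms(
            self._calls(universe, {"A"}, "vehicle"),
            self._calls(universe, {"A"}, "sensitizer"),
            3,
        )
        assert cmp.double_hits == cmp.union_hits == frozenset({"A"})

    def test_disjoint_arms(self):
        universe = ["A", "B", "C", "D"]
        cmp = compare_arms(
            self._calls(universe, {"A"}, "vehicle"),
            self._calls(universe, {"B", "C"}, "sensitizer"),
            4,
        )
        assert len(cmp.union_hits) == 3
        assert not cmp.double_hits

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ScreenValidationError):
            compare_arms(
                self._calls(["A", "B"], set(), "vehicle"),
                self._calls(["A"], set(), "sensitizer"),
                2,
            )


class TestCellNumberOnlyReport:
    def test_pure_antiproliferative_genes_dissociate(
        self, planted_screen_small, small_library
    ):
        ds, truth = planted_screen_small
        report = cell_number_only_report(ds)
        veh = report[report.arm == "vehicle"].iloc[0]
        anti = {
            g for g, r in truth.records.items()
            if r.proliferation_multiplier < 1 and r.differentiation_odds_multiplier == 1
        }
        assert anti <= set(veh.genes)
        hits = hit_genes(call_screen(ds), "vehicle")
        assert not anti & hits
        # genes with both effects are hits, hence absent from the report
        assert not set(veh.genes) & hits

    def test_null_screen_report_is_sparse(self, null_screen_small, small_library):
        ds, _ = null_screen_small
        report = cell_number_only_report(ds)
        veh = report[report.arm == "vehicle"].iloc[0]
        # under the null, few wells pass the cell criterion without Myogenin
        assert veh.n_cell_only_wells <= 0.45 * 3 * small_library.size
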