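"""Classification, additivity and ΣΔΔG assembly rules."""

import math

import pytest

from tcrfootprint.binding import Mutation, VariantId
from tcrfootprint.config import AnalysisConfig
from tcrfootprint.footprint import (CENSORED_LOWER, EXCLUDED_BELOW,
                                    EXCLUDED_ENHANCING, EXCLUDED_NO_TCR,
                                    EXCLUDED_PEPTIDE, INCLUDED_CLUSTER,
                                    INCLUDED_SINGLE, PairFloor,
                                    assemble_sigma_ddg, classify_energetic,
                                    classify_kinetic, peptide_scan_total,
                                    test_additivity as additivity_test)
from tcrfootprint.thermo import EnergyValue


def single(label, position, wt="R", new="A"):
    return VariantId.from_mutations(
        [Mutation("mhc-heavy", position, wt, new)])


def double(p1, wt1, p2, wt2):
    return VariantId.from_mutations([
        Mutation("mhc-heavy", p1, wt1, "A"),
        Mutation("mhc-heavy", p2, wt2, "A")])


class TestClassification:
    @pytest.mark.parametrize("fold,label", [
        (1.0, "no effect"), (0.6, "enhancing"), (1.5, "no effect"),
        (1.7, "1.5-2"), (2.0, "1.5-2"), (3.2, "2-4"), (9.0, ">4")])
    def test_energetic_bins(self, fold, label):
        assert classify_energetic(fold) == label

    def test_censored_lands_in_top_bin_with_marker(self):
        assert classify_energetic(math.inf, censored=True) == \
            ">4 (censored)"

    @pytest.mark.parametrize("fold,label", [
        (2.5, "kinetic"), (2.0, "non-kinetic"),      # strictly more than
        (1.2, "non-kinetic")])
    def test_kinetic_membership_strict_threshold(self, fold, label):
        assert classify_kinetic(fold) == label

    def test_censored_kon_is_indeterminate(self):
        assert classify_kinetic(None, censored=True) == "indeterminate"

    def test_planted_kon_effects_recovered_exactly(self, config):
        # 3 planted effects among 20 residues, noiseless folds
        folds = {f"V{i}A": 1.0 for i in range(20)}
        folds["V3A"], folds["V7A"], folds["V11A"] = 2.6, 3.0, 2.2
        flagged = {v for v, f in folds.items()
                   if classify_kinetic(
                       f, threshold=config.kinetic_fold_threshold)
                   == "kinetic"}
        assert flagged == {"V3A", "V7A", "V11A"}


class TestAdditivity:
    def test_exact_sum_is_additive(self):
        ddgs = {"a": EnergyValue(0.8, 0.06), "b": EnergyValue(0.5, 0.06),
                "ab": EnergyValue(1.3, 0.06)}
        res, warn = additivity_test(ddgs, [("a", "b", "ab")])
        assert res[0].additive and not warn
        assert res[0].deviation == pytest.approx(0.0)

    def test_large_deviation_is_non_additive(self):
        # deviation 0.9 >> max(2*sigma, 0.3)
        ddgs = {"a": EnergyValue(0.8, 0.06), "b": EnergyValue(0.5, 0.06),
                "ab": EnergyValue(2.2, 0.06)}
        res, _ = additivity_test(ddgs, [("a", "b", "ab")])
        assert not res[0].additive
        assert res[0].deviation == pytest.approx(0.9)

    def test_deviation_recomputable_from_members(self):
        ddgs = {"a": EnergyValue(0.8, 0.06), "b": EnergyValue(0.5, 0.06),
                "ab": EnergyValue(2.2, 0.06)}
        res, _ = additivity_test(ddgs, [("a", "b", "ab")])
        r = res[0]
        assert r.deviation == pytest.approx(
            r.ddg_ab.value - r.ddg_a.value - r.ddg_b.value)

    def test_missing_double_skipped_with_warning(self):
        ddgs = {"a": EnergyValue(0.8, 0.06), "b": EnergyValue(0.5, 0.06)}
        res, warn = additivity_test(ddgs, [("a", "b", "ab")])
        assert res == [] and "missing" in warn[0]

    def test_censored_member_skipped(self):
        ddgs = {"a": EnergyValue(0.8, 0.06), "b": EnergyValue(0.5, 0.06),
                "ab": EnergyValue(3.0, 0.0, "lower")}
        res, warn = additivity_test(ddgs, [("a", "b", "ab")])
        assert res == [] and "censored" in warn[0]


@pytest.fixture()
def config():
    return AnalysisConfig()


class TestAssembly:
    def _panel(self):
        return [VariantId(label="WT"),
                single("R65A", 65), single("K66A", 66, wt="K"),
                single("H70A", 70, wt="H"), single("Q155A", 155, wt="Q"),
                single("T73A", 73, wt="T"), single("D61A", 61, wt="D"),
                single("A158G", 158, wt="A", new="G"),
                single("V76A", 76, wt="V"), single("T80A", 80, wt="T"),
                double(76, "V", 80, "T")]

    def _ddgs(self):
        return {
            "R65A": EnergyValue(0.8, 0.03),
            "K66A": EnergyValue(2.46, 0.0, "lower"),
            "H70A": EnergyValue(0.9, 0.03),       # peptide contact
            "Q155A": EnergyValue(0.4, 0.03),
            "T73A": EnergyValue(-0.3, 0.03),      # enhancing
            "D61A": EnergyValue(0.1, 0.03),       # below threshold
            "A158G": EnergyValue(0.4, 0.03),      # no TCR contact
            "V76A": EnergyValue(0.35, 0.03),
            "T80A": EnergyValue(0.4, 0.03),
            "V76A+T80A": EnergyValue(0.75, 0.04),
        }

    def _report(self, config, **kw):
        defaults = dict(
            manual_peptide_exclusions=["H70"],
            manual_tcr_contacts=["R65", "K66", "H70", "Q155", "T73",
                                 "D61", "V76", "T80"],
            clusters=[("V76", "T80")],
        )
        defaults.update(kw)
        return assemble_sigma_ddg(self._ddgs(), self._panel(), config,
                                  **defaults)

    def test_every_variant_gets_exactly_one_decision(self, config):
        report = self._report(config)
        seen = [e.variant for e in report.ledger.entries]
        assert sorted(seen) == sorted(set(seen))
        assert set(seen) == set(self._ddgs())

    def test_reason_codes_follow_the_exclusion_rules(self, config):
        report = self._report(config)
        reasons = {e.variant: e.reason for e in report.ledger.entries}
        assert reasons["R65A"] == INCLUDED_SINGLE
        assert reasons["K66A"] == CENSORED_LOWER
        assert reasons["H70A"] == EXCLUDED_PEPTIDE
        assert reasons["T73A"] == EXCLUDED_ENHANCING
        assert reasons["D61A"] == EXCLUDED_BELOW
        assert reasons["A158G"] == EXCLUDED_NO_TCR
        assert reasons["V76A+T80A"] == INCLUDED_CLUSTER

    def test_cluster_members_contribute_zero_individually(self, config):
        report = self._report(config)
        counted = {e.variant for e in report.ledger.entries if e.counted}
        assert "V76A+T80A" in counted
        assert "V76A" not in counted and "T80A" not in counted
        # counted sum: 0.8 + 2.46 + 0.4 + 0.75
        assert report.ledger.sigma_ddg.value == pytest.approx(4.41)
        assert report.ledger.sigma_ddg.is_lower_limit

    def test_removing_a_residue_shifts_sigma_by_its_contribution(
            self, config):
        full = self._report(config).ledger.sigma_ddg.value
        ddgs = self._ddgs()
        ddgs.pop("R65A")
        panel = [v for v in self._panel() if v.label != "R65A"]
        partial = assemble_sigma_ddg(
            ddgs, panel, config, manual_peptide_exclusions=["H70"],
            manual_tcr_contacts=["R65", "K66", "H70", "Q155", "T73",
                                 "D61", "V76", "T80"],
            clusters=[("V76", "T80")]).ledger.sigma_ddg.value
        assert full - partial == pytest.approx(0.8)

    def test_cluster_without_double_falls_back_to_sum_of_singles(
            self, config):
        panel = [v for v in self._panel() if v.label != "V76A+T80A"]
        ddgs = self._ddgs()
        ddgs.pop("V76A+T80A")
        report = assemble_sigma_ddg(
            ddgs, panel, config, manual_peptide_exclusions=["H70"],
            clusters=[("V76", "T80")])
        assert any("naive additivity" in w for w in report.warnings)
        counted = {e.variant for e in report.ledger.entries if e.counted}
        assert {"V76A", "T80A"} <= counted

    def test_no_qualifying_residues_gives_empty_sum(self, config):
        panel = [VariantId(label="WT"), single("D61A", 61, wt="D")]
        report = assemble_sigma_ddg(
            {"D61A": EnergyValue(0.1, 0.02)}, panel, config)
        assert report.ledger.sigma_ddg is None

    def test_published_style_percent_from_aggregates(self, config):
        # contributions summing to -5.63 against a total of -11.93 -> 47%
        panel = [VariantId(label="WT"), single("R65A", 65),
                 single("Q155A", 155, wt="Q")]
        ddgs = {"R65A": EnergyValue(3.0, 0.1),
                "Q155A": EnergyValue(2.63, 0.125)}
        dg_wt = EnergyValue(-6.93, 0.06)
        report = assemble_sigma_ddg(ddgs, panel, config, dg_wt=dg_wt)
        ledger = report.ledger
        assert ledger.total_calc.value == pytest.approx(-11.93)
        assert ledger.total_calc.uncertainty == pytest.approx(1.06)
        assert ledger.mhc_contribution.value == pytest.approx(-5.63)
        assert round(ledger.pct_mhc_calc[0]) == 47
        assert round(ledger.pct_mhc_calc[1]) == 4

    def test_include_enhancing_switch(self):
        config = AnalysisConfig(include_enhancing=True)
        report = self._report(config)
        entry = report.ledger.entry("T73A")
        assert entry.counted


class TestPeptideScan:
    def test_pair_floor_substitution_reaches_lower_limit_total(self):
        # measurable contributions sum to -5.23; M4+W5 floor adds -2.66
        ddgs = {"pS1": EnergyValue(1.43, 0.03),
                "pI6": EnergyValue(2.2, 0.03),
                "pT7": EnergyValue(1.6, 0.03),
                "pM4": EnergyValue(1.9, 0.03),
                "pW5": EnergyValue(5.0, 0.0, "lower")}
        total, warn = peptide_scan_total(
            ddgs, ["pS1", "pI6", "pT7", "pM4", "pW5"],
            [PairFloor("pM4", "pW5", 2.66)])
        assert total.value == pytest.approx(-7.89)
        assert total.is_lower_limit
        assert not warn

    def test_no_censoring_gives_plain_sum_without_flag(self):
        ddgs = {"pI6": EnergyValue(2.0, 0.03), "pT7": EnergyValue(1.0, 0.03)}
        total, _ = peptide_scan_total(ddgs, ["pI6", "pT7"])
        assert total.value == pytest.approx(-3.0)
        assert not total.is_lower_limit

    def test_zero_floor_counts_only_measurable_members(self):
        ddgs = {"pI6": EnergyValue(2.0, 0.03),
                "pM4": EnergyValue(1.9, 0.03),
                "pW5": EnergyValue(5.0, 0.0, "lower")}
        total, _ = peptide_scan_total(ddgs, ["pI6", "pM4", "pW5"],
                                      [PairFloor("pM4", "pW5", 0.0)])
        assert total.value == pytest.approx(-2.0)

    def test_censored_without_floor_excluded_with_warning(self):
        ddgs = {"pI6": EnergyValue(2.0, 0.03),
                "pW5": EnergyValue(5.0, 0.0, "lower")}
        total, warn = peptide_scan_total(ddgs, ["pI6", "pW5"])
        assert total.value == pytest.approx(-2.0)
        assert total.is_lower_limit
        assert any("pW5" in w for w in warn)
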