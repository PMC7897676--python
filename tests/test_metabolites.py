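"""Transformation rules, candidate enumeration, five-criteria annotation."""

import numpy as np
import pandas as pd
import pytest

from isoformid import reference
from isoformid.errors import DomainError
from isoformid.formula import ElementalFormula, exact_mass, parse_formula, protonate
from isoformid.metabolites import (AnnotationConfig, annotate, build_report,
                                   default_rule_set, enumerate_candidates,
                                   select_panel)
from isoformid.peaks import PeakTable
from isoformid.simulate import (MSSimConfig, reference_plants,
                                simulate_peak_table, simulate_urine_table)

F = ElementalFormula


class TestRuleSet:
    def test_o_demethylation_gives_demethyl_metabolite(self, parent):
        rule = next(r for r in default_rule_set()
                    if r.name == "O-demethylation")
        demethyl = rule.apply(parent)
        assert demethyl.hill() == "C17H25NO"
        assert exact_mass(protonate(demethyl), decimals=4) == 260.2009

    def test_demethyl_glucuronide_composition(self, parent):
        rules = {r.name: r for r in default_rule_set()}
        aglycone = rules["O-demethylation"].apply(parent)
        conjugate = rules["glucuronidation"].apply(aglycone)
        assert conjugate.hill() == "C23H33NO7"
        assert (conjugate + F(H=1)).hill() == "C23H34NO7"  # MH+ of M2a

    def test_phase_two_rules_present(self):
        rules = default_rule_set()
        assert any(r.phase == "II" for r in rules)
        artifact_rules = [r for r in rules if r.artifact]
        assert all(r.name == "methylation-artifact" for r in artifact_rules)


class TestEnumeration:
    def test_depth_zero_returns_parent_only(self, parent):
        cands = enumerate_candidates(parent, default_rule_set(), 0)
        assert [c.neutral for c in cands] == [parent]

    def test_depth_one_single_rule(self, parent):
        rules = [r for r in default_rule_set() if r.name == "hydroxylation"]
        cands = enumerate_candidates(parent, rules, 1)
        neutrals = {c.neutral.hill() for c in cands}
        assert neutrals == {parent.hill(), (parent + F(O=1)).hill()}

    def test_closure_over_reported_compositions(self, parent):
        """Every distinct MH+ composition in the published metabolite table
        arises from <= 3 phase I steps plus optional glucuronidation."""
        cands = enumerate_candidates(parent, default_rule_set(), 3)
        generated = {c.mh_formula.hill() for c in cands}
        assert reference.distinct_mh_compositions() <= generated

    def test_duplicate_formulas_are_merged_with_all_paths(self, parent):
        cands = enumerate_candidates(parent, default_rule_set(), 3)
        by_formula = {}
        for c in cands:
            assert c.neutral not in by_formula, "duplicate candidate formula"
            by_formula[c.neutral] = c
        # oxo = hydroxylation + dehydrogenation reaches the same formula
        oxo = by_formula[parent + F(O=1) - F(H=2)]
        assert len(oxo.paths) >= 2

    def test_infeasible_paths_pruned_silently(self):
        # O-demethylation of CH2O leaves bare O; the subsequent
        # dehydrogenation step is infeasible and must be pruned, not raised
        tiny = parse_formula("CH2O")
        cands = enumerate_candidates(tiny, default_rule_set(), 2)
        assert all(min(c.neutral.values(), default=1) > 0 for c in cands)
        assert parse_formula("CO", allowed=None) in {c.neutral for c in cands}


def _annotation_inputs(seed=1, jitter=1.0):
    table, truth = simulate_urine_table(seed=seed, mass_jitter_ppm=jitter)
    candidates = enumerate_candidates(parse_formula("C18H27NO"))
    return table, truth, candidates


class TestAnnotate:
    def test_zero_jitter_closed_loop(self, parent):
        """Noise-free peaks planted from the reference compositions come
        back identified with zero mass error."""
        config = MSSimConfig(seed=0, mass_jitter_ppm=0.0, envelope_noise=0.0,
                             decoy_peaks=0)
        table, truth = simulate_peak_table(config, reference_plants())
        candidates = enumerate_candidates(parent)
        literature = frozenset(truth["neutral"])
        annotated = annotate(table, candidates, reference.PARENT_RT_MIN,
                             AnnotationConfig(literature_formulas=literature))
        planted = set(truth["neutral"])
        for cand in annotated:
            if cand.neutral.hill() in planted:
                assert cand.status == "identified"
                assert cand.evidence.mass.value == pytest.approx(0.0,
                                                                 abs=1e-9)

    def test_systematic_bias_beyond_tolerance_matches_nothing(self, parent):
        config = MSSimConfig(seed=0, mass_jitter_ppm=0.0,
                             mass_bias_ppm=10.0, decoy_peaks=0)
        table, truth = simulate_peak_table(config, reference_plants())
        annotated = annotate(table, enumerate_candidates(parent),
                             reference.PARENT_RT_MIN,
                             AnnotationConfig(ppm_tolerance=5.0))
        assert all(c.status == "rejected" for c in annotated)

    def test_metabolites_pass_rt_criterion_parent_reference(self, parent):
        table, truth, candidates = _annotation_inputs()
        annotated = annotate(table, candidates, reference.PARENT_RT_MIN)
        for cand in annotated:
            if cand.status == "identified" and not cand.is_parent:
                assert cand.evidence.rt.value < reference.PARENT_RT_MIN

    def test_isomer_groups_become_separate_matches_with_star(self, parent):
        table, truth, candidates = _annotation_inputs()
        annotated = annotate(table, candidates, reference.PARENT_RT_MIN)
        m1c_composition = reference.record("M1c").neutral_formula
        cand = next(c for c in annotated if c.neutral == m1c_composition)
        # M1b (one tR) and M1c (three tRs) share this composition: 4 features
        assert len(cand.matches) == 4
        assert sum(m.starred for m in cand.matches) == 1
        starred = next(m for m in cand.matches if m.starred)
        assert starred.feature.mono_intensity == max(
            m.feature.mono_intensity for m in cand.matches)

    def test_product_ion_criterion_counts_reference_fragments(self, parent):
        table, truth, candidates = _annotation_inputs(jitter=0.0)
        fragments = {
            rec.neutral_formula.hill(): rec.product_ions
            for rec in reference.REFERENCE_TABLE if rec.product_ions}
        annotated = annotate(
            table, candidates, reference.PARENT_RT_MIN,
            AnnotationConfig(fragment_reference=fragments))
        # M1g's MH+ composition is unique in the table, so its fragment
        # reference list is unambiguous
        m1g = next(c for c in annotated
                   if c.neutral == reference.record("M1g").neutral_formula)
        assert m1g.evidence.product_ions.value == len(
            reference.record("M1g").product_ions)
        assert m1g.evidence.product_ions.passed

    def test_recovery_non_increasing_in_jitter(self, parent):
        """Planted-truth recovery is 100% at zero jitter and degrades
        monotonically as mass jitter grows past the match tolerance."""
        candidates = enumerate_candidates(parent)
        by_comp = {c.mh_formula.hill(): c for c in candidates}

        def recovery(jitter):
            rates = []
            for seed in (0, 1, 2):
                table, truth = simulate_urine_table(seed=seed,
                                                    mass_jitter_ppm=jitter)
                annotated = annotate(table, candidates,
                                     reference.PARENT_RT_MIN)
                matched = {m.feature.feature_id
                           for c in annotated for m in c.matches}
                rates.append(truth["feature_id"].isin(matched).mean())
            return float(np.mean(rates))

        rates = [recovery(j) for j in (0.0, 2.0, 5.0, 20.0)]
        assert rates[0] == 1.0
        assert all(b <= a for a, b in zip(rates, rates[1:]))


class TestPanel:
    def test_reported_urine_panel_is_reproduced(self, parent, urine_scenario):
        table, truth = urine_scenario
        annotated = annotate(table, enumerate_candidates(parent),
                             reference.PARENT_RT_MIN)
        panel = select_panel(annotated, 7)
        assert len(panel) == 7
        fid_to_acronym = dict(zip(truth.feature_id, truth.analyte_id))
        acronyms = {fid_to_acronym[e.feature_id].split("#")[0]
                    for e in panel}
        assert acronyms == set(reference.URINE_PANEL_ACRONYMS)
        assert fid_to_acronym[panel[0].feature_id] == "3-MeO-PCP"

    def test_k_one_returns_parent_only(self, parent, urine_scenario):
        table, truth = urine_scenario
        annotated = annotate(table, enumerate_candidates(parent),
                             reference.PARENT_RT_MIN)
        panel = select_panel(annotated, 1)
        assert len(panel) == 1
        assert panel[0].label == "parent"

    def test_equal_intensities_break_ties_by_label(self, parent):
        plants = reference_plants(
            {a: 10.0 for a in ("3-MeO-PCP", "M1a", "M1b", "M1g")})
        config = MSSimConfig(seed=0, mass_jitter_ppm=0.0, envelope_noise=0.0,
                             decoy_peaks=0)
        table, truth = simulate_peak_table(config, plants)
        annotated = annotate(table, enumerate_candidates(parent),
                             reference.PARENT_RT_MIN)
        panel = select_panel(annotated, 3)
        labels = [e.label for e in panel[1:]]
        assert labels == sorted(labels)

    def test_artifacts_are_excluded_by_default(self, parent, urine_scenario):
        table, truth = urine_scenario
        annotated = annotate(table, enumerate_candidates(parent),
                             reference.PARENT_RT_MIN)
        # M1m and M1p have artifact-only compositions; M1n shares its
        # composition with the genuine metabolite M1o and cannot be told
        # apart at the formula level
        artifact_features = set(
            truth.loc[truth.analyte_id.str.startswith(("M1m", "M1p")),
                      "feature_id"])
        panel = select_panel(annotated, 24)
        assert not artifact_features & {e.feature_id for e in panel}


class TestReport:
    def test_full_pattern_rows_have_four_triplets(self, parent,
                                                  urine_scenario):
        table, truth = urine_scenario
        annotated = annotate(table, enumerate_candidates(parent),
                             reference.PARENT_RT_MIN)
        report = build_report(annotated)
        first = report.iloc[0]
        for label in ("M0", "M1", "M2", "M3"):
            assert first[f"{label}_exact"] > 0
            assert first[f"{label}_accurate"] != "-"

    def test_truncated_envelope_rendered_as_missing(self, parent):
        rows = []
        pattern = protonate(parent)
        from isoformid.isotopes import isotope_pattern
        peaks = isotope_pattern(pattern, 2)  # M+0, M+1 only
        for peak in peaks:
            rows.append({"feature_id": "F1", "mz": peak.mz,
                         "intensity": 1000 * peak.abundance,
                         "rt_min": reference.PARENT_RT_MIN})
        table = PeakTable(pd.DataFrame(rows))
        annotated = annotate(table, enumerate_candidates(parent),
                             reference.PARENT_RT_MIN)
        report = build_report(annotated)
        row = report.iloc[0]
        assert row["M3_accurate"] == "-"
        assert row["M3_ppm"] == "-"
        assert row["M0_accurate"] != "-"

    def test_ppm_columns_recomputable_from_mass_columns(self, parent,
                                                        urine_scenario):
        from isoformid.formula import ppm_error
        table, truth = urine_scenario
        annotated = annotate(table, enumerate_candidates(parent),
                             reference.PARENT_RT_MIN)
        report = build_report(annotated)
        for _, row in report.iterrows():
            for label in ("M0", "M1", "M2", "M3"):
                if row[f"{label}_accurate"] == "-":
                    continue
                recomputed = ppm_error(row[f"{label}_accurate"],
                                       row[f"{label}_exact"])
                assert recomputed == pytest.approx(row[f"{label}_ppm"],
                                                   abs=0.01)

    def test_no_identified_candidates_raises(self, parent):
        with pytest.raises(DomainError):
            build_report([])
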