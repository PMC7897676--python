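"""Biotransformation-based metabolite annotation.

Candidate metabolite formulas are generated from a parent compound by a rule
set of phase I mass shifts (O-demethylation, hydroxylation, oxidation to oxo,
dehydrogenation, carboxylation after ring opening) with an optional terminal
phase II conjugation (glucuronidation). Candidates are matched against an
observed peak table and scored on five identification criteria:

1. chromatographic behavior — metabolites, being more hydrophilic, elute
   earlier than the parent;
2. accurate mass of the MH+ ion within a ppm window;
3. agreement of the MH+ isotopic pattern (M+0..M+3 mass accuracy and RIA);
4. accurate-mass matches of collision-induced product ions against a
   reference fragment list;
5. concordance with literature-reported metabolite formulas.

A candidate is *identified* when criteria 2 and 3 pass together with at least
one of 1, 4, 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement

import pandas as pd

from .errors import DomainError, InfeasibleTransformationError
from .formula import ElementalFormula, ppm_error, protonate
from .isotopes import (DEFAULT_RIA_TOLERANCE_PCT,
                       IsotopePattern, PatternAgreement, compare_patterns,
                       isotope_pattern)
from .peaks import Feature, PeakTable

log = logging.getLogger(__name__)

GLUCURONIDE = ElementalFormula(C=6, H=8, O=6)


@dataclass(frozen=True)
class TransformationRule:
    """A biotransformation as a formula delta."""

    name: str
    added: ElementalFormula
    removed: ElementalFormula
    phase: str                 # "I" or "II"
    max_applications: int = 1
    artifact: bool = False

    def __post_init__(self):
        if not (self.added or self.removed):
            raise DomainError(f"rule {self.name!r} has an empty delta")
        if self.phase not in ("I", "II"):
            raise DomainError(f"rule {self.name!r}: phase must be I or II")

    def apply(self, formula: ElementalFormula) -> ElementalFormula:
        return (formula + self.added) - self.removed


def default_rule_set() -> list[TransformationRule]:
    """The phase I/II transformation vocabulary of PCP-type metabolism."""
    F = ElementalFormula
    return [
        TransformationRule("O-demethylation", F(), F(C=1, H=2), "I"),
        TransformationRule("hydroxylation", F(O=1), F(), "I",
                           max_applications=3),
        TransformationRule("dehydrogenation", F(), F(H=2), "I"),
        TransformationRule("oxidation-to-oxo", F(O=1), F(H=2), "I",
                           max_applications=2),
        TransformationRule("carboxylation", F(O=2), F(), "I"),
        TransformationRule("methylation-artifact", F(C=1, H=2), F(), "I",
                           artifact=True),
        TransformationRule("glucuronidation", GLUCURONIDE, F(), "II"),
    ]


@dataclass(frozen=True)
class CriterionResult:
    value: object
    passed: bool | None  # None = not evaluable (no data supplied)


@dataclass(frozen=True)
class Evidence:
    rt: CriterionResult | None = None
    mass: CriterionResult | None = None
    pattern: CriterionResult | None = None
    product_ions: CriterionResult | None = None
    literature: CriterionResult | None = None


@dataclass(frozen=True)
class FeatureMatch:
    feature: Feature
    delta_ppm: float
    starred: bool  # most abundant isomer in the match group


@dataclass(frozen=True)
class MetaboliteCandidate:
    """A transformation-derived formula plus its annotation evidence."""

    neutral: ElementalFormula
    paths: tuple[tuple[str, ...], ...]  # all generating rule-name paths
    phase: str                          # "parent", "I" or "II"
    artifact: bool
    matches: tuple[FeatureMatch, ...] = ()
    ambiguous: bool = False
    evidence: Evidence = field(default_factory=Evidence)
    status: str = "unmatched"           # identified / tentative / rejected

    @property
    def path(self) -> tuple[str, ...]:
        return self.paths[0]

    @property
    def is_parent(self) -> bool:
        return self.paths[0] == ()

    @property
    def mh_formula(self) -> ElementalFormula:
        return self.neutral + ElementalFormula(H=1)

    @property
    def label(self) -> str:
        if self.is_parent:
            return "parent"
        steps: list[str] = []
        seen: dict[str, int] = {}
        for name in self.path:
            seen[name] = seen.get(name, 0) + 1
        for name, n in seen.items():
            steps.append(name if n == 1 else f"{n}x{name}")
        return "+".join(steps)

    @property
    def primary_match(self) -> FeatureMatch | None:
        return self.matches[0] if self.matches else None

    def predicted_pattern(self, n_labels: int = 4) -> IsotopePattern:
        return isotope_pattern(protonate(self.neutral), n_labels)

    @property
    def predicted_mh_mz(self) -> float:
        return self.predicted_pattern(1).peaks[0].mz


def enumerate_candidates(parent: ElementalFormula,
                         rules: list[TransformationRule] | None = None,
                         depth: int = 3) -> list[MetaboliteCandidate]:
    """All distinct formula outcomes of the rule set on a parent compound.

    ``depth`` bounds the number of phase I applications (each rule also
    respecting its own per-candidate maximum); one phase II conjugation may
    then be applied as the terminal step. Infeasible subtractions are pruned
    silently; duplicate formulas are merged with all generating paths kept.
    The parent itself is returned as the empty-path candidate.
    """
    if depth < 0:
        raise DomainError("depth must be >= 0")
    rules = default_rule_set() if rules is None else rules
    phase1 = [r for r in rules if r.phase == "I"]
    phase2 = [r for r in rules if r.phase == "II"]

    outcomes: dict[ElementalFormula, list[tuple[tuple[str, ...], bool, str]]] = {}

    def record(formula, path, artifact, phase):
        outcomes.setdefault(formula, []).append((path, artifact, phase))

    record(parent, (), False, "parent")
    for n_steps in range(1, depth + 1):
        for combo in combinations_with_replacement(phase1, n_steps):
            if any(combo.count(r) > r.max_applications for r in set(combo)):
                continue
            formula = parent
            try:
                for rule in combo:
                    formula = rule.apply(formula)
            except InfeasibleTransformationError:
                continue
            path = tuple(r.name for r in combo)
            record(formula, path, any(r.artifact for r in combo), "I")

    # terminal phase II conjugation of every phase I outcome (and the
    # parent); at depth 0 no transformation at all is allowed
    for formula, paths in list(outcomes.items()) if depth >= 1 else []:
        for rule in phase2:
            try:
                conjugate = rule.apply(formula)
            except InfeasibleTransformationError:
                continue
            for path, artifact, _phase in paths:
                record(conjugate, path + (rule.name,),
                       artifact or rule.artifact, "II")

    candidates = []
    for formula, entries in outcomes.items():
        paths = tuple(sorted({p for p, _a, _ph in entries}, key=lambda p: (len(p), p)))
        artifact = all(a for _p, a, _ph in entries)
        phase = entries[0][2] if len({ph for _p, _a, ph in entries}) == 1 else \
            sorted({ph for _p, _a, ph in entries})[0]
        if formula == parent and () in paths:
            phase = "parent"
        candidates.append(MetaboliteCandidate(formula, paths, phase, artifact))
    candidates.sort(key=lambda c: (len(c.path), c.neutral.hill()))
    return candidates


@dataclass(frozen=True)
class AnnotationConfig:
    """Tolerances and reference inputs for the five criteria."""

    ppm_tolerance: float = 5.0            # criterion 2 MH+ window
    rt_guard_min: float = 0.1             # criterion 1 guard band below parent
    pattern_ppm_tolerances: dict | None = None   # criterion 3, per label
    ria_tolerance_pct: float = DEFAULT_RIA_TOLERANCE_PCT
    fragment_tolerance_ppm: float = 10.0  # criterion 4
    min_product_ions: int = 1
    fragment_reference: dict[str, tuple[float, ...]] | None = None
    literature_formulas: frozenset[str] | None = None

    def __post_init__(self):
        if self.ppm_tolerance <= 0 or self.fragment_tolerance_ppm <= 0:
            raise DomainError("tolerances must be positive")


def _score_candidate(cand: MetaboliteCandidate, features: list[Feature],
                     parent_rt: float, config: AnnotationConfig,
                     ) -> MetaboliteCandidate:
    target = cand.predicted_mh_mz
    pattern = cand.predicted_pattern()
    in_window = [(ppm_error(f.mono_mz, target), f) for f in features]
    in_window = [(dm, f) for dm, f in in_window
                 if abs(dm) <= config.ppm_tolerance]
    if not in_window:
        return replace(cand, matches=(), ambiguous=False,
                       evidence=Evidence(mass=CriterionResult(None, False)),
                       status="rejected")
    # deterministic primary: smallest |Δm|, tie -> larger intensity, then id
    in_window.sort(key=lambda t: (abs(t[0]), -t[1].mono_intensity,
                                  t[1].feature_id))
    star_id = max(in_window, key=lambda t: t[1].mono_intensity)[1].feature_id
    matches = tuple(FeatureMatch(f, dm, f.feature_id == star_id)
                    for dm, f in in_window)
    primary = matches[0]
    feat = primary.feature

    rt_pass = feat.rt_min < parent_rt - config.rt_guard_min
    c1 = CriterionResult(feat.rt_min, rt_pass)
    c2 = CriterionResult(primary.delta_ppm, True)
    agreement = compare_patterns(feat.isotope_pattern(), pattern,
                                 config.pattern_ppm_tolerances,
                                 config.ria_tolerance_pct)
    c3 = CriterionResult(agreement, agreement.all_present_pass)

    c4 = None
    if config.fragment_reference is not None:
        ref = config.fragment_reference.get(cand.neutral.hill())
        if ref:
            observed = feat.all_product_ions()
            count = sum(
                any(abs(ppm_error(o, r)) <= config.fragment_tolerance_ppm
                    for o in observed) for r in ref)
            c4 = CriterionResult(count, count >= config.min_product_ions)
    c5 = None
    if config.literature_formulas is not None:
        hit = cand.neutral.hill() in config.literature_formulas
        c5 = CriterionResult(hit, hit)

    if cand.is_parent:
        # the parent is its own chromatographic reference; criterion 1 is
        # satisfied by definition
        c1 = CriterionResult(feat.rt_min, True)

    core = c2.passed and c3.passed
    supporting = [c for c in (c1, c4, c5) if c is not None]
    status = "identified" if core and any(c.passed for c in supporting) \
        else "tentative"
    return replace(cand, matches=matches, ambiguous=len(matches) > 1,
                   evidence=Evidence(c1, c2, c3, c4, c5), status=status)


def annotate(peaks: PeakTable,
             candidates: list[MetaboliteCandidate],
             parent_rt: float,
             config: AnnotationConfig | None = None,
             ) -> list[MetaboliteCandidate]:
    """Match candidates against a peak table and fill in the evidence."""
    if parent_rt <= 0:
        raise DomainError("parent retention time must be positive")
    config = config or AnnotationConfig()
    features = peaks.features()
    return [_score_candidate(c, features, parent_rt, config)
            for c in candidates]


@dataclass(frozen=True)
class PanelEntry:
    label: str
    feature_id: str
    mh_composition: str
    rt_min: float
    intensity: float


def select_panel(annotated: list[MetaboliteCandidate], k: int,
                 include_artifacts: bool = False) -> list[PanelEntry]:
    """The top-k screening panel: parent plus the most abundant identified
    metabolite features (isomer features count separately).

    Carboxy/methyl ester artifacts are excluded by default. Ties are broken
    by candidate label then feature id for reproducibility.
    """
    if k < 1:
        raise DomainError("k must be >= 1")

    def entries_for(cand):
        return [PanelEntry(cand.label, m.feature.feature_id,
                           cand.mh_formula.hill(), m.feature.rt_min,
                           m.feature.mono_intensity)
                for m in cand.matches]

    parent = next((c for c in annotated if c.is_parent), None)
    panel: list[PanelEntry] = []
    if parent is not None and parent.matches:
        panel.append(entries_for(parent)[0])
    pool: list[PanelEntry] = []
    for cand in annotated:
        if cand.is_parent or cand.status != "identified":
            continue
        if cand.artifact and not include_artifacts:
            continue
        pool.extend(entries_for(cand))
    pool.sort(key=lambda e: (-e.intensity, e.label, e.feature_id))
    panel.extend(pool[:max(0, k - len(panel))])
    if len(panel) < k:
        log.warning("panel has only %d of %d requested analytes",
                    len(panel), k)
    return panel


MISSING = "-"


def build_report(annotated: list[MetaboliteCandidate],
                 decimals: int = 4, max_product_ions: int = 7) -> pd.DataFrame:
    """Case-report table: one row per identified candidate with
    per-isotopologue exact/accurate/Δm triplets and product ions.

    Missing measurements are rendered as ``"-"``; for isomer groups the
    retention time of the most abundant feature is starred and its MS data
    reported.
    """
    rows = []
    identified = [c for c in annotated if c.status == "identified"]
    if not identified:
        raise DomainError("no identified candidates to report")
    for cand in identified:
        pattern = cand.predicted_pattern()
        starred = next(m for m in cand.matches if m.starred)
        observed = starred.feature.isotope_pattern()
        rts = sorted(cand.matches, key=lambda m: m.feature.rt_min)
        rt_text = "/".join(
            f"{m.feature.rt_min:.2f}" + ("*" if m.starred and len(rts) > 1 else "")
            for m in rts)
        row: dict[str, object] = {
            "metabolite": cand.label,
            "mh_composition": cand.mh_formula.hill(),
            "rt_min": rt_text,
        }
        for peak in pattern:
            key = peak.label.replace("+", "")
            exact = round(peak.mz, decimals)
            if peak.label in observed.labels:
                accurate = round(observed.peak(peak.label).mz, decimals)
                row[f"{key}_exact"] = exact
                row[f"{key}_accurate"] = accurate
                row[f"{key}_ppm"] = round(ppm_error(accurate, exact), 2)
            else:
                row[f"{key}_exact"] = exact
                row[f"{key}_accurate"] = MISSING
                row[f"{key}_ppm"] = MISSING
        ions = starred.feature.all_product_ions()[:max_product_ions]
        for i in range(max_product_ions):
            row[f"product_ion_{i + 1}"] = ions[i] if i < len(ions) else MISSING
        rows.append(row)
    return pd.DataFrame(rows)
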