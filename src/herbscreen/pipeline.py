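"""End-to-end herb screen: material basis AND drug property.

A herb is screened positive when it both contains many known
hepatoprotective ingredients (degree in the undetermined herb-ingredient
network at or above a threshold) and holds hepatoprotective-like drug
properties (cluster-branch verdict against labeled references).  Matched
association rules are reported as supporting evidence only; they do not
gate the final call.  Herbs lacking channel-tropism information cannot be
clustered and are reported as unassessable rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .herbs import (
    HEPATO_LIKE,
    AssociationRule,
    cluster_classify,
    match_rules_to_herb,
    mine_association_rules,
)
from .io import (
    HEPATOPROTECTIVE,
    NON_HEPATOPROTECTIVE,
    DataError,
    HerbIngredientEdges,
    HerbRecord,
)
from .network import build_networks, filter_candidates, ingredient_degree


@dataclass(frozen=True)
class ScreenConfig:
    """Every threshold of the screen, embedded in the report header."""

    min_count: int = 15
    min_support: float = 0.05
    min_confidence: float = 0.65
    min_lift: float = 1.0
    max_antecedent: int = 3
    linkage: str = "ward"
    k_cut: int = 2
    seed: int = 0


@dataclass(frozen=True)
class CandidateReport:
    name: str
    n_active_ingredients: int
    verdict: str | None  # None when unassessable
    matched_rules: tuple[int, ...]
    screened: bool
    supporting_category: str = ""
    unassessable: bool = False


@dataclass
class ScreenResult:
    config: ScreenConfig
    reports: list[CandidateReport]
    rules: list[AssociationRule] = field(default_factory=list)

    @property
    def screened(self) -> list[CandidateReport]:
        return [r for r in self.reports if r.screened]


def run_screen(
    edges: HerbIngredientEdges,
    active_ingredients: Sequence[str],
    herb_table: Sequence[HerbRecord],
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Run the full two-condition screen over an undetermined herb pool.

    Reference herbs are the table rows with a determined status; herbs with
    undetermined status form the pool.  Stage errors propagate with the
    stage name prefixed.
    """
    by_name = {h.name: h for h in herb_table}
    hepato_herbs = {h.name for h in herb_table if h.status == HEPATOPROTECTIVE}
    reference = [
        h for h in herb_table
        if h.status in (HEPATOPROTECTIVE, NON_HEPATOPROTECTIVE)
    ]

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise DataError(f"stage {name!r} failed: {exc}") from exc

    _, undetermined = stage(
        "build_networks", build_networks, edges, active_ingredients, hepato_herbs
    )
    degrees = stage("ingredient_degree", ingredient_degree, undetermined)
    candidates = stage(
        "filter_candidates", filter_candidates, degrees, config.min_count
    )
    rules = stage(
        "mine_rules",
        mine_association_rules,
        reference,
        min_support=config.min_support,
        min_confidence=config.min_confidence,
        min_lift=config.min_lift,
        max_antecedent=config.max_antecedent,
    )

    cand_records: list[HerbRecord] = [
        by_name[d.herb]
        for d in candidates
        if d.herb in by_name and by_name[d.herb].clusterable
    ]
    assignments = (
        stage(
            "cluster_classify",
            cluster_classify,
            reference,
            cand_records,
            linkage=config.linkage,
            k_cut=config.k_cut,
        )
        if cand_records
        else []
    )
    verdict_of = {a.name: a.verdict for a in assignments}

    reports: list[CandidateReport] = []
    for d in candidates:
        rec = by_name.get(d.herb)
        if rec is None or not rec.clusterable:
            reports.append(
                CandidateReport(
                    d.herb, d.n_active_ingredients, None, (), False,
                    supporting_category=rec.efficacy_category if rec else "",
                    unassessable=True,
                )
            )
            continue
        verdict = verdict_of[d.herb]
        matched = tuple(match_rules_to_herb(rec, rules))
        screened = (
            d.n_active_ingredients >= config.min_count and verdict == HEPATO_LIKE
        )
        reports.append(
            CandidateReport(
                d.herb, d.n_active_ingredients, verdict, matched, screened,
                supporting_category=rec.efficacy_category,
            )
        )
    return ScreenResult(config, reports, rules)


def count_rule_hits(
    herb_names: Sequence[str], annotations: Mapping[str, Sequence[int]]
) -> int:
    """Total number of rule matches over the named herbs.

    ``annotations`` maps herb name to its (possibly empty) matched-rule-ID
    list; naming a herb without an annotation entry is a data error.
    """
    missing = [h for h in herb_names if h not in annotations]
    if missing:
        raise DataError(f"no rule annotation for herbs: {missing}")
    return sum(len(annotations[h]) for h in herb_names)


def _header_lines(config: ScreenConfig) -> list[str]:
    keys = (
        "min_count min_support min_confidence min_lift max_antecedent "
        "linkage k_cut seed"
    ).split()
    return [f"# {k} = {getattr(config, k)}" for k in keys]


def render_report(
    result: ScreenResult, path: str | Path, fmt: str = "delimited"
) -> None:
    """Write the candidate report deterministically (Table-5-style columns).

    Columns: name, number of active ingredients, matched rule IDs, cluster
    verdict, screened flag.  A provenance header records every threshold.
    Identical inputs and config produce byte-identical output.
    """
    rows = sorted(
        result.reports, key=lambda r: (-r.n_active_ingredients, r.name)
    )
    lines: list[str] = []
    if fmt == "delimited":
        lines.extend(_header_lines(result.config))
        lines.append("name\tn_active_ingredients\tmatched_rules\tverdict\tscreened")
        for r in rows:
            verdict = "unassessable" if r.unassessable else r.verdict
            lines.append(
                "\t".join(
                    [
                        r.name,
                        str(r.n_active_ingredients),
                        ", ".join(map(str, r.matched_rules)) or "-",
                        verdict,
                        str(r.screened).lower(),
                    ]
                )
            )
    elif fmt == "markdown":
        lines.extend(_header_lines(result.config))
        lines.append("| Name | Components | Association rules | Verdict | Screened |")
        lines.append("| --- | --- | --- | --- | --- |")
        for r in rows:
            verdict = "unassessable" if r.unassessable else r.verdict
            lines.append(
                f"| {r.name} | {r.n_active_ingredients} | "
                f"{', '.join(map(str, r.matched_rules)) or '-'} | "
                f"{verdict} | {str(r.screened).lower()} |"
            )
    else:
        raise DataError(f"unknown report format {fmt!r}")
    Path(path).write_text("\n".join(lines) + "\n")
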