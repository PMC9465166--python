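"""Herb-level drug-property statistics.

A herb's drug property (nature, flavor, channel tropism) is encoded as a
24-bit binary vector in the fixed vocabulary order.  This module provides:

* frequency summaries by efficacy category or property term, per
  hepatoprotection status, with an overlap report;
* a two-tailed chi-squared contrast of property profiles between
  hepatoprotective and non-hepatoprotective herbs (omnibus 2 x 24
  homogeneity test, or 24 per-term 2 x 2 tests with Benjamini-Hochberg
  adjustment);
* Apriori association-rule mining with the consequent fixed to
  hepatoprotection, reporting support, confidence and lift;
* hierarchical-cluster branch classification: candidates are clustered
  jointly with labeled reference herbs (Euclidean distance, Ward linkage by
  default) and called hepatoprotective-like when their branch is enriched
  in hepatoprotective references beyond the global prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .io import (
    HEPATOPROTECTIVE,
    NON_HEPATOPROTECTIVE,
    ConfigurationError,
    DataError,
    HerbRecord,
)
from .vocab import PROPERTY_TERMS, TERM_INDEX


def encode_properties(record: HerbRecord) -> np.ndarray:
    """24-bit binary property vector in the fixed vocabulary order."""
    bits = np.zeros(len(PROPERTY_TERMS), dtype=int)
    for term in record.properties:
        bits[TERM_INDEX[term]] = 1
    return bits


def encode_property_matrix(records: Sequence[HerbRecord]) -> pd.DataFrame:
    """Stacked property vectors, indexed by herb name."""
    return pd.DataFrame(
        [encode_properties(r) for r in records],
        index=[r.name for r in records],
        columns=list(PROPERTY_TERMS),
    )


def frequency_summary(
    herbs: Sequence[HerbRecord], group_by: str = "efficacy_category"
) -> pd.DataFrame:
    """Counts per group per hepatoprotection status.

    ``group_by`` is ``"efficacy_category"`` or ``"property"`` (one row per
    vocabulary term).  Sorted by the hepatoprotective count, descending.
    """
    if not herbs:
        raise DataError("no herbs to summarize")
    statuses = [HEPATOPROTECTIVE, NON_HEPATOPROTECTIVE]
    rows: dict[str, dict[str, int]] = {}
    for r in herbs:
        keys = [r.efficacy_category] if group_by == "efficacy_category" else [
            t for t in PROPERTY_TERMS if t in r.properties
        ]
        for key in keys:
            d = rows.setdefault(key, {s: 0 for s in statuses})
            if r.status in d:
                d[r.status] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return df.sort_values(HEPATOPROTECTIVE, ascending=False)


def overlap_report(
    protective_names: Iterable[str], toxic_names: Iterable[str]
) -> set[str]:
    """Herbs reported both hepatoprotective and hepatotoxic."""
    return set(protective_names) & set(toxic_names)


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p: float
    term: str | None = None  # None for the omnibus test
    p_adjusted: float | None = None
    warning: str | None = None


def chi_squared_contrast(
    hepato: np.ndarray | pd.DataFrame,
    non_hepato: np.ndarray | pd.DataFrame,
    mode: str = "omnibus",
    correction: bool = False,
) -> ChiSquaredResult | list[ChiSquaredResult]:
    """Two-tailed chi-squared contrast of drug-property profiles.

    ``omnibus`` tests homogeneity of the 2 x 24 per-term possession-count
    table; ``per_feature`` runs 24 individual 2 x 2 tests (possession vs
    group) with Benjamini-Hochberg adjusted p-values alongside the raw ones.
    Continuity correction is off by default.  Low expected cells attach a
    warning to the result instead of failing.
    """
    A = np.asarray(hepato, dtype=int)
    B = np.asarray(non_hepato, dtype=int)
    if A.size == 0 or B.size == 0:
        raise DataError("both groups must be non-empty")
    nA, nB = A.shape[0], B.shape[0]
    countA, countB = A.sum(axis=0), B.sum(axis=0)
    if mode == "omnibus":
        table = np.vstack([countA, countB])
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        if np.allclose(table[0] * table[1].sum(), table[1] * table[0].sum()):
            # proportional profiles: statistic exactly 0 by construction
            return ChiSquaredResult(0.0, table.shape[1] - 1, 1.0)
        stat, p, df, expected = chi2_contingency(table, correction=False)
        warn = "expected cell < 1" if (expected < 1).any() else None
        return ChiSquaredResult(float(stat), int(df), float(p), warning=warn)
    if mode != "per_feature":
        raise ConfigurationError(f"unknown mode {mode!r}")
    results = []
    raw_ps = []
    for t, term in enumerate(PROPERTY_TERMS):
        table = np.array(
            [[countA[t], nA - countA[t]], [countB[t], nB - countB[t]]]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            results.append(ChiSquaredResult(0.0, 1, 1.0, term=term,
                                            warning="degenerate table"))
            raw_ps.append(1.0)
            continue
        stat, p, df, expected = chi2_contingency(table, correction=correction)
        warn = "expected cell < 1" if (expected < 1).any() else None
        results.append(ChiSquaredResult(float(stat), int(df), float(p),
                                        term=term, warning=warn))
        raw_ps.append(float(p))
    adj = multipletests(raw_ps, method="fdr_bh")[1]
    return [
        ChiSquaredResult(r.statistic, r.df, r.p, term=r.term,
                         p_adjusted=float(a), warning=r.warning)
        for r, a in zip(results, adj)
    ]


@dataclass(frozen=True)
class AssociationRule:
    """Antecedent property-term set => hepatoprotection, with its measures."""

    antecedent: frozenset[str]
    support: float  # P(antecedent AND hepatoprotective)
    confidence: float  # P(hepatoprotective | antecedent)
    lift: float  # confidence / prior(hepatoprotective)

    @property
    def id_str(self) -> str:
        return "{" + ", ".join(sorted(self.antecedent)) + "}"


def mine_association_rules(
    herbs: Sequence[HerbRecord],
    min_support: float = 0.05,
    min_confidence: float = 0.65,
    min_lift: float = 1.0,
    max_antecedent: int = 3,
) -> list[AssociationRule]:
    """Apriori rules with the consequent fixed to hepatoprotection.

    Level-wise frequent-itemset expansion over the property terms with the
    anti-monotone support prune (an antecedent is expanded only while
    P(antecedent AND hepatoprotective) >= min_support).  Rules must pass all
    three thresholds and have at most ``max_antecedent`` items; sorted by
    confidence descending, then support descending.
    """
    for thr in (min_support, min_confidence):
        if not 0 < thr <= 1:
            raise ConfigurationError("support/confidence thresholds must be in (0, 1]")
    herbs = [h for h in herbs if h.status in (HEPATOPROTECTIVE, NON_HEPATOPROTECTIVE)]
    n = len(herbs)
    if n == 0:
        raise DataError("no herbs with determined status")
    positive = [h.properties for h in herbs if h.status == HEPATOPROTECTIVE]
    allsets = [h.properties for h in herbs]
    prior = len(positive) / n
    if prior == 0:
        return []

    def joint_count(itemset: frozenset[str]) -> int:
        return sum(1 for s in positive if itemset <= s)

    def antecedent_count(itemset: frozenset[str]) -> int:
        return sum(1 for s in allsets if itemset <= s)

    items = sorted({t for s in allsets for t in s})
    level = [frozenset([t]) for t in items]
    frequent: list[frozenset[str]] = []
    while level and len(next(iter(level))) <= max_antecedent:
        survivors = [s for s in level if joint_count(s) / n >= min_support]
        frequent.extend(survivors)
        if len(next(iter(level), frozenset())) == max_antecedent:
            break
        # candidate generation: join survivors sharing all but one item
        seen = set()
        nxt = []
        for a, b in combinations(survivors, 2):
            u = a | b
            if len(u) == len(a) + 1 and u not in seen:
                seen.add(u)
                nxt.append(u)
        level = sorted(nxt, key=lambda s: sorted(s))
    rules = []
    for ante in frequent:
        n_ante = antecedent_count(ante)
        n_joint = joint_count(ante)
        support = n_joint / n
        confidence = n_joint / n_ante
        lift = confidence / prior
        if confidence >= min_confidence and lift > min_lift:
            rules.append(AssociationRule(ante, support, confidence, lift))
    return sorted(rules, key=lambda r: (-r.confidence, -r.support, r.id_str))


def match_rules_to_herb(
    record: HerbRecord, rules: Sequence[AssociationRule]
) -> list[int]:
    """1-based IDs of the rules whose antecedent is a subset of the herb's terms."""
    return [
        i for i, rule in enumerate(rules, start=1)
        if rule.antecedent <= record.properties
    ]


@dataclass(frozen=True)
class ClusterAssignment:
    name: str
    branch: int
    verdict: str  # "hepatoprotective-like" / "non-hepatoprotective-like"
    branch_composition: dict[str, int] = field(hash=False, compare=False, default=None)


HEPATO_LIKE = "hepatoprotective-like"
NON_HEPATO_LIKE = "non-hepatoprotective-like"


def cluster_classify(
    reference: Sequence[HerbRecord],
    candidates: Sequence[HerbRecord],
    linkage: str = "ward",
    k_cut: int = 2,
) -> list[ClusterAssignment]:
    """Classify candidate herbs by the branch they share with references.

    References and candidates are clustered jointly (agglomerative,
    Euclidean distance, configurable linkage), the tree cut into ``k_cut``
    branches; a candidate is hepatoprotective-like iff the fraction of
    hepatoprotective reference herbs in its branch exceeds the global
    reference prior.  A branch containing no reference herbs yields a
    non-hepatoprotective-like verdict (enrichment cannot be established).
    """
    statuses = {r.status for r in reference}
    if not {HEPATOPROTECTIVE, NON_HEPATOPROTECTIVE} <= statuses:
        raise DataError("reference must contain both statuses")
    ref_names = {r.name for r in reference}
    clash = [c.name for c in candidates if c.name in ref_names]
    if clash:
        raise DataError(f"candidates duplicate reference herbs: {sorted(clash)}")
    records = list(reference) + list(candidates)
    X = encode_property_matrix(records).to_numpy(dtype=float)
    Z = scipy_linkage(X, method=linkage, metric="euclidean")
    branches = fcluster(Z, t=k_cut, criterion="maxclust")
    n_ref = len(reference)
    prior = sum(1 for r in reference if r.status == HEPATOPROTECTIVE) / n_ref
    out = []
    for ci, cand in enumerate(candidates):
        b = int(branches[n_ref + ci])
        comp = {HEPATOPROTECTIVE: 0, NON_HEPATOPROTECTIVE: 0}
        for ri, ref in enumerate(reference):
            if int(branches[ri]) == b:
                comp[ref.status] = comp.get(ref.status, 0) + 1
        total = comp[HEPATOPROTECTIVE] + comp[NON_HEPATOPROTECTIVE]
        frac = comp[HEPATOPROTECTIVE] / total if total else 0.0
        verdict = HEPATO_LIKE if frac > prior else NON_HEPATO_LIKE
        out.append(ClusterAssignment(cand.name, b, verdict, comp))
    return out
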