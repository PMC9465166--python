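"""Synthetic desk-scale inputs with the statistical structure every stage assumes.

Three generators share one seeded spec:

* ``generate_compounds`` — labeled SMILES built from a small scaffold
  grammar (rings, chains, common substituents), with discriminative motifs
  planted into the actives at a stated penetrance and leaking into the
  inactives at a stated rate;
* ``generate_herbs`` — reference herbs (hepatoprotective /
  non-hepatoprotective, roughly the 123:132 regime) carrying 24-term
  property vectors with planted antecedent->status association rules at
  stated confidences, plus undetermined candidate herbs drawn from either
  the hepatoprotective-like or the non-hepatoprotective-like property
  profile;
* ``generate_edges`` — a bipartite herb-ingredient list in which designated
  candidate herbs are enriched (>= planted_degree distinct active
  ingredients) against a sparse background.

All randomness flows from ``SyntheticSpec.seed``; the same seed reproduces
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .io import (
    ACTIVE,
    HEPATOPROTECTIVE,
    INACTIVE,
    NON_HEPATOPROTECTIVE,
    UNDETERMINED,
    ConfigurationError,
    CompoundSet,
    HerbIngredientEdges,
    HerbRecord,
    LabeledCompound,
)
from .vocab import CHANNELS, FLAVORS, NATURES

#: planted structural alert used by default: a nitroaromatic motif
NITROAROMATIC = "c1ccc(cc1)[N+](=O)[O-]"

# scaffold grammar: each piece is a SMILES chunk that can be chained by
# concatenation (the last atom of the growing string bonds the first atom
# of the next piece); ring-closure digits are unique per piece
_PIECES = (
    "CC", "CCC", "CCO", "CC(C)C", "CCN", "CC(=O)C", "CCOC",
    "c1ccccc1", "C1CCCCC1", "c1ccncc1", "c1ccoc1", "C1CCOC1",
    "c2ccccc2", "C2CCCC2", "c2ccsc2",
)


@dataclass(frozen=True)
class PlantedAlert:
    motif: str = NITROAROMATIC
    penetrance: float = 2.0 / 7.0  # fraction of actives carrying the motif
    leak: float = 0.0  # fraction of inactives carrying it


@dataclass(frozen=True)
class PlantedRule:
    antecedent: frozenset[str] = frozenset({"sour"})
    confidence: float = 0.714  # P(hepatoprotective | antecedent)
    base_rate: float = 0.48  # P(hepatoprotective) away from the antecedent


@dataclass(frozen=True)
class SyntheticSpec:
    """Stated world for the generators.

    Defaults emulate the study regime: ~700 active / 200 inactive compounds
    with one planted nitroaromatic alert; ~250 reference herbs at a ~0.48
    hepatoprotective prior with a planted sour->hepatoprotection rule;
    25 undetermined candidate herbs, 12 of them drawn from the
    hepatoprotective-like property profile, all enriched to >= 15 distinct
    active ingredients in the edge list.
    """

    seed: int = 0
    n_active: int = 700
    n_inactive: int = 200
    planted_alerts: tuple[PlantedAlert, ...] = (PlantedAlert(),)
    n_herbs: int = 250
    planted_rules: tuple[PlantedRule, ...] = (PlantedRule(),)
    n_candidates: int = 25
    n_hepato_like: int = 12
    n_enriched: int = 25  # candidates given >= planted_degree active edges
    n_enriched_hepato_like: int = 12  # of which drawn from the hepato profile
    planted_degree: int = 15
    background_edge_rate: float = 0.01
    profile_shift: float = 0.85  # strength of the status-linked profile bits

    def __post_init__(self) -> None:
        for a in self.planted_alerts:
            if not (0 <= a.penetrance <= 1 and 0 <= a.leak <= 1):
                raise ConfigurationError("penetrance/leak must be in [0, 1]")
            if Chem.MolFromSmiles(a.motif) is None:
                raise ConfigurationError(f"unembeddable motif {a.motif!r}")
        seen: dict[frozenset[str], float] = {}
        for r in self.planted_rules:
            if not (0 <= r.confidence <= 1 and 0 <= r.base_rate <= 1):
                raise ConfigurationError("confidence/base rate must be in [0, 1]")
            if seen.get(r.antecedent, r.confidence) != r.confidence:
                raise ConfigurationError(
                    f"inconsistent confidences for antecedent {set(r.antecedent)}"
                )
            seen[r.antecedent] = r.confidence
        if self.planted_degree < 1:
            raise ConfigurationError("planted_degree must be at least 1")
        if self.n_hepato_like > self.n_candidates:
            raise ConfigurationError("n_hepato_like exceeds n_candidates")


def _random_scaffold(rng: np.random.Generator, n_pieces: int) -> str:
    parts = []
    for i in range(n_pieces):
        piece = _PIECES[int(rng.integers(len(_PIECES)))]
        # re-number ring closures so chained pieces never collide
        digit = str(3 + (i % 7))
        parts.append(piece.replace("1", digit).replace("2", digit))
    return "".join(parts)


def _build_smiles(rng: np.random.Generator, motif: str | None) -> str:
    for _ in range(50):
        smi = _random_scaffold(rng, int(rng.integers(1, 4)))
        if motif is not None:
            smi = smi + motif
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            return Chem.MolToSmiles(mol)
    raise ConfigurationError(f"could not assemble a molecule around {motif!r}")


def generate_compounds(spec: SyntheticSpec) -> CompoundSet:
    """Labeled compound set with planted discriminative substructures."""
    rng = np.random.default_rng(spec.seed)
    compounds: list[LabeledCompound] = []
    for i in range(spec.n_active):
        motif = None
        for alert in spec.planted_alerts:
            if rng.random() < alert.penetrance:
                motif = alert.motif
                break
        compounds.append(
            LabeledCompound(f"ACT{i:04d}", _build_smiles(rng, motif), ACTIVE)
        )
    for i in range(spec.n_inactive):
        motif = None
        for alert in spec.planted_alerts:
            if rng.random() < alert.leak:
                motif = alert.motif
                break
        compounds.append(
            LabeledCompound(f"INA{i:04d}", _build_smiles(rng, motif), INACTIVE)
        )
    return CompoundSet(compounds)


# status-linked profile bits: hepatoprotective-like herbs lean sweet/sour,
# warm, liver/kidney; non-hepatoprotective-like lean cold/bitter/pungent,
# large intestine/spleen (the enrichment directions reported for real herbs)
_HEPATO_PROFILE = ("sweet", "sour", "warm", "liver", "kidney")
_NON_HEPATO_PROFILE = ("cold", "bitter", "pungent", "large intestine", "spleen")

_BASE_MARGINALS = {
    **{t: 0.18 for t in NATURES},
    **{t: 0.15 for t in FLAVORS},
    **{t: 0.12 for t in CHANNELS},
}

_CATEGORIES = (
    "antipyretics",
    "tonifying medicinal",
    "blood-activating stasis-removing drugs",
    "diaphoretics",
    "expectorant antitussive antiasthmetics",
    "qi-regulating drugs",
)


def _draw_terms(rng: np.random.Generator, profile: Sequence[str] | None,
                shift: float) -> frozenset[str]:
    terms = {t for t in _BASE_MARGINALS if rng.random() < _BASE_MARGINALS[t]}
    if profile is not None:
        # force-set each profile bit with probability `shift`, otherwise
        # leave it at its base marginal; shift 0 plants no structure at all
        for t in profile:
            if rng.random() < shift:
                terms.add(t)
    if not any(t in NATURES or t in FLAVORS for t in terms):
        terms.add(("neutral", "sweet")[int(rng.integers(2))])
    if not any(t in CHANNELS for t in terms):
        terms.add(CHANNELS[int(rng.integers(len(CHANNELS)))])
    return frozenset(terms)


def generate_herbs(spec: SyntheticSpec) -> list[HerbRecord]:
    """Reference herbs with planted association rules, plus candidates.

    Reference statuses follow the planted rules: a herb matching a planted
    antecedent is hepatoprotective with that rule's confidence (the most
    specific matching antecedent wins), otherwise with the base rate — so
    each rule's empirical confidence converges to its target as n grows.
    Status-linked profile bits (outside any planted antecedent) separate
    the two populations so the cluster model can recover the verdicts.
    Candidate herbs are appended with undetermined status; the first
    ``n_hepato_like`` draw the hepatoprotective-like profile.
    """
    rng = np.random.default_rng(spec.seed + 1)
    base_rate = spec.planted_rules[0].base_rate if spec.planted_rules else 0.48
    records: list[HerbRecord] = []
    for i in range(spec.n_herbs):
        terms = set(_draw_terms(rng, None, 0.0))
        matching = [r for r in spec.planted_rules if r.antecedent <= terms]
        if matching:
            rule = max(matching, key=lambda r: len(r.antecedent))
            p = rule.confidence
        else:
            p = base_rate
        status = HEPATOPROTECTIVE if rng.random() < p else NON_HEPATOPROTECTIVE
        # profile shift on status-linked bits that sit outside every planted
        # antecedent, preserving the planted confidences exactly
        planted_terms = {t for r in spec.planted_rules for t in r.antecedent}
        profile = (
            _HEPATO_PROFILE if status == HEPATOPROTECTIVE else _NON_HEPATO_PROFILE
        )
        for t in profile:
            if t in planted_terms:
                continue
            if rng.random() < spec.profile_shift:
                terms.add(t)
        if not any(t in CHANNELS for t in terms):
            terms.add(CHANNELS[int(rng.integers(len(CHANNELS)))])
        records.append(
            HerbRecord(
                f"Herb-{i:03d}",
                _CATEGORIES[int(rng.integers(len(_CATEGORIES)))],
                frozenset(terms),
                status,
            )
        )
    for i in range(spec.n_candidates):
        profile = (
            _HEPATO_PROFILE if i < spec.n_hepato_like else _NON_HEPATO_PROFILE
        )
        records.append(
            HerbRecord(
                f"Cand-{i:03d}",
                _CATEGORIES[int(rng.integers(len(_CATEGORIES)))],
                _draw_terms(rng, profile, spec.profile_shift),
                UNDETERMINED,
            )
        )
    return records


def generate_edges(
    spec: SyntheticSpec,
    compounds: CompoundSet,
    herbs: Sequence[HerbRecord],
) -> HerbIngredientEdges:
    """Bipartite edge list with degree-enriched designated candidates.

    The enriched candidates are the first ``n_enriched_hepato_like`` of the
    hepatoprotective-like candidates plus enough non-hepato-like ones to
    reach ``n_enriched``; each receives ``planted_degree`` distinct active
    ingredients.  Background herbs connect to actives at
    ``background_edge_rate`` per (herb, ingredient) pair.
    """
    rng = np.random.default_rng(spec.seed + 2)
    active_ids = [c.id for c in compounds.actives]
    if spec.planted_degree > len(active_ids):
        raise ConfigurationError(
            "planted_degree exceeds the number of active ingredients"
        )
    hepato_like = [h.name for h in herbs if h.name.startswith("Cand-")][
        : spec.n_hepato_like
    ]
    others = [
        h.name for h in herbs
        if h.name.startswith("Cand-") and h.name not in hepato_like
    ]
    enriched = (
        hepato_like[: spec.n_enriched_hepato_like]
        + others[: max(0, spec.n_enriched - spec.n_enriched_hepato_like)]
    )
    edges: set[tuple[str, str]] = set()
    for herb in enriched:
        extra = int(rng.integers(0, 6))
        picks = rng.choice(
            len(active_ids),
            size=min(spec.planted_degree + extra, len(active_ids)),
            replace=False,
        )
        edges.update((herb, active_ids[int(k)]) for k in picks)
    background = [
        h.name for h in herbs
        if h.status == UNDETERMINED and h.name not in set(enriched)
    ]
    for herb in background:
        for ing in active_ids:
            if rng.random() < spec.background_edge_rate:
                edges.add((herb, ing))
    return HerbIngredientEdges(edges)


def enriched_candidate_names(spec: SyntheticSpec, herbs: Sequence[HerbRecord]) -> list[str]:
    """Names of the candidates the edge generator enriches (ground truth)."""
    hepato_like = [h.name for h in herbs if h.name.startswith("Cand-")][
        : spec.n_hepato_like
    ]
    others = [
        h.name for h in herbs
        if h.name.startswith("Cand-") and h.name not in hepato_like
    ]
    return (
        hepato_like[: spec.n_enriched_hepato_like]
        + others[: max(0, spec.n_enriched - spec.n_enriched_hepato_like)]
    )
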