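"""Structural-alert mining by likelihood ratio.

Fragments are generated from the active compounds by recursively breaking
acyclic single bonds (rings are kept intact), deduplicated by canonical
SMILES.  Each fragment is scored as a substructure rule: tp / fp are the
numbers of active / inactive compounds containing it (a compound counts
once regardless of match multiplicity), the likelihood ratio is

    LR = (tp / P) / (fp / N),

with P, N the class totals, +infinity when no inactive matches, and the
precision percentage is 100 * tp / (tp + fp).  Alerts are the rules passing
both a minimum LR and a minimum frequency (tp) threshold, ranked with all
infinite-LR rules first, descending tp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from rdkit import Chem

from .io import ACTIVE, CompoundSet, DataError, parse_smiles

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragment:
    """A canonical substructure pattern with its heavy-atom count."""

    pattern: str  # canonical SMILES, usable as a substructure query
    n_heavy_atoms: int

    def query_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.pattern)
        if mol is None:  # pragma: no cover - canonical SMILES always parse
            raise DataError(f"unparseable fragment pattern {self.pattern!r}")
        return mol


@dataclass(frozen=True)
class SubstructureRule:
    """A scored fragment: occurrence counts, likelihood ratio, precision."""

    fragment: Fragment
    tp: int
    fp: int
    lr: float  # may be math.inf; nan flags an undefined (tp=fp=0) rule
    precision_pct: float
    matched_active_ids: frozenset[str] = field(default=frozenset(), compare=False)


@dataclass(frozen=True)
class MinerConfig:
    min_lr: float = 10.0
    min_freq: int = 10
    min_atoms: int = 2
    max_atoms: int = 18
    extraction_mode: str = "score_all"  # or "iterative_cover"

    def __post_init__(self) -> None:
        if self.min_lr <= 1:
            raise DataError("min_lr must exceed 1")
        if self.min_freq < 1:
            raise DataError("min_freq must be at least 1")
        if self.min_atoms < 2:
            raise DataError("min_atoms must be at least 2")
        if self.extraction_mode not in ("score_all", "iterative_cover"):
            raise DataError(f"unknown extraction mode {self.extraction_mode!r}")


def _acyclic_single_bonds(mol: Chem.Mol) -> list[int]:
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    ]


def _fragment_smiles(mol: Chem.Mol, max_atoms: int, seen: set[str]) -> None:
    """Recursively cut acyclic single bonds, collecting canonical pieces."""
    smi = Chem.MolToSmiles(mol)
    if smi in seen:
        return
    seen.add(smi)
    for bidx in _acyclic_single_bonds(mol):
        pieces = Chem.GetMolFrags(
            Chem.FragmentOnBonds(mol, [bidx], addDummies=False), asMols=True,
            sanitizeFrags=False,
        )
        for piece in pieces:
            try:
                Chem.SanitizeMol(piece)
            except Exception:
                continue
            _fragment_smiles(piece, max_atoms, seen)


def generate_fragments(
    compounds: CompoundSet, config: MinerConfig = MinerConfig()
) -> list[Fragment]:
    """All connected fragments of the active molecules within the size bounds.

    Produced by recursive acyclic-single-bond cutting (no ring opening),
    deduplicated by canonical SMILES; the intact parent molecule itself is a
    fragment when it fits the bounds.
    """
    seen: set[str] = set()
    for c in compounds:
        if c.label != ACTIVE:
            continue
        mol = parse_smiles(c.smiles)
        if mol is None:
            continue
        _fragment_smiles(mol, config.max_atoms, seen)
    frags = []
    for smi in seen:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        n = mol.GetNumHeavyAtoms()
        if config.min_atoms <= n <= config.max_atoms:
            frags.append(Fragment(smi, n))
    return sorted(frags, key=lambda f: (f.n_heavy_atoms, f.pattern))


def _parsed(compounds: CompoundSet) -> list[tuple[str, str, Chem.Mol]]:
    out = []
    for c in compounds:
        mol = parse_smiles(c.smiles)
        if mol is not None:
            out.append((c.id, c.label, mol))
    return out


def _score_parsed(
    fragment: Fragment, parsed: list[tuple[str, str, Chem.Mol]]
) -> SubstructureRule:
    query = fragment.query_mol()
    matched_active: set[str] = set()
    tp = fp = 0
    P = N = 0
    for cid, label, mol in parsed:
        if label == ACTIVE:
            P += 1
        else:
            N += 1
        if mol.HasSubstructMatch(query):
            if label == ACTIVE:
                tp += 1
                matched_active.add(cid)
            else:
                fp += 1
    if P < 1 or N < 1:
        raise DataError("both classes must be non-empty to score fragments")
    if tp == 0 and fp == 0:
        lr = math.nan  # undefined: fragment matches nothing
        precision = 0.0
    elif fp == 0:
        lr = math.inf
        precision = 100.0
    else:
        lr = (tp / P) / (fp / N)
        precision = 100.0 * tp / (tp + fp)
    return SubstructureRule(
        fragment, tp, fp, lr, precision, frozenset(matched_active)
    )


def score_fragment(
    fragment: Fragment, compounds: CompoundSet
) -> SubstructureRule:
    """Count tp/fp by substructure matching and derive LR and precision."""
    return _score_parsed(fragment, _parsed(compounds))


def _rule_sort_key(rule: SubstructureRule):
    # inf LR sorts first; then lr desc, tp desc, fewer atoms, canonical order
    return (
        0 if math.isinf(rule.lr) else 1,
        -rule.tp if math.isinf(rule.lr) else -rule.lr,
        -rule.tp,
        rule.fragment.n_heavy_atoms,
        rule.fragment.pattern,
    )


def _passes(rule: SubstructureRule, config: MinerConfig) -> bool:
    if math.isnan(rule.lr):
        return False
    return rule.tp >= config.min_freq and (
        math.isinf(rule.lr) or rule.lr >= config.min_lr
    )


def mine_alerts(
    compounds: CompoundSet, config: MinerConfig = MinerConfig()
) -> list[SubstructureRule]:
    """Mine representative substructures (structural alerts) for activity.

    In ``score_all`` mode every passing rule is ranked and a redundancy
    filter drops any rule whose matched-active set is a subset of an
    already-accepted rule's.  In ``iterative_cover`` mode, after accepting
    the best rule all actives it matches are removed and scoring repeats
    until nothing passes (the set-cover style of classic alert extractors).
    """
    if len(compounds.actives) == 0 or len(compounds.inactives) == 0:
        raise DataError("both classes must be non-empty")
    fragments = generate_fragments(compounds, config)
    parsed = _parsed(compounds)
    if config.extraction_mode == "score_all":
        rules = [_score_parsed(f, parsed) for f in fragments]
        rules = sorted((r for r in rules if _passes(r, config)), key=_rule_sort_key)
        accepted: list[SubstructureRule] = []
        for rule in rules:
            if any(
                rule.matched_active_ids <= a.matched_active_ids for a in accepted
            ):
                continue
            accepted.append(rule)
    else:
        working = list(parsed)
        accepted = []
        while any(label == ACTIVE for _, label, _ in working):
            candidates = [_score_parsed(f, working) for f in fragments]
            candidates = sorted(
                (r for r in candidates if _passes(r, config)), key=_rule_sort_key
            )
            if not candidates:
                break
            best = candidates[0]
            accepted.append(best)
            working = [
                (cid, label, mol)
                for cid, label, mol in working
                if not (label == ACTIVE and cid in best.matched_active_ids)
            ]
    if not accepted:
        logger.warning("thresholds eliminated every fragment; no alerts mined")
    return accepted
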