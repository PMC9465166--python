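"""Fragment generation, likelihood-ratio scoring and alert extraction."""

import math
from itertools import combinations

import pytest
from rdkit import Chem

import herbscreen as hs
from herbscreen.fragments import _rule_sort_key
from herbscreen.io import DataError


def brute_force_fragments(smiles_list, min_atoms, max_atoms):
    """Oracle: cut every subset of acyclic single bonds at once and collect
    the canonical SMILES of all resulting connected components."""
    out = set()
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        bonds = [
            b.GetIdx() for b in mol.GetBonds()
            if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
        ]
        for r in range(len(bonds) + 1):
            for cut in combinations(bonds, r):
                frag_mol = (
                    Chem.FragmentOnBonds(mol, list(cut), addDummies=False)
                    if cut else mol
                )
                for piece in Chem.GetMolFrags(
                    frag_mol, asMols=True, sanitizeFrags=False
                ):
                    try:
                        Chem.SanitizeMol(piece)
                    except Exception:
                        continue
                    if min_atoms <= piece.GetNumHeavyAtoms() <= max_atoms:
                        out.add(Chem.MolToSmiles(piece))
    return out


class TestGenerateFragments:
    def test_ethylbenzene_manual_enumeration(self):
        cs = hs.CompoundSet([hs.LabeledCompound("e", "c1ccccc1CC", hs.ACTIVE)])
        frags = {
            f.pattern
            for f in hs.generate_fragments(cs, hs.MinerConfig(min_atoms=2, max_atoms=8))
        }
        # two acyclic single-bond cuts: ring|CH2-CH3 and ring-CH2|CH3
        assert frags == {"CC", "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1"}

    def test_methane_below_min_atoms_yields_nothing(self):
        cs = hs.CompoundSet([hs.LabeledCompound("m", "C", hs.ACTIVE)])
        assert hs.generate_fragments(cs, hs.MinerConfig(min_atoms=2)) == []

    def test_duplicate_molecules_dedup_idempotent(self):
        one = hs.CompoundSet([hs.LabeledCompound("a", "CCOc1ccccc1", hs.ACTIVE)])
        two = hs.CompoundSet(
            [
                hs.LabeledCompound("a", "CCOc1ccccc1", hs.ACTIVE),
                hs.LabeledCompound("b", "CCOc1ccccc1", hs.ACTIVE),
            ]
        )
        assert hs.generate_fragments(one) == hs.generate_fragments(two)

    def test_matches_brute_force_enumeration(self):
        smiles = ["CCc1ccccc1O", "CC(C)Cc1ccncc1", "OCCOC1CCCC1"]
        cs = hs.CompoundSet(
            [hs.LabeledCompound(f"c{i}", s, hs.ACTIVE) for i, s in enumerate(smiles)]
        )
        cfg = hs.MinerConfig(min_atoms=2, max_atoms=10)
        got = {f.pattern for f in hs.generate_fragments(cs, cfg)}
        assert got == brute_force_fragments(smiles, 2, 10)


class TestScoreFragment:
    @pytest.mark.parametrize(
        "tp,fp,P,N,lr,precision",
        [
            (45, 0, 536, 171, math.inf, 100.00),  # top-ranked alert regime
            (41, 1, 536, 171, 13.08, 97.62),
            (39, 1, 536, 171, 12.44, 97.50),
            (77, 2, 536, 171, 12.28, 97.47),
            (33, 1, 536, 171, 10.53, 97.06),
            (65, 2, 536, 171, 10.37, 97.01),
            (30, 3, 100, 100, 10.0, 90.91),
        ],
    )
    def test_lr_and_precision_arithmetic(self, tp, fp, P, N, lr, precision):
        """LR and precision reproduce the printed finite-alert arithmetic."""
        # actives/inactives either contain a chlorobenzene marker or not
        hit, miss = "Clc1ccccc1", "CCO"
        comps = (
            [hs.LabeledCompound(f"a{i}", hit if i < tp else miss, hs.ACTIVE)
             for i in range(P)]
            + [hs.LabeledCompound(f"i{i}", hit if i < fp else miss, hs.INACTIVE)
               for i in range(N)]
        )
        rule = hs.score_fragment(
            hs.Fragment("Clc1ccccc1", 7), hs.CompoundSet(comps)
        )
        assert (rule.tp, rule.fp) == (tp, fp)
        if math.isinf(lr):
            assert math.isinf(rule.lr)
        else:
            assert round(rule.lr, 2) == lr
        assert round(rule.precision_pct, 2) == precision

    def test_unmatched_fragment_flagged_undefined(self, tiny_compounds):
        rule = hs.score_fragment(hs.Fragment("FC(F)F", 4), tiny_compounds)
        assert rule.tp == rule.fp == 0 and math.isnan(rule.lr)

    def test_lr_monotonicity(self):
        P = N = 100

        def lr(tp, fp):
            return math.inf if fp == 0 else (tp / P) / (fp / N)

        for tp in range(1, 50, 7):
            for fp in range(1, 20, 3):
                assert lr(tp + 1, fp) >= lr(tp, fp)
                assert lr(tp, fp + 1) <= lr(tp, fp)


def _oracle_mine(compounds, cfg):
    """Straight-line re-derivation of score_all mining from the documented
    rules: brute-force fragments, direct scoring, threshold filter, ranking,
    subset-redundancy filter."""
    frags = brute_force_fragments(
        [c.smiles for c in compounds.actives], cfg.min_atoms, cfg.max_atoms
    )
    scored = []
    for smi in sorted(frags):
        mol = Chem.MolFromSmiles(smi)
        rule = hs.score_fragment(hs.Fragment(smi, mol.GetNumHeavyAtoms()), compounds)
        ok = rule.tp >= cfg.min_freq and (
            math.isinf(rule.lr) or (not math.isnan(rule.lr) and rule.lr >= cfg.min_lr)
        )
        if ok:
            scored.append(rule)
    scored.sort(key=_rule_sort_key)
    accepted = []
    for r in scored:
        if not any(r.matched_active_ids <= a.matched_active_ids for a in accepted):
            accepted.append(r)
    return accepted


class TestMineAlerts:
    def test_score_all_equals_brute_force_oracle(self):
        smiles_act = [
            "CCc1ccccc1O", "CCc1ccccc1N", "OCc1ccccc1O", "CCCc1ccccc1O",
            "COc1ccccc1O", "CC(C)c1ccccc1O", "OCCc1ccccc1O", "CNc1ccccc1O",
        ]
        smiles_ina = ["C1CCCCC1", "CCCCCC", "CC(C)CC", "C1CCOC1"]
        cs = hs.CompoundSet(
            [hs.LabeledCompound(f"a{i}", s, hs.ACTIVE) for i, s in enumerate(smiles_act)]
            + [hs.LabeledCompound(f"i{i}", s, hs.INACTIVE) for i, s in enumerate(smiles_ina)]
        )
        cfg = hs.MinerConfig(min_lr=2.0, min_freq=3, min_atoms=2, max_atoms=10)
        got = [(r.fragment.pattern, r.tp, r.fp) for r in hs.mine_alerts(cs, cfg)]
        want = [(r.fragment.pattern, r.tp, r.fp) for r in _oracle_mine(cs, cfg)]
        assert got == want

    def test_emitted_rules_satisfy_thresholds_and_match_sources(self, small_world):
        _, compounds, _, _ = small_world
        cfg = hs.MinerConfig(min_lr=5.0, min_freq=5)
        rules = hs.mine_alerts(compounds, cfg)
        assert rules, "expected at least one alert in the planted world"
        for r in rules:
            assert r.tp >= cfg.min_freq
            assert math.isinf(r.lr) or r.lr >= cfg.min_lr
            # matching consistency: the fragment matches every recorded active
            query = r.fragment.query_mol()
            by_id = {c.id: c for c in compounds}
            for cid in r.matched_active_ids:
                mol = Chem.MolFromSmiles(by_id[cid].smiles)
                assert mol.HasSubstructMatch(query)

    def test_identical_classes_yield_no_alerts(self):
        smiles = ["CCO", "c1ccccc1C", "CCCN"]
        cs = hs.CompoundSet(
            [hs.LabeledCompound(f"a{i}", s, hs.ACTIVE) for i, s in enumerate(smiles)]
            + [hs.LabeledCompound(f"i{i}", s, hs.INACTIVE) for i, s in enumerate(smiles)]
        )
        assert hs.mine_alerts(cs, hs.MinerConfig(min_lr=10, min_freq=1)) == []

    def test_iterative_cover_removes_covered_actives(self):
        # two disjoint motifs, each covering half the actives
        acts = ["Clc1ccccc1CC", "Clc1ccccc1CCC", "OC1CCCC1CC", "OC1CCCC1CCC"]
        cs = hs.CompoundSet(
            [hs.LabeledCompound(f"a{i}", s, hs.ACTIVE) for i, s in enumerate(acts)]
            + [hs.LabeledCompound("i0", "CCCCCC", hs.INACTIVE)]
        )
        cfg = hs.MinerConfig(
            min_lr=2, min_freq=2, min_atoms=5, max_atoms=9,
            extraction_mode="iterative_cover",
        )
        rules = hs.mine_alerts(cs, cfg)
        covered = set()
        for r in rules:
            assert not (r.matched_active_ids & covered)
            covered |= r.matched_active_ids
        assert covered == {"a0", "a1", "a2", "a3"}

    def test_empty_class_is_error(self):
        cs = hs.CompoundSet([hs.LabeledCompound("a", "CCO", hs.ACTIVE)])
        with pytest.raises(DataError):
            hs.mine_alerts(cs)
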