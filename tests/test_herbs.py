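"""Property encoding, contrasts, association rules, cluster classification."""

from itertools import combinations

import numpy as np
import pytest

import herbscreen as hs
from herbscreen.io import DataError
from herbscreen.vocab import PROPERTY_TERMS, TERM_INDEX


def _herb(name, terms, status=hs.HEPATOPROTECTIVE, cat="antipyretics"):
    return hs.HerbRecord(name, cat, frozenset(terms), status)


class TestEncodeProperties:
    def test_worked_chuan_xiong_encoding(self):
        rec = _herb(
            "Chuan Xiong",
            {"warm", "pungent", "liver", "gall bladder", "pericardium"},
        )
        bits = hs.encode_properties(rec)
        on = {PROPERTY_TERMS[i] for i in np.flatnonzero(bits)}
        assert on == rec.properties and bits.sum() == 5

    def test_empty_and_full_vectors(self):
        assert hs.encode_properties(_herb("x", set())).sum() == 0
        assert hs.encode_properties(_herb("y", set(PROPERTY_TERMS))).sum() == 24

    def test_fixed_term_order(self):
        bits = hs.encode_properties(_herb("z", {"cold", "pungent", "liver"}))
        assert [int(b) for b in bits[[0, 5, 12]]] == [1, 1, 1]


class TestFrequencySummary:
    def test_category_counts(self):
        herbs = [
            _herb("a", {"cold", "liver"}, cat="antipyretics"),
            _herb("b", {"warm", "liver"}, cat="antipyretics"),
            _herb("c", {"warm", "lung"}, cat="diaphoretics",
                  status=hs.NON_HEPATOPROTECTIVE),
        ]
        df = hs.frequency_summary(herbs)
        assert df.loc["antipyretics", hs.HEPATOPROTECTIVE] == 2
        assert df.loc["diaphoretics", hs.NON_HEPATOPROTECTIVE] == 1

    def test_property_grouping_and_overlap(self):
        herbs = [_herb("a", {"sweet", "liver"}), _herb("b", {"sweet", "lung"})]
        df = hs.frequency_summary(herbs, group_by="property")
        assert df.loc["sweet", hs.HEPATOPROTECTIVE] == 2
        assert hs.herbs.overlap_report(["a", "b", "c"], ["b", "c", "d"]) == {"b", "c"}


class TestChiSquared:
    def test_hand_computed_two_by_two(self):
        """50 all-sweet vs 50 never-sweet: chi2 = 100 plain, 96.04 Yates."""
        A = np.zeros((50, 24), int)
        A[:, TERM_INDEX["sweet"]] = 1
        B = np.zeros((50, 24), int)
        B[:, TERM_INDEX["bitter"]] = 1
        plain = hs.chi_squared_contrast(A, B, mode="per_feature", correction=False)
        yates = hs.chi_squared_contrast(A, B, mode="per_feature", correction=True)
        sweet_plain = next(r for r in plain if r.term == "sweet")
        sweet_yates = next(r for r in yates if r.term == "sweet")
        assert sweet_plain.statistic == pytest.approx(100.0)
        assert sweet_yates.statistic == pytest.approx(96.04)
        assert sweet_yates.p < 1e-20
        assert sweet_plain.p_adjusted is not None

    def test_identical_groups_omnibus_zero(self):
        A = np.zeros((30, 24), int)
        A[:, :3] = 1
        res = hs.chi_squared_contrast(A, A.copy(), mode="omnibus")
        assert res.statistic == 0.0 and res.p == 1.0

    def test_proportional_profiles_are_null(self):
        A = np.zeros((20, 24), int)
        A[:, 0] = 1
        A[:10, 1] = 1
        B = np.vstack([A, A])  # same profile, double the size
        res = hs.chi_squared_contrast(A, B, mode="omnibus")
        assert res.statistic == 0.0

    def test_null_omnibus_controls_type_one_error(self):
        """Groups drawn from one distribution: the omnibus test on the
        possession-count table never piles p-values near 0 (it is in fact
        conservative, since possession counts are not multinomial)."""
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(60):
            A = (rng.random((120, 24)) < 0.3).astype(int)
            B = (rng.random((120, 24)) < 0.3).astype(int)
            ps.append(hs.chi_squared_contrast(A, B, mode="omnibus").p)
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.05
        assert np.median(ps) > 0.2


def brute_force_rules(herbs, min_support, min_confidence, min_lift, max_ante):
    """Oracle: enumerate every antecedent subset with direct counting."""
    det = [h for h in herbs if h.status in (hs.HEPATOPROTECTIVE, hs.NON_HEPATOPROTECTIVE)]
    n = len(det)
    prior = sum(h.status == hs.HEPATOPROTECTIVE for h in det) / n
    items = sorted({t for h in det for t in h.properties})
    out = set()
    for k in range(1, max_ante + 1):
        for ante in combinations(items, k):
            aset = frozenset(ante)
            n_ante = sum(aset <= h.properties for h in det)
            n_joint = sum(
                aset <= h.properties and h.status == hs.HEPATOPROTECTIVE for h in det
            )
            if n_ante == 0 or n_joint / n < min_support:
                continue
            conf = n_joint / n_ante
            if conf >= min_confidence and conf / prior > min_lift:
                out.add((aset, round(n_joint / n, 10), round(conf, 10)))
    return out


class TestAssociationRules:
    def test_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        terms = ["cold", "warm", "sweet", "sour", "liver", "kidney"]
        herbs = []
        for i in range(12):
            sub = {t for t in terms if rng.random() < 0.5} or {"sweet"}
            status = hs.HEPATOPROTECTIVE if rng.random() < 0.5 else hs.NON_HEPATOPROTECTIVE
            herbs.append(_herb(f"h{i}", sub, status))
        got = {
            (r.antecedent, round(r.support, 10), round(r.confidence, 10))
            for r in hs.mine_association_rules(
                herbs, min_support=0.1, min_confidence=0.5, min_lift=0.0,
                max_antecedent=3,
            )
        }
        assert got == brute_force_rules(herbs, 0.1, 0.5, 0.0, 3)

    def test_printed_lift_regime(self):
        """confidence 71.43% against a 123/255 prior gives lift 1.48."""
        herbs = []
        # 21 sour herbs, 15 hepatoprotective; remaining herbs make the prior
        for i in range(21):
            herbs.append(_herb(f"s{i}", {"sour", "liver"},
                               hs.HEPATOPROTECTIVE if i < 15 else hs.NON_HEPATOPROTECTIVE))
        for i in range(234):
            herbs.append(_herb(f"o{i}", {"tasteless", "lung"},
                               hs.HEPATOPROTECTIVE if i < 108 else hs.NON_HEPATOPROTECTIVE))
        rules = hs.mine_association_rules(herbs, min_support=0.05,
                                          min_confidence=0.65, min_lift=1.0)
        sour = next(r for r in rules if r.antecedent == frozenset({"sour"}))
        assert round(100 * sour.support, 2) == 5.88
        assert round(100 * sour.confidence, 2) == 71.43
        assert round(sour.lift, 2) == 1.48

    def test_measure_identities(self, small_world):
        _, _, herbs, _ = small_world
        rules = hs.mine_association_rules(herbs, min_support=0.05,
                                          min_confidence=0.5)
        det = [h for h in herbs if h.status != hs.UNDETERMINED]
        prior = sum(h.status == hs.HEPATOPROTECTIVE for h in det) / len(det)
        assert rules
        for r in rules:
            assert 0 < r.support <= r.confidence <= 1
            assert r.lift * prior == pytest.approx(r.confidence)
            n_joint = r.support * len(det)
            assert n_joint / r.confidence == pytest.approx(round(n_joint / r.confidence))

    def test_independent_antecedents_have_unit_lift(self):
        """No planted structure: every mined lift concentrates near 1."""
        spec = hs.SyntheticSpec(
            seed=5, n_herbs=2000, planted_rules=(), profile_shift=0.0,
            n_candidates=0, n_hepato_like=0, n_enriched=0,
            n_enriched_hepato_like=0,
        )
        herbs = hs.generate_herbs(spec)
        rules = hs.mine_association_rules(
            herbs, min_support=0.05, min_confidence=0.01, min_lift=0.0,
            max_antecedent=2,
        )
        lifts = np.array([r.lift for r in rules])
        assert len(lifts) > 10
        assert abs(np.median(lifts) - 1.0) < 0.05
        assert np.all(np.abs(lifts - 1.0) < 0.25)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(Exception):
            hs.mine_association_rules([_herb("a", {"sweet"})], min_support=1.5)


class TestMatchRules:
    TABLE_RULES = [
        hs.AssociationRule(frozenset({"sweet", "kidney"}), 0.1059, 0.6923, 1.44),
        hs.AssociationRule(frozenset({"sweet", "warm"}), 0.0667, 0.7391, 1.53),
        hs.AssociationRule(frozenset({"sour"}), 0.0588, 0.7143, 1.48),
        hs.AssociationRule(frozenset({"sweet", "liver", "kidney"}), 0.0549, 0.6667, 1.38),
        hs.AssociationRule(frozenset({"sweet", "stomach"}), 0.0667, 0.6538, 1.36),
    ]

    def test_subset_matching(self):
        herb = _herb("x", {"sweet", "kidney", "liver", "warm"})
        assert hs.match_rules_to_herb(herb, self.TABLE_RULES) == [1, 2, 4]

    def test_no_sweet_or_sour_matches_nothing(self):
        herb = _herb("y", {"bitter", "cold", "lung"})
        assert hs.match_rules_to_herb(herb, self.TABLE_RULES) == []

    def test_three_rule_herb(self):
        # a berry-like astringent herb hitting rules 1, 2 and 5
        herb = _herb("Fu Pen Zi", {"sweet", "sour_", "kidney", "warm", "stomach"} - {"sour_"})
        assert len(hs.match_rules_to_herb(herb, self.TABLE_RULES)) == 3


class TestClusterClassify:
    def _two_blob_refs(self, rng, n_each=100, sep=0.85):
        refs = []
        for i in range(n_each):
            refs.append(_herb(
                f"P{i}",
                {t for t in ("sweet", "sour", "warm", "liver", "kidney")
                 if rng.random() < sep} | {"lung"},
                hs.HEPATOPROTECTIVE,
            ))
            refs.append(_herb(
                f"T{i}",
                {t for t in ("cold", "bitter", "pungent", "spleen", "large intestine")
                 if rng.random() < sep} | {"lung"},
                hs.NON_HEPATOPROTECTIVE,
            ))
        return refs

    def test_identical_candidate_follows_its_reference(self):
        rng = np.random.default_rng(2)
        refs = self._two_blob_refs(rng, 30)
        cand = _herb("u", refs[0].properties, hs.UNDETERMINED)
        (a,) = hs.cluster_classify(refs, [cand])
        assert a.verdict == hs.herbs.HEPATO_LIKE
        assert a.branch_composition[hs.HEPATOPROTECTIVE] > 0

    def test_planted_two_population_recovery(self):
        rng = np.random.default_rng(3)
        refs = self._two_blob_refs(rng, 100)
        cands = [
            _herb(f"u{i}",
                  {t for t in ("sweet", "sour", "warm", "liver", "kidney")
                   if rng.random() < 0.85} | {"lung"},
                  hs.UNDETERMINED)
            for i in range(20)
        ]
        out = hs.cluster_classify(refs, cands)
        n_like = sum(a.verdict == hs.herbs.HEPATO_LIKE for a in out)
        assert n_like >= 18

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        refs = self._two_blob_refs(rng, 20)
        cands = [_herb(f"u{i}", refs[2 * i].properties, hs.UNDETERMINED)
                 for i in range(5)]
        fwd = {a.name: a.verdict for a in hs.cluster_classify(refs, cands)}
        rev = {a.name: a.verdict
               for a in hs.cluster_classify(refs[::-1], cands[::-1])}
        assert fwd == rev

    def test_name_clash_is_error(self):
        refs = self._two_blob_refs(np.random.default_rng(5), 10)
        with pytest.raises(DataError):
            hs.cluster_classify(refs, [_herb("P0", {"sweet", "liver"},
                                             hs.UNDETERMINED)])
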