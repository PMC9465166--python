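"""Molecular descriptor matrices and two-stage feature selection.

Descriptor computation is a pluggable provider contract: any callable object
that maps one parsed molecule to a fixed-length numeric vector with stable
feature names qualifies.  Two providers ship with the package — a toy
2-descriptor provider for tests/examples and an RDKit 2D-descriptor provider
(~210 physicochemical/topological descriptors) as the realistic default.

Selection is two-stage: a shadow-feature relevance selector (each round,
permuted copies of all features are appended, a tree ensemble is fitted,
and real features are confirmed or rejected by a binomial test on how often
they beat the best shadow importance), followed by Pearson-correlation
pruning at |r| <= r_max keeping the higher-relevance member of each
correlated pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from .io import CompoundSet, DataError, RejectedRow, parse_smiles


class DescriptorProvider(Protocol):
    """Contract: stable feature names + one numeric vector per molecule."""

    @property
    def feature_names(self) -> list[str]: ...

    def __call__(self, mol: Chem.Mol) -> np.ndarray: ...


class ToyProvider:
    """Two descriptors (heavy-atom and aromatic-atom counts); for tests."""

    feature_names = ["n_atoms", "n_aromatic_atoms"]

    def __call__(self, mol: Chem.Mol) -> np.ndarray:
        return np.array(
            [mol.GetNumHeavyAtoms(),
             sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())],
            dtype=float,
        )


class RDKit2DProvider:
    """All RDKit 2D molecular descriptors (MolWt, TPSA, connectivity indices...)."""

    def __init__(self) -> None:
        self._descs = [(name, fn) for name, fn in Descriptors.descList]

    @property
    def feature_names(self) -> list[str]:
        return [name for name, _ in self._descs]

    def __call__(self, mol: Chem.Mol) -> np.ndarray:
        out = np.empty(len(self._descs))
        for i, (_, fn) in enumerate(self._descs):
            try:
                out[i] = float(fn(mol))
            except Exception:
                out[i] = np.nan
        return out


@dataclass
class DescriptorMatrix:
    """Numeric matrix (compounds x features) with aligned ids and names."""

    values: pd.DataFrame  # index = compound ids, columns = feature names
    zero_variance: list[str] = field(default_factory=list)
    imputed: dict[str, int] = field(default_factory=dict)  # feature -> n imputed

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class FeatureMask:
    """Ordered kept-feature subset plus a per-feature decision record."""

    kept: list[str]
    provenance: dict[str, str]
    importances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in self.kept if f not in self.provenance]
        if missing:
            raise ValueError(f"provenance missing for kept features {missing}")


def compute_descriptors(
    compounds: CompoundSet, provider: DescriptorProvider
) -> DescriptorMatrix:
    """Descriptor matrix for a compound set; rows align with compound order.

    Compounds the provider fails on entirely are moved to the set's rejects.
    Sporadic missing values are imputed by the feature median (logged in the
    matrix metadata); zero-variance columns are flagged, not dropped.
    """
    names = provider.feature_names
    rows, ids, keep = [], [], []
    for c in compounds:
        mol = parse_smiles(c.smiles)
        if mol is None:
            compounds.rejects.append(RejectedRow(c.id, c.smiles, "unparseable structure"))
            continue
        try:
            vec = np.asarray(provider(mol), dtype=float)
        except Exception as exc:  # provider failure -> reject with reason
            compounds.rejects.append(RejectedRow(c.id, c.smiles, f"descriptor failure: {exc}"))
            continue
        if np.isnan(vec).all():
            compounds.rejects.append(RejectedRow(c.id, c.smiles, "all descriptors missing"))
            continue
        rows.append(vec)
        ids.append(c.id)
        keep.append(c)
    compounds.compounds = keep
    df = pd.DataFrame(np.vstack(rows), index=ids, columns=names)
    imputed = {}
    for col in df.columns[df.isna().any()]:
        n = int(df[col].isna().sum())
        df[col] = df[col].fillna(df[col].median())
        imputed[col] = n
    zero_var = [c for c in df.columns if df[c].nunique() <= 1]
    return DescriptorMatrix(df, zero_variance=zero_var, imputed=imputed)


def _binary_y(y) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise DataError("labels must be binary with both classes present")
    return y


def select_relevant(
    X: DescriptorMatrix | pd.DataFrame,
    y,
    alpha: float = 0.05,
    max_iter: int = 100,
    seed: int = 0,
    n_estimators: int = 500,
) -> FeatureMask:
    """Shadow-feature relevance selection (Boruta-style).

    Each iteration appends a permuted (shadow) copy of every feature, fits a
    random-forest importance, and scores a "hit" for each real feature whose
    importance beats the best shadow importance.  After each round, a
    two-sided binomial test on the hit count at p=0.5 confirms features that
    win significantly more often than chance and rejects those that lose
    significantly; features still tentative at ``max_iter`` are resolved by
    comparing their median importance to the median best-shadow importance.
    """
    df = X.values if isinstance(X, DescriptorMatrix) else X
    if df.shape[1] < 1:
        raise DataError("need at least one feature")
    y = _binary_y(y)
    rng = np.random.default_rng(seed)
    names = list(df.columns)
    p = len(names)
    hits = np.zeros(p, dtype=int)
    status = {f: "tentative" for f in names}
    history: list[np.ndarray] = []
    shadow_history: list[float] = []
    Xv = df.to_numpy(dtype=float)

    n_done = 0
    for it in range(max_iter):
        shadow = Xv.copy()
        for jcol in range(p):
            rng.shuffle(shadow[:, jcol])
        # max_features=None: every split sees every feature, so truly
        # relevant features shadow out chance-correlated noise columns
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=7,
            max_features=None,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(np.hstack([Xv, shadow]), y)
        imp = rf.feature_importances_
        real, sh = imp[:p], imp[p:]
        best_shadow = float(sh.max())
        hits += (real > best_shadow).astype(int)
        history.append(real)
        shadow_history.append(best_shadow)
        n_done = it + 1
        if n_done >= 5:  # need a few rounds before the binomial test has power
            for j, f in enumerate(names):
                if status[f] != "tentative":
                    continue
                pval = binomtest(int(hits[j]), n_done, 0.5).pvalue
                # Bonferroni-corrected confirmation guards against noise
                # features that beat the shadows by a fixed chance correlation
                if hits[j] > n_done / 2 and pval < alpha / p:
                    status[f] = "kept-by-relevance"
                elif hits[j] < n_done / 2 and pval < alpha:
                    status[f] = "dropped-shadow"
            if all(s != "tentative" for s in status.values()):
                break

    med_shadow = float(np.median(shadow_history))
    med_imp = np.median(np.vstack(history), axis=0)
    for j, f in enumerate(names):
        if status[f] == "tentative":
            status[f] = (
                "kept-by-relevance" if med_imp[j] > med_shadow else "dropped-shadow"
            )
    kept = [f for f in names if status[f] == "kept-by-relevance"]
    importances = {f: float(med_imp[j]) for j, f in enumerate(names)}
    return FeatureMask(kept, provenance=dict(status), importances=importances)


def prune_correlated(
    X: DescriptorMatrix | pd.DataFrame,
    mask: FeatureMask,
    r_max: float = 0.90,
) -> FeatureMask:
    """Drop one member of every feature pair with |Pearson r| > r_max.

    The lower-relevance member (by the selector's importances; ties by name
    order) is dropped.  Zero-variance features, for which r is undefined,
    are dropped first.  The returned set has all pairwise |r| <= r_max.
    """
    df = X.values if isinstance(X, DescriptorMatrix) else X
    if not mask.kept:
        raise DataError("feature mask is empty")
    provenance = dict(mask.provenance)
    features = [f for f in mask.kept]
    sub = df[features]
    usable = []
    for f in features:
        if sub[f].std() == 0:
            provenance[f] = "dropped-zero-variance"
        else:
            usable.append(f)
    corr = df[usable].corr().abs()
    # rank by descending importance, ties by name: higher-ranked kept first
    order = sorted(usable, key=lambda f: (-mask.importances.get(f, 0.0), f))
    kept: list[str] = []
    for f in order:
        clash = next((g for g in kept if corr.loc[f, g] > r_max), None)
        if clash is None:
            kept.append(f)
        else:
            provenance[f] = f"dropped-correlated-with {clash}"
    kept_in_order = [f for f in features if f in set(kept)]
    return FeatureMask(kept_in_order, provenance, importances=dict(mask.importances))
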