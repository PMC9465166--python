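"""Domain types and delimited-text readers/writers.

Three kinds of input drive the pipeline:

* a labeled compound table (``id,smiles,label``) — the molecule-level unit
  of analysis for the structure-activity model and the alert miner;
* a herb table (``name,category,natures,flavors,channels,status``) with
  ``|``-separated multi-valued cells — the herb-level unit carrying
  drug-property terms;
* a herb-ingredient edge list (``herb,ingredient``) — the bipartite
  material-basis network.

Structure-parsing failures and malformed rows are collected into a rejects
list, never silently dropped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .vocab import CHANNELS, normalize_term

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"

_LABEL_ALIASES = {
    "active": ACTIVE,
    "1": ACTIVE,
    "positive": ACTIVE,
    "hepatoprotective": ACTIVE,
    "inactive": INACTIVE,
    "0": INACTIVE,
    "negative": INACTIVE,
    "non-hepatoprotective": INACTIVE,
}

HEPATOPROTECTIVE = "hepatoprotective"
NON_HEPATOPROTECTIVE = "non-hepatoprotective"
UNDETERMINED = "undetermined"

_STATUS_ALIASES = {
    "hepatoprotective": HEPATOPROTECTIVE,
    "non-hepatoprotective": NON_HEPATOPROTECTIVE,
    "nonhepatoprotective": NON_HEPATOPROTECTIVE,
    "undetermined": UNDETERMINED,
    "unknown": UNDETERMINED,
}


class ConfigurationError(ValueError):
    """Raised when inputs violate a structural contract (missing columns...)."""


class DataError(ValueError):
    """Raised when input data are semantically invalid."""


@dataclass(frozen=True)
class LabeledCompound:
    """A compound with a SMILES structure and a binary activity label."""

    id: str
    smiles: str
    label: str  # ACTIVE or INACTIVE

    def __post_init__(self) -> None:
        if self.label not in (ACTIVE, INACTIVE):
            raise DataError(f"label must be active/inactive, got {self.label!r}")


@dataclass(frozen=True)
class RejectedRow:
    id: str
    smiles: str
    reason: str


@dataclass
class CompoundSet:
    """Ordered collection of labeled compounds plus the rows rejected on read."""

    compounds: list[LabeledCompound]
    rejects: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    @property
    def n_active(self) -> int:
        return sum(1 for c in self.compounds if c.label == ACTIVE)

    @property
    def n_inactive(self) -> int:
        return sum(1 for c in self.compounds if c.label == INACTIVE)

    @property
    def actives(self) -> list[LabeledCompound]:
        return [c for c in self.compounds if c.label == ACTIVE]

    @property
    def inactives(self) -> list[LabeledCompound]:
        return [c for c in self.compounds if c.label == INACTIVE]


@dataclass(frozen=True)
class HerbRecord:
    """A named herbal drug with efficacy category and drug-property terms.

    ``properties`` holds normalized terms from the 24-term vocabulary.
    A record without any channel-tropism term is retained but flagged not
    clusterable (the cluster model needs the full 24-bit encoding to be
    meaningful).
    """

    name: str
    efficacy_category: str
    properties: frozenset[str]
    status: str  # HEPATOPROTECTIVE / NON_HEPATOPROTECTIVE / UNDETERMINED

    @property
    def clusterable(self) -> bool:
        return any(t in CHANNELS for t in self.properties)


@dataclass
class HerbIngredientEdges:
    """Deduplicated set of (herb name, ingredient id) pairs."""

    edges: set[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.edges)


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _read_rows(path: str | Path, delimiter: str | None) -> list[dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    text = path.read_text()
    if not text.strip():
        raise DataError(f"empty input file: {path}")
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    return [row for row in reader]


def parse_smiles(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES string; None when the structure is unrecognizable."""
    if not smiles or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles.strip())


def read_compound_table(
    path: str | Path, delimiter: str | None = None
) -> CompoundSet:
    """Read a labeled compound table (columns ``id,smiles,label``).

    Rows with unparseable structures or labels outside {active, inactive}
    are routed to the rejects list with a reason.
    """
    rows = _read_rows(path, delimiter)
    required = {"id", "smiles", "label"}
    if not rows or not required.issubset(rows[0].keys()):
        raise ConfigurationError(
            f"compound table must have columns {sorted(required)}"
        )
    compounds: list[LabeledCompound] = []
    rejects: list[RejectedRow] = []
    for row in rows:
        cid = row["id"].strip()
        smiles = row["smiles"].strip()
        raw_label = row["label"].strip().lower()
        label = _LABEL_ALIASES.get(raw_label)
        if label is None:
            rejects.append(RejectedRow(cid, smiles, f"unknown label {row['label']!r}"))
            continue
        if parse_smiles(smiles) is None:
            rejects.append(RejectedRow(cid, smiles, "unparseable structure"))
            continue
        compounds.append(LabeledCompound(cid, smiles, label))
    cs = CompoundSet(compounds, rejects)
    logger.info(
        "read %d compounds (%d active, %d inactive), %d rejected",
        len(cs), cs.n_active, cs.n_inactive, len(rejects),
    )
    return cs


def write_compound_table(cs: CompoundSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "label"])
        for c in cs.compounds:
            w.writerow([c.id, c.smiles, c.label])


def _split_cell(cell: str) -> list[str]:
    return [t for t in (s.strip() for s in cell.split("|")) if t]


def read_herb_table(path: str | Path, delimiter: str | None = None) -> list[HerbRecord]:
    """Read a herb table (``name,category,natures,flavors,channels,status``).

    Property terms are normalized against the 24-term vocabulary; an unknown
    term is a data error naming the term and the row.  Duplicate herb names
    are an error.  Herbs without channel information are retained, flagged
    not clusterable via :attr:`HerbRecord.clusterable`.
    """
    rows = _read_rows(path, delimiter)
    required = {"name", "category", "natures", "flavors", "channels", "status"}
    if not rows or not required.issubset(rows[0].keys()):
        raise ConfigurationError(f"herb table must have columns {sorted(required)}")
    records: list[HerbRecord] = []
    seen: dict[str, int] = {}
    dupes: list[str] = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        name = row["name"].strip()
        if name in seen:
            dupes.append(name)
            continue
        seen[name] = i
        terms: set[str] = set()
        for col in ("natures", "flavors", "channels"):
            for raw in _split_cell(row[col]):
                try:
                    terms.add(normalize_term(raw))
                except ValueError as exc:
                    raise DataError(f"row {i} ({name}): {exc}") from None
        status = _STATUS_ALIASES.get(row["status"].strip().lower())
        if status is None:
            raise DataError(f"row {i} ({name}): unknown status {row['status']!r}")
        rec = HerbRecord(name, row["category"].strip(), frozenset(terms), status)
        if not rec.clusterable:
            logger.info("herb %s lacks channel tropism; flagged not clusterable", name)
        records.append(rec)
    if dupes:
        raise DataError(f"duplicate herb names: {sorted(set(dupes))}")
    return records


def write_herb_table(records: Sequence[HerbRecord], path: str | Path) -> None:
    from .vocab import FLAVORS, NATURES

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "category", "natures", "flavors", "channels", "status"])
        for r in records:
            w.writerow([
                r.name,
                r.efficacy_category,
                "|".join(t for t in NATURES if t in r.properties),
                "|".join(t for t in FLAVORS if t in r.properties),
                "|".join(t for t in CHANNELS if t in r.properties),
                r.status,
            ])


def read_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    ingredient_registry: Iterable[str] | None = None,
) -> HerbIngredientEdges:
    """Read a herb-ingredient edge list (columns ``herb,ingredient``).

    Duplicate pairs are collapsed.  When an ingredient registry is supplied,
    unresolvable ingredient ids are a data error.
    """
    rows = _read_rows(path, delimiter)
    required = {"herb", "ingredient"}
    if not rows or not required.issubset(rows[0].keys()):
        raise ConfigurationError(f"edge list must have columns {sorted(required)}")
    edges = {(r["herb"].strip(), r["ingredient"].strip()) for r in rows}
    if ingredient_registry is not None:
        registry = set(ingredient_registry)
        unknown = sorted({i for _, i in edges if i not in registry})
        if unknown:
            raise DataError(f"unresolvable ingredient ids: {unknown[:10]}")
    return HerbIngredientEdges(edges)


def write_edge_list(edges: HerbIngredientEdges, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["herb", "ingredient"])
        for herb, ing in sorted(edges.edges):
            w.writerow([herb, ing])
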