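"""Typed readers, writers and aggregation for specimen tables, species tables
and phylogenies.

The observational unit of the downstream regressions is usually the species
average (arithmetic means of the raw, not log-transformed, measurements), but
specimen-level records are kept first-class because individual-level fits and
the body-condition ranking both operate on them.

Units are fixed throughout the package: lengths (OCW, CBL, HBL) in millimetres,
masses in grams.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Morphotype",
    "SpecimenRecord",
    "SpeciesRecord",
    "RowIssue",
    "ReadResult",
    "SchemaError",
    "NotRankableError",
    "TreeFormatError",
    "DEFAULT_SCHEMA",
    "read_specimen_table",
    "specimens_from_frame",
    "specimens_to_frame",
    "aggregate_species",
    "species_to_frame",
    "rank_specimens_by_condition",
    "read_tree",
    "write_tree",
    "normalize_taxon",
    "match_species_to_tips",
]


class Morphotype(str, enum.Enum):
    """Discrete occiput configuration.

    Most mammals share a generalized condition (reniform condyles hugging the
    foramen magnum). Lagomorph-like (narrow, pulley-shaped) and monotreme-like
    (wide, laterally divergent) occiputs shift the intercept of the OCW-mass
    relationship; cingulate-like and other apomorphic states are flagged so
    they can be excluded explicitly, never dropped silently.
    """

    GENERALIZED = "generalized"
    RABBIT_LIKE = "rabbit_like"
    MONOTREME_LIKE = "monotreme_like"
    CINGULATE_LIKE = "cingulate_like"
    OTHER_APOMORPHIC = "other_apomorphic"


class SchemaError(ValueError):
    """A required column could not be resolved in an input table."""


class NotRankableError(ValueError):
    """Too few complete specimens to build an intraspecific condition index."""


class TreeFormatError(ValueError):
    """Tree file could not be parsed, or lacks required branch lengths."""


@dataclass
class SpecimenRecord:
    """One measured individual."""

    specimen_id: str
    species: str
    ocw: float  # mm, > 0
    body_mass: float  # g, > 0
    order: str = ""
    suborder: str = ""
    family: str = ""
    sex: str = "unknown"  # male / female / unknown
    captive: str = "unknown"  # wild / captive / unknown
    morphotype: Morphotype = Morphotype.GENERALIZED
    hbl: float | None = None  # mm
    cbl: float | None = None  # mm

    def __post_init__(self) -> None:
        if not self.ocw > 0:
            raise ValueError(f"ocw must be > 0, got {self.ocw}")
        if not self.body_mass > 0:
            raise ValueError(f"body_mass must be > 0, got {self.body_mass}")
        if self.hbl is not None and not np.isnan(self.hbl) and self.ocw >= self.hbl:
            raise ValueError(
                f"ocw ({self.ocw} mm) must be smaller than hbl ({self.hbl} mm)"
            )


@dataclass
class SpeciesRecord:
    """Per-species aggregate used as the regression observation unit."""

    species: str
    n_specimens: int
    mean_ocw: float
    mean_body_mass: float
    order: str = ""
    suborder: str = ""
    family: str = ""
    mean_hbl: float | None = None
    mean_cbl: float | None = None
    brain_mass: float | None = None
    morphotype: Morphotype = Morphotype.GENERALIZED
    fraction_captive: float = 0.0
    sex: str | None = None  # set in by-sex aggregation mode


@dataclass
class RowIssue:
    row: int
    reason: str


@dataclass
class ReadResult:
    records: list[SpecimenRecord]
    rejected: list[RowIssue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


#: Default column mapping; keys are canonical names, values the CSV headers.
DEFAULT_SCHEMA: dict[str, str] = {
    "specimen_id": "specimen_id",
    "species": "species",
    "order": "order",
    "suborder": "suborder",
    "family": "family",
    "ocw": "ocw",
    "body_mass": "body_mass",
    "sex": "sex",
    "captive": "captive",
    "morphotype": "morphotype",
    "hbl": "hbl",
    "cbl": "cbl",
}

_REQUIRED = ("species", "ocw", "body_mass")


def _parse_enumish(value, choices: Sequence[str], default: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return default
    text = str(value).strip().lower()
    if text in ("", "nan", "na", "unknown", "?"):
        return default
    if text in choices:
        return text
    return default


def _parse_morphotype(value) -> Morphotype:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return Morphotype.GENERALIZED
    text = str(value).strip().lower().replace("-", "_").replace(" ", "_")
    if text in ("", "nan", "na"):
        return Morphotype.GENERALIZED
    try:
        return Morphotype(text)
    except ValueError:
        return Morphotype.OTHER_APOMORPHIC


def _opt_float(value) -> float | None:
    if value is None:
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(x) else x


def specimens_from_frame(
    frame: pd.DataFrame, schema: Mapping[str, str] | None = None
) -> ReadResult:
    """Convert a raw table into validated :class:`SpecimenRecord` objects.

    Every row either becomes a record or is logged (and returned) with the
    offending row number and reason; nothing is dropped silently.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    missing = [k for k in _REQUIRED if schema[k] not in frame.columns]
    if missing:
        raise SchemaError(
            f"required columns not resolvable: {[schema[k] for k in missing]} "
            f"(available: {list(frame.columns)})"
        )

    def col(row, key, default=None):
        name = schema.get(key)
        if name is not None and name in frame.columns:
            return row[name]
        return default

    records: list[SpecimenRecord] = []
    rejected: list[RowIssue] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            ocw = float(col(row, "ocw"))
            mass = float(col(row, "body_mass"))
        except (TypeError, ValueError):
            rejected.append(RowIssue(i, "non-numeric ocw or body_mass"))
            continue
        try:
            rec = SpecimenRecord(
                specimen_id=str(col(row, "specimen_id", f"row{i}")),
                species=str(col(row, "species")).strip(),
                ocw=ocw,
                body_mass=mass,
                order=str(col(row, "order", "") or ""),
                suborder=str(col(row, "suborder", "") or ""),
                family=str(col(row, "family", "") or ""),
                sex=_parse_enumish(col(row, "sex"), ("male", "female"), "unknown"),
                captive=_parse_enumish(col(row, "captive"), ("wild", "captive"), "unknown"),
                morphotype=_parse_morphotype(col(row, "morphotype")),
                hbl=_opt_float(col(row, "hbl")),
                cbl=_opt_float(col(row, "cbl")),
            )
        except ValueError as exc:
            rejected.append(RowIssue(i, str(exc)))
            continue
        records.append(rec)
    for issue in rejected:
        logger.warning("rejected specimen row %d: %s", issue.row, issue.reason)
    return ReadResult(records=records, rejected=rejected)


def read_specimen_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> ReadResult:
    """Read a specimen CSV (comma-separated, UTF-8, header row required)."""
    frame = pd.read_csv(path)
    return specimens_from_frame(frame, schema)


def specimens_to_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "order": r.order,
                "suborder": r.suborder,
                "family": r.family,
                "ocw": r.ocw,
                "body_mass": r.body_mass,
                "sex": r.sex,
                "captive": r.captive,
                "morphotype": r.morphotype.value,
                "hbl": r.hbl,
                "cbl": r.cbl,
            }
        )
    return pd.DataFrame(rows)


def _aggregate_group(
    species: str, group: list[SpecimenRecord], sex: str | None = None
) -> SpeciesRecord:
    ocw = np.array([r.ocw for r in group], dtype=float)
    mass = np.array([r.body_mass for r in group], dtype=float)
    hbl = [r.hbl for r in group if r.hbl is not None]
    cbl = [r.cbl for r in group if r.cbl is not None]
    captive = np.array([r.captive == "captive" for r in group])
    # morphotype is taxon-level: take the modal (in practice constant) flag
    morphs = [r.morphotype for r in group]
    morph = max(set(morphs), key=morphs.count)
    first = group[0]
    return SpeciesRecord(
        species=species,
        n_specimens=len(group),
        mean_ocw=float(ocw.mean()),
        mean_body_mass=float(mass.mean()),
        order=first.order,
        suborder=first.suborder,
        family=first.family,
        mean_hbl=float(np.mean(hbl)) if hbl else None,
        mean_cbl=float(np.mean(cbl)) if cbl else None,
        morphotype=morph,
        fraction_captive=float(captive.mean()),
        sex=sex,
    )


def aggregate_species(
    records: Iterable[SpecimenRecord], mode: str = "pooled"
) -> list[SpeciesRecord]:
    """Aggregate specimens to species (or species-by-sex) arithmetic means.

    ``mode='by_sex'`` emits one record per species/sex combination and excludes
    specimens of unknown sex; species left with no usable specimens after that
    filter are reported via the module logger, not emitted.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot aggregate an empty specimen collection")
    if mode not in ("pooled", "by_sex"):
        raise ValueError(f"unknown aggregation mode {mode!r}")

    out: list[SpeciesRecord] = []
    by_species: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    for species in sorted(by_species):
        group = by_species[species]
        if mode == "pooled":
            out.append(_aggregate_group(species, group))
        else:
            usable = [r for r in group if r.sex in ("male", "female")]
            if not usable:
                logger.warning(
                    "species %s has no specimens of known sex; skipped in by_sex mode",
                    species,
                )
                continue
            for sex in ("female", "male"):
                sub = [r for r in usable if r.sex == sex]
                if sub:
                    out.append(_aggregate_group(species, sub, sex=sex))
    return out


def species_to_frame(records: Iterable[SpeciesRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species,
                "order": r.order,
                "suborder": r.suborder,
                "family": r.family,
                "n_specimens": r.n_specimens,
                "ocw": r.mean_ocw,
                "body_mass": r.mean_body_mass,
                "hbl": r.mean_hbl,
                "cbl": r.mean_cbl,
                "brain_mass": r.brain_mass,
                "morphotype": r.morphotype.value,
                "fraction_captive": r.fraction_captive,
                "sex": r.sex,
            }
        )
    return pd.DataFrame(rows)


def rank_specimens_by_condition(
    records: Sequence[SpecimenRecord],
) -> list[tuple[SpecimenRecord, float]]:
    """Rank one species' specimens by body condition.

    Fits an intraspecific log-log OLS of body mass on head-body length and
    orders specimens by the absolute residual, ascending: specimens nearest
    the intraspecific mass-for-length trend are the best proxies for average
    body condition. Requires at least three specimens with both HBL and mass.
    The sort is stable, so exact ties (e.g. all residuals zero) preserve
    input order.
    """
    usable = [r for r in records if r.hbl is not None]
    if len(usable) < 3:
        raise NotRankableError(
            f"need >= 3 specimens with both HBL and body mass, got {len(usable)}"
        )
    species = {r.species for r in usable}
    if len(species) > 1:
        raise ValueError(f"expected a single species, got {sorted(species)}")
    x = np.log([r.hbl for r in usable])
    y = np.log([r.body_mass for r in usable])
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    order = np.argsort(np.abs(resid), kind="stable")
    return [(usable[i], float(resid[i])) for i in order]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path, format: str = "newick") -> dendropy.Tree:
    """Read a rooted tree with branch lengths from Newick or NEXUS.

    Branch lengths are required downstream (they define the phylogenetic
    covariance), so a tree whose non-root edges lack lengths is refused.
    Multifurcations are preserved.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"format must be 'newick' or 'nexus', got {format!r}")
    try:
        tree = dendropy.Tree.get(path=str(path), schema=format)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeFormatError(f"could not parse {path} as {format}: {exc}") from exc
    _require_branch_lengths(tree)
    return tree


def _require_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeFormatError(
                "tree has edges without branch lengths; lengths are required "
                "for phylogenetic covariance construction"
            )


def write_tree(tree: dendropy.Tree, path: str | Path, format: str = "newick") -> None:
    tree.write(path=str(path), schema=format)


def normalize_taxon(name: str) -> str:
    """Normalize a taxon label for matching: case-fold, underscores to spaces."""
    return " ".join(name.strip().replace("_", " ").split()).casefold()


def match_species_to_tips(
    species: Iterable[str], tree: dendropy.Tree
) -> tuple[dict[str, str], list[str]]:
    """Map analysis species names to tree tip labels.

    Matching is exact after underscore/space normalization and case-folding;
    unmatched names are returned, never guessed. Duplicate tip labels are an
    error.
    """
    tip_map: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else ""
        key = normalize_taxon(label)
        if key in tip_map:
            raise ValueError(f"duplicate tip label after normalization: {label!r}")
        tip_map[key] = label
    matched: dict[str, str] = {}
    unmatched: list[str] = []
    for name in species:
        key = normalize_taxon(name)
        if key in tip_map:
            matched[name] = tip_map[key]
        else:
            unmatched.append(name)
    return matched, unmatched
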