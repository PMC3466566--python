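"""The operon catalog: binary gene-presence traits, complexity index, counts.

An operon catalog has one row per mer operon (not per genome: 23 of the 246
surveyed genomes carry two or three operons) with its taxon/tip label, genome
id, replicon (chromosome or plasmid) and a 0/1 column per scored trait.

The complexity index of an operon is the fraction of the 13 scored core gene
types it carries. Orientation/copy-number variants of merR and merB are
tracked as auxiliary traits and never enter the complexity denominator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "CORE_GENE_TYPES",
    "AUXILIARY_TRAITS",
    "GeneTypeRegistry",
    "TraitMatrix",
    "CatalogError",
    "read_operon_table",
    "write_operon_table",
    "complexity_index",
    "complexity_profile",
    "trait_counts",
    "subset_by_replicon",
    "catalog_summary",
    "round_half_up",
]

# The 13 scored core gene types. merR counts once regardless of orientation
# or copy number; merA is always present (the catalog is anchored on it).
CORE_GENE_TYPES = (
    "merA",
    "arsR",
    "merR",
    "merP",
    "merT",
    "merC",
    "merF",
    "merE",
    "merG",
    "merH",
    "merB",
    "merD",
    "TRASH",
)

AUXILIARY_TRAITS = (
    "merR_convergent",
    "merR_divergent",
    "merR_multiple",
    "merB_multiple",
)

_META_COLUMNS = ("operon_id", "taxon_label", "genome_id", "replicon")
_REPLICONS = ("chromosome", "plasmid")


class CatalogError(ValueError):
    """Raised on malformed operon catalogs."""


@dataclass(frozen=True)
class GeneTypeRegistry:
    """Registered traits: 13 core types plus auxiliary orientation/copy traits."""

    core: tuple[str, ...] = CORE_GENE_TYPES
    auxiliary: tuple[str, ...] = AUXILIARY_TRAITS

    def __post_init__(self):
        if len(self.core) != 13:
            raise ValueError("exactly 13 core gene types are scored")
        if set(self.core) & set(self.auxiliary):
            raise ValueError("core and auxiliary traits overlap")

    @property
    def all_traits(self) -> tuple[str, ...]:
        return self.core + self.auxiliary


DEFAULT_REGISTRY = GeneTypeRegistry()


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TraitMatrix:
    """Validated operon catalog: metadata columns plus 0/1 trait columns."""

    data: pd.DataFrame = field(repr=False)
    registry: GeneTypeRegistry = DEFAULT_REGISTRY

    def __post_init__(self):
        df = self.data
        for col in _META_COLUMNS:
            if col not in df.columns:
                raise CatalogError(f"missing required column {col!r}")
        if df["operon_id"].duplicated().any():
            dups = df.loc[df["operon_id"].duplicated(), "operon_id"].tolist()
            raise CatalogError(f"duplicate operon ids: {dups}")
        bad_rep = ~df["replicon"].isin(_REPLICONS)
        if bad_rep.any():
            row = int(bad_rep.idxmax())
            raise CatalogError(
                f"unknown replicon {df.loc[row, 'replicon']!r} in row {row}"
            )
        for col in self.trait_names:
            bad = ~df[col].isin([0, 1])
            if bad.any():
                row = int(bad.idxmax())
                raise CatalogError(
                    f"non-binary value {df.loc[row, col]!r} in trait column "
                    f"{col!r}, row {row}"
                )
        object.__setattr__(self, "data", df.reset_index(drop=True))

    # -- views -------------------------------------------------------------
    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in _META_COLUMNS)

    @property
    def n_operons(self) -> int:
        return len(self.data)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.data["taxon_label"])

    def trait_vector(self, trait: str, taxa=None):
        """0/1 values for one trait, optionally reordered to ``taxa``."""
        if trait not in self.trait_names:
            raise CatalogError(f"unknown trait {trait!r}")
        series = self.data.set_index("taxon_label")[trait]
        if taxa is not None:
            series = series.loc[list(taxa)]
        return series.to_numpy(dtype=float)

    def merR_core(self) -> pd.Series:
        """Core merR presence: convergent OR divergent orientation."""
        df = self.data
        if "merR" in df.columns:
            return df["merR"]
        conv = df.get("merR_convergent", 0)
        div = df.get("merR_divergent", 0)
        return ((conv + div) > 0).astype(int)


def read_operon_table(path_or_buffer, registry: GeneTypeRegistry = DEFAULT_REGISTRY) -> TraitMatrix:
    """Read a tab-separated operon catalog, preserving row order."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype={"operon_id": str, "genome_id": str})
    return TraitMatrix(df, registry)


def write_operon_table(matrix: TraitMatrix, path=None) -> str | None:
    if path is None:
        buf = io.StringIO()
        matrix.data.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    matrix.data.to_csv(path, sep="\t", index=False)
    return None


def complexity_index(record, registry: GeneTypeRegistry = DEFAULT_REGISTRY) -> float:
    """Fraction of the 13 core gene types present in one operon record.

    ``record`` is a mapping (e.g. a catalog row) from trait name to 0/1; a
    missing merR column is derived from the orientation variants. Reported to
    3 decimals; always >= 1/13 because merA anchors every operon.
    """
    count = 0
    for gene in registry.core:
        if gene in record:
            count += int(record[gene])
        elif gene == "merR":
            conv = int(record.get("merR_convergent", 0))
            div = int(record.get("merR_divergent", 0))
            count += 1 if (conv or div) else 0
    return round(count / 13, 3)


def complexity_profile(matrix: TraitMatrix) -> pd.DataFrame:
    """Per-operon complexity indices (the tree side-bar values)."""
    rows = []
    for _, rec in matrix.data.iterrows():
        rows.append(
            {
                "operon_id": rec["operon_id"],
                "taxon_label": rec["taxon_label"],
                "complexity": complexity_index(rec, matrix.registry),
            }
        )
    return pd.DataFrame(rows)


def trait_counts(matrix: TraitMatrix, trait: str) -> tuple[int, int, float]:
    """(presence, absence, percent-of-total) for one trait.

    Percent is 100 * presence / n rounded half-up to one decimal, matching
    how published presence/absence tables print their "% of Total" column.
    """
    x = matrix.trait_vector(trait)
    presence = int(x.sum())
    absence = matrix.n_operons - presence
    percent = round_half_up(100.0 * presence / matrix.n_operons, 1)
    return presence, absence, percent


def subset_by_replicon(matrix: TraitMatrix, which: str) -> TraitMatrix:
    """Filter the catalog to one replicon class; ``which='all'`` is identity."""
    if which == "all":
        return matrix
    if which not in _REPLICONS:
        raise CatalogError(f"replicon must be one of {_REPLICONS + ('all',)}, got {which!r}")
    return TraitMatrix(
        matrix.data[matrix.data["replicon"] == which].reset_index(drop=True),
        matrix.registry,
    )


def catalog_summary(matrix: TraitMatrix) -> dict:
    """Headline catalog counts: operons, genomes, multi-operon genomes, plasmids."""
    counts = matrix.data["genome_id"].value_counts()
    return {
        "n_operons": matrix.n_operons,
        "n_distinct_genomes": int(counts.size),
        "n_genomes_with_multiple_operons": int((counts > 1).sum()),
        "n_plasmid_operons": int((matrix.data["replicon"] == "plasmid").sum()),
    }
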