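"""Phylogenetic profile matrices: construction, normalization, filtering.

A phylogenetic profile records how well each human gene is conserved across
a panel of eukaryotic genomes.  The raw conservation value is the
length-normalized bitscore: the best-hit bitscore of the gene in a target
species divided by the bitscore of the gene's human self-hit (LNPP).  A
second, per-species normalization (NPP) removes the global effect of
phylogenetic distance from the query species so that correlations between
gene profiles reflect gene-specific gain/loss patterns rather than overall
genome divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "BitscoreTable",
    "CladeMap",
    "ConservationCriterion",
    "read_profile_csv",
    "read_bitscore_table",
    "read_clade_map",
    "build_lnpp",
    "filter_all_zero_genes",
    "normalize_npp",
    "restrict_to_clade",
    "conserved_genes",
]


class ProfileError(ValueError):
    """Raised for malformed or degenerate profile data."""


@dataclass
class ProfileMatrix:
    """Dense gene × species conservation matrix.

    Parameters
    ----------
    genes : list of str
        HGNC gene symbols (uppercase, unique), row order.
    species : list of str
        Opaque species identifiers (unique), column order.
    values : ndarray of shape (n_genes, n_species)
    variant : {"LNPP", "NPP"}
        LNPP holds raw bitscore ratios in [0, ceiling]; NPP holds
        per-species standardized log-scale values.
    """

    genes: list[str]
    species: list[str]
    values: np.ndarray
    variant: str = "LNPP"

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.species = [str(s) for s in self.species]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.species)):
            raise ProfileError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.species)} species"
            )
        dup = _duplicates(self.genes)
        if dup:
            raise ProfileError(f"duplicate gene symbols: {sorted(dup)}")
        dup = _duplicates(self.species)
        if dup:
            raise ProfileError(f"duplicate species ids: {sorted(dup)}")
        if self.variant not in ("LNPP", "NPP"):
            raise ProfileError(f"unknown variant {self.variant!r}")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise ProfileError(f"gene {gene!r} not in matrix") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def subset_genes(self, genes: Sequence[str]) -> "ProfileMatrix":
        idx = [self._gene_index[g] if g in self._gene_index else _missing(g) for g in genes]
        return ProfileMatrix(list(genes), list(self.species), self.values[idx], self.variant)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.genes, columns=self.species)
        df.index.name = "gene"
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")


def _missing(g: str):
    raise ProfileError(f"gene {g!r} not in matrix")


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


@dataclass
class BitscoreTable:
    """Best-hit bitscores per (gene, species) plus human self-hit bitscores.

    Duplicate (gene, species) records are resolved by keeping the maximum
    bitscore (best hit).  Self-hit bitscores must be strictly positive.
    """

    records: pd.DataFrame  # columns: gene, species, bitscore
    self_hits: dict[str, float]

    def __post_init__(self) -> None:
        df = self.records.copy()
        df.columns = ["gene", "species", "bitscore"]
        df["gene"] = df["gene"].astype(str).str.strip().str.upper()
        df["species"] = df["species"].astype(str).str.strip()
        df["bitscore"] = pd.to_numeric(df["bitscore"])
        if (df["bitscore"] < 0).any():
            bad = df.loc[df["bitscore"] < 0].iloc[0]
            raise ProfileError(
                f"negative bitscore {bad['bitscore']} for ({bad['gene']}, {bad['species']})"
            )
        # best hit per gene-species pair
        self.records = df.groupby(["gene", "species"], as_index=False)["bitscore"].max()
        self.self_hits = {
            str(g).strip().upper(): float(b) for g, b in self.self_hits.items()
        }
        for g, b in self.self_hits.items():
            if b <= 0:
                raise ProfileError(f"self-hit bitscore for {g} must be positive, got {b}")


@dataclass
class CladeMap:
    """Assignment of species to named clades.

    One clade (``universal``) covers every species; species may belong to
    several nested clades.
    """

    membership: dict[str, set[str]]  # species -> clade names
    universal: str = "Eukaryota"
    clade_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names: list[str] = []
        for sp, clades in self.membership.items():
            self.membership[sp] = set(clades) | {self.universal}
            for c in self.membership[sp]:
                if c not in names:
                    names.append(c)
        if self.universal in names:
            names.remove(self.universal)
        self.clade_names = [self.universal] + sorted(names)

    def members(self, clade: str) -> set[str]:
        if clade not in self.clade_names:
            raise ProfileError(
                f"unknown clade {clade!r}; available: {', '.join(self.clade_names)}"
            )
        return {sp for sp, cl in self.membership.items() if clade in cl}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sp, c)
            for sp in self.membership
            for c in sorted(self.membership[sp])
        ]
        return pd.DataFrame(rows, columns=["species", "clade"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ConservationCriterion:
    """A gene counts as conserved in a clade when its raw (LNPP) profile
    value exceeds ``value_floor`` in at least ``min_fraction`` of the
    clade's species."""

    value_floor: float = 0.05
    min_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.value_floor < 0:
            raise ProfileError("value_floor must be >= 0")
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ProfileError("min_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# I/O


def read_profile_csv(path: str | Path) -> ProfileMatrix:
    """Read a gene × species profile matrix from CSV.

    The first row holds the species ids (first cell is the gene-column
    header), each subsequent row a gene symbol followed by numeric values.
    Gene symbols are uppercased.  Duplicate symbols and non-numeric cells
    are reported with their location.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ProfileError(f"empty profile file: {path}") from None
    if raw.shape[0] == 0 or raw.shape[1] < 2:
        raise ProfileError(f"profile file {path} has no data rows/columns")
    genes = [g.strip().upper() for g in raw.iloc[:, 0]]
    dup = _duplicates(genes)
    if dup:
        raise ProfileError(f"duplicate gene symbol(s) in {path}: {sorted(dup)}")
    species = [str(c).strip() for c in raw.columns[1:]]
    body = raw.iloc[:, 1:]
    values = np.empty((len(genes), len(species)), dtype=float)
    for j, col in enumerate(body.columns):
        converted = pd.to_numeric(body[col], errors="coerce")
        if converted.isna().any():
            i = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ProfileError(
                f"non-numeric value {body[col].iloc[i]!r} at gene {genes[i]!r}, "
                f"species {species[j]!r} (row {i + 2}, column {j + 2}) in {path}"
            )
        values[:, j] = converted.to_numpy()
    variant = "NPP" if np.nanmin(values) < 0 else "LNPP"
    return ProfileMatrix(genes, species, values, variant)


def read_bitscore_table(
    hits_path: str | Path, self_hits_path: str | Path
) -> BitscoreTable:
    """Read best-hit bitscores (columns gene, species, bitscore; comma or
    tab separated) and self-hit bitscores (columns gene, bitscore)."""
    hits = pd.read_csv(hits_path, sep=None, engine="python")
    if hits.shape[1] != 3:
        raise ProfileError(
            f"bitscore table {hits_path} must have 3 columns, found {hits.shape[1]}"
        )
    selfs = pd.read_csv(self_hits_path, sep=None, engine="python")
    if selfs.shape[1] != 2:
        raise ProfileError(
            f"self-hit table {self_hits_path} must have 2 columns, found {selfs.shape[1]}"
        )
    self_map = dict(zip(selfs.iloc[:, 0], pd.to_numeric(selfs.iloc[:, 1])))
    return BitscoreTable(hits, self_map)


def read_clade_map(path: str | Path, universal: str = "Eukaryota") -> CladeMap:
    """Read a species,clade CSV (one row per membership)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ProfileError(f"clade map {path} needs columns species,clade")
    membership: dict[str, set[str]] = {}
    for sp, clade in zip(df.iloc[:, 0], df.iloc[:, 1]):
        membership.setdefault(str(sp).strip(), set()).add(str(clade).strip())
    return CladeMap(membership, universal=universal)


# ---------------------------------------------------------------------------
# Matrix construction and transforms


def build_lnpp(
    hits: BitscoreTable,
    genes: Sequence[str],
    species: Sequence[str],
    ceiling: float = 1.0,
) -> ProfileMatrix:
    """Build the length-normalized profile matrix from bitscores.

    value(g, s) = best-hit bitscore of gene g in species s, divided by the
    bitscore of g's human self-hit; pairs without a hit record yield 0.
    Ratios above ``ceiling`` (a best hit can marginally exceed the
    self-hit) are clipped.
    """
    genes = [str(g).strip().upper() for g in genes]
    species = [str(s).strip() for s in species]
    if not species:
        raise ProfileError("species list is empty")
    missing = [g for g in genes if g not in hits.self_hits]
    if missing:
        raise ProfileError(f"gene(s) without self-hit bitscore: {missing}")
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: j for j, s in enumerate(species)}
    values = np.zeros((len(genes), len(species)))
    for gene, sp, score in hits.records.itertuples(index=False):
        if gene in gi and sp in si:
            values[gi[gene], si[sp]] = score / hits.self_hits[gene]
    np.clip(values, 0.0, ceiling, out=values)
    return ProfileMatrix(genes, species, values, "LNPP")


def filter_all_zero_genes(m: ProfileMatrix) -> tuple[ProfileMatrix, list[str]]:
    """Drop genes with zero conservation in every species.

    Returns the filtered matrix and the removed genes in input order.
    """
    if m.variant != "LNPP":
        raise ProfileError("all-zero filtering applies to the LNPP matrix")
    nonzero = (m.values != 0).any(axis=1)
    removed = [g for g, keep in zip(m.genes, nonzero) if not keep]
    if not nonzero.any():
        raise ProfileError("all genes are zero across all species; nothing left")
    kept = [g for g, keep in zip(m.genes, nonzero) if keep]
    return ProfileMatrix(kept, list(m.species), m.values[nonzero], "LNPP"), removed


def normalize_npp(
    m: ProfileMatrix,
    floor_epsilon: float = 0.01,
    method: str = "zscore",
) -> ProfileMatrix:
    """Per-species normalization of an LNPP matrix.

    Each species column is transformed to log2(value + floor_epsilon) and
    standardized to mean 0, sd 1 across genes, removing the column-wise
    (phylogenetic-distance) component of conservation.  Constant columns
    become all-zero with a logged warning.  ``method="rank"`` replaces the
    log step with a rank transform before standardization, as a sensitivity
    alternative.
    """
    if m.variant != "LNPP":
        raise ProfileError("normalize_npp expects an LNPP matrix")
    if m.n_genes < 3:
        raise ProfileError("need at least 3 genes to standardize columns")
    if floor_epsilon <= 0:
        raise ProfileError("floor_epsilon must be positive")
    if method == "zscore":
        x = np.log2(m.values + floor_epsilon)
    elif method == "rank":
        x = pd.DataFrame(m.values).rank(axis=0).to_numpy(dtype=float)
    else:
        raise ProfileError(f"unknown NPP method {method!r}")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(x)
    nonconst = sd > 0
    if not nonconst.all():
        bad = [s for s, ok in zip(m.species, nonconst) if not ok]
        logger.warning(
            "constant profile column(s) mapped to zero during NPP: %s", ", ".join(bad)
        )
    out[:, nonconst] = (x[:, nonconst] - mu[nonconst]) / sd[nonconst]
    return ProfileMatrix(list(m.genes), list(m.species), out, "NPP")


def restrict_to_clade(m: ProfileMatrix, clades: CladeMap, clade: str) -> ProfileMatrix:
    """Restrict the matrix columns to the species of one clade (order kept)."""
    members = clades.members(clade)
    keep = [j for j, s in enumerate(m.species) if s in members]
    if not keep:
        raise ProfileError(f"no species of clade {clade!r} present in the matrix")
    return ProfileMatrix(
        list(m.genes), [m.species[j] for j in keep], m.values[:, keep], m.variant
    )


def conserved_genes(
    m: ProfileMatrix, criterion: ConservationCriterion = ConservationCriterion()
) -> list[str]:
    """Genes conserved in the (clade-restricted) matrix under the criterion.

    A gene qualifies when the fraction of species with LNPP value strictly
    above ``value_floor`` is at least ``min_fraction``.
    """
    if m.variant != "LNPP":
        raise ProfileError("conservation criterion applies to LNPP values")
    frac = (m.values > criterion.value_floor).mean(axis=1)
    return [g for g, f in zip(m.genes, frac) if f >= criterion.min_fraction]
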