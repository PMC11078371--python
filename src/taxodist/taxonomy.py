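"""Linnaean hierarchy handling and pairwise taxonomic path lengths.

A taxonomy table maps each species to its genus, family and class.  The
table must describe a strict tree: a genus belongs to exactly one family
and a family to exactly one class.  From a validated table the pairwise
path-length matrix ``omega`` is built: congeneric species are one step
apart, confamilial species (different genus) two, species in different
families of the same class three.  Step lengths are configurable and the
matrix is rescaled so the largest attainable path equals ``scale_max``
(100 by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StepWeights",
    "PathLengthMatrix",
    "TaxonomyError",
    "DuplicateSpeciesError",
    "PolyphylyError",
    "EmptyTaxonomyError",
    "MissingSpeciesError",
    "validate_taxonomy",
    "path_lengths",
]

RANKS = ("species", "genus", "family", "class")

_WS = re.compile(r"\s+")


class TaxonomyError(ValueError):
    """Base class for taxonomy validation failures."""


class DuplicateSpeciesError(TaxonomyError):
    """A species name appears more than once."""


class PolyphylyError(TaxonomyError):
    """A taxon is assigned to more than one parent taxon."""


class EmptyTaxonomyError(TaxonomyError):
    """The taxonomy table has no rows."""


class MissingSpeciesError(TaxonomyError):
    """Species referenced elsewhere are absent from the taxonomy."""


@dataclass(frozen=True)
class StepWeights:
    """Per-level step lengths of the taxonomic tree.

    ``species_to_genus`` is the step between congeneric species,
    ``genus_to_family`` the extra step to reach the family level and
    ``family_to_root`` the extra step to the class-level root.  After
    construction the matrix is rescaled so the maximum attainable path
    equals ``scale_max``.
    """

    species_to_genus: float = 1.0
    genus_to_family: float = 1.0
    family_to_root: float = 1.0
    scale_max: float = 100.0

    def __post_init__(self) -> None:
        for name in ("species_to_genus", "genus_to_family", "family_to_root"):
            if getattr(self, name) <= 0:
                raise ValueError(f"step weight {name!r} must be > 0")
        if self.scale_max <= 0:
            raise ValueError("scale_max must be > 0")

    @property
    def cumulative(self) -> np.ndarray:
        """Unscaled path lengths to the genus, family and root levels."""
        return np.cumsum(
            [self.species_to_genus, self.genus_to_family, self.family_to_root]
        )


@dataclass
class PathLengthMatrix:
    """Symmetric matrix of pairwise taxonomic path lengths.

    Attributes
    ----------
    species : list of str
        Row/column labels, in matrix order.
    values : ndarray of shape (S, S)
        ``values[i, j]`` is the path length between species i and j;
        zero diagonal, symmetric.
    scale_max : float
        The value the maximal path was scaled to.
    """

    species: list[str]
    values: np.ndarray
    scale_max: float = 100.0
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species list")
        self._index = {s: i for i, s in enumerate(self.species)}

    def indices(self, species: "list[str] | tuple[str, ...]") -> np.ndarray:
        """Integer positions of *species*; raises on unknown names."""
        missing = [s for s in species if s not in self._index]
        if missing:
            raise MissingSpeciesError(
                f"species absent from taxonomy: {sorted(missing)}"
            )
        return np.asarray([self._index[s] for s in species], dtype=int)

    def submatrix(self, species: "list[str] | tuple[str, ...]") -> np.ndarray:
        idx = self.indices(species)
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale_max: float = 100.0) -> "PathLengthMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("path-length frame must have identical index and columns")
        return cls(list(frame.index), frame.to_numpy(dtype=float), scale_max)


def _normalize_name(name: object, capitalized: bool = True) -> str:
    text = _WS.sub(" ", str(name).strip())
    if not text:
        return ""
    if capitalized:
        text = text[0].upper() + text[1:].lower()
    return text


def validate_taxonomy(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize names and enforce the strict-tree invariants.

    Parameters
    ----------
    table : DataFrame
        Must contain columns ``species, genus, family, class``.  Extra
        columns are preserved untouched.

    Returns
    -------
    DataFrame
        Copy with trimmed, case-normalized names.

    Raises
    ------
    EmptyTaxonomyError, DuplicateSpeciesError, PolyphylyError, TaxonomyError
    """
    if table is None or len(table) == 0:
        raise EmptyTaxonomyError("empty taxonomy")
    missing_cols = [c for c in RANKS if c not in table.columns]
    if missing_cols:
        raise TaxonomyError(f"taxonomy table missing columns: {missing_cols}")

    out = table.copy()
    for col in RANKS:
        out[col] = out[col].map(_normalize_name)
        blank = out[out[col] == ""]
        if len(blank):
            raise TaxonomyError(
                f"blank {col!r} name in rows {list(blank.index)}"
            )

    dup = out["species"][out["species"].duplicated()]
    if len(dup):
        raise DuplicateSpeciesError(
            f"duplicate species names: {sorted(dup.unique())}"
        )

    for child, parent in (("genus", "family"), ("family", "class")):
        parents = out.groupby(child)[parent].nunique()
        bad = parents[parents > 1]
        if len(bad):
            details = {
                name: sorted(out.loc[out[child] == name, parent].unique())
                for name in bad.index
            }
            raise PolyphylyError(
                f"{child} assigned to multiple {parent} values: {details}"
            )

    return out.reset_index(drop=True)


def path_lengths(
    table: pd.DataFrame, weights: StepWeights | None = None
) -> PathLengthMatrix:
    """Pairwise taxonomic path lengths for every species pair.

    The path between two species runs up to their lowest common rank:
    one unscaled step for congeners, two for confamilials in different
    genera, three for members of different families.  The matrix is
    rescaled so the maximum attainable path equals ``weights.scale_max``.
    """
    weights = weights or StepWeights()
    table = validate_taxonomy(table)

    species = list(table["species"])
    genus = table["genus"].to_numpy()
    family = table["family"].to_numpy()
    klass = table["class"].to_numpy()

    cum = weights.cumulative
    scale = weights.scale_max / cum[-1]

    same_genus = genus[:, None] == genus[None, :]
    same_family = family[:, None] == family[None, :]
    same_class = klass[:, None] == klass[None, :]
    if not same_class.all():
        # multiple classes would need a deeper root; the weights only
        # describe three levels, so refuse rather than silently cap
        pairs = np.argwhere(~same_class)
        i, j = pairs[0]
        raise TaxonomyError(
            "table spans multiple classes (e.g. "
            f"{species[i]!r} vs {species[j]!r}); single-class tables only"
        )

    steps = np.full((len(species), len(species)), cum[2])
    steps[same_family] = cum[1]
    steps[same_genus] = cum[0]
    np.fill_diagonal(steps, 0.0)

    return PathLengthMatrix(species, steps * scale, weights.scale_max)
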