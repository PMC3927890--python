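"""Core in-memory containers shared across the analysis modules.

The pipeline revolves around a handful of tabular objects: diploid
microsatellite genotypes, per-individual habitat-use proportions over the
seven land-cover classes, symmetric individual-by-individual matrices
(relatedness, distances, sex similarity, ecological divergence), phenotype
records, and translocation events.  Everything heavier (model fits, cluster
solutions) lives with the module that produces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven land-cover classes, in canonical column order.
HABITAT_CLASSES = (
    "wetland",
    "cutblock",
    "shrub",
    "wetland-herbaceous",
    "upland-herbaceous",
    "barren",
    "upland-forest",
)

#: Provincial management units in strict south-to-north order.
MANAGEMENT_UNITS = (
    "Castle",
    "Livingstone",
    "Clearwater",
    "Yellowhead",
    "GrandeCache",
    "SwanHills",
)


class BearlinkError(Exception):
    """Base class for all package errors."""


class ValidationError(BearlinkError):
    """Raised when an input violates a documented contract."""


@dataclass
class GenotypeTable:
    """Diploid multi-allelic genotypes for a sample of individuals.

    Parameters
    ----------
    ids : list of str
        Individual identifiers, one per row.
    loci : list of str
        Locus names, one per genotype column.
    alleles : ndarray of shape (n_individuals, n_loci, 2)
        Positive integer allele codes; 0 denotes a missing call.  Both
        copies at a locus must be missing together (half-missing genotypes
        are rejected at validation).
    populations : list of str, optional
        Per-individual population / management-unit label.
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValidationError(
                f"allele array must be (n, L, 2), got {self.alleles.shape}"
            )
        n, L, _ = self.alleles.shape
        if len(self.ids) != n:
            raise ValidationError(f"{len(self.ids)} ids for {n} genotype rows")
        if len(self.loci) != L:
            raise ValidationError(f"{len(self.loci)} locus names for {L} columns")
        if self.populations is not None and len(self.populations) != n:
            raise ValidationError("population labels do not match individuals")
        half = (self.alleles == 0).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValidationError(
                f"half-missing genotype for individual {self.ids[i]!r} "
                f"at locus {self.loci[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask, True where the genotype is missing."""
        return self.alleles[:, :, 0] == 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
            and self.populations == other.populations
        )


@dataclass
class PairwiseMatrix:
    """Dense symmetric individual-by-individual matrix with a kind tag.

    The diagonal carries whatever the kind defines (0 for distances, the
    self-value for similarities); Mantel vectorisation always uses the
    strictly lower triangle and never touches the diagonal.
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValidationError(f"{self.kind} matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def triangle(self) -> np.ndarray:
        """Strictly-lower-triangle vector, row-major order."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reorder(self, ids: list[str]) -> "PairwiseMatrix":
        """Return a copy with rows/columns in the given id order."""
        pos = {v: k for k, v in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unknown id {exc.args[0]!r}") from exc
        return PairwiseMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)


@dataclass
class HabitatUseTable:
    """Per-individual proportions of use over the seven land-cover classes."""

    ids: list[str]
    proportions: np.ndarray  # (n, 7)
    fix_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        n = len(self.ids)
        if self.proportions.shape != (n, len(HABITAT_CLASSES)):
            raise ValidationError(
                f"proportions shape {self.proportions.shape}, expected "
                f"({n}, {len(HABITAT_CLASSES)})"
            )
        if (self.proportions < 0).any():
            raise ValidationError("negative habitat-use proportion")
        sums = self.proportions.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-12:
            raise ValidationError("habitat-use rows must sum to 1 within 1e-12")
        if self.fix_counts is not None:
            self.fix_counts = np.asarray(self.fix_counts, dtype=np.int64)
            if self.fix_counts.shape != (n,):
                raise ValidationError("fix_counts length mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, columns=list(HABITAT_CLASSES))
        df.insert(0, "id", self.ids)
        if self.fix_counts is not None:
            df["fix_count"] = self.fix_counts
        return df


@dataclass
class AvailabilityTable:
    """Habitat availability proportions per management unit."""

    units: list[str]
    proportions: np.ndarray  # (U, 7)
    point_counts: np.ndarray  # (U,)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.point_counts = np.asarray(self.point_counts, dtype=np.int64)
        U = len(self.units)
        if self.proportions.shape != (U, len(HABITAT_CLASSES)):
            raise ValidationError("availability proportions shape mismatch")
        sums = self.proportions.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-12:
            raise ValidationError("availability rows must sum to 1 within 1e-12")
        if self.point_counts.shape != (U,):
            raise ValidationError("point_counts length mismatch")

    def counts(self) -> np.ndarray:
        """Reconstructed units x classes point counts (rounded)."""
        return np.rint(self.proportions * self.point_counts[:, None]).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, columns=list(HABITAT_CLASSES))
        df.insert(0, "unit", self.units)
        df["point_count"] = self.point_counts
        return df


@dataclass
class TranslocationTable:
    """Management translocation events between units."""

    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["event_id", "year", "source_unit", "dest_unit"]
        )
    )

    def __post_init__(self) -> None:
        required = {"event_id", "year", "source_unit", "dest_unit"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValidationError(f"translocation table missing columns {sorted(missing)}")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def validate_years(self, lo: int = 1974, hi: int = 2012) -> None:
        yrs = self.events["year"]
        if len(yrs) and ((yrs < lo) | (yrs > hi)).any():
            raise ValidationError(f"translocation year outside [{lo}, {hi}]")
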