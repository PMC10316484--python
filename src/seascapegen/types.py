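"""Core domain containers shared by every analysis stage.

All downstream stages consume these validated types; no stage reads raw
files directly.  Genotypes are codominant diploid microsatellite calls
(integer allele sizes, 0 = missing, following the GenAlEx convention);
internally missingness is carried as a boolean mask and the sentinel never
enters a computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = 0  # GenAlEx missing-allele sentinel

#: Wentworth grain-size categories accepted for the sediment variable.
WENTWORTH_CLASSES = ("boulder", "cobble", "pebble", "granule", "sand", "silt", "clay")

#: Geomorphic habitat categories.
HABITAT_CLASSES = ("reef terrace", "reef lagoon")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class GenotypeTable:
    """Samples x loci diploid allele-size matrix with site labels.

    ``alleles`` has shape (n_samples, n_loci, 2) with positive integer
    allele sizes, or 0 for a missing call.  A locus is missing for a
    sample when either of its two allele copies is the sentinel.
    """

    sample_id: np.ndarray  # (n,) str
    site_id: np.ndarray  # (n,) str
    locus_names: list[str]
    alleles: np.ndarray  # (n, L, 2) int

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.site_id = np.asarray(self.site_id, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValidationError("alleles must have shape (n_samples, n_loci, 2)")
        n, L, _ = self.alleles.shape
        if n < 1 or L < 1:
            raise ValidationError("need at least 1 sample and 1 locus")
        if len(self.locus_names) != L:
            raise ValidationError("locus_names length does not match allele matrix")
        if len(self.sample_id) != n or len(self.site_id) != n:
            raise ValidationError("sample/site label length does not match allele matrix")
        if (self.alleles < 0).any():
            raise ValidationError("allele sizes must be positive integers or 0 (missing)")

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean (n_samples, n_loci) mask: True where the call is missing."""
        return (self.alleles == MISSING).any(axis=2)

    @property
    def sites(self) -> list[str]:
        """Site labels in order of first appearance."""
        return list(dict.fromkeys(self.site_id.tolist()))

    def subset(self, index: np.ndarray) -> "GenotypeTable":
        """Row subset (boolean or integer index)."""
        index = np.asarray(index)
        return GenotypeTable(
            sample_id=self.sample_id[index],
            site_id=self.site_id[index],
            locus_names=list(self.locus_names),
            alleles=self.alleles[index],
        )

    def by_site(self, site: str) -> "GenotypeTable":
        return self.subset(self.site_id == site)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            list(self.sample_id) == list(other.sample_id)
            and list(self.site_id) == list(other.site_id)
            and self.locus_names == other.locus_names
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class SiteTable:
    """Site id, coordinates and region, in either geographic or planar mode.

    ``crs`` is "lonlat" (decimal degrees, great-circle metrics) or "planar"
    (meters); mixing modes downstream is an error.
    """

    data: pd.DataFrame  # columns: site_id, x, y, region
    crs: str = "lonlat"

    def __post_init__(self) -> None:
        required = {"site_id", "x", "y", "region"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"site table needs columns {sorted(required)}")
        if self.crs not in ("lonlat", "planar"):
            raise ValidationError("crs must be 'lonlat' or 'planar'")
        if self.data["site_id"].duplicated().any():
            raise ValidationError("duplicate site_id in site table")
        if not np.isfinite(self.data[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValidationError("site coordinates must be finite")
        self.data = self.data.reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return self.data["site_id"].tolist()

    @property
    def coords(self) -> np.ndarray:
        """(n_sites, 2) array of (x, y) -- lon/lat degrees or planar meters."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class EnvironmentTable:
    """Per-site habitat covariates: depth, sediment, habitat type,
    number of other seagrass species, coral presence."""

    data: pd.DataFrame

    NUMERIC = ("depth", "n_other_seagrass")
    CATEGORICAL = ("sediment", "habitat")
    BOOLEAN = ("coral_present",)

    def __post_init__(self) -> None:
        required = {"site_id", "depth", "sediment", "habitat", "n_other_seagrass", "coral_present"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"environment table needs columns {sorted(required)}")
        if self.data["site_id"].duplicated().any():
            raise ValidationError("duplicate site_id in environment table")
        bad_sed = set(self.data["sediment"]) - set(WENTWORTH_CLASSES)
        if bad_sed:
            raise ValidationError(f"unknown sediment categories {sorted(bad_sed)}")
        bad_hab = set(self.data["habitat"]) - set(HABITAT_CLASSES)
        if bad_hab:
            raise ValidationError(f"unknown habitat categories {sorted(bad_hab)}")
        if not np.isfinite(self.data["depth"].to_numpy(dtype=float)).all():
            raise ValidationError("depth must be finite")
        self.data = self.data.reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return self.data["site_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative site x site matrix with zero diagonal."""

    site_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix dimensions do not match site list")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        finite = self.values[np.isfinite(self.values)]
        if (finite < -1e-12).any():
            raise ValidationError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) values in row-major order."""
        iu = np.triu_indices(len(self.site_ids), k=1)
        return self.values[iu]

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.site_ids.index(s) for s in ids]
        return DistanceMatrix(site_ids=list(ids), values=self.values[np.ix_(idx, idx)])


@dataclass
class DirectedMatrix:
    """Square nonnegative site x site matrix, not necessarily symmetric."""

    site_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix dimensions do not match site list")
        if (self.values < 0).any():
            raise ValidationError("values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def subset(self, ids: Sequence[str]) -> "DirectedMatrix":
        idx = [self.site_ids.index(s) for s in ids]
        return DirectedMatrix(site_ids=list(ids), values=self.values[np.ix_(idx, idx)])


@dataclass
class AnalysisConfig:
    """Run configuration: seeds, permutation counts, schedule parameters.

    Every stochastic stage draws its seed from ``seed`` via a stable
    per-stage offset so a single integer reproduces the whole run.
    """

    seed: int = 0
    n_perm_fst: int = 999
    n_perm_mantel: int = 9999
    n_perm_rda: int = 999
    n_perm_autocorr: int = 9999
    n_boot_autocorr: int = 9999
    distance_class_endpoints_km: Sequence[float] = (
        0.01, 0.025, 0.05, 5, 10, 15, 20, 25, 30, 35, 45, 60,
    )
    particles_per_release: int = 100
    release_interval_days: int = 3
    rarefaction_g: Sequence[int] = (14, 20)
    min_mlg_per_site: int = 6
    missing_policy: str = "permissive"
    outdir: str = "results"
    extra: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        h = 2166136261
        for ch in stage:
            h = ((h ^ ord(ch)) * 16777619) & 0xFFFFFFFF
        return (self.seed * 1000003 + h) % (2**31 - 1)
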