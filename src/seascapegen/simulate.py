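"""Synthetic data with the statistical structure the analysis assumes.

Three generators stand in for the field and hydrodynamic data: multi-site
microsatellite genotypes under a Balding–Nichols island model with
within-site inbreeding and clonal replication; gridded hourly surface
currents (residual + tidal sinusoid, with simple presets); and mixed-type
habitat covariates that can be associated with declared site groups.

Each generator is a pure function of its spec (same seed => bit-identical
output) and returns a truth record where parameter recovery is tested
downstream.

The genotype model, per locus:

* ancestral allele frequencies ``p`` drawn from a symmetric Dirichlet;
* site frequencies from the multi-allele Balding–Nichols distribution,
  ``Dirichlet(p (1-theta)/theta)``, so allele-frequency variance among
  sites is ``theta * p(1-p)`` (theta plays the role of F_ST);
* optionally hierarchical: group frequencies drawn first with
  ``theta_between``, then site frequencies within groups with ``theta``;
* genotypes drawn with inbreeding ``f`` (with probability f the individual
  is autozygous at the locus, else a Hardy–Weinberg draw);
* with probability ``clonality`` a new sample is a ramet copying the full
  multilocus genotype of a previously generated same-site sample;
* missing calls are then dropped independently at ``missing_rate`` per
  (sample, locus) — clones therefore share a genet but not necessarily a
  missing-data pattern, which keeps genotype matching under missing data
  exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .types import (
    EnvironmentTable,
    GenotypeTable,
    SiteTable,
    ValidationError,
    HABITAT_CLASSES,
    WENTWORTH_CLASSES,
)


# ------------------------------------------------------------- genotypes

@dataclass
class GenotypeSimSpec:
    """Parameters of the genotype generator (defaults mirror the study
    scale: ~48 ramets per site genotyped at 16 microsatellite loci)."""

    n_sites: int = 12
    samples_per_site: int = 48
    n_loci: int = 16
    alleles_per_locus: int = 5
    dirichlet_alpha: float = 1.0
    theta: float = 0.2  # among-site differentiation (F_ST scale)
    f: float = 0.0  # within-site inbreeding
    clonality: float = 0.0  # probability a sample is a ramet of an earlier one
    missing_rate: float = 0.02
    site_groups: Sequence[int] | None = None  # optional group label per site
    theta_between: float | None = None  # among-group differentiation
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 1 or self.n_sites < 1 or self.samples_per_site < 1:
            raise ValidationError("degenerate genotype spec: zero loci/sites/samples")
        if not (0 <= self.theta < 1):
            raise ValidationError("theta must be in [0, 1)")
        if not (-1 < self.f < 1):
            raise ValidationError("f must be in (-1, 1)")
        if not (0 <= self.clonality < 1):
            raise ValidationError("clonality must be in [0, 1)")
        if self.alleles_per_locus < 2:
            raise ValidationError("need at least 2 alleles per locus")
        if self.site_groups is not None and len(self.site_groups) != self.n_sites:
            raise ValidationError("site_groups length must equal n_sites")


@dataclass
class GenotypeTruth:
    """Realized parameters recorded alongside a simulated dataset."""

    theta: float
    f: float
    clonality: float
    site_freqs: np.ndarray  # (n_sites, n_loci, n_alleles)
    ancestral_freqs: np.ndarray  # (n_loci, n_alleles)
    clone_donor: np.ndarray  # (n_samples,) donor row index, -1 for founders
    genet_id: np.ndarray  # (n_samples,) true genet (MLG) label
    site_groups: np.ndarray | None = None

    @property
    def n_genets(self) -> int:
        return len(np.unique(self.genet_id))

    def true_clonal_richness(self) -> float:
        """(G-1)/(N-1) computed from the true genet labels."""
        n = len(self.genet_id)
        return (self.n_genets - 1) / (n - 1)


def _dirichlet_bn(rng: np.random.Generator, p: np.ndarray, theta: float) -> np.ndarray:
    """One multi-allele Balding–Nichols draw around frequency vector p."""
    if theta <= 0:
        return p.copy()
    conc = p * (1 - theta) / theta
    # guard against zero concentration entries (numpy requires > 0)
    conc = np.maximum(conc, 1e-9)
    return rng.dirichlet(conc)


def simulate_genotypes(spec: GenotypeSimSpec) -> tuple[GenotypeTable, GenotypeTruth]:
    """Draw a multi-site genotype table and its truth record."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L, A = spec.n_loci, spec.alleles_per_locus

    ancestral = rng.dirichlet(np.full(A, spec.dirichlet_alpha), size=L)  # (L, A)

    groups = None
    if spec.site_groups is not None and spec.theta_between is not None:
        groups = np.asarray(spec.site_groups)
        uniq = np.unique(groups)
        group_freqs = {
            g: np.stack([_dirichlet_bn(rng, ancestral[l], spec.theta_between) for l in range(L)])
            for g in uniq
        }
        site_freqs = np.stack(
            [
                np.stack([_dirichlet_bn(rng, group_freqs[groups[s]][l], spec.theta) for l in range(L)])
                for s in range(spec.n_sites)
            ]
        )
    else:
        site_freqs = np.stack(
            [
                np.stack([_dirichlet_bn(rng, ancestral[l], spec.theta) for l in range(L)])
                for s in range(spec.n_sites)
            ]
        )

    # allele sizes: even integers in a locus-specific range (dinucleotide-like)
    allele_sizes = np.stack([100 + 10 * l + 2 * np.arange(A) for l in range(L)])  # (L, A)

    n_total = spec.n_sites * spec.samples_per_site
    alleles = np.zeros((n_total, L, 2), dtype=np.int64)
    sample_id = np.empty(n_total, dtype=object)
    site_id = np.empty(n_total, dtype=object)
    clone_donor = np.full(n_total, -1, dtype=np.int64)
    genet_id = np.zeros(n_total, dtype=np.int64)

    row = 0
    genet_counter = 0
    f_draw = max(spec.f, 0.0)
    for s in range(spec.n_sites):
        site = f"S{s + 1:02d}"
        site_rows: list[int] = []
        for k in range(spec.samples_per_site):
            sample_id[row] = f"{site}_{k + 1:03d}"
            site_id[row] = site
            if site_rows and rng.random() < spec.clonality:
                donor = site_rows[rng.integers(len(site_rows))]
                alleles[row] = alleles[donor]
                clone_donor[row] = donor
                genet_id[row] = genet_id[donor]
            else:
                for l in range(L):
                    p = site_freqs[s, l]
                    if f_draw > 0 and rng.random() < f_draw:
                        a = rng.choice(A, p=p)
                        pair = (a, a)
                    else:
                        pair = tuple(rng.choice(A, size=2, p=p))
                    alleles[row, l, 0] = allele_sizes[l, pair[0]]
                    alleles[row, l, 1] = allele_sizes[l, pair[1]]
                genet_id[row] = genet_counter
                genet_counter += 1
            site_rows.append(row)
            row += 1

    if spec.missing_rate > 0:
        drop = rng.random((n_total, L)) < spec.missing_rate
        alleles[drop] = 0

    table = GenotypeTable(
        sample_id=sample_id,
        site_id=site_id,
        locus_names=[f"L{l + 1:02d}" for l in range(L)],
        alleles=alleles,
    )
    truth = GenotypeTruth(
        theta=spec.theta,
        f=spec.f,
        clonality=spec.clonality,
        site_freqs=site_freqs,
        ancestral_freqs=ancestral,
        clone_donor=clone_donor,
        genet_id=genet_id,
        site_groups=groups,
    )
    return table, truth


# --------------------------------------------------------- velocity field

@dataclass
class FieldSimSpec:
    """Parameters of the gridded surface-current generator.

    The grid is planar (meters) with 2 km default spacing, mirroring a
    fine-scale coastal hydrodynamic hindcast; velocities are hourly.
    """

    nx: int = 50
    ny: int = 50
    dx: float = 2000.0  # m
    duration_h: int = 240
    preset: str = "uniform"  # uniform | solid_rotation | tidal_channel
    u0: float = 0.0  # residual flow, m/s
    v0: float = 0.0
    tidal_amplitude: float = 0.0  # U_t, m/s
    tidal_period_h: float = 12.0
    tidal_axis: tuple[float, float] = (1.0, 0.0)
    omega: float = 0.0  # rad/s for solid rotation
    land_mask: np.ndarray | None = None  # (ny, nx) bool, True = land
    seed: int = 0

    def validate(self) -> None:
        if self.dx <= 0:
            raise ValidationError("grid spacing must be positive")
        if self.tidal_period_h <= 0:
            raise ValidationError("tidal period must be positive")
        if self.duration_h < 1:
            raise ValidationError("duration must be at least 1 hour")
        if self.land_mask is not None and self.land_mask.shape != (self.ny, self.nx):
            raise ValidationError("land mask dimensions must match grid")


def simulate_velocity_field(spec: FieldSimSpec) -> xr.Dataset:
    """Build an hourly gridded velocity field as an xarray Dataset.

    Variables ``u``, ``v`` (m/s; dims time, y, x) and ``mask`` (bool,
    dims y, x; True on land).  Land cells carry zero velocity.
    """
    spec.validate()
    x = (np.arange(spec.nx) + 0.5) * spec.dx
    y = (np.arange(spec.ny) + 0.5) * spec.dx
    t = np.arange(spec.duration_h + 1, dtype=float)  # hours, inclusive end
    mask = (
        spec.land_mask.astype(bool)
        if spec.land_mask is not None
        else np.zeros((spec.ny, spec.nx), dtype=bool)
    )

    X, Y = np.meshgrid(x, y)
    nt = len(t)
    u = np.zeros((nt, spec.ny, spec.nx))
    v = np.zeros((nt, spec.ny, spec.nx))

    if spec.preset == "uniform":
        u += spec.u0
        v += spec.v0
    elif spec.preset == "solid_rotation":
        xc, yc = x.mean(), y.mean()
        u += -spec.omega * (Y - yc)
        v += spec.omega * (X - xc)
    elif spec.preset == "tidal_channel":
        ax = np.asarray(spec.tidal_axis, dtype=float)
        ax = ax / np.hypot(*ax)
        tide = spec.tidal_amplitude * np.sin(2 * np.pi * t * 3600 / (spec.tidal_period_h * 3600))
        u += spec.u0 + tide[:, None, None] * ax[0]
        v += spec.v0 + tide[:, None, None] * ax[1]
    else:
        raise ValidationError(f"unknown field preset {spec.preset!r}")

    u[:, mask] = 0.0
    v[:, mask] = 0.0

    return xr.Dataset(
        {
            "u": (("time", "y", "x"), u),
            "v": (("time", "y", "x"), v),
            "mask": (("y", "x"), mask),
        },
        coords={"time": t, "y": y, "x": x},
        attrs={"dx": spec.dx, "crs": "planar"},
    )


# ----------------------------------------------------------- environment

# per-group habitat profiles used in "grouped" mode; supports are disjoint
# so between-group environmental dissimilarity is forced above within-group
_GROUP_PROFILES = [
    dict(sediment=("granule", "pebble"), habitat="reef terrace", depth=(0.0, 1.0),
         coral_p=0.1, seagrass_lam=0.3),
    dict(sediment=("sand", "silt"), habitat="reef lagoon", depth=(3.0, 5.0),
         coral_p=0.9, seagrass_lam=2.5),
    dict(sediment=("boulder", "cobble"), habitat="reef terrace", depth=(1.5, 2.5),
         coral_p=0.5, seagrass_lam=1.2),
]


def simulate_environment(
    sites: SiteTable,
    association: str = "none",
    groups: Sequence[int] | None = None,
    seed: int = 0,
) -> EnvironmentTable:
    """Draw per-site habitat covariates.

    ``association="none"`` draws every site from one common distribution;
    ``"grouped"`` gives each declared site group a distinct profile with
    disjoint sediment/habitat supports, so environmental dissimilarity
    aligns with the groups.
    """
    rng = np.random.default_rng(seed)
    n = len(sites)
    if association not in ("none", "grouped"):
        raise ValidationError("association must be 'none' or 'grouped'")
    if association == "grouped":
        if groups is None:
            raise ValidationError("grouped association requires site groups")
        groups = np.asarray(groups)
        if len(groups) != n:
            raise ValidationError("groups length must match site table")

    rows = []
    for i, sid in enumerate(sites.site_ids):
        if association == "grouped":
            prof = _GROUP_PROFILES[int(groups[i]) % len(_GROUP_PROFILES)]
            sediment = prof["sediment"][rng.integers(len(prof["sediment"]))]
            habitat = prof["habitat"]
            depth = float(np.round(rng.uniform(*prof["depth"]), 1))
            coral = bool(rng.random() < prof["coral_p"])
            n_sg = int(min(rng.poisson(prof["seagrass_lam"]), 3))
        else:
            sediment = WENTWORTH_CLASSES[rng.integers(len(WENTWORTH_CLASSES))]
            habitat = HABITAT_CLASSES[rng.integers(len(HABITAT_CLASSES))]
            depth = float(np.round(rng.uniform(0.0, 5.0), 1))
            coral = bool(rng.random() < 0.5)
            n_sg = int(min(rng.poisson(1.5), 3))
        rows.append(
            dict(site_id=sid, depth=depth, sediment=sediment, habitat=habitat,
                 n_other_seagrass=n_sg, coral_present=coral)
        )
    return EnvironmentTable(data=pd.DataFrame(rows))
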