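"""End-to-end orchestration: genotypes to variance partitioning.

``run_full_analysis`` executes the whole workflow — clone filtering,
per-site diversity, F_ST and its linearization, dispersal-based
connectivity, network metrics and their PCA (OC), overwater distances and
PCNM (GD), habitat Gower/CA (EN), the Mantel suite, and the partial-RDA
variance partitioning GS ~ GD + OC + EN — on either user-supplied inputs
or a simulated scenario.  Stages communicate only through the typed
artifacts of the other modules, and every stochastic stage derives its
seed from the single configured seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import clonal, dispersal, fstats, network, varpart
from .io import RunLog, write_genotypes, write_matrix
from .simulate import (
    FieldSimSpec,
    GenotypeSimSpec,
    simulate_environment,
    simulate_genotypes,
    simulate_velocity_field,
)
from .types import (
    AnalysisConfig,
    DirectedMatrix,
    DistanceMatrix,
    EnvironmentTable,
    GenotypeTable,
    SiteTable,
    ValidationError,
)

__all__ = ["SimulationScenario", "RunReport", "simulate_scenario", "run_full_analysis"]


@dataclass
class SimulationScenario:
    """A complete synthetic study: sites, genotypes, currents, habitat.

    The default emulates the study conditions this pipeline targets:
    12 sites at ~48 ramets each over an ~80 km coastal domain, 16
    microsatellite loci, hierarchical differentiation between two site
    groups laid out so group membership alternates along the coast
    (spatially interleaved rather than contiguous), grouped habitat
    covariates, and group-structured dispersal connectivity with average
    particle counts in the 0-7.5 per-release range.
    """

    n_sites: int = 12
    samples_per_site: int = 48
    n_loci: int = 16
    theta_within: float = 0.02
    theta_between: float = 0.15
    inbreeding_f: float = 0.1
    clonality: float = 0.4
    missing_rate: float = 0.02
    domain_km: float = 80.0
    grid_dx_m: float = 2000.0
    #: "particles" runs the Lagrangian simulation; "grouped" draws the
    #: connectivity matrix directly from the group structure
    connectivity_mode: str = "particles"
    n_releases: int = 3
    particles_per_release: int = 30
    env_association: str = "grouped"
    seed: int = 0

    def groups(self) -> np.ndarray:
        # alternating along the transect: spatially interleaved groups
        return np.arange(self.n_sites) % 2

    def site_table(self) -> SiteTable:
        rng = np.random.default_rng(self.seed + 7)
        span = self.domain_km * 1000.0
        # irregular coastal transect with cross-shore scatter
        t = np.sort(rng.uniform(0.08, 0.92, self.n_sites))
        x = t * span
        y = span / 2 + rng.uniform(-0.12, 0.12, self.n_sites) * span
        return SiteTable(
            data=pd.DataFrame(
                {
                    "site_id": [f"S{i + 1:02d}" for i in range(self.n_sites)],
                    "x": x,
                    "y": y,
                    "region": np.where(self.groups() == 0, "north", "south"),
                }
            ),
            crs="planar",
        )


@dataclass
class RunReport:
    """All pipeline outputs plus the seeds that produced them."""

    genotypes: GenotypeTable
    sites: SiteTable
    environment: EnvironmentTable
    diversity: pd.DataFrame
    fst: fstats.FstResult
    linearized_fst: DistanceMatrix
    connectivity: DirectedMatrix
    network_metrics: pd.DataFrame
    gs_block: pd.DataFrame
    gd_block: pd.DataFrame
    oc_block: pd.DataFrame
    en_block: pd.DataFrame
    overwater: DistanceMatrix
    gower_env: DistanceMatrix
    mantel: dict[str, tuple[float, float]]
    varpart: varpart.VarpartResult
    analyzed_sites: list[str]
    excluded_sites: list[str]
    seeds: dict[str, int] = field(default_factory=dict)
    truth: object | None = None

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes(self.genotypes, out / "genotypes.csv")
        self.sites.data.to_csv(out / "sites.csv", index=False)
        self.environment.data.to_csv(out / "environment.csv", index=False)
        self.diversity.to_csv(out / "diversity_by_site.csv", index=False)
        write_matrix(self.fst.pairwise, out / "pairwise_fst.csv")
        write_matrix(self.linearized_fst, out / "linearized_fst.csv")
        write_matrix(self.connectivity, out / "connectivity.csv")
        write_matrix(self.overwater, out / "overwater_km.csv")
        write_matrix(self.gower_env, out / "gower_env.csv")
        self.network_metrics.to_csv(out / "network_metrics.csv")
        for name, block in (
            ("gs", self.gs_block), ("gd", self.gd_block),
            ("oc", self.oc_block), ("en", self.en_block),
        ):
            block.to_csv(out / f"block_{name}.csv")
        self.varpart.table().to_csv(out / "varpart_table.csv", index=False)
        pd.DataFrame(
            [(k, r, p) for k, (r, p) in self.mantel.items()],
            columns=["comparison", "r", "p"],
        ).to_csv(out / "mantel_tests.csv", index=False)


def _grouped_connectivity(
    sites: SiteTable, groups: np.ndarray, seed: int,
    isolated_within=(0.2, 1.2), connected_within=(3.0, 7.5), between=(0.0, 0.3),
) -> DirectedMatrix:
    """Directed connectivity drawn from the group structure.

    Group 0 is oceanographically isolated (weak exchange even among its
    own sites), group 1 well connected internally, and between-group
    exchange minimal — the qualitative structure in which an isolated
    site cluster coincides with a distinct genetic cluster.  Magnitudes
    sit on the 0-7.5 average-particles-per-release scale.
    """
    rng = np.random.default_rng(seed)
    n = len(sites)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if groups[i] != groups[j]:
                lo, hi = between
            elif groups[i] == 0:
                lo, hi = isolated_within
            else:
                lo, hi = connected_within
            vals[i, j] = rng.uniform(lo, hi)
    return DirectedMatrix(site_ids=sites.site_ids, values=vals)


def simulate_scenario(scenario: SimulationScenario):
    """Generate all inputs for one synthetic study.

    Returns (genotypes, truth, sites, environment, connectivity-or-None,
    field-or-None): in "particles" mode the velocity field is returned and
    connectivity is left for the dispersal stage; in "grouped" mode the
    connectivity matrix is returned directly.
    """
    groups = scenario.groups()
    sites = scenario.site_table()
    gspec = GenotypeSimSpec(
        n_sites=scenario.n_sites,
        samples_per_site=scenario.samples_per_site,
        n_loci=scenario.n_loci,
        theta=scenario.theta_within,
        theta_between=scenario.theta_between,
        site_groups=groups,
        f=scenario.inbreeding_f,
        clonality=scenario.clonality,
        missing_rate=scenario.missing_rate,
        seed=scenario.seed,
    )
    genotypes, truth = simulate_genotypes(gspec)
    env = simulate_environment(
        sites, association=scenario.env_association,
        groups=groups if scenario.env_association == "grouped" else None,
        seed=scenario.seed + 1,
    )
    connectivity = None
    fld = None
    if scenario.connectivity_mode == "grouped":
        connectivity = _grouped_connectivity(sites, groups, scenario.seed + 2)
    elif scenario.connectivity_mode == "particles":
        span_cells = int(np.ceil(scenario.domain_km * 1000 / scenario.grid_dx_m))
        duration = 24 * 3 * (scenario.n_releases - 1) + 169
        fld = simulate_velocity_field(
            FieldSimSpec(
                nx=span_cells, ny=span_cells, dx=scenario.grid_dx_m,
                duration_h=duration, preset="tidal_channel",
                u0=0.05, v0=0.02, tidal_amplitude=0.8, tidal_period_h=12.0,
                seed=scenario.seed + 3,
            )
        )
    else:
        raise ValidationError("connectivity_mode must be 'particles' or 'grouped'")
    return genotypes, truth, sites, env, connectivity, fld


def run_full_analysis(
    config: AnalysisConfig,
    scenario: SimulationScenario | None = None,
    genotypes: GenotypeTable | None = None,
    sites: SiteTable | None = None,
    environment: EnvironmentTable | None = None,
    connectivity: DirectedMatrix | None = None,
    velocity_field: xr.Dataset | None = None,
    write: bool = False,
) -> RunReport:
    """Execute the full workflow and return a RunReport.

    Either pass a SimulationScenario (inputs are generated) or the actual
    inputs (genotypes + sites + environment, plus a connectivity matrix or
    a velocity field for the dispersal stage).
    """
    log = RunLog(Path(config.outdir) / "run.log" if write else None)
    truth = None
    if scenario is not None:
        scenario = SimulationScenario(**{**scenario.__dict__, "seed": scenario.seed or config.seed})
        genotypes, truth, sites, environment, connectivity, velocity_field = simulate_scenario(scenario)
        log.record("simulate", seed=scenario.seed, n_sites=scenario.n_sites)
    if genotypes is None or sites is None or environment is None:
        raise ValidationError("need genotypes, sites and environment (or a scenario)")

    # ---- clone filtering
    partition = clonal.identify_mlgs(genotypes, missing_policy=config.missing_policy)
    cc = clonal.clone_correct(genotypes, partition)
    g_by_site = partition.g_by_site()
    analyzed = [s for s in genotypes.sites if g_by_site.get(s, 0) >= config.min_mlg_per_site]
    excluded = [s for s in genotypes.sites if s not in analyzed]
    if excluded:
        warnings.warn(f"sites excluded for low MLG counts: {excluded}")
    if len(analyzed) < 4:
        raise ValidationError("fewer than 4 analyzable sites")
    log.record("mlg_filter", policy=config.missing_policy, analyzed=len(analyzed), excluded=len(excluded))

    # ---- diversity (Table-1 analogue)
    div_seed = config.stage_seed("diversity")
    diversity = clonal.site_diversity_table(
        genotypes, partition, rarefaction_g=tuple(config.rarefaction_g),
        n_perm=min(config.n_perm_fst, 199), seed=div_seed,
    )
    log.record("diversity", seed=div_seed)

    # ---- F_ST
    cc_analyzed = cc.subset(np.isin(cc.site_id, analyzed))
    fst_seed = config.stage_seed("fst")
    fst_res = fstats.fst(
        cc_analyzed, estimator="weir_cockerham",
        n_perm=config.n_perm_fst, seed=fst_seed, pairwise_perm=False,
    )
    lin = fstats.linearize_fst(fst_res.pairwise)
    log.record("fst", seed=fst_seed, global_theta=fst_res.global_theta, p=fst_res.global_p)

    # ---- connectivity
    disp_seed = config.stage_seed("dispersal")
    if connectivity is None:
        if velocity_field is None:
            raise ValidationError("need a connectivity matrix or a velocity field")
        schedule = dispersal.ReleaseSchedule.uniform(
            0.0,
            float(velocity_field["time"].values[-1]) - 169.0,
            24.0 * config.release_interval_days,
            particles_per_release=config.particles_per_release,
        )
        counts = dispersal.run_releases(velocity_field, sites, schedule, seed=disp_seed)
        connectivity = dispersal.connectivity_matrix(counts, sites.site_ids, diagonal_policy="zero")
    log.record("connectivity", seed=disp_seed)
    conn_sub = connectivity.subset(analyzed)

    # ---- predictor block width: 3 axes per block where the site count
    # allows (>= 11 sites leaves residual df >= 1, as in the study
    # design), fewer for smaller panels
    k_axes = min(3, max(1, (len(analyzed) - 2) // 3))

    # ---- OC block: network metrics + PCA
    metrics = network.network_metrics(conn_sub).table
    oc = network.pca_block(metrics, n_axes=k_axes).scores
    log.record("oc_block", axes=oc.shape[1])

    # ---- GD block: overwater distance + PCNM
    if velocity_field is not None:
        mask = velocity_field["mask"].values
        dx = float(velocity_field.attrs["dx"])
        overwater = dispersal.overwater_distance(mask, sites, cell_size_m=dx)
    else:
        # no raster: open-water straight-line distances
        xy = sites.coords
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(axis=2)) / 1000.0
        overwater = DistanceMatrix(site_ids=sites.site_ids, values=d)
    ow_sub = overwater.subset(analyzed)
    pcnm_axes, _ = varpart.pcnm(ow_sub)
    log.record("gd_block", candidates=pcnm_axes.shape[1])

    # ---- GS block: PCoA of linearized F_ST
    gs = varpart.pcoa(lin).coordinates
    gd = varpart.select_predictor_axes(pcnm_axes, gs, rule="first_k", k=min(k_axes, pcnm_axes.shape[1]))

    # ---- EN block: Gower (for Mantel) + CA axes
    env_sub = EnvironmentTable(
        data=environment.data[environment.data["site_id"].isin(analyzed)].copy()
    )
    gow = varpart.gower(env_sub)
    ca_scores, _ = varpart.correspondence_analysis(varpart.encode_environment(env_sub))
    en = ca_scores.iloc[:, : min(k_axes, ca_scores.shape[1])]
    log.record("en_block", axes=en.shape[1])

    # ---- Mantel suite
    mantel_seed = config.stage_seed("mantel")
    pair_sum = conn_sub.values + conn_sub.values.T  # total particles per site pair
    np.fill_diagonal(pair_sum, 0.0)
    conn_pair = DistanceMatrix(site_ids=analyzed, values=pair_sum)
    mantel_res = {
        "linFST~overwater": varpart.mantel(lin, ow_sub, config.n_perm_mantel, mantel_seed),
        "linFST~connectivity": varpart.mantel(lin, conn_pair, config.n_perm_mantel, mantel_seed + 1),
        "linFST~environment": varpart.mantel(lin, gow, config.n_perm_mantel, mantel_seed + 2),
    }
    log.record("mantel", seed=mantel_seed)

    # ---- variance partitioning
    vp_seed = config.stage_seed("varpart")
    vp = varpart.variation_partitioning(
        gs, {"GD": gd, "OC": oc, "EN": en}, n_perm=config.n_perm_rda, seed=vp_seed,
    )
    log.record("varpart", seed=vp_seed)

    report = RunReport(
        genotypes=genotypes, sites=sites, environment=environment,
        diversity=diversity, fst=fst_res, linearized_fst=lin,
        connectivity=connectivity, network_metrics=metrics,
        gs_block=gs, gd_block=gd, oc_block=oc, en_block=en,
        overwater=overwater, gower_env=gow, mantel=mantel_res, varpart=vp,
        analyzed_sites=analyzed, excluded_sites=excluded,
        seeds=dict(diversity=div_seed, fst=fst_seed, dispersal=disp_seed,
                   mantel=mantel_seed, varpart=vp_seed),
        truth=truth,
    )
    if write:
        report.write(config.outdir)
    return report
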