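"""Readers and writers for all tabular inputs and outputs.

Genotypes travel in the GenAlEx codominant CSV dialect (three header rows:
counts; title and population names; locus names over paired allele
columns).  Site and environment tables and all matrices are plain labeled
CSV.  A line-oriented run log records seeds and the provenance of every
file written.
"""

from __future__ import annotations

import csv
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    AnalysisConfig,
    DirectedMatrix,
    DistanceMatrix,
    EnvironmentTable,
    GenotypeTable,
    SiteTable,
    ValidationError,
    MISSING,
)


class FormatError(ValueError):
    """Raised on a malformed input file."""


# ---------------------------------------------------------------- genotypes

def read_genotypes(path: str | Path, dialect: str = "genalex") -> GenotypeTable:
    """Read a GenAlEx-dialect codominant CSV.

    Header row 1: n_loci, n_samples, n_pops, size_pop1, size_pop2, ...
    Header row 2: dataset title (population names may follow from col 4).
    Header row 3: Sample, Pop, locus names over paired allele columns.
    Missing alleles are coded 0.
    """
    if dialect != "genalex":
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise FormatError("GenAlEx file needs 3 header rows and at least 1 sample")
    try:
        n_loci = int(rows[0][0])
        n_samples = int(rows[0][1])
    except (ValueError, IndexError) as exc:
        raise FormatError("malformed GenAlEx count header") from exc

    header = rows[2]
    locus_cells = header[2:]
    # locus names sit over the first column of each allele pair
    n_pairs = len(locus_cells) // 2
    if len(locus_cells) % 2 != 0:
        # trailing blank columns are tolerated; odd allele columns are not
        trailing = [c for c in locus_cells[n_pairs * 2:] if c.strip()]
        if trailing:
            raise FormatError("odd number of allele columns")
    locus_names = [locus_cells[2 * i].strip() for i in range(n_pairs)]
    locus_names = [nm for nm in locus_names if nm]
    if len(locus_names) != n_loci:
        raise FormatError(
            f"header declares {n_loci} loci but {len(locus_names)} locus columns found"
        )

    sample_id, site_id, alleles = [], [], []
    for raw in rows[3:]:
        if not any(cell.strip() for cell in raw):
            continue
        if len(raw) < 2 + 2 * n_loci:
            raise FormatError(f"data row for {raw[0]!r} has too few allele columns")
        sample_id.append(raw[0].strip())
        site_id.append(raw[1].strip())
        vals = []
        for cell in raw[2 : 2 + 2 * n_loci]:
            cell = cell.strip()
            if cell == "":
                vals.append(MISSING)
                continue
            try:
                vals.append(int(cell))
            except ValueError as exc:
                raise FormatError(f"non-integer allele value {cell!r}") from exc
        alleles.append(np.array(vals).reshape(n_loci, 2))
    if len(sample_id) != n_samples:
        raise FormatError(
            f"header declares {n_samples} samples but {len(sample_id)} data rows found"
        )
    table = GenotypeTable(
        sample_id=np.array(sample_id, dtype=object),
        site_id=np.array(site_id, dtype=object),
        locus_names=locus_names,
        alleles=np.stack(alleles),
    )
    return table


def write_genotypes(table: GenotypeTable, path: str | Path, title: str = "seascapegen export") -> None:
    """Write a GenotypeTable as GenAlEx codominant CSV (inverse of read_genotypes)."""
    path = Path(path)
    sites = table.sites
    pop_sizes = [int((table.site_id == s).sum()) for s in sites]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([table.n_loci, table.n_samples, len(sites), *pop_sizes])
        w.writerow([title, "", "", *sites])
        header = ["Sample", "Pop"]
        for nm in table.locus_names:
            header.extend([nm, ""])
        w.writerow(header)
        for i in range(table.n_samples):
            row = [table.sample_id[i], table.site_id[i]]
            row.extend(int(a) for a in table.alleles[i].ravel())
            w.writerow(row)


# ------------------------------------------------------- site / environment

def read_site_table(path: str | Path, crs: str | None = None) -> SiteTable:
    """Read a site CSV with columns site_id, x (or lon), y (or lat), region.

    ``crs`` may be given explicitly; otherwise lon/lat column names imply
    geographic mode and x/y imply planar meters.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "lon" in cols and "lat" in cols:
        df = df.rename(columns={cols["lon"]: "x", cols["lat"]: "y"})
        inferred = "lonlat"
    elif "x" in cols and "y" in cols:
        inferred = "planar"
    else:
        raise FormatError("site table needs lon/lat or x/y columns")
    if "region" not in df.columns:
        df["region"] = "all"
    return SiteTable(data=df[["site_id", "x", "y", "region"]].copy(), crs=crs or inferred)


def read_environment_table(path: str | Path) -> EnvironmentTable:
    df = pd.read_csv(path)
    if "coral_present" in df.columns:
        df["coral_present"] = df["coral_present"].astype(bool)
    return EnvironmentTable(data=df)


# ---------------------------------------------------------------- matrices

def write_matrix(m: DistanceMatrix | DirectedMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, index_label="site_id")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(site_ids=[str(s) for s in df.index], values=df.to_numpy(dtype=float))


def read_directed_matrix(path: str | Path) -> DirectedMatrix:
    df = pd.read_csv(path, index_col=0)
    return DirectedMatrix(site_ids=[str(s) for s in df.index], values=df.to_numpy(dtype=float))


# ------------------------------------------------------------ config / log

def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    cfg = AnalysisConfig(**kwargs)
    cfg.extra.update(extra)
    return cfg


class RunLog:
    """Line-oriented run log: timestamps, seeds, and output-file provenance."""

    def __init__(self, path: str | Path | None):
        self.path = Path(path) if path is not None else None
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("")

    def record(self, stage: str, **fields) -> None:
        entry = {"time": datetime.datetime.now().isoformat(timespec="seconds"), "stage": stage}
        entry.update({k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v)) for k, v in fields.items()})
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
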