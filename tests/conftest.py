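"""Shared fixtures: small genotype tables built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seascapegen.types import EnvironmentTable, GenotypeTable, SiteTable


def make_genotypes(alleles, sites=None, locus_names=None) -> GenotypeTable:
    """Build a GenotypeTable from a nested list (n, L, 2) of allele sizes."""
    alleles = np.asarray(alleles, dtype=np.int64)
    n = alleles.shape[0]
    sites = sites if sites is not None else ["A"] * n
    locus_names = locus_names or [f"L{i + 1}" for i in range(alleles.shape[1])]
    return GenotypeTable(
        sample_id=np.array([f"s{i + 1}" for i in range(n)], dtype=object),
        site_id=np.array(sites, dtype=object),
        locus_names=locus_names,
        alleles=alleles,
    )


@pytest.fixture
def toy_two_sites() -> GenotypeTable:
    """Two sites fixed for different alleles at both loci (F_ST = 1)."""
    a = [[[100, 100], [200, 200]]] * 4 + [[[102, 102], [202, 202]]] * 4
    return make_genotypes(a, sites=["A"] * 4 + ["B"] * 4)


@pytest.fixture
def site_table_planar() -> SiteTable:
    return SiteTable(
        data=pd.DataFrame(
            {
                "site_id": ["A", "B", "C", "D"],
                "x": [1000.0, 5000.0, 9000.0, 13000.0],
                "y": [2000.0, 2500.0, 1800.0, 2200.0],
                "region": ["w", "w", "e", "e"],
            }
        ),
        crs="planar",
    )


@pytest.fixture
def env_table() -> EnvironmentTable:
    return EnvironmentTable(
        data=pd.DataFrame(
            {
                "site_id": ["A", "B", "C", "D"],
                "depth": [0.0, 5.0, 2.0, 3.0],
                "sediment": ["sand", "sand", "granule", "silt"],
                "habitat": ["reef terrace", "reef lagoon", "reef lagoon", "reef terrace"],
                "n_other_seagrass": [0, 3, 1, 2],
                "coral_present": [False, True, True, False],
            }
        )
    )
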