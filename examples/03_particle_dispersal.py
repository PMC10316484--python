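"""Propagule dispersal on a tidal velocity field -> connectivity matrix.

Builds an hourly synthetic current field (residual drift + tidal
sinusoid), releases particles at three sites on a 3-day schedule, tracks
them with hourly RK4 updates and a 1 m^2/s random walk for 7 days, and
averages detections in 500 m site cells into the directed connectivity
matrix.  Asymmetry (A->B != B->A) reflects the residual drift direction.
"""

import numpy as np
import pandas as pd

from seascapegen.dispersal import ReleaseSchedule, connectivity_matrix, run_releases
from seascapegen.simulate import FieldSimSpec, simulate_velocity_field
from seascapegen.types import SiteTable

field = simulate_velocity_field(
    FieldSimSpec(nx=40, ny=20, dx=2000.0, duration_h=320, preset="tidal_channel",
                 u0=0.05, v0=0.0, tidal_amplitude=0.8, tidal_period_h=12.0)
)
sites = SiteTable(
    data=pd.DataFrame({
        "site_id": ["west", "mid", "east"],
        "x": [12_000.0, 40_000.0, 66_000.0],
        "y": [20_000.0, 21_000.0, 20_000.0],
        "region": ["w", "m", "e"],
    }),
    crs="planar",
)
schedule = ReleaseSchedule.uniform(0.0, 144.0, 72.0, particles_per_release=100)
counts = run_releases(field, sites, schedule, diffusivity=1.0, seed=3)
conn = connectivity_matrix(counts, sites.site_ids, diagonal_policy="zero")

print("average particles per release from row site detected at column site:")
print(conn.to_frame().round(2).to_string())
down = conn.values[0, 1] + conn.values[1, 2]
up = conn.values[1, 0] + conn.values[2, 1]
print(f"\ndownstream total {down:.1f} vs upstream {up:.1f}: the 0.05 m/s "
      "residual drift makes exchange directional even under strong tides.")
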