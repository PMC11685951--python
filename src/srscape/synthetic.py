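"""Synthetic landscapes with known truth for end-to-end testing.

The generator mimics the statistical structure bioavailable-Sr isoscapes
assume: a blocky "geology" (Voronoi terranes whose age drives the Sr
baseline, old terranes being more radiogenic), smooth climate-like
covariates (an aeolian-dust field that depresses ratios, precipitation
with a mild positive effect, elevation), a categorical lithology layer,
and within-cell sampling noise on top of the true cell means.  It makes
no attempt to reproduce real African geography or the real predictors'
distributions - only the block-plus-smooth spatial character that makes
recovery measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .assignment import water_to_carb_vpdb
from .grid import GridSpec, PredictorStack, Raster, SampleTable


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic landscape.

    Defaults are the standing conditions every recovery experiment uses:
    a 200 x 200 grid, 800 sample sites, 100 individuals and 0.002
    within-cell sampling noise (about the natural 87Sr/86Sr scatter among
    substrates within one cell).  Block mean ratios span 0.705-0.735 and
    the truth surface is clipped to the plausible bioavailable window
    [0.703, 0.88].
    """

    n_rows: int = 200
    n_cols: int = 200
    n_geology_blocks: int = 12
    n_lithology_classes: int = 6
    smoothness: float = 8.0          # gaussian sigma of smooth fields, in cells
    sr_base: tuple[float, float] = (0.705, 0.735)
    dust_effect: float = 0.008       # max depression of the Sr ratio by dust
    precip_effect: float = 0.003     # max elevation of the Sr ratio by rain
    smooth_sd: float = 0.002         # sd of the smooth truth-noise term
    within_cell_sd: float = 0.002    # sampling noise sd, 87Sr/86Sr units
    n_samples: int = 800
    n_individuals: int = 100
    seed: int = 0
    cell_size: float = 0.05          # decimal degrees
    x_min: float = 10.0
    y_max: float = 5.0
    crs: str = "EPSG:4326"

    @property
    def grid_spec(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            x_min=self.x_min,
            y_max=self.y_max,
            cell_size=self.cell_size,
            crs=self.crs,
        )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


SR_CLIP = (0.703, 0.88)


def _voronoi_labels(shape, n_blocks, rng) -> np.ndarray:
    rows, cols = np.indices(shape)
    points = np.column_stack([rows.ravel(), cols.ravel()])
    centers = np.column_stack(
        [rng.uniform(0, shape[0], n_blocks), rng.uniform(0, shape[1], n_blocks)]
    )
    _, labels = cKDTree(centers).query(points)
    return labels.reshape(shape)


def _smooth01(shape, sigma, rng) -> np.ndarray:
    """Smoothed Gaussian field rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def make_landscape(config: SyntheticConfig) -> tuple[PredictorStack, Raster]:
    """Build the predictor stack and the true Sr mean surface.

    The truth is a monotone function of terrane age minus a dust term
    plus small precipitation and smooth-noise terms, clipped to the
    plausible range; it is fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    spec = config.grid_spec

    geology = _voronoi_labels(shape, config.n_geology_blocks, rng)
    block_u = rng.uniform(0.0, 1.0, config.n_geology_blocks)
    age_u = block_u[geology]
    terrane_age = 200.0 + 3300.0 * age_u  # Ma

    dust01 = _smooth01(shape, config.smoothness, rng)
    precip01 = _smooth01(shape, config.smoothness, rng)
    elev01 = _smooth01(shape, config.smoothness, rng)
    smooth_noise = gaussian_filter(rng.standard_normal(shape), config.smoothness / 2, mode="reflect")
    sd = smooth_noise.std()
    if sd > 0:
        smooth_noise = smooth_noise / sd

    lithology = _voronoi_labels(shape, config.n_lithology_classes, rng).astype(float)

    lo, hi = config.sr_base
    truth = (
        lo
        + (hi - lo) * age_u
        - config.dust_effect * dust01
        + config.precip_effect * precip01
        + config.smooth_sd * smooth_noise
    )
    truth = np.clip(truth, *SR_CLIP)

    stack = PredictorStack(
        layers={
            "terrane_age": terrane_age,
            "dust": 50.0 * dust01,            # g m-2 yr-1, arbitrary plausible scale
            "precipitation": 400.0 + 1800.0 * precip01,  # mm yr-1
            "elevation": 1200.0 * elev01,     # m
            "lithology": lithology,
        },
        kinds={
            "terrane_age": "continuous",
            "dust": "continuous",
            "precipitation": "continuous",
            "elevation": "continuous",
            "lithology": "categorical",
        },
        spec=spec,
    )
    return stack, Raster(truth, spec)


def sample_sites(
    truth: Raster,
    n: int,
    within_cell_sd: float,
    seed: int,
    jitter: bool = True,
) -> SampleTable:
    """Draw ``n`` sample sites uniformly over valid cells.

    Duplicate cells are allowed (no aggregation of co-located samples).
    Observed ratios are truth plus Normal(0, within_cell_sd) noise;
    coordinates are jittered uniformly within the cell so that points,
    not just cells, carry distinct locations.
    """
    rng = np.random.default_rng(seed)
    spec = truth.spec
    valid_rows, valid_cols = np.nonzero(truth.valid)
    if n > 0 and valid_rows.size == 0:
        raise ValueError("truth surface has no valid cells")
    pick = rng.integers(0, valid_rows.size, n) if n > 0 else np.array([], dtype=int)
    rows, cols = valid_rows[pick], valid_cols[pick]
    x, y = spec.cell_center(rows, cols)
    if jitter and n > 0:
        half = spec.cell_size / 2
        x = x + rng.uniform(-half, half, n) * 0.999
        y = y + rng.uniform(-half, half, n) * 0.999
    sr = truth.values[rows, cols] + rng.normal(0.0, within_cell_sd, n)
    frame = pd.DataFrame(
        {
            "sample_id": [f"SYN{i:05d}" for i in range(n)],
            "longitude": x,
            "latitude": y,
            "sr_ratio": sr,
            "sample_type": "plant",
            "source": "new",
            "reference": "synthetic",
        }
    )
    return SampleTable(frame)


def make_oxygen_isoscape(
    spec: GridSpec,
    seed: int,
    mean_range: tuple[float, float] = (-12.0, -2.0),
    sd: float = 0.5,
    smoothness: float = 12.0,
) -> tuple[Raster, Raster]:
    """A smooth synthetic precipitation-d18O surface (VSMOW) plus its SD."""
    rng = np.random.default_rng(seed)
    field01 = _smooth01(spec.shape, smoothness, rng)
    lo, hi = mean_range
    mean = lo + (hi - lo) * field01
    return Raster(mean, spec), Raster(np.full(spec.shape, sd), spec)


def simulate_individuals(
    truth: Raster,
    m: int,
    seed: int,
    tissue_sd: float = 0.002,
    o_truth: Raster | None = None,
    o_tissue_sd: float = 0.5,
) -> pd.DataFrame:
    """Individuals with known origin cells and tissue isotope values.

    Tissue Sr is the origin cell's truth plus Normal(0, tissue_sd).  When
    an oxygen truth surface is supplied, drinking-water d18O at the
    origin (plus noise) is mapped back to enamel carbonate VPDB through
    the inverted conversion chain, so the forward conversion in
    assignment recovers it exactly.
    """
    rng = np.random.default_rng(seed)
    valid_rows, valid_cols = np.nonzero(truth.valid)
    pick = rng.integers(0, valid_rows.size, m)
    rows, cols = valid_rows[pick], valid_cols[pick]
    out = pd.DataFrame(
        {
            "individual_id": [f"IND{i:03d}" for i in range(m)],
            "sr87_sr86": truth.values[rows, cols] + rng.normal(0.0, tissue_sd, m),
            "origin_row": rows,
            "origin_col": cols,
        }
    )
    if o_truth is not None:
        water = o_truth.values[rows, cols] + rng.normal(0.0, o_tissue_sd, m)
        out["d18o_carb_vpdb"] = water_to_carb_vpdb(water)
    return out
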