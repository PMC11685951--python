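"""Continuous-surface geographic assignment from tissue isotope values.

Given an isoscape (per-cell mean mu_c and standard error sigma_c), a
measured tissue value y yields a per-cell likelihood

    L_c = Normal(y | mu_c, sqrt(sigma_c^2 + extra_sd^2))

which, multiplied by an optional spatial prior and renormalised over
valid cells, is the posterior origin surface.  A max-normalised copy
(every cell divided by the maximum) is kept for display, matching how
such surfaces are usually mapped.

Tooth-enamel carbonate d18O (VPDB) is converted to drinking-water d18O
(VSMOW) through three affine stages: carbonate VPDB -> VSMOW
(1.03091 x + 30.91), carbonate -> phosphate (0.98 x - 8.5), and
phosphate -> drinking water (1.54 x - 33.72).  The conversions carry
about 1 permil of error, added in quadrature to the water-isoscape SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .grid import AlignmentError, Raster

# carbonate VPDB -> carbonate VSMOW (Coplen)
VPDB_TO_VSMOW = (1.03091, 30.91)
# carbonate VSMOW -> phosphate VSMOW (Iacumin)
CARB_TO_PHOSPHATE = (0.98, -8.5)
# phosphate VSMOW -> drinking water VSMOW (Daux)
PHOSPHATE_TO_WATER = (1.54, -33.72)

#: default extra uncertainty (permil) for the d18O conversion chain
O18_EXTRA_SD = 1.0

#: plausible enamel-carbonate d18O window on VPDB (permil)
D18O_PLAUSIBLE = (-20.0, 10.0)


@dataclass
class ConversionResult:
    """The three stages of the enamel d18O conversion, all in permil."""

    d18o_carb_vsmow: np.ndarray | float
    d18o_phosphate_vsmow: np.ndarray | float
    d18o_water_vsmow: np.ndarray | float


def carb_vpdb_to_water(d18o_carb_vpdb) -> ConversionResult:
    """Convert enamel carbonate d18O (VPDB) to drinking-water d18O (VSMOW).

    Pure affine arithmetic; inputs outside a plausible enamel range are
    flagged with a warning but still converted.
    """
    x = np.asarray(d18o_carb_vpdb, dtype=float)
    if np.any((x < D18O_PLAUSIBLE[0]) | (x > D18O_PLAUSIBLE[1])):
        warnings.warn(
            f"d18O input outside plausible enamel range {D18O_PLAUSIBLE} permil",
            stacklevel=2,
        )
    vsmow = VPDB_TO_VSMOW[0] * x + VPDB_TO_VSMOW[1]
    phosphate = CARB_TO_PHOSPHATE[0] * vsmow + CARB_TO_PHOSPHATE[1]
    water = PHOSPHATE_TO_WATER[0] * phosphate + PHOSPHATE_TO_WATER[1]
    if np.ndim(d18o_carb_vpdb) == 0:
        return ConversionResult(float(vsmow), float(phosphate), float(water))
    return ConversionResult(vsmow, phosphate, water)


def water_to_carb_vpdb(d18o_water_vsmow):
    """Exact inverse of :func:`carb_vpdb_to_water` (affine chain inverted)."""
    w = np.asarray(d18o_water_vsmow, dtype=float)
    phosphate = (w - PHOSPHATE_TO_WATER[1]) / PHOSPHATE_TO_WATER[0]
    vsmow = (phosphate - CARB_TO_PHOSPHATE[1]) / CARB_TO_PHOSPHATE[0]
    vpdb = (vsmow - VPDB_TO_VSMOW[1]) / VPDB_TO_VSMOW[0]
    return float(vpdb) if np.ndim(d18o_water_vsmow) == 0 else vpdb


def conversion_affine() -> tuple[float, float]:
    """(slope, intercept) of the composed VPDB -> water map."""
    a1, b1 = VPDB_TO_VSMOW
    a2, b2 = CARB_TO_PHOSPHATE
    a3, b3 = PHOSPHATE_TO_WATER
    return a3 * a2 * a1, a3 * (a2 * b1 + b2) + b3


def likelihood_surface(
    y: float,
    mean: Raster,
    se: Raster,
    extra_sd: float = 0.0,
) -> Raster:
    """Per-cell normal likelihood of a tissue value under the isoscape.

    Masked (NaN) cells get zero likelihood.  ``extra_sd`` is combined in
    quadrature with the isoscape SE.
    """
    if not mean.spec.matches(se.spec):
        raise AlignmentError("mean and SE rasters are not on one grid")
    if extra_sd < 0:
        raise ValueError("extra_sd must be >= 0")
    mu = mean.values.astype(float)
    sd = np.sqrt(se.values.astype(float) ** 2 + extra_sd**2)
    valid = ~(np.isnan(mu) | np.isnan(sd))
    out = np.zeros(mean.spec.shape)
    zero_sd = valid & (sd == 0)
    pos = valid & (sd > 0)
    if not pos.any():
        # fully degenerate surface: point masses on exact matches only
        if not np.any(mu[zero_sd] == y):
            raise ValueError(
                "every isoscape SD is zero and the tissue value matches no "
                "cell mean; supply extra_sd > 0 (e.g. the measurement error)"
            )
        out[zero_sd] = np.where(mu[zero_sd] == y, 1.0, 0.0)
        return Raster(out, mean.spec)
    # cells whose sd is exactly zero (IJ truncation) carry no density;
    # extra_sd > 0 restores their support
    out[pos] = norm.pdf(y, loc=mu[pos], scale=sd[pos])
    return Raster(out, mean.spec)


@dataclass
class AssignmentResult:
    """Posterior origin surface for one individual.

    ``posterior`` sums to 1 over valid cells; ``display`` is the same
    surface divided by its maximum; ``components`` keeps the per-isotope
    posteriors of a dual-isotope assignment.
    """

    posterior: Raster
    display: Raster
    components: dict[str, Raster] = field(default_factory=dict)

    @property
    def argmax_cell(self) -> tuple[int, int]:
        flat = np.nanargmax(self.posterior.values)
        return np.unravel_index(flat, self.posterior.spec.shape)


def posterior(likelihood: Raster, prior: Raster | np.ndarray | None = None) -> AssignmentResult:
    """Normalise prior x likelihood into an :class:`AssignmentResult`.

    ``prior`` may be a boolean region mask or a non-negative weight grid;
    a prior that removes all support raises.
    """
    L = likelihood.values.astype(float).copy()
    L[np.isnan(L)] = 0.0
    if prior is not None:
        p = prior.values if isinstance(prior, Raster) else np.asarray(prior)
        p = np.nan_to_num(p.astype(float), nan=0.0)
        if p.shape != L.shape:
            raise AlignmentError("prior grid shape mismatch")
        if np.any(p < 0):
            raise ValueError("prior weights must be non-negative")
        L = L * p
    total = L.sum()
    if total <= 0:
        raise ValueError("empty posterior support: prior excludes all likelihood")
    post = L / total
    display = post / post.max()
    return AssignmentResult(Raster(post, likelihood.spec), Raster(display, likelihood.spec))


def joint_assignment(
    sr_value: float,
    sr_mean: Raster,
    sr_se: Raster,
    d18o_carb_vpdb: float | None = None,
    o_mean: Raster | None = None,
    o_sd: Raster | None = None,
    sr_extra_sd: float = 0.0,
    o_extra_sd: float = O18_EXTRA_SD,
    prior: Raster | np.ndarray | None = None,
) -> AssignmentResult:
    """Single- or dual-isotope assignment.

    With oxygen data, the tissue carbonate value is converted to drinking
    water, the raw per-isotope likelihoods are multiplied cell-wise and
    normalised once; the per-isotope posteriors are retained in
    ``components``.
    """
    L_sr = likelihood_surface(sr_value, sr_mean, sr_se, extra_sd=sr_extra_sd)
    components = {"sr": posterior(L_sr, prior).posterior}
    L = L_sr.values
    if d18o_carb_vpdb is not None:
        if o_mean is None or o_sd is None:
            raise ValueError("oxygen isoscape mean+sd required for dual-isotope use")
        if not o_mean.spec.matches(sr_mean.spec):
            raise AlignmentError("Sr and O isoscapes are not on one grid")
        water = carb_vpdb_to_water(d18o_carb_vpdb).d18o_water_vsmow
        L_o = likelihood_surface(water, o_mean, o_sd, extra_sd=o_extra_sd)
        components["o18"] = posterior(L_o, prior).posterior
        L = L * L_o.values
    result = posterior(Raster(L, sr_mean.spec), prior)
    result.components = components
    return result


def top_fraction_region(result: AssignmentResult, q: float) -> np.ndarray:
    """Smallest cell set holding at least fraction ``q`` of posterior mass.

    Cells are ranked by posterior, ties broken by row-major cell index;
    q = 0 gives the empty region, q = 1 every positive-posterior cell.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    post = result.posterior.values.ravel()
    region = np.zeros(post.size, dtype=bool)
    if q > 0:
        order = np.lexsort((np.arange(post.size), -post))
        csum = np.cumsum(post[order])
        n_cells = int(np.searchsorted(csum, q - 1e-12) + 1)
        chosen = order[:n_cells]
        region[chosen[post[chosen] > 0]] = True
    return region.reshape(result.posterior.spec.shape)
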