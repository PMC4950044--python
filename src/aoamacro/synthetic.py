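"""Niche-structured metacommunity and transect-survey simulator.

The generator emulates the statistical structure a latitudinal marine
macroecology analysis assumes: taxa respond to latitude through Gaussian
niches; a configurable fraction is *bipolar* (responds to absolute latitude,
so the same taxon occupies both high-latitude ends); niche breadth grows
with the absolute latitude of the niche center at rate ``rapoport_k``
(Rapoport structure); each taxon has depth-layer affinities; and the two
observation processes of such surveys are modelled separately —
multinomial read sampling for sequencing libraries, and multiplicative
lognormal peak-height noise plus a relative detection threshold for
fingerprints.

All randomness derives from one master seed through named substreams
(numpy ``SeedSequence`` children), so each stage can be regenerated
independently:

========  ==========================
child     stage
========  ==========================
0         metacommunity parameters
1         read counts (multinomial)
2         fingerprint peak noise
========  ==========================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import LAYER_NAMES, OtuTable, assign_layer, assign_province

logger = logging.getLogger(__name__)

__all__ = ["NicheParams", "SurveyConfig", "build_metacommunity", "simulate_survey"]


@dataclass
class NicheParams:
    """Per-OTU niche parameters.

    ``niche_center`` is in degrees latitude; for ``symmetric`` (bipolar) taxa
    the response is evaluated on absolute latitude, so the center is stored
    non-negative.  ``niche_breadth`` is the Gaussian sigma in degrees.
    ``layer_affinity`` holds non-negative weights over the four depth layers
    (EPI, MESO, UPPER_BATHY, LOWER_BATHY) summing to 1.  ``abundance_scale``
    is the lognormal carrying capacity multiplier.
    """

    otu_id: str
    niche_center: float
    niche_breadth: float
    symmetric: bool
    layer_affinity: np.ndarray
    abundance_scale: float

    def __post_init__(self):
        self.layer_affinity = np.asarray(self.layer_affinity, dtype=float)
        if not self.niche_breadth > 0:
            raise ValueError(f"{self.otu_id}: niche_breadth must be > 0")
        if np.any(self.layer_affinity < 0) or abs(self.layer_affinity.sum() - 1) > 1e-9:
            raise ValueError(f"{self.otu_id}: layer_affinity must be a probability 4-vector")
        if not self.abundance_scale > 0:
            raise ValueError(f"{self.otu_id}: abundance_scale must be > 0")


@dataclass
class SurveyConfig:
    """Survey design and generator settings.

    Defaults mirror the transect the package emulates: 51 stations spanning
    55S-64N sampled at 7 depths from the euphotic layer to the abyss, with a
    0.5% relative fingerprint detection threshold.

    ``sigma0`` is the baseline niche breadth (degrees latitude); breadth of a
    taxon with niche center c is ``sigma0 + rapoport_k * |c|``.  ``sigma0 =
    inf`` is the neutral limit: no latitudinal selection at all (flat
    response), useful as an exchangeable null.  ``richness_gradient`` is the
    fraction of taxa whose centers are drawn from a tropical pool (normal,
    mean 0, sd 15 degrees) instead of uniformly, producing the excess of
    low-latitude taxa behind a latitudinal diversity gradient.
    """

    n_stations: int = 51
    lat_range: tuple = (-55.0, 64.0)
    depths_per_station: tuple = (50.0, 250.0, 500.0, 1000.0, 1500.0, 2500.0, 4000.0)
    n_otus: int = 300
    rapoport_k: float = 0.5
    bipolar_fraction: float = 0.3
    richness_gradient: float = 0.3
    read_depth: int = 2000
    trflp_threshold: float = 0.005
    noise_cv: float = 0.25
    seed: int = 0
    sigma0: float = 8.0
    center_margin_sigmas: float = 2.5  # shrink center pool to limit edge clipping

    def validate(self) -> None:
        if self.n_stations < 2:
            raise ValueError("n_stations must be >= 2")
        if not self.lat_range[0] < self.lat_range[1]:
            raise ValueError("lat_range must be ordered (south, north)")
        if self.n_otus < 1:
            raise ValueError("n_otus must be >= 1")
        if self.rapoport_k < 0:
            raise ValueError("rapoport_k must be >= 0")
        if not 0 <= self.bipolar_fraction <= 1:
            raise ValueError("bipolar_fraction must be in [0, 1]")
        if not 0 <= self.richness_gradient <= 1:
            raise ValueError("richness_gradient must be in [0, 1]")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if not 0 <= self.trflp_threshold < 1:
            raise ValueError("trflp_threshold must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.sigma0 > 0:
            raise ValueError("sigma0 must be > 0")

    def rng(self, stage: int) -> np.random.Generator:
        """Named substream: one child generator per pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


def build_metacommunity(config: SurveyConfig) -> list:
    """Draw ``config.n_otus`` :class:`NicheParams` for the metacommunity.

    Niche centers are uniform over the survey span shrunk by
    ``min(center_margin_sigmas * sigma0, 30% of span)`` at each end (so that
    baseline ranges are not clipped by the survey boundary), except for the
    ``richness_gradient`` fraction drawn from the tropical pool.  Breadths
    are deterministic given the center: ``sigma0 + rapoport_k * |center|``.
    """
    config.validate()
    rng = config.rng(0)
    lo, hi = config.lat_range
    span = hi - lo
    margin = 0.0 if np.isinf(config.sigma0) else min(
        config.center_margin_sigmas * config.sigma0, 0.3 * span
    )
    lo_c, hi_c = lo + margin, hi - margin

    n = config.n_otus
    tropical = rng.random(n) < config.richness_gradient
    centers = rng.uniform(lo_c, hi_c, size=n)
    centers[tropical] = np.clip(rng.normal(0.0, 15.0, size=tropical.sum()), lo_c, hi_c)
    symmetric = rng.random(n) < config.bipolar_fraction
    centers[symmetric] = np.abs(centers[symmetric])
    breadths = config.sigma0 + config.rapoport_k * np.abs(centers)
    scales = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    preferred = rng.integers(0, len(LAYER_NAMES), size=n)
    alphas = 0.5 + 4.0 * np.eye(len(LAYER_NAMES))[preferred]
    affinities = np.vstack([rng.dirichlet(a) for a in alphas])

    width = len(str(n - 1))
    return [
        NicheParams(
            otu_id=f"otu{str(i).zfill(width)}",
            niche_center=float(centers[i]),
            niche_breadth=float(breadths[i]),
            symmetric=bool(symmetric[i]),
            layer_affinity=affinities[i],
            abundance_scale=float(scales[i]),
        )
        for i in range(n)
    ]


def expected_relative_abundance(
    metacommunity: list, latitudes: np.ndarray, layers: list
) -> np.ndarray:
    """Deterministic expected relative abundances, shape (n_samples, n_otus).

    Row s, OTU i is proportional to
    ``scale_i * exp(-(x_s - c_i)^2 / (2 sigma_i^2)) * affinity_i[layer(s)]``
    where ``x_s`` is absolute latitude for symmetric taxa and signed latitude
    otherwise.  Rows are normalized to sum 1.
    """
    lat = np.asarray(latitudes, dtype=float)
    layer_idx = np.array([LAYER_NAMES.index(l) for l in layers])
    dens = np.empty((len(lat), len(metacommunity)))
    for i, p in enumerate(metacommunity):
        x = np.abs(lat) if p.symmetric else lat
        if np.isinf(p.niche_breadth):
            g = np.ones_like(x)
        else:
            g = np.exp(-((x - p.niche_center) ** 2) / (2.0 * p.niche_breadth**2))
        dens[:, i] = p.abundance_scale * g * p.layer_affinity[layer_idx]
    totals = dens.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a sample has zero expected abundance for every OTU")
    return dens / totals


def _environment(meta: pd.DataFrame) -> pd.DataFrame:
    """Smooth hydrography as functions of latitude and depth.

    Temperature declines with absolute latitude and depth toward a 2 C deep
    ocean; oxygen has a tropical minimum near 250 m; nitrite peaks near the
    oxygen minimum; salinity has subtropical surface maxima.  These are
    caricatures with realistic magnitudes, not an ocean model.
    """
    lat = meta["latitude"].to_numpy()
    depth = meta["depth_m"].to_numpy()
    alat = np.abs(lat)
    t_surf = -1.0 + 29.0 * np.exp(-((alat / 35.0) ** 2))
    temp = 2.0 + (t_surf - 2.0) * np.exp(-depth / 400.0)
    omz = np.exp(-(((depth - 250.0) / 300.0) ** 2)) * np.exp(-((alat / 20.0) ** 2))
    oxygen = 245.0 + 0.4 * alat - 150.0 * omz - 20.0 * np.exp(-depth / 2000.0)
    nitrite = 0.02 + 0.6 * np.exp(-(((depth - 300.0) / 300.0) ** 2)) * np.exp(
        -((alat / 25.0) ** 2)
    )
    salinity = 34.5 + 2.2 * np.exp(-(((alat - 25.0) / 15.0) ** 2)) * np.exp(-depth / 500.0)
    thaum = 2.0e4 * np.exp(-depth / 1500.0) + 1.0e3
    lac_hac = 0.2 + 1.6 * (1.0 - np.exp(-depth / 800.0))
    out = meta.copy()
    out["temperature_c"] = np.round(temp, 3)
    out["salinity"] = np.round(salinity, 3)
    out["oxygen_umol_kg"] = np.round(oxygen, 2)
    out["nitrite_umol_l"] = np.round(nitrite, 4)
    out["thaum_16s_per_ml"] = np.round(thaum, 1)
    out["lac_hac_ratio"] = np.round(lac_hac, 3)
    return out


def simulate_survey(metacommunity: list, config: SurveyConfig):
    """Simulate one transect survey.

    Returns ``(counts, fingerprint, meta)``: a counts-mode
    :class:`~aoamacro.tables.OtuTable` (multinomial reads at
    ``config.read_depth``), a relative-mode fingerprint table (expected
    relative abundances with lognormal noise of CV ``noise_cv``, peaks below
    ``trflp_threshold`` of each sample total removed, survivors
    renormalized), and the sample metadata frame.  Samples left all-zero by
    thresholding are dropped from the fingerprint table with a log record.
    """
    config.validate()
    if not metacommunity:
        raise ValueError("metacommunity is empty")

    lo, hi = config.lat_range
    station_lats = np.linspace(lo, hi, config.n_stations)
    records = []
    start = np.datetime64("2010-04-15")
    for s, lat in enumerate(station_lats):
        for depth in config.depths_per_station:
            records.append(
                {
                    "sample_id": f"st{s:02d}_d{int(depth):04d}",
                    "latitude": round(float(lat), 4),
                    "longitude": round(float(-20.0 + 12.0 * np.sin(np.radians(lat))), 4),
                    "depth_m": float(depth),
                    "date_iso": str(start + np.timedelta64(s * 2, "D")),
                    "province": assign_province(min(max(lat, -55.0), 70.0)),
                    "layer": assign_layer(depth),
                }
            )
    meta = _environment(pd.DataFrame.from_records(records))
    meta = meta[
        [c for c in (
            "sample_id", "latitude", "longitude", "depth_m", "temperature_c",
            "salinity", "oxygen_umol_kg", "nitrite_umol_l", "date_iso",
            "thaum_16s_per_ml", "lac_hac_ratio", "province", "layer",
        )]
    ]

    probs = expected_relative_abundance(
        metacommunity, meta["latitude"].to_numpy(), list(meta["layer"])
    )
    otu_ids = [p.otu_id for p in metacommunity]
    sample_ids = list(meta["sample_id"])

    rng_counts = config.rng(1)
    counts = np.vstack([rng_counts.multinomial(config.read_depth, p) for p in probs])
    counts_table = OtuTable(sample_ids, otu_ids, counts, "counts")

    rng_noise = config.rng(2)
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = rng_noise.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=probs.shape)
    else:
        noise = 1.0
    heights = probs * noise
    rel = heights / heights.sum(axis=1, keepdims=True)
    rel[rel < config.trflp_threshold] = 0.0  # detection threshold, >= kept
    row_sums = rel.sum(axis=1)
    empty = row_sums == 0
    if np.any(empty):
        dropped = [sample_ids[i] for i in np.flatnonzero(empty)]
        logger.warning(
            "simulate_survey: %d samples all-zero after thresholding, dropped: %s",
            len(dropped), dropped,
        )
    rel = rel[~empty] / row_sums[~empty, None]
    fp_samples = [s for s, e in zip(sample_ids, empty) if not e]
    fingerprint = OtuTable(fp_samples, otu_ids, rel, "relative")

    return counts_table, fingerprint, meta
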