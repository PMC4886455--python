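"""Synthetic study worlds for end-to-end testing of the exposure pipeline.

Generates, from one root seed, everything the analysis consumes: regional
crop mosaics, a child population with census-tract socioeconomic scores and
an industrial-proximity flag, case status driven by a known logistic model
on the Global Crop Index, a diagnostic-group label per case, and 6:1
controls matched on birth year, region and sex.  Because the generating
effect sizes are known, every downstream estimate can be checked for
parameter recovery.

The default configuration emulates the study design it is meant to
exercise: five administrative regions (four pooled as a "north" unit with
a region random intercept, one analyzed alone), a 1996-2011 birth window,
a male share of 1.28/2.28, a crop-class mixture dominated by irrigated and
heterogeneous agriculture, an 11-group diagnostic mix, a true odds ratio
of 1.02 per 1% of crop index, and a 2.5 km industrial proximity flag.

Randomness flows from the root seed through named substreams (landcover,
population, industry, ses, outcomes, matching — per region where
relevant), so each layer can be regenerated independently and
reproducibly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from shapely.geometry import box

from .landcover import (
    CROP_CLASSES,
    BufferSpec,
    InvalidInputError,
    LandCoverMap,
    LandCoverPolygon,
    crop_profiles,
)

#: Diagnostic groups in the 11-group childhood-cancer classification style.
DIAGNOSTIC_GROUPS = (
    "leukemia",
    "hodgkin_lymphoma",
    "non_hodgkin_lymphoma",
    "cns",
    "neuroblastoma",
    "retinoblastoma",
    "renal",
    "hepatic",
    "bone",
    "sarcoma",
    "germ_cell",
)

#: Default case-mix weights (relative frequencies of the 11 groups).
DIAGNOSTIC_GROUP_WEIGHTS = (1062, 92, 245, 711, 398, 139, 212, 57, 114, 200, 120)

#: Default agricultural-class mixture (shares of agricultural area).
DEFAULT_CROP_MIXTURE = {
    "irrigated": 0.384,
    "heterogeneous": 0.332,
    "fruits": 0.156,
    "vineyards": 0.088,
    "olives": 0.031,
    "rice": 0.009,
}

#: Column order of the subjects table (CSV contract).
SUBJECT_COLUMNS = (
    "subject_id",
    "region_id",
    "x",
    "y",
    "birth_year",
    "sex",
    "is_case",
    "diagnostic_group",
    "ses_unemployment",
    "ses_condition",
    "industrial_exposed",
    "matched_case_id",
)

INDUSTRY_COLUMNS = ("facility_id", "region_id", "x", "y")


class MatchingError(RuntimeError):
    """A matching stratum ran out of eligible controls."""


@dataclass(frozen=True)
class RegionSpec:
    """Extent and composition of one synthetic region.

    The region is the axis-aligned square/rectangle [x0, x0+width] x
    [y0, y0+height] in meters.  Land cover is laid out on a grid of
    ``cell_size`` cells: each cell independently becomes an agricultural
    polygon (probability ``ag_cover``, class drawn from ``crop_mixture``),
    an ``other`` polygon (probability ``other_cover``) or stays bare.
    """

    region_id: str
    x0: float
    y0: float
    width: float = 30_000.0
    height: float = 30_000.0
    n_population: int = 4000
    crop_mixture: dict = field(default_factory=lambda: dict(DEFAULT_CROP_MIXTURE))
    ag_cover: float = 0.10
    other_cover: float = 0.30
    cell_size: float = 500.0
    smooth_sigma_cells: float = 2.0
    industry_count: int = 25

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x0 + self.width, self.y0 + self.height)


def default_regions() -> list[RegionSpec]:
    """Five disconnected regions: a four-region northern block + one alone."""
    names = ("aragon", "catalonia", "navarre", "basque", "madrid")
    return [RegionSpec(nm, x0=i * 50_000.0, y0=0.0) for i, nm in enumerate(names)]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic world; seed-complete and reproducible.

    The outcome model is
    ``logit P(case) = baseline_logit + beta_per_percent * global_percent
    + beta_ses * (ses_unemployment + ses_condition)
    + beta_industry * industrial_exposed + u_region``,
    with ``u_region ~ N(0, sigma_region^2)``.  ``beta_per_percent``
    defaults to log(1.02): an odds ratio of 1.02 per 1% of crop index, the
    scale of association the design is powered to detect.
    """

    seed: int = 0
    regions: tuple = field(default_factory=lambda: tuple(default_regions()))
    baseline_logit: float = -4.2
    beta_per_percent: float = float(np.log(1.02))
    beta_ses: float = 0.10
    beta_industry: float = 0.18
    sigma_region: float = 0.2
    control_ratio: int = 6
    industry_radius: float = 2500.0
    birth_years: tuple[int, int] = (1996, 2011)
    male_fraction: float = 1.28 / 2.28
    tract_cell_size: float = 1000.0
    diagnostic_weights: tuple = DIAGNOSTIC_GROUP_WEIGHTS
    match_replacement_across_cases: bool = False
    buffer: BufferSpec = BufferSpec()

    def __post_init__(self) -> None:
        if self.control_ratio < 1:
            raise InvalidInputError("control_ratio must be >= 1")
        if self.sigma_region < 0:
            raise InvalidInputError("sigma_region must be >= 0")
        if self.birth_years[1] < self.birth_years[0]:
            raise InvalidInputError("birth year window is empty")

    def region(self, region_id: str) -> RegionSpec:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)


def substream(seed: int, *tags) -> np.random.Generator:
    """Named, order-independent child stream of the root seed."""
    key = tuple(zlib.crc32(str(t).encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Land cover
# ---------------------------------------------------------------------------


def generate_landcover(config: SimulationConfig, region_id: str) -> LandCoverMap:
    """Random grid-cell crop mosaic for one region.

    Cells are non-overlapping by construction, satisfying the partition
    contract of the land-cover layer.  Each cell has side ``cell_size``
    (default 500 m, i.e. 25 ha — the minimum mapping unit of the source
    taxonomy the mosaic emulates).  Agricultural cells are spatially
    clustered: a Gaussian-smoothed random field is thresholded at the
    quantile that yields the configured ``ag_cover`` fraction, so crops
    form contiguous farming belts and most of the region — where most
    children live — is crop-free, as in a real mosaic.  Remaining cells
    independently become ``other`` (non-agricultural land cover) or stay
    bare; agricultural cells draw their class from the region's mixture.
    Deterministic under the root seed.
    """
    from scipy import ndimage

    spec = config.region(region_id)
    rng = substream(config.seed, "landcover", region_id)
    nx = int(spec.width // spec.cell_size)
    ny = int(spec.height // spec.cell_size)
    field_ = ndimage.gaussian_filter(rng.standard_normal((nx, ny)), spec.smooth_sigma_cells)
    is_ag = field_ >= np.quantile(field_, 1.0 - spec.ag_cover) if spec.ag_cover > 0 else np.zeros((nx, ny), bool)
    u = rng.random((nx, ny))
    classes = np.array(list(spec.crop_mixture))
    w = np.array([spec.crop_mixture[c] for c in classes], dtype=float)
    if w.sum() <= 0:
        raise InvalidInputError("crop mixture weights must sum to > 0")
    w = w / w.sum()
    ag_class_idx = rng.choice(len(classes), size=(nx, ny), p=w)
    p_other = spec.other_cover / max(1.0 - spec.ag_cover, 1e-12)
    polys = []
    for i in range(nx):
        for j in range(ny):
            if is_ag[i, j]:
                cls = str(classes[ag_class_idx[i, j]])
            elif u[i, j] < p_other:
                cls = "other"
            else:
                continue
            x0 = spec.x0 + i * spec.cell_size
            y0 = spec.y0 + j * spec.cell_size
            polys.append(
                LandCoverPolygon(
                    f"{region_id}-{i}-{j}", box(x0, y0, x0 + spec.cell_size, y0 + spec.cell_size), cls
                )
            )
    return LandCoverMap(region_id, polys)


# ---------------------------------------------------------------------------
# Population, confounders, industry
# ---------------------------------------------------------------------------


def generate_industries(config: SimulationConfig, region_id: str) -> pd.DataFrame:
    """Uniformly placed industrial facilities in the region extent."""
    spec = config.region(region_id)
    rng = substream(config.seed, "industry", region_id)
    n = spec.industry_count
    xmin, ymin, xmax, ymax = spec.extent
    return pd.DataFrame(
        {
            "facility_id": [f"{region_id}-F{i}" for i in range(n)],
            "region_id": region_id,
            "x": rng.uniform(xmin, xmax, n),
            "y": rng.uniform(ymin, ymax, n),
        },
        columns=list(INDUSTRY_COLUMNS),
    )


def industrial_proximity(points_xy: np.ndarray, industries: pd.DataFrame, radius: float) -> np.ndarray:
    """Flag points with any facility within ``radius`` meters (closed
    boundary: a facility at exactly the radius counts as exposed)."""
    pts = np.asarray(points_xy, dtype=float)
    if industries.empty:
        return np.zeros(len(pts), dtype=bool)
    fac = industries[["x", "y"]].to_numpy(dtype=float)
    d2 = ((pts[:, None, :] - fac[None, :, :]) ** 2).sum(axis=2)
    return (d2 <= radius**2).any(axis=1)


def generate_population(
    config: SimulationConfig,
    region_id: str,
    landcover: LandCoverMap | None = None,
    industries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """A region's child population, without outcomes.

    Locations are uniform over the region extent; birth years uniform over
    the configured window; sex Bernoulli with the configured male share.
    Census tracts are square grid cells of ``tract_cell_size``: both
    socioeconomic scores (standardized unemployment and socioeconomic
    condition) are drawn once per tract and shared by every subject in the
    cell.  ``industrial_exposed`` flags any facility within
    ``industry_radius`` (facilities generated from their own substream if
    not supplied).  ``landcover`` is accepted for signature symmetry with
    clustered placement variants; uniform placement does not use it.
    """
    spec = config.region(region_id)
    rng = substream(config.seed, "population", region_id)
    n = spec.n_population
    xmin, ymin, xmax, ymax = spec.extent
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    birth_year = rng.integers(config.birth_years[0], config.birth_years[1] + 1, n)
    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")

    # tract-level SES: one pair of scores per grid cell
    cell = config.tract_cell_size
    ci = ((x - xmin) // cell).astype(int)
    cj = ((y - ymin) // cell).astype(int)
    nx = int(np.ceil(spec.width / cell))
    ny = int(np.ceil(spec.height / cell))
    ses_rng = substream(config.seed, "ses", region_id)
    unemp_grid = ses_rng.standard_normal((nx, ny))
    cond_grid = ses_rng.standard_normal((nx, ny))
    ses_unemployment = unemp_grid[ci, cj]
    ses_condition = cond_grid[ci, cj]

    if industries is None:
        industries = generate_industries(config, region_id)
    exposed_ind = industrial_proximity(np.column_stack([x, y]), industries, config.industry_radius)

    return pd.DataFrame(
        {
            "subject_id": [f"{region_id}-S{i}" for i in range(n)],
            "region_id": region_id,
            "x": x,
            "y": y,
            "birth_year": birth_year,
            "sex": sex,
            "is_case": False,
            "diagnostic_group": pd.array([None] * n, dtype="object"),
            "ses_unemployment": ses_unemployment,
            "ses_condition": ses_condition,
            "industrial_exposed": exposed_ind,
            "matched_case_id": pd.array([None] * n, dtype="object"),
        },
        columns=list(SUBJECT_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Outcomes and matching
# ---------------------------------------------------------------------------


def assign_outcomes(subjects: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw case status from the known logistic model.

    Requires a ``global_percent`` column (exposure profiles computed).
    Region random intercepts are drawn once per region from their own
    substream; cases receive a diagnostic group from the configured
    multinomial.  Returns a new frame; deterministic under the seed.
    """
    if "global_percent" not in subjects.columns:
        raise InvalidInputError("assign_outcomes requires a global_percent column")
    out = subjects.copy()
    regions = sorted(out["region_id"].unique())
    u_rng = substream(config.seed, "region_effects")
    u_map = {r: config.sigma_region * u_rng.standard_normal() for r in regions}
    u = out["region_id"].map(u_map).to_numpy(dtype=float)
    eta = (
        config.baseline_logit
        + config.beta_per_percent * out["global_percent"].to_numpy(dtype=float)
        + config.beta_ses
        * (out["ses_unemployment"].to_numpy(dtype=float) + out["ses_condition"].to_numpy(dtype=float))
        + config.beta_industry * out["industrial_exposed"].to_numpy(dtype=float)
        + u
    )
    rng = substream(config.seed, "outcomes")
    is_case = rng.random(len(out)) < special.expit(eta)
    out["is_case"] = is_case
    w = np.asarray(config.diagnostic_weights, dtype=float)
    groups = rng.choice(np.array(DIAGNOSTIC_GROUPS), size=int(is_case.sum()), p=w / w.sum())
    diag = np.full(len(out), None, dtype=object)
    diag[is_case] = groups
    out["diagnostic_group"] = diag
    return out


def sample_matched_controls(
    cases: pd.DataFrame, pool: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Sample ``control_ratio`` matched controls per case.

    Controls share the case's (birth_year, region_id, sex) and are sampled
    without replacement within a case; by default also without replacement
    across cases (set ``match_replacement_across_cases`` to reuse the
    stratum pool).  Without replacement, sampling is realized by shuffling
    each stratum's pool once and assigning consecutive blocks of
    ``control_ratio`` controls to its cases — distributionally identical
    to case-by-case draws.  An exhausted stratum raises
    :class:`MatchingError` naming the stratum.  Returned controls carry
    ``matched_case_id``.
    """
    if pool["is_case"].any():
        raise InvalidInputError("control pool must exclude cases")
    keys = ["birth_year", "region_id", "sex"]
    pool_by_stratum = {k: df.index.to_numpy() for k, df in pool.groupby(keys, sort=True)}
    rng = substream(config.seed, "matching")
    m = config.control_ratio
    chosen_idx: list[np.ndarray] = []
    matched_ids: list[np.ndarray] = []
    cases_sorted = cases.sort_values("subject_id")
    for k, case_ids in cases_sorted.groupby(keys, sort=True)["subject_id"]:
        avail = pool_by_stratum.get(k, np.empty(0, dtype=int))
        need = m * len(case_ids)
        short = (len(avail) < need) if not config.match_replacement_across_cases else (len(avail) < m)
        if short:
            raise MatchingError(
                f"stratum (birth_year={k[0]}, region={k[1]}, sex={k[2]}) has "
                f"{len(avail)} eligible controls; {need} needed for "
                f"{len(case_ids)} case(s)"
            )
        if config.match_replacement_across_cases:
            picks = np.concatenate(
                [avail[rng.choice(len(avail), size=m, replace=False)] for _ in case_ids]
            )
        else:
            picks = rng.permutation(avail)[:need]
        chosen_idx.append(picks)
        matched_ids.append(np.repeat(case_ids.to_numpy(), m))
    if not chosen_idx:
        return pool.iloc[0:0].copy()
    controls = pool.loc[np.concatenate(chosen_idx)].copy()
    controls["matched_case_id"] = np.concatenate(matched_ids)
    return controls.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Whole worlds
# ---------------------------------------------------------------------------


@dataclass
class World:
    """One synthetic study: maps, facilities and the analysis-ready subjects."""

    config: SimulationConfig
    landcover: dict[str, LandCoverMap]
    industries: pd.DataFrame
    subjects: pd.DataFrame  # cases + matched controls, with exposure columns


def attach_profiles(subjects: pd.DataFrame, maps: dict[str, LandCoverMap], spec: BufferSpec) -> pd.DataFrame:
    """Compute and attach the seven index columns for every subject."""
    out = subjects.copy()
    cols = [f"pct_{c}" for c in CROP_CLASSES] + ["global_percent"]
    vals = np.zeros((len(out), len(cols)))
    for region, sub in out.groupby("region_id", sort=False):
        vals[out.index.get_indexer(sub.index)] = crop_profiles(
            sub[["x", "y"]].to_numpy(dtype=float), maps[region], spec
        )
    for j, c in enumerate(cols):
        out[c] = vals[:, j]
    return out


def generate_world(config: SimulationConfig) -> World:
    """Full pipeline input: land cover, exposed population, outcomes, matching."""
    maps = {r.region_id: generate_landcover(config, r.region_id) for r in config.regions}
    industries = pd.concat(
        [generate_industries(config, r.region_id) for r in config.regions], ignore_index=True
    )
    pops = [
        generate_population(
            config,
            r.region_id,
            maps[r.region_id],
            industries[industries["region_id"] == r.region_id],
        )
        for r in config.regions
    ]
    population = pd.concat(pops, ignore_index=True)
    population = attach_profiles(population, maps, config.buffer)
    population = assign_outcomes(population, config)
    cases = population[population["is_case"]]
    pool = population[~population["is_case"]]
    controls = sample_matched_controls(cases, pool, config)
    subjects = pd.concat([cases, controls], ignore_index=True)
    return World(config=config, landcover=maps, industries=industries, subjects=subjects)
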