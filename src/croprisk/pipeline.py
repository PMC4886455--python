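"""End-to-end study orchestration.

Reads a land-cover layer and a subject table (or takes an in-memory
synthetic world), computes buffer crop profiles, categorizes exposure per
region and crop type, summarizes exposure by diagnostic group, fits the
continuous (per-1%) and categorical (quartile) odds-ratio models per
diagnostic group and crop type — pooled regions get a region random
intercept, single regions a plain logistic model — and writes tidy CSV
tables plus a run manifest.  Deterministic given config and seed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .exposure import (
    CROP_TYPES,
    InsufficientExposureError,
    QuartileScheme,
    categorize_many,
    fit_quartile_scheme,
    schemes_to_frame,
)
from .landcover import BufferSpec, InvalidInputError, LandCoverMap, read_landcover_geojson
from .models import EstimationError, eligibility, fit_logistic, fit_mixed_logistic, or_table, trend_test
from .simulate import SUBJECT_COLUMNS, attach_profiles, industrial_proximity

log = logging.getLogger("croprisk")

ADJUSTERS = ("ses_unemployment", "ses_condition", "industrial_exposed")

#: Default pooling of regions into model units: the four northern regions
#: share one mixed model (region as random intercept); the remaining
#: region is fitted alone with a plain model.
DEFAULT_MODEL_UNITS = {
    "north": ("aragon", "catalonia", "navarre", "basque"),
    "madrid": ("madrid",),
}


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    landcover_paths: dict[str, str] | None = None  # region_id -> GeoJSON path
    subjects_csv: str | None = None
    industries_csv: str | None = None
    out_dir: str = "croprisk_out"
    buffer_radius: float = 1000.0
    n_segments: int = 128
    industry_radius: float = 2500.0
    crop_types: tuple = CROP_TYPES
    min_exposed_cases: int = 3
    min_exposed_for_quartiles: int = 4
    quantile_method: str = "linear"
    model_units: dict = field(default_factory=lambda: dict(DEFAULT_MODEL_UNITS))
    seed: int = 0

    @property
    def buffer(self) -> BufferSpec:
        return BufferSpec(self.buffer_radius, self.n_segments)


@dataclass
class StudyResult:
    """In-memory bundle of everything :func:`run_analysis` produced."""

    exposure: pd.DataFrame
    summary: pd.DataFrame
    schemes: list[QuartileScheme]
    or_continuous: pd.DataFrame
    or_categorical: pd.DataFrame
    manifest: str = ""


def load_subjects(path) -> pd.DataFrame:
    """Read and validate a subjects CSV against the documented schema."""
    df = pd.read_csv(path, dtype={"subject_id": str, "region_id": str})
    required = [c for c in SUBJECT_COLUMNS if c not in ("industrial_exposed", "matched_case_id")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: subjects CSV lacks columns {missing}")
    if "matched_case_id" not in df.columns:
        df["matched_case_id"] = None
    df["is_case"] = df["is_case"].astype(bool)
    bad = df["is_case"] != df["diagnostic_group"].notna()
    if bad.any():
        raise InvalidInputError(
            f"{path}: diagnostic_group must be set exactly for cases "
            f"({int(bad.sum())} rows violate this)"
        )
    return df


def index_column(crop_type: str) -> str:
    return "global_percent" if crop_type == "global" else f"pct_{crop_type}"


# ---------------------------------------------------------------------------
# Exposure table and summary
# ---------------------------------------------------------------------------


def build_exposure_table(
    subjects: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, list[QuartileScheme]]:
    """Exposed flag + per-region quartile categories for every crop type.

    Quartile schemes are fitted per (region, crop type) on the pooled
    exposed cases and controls; crop types with too few exposed subjects
    in a region get no scheme there (their category column is left NA for
    that region) and a logged notice.
    """
    out = subjects.copy()
    out["exposed"] = out["global_percent"] > 0
    schemes: list[QuartileScheme] = []
    for crop in config.crop_types:
        col = index_column(crop)
        cat = pd.array([pd.NA] * len(out), dtype="Int64")
        for region, sub in out.groupby("region_id", sort=True):
            try:
                scheme = fit_quartile_scheme(
                    sub[col], region, crop,
                    min_exposed=config.min_exposed_for_quartiles,
                    method=config.quantile_method,
                )
            except InsufficientExposureError as exc:
                log.info("skipping quartile scheme: %s", exc)
                continue
            schemes.append(scheme)
            idx = out.index.get_indexer(sub.index)
            cat[idx] = categorize_many(sub[col].to_numpy(dtype=float), scheme)
        out[f"cat_{crop}"] = cat
    return out, schemes


def summarize_exposure(subjects: pd.DataFrame) -> pd.DataFrame:
    """Exposure counts and proportions by diagnostic group.

    One row per diagnostic group plus a ``total`` row: total and exposed
    cases and controls, with exposed proportions rounded to 2 decimals
    (full precision kept in parallel columns).  A group's controls are the
    ones matched to its cases when ``matched_case_id`` is available;
    otherwise every control is counted in every group's comparison.
    Groups with zero cases are omitted with a logged notice.
    """
    if "exposed" not in subjects.columns:
        subjects = subjects.assign(exposed=subjects["global_percent"] > 0)
    cases = subjects[subjects["is_case"]]
    controls = subjects[~subjects["is_case"]]
    have_links = controls["matched_case_id"].notna().any()
    if have_links:
        case_group = cases.set_index("subject_id")["diagnostic_group"]
        ctrl_groups = controls["matched_case_id"].map(case_group)
    rows = []
    groups = [g for g in cases["diagnostic_group"].dropna().unique()]
    for g in sorted(groups):
        cg = cases[cases["diagnostic_group"] == g]
        if len(cg) == 0:
            log.info("diagnostic group %s has zero cases; omitted from summary", g)
            continue
        tg = controls[ctrl_groups == g] if have_links else controls
        rows.append(_summary_row(g, cg, tg))
    rows.append(_summary_row("total", cases, controls))
    return pd.DataFrame(rows)


def _summary_row(name: str, cases: pd.DataFrame, controls: pd.DataFrame) -> dict:
    ec, et = int(cases["exposed"].sum()), int(controls["exposed"].sum())
    nc, nt = len(cases), len(controls)
    return {
        "diagnostic_group": name,
        "total_cases": nc,
        "total_controls": nt,
        "exposed_cases": ec,
        "exposed_controls": et,
        "prop_exposed_cases": round(ec / nc, 2) if nc else np.nan,
        "prop_exposed_controls": round(et / nt, 2) if nt else np.nan,
        "prop_exposed_cases_full": ec / nc if nc else np.nan,
        "prop_exposed_controls_full": et / nt if nt else np.nan,
    }


# ---------------------------------------------------------------------------
# Model fitting per unit x diagnostic group x crop type
# ---------------------------------------------------------------------------


def _group_data(subjects: pd.DataFrame, regions, group: str) -> pd.DataFrame:
    """Cases of one diagnostic group and their comparison controls, one unit."""
    sub = subjects[subjects["region_id"].isin(regions)]
    cases = sub[sub["is_case"] & (sub["diagnostic_group"] == group)]
    controls = sub[~sub["is_case"]]
    if controls["matched_case_id"].notna().any():
        controls = controls[controls["matched_case_id"].isin(set(cases["subject_id"]))]
    return pd.concat([cases, controls])


def _fit(y, X, groups, mixed: bool):
    # a pooled unit degenerates to a plain fit when the subset at hand
    # (e.g. one rare diagnostic group) spans a single region
    if mixed and len(pd.unique(groups)) > 1:
        return fit_mixed_logistic(y, X, groups)
    return fit_logistic(y, X)


def fit_or_tables(subjects: pd.DataFrame, config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Continuous (per-1%) and categorical (quartile) OR tables.

    One continuous row per eligible (unit, diagnostic group, crop type);
    four categorical rows (quartiles 1-4 vs unexposed) plus a Wald trend
    p-value on the 0-4 score.  Rows failing the minimum-exposed-cases rule
    carry no estimates; estimation failures are recorded in ``status``,
    never silently dropped.
    """
    cont_rows, cat_rows = [], []
    groups_present = sorted(subjects.loc[subjects["is_case"], "diagnostic_group"].dropna().unique())
    for unit, regions in config.model_units.items():
        unit_sub = subjects[subjects["region_id"].isin(regions)]
        if unit_sub.empty:
            log.info("model unit %s matches no subjects; skipped", unit)
            continue
        mixed = len(pd.unique(unit_sub["region_id"])) > 1
        for g in groups_present:
            data = _group_data(subjects, regions, g)
            if data["is_case"].sum() == 0:
                continue
            for crop in config.crop_types:
                col = index_column(crop)
                cont_rows.append(_continuous_row(data, unit, g, crop, col, config, mixed))
                cat_rows.extend(_categorical_rows(data, unit, g, crop, config, mixed))
    cols = ["unit", "diagnostic_group", "crop_type", "term", "n_exposed_cases",
            "or", "ci_low", "ci_high", "trend_p", "eligible", "status"]
    return (
        pd.DataFrame(cont_rows, columns=cols),
        pd.DataFrame(cat_rows, columns=cols),
    )


def _base_row(unit, g, crop, term):
    return {
        "unit": unit, "diagnostic_group": g, "crop_type": crop, "term": term,
        "n_exposed_cases": 0, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "trend_p": np.nan, "eligible": False, "status": "",
    }


def _continuous_row(data, unit, g, crop, col, config, mixed):
    row = _base_row(unit, g, crop, "per_1pct")
    n_exp = int(((data[col] > 0) & data["is_case"]).sum())
    row["n_exposed_cases"] = n_exp
    if not eligibility(n_exp, config.min_exposed_cases):
        row["status"] = "ineligible: fewer exposed cases than threshold"
        return row
    row["eligible"] = True
    X = pd.DataFrame({"intercept": 1.0, "index": data[col].astype(float)})
    for a in ADJUSTERS:
        X[a] = data[a].astype(float).to_numpy()
    y = data["is_case"].to_numpy(dtype=float)
    try:
        fit = _fit(y, X, data["region_id"].to_numpy(), mixed)
        tab = or_table(fit, ["index"]).iloc[0]
        row.update({"or": tab["or"], "ci_low": tab["ci_low"], "ci_high": tab["ci_high"], "status": "ok"})
    except EstimationError as exc:
        row["status"] = f"estimation_failed: {exc}"
    return row


def _categorical_rows(data, unit, g, crop, config, mixed):
    cat_col = f"cat_{crop}"
    terms = [f"quartile_{q}" for q in (1, 2, 3, 4)]
    rows = [_base_row(unit, g, crop, t) for t in terms]
    if cat_col not in data.columns or data[cat_col].isna().any():
        for r in rows:
            r["status"] = "no quartile scheme (too few exposed in some region)"
        return rows
    cat = data[cat_col].to_numpy(dtype=int)
    y = data["is_case"].to_numpy(dtype=float)
    n_case_by_cat = {q: int(((cat == q) & data["is_case"]).sum()) for q in (1, 2, 3, 4)}
    present = [q for q in (1, 2, 3, 4) if (cat == q).any()]
    X = pd.DataFrame({"intercept": np.ones(len(data))})
    for q in present:
        X[f"quartile_{q}"] = (cat == q).astype(float)
    for a in ADJUSTERS:
        X[a] = data[a].astype(float).to_numpy()
    fit, fit_err = None, ""
    try:
        fit = _fit(y, X, data["region_id"].to_numpy(), mixed)
    except EstimationError as exc:
        fit_err = f"estimation_failed: {exc}"
    trend_p = np.nan
    if fit is not None:
        try:
            trend_p = trend_test(
                y, cat.astype(float), data[list(ADJUSTERS)].astype(float),
                groups=data["region_id"].to_numpy() if mixed else None,
            )
        except (EstimationError, InvalidInputError) as exc:
            log.info("trend test failed for %s/%s/%s: %s", unit, g, crop, exc)
    for r, q in zip(rows, (1, 2, 3, 4)):
        r["n_exposed_cases"] = n_case_by_cat[q]
        if not eligibility(n_case_by_cat[q], config.min_exposed_cases):
            r["status"] = "ineligible: fewer cases in category than threshold"
            continue
        r["eligible"] = True
        if fit is None:
            r["status"] = fit_err
        elif q not in present:
            r["status"] = "empty category"
        else:
            tab = or_table(fit, [f"quartile_{q}"]).iloc[0]
            r.update({"or": tab["or"], "ci_low": tab["ci_low"], "ci_high": tab["ci_high"],
                      "trend_p": trend_p, "status": "ok"})
    return rows


# ---------------------------------------------------------------------------
# Top-level entry points
# ---------------------------------------------------------------------------


def run_analysis(
    subjects: pd.DataFrame,
    maps: dict[str, LandCoverMap] | None,
    config: AnalysisConfig,
) -> StudyResult:
    """Full analysis on in-memory inputs.

    ``subjects`` may already carry the index columns (e.g. from the
    synthetic generator); otherwise ``maps`` must cover every region and
    profiles are computed here.
    """
    if "global_percent" not in subjects.columns:
        if maps is None:
            raise InvalidInputError("no exposure columns and no land-cover maps given")
        subjects = attach_profiles(subjects, maps, config.buffer)
    exposure, schemes = build_exposure_table(subjects, config)
    summary = summarize_exposure(exposure)
    or_cont, or_cat = fit_or_tables(exposure, config)
    manifest = _manifest(config, exposure, summary, or_cont, or_cat)
    return StudyResult(exposure, summary, schemes, or_cont, or_cat, manifest)


def run_study(config: AnalysisConfig, subjects: pd.DataFrame | None = None,
              maps: dict[str, LandCoverMap] | None = None) -> StudyResult:
    """Read inputs per config (unless given in memory), analyze, write outputs."""
    if subjects is None:
        if config.subjects_csv is None:
            raise InvalidInputError("config.subjects_csv is required when no subjects are passed")
        subjects = load_subjects(config.subjects_csv)
    if maps is None and config.landcover_paths:
        maps = {rid: read_landcover_geojson(p, rid) for rid, p in config.landcover_paths.items()}
    if "industrial_exposed" not in subjects.columns:
        if config.industries_csv is None:
            raise InvalidInputError("subjects lack industrial_exposed and no industries CSV given")
        industries = pd.read_csv(config.industries_csv)
        subjects = subjects.copy()
        flags = np.zeros(len(subjects), dtype=bool)
        for region, sub in subjects.groupby("region_id"):
            fac = industries[industries["region_id"] == region]
            flags[subjects.index.get_indexer(sub.index)] = industrial_proximity(
                sub[["x", "y"]].to_numpy(dtype=float), fac, config.industry_radius
            )
        subjects["industrial_exposed"] = flags
    result = run_analysis(subjects, maps, config)
    write_outputs(result, config.out_dir)
    return result


def write_outputs(result: StudyResult, out_dir) -> None:
    """Write every table plus the manifest; identical inputs give
    byte-identical files."""
    os.makedirs(out_dir, exist_ok=True)
    result.exposure.to_csv(os.path.join(out_dir, "exposure.csv"), index=False)
    result.summary.to_csv(os.path.join(out_dir, "exposure_summary.csv"), index=False)
    schemes_to_frame(result.schemes).to_csv(os.path.join(out_dir, "quartile_schemes.csv"), index=False)
    result.or_continuous.to_csv(os.path.join(out_dir, "or_continuous.csv"), index=False)
    result.or_categorical.to_csv(os.path.join(out_dir, "or_categorical.csv"), index=False)
    with open(os.path.join(out_dir, "manifest.txt"), "w") as fh:
        fh.write(result.manifest)


def _manifest(config, exposure, summary, or_cont, or_cat) -> str:
    import scipy
    import shapely
    import statsmodels

    lines = [
        f"croprisk {__version__}",
        f"numpy {np.__version__}; scipy {scipy.__version__}; pandas {pd.__version__}; "
        f"statsmodels {statsmodels.__version__}; shapely {shapely.__version__}",
        f"seed: {config.seed}",
        f"buffer_radius_m: {config.buffer_radius}; n_segments: {config.n_segments}",
        f"industry_radius_m: {config.industry_radius}",
        f"crop_types: {', '.join(config.crop_types)}",
        f"min_exposed_cases: {config.min_exposed_cases}",
        f"quantile_method: {config.quantile_method}",
        f"model_units: {config.model_units}",
        f"rows: exposure={len(exposure)} summary={len(summary)} "
        f"or_continuous={len(or_cont)} or_categorical={len(or_cat)}",
    ]
    return "\n".join(lines) + "\n"
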