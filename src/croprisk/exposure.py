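"""Exposure variables derived from crop-index profiles.

Three analysis variables are built from the index of each subject:

* the *exposed* flag — index strictly greater than 0%;
* the continuous per-1% index, used directly in the regression models;
* a five-level category — 0 for the unexposed, 1-4 for the quartiles of
  the index among the *exposed* individuals, with quartile cutpoints
  fitted separately per region and crop type and shared by cases and
  controls.

Category intervals are left-open / right-closed, "(a-b]", so a value equal
to a cutpoint belongs to the lower category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landcover import CROP_CLASSES, ExposureProfile, InvalidInputError

#: Index variables that can be categorized: the global index plus one per crop.
CROP_TYPES = ("global",) + CROP_CLASSES

#: Fewer strictly positive values than this and no quartile scheme is fitted
#: (crop types with only a handful of exposed subjects, e.g. rice, are
#: skipped rather than categorized on noise).
DEFAULT_MIN_EXPOSED = 4


class InsufficientExposureError(ValueError):
    """Too few exposed individuals to fit a quartile scheme."""


@dataclass(frozen=True)
class QuartileScheme:
    """Quartile cutpoints of one index among exposed individuals.

    ``cutpoints = (q1, q2, q3)`` are the 25/50/75 empirical quantiles of
    the strictly positive index values in one region for one crop type;
    ``n_exposed`` records how many values they were fitted on.
    """

    region_id: str
    crop_type: str
    cutpoints: tuple[float, float, float]
    n_exposed: int

    def __post_init__(self) -> None:
        q1, q2, q3 = self.cutpoints
        if not (0 < q1 <= q2 <= q3 <= 100):
            raise InvalidInputError(f"cutpoints must satisfy 0 < q1 <= q2 <= q3 <= 100, got {self.cutpoints}")
        if self.crop_type not in CROP_TYPES:
            raise InvalidInputError(f"unknown crop_type {self.crop_type!r}")


def is_exposed(profile: ExposureProfile | float) -> bool:
    """True iff the global crop index is strictly greater than 0%."""
    value = profile.global_percent if isinstance(profile, ExposureProfile) else float(profile)
    return value > 0.0


def fit_quartile_scheme(
    values,
    region_id: str,
    crop_type: str,
    min_exposed: int = DEFAULT_MIN_EXPOSED,
    method: str = "linear",
) -> QuartileScheme:
    """Fit quartile cutpoints on the exposed (strictly positive) values.

    Zeros (the unexposed) are removed first; the cutpoints are the
    25/50/75 empirical quantiles of what remains, by default with the
    linear-interpolation convention (``numpy``'s default, shared by
    mainstream statistical software).  ``method`` accepts any
    ``np.quantile`` method name.

    Raises
    ------
    InsufficientExposureError
        If fewer than ``min_exposed`` strictly positive values remain.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise InvalidInputError("index values must lie in [0, 100]")
    pos = arr[arr > 0]
    if pos.size < max(min_exposed, 4):
        raise InsufficientExposureError(
            f"{region_id}/{crop_type}: only {pos.size} exposed values; "
            f"need at least {max(min_exposed, 4)}"
        )
    q1, q2, q3 = np.quantile(pos, [0.25, 0.5, 0.75], method=method)
    return QuartileScheme(region_id, crop_type, (float(q1), float(q2), float(q3)), int(pos.size))


def categorize(index: float, scheme: QuartileScheme) -> int:
    """Map one index value to its five-level exposure category.

    0 iff the index is 0; otherwise 1 for (0, q1], 2 for (q1, q2],
    3 for (q2, q3] and 4 for (q3, 100].
    """
    if not (0 <= index <= 100):
        raise InvalidInputError(f"index must lie in [0, 100], got {index}")
    if index == 0:
        return 0
    q1, q2, q3 = scheme.cutpoints
    if index <= q1:
        return 1
    if index <= q2:
        return 2
    if index <= q3:
        return 3
    return 4


def categorize_many(values, scheme: QuartileScheme) -> np.ndarray:
    """Vectorized :func:`categorize` over an array of index values."""
    arr = np.asarray(values, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise InvalidInputError("index values must lie in [0, 100]")
    q1, q2, q3 = scheme.cutpoints
    cat = np.searchsorted([q1, q2, q3], arr, side="left") + 1
    cat[arr == 0] = 0
    return cat


def schemes_to_frame(schemes) -> pd.DataFrame:
    """Tabulate schemes as (region_id, crop_type, q1, q2, q3, n_exposed)."""
    rows = [
        {
            "region_id": s.region_id,
            "crop_type": s.crop_type,
            "q1": s.cutpoints[0],
            "q2": s.cutpoints[1],
            "q3": s.cutpoints[2],
            "n_exposed": s.n_exposed,
        }
        for s in schemes
    ]
    return pd.DataFrame(rows, columns=["region_id", "crop_type", "q1", "q2", "q3", "n_exposed"])


def frame_to_schemes(frame: pd.DataFrame) -> list[QuartileScheme]:
    """Inverse of :func:`schemes_to_frame` (e.g. after a CSV round trip)."""
    return [
        QuartileScheme(
            str(r.region_id), str(r.crop_type), (float(r.q1), float(r.q2), float(r.q3)), int(r.n_exposed)
        )
        for r in frame.itertuples(index=False)
    ]
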