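"""The 153-feature binned tumor nuclear image profile.

Retained nuclei (area 50-500 px^2) are split into 10 evenly spaced area bins
of width 45 px^2.  For each of six per-nucleus parameters — area (Ar),
perimeter (Pe), circularity (Ci), aspect ratio (AR), solidity (So),
roundness (Ro) — the mean and SD are computed per bin and over all nuclei
(``Total``), giving 2 x 6 x 11 = 132 features; per-bin counts (10) and
percentages (10) and one spatial-compactness statistic complete the
153-entry profile.

Compactness is the Clark-Evans aggregation index: the observed mean
nearest-neighbour distance between nucleus centroids divided by the value
expected under complete spatial randomness at the same density,
0.5 / sqrt(n / A).  Values below 1 indicate clustering, ~1 randomness,
above 1 regular spacing.

Feature order is fixed: all means (parameter-major, Bin1..Bin10 then Total),
all SDs in the same order, Count_Bin1..10, Pct_Bin1..10, Compactness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .morphometry import NucleusMeasurement, SampleNucleusSet

PARAM_CODES = {
    "Ar": "area",
    "Pe": "perimeter",
    "Ci": "circularity",
    "AR": "aspect_ratio",
    "So": "solidity",
    "Ro": "roundness",
}
N_BINS = 10
BIN_LABELS = [f"Bin{i}" for i in range(1, N_BINS + 1)] + ["Total"]
DEFAULT_AREA_MIN = 50.0
DEFAULT_AREA_MAX = 500.0


def feature_names() -> list[str]:
    """The 153 profile feature names in their fixed order."""
    names = [f"Mean_{p}_{b}" for p in PARAM_CODES for b in BIN_LABELS]
    names += [f"Std_{p}_{b}" for p in PARAM_CODES for b in BIN_LABELS]
    names += [f"Count_Bin{i}" for i in range(1, N_BINS + 1)]
    names += [f"Pct_Bin{i}" for i in range(1, N_BINS + 1)]
    names += ["Compactness"]
    return names


FEATURE_NAMES = feature_names()
assert len(FEATURE_NAMES) == 153


@dataclass
class MorphProfile:
    sample_id: str
    features: dict[str, float]

    def __post_init__(self) -> None:
        if list(self.features) != FEATURE_NAMES:
            raise ValueError("profile must contain exactly the 153 named features in order")

    def to_series(self) -> pd.Series:
        return pd.Series(self.features, name=self.sample_id)


def assign_bin(
    area: float,
    area_min: float = DEFAULT_AREA_MIN,
    area_max: float = DEFAULT_AREA_MAX,
    n_bins: int = N_BINS,
) -> int:
    """Bin index in 1..n_bins for an in-range nuclear area.

    Bin b covers [area_min + (b-1)w, area_min + b*w) with w = 45 px^2 for the
    defaults; the last bin is closed at ``area_max``.  Out-of-range areas are
    a contract violation (the size filter must run first).
    """
    if not area_min <= area <= area_max:
        raise ValueError(f"area {area} outside [{area_min}, {area_max}]: filter first")
    w = (area_max - area_min) / n_bins
    b = int((area - area_min) // w) + 1
    return min(b, n_bins)


def compactness(
    centroids: list[tuple[float, float]] | np.ndarray,
    image_shape: tuple[int, int],
    n_images: int = 1,
) -> float:
    """Clark-Evans nearest-neighbour index of nucleus centroids.

    Observed mean NN distance over 0.5/sqrt(density), density = n points per
    total imaged area (``n_images`` fields of ``image_shape``).  Returns NaN
    for fewer than two centroids.
    """
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 2:
        return float("nan")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    mean_nn = float(d[:, 1].mean())
    area = float(image_shape[0]) * float(image_shape[1]) * n_images
    expected = 0.5 / np.sqrt(len(pts) / area)
    return mean_nn / expected


def _bin_stats(values: np.ndarray, sd_ddof: int) -> tuple[float, float]:
    if len(values) == 0:
        return float("nan"), float("nan")
    return float(np.mean(values)), float(np.std(values, ddof=sd_ddof))


def build_profile(
    nuclei: SampleNucleusSet,
    area_min: float = DEFAULT_AREA_MIN,
    area_max: float = DEFAULT_AREA_MAX,
    sd_ddof: int = 0,
) -> MorphProfile:
    """Build the 153-feature profile for one sample's retained nuclei.

    Means/SDs use the population-SD convention by default (``sd_ddof=0``) so
    single-nucleus bins have SD 0 rather than an undefined value; empty bins
    carry NaN means/SDs and zero counts.  An empty nucleus set yields NaN for
    all means/SDs/percentages/compactness and zero counts.
    """
    ms = nuclei.measurements
    by_bin: dict[int, list[NucleusMeasurement]] = {b: [] for b in range(1, N_BINS + 1)}
    for m in ms:
        by_bin[assign_bin(m.area, area_min, area_max)].append(m)

    groups: dict[str, list[NucleusMeasurement]] = {
        f"Bin{b}": by_bin[b] for b in range(1, N_BINS + 1)
    }
    groups["Total"] = list(ms)

    features: dict[str, float] = {}
    for code, attr in PARAM_CODES.items():
        for lab in BIN_LABELS:
            vals = np.array([getattr(m, attr) for m in groups[lab]])
            features[f"Mean_{code}_{lab}"], _ = _bin_stats(vals, sd_ddof)
    for code, attr in PARAM_CODES.items():
        for lab in BIN_LABELS:
            vals = np.array([getattr(m, attr) for m in groups[lab]])
            _, features[f"Std_{code}_{lab}"] = _bin_stats(vals, sd_ddof)

    total = len(ms)
    for b in range(1, N_BINS + 1):
        features[f"Count_Bin{b}"] = float(len(by_bin[b]))
    for b in range(1, N_BINS + 1):
        features[f"Pct_Bin{b}"] = (
            100.0 * len(by_bin[b]) / total if total else float("nan")
        )
    features["Compactness"] = compactness(
        [m.centroid for m in ms], nuclei.image_shape, nuclei.n_images
    )
    assert len(features) == 153
    return MorphProfile(nuclei.sample_id, features)


def profiles_to_matrix(profiles: list[MorphProfile]) -> pd.DataFrame:
    """Stack profiles into a samples x 153 feature matrix (provenance raw)."""
    df = pd.DataFrame([p.to_series() for p in profiles])
    df.index.name = "sample_id"
    df.attrs["provenance"] = "raw"
    return df


def normalize_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Log-transform then median-center each feature across samples.

    Each entry becomes log(value / feature median), i.e. natural log followed
    by subtraction of the per-feature median of logs, so every feature has
    median 0.  Non-positive raw values cannot be log-scaled: they become NaN
    (with a warning) and are excluded from that feature's median; missing
    values propagate.
    """
    vals = matrix.to_numpy(dtype=float)
    nonpos = vals <= 0
    if np.any(nonpos & np.isfinite(vals)):
        warnings.warn(
            f"{int((nonpos & np.isfinite(vals)).sum())} non-positive values "
            "excluded from log normalization",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.where(nonpos, np.nan, np.log(vals))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        med = np.nanmedian(logged, axis=0, keepdims=True)
    out = pd.DataFrame(logged - med, index=matrix.index, columns=matrix.columns)
    out.attrs["provenance"] = "normalized"
    return out
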