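"""The 56-feature tumor descriptor.

For each of the four parametric maps (ESD, EAC, MBF, SI):

* mean and SNR over the tumor core (``M_C``, ``SNR_C``) and over the
  5 mm margin (``M_m``, ``SNR_m``) — 16 features;
* mean and SNR over each of the three segmented intra-tumor regions
  (``M_r``, ``SNR_r``) — 24 features;
* pairwise differences of region means ``M_2-1``, ``M_3-1``, ``M_3-2``
  (higher-index minus lower-index) — 12 features;

plus the region area proportions within the core (``A_1``..``A_3``) and
the margin area relative to the core (``A_m``) — 4 features.

Regional SNR is mean/standard-deviation of the pixel values, an inverse
measure of spatial heterogeneity.  Features are computed per imaging
plane and averaged over the planes of a tumor.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "MAP_NAMES",
    "region_stats",
    "extract_features",
    "aggregate_planes",
]

MAP_NAMES = ("ESD", "EAC", "MBF", "SI")


def _build_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    for m in MAP_NAMES:
        names += [f"M_C_{m}", f"SNR_C_{m}"]
    for m in MAP_NAMES:
        names += [f"M_m_{m}", f"SNR_m_{m}"]
    for m in MAP_NAMES:
        for r in (1, 2, 3):
            names += [f"M_{r}_{m}", f"SNR_{r}_{m}"]
    for m in MAP_NAMES:
        names += [f"M_2-1_{m}", f"M_3-1_{m}", f"M_3-2_{m}"]
    names += ["A_1", "A_2", "A_3", "A_m"]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _build_feature_names()
assert len(FEATURE_NAMES) == 56


def region_stats(values: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    """Mean and SNR (mean/std) of the pixel values of one region.

    Returns NaN SNR when fewer than 2 pixels are available or the spread
    is zero (degenerate region); the mean is still reported when at least
    one pixel exists.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.nan, np.nan
    mean = float(values.mean())
    if values.size < 2:
        return mean, np.nan
    std = float(values.std(ddof=ddof))
    if std == 0:
        return mean, np.nan
    return mean, mean / std


def extract_features(
    maps: dict[str, np.ndarray],
    labels: np.ndarray,
    core: np.ndarray,
    margin: np.ndarray,
    valid: np.ndarray | None = None,
) -> dict[str, float]:
    """Compute the 56 features for one imaging plane.

    ``maps`` holds the four channel arrays; ``labels`` the region map
    (1..3 inside the core, 0 elsewhere); ``core``/``margin`` boolean
    masks; ``valid`` an optional pixel-validity mask.  A region absent in
    the plane yields NaN for its features (resolved at plane
    aggregation); area proportions are over valid core pixels.
    """
    labels = np.asarray(labels)
    core = np.asarray(core, dtype=bool)
    margin = np.asarray(margin, dtype=bool)
    if valid is None:
        valid = np.ones_like(core, dtype=bool)
    valid = np.asarray(valid, dtype=bool)

    out: dict[str, float] = {}
    for m in MAP_NAMES:
        ch = np.asarray(maps[m], dtype=float)
        out[f"M_C_{m}"], out[f"SNR_C_{m}"] = region_stats(ch[core & valid])
    for m in MAP_NAMES:
        ch = np.asarray(maps[m], dtype=float)
        out[f"M_m_{m}"], out[f"SNR_m_{m}"] = region_stats(ch[margin & valid])
    for m in MAP_NAMES:
        ch = np.asarray(maps[m], dtype=float)
        for r in (1, 2, 3):
            sel = core & valid & (labels == r)
            out[f"M_{r}_{m}"], out[f"SNR_{r}_{m}"] = region_stats(ch[sel])
    for m in MAP_NAMES:
        for hi, lo in ((2, 1), (3, 1), (3, 2)):
            out[f"M_{hi}-{lo}_{m}"] = out[f"M_{hi}_{m}"] - out[f"M_{lo}_{m}"]

    n_core = int((core & valid).sum())
    n_margin = int((margin & valid).sum())
    n_labeled = int((core & valid & (labels > 0)).sum())
    for r in (1, 2, 3):
        n_r = int((core & valid & (labels == r)).sum())
        out[f"A_{r}"] = n_r / n_labeled if n_labeled else np.nan
    out["A_m"] = n_margin / n_core if n_core else np.nan

    assert set(out) == set(FEATURE_NAMES)
    return {name: out[name] for name in FEATURE_NAMES}


def aggregate_planes(plane_features: list[dict[str, float]]) -> tuple[dict[str, float], bool]:
    """Unweighted mean of per-plane features, ignoring per-plane NaNs.

    Returns ``(features, complete)``; ``complete`` is False when any
    feature is missing in every plane or present in only a subset of the
    planes (the tumor should then be flagged for review).
    """
    if not plane_features:
        raise ValueError("need at least one plane")
    complete = True
    out: dict[str, float] = {}
    for name in FEATURE_NAMES:
        vals = np.array([p[name] for p in plane_features], dtype=float)
        finite = np.isfinite(vals)
        if finite.all():
            out[name] = float(vals.mean())
        elif finite.any():
            out[name] = float(vals[finite].mean())
            complete = False
        else:
            out[name] = np.nan
            complete = False
    return out, complete
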