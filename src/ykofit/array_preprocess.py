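"""Feature-level array intensities -> one log2 value per tag per array.

Each tag is printed as several replicate features dispersed across the array;
single-feature hybridization artifacts are removed by a robust MAD trim before
averaging. All intensities are log2 from ingestion onward.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import InputError, TagIntensityMatrix, validate_manifest

MAD_SCALE = 1.4826  # consistency factor so MAD estimates a normal sd


def load_intensity_table(
    path: str | Path, manifest_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a feature-level intensity TSV plus its array manifest.

    The intensity table carries tag_id, array_id and feature_1..k columns;
    the manifest is validated (required columns, known roles, unique
    array_id, a control array in every set).
    """
    features = pd.read_csv(path, sep="\t")
    for col in ("tag_id", "array_id"):
        if col not in features.columns:
            raise InputError(f"intensity table is missing required column {col!r}")
    if not [c for c in features.columns if c.startswith("feature_")]:
        raise InputError("intensity table has no feature_* columns")
    manifest = validate_manifest(pd.read_csv(manifest_path, sep="\t"))
    unknown = sorted(set(features["array_id"]) - set(manifest.index))
    if unknown:
        raise InputError(f"arrays {unknown} appear in intensities but not in manifest")
    return features, manifest


def mask_replicate_features(
    features: np.ndarray | list[float],
    mad_k: float = 4.0,
    min_keep: int = 3,
) -> tuple[float, np.ndarray]:
    """Flag artifact features and summarize the rest.

    A feature is flagged when |x - median| > mad_k * MAD (MAD scaled by
    1.4826). A zero MAD means at least half the features share one exact
    value, so the spread of the well-behaved features is zero; the rule then
    degenerates and flagging falls back to: a feature is an artifact if it
    deviates from that majority value by more than a numerical tolerance. If
    flagging would leave fewer than ``min_keep`` features, the ``min_keep``
    closest to the median are kept instead. Returns (mean of unflagged,
    flags); the summary is NaN when fewer than ``min_keep`` finite features
    exist.
    """
    x = np.asarray(features, dtype=float)
    flags = np.zeros(x.shape, dtype=bool)
    finite = np.isfinite(x)
    if finite.sum() < min_keep:
        return float("nan"), flags
    xv = x[finite]
    med = np.median(xv)
    mad = MAD_SCALE * np.median(np.abs(xv - med))
    if mad > 0:
        out = np.abs(xv - med) > mad_k * mad
    else:
        out = _zero_mad_outliers(xv, med)
    if (~out).sum() < min_keep:
        keep_idx = np.argsort(np.abs(xv - med), kind="stable")[:min_keep]
        out = np.ones(xv.shape, dtype=bool)
        out[keep_idx] = False
    flags[finite] = out
    summary = float(xv[~out].mean())
    return summary, flags


def _zero_mad_outliers(xv: np.ndarray, med: float) -> np.ndarray:
    """MAD=0 fallback: a zero MAD means at least half the features equal the
    median exactly, so the well-behaved spread is zero and any feature off
    that majority value (beyond rounding error) is flagged."""
    if xv.size < 3:
        return np.zeros(xv.size, dtype=bool)
    tol = 1e-9 * (1.0 + abs(med))
    return np.abs(xv - med) > tol


def summarize_to_tags(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    mad_k: float = 4.0,
    min_keep: int = 3,
) -> TagIntensityMatrix:
    """Collapse replicate features to one value per (tag, array).

    Vectorized version of :func:`mask_replicate_features` over all rows;
    every removed feature is recorded in the returned matrix's ``mask_log``.
    Tags with fewer than ``min_keep`` finite features on an array are NaN
    (missing) there.
    """
    feat_cols = [c for c in features.columns if c.startswith("feature_")]
    if not feat_cols:
        raise InputError("no feature_* columns to summarize")
    X = features[feat_cols].to_numpy(dtype=float)
    n, k = X.shape
    finite = np.isfinite(X)
    n_finite = finite.sum(axis=1)

    if k == 1:
        summary = X[:, 0].copy()
        flags = np.zeros_like(X, dtype=bool)
        summary[n_finite < min(min_keep, 1)] = np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(X, axis=1, keepdims=True)
            mad = MAD_SCALE * np.nanmedian(np.abs(X - med), axis=1, keepdims=True)
        dev = np.abs(X - med)
        flags = dev > mad_k * mad  # NaN comparisons yield False
        flags &= finite

        zero_mad = (mad[:, 0] == 0) & (n_finite >= min_keep)
        if zero_mad.any():
            tol = 1e-9 * (1.0 + np.abs(med[:, 0]))
            fallback = (dev > tol[:, None]) & finite
            flags[zero_mad] = fallback[zero_mad]

        # never flag below min_keep survivors: keep the closest to the median
        kept = finite & ~flags
        too_few = (kept.sum(axis=1) < min_keep) & (n_finite >= min_keep)
        for i in np.nonzero(too_few)[0]:
            order = np.argsort(np.where(finite[i], dev[i], np.inf), kind="stable")
            row = np.ones(k, dtype=bool)
            row[order[:min_keep]] = False
            flags[i] = row & finite[i]

        kept = finite & ~flags
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            summary = np.where(kept, X, np.nan)
            summary = np.nanmean(summary, axis=1)
        summary[n_finite < min_keep] = np.nan
        flags[n_finite < min_keep] = False

    ri, fi = np.nonzero(flags)
    mask_log = pd.DataFrame(
        {
            "tag_id": features["tag_id"].to_numpy()[ri],
            "array_id": features["array_id"].to_numpy()[ri],
            "feature": fi + 1,
            "reason": "mad_outlier",
        }
    )

    values = (
        pd.DataFrame(
            {
                "tag_id": features["tag_id"],
                "array_id": features["array_id"],
                "value": summary,
            }
        )
        .pivot(index="tag_id", columns="array_id", values="value")
        .rename_axis(index=None, columns=None)
    )
    # preserve first-seen tag order from the input table and manifest array order
    order = features["tag_id"].drop_duplicates().tolist()
    values = values.loc[order, [a for a in manifest.index if a in values.columns]]
    return TagIntensityMatrix(values=values, manifest=manifest, mask_log=mask_log)
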