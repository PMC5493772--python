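"""Fitness-defect scoring from tag intensities.

Within a set (collection x media): uptags and downtags are median-normalized
separately across arrays, each strain is collapsed to its best tag (lowest
coefficient of variation across control replicates), arrays are batch
corrected, and the fitness defect of a strain on a treatment array is

    FD = median log2 intensity over control arrays - treatment log2 intensity

so a positive FD means depletion (a fitness defect). Condition-level scores
are medians over the replicate treatment arrays; significance is assessed per
strain per condition with Benjamini-Hochberg correction across strains.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._types import (
    FitnessTable,
    InputError,
    TagIntensityMatrix,
    library_tags,
    strain_of,
)

MAD_SCALE = 1.4826
TINY_P = np.finfo(float).tiny


def normalize_by_tag_class_median(
    matrix: TagIntensityMatrix, library: pd.DataFrame
) -> tuple[TagIntensityMatrix, pd.DataFrame]:
    """Median-align uptags and downtags separately within each set.

    Each array's uptag values are shifted so its uptag median equals the
    set's grand uptag median (the median of the per-array medians, which
    makes the operation exactly idempotent); likewise for downtags. Returns
    the normalized matrix and a log of the applied shifts. A single-array
    set is returned unchanged with a warning.
    """
    tagtab = library_tags(library).set_index("tag_id")
    out = matrix.copy()
    shifts = []
    for coll, media in matrix.sets():
        arrays = matrix.arrays_in_set(coll, media)
        if len(arrays) < 2:
            warnings.warn(
                f"set ({coll}, {media}) has a single array; normalization skipped"
            )
            continue
        for tag_class in ("uptag", "downtag"):
            rows = [
                t for t in matrix.values.index
                if t in tagtab.index and tagtab.loc[t, "tag_class"] == tag_class
            ]
            if not rows:
                continue
            block = out.values.loc[rows, arrays]
            array_medians = block.median(axis=0)
            grand = float(array_medians.median())
            shift = grand - array_medians
            out.values.loc[rows, arrays] = block.add(shift, axis=1)
            for arr in arrays:
                shifts.append(
                    {
                        "collection": coll,
                        "media": media,
                        "array_id": arr,
                        "tag_class": tag_class,
                        "shift": float(shift[arr]),
                    }
                )
    return out, pd.DataFrame(shifts)


def select_best_tag(
    matrix: TagIntensityMatrix,
    library: pd.DataFrame,
    strains: set[str] | None = None,
) -> tuple[pd.DataFrame, TagIntensityMatrix]:
    """Collapse the two tags per strain to the best one.

    The best tag has the lowest coefficient of variation (sd/mean of the
    linear-scale 2^log2 intensities) across the set's control replicates;
    ties go to the uptag. Strains with no usable tag are excluded. Returns
    (choice table, strains x arrays matrix).
    """
    tagtab = library_tags(library).set_index("tag_id")
    choices = []
    blocks = []
    for coll, media in matrix.sets():
        arrays = matrix.arrays_in_set(coll, media)
        controls = matrix.arrays_in_set(coll, media, role="control")
        if len(controls) < 2:
            raise InputError(
                f"set ({coll}, {media}) needs >= 2 control replicates for CV-based tag selection"
            )
        lin = 2.0 ** matrix.values.loc[:, controls]
        cv = lin.std(axis=1, ddof=1) / lin.mean(axis=1)

        strain_rows = {}
        for tag in matrix.values.index:
            if tag not in tagtab.index:
                continue
            s = tagtab.loc[tag, "strain_id"]
            if strains is not None and s not in strains:
                continue
            strain_rows.setdefault(s, {})[tagtab.loc[tag, "tag_class"]] = tag

        collapsed = {}
        for s, tags in strain_rows.items():
            cands = {
                cls: t for cls, t in tags.items() if np.isfinite(cv.get(t, np.nan))
            }
            if not cands:
                continue
            if "uptag" in cands and "downtag" in cands:
                # strict inequality: an exact tie keeps the uptag
                cls = "downtag" if cv[cands["downtag"]] < cv[cands["uptag"]] else "uptag"
            else:
                cls = next(iter(cands))
            choices.append(
                {"strain_id": s, "collection": coll, "media": media, "tag_class": cls}
            )
            collapsed[s] = matrix.values.loc[cands[cls], arrays]
        blocks.append(pd.DataFrame(collapsed).T)

    values = pd.concat(blocks, axis=1) if blocks else pd.DataFrame()
    out = TagIntensityMatrix(values=values, manifest=matrix.manifest)
    return pd.DataFrame(choices), out


def batch_correct(matrix: TagIntensityMatrix) -> TagIntensityMatrix:
    """Location-scale batch standardization within each set.

    Per strain, per batch: subtract the batch mean, divide by the batch sd,
    then restore the strain's pooled mean and sd over the set, so the
    strain's pooled mean is preserved. Batches with a single array (or zero
    within-batch variance) get a location-only correction with a warning;
    single-batch sets are returned unchanged.
    """
    out = matrix.copy()
    man = matrix.manifest
    for coll, media in matrix.sets():
        arrays = matrix.arrays_in_set(coll, media)
        batches = man.loc[arrays, "batch"]
        if batches.nunique() < 2:
            continue
        X = out.values.loc[:, arrays].to_numpy(dtype=float)
        pooled_mean = X.mean(axis=1, keepdims=True)
        pooled_sd = X.std(axis=1, ddof=1, keepdims=True)
        new = np.empty_like(X)
        for b in batches.unique():
            idx = np.nonzero((batches == b).to_numpy())[0]
            Xb = X[:, idx]
            m = Xb.mean(axis=1, keepdims=True)
            if len(idx) < 2:
                warnings.warn(
                    f"batch {b!r} in set ({coll}, {media}) has one array; "
                    "location-only correction applied"
                )
                new[:, idx] = Xb - m + pooled_mean
                continue
            s = Xb.std(axis=1, ddof=1, keepdims=True)
            z = np.where(s > 0, (Xb - m) / np.where(s > 0, s, 1.0), 0.0)
            new[:, idx] = z * pooled_sd + pooled_mean
        out.values.loc[:, arrays] = new
    return out


def compute_fd_scores(matrix: TagIntensityMatrix) -> FitnessTable:
    """FD scores for one set's collapsed strain x array matrix.

    FD(strain, treatment array) = median over control arrays - treatment
    value; FD_median is the per-condition median over replicate arrays.
    """
    sets = matrix.sets()
    if len(sets) != 1:
        raise InputError(
            "compute_fd_scores operates on a single set; got " + str(sets)
        )
    coll, media = sets[0]
    controls = matrix.arrays_in_set(coll, media, role="control")
    if not controls:
        raise InputError(f"set ({coll}, {media}) has no control arrays")
    treatments = matrix.arrays_in_set(coll, media, role="treatment")
    ctrl_median = matrix.values[controls].median(axis=1)

    man = matrix.manifest.loc[treatments]
    fd: dict[str, pd.DataFrame] = {}
    for cond, grp in man.groupby("condition", sort=True):
        arrs = list(grp.index)
        if not arrs:
            raise InputError(f"condition {cond!r} has no treatment arrays")
        fd[cond] = matrix.values[arrs].rsub(ctrl_median, axis=0)
    if not fd:
        raise InputError(f"set ({coll}, {media}) has no treatment arrays")
    fd_median = pd.DataFrame({c: df.median(axis=1) for c, df in fd.items()})
    return FitnessTable(fd=fd, fd_median=fd_median, collection=coll, media=media)


def compute_significance(
    fd: dict[str, pd.DataFrame], method: str = "t"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-strain, per-condition test of mean FD != 0, BH-corrected.

    method="t"
        Intercept-only least-squares fit of the replicate FDs per strain,
        i.e. a one-sample two-sided t test (df = n_replicates - 1). Zero
        replicate variance with a nonzero mean yields the smallest
        representable p.
    method="robust_z"
        A genome-wide null model: the mean FD is standardized by the robust
        (MAD-based) spread of mean FDs across all strains in the condition,
        and referred to a standard normal. This pools the null variance over
        the screen - including the control-median error shared by a strain's
        replicates, which no within-strain estimate can see - and is the
        pipeline default for genome-scale screens.

    Returns (p, q, statistic), each strains x conditions; q is BH step-up
    within each condition.
    """
    if method not in ("t", "robust_z"):
        raise InputError(f"unknown significance method {method!r}")
    p_cols, q_cols, s_cols = {}, {}, {}
    for cond, reps in fd.items():
        X = reps.to_numpy(dtype=float)
        if X.shape[1] < 2:
            raise InputError(f"condition {cond!r} has fewer than 2 replicates")
        n = np.isfinite(X).sum(axis=1)
        mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=1)
        if method == "t":
            sd = np.nanstd(np.where(np.isfinite(X), X, np.nan), axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = mean / (sd / np.sqrt(n))
            p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 1, 1))
            zero_var = sd == 0
            p[zero_var & (mean == 0)] = 1.0
            p[zero_var & (mean != 0)] = TINY_P
            stat = t
        else:
            center = np.nanmedian(mean)
            scale = MAD_SCALE * np.nanmedian(np.abs(mean - center))
            if scale == 0:
                diff = mean - center
                z = np.sign(diff) * np.where(diff == 0, 0.0, np.inf)
            else:
                z = (mean - center) / scale
            p = 2.0 * stats.norm.sf(np.abs(z))
            p[p == 0] = TINY_P
            stat = z
        p[n < 2] = np.nan

        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        idx = reps.index
        p_cols[cond] = pd.Series(p, index=idx)
        q_cols[cond] = pd.Series(q, index=idx)
        s_cols[cond] = pd.Series(stat, index=idx)
    return pd.DataFrame(p_cols), pd.DataFrame(q_cols), pd.DataFrame(s_cols)


def add_significance(table: FitnessTable, method: str = "robust_z") -> FitnessTable:
    table.p, table.q, table.stat = compute_significance(table.fd, method=method)
    return table


def score_set(
    matrix: TagIntensityMatrix,
    library: pd.DataFrame,
    collection: str,
    media: str,
    present_strains: set[str] | None = None,
    significance_method: str = "robust_z",
) -> FitnessTable:
    """Run the full within-set chain: normalize -> best tag -> batch correct
    -> FD -> significance, restricted to ``present_strains`` when given."""
    arrays = matrix.arrays_in_set(collection, media)
    sub = TagIntensityMatrix(
        values=matrix.values[arrays],
        manifest=matrix.manifest.loc[arrays],
        mask_log=matrix.mask_log,
    )
    normed, _ = normalize_by_tag_class_median(sub, library)
    best, collapsed = select_best_tag(normed, library, strains=present_strains)
    corrected = batch_correct(collapsed)
    table = compute_fd_scores(corrected)
    table.best_tag = best.set_index("strain_id")["tag_class"] if len(best) else None
    return add_significance(table, method=significance_method)
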