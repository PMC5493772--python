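"""Shared fitness signatures and their subtraction.

When one confound produces the same fitness defects across a group of
conditions (for a plasmid-complemented prototrophic pool, the plasmid/
mini-chromosome maintenance burden shared by the histidine-, leucine- and
uracil-dropout screens), the shared signature is defined as the per-strain
median FD across the group and subtracted from each group condition, leaving
the condition-specific effects.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._types import InputError, Signature


def define_shared_signature(
    fd_median: pd.DataFrame,
    group: list[str] | tuple[str, ...],
    threshold: float = 1.0,
    rule: str = "all",
) -> Signature:
    """Define a shared signature over a condition group.

    ``fd_median`` is strains x conditions. The profile is the per-strain
    median FD across the group; members are the strains with FD_median >=
    threshold in every group condition (rule="all", default) or in at least
    one (rule="any").
    """
    group = tuple(group)
    missing = [c for c in group if c not in fd_median.columns]
    if missing:
        raise InputError(f"condition(s) {missing} not in the fitness table")
    if rule not in ("all", "any"):
        raise InputError(f"unknown membership rule {rule!r}")
    if len(group) == 1:
        warnings.warn("signature over a single condition equals that condition")
    block = fd_median[list(group)]
    profile = block.median(axis=1)
    passing = block >= threshold
    mask = passing.all(axis=1) if rule == "all" else passing.any(axis=1)
    # membership requires a defined FD in every group condition
    mask &= block.notna().all(axis=1)
    return Signature(
        condition_group=group,
        profile=profile,
        members=set(fd_median.index[mask]),
        threshold=threshold,
        rule=rule,
    )


def subtract_signature(
    fd_median: pd.Series, condition: str, signature: Signature
) -> tuple[pd.Series, set[str]]:
    """Recompute one group condition's FDs against the signature reference.

    corrected FD = FD_median - signature profile, per strain. Strains with no
    profile value pass through unchanged and are returned as flagged. Raises
    when the condition is outside the signature's group (the correction is
    undefined there).
    """
    if condition not in signature.condition_group:
        raise InputError(
            f"condition {condition!r} is outside the signature group "
            f"{signature.condition_group}; correction undefined"
        )
    profile = signature.profile.reindex(fd_median.index)
    corrected = fd_median - profile.fillna(0.0)
    flagged = set(fd_median.index[profile.isna()])
    return corrected, flagged


def profile_correlation(
    fd_a: pd.DataFrame,
    fd_b: pd.DataFrame,
    threshold: float = 1.0,
    conditions: list[str] | None = None,
) -> pd.Series:
    """Pearson r between two collections' fitness profiles, per condition.

    Computed over the strains present in both tables whose FD_median exceeds
    ``threshold`` in at least one shared condition (in either collection).
    Conditions with fewer than 3 qualifying strains report NaN.
    """
    shared = [c for c in fd_a.columns if c in fd_b.columns]
    if conditions is not None:
        shared = [c for c in shared if c in conditions]
    if not shared:
        raise InputError("no shared conditions between the two fitness tables")
    strains = fd_a.index.intersection(fd_b.index)
    a = fd_a.loc[strains, shared]
    b = fd_b.loc[strains, shared]
    include = ((a > threshold) | (b > threshold)).any(axis=1)
    out = {}
    for cond in shared:
        x = a.loc[include, cond]
        y = b.loc[include, cond]
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            out[cond] = float("nan")
        else:
            out[cond] = float(pearsonr(x[ok], y[ok])[0])
    return pd.Series(out)


def signature_frame(signature: Signature) -> pd.DataFrame:
    """Exportable per-strain view: profile FD and membership flag."""
    return pd.DataFrame(
        {
            "strain_id": signature.profile.index,
            "profile_fd": signature.profile.to_numpy(),
            "member": [
                int(s in signature.members) for s in signature.profile.index
            ],
        }
    )
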