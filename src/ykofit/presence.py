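"""Strain presence calling and roster comparison.

Pool composition differs between deletion collections, so the background
threshold separating hybridized (present) from unhybridized (absent) tags is
fitted independently per pool: a two-component Gaussian mixture on the
control-array tag intensities. A strain is called present only when every one
of its tags has posterior P(present) strictly greater than the threshold on
every control replicate; absent strains are removed before any downstream
fitness analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._types import (
    DegenerateInputError,
    InputError,
    MixtureFit,
    PresenceCall,
    TagIntensityMatrix,
    VennCounts,
    library_tags,
)

VAR_FLOOR = 1e-4
SEPARATION_SD = 0.5  # below this many pooled sd between means: "no separation"


class NoSeparationWarning(UserWarning):
    """The two fitted components are not meaningfully separated."""


def fit_background_mixture(
    intensities: np.ndarray | pd.Series,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Fit a 1-D two-component Gaussian mixture by EM.

    Deterministic initialization: means at the 25th/75th percentiles, equal
    weights, pooled sd (``seed`` is accepted for API symmetry; the default
    fit uses no randomness). Components are relabeled so the present
    component has the larger mean. The log-likelihood is non-decreasing over
    iterations; variances are floored at 1e-4.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise DegenerateInputError("need >= 20 finite intensities to fit a background")
    pooled_sd = float(np.std(x))
    if pooled_sd == 0:
        raise DegenerateInputError("all intensities identical; mixture undefined")

    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    sd = np.array([pooled_sd, pooled_sd])
    w = np.array([0.5, 0.5])

    trace = []
    converged = False
    for _ in range(max_iter):
        # E step in log space
        log_comp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sd[:, None])
        m = log_comp.max(axis=0)
        log_norm = m + np.log(np.exp(log_comp - m).sum(axis=0))
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm)

        trace.append(ll)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) < tol * max(abs(prev), 1.0):
                converged = True
                break

        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - mu**2
        sd = np.sqrt(np.maximum(var, VAR_FLOOR))

    if not converged:
        warnings.warn("EM did not converge; returning best fit", RuntimeWarning)

    order = np.argsort(mu)  # absent first, present second
    mu, sd, w = mu[order], sd[order], w[order]
    separated = abs(mu[1] - mu[0]) >= SEPARATION_SD * pooled_sd
    if not separated:
        warnings.warn(
            "mixture components are not separated "
            f"(|mu_p - mu_a| = {abs(mu[1] - mu[0]):.3f} < "
            f"{SEPARATION_SD} * pooled sd = {SEPARATION_SD * pooled_sd:.3f}); "
            "presence calling will treat all tags as present",
            NoSeparationWarning,
        )
    return MixtureFit(
        weights=w,
        means=mu,
        sds=sd,
        loglik_trace=np.array(trace),
        converged=converged,
        separated=separated,
        n=x.size,
    )


def call_tag_presence(
    fits: dict[str, MixtureFit],
    values: pd.DataFrame,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tag presence per control array: posterior strictly > threshold.

    ``fits`` maps control array id -> its background fit; ``values`` is the
    tags x arrays intensity matrix restricted (or restrictable) to those
    arrays. Returns (boolean calls, posteriors), tags x control arrays. For a
    non-separated fit every tag on that array is called present (conservative
    fallback: no mass false absences when the pool has no absent mode).
    """
    missing = [a for a in fits if a not in values.columns]
    if missing:
        raise InputError(f"no intensity column for control array(s) {missing}")
    post = {}
    calls = {}
    for arr, fit in fits.items():
        p = fit.posterior(values[arr].to_numpy())
        post[arr] = p
        if fit.separated:
            calls[arr] = p > threshold
        else:
            calls[arr] = np.ones(len(p), dtype=bool)
    posteriors = pd.DataFrame(post, index=values.index)
    return pd.DataFrame(calls, index=values.index), posteriors


def call_strain_presence(
    tag_calls: pd.DataFrame,
    posteriors: pd.DataFrame,
    library: pd.DataFrame,
    collection: str = "",
    media: str = "",
    threshold: float = 0.5,
) -> PresenceCall:
    """Collapse tag calls to strains: present iff *all* tags representing the
    strain pass on *all* control replicates. Strains with no tags on the
    array are treated as absent and logged."""
    tagtab = library_tags(library)
    no_tag: list[str] = []
    present = {}
    for strain, grp in tagtab.groupby("strain_id", sort=False):
        tags = [t for t in grp["tag_id"] if t in tag_calls.index]
        if not tags:
            no_tag.append(strain)
            present[strain] = False
            continue
        present[strain] = bool(tag_calls.loc[tags].to_numpy().all())
    return PresenceCall(
        collection=collection,
        media=media,
        present=pd.Series(present),
        tag_posteriors=posteriors,
        threshold=threshold,
        no_tag_strains=no_tag,
    )


def call_presence(
    matrix: TagIntensityMatrix,
    library: pd.DataFrame,
    collection: str,
    media: str,
    threshold: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> PresenceCall:
    """Fit one background mixture per control array of a set and call strains."""
    controls = matrix.arrays_in_set(collection, media, role="control")
    if not controls:
        raise InputError(f"set ({collection}, {media}) has no control arrays")
    fits = {
        arr: fit_background_mixture(matrix.values[arr], tol=tol, max_iter=max_iter)
        for arr in controls
    }
    calls, post = call_tag_presence(fits, matrix.values[controls], threshold)
    return call_strain_presence(calls, post, library, collection, media, threshold)


def compare_rosters(calls: dict[str, PresenceCall]) -> VennCounts:
    """Venn-region counts of present strains across >=2 collections.

    The universe is the union of present strains; all 2^k - 1 occupied-or-not
    membership regions are enumerated, with the per-region strain lists kept
    for downstream enrichment.
    """
    if len(calls) < 2:
        raise InputError("roster comparison needs at least two collections")
    collections = list(calls)
    present = {c: calls[c].present_strains for c in collections}
    universe = set.union(*present.values())
    if not universe:
        raise InputError("no strain is present in any collection")

    regions: dict[tuple[bool, ...], set[str]] = {}
    for strain in universe:
        key = tuple(strain in present[c] for c in collections)
        regions.setdefault(key, set()).add(strain)
    # emit every non-empty-membership region, even when its count is zero
    from itertools import product

    counts = {}
    strains = {}
    for key in product([True, False], repeat=len(collections)):
        if not any(key):
            continue
        counts[key] = len(regions.get(key, set()))
        strains[key] = regions.get(key, set())
    return VennCounts(
        collections=collections, regions=counts, region_strains=strains, universe=universe
    )


def missing_strain_report(
    venn: VennCounts,
    calls: dict[str, PresenceCall],
    annotations: list[str] | None = None,
) -> pd.DataFrame:
    """Per collection: how many universe strains are missing, and what
    fraction of a supplied annotation list (e.g. known slow growers) is
    missing. Fractions are NaN when the annotation list is empty."""
    ann = set(annotations or [])
    rows = []
    for coll in venn.collections:
        present = calls[coll].present_strains & venn.universe
        missing = venn.universe - present
        frac = len(ann & missing) / len(ann) if ann else float("nan")
        rows.append(
            {
                "collection": coll,
                "n_present": len(present),
                "n_missing": len(missing),
                "frac_annotation_missing": frac,
            }
        )
    return pd.DataFrame(rows)
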