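"""Shared containers for the pooled-screen analysis.

All log-intensity data are handled on the log2 scale throughout. A "set" is a
(collection, media) pair: presence calling, normalization, best-tag selection
and fitness scoring are all done within a set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Columns every array/sample manifest must carry.
MANIFEST_COLUMNS = (
    "array_id",
    "collection",
    "media",
    "condition",
    "batch",
    "replicate",
    "role",
)

#: Allowed values of the manifest ``role`` column.
ROLES = ("control", "treatment")

#: Suffixes appended to a strain id to form its two tag ids.
TAG_SUFFIXES = {"uptag": "_up", "downtag": "_dn"}


class InputError(ValueError):
    """Malformed user input (bad table, unknown role, missing column...)."""


class DegenerateInputError(ValueError):
    """Input that is formally valid but statistically degenerate."""


def tag_id(strain_id: str, tag_class: str) -> str:
    """Canonical tag identifier for a strain's uptag or downtag."""
    return strain_id + TAG_SUFFIXES[tag_class]


def tag_class_of(tag: str) -> str:
    if tag.endswith("_up"):
        return "uptag"
    if tag.endswith("_dn"):
        return "downtag"
    raise InputError(f"tag id {tag!r} has no recognized _up/_dn suffix")


def strain_of(tag: str) -> str:
    return tag[:-3]


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check a manifest table and return it indexed by array_id.

    Raises :class:`InputError` naming the offending column/value when the
    table is malformed.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise InputError(f"manifest is missing required column(s): {missing}")
    if manifest["array_id"].duplicated().any():
        dup = manifest.loc[manifest["array_id"].duplicated(), "array_id"].tolist()
        raise InputError(f"duplicate array_id in manifest: {dup}")
    bad_roles = sorted(set(manifest["role"]) - set(ROLES))
    if bad_roles:
        raise InputError(
            f"unknown role(s) {bad_roles} in manifest; allowed roles are {list(ROLES)}"
        )
    out = manifest.set_index("array_id", drop=False)
    # every set must contain at least one control array for its treatments
    for (coll, media), grp in out.groupby(["collection", "media"]):
        if not (grp["role"] == "control").any():
            raise InputError(
                f"set ({coll}, {media}) has treatment arrays but no control array"
            )
    return out


@dataclass
class TagIntensityMatrix:
    """One log2 intensity per tag per array, plus the array manifest.

    ``values`` is a tags x arrays DataFrame; ``manifest`` is indexed by
    array_id; ``mask_log`` records every replicate feature removed during
    summarization as (tag_id, array_id, feature, reason).
    """

    values: pd.DataFrame
    manifest: pd.DataFrame
    mask_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["tag_id", "array_id", "feature", "reason"]
        )
    )

    def __post_init__(self) -> None:
        unknown = [a for a in self.values.columns if a not in self.manifest.index]
        if unknown:
            raise InputError(f"arrays {unknown} present in values but not in manifest")

    def sets(self) -> list[tuple[str, str]]:
        man = self.manifest.loc[list(self.values.columns)]
        return sorted({(r.collection, r.media) for r in man.itertuples()})

    def arrays_in_set(self, collection: str, media: str, role: str | None = None) -> list[str]:
        man = self.manifest.loc[list(self.values.columns)]
        sel = (man["collection"] == collection) & (man["media"] == media)
        if role is not None:
            sel &= man["role"] == role
        return list(man.index[sel])

    def copy(self) -> "TagIntensityMatrix":
        return TagIntensityMatrix(
            self.values.copy(), self.manifest.copy(), self.mask_log.copy()
        )


@dataclass
class TruthBundle:
    """Planted ground truth for a synthetic pooled screen.

    ``fitness_coeff`` maps (strain, condition) to the per-generation relative
    growth deficit d >= 0; the planted log2 fitness defect after ``generations``
    doublings is g*d. Strains absent from the map have d = 0.
    """

    strains: list[str]
    present_by_collection: dict[str, set[str]]
    fitness_coeff: dict[tuple[str, str], float]
    conditions: set[str]
    generations: int = 5
    signature_members: set[str] = field(default_factory=set)
    signature_conditions: tuple[str, ...] = ()
    batch_of_array: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        strain_set = set(self.strains)
        for (strain, cond), d in self.fitness_coeff.items():
            if strain not in strain_set:
                raise InputError(f"fitness_coeff strain {strain!r} not in strains")
            if cond == "control" and d != 0:
                raise InputError("control-condition fitness coefficients must be 0")
            if d < 0:
                raise InputError("fitness coefficients must be >= 0")
        for coll, present in self.present_by_collection.items():
            extra = present - strain_set
            if extra:
                raise InputError(
                    f"present_by_collection[{coll!r}] contains unknown strains {sorted(extra)[:3]}"
                )

    def planted_fd(self, strain: str, condition: str) -> float:
        """Planted log2 fitness defect g*d for a strain in a condition."""
        return self.generations * self.fitness_coeff.get((strain, condition), 0.0)


@dataclass
class MixtureFit:
    """Two-component Gaussian background fit on one control array.

    Components are relabeled after EM so index 0 is the absent (low) and
    index 1 the present (high) component.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    separated: bool
    n: int

    def posterior(self, x: np.ndarray | float) -> np.ndarray:
        """P(present | intensity) under the fitted mixture."""
        x = np.asarray(x, dtype=float)
        from scipy.stats import norm

        la = np.log(self.weights[0]) + norm.logpdf(x, self.means[0], self.sds[0])
        lp = np.log(self.weights[1]) + norm.logpdf(x, self.means[1], self.sds[1])
        m = np.maximum(la, lp)
        return np.exp(lp - m) / (np.exp(la - m) + np.exp(lp - m))


@dataclass
class PresenceCall:
    """Present/absent call per strain within one collection's set."""

    collection: str
    media: str
    present: pd.Series  # bool per strain
    tag_posteriors: pd.DataFrame  # tags x control arrays
    threshold: float
    no_tag_strains: list[str] = field(default_factory=list)

    @property
    def present_strains(self) -> set[str]:
        return set(self.present.index[self.present])


@dataclass
class VennCounts:
    """Region counts of present strains over >=2 collections."""

    collections: list[str]
    regions: dict[tuple[bool, ...], int]
    region_strains: dict[tuple[bool, ...], set[str]]
    universe: set[str]

    def count(self, *members: str) -> int:
        key = tuple(c in members for c in self.collections)
        return self.regions.get(key, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, n in sorted(self.regions.items(), reverse=True):
            mask = "".join("1" if b else "0" for b in key)
            label = "&".join(c for c, b in zip(self.collections, key) if b)
            rows.append({"region": label, "bitmask": mask, "count": n})
        return pd.DataFrame(rows)


@dataclass
class FitnessTable:
    """Fitness-defect scores per strain, per condition.

    ``fd`` maps condition -> strains x replicate-array DataFrame of FD scores
    (control median minus treatment, positive = depleted); ``fd_median`` is
    the strains x conditions median over replicates; p and q are filled in by
    :func:`ykofit.fitness.compute_significance`.
    """

    fd: dict[str, pd.DataFrame]
    fd_median: pd.DataFrame
    p: pd.DataFrame | None = None
    q: pd.DataFrame | None = None
    stat: pd.DataFrame | None = None
    best_tag: pd.Series | None = None
    collection: str | None = None
    media: str | None = None

    @property
    def conditions(self) -> list[str]:
        return list(self.fd_median.columns)

    def to_frame(self) -> pd.DataFrame:
        """Long export: one row per strain x condition with replicate FDs."""
        rows = []
        for cond, reps in self.fd.items():
            df = pd.DataFrame(
                {f"fd_rep{i + 1}": reps.iloc[:, i] for i in range(reps.shape[1])}
            )
            df.insert(0, "condition", cond)
            df["fd_median"] = self.fd_median[cond]
            if self.p is not None:
                df["p"] = self.p[cond]
            if self.q is not None:
                df["q"] = self.q[cond]
            df.insert(0, "strain_id", df.index)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass
class Signature:
    """A shared fitness signature across a condition group."""

    condition_group: tuple[str, ...]
    profile: pd.Series  # per-strain median FD across the group
    members: set[str]
    threshold: float
    rule: str = "all"


@dataclass
class CountMatrix:
    """Bar-seq tag counts with per-sample read accounting."""

    counts: pd.DataFrame  # tags x samples, int
    manifest: pd.DataFrame  # indexed by sample id: condition, replicate, role
    stats: pd.DataFrame  # per sample: total, matched, ambiguous, unmatched

    def __post_init__(self) -> None:
        s = self.stats
        if len(s):
            tot = s["matched"] + s["ambiguous"] + s["unmatched"]
            if not (tot == s["total"]).all():
                raise AssertionError("read accounting does not conserve totals")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # hits in query
    K: int  # term size within universe
    n: int  # query size
    N: int  # universe size
    p_raw: float
    p_adj: float
    passed: bool


def library_tags(library: pd.DataFrame) -> pd.DataFrame:
    """Expand a strain library to one row per tag.

    Input columns: strain_id, uptag_seq, downtag_seq. Output: tag_id,
    strain_id, tag_class, seq.
    """
    for col in ("strain_id", "uptag_seq", "downtag_seq"):
        if col not in library.columns:
            raise InputError(f"library is missing required column {col!r}")
    rows = []
    for r in library.itertuples():
        rows.append((tag_id(r.strain_id, "uptag"), r.strain_id, "uptag", r.uptag_seq))
        rows.append((tag_id(r.strain_id, "downtag"), r.strain_id, "downtag", r.downtag_seq))
    return pd.DataFrame(rows, columns=["tag_id", "strain_id", "tag_class", "seq"])
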