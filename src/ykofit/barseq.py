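"""Bar-seq barcode quantification and count-based fitness scores.

Reads are trimmed, the 20-base barcode is located via its constant primer
context (with a full-offset scan as fallback) and matched against the
barcode library: exact hits by hash lookup, otherwise the best Hamming-
distance hit within ``max_mismatch``, counted only when the best hit is
unique and beats the runner-up by at least one mismatch. Tag counts are
filtered on control coverage, summed per strain, normalized by
median-of-ratios size factors and converted to log2 fitness-defect scores.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from ._types import CountMatrix, FitnessTable, InputError, library_tags, validate_manifest
from .fitness import compute_significance

DEFAULT_ANCHORS = (synthetic.UPTAG_ANCHOR, synthetic.DOWNTAG_ANCHOR)
BARCODE_LEN = 20


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path):
    """Yield (name, sequence) from a FASTQ file, gzipped or plain."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            plus = fh.readline()
            fh.readline()  # qualities, unused
            if not header.startswith("@") or not plus.startswith("+"):
                raise InputError(f"{path}: malformed FASTQ record near {header!r}")
            yield header[1:].strip(), seq


class _Matcher:
    """Barcode matcher: exact hash lookup plus vectorized Hamming search."""

    def __init__(self, tagtab: pd.DataFrame, max_mismatch: int, anchors):
        if tagtab["seq"].duplicated().any():
            dups = tagtab.loc[tagtab["seq"].duplicated(), "tag_id"].tolist()
            raise InputError(f"duplicate barcode sequences in library (e.g. {dups[:3]})")
        self.tags = tagtab["tag_id"].tolist()
        self.exact = dict(zip(tagtab["seq"], range(len(self.tags))))
        self.bc = np.vstack(
            [np.frombuffer(s.encode(), dtype=np.uint8) for s in tagtab["seq"]]
        )
        self.max_mismatch = max_mismatch
        self.anchors = list(anchors)

    def _best(self, dists: np.ndarray) -> int | None:
        """Index of the unique best barcode, or None (ambiguous/unmatched).

        ``dists`` is the per-barcode minimum distance over the windows
        considered. A hit must be within max_mismatch and beat the runner-up
        by >= 1 mismatch.
        """
        i = int(dists.argmin())
        d1 = int(dists[i])
        if d1 > self.max_mismatch:
            return None
        dists[i] = np.iinfo(dists.dtype).max if dists.dtype.kind in "iu" else np.inf
        d2 = int(dists.min()) if dists.size > 1 else d1 + 2
        dists[i] = d1
        if d2 <= d1:  # tie or better elsewhere: ambiguous
            return -1
        return i

    def match(self, seq: str) -> int | None:
        """Return barcode index, -1 for ambiguous, None for unmatched."""
        for anchor in self.anchors:
            pos = seq.find(anchor)
            if pos < 0:
                continue
            start = pos + len(anchor)
            window = seq[start : start + BARCODE_LEN]
            if len(window) < BARCODE_LEN:
                continue
            hit = self.exact.get(window)
            if hit is not None:
                return hit
            w = np.frombuffer(window.encode(), dtype=np.uint8)
            dists = (self.bc != w).sum(axis=1)
            res = self._best(dists)
            if res is not None:
                return res
        # no (clean) anchor: scan every offset
        if len(seq) < BARCODE_LEN:
            return None
        s = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(s, BARCODE_LEN)
        dists = (windows[:, None, :] != self.bc[None, :, :]).sum(axis=2).min(axis=0)
        return self._best(dists)


def trim_and_match(
    fastq_paths: dict[str, str | Path],
    library: pd.DataFrame,
    sample_manifest: pd.DataFrame,
    trim_len: int = 50,
    max_mismatch: int = 2,
    anchors=DEFAULT_ANCHORS,
) -> CountMatrix:
    """Count barcode hits per tag per sample.

    ``fastq_paths`` maps sample id -> FASTQ path (gzip ok); ``sample_manifest``
    uses the manifest dialect with array_id as the sample id. Reads are
    trimmed to ``trim_len`` bases (shorter reads are used whole) before
    matching. Per-sample totals satisfy matched + ambiguous + unmatched =
    total.
    """
    if library is None or not len(library):
        raise InputError("a barcode library is required for matching")
    manifest = validate_manifest(sample_manifest)
    unknown = sorted(set(fastq_paths) - set(manifest.index))
    if unknown:
        raise InputError(f"samples {unknown} have FASTQ files but no manifest row")
    matcher = _Matcher(library_tags(library), max_mismatch, anchors)

    counts = {}
    stats = []
    for sample in manifest.index:
        if sample not in fastq_paths:
            raise InputError(f"sample {sample!r} has no FASTQ file")
        path = Path(fastq_paths[sample])
        if not path.exists():
            raise InputError(f"FASTQ file not found: {path}")
        c = np.zeros(len(matcher.tags), dtype=np.int64)
        total = matched = ambiguous = 0
        for _, seq in read_fastq(path):
            total += 1
            res = matcher.match(seq[:trim_len])
            if res is None:
                continue
            if res == -1:
                ambiguous += 1
            else:
                matched += 1
                c[res] += 1
        if total == 0:
            raise InputError(f"FASTQ file {path} contains no reads")
        counts[sample] = c
        stats.append(
            {
                "sample": sample,
                "total": total,
                "matched": matched,
                "ambiguous": ambiguous,
                "unmatched": total - matched - ambiguous,
            }
        )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=matcher.tags),
        manifest=manifest,
        stats=pd.DataFrame(stats).set_index("sample"),
    )


def filter_and_combine(
    cm: CountMatrix,
    library: pd.DataFrame,
    min_control_count: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep tags with >= min_control_count in *every* control replicate, then
    sum surviving uptag + downtag counts per strain.

    Returns (strain x sample matrix, dropped log). Strains whose tags are all
    filtered are dropped and logged; raises when no tag survives.
    """
    controls = list(cm.manifest.index[cm.manifest["role"] == "control"])
    if not controls:
        raise InputError("no control samples for the count filter")
    keep = (cm.counts[controls] >= min_control_count).all(axis=1)
    if not keep.any():
        raise InputError(
            f"no tag reaches {min_control_count} counts in every control replicate"
        )
    tagtab = library_tags(library).set_index("tag_id")
    surv = cm.counts[keep]
    strain_ids = tagtab.loc[surv.index, "strain_id"]
    strain_counts = surv.groupby(strain_ids.to_numpy()).sum()
    strain_counts.index.name = "strain_id"

    dropped = []
    for tag in cm.counts.index[~keep]:
        dropped.append(
            {"id": tag, "kind": "tag", "reason": "below_min_control_count"}
        )
    lost = set(tagtab["strain_id"]) - set(strain_counts.index)
    for s in sorted(lost):
        dropped.append({"id": s, "kind": "strain", "reason": "no_surviving_tag"})
    return strain_counts, pd.DataFrame(dropped, columns=["id", "kind", "reason"])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Strains with a zero count in any sample are excluded from the reference
    (their geometric mean is degenerate); raises if none remain.
    """
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise InputError("no strain has nonzero counts in every sample")
    logc = np.log(counts[pos].to_numpy(dtype=float))
    ref = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - ref, axis=0))
    return pd.Series(sf, index=counts.columns)


def count_fitness(
    strain_counts: pd.DataFrame,
    sample_manifest: pd.DataFrame,
    pseudo: float = 0.5,
    significance_method: str = "robust_z",
) -> FitnessTable:
    """Count-based fitness defects.

    FD(strain, treatment sample) = log2(median normalized control count +
    pseudo) - log2(normalized treatment count + pseudo). Medians over
    replicate samples and the significance machinery mirror the array arm.
    """
    manifest = validate_manifest(sample_manifest)
    manifest = manifest.loc[[s for s in strain_counts.columns]]
    controls = list(manifest.index[manifest["role"] == "control"])
    treatments = manifest[manifest["role"] == "treatment"]
    if not controls or not len(treatments):
        raise InputError("count fitness needs >= 1 control and >= 1 treatment sample")
    sf = size_factors(strain_counts)
    norm = strain_counts / sf
    ctrl_log = np.log2(norm[controls].median(axis=1) + pseudo)

    fd: dict[str, pd.DataFrame] = {}
    for cond, grp in treatments.groupby("condition", sort=True):
        arrs = list(grp.index)
        fd[cond] = np.log2(norm[arrs] + pseudo).rsub(ctrl_log, axis=0)
    fd_median = pd.DataFrame({c: df.median(axis=1) for c, df in fd.items()})
    table = FitnessTable(fd=fd, fd_median=fd_median)
    table.p, table.q, table.stat = compute_significance(fd, method=significance_method)
    return table
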