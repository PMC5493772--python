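"""Synthetic pooled-screen generator.

Emulates the data a comparative deletion-collection fitness screen produces:

* a genetic roster per collection (strains present/absent in each pool),
* barcode-array intensities: each tag is represented by five replicate
  features; tag-level log2 intensity is bimodal (present vs absent tags),
  treatment arrays of a present strain are shifted down by g*d log2 units
  after g doublings at per-generation deficit d, with optional per-batch
  offsets and additive spatial artifacts on single features,
* Bar-seq reads: a primer context followed by the 20-base barcode, drawn
  multinomially per sample with abundances proportional to 2^(-g*d), with
  optional per-base substitution errors.

Everything is deterministic for a fixed seed; all text outputs are
byte-identical on re-runs.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import (
    InputError,
    TagIntensityMatrix,
    TruthBundle,
    library_tags,
    tag_id,
    validate_manifest,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Constant primer context flanking the barcodes in a Bar-seq read.
UPTAG_ANCHOR = "GATGTCCACGAGGTCTCT"
UPTAG_SUFFIX = "GTCGACCTGCAGCGTACG"
DOWNTAG_ANCHOR = "GAAAACGAGCTCGAATTCATCG"
DOWNTAG_SUFFIX = "CGGTGTCGGTCTCGTAG"
READ_LENGTH = 100


@dataclass
class ArraySimParams:
    """Parameters of the two-component intensity model.

    Defaults place the present and absent components >3 pooled sd apart,
    the regime in which mixture-based presence calling is reliable. noise_sd
    is per replicate feature; the tag-level summary of k features therefore
    has noise ~ noise_sd/sqrt(k).
    """

    mu_present: float = 10.0
    sigma_present: float = 0.8
    mu_absent: float = 6.5
    sigma_absent: float = 0.7
    n_replicate_features: int = 5
    artifact_rate: float = 0.0
    artifact_shift: float = 4.0
    batch_shift_sd: float = 0.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not self.mu_present > self.mu_absent:
            raise InputError("mu_present must exceed mu_absent")
        if self.sigma_present <= 0 or self.sigma_absent <= 0:
            raise InputError("component sds must be positive")
        if not 0 <= self.artifact_rate <= 1:
            raise InputError("artifact_rate must lie in [0, 1]")
        if self.n_replicate_features < 1:
            raise InputError("n_replicate_features must be >= 1")
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise InputError("noise scales must be >= 0")


@dataclass
class ScreenSim:
    """Output of :func:`generate_array_screen`."""

    features: pd.DataFrame  # tag_id, array_id, feature_1..k
    matrix: TagIntensityMatrix  # artifact-free feature means
    artifact_truth: pd.DataFrame  # tag_id, array_id, feature (planted artifacts)


def generate_truth(
    n_strains: int,
    collections: tuple[str, ...] = ("YKO",),
    dropout_fracs: dict[str, float] | None = None,
    effect_spec: dict[str, tuple[int, list[float]]] | None = None,
    conditions: list[str] | None = None,
    shared_signature: tuple[tuple[str, ...], int, float] | None = None,
    generations: int = 5,
    seed: int = 0,
) -> TruthBundle:
    """Plant a ground-truth screen.

    Parameters
    ----------
    dropout_fracs
        Per-collection fraction of strains absent from the pool, applied as a
        deterministic fixed fraction: the first floor(f*n) strains of a seeded
        shuffle are dropped, so roster counts are exact.
    effect_spec
        condition -> (n_hit, fd_sizes): plant n_hit strains with log2 fitness
        defects cycling through fd_sizes; the per-generation coefficient is
        d = FD / generations. Hit sets are disjoint across conditions and
        from the shared signature, so planted effects are condition-specific.
    shared_signature
        (condition_group, n_members, fd): plant one set of strains with the
        same defect in every condition of the group (a shared signature in
        the sense of the plasmid-maintenance HLU signature).
    """
    dropout_fracs = dropout_fracs or {}
    effect_spec = effect_spec or {}
    rng = np.random.default_rng(seed)
    strains = [f"S{i:04d}" for i in range(n_strains)]

    present_by_collection: dict[str, set[str]] = {}
    for coll in collections:
        f = float(dropout_fracs.get(coll, 0.0))
        if not 0 <= f < 1:
            raise InputError(f"dropout fraction for {coll!r} must lie in [0, 1)")
        perm = rng.permutation(n_strains)
        n_drop = math.floor(f * n_strains + 1e-9)
        dropped = {strains[i] for i in perm[:n_drop]}
        present_by_collection[coll] = set(strains) - dropped

    present_all = sorted(set.intersection(*present_by_collection.values()))
    cond_set = set(conditions or [])
    cond_set.update(effect_spec)
    fitness_coeff: dict[tuple[str, str], float] = {}

    signature_members: set[str] = set()
    signature_conditions: tuple[str, ...] = ()
    if shared_signature is not None:
        group, n_members, fd = shared_signature
        if fd < 0:
            raise InputError("signature FD must be >= 0")
        if n_members > len(present_all):
            raise InputError("signature asks for more members than present strains")
        picked = rng.choice(len(present_all), size=n_members, replace=False)
        signature_members = {present_all[i] for i in picked}
        signature_conditions = tuple(group)
        cond_set.update(group)
        for strain in signature_members:
            for cond in group:
                fitness_coeff[(strain, cond)] = fd / generations

    eligible = [s for s in present_all if s not in signature_members]
    for cond in sorted(effect_spec):
        n_hit, sizes = effect_spec[cond]
        if any(fd < 0 for fd in sizes):
            raise InputError("planted FD sizes must be >= 0")
        if n_hit > len(eligible):
            raise InputError(
                f"condition {cond!r} asks for {n_hit} hit strains but only "
                f"{len(eligible)} are eligible"
            )
        picked = rng.choice(len(eligible), size=n_hit, replace=False)
        for j, i in enumerate(picked):
            fd = float(sizes[j % len(sizes)])
            if fd > 0:
                fitness_coeff[(eligible[i], cond)] = fd / generations
        # hits are disjoint across conditions (and from the signature), so
        # every planted effect is condition-specific by construction
        taken = {eligible[i] for i in picked}
        eligible = [s for s in eligible if s not in taken]

    return TruthBundle(
        strains=strains,
        present_by_collection=present_by_collection,
        fitness_coeff=fitness_coeff,
        conditions=cond_set,
        generations=generations,
        signature_members=signature_members,
        signature_conditions=signature_conditions,
        seed=seed,
    )


def generate_array_screen(
    truth: TruthBundle,
    params: ArraySimParams,
    design: pd.DataFrame,
    seed: int = 0,
) -> ScreenSim:
    """Render a truth bundle as feature-level array intensities.

    The expected log2 intensity of a present strain's tag on a treatment
    array is its control-array mean minus g*d (before noise, batch and
    artifact terms); absent strains draw from the absent component on every
    array. Each tag receives ``params.n_replicate_features`` feature values.
    """
    manifest = validate_manifest(design)
    rng = np.random.default_rng(seed)

    for r in manifest.itertuples():
        if r.role == "treatment" and r.condition not in truth.conditions:
            raise InputError(
                f"array {r.array_id}: condition {r.condition!r} is not part of the truth bundle"
            )
        if r.collection not in truth.present_by_collection:
            raise InputError(
                f"array {r.array_id}: collection {r.collection!r} is not part of the truth bundle"
            )

    strains = truth.strains
    tags = [tag_id(s, c) for s in strains for c in ("uptag", "downtag")]
    tag_strain = np.repeat(np.arange(len(strains)), 2)
    n_tags = len(tags)

    # per-tag baselines, fixed across arrays so noiseless screens are exact
    base_present = rng.normal(params.mu_present, params.sigma_present, n_tags)
    base_absent = rng.normal(params.mu_absent, params.sigma_absent, n_tags)

    batches = sorted(set(manifest["batch"]))
    batch_offset = dict(
        zip(batches, rng.normal(0.0, params.batch_shift_sd, len(batches)))
        if params.batch_shift_sd > 0
        else zip(batches, np.zeros(len(batches)))
    )
    truth.batch_of_array.update(
        {r.array_id: r.batch for r in manifest.itertuples()}
    )

    arrays = list(manifest.index)
    k = params.n_replicate_features
    values = np.empty((n_tags, len(arrays)))
    present_masks = {
        coll: np.array([s in pres for s in strains])[tag_strain]
        for coll, pres in truth.present_by_collection.items()
    }
    for j, arr in enumerate(arrays):
        row = manifest.loc[arr]
        present = present_masks[row["collection"]]
        v = np.where(present, base_present, base_absent).copy()
        if row["role"] == "treatment":
            d = np.array(
                [truth.fitness_coeff.get((s, row["condition"]), 0.0) for s in strains]
            )[tag_strain]
            v -= np.where(present, truth.generations * d, 0.0)
        v += batch_offset[row["batch"]]
        values[:, j] = v

    noise = (
        rng.normal(0.0, params.noise_sd, (n_tags, len(arrays), k))
        if params.noise_sd > 0
        else np.zeros((n_tags, len(arrays), k))
    )
    feats = values[:, :, None] + noise
    summary = feats.mean(axis=2)  # artifact-free tag-level matrix

    if params.artifact_rate > 0:
        hit = rng.random((n_tags, len(arrays), k)) < params.artifact_rate
        feats = feats + hit * params.artifact_shift
        ti, ai, fi = np.nonzero(hit)
        artifact_truth = pd.DataFrame(
            {
                "tag_id": [tags[i] for i in ti],
                "array_id": [arrays[i] for i in ai],
                "feature": fi + 1,
            }
        )
    else:
        artifact_truth = pd.DataFrame(columns=["tag_id", "array_id", "feature"])

    features = pd.DataFrame(
        {
            "tag_id": np.repeat(tags, len(arrays)),
            "array_id": np.tile(arrays, n_tags),
        }
    )
    flat = feats.reshape(n_tags * len(arrays), k)
    for f in range(k):
        features[f"feature_{f + 1}"] = flat[:, f]

    matrix = TagIntensityMatrix(
        values=pd.DataFrame(summary, index=tags, columns=arrays),
        manifest=manifest,
    )
    return ScreenSim(features=features, matrix=matrix, artifact_truth=artifact_truth)


def make_screen_design(
    collections: tuple[str, ...] = ("YKO",),
    media: str = "SC",
    conditions: tuple[str, ...] = (),
    n_control: int = 3,
    n_replicates: int = 3,
    batches: tuple[str, ...] = ("b1",),
) -> pd.DataFrame:
    """Convenience manifest builder: n_control controls plus n_replicates
    treatment arrays per condition, per collection, batches assigned
    round-robin over replicates."""
    rows = []
    for coll in collections:
        for i in range(n_control):
            rows.append(
                (f"{coll}_{media}_ctrl_{i + 1}", coll, media, "control",
                 batches[i % len(batches)], i + 1, "control")
            )
        for cond in conditions:
            for i in range(n_replicates):
                rows.append(
                    (f"{coll}_{media}_{cond}_{i + 1}", coll, media, cond,
                     batches[i % len(batches)], i + 1, "treatment")
                )
    return pd.DataFrame(
        rows,
        columns=["array_id", "collection", "media", "condition", "batch", "replicate", "role"],
    )


def make_random_library(strains: list[str], seed: int = 0) -> pd.DataFrame:
    """Random 20-base uptag/downtag barcodes, unique across the library."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()

    def draw() -> str:
        while True:
            bc = "".join("ACGT"[b] for b in rng.integers(0, 4, 20))
            if bc not in seen:
                seen.add(bc)
                return bc

    return pd.DataFrame(
        {
            "strain_id": strains,
            "uptag_seq": [draw() for _ in strains],
            "downtag_seq": [draw() for _ in strains],
        }
    )


def _apply_errors(seqs: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitution errors on a (n_reads, read_len) uint8 base array."""
    if error_rate <= 0:
        return seqs
    hit = rng.random(seqs.shape) < error_rate
    shift = rng.integers(1, 4, seqs.shape)
    code = np.zeros_like(seqs)
    for i, b in enumerate(BASES):
        code[seqs == b] = i
    mutated = BASES[(code + shift) % 4]
    return np.where(hit, mutated, seqs)


def generate_barseq_reads(
    truth: TruthBundle,
    library: pd.DataFrame,
    design: pd.DataFrame,
    outdir: str | Path,
    depth: int = 10000,
    error_rate: float = 0.0,
    collection: str | None = None,
    seed: int = 0,
    compress: bool = False,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write one FASTQ per sample and return the exact expected count matrix.

    ``design`` uses the manifest dialect (array_id doubles as sample id). Tag
    abundance in a treatment sample is proportional to 2^(-g*d); counts are
    one multinomial draw of ``depth`` reads over tags, and the returned
    matrix is that exact draw, so matcher recovery is checkable
    read-for-read. Read names encode the source tag.
    """
    manifest = validate_manifest(design)
    tagtab = library_tags(library)
    for cls in ("uptag", "downtag"):
        seqs = tagtab.loc[tagtab["tag_class"] == cls, "seq"]
        if seqs.duplicated().any():
            raise InputError(f"duplicate {cls} barcode sequences in library")
    if collection is None:
        collection = manifest["collection"].iloc[0]
    present = truth.present_by_collection[collection]
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    strains = [s for s in library["strain_id"] if s in present]
    tag_rows = tagtab[tagtab["strain_id"].isin(strains)].reset_index(drop=True)
    contexts = {
        "uptag": (UPTAG_ANCHOR, UPTAG_SUFFIX),
        "downtag": (DOWNTAG_ANCHOR, DOWNTAG_SUFFIX),
    }
    templates = []
    for r in tag_rows.itertuples():
        anchor, suffix = contexts[r.tag_class]
        read = (anchor + r.seq + suffix).ljust(READ_LENGTH, "A")[:READ_LENGTH]
        templates.append(np.frombuffer(read.encode(), dtype=np.uint8))
    templates = np.vstack(templates)

    counts = {}
    paths = {}
    qual = "I" * READ_LENGTH
    for sample in manifest.index:
        row = manifest.loc[sample]
        cond = row["condition"] if row["role"] == "treatment" else "control"
        if row["role"] == "treatment" and cond not in truth.conditions:
            raise InputError(f"sample {sample}: condition {cond!r} not in truth bundle")
        w = np.array(
            [
                2.0 ** (-truth.generations * truth.fitness_coeff.get((s, cond), 0.0))
                for s in tag_rows["strain_id"]
            ]
        )
        p = w / w.sum()
        draw = rng.multinomial(depth, p)
        counts[sample] = draw

        reads = np.repeat(templates, draw, axis=0)
        names = [
            f"{sample}:{tag}:{i}"
            for tag, c in zip(tag_rows["tag_id"], draw)
            for i in range(c)
        ]
        order = rng.permutation(len(names))
        reads = _apply_errors(reads[order], error_rate, rng)
        names = [names[i] for i in order]

        path = outdir / f"{sample}.fastq{'.gz' if compress else ''}"
        opener = gzip.open if compress else open
        with opener(path, "wt") as fh:
            for name, seq in zip(names, reads):
                fh.write(f"@{name}\n{seq.tobytes().decode()}\n+\n{qual}\n")
        paths[sample] = path

    expected = pd.DataFrame(counts, index=tag_rows["tag_id"].tolist())
    return paths, expected


# ---------------------------------------------------------------------------
# truth-bundle serialization (exact round trip, plain TSV)


def write_truth(truth: TruthBundle, path: str | Path) -> Path:
    path = Path(path)
    rows: list[tuple[str, str, str, str]] = []
    rows.append(("meta", "generations", "", str(truth.generations)))
    rows.append(("meta", "seed", "", str(truth.seed)))
    for s in truth.strains:
        rows.append(("strain", s, "", ""))
    for cond in sorted(truth.conditions):
        rows.append(("condition", cond, "", ""))
    for coll in sorted(truth.present_by_collection):
        for s in sorted(truth.present_by_collection[coll]):
            rows.append(("presence", coll, s, "1"))
    for (s, cond), d in sorted(truth.fitness_coeff.items()):
        rows.append(("fitness", s, cond, repr(d)))
    for s in sorted(truth.signature_members):
        rows.append(("signature_member", s, "", ""))
    for cond in truth.signature_conditions:
        rows.append(("signature_condition", cond, "", ""))
    pd.DataFrame(rows, columns=["record", "key1", "key2", "value"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_truth(path: str | Path) -> TruthBundle:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    meta = {r.key1: r.value for r in df[df["record"] == "meta"].itertuples()}
    strains = df.loc[df["record"] == "strain", "key1"].tolist()
    conditions = set(df.loc[df["record"] == "condition", "key1"])
    presence: dict[str, set[str]] = {}
    for r in df[df["record"] == "presence"].itertuples():
        presence.setdefault(r.key1, set()).add(r.key2)
    fitness = {
        (r.key1, r.key2): float(r.value)
        for r in df[df["record"] == "fitness"].itertuples()
    }
    return TruthBundle(
        strains=strains,
        present_by_collection=presence,
        fitness_coeff=fitness,
        conditions=conditions,
        generations=int(meta["generations"]),
        signature_members=set(df.loc[df["record"] == "signature_member", "key1"]),
        signature_conditions=tuple(df.loc[df["record"] == "signature_condition", "key1"]),
        seed=int(meta["seed"]),
    )


def write_fixture_bundle(
    outdir: str | Path,
    n_strains: int = 60,
    seed: int = 0,
    error_rate: float = 0.0,
    depth: int = 12000,
) -> dict[str, Path]:
    """Write a small self-consistent fixture: intensities, manifest, library,
    truth and per-sample FASTQ. Files round-trip through the module readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(
        n_strains,
        collections=("YKO",),
        dropout_fracs={"YKO": 0.1},
        effect_spec={"condA": (5, [2.0]), "condB": (5, [1.5])},
        seed=seed,
    )
    design = make_screen_design(conditions=("condA", "condB"))
    params = ArraySimParams(noise_sd=0.2)
    sim = generate_array_screen(truth, params, design, seed=seed + 1)
    library = make_random_library(truth.strains, seed=seed + 2)

    paths: dict[str, Path] = {}
    paths["intensities"] = outdir / "intensities.tsv"
    sim.features.to_csv(paths["intensities"], sep="\t", index=False, float_format="%.6f")
    paths["manifest"] = outdir / "manifest.tsv"
    design.to_csv(paths["manifest"], sep="\t", index=False)
    paths["library"] = outdir / "library.tsv"
    library.to_csv(paths["library"], sep="\t", index=False)
    paths["truth"] = write_truth(truth, outdir / "truth.tsv")

    fq_design = make_screen_design(conditions=("condA",), n_control=2, n_replicates=2)
    fq_paths, expected = generate_barseq_reads(
        truth, library, fq_design, outdir, depth=depth, error_rate=error_rate,
        seed=seed + 3,
    )
    paths["fastq"] = sorted(fq_paths.values())[0].parent
    paths.update({f"fastq_{k}": v for k, v in fq_paths.items()})
    paths["expected_counts"] = outdir / "expected_counts.tsv"
    expected.rename_axis("tag_id").to_csv(paths["expected_counts"], sep="\t")
    paths["fastq_manifest"] = outdir / "fastq_manifest.tsv"
    fq_design.to_csv(paths["fastq_manifest"], sep="\t", index=False)
    return paths
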