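"""End-to-end orchestration of the two analysis tracks.

The array track runs mask -> summarize -> mixture/presence -> normalize ->
best tag -> batch -> FD -> significance -> optional signature subtraction and
enrichment; the Bar-seq track runs trim/match -> filter/combine -> count
fitness. Every run writes plain TSV outputs, a structured machine-readable
run log (stage record counts, parameters, seed, version) and a single
exclusion log listing every strain dropped at any stage with a reason code.
Outputs are deterministic byte-for-byte for a fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._types import InputError
from .array_preprocess import load_intensity_table, summarize_to_tags
from .barseq import count_fitness, filter_and_combine, trim_and_match
from .enrichment import hypergeometric_enrichment, load_annotations, results_frame
from .fitness import score_set
from .presence import call_presence, compare_rosters
from .signature import define_shared_signature, signature_frame, subtract_signature

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Declarative run description; defaults are the analysis' printed
    thresholds (posterior 0.5, FD 1.0, q 0.05, count filter 50, trim 50,
    term sizes 5-300)."""

    outdir: str = "ykofit_out"
    seed: int = 0
    array: dict = field(default_factory=dict)
    barseq: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            outdir=raw.get("outdir", "ykofit_out"),
            seed=int(raw.get("seed", 0)),
            array=raw.get("array", {}) or {},
            barseq=raw.get("barseq", {}) or {},
        )
        for section in (cfg.array, cfg.barseq):
            for key in ("intensities", "manifest", "library", "annotations", "fastq_dir"):
                p = section.get(key)
                if p is not None and not Path(p).exists():
                    raise InputError(f"configured path does not exist: {key}: {p}")
        return cfg


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, **kw)


def run_array_pipeline(config: RunConfig) -> dict:
    """Run the array track; returns the run log (also written as JSON)."""
    a = config.array
    for key in ("intensities", "manifest", "library"):
        if key not in a:
            raise InputError(f"array config is missing required path {key!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"pipeline": "array", "version": __version__, "seed": config.seed,
                 "parameters": {k: v for k, v in a.items()}, "stages": []}
    exclusions: list[dict] = []

    features, manifest = load_intensity_table(a["intensities"], a["manifest"])
    library = pd.read_csv(a["library"], sep="\t")
    log["stages"].append({"stage": "load", "n_feature_rows": int(len(features)),
                          "n_arrays": int(len(manifest))})

    matrix = summarize_to_tags(
        features, manifest, mad_k=float(a.get("mad_k", 4.0)),
        min_keep=int(a.get("min_keep", 3)),
    )
    _write(matrix.values.rename_axis("tag_id").reset_index(), outdir / "tag_intensities.tsv")
    _write(matrix.mask_log, outdir / "mask_log.tsv")
    log["stages"].append({"stage": "summarize", "n_tags": int(len(matrix.values)),
                          "n_masked_features": int(len(matrix.mask_log))})

    threshold = float(a.get("posterior_threshold", 0.5))
    calls = {}
    presence_rows = []
    for coll, media in matrix.sets():
        call = call_presence(matrix, library, coll, media, threshold=threshold)
        calls[(coll, media)] = call
        for strain, pres in call.present.items():
            presence_rows.append(
                {"strain_id": strain, "collection": coll, "media": media,
                 "present": int(pres)}
            )
            if not pres:
                exclusions.append({"id": strain, "collection": coll,
                                   "stage": "presence", "reason": "below_background"})
        for strain in call.no_tag_strains:
            exclusions.append({"id": strain, "collection": coll,
                               "stage": "presence", "reason": "no_tag_on_array"})
    _write(pd.DataFrame(presence_rows), outdir / "presence.tsv")
    log["stages"].append({
        "stage": "presence",
        "n_present": {f"{c}:{m}": int(call.present.sum()) for (c, m), call in calls.items()},
    })

    by_collection = {}
    for (coll, media), call in calls.items():
        by_collection.setdefault(coll, call)  # first media wins for rosters
    if len(by_collection) >= 2:
        venn = compare_rosters(by_collection)
        _write(venn.to_frame(), outdir / "venn.tsv")
        log["stages"].append({"stage": "rosters", "universe": len(venn.universe)})

    tables = {}
    fd_frames = []
    for (coll, media), call in calls.items():
        table = score_set(
            matrix, library, coll, media,
            present_strains=call.present_strains,
            significance_method=a.get("significance_method", "robust_z"),
        )
        tables[(coll, media)] = table
        frame = table.to_frame()
        frame.insert(1, "collection", coll)
        frame.insert(2, "media", media)
        fd_frames.append(frame)
    _write(pd.concat(fd_frames, ignore_index=True), outdir / "fd.tsv")
    log["stages"].append({
        "stage": "fitness",
        "n_scored": {f"{c}:{m}": int(len(t.fd_median)) for (c, m), t in tables.items()},
    })

    sig_cfg = a.get("signature")
    universe = set.union(*(c.present_strains for c in calls.values()))
    if sig_cfg:
        group = list(sig_cfg["group"])
        coll = sig_cfg.get("collection")
        table = next(
            t for (c, m), t in tables.items() if coll is None or c == coll
        )
        sig = define_shared_signature(
            table.fd_median, group,
            threshold=float(sig_cfg.get("threshold", a.get("fd_threshold", 1.0))),
            rule=sig_cfg.get("rule", "all"),
        )
        _write(signature_frame(sig), outdir / "signature.tsv")
        corr_rows = []
        for cond in group:
            corrected, flagged = subtract_signature(table.fd_median[cond], cond, sig)
            for strain, v in corrected.items():
                corr_rows.append({"strain_id": strain, "condition": cond,
                                  "fd_corrected": v,
                                  "profile_missing": int(strain in flagged)})
        _write(pd.DataFrame(corr_rows), outdir / "fd_corrected.tsv")
        log["stages"].append({"stage": "signature", "n_members": len(sig.members)})

        if a.get("annotations"):
            ann = load_annotations(a["annotations"])
            results = hypergeometric_enrichment(
                sig.members & universe, universe, ann,
                min_size=int(a.get("min_term_size", 5)),
                max_size=int(a.get("max_term_size", 300)),
                p_cut=float(a.get("enrichment_p_cut", 0.0005)),
            )
            _write(results_frame(results), outdir / "enrichment.tsv")
            log["stages"].append({"stage": "enrichment", "n_terms": len(results)})

    _write(pd.DataFrame(exclusions, columns=["id", "collection", "stage", "reason"]),
           outdir / "exclusions.tsv")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log


def run_barseq_pipeline(config: RunConfig) -> dict:
    """Run the Bar-seq track; returns the run log (also written as JSON)."""
    b = config.barseq
    for key in ("fastq_dir", "manifest", "library"):
        if key not in b:
            raise InputError(f"barseq config is missing required path {key!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"pipeline": "barseq", "version": __version__, "seed": config.seed,
                 "parameters": {k: v for k, v in b.items()}, "stages": []}

    manifest = pd.read_csv(b["manifest"], sep="\t")
    library = pd.read_csv(b["library"], sep="\t")
    fq_dir = Path(b["fastq_dir"])
    paths = {}
    for sample in manifest["array_id"]:
        for suffix in (".fastq", ".fastq.gz", ".fq", ".fq.gz"):
            p = fq_dir / f"{sample}{suffix}"
            if p.exists():
                paths[sample] = p
                break
        else:
            raise InputError(f"no FASTQ found for sample {sample!r} under {fq_dir}")

    cm = trim_and_match(
        paths, library, manifest,
        trim_len=int(b.get("trim_len", 50)),
        max_mismatch=int(b.get("max_mismatch", 2)),
    )
    _write(cm.counts.rename_axis("tag_id").reset_index(), outdir / "tag_counts.tsv")
    _write(cm.stats.reset_index(), outdir / "match_stats.tsv")
    log["stages"].append({
        "stage": "match",
        "reads": {s: int(cm.stats.loc[s, "total"]) for s in cm.stats.index},
        "matched": int(cm.stats["matched"].sum()),
    })

    strain_counts, dropped = filter_and_combine(
        cm, library, min_control_count=int(b.get("min_control_count", 50))
    )
    _write(strain_counts.reset_index(), outdir / "strain_counts.tsv")
    _write(dropped, outdir / "barseq_exclusions.tsv")
    log["stages"].append({"stage": "filter", "n_strains": int(len(strain_counts)),
                          "n_dropped": int(len(dropped))})

    table = count_fitness(
        strain_counts, manifest,
        significance_method=b.get("significance_method", "robust_z"),
    )
    _write(table.to_frame(), outdir / "fd_barseq.tsv")
    log["stages"].append({"stage": "count_fitness",
                          "n_conditions": len(table.conditions)})

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
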