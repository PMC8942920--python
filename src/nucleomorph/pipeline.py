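"""Pipeline wiring: declarative run configuration, stage chaining, and
reproducibility metadata.

Stages (simulate → segment → measure → classify → te-fraction → profile)
read and write plain CSV/TIFF artifacts in a working directory. Every CSV
carries a header comment with the package version and a hash of the full
run configuration, and all writes are atomic (tmp file + rename), so a
rerun with an identical config reproduces byte-identical outputs for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassThresholds, classify, shape_descriptors
from .errors import ConfigurationError, MissingArtifactError
from .morphometry import measure
from .profiling import (
    DEFAULT_PARAMS, compare_groups, correlate, group_summary, pca_profile,
)
from .repeats import GENOME_SIZE_ESTIMATES_MB, TANDEM_TOTAL_MB, partition_table
from .segment import SegmentationConfig, read_image, segment
from .simulate import generate_population, get_preset, write_population

STAGES = ("simulate", "segment", "measure", "classify", "te-fraction", "profile")


@dataclass
class RunConfig:
    seed: int = 1
    preset: str = "GC"
    n: int = 50
    pixel_size: float = 0.1
    # segmentation knobs
    cc_k: float = 2.0
    min_cc_area: int = 4
    channel: str | None = None
    # genome model
    genome_sizes: tuple[float, ...] = GENOME_SIZE_ESTIMATES_MB
    tandem_total: float = TANDEM_TOTAL_MB
    te_fraction_of_genome: float = 0.10
    # classification thresholds
    A_gc: float = 30.0
    A_ec: float = 120.0
    c_gc: float = 0.85
    r_vc: float = 3.0
    # profiling
    group_col: str = "cell_type"
    ploidy_anchor: str = "GC"
    ploidy_anchor_c: float = 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome_sizes"] = list(self.genome_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "genome_sizes" in d:
            d["genome_sizes"] = tuple(d["genome_sizes"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key/value config (JSON, or YAML if available)."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            try:
                import yaml

                data = yaml.safe_load(text)
            except ImportError as exc:
                raise ConfigurationError(f"cannot parse config {path}") from exc
        return cls.from_dict(data)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(cc_k=self.cc_k, min_cc_area=self.min_cc_area)

    def class_thresholds(self) -> ClassThresholds:
        return ClassThresholds(A_gc=self.A_gc, A_ec=self.A_ec, c_gc=self.c_gc, r_vc=self.r_vc)


def _header(config: RunConfig) -> str:
    return f"nucleomorph v{__version__} config={config.hash()}"


def write_csv(df: pd.DataFrame, path: str | Path, config: RunConfig) -> Path:
    """Atomically write a CSV with the version/config-hash header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    buf.write(f"# {_header(config)}\n")
    df.to_csv(buf, index=False)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(buf.getvalue())
    tmp.replace(path)
    return path


def read_csv(path: str | Path, stage: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the '{stage}' stage first"
        )
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# in-memory pipeline (also used by the statistics stages and the tests)


def measure_pairs(pairs, config: RunConfig | None = None) -> pd.DataFrame:
    """Segment and measure in-memory (image, ground-truth) pairs.

    Returns one row per nucleus with the morphometric record, shape
    descriptors and (when ground truth is present) the generator's true
    values and labels, ready for classification and profiling.
    """
    config = config or RunConfig()
    seg_cfg = config.segmentation()
    rows = []
    for img, truth in pairs:
        seg = segment(img, seg_cfg)
        rec = measure(img, seg)
        desc = shape_descriptors(seg.nucleus_mask, img.pixel_size)
        row = rec.to_dict()
        row.update(
            area=desc.area, circularity=desc.circularity, aspect_ratio=desc.aspect_ratio
        )
        if truth is not None:
            row.update(
                true_area=truth.true_area, true_content=truth.true_content,
                true_rhf=truth.true_rhf, true_cc_count=truth.true_cc_count,
                true_cell_type=truth.cell_type_label, accession=truth.accession_label,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def classify_table(df: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Add cell_type labels and anchor-calibrated C-values to a measurement table."""
    from .classify import ShapeDescriptors

    config = config or RunConfig()
    th = config.class_thresholds()
    df = df.copy()
    df["cell_type"] = [
        classify(ShapeDescriptors(a, c, r), th)
        for a, c, r in zip(df["area"], df["circularity"], df["aspect_ratio"])
    ]
    if (df["cell_type"] == config.ploidy_anchor).any():
        anchor_mean = df.loc[df["cell_type"] == config.ploidy_anchor, "content_nu"].mean()
        df["c_value"] = config.ploidy_anchor_c * df["content_nu"] / anchor_mean
    return df


# ---------------------------------------------------------------------------
# disk-based stages


def stage_simulate(config: RunConfig, workdir: Path) -> Path:
    preset = get_preset(config.preset)
    if config.pixel_size != preset.pixel_size:
        preset = dataclasses.replace(preset, pixel_size=config.pixel_size)
    pairs = generate_population(preset, config.n, config.seed)
    return write_population(pairs, workdir / "images", header_comment=_header(config))


def stage_segment(config: RunConfig, workdir: Path) -> Path:
    import tifffile

    imgdir = workdir / "images"
    truth_csv = imgdir / "ground_truth.csv"
    if not truth_csv.exists():
        raise MissingArtifactError(
            f"missing artifact {truth_csv}; run the 'simulate' stage first"
        )
    truth = pd.read_csv(truth_csv, comment="#")
    segdir = workdir / "segmentation"
    segdir.mkdir(parents=True, exist_ok=True)
    seg_cfg = config.segmentation()
    log = []
    for fname in truth["file"]:
        img = read_image(imgdir / fname, channel=config.channel,
                         pixel_size=config.pixel_size)
        seg = segment(img, seg_cfg)
        stem = Path(fname).stem
        tifffile.imwrite(segdir / f"{stem}_mask.tif",
                         seg.nucleus_mask.astype(np.uint16))
        tifffile.imwrite(segdir / f"{stem}_cc.tif", seg.cc_labels.astype(np.uint16))
        log.append(
            {"file": fname, "background_level": seg.background_level,
             "nucleus_threshold": seg.nucleus_threshold,
             "cc_threshold": seg.cc_threshold, "n_cc": seg.n_cc}
        )
    params = {"config_hash": config.hash(), "cc_k": config.cc_k,
              "min_cc_area": config.min_cc_area, "images": log}
    out = segdir / "segmentation.json"
    tmp = out.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(params, indent=1, sort_keys=True))
    tmp.replace(out)
    return out


def stage_measure(config: RunConfig, workdir: Path) -> Path:
    import tifffile

    imgdir = workdir / "images"
    segdir = workdir / "segmentation"
    truth_csv = imgdir / "ground_truth.csv"
    if not truth_csv.exists():
        raise MissingArtifactError(
            f"missing artifact {truth_csv}; run the 'simulate' stage first"
        )
    truth = pd.read_csv(truth_csv, comment="#").fillna({"accession_label": ""})
    rows = []
    for _, t in truth.iterrows():
        stem = Path(t["file"]).stem
        mask_path = segdir / f"{stem}_mask.tif"
        cc_path = segdir / f"{stem}_cc.tif"
        if not mask_path.exists() or not cc_path.exists():
            raise MissingArtifactError(
                f"missing artifact {mask_path}; run the 'segment' stage first"
            )
        seg_log = json.loads((segdir / "segmentation.json").read_text())
        by_file = {e["file"]: e for e in seg_log["images"]}
        entry = by_file[t["file"]]
        img = read_image(imgdir / t["file"], channel=config.channel,
                         pixel_size=config.pixel_size)
        from .segment import SegmentationResult

        seg = SegmentationResult(
            nucleus_mask=tifffile.imread(mask_path).astype(bool),
            cc_labels=tifffile.imread(cc_path).astype(np.int32),
            background_level=entry["background_level"],
            nucleus_threshold=entry["nucleus_threshold"],
            cc_threshold=entry["cc_threshold"],
        )
        rec = measure(img, seg)
        desc = shape_descriptors(seg.nucleus_mask, img.pixel_size)
        row = rec.to_dict()
        row.update(area=desc.area, circularity=desc.circularity,
                   aspect_ratio=desc.aspect_ratio,
                   true_rhf=t["true_rhf"], true_cc_count=t["true_cc_count"],
                   true_cell_type=t["cell_type_label"],
                   accession=t.get("accession_label", ""))
        rows.append(row)
    return write_csv(pd.DataFrame(rows), workdir / "measurements.csv", config)


def stage_classify(config: RunConfig, workdir: Path) -> Path:
    df = read_csv(workdir / "measurements.csv", stage="measure")
    labeled = classify_table(df, config)
    return write_csv(labeled, workdir / "labeled.csv", config)


def stage_te_fraction(config: RunConfig, workdir: Path) -> Path:
    df = read_csv(workdir / "labeled.csv", stage="classify")
    rhf_by_group = df.groupby(config.group_col)["rhf"].mean().to_dict()
    table = partition_table(
        rhf_by_group, genome_sizes=config.genome_sizes,
        tandem_total=config.tandem_total,
        te_fraction_of_genome=config.te_fraction_of_genome,
    )
    return write_csv(table, workdir / "te_partition.csv", config)


def stage_profile(config: RunConfig, workdir: Path) -> Path:
    df = read_csv(workdir / "labeled.csv", stage="classify")
    outdir = workdir / "profile"
    outdir.mkdir(parents=True, exist_ok=True)
    gc = config.group_col
    write_csv(group_summary(df, gc), outdir / "group_summary.csv", config)
    n_groups = df[gc].nunique()
    if (df.groupby(gc).size() >= 3).all():
        corr = correlate(df, gc)
        for group in corr.r:
            write_csv(corr.r[group].reset_index(names="parameter"),
                      outdir / f"corr_{group}.csv", config)
            write_csv(corr.p[group].reset_index(names="parameter"),
                      outdir / f"pvals_{group}.csv", config)
    prof = pca_profile(df, group_col=gc)
    write_csv(prof.scores, outdir / "pca_scores.csv", config)
    write_csv(prof.loadings.reset_index(names="parameter"),
              outdir / "pca_loadings.csv", config)
    if n_groups >= 2 and (df.groupby(gc).size() >= 2).all():
        tests = pd.concat(
            [compare_groups(df, gc, p) for p in DEFAULT_PARAMS if p in df.columns],
            ignore_index=True,
        )
        write_csv(tests, outdir / "tests.csv", config)
    return outdir


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "measure": stage_measure,
    "classify": stage_classify,
    "te-fraction": stage_te_fraction,
    "profile": stage_profile,
}


def run_pipeline(
    config: RunConfig, workdir: str | Path, stages: tuple[str, ...] = STAGES
) -> dict[str, Path]:
    """Run the requested stages in canonical order; returns stage → artifact."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ConfigurationError(f"unknown stages: {unknown}; choose from {STAGES}")
    results = {}
    for stage in STAGES:
        if stage in stages:
            results[stage] = _STAGE_FUNCS[stage](config, workdir)
    return results
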