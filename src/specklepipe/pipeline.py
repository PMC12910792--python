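"""Pipeline orchestration: configuration, per-image processing, provenance.

One :func:`run_pipeline` call takes a manifest of calibrated images
(planes or Z-stacks) with subject/group metadata and optional ROI masks,
runs EDF → enhancement → segmentation → classification per image, then
aggregates per-subject area histograms and the two-group comparison.  All
parameters, the package version, and the seed are written to a
machine-readable provenance file so every number in the summary is
reproducible from it alone.  Per-image failures are logged and skipped;
the run summary lists them and the process-level exit code reflects them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .edf import EdfParams, edf_variance
from .enhance import EnhanceParams, enhance
from .images import RegionOfInterest, ZStack, read_image, write_plane
from .quantify import (
    DEFAULT_BIN_EDGES,
    compare_groups,
    histogram_areas,
    histograms_to_frame,
)
from .segment import ClassifierRules, SegmentationParams, classify, records_to_dataframe, segment

logger = logging.getLogger(__name__)

__all__ = ["ImageEntry", "PipelineConfig", "PipelineResult", "run_pipeline", "process_image"]


@dataclass(frozen=True)
class ImageEntry:
    """One manifest row: an image file plus its subject/group metadata."""

    path: str
    subject_id: str
    group: str
    roi_path: str | None = None
    roi_name: str = "full_field"


@dataclass(frozen=True)
class PipelineConfig:
    manifest: tuple[ImageEntry, ...]
    output_dir: str
    pixel_size_um: float = 0.173
    edf: EdfParams = field(default_factory=EdfParams)
    enhancement: EnhanceParams = field(default_factory=EnhanceParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classifier: ClassifierRules = field(default_factory=ClassifierRules)
    bin_edges_um2: tuple[float, ...] = DEFAULT_BIN_EDGES
    welch: bool = False
    seed: int = 0
    save_intermediates: bool = False

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if not self.manifest:
            raise ValueError("manifest is empty")

    def validate_paths(self) -> None:
        missing = [e.path for e in self.manifest if not Path(e.path).exists()]
        missing += [
            e.roi_path
            for e in self.manifest
            if e.roi_path is not None and not Path(e.roi_path).exists()
        ]
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        manifest = tuple(ImageEntry(**e) for e in raw.pop("manifest"))
        kwargs = {}
        for key, klass in (
            ("edf", EdfParams),
            ("enhancement", EnhanceParams),
            ("segmentation", SegmentationParams),
            ("classifier", ClassifierRules),
        ):
            if key in raw:
                kwargs[key] = klass(**raw.pop(key))
        if "bin_edges_um2" in raw:
            raw["bin_edges_um2"] = tuple(raw["bin_edges_um2"])
        return cls(manifest=manifest, **raw, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["manifest"] = [dataclasses.asdict(e) for e in self.manifest]
        d["bin_edges_um2"] = list(self.bin_edges_um2)
        return d


@dataclass
class PipelineResult:
    records: pd.DataFrame
    histograms: pd.DataFrame
    comparison: pd.DataFrame | None
    summary: dict
    output_dir: Path

    @property
    def n_failed(self) -> int:
        return len(self.summary["failures"])


def _load_roi(entry: ImageEntry, shape: tuple[int, int]) -> RegionOfInterest:
    if entry.roi_path is None:
        return RegionOfInterest.full_field(shape, name=entry.roi_name)
    mask = tifffile.imread(entry.roi_path) > 0
    return RegionOfInterest(name=entry.roi_name, mask=mask)


def process_image(entry: ImageEntry, config: PipelineConfig, out_dir: Path | None = None):
    """EDF (if stack) → enhance → segment → classify for one manifest entry.

    Returns the classified record list.  ``out_dir`` enables intermediate
    artifacts (EDF, enhanced, label TIFFs), each loadable by the
    corresponding stage CLI.
    """
    image = read_image(entry.path, config.pixel_size_um)
    if isinstance(image, ZStack):
        plane, _index_map = edf_variance(image, config.edf)
    else:
        plane = image
    roi = _load_roi(entry, plane.shape)
    enhanced = enhance(plane, config.enhancement)
    label_map, records = segment(enhanced, plane, roi, config.segmentation)
    records = classify(
        records,
        config.classifier,
        label_map,
        enhanced,
        raw=plane,
        min_area_um2=config.segmentation.min_area_um2,
        max_area_um2=config.segmentation.max_area_um2,
    )
    if out_dir is not None:
        stem = Path(entry.path).stem
        write_plane(out_dir / f"{stem}_edf.tif", plane, dtype=np.float32)
        write_plane(out_dir / f"{stem}_enhanced.tif", enhanced, dtype=np.float32)
        tifffile.imwrite(out_dir / f"{stem}_labels.tif", label_map.astype(np.int32))
    return records


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis over a manifest and write all artifacts.

    Outputs under ``config.output_dir``: records.csv (one row per object,
    all images), histograms.csv (one row per subject), comparison.csv
    (per-bin + total statistics, if two groups are present), summary.json,
    and provenance.json.  Reruns with identical config and inputs are
    byte-identical in the CSV outputs.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_file = logging.FileHandler(out / "run.log", mode="w")
    log_file.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("specklepipe")
    root.addHandler(log_file)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(log_file)
        log_file.close()


def _run(config: PipelineConfig, out: Path) -> PipelineResult:
    inter_dir = None
    if config.save_intermediates:
        inter_dir = out / "intermediates"
        inter_dir.mkdir(exist_ok=True)

    all_records = []
    failures = []
    for entry in config.manifest:
        try:
            records = process_image(entry, config, out_dir=inter_dir)
        except Exception as exc:  # per-image isolation: log, skip, report
            logger.error("failed to process %s: %s", entry.path, exc)
            failures.append({"path": entry.path, "error": str(exc)})
            continue
        df = records_to_dataframe(records)
        df.insert(0, "subject_id", entry.subject_id)
        df.insert(1, "group", entry.group)
        df.insert(2, "image", entry.path)
        all_records.append(df)
        logger.info(
            "%s: %d objects (%d accepted)", entry.path, len(df), int(df["accepted"].sum())
        )

    records_df = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else records_to_dataframe([]).assign(subject_id=[], group=[], image=[])
    )
    records_df.to_csv(out / "records.csv", index=False)

    histograms = []
    for subject_id, sub_df in records_df.groupby("subject_id", sort=True):
        accepted = sub_df[sub_df["accepted"]]
        histograms.append(
            histogram_areas(
                accepted["area_um2"].to_numpy(),
                config.bin_edges_um2,
                roi_name=str(sub_df["roi_name"].iloc[0]) if len(sub_df) else "",
                subject_id=str(subject_id),
                group=str(sub_df["group"].iloc[0]),
            )
        )
    hist_df = histograms_to_frame(histograms)
    hist_df.to_csv(out / "histograms.csv", index=False)

    comparison_df = None
    groups = sorted({h.group for h in histograms})
    if len(groups) == 2 and all(
        sum(h.group == g for h in histograms) >= 2 for g in groups
    ):
        comparison = compare_groups(histograms, welch=config.welch)
        comparison_df = comparison.to_frame()
        comparison_df.to_csv(out / "comparison.csv", index=False)
    else:
        logger.info("comparison skipped: need two groups with >= 2 subjects each")

    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_images": len(config.manifest),
        "n_processed": len(config.manifest) - len(failures),
        "n_objects": int(len(records_df)),
        "n_accepted": int(records_df["accepted"].sum()) if len(records_df) else 0,
        "n_subjects": len(histograms),
        "groups": groups,
        "failures": failures,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    provenance = {"version": __version__, "config": config.to_dict()}
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return PipelineResult(
        records=records_df,
        histograms=hist_df,
        comparison=comparison_df,
        summary=summary,
        output_dir=out,
    )
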