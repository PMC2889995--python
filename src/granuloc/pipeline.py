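"""End-to-end analysis pipeline driven by a config document.

Config keys (YAML or a dict):

``input``             path to the multipage TIFF (interleaved by slice)
``channels``          ordered channel names
``roles``             optional map channel -> role (mRNA, protein_1, ...)
``pixel_size_um``     in-plane sampling
``z_interval_um``     optical-section interval (0 for single plane)
``field_size_um``     optional field extent
``background_window_px``  local-background window (default 31)
``overlap_threshold``     object-overlap cutoff (default 0.30)
``min_punctum_voxels``    smallest accepted punctum (default 4)
``segmentation_percentile``  background percentile subtracted before
                             seven-color segmentation (default 50)
``seed``              recorded in the report for provenance
``out``               output directory

The pipeline detects puncta per channel, scores directional percent
co-localization for every ordered channel pair (plus the triple count
for 3-channel stacks), segments the RGB composite of the maximum
projection into seven pseudo-channels, and writes a delimited report.
Identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import colocalization as coloc
from . import puncta as _puncta
from . import segmentation as seg
from .projection import max_projection
from .stack_io import Stack, VoxelGeometry, read_stack, write_pseudo_channels

REQUIRED_KEYS = ("input", "channels", "pixel_size_um")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where it wrote the files."""

    report: pd.DataFrame
    puncta: dict
    n_triple: int | None
    segmap: seg.SegmentationMap | None
    out_dir: Path | None
    report_path: Path | None = None
    pseudo_paths: dict = field(default_factory=dict)


def load_config(source) -> dict:
    """Read a config mapping from a YAML path or pass a dict through."""
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config must be a mapping, got {type(cfg).__name__}")
    return cfg


def _geometry_from_config(cfg: dict) -> VoxelGeometry:
    return VoxelGeometry(
        pixel_size_xy=float(cfg["pixel_size_um"]),
        z_interval=float(cfg.get("z_interval_um", 0.0)),
        field_size_xy=(float(cfg["field_size_um"]) if cfg.get("field_size_um") else None),
        frame_interval=(
            float(cfg["frame_interval_s"]) if cfg.get("frame_interval_s") else None
        ),
    )


def run_pipeline(config, stack: Stack | None = None) -> PipelineResult:
    """Run segmentation, detection, co-localization and projection.

    ``config`` is a YAML path or a dict (see module docstring).  A
    pre-loaded ``stack`` bypasses ``input``; otherwise the TIFF named by
    the config is read.
    """
    cfg = load_config(config)
    if stack is None:
        missing = [k for k in REQUIRED_KEYS if k not in cfg]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        geometry = _geometry_from_config(cfg)
        stack = read_stack(cfg["input"], geometry, cfg["channels"], cfg.get("roles"))

    window = int(cfg.get("background_window_px", 31))
    threshold = float(cfg.get("overlap_threshold", coloc.DEFAULT_OVERLAP_THRESHOLD))
    min_size = int(cfg.get("min_punctum_voxels", 4))
    seg_pct = float(cfg.get("segmentation_percentile", 50.0))
    seed = cfg.get("seed")
    out_dir = Path(cfg["out"]) if cfg.get("out") else None

    names = stack.channel_names
    puncta_sets = {
        name: _puncta.detect_puncta_channel(
            np.squeeze(stack.channels[name]) if stack.shape[0] == 1 else stack.channels[name],
            name,
            window=window,
            min_size=min_size,
        )
        for name in names
    }
    _puncta.warn_if_small_sample(sum(len(ps) for ps in puncta_sets.values()))

    rows = []
    for ref in names:
        for tgt in names:
            if ref == tgt:
                continue
            if len(puncta_sets[ref]) == 0:
                rows.append(
                    {"pair": f"{ref}->{tgt}", "n_ref_events": 0, "n_coloc_events": 0,
                     "percent": float("nan")}
                )
                continue
            res = coloc.percent_colocalization(puncta_sets[ref], puncta_sets[tgt], threshold)
            rows.append(
                {
                    "pair": f"{ref}->{tgt}",
                    "n_ref_events": res.n_ref_events,
                    "n_coloc_events": res.n_coloc_events,
                    "percent": round(res.percent, 4),
                }
            )
    report = pd.DataFrame(rows, columns=["pair", "n_ref_events", "n_coloc_events", "percent"])

    n_triple = None
    if len(names) == 3 and all(len(puncta_sets[n]) for n in names):
        triple = coloc.triple_colocalization(*(puncta_sets[n] for n in names), threshold)
        n_triple = triple.n_triple

    segmap = None
    if len(names) == 3:
        mips = max_projection(stack)
        composite = np.stack(
            [
                seg.subtract_background(mips[n], "constant_percentile", seg_pct)
                for n in names
            ],
            axis=0,
        )
        segmap = seg.segment_image(composite)

    result = PipelineResult(
        report=report,
        puncta=puncta_sets,
        n_triple=n_triple,
        segmap=segmap,
        out_dir=out_dir,
    )
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        report_path = out_dir / "coloc_report.tsv"
        meta = [f"# seed={seed}", f"# overlap_threshold={threshold}"]
        if n_triple is not None:
            meta.append(f"# n_triple={n_triple}")
        with open(report_path, "w", newline="") as fh:
            fh.write("\n".join(meta) + "\n")
            report.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        result.report_path = report_path
        if segmap is not None:
            result.pseudo_paths = write_pseudo_channels(segmap, out_dir)
        mips = max_projection(stack)
        for n in names:
            tifffile.imwrite(out_dir / f"mip_{n}.tif", mips[n])
        for n in names:
            puncta_sets[n].to_table().to_csv(out_dir / f"puncta_{n}.tsv", sep="\t", index=False)
    return result
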