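"""End-to-end runs: preprocess → (DBSCAN | FCM) → lesion mask → metrics.

The pipeline follows the standard border-detection chain
(pre-processing, segmentation, post-processing, evaluation).  A run is
configured by a single :class:`RunConfig`; all randomness (FCM
initialization) flows from its one seed, so identical config + seed
reproduces byte-identical mask files and CSV reports.
"""

from __future__ import annotations

import glob as globmod
import logging
import time
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import evaluation
from .core_io import (
    BinaryMask,
    OverlayLayer,
    OverlaySpec,
    load_image,
    load_mask,
    render_overlay,
    save_mask,
)
from .dbscan_seg import DbscanParams, dbscan, select_lesion_mask
from .fcm_seg import FcmParams, fcm_segment_image
from .preprocess import BinarizationConfig, binarize

__all__ = ["RunConfig", "run_single", "run_batch", "save_config", "load_config"]

logger = logging.getLogger(__name__)

# overlay color convention: manual red, DBSCAN blue, FCM green
MANUAL_COLOR = (255, 0, 0)
METHOD_COLORS = {"dbscan": (0, 0, 255), "fcm": (0, 255, 0)}


@dataclass(frozen=True)
class RunConfig:
    method: str = "dbscan"  # "dbscan" | "fcm"
    binarization: BinarizationConfig = field(default_factory=BinarizationConfig)
    dbscan: DbscanParams = field(default_factory=DbscanParams)
    fcm: FcmParams = field(default_factory=FcmParams)
    select_policy: str = "largest"
    fill_holes: bool = True
    lesion_cluster: int | str = "auto"
    emit_overlays: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("dbscan", "fcm"):
            raise ValueError(f"method must be 'dbscan' or 'fcm', got {self.method!r}")


def segment_image(image, config: RunConfig) -> BinaryMask:
    """Run the configured segmentation chain on one loaded image."""
    t0 = time.perf_counter()
    if config.method == "dbscan":
        binary = binarize(image, config.binarization)
        logger.info(
            "stage=binarize method=%s channel=%s positive=%d elapsed=%.3fs",
            config.binarization.method, config.binarization.channel,
            binary.positive_count, time.perf_counter() - t0,
        )
        t0 = time.perf_counter()
        label_map = dbscan(binary, config.dbscan)
        logger.info(
            "stage=dbscan eps=%g min_pxl=%d clusters=%d elapsed=%.3fs",
            config.dbscan.eps, config.dbscan.min_pxl, label_map.n_clusters,
            time.perf_counter() - t0,
        )
        mask = select_lesion_mask(label_map, config.select_policy, config.fill_holes)
    else:
        mask, _labels, fit = fcm_segment_image(image, config.fcm, config.lesion_cluster)
        logger.info(
            "stage=fcm c=%d m=%g T=%g iters=%d converged=%s elapsed=%.3fs",
            config.fcm.c, config.fcm.m, config.fcm.T, fit.n_iter, fit.converged,
            time.perf_counter() - t0,
        )
    return mask


def _find_manual(image_path: Path, manual_path: str | Path | None) -> Path | None:
    if manual_path is not None:
        return Path(manual_path)
    candidate = image_path.with_name(image_path.stem + "_manual.png")
    return candidate if candidate.exists() else None


def run_single(
    image_path: str | Path,
    config: RunConfig,
    out_dir: str | Path | None = None,
    manual_path: str | Path | None = None,
) -> tuple[BinaryMask, evaluation.EvaluationRecord | None]:
    """Segment one image; evaluate against its manual mask when present.

    The manual mask is found by the ``<stem>_manual.png`` convention
    next to the image unless given explicitly.  When ``out_dir`` is
    set, the automatic mask (and optionally an overlay) are written
    there as PNGs.
    """
    image_path = Path(image_path)
    image = load_image(image_path)
    mask = segment_image(image, config)
    if mask.positive_count == 0:
        warnings.warn(f"empty segmentation for {image_path.name}", stacklevel=2)

    record = None
    found = _find_manual(image_path, manual_path)
    if found is None:
        warnings.warn(
            f"no manual mask for {image_path.name}; metrics skipped", stacklevel=2
        )
    else:
        manual = load_mask(found)
        record = evaluation.evaluate_pair(image_path.stem, mask, manual)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_mask(mask, out_dir / f"{image_path.stem}_mask.png")
        if config.emit_overlays:
            layers = []
            if found is not None:
                layers.append(OverlayLayer(load_mask(found), MANUAL_COLOR))
            layers.append(OverlayLayer(mask, METHOD_COLORS[config.method]))
            render_overlay(
                image, OverlaySpec(tuple(layers)),
                out_dir / f"{image_path.stem}_overlay.png",
            )
    return mask, record


def run_batch(
    pattern: str,
    config: RunConfig,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, list[str]]:
    """Segment every image matching a glob; write masks and a CSV report.

    Returns the report table (per-image rows + mean row) and the list
    of failed image paths; failures do not abort the batch.
    """
    paths = sorted(
        p for p in globmod.glob(pattern)
        if not p.endswith("_manual.png") and not p.endswith("_mask.png")
        and not p.endswith("_overlay.png")
    )
    if not paths:
        raise ValueError(f"no images match {pattern!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pairs = []
    failures: list[str] = []
    for p in paths:
        try:
            mask, record = run_single(p, config, out_dir=out_dir)
        except Exception as exc:
            logger.error("image %s failed: %s", p, exc)
            failures.append(p)
            continue
        if record is not None:
            pairs.append((record.image_id, mask, load_mask(_find_manual(Path(p), None))))

    if pairs:
        table = evaluation.batch_evaluate(pairs)
    else:
        table = pd.DataFrame(
            columns=["image_id", "border_error_pct", "precision", "recall"]
        )
    evaluation.write_report(table, out_dir / "report.csv")
    save_config(config, out_dir / "run_config.txt")
    return table, failures


# -- flat key=value config serialization -------------------------------------

def _flatten(config: RunConfig) -> dict[str, str]:
    flat: dict[str, str] = {}
    for f in fields(config):
        value = getattr(config, f.name)
        if hasattr(value, "__dataclass_fields__"):
            for sub in fields(value):
                flat[f"{f.name}.{sub.name}"] = repr(getattr(value, sub.name))
        else:
            flat[f.name] = repr(value)
    return flat


def save_config(config: RunConfig, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in sorted(_flatten(config).items())]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> RunConfig:
    import ast

    flat: dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        text = raw.split("#", 1)[0].strip()
        if not text:
            continue
        key, _, value = text.partition("=")
        flat[key.strip()] = ast.literal_eval(value.strip())

    groups: dict[str, dict] = {}
    top: dict[str, object] = {}
    for key, value in flat.items():
        if "." in key:
            group, sub = key.split(".", 1)
            groups.setdefault(group, {})[sub] = value
        else:
            top[key] = value
    config = RunConfig(
        binarization=BinarizationConfig(**groups.get("binarization", {})),
        dbscan=DbscanParams(**groups.get("dbscan", {})),
        fcm=FcmParams(**groups.get("fcm", {})),
        **top,
    )
    return config
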