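"""Graph -> (mask, image) correspondence and per-case visual reports.

Artifacts are joined on (class subdirectory, filename stem); the mapping must
be total and single-valued over the graph set or the build fails loudly with
the list of orphaned stems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import OrphanError
from .synth import load_image_png, load_mask_png

__all__ = ["MappingTable", "build_mapping", "render_case_report"]


@dataclass
class MappingTable:
    rows: pd.DataFrame  # columns: graph_path, mask_path, image_path, class_label

    def __len__(self) -> int:
        return len(self.rows)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _index_by_stem(
    root: Path, suffix: str, subdir: str | None = None
) -> dict[tuple[str, str], Path]:
    out: dict[tuple[str, str], Path] = {}
    for p in sorted(root.rglob(f"*{suffix}")):
        parts = p.relative_to(root).parts
        if subdir is not None and (len(parts) < 3 or parts[-2] != subdir):
            continue
        out[(parts[0], p.stem)] = p
    return out


def build_mapping(
    graph_dir,
    mask_dir,
    image_dir,
    mask_subdir: str | None = None,
    image_subdir: str | None = None,
) -> MappingTable:
    """Associate every graph with exactly one mask and image by shared stem.

    The join key is (class subdirectory, filename stem).  Graph files named
    ``<stem>_aug_<k>.gml`` whose exact stem has no counterpart fall back to
    the first (lexicographic) pair of their class, i.e. augmented graphs map
    to their source table's representative mask.  ``mask_subdir``/``image_subdir``
    restrict the search to ``<class>/<subdir>/`` when masks and images share a root.
    """
    graph_dir, mask_dir, image_dir = Path(graph_dir), Path(mask_dir), Path(image_dir)
    for d in (graph_dir, mask_dir, image_dir):
        if not d.is_dir():
            raise OrphanError(f"directory does not exist: {d}")
    masks = _index_by_stem(mask_dir, ".png", mask_subdir)
    images = _index_by_stem(image_dir, ".png", image_subdir)
    paired = sorted(set(masks) & set(images))
    first_of_class: dict[str, str] = {}
    for cls, stem in paired:
        first_of_class.setdefault(cls, stem)
    records = []
    orphans = []
    for gpath in sorted(graph_dir.rglob("*.gml")):
        cls = gpath.relative_to(graph_dir).parts[0]
        stems = [gpath.stem]
        if "_aug_" in gpath.stem and cls in first_of_class:
            stems.append(first_of_class[cls])
        hit = next((s for s in stems if (cls, s) in masks and (cls, s) in images), None)
        if hit is None:
            orphans.append(f"{cls}/{gpath.stem}")
            continue
        records.append(
            {
                "graph_path": str(gpath),
                "mask_path": str(masks[(cls, hit)]),
                "image_path": str(images[(cls, hit)]),
                "class_label": cls,
            }
        )
    if orphans:
        raise OrphanError(
            f"{len(orphans)} graph(s) lack a mask/image counterpart: {orphans[:10]}",
            orphans=orphans,
        )
    df = pd.DataFrame(records, columns=["graph_path", "mask_path", "image_path", "class_label"])
    if df["graph_path"].duplicated().any():
        raise OrphanError("mapping is not single-valued: duplicate graph paths")
    return MappingTable(rows=df)


def render_case_report(
    mapping_row, prediction: str, metrics: dict, out_dir
) -> tuple[Path, Path]:
    """Composite figure (image, mask, overlay) + JSON sidecar for one case.

    Output paths derive deterministically from the mask stem.  Returns
    (png_path, json_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image = load_image_png(mapping_row["image_path"])
    mask = load_mask_png(mapping_row["mask_path"])
    stem = Path(mapping_row["mask_path"]).stem
    png_path = out_dir / f"{stem}_report.png"
    json_path = out_dir / f"{stem}_report.json"

    overlay = np.stack([image, image, image], axis=-1)
    fg = mask > 0
    overlay[fg, 0] = 0.8 * overlay[fg, 0] + 0.2  # highlight lesion pixels in red
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    axes[0].imshow(image, cmap="gray", vmin=0, vmax=1)
    axes[0].set_title("image")
    axes[1].imshow(mask, cmap="nipy_spectral")
    axes[1].set_title("mask")
    axes[2].imshow(overlay)
    axes[2].set_title(f"true={mapping_row['class_label']} pred={prediction}")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(png_path, dpi=100)
    plt.close(fig)

    record = {
        "stem": stem,
        "graph_path": str(mapping_row["graph_path"]),
        "mask_path": str(mapping_row["mask_path"]),
        "image_path": str(mapping_row["image_path"]),
        "true_class": str(mapping_row["class_label"]),
        "predicted_class": str(prediction),
        "overlay_foreground_pixels": int(fg.sum()),
        "mask_foreground_pixels": int((mask > 0).sum()),
        "metrics": metrics,
    }
    json_path.write_text(json.dumps(record, indent=2))
    return png_path, json_path
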