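"""Dataset adapters: image/label listings for folder-organised collections.

The ``folder`` adapter reads any ``<root>/<class>/*.png|jpg`` layout and is
the one exercised by the tests (on synthetic dumps).  The remaining adapters
target the public MED-NODE, 7-Point and PAD-UFES-20 collections in the
layouts they are distributed in; they only enumerate files and map raw
diagnosis labels onto the binary nevus/melanoma task (7-Point's "atypical
nevus" folds into nevus), never download anything.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = ["ADAPTER_NAMES", "load_dataset_adapter"]

ADAPTER_NAMES = ("folder", "mednode", "sevenpoint", "padufes20")

_IMG_SUFFIXES = {".png", ".jpg", ".jpeg"}


def _images_in(directory: Path) -> list[Path]:
    return sorted(p for p in directory.iterdir() if p.suffix.lower() in _IMG_SUFFIXES)


def _folder(root: Path) -> list[tuple[Path, str]]:
    pairs = [
        (img, sub.name)
        for sub in sorted(p for p in root.iterdir() if p.is_dir())
        for img in _images_in(sub)
    ]
    if not pairs:
        logger.warning("no images found under %s", root)
    return pairs


def _mednode(root: Path) -> list[tuple[Path, str]]:
    mapping = {"melanoma": "melanoma", "naevus": "nevus"}
    pairs = []
    for sub, label in mapping.items():
        d = root / sub
        if not d.is_dir():
            raise FileNotFoundError(f"expected MED-NODE class directory {d}")
        pairs.extend((img, label) for img in _images_in(d))
    return pairs


def _sevenpoint(root: Path, image_list: Path | None) -> list[tuple[Path, str, str]]:
    """7-Point pairs as (path, binary_label, raw_label).

    Requires the distribution's ``meta/meta.csv``.  ``image_list`` (one derm
    path per line) restricts to an explicit image subset, since published
    studies typically use only part of the collection.
    """
    meta = root / "meta" / "meta.csv"
    if not meta.is_file():
        raise FileNotFoundError(f"missing 7-Point metadata file {meta}")
    wanted = None
    if image_list is not None:
        wanted = {line.strip() for line in Path(image_list).read_text().splitlines() if line.strip()}
    out = []
    with open(meta, newline="") as fh:
        for row in csv.DictReader(fh):
            derm = row.get("derm", "")
            raw = row.get("diagnosis", "").lower()
            if wanted is not None and derm not in wanted:
                continue
            if "melanoma" in raw:
                binary = "melanoma"
            elif "nevus" in raw or "naevus" in raw:
                binary = "nevus"  # includes the atypical-nevus class
            else:
                continue
            out.append((root / "images" / derm, binary, raw))
    return out


def _padufes20(root: Path) -> list[tuple[Path, str]]:
    meta = root / "metadata.csv"
    if not meta.is_file():
        raise FileNotFoundError(f"missing PAD-UFES-20 metadata file {meta}")
    mapping = {"MEL": "melanoma", "NEV": "nevus"}
    out = []
    with open(meta, newline="") as fh:
        for row in csv.DictReader(fh):
            label = mapping.get(row.get("diagnostic", ""))
            if label is not None:
                out.append((root / "images" / row["img_id"], label))
    return out


def load_dataset_adapter(name: str, root_path, image_list=None):
    """List of (image path, class label) pairs for a recognised adapter.

    The ``sevenpoint`` adapter returns 3-tuples that additionally expose the
    raw diagnosis string.
    """
    root = Path(root_path)
    if name == "folder":
        return _folder(root)
    if name == "mednode":
        return _mednode(root)
    if name == "sevenpoint":
        return _sevenpoint(root, image_list)
    if name == "padufes20":
        return _padufes20(root)
    raise ValueError(f"unknown adapter {name!r}; valid adapters: {list(ADAPTER_NAMES)}")
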