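"""Reading and writing the package's on-disk formats.

Images travel as multi-page TIFF (one page per channel/z plane), tables as
CSV with the documented column headers, probe sets as FASTA plus a TSV
manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .probedesign import ProbeSet
from .simgen import ImageStack


def write_stack(path, stack: ImageStack) -> None:
    """Write an ImageStack as multi-page TIFF with channel/pixel-size metadata."""
    pages, names = [], []
    for name, planes in stack.channels.items():
        for z in range(planes.shape[0]):
            pages.append(planes[z].astype(np.float32))
            names.append(f"{name}/z{z}")
    meta = {"channels": names, "pixel_size_um": stack.pixel_size_um}
    tifffile.imwrite(
        path,
        np.stack(pages),
        photometric="minisblack",
        metadata=None,
        description=json.dumps(meta),
    )


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    channels: dict[str, list[np.ndarray]] = {}
    for page, name in zip(pages, meta["channels"]):
        channels.setdefault(name.split("/")[0], []).append(page)
    return ImageStack(
        channels={k: np.stack(v) for k, v in channels.items()},
        pixel_size_um=float(meta["pixel_size_um"]),
    )


def write_label_mask(path, labels: np.ndarray) -> None:
    """Write a label mask as 16-bit TIFF."""
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_probeset(path_prefix, probeset: ProbeSet) -> tuple[Path, Path]:
    """Write a probe set as role-tagged FASTA plus a TSV manifest.

    ``<prefix>.fasta`` holds one record per oligo (ODNs, padlock, detection
    oligo); ``<prefix>.tsv`` lists gene, role, sequence and target
    coordinates. Returns the two paths.
    """
    prefix = Path(path_prefix)
    fasta = prefix.with_suffix(".fasta")
    tsv = prefix.with_suffix(".tsv")
    rows = []
    with open(fasta, "w") as fh:
        for i, odn in enumerate(probeset.odns, start=1):
            rid = f"{probeset.gene_id}|odn{i}"
            fh.write(f">{rid}\n{odn.sequence}\n")
            rows.append(
                dict(gene=probeset.gene_id, role=f"odn{i}", sequence=odn.sequence,
                     target_start=odn.target_start, target_end=odn.target_end)
            )
        fh.write(f">{probeset.gene_id}|padlock\n{probeset.padlock.sequence}\n")
        rows.append(
            dict(gene=probeset.gene_id, role="padlock",
                 sequence=probeset.padlock.sequence, target_start="", target_end="")
        )
        fh.write(
            f">{probeset.gene_id}|detection\n{probeset.detection_oligo.sequence}\n"
        )
        rows.append(
            dict(gene=probeset.gene_id, role="detection",
                 sequence=probeset.detection_oligo.sequence,
                 target_start="", target_end="")
        )
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
    return fasta, tsv
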