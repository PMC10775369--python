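"""In-memory model of a cyclic immunofluorescence acquisition.

A cyclic mIF experiment images the same specimen over N staining cycles.
Each cycle stains a handful of markers, images M fields of view in C
fluorescent channels, then quenches the fluorophores and re-images the same
frames to record per-pixel background ("quench" images). The dataset is the
complete grid of (fov, cycle, channel) stain/quench pairs together with a
marker manifest mapping (cycle, channel) -> marker name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Mapping, Optional, Tuple

import numpy as np
import tifffile

from .errors import DatasetError

#: default filename dialect, shared with the synthetic generator
DEFAULT_NAMING_PATTERN = (
    r"(?P<sample>.+)_f(?P<fov>\d+)_c(?P<cycle>\d+)_ch(?P<channel>\d+)"
    r"_(?P<kind>stain|quench)\.tiff?$"
)


@dataclass
class ChannelImage:
    """A single-channel grayscale image plus its normalization state."""

    pixels: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage expects a 2-D array")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class StainPair:
    stain: ChannelImage
    quench: ChannelImage


@dataclass
class CyclicDataset:
    """Complete (fov, cycle, channel) grid of stain/quench image pairs.

    Keys are 0-based. ``manifest`` maps (cycle, channel) to the marker name
    imaged in that slot; marker names are unique across the panel.
    """

    images: Dict[Tuple[int, int, int], StainPair]
    manifest: Dict[Tuple[int, int], str]
    n_fovs: int
    n_cycles: int
    n_channels: int
    sample: str = "sample"

    def validate(self) -> None:
        missing = [
            (i, j, c)
            for i in range(self.n_fovs)
            for j in range(self.n_cycles)
            for c in range(self.n_channels)
            if (i, j, c) not in self.images
        ]
        if missing:
            raise DatasetError(
                f"incomplete (fov, cycle, channel) grid; {len(missing)} "
                f"triples missing, first: {missing[:5]}",
                missing=missing,
            )
        markers = list(self.manifest.values())
        if len(set(markers)) != len(markers):
            raise DatasetError("marker names are not unique across the panel")
        shapes = {}
        for (i, j, c), pair in self.images.items():
            shapes.setdefault(i, pair.stain.shape)
            if pair.stain.shape != shapes[i] or pair.quench.shape != shapes[i]:
                raise DatasetError(
                    f"images of FOV {i} do not share one shape"
                )

    def pair(self, fov: int, cycle: int, channel: int) -> StainPair:
        return self.images[(fov, cycle, channel)]

    def marker(self, cycle: int, channel: int) -> str:
        return self.manifest[(cycle, channel)]

    def iter_fovs(self) -> Iterator[int]:
        return iter(range(self.n_fovs))

    def fov_shape(self, fov: int) -> Tuple[int, int]:
        return self.images[(fov, 0, 0)].stain.shape


@dataclass
class GroupingReport:
    """What ``group_images`` matched, skipped and found missing."""

    n_matched: int = 0
    skipped: list = field(default_factory=list)
    missing_partners: list = field(default_factory=list)


def group_images(
    file_paths,
    naming_pattern: str = DEFAULT_NAMING_PATTERN,
    manifest: Optional[Mapping[Tuple[int, int], str]] = None,
) -> Tuple[CyclicDataset, GroupingReport]:
    """Group raw TIFF files into a :class:`CyclicDataset`.

    ``naming_pattern`` is a regex with named groups ``fov``, ``cycle``,
    ``channel`` and ``kind`` (stain|quench); an optional ``sample`` group
    names the specimen. Files matching no pattern are listed in the report;
    an incomplete grid raises :class:`DatasetError` naming missing triples.
    """
    pattern = re.compile(naming_pattern)
    report = GroupingReport()
    found: Dict[Tuple[int, int, int], Dict[str, Path]] = {}
    sample = "sample"
    for p in map(Path, file_paths):
        m = pattern.search(p.name)
        if m is None:
            report.skipped.append(str(p))
            continue
        d = m.groupdict()
        key = (int(d["fov"]), int(d["cycle"]), int(d["channel"]))
        found.setdefault(key, {})[d["kind"]] = p
        sample = d.get("sample") or sample
        report.n_matched += 1

    if not found:
        raise DatasetError("no files matched the naming pattern",
                           skipped=report.skipped)

    fovs = sorted({k[0] for k in found})
    cycles = sorted({k[1] for k in found})
    channels = sorted({k[2] for k in found})
    # indices are remapped to a dense 0-based grid
    fmap = {v: i for i, v in enumerate(fovs)}
    jmap = {v: i for i, v in enumerate(cycles)}
    cmap = {v: i for i, v in enumerate(channels)}

    images: Dict[Tuple[int, int, int], StainPair] = {}
    missing = []
    for i in fovs:
        for j in cycles:
            for c in channels:
                entry = found.get((i, j, c), {})
                if "stain" not in entry or "quench" not in entry:
                    missing.append((i, j, c))
                    continue
                stain = tifffile.imread(entry["stain"])
                quench = tifffile.imread(entry["quench"])
                images[(fmap[i], jmap[j], cmap[c])] = StainPair(
                    ChannelImage(stain), ChannelImage(quench)
                )
    if missing:
        report.missing_partners = missing
        raise DatasetError(
            f"missing stain/quench partners for triples {missing[:10]}"
            + ("..." if len(missing) > 10 else ""),
            missing=missing,
        )

    if manifest is None:
        manifest = {
            (jmap[j], cmap[c]): f"marker_c{j}ch{c}"
            for j in cycles
            for c in channels
        }
    ds = CyclicDataset(
        images=images,
        manifest=dict(manifest),
        n_fovs=len(fovs),
        n_cycles=len(cycles),
        n_channels=len(channels),
        sample=sample,
    )
    ds.validate()
    return ds, report
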