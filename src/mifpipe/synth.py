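"""Ground-truthed synthetic cyclic immunofluorescence datasets.

The generator emulates the acquisition a cyclic mIF microscope produces:
a fixed scene of disk-like cells is imaged over N staining cycles, each
cycle shifted by a planted rigid translation (slides are removed and
remounted between cycles), in C channels per cycle, with a paired
quench-background image for every stain image. Every downstream stage can
therefore be tested against exact ground truth: the planted shifts, the
per-FOV instance label map, and each cell's phenotype and true marker
means.

Cells are rendered as soft-edged disks (intensity 1 inside the radius,
Gaussian falloff over ~1 px at the rim) with a concentric nuclear disk for
DAPI. A cell's marker intensities follow its phenotype: markers in the
phenotype's positive set are "on", everything else is "off", and per-cell
means are drawn around the configured on/off levels. Stain images are
background + cell signal + Gaussian noise; quench images share the noise
model but not the realization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dataset import ChannelImage, CyclicDataset, StainPair
from .errors import ConfigurationError
from .phenotypes import PhenotypeRule, default_rules, rules_by_name, save_rules

# channel 0 of every cycle re-images the nuclear counterstain (the
# registration anchor visible in all cells); the remaining slots walk
# this protein panel, CD45 first so small configurations keep it
DEFAULT_PANEL_MARKERS = [
    "CD45", "CK56",
    "CD3", "CD4", "CD8",
    "CD56", "CD20", "CD11b",
    "CD66b", "CD68", "CD11c",
    "p16", "PD-L1", "PD-1",
    "Ki67", "CD163", "HLA-DR",
    "FoxP3", "CD31", "aSMA",
]

# observed abundance ordering: granulocytes/macrophages common, NK and
# dendritic cells rare
DEFAULT_MIXTURE = [
    ("Neutrophils", 0.25),
    ("Macrophages", 0.22),
    ("CD4+ T cells", 0.15),
    ("CD8+ T cells", 0.12),
    ("B cells", 0.10),
    ("Immune cells", 0.08),
    ("Natural killer cells", 0.04),
    ("Dendritic cells", 0.04),
]


def default_intensity_map(markers: Sequence[str]) -> Dict[str, Tuple[float, float, float]]:
    """marker -> (mean_on, mean_off, sd_fraction).

    Per-cell marker means are drawn with a coefficient of variation of
    ``sd_fraction`` around the on/off level (so the spread scales with the
    level, as fluorescence does), truncated at zero.
    """
    out = {m: (2500.0, 100.0, 0.25) for m in markers}
    for m in out:
        if m.startswith("DAPI"):
            out[m] = (3000.0, 0.0, 0.15)
    return out


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated specimen."""

    n_cycles: int = 7
    n_fovs: int = 2
    n_channels_per_cycle: int = 4   # nuclear counterstain + 3 proteins
    image_shape: Tuple[int, int] = (512, 512)
    n_cells: int = 150
    cell_radius_range: Tuple[float, float] = (4.0, 9.0)
    max_shift: int = 15
    phenotype_mixture: Sequence[Tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_MIXTURE))
    marker_intensity_map: Optional[Dict[str, Tuple[float, float, float]]] = None
    background_level: float = 200.0
    noise_sd: float = 30.0
    min_gap: float = 2.0
    touching_fraction: float = 0.0
    subpixel_shifts: bool = False
    seed: int = 0
    sample: str = "synthetic"

    def __post_init__(self):
        if self.n_cycles < 2:
            raise ConfigurationError("n_cycles must be >= 2")
        total = sum(p for _, p in self.phenotype_mixture)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phenotype mixture proportions sum to {total}, expected 1")
        if self.max_shift >= min(self.image_shape) / 4:
            raise ConfigurationError("max_shift must be < min(image_shape)/4")
        if self.marker_intensity_map is not None:
            for m, (on, off, sd) in self.marker_intensity_map.items():
                if on < 0 or off < 0 or sd < 0:
                    raise ConfigurationError(f"negative intensity for {m}")

    def panel(self) -> Dict[Tuple[int, int], str]:
        """Channel 0 of each cycle is the nuclear counterstain ("DAPI" in
        cycle 0, "DAPI_c{j}" after — unique names, same stain); remaining
        slots walk the protein marker list."""
        n_slots = self.n_cycles * (self.n_channels_per_cycle - 1)
        names = list(DEFAULT_PANEL_MARKERS)
        while len(names) < n_slots:
            names.append(f"extra{len(names)}")
        out: Dict[Tuple[int, int], str] = {}
        k = 0
        for j in range(self.n_cycles):
            out[(j, 0)] = "DAPI" if j == 0 else f"DAPI_c{j}"
            for c in range(1, self.n_channels_per_cycle):
                out[(j, c)] = names[k]
                k += 1
        return out

    def intensities(self) -> Dict[str, Tuple[float, float, float]]:
        markers = list(self.panel().values())
        out = default_intensity_map(markers)
        if self.marker_intensity_map:
            out.update(self.marker_intensity_map)
        return out


@dataclass
class GroundTruth:
    """Everything the generator planted, in the reference-cycle frame."""

    shifts: List[Tuple[float, float]]
    instance_maps: Dict[int, np.ndarray]
    cell_tables: Dict[int, pd.DataFrame]

    def n_cells(self, fov: int) -> int:
        return len(self.cell_tables[fov])


def plant_shifts(n_cycles: int, max_shift: int, seed,
                 subpixel: bool = False) -> List[Tuple[float, float]]:
    """Per-cycle translations; the reference cycle (index 0) gets (0, 0).

    Others are drawn uniformly on the integers in [-max_shift, max_shift]^2
    (uniform reals when ``subpixel``).
    """
    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    shifts: List[Tuple[float, float]] = [(0.0, 0.0)]
    for _ in range(n_cycles - 1):
        if subpixel:
            dy, dx = rng.uniform(-max_shift, max_shift, 2)
        else:
            dy, dx = rng.integers(-max_shift, max_shift + 1, 2)
        shifts.append((float(dy), float(dx)))
    return shifts


def _place_cells(config: SyntheticConfig, rng: np.random.Generator
                 ) -> List[Tuple[float, float, float]]:
    """Place (row, col, radius) tuples, spaced by min_gap except for an
    optional fraction planted as touching pairs."""
    h, w = config.image_shape
    r_lo, r_hi = config.cell_radius_range
    placed: List[Tuple[float, float, float]] = []

    def ok(r, c, rad, gap):
        if not (rad < r < h - rad and rad < c < w - rad):
            return False
        for (pr, pc, prad) in placed:
            if np.hypot(r - pr, c - pc) < rad + prad + gap:
                return False
        return True

    n_pairs = int(config.touching_fraction * config.n_cells / 2)
    attempts = 0
    while len(placed) < 2 * n_pairs and attempts < 20000:
        attempts += 1
        rad1 = rng.uniform(r_lo, r_hi)
        rad2 = rng.uniform(r_lo, r_hi)
        r1, c1 = rng.uniform(0, h), rng.uniform(0, w)
        theta = rng.uniform(0, 2 * np.pi)
        d = rad1 + rad2 - 1.0  # overlapping rims -> touching instances
        r2, c2 = r1 + d * np.cos(theta), c1 + d * np.sin(theta)
        if ok(r1, c1, rad1, config.min_gap):
            placed.append((r1, c1, rad1))
            if ok(r2, c2, rad2, -2 * max(rad1, rad2)):
                placed.append((r2, c2, rad2))
            else:
                placed.pop()
    while len(placed) < config.n_cells and attempts < 100000:
        attempts += 1
        rad = rng.uniform(r_lo, r_hi)
        r, c = rng.uniform(0, h), rng.uniform(0, w)
        if ok(r, c, rad, config.min_gap):
            placed.append((r, c, rad))
    if len(placed) < config.n_cells:
        raise ConfigurationError(
            f"could not place {config.n_cells} cells of radius "
            f"{config.cell_radius_range} in {config.image_shape}")
    return placed


def _soft_disk(shape, center, radius, edge_sigma=0.6) -> Tuple[np.ndarray, tuple]:
    """Soft-edged disk footprint on a bounding-box window.

    Returns (footprint, (r0, r1, c0, c1)); the footprint is 1 for
    d <= radius - 0.5 and decays as a Gaussian over ~1 px beyond.
    """
    h, w = shape
    cr, cc = center
    pad = int(np.ceil(radius + 3))
    r0, r1 = max(0, int(cr) - pad), min(h, int(cr) + pad + 1)
    c0, c1 = max(0, int(cc) - pad), min(w, int(cc) + pad + 1)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((0, 0)), (r0, r0, c0, c0)
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - cr, cc_ - cc)
    core = radius - 0.5
    f = np.where(d <= core, 1.0,
                 np.exp(-((d - core) / edge_sigma) ** 2))
    f[d > radius + 2.5] = 0.0
    return f, (r0, r1, c0, c1)


def _hard_disk_mask(shape, center, radius):
    f, box = _soft_disk(shape, center, radius)
    r0, r1, c0, c1 = box
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    return np.hypot(rr - center[0], cc_ - center[1]) <= radius - 0.5, box


def render_fov(cells: pd.DataFrame, shift: Tuple[float, float],
               config: SyntheticConfig, cycle: int,
               rng: np.random.Generator) -> Dict[int, Tuple[np.ndarray, np.ndarray]]:
    """Render one cycle of one FOV: channel -> (stain, quench) uint16 pair.

    ``cells`` carries per-cell centroids (reference frame), radii and true
    marker means; the whole scene is translated by ``shift`` before
    rendering, and cells pushed out of frame are clipped.
    """
    h, w = config.image_shape
    panel = config.panel()
    dy, dx = shift
    out = {}
    rows_r = cells["centroid_r"].to_numpy()
    rows_c = cells["centroid_c"].to_numpy()
    radii = cells["radius"].to_numpy()
    for c in range(config.n_channels_per_cycle):
        marker = panel[(cycle, c)]
        levels = cells[f"mean_{marker}"].to_numpy()
        img = np.full((h, w), config.background_level, dtype=np.float64)
        for k in range(len(cells)):
            if levels[k] <= 0:
                continue
            radius = radii[k]
            center = (rows_r[k] + dy, rows_c[k] + dx)
            if marker.startswith("DAPI"):
                radius = max(1.5, 0.7 * radius)
            f, (r0, r1, c0, c1) = _soft_disk((h, w), center, radius)
            if f.size:
                img[r0:r1, c0:c1] += levels[k] * f
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, (h, w))
        quench = np.full((h, w), config.background_level, dtype=np.float64)
        if config.noise_sd > 0:
            quench = quench + rng.normal(0.0, config.noise_sd, (h, w))
        out[c] = (_to_uint16(img), _to_uint16(quench))
    return out


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def _build_cell_table(config: SyntheticConfig, rules_map, rng
                      ) -> Tuple[pd.DataFrame, np.ndarray]:
    """Assign phenotypes and true marker means; rasterize the instance map.

    True means are drawn for every marker the rules reference, even those
    outside the imaging panel — the cell's biology does not depend on what
    was imaged; only panel markers are rendered.
    """
    rule_markers = sorted({m for r in rules_map.values() for m in r.markers})
    markers = list(dict.fromkeys(
        list(config.panel().values()) + rule_markers))
    intensities = config.intensities()
    for m in rule_markers:
        intensities.setdefault(m, (2500.0, 100.0, 0.25))
    # largest-remainder apportionment of the mixture over n_cells
    names = [n for n, _ in config.phenotype_mixture]
    props = np.array([p for _, p in config.phenotype_mixture])
    raw = props * config.n_cells
    counts = np.floor(raw).astype(int)
    rem = config.n_cells - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    phenos = [n for n, k in zip(names, counts) for _ in range(k)]
    rng.shuffle(phenos)

    placed = _place_cells(config, rng)
    rows = []
    inst = np.zeros(config.image_shape, dtype=np.int32)
    for cid, ((r, c, rad), pheno) in enumerate(zip(placed, phenos), start=1):
        rule = rules_map[pheno]
        rec = {"cell_id": cid, "phenotype": pheno,
               "centroid_r": r, "centroid_c": c, "radius": rad}
        for m in markers:
            on = (m in rule.positive_markers) or m.startswith("DAPI")
            mean_on, mean_off, sd_frac = intensities[m]
            mu = mean_on if on else mean_off
            # truncated at +-2 sd so on/off populations stay separated
            sd = sd_frac * mu
            draw = mu + float(np.clip(rng.normal(0.0, sd), -2 * sd, 2 * sd))
            rec[f"mean_{m}"] = max(0.0, draw) if mu > 0 else 0.0
        mask, (r0, r1, c0, c1) = _hard_disk_mask(config.image_shape, (r, c), rad)
        inst[r0:r1, c0:c1][mask] = cid
        rec["area"] = int(mask.sum())
        rows.append(rec)
    table = pd.DataFrame(rows)
    return table, inst


def generate_dataset(config: SyntheticConfig,
                     rules: Optional[Sequence[PhenotypeRule]] = None
                     ) -> Tuple[CyclicDataset, GroundTruth]:
    """Simulate a full cyclic acquisition with exact ground truth.

    Raises :class:`ConfigurationError` when the phenotype mixture names a
    rule absent from ``rules`` (default: the standard immune gating table).
    """
    rules = list(rules) if rules is not None else default_rules()
    rmap = rules_by_name(rules)
    for name, _ in config.phenotype_mixture:
        if name not in rmap:
            raise ConfigurationError(f"unknown phenotype rule {name!r}")

    rng = np.random.default_rng(config.seed)
    shifts = plant_shifts(config.n_cycles, config.max_shift, rng,
                          subpixel=config.subpixel_shifts)

    images: Dict[Tuple[int, int, int], StainPair] = {}
    instance_maps: Dict[int, np.ndarray] = {}
    cell_tables: Dict[int, pd.DataFrame] = {}
    for i in range(config.n_fovs):
        table, inst = _build_cell_table(config, rmap, rng)
        instance_maps[i] = inst
        cell_tables[i] = table
        for j in range(config.n_cycles):
            rendered = render_fov(table, shifts[j], config, j, rng)
            for c, (stain, quench) in rendered.items():
                images[(i, j, c)] = StainPair(ChannelImage(stain),
                                              ChannelImage(quench))

    ds = CyclicDataset(images=images, manifest=config.panel(),
                       n_fovs=config.n_fovs, n_cycles=config.n_cycles,
                       n_channels=config.n_channels_per_cycle,
                       sample=config.sample)
    ds.validate()
    return ds, GroundTruth(shifts=shifts, instance_maps=instance_maps,
                           cell_tables=cell_tables)


def write_dataset(dataset: CyclicDataset, gt: Optional[GroundTruth],
                  outdir, rules: Optional[Sequence[PhenotypeRule]] = None
                  ) -> Path:
    """Persist a dataset (and ground truth) as plain TIFF/CSV/JSON/YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = dataset.sample
    for (i, j, c), pair in dataset.images.items():
        base = f"{s}_f{i:02d}_c{j:02d}_ch{c}"
        tifffile.imwrite(outdir / f"{base}_stain.tif",
                         np.asarray(pair.stain.pixels))
        tifffile.imwrite(outdir / f"{base}_quench.tif",
                         np.asarray(pair.quench.pixels))
    manifest = {f"{j},{c}": m for (j, c), m in dataset.manifest.items()}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    if gt is not None:
        for i, inst in gt.instance_maps.items():
            tifffile.imwrite(outdir / f"{s}_f{i:02d}_labels.tif",
                             inst.astype(np.int32))
            gt.cell_tables[i].to_csv(outdir / f"{s}_f{i:02d}_cells.csv",
                                     index=False)
        with open(outdir / "shifts.json", "w") as fh:
            json.dump({str(j): {"dy": dy, "dx": dx}
                       for j, (dy, dx) in enumerate(gt.shifts)}, fh, indent=1)
    save_rules(rules if rules is not None else default_rules(),
               outdir / "phenotype_rules.yaml")
    return outdir


def load_manifest(path) -> Dict[Tuple[int, int], str]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {tuple(int(x) for x in k.split(",")): v for k, v in raw.items()}
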