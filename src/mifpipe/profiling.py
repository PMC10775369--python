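"""Single-cell marker quantification and phenotype calling.

Aligned marker images plus an instance label map become a cells x markers
table of mean intensities. The table then goes through the standard
post-processing chain: high-intensity outlier removal (median + k * MAD,
high side only), natural-log transform, per-marker positivity thresholds,
rule-based phenotype assignment, and z-scoring for visualization.

Two positivity threshold modes are provided. ``mean_minus_3sd`` places the
cutoff three standard deviations below the marker's mean log intensity —
appropriate when the marker distribution is dominated by a single positive
population with a sparse negative tail. ``otsu`` finds the split of a
bimodal on/off log-intensity distribution; use it when markers have
substantial positive and negative fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError
from .phenotypes import UNASSIGNED, PhenotypeRule, default_rules

LOG_PSEUDOCOUNT = 1e-6

META_COLUMNS = ["cell_id", "fov", "area", "centroid_r", "centroid_c"]


@dataclass
class SingleCellTable:
    """cells x markers matrix with per-cell metadata.

    ``data`` holds one row per cell: the META_COLUMNS plus one column per
    marker. ``transform_state`` walks raw -> log (-> zscore via
    :func:`zscore_matrix`, which returns a separate matrix). Positivity and
    phenotype columns appear once computed.
    """

    data: pd.DataFrame
    markers: List[str]
    transform_state: str = "raw"
    positivity: Optional[pd.DataFrame] = None
    phenotypes: Optional[pd.Series] = None

    def __len__(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data[self.markers].to_numpy(dtype=np.float64)

    def copy(self) -> "SingleCellTable":
        return SingleCellTable(self.data.copy(), list(self.markers),
                               self.transform_state,
                               None if self.positivity is None
                               else self.positivity.copy(),
                               None if self.phenotypes is None
                               else self.phenotypes.copy())

    def to_csv(self, path) -> None:
        out = self.data.copy()
        if self.phenotypes is not None:
            out["phenotype"] = self.phenotypes.values
        out.to_csv(path, index=False)


def aggregate_cell_signals(instances: np.ndarray,
                           aligned_stack: Mapping[str, np.ndarray],
                           fov: int = 0) -> SingleCellTable:
    """Mean marker intensity over each cell's pixel set.

    ``aligned_stack`` maps marker name -> image aligned to the reference
    frame. Records area and centroid per cell; labels must be contiguous
    1..K (the extraction contract).
    """
    inst = np.asarray(instances)
    n = int(inst.max())
    markers = list(aligned_stack)
    for m, img in aligned_stack.items():
        if np.asarray(img).shape != inst.shape:
            raise ValueError(
                f"marker {m!r} image shape {np.asarray(img).shape} does not "
                f"match instance map {inst.shape}")
    if n == 0:
        cols = {c: [] for c in META_COLUMNS}
        cols.update({m: [] for m in markers})
        return SingleCellTable(pd.DataFrame(cols), markers)

    ids = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(inst, dtype=np.float64),
                               inst, ids)
    centroids = ndimage.center_of_mass(np.ones_like(inst, dtype=np.float64),
                                       inst, ids)
    rows = {
        "cell_id": ids,
        "fov": np.full(n, fov),
        "area": areas.astype(int),
        "centroid_r": [c[0] for c in centroids],
        "centroid_c": [c[1] for c in centroids],
    }
    for m in markers:
        img = np.asarray(aligned_stack[m], dtype=np.float64)
        rows[m] = ndimage.mean(img, inst, ids)
    return SingleCellTable(pd.DataFrame(rows), markers)


def concat_tables(tables: Sequence[SingleCellTable]) -> SingleCellTable:
    """Stack per-FOV tables; (fov, cell_id) stays the unique key."""
    tables = [t for t in tables if len(t)]
    if not tables:
        raise ValueError("no cells to concatenate")
    markers = tables[0].markers
    df = pd.concat([t.data for t in tables], ignore_index=True)
    return SingleCellTable(df, list(markers), tables[0].transform_state)


def remove_outliers_mad(table: SingleCellTable, k: float = 5.0
                        ) -> Tuple[SingleCellTable, List[int]]:
    """Drop cells whose value exceeds median + k * MAD for any marker.

    Only the high side is filtered (the artifacts of interest are
    saturated debris). MAD is the median absolute deviation from the
    median; for an all-equal column (MAD = 0) any value strictly above the
    median counts as an outlier, so a constant column removes nothing.
    """
    if len(table) < 3:
        raise ValueError("outlier removal needs at least 3 cells")
    x = table.values()
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    with np.errstate(invalid="ignore"):
        high = np.where(mad > 0, x > med + k * mad, x > med)
    drop = high.any(axis=1)
    removed = table.data.loc[drop, "cell_id"].tolist()
    kept = SingleCellTable(table.data.loc[~drop].reset_index(drop=True),
                           list(table.markers), table.transform_state)
    return kept, removed


def log_transform(table: SingleCellTable,
                  pseudocount: float = LOG_PSEUDOCOUNT) -> SingleCellTable:
    """x -> ln(x + pseudocount); raw tables only (state machine)."""
    if table.transform_state != "raw":
        raise ValueError(
            f"log_transform expects a raw table, got {table.transform_state}")
    out = table.copy()
    out.data[table.markers] = np.log(
        out.data[table.markers].to_numpy(dtype=np.float64) + pseudocount)
    out.transform_state = "log"
    return out


def positivity_thresholds(table: SingleCellTable,
                          method: str = "mean_minus_3sd"
                          ) -> Dict[str, float]:
    """Per-marker positivity cutoffs on the log scale.

    ``mean_minus_3sd``: threshold = mean - 3 * sd over all cells —
    appropriate when the marker is expressed by essentially all cells and
    only a sparse negative tail must be cut; on a mixture of positive and
    negative populations the mixture variance pushes the cutoff below the
    negative population and every cell comes out positive.

    ``otsu``: Otsu's split of the log-intensity histogram, guarded by a
    bimodality test (two- vs one-component Gaussian mixture, BIC). A
    marker whose distribution is effectively unimodal cannot be split:
    if its values sit high on the panel-wide intensity scale it is a
    pan-positive anchor (like CD45 after immune gating) and the cutoff
    falls back to mean - 3 * sd; if they sit low the marker is absent
    and every cell is negative.
    """
    if table.transform_state != "log":
        raise ValueError("thresholds are computed on log-transformed tables")
    if len(table) < 2:
        raise ValueError("cannot estimate thresholds from a single cell")
    out = {}
    pooled = table.values().ravel()
    mid = float((np.percentile(pooled, 5) + np.percentile(pooled, 95)) / 2)
    for m in table.markers:
        v = table.data[m].to_numpy(dtype=np.float64)
        if method == "mean_minus_3sd":
            out[m] = float(v.mean() - 3.0 * v.std(ddof=0))
        elif method == "otsu":
            out[m] = _guarded_otsu(v, mid)
        else:
            raise ConfigurationError(f"unknown threshold method {method!r}")
    return out


_BIC_MARGIN = 10.0


def _guarded_otsu(v: np.ndarray, mid: float) -> float:
    """Otsu split when the distribution is genuinely bimodal; otherwise
    all-positive (mean - 3 sd) or all-negative depending on whether the
    single mode sits above or below the panel-wide midpoint ``mid``."""
    from sklearn.mixture import GaussianMixture

    all_positive = float(v.mean() - 3.0 * v.std(ddof=0))
    all_negative = float(v.max()) + 1.0
    if np.ptp(v) == 0:
        return all_positive if v.mean() >= mid else all_negative
    X = v.reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=0).fit(X)
    init = np.percentile(v, [10, 99]).reshape(-1, 1)
    g2 = GaussianMixture(2, random_state=0, means_init=init).fit(X)
    if g2.bic(X) < g1.bic(X) - _BIC_MARGIN:
        mlo, mhi = sorted(g2.means_.ravel())
        if mlo >= mid:          # both modes high: pan-positive marker
            return all_positive
        if mhi <= mid:          # both modes low: absent marker
            return all_negative
        # Otsu can sit at a cluster edge when the inter-mode gap is wide
        # (between-class variance is flat across the gap); a short 1-D
        # 2-means refinement centers the cutoff between the cluster means
        t = float(threshold_otsu(v))
        for _ in range(20):
            lo, hi = v[v <= t], v[v > t]
            if len(lo) == 0 or len(hi) == 0:
                break
            t_new = (lo.mean() + hi.mean()) / 2.0
            if abs(t_new - t) < 1e-9:
                break
            t = t_new
        return t
    return all_positive if v.mean() >= mid else all_negative


def call_positivity(table: SingleCellTable,
                    thresholds: Mapping[str, float]) -> pd.DataFrame:
    """Boolean cells x markers matrix: positive iff value > threshold."""
    pos = pd.DataFrame(
        {m: table.data[m].to_numpy(dtype=np.float64) > thresholds[m]
         for m in table.markers})
    table.positivity = pos
    return pos


def assign_phenotypes(table: SingleCellTable,
                      rules: Optional[Sequence[PhenotypeRule]] = None
                      ) -> pd.Series:
    """First-match-wins rule assignment over the positivity matrix.

    Rules are evaluated in order, most specific first; cells matching no
    rule (in particular non-CD45+ cells) are labeled "unassigned". A rule
    referencing a marker outside the panel raises
    :class:`ConfigurationError`.
    """
    if table.positivity is None:
        raise ValueError("call_positivity must run before assign_phenotypes")
    rules = list(rules) if rules is not None else default_rules()
    panel = set(table.markers)
    for r in rules:
        missing = r.markers - panel
        if missing:
            raise ConfigurationError(
                f"rule {r.name!r} references markers absent from the panel: "
                f"{sorted(missing)}")
    pos = table.positivity
    labels = np.full(len(table), UNASSIGNED, dtype=object)
    unmatched = np.ones(len(table), dtype=bool)
    for r in rules:
        match = unmatched.copy()
        for m in r.positive_markers:
            match &= pos[m].to_numpy()
        for m in r.negative_markers:
            match &= ~pos[m].to_numpy()
        labels[match] = r.name
        unmatched &= ~match
    series = pd.Series(labels, name="phenotype")
    table.phenotypes = series
    return series


def zscore_matrix(table: SingleCellTable) -> pd.DataFrame:
    """Per-marker standardization of the log table; constant markers -> 0."""
    if table.transform_state != "log":
        raise ValueError("z-scores are computed on log-transformed tables")
    x = table.values()
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    return pd.DataFrame(z, columns=table.markers)


def profile_cells(instance_maps: Mapping[int, np.ndarray],
                  stacks: Mapping[int, Mapping[str, np.ndarray]],
                  mad_k: Optional[float] = 5.0,
                  threshold_method: str = "mean_minus_3sd",
                  rules: Optional[Sequence[PhenotypeRule]] = None,
                  border_margin: int = 0) -> SingleCellTable:
    """Full profiling chain over a set of FOVs.

    aggregate -> MAD outlier removal -> log transform -> positivity ->
    phenotype assignment. Returns the log-scale table with positivity and
    phenotypes attached.

    ``mad_k=None`` disables outlier removal. Note that on panels where a
    marker has a clean minority of strongly positive cells, the high-side
    MAD filter treats exactly those positive cells as outliers (the median
    and MAD describe the negative majority); disable it or raise ``k``
    when marker distributions are well-separated mixtures rather than
    noisy unimodal distributions with sparse artifacts.

    ``border_margin`` drops cells whose centroid lies within that many
    pixels of the FOV border — after alignment, border regions are
    unobserved (zero-filled) in some cycles, so border cells carry
    truncated signal; set it to the largest |shift| applied.
    """
    tables = [aggregate_cell_signals(instance_maps[i], stacks[i], fov=i)
              for i in sorted(instance_maps)]
    if border_margin > 0:
        for t, i in zip(tables, sorted(instance_maps)):
            h, w = np.asarray(instance_maps[i]).shape
            d = t.data
            inside = ((d["centroid_r"] >= border_margin)
                      & (d["centroid_r"] < h - border_margin)
                      & (d["centroid_c"] >= border_margin)
                      & (d["centroid_c"] < w - border_margin))
            t.data = d.loc[inside].reset_index(drop=True)
    table = concat_tables(tables)
    if mad_k is not None:
        table, _removed = remove_outliers_mad(table, k=mad_k)
    table = log_transform(table)
    thresholds = positivity_thresholds(table, method=threshold_method)
    call_positivity(table, thresholds)
    assign_phenotypes(table, rules)
    return table
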