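"""Raster/vector/genotype I/O, grid alignment, and genotype quality filters.

Rasters are exchanged as ESRI ASCII grids (``.asc``), one file per band,
with an optional JSON sidecar carrying band names, CRS, period and scenario
labels.  All coordinates are projected meters (UTM-like); grids are
row-major with origin at the upper-left corner and half-open cell
intervals, so the cell containing a point ``(x, y)`` is::

    col = floor((x - xmin) / cellsize)
    row = floor((ymax - y) / cellsize)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

MISSING = -9  # genotype missing sentinel (dosage matrices are int8)

__all__ = [
    "MISSING",
    "GridSpec",
    "EnvStack",
    "OccurrenceSet",
    "GenotypeMatrix",
    "PolygonLayer",
    "GridMismatchError",
    "read_ascii_grid",
    "write_ascii_grid",
    "load_env_stack",
    "write_env_stack",
    "screen_collinearity",
    "load_genotypes",
    "write_genotypes_012",
    "filter_snps",
    "load_occurrences",
    "rarefy_occurrences",
    "load_polygons",
    "rasterize_mask",
]


class GridMismatchError(ValueError):
    """Raised when rasters do not share a grid and resampling was not requested."""


@dataclass(frozen=True)
class GridSpec:
    """Georeference of a north-up, square-cell raster grid."""

    nrow: int
    ncol: int
    xmin: float
    ymin: float
    cellsize: float
    crs: str = "EPSG:32738"

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncol * self.cellsize

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrow * self.cellsize

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrow, self.ncol)

    def cell_of(self, x, y):
        """Row/col of the cells containing projected points (vectorized)."""
        col = np.floor((np.asarray(x) - self.xmin) / self.cellsize).astype(int)
        row = np.floor((self.ymax - np.asarray(y)) / self.cellsize).astype(int)
        return row, col

    def cell_centers(self):
        """(nrow, ncol) arrays of cell-center x and y coordinates."""
        xs = self.xmin + (np.arange(self.ncol) + 0.5) * self.cellsize
        ys = self.ymax - (np.arange(self.nrow) + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def matches(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.xmin - other.xmin) <= tol
            and abs(self.ymin - other.ymin) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )


@dataclass
class EnvStack:
    """Named multi-band raster stack on a shared grid.

    ``values`` has shape (n_var, nrow, ncol) with ``np.nan`` marking nodata;
    the nodata mask is unified across bands on construction.
    """

    values: np.ndarray
    var_names: list[str]
    grid: GridSpec
    period: str = "current"
    scenario: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_var, nrow, ncol)")
        if self.values.shape[0] != len(self.var_names):
            raise ValueError("var_names length must match band count")
        if len(set(self.var_names)) != len(self.var_names):
            raise ValueError("var_names must be unique")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError("band shape does not match grid")
        # unify nodata: a cell missing in any band is missing in all
        bad = np.isnan(self.values).any(axis=0)
        self.values[:, bad] = np.nan

    @property
    def n_var(self) -> int:
        return len(self.var_names)

    @property
    def mask(self) -> np.ndarray:
        """Boolean (nrow, ncol) array, True where data are valid."""
        return ~np.isnan(self.values[0])

    def band(self, name: str) -> np.ndarray:
        return self.values[self.var_names.index(name)]

    def select(self, names: list[str]) -> "EnvStack":
        idx = [self.var_names.index(n) for n in names]
        return EnvStack(self.values[idx].copy(), list(names), self.grid,
                        self.period, self.scenario)

    def values_at(self, x, y) -> np.ndarray:
        """Environment matrix (n_points, n_var) at projected coordinates."""
        row, col = self.grid.cell_of(x, y)
        if (row < 0).any() or (row >= self.grid.nrow).any() or \
           (col < 0).any() or (col >= self.grid.ncol).any():
            raise ValueError("coordinates fall outside the raster grid")
        return self.values[:, row, col].T

    def table(self) -> pd.DataFrame:
        """Valid cells as a DataFrame (row, col, x, y, one column per band)."""
        ok = self.mask
        row, col = np.nonzero(ok)
        xc, yc = self.grid.cell_centers()
        df = pd.DataFrame({"row": row, "col": col, "x": xc[ok], "y": yc[ok]})
        for i, n in enumerate(self.var_names):
            df[n] = self.values[i, row, col]
        return df


@dataclass
class OccurrenceSet:
    """Presence records on projected coordinates, snapped to grid cells."""

    ids: list[str]
    x: np.ndarray
    y: np.ndarray
    grid: GridSpec | None = None
    cell_index: np.ndarray | None = None  # (n, 2) row, col

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.ids) == 0:
            raise ValueError("occurrence set must contain at least one record")
        if self.grid is not None and self.cell_index is None:
            self.cell_index = np.column_stack(self.grid.cell_of(self.x, self.y))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class GenotypeMatrix:
    """Individuals x loci alt-allele dosages in {0, 1, 2, MISSING}."""

    genotypes: np.ndarray
    ind_ids: list[str]
    locus_ids: list[str]
    coords: np.ndarray | None = None
    pop_labels: list[str] | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, L = self.genotypes.shape
        if len(self.ind_ids) != n or len(self.locus_ids) != L:
            raise ValueError("id lengths inconsistent with genotype matrix")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2) or not np.isfinite(self.coords).all():
                raise ValueError("coords must be a finite (n, 2) array")
        bad = (self.genotypes != MISSING) & ((self.genotypes < 0) | (self.genotypes > 2))
        if bad.any():
            raise ValueError("genotypes must be 0/1/2 or the missing sentinel")

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def as_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing."""
        g = self.genotypes.astype(float)
        g[self.genotypes == MISSING] = np.nan
        return g

    def select_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return GenotypeMatrix(
            self.genotypes[:, idx],
            list(self.ind_ids),
            [self.locus_ids[i] for i in idx],
            None if self.coords is None else self.coords.copy(),
            None if self.pop_labels is None else list(self.pop_labels),
        )


@dataclass
class PolygonLayer:
    """Labeled polygon geometries in the working projected CRS."""

    geometries: list
    labels: list[str]
    crs: str = "EPSG:32738"

    def __post_init__(self):
        if len(self.geometries) != len(self.labels):
            raise ValueError("labels must match geometries")
        self.geometries = [shapely.make_valid(g) for g in self.geometries]


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_ascii_grid(path, array, grid: GridSpec, nodata: float = -9999.0):
    arr = np.asarray(array, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {grid.ncol}\nnrows {grid.nrow}\n"
        f"xllcorner {grid.xmin!r}\nyllcorner {grid.ymin!r}\n"
        f"cellsize {grid.cellsize!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path, crs: str = "EPSG:32738"):
    """Read an ESRI ASCII grid; returns (array with NaN nodata, GridSpec)."""
    head = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "xllcenter", "yllcenter",
            }:
                head[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh)
    nrow, ncol = int(head["nrows"]), int(head["ncols"])
    data = data.reshape(nrow, ncol)
    cs = head["cellsize"]
    if "xllcorner" in head:
        xmin, ymin = head["xllcorner"], head["yllcorner"]
    else:  # center registration
        xmin, ymin = head["xllcenter"] - cs / 2, head["yllcenter"] - cs / 2
    nod = head.get("nodata_value", -9999.0)
    data[data == nod] = np.nan
    return data, GridSpec(nrow, ncol, xmin, ymin, cs, crs)


def _resample_nearest(arr: np.ndarray, src: GridSpec, dst: GridSpec) -> np.ndarray:
    xc, yc = dst.cell_centers()
    row, col = src.cell_of(xc.ravel(), yc.ravel())
    out = np.full(dst.shape, np.nan)
    ok = (row >= 0) & (row < src.nrow) & (col >= 0) & (col < src.ncol)
    vals = np.full(row.shape, np.nan)
    vals[ok] = arr[row[ok], col[ok]]
    return vals.reshape(dst.shape)


def load_env_stack(paths, var_names=None, resample=False, crs="EPSG:32738",
                   period="current", scenario="") -> EnvStack:
    """Load single-band ASCII grids onto one aligned stack.

    All grids must match the first one unless ``resample=True``, in which
    case later bands are nearest-neighbour resampled onto the first grid.
    Nodata is unified across bands (union of the per-band masks).
    """
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
    if var_names is None:
        var_names = [p.stem for p in paths]
    bands, grid = [], None
    for p in paths:
        arr, g = read_ascii_grid(p, crs=crs)
        if grid is None:
            grid = g
        elif not g.matches(grid):
            if not resample:
                raise GridMismatchError(
                    f"{p} grid {g.shape}@{g.cellsize} does not match "
                    f"{grid.shape}@{grid.cellsize}; pass resample=True"
                )
            arr = _resample_nearest(arr, g, grid)
        bands.append(arr)
    return EnvStack(np.stack(bands), list(var_names), grid, period, scenario)


def write_env_stack(stack: EnvStack, out_dir, nodata: float = -9999.0) -> Path:
    """Write one .asc per band plus a JSON sidecar; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(stack.var_names):
        write_ascii_grid(out / f"{name}.asc", stack.values[i], stack.grid, nodata)
    meta = {
        "var_names": stack.var_names,
        "crs": stack.grid.crs,
        "period": stack.period,
        "scenario": stack.scenario,
    }
    (out / "stack.json").write_text(json.dumps(meta, indent=1))
    return out


def load_env_stack_dir(path) -> EnvStack:
    path = Path(path)
    meta = json.loads((path / "stack.json").read_text())
    return load_env_stack(
        [path / f"{n}.asc" for n in meta["var_names"]],
        meta["var_names"], crs=meta["crs"],
        period=meta["period"], scenario=meta["scenario"],
    )


# ---------------------------------------------------------------------------
# Collinearity screen

def screen_collinearity(stack: EnvStack, threshold: float = 0.75,
                        sample_cells: int = 50_000, seed: int = 0) -> list[str]:
    """Greedy variable elimination until no pair exceeds ``|r| > threshold``.

    At each step the pair with the highest |Pearson r| above the threshold
    is found and the member with the larger mean |r| to all remaining
    variables is dropped.  Survivors are returned in original order.
    Correlations are estimated on up to ``sample_cells`` seeded random
    non-nodata cells.
    """
    if stack.n_var < 2:
        raise ValueError("need at least two variables")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ok = stack.mask
    flat = stack.values[:, ok]  # (n_var, n_cells)
    n_cells = flat.shape[1]
    if n_cells > sample_cells:
        rng = np.random.default_rng(seed)
        flat = flat[:, rng.choice(n_cells, sample_cells, replace=False)]
    sd = flat.std(axis=1)
    const = np.nonzero(sd == 0)[0]
    if const.size:
        raise ValueError(
            f"constant band(s): {[stack.var_names[i] for i in const]}"
        )
    r = np.abs(np.corrcoef(flat))
    np.fill_diagonal(r, 0.0)
    alive = list(range(stack.n_var))
    while True:
        sub = r[np.ix_(alive, alive)]
        if sub.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = alive[i], alive[j]
        mean_r = sub.sum(axis=0) / (len(alive) - 1)
        drop = a if mean_r[i] >= mean_r[j] else b
        alive.remove(drop)
    return [stack.var_names[i] for i in alive]


# ---------------------------------------------------------------------------
# Genotypes

def _read_012(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    locus_ids = [str(c) for c in df.columns]
    ind_ids = [str(i) for i in df.index]
    vals = df.to_numpy()
    g = np.full(vals.shape, MISSING, dtype=np.int8)
    for tok, code in (("0", 0), ("1", 1), ("2", 2)):
        g[vals == tok] = code
    known = np.isin(vals, ["0", "1", "2", "9", "NA"]) | pd.isna(vals)
    if not known.all():
        bad = vals[~known][0]
        raise ValueError(f"unrecognized genotype token {bad!r} in {path}")
    return g, ind_ids, locus_ids


def write_genotypes_012(g: GenotypeMatrix, path):
    """Tab-separated 012 matrix: header of locus ids, first column ind id."""
    vals = g.genotypes.astype(object)
    vals[g.genotypes == MISSING] = 9
    df = pd.DataFrame(vals, index=g.ind_ids, columns=g.locus_ids)
    df.to_csv(path, sep="\t", index_label="ind")


def _read_vcf(path, strict: bool = True):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ind_ids = list(vcf.samples)
    rows, locus_ids = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            if strict:
                raise ValueError(
                    f"multiallelic site at {v.CHROM}:{v.POS}; "
                    "strict mode accepts biallelic sites only"
                )
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = v.gt_types
        row = np.full(gt.shape, MISSING, dtype=np.int8)
        row[gt == 0] = 0
        row[gt == 1] = 1
        row[gt == 3] = 2
        rows.append(row)
        locus_ids.append(v.ID if v.ID and v.ID != "." else f"{v.CHROM}:{v.POS}")
    g = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(ind_ids), 0), np.int8)
    return g, ind_ids, locus_ids


def load_genotypes(path, coords_path=None, strict: bool = True) -> GenotypeMatrix:
    """Load a VCF or 012 text matrix, with optional per-individual coordinates.

    The coordinates CSV needs columns ``id, x, y`` (optional ``pop``) and must
    cover the genotyped individuals 1:1.
    """
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        g, ind_ids, locus_ids = _read_vcf(path, strict=strict)
    else:
        g, ind_ids, locus_ids = _read_012(path)
    coords = pops = None
    if coords_path is not None:
        meta = pd.read_csv(coords_path, dtype={"id": str}).set_index("id")
        missing = [i for i in ind_ids if i not in meta.index]
        extra = [i for i in meta.index if i not in ind_ids]
        if missing or extra:
            raise ValueError(
                f"individual id mismatch: missing from coords {missing}, "
                f"absent from genotypes {extra}"
            )
        meta = meta.loc[ind_ids]
        coords = meta[["x", "y"]].to_numpy(float)
        pops = [str(p) for p in meta["pop"]] if "pop" in meta.columns else None
    return GenotypeMatrix(g, ind_ids, locus_ids, coords, pops)


def filter_snps(g: GenotypeMatrix, min_call_rate: float = 0.85,
                min_mac: int = 2, max_hobs: float = 0.5):
    """Quality-filter loci: call rate, minor allele count, heterozygosity.

    A locus is kept when it is genotyped in at least ``min_call_rate`` of
    individuals, its minor allele count is at least ``min_mac`` and its
    observed heterozygosity does not exceed ``max_hobs``.  Returns the
    filtered matrix and a per-rule removal report (a locus failing several
    rules is counted under each).
    """
    if g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    gt = g.genotypes
    called = gt != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / g.n_ind
    alt = np.where(called, gt, 0).sum(axis=0)
    mac = np.minimum(alt, 2 * n_called - alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        hobs = np.where(called, gt == 1, False).sum(axis=0) / n_called
    hobs = np.nan_to_num(hobs, nan=0.0)
    fail_cr = call_rate < min_call_rate
    fail_mac = mac < min_mac
    fail_h = hobs > max_hobs
    keep = ~(fail_cr | fail_mac | fail_h)
    report = {
        "call_rate": int(fail_cr.sum()),
        "mac": int(fail_mac.sum()),
        "hobs": int(fail_h.sum()),
        "removed": int((~keep).sum()),
        "retained": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError(
            "no loci survive filtering; review thresholds "
            f"(removed per rule: {report})"
        )
    return g.select_loci(keep), report


# ---------------------------------------------------------------------------
# Occurrences and polygons

def load_occurrences(path, grid: GridSpec | None = None) -> OccurrenceSet:
    df = pd.read_csv(path, dtype={"id": str})
    return OccurrenceSet(list(df["id"]), df["x"].to_numpy(float),
                         df["y"].to_numpy(float), grid)


def rarefy_occurrences(occ: OccurrenceSet, grid: GridSpec,
                       random_choice: bool = False, seed: int = 0) -> OccurrenceSet:
    """Keep at most one record per raster cell.

    By default the first record in file order wins; ``random_choice=True``
    picks a seeded random record per cell instead.
    """
    row, col = grid.cell_of(occ.x, occ.y)
    key = row * grid.ncol + col
    order = np.arange(len(occ))
    if random_choice:
        order = np.random.default_rng(seed).permutation(len(occ))
    keep, seen = [], set()
    for i in order:
        if key[i] not in seen:
            seen.add(key[i])
            keep.append(i)
    keep = sorted(keep)
    return OccurrenceSet([occ.ids[i] for i in keep], occ.x[keep], occ.y[keep], grid)


def load_polygons(path, crs: str = "EPSG:32738") -> PolygonLayer:
    """Load polygons from a GeoJSON FeatureCollection."""
    data = json.loads(Path(path).read_text())
    geoms, labels = [], []
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    for k, f in enumerate(feats):
        geoms.append(shapely.geometry.shape(f["geometry"]))
        props = f.get("properties") or {}
        labels.append(str(props.get("name", k)))
    return PolygonLayer(geoms, labels, crs)


def rasterize_mask(layer: PolygonLayer, grid: GridSpec) -> np.ndarray:
    """Binary raster: 1 where the cell center lies inside any polygon."""
    if not layer.geometries:
        warnings.warn("empty polygon layer: all-zero mask")
        return np.zeros(grid.shape, dtype=np.int8)
    union = shapely.union_all(layer.geometries)
    xc, yc = grid.cell_centers()
    inside = shapely.contains_xy(union, xc.ravel(), yc.ravel())
    return inside.reshape(grid.shape).astype(np.int8)
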