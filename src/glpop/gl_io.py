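"""Readers and writers for the text formats the pipeline touches.

Internal genomic coordinates are uniformly 1-based inclusive; only BED I/O
converts (BED is 0-based half-open).  Beagle genotype-likelihood triplets are
stored linear and sum-normalised; readers tolerate any positive scaling
because downstream math is normalisation-invariant.  A triplet that is
exactly flat after normalisation (tolerance 1e-9) marks a missing
site x individual observation, which is how depth-0 sites behave in
genotype-likelihood pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOL = 1e-9


@dataclass
class GLDataset:
    """Markers x individuals x 3 genotype likelihoods plus marker metadata.

    ``likelihoods[j, i, g]`` is the likelihood of genotype ``g`` (copies of
    the minor allele) for individual ``i`` at marker ``j``, normalised so each
    triplet sums to 1.
    """

    chroms: np.ndarray          # (M,) str
    positions: np.ndarray       # (M,) int, 1-based
    major: np.ndarray           # (M,) str
    minor: np.ndarray           # (M,) str
    likelihoods: np.ndarray     # (M, N, 3) float
    individuals: list[str]

    def __post_init__(self) -> None:
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if self.likelihoods.ndim != 3 or self.likelihoods.shape[2] != 3:
            raise ValueError("likelihoods must have shape (markers, individuals, 3)")
        if np.any(self.likelihoods < 0):
            raise ValueError("negative genotype likelihoods")
        sums = self.likelihoods.sum(axis=2, keepdims=True)
        if np.any(sums == 0):
            raise ValueError("all-zero likelihood triplet")
        self.likelihoods = self.likelihoods / sums
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        for chrom in pd.unique(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_markers(self) -> int:
        return self.likelihoods.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.likelihoods.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return np.array([f"{c}_{p}" for c, p in zip(self.chroms, self.positions)],
                        dtype=object)

    def missing_mask(self) -> np.ndarray:
        """(M, N) bool: True where the triplet is flat (no data)."""
        gl = self.likelihoods
        return (np.abs(gl - 1.0 / 3.0) < MISSING_TOL).all(axis=2)

    def subset_markers(self, idx) -> "GLDataset":
        idx = np.asarray(idx)
        return GLDataset(self.chroms[idx], self.positions[idx], self.major[idx],
                         self.minor[idx], self.likelihoods[idx], list(self.individuals))

    def subset_individuals(self, idx) -> "GLDataset":
        idx = np.asarray(idx)
        return GLDataset(self.chroms, self.positions, self.major, self.minor,
                         self.likelihoods[:, idx], [self.individuals[i] for i in idx])


@dataclass
class SampleTable:
    """Per-sample metadata: id, sampling-site code, coordinates, optional grid cell."""

    table: pd.DataFrame  # columns: id, site, lat, lon[, row, col, group]

    def __post_init__(self) -> None:
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def sites(self) -> np.ndarray:
        return self.table["site"].to_numpy()


@dataclass
class RasterMap:
    """Arc-ASCII style land/water grid; water = 0, land = 1, cell size in km."""

    grid: np.ndarray        # (rows, cols) int
    xllcorner: float
    yllcorner: float
    cellsize_km: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def is_water(self, row: int, col: int) -> bool:
        return self.grid[row, col] == 0


@dataclass
class RegionSet:
    """Genomic intervals with provenance; 1-based inclusive internally."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "label", "provenance", "score"]))

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and (t["start"] >= t["end"]).any():
            raise ValueError("region start must be < end")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneAnnotation:
    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand


def read_beagle(path) -> GLDataset:
    """Read a Beagle genotype-likelihood TSV (marker, allele1, allele2, 3 cols/ind)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 3 or (len(header) - 3) % 3 != 0:
        raise ValueError("malformed Beagle header")
    n_ind = (len(header) - 3) // 3
    ind_ids = [header[3 + 3 * i] for i in range(n_ind)]
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None, dtype=str)
    if df.shape[1] != len(header):
        raise ValueError("ragged Beagle rows")
    markers = df.iloc[:, 0].to_numpy(dtype=object)
    if len(set(markers)) != len(markers):
        dup = pd.Series(markers)[pd.Series(markers).duplicated()].iloc[0]
        line = int(np.where(markers == dup)[0][1]) + 2
        raise ValueError(f"duplicated marker {dup!r} at line {line}")
    chroms, positions = [], []
    for k, m in enumerate(markers):
        # split on the LAST underscore so chromosome names may contain underscores
        chrom, _, pos = m.rpartition("_")
        if not chrom:
            raise ValueError(f"marker {m!r} at line {k + 2} lacks chrom_pos form")
        chroms.append(chrom)
        positions.append(int(pos))
    try:
        gl = df.iloc[:, 3:].to_numpy(dtype=float).reshape(len(markers), n_ind, 3)
    except ValueError as exc:
        raise ValueError(f"non-numeric likelihood in {path}: {exc}") from exc
    return GLDataset(np.array(chroms, dtype=object), np.array(positions),
                     df.iloc[:, 1].to_numpy(dtype=object),
                     df.iloc[:, 2].to_numpy(dtype=object), gl, ind_ids)


def write_beagle(ds: GLDataset, path) -> None:
    cols = ["marker", "allele1", "allele2"]
    for ind in ds.individuals:
        cols += [ind] * 3
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        gl = ds.likelihoods
        for j in range(ds.n_markers):
            row = [f"{ds.chroms[j]}_{ds.positions[j]}", str(ds.major[j]),
                   str(ds.minor[j])]
            row += [format(v, ".6g") for v in gl[j].ravel()]
            fh.write("\t".join(row) + "\n")


def read_regions_bed(path) -> RegionSet:
    rows = []
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start0, end0 = f[0], int(f[1]), int(f[2])
            if start0 >= end0:
                raise ValueError(f"BED start >= end at line {k}")
            rows.append({"chrom": chrom, "start": start0 + 1, "end": end0,
                         "label": f[3] if len(f) > 3 else f"region{k}",
                         "provenance": f[5] if len(f) > 5 else "",
                         "score": float(f[4]) if len(f) > 4 and f[4] != "." else np.nan})
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                                 "provenance", "score"]))


def write_regions_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for _, r in regions.table.iterrows():
            score = "." if pd.isna(r["score"]) else format(r["score"], "g")
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t"
                     f"{r['label']}\t{score}\t{r['provenance']}\n")


def read_raster(path) -> RasterMap:
    """Arc-ASCII grid: ncols/nrows/xllcorner/yllcorner/cellsize header + rows."""
    header: dict[str, float] = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append([int(float(v)) for v in parts])
    grid = np.array(data_lines, dtype=int)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("raster grid shape does not match header")
    return RasterMap(grid, header.get("xllcorner", 0.0), header.get("yllcorner", 0.0),
                     header.get("cellsize", 1.0))


def write_raster(raster: RasterMap, path) -> None:
    rows, cols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\nnrows {rows}\n")
        fh.write(f"xllcorner {raster.xllcorner}\nyllcorner {raster.yllcorner}\n")
        fh.write(f"cellsize {raster.cellsize_km}\n")
        for r in range(rows):
            fh.write(" ".join(str(int(v)) for v in raster.grid[r]) + "\n")


def read_gff_genes(path) -> GeneAnnotation:
    """Parse records of type 'gene' from a GFF3 file (1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"short GFF record at line {k}")
            if f[2] != "gene":
                warnings.warn(f"skipping non-gene GFF record of type {f[2]!r}")
                continue
            start, end = int(f[3]), int(f[4])
            if end < start:
                raise ValueError(f"GFF end < start at line {k}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene_id = attrs.get("ID", f"gene{k}")
            rows.append({"gene_id": gene_id, "chrom": f[0], "start": start,
                         "end": end, "strand": f[6]})
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "start",
                                                      "end", "strand"]))


def read_gene2go(path) -> dict[str, set[str]]:
    """Two-column TSV gene_id -> GO id; duplicate rows collapse to set semantics."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            gene, go = line.rstrip("\n").split("\t")[:2]
            if not (go.startswith("GO:") and len(go) == 10 and go[3:].isdigit()):
                raise ValueError(f"malformed GO id {go!r} at line {k}")
            mapping.setdefault(gene, set()).add(go)
    return mapping


def read_depth_sidecar(path, ds: GLDataset | None = None) -> np.ndarray:
    """Integer depth matrix (markers x individuals) aligned to a GLDataset."""
    df = pd.read_csv(path, sep="\t")
    depths = df.iloc[:, 1:].to_numpy(dtype=int)
    if ds is not None:
        if depths.shape != (ds.n_markers, ds.n_individuals):
            raise ValueError("depth sidecar shape does not match dataset")
        if not np.array_equal(df.iloc[:, 0].to_numpy(dtype=object), ds.marker_ids):
            raise ValueError("depth sidecar markers do not match dataset")
    return depths


def write_depth_sidecar(depths: np.ndarray, ds: GLDataset, path) -> None:
    df = pd.DataFrame(depths, columns=ds.individuals)
    df.insert(0, "marker", ds.marker_ids)
    df.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t"))


def write_sample_table(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)
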