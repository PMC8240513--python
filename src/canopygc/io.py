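"""On-disk formats: design/truth CSV, PNG images, point clouds (CSV/PLY), NDVI CSV.

The estimators accept real-world sensor exports in these formats; the
simulator can write the same layout, so a simulated trial round-trips through
files identically to a field campaign. Point clouds use CSV columns
x,y,z,intensity (x = along track, y = cross track) or ASCII PLY with the same
four properties.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .sensors import LidarScan, NdviStream, SensorBundle
from .trial import GroundTruth, TrialDesign


# -- design / truth ----------------------------------------------------------

def save_design(design: TrialDesign, truth: GroundTruth | None, path) -> None:
    """One row per plot: plot,row,col,genotype[,true_gc,canopy_height,effects]."""
    df = design.plots.copy()
    if truth is not None:
        df = df.merge(truth.table.drop(columns=["genotype"]), on="plot")
    df.attrs = {}
    header = (
        f"# plot_length={design.plot_length} n_rows_per_plot={design.n_rows_per_plot}"
        f" row_spacing={design.row_spacing} path_width={design.path_width}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def load_design(path) -> tuple[TrialDesign, GroundTruth | None]:
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            for tok in first[1:].split():
                k, v = tok.split("=")
                meta[k] = float(v)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    design = TrialDesign(
        plots=df[["plot", "row", "col", "genotype"]].copy(),
        plot_length=meta.get("plot_length", 6.0),
        n_rows_per_plot=int(meta.get("n_rows_per_plot", 7)),
        row_spacing=meta.get("row_spacing", 0.25),
        path_width=meta.get("path_width", 0.4),
    )
    truth = None
    if "true_gc" in df.columns:
        cols = [c for c in df.columns if c not in ("row", "col")]
        truth = GroundTruth(table=df[cols].copy(), mu=float("nan"))
    return design, truth


# -- point clouds ------------------------------------------------------------

def save_cloud_csv(scan: LidarScan, path) -> None:
    pd.DataFrame(scan.points, columns=["x", "y", "z", "intensity"]).to_csv(
        path, index=False
    )


def load_cloud_csv(path) -> LidarScan:
    df = pd.read_csv(path)
    return LidarScan(df[["x", "y", "z", "intensity"]].to_numpy(dtype=float))


def save_cloud_ply(scan: LidarScan, path) -> None:
    """Minimal ASCII PLY with x, y, z, intensity vertex properties."""
    pts = scan.points
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(pts)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property float intensity\nend_header\n"
        )
        np.savetxt(fh, pts, fmt="%.6f")


def load_cloud_ply(path) -> LidarScan:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        n_vertex = None
        props: list[str] = []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unterminated PLY header")
            line = line.strip()
            if line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
            elif line.startswith("property"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        if n_vertex is None:
            raise ValueError("PLY header missing vertex element")
        data = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    cols = {name: i for i, name in enumerate(props)}
    needed = ["x", "y", "z", "intensity"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"PLY missing properties: {missing}")
    return LidarScan(data[:, [cols[c] for c in needed]])


def load_cloud(path) -> LidarScan:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return load_cloud_ply(path)
    return load_cloud_csv(path)


# -- NDVI streams ------------------------------------------------------------

def save_ndvi_csv(stream: NdviStream, path) -> None:
    pd.DataFrame(stream.readings, columns=["position", "ndvi"]).to_csv(
        path, index=False
    )


def load_ndvi_csv(path) -> NdviStream:
    df = pd.read_csv(path)
    return NdviStream(df[["position", "ndvi"]].to_numpy(dtype=float))


# -- images ------------------------------------------------------------------

def save_bundle(bundle: SensorBundle, out_dir) -> None:
    """Write one bundle's streams: PNGs + manifest, cloud CSV, NDVI CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p, e = bundle.plot, bundle.event_id
    rows = []
    for k, (pos, img) in enumerate(zip(bundle.image_positions, bundle.images), 1):
        name = f"plot{p}_event{e}_img{k}.png"
        iio.imwrite(out / name, img)
        rows.append({"plot": p, "event": e, "k": k, "position": pos, "file": name})
    pd.DataFrame(rows).to_csv(out / f"plot{p}_event{e}_images.csv", index=False)
    if bundle.scan is not None:
        save_cloud_csv(bundle.scan, out / f"plot{p}_event{e}_cloud.csv")
    if bundle.ndvi is not None:
        save_ndvi_csv(bundle.ndvi, out / f"plot{p}_event{e}_ndvi.csv")


def load_images_dir(images_dir, manifest=None):
    """Load PNG images (and positions if a manifest CSV is present).

    Returns (positions, images). Without a manifest, files sort by name and
    positions default to a 1 m grid starting at 0.5 m.
    """
    images_dir = Path(images_dir)
    if manifest is not None:
        man = pd.read_csv(manifest)
        positions = man["position"].tolist()
        images = [iio.imread(images_dir / f) for f in man["file"]]
        return positions, images
    files = sorted(images_dir.glob("*.png"))
    images = [iio.imread(f) for f in files]
    positions = [0.5 + 1.0 * k for k in range(len(images))]
    return positions, images


# -- GC tables ---------------------------------------------------------------

def save_gc_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.8g")


def load_gc_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
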