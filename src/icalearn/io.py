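"""Readers and writers: NIfTI volumes, manifests, truth sidecars, configs.

Voxel indexing is 0-based throughout; NIfTI affines are carried through
untouched and no resampling is performed, so multi-site data must already
share a common grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import SubjectScan, VolumeGrid
from .synthetic import SiteParams, TruthRecord

MANIFEST_COLUMNS = ["subject_id", "group", "site", "path"]


def read_4d_volume(
    path: str | Path,
    mask: str | Path | np.ndarray | None = None,
    subject_id: str | None = None,
    group: str = "unknown",
    site: str = "",
) -> tuple[SubjectScan, np.ndarray]:
    """Load a 4-D NIfTI as a masked T x V scan; returns (scan, affine)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got {data.ndim}-D")
    shape3 = data.shape[:3]
    if mask is None:
        mask_arr = np.ones(shape3, dtype=bool)
    else:
        if isinstance(mask, (str, Path)):
            mask_arr = np.asanyarray(nib.load(str(mask)).dataobj) > 0
        else:
            mask_arr = np.asarray(mask, dtype=bool)
        if mask_arr.shape != shape3:
            raise ValueError(
                f"{path}: mask shape {mask_arr.shape} does not match volume grid {shape3}"
            )
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: non-finite values in volume")
    grid = VolumeGrid(shape3, mask_arr)
    matrix = data[mask_arr].T  # T x V (time is the 4th NIfTI axis)
    scan = SubjectScan(
        subject_id=subject_id or path.stem.replace(".nii", ""),
        group=group,
        site=site,
        data=matrix,
        grid=grid,
    )
    return scan, np.asarray(img.affine)


def write_4d_volume(
    data: np.ndarray, grid: VolumeGrid, path: str | Path, affine: np.ndarray | None = None
) -> Path:
    """Write a T x V masked matrix as a 4-D NIfTI (zeros outside the mask)."""
    vol = grid.unmask(np.asarray(data))  # T x X x Y x Z
    vol = np.moveaxis(vol, 0, -1)
    img = nib.Nifti1Image(vol.astype(np.float32), affine if affine is not None else np.eye(4))
    path = Path(path)
    nib.save(img, str(path))
    return path


def write_component_maps(
    maps: np.ndarray,
    grid: VolumeGrid,
    path: str | Path,
    z_score: bool = False,
    affine: np.ndarray | None = None,
) -> Path:
    """Write K x V spatial maps as a 4-D NIfTI (component as 4th axis)."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 1:
        raise ValueError("need at least one component map (K x V)")
    if z_score:
        mu = maps.mean(axis=1, keepdims=True)
        sd = maps.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot z-score a constant map")
        maps = (maps - mu) / sd
    return write_4d_volume(maps, grid, path, affine=affine)


def read_component_maps(path: str | Path, mask: np.ndarray | None = None) -> np.ndarray:
    """Read a 4-D component NIfTI back to K x V over the mask."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4-D component file")
    mask_arr = np.ones(data.shape[:3], dtype=bool) if mask is None else np.asarray(mask, bool)
    return data[mask_arr].T


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a tab-separated subject manifest."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dupes}")
    bad = set(df["group"]) - {"SZ", "HC", "unknown"}
    if bad:
        raise ValueError(f"manifest groups outside SZ/HC/unknown: {sorted(bad)}")
    base = Path(path).parent
    for p in df["path"]:
        full = (base / p) if not Path(p).is_absolute() else Path(p)
        if not full.exists():
            raise FileNotFoundError(f"manifest entry does not exist: {full}")
    return df


def load_cohort(manifest_path: str | Path, mask: np.ndarray | None = None) -> list[SubjectScan]:
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    scans = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        scan, _ = read_4d_volume(
            p, mask=mask, subject_id=row.subject_id, group=row.group, site=row.site
        )
        scans.append(scan)
    return scans


def write_cohort(scans, truth: TruthRecord | None, out_dir: str | Path) -> Path:
    """Write each scan as 4-D NIfTI plus a manifest; truth as a sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in scans:
        fname = f"{s.subject_id}.nii.gz"
        write_4d_volume(s.data, s.grid, out / fname)
        rows.append(
            {"subject_id": s.subject_id, "group": s.group, "site": s.site, "path": fname}
        )
    manifest = write_manifest(rows, out / "manifest.tsv")
    if truth is not None:
        write_truth_sidecar(truth, out / "truth.txt")
    return manifest


def write_truth_sidecar(truth: TruthRecord, path: str | Path) -> Path:
    """Plain-text key/value + matrix sidecar with the planted ground truth."""
    lines = [
        "# synthetic cohort ground truth (oracle only; not a pipeline input)",
        f"grid_shape\t{' '.join(map(str, truth.grid.shape))}",
        f"affected_components\t{' '.join(map(str, truth.affected_components))}",
        f"effect_size\t{truth.effect_size}",
    ]
    for site, p in truth.site_params.items():
        lines.append(
            f"site\t{site}\tgain={p.gain}\tnoise_sd={p.noise_sd}\t"
            f"displacement={','.join(map(str, p.displacement))}"
        )
    lines.append(f"component_maps\t{truth.component_maps.shape[0]}\t{truth.component_maps.shape[1]}")
    for row in truth.component_maps:
        lines.append(" ".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def save_decomposition(dec, path: str | Path) -> Path:
    """Serialize a GroupDecomposition to a versioned npz container."""
    path = Path(path)
    np.savez(
        path,
        version=np.array([1]),
        spatial_maps=dec.spatial_maps,
        group_reducer=dec.group_reducer,
        unmixing=dec.unmixing,
        whitening=dec.whitening,
        K=np.array([dec.K]),
        training_subject_ids=np.array(dec.training_subject_ids, dtype=object),
        **{f"reducer_{sid}": r for sid, r in dec.subject_reducers.items()},
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_decomposition(path: str | Path):
    from .ica import GroupDecomposition

    with np.load(path, allow_pickle=True) as z:
        if int(z["version"][0]) != 1:
            raise ValueError(f"unsupported decomposition container version in {path}")
        ids = [str(s) for s in z["training_subject_ids"]]
        return GroupDecomposition(
            spatial_maps=z["spatial_maps"],
            subject_reducers={sid: z[f"reducer_{sid}"] for sid in ids},
            group_reducer=z["group_reducer"],
            unmixing=z["unmixing"],
            whitening=z["whitening"],
            K=int(z["K"][0]),
            training_subject_ids=ids,
        )


KNOWN_CONFIG_KEYS = {
    "n_sub_pc", "K", "K_sel", "kernel", "d", "t0_percentile_lo", "t0_percentile_hi",
    "n_perm", "seed", "effect_size", "noise_sd", "gain", "displacement",
    "n_per_group", "T_main", "T_validated", "K_true", "grid_shape",
}


def read_config(path: str | Path) -> dict:
    """Flat key/value config; unknown keys are errors, not warnings."""
    out = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        key, _, value = ln.partition("=")
        key, value = key.strip(), value.strip()
        if key not in KNOWN_CONFIG_KEYS:
            raise ValueError(f"unknown config key {key!r}")
        out[key] = value
    return out


def write_json_report(obj: dict, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")
    return Path(path)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")
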