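"""File IO: sparse triplet matrices, component maps, geometry tables.

The on-disk matrix dialect is a whitespace-separated triplet text format
(``row col value``), 0-based by default, with ``#`` header lines recording
shape, dialect and the per-seed streamline budget — an interoperable stand-in
for FSL "matrix2"-style sparse outputs.  Component maps are written as
NIfTI-1 volumes (white matter), per-vertex TSV/GIFTI metric tables (grey
matter) and integer label volumes/tables (hard parcellation).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthgeo import Geometry, GroundTruth, TractographyMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_component_maps",
    "read_component_volume",
    "save_geometry",
    "load_geometry",
    "save_truth",
    "load_truth",
]

_AFFINE = np.eye(4)  # 1 mm isotropic, index space


def _format_value(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_matrix(matrix: TractographyMatrix, path: str | Path) -> None:
    """Write a matrix as 0-based sorted triplet lines with a header."""
    path = Path(path)
    n_seeds, n_targets = matrix.shape
    rows, cols = np.nonzero(matrix.counts)
    with open(path, "w") as fh:
        fh.write("# tractoica sparse matrix v1\n")
        fh.write(f"# shape: {n_seeds} {n_targets}\n")
        fh.write("# dialect: 0-based\n")
        fh.write(f"# n_samples_per_seed: {matrix.n_samples_per_seed}\n")
        fh.write(f"# subject_id: {matrix.subject_id}\n")
        for r, c in zip(rows, cols):  # np.nonzero is already (row, col) sorted
            fh.write(f"{r} {c} {_format_value(matrix.counts[r, c])}\n")


class MatrixFormatError(ValueError):
    """Malformed triplet file; message carries the offending line number."""


def read_matrix(
    path: str | Path,
    geometry: Geometry,
    one_based: bool = False,
) -> TractographyMatrix:
    """Read a triplet sparse matrix into a dense counts array.

    Lines starting with ``#`` are headers; the shape comes from ``geometry``
    (cross-checked against a ``# shape:`` header when present).  With
    ``one_based`` the file's indices are 1-based FSL style and converted.
    """
    path = Path(path)
    n_seeds, n_targets = geometry.n_seeds, geometry.n_targets
    counts = np.zeros((n_seeds, n_targets))
    seen: set[tuple[int, int]] = set()
    n_samples = 10_000
    subject_id = "unknown"
    offset = 1 if one_based else 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("shape:"):
                    hs = tuple(int(x) for x in body.split(":", 1)[1].split())
                    if hs != (n_seeds, n_targets):
                        raise MatrixFormatError(
                            f"{path} line {lineno}: header shape {hs} does not "
                            f"match geometry shape {(n_seeds, n_targets)}"
                        )
                elif body.startswith("n_samples_per_seed:"):
                    n_samples = int(float(body.split(":", 1)[1]))
                elif body.startswith("subject_id:"):
                    subject_id = body.split(":", 1)[1].strip()
                continue
            parts = line.split()
            if len(parts) != 3:
                raise MatrixFormatError(
                    f"{path} line {lineno}: expected 'row col value', got {line!r}"
                )
            try:
                r, c, v = int(parts[0]) - offset, int(parts[1]) - offset, float(parts[2])
            except ValueError as exc:
                raise MatrixFormatError(f"{path} line {lineno}: {exc}") from exc
            if not (0 <= r < n_seeds and 0 <= c < n_targets):
                raise MatrixFormatError(
                    f"{path} line {lineno}: index ({r}, {c}) out of range for "
                    f"shape {(n_seeds, n_targets)}"
                )
            if v < 0:
                raise MatrixFormatError(f"{path} line {lineno}: negative value {v}")
            if (r, c) in seen:
                raise MatrixFormatError(
                    f"{path} line {lineno}: duplicate entry ({r}, {c})"
                )
            seen.add((r, c))
            counts[r, c] = v

    return TractographyMatrix(
        counts=counts,
        n_samples_per_seed=n_samples,
        geometry=geometry,
        subject_id=subject_id,
    )


def _vector_to_volume(values: np.ndarray, geometry: Geometry) -> np.ndarray:
    vol = np.zeros(geometry.volume_shape, dtype=np.float32)
    i, j, k = geometry.target_coords.T
    vol[i, j, k] = values
    return vol


def read_component_volume(path: str | Path, geometry: Geometry) -> np.ndarray:
    """Load a NIfTI component volume back into a per-target vector."""
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    i, j, k = geometry.target_coords.T
    return vol[i, j, k]


def write_component_maps(
    components,
    geometry: Geometry,
    out_dir: str | Path,
    seed_labels: np.ndarray | None = None,
    voxel_labels: np.ndarray | None = None,
) -> None:
    """Write a ComponentSet in the documented layout.

    Per-component white maps become ``white_component_<k>.nii`` volumes on
    the geometry grid; grey maps a ``grey_maps.tsv`` vertex table plus a
    GIFTI metric file; optional hard-parcellation labels an integer volume
    and vertex table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grey, white, K = components.grey, components.white, components.K
    if grey.shape[0] != geometry.n_seeds or white.shape[0] != geometry.n_targets:
        raise ValueError(
            f"component maps ({grey.shape[0]} seeds, {white.shape[0]} targets) do "
            f"not match geometry ({geometry.n_seeds}, {geometry.n_targets})"
        )

    for k in range(K):
        img = nib.Nifti1Image(_vector_to_volume(white[:, k], geometry), _AFFINE)
        nib.save(img, str(out_dir / f"white_component_{k:02d}.nii"))

    df = pd.DataFrame(
        grey.astype(np.float32), columns=[f"comp_{k:02d}" for k in range(K)]
    )
    df.insert(0, "hemi", geometry.seed_hemi)
    df.insert(0, "seed_index", np.arange(geometry.n_seeds))
    df.to_csv(out_dir / "grey_maps.tsv", sep="\t", index=False)

    gii = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                grey[:, k].astype(np.float32), intent="NIFTI_INTENT_NONE"
            )
            for k in range(K)
        ]
    )
    nib.save(gii, str(out_dir / "grey_maps.func.gii"))

    if voxel_labels is not None:
        vol = np.full(geometry.volume_shape, -1, dtype=np.int16)
        i, j, k_ = geometry.target_coords.T
        vol[i, j, k_] = voxel_labels
        nib.save(nib.Nifti1Image(vol, _AFFINE), str(out_dir / "voxel_labels.nii"))
    if seed_labels is not None:
        pd.DataFrame(
            {"seed_index": np.arange(geometry.n_seeds), "label": seed_labels}
        ).to_csv(out_dir / "seed_labels.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# geometry / ground-truth serialization

def save_geometry(geometry: Geometry, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "seed_index": np.arange(geometry.n_seeds),
            "x": geometry.seed_coords[:, 0],
            "y": geometry.seed_coords[:, 1],
            "z": geometry.seed_coords[:, 2],
            "hemi": geometry.seed_hemi,
            "mirror_index": geometry.seed_mirror,
        }
    ).to_csv(out_dir / "seeds.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "target_index": np.arange(geometry.n_targets),
            "i": geometry.target_coords[:, 0],
            "j": geometry.target_coords[:, 1],
            "k": geometry.target_coords[:, 2],
        }
    ).to_csv(out_dir / "targets.tsv", sep="\t", index=False)
    with open(out_dir / "geometry.json", "w") as fh:
        json.dump(
            {
                "n_seeds_per_hemi": geometry.n_seeds_per_hemi,
                "volume_shape": list(geometry.volume_shape),
                "n_targets": geometry.n_targets,
            },
            fh,
            indent=2,
        )


def load_geometry(in_dir: str | Path) -> Geometry:
    in_dir = Path(in_dir)
    with open(in_dir / "geometry.json") as fh:
        meta = json.load(fh)
    seeds = pd.read_csv(in_dir / "seeds.tsv", sep="\t")
    targets = pd.read_csv(in_dir / "targets.tsv", sep="\t")
    shape = tuple(meta["volume_shape"])
    d0, d1, d2 = shape
    tc = targets[["i", "j", "k"]].to_numpy()
    target_mirror = ((d0 - 1 - tc[:, 0]) * d1 * d2 + tc[:, 1] * d2 + tc[:, 2])
    geom = Geometry(
        n_seeds_per_hemi=int(meta["n_seeds_per_hemi"]),
        seed_coords=seeds[["x", "y", "z"]].to_numpy(),
        seed_hemi=seeds["hemi"].to_numpy().astype(str),
        volume_shape=shape,
        n_targets=int(meta["n_targets"]),
        target_coords=tc,
        seed_mirror=seeds["mirror_index"].to_numpy(),
        target_mirror=target_mirror.astype(np.intp),
    )
    geom.validate()
    return geom


def save_truth(truth: GroundTruth, geometry: Geometry, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = [f"comp_{k:02d}" for k in range(truth.k_true)]
    df = pd.DataFrame(truth.grey_truth, columns=cols)
    df.insert(0, "seed_index", np.arange(geometry.n_seeds))
    df["winner"] = truth.winner_truth
    df.to_csv(out_dir / "grey_truth.tsv", sep="\t", index=False)
    for k in range(truth.k_true):
        img = nib.Nifti1Image(
            _vector_to_volume(truth.white_truth[:, k], geometry), _AFFINE
        )
        nib.save(img, str(out_dir / f"white_truth_{k:02d}.nii"))
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "k_true": truth.k_true,
                "baseline_rate": truth.baseline_rate,
                "amplitude": truth.amplitude.tolist(),
                "symmetric_pairs": [list(p) for p in truth.symmetric_pairs],
            },
            fh,
            indent=2,
        )


def load_truth(in_dir: str | Path, geometry: Geometry) -> GroundTruth:
    in_dir = Path(in_dir)
    with open(in_dir / "truth.json") as fh:
        meta = json.load(fh)
    k_true = int(meta["k_true"])
    df = pd.read_csv(in_dir / "grey_truth.tsv", sep="\t")
    grey = df[[f"comp_{k:02d}" for k in range(k_true)]].to_numpy()
    white = np.column_stack(
        [
            read_component_volume(in_dir / f"white_truth_{k:02d}.nii", geometry)
            for k in range(k_true)
        ]
    ).astype(np.float64)
    return GroundTruth(
        k_true=k_true,
        grey_truth=grey,
        white_truth=white,
        baseline_rate=float(meta["baseline_rate"]),
        amplitude=np.asarray(meta["amplitude"]),
        symmetric_pairs=[tuple(p) for p in meta["symmetric_pairs"]],
        winner_truth=df["winner"].to_numpy(),
    )
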