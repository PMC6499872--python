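"""End-to-end orchestration: simulate/load -> average -> reduce -> ICA ->
back-project -> parcellate -> threshold -> symmetry -> evaluate.

A single :class:`RunConfig` drives the whole run; every stage parameter is
recorded in the emitted manifest (no silent defaults), per-stage seeds are
derived deterministically from one master seed, and rerunning the same
config reproduces all numeric artifacts bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import matio, synthgeo
from .ica import align_signs, back_project, run_ica, variance_explained, ComponentSet
from .migp import migp_reduce
from .parcellation import HardParcellation, fit_ggm, threshold_map, winner_take_all
from .symmetry import match_to_truth, symmetry_scores

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seed"]

_STAGES = ("geometry", "truth", "subjects", "migp", "ica", "ggm")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Every knob of a pipeline run.  Full-scale defaults mirror the study
    conditions (10,000 streamlines/seed, 10,000-voxel chunks, 4,000
    principal components, K=50, p>0.5); synthetic runs scale these down."""

    mode: str = "synthetic"          # "synthetic" | "files"
    out_dir: str = "tractoica_run"
    # synthetic-mode generator parameters
    n_seeds_per_hemi: int = 100
    volume_shape: tuple[int, int, int] = (20, 16, 16)
    k_true: int = 8
    overlap: float = 0.0
    symmetric: bool = True
    n_subjects: int = 10
    n_samples_per_seed: int = 10_000
    noise_scale: float = 0.0
    baseline_rate: float = 0.01
    # files-mode inputs
    matrix_path: str | None = None
    geometry_dir: str | None = None
    # reduction / decomposition / thresholding
    n_pca: int = 30
    chunk_size: int = 512
    center: bool = False
    K: int = 8
    nonlinearity: str = "logcosh"
    tol: float = 1e-6
    max_iter: int = 1000
    p_threshold: float = 0.5
    master_seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.mode not in ("synthetic", "files"):
            errs.append(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.K > self.n_pca:
            errs.append(f"K ({self.K}) must not exceed n_pca ({self.n_pca})")
        if self.mode == "synthetic":
            if self.n_pca > 2 * self.n_seeds_per_hemi:
                errs.append(
                    f"n_pca ({self.n_pca}) must not exceed the seed count "
                    f"({2 * self.n_seeds_per_hemi})"
                )
            if self.symmetric and self.k_true % 2:
                errs.append(f"symmetric planting needs even k_true, got {self.k_true}")
            if self.noise_scale < 0:
                errs.append(f"noise_scale must be nonnegative, got {self.noise_scale}")
            if self.n_subjects < 1:
                errs.append("n_subjects must be >= 1")
        else:
            if not self.matrix_path or not self.geometry_dir:
                errs.append("files mode requires matrix_path and geometry_dir")
        if not (0.0 < self.p_threshold < 1.0):
            errs.append(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if errs:
            raise ValueError("invalid config: " + "; ".join(errs))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.pop("_provenance", None)
        if "volume_shape" in data:
            data["volume_shape"] = tuple(data["volume_shape"])
        return cls(**data)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the master
    seed and the stage name via SHA-256 (documented, platform-stable)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write every artifact under ``config.out_dir``.

    Returns a results bundle (geometry, matrix, reduced, components,
    parcellation, fits, reports, manifest).  Synthetic mode also evaluates
    recovery against the planted truth and writes a match report.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "tractoica",
        "version": __version__,
        "config": {**asdict(config), "volume_shape": list(config.volume_shape)},
        "stages": {},
    }
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    marker.write_text(f"failed at stage: {name}\n")
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"].setdefault(name, {})["seconds"] = (
                    time.perf_counter() - self_inner.t0
                )
                return False

        return _Ctx()

    truth = None
    with stage("input"):
        if config.mode == "synthetic":
            geometry = synthgeo.make_geometry(
                config.n_seeds_per_hemi,
                config.volume_shape,
                seed=stage_seed(config.master_seed, "geometry"),
            )
            truth = synthgeo.plant_components(
                geometry,
                k_true=config.k_true,
                overlap=config.overlap,
                symmetric=config.symmetric,
                seed=stage_seed(config.master_seed, "truth"),
                baseline_rate=config.baseline_rate,
            )
            subj_root = stage_seed(config.master_seed, "subjects")
            subjects = [
                synthgeo.simulate_subject_matrix(
                    truth,
                    geometry,
                    n_samples_per_seed=config.n_samples_per_seed,
                    noise_scale=config.noise_scale,
                    seed=(subj_root + i) % (2**31),
                    subject_id=f"sub-{i:03d}",
                )
                for i in range(config.n_subjects)
            ]
            group = synthgeo.average_matrices(subjects)
            matio.save_geometry(geometry, out / "geometry")
            matio.save_truth(truth, geometry, out / "truth")
        else:
            geometry = matio.load_geometry(config.geometry_dir)
            group = matio.read_matrix(config.matrix_path, geometry)
        matio.write_matrix(group, out / "group_matrix.txt")
        manifest["stages"]["input"] = {"matrix_checksum": _checksum(group.counts)}

    with stage("reduce"):
        reduced = migp_reduce(
            group,
            n_pca=config.n_pca,
            chunk_size=config.chunk_size,
            seed=stage_seed(config.master_seed, "migp"),
            center=config.center,
        )
        np.save(out / "reduced_scores.npy", reduced.scores)
        manifest["stages"]["reduce"] = {
            "effective_rank": reduced.effective_rank,
            "scores_checksum": _checksum(reduced.scores),
        }

    with stage("decompose"):
        comps = run_ica(
            reduced,
            K=config.K,
            nonlinearity=config.nonlinearity,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=stage_seed(config.master_seed, "ica"),
        )
        white = back_project(comps.grey, group)
        comps = ComponentSet(
            grey=comps.grey,
            white=white,
            K=comps.K,
            mixing=comps.mixing,
            ica_params=comps.ica_params,
        )
        comps = align_signs(comps)
        ve = variance_explained(group, comps)
        comps = ComponentSet(
            grey=comps.grey,
            white=comps.white,
            K=comps.K,
            mixing=comps.mixing,
            ica_params=comps.ica_params,
            variance_explained=ve,
        )
        manifest["stages"]["decompose"] = {
            **comps.ica_params,
            "variance_explained": ve,
            "grey_checksum": _checksum(comps.grey),
        }

    with stage("parcellate"):
        parc = HardParcellation(
            seed_labels=winner_take_all(comps.grey),
            voxel_labels=winner_take_all(comps.white),
        )
        matio.write_component_maps(
            comps,
            geometry,
            out / "components",
            seed_labels=parc.seed_labels,
            voxel_labels=parc.voxel_labels,
        )

    with stage("threshold"):
        rows = []
        masks_grey = np.zeros(comps.grey.shape, dtype=bool)
        masks_white = np.zeros(comps.white.shape, dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in range(comps.K):
                for domain, maps, masks in (
                    ("grey", comps.grey, masks_grey),
                    ("white", comps.white, masks_white),
                ):
                    fit = fit_ggm(
                        maps[:, k],
                        seed=stage_seed(config.master_seed, f"ggm-{domain}-{k}"),
                    )
                    masks[:, k] = threshold_map(fit, maps[:, k], p=config.p_threshold)
                    rows.append(
                        {
                            "component": k,
                            "domain": domain,
                            "pi0": fit.pi0,
                            "mu0": fit.mu0,
                            "sigma0": fit.sigma0,
                            "pi1": fit.pi1,
                            "shape": fit.shape,
                            "scale": fit.scale,
                            "loc": fit.loc,
                            "n_iter": fit.n_iter,
                            "converged": fit.converged,
                            "null_only": fit.null_only,
                        }
                    )
        ggm_report = pd.DataFrame(rows)
        ggm_report.to_csv(out / "ggm_fits.tsv", sep="\t", index=False)
        pd.DataFrame(
            masks_grey.astype(int),
            columns=[f"comp_{k:02d}" for k in range(comps.K)],
        ).to_csv(out / "grey_masks.tsv", sep="\t", index=False)

    with stage("symmetry"):
        sym = symmetry_scores(comps, geometry.seed_mirror)
        pd.DataFrame(
            {
                "component": np.arange(comps.K),
                "best_match": sym.best_match,
                "best_r": sym.best_r,
            }
        ).to_csv(out / "symmetry.tsv", sep="\t", index=False)

    match = None
    if truth is not None:
        with stage("evaluate"):
            match = match_to_truth(comps, truth)
            pd.DataFrame(
                {
                    "component": list(match.pairing.keys()),
                    "truth_component": list(match.pairing.values()),
                    "r_grey": match.paired_r_grey,
                    "r_white": match.paired_r_white,
                }
            ).to_csv(out / "match.tsv", sep="\t", index=False)
            manifest["stages"]["evaluate"] = {
                "mean_abs_r_grey": match.mean_abs_r_grey,
                "mean_abs_r_white": match.mean_abs_r_white,
            }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    marker.unlink()

    return {
        "geometry": geometry,
        "truth": truth,
        "group_matrix": group,
        "reduced": reduced,
        "components": comps,
        "parcellation": parc,
        "ggm_report": ggm_report,
        "symmetry": sym,
        "match": match,
        "manifest": manifest,
    }
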