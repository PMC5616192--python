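"""End-to-end pipeline: simulate -> fit -> maps -> roistats -> histo ->
classify, driven by a single JSON-serialisable configuration and one
global seed.

Per-stage seeds are derived deterministically from the global seed with
``numpy.random.SeedSequence(global_seed).spawn(...)`` so that one integer
reproduces a full study.  Every stage writes its artifacts under the
output directory and the run ends with a manifest recording seeds, stage
status, wall time and file hashes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import RFConfig, metric_subset_trials, rank_rois, rf_classify
from .cohort import CohortSpec, make_feature_cohort
from .datasets import (HISTO_MARKERS, dti_effect_sizes, histo_effect_sizes)
from .dti import metric_maps
from .groupmaps import average_tensors, fa_difference_map, fa_map, render_overlay
from .histo import DEFAULT_THRESHOLD, serial_section_measure
from .io import (file_sha256, save_feature_table, save_json, save_nifti)
from .phantom import (PhantomSpec, build_tensor_phantom, default_injury_effects,
                      make_histo_image, synthesize_dwi)
from .roistats import results_frame, roi_means, table_analysis
from .scheme import make_scheme

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "fit", "maps", "roistats", "histo", "classify")


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


@dataclass
class PipelineConfig:
    """One JSON document describing a full synthetic study."""

    seed: int = 0
    out_dir: str = "tbikit_run"
    # phantom / acquisition
    snr: float = 40.0
    s0: float = 1000.0
    low_shell_dirs: int = 6
    high_shell_dirs: int = 32
    # analysis options
    westin_convention: str = "trace"
    nonlinear_fit: bool = True
    alpha: float = 0.05
    histo_threshold: int = DEFAULT_THRESHOLD
    # cohort
    n_sham: int = 5
    n_injured: int = 5
    # classifier
    n_trees: int = 2000
    n_repeats: int = 10
    # which stages to run
    stages: tuple[str, ...] = _STAGES

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        cfg = cls(**d)
        bad = set(cfg.stages) - set(_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["stages"] = list(d["stages"])
        return d


@dataclass
class _Manifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {"version": self.version, "config": self.config,
                "stage_seeds": self.seeds, "stages": self.stages,
                "files": self.files}


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage 31-bit seeds from one global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1, np.uint32)[0] % (2**31))
            for name, c in zip(_STAGES, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict (also
    written to ``<out_dir>/manifest.json``).  A stage failure is recorded
    in the manifest and aborts the remaining stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = _Manifest(config=config.to_dict(), seeds=seeds)
    state: dict = {}
    for stage in _STAGES:
        if stage not in config.stages:
            manifest.stages[stage] = {"status": "skipped"}
            continue
        t0 = time.perf_counter()
        try:
            _RUNNERS[stage](config, seeds[stage], out, state, manifest)
            manifest.stages[stage] = {"status": "complete",
                                      "seconds": round(time.perf_counter() - t0, 3)}
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            manifest.stages[stage] = {"status": "failed", "error": repr(exc),
                                      "seconds": round(time.perf_counter() - t0, 3)}
            break
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.files[str(p.relative_to(out))] = file_sha256(p)
    save_json(manifest.to_dict(), out / "manifest.json")
    return manifest.to_dict()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                    manifest: _Manifest) -> None:
    scheme = make_scheme(cfg.low_shell_dirs, cfg.high_shell_dirs)
    scheme.save(out / "scheme")
    spec = PhantomSpec(snr=cfg.snr, seed=seed,
                       injury_effects=default_injury_effects())
    sham = build_tensor_phantom(spec, "sham")
    injured = build_tensor_phantom(spec, "injured")
    dwi_sham = synthesize_dwi(sham, scheme, cfg.s0, cfg.snr, seed)
    dwi_injured = synthesize_dwi(injured, scheme, cfg.s0, cfg.snr, seed + 1)
    save_nifti(sham.labels.astype(float), out / "labels.nii.gz", spec.voxel_size)
    save_nifti(dwi_sham, out / "dwi_sham.nii.gz", spec.voxel_size)
    save_nifti(dwi_injured, out / "dwi_injured.nii.gz", spec.voxel_size)
    state.update(scheme=scheme, spec=spec, sham=sham, injured=injured,
                 dwi={"sham": dwi_sham, "injured": dwi_injured})


def _stage_fit(cfg: PipelineConfig, seed: int, out: Path, state: dict,
               manifest: _Manifest) -> None:
    state["maps"] = {}
    for group, dwi in state["dwi"].items():
        maps = metric_maps(dwi, state["scheme"], cfg.westin_convention,
                           nonlinear=cfg.nonlinear_fit)
        state["maps"][group] = maps
        for name in ("FA", "T", "AD", "RD", "WL", "WP"):
            save_nifti(maps[name], out / f"{group}_{name}.nii.gz",
                       state["spec"].voxel_size)
        save_nifti(maps["tensor"], out / f"{group}_tensor.nii.gz",
                   state["spec"].voxel_size)


def _stage_maps(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                manifest: _Manifest) -> None:
    avg_sham = average_tensors([state["maps"]["sham"]["tensor"]])
    avg_injured = average_tensors([state["maps"]["injured"]["tensor"]])
    diff = fa_difference_map(avg_injured, avg_sham)
    save_nifti(diff, out / "fa_difference.nii.gz", state["spec"].voxel_size)
    render_overlay(diff, fa_map(avg_sham), out / "overlays")
    state["fa_diff"] = diff


def _stage_roistats(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                    manifest: _Manifest) -> None:
    # per-ROI means of the fitted maps (descriptive)
    rows = []
    for group, maps in state["maps"].items():
        labels = state[group].labels
        for metric in ("FA", "T", "AD", "RD", "WL", "WP"):
            means = roi_means(maps[metric], labels, state[group].roi_labels)
            rows += [{"group": group, "metric": metric, "roi": r, "mean": v}
                     for r, v in means.items()]
    pd.DataFrame(rows).to_csv(out / "roi_means.csv", index=False)
    # calibrated cohort + family-wise t tests
    spec = CohortSpec.from_effect_frame(dti_effect_sizes(),
                                        n_sham=cfg.n_sham,
                                        n_injured=cfg.n_injured, seed=seed)
    cohort = make_feature_cohort(spec)
    save_feature_table(cohort, out / "dti_cohort.csv")
    frames = [results_frame(table_analysis(cohort, m, alpha=cfg.alpha))
              for m in spec.metrics]
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(out / "roi_ttests.csv", index=False)
    state["dti_cohort"] = cohort
    state["roistats"] = results


def _stage_histo(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                 manifest: _Manifest) -> None:
    # demonstrate the quantification on two serial synthetic sections,
    # then build the marker cohort calibrated from the reference t values
    rng = np.random.default_rng(seed)
    records = []
    for marker in HISTO_MARKERS:
        sections = [(make_histo_image(0.2, (128, 128),
                                      int(rng.integers(2**31))), None)
                    for _ in range(2)]
        m = serial_section_measure(sections, marker, roi="demo",
                                   threshold=cfg.histo_threshold)
        records.append({"roi": m.roi, "marker": m.marker, "value": m.value,
                        "measure": m.measure, "n_sections": m.n_sections})
    pd.DataFrame(records).to_csv(out / "histo_measures.csv", index=False)
    spec = CohortSpec.from_effect_frame(histo_effect_sizes(),
                                        n_sham=cfg.n_sham,
                                        n_injured=cfg.n_injured,
                                        baseline=10.0, sigma=2.0,
                                        seed=seed + 1)
    cohort = make_feature_cohort(spec)
    save_feature_table(cohort, out / "histo_cohort.csv")
    frames = [results_frame(table_analysis(cohort, m, alpha=cfg.alpha))
              for m in spec.metrics]
    pd.concat(frames, ignore_index=True).to_csv(out / "histo_ttests.csv",
                                                index=False)
    state["histo_cohort"] = cohort


def _stage_classify(cfg: PipelineConfig, seed: int, out: Path, state: dict,
                    manifest: _Manifest) -> None:
    rfc = RFConfig(n_trees=cfg.n_trees, seed=seed, n_repeats=cfg.n_repeats)
    report = rf_classify(state["dti_cohort"], config=rfc)
    ranked = rank_rois(report)
    subsets = metric_subset_trials(
        state["dti_cohort"],
        {"FA-T": ("FA", "T"), "AD-RD": ("AD", "RD"),
         "T-WL-WP": ("T", "WL", "WP")},
        config=rfc)
    report.mda.to_csv(out / "rf_importance.csv")
    ranked.to_json(out / "rf_top_rois.json", orient="records", indent=1)
    save_json(
        {
            "full": {"class_error": report.class_error,
                     "overall_error": report.overall_error,
                     "confusion": report.confusion},
            "subsets": {k: {"class_error": r.class_error,
                            "overall_error": r.overall_error}
                        for k, r in subsets.items()},
        },
        out / "rf_report.json",
    )
    state["rf_report"] = report
    state["rf_ranked"] = ranked


_RUNNERS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "maps": _stage_maps,
    "roistats": _stage_roistats,
    "histo": _stage_histo,
    "classify": _stage_classify,
}
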