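"""End-to-end study orchestration.

``run_study`` composes the whole contrast-free infarct-quantification
analysis on a synthetic cohort: phantom simulation, (optionally) MOLLI
T1-map fitting, remote-ROI SD-threshold segmentation on T1 and LGE,
infarct size and transmurality per slice, AHA segment tables, and the
segment-level diagnostic validation (ROC/Youden/DeLong) plus
animal-level agreement (Bland-Altman) and regression blocks.

Inter-observer reproducibility is emulated by re-running the T1
segmentation with a second, rotated remote-ROI placement.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from .aha import contrast_result, partition_segments, segment_table
from .core import ParametricMap
from .molli import fit_t1_map
from .phantom import (
    Cohort,
    CohortVariation,
    TissueStats,
    make_cohort,
    make_molli_series,
)
from .segment import infarct_size, remote_roi_mask, remote_stats, threshold_mask
from .stats import (
    bland_altman,
    delong_compare,
    linear_regression,
    roc_curve,
    youden_optimal_cutoff,
)
from .transmurality import transmural_extent

__all__ = ["RunConfig", "StudyReport", "run_study", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one synthetic validation study.

    Defaults reproduce the reference analysis choices: k = 3 SD
    threshold on T1 maps, k = 5 on LGE, 10 transmural radii, a
    10-animal cohort of basal/mid/apical slices at 1.4 mm spacing with
    the 2-week swine tissue statistics.
    """

    seed: int = 0
    n_animals: int = 10
    tissue: TissueStats = field(default_factory=TissueStats)
    variation: CohortVariation = field(default_factory=CohortVariation)
    pixel_spacing: float = 1.4
    noise_scale: float = 1.0
    k_t1: float = 3.0
    k_lge: float = 5.0
    n_radii: int = 10
    t1_cutoff: Optional[float] = None
    roi_half_width_deg: float = 30.0
    observer2_rotation_deg: float = 25.0
    fit_molli: bool = False
    molli_noise_sd: float = 0.0
    save_images: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("tissue"), dict):
            d["tissue"] = TissueStats(**d["tissue"])
        if isinstance(d.get("variation"), dict):
            d["variation"] = CohortVariation(**d["variation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class StudyReport:
    """All study outputs: per-slice and per-segment tables, the
    per-animal contrast table, and the performance/agreement/regression
    summary blocks."""

    config: RunConfig
    slice_table: pd.DataFrame
    segment_table: pd.DataFrame
    contrast_table: pd.DataFrame
    performance: dict
    agreement: dict
    regression: dict
    cohort: Optional[Cohort] = None

    def summary(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "performance": self.performance,
            "agreement": self.agreement,
            "regression": self.regression,
        }


def _tm_pct(mask, geometry, n_radii):
    res = transmural_extent(mask, geometry, n_radii=n_radii)
    return res.extent_pct if res.defined else float("nan")


def _analyze_slice(ph, animal, level, cfg: RunConfig, manifest_row) -> tuple[dict, pd.DataFrame]:
    geom = ph.geometry
    infarct_angle = float(manifest_row["center_angle_deg"])
    remote_angle = (infarct_angle + 180.0) % 360.0

    if cfg.fit_molli:
        series = make_molli_series(ph, noise_sd=cfg.molli_noise_sd)
        t1_map = fit_t1_map(series, myo_mask=ph.myo_mask)
    else:
        t1_map = ph.t1_map

    roi = remote_roi_mask(geom, remote_angle, cfg.roi_half_width_deg)
    t1_stats = remote_stats(t1_map, roi, myo_mask=ph.myo_mask)
    lge_stats = remote_stats(ph.lge_image, roi, myo_mask=ph.myo_mask)

    t1_mask = threshold_mask(t1_map, ph.myo_mask, t1_stats, cfg.k_t1)
    lge_mask = threshold_mask(ph.lge_image, ph.myo_mask, lge_stats, cfg.k_lge)

    spacing = geom.pixel_spacing
    size_t1 = infarct_size(t1_mask, ph.myo_mask, spacing, t1_stats.threshold(cfg.k_t1), cfg.k_t1)
    size_lge = infarct_size(lge_mask, ph.myo_mask, spacing, lge_stats.threshold(cfg.k_lge), cfg.k_lge)
    size_gt = infarct_size(ph.gt_infarct_mask, ph.myo_mask, spacing)

    # observer 2: same criteria, remote ROI rotated by a fixed offset
    roi2 = remote_roi_mask(geom, (remote_angle + cfg.observer2_rotation_deg) % 360.0,
                           cfg.roi_half_width_deg)
    t1_stats2 = remote_stats(t1_map, roi2, myo_mask=ph.myo_mask)
    t1_mask2 = threshold_mask(t1_map, ph.myo_mask, t1_stats2, cfg.k_t1)
    size_t1_obs2 = infarct_size(t1_mask2, ph.myo_mask, spacing,
                                t1_stats2.threshold(cfg.k_t1), cfg.k_t1)

    row = {
        "animal_id": animal,
        "level": level,
        "gt_size_pct": ph.gt_size_pct,
        "gt_transmurality_analytic_pct": ph.gt_transmurality_pct,
        "t1_size_pct": size_t1.pct_of_slice_myocardium,
        "lge_size_pct": size_lge.pct_of_slice_myocardium,
        "ttc_size_pct": size_gt.pct_of_slice_myocardium,
        "t1_area_mm2": size_t1.area_mm2,
        "lge_area_mm2": size_lge.area_mm2,
        "ttc_area_mm2": size_gt.area_mm2,
        "t1_threshold": size_t1.threshold_used,
        "lge_threshold": size_lge.threshold_used,
        "remote_t1_mean": t1_stats.mean,
        "remote_t1_sd": t1_stats.sd,
        "remote_lge_mean": lge_stats.mean,
        "remote_lge_sd": lge_stats.sd,
        "t1_transmurality_pct": _tm_pct(t1_mask, geom, cfg.n_radii),
        "lge_transmurality_pct": _tm_pct(lge_mask, geom, cfg.n_radii),
        "ttc_transmurality_pct": _tm_pct(ph.gt_infarct_mask, geom, cfg.n_radii),
        "t1_size_pct_obs2": size_t1_obs2.pct_of_slice_myocardium,
        "t1_transmurality_pct_obs2": _tm_pct(t1_mask2, geom, cfg.n_radii),
    }

    labels = partition_segments(geom, ph.myo_mask, level)
    seg = segment_table(
        t1_map,
        lge_mask,
        ph.gt_infarct_mask,
        labels,
        t1_cutoff=cfg.t1_cutoff,
        animal_id=animal,
        slice_level=level,
    )
    artifacts = {
        "t1_map": t1_map,
        "t1_mask": t1_mask,
        "lge_mask": lge_mask,
        "labels": labels,
    }
    return row, seg, artifacts


def run_study(config: RunConfig, out_dir: Optional[str] = None) -> StudyReport:
    """Run the complete synthetic validation study.

    Deterministic given ``config.seed``; when ``out_dir`` is given, all
    intermediates (maps, masks, tables) and the summary report are
    written there.
    """
    cfg = config
    cohort = make_cohort(
        n_animals=cfg.n_animals,
        variation=cfg.variation,
        tissue=cfg.tissue,
        seed=cfg.seed,
        pixel_spacing=cfg.pixel_spacing,
        noise_scale=cfg.noise_scale,
    )
    manifest = cohort.manifest.set_index(["animal_id", "level"])

    slice_rows = []
    seg_tables = []
    artifacts = {}
    for (animal, level), ph in cohort.slices():
        try:
            row, seg, art = _analyze_slice(ph, animal, level, cfg, manifest.loc[(animal, level)])
        except Exception as e:  # noqa: BLE001 - re-raise with slice context
            raise RuntimeError(
                f"slice analysis failed for animal {animal}, {level} slice: {e}"
            ) from e
        slice_rows.append(row)
        seg_tables.append(seg)
        artifacts[(animal, level)] = art
    slice_table = pd.DataFrame(slice_rows)
    seg_all = pd.concat(seg_tables, ignore_index=True)

    # ---- segment-level diagnostic performance ----
    usable = seg_all[~seg_all["excluded"]].reset_index(drop=True)
    scores_t1 = usable["mean_t1"].to_numpy(float)
    scores_lge = usable["lge_positive"].to_numpy(float)
    labels = usable["reference_positive"].to_numpy(bool)
    performance: dict = {"n_segments": int(len(usable)),
                         "n_reference_positive": int(labels.sum())}
    if labels.any() and not labels.all():
        roc_t1 = roc_curve(scores_t1, labels)
        roc_lge = roc_curve(scores_lge, labels)
        cutoff, perf_at = youden_optimal_cutoff(scores_t1, labels)
        dl = delong_compare(scores_t1, scores_lge, labels)
        performance.update(
            {
                "auc_t1": roc_t1.auc,
                "auc_t1_se": roc_t1.auc_se,
                "auc_lge": roc_lge.auc,
                "auc_lge_se": roc_lge.auc_se,
                "youden_cutoff_ms": cutoff,
                "youden_j": perf_at.youden_j,
                "t1_sensitivity_pct": perf_at.sensitivity,
                "t1_specificity_pct": perf_at.specificity,
                "delong_z": dl.z,
                "delong_p": dl.p,
            }
        )

    # ---- animal-level agreement and regression (infarcted slices only) ----
    infarcted = slice_table[slice_table["gt_size_pct"] > 0]
    per_animal = infarcted.groupby("animal_id")[
        ["t1_size_pct", "lge_size_pct", "ttc_size_pct",
         "t1_transmurality_pct", "lge_transmurality_pct", "ttc_transmurality_pct"]
    ].mean()
    agreement: dict = {}
    regression: dict = {}
    if len(per_animal) >= 2:
        for key, (col_a, col_b) in {
            "size_t1_vs_lge": ("lge_size_pct", "t1_size_pct"),
            "size_t1_vs_ttc": ("ttc_size_pct", "t1_size_pct"),
            "tm_t1_vs_lge": ("lge_transmurality_pct", "t1_transmurality_pct"),
            "tm_t1_vs_ttc": ("ttc_transmurality_pct", "t1_transmurality_pct"),
        }.items():
            ba = bland_altman(per_animal[col_a], per_animal[col_b])
            agreement[key] = dataclasses.asdict(ba)
            if len(per_animal) >= 3 and np.var(per_animal[col_a].to_numpy()) > 0:
                reg = linear_regression(per_animal[col_a], per_animal[col_b])
                regression[key] = dataclasses.asdict(reg)
    # inter-observer reproducibility on per-slice T1 measurements
    if len(infarcted) >= 2:
        agreement["interobserver_size"] = dataclasses.asdict(
            bland_altman(infarcted["t1_size_pct"], infarcted["t1_size_pct_obs2"])
        )
        tm_pairs = infarcted[["t1_transmurality_pct", "t1_transmurality_pct_obs2"]].dropna()
        if len(tm_pairs) >= 2:
            agreement["interobserver_transmurality"] = dataclasses.asdict(
                bland_altman(tm_pairs["t1_transmurality_pct"],
                             tm_pairs["t1_transmurality_pct_obs2"])
            )

    # ---- per-animal tissue contrast (infarct vs remote) ----
    contrast_rows = []
    for animal in sorted(set(slice_table["animal_id"])):
        t1_inf, t1_rem, lge_inf, lge_rem = [], [], [], []
        for (a, level), ph in cohort.slices():
            if a != animal:
                continue
            art = artifacts[(a, level)]
            roi = remote_stats(
                art["t1_map"],
                remote_roi_mask(
                    ph.geometry,
                    (float(manifest.loc[(a, level)]["center_angle_deg"]) + 180.0) % 360.0,
                    cfg.roi_half_width_deg,
                ),
            )
            if ph.gt_infarct_mask.any():
                t1_inf.append(art["t1_map"].values[ph.gt_infarct_mask])
                lge_inf.append(ph.lge_image.values[ph.gt_infarct_mask])
            t1_rem.append(art["t1_map"].values[roi.roi_mask])
            lge_rem.append(ph.lge_image.values[roi.roi_mask])
        if not t1_inf:
            continue
        t1c = contrast_result(np.concatenate(t1_inf).mean(), np.concatenate(t1_rem).mean())
        lgec = contrast_result(np.concatenate(lge_inf).mean(), np.concatenate(lge_rem).mean())
        contrast_rows.append(
            {
                "animal_id": animal,
                "t1_infarct_mean": t1c.infarct_mean,
                "t1_remote_mean": t1c.remote_mean,
                "t1_normalized_difference": t1c.normalized_difference,
                "lge_infarct_mean": lgec.infarct_mean,
                "lge_remote_mean": lgec.remote_mean,
                "lge_normalized_difference": lgec.normalized_difference,
            }
        )
    contrast_table = pd.DataFrame(contrast_rows)

    report = StudyReport(
        config=cfg,
        slice_table=slice_table,
        segment_table=seg_all,
        contrast_table=contrast_table,
        performance=performance,
        agreement=agreement,
        regression=regression,
        cohort=cohort,
    )
    if out_dir is not None:
        write_report(report, out_dir, artifacts)
    return report


def write_report(report: StudyReport, out_dir, artifacts: Optional[dict] = None) -> None:
    """Write all report tables, the JSON summary, the serialized config
    and (when artifacts are available and configured) the per-slice
    NIfTI maps and masks. Output is byte-deterministic for a fixed
    config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iomod.write_table(report.slice_table, out / "slice_table.csv")
    iomod.write_table(report.segment_table, out / "segment_table.csv")
    iomod.write_table(report.contrast_table, out / "contrast_table.csv")
    iomod.write_json(report.summary(), out / "report.json")
    (out / "config.yaml").write_text(yaml.safe_dump(report.config.to_dict(), sort_keys=True))
    (out / "run.log").write_text(
        f"config_hash={report.config.config_hash()}\n"
        f"n_slices={len(report.slice_table)}\n"
        f"n_segments={len(report.segment_table)}\n"
    )
    if artifacts and report.config.save_images and report.cohort is not None:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for (animal, level), ph in report.cohort.slices():
            art = artifacts[(animal, level)]
            stem = f"a{animal:02d}_{level}"
            sp = ph.geometry.pixel_spacing
            iomod.write_map(art["t1_map"], img_dir / f"{stem}_t1.nii")
            iomod.write_map(ph.lge_image, img_dir / f"{stem}_lge.nii")
            iomod.write_mask(ph.myo_mask, sp, img_dir / f"{stem}_myo.nii")
            iomod.write_mask(ph.gt_infarct_mask, sp, img_dir / f"{stem}_gt.nii")
            iomod.write_mask(art["t1_mask"], sp, img_dir / f"{stem}_t1seg.nii")
            iomod.write_mask(art["lge_mask"], sp, img_dir / f"{stem}_lgeseg.nii")
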