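"""End-to-end analysis pipeline: image -> phases -> cells + voids -> summary.

The stages mirror the standard cortex-tissue protocol: crop, global Otsu
segmentation, speckle filtering, then two parallel tracks — watershed
cell isolation with border removal and the virtual sieve, and void
labelling with edge-corrected counting, skeletonization, anisotropy and
fragmentation — merged into a single TissueSummary with full provenance
(every threshold and seed used).  Identical config in, identical summary
out.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from parenchyma3d import cells as cells_mod
from parenchyma3d import diffusivity as diff_mod
from parenchyma3d import phantom as phantom_mod
from parenchyma3d import segmentation as seg_mod
from parenchyma3d import skeleton as skel_mod
from parenchyma3d import voids as voids_mod
from parenchyma3d.image_io import PhaseMasks, VoxelImage, crop_margins, read_stack, write_mask

__all__ = ["DEFAULT_CONFIG", "run_analyze"]

log = logging.getLogger(__name__)

_pkg_version = "0.1.0"

DEFAULT_CONFIG: dict = {
    "input": {"path": None, "pitch_um": 5.14, "phantom": None},
    "crop": {"lateral_um": 0.0, "axial_um": 0.0},
    "threshold": {"method": "otsu", "value": None, "voids_dark": True},
    "noise": {"min_voxels": 51, "connectivity": 26, "apply_to_cells": True},
    "cells": {
        "h_min_um": 10.0,
        "sieve": {"enabled": True, "max_length_um": 400.0, "min_sphericity": 0.75},
    },
    "voids": {
        "connectivity": 26,
        "mil": {"enabled": True, "n_directions": 128, "seed": 0},
        "fi": {"enabled": True},
    },
    "skeleton": {"enabled": True, "prune_spurs_below_vox": 2},
    "diffusivity": {"enabled": False, "tau": None, "w": None, "D_measured": None},
    "output": {"dir": None},
}


def _merge(default: dict, override: dict | None) -> dict:
    out = {}
    for k, v in default.items():
        if isinstance(v, dict):
            out[k] = _merge(v, (override or {}).get(k))
        else:
            out[k] = (override or {}).get(k, v)
    # keep unknown keys so configs can carry annotations
    for k, v in (override or {}).items():
        if k not in out:
            out[k] = v
    return out


def _load_input(cfg: dict) -> tuple[VoxelImage, PhaseMasks | None]:
    inp = cfg["input"]
    if inp.get("phantom"):
        ph = dict(inp["phantom"])
        img, masks, _truth = phantom_mod.generate_tissue(**ph)
        return img, None
    if not inp.get("path"):
        raise ValueError("config must set input.path or input.phantom")
    return read_stack(inp["path"], pitch_um=inp["pitch_um"]), None


def _panel(series: pd.Series) -> dict:
    vals = series.to_numpy(float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0}
    return {
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        "n": int(len(vals)),
    }


def run_analyze(config: dict | None = None, output_dir: str | None = None) -> voids_mod.TissueSummary:
    """Run the full tissue-analysis pipeline from a config dictionary.

    Unspecified keys fall back to DEFAULT_CONFIG.  If ``output_dir`` (or
    config output.dir) is set, masks, per-object CSV tables and the
    summary JSON are written there.  All parameters and seeds are echoed
    into the summary provenance so any number is reproducible from the
    config alone.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out_dir = output_dir or cfg["output"]["dir"]
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        img, _ = _load_input(cfg)

        stage = "crop"
        crop = cfg["crop"]
        if crop["lateral_um"] or crop["axial_um"]:
            img = crop_margins(img, crop["lateral_um"], crop["axial_um"])

        stage = "threshold"
        th = cfg["threshold"]
        if th["method"] == "otsu":
            masks = seg_mod.otsu_threshold(img, voids_dark=th["voids_dark"])
        elif th["method"] == "manual":
            if th["value"] is None:
                raise ValueError("threshold.method=manual requires threshold.value")
            dark = img.data <= th["value"]
            voids = dark if th["voids_dark"] else ~dark
            masks = PhaseMasks(cells=~voids, voids=voids, pitch_um=img.pitch_um)
        else:
            raise ValueError(f"unknown threshold method {th['method']!r}")

        stage = "noise"
        noise = cfg["noise"]
        voids_clean = seg_mod.remove_small_components(
            masks.voids, noise["min_voxels"], noise["connectivity"]
        )
        cells_mask = ~voids_clean
        if noise["apply_to_cells"]:
            cells_clean = seg_mod.remove_small_components(
                cells_mask, noise["min_voxels"], noise["connectivity"]
            )
            # voxels dropped from the cell phase rejoin the voids so the
            # two phases keep partitioning the domain
            voids_clean = ~cells_clean
            cells_mask = cells_clean
        masks = PhaseMasks(
            cells=cells_mask, voids=voids_clean, pitch_um=img.pitch_um, name=img.name
        )
        masks.validate()

        domain_volume_mm3 = masks.voids.size * masks.voxel_volume_mm3
        poro = voids_mod.porosity(masks)

        # ---- cell track -------------------------------------------------
        stage = "cells.watershed"
        labels = cells_mod.watershed_separate(
            masks.cells, img.pitch_um, cfg["cells"]["h_min_um"]
        )
        stage = "cells.border"
        labels, removed_frac = cells_mod.remove_border_labels(labels)
        stage = "cells.morphometrics"
        cell_table = cells_mod.cell_morphometrics(labels, masks.voids, img.pitch_um)
        sieve_cfg = cfg["cells"]["sieve"]
        rejection = pd.DataFrame()
        if sieve_cfg["enabled"]:
            stage = "cells.sieve"
            labels, rejection = cells_mod.virtual_sieve(
                labels,
                img.pitch_um,
                max_length_um=sieve_cfg["max_length_um"],
                min_sphericity=sieve_cfg["min_sphericity"],
                table=cell_table,
            )
            cell_table = cell_table[~cell_table["label"].isin(rejection["label"])]

        # ---- void track -------------------------------------------------
        stage = "voids.label"
        void_labels = voids_mod.label_voids(masks.voids, cfg["voids"]["connectivity"])
        stage = "voids.morphometrics"
        void_table = voids_mod.void_morphometrics(void_labels, img.pitch_um)
        interior = void_table[~void_table["touches_border"]]
        weighted_count = (
            voids_mod.weighted_void_count_per_mm3(void_table, domain_volume_mm3)
            if len(interior)
            else float("nan")
        )
        border_void_frac = (
            float(
                void_table.loc[void_table["touches_border"], "volume_mm3"].sum()
                / void_table["volume_mm3"].sum()
            )
            if len(void_table)
            else float("nan")
        )

        anis = float("nan")
        if cfg["voids"]["mil"]["enabled"] and masks.voids.any():
            stage = "voids.mil"
            anis, _ = voids_mod.mil_anisotropy(
                masks.voids,
                img.pitch_um,
                n_directions=cfg["voids"]["mil"]["n_directions"],
                seed=cfg["voids"]["mil"]["seed"],
            )
        fi = float("nan")
        if cfg["voids"]["fi"]["enabled"] and masks.voids.any():
            stage = "voids.fi"
            fi = voids_mod.fragmentation_index(masks.voids, img.pitch_um)

        net = {}
        if cfg["skeleton"]["enabled"] and masks.voids.any():
            stage = "skeleton"
            center = skel_mod.skeletonize(masks.voids, img.pitch_um)
            graph = skel_mod.build_graph(
                center,
                masks.voids,
                img.pitch_um,
                prune_spurs_below_vox=cfg["skeleton"]["prune_spurs_below_vox"],
            )
            net = skel_mod.network_summary(graph, domain_volume_mm3)

        diffu = None
        dcfg = cfg["diffusivity"]
        if dcfg["enabled"]:
            stage = "diffusivity"
            tau = dcfg["tau"]
            if tau is None:
                # the mean interior void shape factor is a fair tortuosity
                # proxy; fall back to all voids when every void touches a
                # border (small samples of well-connected networks)
                pool = interior if len(interior) else void_table
                tau = float(pool["shape_factor"].mean())
            c = diff_mod.GasConstants()
            if dcfg.get("D_measured") is not None:
                w = diff_mod.estimate_w(dcfg["D_measured"], poro, tau, c)
            else:
                w = dcfg["w"] if dcfg["w"] is not None else 1.0
            diffu = diff_mod.combined_model(poro, tau, w, c).__dict__

        stage = "summary"
        cell_panel = {
            k: _panel(cell_table[k])
            for k in ("volume_mm3", "surface_mm2", "esd_um", "elongation",
                      "sphericity", "cell_to_void_area_fraction")
        }
        void_panel = {
            k: _panel(interior[k])
            for k in ("volume_mm3", "surface_mm2", "esd_um", "elongation", "shape_factor")
        }
        summary = voids_mod.TissueSummary(
            porosity_fraction=poro,
            cell_panel=cell_panel,
            void_panel=void_panel,
            weighted_void_count_per_mm3=weighted_count,
            branch_count_per_mm3=net.get("branch_count_per_mm3", float("nan")),
            total_path_length_mm_per_mm3=net.get(
                "total_path_length_mm_per_mm3", float("nan")
            ),
            mean_path_per_void_mm=net.get("mean_path_per_void_mm", float("nan")),
            anisotropy=anis,
            fragmentation_index_per_mm=fi,
            border_void_volume_fraction=border_void_frac,
            diffusivity=diffu,
            provenance={
                "config": cfg,
                "version": _pkg_version,
                "domain_volume_mm3": domain_volume_mm3,
                "cell_border_removed_volume_fraction": removed_frac,
                "n_cells_kept": int(len(cell_table)),
                "n_cells_rejected": int(len(rejection)),
                "n_voids": int(len(void_table)),
                "n_voids_interior": int(len(interior)),
            },
        )

        if out_dir:
            stage = "output"
            cell_table.to_csv(out_dir / "cells.csv", index=False)
            void_table.to_csv(out_dir / "voids.csv", index=False)
            if len(rejection):
                rejection.to_csv(out_dir / "cell_rejections.csv", index=False)
            write_mask(out_dir / "voids_mask.tif", masks.voids)
            np_labels = labels.astype(np.int32)
            import tifffile

            tifffile.imwrite(out_dir / "cell_labels.tif", np_labels)
            with open(out_dir / "summary.json", "w") as fh:
                json.dump(summary.to_dict(), fh, indent=2, default=_json_default)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
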