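"""Orchestration: run every analysis over a cohort manifest and render outputs.

``run_all`` makes a single streaming pass over the cohort collecting compact
per-eye summaries (en-face presence maps and per-B-scan voxel counts), then
emits per biomarker: prevalence counts, the population heatmap with its
Gaussian fit, the FOV-crop sensitivity map, and the ISD sensitivity /
volume / MAPE tables. Everything numeric lands in one machine-readable
``summary.json`` (deterministic for fixed manifest + config); figures are
side effects rendered from the summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import enface, fov, heatmap_fit, isd
from .errors import ValidationError
from .volume_io import (
    Biomarker,
    CohortManifest,
    FLUID_BIOMARKERS,
    as_biomarker,
    load_cohort,
    read_manifest,
)

__all__ = ["RunConfig", "run_all", "render_figures"]

logger = logging.getLogger("octscan")

_DEFAULT_BIOMARKERS = (
    Biomarker.IRF,
    Biomarker.SRF,
    Biomarker.IRF_SRF,
    Biomarker.PED,
    Biomarker.RETINA,
)


@dataclass
class RunConfig:
    manifest: Path
    out_dir: Path
    biomarkers: Sequence["Biomarker | str"] = _DEFAULT_BIOMARKERS
    fov_step_um: float = 250.0
    isd_factors: Sequence[int] = isd.DEFAULT_FACTORS
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        self.biomarkers = tuple(as_biomarker(b) for b in self.biomarkers)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_all(config: RunConfig) -> dict:
    """Execute all four analyses; write summary.json, tables and arrays to out_dir."""
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    manifest = read_manifest(config.manifest)
    base_dir = config.manifest.parent
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    fluids = [b for b in config.biomarkers if b in FLUID_BIOMARKERS]
    bms = list(config.biomarkers)

    maps: dict[Biomarker, list] = {b: [] for b in bms}
    geometry = None
    for v in load_cohort(manifest, base_dir):
        if geometry is None:
            geometry = v.geometry
        elif v.geometry != geometry:
            raise ValidationError(
                f"heterogeneous cohort geometry at eye {v.eye_id}: "
                f"{v.geometry} != {geometry}"
            )
        vn = enface.mirror_if_left(v)
        for b in bms:
            maps[b].append(enface.binarize(enface.project(vn, b)))
    if geometry is None:
        raise ValidationError("manifest lists no eyes")
    n_eyes = len(manifest.entries)
    logger.info("projected %d eyes in %.1fs", n_eyes, time.time() - t0)

    summary: dict = {
        "n_eyes": n_eyes,
        "geometry": geometry.to_dict(),
        "provenance": manifest.provenance,
        "seed": manifest.seed,
        "biomarkers": [b.value for b in bms],
        "prevalence": {},
        "heatmap": {},
        "fov": {},
        "isd": {},
    }

    # prevalence (fraction of eyes with any presence in the full FOV)
    for b in bms:
        n_pos = sum(1 for m in maps[b] if m.presence.any())
        summary["prevalence"][b.value] = {
            "n_positive": n_pos,
            "fraction": n_pos / n_eyes,
        }

    # population heatmaps + Gaussian fits (fluid biomarkers)
    t = time.time()
    for b in fluids:
        h = heatmap_fit.aggregate(maps[b])
        np.save(out / f"heatmap_{b.value}.npy", h.fraction)
        if not np.any(h.fraction > 0):
            summary["heatmap"][b.value] = {"status": "n/a", "n_positive": 0}
            continue
        fit = heatmap_fit.fit_gaussian(h)
        summary["heatmap"][b.value] = {
            "status": "ok",
            "max_fraction": float(h.fraction.max()),
            "fit": fit.to_dict(),
            "array": f"heatmap_{b.value}.npy",
        }
    logger.info("heatmap fits in %.1fs", time.time() - t)

    # FOV crop sensitivity
    t = time.time()
    for b in fluids:
        if not any(m.presence.any() for m in maps[b]):
            summary["fov"][b.value] = {"status": "n/a", "n_positive": 0}
            continue
        smap = fov.sensitivity_map(maps[b], step_um=config.fov_step_um)
        pd.DataFrame(
            smap.sensitivity,
            index=smap.sizes_y_um.astype(int),
            columns=smap.sizes_x_um.astype(int),
        ).to_csv(out / f"fov_sensitivity_{b.value}.csv")
        summary["fov"][b.value] = {
            "status": "ok",
            "n_positive": smap.n_positive_reference,
            "step_um": smap.step_um,
            "sensitivity": smap.sensitivity.tolist(),
            "sizes_x_um": smap.sizes_x_um.tolist(),
            "sizes_y_um": smap.sizes_y_um.tolist(),
            "exemplary": fov.exemplary_sensitivities(smap),
        }
    logger.info("fov maps in %.1fs", time.time() - t)

    # ISD analysis from per-B-scan counts: re-derive counts from stored maps is
    # not possible (maps are depth-collapsed), so make a second streaming pass
    t = time.time()
    result = isd.isd_analysis(
        (enface.mirror_if_left(v) for v in load_cohort(manifest, base_dir)),
        biomarkers=bms,
        factors=config.isd_factors,
    )
    result.volumes.to_csv(out / "isd_volumes.csv", index=False)
    mape_out = result.mape_table.rename(
        columns=lambda c: c, index=lambda i: int(i)
    )
    mape_out.to_csv(out / "isd_mape.csv", na_rep="n/a")
    summary["isd"] = {
        "factors": list(result.factors),
        "sensitivity": {
            b.value: {str(f): s for f, s in by_f.items()}
            for b, by_f in result.sensitivity.items()
        },
        "n_positive": {b.value: n for b, n in result.n_positive.items()},
        "mape_percent": {
            b: {str(int(i)): (None if pd.isna(v) else float(v)) for i, v in col.items()}
            for b, col in result.mape_table.to_dict().items()
        },
        "n_excluded": {
            b.value: {str(f): n for f, n in by_f.items()}
            for b, by_f in result.n_excluded.items()
        },
    }
    logger.info("isd analysis in %.1fs", time.time() - t)

    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(_round_floats(summary), indent=2, sort_keys=True) + "\n"
    )
    logger.info("summary written to %s (total %.1fs)", summary_path, time.time() - t0)
    return summary


def _etdrs_overlay(ax, geometry_dict: dict) -> None:
    import matplotlib.patches as patches

    cx = geometry_dict["fov_x_um"] / 2.0
    cy = geometry_dict["fov_y_um"] / 2.0
    for d_mm in (1, 3, 6):
        ax.add_patch(
            patches.Circle(
                (cx, cy), d_mm * 1000 / 2.0, fill=False, color="white", lw=0.8
            )
        )


def render_figures(summary: dict, out_dir: "Path | str") -> list[Path]:
    """Render heatmap, FOV-map and ISD figures from a run_all summary.

    Rendering failures are logged and skipped — numeric outputs are the
    contract, figures are a convenience.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    g = summary["geometry"]

    for b, sec in summary.get("heatmap", {}).items():
        if sec.get("status") != "ok":
            logger.info("skipping heatmap figure for %s (n/a)", b)
            continue
        try:
            arr = np.load(out / sec["array"]) if (out / sec["array"]).exists() else None
            if arr is None:
                continue
            fig, ax = plt.subplots(figsize=(5, 5))
            # per-biomarker color scale spanning [0, max fraction]
            im = ax.imshow(
                arr,
                origin="lower",
                extent=(0, g["fov_x_um"], 0, g["fov_y_um"]),
                vmin=0.0,
                vmax=max(sec.get("max_fraction", 1.0), 1e-9),
                cmap="viridis",
            )
            _etdrs_overlay(ax, g)
            ax.set_xlabel("x (µm, nasal →)")
            ax.set_ylabel("y (µm)")
            ax.set_title(f"{b} heatmap (n={summary['n_eyes']})")
            fig.colorbar(im, ax=ax, label="fraction of eyes")
            p = out / f"heatmap_{b}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        except Exception as exc:  # pragma: no cover - non-fatal by contract
            logger.warning("heatmap figure for %s failed: %s", b, exc)

    for b, sec in summary.get("fov", {}).items():
        if sec.get("status") != "ok":
            continue
        try:
            arr = np.array(sec["sensitivity"])
            sx = np.array(sec["sizes_x_um"])
            sy = np.array(sec["sizes_y_um"])
            fig, ax = plt.subplots(figsize=(5.5, 5))
            im = ax.imshow(
                arr,
                origin="lower",
                extent=(sx[0] - sec["step_um"] / 2, sx[-1] + sec["step_um"] / 2,
                        sy[0] - sec["step_um"] / 2, sy[-1] + sec["step_um"] / 2),
                vmin=0,
                vmax=1,
                cmap="viridis",
            )
            for mm in (3000, 2000, 1000):
                ax.plot(mm, mm, marker="s", ms=10, mfc="none", mec="red", mew=1.5)
            ax.set_xlabel("crop width x (µm)")
            ax.set_ylabel("crop width y (µm)")
            ax.set_title(f"{b} detection sensitivity vs crop size")
            fig.colorbar(im, ax=ax, label="sensitivity")
            p = out / f"fov_{b}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        except Exception as exc:  # pragma: no cover
            logger.warning("fov figure for %s failed: %s", b, exc)

    isd_sec = summary.get("isd", {})
    vol_csv = out / "isd_volumes.csv"
    if isd_sec and vol_csv.exists():
        try:
            vols = pd.read_csv(vol_csv)
            for b, sens in isd_sec.get("sensitivity", {}).items():
                sub = vols[vols["biomarker"] == b]
                if sub.empty or all(v is None for v in sens.values()):
                    continue
                ref = sub[sub["factor"] == 1].set_index("eye_id")["volume_um3"]
                pos = ref[ref > 0].index
                if len(pos) == 0:
                    continue
                fig, ax = plt.subplots(figsize=(5.5, 4))
                factors = sorted(int(f) for f in sens)
                rel = [
                    (
                        sub[(sub["factor"] == f) & sub["eye_id"].isin(pos)]
                        .set_index("eye_id")["volume_um3"]
                        / ref.loc[pos]
                    ).values
                    for f in factors
                ]
                ax.boxplot(
                    rel,
                    tick_labels=[str(sub[sub["factor"] == f]["effective_isd_um"].iloc[0])
                                 for f in factors],
                    medianprops={"color": "red"},
                    flierprops={"marker": ".", "markerfacecolor": "grey"},
                )
                ax2 = ax.twinx()
                ax2.plot(
                    range(1, len(factors) + 1),
                    [sens[str(f)] for f in factors],
                    "k-o",
                    label="sensitivity",
                )
                ax2.set_ylim(0, 1.05)
                ax2.set_ylabel("sensitivity")
                ax.set_xlabel("effective ISD (µm)")
                ax.set_ylabel("relative volume")
                ax.set_title(f"{b}: ISD vs sensitivity and relative volume")
                p = out / f"isd_{b}.png"
                fig.savefig(p, dpi=120)
                plt.close(fig)
                written.append(p)
        except Exception as exc:  # pragma: no cover
            logger.warning("isd figures failed: %s", exc)

    return written
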