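"""Validated run configuration and the umbrella pipeline.

A :class:`RunConfig` describes one reproducible run: which stages to
execute, every numeric parameter they need, and a single top-level seed
from which all stage seeds are derived.  :func:`run_pipeline` executes the
requested stages in order, writes each stage's outputs under the run
directory, and records a manifest (parameters, seed, package version,
per-stage status and output files).  A failing stage halts everything
downstream but completed outputs are kept.
"""

from __future__ import annotations

import json
import traceback
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import __version__
from .errors import ConfigError
from . import phantom as ph
from .io import write_sidecar, write_stack
from .morphometrics import growth_curve
from .penetration import estimate_penetration
from .profiling import profile_zstack
from .response import cytotoxicity_index, relative_viability

__all__ = ["SimulateConfig", "RunConfig", "run_pipeline"]

STAGES = ("simulate", "morpho", "profile", "penetration", "response")


class SimulateConfig(BaseModel):
    kind: Literal["section", "growth", "zstack"] = "zstack"
    radius_um: float = Field(250.0, gt=0)
    marker: str = "nanocarrier"
    f_pen: float = Field(1.0, ge=0.0, le=1.0)
    modality: Literal["clsm", "lsfm", "ideal"] = "lsfm"
    growth_model: Literal["constant", "linear", "logistic"] = "linear"
    d0_um: float = Field(500.0, gt=0)
    d_final_um: float = Field(1000.0, gt=0)
    duration_d: float = Field(10.0, gt=0)
    sampling_interval_d: float = Field(1.0, gt=0)


class RunConfig(BaseModel):
    """Everything needed to reproduce a run, bar the input images."""

    out_dir: str
    seed: int = 0
    stages: list[str] = Field(default_factory=lambda: list(STAGES[:4]))
    pixel_size_um: float = Field(4.0, gt=0)
    channel_map: dict[str, int] = Field(
        default_factory=lambda: {"nuclear": 0, "nanocarrier": 1}
    )
    n_segments: int = Field(12, ge=4)
    n_bins: int = Field(100, ge=10)
    smooth_window: int = Field(5, ge=1)
    penetration_threshold: float = Field(0.5, gt=0.0, le=1.0)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    plate_csv: str | None = None

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: list[str]) -> list[str]:
        unknown = [s for s in v if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        return v

    @field_validator("smooth_window")
    @classmethod
    def _odd_window(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("smooth_window must be odd")
        return v

    @field_validator("channel_map")
    @classmethod
    def _injective(cls, v: dict[str, int]) -> dict[str, int]:
        if len(set(v.values())) != len(v):
            raise ValueError("channel map must be injective")
        return v


def _stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "stages": {},
        "exit_status": 0,
    }

    state: dict = {}
    halted = False
    for stage in config.stages:
        entry: dict = {"status": "skipped" if halted else "running", "outputs": []}
        manifest["stages"][stage] = entry
        if halted:
            continue
        try:
            outputs = _run_stage(stage, config, state, out)
            entry["status"] = "completed"
            entry["outputs"] = outputs
        except Exception as exc:
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            entry["traceback"] = traceback.format_exc(limit=5)
            manifest["exit_status"] = 1
            halted = True

    (out / "manifest.json").write_text(json.dumps(_clean(manifest), indent=2))
    return manifest


def _clean(obj):
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path) -> list[str]:
    sim = config.simulate
    seed = _stage_seed(config.seed, stage)

    if stage == "simulate":
        if sim.kind == "growth":
            spec = ph.GrowthModelSpec(
                model=sim.growth_model,
                d0=sim.d0_um,
                d_final=sim.d_final_um,
                duration=sim.duration_d,
                sampling_interval=sim.sampling_interval_d,
            )
            images, times, diams = ph.make_growth_series(
                spec, pixel_size=config.pixel_size_um, seed=seed
            )
            state["growth"] = (images, times)
            path = out / "growth_truth.json"
            write_sidecar(
                path, {"times_d": times, "true_diameters_um": diams, "seed": seed}
            )
            return [path.name]
        spheroid = ph.SpheroidPhantom(
            radius=sim.radius_um,
            pixel_size=config.pixel_size_um,
            marker_profiles={sim.marker: ph.penetration_front(sim.f_pen)},
        )
        if sim.kind == "section":
            image, truth = ph.make_section_image(spheroid, [sim.marker], seed=seed)
            state["section"] = image
            img_path = out / "section.tif"
            write_stack(img_path, image[:, None])
            write_sidecar(out / "section_truth.json", {**truth, "seed": seed})
            return [img_path.name, "section_truth.json"]
        modality = ph.MODALITY_PRESETS[sim.modality]
        stack, truth = ph.make_zstack(spheroid, modality, seed=seed)
        state["zstack"] = stack
        stack_path = out / "zstack.tif"
        write_stack(stack_path, stack)
        write_sidecar(out / "zstack_truth.json", {**truth, "seed": seed})
        return [stack_path.name, "zstack_truth.json"]

    if stage == "morpho":
        if "growth" not in state:
            raise ConfigError("morpho stage requires a simulated growth series")
        images, times = state["growth"]
        curve = growth_curve(images, times, pixel_size=config.pixel_size_um)
        path = out / "growth_curve.csv"
        curve.to_frame().to_csv(path, index=False)
        return [path.name]

    if stage == "profile":
        if "zstack" not in state:
            raise ConfigError("profile stage requires a simulated z-stack")
        zp = profile_zstack(
            state["zstack"],
            nuclear_index=config.channel_map.get("nuclear", 0),
            marker_index=config.channel_map.get(sim.marker, 1),
            n_segments=config.n_segments,
            n_bins=config.n_bins,
            smooth_window=config.smooth_window,
            channel_name=sim.marker,
        )
        state["profiles"] = zp
        rep = zp.representative
        path = out / "profile.csv"
        pd.DataFrame(
            {
                "bin_center": rep.bin_centers,
                "normalized_smoothed_intensity": rep.smoothed,
            }
        ).to_csv(path, index=False)
        diag = out / "profile_sections.json"
        write_sidecar(
            diag,
            {
                "representative_index": zp.representative_index,
                "section_areas_px": zp.section_areas,
                "n_usable_sections": len(zp.profiles),
            },
        )
        return [path.name, diag.name]

    if stage == "penetration":
        if "profiles" not in state:
            raise ConfigError("penetration stage requires profiles")
        result = estimate_penetration(
            state["profiles"].representative,
            threshold=config.penetration_threshold,
            source=f"{sim.modality}/z{state['profiles'].representative_index}",
        )
        path = out / "penetration.csv"
        pd.DataFrame(
            [
                {
                    "radial_fraction": result.radial_fraction,
                    "volumetric_fraction": result.volumetric_fraction,
                    "threshold": result.threshold,
                    "source": result.source,
                }
            ]
        ).to_csv(path, index=False)
        return [path.name]

    if stage == "response":
        if config.plate_csv is None:
            raise ConfigError("response stage requires plate_csv")
        table = pd.read_csv(config.plate_csv)
        per_well, per_dose = relative_viability(table)
        outputs = []
        for name, frame in (("viability_wells", per_well), ("viability_doses", per_dose)):
            path = out / f"{name}.csv"
            frame.to_csv(path, index=False)
            outputs.append(path.name)
        if (table["assay"] == "cytotoxicity").any():
            _, cyto = cytotoxicity_index(table)
            path = out / "cytotoxicity_doses.csv"
            cyto.to_csv(path, index=False)
            outputs.append(path.name)
        return outputs

    raise ConfigError(f"unknown stage: {stage}")
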