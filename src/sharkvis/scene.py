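"""Scene description and pipeline orchestration.

A scene ties together the inputs of one appearance/contrast analysis: a
beige/dark skin-patch pair (packaged species fixtures or CSV/EEM files), a
water class, depths, the observer, and the ambient surface spectrum.
``run_pipeline`` executes the requested stages in dependency order and
returns a machine-readable report (plain dicts of floats, JSON-safe), with
the configuration echoed so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .camera import (
    default_sensor,
    effective_response,
    image_patch,
    shark_eye_stack,
)
from .colorimetry import render_patch_pair
from .contrast import (
    ThresholdModel,
    depth_detectability_profile,
    pigment_locus,
)
from .fluorescence import EEM, SkinPatch, skin_radiance
from .light import LightField, WaterType, downwelling, flat_surface, spacelight, water_type
from .pigments import VisualPigmentTemplate
from .spectra import SpectralCurve
from .synth import gen_patch_pair, species_lambda_max

__all__ = ["Scene", "run_pipeline", "STAGES"]

OBSERVERS = ("shark484", "shark488", "human", "camera-blue")
STAGES = ("light", "fluoresce", "contrast", "camera", "render")


@dataclass(frozen=True)
class Scene:
    """Inputs of one analysis run."""

    beige: SkinPatch
    dark: SkinPatch
    water: WaterType
    depths: tuple[float, ...] = (1.0, 10.0, 20.0, 30.0)
    observer: str = "shark484"
    surface: SpectralCurve = field(default_factory=flat_surface)

    def __post_init__(self) -> None:
        if self.observer not in OBSERVERS:
            raise ValueError(
                f"unknown observer {self.observer!r}; expected one of {OBSERVERS}"
            )

    @property
    def pigment(self) -> VisualPigmentTemplate:
        lmax = 488.0 if self.observer == "shark488" else 484.0
        return VisualPigmentTemplate(lmax)

    @classmethod
    def from_species(cls, species: str, water_name: str = "blue", **kw) -> "Scene":
        beige, dark = gen_patch_pair(species)
        return cls(beige, dark, water_type(water_name), **kw)

    @classmethod
    def from_yaml(cls, path) -> "Scene":
        """Load a scene description YAML.

        Keys: ``species`` (fixture patches) or ``patches`` (per-patch
        ``reflectance`` CSV + ``eem`` CSV paths), ``water`` (packaged name),
        ``depths``, ``observer``.
        """
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        if "patches" in cfg:
            patches = {}
            for label in ("beige", "dark"):
                entry = cfg["patches"][label]
                patches[label] = SkinPatch(
                    label,
                    SpectralCurve.from_csv(entry["reflectance"]),
                    EEM.from_csv(entry["eem"]),
                )
            beige, dark = patches["beige"], patches["dark"]
        else:
            beige, dark = gen_patch_pair(cfg.get("species", "C_ventriosum"))
        return cls(
            beige,
            dark,
            water_type(cfg.get("water", "blue")),
            tuple(float(d) for d in cfg.get("depths", (1, 10, 20, 30))),
            cfg.get("observer", "shark484"),
        )


def _stage_light(scene: Scene, report: dict) -> None:
    rows = []
    for z in scene.depths:
        lf = LightField(scene.surface, scene.water, z)
        ed = downwelling(lf)
        rows.append({
            "depth_m": z,
            "peak_nm": ed.peak_wavelength,
            "total_irradiance": float(np.trapezoid(ed.values, ed.wavelengths)),
        })
    report["light"] = rows


def _stage_fluoresce(scene: Scene, report: dict) -> None:
    rows = []
    for z in scene.depths:
        lf = LightField(scene.surface, scene.water, z)
        for label, patch in (("beige", scene.beige), ("dark", scene.dark)):
            rad = skin_radiance(patch, lf)
            rows.append({
                "depth_m": z, "patch": label,
                "radiance_peak_nm": rad.peak_wavelength,
            })
    report["fluoresce"] = rows


def _stage_contrast(scene: Scene, report: dict) -> None:
    prof = depth_detectability_profile(
        scene.beige, scene.dark, scene.water, scene.depths, scene.pigment,
        surface=scene.surface,
    )
    report["contrast"] = [
        {
            "depth_m": r.depth,
            "q_target": r.q_target,
            "q_background": r.q_background,
            "weber": r.weber,
            "detectable": r.detectable,
        }
        for r in prof
    ]


def _observer_sensitivity(scene: Scene):
    if scene.observer == "camera-blue":
        return effective_response(default_sensor(), shark_eye_stack()).channel("B")
    return scene.pigment


def _stage_camera(scene: Scene, report: dict) -> None:
    cam = effective_response(default_sensor(), shark_eye_stack())
    rows = []
    for z in scene.depths:
        lf = LightField(scene.surface, scene.water, z)
        for label, patch in (("beige", scene.beige), ("dark", scene.dark)):
            vals = image_patch(cam, skin_radiance(patch, lf))
            rows.append({"depth_m": z, "patch": label, **vals})
    report["camera"] = rows


def _stage_render(scene: Scene, report: dict) -> None:
    obs = "human" if scene.observer == "human" else _observer_sensitivity(scene)
    rows = []
    for z in scene.depths:
        lf = LightField(scene.surface, scene.water, z)
        beige_rgb, dark_rgb, ratio = render_patch_pair(
            skin_radiance(scene.beige, lf), skin_radiance(scene.dark, lf), obs
        )
        rows.append({
            "depth_m": z,
            "beige_rgb": list(beige_rgb),
            "dark_rgb": list(dark_rgb),
            "beige_dark_ratio": ratio,
        })
    report["render"] = rows


_STAGE_FNS = {
    "light": (_stage_light, ()),
    "fluoresce": (_stage_fluoresce, ()),
    "contrast": (_stage_contrast, ("light", "fluoresce")),
    "camera": (_stage_camera, ("light", "fluoresce")),
    "render": (_stage_render, ("light", "fluoresce")),
}


def run_pipeline(scene: Scene, stages) -> dict:
    """Run the requested stages in dependency order; return the report.

    Stage dependencies are resolved automatically; an unknown stage raises
    an error naming it.
    """
    stages = list(stages)
    for s in stages:
        if s not in _STAGE_FNS:
            raise ValueError(
                f"unknown stage {s!r}; available: {list(_STAGE_FNS)}"
            )
    # close over dependencies, keep canonical order
    wanted: set = set()

    def add(s: str) -> None:
        if s in wanted:
            return
        for dep in _STAGE_FNS[s][1]:
            add(dep)
        wanted.add(s)

    for s in stages:
        add(s)
    ordered = [s for s in STAGES if s in wanted]

    report: dict = {
        "meta": {
            "sharkvis_version": __version__,
            "observer": scene.observer,
            "water": scene.water.name,
            "depths_m": list(scene.depths),
            "stages": ordered,
        }
    }
    for s in ordered:
        _STAGE_FNS[s][0](scene, report)
    return report
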