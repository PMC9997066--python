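"""Packaged reference design: geometries, layer stack and design report.

The packaged YAML fixture holds the eight-channel reference array (outline
and support-beam dimensions, design frequencies, and the six-layer
Si/Al/SiN/ZnO/SiN/Al stack).  Loaders convert the mm/um fixture units to SI.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cantilever import (
    CantileverGeometry,
    MaterialLayer,
    compose_segment_properties,
    estimate_root_stress,
    mel_forward,
    piezo_open_circuit_voltage,
    solve_stepped_modes,
)

__all__ = [
    "load_design_config",
    "reference_geometries",
    "reference_layers",
    "silicon_only_layers",
    "design_frequencies",
    "design_report",
]

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "um": 1e-6}


def load_design_config(path: str | Path | None = None) -> dict:
    """Load a design config YAML (packaged reference fixture by default)."""
    if path is None:
        text = resources.files("rmakit.data").joinpath("rma_design.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    for key in ("cantilevers", "layers", "units"):
        if key not in cfg:
            raise ValueError(f"design config is missing required key {key!r}")
    return cfg


def reference_geometries(cfg: dict | None = None) -> list[CantileverGeometry]:
    """The cantilever geometries of the reference array, in SI units."""
    cfg = cfg or load_design_config()
    scale = _UNIT_SCALE[cfg["units"].get("geometry", "m")]
    h = _layer_defs(cfg)[0].thickness  # structural thickness from the stack
    n_beams = int(cfg.get("n_support_beams", 2))
    return [
        CantileverGeometry(
            l=row["l"] * scale,
            c=row["c"] * scale,
            l_n=row["l_n"] * scale,
            c_n=row["c_n"] * scale,
            h=h,
            n_support_beams=n_beams,
        )
        for row in cfg["cantilevers"]
    ]


def _layer_defs(cfg: dict) -> list[MaterialLayer]:
    tscale = _UNIT_SCALE[cfg["units"].get("layer_thickness", "m")]
    layers = []
    for row in cfg["layers"]:
        layers.append(
            MaterialLayer(
                name=row["name"],
                thickness=row["thickness"] * tscale,
                young_modulus=row["E"] * 1e9,
                density=row["rho"],
                d31=row.get("d31"),
                relative_permittivity=row.get("relative_permittivity"),
                narrow_only=bool(row.get("narrow_only", False)),
            )
        )
    return layers


def reference_layers(cfg: dict | None = None) -> list[MaterialLayer]:
    """Full layer stack: Si plate plus the narrow-beam electrode/piezo stack."""
    return _layer_defs(cfg or load_design_config())


def silicon_only_layers(cfg: dict | None = None) -> list[MaterialLayer]:
    """The bare structural Si layer (simplified single-material model)."""
    return [_layer_defs(cfg or load_design_config())[0]]


def design_frequencies(cfg: dict | None = None) -> np.ndarray:
    """The quoted design resonance frequencies of the reference array (Hz)."""
    cfg = cfg or load_design_config()
    return np.array([row["f_design"] for row in cfg["cantilevers"]], dtype=float)


def design_report(
    geometries: list[CantileverGeometry] | None = None,
    layers: list[MaterialLayer] | None = None,
    n_modes: int = 3,
    pressure: float = 1.0,
) -> pd.DataFrame:
    """Per-cantilever design table: dimensions, modes, Mel coordinate,
    root-stress and open-circuit voltage estimates at the given pressure.
    """
    if geometries is None:
        geometries = reference_geometries()
    if layers is None:
        layers = reference_layers()
    piezo = next((ly for ly in layers if ly.is_piezo), None)
    rows = []
    for i, geom in enumerate(geometries, start=1):
        props = compose_segment_properties(geom, layers)
        modes = solve_stepped_modes(props, geom, n_modes=n_modes)
        stress = estimate_root_stress(geom, pressure)
        row = {
            "cantilever": i,
            "l_mm": geom.l * 1e3,
            "c_mm": geom.c * 1e3,
            "l_n_mm": geom.l_n * 1e3,
            "c_n_mm": geom.c_n * 1e3,
        }
        for mode in modes:
            row[f"f{mode.mode_index}_hz"] = mode.frequency
        row["mel"] = mel_forward(modes[0].frequency)
        row["root_stress_pa"] = stress
        if piezo is not None:
            row["voltage_v"] = piezo_open_circuit_voltage(stress, piezo)
        rows.append(row)
    return pd.DataFrame(rows)
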