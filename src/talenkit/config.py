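"""Architecture presets and plain-text (YAML) configuration.

All geometric defaults -- scaffold cleavage offsets, repeat count, active
spacer windows -- live in ``data/presets.yaml`` and can be overridden by a
user-supplied YAML file of the same shape.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import yaml

from .core import (
    Architecture,
    ArrayGeometry,
    Scaffold,
    ScaffoldKind,
    SpacerWindows,
)

__all__ = [
    "load_presets",
    "architecture",
    "all_architectures",
    "array_geometry",
    "ARCH_NAMES",
    "WINDOW_PRESETS",
]

ARCH_NAMES = ("TtT", "HtH", "TtH")
WINDOW_PRESETS = ("results", "chr1-scan")


def load_presets(path: str | None = None) -> dict:
    """Load the preset file; ``path`` overrides the packaged defaults."""
    if path is None:
        text = (
            resources.files("talenkit").joinpath("data/presets.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def _scaffold(kind: ScaffoldKind, presets: dict,
              offsets: Mapping | None) -> Scaffold:
    offset = presets["scaffolds"][kind.name]["cleavage_offset"]
    if offsets:
        for key, value in offsets.items():
            if ScaffoldKind.parse(key) is kind:
                offset = value
    return Scaffold(kind, float(offset))


def architecture(
    name: str,
    windows_preset: str = "results",
    presets: dict | None = None,
    offsets: Mapping | None = None,
    windows=None,
) -> Architecture:
    """Build a preset :class:`Architecture`.

    Parameters
    ----------
    name:
        ``TtT``, ``HtH`` or ``TtH``.
    windows_preset:
        ``results`` (activity-assay windows) or ``chr1-scan``.
    presets:
        Parsed preset mapping (defaults to the packaged file).
    offsets:
        Optional ``{scaffold kind: cleavage offset}`` overrides.
    windows:
        Explicit spacer windows, overriding the preset entirely.
    """
    presets = presets or load_presets()
    if name not in ARCH_NAMES:
        raise ValueError(f"unknown architecture {name!r}; expected one of {ARCH_NAMES}")
    if windows is None:
        try:
            windows = presets["windows"][windows_preset][name]
        except KeyError:
            raise ValueError(f"unknown windows preset {windows_preset!r}") from None
    kinds = {
        "TtT": (ScaffoldKind.TALE_FOKI, ScaffoldKind.TALE_FOKI),
        "HtH": (ScaffoldKind.FOKI_TALE, ScaffoldKind.FOKI_TALE),
        "TtH": (ScaffoldKind.TALE_FOKI, ScaffoldKind.FOKI_TALE),
    }[name]
    return Architecture(
        name,
        _scaffold(kinds[0], presets, offsets),
        _scaffold(kinds[1], presets, offsets),
        SpacerWindows.parse(windows),
    )


def all_architectures(
    windows_preset: str = "results",
    presets: dict | None = None,
    offsets: Mapping | None = None,
) -> dict[str, Architecture]:
    presets = presets or load_presets()
    return {
        name: architecture(name, windows_preset, presets, offsets)
        for name in ARCH_NAMES
    }


def array_geometry(repeats: float | None = None,
                   presets: dict | None = None) -> ArrayGeometry:
    if repeats is None:
        presets = presets or load_presets()
        repeats = presets["array"]["repeats"]
    return ArrayGeometry(float(repeats))
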