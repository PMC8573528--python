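"""Packaged template-angle tables.

``ten_twenty_64``: a 64-channel 10-20 layout (idealized: the temporal/
occipital/frontal-pole ring sits at exactly 90 degrees inclination).
``radial_128``: a 128-channel layout with electrodes radially equidistant
from Cz; the five channels coinciding with the 10-20 anchor positions carry
their 10-20 names (Cz, FPz, Oz, T7, T8). Both are idealized approximations
of vendor cap specifications, adequate for synthetic-data studies.
"""

from __future__ import annotations

from importlib import resources

from .head_models import TemplateAngles
from .montage_io import read_template_angles

__all__ = ["BUILTIN_LAYOUTS", "load_builtin"]

BUILTIN_LAYOUTS = ("ten_twenty_64", "radial_128")


def load_builtin(name: str) -> TemplateAngles:
    """Load a packaged angle table by name (see ``BUILTIN_LAYOUTS``)."""
    if name not in BUILTIN_LAYOUTS:
        raise KeyError(f"unknown layout {name!r}; available: {', '.join(BUILTIN_LAYOUTS)}")
    ref = resources.files("sparsecap").joinpath("data", f"{name}.csv")
    with resources.as_file(ref) as path:
        return read_template_angles(path)
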