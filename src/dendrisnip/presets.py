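"""Shipped default parameter sets.

Growth defaults for the two hippocampal neuron classes are calibrated (see
``scripts/calibrate_growth.py``) so that 10-neuron populations reproduce the
target morphometrics of young-adult mouse neurons: GCL total dendritic
length ~926 um with ~12.9 branch points and ~26.7 branches from a single
primary; CA1 pyramidal cells ~1589 um total split into ~855 um apical (one
primary) and ~734 um basal (three primaries), with apical Sholl peaking near
100 um and basal near 50 um from the soma.

Damage presets are the published low-LET parameter sets per neuron type and
radiation quality: Hill constant K = 0.01 um^(3 eta) for all, saturation
dose D_m = 3000 Gy (GCL gamma) or 2000 Gy (protons), Hill coefficient eta =
3.5 / 3 / 2 / 3.5 for GCL-gamma / GCL-proton / CA1-apical / CA1-basal, and
population survival doses D_0 = 25 Gy (gamma) and 18 Gy (protons) for GCL
only (CA1 comparisons are single-neuron).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .damage import DamageParams
from .growth import AngleModel, CompartmentSpec, GrowthParams
from .regions import Cone, Hemisphere

__all__ = ["growth_defaults", "damage_preset", "DAMAGE_PRESETS", "GROWTH_CLASSES"]

GROWTH_CLASSES = ("GCL", "CA1")


def gcl_growth_params() -> GrowthParams:
    """Dentate granule cell: one primary dendrite in a cone-shaped field."""
    comp = CompartmentSpec(
        label="dendrite",
        n_primaries=1,
        initial_radius=3.0,
        taper_rate=0.022,
        alpha_schedule={1: 0.10, 2: 0.10, 3: 0.10, 4: 0.10},
        terminal_length_mean=34.0,
        bounding_volume=Cone(axis=np.array([0.0, 0.0, 1.0]), half_angle_deg=35.0, height=220.0),
    )
    return GrowthParams(
        neuron_class="GCL",
        angle_model=AngleModel(half_angle_mean_deg=28.0, half_angle_sd_deg=7.0, wobble_sd_deg=3.0),
        compartments=[comp],
        soma_radius=5.0,
    )


def ca1_growth_params() -> GrowthParams:
    """CA1 pyramidal cell: one apical primary (cone) + three basal primaries
    (hemisphere on the opposite side of the soma)."""
    apical = CompartmentSpec(
        label="apical",
        n_primaries=1,
        initial_radius=3.0,
        taper_rate=0.030,
        alpha_schedule={1: 0.13, 2: 0.13, 3: 0.13, 4: 0.13},
        terminal_length_mean=36.0,
        bounding_volume=Cone(axis=np.array([0.0, 0.0, 1.0]), half_angle_deg=40.0, height=250.0),
    )
    basal = CompartmentSpec(
        label="basal",
        n_primaries=3,
        initial_radius=1.3,
        taper_rate=0.035,
        alpha_schedule={1: 0.13, 2: 0.13, 3: 0.13},
        terminal_length_mean=25.0,
        bounding_volume=Hemisphere(axis=np.array([0.0, 0.0, -1.0]), radius=150.0),
    )
    return GrowthParams(
        neuron_class="CA1",
        angle_model=AngleModel(half_angle_mean_deg=24.5, half_angle_sd_deg=6.0, wobble_sd_deg=4.0),
        compartments=[apical, basal],
        soma_radius=7.5,
    )


def growth_defaults(neuron_class: str) -> GrowthParams:
    if neuron_class.upper() == "GCL":
        return gcl_growth_params()
    if neuron_class.upper() == "CA1":
        return ca1_growth_params()
    raise KeyError(f"unknown neuron class {neuron_class!r}; choose from {GROWTH_CLASSES}")


DAMAGE_PRESETS: dict[str, DamageParams] = {
    "GCL-gamma": DamageParams(K=0.01, D_m=3000.0, eta=3.5, D0=25.0),
    "GCL-proton": DamageParams(K=0.01, D_m=2000.0, eta=3.0, D0=18.0),
    "CA1-apical-proton": DamageParams(K=0.01, D_m=2000.0, eta=2.0, D0=None),
    "CA1-basal-proton": DamageParams(K=0.01, D_m=2000.0, eta=3.5, D0=None),
}


def damage_preset(name: str) -> DamageParams:
    """A fresh copy of a named damage parameter set."""
    try:
        return replace(DAMAGE_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown damage preset {name!r}; choose from {sorted(DAMAGE_PRESETS)}"
        ) from None
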