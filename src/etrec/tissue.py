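"""Four-layer fingertip tissue model with Cole-Cole dispersion.

The fingertip is represented as a flat slab of four skin layers with
fixed thicknesses (stratum corneum 0.029 mm, viable epidermis 0.089 mm,
dermis 1.380 mm, subcutaneous tissue 3.500 mm; 4.998 mm total).  Each
layer carries a Cole-Cole conductivity dispersion

    sigma_c(f) = sigma_inf / (1 + (j*omega*tau)^(1-alpha)) + sigma_0

evaluated at a single effective frequency for the quasi-static solve
(default 5 kHz, the dominant spectral content of a 100 us rectangular
phase, f_eff = 1/(2*pw)).  The real part of sigma_c drives conduction.

Subject personalisation is a smooth multiplicative factor on each
layer's sigma_inf and sigma_0,

    g = clamp(1 + a1*(bmi-22)/22 + a2*(age-25)/25 + a3*(sex-0.5), 0.5, 1.5)

with sex encoded 0 (female) / 1 (male).  Layer thicknesses are never
modified.  The coefficients are configuration data, not physiology
asserted by the model; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

LAYER_NAMES = ("stratum_corneum", "viable_epidermis", "dermis", "subcutaneous")
LAYER_THICKNESSES_MM = (0.029, 0.089, 1.380, 3.500)
TOTAL_DEPTH_MM = 4.998

#: Effective frequency of the quasi-static solve for a 100 us phase width.
DEFAULT_EFFECTIVE_FREQUENCY_HZ = 5000.0

#: Default lateral (x, y) extent of the slab in mm.  Large enough that the
#: biggest candidate array (12.0 x 19.5 mm bounding rectangle, D4.5Q3)
#: fits with >= 3 mm of margin per side.
DEFAULT_LATERAL_EXTENT_MM = (20.0, 28.0)


@dataclass(frozen=True)
class ColeColeParams:
    """Single-pole Cole-Cole conductivity dispersion parameters."""

    sigma_inf: float  # S/m
    sigma_0: float  # S/m
    tau: float  # s
    alpha: float  # dimensionless, in [0, 1)

    def __post_init__(self) -> None:
        if self.sigma_inf < 0 or self.sigma_0 < 0:
            raise ValueError("conductivities must be non-negative")
        if self.tau <= 0:
            raise ValueError("relaxation time must be positive")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")


@dataclass(frozen=True)
class TissueLayer:
    name: str
    thickness_mm: float
    cole_cole: ColeColeParams
    # Carried for completeness; the quasi-static conduction solve uses
    # only the real conductivity.
    rel_permittivity: float = 1.0e4


# Baseline per-layer dispersion parameters.  These are representative
# values assembled from the skin dielectric-dispersion literature (dry
# stratum corneum is orders of magnitude less conductive than the living
# layers at audio frequencies); they are configuration data with the
# defaults recorded here, not quantities the model claims to measure.
DEFAULT_LAYERS: tuple[TissueLayer, ...] = (
    TissueLayer("stratum_corneum", 0.029, ColeColeParams(4.0e-4, 1.0e-4, 7.96e-5, 0.80), 1.1e3),
    TissueLayer("viable_epidermis", 0.089, ColeColeParams(0.15, 0.05, 7.96e-6, 0.20), 3.0e4),
    TissueLayer("dermis", 1.380, ColeColeParams(0.25, 0.10, 7.96e-6, 0.20), 3.0e4),
    TissueLayer("subcutaneous", 3.500, ColeColeParams(0.04, 0.02, 1.59e-5, 0.25), 2.5e4),
)


@dataclass(frozen=True)
class SubjectDescriptors:
    """Basic anthropometric descriptors parameterising the tissue model."""

    sex: int  # 0 = female, 1 = male
    age: float  # years
    height_cm: float
    weight_kg: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError("sex must be encoded 0 (female) or 1 (male)")
        if self.age <= 0 or self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("age, height and weight must be positive")

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass(frozen=True)
class PersonalizationCoefficients:
    """Coefficients of the multiplicative conductivity factor g(subject)."""

    a_bmi: float = 0.15
    a_age: float = -0.05
    a_sex: float = 0.05
    bmi_ref: float = 22.0
    age_ref: float = 25.0
    sex_ref: float = 0.5
    g_min: float = 0.5
    g_max: float = 1.5


def cole_cole_conductivity(p: ColeColeParams, f: float) -> complex:
    """Complex Cole-Cole conductivity at frequency ``f`` (Hz).

    Principal branch of the fractional power; at f = 0 the dispersive
    term is exactly sigma_inf, so sigma_c(0) = sigma_inf + sigma_0.
    """
    if f < 0:
        raise ValueError("frequency must be non-negative")
    omega = 2.0 * np.pi * f
    jwt = 1j * omega * p.tau
    if omega == 0.0:
        disp = complex(p.sigma_inf)
    else:
        disp = p.sigma_inf / (1.0 + jwt ** (1.0 - p.alpha))
    return disp + p.sigma_0


def effective_conductivity(p: ColeColeParams, f: float) -> float:
    """Real part of the Cole-Cole conductivity, used by the conduction solve."""
    return float(cole_cole_conductivity(p, f).real)


def personalization_factor(
    subject: SubjectDescriptors,
    coeffs: PersonalizationCoefficients = PersonalizationCoefficients(),
) -> float:
    """Smooth, clamped multiplicative conductivity factor for one subject."""
    g = (
        1.0
        + coeffs.a_bmi * (subject.bmi - coeffs.bmi_ref) / coeffs.bmi_ref
        + coeffs.a_age * (subject.age - coeffs.age_ref) / coeffs.age_ref
        + coeffs.a_sex * (subject.sex - coeffs.sex_ref)
    )
    return float(np.clip(g, coeffs.g_min, coeffs.g_max))


def personalize_layers(
    subject: SubjectDescriptors,
    baseline: tuple[TissueLayer, ...] = DEFAULT_LAYERS,
    coeffs: PersonalizationCoefficients = PersonalizationCoefficients(),
) -> tuple[TissueLayer, ...]:
    """Scale each layer's sigma_inf and sigma_0 by g(subject).

    Pure and deterministic; geometry (thicknesses, ordering) unchanged.
    """
    if len(baseline) != 4:
        raise ValueError("baseline must contain exactly the four skin layers")
    g = personalization_factor(subject, coeffs)
    out = []
    for layer in baseline:
        cc = layer.cole_cole
        out.append(
            replace(
                layer,
                cole_cole=replace(cc, sigma_inf=cc.sigma_inf * g, sigma_0=cc.sigma_0 * g),
            )
        )
    return tuple(out)


@dataclass(frozen=True)
class FingertipModel:
    """Layered slab model of one subject's fingertip."""

    layers: tuple[TissueLayer, ...]
    subject: SubjectDescriptors
    lateral_extent_mm: tuple[float, float] = DEFAULT_LATERAL_EXTENT_MM
    effective_frequency_hz: float = DEFAULT_EFFECTIVE_FREQUENCY_HZ

    def __post_init__(self) -> None:
        if len(self.layers) != 4:
            raise ValueError("fingertip model requires exactly four layers")
        total = sum(l.thickness_mm for l in self.layers)
        if abs(total - TOTAL_DEPTH_MM) > 1e-9:
            raise ValueError(f"total depth must be {TOTAL_DEPTH_MM} mm, got {total}")

    @property
    def total_depth_mm(self) -> float:
        return sum(l.thickness_mm for l in self.layers)


def build_fingertip_model(
    subject: SubjectDescriptors,
    baseline: tuple[TissueLayer, ...] = DEFAULT_LAYERS,
    coeffs: PersonalizationCoefficients = PersonalizationCoefficients(),
    lateral_extent_mm: tuple[float, float] = DEFAULT_LATERAL_EXTENT_MM,
    effective_frequency_hz: float = DEFAULT_EFFECTIVE_FREQUENCY_HZ,
) -> FingertipModel:
    """Personalised fingertip model for one subject."""
    return FingertipModel(
        layers=personalize_layers(subject, baseline, coeffs),
        subject=subject,
        lateral_extent_mm=lateral_extent_mm,
        effective_frequency_hz=effective_frequency_hz,
    )
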