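"""Cone spectral sensitivities for a tetrachromatic (avian) eye.

The effective sensitivity of cone class *i* is the product of three
wavelength-dependent factors,

    R_i(λ) = r_i(λ) · p_i(λ) · o(λ),

where r_i is the normalised visual-pigment absorbance, p_i the transmittance
of the cone's oil droplet (a long-pass cut-off filter; absent in UVS/VS
cones, whose droplets are unpigmented), and o the ocular-media
transmittance.  Self-screening of the pigment is assumed negligible, so the
sensitivity is exactly this triple product.

Pigment absorbance follows the Govardovskii et al. (2000) A1 template
(α-band rational-exponential form plus Gaussian β-band); oil droplets use an
exponential (Gompertz-type) cut-off.  Both model forms can be bypassed by
supplying tabulated sensitivities directly, so analyses that have measured
sensitivity curves never depend on the templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .spectra import (DEFAULT_GRID, Spectrum, SpectrumError, common_grid,
                      read_spectrum, resample)

__all__ = [
    "RECEPTOR_ORDER",
    "PigmentSpec",
    "OilDropletSpec",
    "VisualSystem",
    "pigment_absorbance",
    "droplet_transmittance",
    "cone_sensitivity",
    "load_visual_system",
]

#: Canonical receptor ordering, shortest to longest peak wavelength.
RECEPTOR_ORDER = ("UVS", "SWS", "MWS", "LWS")


@dataclass(frozen=True)
class PigmentSpec:
    """Visual pigment described by its peak wavelength.

    Only the A1 (retinal) chromophore template is implemented; avian cone
    pigments are A1-based.
    """
    lambda_max: float
    template_variant: str = "A1"

    def __post_init__(self) -> None:
        if not 300.0 <= self.lambda_max <= 700.0:
            raise ValueError(f"lambda_max {self.lambda_max} outside 300-700 nm")
        if self.template_variant != "A1":
            raise ValueError(f"unsupported template {self.template_variant!r}")


@dataclass(frozen=True)
class OilDropletSpec:
    """Oil-droplet cut-off filter.

    ``exponential_cutoff`` uses the Gompertz form
    T(λ) = exp(-exp(-s·(λ - λ_cut))), which is ~0.37 at λ_cut, approaches 1
    above and 0 below; ``hard_step`` is the idealised step; ``none`` is the
    identity filter (UVS cones).
    """
    lambda_cut: float = 0.0
    slope_param: float = 0.05   # per nm
    model_variant: str = "exponential_cutoff"

    def __post_init__(self) -> None:
        if self.model_variant not in ("exponential_cutoff", "hard_step", "none"):
            raise ValueError(f"unknown droplet model {self.model_variant!r}")
        if self.slope_param < 0:
            raise ValueError("droplet slope must be non-negative")


def pigment_absorbance(spec: PigmentSpec,
                       grid: Sequence[float] | np.ndarray = DEFAULT_GRID
                       ) -> Spectrum:
    """Peak-normalised A1 visual-pigment absorbance template.

    α-band:  S_α(λ) = 1 / (exp[A(a-x)] + exp[B(b-x)] + exp[C(c-x)] + D)
    with x = λ_max/λ, A=69.7, B=28, C=-14.9, D=0.674, b=0.922, c=1.104 and
    a = 0.8795 + 0.0459·exp(-(λ_max-300)²/11940).

    β-band:  Gaussian with amplitude 0.26, centre 189 + 0.315·λ_max and
    width -40.5 + 0.195·λ_max.

    The sum is renormalised to peak 1.
    """
    grid = np.asarray(grid, dtype=float)
    lm = spec.lambda_max
    if not grid[0] <= lm <= grid[-1]:
        raise ValueError(f"lambda_max {lm} nm outside grid "
                         f"[{grid[0]}, {grid[-1]}] nm")
    x = lm / grid
    a = 0.8795 + 0.0459 * np.exp(-((lm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    lam_beta = 189.0 + 0.315 * lm
    width_beta = -40.5 + 0.195 * lm
    beta = 0.26 * np.exp(-(((grid - lam_beta) / width_beta) ** 2))
    total = alpha + beta
    total = total / total.max()
    return Spectrum(grid, total, "sensitivity", f"pigment_{lm:g}nm")


def droplet_transmittance(spec: OilDropletSpec,
                          grid: Sequence[float] | np.ndarray = DEFAULT_GRID
                          ) -> Spectrum:
    """Transmittance of an oil-droplet cut-off filter on a grid.

    Non-decreasing in wavelength for every variant.
    """
    grid = np.asarray(grid, dtype=float)
    if spec.model_variant == "none":
        t = np.ones_like(grid)
    elif spec.model_variant == "hard_step":
        t = np.where(grid >= spec.lambda_cut, 1.0, 0.0)
    else:
        t = np.exp(-np.exp(-spec.slope_param * (grid - spec.lambda_cut)))
    return Spectrum(grid, t, "transmittance",
                    f"droplet_{spec.model_variant}")


def cone_sensitivity(pigment: Spectrum, droplet: Spectrum,
                     ocular: Spectrum) -> Spectrum:
    """Pointwise product R(λ) = r(λ)·p(λ)·o(λ) on the coarsest common grid."""
    for s, role in ((droplet, "transmittance"), (ocular, "transmittance")):
        if s.unit_role != role:
            raise SpectrumError(f"expected {role} spectrum, got {s.unit_role}")
    grid = common_grid(pigment, droplet)
    grid_spec = Spectrum(grid, np.zeros_like(grid), "sensitivity")
    grid = common_grid(grid_spec, ocular)
    r = resample(pigment, grid).values
    p = resample(droplet, grid).values
    o = resample(ocular, grid).values
    return Spectrum(grid, r * p * o, "sensitivity", pigment.name)


@dataclass(frozen=True)
class VisualSystem:
    """The receptor-level description of one eye.

    Holds the four single-cone sensitivities (keyed UVS/SWS/MWS/LWS), the
    double-cone sensitivity used only for achromatic (Michelson) contrast,
    the limiting Weber fraction of the LWS channel, and the relative cone
    abundances that scale channel noise.
    """
    sensitivities: Mapping[str, Spectrum]
    double_cone: Spectrum
    weber_lws: float = 0.1
    abundances: Mapping[str, float] = field(
        default_factory=lambda: dict(zip(RECEPTOR_ORDER, (1.0, 1.5, 2.0, 3.0))))
    noise_scaling: str = "sqrt"

    def __post_init__(self) -> None:
        missing = set(RECEPTOR_ORDER) - set(self.sensitivities)
        if missing:
            raise ValueError(f"missing receptor sensitivities: {sorted(missing)}")
        if self.weber_lws <= 0:
            raise ValueError("weber_lws must be positive")
        if any(self.abundances.get(r, 0) <= 0 for r in RECEPTOR_ORDER):
            raise ValueError("all abundances must be positive")
        if self.noise_scaling not in ("sqrt", "linear"):
            raise ValueError("noise_scaling must be 'sqrt' or 'linear'")

    @property
    def receptor_names(self) -> tuple[str, ...]:
        return RECEPTOR_ORDER

    def sensitivity_array(self, grid: np.ndarray) -> np.ndarray:
        """Stack R_i resampled onto ``grid``, rows ordered UVS..LWS."""
        return np.stack([resample(self.sensitivities[r], grid).values
                         for r in RECEPTOR_ORDER])


def _build_ocular(entry, base: Path) -> Spectrum:
    if isinstance(entry, str):
        return read_spectrum(base / entry, "transmittance")
    # logistic long-pass parametrisation: {half_point_nm, slope_per_nm}
    half = float(entry.get("half_point_nm", 330.0))
    slope = float(entry.get("slope_per_nm", 0.1))
    t = 1.0 / (1.0 + np.exp(-slope * (DEFAULT_GRID - half)))
    return Spectrum(DEFAULT_GRID, t, "transmittance", "ocular_media")


def load_visual_system(config_path: str | Path) -> VisualSystem:
    """Assemble a :class:`VisualSystem` from a YAML config.

    Two layouts are accepted per receptor: a model description
    (``lambda_max`` plus optional droplet parameters) rendered through the
    templates, or ``table: <csv path>`` pointing at a tabulated sensitivity
    (path relative to the config file).
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    base = config_path.parent
    ocular = _build_ocular(cfg.get("ocular_media", {}), base)

    sens: dict[str, Spectrum] = {}
    for rec in RECEPTOR_ORDER:
        entry = cfg["receptors"][rec]
        if "table" in entry:
            sens[rec] = read_spectrum(base / entry["table"], "sensitivity",
                                      name=rec)
            continue
        pig = pigment_absorbance(PigmentSpec(float(entry["lambda_max"])))
        if rec == "UVS" or "droplet_cut_nm" not in entry:
            drop = droplet_transmittance(OilDropletSpec(model_variant="none"))
        else:
            drop = droplet_transmittance(OilDropletSpec(
                lambda_cut=float(entry["droplet_cut_nm"]),
                slope_param=float(entry.get("droplet_slope", 0.05))))
        sens[rec] = cone_sensitivity(pig, drop, ocular)

    dc = cfg["double_cone"]
    if "table" in dc:
        double = read_spectrum(base / dc["table"], "sensitivity", name="double")
    else:
        pig = pigment_absorbance(PigmentSpec(float(dc["lambda_max"])))
        if "droplet_cut_nm" in dc:
            drop = droplet_transmittance(OilDropletSpec(
                lambda_cut=float(dc["droplet_cut_nm"]),
                slope_param=float(dc.get("droplet_slope", 0.05))))
        else:
            drop = droplet_transmittance(OilDropletSpec(model_variant="none"))
        double = cone_sensitivity(pig, drop, ocular)

    return VisualSystem(
        sensitivities=sens,
        double_cone=double,
        weber_lws=float(cfg.get("weber_lws", 0.1)),
        abundances={r: float(v) for r, v in
                    cfg.get("abundances",
                            dict(zip(RECEPTOR_ORDER, (1, 1.5, 2, 3)))).items()},
        noise_scaling=cfg.get("noise_scaling", "sqrt"),
    )
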