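"""Receptor-noise-limited (RNL) colour contrast under background adaptation.

The chain from spectra to a colour distance in just-noticeable-difference
(JND) units:

1.  quantum catch      Q_i = k_i ∫ R_i(λ) L(λ) dλ          (300-700 nm)
2.  von Kries gain     k_i = 1 / ∫ R_i(λ) L_b(λ) dλ        (background L_b)
3.  chromaticity       q_i = Q_i / Σ_j Q_j
4.  receptor contrast  Δf_i = ln(Q_i,1 / Q_i,2)
5.  channel noise      ω_i = v / √η_i, anchored so ω_LWS has a set value
6.  ΔS: the tetrachromatic RNL distance, equal to
        min_c Σ_i (Δf_i - c)² / ω_i²
    — the best-fitting uniform (intensity) shift is discounted, and what
    remains is weighted by channel reliability.  ΔS = 1 corresponds to the
    model's discrimination threshold.

Achromatic contrast is handled separately via the double cone's Michelson
contrast (step 6 never sees intensity by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .receptors import RECEPTOR_ORDER, VisualSystem
from .spectra import Spectrum, SpectrumError, UnitRoleError, resample

__all__ = [
    "CatchSet",
    "NoiseModel",
    "quantum_catch",
    "adaptation_coefficients",
    "catch_set",
    "relative_catches",
    "receptor_contrast",
    "weber_fractions",
    "delta_S",
    "delta_S_general",
    "michelson_contrast",
    "stimulus_contrast",
]


class DegenerateBackgroundError(ValueError):
    """The adapting background produces zero catch in some receptor."""


@dataclass(frozen=True)
class CatchSet:
    """Quantum catches per receptor class for one stimulus.

    ``adapted`` records whether the von Kries gains of a background have
    been applied; adapted catches of the adapting background itself are 1
    in every receptor.
    """
    Q: Mapping[str, float]
    adapted: bool = False
    background_id: str = ""

    def __post_init__(self) -> None:
        if any(q < 0 for q in self.Q.values()):
            raise ValueError("quantum catches must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.Q[r] for r in RECEPTOR_ORDER])


@dataclass(frozen=True)
class NoiseModel:
    """Limiting Weber fractions ω_i per receptor channel."""
    omega: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.omega.values()):
            raise ValueError("Weber fractions must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.omega[r] for r in RECEPTOR_ORDER])


def quantum_catch(R: Spectrum, L: Spectrum) -> float:
    """Trapezoid integral of R·L over the receptor's grid (300-700 nm)."""
    if L.unit_role != "quantum_radiance":
        raise UnitRoleError(
            f"stimulus must be quantum_radiance, got {L.unit_role}")
    grid = R.wavelengths_nm
    lo, hi = max(grid[0], L.wavelengths_nm[0]), min(grid[-1], L.wavelengths_nm[-1])
    if hi <= lo:
        raise SpectrumError("sensitivity and stimulus grids do not overlap")
    g = grid[(grid >= lo) & (grid <= hi)]
    rv = resample(R, g).values
    lv = resample(L, g).values
    return float(np.trapezoid(rv * lv, g))


def adaptation_coefficients(vs: VisualSystem,
                            background: Spectrum) -> dict[str, float]:
    """von Kries gains k_i = 1/∫R_i·L_b so the background catches are all 1."""
    ks: dict[str, float] = {}
    for rec in RECEPTOR_ORDER:
        c = quantum_catch(vs.sensitivities[rec], background)
        if c <= 0:
            raise DegenerateBackgroundError(
                f"background yields zero catch in {rec}; "
                "adaptation undefined")
        ks[rec] = 1.0 / c
    return ks


def catch_set(vs: VisualSystem, stimulus: Spectrum,
              adapt_to: Spectrum | None = None,
              background_id: str = "") -> CatchSet:
    """Quantum catches of a stimulus, optionally von Kries adapted."""
    ks = (adaptation_coefficients(vs, adapt_to)
          if adapt_to is not None else {r: 1.0 for r in RECEPTOR_ORDER})
    Q = {r: ks[r] * quantum_catch(vs.sensitivities[r], stimulus)
         for r in RECEPTOR_ORDER}
    return CatchSet(Q, adapted=adapt_to is not None,
                    background_id=background_id)


def relative_catches(c: CatchSet) -> dict[str, float]:
    """Chromaticity coordinates q_i = Q_i/ΣQ_j (sum to 1)."""
    total = sum(c.Q.values())
    if total <= 0:
        raise ValueError("all catches are zero; chromaticity undefined")
    return {r: c.Q[r] / total for r in RECEPTOR_ORDER}


def receptor_contrast(c1: CatchSet, c2: CatchSet) -> dict[str, float]:
    """Log catch ratios Δf_i = ln(Q_i,1/Q_i,2) between two stimuli.

    Both catch sets must be adapted to the same background.
    """
    if c1.adapted != c2.adapted or c1.background_id != c2.background_id:
        raise ValueError("catch sets are adapted to different backgrounds")
    df: dict[str, float] = {}
    for r in RECEPTOR_ORDER:
        if c1.Q[r] <= 0 or c2.Q[r] <= 0:
            raise ValueError(
                f"zero quantum catch in {r}: log contrast undefined")
        df[r] = float(np.log(c1.Q[r] / c2.Q[r]))
    return df


def weber_fractions(weber_lws: float, abundances: Mapping[str, float],
                    scaling: str = "sqrt") -> NoiseModel:
    """Per-channel Weber fractions from an LWS anchor and cone abundances.

    A single cone has noise-to-signal ratio v; pooling η_i cones per
    receptive field reduces channel noise as ω_i = v/√η_i (``sqrt``, the
    standard RNL convention) or ω_i = v/η_i (``linear``).  v is inferred
    from the stated LWS Weber fraction and η_LWS.
    """
    if weber_lws <= 0:
        raise ValueError("weber_lws must be positive")
    if any(abundances[r] <= 0 for r in RECEPTOR_ORDER):
        raise ValueError("abundances must be positive")
    pool = (np.sqrt if scaling == "sqrt" else np.asarray) if scaling in (
        "sqrt", "linear") else None
    if pool is None:
        raise ValueError("scaling must be 'sqrt' or 'linear'")

    def eff(eta: float) -> float:
        return float(np.sqrt(eta)) if scaling == "sqrt" else float(eta)

    v = weber_lws * eff(abundances["LWS"])
    return NoiseModel({r: v / eff(abundances[r]) for r in RECEPTOR_ORDER})


def delta_S(df: Mapping[str, float], noise: NoiseModel) -> float:
    """Tetrachromatic RNL colour distance in JND units.

    Closed form over the six receptor pairs:

        ΔS² = Σ_{i<j} (ω_k ω_l)² (Δf_i - Δf_j)²  /  Σ_m (Π_{n≠m} ω_n)²

    where for each pair {i,j}, {k,l} are the two remaining receptors.
    Pure intensity shifts (equal Δf in all channels) give exactly 0.
    """
    if set(df) != set(RECEPTOR_ORDER):
        raise ValueError(
            f"closed form requires the four receptors {RECEPTOR_ORDER}; "
            "use delta_S_general for other channel counts")
    f = np.array([df[r] for r in RECEPTOR_ORDER])
    w = noise.as_array()
    u, s, m, l = w
    fu, fs, fm, fl = f
    num = ((u * s) ** 2 * (fl - fm) ** 2
           + (u * m) ** 2 * (fl - fs) ** 2
           + (u * l) ** 2 * (fm - fs) ** 2
           + (s * m) ** 2 * (fl - fu) ** 2
           + (s * l) ** 2 * (fm - fu) ** 2
           + (m * l) ** 2 * (fs - fu) ** 2)
    den = ((u * s * m) ** 2 + (u * s * l) ** 2
           + (u * m * l) ** 2 + (s * m * l) ** 2)
    return float(np.sqrt(num / den))


def delta_S_general(df: np.ndarray, omega: np.ndarray) -> float:
    """RNL distance for any number of channels n ≥ 2.

    Evaluates min_c Σ_i (Δf_i - c)²/ω_i² at its analytic optimum (the
    noise-weighted mean of Δf), which reduces to the pairwise closed form
    for n = 4.
    """
    df = np.asarray(df, dtype=float)
    w = 1.0 / np.asarray(omega, dtype=float) ** 2
    if df.size < 2:
        raise ValueError("need at least two receptor channels")
    c = np.sum(w * df) / np.sum(w)
    return float(np.sqrt(np.sum(w * (df - c) ** 2)))


def michelson_contrast(qd1: float, qd2: float) -> float:
    """Double-cone Michelson contrast (Qmax - Qmin)/(Qmax + Qmin) ∈ [0, 1]."""
    if qd1 < 0 or qd2 < 0:
        raise ValueError("catches must be non-negative")
    if qd1 + qd2 == 0:
        raise ValueError("Michelson contrast undefined for two zero catches")
    hi, lo = max(qd1, qd2), min(qd1, qd2)
    return (hi - lo) / (hi + lo)


def stimulus_contrast(vs: VisualSystem, stim1: Spectrum, stim2: Spectrum,
                      background: Spectrum) -> float:
    """ΔS (JND) between two stimuli with receptors adapted to a background."""
    c1 = catch_set(vs, stim1, adapt_to=background, background_id="bg")
    c2 = catch_set(vs, stim2, adapt_to=background, background_id="bg")
    noise = weber_fractions(vs.weber_lws, vs.abundances, vs.noise_scaling)
    return delta_S(receptor_contrast(c1, c2), noise)
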