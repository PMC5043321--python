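"""Synthetic study generator: monitor spectra, stimulus series, observers.

This module fabricates every input the analysis pipeline needs, emulating a
two-alternative choice experiment on colour discrimination against adapting
backgrounds:

* monitor-like stimulus spectra as sums of Gaussian primaries (peaks near
  450/550/610 nm — an arbitrary but plausible RGB gamut);
* a grey-to-red saturation series whose steps are solved to sit at a target
  ladder of JND contrasts against the rewarded red endpoint (default ladder
  0.1, 0.6, 2.1, 3.7, 5.2, 6.9 JND, adapted to the grey background), with
  all discs balanced to equal double-cone catch (Michelson contrast 0,
  comfortably under the 4% balance criterion);
* constrained pseudo-random left/right reward schedules (no more than four
  consecutive rewarded presentations on one side);
* simulated observers whose true psychometric functions follow a clamped
  linear dependence of threshold on background contrast, producing binomial
  choice counts (default 30 per level).

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .contrast import michelson_contrast, quantum_catch, stimulus_contrast
from .psychometrics import LevelData, psi
from .receptors import VisualSystem, load_visual_system
from .spectra import DEFAULT_GRID, Spectrum, write_spectrum
from .thresholds import RNL_FLOOR_JND

__all__ = [
    "MonitorModel",
    "SimulatedObserver",
    "synth_spectrum",
    "make_saturation_series",
    "calibrate_series_to_jnds",
    "fellows_schedule",
    "simulate_session",
    "StudyDesign",
    "default_visual_system",
    "build_study",
    "write_fixture_set",
]

#: Stimulus ladder of the discrimination task: JND contrast of each
#: non-rewarded disc against the rewarded red disc (grey-background
#: adaptation).
DISCRIMINATION_LADDER = (0.1, 0.6, 2.1, 3.7, 5.2, 6.9)

#: Ladder of the chromatic detection task: JND contrast of the single
#: presented disc against the grey background.
DETECTION_LADDER = (1.0, 1.7, 3.1, 4.8, 6.3, 6.8)

TRIALS_PER_LEVEL = 30
MAX_SIDE_RUN = 4


@dataclass(frozen=True)
class MonitorModel:
    """Additive display model: Gaussian primaries on the canonical grid."""
    peaks_nm: tuple[float, ...] = (450.0, 550.0, 610.0)
    bandwidths_nm: tuple[float, ...] = (30.0, 35.0, 35.0)
    max_radiance: tuple[float, ...] = (1e12, 1e12, 1e12)

    def __post_init__(self) -> None:
        n = len(self.peaks_nm)
        if n < 3:
            raise ValueError("need at least three primaries")
        if len(self.bandwidths_nm) != n or len(self.max_radiance) != n:
            raise ValueError("primary parameter lengths disagree")
        if (min(self.peaks_nm) <= 0 or min(self.bandwidths_nm) <= 0
                or min(self.max_radiance) <= 0):
            raise ValueError("all monitor parameters must be positive")


def synth_spectrum(model: MonitorModel, weights: Sequence[float],
                   name: str = "") -> Spectrum:
    """Quantum-radiance spectrum of the monitor at given drive levels."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(model.peaks_nm),):
        raise ValueError("one weight per primary required")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("drive weights must lie in [0, 1]")
    vals = np.zeros_like(DEFAULT_GRID)
    for wi, mu, sigma, amp in zip(w, model.peaks_nm, model.bandwidths_nm,
                                  model.max_radiance):
        vals += wi * amp * np.exp(-0.5 * ((DEFAULT_GRID - mu) / sigma) ** 2)
    return Spectrum(DEFAULT_GRID, vals, "quantum_radiance", name)


def _mixture(grey: Spectrum, red: Spectrum, t: float) -> Spectrum:
    vals = (1.0 - t) * grey.values + t * red.values
    return Spectrum(grey.wavelengths_nm, vals, "quantum_radiance",
                    f"mix_{t:.4f}")


def _balance_to_reference(spec: Spectrum, ref: Spectrum,
                          vs: VisualSystem) -> Spectrum:
    """Scale a stimulus so its double-cone catch equals the reference's."""
    q = quantum_catch(vs.double_cone, spec)
    q_ref = quantum_catch(vs.double_cone, ref)
    return spec.scaled(q_ref / q)


def make_saturation_series(grey: Spectrum, red: Spectrum, n_steps: int,
                           vs: VisualSystem, background: Spectrum,
                           balance_intensity: bool = True) -> dict:
    """Convex grey→red mixtures with their JND contrasts.

    Returns the series spectra plus each element's JND distance to the red
    endpoint and to the background, both under adaptation to the
    background.  With ``balance_intensity`` every element is rescaled to
    the red endpoint's double-cone catch, so all pairwise double-cone
    Michelson contrasts are ~0 (well inside a 4% balance criterion).
    """
    if n_steps < 2:
        raise ValueError("need at least two steps")
    if not np.array_equal(grey.wavelengths_nm, red.wavelengths_nm):
        raise ValueError("endpoints must share a wavelength grid")
    ts = np.linspace(0.0, 1.0, n_steps)
    series = [_mixture(grey, red, float(t)) for t in ts]
    if balance_intensity:
        series = [_balance_to_reference(s, red, vs) for s in series]
        series[-1] = red
    jnd_to_red = [stimulus_contrast(vs, s, red, background) for s in series]
    jnd_to_bg = [stimulus_contrast(vs, s, background, background)
                 for s in series]
    return {"mixing": ts, "spectra": series,
            "jnd_to_red": np.array(jnd_to_red),
            "jnd_to_background": np.array(jnd_to_bg)}


def calibrate_series_to_jnds(grey: Spectrum, red: Spectrum,
                             targets: Sequence[float], vs: VisualSystem,
                             background: Spectrum,
                             balance_intensity: bool = True
                             ) -> list[Spectrum]:
    """Solve mixture fractions so each disc sits at a target JND contrast
    to the red endpoint (adapted to ``background``).

    The contrast is monotone decreasing in the red fraction t, so each
    target is found by bracketed root finding.  Targets beyond the grey
    endpoint's contrast are unreachable and raise.
    """
    def contrast_at(t: float) -> float:
        s = _mixture(grey, red, t)
        if balance_intensity:
            s = _balance_to_reference(s, red, vs)
        return stimulus_contrast(vs, s, red, background)

    max_c = contrast_at(0.0)
    out = []
    for target in targets:
        if target < 0 or target > max_c:
            raise ValueError(
                f"target {target} JND outside attainable range [0, {max_c:.2f}]")
        if target == 0:
            out.append(red)
            continue
        t_star = optimize.brentq(lambda t: contrast_at(t) - target,
                                 0.0, 1.0, xtol=1e-10)
        s = _mixture(grey, red, float(t_star))
        if balance_intensity:
            s = _balance_to_reference(s, red, vs)
        out.append(Spectrum(s.wavelengths_nm, s.values, "quantum_radiance",
                            f"disc_{target:g}jnd"))
    return out


def fellows_schedule(n_trials: int, max_run: int = MAX_SIDE_RUN,
                     seed: int = 0) -> list[str]:
    """Balanced pseudo-random left/right schedule with a run-length cap.

    Sides are drawn without replacement from an (as even as possible)
    left/right pool; whenever ``max_run`` identical sides have just been
    dealt, the other side is forced.  Rare dead ends (the forced side
    exhausted) restart the deal.  Reproducible for a given seed.
    """
    if n_trials < 1 or max_run < 1:
        raise ValueError("n_trials and max_run must be >= 1")
    rng = np.random.default_rng(seed)
    n_left = n_trials // 2 + (int(rng.integers(2)) if n_trials % 2 else 0)
    for _ in range(1000):
        remaining = {"left": n_left, "right": n_trials - n_left}
        seq: list[str] = []
        ok = True
        while len(seq) < n_trials:
            run_side = seq[-1] if seq else None
            run_len = 0
            for s in reversed(seq):
                if s == run_side:
                    run_len += 1
                else:
                    break
            choices = [s for s in ("left", "right") if remaining[s] > 0]
            if run_len >= max_run and run_side in choices and len(choices) > 1:
                choices.remove(run_side)
            elif run_len >= max_run and choices == [run_side]:
                ok = False
                break
            probs = np.array([remaining[s] for s in choices], dtype=float)
            side = str(rng.choice(choices, p=probs / probs.sum()))
            seq.append(side)
            remaining[side] -= 1
        if ok:
            return seq
    raise RuntimeError(
        f"could not satisfy schedule constraints (n={n_trials}, "
        f"max_run={max_run})")


@dataclass(frozen=True)
class SimulatedObserver:
    """A stochastic observer with a known logistic psychometric function."""
    position: float           # a
    steepness: float = 0.8    # b
    lapse_rate: float = 0.05
    guess_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if not 0.0 <= self.lapse_rate <= 0.25:
            raise ValueError("lapse rate must lie in [0, 0.25]")

    @classmethod
    def from_threshold(cls, threshold: float, criterion: float,
                       steepness: float = 0.8,
                       lapse_rate: float = 0.05) -> "SimulatedObserver":
        """Place the curve so its criterion crossing equals ``threshold``."""
        g = 0.5
        ratio = (1.0 - g - lapse_rate) / (criterion - g) - 1.0
        a = threshold + steepness * np.log(ratio)
        return cls(position=float(a), steepness=steepness,
                   lapse_rate=lapse_rate)

    def p_correct(self, x) -> float:
        return psi(x, self.guess_rate, self.lapse_rate,
                   self.position, self.steepness)


def simulate_session(obs: SimulatedObserver, levels: Sequence[float],
                     trials_per_level: int = TRIALS_PER_LEVEL,
                     seed: int = 0) -> list[LevelData]:
    """Binomial choice counts per stimulus level for one observer."""
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    rng = np.random.default_rng(seed)
    out = []
    for x in levels:
        p = obs.p_correct(float(x))
        k = int(rng.binomial(trials_per_level, p))
        out.append(LevelData(float(x), trials_per_level, k))
    return out


def default_visual_system() -> VisualSystem:
    """The packaged example (zebra finch-like) visual system."""
    path = resources.files("rnlcolour.data") / "zebra_finch_example.yaml"
    return load_visual_system(str(path))


#: Drive weights of the synthetic backgrounds and disc endpoints.
_BACKGROUND_WEIGHTS = {
    "medium_red": (0.13, 0.34, 0.50),
    "yellow": (0.12, 0.50, 0.46),
    "grey": (0.45, 0.45, 0.45),
    "bright_grey": (0.60, 0.60, 0.60),
    "green": (0.06, 0.75, 0.10),
}
_RED_DISC_WEIGHTS = (0.19, 0.32, 0.72)
_GREY_DISC_WEIGHTS = (0.45, 0.45, 0.45)

#: Generating threshold-vs-background-contrast law of the simulated birds:
#: threshold = max(1, intercept + slope·bg_contrast); slope of 0.26 with a
#: modest intercept keeps the study backgrounds in the linear regime, and a
#: detection threshold of 2.8 JND sits inside the 2.5-3.2 JND band typical
#: of chromatic detection on an adapting background.
TRUE_SLOPE = 0.26
TRUE_INTERCEPT = 0.60
TRUE_DETECTION_THRESHOLD = 2.8


@dataclass
class StudyDesign:
    """Everything one synthetic run of the experiment produced."""
    visual_system: VisualSystem
    monitor: MonitorModel
    backgrounds: dict[str, Spectrum]
    reward_disc: Spectrum
    disc_series: list[Spectrum]
    background_contrasts: dict[str, float]   # reward vs background, JND
    true_thresholds: dict[str, float]
    observers: dict[str, SimulatedObserver]
    trials: dict[str, list[LevelData]]       # per condition
    detection_trials: list[LevelData] = field(default_factory=list)
    criterion: float = 2.0 / 3.0
    seed: int = 0


def build_study(seed: int = 0,
                trials_per_level: int = TRIALS_PER_LEVEL,
                vs: VisualSystem | None = None,
                n_subjects: int = 1) -> StudyDesign:
    """Simulate the full experiment for one (or several pooled) observer(s).

    Study conditions mirror the behavioural design: four discrimination
    backgrounds (medium red, yellow, grey, green) plus a bright grey
    control of identical chromaticity, a six-step disc ladder at the
    default JND contrasts, 30 choices per level, and one chromatic
    detection series on the grey background at zero background contrast.
    """
    rng = np.random.default_rng(seed)
    vs = vs or default_visual_system()
    monitor = MonitorModel()
    backgrounds = {name: synth_spectrum(monitor, w, name=name)
                   for name, w in _BACKGROUND_WEIGHTS.items()}
    grey_disc = synth_spectrum(monitor, _GREY_DISC_WEIGHTS, "disc_grey")
    red = synth_spectrum(monitor, _RED_DISC_WEIGHTS, "disc_red")
    red = _balance_to_reference(red, grey_disc, vs)

    discs = calibrate_series_to_jnds(grey_disc, red, DISCRIMINATION_LADDER,
                                     vs, backgrounds["grey"])

    bg_contrast = {name: stimulus_contrast(vs, red, bg, bg)
                   for name, bg in backgrounds.items()}

    true_thr = {name: max(RNL_FLOOR_JND,
                          TRUE_INTERCEPT + TRUE_SLOPE * bg_contrast[name])
                for name in backgrounds}
    true_thr["detection"] = TRUE_DETECTION_THRESHOLD

    criterion = 2.0 / 3.0
    observers: dict[str, SimulatedObserver] = {}
    trials: dict[str, list[LevelData]] = {}
    for name in backgrounds:
        obs = SimulatedObserver.from_threshold(true_thr[name], criterion)
        observers[name] = obs
        trials[name] = simulate_session(
            obs, DISCRIMINATION_LADDER, trials_per_level,
            seed=int(rng.integers(2**31)))
    det_obs = SimulatedObserver.from_threshold(true_thr["detection"],
                                               criterion)
    observers["detection"] = det_obs
    detection = simulate_session(det_obs, DETECTION_LADDER, trials_per_level,
                                 seed=int(rng.integers(2**31)))

    return StudyDesign(visual_system=vs, monitor=monitor,
                       backgrounds=backgrounds, reward_disc=red,
                       disc_series=discs, background_contrasts=bg_contrast,
                       true_thresholds=true_thr, observers=observers,
                       trials=trials, detection_trials=detection,
                       criterion=criterion, seed=seed)


def write_fixture_set(outdir: str | Path, seed: int = 0,
                      trials_per_level: int = TRIALS_PER_LEVEL) -> Path:
    """Write a complete synthetic data set (spectra, schedules, trials).

    Produces CSVs consumable by the psychometric and threshold-analysis
    stages plus a pipeline config; returns the config path.
    """
    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    (outdir / "trials").mkdir(exist_ok=True)
    study = build_study(seed=seed, trials_per_level=trials_per_level)

    for name, bg in study.backgrounds.items():
        write_spectrum(bg, outdir / "spectra" / f"bg_{name}.csv")
    write_spectrum(study.reward_disc, outdir / "spectra" / "disc_red.csv")
    for target, disc in zip(DISCRIMINATION_LADDER, study.disc_series):
        write_spectrum(disc, outdir / "spectra" / f"disc_{target:g}jnd.csv")

    def dump_trials(name: str, rows: list[LevelData]) -> None:
        with open(outdir / "trials" / f"{name}.csv", "w") as fh:
            fh.write("level,n_trials,n_correct\n")
            for r in rows:
                fh.write(f"{r.level},{r.n_trials},{r.n_correct}\n")

    for name, rows in study.trials.items():
        dump_trials(name, rows)
    dump_trials("detection", study.detection_trials)

    sched = fellows_schedule(trials_per_level * len(DISCRIMINATION_LADDER),
                             MAX_SIDE_RUN, seed=seed)
    with open(outdir / "trials" / "schedule.csv", "w") as fh:
        fh.write("trial,rewarded_side\n")
        for i, side in enumerate(sched, 1):
            fh.write(f"{i},{side}\n")

    from importlib import resources
    vs_src = resources.files("rnlcolour.data") / "zebra_finch_example.yaml"
    (outdir / "visual_system.yaml").write_text(vs_src.read_text())

    cfg_lines = [
        "visual_system: visual_system.yaml",
        "reward_spectrum: spectra/disc_red.csv",
        "criterion: auto",
        "conditions:",
    ]
    for name in study.backgrounds:
        cfg_lines += [
            f"  - name: {name}",
            f"    trials: trials/{name}.csv",
            f"    background: spectra/bg_{name}.csv",
            "    task: discrimination",
        ]
    cfg_lines += [
        "  - name: detection",
        "    trials: trials/detection.csv",
        "    background: spectra/bg_grey.csv",
        "    task: detection",
    ]
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text("\n".join(cfg_lines) + "\n")
    return cfg_path
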