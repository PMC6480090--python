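"""Synthetic triaxial-accelerometer windows with fall and ADL morphology.

The simulator exists so the whole pipeline (augment → normalize → split →
train → evaluate) can be exercised without any sensor recording.  It
emulates the two signatures a wearable fall detector discriminates:

* **ADL** — a gravity baseline (≈1 g) plus a periodic motion component
  (walking/jogging cadence) and sensor noise, with the gravity direction
  randomly oriented per window (people wear devices at arbitrary angles —
  and the rotation-augmentation module then has meaningful work to do).
* **Fall** — the standard biomechanical sequence: a short ADL-like
  pre-fall phase, a free-fall dip where magnitude drops toward zero, a
  single impact spike of several g, then near-stationary rest at gravity.

Magnitudes are in g.  Classes are strongly separable by construction
(an ADL window never reaches the impact-spike range under the default
configuration), so a correct classifier should approach perfect accuracy;
harder overlapping distributions can be generated by narrowing the gap
between ``adl_osc_amplitude``/``fall_impact_peak``/``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import LABEL_ADL, LABEL_FALL, LabeledDataset, Window


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters (magnitudes in g, lengths in samples).

    ``window_length`` must be at least 8 so the four fall phases fit;
    ``fall_impact_peak`` is the (low, high) range the impact magnitude is
    drawn from.
    """

    window_length: int = 25
    gravity: float = 1.0
    adl_osc_amplitude: float = 0.4
    adl_osc_period: float = 10.0
    fall_freefall_floor: float = 0.1
    fall_impact_peak: tuple[float, float] = (3.0, 6.0)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 8:
            raise ValueError("window_length must be >= 8 (phases must fit)")
        lo, hi = self.fall_impact_peak
        if not (hi >= lo > self.gravity > self.fall_freefall_floor >= 0):
            raise ValueError(
                "need impact peak > gravity > freefall floor >= 0")
        if self.noise_sd < 0 or self.adl_osc_amplitude < 0:
            raise ValueError("noise_sd and adl_osc_amplitude must be >= 0")
        if self.adl_osc_period <= 0:
            raise ValueError("adl_osc_period must be positive")


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - astronomically unlikely
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _to_vectors(magnitude: np.ndarray, direction: np.ndarray) -> np.ndarray:
    return np.clip(magnitude, 0.0, None)[:, None] * direction[None, :]


def gen_adl_window(cfg: SimConfig, rng: np.random.Generator) -> Window:
    """One activity-of-daily-living window.

    Magnitude = gravity + sinusoid(random phase) + Gaussian noise, mapped
    onto a random fixed orientation.
    """
    t = np.arange(cfg.window_length, dtype=float)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    magnitude = (cfg.gravity
                 + cfg.adl_osc_amplitude
                 * np.sin(2.0 * np.pi * t / cfg.adl_osc_period + phase)
                 + rng.normal(0.0, cfg.noise_sd, cfg.window_length))
    direction = _random_unit_vector(rng)
    return Window(_to_vectors(magnitude, direction),
                  label=LABEL_ADL, origin="synthetic")


def gen_fall_window(cfg: SimConfig, rng: np.random.Generator) -> Window:
    """One fall window: pre-fall activity → free-fall dip → impact spike →
    rest.

    Phase boundaries are randomized within the window; the impact sample
    carries exactly the drawn peak magnitude (no noise is added to that
    single sample) so the spike is never blurred below the configured range.
    """
    length = cfg.window_length
    # phase lengths: each at least 1 sample, free-fall/rest get the bulk
    n_pre = int(rng.integers(1, max(2, length // 4)))
    n_free = int(rng.integers(2, max(3, length // 4)))
    n_impact = 1
    n_rest = length - n_pre - n_free - n_impact
    if n_rest < 1:
        n_pre, n_free, n_rest = 1, 2, length - 4
        n_impact = 1

    t_pre = np.arange(n_pre, dtype=float)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    pre = (cfg.gravity + cfg.adl_osc_amplitude
           * np.sin(2.0 * np.pi * t_pre / cfg.adl_osc_period + phase))
    # linear descent from gravity to the free-fall floor
    free = np.linspace(cfg.gravity, cfg.fall_freefall_floor, n_free + 1)[1:]
    peak = rng.uniform(*cfg.fall_impact_peak)
    rest = np.full(n_rest, cfg.gravity)

    magnitude = np.concatenate([pre, free, [peak], rest])
    noise = rng.normal(0.0, cfg.noise_sd, length)
    noise[n_pre + n_free] = 0.0  # keep the impact sample at its drawn peak
    floor_idx = n_pre + n_free - 1
    noise[floor_idx] = 0.0       # keep the deepest free-fall sample exact
    magnitude = magnitude + noise

    direction = _random_unit_vector(rng)
    return Window(_to_vectors(magnitude, direction),
                  label=LABEL_FALL, origin="synthetic")


def gen_dataset(cfg: SimConfig, n_fall: int, n_adl: int) -> LabeledDataset:
    """A reproducibly seeded, shuffled dataset of n_fall + n_adl windows."""
    if n_fall < 0 or n_adl < 0:
        raise ValueError("window counts must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    windows = [gen_fall_window(cfg, rng) for _ in range(n_fall)]
    windows += [gen_adl_window(cfg, rng) for _ in range(n_adl)]
    order = rng.permutation(len(windows))
    return LabeledDataset([windows[i] for i in order])


def magnitude_threshold_accuracy(dataset: LabeledDataset,
                                 threshold: float) -> float:
    """Accuracy of the trivial detector `max ‖a(t)‖ > threshold ⇒ fall`.

    A calibration check on the simulator: under the default configuration
    this should be essentially perfect, confirming the classes are
    learnable by design.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    correct = 0
    for w in dataset:
        mags = np.linalg.norm(w.values, axis=1)
        predicted = LABEL_FALL if mags.max() > threshold else LABEL_ADL
        correct += int(predicted == w.label)
    return correct / len(dataset)
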