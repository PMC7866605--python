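"""Seeded generator of two-sensor NIR-like spectra for pipeline testing.

The real study material (dried citrus pericarp measured on its outer skin
and inner capsule) is not publicly deposited, so this module emulates its
statistical structure: five storage-age classes of 40 samples each, spectra
of 2,204 channels from 12,000 down to 3,500 cm^-1, six Gaussian absorption
band groups at the literature wavenumber ranges, multiplicative scatter,
random quadratic baseline drift and channel noise, measured in triplicate
and averaged.

Age affects band amplitudes non-monotonically (rising to mid-age, then
falling), and the discriminative information is split between the sensors
by construction: the outer-skin sensor cannot distinguish the two oldest
classes and the inner-capsule sensor cannot distinguish two mid-age
classes, so only the fused data separates all five ages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .spectra_io import SpectraSet, average_replicates

#: Six absorption band groups: (centre cm^-1, Gaussian sigma cm^-1, base amplitude).
#: Centres sit inside the ranges 9000-8000, 7300-6000, 6000-5500, 5400-4980,
#: 4980-4500 and 4500-4150 cm^-1 (C-H 2nd overtone, O-H 1st overtone, C-H 1st
#: overtone, O-H combination, N-H/O-H combination, C-H combination).
DEFAULT_BANDS = (
    (8500.0, 260.0, 0.35),
    (6650.0, 330.0, 0.55),
    (5750.0, 140.0, 0.45),
    (5190.0, 110.0, 0.60),
    (4740.0, 130.0, 0.50),
    (4325.0, 100.0, 0.40),
)

#: Per-class band-amplitude offsets, per sensor: class -> length-6 vector.
#: Outer skin responds on bands 0/2/4, inner capsule on bands 1/3/5.  The
#: trajectories rise then fall with age, and each sensor leaves one class
#: pair unresolved (outer: 20 vs 25; inner: 10 vs 15) so that neither
#: sensor alone can separate all five ages.
DEFAULT_CLASS_EFFECTS = {
    "outer_skin": {
        5:  (0.000, 0.0, 0.000, 0.0, 0.000, 0.0),
        10: (0.040, 0.0, 0.025, 0.0, -0.030, 0.0),
        15: (0.070, 0.0, 0.045, 0.0, -0.050, 0.0),
        20: (0.030, 0.0, 0.015, 0.0, -0.020, 0.0),
        25: (0.030, 0.0, 0.015, 0.0, -0.020, 0.0),
    },
    "inner_capsule": {
        5:  (0.0, 0.000, 0.0, 0.000, 0.0, 0.000),
        10: (0.0, 0.045, 0.0, 0.030, 0.0, -0.035),
        15: (0.0, 0.045, 0.0, 0.030, 0.0, -0.035),
        20: (0.0, 0.070, 0.0, 0.050, 0.0, -0.055),
        25: (0.0, 0.025, 0.0, 0.015, 0.0, -0.015),
    },
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic two-sensor spectra generator.

    Defaults reproduce the study-scale conditions: 5 age classes x 40
    samples, 2,204 channels over 12,000-3,500 cm^-1, three averaged
    replicates, and artifact magnitudes chosen so that raw spectra are
    baseline/scatter dominated while pretreated, fused data is separable.
    """

    n_per_class: int = 40
    classes: tuple = (5, 10, 15, 20, 25)
    m: int = 2204
    wn_high: float = 12000.0
    wn_low: float = 3500.0
    band_groups: tuple = DEFAULT_BANDS
    class_effects: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in DEFAULT_CLASS_EFFECTS.items()
    })
    scatter_sd: float = 0.05
    baseline_coeffs_sd: float = 0.03
    noise_sd: float = 0.0005
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1 or self.m < 8 or self.replicates < 1:
            raise ValueError("nonpositive or too-small size parameter")
        for c, w, _ in self.band_groups:
            if not (self.wn_low <= c <= self.wn_high) or w <= 0:
                raise ValueError(f"band centre {c} outside grid or bad width")
        for sensor in ("outer_skin", "inner_capsule"):
            if sensor not in self.class_effects:
                raise ValueError(f"class_effects missing sensor {sensor!r}")
            for c in self.classes:
                if c not in self.class_effects[sensor]:
                    raise ValueError(f"class_effects[{sensor!r}] missing class {c!r}")

    @property
    def n(self) -> int:
        return self.n_per_class * len(self.classes)

    @property
    def grid(self) -> np.ndarray:
        # acquisition order: descending wavenumber
        return np.linspace(self.wn_high, self.wn_low, self.m)


def _clean_spectrum(cfg: GeneratorConfig, sensor: str, cls) -> np.ndarray:
    wn = cfg.grid
    eff = cfg.class_effects[sensor][cls]
    out = np.zeros(cfg.m)
    for (centre, width, amp), de in zip(cfg.band_groups, eff):
        out += (amp + de) * np.exp(-((wn - centre) ** 2) / (2.0 * width**2))
    return out


def _sensor_set(cfg: GeneratorConfig, sensor: str, rng: np.random.Generator) -> SpectraSet:
    grid = cfg.grid
    t = np.linspace(0.0, 1.0, cfg.m)  # normalized channel position for baselines
    labels, ids, rows = [], [], []
    for cls in cfg.classes:
        clean = _clean_spectrum(cfg, sensor, cls)
        for i in range(cfg.n_per_class):
            labels.append(cls)
            ids.append(f"y{cls}_{i:03d}")
            rows.append(clean)
    clean_mat = np.stack(rows)

    reps = []
    for _ in range(cfg.replicates):
        scatter = 1.0 + rng.normal(0.0, cfg.scatter_sd, size=(cfg.n, 1))
        coeffs = rng.normal(0.0, cfg.baseline_coeffs_sd, size=(cfg.n, 3))
        baseline = coeffs[:, [0]] + coeffs[:, [1]] * t + coeffs[:, [2]] * t**2
        noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n, cfg.m))
        reps.append(SpectraSet(
            grid=grid,
            intensities=scatter * clean_mat + baseline + noise,
            labels=tuple(labels),
            sensor=sensor,
            sample_ids=tuple(ids),
        ))
    return average_replicates(reps)


def generate(cfg: GeneratorConfig | None = None) -> tuple[SpectraSet, SpectraSet]:
    """Generate the (outer skin, inner capsule) spectra sets.

    Deterministic under a fixed ``cfg.seed``; each sensor draws from its own
    child stream of the master seed, so sensors can be regenerated
    independently.
    """
    cfg = cfg or GeneratorConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(2)
    outer = _sensor_set(cfg, "outer_skin", np.random.default_rng(streams[0]))
    inner = _sensor_set(cfg, "inner_capsule", np.random.default_rng(streams[1]))
    return outer, inner


def describe(cfg: GeneratorConfig | None = None) -> dict:
    """Full provenance record of a generator configuration (JSON-safe)."""
    cfg = cfg or GeneratorConfig()
    rec = asdict(cfg)
    rec["class_effects"] = {
        sensor: {str(k): list(v) for k, v in eff.items()}
        for sensor, eff in rec["class_effects"].items()
    }
    rec["band_groups"] = [list(b) for b in rec["band_groups"]]
    rec["classes"] = list(rec["classes"])
    rec["n_total_per_sensor"] = cfg.n
    digest = hashlib.sha256(
        json.dumps(rec, sort_keys=True).encode()
    ).hexdigest()
    rec["config_sha256"] = digest
    return rec
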