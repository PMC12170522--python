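"""Synthetic spectra and tabular benchmarks with known ground truth.

These generators make every part of the pipeline testable without any
external data: class-discriminative reflectance curves with planted
informative bands (plus the multiplicative/additive scatter that MSC/SNV
are meant to remove and band-wise noise for SG to smooth), generic
feature-selection benchmarks, and an exhaustive-search oracle for the
wrapper objective at small dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .fitness import FitnessConfig, SubsetEvaluator
from .preprocess import SpectraSet

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_seed_spectra",
    "generate_fs_benchmark",
    "exhaustive_oracle",
]


@dataclass
class SyntheticSpec:
    """Parameters of the seed-spectra generator."""

    n_per_class: int = 40
    classes: tuple = ("control", "water_bath", "microwave")
    n_bands: int = 60
    wl_low: float = 395.24
    wl_high: float = 1008.20
    n_informative: int = 8
    informative_bands: tuple | None = None  # explicit indices override n_informative
    effect_size: float = 0.04  # reflectance offset at informative bands
    noise_sigma: float = 0.01
    scatter: bool = True
    scatter_mult: tuple = (0.8, 1.2)
    scatter_add: tuple = (-0.05, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_bands < 2:
            raise ValueError("n_per_class and n_bands must be positive")
        if self.informative_bands is None and not 0 < self.n_informative <= self.n_bands:
            raise ValueError("n_informative must lie in (0, n_bands]")
        if self.informative_bands is not None:
            bad = [i for i in self.informative_bands if not 0 <= i < self.n_bands]
            if bad:
                raise ValueError(f"informative band indices out of range: {bad}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a generated dataset."""

    informative_bands: np.ndarray
    class_means: np.ndarray  # n_classes x D noiseless curves
    params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "informative_bands": [int(i) for i in self.informative_bands],
            "class_means": np.asarray(self.class_means).tolist(),
            "params": self.params,
            "warnings": list(self.warnings),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _base_curve(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth reflectance template: rise over 500-700 nm, flat high NIR."""
    w = wavelengths
    curve = 0.15 + 0.35 / (1.0 + np.exp(-(w - 600.0) / 45.0))
    curve += 0.05 * np.exp(-0.5 * ((w - 750.0) / 35.0) ** 2)
    return curve


def generate_seed_spectra(spec: SyntheticSpec) -> tuple[SpectraSet, SyntheticTruth]:
    """Per-class reflectance curves with planted discriminative bands.

    Each sample is ``b * (base + class effect) + a + noise`` with scatter
    factors ``b``/``a`` drawn per sample and Gaussian band noise, so the MSC,
    SNV and SG transforms each have a defect to correct.
    """
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.classes)
    wavelengths = np.linspace(spec.wl_low, spec.wl_high, spec.n_bands)
    base = _base_curve(wavelengths)

    if spec.informative_bands is not None:
        informative = np.asarray(sorted(spec.informative_bands), dtype=int)
    else:
        informative = np.sort(
            rng.choice(spec.n_bands, size=spec.n_informative, replace=False)
        )

    # class 0 is the untouched control; later classes get signed offsets of
    # graded magnitude at the planted bands
    effects = np.zeros((n_classes, spec.n_bands))
    for c in range(1, n_classes):
        signs = rng.choice([-1.0, 1.0], size=informative.size)
        magnitude = spec.effect_size * (1.0 + 0.5 * (c - 1))
        effects[c, informative] = signs * magnitude

    warnings = []
    if spec.noise_sigma > 0 and spec.effect_size < 2.0 * spec.noise_sigma:
        warnings.append(
            f"effect size {spec.effect_size} below 2x noise sigma "
            f"{spec.noise_sigma}; planted bands may not be recoverable"
        )

    n = spec.n_per_class * n_classes
    reflectance = np.empty((n, spec.n_bands))
    labels = np.empty(n, dtype=object)
    row = 0
    for c, name in enumerate(spec.classes):
        clean = base + effects[c]
        for _ in range(spec.n_per_class):
            if spec.scatter:
                b = rng.uniform(*spec.scatter_mult)
                a = rng.uniform(*spec.scatter_add)
            else:
                b, a = 1.0, 0.0
            noise = (
                rng.normal(0.0, spec.noise_sigma, size=spec.n_bands)
                if spec.noise_sigma > 0
                else 0.0
            )
            reflectance[row] = b * clean + a + noise
            labels[row] = name
            row += 1

    spectra = SpectraSet(
        wavelengths=wavelengths,
        reflectance=reflectance,
        labels=labels,
        sample_ids=np.array([f"s{i:04d}" for i in range(n)]),
    )
    truth = SyntheticTruth(
        informative_bands=informative,
        class_means=base[None, :] + effects,
        params=spec.to_dict(),
        warnings=warnings,
    )
    return spectra, truth


def generate_fs_benchmark(
    n: int,
    d: int,
    n_informative: int,
    n_redundant: int = 0,
    class_sep: float = 2.0,
    n_classes: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Tabular benchmark: informative, redundant and pure-noise columns.

    Informative columns are class-shifted unit Gaussians (class c centred at
    ``c * class_sep``); redundant columns are noisy linear copies of
    informative ones; the rest is standard normal noise.
    """
    if n_informative < 1 or n_informative + n_redundant > d:
        raise ValueError(
            "need 1 <= n_informative and n_informative + n_redundant <= d"
        )
    rng = np.random.default_rng(seed)
    y = np.arange(n) % n_classes
    rng.shuffle(y)
    X = rng.normal(size=(n, d))

    informative = np.arange(n_informative)
    for j in informative:
        X[:, j] += y * class_sep
    redundant = np.arange(n_informative, n_informative + n_redundant)
    for j in redundant:
        src = int(rng.integers(n_informative))
        coef = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
        X[:, j] = coef * X[:, src] + rng.normal(0.0, 0.3, size=n)

    truth = {
        "informative": informative.tolist(),
        "redundant": redundant.tolist(),
        "noise": list(range(n_informative + n_redundant, d)),
        "class_sep": class_sep,
        "seed": seed,
    }
    return X, y, truth


def exhaustive_oracle(
    X: np.ndarray,
    y,
    fitness_cfg: FitnessConfig | None = None,
    d_max: int = 12,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Global optimum of the wrapper objective by full enumeration.

    Evaluates every nonempty mask (``2**d - 1`` of them) and returns the best
    mask, its fitness, and the complete landscape indexed by the mask's
    integer encoding minus one (bit j of the code = column j selected).
    Ties are broken toward smaller subsets, then lower encoding.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if d > d_max:
        raise ValueError(f"refusing exhaustive search over {d} > d_max={d_max} columns")
    evaluator = SubsetEvaluator(X, y, fitness_cfg)
    landscape = np.empty(2**d - 1)
    best_code, best_fit, best_size = -1, np.inf, d + 1
    for code in range(1, 2**d):
        mask = np.array([(code >> j) & 1 for j in range(d)], dtype=bool)
        fit = evaluator(mask)
        landscape[code - 1] = fit
        size = int(mask.sum())
        if fit < best_fit or (fit == best_fit and size < best_size):
            best_code, best_fit, best_size = code, fit, size
    best_mask = np.array([(best_code >> j) & 1 for j in range(d)], dtype=bool)
    return best_mask, float(best_fit), landscape
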