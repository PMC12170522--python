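"""Binary PSO and binary SCA comparators.

Both share the sigmoid binarization, empty-mask repair, greedy best
archiving, and the :class:`~eiaofs.eiao.SelectionResult` trace contract of
the main optimizer, so comparison tables across algorithms are mechanical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .eiao import SelectionResult, binarize

__all__ = ["BaselineConfig", "binary_pso", "binary_sca", "run_algorithm"]


@dataclass
class BaselineConfig:
    """Shared baseline parameterization (budget mirrors the main optimizer)."""

    algorithm: str = "pso"  # "pso" or "sca"
    n_dims: int = 0
    n_agents: int = 20
    max_iter: int = 50
    lb: float = -4.0
    ub: float = 4.0
    threshold_mode: str = "fixed_half"
    # PSO
    c1: float = 2.0
    c2: float = 2.0
    inertia: float = 1.0
    v_max: float = 6.0
    # SCA
    a: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("pso", "sca"):
            raise ValueError(f"unknown baseline algorithm {self.algorithm!r}")
        if self.lb >= self.ub:
            raise ValueError("lb must be strictly below ub")
        for name in ("c1", "c2", "inertia", "v_max", "a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _setup(fitness_fn, cfg: BaselineConfig):
    rng = np.random.default_rng(cfg.seed)
    positions = rng.uniform(cfg.lb, cfg.ub, size=(cfg.n_agents, cfg.n_dims))
    masks, fits = [], np.empty(cfg.n_agents)
    for i in range(cfg.n_agents):
        masks.append(binarize(positions[i], cfg.threshold_mode, rng))
        fits[i] = float(fitness_fn(masks[i]))
    return rng, positions, masks, fits


def binary_pso(fitness_fn, cfg: BaselineConfig, accuracy_fn=None) -> SelectionResult:
    """Sigmoid-binarized particle swarm with inertia/cognitive/social terms."""
    if cfg.n_dims < 2:
        raise ValueError("n_dims must be >= 2")
    rng, positions, masks, fits = _setup(fitness_fn, cfg)
    velocities = np.zeros_like(positions)

    pbest_pos = positions.copy()
    pbest_fit = fits.copy()
    pbest_masks = [m.copy() for m in masks]
    g = int(np.argmin(fits))
    gbest_pos, gbest_mask, gbest_fit = positions[g].copy(), masks[g].copy(), float(fits[g])

    trace = []
    for _ in range(cfg.max_iter):
        for i in range(cfg.n_agents):
            r1 = rng.uniform(size=cfg.n_dims)
            r2 = rng.uniform(size=cfg.n_dims)
            velocities[i] = (
                cfg.inertia * velocities[i]
                + cfg.c1 * r1 * (pbest_pos[i] - positions[i])
                + cfg.c2 * r2 * (gbest_pos - positions[i])
            )
            np.clip(velocities[i], -cfg.v_max, cfg.v_max, out=velocities[i])
            positions[i] = np.clip(positions[i] + velocities[i], cfg.lb, cfg.ub)
            masks[i] = binarize(positions[i], cfg.threshold_mode, rng)
            fits[i] = float(fitness_fn(masks[i]))
            if fits[i] < pbest_fit[i]:
                pbest_pos[i] = positions[i].copy()
                pbest_fit[i] = fits[i]
                pbest_masks[i] = masks[i].copy()
            if fits[i] < gbest_fit:
                gbest_pos = positions[i].copy()
                gbest_mask = masks[i].copy()
                gbest_fit = float(fits[i])
        trace.append(gbest_fit)

    return _result(gbest_mask, gbest_fit, trace, cfg, accuracy_fn)


def binary_sca(fitness_fn, cfg: BaselineConfig, accuracy_fn=None) -> SelectionResult:
    """Sigmoid-binarized sine-cosine search toward the incumbent best.

    The amplitude schedule is ``r1 = a - iter*a/max_iter``, so step sizes
    shrink linearly to zero by the final iteration.
    """
    if cfg.n_dims < 2:
        raise ValueError("n_dims must be >= 2")
    rng, positions, masks, fits = _setup(fitness_fn, cfg)
    g = int(np.argmin(fits))
    gbest_pos, gbest_mask, gbest_fit = positions[g].copy(), masks[g].copy(), float(fits[g])

    trace = []
    for it in range(1, cfg.max_iter + 1):
        r1 = cfg.a - it * cfg.a / cfg.max_iter
        for i in range(cfg.n_agents):
            r2 = rng.uniform(0.0, 2.0 * math.pi, size=cfg.n_dims)
            r3 = rng.uniform(0.0, 2.0, size=cfg.n_dims)
            r4 = rng.uniform(size=cfg.n_dims)
            pull = np.abs(r3 * gbest_pos - positions[i])
            step = np.where(
                r4 < 0.5, r1 * np.sin(r2) * pull, r1 * np.cos(r2) * pull
            )
            positions[i] = np.clip(positions[i] + step, cfg.lb, cfg.ub)
            masks[i] = binarize(positions[i], cfg.threshold_mode, rng)
            fits[i] = float(fitness_fn(masks[i]))
            if fits[i] < gbest_fit:
                gbest_pos = positions[i].copy()
                gbest_mask = masks[i].copy()
                gbest_fit = float(fits[i])
        trace.append(gbest_fit)

    return _result(gbest_mask, gbest_fit, trace, cfg, accuracy_fn)


def _result(mask, fit, trace, cfg, accuracy_fn) -> SelectionResult:
    return SelectionResult(
        best_mask=mask,
        best_fitness=fit,
        best_accuracy=None if accuracy_fn is None else float(accuracy_fn(mask)),
        n_selected=int(mask.sum()),
        trace=trace,
        seed=cfg.seed,
        config=cfg.to_dict(),
    )


def run_algorithm(name: str, fitness_fn, n_dims: int, accuracy_fn=None, **kw) -> SelectionResult:
    """Dispatch by algorithm name: eiao, iao, pso or sca (shared budget keys)."""
    from .eiao import OptimizerConfig, optimize

    name = name.lower()
    if name == "eiao":
        cfg = OptimizerConfig.eiao(n_dims, **kw)
        return optimize(fitness_fn, cfg, accuracy_fn=accuracy_fn)
    if name == "iao":
        cfg = OptimizerConfig.iao(n_dims, **kw)
        return optimize(fitness_fn, cfg, accuracy_fn=accuracy_fn)
    if name in ("pso", "sca"):
        cfg = BaselineConfig(algorithm=name, n_dims=n_dims, **kw)
        fn = binary_pso if name == "pso" else binary_sca
        return fn(fitness_fn, cfg, accuracy_fn=accuracy_fn)
    raise ValueError(f"unknown algorithm {name!r}; choose eiao, iao, pso or sca")
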