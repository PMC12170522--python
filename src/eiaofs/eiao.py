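"""Binary information-acquisition optimizers (EIAO and its IAO ablation).

The optimizer searches a continuous box, maps positions to band masks
through a sigmoid transfer function, and scores masks with a user-supplied
fitness callable (lower is better).  Each iteration runs three update
stages per agent — collect, filter, organize — with greedy per-stage
acceptance, followed by one Laplace crossover between the global best and a
random agent.

The enhanced variant (EIAO) differs from the base algorithm (IAO) by five
switchable components: chaotic-logistic initialization with elite
opposition learning, a second difference pair in the collect stage,
sine/cosine modulation in the filter stage, a Levy-flight jump in the
organize stage, and the Laplace crossover.  With every flag off the code
path reduces exactly to IAO, so ablation comparisons are trajectory-exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "OptimizerConfig",
    "IterationFactors",
    "SelectionResult",
    "logistic_sequence",
    "chaotic_init",
    "elite_opposition",
    "transfer_sigmoid",
    "binarize",
    "subjective_influence",
    "quality_factor",
    "reliability_factor",
    "signed_power",
    "draw_iteration_factors",
    "stage1_collect",
    "stage2_filter",
    "levy_step",
    "stage3_organize",
    "laplace_sample",
    "laplace_crossover",
    "optimize",
]

_DEGENERATE_LOGISTIC = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class OptimizerConfig:
    """Full parameterization of one optimizer run.

    ``dual_difference``, ``sine_cosine_stage2``, ``levy_stage3``,
    ``laplace_crossover`` and ``elite_opposition`` are the enhancement
    switches; all on is the enhanced algorithm, all off is the base one.
    """

    n_dims: int = 0
    n_agents: int = 20
    max_iter: int = 50
    lb: float = -4.0
    ub: float = 4.0
    logistic_mu: float = 4.0
    elite_fraction: float = 0.10
    levy_exponent: float = 1.5
    # fraction of the box width per dimension; large enough that a Levy jump
    # can actually flip sigmoid-thresholded bits at the default +/-4 bounds
    levy_scale: float = 0.3
    laplace_p: float = 0.0
    laplace_q: float = 0.5
    laplace_variant: str = "two_uniform"  # or "as_printed"
    threshold_mode: str = "fixed_half"  # or "uniform_random"
    dual_difference: bool = True
    sine_cosine_stage2: bool = True
    levy_stage3: bool = True
    laplace_crossover: bool = True
    elite_opposition: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dims and self.n_dims < 2:
            raise ValueError("n_dims must be >= 2")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must lie in (0, 1)")
        if self.lb >= self.ub:
            raise ValueError("lb must be strictly below ub")
        if not 1.0 < self.levy_exponent <= 2.0:
            raise ValueError("levy_exponent must lie in (1, 2]")
        if self.laplace_q <= 0:
            raise ValueError("laplace_q must be positive")
        if self.threshold_mode not in ("fixed_half", "uniform_random"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.laplace_variant not in ("two_uniform", "as_printed"):
            raise ValueError(f"unknown laplace variant {self.laplace_variant!r}")
        if self.dual_difference and self.n_agents < 5:
            raise ValueError("dual_difference needs at least 5 agents")
        if not self.dual_difference and self.n_agents < 3:
            raise ValueError("need at least 3 agents")

    @classmethod
    def eiao(cls, n_dims: int, **kw) -> "OptimizerConfig":
        """The enhanced variant (all switches on)."""
        return cls(n_dims=n_dims, **kw)

    @classmethod
    def iao(cls, n_dims: int, **kw) -> "OptimizerConfig":
        """The base variant: every enhancement switched off."""
        kw.update(
            dual_difference=False,
            sine_cosine_stage2=False,
            levy_stage3=False,
            laplace_crossover=False,
            elite_opposition=False,
        )
        return cls(n_dims=n_dims, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IterationFactors:
    """Per-agent, per-iteration scalars driving the three update stages."""

    theta: float  # step weight of the collect stage, U(0,1)
    xi: float  # subjective influence, in [0, 2)
    phi: float  # information quality
    gamma: float  # reliability
    delta: float  # filtering error = signed cos(pi/2*|gamma|)^xi
    lam: float  # organize-stage control = 2*(|gamma| - 2)
    r5: float  # sine/cosine phase, U(0, 2*pi)


@dataclass
class SelectionResult:
    """Outcome of one optimizer run."""

    best_mask: np.ndarray
    best_fitness: float
    best_accuracy: float | None
    n_selected: int
    trace: list
    seed: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        mask = np.asarray(self.best_mask).astype(int)
        return {
            "best_fitness": float(self.best_fitness),
            "best_accuracy": None
            if self.best_accuracy is None
            else float(self.best_accuracy),
            "n_selected": int(self.n_selected),
            "selected_indices": [int(i) for i in np.flatnonzero(mask)],
            "mask_bits": "".join(str(int(b)) for b in mask),
            "seed": int(self.seed),
            "config": self.config,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def save_trace_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration,best_fitness\n")
            for it, f in enumerate(self.trace, start=1):
                fh.write(f"{it},{f!r}\n")


# ---------------------------------------------------------------------------
# initialization


def logistic_sequence(theta0: float, mu: float, n: int) -> np.ndarray:
    """Iterate the logistic map ``theta <- mu*theta*(1-theta)`` n times."""
    if not 0.0 < mu <= 4.0:
        raise ValueError("mu must lie in (0, 4]")
    if any(abs(theta0 - d) < 1e-6 for d in _DEGENERATE_LOGISTIC):
        raise ValueError(f"theta0={theta0} is (near) a degenerate point of the map")
    out = np.empty(n)
    t = theta0
    for i in range(n):
        t = mu * t * (1.0 - t)
        out[i] = t
    return out


def _draw_theta0(rng: np.random.Generator) -> float:
    while True:
        t = float(rng.uniform())
        if all(abs(t - d) >= 1e-6 for d in _DEGENERATE_LOGISTIC):
            return t


def chaotic_init(config: OptimizerConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial positions from per-agent logistic-map sequences, scaled to bounds."""
    pos = np.empty((config.n_agents, config.n_dims))
    for i in range(config.n_agents):
        theta = logistic_sequence(_draw_theta0(rng), config.logistic_mu, config.n_dims)
        pos[i] = (config.ub - config.lb) * theta + config.lb
    return pos


def elite_opposition(
    positions: np.ndarray,
    fitnesses: np.ndarray,
    fitness_of,
    elite_fraction: float,
    lb: float,
    ub: float,
    rng: np.random.Generator,
):
    """Greedy opposition learning on the elite subpopulation.

    For the best ``ceil(elite_fraction*N)`` agents the opposite point
    ``r*(da + db) - x`` is formed inside the elite group's per-dimension
    envelope ``[da, db]``; the better of original and opposite is kept.
    ``fitness_of`` maps a position to ``(mask, fitness)``.
    """
    n = positions.shape[0]
    n_elite = math.ceil(elite_fraction * n)
    elite_idx = np.argsort(fitnesses, kind="stable")[:n_elite]
    da = positions[elite_idx].min(axis=0)
    db = positions[elite_idx].max(axis=0)
    masks_out = {}
    for i in elite_idx:
        r = rng.uniform()
        opposite = np.clip(r * (da + db) - positions[i], lb, ub)
        mask, fit = fitness_of(opposite)
        if fit < fitnesses[i]:
            positions[i] = opposite
            fitnesses[i] = fit
            masks_out[int(i)] = mask
    return positions, fitnesses, masks_out


# ---------------------------------------------------------------------------
# binarization


def transfer_sigmoid(x):
    """S-shaped transfer 1/(1+exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def binarize(x: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Threshold the sigmoid of a position into a band mask.

    An all-zero outcome is repaired by switching one uniformly random bit on,
    since the fitness of an empty subset is undefined.
    """
    t = transfer_sigmoid(x)
    if mode == "fixed_half":
        bits = t >= 0.5
    elif mode == "uniform_random":
        bits = t >= rng.uniform(size=t.shape)
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    bits = bits.astype(bool)
    if not bits.any():
        bits[rng.integers(bits.size)] = True
    return bits


# ---------------------------------------------------------------------------
# iteration factors


def subjective_influence(
    rng: np.random.Generator,
    nu: float | None = None,
    beta_r: float | None = None,
    gamma_r: float | None = None,
) -> float:
    """Chaotic subjective-influence multiplier in [0, 2).

    Computed as ``2 * frac(3.648 * nu * (1-beta) * acos(gamma) * 1e4)`` with
    the three draws uniform on [0, 1].
    """
    nu = float(rng.uniform()) if nu is None else nu
    beta_r = float(rng.uniform()) if beta_r is None else beta_r
    gamma_r = float(rng.uniform()) if gamma_r is None else gamma_r
    return 2.0 * math.fmod(3.648 * nu * (1.0 - beta_r) * math.acos(gamma_r) * 1e4, 1.0)


def quality_factor(
    it: int, max_iter: int, rng: np.random.Generator, delta_r: float | None = None
) -> float:
    """Information-quality factor ``cos(2*delta + 1) * (1 - it/max_iter)``."""
    delta_r = float(rng.uniform()) if delta_r is None else delta_r
    return math.cos(2.0 * delta_r + 1.0) * (1.0 - it / max_iter)


def reliability_factor(it: int, max_iter: int, phi: float) -> float:
    """Reliability ``sin(pi/4 * it/max_iter) + phi + log10(it/max_iter)/8``."""
    if it < 1:
        raise ValueError("iteration index must be >= 1 (log term undefined at 0)")
    frac = it / max_iter
    return math.sin(math.pi / 4.0 * frac) + phi + math.log10(frac) / 8.0


def signed_power(base: float, exponent: float) -> float:
    """``sign(base)*|base|**exponent`` — real-valued for any sign of the base."""
    if base == 0.0:
        return 0.0
    return math.copysign(abs(base) ** exponent, base)


def draw_iteration_factors(
    it: int, max_iter: int, rng: np.random.Generator
) -> IterationFactors:
    """Draw the per-agent scalars for one update (theta, xi, phi, gamma, ...)."""
    theta = float(rng.uniform())
    xi = subjective_influence(rng)
    phi = quality_factor(it, max_iter, rng)
    gamma = reliability_factor(it, max_iter, phi)
    delta = signed_power(math.cos(math.pi / 2.0 * abs(gamma)), xi)
    lam = 2.0 * (abs(gamma) - 2.0)
    r5 = float(rng.uniform(0.0, 2.0 * math.pi))
    return IterationFactors(
        theta=theta, xi=xi, phi=phi, gamma=gamma, delta=delta, lam=lam, r5=r5
    )


# ---------------------------------------------------------------------------
# update stages


def _difference_update(x, xr1, xr2, theta, xr3=None, xr4=None):
    cand = x + theta * (xr1 - xr2)
    if xr3 is not None:
        cand = cand + theta * (xr3 - xr4)
    return cand


def stage1_collect(
    positions: np.ndarray,
    self_idx: int,
    theta: float,
    dual_difference: bool,
    rng: np.random.Generator,
    lb: float,
    ub: float,
) -> np.ndarray:
    """Collect stage: difference-vector step built from random distinct donors."""
    n = positions.shape[0]
    n_donors = 4 if dual_difference else 2
    if n < n_donors + 1:
        raise ValueError(
            f"population of {n} too small for {n_donors} distinct donors"
        )
    pool = np.delete(np.arange(n), self_idx)
    donors = rng.choice(pool, size=n_donors, replace=False)
    x = positions[self_idx]
    if dual_difference:
        r1, r2, r3, r4 = donors
        cand = _difference_update(
            x, positions[r1], positions[r2], theta, positions[r3], positions[r4]
        )
    else:
        r1, r2 = donors
        cand = _difference_update(x, positions[r1], positions[r2], theta)
    return np.clip(cand, lb, ub)


def stage2_filter(
    x: np.ndarray,
    x_rand: np.ndarray,
    factors: IterationFactors,
    sine_cosine: bool,
    rng: np.random.Generator,
    lb: float,
    ub: float,
    branch: float | None = None,
    step: float | None = None,
) -> np.ndarray:
    """Filter stage: move relative to a random reference, scaled by delta.

    With ``sine_cosine`` the step is additionally modulated by sin/cos of the
    phase ``r5``; the branch selector and step weight are uniform draws.
    """
    branch = float(rng.uniform()) if branch is None else branch
    step = float(rng.uniform()) if step is None else step
    diff = x_rand - x
    if sine_cosine:
        if branch < 0.5:
            cand = x - factors.delta * math.sin(factors.r5) * step * diff
        else:
            cand = x + factors.delta * math.cos(factors.r5) * step * diff
    else:
        if branch < 0.5:
            cand = x - factors.delta * step * diff
        else:
            cand = x + factors.delta * step * diff
    return np.clip(cand, lb, ub)


def levy_step(
    n_dims: int,
    exponent: float,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> np.ndarray:
    """Heavy-tailed step via the Mantegna generator, ``u / |v|^(1/exponent)``."""
    if not 1.0 < exponent <= 2.0:
        raise ValueError("exponent must lie in (1, 2]")
    lam = exponent
    sigma_u = (
        math.gamma(1.0 + lam)
        * math.sin(math.pi * lam / 2.0)
        / (math.gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0))
    ) ** (1.0 / lam)
    u = rng.normal(0.0, sigma_u, size=n_dims)
    v = rng.normal(0.0, 1.0, size=n_dims)
    return scale * u / np.abs(v) ** (1.0 / lam)


def stage3_organize(
    x_best: np.ndarray,
    factors: IterationFactors,
    levy_on: bool,
    rng: np.random.Generator,
    lb: float,
    ub: float,
    levy_exponent: float = 1.5,
    levy_scale: float = 0.3,
    levy_vec: np.ndarray | None = None,
) -> np.ndarray:
    """Organize stage: local search around the incumbent best position.

    Two branches keyed on the quality factor phi; both contract the best
    position by ``cos(pi/2 * cbrt(lam))`` and subtract a randomized pull
    toward/away from its dimension mean.  ``levy_on`` adds a heavy-tailed
    jump on top.
    """
    m = float(np.mean(x_best))
    contraction = math.cos(math.pi / 2.0 * math.copysign(abs(factors.lam) ** (1 / 3), factors.lam))
    if factors.phi >= 0.5:
        eps = rng.uniform()
        cand = x_best * contraction - eps * (m - x_best)
    else:
        zeta, kappa, omega = rng.uniform(size=3)
        cand = x_best * contraction - 0.8 * (zeta * kappa * m - (2.0 * omega - 1.0) * x_best)
    if levy_on:
        if levy_vec is None:
            levy_vec = levy_step(
                x_best.size, levy_exponent, rng, scale=levy_scale * (ub - lb)
            )
        cand = cand + levy_vec
    return np.clip(cand, lb, ub)


# ---------------------------------------------------------------------------
# Laplace crossover


def laplace_sample(
    p: float,
    q: float,
    rng: np.random.Generator,
    variant: str = "two_uniform",
    u: float | None = None,
    branch_u: float | None = None,
) -> float:
    """Draw one Laplace-operator deviate.

    ``two_uniform`` uses an independent uniform for the branch and for the
    magnitude, recovering a genuine Laplace(p, q) law.  ``as_printed`` reuses
    a single uniform for both, which leaves a gap in the support around p;
    it is kept for fidelity to the one-draw formulation.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    u = float(rng.uniform()) if u is None else u
    if variant == "as_printed":
        return p - q * math.log(u) if u <= 0.5 else p + q * math.log(u)
    if variant == "two_uniform":
        branch_u = float(rng.uniform()) if branch_u is None else branch_u
        return p - q * math.log(u) if branch_u <= 0.5 else p + q * math.log(u)
    raise ValueError(f"unknown laplace variant {variant!r}")


def laplace_crossover(
    x1: np.ndarray,
    x2: np.ndarray,
    p: float,
    q: float,
    rng: np.random.Generator,
    variant: str = "two_uniform",
    lb: float | None = None,
    ub: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Offspring placed symmetrically around the parents at Laplace distances."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"parent length mismatch: {x1.shape} vs {x2.shape}")
    ell = np.array([laplace_sample(p, q, rng, variant) for _ in range(x1.size)])
    gap = np.abs(x1 - x2)
    y1 = x1 + ell * gap
    y2 = x2 + ell * gap
    if lb is not None:
        y1 = np.clip(y1, lb, ub)
        y2 = np.clip(y2, lb, ub)
    return y1, y2


# ---------------------------------------------------------------------------
# the main loop


def optimize(fitness_fn, config: OptimizerConfig, accuracy_fn=None) -> SelectionResult:
    """Run the configured optimizer against a mask-valued fitness function.

    ``fitness_fn`` maps a boolean mask to a real score, lower better.  All
    randomness comes from ``config.seed``, so identical configs reproduce
    bit-identical results.  Candidate positions are accepted per stage only
    when their binarized fitness strictly improves the agent's; the global
    best is archived across every evaluation, so the returned trace is
    non-increasing.
    """
    if config.n_dims < 2:
        raise ValueError("n_dims must be >= 2")
    rng = np.random.default_rng(config.seed)
    lb, ub = config.lb, config.ub

    def evaluate(position, where):
        mask = binarize(position, config.threshold_mode, rng)
        try:
            fit = float(fitness_fn(mask))
        except Exception as exc:  # re-raise with loop context
            raise RuntimeError(f"fitness function failed at {where}") from exc
        return mask, fit

    if config.elite_opposition:
        positions = chaotic_init(config, rng)
    else:
        positions = rng.uniform(lb, ub, size=(config.n_agents, config.n_dims))

    masks = []
    fits = np.empty(config.n_agents)
    for i in range(config.n_agents):
        mask, fits[i] = evaluate(positions[i], f"init agent {i}")
        masks.append(mask)

    if config.elite_opposition:
        positions, fits, new_masks = elite_opposition(
            positions,
            fits,
            lambda pos: evaluate(pos, "elite opposition"),
            config.elite_fraction,
            lb,
            ub,
            rng,
        )
        for i, mask in new_masks.items():
            masks[i] = mask

    best = int(np.argmin(fits))
    gbest_pos = positions[best].copy()
    gbest_mask = masks[best].copy()
    gbest_fit = float(fits[best])

    def archive(position, mask, fit):
        nonlocal gbest_pos, gbest_mask, gbest_fit
        if fit < gbest_fit:
            gbest_pos = position.copy()
            gbest_mask = mask.copy()
            gbest_fit = fit

    trace = []
    for it in range(1, config.max_iter + 1):
        for i in range(config.n_agents):
            factors = draw_iteration_factors(it, config.max_iter, rng)
            where = f"iteration {it}, agent {i}"

            cand = stage1_collect(
                positions, i, factors.theta, config.dual_difference, rng, lb, ub
            )
            mask, fit = evaluate(cand, where + " (collect)")
            archive(cand, mask, fit)
            if fit < fits[i]:
                positions[i], masks[i], fits[i] = cand, mask, fit

            j = int(rng.integers(config.n_agents))
            cand = stage2_filter(
                positions[i],
                positions[j],
                factors,
                config.sine_cosine_stage2,
                rng,
                lb,
                ub,
            )
            mask, fit = evaluate(cand, where + " (filter)")
            archive(cand, mask, fit)
            if fit < fits[i]:
                positions[i], masks[i], fits[i] = cand, mask, fit

            cand = stage3_organize(
                gbest_pos,
                factors,
                config.levy_stage3,
                rng,
                lb,
                ub,
                levy_exponent=config.levy_exponent,
                levy_scale=config.levy_scale,
            )
            mask, fit = evaluate(cand, where + " (organize)")
            archive(cand, mask, fit)
            if fit < fits[i]:
                positions[i], masks[i], fits[i] = cand, mask, fit

        if config.laplace_crossover:
            j = int(rng.integers(config.n_agents))
            y1, y2 = laplace_crossover(
                gbest_pos,
                positions[j],
                config.laplace_p,
                config.laplace_q,
                rng,
                variant=config.laplace_variant,
                lb=lb,
                ub=ub,
            )
            m1, f1 = evaluate(y1, f"iteration {it} (crossover y1)")
            archive(y1, m1, f1)
            m2, f2 = evaluate(y2, f"iteration {it} (crossover y2)")
            archive(y2, m2, f2)
            if f1 < f2:
                yb, mb, fb = y1, m1, f1
            else:
                yb, mb, fb = y2, m2, f2
            if fb < fits[j]:
                positions[j], masks[j], fits[j] = yb, mb, fb

        trace.append(gbest_fit)

    best_accuracy = None if accuracy_fn is None else float(accuracy_fn(gbest_mask))
    return SelectionResult(
        best_mask=gbest_mask,
        best_fitness=gbest_fit,
        best_accuracy=best_accuracy,
        n_selected=int(gbest_mask.sum()),
        trace=trace,
        seed=config.seed,
        config=config.to_dict(),
    )
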