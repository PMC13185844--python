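"""Characterisation-in-the-loop stiffness seeking.

The goal: find the grayscale dose g* in [G_min, G_max] whose printed
construct measures a target bulk modulus E_target, given only noisy oracle
access to the unknown material response f(g) — print at g, compress, record
E.  Because each evaluation costs one print, the loop is a zero-order
(continuum-armed bandit) scheme:

* **gradient estimation** — finite differences over the most recent
  evaluation pairs, smoothed by an exponential moving average
  ``grad <- (1 - alpha) * grad + alpha * grad_new``, with a confidence
  counter ``c <- min(1, c + dc)`` incremented per successful update;
* **adaptive control** — a Newton-like step
  ``g_next = g + (E_target - E) / grad`` when the gradient is trusted
  (c > c_min and |grad| > eps), otherwise proportional control
  ``g_next = g + lambda * (E_target - E) / E_target``;
* **exploration** — additive Gaussian noise with standard deviation
  ``sigma_k = sigma0 * exp(-k / tau)``, decaying so late iterations exploit;
* **convergence** — terminate once ``|E_k - E_target| / E_target <= eps_tol``
  or the iteration budget k_max is spent.

Proposals are kept continuous internally and clamped (not resampled) to the
grayscale bounds, so the iteration count is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError, EmptyFeasibleSetError, NoGradientError

__all__ = [
    "SeekConfig",
    "SeekState",
    "SeekResult",
    "FidelityMap",
    "LineProtocolOracle",
    "bound_grayscale",
    "finite_difference_gradient",
    "ema_update",
    "confidence_update",
    "propose_next",
    "converged",
    "seek",
]

FULL_GRAYSCALE_BOUNDS = (1.0, 255.0)


@dataclass(frozen=True)
class SeekConfig:
    """Constants of the seek loop.

    The paper-level quantities are the grayscale bounds and the convergence
    tolerance; the remaining gains are implementation defaults, every one
    config-exposed.  Units: gradients in Pa per grayscale unit, sigma0 in
    grayscale units.
    """

    G_min: float = FULL_GRAYSCALE_BOUNDS[0]
    G_max: float = FULL_GRAYSCALE_BOUNDS[1]
    learn_alpha: float = 0.5  # EMA rate
    conf_delta: float = 0.34  # confidence increment per gradient update
    conf_min: float = 0.5  # confidence gate for Newton control
    grad_eps: float = 1.0  # |gradient| gate, Pa per grayscale unit
    prop_gain_lambda: float = 30.0  # proportional gain, grayscale units
    sigma0: float = 5.0  # initial exploration sd, grayscale units
    tau: float = 3.0  # exploration decay constant, iterations
    explore: bool = True
    k_max: int = 20
    eps_tol: float = 0.03  # relative modulus tolerance
    n_recent: int = 3  # pairs in the finite-difference mean
    delta_g_min: float = 0.5  # minimum |dg| for an admissible pair
    init_mode: str = "midpoint"  # midpoint | lower | upper | given
    init_g: float | None = None  # used when init_mode == "given"
    seed: int | None = None

    def __post_init__(self):
        if not self.G_min < self.G_max:
            raise DomainError("require G_min < G_max")
        if not 0.0 <= self.learn_alpha <= 1.0:
            raise DomainError("learn_alpha must lie in [0, 1]")
        if self.eps_tol <= 0:
            raise DomainError("eps_tol must be positive")
        if self.k_max < 1:
            raise DomainError("k_max must be >= 1")
        if self.init_mode not in ("midpoint", "lower", "upper", "given"):
            raise DomainError(f"unknown init_mode {self.init_mode!r}")
        if self.init_mode == "given" and self.init_g is None:
            raise DomainError("init_mode 'given' requires init_g")

    def initial_g(self) -> float:
        if self.init_mode == "midpoint":
            return 0.5 * (self.G_min + self.G_max)
        if self.init_mode == "lower":
            return self.G_min
        if self.init_mode == "upper":
            return self.G_max
        return float(np.clip(self.init_g, self.G_min, self.G_max))


@dataclass
class SeekState:
    """Mutable loop state: evaluation history, EMA gradient, confidence."""

    history: list[tuple[float, float]] = field(default_factory=list)  # (g, E_Pa)
    grad_fk: float | None = None  # Pa per grayscale unit; None until first update
    conf_ck: float = 0.0
    k: int = 0  # completed evaluations

    def record(self, g: float, E: float) -> None:
        self.history.append((float(g), float(E)))
        self.k += 1

    @property
    def last(self) -> tuple[float, float]:
        return self.history[-1]


@dataclass(frozen=True)
class SeekResult:
    """Outcome of a seek run, with the full trajectory for telemetry."""

    g_star: float
    E_final: float  # Pa
    iterations: int
    converged: bool
    termination: str  # "converged" | "budget"
    trajectory: tuple[tuple[float, float], ...]  # (g, E_Pa) per iteration
    gradients: tuple[float, ...] = ()
    confidences: tuple[float, ...] = ()
    sigmas: tuple[float, ...] = ()


@dataclass(frozen=True)
class FidelityMap:
    """Resolvability of printed test features versus grayscale.

    ``entries`` holds (g, flag-or-score) pairs from a parametric print sweep;
    scores are binarised at ``threshold``.
    """

    entries: tuple[tuple[float, float], ...]
    threshold: float = 0.5

    def resolvable_g(self) -> np.ndarray:
        if not self.entries:
            return np.empty(0)
        arr = np.asarray(self.entries, dtype=float)
        return arr[arr[:, 1] >= self.threshold, 0]


def bound_grayscale(fmap: FidelityMap | None) -> tuple[float, float]:
    """Grayscale search bounds from a fidelity map.

    (min, max) over the resolvable entries; with no sweep available the full
    8-bit range [1, 255] is used at the expense of convergence speed.
    """
    if fmap is None:
        return FULL_GRAYSCALE_BOUNDS
    g = fmap.resolvable_g()
    if g.size == 0:
        raise EmptyFeasibleSetError("fidelity map has no resolvable entries")
    return float(np.min(g)), float(np.max(g))


def finite_difference_gradient(
    history: Sequence[tuple[float, float]],
    n_recent: int = 3,
    delta_g_min: float = 0.5,
) -> float:
    """Mean difference quotient over the most recent admissible pairs.

    grad = (1/n) sum (E_i - E_{i-1}) / (g_i - g_{i-1}) over the last
    ``n_recent`` consecutive pairs with |dg| >= delta_g_min; smaller spacings
    are excluded because noise dominates the quotient.
    """
    if len(history) < 2:
        raise NoGradientError("need >= 2 evaluations for a finite difference")
    quotients = []
    for (g0, e0), (g1, e1) in zip(history[:-1], history[1:]):
        if abs(g1 - g0) >= delta_g_min:
            quotients.append((e1 - e0) / (g1 - g0))
    if not quotients:
        raise NoGradientError(
            f"no evaluation pair spaced by >= {delta_g_min} grayscale units"
        )
    return float(np.mean(quotients[-n_recent:]))


def ema_update(grad_fk: float, grad_new: float, learn_alpha: float) -> float:
    """Exponential moving average: (1 - alpha) * grad_fk + alpha * grad_new."""
    if not 0.0 <= learn_alpha <= 1.0:
        raise DomainError("learn_alpha must lie in [0, 1]")
    return (1.0 - learn_alpha) * grad_fk + learn_alpha * grad_new


def confidence_update(conf_ck: float, conf_delta: float) -> float:
    """Saturating confidence increment min(1, c + dc)."""
    if not 0.0 <= conf_ck <= 1.0:
        raise DomainError("confidence must lie in [0, 1]")
    return min(1.0, conf_ck + conf_delta)


def exploration_sigma(k: int, config: SeekConfig) -> float:
    """Decaying exploration sd sigma_k = sigma0 * exp(-k / tau)."""
    if not config.explore:
        return 0.0
    return config.sigma0 * float(np.exp(-k / config.tau))


def propose_next(
    state: SeekState,
    E_target: float,
    config: SeekConfig,
    rng: np.random.Generator,
) -> float:
    """Next grayscale: Newton or proportional step + decaying exploration.

    Newton when the gradient is confidently known (c > c_min, |grad| > eps);
    the |grad| gate is two-sided, since a confidently negative slope is just
    as usable.  The result is clamped to [G_min, G_max].

    Stall guard: a Newton step that would re-clamp onto the bound the loop
    already sits on is a deadlock — every new evaluation pair there has zero
    grayscale spacing, so a corrupted gradient estimate could never be
    refreshed.  Such steps fall back to proportional control, which moves
    back into the interior.
    """
    if not state.history:
        raise DomainError("propose_next requires at least one evaluation")
    g_k, E_k = state.last
    use_newton = (
        state.grad_fk is not None
        and state.conf_ck > config.conf_min
        and abs(state.grad_fk) > config.grad_eps
    )
    g_prop = g_k + config.prop_gain_lambda * (E_target - E_k) / E_target
    if use_newton:
        g_pred = g_k + (E_target - E_k) / state.grad_fk
        stalled_high = g_pred >= config.G_max and g_k >= config.G_max
        stalled_low = g_pred <= config.G_min and g_k <= config.G_min
        if stalled_high or stalled_low:
            g_pred = g_prop
    else:
        g_pred = g_prop
    sigma_k = exploration_sigma(state.k, config)
    if sigma_k > 0.0:
        g_pred += sigma_k * rng.standard_normal()
    return float(np.clip(g_pred, config.G_min, config.G_max))


def converged(E_k: float, E_target: float, eps_tol: float) -> bool:
    """Relative-error convergence test |E_k - E_target| / E_target <= eps_tol."""
    if E_target <= 0:
        raise DomainError("E_target must be positive")
    return abs(E_k - E_target) / E_target <= eps_tol


class LineProtocolOracle:
    """Hardware-in-the-loop evaluation over a line-based handshake.

    Each call writes one grayscale value per line to ``command_stream``
    (flushed immediately), then blocks until one measured modulus (Pa)
    arrives per line on ``response_stream``.  Works over FIFOs, sockets
    wrapped as files, or any file-like pair, so a physical printer can stand
    in for the simulated material without changing the loop.
    """

    def __init__(self, command_stream, response_stream):
        self._cmd = command_stream
        self._resp = response_stream

    def __call__(self, g: float) -> float:
        self._cmd.write(f"{float(g):.6f}\n")
        self._cmd.flush()
        line = self._resp.readline()
        if not line:
            raise DomainError("modulus stream closed before a response arrived")
        return float(line)


def seek(
    oracle: Callable[[float], float],
    E_target: float,
    config: SeekConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SeekResult:
    """Run the full stiffness-seeking loop against an evaluation oracle.

    ``oracle(g)`` measures the modulus (Pa) of a construct printed at
    grayscale g — the simulated response in testing, or one physical
    print-and-compress cycle on hardware.  Convergence is checked after each
    measurement, before the next proposal.  Deterministic for a fixed seed
    and oracle.
    """
    config = SeekConfig() if config is None else config
    if E_target <= 0:
        raise DomainError("E_target must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    state = SeekState()
    gradients: list[float] = []
    confidences: list[float] = []
    sigmas: list[float] = []
    g = config.initial_g()
    termination = "budget"

    for _ in range(config.k_max):
        try:
            E = float(oracle(g))
        except Exception as exc:  # annotate oracle failures with loop context
            raise RuntimeError(
                f"oracle evaluation failed at iteration {state.k + 1}, g={g:.3f}"
            ) from exc
        state.record(g, E)
        if converged(E, E_target, config.eps_tol):
            termination = "converged"
            gradients.append(state.grad_fk if state.grad_fk is not None else np.nan)
            confidences.append(state.conf_ck)
            sigmas.append(exploration_sigma(state.k, config))
            break
        try:
            grad_new = finite_difference_gradient(
                state.history, config.n_recent, config.delta_g_min
            )
        except NoGradientError:
            pass  # fall back to proportional control; confidence unchanged
        else:
            if state.grad_fk is None:
                state.grad_fk = grad_new
            else:
                state.grad_fk = ema_update(state.grad_fk, grad_new, config.learn_alpha)
            state.conf_ck = confidence_update(state.conf_ck, config.conf_delta)
        gradients.append(state.grad_fk if state.grad_fk is not None else np.nan)
        confidences.append(state.conf_ck)
        sigmas.append(exploration_sigma(state.k, config))
        g = propose_next(state, E_target, config, rng)

    g_final, E_final = state.last
    return SeekResult(
        g_star=g_final,
        E_final=E_final,
        iterations=state.k,
        converged=(termination == "converged"),
        termination=termination,
        trajectory=tuple(state.history),
        gradients=tuple(gradients),
        confidences=tuple(confidences),
        sigmas=tuple(sigmas),
    )
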