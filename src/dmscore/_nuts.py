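"""A compact No-U-Turn sampler (dynamic Hamiltonian Monte Carlo).

Implements the efficient NUTS recursion with slice sampling, dual-averaging
step-size adaptation toward a target acceptance statistic, and diagonal mass
matrix estimation from the second half of warmup.  Intended for moderate
dimensionality; the heavy screen-scale fits in :mod:`dmscore.model` use the
conjugate Gibbs engine and NUTS serves as an independent sampling route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DELTA_MAX = 1000.0  # divergence threshold on the joint log-density error


@dataclass
class NutsResult:
    samples: np.ndarray  # (draws, dim)
    accept_stat: float
    step_size: float
    n_divergent: int


def _leapfrog(logp_grad, z, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    z = z + eps * inv_mass * p
    logp, grad = logp_grad(z)
    p = p + 0.5 * eps * grad
    return z, p, logp, grad


def _find_reasonable_step(logp_grad, z, inv_mass, rng):
    eps = 1.0
    logp, grad = logp_grad(z)
    p = rng.standard_normal(z.size) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * np.sum(inv_mass * p * p)
    z1, p1, logp1, _ = _leapfrog(logp_grad, z, p, grad, eps, inv_mass)
    h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if h1 - h0 > math.log(0.5) else -1.0
    while a * (h1 - h0) > -a * math.log(2.0):
        eps *= 2.0**a
        if eps > 1e7 or eps < 1e-10:
            break
        z1, p1, logp1, _ = _leapfrog(logp_grad, z, p, grad, eps, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h1):
            h1 = -np.inf
    return eps


class _Tree:
    __slots__ = (
        "z_minus", "p_minus", "grad_minus", "z_plus", "p_plus", "grad_plus",
        "z_prop", "n", "stop", "alpha", "n_alpha", "divergent",
    )


def _build_tree(logp_grad, z, p, grad, logu, direction, depth, eps, h0, inv_mass, rng):
    t = _Tree()
    if depth == 0:
        z1, p1, logp1, grad1 = _leapfrog(logp_grad, z, p, grad, direction * eps, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        t.z_minus = t.z_plus = z1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.z_prop = z1
        t.n = 1 if logu <= h1 else 0
        t.divergent = logu - _DELTA_MAX >= h1
        t.stop = t.divergent
        t.alpha = min(1.0, math.exp(min(0.0, h1 - h0)))
        t.n_alpha = 1
        return t
    t = _build_tree(logp_grad, z, p, grad, logu, direction, depth - 1, eps, h0, inv_mass, rng)
    if not t.stop:
        if direction == -1:
            t2 = _build_tree(
                logp_grad, t.z_minus, t.p_minus, t.grad_minus, logu, direction,
                depth - 1, eps, h0, inv_mass, rng,
            )
            t.z_minus, t.p_minus, t.grad_minus = t2.z_minus, t2.p_minus, t2.grad_minus
        else:
            t2 = _build_tree(
                logp_grad, t.z_plus, t.p_plus, t.grad_plus, logu, direction,
                depth - 1, eps, h0, inv_mass, rng,
            )
            t.z_plus, t.p_plus, t.grad_plus = t2.z_plus, t2.p_plus, t2.grad_plus
        if t2.n > 0 and rng.random() < t2.n / max(t.n + t2.n, 1):
            t.z_prop = t2.z_prop
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.n += t2.n
        dz = t.z_plus - t.z_minus
        turned = (
            np.dot(dz, inv_mass * t.p_minus) < 0 or np.dot(dz, inv_mass * t.p_plus) < 0
        )
        t.stop = t2.stop or turned
        t.divergent = t.divergent or t2.divergent
    return t


def sample_nuts(
    logp_grad: LogpGrad,
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws."""
    rng = np.random.default_rng(seed)
    z = np.asarray(z0, dtype=float).copy()
    dim = z.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(z)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_step(logp_grad, z, inv_mass, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    mass_window: list[np.ndarray] = []
    samples = np.empty((n_draws, dim))
    accept_stats = []
    n_divergent = 0
    total = n_warmup + n_draws
    adapt_count = 0

    for it in range(total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * np.sum(inv_mass * p0 * p0)
        logu = h0 + math.log(rng.random())
        z_minus = z_plus = z
        p_minus = p_plus = p0
        grad_minus = grad_plus = grad
        z_prop = z
        n = 1
        stop = False
        alpha_sum, n_alpha_sum = 0.0, 0
        depth = 0
        while not stop and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                t = _build_tree(
                    logp_grad, z_minus, p_minus, grad_minus, logu, direction,
                    depth, eps, h0, inv_mass, rng,
                )
                z_minus, p_minus, grad_minus = t.z_minus, t.p_minus, t.grad_minus
            else:
                t = _build_tree(
                    logp_grad, z_plus, p_plus, grad_plus, logu, direction,
                    depth, eps, h0, inv_mass, rng,
                )
                z_plus, p_plus, grad_plus = t.z_plus, t.p_plus, t.grad_plus
            if not t.stop and t.n > 0 and rng.random() < min(1.0, t.n / n):
                z_prop = t.z_prop
            alpha_sum += t.alpha
            n_alpha_sum += t.n_alpha
            n += t.n
            dz = z_plus - z_minus
            stop = t.stop or (
                np.dot(dz, inv_mass * p_minus) < 0 or np.dot(dz, inv_mass * p_plus) < 0
            )
            if t.divergent:
                n_divergent += 1
            depth += 1
        z = z_prop
        logp, grad = logp_grad(z)
        accept = alpha_sum / max(n_alpha_sum, 1)

        if it < n_warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept)
            log_eps = mu - math.sqrt(adapt_count) / gamma * h_bar
            weight = adapt_count ** (-kappa)
            log_eps_bar = weight * log_eps + (1 - weight) * log_eps_bar
            eps = math.exp(log_eps)
            if it >= n_warmup // 2:
                mass_window.append(z.copy())
            # switch on the estimated mass matrix shortly before warmup ends
            if it == n_warmup - max(10, n_warmup // 20) and len(mass_window) > 10:
                var = np.var(np.asarray(mass_window), axis=0)
                inv_mass = np.clip(var, 1e-8, None)
                eps = _find_reasonable_step(logp_grad, z, inv_mass, rng)
                mu = math.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = math.log(eps), 0.0, 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            samples[it - n_warmup] = z
            accept_stats.append(accept)

    return NutsResult(
        samples=samples,
        accept_stat=float(np.mean(accept_stats)) if accept_stats else float("nan"),
        step_size=eps,
        n_divergent=n_divergent,
    )
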