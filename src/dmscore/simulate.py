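"""Generative growth-screen simulator with ground truth.

The generative chain mimics the experiment rather than the inference model:

1. Mutants are apportioned to mutant groups by the fitted proportions; each
   position draws a composition over (mutant group, variant group) cells
   from ``Dirichlet(alpha)`` and variant-group labels are allocated to match
   it (largest-remainder rounding).  In ``position_homogeneous`` mode every
   position instead draws a single variant group for all its variants.
2. Functional scores: LOF/GOF variants draw ``beta ~ Normal(mu_g, sd_g^2)``
   from the fitted group parameters; neutral and control variants have
   ``beta = 0`` exactly.
3. Scores map to growth rates via ``mu_v = mu_wt * (beta_v/(delta*T*ln2) + 1)``
   with ``mu_wt = sgn(delta)`` and pseudo-passing time ``dt = |delta|*ln2``,
   so that the expected naive slope of the normalized log counts recovers
   ``beta_v``.
4. Cells: the initial population ``N[:,0,r] ~ DirMult(P0, eta0)`` (uniform
   concentrations), then exponential growth with Poisson noise
   ``N[:,t,r] ~ Poisson(N[:,t-1,r] * exp(mu_v * dt))``; replicates are
   independent biological replicates.
5. Sequencing: ``c[:,t,r] ~ DirMult(D*V, eta * V * N/sum(N))`` — per-category
   concentration convention so the dispersion round-trips through the
   estimator; ``eta_total_concentration=True`` uses ``eta * N/sum(N)``
   instead.  Infinite dispersion yields plain multinomial sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dmscore.data import ScreenCounts, screen_from_frame
from dmscore.summaries import ScreenSummary, VariantGroup


class SimulationError(RuntimeError):
    """Simulation failed (e.g. the cell population went extinct)."""


@dataclass
class SimConfig:
    """Simulation hyperparameters.

    ``n_mutants`` counts substitution rows per position, of which the first
    ``syn_mutant_rows`` behave as synonymous controls (neutral by
    construction, annotated synonymous so they can serve as negative-control
    proxies).  ``reads_per_variant`` is the sequencing depth D;
    ``pop0`` defaults to 200 cells per variant; ``doubling_rate`` is the
    wild-type doublings per selection round (sign sets the direction of
    selection).
    """

    n_mutants: int = 20
    n_positions: int = 50
    reads_per_variant: int = 100
    pop0: int | None = None
    doubling_rate: float = 2.0
    n_reps: int = 3
    n_rounds: int = 3
    seed: int = 0
    mode: str = "standard"
    syn_mutant_rows: int = 1
    eta_multiplier: float = 1.0
    eta0_multiplier: float = 1.0
    eta_total_concentration: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "position_homogeneous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.doubling_rate == 0:
            raise ValueError("doubling_rate must be nonzero")
        if self.eta_multiplier < 1 or self.eta0_multiplier < 1:
            raise ValueError("dispersion multipliers must be >= 1")
        if not (0 <= self.syn_mutant_rows < self.n_mutants):
            raise ValueError("syn_mutant_rows must leave at least one non-control mutant")

    @property
    def n_variants(self) -> int:
        return self.n_mutants * self.n_positions

    @property
    def mu_wt(self) -> float:
        return math.copysign(1.0, self.doubling_rate)

    @property
    def dt(self) -> float:
        """Pseudo-passing time per round: delta*ln2/mu_wt = |delta|*ln2 > 0."""
        return abs(self.doubling_rate) * math.log(2.0)

    @property
    def total_pop0(self) -> int:
        return self.pop0 if self.pop0 is not None else 200 * self.n_variants


@dataclass
class SimulatedScreen:
    """Counts plus ground truth for benchmarking."""

    screen: ScreenCounts
    truth: pd.DataFrame  # variant_id, beta, mu, mutant_group, variant_group
    cell_counts: np.ndarray  # (V, T+1, R)
    config: SimConfig
    summary: ScreenSummary


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` items to cells proportionally, never negative."""
    weights = np.clip(np.asarray(weights, dtype=float), 0.0, None)
    if weights.sum() == 0:
        weights = np.ones_like(weights)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def draw_variant_structure(
    summary: ScreenSummary, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign every variant its mutant group and variant group labels."""
    n_gm = summary.n_mutant_groups
    gv_order = [g.label for g in summary.variant_groups]
    n_gv = len(gv_order)
    n_sub = cfg.n_mutants - cfg.syn_mutant_rows
    gm_counts = _largest_remainder(summary.mutant_group_props, n_sub)
    gm_of_mutant = np.repeat(np.arange(n_gm), gm_counts)

    rows = []
    alpha = np.asarray(summary.alpha, dtype=float).reshape(n_gm, n_gv)
    gv_marginal = alpha.sum(axis=0)
    for p in range(1, cfg.n_positions + 1):
        if cfg.mode == "position_homogeneous":
            # one variant group per position, weighted by the Dirichlet marginal
            gv_idx = rng.choice(n_gv, p=gv_marginal / gv_marginal.sum())
            gv_of_mutant = np.full(n_sub, gv_idx)
        else:
            comp = rng.dirichlet(np.clip(alpha.ravel(), 1e-6, None)).reshape(n_gm, n_gv)
            gv_of_mutant = np.empty(n_sub, dtype=int)
            for g in range(n_gm):
                idx = np.nonzero(gm_of_mutant == g)[0]
                if idx.size == 0:
                    continue
                counts = _largest_remainder(comp[g], idx.size)
                labels = np.repeat(np.arange(n_gv), counts)
                gv_of_mutant[rng.permutation(idx)] = labels
        for j in range(cfg.syn_mutant_rows):
            rows.append((f"p{p}_syn{j}", p, f"syn{j}", "synonymous", -1, "control"))
        for j in range(n_sub):
            rows.append(
                (
                    f"p{p}_m{j}",
                    p,
                    f"m{j}",
                    "missense",
                    int(gm_of_mutant[j]),
                    gv_order[int(gv_of_mutant[j])],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "position", "mutant", "mutation_type",
                 "mutant_group", "variant_group"],
    )


def draw_beta(
    labels: pd.DataFrame, summary: ScreenSummary, rng: np.random.Generator
) -> np.ndarray:
    """Functional scores: Gaussian for LOF/GOF groups, exactly 0 otherwise."""
    params = {g.label: g for g in summary.variant_groups}
    beta = np.zeros(len(labels))
    for label, g in params.items():
        if label in ("neutral", "control"):
            continue
        mask = (labels["variant_group"] == label).to_numpy()
        beta[mask] = rng.normal(g.mean, g.sd, size=int(mask.sum()))
    return beta


def beta_to_mu(beta: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Map functional scores to growth rates (beta = 0 gives the wild-type rate)."""
    return cfg.mu_wt * (
        np.asarray(beta, dtype=float) / (cfg.doubling_rate * cfg.n_rounds * math.log(2.0))
        + 1.0
    )


def _dirichlet_multinomial(
    rng: np.random.Generator, total: int, concentration: np.ndarray | None,
    probs: np.ndarray,
) -> np.ndarray:
    """Draw DirMult(total, concentration); ``concentration=None`` is the
    multinomial limit at the given probabilities."""
    if concentration is None:
        return rng.multinomial(total, probs)
    p = rng.dirichlet(np.clip(concentration, 1e-12, None))
    return rng.multinomial(total, p)


def simulate_counts(
    mu: np.ndarray, summary: ScreenSummary, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate cell and sequencing counts; returns (N, c), each (V, T+1, R)."""
    V = mu.size
    D = cfg.reads_per_variant
    eta = summary.eta * cfg.eta_multiplier
    eta0 = summary.eta0 * cfg.eta0_multiplier
    N = np.zeros((V, cfg.n_rounds + 1, cfg.n_reps))
    c = np.zeros((V, cfg.n_rounds + 1, cfg.n_reps))
    uniform = np.full(V, 1.0 / V)
    growth = np.exp(mu * cfg.dt)
    for r in range(cfg.n_reps):
        conc0 = None if not np.isfinite(eta0) else np.full(V, eta0)
        N[:, 0, r] = _dirichlet_multinomial(rng, cfg.total_pop0, conc0, uniform)
        for t in range(1, cfg.n_rounds + 1):
            lam = N[:, t - 1, r] * growth
            if lam.sum() <= 0:
                raise SimulationError(f"population extinct before round {t}, replicate {r + 1}")
            N[:, t, r] = rng.poisson(lam)
        for t in range(cfg.n_rounds + 1):
            totN = N[:, t, r].sum()
            if totN <= 0:
                raise SimulationError(f"population extinct at round {t}, replicate {r + 1}")
            props = N[:, t, r] / totN
            if np.isfinite(eta):
                scale = eta if cfg.eta_total_concentration else eta * V
                conc = scale * props
            else:
                conc = None
            c[:, t, r] = _dirichlet_multinomial(rng, D * V, conc, props)
    return N, c


def simulate_screen(summary: ScreenSummary, cfg: SimConfig) -> SimulatedScreen:
    """Run the full generative chain; deterministic given (summary, cfg, seed)."""
    rng = np.random.default_rng(cfg.seed)
    labels = draw_variant_structure(summary, cfg, rng)
    beta = draw_beta(labels, summary, rng)
    mu = beta_to_mu(beta, cfg)
    N, c = simulate_counts(mu, summary, cfg, rng)
    ann = labels.loc[:, ["variant_id", "position", "mutant", "mutation_type"]].copy()
    screen = screen_from_frame(ann, c, cfg.n_rounds, cfg.n_reps)
    truth = labels.copy()
    truth["beta"] = beta
    truth["mu"] = mu
    return SimulatedScreen(screen=screen, truth=truth, cell_counts=N, config=cfg,
                           summary=summary)


def default_summary(
    eta: float = 50.0,
    eta0: float = 5.0,
    lof_mean: float = -3.0,
    lof_sd: float = 0.5,
    lof_weight: float = 0.3,
    n_mutant_groups: int = 4,
    n_rounds: int = 3,
    selection_sign: str | None = None,
    alpha_concentration: float = 10.0,
) -> ScreenSummary:
    """A hand-specified summary for simulation without a fitted screen.

    Defaults describe a typical negative-selection screen: a neutral mode at
    0 and a LOF mode at -3 holding ~30% of variants, moderate sequencing
    over-dispersion (eta=50) and a strongly imbalanced library (eta0=5).
    """
    if selection_sign is None:
        selection_sign = "positive" if lof_mean > 0 else "negative"
    groups = [
        VariantGroup(label="neutral", mean=0.0, sd=0.2, weight=1.0 - lof_weight),
        VariantGroup(label="lof", mean=lof_mean, sd=lof_sd, weight=lof_weight),
    ]
    props = np.full(n_mutant_groups, 1.0 / n_mutant_groups)
    cell_weights = np.outer(props, [1.0 - lof_weight, lof_weight]).ravel()
    alpha = alpha_concentration * cell_weights
    return ScreenSummary(
        eta=eta,
        eta0=eta0,
        mutant_group_props=props,
        mutant_group_map={},
        variant_groups=groups,
        cutoffs=[lof_mean / 2.0],
        alpha=alpha,
        n_rounds=n_rounds,
        selection_sign=selection_sign,
    )
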