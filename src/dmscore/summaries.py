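"""Interpretable summary statistics of a growth screen.

Five statistics are enough to regenerate a screen with realistic structure:

- ``eta`` — Dirichlet-multinomial dispersion of the sequencing counts,
  estimated on synonymous variants whose proportions should be stable over
  selection (smaller eta = more over-dispersion; very large eta = counts are
  effectively multinomial).
- ``eta0`` — dispersion of the pre-selection variant library around a
  uniform composition, estimated on the t=0 counts of all variants.
- ``p`` — mutant-group proportions from hierarchical clustering of per-mutant
  score distributions under Jensen-Shannon divergence.
- ``theta`` — per variant-group Gaussian score parameters from a Gaussian
  mixture cut of the non-synonymous score distribution (neutral effects are
  fixed at exactly 0 when simulating).
- ``alpha`` — Dirichlet concentration of the per-position composition of
  (mutant group, variant group) identities, treating positions as
  exchangeable observations.

Naive per-variant scores (pooled OLS of normalized log counts on t/T) are
the default input: uncalibrated but unbiased, which is all a distributional
summary needs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import jensenshannon, squareform
from sklearn.mixture import GaussianMixture

from dmscore.data import SCORE_COLUMNS, ScreenCounts
from dmscore.preprocess import NormalizedScreen

LOG_ETA_BOUNDS = (-3.0, 6.0)  # log10-scale search window for dispersion MLEs


@dataclass
class DispersionEstimate:
    """MLE of a Dirichlet-multinomial dispersion with bound diagnostics."""

    value: float
    at_upper_bound: bool
    log10_value: float
    per_timepoint: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return self.value


@dataclass
class VariantGroup:
    """One component of the variant-effect mixture."""

    label: str  # neutral | lof | gof | control
    mean: float
    sd: float
    weight: float


@dataclass
class ScreenSummary:
    """Everything needed to simulate a screen with matching structure."""

    eta: float
    eta0: float
    mutant_group_props: np.ndarray
    mutant_group_map: dict
    variant_groups: list
    cutoffs: list
    alpha: np.ndarray
    n_rounds: int
    selection_sign: str
    eta_at_bound: bool = False
    eta0_at_bound: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_mutant_groups(self) -> int:
        return len(self.mutant_group_props)

    @property
    def n_variant_groups(self) -> int:
        return len(self.variant_groups)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = dataclasses.asdict(self)
        payload["mutant_group_props"] = list(map(float, self.mutant_group_props))
        payload["alpha"] = list(map(float, self.alpha))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ScreenSummary":
        with open(path) as fh:
            payload = json.load(fh)
        payload["mutant_group_props"] = np.asarray(payload["mutant_group_props"])
        payload["alpha"] = np.asarray(payload["alpha"])
        payload["variant_groups"] = [VariantGroup(**g) for g in payload["variant_groups"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# naive scoring


def naive_scores(ns: NormalizedScreen) -> pd.DataFrame:
    """Per-variant simple linear regression of m on t/T, replicates pooled.

    Returns a score table with the OLS slope as estimate, the two-sided
    p-value from the t statistic, and Benjamini-Hochberg adjusted p-values.
    Variants with fewer than 3 finite observations are skipped with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    m = ns.m
    V, Tp1, R = m.shape
    T = Tp1 - 1
    x = np.tile(np.arange(Tp1) / T, R)  # flattened (t, r) design
    y = m.transpose(0, 2, 1).reshape(V, -1)  # (V, R*(T+1)) matching x order
    finite = np.isfinite(y)
    n = finite.sum(axis=1)
    usable = n >= 3
    if not usable.all():
        warnings.warn(f"skipping {int((~usable).sum())} variants with < 3 observations",
                      stacklevel=2)

    y0 = np.where(finite, y, 0.0)
    sx = (finite * x).sum(axis=1)
    sy = y0.sum(axis=1)
    sxx = (finite * x * x).sum(axis=1)
    sxy = (y0 * x).sum(axis=1)
    syy = (y0 * y0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy * sy / n
        slope = sxy_c / sxx_c
        intercept = sy / n - slope * sx / n
        rss = np.maximum(syy_c - slope * sxy_c, 0.0)
        df = n - 2
        s2 = rss / np.maximum(df, 1)
        se = np.sqrt(s2 / sxx_c)
    stat = np.zeros(V)
    p = np.ones(V)
    ok = usable & (se > 0)
    stat[ok] = slope[ok] / se[ok]
    p[ok] = 2 * stats.t.sf(np.abs(stat[ok]), df[ok])
    # zero residual variance: an exact line; p -> 0 unless the slope is 0 too
    exact = usable & (se == 0) & (np.abs(slope) > 0)
    stat[exact] = np.inf * np.sign(slope[exact])
    p[exact] = 0.0

    table = ns.annotations.loc[:, ["variant_id", "position", "mutant", "mutation_type"]].copy()
    table["estimate"] = np.where(usable, slope, np.nan)
    table["se"] = np.where(usable, se, np.nan)
    table["stat"] = np.where(usable, stat, np.nan)
    table["raw"] = np.where(usable, p, np.nan)
    table = table.loc[usable].reset_index(drop=True)
    table["adjusted"] = multipletests(table["raw"].to_numpy(), method="fdr_bh")[1]
    table["method"] = "naive-ols"
    table = table.sort_values(
        ["raw", "estimate"],
        key=lambda s: -s.abs() if s.name == "estimate" else s,
        kind="stable",
    ).reset_index(drop=True)
    return table.loc[:, list(SCORE_COLUMNS)]


# ---------------------------------------------------------------------------
# dispersion MLEs


def _dirmult_loglik(counts_matrix: np.ndarray, base_props: np.ndarray, log10_eta: float,
                    scale: float) -> float:
    """Summed Dirichlet-multinomial log-likelihood over rows of counts_matrix.

    Concentration = eta * scale * base_props (per-category convention:
    ``scale`` is the number of categories, so eta is a per-category mean
    concentration).
    """
    eta = 10.0**log10_eta
    alpha = eta * scale * base_props
    total = 0.0
    for row in counts_matrix:
        n = int(round(row.sum()))
        total += float(stats.dirichlet_multinomial.logpmf(np.round(row), alpha, n))
    return total


def _fit_dispersion(counts_matrix: np.ndarray, base_props: np.ndarray) -> DispersionEstimate:
    scale = base_props.size
    lo, hi = LOG_ETA_BOUNDS

    def neg(log10_eta: float) -> float:
        return -_dirmult_loglik(counts_matrix, base_props, log10_eta, scale)

    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-4})
    log10_eta = float(res.x)
    at_bound = log10_eta >= hi - 1e-2
    if at_bound:
        log10_eta = hi
    return DispersionEstimate(
        value=10.0**log10_eta, at_upper_bound=at_bound, log10_value=log10_eta
    )


def estimate_eta(sc: ScreenCounts) -> DispersionEstimate:
    """MLE of the sequencing-count dispersion eta on synonymous variants.

    Models the synonymous count vector at each post-selection time point as
    Dirichlet-multinomial around the t=0 synonymous proportions, summing the
    log-likelihood over all (t >= 1, replicate) observations.  A fit at the
    search upper bound means the counts are effectively multinomial.
    """
    syn = (sc.annotations["mutation_type"] == "synonymous").to_numpy()
    if syn.sum() < 2:
        raise ValueError("need at least 2 synonymous variants to estimate eta")
    rows = []
    per_t: dict[int, list[float]] = {}
    base_list = []
    for r in range(sc.n_reps):
        c0 = sc.counts[syn, 0, r]
        if np.isnan(c0).any():
            raise ValueError("missing synonymous counts at t=0; impute first")
        props = (c0 + 0.5) / (c0 + 0.5).sum()  # half-count guard against zero categories
        for t in range(1, sc.n_rounds + 1):
            ct = sc.counts[syn, t, r]
            if np.isnan(ct).any():
                continue
            rows.append((ct, props, t))
    if not rows:
        raise ValueError("no complete post-selection synonymous count vectors")

    scale = int(syn.sum())
    lo, hi = LOG_ETA_BOUNDS

    def neg(log10_eta: float) -> float:
        eta = 10.0**log10_eta
        ll = 0.0
        for ct, props, _ in rows:
            n = int(round(ct.sum()))
            ll += float(stats.dirichlet_multinomial.logpmf(np.round(ct), eta * scale * props, n))
        return -ll

    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-4})
    log10_eta = float(res.x)
    at_bound = log10_eta >= hi - 1e-2
    est = DispersionEstimate(
        value=10.0**(hi if at_bound else log10_eta),
        at_upper_bound=at_bound,
        log10_value=hi if at_bound else log10_eta,
    )
    # per-time-point fits, for diagnostics only
    for t in sorted({t for _, _, t in rows}):
        sub = [(ct, props) for ct, props, tt in rows if tt == t]

        def neg_t(log10_eta: float, sub=sub) -> float:
            eta = 10.0**log10_eta
            return -sum(
                float(stats.dirichlet_multinomial.logpmf(np.round(ct), eta * scale * props,
                                                         int(round(ct.sum()))))
                for ct, props in sub
            )

        rt = optimize.minimize_scalar(neg_t, bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-3})
        est.per_timepoint[t] = 10.0 ** float(rt.x)
    return est


def estimate_eta0(sc: ScreenCounts) -> DispersionEstimate:
    """MLE of the library dispersion eta0 on the t=0 counts of all variants.

    The pre-selection library is modeled as Dirichlet-multinomial around a
    uniform composition; each replicate contributes one observation.
    Typically eta0 is much smaller than eta because it absorbs library
    imbalance on top of sequencing noise.
    """
    V = sc.n_variants
    rows = []
    for r in range(sc.n_reps):
        c0 = sc.counts[:, 0, r]
        if np.isnan(c0).any():
            raise ValueError("missing counts at t=0; impute first")
        rows.append(np.round(c0))
    base = np.full(V, 1.0 / V)
    return _fit_dispersion(np.asarray(rows), base)


# ---------------------------------------------------------------------------
# mutant clustering


def score_density(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Empirical probability mass over fixed bins (normalized histogram)."""
    h, _ = np.histogram(values[np.isfinite(values)], bins=edges)
    total = h.sum()
    return h / total if total else np.full(h.size, 1.0 / h.size)


def jsd_matrix(densities: np.ndarray) -> np.ndarray:
    """Pairwise Jensen-Shannon divergence (natural log, bounded by ln 2)."""
    n = densities.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jensenshannon(densities[i], densities[j], base=math.e) ** 2
            D[i, j] = D[j, i] = 0.0 if np.isnan(d) else float(d)
    return D


def cluster_mutants(
    score_matrix: pd.DataFrame, n_groups: int = 4, bin_width: float = 0.1
) -> tuple[dict, np.ndarray]:
    """Cluster mutants by the shape of their score distributions.

    ``score_matrix`` is mutants x positions (NaN allowed).  Per-mutant
    empirical densities are binned at ``bin_width`` over the global range
    padded by one bin; mutants are clustered by complete-linkage hierarchical
    clustering of the pairwise Jensen-Shannon divergence and cut into
    ``n_groups`` groups.  Returns (mutant -> group index, group proportions).
    """
    mutants = list(score_matrix.index)
    if n_groups > len(mutants):
        raise ValueError(f"n_groups={n_groups} exceeds number of mutants {len(mutants)}")
    values = score_matrix.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    lo = np.floor(finite.min() / bin_width) * bin_width - bin_width
    hi = np.ceil(finite.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    dens = np.stack([score_density(values[i], edges) for i in range(len(mutants))])
    D = jsd_matrix(dens)
    if len(mutants) == n_groups:
        labels = np.arange(len(mutants))
    else:
        Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
        labels = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust") - 1
    _, labels = np.unique(labels, return_inverse=True)
    props = np.bincount(labels, minlength=labels.max() + 1) / len(mutants)
    f1 = dict(zip(mutants, labels.tolist()))
    return f1, props


# ---------------------------------------------------------------------------
# variant-effect mixture


def assign_by_cutoffs(values: np.ndarray, cutoffs: list) -> np.ndarray:
    """Group index of each score given sorted cutoffs.

    A score exactly at a cutoff joins the lower-index (more negative) group.
    """
    return np.searchsorted(np.asarray(cutoffs), values, side="left")


def cluster_variant_groups(
    scores: pd.DataFrame,
    n_components: int = 2,
    selection_sign: str | None = None,
    seed: int = 0,
    max_retries: int = 5,
) -> tuple[np.ndarray, list, list]:
    """Cut the non-synonymous score distribution into effect groups.

    A Gaussian mixture with ``n_components`` fixes the group cutoffs (the
    score values where the posterior responsibility switches between
    mean-ordered adjacent components); each group's Gaussian is then re-fit
    on its members.  Synonymous variants are labeled ``control``.  Group
    identity (neutral / lof / gof) follows the sign of the re-fit mean and
    the direction of selection; scores exactly at a cutoff go to the
    lower-index (more negative) group.

    Returns (per-variant labels aligned with ``scores``, VariantGroup list,
    cutoffs).
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    est = scores["estimate"].to_numpy(dtype=float)
    is_syn = (scores["mutation_type"] == "synonymous").to_numpy()
    nonsyn = est[~is_syn & np.isfinite(est)]
    if nonsyn.size < 10 * n_components:
        raise ValueError("too few non-synonymous scores for the requested mixture")

    X = nonsyn.reshape(-1, 1)
    gmm = None
    for attempt in range(max_retries):
        cand = GaussianMixture(n_components=n_components, random_state=seed + attempt,
                               n_init=3).fit(X)
        if cand.weights_.min() > 1e-3 and np.sqrt(cand.covariances_).min() > 1e-6:
            gmm = cand
            break
    if gmm is None:
        raise RuntimeError("Gaussian mixture repeatedly degenerate")

    order = np.argsort(gmm.means_.ravel())
    cutoffs: list[float] = []
    if n_components > 1:
        grid = np.linspace(nonsyn.min(), nonsyn.max(), 20001).reshape(-1, 1)
        resp = gmm.predict_proba(grid)[:, order]
        assign = resp.argmax(axis=1)
        for k in range(n_components - 1):
            crossings = np.nonzero((assign[:-1] <= k) & (assign[1:] > k))[0]
            mid = gmm.means_.ravel()[order]
            fallback = 0.5 * (mid[k] + mid[k + 1])
            cutoffs.append(float(grid[crossings[0], 0]) if crossings.size else fallback)
    comp_of_score = assign_by_cutoffs(est, cutoffs)

    # re-fit each group's Gaussian on its members
    groups: list[VariantGroup] = []
    for k in range(n_components):
        members = nonsyn[assign_by_cutoffs(nonsyn, cutoffs) == k]
        mu = float(members.mean()) if members.size else float(gmm.means_.ravel()[order][k])
        sd = float(members.std(ddof=1)) if members.size > 1 else float(
            np.sqrt(gmm.covariances_.ravel()[order][k])
        )
        groups.append(VariantGroup(label="", mean=mu, sd=sd,
                                   weight=float(members.size / nonsyn.size)))

    neutral_idx = int(np.argmin([abs(g.mean) for g in groups]))
    groups[neutral_idx].label = "neutral"
    if selection_sign is None:
        others = [g for i, g in enumerate(groups) if i != neutral_idx]
        if others:
            dominant = max(others, key=lambda g: g.weight)
            selection_sign = "positive" if dominant.mean > 0 else "negative"
        else:
            selection_sign = "negative"
    lof_sign = 1.0 if selection_sign == "positive" else -1.0
    for i, g in enumerate(groups):
        if i == neutral_idx:
            continue
        g.label = "lof" if np.sign(g.mean - groups[neutral_idx].mean) == lof_sign else "gof"

    labels = np.array([groups[k].label for k in comp_of_score], dtype=object)
    labels[is_syn] = "control"
    labels[~np.isfinite(est)] = "control"
    return labels, groups, cutoffs


# ---------------------------------------------------------------------------
# Dirichlet concentration of positional composition


def _dirichlet_mle(P: np.ndarray, tol: float = 1e-10, max_iter: int = 2000) -> np.ndarray:
    """Minka fixed-point MLE for Dirichlet concentrations from compositions P (n x K)."""
    logp_bar = np.log(P).mean(axis=0)
    mean = P.mean(axis=0)
    m2 = (P * P).mean(axis=0)
    # moment-matching initialization for the total concentration
    with np.errstate(divide="ignore", invalid="ignore"):
        s_init = np.nanmedian((mean - m2) / (m2 - mean * mean))
    if not np.isfinite(s_init) or s_init <= 0:
        s_init = 1.0
    alpha = mean * max(s_init, 1e-3)
    for _ in range(max_iter):
        target = special.digamma(alpha.sum()) + logp_bar
        new = _inv_digamma(target)
        if np.max(np.abs(new - alpha)) < tol * max(1.0, np.max(np.abs(alpha))):
            alpha = new
            break
        alpha = new
    return alpha


def _inv_digamma(y: np.ndarray, n_iter: int = 30) -> np.ndarray:
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - special.digamma(1.0)))
    for _ in range(n_iter):
        x = x - (special.digamma(x) - y) / special.polygamma(1, x)
        x = np.clip(x, 1e-12, None)
    return x


def fit_alpha(
    positions: np.ndarray,
    gm_labels: np.ndarray,
    gv_labels: np.ndarray,
    n_gm: int | None = None,
    gv_order: list | None = None,
    smoothing: float = 1e-6,
) -> np.ndarray:
    """Dirichlet MLE of the per-position (mutant group, variant group) composition.

    Each real position contributes one observed composition over the
    ``n_gm * n_gv`` cells of counts ``o[p, g_m, g_v]``; positions are treated
    as exchangeable.  Zero cells get additive smoothing before normalization
    (the Dirichlet density is degenerate on the simplex boundary).  Control
    variants must be excluded beforehand.
    """
    positions = np.asarray(positions)
    gm = np.asarray(gm_labels)
    gv = np.asarray(gv_labels)
    uniq_pos = np.unique(positions)
    if uniq_pos.size < 3:
        raise ValueError("need at least 3 positions to fit a Dirichlet")
    if n_gm is None:
        n_gm = int(gm.max()) + 1
    if gv_order is None:
        gv_order = sorted(set(gv.tolist()))
    gv_index = {g: i for i, g in enumerate(gv_order)}
    n_gv = len(gv_order)
    O = np.zeros((uniq_pos.size, n_gm * n_gv))
    pos_index = {p: i for i, p in enumerate(uniq_pos.tolist())}
    for p, a, b in zip(positions.tolist(), gm.tolist(), gv.tolist()):
        O[pos_index[p], int(a) * n_gv + gv_index[b]] += 1
    P = O + smoothing
    P = P / P.sum(axis=1, keepdims=True)
    return _dirichlet_mle(P)


# ---------------------------------------------------------------------------
# end-to-end fit


def fit_summary(
    sc: ScreenCounts,
    ns: NormalizedScreen,
    scores: pd.DataFrame | None = None,
    n_mutant_groups: int = 4,
    n_variant_groups: int = 2,
    selection_sign: str | None = None,
    seed: int = 0,
) -> ScreenSummary:
    """Estimate all five summary statistics from a (preprocessed) screen."""
    if scores is None:
        scores = naive_scores(ns)
    eta = estimate_eta(sc)
    eta0 = estimate_eta0(sc)

    nonsyn = scores.loc[scores["mutation_type"] != "synonymous"]
    score_matrix = nonsyn.pivot_table(index="mutant", columns="position",
                                      values="estimate", aggfunc="mean")
    n_groups = min(n_mutant_groups, len(score_matrix))
    f1, props = cluster_mutants(score_matrix, n_groups=n_groups)

    gv_labels, groups, cutoffs = cluster_variant_groups(
        scores, n_components=n_variant_groups, selection_sign=selection_sign, seed=seed
    )
    if selection_sign is None:
        non_neutral = [g for g in groups if g.label == "lof"]
        selection_sign = (
            "positive" if non_neutral and non_neutral[0].mean > 0 else "negative"
        )

    mask = (scores["mutation_type"] != "synonymous").to_numpy() & (gv_labels != "control")
    gm_of_variant = scores["mutant"].map(f1).to_numpy()
    gv_order = [g.label for g in sorted(groups, key=lambda g: g.mean)]
    alpha = fit_alpha(
        scores["position"].to_numpy()[mask],
        gm_of_variant[mask].astype(int),
        gv_labels[mask],
        n_gm=int(props.size),
        gv_order=gv_order,
    )
    return ScreenSummary(
        eta=eta.value,
        eta0=eta0.value,
        mutant_group_props=props,
        mutant_group_map=f1,
        variant_groups=groups,
        cutoffs=cutoffs,
        alpha=alpha,
        n_rounds=sc.n_rounds,
        selection_sign=selection_sign,
        eta_at_bound=eta.at_upper_bound,
        eta0_at_bound=eta0.at_upper_bound,
        diagnostics={
            "eta_per_timepoint": eta.per_timepoint,
            "gv_order": gv_order,
        },
    )
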