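"""Default pre-processing of a growth-screen count table.

The pipeline is: per-replicate variant filtering, imputation of sparse
missing cells, wild-type (or total-count) log-ratio normalization with a
pseudo-count of 1/2, integration of replicate dropouts, assignment of
synonymous variants to artificial control positions, regrouping of sparse
positions, and mean-count grouping for the shared residual variance.

Normalization (wild-type form)::

    m[v,t,r] = log((c[v,t,r]+1/2)/(c_wt[t,r]+1/2)) - log((c[v,0,r]+1/2)/(c_wt[0,r]+1/2))

so every trajectory is aligned to 0 at t=0 and a wild-type-like variant has
score ~0.  Under ``method="total"`` the wild-type series is replaced by the
per-(t, r) column total.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from dmscore.data import ConfigError, ScreenCounts, ScreenFormatError, wildtype_series


@dataclass
class NormalizedScreen:
    """Wild-type-normalized log-scale screen plus model groupings.

    ``m`` has shape ``(V, T+1, R)`` with ``m[:, 0, :] == 0``.  ``position_label``
    maps each variant to an integer position label (real residue index for
    non-synonymous variants, artificial control labels above the real range
    for synonymous/wild-type rows).  ``mean_group`` indexes blocks of variants
    with similar mean raw count that share a residual variance.
    """

    m: np.ndarray
    annotations: pd.DataFrame
    n_rounds: int
    n_reps: int
    mean_count: np.ndarray
    position_label: np.ndarray | None = None
    mean_group: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return self.m.shape[0]

    def copy(self) -> "NormalizedScreen":
        return NormalizedScreen(
            m=self.m.copy(),
            annotations=self.annotations.copy(),
            n_rounds=self.n_rounds,
            n_reps=self.n_reps,
            mean_count=self.mean_count.copy(),
            position_label=None if self.position_label is None else self.position_label.copy(),
            mean_group=None if self.mean_group is None else self.mean_group.copy(),
            provenance=dict(self.provenance),
        )


def filter_variants(sc: ScreenCounts, max_missing_frac: float = 0.5) -> ScreenCounts:
    """Drop variant/replicate series with too much missing data.

    A variant is removed from a replicate when strictly more than
    ``max_missing_frac`` of its T+1 time points are missing there (the whole
    series becomes NaN).  Variants missing from every replicate are removed
    entirely.  Removals are recorded in ``provenance``.
    """
    if not (0 <= max_missing_frac < 1):
        raise ValueError("max_missing_frac must be in [0, 1)")
    out = sc.copy()
    frac = np.isnan(out.counts).mean(axis=1)  # (V, R)
    drop = frac > max_missing_frac  # strict: exactly at threshold is retained
    for v, r in zip(*np.nonzero(drop)):
        out.counts[v, :, r] = np.nan
    keep = ~drop.all(axis=1)
    if not keep.any():
        raise ScreenFormatError("all variants removed by missing-data filter")
    out.provenance.setdefault("filter", {})
    out.provenance["filter"] = {
        "max_missing_frac": max_missing_frac,
        "replicate_series_dropped": int(drop.sum()),
        "variants_removed": out.annotations.loc[~keep, "variant_id"].tolist(),
    }
    out.counts = out.counts[keep]
    out.annotations = out.annotations.loc[keep].reset_index(drop=True)
    return out


def impute_counts(sc: ScreenCounts, method: str = "knn", k: int = 10) -> ScreenCounts:
    """Fill residual missing cells in retained variant/replicate series.

    ``knn`` imputes each missing cell from the ``k`` nearest variants in the
    same replicate, with Euclidean distance over log(c+1/2) profiles
    restricted to mutually observed time points (missing-dimension-corrected,
    as in nan-Euclidean); the neighbor average is taken on the log scale and
    transformed back to a count.  ``zero`` fills with 0.  Series that were
    dropped whole by :func:`filter_variants` stay NaN; they are resolved
    later by :func:`integrate_replicates` on the normalized scale.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if method not in ("knn", "zero"):
        raise ValueError(f"unknown imputation method {method!r}")
    out = sc.copy()
    for r in range(out.n_reps):
        block = out.counts[:, :, r]
        retained = ~np.isnan(block).all(axis=1)
        sub = block[retained]
        if not np.isnan(sub).any():
            continue
        if method == "zero":
            sub = np.where(np.isnan(sub), 0.0, sub)
        else:
            complete = (~np.isnan(sub)).all(axis=1).sum()
            n_neighbors = min(k, max(1, int(complete)))
            if n_neighbors < k:
                warnings.warn(
                    f"replicate {r + 1}: only {complete} complete neighbor "
                    f"variants; using k={n_neighbors}",
                    stacklevel=2,
                )
            logsub = np.log(sub + 0.5)
            imputer = KNNImputer(n_neighbors=n_neighbors, weights="uniform")
            logimp = imputer.fit_transform(logsub)
            imp = np.exp(logimp) - 0.5
            sub = np.where(np.isnan(sub), np.clip(imp, 0.0, None), sub)
        block[retained] = sub
        out.counts[:, :, r] = block
    out.provenance["imputation"] = {"method": method, "k": k}
    return out


def normalize(sc: ScreenCounts, method: str = "wt") -> NormalizedScreen:
    """Log-ratio normalization with pseudo-count 1/2, aligned to 0 at t=0.

    ``method="wt"`` divides by the wild-type series (designated rows or the
    synonymous sum); ``method="total"`` divides by the per-(t, r) column
    total.  Whole-replicate NaN series propagate and are resolved by
    :func:`integrate_replicates`.
    """
    if method == "wt":
        ref = wildtype_series(sc)  # (T+1, R)
    elif method == "total":
        ref = np.nansum(sc.counts, axis=0)
    else:
        raise ConfigError(f"unknown normalization method {method!r}")
    if np.any(ref[~np.isnan(ref)] < 0) or np.all(ref == 0):
        raise ConfigError("unresolvable reference series")
    logratio = np.log(sc.counts + 0.5) - np.log(ref + 0.5)[None, :, :]
    m = logratio - logratio[:, [0], :]
    mean_count = np.nanmean(sc.counts, axis=(1, 2))
    return NormalizedScreen(
        m=m,
        annotations=sc.annotations.copy().reset_index(drop=True),
        n_rounds=sc.n_rounds,
        n_reps=sc.n_reps,
        mean_count=mean_count,
        provenance={**sc.provenance, "normalization": method},
    )


def integrate_replicates(ns: NormalizedScreen) -> NormalizedScreen:
    """Fill whole-replicate dropouts with the across-replicate mean trajectory."""
    out = ns.copy()
    if out.n_reps == 1:
        return out
    missing_rep = np.isnan(out.m).all(axis=1)  # (V, R)
    if missing_rep.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_traj = np.nanmean(out.m, axis=2)  # (V, T+1)
        for v, r in zip(*np.nonzero(missing_rep)):
            out.m[v, :, r] = mean_traj[v]
        out.provenance["replicate_integration"] = int(missing_rep.sum())
    return out


def _greedy_merge(ordered_labels: list[int], sizes: dict[int, int], min_variants: int) -> dict[int, int]:
    """Left-to-right greedy merge of adjacent labels until each block >= min_variants.

    Returns old-label -> merged-label (the leftmost label of each block).
    A trailing short block is merged into its predecessor.
    """
    mapping: dict[int, int] = {}
    block: list[int] = []
    block_size = 0
    blocks: list[list[int]] = []
    for lab in ordered_labels:
        block.append(lab)
        block_size += sizes[lab]
        if block_size >= min_variants:
            blocks.append(block)
            block, block_size = [], 0
    if block:
        if blocks:
            blocks[-1].extend(block)
        else:
            blocks.append(block)
    for blk in blocks:
        for lab in blk:
            mapping[lab] = blk[0]
    return mapping


def assign_positions(
    ns: NormalizedScreen,
    min_variants: int = 10,
    seed: int = 0,
) -> NormalizedScreen:
    """Assign every variant a position label for the positional prior.

    Non-synonymous variants keep their residue index (indels are annotated at
    the leftmost residue); adjacent sparse positions are merged left-to-right
    until each label holds at least ``min_variants`` variants.  Synonymous and
    wild-type-reference variants are spread over artificial control-position
    labels, each sized to the maximum number of non-synonymous variants at
    any real position, by a seeded random partition.
    """
    out = ns.copy()
    ann = out.annotations
    is_control = (
        (ann["mutation_type"] == "synonymous") | ann["is_wildtype_reference"]
    ).to_numpy()
    positions = ann["position"].to_numpy()
    labels = np.empty(out.n_variants, dtype=int)

    nonsyn_pos = positions[~is_control]
    if nonsyn_pos.size:
        uniq, counts = np.unique(nonsyn_pos, return_counts=True)
        sizes = dict(zip(uniq.tolist(), counts.tolist()))
        mapping = _greedy_merge(sorted(sizes), sizes, min_variants)
        labels[~is_control] = [mapping[p] for p in nonsyn_pos]
        n_syn_per_pos = int(counts.max())
        max_real = int(uniq.max())
    else:
        n_syn_per_pos = max(min_variants, 1)
        max_real = int(positions.max(initial=0))

    n_controls = int(is_control.sum())
    if n_controls == 0:
        warnings.warn("no synonymous/wild-type variants; control positions skipped", stacklevel=2)
    else:
        n_ctrl_pos = max(1, math.ceil(n_controls / n_syn_per_pos))
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_controls)
        # near-equal random partition into n_ctrl_pos groups
        group_of = np.array_split(perm, n_ctrl_pos)
        ctrl_labels = np.empty(n_controls, dtype=int)
        for i, idx in enumerate(group_of):
            ctrl_labels[idx] = max_real + 1 + i
        # regroup control labels too, if the screen is syn-poor
        uniqc, countsc = np.unique(ctrl_labels, return_counts=True)
        csizes = dict(zip(uniqc.tolist(), countsc.tolist()))
        cmap = _greedy_merge(sorted(csizes), csizes, min_variants)
        labels[is_control] = [cmap[l] for l in ctrl_labels]
        out.provenance["control_positions"] = {
            "n_syn_per_pos": n_syn_per_pos,
            "n_control_positions": len(set(cmap.values())),
            "seed": seed,
        }
    out.position_label = labels
    return out


def assign_mean_groups(
    ns: NormalizedScreen,
    sc: ScreenCounts | None = None,
    group_size: int = 25,
) -> NormalizedScreen:
    """Block variants into mean-count groups sharing one residual variance.

    Variants are stably sorted by mean raw count (across time points and
    replicates) and cut into consecutive blocks of ``group_size``; a trailing
    block smaller than half the group size is merged into its predecessor.
    """
    out = ns.copy()
    mean_count = (
        np.nanmean(sc.counts, axis=(1, 2)) if sc is not None else out.mean_count
    )
    order = np.argsort(mean_count, kind="stable")
    V = out.n_variants
    n_groups = max(1, V // group_size + (1 if V % group_size else 0))
    groups = np.empty(V, dtype=int)
    for i in range(n_groups):
        groups[order[i * group_size : (i + 1) * group_size]] = i
    remainder = V % group_size
    if n_groups > 1 and 0 < remainder < group_size / 2:
        groups[groups == n_groups - 1] = n_groups - 2
    # re-densify group codes
    _, groups = np.unique(groups, return_inverse=True)
    out.mean_group = groups
    return out


def preprocess_screen(
    sc: ScreenCounts,
    max_missing_frac: float = 0.5,
    impute_method: str = "knn",
    k: int = 10,
    norm_method: str = "wt",
    min_variants_per_position: int = 10,
    mean_group_size: int = 25,
    seed: int = 0,
) -> NormalizedScreen:
    """Run the full default pipeline: filter, impute, normalize, integrate, group."""
    filtered = filter_variants(sc, max_missing_frac=max_missing_frac)
    imputed = impute_counts(filtered, method=impute_method, k=k)
    ns = normalize(imputed, method=norm_method)
    ns = integrate_replicates(ns)
    ns = assign_positions(ns, min_variants=min_variants_per_position, seed=seed)
    ns = assign_mean_groups(ns, imputed, group_size=mean_group_size)
    return ns
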