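"""Scalar and one-dimensional repeated-measures inference.

Scalar outcomes (co-contraction indices, coupling coefficients) are tested
with a two-way mixed ANOVA - between factor group (2 levels), within factor
session (3 levels) - with Greenhouse-Geisser correction when sphericity is
violated, partial eta squared effect sizes and Bonferroni-adjusted pairwise
session contrasts within each group when the interaction is significant.

Waveform outcomes (margin of stability, frontal-plane torques on the
101-node window base) are tested with a permutation-based 1D repeated-
measures ANOVA: the pointwise F statistic is computed at every node from
the classical sums-of-squares decomposition, and family-wise inference uses
the permutation distribution of the trace-wide maximum F. Session labels
are permuted within participants (within effects, interaction) and group
labels across participants (between effect); the identity permutation is
always included, making the test exact-level under exchangeability.
Clusters are maximal suprathreshold runs of the observed F trace, with
cluster p-values read off the same max-F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sci_stats

from .errors import DataError, DegenerateError, DesignError

__all__ = [
    "AnovaResult",
    "Spm1dResult",
    "mixed_anova_scalar",
    "spm_rm_anova_1d",
    "balance_design",
    "sensitivity_leave_one_out",
    "pearson_cait",
    "mann_whitney_attempts",
    "empirical_fwer",
]

ALPHA_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# scalar mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    effect: str                      # "group" | "session" | "interaction"
    F: float
    df: tuple[float, float]          # fractional under Greenhouse-Geisser
    p: float
    partial_eta_sq: float
    posthoc: list[tuple[str, float]] = field(default_factory=list)
    sphericity_eps: float | None = None


def mixed_anova_scalar(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "session",
    subject: str = "subject",
    between: str = "group",
    alpha: float = ALPHA_DEFAULT,
) -> list[AnovaResult]:
    """Two-way mixed ANOVA on a long-format scalar table.

    Participants with incomplete session data are dropped listwise. When the
    interaction is significant at ``alpha``, Bonferroni-adjusted pairwise
    session contrasts are computed within each group and attached to the
    interaction result as ``("<group>: s<i> vs s<j>", p_adj)`` tuples.
    """
    import pingouin as pg

    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    complete = counts[counts == n_levels].index
    if len(complete) < len(counts):
        data = data[data[subject].isin(complete)]
    per_group = data.groupby(between)[subject].nunique()
    if (per_group < 2).any() or len(per_group) < 2:
        raise DesignError("need >= 2 participants in each of two groups")

    if np.ptp(data[dv].to_numpy()) == 0:
        # no variance anywhere: every effect is exactly null
        return [AnovaResult(effect=e, F=0.0, df=(np.nan, np.nan), p=1.0,
                            partial_eta_sq=0.0)
                for e in ("group", "session", "interaction")]

    aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                         between=between, correction="auto", effsize="np2")
    name_map = {between: "group", within: "session", "Interaction": "interaction"}
    results: dict[str, AnovaResult] = {}
    for _, row in aov.iterrows():
        effect = name_map.get(row["Source"], row["Source"])
        p = row["p_unc"]
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        eps = row.get("eps", np.nan)
        p_gg = row.get("p_GG_corr", np.nan)
        sphericity_ok = bool(row.get("sphericity", True))
        if not sphericity_ok and np.isfinite(p_gg):
            p = p_gg
            df1, df2 = eps * df1, eps * df2
        results[effect] = AnovaResult(
            effect=effect, F=float(row["F"]), df=(df1, df2), p=float(p),
            partial_eta_sq=float(row["np2"]),
            sphericity_eps=float(eps) if np.isfinite(eps) else None)

    inter = results.get("interaction")
    if inter is not None and inter.p < alpha:
        for grp, sub in data.groupby(between):
            ph = pg.pairwise_tests(data=sub, dv=dv, within=within,
                                   subject=subject, padjust="bonf")
            pcol = "p_corr" if "p_corr" in ph.columns else "p_unc"
            for _, row in ph.iterrows():
                inter.posthoc.append(
                    (f"{grp}: {row['A']} vs {row['B']}", float(row[pcol])))
    return [results[e] for e in ("group", "session", "interaction") if e in results]


# ---------------------------------------------------------------------------
# pointwise F statistics (vectorized over nodes and permutation batches)
# ---------------------------------------------------------------------------

def _f_two_way_mixed(yg: np.ndarray) -> dict[str, np.ndarray]:
    """Pointwise F traces for a balanced two-way mixed design.

    ``yg`` has shape (..., a, n, b, K): groups x subjects-per-group x
    sessions x nodes, with arbitrary leading batch dimensions.
    Zero-variance nodes yield F = 0.
    """
    a, n, b = yg.shape[-4], yg.shape[-3], yg.shape[-2]
    grand = yg.mean(axis=(-4, -3, -2), keepdims=True)
    m_g = yg.mean(axis=(-3, -2), keepdims=True)
    m_s = yg.mean(axis=(-4, -3), keepdims=True)
    m_gs = yg.mean(axis=-3, keepdims=True)
    m_gi = yg.mean(axis=-2, keepdims=True)
    sum_cells = lambda x: x.sum(axis=(-4, -3, -2))
    ss_a = n * b * sum_cells((m_g - grand) ** 2)
    ss_subj = b * sum_cells((m_gi - m_g) ** 2)
    ss_b = a * n * sum_cells((m_s - grand) ** 2)
    ss_ab = n * sum_cells((m_gs - m_g - m_s + grand) ** 2)
    ss_err = sum_cells((yg - m_gs - m_gi + m_g) ** 2)
    # round-off floor: sums of squares at the accumulation-noise level of
    # the data magnitude are treated as zero (constant data -> F = 0)
    floor = 1e-22 * sum_cells(yg ** 2) + 1e-300

    def fratio(ss_num, df_num, ss_den, df_den):
        num = ss_num / df_num
        den = ss_den / df_den
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(den > floor, num / np.where(den > 0, den, 1.0), 0.0)
        return f

    df_between_err = a * (n - 1)
    df_within_err = a * (n - 1) * (b - 1)
    return {
        "group": fratio(ss_a, a - 1, ss_subj, df_between_err),
        "session": fratio(ss_b, b - 1, ss_err, df_within_err),
        "interaction": fratio(ss_ab, (a - 1) * (b - 1), ss_err, df_within_err),
    }


def _f_one_way_rm(y: np.ndarray) -> np.ndarray:
    """Pointwise F trace(s) for a one-way repeated-measures design.

    ``y`` has shape (..., n, b, K): subjects x sessions x nodes.
    """
    n, b = y.shape[-3], y.shape[-2]
    grand = y.mean(axis=(-3, -2), keepdims=True)
    m_i = y.mean(axis=-2, keepdims=True)
    m_j = y.mean(axis=-3, keepdims=True)
    ss_b = ((m_j - grand) ** 2).sum(axis=(-3, -2)) * n
    ss_err = ((y - m_i - m_j + grand) ** 2).sum(axis=(-3, -2))
    floor = 1e-22 * (y ** 2).sum(axis=(-3, -2)) + 1e-300
    num = ss_b / (b - 1)
    den = ss_err / ((n - 1) * (b - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > floor, num / np.where(den > 0, den, 1.0), 0.0)


# ---------------------------------------------------------------------------
# permutation SPM
# ---------------------------------------------------------------------------

@dataclass
class Spm1dResult:
    """Permutation inference for one effect over the waveform."""

    effect: str
    f_trace: np.ndarray                    # pointwise F, length K
    threshold: float                       # critical F* at the nominal level
    clusters: list[tuple[float, float]]    # suprathreshold time intervals, s
    cluster_p: list[float]
    p_max: float                           # p of the trace-wide maximum F
    n_permutations: int
    alpha: float
    seed: int

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def _session_perm_indices(rng: np.random.Generator, n_perm: int, n_subj: int,
                          b: int) -> np.ndarray:
    """(n_perm, n_subj, b) session-label permutations; first is identity."""
    idx = np.empty((n_perm, n_subj, b), dtype=np.intp)
    idx[0] = np.arange(b)
    base = np.tile(np.arange(b), (n_subj, 1))
    for p in range(1, n_perm):
        idx[p] = rng.permuted(base, axis=1)
    return idx


def _clusters_from_trace(f_trace: np.ndarray, threshold: float,
                         node_dt: float) -> tuple[list[tuple[float, float]], list[float]]:
    above = f_trace > threshold
    clusters: list[tuple[float, float]] = []
    maxima: list[float] = []
    k = 0
    K = f_trace.size
    while k < K:
        if above[k]:
            start = k
            while k + 1 < K and above[k + 1]:
                k += 1
            clusters.append((start * node_dt, k * node_dt))
            maxima.append(float(f_trace[start:k + 1].max()))
        k += 1
    return clusters, maxima


def spm_rm_anova_1d(
    waveforms: np.ndarray,
    groups: np.ndarray | list | None = None,
    design: str = "two-way",
    n_permutations: int = 1000,
    alpha: float = ALPHA_DEFAULT,
    seed: int = 0,
    node_rate: float = 100.0,
    batch: int = 128,
    effects: list[str] | None = None,
) -> dict[str, Spm1dResult]:
    """Permutation 1D repeated-measures ANOVA over a waveform family.

    Parameters
    ----------
    waveforms:
        Array (n_subjects, n_sessions, n_nodes).
    groups:
        Group label per subject (two-way design only); the design must be
        balanced - use :func:`balance_design` first otherwise.
    design:
        ``"two-way"`` (mixed: between group x within session) or
        ``"one-way"`` (within session only).
    n_permutations:
        Size of the max-F null distribution, identity included (>= 100).
    effects:
        Restrict the two-way analysis to a subset of
        {"group", "session", "interaction"} (all by default).

    Returns a mapping from effect name to :class:`Spm1dResult`.
    """
    y = np.asarray(waveforms, dtype=float)
    if y.ndim != 3:
        raise DataError("waveforms must be (subjects, sessions, nodes)")
    if n_permutations < 100:
        raise DataError("n_permutations must be >= 100")
    n_subj, b, K = y.shape
    rng = np.random.default_rng([seed, 0x5B])
    node_dt = 1.0 / node_rate
    k_crit = int(np.floor(alpha * n_permutations))

    def build_result(effect, f_obs, perm_max):
        perm_sorted = np.sort(perm_max)[::-1]
        threshold = float(perm_sorted[k_crit]) if k_crit < n_permutations else np.inf
        obs_max = float(f_obs.max())
        p_max = float(np.mean(perm_max >= obs_max))
        clusters, maxima = _clusters_from_trace(f_obs, threshold, node_dt)
        cluster_p = [float(np.mean(perm_max >= m)) for m in maxima]
        return Spm1dResult(effect=effect, f_trace=f_obs, threshold=threshold,
                           clusters=clusters, cluster_p=cluster_p, p_max=p_max,
                           n_permutations=n_permutations, alpha=alpha, seed=seed)

    if design == "one-way":
        f_obs = _f_one_way_rm(y)
        idx = _session_perm_indices(rng, n_permutations, n_subj, b)
        perm_max = np.empty(n_permutations)
        subj_ax = np.arange(n_subj)[None, :, None]
        for lo in range(0, n_permutations, batch):
            hi = min(lo + batch, n_permutations)
            yp = y[subj_ax, idx[lo:hi], :]
            perm_max[lo:hi] = _f_one_way_rm(yp).max(axis=-1)
        return {"session": build_result("session", f_obs, perm_max)}

    if design != "two-way":
        raise DataError(f"unknown design {design!r}")
    if groups is None:
        raise DesignError("two-way design requires group labels")
    groups = np.asarray(groups)
    if groups.shape[0] != n_subj:
        raise DesignError("groups length must match the number of subjects")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) != 2:
        raise DesignError("two-way design requires exactly two groups")
    if counts[0] != counts[1]:
        raise DesignError(
            f"unbalanced design ({counts[0]} vs {counts[1]}); "
            "apply balance_design before the two-way 1D ANOVA")
    n = int(counts[0])
    order = np.argsort(groups, kind="stable")
    yg = y[order].reshape(2, n, b, K)
    f_obs = _f_two_way_mixed(yg)
    wanted = list(effects) if effects is not None else ["group", "session", "interaction"]
    unknown = set(wanted) - {"group", "session", "interaction"}
    if unknown:
        raise DataError(f"unknown effect(s) {sorted(unknown)}")

    results: dict[str, Spm1dResult] = {}
    y_sorted = y[order]
    within_wanted = [e for e in ("session", "interaction") if e in wanted]
    if within_wanted:
        # within-subject permutations: session and interaction effects
        idx = _session_perm_indices(rng, n_permutations, n_subj, b)
        perm_max = {e: np.empty(n_permutations) for e in within_wanted}
        subj_ax = np.arange(n_subj)[None, :, None]
        for lo in range(0, n_permutations, batch):
            hi = min(lo + batch, n_permutations)
            yp = y_sorted[subj_ax, idx[lo:hi], :].reshape(hi - lo, 2, n, b, K)
            f_perm = _f_two_way_mixed(yp)
            for e in within_wanted:
                perm_max[e][lo:hi] = f_perm[e].max(axis=-1)
        for e in within_wanted:
            results[e] = build_result(e, f_obs[e], perm_max[e])

    if "group" in wanted:
        # between-subject permutations: group effect
        gidx = np.empty((n_permutations, n_subj), dtype=np.intp)
        gidx[0] = np.arange(n_subj)
        for p in range(1, n_permutations):
            gidx[p] = rng.permutation(n_subj)
        perm_max_g = np.empty(n_permutations)
        for lo in range(0, n_permutations, batch):
            hi = min(lo + batch, n_permutations)
            yp = y_sorted[gidx[lo:hi]].reshape(hi - lo, 2, n, b, K)
            perm_max_g[lo:hi] = _f_two_way_mixed(yp)["group"].max(axis=-1)
        results["group"] = build_result("group", f_obs["group"], perm_max_g)
    return {e: results[e] for e in ("group", "session", "interaction") if e in results}


# ---------------------------------------------------------------------------
# design balancing
# ---------------------------------------------------------------------------

def balance_design(
    subject_groups: dict[str, str],
    drop: str | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str], str]:
    """Trim the surplus group so both groups have equal size.

    Returns (kept ids, dropped ids, note). Already-balanced input is a
    no-op. ``drop`` pins a specific surplus-group participant (for
    leave-one-out sensitivity); otherwise the choice is seeded-random.
    """
    ids = list(subject_groups)
    by_group: dict[str, list[str]] = {}
    for sid, g in subject_groups.items():
        by_group.setdefault(g, []).append(sid)
    if len(by_group) != 2:
        raise DesignError("balance_design expects exactly two groups")
    (g1, ids1), (g2, ids2) = by_group.items()
    if len(ids1) == len(ids2):
        return ids, [], "already balanced; no exclusion"
    surplus_group, surplus = (g1, ids1) if len(ids1) > len(ids2) else (g2, ids2)
    n_drop = abs(len(ids1) - len(ids2))
    if drop is not None:
        if drop not in surplus:
            raise DesignError(f"{drop!r} is not in the surplus group {surplus_group}")
        dropped = [drop]
        if n_drop > 1:
            rng = np.random.default_rng([seed, 0xBA])
            rest = [s for s in surplus if s != drop]
            dropped += list(rng.choice(rest, size=n_drop - 1, replace=False))
    else:
        rng = np.random.default_rng([seed, 0xBA])
        dropped = list(rng.choice(surplus, size=n_drop, replace=False))
    kept = [sid for sid in ids if sid not in dropped]
    note = f"excluded {dropped} from {surplus_group} to balance the design"
    return kept, dropped, note


def _interval_jaccard(a: list[tuple[float, float]], b: list[tuple[float, float]],
                      grid: np.ndarray) -> float:
    """Jaccard overlap of two interval unions evaluated on a time grid."""
    in_a = np.zeros(grid.size, dtype=bool)
    in_b = np.zeros(grid.size, dtype=bool)
    for lo, hi in a:
        in_a |= (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    for lo, hi in b:
        in_b |= (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    union = (in_a | in_b).sum()
    if union == 0:
        return 1.0
    return float((in_a & in_b).sum() / union)


def sensitivity_leave_one_out(
    waveforms: np.ndarray,
    subject_ids: list[str],
    subject_groups: dict[str, str],
    effect: str = "interaction",
    **spm_kwargs,
) -> dict:
    """Leave-one-out sensitivity of the balanced two-way 1D ANOVA.

    Repeats the balanced analysis once per surplus-group participant
    (each excluded in turn) and reports the cluster intervals of
    ``effect`` per replicate plus the mean pairwise Jaccard overlap.
    """
    groups_arr = np.asarray([subject_groups[s] for s in subject_ids])
    labels, counts = np.unique(groups_arr, return_counts=True)
    if counts[0] == counts[1]:
        raise DesignError("design already balanced; nothing to leave out")
    surplus_group = labels[np.argmax(counts)]
    surplus_ids = [s for s in subject_ids if subject_groups[s] == surplus_group]
    replicates: dict[str, list[tuple[float, float]]] = {}
    for drop_id in surplus_ids:
        kept, _, _ = balance_design(subject_groups, drop=drop_id)
        sel = [subject_ids.index(s) for s in kept]
        res = spm_rm_anova_1d(np.asarray(waveforms)[sel],
                              groups=[subject_groups[s] for s in kept],
                              design="two-way", **spm_kwargs)
        replicates[drop_id] = res[effect].clusters
    grid = np.arange(0.0, 1.0 + 1e-9, 0.01)
    keys = list(replicates)
    overlaps = [
        _interval_jaccard(replicates[keys[i]], replicates[keys[j]], grid)
        for i in range(len(keys)) for j in range(i + 1, len(keys))
    ]
    return {"effect": effect, "replicates": replicates,
            "mean_jaccard": float(np.mean(overlaps)) if overlaps else 1.0}


# ---------------------------------------------------------------------------
# scalar correlations and rank tests
# ---------------------------------------------------------------------------

def pearson_cait(cait: np.ndarray, cci_means: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between CAIT scores and across-block mean CCIs."""
    cait = np.asarray(cait, dtype=float)
    cci_means = np.asarray(cci_means, dtype=float)
    if cait.shape != cci_means.shape or cait.ndim != 1 or cait.size < 3:
        raise DataError("paired vectors of length >= 3 required")
    if cait.std() == 0 or cci_means.std() == 0:
        raise DegenerateError("zero-variance input; correlation undefined")
    r, p = sci_stats.pearsonr(cait, cci_means)
    return float(r), float(p)


def mann_whitney_attempts(a, b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation.

    Returns (U, Z, p) where U is the smaller of the two U statistics (the
    convention under which the study's software reports U) and Z is the
    tie-corrected standardized statistic (no continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sci_stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    mu = n1 * n2 / 2.0
    N = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1))
    sigma_sq = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if sigma_sq <= 0:
        return float(u), 0.0, 1.0
    z = (u - mu) / np.sqrt(sigma_sq)
    p = 2.0 * sci_stats.norm.sf(abs(z))
    return float(u), float(z), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# null-simulation calibration of the permutation SPM
# ---------------------------------------------------------------------------

def empirical_fwer(
    n_datasets: int = 500,
    n_per_group: int = 12,
    n_sessions: int = 3,
    n_nodes: int = 101,
    n_permutations: int = 500,
    alpha: float = ALPHA_DEFAULT,
    seed: int = 0,
    effect: str = "interaction",
    smooth_sigma: float = 8.0,
) -> dict:
    """Family-wise false-positive rate of the permutation 1D RM-ANOVA under
    a global null.

    Each dataset is a balanced two-group design of smooth Gaussian
    waveforms with no effects whatsoever (white noise smoothed along the
    node axis); the returned ``fwer`` is the fraction of datasets for which
    the requested effect yields any significant cluster at the nominal
    level. For a valid procedure this estimate should match ``alpha`` up to
    binomial error.
    """
    from scipy.ndimage import gaussian_filter1d

    n_subj = 2 * n_per_group
    groups = ["A"] * n_per_group + ["B"] * n_per_group
    hits = 0
    for d in range(n_datasets):
        rng = np.random.default_rng([seed, 0xFE, d])
        y = gaussian_filter1d(
            rng.standard_normal((n_subj, n_sessions, n_nodes)),
            smooth_sigma, axis=-1)
        res = spm_rm_anova_1d(y, groups=groups, design="two-way",
                              n_permutations=n_permutations, alpha=alpha,
                              seed=d + 1, effects=[effect])
        hits += res[effect].significant
    return {"fwer": hits / n_datasets, "hits": hits, "n_datasets": n_datasets,
            "alpha": alpha, "effect": effect,
            "n_permutations": n_permutations}
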