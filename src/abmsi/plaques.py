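"""Plaque-level truncation statistics and group comparisons.

Peptides are grouped into four truncation categories — full-length
(unmodified A-beta 1-40/1-42), N-terminally truncated (A-beta x-40/x-42 with
a ragged or pyroglutamate-modified N-terminus), C-terminally truncated
(A-beta 1-y, y not in {40, 42}) and bi-terminally truncated — and each
plaque's TIC-normalised peptide abundances are converted to category
fractions plus the Aβx-40 vs Aβx-42 terminal split of the N-truncated pool.
Per-subject sampling caps the number of plaques per subject (random, seeded)
so that no individual dominates group statistics; co-localization is
summarised by Pearson correlation on log-transformed abundances; group
differences use a Shapiro-Wilk normality gate feeding Welch's t-test or
Mann-Whitney U (two groups) and Kruskal-Wallis with Dunn's post-hoc tests
(more than two).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .masslist import PeptideVariant

__all__ = [
    "TruncationCategory",
    "META_COLUMNS",
    "classify_truncation",
    "category_fractions",
    "truncation_profiles",
    "subject_profiles",
    "sample_plaques",
    "log_pearson_matrix",
    "compare_groups",
    "GroupComparisonResult",
]

#: Non-variant columns of a plaque peptide table.
META_COLUMNS = ["plaque_id", "subject", "group", "area_um2"]

CATEGORIES = ["full_length", "N_truncated", "C_truncated", "bi_truncated"]


class TruncationCategory(str, Enum):
    full_length = "full_length"
    N_truncated = "N_truncated"
    C_truncated = "C_truncated"
    bi_truncated = "bi_truncated"


def classify_truncation(v: PeptideVariant) -> TruncationCategory:
    """Four-way truncation category of a variant (total function).

    Pyroglutamate formation modifies the N-terminus, so pE species count as
    N-terminally truncated (or bi-truncated if the C-terminus is short too).
    """
    full_c_terminus = v.end in (40, 42)
    intact_n = v.start == 1 and not v.pyroglu
    if intact_n and full_c_terminus:
        return TruncationCategory.full_length
    if intact_n:
        return TruncationCategory.C_truncated
    if full_c_terminus:
        return TruncationCategory.N_truncated
    return TruncationCategory.bi_truncated


def variant_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("Abeta")]


def _category_of_column(name: str, masslist: Sequence[PeptideVariant]) -> TruncationCategory:
    for v in masslist:
        if v.name == name:
            return classify_truncation(v)
    raise KeyError(f"variant {name!r} not in mass list")


def category_fractions(
    abundances: Mapping[str, float] | pd.Series,
    masslist: Sequence[PeptideVariant],
) -> dict[str, float]:
    """Per-category fraction of total A-beta abundance for one plaque.

    Returns the four fractions (summing to 1) plus the terminal split of the
    N-truncated pool over {x-40, x-42}. Zero total abundance raises, since
    such a plaque carries no defined profile and is excluded upstream.
    """
    by_cat = {c: 0.0 for c in CATEGORIES}
    split = {"40": 0.0, "42": 0.0}
    lookup = {v.name: v for v in masslist}
    total = 0.0
    for name, value in dict(abundances).items():
        if not name.startswith("Abeta") or value <= 0:
            continue
        v = lookup[name]
        cat = classify_truncation(v)
        by_cat[cat.value] += value
        total += value
        if cat is TruncationCategory.N_truncated:
            split[str(v.end)] += value
    if total <= 0:
        raise ValueError("zero total abundance: undefined profile")
    out = {c: by_cat[c] / total for c in CATEGORIES}
    n_total = split["40"] + split["42"]
    out["split_40"] = split["40"] / n_total if n_total > 0 else np.nan
    out["split_42"] = split["42"] / n_total if n_total > 0 else np.nan
    return out


def truncation_profiles(
    table: pd.DataFrame, masslist: Sequence[PeptideVariant]
) -> pd.DataFrame:
    """Per-plaque truncation profile table.

    Plaques with zero total abundance are excluded with a warning and listed
    nowhere downstream.
    """
    cols = variant_columns(table)
    rows = []
    n_dropped = 0
    for _, row in table.iterrows():
        try:
            frac = category_fractions(row[cols], masslist)
        except ValueError:
            n_dropped += 1
            continue
        rec = {m: row[m] for m in META_COLUMNS if m in table.columns}
        rec.update(frac)
        rows.append(rec)
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} plaque(s) with zero total abundance")
    return pd.DataFrame(rows)


def subject_profiles(
    table: pd.DataFrame,
    masslist: Sequence[PeptideVariant],
    method: str = "pooled",
) -> pd.DataFrame:
    """Per-subject truncation profile.

    ``pooled`` (default) sums abundance over the subject's plaques before
    taking fractions; ``mean_of_plaques`` averages per-plaque fractions.
    """
    cols = variant_columns(table)
    out = []
    for (subject, group), sub in table.groupby(["subject", "group"], sort=True):
        if method == "pooled":
            pooled = sub[cols].sum(axis=0)
            frac = category_fractions(pooled, masslist)
        elif method == "mean_of_plaques":
            prof = truncation_profiles(sub, masslist)
            frac = {c: prof[c].mean() for c in CATEGORIES + ["split_40", "split_42"]}
        else:
            raise ValueError("method must be 'pooled' or 'mean_of_plaques'")
        rec = {"subject": subject, "group": group, "n_plaques": len(sub)}
        rec.update(frac)
        out.append(rec)
    return pd.DataFrame(out)


def sample_plaques(
    table: pd.DataFrame, n_per_subject: int = 300, seed: int = 0
) -> pd.DataFrame:
    """Uniform per-subject random sample of plaques, without replacement.

    Caps every subject at ``n_per_subject`` rows so that plaque-rich subjects
    do not dominate group statistics; subjects with fewer plaques contribute
    all rows (with a warning). Deterministic given the seed.
    """
    if n_per_subject < 1:
        raise ValueError("n_per_subject must be >= 1")
    if table.empty:
        return table.copy()
    rng = np.random.default_rng(seed)
    parts = []
    for subject, sub in table.groupby("subject", sort=True):
        if len(sub) <= n_per_subject:
            if len(sub) < n_per_subject:
                warnings.warn(
                    f"subject {subject!r} has only {len(sub)} plaques "
                    f"(< {n_per_subject}); using all"
                )
            parts.append(sub)
        else:
            take = rng.choice(len(sub), size=n_per_subject, replace=False)
            parts.append(sub.iloc[np.sort(take)])
    return pd.concat(parts, axis=0).reset_index(drop=True)


def log_pearson_matrix(
    table: pd.DataFrame, floor_policy: str = "half_min_positive"
) -> pd.DataFrame:
    """Pearson correlation of log-transformed abundances across plaques.

    Zeros are floored at half the smallest positive abundance of each
    variant before the log. Variants with zero variance (including
    all-zero columns) give undefined entries, reported as NaN and flagged
    with a warning, never as 0. The diagonal is 1 where defined.
    """
    cols = variant_columns(table)
    X = table[cols].to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("correlation needs at least 3 plaques")
    if floor_policy != "half_min_positive":
        raise ValueError("unknown floor policy")
    floored = X.copy()
    for j in range(X.shape[1]):
        pos = X[:, j][X[:, j] > 0]
        if len(pos):
            floored[:, j] = np.maximum(X[:, j], pos.min() / 2)
    with np.errstate(divide="ignore"):
        L = np.log(floored)
    L[~np.isfinite(L)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(L, axis=0)
    constant = ~(sd > 0) | np.isnan(sd)
    if constant.any():
        warnings.warn(
            "constant columns with undefined correlations: "
            + ", ".join(np.array(cols)[constant])
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = np.corrcoef(L, rowvar=False)
    R[constant, :] = np.nan
    R[:, constant] = np.nan
    return pd.DataFrame(R, index=cols, columns=cols)


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    p_value: float
    group_stats: dict[str, dict[str, float]]
    posthoc: pd.DataFrame | None = None
    normality_p: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "none") -> pd.DataFrame:
    """Dunn's pairwise rank z-tests after Kruskal-Wallis, with tie correction."""
    names = list(groups)
    all_values = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(all_values)
    n_total = len(all_values)
    mean_ranks = {}
    start = 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[start : start + n_g].mean()
        start += n_g
    _, tie_counts = np.unique(all_values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    rows = []
    raw_ps = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(
                (n_total * (n_total + 1) / 12 - tie_term)
                * (1 / len(groups[a]) + 1 / len(groups[b]))
            )
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
            raw_ps.append(p)
    df = pd.DataFrame(rows)
    raw = np.asarray(raw_ps)
    if adjust == "none":
        df["p_adj"] = raw
    elif adjust == "bonferroni":
        df["p_adj"] = np.minimum(raw * len(raw), 1.0)
    elif adjust == "holm":
        order = np.argsort(raw)
        adj = np.empty_like(raw)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, raw[idx] * (len(raw) - rank))
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    else:
        raise ValueError("adjust must be 'none', 'bonferroni' or 'holm'")
    return df


def compare_groups(
    values_by_group: Mapping[str, np.ndarray],
    alpha: float = 0.05,
    posthoc_adjust: str = "none",
) -> GroupComparisonResult:
    """Normality-gated group comparison.

    Two groups: Shapiro-Wilk on each at ``alpha``; if both pass, Welch's
    unequal-variance t-test, otherwise Mann-Whitney U (exact for small
    samples without ties, normal approximation with tie correction
    otherwise). More than two groups: Kruskal-Wallis, followed by Dunn's
    pairwise z-tests when significant. Groups with fewer than 3 values skip
    the normality gate and force the rank test, with a warning.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    group_stats = {
        g: {"n": len(v), "mean": float(np.mean(v)), "median": float(np.median(v))}
        for g, v in groups.items()
    }
    if len(groups) == 2:
        (name_a, a), (name_b, b) = groups.items()
        gate_ok = all(len(v) >= 3 for v in (a, b))
        normality_p = None
        normal = False
        if gate_ok:
            normality_p = {
                name_a: float(stats.shapiro(a).pvalue),
                name_b: float(stats.shapiro(b).pvalue),
            }
            normal = all(p > alpha for p in normality_p.values())
        else:
            warnings.warn("group with < 3 values: normality gate skipped, rank test used")
        if normal:
            res = stats.ttest_ind(a, b, equal_var=False)
            return GroupComparisonResult(
                test="welch_t", statistic=float(res.statistic),
                p_value=float(res.pvalue), group_stats=group_stats,
                normality_p=normality_p,
            )
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupComparisonResult(
            test="mann_whitney", statistic=float(res.statistic),
            p_value=float(res.pvalue), group_stats=group_stats,
            normality_p=normality_p,
        )
    res = stats.kruskal(*groups.values())
    posthoc = None
    if res.pvalue <= alpha:
        posthoc = _dunn_posthoc(groups, adjust=posthoc_adjust)
    return GroupComparisonResult(
        test="kruskal_wallis", statistic=float(res.statistic),
        p_value=float(res.pvalue), group_stats=group_stats, posthoc=posthoc,
    )
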