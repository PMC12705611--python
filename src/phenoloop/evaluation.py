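"""Model-assessment protocol: stratified repeated k-fold CV with NRMSE/CRPS,
bootstrap confidence intervals, scrambled-null ratios, and group comparisons.

The scheme mirrors the study protocol: doses are binned into 3 equal-frequency
bins (quantile discretization), 5 repeats of stratified 6-fold CV give 30
test-train splits, each test fold is scored by NRMSE (normalized by that test
set's target range) and mean CRPS, the split-level NRMSE mean gets a
1000-resample percentile bootstrap 95% CI, and a "null ratio" divides the
full-data NRMSE by the NRMSE obtained after scrambling the targets (a ratio
near 1 means no dose signal; below 1, genuine signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import KBinsDiscretizer
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .gp import GPConfig, fit_gp, crps_gaussian, nrmse

__all__ = [
    "CVScheme",
    "EvaluationReport",
    "ComparisonResult",
    "stratified_splits",
    "evaluate_model",
    "null_nrmse_ratio",
    "compare_models",
    "endpoint_comparison",
    "anova_tukey",
    "minmax_scale",
    "cohens_d",
]


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold scheme (k * repeats splits)."""

    k: int = 6
    repeats: int = 5
    n_bins: int = 3
    seed: int = 0

    @property
    def n_splits(self) -> int:
        return self.k * self.repeats


def stratified_splits(doses, scheme: CVScheme | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Dose-stratified repeated k-fold splits.

    Doses are quantile-binned into ``n_bins`` equal-frequency bins; each
    repeat is a seeded stratified shuffle so per-fold bin counts differ by
    at most 1, and folds differ between repeats.
    """
    scheme = scheme or CVScheme()
    doses = np.asarray(doses, dtype=float).reshape(-1, 1)
    if doses.shape[0] < scheme.k:
        raise ValueError("fewer samples than folds")
    if np.unique(doses).size < scheme.n_bins:
        raise ValueError("fewer distinct doses than stratification bins")
    binner = KBinsDiscretizer(n_bins=scheme.n_bins, encode="ordinal", strategy="quantile")
    bins = binner.fit_transform(doses).ravel().astype(int)
    # stratification needs >= k members per bin; otherwise (e.g. leave-one-out
    # at n == k) fall back to a plain shuffled k-fold
    stratify = np.bincount(bins).min() >= scheme.k
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(scheme.repeats):
        state = (scheme.seed * 1000 + rep) % (2 ** 31)
        if stratify:
            skf = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=state)
            folds = skf.split(doses, bins)
        else:
            folds = KFold(n_splits=scheme.k, shuffle=True, random_state=state).split(doses)
        splits.extend((tr.copy(), te.copy()) for tr, te in folds)
    return splits


@dataclass
class EvaluationReport:
    """Per-split scores plus the aggregate quantities of the protocol."""

    per_split: pd.DataFrame          # split, nrmse, crps, excluded
    mean_nrmse: float
    mean_crps: float
    ci95: tuple[float, float]        # percentile bootstrap over split NRMSE
    full_nrmse: float
    null_ratio: float
    n_excluded_splits: int
    target: str = ""
    variant: str = ""

    def to_json_dict(self) -> dict:
        return dict(target=self.target, variant=self.variant,
                    mean_nrmse=self.mean_nrmse, mean_crps=self.mean_crps,
                    ci95=list(self.ci95), full_nrmse=self.full_nrmse,
                    null_ratio=self.null_ratio,
                    n_excluded_splits=self.n_excluded_splits)


def null_nrmse_ratio(X, y, gp_config: GPConfig | None = None, seed: int = 0,
                     n_scrambles: int = 1) -> float:
    """Full-data NRMSE of the real targets over the scrambled-target NRMSE."""
    gp_config = gp_config or GPConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    real = fit_gp(X, y, gp_config)
    real_nrmse = nrmse(real.predict(X), y)
    rng = np.random.default_rng(seed)
    null_vals = []
    for _ in range(n_scrambles):
        y_perm = rng.permutation(y)
        scram = fit_gp(X, y_perm, gp_config)
        null_vals.append(nrmse(scram.predict(X), y_perm))
    return float(real_nrmse / np.mean(null_vals))


def evaluate_model(X, y, scheme: CVScheme | None = None,
                   gp_config: GPConfig | None = None, n_boot: int = 1000,
                   n_scrambles: int = 1, target: str = "",
                   variant: str = "") -> EvaluationReport:
    """Run the full CV / bootstrap / null-ratio protocol for one model variant."""
    scheme = scheme or CVScheme()
    gp_config = gp_config or GPConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    doses = X if X.ndim == 1 else X[:, 0]
    splits = stratified_splits(doses, scheme)

    rows = []
    for i, (tr, te) in enumerate(splits):
        y_te = y[te]
        rng_range = float(y_te.max() - y_te.min())
        if rng_range <= 0:
            rows.append(dict(split=i, nrmse=np.nan, crps=np.nan, excluded=True))
            continue
        model = fit_gp(X[tr], y[tr], gp_config)
        mu, sd = model.predict(X[te], return_std=True, include_noise=True)
        rows.append(dict(split=i, nrmse=nrmse(mu, y_te, rng_range),
                         crps=float(np.mean(crps_gaussian(mu, sd, y_te))),
                         excluded=False))
    per_split = pd.DataFrame(rows)
    kept = per_split.loc[~per_split.excluded, "nrmse"].to_numpy()
    if kept.size == 0:
        raise ValueError("every split had zero test-target range")
    mean_nrmse = float(kept.mean())
    mean_crps = float(per_split.loc[~per_split.excluded, "crps"].mean())

    rng = np.random.default_rng(scheme.seed + 7919)
    boot_idx = rng.integers(0, kept.size, size=(n_boot, kept.size))
    boot_means = kept[boot_idx].mean(axis=1)
    ci95 = (float(np.percentile(boot_means, 2.5)), float(np.percentile(boot_means, 97.5)))

    full = fit_gp(X, y, gp_config)
    full_nrmse = nrmse(full.predict(X), y)
    ratio = null_nrmse_ratio(X, y, gp_config, seed=scheme.seed + 104729,
                             n_scrambles=n_scrambles)
    return EvaluationReport(per_split=per_split, mean_nrmse=mean_nrmse,
                            mean_crps=mean_crps, ci95=ci95, full_nrmse=full_nrmse,
                            null_ratio=ratio,
                            n_excluded_splits=int(per_split.excluded.sum()),
                            target=target, variant=variant)


@dataclass
class ComparisonResult:
    """A t-test / ANOVA+Tukey comparison with effect sizes."""

    kind: str                         # "t-test" or "anova+tukey"
    statistic: float
    pvalue: float                     # omnibus p (t-test or ANOVA F)
    pairwise: pd.DataFrame            # group_a, group_b, p_adj [, effect_size]
    improvements: dict = field(default_factory=dict)  # (a, b) -> percent


def _split_values(report_or_values) -> np.ndarray:
    if isinstance(report_or_values, EvaluationReport):
        df = report_or_values.per_split
        return df.loc[~df.excluded, "nrmse"].to_numpy()
    return np.asarray(report_or_values, dtype=float)


def compare_models(variants: dict) -> ComparisonResult:
    """Compare 2-3 model variants on per-split NRMSE.

    Two variants: Student's t-test.  Three: one-way ANOVA plus Tukey HSD.
    Percent improvement of B over A is (mean_A - mean_B)/mean_A * 100,
    computed from unrounded means.
    """
    names = list(variants)
    values = {k: _split_values(v) for k, v in variants.items()}
    lengths = {len(v) for v in values.values()}
    if len(lengths) != 1:
        raise ValueError("variants must have equal split counts")
    if not 2 <= len(names) <= 3:
        raise ValueError("compare 2 or 3 variants")
    improvements = {}
    for a in names:
        for b in names:
            if a != b:
                ma = values[a].mean()
                improvements[(a, b)] = float((ma - values[b].mean()) / ma * 100.0)
    if len(names) == 2:
        t, p = stats.ttest_ind(values[names[0]], values[names[1]])
        pairwise = pd.DataFrame([dict(group_a=names[0], group_b=names[1],
                                      p_adj=float(p))])
        return ComparisonResult(kind="t-test", statistic=float(t), pvalue=float(p),
                                pairwise=pairwise, improvements=improvements)
    f, p = stats.f_oneway(*(values[n] for n in names))
    flat = np.concatenate([values[n] for n in names])
    labels = np.concatenate([[n] * len(values[n]) for n in names])
    tukey = pairwise_tukeyhsd(flat, labels)
    pairs = [(a, b) for i, a in enumerate(tukey.groupsunique)
             for b in tukey.groupsunique[i + 1:]]
    pairwise = pd.DataFrame([dict(group_a=a, group_b=b, p_adj=float(padj))
                             for (a, b), padj in zip(pairs, tukey.pvalues)])
    return ComparisonResult(kind="anova+tukey", statistic=float(f), pvalue=float(p),
                            pairwise=pairwise, improvements=improvements)


def cohens_d(a, b) -> float:
    """Standardized mean difference (pooled sd)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def anova_tukey(groups: dict) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD over all pairs of the given groups."""
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    f, p = stats.f_oneway(*arrays)
    flat = np.concatenate(arrays)
    labels = np.concatenate([[str(n)] * len(a) for n, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(flat, labels)
    pairs = [(a, b) for i, a in enumerate(tukey.groupsunique)
             for b in tukey.groupsunique[i + 1:]]
    pairwise = pd.DataFrame([dict(group_a=a, group_b=b, p_adj=float(padj))
                             for (a, b), padj in zip(pairs, tukey.pvalues)])
    return ComparisonResult(kind="anova+tukey", statistic=float(f), pvalue=float(p),
                            pairwise=pairwise)


def endpoint_comparison(groups: dict, control_label) -> ComparisonResult:
    """Harvest-endpoint comparison of treatment groups against a control.

    Two groups fall back to a Student's t-test; otherwise one-way ANOVA with
    Tukey HSD restricted to pairs containing the control, plus Cohen's d
    (pooled sd) of each treatment versus the control.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    names = list(groups)
    arrays = {n: np.asarray(groups[n], dtype=float) for n in names}
    if len(names) < 2 or any(len(a) < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    control = arrays[control_label]
    if len(names) == 2:
        other = next(n for n in names if n != control_label)
        t, p = stats.ttest_ind(arrays[other], control)
        pairwise = pd.DataFrame([dict(group_a=str(other), group_b=str(control_label),
                                      p_adj=float(p),
                                      effect_size=cohens_d(arrays[other], control))])
        return ComparisonResult(kind="t-test", statistic=float(t), pvalue=float(p),
                                pairwise=pairwise)
    res = anova_tukey(arrays)
    ctrl = str(control_label)
    mask = (res.pairwise.group_a == ctrl) | (res.pairwise.group_b == ctrl)
    pairwise = res.pairwise.loc[mask].reset_index(drop=True).copy()
    effects = []
    for _, row in pairwise.iterrows():
        treat = row.group_b if row.group_a == ctrl else row.group_a
        key = next(n for n in names if str(n) == treat)
        effects.append(cohens_d(arrays[key], control))
    pairwise["effect_size"] = effects
    return ComparisonResult(kind="anova+tukey", statistic=res.statistic,
                            pvalue=res.pvalue, pairwise=pairwise)


def minmax_scale(values, scope: str = "global", groups=None) -> np.ndarray:
    """(v - min)/(max - min), globally or within groups."""
    values = np.asarray(values, dtype=float)
    if scope == "global":
        rng = values.max() - values.min()
        if rng <= 0:
            raise ValueError("zero range in scaling scope")
        return (values - values.min()) / rng
    if scope == "per-group":
        if groups is None:
            raise ValueError("per-group scaling needs group labels")
        groups = np.asarray(groups)
        out = np.empty_like(values)
        for g in np.unique(groups):
            m = groups == g
            rng = values[m].max() - values[m].min()
            if rng <= 0:
                raise ValueError(f"zero range in scaling scope (group {g!r})")
            out[m] = (values[m] - values[m].min()) / rng
        return out
    raise ValueError("scope must be 'global' or 'per-group'")
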