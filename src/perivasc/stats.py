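"""Statistical layer: repeated-measures ANOVA, gated two-group tests, and
lane-intensity comparisons.

The headline test asks whether the percent of NFT-bearing neurons near a
vessel segment varies with the segment's surface-tau decile, treating the
donor as the repeated factor. It is a one-way within-subject ANOVA:

    SS_total  = SS_subject + SS_effect + SS_error
    F = (SS_effect / df_effect) / (SS_error / df_error)

with df_effect = k - 1 and df_error = (n - 1)(k - 1) for n donors and k
decile levels. The reported R^2 is partial eta-squared,
SS_effect / (SS_effect + SS_error) — the subject variance is absorbed, not
counted against the effect. Donor x decile cells missing in any donor drop
that decile level (complete-case on levels); dropped levels are recorded.

Two-group comparisons are gated by Shapiro-Wilk normality: both groups
normal at alpha -> equal-variance two-tailed t test, otherwise two-sided
Mann-Whitney U. Lane-intensity (capillary Western) tables are normalized to
the mean of the control lanes and compared with a one-tailed t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RMAnovaResult:
    """Result of the one-way within-subject (repeated-measures) ANOVA."""

    F: float
    df_effect: int
    df_error: int
    p: float
    R2: float  # partial eta-squared
    cell_means: pd.Series
    ss_subject: float
    ss_effect: float
    ss_error: float
    n_subjects: int
    dropped_levels: list = field(default_factory=list)
    gg_epsilon: float | None = None
    p_gg: float | None = None

    def summary(self) -> str:
        lines = [
            "Repeated-measures ANOVA (within-subject factor: level)",
            f"  subjects: {self.n_subjects}   levels: {len(self.cell_means)}",
            f"  F({self.df_effect}, {self.df_error}) = {self.F:.4f}   "
            f"p = {self.p:.4g}   R2 (partial eta^2) = {self.R2:.3f}",
        ]
        if self.p_gg is not None:
            lines.append(
                f"  Greenhouse-Geisser: epsilon = {self.gg_epsilon:.3f}, "
                f"p = {self.p_gg:.4g}"
            )
        if self.dropped_levels:
            lines.append(f"  dropped incomplete levels: {self.dropped_levels}")
        lines.append("  cell means:")
        for lvl, m in self.cell_means.items():
            lines.append(f"    {lvl}: {m:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "F": self.F, "df_effect": self.df_effect, "df_error": self.df_error,
            "p": self.p, "R2": self.R2,
            "cell_means": {str(k): float(v) for k, v in self.cell_means.items()},
            "ss_subject": self.ss_subject, "ss_effect": self.ss_effect,
            "ss_error": self.ss_error, "n_subjects": self.n_subjects,
            "dropped_levels": [str(x) for x in self.dropped_levels],
            "gg_epsilon": self.gg_epsilon, "p_gg": self.p_gg,
        }


def rm_anova(table: pd.DataFrame, gg_correction: bool = False) -> RMAnovaResult:
    """One-way within-subject ANOVA on a subjects x levels table.

    ``table`` is wide: one row per subject (donor), one column per level
    (decile), values e.g. percent of NFT-bearing neurons. Columns containing
    any NaN are dropped (complete-case on levels).
    """
    table = pd.DataFrame(table).astype(float)
    complete = table.columns[table.notna().all(axis=0)]
    dropped = [c for c in table.columns if c not in set(complete)]
    x = table[complete]
    n, k = x.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")
    if k < 2:
        raise ValueError(f"need >= 2 complete levels, have {k} (dropped {dropped})")
    values = x.to_numpy()
    grand = values.mean()
    subj_means = values.mean(axis=1)
    level_means = values.mean(axis=0)
    ss_subject = k * float(np.sum((subj_means - grand) ** 2))
    ss_effect = n * float(np.sum((level_means - grand) ** 2))
    resid = values - subj_means[:, None] - level_means[None, :] + grand
    ss_error = float(np.sum(resid**2))
    df_effect = k - 1
    df_error = (n - 1) * (k - 1)
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    if ms_error == 0:
        f_stat = 0.0 if ss_effect == 0 else np.inf
        p = 1.0 if ss_effect == 0 else 0.0
    else:
        f_stat = ms_effect / ms_error
        p = float(sps.f.sf(f_stat, df_effect, df_error))
    denom = ss_effect + ss_error
    r2 = ss_effect / denom if denom > 0 else 0.0
    gg_epsilon = p_gg = None
    if gg_correction:
        # Greenhouse-Geisser epsilon from the level covariance matrix
        cov = np.cov(values, rowvar=False)
        mean_diag = np.trace(cov) / k
        mean_all = cov.mean()
        row_means = cov.mean(axis=1)
        num = (k * (mean_diag - mean_all)) ** 2
        den = (k - 1) * (
            np.sum(cov**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2
        )
        gg_epsilon = float(num / den) if den > 0 else 1.0
        gg_epsilon = min(max(gg_epsilon, 1.0 / (k - 1)), 1.0)
        if np.isfinite(f_stat):
            p_gg = float(
                sps.f.sf(f_stat, gg_epsilon * df_effect, gg_epsilon * df_error)
            )
    return RMAnovaResult(
        F=float(f_stat), df_effect=df_effect, df_error=df_error, p=p, R2=float(r2),
        cell_means=pd.Series(level_means, index=complete),
        ss_subject=ss_subject, ss_effect=ss_effect, ss_error=ss_error,
        n_subjects=n, dropped_levels=dropped,
        gg_epsilon=gg_epsilon, p_gg=p_gg,
    )


@dataclass
class TwoGroupResult:
    branch: str  # "t-test" | "mann-whitney" | "degenerate"
    statistic: float
    p: float
    shapiro_p: tuple[float, float] | None = None

    def summary(self) -> str:
        return (
            f"two-group comparison via {self.branch}: statistic = "
            f"{self.statistic:.4f}, p = {self.p:.4g}"
        )


def _is_normal(x: np.ndarray, alpha: float) -> tuple[bool, float]:
    if np.ptp(x) == 0:
        return False, 0.0  # constant sample: treat as non-normal
    w, p = sps.shapiro(x)
    return p > alpha, float(p)


def two_group_test(
    a: Sequence[float], b: Sequence[float], alpha_normality: float = 0.05
) -> TwoGroupResult:
    """Normality-gated two-group comparison.

    Shapiro-Wilk on each group; both pass -> equal-variance two-tailed t
    test; otherwise two-sided Mann-Whitney U. Two constant groups with equal
    means are degenerate (no evidence of difference, p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return TwoGroupResult("degenerate", 0.0, 1.0, None)
    ok_a, p_a = _is_normal(a, alpha_normality)
    ok_b, p_b = _is_normal(b, alpha_normality)
    if ok_a and ok_b:
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return TwoGroupResult("t-test", float(t), float(p), (p_a, p_b))
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TwoGroupResult("mann-whitney", float(u), float(p), (p_a, p_b))


def lane_normalize_and_test(
    lanes: pd.DataFrame,
    direction: str = "greater",
    control_label: str = "control",
) -> pd.DataFrame:
    """Normalize capillary-Western lane intensities to controls and test.

    ``lanes`` has columns ``sample, group, antibody, intensity``. Per
    antibody, every lane is divided by the mean of the control lanes (so the
    normalized control mean is 1 by construction), then a one-tailed
    equal-variance t test compares case vs control in the stated direction
    ("greater": cases higher). Returns one row per antibody with the
    normalized group means, t, p, and significance flags at 0.05 / 0.01.
    """
    required = {"sample", "group", "antibody", "intensity"}
    if not required <= set(lanes.columns):
        raise ValueError(f"lane table needs columns {sorted(required)}")
    rows = []
    for antibody, grp in lanes.groupby("antibody"):
        ctrl = grp.loc[grp["group"] == control_label, "intensity"].to_numpy(float)
        case = grp.loc[grp["group"] != control_label, "intensity"].to_numpy(float)
        if len(ctrl) == 0:
            raise ValueError(f"{antibody}: no control lanes")
        if len(case) == 0:
            raise ValueError(f"{antibody}: no case lanes")
        ref = ctrl.mean()
        if ref <= 0:
            raise ValueError(f"{antibody}: control mean must be > 0")
        ctrl_n, case_n = ctrl / ref, case / ref
        t, p = sps.ttest_ind(case_n, ctrl_n, equal_var=True, alternative=direction)
        rows.append(
            {
                "antibody": antibody,
                "control_mean_norm": float(ctrl_n.mean()),
                "case_mean_norm": float(case_n.mean()),
                "n_control": len(ctrl),
                "n_case": len(case),
                "t": float(t),
                "p_one_tailed": float(p),
                "sig_05": bool(p < 0.05),
                "sig_01": bool(p < 0.01),
            }
        )
    return pd.DataFrame(rows)


def simulate_nft_decile_table(
    rng: np.random.Generator,
    n_donors: int = 6,
    n_deciles: int = 10,
    neurons_per_cell: int = 40,
    base_prob: float = 0.05,
    slope: float = 0.0,
    donor_sd: float = 0.03,
) -> pd.DataFrame:
    """Simulate a donor x decile table of NFT-bearing neuron percentages.

    Uses the generator's clamped linear probability link: in decile j
    (1-based), p_j = clip(base + slope * (j-1)/(n_deciles-1) + donor shift,
    0, 1); each cell is a binomial fraction over ``neurons_per_cell``
    neurons. slope = 0 gives an exchangeable null across deciles.
    """
    shifts = rng.normal(0.0, donor_sd, size=n_donors)
    j = np.arange(n_deciles)
    p = base_prob + slope * j / max(n_deciles - 1, 1)
    p_cells = np.clip(p[None, :] + shifts[:, None], 0.0, 1.0)
    counts = rng.binomial(neurons_per_cell, p_cells)
    frac = 100.0 * counts / neurons_per_cell
    return pd.DataFrame(
        frac,
        index=[f"donor_{i:02d}" for i in range(n_donors)],
        columns=np.arange(1, n_deciles + 1),
    )


def decile_association_rejection_rate(
    n_sims: int,
    seed: int,
    alpha: float = 0.05,
    **table_kwargs,
) -> float:
    """Fraction of simulated cohorts where rm_anova rejects at ``alpha``."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        table = simulate_nft_decile_table(rng, **table_kwargs)
        if rm_anova(table).p < alpha:
            hits += 1
    return hits / n_sims
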