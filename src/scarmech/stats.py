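"""Group-comparison statistics with effect sizes and a boundary decision rule.

The decision layer used throughout the study-style analyses:

1. every group is gated through a Shapiro-Wilk normality test (alpha = 0.05);
2. two groups: Student's t-test if all groups look normal, otherwise
   Mann-Whitney; a paired variant when pairing ids are present;
3. more than two groups: Kruskal-Wallis followed by Dunn's multiple
   comparisons;
4. alongside the p-value an effect size is reported — Cohen's d for t-tests,
   the common-language effect size theta (probability that a random
   observation from one group exceeds one from the other) for rank tests —
   each with an asymptotic standard error;
5. a difference counts as significant only when p < 0.05 AND the effect-size
   interval (estimate +/- uncertainty) excludes the no/trivial-effect
   boundary (d_c = 1 for d, theta_c = 0.5 for theta).  The alternative
   reading, requiring only the point estimate to lie beyond the boundary, is
   available via ``rule="beyond"``.

Also houses the percent-change summary convention and the delta-delta-Ct
fold-change calculation for qRT-PCR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestPlan",
    "EffectSizeResult",
    "choose_test",
    "run_tests",
    "cohens_d",
    "cles_theta",
    "dunn_test",
    "significance_decision",
    "percent_change",
    "ddct_fold_change",
    "compare_groups",
]

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class TestPlan:
    test: str                      # "t" | "paired_t" | "mannwhitney" | "wilcoxon" | "kruskal_dunn"
    normal: bool
    shapiro_p: tuple[float, ...]


@dataclass
class EffectSizeResult:
    kind: str                      # "cohen_d" | "cles_theta"
    estimate: float
    uncertainty: float
    boundary: float                # d_c = 1 or theta_c = 0.5
    boundary_excluded: bool

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


def _as_groups(groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float) for g in groups]


def choose_test(groups, paired: bool = False) -> TestPlan:
    """Pick the test the normality gate prescribes for these groups.

    Each group needs n >= 3 for Shapiro-Wilk.  All groups must pass at
    alpha = 0.05 for a parametric choice.  More than two groups always route
    to Kruskal-Wallis + Dunn.
    """
    gs = _as_groups(groups)
    if any(len(g) < 3 for g in gs):
        raise ValueError("each group needs n >= 3 for the Shapiro-Wilk gate")
    pvals = tuple(float(sps.shapiro(g).pvalue) for g in gs)
    normal = all(p > SHAPIRO_ALPHA for p in pvals)
    if len(gs) > 2:
        return TestPlan("kruskal_dunn", normal, pvals)
    if normal:
        return TestPlan("paired_t" if paired else "t", normal, pvals)
    return TestPlan("wilcoxon" if paired else "mannwhitney", normal, pvals)


def run_tests(plan: TestPlan, groups):
    """Two-tailed p-value(s) for the planned test.

    Returns a float for two-group designs, or a DataFrame of Dunn pairwise
    comparisons (columns group_a, group_b, z, p, p_adjusted) after a global
    Kruskal-Wallis whose p-value is attached as ``df.attrs["kruskal_p"]``.
    """
    gs = _as_groups(groups)
    if plan.test == "t":
        return float(sps.ttest_ind(gs[0], gs[1]).pvalue)
    if plan.test == "paired_t":
        return float(sps.ttest_rel(gs[0], gs[1]).pvalue)
    if plan.test == "mannwhitney":
        if len(np.unique(np.concatenate(gs))) == 1:
            raise ValueError("all observations tied: rank test degenerate")
        method = "exact" if max(len(g) for g in gs) <= 8 else "auto"
        return float(sps.mannwhitneyu(gs[0], gs[1], alternative="two-sided",
                                      method=method).pvalue)
    if plan.test == "wilcoxon":
        return float(sps.wilcoxon(gs[0], gs[1]).pvalue)
    if plan.test == "kruskal_dunn":
        kw = float(sps.kruskal(*gs).pvalue)
        df = dunn_test(gs)
        df.attrs["kruskal_p"] = kw
        return df
    raise ValueError(f"unknown test {plan.test!r}")


def cohens_d(a, b):
    """Cohen's d (pooled SD, no small-sample correction) with asymptotic SE.

    d = (mean(b) - mean(a)) / s_pooled;
    SE = sqrt((na+nb)/(na*nb) + d**2 / (2*(na+nb))).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = (b.mean() - a.mean()) / pooled
    se = np.sqrt((na + nb) / (na * nb) + d ** 2 / (2 * (na + nb)))
    return float(d), float(se)


def cles_theta(a, b):
    """Common-language effect size theta with U-statistic asymptotic SE.

    theta = P(a > b) + P(a = b)/2, estimated over all n_a * n_b pairs.  The
    standard error uses the two-sample placement (DeLong-style) variance
    estimate; it is 0 for fully separated or fully tied samples.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("groups must be non-empty")
    gt = (a[:, None] > b[None, :]).astype(float)
    eq = (a[:, None] == b[None, :]).astype(float)
    h = gt + 0.5 * eq
    theta = float(h.mean())
    # placement values: per-a and per-b means of the pairwise kernel
    v_a = h.mean(axis=1)
    v_b = h.mean(axis=0)
    var = (v_a.var(ddof=1) / na if na > 1 else 0.0) \
        + (v_b.var(ddof=1) / nb if nb > 1 else 0.0)
    return theta, float(np.sqrt(var))


def dunn_test(groups, labels=None, comparisons: str = "all"):
    """Dunn's post-hoc rank comparisons with Bonferroni adjustment.

    Standard z-statistics on mean ranks of the pooled sample with tie
    correction.  ``comparisons="all"`` tests every pair; ``"control"`` tests
    each group against the first.  Adjusted p-values are Bonferroni over the
    performed comparisons, capped at 1.
    """
    gs = _as_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    n = np.array([len(g) for g in gs])
    pooled = np.concatenate(gs)
    big_n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for ni in n:
        mean_ranks.append(ranks[start:start + ni].mean())
        start += ni
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (big_n - 1))
    pairs = ([(0, j) for j in range(1, k)] if comparisons == "control"
             else [(i, j) for i in range(k) for j in range(i + 1, k)])
    rows = []
    m = len(pairs)
    for i, j in pairs:
        se = np.sqrt((big_n * (big_n + 1) / 12.0 - tie_term)
                     * (1.0 / n[i] + 1.0 / n[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z,
                     "p": p, "p_adjusted": min(1.0, m * p)})
    return pd.DataFrame(rows)


def significance_decision(p: float, effect: EffectSizeResult, *,
                          alpha: float = 0.05, rule: str = "exclude") -> bool:
    """Combined significance call from p-value and effect-size boundary.

    ``rule="exclude"`` (default): significant iff p < alpha and the interval
    estimate +/- uncertainty does not contain the boundary.
    ``rule="beyond"``: significant iff p < alpha and |estimate - neutral| is
    beyond the boundary distance, ignoring the uncertainty, where neutral is
    0 for Cohen's d and 0.5 for theta.
    """
    if p >= alpha:
        return False
    if rule == "exclude":
        lo = effect.estimate - effect.uncertainty
        hi = effect.estimate + effect.uncertainty
        return not (lo <= effect.boundary <= hi)
    if rule == "beyond":
        neutral = 0.5 if effect.kind == "cles_theta" else 0.0
        return abs(effect.estimate - neutral) >= abs(effect.boundary - neutral)
    raise ValueError(f"unknown rule {rule!r}")


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Percent reduction of the treated mean relative to control.

    100 * (control - treated) / control; positive for reductions.
    """
    if control_mean == 0:
        raise ValueError("control mean must be non-zero")
    return 100.0 * (control_mean - treated_mean) / control_mean


def ddct_fold_change(ct_target_ctrl, ct_target_cond, ct_ref_ctrl, ct_ref_cond) -> float:
    """Fold change by the delta-delta-Ct method: FC = 2**(-ddCt).

    ddCt = (Ct_target - Ct_ref)_condition - (Ct_target - Ct_ref)_control.
    Inputs may be scalars or replicate arrays (averaged first).
    """
    vals = [float(np.mean(v)) for v in
            (ct_target_ctrl, ct_target_cond, ct_ref_ctrl, ct_ref_cond)]
    if not all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    ddct = (vals[1] - vals[3]) - (vals[0] - vals[2])
    return float(2.0 ** (-ddct))


def compare_groups(a, b, *, paired: bool = False, rule: str = "exclude"):
    """Full two-group pipeline: normality gate, test, effect size, decision.

    Returns ``(plan, p, EffectSizeResult, significant)``.
    """
    plan = choose_test([a, b], paired=paired)
    p = run_tests(plan, [a, b])
    if plan.normal:
        d, se = cohens_d(a, b)
        bound = 1.0 if d >= 0 else -1.0   # d_c applies to the magnitude
        effect = EffectSizeResult("cohen_d", d, se, boundary=bound,
                                  boundary_excluded=not (d - se <= bound <= d + se))
    else:
        theta, se = cles_theta(a, b)
        effect = EffectSizeResult("cles_theta", theta, se, boundary=0.5,
                                  boundary_excluded=not (theta - se <= 0.5 <= theta + se))
    return plan, p, effect, significance_decision(p, effect, rule=rule)
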