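"""Intention-to-treat statistics for a two-arm repeated-measures trial.

The pipeline a blinded-assessor RCT of this design needs: MCAR "mean of
series" imputation (groupwise mean for parametric variables, median for
non-parametric), normality and homoscedasticity checks, a mixed two-way
repeated-measures ANOVA (between: group; within: time) for the group×time
interaction, Newman–Keuls stepdown post hoc on ordered means, one-way
repeated-measures ANOVA or Friedman's test for the three-timepoint
follow-up within the intervention arm, Mann–Whitney / Wilcoxon rank tests
with exact small-sample p-values, Cohen's d with the trial's effect-size
labels, Hodges–Lehmann median differences with distribution-free 95 %
CIs, balanced block randomization, and the noncentral-F power/sample-size
computation for a repeated-measures design.

The mixed ANOVA is exposed both as the statsmodels-style pair
:class:`MixedRmAnova` / :class:`MixedRmAnovaResults` and through the
functional :func:`rm_anova_interaction` wrapper.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "TIMEPOINTS",
    "TrialTable",
    "EffectSize",
    "AnovaResult",
    "DegenerateTestError",
    "UnimputableCellError",
    "MixedRmAnova",
    "MixedRmAnovaResults",
    "impute_missing",
    "check_assumptions",
    "rm_anova_interaction",
    "newman_keuls",
    "followup_tests",
    "rank_tests",
    "cohens_d",
    "median_difference_ci",
    "block_randomization",
    "sample_size_rm_f",
]

TIMEPOINTS = ("baseline", "week12", "week24")
GROUPS = ("control", "intervention")

#: Effect-size label boundaries calibrated to this trial's usage
#: (0.3 labelled small, 0.4-0.6 medium, >=0.7 large), tighter than
#: Cohen's textbook 0.2/0.5/0.8.
EFFECT_SIZE_BOUNDS = (0.4, 0.7)


class DegenerateTestError(ValueError):
    """The requested test is undefined on this input (e.g. all-zero diffs)."""


class UnimputableCellError(ValueError):
    """A group × timepoint cell has no observed values to impute from."""


# ---------------------------------------------------------------------------
# trial table

@dataclass
class TrialTable:
    """Subject × timepoint outcome matrix with variable-type tags.

    ``data`` is a wide DataFrame with columns ``subject``, ``group``
    (control/intervention), ``timepoint`` (baseline/week12/week24) and one
    numeric column per outcome variable; missing outcomes are NaN.
    ``var_types`` maps each variable to ``"parametric"`` or
    ``"nonparametric"`` and decides both the imputation statistic and the
    follow-up test family.  Week-24 rows exist only for the intervention
    arm (the control arm has no follow-up assessment).
    """

    data: pd.DataFrame
    var_types: dict[str, str]

    def __post_init__(self):
        required = {"subject", "group", "timepoint"}
        if not required <= set(self.data.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        bad = set(self.data["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {bad}")
        bad = set(self.data["timepoint"]) - set(TIMEPOINTS)
        if bad:
            raise ValueError(f"unknown timepoints {bad}")
        dup = self.data.duplicated(["subject", "timepoint"])
        if dup.any():
            raise ValueError("duplicate subject × timepoint rows")
        w24 = self.data[self.data["timepoint"] == "week24"]
        if (w24["group"] == "control").any():
            raise ValueError("week24 rows are only defined for the "
                             "intervention group")
        unknown = set(self.var_types) - set(self.variables)
        if unknown:
            raise ValueError(f"var_types for unknown variables {unknown}")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns
                if c not in ("subject", "group", "timepoint")]

    def group_sizes(self) -> dict[str, int]:
        base = self.data[self.data["timepoint"] == "baseline"]
        return base.groupby("group")["subject"].nunique().to_dict()

    def values(self, group: str, timepoint: str, variable: str,
               dropna: bool = True) -> np.ndarray:
        sel = self.data[(self.data["group"] == group)
                        & (self.data["timepoint"] == timepoint)]
        v = sel[variable].to_numpy(float)
        return v[~np.isnan(v)] if dropna else v

    def copy(self) -> "TrialTable":
        return TrialTable(self.data.copy(), dict(self.var_types))


def impute_missing(table: TrialTable) -> TrialTable:
    """'Mean of series' MCAR imputation, groupwise per timepoint.

    A missing parametric value is replaced by the mean of the observed
    values of that variable within the same group and timepoint; a
    non-parametric one by the median.  Observed values are never altered.
    Raises :class:`UnimputableCellError` when a needed cell has no
    observed value at all.
    """
    out = table.copy()
    df = out.data
    for var in out.variables:
        kind = out.var_types.get(var, "parametric")
        stat = "mean" if kind == "parametric" else "median"
        grp = df.groupby(["group", "timepoint"], observed=True)[var]
        fill = grp.transform(stat)
        missing = df[var].isna()
        if (missing & fill.isna()).any():
            bad = df.loc[missing & fill.isna(), ["group", "timepoint"]]
            cell = bad.iloc[0].tolist()
            raise UnimputableCellError(
                f"{var}: no observed values in cell {cell}")
        df[var] = df[var].where(~missing, fill)
    return out


# ---------------------------------------------------------------------------
# assumption checks

@dataclass(frozen=True)
class AssumptionReport:
    """Normality per cell plus homoscedasticity across cells."""

    normality: dict[str, tuple[float, float]]   # cell -> (KS stat, p)
    levene: tuple[float, float]                 # (stat, p)

    def all_parametric(self, alpha: float = 0.05) -> bool:
        return (all(p > alpha for _, p in self.normality.values())
                and self.levene[1] > alpha)


def check_assumptions(cells: dict[str, np.ndarray]) -> AssumptionReport:
    """KS normality per cell and Levene homoscedasticity across cells.

    Normality uses the Lilliefors variant of the Kolmogorov–Smirnov test
    (mean and SD estimated from the sample — the case that actually
    arises in a trial).  Each cell needs at least 3 observations.
    """
    if len(cells) < 2:
        raise ValueError("need at least two cells")
    normality = {}
    for name, values in cells.items():
        v = np.asarray(values, float)
        if v.size < 3:
            raise ValueError(f"cell {name!r} has fewer than 3 observations")
        if np.ptp(v) == 0:
            normality[name] = (0.0, 1.0)  # constant sample: KS degenerate
        else:
            stat, p = lilliefors(v, dist="norm")
            normality[name] = (float(stat), float(p))
    stat, p = sps.levene(*cells.values())
    return AssumptionReport(normality=normality, levene=(float(stat), float(p)))


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA (Model / Results pair)

@dataclass(frozen=True)
class AnovaResult:
    """Effect terms of a (mixed) ANOVA with optional post-hoc decisions."""

    terms: dict[str, tuple[float, int, int, float]]  # name -> (F, df1, df2, p)
    cell_means: dict[tuple[str, str], float]
    mse_within: float
    n_per_group: dict[str, int]
    posthoc: pd.DataFrame | None = None

    def p(self, term: str) -> float:
        return self.terms[term][3]


class MixedRmAnova:
    """Mixed-design ANOVA: one between factor (group), one within (time).

    Restricted to two groups × two timepoints — exactly the
    baseline-vs-12-weeks interaction contrast a two-arm trial tests.  With
    a two-level within factor, sphericity holds trivially and the
    univariate and multivariate approaches coincide; the model reduces to
    exact F tests on subject difference and mean scores:

    * interaction — one-way ANOVA on the within-subject difference scores
      across groups,
    * time — test that the unweighted mean of the groups' difference-score
      means is zero (type-III convention for unbalanced groups),
    * group — one-way ANOVA on subject means.

    ``fit()`` returns a :class:`MixedRmAnovaResults`.
    """

    def __init__(self, table: TrialTable, variable: str,
                 timepoints: tuple[str, str] = ("baseline", "week12")):
        if len(timepoints) != 2:
            raise ValueError("the mixed design supports exactly two timepoints")
        df = table.data[table.data["timepoint"].isin(timepoints)]
        wide = df.pivot_table(index=["subject", "group"], columns="timepoint",
                              values=variable, observed=True)
        if wide.isna().any().any() or set(wide.columns) != set(timepoints):
            raise ValueError(
                "design incomplete: every subject needs both timepoints "
                "(impute first)")
        wide = wide.reset_index()
        groups = [g for g in GROUPS if (wide["group"] == g).any()]
        if len(groups) != 2:
            raise ValueError("the mixed design needs both groups")
        self.variable = variable
        self.timepoints = tuple(timepoints)
        self.groups = tuple(groups)
        self._wide = wide

    def fit(self) -> "MixedRmAnovaResults":
        t0, t1 = self.timepoints
        d, s, ns, cell_means = [], [], {}, {}
        for g in self.groups:
            sub = self._wide[self._wide["group"] == g]
            y0 = sub[t0].to_numpy(float)
            y1 = sub[t1].to_numpy(float)
            d.append(y1 - y0)
            s.append((y0 + y1) / 2)
            ns[g] = len(sub)
            cell_means[(g, t0)] = float(y0.mean())
            cell_means[(g, t1)] = float(y1.mean())
        n1, n2 = (ns[g] for g in self.groups)
        n_tot = n1 + n2
        if min(n1, n2) < 2 or n_tot < 4:
            raise ValueError("need at least 2 subjects per group")
        df2 = n_tot - 2

        def oneway_f(a, b):
            gm = (a.sum() + b.sum()) / n_tot
            ssb = len(a) * (a.mean() - gm) ** 2 + len(b) * (b.mean() - gm) ** 2
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            msw = ssw / df2
            f = ssb / msw if msw > 0 else (0.0 if ssb == 0 else np.inf)
            return f, msw

        f_int, ms_d = oneway_f(d[0], d[1])
        f_grp, _ = oneway_f(s[0], s[1])
        # type-III time effect: unweighted mean of group difference means
        est = (d[0].mean() + d[1].mean()) / 2
        var_est = ms_d / 4 * (1 / n1 + 1 / n2)
        f_time = est ** 2 / var_est if var_est > 0 else (0.0 if est == 0 else np.inf)

        def pval(f):
            return float(sps.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0

        terms = {
            "group": (float(f_grp), 1, df2, pval(f_grp)),
            "time": (float(f_time), 1, df2, pval(f_time)),
            "interaction": (float(f_int), 1, df2, pval(f_int)),
        }
        # within-cell error variance on the original scale, for post hocs:
        # Var(y) within cells, pooled over the four cells
        ss = 0.0
        dfe = 0
        for g in self.groups:
            sub = self._wide[self._wide["group"] == g]
            for t in self.timepoints:
                y = sub[t].to_numpy(float)
                ss += ((y - y.mean()) ** 2).sum()
                dfe += len(y) - 1
        mse = ss / dfe if dfe else np.nan
        return MixedRmAnovaResults(
            model=self,
            result=AnovaResult(terms=terms, cell_means=cell_means,
                               mse_within=float(mse),
                               n_per_group=dict(ns)),
        )


@dataclass(frozen=True)
class MixedRmAnovaResults:
    """Fitted mixed rm-ANOVA: term table, cell means, post-hoc access."""

    model: MixedRmAnova
    result: AnovaResult

    def summary(self) -> pd.DataFrame:
        rows = [(name, f, d1, d2, p)
                for name, (f, d1, d2, p) in self.result.terms.items()]
        return pd.DataFrame(rows, columns=["source", "F", "df1", "df2", "p"])

    def newman_keuls(self, alpha: float = 0.05) -> pd.DataFrame:
        means = np.array(list(self.result.cell_means.values()))
        labels = [f"{g}:{t}" for g, t in self.result.cell_means]
        n_cells = np.array([self.result.n_per_group[g]
                            for g, _ in self.result.cell_means])
        dfe = sum(self.result.n_per_group.values()) * 2 - 4
        return newman_keuls(means, self.result.mse_within, n_cells, dfe,
                            alpha=alpha, labels=labels)


def rm_anova_interaction(table: TrialTable, variable: str,
                         timepoints: tuple[str, str] = ("baseline", "week12"),
                         alpha: float = 0.05,
                         posthoc: bool = False) -> AnovaResult:
    """Group × time interaction via the mixed rm-ANOVA (α = 0.05).

    Expects an imputed table (every subject present at both timepoints).
    With ``posthoc=True`` the Newman–Keuls decisions over the four cell
    means are attached.
    """
    res = MixedRmAnova(table, variable, timepoints).fit()
    out = res.result
    if posthoc:
        out = AnovaResult(terms=out.terms, cell_means=out.cell_means,
                          mse_within=out.mse_within,
                          n_per_group=out.n_per_group,
                          posthoc=res.newman_keuls(alpha=alpha))
    return out


# ---------------------------------------------------------------------------
# Newman–Keuls stepdown

def newman_keuls(means: np.ndarray, mse: float, n, df: int,
                 alpha: float = 0.05, labels: list[str] | None = None
                 ) -> pd.DataFrame:
    """Newman–Keuls stepwise studentized-range procedure on ordered means.

    Means are sorted; each pair is tested with the studentized-range
    statistic at the span (number of means enclosed) of its range, and a
    range is declared significant only if every range containing it is —
    so a non-significant range silently protects all of its sub-ranges
    (the procedure's coherence property).  Unequal cell sizes use the
    harmonic mean of the pair's sizes.

    Returns one row per pair: labels, mean difference, q, span, p, and the
    significance decision.
    """
    means = np.asarray(means, float)
    k = means.size
    if k < 2:
        raise ValueError("need at least 2 cell means")
    if not mse > 0:
        raise ValueError("mse must be > 0")
    n = np.broadcast_to(np.asarray(n, float), (k,))
    if labels is None:
        labels = [f"cell{i}" for i in range(k)]
    order = np.argsort(means, kind="stable")
    sm = means[order]
    sn = n[order]
    slab = [labels[i] for i in order]

    # process spans top-down: a range may only be declared significant if
    # every range containing it is, which reduces to its (at most two)
    # immediate parents one span up
    sig: dict[tuple[int, int], tuple[float, int, float, bool]] = {}
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            nh = 2.0 / (1.0 / sn[i] + 1.0 / sn[j])
            q = (sm[j] - sm[i]) / math.sqrt(mse / nh)
            p = float(sps.studentized_range.sf(q, span, df)) if q > 0 else 1.0
            parents_ok = all(sig[par][3]
                             for par in ((i - 1, j), (i, j + 1)) if par in sig)
            sig[(i, j)] = (q, span, p, parents_ok and p < alpha)

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            q, span, p, s = sig[(i, j)]
            rows.append((slab[i], slab[j], sm[j] - sm[i], q, span, p, s))
    return pd.DataFrame(rows, columns=["level_low", "level_high", "diff",
                                       "q", "span", "p", "significant"])


# ---------------------------------------------------------------------------
# follow-up (three timepoints, intervention arm)

@dataclass(frozen=True)
class FollowupResult:
    test: str        # "rm_anova" or "friedman"
    statistic: float
    df: tuple[int, int] | int | None
    p: float


def followup_tests(table: TrialTable, variable: str,
                   group: str = "intervention") -> FollowupResult:
    """Within-group comparison over baseline / week 12 / week 24.

    Parametric variables use a one-way repeated-measures ANOVA (subjects
    as blocks), non-parametric ones Friedman's rank test — answering
    whether treated subjects drifted back to baseline at follow-up.
    """
    wide = table.data[table.data["group"] == group].pivot_table(
        index="subject", columns="timepoint", values=variable, observed=True)
    missing_tp = set(TIMEPOINTS) - set(wide.columns)
    if missing_tp:
        raise ValueError(f"group {group!r} lacks timepoints {sorted(missing_tp)}")
    y = wide[list(TIMEPOINTS)].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("incomplete cases: impute first")
    n, t = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if table.var_types.get(variable, "parametric") == "nonparametric":
        with np.errstate(invalid="ignore"):
            stat, p = sps.friedmanchisquare(*(y[:, j] for j in range(t)))
        if np.isnan(stat):  # scipy yields nan on all-constant input
            stat, p = 0.0, 1.0
        return FollowupResult("friedman", float(stat), t - 1, float(p))
    grand = y.mean()
    ss_time = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = t * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_time - ss_subj
    df1, df2 = t - 1, (n - 1) * (t - 1)
    ms_err = ss_err / df2
    f = (ss_time / df1) / ms_err if ms_err > 0 else (0.0 if ss_time == 0 else np.inf)
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return FollowupResult("rm_anova", float(f), (df1, df2), p)


# ---------------------------------------------------------------------------
# rank tests

EXACT_N_MAX = 12


def rank_tests(a, b, paired: bool = False) -> tuple[float, float]:
    """Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    Small tie-free samples (each n ≤ 12) get exact p-values; larger or
    tied samples use the tie-corrected normal approximation.  Fully
    degenerate inputs (identical samples / all-zero paired differences)
    raise :class:`DegenerateTestError` for the paired test and return
    p = 1 for the unpaired one.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        diffs = b - a
        if np.all(diffs == 0):
            raise DegenerateTestError("all paired differences are zero")
        nz = diffs[diffs != 0]
        exact = nz.size <= EXACT_N_MAX and np.unique(np.abs(nz)).size == nz.size
        res = sps.wilcoxon(a, b, zero_method="wilcox",
                           method="exact" if exact else "approx",
                           correction=not exact)
        return float(res.statistic), float(res.pvalue)
    if a.size < 1 or b.size < 1:
        raise ValueError("need at least one observation per sample")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all values identical: no evidence against the null at all
        return float(a.size * b.size / 2), 1.0
    exact = (not ties) and max(a.size, b.size) <= EXACT_N_MAX
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# effect sizes

@dataclass(frozen=True)
class EffectSize:
    """Cohen's d (absolute) with the trial's small/medium/large label."""

    d: float
    label: str
    comparison: str = ""


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float,
             comparison: str = "") -> EffectSize:
    """Cohen's d with the unweighted pooled SD ``sqrt((s1²+s2²)/2)``.

    Reported as an absolute value; labels follow the boundaries used for
    this cohort's tables: small below 0.4, medium 0.4–0.7, large from
    0.7.  Undefined when both SDs are zero.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateTestError("Cohen's d undefined: both SDs are zero")
    d = abs(mean1 - mean2) / math.sqrt((sd1 ** 2 + sd2 ** 2) / 2)
    lo, hi = EFFECT_SIZE_BOUNDS
    label = "small" if d < lo else ("medium" if d < hi else "large")
    return EffectSize(d=d, label=label, comparison=comparison)


# ---------------------------------------------------------------------------
# Hodges–Lehmann median difference

def median_difference_ci(a, b, confidence: float = 0.95
                         ) -> tuple[float, tuple[float, float]]:
    """Hodges–Lehmann estimate of the b−a shift with a distribution-free CI.

    The estimate is the median of all pairwise differences ``b_j − a_i``;
    the CI takes order statistics of those differences at ranks from the
    normal approximation to the Mann–Whitney null distribution.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    diffs = np.sort((b[:, None] - a[None, :]).ravel())
    est = float(np.median(diffs))
    n1, n2 = a.size, b.size
    m = n1 * n2
    z = sps.norm.ppf(0.5 + confidence / 2)
    k = int(math.floor(m / 2 - z * math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)))
    k = max(k, 0)
    lower = float(diffs[k]) if k < m else float(diffs[0])
    upper = float(diffs[m - 1 - k])
    return est, (lower, upper)


# ---------------------------------------------------------------------------
# randomization & sample size

def block_randomization(n: int, seed: int,
                        groups: tuple[str, str] = GROUPS,
                        max_block: int = 8,
                        return_blocks: bool = False):
    """Blocked two-arm allocation with block sizes drawn randomly from 1..8.

    Each block is balanced up to rounding; an odd block's extra slot goes
    to whichever arm is currently under-represented (coin flip on ties),
    so the arm imbalance never exceeds one at any completed-block
    boundary.  Deterministic for a given seed.  With ``return_blocks``
    the drawn block sizes are returned alongside the sequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    sizes: list[int] = []
    counts = {g: 0 for g in groups}
    while len(out) < n:
        size = int(rng.integers(1, max_block + 1))
        half = size // 2
        block = [groups[0]] * half + [groups[1]] * half
        if size % 2:
            if counts[groups[0]] < counts[groups[1]]:
                extra = groups[0]
            elif counts[groups[1]] < counts[groups[0]]:
                extra = groups[1]
            else:
                extra = groups[int(rng.integers(2))]
            block.append(extra)
        rng.shuffle(block)
        for g in block:
            counts[g] += 1
        out.extend(block)
        sizes.append(size)
    seq = out[:n]
    return (seq, sizes) if return_blocks else seq


@dataclass(frozen=True)
class SampleSizeResult:
    """Required sample size for the repeated-measures F design."""

    n_total: int          # smallest N reaching the target power
    n_inflated: int       # after inflation for the anticipated loss
    achieved_power: float
    effect_f: float
    alpha: float
    n_groups: int
    n_measures: int
    correlation: float    # assumed within-subject correlation


def _rm_f_power(n_total, effect_f, alpha, n_groups, n_measures, correlation):
    df1 = (n_groups - 1) * (n_measures - 1)
    df2 = (n_total - n_groups) * (n_measures - 1)
    if df2 < 1:
        return 0.0
    lam = effect_f ** 2 * n_total * n_measures / (1 + (n_measures - 1) * correlation)
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def sample_size_rm_f(effect_f: float, alpha: float = 0.05, power: float = 0.81,
                     n_groups: int = 2, n_measures: int = 2,
                     correlation: float = 0.5, loss_fraction: float = 0.0,
                     n_max: int = 10_000) -> SampleSizeResult:
    """Smallest total N for the between×within repeated-measures F test.

    Noncentral-F formulation with noncentrality
    ``λ = f²·N·m / (1 + (m−1)ρ)``, numerator df ``(g−1)(m−1)`` and
    denominator df ``(N−g)(m−1)`` — the conventional power formulation
    for the group×time interaction, under an assumed (and explicitly
    reported) uniform within-subject correlation ρ.  The returned
    ``n_inflated`` applies the anticipated loss-to-follow-up fraction.
    """
    if effect_f <= 0:
        raise ValueError("effect_f must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if not 0 <= loss_fraction < 1:
        raise ValueError("loss_fraction must lie in [0, 1)")
    for n in range(n_groups + 1, n_max + 1):
        pw = _rm_f_power(n, effect_f, alpha, n_groups, n_measures, correlation)
        if pw >= power:
            return SampleSizeResult(
                n_total=n,
                n_inflated=math.ceil(n / (1 - loss_fraction)),
                achieved_power=pw,
                effect_f=effect_f, alpha=alpha, n_groups=n_groups,
                n_measures=n_measures, correlation=correlation,
            )
    raise ValueError(f"target power not reachable with N <= {n_max}")
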