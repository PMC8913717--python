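"""Cohort-level inference: t-tests and mixed (split-plot) factorial ANOVA.

The mixed ANOVA has one between-subject factor (treatment group) and one
within-subject factor (timepoint) on a complete balanced table.  Sums of
squares follow the classical split-plot partition: the group effect is
tested against between-subject error and the time and group×time effects
against the subject×time error.  Mauchly's test probes sphericity of the
within-subject covariance; when it rejects (p < 0.05, or always by
configuration) the Greenhouse–Geisser epsilon multiplies the within-effect
degrees of freedom.  Tests are two-sided at alpha = 0.05 and p-values are
deliberately not adjusted for multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigError, ContractError

ALPHA = 0.05


# ----------------------------------------------------------------------
# t-tests
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    mean_difference: float
    kind: str  # "paired" | "unpaired"
    degenerate: bool = False  # zero-variance input handled by convention

    def format(self) -> str:
        return f"t({self.df:g}) = {self.statistic:.2f} p = {self.p_value:.3f}"


def t_test(x, y, *, paired: bool = False, welch: bool = False) -> TTestResult:
    """Two-sided Student t-test.

    Unpaired defaults to the pooled-variance statistic (Welch by flag).
    Degenerate zero-variance inputs follow the conventions: identical
    constant samples give p = 1; a constant nonzero difference gives
    p -> 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if paired:
        if x.shape != y.shape:
            raise ContractError("paired samples must have equal length")
        if len(x) < 2:
            raise ContractError("paired t-test needs n >= 2")
        d = x - y
        n = len(d)
        md = float(d.mean())
        sd = float(d.std(ddof=1))
        df = float(n - 1)
        if sd == 0.0:
            if md == 0.0:
                return TTestResult(0.0, df, 1.0, 0.0, "paired", True)
            stat = math.inf if md > 0 else -math.inf
            return TTestResult(stat, df, 0.0, md, "paired", True)
        stat = md / (sd / math.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(stat), df))
        return TTestResult(float(stat), df, p, md, "paired")

    if len(x) < 2 or len(y) < 2:
        raise ContractError("unpaired t-test needs n >= 2 per sample")
    nx, ny = len(x), len(y)
    md = float(x.mean() - y.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    if vx == 0.0 and vy == 0.0:
        if md == 0.0:
            return TTestResult(0.0, float(nx + ny - 2), 1.0, 0.0, "unpaired", True)
        stat = math.inf if md > 0 else -math.inf
        return TTestResult(stat, float(nx + ny - 2), 0.0, md, "unpaired", True)
    if welch:
        se2x, se2y = vx / nx, vy / ny
        stat = md / math.sqrt(se2x + se2y)
        df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        stat = md / math.sqrt(sp2 * (1 / nx + 1 / ny))
        df = float(nx + ny - 2)
    p = 2.0 * float(sps.t.sf(abs(stat), df))
    return TTestResult(float(stat), float(df), p, md, "unpaired")


# ----------------------------------------------------------------------
# mixed (split-plot) ANOVA
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    effect: str  # "group" | "time" | "group_x_time"
    F: float
    df1: float
    df2: float
    p_value: float
    gg_epsilon: float
    corrected: bool
    mauchly_W: float = math.nan
    mauchly_p: float = math.nan

    def format(self) -> str:
        return f"F({self.df1:.4g}, {self.df2:.4g}) = {self.F:.2f} p = {self.p_value:.3f}"


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    raw = np.zeros((k - 1, k))
    for i in range(k - 1):
        raw[i, : i + 1] = 1.0
        raw[i, i + 1] = -(i + 1.0)
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def gg_epsilon(pooled_cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon of a k x k within-subject covariance.

    Computed from the orthonormally contrasted covariance ``S_c = C S C'``
    as ``tr(S_c)^2 / ((k-1) tr(S_c @ S_c))``, bounded to
    ``(1/(k-1), 1]``.
    """
    k = pooled_cov.shape[0]
    c = _orthonormal_contrasts(k)
    sc = c @ pooled_cov @ c.T
    tr = float(np.trace(sc))
    tr2 = float(np.trace(sc @ sc))
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / ((k - 1) * tr2)
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def mauchly_test(pooled_cov: np.ndarray, df_error: int) -> tuple[float, float]:
    """Mauchly's sphericity test on the contrasted covariance.

    ``df_error`` is the between-subject error df (n - g).  Returns (W, p);
    for k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    k = pooled_cov.shape[0]
    if k <= 2:
        return 1.0, 1.0
    c = _orthonormal_contrasts(k)
    sc = c @ pooled_cov @ c.T
    d = k - 1
    eig = np.linalg.eigvalsh(sc)
    if (eig <= 0).any():
        return 0.0, 0.0
    w = float(np.prod(eig) / (eig.mean() ** d))
    # two-term asymptotic chi-square expansion (as in ezANOVA/SPSS)
    f = 1.0 - (2 * d * d + d + 2) / (6.0 * d * df_error)
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
          / (288.0 * (df_error * d * f) ** 2))
    chi2 = -df_error * f * math.log(max(w, 1e-300))
    df = d * (d + 1) // 2 - 1
    p1 = float(sps.chi2.sf(chi2, df))
    p2 = float(sps.chi2.sf(chi2, df + 4))
    p = min(max(p1 + w2 * (p2 - p1), 0.0), 1.0)
    return w, p


def mixed_anova(
    values: pd.DataFrame,
    groups: pd.Series,
    *,
    correction: str = "auto",
) -> dict[str, AnovaResult]:
    """Split-plot ANOVA of a complete balanced subjects × timepoints table.

    Parameters
    ----------
    values
        DataFrame indexed by subject with one column per within-subject
        level (ordered), no missing cells.
    groups
        Between-subject factor, indexed like ``values``.
    correction
        ``"auto"`` applies Greenhouse–Geisser when Mauchly p < 0.05,
        ``"always"`` and ``"never"`` override.

    Returns a dict with effects ``group``, ``time`` and ``group_x_time``.
    """
    if correction not in ("auto", "always", "never"):
        raise ConfigError("correction must be auto/always/never")
    if values.isna().any().any():
        raise ContractError("missing cells are not allowed (no imputation)")
    groups = groups.loc[values.index]
    y = values.to_numpy(dtype=np.float64)
    n, k = y.shape
    labels = pd.unique(groups)
    g = len(labels)
    if g < 1 or n < g + 1:
        raise ContractError("need >= 2 subjects per group")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ContractError("need >= 2 subjects per group")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)

    group_idx = {lab: np.flatnonzero((groups == lab).to_numpy()) for lab in labels}
    group_means = {lab: y[idx].mean() for lab, idx in group_idx.items()}
    gt_means = {lab: y[idx].mean(axis=0) for lab, idx in group_idx.items()}

    ss_between_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_group = k * sum(len(idx) * (group_means[lab] - grand) ** 2
                       for lab, idx in group_idx.items())
    ss_subj_within = ss_between_subj - ss_group

    ss_total = float(((y - grand) ** 2).sum())
    ss_within_subj = ss_total - ss_between_subj
    ss_time = n * float(((time_means - grand) ** 2).sum())
    ss_gt = sum(
        len(idx) * float(((gt_means[lab] - group_means[lab] - time_means + grand) ** 2).sum())
        for lab, idx in group_idx.items()
    )
    ss_err_w = ss_within_subj - ss_time - ss_gt

    df_group, df_err_b = g - 1, n - g
    df_time = k - 1
    df_gt = (g - 1) * (k - 1)
    df_err_w = (n - g) * (k - 1)

    # pooled within-group covariance of the repeated measures
    pooled = np.zeros((k, k))
    for lab, idx in group_idx.items():
        centered = y[idx] - y[idx].mean(axis=0)
        pooled += centered.T @ centered
    pooled /= max(n - g, 1)

    eps = gg_epsilon(pooled)
    mau_w, mau_p = mauchly_test(pooled, n - g)
    if correction == "always":
        apply_gg = True
    elif correction == "never":
        apply_gg = False
    else:
        apply_gg = mau_p < ALPHA

    def f_result(effect: str, ss: float, df1: int, ss_err: float, df2: int,
                 within: bool) -> AnovaResult:
        ms_err = ss_err / df2
        if ms_err <= 0:
            # all observations identical: nothing to test
            return AnovaResult(effect, 0.0, float(df1), float(df2), 1.0,
                               eps, False, mau_w, mau_p)
        f = (ss / df1) / ms_err
        corrected = within and apply_gg
        d1 = df1 * eps if corrected else float(df1)
        d2 = df2 * eps if corrected else float(df2)
        p = float(sps.f.sf(f, d1, d2))
        return AnovaResult(effect, float(f), d1, d2, p, eps, corrected, mau_w, mau_p)

    return {
        "group": f_result("group", ss_group, df_group, ss_subj_within, df_err_b, False),
        "time": f_result("time", ss_time, df_time, ss_err_w, df_err_w, True),
        "group_x_time": f_result("group_x_time", ss_gt, df_gt, ss_err_w, df_err_w, True),
    }


def mixed_anova_long(
    table: pd.DataFrame,
    *,
    value: str,
    subject: str = "patient_id",
    within: str = "timepoint",
    between: str = "group",
    correction: str = "auto",
    within_order: list[str] | None = None,
) -> dict[str, AnovaResult]:
    """Convenience wrapper accepting a long table (one row per cell)."""
    wide = table.pivot(index=subject, columns=within, values=value)
    if within_order is not None:
        wide = wide[[c for c in within_order if c in wide.columns]]
    if wide.isna().any().any():
        raise ContractError("incomplete design: every subject needs every timepoint")
    groups = table.drop_duplicates(subject).set_index(subject)[between]
    return mixed_anova(wide, groups.loc[wide.index], correction=correction)


# ----------------------------------------------------------------------
# headline battery
# ----------------------------------------------------------------------


@dataclass
class ContrastReport:
    """One named test of the results battery."""

    name: str
    kind: str  # "paired_t" | "mixed_anova"
    result: object

    def format(self) -> str:
        if self.kind == "paired_t":
            return f"{self.name}: {self.result.format()}"
        lines = [f"{self.name}:"]
        for effect, res in self.result.items():
            star = " [GG]" if res.corrected else ""
            lines.append(f"  {effect}: {res.format()}{star}")
        return "\n".join(lines)


def headline_contrasts(
    tracking: pd.DataFrame,
    metric_tables: dict[str, pd.DataFrame] | None = None,
    specificity: pd.DataFrame | None = None,
    *,
    post_policy: str = "first_post",
    correction: str = "auto",
) -> list[ContrastReport]:
    """Reproduce the cohort test battery on pipeline output tables.

    * paired pre-vs-post t-tests (groups pooled, per phenotype) of the
      donor-reactive clonotype percentage and cumulative frequency;
    * mixed ANOVA (group × time) of each supplied scalar metric table
      (clonality, R20, JSD ...) per phenotype;
    * mixed ANOVA of per-species specificity mass, when supplied.

    ``tracking`` columns: patient_id, group, phenotype, timepoint,
    pct_clonotypes, cum_freq.  Metric tables: patient_id, group, phenotype,
    timepoint, mean.  No multiplicity adjustment is applied.
    """
    from .donor_reactive import delta_table  # local import to avoid cycle

    reports: list[ContrastReport] = []
    for phenotype in sorted(tracking["phenotype"].unique()):
        sub = tracking[tracking["phenotype"] == phenotype]
        for value, label in (("pct_clonotypes", "pct donor-reactive clonotypes"),
                             ("cum_freq", "cumulative donor-reactive frequency")):
            deltas = delta_table(sub, value=value, post_policy=post_policy)
            if len(deltas) >= 2:
                res = t_test(deltas["pre"], deltas["post"], paired=True)
                reports.append(ContrastReport(
                    name=f"{phenotype} {label}: preTx vs post (paired)",
                    kind="paired_t", result=res))
        # group-over-time ANOVA of the tracking percentage
        if sub["timepoint"].nunique() >= 2 and sub["group"].nunique() == 2:
            res = mixed_anova_long(sub, value="pct_clonotypes", correction=correction)
            reports.append(ContrastReport(
                name=f"{phenotype} pct donor-reactive clonotypes: group x time",
                kind="mixed_anova", result=res))

    for metric_name, table in (metric_tables or {}).items():
        for phenotype in sorted(table["phenotype"].unique()):
            sub = table[table["phenotype"] == phenotype]
            if sub["timepoint"].nunique() < 2 or sub["group"].nunique() != 2:
                continue
            res = mixed_anova_long(sub, value="mean", correction=correction)
            reports.append(ContrastReport(
                name=f"{phenotype} {metric_name}: group x time",
                kind="mixed_anova", result=res))

    if specificity is not None and len(specificity):
        for (species, phenotype), sub in specificity.groupby(
                ["antigen_species", "phenotype"]):
            if sub["timepoint"].nunique() < 2 or sub["group"].nunique() != 2:
                continue
            res = mixed_anova_long(sub, value="cum_freq", correction=correction)
            reports.append(ContrastReport(
                name=f"{phenotype} {species}-specific mass: group x time",
                kind="mixed_anova", result=res))
    return reports
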