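"""Statistical battery: normality, agreement, group comparison, ROC.

Implements the analysis toolkit used for evaluating candidate diagnostic
indices: Lilliefors-corrected Kolmogorov-Smirnov normality testing, paired
instrument agreement (paired t, Bland-Altman limits of agreement, ICC(2,1),
concordance correlation coefficient), one-way ANOVA with Fisher LSD
pairwise tests, Pearson correlation, empirical ROC analysis with Youden
cutoff selection, and the DeLong paired comparison of correlated AUCs.

Established libraries stand behind the standard pieces (statsmodels for
Lilliefors, pingouin for ICC, scikit-learn for the ROC curve, scipy for t /
F / normal tails); the concordance formula, LSD, ANOVA decomposition and
DeLong placement-value construction are implemented explicitly because
their exact formulas are part of this module's contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.diagnostic import lilliefors as _lilliefors


@dataclass
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    paired_t_p: float
    icc: float
    ccc: float
    n: int
    icc_form: str = "ICC(2,1) two-way random, absolute agreement, single"


@dataclass
class GroupComparison:
    means: Dict[str, float]
    sds: Dict[str, float]
    ns: Dict[str, int]
    F: float
    p: float
    pairwise: Dict[Tuple[str, str], float]
    ss_between: float
    ss_within: float
    flags: set = field(default_factory=set)


@dataclass
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    curve: List[Tuple[float, float]]  # (fpr, tpr)
    direction: str  # "case_high" or "case_low"


def normality_test(sample: Sequence[float]) -> Tuple[float, float]:
    """Lilliefors-corrected one-sample K-S test against a fitted normal.

    The classical K-S null assumes fully specified parameters; estimating
    mean and SD from the sample requires the Lilliefors correction, which
    is what statistics packages apply in this situation.  Returns
    (statistic, p) where the statistic is the maximum ECDF-CDF gap.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("normality test requires n >= 5")
    if np.std(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    stat, p = _lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p)


def concordance_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Concordance correlation coefficient, population-moment form:

    CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population moments (ddof=0)
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0  # both samples constant and identical
    return float(2.0 * cov / denom)


def _icc_2_1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1) via pingouin on the long-format two-rater table."""
    import pingouin as pg

    n = len(x)
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["x", "y"], n),
            "score": np.concatenate([x, y]),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    )
    # label differs across pingouin versions: ICC2 == ICC(A,1)
    row = table[table["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


def agreement_suite(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Two-instrument agreement: bias, 95% limits, paired t, ICC, CCC.

    Bland-Altman: bias = mean(y - x), limits of agreement
    bias +- 1.96 * SD(y - x) (sample SD).  The paired t-test is on the
    differences; ICC uses the two-way random, absolute-agreement, single
    measure form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("agreement suite requires n >= 3")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.allclose(d, d[0]) and np.isclose(sd, 0.0):
        t_p = 1.0 if np.isclose(bias, 0.0) else 0.0
    else:
        t_p = float(sps.ttest_rel(y, x).pvalue)
    if np.allclose(x, y):
        icc = 1.0
    else:
        icc = _icc_2_1(x, y)
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        paired_t_p=t_p,
        icc=icc,
        ccc=concordance_ccc(x, y),
        n=n,
    )


def anova_lsd(groups: Dict[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA with Fisher LSD pairwise tests.

    The F statistic is computed from the explicit sum-of-squares
    decomposition (SST = SSB + SSW is an invariant of this routine); LSD
    pairwise p-values use t statistics with the pooled within-group mean
    square and its degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrs.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    labels = list(arrs)
    ns = {k: int(a.size) for k, a in arrs.items()}
    means = {k: float(a.mean()) for k, a in arrs.items()}
    sds = {k: float(a.std(ddof=1)) for k, a in arrs.items()}
    allx = np.concatenate(list(arrs.values()))
    grand = allx.mean()
    ssb = float(sum(ns[k] * (means[k] - grand) ** 2 for k in labels))
    ssw = float(sum(((arrs[k] - means[k]) ** 2).sum() for k in labels))
    df_b = len(labels) - 1
    df_w = allx.size - len(labels)
    flags: set = set()
    if ssw == 0.0:
        if ssb == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
            flags.add("zero_within_variance")
        msw = 0.0
    else:
        msb = ssb / df_b
        msw = ssw / df_w
        F = msb / msw
        p = float(sps.f.sf(F, df_b, df_w))
    pairwise: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if msw == 0.0:
                pairwise[(a, b)] = 1.0 if means[a] == means[b] else 0.0
                continue
            se = np.sqrt(msw * (1.0 / ns[a] + 1.0 / ns[b]))
            tstat = (means[a] - means[b]) / se
            pairwise[(a, b)] = float(2.0 * sps.t.sf(abs(tstat), df_w))
    return GroupComparison(
        means=means, sds=sds, ns=ns, F=float(F), p=p, pairwise=pairwise,
        ss_between=ssb, ss_within=ssw, flags=flags,
    )


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = "auto",
) -> ROCResult:
    """Empirical ROC with trapezoidal AUC and Youden-index cutoff.

    ``labels`` are True for cases.  With ``direction='auto'`` the score
    orientation is flipped when cases score low, so the reported AUC is
    always >= 0.5 and the orientation is recorded.  The cutoff maximises
    the Youden index J = sensitivity + specificity - 1; ties are broken
    toward higher specificity.  The cutoff is reported in original score
    units; with ``case_high`` a subject is called positive when
    score >= cutoff, with ``case_low`` when score <= cutoff.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present")
    if direction not in ("auto", "case_high", "case_low"):
        raise ValueError("direction must be auto, case_high or case_low")
    if direction == "auto":
        direction = (
            "case_high" if s[lab].mean() >= s[~lab].mean() else "case_low"
        )
        fpr, tpr, thr = _sk_roc_curve(lab, s if direction == "case_high" else -s)
        if _trapezoid_auc(fpr, tpr) < 0.5:
            direction = "case_low" if direction == "case_high" else "case_high"
    oriented = s if direction == "case_high" else -s
    fpr, tpr, thr = _sk_roc_curve(lab, oriented)
    area = float(_trapezoid_auc(fpr, tpr))
    youden = tpr - fpr
    best = np.flatnonzero(np.isclose(youden, youden.max()))
    # ties toward higher specificity == lower fpr; sklearn thresholds are
    # descending so the first tied index already has the lowest fpr
    i = int(best[np.argmin(fpr[best])])
    cutoff = float(thr[i] if direction == "case_high" else -thr[i])
    if not np.isfinite(cutoff):
        cutoff = float(s[lab].min() if direction == "case_high" else s[lab].max())
    return ROCResult(
        auc=area,
        cutoff=cutoff,
        sensitivity=float(tpr[i]),
        specificity=float(1.0 - fpr[i]),
        curve=list(zip(fpr.tolist(), tpr.tolist())),
        direction=direction,
    )


def _placements(cases: np.ndarray, controls: np.ndarray):
    """DeLong placement values (Mann-Whitney kernel, ties counted 1/2).

    Returns (V10 over cases, V01 over controls, AUC).
    """
    diff_c = cases[:, None] - controls[None, :]
    psi = (diff_c > 0).astype(float) + 0.5 * (diff_c == 0)
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def roc_compare(
    scores1: Sequence[float],
    scores2: Sequence[float],
    labels: Sequence[bool],
    direction: str = "auto",
) -> Tuple[float, float]:
    """DeLong paired test of two correlated AUCs on identical subjects.

    Returns ``(z, p)`` for the two-sided test of equal AUCs.  With
    ``direction='auto'`` each score vector is oriented cases-high before
    comparison (the usual convention when comparing diagnostic indices of
    opposite polarity).  ``z = 0, p = 1`` when the AUC difference variance
    vanishes (e.g. identical or rank-equivalent scores).
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if s1.shape != s2.shape or s1.shape != lab.shape:
        raise ValueError("score vectors and labels must have equal length")
    if lab.all() or not lab.any():
        raise ValueError("both classes must be present")

    def orient(s):
        if direction == "case_low":
            return -s
        if direction == "case_high":
            return s
        v10, _, a = _placements(s[lab], s[~lab])
        return s if a >= 0.5 else -s

    s1o, s2o = orient(s1), orient(s2)
    v10_1, v01_1, a1 = _placements(s1o[lab], s1o[~lab])
    v10_2, v01_2, a2 = _placements(s2o[lab], s2o[~lab])
    m, n = int(lab.sum()), int((~lab).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0 or np.isclose(a1, a2):
        if np.isclose(a1, a2):
            return 0.0, 1.0
        return float(np.sign(a1 - a2) * np.inf), 0.0
    z = float((a1 - a2) / np.sqrt(var))
    return z, float(2.0 * sps.norm.sf(abs(z)))


def correlate(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r with the two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def group_table(
    df: pd.DataFrame,
    parameters: Sequence[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-parameter group means +- SD with ANOVA F/p and LSD pairwise p."""
    rows = []
    for param in parameters:
        groups = {
            g: sub[param].dropna().to_numpy()
            for g, sub in df.groupby(group_col)
        }
        comp = anova_lsd(groups)
        row = {"parameter": param, "F": comp.F, "p": comp.p}
        for g in groups:
            row[f"{g}_mean"] = comp.means[g]
            row[f"{g}_sd"] = comp.sds[g]
        for (a, b), pv in comp.pairwise.items():
            row[f"LSD_{a}_vs_{b}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)


def roc_table(
    df: pd.DataFrame,
    parameters: Sequence[str],
    case_group: str,
    control_group: str,
    group_col: str = "group",
) -> pd.DataFrame:
    """Cutoff / specificity / sensitivity / AUC per parameter for a contrast."""
    sub = df[df[group_col].isin([case_group, control_group])]
    labels = (sub[group_col] == case_group).to_numpy()
    rows = []
    for param in parameters:
        vals = sub[param].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        res = roc_curve(vals[ok], labels[ok])
        rows.append(
            {
                "parameter": param,
                "contrast": f"{case_group}_vs_{control_group}",
                "cutoff": res.cutoff,
                "specificity": res.specificity,
                "sensitivity": res.sensitivity,
                "auc": res.auc,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows)
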