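"""Validation arithmetic: ΔΔCP relative quantification, Student t-tests and
microarray/qPCR correlation.

ΔΔCP doubles as a log2 fold-change estimate because one PCR cycle is one
two-fold change in transcript abundance:

    ΔΔCP = ΔCP_treated − ΔCP_untreated,
    ΔCP  = CP_reference − CP_tested  (within one condition),

so induction gives a positive ΔΔCP.  The reference gene is the actin locus
*actA* (AN6542) by default.  Summaries carry the mean ± sample SD over
biological replicates and a one-sample Student t-test against zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import REFERENCE_GENE, UNTREATED

ALPHA = 0.05


@dataclass
class TTestResult:
    t: float
    p: float
    significant: bool
    df: float


@dataclass
class QpcrSummary:
    gene_id: str
    strain: str
    stress: str
    ddcp_mean: float
    ddcp_sd: float
    n: int
    t: float
    p: float
    significant: bool


def one_sample_ttest(mean: float, sd: float, n: int, two_sided: bool = True,
                     alpha: float = ALPHA) -> TTestResult:
    """Student's one-sample t-test against zero from summary statistics.

    The SD is the sample SD (n−1 denominator).  With sd = 0 the test is
    degenerate: a nonzero mean is reported as significant with p at the
    distribution's limit (0.0), a zero mean gives t = 0, p = 1.
    """
    if n < 2:
        raise ValueError(f"one-sample t-test needs n >= 2, got {n}")
    if sd < 0:
        raise ValueError(f"sd must be nonnegative, got {sd}")
    df = n - 1
    if sd == 0:
        if mean == 0:
            return TTestResult(0.0, 1.0, False, df)
        return TTestResult(math.copysign(math.inf, mean), 0.0, True, df)
    t = mean / (sd / math.sqrt(n))
    tail = stats.t.sf(abs(t), df)
    p = 2 * tail if two_sided else float(stats.t.sf(t, df))
    return TTestResult(float(t), float(p), p < alpha, df)


def one_sample_ttest_from_values(values, two_sided: bool = True,
                                 alpha: float = ALPHA) -> TTestResult:
    values = np.asarray(values, dtype=float)
    return one_sample_ttest(float(values.mean()), float(values.std(ddof=1)),
                            len(values), two_sided, alpha)


def two_sample_ttest(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
                     two_sided: bool = True, welch: bool = False,
                     alpha: float = ALPHA) -> TTestResult:
    """Two-sample Student t-test from summary statistics.

    Classical pooled-variance form by default (df = n1+n2−2); ``welch=True``
    uses the unequal-variance Welch–Satterthwaite form.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("two-sample t-test needs n >= 2 in both groups")
    v1, v2 = sd1 ** 2, sd2 ** 2
    if v1 == 0 and v2 == 0:
        if mean1 == mean2:
            return TTestResult(0.0, 1.0, False, n1 + n2 - 2)
        return TTestResult(math.copysign(math.inf, mean1 - mean2), 0.0, True, n1 + n2 - 2)
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = (mean1 - mean2) / math.sqrt(se2)
    else:
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        t = (mean1 - mean2) / math.sqrt(pooled * (1 / n1 + 1 / n2))
    tail = stats.t.sf(abs(t), df)
    p = 2 * tail if two_sided else float(stats.t.sf(t, df))
    return TTestResult(float(t), float(p), p < alpha, float(df))


def delta_delta_cp(table: pd.DataFrame, gene: str, strain: str, stress: str,
                   reference_gene: str = REFERENCE_GENE, untreated: str = UNTREATED,
                   two_sided: bool = True) -> tuple[np.ndarray, QpcrSummary]:
    """Per-replicate ΔΔCP of one gene under one stress, plus its summary.

    The long-format ``table`` has columns (gene_id, strain, condition,
    replicate, cp).  Replicates are paired by index within each condition;
    if the treated and untreated replicate counts differ, the summary falls
    back to the difference of per-condition means with a delta-method SD.
    """
    def cp_vector(g: str, condition: str) -> pd.Series:
        sel = table[(table["gene_id"] == g) & (table["strain"] == strain)
                    & (table["condition"] == condition)]
        if sel.empty:
            raise ValueError(f"no CP measurements for {g!r} in {strain}/{condition}")
        return sel.sort_values("replicate").set_index("replicate")["cp"]

    ref_t, ref_u = cp_vector(reference_gene, stress), cp_vector(reference_gene, untreated)
    gene_t, gene_u = cp_vector(gene, stress), cp_vector(gene, untreated)
    dcp_t = ref_t - gene_t
    dcp_u = ref_u - gene_u

    if len(dcp_t) == len(dcp_u):
        ddcp = (dcp_t.to_numpy() - dcp_u.to_numpy())
        mean, sd, n = float(ddcp.mean()), float(ddcp.std(ddof=1)), len(ddcp)
    else:  # unpaired fallback: difference of condition means, delta-method SD
        ddcp = np.array([dcp_t.mean() - dcp_u.mean()])
        var = dcp_t.var(ddof=1) / len(dcp_t) + dcp_u.var(ddof=1) / len(dcp_u)
        mean, sd, n = float(ddcp[0]), float(math.sqrt(var)), min(len(dcp_t), len(dcp_u))
    test = one_sample_ttest(mean, sd, n, two_sided=two_sided)
    return ddcp, QpcrSummary(gene, strain, stress, mean, sd, n, test.t, test.p,
                             test.significant)


def qpcr_summary_table(table: pd.DataFrame, reference_gene: str = REFERENCE_GENE,
                       untreated: str = UNTREATED, two_sided: bool = True) -> pd.DataFrame:
    """ΔΔCP summaries for every (gene, strain, stress) in a long CP table."""
    genes = [g for g in table["gene_id"].unique() if g != reference_gene]
    strains = table["strain"].unique()
    stresses = [c for c in table["condition"].unique() if c != untreated]
    rows = []
    for strain in strains:
        for stress in stresses:
            for gene in genes:
                _, s = delta_delta_cp(table, gene, strain, stress, reference_gene,
                                      untreated, two_sided)
                rows.append(s.__dict__)
    return pd.DataFrame(rows)


def pearson_correlation(x, y) -> float:
    """Pearson r of paired values (e.g. microarray log2R vs qPCR ΔΔCP)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance in one vector")
    return float(stats.pearsonr(x, y)[0])


def _concordance_status(p_two: float, p_one: float, published: bool,
                        alpha: float = ALPHA) -> str:
    """Classify a recomputed-vs-published significance comparison.

    concordant: the two-sided verdict matches the published flag.
    borderline: only the one-sided verdict matches (the published tests'
    sidedness is not documented, so these cells are reported, not asserted).
    discordant: neither convention reproduces the published flag — typically
    a rounding artifact of the printed mean ± SD.
    """
    if (p_two < alpha) == published:
        return "concordant"
    if (p_one < alpha) == published:
        return "borderline"
    return "discordant"


def qpcr_concordance_report(panel: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Recompute one-sample t-tests for a published ΔΔCP summary panel.

    ``panel`` columns: gene_id, strain, stress, ddcp_mean, ddcp_sd, n,
    significant (the published flag).  Adds recomputed two- and one-sided
    p-values and a concordance status per cell.
    """
    rows = []
    for row in panel.itertuples(index=False):
        two = one_sample_ttest(row.ddcp_mean, row.ddcp_sd, row.n, two_sided=True,
                               alpha=alpha)
        p_one = two.p / 2  # one-sided in the direction of the observed mean
        rows.append({"gene_id": row.gene_id, "strain": row.strain, "stress": row.stress,
                     "ddcp_mean": row.ddcp_mean, "ddcp_sd": row.ddcp_sd, "n": row.n,
                     "t": two.t, "p_two_sided": two.p, "p_one_sided": p_one,
                     "published_significant": bool(row.significant),
                     "status": _concordance_status(two.p, p_one, bool(row.significant),
                                                   alpha)})
    return pd.DataFrame(rows)


def enzyme_concordance_report(panel: pd.DataFrame, untreated: str = UNTREATED,
                              alpha: float = ALPHA) -> pd.DataFrame:
    """Recompute stressed-vs-untreated two-sample t-tests for an assay panel.

    ``panel`` columns: strain, condition, assay, mean, sd, n, significant.
    Each stressed culture is compared against the same strain's untreated
    culture with the pooled-variance Student t-test.
    """
    base = panel[panel["condition"] == untreated].set_index(["strain", "assay"])
    rows = []
    for row in panel[panel["condition"] != untreated].itertuples(index=False):
        u = base.loc[(row.strain, row.assay)]
        two = two_sample_ttest(row.mean, row.sd, row.n, u["mean"], u["sd"], int(u["n"]),
                               two_sided=True, alpha=alpha)
        p_one = two.p / 2
        rows.append({"strain": row.strain, "condition": row.condition, "assay": row.assay,
                     "mean": row.mean, "sd": row.sd, "n": row.n,
                     "untreated_mean": float(u["mean"]), "t": two.t,
                     "p_two_sided": two.p, "p_one_sided": p_one,
                     "published_significant": bool(row.significant),
                     "status": _concordance_status(two.p, p_one, bool(row.significant),
                                                   alpha)})
    return pd.DataFrame(rows)


def calls_from_qpcr_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Regulation profile (genes x (strain, stress) calls) from ΔΔCP summaries.

    up = significant positive mean, down = significant negative mean.
    Accepts either recomputed summaries (columns ddcp_mean/significant) or a
    published panel with the same columns.
    """
    call = np.where(~summary["significant"].astype(bool), "none",
                    np.where(summary["ddcp_mean"] > 0, "up", "down"))
    long = summary.assign(call=call)[["gene_id", "strain", "stress", "call"]]
    wide = long.pivot_table(index="gene_id", columns=["strain", "stress"], values="call",
                            aggfunc="first")
    return wide.fillna("none")
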