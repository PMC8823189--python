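"""Group-specific paired differential expression with FDR control.

The study design estimates the condition effect (post vs baseline) within
subject, separately per intervention group.  Here the per-gene statistic is
a one-sample location test of the within-subject log2 fold changes against
zero.  By default the per-gene variance is moderated by empirical-Bayes
shrinkage toward a pooled prior (the limma squeezeVar model: per-gene
sample variances are assumed scaled chi-square around a gene-level variance
with a scaled inverse chi-square prior, whose d0 and s0^2 are estimated by
method of moments on log variances).  With only a handful of subjects per
group, raw per-gene variances of df = n-1 are far too unstable for
genome-wide testing; shrinkage borrows strength across genes much as the
dispersion-shrinkage of dedicated count-based tools does.  ``moderated=False``
gives the plain per-gene t-test.

Multiple testing is controlled by Benjamini-Hochberg; genes must also pass
a TPM > 0.1 expression floor (mean over the group's samples) to be tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, ValidationError, sample_of, validate_sample_sheet
from .normalize import DEFAULT_EPSILON

DEFAULT_TPM_FLOOR = 0.1
DEFAULT_ALPHA = 0.05

_MAX_PRIOR_DF = 1e7  # treated as an effectively infinite prior


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved.

    The adjusted value for the i-th smallest p is
    ``min_{j >= i} p_(j) * m / j`` capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > special.polygamma(1, 1e-8):
        return 1e-8
    if y < special.polygamma(1, 1e8):
        return 1e8
    return float(
        optimize.brentq(lambda x: special.polygamma(1, x) - y, 1e-8, 1e8, xtol=1e-12)
    )


def squeeze_var(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of sample variances (limma's squeezeVar).

    Parameters
    ----------
    s2
        Per-gene sample variances, each on ``df`` degrees of freedom.
    df
        Residual degrees of freedom of each variance (n - 1 here).

    Returns
    -------
    (posterior variances, prior df d0, prior variance s0^2).  When the
    spread of log variances is no larger than expected from chi-square
    sampling alone, d0 is effectively infinite and every posterior
    variance equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) < 2:
        raise ValueError("squeeze_var needs at least two positive variances")
    # method of moments on z = log(s2): E z = log(sigma2) + psi(df/2) - log(df/2)
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        d0 = min(d0, _MAX_PRIOR_DF)
        s0_2 = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = _MAX_PRIOR_DF
        s0_2 = float(np.exp(mean_e))
    if np.isfinite(d0) and d0 < _MAX_PRIOR_DF:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        post = np.full_like(s2, s0_2)
    return post, d0, s0_2


def moderated_one_sample_t(fc: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Moderated one-sample t-test of each row of ``fc`` against zero.

    ``fc`` is genes x subjects.  Returns (t, p, d0, s0^2); p is two-sided
    with df = (n - 1) + d0.
    """
    n = fc.shape[1]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = fc.mean(axis=1)
    s2 = fc.var(axis=1, ddof=1)
    if (s2 <= 0).all():
        # fully degenerate input (e.g. noiseless null): no evidence against 0
        t = np.zeros_like(mean)
        p = np.ones_like(mean)
        return t, p, float("inf"), 0.0
    post, d0, s0_2 = squeeze_var(s2, n - 1)
    se = np.sqrt(post / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    df_total = min((n - 1) + d0, _MAX_PRIOR_DF)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero posterior variance with zero mean: no signal
    p = np.where(se == 0, np.where(mean == 0, 1.0, 0.0), p)
    t = np.where(se == 0, np.where(mean == 0, 0.0, np.inf) * np.sign(mean), t)
    return t, np.clip(p, 0.0, 1.0), d0, s0_2


def paired_de_test(
    matrix: ExpressionMatrix,
    sheet: pd.DataFrame,
    group: str,
    epsilon: float = DEFAULT_EPSILON,
    tpm_floor: float = DEFAULT_TPM_FLOOR,
    alpha: float = DEFAULT_ALPHA,
    moderated: bool = True,
) -> pd.DataFrame:
    """Paired differential expression for one intervention group.

    Genes whose mean TPM over the group's samples is <= ``tpm_floor``
    carry no p-value.  Per tested gene: mean within-subject log2FC, raw p
    from the (moderated) one-sample t, BH-adjusted p, and a significance
    flag (adjusted p < alpha; implies the expression filter passed).
    Zero-variance genes under the plain test are assigned p = 1 and
    flagged ``degenerate``.
    """
    validate_sample_sheet(sheet)
    grp_sheet = sheet[sheet["intervention"] == group]
    subjects = sorted(grp_sheet["subject_id"].unique())
    if len(subjects) < 3:
        raise ValidationError(f"group {group!r} has {len(subjects)} subjects; need >= 3")

    samples = grp_sheet["sample_id"].tolist()
    mean_tpm = matrix.values[samples].mean(axis=1)
    passed = mean_tpm > tpm_floor

    fc_cols = []
    for s in subjects:
        base = matrix.values[sample_of(grp_sheet, s, "baseline")]
        post = matrix.values[sample_of(grp_sheet, s, "post")]
        fc_cols.append(np.log2((post + epsilon) / (base + epsilon)))
    fc = np.stack(fc_cols, axis=1)

    result = pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "group": group,
            "mean_tpm": mean_tpm.to_numpy(),
            "passed_filter": passed.to_numpy(),
            "log2fc": fc.mean(axis=1),
            "p": np.nan,
            "adj_p": np.nan,
            "significant": False,
            "degenerate": False,
        }
    ).set_index("gene_id")

    tested = result.index[result["passed_filter"]]
    if len(tested) == 0:
        return result
    fc_tested = fc[result["passed_filter"].to_numpy()]
    if moderated:
        _, p, _, _ = moderated_one_sample_t(fc_tested)
        degenerate = np.zeros(len(tested), dtype=bool)
    else:
        s2 = fc_tested.var(axis=1, ddof=1)
        degenerate = s2 == 0
        p = np.ones(len(tested))
        ok = ~degenerate
        if ok.any():
            res = stats.ttest_1samp(fc_tested[ok], 0.0, axis=1)
            p[ok] = res.pvalue
    adj = benjamini_hochberg(p)
    result.loc[tested, "p"] = p
    result.loc[tested, "adj_p"] = adj
    result.loc[tested, "degenerate"] = degenerate
    result.loc[tested, "significant"] = adj < alpha
    return result


@dataclass
class OverlapSummary:
    """Bookkeeping of DEG agreement between the two intervention groups."""

    shared: int
    same_direction_up: int
    same_direction_down: int
    opposing: int
    genes: dict[str, list[str]]

    def as_dict(self) -> dict:
        return {
            "shared": self.shared,
            "same_direction_up": self.same_direction_up,
            "same_direction_down": self.same_direction_down,
            "opposing": self.opposing,
            "genes": self.genes,
        }


def overlap_summary(deg_control: pd.DataFrame, deg_exercise: pd.DataFrame) -> OverlapSummary:
    """Partition the shared significant genes by sign agreement.

    shared = same_direction_up + same_direction_down + opposing holds on
    every input; a zero log2FC on either side counts as opposing (no
    direction agreement can be claimed).
    """
    sig_c = set(deg_control.index[deg_control["significant"]])
    sig_e = set(deg_exercise.index[deg_exercise["significant"]])
    shared = sorted(sig_c & sig_e)
    up, down, opp = [], [], []
    for g in shared:
        fc_c = deg_control.loc[g, "log2fc"]
        fc_e = deg_exercise.loc[g, "log2fc"]
        if fc_c > 0 and fc_e > 0:
            up.append(g)
        elif fc_c < 0 and fc_e < 0:
            down.append(g)
        else:
            opp.append(g)
    return OverlapSummary(
        shared=len(shared),
        same_direction_up=len(up),
        same_direction_down=len(down),
        opposing=len(opp),
        genes={"shared": shared, "same_direction_up": up, "same_direction_down": down, "opposing": opp},
    )


def rank_top_genes(deg_table: pd.DataFrame, n: int) -> tuple[list[str], list[str]]:
    """Top-n significant genes per direction, ordered by |log2FC|.

    Returns (upregulated, downregulated) lists; ties break
    lexicographically by gene_id.  Negating every log2FC swaps the lists.
    """
    sig = deg_table[deg_table["significant"]]
    up = sig[sig["log2fc"] > 0]
    down = sig[sig["log2fc"] < 0]
    order = lambda df: sorted(df.index, key=lambda g: (-abs(df.loc[g, "log2fc"]), g))  # noqa: E731
    return order(up)[:n], order(down)[:n]


class PairedDifferentialExpression(BaseEstimator):
    """Sklearn-style estimator for the paired group-specific DE test.

    Attributes (after ``fit(matrix, sheet)``)
    ----------
    results_ : DataFrame per gene (log2fc, p, adj_p, significant, ...)
    significant_ : Index of significant genes
    upregulated_, downregulated_ : significant genes split by sign
    """

    def __init__(
        self,
        group: str = "control",
        epsilon: float = DEFAULT_EPSILON,
        tpm_floor: float = DEFAULT_TPM_FLOOR,
        alpha: float = DEFAULT_ALPHA,
        moderated: bool = True,
    ):
        self.group = group
        self.epsilon = epsilon
        self.tpm_floor = tpm_floor
        self.alpha = alpha
        self.moderated = moderated

    def fit(self, X: ExpressionMatrix, sheet: pd.DataFrame):
        self.results_ = paired_de_test(
            X,
            sheet,
            group=self.group,
            epsilon=self.epsilon,
            tpm_floor=self.tpm_floor,
            alpha=self.alpha,
            moderated=self.moderated,
        )
        sig = self.results_[self.results_["significant"]]
        self.significant_ = sig.index
        self.upregulated_ = sig.index[sig["log2fc"] > 0]
        self.downregulated_ = sig.index[sig["log2fc"] < 0]
        return self
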