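"""Count-based differential expression between two pooled libraries.

Expression is normalised to reads per million of each library's valid
(clean) reads.  Significance uses the Audic-Claverie exact test for
two-library count data -- the conditional distribution of the second
count given the first,

    p(y|x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

with lower tail C = sum_{k<=y} p(k|x), upper tail D = sum_{k>=y} p(k|x)
and a two-sided p of min(1, 2*min(C, D)) -- alongside Fisher's exact and a
continuity-corrected chi-square test on the corresponding 2x2 table.
Everything is computed in log space for overflow safety.

Also includes the 2^-ddCt helper for qPCR relative expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2_contingency, fisher_exact


@dataclass(frozen=True)
class DEThresholds:
    """Flagging rules for differential expression.

    A miRNA is differentially expressed when its pooled raw count exceeds
    ``min_total_reads``, the exact-test p is below ``alpha`` and
    |log2 fold change| >= ``min_abs_log2fc``.  Records below
    ``low_expression_floor`` TPM in both libraries are removed before
    testing; a zero TPM is replaced by ``zero_substitute`` before the fold
    change only.
    """

    min_total_reads: int = 10
    alpha: float = 0.05
    min_abs_log2fc: float = 1.5
    low_expression_floor: float = 1.0
    zero_substitute: float = 0.01

    def __post_init__(self):
        if min(self.min_total_reads, self.alpha, self.min_abs_log2fc,
               self.low_expression_floor, self.zero_substitute) <= 0:
            raise ValueError("all thresholds must be positive")


DEFAULT_DE = DEThresholds()


def tpm(count: int, total: int) -> float:
    """Reads per million: 10^6 * count / total clean reads."""
    if total <= 0:
        raise ValueError("total clean reads must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return 1e6 * count / total


class ACResult(NamedTuple):
    point: float      # p(y|x)
    lower: float      # C(y' <= y | x)
    upper: float      # D(y' >= y | x)
    two_sided: float


def _log_pmf(ks: np.ndarray, x: int, log_r: float) -> np.ndarray:
    """log p(k|x) for the count-ratio exact distribution, r = N2/N1."""
    return (ks * log_r + gammaln(x + ks + 1) - gammaln(x + 1)
            - gammaln(ks + 1) - (x + ks + 1) * np.log1p(np.exp(log_r)))


def ac_pvalue(x: int, y: int, N1: int, N2: int) -> ACResult:
    """Audic-Claverie exact test of count x (library 1) vs y (library 2)."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    log_r = np.log(N2) - np.log(N1)
    ks = np.arange(y + 1)
    pmf = np.exp(_log_pmf(ks, x, log_r))
    point = float(pmf[-1])
    lower = float(min(1.0, pmf.sum()))
    upper = float(min(1.0, max(0.0, 1.0 - (pmf[:-1].sum()))))
    two_sided = min(1.0, 2.0 * min(lower, upper))
    return ACResult(point, lower, upper, two_sided)


def test_2x2(x: int, y: int, N1: int, N2: int) -> tuple[float, float]:
    """Two-sided Fisher exact and continuity-corrected chi-square p-values
    for the table [[x, N1-x], [y, N2-y]]."""
    table = np.array([[x, N1 - x], [y, N2 - y]])
    if table.min() < 0:
        raise ValueError("counts exceed library totals")
    _, fisher_p = fisher_exact(table, alternative="two-sided")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        chi2_p = 1.0
    else:
        chi2_p = float(chi2_contingency(table, correction=True).pvalue)
    return float(fisher_p), chi2_p


def _bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, never gating)."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    prev = 1.0
    for rank, idx in list(enumerate(order, start=1))[::-1]:
        prev = min(prev, pvals[idx] * n / rank)
        adj[idx] = prev
    return adj


def de_table(counts, totals: tuple[int, int],
             thresholds: DEThresholds = DEFAULT_DE):
    """Differential-expression table from per-miRNA counts.

    ``counts`` is a DataFrame with columns ``count_E`` and ``count_L``
    (index = miRNA id); ``totals`` are the two libraries' valid-read
    totals.  Applies, in order: TPM normalisation; removal of records below
    the low-expression floor in both libraries; zero substitution before
    the fold change; all three tests on the raw counts; DE and
    library-specific flags.
    """
    import pandas as pd

    n1, n2 = totals
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    df = counts.copy()
    df["tpm_E"] = [tpm(c, n1) for c in df["count_E"]]
    df["tpm_L"] = [tpm(c, n2) for c in df["count_L"]]
    df["removed_low"] = (
        (df["tpm_E"] < thresholds.low_expression_floor)
        & (df["tpm_L"] < thresholds.low_expression_floor)
    )
    kept = df[~df["removed_low"]].copy()
    sub = thresholds.zero_substitute
    e = kept["tpm_E"].replace(0.0, sub)
    l = kept["tpm_L"].replace(0.0, sub)
    kept["log2fc"] = np.log2(l / e)

    p_ac, p_f, p_c = [], [], []
    for x, y in zip(kept["count_E"].astype(int), kept["count_L"].astype(int)):
        p_ac.append(ac_pvalue(x, y, n1, n2).two_sided)
        fp, cp = test_2x2(x, y, n1, n2)
        p_f.append(fp)
        p_c.append(cp)
    kept["p_ac"] = p_ac
    kept["p_fisher"] = p_f
    kept["p_chi2"] = p_c
    kept["p_ac_bh"] = _bh(np.asarray(p_ac)) if len(p_ac) else []

    total_reads = kept["count_E"] + kept["count_L"]
    kept["de"] = (
        (total_reads > thresholds.min_total_reads)
        & (kept["p_ac"] < thresholds.alpha)
        & (kept["log2fc"].abs() >= thresholds.min_abs_log2fc)
    )
    kept["specific_E"] = (kept["count_L"] == 0) & (kept["count_E"] > thresholds.min_total_reads)
    kept["specific_L"] = (kept["count_E"] == 0) & (kept["count_L"] > thresholds.min_total_reads)
    out = kept.reindex(df.index)
    out["removed_low"] = df["removed_low"]
    for c in ("count_E", "count_L", "tpm_E", "tpm_L"):
        out[c] = df[c]
    for c in ("de", "specific_E", "specific_L"):
        out[c] = [bool(v) if v == v else False for v in out[c]]
    return out


def ddct(ct_target_a: float, ct_ref_a: float,
         ct_target_b: float, ct_ref_b: float) -> float:
    """Relative qPCR expression 2^-ddCt of condition A vs calibrator B,
    each normalised to a reference gene (e.g. U6)."""
    if min(ct_target_a, ct_ref_a, ct_target_b, ct_ref_b) <= 0:
        raise ValueError("Ct values must be positive")
    ddct_val = (ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b)
    return float(2.0 ** (-ddct_val))
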