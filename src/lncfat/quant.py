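"""Expression quantification (FPKM), differential screening and qPCR helpers.

FPKM for feature *g* in sample *s* is

    fpkm[g, s] = counts[g, s] * 1e9 / (library_total[s] * effective_length[g])

with ``library_total[s]`` the column sum of fragment counts. Features are kept
for analysis when FPKM exceeds 0.1 in at least one sample (strict).

The differential screen contrasts the two tissues (ST over LT): fold change is
computed on tissue-mean FPKM with a pseudocount of 1,

    log2fc = log2((mean_ST + 1) / (mean_LT + 1)),

and the p-value comes from Welch's two-sided t-test on log2(FPKM + 1) sample
values (pre-computed p-values may be supplied instead). A feature is called
``up`` when log2fc > 1 and p < 0.05, ``down`` when log2fc < -1 and p < 0.05,
else ``ns``; raw p-values drive the call and Benjamini-Hochberg adjusted
values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "compute_fpkm",
    "filter_expressed",
    "differential_screen",
    "call_specificity",
    "ddct",
]

TISSUES = ("LT", "ST")


@dataclass
class ExpressionMatrix:
    """Counts + FPKM for features x samples, with a sample->tissue map.

    ``counts`` and ``fpkm`` are DataFrames indexed by feature id with sample
    columns; ``effective_length`` is a bp Series over features; ``tissues``
    maps each sample id to "LT" or "ST".
    """

    counts: pd.DataFrame
    effective_length: pd.Series
    tissues: pd.Series
    fpkm: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        missing = set(self.counts.columns) - set(self.tissues.index)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)}")
        bad = set(self.tissues.loc[list(self.counts.columns)]) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")
        if self.fpkm is None:
            self.fpkm = _fpkm_from_counts(self.counts, self.effective_length)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.samples if self.tissues[s] == tissue]

    def subset(self, features) -> "ExpressionMatrix":
        idx = self.counts.index.intersection(pd.Index(features))
        return ExpressionMatrix(
            counts=self.counts.loc[idx],
            effective_length=self.effective_length.loc[idx],
            tissues=self.tissues,
            fpkm=self.fpkm.loc[idx],
        )

    def log2_fpkm(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return np.log2(self.fpkm + pseudocount)


def _fpkm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"effective length missing for features {missing}")
    if (lengths <= 0).any():
        bad = list(counts.index[lengths <= 0])[:5]
        raise ValueError(f"effective length must be > 0; offending: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero library total in sample(s): {list(zero.index)}")
    return counts * 1e9 / totals / lengths.to_numpy()[:, None]


def compute_fpkm(
    counts: pd.DataFrame, effective_lengths: pd.Series, tissues: pd.Series
) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` with FPKM from raw fragment counts."""
    return ExpressionMatrix(counts=counts, effective_length=effective_lengths, tissues=tissues)


def filter_expressed(m: ExpressionMatrix, threshold: float = 0.1) -> ExpressionMatrix:
    """Keep features with FPKM strictly above ``threshold`` in >= 1 sample."""
    keep = m.fpkm.max(axis=1) > threshold
    return ExpressionMatrix(
        counts=m.counts.loc[keep],
        effective_length=m.effective_length.loc[keep.index[keep]],
        tissues=m.tissues,
        fpkm=m.fpkm.loc[keep],
    )


def differential_screen(
    m: ExpressionMatrix,
    fc_cut: float = 1.0,
    p_cut: float = 0.05,
    pseudocount: float = 1.0,
    pvalues: pd.Series | None = None,
) -> pd.DataFrame:
    """Screen features for differential expression between ST and LT.

    Returns a DataFrame indexed by feature with columns ``mean_fpkm_LT``,
    ``mean_fpkm_ST``, ``log2fc``, ``pvalue``, ``padj``, ``status`` and
    ``specificity``. ``pvalues``, if given, replaces the built-in Welch test
    (e.g. to plug in an external DE engine).
    """
    lt, st = m.samples_of("LT"), m.samples_of("ST")
    if pvalues is None and (len(lt) < 2 or len(st) < 2):
        raise ValueError(
            f"need >= 2 samples per tissue for the t-test (LT={len(lt)}, ST={len(st)})"
        )
    mean_lt = m.fpkm[lt].mean(axis=1)
    mean_st = m.fpkm[st].mean(axis=1)
    log2fc = np.log2((mean_st + pseudocount) / (mean_lt + pseudocount))

    if pvalues is not None:
        pvals = pvalues.reindex(m.features).to_numpy(float)
    else:
        x = m.log2_fpkm(pseudocount)
        with np.errstate(invalid="ignore", divide="ignore"):
            pvals = stats.ttest_ind(
                x[st].to_numpy(), x[lt].to_numpy(), axis=1, equal_var=False
            ).pvalue
    pvals = np.asarray(pvals, float)

    finite = np.isfinite(pvals)
    padj = np.full_like(pvals, np.nan)
    if finite.any():
        padj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]

    sig = finite & (pvals < p_cut)
    status = np.where(
        sig & (log2fc > fc_cut), "up", np.where(sig & (log2fc < -fc_cut), "down", "ns")
    )
    out = pd.DataFrame(
        {
            "mean_fpkm_LT": mean_lt,
            "mean_fpkm_ST": mean_st,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "status": status,
        },
        index=m.features,
    )
    out["specificity"] = call_specificity(m)
    return out


def call_specificity(m: ExpressionMatrix, threshold: float = 0.1) -> pd.Series:
    """Label each feature LT_specific / ST_specific / shared / not_expressed.

    A feature is expressed in a tissue when FPKM > ``threshold`` in at least
    one sample of that tissue; "specific" means expressed in exactly one
    tissue (and <= threshold in every sample of the other).
    """
    lt, st = m.samples_of("LT"), m.samples_of("ST")
    in_lt = (m.fpkm[lt] > threshold).any(axis=1)
    in_st = (m.fpkm[st] > threshold).any(axis=1)
    lab = np.where(
        in_lt & in_st,
        "shared",
        np.where(in_st, "ST_specific", np.where(in_lt, "LT_specific", "not_expressed")),
    )
    return pd.Series(lab, index=m.features, name="specificity")


def ddct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,cal - Ct_ref,cal);
    the result is 2**(-ddCt), i.e. 1 when ddCt = 0.
    """
    for v in (ct_target_test, ct_ref_test, ct_target_cal, ct_ref_cal):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct_value = (ct_target_test - ct_ref_test) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct_value))
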