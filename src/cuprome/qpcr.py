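"""Copper-induction qPCR analysis: reference stability, ddCT, significance.

Cycle-threshold (CT) tables are analysed with the ddCT method: per
replicate, dCT = CT(target) - CT(reference); ddCT is the mean treated dCT
minus the mean control dCT; fold change = 2^(-ddCT) and results are
reported as log2 fold changes.  Candidate reference genes are screened by
the BestKeeper standard-deviation criterion (SD of CT across all samples
< 1 cycle = stable).  Group differences in dCT are tested with a
Shapiro-Wilk-gated choice between Welch's t-test and the Mann-Whitney U
test, at alpha = 0.05, with no multiple-testing correction by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["strain", "gene", "condition", "timepoint", "replicate", "ct"]


@dataclass
class ExpressionResult:
    gene: str
    condition: str
    dct_treated: np.ndarray  # per-replicate dCT, treated
    dct_control: np.ndarray  # per-replicate dCT, control
    ddct: float
    log2_fold_change: float
    fold_change: float
    test_used: str  # "t_test" | "mann_whitney"
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        assert np.isclose(self.fold_change * 2.0 ** self.ddct, 1.0)
        assert np.isclose(self.log2_fold_change, -self.ddct)


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"CT table lacks columns: {sorted(missing)}")
    return table


def reference_stability(records: pd.DataFrame, gene: str) -> tuple[float, bool]:
    """BestKeeper-style stability of a candidate reference gene.

    Returns the sample standard deviation (n-1 denominator) of all CT
    values observed for ``gene`` across conditions and replicates, and the
    stability call: stable iff SD < 1 cycle (strict).
    """
    cts = records.loc[records["gene"] == gene, "ct"].to_numpy(dtype=float)
    if cts.size < 2:
        raise ValueError(f"need at least 2 CT observations for {gene!r}, found {cts.size}")
    sd = float(np.std(cts, ddof=1))
    return sd, sd < 1.0


def expression_test(
    dct_treated: np.ndarray,
    dct_control: np.ndarray,
    alpha: float = 0.05,
) -> tuple[str, float, bool]:
    """Normality-gated two-sample test on dCT groups.

    Shapiro-Wilk is applied to each group; when both pass (p >= 0.05) a
    two-sided Welch t-test is used, otherwise the two-sided Mann-Whitney U
    test.  Groups smaller than 3 cannot be normality-tested and fall back
    to Mann-Whitney with a warning.  Identical constant groups have no
    variance to test and return p = 1.
    """
    a = np.asarray(dct_treated, dtype=float)
    b = np.asarray(dct_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    if a.size < 3 or b.size < 3:
        warnings.warn("group smaller than 3: skipping the normality gate, using Mann-Whitney")
        normal = False
    elif np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return "t_test", 1.0, False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns on near-constant input
            p_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 1.0
            p_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 1.0
        normal = p_a >= 0.05 and p_b >= 0.05

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate (constant) groups
        if normal:
            res = stats.ttest_ind(a, b, equal_var=False)
            test_used = "t_test"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test_used = "mann_whitney"
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return test_used, p, p < alpha


def delta_delta_ct(
    records: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    condition: str,
    control_condition: str = "control",
    timepoint: str | None = None,
    strain: str | None = None,
    alpha: float = 0.05,
) -> ExpressionResult:
    """Relative expression of ``target_gene`` in ``condition`` vs control.

    Per replicate within each condition, dCT = CT(target) - CT(reference);
    ddCT = mean(dCT treated) - mean(dCT control); fold change = 2^(-ddCT).
    The calibrator is the mean control dCT (replicates are not paired
    across conditions).  Any replicate with a target CT but no reference CT
    is an error naming the replicate.
    """
    table = records
    if strain is not None:
        table = table[table["strain"] == strain]
    if timepoint is not None:
        table = table[table["timepoint"] == timepoint]

    def _dct(cond: str) -> np.ndarray:
        sub = table[table["condition"] == cond]
        target = sub[sub["gene"] == target_gene].set_index("replicate")["ct"]
        ref = sub[sub["gene"] == reference_gene].set_index("replicate")["ct"]
        if target.empty:
            raise ValueError(f"no CT observations for {target_gene!r} in condition {cond!r}")
        missing = sorted(set(target.index) - set(ref.index))
        if missing:
            raise ValueError(
                f"missing reference CT for replicate(s) {missing} of condition {cond!r}"
            )
        return (target - ref.loc[target.index]).to_numpy(dtype=float)

    dct_treated = _dct(condition)
    dct_control = _dct(control_condition)
    ddct = float(dct_treated.mean() - dct_control.mean())
    test_used, p, sig = expression_test(dct_treated, dct_control, alpha=alpha)
    return ExpressionResult(
        gene=target_gene,
        condition=condition,
        dct_treated=dct_treated,
        dct_control=dct_control,
        ddct=ddct,
        log2_fold_change=-ddct,
        fold_change=2.0 ** (-ddct),
        test_used=test_used,
        p_value=p,
        significant=sig,
    )


def run_expression_analysis(
    records: pd.DataFrame,
    reference_gene: str,
    control_condition: str = "control",
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """ddCT analysis of every (gene, condition, timepoint) vs control.

    The reference gene must pass the stability screen (SD of CT < 1).
    Returns a tidy results table; ``bh_correction`` optionally applies a
    Benjamini-Hochberg adjustment across all tests (off by default).
    """
    sd, stable = reference_stability(records, reference_gene)
    if not stable:
        raise ValueError(
            f"reference gene {reference_gene!r} is not stable (SD of CT = {sd:.2f} >= 1)"
        )
    genes = [g for g in records["gene"].unique() if g != reference_gene]
    conditions = [c for c in records["condition"].unique() if c != control_condition]
    timepoints = records["timepoint"].unique()
    rows = []
    for gene in genes:
        for cond in conditions:
            for tp in timepoints:
                res = delta_delta_ct(
                    records, gene, reference_gene, cond,
                    control_condition=control_condition, timepoint=tp, alpha=alpha,
                )
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "timepoint": tp,
                        "ddct": res.ddct,
                        "log2_fold_change": res.log2_fold_change,
                        "fold_change": res.fold_change,
                        "test_used": res.test_used,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
    out = pd.DataFrame(rows)
    if bh_correction and not out.empty:
        from statsmodels.stats.multitest import multipletests

        rejected, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
        out["p_adjusted"] = p_adj
        out["significant"] = rejected
    return out
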