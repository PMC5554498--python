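"""Nonparametric group comparisons, laterality predicates and clinical
correlations.

MPI distributions fail normality checks at the cohort sizes of interest, so
group comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney) test --
exact enumeration for small tie-free samples, tie-corrected normal
approximation otherwise -- and correlations use Spearman's rho.

The laterality analysis asks which MPIs separate the affected from the
unaffected hand in patients while staying symmetric in controls.  Patients'
hands are oriented affected/unaffected before pooling left- and
right-affected subgroups; a per-subgroup mode is available.  The default
hand comparison is the *paired* Wilcoxon signed-rank test: hands are paired
within subject, and pairing removes the between-subject amplitude spread
that otherwise swamps the asymmetry signal at realistic per-stage group
sizes.  The unpaired rank-sum variant is available via ``test="unpaired"``.

P-values are reported raw across the 84 MPIs, with an optional
Benjamini-Hochberg flag for the screening lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .data_model import (
    HANDS,
    MPI_NAMES,
    ValidationError,
    parse_mpi_name,
)

__all__ = [
    "TestResult",
    "CorrelationResult",
    "LateralityResult",
    "wilcoxon_ranksum",
    "wilcoxon_signed_rank",
    "ks_normality",
    "spearman",
    "laterality_relevance_pc",
    "laterality_relevance_stages",
    "laterality_table",
    "correlated_mpis",
    "correlation_table",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str = ""


@dataclass
class CorrelationResult:
    mpi_name: str
    scale_name: str
    rho: float
    p_value: float
    n: int = 0


@dataclass
class LateralityResult:
    mpi_base: str  # "<measurement>_<movement>"
    relevant: bool
    evidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Basic tests
# ---------------------------------------------------------------------------

def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when the smaller sample has <= 10 observations and the
    pooled data are tie-free; tie-corrected normal approximation with
    continuity correction otherwise.  The reported statistic is the rank sum
    of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    exact = min(a.size, b.size) <= 10 and not _has_ties(np.concatenate([a, b]))
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    rank_sum = float(res.statistic + a.size * (a.size + 1) / 2)
    return TestResult(statistic=rank_sum, p_value=float(min(res.pvalue, 1.0)),
                      n_a=int(a.size), n_b=int(b.size),
                      method="exact" if exact else "asymptotic")


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test on ``a - b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("paired samples must be non-empty and aligned")
    d = a - b
    if np.all(d == 0):
        return TestResult(statistic=0.0, p_value=1.0, n_a=a.size, n_b=b.size,
                          method="signed-rank")
    exact = a.size <= 25 and not _has_ties(np.abs(d[d != 0]))
    res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox",
                         method="exact" if exact else "approx")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n_a=int(a.size), n_b=int(b.size), method="signed-rank")


def ks_normality(values: Sequence[float]) -> TestResult:
    """Lilliefors-type one-sample KS test against a fitted normal.

    The null-distribution critical values account for the mean and SD being
    estimated from the sample.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValidationError("normality check needs at least 5 observations")
    stat, pval = lilliefors(values, dist="norm", pvalmethod="table")
    return TestResult(statistic=float(stat), p_value=float(pval),
                      n_a=int(values.size), n_b=0, method="lilliefors")


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for tie-free samples (n <= 9)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    denom = n * (n * n - 1) / 6.0
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in permutations(ry):
        d = rx - np.asarray(perm)
        r = 1.0 - np.dot(d, d) / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman(x: Sequence[float], y: Sequence[float],
             mpi: str = "", scale: str = "") -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses exact permutation enumeration for tie-free samples with
    n <= 9 and the t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("correlation needs >= 3 aligned observations")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    tie_free = not _has_ties(x) and not _has_ties(y)
    if x.size <= 9 and tie_free and np.isfinite(rho):
        p = _spearman_exact_p(x, y, rho)
    return CorrelationResult(mpi_name=mpi, scale_name=scale, rho=rho,
                             p_value=float(p), n=int(x.size))


# ---------------------------------------------------------------------------
# Laterality predicates
# ---------------------------------------------------------------------------

def _hand_columns(mpi_base: str) -> tuple[str, str]:
    right = f"{mpi_base}_R"
    left = f"{mpi_base}_L"
    parse_mpi_name(right)  # validates measurement and movement
    return right, left


def _oriented_values(patients: pd.DataFrame, mpi_base: str
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Affected- and unaffected-hand values, oriented per subject."""
    right, left = _hand_columns(mpi_base)
    affected = np.where(patients["affected_side"].to_numpy() == "R",
                        patients[right].to_numpy(), patients[left].to_numpy())
    unaffected = np.where(patients["affected_side"].to_numpy() == "R",
                          patients[left].to_numpy(), patients[right].to_numpy())
    return affected.astype(float), unaffected.astype(float)


def _hand_test(a: np.ndarray, b: np.ndarray, test: str) -> TestResult:
    if test == "paired":
        return wilcoxon_signed_rank(a, b)
    if test == "unpaired":
        return wilcoxon_ranksum(a, b)
    raise ValidationError(f"unknown test {test!r} (use 'paired' or 'unpaired')")


def laterality_relevance_pc(mpi_base: str, cohort: pd.DataFrame,
                            test: Literal["paired", "unpaired"] = "paired",
                            alpha: float = 0.05,
                            mode: Literal["pooled", "per_side"] = "pooled"
                            ) -> LateralityResult:
    """Patients-vs-controls laterality relevance of one MPI.

    True iff (i) the patients' affected-vs-unaffected difference is
    significant at ``alpha`` with the unaffected hand scoring higher, and
    (ii) the controls' left-right difference is *not* significant.  In
    ``per_side`` mode, condition (i) must hold separately in the right- and
    left-affected subgroups.
    """
    right, left = _hand_columns(mpi_base)
    patients = cohort[cohort["group"] == "patient"]
    controls = cohort[cohort["group"] == "control"]
    if len(patients) == 0 or len(controls) == 0:
        raise ValidationError("laterality analysis needs both groups")

    def _patient_condition(sub: pd.DataFrame) -> tuple[bool, dict]:
        aff, unaff = _oriented_values(sub, mpi_base)
        res = _hand_test(unaff, aff, test)
        direction = float(unaff.mean()) > float(aff.mean())
        return (res.p_value < alpha and direction), {
            "p": res.p_value,
            "mean_unaffected": float(unaff.mean()),
            "mean_affected": float(aff.mean()),
            "n": len(sub),
        }

    if mode == "pooled":
        pat_ok, pat_ev = _patient_condition(patients)
        patient_evidence = {"pooled": pat_ev}
    elif mode == "per_side":
        checks = {}
        oks = []
        for side in HANDS:
            sub = patients[patients["affected_side"] == side]
            if len(sub) == 0:
                continue
            ok, ev = _patient_condition(sub)
            checks[side] = ev
            oks.append(ok)
        pat_ok = bool(oks) and all(oks)
        patient_evidence = checks
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    ctl_res = _hand_test(controls[left].to_numpy(), controls[right].to_numpy(), test)
    ctl_ok = ctl_res.p_value > alpha
    return LateralityResult(
        mpi_base=mpi_base,
        relevant=bool(pat_ok and ctl_ok),
        evidence={
            "patients": patient_evidence,
            "controls": {"p": ctl_res.p_value, "n": len(controls)},
            "test": test,
            "mode": mode,
        },
    )


def laterality_relevance_stages(mpi_base: str, cohort: pd.DataFrame,
                                test: Literal["paired", "unpaired"] = "paired",
                                alpha: float = 0.05) -> LateralityResult:
    """Stage-wise laterality relevance of one MPI.

    True iff, in every stage group, the affected-vs-unaffected difference is
    significant with the unaffected hand higher, and across stages 1 -> 3
    (a) the stage means of the subject-level MPI (both hands averaged)
    strictly decrease and (b) the stage means of the within-subject
    unaffected/affected ratio strictly increase.  The ratio isolates the
    asymmetry trend from the overall amplitude decline; absolute differences
    are also reported in the evidence.
    """
    patients = cohort[cohort["group"] == "patient"]
    stages = (1, 2, 3)
    per_stage: dict[int, dict] = {}
    level_means = []
    ratio_means = []
    diff_means = []
    all_sig = True
    for stage in stages:
        sub = patients[patients["hy_stage"] == stage]
        if len(sub) < 2:
            raise ValidationError(
                f"stage {stage} has {len(sub)} subjects; need >= 2 per stage"
            )
        aff, unaff = _oriented_values(sub, mpi_base)
        res = _hand_test(unaff, aff, test)
        direction = float(unaff.mean()) > float(aff.mean())
        sig = res.p_value < alpha and direction
        all_sig = all_sig and sig
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(aff > 0, unaff / aff, np.nan)
        per_stage[stage] = {
            "p": res.p_value,
            "mean_unaffected": float(unaff.mean()),
            "mean_affected": float(aff.mean()),
            "n": len(sub),
            "significant": bool(sig),
        }
        level_means.append(float((aff + unaff).mean() / 2))
        ratio_means.append(float(np.nanmean(ratios)))
        diff_means.append(float((unaff - aff).mean()))
    decreasing = all(a > b for a, b in zip(level_means, level_means[1:]))
    ratio_increasing = all(a < b for a, b in zip(ratio_means, ratio_means[1:]))
    return LateralityResult(
        mpi_base=mpi_base,
        relevant=bool(all_sig and decreasing and ratio_increasing),
        evidence={
            "per_stage": per_stage,
            "stage_level_means": level_means,
            "stage_ratio_means": ratio_means,
            "stage_abs_diff_means": diff_means,
            "levels_decreasing": bool(decreasing),
            "asymmetry_increasing": bool(ratio_increasing),
            "test": test,
        },
    )


def laterality_table(cohort: pd.DataFrame, analysis: str = "pc",
                     test: Literal["paired", "unpaired"] = "paired",
                     alpha: float = 0.05, bh_correct: bool = False
                     ) -> pd.DataFrame:
    """One row per MPI base name with the relevance flag and key evidence."""
    bases = sorted({n.rsplit("_", 1)[0] for n in MPI_NAMES
                    if f"{n.rsplit('_', 1)[0]}_R" in cohort.columns
                    and f"{n.rsplit('_', 1)[0]}_L" in cohort.columns})
    rows = []
    for base in bases:
        if analysis == "pc":
            res = laterality_relevance_pc(base, cohort, test=test, alpha=alpha)
            p = res.evidence["patients"].get("pooled", {}).get("p", np.nan) \
                if "pooled" in res.evidence["patients"] else np.nan
            rows.append({"mpi_base": base, "relevant": res.relevant,
                         "patient_p": p,
                         "control_p": res.evidence["controls"]["p"]})
        elif analysis == "stages":
            res = laterality_relevance_stages(base, cohort, test=test, alpha=alpha)
            rows.append({"mpi_base": base, "relevant": res.relevant,
                         "max_stage_p": max(v["p"] for v in
                                            res.evidence["per_stage"].values()),
                         "levels_decreasing": res.evidence["levels_decreasing"],
                         "asymmetry_increasing": res.evidence["asymmetry_increasing"]})
        else:
            raise ValidationError("analysis must be 'pc' or 'stages'")
    table = pd.DataFrame(rows).set_index("mpi_base")
    if bh_correct and "patient_p" in table.columns:
        rej, adj, _, _ = multipletests(table["patient_p"].fillna(1.0),
                                       alpha=alpha, method="fdr_bh")
        table["patient_p_bh"] = adj
        table["relevant_bh"] = table["relevant"] & rej
    return table


# ---------------------------------------------------------------------------
# Clinical-scale correlations
# ---------------------------------------------------------------------------

_SCALE_DIRECTIONS = {
    "taps_proximal": "positive",
    "taps_distal": "positive",
    "updrs3_total": "negative",
    "updrs3_brady_sub": "negative",
}


def correlated_mpis(cohort: pd.DataFrame, scale: str,
                    direction: Literal["positive", "negative"] | None = None,
                    rho_threshold: float = 0.5, alpha: float = 0.05,
                    bh_correct: bool = False) -> list[str]:
    """MPIs passing the direction-specific (|rho| >= 0.5, p < 0.05) screen.

    Positive direction keeps rho in [threshold, 1] (tapping counts: better
    performance, more taps); negative keeps rho in [-1, -threshold]
    (UPDRS-III: worse impairment, higher score).
    """
    table = correlation_table(cohort, scale, bh_correct=bh_correct)
    direction = direction or _SCALE_DIRECTIONS.get(scale)
    if direction not in ("positive", "negative"):
        raise ValidationError(f"direction needed for scale {scale!r}")
    p_col = "p_value_bh" if bh_correct else "p_value"
    if direction == "positive":
        mask = (table["rho"] >= rho_threshold) & (table[p_col] < alpha)
    else:
        mask = (table["rho"] <= -rho_threshold) & (table[p_col] < alpha)
    return table.index[mask].tolist()


def correlation_table(cohort: pd.DataFrame, scale: str,
                      bh_correct: bool = False) -> pd.DataFrame:
    """Spearman rho and p of every MPI column against one clinical scale."""
    if scale not in cohort.columns:
        raise ValidationError(f"scale column {scale!r} not in cohort table")
    mpi_cols = [c for c in cohort.columns if c in MPI_NAMES]
    if not mpi_cols:
        raise ValidationError("cohort table has no MPI columns")
    y = cohort[scale].to_numpy(dtype=float)
    rows = []
    for col in mpi_cols:
        res = spearman(cohort[col].to_numpy(dtype=float), y, mpi=col, scale=scale)
        rows.append({"mpi_name": col, "rho": res.rho, "p_value": res.p_value,
                     "n": res.n})
    table = pd.DataFrame(rows).set_index("mpi_name")
    if bh_correct:
        _, adj, _, _ = multipletests(table["p_value"], method="fdr_bh")
        table["p_value_bh"] = adj
    return table
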