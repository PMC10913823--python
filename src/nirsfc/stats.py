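"""Group-level inference on Fisher-z connectivity and on the behavioural tables.

One-sample t-tests assess whether connectivity is present in each condition;
paired t-tests compare conditions; both are corrected with Benjamini-Hochberg
FDR over the family of 24 frontal x temporo-parietal ROI pairs (per chromophore
per test).  Behavioural analyses are chi-square tests of independence on 2x2
choice tables (no continuity correction) and paired t-tests on bubble counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .montage import fronto_temporoparietal_pairs
from .simulate import AVATAR_AGE, AVATAR_GENDER


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    df: int
    p_value: float
    n: int
    mean_difference: float | None = None
    identifier: str = ""


def one_sample_t(values: np.ndarray, identifier: str = "") -> StatResult:
    """Classical one-sample t against 0, two-sided."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        raise ValueError(f"one-sample t needs n >= 3, got {n} ({identifier})")
    if np.ptp(x) == 0:
        raise ValueError(f"zero variance in one-sample t ({identifier})")
    t, p = sst.ttest_1samp(x, 0.0)
    return StatResult(test="one_sample_t", statistic=float(t), df=n - 1,
                      p_value=float(p), n=n, mean_difference=float(x.mean()),
                      identifier=identifier)


def paired_t(x: np.ndarray, y: np.ndarray, identifier: str = "") -> StatResult:
    """Paired t on matched samples; mean_difference is mean(x - y) (A minus B)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples differ in length: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    d = x[ok] - y[ok]
    n = len(d)
    if n < 3:
        raise ValueError(f"paired t needs n >= 3 complete pairs, got {n} ({identifier})")
    if np.ptp(d) == 0:
        if d[0] == 0:
            return StatResult(test="paired_t", statistic=0.0, df=n - 1, p_value=1.0,
                              n=n, mean_difference=0.0, identifier=identifier)
        raise ValueError(f"zero variance in paired differences ({identifier})")
    t, p = sst.ttest_rel(x[ok], y[ok])
    return StatResult(test="paired_t", statistic=float(t), df=n - 1, p_value=float(p),
                      n=n, mean_difference=float(d.mean()), identifier=identifier)


@dataclass
class FdrFamily:
    """A family of p-values corrected together by Benjamini-Hochberg at level q.

    For connectivity tests the family is the 24 frontal x temporo-parietal ROI
    pairs (per chromophore per test); the membership is carried explicitly so
    every report can list it.
    """

    pair_ids: list[str]
    p_values: np.ndarray
    q: float = 0.05
    adjusted_p: np.ndarray | None = None
    rejected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.pair_ids) != len(self.p_values):
            raise ValueError("pair_ids and p_values differ in length")
        if len(self.p_values) == 0:
            raise ValueError("empty FDR family")


def bh_fdr(family: FdrFamily) -> FdrFamily:
    """Benjamini-Hochberg step-up over the family, in place of raw thresholds."""
    rejected, adj, _, _ = multipletests(family.p_values, alpha=family.q, method="fdr_bh")
    family.adjusted_p = adj
    family.rejected = rejected
    return family


def connectivity_family_ids(chrom: str, test: str) -> list[str]:
    return [f"{test}:{chrom}:{a}-{b}" for a, b in fronto_temporoparietal_pairs()]


def chi_square_2x2(table: np.ndarray, identifier: str = "") -> StatResult:
    """Pearson chi-square of independence on a 2x2 table, df=1, no continuity
    correction (matching the convention of the behavioural worked examples)."""
    T = np.asarray(table)
    if T.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(T < 0) or not np.issubdtype(T.dtype, np.number):
        raise ValueError("table must hold non-negative counts")
    if T.sum() < 1:
        raise ValueError("empty table")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError(f"zero marginal in 2x2 table ({identifier})")
    chi2, p, dof, _ = sst.chi2_contingency(T, correction=False)
    return StatResult(test="chi_square_2x2", statistic=float(chi2), df=int(dof),
                      p_value=float(p), n=int(T.sum()), identifier=identifier)


def round_half_up_percent(count: int, total: int) -> int:
    """Percentage rounded half-up to an integer (reporting convention)."""
    return int(math.floor(count / total * 100 + 0.5))


@dataclass
class ChoiceTabulation:
    avatar_counts: dict[str, int]
    avatar_percent: dict[str, int]
    n: int
    same_age: int
    same_gender: int
    both_match: int
    either_match: int
    neither_match: int
    tables: dict[str, np.ndarray] = field(default_factory=dict)


def tabulate_choices(behaviour: pd.DataFrame) -> ChoiceTabulation:
    """Counts, percentages and the 2x2 tables consumed by chi_square_2x2.

    Tables (rows x columns):
      gender_vs_avatar_age:      participant gender (male, female) x avatar age (toddler, adult)
      gender_vs_avatar_gender:   participant gender x avatar gender (same, opposite)
      agegroup_vs_avatar_age:    participant age group (younger, older) x avatar age
      agegroup_vs_avatar_gender: participant age group x avatar gender (same, opposite)
    """
    required = {"gender", "age_group", "chosen_avatar"}
    if not required.issubset(behaviour.columns):
        raise ValueError(f"behaviour table needs columns {sorted(required)}")
    unknown = set(behaviour["chosen_avatar"]) - set(AVATAR_AGE)
    if unknown:
        raise ValueError(f"unknown avatar categories: {sorted(unknown)}")

    df = behaviour.copy()
    df["avatar_age"] = df["chosen_avatar"].map(AVATAR_AGE)
    df["avatar_gender"] = df["chosen_avatar"].map(AVATAR_GENDER)
    df["same_gender"] = df["avatar_gender"] == df["gender"]
    df["same_age"] = df["avatar_age"] == "toddler"  # participants are all preschoolers

    n = len(df)
    counts = {a: int((df["chosen_avatar"] == a).sum()) for a in AVATAR_AGE}
    both = int((df["same_gender"] & df["same_age"]).sum())
    either = int((df["same_gender"] ^ df["same_age"]).sum())

    def table(row_col: str, row_vals: tuple[str, str], flag_col: str) -> np.ndarray:
        out = np.zeros((2, 2), dtype=int)
        for i, rv in enumerate(row_vals):
            sub = df[df[row_col] == rv]
            out[i, 0] = int(sub[flag_col].sum())
            out[i, 1] = len(sub) - out[i, 0]
        return out

    tables = {
        "gender_vs_avatar_age": table("gender", ("male", "female"), "same_age"),
        "gender_vs_avatar_gender": table("gender", ("male", "female"), "same_gender"),
        "agegroup_vs_avatar_age": table("age_group", ("younger", "older"), "same_age"),
        "agegroup_vs_avatar_gender": table("age_group", ("younger", "older"), "same_gender"),
    }
    return ChoiceTabulation(
        avatar_counts=counts,
        avatar_percent={a: round_half_up_percent(c, n) for a, c in counts.items()},
        n=n,
        same_age=int(df["same_age"].sum()),
        same_gender=int(df["same_gender"].sum()),
        both_match=both,
        either_match=either,
        neither_match=n - both - either,
        tables=tables,
    )


def stats_to_frame(results: list[StatResult], family: FdrFamily | None = None) -> pd.DataFrame:
    rows = [
        {
            "test": r.test,
            "identifier": r.identifier,
            "statistic": r.statistic,
            "df": r.df,
            "n": r.n,
            "p": r.p_value,
            "mean_difference": r.mean_difference,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if family is not None and family.adjusted_p is not None:
        adj = dict(zip(family.pair_ids, zip(family.adjusted_p, family.rejected)))
        df["p_adjusted"] = [adj.get(i, (np.nan, False))[0] for i in df["identifier"]]
        df["significant"] = [bool(adj.get(i, (np.nan, False))[1]) for i in df["identifier"]]
    return df
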