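"""Relative qPCR quantification and group comparison.

Expression is quantified by the 2^-ddCt method against a reference gene
and a calibrator group; groups are compared by one-way ANOVA and Duncan's
multiple range test, with a compact letter display (groups sharing a
letter are not significantly different at the chosen alpha).

Duncan's test sorts the group means and compares the range of every span
of p ordered means against R_p = q(alpha_p, p, df_error) * sqrt(MSE/n_h),
where alpha_p = 1 - (1-alpha)^(p-1) is the protection level, q the
studentized-range quantile and n_h the harmonic mean group size.  A span
whose range fails R_p protects all its sub-spans from being declared
different (the standard stepwise rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ddct", "anova_oneway", "duncan_mrt", "DuncanResult"]


def ddct(
    records: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """Per-replicate 2^-ddCt fold changes.

    ``records`` columns: group, gene, replicate, ct.  For each target gene,
    dCt(rep) = Ct_target(rep) - mean Ct_ref(group); ddCt subtracts the
    calibrator group's mean dCt; fold = 2^-ddCt.  The calibrator group's
    mean fold is 1 by construction.
    """
    required = {"group", "gene", "replicate", "ct"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    ref = records[records["gene"] == reference_gene]
    targets = records[records["gene"] != reference_gene]
    if ref.empty:
        raise ValueError(f"no records for reference gene {reference_gene!r}")
    ref_means = ref.groupby("group")["ct"].mean()
    rows = []
    for gene, sub in targets.groupby("gene"):
        missing = set(sub["group"]) - set(ref_means.index)
        if missing:
            raise ValueError(
                f"missing reference-gene Ct for group(s) {sorted(missing)}"
            )
        dct = sub["ct"] - sub["group"].map(ref_means)
        cal = dct[sub["group"] == calibrator_group]
        if cal.empty:
            raise ValueError(f"calibrator group {calibrator_group!r} absent for {gene}")
        ddct_vals = dct - cal.mean()
        for (_, rec), d, dd in zip(sub.iterrows(), dct, ddct_vals):
            rows.append(
                {
                    "gene": gene,
                    "group": rec["group"],
                    "replicate": rec["replicate"],
                    "dct": float(d),
                    "ddct": float(dd),
                    "fold": float(2.0 ** -dd),
                }
            )
    return pd.DataFrame(rows)


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA: (F, (df_between, df_within), p).

    All group variances zero with equal means yields F = 0, p = 1 (flagged
    in the log) rather than 0/0.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    N = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, N - k
    if ssw == 0:
        if ssb == 0:
            logger.warning("degenerate ANOVA: zero variance everywhere; p = 1")
            return 0.0, (df1, df2), 1.0
        return math.inf, (df1, df2), 0.0
    F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


# ---------------------------------------------------------------------------
# Duncan's multiple range test

@lru_cache(maxsize=4096)
def _duncan_q(alpha: float, p: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level
    alpha_p = 1 - (1-alpha)^(p-1)."""
    return float(stats.studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df))


@dataclass
class DuncanResult:
    groups: list[str]  # sorted by mean, descending
    means: pd.Series
    significant: pd.DataFrame  # boolean group x group
    letters: dict[str, str]
    mse: float
    df_error: int


def duncan_mrt(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Unequal group sizes are handled through the harmonic mean size.  Two
    groups share a letter exactly when the stepwise procedure does not
    declare them different.
    """
    names = list(groups)
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(names) < 2 or any(len(a) < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    sizes = {g: len(a) for g, a in arrays.items()}
    N, k = sum(sizes.values()), len(names)
    df_error = N - k
    if df_error <= 0:
        raise ValueError("df_error <= 0")
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_error
    n_h = k / sum(1.0 / n for n in sizes.values())
    means = pd.Series({g: a.mean() for g, a in arrays.items()})
    order = list(means.sort_values(ascending=False).index)
    m = means[order].to_numpy()

    # stepwise protected range tests: a span failing its critical range
    # shields every sub-span
    nonsig_spans: list[tuple[int, int]] = []

    def covered(i: int, j: int) -> bool:
        return any(s <= i and j <= e for s, e in nonsig_spans)

    for p in range(k, 1, -1):
        rp = _duncan_q(alpha, p, df_error) * math.sqrt(mse / n_h)
        for i in range(0, k - p + 1):
            j = i + p - 1
            if covered(i, j):
                continue
            if m[i] - m[j] <= rp:
                nonsig_spans.append((i, j))

    sig = pd.DataFrame(False, index=order, columns=order)
    for i in range(k):
        for j in range(i + 1, k):
            s = not covered(i, j)
            sig.iloc[i, j] = sig.iloc[j, i] = s

    # letters: one per maximal non-significant span (interval structure of
    # the protected procedure makes this exact)
    maximal = [
        (s, e)
        for s, e in nonsig_spans
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in nonsig_spans)
    ]
    maximal.sort()
    letter_sets: dict[str, list[str]] = {g: [] for g in order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    li = 0
    in_span = set()
    for s, e in maximal:
        for idx in range(s, e + 1):
            letter_sets[order[idx]].append(alphabet[li])
            in_span.add(idx)
        li += 1
    for idx in range(k):
        if idx not in in_span:
            letter_sets[order[idx]].append(alphabet[li])
            li += 1
    letters = {g: "".join(v) for g, v in letter_sets.items()}
    return DuncanResult(
        groups=order,
        means=means[order],
        significant=sig,
        letters=letters,
        mse=float(mse),
        df_error=df_error,
    )
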