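"""One-way ANOVA, Duncan's multiple range test, and compact letter displays.

Duncan's test ranks the k group means and compares each pair through the
studentized range: a pair whose ordered positions span p means is declared
different when the observed difference exceeds the critical range

    R_p = q(alpha_p, p, df_error) * sqrt(MSE/n),

with Duncan's protection level alpha_p = 1 - (1-alpha)^(p-1).  The usual
step-down rule applies: once a span is found homogeneous, no pair inside
it may be declared different.  Letters are assigned to descending means by
insert-and-absorb, so two groups share a letter iff their comparison is
non-significant.

Only balanced designs (equal replicate counts) are accepted; the classic
protected procedure is defined for them, and the triplicate designs this
package targets are balanced.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupData",
    "AnovaResult",
    "LetterDisplay",
    "one_way_anova",
    "studentized_range_quantile",
    "duncan_mrt",
    "compact_letters",
    "duncan_letters",
]


@dataclass
class GroupData:
    """Labelled replicate measurements for a one-way layout."""

    labels: list
    values: list  # one array-like of replicates per label
    alpha: float = 0.05

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("at least 2 groups are required")
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values length mismatch")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if any(v.size < 2 for v in self.values):
            raise ValueError("each group needs at least 2 replicates")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group: str = "group",
                   value: str = "value", alpha: float = 0.05) -> "GroupData":
        labels = sorted(frame[group].unique().tolist())
        values = [frame.loc[frame[group] == lab, value].to_numpy(dtype=float)
                  for lab in labels]
        return cls(labels=labels, values=values, alpha=alpha)


@dataclass
class AnovaResult:
    mse: float
    df_error: int
    means: np.ndarray
    n_per_group: np.ndarray
    labels: list
    zero_variance: bool = False


@dataclass
class LetterDisplay:
    """Letter strings per label plus the pairwise significance matrix."""

    letters: dict
    significance: pd.DataFrame = field(repr=False, default=None)

    def share_letter(self, a, b) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def one_way_anova(data: GroupData) -> AnovaResult:
    """Within-group mean square and error degrees of freedom.

    The MSE here is the pooled within-group variance that feeds Duncan's
    critical ranges; when every group has zero spread the result is flagged
    (critical ranges collapse to 0).
    """
    ns = np.array([v.size for v in data.values])
    means = np.array([v.mean() for v in data.values])
    sse = float(sum(((v - v.mean()) ** 2).sum() for v in data.values))
    df_error = int(ns.sum() - len(data.values))
    mse = sse / df_error
    return AnovaResult(mse=mse, df_error=df_error, means=means,
                       n_per_group=ns, labels=list(data.labels),
                       zero_variance=sse == 0.0)


def studentized_range_quantile(p: float, k: int, df: float) -> float:
    """Upper-p quantile of the studentized range of k means with df error df.

    Delegates to scipy's studentized_range distribution (CDF by numerical
    integration, quantile by root-finding).  For k = 2 this reduces to
    sqrt(2) times the two-sided t quantile.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if k < 2 or df < 1:
        raise ValueError("need k >= 2 and df >= 1")
    return float(stats.studentized_range.isf(p, k, df))


def duncan_mrt(anova: AnovaResult, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise significance matrix from Duncan's multiple range test.

    Returns a symmetric boolean DataFrame whose rows/columns are the group
    labels ordered by descending mean (ties broken by label order, and
    noted nowhere else: equal means compare as non-significant anyway).
    Requires a balanced design.
    """
    ns = anova.n_per_group
    if np.ptp(ns) != 0:
        raise ValueError("Duncan's test here requires balanced groups")
    n = int(ns[0])
    k = len(anova.labels)
    order = sorted(range(k), key=lambda i: (-anova.means[i], anova.labels[i]))
    means = anova.means[order]
    labels = [anova.labels[i] for i in order]
    sem = float(np.sqrt(anova.mse / n))

    sig = np.zeros((k, k), dtype=bool)
    homogeneous: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        r_crit = (studentized_range_quantile(alpha_p, span, anova.df_error) * sem
                  if sem > 0 else 0.0)
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(ci <= i and j <= cj for ci, cj in homogeneous):
                continue
            if means[i] - means[j] > r_crit:
                sig[i, j] = sig[j, i] = True
            else:
                homogeneous.append((i, j))
    return pd.DataFrame(sig, index=labels, columns=labels)


def compact_letters(sig: pd.DataFrame) -> LetterDisplay:
    """Insert-and-absorb compact letter display.

    ``sig`` must be a symmetric boolean matrix ordered by descending mean
    (as produced by :func:`duncan_mrt`); True marks a significant pair.
    Two groups share a letter iff their comparison is non-significant.
    """
    mat = sig.to_numpy(dtype=bool)
    if mat.shape[0] != mat.shape[1] or not np.array_equal(mat, mat.T):
        raise ValueError("significance matrix must be square and symmetric")
    labels = list(sig.index)
    k = len(labels)
    columns: list[set] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not mat[i, j]:
                continue
            new_cols = []
            for col in columns:
                if i in col and j in col:
                    new_cols.append(col - {i})
                    new_cols.append(col - {j})
                else:
                    new_cols.append(col)
            # absorb: drop columns contained in another
            columns = [c for c in new_cols
                       if c and not any(c < d for d in new_cols)]
            # drop exact duplicates, order-preserving
            uniq = []
            for c in columns:
                if c not in uniq:
                    uniq.append(c)
            columns = uniq
    # letter per column, ordered by the smallest (highest-mean) member
    columns.sort(key=lambda c: sorted(c))
    alphabet = string.ascii_lowercase
    names = [alphabet[i % 26] * (i // 26 + 1) for i in range(len(columns))]
    letters = {
        lab: "".join(names[c] for c, col in enumerate(columns) if i in col)
        for i, lab in enumerate(labels)
    }
    return LetterDisplay(letters=letters, significance=sig)


def duncan_letters(data: GroupData, alpha: float | None = None,
                   *, uppercase: bool = False) -> LetterDisplay:
    """Convenience: ANOVA → Duncan's MRT → compact letters in one call.

    ``uppercase=True`` emits capital letters — the usual figure convention
    when the factor compared is the enzyme rather than the substrate (the
    two factors are handled as two independent one-way analyses).
    """
    anova = one_way_anova(data)
    sig = duncan_mrt(anova, alpha if alpha is not None else data.alpha)
    disp = compact_letters(sig)
    if uppercase:
        disp = LetterDisplay(
            letters={k: v.upper() for k, v in disp.letters.items()},
            significance=disp.significance)
    return disp
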