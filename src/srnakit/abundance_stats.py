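"""Tag-count differential expression statistic for unreplicated sRNA libraries.

Two libraries are compared one tag (or feature) at a time.  Under the null
hypothesis that a tag is equally expressed in both libraries, the count ``y``
observed in the treatment library, conditional on the count ``x`` observed in
the control library and on the library depths ``N1`` (control) and ``N2``
(treatment), follows

    p(y | x) = (N2/N1)**y * (x + y)! / (x! * y!) / (1 + N2/N1)**(x + y + 1)

the negative-binomial form of the classical tag-count test for comparing two
sequencing libraries (Audic & Claverie, Genome Res 1997).  A two-tailed
p-value is obtained by accumulating q = sum_{y'<=y} p(y'|x) and doubling the
smaller tail: p = 2q if q <= 0.5, else p = 2(1 - q), clipped to [0, 1].

Expression values are normalized to reads-per-15-million:
``count / clean_total * 15_000_000``.  A tag is called *up* when the log2
ratio of normalized treatment over control exceeds 1 with p < 0.05, *down*
when it is below -1 with p < 0.05, and *equal* otherwise (strict inequalities
on both thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln
from statsmodels.stats.multitest import multipletests

SCALE = 15_000_000

LOG2_CUTOFF = 1.0
P_CUTOFF = 0.05


def normalize(count: float, clean_total: int, scale: int = SCALE) -> float:
    """Normalize a raw tag count to reads-per-``scale`` (default 15 million).

    Parameters
    ----------
    count : raw tag count in the library.
    clean_total : total clean reads of the library (must be positive).
    """
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    return count / clean_total * scale


def log_ac_probability(x: int, y: int, n1: int, n2: int) -> float:
    """Natural log of p(y|x); evaluated with log-gamma so it stays finite
    for counts up to at least 1e7."""
    _check_counts(x, y, n1, n2)
    log_r = math.log(n2) - math.log(n1)
    # log(1 + r) computed stably for extreme depth ratios
    log_1pr = np.logaddexp(0.0, log_r)
    return (
        y * log_r
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log_1pr
    )


def ac_probability(x: int, y: int, n1: int, n2: int) -> float:
    """Conditional null probability p(y|x) of seeing y treatment counts given
    x control counts, with library depths n1 (control) and n2 (treatment)."""
    return float(math.exp(log_ac_probability(x, y, n1, n2)))


def _check_counts(x: int, y: int, n1: int, n2: int) -> None:
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")


def cumulative_probability(x: int, y: int, n1: int, n2: int) -> float:
    """q = sum_{y'=0}^{y} p(y'|x).

    p(.|x) is a negative binomial with x+1 "successes" of probability
    N1/(N1+N2), so the cumulative is the regularized incomplete beta
    I_{N1/(N1+N2)}(x+1, y+1); this keeps the tail sum exact and O(1) even
    for multi-million read counts.
    """
    _check_counts(x, y, n1, n2)
    return float(betainc(x + 1, y + 1, n1 / (n1 + n2)))


def two_tailed_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-tailed p-value: p = 2q for q <= 0.5, else 2(1-q), clipped to [0,1].

    The doubling can exceed 1 when y sits at the mode of p(.|x); the result
    is clipped so the probability contract holds.
    """
    q = cumulative_probability(x, y, n1, n2)
    p = 2 * q if q <= 0.5 else 2 * (1 - q)
    return min(max(p, 0.0), 1.0)


@dataclass
class DiffExprResult:
    """Outcome of the two-library test for one feature.

    ``log2_ratio`` is computed on per-15M normalized values; when exactly one
    of the two counts is zero it is replaced by half a read (0.5) for the
    ratio only — the p-value always uses the raw counts.
    """

    feature_id: str
    x: int
    y: int
    n1: int
    n2: int
    normalized_control: float = field(init=False)
    normalized_treatment: float = field(init=False)
    log2_ratio: float = field(init=False)
    p_two_tailed: float = field(init=False)
    call: str = field(init=False)

    def __post_init__(self) -> None:
        _check_counts(self.x, self.y, self.n1, self.n2)
        self.normalized_control = normalize(self.x, self.n1)
        self.normalized_treatment = normalize(self.y, self.n2)
        if self.x == 0 and self.y == 0:
            self.log2_ratio = 0.0
            self.p_two_tailed = 1.0
            self.call = "equal"
            return
        num = self.normalized_treatment or normalize(0.5, self.n2)
        den = self.normalized_control or normalize(0.5, self.n1)
        self.log2_ratio = math.log2(num / den)
        self.p_two_tailed = two_tailed_p(self.x, self.y, self.n1, self.n2)
        if self.log2_ratio > LOG2_CUTOFF and self.p_two_tailed < P_CUTOFF:
            self.call = "up"
        elif self.log2_ratio < -LOG2_CUTOFF and self.p_two_tailed < P_CUTOFF:
            self.call = "down"
        else:
            self.call = "equal"


def classify_de(x: int, y: int, n1: int, n2: int, feature_id: str = "") -> DiffExprResult:
    """Run the full test for one feature and classify it up/equal/down."""
    return DiffExprResult(feature_id=feature_id, x=x, y=y, n1=n1, n2=n2)


def de_table(
    counts: pd.DataFrame,
    control: str,
    treatment: str,
    n1: int,
    n2: int,
) -> pd.DataFrame:
    """Test every row of a per-feature count table.

    Parameters
    ----------
    counts : DataFrame indexed by feature id with one column per library.
    control, treatment : column names of the two libraries to compare.
    n1, n2 : clean-read totals of the control and treatment libraries.

    Returns a DataFrame with columns (id, x, y, N1, N2, norm_x, norm_y,
    log2fc, p, bh_fdr, call).  The Benjamini–Hochberg column is reported for
    transparency; calls use the raw p < 0.05 threshold.
    """
    rows = []
    for feature_id, row in counts.iterrows():
        r = classify_de(int(row[control]), int(row[treatment]), n1, n2, str(feature_id))
        rows.append(
            {
                "id": r.feature_id,
                "x": r.x,
                "y": r.y,
                "N1": r.n1,
                "N2": r.n2,
                "norm_x": r.normalized_control,
                "norm_y": r.normalized_treatment,
                "log2fc": r.log2_ratio,
                "p": r.p_two_tailed,
                "call": r.call,
            }
        )
    columns = ["id", "x", "y", "N1", "N2", "norm_x", "norm_y", "log2fc", "p", "bh_fdr", "call"]
    if not rows:
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows)
    out["bh_fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[columns]


def fold_change_percent(treatment_signal: float, control_signal: float) -> int:
    """Expression ratio as an integer percent, rounded half away from zero.

    Used for microarray-style worked examples where signals are compared as
    ``100 * treatment / control``.
    """
    if control_signal <= 0:
        raise ValueError("control signal must be positive")
    ratio = 100.0 * treatment_signal / control_signal
    return int(math.floor(ratio + 0.5)) if ratio >= 0 else -int(math.floor(-ratio + 0.5))
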