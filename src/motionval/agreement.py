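"""Method-comparison statistics: Bland-Altman agreement and repeatability.

When two instruments both estimate an unobservable true quantity (here a
joint angle read by a manual goniometer and by a camera-based pipeline),
correlation says little; *agreement* is the question.  The Bland-Altman
construction summarises the per-pair differences d = a - b by their mean
(the bias) and the 95% limits of agreement

    lower = mean(d) - 1.96 sd(d),   upper = mean(d) + 1.96 sd(d)

between which ~95% of future differences are expected when d is roughly
Gaussian.  Test-retest *repeatability* applies the same construction to the
session differences u = session1 - session2 of a single method and adds the
coefficient of repeatability

    CR = sqrt( sum(u^2) / n )

the root-mean-square session difference, below which 95% of repeat
differences are expected (British Standards convention: |u| < 2 sd).

The module follows the statsmodels idiom: a model object is built from the
paired data and ``fit()`` returns a results object carrying estimates,
limits, counts, a ``summary()`` table and plot support.  Conventions fixed
here: differences are first argument minus second argument; the sd of
differences uses the sample (n-1) denominator while CR keeps n; boundary
points count as within the limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PairedMeasurements",
    "BlandAltman",
    "AgreementResult",
    "Repeatability",
    "RepeatabilityResult",
    "bland_altman",
    "repeatability",
    "agreement_report",
]

Z_LIMIT = 1.96


@dataclass
class PairedMeasurements:
    """Matched scalar readings from two methods (or two sessions).

    ``diff`` is ``a - b`` and ``pair_mean`` is ``(a + b) / 2``, the axes of a
    Bland-Altman plot.  ``subject`` is an optional id per pair.
    """

    a: np.ndarray
    b: np.ndarray
    subject: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.ndim != 1 or self.a.shape != self.b.shape:
            raise ValueError("a and b must be 1-D arrays of equal length")
        if self.a.size < 2:
            raise ValueError(f"need at least 2 pairs, got {self.a.size}")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("measurements must be finite")
        if self.subject is not None:
            self.subject = np.asarray(self.subject)
            if self.subject.shape != self.a.shape:
                raise ValueError("subject ids must match the number of pairs")

    @property
    def n(self) -> int:
        return int(self.a.size)

    @property
    def diff(self) -> np.ndarray:
        return self.a - self.b

    @property
    def pair_mean(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, a: str = "a", b: str = "b", subject: str = "subject"
    ) -> "PairedMeasurements":
        subj = df[subject].to_numpy() if subject in df.columns else None
        return cls(df[a].to_numpy(float), df[b].to_numpy(float), subject=subj)

    def to_dataframe(self, a: str = "a", b: str = "b") -> pd.DataFrame:
        cols = {
            "subject": self.subject
            if self.subject is not None
            else np.arange(self.n, dtype=int),
            a: self.a,
            b: self.b,
        }
        return pd.DataFrame(cols)


def _fraction_within(d: np.ndarray, lower: float, upper: float) -> tuple[int, float]:
    # boundary values count as within
    outside = int(np.count_nonzero((d < lower) | (d > upper)))
    return outside, 1.0 - outside / d.size


def _summary_table(title: str, rows: list[tuple[str, str]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    bar = "=" * (width + 14)
    lines = [title.center(width + 14), bar]
    lines += [f"{k:<{width}}{v:>12}" for k, v in rows]
    lines.append(bar)
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# agreement between two methods


class BlandAltman:
    """Bland-Altman agreement model for two measurement methods.

    Differences are taken as ``a - b`` (first method minus second).
    """

    def __init__(self, a, b=None, subject=None) -> None:
        if isinstance(a, PairedMeasurements):
            if b is not None:
                raise ValueError("pass either a PairedMeasurements or two arrays")
            self.pairs = a
        else:
            self.pairs = PairedMeasurements(a, b, subject=subject)

    @classmethod
    def from_pairs(cls, pairs: PairedMeasurements) -> "BlandAltman":
        obj = cls.__new__(cls)
        obj.pairs = pairs
        return obj

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, a: str = "a", b: str = "b") -> "BlandAltman":
        return cls.from_pairs(PairedMeasurements.from_dataframe(df, a=a, b=b))

    def fit(self) -> "AgreementResult":
        d = self.pairs.diff
        mean_diff = float(d.mean())
        sd_diff = float(d.std(ddof=1))
        lower = mean_diff - Z_LIMIT * sd_diff
        upper = mean_diff + Z_LIMIT * sd_diff
        n_outside, frac = _fraction_within(d, lower, upper)
        return AgreementResult(
            mean_diff=mean_diff,
            sd_diff=sd_diff,
            lower=lower,
            upper=upper,
            n=self.pairs.n,
            n_outside=n_outside,
            fraction_within=frac,
            pair_mean=self.pairs.pair_mean,
            diff=d,
        )


@dataclass
class AgreementResult:
    """Bias, dispersion and 95% limits of agreement between two methods."""

    mean_diff: float
    sd_diff: float
    lower: float
    upper: float
    n: int
    n_outside: int
    fraction_within: float
    pair_mean: np.ndarray = field(repr=False)
    diff: np.ndarray = field(repr=False)

    diff_direction: str = "a_minus_b"

    def summary(self) -> str:
        return _summary_table(
            "Bland-Altman agreement",
            [
                ("n pairs", f"{self.n}"),
                ("mean diff (deg)", f"{self.mean_diff:.4f}"),
                ("sd diff (deg)", f"{self.sd_diff:.4f}"),
                ("lower limit", f"{self.lower:.4f}"),
                ("upper limit", f"{self.upper:.4f}"),
                ("outside limits", f"{self.n_outside}"),
                ("fraction within", f"{self.fraction_within:.4f}"),
            ],
        )

    def to_report(self) -> dict:
        return {
            "kind": "agreement",
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "lower": self.lower,
            "upper": self.upper,
            "n_outside": self.n_outside,
            "fraction_within": self.fraction_within,
            "diff_direction": self.diff_direction,
            "pair_mean": [float(v) for v in self.pair_mean],
            "diff": [float(v) for v in self.diff],
        }

    def plot(self, ax=None):
        """Bland-Altman scatter: solid mean line, dashed limit lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.pair_mean, self.diff, s=12, alpha=0.7)
        ax.axhline(self.mean_diff, color="k", linestyle="-", label="mean diff")
        ax.axhline(self.lower, color="k", linestyle="--", label="95% limits")
        ax.axhline(self.upper, color="k", linestyle="--")
        ax.set_xlabel("pair mean (deg)")
        ax.set_ylabel("difference (deg)")
        ax.legend(loc="best")
        return ax


# ---------------------------------------------------------------------------
# test-retest repeatability


class Repeatability:
    """Repeatability model for one method measured in two sessions.

    ``reference`` (degrees, > 0) is the range against which CR is expressed
    as a percentage -- typically the protocol's nominal angle (90 deg for a
    90-degree flexion task).
    """

    def __init__(self, session1, session2, reference: float = 90.0) -> None:
        s1 = np.asarray(session1, dtype=float)
        s2 = np.asarray(session2, dtype=float)
        if s1.ndim != 1 or s1.shape != s2.shape:
            raise ValueError("session1 and session2 must be 1-D arrays of equal length")
        if s1.size < 2:
            raise ValueError(f"need at least 2 subjects, got {s1.size}")
        if not reference > 0:
            raise ValueError(f"reference must be positive, got {reference}")
        self.session1 = s1
        self.session2 = s2
        self.reference = float(reference)

    def fit(self) -> "RepeatabilityResult":
        u = self.session1 - self.session2
        mean_u = float(u.mean())
        sd_u = float(u.std(ddof=1))
        lower = mean_u - Z_LIMIT * sd_u
        upper = mean_u + Z_LIMIT * sd_u
        n_outside, frac = _fraction_within(u, lower, upper)
        cr = float(np.sqrt(np.mean(u**2)))
        return RepeatabilityResult(
            mean_u=mean_u,
            sd_u=sd_u,
            lower=lower,
            upper=upper,
            cr=cr,
            cr_percent=100.0 * cr / self.reference,
            reference=self.reference,
            n=u.size,
            n_outside=n_outside,
            fraction_within=frac,
            u=u,
            session_mean=0.5 * (self.session1 + self.session2),
        )


@dataclass
class RepeatabilityResult:
    """Session-difference limits and coefficient of repeatability."""

    mean_u: float
    sd_u: float
    lower: float
    upper: float
    cr: float
    cr_percent: float
    reference: float
    n: int
    n_outside: int
    fraction_within: float
    u: np.ndarray = field(repr=False)
    session_mean: np.ndarray = field(repr=False)

    diff_direction: str = "session1_minus_session2"

    def summary(self) -> str:
        return _summary_table(
            "Repeatability (two sessions)",
            [
                ("n subjects", f"{self.n}"),
                ("mean u (deg)", f"{self.mean_u:.4f}"),
                ("sd u (deg)", f"{self.sd_u:.4f}"),
                ("lower limit", f"{self.lower:.4f}"),
                ("upper limit", f"{self.upper:.4f}"),
                ("CR (deg)", f"{self.cr:.4f}"),
                ("CR (% of ref)", f"{self.cr_percent:.4f}"),
                ("outside limits", f"{self.n_outside}"),
            ],
        )

    def to_report(self) -> dict:
        return {
            "kind": "repeatability",
            "n": self.n,
            "mean_u": self.mean_u,
            "sd_u": self.sd_u,
            "lower": self.lower,
            "upper": self.upper,
            "cr": self.cr,
            "cr_percent": self.cr_percent,
            "reference": self.reference,
            "n_outside": self.n_outside,
            "fraction_within": self.fraction_within,
            "diff_direction": self.diff_direction,
            "pair_mean": [float(v) for v in self.session_mean],
            "diff": [float(v) for v in self.u],
        }

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.session_mean, self.u, s=12, alpha=0.7)
        ax.axhline(self.mean_u, color="k", linestyle="-", label="mean u")
        ax.axhline(self.lower, color="k", linestyle="--", label="95% limits")
        ax.axhline(self.upper, color="k", linestyle="--")
        ax.set_xlabel("session mean (deg)")
        ax.set_ylabel("session difference (deg)")
        ax.legend(loc="best")
        return ax


# ---------------------------------------------------------------------------
# functional surface


def bland_altman(pairs: PairedMeasurements) -> AgreementResult:
    """Bland-Altman agreement of paired measurements (``a - b`` differences)."""
    return BlandAltman.from_pairs(pairs).fit()


def repeatability(session1, session2, reference: float = 90.0) -> RepeatabilityResult:
    """Repeatability limits and CR from two measurement sessions."""
    return Repeatability(session1, session2, reference=reference).fit()


def agreement_report(result) -> dict:
    """JSON-serialisable report for an agreement or repeatability result.

    Keys with empty optional values are omitted, never null-padded.
    """
    rep = result.to_report()
    return {k: v for k, v in rep.items() if v is not None}
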