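"""Correlation-based scoring and psychometric evaluation.

Optotype Correlation (OC) measures how good a wrong guess is: the peak
normalized cross-correlation between the undistorted letter images of the
displayed and guessed characters, linearly transformed so that correct
identifications score exactly 1 and the expected score of a random guess
equals 1/26.  Averaging OC over the guess set of a single presentation,
and then over all 26 letters of one size, yields the Rate of Recognition
RR — a graded generalization of recognition probability.

The psychometric function RR(s) over letter size s (logMAR) is fitted
with a transformed two-parameter logistic whose asymptotes are the chance
level 1/26 and 1; visual acuity V is the size at which the fitted curve
crosses the calibrated threshold RR0 = 0.68.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .optotypes import LETTERS, render_letter
from .recognition import pearson_peak

#: Calibrated Rate-of-Recognition threshold defining the acuity value.
RR0_DEFAULT = 0.68
#: Chance level with a 26-letter response set.
CHANCE = 1.0 / 26.0
#: Reference letter size (logMAR) at which the OC raw correlations are
#: computed; normalized correlation makes the choice weakly influential.
OC_REFERENCE_SIZE = 0.3


@dataclass(frozen=True)
class OCMatrix:
    """26 x 26 Optotype Correlation table, entry (displayed, guessed)."""

    values: np.ndarray
    letters: tuple[str, ...] = LETTERS

    def __getitem__(self, pair: tuple[str, str]) -> float:
        d, g = pair
        return float(self.values[self.letters.index(d), self.letters.index(g)])

    def to_dataframe(self):
        """Labeled table (rows: displayed, columns: guessed)."""
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.letters),
                            columns=list(self.letters))


def _ink_crop(ii: np.ndarray, margin: int = 2) -> np.ndarray:
    rows = np.flatnonzero((ii < 0.5).any(axis=1))
    cols = np.flatnonzero((ii < 0.5).any(axis=0))
    r0, r1 = rows[0] - margin, rows[-1] + margin + 1
    c0, c1 = cols[0] - margin, cols[-1] + margin + 1
    return ii[r0:r1, c0:c1]


def oc_matrix(reference_size: float = OC_REFERENCE_SIZE,
              include_identical_pairs: bool = True) -> OCMatrix:
    """Optotype Correlation matrix from the undistorted letter images.

    Raw similarity c(p, q) is the Pearson correlation peak between the
    ideal binary images of p and q; OC = A*c + B with A and B solved so
    the diagonal maps to exactly 1 and the mean over letter pairs equals
    1/26.  With ``include_identical_pairs`` the expectation is over
    uniform independent draws of both letters (identical pairs included);
    otherwise over distinct ordered pairs.
    """
    crops = [_ink_crop(render_letter(ch, reference_size).values) for ch in LETTERS]
    n = len(LETTERS)
    raw = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw[i, j] = raw[j, i] = pearson_peak(crops[i], crops[j])
    if include_identical_pairs:
        mean_raw = raw.mean()
    else:
        off = ~np.eye(n, dtype=bool)
        mean_raw = raw[off].mean()
    target_mean = CHANCE
    if abs(1.0 - mean_raw) < 1e-12:
        raise ValueError("degenerate letter set: all pairs fully correlated")
    a = (1.0 - target_mean) / (1.0 - mean_raw)
    b = 1.0 - a
    oc = a * raw + b
    np.fill_diagonal(oc, 1.0)
    return OCMatrix(oc)


def score_letter(displayed: str, guesses, oc: OCMatrix) -> float:
    """Mean OC of the displayed letter against every guess in the
    discrimination set (the subject's hesitation average)."""
    guesses = tuple(guesses)
    if not guesses:
        raise ValueError("guess set must be non-empty")
    return float(np.mean([oc[displayed, g] for g in guesses]))


def rate_of_recognition(scores) -> float:
    """RR at one size: the mean per-letter OC score."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one score")
    return float(scores.mean())


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted transformed logistic and the acuity it implies."""

    k: float        # steepness, 1/logMAR
    s_mp: float     # midpoint, logMAR
    rr0: float
    acuity: float   # V, logMAR

    def curve(self, s: np.ndarray) -> np.ndarray:
        return logistic_rr(np.asarray(s, dtype=float), self.k, self.s_mp)


def logistic_rr(s: np.ndarray, k: float, s_mp: float) -> np.ndarray:
    """Transformed logistic psychometric curve with asymptotes 1/26 and 1,
    increasing with letter size s."""
    return (1.0 - CHANCE) / (1.0 + np.exp(-4.0 * k * (s - s_mp))) + CHANCE


def invert_logistic(k: float, s_mp: float, rr0: float) -> float:
    """Letter size s0 with L(s0) = rr0 (closed form)."""
    if not CHANCE < rr0 < 1.0:
        raise ValueError(f"threshold {rr0} outside (1/26, 1)")
    q = (rr0 - CHANCE) / (1.0 - CHANCE)
    return s_mp - np.log(1.0 / q - 1.0) / (4.0 * k)


def fit_psychometric(sizes, rr, rr0: float = RR0_DEFAULT) -> PsychometricFit:
    """Least-squares logistic regression of RR against letter size.

    Initialization: s_mp at the tested size whose RR is nearest the
    threshold, k = 4 /logMAR; k bounded to (0.1, 50).  The acuity is the
    closed-form inversion of the fitted curve at ``rr0``; if the data do
    not bracket the threshold the inversion extrapolates (with a warning).
    """
    s = np.asarray(sizes, dtype=float)
    y = np.asarray(rr, dtype=float)
    if s.size < 4:
        raise ValueError("psychometric fit needs at least 4 points")
    order = np.argsort(s)
    s, y = s[order], y[order]
    s_mp0 = float(s[np.argmin(np.abs(y - rr0))])
    try:
        popt, _ = curve_fit(logistic_rr, s, y, p0=(4.0, s_mp0),
                            bounds=((0.1, s.min() - 2.0), (50.0, s.max() + 2.0)),
                            maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"psychometric fit did not converge: {err}") from err
    k, s_mp = map(float, popt)
    if not (y.min() <= rr0 <= y.max()):
        warnings.warn("measured RR values do not bracket the threshold; "
                      "acuity is extrapolated", stacklevel=2)
    acuity = float(invert_logistic(k, s_mp, rr0))
    return PsychometricFit(k, s_mp, rr0, acuity)


def acuity_probability_scored(sizes, p_correct, p0: float = 0.5) -> float:
    """Comparison mode: threshold the recognition-probability curve at the
    conventional 50% level instead of the correlation-based RR0."""
    fit = fit_psychometric(sizes, p_correct, rr0=p0)
    return fit.acuity
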