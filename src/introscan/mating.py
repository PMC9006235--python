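"""Statistics for no-choice and two-choice mating assays.

No-choice assays pair one male and one female per vial and count
successful copulations out of a fixed number of vials; each heterogamic
cross is compared against the homogamic *D. yakuba* success rate (17 of
20 by convention here) with a goodness-of-fit chi-squared test.
Two-choice assays give a focal fly a homogamic and a heterogamic partner
simultaneously; the 2x2 table of focal strain by chosen mate strain is
tested for assortative mating (homogamy) with Fisher's exact test.

Significance stars follow the usual cutpoints: * p<.05, ** p<.01,
*** p<.001.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

DEFAULT_REF_SUCCESSES = 17
DEFAULT_REF_TRIALS = 20

STAR_CUTPOINTS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars for a p value ('ns' above .05)."""
    for cut, mark in STAR_CUTPOINTS:
        if p < cut:
            return mark
    return "ns"


@dataclass(frozen=True)
class NoChoiceResult:
    observed_successes: int
    trials: int
    ref_successes: int
    ref_trials: int
    chi2: float
    p: float
    stars: str


@dataclass(frozen=True)
class TwoChoiceResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p: float
    stars: str


def nochoice_test(
    successes: int,
    trials: int,
    ref_successes: int = DEFAULT_REF_SUCCESSES,
    ref_trials: int = DEFAULT_REF_TRIALS,
) -> NoChoiceResult:
    """Goodness-of-fit chi-squared of a cross's success count vs a reference.

    Observed (successes, failures) is compared with expected proportions
    (ref_successes/ref_trials, 1 - ...) scaled to ``trials``; df = 1, no
    continuity correction (matching R's ``chisq.test`` goodness-of-fit
    path).

    Raises
    ------
    ValueError
        If trials <= 0, successes out of range, or an expected cell is 0.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not (0 <= successes <= trials):
        raise ValueError(f"successes {successes} outside 0..{trials}")
    p_ref = ref_successes / ref_trials
    expected = (trials * p_ref, trials * (1.0 - p_ref))
    if min(expected) == 0:
        raise ValueError("expected cell is zero; reference proportion degenerate")
    chi2, p = stats.chisquare(
        f_obs=[successes, trials - successes], f_exp=list(expected)
    )
    return NoChoiceResult(
        successes, trials, ref_successes, ref_trials, float(chi2), float(p), stars(p)
    )


def twochoice_fisher(
    homogamic_by_focal_a: tuple[int, int],
    homogamic_by_focal_b: tuple[int, int],
) -> TwoChoiceResult:
    """Two-sided Fisher exact test for homogamy in a two-choice assay.

    Rows are the focal strains, columns the chosen mate's strain:
    ``homogamic_by_focal_a = (chose A, chose B)`` for focal strain A, and
    likewise for focal strain B. Under random mating the rows are
    exchangeable; assortative mating concentrates counts on the diagonal.

    Raises
    ------
    ValueError
        On negative counts or an all-zero table.
    """
    table = (tuple(homogamic_by_focal_a), tuple(homogamic_by_focal_b))
    flat = [c for row in table for c in row]
    if any(c < 0 for c in flat):
        raise ValueError("counts must be non-negative")
    if sum(flat) == 0:
        raise ValueError("all-zero table: no copulations observed")
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return TwoChoiceResult(table, p, stars(p))


def twochoice_chi2(
    homogamic_by_focal_a: tuple[int, int],
    homogamic_by_focal_b: tuple[int, int],
) -> TwoChoiceResult:
    """Chi-squared alternative to :func:`twochoice_fisher` (no correction).

    Retained because the assay can also be analysed as a contingency
    chi-squared; Fisher's exact test is the default reported statistic.
    """
    table = (tuple(homogamic_by_focal_a), tuple(homogamic_by_focal_b))
    if sum(c for row in table for c in row) == 0:
        raise ValueError("all-zero table: no copulations observed")
    res = stats.chi2_contingency(table, correction=False)
    return TwoChoiceResult(table, float(res.pvalue), stars(res.pvalue))
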