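"""Abdominal pigmentation scores: data model, PCA trajectories, group tests.

Pigmentation is scored visually per tergite in 11 ordinal classes, 0 (no
black pigment) to 10 (tergite completely black). Six successive abdominal
segments are analysed per individual — tergites 2-7 plus the epigynium
(tergite 8) in females, tergites 2-6 plus the epandrium (tergite 9) in
males — aligned positionally so both sexes contribute six columns to a
combined PCA. PCA coordinates summarise each strain-by-year sample's
position between the light and dark parental species; two-sample t tests
on sums of posterior segments quantify specific contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

N_SEGMENTS = 6
MAX_CLASS = 10

SEGMENT_COLUMNS = [f"seg{i}" for i in range(1, N_SEGMENTS + 1)]


@dataclass(frozen=True)
class PigmentationRecord:
    """One individual's six ordered segment scores (classes 0-10)."""

    individual: str
    strain: str
    sex: str  # "F" or "M"
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if len(self.scores) != N_SEGMENTS:
            raise ValueError(
                f"{self.individual}: expected {N_SEGMENTS} segment scores, "
                f"got {len(self.scores)}"
            )
        for s in self.scores:
            if not (0 <= s <= MAX_CLASS and float(s).is_integer()):
                raise ValueError(
                    f"{self.individual}: score {s} outside classes 0-{MAX_CLASS}"
                )


@dataclass
class PcaResult:
    """PCA of the individuals-by-segments score matrix.

    ``variance_explained`` is in percent and sums to 100 over all
    components; ``coordinates`` has one row per individual;
    ``loading_correlations[k, j]`` is the Pearson r between component k
    scores and segment j.
    """

    variance_explained: np.ndarray
    coordinates: np.ndarray
    loading_correlations: np.ndarray
    mode: str  # "covariance" or "correlation"


def read_scores(stream: IO[str] | str) -> list[PigmentationRecord]:
    """Read a wide TSV/CSV of scores into validated records.

    Expected columns: ``individual``, ``strain``, ``sex``, and
    ``seg1``..``seg6`` (the six analysis segments, anterior to ultimate).
    Delimiter is sniffed from the header (tab preferred).

    Raises
    ------
    ValueError
        On missing columns or any score outside classes 0-10, naming the
        offending row.
    """
    df = pd.read_csv(stream, sep=None, engine="python")
    required = ["individual", "strain", "sex"] + SEGMENT_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"score table lacks columns: {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            rec = PigmentationRecord(
                individual=str(row["individual"]),
                strain=str(row["strain"]),
                sex=str(row["sex"]),
                scores=tuple(int(row[c]) for c in SEGMENT_COLUMNS),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {row['individual']!r}: {exc}") from exc
        records.append(rec)
    return records


def write_scores(records: Iterable[PigmentationRecord], stream: IO[str]) -> None:
    """Write records as the wide TSV dialect read by :func:`read_scores`."""
    stream.write("individual\tstrain\tsex\t" + "\t".join(SEGMENT_COLUMNS) + "\n")
    for r in records:
        stream.write(
            f"{r.individual}\t{r.strain}\t{r.sex}\t"
            + "\t".join(str(s) for s in r.scores)
            + "\n"
        )


def score_matrix(records: Sequence[PigmentationRecord]) -> np.ndarray:
    """Individuals-by-segments float matrix in input order."""
    return np.array([r.scores for r in records], dtype=float)


def pca_trajectory(
    records: Sequence[PigmentationRecord], mode: str = "covariance"
) -> PcaResult:
    """Centered PCA of the score matrix, combined across sexes and strains.

    The default operates on the covariance matrix: all six variables share
    the 0-10 class scale, so no rescaling is needed; ``mode="correlation"``
    standardises each segment to unit variance first. Component signs are
    fixed deterministically — PC1 to correlate positively with mean
    pigmentation, later components so their largest-|r| segment loads
    positively.

    Raises
    ------
    ValueError
        With fewer than 2 individuals, or a constant score matrix
        ("no variance").
    """
    if len(records) < 2:
        raise ValueError("PCA needs at least 2 individuals")
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"unknown PCA mode {mode!r}")
    x = score_matrix(records)
    if np.allclose(x, x[0]):
        raise ValueError("no variance: all individuals have identical scores")
    if mode == "correlation":
        sd = x.std(axis=0, ddof=1)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    pca = PCA()
    coords = pca.fit_transform(x)
    var_pct = pca.explained_variance_ratio_ * 100.0

    mean_pig = score_matrix(records).mean(axis=1)
    loadings = np.zeros((coords.shape[1], N_SEGMENTS))
    raw = score_matrix(records)
    for k in range(coords.shape[1]):
        if coords[:, k].std() == 0:
            continue
        for j in range(N_SEGMENTS):
            if raw[:, j].std() == 0:
                continue
            loadings[k, j] = np.corrcoef(coords[:, k], raw[:, j])[0, 1]
        # deterministic sign convention
        if k == 0:
            flip = np.corrcoef(coords[:, 0], mean_pig)[0, 1] < 0
        else:
            jmax = int(np.argmax(np.abs(loadings[k])))
            flip = loadings[k, jmax] < 0
        if flip:
            coords[:, k] *= -1
            loadings[k] *= -1
    return PcaResult(var_pct, coords, loadings, mode)


def segment_sum_test(
    group_a: Sequence[PigmentationRecord],
    group_b: Sequence[PigmentationRecord],
    segments: Sequence[int],
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t test on per-individual sums over named segments.

    ``segments`` are 1-based analysis-segment indices (e.g. ``(5, 6)``
    for the pre-penultimate and penultimate columns). Welch's unequal-
    variance test by default (R's convention); ``equal_var=True`` gives
    Student's t. Returns (t, p, df).

    Raises
    ------
    ValueError
        If a group has fewer than 2 individuals, or both groups have zero
        within-group variance with different means (degenerate variance).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 individuals")
    idx = [s - 1 for s in segments]
    if any(i < 0 or i >= N_SEGMENTS for i in idx):
        raise ValueError(f"segment indices must be in 1..{N_SEGMENTS}")
    a = score_matrix(group_a)[:, idx].sum(axis=1)
    b = score_matrix(group_b)[:, idx].sum(axis=1)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, float(len(a) + len(b) - 2)
        raise ValueError("degenerate variance: both groups constant, means differ")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue), float(res.df)
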