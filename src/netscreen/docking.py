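"""Docking-score matrices and per-compound rank normalisation.

Scores live on a 0-10 pKd/pKi scale (negative log10 of a predicted
dissociation/association constant).  Raw scores are biased by compound size —
bigger molecules accumulate enthalpic contributions — so before any
cross-compound comparison each compound's scores are replaced by descending
ranks across its protein panel (rank 1 = strongest predicted binder, ties
averaged).  Ranks are invariant under any strictly increasing transform of a
compound's scores, which is exactly the bias removal wanted here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DockingScoreMatrix",
    "RankMatrix",
    "read_docking_matrix",
    "rank_normalize",
]

MISSING_TOKENS = ["", "NA", "NaN"]
SCORE_MIN, SCORE_MAX = 0.0, 10.0


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dupes = sorted(set(seen[seen.duplicated()]))
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class DockingScoreMatrix:
    """Compound x protein docking scores; each present value in [0, 10]."""

    scores: pd.DataFrame  # index = compound ids, columns = protein ids

    def __post_init__(self) -> None:
        df = self.scores
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError(
                f"need at least 2 compounds and 2 proteins, got {df.shape}"
            )
        _check_unique(df.index, "compound ids")
        _check_unique(df.columns, "protein ids")
        bad = (df < SCORE_MIN) | (df > SCORE_MAX)
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"docking score out of [0, 10] at compound {df.index[r]!r}, "
                f"protein {df.columns[c]!r}: {df.iat[r, c]}"
            )

    @property
    def compound_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.scores.columns)

    def to_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path, index_label="compound_id", na_rep="NA")


@dataclass
class RankMatrix:
    """Per-compound descending average-tie ranks of docking scores.

    Each row's non-missing ranks form a multiset summing to ``p(p+1)/2``
    where ``p`` is that row's non-missing protein count.
    """

    ranks: pd.DataFrame

    @property
    def compound_ids(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.ranks.columns)

    def to_csv(self, path: str | Path) -> None:
        self.ranks.to_csv(path, index_label="compound_id", na_rep="NA")


def read_docking_matrix(path: str | Path, transpose: bool = False) -> DockingScoreMatrix:
    """Read a labelled CSV of docking scores.

    Header row = protein ids, first column = compound ids (``transpose=True``
    for the opposite orientation).  Empty cells, ``NA`` and ``NaN`` are
    missing values; anything outside [0, 10] is a validation error naming the
    cell.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such docking-score file: {path}")
    df = pd.read_csv(
        path, index_col=0, na_values=MISSING_TOKENS, keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric docking score in {path}: {exc}") from exc
    if transpose:
        df = df.T
    return DockingScoreMatrix(scores=df)


def rank_normalize(m: DockingScoreMatrix) -> RankMatrix:
    """Replace each compound's scores with descending average-tie ranks.

    Ranks are computed over the non-missing proteins of each row; missing
    cells stay missing.  Rows with fewer than two non-missing scores cannot
    be ranked and raise, naming the compound.
    """
    df = m.scores
    out = np.full(df.shape, np.nan)
    values = df.to_numpy(dtype=float)
    for i, cid in enumerate(df.index):
        row = values[i]
        present = ~np.isnan(row)
        p = int(present.sum())
        if p == 0:
            raise ValueError(f"compound {cid!r}: all docking scores missing")
        if p < 2:
            raise ValueError(
                f"compound {cid!r}: need >= 2 non-missing scores to rank, got {p}"
            )
        # descending: highest score gets rank 1; ties -> average rank
        out[i, present] = rankdata(-row[present], method="average")
    return RankMatrix(ranks=pd.DataFrame(out, index=df.index, columns=df.columns))
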