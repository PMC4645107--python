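"""Per-pattern fluence proxies and selection of the highest-dose snapshots.

Each diffraction snapshot carries three observables positively correlated
with the true on-crystal fluence: the upstream pulse-energy reading, the
number of Bragg peaks found and their average integrated intensity.  The
score of a pattern is the mean of the empirical percentile ranks of the
three observables (ties share the midrank), which is scale-free and
invariant under monotone rescaling of any single observable; the selection
keeps the top-scoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from hiphase.errors import ConfigError, DomainError

__all__ = [
    "REQUIRED_COLUMNS",
    "SCORE_VARIABLES",
    "SelectionResult",
    "score_patterns",
    "select_best",
    "stream_summaries",
]

SCORE_VARIABLES = ("n_peaks", "mean_peak_intensity", "pulse_energy_reading_mJ")
REQUIRED_COLUMNS = ("id",) + SCORE_VARIABLES + ("max_resolution_A",)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a top-fraction selection."""

    selected_ids: tuple[str, ...]
    fraction: float
    score_definition: str
    thresholds: dict = field(default_factory=dict)


def _validate(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise DomainError("pattern list is empty")
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise DomainError(f"missing required column {col!r}")
        bad = records.index[records[col].isna()]
        if len(bad):
            rec_id = records.loc[bad[0], "id"] if "id" in records else bad[0]
            raise DomainError(
                f"record {rec_id!r}: missing value in column {col!r}"
            )
    if (records["max_resolution_A"] <= 0).any():
        raise DomainError("max_resolution_A must be > 0")
    if (records["n_peaks"] < 0).any() or (records["mean_peak_intensity"] < 0).any():
        raise DomainError("counts and intensities must be >= 0")


def score_patterns(records: pd.DataFrame) -> pd.Series:
    """Mean empirical percentile rank over the three fluence proxies.

    The maximal record in all three variables scores exactly 1; ties share
    the midrank.  Scores are index-aligned with the input.
    """
    _validate(records)
    n = len(records)
    ranks = np.column_stack(
        [rankdata(records[col].to_numpy(), method="average") for col in SCORE_VARIABLES]
    )
    return pd.Series(ranks.mean(axis=1) / n, index=records.index, name="score")


def select_best(records: pd.DataFrame, fraction: float) -> SelectionResult:
    """Keep the top-scoring ``fraction`` of patterns (deterministic).

    Ties at the cut are broken by id so reruns give identical selections.
    """
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must lie in (0, 1]")
    _validate(records)
    scores = score_patterns(records)
    n_keep = max(1, int(np.floor(fraction * len(records))))
    order = sorted(
        records.index, key=lambda i: (-scores[i], str(records.loc[i, "id"]))
    )
    chosen = order[:n_keep]
    ids = tuple(str(records.loc[i, "id"]) for i in chosen)
    return SelectionResult(
        selected_ids=ids,
        fraction=fraction,
        score_definition=(
            "mean of empirical percentile midranks of "
            + ", ".join(SCORE_VARIABLES)
        ),
        thresholds={
            "min_score_selected": float(scores[chosen[-1]]),
            "n_selected": n_keep,
            "n_total": len(records),
        },
    )


def stream_summaries(
    records: pd.DataFrame, bins: int = 20
) -> dict[str, pd.DataFrame]:
    """Binned summaries of the pattern stream, as plain tables.

    Returns 2-D histograms (mean peak intensity vs pulse-energy reading;
    number of peaks vs best resolution) and the marginal histograms of the
    three score variables.
    """
    _validate(records)
    out: dict[str, pd.DataFrame] = {}

    def hist2d(xcol: str, ycol: str, name: str) -> None:
        x = records[xcol].to_numpy(dtype=float)
        y = records[ycol].to_numpy(dtype=float)
        counts, xe, ye = np.histogram2d(x, y, bins=bins)
        out[name] = pd.DataFrame(
            counts,
            index=pd.Index(0.5 * (xe[:-1] + xe[1:]), name=xcol),
            columns=pd.Index(0.5 * (ye[:-1] + ye[1:]), name=ycol),
        )

    hist2d("pulse_energy_reading_mJ", "mean_peak_intensity", "intensity_vs_pulse_energy")
    hist2d("max_resolution_A", "n_peaks", "n_peaks_vs_resolution")
    for col in SCORE_VARIABLES + ("max_resolution_A",):
        counts, edges = np.histogram(records[col].to_numpy(dtype=float), bins=bins)
        out[f"marginal_{col}"] = pd.DataFrame(
            {
                "bin_center": 0.5 * (edges[:-1] + edges[1:]),
                "count": counts,
            }
        )
    return out
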