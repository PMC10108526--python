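"""Site-level aggregation of per-read calls, and multi-site phasing.

A read counts as edited when its predicted probability reaches 0.9.
Sites with fewer than 30 mapped reads are abandoned (no verdict); a
surviving site is called edited when its predicted editing ratio
(edited reads / total reads) reaches 0.1. Benchmark construction
follows the published convention: completely edited sites have a
short-read editing ratio strictly above 0.9, unedited sites exactly 0.

Phasing restricts to reads with predictions at every listed site of one
transcript and tabulates the binary editing pattern per molecule, with
a mutual-exclusivity summary (observed co-editing fraction versus the
product of the per-site marginals under independence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ValidationError
from .io import EditingSite

SUMMARY_COLUMNS = [
    "transcript_id",
    "pos",
    "n_reads",
    "n_edited",
    "editing_ratio",
    "abandoned",
    "called_edited",
]


def summarize_sites(preds: pd.DataFrame, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Per-site read counts, editing ratio and edited/abandoned verdicts.

    ``preds`` columns: read_id, transcript_id, pos, probability.
    ``called_edited`` is pd.NA for abandoned sites: an abandoned site
    carries no verdict.
    """
    cfg = cfg or RunConfig()
    if len(preds) == 0:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    p = preds["probability"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probability outside [0, 1]")
    grouped = (
        preds.assign(edited=p >= cfg.call_prob)
        .groupby(["transcript_id", "pos"], sort=True)
        .agg(n_reads=("read_id", "size"), n_edited=("edited", "sum"))
        .reset_index()
    )
    grouped["editing_ratio"] = grouped["n_edited"] / grouped["n_reads"]
    grouped["abandoned"] = grouped["n_reads"] < cfg.site_min_reads
    verdict = grouped["editing_ratio"] >= cfg.site_edited_ratio
    grouped["called_edited"] = verdict.astype(object).mask(grouped["abandoned"], pd.NA)
    return grouped[SUMMARY_COLUMNS]


def benchmark_sets(
    sites: Sequence[EditingSite],
) -> Tuple[List[EditingSite], List[EditingSite]]:
    """Completely edited (ratio > 0.9) and unedited (ratio = 0) sites.

    Sites between the two definitions are excluded from benchmarking.
    """
    positives = [s for s in sites if s.mean_ratio > 0.9]
    negatives = [s for s in sites if s.mean_ratio == 0.0]
    return positives, negatives


@dataclass
class PhasingMatrix:
    """Binary per-molecule editing status across the sites of a transcript."""

    transcript_id: str
    sites: Tuple[int, ...]
    matrix: pd.DataFrame  # index read_id, one 0/1 column per site pos
    pattern_counts: Dict[str, int]
    pattern_fractions: Dict[str, float]
    n_reads: int
    marginals: Tuple[float, ...]
    co_edited_fraction: float
    expected_independent: float


def phase_reads(
    preds: pd.DataFrame,
    transcript_id: str,
    site_positions: Sequence[int],
    cfg: RunConfig | None = None,
) -> PhasingMatrix:
    """Tabulate per-read editing patterns across >= 2 sites.

    Only reads with a prediction at every listed site are included;
    phasing claims require direct observation of each site on the same
    molecule. Patterns are strings like "01" in the order of the sorted
    site positions.
    """
    cfg = cfg or RunConfig()
    positions = tuple(sorted(int(p) for p in site_positions))
    if len(positions) < 2:
        raise ValidationError("phasing requires at least two sites")
    if len(set(positions)) != len(positions):
        raise ValidationError("duplicate site positions")
    sel = preds[
        (preds["transcript_id"] == transcript_id) & preds["pos"].isin(positions)
    ]
    wide = sel.pivot_table(
        index="read_id", columns="pos", values="probability", aggfunc="first"
    ).reindex(columns=positions)
    wide = wide.dropna()
    calls = (wide >= cfg.call_prob).astype(int)
    calls = calls.sort_index()
    n = len(calls)
    patterns = ["".join(map(str, row)) for row in calls.to_numpy()]
    counts: Dict[str, int] = {}
    for pat in patterns:
        counts[pat] = counts.get(pat, 0) + 1
    fractions = {k: v / n for k, v in counts.items()} if n else {}
    marginals = (
        tuple(float(calls[p].mean()) for p in positions) if n else tuple(0.0 for _ in positions)
    )
    co = float((calls.sum(axis=1) == len(positions)).mean()) if n else 0.0
    return PhasingMatrix(
        transcript_id=transcript_id,
        sites=positions,
        matrix=calls,
        pattern_counts=dict(sorted(counts.items())),
        pattern_fractions=dict(sorted(fractions.items())),
        n_reads=n,
        marginals=marginals,
        co_edited_fraction=co,
        expected_independent=float(np.prod(marginals)) if n else 0.0,
    )


def phasing_to_frame(pm: PhasingMatrix) -> pd.DataFrame:
    """Per-read phasing report rows (read_id, per-site calls, pattern)."""
    df = pm.matrix.reset_index()
    df.columns = ["read_id"] + [f"site_{p}" for p in pm.sites]
    df["pattern"] = ["".join(map(str, row)) for row in pm.matrix.to_numpy()]
    df.insert(1, "transcript_id", pm.transcript_id)
    return df
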