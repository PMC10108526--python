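"""Per-(read, site) feature vectors over the 6-mer window -3..+2.

Feature families: per-offset normalized current mean (Mean), current
standard deviation (STD), dwell divided by 100 (Length), one-hot base
identity of the called base (Base), and mean deviations between
adjacent window positions (MD, 5 values for a 6-mer). Layout is
offset-major with family order Mean, STD, Length, Base within each
offset, followed by the MD block; dropping a family removes exactly its
block. A (read, site) pair is emitted only when the read covers all six
window positions contiguously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ConfigError
from .io import BASES, EventRead

FEATURE_FAMILIES = ("mean", "std", "length", "base", "md")
DEFAULT_FEATURES = ("mean", "std", "length", "base")


@dataclass
class FeatureMatrix:
    """Dense feature matrix with its (read, site) index and layout."""

    X: np.ndarray
    index: pd.DataFrame  # columns: read_id, transcript_id, pos
    layout: Tuple[str, ...]
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.X)

    def to_frame(self) -> pd.DataFrame:
        df = self.index.reset_index(drop=True).copy()
        for j, name in enumerate(self.layout):
            df[name] = self.X[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = ["read_id", "transcript_id", "pos"]
        layout = tuple(c for c in df.columns if c not in meta and c != "label")
        return cls(
            X=df[list(layout)].to_numpy(dtype=np.float64),
            index=df[meta].copy(),
            layout=layout,
        )


def feature_layout(
    feature_set: Sequence[str], offsets: Sequence[int]
) -> Tuple[str, ...]:
    """Deterministic column names for a feature family selection."""
    fams = [f.lower() for f in feature_set]
    unknown = set(fams) - set(FEATURE_FAMILIES)
    if unknown:
        raise ConfigError(f"unknown feature families: {sorted(unknown)}")
    if not fams:
        raise ConfigError("feature_set must be non-empty")
    names: List[str] = []
    for off in offsets:
        if "mean" in fams:
            names.append(f"mean_{off}")
        if "std" in fams:
            names.append(f"std_{off}")
        if "length" in fams:
            names.append(f"length_{off}")
        if "base" in fams:
            names.extend(f"base_{off}_{b}" for b in BASES)
    if "md" in fams:
        names.extend(f"md_{j}" for j in range(1, len(offsets)))
    return tuple(names)


def extract_features(
    reads: Sequence[EventRead],
    sites: Sequence[Tuple[str, int]],
    feature_set: Sequence[str] = DEFAULT_FEATURES,
    cfg: RunConfig | None = None,
) -> FeatureMatrix:
    """Build one vector per (read, site) pair with full window coverage.

    ``sites`` is a sequence of (transcript_id, pos). Extraction is a
    pure function of its inputs; pairs whose read does not cover the
    whole window are skipped and counted in ``n_skipped``.
    """
    cfg = cfg or RunConfig()
    fams = [f.lower() for f in feature_set]
    offsets = list(cfg.window_offsets)
    layout = feature_layout(fams, offsets)
    by_tx: Dict[str, List[int]] = {}
    for tx, pos in sites:
        by_tx.setdefault(tx, []).append(int(pos))

    base_code = {b: i for i, b in enumerate(BASES)}
    vectors: List[np.ndarray] = []
    idx_rows: List[Tuple[str, str, int]] = []
    n_skipped = 0
    w = len(offsets)

    for read in reads:
        site_list = by_tx.get(read.transcript_id)
        if not site_list:
            continue
        base_col = (
            read.called_base if cfg.use_called_base else read.ref_base
        )
        for pos in site_list:
            start = read.index_of(pos + offsets[0])
            if start < 0 or start + w > len(read):
                n_skipped += 1
                continue
            window = slice(start, start + w)
            if not np.array_equal(
                read.pos[window], pos + np.asarray(offsets, dtype=np.int64)
            ):
                n_skipped += 1
                continue
            means = read.norm_mean[window]
            parts: List[np.ndarray] = []
            for k in range(w):
                if "mean" in fams:
                    parts.append(means[k : k + 1])
                if "std" in fams:
                    parts.append(read.norm_std[window][k : k + 1])
                if "length" in fams:
                    parts.append(read.dwell[window][k : k + 1] / cfg.length_scale)
                if "base" in fams:
                    onehot = np.zeros(4)
                    onehot[base_code[base_col[window][k]]] = 1.0
                    parts.append(onehot)
            if "md" in fams:
                parts.append(np.diff(means))
            vectors.append(np.concatenate(parts))
            idx_rows.append((read.read_id, read.transcript_id, pos))

    X = (
        np.vstack(vectors)
        if vectors
        else np.empty((0, len(layout)), dtype=np.float64)
    )
    index = pd.DataFrame(
        idx_rows, columns=["read_id", "transcript_id", "pos"]
    )
    return FeatureMatrix(X=X, index=index, layout=layout, n_skipped=n_skipped)
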