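"""Readers and writers for every on-disk artifact.

All tables are plain TSV with a mandatory header, 0-based transcript
coordinates, and deterministic row order, so that identical inputs
produce byte-identical files. Event tables are a flat, format-stable
stand-in for re-squiggled signal summaries (one row per aligned base of
one read); pileup tables are a tabular stand-in for per-position
mpileup-style base counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

BASES = ("A", "C", "G", "T")

EVENT_COLUMNS = [
    "read_id",
    "transcript_id",
    "pos",
    "ref_base",
    "called_base",
    "norm_mean",
    "norm_std",
    "dwell",
]

PILEUP_COLUMNS = [
    "sample_id",
    "transcript_id",
    "pos",
    "ref_base",
    "depth",
    "nA",
    "nC",
    "nG",
    "nT",
]

SITE_COLUMNS = [
    "transcript_id",
    "start",
    "end",
    "ref_base",
    "editing_ratio",
    "coverage",
]

PREDICTION_COLUMNS = ["read_id", "transcript_id", "pos", "probability"]
LABEL_COLUMNS = ["read_id", "transcript_id", "pos", "label"]
TRUTH_COLUMNS = ["read_id", "transcript_id", "pos", "edited"]


@dataclass
class EventRead:
    """Re-squiggled signal summary of one forward-strand read.

    Arrays are position-parallel: ``pos`` is strictly increasing 0-based
    transcript coordinates; ``norm_mean``/``norm_std`` are z-normalized
    current statistics; ``dwell`` counts raw signal samples (>= 1).
    """

    read_id: str
    transcript_id: str
    pos: np.ndarray
    ref_base: np.ndarray
    called_base: np.ndarray
    norm_mean: np.ndarray
    norm_std: np.ndarray
    dwell: np.ndarray
    strand: str = "forward"

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_base = np.asarray(self.ref_base, dtype="<U1")
        self.called_base = np.asarray(self.called_base, dtype="<U1")
        self.norm_mean = np.asarray(self.norm_mean, dtype=np.float64)
        self.norm_std = np.asarray(self.norm_std, dtype=np.float64)
        self.dwell = np.asarray(self.dwell, dtype=np.int64)

    def validate(self) -> "EventRead":
        n = len(self.pos)
        for name in ("ref_base", "called_base", "norm_mean", "norm_std", "dwell"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"read {self.read_id}: column {name} length mismatch"
                )
        if self.strand != "forward":
            raise ValidationError(
                f"read {self.read_id}: only forward-strand reads are admitted"
            )
        if n and np.any(np.diff(self.pos) <= 0):
            raise ValidationError(
                f"read {self.read_id}: positions are not strictly increasing"
            )
        if not (np.all(np.isfinite(self.norm_mean)) and np.all(np.isfinite(self.norm_std))):
            raise ValidationError(f"read {self.read_id}: non-finite signal value")
        if np.any(self.norm_std < 0):
            raise ValidationError(f"read {self.read_id}: negative norm_std")
        bad = np.flatnonzero(self.dwell < 1)
        if bad.size:
            raise ValidationError(
                f"read {self.read_id}: dwell < 1 at pos {int(self.pos[bad[0]])}"
            )
        for name in ("ref_base", "called_base"):
            arr = getattr(self, name)
            if n and not np.isin(arr, BASES).all():
                raise ValidationError(f"read {self.read_id}: invalid base in {name}")
        return self

    def __len__(self) -> int:
        return len(self.pos)

    def index_of(self, pos: int) -> int:
        """Index of transcript position ``pos`` in this read, or -1."""
        i = int(np.searchsorted(self.pos, pos))
        if i < len(self.pos) and self.pos[i] == pos:
            return i
        return -1


@dataclass
class PileupTable:
    """Per-position per-base called counts for one sample.

    ``df`` columns: transcript_id, pos, ref_base, depth, nA, nC, nG, nT,
    with sum of counts equal to depth at every row.
    """

    sample_id: str
    df: pd.DataFrame

    def validate(self) -> "PileupTable":
        needed = PILEUP_COLUMNS[1:]
        missing = [c for c in needed if c not in self.df.columns]
        if missing:
            raise ValidationError(f"pileup missing columns: {missing}")
        counts = self.df[["nA", "nC", "nG", "nT"]].to_numpy()
        if (counts < 0).any():
            raise ValidationError("negative base count in pileup")
        if (counts.sum(axis=1) != self.df["depth"].to_numpy()).any():
            raise ValidationError("pileup counts do not sum to depth")
        if self.df.duplicated(["transcript_id", "pos"]).any():
            raise ValidationError("duplicate (transcript, pos) in pileup")
        return self

    def lookup(self, transcript_id: str, pos: int):
        """Row for one position as a Series, or None if absent."""
        key = (transcript_id, pos)
        idx = self._index().get(key)
        if idx is None:
            return None
        return self.df.loc[idx]

    def _index(self) -> Dict[Tuple[str, int], int]:
        cached = getattr(self, "_idx_cache", None)
        if cached is None or len(cached) != len(self.df):
            cached = {
                (t, int(p)): i
                for i, (t, p) in zip(
                    self.df.index, zip(self.df["transcript_id"], self.df["pos"])
                )
            }
            self._idx_cache = cached
        return cached


@dataclass
class EditingSite:
    """A called A-to-I editing site with per-sample support."""

    transcript_id: str
    pos: int
    ref_base: str = "A"
    coverage: Dict[str, int] = field(default_factory=dict)
    editing_ratio: Dict[str, float] = field(default_factory=dict)

    @property
    def min_coverage(self) -> int:
        return min(self.coverage.values()) if self.coverage else 0

    @property
    def mean_ratio(self) -> float:
        if not self.editing_ratio:
            return float("nan")
        return float(np.mean(list(self.editing_ratio.values())))


def _require_header(df_cols: Sequence[str], expected: Sequence[str], what: str) -> None:
    if list(df_cols) != list(expected):
        raise FormatError(
            f"{what}: header {list(df_cols)} does not match expected {list(expected)}"
        )


def _read_tsv(path, expected: Sequence[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{what}: file {path} has no header")
    _require_header(df.columns, expected, what)
    return df


def _to_numeric(df: pd.DataFrame, col: str, kind: str, what: str) -> pd.Series:
    if kind == "float":
        # exact parse: pandas' fast float path can be 1 ulp off, which
        # would break byte-level round-trip guarantees
        vals = np.empty(len(df), dtype=np.float64)
        for i, s in enumerate(df[col].to_numpy()):
            try:
                vals[i] = float(s)
            except ValueError:
                # +2: one for the header line, one for 0- vs 1-based numbering
                raise FormatError(
                    f"{what}: malformed value in column {col} at line {i + 2}"
                )
        return pd.Series(vals, index=df.index)
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.index[out.isna()]
    if len(bad):
        raise FormatError(
            f"{what}: malformed value in column {col} at line {int(bad[0]) + 2}"
        )
    if kind == "int":
        frac = out[np.mod(out, 1) != 0]
        if len(frac):
            raise FormatError(
                f"{what}: non-integer value in column {col} at line "
                f"{int(frac.index[0]) + 2}"
            )
        return out.astype(np.int64)
    return out.astype(np.float64)


# ---------------------------------------------------------------------------
# event tables


def events_to_frame(reads: Iterable[EventRead]) -> pd.DataFrame:
    """Flatten reads into one row per aligned base, in read order."""
    parts = []
    for r in reads:
        parts.append(
            pd.DataFrame(
                {
                    "read_id": r.read_id,
                    "transcript_id": r.transcript_id,
                    "pos": r.pos,
                    "ref_base": r.ref_base,
                    "called_base": r.called_base,
                    "norm_mean": r.norm_mean,
                    "norm_std": r.norm_std,
                    "dwell": r.dwell,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(parts, ignore_index=True)[EVENT_COLUMNS]


def frame_to_reads(df: pd.DataFrame, validate: bool = True) -> List[EventRead]:
    """Group a flat event frame into EventRead objects (input order kept)."""
    reads: List[EventRead] = []
    for (read_id, transcript_id), grp in df.groupby(
        ["read_id", "transcript_id"], sort=False
    ):
        read = EventRead(
            read_id=str(read_id),
            transcript_id=str(transcript_id),
            pos=grp["pos"].to_numpy(),
            ref_base=grp["ref_base"].to_numpy(dtype="<U1"),
            called_base=grp["called_base"].to_numpy(dtype="<U1"),
            norm_mean=grp["norm_mean"].to_numpy(),
            norm_std=grp["norm_std"].to_numpy(),
            dwell=grp["dwell"].to_numpy(),
        )
        if validate:
            read.validate()
        reads.append(read)
    return reads


def read_event_table(path) -> List[EventRead]:
    """Parse an event TSV into validated reads, grouped by read_id."""
    df = _read_tsv(path, EVENT_COLUMNS, "event table")
    if df.empty:
        return []
    df = df.assign(
        pos=_to_numeric(df, "pos", "int", "event table"),
        norm_mean=_to_numeric(df, "norm_mean", "float", "event table"),
        norm_std=_to_numeric(df, "norm_std", "float", "event table"),
        dwell=_to_numeric(df, "dwell", "int", "event table"),
    )
    return frame_to_reads(df)


def write_event_table(reads: Iterable[EventRead], path) -> None:
    df = events_to_frame(reads)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# pileup tables


def read_pileup_table(path) -> PileupTable:
    df = _read_tsv(path, PILEUP_COLUMNS, "pileup table")
    samples = df["sample_id"].unique().tolist() if len(df) else ["sample"]
    if len(samples) > 1:
        raise FormatError(f"pileup table contains multiple samples: {samples}")
    body = df.drop(columns=["sample_id"])
    if len(body):
        body = body.assign(
            pos=_to_numeric(df, "pos", "int", "pileup table"),
            depth=_to_numeric(df, "depth", "int", "pileup table"),
            **{
                c: _to_numeric(df, c, "int", "pileup table")
                for c in ("nA", "nC", "nG", "nT")
            },
        )
    else:
        body = body.astype(
            {"pos": np.int64, "depth": np.int64, "nA": np.int64, "nC": np.int64,
             "nG": np.int64, "nT": np.int64},
            errors="ignore",
        )
    return PileupTable(sample_id=str(samples[0]), df=body.reset_index(drop=True)).validate()


def write_pileup_table(pileup: PileupTable, path) -> None:
    pileup.validate()
    df = pileup.df.copy()
    df.insert(0, "sample_id", pileup.sample_id)
    df = df.sort_values(["transcript_id", "pos"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# site lists (BED-like, half-open interval of width 1)


def write_site_table(sites: Iterable[EditingSite], path) -> None:
    rows = [
        {
            "transcript_id": s.transcript_id,
            "start": s.pos,
            "end": s.pos + 1,
            "ref_base": s.ref_base,
            "editing_ratio": s.mean_ratio,
            "coverage": s.min_coverage,
        }
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df = df.sort_values(["transcript_id", "start"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_site_table(path) -> List[EditingSite]:
    df = _read_tsv(path, SITE_COLUMNS, "site table")
    sites = []
    for i in range(len(df)):
        row = df.iloc[i]
        start = int(row["start"])
        if int(row["end"]) != start + 1:
            raise FormatError(f"site table: interval wider than 1 at line {i + 2}")
        sites.append(
            EditingSite(
                transcript_id=row["transcript_id"],
                pos=start,
                ref_base=row["ref_base"],
                coverage={"merged": int(float(row["coverage"]))},
                editing_ratio={"merged": float(row["editing_ratio"])},
            )
        )
    return sites


# ---------------------------------------------------------------------------
# predictions / labels / truth


def write_predictions(preds, path) -> None:
    """Write per-(read, site) probabilities sorted by (transcript, pos, read)."""
    if isinstance(preds, pd.DataFrame):
        df = preds[PREDICTION_COLUMNS].copy()
    else:
        df = pd.DataFrame(list(preds), columns=PREDICTION_COLUMNS)
    if len(df):
        p = df["probability"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise ValidationError("probability outside [0, 1]")
    df = df.sort_values(["transcript_id", "pos", "read_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path) -> pd.DataFrame:
    df = _read_tsv(path, PREDICTION_COLUMNS, "predictions")
    if df.empty:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)
    return df.assign(
        pos=_to_numeric(df, "pos", "int", "predictions"),
        probability=_to_numeric(df, "probability", "float", "predictions"),
    )


def write_labels(labels: pd.DataFrame, path) -> None:
    df = labels[LABEL_COLUMNS].sort_values(
        ["transcript_id", "pos", "read_id"], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_labels(path) -> pd.DataFrame:
    df = _read_tsv(path, LABEL_COLUMNS, "labels")
    if df.empty:
        return pd.DataFrame(columns=LABEL_COLUMNS)
    return df.assign(pos=_to_numeric(df, "pos", "int", "labels"))


def write_truth(truth: pd.DataFrame, path) -> None:
    df = truth[TRUTH_COLUMNS].copy()
    df["edited"] = df["edited"].astype(int)
    df = df.sort_values(["transcript_id", "pos", "read_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth(path) -> pd.DataFrame:
    df = _read_tsv(path, TRUTH_COLUMNS, "truth")
    if df.empty:
        return pd.DataFrame(columns=TRUTH_COLUMNS)
    df = df.assign(
        pos=_to_numeric(df, "pos", "int", "truth"),
        edited=_to_numeric(df, "edited", "int", "truth").astype(bool),
    )
    return df
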