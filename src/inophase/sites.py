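"""Short-read style A-to-I editing-site discovery from pileup tables.

A transparent frequency-based SNV caller feeds a four-rule site filter:
a site must be an A->G variant in every treatment replicate, in no
control replicate, absent from a user-supplied genomic-SNP exclusion
set, and covered (depth >= 50) with editing ratio >= 0.1 in all
treatment replicates. The editing ratio uses the A/G dichotomy the
method models: nG / (nA + nG).
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ConfigError
from .io import EditingSite, PileupTable

# tie-break order for the most-supported alternative base: the A->G
# editing signature first, then T, then C
_ALT_PRIORITY = ["G", "T", "C", "A"]


def call_snvs(
    pileup: PileupTable,
    min_alt_reads: int = 5,
    min_alt_fraction: float = 0.05,
) -> pd.DataFrame:
    """Frequency-based single-nucleotide variant calls for one sample.

    The most-supported non-reference base at each position is reported
    when its read support and fraction of total depth pass the floors.

    Returns a DataFrame with columns transcript_id, pos, ref_base,
    alt_base, alt_count, depth, alt_fraction.
    """
    df = pileup.df
    cols = ["transcript_id", "pos", "ref_base", "alt_base", "alt_count", "depth", "alt_fraction"]
    if df.empty:
        return pd.DataFrame(columns=cols)
    counts = df[["nA", "nC", "nG", "nT"]].to_numpy()
    base_order = np.array(["A", "C", "G", "T"])
    # reorder columns by tie-break priority so argmax resolves ties
    prio_idx = [int(np.flatnonzero(base_order == b)[0]) for b in _ALT_PRIORITY]
    prio_counts = counts[:, prio_idx].astype(float)
    ref = df["ref_base"].to_numpy(dtype="<U1")
    for j, b in enumerate(_ALT_PRIORITY):
        prio_counts[ref == b, j] = -1.0  # never call the reference base
    best = np.argmax(prio_counts, axis=1)
    alt_base = np.array(_ALT_PRIORITY)[best]
    alt_count = prio_counts[np.arange(len(df)), best].astype(np.int64)
    depth = df["depth"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
    keep = (alt_count >= min_alt_reads) & (frac >= min_alt_fraction)
    out = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"].to_numpy()[keep],
            "pos": df["pos"].to_numpy()[keep],
            "ref_base": ref[keep],
            "alt_base": alt_base[keep],
            "alt_count": alt_count[keep],
            "depth": depth[keep],
            "alt_fraction": frac[keep],
        }
    )
    return out.reset_index(drop=True)


def _snv_positions(
    pileup: PileupTable, ref: str, alt: str, min_alt_reads: int, min_alt_fraction: float
) -> Set[Tuple[str, int]]:
    snvs = call_snvs(pileup, min_alt_reads, min_alt_fraction)
    sel = snvs[(snvs["ref_base"] == ref) & (snvs["alt_base"] == alt)]
    return {(t, int(p)) for t, p in zip(sel["transcript_id"], sel["pos"])}


def _ag_ratio(row) -> float:
    denom = int(row["nA"]) + int(row["nG"])
    return float(row["nG"]) / denom if denom > 0 else float("nan")


def call_editing_sites(
    treat_reps: Sequence[PileupTable],
    ctrl_reps: Sequence[PileupTable],
    genomic_snps: Iterable[Tuple[str, int]] = (),
    cfg: RunConfig | None = None,
) -> List[EditingSite]:
    """Apply the four-rule filter for high-confidence A-to-I sites.

    A site survives iff it is an A->G SNV in every treatment replicate,
    an A->G SNV in no control replicate, not in ``genomic_snps``, and
    has depth >= cfg.coverage_site and editing ratio (nG/(nA+nG)) >=
    cfg.ratio_site in all treatment replicates.
    """
    cfg = cfg or RunConfig()
    if len(treat_reps) < 1:
        raise ConfigError("at least one treatment replicate is required")
    snp_set = set(genomic_snps)

    per_rep = [
        _snv_positions(p, "A", "G", cfg.min_alt_reads, cfg.min_alt_fraction)
        for p in treat_reps
    ]
    candidates = set.intersection(*per_rep)
    for ctrl in ctrl_reps:
        candidates -= _snv_positions(
            ctrl, "A", "G", cfg.min_alt_reads, cfg.min_alt_fraction
        )
    candidates -= snp_set

    sites: List[EditingSite] = []
    for tx, pos in sorted(candidates):
        coverage = {}
        ratio = {}
        ok = True
        for rep in treat_reps:
            row = rep.lookup(tx, pos)
            if row is None:
                ok = False
                break
            depth = int(row["depth"])
            r = _ag_ratio(row)
            if depth < cfg.coverage_site or not r >= cfg.ratio_site:
                ok = False
                break
            coverage[rep.sample_id] = depth
            ratio[rep.sample_id] = r
        if ok:
            sites.append(
                EditingSite(
                    transcript_id=tx, pos=pos, ref_base="A",
                    coverage=coverage, editing_ratio=ratio,
                )
            )
    return sites


def call_antisense_sites(
    treat_reps: Sequence[PileupTable],
    ctrl_reps: Sequence[PileupTable],
    cfg: RunConfig | None = None,
) -> List[Tuple[str, int]]:
    """T->C variants consistent in treatment and absent from control.

    These arise from editing on the strand complementary to the
    reference mRNA; they are reported descriptively and not used
    downstream.
    """
    cfg = cfg or RunConfig()
    if len(treat_reps) < 1:
        raise ConfigError("at least one treatment replicate is required")
    per_rep = [
        _snv_positions(p, "T", "C", cfg.min_alt_reads, cfg.min_alt_fraction)
        for p in treat_reps
    ]
    candidates = set.intersection(*per_rep)
    for ctrl in ctrl_reps:
        candidates -= _snv_positions(
            ctrl, "T", "C", cfg.min_alt_reads, cfg.min_alt_fraction
        )
    return sorted(candidates)
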