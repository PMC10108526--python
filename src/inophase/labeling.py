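"""Systematic base-calling errors (ASEs) and per-read training labels.

Inosine perturbs nanopore base-calling around an edited adenosine, so
the editing-competent sample accumulates position-specific miscalls
(ADAR-specific errors) that random noise does not reproduce. An ASE
passes three rules: it is the most-supported non-reference base at its
position; it is absent from the control sample or at least twice as
frequent in treatment; and it has >= 5 supporting reads with error
ratio >= 0.1.

Reads at a site with a qualifying ASE configuration at offsets -1..+1
(A->G at -1, A->G at 0, A->G or C->T at +1) are split into I-type
(carrying a qualifying miscall: inosine-bearing) and A-type (unedited)
training labels; reads from the control sample are labeled `control`.
Sites with another editing site within 3 nt are excluded so that
neighbouring signal perturbation cannot contaminate the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .config import RunConfig
from .io import EditingSite, EventRead, PileupTable
from .sites import call_snvs

logger = logging.getLogger(__name__)

#: (ref_base, err_base) combinations that qualify an ASE at each offset
QUALIFYING_ERRORS: Dict[int, frozenset] = {
    -1: frozenset({("A", "G")}),
    0: frozenset({("A", "G")}),
    1: frozenset({("A", "G"), ("C", "T")}),
}

I_TYPE = "I-type"
A_TYPE = "A-type"
CONTROL = "control"


@dataclass
class ASERecord:
    """One candidate systematic error with its three pass/fail flags."""

    transcript_id: str
    pos: int
    ref_base: str
    err_base: str
    n_err_treat: int
    n_total_treat: int
    n_err_ctrl: int
    n_total_ctrl: int
    ctrl_missing: bool = False

    @property
    def err_ratio_treat(self) -> float:
        return self.n_err_treat / self.n_total_treat if self.n_total_treat else 0.0

    @property
    def err_ratio_ctrl(self) -> float:
        return self.n_err_ctrl / self.n_total_ctrl if self.n_total_ctrl else 0.0

    def pass_dominant(self) -> bool:
        # err_base is chosen as the most-supported non-reference base,
        # so the flag only asserts there is any error support at all
        return self.n_err_treat > 0

    def pass_control(self, fold: float) -> bool:
        if self.n_err_ctrl == 0:
            return True
        return self.err_ratio_treat >= fold * self.err_ratio_ctrl

    def pass_support(self, min_reads: int, min_ratio: float) -> bool:
        return self.n_err_treat >= min_reads and self.err_ratio_treat >= min_ratio

    def passes(self, cfg: RunConfig) -> bool:
        return (
            self.pass_dominant()
            and self.pass_control(cfg.ase_fold)
            and self.pass_support(cfg.ase_min_reads, cfg.ase_min_ratio)
        )


def find_ases(
    treat: PileupTable,
    ctrl: PileupTable,
    cfg: RunConfig | None = None,
    positions: Optional[Iterable[Tuple[str, int]]] = None,
) -> List[ASERecord]:
    """Candidate ASEs at every treatment position (or a restricted set).

    Positions absent from the control table are treated as zero control
    coverage: the absence branch of the control rule applies, and the
    record is flagged ``ctrl_missing``.
    """
    cfg = cfg or RunConfig()
    # dominant non-reference base per position, no support floor here:
    # the three ASE rules are applied on the records themselves
    snvs = call_snvs(treat, min_alt_reads=1, min_alt_fraction=0.0)
    if positions is not None:
        wanted = set(positions)
        snvs = snvs[
            [
                (t, int(p)) in wanted
                for t, p in zip(snvs["transcript_id"], snvs["pos"])
            ]
        ]
    records: List[ASERecord] = []
    for row in snvs.itertuples(index=False):
        crow = ctrl.lookup(row.transcript_id, int(row.pos))
        if crow is None:
            n_err_ctrl, n_total_ctrl, missing = 0, 0, True
        else:
            n_err_ctrl = int(crow[f"n{row.alt_base}"])
            n_total_ctrl = int(crow["depth"])
            missing = False
        records.append(
            ASERecord(
                transcript_id=row.transcript_id,
                pos=int(row.pos),
                ref_base=row.ref_base,
                err_base=row.alt_base,
                n_err_treat=int(row.alt_count),
                n_total_treat=int(row.depth),
                n_err_ctrl=n_err_ctrl,
                n_total_ctrl=n_total_ctrl,
                ctrl_missing=missing,
            )
        )
    return records


def ases_to_frame(records: Sequence[ASERecord], cfg: RunConfig | None = None) -> pd.DataFrame:
    cfg = cfg or RunConfig()
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "pos": r.pos,
                "ref_base": r.ref_base,
                "err_base": r.err_base,
                "n_err_treat": r.n_err_treat,
                "n_total_treat": r.n_total_treat,
                "n_err_ctrl": r.n_err_ctrl,
                "n_total_ctrl": r.n_total_ctrl,
                "err_ratio_treat": r.err_ratio_treat,
                "err_ratio_ctrl": r.err_ratio_ctrl,
                "ctrl_missing": r.ctrl_missing,
                "pass_dominant": r.pass_dominant(),
                "pass_control": r.pass_control(cfg.ase_fold),
                "pass_support": r.pass_support(cfg.ase_min_reads, cfg.ase_min_ratio),
                "passes": r.passes(cfg),
            }
            for r in records
        ]
    )


def qualifying_ases(
    site: EditingSite, ases: Sequence[ASERecord], cfg: RunConfig
) -> Dict[int, ASERecord]:
    """Passing ASEs at offsets -1..+1 with an editing-consistent type."""
    out: Dict[int, ASERecord] = {}
    for r in ases:
        if r.transcript_id != site.transcript_id:
            continue
        off = r.pos - site.pos
        allowed = QUALIFYING_ERRORS.get(off)
        if allowed is None or (r.ref_base, r.err_base) not in allowed:
            continue
        if r.passes(cfg):
            out[off] = r
    return out


def _crowded(site: EditingSite, sites: Sequence[EditingSite], spacing: int) -> bool:
    return any(
        s is not site
        and s.transcript_id == site.transcript_id
        and abs(s.pos - site.pos) <= spacing
        for s in sites
    )


def separate_reads(
    sites: Sequence[EditingSite],
    ases: Sequence[ASERecord],
    treat_reads: Sequence[EventRead],
    cfg: RunConfig | None = None,
    ctrl_reads: Sequence[EventRead] | None = None,
) -> pd.DataFrame:
    """Label reads at qualifying sites as I-type / A-type / control.

    Returns a DataFrame with columns read_id, transcript_id, pos, label;
    every treatment read covering offsets -1..+1 of a qualifying site
    receives exactly one label there.
    """
    cfg = cfg or RunConfig()
    usable: List[Tuple[EditingSite, Dict[int, ASERecord]]] = []
    for site in sites:
        if _crowded(site, sites, cfg.site_spacing_exclude):
            logger.info(
                "site %s:%d excluded: neighbouring editing site within %d nt",
                site.transcript_id, site.pos, cfg.site_spacing_exclude,
            )
            continue
        qual = qualifying_ases(site, ases, cfg)
        needed = len(QUALIFYING_ERRORS) if cfg.ase_require_all else 1
        if len(qual) < needed:
            continue
        usable.append((site, qual))

    rows = []
    n_skipped = 0
    by_tx: Dict[str, List[Tuple[EditingSite, Dict[int, ASERecord]]]] = {}
    for site, qual in usable:
        by_tx.setdefault(site.transcript_id, []).append((site, qual))

    for read in treat_reads:
        for site, qual in by_tx.get(read.transcript_id, []):
            idxs = {off: read.index_of(site.pos + off) for off in (-1, 0, 1)}
            if any(i < 0 for i in idxs.values()):
                n_skipped += 1
                continue
            is_i = any(
                read.called_base[idxs[off]] == rec.err_base
                for off, rec in qual.items()
            )
            rows.append(
                {
                    "read_id": read.read_id,
                    "transcript_id": site.transcript_id,
                    "pos": site.pos,
                    "label": I_TYPE if is_i else A_TYPE,
                }
            )
    for read in ctrl_reads or []:
        for site, _qual in by_tx.get(read.transcript_id, []):
            idxs = [read.index_of(site.pos + off) for off in (-1, 0, 1)]
            if any(i < 0 for i in idxs):
                n_skipped += 1
                continue
            rows.append(
                {
                    "read_id": read.read_id,
                    "transcript_id": site.transcript_id,
                    "pos": site.pos,
                    "label": CONTROL,
                }
            )
    if n_skipped:
        logger.info("%d (read, site) pairs skipped: window -1..+1 not covered", n_skipped)
    return pd.DataFrame(rows, columns=["read_id", "transcript_id", "pos", "label"])
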