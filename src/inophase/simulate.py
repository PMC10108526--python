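"""Synthetic nanopore event-table generator with editing structure.

The generator emulates the signal phenomenology the detection method
relies on, without modeling pore physics:

* each transcript position has a 6-mer-context baseline current mean
  (drawn once from a fixed seeded context table) with unit-variance
  per-read noise, mimicking z-normalized re-squiggled signal;
* reads edited at a site get their current means shifted at window
  offsets -3..+1 around the edited adenosine, with the full headline
  shift at the site itself and decaying fractions at neighbours;
* edited reads additionally show editing-correlated base-calling errors
  at offsets -1 (A->G), 0 (A->G) and +1 (A->G or C->T), on top of a
  uniform baseline miscall rate affecting all reads;
* dwell is a shifted-geometric raw-sample count; norm_std is drawn from
  a gamma distribution independent of editing status.

Editing status per (read, site) is either independent Bernoulli at the
site's true editing ratio, or drawn from an explicit multi-site pattern
distribution for phasing experiments. Outputs are byte-deterministic
given the spec and its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import SimulationSpecError
from .io import EventRead, PileupTable

BASES = np.array(["A", "C", "G", "T"])
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

#: Fractions of the headline current-mean shift applied at each window
#: offset of an edited read; only -3..+1 carry signal.
DEFAULT_SHIFT_PROFILE: Dict[int, float] = {-3: 0.2, -2: 0.3, -1: 0.5, 0: 1.0, 1: 0.4}

#: Probability that an edited read shows the editing-correlated miscall
#: at each offset (A->G at -1 and 0; A->G or C->T at +1).
DEFAULT_EDIT_ERROR_PROBS: Dict[int, float] = {-1: 0.15, 0: 0.4, 1: 0.15}

_SEQ_SALT = b"inophase-seq:"
_PORE_SALT = b"inophase-pore:"
_context_cache: Dict[str, float] = {}


def _stable_seed(salt: bytes, key: str) -> int:
    return zlib.crc32(salt + key.encode())


def context_mean(kmer: str) -> float:
    """Baseline current mean for one 6-mer context.

    Values are standard-normal draws from a table seeded by the k-mer
    itself, so the 'pore model' is a fixed property of the generator,
    identical across runs, machines, and simulation seeds.
    """
    v = _context_cache.get(kmer)
    if v is None:
        v = float(np.random.default_rng(_stable_seed(_PORE_SALT, kmer)).standard_normal())
        _context_cache[kmer] = v
    return v


def _sequence_means(seq: str) -> np.ndarray:
    padded = "A" * 3 + seq + "A" * 2
    return np.array([context_mean(padded[i : i + 6]) for i in range(len(seq))])


@dataclass
class TranscriptSpec:
    """One transcript: either an explicit sequence or a length.

    Auto-generated sequences are uniform over ACGT, seeded by the
    transcript id alone so the same id yields the same sequence in every
    sample of an experiment.
    """

    transcript_id: str
    length: Optional[int] = None
    sequence: Optional[str] = None

    def resolve_sequence(self) -> str:
        if self.sequence is not None:
            return self.sequence.upper()
        if self.length is None or self.length < 6:
            raise SimulationSpecError(
                f"transcript {self.transcript_id}: need sequence or length >= 6"
            )
        rng = np.random.default_rng(_stable_seed(_SEQ_SALT, self.transcript_id))
        return "".join(rng.choice(BASES, size=self.length))


@dataclass
class SiteSpec:
    transcript_id: str
    pos: int
    editing_ratio: float


@dataclass
class SimulationSpec:
    """Full description of one simulated direct-RNA sample."""

    transcripts: List[TranscriptSpec]
    sites: List[SiteSpec] = field(default_factory=list)
    coverage: int = 100
    headline_shift: float = 1.0
    shift_profile: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SHIFT_PROFILE)
    )
    edit_error_probs: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_EDIT_ERROR_PROBS)
    )
    baseline_error_rate: float = 0.01
    dwell_mean: float = 10.0
    norm_std_shape: float = 5.0
    norm_std_scale: float = 0.1
    phasing_patterns: Optional[Dict[str, Dict[str, float]]] = None
    read_prefix: str = "r"
    seed: int = 0

    def sites_of(self, transcript_id: str) -> List[SiteSpec]:
        return sorted(
            (s for s in self.sites if s.transcript_id == transcript_id),
            key=lambda s: s.pos,
        )

    def validate(self) -> "SimulationSpec":
        tx_ids = [t.transcript_id for t in self.transcripts]
        if len(set(tx_ids)) != len(tx_ids):
            raise SimulationSpecError("duplicate transcript ids")
        sequences = {t.transcript_id: _resolved_sequence(t, self) for t in self.transcripts}
        for s in self.sites:
            if s.transcript_id not in sequences:
                raise SimulationSpecError(f"site on unknown transcript {s.transcript_id}")
            seq = sequences[s.transcript_id]
            if not 0 <= s.pos < len(seq):
                raise SimulationSpecError(
                    f"site {s.transcript_id}:{s.pos} outside transcript"
                )
            if seq[s.pos] != "A":
                raise SimulationSpecError(
                    f"site {s.transcript_id}:{s.pos} is not an A in the sequence"
                )
            if not 0.0 <= s.editing_ratio <= 1.0:
                raise SimulationSpecError("editing_ratio must be in [0, 1]")
        if self.phasing_patterns:
            for tx, patterns in self.phasing_patterns.items():
                n_sites = len(self.sites_of(tx))
                if n_sites < 1:
                    raise SimulationSpecError(f"phasing patterns for siteless {tx}")
                freqs = np.array(list(patterns.values()), dtype=float)
                if abs(freqs.sum() - 1.0) > 1e-9:
                    raise SimulationSpecError("phasing pattern frequencies must sum to 1")
                for pat in patterns:
                    if len(pat) != n_sites or set(pat) - {"0", "1"}:
                        raise SimulationSpecError(f"bad pattern {pat!r} for {tx}")
                # marginals implied by the patterns must agree with the
                # per-site ratios when both are given
                for j, site in enumerate(self.sites_of(tx)):
                    marginal = sum(f for p, f in patterns.items() if p[j] == "1")
                    if abs(marginal - site.editing_ratio) > 1e-6:
                        raise SimulationSpecError(
                            f"pattern marginal {marginal:.4f} != editing_ratio "
                            f"{site.editing_ratio:.4f} at {tx}:{site.pos}"
                        )
        if self.coverage < 1:
            raise SimulationSpecError("coverage must be >= 1")
        return self


def _resolved_sequence(t: TranscriptSpec, spec: SimulationSpec) -> str:
    """Transcript sequence with A forced at site positions when auto-generated."""
    seq = t.resolve_sequence()
    if t.sequence is None:
        chars = list(seq)
        for s in spec.sites:
            if s.transcript_id == t.transcript_id and 0 <= s.pos < len(chars):
                chars[s.pos] = "A"
        seq = "".join(chars)
    return seq


def _draw_edit_matrix(
    spec: SimulationSpec, tx: str, sites: List[SiteSpec], n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_reads, n_sites) boolean editing status."""
    if not sites:
        return np.zeros((n, 0), dtype=bool)
    patterns = (spec.phasing_patterns or {}).get(tx)
    if patterns:
        keys = sorted(patterns)
        freqs = np.array([patterns[k] for k in keys], dtype=float)
        freqs = freqs / freqs.sum()
        choice = rng.choice(len(keys), size=n, p=freqs)
        mat = np.array([[c == "1" for c in k] for k in keys], dtype=bool)
        return mat[choice]
    ratios = np.array([s.editing_ratio for s in sites])
    return rng.random((n, len(sites))) < ratios[None, :]


def simulate_reads(
    spec: SimulationSpec,
) -> Tuple[List[EventRead], pd.DataFrame]:
    """Generate full-length reads and a per-(read, site) truth table.

    Returns
    -------
    reads:
        One EventRead per simulated molecule, spanning its whole
        transcript.
    truth:
        DataFrame with columns read_id, transcript_id, pos, edited —
        one row for every (read, editing site) pair.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    reads: List[EventRead] = []
    truth_parts: List[pd.DataFrame] = []
    offsets = sorted(spec.shift_profile)
    err_offsets = sorted(spec.edit_error_probs)

    for t in spec.transcripts:
        seq = _resolved_sequence(t, spec)
        L = len(seq)
        sites = spec.sites_of(t.transcript_id)
        mu = _sequence_means(seq)
        ref_codes = np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)
        n = spec.coverage

        edited = _draw_edit_matrix(spec, t.transcript_id, sites, n, rng)
        norm_mean = mu[None, :] + rng.standard_normal((n, L))
        for j, site in enumerate(sites):
            rows = edited[:, j]
            if not rows.any():
                continue
            for off in offsets:
                p = site.pos + off
                if 0 <= p < L:
                    norm_mean[rows, p] += spec.headline_shift * spec.shift_profile[off]
        norm_std = rng.gamma(spec.norm_std_shape, spec.norm_std_scale, size=(n, L))
        dwell = rng.geometric(1.0 / spec.dwell_mean, size=(n, L))

        called = np.tile(ref_codes, (n, 1))
        base_err = rng.random((n, L)) < spec.baseline_error_rate
        alt_step = rng.integers(1, 4, size=(n, L), dtype=np.int8)
        called = np.where(base_err, (called + alt_step) % 4, called)
        for j, site in enumerate(sites):
            rows = np.flatnonzero(edited[:, j])
            if rows.size == 0:
                continue
            for off in err_offsets:
                p = site.pos + off
                if not 0 <= p < L:
                    continue
                ref = seq[p]
                if off in (-1, 0) and ref != "A":
                    continue
                if off == 1 and ref not in ("A", "C"):
                    continue
                miscall = rng.random(rows.size) < spec.edit_error_probs[off]
                target = _BASE_CODE["G"] if ref == "A" else _BASE_CODE["T"]
                called[rows[miscall], p] = target

        pos_arr = np.arange(L, dtype=np.int64)
        ref_arr = BASES[ref_codes]
        width = max(5, len(str(n)))
        for i in range(n):
            rid = f"{t.transcript_id}_{spec.read_prefix}{i:0{width}d}"
            reads.append(
                EventRead(
                    read_id=rid,
                    transcript_id=t.transcript_id,
                    pos=pos_arr,
                    ref_base=ref_arr,
                    called_base=BASES[called[i]],
                    norm_mean=norm_mean[i],
                    norm_std=norm_std[i],
                    dwell=dwell[i],
                )
            )
        if sites:
            rids = [
                f"{t.transcript_id}_{spec.read_prefix}{i:0{width}d}" for i in range(n)
            ]
            truth_parts.append(
                pd.DataFrame(
                    {
                        "read_id": np.repeat(rids, len(sites)),
                        "transcript_id": t.transcript_id,
                        "pos": np.tile([s.pos for s in sites], n),
                        "edited": edited.reshape(-1),
                    }
                )
            )

    truth = (
        pd.concat(truth_parts, ignore_index=True)
        if truth_parts
        else pd.DataFrame(columns=["read_id", "transcript_id", "pos", "edited"])
    )
    return reads, truth


def pileup_from_reads(reads: Sequence[EventRead], sample_id: str) -> PileupTable:
    """Tally called bases per (transcript, position) across reads."""
    if not reads:
        return PileupTable(
            sample_id=sample_id,
            df=pd.DataFrame(
                columns=["transcript_id", "pos", "ref_base", "depth", "nA", "nC", "nG", "nT"]
            ),
        )
    tx = np.concatenate([np.repeat(r.transcript_id, len(r)) for r in reads])
    pos = np.concatenate([r.pos for r in reads])
    ref = np.concatenate([r.ref_base for r in reads])
    called = np.concatenate([r.called_base for r in reads])
    df = pd.DataFrame(
        {"transcript_id": tx, "pos": pos, "ref_base": ref, "called_base": called}
    )
    counts = (
        df.groupby(["transcript_id", "pos", "ref_base"], sort=True)["called_base"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(BASES), fill_value=0)
        .reset_index()
    )
    counts.columns = ["transcript_id", "pos", "ref_base", "nA", "nC", "nG", "nT"]
    counts["depth"] = counts[["nA", "nC", "nG", "nT"]].sum(axis=1)
    out = counts[
        ["transcript_id", "pos", "ref_base", "depth", "nA", "nC", "nG", "nT"]
    ].copy()
    out["pos"] = out["pos"].astype(np.int64)
    return PileupTable(sample_id=sample_id, df=out).validate()


def short_read_pileup(
    spec: SimulationSpec,
    sample_id: str,
    depth: int = 100,
    error_rate: float = 0.001,
    seed: Optional[int] = None,
) -> PileupTable:
    """Illumina-style pileup implied by the editing structure of ``spec``.

    Short reads report inosine as G essentially deterministically and
    carry no editing-correlated systematic errors, so the table has
    A->G counts binomial in the true editing ratio at each site and
    only a uniform sequencing-error rate elsewhere. This is the input
    to site discovery, which in the published workflow runs on
    short-read data rather than on nanopore base-calls.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for t in spec.transcripts:
        seq = _resolved_sequence(t, spec)
        L = len(seq)
        ref_codes = np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)
        counts = np.zeros((L, 4), dtype=np.int64)
        counts[np.arange(L), ref_codes] = depth
        for site in spec.sites_of(t.transcript_id):
            k = int(rng.binomial(depth, site.editing_ratio))
            counts[site.pos, _BASE_CODE["A"]] -= k
            counts[site.pos, _BASE_CODE["G"]] += k
        n_err = rng.binomial(depth, error_rate, size=L)
        for p in np.flatnonzero(n_err):
            alts = [c for c in range(4) if c != ref_codes[p]]
            split = rng.multinomial(n_err[p], [1 / 3] * 3)
            take = min(int(n_err[p]), int(counts[p, ref_codes[p]]))
            counts[p, ref_codes[p]] -= take
            # distribute errors over the three alternative bases
            total = split.sum()
            if total:
                scaled = (split * take) // total
                rem = take - scaled.sum()
                scaled[0] += rem
                for c, k2 in zip(alts, scaled):
                    counts[p, c] += int(k2)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": t.transcript_id,
                    "pos": np.arange(L, dtype=np.int64),
                    "ref_base": BASES[ref_codes],
                    "depth": counts.sum(axis=1),
                    "nA": counts[:, 0],
                    "nC": counts[:, 1],
                    "nG": counts[:, 2],
                    "nT": counts[:, 3],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return PileupTable(sample_id=sample_id, df=df).validate()
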