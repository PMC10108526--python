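"""Statistical and determinism properties of the synthetic generator."""

import numpy as np
import pytest
from scipy import stats

from inophase.errors import SimulationSpecError
from inophase.io import EventRead
from inophase.simulate import (
    SimulationSpec,
    SiteSpec,
    TranscriptSpec,
    pileup_from_reads,
    short_read_pileup,
    simulate_reads,
)
from inophase.io import write_event_table


def small_spec(seed=0, ratio=0.5, coverage=50, shift=1.0, **kw):
    return SimulationSpec(
        transcripts=[TranscriptSpec("tx1", length=30)],
        sites=[SiteSpec("tx1", 15, ratio)],
        coverage=coverage,
        headline_shift=shift,
        seed=seed,
        **kw,
    )


def test_determinism_byte_identical(tmp_path):
    """Same spec and seed give byte-identical event tables and truth."""
    for run in ("a", "b"):
        reads, truth = simulate_reads(small_spec(seed=7))
        write_event_table(reads, tmp_path / f"events_{run}.tsv")
        truth.to_csv(tmp_path / f"truth_{run}.tsv", sep="\t", index=False)
    assert (tmp_path / "events_a.tsv").read_bytes() == (tmp_path / "events_b.tsv").read_bytes()
    assert (tmp_path / "truth_a.tsv").read_bytes() == (tmp_path / "truth_b.tsv").read_bytes()


def test_site_must_be_adenosine():
    spec = SimulationSpec(
        transcripts=[TranscriptSpec("tx1", sequence="ACGTCCGGTT")],
        sites=[SiteSpec("tx1", 1, 0.5)],  # a C
    )
    with pytest.raises(SimulationSpecError, match="not an A"):
        simulate_reads(spec)


def test_pattern_marginals_must_match_site_ratios():
    spec = SimulationSpec(
        transcripts=[TranscriptSpec("tx1", length=40)],
        sites=[SiteSpec("tx1", 10, 0.5), SiteSpec("tx1", 30, 0.5)],
        phasing_patterns={"tx1": {"00": 0.5, "11": 0.5}},
    )
    spec.sites[0].editing_ratio = 0.9  # now inconsistent with the patterns
    with pytest.raises(SimulationSpecError, match="marginal"):
        spec.validate()


def test_editing_ratio_converges_binomially():
    """Marginal edited fraction at coverage 10,000 sits in the binomial CI."""
    ratio = 0.3
    _, truth = simulate_reads(small_spec(seed=3, ratio=ratio, coverage=10_000))
    frac = truth["edited"].mean()
    se = np.sqrt(ratio * (1 - ratio) / 10_000)
    assert abs(frac - ratio) < 4 * se


def test_truth_covers_every_read_site_pair():
    reads, truth = simulate_reads(small_spec(seed=1, coverage=20))
    assert len(truth) == 20
    assert set(truth["read_id"]) == {r.read_id for r in reads}


def test_fraction_of_edited_reads_matches_ratio():
    _, truth = simulate_reads(small_spec(seed=5, ratio=0.5, coverage=1000))
    assert abs(truth["edited"].mean() - 0.5) <= 0.05


def _ks_at_site(spec):
    reads, truth = simulate_reads(spec)
    edited_ids = set(truth.loc[truth["edited"], "read_id"])
    x, y = [], []
    for r in reads:
        i = r.index_of(15)
        (x if r.read_id in edited_ids else y).append(r.norm_mean[i])
    if not x or not y:
        return np.nan, np.nan
    return stats.ks_2samp(x, y, method="asymp")


def test_ks_statistic_monotone_in_shift():
    """Mean KS D at the site is nondecreasing across shifts 0.25..2 SD."""
    shifts = [0.25, 0.5, 1.0, 2.0]
    mean_d = []
    for shift in shifts:
        ds = [
            _ks_at_site(small_spec(seed=100 + s, shift=shift, coverage=200))[0]
            for s in range(20)
        ]
        mean_d.append(np.nanmean(ds))
    assert all(b >= a for a, b in zip(mean_d, mean_d[1:])), mean_d


def test_null_spec_gives_uniform_ks_pvalues():
    """Zero shift and equal error rates: edited vs unedited signal is null."""
    pvals = []
    for s in range(25):
        _, p = _ks_at_site(
            small_spec(
                seed=200 + s, coverage=200, shift=0.0, edit_error_probs={}
            )
        )
        if np.isfinite(p):
            pvals.append(p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_phasing_pattern_counts_multinomial():
    patterns = {"00": 0.6, "10": 0.1, "01": 0.25, "11": 0.05}
    n = 5000
    spec = SimulationSpec(
        transcripts=[TranscriptSpec("tx1", length=60)],
        sites=[SiteSpec("tx1", 20, 0.15), SiteSpec("tx1", 40, 0.30)],
        coverage=n,
        phasing_patterns={"tx1": patterns},
        seed=17,
    )
    _, truth = simulate_reads(spec)
    wide = truth.pivot_table(index="read_id", columns="pos", values="edited", aggfunc="first")
    observed = {
        f"{int(a)}{int(b)}": 0 for a in (0, 1) for b in (0, 1)
    }
    for a, b in wide.to_numpy():
        observed[f"{int(a)}{int(b)}"] += 1
    for pat, f in patterns.items():
        sd = np.sqrt(n * f * (1 - f))
        assert abs(observed[pat] - n * f) <= 3 * sd, (pat, observed)


def test_pileup_matches_brute_force_tally(random_reads):
    pileup = pileup_from_reads(random_reads, "s")
    tally = {}
    for r in random_reads:
        for p, b in zip(r.pos, r.called_base):
            key = (r.transcript_id, int(p))
            tally.setdefault(key, {"A": 0, "C": 0, "G": 0, "T": 0})[b] += 1
    assert len(pileup.df) == len(tally)
    for row in pileup.df.itertuples(index=False):
        counts = tally[(row.transcript_id, row.pos)]
        assert (row.nA, row.nC, row.nG, row.nT) == (
            counts["A"], counts["C"], counts["G"], counts["T"],
        )
        assert row.depth == sum(counts.values())


def test_pileup_identical_reads():
    base = dict(
        transcript_id="tx",
        pos=np.arange(10),
        ref_base=list("ACGTACGTAC"),
        called_base=list("ACGTACGTAC"),
        norm_mean=np.zeros(10),
        norm_std=np.full(10, 0.1),
        dwell=np.full(10, 5),
    )
    reads = [EventRead(read_id=f"r{i}", **base) for i in range(10)]
    pileup = pileup_from_reads(reads, "s")
    assert (pileup.df["depth"] == 10).all()
    assert (pileup.df[["nA", "nC", "nG", "nT"]].to_numpy().max(axis=1) == 10).all()


def test_short_read_pileup_reflects_editing():
    spec = small_spec(seed=9, ratio=0.4)
    pileup = short_read_pileup(spec, "sr", depth=2000, error_rate=0.0)
    row = pileup.lookup("tx1", 15)
    assert row["depth"] == 2000
    ag_ratio = row["nG"] / (row["nA"] + row["nG"])
    assert abs(ag_ratio - 0.4) < 4 * np.sqrt(0.4 * 0.6 / 2000)
    # non-site positions are error-free at error_rate 0
    other = pileup.lookup("tx1", 5)
    assert other[f"n{other['ref_base']}"] == 2000
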