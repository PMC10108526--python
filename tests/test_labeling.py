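"""Systematic-error discovery and I-type / A-type read separation."""

import numpy as np
import pytest

from inophase.config import RunConfig
from inophase.io import EditingSite
from inophase.labeling import (
    A_TYPE,
    CONTROL,
    I_TYPE,
    find_ases,
    qualifying_ases,
    separate_reads,
)
from inophase.pipeline import training_specs, ExperimentSizes
from inophase.simulate import pileup_from_reads, simulate_reads

from conftest import make_pileup, make_read

CFG = RunConfig()


def _ase_fixture():
    """8 treatment positions, each probing one discovery rule.

    Designed survivors: pos 0 (clean), pos 3 (fold branch), pos 5
    (dominance tie G>T), pos 6 (position absent from control), pos 7
    (non-A->G error type; type filtering is downstream).
    """
    treat = make_pileup(
        "t",
        [
            ("tx", 0, "A", 40, 0, 10, 0),   # ratio 0.2, absent in control
            ("tx", 1, "A", 40, 0, 10, 0),   # control ratio 0.118: fails fold
            ("tx", 2, "A", 46, 0, 4, 0),    # 4 reads / ratio 0.08: fails support
            ("tx", 3, "A", 40, 0, 10, 0),   # ctrl ratio 0.0526: passes fold
            ("tx", 4, "A", 50, 0, 0, 0),    # no error at all
            ("tx", 5, "A", 40, 0, 5, 5),    # G-T tie -> G, ratio 0.1 boundary
            ("tx", 6, "A", 40, 0, 10, 0),   # position missing from control
            ("tx", 7, "A", 40, 10, 0, 0),   # dominant error is A->C
        ],
    )
    ctrl = make_pileup(
        "c",
        [
            ("tx", 0, "A", 50, 0, 0, 0),
            ("tx", 1, "A", 45, 0, 6, 0),
            ("tx", 2, "A", 50, 0, 0, 0),
            ("tx", 3, "A", 90, 0, 5, 0),
            ("tx", 4, "A", 50, 0, 0, 0),
            ("tx", 5, "A", 50, 0, 0, 0),
            ("tx", 7, "A", 50, 0, 0, 0),
        ],
    )
    return treat, ctrl


def test_ase_fixture_exact_survivors():
    treat, ctrl = _ase_fixture()
    records = find_ases(treat, ctrl, CFG)
    passing = {r.pos: r for r in records if r.passes(CFG)}
    assert sorted(passing) == [0, 3, 5, 6, 7]
    assert passing[5].err_base == "G"          # tie broken toward G
    assert passing[6].ctrl_missing
    assert passing[7].err_base == "C"          # type-agnostic at this stage
    failing = {r.pos: r for r in records if not r.passes(CFG)}
    assert not failing[1].pass_control(CFG.ase_fold)
    assert not failing[2].pass_support(CFG.ase_min_reads, CFG.ase_min_ratio)
    assert 4 not in passing and 4 not in failing  # no error: never emitted


@pytest.mark.parametrize(
    "treat_counts, ctrl_counts, expected",
    [
        ((40, 10), (50, 0), True),    # absent in control
        ((40, 10), (45, 6), False),   # 0.2 < 2 x 0.118
        ((46, 4), (50, 0), False),    # ratio 0.08 and 4 supporting reads
    ],
)
def test_ase_criteria_arithmetic(treat_counts, ctrl_counts, expected):
    treat = make_pileup("t", [("tx", 0, "A", treat_counts[0], 0, treat_counts[1], 0)])
    ctrl = make_pileup("c", [("tx", 0, "A", ctrl_counts[0], 0, ctrl_counts[1], 0)])
    records = find_ases(treat, ctrl, CFG)
    got = any(r.passes(CFG) for r in records)
    assert got is expected


def _qualifying_setup(site_pos=10):
    """A site whose offsets -1, 0, +1 all carry passing ASEs."""
    # reference around the site: ... A A C ... (so +1 is a C->T ASE)
    treat = make_pileup(
        "t",
        [
            ("tx", site_pos - 1, "A", 80, 0, 20, 0),
            ("tx", site_pos, "A", 60, 0, 40, 0),
            ("tx", site_pos + 1, "C", 0, 80, 0, 20),
        ],
    )
    ctrl = make_pileup(
        "c",
        [
            ("tx", site_pos - 1, "A", 100, 0, 0, 0),
            ("tx", site_pos, "A", 100, 0, 0, 0),
            ("tx", site_pos + 1, "C", 0, 100, 0, 0),
        ],
    )
    return find_ases(treat, ctrl, CFG)


def test_qualifying_ases_by_offset():
    site = EditingSite("tx", 10, "A")
    qual = qualifying_ases(site, _qualifying_setup(), CFG)
    assert sorted(qual) == [-1, 0, 1]
    assert qual[1].err_base == "T"


def test_read_separation_i_vs_a_type():
    ases = _qualifying_setup()
    site = EditingSite("tx", 10, "A")
    # window ref bases around pos 10: positions 7..13
    ref = "GGAACCG"
    reads = [
        make_read("edited_mid", "tx", 7, ref, called_seq="GGAGCCG"),   # G at site
        make_read("edited_plus", "tx", 7, ref, called_seq="GGAATCG"),  # C->T at +1
        make_read("clean", "tx", 7, ref),
        make_read("too_short", "tx", 10, "ACC"),  # misses offset -1
    ]
    labels = separate_reads([site], ases, reads, CFG)
    got = dict(zip(labels["read_id"], labels["label"]))
    assert got == {
        "edited_mid": I_TYPE,
        "edited_plus": I_TYPE,
        "clean": A_TYPE,
    }


def test_every_covering_read_gets_exactly_one_label():
    ases = _qualifying_setup()
    site = EditingSite("tx", 10, "A")
    rng = np.random.default_rng(0)
    reads = []
    for i in range(40):
        called = list("GGAACCG")
        if rng.random() < 0.5:
            called[3] = "G"
        reads.append(make_read(f"r{i}", "tx", 7, "GGAACCG", "".join(called)))
    labels = separate_reads([site], ases, reads, CFG)
    assert len(labels) == 40
    assert labels["read_id"].is_unique
    n_i = (labels["label"] == I_TYPE).sum()
    n_a = (labels["label"] == A_TYPE).sum()
    assert n_i + n_a == 40


def test_adjacent_sites_excluded():
    ases = _qualifying_setup()
    near = [EditingSite("tx", 10, "A"), EditingSite("tx", 12, "A")]
    reads = [make_read("r0", "tx", 7, "GGAACCG", "GGAGCCG")]
    assert len(separate_reads(near, ases, reads, CFG)) == 0
    far = [EditingSite("tx", 10, "A"), EditingSite("tx", 14, "A")]
    labels = separate_reads(far, ases, reads, CFG)
    assert set(labels["pos"]) == {10}  # site 14 has no qualifying ASE


def test_control_reads_labeled_control():
    ases = _qualifying_setup()
    site = EditingSite("tx", 10, "A")
    ctrl = [make_read("c0", "tx", 7, "GGAACCG", "GGAGCCG")]  # even with a G
    labels = separate_reads([site], ases, [], CFG, ctrl_reads=ctrl)
    assert list(labels["label"]) == [CONTROL]


def test_require_all_strictness_flag():
    ases = [a for a in _qualifying_setup() if a.pos != 9]  # drop the -1 ASE
    site = EditingSite("tx", 10, "A")
    reads = [make_read("r0", "tx", 7, "GGAACCG", "GGAGCCG")]
    strict = RunConfig(ase_require_all=True)
    assert len(separate_reads([site], ases, reads, strict)) == 0
    assert len(separate_reads([site], ases, reads, CFG)) == 1


def test_no_qualifying_sites_on_null_data():
    """Without editing, baseline miscalls at 1% never assemble an ASE."""
    sizes = ExperimentSizes(
        n_transcripts=3, length=40, site_offset=20,
        coverage_treat=100, coverage_ctrl=100, editing_ratio=0.0,
    )
    for seed in range(10):
        treat_spec, ctrl_spec = training_specs(seed, sizes)
        treat_reads, _ = simulate_reads(treat_spec)
        ctrl_reads, _ = simulate_reads(ctrl_spec)
        ases = find_ases(
            pileup_from_reads(treat_reads, "t"),
            pileup_from_reads(ctrl_reads, "c"),
            CFG,
        )
        sites = [EditingSite(s.transcript_id, s.pos, "A") for s in treat_spec.sites]
        assert all(not qualifying_ases(s, ases, CFG) for s in sites), seed


def test_labeling_precision_on_simulated_truth():
    """I-type labels are nearly always truly edited reads (>= 0.95)."""
    sizes = ExperimentSizes(
        n_transcripts=4, length=40, site_offset=20,
        coverage_treat=150, coverage_ctrl=150, editing_ratio=0.8,
    )
    n_true = n_itype = 0
    for seed in range(10):
        treat_spec, ctrl_spec = training_specs(seed, sizes)
        treat_reads, truth = simulate_reads(treat_spec)
        ctrl_reads, _ = simulate_reads(ctrl_spec)
        ases = find_ases(
            pileup_from_reads(treat_reads, "t"),
            pileup_from_reads(ctrl_reads, "c"),
            CFG,
        )
        sites = [EditingSite(s.transcript_id, s.pos, "A") for s in treat_spec.sites]
        labels = separate_reads(sites, ases, treat_reads, CFG)
        itype = labels[labels["label"] == I_TYPE]
        merged = itype.merge(truth, on=["read_id", "transcript_id", "pos"])
        n_itype += len(itype)
        n_true += int(merged["edited"].sum())
    assert n_itype > 100
    assert n_true / n_itype >= 0.95
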