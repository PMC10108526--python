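"""End-to-end experiment drivers on synthetic data.

These functions wire the full chain together — simulate a treatment
(editing-competent) and a control sample, discover sites, find
systematic errors, label reads, extract features, train the classifier
and evaluate — with one integer seed controlling every source of
randomness. They are the programmatic analogue of running the CLI
stages in order, and are used by the test-suite and the reproduction
script.

The default experiment simulates single-site transcripts with a true
per-site editing ratio of 0.8 in the treatment sample, so that all
three qualifying error offsets (-1, 0, +1) can clear the 0.1
error-ratio floor and the labeled I-type reads carry miscalls at a mix
of offsets rather than only at the site itself. The null variant keeps
the same editing structure but removes its observable consequences
(zero signal shift, no editing-correlated miscalls); systematic-error
discovery then correctly finds nothing, so the null pipeline trains on
simulator truth labels, whose feature distributions are identical
between classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aggregate import PhasingMatrix, phase_reads, summarize_sites
from .config import RunConfig
from .features import DEFAULT_FEATURES, FeatureMatrix, extract_features
from .io import EditingSite, EventRead
from .labeling import I_TYPE, find_ases, separate_reads
from .model import ReadEditingClassifier, evaluate_auc
from .simulate import (
    SimulationSpec,
    SiteSpec,
    TranscriptSpec,
    pileup_from_reads,
    short_read_pileup,
    simulate_reads,
)
from .sites import call_editing_sites


def derive_seeds(seed: int, n: int) -> List[int]:
    """Independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n, dtype=np.uint64)]


@dataclass
class ExperimentSizes:
    """Problem sizes of the default synthetic experiment."""

    n_transcripts: int = 25
    length: int = 160
    site_offset: int = 80
    coverage_treat: int = 250
    coverage_ctrl: int = 200
    editing_ratio: float = 0.8


def training_specs(
    seed: int, sizes: ExperimentSizes | None = None, null: bool = False
) -> Tuple[SimulationSpec, SimulationSpec]:
    """Matched treatment / control simulation specs for one experiment."""
    sizes = sizes or ExperimentSizes()
    s_treat, s_ctrl = derive_seeds(seed, 2)
    transcripts = [
        TranscriptSpec(f"tx{i:03d}", length=sizes.length)
        for i in range(sizes.n_transcripts)
    ]
    sites = [
        SiteSpec(t.transcript_id, sizes.site_offset, sizes.editing_ratio)
        for t in transcripts
    ]
    common = {}
    if null:
        common = {"headline_shift": 0.0, "edit_error_probs": {}}
    treat = SimulationSpec(
        transcripts=transcripts,
        sites=sites,
        coverage=sizes.coverage_treat,
        read_prefix="t",
        seed=s_treat,
        **common,
    )
    # the control sample carries the same sites at ratio 0 so both
    # samples resolve identical transcript sequences
    ctrl = SimulationSpec(
        transcripts=transcripts,
        sites=[SiteSpec(s.transcript_id, s.pos, 0.0) for s in sites],
        coverage=sizes.coverage_ctrl,
        read_prefix="c",
        seed=s_ctrl,
        **common,
    )
    return treat, ctrl


@dataclass
class EndToEndResult:
    """Everything the end-to-end run produced, for inspection and reuse."""

    auc: float
    model: ReadEditingClassifier
    cfg: RunConfig
    sites: List[EditingSite]
    labels: pd.DataFrame
    features: FeatureMatrix
    y: np.ndarray
    n_positive: int
    n_negative: int
    labeling_precision: float
    labeling_recall: float
    treat_reads: List[EventRead] = field(repr=False, default_factory=list)
    ctrl_reads: List[EventRead] = field(repr=False, default_factory=list)
    truth: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def run_end_to_end(
    seed: int,
    feature_set: Sequence[str] = DEFAULT_FEATURES,
    null: bool = False,
    sizes: ExperimentSizes | None = None,
    cfg: RunConfig | None = None,
    model_params: Optional[dict] = None,
    keep_reads: bool = False,
) -> EndToEndResult:
    """Simulate, label, featurize, train; report held-out AUC.

    Positive examples are I-type treatment reads (or truth-edited reads
    in the null variant, where no systematic errors exist by
    construction); negatives are control-sample reads at the same
    sites.
    """
    sizes = sizes or ExperimentSizes()
    cfg = cfg or RunConfig()
    _, _, s_model = derive_seeds(seed, 3)
    treat_spec, ctrl_spec = training_specs(seed, sizes, null=null)
    treat_reads, truth = simulate_reads(treat_spec)
    ctrl_reads, _ = simulate_reads(ctrl_spec)

    site_pairs: List[Tuple[str, int]]
    if null:
        sites = []
        labels = pd.DataFrame(columns=["read_id", "transcript_id", "pos", "label"])
        site_pairs = sorted(
            {(s.transcript_id, s.pos) for s in treat_spec.sites}
        )
        pos_pairs = truth[truth["edited"]][["read_id", "transcript_id", "pos"]]
        precision = recall = float("nan")
    else:
        # site discovery runs on short-read-style tables (the published
        # workflow calls sites from Illumina data); systematic-error
        # discovery compares the nanopore base-calls of the two samples
        s_sr_treat, s_sr_ctrl = derive_seeds(seed + 101, 2)
        sr_treat = short_read_pileup(
            treat_spec, "treat_sr", depth=max(cfg.coverage_site * 2, 100), seed=s_sr_treat
        )
        sr_ctrl = short_read_pileup(
            ctrl_spec, "ctrl_sr", depth=max(cfg.coverage_site * 2, 100), seed=s_sr_ctrl
        )
        sites = call_editing_sites([sr_treat], [sr_ctrl], cfg=cfg)
        treat_pileup = pileup_from_reads(treat_reads, "treat")
        ctrl_pileup = pileup_from_reads(ctrl_reads, "ctrl")
        window_positions = {
            (s.transcript_id, s.pos + off) for s in sites for off in (-1, 0, 1)
        }
        ases = find_ases(treat_pileup, ctrl_pileup, cfg, positions=window_positions)
        labels = separate_reads(sites, ases, treat_reads, cfg)
        site_pairs = sorted({(s.transcript_id, s.pos) for s in sites})
        pos_pairs = labels[labels["label"] == I_TYPE][
            ["read_id", "transcript_id", "pos"]
        ]
        merged = pos_pairs.merge(truth, on=["read_id", "transcript_id", "pos"], how="left")
        truly = merged["edited"].fillna(False).to_numpy(dtype=bool)
        precision = float(truly.mean()) if len(merged) else float("nan")
        edited_at_labeled = truth.merge(
            pd.DataFrame(site_pairs, columns=["transcript_id", "pos"]),
            on=["transcript_id", "pos"],
        )
        n_edited_truth = int(edited_at_labeled["edited"].sum())
        recall = float(truly.sum() / n_edited_truth) if n_edited_truth else float("nan")

    neg_rows = [
        {"read_id": r.read_id, "transcript_id": tx, "pos": p}
        for r in ctrl_reads
        for tx, p in site_pairs
        if tx == r.transcript_id
    ]
    neg_pairs = pd.DataFrame(neg_rows, columns=["read_id", "transcript_id", "pos"])

    pairs = pd.concat(
        [pos_pairs.assign(y=1), neg_pairs.assign(y=0)], ignore_index=True
    )
    feats = extract_features(
        list(treat_reads) + list(ctrl_reads), site_pairs, feature_set, cfg
    )
    joined = feats.index.reset_index(drop=True).reset_index(names="row")
    joined = joined.merge(pairs, on=["read_id", "transcript_id", "pos"], how="inner")
    X = feats.X[joined["row"].to_numpy()]
    y = joined["y"].to_numpy()
    labeled = FeatureMatrix(
        X=X,
        index=joined[["read_id", "transcript_id", "pos"]].reset_index(drop=True),
        layout=feats.layout,
        n_skipped=feats.n_skipped,
    )

    model = ReadEditingClassifier(
        random_state=s_model, **(model_params or {})
    )
    model.fit(labeled.X, y, feature_layout=labeled.layout)

    return EndToEndResult(
        auc=float(model.heldout_auc_),
        model=model,
        cfg=cfg,
        sites=sites,
        labels=labels,
        features=labeled,
        y=y,
        n_positive=int((y == 1).sum()),
        n_negative=int((y == 0).sum()),
        labeling_precision=precision,
        labeling_recall=recall,
        treat_reads=list(treat_reads) if keep_reads else [],
        ctrl_reads=list(ctrl_reads) if keep_reads else [],
        truth=truth if keep_reads else pd.DataFrame(),
    )


def oracle_predictions(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-(read, site) probabilities taken directly from truth labels."""
    return truth.assign(
        probability=truth["edited"].to_numpy(dtype=float)
    )[["read_id", "transcript_id", "pos", "probability"]]


def ratio_recovery_experiment(
    seed: int,
    ratios: Sequence[float] = (0.0, 0.1, 0.5, 0.9),
    coverage: int = 500,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Recover per-site editing ratios from oracle read labels.

    One single-site transcript per true ratio; per-read probabilities
    come from the simulator truth, so the comparison isolates the
    sampling noise of the generator plus the aggregation rules.
    Returns a DataFrame with true and recovered ratios per site.
    """
    cfg = cfg or RunConfig()
    (s_sim,) = derive_seeds(seed, 1)
    transcripts = [TranscriptSpec(f"rx{i}", length=60) for i in range(len(ratios))]
    sites = [
        SiteSpec(t.transcript_id, 30, r) for t, r in zip(transcripts, ratios)
    ]
    spec = SimulationSpec(
        transcripts=transcripts, sites=sites, coverage=coverage, seed=s_sim
    )
    _, truth = simulate_reads(spec)
    summary = summarize_sites(oracle_predictions(truth), cfg)
    expected = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "pos": [s.pos for s in sites],
            "true_ratio": list(ratios),
        }
    )
    return expected.merge(summary, on=["transcript_id", "pos"])


DEFAULT_PATTERNS: Dict[str, float] = {"00": 0.6, "10": 0.1, "01": 0.25, "11": 0.05}


def phasing_spec(
    seed: int,
    patterns: Dict[str, float] | None = None,
    n_reads: int = 5000,
    null: bool = False,
) -> SimulationSpec:
    """Two-site transcript with an explicit editing-pattern distribution."""
    patterns = patterns or dict(DEFAULT_PATTERNS)
    (s_sim,) = derive_seeds(seed + 7, 1)
    positions = (60, 140)
    marginals = [
        sum(f for p, f in patterns.items() if p[j] == "1") for j in range(2)
    ]
    transcripts = [TranscriptSpec("phx", length=200)]
    sites = [SiteSpec("phx", pos, m) for pos, m in zip(positions, marginals)]
    common = {"headline_shift": 0.0, "edit_error_probs": {}} if null else {}
    return SimulationSpec(
        transcripts=transcripts,
        sites=sites,
        coverage=n_reads,
        phasing_patterns={"phx": patterns},
        read_prefix="p",
        seed=s_sim,
        **common,
    )


def phasing_experiment(
    seed: int,
    patterns: Dict[str, float] | None = None,
    n_reads: int = 5000,
    model: ReadEditingClassifier | None = None,
    feature_set: Sequence[str] = DEFAULT_FEATURES,
    cfg: RunConfig | None = None,
) -> Dict[str, object]:
    """Phase a two-site transcript with oracle labels and, optionally, a model.

    Returns the simulated truth pattern distribution, the oracle-label
    PhasingMatrix, and (when a trained model is supplied) the
    model-prediction PhasingMatrix on the same reads.
    """
    cfg = cfg or RunConfig()
    patterns = patterns or dict(DEFAULT_PATTERNS)
    spec = phasing_spec(seed, patterns, n_reads)
    reads, truth = simulate_reads(spec)
    positions = [s.pos for s in spec.sites]
    oracle = phase_reads(oracle_predictions(truth), "phx", positions, cfg)
    out: Dict[str, object] = {
        "patterns": patterns,
        "n_reads": n_reads,
        "oracle": oracle,
        "spec": spec,
        "truth": truth,
    }
    if model is not None:
        feats = extract_features(reads, [("phx", p) for p in positions], feature_set, cfg)
        preds = feats.index.copy()
        preds["probability"] = model.editing_probability(feats.X)
        out["model_matrix"] = phase_reads(preds, "phx", positions, cfg)
    return out


def ks_profile_experiment(
    seed: int,
    n_transcripts: int = 10,
    coverage: int = 400,
    editing_ratio: float = 0.5,
    headline_shift: float = 1.0,
    length: int = 80,
    cfg: RunConfig | None = None,
):
    """Signal-shift KS profiles at editing sites vs random adenosines.

    Simulates matched treatment/control samples, runs the windowed KS
    test at the true sites and at randomly chosen control adenosines
    well away from any site, and returns both profiles.

    The default read depth of 400 per sample keeps the discrete lattice
    of achievable KS p-values (spacing ~1/coverage) fine relative to
    the resolution of downstream uniformity checks on the control
    profile; at much lower depth, p-value discreteness — not any signal
    difference — dominates a comparison against the uniform
    distribution.
    """
    cfg = cfg or RunConfig()
    sizes = ExperimentSizes(
        n_transcripts=n_transcripts,
        length=length,
        site_offset=length // 2,
        coverage_treat=coverage,
        coverage_ctrl=coverage,
        editing_ratio=editing_ratio,
    )
    treat_spec, ctrl_spec = training_specs(seed + 13, sizes)
    treat_spec.headline_shift = headline_shift
    treat_reads, _ = simulate_reads(treat_spec)
    ctrl_reads, _ = simulate_reads(ctrl_spec)

    from .signal_ks import window_ks_profile
    from .simulate import _resolved_sequence

    sites = [
        EditingSite(s.transcript_id, s.pos, "A") for s in treat_spec.sites
    ]
    rng = np.random.default_rng(derive_seeds(seed + 29, 1)[0])
    controls: List[EditingSite] = []
    for t in treat_spec.transcripts:
        seq = _resolved_sequence(t, treat_spec)
        site_pos = {s.pos for s in treat_spec.sites if s.transcript_id == t.transcript_id}
        a_positions = [
            i
            for i, b in enumerate(seq)
            if b == "A"
            and 5 <= i < len(seq) - 5
            and all(abs(i - sp) > 8 for sp in site_pos)
        ]
        if a_positions:
            pick = int(rng.choice(a_positions))
            controls.append(EditingSite(t.transcript_id, pick, "A"))
    profile_sites = window_ks_profile(sites, treat_reads, ctrl_reads, cfg)
    profile_controls = window_ks_profile(controls, treat_reads, ctrl_reads, cfg)
    return profile_sites, profile_controls
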