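"""Run-wide thresholds and window definitions.

All thresholds trace to the published detection rules: short-read site
calling (coverage >= 50, editing ratio >= 0.1 in every treatment
replicate), signal comparison (coverage >= 30 per sample, window -5..+5),
systematic-error discovery (>= 5 supporting reads, error ratio >= 0.1,
control fold 2), per-read calling (probability >= 0.9), and site-level
aggregation (>= 30 reads else abandoned, edited if ratio >= 0.1).
Coordinates are 0-based transcript positions throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Tuple

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Thresholds and windows used by every pipeline stage.

    Attributes
    ----------
    coverage_site, ratio_site:
        Short-read site calling: minimum depth and minimum editing ratio
        (nG / (nA + nG)) required in every treatment replicate.
    min_alt_reads, min_alt_fraction:
        The frequency-based SNV caller applied per replicate before the
        site-level filters; alt fraction is alt_count / depth.
    coverage_ks, ks_window:
        Per-sample read-count floor and inclusive offset window for the
        two-sample KS signal comparison around a site.
    ase_min_reads, ase_min_ratio, ase_fold:
        Systematic base-calling-error (ASE) discovery: minimum supporting
        reads, minimum error ratio (n_err / depth) in treatment, and the
        fold by which the treatment error ratio must exceed control when
        the error is present in control at all.
    ase_require_all:
        If True a site needs qualifying ASEs at all of offsets -1, 0, +1
        to be used for read labeling; default requires at least one.
    site_spacing_exclude:
        Sites with another editing site within this many nucleotides are
        excluded from read labeling (signal perturbation by neighbours).
    window:
        Inclusive feature window around the edited adenosine; (-3, 2)
        spans the 6-mer used by the classifier.
    length_scale:
        Dwell (raw sample count) is divided by this before modeling.
    use_called_base:
        Encode the base-caller's output (True) or the reference base in
        the one-hot base feature block.
    call_prob:
        A read counts as edited when its predicted probability reaches
        this value.
    site_min_reads, site_edited_ratio:
        Aggregation: sites with fewer reads are abandoned; a site is
        called edited when the predicted editing ratio reaches the floor.
    """

    coverage_site: int = 50
    ratio_site: float = 0.1
    min_alt_reads: int = 5
    min_alt_fraction: float = 0.05
    coverage_ks: int = 30
    ks_window: Tuple[int, int] = (-5, 5)
    ase_min_reads: int = 5
    ase_min_ratio: float = 0.1
    ase_fold: float = 2.0
    ase_require_all: bool = False
    site_spacing_exclude: int = 3
    window: Tuple[int, int] = (-3, 2)
    length_scale: float = 100.0
    use_called_base: bool = True
    call_prob: float = 0.9
    site_min_reads: int = 30
    site_edited_ratio: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "coverage_site ratio_site min_alt_reads min_alt_fraction "
            "coverage_ks ase_min_reads ase_min_ratio ase_fold "
            "site_spacing_exclude length_scale call_prob site_min_reads "
            "site_edited_ratio"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.window
        if hi - lo + 1 != 6 or not lo <= 0 <= hi:
            raise ConfigError("window must span 6 positions including 0")
        klo, khi = self.ks_window
        if not klo <= 0 <= khi:
            raise ConfigError("ks_window must include offset 0")

    @property
    def window_offsets(self) -> range:
        return range(self.window[0], self.window[1] + 1)

    @property
    def ks_offsets(self) -> range:
        return range(self.ks_window[0], self.ks_window[1] + 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        d["ks_window"] = list(self.ks_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("window", "ks_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})
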