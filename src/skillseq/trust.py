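"""Trustworthiness quantification of a classifier's prediction records.

A model is trustworthy when it is confident exactly where it is right.
The *question-answer trust* of one prediction rewards softmax confidence C
on correct answers and penalizes it on wrong ones::

    Q_z = C^alpha        if predicted class == true class
    Q_z = 1 - C^beta     otherwise

with reward/penalty exponents alpha, beta (both default 1).  Aggregating
over the records of a true class z gives the *trust spectrum* T_M(z) (the
sample mean of Q_z — the discrete estimator of the defining integral), and
the prevalence-weighted sum over classes is the *NetTrustScore*::

    NTS = sum_z P(z) * T_M(z),   P(z) = empirical class frequency.

*Trust densities* (Gaussian kernel density estimates of the Q values, also
conditioned on correct/incorrect) are diagnostic curves; they never feed
back into the NTS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .classifier import PredictionRecord
from .sequences import ValidationError

DENSITY_GRID = (-0.2, 1.2, 281)


@dataclass
class TrustConfig:
    alpha: float = 1.0
    beta: float = 1.0
    kde_bandwidth: str | float = "scott"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("alpha and beta must be positive")


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class ClassTrust:
    class_name: str
    q_values: np.ndarray
    q_matched: np.ndarray
    q_mismatched: np.ndarray
    trust_spectrum: float | None
    prevalence: float
    conditional_nts_matched: float | None
    conditional_nts_mismatched: float | None
    density: DensityCurve | None = None
    density_matched: DensityCurve | None = None
    density_mismatched: DensityCurve | None = None


@dataclass
class TrustReport:
    classes: dict[str, ClassTrust]
    nts: float
    config: TrustConfig
    undefined_classes: list[str] = field(default_factory=list)


def question_answer_trust(record: PredictionRecord, cfg: TrustConfig | None = None) -> float:
    """Q_z for one prediction record."""
    cfg = cfg or TrustConfig()
    c = record.confidence
    if c is None or not (0.0 <= c <= 1.0):
        raise ValidationError("record confidence must lie in [0, 1]")
    if record.true_class is None:
        raise ValidationError("record lacks a true class")
    if record.correct:
        return float(c ** cfg.alpha)
    return float(1.0 - c ** cfg.beta)


def trust_density(
    q_values: np.ndarray,
    cfg: TrustConfig | None = None,
    grid: np.ndarray | None = None,
) -> DensityCurve:
    """Gaussian-kernel density estimate of Q values on a fixed grid.

    The grid spans [-0.2, 1.2] so boundary mass at 0 and 1 stays on the
    grid.  Degenerate samples (zero spread) fall back to a narrow fixed
    kernel so a point mass still renders as a peak.
    """
    cfg = cfg or TrustConfig()
    q = np.asarray(q_values, dtype=float)
    if q.size < 2:
        raise ValidationError("need at least two Q values for a density")
    if grid is None:
        grid = np.linspace(*DENSITY_GRID)
    if np.std(q) > 1e-9:  # Q lives in [0, 1]; below this the sample is a point mass
        bw = cfg.kde_bandwidth if isinstance(cfg.kde_bandwidth, str) else (
            cfg.kde_bandwidth / np.std(q, ddof=1))
        kde = sps.gaussian_kde(q, bw_method=bw)
        dens = kde(grid)
    else:
        h = cfg.kde_bandwidth if isinstance(cfg.kde_bandwidth, (int, float)) else 0.02
        dens = np.mean(
            [sps.norm.pdf(grid, loc=v, scale=h) for v in q], axis=0)
    return DensityCurve(grid=grid, density=dens)


def trust_spectrum_and_nts(
    records: list[PredictionRecord],
    cfg: TrustConfig | None = None,
    class_names: list[str] | None = None,
    densities: bool = True,
) -> TrustReport:
    """Per-class trust spectrum, conditional trust, densities and the NTS.

    T_M(z) is the mean Q over records whose *true* class is z; P(z) is the
    empirical prevalence of z; NTS = sum_z P(z) T_M(z).  Conditional NTS is
    the mean Q restricted to correct (matched) and incorrect (mismatched)
    records of z.  Classes with no records are reported as undefined rather
    than silently dropped.
    """
    cfg = cfg or TrustConfig()
    if not records:
        raise ValidationError("need at least one prediction record")
    if class_names is None:
        class_names = sorted({r.true_class for r in records if r.true_class is not None})
    classes: dict[str, ClassTrust] = {}
    undefined: list[str] = []
    n_total = len(records)
    nts = 0.0
    for z in class_names:
        subset = [r for r in records if r.true_class == z]
        q = np.array([question_answer_trust(r, cfg) for r in subset])
        q_m = np.array([question_answer_trust(r, cfg) for r in subset if r.correct])
        q_x = np.array([question_answer_trust(r, cfg) for r in subset if not r.correct])
        prevalence = len(subset) / n_total
        t_m = float(q.mean()) if q.size else None
        if t_m is None:
            undefined.append(z)
        else:
            nts += prevalence * t_m
        entry = ClassTrust(
            class_name=z,
            q_values=q,
            q_matched=q_m,
            q_mismatched=q_x,
            trust_spectrum=t_m,
            prevalence=prevalence,
            conditional_nts_matched=float(q_m.mean()) if q_m.size else None,
            conditional_nts_mismatched=float(q_x.mean()) if q_x.size else None,
        )
        if densities and q.size >= 2:
            entry.density = trust_density(q, cfg)
            if q_m.size >= 2:
                entry.density_matched = trust_density(q_m, cfg)
            if q_x.size >= 2:
                entry.density_mismatched = trust_density(q_x, cfg)
        classes[z] = entry
    return TrustReport(classes=classes, nts=float(nts), config=cfg,
                       undefined_classes=undefined)
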