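"""End-to-end orchestration: simulate -> correlate -> fit, plus the
subset-stability diagnostic.

A single :class:`RunConfig` drives every stage; all randomness flows
from its seed and every container written carries a config echo, so a
rerun with the same config is bit-identical for the deterministic
stages.  The stability check compares SAXS and g2 curves from subsets of
an acquisition pairwise (reduced chi-square with combined errors) — a
stationary sample with no radiation damage passes; drifting dynamics do
not.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import io as vio
from .correlator import (
    G2Result,
    average_accumulators,
    build_lags,
    correlate_multitau,
    flag_bad_pixels,
    normalize,
)
from .dynamics import (
    DiffusionFit,
    Environment,
    G2Fit,
    fit_g2_result,
    fit_tau_vs_q,
    stokes_einstein_radius,
)
from .geometry import qmap_from_rings
from .saxs import SaxsCurve
from .simulate import PhotonEvents, SimulationConfig, brownian_speckle_sequence

logger = logging.getLogger("virusxpcs")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "StageError",
    "StabilityReport",
    "run_pipeline",
    "analyze_events",
    "check_stability",
]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class CorrelatorConfig:
    channels_per_level: int = 8
    levels: int | None = None
    max_lag_fraction: float = 0.25
    flag_bad: bool = True


@dataclass
class FitConfig:
    beta: float | None = None    # None -> use simulation realized beta; nan -> free
    q_max: float = 0.1           # nm^-1
    temperature: float = 279.0   # K
    viscosity: float = 1.520e-3  # Pa s
    label: str = "sample"


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    correlator: CorrelatorConfig = field(default_factory=CorrelatorConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    out_path: str | None = None

    def __post_init__(self) -> None:
        # one seed drives everything; the simulation block inherits it
        self.simulation.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    events: PhotonEvents
    g2_result: G2Result
    g2_fits: G2Fit
    diffusion: DiffusionFit
    r_h: float
    sigma_r_h: float


def analyze_events(
    events: PhotonEvents,
    qmap,
    corr_cfg: CorrelatorConfig | None = None,
) -> G2Result:
    """Correlate a photon stream on a qmap: multi-tau sums, bad-pixel
    flagging, binned normalization."""
    corr_cfg = corr_cfg or CorrelatorConfig()
    lags = build_lags(
        events.n_frames,
        events.frame_rate,
        levels=corr_cfg.levels,
        channels_per_level=corr_cfg.channels_per_level,
        max_lag_fraction=corr_cfg.max_lag_fraction,
    )
    acc = correlate_multitau(events, qmap, lags)
    if corr_cfg.flag_bad:
        flag_bad_pixels(acc)
    return normalize(acc, qmap)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate, correlate, and fit in one reproducible run."""
    stage = "simulate"
    try:
        logger.info("stage=%s config=%s", stage, config.config_hash())
        events = brownian_speckle_sequence(config.simulation)
        qmap = qmap_from_rings(config.simulation.ring_spec)

        stage = "correlate"
        logger.info("stage=%s n_events=%d", stage, events.n_events)
        g2_result = analyze_events(events, qmap, config.correlator)

        stage = "fit"
        beta = config.fit.beta
        if beta is None:
            beta = config.simulation.realized_beta
        elif np.isnan(beta):
            beta = None  # free-beta diagnostics mode
        g2_result.beta_used = beta
        g2_fits = fit_g2_result(g2_result, beta=beta)
        diffusion = fit_tau_vs_q(g2_fits, q_max=config.fit.q_max)
        env = Environment(
            temperature=config.fit.temperature,
            viscosity=config.fit.viscosity,
            label=config.fit.label,
        )
        radius = stokes_einstein_radius(diffusion, env)
    except (ValueError, RuntimeError) as exc:
        raise StageError(stage, str(exc)) from exc

    result = PipelineResult(
        config=config,
        events=events,
        g2_result=g2_result,
        g2_fits=g2_fits,
        diffusion=diffusion,
        r_h=radius.r_h,
        sigma_r_h=radius.sigma_r_h,
    )
    if config.out_path:
        _write_result(config.out_path, result)
    return result


def _write_result(path, result: PipelineResult) -> None:
    import h5py

    vio.write_g2_result(
        path, result.g2_result, group="g2",
        attrs={"config_hash": result.config.config_hash(),
               "seed": result.config.seed},
    )
    with h5py.File(path, "a") as f:
        if "fit" in f:
            del f["fit"]
        g = f.create_group("fit")
        conv = result.g2_fits.converged_entries
        g.create_dataset("q", data=[e.q for e in conv])
        g.create_dataset("tau0", data=[e.tau0 for e in conv])
        g.create_dataset("sigma_tau0", data=[e.sigma_tau0 for e in conv])
        g.attrs["D_m2_per_s"] = result.diffusion.d
        g.attrs["sigma_D"] = result.diffusion.sigma_d
        g.attrs["R_H_nm"] = result.r_h
        g.attrs["sigma_R_H_nm"] = result.sigma_r_h
        g.attrs["q_max_used"] = result.diffusion.q_max_used
        g.attrs["config_echo"] = json.dumps(result.config.to_dict(), default=str)


@dataclass
class StabilityReport:
    """Pairwise reduced chi-square between subset curves; symmetric
    matrices, one for SAXS and one per-Q-summarized for g2."""

    chisq_saxs: np.ndarray | None
    chisq_g2: np.ndarray | None
    threshold: float
    passed: bool


def _chisq_curves(a_val, a_sig, b_val, b_sig) -> float:
    var = a_sig**2 + b_sig**2
    ok = np.isfinite(a_val) & np.isfinite(b_val) & (var > 0)
    if not ok.any():
        return 0.0
    return float(np.mean((a_val[ok] - b_val[ok]) ** 2 / var[ok]))


def check_stability(
    subsets_saxs: list[SaxsCurve] | None = None,
    subsets_g2: list[G2Result] | None = None,
    threshold: float = 2.0,
) -> StabilityReport:
    """Pairwise consistency of SAXS and g2 curves across acquisition
    subsets; passes when every pairwise reduced chi-square (combined
    errors) stays below ``threshold``."""
    chisq_saxs = chisq_g2 = None
    if subsets_saxs:
        n = len(subsets_saxs)
        if n < 2:
            raise ValueError("need >= 2 subsets")
        chisq_saxs = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = subsets_saxs[i], subsets_saxs[j]
                if a.q.size != b.q.size or not np.allclose(a.q, b.q):
                    raise ValueError("subset SAXS curves have mismatched binning")
                chisq_saxs[i, j] = chisq_saxs[j, i] = _chisq_curves(
                    a.intensity, a.sigma_intensity, b.intensity, b.sigma_intensity
                )
    if subsets_g2:
        n = len(subsets_g2)
        if n < 2:
            raise ValueError("need >= 2 subsets")
        chisq_g2 = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = subsets_g2[i], subsets_g2[j]
                if a.g2.shape != b.g2.shape or not np.allclose(a.delays, b.delays):
                    raise ValueError("subset g2 results have mismatched binning")
                # per-pixel population stds are not SEMs; scale to SEM for
                # the comparison
                sa = a.sigma_g2 / np.sqrt(np.maximum(a.n_pixels[:, None], 1))
                sb = b.sigma_g2 / np.sqrt(np.maximum(b.n_pixels[:, None], 1))
                per_q = [
                    _chisq_curves(a.g2[k], sa[k], b.g2[k], sb[k])
                    for k in range(a.g2.shape[0])
                ]
                chisq_g2[i, j] = chisq_g2[j, i] = float(np.max(per_q))
    if chisq_saxs is None and chisq_g2 is None:
        raise ValueError("nothing to compare")
    worst = max(
        float(chisq_saxs.max()) if chisq_saxs is not None else 0.0,
        float(chisq_g2.max()) if chisq_g2 is not None else 0.0,
    )
    return StabilityReport(
        chisq_saxs=chisq_saxs,
        chisq_g2=chisq_g2,
        threshold=threshold,
        passed=worst < threshold,
    )
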