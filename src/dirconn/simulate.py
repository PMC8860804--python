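"""Synthetic multichannel datasets with planted directed coupling.

The generator emulates a two-condition within-subject EEG experiment:
per subject and condition it produces trials of pink (1/f) background
noise per ROI, and in the "memory" condition only it embeds

* phase-lag links: a narrowband carrier (band-filtered noise) in the
  source ROI, and in the destination ROI the same carrier rotated in the
  analytic domain so its instantaneous phase trails by a chosen lag;
  per-sample phase jitter controls the coupling strength (the lagged
  relation holds on a fraction ~= strength of samples, the rest get
  uniform phase noise), which gives direct analytic control of the
  ground-truth directed phase lag index;

* phase-amplitude links: a high-theta carrier in the phase-source ROI
  whose instantaneous phase modulates the gamma-band envelope of the
  amplitude-destination ROI through a von-Mises-shaped bump
  g(dphi) = exp(kappa*(cos(dphi) - 1)), peak 1 at the preferred phase;
  the envelope is (1 - depth) + depth * g, so depth = 0 is a constant
  envelope and depth has a clean meaning in [0, 1].

Planted components are scaled so their RMS is ``noise_snr`` times the
background's RMS within the same band.  An optional instantaneous
(zero-lag) mixing matrix emulates linear source leakage; an optional
artifact fraction marks a contiguous bad segment per trial.  Everything
is driven by one integer seed and is bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import bandpass, wrap_phase
from .source_roi import RoiTable

CONDITIONS = ("memory", "math")


@dataclass(frozen=True)
class PlantedLagLink:
    """Ground-truth directed phase-lag link: dst's phase trails src's by
    ``lag`` radians on a fraction ~``strength`` of samples."""

    src: int
    dst: int
    lag: float
    strength: float
    band: str = "theta"  # which band carries the lagged pair

    def __post_init__(self) -> None:
        if not (-np.pi < self.lag <= np.pi):
            raise ValueError("lag must lie in (-pi, pi]")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("coupling strength must be in [0, 1]")
        if self.band not in ("theta", "gamma"):
            raise ValueError("band must be 'theta' or 'gamma'")


@dataclass(frozen=True)
class PlantedPacLink:
    """Ground-truth phase-amplitude link: the theta phase of
    ``phase_src`` modulates the gamma envelope of ``amp_dst``."""

    phase_src: int
    amp_dst: int
    depth: float
    preferred_phase: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth <= 1.0):
            raise ValueError("modulation depth must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated acquisition: 15 subjects, 2 conditions,
    40 trials of 30 s at 500 Hz, 84 ROIs, high-theta 7-10 Hz and gamma
    30-80 Hz.  Planted link lists default to empty (a null dataset).
    """

    n_subjects: int = 15
    n_rois: int = 84
    n_trials: int = 40
    trial_duration: float = 30.0
    sampling_rate: float = 500.0
    theta_band: tuple[float, float] = (7.0, 10.0)
    gamma_band: tuple[float, float] = (30.0, 80.0)
    planted_dpli_links: tuple[PlantedLagLink, ...] = ()
    planted_pac_links: tuple[PlantedPacLink, ...] = ()
    noise_snr: float = 1.0
    mixing_matrix: np.ndarray | str = "identity"
    artifact_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2.0 * self.gamma_band[1]:
            raise ValueError("sampling_rate must exceed twice the upper gamma edge")
        for band in (self.theta_band, self.gamma_band):
            if not (0.0 < band[0] < band[1]):
                raise ValueError(f"invalid band {band}")
        if not (0.0 <= self.artifact_fraction < 1.0):
            raise ValueError("artifact_fraction must be in [0, 1)")
        if self.noise_snr <= 0:
            raise ValueError("noise_snr must be positive")
        object.__setattr__(
            self, "planted_dpli_links", tuple(self.planted_dpli_links)
        )
        object.__setattr__(self, "planted_pac_links", tuple(self.planted_pac_links))
        for link in self.planted_dpli_links:
            self._check_roi(link.src), self._check_roi(link.dst)
        for link in self.planted_pac_links:
            self._check_roi(link.phase_src), self._check_roi(link.amp_dst)
        if not isinstance(self.mixing_matrix, str):
            mm = np.asarray(self.mixing_matrix, dtype=float)
            if mm.ndim != 2 or mm.shape[1] != self.n_rois:
                raise ValueError(
                    "mixing_matrix must be (n_channels, n_rois) or 'identity'"
                )
            object.__setattr__(self, "mixing_matrix", mm)
        elif self.mixing_matrix != "identity":
            raise ValueError("mixing_matrix string form must be 'identity'")

    def _check_roi(self, i: int) -> None:
        if not (0 <= i < self.n_rois):
            raise ValueError(f"planted link references invalid ROI {i}")

    @property
    def n_samples_per_trial(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))


@dataclass
class SyntheticDataset:
    """Generated signals plus everything needed to score recovery.

    ``signals[(subject, condition)]`` is a list of (n_samples,
    n_channels) trial arrays; ``annotations`` holds trial bounds and
    artifact intervals in seconds; ``truth`` is the planted edge list.
    """

    config: SimulationConfig
    signals: dict[tuple[int, str], list[np.ndarray]]
    annotations: pd.DataFrame
    truth: pd.DataFrame
    roi_table: RoiTable

    def artifacts(self, subject: int, condition: str) -> list[list[tuple[float, float]]]:
        """Per-trial artifact intervals (seconds, trial-relative)."""
        sel = self.annotations[
            (self.annotations.subject == subject)
            & (self.annotations.condition == condition)
            & (self.annotations.label == "artifact")
        ]
        out: list[list[tuple[float, float]]] = [
            [] for _ in range(self.config.n_trials)
        ]
        for row in sel.itertuples():
            out[int(row.trial)].append((float(row.start_s), float(row.stop_s)))
        return out


# ---------------------------------------------------------------------------
# signal primitives


def pink_noise(n: int, rng: np.random.Generator, n_channels: int | None = None) -> np.ndarray:
    """1/f-amplitude noise, unit RMS, via spectral shaping of white noise."""
    shape = (n,) if n_channels is None else (n, n_channels)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale.reshape(-1, *([1] * (len(shape) - 1))), n=n, axis=0)
    return out / out.std(axis=0, keepdims=True)


def narrowband_analytic(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Complex analytic narrowband carrier: band-filtered white noise put
    through the Hilbert transform, normalized to unit RMS real part."""
    x = bandpass(rng.standard_normal((n, 1)), fs, band)[:, 0]
    z = signal.hilbert(x)
    return z / np.sqrt(np.mean(z.real**2))


def _band_for(f_center: float, fs: float) -> tuple[float, float]:
    half_bw = max(0.5, 0.1 * f_center)
    return (max(0.1, f_center - half_bw), min(fs / 2 * 0.95, f_center + half_bw))


def gen_phase_lagged_pair(
    f_center: float,
    lag: float,
    strength: float,
    n: int,
    fs: float,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two real narrowband series where the second's instantaneous phase
    trails the first's by ``lag`` on a fraction ~``strength`` of samples
    (uniform phase noise elsewhere).

    With strength 1 the pair's phase difference is +lag everywhere, so
    the directed phase lag index of x over y is 1 for positive lags;
    with strength 0 the phases are unrelated and the dPLI is ~0.5.
    """
    if not (0.0 < f_center < fs / 2.0):
        raise ValueError("f_center must lie strictly inside (0, fs/2)")
    if not (-np.pi < lag <= np.pi):
        raise ValueError("lag must lie in (-pi, pi]")
    if not (0.0 <= strength <= 1.0):
        raise ValueError("strength must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = narrowband_analytic(n, fs, _band_for(f_center, fs), rng)
    phase_y = np.angle(z) - lag
    jitter_mask = rng.random(n) >= strength
    phase_y = phase_y + jitter_mask * rng.uniform(-np.pi, np.pi, size=n)
    x = z.real
    y = np.abs(z) * np.cos(phase_y)
    return x, y


def vonmises_bump(dphi: np.ndarray, kappa: float = 4.0) -> np.ndarray:
    """Smooth unimodal modulation shape, peak 1 at dphi = 0."""
    return np.exp(kappa * (np.cos(dphi) - 1.0))


def gen_pac_series(
    f_theta: float,
    f_gamma: float,
    depth: float,
    pref_phase: float,
    n: int,
    fs: float,
    seed: int | np.random.Generator | None = None,
    inter_regional: bool = False,
    kappa: float = 4.0,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """A series (or pair) whose gamma-band envelope follows the theta
    phase: envelope = (1 - depth) + depth * g(phi_theta - pref_phase).

    ``inter_regional=True`` returns the (theta carrier, modulated gamma)
    pair for planting the phase and the amplitude in different regions;
    otherwise their sum is returned (local coupling within one region).
    """
    if not (0.0 < f_theta < f_gamma < fs / 2.0):
        raise ValueError("need 0 < f_theta < f_gamma < fs/2")
    if not (0.0 <= depth <= 1.0):
        raise ValueError("modulation depth must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_theta = narrowband_analytic(n, fs, _band_for(f_theta, fs), rng)
    z_gamma = narrowband_analytic(n, fs, _band_for(f_gamma, fs), rng)
    carrier = z_gamma.real / np.abs(z_gamma)  # unit-envelope gamma carrier
    envelope = (1.0 - depth) + depth * vonmises_bump(
        wrap_phase(np.angle(z_theta) - pref_phase), kappa
    )
    gamma = envelope * carrier
    theta = z_theta.real
    if inter_regional:
        return theta, gamma
    return theta + gamma


# ---------------------------------------------------------------------------
# dataset assembly


def _band_rms(noise_col: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    return float(np.sqrt(np.mean(bandpass(noise_col[:, None], fs, band)[:, 0] ** 2)))


def _plant_trial(
    base: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Add the planted coupling components to one trial of background
    noise, scaled to the configured in-band SNR."""
    n, fs = base.shape[0], cfg.sampling_rate
    bands = {"theta": cfg.theta_band, "gamma": cfg.gamma_band}
    out = base.copy()

    by_src: dict[tuple[int, str], list[PlantedLagLink]] = {}
    for link in cfg.planted_dpli_links:
        by_src.setdefault((link.src, link.band), []).append(link)
    for (src, band_name), links in by_src.items():
        band = bands[band_name]
        z = narrowband_analytic(n, fs, band, rng)
        amp = cfg.noise_snr * _band_rms(base[:, src], fs, band)
        out[:, src] += amp * z.real
        for link in links:
            phase_y = np.angle(z) - link.lag
            jitter = rng.random(n) >= link.strength
            phase_y = phase_y + jitter * rng.uniform(-np.pi, np.pi, size=n)
            partner = np.abs(z) * np.cos(phase_y)
            partner /= np.sqrt(np.mean(partner**2))
            amp_d = cfg.noise_snr * _band_rms(base[:, link.dst], fs, band)
            out[:, link.dst] += amp_d * partner

    pac_by_src: dict[int, list[PlantedPacLink]] = {}
    for link in cfg.planted_pac_links:
        pac_by_src.setdefault(link.phase_src, []).append(link)
    f_theta = 0.5 * (cfg.theta_band[0] + cfg.theta_band[1])
    for src, links in pac_by_src.items():
        z_theta = narrowband_analytic(n, fs, cfg.theta_band, rng)
        amp_s = cfg.noise_snr * _band_rms(base[:, src], fs, cfg.theta_band)
        out[:, src] += amp_s * z_theta.real
        for link in links:
            z_gamma = narrowband_analytic(n, fs, cfg.gamma_band, rng)
            carrier = z_gamma.real / np.abs(z_gamma)
            env = (1.0 - link.depth) + link.depth * vonmises_bump(
                wrap_phase(np.angle(z_theta) - link.preferred_phase)
            )
            modulated = env * carrier
            modulated /= np.sqrt(np.mean(modulated**2))
            amp_d = cfg.noise_snr * _band_rms(base[:, link.amp_dst], fs, cfg.gamma_band)
            out[:, link.amp_dst] += amp_d * modulated
    return out


def synthetic_roi_table(n_rois: int = 84, seed: int = 12345) -> RoiTable:
    """A synthetic stand-in atlas table with plausible bilateral MNI-like
    centroids (mm) and L/R-paired abbreviations.

    The centroid geometry is generated, not taken from any published
    atlas; it exists so that distance profiling and adjacency have
    realistic coordinates to work with.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_rois):
        pair = i // 2
        hemi = "L" if i % 2 == 0 else "R"
        x = (1 if hemi == "R" else -1) * rng.uniform(4, 62)
        y, z = rng.uniform(-90, 65), rng.uniform(-45, 70)
        rows.append(
            {
                "roi": i,
                "abbrev": f"ROI{pair:02d}.{hemi}",
                "x": round(x, 1),
                "y": round(y, 1),
                "z": round(z, 1),
                "sources": "",
            }
        )
    return RoiTable(pd.DataFrame(rows))


def gen_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full two-condition dataset described by ``config``.

    Planted links are embedded only in the "memory" condition; the
    "math" condition is background noise with identical statistics.
    Identical configs (same seed) give bit-identical datasets.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples_per_trial
    mixing = None if isinstance(cfg.mixing_matrix, str) else cfg.mixing_matrix
    signals: dict[tuple[int, str], list[np.ndarray]] = {}
    ann_rows = []
    for subj in range(cfg.n_subjects):
        for cond in CONDITIONS:
            trials = []
            for trial in range(cfg.n_trials):
                base = pink_noise(n, rng, cfg.n_rois)
                data = _plant_trial(base, cfg, rng) if cond == "memory" else base
                if mixing is not None:
                    data = data @ mixing.T
                trials.append(data)
                ann_rows.append(
                    {
                        "subject": subj,
                        "condition": cond,
                        "trial": trial,
                        "start_s": 0.0,
                        "stop_s": cfg.trial_duration,
                        "label": "trial",
                    }
                )
                if cfg.artifact_fraction > 0:
                    length = cfg.artifact_fraction * cfg.trial_duration
                    start = rng.uniform(0.0, cfg.trial_duration - length)
                    ann_rows.append(
                        {
                            "subject": subj,
                            "condition": cond,
                            "trial": trial,
                            "start_s": start,
                            "stop_s": start + length,
                            "label": "artifact",
                        }
                    )
            signals[(subj, cond)] = trials
    truth_rows = [
        {
            "src": l.src,
            "dst": l.dst,
            "type": f"phase_lag_{l.band}",
            "parameter": l.lag,
            "strength": l.strength,
        }
        for l in cfg.planted_dpli_links
    ] + [
        {
            "src": l.phase_src,
            "dst": l.amp_dst,
            "type": "pac",
            "parameter": l.preferred_phase,
            "strength": l.depth,
        }
        for l in cfg.planted_pac_links
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["src", "dst", "type", "parameter", "strength"]
    )
    return SyntheticDataset(
        config=cfg,
        signals=signals,
        annotations=pd.DataFrame(
            ann_rows,
            columns=["subject", "condition", "trial", "start_s", "stop_s", "label"],
        ),
        truth=truth,
        roi_table=synthetic_roi_table(cfg.n_rois),
    )


# ---------------------------------------------------------------------------
# plain-text persistence


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write one delimited matrix per subject/condition (trials stacked,
    rows = samples, columns = channels), the annotation table, the
    ground-truth edge list and the ROI table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (subj, cond), trials in ds.signals.items():
        np.savetxt(
            outdir / f"sub{subj:02d}_{cond}.tsv",
            np.vstack(trials),
            delimiter="\t",
            fmt="%.6e",
        )
    ds.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    ds.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    ds.roi_table.to_tsv(outdir / "roi_table.tsv")


def read_dataset(indir: str | Path, config: SimulationConfig) -> SyntheticDataset:
    """Re-assemble a dataset written by :func:`write_dataset` (the config
    supplies trial geometry)."""
    indir = Path(indir)
    n = config.n_samples_per_trial
    signals = {}
    for subj in range(config.n_subjects):
        for cond in CONDITIONS:
            flat = np.loadtxt(indir / f"sub{subj:02d}_{cond}.tsv", delimiter="\t", ndmin=2)
            signals[(subj, cond)] = [
                flat[i * n : (i + 1) * n] for i in range(config.n_trials)
            ]
    return SyntheticDataset(
        config=config,
        signals=signals,
        annotations=pd.read_csv(indir / "annotations.tsv", sep="\t"),
        truth=pd.read_csv(indir / "ground_truth.tsv", sep="\t"),
        roi_table=RoiTable.from_tsv(indir / "roi_table.tsv"),
    )
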