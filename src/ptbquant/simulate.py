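"""Synthetic data with the statistical structure the analyses assume.

Every input the pipeline consumes can be generated here: photobleaching
step-count histograms and intensity traces, footprinting gel lanes, splicing
product band triples and filter-binding isotherms.  The generators are the
sampling counterparts of the fitted models, so parameter-recovery tests can
compare estimates against known ground truth.

Conventions
-----------
* Bound-fluorophore counts are Binomial(n_sites, occupancy) conditioned on
  at least one bound (unbound complexes are invisible on the slide),
  realised by rejection sampling.
* A fluorophore emits a constant per-bin brightness until a geometrically
  distributed bleach time (per-bin bleaching probability ``bleach_rate``),
  so its total emission is approximately exponential with mean
  ``mu_emission``.
* Gel band noise is multiplicative lognormal: densitometry errors scale
  with band intensity.
* Each generator takes an explicit seed and owns a single RNG stream; runs
  are bit-reproducible for a fixed (seed, config).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np

from .binding import BindingIsotherm
from .exceptions import ConfigurationError
from .footprint import LaneProfile
from .smtirf import IntensityTrace, StepCountHistogram

__all__ = [
    "SimConfig",
    "TraceTruth",
    "SplicingBands",
    "simulate_step_histogram",
    "simulate_traces",
    "simulate_emissions",
    "simulate_gel",
    "simulate_splicing",
    "simulate_isotherm",
]


@dataclass
class SimConfig:
    """Ground-truth parameters for the single-molecule generators.

    Defaults mirror the reference acquisition protocol: 500 time bins of
    200 ms, the first 30 bins recording the RNA dye before switching to GFP.

    Parameters
    ----------
    seed : int
        RNG seed; every generator call is reproducible given (seed, config).
    n_sites : int
        True number of specific binding sites n on the RNA.
    occupancy : float
        True fractional occupancy theta, strictly inside (0, 1).
    n_complexes : int
        Number of complexes to simulate.
    mu_emission : float
        Mean total emission per fluorophore (arbitrary units).
    bleach_rate : float
        Per-bin bleaching probability; mean bleach time is 1/bleach_rate bins.
    noise_sd : float
        Per-bin additive Gaussian noise on traces.
    n_bins, bin_ms : int, float
        Acquisition length and bin duration.
    dye_bins : int
        Dye pre-acquisition window; GFP fluorophores start emitting at this
        bin.  The dye window is filled with a constant marker intensity
        above any GFP level so noiseless traces are monotone non-increasing.
    """

    seed: int
    n_sites: int = 4
    occupancy: float = 0.5
    n_complexes: int = 500
    mu_emission: float = 100.0
    bleach_rate: float = 0.02
    noise_sd: float = 0.0
    n_bins: int = 500
    bin_ms: float = 200.0
    dye_bins: int = 30

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError(f"n_sites must be >= 1, got {self.n_sites}")
        if not 0.0 < self.occupancy < 1.0:
            raise ConfigurationError(
                f"occupancy must lie strictly in (0, 1), got {self.occupancy}"
            )
        if self.n_complexes < 0:
            raise ConfigurationError("n_complexes must be non-negative")
        if self.mu_emission <= 0 or self.bleach_rate <= 0 or not 0 < self.bleach_rate <= 1:
            raise ConfigurationError("mu_emission > 0 and 0 < bleach_rate <= 1 required")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_bins < 2 or self.bin_ms <= 0:
            raise ConfigurationError("n_bins >= 2 and bin_ms > 0 required")
        if not 0 <= self.dye_bins < self.n_bins - 1:
            raise ConfigurationError("dye window must leave a usable GFP segment")

    @property
    def brightness(self) -> float:
        """Per-bin brightness of one fluorophore (mu_emission * bleach_rate)."""
        return self.mu_emission * self.bleach_rate


TraceTruth = namedtuple("TraceTruth", "complex_id n_fluorophores bleach_bins")
SplicingBands = namedtuple("SplicingBands", "s57 s56 s67")


def _draw_truncated_binomial(rng: np.random.Generator, n: int, theta: float, size: int) -> np.ndarray:
    """i ~ Binomial(n, theta) | i >= 1, by rejection."""
    out = rng.binomial(n, theta, size=size)
    while True:
        zero = out == 0
        k = int(zero.sum())
        if k == 0:
            return out
        out[zero] = rng.binomial(n, theta, size=k)


def simulate_step_histogram(cfg: SimConfig) -> StepCountHistogram:
    """Draw per-complex bound counts from the truncated binomial law."""
    rng = np.random.default_rng(cfg.seed)
    steps = _draw_truncated_binomial(rng, cfg.n_sites, cfg.occupancy, cfg.n_complexes)
    return StepCountHistogram.from_step_counts(steps)


def simulate_traces(cfg: SimConfig) -> tuple[list[IntensityTrace], list[TraceTruth]]:
    """Simulate stepwise-bleaching intensity traces with ground truth.

    Each complex carries ``i >= 1`` fluorophores (truncated binomial); each
    fluorophore emits ``cfg.brightness`` per bin for a geometric number of
    bins after the dye window, then bleaches.  The dye window is filled with
    a constant marker level above the maximal GFP level.  Gaussian noise of
    sd ``cfg.noise_sd`` is added to every bin.

    Returns (traces, truths); each truth records the hidden fluorophore
    count and the (sorted) bleach bins relative to the GFP segment start.
    """
    rng = np.random.default_rng(cfg.seed)
    segment_len = cfg.n_bins - cfg.dye_bins
    dye_level = 2.0 * cfg.n_sites * cfg.brightness
    traces: list[IntensityTrace] = []
    truths: list[TraceTruth] = []
    for idx in range(cfg.n_complexes):
        m = int(_draw_truncated_binomial(rng, cfg.n_sites, cfg.occupancy, 1)[0])
        # geometric: number of whole bins of emission before bleaching
        lifetimes = rng.geometric(cfg.bleach_rate, size=m)
        y = np.zeros(cfg.n_bins)
        y[: cfg.dye_bins] = dye_level
        gfp = y[cfg.dye_bins:]
        for t in lifetimes:
            gfp[: min(int(t), segment_len)] += cfg.brightness
        if cfg.noise_sd > 0:
            y = y + rng.normal(0.0, cfg.noise_sd, size=cfg.n_bins)
        traces.append(IntensityTrace(f"c{idx:05d}", y, cfg.bin_ms))
        truths.append(
            TraceTruth(
                complex_id=f"c{idx:05d}",
                n_fluorophores=m,
                bleach_bins=tuple(sorted(int(min(t, segment_len)) for t in lifetimes)),
            )
        )
    return traces, truths


def simulate_emissions(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw total emissions from the Erlang mixture directly.

    The continuous idealisation of :func:`simulate_traces`: a complex with
    i fluorophores emits a Gamma(shape=i, mean=i*mu_emission) total.

    Returns (emissions, true_counts).
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _draw_truncated_binomial(rng, cfg.n_sites, cfg.occupancy, cfg.n_complexes)
    emissions = rng.gamma(shape=counts.astype(float), scale=cfg.mu_emission)
    return emissions, counts


def simulate_gel(
    true_ratios: dict[int, float],
    n_background: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
    background_intensity: float = 1000.0,
    cleavage_intensity: float = 200.0,
    lane_scale: float | None = None,
) -> tuple[LaneProfile, LaneProfile]:
    """Simulate a (Cys-less control, tethered-probe) pair of gel lanes.

    The control lane carries ``n_background`` invariant background bands plus
    baseline cleavage bands at the keys of ``true_ratios``; the probe lane
    multiplies each cleavage band by its fold-ratio and the whole lane by a
    global loading factor (``lane_scale``; drawn lognormal around 1 if not
    given).  Probe-lane bands are perturbed with mean-one lognormal noise of
    coefficient of variation ``noise_cv``; the control lane is the noiseless
    reference.
    """
    if not true_ratios:
        raise ConfigurationError("true_ratios must designate at least one cleavage band")
    if any(r < 0 for r in true_ratios.values()):
        raise ConfigurationError("fold-ratios must be non-negative")
    if n_background < 1:
        raise ConfigurationError("need at least one background band")
    rng = np.random.default_rng(seed)
    cleavage_pos = sorted(int(p) for p in true_ratios)
    # background bands interleaved away from cleavage positions
    background_pos: list[int] = []
    pos = min(cleavage_pos) - 40
    while len(background_pos) < n_background:
        if pos not in cleavage_pos:
            background_pos.append(pos)
        pos += 37
    if lane_scale is None:
        lane_scale = float(rng.lognormal(0.0, 0.2))
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))

    def noisy(x: float) -> float:
        if sigma == 0:
            return x
        return float(x * rng.lognormal(-sigma * sigma / 2.0, sigma))

    control_bands = {p: background_intensity for p in background_pos}
    control_bands.update({p: cleavage_intensity for p in cleavage_pos})
    probe_bands = {p: noisy(lane_scale * background_intensity) for p in background_pos}
    probe_bands.update(
        {p: noisy(lane_scale * cleavage_intensity * true_ratios[p]) for p in cleavage_pos}
    )
    bg = frozenset(background_pos)
    control = LaneProfile("control", "Cys-less", control_bands, bg)
    probe = LaneProfile("probe", "probe", probe_bands, bg)
    return control, probe


def simulate_splicing(
    true_skip_pct: float,
    total_signal: float = 1000.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[SplicingBands]:
    """Simulate splicing-product band triples (5-7, 5-6, 6-7).

    The noiseless triple satisfies
    ``100 * s57 / (s57 + 0.5 * (s56 + s67)) == true_skip_pct`` with the
    inclusion signal split equally between the two inclusion-junction
    products.  Gaussian noise of sd ``noise_sd`` is added per band and
    negative intensities are clipped to zero.
    """
    if not 0.0 <= true_skip_pct <= 100.0:
        raise ConfigurationError("true_skip_pct must lie in [0, 100]")
    if total_signal <= 0 or noise_sd < 0 or n_replicates < 1:
        raise ConfigurationError("invalid splicing simulation parameters")
    rng = np.random.default_rng(seed)
    s57 = total_signal * true_skip_pct / 100.0
    inclusion = 2.0 * total_signal * (1.0 - true_skip_pct / 100.0)
    base = np.array([s57, inclusion / 2.0, inclusion / 2.0])
    out = []
    for _ in range(n_replicates):
        bands = base + (rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else 0.0)
        bands = np.clip(bands, 0.0, None)
        out.append(SplicingBands(*map(float, bands)))
    return out


def simulate_isotherm(
    kd_nM: float,
    protein_nM,
    noise_sd: float = 0.0,
    seed: int = 0,
    rna_nM: float = 3.0,
) -> BindingIsotherm:
    """Simulate a single-site filter-binding titration.

    In the protein-excess regime bound/free = [P]/Kd, i.e. the bound
    fraction is [P]/([P] + Kd).  Gaussian noise of sd ``noise_sd`` is added
    to the bound fraction, then clipped into [0, 1).
    """
    if kd_nM <= 0:
        raise ConfigurationError("kd_nM must be positive")
    protein = np.asarray(list(protein_nM), dtype=float)
    if protein.size == 0 or np.any(protein <= 0):
        raise ConfigurationError("protein concentrations must be positive")
    rng = np.random.default_rng(seed)
    f = protein / (protein + kd_nM)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    f = np.clip(f, 0.0, 1.0 - 1e-9)
    return BindingIsotherm(protein_nM=protein, fraction_bound=f, rna_nM=rna_nM)
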