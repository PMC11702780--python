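"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its config block and a seed: the same
(config, seed) pair reproduces the output exactly.  Alongside the data each
generator returns a *truth record* — the generating parameters and the
derived quantities the analysis stages are expected to recover — so
end-to-end tests compare estimates to truth rather than to constants.

Noise models are the simplest ones consistent with each data type: binomial
read sampling for junction counts, multiplicative Gaussian noise on
intensity profiles, additive Gaussian noise on forces and ODs, lognormal
fiber sizes and multinomial fiber-type calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .densitometry import DilutionSeries
from .histomorphometry import FIBER_TYPES, FiberOutline
from .mechanics import (
    FATIGUE_INTERVAL_S,
    FATIGUE_REPETITIONS,
    SOL_FREQUENCIES,
    FatigueTrace,
    ForceFrequencyData,
    sigmoid_eval,
)
from .sarcomere import HALF_MAX_FACTOR, LineProfile, band_model
from .splicing import ExonLocusModel, JunctionRecord

# fiber-type compositions observed in adult mouse TA muscle by genotype
FIBER_TYPE_PROPS_WT = {"I": 0.0, "IIa": 0.1227, "IIx": 0.2326, "IIb": 0.6447}
FIBER_TYPE_PROPS_HOM = {"I": 0.0587, "IIa": 0.2337, "IIx": 0.2491, "IIb": 0.4586}

DEFAULT_LOCUS = ExonLocusModel(
    chrom="2",
    donor_exon_end=100_000,
    pseudoexon_start=100_500,
    pseudoexon_end=100_701,  # 202 bp pseudoexon
    acceptor_exon_start=101_200,
    frame_offset=0,
)


@dataclass
class JunctionSimConfig:
    """Junction-table generator: pseudoexon inclusion evidence plus noise.

    ``inclusion_p`` is the per-transcript probability of pseudoexon
    inclusion (0.945 in the severe model, 0.064 after humanization);
    ``depth`` the number of informative donor-side junction reads;
    ``n_noise_junctions`` spurious 1-2 read junctions removable by the
    min-count filter.
    """

    inclusion_p: float = 0.945
    depth: int = 200
    n_noise_junctions: int = 3
    locus: ExonLocusModel = field(default_factory=lambda: DEFAULT_LOCUS)


@dataclass
class ProfileSimConfig:
    """Phalloidin line-profile generator (positions in um, intensity AU).

    Band shape parameters mirror wild-type EDL values: rectangle width
    1.72 um and edge sigma 0.16986 um give TFL = 1.06 um; sarcomere length
    2.6 um sits mid-way in the 2.4-2.8 um analysis window.  ``bump_height``
    (fraction of amplitude) and ``bump_fwhm`` (fraction of W) add the
    central Z-disk actin bump; ``noise_sigma`` is the multiplicative
    Gaussian noise fraction.
    """

    n_bands: int = 3
    sl: float = 2.6
    width: float = 1.72
    sigma: float = 0.16986
    amplitude: float = 100.0
    baseline: float = 10.0
    bump_height: float = 0.0
    bump_fwhm: float = 0.1
    noise_sigma: float = 0.0
    spacing: float = 0.02
    margin: float = 1.6


@dataclass
class MechanicsSimConfig:
    """Force-frequency generator at a stimulation protocol.

    Default sigmoid (P0min 5, P0max 25, Fhalf 40 Hz, k 8 Hz) over the
    soleus protocol frequencies; ``noise_frac`` scales additive Gaussian
    noise by P0max.
    """

    p0min: float = 5.0
    p0max: float = 25.0
    fhalf: float = 40.0
    k: float = 8.0
    frequencies: tuple[float, ...] = SOL_FREQUENCIES
    noise_frac: float = 0.02


@dataclass
class FatigueSimConfig:
    """Fatigue-trace generator: F_i = F0 * (r + (1-r) * exp(-i/tau)).

    ``r`` is the asymptotic force fraction (the fatigue index when tau is
    much smaller than the protocol length), ``tau`` the decay constant in
    tetani.  Protocol defaults: 74 tetani at 3 s intervals.
    """

    f0: float = 100.0
    r: float = 0.4
    tau: float = 12.0
    repetitions: int = FATIGUE_REPETITIONS
    interval: float = FATIGUE_INTERVAL_S
    frequency: float = 40.0
    noise_frac: float = 0.0


@dataclass
class FiberSimConfig:
    """Fiber-outline generator: regular polygons at lognormal sizes.

    Each fiber is a regular ``n_vertices``-gon scaled so its minimum Feret
    diameter equals a lognormal draw (median exp(mu) um, shape sigma),
    randomly rotated and translated; ``jitter`` adds fractional radial
    vertex noise (breaking the exact min-Feret target).
    """

    n_fibers: int = 200
    mu: float = math.log(38.0)
    sigma: float = 0.25
    n_vertices: int = 6
    jitter: float = 0.0


@dataclass
class FiberTypeSimConfig:
    proportions: dict[str, float] = field(default_factory=lambda: dict(FIBER_TYPE_PROPS_WT))
    n_fibers: int = 500
    n_samples: int = 4


@dataclass
class DilutionSimConfig:
    """Dilution-series generator: OD = intercept + slope * volume + noise.

    Default slopes encode a sample in which nebulin is present at half the
    signal of MHC; ``noise_frac`` scales additive Gaussian noise by the
    mid-series OD of each protein.
    """

    volumes: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    slopes: dict[str, float] = field(
        default_factory=lambda: {"nebulin": 0.5, "titin": 0.8, "MHC": 1.0}
    )
    intercept: float = 0.05
    noise_frac: float = 0.05


def gen_junction_table(
    config: JunctionSimConfig, seed: int
) -> tuple[list[JunctionRecord], dict]:
    """Binomially sampled inclusion/skip junction records plus noise rows."""
    if not 0 <= config.inclusion_p <= 1:
        raise ValueError("inclusion_p must be in [0, 1]")
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    loc = config.locus
    included = int(rng.binomial(config.depth, config.inclusion_p))
    excluded = config.depth - included
    records = []
    if included:
        records.append(
            JunctionRecord(loc.chrom, *loc.inclusion_junction, "+", included)
        )
        records.append(
            JunctionRecord(loc.chrom, *loc.acceptor_side_junction, "+", included)
        )
    if excluded:
        records.append(JunctionRecord(loc.chrom, *loc.skip_junction, "+", excluded))
    span = loc.acceptor_exon_start - loc.donor_exon_end
    for _ in range(config.n_noise_junctions):
        s = loc.donor_exon_end + int(rng.integers(span // 2, 20 * span))
        e = s + int(rng.integers(50, 5000))
        records.append(JunctionRecord(loc.chrom, s, e, "+", int(rng.integers(1, 3))))
    truth = {
        "seed": seed,
        "inclusion_p": config.inclusion_p,
        "depth": config.depth,
        "included": included,
        "excluded": excluded,
        "inclusion_fraction": included / config.depth,
    }
    return records, truth


def gen_pseudoexon_sequence(
    length_bp: int = 202, n_ptcs: int = 2, frame_offset: int = 0, seed: int = 0
) -> tuple[str, dict]:
    """Random coding-like sequence with exactly ``n_ptcs`` in-frame stops.

    Non-stop codons are drawn uniformly from the 61 sense codons; stop
    codons are planted at distinct random in-frame codon positions.  Bases
    outside the codon walk (frame padding, trailing partial codon) are
    drawn from sense codons so they cannot create in-frame stops.
    """
    from .splicing import STOP_CODONS

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    sense = [
        a + b + c
        for a in bases for b in bases for c in bases
        if a + b + c not in STOP_CODONS
    ]
    n_codons = (length_bp - frame_offset) // 3
    if n_ptcs > n_codons:
        raise ValueError("more PTCs requested than codons available")
    ptc_pos = sorted(rng.choice(n_codons, size=n_ptcs, replace=False).tolist())
    codons = [sense[rng.integers(len(sense))] for _ in range(n_codons)]
    for i in ptc_pos:
        codons[i] = sorted(STOP_CODONS)[int(rng.integers(3))]
    prefix = "".join(bases[rng.integers(4)] for _ in range(frame_offset))
    body = "".join(codons)
    tail_len = length_bp - frame_offset - 3 * n_codons
    tail = sense[rng.integers(len(sense))][:tail_len]
    seq = prefix + body + tail
    assert len(seq) == length_bp
    truth = {"seed": seed, "frame_offset": frame_offset, "ptc_codon_indices": ptc_pos}
    return seq, truth


def gen_line_profile(config: ProfileSimConfig, seed: int = 0) -> tuple[LineProfile, dict]:
    """Periodic phalloidin band profile from the rectangle + half-Gaussian model."""
    if config.n_bands < 1:
        raise ValueError("need at least one band")
    if config.n_bands > 1 and config.sl <= config.width + 4 * config.sigma:
        raise ValueError("bands overlap: require SL > W + 4*sigma")
    rng = np.random.default_rng(seed)
    centers = config.margin + config.sl * np.arange(config.n_bands)
    length = centers[-1] + config.margin
    positions = np.arange(0.0, length + config.spacing / 2, config.spacing)
    y = np.full(positions.shape, config.baseline)
    for c in centers:
        y += band_model(
            positions, c, config.width, config.sigma, config.sigma, config.amplitude, 0.0
        )
        if config.bump_height > 0:
            bump_sigma = config.bump_fwhm * config.width / (2.0 * HALF_MAX_FACTOR)
            y += (
                config.bump_height
                * config.amplitude
                * np.exp(-((positions - c) ** 2) / (2.0 * bump_sigma**2))
            )
    if config.noise_sigma > 0:
        y = y * (1.0 + config.noise_sigma * rng.standard_normal(y.shape))
    tfl = config.width / 2.0 + HALF_MAX_FACTOR * config.sigma
    truth = {
        "seed": seed,
        "centers": centers.tolist(),
        "sl": config.sl,
        "width": config.width,
        "sigma": config.sigma,
        "tfl": tfl,
    }
    return LineProfile(positions=positions, intensities=y), truth


def gen_force_frequency(
    config: MechanicsSimConfig, seed: int = 0
) -> tuple[ForceFrequencyData, dict]:
    rng = np.random.default_rng(seed)
    freqs = np.asarray(config.frequencies, dtype=float)
    clean = sigmoid_eval(freqs, config.p0min, config.p0max, config.fhalf, config.k)
    noisy = clean + config.noise_frac * config.p0max * rng.standard_normal(freqs.shape)
    noisy = np.clip(noisy, 0.0, None)
    truth = {
        "seed": seed,
        "p0min": config.p0min,
        "p0max": config.p0max,
        "fhalf": config.fhalf,
        "k": config.k,
    }
    return ForceFrequencyData(frequencies=freqs, peak_forces=noisy), truth


def gen_fatigue_trace(config: FatigueSimConfig, seed: int = 0) -> tuple[FatigueTrace, dict]:
    rng = np.random.default_rng(seed)
    i = np.arange(config.repetitions, dtype=float)
    forces = config.f0 * (config.r + (1.0 - config.r) * np.exp(-i / config.tau))
    if config.noise_frac > 0:
        forces = forces * (1.0 + config.noise_frac * rng.standard_normal(forces.shape))
        forces = np.clip(forces, 0.0, None)
    truth = {"seed": seed, "r": config.r, "tau": config.tau, "f0": config.f0}
    return (
        FatigueTrace(
            tetanus_peak_forces=forces,
            stimulation_frequency=config.frequency,
            interval=config.interval,
        ),
        truth,
    )


def _regular_polygon_for_min_feret(
    target: float, n_vertices: int
) -> np.ndarray:
    """Regular n-gon (centered at origin) whose min Feret equals ``target``."""
    if n_vertices < 3:
        raise ValueError("need at least 3 vertices")
    half_angle = math.pi / n_vertices
    if n_vertices % 2 == 0:
        radius = target / (2.0 * math.cos(half_angle))  # opposite-edge distance
    else:
        radius = target / (1.0 + math.cos(half_angle))  # vertex-to-opposite-edge
    theta = 2.0 * math.pi * np.arange(n_vertices) / n_vertices
    return radius * np.column_stack([np.cos(theta), np.sin(theta)])


def gen_fiber_outlines(config: FiberSimConfig, seed: int = 0) -> tuple[list[FiberOutline], dict]:
    """Lognormally sized polygon outlines with known min-Feret targets."""
    rng = np.random.default_rng(seed)
    targets = rng.lognormal(config.mu, config.sigma, size=config.n_fibers)
    outlines = []
    for i, t in enumerate(targets):
        v = _regular_polygon_for_min_feret(float(t), config.n_vertices)
        if config.jitter > 0:
            v = v * (1.0 + config.jitter * rng.standard_normal((len(v), 1)))
        phi = rng.uniform(0, 2 * math.pi)
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        v = v @ rot.T + rng.uniform(0, 2000, size=2)
        outlines.append(FiberOutline(fiber_id=f"fiber_{i:04d}", vertices=v))
    truth = {"seed": seed, "min_feret_targets": targets.tolist()}
    return outlines, truth


def gen_fiber_type_calls(config: FiberTypeSimConfig, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Multinomial fiber-type call table (sample_id, fiber_id, type)."""
    props = np.array([config.proportions.get(t, 0.0) for t in FIBER_TYPES])
    # published compositions carry rounding error; renormalize within 0.5%
    if not math.isclose(props.sum(), 1.0, abs_tol=5e-3):
        raise ValueError("type proportions must sum to 1")
    props = props / props.sum()
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(config.n_samples):
        counts = rng.multinomial(config.n_fibers, props)
        fid = 0
        for t, c in zip(FIBER_TYPES, counts):
            for _ in range(c):
                rows.append({"sample_id": f"sample_{s}", "fiber_id": f"f{fid:05d}", "type": t})
                fid += 1
    truth = {"seed": seed, "proportions": dict(zip(FIBER_TYPES, props.tolist()))}
    return pd.DataFrame(rows), truth


def gen_dilution_series(
    config: DilutionSimConfig, seed: int = 0, sample_id: str = "sample_0"
) -> tuple[list[DilutionSeries], dict]:
    """Linear OD-vs-volume series per protein, one sample."""
    rng = np.random.default_rng(seed)
    vols = np.asarray(config.volumes, dtype=float)
    series = []
    for protein, slope in config.slopes.items():
        clean = config.intercept + slope * vols
        noise_sd = config.noise_frac * slope * float(vols.mean())
        od = np.clip(clean + noise_sd * rng.standard_normal(vols.shape), 0.0, None)
        series.append(
            DilutionSeries(sample_id=sample_id, protein=protein, loading_volumes=vols, od_values=od)
        )
    truth = {"seed": seed, "slopes": dict(config.slopes), "intercept": config.intercept}
    return series, truth


def config_record(config) -> dict:
    """Serializable dict of a generator config block (for truth sidecars)."""
    d = asdict(config)
    if "locus" in d:
        d["locus"] = asdict(config.locus) if hasattr(config.locus, "__dataclass_fields__") else d["locus"]
    return d
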