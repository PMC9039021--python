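"""Synthetic two-channel dPCR experiments with known ground truth.

The generator emulates the statistical structure a digital-PCR rare-variant
analysis assumes: Poisson partition occupancy of mutant (FAM) and wild-type
(HEX) templates, well-separated negative/positive fluorescence clouds with a
configurable "rain" fraction between them, rare spurious FAM-positive
artifact droplets (probe degradation), optional cross-hybridisation of the
mutant probe to the wild-type allele, and a stochastic limited-cycle
preamplification modelled as a per-molecule Bernoulli branching process.

The amplitude model is parametric (Gaussian clouds); it does not attempt to
reproduce PCR chemistry kinetics, droplet coalescence or optical crosstalk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .droplet_io import DropletRecord
from .errors import InvalidParameterError

__all__ = [
    "SimConfig",
    "SimTruth",
    "ExperimentResult",
    "DROPLET_GEOMETRY",
    "NANOPLATE_GEOMETRY",
    "DROPLET_CLOUDS",
    "NANOPLATE_CLOUDS",
    "simulate_preamp",
    "simulate_well",
    "simulate_experiment",
]

# (n_partitions, partition_volume_nl)
DROPLET_GEOMETRY = (20_000, 0.85)
NANOPLATE_GEOMETRY = (8_500, 1.34)

# ((fam_mean, fam_sd), (hex_mean, hex_sd)) in RFU, chosen so the platform
# thresholds (2000/1500 droplet, 40/20 nanoplate) fall between the clouds.
DROPLET_CLOUDS = {
    "neg": ((900.0, 180.0), (600.0, 140.0)),
    "pos": ((5500.0, 450.0), (3800.0, 350.0)),
}
NANOPLATE_CLOUDS = {
    "neg": ((15.0, 5.0), (8.0, 3.0)),
    "pos": ((120.0, 15.0), (60.0, 8.0)),
}

Cloud = tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dPCR experiment.

    Concentrations are copies/µl in the template loaded into preamplification
    (the "starting sample"); ``sample_volume_ul`` µl of it enters each
    replicate reaction.  Defaults reproduce the optimised protocol's
    operating point: 8 preamplification cycles with a per-cycle efficiency
    calibrated so the expected per-molecule amplification factor is ~24.2,
    droplet-platform geometry, a small rain fraction and roughly one
    spurious FAM droplet per 20,000 partitions.
    """

    conc_mut: float
    conc_wt: float
    sample_volume_ul: float = 5.0
    preamp_cycles: int = 8
    preamp_efficiency: float = 0.4887
    n_partitions: int = DROPLET_GEOMETRY[0]
    partition_volume_nl: float = DROPLET_GEOMETRY[1]
    neg_cloud: Cloud = DROPLET_CLOUDS["neg"]
    pos_cloud: Cloud = DROPLET_CLOUDS["pos"]
    rain_fraction: float = 0.02
    fp_artifact_rate: float = 5e-5
    cross_hyb_rate: float = 0.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_mut < 0 or self.conc_wt < 0:
            raise InvalidParameterError("concentrations must be >= 0")
        if self.sample_volume_ul <= 0:
            raise InvalidParameterError("sample_volume_ul must be > 0")
        if self.preamp_cycles < 0 or int(self.preamp_cycles) != self.preamp_cycles:
            raise InvalidParameterError("preamp_cycles must be an integer >= 0")
        for name in ("preamp_efficiency", "rain_fraction", "fp_artifact_rate", "cross_hyb_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_partitions < 1:
            raise InvalidParameterError("n_partitions must be >= 1")
        if self.partition_volume_nl <= 0:
            raise InvalidParameterError("partition_volume_nl must be > 0")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        for ch in (0, 1):
            if self.pos_cloud[ch][0] <= self.neg_cloud[ch][0]:
                raise InvalidParameterError(
                    "positive cloud mean must exceed negative cloud mean per channel"
                )

    @property
    def true_vaf(self) -> float:
        """Mutant allele fraction in the template (0 when no template)."""
        total = self.conc_mut + self.conc_wt
        return self.conc_mut / total if total > 0 else 0.0

    @classmethod
    def for_platform(cls, platform: str, conc_mut: float, conc_wt: float, **kwargs) -> "SimConfig":
        """Config with the geometry and amplitude clouds of a named platform
        (``"droplet"``/``"qx200"`` or ``"nanoplate"``/``"qiacuity"``)."""
        if platform in ("droplet", "qx200"):
            geom, clouds = DROPLET_GEOMETRY, DROPLET_CLOUDS
        elif platform in ("nanoplate", "qiacuity"):
            geom, clouds = NANOPLATE_GEOMETRY, NANOPLATE_CLOUDS
        else:
            raise InvalidParameterError(f"unknown platform {platform!r}")
        base = dict(
            n_partitions=geom[0],
            partition_volume_nl=geom[1],
            neg_cloud=clouds["neg"],
            pos_cloud=clouds["pos"],
        )
        base.update(kwargs)
        return cls(conc_mut=conc_mut, conc_wt=conc_wt, **base)


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment, one entry per replicate."""

    true_vaf: float
    copies_mut_loaded: list[int]
    copies_wt_loaded: list[int]
    post_preamp_mut: list[int]
    post_preamp_wt: list[int]


@dataclass
class ExperimentResult:
    """Replicated simulated wells plus their ground truth."""

    wells: list[list[DropletRecord]]
    truth: SimTruth
    config: SimConfig


def simulate_preamp(k: int, cycles: int, efficiency: float, rng=None) -> int:
    """Stochastic limited-cycle preamplification of ``k`` template molecules.

    Each molecule is copied with probability ``efficiency`` in each cycle
    (Bernoulli branching process), so the expected output is
    ``k * (1 + efficiency) ** cycles``; with ``efficiency == 1`` the process
    is deterministic doubling.  The stochastic form matters at low copy
    number, where per-molecule dropout makes the realised amplification
    factor itself a random variable.
    """
    if k < 0 or int(k) != k:
        raise InvalidParameterError(f"k must be a non-negative integer, got {k!r}")
    if cycles < 0 or int(cycles) != cycles:
        raise InvalidParameterError(f"cycles must be a non-negative integer, got {cycles!r}")
    if not 0.0 <= efficiency <= 1.0:
        raise InvalidParameterError(f"efficiency must be in [0, 1], got {efficiency!r}")
    rng = np.random.default_rng(rng)
    n = int(k)
    for _ in range(int(cycles)):
        if n == 0:
            break
        n += int(rng.binomial(n, efficiency))
    return n


def _sample_amplitudes(
    rng: np.random.Generator,
    positive: np.ndarray,
    neg: tuple[float, float],
    pos: tuple[float, float],
    rain_fraction: float,
    rain_eligible: np.ndarray,
) -> np.ndarray:
    """Draw per-partition amplitudes for one channel.

    Positive partitions draw from the positive Gaussian cloud except for a
    ``rain_fraction`` subset of ``rain_eligible`` ones whose amplitude is
    uniform between (neg mean + 2 sd) and (pos mean − 2 sd).  Amplitudes are
    clipped at zero (RFU cannot be negative).
    """
    n = positive.size
    amps = rng.normal(neg[0], neg[1], size=n)
    n_pos = int(positive.sum())
    if n_pos:
        amps[positive] = rng.normal(pos[0], pos[1], size=n_pos)
    if rain_fraction > 0:
        lo = neg[0] + 2 * neg[1]
        hi = pos[0] - 2 * pos[1]
        candidates = positive & rain_eligible
        is_rain = candidates & (rng.random(n) < rain_fraction)
        n_rain = int(is_rain.sum())
        if n_rain and hi > lo:
            amps[is_rain] = rng.uniform(lo, hi, size=n_rain)
    return np.clip(amps, 0.0, None)


def _simulate_partitions(
    config: SimConfig,
    post_mut: int,
    post_wt: int,
    rng: np.random.Generator,
    well_id: str,
    replicate_id: str,
) -> list[DropletRecord]:
    n = config.n_partitions
    lam_mut = post_mut / n
    lam_wt = post_wt / n
    occ_mut = rng.poisson(lam_mut, size=n) if lam_mut > 0 else np.zeros(n, dtype=int)
    occ_wt = rng.poisson(lam_wt, size=n) if lam_wt > 0 else np.zeros(n, dtype=int)

    fam_true = occ_mut > 0
    # cross-hybridisation: a wild-type-occupied, mutant-free partition fires FAM
    cross = (~fam_true) & (occ_wt > 0) & (rng.random(n) < config.cross_hyb_rate)
    # spontaneous probe-degradation artifacts on remaining mutant-free partitions
    artifact = (~fam_true) & (~cross) & (rng.random(n) < config.fp_artifact_rate)
    fam_pos = fam_true | cross | artifact
    hex_pos = occ_wt > 0

    # rain only affects genuinely template-driven positives; artifact droplets
    # are sporadic high-fluorescence events by construction
    fam = _sample_amplitudes(
        rng, fam_pos, config.neg_cloud[0], config.pos_cloud[0], config.rain_fraction, fam_true
    )
    hexv = _sample_amplitudes(
        rng, hex_pos, config.neg_cloud[1], config.pos_cloud[1], config.rain_fraction, hex_pos
    )
    return [
        DropletRecord(well_id, replicate_id, float(f), float(h))
        for f, h in zip(fam, hexv)
    ]


def simulate_well(config: SimConfig, rng_seed=None) -> tuple[list[DropletRecord], SimTruth]:
    """Simulate a single well: load, preamplify, partition, fluoresce.

    Template loading is Poisson with mean ``conc × sample_volume_ul`` per
    allele; the loaded molecules pass through the branching-process
    preamplification and are then distributed over partitions with Poisson
    occupancy at λ = post-preamplification copies / n_partitions.  Identical
    ``rng_seed`` (and config) gives identical output.
    """
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    load_mut = int(rng.poisson(config.conc_mut * config.sample_volume_ul))
    load_wt = int(rng.poisson(config.conc_wt * config.sample_volume_ul))
    post_mut = simulate_preamp(load_mut, config.preamp_cycles, config.preamp_efficiency, rng)
    post_wt = simulate_preamp(load_wt, config.preamp_cycles, config.preamp_efficiency, rng)
    records = _simulate_partitions(config, post_mut, post_wt, rng, "A01", "rep1")
    truth = SimTruth(
        true_vaf=config.true_vaf,
        copies_mut_loaded=[load_mut],
        copies_wt_loaded=[load_wt],
        post_preamp_mut=[post_mut],
        post_preamp_wt=[post_wt],
    )
    return records, truth


def simulate_experiment(config: SimConfig) -> ExperimentResult:
    """Simulate ``n_replicates`` wells drawn from one template stock.

    The stock (``n_replicates × sample_volume_ul`` µl) holds a Poisson total
    of each allele; molecules are split over replicates multinomially, so
    each replicate's load is marginally binomial with expectation
    ``conc × sample_volume_ul``.  Replicates then amplify and partition
    independently.
    """
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_replicates
    stock_volume = config.sample_volume_ul * n_rep
    weights = np.full(n_rep, 1.0 / n_rep)
    loads = {}
    for allele, conc in (("mut", config.conc_mut), ("wt", config.conc_wt)):
        total = rng.poisson(conc * stock_volume)
        loads[allele] = rng.multinomial(total, weights)

    wells: list[list[DropletRecord]] = []
    post = {"mut": [], "wt": []}
    for i in range(n_rep):
        post_mut = simulate_preamp(int(loads["mut"][i]), config.preamp_cycles,
                                   config.preamp_efficiency, rng)
        post_wt = simulate_preamp(int(loads["wt"][i]), config.preamp_cycles,
                                  config.preamp_efficiency, rng)
        post["mut"].append(post_mut)
        post["wt"].append(post_wt)
        wells.append(
            _simulate_partitions(config, post_mut, post_wt, rng,
                                 well_id=f"A{i + 1:02d}", replicate_id=f"rep{i + 1}")
        )
    truth = SimTruth(
        true_vaf=config.true_vaf,
        copies_mut_loaded=[int(x) for x in loads["mut"]],
        copies_wt_loaded=[int(x) for x in loads["wt"]],
        post_preamp_mut=post["mut"],
        post_preamp_wt=post["wt"],
    )
    return ExperimentResult(wells=wells, truth=truth, config=config)
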