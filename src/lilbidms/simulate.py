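"""Forward model of LILBID spectra of nanodisc samples.

The generator renders what the instrument reports after droplet desorption:
each surviving complex contributes a ladder of Gaussian peaks — one per
retained lipid-adduct count and charge state — on a uniform mass-per-charge
grid, plus droplet-averaging noise.  Laser energy enters through a
dissociation step applied to the solution-state abundances: scaffold
proteins are the first to leave the disc, target subunits are lost more
reluctantly, and lipids are shed most readily, all with logistic
energy dependence.  Every stochastic element takes an explicit seed; there
is no hidden global randomness.

Lipid-adduct model.  The attached-lipid count reported for these spectra is
*defined* operationally: the half-maximum width of the lipid-broadened
scaffold peak minus the bare-protein width, divided by the lipid mass.  The
default ladder therefore plants a discrete-Gaussian adduct-count
distribution with mean λ and standard deviation λ/2.3548, whose half-max
span in count space is exactly λ — so the downstream FWHM counter recovers
the planted number.  A truncated Poisson ladder (mean λ) is available as
``adduct_model="poisson"``; note its half-max span is ≈2.3548·√λ counts, so
the FWHM counter will report that, not λ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp, sqrt
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .complexes import SampleDefinition
from .masses import complex_mass

__all__ = [
    "LASER_ENERGY_RANGE_MJ",
    "FWHM_PER_SIGMA",
    "Spectrum",
    "DissociationParams",
    "SimulationScenario",
    "adduct_weights",
    "dissociate",
    "render_spectrum",
    "simulate_replicates",
    "write_spectrum",
    "read_spectrum",
]

#: Nominal pulse-energy span of the desorption laser (mJ).
LASER_ENERGY_RANGE_MJ = (9.5, 23.0)

#: FWHM of a Gaussian in units of its standard deviation, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * sqrt(2.0 * np.log(2.0))

Stoich = tuple[int, int, int]


@dataclass(frozen=True)
class Spectrum:
    """An ordered (mass-per-charge, intensity) series with run metadata."""

    mz_kda: np.ndarray
    intensity: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz_kda, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or mz.shape != y.shape:
            raise ValueError("grid and intensity must be 1-D arrays of equal length")
        if mz.size < 2 or np.any(np.diff(mz) <= 0):
            raise ValueError("mass-per-charge grid must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz_kda", mz)
        object.__setattr__(self, "intensity", y)
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def step_kda(self) -> float:
        return float(self.mz_kda[1] - self.mz_kda[0])

    def with_intensity(self, y: np.ndarray) -> "Spectrum":
        return Spectrum(self.mz_kda, y, self.metadata)


@dataclass(frozen=True)
class DissociationParams:
    """Logistic laser-energy dependence of per-copy loss probabilities.

    Each class c has p_c(E) = pmax_c / (1 + exp(-(E - mid_c)/slope_c)).
    Defaults keep the ordering p_subunit(E) < p_scaffold(E) <= p_lipid(E)
    over the whole energy range: lipids are shed first, scaffolds leave the
    disc before target subunits dissociate.
    """

    pmax_scaffold: float = 0.7
    mid_scaffold_mj: float = 15.0
    slope_scaffold_mj: float = 2.0
    pmax_subunit: float = 0.25
    mid_subunit_mj: float = 18.0
    slope_subunit_mj: float = 2.0
    pmax_lipid: float = 0.9
    mid_lipid_mj: float = 13.0
    slope_lipid_mj: float = 2.0

    @classmethod
    def none(cls) -> "DissociationParams":
        """No dissociation at any energy."""
        return cls(pmax_scaffold=0.0, pmax_subunit=0.0, pmax_lipid=0.0)

    def _logistic(self, energy_mj: float, pmax: float, mid: float, slope: float) -> float:
        p = pmax / (1.0 + exp(-(energy_mj - mid) / slope))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"dissociation probability {p} outside [0, 1]")
        return p

    def p_scaffold(self, energy_mj: float) -> float:
        return self._logistic(energy_mj, self.pmax_scaffold,
                              self.mid_scaffold_mj, self.slope_scaffold_mj)

    def p_subunit(self, energy_mj: float) -> float:
        return self._logistic(energy_mj, self.pmax_subunit,
                              self.mid_subunit_mj, self.slope_subunit_mj)

    def p_lipid(self, energy_mj: float) -> float:
        return self._logistic(energy_mj, self.pmax_lipid,
                              self.mid_lipid_mj, self.slope_lipid_mj)


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to render one spectrum deterministically.

    ``abundances`` maps solution-state stoichiometries (n, m, k) to particle
    counts (the baseline k is usually 0; attached lipids are added by the
    adduct ladder).  ``lambda_adducts`` is the mean attached-lipid count per
    protein species; ``sigma_inst_kda`` the instrument peak width (Gaussian
    sigma); ``charge_weights`` the relative weight of z = 1, 2, ... (mostly
    singly charged in this technique); ``n_droplets`` the number of averaged
    droplets — additive noise scales as 1/sqrt(n_droplets).
    """

    sample: SampleDefinition
    abundances: Mapping[Stoich, float]
    seed: int
    lambda_adducts: float = 0.0
    sigma_inst_kda: float = 0.05
    charge_weights: Sequence[float] = (0.7, 0.15, 0.1, 0.05)
    laser_mj: float = 10.0
    dissociation: DissociationParams = field(default_factory=DissociationParams.none)
    n_droplets: int = 1200
    noise_amplitude: float = 0.5
    grid_kda: tuple[float, float, float] = (1.0, 200.0, 0.005)
    polarity: str = "anionic"
    replicate_id: int = 0
    adduct_model: str = "fwhm"

    def __post_init__(self) -> None:
        if not self.abundances:
            raise ValueError("abundance map must not be empty")
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        if all(v == 0 for v in self.abundances.values()):
            raise ValueError("at least one abundance must be positive")
        lo, hi = LASER_ENERGY_RANGE_MJ
        if not lo <= self.laser_mj <= hi:
            raise ValueError(f"laser energy must lie within {lo}-{hi} mJ")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.lambda_adducts < 0 or self.sigma_inst_kda <= 0:
            raise ValueError("lambda_adducts >= 0 and sigma_inst_kda > 0 required")
        if self.adduct_model not in ("fwhm", "poisson"):
            raise ValueError("adduct_model must be 'fwhm' or 'poisson'")
        object.__setattr__(self, "abundances", dict(self.abundances))


def adduct_weights(lam: float, k_max: int, model: str = "fwhm") -> np.ndarray:
    """Normalized weights of 0..k_max attached lipids.

    ``"fwhm"``: discrete Gaussian with mean ``lam`` and sigma
    ``lam / 2.3548`` — its half-max span is ``lam`` counts, matching the
    operational definition of the attached-lipid number.  ``"poisson"``:
    truncated Poisson with mean ``lam``.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    j = np.arange(k_max + 1)
    if lam == 0:
        w = np.zeros(k_max + 1)
        w[0] = 1.0
        return w
    if model == "poisson":
        w = stats.poisson.pmf(j, lam)
    elif model == "fwhm":
        w = stats.norm.pdf(j, loc=lam, scale=lam / FWHM_PER_SIGMA)
    else:
        raise ValueError("model must be 'fwhm' or 'poisson'")
    total = w.sum()
    if total <= 0:
        raise ValueError("adduct ladder truncated to zero weight; raise k_max")
    return w / total


def dissociate(
    abundances: Mapping[Stoich, float],
    energy_mj: float,
    params: DissociationParams,
    seed: int,
) -> dict[Stoich, int]:
    """Laser-induced redistribution of complex abundances.

    Each particle of species (n, m, k) independently loses each scaffold
    copy with probability p_scaffold(E), each target subunit with
    p_subunit(E) and each lipid with p_lipid(E).  Released scaffolds and
    target subunits reappear as free monomers (0,1,0) and (1,0,0), so the
    total protein copy number is conserved; shed lipids are not tracked.
    Abundances are treated as particle counts (rounded to integers).
    """
    lo, hi = LASER_ENERGY_RANGE_MJ
    if not lo <= energy_mj <= hi:
        raise ValueError(f"laser energy must lie within {lo}-{hi} mJ")
    p_msp = params.p_scaffold(energy_mj)
    p_sub = params.p_subunit(energy_mj)
    p_lip = params.p_lipid(energy_mj)
    rng = np.random.default_rng(seed)
    out: dict[Stoich, int] = {}

    def add(st: Stoich, count: int) -> None:
        if count > 0 and (st[0] + st[1]) > 0:
            out[st] = out.get(st, 0) + int(count)

    for (n, m, k), raw in sorted(abundances.items()):
        count = int(round(raw))
        if count <= 0:
            continue
        dn = rng.binomial(n, p_sub, size=count) if n and p_sub else np.zeros(count, int)
        dm = rng.binomial(m, p_msp, size=count) if m and p_msp else np.zeros(count, int)
        dk = rng.binomial(k, p_lip, size=count) if k and p_lip else np.zeros(count, int)
        remaining = np.stack([n - dn, m - dm, k - dk], axis=1)
        uniq, counts = np.unique(remaining, axis=0, return_counts=True)
        for (rn, rm, rk), c in zip(uniq, counts):
            add((int(rn), int(rm), int(rk)), int(c))
        add((1, 0, 0), int(dn.sum()))
        add((0, 1, 0), int(dm.sum()))
    return out


def _gaussian(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def render_spectrum(scenario: SimulationScenario) -> Spectrum:
    """Render one spectrum from a scenario (deterministic given the seed).

    The solution abundances are first passed through the dissociation step
    at the scenario's laser energy, then each surviving species contributes
    Gaussian peaks at (M + j·M_lipid)/z for every adduct count j and charge
    state z, weighted by the adduct ladder and the charge-state weights.
    Additive white Gaussian noise with standard deviation
    ``noise_amplitude · max_signal / sqrt(n_droplets)`` emulates droplet
    averaging; negative ordinates are clipped at zero.
    """
    sc = scenario
    lo, hi, step = sc.grid_kda
    grid = np.arange(lo, hi + step / 2, step)
    signal = np.zeros_like(grid)

    post = dissociate(sc.abundances, sc.laser_mj, sc.dissociation, seed=sc.seed)
    if not post:
        raise ValueError("all particles dissociated away; nothing to render")

    lipid = sc.sample.lipid
    lipid_mass = lipid.mass_kda if lipid is not None else 0.0
    z_weights = np.asarray(sc.charge_weights, dtype=float)
    z_weights = z_weights / z_weights.sum()

    for (n, m, k), count in sorted(post.items()):
        base = complex_mass((n, m, k), sc.sample.target, sc.sample.scaffold, lipid)
        lam = sc.lambda_adducts if lipid is not None else 0.0
        ladder_max = max(sc.sample.k_max - k, 0)
        w_adduct = adduct_weights(lam, ladder_max, sc.adduct_model)
        for z, wz in enumerate(z_weights, start=1):
            if wz == 0:
                continue
            for j, wj in enumerate(w_adduct):
                if wj < 1e-12:
                    continue
                center = (base + j * lipid_mass) / z
                if center < lo - 5 * sc.sigma_inst_kda or center > hi + 5 * sc.sigma_inst_kda:
                    continue
                signal += count * wz * wj * _gaussian(grid, center, sc.sigma_inst_kda)

    if sc.noise_amplitude > 0 and signal.max() > 0:
        rng = np.random.default_rng(sc.seed + 1)  # separate stream from dissociation
        sigma_noise = sc.noise_amplitude * signal.max() / sqrt(sc.n_droplets)
        signal = signal + rng.normal(0.0, sigma_noise, size=signal.shape)
    signal = np.clip(signal, 0.0, None)

    meta = {
        "polarity": sc.polarity,
        "laser_mJ": sc.laser_mj,
        "seed": sc.seed,
        "replicate": sc.replicate_id,
    }
    return Spectrum(grid, signal, meta)


def simulate_replicates(
    scenario: SimulationScenario, n_replicates: int, seeds: Sequence[int]
) -> list[Spectrum]:
    """Independent replicate spectra sharing one scenario.

    ``seeds`` must contain ``n_replicates`` distinct values; each replicate
    records its seed and replicate index in the metadata.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(seeds) != n_replicates:
        raise ValueError("need exactly one seed per replicate")
    if len(set(seeds)) != len(seeds):
        raise ValueError("replicate seeds must be distinct")
    return [
        render_spectrum(replace(scenario, seed=int(s), replicate_id=i))
        for i, s in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# Two-column text format
# ---------------------------------------------------------------------------


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write as whitespace-delimited two-column text with ``#`` metadata header."""
    lines = [f"# {key}: {value}" for key, value in spectrum.metadata.items()]
    lines += [
        f"{mz:.6f} {y:.8g}" for mz, y in zip(spectrum.mz_kda, spectrum.intensity)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read the two-column text format; tolerates comment-only headers."""
    metadata: dict[str, object] = {}
    mz, ys = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                value = value.strip()
                for cast in (int, float):
                    try:
                        value = cast(value)
                        break
                    except ValueError:
                        continue
                metadata[key.strip()] = value
            continue
        a, b = line.split()[:2]
        mz.append(float(a))
        ys.append(float(b))
    return Spectrum(np.asarray(mz), np.asarray(ys), metadata)
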