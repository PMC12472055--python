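"""Synthetic 1D 1H-NMR spectrum generator.

Emulates the statistical structure of a cell-count x number-of-scans (NS)
titration experiment on extracted cell metabolomes:

* metabolite signal: sums of Lorentzian lines, peak height proportional to
  cell count (optionally with a saturating recovery term for metabolites
  that are lost disproportionately at low input, e.g. proline/mannose);
* additive i.i.d. Gaussian noise whose *standard deviation* scales as
  1/sqrt(NS / NS_ref) — doubling the number of scans buys a sqrt(2)
  signal-to-noise gain;
* smooth polynomial baseline drift (random per spectrum, independent of
  cell count) plus a residual-water hump centred in the 4.40-5.00 ppm
  region;
* small chemical-shift jitter applied per metabolite (all of a
  metabolite's peaks move together, mimicking pH/ionic-strength shifts);
* a TSP reference singlet at 0 ppm with constant amplitude (an added
  internal standard does not scale with cell count).

The default configuration mirrors the titration design the pipeline is
meant to analyse: cell counts 100k, 200k, 400k, 800k, 1.6M, 3.2M and 5M,
NS in {256, 512, 1024, 2048}, seven replicates per condition, with noise
calibrated so the 100,000-cell condition sits near the detection limit at
the reference NS of 256.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, FormatError
from .io import BinDefinition, PatternFile, Spectrum

# Fixed shape constants of the residual-water hump (centre of the
# 4.40-5.00 ppm exclusion window; width chosen so the hump is negligible
# outside it).
WATER_CENTER_PPM = 4.70
WATER_SIGMA_PPM = 0.10


@dataclass(frozen=True)
class PeakShape:
    """A single Lorentzian line: position, relative height, FWHM (ppm)."""

    center_ppm: float
    relative_amplitude: float
    fwhm_ppm: float

    def __post_init__(self):
        if not self.fwhm_ppm > 0:
            raise ConfigError("fwhm_ppm must be positive")
        if not self.relative_amplitude > 0:
            raise ConfigError("relative_amplitude must be positive")


@dataclass(frozen=True)
class MetaboliteSpec:
    """One metabolite in the simulation library.

    ``per_cell_scale`` is the signal contributed per cell (arbitrary
    units); the peak height of peak k is
    ``per_cell_scale * cell_count * recovery(cell_count) * relative_amplitude_k``.

    ``recovery_half_cells`` models concentration-dependent sample-prep
    loss as a sigmoidal threshold (Hill form with exponent 4):
    recovery(c) = c^4 / (c^4 + recovery_half_cells^4). Half the material
    survives extraction at the half-constant and recovery collapses
    steeply below it — the "present above the threshold count, detected
    only at extremely low levels beneath it" behaviour of labile,
    low-abundance metabolites. The default 0 means full recovery at every
    cell count (signal exactly linear in cells).
    """

    name: str
    peaks: tuple
    per_cell_scale: float
    recovery_half_cells: float = 0.0

    def __post_init__(self):
        if len(self.peaks) == 0:
            raise ConfigError(f"metabolite {self.name!r} needs at least one peak")
        if not self.per_cell_scale > 0:
            raise ConfigError("per_cell_scale must be positive")

    def recovery(self, cell_count: float) -> float:
        if self.recovery_half_cells <= 0:
            return 1.0
        c4 = float(cell_count) ** 4
        return c4 / (c4 + self.recovery_half_cells**4)


def lorentzian(ppm: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian line shape (solution-state NMR line)."""
    half = fwhm / 2.0
    return half * half / ((ppm - center) ** 2 + half * half)


def lorentzian_area(height: float, fwhm: float, left: float, right: float,
                    center: float) -> float:
    """Closed-form integral of a height-normalised Lorentzian over [right, left]."""
    half = fwhm / 2.0
    return height * half * (
        np.arctan((left - center) / half) - np.arctan((right - center) / half)
    )


# --------------------------------------------------------------------------
# default metabolite library and matching pattern file
# --------------------------------------------------------------------------

# (name, abundance, recovery_half_cells, [(ppm, rel_amp, fwhm), ...])
# Abundances are relative; per_cell_scale = 1e-6 * abundance so a unit
# amplitude peak at 400k cells has height ~0.4*abundance. Chemical shifts
# follow standard HMDB assignments for intracellular metabolites; two
# deliberately co-binned pairs (lactate/threonine at ~1.33 ppm and
# proline/mannose at ~3.95 ppm) exercise shared-bin handling. Recovery
# half-constants grade from robust (0: lactate, acetate, glutamate,
# creatine, taurine, glycine, formate) through mild loss (100-250k) to a
# sharp presence/absence threshold between 200k and 400k cells for the
# labile low-abundance species (proline, mannose, acetone, acetoacetate,
# ATP) and NAD weakest of all.
_DEFAULT_LIBRARY = [
    ("isoleucine", 0.6, 150000, [(0.94, 1.0, 0.0020), (1.26, 0.35, 0.0020)]),
    ("leucine", 0.9, 120000, [(0.97, 1.0, 0.0020), (1.71, 0.40, 0.0022)]),
    ("valine", 0.8, 120000, [(1.00, 1.0, 0.0020), (1.04, 0.90, 0.0020), (3.61, 0.20, 0.0020)]),
    ("lactate", 3.0, 0, [(1.33, 1.0, 0.0018), (4.11, 0.35, 0.0020)]),
    ("threonine", 0.7, 150000, [(1.325, 0.9, 0.0020), (4.25, 0.50, 0.0020)]),
    ("alanine", 1.2, 100000, [(1.48, 1.0, 0.0020), (3.78, 0.30, 0.0020)]),
    ("acetate", 1.1, 0, [(1.92, 1.0, 0.0018)]),
    ("proline", 1.2, 300000, [(2.01, 0.50, 0.0022), (3.95, 0.60, 0.0022), (4.14, 0.40, 0.0022)]),
    ("glutamate", 1.5, 0, [(2.08, 0.80, 0.0022), (2.35, 1.0, 0.0022)]),
    ("glutamine", 1.4, 100000, [(2.14, 0.80, 0.0022), (2.45, 1.0, 0.0022)]),
    ("acetone", 1.2, 280000, [(2.23, 1.0, 0.0018)]),
    ("acetoacetate", 1.2, 280000, [(2.28, 1.0, 0.0018), (3.47, 0.30, 0.0020)]),
    ("creatine", 1.6, 0, [(3.04, 1.0, 0.0020), (3.91, 0.70, 0.0020)]),
    ("phosphocholine", 1.3, 100000, [(3.22, 1.0, 0.0020)]),
    ("taurine", 2.0, 0, [(3.25, 1.0, 0.0020), (3.42, 0.90, 0.0020)]),
    ("glycine", 1.8, 0, [(3.56, 1.0, 0.0018)]),
    ("myo-inositol", 1.0, 180000, [(3.28, 0.50, 0.0022), (3.52, 0.60, 0.0022), (4.06, 0.30, 0.0022)]),
    ("mannose", 1.2, 300000, [(3.96, 0.60, 0.0022), (5.18, 0.30, 0.0022)]),
    ("atp", 0.8, 320000, [(6.14, 0.40, 0.0025), (8.27, 0.50, 0.0025), (8.52, 0.60, 0.0025)]),
    ("fumarate", 0.2, 250000, [(6.52, 1.0, 0.0020)]),
    ("tyrosine", 0.5, 200000, [(6.90, 1.0, 0.0022), (7.19, 0.90, 0.0022)]),
    ("histidine", 0.45, 250000, [(7.09, 1.0, 0.0022), (7.82, 0.80, 0.0022)]),
    ("phenylalanine", 0.5, 200000, [(7.33, 0.80, 0.0022), (7.38, 1.0, 0.0022), (7.43, 0.60, 0.0022)]),
    ("nad", 0.4, 500000, [(8.84, 0.50, 0.0025), (9.34, 0.60, 0.0025)]),
    ("formate", 0.4, 0, [(8.46, 1.0, 0.0020)]),
    # unannotated peaks: real spectra carry signals never assigned to a
    # metabolite; these populate the pattern's "unknown" bins.
    ("unknown_1", 0.5, 0, [(0.87, 1.0, 0.0020)]),
    ("unknown_2", 0.8, 0, [(1.18, 1.0, 0.0020)]),
    ("unknown_3", 0.4, 200000, [(2.74, 1.0, 0.0020)]),
    ("unknown_4", 0.6, 0, [(3.11, 1.0, 0.0020)]),
    ("unknown_5", 0.5, 0, [(3.68, 1.0, 0.0020)]),
    ("unknown_6", 0.3, 300000, [(5.32, 1.0, 0.0022)]),
    ("unknown_7", 0.4, 0, [(6.70, 1.0, 0.0022)]),
    ("unknown_8", 0.35, 250000, [(7.65, 1.0, 0.0022)]),
    ("unknown_9", 0.45, 0, [(8.05, 1.0, 0.0025)]),
]


def default_library() -> list:
    """The bundled ~25-metabolite library spanning 0.8-9.4 ppm."""
    return [
        MetaboliteSpec(
            name=name,
            peaks=tuple(PeakShape(c, a, w) for c, a, w in peaks),
            per_cell_scale=1e-6 * abundance,
            recovery_half_cells=float(half),
        )
        for name, abundance, half, peaks in _DEFAULT_LIBRARY
    ]


def default_pattern(half_width: float = 0.012) -> PatternFile:
    """Pattern file matching :func:`default_library`.

    One bin per resolved peak; the two deliberately shared bins merge the
    overlapping lactate/threonine methyl doublets (~1.33 ppm) and the
    proline/mannose ring region (~3.95 ppm). Unannotated peaks get
    "unknown" bins, which CRS filtering removes.
    """
    bins = []
    shared = {
        # peaks at these centres fall inside a shared (co-binned) interval
        ("lactate", 1.33): None,
        ("threonine", 1.325): None,
        ("proline", 3.95): None,
        ("mannose", 3.96): None,
    }
    bins.append(BinDefinition("b_lac_thr", 1.345, 1.310, "lactate/threonine", "M_lac_thr"))
    bins.append(BinDefinition("b_pro_man", 3.975, 3.935, "proline/mannose", "M_pro_man"))
    counter: dict = {}
    for name, _, _, peaks in _DEFAULT_LIBRARY:
        for center, _, _ in peaks:
            if (name, center) in shared:
                continue
            counter[name] = counter.get(name, 0) + 1
            bin_id = f"b_{name}_{counter[name]}".replace("-", "_")
            if name.startswith("unknown"):
                annotation, met_id = "unknown", ""
            else:
                annotation, met_id = name, f"M_{name}".replace("-", "_")
            bins.append(
                BinDefinition(bin_id, center + half_width, center - half_width,
                              annotation, met_id)
            )
    return PatternFile(bins)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Study-design parameters of the simulated titration experiment."""

    library: list = field(default_factory=default_library)
    cell_counts: tuple = (100_000, 200_000, 400_000, 800_000, 1_600_000, 3_200_000, 5_000_000)
    ns_values: tuple = (256, 512, 1024, 2048)
    replicates_per_condition: int = 7
    noise_sigma_ref: float = 0.05
    ns_ref: int = 256
    baseline_degree: int = 5
    baseline_amplitude: float = 2.0
    water_hump_amplitude: float = 5.0
    shift_jitter_sd_ppm: float = 0.002
    ppm_min: float = -0.5
    ppm_max: float = 10.0
    n_points: int = 32768
    tsp_amplitude: float = 2.0
    tsp_fwhm_ppm: float = 0.0012
    seed: int = 0

    def __post_init__(self):
        if not self.ppm_min < self.ppm_max:
            raise ConfigError("ppm_min must be below ppm_max")
        if len(self.cell_counts) == 0 or len(self.ns_values) == 0:
            raise ConfigError("cell_counts and ns_values must be non-empty")
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        if self.replicates_per_condition < 1:
            raise ConfigError("replicates_per_condition must be positive")
        if self.noise_sigma_ref < 0 or self.baseline_amplitude < 0 \
                or self.water_hump_amplitude < 0 or self.shift_jitter_sd_ppm < 0:
            raise ConfigError("noise/baseline/water/jitter amplitudes must be >= 0")
        if self.baseline_degree < 0:
            raise ConfigError("baseline_degree must be >= 0")
        self.cell_counts = tuple(int(c) for c in self.cell_counts)
        self.ns_values = tuple(int(n) for n in self.ns_values)

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)

    def noise_sigma(self, n_scans: int) -> float:
        """Noise SD at a given NS: sigma_ref * sqrt(NS_ref / NS)."""
        return self.noise_sigma_ref * np.sqrt(self.ns_ref / n_scans)


@dataclass
class SpectrumSet:
    """A cohort: spectra plus the design record of each one."""

    spectra: list
    design: pd.DataFrame

    def __post_init__(self):
        if len(self.spectra) != len(self.design):
            raise ConfigError("design length must equal the number of spectra")
        self.design = self.design.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _bernstein_design(u: np.ndarray, degree: int) -> np.ndarray:
    from scipy.special import comb

    cols = [comb(degree, k) * u**k * (1 - u) ** (degree - k) for k in range(degree + 1)]
    return np.column_stack(cols)


def generate_spectrum(
    config: SyntheticConfig,
    cell_count: int,
    n_scans: int,
    seed: int,
    *,
    library: Optional[Sequence[MetaboliteSpec]] = None,
) -> Spectrum:
    """Simulate one spectrum at a given cell count and number of scans.

    intensity(ppm) = sum over metabolites of
    per_cell_scale * cells * recovery(cells) * sum of Lorentzian peaks
    (jittered per metabolite) + baseline + water hump + TSP singlet
    + Gaussian noise with SD ``config.noise_sigma(n_scans)``.
    Identical (config, cell_count, n_scans, seed) gives identical output.
    """
    if cell_count <= 0 or n_scans <= 0:
        raise ConfigError("cell_count and n_scans must be positive")
    lib = list(library if library is not None else config.library)
    rng = np.random.default_rng(seed)
    ppm = config.axis
    y = np.zeros_like(ppm)

    # draw order is fixed so seeds mean the same thing across versions:
    # 1) per-metabolite jitter, 2) baseline coefficients, 3) noise.
    jitter = (
        rng.normal(0.0, config.shift_jitter_sd_ppm, size=len(lib))
        if config.shift_jitter_sd_ppm > 0
        else np.zeros(len(lib))
    )
    for met, dppm in zip(lib, jitter):
        height0 = met.per_cell_scale * cell_count * met.recovery(cell_count)
        for peak in met.peaks:
            y += (height0 * peak.relative_amplitude) * lorentzian(
                ppm, peak.center_ppm + dppm, peak.fwhm_ppm
            )

    if config.baseline_amplitude > 0 and config.baseline_degree >= 0:
        coeffs = rng.uniform(-1.0, 1.0, size=config.baseline_degree + 1)
        u = (ppm - config.ppm_min) / (config.ppm_max - config.ppm_min)
        y += config.baseline_amplitude * (_bernstein_design(u, config.baseline_degree) @ coeffs)

    if config.water_hump_amplitude > 0:
        y += config.water_hump_amplitude * np.exp(
            -0.5 * ((ppm - WATER_CENTER_PPM) / WATER_SIGMA_PPM) ** 2
        )

    if config.tsp_amplitude > 0:
        y += config.tsp_amplitude * lorentzian(ppm, 0.0, config.tsp_fwhm_ppm)

    sigma = config.noise_sigma(n_scans)
    if sigma > 0:
        y += rng.normal(0.0, sigma, size=ppm.size)

    meta = {
        "cell_count": int(cell_count),
        "n_scans": int(n_scans),
        "seed": int(seed),
    }
    return Spectrum(ppm.copy(), y, frequency_mhz=700.0, meta=meta)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-spectrum seeds below 2**31 derived from one seed."""
    ss = np.random.SeedSequence(int(seed))
    return (ss.generate_state(n, dtype=np.uint64) % (2**31)).astype(np.int64)


def generate_titration_cohort(config: SyntheticConfig) -> SpectrumSet:
    """One spectrum per (cell_count x n_scans x replicate).

    Per-spectrum seeds are derived deterministically from ``config.seed``,
    so two calls with the same config produce bit-identical cohorts.
    """
    conditions = [
        (c, ns, r)
        for c in config.cell_counts
        for ns in config.ns_values
        for r in range(config.replicates_per_condition)
    ]
    seeds = _child_seeds(config.seed, len(conditions))
    spectra, rows = [], []
    for (cells, ns, rep), sd in zip(conditions, seeds):
        s = generate_spectrum(config, cells, ns, int(sd))
        s.meta["sample_id"] = f"c{cells}_ns{ns}_r{rep}"
        s.meta["replicate"] = rep
        s.meta["group"] = f"c{cells}"
        spectra.append(s)
        rows.append(
            {
                "sample_id": s.meta["sample_id"],
                "cell_count": cells,
                "n_scans": ns,
                "replicate": rep,
                "group": f"c{cells}",
                "seed": int(sd),
            }
        )
    return SpectrumSet(spectra, pd.DataFrame(rows))


def two_group_cohort(
    config: SyntheticConfig,
    effect: Mapping[str, float],
    n_per_group: int,
    *,
    cell_count: Optional[int] = None,
    n_scans: Optional[int] = None,
) -> SpectrumSet:
    """Two-group cohort for the classification stages.

    Group A draws from the library as-is; group B multiplies the
    ``per_cell_scale`` of the metabolites named in ``effect`` by their
    fold-change. Defaults to the largest cell count and NS of the config.
    """
    names = {m.name for m in config.library}
    for met, fc in effect.items():
        if met not in names:
            raise ConfigError(f"unknown metabolite in effect map: {met!r}")
        if not fc > 0:
            raise ConfigError(f"fold-change for {met!r} must be positive")
    if n_per_group < 1:
        raise ConfigError("n_per_group must be positive")
    cells = int(cell_count if cell_count is not None else max(config.cell_counts))
    ns = int(n_scans if n_scans is not None else max(config.ns_values))
    lib_b = [
        replace(m, per_cell_scale=m.per_cell_scale * float(effect.get(m.name, 1.0)))
        for m in config.library
    ]
    seeds = _child_seeds(config.seed, 2 * n_per_group)
    spectra, rows = [], []
    for i, sd in enumerate(seeds):
        group = "A" if i < n_per_group else "B"
        rep = i % n_per_group
        lib = config.library if group == "A" else lib_b
        s = generate_spectrum(config, cells, ns, int(sd), library=lib)
        s.meta["sample_id"] = f"{group}_r{rep}"
        s.meta["group"] = group
        s.meta["replicate"] = rep
        spectra.append(s)
        rows.append(
            {
                "sample_id": s.meta["sample_id"],
                "cell_count": cells,
                "n_scans": ns,
                "replicate": rep,
                "group": group,
                "seed": int(sd),
            }
        )
    return SpectrumSet(spectra, pd.DataFrame(rows))


# --------------------------------------------------------------------------
# library file format
# --------------------------------------------------------------------------


def read_library(path) -> list:
    """Read a metabolite library from delimited text.

    Columns: name, per_cell_scale, recovery_half_cells, then repeated
    (center_ppm, relative_amplitude, fwhm_ppm) triples.
    """
    path = Path(path)
    lib = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 6 or (len(parts) - 3) % 3 != 0:
            raise FormatError(
                f"{path}:{lineno}: expected name, per_cell_scale, "
                "recovery_half_cells, then (center, amplitude, fwhm) triples"
            )
        try:
            scale = float(parts[1])
            half = float(parts[2])
            vals = [float(v) for v in parts[3:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
        peaks = tuple(
            PeakShape(vals[i], vals[i + 1], vals[i + 2]) for i in range(0, len(vals), 3)
        )
        lib.append(MetaboliteSpec(parts[0], peaks, scale, half))
    if not lib:
        raise FormatError(f"{path}: no metabolite rows found")
    return lib


def write_library(library: Sequence[MetaboliteSpec], path) -> None:
    path = Path(path)
    lines = ["# neutromet metabolite library v1"]
    lines.append("# name, per_cell_scale, recovery_half_cells, (center, amplitude, fwhm)*")
    for m in library:
        row = [m.name, f"{m.per_cell_scale:.10g}", f"{m.recovery_half_cells:.10g}"]
        for p in m.peaks:
            row += [f"{p.center_ppm:.6g}", f"{p.relative_amplitude:.6g}", f"{p.fwhm_ppm:.6g}"]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")
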