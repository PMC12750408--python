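"""Colorant registry, spectral mixing, and the synthetic dye generator.

The registry assigns each colorant a short ESID code, a chemistry pathway
(oxidative vs nonoxidative) and a role:

* ``primary``   - oxidative intermediate; self-oxidizes under peroxide;
* ``coupler``   - oxidative modifier; reacts with a primary to form new
  chromophores (no color on its own);
* ``direct``    - nonoxidative dye; deposits unreacted;
* ``pigment``   - insoluble colorant outside the modeled label space.

**LASM** (linear additive spectral mixing) builds training mixtures for the
nonoxidative branch: an equal-weight (or weighted) mean of preprocessed
pure-component spectra, re-area-normalized.  This is chemically justified
only for nonoxidative dyes, whose components deposit unchanged; oxidative
dyeing forms new chromophores whose bands are absent from every component.

The synthetic generator emulates exactly that distinction so the whole
pipeline is testable without instrument data.  Pseudo-colorants are random
Gaussian peak sets on smooth polynomial baselines.  A simulated
nonoxidative dye is the LASM of its components plus SERS-like nuisance
(smooth multiplicative enhancement jitter and additive noise); a simulated
oxidative dye is a convex blend of that LASM with a *reaction-product*
profile derived deterministically from the sorted component codes, with
blend weight alpha drawn from a configured range — new bands appear and
component bands are attenuated, so linear reconstruction degrades just as
it does for real permanent dyes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DataError, UsageError
from .preprocess import DEFAULT_CONFIG, PreprocessConfig, area_normalize, preprocess
from .spectra import CANONICAL_GRID, Spectrum, SpectrumTable

OXIDATIVE = "oxidative"
NONOXIDATIVE = "nonoxidative"
ROLES = ("primary", "coupler", "direct", "pigment")

#: Instrument-like acquisition grid the generator emits raw spectra on
#: (wider than the analysis window, ~1.5 cm^-1 spacing).
INSTRUMENT_GRID: np.ndarray = np.arange(308.0, 1952.0 + 0.75, 1.5)
INSTRUMENT_GRID.setflags(write=False)


# ---------------------------------------------------------------------------
# registry types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColorantRecord:
    esid: str
    name: str
    pathway: str
    role: str
    modeled: bool = True

    def __post_init__(self):
        if self.pathway not in (OXIDATIVE, NONOXIDATIVE):
            raise UsageError(f"unknown pathway {self.pathway!r}")
        if self.role not in ROLES:
            raise UsageError(f"unknown role {self.role!r}")
        if self.role == "coupler" and self.pathway != OXIDATIVE:
            raise UsageError("couplers are oxidative by definition")
        if self.role == "direct" and self.pathway != NONOXIDATIVE:
            raise UsageError("direct dyes are nonoxidative by definition")


@dataclass(frozen=True)
class MixtureLabel:
    """A set of ESID codes; the empty set means 'No Match'."""

    esids: frozenset = frozenset()

    @classmethod
    def of(cls, *codes: str) -> "MixtureLabel":
        return cls(frozenset(codes))

    @classmethod
    def parse(cls, text: str) -> "MixtureLabel":
        codes = [t.strip() for t in text.split("+") if t.strip()]
        return cls(frozenset(codes))

    @property
    def is_empty(self) -> bool:
        return len(self.esids) == 0

    def __str__(self) -> str:
        return "+".join(sorted(self.esids)) if self.esids else "No Match"

    def __iter__(self):
        return iter(sorted(self.esids))

    def __len__(self) -> int:
        return len(self.esids)


@dataclass(frozen=True)
class DyeProduct:
    """A dye product: a colorant mixture, its pathway, and a color label."""

    product_id: str
    mixture: MixtureLabel
    color: str
    pathway: str
    pathway_override: bool = False  # marketing label contradicts chemistry

    def validate_against(self, library: "ColorantLibrary") -> None:
        pathways = {library[c].pathway for c in self.mixture}
        if not self.pathway_override and pathways and {self.pathway} != pathways:
            if not (self.pathway in pathways and len(pathways) == 1):
                raise UsageError(
                    f"product {self.product_id}: pathway {self.pathway!r} "
                    f"inconsistent with member pathways {sorted(pathways)}"
                )


class ColorantLibrary:
    """ESID-keyed colorant registry."""

    def __init__(self, records: Iterable[ColorantRecord] = ()):
        self._records: dict[str, ColorantRecord] = {}
        for r in records:
            self.add(r)

    def add(self, record: ColorantRecord) -> None:
        if record.esid in self._records:
            raise UsageError(f"duplicate ESID {record.esid!r}")
        self._records[record.esid] = record

    def __getitem__(self, esid: str) -> ColorantRecord:
        try:
            return self._records[esid]
        except KeyError:
            raise LookupError(f"unknown colorant ESID {esid!r}") from None

    def __contains__(self, esid: str) -> bool:
        return esid in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def by_role(self, role: str) -> list[ColorantRecord]:
        if role not in ROLES:
            raise UsageError(f"unknown role {role!r}")
        return [r for r in self._records.values() if r.role == role]

    def modeled_codes(self, pathway: str | None = None) -> list[str]:
        return sorted(
            r.esid
            for r in self._records.values()
            if r.modeled and (pathway is None or r.pathway == pathway)
        )

    def to_csv(self, sink) -> None:
        df = pd.DataFrame(
            [
                {
                    "esid": r.esid,
                    "name": r.name,
                    "pathway": r.pathway,
                    "role": r.role,
                    "modeled": r.modeled,
                }
                for r in self._records.values()
            ]
        )
        df.to_csv(sink, index=False)

    @classmethod
    def from_csv(cls, source) -> "ColorantLibrary":
        df = pd.read_csv(source, dtype=str)
        recs = [
            ColorantRecord(
                esid=row["esid"],
                name=row.get("name", row["esid"]),
                pathway=row["pathway"],
                role=row["role"],
                modeled=str(row.get("modeled", "True")).lower()
                in ("1", "true", "yes"),
            )
            for _, row in df.iterrows()
        ]
        return cls(recs)


# ---------------------------------------------------------------------------
# mixing operations
# ---------------------------------------------------------------------------

def lasm_mix(
    spectra: Sequence[Spectrum],
    weights: Sequence[float] | None = None,
    spectrum_id: str = "",
    sample_id: str = "",
) -> Spectrum:
    """Linear additive spectral mixing: weighted mean, re-area-normalized.

    Equal weights by default.  All spectra must share one grid; weights are
    nonnegative with positive sum (they are homogeneous of degree zero —
    only their proportions matter).
    """
    spectra = list(spectra)
    if not spectra:
        raise UsageError("lasm_mix needs at least one spectrum")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise AlignmentError("lasm_mix inputs must share one grid")
    if weights is None:
        weights = np.ones(len(spectra))
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(spectra):
        raise UsageError("one weight per spectrum required")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise UsageError("weights must be nonnegative with positive sum")
    weights = weights / weights.sum()
    mixed = np.einsum("i,ij->j", weights, np.vstack([s.intensities for s in spectra]))
    return Spectrum(grid, area_normalize(mixed), spectrum_id, sample_id)


def enumerate_primary_coupler_pairs(
    primaries: Sequence[ColorantRecord],
    couplers: Sequence[ColorantRecord],
) -> list[MixtureLabel]:
    """Full Cartesian product of primary x coupler as 2-element mixtures."""
    for p in primaries:
        if p.role != "primary":
            raise UsageError(f"{p.esid} is not a primary")
    for c in couplers:
        if c.role != "coupler":
            raise UsageError(f"{c.esid} is not a coupler")
    return [
        MixtureLabel.of(p.esid, c.esid) for p in primaries for c in couplers
    ]


# ---------------------------------------------------------------------------
# synthetic pseudo-colorant generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticColorantSpec:
    """Gaussian-peak recipe for one pseudo-colorant.

    Peaks live inside the analysis window; the baseline is a polynomial in
    the normalized coordinate u = (wavenumber - 450) / 1200.
    """

    centers: np.ndarray
    widths: np.ndarray
    amplitudes: np.ndarray
    baseline_coeffs: np.ndarray = field(
        default_factory=lambda: np.array([0.0])
    )
    noise_sigma: float = 0.0  # additive, relative to the mean raw intensity
    jitter: float = 0.0  # amplitude of the smooth multiplicative gain

    def __post_init__(self):
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.baseline_coeffs = np.atleast_1d(
            np.asarray(self.baseline_coeffs, dtype=float)
        )
        if not (self.centers.size == self.widths.size == self.amplitudes.size):
            raise UsageError("centers, widths, amplitudes must align")
        if self.centers.size and (
            self.centers.min() <= 450.0 or self.centers.max() >= 1650.0
        ):
            raise UsageError("peak centers must lie inside (450, 1650) cm^-1")
        if np.any(self.widths <= 0):
            raise UsageError("peak widths must be positive")
        if self.noise_sigma < 0 or self.jitter < 0:
            raise UsageError("noise_sigma and jitter must be >= 0")

    def signal(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Clean raw signal: Gaussian peaks on the polynomial baseline."""
        wn = np.asarray(wavenumbers, dtype=float)
        u = (wn - 450.0) / 1200.0
        y = np.polyval(self.baseline_coeffs[::-1], u) * np.ones_like(wn)
        for c, w, a in zip(self.centers, self.widths, self.amplitudes):
            y = y + a * np.exp(-0.5 * ((wn - c) / w) ** 2)
        return y


def random_colorant_spec(
    rng: np.random.Generator,
    n_peaks_range: tuple[int, int] = (4, 9),
    width_range: tuple[float, float] = (8.0, 30.0),
    amplitude_range: tuple[float, float] = (0.3, 1.0),
    baseline_scale: float = 0.5,
    noise_sigma: float = 0.0,
    jitter: float = 0.0,
) -> SyntheticColorantSpec:
    """Draw a random pseudo-colorant recipe."""
    n = int(rng.integers(n_peaks_range[0], n_peaks_range[1] + 1))
    centers = rng.uniform(480.0, 1620.0, size=n)
    widths = rng.uniform(*width_range, size=n)
    amps = rng.uniform(*amplitude_range, size=n)
    base = np.array(
        [baseline_scale * rng.uniform(0.5, 1.5), rng.uniform(-0.3, 0.6),
         rng.uniform(-0.3, 0.3)]
    )
    return SyntheticColorantSpec(
        centers, widths, amps, base, noise_sigma=noise_sigma, jitter=jitter
    )


def _smooth_gain(rng: np.random.Generator, wn: np.ndarray, jitter: float) -> np.ndarray:
    """Slowly varying multiplicative enhancement curve, mean ~ 1."""
    if jitter == 0.0:
        return np.ones_like(wn)
    u = (wn - wn[0]) / (wn[-1] - wn[0])
    coeffs = rng.uniform(-1.0, 1.0, size=3)
    curve = coeffs[0] * u + coeffs[1] * np.sin(np.pi * u) + coeffs[2] * np.cos(
        2 * np.pi * u
    )
    gain = 1.0 + jitter * curve
    return np.clip(gain, 0.05, None)


def realize_raw_spectrum(
    spec: SyntheticColorantSpec,
    rng: np.random.Generator,
    wavenumbers: np.ndarray = INSTRUMENT_GRID,
) -> np.ndarray:
    """One noisy raw acquisition of a pseudo-colorant signal."""
    y = spec.signal(wavenumbers)
    y = y * _smooth_gain(rng, wavenumbers, spec.jitter)
    if spec.noise_sigma > 0:
        scale = spec.noise_sigma * max(float(np.mean(np.abs(y))), 1e-12)
        y = y + rng.normal(0.0, scale, size=y.size)
    return y


def generate_colorant_profile(
    spec: SyntheticColorantSpec,
    grid: np.ndarray = CANONICAL_GRID,
    seed: int = 0,
    cfg: PreprocessConfig | None = None,
    spectrum_id: str = "",
    sample_id: str = "",
) -> Spectrum:
    """A preprocessed pseudo-colorant spectrum (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    raw = realize_raw_spectrum(spec, rng)
    s = Spectrum(INSTRUMENT_GRID, raw - raw.min() + 1e-9, spectrum_id, sample_id)
    return preprocess(s, cfg or DEFAULT_CONFIG, grid)


def reaction_product_spec(
    component_esids: Iterable[str],
    n_peaks_range: tuple[int, int] = (5, 10),
) -> SyntheticColorantSpec:
    """Deterministic pseudo reaction-product recipe for an oxidative mix.

    Keyed by a CRC of the sorted component codes, so the same mixture
    always produces the same new-band profile on every platform — the
    reproducible stand-in for coupling chemistry.
    """
    key = "+".join(sorted(component_esids))
    seed = zlib.crc32(key.encode("utf-8"))
    rng = np.random.default_rng(seed)
    return random_colorant_spec(rng, n_peaks_range=n_peaks_range)


# ---------------------------------------------------------------------------
# dye-sample simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Nuisance model for simulated dyed samples (the study conditions).

    ``noise_sigma`` is additive noise relative to the mean raw intensity of
    one acquisition; ``jitter`` is the amplitude of the smooth multiplicative
    enhancement curve (SERS enhancement variability); ``alpha_range`` is the
    convex weight of the reaction-product profile in oxidative dyes.
    """

    noise_sigma: float = 0.05
    jitter: float = 0.2
    alpha_range: tuple[float, float] = (0.4, 0.7)


DEFAULT_SIMULATION = SimulationConfig()


class SpectralLibrary:
    """Pairs a colorant registry with clean pseudo-colorant profiles."""

    def __init__(
        self,
        library: ColorantLibrary,
        specs: dict[str, SyntheticColorantSpec],
        grid: np.ndarray = CANONICAL_GRID,
    ):
        missing = [r.esid for r in library if r.modeled and r.esid not in specs]
        if missing:
            raise LookupError(f"no spectral profile for colorants {missing}")
        self.library = library
        self.specs = specs
        self.grid = np.asarray(grid, dtype=float)
        self._profiles: dict[str, Spectrum] = {}
        self._reaction_cache: dict[frozenset, Spectrum] = {}

    def profile(self, esid: str) -> Spectrum:
        """Clean preprocessed profile of one colorant (cached)."""
        if esid not in self._profiles:
            if esid not in self.specs:
                raise LookupError(f"unknown colorant ESID {esid!r}")
            spec = self.specs[esid]
            clean = SyntheticColorantSpec(
                spec.centers, spec.widths, spec.amplitudes,
                spec.baseline_coeffs, noise_sigma=0.0, jitter=0.0,
            )
            self._profiles[esid] = generate_colorant_profile(
                clean, self.grid, seed=0, spectrum_id=esid, sample_id=esid
            )
        return self._profiles[esid]

    def lasm_reconstruction(self, mixture: MixtureLabel) -> Spectrum:
        """Equal-weight LASM of the mixture's clean component profiles."""
        return lasm_mix([self.profile(c) for c in mixture])

    def reaction_profile(self, mixture: MixtureLabel) -> Spectrum:
        if mixture.esids not in self._reaction_cache:
            spec = reaction_product_spec(mixture.esids)
            self._reaction_cache[mixture.esids] = generate_colorant_profile(
                spec, self.grid, seed=0
            )
        return self._reaction_cache[mixture.esids]


def simulate_dye_spectrum(
    product: DyeProduct,
    spectral_library: SpectralLibrary,
    replicate_seed: int,
    sim: SimulationConfig | None = None,
    spectrum_id: str = "",
    sample_id: str = "",
) -> Spectrum:
    """Simulate one SER acquisition of a dyed sample.

    Nonoxidative: LASM of components, then enhancement jitter and noise.
    Oxidative: convex blend ``alpha * reaction_product + (1-alpha) * LASM``
    before the nuisance is applied (alpha ~ U(alpha_range)).
    """
    sim = sim or DEFAULT_SIMULATION
    rng = np.random.default_rng(replicate_seed)
    if product.mixture.is_empty:
        raise UsageError("cannot simulate an empty mixture")
    base = spectral_library.lasm_reconstruction(product.mixture)
    y = base.intensities
    if product.pathway == OXIDATIVE:
        alpha = float(rng.uniform(*sim.alpha_range))
        y = alpha * spectral_library.reaction_profile(product.mixture).intensities + (
            1.0 - alpha
        ) * y
    grid = spectral_library.grid
    y = y * _smooth_gain(rng, grid, sim.jitter)
    if sim.noise_sigma > 0:
        y = y + rng.normal(0.0, sim.noise_sigma * float(np.mean(np.abs(y))), y.size)
    return Spectrum(
        grid, area_normalize(y), spectrum_id or product.product_id, sample_id
    )


def simulate_control_spectrum(
    spectral_library: SpectralLibrary,
    replicate_seed: int,
    sim: SimulationConfig | None = None,
    spectrum_id: str = "NC",
    sample_id: str = "NC",
) -> Spectrum:
    """Undyed control: smooth baseline hump plus nuisance, no colorant bands."""
    sim = sim or DEFAULT_SIMULATION
    rng = np.random.default_rng(replicate_seed)
    grid = spectral_library.grid
    u = (grid - grid[0]) / (grid[-1] - grid[0])
    y = 0.5 + 0.3 * np.sin(np.pi * u)
    y = y * _smooth_gain(rng, grid, sim.jitter)
    y = y + rng.normal(0.0, max(sim.noise_sigma, 0.01) * float(np.mean(y)), y.size)
    return Spectrum(grid, area_normalize(y), spectrum_id, sample_id)


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------

@dataclass
class LabeledTable:
    """A shared-grid table with one label per spectrum."""

    table: SpectrumTable
    labels: list

    def __post_init__(self):
        if len(self.table) != len(self.labels):
            raise UsageError("one label per spectrum required")


@dataclass
class TrainingSets:
    phase1: LabeledTable  # labels: pathway strings
    phase2_nonox: LabeledTable  # labels: MixtureLabel over direct dyes
    phase2_ox_train: LabeledTable  # labels: MixtureLabel over ox colorants
    phase2_ox_test: LabeledTable


def _derive_seed(seed: int, *parts) -> int:
    key = ":".join(str(p) for p in (seed,) + parts)
    return zlib.crc32(key.encode("utf-8")) % (2**31 - 1)


def build_phase1_training(
    spectral_library: SpectralLibrary,
    n_replicates: int = 4,
    seed: int = 0,
    sim: SimulationConfig | None = None,
    include_couplers_alone: bool = True,
) -> LabeledTable:
    """Phase I training set: pure colorants plus all primary x coupler pairs.

    Direct dyes are nonoxidative; primaries (self-oxidized), couplers alone
    (optionally) and every primary x coupler pair are oxidative — the pairs
    carry the composite reaction signatures of oxidative dye formation.
    """
    if n_replicates < 1:
        raise UsageError("n_replicates must be >= 1")
    lib = spectral_library.library
    primaries = lib.by_role("primary")
    couplers = lib.by_role("coupler")
    directs = lib.by_role("direct")

    jobs: list[tuple[MixtureLabel, str]] = []
    jobs += [(MixtureLabel.of(d.esid), NONOXIDATIVE) for d in directs]
    jobs += [(MixtureLabel.of(p.esid), OXIDATIVE) for p in primaries]
    if include_couplers_alone:
        jobs += [(MixtureLabel.of(c.esid), OXIDATIVE) for c in couplers]
    jobs += [
        (pair, OXIDATIVE)
        for pair in enumerate_primary_coupler_pairs(primaries, couplers)
    ]

    spectra, labels = [], []
    for mixture, pathway in jobs:
        product = DyeProduct(f"train_{mixture}", mixture, "n/a", pathway)
        for k in range(n_replicates):
            sid = f"p1_{mixture}_{k}"
            spectra.append(
                simulate_dye_spectrum(
                    product,
                    spectral_library,
                    _derive_seed(seed, "phase1", str(mixture), k),
                    sim,
                    spectrum_id=sid,
                    sample_id=sid,
                )
            )
            labels.append(pathway)
    table = SpectrumTable(spectra, grid=spectral_library.grid)
    return LabeledTable(table, labels)


def build_phase2_nonox_training(
    spectral_library: SpectralLibrary,
    max_subset_size: int = 3,
    n_replicates: int = 3,
    seed: int = 0,
    sim: SimulationConfig | None = None,
) -> LabeledTable:
    """LASM mixtures over all direct-dye subsets up to ``max_subset_size``.

    Each subset contributes noisy replicates (the nuisance model applied to
    the clean LASM) so the multi-label model sees realistic variability.
    """
    directs = [r.esid for r in spectral_library.library.by_role("direct")]
    if not directs:
        raise UsageError("library has no direct dyes")
    if n_replicates < 1:
        raise UsageError("n_replicates must be >= 1")
    spectra, labels = [], []
    for size in range(1, max_subset_size + 1):
        for combo in combinations(sorted(directs), size):
            mixture = MixtureLabel.of(*combo)
            product = DyeProduct(f"syn_{mixture}", mixture, "n/a", NONOXIDATIVE)
            for k in range(n_replicates):
                sid = f"syn_{mixture}_{k}"
                spectra.append(
                    simulate_dye_spectrum(
                        product,
                        spectral_library,
                        _derive_seed(seed, "lasm", str(mixture), k),
                        sim,
                        spectrum_id=sid,
                        sample_id=sid,
                    )
                )
                labels.append(mixture)
    return LabeledTable(SpectrumTable(spectra, grid=spectral_library.grid), labels)


def grouped_train_test_split(
    sample_ids: Sequence[str],
    groups: Sequence[str],
    train_fraction: float,
    seed: int,
) -> tuple[set, set]:
    """Split *sample* ids into train/test with no sample crossing sides.

    ``groups`` maps each sample to its product; at least one sample per
    product lands in the training side (the reference-limited deployment
    split: a small training share, the bulk held out).
    """
    if not 0.0 < train_fraction < 1.0:
        raise UsageError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for sid, g in zip(sample_ids, groups):
        by_group.setdefault(g, [])
        if sid not in by_group[g]:
            by_group[g].append(sid)
    train: set = set()
    for g in sorted(by_group):
        sids = by_group[g]
        k = max(1, int(round(train_fraction * len(sids))))
        chosen = rng.choice(len(sids), size=k, replace=False)
        train.update(sids[i] for i in chosen)
    test = {sid for sid in sample_ids if sid not in train}
    return train, test


def indicator_matrix(labels: Sequence[MixtureLabel], vocabulary: Sequence[str]):
    """(n_samples, n_codes) 0/1 matrix over a fixed code vocabulary."""
    vocab = list(vocabulary)
    index = {c: j for j, c in enumerate(vocab)}
    Y = np.zeros((len(labels), len(vocab)))
    for i, lab in enumerate(labels):
        for c in lab:
            if c in index:
                Y[i, index[c]] = 1.0
    return Y
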