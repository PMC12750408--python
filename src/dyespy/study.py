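"""End-to-end synthetic study: build, train, classify, score.

This module stands up the whole platform on generated data: a registry of
pseudo-colorants (primaries, couplers, direct dyes), a product catalog of
dye mixtures with simplified color labels, the three training sets, the
similarity-threshold calibration, and a held-out test run through the full
pipeline.  It is the package's reproducible in-silico analogue of a dyed
hair study — every randomized step derives its stream from one study seed.

It also hosts the spectral-additivity experiment: simulated nonoxidative
dyes reconstruct well from the linear mix of their components while
oxidative dyes do not, and a right-sided Welch test quantifies that gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    ThresholdCalibration,
    WelchResult,
    cosine_similarity,
    shuffle_mixture_ids,
    welch_one_tailed,
    youden_threshold,
)
from .classifiers import (
    MultilabelANN,
    NONOX_ANN_CONFIG,
    OX_ANN_CONFIG,
    make_phase1_model,
)
from .library import (
    ColorantLibrary,
    ColorantRecord,
    DyeProduct,
    MixtureLabel,
    NONOXIDATIVE,
    OXIDATIVE,
    SimulationConfig,
    SpectralLibrary,
    SpectrumTable,
    _derive_seed,
    build_phase1_training,
    build_phase2_nonox_training,
    grouped_train_test_split,
    indicator_matrix,
    random_colorant_spec,
    simulate_control_spectrum,
    simulate_dye_spectrum,
)
from .metrics import NO_COLOR_MATCH
from .pipeline import (
    ColorAssigner,
    Phase3Reference,
    PipelineModels,
    run_pipeline,
)

COLOR_PALETTE = (
    "black", "brown", "dark blue", "red", "pink",
    "purple", "blonde", "green",
)


@dataclass
class StudyConfig:
    """Design of the synthetic study (the study conditions)."""

    n_primaries: int = 5
    n_couplers: int = 8
    n_direct: int = 7
    n_products: int = 30
    oxidative_fraction: float = 0.6
    samples_per_ox_product: int = 5  # for the grouped 20/80 split
    samples_per_nonox_product: int = 2
    spectra_per_sample: int = 5
    spectra_per_nonox_sample: int = 15
    n_controls: int = 3
    spectra_per_control: int = 15
    calibration_samples_per_product: int = 2
    phase1_replicates: int = 4
    phase2_replicates: int = 3
    max_nonox_mixture_size: int = 3
    ox_train_fraction: float = 0.2
    phase1_kind: str = "PLSDA"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def make_demo_library(seed: int, cfg: StudyConfig | None = None):
    """Pseudo-colorant registry plus spectral profiles, seeded."""
    cfg = cfg or StudyConfig()
    primaries = [chr(ord("A") + i) for i in range(cfg.n_primaries)]
    couplers = [2 * chr(ord("A") + i) for i in range(cfg.n_couplers)]
    directs = [chr(ord("A") + i) + "X" for i in range(cfg.n_direct)]
    records = (
        [ColorantRecord(e, f"pseudo-primary {e}", OXIDATIVE, "primary")
         for e in primaries]
        + [ColorantRecord(e, f"pseudo-coupler {e}", OXIDATIVE, "coupler")
           for e in couplers]
        + [ColorantRecord(e, f"pseudo-direct {e}", NONOXIDATIVE, "direct")
           for e in directs]
    )
    library = ColorantLibrary(records)
    sim = cfg.simulation
    specs = {}
    for rec in library:
        rng = np.random.default_rng(_derive_seed(seed, "profile", rec.esid))
        spec = random_colorant_spec(rng)
        spec.noise_sigma = sim.noise_sigma
        spec.jitter = sim.jitter
        specs[rec.esid] = spec
    return library, SpectralLibrary(library, specs)


def make_products(
    library: ColorantLibrary, seed: int, cfg: StudyConfig | None = None
) -> list[DyeProduct]:
    """Random catalog of unique dye products with simplified colors."""
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(_derive_seed(seed, "products"))
    primaries = sorted(r.esid for r in library.by_role("primary"))
    couplers = sorted(r.esid for r in library.by_role("coupler"))
    directs = sorted(r.esid for r in library.by_role("direct"))
    n_ox = int(round(cfg.oxidative_fraction * cfg.n_products))
    products: list[DyeProduct] = []
    seen: set[frozenset] = set()
    i = 0
    while len(products) < cfg.n_products:
        i += 1
        if i > 10_000:
            raise RuntimeError("could not draw enough unique product mixtures")
        oxidative = len(products) < n_ox
        if oxidative:
            n_p = int(rng.integers(1, 3))
            n_c = int(rng.integers(1, 4))
            codes = list(rng.choice(primaries, size=min(n_p, len(primaries)),
                                    replace=False))
            codes += list(rng.choice(couplers, size=min(n_c, len(couplers)),
                                     replace=False))
        else:
            n_d = int(rng.integers(1, cfg.max_nonox_mixture_size + 1))
            codes = list(rng.choice(directs, size=n_d, replace=False))
        mixture = frozenset(codes)
        if mixture in seen:
            continue
        seen.add(mixture)
        color = str(rng.choice(COLOR_PALETTE))
        pid = f"P{len(products) + 1:02d}"
        products.append(
            DyeProduct(
                pid,
                MixtureLabel(mixture),
                color,
                OXIDATIVE if oxidative else NONOXIDATIVE,
            )
        )
    return products


# ---------------------------------------------------------------------------
# additivity experiment
# ---------------------------------------------------------------------------

@dataclass
class AdditivityResult:
    nonox_scores: np.ndarray
    ox_scores: np.ndarray
    welch: WelchResult

    @property
    def nonox_mean(self) -> float:
        return float(self.nonox_scores.mean())

    @property
    def ox_mean(self) -> float:
        return float(self.ox_scores.mean())


def additivity_gap(
    seed: int,
    n_products: int = 50,
    cfg: StudyConfig | None = None,
) -> AdditivityResult:
    """Cosine similarity of simulated dyes to their linear reconstruction.

    Half the products are nonoxidative, half oxidative; each contributes
    one simulated acquisition compared against the equal-weight LASM of its
    clean component profiles.  The right-sided Welch test asks whether
    nonoxidative dyes are more additive.
    """
    cfg = cfg or StudyConfig(n_products=n_products)
    cfg.n_products = n_products
    cfg.oxidative_fraction = 0.5
    library, speclib = make_demo_library(seed, cfg)
    products = make_products(library, seed, cfg)
    nonox, ox = [], []
    for k, product in enumerate(products):
        s = simulate_dye_spectrum(
            product, speclib, _derive_seed(seed, "additivity", k),
            cfg.simulation,
        )
        recon = speclib.lasm_reconstruction(product.mixture)
        score = cosine_similarity(s.intensities, recon.intensities)
        (ox if product.pathway == OXIDATIVE else nonox).append(score)
    nonox = np.array(nonox)
    ox = np.array(ox)
    return AdditivityResult(nonox, ox, welch_one_tailed(nonox, ox, "greater"))


# ---------------------------------------------------------------------------
# full synthetic study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    config: StudyConfig
    products: list[DyeProduct]
    calibration: ThresholdCalibration
    records: list
    verdicts: list
    phase1_sample_accuracy: float
    phase2_nonox_subset_recall: float
    phase2_ox_subset_recall: float
    phase2_accuracy: float
    phase3_accuracy: float
    controls_all_no_color_match: bool
    n_test_samples: int
    n_control_samples: int

    def summary(self) -> dict:
        return {
            "phase1_sample_accuracy": self.phase1_sample_accuracy,
            "phase2_nonox_subset_recall": self.phase2_nonox_subset_recall,
            "phase2_ox_subset_recall": self.phase2_ox_subset_recall,
            "phase2_accuracy": self.phase2_accuracy,
            "phase3_accuracy": self.phase3_accuracy,
            "calibration_accuracy": self.calibration.accuracy,
            "calibration_threshold": self.calibration.threshold,
            "controls_all_no_color_match": float(self.controls_all_no_color_match),
            "n_test_samples": self.n_test_samples,
        }


def _simulate_sample(
    product: DyeProduct,
    speclib: SpectralLibrary,
    sample_id: str,
    n_spectra: int,
    seed: int,
    sim: SimulationConfig,
) -> list:
    return [
        simulate_dye_spectrum(
            product, speclib, _derive_seed(seed, sample_id, k), sim,
            spectrum_id=f"{sample_id}_{k}", sample_id=sample_id,
        )
        for k in range(n_spectra)
    ]


def train_models(
    seed: int, cfg: StudyConfig | None = None
) -> tuple[PipelineModels, dict]:
    """Train all pipeline assets on synthetic data; return models + context.

    The context dict carries the library, products, truth maps, the ox
    train/test tables, and the threshold calibration — everything the
    study (or a caller wanting the trained pipeline) needs downstream.
    """
    cfg = cfg or StudyConfig()
    sim = cfg.simulation
    library, speclib = make_demo_library(seed, cfg)
    products = make_products(library, seed, cfg)
    ox_products = [p for p in products if p.pathway == OXIDATIVE]
    nonox_products = [p for p in products if p.pathway == NONOXIDATIVE]

    # Phase I: pure colorants + primary x coupler pairs
    p1 = build_phase1_training(
        speclib, n_replicates=cfg.phase1_replicates,
        seed=_derive_seed(seed, "p1"), sim=sim,
    )
    phase1 = make_phase1_model(cfg.phase1_kind, seed=_derive_seed(seed, "p1m"))
    phase1.fit(p1.table.to_matrix(), np.array(p1.labels))

    # Phase II nonoxidative: LASM mixtures over direct-dye subsets
    nonox_vocab = sorted(r.esid for r in library.by_role("direct"))
    p2n = build_phase2_nonox_training(
        speclib, max_subset_size=cfg.max_nonox_mixture_size,
        n_replicates=cfg.phase2_replicates,
        seed=_derive_seed(seed, "p2n"), sim=sim,
    )
    phase2_nonox = MultilabelANN(
        vocabulary=nonox_vocab, config=NONOX_ANN_CONFIG,
        random_state=_derive_seed(seed, "p2n-net"),
    )
    phase2_nonox.fit(
        p2n.table.to_matrix(), indicator_matrix(p2n.labels, nonox_vocab)
    )

    # Phase II oxidative: simulated dyed samples, grouped small-train split
    ox_vocab = sorted(
        r.esid for r in library if r.role in ("primary", "coupler")
    )
    ox_spectra, ox_sample_ids, ox_groups, ox_labels = [], [], [], []
    sample_truth: dict[str, DyeProduct] = {}
    for p in ox_products:
        for j in range(cfg.samples_per_ox_product):
            sid = f"{p.product_id}_s{j}"
            sample_truth[sid] = p
            spectra = _simulate_sample(
                p, speclib, sid, cfg.spectra_per_sample,
                _derive_seed(seed, "ox"), sim,
            )
            ox_spectra += spectra
            ox_sample_ids += [sid] * len(spectra)
            ox_groups += [p.product_id] * len(spectra)
            ox_labels += [p.mixture] * len(spectra)
    train_sids, _ = grouped_train_test_split(
        ox_sample_ids, ox_groups, cfg.ox_train_fraction,
        _derive_seed(seed, "oxsplit"),
    )
    train_mask = np.array([sid in train_sids for sid in ox_sample_ids])
    X_ox = np.vstack([s.intensities for s in ox_spectra])
    Y_ox = indicator_matrix(ox_labels, ox_vocab)
    phase2_ox = MultilabelANN(
        vocabulary=ox_vocab, config=OX_ANN_CONFIG,
        random_state=_derive_seed(seed, "p2o-net"),
    )
    phase2_ox.fit(X_ox[train_mask], Y_ox[train_mask])

    # Phase III references: centroids of dedicated reference samples
    ref_matrices, colors, mixtures = {}, {}, {}
    for p in products:
        spectra = _simulate_sample(
            p, speclib, f"{p.product_id}_ref", cfg.spectra_per_sample,
            _derive_seed(seed, "ref"), sim,
        )
        ref_matrices[p.product_id] = np.vstack([s.intensities for s in spectra])
        colors[p.product_id] = p.color
        mixtures[p.product_id] = p.mixture
    references = [
        Phase3Reference(
            mixture=mixtures[pid], color=colors[pid],
            centroid=ref_matrices[pid].mean(axis=0), members=ref_matrices[pid],
        )
        for pid in sorted(ref_matrices)
    ]

    # Shuffled-null calibration on held-aside calibration samples
    centroid = {p.product_id: ref_matrices[p.product_id].mean(axis=0)
                for p in products}
    cal_ids, cal_means = [], []
    for p in products:
        for j in range(cfg.calibration_samples_per_product):
            sid = f"{p.product_id}_cal{j}"
            spectra = _simulate_sample(
                p, speclib, sid, cfg.spectra_per_sample,
                _derive_seed(seed, "cal"), sim,
            )
            cal_ids.append(p.product_id)
            cal_means.append(
                np.mean([s.intensities for s in spectra], axis=0)
            )
    true_scores = [
        cosine_similarity(m, centroid[pid]) for m, pid in zip(cal_means, cal_ids)
    ]
    shuffled = shuffle_mixture_ids(cal_ids, _derive_seed(seed, "shuffle"))
    false_scores = [
        cosine_similarity(m, centroid[pid]) for m, pid in zip(cal_means, shuffled)
    ]
    calibration = youden_threshold(true_scores, false_scores)

    models = PipelineModels(
        phase1=phase1,
        phase2_nonox=phase2_nonox,
        phase2_ox=phase2_ox,
        phase3=ColorAssigner(references, calibration.threshold),
        substrate="hair",
    )
    context = {
        "library": library,
        "speclib": speclib,
        "products": products,
        "ox_products": ox_products,
        "nonox_products": nonox_products,
        "ox_spectra": ox_spectra,
        "ox_sample_ids": ox_sample_ids,
        "train_sids": train_sids,
        "sample_truth": sample_truth,
        "calibration": calibration,
        "config": cfg,
    }
    return models, context


def run_synthetic_study(
    seed: int,
    cfg: StudyConfig | None = None,
    pretrained: tuple[PipelineModels, dict] | None = None,
) -> StudyResult:
    """Train on synthetic data and score a held-out test run.

    ``pretrained`` may supply the ``(models, context)`` pair from
    :func:`train_models` (same seed and config) to skip retraining.
    """
    cfg = cfg or StudyConfig()
    models, ctx = pretrained if pretrained is not None else train_models(seed, cfg)
    speclib: SpectralLibrary = ctx["speclib"]
    sim = cfg.simulation
    sample_truth: dict[str, DyeProduct] = dict(ctx["sample_truth"])

    # Held-out test spectra: ox samples not in the training split,
    # fresh nonoxidative samples, and undyed negative controls.
    test_spectra = [
        s for s, sid in zip(ctx["ox_spectra"], ctx["ox_sample_ids"])
        if sid not in ctx["train_sids"]
    ]
    for p in ctx["nonox_products"]:
        for j in range(cfg.samples_per_nonox_product):
            sid = f"{p.product_id}_t{j}"
            sample_truth[sid] = p
            test_spectra += _simulate_sample(
                p, speclib, sid, cfg.spectra_per_nonox_sample,
                _derive_seed(seed, "nonox-test"), sim,
            )
    control_ids = []
    for j in range(cfg.n_controls):
        sid = f"NC{j}"
        control_ids.append(sid)
        test_spectra += [
            simulate_control_spectrum(
                speclib, _derive_seed(seed, "nc", sid, k), sim,
                spectrum_id=f"{sid}_{k}", sample_id=sid,
            )
            for k in range(cfg.spectra_per_control)
        ]

    table = SpectrumTable(test_spectra, grid=speclib.grid)
    records, verdicts = run_pipeline(table, models, already_preprocessed=True)

    dyed = [v for v in verdicts if v.sample_id in sample_truth]
    controls = [v for v in verdicts if v.sample_id in control_ids]

    p1_hits = [
        (not v.phase1.ic) and v.phase1.label == sample_truth[v.sample_id].pathway
        for v in dyed
    ]
    phase1_sample_accuracy = float(np.mean(p1_hits))

    def _subset_hits(pathway: str) -> list[float]:
        hits = []
        for v, ok in zip(dyed, p1_hits):
            truth = sample_truth[v.sample_id]
            if truth.pathway != pathway or not ok:
                continue
            pred = v.phase2.label
            hit = (
                pred is not None
                and not pred.is_empty
                and len(pred.esids & truth.mixture.esids) >= 1
            )
            hits.append(float(hit))
        return hits

    nonox_hits = _subset_hits(NONOXIDATIVE)
    ox_hits = _subset_hits(OXIDATIVE)

    def _partial(v, truth) -> float:
        pred = v.phase2.label
        if pred is None or pred.is_empty:
            return 0.0
        return len(pred.esids & truth.mixture.esids) / len(pred.esids)

    scored = [
        (v, sample_truth[v.sample_id])
        for v, ok in zip(dyed, p1_hits) if ok
    ]
    phase2_acc = float(np.mean([_partial(v, t) for v, t in scored]))

    def _p3_score(v, truth) -> float:
        if v.phase3.ic:
            return 0.0
        exact = v.phase2.label is not None and v.phase2.label == truth.mixture
        if v.phase3.label == NO_COLOR_MATCH:
            return 0.0 if exact else 1.0
        return 1.0 if v.phase3.label == truth.color else 0.0

    phase3_acc = float(np.mean([_p3_score(v, t) for v, t in scored]))

    controls_clean = all(
        (not v.phase3.ic) and v.phase3.label == NO_COLOR_MATCH for v in controls
    )

    return StudyResult(
        config=cfg,
        products=ctx["products"],
        calibration=ctx["calibration"],
        records=records,
        verdicts=verdicts,
        phase1_sample_accuracy=phase1_sample_accuracy,
        phase2_nonox_subset_recall=float(np.mean(nonox_hits)) if nonox_hits else 0.0,
        phase2_ox_subset_recall=float(np.mean(ox_hits)) if ox_hits else 0.0,
        phase2_accuracy=phase2_acc,
        phase3_accuracy=phase3_acc,
        controls_all_no_color_match=controls_clean,
        n_test_samples=len(dyed),
        n_control_samples=len(controls),
    )
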