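"""Tiered classification pipeline and sample-level aggregation.

Each spectrum is preprocessed and then routed through three phases:

* **Phase I** — binary pathway call (oxidative vs nonoxidative).  The call
  is made per spectrum, so spectra of one sample may take different
  branches; the sample verdict is recomputed per phase.
* **Phase II** — the Phase I label selects the branch-specific multi-label
  mixture model; an all-below-threshold output is 'No Match'.
* **Phase III** — cosine similarity between the spectrum and the centroid
  of the reference dye class whose mixture equals the Phase II call.  At or
  above the calibrated threshold the class's simplified color is assigned;
  below it — or when the mixture is empty or unknown — the conservative
  'No Color Match' is returned.

Sample aggregation takes the modal label per phase; support <= 50% (ties
included) yields the inconclusive (IC) verdict.  Samples with fewer than
15 spectra are processed but flagged against the recommended minimum
(5 spectra per strand, 3 strands).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .calibration import cosine_similarity
from .classifiers import (
    CosineNearestNeighborClassifier,
    MultilabelANN,
    predict_multilabel,
)
from .exceptions import ConfigurationError, UsageError
from .library import MixtureLabel, NONOXIDATIVE, OXIDATIVE
from .metrics import NO_COLOR_MATCH
from .preprocess import PreprocessConfig, preprocess_table
from .spectra import Spectrum, SpectrumTable

#: Recommended minimum spectra per sample (5 per strand x 3 strands).
MIN_RECOMMENDED_SPECTRA = 15


@dataclass
class PredictionRecord:
    """Per-spectrum path through the three phases."""

    spectrum_id: str
    sample_id: str
    phase1_label: str
    phase1_score: float
    phase2_mixture: MixtureLabel
    phase3_color: str
    phase3_similarity: float | None = None

    @property
    def phase2_mixture_text(self) -> str:
        return str(self.phase2_mixture)


@dataclass
class PhaseVerdict:
    """Sample-level outcome of one phase."""

    label: object = None  # None when inconclusive
    support: float = 0.0
    ic: bool = False
    distribution: dict = field(default_factory=dict)


@dataclass
class SampleVerdict:
    sample_id: str
    n_spectra: int
    phase1: PhaseVerdict
    phase2: PhaseVerdict
    phase3: PhaseVerdict
    low_spectra_warning: bool = False


def aggregate_sample(labels) -> PhaseVerdict:
    """Modal label with support fraction; support <= 0.5 or a tie -> IC."""
    labels = list(labels)
    if not labels:
        raise UsageError("aggregate_sample needs >= 1 record")
    counts = Counter(labels)
    total = len(labels)
    (top, top_n), *rest = counts.most_common()
    support = top_n / total
    tie = bool(rest) and rest[0][1] == top_n
    distribution = {_text(lbl): n / total for lbl, n in counts.items()}
    if support <= 0.5 or tie:
        return PhaseVerdict(None, support, True, distribution)
    return PhaseVerdict(top, support, False, distribution)


def _text(label) -> str:
    return str(label)


@dataclass
class Phase3Reference:
    """One reference dye class: its mixture, color, and centroid spectrum."""

    mixture: MixtureLabel
    color: str
    centroid: np.ndarray
    members: np.ndarray | None = None  # optional per-instance reference rows


class ColorAssigner:
    """Phase III: similarity-gated color lookup against reference classes."""

    def __init__(
        self,
        references: list[Phase3Reference],
        threshold: float,
        use_centroid: bool = True,
    ):
        self.references = {r.mixture: r for r in references}
        self.threshold = float(threshold)
        self.use_centroid = use_centroid

    def assign(self, mixture: MixtureLabel, query) -> tuple[str, float | None]:
        """(color or 'No Color Match', similarity or None)."""
        if mixture is None or mixture.is_empty:
            return NO_COLOR_MATCH, None
        ref = self.references.get(mixture)
        if ref is None:
            return NO_COLOR_MATCH, None
        q = query.intensities if isinstance(query, Spectrum) else np.asarray(query)
        if self.use_centroid or ref.members is None:
            sim = cosine_similarity(q, ref.centroid)
        else:
            sims = [cosine_similarity(q, m) for m in ref.members]
            sim = float(max(sims))
        if sim >= self.threshold:
            return ref.color, sim
        return NO_COLOR_MATCH, sim


def assign_color(
    mixture: MixtureLabel, references: list[Phase3Reference], query, threshold: float
) -> tuple[str, float | None]:
    """Functional form of :meth:`ColorAssigner.assign`."""
    return ColorAssigner(references, threshold).assign(mixture, query)


@dataclass
class PipelineModels:
    """The trained assets one substrate's pipeline needs."""

    phase1: object  # fitted binary classifier
    phase2_nonox: MultilabelANN
    phase2_ox: MultilabelANN
    phase3: ColorAssigner
    substrate: str = "hair"

    def validate(self) -> None:
        for name, attr in (
            ("Phase I", self.phase1),
            ("Phase II nonoxidative", self.phase2_nonox),
            ("Phase II oxidative", self.phase2_ox),
            ("Phase III", self.phase3),
        ):
            if attr is None:
                raise ConfigurationError(f"missing model asset for {name}")


def _phase1_score(model, x) -> float:
    """Confidence of the predicted class, in [0, 1] where available."""
    X = np.atleast_2d(x)
    if hasattr(model, "predict_proba"):
        return float(np.max(model.predict_proba(X)))
    if isinstance(model, CosineNearestNeighborClassifier):
        return float(model.classify(x)[1])
    return 1.0


def run_pipeline(
    table: SpectrumTable,
    models: PipelineModels,
    preprocess_cfg: PreprocessConfig | None = None,
    already_preprocessed: bool = False,
) -> tuple[list[PredictionRecord], list[SampleVerdict]]:
    """Classify every spectrum of a table and aggregate per sample.

    Routing is exhaustive and exclusive: each spectrum takes exactly one
    Phase II branch, chosen by its own Phase I label.
    """
    models.validate()
    if not already_preprocessed:
        table = preprocess_table(table, preprocess_cfg)

    records: list[PredictionRecord] = []
    for s in table:
        x = s.intensities
        label = str(models.phase1.predict(np.atleast_2d(x))[0])
        score = _phase1_score(models.phase1, x)
        branch = models.phase2_nonox if label == NONOXIDATIVE else models.phase2_ox
        mixture = predict_multilabel(branch, x)
        color, sim = models.phase3.assign(mixture, s)
        records.append(
            PredictionRecord(
                spectrum_id=s.spectrum_id,
                sample_id=s.sample_id,
                phase1_label=label,
                phase1_score=score,
                phase2_mixture=mixture,
                phase3_color=color,
                phase3_similarity=sim,
            )
        )

    verdicts: list[SampleVerdict] = []
    for sample_id, recs in _group_by_sample(records).items():
        v = SampleVerdict(
            sample_id=sample_id,
            n_spectra=len(recs),
            phase1=aggregate_sample([r.phase1_label for r in recs]),
            phase2=aggregate_sample([r.phase2_mixture for r in recs]),
            phase3=aggregate_sample([r.phase3_color for r in recs]),
            low_spectra_warning=len(recs) < MIN_RECOMMENDED_SPECTRA,
        )
        if v.low_spectra_warning:
            warnings.warn(
                f"sample {sample_id!r}: {len(recs)} spectra, below the "
                f"recommended minimum of {MIN_RECOMMENDED_SPECTRA}",
                stacklevel=2,
            )
        verdicts.append(v)
    return records, verdicts


def _group_by_sample(records) -> dict[str, list[PredictionRecord]]:
    out: dict[str, list[PredictionRecord]] = {}
    for r in records:
        out.setdefault(r.sample_id, []).append(r)
    return out


def build_phase3_references(
    tables_by_product: dict, colors: dict, mixtures: dict
) -> list[Phase3Reference]:
    """Centroid references from per-product reference spectra.

    ``tables_by_product`` maps product_id -> (n, d) matrix of preprocessed
    reference spectra; ``mixtures``/``colors`` map product_id to its
    mixture label and simplified color.
    """
    refs = []
    for pid in sorted(tables_by_product):
        X = np.asarray(tables_by_product[pid], dtype=float)
        refs.append(
            Phase3Reference(
                mixture=mixtures[pid],
                color=colors[pid],
                centroid=X.mean(axis=0),
                members=X,
            )
        )
    return refs
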